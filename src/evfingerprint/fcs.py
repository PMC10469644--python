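"""Minimal FCS 3.1 list-mode reader/writer.

Supports what the package needs: MODE L, DATATYPE F or D, a single dataset
per file, little- or big-endian byte order, and the standard ``$VOL`` keyword
(acquisition volume in nanolitres).  Package-specific metadata travels in
non-``$`` keywords (``EVFDILUTION``, ``EVFPATIENT``, ``EVFREPLICATE``,
``EVFDURATION``) so that files remain standard-conforming.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError

_HEADER_LEN = 58
_DELIM = "/"


def write_fcs(path, data: pd.DataFrame, *, volume_ul: float, dilution_factor: float,
              patient_id: str = "", replicate_id: int = 0,
              duration_s: float | None = None) -> None:
    """Write an event matrix (rows = events, columns = channels) as FCS 3.1.

    Intensities are stored as little-endian float32; channel names go into
    the ``$PnN`` keywords.
    """
    arr = np.asarray(data, dtype="<f4")
    n_events, n_par = arr.shape
    keywords = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par), "$TOT": str(n_events),
        "$VOL": repr(float(volume_ul) * 1000.0),  # nanolitres per the standard
        "EVFDILUTION": repr(float(dilution_factor)),
        "EVFPATIENT": str(patient_id),
        "EVFREPLICATE": str(replicate_id),
    }
    if duration_s is not None:
        keywords["EVFDURATION"] = repr(float(duration_s))
    for i, name in enumerate(data.columns, start=1):
        keywords[f"$P{i}N"] = str(name)
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = repr(float(np.nanmax(arr[:, i - 1])) + 1.0 if n_events else 1.0)

    # $BEGINDATA/$ENDDATA live inside TEXT; fixed-width values keep the
    # segment length independent of the offsets themselves.
    def render(begin_data: int, end_data: int) -> bytes:
        kw = dict(keywords)
        kw["$BEGINDATA"] = f"{begin_data:010d}"
        kw["$ENDDATA"] = f"{end_data:010d}"
        parts = [_DELIM]
        for k, v in kw.items():
            parts.append(f"{k}{_DELIM}{v if v != '' else ' '}{_DELIM}")
        return "".join(parts).encode("ascii")

    text = render(0, 0)
    text_begin = _HEADER_LEN
    text_end = text_begin + len(text) - 1
    data_begin = text_begin + len(text)
    data_end = data_begin + arr.nbytes - 1 if arr.nbytes else data_begin
    text = render(data_begin, data_end)

    if data_end > 99_999_999:
        raise FormatError("FCS data segment too large for 8-character header offsets")
    header = (b"FCS3.1    "
              + f"{text_begin:8d}".encode() + f"{text_end:8d}".encode()
              + f"{data_begin:8d}".encode() + f"{data_end:8d}".encode()
              + f"{0:8d}".encode() + f"{0:8d}".encode())
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(arr.tobytes())


def read_fcs(path):
    """Read a list-mode FCS 3.0/3.1 file.

    Returns ``(data, keywords)`` where ``data`` is a DataFrame with one column
    per ``$PnN`` channel and ``keywords`` is the raw TEXT-segment dictionary.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER_LEN or not raw[:6].startswith(b"FCS3"):
        raise FormatError(f"{path}: not an FCS 3.x file")
    try:
        offsets = [int(raw[10 + 8 * i: 18 + 8 * i]) for i in range(4)]
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FCS header offsets") from exc
    text_begin, text_end, data_begin, data_end = offsets
    text = raw[text_begin: text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    fields = text[1:].split(delim)
    if fields and fields[-1] == "":
        fields = fields[:-1]
    keywords = {fields[i].strip(): fields[i + 1] for i in range(0, len(fields) - 1, 2)}

    if keywords.get("$MODE", "L") != "L":
        raise FormatError(f"{path}: only list mode ($MODE/L) is supported")
    if data_begin == 0:
        data_begin = int(keywords["$BEGINDATA"])
        data_end = int(keywords["$ENDDATA"])
    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    dtype_char = {"F": "f4", "D": "f8"}.get(keywords.get("$DATATYPE", "F"))
    if dtype_char is None:
        raise FormatError(f"{path}: unsupported $DATATYPE {keywords.get('$DATATYPE')!r}")
    order = "<" if keywords.get("$BYTEORD", "1,2,3,4").startswith("1") else ">"
    buf = raw[data_begin: data_end + 1]
    arr = np.frombuffer(buf, dtype=order + dtype_char, count=n_tot * n_par)
    arr = arr.reshape(n_tot, n_par).astype(float)
    names = [keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(arr, columns=names), keywords
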