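"""Event-level microflow-cytometry data and ROI particle-concentration features.

A single-EV flow cytometry run records, per detected particle, two light
scatter intensities (LALS, SALS — proxies for particle size) and three marker
fluorescence intensities (PSMA antibody, ghrelin peptide probe, polysialic
acid antibody).  Each patient's replicates are reduced to a fixed-length
feature vector: intensities are log10-transformed, binned into a 16x16 grid
for four channel pairs, and the event count in each of the 4 x 256 regions of
interest (ROIs) is converted to a particle concentration (events per uL of
undiluted plasma) and averaged over replicates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fcs
from .errors import ConfigurationError, FormatError, InputError

#: Canonical channel names ($PnN keywords in serialized files).
CHANNELS = ("LALS", "SALS", "FL-PSMA", "FL-GHRL", "FL-PSA2")

#: The four bivariate histograms, in fixed order: scatter vs PSMA, scatter vs
#: ghrelin, PSMA vs ghrelin, scatter vs polysialic acid.
DEFAULT_CHANNEL_PAIRS = (
    ("LALS", "FL-PSMA"),
    ("LALS", "FL-GHRL"),
    ("FL-PSMA", "FL-GHRL"),
    ("LALS", "FL-PSA2"),
)

#: Default per-channel log10 intensity range used for fixed-range binning.
DEFAULT_LOG_RANGE = (0.0, 4.0)


@dataclass
class EventTable:
    """Per-replicate event intensities plus acquisition metadata.

    ``data`` holds one row per detected event with the five channel columns;
    ``acquisition_volume_ul`` is the volume of *diluted* sample interrogated
    (flow rate x acquisition duration), and ``dilution_factor`` the fold
    dilution of plasma before acquisition.
    """

    data: pd.DataFrame
    acquisition_volume_ul: float
    dilution_factor: float
    patient_id: str = ""
    replicate_id: int = 0
    duration_used_s: float | None = None

    def __post_init__(self) -> None:
        if self.acquisition_volume_ul <= 0:
            raise InputError("acquisition_volume_ul must be > 0")
        if self.dilution_factor < 1:
            raise InputError("dilution_factor must be >= 1")
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise FormatError(f"event table missing channels: {', '.join(missing)}")

    @property
    def n_events(self) -> int:
        return len(self.data)

    def equals(self, other: "EventTable") -> bool:
        return (self.n_events == other.n_events
                and np.allclose(self.data[list(CHANNELS)].to_numpy(),
                                other.data[list(CHANNELS)].to_numpy(), rtol=1e-6)
                and np.isclose(self.acquisition_volume_ul, other.acquisition_volume_ul)
                and np.isclose(self.dilution_factor, other.dilution_factor))


@dataclass
class HistogramSpec:
    """Binning specification for the four bivariate ROI histograms."""

    channel_pairs: tuple = DEFAULT_CHANNEL_PAIRS
    n_bins: int = 16
    bin_edges: dict | None = None  # channel -> strictly increasing log10 edges
    log_floor: float | None = None  # clamp for nonpositive intensities; None = adaptive
    frozen: bool = False

    def __post_init__(self) -> None:
        if len(self.channel_pairs) != 4:
            raise ConfigurationError("channel_pairs: exactly 4 bivariate pairs required")
        if self.n_bins < 1:
            raise ConfigurationError("n_bins must be >= 1")
        if self.bin_edges is not None:
            for ch, edges in self.bin_edges.items():
                edges = np.asarray(edges, dtype=float)
                if len(edges) != self.n_bins + 1:
                    raise ConfigurationError(
                        f"bin_edges[{ch}]: need n_bins+1 = {self.n_bins + 1} edges")
                if not np.all(np.diff(edges) > 0):
                    raise ConfigurationError(f"bin_edges[{ch}]: edges must be strictly increasing")

    @property
    def n_features(self) -> int:
        return 4 * self.n_bins ** 2

    def edges_for(self, channel: str) -> np.ndarray:
        if self.bin_edges is not None and channel in self.bin_edges:
            return np.asarray(self.bin_edges[channel], dtype=float)
        return np.linspace(*DEFAULT_LOG_RANGE, self.n_bins + 1)

    def with_edges(self, edges: dict) -> "HistogramSpec":
        """Return a frozen copy using ``edges``; warns if already frozen.

        Edges must be fit once, on training data only, and reused unchanged
        for every later patient — refitting on evaluation data leaks.
        """
        if self.frozen:
            warnings.warn("replacing bin edges on a frozen HistogramSpec; "
                          "refitting edges on evaluation data leaks information",
                          stacklevel=2)
        return replace(self, bin_edges=edges, frozen=True)

    def feature_names(self) -> list:
        return [f"h{h + 1}_r{r}_c{c}"
                for h in range(4)
                for r in range(self.n_bins)
                for c in range(self.n_bins)]


@dataclass
class ROIFeatureVector:
    """Replicate-averaged ROI particle concentrations for one patient."""

    patient_id: str
    values: np.ndarray
    feature_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.feature_names) != len(self.values):
            raise InputError("feature_names and values length mismatch")
        if np.any(self.values < 0):
            raise InputError("ROI concentrations must be non-negative")


def _log10_clamped(x: np.ndarray, floor: float | None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if floor is None:
        pos = x[x > 0]
        floor = 0.5 * pos.min() if pos.size else 1e-6
    return np.log10(np.maximum(x, floor))


def _bin_indices(values: np.ndarray, edges: np.ndarray, n_bins: int) -> np.ndarray:
    # np.digitize is right-open; out-of-range events clamp into the outer bins
    # so that no event is ever discarded (conservation of particle counts).
    idx = np.digitize(values, edges) - 1
    return np.clip(idx, 0, n_bins - 1)


def _histogram_counts(table: EventTable, spec: HistogramSpec) -> np.ndarray:
    """Raw ROI event counts, shape (4, n_bins, n_bins)."""
    nb = spec.n_bins
    out = np.zeros((4, nb, nb), dtype=float)
    if table.n_events == 0:
        return out
    logged = {}
    for ch in CHANNELS:
        logged[ch] = _log10_clamped(table.data[ch].to_numpy(), spec.log_floor)
    for h, (ch_row, ch_col) in enumerate(spec.channel_pairs):
        r = _bin_indices(logged[ch_row], spec.edges_for(ch_row), nb)
        c = _bin_indices(logged[ch_col], spec.edges_for(ch_col), nb)
        np.add.at(out[h], (r, c), 1.0)
    return out


def build_roi_features(replicates, spec: HistogramSpec | None = None) -> ROIFeatureVector:
    """Reduce one patient's replicate event tables to the ROI feature vector.

    Per replicate, each ROI count is divided by the volume of undiluted plasma
    interrogated (``acquisition_volume / dilution_factor``); the resulting
    concentrations are then averaged element-wise across replicates.
    """
    spec = spec or HistogramSpec()
    replicates = list(replicates)
    if not replicates:
        raise InputError("at least one replicate EventTable is required")
    patient_ids = {t.patient_id for t in replicates}
    if len(patient_ids) > 1:
        raise InputError(f"replicates span multiple patients: {sorted(patient_ids)}")
    conc = np.zeros(spec.n_features, dtype=float)
    for table in replicates:
        counts = _histogram_counts(table, spec).ravel()
        plasma_volume = table.acquisition_volume_ul / table.dilution_factor
        conc += counts / plasma_volume
    conc /= len(replicates)
    return ROIFeatureVector(patient_id=replicates[0].patient_id, values=conc,
                            feature_names=spec.feature_names())


def fit_bin_edges(training_tables, n_bins: int = 16, strategy: str = "fixed",
                  log_range: tuple = DEFAULT_LOG_RANGE, channels=CHANNELS,
                  log_floor: float | None = None, pool: str = "training") -> dict:
    """Fit per-channel log10 bin edges.

    ``"fixed"`` ignores the data and spaces ``n_bins + 1`` edges evenly over
    ``log_range`` (deterministic, leakage-proof — the default downstream).
    ``"quantile"`` places edges at equispaced quantiles of the pooled training
    intensities; those edges must be frozen and reused for all later data.
    """
    if pool != "training":
        warnings.warn(f"fitting bin edges on a {pool!r} pool: evaluation data must "
                      "never inform edge placement", stacklevel=2)
    if strategy == "fixed":
        edges = np.linspace(log_range[0], log_range[1], n_bins + 1)
        return {ch: edges.copy() for ch in channels}
    if strategy != "quantile":
        raise ConfigurationError(f"unknown edge strategy {strategy!r}")
    tables = list(training_tables)
    if not tables:
        raise InputError("quantile strategy requires at least one training table")
    out = {}
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    for ch in channels:
        pooled = np.concatenate([_log10_clamped(t.data[ch].to_numpy(), log_floor)
                                 for t in tables])
        if np.unique(pooled).size < n_bins:
            raise InputError(f"channel {ch}: fewer than n_bins distinct values; "
                             "quantile edges would be degenerate")
        edges = np.quantile(pooled, qs)
        # enforce strict monotonicity under heavy ties
        eps = 1e-9 * max(1.0, np.abs(edges).max())
        for i in range(1, len(edges)):
            if edges[i] <= edges[i - 1]:
                edges[i] = edges[i - 1] + eps
        out[ch] = edges
    return out


# ---------------------------------------------------------------------------
# I/O: FCS 3.1 and a plain-text tabular dialect
# ---------------------------------------------------------------------------

def write_events(table: EventTable, path, format: str = "csv") -> None:
    """Serialize an EventTable as FCS 3.1 or as CSV with ``# key=value`` metadata."""
    if format == "fcs":
        fcs.write_fcs(path, table.data[list(CHANNELS)],
                      volume_ul=table.acquisition_volume_ul,
                      dilution_factor=table.dilution_factor,
                      patient_id=table.patient_id, replicate_id=table.replicate_id,
                      duration_s=table.duration_used_s)
        return
    if format != "csv":
        raise ConfigurationError(f"unknown event format {format!r}")
    with open(path, "w") as fh:
        fh.write(f"# acquisition_volume_ul={table.acquisition_volume_ul!r}\n")
        fh.write(f"# dilution_factor={table.dilution_factor!r}\n")
        fh.write(f"# patient_id={table.patient_id}\n")
        fh.write(f"# replicate_id={table.replicate_id}\n")
        table.data[list(CHANNELS)].to_csv(fh, index=False)


def read_events(path, format: str = "auto", channel_map: dict | None = None,
                acquisition_volume_ul: float | None = None,
                dilution_factor: float | None = None,
                patient_id: str | None = None,
                replicate_id: int | None = None) -> EventTable:
    """Read an event table from FCS or the CSV dialect.

    ``channel_map`` renames file channels to the canonical names.  Acquisition
    metadata comes from file keywords / header comments; explicit arguments
    override.  A missing channel or missing volume metadata raises
    :class:`FormatError` — there is no silent default volume.
    """
    path = str(path)
    if format == "auto":
        with open(path, "rb") as fh:
            format = "fcs" if fh.read(6).startswith(b"FCS3") else "csv"
    meta: dict = {}
    if format == "fcs":
        data, kw = fcs.read_fcs(path)
        if "$VOL" in kw:
            meta["acquisition_volume_ul"] = float(kw["$VOL"]) / 1000.0
        if "EVFDILUTION" in kw:
            meta["dilution_factor"] = float(kw["EVFDILUTION"])
        meta["patient_id"] = kw.get("EVFPATIENT", "")
        meta["replicate_id"] = int(kw.get("EVFREPLICATE", 0))
        if "EVFDURATION" in kw:
            meta["duration_used_s"] = float(kw["EVFDURATION"])
    elif format == "csv":
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
        data = pd.read_csv(path, comment="#")
        for k in ("acquisition_volume_ul", "dilution_factor"):
            if k in meta:
                meta[k] = float(meta[k])
        if "replicate_id" in meta:
            meta["replicate_id"] = int(meta["replicate_id"])
    else:
        raise ConfigurationError(f"unknown event format {format!r}")

    if channel_map:
        data = data.rename(columns=channel_map)
    missing = [c for c in CHANNELS if c not in data.columns]
    if missing:
        raise FormatError(f"{path}: missing channel(s) {', '.join(missing)}")

    volume = acquisition_volume_ul if acquisition_volume_ul is not None \
        else meta.get("acquisition_volume_ul")
    if volume is None:
        raise FormatError(f"{path}: acquisition volume metadata absent; pass "
                          "acquisition_volume_ul explicitly")
    dilution = dilution_factor if dilution_factor is not None \
        else meta.get("dilution_factor")
    if dilution is None:
        raise FormatError(f"{path}: dilution factor metadata absent; pass "
                          "dilution_factor explicitly")
    return EventTable(
        data=data, acquisition_volume_ul=float(volume), dilution_factor=float(dilution),
        patient_id=patient_id if patient_id is not None else str(meta.get("patient_id", "")),
        replicate_id=replicate_id if replicate_id is not None else int(meta.get("replicate_id", 0)),
        duration_used_s=meta.get("duration_used_s"))


def features_to_frame(vectors) -> pd.DataFrame:
    """Stack ROIFeatureVectors into a patient x feature DataFrame."""
    vectors = list(vectors)
    if not vectors:
        raise InputError("no feature vectors given")
    names = vectors[0].feature_names
    rows = {}
    for v in vectors:
        if v.feature_names != names:
            raise InputError(f"feature name mismatch for patient {v.patient_id}")
        rows[v.patient_id] = v.values
    df = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    df.index.name = "patient_id"
    return df
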