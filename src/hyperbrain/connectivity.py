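"""Phase-locking-value (PLV) connectivity from epoched ROI time series.

The pipeline mirrors standard MEG/EEG practice: band-pass each epoch
(zero-phase Butterworth), take the analytic-signal angle as the
instantaneous phase, compute the per-epoch modulus of the time-averaged
unit phasor of the phase difference for every source pair, average
moduli across epochs, and average across source pairs within an ROI
pair.  Thresholding turns a PLV matrix into a binary graph; min-max
scaling of the off-diagonal PLV values yields continuous edge-probability
targets for decoder training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

logger = logging.getLogger(__name__)

__all__ = [
    "EpochedSignals", "PhaseSeries", "RoiMap", "ConnectivityMatrix",
    "BrainGraph", "instantaneous_phase", "plv_pair", "build_connectivity",
    "threshold_to_graph", "scale_to_probabilities", "DegenerateRangeError",
    "read_connectivity", "write_connectivity", "read_graph", "write_graph",
    "load_signals",
]

DEFAULT_THRESHOLD = 0.329   # retains ~20% of edges on the study's PLV scale
DEFAULT_EDGE_TRIM = 0.05    # fraction of samples dropped at each epoch edge


class DegenerateRangeError(ValueError):
    """Raised when min-max scaling is requested on a constant matrix."""


@dataclass
class EpochedSignals:
    """Band-limited ROI/source time series: [n_epochs x n_sources x n_samples]."""

    data: np.ndarray
    sample_rate: float
    band: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D: epochs x sources x samples")
        if self.data.shape[0] < 1 or self.data.shape[2] < 2:
            raise ValueError("need >= 1 epoch and >= 2 samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signals contain non-finite values")
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")
        if high >= self.sample_rate / 2:
            raise ValueError("band upper edge must be below the Nyquist frequency")

    @property
    def n_epochs(self):
        return self.data.shape[0]

    @property
    def n_sources(self):
        return self.data.shape[1]

    @property
    def n_samples(self):
        return self.data.shape[2]


@dataclass
class PhaseSeries:
    """Instantaneous phases in (-pi, pi], same shape as the source signals."""

    phases: np.ndarray

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 3:
            raise ValueError("phases must be 3-D: epochs x sources x samples")


@dataclass
class RoiMap:
    """Ordered ROI labels plus the source-index -> ROI-index assignment."""

    roi_names: list[str]
    source_to_roi: np.ndarray | None = None

    def __post_init__(self):
        self.roi_names = list(self.roi_names)
        if self.source_to_roi is None:
            self.source_to_roi = np.arange(len(self.roi_names))
        self.source_to_roi = np.asarray(self.source_to_roi, dtype=int)
        n_roi = len(self.roi_names)
        if np.any(self.source_to_roi < 0) or np.any(self.source_to_roi >= n_roi):
            raise ValueError("source_to_roi indices out of range")
        if len(np.unique(self.source_to_roi)) != n_roi:
            raise ValueError("every ROI must receive at least one source")

    @property
    def n_rois(self):
        return len(self.roi_names)

    @property
    def n_sources(self):
        return self.source_to_roi.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI PLV values in [0, 1] with unit diagonal."""

    values: np.ndarray
    roi_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise ValueError("values must be square")
        if not self.roi_names:
            self.roi_names = [f"ROI{i:03d}" for i in range(n)]
        if len(self.roi_names) != n:
            raise ValueError("roi_names length mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("connectivity matrix must be symmetric (tol 1e-9)")
        off = self.values[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal PLV values must lie in [0, 1]")

    @property
    def n_rois(self):
        return self.values.shape[0]

    def off_diagonal(self):
        n = self.n_rois
        return self.values[~np.eye(n, dtype=bool)]


@dataclass
class BrainGraph:
    """Binary adjacency plus continuous edge-probability targets."""

    adjacency: np.ndarray
    edge_probability: np.ndarray
    threshold: float
    roi_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency)
        self.edge_probability = np.asarray(self.edge_probability, dtype=float)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n) or self.edge_probability.shape != (n, n):
            raise ValueError("adjacency and edge_probability must be square and equal shape")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not set(np.unique(self.adjacency)) <= {0, 1}:
            raise ValueError("adjacency must be binary")
        if not self.roi_names:
            self.roi_names = [f"ROI{i:03d}" for i in range(n)]

    @property
    def n_nodes(self):
        return self.adjacency.shape[0]

    @property
    def n_edges(self):
        return int(self.adjacency.sum() // 2)

    @property
    def density(self):
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def instantaneous_phase(signals: EpochedSignals, order: int = 4) -> PhaseSeries:
    """Zero-phase band-pass then analytic-signal angle, per epoch and source."""
    low, high = signals.band
    sos = butter(order, [low, high], btype="bandpass", output="sos",
                 fs=signals.sample_rate)
    filtered = sosfiltfilt(sos, signals.data, axis=-1)
    analytic = hilbert(filtered, axis=-1)
    return PhaseSeries(np.angle(analytic))


def _epoch_trim_slice(n_samples: int, trim: float) -> slice:
    k = int(np.floor(trim * n_samples))
    return slice(k, n_samples - k if k else None)


def plv_pair(phases_a: np.ndarray, phases_b: np.ndarray, trim: float = 0.0) -> float:
    """PLV between two ROIs given per-source phases.

    Inputs are [n_epochs x n_sources x n_samples] phase arrays (one block
    per ROI).  For every source pair and epoch the modulus of the
    time-averaged phasor ``exp(-j (phi_a - phi_b))`` is computed; moduli
    are averaged across epochs and then across the N_A * N_B source pairs.
    ``trim`` drops that fraction of samples at each epoch edge (filter
    transients).
    """
    pa = np.asarray(phases_a, dtype=float)
    pb = np.asarray(phases_b, dtype=float)
    if pa.ndim == 2:
        pa = pa[:, None, :]
    if pb.ndim == 2:
        pb = pb[:, None, :]
    if pa.shape[0] != pb.shape[0] or pa.shape[2] != pb.shape[2]:
        raise ValueError("phase arrays must share n_epochs and n_samples")
    if pa.shape[1] == 0 or pb.shape[1] == 0:
        raise ValueError("empty source set")
    sl = _epoch_trim_slice(pa.shape[2], trim)
    za = np.exp(1j * pa[:, :, sl])
    zb = np.exp(1j * pb[:, :, sl])
    T = za.shape[2]
    # [epoch, src_a, src_b] per-epoch time-averaged cross-phasor modulus
    cross = np.abs(np.einsum("eat,ebt->eab", za, np.conj(zb))) / T
    return float(cross.mean())


def build_connectivity(signals: EpochedSignals, roi_map: RoiMap,
                       trim: float = DEFAULT_EDGE_TRIM) -> ConnectivityMatrix:
    """All-pairs ROI PLV matrix from epoched signals."""
    if roi_map.n_sources != signals.n_sources:
        raise ValueError(
            f"roi_map covers {roi_map.n_sources} sources but signals have "
            f"{signals.n_sources}")
    phases = instantaneous_phase(signals)
    sl = _epoch_trim_slice(signals.n_samples, trim)
    z = np.exp(1j * phases.phases[:, :, sl])
    T = z.shape[2]
    # per-epoch source-level PLV, then epoch average: [n_src x n_src]
    plv_src = np.abs(np.einsum("eat,ebt->eab", z, np.conj(z))) / T
    plv_src = plv_src.mean(axis=0)
    # ROI aggregation: average over source pairs
    n_roi = roi_map.n_rois
    indic = np.zeros((signals.n_sources, n_roi))
    indic[np.arange(signals.n_sources), roi_map.source_to_roi] = 1.0
    counts = indic.sum(axis=0)
    roi_plv = indic.T @ plv_src @ indic / np.outer(counts, counts)
    roi_plv = np.clip((roi_plv + roi_plv.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(roi_plv, 1.0)
    return ConnectivityMatrix(roi_plv, roi_map.roi_names)


def scale_to_probabilities(conn: ConnectivityMatrix) -> np.ndarray:
    """Min-max scale off-diagonal PLV values to [0, 1] (edge-probability proxy).

    The diagonal is excluded from the min/max and set to 0 in the output.
    """
    n = conn.n_rois
    off_mask = ~np.eye(n, dtype=bool)
    off = conn.values[off_mask]
    lo, hi = off.min(), off.max()
    if hi - lo < 1e-12:
        raise DegenerateRangeError(
            "off-diagonal PLV values are constant; min-max scaling undefined")
    out = (conn.values - lo) / (hi - lo)
    out[~off_mask] = 0.0
    return out


def threshold_to_graph(conn: ConnectivityMatrix,
                       threshold: float = DEFAULT_THRESHOLD) -> BrainGraph:
    """Binary graph (strictly-greater comparison) plus scaled targets."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    n = conn.n_rois
    adjacency = (conn.values > threshold).astype(int)
    np.fill_diagonal(adjacency, 0)
    prob = scale_to_probabilities(conn)
    graph = BrainGraph(adjacency, prob, threshold, conn.roi_names)
    if graph.n_edges == 0:
        warnings.warn("threshold exceeds all off-diagonal PLV values; "
                      "graph has no edges", RuntimeWarning)
    logger.info("thresholded at %.3f: %d edges, density %.3f",
                threshold, graph.n_edges, graph.density)
    return graph


# ---------------------------------------------------------------------------
# file formats (tab-delimited text)
# ---------------------------------------------------------------------------

def write_connectivity(conn: ConnectivityMatrix, path):
    df = pd.DataFrame(conn.values, index=conn.roi_names, columns=conn.roi_names)
    df.to_csv(path, sep="\t")


def read_connectivity(path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("row and column ROI labels differ")
    return ConnectivityMatrix(df.to_numpy(dtype=float), list(df.index))


def write_graph(graph: BrainGraph, prefix):
    """Write `<prefix>.adj.tsv` and `<prefix>.prob.tsv`."""
    prefix = str(prefix)
    for suffix, mat in ((".adj.tsv", graph.adjacency),
                        (".prob.tsv", graph.edge_probability)):
        pd.DataFrame(mat, index=graph.roi_names,
                     columns=graph.roi_names).to_csv(prefix + suffix, sep="\t")


def read_graph(prefix, threshold: float = DEFAULT_THRESHOLD) -> BrainGraph:
    prefix = str(prefix)
    adj = pd.read_csv(prefix + ".adj.tsv", sep="\t", index_col=0)
    prob = pd.read_csv(prefix + ".prob.tsv", sep="\t", index_col=0)
    return BrainGraph(adj.to_numpy(dtype=int), prob.to_numpy(dtype=float),
                      threshold, list(adj.index))


def load_signals(path, sample_rate: float, band: tuple[float, float],
                 pattern: str = "*.tsv") -> EpochedSignals:
    """Load epoched signals from a directory of per-epoch delimited files
    (rows = sources, columns = samples; sorted by filename) or a single
    ``.npy`` 3-D array."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob(pattern))
        if not files:
            raise FileNotFoundError(f"no epoch files matching {pattern} in {path}")
        epochs = [np.loadtxt(f, delimiter="\t") for f in files]
        data = np.stack([np.atleast_2d(e) for e in epochs])
    elif path.suffix == ".npy":
        data = np.load(path)
    else:
        raise ValueError("signals path must be a directory of TSV epochs or a .npy file")
    return EpochedSignals(data, sample_rate, band)
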