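"""ROI time series to quality-gated connectivity edge features.

The processing chain implemented here mirrors standard resting-state
functional-connectivity practice: per-frame head motion is summarised as
framewise displacement (FD), high-motion frames are censored ("scrubbed")
together with a short window around them, runs that survive a minimum
retention criterion are concatenated, and the Pearson correlation matrix of
the retained frames is Fisher r-to-z transformed.  The lower triangle of
that matrix, in a fixed canonical order, is the feature space of the
brain-age model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROITimeSeries",
    "ScrubResult",
    "RetentionCheck",
    "ConnectivityMatrix",
    "EdgeVector",
    "framewise_displacement",
    "scrub_mask",
    "check_retention",
    "concat_runs",
    "connectivity_matrix",
    "edge_vector",
    "reconstruct_matrix",
]

#: default repetition time (seconds); typical multiband-free 3T protocol
DEFAULT_TR_SECONDS = 2.2

#: default head radius (mm) used to convert rotations to arc length
DEFAULT_HEAD_RADIUS_MM = 50.0


@dataclass(frozen=True)
class ROITimeSeries:
    """A single run's parcellated signal: frames x nodes.

    ``values`` are assumed to be already denoised (nuisance-regressed)
    regional averages in arbitrary signal units.
    """

    values: np.ndarray
    tr_seconds: float = DEFAULT_TR_SECONDS
    node_labels: tuple[str, ...] = ()
    subject_id: str = ""
    session: str = ""
    run: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("time series must be a 2-D frames x nodes array")
        n_frames, n_nodes = values.shape
        if n_nodes < 2:
            raise ValueError(f"need at least 2 nodes, got {n_nodes}")
        if n_frames < 2:
            raise ValueError(f"need at least 2 frames, got {n_frames}")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        labels = tuple(self.node_labels) if self.node_labels else tuple(
            f"node{i:03d}" for i in range(n_nodes)
        )
        if len(labels) != n_nodes:
            raise ValueError(
                f"{len(labels)} node labels for {n_nodes} columns"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ScrubResult:
    """FD series and the keep-mask produced by the scrubbing rule."""

    fd: np.ndarray
    keep_mask: np.ndarray

    @property
    def retained_fraction(self) -> float:
        return float(np.mean(self.keep_mask))


@dataclass(frozen=True)
class RetentionCheck:
    retained_fraction: float
    include: bool
    n_kept: int
    n_total: int


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity matrix; the diagonal is stored as 0."""

    z: np.ndarray
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("connectivity matrix must be square")
        off = z[~np.eye(z.shape[0], dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal entries must be finite")
        if not np.allclose(z, z.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        labels = tuple(self.node_labels) if self.node_labels else tuple(
            f"node{i:03d}" for i in range(z.shape[0])
        )
        if len(labels) != z.shape[0]:
            raise ValueError("node label count does not match matrix size")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


@dataclass(frozen=True)
class EdgeVector:
    """Canonical lower-triangle vectorization of a connectivity matrix.

    Edges are ordered row-major over the strict lower triangle, i.e.
    (1,0), (2,0), (2,1), (3,0), ...  For a 100-node parcellation this
    yields the 4950 unique edges used as model features.
    """

    values: np.ndarray
    edge_index: tuple[tuple[int, int], ...]
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) != len(self.edge_index):
            raise ValueError("edge values and edge index lengths differ")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "edge_index", tuple(
            (int(i), int(j)) for i, j in self.edge_index
        ))


def canonical_edge_index(n_nodes: int) -> tuple[tuple[int, int], ...]:
    """Row-major strict-lower-triangle (i, j) pairs with i > j."""
    rows, cols = np.tril_indices(n_nodes, k=-1)
    return tuple((int(i), int(j)) for i, j in zip(rows, cols))


def framewise_displacement(
    motion: np.ndarray,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
    rotation_unit: str = "radians",
) -> np.ndarray:
    """Power-style FD: sum of absolute backward differences of the six
    rigid-body parameters, rotations converted to arc length on a sphere
    of ``head_radius_mm``.

    Parameters
    ----------
    motion:
        frames x 6 array ordered tx, ty, tz (mm), rx, ry, rz.
    rotation_unit:
        "radians" (default) or "degrees".
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must be frames x 6")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion table contains non-finite values")
    if rotation_unit not in ("radians", "degrees"):
        raise ValueError("rotation_unit must be 'radians' or 'degrees'")
    rot = motion[:, 3:]
    if rotation_unit == "degrees":
        rot = np.deg2rad(rot)
    dtrans = np.abs(np.diff(motion[:, :3], axis=0)).sum(axis=1)
    drot = np.abs(np.diff(rot, axis=0)).sum(axis=1)
    fd = np.zeros(motion.shape[0])
    fd[1:] = dtrans + head_radius_mm * drot
    return fd


def scrub_mask(
    fd: np.ndarray,
    threshold_mm: float = 0.5,
    n_before: int = 1,
    n_after: int = 2,
) -> np.ndarray:
    """Boolean keep-mask: frame t is censored iff an exceedance (fd >
    threshold) occurs at some frame s with s - n_before <= t <= s + n_after.
    Windows are clamped at run boundaries.
    """
    fd = np.asarray(fd, dtype=float)
    if np.any(fd < 0):
        raise ValueError("fd must be nonnegative")
    if n_before < 0 or n_after < 0:
        raise ValueError("window sizes must be nonnegative")
    n = len(fd)
    keep = np.ones(n, dtype=bool)
    for s in np.flatnonzero(fd > threshold_mm):
        lo = max(0, s - n_before)
        hi = min(n, s + n_after + 1)
        keep[lo:hi] = False
    return keep


def scrub(ts_motion: np.ndarray, **kwargs) -> ScrubResult:
    """Convenience: FD + keep-mask from a raw motion table."""
    fd_kwargs = {
        k: kwargs.pop(k)
        for k in ("head_radius_mm", "rotation_unit")
        if k in kwargs
    }
    fd = framewise_displacement(ts_motion, **fd_kwargs)
    return ScrubResult(fd=fd, keep_mask=scrub_mask(fd, **kwargs))


def check_retention(
    masks: list[np.ndarray],
    min_fraction: float = 0.7,
) -> RetentionCheck:
    """Session-level retention gate across all runs.

    A session is included when the retained fraction is >= ``min_fraction``
    (exclusion applies to sessions retaining strictly less than the
    criterion, i.e. less than 70% of the resting-state session by default).
    """
    if not masks:
        raise ValueError("need at least one run mask")
    n_kept = int(sum(int(np.sum(m)) for m in masks))
    n_total = int(sum(len(m) for m in masks))
    if n_total == 0:
        raise ValueError("empty masks")
    frac = n_kept / n_total
    return RetentionCheck(
        retained_fraction=frac,
        include=frac >= min_fraction,
        n_kept=n_kept,
        n_total=n_total,
    )


def concat_runs(
    runs: list[ROITimeSeries],
    masks: list[np.ndarray] | None = None,
) -> ROITimeSeries:
    """Concatenate the retained frames of the runs, preserving run order."""
    if not runs:
        raise ValueError("no runs to concatenate")
    labels = runs[0].node_labels
    tr = runs[0].tr_seconds
    for r in runs[1:]:
        if r.node_labels != labels:
            raise ValueError("runs have mismatched node labels")
        if r.tr_seconds != tr:
            raise ValueError("runs have mismatched repetition times")
    if masks is None:
        masks = [np.ones(r.n_frames, dtype=bool) for r in runs]
    if len(masks) != len(runs):
        raise ValueError("one mask per run required")
    pieces = []
    for r, m in zip(runs, masks):
        m = np.asarray(m, dtype=bool)
        if len(m) != r.n_frames:
            raise ValueError("mask length does not match run frames")
        pieces.append(r.values[m])
    values = np.vstack(pieces)
    if values.shape[0] < 2:
        raise ValueError("fewer than 2 frames retained after scrubbing")
    return ROITimeSeries(
        values=values,
        tr_seconds=tr,
        node_labels=labels,
        subject_id=runs[0].subject_id,
        session=runs[0].session,
        run="concat",
    )


def connectivity_matrix(
    ts: ROITimeSeries,
    r_clip: float = 1.0 - 1e-7,
) -> ConnectivityMatrix:
    """Pearson correlation between every node pair, Fisher r-to-z.

    Correlations of exactly +/-1 are clipped to ``r_clip`` before atanh so
    every edge stays finite (|z| ~ 8.4 at the default clip).
    """
    if ts.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation matrix")
    sd = ts.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.node_labels[i] for i in dead)
        raise ValueError(f"zero-variance node(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip(r, -r_clip, r_clip)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z, node_labels=ts.node_labels)


def edge_vector(cm: ConnectivityMatrix, atol: float = 1e-8) -> EdgeVector:
    """Vectorize the strict lower triangle in canonical row-major order."""
    z = cm.z
    if not np.allclose(z, z.T, atol=atol):
        raise ValueError("matrix is asymmetric beyond tolerance")
    idx = canonical_edge_index(z.shape[0])
    rows = [i for i, _ in idx]
    cols = [j for _, j in idx]
    return EdgeVector(
        values=z[rows, cols],
        edge_index=idx,
        node_labels=cm.node_labels,
    )


def reconstruct_matrix(ev: EdgeVector) -> ConnectivityMatrix:
    """Inverse of :func:`edge_vector` (diagonal restored as 0)."""
    m = len(ev.values)
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ValueError(f"{m} edges is not a triangular number")
    z = np.zeros((n, n))
    for (i, j), v in zip(ev.edge_index, ev.values):
        z[i, j] = v
        z[j, i] = v
    labels = ev.node_labels if ev.node_labels else ()
    return ConnectivityMatrix(z=z, node_labels=labels)
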