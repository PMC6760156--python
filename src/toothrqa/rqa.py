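"""Recurrence and cross-recurrence quantification of elemental traces.

A recurrence plot marks pairs of time points whose delay-embedded states
lie within a threshold distance; diagonal line structures in the plot
correspond to repeated (cyclical) stretches of trajectory.  Four measures
summarise that structure:

``DET``   determinism — fraction of recurrence points on diagonal lines of
          length >= ``l_min`` (cycle regularity),
``MDL``   mean diagonal line length (cycle duration),
``ENTR``  Shannon entropy of the diagonal-length distribution (cycle
          complexity), and
``RT``    recurrence time of type 2 — mean white vertical line length
          (interval between cycles).

The distance radius is calibrated per matrix to a target recurrence rate
(default 0.10) rather than fixed, because metal:Ca ratios vary by orders
of magnitude across elements and subjects; a fixed radius would make
features incomparable.  Cross-recurrence aligns two series onto their
overlapping day interval, interpolates to a common uniform grid and
z-normalizes each before embedding.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import (
    DegenerateTrajectoryError,
    DisjointSupportsError,
    InsufficientLengthError,
    ValidationError,
)
from .synthetic import ElementalTimeSeries

__all__ = [
    "MatrixKind",
    "EmbeddingParams",
    "RecurrenceMatrix",
    "LineHistogram",
    "RQAFeatures",
    "embed",
    "calibrate_radius",
    "recurrence_matrix",
    "cross_recurrence_matrix",
    "diagonal_histogram",
    "rqa_features",
    "rqa_features_from_values",
    "MIN_EMBEDDED_POINTS",
]

#: Embedded trajectories shorter than this yield missing features in the
#: cohort pipeline rather than unstable estimates.
MIN_EMBEDDED_POINTS = 50

_NORM_METRICS = {"euclidean": "euclidean", "max": "chebyshev", "manhattan": "cityblock"}


class MatrixKind(str, enum.Enum):
    AUTO = "AUTO"
    CROSS = "CROSS"


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding and thresholding parameters.

    Exactly one of ``radius`` and ``target_rr`` must be set; the default
    calibrates the radius to a 10% recurrence rate.  ``theiler`` masks
    diagonals with ``|i - j| < theiler`` in auto-recurrence plots, so the
    default of 1 excludes exactly the line of identity.
    """

    dimension: int = 3
    delay: int = 1
    radius: float | None = None
    target_rr: float | None = 0.10
    norm: str = "euclidean"
    theiler: int = 1
    l_min: int = 2
    v_min: int = 2

    def __post_init__(self):
        if self.dimension < 1:
            raise ValidationError("dimension must be >= 1", "dimension")
        if self.delay < 1:
            raise ValidationError("delay must be >= 1", "delay")
        if (self.radius is None) == (self.target_rr is None):
            raise ValidationError(
                "exactly one of radius and target_rr must be set", "radius"
            )
        if self.radius is not None and self.radius <= 0:
            raise ValidationError("radius must be > 0", "radius")
        if self.target_rr is not None and not 0.0 < self.target_rr < 1.0:
            raise ValidationError("target_rr must lie in (0, 1)", "target_rr")
        if self.norm not in _NORM_METRICS:
            raise ValidationError(f"unknown norm {self.norm!r}", "norm")
        if self.theiler < 0:
            raise ValidationError("theiler must be >= 0", "theiler")
        if self.l_min < 2 or self.v_min < 2:
            raise ValidationError("l_min and v_min must be >= 2", "l_min")

    @property
    def metric(self) -> str:
        return _NORM_METRICS[self.norm]


@dataclass
class RecurrenceMatrix:
    """Binary (cross-)recurrence structure with its provenance."""

    entries: np.ndarray  # bool, shape (N, M)
    kind: MatrixKind
    params: EmbeddingParams
    n_points: int
    radius: float = float("nan")

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=bool)
        if self.entries.ndim != 2:
            raise ValidationError("entries must be a 2-D matrix", "entries")
        self.kind = MatrixKind(self.kind)

    @property
    def theiler(self) -> int:
        """Effective Theiler window: configured for AUTO, 0 for CROSS."""
        return self.params.theiler if self.kind is MatrixKind.AUTO else 0


@dataclass
class LineHistogram:
    """Counts of maximal diagonal 1-runs and vertical white (0) runs."""

    diagonal_counts: dict[int, int] = field(default_factory=dict)
    vertical_white_counts: dict[int, int] = field(default_factory=dict)


@dataclass
class RQAFeatures:
    """The recurrence measures for one matrix; ``None`` marks a feature
    whose supporting histogram is empty (never encoded as 0)."""

    recurrence_rate: float
    determinism: float | None
    mean_diagonal_length: float | None
    entropy: float | None
    recurrence_time: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "RR": self.recurrence_rate,
            "DET": self.determinism,
            "MDL": self.mean_diagonal_length,
            "ENTR": self.entropy,
            "RT": self.recurrence_time,
        }


def embed(values, dimension: int, delay: int) -> np.ndarray:
    """Time-delay embedding: point i = (v[i], v[i+d], ..., v[i+(m-1)d])."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValidationError("embed expects a 1-D value sequence", "values")
    span = (dimension - 1) * delay
    required = span + 1
    if len(values) < required:
        raise InsufficientLengthError(
            f"series of length {len(values)} too short for m={dimension}, "
            f"tau={delay}; need at least {required} samples",
            required=required,
        )
    n_emb = len(values) - span
    idx = np.arange(n_emb)[:, None] + delay * np.arange(dimension)[None, :]
    return values[idx]


def calibrate_radius(
    trajectory_a: np.ndarray,
    trajectory_b: np.ndarray | None,
    target_rr: float,
    norm: str = "euclidean",
) -> float:
    """Radius as the ``target_rr`` quantile of the pairwise distances.

    Self-distances (i = j) are excluded for auto-recurrence; for
    cross-recurrence between two equal-length (grid-aligned) trajectories
    the aligned pairs i = j — the cross analogue of the line of identity —
    are likewise excluded, so a series crossed with itself calibrates to
    exactly its auto-recurrence radius.
    """
    if not 0.0 < target_rr < 1.0:
        raise ValidationError("target_rr must lie in (0, 1)", "target_rr")
    metric = _NORM_METRICS[norm]
    a = np.atleast_2d(np.asarray(trajectory_a, dtype=float))
    if a.shape[0] == 1:
        a = a.T
    if trajectory_b is None:
        d = cdist(a, a, metric=metric)
        dists = d[~np.eye(d.shape[0], dtype=bool)]
    else:
        b = np.atleast_2d(np.asarray(trajectory_b, dtype=float))
        if b.shape[0] == 1:
            b = b.T
        d = cdist(a, b, metric=metric)
        if a.shape[0] == b.shape[0]:
            dists = d[~np.eye(d.shape[0], dtype=bool)]
        else:
            dists = d.ravel()
    if dists.size == 0 or np.max(dists) == 0.0:
        raise DegenerateTrajectoryError(
            "all pairwise distances are zero; cannot calibrate a radius"
        )
    return float(np.quantile(dists, target_rr))


#: relative tolerance on the radius comparison: quantile thresholds can
#: land exactly on a tied distance, where bit-level noise (e.g. from
#: z-normalizing an affinely transformed series) would otherwise flip cells
_RADIUS_RTOL = 1e-12


def _within_radius(dist: np.ndarray, eps: float) -> np.ndarray:
    return dist <= eps * (1.0 + _RADIUS_RTOL)


def _resolve_radius(params, traj_a, traj_b=None):
    if params.radius is not None:
        return float(params.radius)
    return calibrate_radius(traj_a, traj_b, params.target_rr, params.norm)


def recurrence_matrix(trajectory, params: EmbeddingParams) -> RecurrenceMatrix:
    """Auto-recurrence matrix of one trajectory.

    Accepts raw 1-D values (embedded per ``params``) or an already
    embedded 2-D trajectory.
    """
    x = np.asarray(trajectory, dtype=float)
    if x.ndim == 1:
        x = embed(x, params.dimension, params.delay)
    eps = _resolve_radius(params, x)
    dist = cdist(x, x, metric=params.metric)
    return RecurrenceMatrix(_within_radius(dist, eps), MatrixKind.AUTO, params, x.shape[0], eps)


def _overlap_values(series: ElementalTimeSeries, lo: float, hi: float):
    sel = (series.times >= lo) & (series.times <= hi)
    return series.times[sel], series.values[sel]


def cross_recurrence_matrix(
    series_a: ElementalTimeSeries,
    series_b: ElementalTimeSeries,
    params: EmbeddingParams,
) -> RecurrenceMatrix:
    """Cross-recurrence of two elemental traces.

    Both series are restricted to their overlapping day interval,
    interpolated onto a common uniform grid of length min(N_a, N_b)
    (counts within the overlap), z-normalized independently, and embedded
    with the shared (m, tau).  The radius is calibrated on the pooled
    cross distances.  No Theiler masking applies (kind = CROSS).
    """
    lo = max(series_a.times[0], series_b.times[0])
    hi = min(series_a.times[-1], series_b.times[-1])
    if hi <= lo:
        raise DisjointSupportsError(
            f"series supports [{series_a.times[0]:g}, {series_a.times[-1]:g}] and "
            f"[{series_b.times[0]:g}, {series_b.times[-1]:g}] do not overlap"
        )
    ta, va = _overlap_values(series_a, lo, hi)
    tb, vb = _overlap_values(series_b, lo, hi)
    n = min(len(ta), len(tb))
    span = (params.dimension - 1) * params.delay
    if n < span + 2:
        raise InsufficientLengthError(
            f"overlap of {n} samples too short for embedding", required=span + 2
        )
    grid = np.linspace(lo, hi, n)
    ga = np.interp(grid, series_a.times, series_a.values)
    gb = np.interp(grid, series_b.times, series_b.values)
    za, zb = [], []
    for g, name in ((ga, series_a.element), (gb, series_b.element)):
        sd = g.std()
        if sd == 0.0:
            raise DegenerateTrajectoryError(
                f"series {name or '<unnamed>'} has zero variance on the overlap grid"
            )
        za.append((g - g.mean()) / sd)
    ga, gb = za
    ea = embed(ga, params.dimension, params.delay)
    eb = embed(gb, params.dimension, params.delay)
    eps = _resolve_radius(params, ea, eb)
    dist = cdist(ea, eb, metric=params.metric)
    return RecurrenceMatrix(_within_radius(dist, eps), MatrixKind.CROSS, params, ea.shape[0], eps)


def _run_lengths(flags: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a 1-D boolean array."""
    padded = np.empty(flags.size + 2, dtype=np.int8)
    padded[0] = padded[-1] = 0
    padded[1:-1] = flags
    edges = np.flatnonzero(np.diff(padded))
    return edges[1::2] - edges[0::2]


def diagonal_histogram(R: RecurrenceMatrix) -> LineHistogram:
    """Diagonal 1-run and vertical white-run length histograms.

    For AUTO matrices every diagonal with ``|i - j| < theiler`` is masked
    before counting; masked cells also break vertical white runs (they
    count as neither recurrence nor whitespace).
    """
    m = R.entries
    n_rows, n_cols = m.shape
    w = R.theiler

    # skew-scatter: column (j - i + n_rows - 1) of the padded array holds
    # diagonal k = j - i, with consecutive diagonal cells in consecutive
    # rows, so run structure is preserved column-wise
    skew = np.zeros((n_rows + 1, n_rows + n_cols - 1), dtype=np.int8)
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :] - rows + (n_rows - 1)
    skew[rows, cols] = m
    if w > 0:
        skew[:, n_rows - w : n_rows + w - 1] = 0  # |i-j| < w masked out
    lengths = _run_lengths(skew.ravel(order="F") == 1)
    hist = LineHistogram()
    if lengths.size:
        ls, cs = np.unique(lengths, return_counts=True)
        hist.diagonal_counts = dict(zip(ls.tolist(), cs.tolist()))

    # vertical white runs: encode masked cells as 2 so they break 0-runs,
    # with a separator row so runs never wrap across columns
    coded = m.astype(np.int8)
    if w > 0:
        i = np.arange(n_rows)[:, None]
        j = np.arange(n_cols)[None, :]
        coded[np.abs(i - j) < w] = 2
    sep = np.full((1, n_cols), 2, dtype=np.int8)
    flat = np.concatenate([coded, sep], axis=0).ravel(order="F")
    white = _run_lengths(flat == 0)
    if white.size:
        ls, cs = np.unique(white, return_counts=True)
        hist.vertical_white_counts = dict(zip(ls.tolist(), cs.tolist()))
    return hist


def rqa_features(
    R: RecurrenceMatrix, hist: LineHistogram | None = None
) -> RQAFeatures:
    """Compute RR, DET, MDL, ENTR and RT from a recurrence matrix.

    DET uses the convention that its denominator counts *all* recurrence
    points (every 1 lies on exactly one maximal diagonal run, of length
    possibly 1); MDL and ENTR are taken over lines of length >= l_min.
    Features whose supporting histogram is empty come back as ``None``.
    """
    if hist is None:
        hist = diagonal_histogram(R)
    m = R.entries
    n_rows, n_cols = m.shape
    w = R.theiler
    if w > 0:
        i = np.arange(n_rows)[:, None]
        j = np.arange(n_cols)[None, :]
        valid = np.abs(i - j) >= w
        rr = float(m[valid].sum()) / float(valid.sum())
    else:
        rr = float(m.sum()) / float(m.size)

    P = hist.diagonal_counts
    l_min = R.params.l_min
    total_points = sum(l * c for l, c in P.items())
    long_points = sum(l * c for l, c in P.items() if l >= l_min)
    long_lines = sum(c for l, c in P.items() if l >= l_min)

    det = long_points / total_points if total_points > 0 else None
    mdl = long_points / long_lines if long_lines > 0 else None
    if long_lines > 0:
        probs = np.array(
            [c / long_lines for l, c in P.items() if l >= l_min], dtype=float
        )
        entr = float(-np.sum(probs * np.log(probs)))
    else:
        entr = None

    W = hist.vertical_white_counts
    white_lines = sum(W.values())
    rt = (
        sum(l * c for l, c in W.items()) / white_lines if white_lines > 0 else None
    )
    return RQAFeatures(rr, det, mdl, entr, rt)


def rqa_features_from_values(values, params: EmbeddingParams) -> RQAFeatures:
    """Convenience: embed raw values, build the auto matrix, extract features."""
    return rqa_features(recurrence_matrix(values, params))
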