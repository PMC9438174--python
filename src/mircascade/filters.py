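"""Transcript-selection filters: detection, segmental fold-change, exponential fit.

Three successive filters shrink the transcript universe:

1. **Detection** — keep transcripts whose day-mean log2 signal exceeds a
   detection threshold at a minimum number of distinct days (default 6).
2. **Segmental fold-change** — split the time course into named phases
   ("segments"); within each segment compute the linear fold change between
   the first and last sampled day of the segment and call the transcript
   informative when the fold change falls outside the window
   (``fc <= 0.8`` or ``fc >= 1.2``, thresholds inclusive).
3. **Exponential trajectory** — keep transcripts whose day-mean curve is well
   described by a two-term exponential ``a*exp(b*t') + c*exp(d*t')``
   (t' = day rescaled to [0, 1]); goodness is the Pearson correlation R
   between fitted and observed values, retained when ``R >= 0.7``.

The fold-change rule is a pure ratio filter by design: no replicate-level
test statistic or multiplicity correction is involved at this stage.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .datasets import ExpressionDataset, TimeProfile, to_profiles

__all__ = [
    "SegmentScheme",
    "SegmentalCall",
    "ExpFitResult",
    "detection_filter",
    "segmental_fold_change",
    "segment_overlap",
    "fit_exp2",
    "exponential_filter",
]

_THR_EPS = 1e-12  # absorbs float error in 2**log2(x) round trips at the boundary


@dataclass(frozen=True)
class SegmentScheme:
    """Ordered, non-overlapping phases of the time course as (name, lo, hi) day ranges."""

    segments: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        segs = tuple((str(n), float(lo), float(hi)) for n, lo, hi in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("scheme must contain at least one segment")
        names = [s[0] for s in segs]
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")
        for name, lo, hi in segs:
            if not lo < hi:
                raise ValueError(f"segment {name!r}: day_lo must be < day_hi")
        for (na, _, hi_a), (nb, lo_b, _) in zip(segs, segs[1:]):
            if lo_b < hi_a:
                raise ValueError(f"segments {na!r} and {nb!r} overlap or are out of order")

    @property
    def names(self) -> list[str]:
        return [s[0] for s in self.segments]

    def days_in(self, name: str, days: np.ndarray) -> np.ndarray:
        """Sampled days of `days` falling inside the named segment (inclusive)."""
        for n, lo, hi in self.segments:
            if n == name:
                d = np.asarray(days, dtype=float)
                return d[(d >= lo) & (d <= hi)]
        raise KeyError(name)


@dataclass(frozen=True)
class SegmentalCall:
    """Fold-change call for one transcript in one segment (linear scale)."""

    transcript_id: str
    segment_name: str
    fold_change: float
    direction: str  # up | down | flat
    informative: bool


@dataclass
class ExpFitResult:
    """Two-term exponential fit of a day-mean trajectory.

    ``r_goodness`` is the Pearson correlation between fitted and observed
    values (optionally sqrt(R^2) of the fit, see ``goodness`` in
    :func:`fit_exp2`); ``passed`` applies the retention threshold.
    """

    transcript_id: str
    a: float
    b: float
    c: float
    d: float
    r_goodness: float
    passed: bool
    converged: bool = True
    sse: float = field(default=math.nan)


# -- detection -----------------------------------------------------------------


def detection_filter(
    ds: ExpressionDataset,
    min_timepoints: int = 6,
    detect_thr: float | None = None,
) -> ExpressionDataset:
    """Keep transcripts detected (day-mean log2 > threshold) at enough days.

    ``detect_thr`` defaults to the 10th percentile of the whole matrix — a
    deterministic, data-adaptive floor for "expressed".  Transcripts must
    exceed it at ``min_timepoints`` or more distinct days.  Row order is
    preserved.
    """
    if min_timepoints < 1:
        raise ValueError("min_timepoints must be >= 1")
    n_days = ds.days.size
    if min_timepoints > n_days:
        raise ValueError(
            f"min_timepoints={min_timepoints} exceeds the {n_days} distinct sampled days"
        )
    if detect_thr is None:
        detect_thr = float(np.percentile(ds.values, 10))
    sample_days = ds.sample_days
    day_means = np.column_stack(
        [ds.values[:, sample_days == d].mean(axis=1) for d in ds.days]
    )
    n_detected = (day_means > detect_thr).sum(axis=1)
    keep = [t for t, n in zip(ds.transcript_ids, n_detected) if n >= min_timepoints]
    return ds.subset(keep)


# -- segmental fold change -----------------------------------------------------


def segmental_fold_change(
    profiles: list[TimeProfile],
    scheme: SegmentScheme,
    low_thr: float = 0.8,
    high_thr: float = 1.2,
    strategy: str = "endpoints",
) -> list[SegmentalCall]:
    """Per-transcript, per-segment linear fold change with informative calls.

    With the default ``endpoints`` strategy the fold change is
    ``2**(mean_log2 at the segment's last sampled day - mean_log2 at its
    first sampled day)``; ``segment-mean-vs-day0`` instead compares the
    segment's mean level against the transcript's value at the earliest
    sampled day.  Thresholds are inclusive.
    """
    if not (0 < low_thr < 1 < high_thr):
        raise ValueError("thresholds must satisfy 0 < low_thr < 1 < high_thr")
    if strategy not in ("endpoints", "segment-mean-vs-day0"):
        raise ValueError(f"unknown strategy {strategy!r}")

    calls: list[SegmentalCall] = []
    for prof in profiles:
        day_index = {d: i for i, d in enumerate(prof.days)}
        for name in scheme.names:
            seg_days = scheme.days_in(name, prof.days)
            if seg_days.size < 2:
                raise ValueError(
                    f"segment {name!r} contains {seg_days.size} sampled day(s); needs >= 2"
                )
            idx = [day_index[d] for d in seg_days]
            if strategy == "endpoints":
                delta = prof.mean_log2[idx[-1]] - prof.mean_log2[idx[0]]
            else:
                delta = prof.mean_log2[idx].mean() - prof.mean_log2[0]
            fc = float(2.0**delta)
            informative = fc <= low_thr + _THR_EPS or fc >= high_thr - _THR_EPS
            direction = "up" if fc > 1 else ("down" if fc < 1 else "flat")
            calls.append(SegmentalCall(prof.transcript_id, name, fc, direction, informative))
    return calls


def segment_overlap(calls: list[SegmentalCall]) -> dict[frozenset[str], list[str]]:
    """Venn partition: for every non-empty segment subset, the transcripts
    informative in exactly those segments (sorted ids)."""
    seg_names = sorted({c.segment_name for c in calls})
    if len(seg_names) < 2:
        raise ValueError("segment_overlap needs calls from >= 2 segments")
    membership: dict[str, set[str]] = {}
    for c in calls:
        if c.informative:
            membership.setdefault(c.transcript_id, set()).add(c.segment_name)
    table: dict[frozenset[str], list[str]] = {}
    for r in range(1, len(seg_names) + 1):
        for combo in itertools.combinations(seg_names, r):
            key = frozenset(combo)
            table[key] = sorted(t for t, segs in membership.items() if segs == key)
    return table


# -- exponential fit -----------------------------------------------------------

# Deterministic (b, d) rate initializations, ordered from gentle to steep and
# mixed-sign; a and c are solved linearly at every step (variable projection).
_START_GRID: tuple[tuple[float, float], ...] = (
    (1.0, -1.0),
    (3.0, -3.0),
    (6.0, -6.0),
    (0.5, -0.5),
    (2.0, 0.1),
    (-2.0, -0.1),
    (4.0, 1.0),
    (-4.0, -1.0),
    (8.0, -2.0),
    (-8.0, 2.0),
)
_RATE_BOUND = 25.0


def _vp_residual(bd: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    basis = np.exp(np.clip(np.outer(t, bd), -700, 700))
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return basis @ coef - y


def _vp_coefs(bd: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    basis = np.exp(np.clip(np.outer(t, bd), -700, 700))
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return coef


def fit_exp2(
    profile: TimeProfile,
    r_threshold: float = 0.7,
    n_starts: int = 8,
    goodness: str = "r",
) -> ExpFitResult:
    """Fit ``y(t') = a*exp(b*t') + c*exp(d*t')`` to a day-mean trajectory.

    Days are rescaled to t' in [0, 1] for conditioning; rates (b, d) are
    optimized by bounded nonlinear least squares from ``n_starts``
    deterministic initializations while amplitudes (a, c) are profiled out
    linearly at each step, so the procedure needs no random seed.  The best
    converged start (lowest SSE) is reported.

    ``goodness='r'`` scores the fit by the Pearson correlation between fitted
    and observed values; ``goodness='sqrt_r2'`` uses sqrt(max(R^2, 0)) of the
    regression instead.  ``passed`` is ``r_goodness >= r_threshold``
    (inclusive) for a converged fit.
    """
    if goodness not in ("r", "sqrt_r2"):
        raise ValueError(f"unknown goodness mode {goodness!r}")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    t_raw = profile.days
    y = profile.mean_log2
    if t_raw.size < 5:
        raise ValueError(
            f"{profile.transcript_id}: two-term exponential fit needs >= 5 time points, "
            f"got {t_raw.size}"
        )
    span = t_raw[-1] - t_raw[0]
    t = (t_raw - t_raw[0]) / span

    best_sse = np.inf
    best_bd: np.ndarray | None = None
    starts = list(_START_GRID)
    while len(starts) < n_starts:  # cycle with mild scaling if more starts requested
        k = len(starts) - len(_START_GRID)
        b0, d0 = _START_GRID[k % len(_START_GRID)]
        starts.append((b0 * 1.5, d0 * 1.5))
    for b0, d0 in starts[:n_starts]:
        try:
            sol = least_squares(
                _vp_residual,
                x0=np.array([b0, d0]),
                bounds=(-_RATE_BOUND, _RATE_BOUND),
                args=(t, y),
                method="trf",
                max_nfev=200,
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not sol.success:
            continue
        sse = float(2 * sol.cost)
        if sse < best_sse:
            best_sse = sse
            best_bd = sol.x

    if best_bd is None:
        return ExpFitResult(
            profile.transcript_id, math.nan, math.nan, math.nan, math.nan,
            r_goodness=0.0, passed=False, converged=False, sse=math.nan,
        )

    a, c = _vp_coefs(best_bd, t, y)
    fitted = np.exp(np.clip(np.outer(t, best_bd), -700, 700)) @ np.array([a, c])

    if goodness == "r":
        sy, sf = y.std(), fitted.std()
        if sy == 0 or sf == 0:
            r_good = 0.0
        else:
            r_good = float(np.corrcoef(y, fitted)[0, 1])
    else:
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - best_sse / ss_tot if ss_tot > 0 else 0.0
        r_good = math.sqrt(max(r2, 0.0))

    passed = bool(r_good >= r_threshold - _THR_EPS)
    return ExpFitResult(
        profile.transcript_id,
        float(a), float(best_bd[0]), float(c), float(best_bd[1]),
        r_goodness=r_good, passed=passed, converged=True, sse=best_sse,
    )


def exponential_filter(
    profiles: list[TimeProfile],
    r_threshold: float = 0.7,
    n_starts: int = 8,
    goodness: str = "r",
) -> list[str]:
    """Transcript ids whose trajectories pass :func:`fit_exp2`, input order kept."""
    survivors = []
    for prof in profiles:
        fit = fit_exp2(prof, r_threshold=r_threshold, n_starts=n_starts, goodness=goodness)
        if fit.passed:
            survivors.append(prof.transcript_id)
    return survivors


def detection_then_profiles(ds: ExpressionDataset, **kwargs) -> list[TimeProfile]:
    """Convenience: detection filter then day-mean profiles."""
    return to_profiles(detection_filter(ds, **kwargs))
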