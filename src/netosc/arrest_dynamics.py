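"""Cross-condition dynamics: normalization, alignment, behavior classification.

Behavior classification asks what a transcript does after the shared first
cycle of expression: keeps oscillating, plateaus high, decays to baseline
after an initial pulse, never pulses at all, or something in between
(damped).  Conditions are made comparable by anchoring each time axis at the
time its population reached 50% budded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .errors import (EmptyComparisonError, EmptyReferenceError, InputError,
                     InsufficientWindowError, NoAnchorError, NormalizationError)
from .periodicity import (ALGORITHMS, PeriodPhaseEstimate, bh_fdr, call_periodic,
                          periodicity_statistics, permutation_pvalue)
from .synthgen import BuddingCurve, TimeSeriesMatrix

logger = logging.getLogger(__name__)

BEHAVIOR_LABELS = ("oscillating", "damped", "persistent_high", "repressed", "low_flat")


@dataclass
class BehaviorThresholds:
    """Config-exposed knobs of the label rules (defaults validated by simulation)."""

    alpha: float = 0.05
    persistent_ratio: float = 0.6     # late mean / first-cycle peak, lower bound
    repressed_ratio: float = 0.3      # late mean / first-cycle peak, upper bound
    peak_ratio: float = 2.0           # first-cycle max/min marking a real pulse
    window_start_factor: float = 1.25  # post window starts at this * wt_period
    slope_tolerance: float = 0.2      # |slope|*window span below this * peak -> flat


@dataclass
class BehaviorLabel:
    gene_id: str
    condition: str
    label: str
    features: dict[str, float] = field(default_factory=dict)


@dataclass
class OverlapStat:
    set_a_size: int
    set_b_size: int
    intersection: int
    fraction_of_a: float


# ---------------------------------------------------------------------------
# normalization / alignment
# ---------------------------------------------------------------------------

def log2_relative_to_mean(matrix: TimeSeriesMatrix, pseudocount: float = 0.0) -> np.ndarray:
    """Per-gene log2 fold change relative to the gene's mean expression.

    ``out[g, j] = log2((x[g, j] + c) / (mean_g + c))``.  Scale-invariant per
    row when ``c = 0``.
    """
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    means = matrix.values.mean(axis=1)
    if pseudocount == 0 and np.any(means == 0):
        bad = matrix.gene_ids[int(np.flatnonzero(means == 0)[0])]
        raise NormalizationError(
            f"gene {bad!r} has zero mean; supply a positive pseudocount")
    return np.log2((matrix.values + pseudocount) / (means[:, None] + pseudocount))


def t50_budded(curve: BuddingCurve) -> float:
    """First time the budding index reaches 0.5, by linear interpolation."""
    f = curve.fraction_budded
    t = curve.times
    idx = np.flatnonzero(f >= 0.5)
    if idx.size == 0:
        raise NoAnchorError("budding curve never reaches 50%")
    i = int(idx[0])
    if i == 0 or f[i] == 0.5:
        return float(t[i])
    t0, t1 = t[i - 1], t[i]
    f0, f1 = f[i - 1], f[i]
    return float(t0 + (0.5 - f0) / (f1 - f0) * (t1 - t0))


def align_at_anchor(matrices: list[TimeSeriesMatrix], anchors: list[float],
                    ) -> tuple[list[TimeSeriesMatrix], tuple[float, float]]:
    """Shift each matrix's time axis by its anchor (no resampling).

    Returns the shifted matrices and the (start, end) of the overlapping
    aligned time range.
    """
    if len(matrices) != len(anchors):
        raise InputError("one anchor per matrix required")
    shifted = [replace(m, times=m.times - a) for m, a in zip(matrices, anchors)]
    lo = max(m.times[0] for m in shifted)
    hi = min(m.times[-1] for m in shifted)
    return shifted, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# behavior classification
# ---------------------------------------------------------------------------

def behavior_features(series, times, wt_period: float,
                      thresholds: BehaviorThresholds | None = None) -> dict[str, float]:
    """Shape features of one arrest-condition trajectory.

    The first-cycle window is ``t <= window_start_factor * wt_period``; the
    post window is everything after it and must span at least two periods.
    All features are ratios, invariant to per-gene rescaling.
    """
    thresholds = thresholds or BehaviorThresholds()
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    w = thresholds.window_start_factor * wt_period
    post_mask = times > w
    if not np.any(post_mask) or times[-1] - w < 2.0 * wt_period:
        raise InsufficientWindowError(
            f"series must cover >= 2 periods past t={w:.1f}")
    first = series[~post_mask]
    post = series[post_mask]
    post_t = times[post_mask]

    scale = max(float(np.max(np.abs(series))), 1e-300)
    eps = 1e-12 * scale
    first_peak = float(np.max(first))
    first_cycle_peak_ratio = first_peak / max(float(np.min(first)), eps)

    quarter = times >= times[-1] - 0.25 * (times[-1] - times[0])
    late_mean_ratio = float(np.mean(series[quarter])) / max(first_peak, eps)

    slope = float(stats.linregress(post_t, post).slope)
    span = post_t[-1] - post_t[0]
    if abs(slope) * span < thresholds.slope_tolerance * max(first_peak, eps):
        slope_sign = 0
    else:
        slope_sign = 1 if slope > 0 else -1

    return {
        "first_cycle_peak_ratio": first_cycle_peak_ratio,
        "late_mean_ratio": late_mean_ratio,
        "late_slope_sign": float(slope_sign),
    }


def label_from_features(features: dict[str, float], post_window_q: float,
                        thresholds: BehaviorThresholds | None = None) -> str:
    """Deterministic label rules.

    Order: oscillating (post-window rhythmicity below alpha); low_flat (no
    first-cycle pulse); persistent_high (late level holds near the first
    peak without decline); repressed (late level collapses after a pulse);
    otherwise damped.
    """
    th = thresholds or BehaviorThresholds()
    if post_window_q <= th.alpha:
        return "oscillating"
    if features["first_cycle_peak_ratio"] < th.peak_ratio:
        return "low_flat"
    if (features["late_mean_ratio"] >= th.persistent_ratio
            and features["late_slope_sign"] >= 0):
        return "persistent_high"
    if features["late_mean_ratio"] <= th.repressed_ratio:
        return "repressed"
    return "damped"


def classify_behavior(series, times, wt_period: float,
                      thresholds: BehaviorThresholds | None = None,
                      post_window_q: float | None = None,
                      gene_id: str = "", condition: str = "",
                      n_perm: int = 199, seed: int = 0) -> BehaviorLabel:
    """Classify one gene's arrest trajectory.

    If ``post_window_q`` is not supplied, the post-window series is scored by
    all three periodicity statistics with permutation p-values and their
    maximum is used (single-gene analogue of the consensus intersection).
    """
    thresholds = thresholds or BehaviorThresholds()
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    features = behavior_features(series, times, wt_period, thresholds)
    if post_window_q is None:
        w = thresholds.window_start_factor * wt_period
        mask = times > w
        post, post_t = series[mask], times[mask]
        grid = _window_period_grid(post_t, wt_period)
        scorers = periodicity_statistics(post_t, grid)
        post_window_q = max(
            permutation_pvalue(fn, post, post_t, n_perm=max(n_perm, 99), seed=seed)
            for fn in scorers.values())
    features = dict(features, post_window_q=float(post_window_q))
    label = label_from_features(features, post_window_q, thresholds)
    return BehaviorLabel(gene_id=gene_id, condition=condition, label=label,
                         features=features)


def _window_period_grid(times: np.ndarray, wt_period: float) -> np.ndarray:
    """Candidate periods for the post-window rhythmicity test.

    "Oscillating" means continuing near the reference period, so the grid is
    wt_period * {0.8, 1.0, 1.2}; a wide grid would let the permutation null
    cherry-pick long noisy lags and lose power on the short window.
    """
    dt = float(np.min(np.diff(times)))
    span = times[-1] - times[0]
    grid = wt_period * np.array([0.8, 1.0, 1.2])
    grid = grid[(grid >= 2 * dt) & (grid <= span)]
    if grid.size == 0:
        raise InsufficientWindowError("post window too short for the period grid")
    return grid


def classify_matrix(matrix: TimeSeriesMatrix, wt_period: float,
                    thresholds: BehaviorThresholds | None = None,
                    n_perm: int = 999, seed: int = 0,
                    period_grid=None) -> list[BehaviorLabel]:
    """Classify every gene of an arrest-condition matrix.

    The post-window rhythmicity q-value comes from :func:`call_periodic` on
    the windowed submatrix (max q across the three algorithms, so
    "oscillating" coincides with consensus membership at ``alpha``).
    """
    thresholds = thresholds or BehaviorThresholds()
    w = thresholds.window_start_factor * wt_period
    mask = matrix.times > w
    post_times = matrix.times[mask]
    if post_times.size == 0 or matrix.times[-1] - w < 2.0 * wt_period:
        raise InsufficientWindowError(
            f"matrix must cover >= 2 periods past t={w:.1f}")
    window = TimeSeriesMatrix(
        gene_ids=list(matrix.gene_ids), times=post_times,
        values=matrix.values[:, mask], condition=matrix.condition,
        replicate=matrix.replicate)
    grid = (period_grid if period_grid is not None
            else _window_period_grid(post_times, wt_period))
    calls, _ = call_periodic(window, period_grid=grid, alpha=thresholds.alpha,
                             n_perm=n_perm, seed=seed)
    qmax: dict[str, float] = {}
    for c in calls:
        qmax[c.gene_id] = max(qmax.get(c.gene_id, 0.0), c.q_value)

    labels = []
    for gi, gene_id in enumerate(matrix.gene_ids):
        labels.append(classify_behavior(
            matrix.values[gi], matrix.times, wt_period, thresholds,
            post_window_q=qmax[gene_id], gene_id=gene_id,
            condition=matrix.condition))
    return labels


# ---------------------------------------------------------------------------
# cross-condition summaries
# ---------------------------------------------------------------------------

def persistence_overlap(wt_set: set[str], arrest_set: set[str]) -> OverlapStat:
    """How much of the reference periodic set persists in another condition."""
    wt_set, arrest_set = set(wt_set), set(arrest_set)
    if not wt_set:
        raise EmptyReferenceError("reference set is empty; fraction undefined")
    inter = len(wt_set & arrest_set)
    return OverlapStat(set_a_size=len(wt_set), set_b_size=len(arrest_set),
                       intersection=inter, fraction_of_a=inter / len(wt_set))


def replicate_concordance(rep1: TimeSeriesMatrix, rep2: TimeSeriesMatrix,
                          pseudocount: float = 1.0) -> float:
    """Squared Pearson correlation of two replicates on log2 scale.

    Gene sets must match; time axes are matched by rank and truncated to the
    common length.
    """
    if set(rep1.gene_ids) != set(rep2.gene_ids):
        missing = sorted(set(rep1.gene_ids) ^ set(rep2.gene_ids))
        raise InputError(f"gene sets differ: {missing[:10]}")
    order2 = [rep2.gene_ids.index(g) for g in rep1.gene_ids]
    nt = min(len(rep1.times), len(rep2.times))
    a = np.log2(rep1.values[:, :nt] + pseudocount).ravel()
    b = np.log2(rep2.values[order2, :nt] + pseudocount).ravel()
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def compare_periods(estimates_a: list[PeriodPhaseEstimate],
                    estimates_b: list[PeriodPhaseEstimate]) -> dict[str, float]:
    """Median periods per condition and median absolute difference on shared genes."""
    a = {e.gene_id: e.period for e in estimates_a}
    b = {e.gene_id: e.period for e in estimates_b}
    shared = sorted(set(a) & set(b))
    if not shared:
        raise EmptyComparisonError("no shared genes between the estimate lists")
    diffs = [abs(a[g] - b[g]) for g in shared]
    return {
        "median_a": float(np.median(list(a.values()))),
        "median_b": float(np.median(list(b.values()))),
        "median_abs_diff": float(np.median(diffs)),
        "n_shared": len(shared),
    }
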