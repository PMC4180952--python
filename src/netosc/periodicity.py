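"""Per-gene rhythmicity scoring and the consensus periodic set.

Three independent statistics are computed per gene — a Lomb-Scargle
periodogram maximum, a lagged-autocorrelation maximum, and a rank-based
cosine-template match — each calibrated by a seeded permutation null and
corrected across genes by Benjamini-Hochberg.  The high-confidence periodic
set is the intersection of the three per-algorithm significant sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError, InsufficientDataError
from .synthgen import TimeSeriesMatrix

logger = logging.getLogger(__name__)

ALGORITHMS = ("periodogram", "autocorr", "template_rank")

#: default candidate periods, minutes
DEFAULT_PERIOD_GRID = np.arange(40.0, 241.0, 10.0)

#: weight of the continuous tie-breaker added to the discrete rank statistic
#: so that permutation p-values are exactly uniform under the null
_TIEBREAK = 1e-6

_MIN_POINTS = 8


@dataclass
class PeriodicityCall:
    gene_id: str
    algorithm: str
    score: float
    p_value: float
    q_value: float
    significant: bool


@dataclass
class PeriodPhaseEstimate:
    gene_id: str
    period: float
    peak_time: float
    power: float
    boundary: bool = False


@dataclass
class ConsensusSet:
    gene_ids: set[str]
    per_algorithm: dict[str, set[str]]
    alpha: float

    def __post_init__(self):
        inter = set.intersection(*self.per_algorithm.values()) if self.per_algorithm else set()
        if self.gene_ids != inter:
            raise InputError("consensus set is not the per-algorithm intersection")


# ---------------------------------------------------------------------------
# core statistics
# ---------------------------------------------------------------------------

def _validate_series(series, times):
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.shape != times.shape:
        raise InputError("series and times must have equal length")
    if series.size < _MIN_POINTS:
        raise InsufficientDataError(
            f"need >= {_MIN_POINTS} time points, got {series.size}")
    return series, times


def _lombscargle_batch(rows: np.ndarray, times: np.ndarray,
                       periods: np.ndarray) -> np.ndarray:
    """Normalized Lomb-Scargle power for each row at each candidate period.

    Rows are mean-centered internally; power is normalized by half the
    centered sum of squares (so a pure sinusoid scores ~1).  Zero-variance
    rows get zero power everywhere.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    yc = rows - rows.mean(axis=1, keepdims=True)
    ss_tot = np.sum(yc * yc, axis=1)
    power = np.zeros((rows.shape[0], len(periods)))
    ok = ss_tot > 1e-30
    if not np.any(ok):
        return power
    for j, period in enumerate(periods):
        w = 2.0 * np.pi / period
        tau = np.arctan2(np.sum(np.sin(2 * w * times)),
                         np.sum(np.cos(2 * w * times))) / (2 * w)
        c = np.cos(w * (times - tau))
        s = np.sin(w * (times - tau))
        cc = np.sum(c * c)
        ss = np.sum(s * s)
        a = yc @ c
        b = yc @ s
        # cc + ss == n; a component this degenerate (e.g. the sine term at
        # the Nyquist period) is pure round-off and must be dropped, not
        # divided by
        eps = 1e-9 * times.size
        p = 0.5 * (np.divide(a * a, cc, out=np.zeros_like(a), where=cc > eps)
                   + np.divide(b * b, ss, out=np.zeros_like(b), where=ss > eps))
        power[ok, j] = 2.0 * p[ok] / ss_tot[ok]
    return power


def periodogram_power(series, times, period_grid) -> np.ndarray:
    """Normalized Lomb-Scargle power at each candidate period.

    Handles uneven sampling (missing time points) without imputation.
    All-constant series yield zero power (not an error).
    """
    series, times = _validate_series(series, times)
    period_grid = np.asarray(period_grid, dtype=float)
    dt_min = np.min(np.diff(times))
    span = times[-1] - times[0]
    if np.any(period_grid < 2 * dt_min - 1e-9) or np.any(period_grid > span + 1e-9):
        raise InputError("period_grid must lie within [2*dt, T]")
    return _lombscargle_batch(series, times, period_grid)[0]


def autocorr_score(series, lag_points: int) -> float:
    """Pearson correlation of a series with itself shifted by ``lag_points``.

    Zero variance in either segment yields 0.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if not 1 <= lag_points < n:
        raise InputError(f"lag_points must lie in [1, {n - 1}]")
    a = series[: n - lag_points]
    b = series[lag_points:]
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def template_rank_score(series, times, period: float,
                        phase_grid=None) -> float:
    """Max over phases of Kendall's tau-b between the series and a cosine template.

    Rank-based, hence invariant to monotone distortions of the expression
    scale.  All-tied series score 0.
    """
    series, times = _validate_series(series, times)
    if phase_grid is None:
        phase_grid = np.arange(8) / 8.0
    best = -1.0
    for phi in phase_grid:
        template = np.cos(2 * np.pi * (times / period - phi))
        tau = stats.kendalltau(series, template).statistic
        if np.isnan(tau):
            tau = 0.0
        best = max(best, float(tau))
    return best


# ---------------------------------------------------------------------------
# batched scoring context (shared by call_periodic and the per-series scorers)
# ---------------------------------------------------------------------------

class _ScoringContext:
    """Precomputed grids/templates for scoring many rows over fixed times."""

    def __init__(self, times: np.ndarray, period_grid: np.ndarray, n_phases: int = 8):
        self.times = np.asarray(times, dtype=float)
        n = self.times.size
        if n < _MIN_POINTS:
            raise InsufficientDataError(
                f"need >= {_MIN_POINTS} time points, got {n}")
        self.period_grid = np.asarray(period_grid, dtype=float)
        dts = np.diff(self.times)
        self.dt = float(np.min(dts))
        span = self.times[-1] - self.times[0]
        if np.any(self.period_grid < 2 * self.dt - 1e-9) or np.any(
                self.period_grid > span + 1e-9):
            raise InputError("period_grid must lie within [2*dt, T]")

        # autocorrelation lags implied by the period grid; periods beyond half
        # the span would correlate fewer than half the points and only add
        # selection noise to the max, so they are excluded
        usable = self.period_grid[self.period_grid <= 0.5 * span + 1e-9]
        if usable.size == 0:
            usable = self.period_grid[:1]
        lags = sorted({int(round(p / self.dt)) for p in usable})
        self.lags = [l for l in lags if 1 <= l <= n - 3]
        if not self.lags:
            self.lags = [1]

        # cosine templates over (period, phase); same half-span cap
        phases = np.arange(n_phases) / n_phases
        templates = [np.cos(2 * np.pi * (self.times / p - phi))
                     for p in usable for phi in phases]
        self.templates = np.asarray(templates)          # (n_templates, n)
        iu, ju = np.triu_indices(n, k=1)
        self._iu, self._ju = iu, ju
        self.n_pairs = iu.size
        tsign = np.sign(self.templates[:, iu] - self.templates[:, ju])
        self._template_sign = tsign                     # (n_templates, n_pairs)
        t_ties = np.sum(tsign == 0, axis=1)
        self._template_denom = np.sqrt(np.maximum(self.n_pairs - t_ties, 0))
        tc = self.templates - self.templates.mean(axis=1, keepdims=True)
        tnorm = np.linalg.norm(tc, axis=1)
        self._templates_centered = tc / np.where(tnorm > 1e-30, tnorm, 1.0)[:, None]

    def periodogram(self, rows: np.ndarray) -> np.ndarray:
        """Max normalized Lomb-Scargle power per row."""
        return _lombscargle_batch(rows, self.times, self.period_grid).max(axis=1)

    def autocorr(self, rows: np.ndarray) -> np.ndarray:
        """Max lagged Pearson autocorrelation per row over the period-grid lags."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        n = rows.shape[1]
        best = np.full(rows.shape[0], -np.inf)
        for lag in self.lags:
            a = rows[:, : n - lag]
            b = rows[:, lag:]
            ac = a - a.mean(axis=1, keepdims=True)
            bc = b - b.mean(axis=1, keepdims=True)
            denom = np.sqrt(np.sum(ac * ac, axis=1) * np.sum(bc * bc, axis=1))
            num = np.sum(ac * bc, axis=1)
            r = np.divide(num, denom, out=np.zeros_like(num), where=denom > 1e-30)
            best = np.maximum(best, r)
        return best

    def template(self, rows: np.ndarray) -> np.ndarray:
        """Max Kendall tau-b against the template bank, per row.

        A tiny continuous Pearson tie-breaker is added so the permutation
        distribution has no ties (the discrete tau alone would make
        permutation p-values conservative rather than uniform).
        """
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        ssign = np.sign(rows[:, self._iu] - rows[:, self._ju])
        s_ties = np.sum(ssign == 0, axis=1)
        s_denom = np.sqrt(np.maximum(self.n_pairs - s_ties, 0))
        concord = ssign @ self._template_sign.T        # (m, n_templates)
        denom = s_denom[:, None] * self._template_denom[None, :]
        tau = np.divide(concord, denom, out=np.zeros_like(concord),
                        where=denom > 1e-30)
        rc = rows - rows.mean(axis=1, keepdims=True)
        rnorm = np.linalg.norm(rc, axis=1)
        rc = rc / np.where(rnorm > 1e-30, rnorm, 1.0)[:, None]
        pearson = rc @ self._templates_centered.T
        return tau.max(axis=1) + _TIEBREAK * pearson.max(axis=1)

    def score(self, algorithm: str, rows: np.ndarray) -> np.ndarray:
        return {"periodogram": self.periodogram,
                "autocorr": self.autocorr,
                "template_rank": self.template}[algorithm](rows)


def periodicity_statistics(times, period_grid=None, n_phases: int = 8):
    """Per-series scoring callables ``{algorithm: f(series, times) -> float}``.

    The callables share code with :func:`call_periodic`'s batch path, so a
    generic :func:`permutation_pvalue` over them reproduces the pipeline's
    p-values exactly (given the same permutations).
    """
    if period_grid is None:
        period_grid = DEFAULT_PERIOD_GRID
    ctx = _ScoringContext(np.asarray(times, float), np.asarray(period_grid, float),
                          n_phases=n_phases)

    def make(alg):
        def statistic(series, _times=None):
            return float(ctx.score(alg, np.asarray(series, float))[0])
        return statistic

    return {alg: make(alg) for alg in ALGORITHMS}


# ---------------------------------------------------------------------------
# permutation null and FDR
# ---------------------------------------------------------------------------

def permutation_indices(n: int, n_perm: int, seed) -> np.ndarray:
    """``n_perm`` seeded random orderings of ``range(n)`` (rows)."""
    rng = np.random.default_rng(seed)
    return rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)


def permutation_pvalue(statistic, series, times, n_perm: int = 999, seed=0,
                       permutations: np.ndarray | None = None) -> float:
    """Add-one permutation p-value of ``statistic(series, times)``.

    ``p = (1 + #{permuted >= observed}) / (n_perm + 1)``; permutations
    shuffle the time-point order.  Pass ``permutations`` explicitly to use an
    exhaustive enumeration instead of sampling.
    """
    series = np.asarray(series, dtype=float)
    if permutations is None:
        if n_perm < 99:
            raise InputError("n_perm must be >= 99")
        permutations = permutation_indices(series.size, n_perm, seed)
    else:
        permutations = np.asarray(permutations)
        n_perm = permutations.shape[0]
    observed = statistic(series, times)
    count = 0
    for perm in permutations:
        if statistic(series[perm], times) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InputError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# consensus calling
# ---------------------------------------------------------------------------

def call_periodic(matrix: TimeSeriesMatrix, period_grid=None, alpha: float = 0.05,
                  n_perm: int = 999, seed: int = 0, n_phases: int = 8,
                  ) -> tuple[list[PeriodicityCall], ConsensusSet]:
    """Score every gene with all three algorithms and intersect the calls.

    Permutations are drawn per gene from ``(seed, gene_index)`` and shared
    across the three algorithms; per-algorithm BH control at ``alpha``
    precedes the intersection.
    """
    if not 0.0 <= alpha < 1.0:
        raise InputError("alpha must lie in [0, 1)")
    times = matrix.times
    if period_grid is None:
        dt = float(np.min(np.diff(times)))
        span = times[-1] - times[0]
        period_grid = DEFAULT_PERIOD_GRID[
            (DEFAULT_PERIOD_GRID >= 2 * dt) & (DEFAULT_PERIOD_GRID <= span)]
    ctx = _ScoringContext(times, np.asarray(period_grid, float), n_phases=n_phases)
    n = times.size

    scores = {alg: np.empty(matrix.n_genes) for alg in ALGORITHMS}
    pvals = {alg: np.empty(matrix.n_genes) for alg in ALGORITHMS}
    for gi in range(matrix.n_genes):
        series = matrix.values[gi]
        perms = permutation_indices(n, n_perm, [seed, gi])
        rows = np.vstack([series[None, :], series[perms]])
        for alg in ALGORITHMS:
            stat = ctx.score(alg, rows)
            scores[alg][gi] = stat[0]
            pvals[alg][gi] = (1 + np.sum(stat[1:] >= stat[0])) / (n_perm + 1)

    calls: list[PeriodicityCall] = []
    per_algorithm: dict[str, set[str]] = {}
    for alg in ALGORITHMS:
        q = bh_fdr(pvals[alg])
        sig = q <= alpha
        per_algorithm[alg] = {matrix.gene_ids[i] for i in np.flatnonzero(sig)}
        for gi, gene_id in enumerate(matrix.gene_ids):
            calls.append(PeriodicityCall(
                gene_id=gene_id, algorithm=alg,
                score=float(scores[alg][gi]), p_value=float(pvals[alg][gi]),
                q_value=float(q[gi]), significant=bool(sig[gi])))
    consensus = consensus_from_sets(per_algorithm, alpha)
    return calls, consensus


def consensus_from_sets(per_algorithm: dict[str, set[str]], alpha: float) -> ConsensusSet:
    """Intersection consensus over any subset of the per-algorithm call sets."""
    if not per_algorithm:
        return ConsensusSet(gene_ids=set(), per_algorithm={}, alpha=alpha)
    gene_ids = set.intersection(*per_algorithm.values())
    return ConsensusSet(gene_ids=gene_ids,
                        per_algorithm={k: set(v) for k, v in per_algorithm.items()},
                        alpha=alpha)


def consensus_from_calls(calls: list[PeriodicityCall], alpha: float,
                         algorithms=None) -> ConsensusSet:
    algorithms = tuple(algorithms) if algorithms is not None else ALGORITHMS
    per_algorithm = {alg: {c.gene_id for c in calls
                           if c.algorithm == alg and c.significant}
                     for alg in algorithms}
    return consensus_from_sets(per_algorithm, alpha)


# ---------------------------------------------------------------------------
# period / phase estimation
# ---------------------------------------------------------------------------

def estimate_period_phase(series, times, period_grid=None,
                          gene_id: str = "") -> PeriodPhaseEstimate:
    """Period from the periodogram argmax (quadratic refinement), phase from
    a least-squares cosine fit at the refined period.

    Argmax ties break toward the shorter period (the grid is ascending).  A
    maximum at either grid boundary is returned unrefined with
    ``boundary=True``.
    """
    series, times = _validate_series(series, times)
    if period_grid is None:
        period_grid = DEFAULT_PERIOD_GRID
    period_grid = np.asarray(period_grid, dtype=float)
    power = periodogram_power(series, times, period_grid)
    i = int(np.argmax(power))
    boundary = i == 0 or i == len(period_grid) - 1
    period = float(period_grid[i])
    if not boundary:
        x0, x1, x2 = period_grid[i - 1: i + 2]
        y0, y1, y2 = power[i - 1: i + 2]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        if abs(denom) > 1e-30:
            a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
            b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
            if a < 0:
                vertex = -b / (2 * a)
                period = float(np.clip(vertex, x0, x2))

    w = 2 * np.pi / period
    yc = series - series.mean()
    design = np.column_stack([np.cos(w * times), np.sin(w * times)])
    coef, *_ = np.linalg.lstsq(design, yc, rcond=None)
    peak_time = float((np.arctan2(coef[1], coef[0]) / (2 * np.pi) * period) % period)
    return PeriodPhaseEstimate(gene_id=gene_id, period=period, peak_time=peak_time,
                               power=float(power[i]), boundary=boundary)


def estimate_periods(matrix: TimeSeriesMatrix, gene_ids=None,
                     period_grid=None) -> list[PeriodPhaseEstimate]:
    """Period/phase estimates for a set of genes (default: all)."""
    wanted = list(matrix.gene_ids) if gene_ids is None else list(gene_ids)
    index = {g: i for i, g in enumerate(matrix.gene_ids)}
    out = []
    for g in wanted:
        if g not in index:
            raise InputError(f"gene {g!r} not in matrix")
        out.append(estimate_period_phase(matrix.values[index[g]], matrix.times,
                                         period_grid, gene_id=g))
    return out
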