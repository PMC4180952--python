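"""Generative models for synchronized-population expression time courses.

Single cells traverse the cell cycle as a phase in [0, 1); a synchronized
population starts as a tight phase distribution that broadens over time, so
the population-average (bulk) signal of a phase-locked transcript damps even
though every cell keeps oscillating.  Arrest conditions replace a gene's
free-running trajectory with a condition-specific program (repression after
the first expression pulse, a persistent plateau, silence, ...).

All times are minutes; phases are cell-cycle fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import ConfigurationError, InputError, InvalidModelError

CONDITIONS = (
    "WT",
    "CDK_ON",
    "CDK_OFF",
    "REP_CHECKPOINT",
    "SPINDLE_CHECKPOINT",
    "REP_CHECKPOINT_RAD53OFF",
)

REGULONS = ("SBF", "MBF", "SFF", "SWI5_ACE2", "OTHER")

PROGRAMS = (
    "continue",
    "repress_after_first_peak",
    "persistent_high",
    "off",
    "one_cycle_then_repress",
)

#: wraps summed when evaluating the wrapped-normal phase density
_N_WRAPS = 5
_DEFAULT_NODES = 256


@dataclass
class GeneModel:
    """Single-cell expression profile of one gene plus its arrest programs.

    The single-cell profile is ``b + a * exp(kappa * (cos(2*pi*(theta - phi)) - 1))``:
    a von Mises-shaped bump of height ``a`` on baseline ``b``, peaking at
    phase ``phi`` with sharpness ``kappa``.  ``programs`` maps a condition
    label to one of :data:`PROGRAMS`.
    """

    gene_id: str
    baseline: float
    amplitude: float
    peak_phase: float
    concentration: float
    regulon: str = "OTHER"
    programs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        vals = (self.baseline, self.amplitude, self.peak_phase, self.concentration)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidModelError(f"{self.gene_id}: non-finite parameter in {vals}")
        if self.baseline < 0 or self.amplitude < 0 or self.concentration < 0:
            raise InvalidModelError(f"{self.gene_id}: negative parameter")
        if not 0.0 <= self.peak_phase < 1.0:
            raise InvalidModelError(f"{self.gene_id}: peak_phase {self.peak_phase} outside [0,1)")
        if self.regulon not in REGULONS:
            raise InvalidModelError(f"{self.gene_id}: unknown regulon {self.regulon!r}")
        for cond, prog in self.programs.items():
            if prog not in PROGRAMS:
                raise ConfigurationError(f"{self.gene_id}: unknown program {prog!r} for {cond}")


@dataclass
class SynchronyModel:
    """Phase distribution of the synchronized population.

    The phase at time ``t`` is wrapped-normal with mean
    ``initial_phase + t / period`` and standard deviation
    ``sqrt(initial_sd**2 + (dispersion_rate * t / period)**2)``.
    ``bud_phase`` is the phase at which a cell buds.
    """

    initial_phase: float = 0.05
    initial_sd: float = 0.03
    period: float = 90.0
    dispersion_rate: float = 0.05
    bud_phase: float = 0.3

    def __post_init__(self):
        vals = (self.initial_phase, self.initial_sd, self.period,
                self.dispersion_rate, self.bud_phase)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidModelError(f"non-finite synchrony parameter in {vals}")
        if self.initial_sd < 0 or self.dispersion_rate < 0:
            raise InvalidModelError("initial_sd and dispersion_rate must be >= 0")
        if self.period <= 0:
            raise InvalidModelError("period must be positive")
        if not 0.0 < self.bud_phase < 1.0:
            raise InvalidModelError("bud_phase must lie in (0,1)")

    def phase_sd(self, t):
        """Phase standard deviation at time ``t`` (non-decreasing)."""
        t = np.asarray(t, dtype=float)
        return np.sqrt(self.initial_sd ** 2 + (self.dispersion_rate * t / self.period) ** 2)

    def phase_mean(self, t):
        t = np.asarray(t, dtype=float)
        return self.initial_phase + t / self.period


@dataclass
class ExperimentDesign:
    condition: str = "WT"
    dt: float = 20.0
    total_time: float = 300.0
    noise_cv: float = 0.1
    seed: int = 0
    replicate: int = 1

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if self.dt <= 0 or self.total_time < self.dt:
            raise ConfigurationError("need dt > 0 and total_time >= dt")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.replicate < 1:
            raise ConfigurationError("replicate must be >= 1")

    def times(self) -> np.ndarray:
        n = int(np.floor(self.total_time / self.dt)) + 1
        return np.arange(n) * self.dt


@dataclass
class TimeSeriesMatrix:
    """Gene x time expression values for one condition/replicate."""

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray
    condition: str = "WT"
    replicate: int = 1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise InputError(f"duplicate gene ids: {dupes}")
        if self.values.shape != (len(self.gene_ids), len(self.times)):
            raise InputError(
                f"values shape {self.values.shape} != "
                f"({len(self.gene_ids)}, {len(self.times)})")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InputError("values must be finite")
        if np.any(self.values < 0):
            raise InputError("values must be >= 0")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class BuddingCurve:
    times: np.ndarray
    fraction_budded: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fraction_budded = np.asarray(self.fraction_budded, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise InputError("times must be strictly increasing")
        if np.any((self.fraction_budded < 0) | (self.fraction_budded > 1)):
            raise InputError("fraction_budded must lie in [0,1]")


def _bump(theta, peak_phase, concentration):
    return np.exp(concentration * (np.cos(2.0 * np.pi * (theta - peak_phase)) - 1.0))


def mean_profile(model: GeneModel, sync: SynchronyModel, t, n_nodes: int = _DEFAULT_NODES):
    """Population-average expression of ``model`` at time(s) ``t``.

    Returns ``b + a * E[f(Theta_t)]`` where ``Theta_t`` is the wrapped-normal
    population phase.  The expectation is a deterministic quadrature over
    ``n_nodes`` uniform nodes on [0, 1); dispersion damps the bulk amplitude.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise InvalidModelError("t must be >= 0")
    if model.amplitude == 0.0:
        out = np.full(t_arr.shape, model.baseline)
        return out if np.ndim(t) else float(out[0])

    mu = sync.phase_mean(t_arr) % 1.0
    sd = sync.phase_sd(t_arr)
    expectation = np.empty_like(mu)

    degenerate = sd == 0.0
    if np.any(degenerate):
        expectation[degenerate] = _bump(mu[degenerate], model.peak_phase, model.concentration)
    if np.any(~degenerate):
        nodes = (np.arange(n_nodes) + 0.5) / n_nodes
        f = _bump(nodes, model.peak_phase, model.concentration)
        mu_d = mu[~degenerate][:, None]
        sd_d = sd[~degenerate][:, None]
        half = _N_WRAPS // 2
        dens = np.zeros((mu_d.shape[0], n_nodes))
        for k in range(-half, half + 1):
            z = (nodes[None, :] - mu_d + k) / sd_d
            dens += np.exp(-0.5 * z * z)
        dens /= dens.sum(axis=1, keepdims=True)
        expectation[~degenerate] = dens @ f

    out = model.baseline + model.amplitude * expectation
    return out if np.ndim(t) else float(out[0])


def first_peak_time(model: GeneModel, sync: SynchronyModel) -> float:
    """Time at which the population mean phase first reaches the gene's peak phase."""
    return ((model.peak_phase - sync.initial_phase) % 1.0) * sync.period


def apply_arrest_program(model: GeneModel, condition: str, sync: SynchronyModel, t,
                         n_nodes: int = _DEFAULT_NODES):
    """Trajectory of ``model`` under its arrest program for ``condition``.

    Programs: ``continue`` leaves the free-running bulk profile untouched;
    ``repress_after_first_peak`` decays exponentially to baseline (half-life
    period/4) starting a quarter cycle after the first peak;
    ``persistent_high`` clamps at baseline+amplitude from the first peak on;
    ``off`` is flat baseline; ``one_cycle_then_repress`` allows one extra full
    cycle before the same decay.
    """
    if condition not in model.programs:
        raise ConfigurationError(
            f"{model.gene_id}: no program for condition {condition!r}")
    program = model.programs[condition]
    if program not in PROGRAMS:
        raise ConfigurationError(f"{model.gene_id}: unknown program {program!r}")

    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    scalar = np.ndim(t) == 0

    def _done(out):
        return float(out[0]) if scalar else out

    if program == "off":
        return _done(np.full(t_arr.shape, model.baseline))

    free = np.atleast_1d(mean_profile(model, sync, t_arr, n_nodes=n_nodes))
    if program == "continue":
        return _done(free)

    t_peak = first_peak_time(model, sync)
    if program == "persistent_high":
        plateau = model.baseline + model.amplitude
        out = np.where(t_arr < t_peak, free, plateau)
        return _done(out)

    # repression programs: decay to baseline with half-life period/4
    t_onset = t_peak + 0.25 * sync.period
    if program == "one_cycle_then_repress":
        t_onset += sync.period
    half_life = sync.period / 4.0
    v_onset = mean_profile(model, sync, t_onset, n_nodes=n_nodes)
    decay = model.baseline + (v_onset - model.baseline) * np.power(
        2.0, -(t_arr - t_onset) / half_life)
    out = np.where(t_arr <= t_onset, free, decay)
    return _done(out)


def simulate_experiment(models: list[GeneModel], sync: SynchronyModel,
                        design: ExperimentDesign,
                        n_nodes: int = _DEFAULT_NODES) -> TimeSeriesMatrix:
    """Simulate a bulk expression matrix with multiplicative lognormal noise.

    Noise per entry is ``exp(eps)`` with ``eps ~ Normal(-noise_cv**2/2, noise_cv)``
    (unit mean), drawn from a stream seeded by ``(design.seed, gene_index)`` in
    time order, so results are reproducible and independent of other genes.
    """
    gene_ids = [m.gene_id for m in models]
    if len(set(gene_ids)) != len(gene_ids):
        raise InputError("duplicate gene_ids in models")
    times = design.times()
    cv = design.noise_cv
    values = np.empty((len(models), len(times)))
    for gi, model in enumerate(models):
        traj = np.atleast_1d(
            apply_arrest_program(model, design.condition, sync, times, n_nodes=n_nodes))
        if cv > 0:
            rng = np.random.default_rng([design.seed, design.replicate, gi])
            eps = rng.normal(-0.5 * cv * cv, cv, size=times.shape)
            traj = traj * np.exp(eps)
        values[gi] = traj
    return TimeSeriesMatrix(gene_ids=gene_ids, times=times, values=values,
                            condition=design.condition, replicate=design.replicate)


def simulate_budding(sync: SynchronyModel, design: ExperimentDesign) -> BuddingCurve:
    """Budding-index curve for the design's condition.

    The first-cycle fraction budded is ``Phi((theta0 + t/p - theta_bud) / sigma(t))``.
    Arrest conditions keep cells budded, so the curve is the running maximum;
    WT cells divide at phase 1 and shed the bud, so the WT curve is periodic:
    the probability that the wrapped phase lies in [theta_bud, 1).
    """
    times = design.times()
    mu = sync.phase_mean(times)
    sd = sync.phase_sd(times)

    if design.condition == "WT":
        frac = np.zeros_like(times)
        with np.errstate(divide="ignore", invalid="ignore"):
            for i, (m, s) in enumerate(zip(mu, sd)):
                if s == 0.0:
                    frac[i] = 1.0 if (m % 1.0) >= sync.bud_phase else 0.0
                else:
                    lo = int(np.floor(m)) - 3
                    hi = int(np.floor(m)) + 3
                    acc = 0.0
                    for k in range(lo, hi + 1):
                        acc += norm.cdf((1.0 + k - m) / s) - norm.cdf(
                            (sync.bud_phase + k - m) / s)
                    frac[i] = acc
        frac = np.clip(frac, 0.0, 1.0)
        return BuddingCurve(times=times, fraction_budded=frac)

    z = mu - sync.bud_phase
    frac = np.empty_like(times)
    zero_sd = sd == 0.0
    frac[zero_sd] = np.where(z[zero_sd] > 0, 1.0, np.where(z[zero_sd] < 0, 0.0, 0.5))
    if np.any(~zero_sd):
        frac[~zero_sd] = norm.cdf(z[~zero_sd] / sd[~zero_sd])
    frac = np.clip(frac, 0.0, 1.0)
    frac = np.maximum.accumulate(frac)  # arrested cells stay budded
    return BuddingCurve(times=times, fraction_budded=frac)


# ---------------------------------------------------------------------------
# default scenario
# ---------------------------------------------------------------------------

#: typical peak phase of each regulon (G1/S for SBF/MBF, G2/M for SFF, M/G1
#: for Swi5/Ace2)
REGULON_PHASES = {"SBF": 0.15, "MBF": 0.22, "SFF": 0.55, "SWI5_ACE2": 0.75}

#: documented free choice: fraction of genes assigned to each regulon
DEFAULT_PROPORTIONS = {"SBF": 0.2, "MBF": 0.2, "SFF": 0.2, "SWI5_ACE2": 0.1, "OTHER": 0.3}

#: per-regulon arrest program for each condition
DEFAULT_PROGRAMS = {
    "WT": {r: "continue" for r in REGULONS},
    "CDK_ON": {
        "SBF": "repress_after_first_peak",
        "MBF": "continue",
        "SFF": "persistent_high",
        "SWI5_ACE2": "off",
        "OTHER": "continue",
    },
    "CDK_OFF": {r: "continue" for r in REGULONS},
    "REP_CHECKPOINT": {
        "SBF": "one_cycle_then_repress",
        "MBF": "persistent_high",
        "SFF": "one_cycle_then_repress",
        "SWI5_ACE2": "off",
        "OTHER": "continue",
    },
    "SPINDLE_CHECKPOINT": {
        "SBF": "one_cycle_then_repress",
        "MBF": "one_cycle_then_repress",
        "SFF": "persistent_high",
        "SWI5_ACE2": "off",
        "OTHER": "continue",
    },
    "REP_CHECKPOINT_RAD53OFF": {
        "SBF": "continue",
        "MBF": "continue",
        "SFF": "persistent_high",
        "SWI5_ACE2": "off",
        "OTHER": "continue",
    },
}


def build_gene_models(n_genes: int, seed: int,
                      proportions: dict[str, float] | None = None,
                      programs: dict[str, dict[str, str]] | None = None,
                      phase_jitter: float = 0.03) -> list[GeneModel]:
    """Build a regulon-structured gene panel.

    Regulon members get a strong phase-locked bump near the regulon's
    characteristic phase; OTHER genes are aperiodic (amplitude 0) with varied
    constitutive baselines.
    """
    proportions = dict(DEFAULT_PROPORTIONS if proportions is None else proportions)
    programs = DEFAULT_PROGRAMS if programs is None else programs
    if abs(sum(proportions.values()) - 1.0) > 1e-6:
        raise ConfigurationError("regulon proportions must sum to 1")
    rng = np.random.default_rng(seed)

    counts = {r: int(round(p * n_genes)) for r, p in proportions.items()}
    # fix rounding drift on the largest class
    drift = n_genes - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift

    models = []
    gi = 0
    for regulon in REGULONS:
        for _ in range(counts.get(regulon, 0)):
            gene_id = f"g{gi:05d}_{regulon}"
            baseline = float(rng.uniform(0.5, 2.0))
            if regulon == "OTHER":
                amplitude, kappa = 0.0, 0.0
                phase = float(rng.uniform(0.0, 1.0))
            else:
                amplitude = baseline * float(rng.uniform(6.0, 10.0))
                kappa = float(rng.uniform(4.0, 7.0))
                phase = (REGULON_PHASES[regulon] + rng.normal(0.0, phase_jitter)) % 1.0
            gene_programs = {cond: prog_map.get(regulon, "continue")
                             for cond, prog_map in programs.items()}
            models.append(GeneModel(
                gene_id=gene_id, baseline=baseline, amplitude=amplitude,
                peak_phase=phase, concentration=kappa, regulon=regulon,
                programs=gene_programs))
            gi += 1
    return models


def periodic_gene_models(n_genes: int, seed: int) -> list[GeneModel]:
    """Panel of purely periodic genes (uniform random peak phases), all `continue`."""
    rng = np.random.default_rng(seed)
    models = []
    for gi in range(n_genes):
        baseline = float(rng.uniform(0.5, 2.0))
        models.append(GeneModel(
            gene_id=f"p{gi:05d}",
            baseline=baseline,
            amplitude=baseline * float(rng.uniform(6.0, 10.0)),
            peak_phase=float(rng.uniform(0.0, 1.0)),
            concentration=float(rng.uniform(4.0, 7.0)),
            regulon="OTHER",
            programs={c: "continue" for c in CONDITIONS}))
    return models


def constitutive_gene_models(n_genes: int, seed: int) -> list[GeneModel]:
    """Panel of flat genes; with noise they produce white-noise rows."""
    rng = np.random.default_rng(seed)
    return [GeneModel(
        gene_id=f"c{gi:05d}",
        baseline=float(rng.uniform(0.5, 2.0)),
        amplitude=0.0, peak_phase=0.0, concentration=0.0,
        regulon="OTHER",
        programs={c: "continue" for c in CONDITIONS}) for gi in range(n_genes)]
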