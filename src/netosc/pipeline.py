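"""End-to-end run: simulate -> detect -> classify -> enrich -> report.

Every artifact is a deterministic function of the run configuration and
seed, so rerunning a config reproduces all tables byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import __version__, io
from .arrest_dynamics import (BehaviorLabel, BehaviorThresholds, align_at_anchor,
                              classify_matrix, compare_periods, log2_relative_to_mean,
                              persistence_overlap, replicate_concordance, t50_budded)
from .enrichment import GeneSetAnnotation, cluster_overrepresentation
from .errors import ConfigurationError
from .periodicity import (ALGORITHMS, PeriodicityCall, call_periodic,
                          estimate_periods)
from .synthgen import (CONDITIONS, ExperimentDesign, SynchronyModel,
                       build_gene_models, simulate_budding, simulate_experiment)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat, fully serializable run configuration."""

    # scenario
    n_genes: int = 200
    arrest_condition: str = "CDK_ON"
    dt: float = 20.0
    total_time: float = 360.0
    noise_cv: float = 0.1
    period: float = 100.0
    initial_phase: float = 0.05
    initial_sd: float = 0.03
    dispersion_rate: float = 0.05
    bud_phase: float = 0.3
    # analysis
    period_grid_min: float = 40.0
    period_grid_max: float = 240.0
    period_grid_step: float = 10.0
    alpha: float = 0.05
    n_perm: int = 199
    persistent_ratio: float = 0.6
    repressed_ratio: float = 0.3
    peak_ratio: float = 2.0
    window_start_factor: float = 1.25
    # bookkeeping
    seed: int = 0
    out_dir: str = "netosc_run"

    def __post_init__(self):
        if self.arrest_condition not in CONDITIONS:
            raise ConfigurationError(
                f"unknown arrest condition {self.arrest_condition!r}")
        if not 0.0 <= self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in [0, 1)")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def synchrony(self) -> SynchronyModel:
        return SynchronyModel(initial_phase=self.initial_phase,
                              initial_sd=self.initial_sd, period=self.period,
                              dispersion_rate=self.dispersion_rate,
                              bud_phase=self.bud_phase)

    def period_grid(self) -> np.ndarray:
        grid = np.arange(self.period_grid_min,
                         self.period_grid_max + 0.5 * self.period_grid_step,
                         self.period_grid_step)
        lo, hi = 2 * self.dt, self.total_time
        return grid[(grid >= lo) & (grid <= hi)]

    def thresholds(self) -> BehaviorThresholds:
        return BehaviorThresholds(alpha=self.alpha,
                                  persistent_ratio=self.persistent_ratio,
                                  repressed_ratio=self.repressed_ratio,
                                  peak_ratio=self.peak_ratio,
                                  window_start_factor=self.window_start_factor)


# ---------------------------------------------------------------------------
# table writers (deterministic, 6 significant digits)
# ---------------------------------------------------------------------------

def write_calls(calls: list[PeriodicityCall], path) -> None:
    rows = sorted(calls, key=lambda c: (c.algorithm, c.gene_id))
    with Path(path).open("w") as fh:
        fh.write("gene_id\talgorithm\tscore\tp_value\tq_value\tsignificant\n")
        for c in rows:
            fh.write("\t".join([c.gene_id, c.algorithm, io.fmt(c.score),
                                io.fmt(c.p_value), io.fmt(c.q_value),
                                "1" if c.significant else "0"]) + "\n")


def write_gene_list(gene_ids, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_id\n")
        for g in sorted(gene_ids):
            fh.write(g + "\n")


def write_labels(labels: list[BehaviorLabel], path) -> None:
    keys = ["post_window_q", "late_mean_ratio", "late_slope_sign",
            "first_cycle_peak_ratio"]
    with Path(path).open("w") as fh:
        fh.write("gene_id\tcondition\tlabel\t" + "\t".join(keys) + "\n")
        for lab in sorted(labels, key=lambda x: x.gene_id):
            feats = [io.fmt(lab.features.get(k, float("nan"))) for k in keys]
            fh.write("\t".join([lab.gene_id, lab.condition, lab.label] + feats) + "\n")


def read_labels(path) -> list[BehaviorLabel]:
    labels = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rec = dict(zip(header, fields))
            feats = {k: float(v) for k, v in rec.items()
                     if k not in ("gene_id", "condition", "label")}
            labels.append(BehaviorLabel(gene_id=rec["gene_id"],
                                        condition=rec["condition"],
                                        label=rec["label"], features=feats))
    return labels


def write_enrichment(rows, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("tf_name\tcluster_id\tk\tn\tK\tN\tp_value\tq_value\n")
        for r in rows:
            fh.write("\t".join([r.tf_name, r.cluster_id, str(r.k), str(r.n),
                                str(r.K), str(r.N), io.fmt(r.p_value),
                                io.fmt(r.q_value)]) + "\n")


def render_heatmap(normalized: np.ndarray, gene_order: list[str],
                   gene_ids: list[str], times: np.ndarray, path,
                   title: str = "") -> None:
    """Thin presentation layer: ordered log2 heat map to a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    index = {g: i for i, g in enumerate(gene_ids)}
    data = normalized[[index[g] for g in gene_order if g in index]]
    fig, ax = plt.subplots(figsize=(6, 8))
    vmax = max(1e-6, float(np.percentile(np.abs(data), 98))) if data.size else 1.0
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                   extent=(times[0], times[-1], data.shape[0], 0))
    ax.set_xlabel("time (min)")
    ax.set_ylabel("genes (ordered by peak time)")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="log2 fold change vs gene mean")
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, render: bool = True) -> dict:
    """Execute the full analysis and write the report bundle to ``config.out_dir``.

    Returns a summary dict with the main in-memory results.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run_pipeline: seed=%d out=%s", config.seed, out)

    sync = config.synchrony()
    grid = config.period_grid()
    thresholds = config.thresholds()
    models = build_gene_models(config.n_genes, seed=config.seed)

    # --- simulate -----------------------------------------------------------
    def design(condition, replicate):
        return ExperimentDesign(condition=condition, dt=config.dt,
                                total_time=config.total_time,
                                noise_cv=config.noise_cv, seed=config.seed,
                                replicate=replicate)

    wt1 = simulate_experiment(models, sync, design("WT", 1))
    wt2 = simulate_experiment(models, sync, design("WT", 2))
    arrest = simulate_experiment(models, sync, design(config.arrest_condition, 1))
    bud_wt = simulate_budding(sync, design("WT", 1))
    bud_arrest = simulate_budding(sync, design(config.arrest_condition, 1))

    io.write_matrix(wt1, out / "matrix_WT_rep1.tsv")
    io.write_matrix(wt2, out / "matrix_WT_rep2.tsv")
    io.write_matrix(arrest, out / f"matrix_{config.arrest_condition}.tsv")
    io.write_budding_curve(bud_wt, out / "budding_WT.tsv")
    io.write_budding_curve(bud_arrest, out / f"budding_{config.arrest_condition}.tsv")

    # --- detect -------------------------------------------------------------
    wt_calls, wt_consensus = call_periodic(wt1, period_grid=grid,
                                           alpha=config.alpha,
                                           n_perm=config.n_perm, seed=config.seed)
    ar_calls, ar_consensus = call_periodic(arrest, period_grid=grid,
                                           alpha=config.alpha,
                                           n_perm=config.n_perm, seed=config.seed)
    write_calls(wt_calls, out / "calls_WT.tsv")
    write_calls(ar_calls, out / f"calls_{config.arrest_condition}.tsv")
    write_gene_list(wt_consensus.gene_ids, out / "consensus_WT.tsv")
    write_gene_list(ar_consensus.gene_ids,
                    out / f"consensus_{config.arrest_condition}.tsv")

    consensus_genes = sorted(wt_consensus.gene_ids)
    wt_estimates = estimate_periods(wt1, consensus_genes, grid)
    wt_period = (float(np.median([e.period for e in wt_estimates]))
                 if wt_estimates else config.period)

    # --- classify (the WT-periodic genes, in the arrest condition) ----------
    labels: list[BehaviorLabel] = []
    if consensus_genes:
        idx = [arrest.gene_ids.index(g) for g in consensus_genes]
        sub = type(arrest)(gene_ids=consensus_genes, times=arrest.times,
                           values=arrest.values[idx], condition=arrest.condition,
                           replicate=arrest.replicate)
        labels = classify_matrix(sub, wt_period, thresholds,
                                 n_perm=config.n_perm, seed=config.seed,
                                 period_grid=None)
    write_labels(labels, out / "behavior_labels.tsv")

    # --- overlaps / periods / concordance -----------------------------------
    with (out / "overlap.tsv").open("w") as fh:
        fh.write("set_a\tset_b\tset_a_size\tset_b_size\tintersection\tfraction_of_a\n")
        if wt_consensus.gene_ids:
            ov = persistence_overlap(wt_consensus.gene_ids, ar_consensus.gene_ids)
            fh.write("\t".join(["WT", config.arrest_condition,
                                str(ov.set_a_size), str(ov.set_b_size),
                                str(ov.intersection), io.fmt(ov.fraction_of_a)]) + "\n")

    shared = sorted(wt_consensus.gene_ids & ar_consensus.gene_ids)
    with (out / "period_comparison.tsv").open("w") as fh:
        fh.write("median_a\tmedian_b\tmedian_abs_diff\tn_shared\n")
        if shared:
            ar_estimates = estimate_periods(arrest, shared, grid)
            wt_shared = [e for e in wt_estimates if e.gene_id in set(shared)]
            cmp = compare_periods(wt_shared, ar_estimates)
            fh.write("\t".join([io.fmt(cmp["median_a"]), io.fmt(cmp["median_b"]),
                                io.fmt(cmp["median_abs_diff"]),
                                str(cmp["n_shared"])]) + "\n")

    r2 = replicate_concordance(wt1, wt2)
    with (out / "concordance.tsv").open("w") as fh:
        fh.write("rep_a\trep_b\tr_squared\n")
        fh.write("WT_rep1\tWT_rep2\t" + io.fmt(r2) + "\n")

    # --- enrichment ---------------------------------------------------------
    regulons: dict[str, set[str]] = {}
    for m in models:
        if m.regulon != "OTHER":
            regulons.setdefault(m.regulon, set()).add(m.gene_id)
    annotations = [GeneSetAnnotation(tf_name=r, targets=g)
                   for r, g in sorted(regulons.items())]
    io.write_gene_sets(annotations, out / "regulons.gmt")

    clusters: dict[str, set[str]] = {}
    for lab in labels:
        clusters.setdefault(lab.label, set()).add(lab.gene_id)
    universe = set(arrest.gene_ids)
    enrichment_rows = cluster_overrepresentation(clusters, annotations, universe,
                                                 alpha=config.alpha) if clusters else []
    write_enrichment(enrichment_rows, out / "enrichment.tsv")

    # --- report -------------------------------------------------------------
    order = io.order_by_peak_time(list(wt1.gene_ids), wt_estimates)
    with (out / "gene_order.tsv").open("w") as fh:
        fh.write("rank\tgene_id\n")
        for rank, g in enumerate(order):
            fh.write(f"{rank}\t{g}\n")

    t50_wt = t50_budded(bud_wt)
    t50_ar = t50_budded(bud_arrest)
    with (out / "anchors.tsv").open("w") as fh:
        fh.write("condition\tt50\n")
        fh.write("WT\t" + io.fmt(t50_wt) + "\n")
        fh.write(config.arrest_condition + "\t" + io.fmt(t50_ar) + "\n")
    aligned, _span = align_at_anchor([wt1, arrest], [t50_wt, t50_ar])
    io.write_matrix(aligned[0], out / "matrix_WT_rep1_aligned.tsv")
    io.write_matrix(aligned[1],
                    out / f"matrix_{config.arrest_condition}_aligned.tsv")

    if render:
        norm_wt = log2_relative_to_mean(wt1, pseudocount=1.0)
        norm_ar = log2_relative_to_mean(arrest, pseudocount=1.0)
        render_heatmap(norm_wt, order, wt1.gene_ids, wt1.times,
                       out / "heatmap_WT.png", title="WT")
        render_heatmap(norm_ar, order, arrest.gene_ids, arrest.times,
                       out / f"heatmap_{config.arrest_condition}.png",
                       title=config.arrest_condition)

    # --- provenance ---------------------------------------------------------
    provenance = dict(asdict(config))
    provenance["netosc_version"] = __version__
    io.save_flat_config(provenance, out / "provenance.yaml")

    return {
        "wt_consensus": wt_consensus,
        "arrest_consensus": ar_consensus,
        "labels": labels,
        "enrichment": enrichment_rows,
        "wt_period": wt_period,
        "r_squared": r2,
        "t50": {"WT": t50_wt, config.arrest_condition: t50_ar},
    }
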