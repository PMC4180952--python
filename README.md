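# netosc

Simulation and analysis of cell-cycle transcription-network oscillations in
synchronized yeast populations under checkpoint and CDK arrests.

The package provides:

- **`netosc.synthgen`** — generative models for bulk expression time courses:
  per-gene single-cell profiles (von Mises-shaped bumps over cell-cycle
  phase), a wrapped-normal population-synchrony model with progressive
  dispersion (bulk amplitude damping), per-regulon arrest programs
  (`continue`, `repress_after_first_peak`, `persistent_high`, `off`,
  `one_cycle_then_repress`), multiplicative lognormal measurement noise, and
  budding-index curves.
- **`netosc.periodicity`** — per-gene rhythmicity scoring with three
  independent statistics (Lomb–Scargle periodogram maximum, lagged
  autocorrelation maximum, rank-based cosine-template matching), seeded
  permutation p-values, Benjamini–Hochberg FDR, and the high-confidence
  periodic set as the intersection of the per-algorithm calls; period/phase
  estimation with quadratic refinement.
- **`netosc.arrest_dynamics`** — log2-to-gene-mean normalization, 50%-budded
  anchor estimation and cross-condition time alignment, per-gene arrest
  behavior classification (`oscillating` / `damped` / `persistent_high` /
  `repressed` / `low_flat`), persistence overlaps, replicate concordance
  (r²), and period comparisons.
- **`netosc.enrichment`** — one-sided hypergeometric overrepresentation of
  TF target sets within behavior clusters, BH-corrected across all pairs.
- **`netosc.io` / `netosc.pipeline` / `netosc.cli`** — TSV matrices, GMT
  gene sets, flat YAML configs, deterministic report tables, heat-map
  rendering, and the CLI.

## CLI

```sh
# full pipeline (simulate -> detect -> classify -> enrich -> report)
netosc all --seed 1 --n-genes 200 --out-dir results/demo

# individual stages
netosc simulate --seed 1 --n-genes 200 --condition WT --condition CDK_ON --out-dir results/sim
netosc detect   --matrix results/sim/matrix_WT.tsv --out-dir results/detect
netosc classify --matrix results/sim/matrix_CDK_ON.tsv --wt-period 100 --out-dir results/classify
netosc enrich   --labels results/classify/behavior_labels.tsv \
                --gene-sets results/sim/regulons.gmt \
                --universe results/sim/matrix_CDK_ON.tsv --out-dir results/enrich
netosc report   --matrix results/sim/matrix_WT.tsv --out-dir results/report
```

Flags override a `--config` flat YAML file, which overrides built-in
defaults. Every run is fully determined by its config and `--seed`;
rerunning reproduces all result tables byte-for-byte.

## Output bundle (netosc all)

Per run directory: expression matrices and budding curves per condition,
per-algorithm periodicity calls and consensus gene lists, behavior labels
with features, persistence overlap, period comparison, replicate
concordance, regulon GMT, enrichment table, peak-time gene ordering,
50%-budded anchors plus anchored matrices, heat-map PNGs, and a
`provenance.yaml` echoing the full configuration and seed.
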