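# qhtskit

Analysis toolkit for **quantitative high-throughput screening (qHTS) of
reporter-loss assays**, built around the strictly standardized mean
difference (SSMD). It implements the full desk side of a phenotypic
neuroprotection screen in which a fluorescent reporter marks a cell
population (e.g. YFP-labelled rod photoreceptors in zebrafish larvae),
prodrug-induced ablation collapses the signal, and candidate drugs are
scored by how much signal they preserve.

The package is for screening teams and computational biologists who need:

- **Plate modelling & I/O** — 96-well qHTS layouts (titration series in
  column blocks), a canonical long-format well-table CSV, dilution-series
  generation.
- **Synthetic screens** — a generative model with planted pharmacology
  (Hill-shaped protection, toxicity, compound autofluorescence, dispensing
  errors) and a ground-truth table, so every downstream stage is testable
  without instrument data.
- **QC** — background signal cutoffs from non-transgenic controls
  (mean + k·SD), well filtering, and assay-level SSMD quality control.
- **Hit calling** — per-concentration SSMD scores, effect-class bands,
  dose-trend labels, artifact exclusions.
- **Confirmation statistics** — normalization to the control signal
  window, pooled effects with 95% CIs, Student/Welch t, Bonferroni,
  Fisher's exact, Mann-Whitney U, BH-FDR, ΔΔCt fold changes.
- **Combination analysis** — additive/synergistic classification of
  compound pairs with significance tiers.
- **Power design** — sample sizes for detecting a chosen fraction of the
  signal window, with Monte-Carlo verification.

## The core statistic

For a treated group and negative (fully ablated) controls,

```
SSMD:  β̂ = (x̄_t − x̄_neg) / √(s_t² + s_neg²)
```

β̂ estimates the mean difference in units of the combined spread. A
compound whose best concentration reaches **SSMD ≥ 1** is a candidate hit;
hits are banded fairly moderate [1, 1.28), moderate [1.28, 1.645),
semi-strong [1.645, 2), strong [2, 3), very strong ≥ 3. The same statistic
applied to the ± ablation controls is the assay's QC score (pass at
≥ 1.645). For confirmation, per-well signals are normalized to the control
window,

```
N_i = 100 · (S_i − X̄_neg) / (X̄_pos − X̄_neg)   [% of window]
```

so identical conditions pool across experimental repeats.

## Worked example

Simulate a 24-compound primary screen (3 planted protectants, Emax 0.5 at
saturating dose) and analyse it:

```yaml
# screen.yaml
seed: 11
output_dir: demo/out
design:
  stage: primary
  top_concentration_uM: 4.0
  fold: 2.0
  n_levels: 6
  replicates: 16
  controls: {neg_ctrl: 32, pos_ctrl: 32, nontransgenic: 16}
simulation:
  n_compounds: 24
  frac_protective: 0.125
```

```
$ qhtskit simulate screen.yaml
wrote 2384 wells for 24 compounds to demo/out
$ qhtskit screen analyse.yaml       # inputs: demo/out/well_table.csv
well_table: QC pass (SSMD 1.72), 3 hits of 24 compounds
```

The run's QC score of 1.72 clears the 1.645 pass threshold, so hit calls
are trustworthy. The hit list (`well_table_hits.csv`) contains exactly the
three planted protectants, banded by their maximal SSMD:

```
compound_id  max_ssmd  best_concentration_uM effect_class    dose_trend  is_hit
      C0009      1.57                    2.0     moderate discontinuous    True
      C0019      1.76                    2.0  semi_strong discontinuous    True
      C0022      2.57                    0.5       strong discontinuous    True
```

`well_table_ssmd.csv` holds the full per-concentration score table and
`well_table_heatmaps/` one 8×12 signal grid per plate. Other subcommands:
`confirm` (pooled normalized effects across repeats), `combo` (pair
additivity/synergy), `power` (sample-size tables), `report` (simulate +
screen in one step).

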