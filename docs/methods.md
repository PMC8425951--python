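# Methods

This note documents the statistical procedures, the generative model
behind the synthetic screens, the default parameters and why they were
chosen, and the numerical decisions taken where the design was open.

## Screening model and statistics

**SSMD scoring.** Each (compound, concentration) group is scored against
the same run's ablated vehicle controls with the strictly standardized
mean difference, method-of-moments form β̂ = (x̄_t − x̄_n)/√(s_t² + s_n²),
sample SDs with the n−1 denominator throughout. An unbiased variant
(`estimator="umvue"`) multiplies β̂ by the small-sample Gamma correction
√(2/K)·Γ(K/2)/Γ((K−1)/2), K = n_t + n_n − 2, which removes the upward bias
of 1/s at qHTS group sizes (n = 16); the method-of-moments form remains
the default because it is the conventional plate-analysis choice. Dead
wells and dispensing-error wells are excluded before scoring.

**Hit calling.** A compound is a hit when its best concentration reaches
SSMD ≥ 1 and it is not on the exclusion list (autofluorescent or lethal by
inspection; excluded compounds are retained in the output with the reason,
for audit). Effect classes band the maximal SSMD: fairly moderate
[1, 1.28), moderate [1.28, 1.645), semi-strong [1.645, 2), strong [2, 3),
very strong ≥ 3; bands are closed on the left so boundary scores land in
the stronger class. Ties for best concentration resolve to the lowest
concentration (favouring potency).

**Dose-trend labels.** The screen's three categories are reported without
a published numeric rule, so the package defines one: *singular* if
exactly one concentration reaches SSMD ≥ 1; *concentration-dependent* if
Spearman's ρ between log-concentration and SSMD is ≥ 0.7 across all
levels and at least two levels reach SSMD ≥ 1; *discontinuous* otherwise.
The ρ threshold is a module constant. Note that strong protectants whose
response saturates well below the top concentration often label
*discontinuous*: the plateau levels carry no rank information, and noise
among them drags ρ down. This is a property of any rank-based trend rule,
not a defect of the planted pharmacology.

**QC.** Non-transgenic larvae define the background cutoff mean + k·SD
(default k = 3; at least 8 wells required). Two filter policies exist:
`floor` raises sub-cutoff signals to the cutoff (an ablated well cannot
meaningfully read below background) and keeps the `below_cutoff` flag for
audit; `flag_posctrl` marks non-ablated control wells below the cutoff as
dispensing errors — a transgenic larva cannot read at background, so the
well must be empty. The assay-level score is the SSMD of non-ablated vs
ablated controls computed on usable wells (alive, not flagged); verdicts:
pass ≥ 1.645, marginal [1, 1.645), fail < 1. The pass threshold is the
semi-strong boundary, chosen so that an assay scoring 1.67 — the quality
level at which this kind of screen has been run at scale — qualifies.
The pipeline order in `workflow.screen_run` is: cutoff from
non-transgenics → flag empty pos-ctrl wells → QC score → floor → SSMD
scoring.

**Confirmation statistics.** Signals are normalized per run to that run's
control window (ablated = 0%, non-ablated = 100%), then pooled across
repeats per condition: effect = mean, CI = mean ± t₀.₉₇₅,ₙ₋₁·s/√n.
Normalization uses per-run control means because the window drifts
between assays; pooling happens only after normalization. Significance
uses a pooled-variance two-sided Student's t against the ablated controls
by default (`reference="vs_ablated"`, the natural no-protection null;
`vs_nonablated` is available because confirmation tables are sometimes
reported against the non-ablated side), at the Bonferroni-adjusted level
α/m with m supplied by the caller (default: the number of conditions in
the table) and the 3-decimal display value recorded alongside. Larval
survival is compared condition-vs-ablated-controls with a two-sided
Fisher's exact test on alive/dead counts.

**Combination rule.** With single-agent effects E_A, E_B and pair effect
E_AB (normalized %), the default *relative* mode calls a pair additive
when E_AB ≥ 0.90·(E_A+E_B) and synergistic when E_AB ≥ 1.25·(E_A+E_B);
a pair that reaches the synergy threshold necessarily satisfies the
additive one, and the stronger label is reported. The "±10%" margin is
read as relative for consistency with the explicitly relative ≥ 25%
synergy rule; an `absolute_pp` mode (sum − 10 / sum + 25 percentage
points) is provided because the wording admits either reading, and the
mode used is recorded in the CLI run log. Significance tiers: `plus_plus`
when the pair beats both singles (pooled t, positive direction, p below
the adjusted α), `plus` when it beats exactly one, `ns` otherwise.
Lethality is an observation, not a computation: lethal pairs are supplied
as annotations and carry no effect fields.

**Power design.** For a treatment recovering fraction f of the window
W = μ_pos − μ_neg, the treated variance is interpolated,
σ_t² = (1−f)·σ_neg² + f·σ_pos², expressing that a partially rescued
population sits between the control populations. The default analytic
size is n = ⌈(z₁₋α(/2) + z₁₋β)²·(σ_t² + σ_neg²)/(f·W)²⌉, one-sided by
default (protection is directional), floored at 2. The z form understates
the t-test's requirement at small n: at the z-derived n the exact
noncentral-t power is ≈ 0.95 for n ≳ 16 but drops to ~0.90 at n = 4 and
~0.69 at n = 2. `method="t_iterative"` therefore searches for the
smallest n whose exact noncentral-t power reaches 1 − β and is the method
to use when the computed n is small; `power_mc` verifies either by
simulation (vectorised pooled-t over Gaussian draws, binomial SE
reported). Because n is an integer ceiling, realised power generally
overshoots 1 − β; self-consistency is therefore checked as a lower bound
(power ≥ 1 − β − 3·MC SE).

## The synthetic screen generator

Per-well signal for a larva carrying the reporter:

    ablated:      S = A + B · (r + (1 − r) · P(c))
    non-ablated:  S = A + B
    empty / dead: S = A

with P(c) = Emax·c^h/(c^h + EC50^h) for planted protectants and P = 0
otherwise; autofluorescent compounds add `autofluor_gain · c` to every
well; toxic compounds kill with log-logistic probability
1/(1 + (LC50/c)^slope); dispensing errors leave a well empty at the
configured rate. Signals truncate at 0. The normalized effect of a
protectant is then 100·P(c) in expectation, and of an inactive compound
0, which is what makes the generator a usable oracle for the whole
pipeline.

**Defaults and their provenance** (all configurable):

| parameter | default | rationale |
|---|---|---|
| baseline B | lognormal, median 1000 AU, geometric CV 0.53 | reporter expression is multiplicative and strictly positive; the CV was calibrated by simulation so the *measured* control SSMD-QC score at 96 wells/group averages ≈ 1.67, the quality level of the qualified assay (the plug-in score runs a few percent above the population value on skewed data) |
| background A | normal(50, 12²) truncated at 0 | non-transgenic autofluorescence is a small positive floor, ~5% of the transgene signal |
| residual fraction r | 0.13 | the screening prodrug dose ablates ≈ 87% of reporter signal |
| protection | Emax 0.5, EC50 0.25 µM, Hill 2 | a mid-strength protectant that saturates within the primary 4 µM–125 nM series — the benchmark condition for hit-recovery tests |
| toxicity | LC50 2 µM, slope 4 | lethality emerging within the tested range |
| autofluor_gain | 200 AU/µM | compound fluorescence comparable to the signal window at top dose |
| dispensing_error_rate | 0.02 | a few empty wells per plate, the failure mode that motivated padding group sizes to 16 |
| frac_toxic, frac_autofluorescent | 0 | the recovery benchmarks plant protectants only; artifact classes are exercised explicitly in unit tests |

Controls default to 32 ablated + 32 non-ablated + 16 non-transgenic wells
per run for routine screens; benchmark and QC-calibration runs use 96 per
control group (a full plate per condition, as in assay qualification).

**What the generator does not emulate:** spatial plate effects (edge
evaporation, gradients), between-day drift beyond what independent runs
produce, correlated compound behaviour (all planted protectants share one
Hill curve unless configured otherwise), partial toxicity phenotypes, and
instrument saturation. Passing tests therefore demonstrate that the
*analysis* is correct and well-calibrated under the stated noise model,
not that the noise model captures every artifact of real plates.

## Problem sizes used in the checks

Hit-recovery benchmarks use 20 replicate screens of 100 compounds (10%
planted protectants) at the primary design (6 × 16 wells + controls);
confirmation recovery uses 3 repeats × 30 larvae (n = 90 pooled; the
acceptance script averages 10 such experiments for a stable read-out,
single experiments scatter with SD ≈ 3 percentage points); power
verification uses 10⁴ Monte-Carlo replicates per grid cell; combination
fidelity uses 400 wells per group × 20 seeded replicates, with planted
rescue fractions chosen away from the 0.90 decision boundary (Bliss
0.4 + 0.4 → 0.64 vs sum 0.8; capped-linear 0.25 + 0.30 → 0.55) so the
intended class is unambiguous. These sizes make the whole suite run in
well under a minute while keeping Monte-Carlo error far from the
assertion margins.

## Known limitations

- The dose-trend rule is an operationalization; other reasonable rules
  (e.g. isotonic-fit quality) would classify borderline profiles
  differently.
- The published sample size of n = 9 for a 50% window effect cannot be
  recomputed without the original control variances; the power module
  exposes one-/two-sided and z/t variants so users can explore the space,
  and the worked default (σ ≈ 30 on a 100 window, one-sided, α = β =
  0.05, f = 0.5) yields n = 8.
- `fisher_exact_2x2`, `mann_whitney_u`, BH-FDR and the t-tests are backed
  by scipy/statsmodels; the test suite verifies them against independent
  brute-force enumeration on all small instances rather than trusting
  either implementation blindly.
- Exact Mann-Whitney enumeration is only valid without ties; tied data
  fall back to the tie-corrected normal approximation regardless of mode
  `auto`'s size rule.
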