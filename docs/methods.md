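# Methods

## Panel model and data layout

A panel couples a partial-factorial mating design (Dent maternal lines D,
Flint paternal lines F, crosses H ⊆ D × F), a replicate × analyte matrix of
log10 metabolite intensities covering parents and hybrids, and a hybrid
phenotype table (whole-plant biomass, dt ha⁻¹, with a field-trial label).
Profiles arrive pre-quantified and log-transformed; missing intensities are
rejected rather than imputed, and every genotype needs at least two
replicates so the three-group contrasts have residual degrees of freedom.
Cross identifiers are canonicalized as `<dent>×<flint>`. The between-trial
biomass comparison defaults to the pooled-variance two-sample t-test; Welch
is available by flag.

## Redundancy filter

Pearson correlations are computed over genotype-mean profiles with parents
and hybrids pooled — replicate rows would pseudo-replicate the same
genotype. All pairs with r above the threshold (default 0.85) are
enumerated in descending r; in each still-unresolved pair the member with
the larger mean signed correlation to all other analytes is dropped
(signed, not absolute; ties break by dropping the lexicographically later
id). Zero-variance analytes have
undefined correlations and are removed first and logged. The default is a
single pass over the original correlation matrix; recomputing after every
removal is available behind `iterative=True`. The filter is idempotent, and
the retained count is monotone in the threshold.

## Moderated contrasts and mIP encoding

Per cross, the Dent, Flint and hybrid replicates form a one-way three-group
layout per analyte. The residual variance s²ⱼ (df d = n − 3) is shrunk
toward a prior s₀² with prior df d₀ fitted across the cross's analytes by
the classical method-of-moments on log variances: under s² ~ s₀²·F(d, d₀)
the log variance has closed-form mean and variance in digamma/trigamma
terms, inverted by Newton iteration. When the spread of log variances does
not exceed its χ² sampling floor, d₀ = ∞ and s₀² is the arithmetic mean of
the variances (complete shrinkage). Moderated t statistics for hybrid − b
and hybrid − w use s̃²ⱼ = (d₀s₀² + d·s²ⱼ)/(d₀ + d) with d₀ + d degrees of
freedom, capped at the pooled residual df over the analytes; p-values are
two-sided and unadjusted. The implementation reproduces limma's `eBayes`
to ~1e-14 on shared fixtures (an optional test exercises this oracle via
Rscript). The prior is estimated per cross subset by default; a panel-wide
prior is a flag.

Equality in the encoding ("hybrid = parent") means *not significant at α*
(default 0.05, configurable). With significance states s_b, s_w ∈
{−1, 0, +1} for the two contrasts, the label is:

| s_b \ s_w | −1 | 0  | +1 |
|-----------|----|----|----|
| **−1**    | −2 | −1 | 0  |
| **0**     | −1 | 0  | +1 |
| **+1**    | 0  | +1 | +2 |

The six cells with s_w ≥ s_b are the framework's defining conditionals;
the other three are unreachable under equal replication (the hybrid-vs-worse-parent
contrast is always at least as positive as the hybrid-vs-better-parent one)
and are completed antisymmetrically so the mapping is total — equivalently,
label = s_b + s_w.

**Class-balance filter.** An encoded analyte is dropped when any realized
class covers more than 75% of the hybrids (relaxed variant: 90%) or when
any realized class occurs 2–3 times; if the only offence is a single class
realized exactly once, the analyte is kept and that hybrid is excluded for
this analyte only. Absent classes do not offend (a `strict_absent` flag
treats them as offending for sensitivity analysis); several simultaneous
singleton classes are treated as ambiguous and drop the analyte, with the
decision logged. Under this reading both threshold variants (0.75 and 0.9)
give non-trivial, nested retained sets.

## Classifier comparison and ranking

The predictor matrix X_DF holds, per cross, the replicate-mean profiles of
the Dent parent then the Flint parent, each column z-scored over crosses.
Seven families are compared per encoded analyte: PLS-DA (LDA on PLS scores
of the one-hot response; components 1–10), multinomial elastic net (saga
solver; mixing × strength grid), PLS-RF (random forest on PLS scores),
radial SVM and SVM-W, random forest and RF-W (√p-scaled mtry grid, 500
trees by default). The evaluation protocol is fixed — stratified 75/25
splits, inner 3-fold cross-validation repeated 5×, tuning and evaluation by
Cohen's Kappa, five outer repetitions, class weights {10, 5, 1, 5, 10}
entering SVM-W as per-class misclassification costs and RF-W as class
weights — while the tuning grids are package choices (a reduced
`grid="small"` exists for fast runs). RBF widths
come from the median heuristic (1/median squared distance) times
{0.5, 1, 2}. One master seed expands deterministically into
per-(method, analyte, repetition) streams, so runs are bit-reproducible.
Permuted-label runs shuffle each analyte's labels once before the whole
procedure and provide the no-signal Kappa reference. The family minimizing
sd/mean of test Kappa pooled over analytes × repetitions is selected;
families with non-positive mean Kappa have undefined CV and are excluded.

**Variable importance.** The default importance is model-agnostic: per
predictor column, the one-vs-rest AUC per class (symmetrized as
max(AUC, 1−AUC)) averaged over classes — the standard filter importance
for non-linear kernels, and the measure the selected RBF-SVM family
actually admits. A permutation-importance alternative (Kappa drop under
column permutation of the fitted model) is available by flag. Importances
are scaled so each analyte model's best column is 100; the final score is
the median over analyte models, with deterministic tie-breaks, reported on
the 0–100 scale. Rank diagnostics report Kendall's τ between the positions
of each analyte identity within the Dent-only and Flint-only orderings,
plus cumulative Dent/Flint frequency curves along the ranking.

## Hybrid-performance prediction

Thirteen scenarios draw column subsets from the ranking: Top5; five sampled
from the top 10/20/50/100; five from the bottom 100/50/20/10; Bottom5;
Random5; All; and All with biomass permuted once per repetition. Windows
wider than the ranking are dropped on construction. Random draws are
refreshed each repetition from that repetition's seed stream. Per scenario
and repetition: an 80/20 split (stratified for classification), inner
3-fold cross-validation repeated 10× tuning an RBF SVR (regression) or SVM
(classification), and held-out evaluation. R² is the squared Pearson
correlation of predicted vs observed (invariant to affine rescaling of the
biomass units); the residual-based 1 − SSE/SST is reported alongside.
Classification labels hybrids good when biomass ≥ threshold (default: the
mean); class probabilities come from Platt-scaled SVC and feed ROC AUC and
precision–recall curves over a cutoff grid, with precision reported as
absent (not 0) when nothing is predicted good. The threshold sweep
evaluates nine thresholds centred on the mean and spread symmetrically
inside the observed biomass range, flagging thresholds that empty a class
as degenerate. The two trials are pooled for modeling; a per-trial
stratification flag exists because the trial means differ.

## Synthetic panel generator

The generator's defaults emulate a large Dent × Flint breeding panel:
24 × 25 parental lines, ~55% of the factorial realized (≈332 crosses,
≈99% phenotyped), 269 analytes, five replicates, a 45/55 trial split with
a 60 dt ha⁻¹ trial offset on a 560 dt ha⁻¹ baseline, and biomass noise of
30 dt ha⁻¹ around a 45 dt ha⁻¹ causal signal. The replicate count and the
between-line spread (sd 2.0 log units, with a 5-factor low-rank shared
component) are package choices chosen to keep dominance statistically
identifiable at the default α. Parental line profiles get explicit
redundancy: half the non-informative analytes are noisy clones of another
analyte (r ≈ 0.95), and clones inherit their source's labels, as a
twice-detected compound would.

Labels: 30% of analytes are *informative* — their five-class labels are a
thresholded linear score of the five causal maternal analytes' z-levels
(propensities 0.10/0.20/0.40/0.20/0.10), so the labels are learnable from
X_DF and the causal analytes carry the ranking signal. The rest draw labels
iid from an additivity-heavy vector (0.02/0.05/0.86/0.05/0.02) and are
meant to fall to the balance filter. The hybrid's analyte level follows its
label: mid-parent for additivity; the high (low) parent's level but at
least δ = 1.0 from the other parent for dominance; δ beyond the parental
range for overdominance. Biomass is a linear function of the causal
maternal z-levels plus the trial offset and Gaussian noise.

What the generator does *not* emulate: real metabolite identities and
their empirical correlation structure, non-Gaussian replicate noise,
missing values, batch effects, or genotype-by-environment interaction.
Passing tests therefore demonstrate that the pipeline recovers planted
structure under the stated noise model, not that real panels carry that
structure.

Known identifiability limits, visible in the tests: a dominant hybrid sits
exactly at one parent's level, so an α-level fraction of dominance cells
flips to the adjacent class regardless of noise; dominance where the
parents differ by less than δ is geometrically indistinguishable from weak
overdominance; and additivity flips only where the two parents are nearly
indistinguishable. At the default noise (δ = 1.0, replicate sd 0.5, 5–6
replicates) non-additive planted labels are recovered at ≥ 80% per class.

## Problem sizes in the shipped runs

The test suite and `scripts/acceptance.py` run the pipeline on scaled-down
panels (8–20 lines per pool, 20–40 analytes, reduced tuning grids, 100–150
forest trees, 1–2 inner CV repeats) so a complete run takes minutes on one
CPU; the defaults in the API remain the full published protocol. The
acceptance script reports every quantity it measures — it asserts nothing —
and derives all randomness from `--seed`.
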