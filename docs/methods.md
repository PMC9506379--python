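# Methods

This note records the models, conventions and numerical choices behind
`subtypescreen`, in the order the pipeline runs.

## Consensus subtyping

Each cell line carries one call from each of four taxonomies (MDA, Lund,
TCGA, Consensus). Calls are harmonized onto {basal, luminal,
mesenchymal-like, neuronal} via an editable vocabulary table
(`data/harmonization.tsv`). The predominant subtype is the modal
harmonized label when its multiplicity is ≥ 3 of 4. Neuronal is never a
final cell-line assignment: pure cultured lines lack the stromal
infiltration markers that drive the TCGA/Consensus mesenchymal-like
labels, and intrinsically mesenchymal lines are the known source of
spurious neuronal calls. Lines without a 3-of-4 majority (including a
neuronal majority) fall through to the mesenchymal fallback: a
single-sample EMT-signature score, z-normalized across the panel, above 0
designates mesenchymal-like. The relative (z > 0) criterion is scale-free;
the signature gene list (`data/mesenchymal_signature.txt`) is an editable
default, not a fixed constant. Two caveats are inherent: the vocabulary
entries for Lund "UroA-Prog" and "GU-inf" (mapped to luminal) are
editorial choices rather than published equivalences, and 2–2 modal ties
never auto-assign — only the fallback can resolve them.

The nearest-centroid classifier (per-gene z-scores across samples,
signature-mean argmax, lexicographic tie-break) is a deliberately simple
stand-in used to exercise the consensus rule on synthetic data; it is not
a re-implementation of the published classifiers, whose calls are inputs
in real use.

## Enrichment core

The shared statistic is the classic weighted Kolmogorov–Smirnov running
sum over a ranking ordered best-to-worst (non-increasing metric): member
positions add `|m|^p / Σ_hits |m|^p`, non-members subtract `1/(N − n_hit)`,
and ES is the running-sum value of maximal absolute deviation (first
occurrence on exact ties; an exact tie between the positive peak and
negative trough makes the sign genuinely ambiguous, and only the magnitude
is meaningful there). Defaults: weight exponent p = 1; sets with all-zero
hit weights fall back to p = 0 so their score stays defined.

The null is random set-membership permutation (default 1000 draws), not
phenotype permutation: with three cell lines per subtype a phenotype
relabeling has only 10 distinct outcomes, which cannot support a
permutation p, while set permutation is valid at any group size. NES
divides each score by the mean magnitude of same-sign null scores;
empirical p uses the same-sign tail with add-one correction (minimum
1/(n+1)). FDR q follows the GSEA two-fraction convention on pooled
per-set-normalized null NES, clipped to [0, 1] and monotonized
Benjamini–Hochberg-style within each sign so a more extreme NES never
reports a larger q. When a score has no same-sign nulls the result is
flagged and NES falls back to es/ε.

Welch's t (via the Satterthwaite degrees of freedom) backs the drug
ranking significance and contrast signatures. Degenerate contracts: both
groups constant and equal → t = 0, p = 1; zero pooled standard error with
unequal means → infinite t with the smallest representable positive p.

## Drug-set enrichment analysis

For a one-vs-rest contrast, each drug's metric is Δ = mean(contrast
lines) − mean(rest lines); the ranking is **descending** in Δ, so drugs
the subtype resists head the list and drugs it is sensitive to sit at the
bottom. Both response conventions (screen AUC and fraction-viable) encode
"lower = more sensitive", so subtype-sensitive drug sets are *negatively*
enriched, and the sensitivity call is NES < 0 with FDR q < 0.25 (the
conventional exploratory GSEA cut; star annotations use the NEJM p
thresholds 0.033/0.002/0.001). One-vs-rest contrasts (not all pairwise)
match how the screen is read out. Ties in Δ order by drug id. Drugs with
more than 50% missing values in either group are dropped from the
contrast and logged — sparse repurposing matrices would otherwise bias Δ
through silent imputation. Set-size filters default to [3, N/2] and the
permutation count to 1000; these are exposed because upstream tooling
does not pin them.

## Dose–response analytics

AUC is the trapezoid of (capped-at-1.2) response against log10
concentration, normalized by the log-range, hence unit-invariant; it
serves both ladder designs (8-step 4-fold from 10 µM, and 8-step 2-fold
from 40 µM) without special-casing. The 4PL model
`bottom + (top−bottom)/(1 + (c/IC50)^h)` is fitted by bounded least
squares (`scipy.optimize.least_squares`, tolerances 1e-15) with
multi-start initialization — IC50 starting at every tested concentration
and Hill at ±1 — making the fit deterministic and able to capture rising
curves (negative Hill). Bounds: top ∈ [0.5, 1.5], bottom ∈ [−0.1, 0.8],
log10 IC50 within the tested range ± 2. IC50 is absolute (midpoint
response), robust when curves do not cross 50%; fits with IC50 outside
[min conc/100, max conc×100] are flagged extrapolated, and zero-variance
data yields a flat curve flagged non-converged. Pooled-replicate fitting
is the default; per-replicate fitting is a CLI flag. Subtype IC50
comparisons run Welch t on log10(IC50) of converged curves only.

Plate QC is the Z′-factor with sample standard deviations; the dead-cell
gate for imaging viability is vehicle-control mean + 3 sd of the dead-dye
intensity — anchored to controls, hence scale-free — and fraction-viable
normalizes each well's surviving count to the mean vehicle-well count.

## Essentiality and survival

Essential calls use a strict `score < −1` (a line at exactly −1 is not
called); missing scores propagate. Dependency fractions report their
denominators (non-missing lines per subtype). Subtype comparisons use
Mann–Whitney (exact for small untied samples via scipy's auto policy) and
Kruskal–Wallis, with H = 0, p = 1 on fully tied data. Spearman
correlations use average ranks with an exact permutation p for panels of
n ≤ 8 and the t-approximation above.

The biomarker cutoff maximizes Youden's J over every distinct marker
value with the high group inclusive (marker ≥ cutoff) and J ties broken
toward the larger cutoff; the event definition is the overall-survival
event flag with no landmark (both conventions must be fixed for
reproducibility; the flag-based ROC is the default because that is how
Youden dichotomization is usually paired with overall survival). A
maximum J below 0.05 flags the marker uninformative. Kaplan–Meier
estimation and the log-rank test (hypergeometric variance, no continuity
correction) come from `lifelines`; the reported median is the smallest
time with S(t) ≤ 0.5, undefined (NaN) when never reached.

## Regulon activity

Activity of a regulator in a contrast signature (per-gene Welch t,
subtype vs rest) is the weight-normalized mean of mode-adjusted normal
quantile scores of its targets, Φ⁻¹(rank/(N+1)) — a single-tail-per-mode
simplification of two-tailed enrichment approaches: no pleiotropy or
shadow correction, unknown-mode targets dropped, minimum target overlap
10. NES standardizes the raw score against random same-size target draws
reusing the regulon's weights and modes; p is the two-sided empirical
tail with add-one correction. The simplification preserves exactly the
consumed readout — a signed normalized activity and its p — while staying
fully specified here.

## Synthetic data

Generators are pure functions of (config, seed); the global seed is split
into fixed per-stage substreams so changing one stage's size never
perturbs another's draw. What they emulate:

- **Expression**: Normal(5, 1) log2 background with disjoint 50-gene
  subtype signatures shifted by +3 log2 units (an unambiguous marker-gene
  effect; sized so classifier recovery is expected, not guaranteed, at
  n = 10 lines).
- **Screens**: Normal baseline (0.9 for AUC, 0.95 for viability, sd 0.1)
  truncated to the instrument range ([0, 1.2] / [0, 1.1]) — truncation
  rather than resampling keeps determinism and leaves mass at the bounds
  as real AUC data has; drugs partitioned into disjoint sets (default ten
  sets of ten from 100 drugs); planted (set, subtype) pairs shifted down
  0.4 response units in that subtype's lines. Three lines per subtype
  mirrors the focused-screen design.
- **Dependency**: Normal(0, 0.2) CERES background (null essential-call
  probability Φ(−5) ≈ 3e-7) with planted genes shifted −1.2 in one
  subtype, giving per-line essentiality probability ≈ 0.84 — strong but
  not saturated.
- **Survival**: marker ~ Normal(0, 1); exponential event times with
  hazard λ₀·exp(0.7·1{marker>0}), λ₀ fixing a 36-month baseline median
  (typical of MIBC cohorts); censoring times Uniform(0, c_max) with c_max
  calibrated by bisection so the expected censored fraction is 0.3. The
  uniform (administrative-style) censoring matters: it leaves short
  survivors likelier to have an observed event, so the event flag carries
  marker information and the ROC step is meaningful, while remaining
  non-informative within marker groups so the log-rank null stays
  calibrated.

Planted-truth tables accompany every generator. What the generators do
*not* emulate: inter-gene correlation and batch structure in expression,
heavy-tailed and drug-class-correlated response noise, partial set
overlap between drug catalogs, copy-number artifacts in dependency
scores, and covariate-dependent censoring. Passing recovery tests
therefore demonstrates correctness of the machinery under the assumed
statistical structure, not performance on real screens.

## Problem sizes and tests

The test suite and the acceptance script run at sizes chosen to make
every statistical check stable yet quick: 1000-instance oracle sweeps for
the enrichment statistic, exhaustive Youden verification over all
tie-free event patterns with n ≤ 12 (8164 instances), 50 null screens ×
10 sets for type-I control (99% binomial envelope around 0.05), 20
planted screens for DSEA recovery, 100 noisy 4PL fits, 200 cohorts for
log-rank null uniformity and 25 for marker power. Determinism is pinned
by seeds throughout; `scripts/acceptance.py --seed N` reseeds every
stage from the one argument.

## Known limitations

- The harmonization vocabulary covers the published label sets; novel or
  re-spelled labels require editing the TSV (by design, but a silent gap
  if a taxonomy revises its nomenclature).
- The FDR follows the GSEA pooled-null convention, which is known to be
  conservative for small set collections; q-values near the 0.25 call
  threshold should be read qualitatively.
- The 4PL fit reports an absolute IC50; for curves whose bottom plateau
  is poorly determined by the ladder, the IC50 confidence is not
  quantified (no profile likelihood).
- Regulon scoring assumes target modes are known and correct; it cannot
  discover mode from data as two-tailed methods do.
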