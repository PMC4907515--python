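# Methods

## Trial model and scope

The package analyses balanced multi-environment trials with a crossed
genotype × treatment × year structure and replicates nested within
treatment-year, the layout of a two-treatment (restricted irrigation RI /
rainfed RF) drought evaluation repeated over seasons.  Treatments are
normalized so RF is always the stress level and RI the non-stress level.
Units are carried as metadata strings and never converted; plot yields are
in grams per plot throughout the examples.

Missing plot values are allowed in the containers and reduce the `n` of
arithmetic means, but the closed-form ANOVA refuses unbalanced layouts
with a dedicated error instead of silently dropping records: the
expected-mean-squares algebra below assumes balance, and quietly deleting
plots would bias every downstream statistic.

## Variance components and heritability

For the balanced layout the sums of squares for G, T, Y, GT, GY, TY, GTY
and replicates-within-(T,Y) are computed exactly from marginal means; the
partition is exact by construction and is verified in the tests against an
independent sequential-regression oracle run in rational arithmetic.
Method-of-moments estimators follow from the expected mean squares of the
random model:

```
σ²e   = MS_resid
σ²GTY = (MS_GTY − MS_resid) / r
σ²GY  = (MS_GY − MS_GTY) / (r·t)
σ²GT  = (MS_GT − MS_GTY) / (r·y)
σ²G   = (MS_G − MS_GT − MS_GY + MS_GTY) / (r·t·y)
```

Negative estimates are legitimate outcomes of the method-of-moments
approach; they are *reported* as estimated and flagged, but *truncated to
zero* inside the heritability formula so that H_BS stays in [0, 100].
Broad-sense heritability is computed on the entry-mean basis
(σ²G over the variance of an entry mean across r·t·y plots), in percent.

σP, the phenotypic SD entering genetic advance, is not uniquely defined in
common usage; the package defaults to the SD of entry means — the quantity
relevant to selection among entries — with a `sigma_p_basis="plot"` switch
for the plot-level SD.  GA = K·σP·H with K defaulting to 2.06 (top 5% of a
normal distribution).

With a single year or single treatment the interaction contrasts collapse
to the standard two-way / one-way expected mean squares; the estimator
substitutes the appropriate error line automatically.

## Synthetic data generator

`simulate_met` draws every random effect (G, GT, GY, GTY, replicate,
residual) as an independent Gaussian with the requested variance;
treatment and year effects are fixed additive shifts.  This is exactly the
generating model assumed by the estimator, no more: no spatial trend, no
variance heterogeneity between treatments, no non-normality, no missing
plots.  Passing parameter-recovery tests therefore demonstrates internal
consistency of the estimation chain, not robustness to the field
pathologies real trials exhibit.  Simulated yields are clipped at zero
(yields are physically non-negative); at the default parameters the
Gaussian mass below zero is ~6×10⁻⁴, so the clipping has negligible effect
on moments.

Defaults (`mu=550` g/plot, components 3000/4000/4000/2000/16000) place the
generator in the regime of a stress yield trial: entry-mean σP ≈ 97 g/plot
and H_BS ≈ 31% at t = y = r = 2 — the low-heritability setting in which
drought evaluations typically operate.

`simulate_selection_response` runs cycles of phenotypic truncation
selection: each cycle phenotypes the current population on a balanced
trial, keeps the top fraction by entry mean, and shifts the offspring
genetic mean by h² times the realized phenotypic differential (the
breeder's equation applied at the realized differential).  Genetic
variance is regenerated each cycle — there is no drift, inbreeding, or
Bulmer-effect variance erosion.  The RF-collapse pattern of unselected
material versus RF-maintenance of selected material is reproduced
phenomenologically by scaling RF plots with per-population
`stress_yield_ratio` factors (defaults 0.53 and 1.09); this is a
deliberate device to generate the observed contrast, not a physiological
drought model.

## Drought indices

The six indices follow the standard formulas (README).  Decisions worth
recording:

- **Reference means.** The normalized indices need population references
  (Y_s, Y_ns).  The bundled example resolves them from the pooled
  half-sib row, the only convention under which that row's MRP is exactly
  2 and REI exactly 1; the reference entry (or an explicit pair) is a
  required argument.
- **MPI** is the arithmetic mean of the two yields — the printed values in
  the motivating dataset match this reading exactly, resolving the
  ambiguous typesetting of the formula.
- **Rank direction.** TOL is ranked ascending (most negative = rank 1):
  a negative TOL means higher yield under stress.  All other indices rank
  descending.
- **Ties** get average ranks by default (`competition` available); the
  policy is verified against a brute-force pairwise-comparison oracle.
- **GMP caveat.** Published GMP tables in this literature sometimes run
  0.5–1% below √(Yi_s·Yi_ns), consistent with averaging per-replicate
  geometric means rather than applying the formula to entry means.  The
  package implements the formula; with only entry means available the
  per-replicate variant is not computable.

## Comparisons

- **t-tests** on entry (line) means, Welch by default (the safer choice
  under variance heterogeneity between populations; pooled available).
  The experimental unit is the entry mean, not the plot: populations are
  compared at line level.
- **Dunnett many-to-one** wraps the multivariate-t implementation in
  scipy, seeded for reproducibility; integration error on adjusted
  p-values is about 10⁻³.  Tests verify the k=1 reduction to the
  unadjusted p, dominance over Bonferroni, monotonicity in |t|, and
  familywise error calibration at α = 0.05.
- **Adjusted means** are least-squares entry means from an additive OLS
  fit (entry + treatment + year + rep), predictions averaged over the
  observed nuisance-factor grid.  Replicate enters as a crossed factor in
  this adjustment; on balanced data the result equals the arithmetic entry
  means either way.
- **Trait correlations** are Pearson correlations on adjusted entry means
  with two-sided t-based p-values and a 5% significance flag.

## Progeny BLUPs (EM-REML)

The yield model has six independent random terms — progeny, treatment,
year, rep-within-(treatment, year), progeny×treatment, progeny×year — and
a fixed intercept only.  Variance components are estimated by EM-REML on
Henderson's mixed-model equations.  EM was chosen over average-information
updates because every accepted iterate keeps components non-negative and
the restricted likelihood non-decreasing (both are asserted in tests),
which makes failures diagnosable; the cost is slow convergence near
boundaries.  EM approaches a zero component only sublinearly, so when the
likelihood plateaus (improvement < 100·tol between checks) any component
below 10⁻³ of the total variance is tried at exactly zero and pinned there
if the restricted likelihood does not drop by more than `tol` — the
analogue of a singular fit in other mixed-model software.  Convergence
tolerance is 10⁻⁶ on the restricted log-likelihood change (checked every
10 iterations); hitting the iteration cap raises an error carrying the
last iterate.  The implementation is validated against an independent
REML fit of the same model (lme4) on a frozen fixture: components agree to
~5×10⁻⁴, BLUPs to ~2×10⁻⁴.

Progeny BLUPs are shrinkage predictions; on balanced data shrinkage is
uniform, so the BLUP ranking equals the raw-mean ranking, and under an
empty generating signal the BLUPs contract toward zero inside the raw
deviations.  The fit scales comfortably to tens of progenies; with many
hundreds of progenies the per-iteration dense solve becomes the
bottleneck and a sparse implementation would be preferable.

## Pipeline

`run_pipeline` executes load/simulate → gain tables (population and
per-family) → drought indices → t/Dunnett tests → correlations on
adjusted means → BLUPs, writing each table as CSV plus a provenance
record (config hash, seed, package version, resolved defaults).  Stage
failures for one trait are recorded and do not abort other traits.
Re-running with the same config and seed reproduces every table
byte-identically; all randomness (simulation, Dunnett integration) flows
from the config seed.

## Problem sizes used in the test suite

Monte-Carlo checks run at sizes chosen to keep the statistical assertions
sharp while the suite stays quick: 200 replicate trials of g=100 entries
for variance-component recovery, 500 one-cycle selection simulations of
200 entries against the truncated-normal oracle, 1000 null Welch tests,
2000 Dunnett batteries for familywise-error calibration, and 30 REML
recovery fits on 15-progeny layouts.  Tolerances follow the Monte-Carlo
error at those sizes (3–3.5 σ bands).

## Known limitations

- The closed-form ANOVA path requires complete balance; for unbalanced
  data only the REML/BLUP machinery and adjusted means apply.
- The EMS estimator can return negative components; they are flagged, and
  truncation inside H_BS introduces the usual small upward bias near zero
  genetic variance.
- The generator's independence and normality assumptions make it a tool
  for verifying the estimation chain, not for stress-testing robustness.
- Alpha-lattice incomplete-block adjustment within replicates is not
  modelled; `block` is carried as metadata only.
- No multi-location stability analysis, narrow-sense heritability, or
  marker/pedigree information.
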