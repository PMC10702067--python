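# Methods

## Design and data model

`crosslay` analyses a reciprocal crossbreeding design between two layer
lines, W and Y. Four genetic groups are on test — WW, YY and the
reciprocal crosses WY and YW (sire line written first) — produced so that
each line's sires serve both its purebred and its crossbred matings. Test
hens sit in individual cages whose position is summarised by a 24-level
rack factor. Observed data are (a) a pedigree, (b) daily laying records
with optional oviposition clock times on a 0.5-h grid, and (c) per-egg
measurements at scheduled ages; analysis traits are derived from (b) and
(c).

## Trait derivation

* **Age at first egg (AFE)**: day-of-age of the first lay; hens with no
  lay are flagged non-layers.
* **Cumulative egg number (ENx)**: eggs laid on days of age <= 7x. The
  boundary day is included; the source material does not define the
  boundary, so "till week x" = day <= 7x is a package convention.
* **Clutch statistics (NCx, ACLx, APLx)**: a clutch is a maximal run of
  consecutive laying days. NC = number of runs; ACL = eggs in window /
  NC (so NC * ACL equals the egg count identically); pauses = NC - 1;
  APL = non-laying days strictly between the first and last clutch /
  pauses, undefined for a single clutch.
* **Oviposition period (OP)**: mean of (24 h + clock difference) over
  pairs of lays on consecutive calendar days between the start of week 31
  and the end of week 33 of age. Pairs straddling a pause day are
  excluded: a cohort mean near 25 h is only consistent with within-clutch
  lags, and cross-pause intervals would inflate it. Whether the original
  procedure averaged across clutch boundaries is not documented; the
  consecutive-day rule is our recorded choice.
* **First egg weight (FEWt)**: mean of the chronologically first three
  weighed eggs; fewer than three gives a missing value.
* **Egg shape index / shell ratio / yolk ratio**: 100 * width / length,
  100 * shell weight / egg weight, 100 * yolk weight / egg weight. The
  0-100 scale matches the magnitudes the descriptive tables print
  (shape index ~76, yolk ratio ~30).

## Quality control

Hens that laid no egg at all are removed from the egg-production traits
only. Then a single-pass 3-SD filter runs per trait x age x genetic
group: records deviating more than three standard deviations from their
cell mean (moments computed on the current records) are dropped. One pass,
not iterated: iterating would remove more records than the rule
describes. Cells with zero SD remove nothing. Non-layers are removed
before the filter, matching the order in which the rules are stated.
Descriptives (mean, SD, CV% = 100 SD / mean) pool all animals.

## Animal models

Fixed effects are always overall mean + genetic group (4 levels) + rack
(24 levels), encoded with a reference-level constraint (a sum-to-zero
option exists; predicted group means are estimable and constraint
invariant, which the test-suite asserts). Random terms:

* additive animal effect `a ~ N(0, A sigma_a^2)` with A the numerator
  relationship matrix from the pedigree (unknown parents are unrelated,
  non-inbred founders);
* for repeated-record traits, a permanent environmental effect
  `pe ~ N(0, I sigma_pe^2)`; if requested without repeated records it is
  unidentifiable and fixed to 0 with a warning;
* residual with one variance per genetic group (the default) or a single
  variance; the reported sigma_e^2 is the arithmetic mean of the
  per-group variances.

The bivariate model stacks two traits with 2 x 2 covariance blocks for
a (direct product with A), optionally pe, and the residual. Residual
covariance applies to record pairs: the k-th record of one trait on an
animal is paired with the k-th record of the other trait on the same
animal; unpaired records contribute only their trait's variance. The
phenotypic covariance block is the sum of the component blocks.

The group-specific multivariate model treats one trait as three
pseudo-traits (WW, YY, crossbreds) with all between-group covariances
fixed at zero — each individual carries phenotypes of exactly one group,
and zero genetic covariances prevent one group's variance from borrowing
information from another. Pooled components are weighted averages with
animal-proportion weights (0.22 / 0.25 / 0.53 for the reference design;
recomputed from the data by default).

## REML estimation

Variance parameters are estimated by average-information REML:

* **Start**: the OLS residual variance split equally over the declared
  components.
* **Iterations**: two EM warm-up steps, then AI updates
  `theta += AI^-1 score` with step halving (up to 6 halvings) whenever an
  update would decrease the restricted likelihood, and a full EM step as
  fallback. EM steps are monotone in the likelihood (asserted in tests).
* **Constraints**: variances are floored at 1e-8 of the phenotypic
  variance; a variance sitting at the floor is held there only while its
  gradient points further down. Covariance blocks are kept positive
  definite by clipping the correlation into (-1, 1) (projection to the
  nearest valid block).
* **Convergence**: |change in restricted logL| < 1e-6 and maximum
  relative parameter change < 1e-5, at most 200 iterations.
  Non-convergence is reported as a DNC flag on the results object and in
  the pipeline tables, never silently dropped.
* **Uncertainty**: asymptotic covariance of the variance parameters from
  the inverse AI matrix at the solution; heritability, repeatability and
  correlation standard errors by the delta method. Fixed-effect
  covariance comes from the corresponding block of the inverse mixed
  model equations.
* **Degenerate input**: a response with (near) zero residual variance
  after OLS (noise-free simulations) short-circuits to the GLS solution
  with all variances at the floor — predicted group means are then exact
  and the closed-loop checks are exact identities.

Numerically, all quantities flow through the mixed model equations with a
dense Cholesky factorisation. Scalar identity-structure terms whose
levels do not share records (permanent environment) contribute a diagonal
block, and those equations are absorbed exactly through the Schur
complement before factorising; the test-suite verifies absorbed and
unabsorbed paths agree to 1e-11. Traces needed for scores and EM come
from a LAPACK `dpotri` inverse of the reduced system. Dense relationship
matrices are only materialised up to 4000 animals; A-inverse uses
Henderson's sparse rules with inbreeding (Meuwissen-Luo coefficients).

Wald contrasts on predicted group means use F = estimate^2 / var with 1
numerator df and n - rank(X) denominator df. The denominator df is an
approximation (the df method of the commercial package the field
typically uses is not public); contrast p-values should be read
accordingly. For average pause length, whose distribution is strongly
skewed, contrast p-values are computed on Box-Cox transformed data
(profile-likelihood lambda on a [-2, 2] grid, step 0.01) while the
reported means stay on the original scale.

## Heterosis analysis

From predicted group means: H%(cross) = 100 (cross - parental mean) /
parental mean; RC% = 100 (WY - YW) / parental mean. Benjamini-Hochberg
FDR runs separately per contrast family — one family per crossbred group
and one for the reciprocal contrasts (70 traits each in the full design;
the reciprocal family as a third 70-test family is a package choice).
Significance tiers are rendered as `*` (FDR <= 0.05) and `**`
(FDR <= 0.01). The Dickerson-style reparameterization (line effects,
average heterosis = crossbred mean - parental mean, reciprocal effect =
WY - YW) is an exact linear bijection with the group means and is checked
to 1e-12. The heterosis-heritability regression uses signed heterosis by
default (an absolute-value option exists, the choice being genuinely
ambiguous) and can be run per trait family as well as pooled, since
correlated egg-weight ages could otherwise dominate the pooled estimate.

## Synthetic data generator

The generator emulates the study design so that every stage is testable
without access to the original records:

* **Pedigree**: 30 sires + 300 dams per line in the parental generation,
  preceded by configurable discrete base generations (default 2 in the
  full profile; validation runs use 1) of random mating within line;
  offspring counts per group default to 315/271/315/359 (YY/WW/WY/YW).
  Sires are reused across a line's pure and cross matings; dams are not.
* **Breeding values**: founders N(0, sigma_a^2); descendants get the
  parent average plus a Mendelian-sampling deviation with variance
  sigma_a^2 (0.5 - 0.25 (F_s + F_d)), so the joint covariance is
  A sigma_a^2 (verified against full-sib covariance in tests).
* **Phenotypes**: group mean + rack effect + breeding value + permanent
  environmental value + group-specific residual. Heterosis enters as an
  additive shift on the crossbred expectation and the reciprocal
  difference as a +/- half split between WY and YW, so programmed H% and
  RC% are analytically known — no locus-level dominance is simulated.
* **Laying process**: a first-order two-state (lay/pause) daily Markov
  chain per hen, started at a normally distributed age at first egg, with
  transition probabilities declining linearly with age. Defaults
  (p_lay->lay 0.88 -> 0.70, p_pause->lay 0.78 -> 0.24 across the span,
  mean AFE 168 d, 2.5% non-layers) were calibrated once so the cohort
  produces ~5.8 eggs/week over weeks 24-43 with declining output
  afterwards, matching the descriptive statistics of the reference
  cohort. Oviposition clock times start near 08:00 at the head of a
  clutch and drift later by (lag - 24) h per within-clutch day on the
  0.5-h grid inside 07:00-19:00; the drift model is a stand-in, as no
  distributional detail beyond the recording grid is documented.
* **Egg measurements** are generated by inverting the derived-trait
  definitions from latent trait values (the three first eggs all weigh
  the latent FEWt, width = ESI * length / 100, ...), so derivation
  recovers the latent values exactly and closed-loop checks are exact.
* **Streams** are split per module and per hen via seed-sequence
  spawning: changing one trait's parameters does not perturb the laying
  histories (asserted in tests).

What the generator does **not** emulate: genetic variation in the laying
process itself (laying-derived traits carry no additive signal, so their
fitted heritabilities are near zero on synthetic data — the
heritability-recovery checks use directly simulated phenotypes instead),
dominance at the locus level, sex-linked or mitochondrial inheritance,
mortality, and realistic measurement error in egg dimensions.
Consequently a passing test-suite demonstrates the correctness of the
estimators and the pipeline plumbing under the stated model, not the
biological fidelity of any particular simulated trait.

## Validation problem sizes

The end-to-end checks (test-suite and `scripts/acceptance.py`) use: a
10^6-replicate gene-dropping oracle on pedigrees of up to 16 animals; a
100-sire x 20-offspring balanced half-sib design for the ANOVA
equivalence; 1200 phenotyped hens on the four-group design (one base
generation) for heritability recovery with 20 replicates per archetype;
and 1000 hens in 250 full-sib families nested in 50 sires for the
bivariate correlation recovery. The closed-loop check runs the full
pipeline on an 80-hen noise-free design. Recovery is judged by the mean
estimate over replicates falling within two standard errors of that mean
from the simulated truth. The gene-dropping comparison is entrywise on
the Monte-Carlo standard-error scale with a Sidak-corrected bound on the
maximum |z| (the family-wise equivalent of a single 3-SE comparison),
since the maximum over a hundred-odd entries would exceed a naive 3-SE
bound for a correct implementation on a sizeable fraction of seeds.

## Known limitations

* Bivariate fits assume record pairing by occurrence order within
  animal; designs where the two traits' repeats are not aligned need the
  residual covariance dropped. The EM fallback for a partially paired
  residual block is approximate (the AI step is exact); in practice the
  AI step carries the optimisation.
* The denominator df approximation above.
* Correlation estimates at a boundary (|r| -> 1, e.g. a trait paired
  with itself) are capped at 1 - 1e-6 and typically flagged DNC because
  the boundary prevents the parameter-change criterion from being met;
  the estimates themselves are usable.
* Pedigrees beyond 4000 animals would need an out-of-core A matrix and a
  sparse factorisation of the mixed model equations; the target designs
  are an order of magnitude smaller.
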