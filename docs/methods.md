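# Methods

## Model overview

The package simulates repeated runs of a clinical trial of a fictitious
triglyceride-lowering drug whose effect is pharmaco-epigenetic: each of five
"major" causal SNPs influences a subject's treatment-response slope only to
the extent that a nearby gating CpG site is unmethylated.  One *replicate* is
an independent re-draw of all post-treatment data — visit-4 methylation and
visit-3/4 triglycerides — for the same fixed cohort baseline (genotypes,
visit-1/2 phenotypes, visit-2 methylation never change across replicates).

The simulation proceeds in four stages:

1. **Observed baseline.**  From raw TG (mg/dL) at visits 1–4 and blood-draw
   dates, derive per subject *j*: pre- and post-treatment mean log-TG
   (`O_preRx`, `O_postRx`, natural log), their difference `O_delta`, days on
   treatment `O_daysRx` = mean(v3, v4 dates) − v2 date, the observed slope
   `O_slope = O_delta / O_daysRx`, and the cohort z-score `O_preZ` of
   `O_preRx`.  Cohort moments of `O_preRx` and `O_slope` are reused later for
   standardization and rescaling.

2. **Methylation.**  Simulated visit-4 beta at site *i* is
   `clip(anchor + sd_i · Z, 0, 1)` with one independent N(0,1) draw per
   (subject, site, replicate).  Causal sites anchor on the subject's visit-2
   value — the treatment response is modelled as a fresh excursion from the
   pre-treatment state, uncoupled from the real post-treatment trajectory.
   Non-causal sites anchor on the real visit-4 value when the subject has a
   visit-4 array, else on visit 2.  `sd_i` is 0.4 for the five causal and
   five red-herring sites and 0.03 for every other site.  The mean excursion
   is zero: on average treatment does not move methylation, it only disperses
   it across subjects.

3. **Slope synthesis.**  The standardized slope combines the
   methylation-attenuated major effects `(1 − meth) · √hg² · SSNP`, the
   un-gated polygenic background `√hg² · SSNP` and a residual
   `zenv · √(1 − Σ hg²)`, then is blended with the baseline z-score
   (`corrz = c · preZ + √(1 − c²) · slope`, c = −0.41881) and mapped
   affinely onto the observed slope scale.

4. **Triglyceride emission.**  The projected post-treatment level
   `sim_postRx = sim_slope · O_daysRx + O_preRx` is exponentiated into
   visit-3/4 TG values that keep each subject's real within-pair deviation:
   `sim_TG3 = exp[sim_postRx + (ln TG3 − O_postRx)]` and likewise for TG4.
   Hence `mean(ln simTG3, ln simTG4) = sim_postRx` identically, and the slope
   is exactly reconstructible from the emitted files — the basis of the
   round-trip integrity check.

## Parameters that matter

| parameter | default | units / meaning |
|---|---|---|
| major hg² | 0.125, 0.100, 0.075, 0.050, 0.025 | slope-variance share of each major SNP when unmethylated |
| background hg² | 0.001 × 100 SNPs | polygenic background, not CpG-gated |
| residual scale | √(1 − Σhg²) = √0.525 | SD of the unexplained slope component |
| sd_i (causal, red-herring) | 0.4 | per-subject methylation response SD (beta units) |
| sd_i (background sites) | 0.03 | measurement-error-level methylation noise |
| corr_baseline | −0.41881 | slope vs baseline log-TG correlation to induce |
| n_replicates | 200 | replicates per run |

The hg²-to-SNP pairing follows the published per-marker table
(rs9661059 → 0.125, rs7360046 → 0.075, rs1012116 → 0.100,
rs10828412 → 0.025, rs4399565 → 0.050).  Effects are applied with positive
sign to the coded-allele dosage; every recoverable quantity (variance
explained) is sign-invariant, so the choice is conventional.

Methylation truncation is **censoring**: out-of-range values are clamped to 0
or 1, not redrawn.  With an interior anchor (≈0.49) and noise SD 0.4 this
piles ~10% of mass on each boundary and contracts the visit-4 SD from the
pre-clip √(0.0589² + 0.4²) ≈ 0.404 down to ≈ 0.327 — matching the published
visit-4 moments, which is how the censoring reading is confirmed.  The
truncated values are what enter the slope equation.

Reproducibility: replicate *k* draws its methylation noise from a stream
seeded by (base_seed, k, 1) and its slope residual from (base_seed, k, 2)
(numpy `default_rng` seed sequences), subject-major/site-minor draw order.
Replicates can therefore be generated in any order or in parallel,
bit-identically, and methylation and phenotype noise can be replayed
independently.

## Synthetic cohort

The real trial inputs are access-restricted, so `cohort.gen_cohort` builds a
statistical stand-in: 717 unrelated subjects; dosages ~ Binomial(2, p) with
the published per-SNP coded-allele frequencies (major-SNP frequencies are not
published; default 0.3, a common-variant regime); causal-CpG visit-2 betas
from clipped Normals with the published means/SDs; red-herring and background
betas ~ Beta(2, 2); log-normal TG with baseline ln(120) mg/dL (SD 0.5), a
mean treatment decline of −0.25 log-units (SD 0.15) and within-pair jitter
SD 0.05; visit pairs one day apart with treatment durations uniform within
14–28 days; and whole-array visit-4 methylation missingness for 50% of
subjects (the real fraction is unpublished; 0.5 exercises both anchoring
branches).  The TG scale/decline parameters were chosen once for realism; no
validation target depends on them, because the simulator standardizes and
rescales by the cohort's own observed moments.

What the stand-in deliberately lacks: pedigree/family correlation (subjects
are founders), linkage disequilibrium between SNPs, array-wide probe
chemistry and batch effects, and the genome-wide site/marker counts (the
panel is restricted to the named sites plus a configurable number of generic
background CpGs).  Passing tests therefore demonstrate correctness of the
simulator's equations and distributions, not realism of family structure or
LD — power studies on real-data features are out of scope.

## Validation estimators and their uncertainty

- **Locus variance explained**: per replicate, the sample correlation between
  the standardized slope and the standardized dosage; correlations are
  averaged across replicates *then* squared.  Squaring first would add an
  O(1/n) chi-square bias (~1/717 ≈ 0.0014) that would swamp the background
  value 0.001.
- **Intervention flags**: "force methylation to 0/1" replaces the causal
  methylation values entering the slope equation only — an intervention on
  the model, not an edit of the simulated methylation output.  With
  methylation forced to 0 the slope model is an ordinary linear model and
  each estimate targets its configured hg²; forced to 1, zero.
- **Standard errors**: the cohort is fixed across replicates, so the spread
  of per-replicate correlations measures only redrawn noise.  A fixed
  finite-cohort deviation (sample correlations between SNP columns are
  ~N(0, 1/n) and frozen) would fail any replicate-spread SE check as R grows.
  Reported SEs therefore combine both terms,
  `se_ρ² = var_rep/R + (1 − ρ̂²)²/(n − 1)`, propagated through the square as
  `Var(ρ̂²) = 4ρ̂²·se_ρ² + 2·se_ρ⁴` (the second-order term keeps the SE
  positive at ρ̂ ≈ 0).  Pass thresholds are 3 combined SEs.
- **Methylation moments**: pooled visit-4 mean/SD per site are compared to
  closed-form clipped-normal moments computed from the realized anchors
  (standard-normal partial moments; cross-checked against numeric quadrature
  in the test suite).
- **Round trip**: max over (j, k) of the difference between the slope
  reconstructed from emitted TG files and the simulated slope; tolerance
  1e−10 (observed ~1e−16).

## Numerical and design choices

- Natural logarithms throughout (the TG back-transform uses `exp`).
- Sample SDs use the n−1 denominator everywhere, so standardization and the
  slope rescaling cancel exactly; z-scored columns have sample SD exactly 1.
- Subjects with missing post-treatment TG or draw dates get missing
  `O_postRx`/`O_slope`; cohort slope moments use complete cases; such
  subjects still receive simulated methylation but no simulated TG.  The
  simulator never imputes.
- Dates are accepted as integer day-numbers or ISO calendar dates;
  differences are computed in days with fractional means allowed.
- Monomorphic SNP columns are a hard error at standardization (and the
  synthetic generator redraws any column that comes out constant, which
  matters for coded-allele frequencies near 1).
- Panel restriction: only sites named in the model spec plus the columns
  present in the input panel are simulated; unnamed columns are treated as
  background sites (sd 0.03), which is how an array-scale panel would behave.
- When causal methylation is *not* forced to zero, Var(slope) < 1 (the
  attenuation shrinks the genetic part), so the realized magnitude of
  corr(corrz, preZ) slightly exceeds 0.41881.  The published design does not
  re-standardize the slope and neither does this implementation; correlation
  checks are run under the forced-zero intervention where Var(slope) = 1.
- Visit-4 moment estimates are available per single replicate (matching how
  the published per-site table reads) and pooled across replicates; the
  validation report uses the pooled estimator for tighter Monte-Carlo error.

## Problem sizes

Default validation and acceptance runs use the full design — 717 subjects,
200 replicates, 105 SNPs, 20 CpG sites — which completes in seconds; the
generic test suite uses an 80-subject cohort with 20–80 replicates for unit
and property checks.

## Known limitations

- No LD or family structure in synthetic genotypes; heritability recovery at
  n = 717 carries an irreducible finite-cohort uncertainty of roughly
  ±2·√(hg²)·0.037 per locus, visible in the recovery tables.
- The methylation model is Gaussian-with-censoring per site; it does not
  model the bimodal beta-value mixtures of real arrays (irrelevant to the
  slope model, which only consumes the causal sites' values linearly).
- Red-herring sites mimic causal noise (SD 0.4) but are given no causal role;
  analyses that condition on the red herrings should find nothing.
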