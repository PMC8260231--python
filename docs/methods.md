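# Methods

This note documents the statistical model behind each stage of the pipeline,
the synthetic cohort the test suite runs it on, and the design choices made
where more than one reasonable implementation exists.

## Data model

Methylation is carried as **beta values** — the proportion of methylated
molecules at a CpG, in [0, 1] — in a probes × samples matrix joined to a
sample sheet (id, age in years, sex, castration status, tissue, species,
optional juvenile mass in kg) and, optionally, a probe annotation. All
genomic coordinates are 0-based half-open (BED convention) and probe records
are 2-bp CpG intervals; a probe overlaps a peak when the intervals intersect
by at least 1 bp, so a probe at [150, 152) does *not* overlap a peak ending
at 150. Missing betas are NaN and are excluded pairwise per probe in every
statistic; probes used by a fitted clock must be complete. Readers use
round-trip float parsing and writers emit shortest round-trip decimal
representations, so a load → write → load cycle is lossless.

## Age screening

For each probe the Pearson (or Spearman) correlation r between beta and age
is converted to a Student statistic

    t = r · sqrt((n − 2) / (1 − r²)),   df = n − 2,

with a two-sided p. The Spearman branch applies the same t approximation to
the rank correlation. Zero-variance probes are flagged undefined rather than
dropped, so output rows always align with the input probe set. P-values are
uncorrected by default (screening convention); a Benjamini–Hochberg column
is available behind `bh_adjust=True`. Top-k export ranks by r with
lexicographic probe-id tie-breaks for determinism.

## Clock construction

The clock is an elastic-net linear model of age on beta values
(scikit-learn `ElasticNetCV`): mixing parameter 0.5, a 100-value penalty
path, and 10-fold inner cross-validation minimizing squared error — the
conventions of the penalized-regression clock literature; all three are
exposed on `ClockConfig`. Predictors are standardized internally so the
penalty acts on comparable scales; coefficients are mapped back to raw beta
units before being stored, and zero coefficients are dropped. Training
samples are put into a canonical (sorted-id) order before fitting so the
inner-CV folds, and hence the fit, do not depend on input row order.

Chronological age is fitted untransformed for single-species clocks. In
**relative-age** mode the response is age divided by the species' maximum
recorded lifespan (defaults: sheep 22.8 y, human 122.5 y, from the anAge
database), which places species with very different lifespans on a common
[0, 1] scale; predictions are multiplied back by the lifespan only when
reported in years. No log-linear age warp is applied; `age_transform` is the
hook if one is ever needed.

**Evaluation** is leave-one-out cross-validation: each sample is predicted
by a model retrained from scratch — including penalty reselection — on the
other n − 1 samples, and accuracy is computed on the pooled predictions,
never averaged over folds. Reported metrics are the Pearson correlation and
the **median** absolute error (MAE), in years under the identity transform
and in lifespan fractions under the relative transform.

**Epigenetic age acceleration** is the residual from the OLS regression of
DNAm age on chronological age over the whole evaluated cohort; it is
uncorrelated with age by construction (asserted to 1e-10). Group contrasts
(castrated vs intact males) use a two-sided Mann–Whitney U test restricted
to sexually mature animals (> 18 months by default, configurable): exact
null distribution when both groups have n ≤ 20 with no ties, otherwise the
normal approximation with tie and continuity corrections.

## Androgen-sensitive DMPs

Per group (intact vs castrated males) each probe gets an OLS slope b of beta
on age with standard error s; the interaction statistic is

    t = (b_a − b_b) / sqrt(s_a² + s_b²)

with Welch–Satterthwaite degrees of freedom on the two slope variances —
chosen over a pooled-df t because the study groups are unequal in size and
age range; a normal-approximation option is a one-line config change
(df = ∞ is well approximated at these df). P-values are uncorrected, as in
the screening stage. Ranking is by ascending p with |t|-descending and then
lexicographic tie-breaks.

The mass analysis averages beta over consecutive **non-overlapping** windows
of 100 probes in rank order (blocked rather than sliding, so window tests
are independent), correlates each window mean with juvenile male body mass
within castrate and intact groups, and compares the two correlations with a
Fisher z test. Chromosomal distribution of hits uses a goodness-of-fit
chi-square against expectations proportional to the universe's
per-chromosome probe counts. The tissue-dimorphism expression test is a
pooled-variance two-sample t-test; with zero variance in both classes it
degenerates to p = 1 for equal means (no evidence) and p = 0 otherwise.

## TF-binding enrichment

For the k top-ranked probes, the observed per-factor quantity is the
percentage overlapped by ≥ 1 peak. The null draws k probes uniformly
**without replacement** from the full mapped universe (including the top
set), 1000 times by default, and the expectation is the replicate mean (the
median is also emitted; the two are reported side by side because either
convention is defensible). The empirical one-sided p uses the add-one rule,
p = (1 + #{replicate ≥ observed}) / (n_boot + 1), so p never reaches 0 and
the floor at 1000 replicates is 1/1001 (reported as p < 0.001). Factors are
flagged when fold > 2 (or < 0.5) **and** |observed − expected| > 1
percentage point, both strict. The batch scan repeats the analysis over
consecutive rank-order batches (default 50) with per-batch seed offsets, so
the first batch reproduces a direct `enrich` call with the same seed.

## Synthetic cohort generator

The generator emulates the study's data structure: ~430 samples from two
tissues (ear : blood ≈ 262 : 168), ages uniform on 0–9.1 years with an
optional juvenile excess, and three groups (female / intact male / castrated
male, default 0.5 / 0.25 / 0.25). Probe p in sample s is

    beta = logistic(μ_p + β_p·age + δ_p·age·[intact male] + ε),
    ε ~ Normal(0, noise_sd),

with μ_p ~ Normal(0, 0.8). Noise lives on the logit scale and is mapped
through the logistic function, the standard logit-normal methylation noise
model, so betas are strictly inside (0, 1) with no clamping artifacts.
Clock probes split evenly between β = +0.1 and −0.1 logit/yr; asDMP probes
carry δ = −0.15 logit/yr in intact males only (all other samples have
δ = 0). The peak table has one AR-like factor covering asDMP probes with
probability 0.165 and all probes with background probability 0.0167 —
a planted ~9.9-fold observed/expected ratio — plus nine background factors
at the background rate, so observed/expected scans run over a realistic
panel. Juvenile (< 1 y) male mass is Normal(30, 3²) kg for castrates and
5 kg heavier for intact males, with an |r| = 0.5 coupling to mean asDMP
methylation that is negative in intact males and positive in castrates
(`mass_meth_r`; set to 0 for independent mass). A dual-species variant
shares probe baselines between two "species" and scales slopes per unit of
relative age, giving a conserved cross-species trajectory for relative-age
clock tests.

The generator does **not** simulate probe-level genomic linkage, batch or
chip effects, cell-composition heterogeneity, or nonlinear (e.g.
early-life logarithmic) age trajectories. Passing tests therefore show the
estimators are correct and well calibrated under a linear-in-logit
methylome; they do not certify accuracy on real arrays, where those
complications and probe-quality artifacts matter.

## Evaluation configuration and problem sizes

End-to-end accuracy is measured on a 150-sample, 400-probe cohort (50 clock
probes, 40 asDMPs, noise 0.3 logit) — `ovisclock.simulate.evaluation_config`
— small enough that full LOOCV with per-fold penalty reselection completes
in about a minute while leaving the clock's behaviour qualitatively
unchanged. Screen calibration uses 2000 null probes; asDMP power uses a
300-sample, 1000-probe cohort; enrichment uses a 5050-probe universe with
1000 bootstrap replicates. On these cohorts the LOOCV clock reaches
cor ≈ 0.98 with MAE ≈ 0.3 y, asDMP power ≈ 0.97 at p < 1e-4, and the
planted 10× enrichment is recovered at the 1/1001 empirical-p floor
(exact values are recomputed by `scripts/acceptance.py`).

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1] after the closed-form computation to
  absorb round-off; |r| = 1 maps to p = 0.
- Constant-predictor detection uses an exact max-minus-min test, immune to
  floating-point summation noise in a variance.
- Identical noise-free groups in the slope test produce a 0/0 statistic;
  this is defined as t = 0, p = 1 (no difference).
- Zero expected with nonzero observed enrichment reports fold = +inf;
  0/0 reports NaN. Neither aborts a scan.
- Sample sheets with castrated females, negative ages, duplicate ids, or
  betas outside [0, 1] are rejected at load time with the offending records
  named.

## Known limitations

- The elastic net's `mixing = 0` (pure ridge) endpoint is approximated with
  a tiny l1 fraction because the coordinate-descent solver requires an L1
  component; mixing values in (0, 1] are exact.
- LOOCV retrains n models and is O(n²) in samples at fixed probes; it is
  intended for cohort sizes in the hundreds, not thousands.
- The slope-interaction test assumes within-group residuals independent
  across samples; family or flock structure would need a mixed model, which
  is out of scope.
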