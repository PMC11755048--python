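# Methods

This note documents the generative models, estimators and numerical choices
behind `niptsim`, what the synthetic data do and do not emulate, and the
problem sizes the test suite and reproduction script use.

## Read-count model

A sample's per-chromosome unique-read counts are one multinomial draw of the
read budget *N* (default 1 500 000) from a weight vector `w`:

* Baseline weights are GRCh38 chromosome-length shares renormalized over
  chr1–22 + chrX (the maternal genome carries no Y). Mappability and GC
  weighting are deliberately omitted; any module accepting
  `chromosome_lengths` can be given an alternative weight vector, and the
  caller exposes no correction by default because the assay modelled here
  applies none.
* The fetus contributes a fraction `ff` of cfDNA. A trisomic chromosome's
  weight is multiplied by `(1 + ff/2)`: the fetus carries three copies
  instead of two, so the fetal contribution to that chromosome rises by half.
* A male fetus contributes chrY weight `p_Y · ff` (`p_Y` = chrY length share
  of the whole genome) on top of a female background (default 5 × 10⁻⁴ of
  reads, standing for mis-mapped and Y-homologous reads), and carries a
  single X, scaling the chrX weight by `(1 − ff/2)`.
* The vector is renormalized and drawn once per sample.

**Overdispersion.** Real runs show more run-to-run spread in chromosomal
ratios than multinomial noise. This is modelled by multiplying each weight by
an independent unit-mean gamma variate with CV `overdispersion_cv` before
renormalization, giving ratio CV ≈ `sqrt(CV_multinomial² + od²)`.

**Calibration.** The default `overdispersion_cv` is solved analytically so
that the *expected* chr21 z of a trisomy-21 sample equals 3 at FF = 4.5% —
the midpoint of the 4–5% bin, where the assay's empirical detection rate is
50% — under the default read budget. With GRCh38 lengths and N = 1.5 M this
gives od ≈ 0.34% on top of a multinomial CV of ≈ 0.65% (total ≈ 0.74%). The
assay's published detection-versus-FF profile is the only constraint
available on inter-run variance, so this calibration is an inference, not a
measured quantity; absolute false-positive rates inherit that uncertainty.

A direct consequence worth keeping in mind when reading small LoD tables:
with expected z = 3 at 4.5% FF, the per-replicate detection probability at
5–6% FF is ≈ 75–85%, so a six-replicate bin reaches 6/6 only some of the
time. The "100% detection above 5%" reading corresponds to the upper shoulder
of this power curve; at 10 000 replicates the 4–5% bin sits at 50% and
FF = 10% detection is indistinguishable from 100%.

## z-score caller

`z_c = (r_c − μ_c)/σ_c`, with `r_c` the sample's read share on chromosome
*c* and (μ_c, σ_c) the sample mean and SD (n − 1 denominator) over a euploid
reference panel (default n = 412, mixed fetal sex, FF drawn from the cohort
law). Decision rule: `z ≥ 3` (boundary inclusive) flags high risk on the
scored chromosomes (13, 18, 21 by default; all autosomes scoreable via
configuration). QC gates, applied before any call: total unique reads
< 1 500 000 → `insufficient_reads`; FF < 3.5% → `low_ff_alert` (FF exactly
3.5% passes; re-collection is the clinical recommendation). z values are
computed regardless of QC so that a blocked sample's dosage signal remains
inspectable.

## chrY fetal-fraction estimator

For male fetuses, FF is the linear interpolation coordinate of the observed
chrY ratio between two anchors: the female background ratio (ff = 0) and the
ratio a pure male genome would give (ff = 1), both derived by default from
the simulator's own weight model so the estimator is consistent with the
generative process. The estimate is clipped to [0, 1]. The true chrY ratio
is mildly nonlinear in ff (the chrX reduction and chrY addition perturb the
normalizing constant in opposite directions); at ff = 10% the induced bias
is below 0.1 percentage points, within the estimator's sampling noise.
Fetal sex is confirmed by the chrY z against a female-fetus panel with a
strict z > 15 rule. FF for **female** fetuses has no chrY signal and is
carried as metadata only; size- or SNP-based estimators are out of scope.

## Mixtures and the LoD experiment

Pooling a trisomic male library (concentration C₁, volume V₁, fetal fraction
FF₁) with a euploid female library (C₂, V₂) gives
`expected FF = C₁V₁·FF₁/(C₁V₁ + C₂V₂)`. In silico, the mixture's weight
vector is the mass-weighted average of the two sources' expected weight
vectors followed by one overdispersed multinomial draw — so the chr21 lift
and the chrY content both correspond to the expected FF.

The LoD experiment draws a target FF uniformly within each bin (< 3%, 3–4%,
4–5%, 5–6%, and 8–15% as the representative range of the open > 8% bin;
6–8% stays unsampled to mirror the assay's design), solves the diluent
volume reaching that target from a source library (default FF 16%, above
every bin; a list of distinct source FFs can be cycled instead of
re-diluting one source), and runs the full pipeline per replicate: chrY FF
estimate, QC gates, chr21 z ≥ 3. The LoD is the lowest bin from which
detection is contiguously 100%; six replicates per bin mirrors the original
design, and larger replicate counts turn the table into a power curve.
Physical pooling constraints (≥ 10 pM library concentration before pooling)
surface as flags, not simulation physics.

## Cohort generator and analytics

Maternal weight, gestational age (GA) and maternal age are truncated
normals: weight (56.43, 8) kg on [40, 110], GA (16.48, 3) weeks on [12, 40],
age (30.92, 4.5) years on [18, 48]; fetal sex is Bernoulli(0.5) and twins
are a 1.2% flag with no special dosage model. FF in percent follows a
per-GA-stratum linear law `FF = a + b·weight + ε`, `ε ~ N(0, 3)`, clipped to
[0, 50]%:

| GA stratum (weeks) | intercept a (%) | slope b (%/kg) | 5%-FF crossing |
|---|---|---|---|
| [12, 20) | 16.52 | −0.12 | 96 kg |
| [20, 23) | 16.16 | −0.12 | 93 kg |
| [23, ∞)  | 24.44 | −0.12 | 162 kg |

The slope and crossing weights are the study conditions the analytics are
meant to recover; the intercepts follow from them. The stratum structure
also produces the characteristic GA profile (flat to 19 weeks, slight dip at
20–22, rise from 23). This generator emulates the *statistical structure* of
a screening cohort — negative weight–FF correlation, GA strata, realistic
marginals — not its full joint distribution: FF residuals are homoscedastic
Gaussians, weight and GA are independent, and clinical covariates (parity,
smoking, aneuploidy prevalence) are absent. Passing tests therefore
demonstrate that the estimators recover known generative parameters, not
that real cohorts obey this law.

Analytics are thin, typed wrappers over scipy.stats: Pearson correlation,
Welch's unpaired t-test by default (pooled-variance switch available, since
either reading is defensible), `scipy.stats.linregress` for the per-stratum
OLS, and inverse prediction `weight = (target% − a)/b` with warnings when
the crossing extrapolates beyond the observed weight range (it usually does
— the interesting crossing lies above the heaviest typical patient, which is
precisely why it matters clinically) or when the slope is positive. The
"near the median" comparison group is FF within ±1 percentage point of the
cohort median (window configurable; the notion is otherwise underdetermined).
Inverse prediction reports the point estimate; a bootstrap CI is a natural
extension but is not provided. Significance marks: \*P < 0.05,
\*\*\*\*P < 0.0001.

The non-pregnant control generator produces cfDNA level with a weak negative
age effect (population r ≈ −0.25 by default) and mutually consistent but
cfDNA-independent body covariates, for exercising the correlation screen.

## Fragment-length model and zone ratio

Fetal and maternal fragments are lognormal components parameterized by modal
length (143 / 166 bp) and FWHM (default 20 bp, i.e. σ ≈ 0.059 on the log
scale), mixed in proportion ff and rounded to integer bp. The fetal-zone
area ratio is the histogram mass with bin centres inside [120, 155] bp — a
window bracketing the fetal mode while excluding the maternal one (bounds
configurable; electropherogram zone bounds are instrument conventions). The
ratio is monotone in ff because the fetal component holds strictly more mass
in the zone than the maternal one; tests verify this against direct
integration of the component densities.

A numerical caveat: the max-bin mode of a single 100 000-draw 1 bp histogram
is noisy — adjacent bins near the peak differ by less than their Poisson
noise — so a single draw lands within ±1 bp of the configured mode in only
~85–90% of runs, and consensus (median-of-draws) estimates are used where a
stable mode is asserted.

## Determinism and numerics

Every stochastic function takes a seed or `numpy.random.Generator`; pipeline
drivers derive stage seeds via `numpy.random.SeedSequence` spawning, so one
top-level seed fixes everything and stages are independently reproducible.
Degenerate inputs fail loudly: panels need ≥ 2 samples and strictly positive
SDs, regression needs ≥ 3 samples with non-constant weights, empty cohorts
and zero-mass mixtures raise configuration errors. Boundary conventions: z
thresholds are inclusive (z = 3 calls), the FF alert is strict (< 3.5%), the
male-sex chrY check is strict (> 15), GA bins and strata are half-open
[lo, hi).

## Problem sizes

Defaults chosen for the bundled tests and the reproduction script: reference
panels of 412 simulated euploids; 10 000 trisomy profiles for the 4–5% FF
detection rate and 100 at FF = 10%; 100 000 fragments per modal-length
estimate; 20 cohorts of n = 2000 for the crossing-weight recovery; 1000-draw
means for monotonicity checks. At these sizes the whole suite runs in well
under a minute on one CPU while keeping Monte-Carlo noise far below the
assertion tolerances.

## Known limitations

* No GC or mappability bias, no mosaicism (confined placental mosaicism —
  the usual explanation for high-FF false negatives — is explicitly not
  modelled), no maternal CNV effects.
* The overdispersion calibration ties simulated variance to a single
  empirical operating point (50% detection at 4.5% FF); false-positive and
  borderline-detection rates should be read as consistent with that
  calibration rather than as assay measurements.
* Female-fetus FF estimation is out of scope.
* Fragment components are parametric idealizations of electrophoresis
  traces; nucleosomal 10 bp periodicity is not modelled.
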