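"""Synthetic cfDNA data generators.

Everything downstream (the z-score caller, chrY fetal-fraction estimator,
limit-of-detection experiment, cohort analytics, fragment analysis) is
exercised on data produced here, so this module encodes the generative model
the analysis assumes:

* **Read counts.** A sample's per-chromosome unique-read counts are one
  multinomial draw of the read budget from a weight vector derived from
  chromosome lengths. The fetus contributes a fraction ``ff`` of cfDNA: a
  trisomic chromosome's weight is lifted by ``(1 + ff/2)`` (three fetal
  copies instead of two), a male fetus adds chrY weight ``p_Y * ff`` on top
  of a small female background and carries one X (chrX weight scaled by
  ``1 - ff/2``). Run-to-run overdispersion beyond multinomial noise is
  modelled by gamma-jittering the weight vector per sample.

* **Fragment lengths.** A two-component mixture: fetal fragments modal at
  143 bp, maternal at 166 bp, mixed in proportion ``ff``.

* **Cohorts.** Maternal weight, gestational age and age are drawn from
  truncated normals; FF (in percent) follows a per-gestational-stratum
  linear law ``ff = intercept + slope * weight + noise``, negatively sloped
  in weight.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .genome import CHROMOSOMES, GRCH38_CHROM_LENGTHS, TRISOMY_CHROM

__all__ = [
    "SequencingParams",
    "SampleRecord",
    "CohortParams",
    "FFLawStratum",
    "FFLaw",
    "TruncNormal",
    "FragmentLengthParams",
    "FragmentLengthSample",
    "calibrate_overdispersion",
    "expected_proportions",
    "simulate_read_counts",
    "simulate_fragment_lengths",
    "generate_cohort",
    "generate_reference_cohort",
    "generate_nonpregnant_cohort",
    "as_rng",
]

DEFAULT_Z_TARGET = 3.0
DEFAULT_CALIBRATION_FF = 0.045  # midpoint of the 4-5% detection bin


def as_rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    """Return a ``numpy.random.Generator``; integers and SeedSequences are seeded."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SequencingParams:
    """Sequencing run configuration for the read-count simulator.

    Defaults follow the assay under study: >= 1.5 M unique reads per sample,
    single-end 45 bp reads of which 6 bp are sample barcode, a 3 Gb genome.

    ``overdispersion_cv`` is extra relative SD on chromosomal ratios beyond
    multinomial noise. ``None`` (default) means *calibrated*: solved so the
    expected chr21 z of a trisomy-21 sample equals 3 at FF = 4.5% under the
    configured read budget (see :func:`calibrate_overdispersion`).
    """

    total_unique_reads: int = 1_500_000
    read_length_bp: int = 45
    barcode_length_bp: int = 6
    genome_length_bp: int = 3_000_000_000
    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(GRCH38_CHROM_LENGTHS)
    )
    overdispersion_cv: float | None = None
    chry_female_background: float = 0.0005  # chrY weight in a female-fetus pregnancy

    def __post_init__(self) -> None:
        if self.total_unique_reads < 1:
            raise ConfigurationError("total_unique_reads must be >= 1")
        if min(self.read_length_bp, self.genome_length_bp) <= 0:
            raise ConfigurationError("read and genome lengths must be positive")
        if self.barcode_length_bp < 0 or self.barcode_length_bp >= self.read_length_bp:
            raise ConfigurationError("barcode length must be in [0, read_length)")
        if not self.chromosome_lengths:
            raise ConfigurationError("chromosome_lengths must be non-empty")
        if any(length <= 0 for length in self.chromosome_lengths.values()):
            raise ConfigurationError("all chromosome lengths must be positive")
        if self.overdispersion_cv is not None and self.overdispersion_cv < 0:
            raise ConfigurationError("overdispersion_cv must be >= 0")
        if not 0 <= self.chry_female_background < 1:
            raise ConfigurationError("chry_female_background must be in [0, 1)")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.chromosome_lengths)

    @property
    def effective_read_length_bp(self) -> int:
        return self.read_length_bp - self.barcode_length_bp

    def resolved_overdispersion(self) -> float:
        if self.overdispersion_cv is not None:
            return self.overdispersion_cv
        return calibrate_overdispersion(self)


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one pregnancy sample."""

    sample_id: str
    ff: float
    gestational_age_weeks: float = 16.0
    maternal_age_years: float = 31.0
    maternal_weight_kg: float = 56.0
    fetal_sex: str = "female"
    karyotype: str = "euploid"
    twin: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.ff <= 1.0:
            raise ConfigurationError(f"ff must be in [0, 1], got {self.ff}")
        if self.maternal_weight_kg <= 0:
            raise ConfigurationError("maternal weight must be positive")
        if self.gestational_age_weeks < 0:
            raise ConfigurationError("gestational age must be >= 0")
        if self.fetal_sex not in ("male", "female"):
            raise ConfigurationError(f"unknown fetal_sex {self.fetal_sex!r}")
        if self.karyotype not in ("euploid",) + tuple(TRISOMY_CHROM):
            raise ConfigurationError(f"unknown karyotype {self.karyotype!r}")


@dataclass(frozen=True)
class TruncNormal:
    """Normal(mean, sd) truncated (by rejection) to [lo, hi]."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("sd must be >= 0")
        if self.lo > self.hi:
            raise ConfigurationError("truncation bounds must be ordered")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, float(np.clip(self.mean, self.lo, self.hi)))
        out = rng.normal(self.mean, self.sd, size=n)
        bad = (out < self.lo) | (out > self.hi)
        while bad.any():
            out[bad] = rng.normal(self.mean, self.sd, size=int(bad.sum()))
            bad = (out < self.lo) | (out > self.hi)
        return out


@dataclass(frozen=True)
class FFLawStratum:
    """Linear FF-vs-weight law for one gestational-age stratum.

    FF(%) = intercept_pct + slope_pct_per_kg * weight_kg, plus residual noise.
    """

    ga_lo_weeks: float
    ga_hi_weeks: float
    intercept_pct: float
    slope_pct_per_kg: float


def _default_strata() -> tuple[FFLawStratum, ...]:
    # Intercepts place the 5%-FF crossing at 96 / 93 / 162 kg for the three
    # gestational strata, with a common -0.12 %/kg slope.
    return (
        FFLawStratum(12.0, 20.0, 16.52, -0.12),
        FFLawStratum(20.0, 23.0, 16.16, -0.12),
        FFLawStratum(23.0, math.inf, 24.44, -0.12),
    )


@dataclass(frozen=True)
class FFLaw:
    """Piecewise (per gestational stratum) linear FF generative law."""

    strata: tuple[FFLawStratum, ...] = field(default_factory=_default_strata)
    residual_sd_pct: float = 3.0

    def __post_init__(self) -> None:
        if self.residual_sd_pct < 0:
            raise ConfigurationError("residual SD must be >= 0")
        if not self.strata:
            raise ConfigurationError("at least one FF stratum required")

    def stratum_for(self, ga_weeks: float) -> FFLawStratum:
        for s in self.strata:
            if s.ga_lo_weeks <= ga_weeks < s.ga_hi_weeks:
                return s
        # GA outside all strata: clamp to the nearest one.
        return min(
            self.strata,
            key=lambda s: min(abs(ga_weeks - s.ga_lo_weeks), abs(ga_weeks - s.ga_hi_weeks)),
        )

    def mean_ff_pct(self, ga_weeks: float, weight_kg: float) -> float:
        s = self.stratum_for(ga_weeks)
        return s.intercept_pct + s.slope_pct_per_kg * weight_kg


@dataclass(frozen=True)
class CohortParams:
    """Generative model for a pregnancy screening cohort."""

    n_samples: int
    seed: int
    ff_law: FFLaw = field(default_factory=FFLaw)
    weight_law: TruncNormal = TruncNormal(56.43, 8.0, 40.0, 110.0)
    ga_law: TruncNormal = TruncNormal(16.48, 3.0, 12.0, 40.0)
    age_law: TruncNormal = TruncNormal(30.92, 4.5, 18.0, 48.0)
    male_fraction: float = 0.5
    twin_rate: float = 0.012

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if not 0 <= self.male_fraction <= 1:
            raise ConfigurationError("male_fraction must be in [0, 1]")
        if not 0 <= self.twin_rate <= 1:
            raise ConfigurationError("twin_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# read-count model
# ---------------------------------------------------------------------------


def expected_proportions(
    seq: SequencingParams,
    ff: float,
    fetal_sex: str = "female",
    karyotype: str = "euploid",
) -> dict[str, float]:
    """Expected (noise-free) per-chromosome read proportions for one sample.

    Baseline weights are chromosome-length shares over the non-Y chromosomes
    (the maternal genome carries no Y). The fetal contribution at fraction
    ``ff`` lifts a trisomic chromosome by ``(1 + ff/2)``; a male fetus
    contributes chrY weight ``p_Y * ff`` (``p_Y`` = chrY length share of the
    whole genome) on top of the female background and scales chrX by
    ``(1 - ff/2)``. The vector is renormalized to sum to 1.
    """
    if not 0.0 <= ff <= 1.0:
        raise ConfigurationError(f"ff must be in [0, 1], got {ff}")
    lengths = seq.chromosome_lengths
    non_y = [c for c in lengths if c != "chrY"]
    total_non_y = float(sum(lengths[c] for c in non_y))
    total_all = float(sum(lengths.values()))
    w = {c: lengths[c] / total_non_y for c in non_y}

    y_weight = seq.chry_female_background if "chrY" in lengths else 0.0
    if fetal_sex == "male":
        if "chrX" in w:
            w["chrX"] *= 1.0 - ff / 2.0
        if "chrY" in lengths:
            y_weight += (lengths["chrY"] / total_all) * ff
    if "chrY" in lengths:
        w["chrY"] = y_weight

    if karyotype != "euploid":
        chrom = TRISOMY_CHROM.get(karyotype)
        if chrom is None:
            raise ConfigurationError(f"unknown karyotype {karyotype!r}")
        if chrom not in w:
            raise ConfigurationError(f"trisomic chromosome {chrom} not in weight vector")
        w[chrom] *= 1.0 + ff / 2.0

    total = sum(w.values())
    return {c: w[c] / total for c in seq.chromosomes}


def calibrate_overdispersion(
    seq: SequencingParams,
    target_z: float = DEFAULT_Z_TARGET,
    ff: float = DEFAULT_CALIBRATION_FF,
    chrom: str = "chr21",
) -> float:
    """Solve the extra ratio CV so E[z_chrom] = ``target_z`` for a trisomy at ``ff``.

    The expected z is Δr / (μ sqrt(cv_multinomial² + od²)) where Δr is the
    trisomic minus euploid expected ratio, μ the euploid ratio and
    cv_multinomial² = (1-μ)/(N μ). Returns od; 0 if the multinomial noise
    alone already exceeds the requirement.
    """
    karyotype = next((k for k, c in TRISOMY_CHROM.items() if c == chrom), None)
    if karyotype is None:
        raise ConfigurationError(f"no trisomy karyotype defined for {chrom}")
    mu = expected_proportions(seq, ff=ff, fetal_sex="male", karyotype="euploid")[chrom]
    lifted = expected_proportions(seq, ff=ff, fetal_sex="male", karyotype=karyotype)[chrom]
    required_cv = (lifted - mu) / (target_z * mu)
    cv_multinomial_sq = (1.0 - mu) / (seq.total_unique_reads * mu)
    extra = required_cv**2 - cv_multinomial_sq
    return math.sqrt(extra) if extra > 0 else 0.0


def _weight_array(seq: SequencingParams, proportions: Mapping[str, float]) -> np.ndarray:
    return np.array([proportions[c] for c in seq.chromosomes], dtype=float)


def draw_counts(
    seq: SequencingParams,
    proportions: Mapping[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """One overdispersed multinomial draw of the read budget.

    Per-sample gamma jitter (unit mean, CV = overdispersion_cv) multiplies each
    chromosome weight before renormalization, adding inter-run spread to
    chromosomal ratios on top of multinomial noise.
    """
    w = _weight_array(seq, proportions)
    od = seq.resolved_overdispersion()
    if od > 0:
        shape = 1.0 / od**2
        w = w * rng.gamma(shape, 1.0 / shape, size=w.size)
    w = w / w.sum()
    return rng.multinomial(seq.total_unique_reads, w)


def simulate_read_counts(
    sample: SampleRecord,
    seq: SequencingParams,
    seed: int | np.random.Generator,
):
    """Simulate one sample's per-chromosome unique-read counts.

    Returns a :class:`niptsim.caller.ReadCountProfile` whose counts sum
    exactly to ``seq.total_unique_reads``.
    """
    from .caller import ReadCountProfile  # local import to avoid a cycle

    rng = as_rng(seed)
    props = expected_proportions(seq, sample.ff, sample.fetal_sex, sample.karyotype)
    counts = draw_counts(seq, props, rng)
    return ReadCountProfile(
        sample_id=sample.sample_id,
        counts={c: int(n) for c, n in zip(seq.chromosomes, counts)},
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(params: CohortParams) -> list[SampleRecord]:
    """Draw a cohort of euploid pregnancy records under the configured laws.

    FF follows the per-stratum linear law in maternal weight with Gaussian
    residuals, truncated (clipped) to [0, 50]%. Deterministic per seed.
    """
    rng = as_rng(params.seed)
    n = params.n_samples
    weights = params.weight_law.sample(rng, n)
    gas = params.ga_law.sample(rng, n)
    ages = params.age_law.sample(rng, n)
    sexes = np.where(rng.random(n) < params.male_fraction, "male", "female")
    twins = rng.random(n) < params.twin_rate
    noise = rng.normal(0.0, params.ff_law.residual_sd_pct, size=n)

    records = []
    for i in range(n):
        ff_pct = params.ff_law.mean_ff_pct(gas[i], weights[i]) + noise[i]
        ff = float(np.clip(ff_pct / 100.0, 0.0, 0.5))
        records.append(
            SampleRecord(
                sample_id=f"S{i:05d}",
                ff=ff,
                gestational_age_weeks=float(gas[i]),
                maternal_age_years=float(ages[i]),
                maternal_weight_kg=float(weights[i]),
                fetal_sex=str(sexes[i]),
                karyotype="euploid",
                twin=bool(twins[i]),
            )
        )
    return records


def generate_reference_cohort(
    n: int,
    seq: SequencingParams,
    seed: int,
    cohort_params: CohortParams | None = None,
) -> list:
    """Simulate ``n`` euploid read-count profiles (mixed fetal sex, FF from the
    cohort law) for use as a reference panel.

    ``n >= 2`` is required: a panel SD is undefined otherwise.
    """
    if n < 2:
        raise ConfigurationError("a reference cohort needs n >= 2 (SD undefined)")
    rng = as_rng(seed)
    if cohort_params is None:
        cohort_params = CohortParams(n_samples=n, seed=int(rng.integers(2**31)))
    else:
        cohort_params = replace(cohort_params, n_samples=n)
    records = generate_cohort(cohort_params)
    return [simulate_read_counts(rec, seq, rng) for rec in records]


# ---------------------------------------------------------------------------
# fragment lengths
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentLengthParams:
    """Two-component cfDNA fragment-length mixture.

    Components are lognormal, parameterized by modal length and full width at
    half maximum; fetal fragments are shorter (143 bp mode) than maternal
    (166 bp mode).
    """

    fetal_mode_bp: float = 143.0
    maternal_mode_bp: float = 166.0
    fwhm_bp: float = 20.0

    def __post_init__(self) -> None:
        if min(self.fetal_mode_bp, self.maternal_mode_bp, self.fwhm_bp) <= 0:
            raise ConfigurationError("fragment modes and FWHM must be positive")

    def _sigma(self, mode: float) -> float:
        # Near-Gaussian lognormal: FWHM ~ 2.355 * mode * sigma.
        return self.fwhm_bp / (2.0 * math.sqrt(2.0 * math.log(2.0)) * mode)

    def component_lengths(
        self, mode: float, n: int, rng: np.random.Generator
    ) -> np.ndarray:
        sigma = self._sigma(mode)
        mu = math.log(mode) + sigma**2  # lognormal mode = exp(mu - sigma^2)
        lengths = np.rint(np.exp(rng.normal(mu, sigma, size=n))).astype(int)
        return np.maximum(lengths, 1)


@dataclass(frozen=True)
class FragmentLengthSample:
    """Fragment lengths (bp) drawn for one sample at fetal fraction ``ff``."""

    lengths_bp: np.ndarray
    ff: float
    params: FragmentLengthParams

    def __post_init__(self) -> None:
        if len(self.lengths_bp) and int(np.min(self.lengths_bp)) <= 0:
            raise ConfigurationError("all fragment lengths must be positive")


def simulate_fragment_lengths(
    params: FragmentLengthParams,
    ff: float,
    n: int,
    seed: int | np.random.Generator,
) -> FragmentLengthSample:
    """Draw ``n`` fragment lengths from the ff-weighted fetal/maternal mixture."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if not 0.0 <= ff <= 1.0:
        raise ConfigurationError(f"ff must be in [0, 1], got {ff}")
    rng = as_rng(seed)
    n_fetal = int(rng.binomial(n, ff))
    fetal = params.component_lengths(params.fetal_mode_bp, n_fetal, rng)
    maternal = params.component_lengths(params.maternal_mode_bp, n - n_fetal, rng)
    lengths = np.concatenate([fetal, maternal])
    rng.shuffle(lengths)
    return FragmentLengthSample(lengths_bp=lengths, ff=ff, params=params)


# ---------------------------------------------------------------------------
# non-pregnant controls
# ---------------------------------------------------------------------------


def generate_nonpregnant_cohort(
    n: int = 71,
    seed: int = 0,
    age_cfdna_r: float = -0.25,
):
    """Generate a non-pregnant control cohort as a DataFrame.

    Columns: cfdna_ng_ml, age_years, height_cm, weight_kg, bmi, body_fat_pct,
    basal_metabolism_kcal. Plasma cfDNA concentration carries a weak linear
    age effect tuned to population correlation ``age_cfdna_r``; the body
    covariates are mutually consistent (BMI from height/weight) but
    independent of cfDNA level.
    """
    import pandas as pd

    if n < 3:
        raise ConfigurationError("need n >= 3 for correlation analysis")
    if not -1.0 < age_cfdna_r < 1.0:
        raise ConfigurationError("age_cfdna_r must be in (-1, 1)")
    rng = as_rng(seed)
    age = TruncNormal(30.79, 6.0, 20.0, 45.0).sample(rng, n)
    height = TruncNormal(158.0, 6.0, 140.0, 180.0).sample(rng, n)
    weight = TruncNormal(54.76, 7.0, 38.0, 85.0).sample(rng, n)
    bmi = weight / (height / 100.0) ** 2
    body_fat = np.clip(1.2 * bmi + 0.23 * age - 5.4 + rng.normal(0, 2.0, n), 10, 50)
    basal = 447.6 + 9.25 * weight + 3.1 * height - 4.33 * age + rng.normal(0, 40.0, n)

    # cfdna = base + beta*age + eps with corr(age, cfdna) = r:
    # beta*sd_age / sqrt(beta^2 sd_age^2 + sd_eps^2) = r.
    sd_total = 0.06  # ng/uL scale spread
    sd_age = float(np.std(age))
    beta = age_cfdna_r * sd_total / sd_age
    sd_eps = sd_total * math.sqrt(1.0 - age_cfdna_r**2)
    cfdna = np.clip(0.25 + beta * (age - age.mean()) + rng.normal(0, sd_eps, n), 0.01, None)

    return pd.DataFrame(
        {
            "cfdna_ng_ml": cfdna,
            "age_years": age,
            "height_cm": height,
            "weight_kg": weight,
            "bmi": bmi,
            "body_fat_pct": body_fat,
            "basal_metabolism_kcal": basal,
        }
    )
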