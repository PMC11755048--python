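"""Artificial-mixture model and the limit-of-detection (LoD) experiment.

Two sequencing libraries — one from a trisomy-21 male-fetus pregnancy, one
from a euploid female-fetus pregnancy — are pooled in known amounts. The
mixture's expected fetal fraction follows from the mass (concentration x
volume) each library contributes:

    expected FF = C1*V1*FF1 / (C1*V1 + C2*V2)

In silico the mixture's per-chromosome weight vector is the mass-weighted
average of the two sources' expected weight vectors, followed by one
multinomial draw of the read budget. The LoD experiment dilutes a trisomic
source library to target FF bins, runs the full caller (chrY FF estimate,
QC gates, chr21 z >= 3) on each replicate, and tabulates detection rates per
bin; the LoD is the lowest bin from which detection stays at 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .caller import (
    HIGH_RISK,
    CallerConfig,
    ReadCountProfile,
    ReferencePanel,
    classify,
    z_score,
)
from .errors import ConfigurationError
from .ff import YBaselines, ff_from_chrY
from .synthetic import (
    SampleRecord,
    SequencingParams,
    as_rng,
    draw_counts,
    expected_proportions,
)

__all__ = [
    "LibrarySpec",
    "MixtureDesign",
    "LoDBinResult",
    "LoDTable",
    "DEFAULT_BINS",
    "expected_ff",
    "mix_profiles",
    "design_for_target_ff",
    "run_lod_experiment",
    "estimate_lod",
    "simulate_detection_rate",
]

# The study's dilution bins: <3%, 3-4%, 4-5%, 5-6%, >8% (represented 8-15%);
# 6-8% is deliberately unsampled.
DEFAULT_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 0.03),
    (0.03, 0.04),
    (0.04, 0.05),
    (0.05, 0.06),
    (0.08, 0.15),
)

MIN_POOL_CONCENTRATION_PM = 10.0  # libraries below this are flagged before pooling


@dataclass(frozen=True)
class LibrarySpec:
    """One source sequencing library entering the mixture."""

    concentration_pm: float
    volume_ul: float
    ff: float
    karyotype: str = "euploid"
    fetal_sex: str = "female"

    def __post_init__(self) -> None:
        if self.concentration_pm <= 0:
            raise ConfigurationError("library concentration must be positive")
        if self.volume_ul < 0:
            raise ConfigurationError("library volume must be >= 0")
        if not 0 <= self.ff <= 1:
            raise ConfigurationError("library ff must be in [0, 1]")

    @property
    def mass(self) -> float:
        return self.concentration_pm * self.volume_ul

    @property
    def below_pooling_concentration(self) -> bool:
        return self.concentration_pm < MIN_POOL_CONCENTRATION_PM


def expected_ff(c1: float, v1: float, ff1: float, c2: float, v2: float) -> float:
    """Expected fetal fraction of the pooled library: c1*v1*ff1/(c1*v1 + c2*v2)."""
    mass1 = c1 * v1
    mass2 = c2 * v2
    if mass1 < 0 or mass2 < 0:
        raise ConfigurationError("library masses must be >= 0")
    total = mass1 + mass2
    if total <= 0:
        raise ConfigurationError("total library mass must be positive")
    return mass1 * ff1 / total


@dataclass(frozen=True)
class MixtureDesign:
    """A trisomic male library diluted with a euploid female library."""

    lib1: LibrarySpec  # trisomic, male fetus
    lib2: LibrarySpec  # euploid, female fetus

    @property
    def expected_ff(self) -> float:
        return expected_ff(
            self.lib1.concentration_pm,
            self.lib1.volume_ul,
            self.lib1.ff,
            self.lib2.concentration_pm,
            self.lib2.volume_ul,
        )


def design_for_target_ff(
    target_ff: float,
    source_ff: float = 0.16,
    source_concentration_pm: float = 20.0,
    source_volume_ul: float = 5.0,
    diluent_concentration_pm: float = 20.0,
    diluent_ff: float = 0.10,
    karyotype: str = "T21",
) -> MixtureDesign:
    """Dilution recipe reaching ``target_ff`` from a trisomic male source library.

    Solves the diluent volume from the expected-FF formula; requires
    ``0 < target_ff <= source_ff`` (dilution can only lower FF).
    """
    if not 0 < target_ff <= source_ff:
        raise ConfigurationError(
            f"target ff {target_ff} must be in (0, source ff {source_ff}]"
        )
    mass1 = source_concentration_pm * source_volume_ul
    mass2 = mass1 * (source_ff / target_ff - 1.0)
    lib1 = LibrarySpec(source_concentration_pm, source_volume_ul, source_ff, karyotype, "male")
    lib2 = LibrarySpec(
        diluent_concentration_pm, mass2 / diluent_concentration_pm, diluent_ff, "euploid", "female"
    )
    return MixtureDesign(lib1=lib1, lib2=lib2)


def _library_proportions(lib: LibrarySpec, seq: SequencingParams) -> dict[str, float]:
    return expected_proportions(seq, lib.ff, lib.fetal_sex, lib.karyotype)


def mixture_proportions(design: MixtureDesign, seq: SequencingParams) -> dict[str, float]:
    """Mass-weighted average of the two sources' expected chromosome weights."""
    m1, m2 = design.lib1.mass, design.lib2.mass
    total = m1 + m2
    if total <= 0:
        raise ConfigurationError("mixture has zero total mass")
    p1 = _library_proportions(design.lib1, seq)
    p2 = _library_proportions(design.lib2, seq)
    return {c: (m1 * p1[c] + m2 * p2[c]) / total for c in seq.chromosomes}


def mix_profiles(
    design: MixtureDesign,
    seq: SequencingParams,
    seed: int | np.random.Generator,
    sample_id: str = "mixture",
) -> ReadCountProfile:
    """One simulated sequencing run of the pooled mixture library."""
    rng = as_rng(seed)
    props = mixture_proportions(design, seq)
    counts = draw_counts(seq, props, rng)
    return ReadCountProfile(
        sample_id=sample_id, counts={c: int(n) for c, n in zip(seq.chromosomes, counts)}
    )


@dataclass(frozen=True)
class LoDBinResult:
    """Detection tally for one FF bin."""

    ff_lo: float
    ff_hi: float
    n_replicates: int
    n_detected: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_detected <= self.n_replicates:
            raise ConfigurationError("n_detected must be in [0, n_replicates]")

    @property
    def detection_rate_pct(self) -> float:
        if self.n_replicates == 0:
            return float("nan")
        return 100.0 * self.n_detected / self.n_replicates


@dataclass(frozen=True)
class LoDTable:
    """Detection rates per FF bin over replicate mixtures."""

    bins: tuple[LoDBinResult, ...]

    def __post_init__(self) -> None:
        los = [b.ff_lo for b in self.bins]
        if los != sorted(los):
            raise ConfigurationError("LoD bins must be ordered by lower edge")

    @property
    def rates_pct(self) -> tuple[float, ...]:
        return tuple(b.detection_rate_pct for b in self.bins)


def run_lod_experiment(
    panel: ReferencePanel,
    seq: SequencingParams,
    baselines: YBaselines | None = None,
    *,
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
    replicates_per_bin: int = 6,
    source_ffs: Sequence[float] | None = None,
    source_ff: float = 0.16,
    caller_config: CallerConfig | None = None,
    apply_ff_alert: bool = True,
    seed: int | np.random.Generator = 0,
) -> LoDTable:
    """Dilution-series detection experiment over FF bins.

    Per replicate: draw a target FF uniformly within the bin, build the
    dilution design, simulate the mixture run, estimate FF from chrY, and
    classify; a replicate is *detected* when QC passes and chr21 is called
    high risk. ``source_ffs`` cycles distinct source-library FFs across
    replicates (the alternative to re-diluting one source at ``source_ff``).
    """
    if not bins:
        raise ConfigurationError("at least one FF bin required")
    if replicates_per_bin < 1:
        raise ConfigurationError("replicates_per_bin must be >= 1")
    for lo, hi in bins:
        if not 0 <= lo < hi:
            raise ConfigurationError(f"malformed bin ({lo}, {hi})")
    rng = as_rng(seed)
    baselines = baselines or YBaselines.from_sequencing_params(seq)
    config = caller_config or CallerConfig()

    results = []
    for lo, hi in bins:
        detected = 0
        for rep in range(replicates_per_bin):
            target = float(rng.uniform(lo, hi))
            src = source_ffs[rep % len(source_ffs)] if source_ffs else source_ff
            if target == 0.0 or target > src:
                # zero-FF control (or unreachable target): pure euploid diluent run
                design = MixtureDesign(
                    lib1=LibrarySpec(20.0, 0.0, src, "T21", "male"),
                    lib2=LibrarySpec(20.0, 5.0, 0.10, "euploid", "female"),
                )
            else:
                design = design_for_target_ff(target, source_ff=src)
            profile = mix_profiles(design, seq, rng, sample_id=f"mix_{lo:g}_{rep}")
            ff_est = ff_from_chrY(profile, baselines) if apply_ff_alert else None
            result = classify(profile, panel, ff=ff_est, config=config)
            if result.calls.get("chr21") == HIGH_RISK:
                detected += 1
        results.append(LoDBinResult(lo, hi, replicates_per_bin, detected))
    return LoDTable(bins=tuple(results))


def estimate_lod(table: LoDTable) -> LoDBinResult | None:
    """Lowest bin at and above which detection is 100% (contiguously).

    Returns ``None`` when no such bin exists ("not reached").
    """
    if not table.bins:
        raise ConfigurationError("empty LoD table")
    lod = None
    for b in reversed(table.bins):
        if b.detection_rate_pct == 100.0:
            lod = b
        else:
            break
    return lod


def simulate_detection_rate(
    ff_values: Sequence[float],
    panel: ReferencePanel,
    seq: SequencingParams,
    seed: int | np.random.Generator,
    caller_config: CallerConfig | None = None,
    karyotype: str = "T21",
) -> float:
    """Percent of simulated trisomic male-fetus samples with chr21 z >= threshold.

    Direct power simulation (no mixing, no FF gate): one profile per FF in
    ``ff_values``, scored against the panel with the plain z rule.
    """
    from .synthetic import simulate_read_counts

    config = caller_config or CallerConfig()
    rng = as_rng(seed)
    chrom = {"T21": "chr21", "T18": "chr18", "T13": "chr13"}[karyotype]
    detected = 0
    for i, ff in enumerate(ff_values):
        sample = SampleRecord(
            sample_id=f"pw{i}", ff=float(ff), fetal_sex="male", karyotype=karyotype
        )
        profile = simulate_read_counts(sample, seq, rng)
        if z_score(profile, panel, chrom) >= config.z_threshold:
            detected += 1
    return 100.0 * detected / len(ff_values)
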