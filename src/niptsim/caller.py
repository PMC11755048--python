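"""Z-score aneuploidy caller with a euploid reference panel.

A sample's per-chromosome read proportion is standardized against the mean
and SD of the same proportion over a panel of euploid pregnancies; a
chromosome with z >= 3 is called high risk for that trisomy. Two QC gates
precede calling: a minimum unique-read budget (1.5 M) and a minimum fetal
fraction (3.5%, below which a low-FF alert replaces the call and blood
re-collection is recommended).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, DegeneratePanelError

__all__ = [
    "ReadCountProfile",
    "ReferencePanel",
    "CallerConfig",
    "CallResult",
    "chromosome_ratio",
    "build_reference",
    "z_score",
    "call_from_z",
    "classify",
]

HIGH_RISK = "high_risk"
LOW_RISK = "low_risk"

QC_PASS = "pass"
QC_LOW_FF = "low_ff_alert"
QC_INSUFFICIENT_READS = "insufficient_reads"


@dataclass(frozen=True)
class ReadCountProfile:
    """Per-chromosome unique-read counts for one sample."""

    sample_id: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ConfigurationError("read counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.counts)


def chromosome_ratio(profile: ReadCountProfile, chrom: str) -> float:
    """Fraction of the sample's unique reads mapping to ``chrom``."""
    if chrom not in profile.counts:
        raise ConfigurationError(f"chromosome {chrom!r} not in profile {profile.sample_id}")
    total = profile.total
    if total == 0:
        raise ConfigurationError(f"profile {profile.sample_id} has zero total reads")
    return profile.counts[chrom] / total


@dataclass(frozen=True)
class ReferencePanel:
    """Per-chromosome mean/SD of chromosomal ratios over euploid samples."""

    mu: Mapping[str, float]
    sigma: Mapping[str, float]
    n_reference: int

    def __post_init__(self) -> None:
        if self.n_reference < 2:
            raise DegeneratePanelError("reference panel needs >= 2 samples")
        for chrom, s in self.sigma.items():
            if s <= 0:
                raise DegeneratePanelError(f"zero/negative SD for {chrom}; degenerate panel")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.mu)


def build_reference(profiles: Sequence[ReadCountProfile]) -> ReferencePanel:
    """Sample mean and SD (n-1 denominator) of each chromosome's ratio.

    All profiles must share a chromosome set; identical ratios on any
    chromosome make the panel degenerate.
    """
    if len(profiles) < 2:
        raise DegeneratePanelError("need >= 2 euploid profiles to build a panel")
    chroms = profiles[0].chromosomes
    for p in profiles[1:]:
        if set(p.chromosomes) != set(chroms):
            raise ConfigurationError(f"profile {p.sample_id} has a different chromosome set")
    n = len(profiles)
    mu: dict[str, float] = {}
    sigma: dict[str, float] = {}
    for chrom in chroms:
        ratios = [chromosome_ratio(p, chrom) for p in profiles]
        m = sum(ratios) / n
        var = sum((r - m) ** 2 for r in ratios) / (n - 1)
        mu[chrom] = m
        sigma[chrom] = math.sqrt(var)
    panel = ReferencePanel(mu=mu, sigma=sigma, n_reference=n)
    return panel


def z_score(profile: ReadCountProfile, panel: ReferencePanel, chrom: str) -> float:
    """Standardized deviation of the sample's ratio from the panel: (r - mu)/sigma."""
    if chrom not in panel.mu:
        raise ConfigurationError(f"chromosome {chrom!r} not in reference panel")
    return (chromosome_ratio(profile, chrom) - panel.mu[chrom]) / panel.sigma[chrom]


def call_from_z(z: float, z_threshold: float = 3.0) -> str:
    """Decision rule: z greater than or equal to the threshold is high risk."""
    return HIGH_RISK if z >= z_threshold else LOW_RISK


@dataclass(frozen=True)
class CallerConfig:
    """Decision thresholds and QC gates.

    ``min_unique_reads`` follows the assay's 1.5 M unique-read floor;
    ``ff_alert_threshold`` is the 3.5% low-FF alert (strictly below alerts;
    exactly 3.5% passes). Scored chromosomes default to the common trisomies.
    """

    z_threshold: float = 3.0
    min_unique_reads: int = 1_500_000
    ff_alert_threshold: float = 0.035
    scored_chromosomes: tuple[str, ...] = ("chr13", "chr18", "chr21")


@dataclass(frozen=True)
class CallResult:
    """Outcome of classifying one sample."""

    sample_id: str
    z_values: Mapping[str, float]
    calls: Mapping[str, str]
    qc_status: str
    ff: float | None = None

    @property
    def high_risk_chromosomes(self) -> tuple[str, ...]:
        return tuple(c for c, call in self.calls.items() if call == HIGH_RISK)


def classify(
    profile: ReadCountProfile,
    panel: ReferencePanel,
    ff: float | None = None,
    config: CallerConfig | None = None,
) -> CallResult:
    """Apply QC gates then the z >= threshold rule per scored chromosome.

    QC order: insufficient reads, then low-FF alert (``ff`` of ``None`` skips
    the FF gate, e.g. when no estimate is available). z values are always
    computed; risk calls are only issued when QC passes.
    """
    config = config or CallerConfig()
    z_values = {c: z_score(profile, panel, c) for c in config.scored_chromosomes}

    if profile.total < config.min_unique_reads:
        qc = QC_INSUFFICIENT_READS
    elif ff is not None and ff < config.ff_alert_threshold:
        qc = QC_LOW_FF
    else:
        qc = QC_PASS

    calls: dict[str, str] = {}
    if qc == QC_PASS:
        calls = {c: call_from_z(z, config.z_threshold) for c, z in z_values.items()}
    return CallResult(
        sample_id=profile.sample_id, z_values=z_values, calls=calls, qc_status=qc, ff=ff
    )
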