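"""Fetal-fraction estimation from chrY representation, fetal-sex
confirmation, and sequencing-depth arithmetic.

For a male fetus the chrY read share rises linearly with fetal fraction, from
a small female background (mis-mapped / homologous reads) up to the share a
pure male genome would give. FF is the linear interpolation coordinate of the
observed chrY ratio between those two baselines. Female-fetus FF requires a
different (e.g. fragment-size or vendor-model) estimator and is out of scope;
the pipeline carries female FF as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

from .caller import ReadCountProfile, ReferencePanel, chromosome_ratio, z_score
from .errors import ConfigurationError

__all__ = [
    "YBaselines",
    "ff_from_chrY",
    "chrY_sex_check",
    "sequencing_depth",
    "MALE_CONFIRM_Z",
]

MALE_CONFIRM_Z = 15.0  # chrY z must exceed this (strictly) to confirm a male fetus


@dataclass(frozen=True)
class YBaselines:
    """chrY-ratio anchors of the linear FF estimator.

    ``female_background_ratio``: chrY read share in confirmed-female-fetus
    pregnancies (ff = 0). ``male_full_ratio``: chrY share a pure male genome
    would produce (ff = 1) under the configured chromosome weights.
    """

    female_background_ratio: float
    male_full_ratio: float

    def __post_init__(self) -> None:
        if not 0 <= self.female_background_ratio < self.male_full_ratio:
            raise ConfigurationError(
                "baselines must satisfy 0 <= female background < male full ratio"
            )

    @classmethod
    def from_sequencing_params(cls, seq) -> "YBaselines":
        """Derive both anchors from the simulator's own expected proportions."""
        from .synthetic import expected_proportions

        female = expected_proportions(seq, ff=0.0, fetal_sex="female")["chrY"]
        male_full = expected_proportions(seq, ff=1.0, fetal_sex="male")["chrY"]
        return cls(female_background_ratio=female, male_full_ratio=male_full)


def ff_from_chrY(profile: ReadCountProfile, baselines: YBaselines) -> float:
    """Estimate fetal fraction of a male-fetus sample from its chrY ratio.

    ff = (r_Y - background) / (male_full - background), clipped to [0, 1].
    """
    r_y = chromosome_ratio(profile, "chrY")
    ff = (r_y - baselines.female_background_ratio) / (
        baselines.male_full_ratio - baselines.female_background_ratio
    )
    return min(max(ff, 0.0), 1.0)


def chrY_sex_check(profile: ReadCountProfile, female_panel: ReferencePanel) -> float:
    """chrY z versus a female-fetus euploid panel; z > 15 confirms a male fetus."""
    return z_score(profile, female_panel, "chrY")


def is_male_confirmed(z: float) -> bool:
    """Strict z > 15 rule for male-fetus confirmation."""
    return z > MALE_CONFIRM_Z


def sequencing_depth(
    unique_reads: int,
    read_length_bp: int = 45,
    barcode_length_bp: int = 6,
    genome_length_bp: int = 3_000_000_000,
) -> float:
    """Fold coverage: unique_reads * (read_length - barcode) / genome_length.

    With the assay defaults (1.5 M reads, 45 bp single-end reads carrying a
    6 bp barcode, 3 Gb genome) this is 0.0195x.
    """
    if unique_reads < 0:
        raise ConfigurationError("unique_reads must be >= 0")
    if read_length_bp <= 0 or genome_length_bp <= 0:
        raise ConfigurationError("read and genome lengths must be positive")
    if barcode_length_bp < 0 or barcode_length_bp >= read_length_bp:
        raise ConfigurationError("barcode length must be in [0, read_length)")
    return unique_reads * (read_length_bp - barcode_length_bp) / genome_length_bp
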