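"""GRCh38 chromosome lengths and canonical chromosome ordering.

Per-chromosome read proportions are derived from assembly lengths
(renormalized over the relevant chromosome set); mappability weighting is
deliberately omitted but any module accepting ``chromosome_lengths`` can be
given an alternative weight vector.
"""

from __future__ import annotations

# Full GRCh38 primary-assembly sequence lengths (bp), chr1-22, X, Y.
GRCH38_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 248_956_422,
    "chr2": 242_193_529,
    "chr3": 198_295_559,
    "chr4": 190_214_555,
    "chr5": 181_538_259,
    "chr6": 170_805_979,
    "chr7": 159_345_973,
    "chr8": 145_138_636,
    "chr9": 138_394_717,
    "chr10": 133_797_422,
    "chr11": 135_086_622,
    "chr12": 133_275_309,
    "chr13": 114_364_328,
    "chr14": 107_043_718,
    "chr15": 101_991_189,
    "chr16": 90_338_345,
    "chr17": 83_257_441,
    "chr18": 80_373_285,
    "chr19": 58_617_616,
    "chr20": 64_444_167,
    "chr21": 46_709_983,
    "chr22": 50_818_468,
    "chrX": 156_040_895,
    "chrY": 57_227_415,
}

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("chrX", "chrY")

# Chromosome gaining a third fetal copy under each trisomic karyotype.
TRISOMY_CHROM: dict[str, str] = {"T21": "chr21", "T18": "chr18", "T13": "chr13"}
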