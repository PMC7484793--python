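"""Reference genome model: an ordered set of named chromosomes with lengths.

All genomic coordinates in this package are 0-based half-open.  The genome
model is what lets us place a segment, bin the genome for frequency tracks,
and relocate segments uniformly when building a permutation null.

Two ready-made models ship with the package:

* :func:`default_genome` — a small three-chromosome genome (100/80/60 Mb)
  used by the synthetic cohort generator; large enough for broad/focal
  length classes and Mb-scale binning, small enough that a 1,000-permutation
  null runs in seconds.
* :func:`hg38_genome` — the 24 nuclear chromosomes of GRCh38, for running
  the pipeline on real segment tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["GenomeModel", "default_genome", "hg38_genome"]


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with positive lengths (bp)."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValidationError("genome: names and lengths differ in count")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("genome: chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise ValidationError("genome: chromosome lengths must be > 0")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def length_of(self, name: str) -> int:
        try:
            return int(self.lengths[self._index[name]])
        except KeyError:
            raise ValidationError(f"genome: unknown chromosome {name!r}") from None

    def validate_interval(self, chromosome: str, start: int, end: int) -> None:
        if chromosome not in self:
            raise ValidationError(f"genome: unknown chromosome {chromosome!r}")
        if not (0 <= start < end <= self.length_of(chromosome)):
            raise ValidationError(
                f"interval {chromosome}:{start}-{end} outside chromosome bounds"
            )

    def chromosome_offsets(self) -> np.ndarray:
        """Cumulative start offset of each chromosome on a concatenated axis."""
        return np.concatenate([[0], np.cumsum(self.lengths)[:-1]]).astype(np.int64)


def default_genome() -> GenomeModel:
    """Desk-scale three-chromosome genome used by the simulator."""
    return GenomeModel(("chr1", "chr2", "chr3"), (100_000_000, 80_000_000, 60_000_000))


# GRCh38 primary-assembly chromosome lengths (bp).
_HG38 = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468, "chrX": 156_040_895, "chrY": 57_227_415,
}


def hg38_genome() -> GenomeModel:
    return GenomeModel(tuple(_HG38), tuple(_HG38.values()))
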