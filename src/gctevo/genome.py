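"""Scaled human genome model.

The package operates on a desk-scale genome that preserves the relative
chromosome and arm proportions of GRCh38: 22 autosomes split into p/q arms
at the centromere, chromosome X with its two pseudoautosomal regions (PAR1,
PAR2; baseline two copies in males) flanking the hemizygous non-PAR body,
and chromosome Y (baseline one copy).  The total autosomal length is
configurable; 3 Gb reproduces the human scale while tests use 30 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# GRCh38 chromosome lengths (Mb) and p-arm fraction of the chromosome.
# Acrocentric short arms (13-15, 21, 22) carry their small true fractions.
_CHROM_MB: dict[str, float] = {
    "1": 248.96, "2": 242.19, "3": 198.30, "4": 190.21, "5": 181.54,
    "6": 170.81, "7": 159.35, "8": 145.14, "9": 138.39, "10": 133.80,
    "11": 135.09, "12": 133.28, "13": 114.36, "14": 107.04, "15": 101.99,
    "16": 90.34, "17": 83.26, "18": 80.37, "19": 58.62, "20": 64.44,
    "21": 46.71, "22": 50.82, "X": 156.04, "Y": 57.23,
}

_P_FRACTION: dict[str, float] = {
    "1": 0.497, "2": 0.385, "3": 0.459, "4": 0.263, "5": 0.267,
    "6": 0.349, "7": 0.377, "8": 0.312, "9": 0.310, "10": 0.298,
    "11": 0.395, "12": 0.266, "13": 0.155, "14": 0.160, "15": 0.186,
    "16": 0.407, "17": 0.301, "18": 0.230, "19": 0.419, "20": 0.436,
    "21": 0.281, "22": 0.295, "X": 0.389, "Y": 0.182,
}

# X pseudoautosomal regions as fractions of chromosome X length
# (PAR1 = 2.78 Mb, PAR2 = 0.33 Mb of 156.04 Mb).
_PAR1_FRAC = 2.78 / 156.04
_PAR2_FRAC = 0.33 / 156.04

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))


@dataclass(frozen=True)
class Region:
    """Half-open genomic interval [start, end) with a baseline male copy number."""

    chrom: str
    name: str  # "p", "q", "PAR1", "nonPAR", "PAR2"
    start: int
    end: int
    normal_copies: int  # copies in a normal male cell

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Genome:
    """Scaled genome: chromosome sizes, arm boundaries, PAR annotation."""

    chrom_lengths: dict[str, int]
    regions: tuple[Region, ...] = field(repr=False)

    @property
    def autosome_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in AUTOSOMES)

    def chrom_regions(self, chrom: str) -> list[Region]:
        return [r for r in self.regions if r.chrom == chrom]

    def arm_bounds(self, chrom: str) -> dict[str, tuple[int, int]]:
        """p/q arm intervals for a chromosome (PARs fold into the enclosing arm)."""
        length = self.chrom_lengths[chrom]
        split = int(round(_P_FRACTION[chrom] * length))
        return {"p": (0, split), "q": (split, length)}

    def normal_copies(self, chrom: str, pos: int) -> int:
        """Male germline copy number at a position (2 autosome/PAR, 1 non-PAR X/Y)."""
        for r in self.chrom_regions(chrom):
            if r.start <= pos < r.end:
                return r.normal_copies
        raise ValueError(f"position {chrom}:{pos} outside genome model")


def build_genome(total_autosome_bp: int = 3_000_000_000) -> Genome:
    """Construct the scaled genome.

    Parameters
    ----------
    total_autosome_bp
        Combined length of the 22 autosomes after scaling; X and Y scale by
        the same factor.  Default 3 Gb (human scale); tests use 30 Mb.
    """
    auto_mb = sum(_CHROM_MB[c] for c in AUTOSOMES)
    scale = total_autosome_bp / (auto_mb * 1e6)
    lengths = {c: max(int(round(mb * 1e6 * scale)), 100) for c, mb in _CHROM_MB.items()}

    regions: list[Region] = []
    for c in AUTOSOMES:
        split = int(round(_P_FRACTION[c] * lengths[c]))
        regions.append(Region(c, "p", 0, split, 2))
        regions.append(Region(c, "q", split, lengths[c], 2))
    lx = lengths["X"]
    par1 = max(int(round(_PAR1_FRAC * lx)), 1)
    par2 = max(int(round(_PAR2_FRAC * lx)), 1)
    regions.append(Region("X", "PAR1", 0, par1, 2))
    regions.append(Region("X", "nonPAR", par1, lx - par2, 1))
    regions.append(Region("X", "PAR2", lx - par2, lx, 2))
    regions.append(Region("Y", "body", 0, lengths["Y"], 1))
    return Genome(chrom_lengths=lengths, regions=tuple(regions))


def arm_table(genome: Genome) -> "pandas.DataFrame":  # noqa: F821
    """Arm boundary table (chrom, arm, start, end) for all chromosomes."""
    import pandas as pd

    rows = []
    for chrom in list(AUTOSOMES) + ["X", "Y"]:
        for arm, (s, e) in genome.arm_bounds(chrom).items():
            rows.append({"chrom": chrom, "arm": arm, "start": s, "end": e})
    return pd.DataFrame(rows)
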