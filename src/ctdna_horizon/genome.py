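"""Genome model: chromosomes, bins, and the variant-site registry.

The genome is a coordinate scaffold, not a sequence: each registered site
carries its own reference base and trinucleotide context. Coordinates are
0-based half-open internally; VCF emission converts to 1-based.

The default synthetic genome is desk-scale (22 autosomes x 10 Mb) with a
proportionally scaled bin width; bin arithmetic is scale-free, so copy-number
results do not depend on the physical genome size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
PURINES = {"A", "G"}
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: bin width used with full-size (hg-scale) chromosomes
FULL_BIN_WIDTH = 5_000_000
#: default synthetic chromosome length and proportionally scaled bin width
SYNTH_CHROM_LENGTH = 10_000_000
SYNTH_BIN_WIDTH = 500_000


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in TRANSITIONS


def is_cpg_transition(ref: str, alt: str, context: str) -> bool:
    """True for C>T with following base G, or G>A with preceding base C.

    ``context`` is the 3-mer (previous, ref, next) on the reference strand.
    This is the classic CpG-deamination signature; such transitions are
    excluded from bespoke panels because they are the dominant artifact and
    CHIP-prone mutation class.
    """
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not match ref {ref!r}")
    if ref == "C" and alt == "T":
        return context[2] == "G"
    if ref == "G" and alt == "A":
        return context[0] == "C"
    return False


@dataclass(frozen=True)
class Site:
    """A registered substitution site: position, ref/alt and 3-mer context."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    context: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be one of {BASES}: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("alt equals ref")
        if len(self.context) != 3 or self.context[1] != self.ref:
            raise ValueError(f"context {self.context!r} middle base must equal ref")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


class GenomeModel:
    """Chromosome lengths, a bin tiling, and a registry of variant sites."""

    def __init__(
        self,
        chrom_lengths: dict[str, int],
        bin_width: int = FULL_BIN_WIDTH,
    ) -> None:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for chrom, length in chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        self.chrom_lengths = dict(chrom_lengths)
        self.bin_width = int(bin_width)
        self.sites: dict[tuple[str, int], Site] = {}

    @classmethod
    def synthetic(
        cls,
        n_chroms: int = 22,
        chrom_length: int = SYNTH_CHROM_LENGTH,
        bin_width: int = SYNTH_BIN_WIDTH,
    ) -> "GenomeModel":
        """Desk-scale autosomal genome: chr1..chr22, equal lengths."""
        lengths = {f"chr{i}": chrom_length for i in range(1, n_chroms + 1)}
        return cls(lengths, bin_width=bin_width)

    # -- sites ---------------------------------------------------------------

    def register(self, site: Site) -> Site:
        if site.chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {site.chrom}")
        if not 0 <= site.pos < self.chrom_lengths[site.chrom]:
            raise ValueError(f"position {site.pos} outside {site.chrom}")
        self.sites[site.key] = site
        return site

    def site(self, chrom: str, pos: int) -> Site:
        try:
            return self.sites[(chrom, pos)]
        except KeyError:
            raise KeyError(f"site {chrom}:{pos} not in registry") from None

    def random_site(self, rng: np.random.Generator, chrom: str | None = None) -> Site:
        """Draw a fresh site with random context; registers and returns it.

        Re-draws on position collisions so every registered site is unique.
        """
        chroms = sorted(self.chrom_lengths)
        for _ in range(1000):
            c = chrom if chrom is not None else chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(self.chrom_lengths[c]))
            if (c, pos) in self.sites:
                continue
            ref = BASES[rng.integers(4)]
            alt = BASES[rng.integers(4)]
            while alt == ref:
                alt = BASES[rng.integers(4)]
            context = BASES[rng.integers(4)] + ref + BASES[rng.integers(4)]
            return self.register(Site(c, pos, ref, alt, context))
        raise RuntimeError("could not find a free position (genome saturated?)")

    # -- bins ----------------------------------------------------------------

    def bins(self) -> pd.DataFrame:
        """Tile every autosome with fixed-width bins (last bin may be short)."""
        rows = []
        for chrom in sorted(self.chrom_lengths, key=_chrom_sort_key):
            length = self.chrom_lengths[chrom]
            for start in range(0, length, self.bin_width):
                rows.append((chrom, start, min(start + self.bin_width, length)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    @property
    def n_bins(self) -> int:
        return sum(
            -(-length // self.bin_width) for length in self.chrom_lengths.values()
        )


def _chrom_sort_key(chrom: str):
    name = chrom.removeprefix("chr")
    return (0, int(name)) if name.isdigit() else (1, name)
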