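"""Variant truth records.

A variant couples a genomic substitution with its *truth class* — how it
arose (germline, CHIP, somatic, artifact) — and the annotation flags the
bespoke-panel exclusion filters consume. The truth class is simulation
ground truth; no calling stage reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import Site, is_cpg_transition

TRUTH_CLASSES = ("germline", "chip", "somatic", "artifact")

#: user-settable annotation flags (cpg_transition is derived, never set)
FLAG_NAMES = (
    "in_repeat",
    "in_hard_align",
    "hard_to_amplify",
    "known_snp",
    "cpg_transition",
    "driver_hotspot",
    "truncating_in_tsg",
)


@dataclass(frozen=True)
class Variant:
    """A substitution with truth class, cell fraction and annotation flags.

    cell_fraction is the proportion of the originating cell population
    carrying the variant: germline uses allele dosage (0.5 het, 1.0 hom);
    CHIP is the heterozygous leukocyte-clone fraction in (0, 0.3]; somatic
    is the heterozygous tumor-cell fraction in (0, 1].
    """

    site: Site
    truth_class: str
    cell_fraction: float
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.truth_class not in TRUTH_CLASSES:
            raise ValueError(f"unknown truth class {self.truth_class!r}")
        cf = self.cell_fraction
        if self.truth_class == "germline" and cf not in (0.5, 1.0):
            raise ValueError(f"germline cell fraction must be 0.5 or 1.0, got {cf}")
        if self.truth_class == "chip" and not 0 < cf <= 0.3:
            raise ValueError(f"chip cell fraction must be in (0, 0.3], got {cf}")
        if self.truth_class == "somatic" and not 0 < cf <= 1.0:
            raise ValueError(f"somatic cell fraction must be in (0, 1], got {cf}")
        unknown = set(self.flags) - set(FLAG_NAMES)
        if unknown:
            raise ValueError(f"unknown flags {sorted(unknown)}")
        # cpg_transition is a function of (ref, alt, context), never an input
        derived = is_cpg_transition(self.site.ref, self.site.alt, self.site.context)
        flags = set(self.flags) - {"cpg_transition"}
        if derived:
            flags.add("cpg_transition")
        object.__setattr__(self, "flags", frozenset(flags))

    def has_flag(self, name: str) -> bool:
        return name in self.flags

    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def pos(self) -> int:
        return self.site.pos

    @property
    def ref(self) -> str:
        return self.site.ref

    @property
    def alt(self) -> str:
        return self.site.alt
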