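"""Targeted driver-gene panel assay.

A fixed multiplex panel of commonly mutated driver-gene regions (default
synthetic layout: 121 regions across 40 genes) screened by duplex calling.
A mutation counts toward positivity only if it is duplex-confirmed, absent
in the matched leukocytes, and classified as oncogenic — either a known
hotspot or a truncating variant in a tumor-suppressor gene. A sample is
positive when at least one retained mutation has two or more distinct
mutant molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .duplex import CallParams, MutationCall, call_sites
from .exceptions import OutOfPanelError
from .families import FamilyTable
from .genome import BASES, GenomeModel, Site
from .variants import Variant


@dataclass(frozen=True)
class PanelRegion:
    chrom: str
    start: int
    end: int  # half-open
    gene: str
    role: str  # "oncogene" | "tsg"

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class DriverAnnotation:
    """Panel regions, hotspot lookup, and the tumor-suppressor gene set."""

    def __init__(
        self,
        regions: list[PanelRegion],
        hotspots: dict[tuple[str, int, str], Site],
        tsg_genes: set[str],
    ) -> None:
        self.regions = list(regions)
        self.hotspots = dict(hotspots)
        self.tsg_genes = set(tsg_genes)
        for (chrom, pos, _alt), _site in self.hotspots.items():
            if self.region_at(chrom, pos) is None:
                raise ValueError(f"hotspot {chrom}:{pos} lies outside every region")

    @property
    def genes(self) -> set[str]:
        return {r.gene for r in self.regions}

    def region_at(self, chrom: str, pos: int) -> PanelRegion | None:
        for region in self.regions:
            if region.contains(chrom, pos):
                return region
        return None

    def hotspot_sites(self) -> list[Site]:
        return [self.hotspots[k] for k in sorted(self.hotspots)]

    def random_tsg_site(self, genome: GenomeModel, rng: np.random.Generator) -> Site:
        """A fresh site inside a random tumor-suppressor region."""
        tsg_regions = [r for r in self.regions if r.role == "tsg"]
        if not tsg_regions:
            raise ValueError("annotation has no tumor-suppressor regions")
        for _ in range(100):
            region = tsg_regions[rng.integers(len(tsg_regions))]
            pos = int(rng.integers(region.start, region.end))
            if (region.chrom, pos) not in genome.sites:
                ref = BASES[rng.integers(4)]
                alt = BASES[rng.integers(4)]
                while alt == ref:
                    alt = BASES[rng.integers(4)]
                ctx = BASES[rng.integers(4)] + ref + BASES[rng.integers(4)]
                return genome.register(Site(region.chrom, pos, ref, alt, ctx))
        raise RuntimeError("could not place a TSG site")

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "regions": [
                {"chrom": r.chrom, "start": r.start, "end": r.end,
                 "gene": r.gene, "role": r.role}
                for r in self.regions
            ],
            "hotspots": [
                {"chrom": s.chrom, "pos": s.pos, "ref": s.ref,
                 "alt": s.alt, "context": s.context}
                for s in self.hotspot_sites()
            ],
            "tsg_genes": sorted(self.tsg_genes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DriverAnnotation":
        regions = [PanelRegion(**r) for r in d["regions"]]
        hotspots = {}
        for h in d["hotspots"]:
            site = Site(h["chrom"], h["pos"], h["ref"], h["alt"], h["context"])
            hotspots[(site.chrom, site.pos, site.alt)] = site
        return cls(regions, hotspots, set(d["tsg_genes"]))

    def regions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.chrom, r.start, r.end, r.gene, r.role) for r in self.regions],
            columns=["chrom", "start", "end", "gene", "role"],
        )

    def hotspots_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.chrom, s.pos, s.ref, s.alt, s.context) for s in self.hotspot_sites()],
            columns=["chrom", "pos", "ref", "alt", "context"],
        )


#: canonical driver genes used to name the synthetic default panel
_ONCOGENES = [
    "KRAS", "PIK3CA", "BRAF", "NRAS", "EGFR", "ERBB2", "CTNNB1", "IDH1",
    "IDH2", "AKT1", "GNAS", "FGFR2", "FGFR3", "HRAS", "MET", "KIT",
    "PDGFRA", "ALK", "RET", "MYC", "CDK4", "MDM2",
]
_TSGS = [
    "TP53", "APC", "PTEN", "RB1", "SMAD4", "CDKN2A", "VHL", "NF1", "STK11",
    "BRCA1", "BRCA2", "ATM", "ARID1A", "FBXW7", "KEAP1", "SMARCA4", "BAP1", "MLH1",
]


def default_driver_panel(
    genome: GenomeModel,
    n_regions: int = 121,
    region_length: int = 150,
    seed: int = 0,
) -> DriverAnnotation:
    """Synthetic default panel emulating the assay's structure.

    121 amplicon-sized regions distributed over 40 driver genes (22 oncogenes
    and 18 tumor suppressors, named after canonical drivers); each oncogene
    region carries 1-2 hotspot sites. The real panel's coordinates are not
    public; only the layout and the calling logic matter here.
    """
    rng = np.random.default_rng(seed)
    genes = _ONCOGENES + _TSGS  # 40 genes
    roles = ["oncogene"] * len(_ONCOGENES) + ["tsg"] * len(_TSGS)
    chroms = sorted(genome.chrom_lengths)
    regions: list[PanelRegion] = []
    hotspots: dict[tuple[str, int, str], Site] = {}
    # every gene gets >= 1 region; remaining regions spread round-robin
    gene_idx = list(range(len(genes))) * ((n_regions // len(genes)) + 1)
    for k in range(n_regions):
        gi = gene_idx[k]
        gene, role = genes[gi], roles[gi]
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, genome.chrom_lengths[chrom] - region_length))
        region = PanelRegion(chrom, start, start + region_length, gene, role)
        regions.append(region)
        if role == "oncogene":
            for _ in range(int(rng.integers(1, 3))):
                pos = int(rng.integers(region.start, region.end))
                if (chrom, pos) in genome.sites:
                    continue
                ref = BASES[rng.integers(4)]
                alt = BASES[rng.integers(4)]
                while alt == ref:
                    alt = BASES[rng.integers(4)]
                ctx = BASES[rng.integers(4)] + ref + BASES[rng.integers(4)]
                site = genome.register(Site(chrom, pos, ref, alt, ctx))
                hotspots[(chrom, pos, alt)] = site
    return DriverAnnotation(regions, hotspots, set(_TSGS))


# ---------------------------------------------------------------------------
# classification and the panel assay
# ---------------------------------------------------------------------------


def classify_oncogenic(variant: Variant, annotation: DriverAnnotation) -> bool:
    """Oncogenic = hotspot match, or truncating variant in a TSG region."""
    region = annotation.region_at(variant.chrom, variant.pos)
    if region is None:
        raise OutOfPanelError(
            f"variant {variant.chrom}:{variant.pos} lies outside the panel"
        )
    if (variant.chrom, variant.pos, variant.alt) in annotation.hotspots:
        return True
    return (
        variant.has_flag("truncating_in_tsg")
        and region.role == "tsg"
        and region.gene in annotation.tsg_genes
    )


@dataclass(frozen=True)
class QuerySite:
    """A site interrogated by the targeted assay."""

    site: Site
    truncating_in_tsg: bool = False


@dataclass(frozen=True)
class TargetedParams:
    call: CallParams = field(default_factory=CallParams)
    min_mutant_molecules: int = 2  # "two or more distinct mutant molecules"
    per_mutation: bool = True  # threshold applies per mutation, not summed


@dataclass
class TargetedResult:
    participant_id: str
    timepoint: str
    calls: list[MutationCall]  # retained: oncogenic, not normal-excluded
    positive: bool
    mean_maf: float | None  # over detected retained mutations
    n_detected: int
    warnings: list[str] = field(default_factory=list)

    @property
    def detected_mafs(self) -> list[float]:
        return [
            c.maf
            for c in self.calls
            if c.maf is not None and c.mutant_molecules >= 1
        ]


def run_targeted_panel(
    plasma: FamilyTable,
    leukocyte: FamilyTable | None,
    annotation: DriverAnnotation,
    query_sites: list[QuerySite],
    participant_id: str = "",
    timepoint: str = "early",
    params: TargetedParams = TargetedParams(),
) -> TargetedResult:
    """Run the targeted panel on one sample.

    Every query site is called against the matched leukocytes; calls are
    retained if oncogenic and not excluded by the matched normal. Positivity:
    any retained mutation with >= min_mutant_molecules distinct duplex-mutant
    molecules (or, with per_mutation=False, the summed count).
    """
    warnings: list[str] = []
    if leukocyte is None or len(leukocyte) == 0:
        leukocyte = None
        warnings.append(
            "no leukocyte data: matched-normal exclusion unavailable, "
            "calls flagged insufficient_normal"
        )
    for q in query_sites:
        if annotation.region_at(q.site.chrom, q.site.pos) is None:
            raise OutOfPanelError(
                f"query site {q.site.chrom}:{q.site.pos} outside the panel"
            )
    calls = call_sites(
        plasma, leukocyte,
        [(q.site.chrom, q.site.pos, q.site.ref, q.site.alt) for q in query_sites],
        params.call,
    )
    retained: list[MutationCall] = []
    for q, call in zip(query_sites, calls):
        s = q.site
        probe = Variant(
            s, "somatic", 1.0,
            frozenset({"truncating_in_tsg"}) if q.truncating_in_tsg else frozenset(),
        )
        if not classify_oncogenic(probe, annotation):
            continue
        if call.matched_normal_excluded:
            continue
        retained.append(call)

    detected = [
        c for c in retained if c.mutant_molecules >= params.min_mutant_molecules
    ]
    if params.per_mutation:
        positive = len(detected) > 0
    else:
        positive = (
            sum(c.mutant_molecules for c in retained) >= params.min_mutant_molecules
        )
    mafs = [c.maf for c in detected if c.maf is not None]
    mean_maf = float(np.mean(mafs)) if mafs else None
    return TargetedResult(
        participant_id=participant_id,
        timepoint=timepoint,
        calls=retained,
        positive=positive,
        mean_maf=mean_maf,
        n_detected=len(detected),
        warnings=warnings,
    )
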