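"""Tumor-naive personalized mutation panel design and calling.

From high-depth plasma WGS pileups (matched against leukocyte WGS), a
count-based somatic caller proposes candidates, an exclusion cascade removes
error-prone site classes (repeats, hard alignments, hard-to-amplify regions,
SNP positions, CpG transitions), the top candidates by plasma VAF (at most
96) form the panel, and each panel mutation is validated by duplex
sequencing — present on both strands in plasma, absent in deep leukocyte
duplex data, absent in an unrelated control's plasma — before it is scored
(*bona fide*). A sample is positive on the personalized panel when a single
bona-fide mutant molecule is observed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .duplex import CallParams, MutationCall, call_sites
from .exceptions import ConfigurationError
from .families import FamilyTable
from .genome import _chrom_sort_key, is_cpg_transition
from .variants import Variant

FILTER_NAMES = ("repeat", "hard_align", "hard_to_amplify", "snp", "cpg_transition")


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


class IntervalMask:
    """Sorted, merged half-open intervals per chromosome with point lookup."""

    def __init__(self, intervals: list[tuple[str, int, int]]) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivals in by_chrom.items():
            merged: list[tuple[int, int]] = []
            for start, end in sorted(ivals):
                if merged and start <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], end))
                else:
                    merged.append((start, end))
            self._starts[chrom] = [s for s, _ in merged]
            self._ends[chrom] = [e for _, e in merged]

    def __contains__(self, key: tuple[str, int]) -> bool:
        chrom, pos = key
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos) - 1
        return i >= 0 and pos < self._ends[chrom][i]

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._starts, key=_chrom_sort_key):
            out.extend(
                (chrom, s, e)
                for s, e in zip(self._starts[chrom], self._ends[chrom])
            )
        return out


@dataclass
class MaskSet:
    """The exclusion-filter masks: repeat/hard-align BEDs plus an SNP set."""

    repeat: IntervalMask = field(default_factory=lambda: IntervalMask([]))
    hard_align: IntervalMask = field(default_factory=lambda: IntervalMask([]))
    snp: set = field(default_factory=set)  # {(chrom, pos)}


def masks_from_variants(
    variants: list[Variant], pad: int = 25
) -> MaskSet:
    """Derive masks consistent with variant annotation flags.

    Flagged sites become (padded) mask intervals; the resulting MaskSet and
    the flags agree by construction, as they would when flags are annotated
    *from* the masks in a real pipeline.
    """
    repeat, hard = [], []
    snp: set = set()
    for v in variants:
        if v.has_flag("in_repeat"):
            repeat.append((v.chrom, max(0, v.pos - pad), v.pos + pad + 1))
        if v.has_flag("in_hard_align"):
            hard.append((v.chrom, max(0, v.pos - pad), v.pos + pad + 1))
        if v.has_flag("known_snp") or v.truth_class == "germline":
            snp.add((v.chrom, v.pos))  # germline variants are polymorphisms
    return MaskSet(IntervalMask(repeat), IntervalMask(hard), snp)


# ---------------------------------------------------------------------------
# candidate calling and filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateParams:
    """Thresholds of the count-based plasma-vs-normal somatic caller."""

    min_vaf: float = 0.005  # the assay is applicable above 0.5% MAF
    min_alt: int = 4
    min_normal_depth: int = 15
    max_normal_alt: int = 0  # any leukocyte support excludes the site


@dataclass
class PanelCandidate:
    """One candidate mutation with its plasma VAF and filter verdicts."""

    pileup: "object"  # PileupSite
    plasma_vaf: float
    verdicts: dict = field(default_factory=dict)  # filter name -> bool (pass)
    bona_fide: bool = False
    evaluable: bool = True
    evidence: dict = field(default_factory=dict)

    @property
    def site(self):
        return self.pileup.site

    @property
    def passed_all(self) -> bool:
        return all(self.verdicts.get(f, True) for f in FILTER_NAMES)


def call_wgs_candidates(
    pileups: list,
    params: CandidateParams = CandidateParams(),
) -> list[PanelCandidate]:
    """Count-based somatic candidate caller on plasma-vs-normal pileups.

    Retains sites with plasma VAF >= min_vaf, plasma alt reads >= min_alt,
    normal depth >= min_normal_depth and no alt reads in the normal.
    """
    out = []
    for p in pileups:
        if p.plasma_depth == 0:
            continue
        vaf = p.plasma_alt / p.plasma_depth
        if (
            vaf >= params.min_vaf
            and p.plasma_alt >= params.min_alt
            and p.normal_depth >= params.min_normal_depth
            and p.normal_alt <= params.max_normal_alt
        ):
            out.append(PanelCandidate(pileup=p, plasma_vaf=vaf))
    return out


def apply_exclusion_filters(
    candidates: list[PanelCandidate], masks: MaskSet
) -> list[PanelCandidate]:
    """Apply the five exclusion filters; returns only fully passing candidates.

    Every input candidate gets a complete verdict vector (also on the
    rejected ones, for reporting). Repeat / hard-align / SNP membership is
    tested against the masks *or* the pileup's annotation flags (either
    evidence source excludes); hard-to-amplify comes from the flag; the CpG
    transition verdict is computed from the site context, never from a mask.
    """
    retained = []
    for cand in candidates:
        site = cand.site
        flags = getattr(cand.pileup, "flags", frozenset())
        key = (site.chrom, site.pos)
        cand.verdicts = {
            "repeat": not (key in masks.repeat or "in_repeat" in flags),
            "hard_align": not (key in masks.hard_align or "in_hard_align" in flags),
            "hard_to_amplify": "hard_to_amplify" not in flags,
            "snp": not (key in masks.snp or "known_snp" in flags),
            "cpg_transition": not is_cpg_transition(site.ref, site.alt, site.context),
        }
        if cand.passed_all:
            retained.append(cand)
    return retained


# ---------------------------------------------------------------------------
# panel selection and validation
# ---------------------------------------------------------------------------

MAX_PANEL = 96


@dataclass
class PanelDesign:
    """An ordered personalized panel (<= 96 candidates) for one participant."""

    participant_id: str
    candidates: list[PanelCandidate] = field(default_factory=list)

    @property
    def bona_fide(self) -> list[PanelCandidate]:
        return [c for c in self.candidates if c.bona_fide]

    @property
    def is_empty(self) -> bool:
        return not self.candidates

    def verdicts_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            row = {
                "chrom": c.site.chrom, "pos": c.site.pos,
                "ref": c.site.ref, "alt": c.site.alt,
                "context": c.site.context,
                "plasma_vaf": c.plasma_vaf, "bona_fide": c.bona_fide,
                "evaluable": c.evaluable,
            }
            row.update({f"pass_{k}": v for k, v in c.verdicts.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def select_panel(
    filtered: list[PanelCandidate],
    max_panel: int = MAX_PANEL,
    participant_id: str = "",
) -> PanelDesign:
    """Top candidates by plasma VAF (ties: lower genomic coordinate first)."""
    ranked = sorted(
        filtered,
        key=lambda c: (
            -c.plasma_vaf,
            _chrom_sort_key(c.site.chrom),
            c.site.pos,
        ),
    )
    return PanelDesign(participant_id, ranked[:max_panel])


def validate_bona_fide(
    design: PanelDesign,
    plasma: FamilyTable,
    leukocyte: FamilyTable,
    unrelated_control: FamilyTable,
    params: CallParams = CallParams(),
) -> PanelDesign:
    """Duplex validation of every panel candidate.

    bona fide requires >= 1 duplex-confirmed mutant molecule in the
    participant's plasma, zero mutant molecules in deep leukocyte duplex
    data, and zero in the unrelated control's plasma. Candidates without
    coverage in any validation library are flagged unevaluable.
    """
    sites = [
        (c.site.chrom, c.site.pos, c.site.ref, c.site.alt)
        for c in design.candidates
    ]
    p_calls = call_sites(plasma, None, sites, params)
    l_calls = call_sites(leukocyte, None, sites, params)
    c_calls = call_sites(unrelated_control, None, sites, params)
    for cand, p_call, l_call, c_call in zip(
        design.candidates, p_calls, l_calls, c_calls
    ):
        cand.evidence = {
            "plasma_mutant": p_call.mutant_molecules,
            "plasma_evaluable": p_call.evaluable_molecules,
            "leukocyte_mutant": l_call.mutant_molecules,
            "leukocyte_evaluable": l_call.evaluable_molecules,
            "control_mutant": c_call.mutant_molecules,
            "control_evaluable": c_call.evaluable_molecules,
        }
        if (
            p_call.evaluable_molecules == 0
            or l_call.evaluable_molecules == 0
            or c_call.evaluable_molecules == 0
        ):
            cand.evaluable = False
            cand.bona_fide = False
            continue
        cand.bona_fide = (
            p_call.mutant_molecules >= 1
            and l_call.mutant_molecules == 0
            and c_call.mutant_molecules == 0
        )
    return design


# ---------------------------------------------------------------------------
# personalized panel calling
# ---------------------------------------------------------------------------


@dataclass
class PersonalizedResult:
    participant_id: str
    timepoint: str
    calls: list[MutationCall]
    positive: bool
    n_detected: int
    n_assessed: int
    mean_maf: float | None
    feasible: bool = True

    @property
    def detected_fraction(self) -> float | None:
        if self.n_assessed == 0:
            return None
        return self.n_detected / self.n_assessed


def infeasible_result(participant_id: str, timepoint: str) -> PersonalizedResult:
    """Outcome for participants whose MAF is too low to design a panel."""
    return PersonalizedResult(
        participant_id, timepoint, [], False, 0, 0, None, feasible=False
    )


def call_personalized_panel(
    design: PanelDesign,
    sample: FamilyTable,
    normal: FamilyTable | None = None,
    timepoint: str = "early",
    params: CallParams = CallParams(),
    min_mutant_molecules: int = 1,  # a single mutant molecule is a positive
    maf_over: str = "detected",
) -> PersonalizedResult:
    """Score the bona-fide panel mutations in one sample.

    Only bona-fide mutations are scored; the sample is positive if any has
    >= min_mutant_molecules (default one) duplex mutant molecule. The MAF
    aggregate is the mean over detected mutations by default (maf_over=
    "detected"); maf_over="all" averages over every bona-fide mutation.
    """
    bona = design.bona_fide
    if not bona:
        raise ConfigurationError(
            f"empty bona-fide set for {design.participant_id}: "
            "personalized calling infeasible"
        )
    if maf_over not in ("detected", "all"):
        raise ConfigurationError(f"maf_over must be 'detected' or 'all'")
    calls = call_sites(
        sample, normal,
        [(c.site.chrom, c.site.pos, c.site.ref, c.site.alt) for c in bona],
        params,
    )
    detected = [c for c in calls if c.mutant_molecules >= min_mutant_molecules]
    pool = detected if maf_over == "detected" else calls
    mafs = [c.maf for c in pool if c.maf is not None]
    mean_maf = float(np.mean(mafs)) if mafs else None
    return PersonalizedResult(
        participant_id=design.participant_id,
        timepoint=timepoint,
        calls=calls,
        positive=len(detected) > 0,
        n_detected=len(detected),
        n_assessed=len(calls),
        mean_maf=mean_maf,
    )
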