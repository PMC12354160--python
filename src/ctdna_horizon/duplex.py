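"""Duplex consensus calling.

Collapses read families into per-strand consensuses, per-molecule duplex
calls, and per-site mutation calls. A molecule only counts as mutant when
the Watson and Crick strands independently agree on the same non-reference
base — the concordance requirement that suppresses single-strand errors
(sequencing miscalls, strand-specific damage) by orders of magnitude.
Mutant molecules also observed in the matched normal (leukocytes) are
flagged for exclusion: the germline / clonal-hematopoiesis signature.

Per-molecule statuses partition every UID covering a site:
mutant + reference + discordant + single_strand_only + uncalled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ContractError
from .families import BASE_INDEX, BASE_ORDER, DuplexFamily, FamilyTable

# molecule status codes (vectorised representation)
UNCALLED, REFERENCE, MUTANT, DISCORDANT, SINGLE_STRAND = 0, 1, 2, 3, 4
STATUS_NAMES = {
    UNCALLED: "uncalled",
    REFERENCE: "duplex_reference",
    MUTANT: "duplex_mutant",
    DISCORDANT: "discordant",
    SINGLE_STRAND: "single_strand_only",
}

DEFAULT_MIN_READS_PER_STRAND = 2
DEFAULT_MIN_AGREEMENT = 0.9
DEFAULT_MIN_NORMAL_TEMPLATES = 1000
DEFAULT_MIN_EVALUABLE = 100


@dataclass(frozen=True)
class CallParams:
    """Thresholds of the duplex caller (conventional defaults, all exposed)."""

    min_reads_per_strand: int = DEFAULT_MIN_READS_PER_STRAND
    min_agreement: float = DEFAULT_MIN_AGREEMENT
    min_normal_templates: int = DEFAULT_MIN_NORMAL_TEMPLATES
    min_evaluable: int = DEFAULT_MIN_EVALUABLE


@dataclass(frozen=True)
class StrandConsensus:
    """Per-strand plurality call for one molecule at one site."""

    uid: int
    site: tuple[str, int]
    base: str | None  # None == "ambiguous"
    supporting_reads: int
    agreement: float

    @property
    def is_ambiguous(self) -> bool:
        return self.base is None


@dataclass(frozen=True)
class MoleculeCall:
    uid: int
    site: tuple[str, int]
    status: str
    alt: str | None = None  # set for duplex_mutant


@dataclass
class MutationCall:
    """Per-site, per-alt mutation call with matched-normal accounting."""

    chrom: str
    pos: int
    ref: str
    alt: str
    mutant_molecules: int
    evaluable_molecules: int
    normal_mutant: int = 0
    normal_evaluable: int = 0
    flags: set = field(default_factory=set)

    @property
    def maf(self) -> float | None:
        if self.evaluable_molecules == 0:
            return None
        return self.mutant_molecules / self.evaluable_molecules

    @property
    def matched_normal_excluded(self) -> bool:
        return "matched_normal" in self.flags

    def to_row(self) -> dict:
        return {
            "chrom": self.chrom,
            "pos": self.pos,
            "ref": self.ref,
            "alt": self.alt,
            "mutant_molecules": self.mutant_molecules,
            "evaluable": self.evaluable_molecules,
            "maf": self.maf if self.maf is not None else float("nan"),
            "normal_mutant": self.normal_mutant,
            "normal_evaluable": self.normal_evaluable,
            "flags": ";".join(sorted(self.flags)) or ".",
        }


# ---------------------------------------------------------------------------
# vectorised kernels
# ---------------------------------------------------------------------------


def consensus_kernel(
    counts: np.ndarray,
    min_reads_per_strand: int = DEFAULT_MIN_READS_PER_STRAND,
    min_agreement: float = DEFAULT_MIN_AGREEMENT,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Plurality consensus per row of an (n, 5) base-count matrix.

    Returns (base_idx, ok, agreement, n_reads). A consensus exists (ok)
    when the strand has >= min_reads_per_strand reads, the plurality base is
    unique among A,C,G,T, and its agreement fraction (over all reads, N
    included) meets min_agreement.
    """
    counts = np.asarray(counts)
    acgt = counts[:, :4]
    n_reads = counts.sum(axis=1)
    base_idx = acgt.argmax(axis=1)
    top = acgt[np.arange(len(acgt)), base_idx]
    tie = (acgt == top[:, None]).sum(axis=1) > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        agreement = np.where(n_reads > 0, top / np.maximum(n_reads, 1), 0.0)
    ok = (
        (n_reads >= min_reads_per_strand)
        & (top > 0)
        & ~tie
        & (agreement >= min_agreement)
    )
    return base_idx, ok, agreement, n_reads


def molecule_status_kernel(
    watson: np.ndarray,
    crick: np.ndarray,
    ref_idx: np.ndarray | int,
    params: CallParams = CallParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Duplex molecule statuses for paired (n, 5) strand count matrices.

    Returns (status codes, mutant base index; -1 where not mutant).
    """
    wb, wok, _, _ = consensus_kernel(
        watson, params.min_reads_per_strand, params.min_agreement
    )
    cb, cok, _, _ = consensus_kernel(
        crick, params.min_reads_per_strand, params.min_agreement
    )
    ref_idx = np.broadcast_to(np.asarray(ref_idx), wb.shape)
    status = np.full(len(wb), UNCALLED, dtype=np.int8)
    both = wok & cok
    one = wok ^ cok
    status[one] = SINGLE_STRAND
    concord = both & (wb == cb)
    status[both & ~(wb == cb)] = DISCORDANT
    status[concord & (wb == ref_idx)] = REFERENCE
    is_mut = concord & (wb != ref_idx)
    status[is_mut] = MUTANT
    mut_base = np.where(is_mut, wb, -1)
    return status, mut_base


# ---------------------------------------------------------------------------
# object-level operations
# ---------------------------------------------------------------------------


def _counts_vector(reads) -> np.ndarray:
    v = np.zeros(5, dtype=np.int64)
    for base, n in reads.items():
        v[BASE_INDEX[base]] += n
    return v


def strand_consensus(
    family: DuplexFamily,
    site: tuple[str, int],
    min_reads_per_strand: int = DEFAULT_MIN_READS_PER_STRAND,
    min_agreement: float = DEFAULT_MIN_AGREEMENT,
) -> tuple[StrandConsensus, StrandConsensus]:
    """Watson and Crick plurality consensuses for one family at one site."""
    if not family.covers(*site):
        raise KeyError(f"family {family.uid} does not cover site {site}")
    out = []
    for strand in ("W", "C"):
        counts = _counts_vector(family.reads(strand, *site))[None, :]
        base_idx, ok, agreement, n_reads = consensus_kernel(
            counts, min_reads_per_strand, min_agreement
        )
        top = counts[0, :4].max()
        out.append(
            StrandConsensus(
                uid=family.uid,
                site=site,
                base=BASE_ORDER[base_idx[0]] if ok[0] else None,
                supporting_reads=int(top if ok[0] else 0),
                agreement=float(agreement[0]),
            )
        )
    return out[0], out[1]


def call_molecule(
    watson: StrandConsensus, crick: StrandConsensus, ref: str
) -> MoleculeCall:
    """Combine two strand consensuses into a duplex molecule call."""
    if watson.uid != crick.uid or watson.site != crick.site:
        raise ContractError(
            f"strand consensuses disagree on UID/site: "
            f"{watson.uid}@{watson.site} vs {crick.uid}@{crick.site}"
        )
    uid, site = watson.uid, watson.site
    if watson.is_ambiguous and crick.is_ambiguous:
        return MoleculeCall(uid, site, "uncalled")
    if watson.is_ambiguous or crick.is_ambiguous:
        return MoleculeCall(uid, site, "single_strand_only")
    if watson.base != crick.base:
        return MoleculeCall(uid, site, "discordant")
    if watson.base == ref:
        return MoleculeCall(uid, site, "duplex_reference")
    return MoleculeCall(uid, site, "duplex_mutant", alt=watson.base)


# ---------------------------------------------------------------------------
# site-level calling
# ---------------------------------------------------------------------------


def _site_status_counts(
    table: FamilyTable, chrom: str, pos: int, ref: str, params: CallParams
) -> tuple[np.ndarray, np.ndarray]:
    sub = table.restrict(chrom, pos)
    if len(sub) == 0:
        return np.empty(0, dtype=np.int8), np.empty(0, dtype=np.int64)
    status, mut_base = molecule_status_kernel(
        sub.watson, sub.crick, BASE_INDEX[ref], params
    )
    return status, mut_base


def call_site(
    plasma: FamilyTable,
    normal: FamilyTable | None,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    params: CallParams = CallParams(),
) -> MutationCall:
    """Per-site mutation call: distinct mutant molecules, MAF, normal status.

    Each row of the family table is one molecule at one site (UIDs are
    unique per template), so distinct mutant molecules = mutant rows.
    """
    alt_idx = BASE_INDEX[alt]
    status, mut_base = _site_status_counts(plasma, chrom, pos, ref, params)
    mutant = int(((status == MUTANT) & (mut_base == alt_idx)).sum())
    evaluable = int((status == REFERENCE).sum() + (status == MUTANT).sum())
    call = MutationCall(chrom, pos, ref, alt, mutant, evaluable)
    if evaluable == 0:
        call.flags.add("no_evaluable")
    elif evaluable < params.min_evaluable:
        call.flags.add("low_evaluable")
    if normal is not None and len(normal):
        nstatus, nmut_base = _site_status_counts(normal, chrom, pos, ref, params)
        call.normal_mutant = int(((nstatus == MUTANT) & (nmut_base == alt_idx)).sum())
        call.normal_evaluable = int(
            (nstatus == REFERENCE).sum() + (nstatus == MUTANT).sum()
        )
        if call.normal_mutant >= 1:
            call.flags.add("matched_normal")
        if call.normal_evaluable < params.min_normal_templates:
            call.flags.add("insufficient_normal")
    else:
        call.flags.add("insufficient_normal")
    return call


def _aggregate_counts(
    table: FamilyTable | None,
    pk_index: dict[tuple[str, int], int],
    ref_idx_by_pk: np.ndarray,
    params: CallParams,
) -> tuple[np.ndarray, np.ndarray]:
    """(evaluable per position, mutant per position x base) for one table."""
    n_pk = len(pk_index)
    evaluable = np.zeros(n_pk, dtype=np.int64)
    mutant = np.zeros((n_pk, 4), dtype=np.int64)
    if table is None or len(table) == 0:
        return evaluable, mutant
    row_pk = np.array(
        [pk_index.get((c, p), -1) for c, p in zip(table.chrom, table.pos)],
        dtype=np.int64,
    )
    keep = row_pk >= 0
    if not keep.any():
        return evaluable, mutant
    row_pk = row_pk[keep]
    status, mut_base = molecule_status_kernel(
        table.watson[keep], table.crick[keep], ref_idx_by_pk[row_pk], params
    )
    ev = (status == REFERENCE) | (status == MUTANT)
    evaluable += np.bincount(row_pk[ev], minlength=n_pk)
    is_mut = status == MUTANT
    if is_mut.any():
        flat = row_pk[is_mut] * 4 + mut_base[is_mut]
        mutant += np.bincount(flat, minlength=n_pk * 4).reshape(n_pk, 4)
    return evaluable, mutant


def call_sites(
    plasma: FamilyTable,
    normal: FamilyTable | None,
    sites: list[tuple[str, int, str, str]],
    params: CallParams = CallParams(),
) -> list[MutationCall]:
    """Batch form of call_site over (chrom, pos, ref, alt) tuples.

    One vectorised pass over each family table; multi-allelic positions share
    denominators (each alt is evaluated against the same evaluable pool).
    """
    pk_index: dict[tuple[str, int], int] = {}
    refs: list[str] = []
    for chrom, pos, ref, _alt in sites:
        key = (chrom, pos)
        if key not in pk_index:
            pk_index[key] = len(refs)
            refs.append(ref)
        elif refs[pk_index[key]] != ref:
            raise ContractError(f"conflicting reference bases at {chrom}:{pos}")
    ref_idx_by_pk = np.array([BASE_INDEX[r] for r in refs], dtype=np.int64)
    p_ev, p_mut = _aggregate_counts(plasma, pk_index, ref_idx_by_pk, params)
    has_normal = normal is not None and len(normal) > 0
    n_ev, n_mut = _aggregate_counts(
        normal if has_normal else None, pk_index, ref_idx_by_pk, params
    )
    out = []
    for chrom, pos, ref, alt in sites:
        i = pk_index[(chrom, pos)]
        a = BASE_INDEX[alt]
        call = MutationCall(
            chrom, pos, ref, alt, int(p_mut[i, a]), int(p_ev[i])
        )
        if call.evaluable_molecules == 0:
            call.flags.add("no_evaluable")
        elif call.evaluable_molecules < params.min_evaluable:
            call.flags.add("low_evaluable")
        if has_normal:
            call.normal_mutant = int(n_mut[i, a])
            call.normal_evaluable = int(n_ev[i])
            if call.normal_mutant >= 1:
                call.flags.add("matched_normal")
            if call.normal_evaluable < params.min_normal_templates:
                call.flags.add("insufficient_normal")
        else:
            call.flags.add("insufficient_normal")
        out.append(call)
    return out


def molecule_status_table(
    table: FamilyTable, ref_by_site: dict[tuple[str, int], str],
    params: CallParams = CallParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Statuses for every row of a table, using per-site reference bases."""
    if len(table) == 0:
        return np.empty(0, dtype=np.int8), np.empty(0, dtype=np.int64)
    ref_idx = np.array(
        [BASE_INDEX[ref_by_site[(c, p)]] for c, p in zip(table.chrom, table.pos)],
        dtype=np.int64,
    )
    return molecule_status_kernel(table.watson, table.crick, ref_idx, params)


def background_rate(
    tables: list[FamilyTable],
    ref_by_site: dict[tuple[str, int], str],
    params: CallParams = CallParams(),
) -> float:
    """Observed duplex-mutant fraction across control libraries.

    mutant molecules / evaluable molecules, pooled over all sites and
    samples; the empirical error floor of the duplex assay.
    """
    mutant = evaluable = 0
    for table in tables:
        status, _ = molecule_status_table(table, ref_by_site, params)
        mutant += int((status == MUTANT).sum())
        evaluable += int(((status == MUTANT) | (status == REFERENCE)).sum())
    if evaluable == 0:
        raise ContractError("no evaluable molecules in control data")
    return mutant / evaluable


def single_strand_background_rate(
    tables: list[FamilyTable],
    ref_by_site: dict[tuple[str, int], str],
    params: CallParams = CallParams(),
) -> float:
    """Background of naive single-strand calling on the same data.

    A molecule is scored mutant when *any* strand consensus is non-reference;
    evaluable = molecules with at least one strand consensus. The contrast
    with :func:`background_rate` quantifies duplex error suppression.
    """
    mutant = evaluable = 0
    for table in tables:
        if len(table) == 0:
            continue
        ref_idx = np.array(
            [BASE_INDEX[ref_by_site[(c, p)]] for c, p in zip(table.chrom, table.pos)],
            dtype=np.int64,
        )
        wb, wok, _, _ = consensus_kernel(
            table.watson, params.min_reads_per_strand, params.min_agreement
        )
        cb, cok, _, _ = consensus_kernel(
            table.crick, params.min_reads_per_strand, params.min_agreement
        )
        any_cons = wok | cok
        nonref = (wok & (wb != ref_idx)) | (cok & (cb != ref_idx))
        evaluable += int(any_cons.sum())
        mutant += int(nonref.sum())
    if evaluable == 0:
        raise ContractError("no evaluable molecules in control data")
    return mutant / evaluable


def calls_to_frame(calls: list[MutationCall]) -> pd.DataFrame:
    cols = [
        "chrom", "pos", "ref", "alt", "mutant_molecules", "evaluable",
        "maf", "normal_mutant", "normal_evaluable", "flags",
    ]
    return pd.DataFrame([c.to_row() for c in calls], columns=cols)
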