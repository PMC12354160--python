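"""Cohort serialization: VCF for variants, BED for masks, TSV for duplex
families / bin counts / pileups, YAML for truth and scenario config.

Coordinates are 0-based internally and 1-based on VCF emission. A cohort
written and re-read round-trips to equal truth structures, and a fixed seed
yields byte-identical files.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import pysam
import yaml

from .bespoke import MaskSet, masks_from_variants
from .exceptions import ParseError
from .families import FamilyTable, TSV_COLUMNS
from .genome import GenomeModel, Site, _chrom_sort_key
from .simulate import (
    Cohort,
    ParticipantTruth,
    PileupSite,
    ScenarioConfig,
    TumorProfile,
)
from .targeted import DriverAnnotation
from .variants import Variant

_VCF_INFO_LINES = [
    ('INFO', 'TRUTH_CLASS', '1', 'String', 'Simulation truth class'),
    ('INFO', 'CELL_FRAC', '1', 'String', 'Cell fraction of originating population'),
    ('INFO', 'FLAGS', '.', 'String', 'Annotation flags'),
    ('INFO', 'CONTEXT', '1', 'String', 'Trinucleotide context (ref strand)'),
]


def _vcf_header(genome: GenomeModel) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in sorted(genome.chrom_lengths, key=_chrom_sort_key):
        header.contigs.add(chrom, length=genome.chrom_lengths[chrom])
    for _, name, number, vtype, desc in _VCF_INFO_LINES:
        header.info.add(name, number, vtype, desc)
    return header


def write_variants_vcf(variants: list[Variant], genome: GenomeModel,
                       path: str | os.PathLike) -> None:
    header = _vcf_header(genome)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: (_chrom_sort_key(v.chrom), v.pos)):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos, stop=v.pos + 1,
                alleles=(v.ref, v.alt),
            )
            rec.info["TRUTH_CLASS"] = v.truth_class
            rec.info["CELL_FRAC"] = repr(v.cell_fraction)
            flags = sorted(v.flags)
            if flags:
                rec.info["FLAGS"] = ",".join(flags)
            rec.info["CONTEXT"] = v.site.context
            vcf.write(rec)


def read_variants_vcf(path: str | os.PathLike,
                      genome: GenomeModel | None = None) -> list[Variant]:
    out = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as e:
        raise ParseError(f"{path}: {e}") from e
    with vcf:
        for rec in vcf:
            flags_val = rec.info.get("FLAGS", ())
            flags = frozenset(flags_val) if flags_val else frozenset()
            site = Site(
                rec.chrom, rec.start, rec.ref, rec.alts[0],
                rec.info["CONTEXT"],
            )
            if genome is not None:
                site = genome.register(site)
            out.append(
                Variant(
                    site,
                    rec.info["TRUTH_CLASS"],
                    float(rec.info["CELL_FRAC"]),
                    flags,
                )
            )
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

_FAMILY_DTYPES = {"uid": "int64", "chrom": "string", "pos": "int64",
                  "strand": "string", "base": "string", "reads": "int64"}
_BIN_COLUMNS = ["chrom", "start", "end", "count"]
_PILEUP_COLUMNS = ["chrom", "pos", "ref", "alt", "context", "plasma_depth",
                   "plasma_alt", "normal_depth", "normal_alt", "flags"]


def _read_tsv(path: str | os.PathLike, columns: list[str],
              int_columns: list[str]) -> pd.DataFrame:
    """Strict TSV reader: enforces the schema, names file and line on error."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as e:  # pandas raises several parser error types
        raise ParseError(f"{path}: {e}") from e
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: line 1: missing columns {missing}")
    for col in int_columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ParseError(
                f"{path}: line {line}: invalid value {df.loc[bad.idxmax(), col]!r} "
                f"in column {col!r}"
            )
        df[col] = converted.astype("int64")
    return df


def write_families_tsv(table: FamilyTable, path: str | os.PathLike) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_families_tsv(path: str | os.PathLike) -> FamilyTable:
    df = _read_tsv(path, TSV_COLUMNS, ["uid", "pos", "reads"])
    if (df["reads"] < 0).any():
        raise ParseError(f"{path}: negative read counts")
    return FamilyTable.from_frame(df)


def write_bins_tsv(bins: pd.DataFrame, path: str | os.PathLike) -> None:
    bins[_BIN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bins_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return _read_tsv(path, _BIN_COLUMNS, ["start", "end", "count"])


def write_pileups_tsv(pileups: list[PileupSite], path: str | os.PathLike) -> None:
    rows = [
        {
            "chrom": p.site.chrom, "pos": p.site.pos, "ref": p.site.ref,
            "alt": p.site.alt, "context": p.site.context,
            "plasma_depth": p.plasma_depth, "plasma_alt": p.plasma_alt,
            "normal_depth": p.normal_depth, "normal_alt": p.normal_alt,
            "flags": ";".join(sorted(p.flags)) or ".",
        }
        for p in pileups
    ]
    pd.DataFrame(rows, columns=_PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pileups_tsv(path: str | os.PathLike) -> list[PileupSite]:
    df = _read_tsv(
        path, _PILEUP_COLUMNS,
        ["pos", "plasma_depth", "plasma_alt", "normal_depth", "normal_alt"],
    )
    out = []
    for _, row in df.iterrows():
        flags = frozenset() if row["flags"] in (".", "") else frozenset(
            row["flags"].split(";")
        )
        out.append(
            PileupSite(
                Site(row["chrom"], int(row["pos"]), row["ref"], row["alt"],
                     row["context"]),
                int(row["plasma_depth"]), int(row["plasma_alt"]),
                int(row["normal_depth"]), int(row["normal_alt"]), flags,
            )
        )
    return out


def write_bed(intervals: list[tuple[str, int, int]],
              path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {i}: expected >= 3 BED columns")
            try:
                out.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as e:
                raise ParseError(f"{path}: line {i}: {e}") from e
    return out


# ---------------------------------------------------------------------------
# whole-cohort round trip
# ---------------------------------------------------------------------------


def _participant_to_dict(p: ParticipantTruth) -> dict:
    return {
        "pid": p.pid,
        "is_case": p.is_case,
        "tumor": p.tumor.to_dict(),
        "segments": [list(s) for s in p.segments],
        "days_to_dx": dict(p.days_to_dx),
        "very_early_available": p.very_early_available,
    }


def write_cohort(cohort: Cohort, directory: str | os.PathLike) -> list[str]:
    """Serialize a cohort; returns the file manifest (relative paths)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def emit(rel: str) -> Path:
        manifest.append(rel)
        path = directory / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        return path

    with open(emit("config.yaml"), "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)
    with open(emit("panel.yaml"), "w") as fh:
        yaml.safe_dump(cohort.annotation.to_dict(), fh, sort_keys=True)
    truth = {
        "participants": [_participant_to_dict(p) for p in cohort.participants],
        "unrelated_control": (
            _participant_to_dict(cohort.unrelated_control)
            if cohort.unrelated_control else None
        ),
    }
    with open(emit("truth.yaml"), "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)

    write_variants_vcf(cohort.artifact_sites, cohort.genome, emit("artifacts.vcf"))
    for p in cohort.participants + (
        [cohort.unrelated_control] if cohort.unrelated_control else []
    ):
        write_variants_vcf(
            p.all_variants(), cohort.genome, emit(f"participants/{p.pid}.vcf")
        )

    all_variants = [v for p in cohort.participants for v in p.all_variants()]
    masks = masks_from_variants(all_variants)
    write_bed(masks.repeat.intervals(), emit("masks/repeat.bed"))
    write_bed(masks.hard_align.intervals(), emit("masks/hard_align.bed"))
    write_bed(
        sorted((c, p, p + 1) for c, p in masks.snp), emit("masks/snp.bed")
    )
    return manifest


def _participant_from_dict(d: dict, variants: list[Variant],
                           artifacts: list[Variant]) -> ParticipantTruth:
    by_class: dict[str, list[Variant]] = {"germline": [], "chip": [], "somatic": []}
    for v in variants:
        by_class.setdefault(v.truth_class, []).append(v)
    return ParticipantTruth(
        pid=d["pid"],
        is_case=d["is_case"],
        tumor=TumorProfile.from_dict(d["tumor"]),
        tumor_mutations=by_class["somatic"],
        germline=by_class["germline"],
        chip=by_class["chip"],
        artifacts=artifacts,
        segments=[tuple(s) for s in d["segments"]],
        days_to_dx=dict(d["days_to_dx"]),
        very_early_available=d["very_early_available"],
    )


def read_cohort(directory: str | os.PathLike) -> Cohort:
    directory = Path(directory)
    try:
        with open(directory / "config.yaml") as fh:
            config = ScenarioConfig.from_dict(yaml.safe_load(fh))
        with open(directory / "panel.yaml") as fh:
            annotation = DriverAnnotation.from_dict(yaml.safe_load(fh))
        with open(directory / "truth.yaml") as fh:
            truth = yaml.safe_load(fh)
    except FileNotFoundError as e:
        raise ParseError(f"{directory}: not a cohort directory ({e})") from e
    genome = GenomeModel.synthetic(
        config.n_chroms, config.chrom_length, config.bin_width
    )
    for site in annotation.hotspot_sites():
        genome.register(site)
    artifacts = read_variants_vcf(directory / "artifacts.vcf", genome)
    participants = []
    for d in truth["participants"]:
        variants = read_variants_vcf(
            directory / "participants" / f"{d['pid']}.vcf", genome
        )
        participants.append(_participant_from_dict(d, variants, artifacts))
    unrelated = None
    if truth.get("unrelated_control"):
        d = truth["unrelated_control"]
        variants = read_variants_vcf(
            directory / "participants" / f"{d['pid']}.vcf", genome
        )
        unrelated = _participant_from_dict(d, variants, artifacts)
    return Cohort(
        genome=genome,
        participants=participants,
        config=config,
        annotation=annotation,
        unrelated_control=unrelated,
        artifact_sites=artifacts,
    )


def cohort_masks(cohort: Cohort, participant: ParticipantTruth) -> MaskSet:
    """Masks for one participant's panel design (flag-consistent)."""
    return masks_from_variants(participant.all_variants())
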