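"""Synthetic cfDNA cohort generator.

Emulates the data a tumor-naive plasma MCED workflow consumes:

* participant ground truth — germline variants, CHIP clones shared between
  leukocytes and plasma, clonal somatic tumor mutations whose plasma allele
  fraction is tumor_fraction x cell_fraction / 2, and segment-level
  aneuploidy consistent with that tumor fraction;
* duplex read families (Watson/Crick strands with strand-asymmetric error
  modes) sampled per site from a configured number of template molecules;
* low-depth WGS bin-level read counts for aneuploidy screening;
* high-depth WGS pileups (plasma vs matched leukocytes) for bespoke panel
  design, including plasma-only library artifacts and cohort-recurrent
  artifact sites that only the unrelated-control check can reject.

Everything is driven by one master seed; per-participant / per-stage streams
are derived by stable hashing so outputs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .exceptions import ConfigurationError
from .families import BASE_INDEX, FamilyTable
from .genome import GenomeModel, Site
from .variants import FLAG_NAMES, Variant

TIMEPOINTS = ("early", "very_early")
COMPARTMENTS = ("plasma", "leukocyte")

#: default per-flag probabilities for randomly annotated (passenger) sites
DEFAULT_FLAG_PROBS = {
    "in_repeat": 0.01,
    "in_hard_align": 0.01,
    "hard_to_amplify": 0.01,
    "known_snp": 0.01,
}


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorModel:
    """Error structure of simulated duplex libraries.

    seq_error
        per-read probability of a miscalled base (independent across reads).
    ss_damage
        per-template probability of a lesion on one randomly chosen strand
        (e.g. cytosine deamination); propagates to every read of that strand.
    ds_artifact
        per-template probability of a pre-ligation event altering *both*
        strands — indistinguishable from a true mutation by design.
    strand_loss
        probability that one strand of a template yields no reads at all.
    reads_per_strand
        Poisson mean of the per-strand replicate read count.
    """

    seq_error: float = 1e-3
    ss_damage: float = 1e-5
    ds_artifact: float = 1e-7
    strand_loss: float = 0.1
    reads_per_strand: float = 4.0

    def __post_init__(self) -> None:
        for name in ("seq_error", "ss_damage", "ds_artifact", "strand_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.reads_per_strand <= 0:
            raise ConfigurationError(
                f"reads_per_strand must be positive, got {self.reads_per_strand}"
            )

    def to_dict(self) -> dict:
        return {
            "seq_error": self.seq_error,
            "ss_damage": self.ss_damage,
            "ds_artifact": self.ds_artifact,
            "strand_loss": self.strand_loss,
            "reads_per_strand": self.reads_per_strand,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorModel":
        return cls(**d)


@dataclass(frozen=True)
class TumorProfile:
    """Per-case tumor parameters.

    early_tumor_fraction is the Early-timepoint ctDNA tumor fraction t; a
    clonal heterozygous mutation then has expected plasma MAF t/2.
    fold_decrease scales t down at the Very Early timepoint (~3 years
    earlier); None emulates a case whose Very Early sample carries no
    detectable ctDNA at all.
    """

    early_tumor_fraction: float = 0.0
    fold_decrease: float | None = 20.0
    n_driver_mutations: int = 0
    n_passenger_mutations: int = 40
    aneuploid_fraction: float = 0.0
    cell_fraction: float = 1.0
    cancer_type: str = "Unknown"
    stage: str = "Unknown"
    days_to_dx_early: int | None = None
    days_to_dx_very_early: int | None = None
    very_early_available: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.early_tumor_fraction <= 1.0:
            raise ConfigurationError(
                f"early_tumor_fraction must be in [0, 1], got {self.early_tumor_fraction}"
            )
        if self.fold_decrease is not None and self.fold_decrease <= 1.0:
            raise ConfigurationError(
                f"fold_decrease must exceed 1, got {self.fold_decrease}"
            )
        if not 0.0 < self.cell_fraction <= 1.0:
            raise ConfigurationError(
                f"cell_fraction must be in (0, 1], got {self.cell_fraction}"
            )
        if not 0.0 <= self.aneuploid_fraction < 1.0:
            raise ConfigurationError(
                f"aneuploid_fraction must be in [0, 1), got {self.aneuploid_fraction}"
            )

    @classmethod
    def from_early_maf(cls, early_maf: float, **kwargs) -> "TumorProfile":
        """Specify the tumor in expected-MAF terms (MAF = t/2 for clonal het)."""
        return cls(early_tumor_fraction=2.0 * early_maf, **kwargs)

    @property
    def very_early_tumor_fraction(self) -> float:
        if self.fold_decrease is None:
            return 0.0
        return self.early_tumor_fraction / self.fold_decrease

    def to_dict(self) -> dict:
        return {
            "early_tumor_fraction": self.early_tumor_fraction,
            "fold_decrease": self.fold_decrease,
            "n_driver_mutations": self.n_driver_mutations,
            "n_passenger_mutations": self.n_passenger_mutations,
            "aneuploid_fraction": self.aneuploid_fraction,
            "cell_fraction": self.cell_fraction,
            "cancer_type": self.cancer_type,
            "stage": self.stage,
            "days_to_dx_early": self.days_to_dx_early,
            "days_to_dx_very_early": self.days_to_dx_very_early,
            "very_early_available": self.very_early_available,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TumorProfile":
        return cls(**d)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full cohort scenario: study size, assay scale, error model, tumors."""

    n_cases: int = 26
    n_controls: int = 26
    seed: int = 0
    plasma_templates: int = 1500  # template molecules per site per ~5 mL plasma
    leukocyte_templates: int = 6000
    error_model: ErrorModel = field(default_factory=ErrorModel)
    shedders: tuple[TumorProfile, ...] = ()
    # truth structure
    n_germline: int = 20
    chip_mean: float = 2.0
    chip_cell_fraction_range: tuple[float, float] = (0.02, 0.25)
    chip_hotspot_prob: float = 0.25
    n_recurrent_artifacts: int = 5
    flag_probs: dict = field(default_factory=lambda: dict(DEFAULT_FLAG_PROBS))
    # genome scale
    n_chroms: int = 22
    chrom_length: int = 10_000_000
    bin_width: int = 500_000
    # WGS / bin-count scales
    plasma_wgs_depth: float = 80.0
    normal_wgs_depth: float = 30.0
    mean_reads_per_bin: float = 50_000.0
    nb_size: float = 2e5

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigurationError("n_cases/n_controls must be non-negative")
        if len(self.shedders) > self.n_cases:
            raise ConfigurationError(
                f"shedders ({len(self.shedders)}) exceed n_cases ({self.n_cases})"
            )
        for name in ("plasma_templates", "leukocyte_templates", "n_germline"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.nb_size <= 0 or self.mean_reads_per_bin <= 0:
            raise ConfigurationError("mean_reads_per_bin and nb_size must be positive")

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_cases", "n_controls", "seed", "plasma_templates",
                "leukocyte_templates", "n_germline", "chip_mean",
                "chip_hotspot_prob", "n_recurrent_artifacts", "n_chroms",
                "chrom_length", "bin_width", "plasma_wgs_depth",
                "normal_wgs_depth", "mean_reads_per_bin", "nb_size",
            )
        }
        d["chip_cell_fraction_range"] = list(self.chip_cell_fraction_range)
        d["flag_probs"] = dict(self.flag_probs)
        d["error_model"] = self.error_model.to_dict()
        d["shedders"] = [s.to_dict() for s in self.shedders]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "error_model" in d:
            d["error_model"] = ErrorModel.from_dict(d["error_model"])
        if "shedders" in d:
            d["shedders"] = tuple(TumorProfile.from_dict(s) for s in d["shedders"])
        if "chip_cell_fraction_range" in d:
            d["chip_cell_fraction_range"] = tuple(d["chip_cell_fraction_range"])
        return cls(**d)


# ---------------------------------------------------------------------------
# participant truth and cohort containers
# ---------------------------------------------------------------------------


@dataclass
class ParticipantTruth:
    """Ground truth for one participant (never read by calling stages)."""

    pid: str
    is_case: bool
    tumor: TumorProfile
    tumor_mutations: list[Variant] = field(default_factory=list)
    germline: list[Variant] = field(default_factory=list)
    chip: list[Variant] = field(default_factory=list)
    artifacts: list[Variant] = field(default_factory=list)  # cohort-recurrent
    segments: list[tuple[str, int, int, int]] = field(default_factory=list)
    days_to_dx: dict = field(default_factory=dict)
    very_early_available: bool = True

    def __post_init__(self) -> None:
        if not self.is_case and (self.tumor_mutations or self.segments):
            raise ConfigurationError(
                f"control {self.pid} carries tumor mutations or aneuploid segments"
            )

    def tumor_fraction(self, timepoint: str) -> float:
        _check_timepoint(timepoint)
        if timepoint == "early":
            return self.tumor.early_tumor_fraction
        return self.tumor.very_early_tumor_fraction

    def all_variants(self) -> list[Variant]:
        return self.germline + self.chip + self.tumor_mutations

    def expected_allele_fraction(
        self, variant: Variant, timepoint: str, compartment: str
    ) -> float:
        """Expected allele fraction of one variant in one library."""
        _check_compartment(compartment)
        cls_, cf = variant.truth_class, variant.cell_fraction
        if cls_ == "germline":
            return cf  # dosage convention: 0.5 het, 1.0 hom
        if cls_ == "chip":
            return cf / 2.0
        if cls_ == "somatic":
            if compartment != "plasma":
                return 0.0
            return self.tumor_fraction(timepoint) * cf / 2.0
        if cls_ == "artifact":
            # recurrent cfDNA artifact: plasma libraries only
            return cf / 2.0 if compartment == "plasma" else 0.0
        raise ValueError(cls_)


@dataclass
class Cohort:
    """A simulated study: genome, annotation, participants, shared truth."""

    genome: GenomeModel
    participants: list[ParticipantTruth]
    config: ScenarioConfig
    annotation: "object" = None  # DriverAnnotation; typed loosely to avoid cycle
    unrelated_control: ParticipantTruth | None = None
    artifact_sites: list[Variant] = field(default_factory=list)

    @property
    def cases(self) -> list[ParticipantTruth]:
        return [p for p in self.participants if p.is_case]

    @property
    def controls(self) -> list[ParticipantTruth]:
        return [p for p in self.participants if not p.is_case]

    def participant(self, pid: str) -> ParticipantTruth:
        for p in self.participants:
            if p.pid == pid:
                return p
        if self.unrelated_control is not None and self.unrelated_control.pid == pid:
            return self.unrelated_control
        raise KeyError(f"no participant {pid}")


def _check_timepoint(timepoint: str) -> None:
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"timepoint must be one of {TIMEPOINTS}, got {timepoint!r}")


def _check_compartment(compartment: str) -> None:
    if compartment not in COMPARTMENTS:
        raise ValueError(
            f"compartment must be one of {COMPARTMENTS}, got {compartment!r}"
        )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _draw_flags(rng: np.random.Generator, flag_probs: dict) -> frozenset:
    flags = {name for name, p in flag_probs.items() if rng.random() < p}
    unknown = flags - set(FLAG_NAMES)
    if unknown:
        raise ConfigurationError(f"flag_probs has unknown flags {sorted(unknown)}")
    return frozenset(flags)


def _draw_germline(
    rng: np.random.Generator, genome: GenomeModel, n: int, flag_probs: dict
) -> list[Variant]:
    out = []
    for _ in range(n):
        site = genome.random_site(rng)
        cf = 1.0 if rng.random() < 0.2 else 0.5
        flags = _draw_flags(rng, flag_probs) | {"known_snp"}  # germline = SNP
        out.append(Variant(site, "germline", cf, flags))
    return out


def _fresh_hotspot(
    rng: np.random.Generator, annotation, used: set
) -> "Site":
    hotspots = annotation.hotspot_sites()
    order = rng.permutation(len(hotspots))
    for i in order:
        if hotspots[i].key not in used:
            return hotspots[i]
    raise ConfigurationError("hotspot registry exhausted for this participant")


def _draw_chip(
    rng: np.random.Generator,
    genome: GenomeModel,
    config: ScenarioConfig,
    annotation,
    used: set,
) -> list[Variant]:
    out = []
    lo, hi = config.chip_cell_fraction_range
    for _ in range(int(rng.poisson(config.chip_mean))):
        cf = float(rng.uniform(lo, hi))
        if annotation is not None and rng.random() < config.chip_hotspot_prob:
            # CHIP clone at an oncogenic hotspot: only the matched-leukocyte
            # comparison can stop it from being called a tumor mutation
            site = _fresh_hotspot(rng, annotation, used)
            out.append(Variant(site, "chip", cf, frozenset({"driver_hotspot"})))
        else:
            site = genome.random_site(rng)
            out.append(Variant(site, "chip", cf, _draw_flags(rng, config.flag_probs)))
        used.add(out[-1].site.key)
    return out


def _draw_tumor_mutations(
    rng: np.random.Generator,
    genome: GenomeModel,
    profile: TumorProfile,
    flag_probs: dict,
    annotation,
    used: set,
) -> list[Variant]:
    out = []
    for _ in range(profile.n_driver_mutations):
        if annotation is None:
            raise ConfigurationError(
                "n_driver_mutations > 0 requires a driver annotation"
            )
        if rng.random() < 0.7:
            site = _fresh_hotspot(rng, annotation, used)
            flags = frozenset({"driver_hotspot"})
        else:
            site = annotation.random_tsg_site(genome, rng)
            flags = frozenset({"truncating_in_tsg"})
        used.add(site.key)
        out.append(Variant(site, "somatic", profile.cell_fraction, flags))
    for _ in range(profile.n_passenger_mutations):
        site = genome.random_site(rng)
        out.append(
            Variant(site, "somatic", profile.cell_fraction, _draw_flags(rng, flag_probs))
        )
    return out


def _draw_segments(
    rng: np.random.Generator, genome: GenomeModel, fraction: float
) -> list[tuple[str, int, int, int]]:
    """Whole/half-chromosome gains and losses covering ~`fraction` of genome."""
    if fraction <= 0:
        return []
    chroms = sorted(genome.chrom_lengths)
    order = rng.permutation(len(chroms))
    total = sum(genome.chrom_lengths.values())
    target = fraction * total
    covered = 0.0
    segments: list[tuple[str, int, int, int]] = []
    copy_cycle = [3, 1, 4, 1, 3]  # mix of gains and losses
    for i, idx in enumerate(order):
        if covered >= target:
            break
        chrom = chroms[idx]
        length = genome.chrom_lengths[chrom]
        cn = copy_cycle[i % len(copy_cycle)]
        if target - covered < 0.75 * length:
            end = max(genome.bin_width, int(target - covered))
            end = min(end, length)
        else:
            end = length
        segments.append((chrom, 0, end, cn))
        covered += end
    return segments


def _draw_artifact_sites(
    rng: np.random.Generator, genome: GenomeModel, n: int
) -> list[Variant]:
    """Cohort-recurrent plasma artifact sites (shared by every participant)."""
    out = []
    for _ in range(n):
        site = genome.random_site(rng)
        cf = float(rng.uniform(0.004, 0.02))  # plasma AF cf/2: 0.002 - 0.01
        out.append(Variant(site, "artifact", cf))
    return out


def _simulate_participant(
    pid: str,
    is_case: bool,
    profile: TumorProfile,
    config: ScenarioConfig,
    genome: GenomeModel,
    annotation,
    artifacts: list[Variant],
) -> ParticipantTruth:
    rng = np.random.default_rng(derive_seed(config.seed, pid, "truth"))
    germline = _draw_germline(rng, genome, config.n_germline, config.flag_probs)
    used = {v.site.key for v in germline}
    chip = _draw_chip(rng, genome, config, annotation, used)
    tumor_mutations: list[Variant] = []
    segments: list[tuple[str, int, int, int]] = []
    days: dict = {}
    if is_case:
        tumor_mutations = _draw_tumor_mutations(
            rng, genome, profile, config.flag_probs, annotation, used
        )
        segments = _draw_segments(rng, genome, profile.aneuploid_fraction)
        days["early"] = (
            profile.days_to_dx_early
            if profile.days_to_dx_early is not None
            else int(rng.integers(10, 115))
        )
        days["very_early"] = (
            profile.days_to_dx_very_early
            if profile.days_to_dx_very_early is not None
            else int(rng.integers(1100, 1275))
        )
    return ParticipantTruth(
        pid=pid,
        is_case=is_case,
        tumor=profile,
        tumor_mutations=tumor_mutations,
        germline=germline,
        chip=chip,
        artifacts=list(artifacts),
        segments=segments,
        days_to_dx=days,
        very_early_available=profile.very_early_available if is_case else True,
    )


def simulate_cohort(config: ScenarioConfig, annotation=None) -> Cohort:
    """Generate a full cohort of ParticipantTruth records.

    Cases beyond the configured shedder profiles are non-shedding (tumor
    fraction 0, so nothing reaches the plasma) but still carry >= 1 somatic
    mutation, as real cases would. Controls carry only germline and CHIP.
    A dedicated unrelated control (outside the cohort) is generated for
    bona-fide validation.
    """
    if config.n_cases < 1:
        raise ConfigurationError("n_cases must be >= 1")
    genome = GenomeModel.synthetic(
        config.n_chroms, config.chrom_length, config.bin_width
    )
    if annotation is None:
        from .targeted import default_driver_panel

        annotation = default_driver_panel(
            genome, seed=derive_seed(config.seed, "panel")
        )
    art_rng = np.random.default_rng(derive_seed(config.seed, "artifacts"))
    artifacts = _draw_artifact_sites(art_rng, genome, config.n_recurrent_artifacts)

    nonshedder = TumorProfile(
        early_tumor_fraction=0.0, n_driver_mutations=1, n_passenger_mutations=30
    )
    participants = []
    for i in range(config.n_cases):
        profile = config.shedders[i] if i < len(config.shedders) else nonshedder
        participants.append(
            _simulate_participant(
                f"P{i + 1:03d}", True, profile, config, genome, annotation, artifacts
            )
        )
    for j in range(config.n_controls):
        participants.append(
            _simulate_participant(
                f"C{j + 1:03d}",
                False,
                TumorProfile(),
                config,
                genome,
                annotation,
                artifacts,
            )
        )
    unrelated = _simulate_participant(
        "UNRELATED", False, TumorProfile(), config, genome, annotation, artifacts
    )
    return Cohort(
        genome=genome,
        participants=participants,
        config=config,
        annotation=annotation,
        unrelated_control=unrelated,
        artifact_sites=artifacts,
    )


# ---------------------------------------------------------------------------
# duplex family sampling
# ---------------------------------------------------------------------------


def _other_base(rng: np.random.Generator, base_idx: np.ndarray) -> np.ndarray:
    """A uniformly random base different from base_idx (indices 0-3)."""
    return (base_idx + rng.integers(1, 4, size=len(base_idx))) % 4


def _strand_counts(
    rng: np.random.Generator,
    template_base: np.ndarray,
    lost: np.ndarray,
    error: ErrorModel,
) -> np.ndarray:
    """Read base counts (n, 5) for one strand given its template base."""
    n = len(template_base)
    n_reads = rng.poisson(error.reads_per_strand, size=n)
    n_reads[lost] = 0
    n_err = rng.binomial(n_reads, error.seq_error)
    counts = np.zeros((n, 5), dtype=np.int32)
    rows = np.arange(n)
    counts[rows, template_base] += (n_reads - n_err).astype(np.int32)
    with_err = n_err > 0
    if with_err.any():
        split = rng.multinomial(n_err[with_err], [1 / 3] * 3)
        err_bases = (template_base[with_err, None] + np.array([1, 2, 3])) % 4
        np.add.at(counts, (rows[with_err, None], err_bases), split.astype(np.int32))
    return counts


def _simulate_family_counts(
    rng: np.random.Generator,
    af: np.ndarray,
    ref_idx: np.ndarray,
    alt_idx: np.ndarray,
    error: ErrorModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate Watson/Crick base counts for n independent template molecules.

    Truth assignment first (binomial in af), then double-strand artifacts,
    then single-strand damage, strand loss, replicate reads and per-read
    sequencing errors — mirroring how a real library acquires each error class.
    """
    n = len(af)
    mutant = rng.random(n) < af
    watson_base = np.where(mutant, alt_idx, ref_idx).astype(np.int64)
    # double-strand artifact: both strands altered, indistinguishable from truth
    ds = (rng.random(n) < error.ds_artifact) & ~mutant
    if ds.any():
        watson_base[ds] = _other_base(rng, ref_idx[ds])
    crick_base = watson_base.copy()
    # single-strand damage: one randomly chosen strand per affected template
    ssd = rng.random(n) < error.ss_damage
    if ssd.any():
        on_watson = rng.random(ssd.sum()) < 0.5
        idx = np.flatnonzero(ssd)
        w_idx, c_idx = idx[on_watson], idx[~on_watson]
        watson_base[w_idx] = _other_base(rng, watson_base[w_idx])
        crick_base[c_idx] = _other_base(rng, crick_base[c_idx])
    lost_w = rng.random(n) < error.strand_loss
    lost_c = rng.random(n) < error.strand_loss
    watson = _strand_counts(rng, watson_base, lost_w, error)
    crick = _strand_counts(rng, crick_base, lost_c, error)
    return watson, crick


def sample_duplex_families(
    truth: ParticipantTruth,
    sites: list[Site],
    timepoint: str,
    compartment: str,
    n_templates: int,
    error: ErrorModel,
    seed: int,
    uid_start: int = 0,
    genome: GenomeModel | None = None,
) -> FamilyTable:
    """Sample duplex read families at the given sites for one library.

    Per site, the count of truly mutant templates is Binomial(n_templates,
    expected allele fraction of the site's variant in this compartment and
    timepoint); error processes are layered on afterwards per the ErrorModel.
    When a genome is given, sites must belong to its registry.
    """
    _check_timepoint(timepoint)
    _check_compartment(compartment)
    if genome is not None:
        for s in sites:
            if s.key not in genome.sites:
                raise KeyError(f"site {s.chrom}:{s.pos} not in genome registry")
    rng = np.random.default_rng(seed)
    n_sites = len(sites)
    if n_sites == 0 or n_templates == 0:
        return FamilyTable.empty()

    by_key: dict[tuple[str, int], float] = {}
    for v in truth.all_variants() + truth.artifacts:
        af = truth.expected_allele_fraction(v, timepoint, compartment)
        if af > 0:
            by_key[v.site.key] = by_key.get(v.site.key, 0.0) + af

    af_site = np.array([min(by_key.get(s.key, 0.0), 1.0) for s in sites])
    ref_site = np.array([BASE_INDEX[s.ref] for s in sites], dtype=np.int64)
    alt_site = np.array([BASE_INDEX[s.alt] for s in sites], dtype=np.int64)

    af = np.repeat(af_site, n_templates)
    ref_idx = np.repeat(ref_site, n_templates)
    alt_idx = np.repeat(alt_site, n_templates)
    watson, crick = _simulate_family_counts(rng, af, ref_idx, alt_idx, error)

    n = n_sites * n_templates
    uid = uid_start + np.arange(n, dtype=np.int64)
    chrom = np.repeat(np.array([s.chrom for s in sites], dtype=object), n_templates)
    pos = np.repeat(np.array([s.pos for s in sites], dtype=np.int64), n_templates)
    return FamilyTable(uid, chrom, pos, watson, crick)


# ---------------------------------------------------------------------------
# bin counts and WGS pileups
# ---------------------------------------------------------------------------


def copy_number_per_bin(
    bins, segments: list[tuple[str, int, int, int]]
) -> np.ndarray:
    """Integer copy number of each bin (midpoint rule; neutral = 2)."""
    cn = np.full(len(bins), 2, dtype=np.int64)
    mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
    chroms = bins["chrom"].to_numpy()
    for chrom, start, end, c in segments:
        cn[(chroms == chrom) & (mid >= start) & (mid < end)] = c
    return cn


def simulate_bin_counts(
    truth: ParticipantTruth,
    genome: GenomeModel,
    mean_depth: float = 50_000.0,
    nb_size: float = 2e5,
    seed: int = 0,
    timepoint: str = "early",
):
    """Low-depth WGS bin read counts.

    A bin with copy number c at tumor fraction t has expected count
    proportional to (t*c + (1-t)*2) / 2; counts are negative-binomial with
    configurable dispersion (variance = mu * (1 + mu / nb_size)).
    """
    rng = np.random.default_rng(seed)
    bins = genome.bins()
    t = truth.tumor_fraction(timepoint)
    cn = copy_number_per_bin(bins, truth.segments)
    mu = mean_depth * (t * cn + (1.0 - t) * 2.0) / 2.0
    p = nb_size / (nb_size + mu)
    counts = rng.negative_binomial(nb_size, p)
    out = bins.copy()
    out["count"] = counts.astype(np.int64)
    return out


@dataclass(frozen=True)
class PileupSite:
    """One site of a plasma-vs-normal WGS pileup."""

    site: Site
    plasma_depth: int
    plasma_alt: int
    normal_depth: int
    normal_alt: int
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.plasma_alt > self.plasma_depth or self.normal_alt > self.normal_depth:
            raise ConfigurationError("alt reads exceed depth")

    @property
    def plasma_vaf(self) -> float:
        return self.plasma_alt / self.plasma_depth if self.plasma_depth else 0.0


def simulate_wgs_pileups(
    truth: ParticipantTruth,
    genome: GenomeModel,
    plasma_depth: float = 80.0,
    normal_depth: float = 30.0,
    seq_error: float = 1e-3,
    n_library_artifacts: int = 25,
    flag_probs: dict | None = None,
    seed: int = 0,
    timepoint: str = "early",
    normal_source: str = "leukocyte",
) -> list[PileupSite]:
    """High-depth WGS pileups at every truth-variant site plus artifact sites.

    ``normal_source`` selects what serves as the matched normal: the
    participant's leukocytes (default) or, when leukocytes are unavailable,
    the Very Early plasma sample ("very_early_plasma") whose neoplastic
    content is expected to be negligible.
    """
    if normal_source not in ("leukocyte", "very_early_plasma"):
        raise ConfigurationError(f"unknown normal_source {normal_source!r}")
    rng = np.random.default_rng(seed)
    flag_probs = dict(DEFAULT_FLAG_PROBS) if flag_probs is None else flag_probs
    rows: list[PileupSite] = []

    def _depths_alts(af_plasma: float, af_normal: float) -> tuple[int, int, int, int]:
        pd_ = int(rng.poisson(plasma_depth))
        nd = int(rng.poisson(normal_depth))
        pa = int(rng.binomial(pd_, min(af_plasma + seq_error / 3.0, 1.0)))
        na = int(rng.binomial(nd, min(af_normal + seq_error / 3.0, 1.0)))
        return pd_, pa, nd, na

    for v in truth.all_variants() + truth.artifacts:
        af_p = truth.expected_allele_fraction(v, timepoint, "plasma")
        if normal_source == "leukocyte":
            af_n = truth.expected_allele_fraction(v, timepoint, "leukocyte")
        else:
            af_n = truth.expected_allele_fraction(v, "very_early", "plasma")
        pd_, pa, nd, na = _depths_alts(af_p, af_n)
        rows.append(PileupSite(v.site, pd_, pa, nd, na, v.flags))

    # plasma-only library-preparation artifacts: no duplex support anywhere
    for _ in range(n_library_artifacts):
        site = genome.random_site(rng)
        vaf = float(rng.uniform(0.008, 0.04))
        pd_, pa, nd, na = _depths_alts(vaf, 0.0)
        flags = frozenset(
            {name for name, p in flag_probs.items() if rng.random() < p}
        )
        rows.append(PileupSite(site, pd_, pa, nd, na, flags))
    return rows
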