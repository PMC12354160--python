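"""Cohort orchestration and longitudinal statistics.

Runs the study decision flow over a cohort: targeted driver panel on the
Early plasma; aneuploidy (tumor-fraction) screening of the targeted-negative
participants; for every Early-positive participant whose MAF clears the
personalized-feasibility cutoff (0.5%), bespoke panel design and duplex
validation, then personalized-panel scoring of the Early and Very Early
samples. Computes per-participant MAF fold-changes, cohort sensitivity and
specificity with the Wilson score interval, and writes the report tables.

Blinding contract: no calling stage reads case/control labels; only the
summary stage does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._seeds import derive_seed
from .bespoke import (
    CandidateParams,
    PanelDesign,
    PersonalizedResult,
    apply_exclusion_filters,
    call_personalized_panel,
    call_wgs_candidates,
    infeasible_result,
    masks_from_variants,
    select_panel,
    validate_bona_fide,
)
from .cna import (
    DEFAULT_PON_SIZE,
    PanelOfNormals,
    TumorFractionResults,
    fit_tumor_fraction,
    normalize_bins,
)
from .duplex import CallParams
from .exceptions import ConfigurationError
from .simulate import (
    Cohort,
    ParticipantTruth,
    TumorProfile,
    sample_duplex_families,
    simulate_bin_counts,
    simulate_wgs_pileups,
)
from .targeted import QuerySite, TargetedParams, TargetedResult, run_targeted_panel

#: personalized design requires MAF above this (assay applicability bound)
FEASIBILITY_MAF = 0.005

NOT_AVAILABLE = "Sample not available"
NOT_DETECTABLE = "Mutation not detectable"
NOT_APPLICABLE = "Not applicable"


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def wilson_interval(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Better small-sample coverage than the Wald interval; the lower bound is
    exactly 0 when successes = 0.
    """
    if trials < 1:
        raise ConfigurationError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ConfigurationError("successes must be in [0, trials]")
    if not 0 < confidence < 1:
        raise ConfigurationError("confidence must be in (0, 1)")
    low, high = proportion_confint(
        successes, trials, alpha=1.0 - confidence, method="wilson"
    )
    # the closed form gives exactly 0 / 1 at the boundaries; keep it exact
    low = 0.0 if successes == 0 else max(float(low), 0.0)
    high = 1.0 if successes == trials else min(float(high), 1.0)
    return low, high


def fold_change(early_maf: float, very_early_maf: float) -> float | None:
    """Early / Very Early MAF ratio; None ("Not applicable") if the Very
    Early MAF is zero or undefined."""
    if early_maf is None or early_maf <= 0:
        raise ConfigurationError("early MAF must be positive")
    if very_early_maf is None or very_early_maf <= 0:
        return None
    return early_maf / very_early_maf


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


@dataclass
class ParticipantOutcome:
    pid: str
    is_case: bool
    cancer_type: str
    stage: str
    targeted: TargetedResult
    cna: TumorFractionResults | None = None
    personalized_early: PersonalizedResult | None = None
    personalized_very_early: PersonalizedResult | None = None
    early_positive: bool = False
    positive_by: str | None = None  # "targeted" | "aneuploidy"
    early_maf: float | None = None
    very_early_maf: float | None = None
    very_early_status: str = "not_assessed"
    fold: float | None = None
    days_to_dx: dict = field(default_factory=dict)

    @property
    def detected_fraction_very_early(self) -> float | None:
        if self.personalized_very_early is None:
            return None
        return self.personalized_very_early.detected_fraction


@dataclass
class CohortSummary:
    n_cases: int
    n_controls: int
    case_positives: int
    control_positives: int
    sensitivity: float
    ci_lower: float
    ci_upper: float
    fold_changes: dict
    median_fold_change: float | None
    detected_fractions: dict

    def summary(self) -> str:
        lines = [
            "Cohort summary",
            "=" * 60,
            f"cases / controls                {self.n_cases} / {self.n_controls}",
            f"positives among cases           {self.case_positives}",
            f"positives among controls        {self.control_positives}",
            (
                f"sensitivity                     "
                f"{100 * self.sensitivity:.0f}% "
                f"({self.case_positives} of {self.n_cases}; "
                f"95% CI: {100 * self.ci_lower:.0f} to "
                f"{100 * self.ci_upper:.0f}%)"
            ),
        ]
        if self.median_fold_change is not None:
            lines.append(
                f"median Early/Very Early fold    "
                f"{self.median_fold_change:.1f}"
            )
        for pid, (k, n) in sorted(self.detected_fractions.items()):
            lines.append(
                f"  {pid}: {k} of {n} panel mutations detected at Very Early "
                f"({100 * k / n:.0f}%)"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the decision flow
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunParams:
    """Tunables of the cohort run (calling thresholds and scales)."""

    call: CallParams = field(default_factory=CallParams)
    targeted: TargetedParams = field(default_factory=TargetedParams)
    candidate: CandidateParams = field(default_factory=CandidateParams)
    feasibility_maf: float = FEASIBILITY_MAF
    max_panel: int = 96
    pon_size: int = DEFAULT_PON_SIZE
    n_library_artifacts: int = 25


def _targeted_query_sites(participant: ParticipantTruth, annotation) -> list[QuerySite]:
    """Hotspot sites plus the participant's in-panel variant sites."""
    queries: dict[tuple[str, int, str], QuerySite] = {}
    for site in annotation.hotspot_sites():
        queries[(site.chrom, site.pos, site.alt)] = QuerySite(site)
    for v in participant.all_variants():
        key = (v.chrom, v.pos, v.alt)
        if key in queries:
            continue
        if annotation.region_at(v.chrom, v.pos) is not None:
            queries[key] = QuerySite(v.site, v.has_flag("truncating_in_tsg"))
    return [queries[k] for k in sorted(queries)]


def build_panel_of_normals(cohort: Cohort, params: RunParams) -> PanelOfNormals:
    """PoN from dedicated synthetic normals (never from cohort participants)."""
    cfg = cohort.config
    profiles = []
    for i in range(params.pon_size):
        truth = ParticipantTruth(f"PON{i:03d}", False, TumorProfile())
        counts = simulate_bin_counts(
            truth, cohort.genome, cfg.mean_reads_per_bin, cfg.nb_size,
            seed=derive_seed(cfg.seed, "pon", i),
        )
        profiles.append(counts["count"].to_numpy())
    return PanelOfNormals.from_counts(cohort.genome.bins(), profiles)


def _run_participant(
    p: ParticipantTruth,
    cohort: Cohort,
    pon: PanelOfNormals,
    params: RunParams,
    log: list[dict],
) -> ParticipantOutcome:
    cfg = cohort.config
    genome, annotation = cohort.genome, cohort.annotation
    error = cfg.error_model
    seed = cfg.seed

    def stage_seed(stage: str) -> int:
        return derive_seed(seed, p.pid, stage)

    # --- targeted driver panel on the Early plasma ---------------------------
    query = _targeted_query_sites(p, annotation)
    sites = [q.site for q in query]
    plasma = sample_duplex_families(
        p, sites, "early", "plasma", cfg.plasma_templates, error,
        stage_seed("targeted_plasma_early"), genome=genome,
    )
    leuko = sample_duplex_families(
        p, sites, "early", "leukocyte", cfg.leukocyte_templates, error,
        stage_seed("targeted_leukocyte"), genome=genome,
    )
    targeted = run_targeted_panel(
        plasma, leuko, annotation, query, p.pid, "early", params.targeted
    )
    log.append(
        {"pid": p.pid, "stage": "targeted", "positive": targeted.positive,
         "n_detected": targeted.n_detected, "mean_maf": targeted.mean_maf}
    )

    outcome = ParticipantOutcome(
        pid=p.pid, is_case=p.is_case,
        cancer_type=p.tumor.cancer_type if p.is_case else "",
        stage=p.tumor.stage if p.is_case else "",
        targeted=targeted, days_to_dx=dict(p.days_to_dx),
    )

    # --- aneuploidy arm: targeted-negative participants only -----------------
    cna_res = None
    if targeted.positive:
        outcome.early_positive = True
        outcome.positive_by = "targeted"
        maf_proxy = targeted.mean_maf
    else:
        bins = simulate_bin_counts(
            p, genome, cfg.mean_reads_per_bin, cfg.nb_size,
            seed=stage_seed("bins_early"),
        )
        cna_res = fit_tumor_fraction(normalize_bins(bins, pon))
        outcome.cna = cna_res
        log.append(
            {"pid": p.pid, "stage": "aneuploidy",
             "tumor_fraction": cna_res.tumor_fraction,
             "positive": cna_res.positive}
        )
        if cna_res.positive:
            outcome.early_positive = True
            outcome.positive_by = "aneuploidy"
            maf_proxy = cna_res.tumor_fraction / 2.0
        else:
            maf_proxy = None

    if not outcome.early_positive:
        return outcome

    # --- personalized panel: design, validate, score -------------------------
    if maf_proxy is None or maf_proxy <= params.feasibility_maf:
        outcome.personalized_early = infeasible_result(p.pid, "early")
        outcome.early_maf = targeted.mean_maf
        log.append(
            {"pid": p.pid, "stage": "personalized_design",
             "feasible": False, "maf_proxy": maf_proxy}
        )
        return outcome

    pileups = simulate_wgs_pileups(
        p, genome, cfg.plasma_wgs_depth, cfg.normal_wgs_depth,
        error.seq_error, params.n_library_artifacts, cfg.flag_probs,
        seed=stage_seed("wgs_pileups"),
    )
    candidates = call_wgs_candidates(pileups, params.candidate)
    filtered = apply_exclusion_filters(
        candidates, masks_from_variants(p.all_variants())
    )
    design = select_panel(filtered, params.max_panel, p.pid)
    if design.is_empty:
        outcome.personalized_early = infeasible_result(p.pid, "early")
        outcome.early_maf = targeted.mean_maf
        log.append(
            {"pid": p.pid, "stage": "personalized_design", "feasible": False,
             "reason": "no candidates passed selection"}
        )
        return outcome

    cand_sites = [c.site for c in design.candidates]
    plasma_val = sample_duplex_families(
        p, cand_sites, "early", "plasma", cfg.plasma_templates, error,
        stage_seed("personal_plasma_early"), genome=genome,
    )
    leuko_val = sample_duplex_families(
        p, cand_sites, "early", "leukocyte", cfg.leukocyte_templates, error,
        stage_seed("personal_leukocyte"), genome=genome,
    )
    ctrl_val = sample_duplex_families(
        cohort.unrelated_control, cand_sites, "early", "plasma",
        cfg.plasma_templates, error, stage_seed("personal_control"),
        genome=genome,
    )
    design = validate_bona_fide(design, plasma_val, leuko_val, ctrl_val, params.call)
    log.append(
        {"pid": p.pid, "stage": "personalized_design", "feasible": True,
         "n_candidates": len(design.candidates),
         "n_bona_fide": len(design.bona_fide)}
    )
    if not design.bona_fide:
        outcome.personalized_early = infeasible_result(p.pid, "early")
        outcome.early_maf = targeted.mean_maf
        return outcome

    personal_early = call_personalized_panel(
        design, plasma_val, leuko_val, "early", params.call
    )
    outcome.personalized_early = personal_early
    outcome.early_maf = (
        personal_early.mean_maf
        if personal_early.mean_maf is not None
        else targeted.mean_maf
    )
    log.append(
        {"pid": p.pid, "stage": "personalized_early",
         "positive": personal_early.positive,
         "n_detected": personal_early.n_detected,
         "n_assessed": personal_early.n_assessed,
         "mean_maf": personal_early.mean_maf}
    )

    if not p.very_early_available:
        outcome.very_early_status = NOT_AVAILABLE
        return outcome
    plasma_ve = sample_duplex_families(
        p, cand_sites, "very_early", "plasma", cfg.plasma_templates, error,
        stage_seed("personal_plasma_very_early"), genome=genome,
    )
    personal_ve = call_personalized_panel(
        design, plasma_ve, None, "very_early", params.call
    )
    outcome.personalized_very_early = personal_ve
    if personal_ve.positive:
        outcome.very_early_status = "detected"
        outcome.very_early_maf = personal_ve.mean_maf
        if outcome.early_maf:
            outcome.fold = fold_change(outcome.early_maf, outcome.very_early_maf)
    else:
        outcome.very_early_status = NOT_DETECTABLE
    log.append(
        {"pid": p.pid, "stage": "personalized_very_early",
         "positive": personal_ve.positive,
         "n_detected": personal_ve.n_detected,
         "n_assessed": personal_ve.n_assessed,
         "mean_maf": personal_ve.mean_maf}
    )
    return outcome


def run_cohort(
    cohort: Cohort,
    params: RunParams = RunParams(),
    out_dir: str | Path | None = None,
) -> tuple[list[ParticipantOutcome], CohortSummary]:
    """Execute the full decision flow and summarize the cohort.

    When ``out_dir`` is given, writes outcomes/summary/report tables, the
    paired-MAF plot and a JSON-lines log of every stage decision.
    """
    log: list[dict] = []
    pon = build_panel_of_normals(cohort, params)
    outcomes = [
        _run_participant(p, cohort, pon, params, log)
        for p in cohort.participants
    ]
    summary = summarize(outcomes, out_dir=out_dir)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "log.jsonl", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    return outcomes, summary


# ---------------------------------------------------------------------------
# summaries and reports
# ---------------------------------------------------------------------------


def _fmt_maf(maf: float | None, status: str | None = None) -> str:
    if maf is not None:
        return f"{100 * maf:.2f}%"
    return status or ""


def table1_frame(outcomes: list[ParticipantOutcome]) -> pd.DataFrame:
    """Summary table of the Early-positive participants (report layout:
    days to diagnosis and MAF per timepoint, Early/Very-Early MAF ratio)."""
    rows = []
    for o in outcomes:
        if not o.early_positive:
            continue
        if o.very_early_status == NOT_AVAILABLE:
            ve_days, ve_maf, ratio = NOT_AVAILABLE, NOT_AVAILABLE, NOT_AVAILABLE
        else:
            ve_days = o.days_to_dx.get("very_early", "")
            ve_maf = _fmt_maf(o.very_early_maf, NOT_DETECTABLE)
            ratio = f"{o.fold:.1f}" if o.fold is not None else NOT_APPLICABLE
        rows.append(
            {
                "participant": o.pid,
                "cancer": o.cancer_type,
                "stage": o.stage,
                "days_to_dx_early": o.days_to_dx.get("early", ""),
                "maf_early": _fmt_maf(o.early_maf),
                "days_to_dx_very_early": ve_days,
                "maf_very_early": ve_maf,
                "maf_ratio_early_to_very_early": ratio,
            }
        )
    return pd.DataFrame(rows)


def outcomes_frame(outcomes: list[ParticipantOutcome]) -> pd.DataFrame:
    rows = []
    for o in outcomes:
        rows.append(
            {
                "participant": o.pid,
                "case": o.is_case,
                "targeted_positive": o.targeted.positive,
                "targeted_mean_maf": (
                    o.targeted.mean_maf if o.targeted.mean_maf is not None
                    else float("nan")
                ),
                "aneuploidy_tumor_fraction": (
                    o.cna.tumor_fraction if o.cna is not None else float("nan")
                ),
                "aneuploidy_positive": (
                    o.cna.positive if o.cna is not None else False
                ),
                "early_positive": o.early_positive,
                "positive_by": o.positive_by or "",
                "early_maf": (
                    o.early_maf if o.early_maf is not None else float("nan")
                ),
                "very_early_status": o.very_early_status,
                "very_early_maf": (
                    o.very_early_maf if o.very_early_maf is not None
                    else float("nan")
                ),
                "fold_change": o.fold if o.fold is not None else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def median_fold(ratios: list[float]) -> float | None:
    """Median ratio; even counts take the midpoint of the central pair."""
    if not ratios:
        return None
    return float(np.median(ratios))


def summarize(
    outcomes: list[ParticipantOutcome], out_dir: str | Path | None = None
) -> CohortSummary:
    """Cohort-level sensitivity/specificity and fold-change statistics.

    The only stage allowed to read case/control labels.
    """
    if not outcomes:
        raise ConfigurationError("need >= 1 outcome")
    cases = [o for o in outcomes if o.is_case]
    controls = [o for o in outcomes if not o.is_case]
    k = sum(o.early_positive for o in cases)
    fp = sum(o.early_positive for o in controls)
    n = len(cases)
    sens = k / n if n else float("nan")
    if n:
        lo, hi = wilson_interval(k, n, 0.95)
    else:
        lo = hi = float("nan")
    folds = {o.pid: o.fold for o in outcomes if o.fold is not None}
    detected = {
        o.pid: (
            o.personalized_very_early.n_detected,
            o.personalized_very_early.n_assessed,
        )
        for o in outcomes
        if o.personalized_very_early is not None
        and o.personalized_very_early.n_assessed > 0
    }
    summary = CohortSummary(
        n_cases=n,
        n_controls=len(controls),
        case_positives=int(k),
        control_positives=int(fp),
        sensitivity=sens,
        ci_lower=lo,
        ci_upper=hi,
        fold_changes=folds,
        median_fold_change=median_fold(list(folds.values())),
        detected_fractions=detected,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        outcomes_frame(outcomes).to_csv(
            out_dir / "outcomes.tsv", sep="\t", index=False
        )
        table1_frame(outcomes).to_csv(out_dir / "table1.tsv", sep="\t", index=False)
        with open(out_dir / "summary.tsv", "w") as fh:
            fh.write(
                "n_cases\tn_controls\tcase_positives\tcontrol_positives\t"
                "sensitivity\tci_lower\tci_upper\tmedian_fold_change\n"
            )
            med = (
                f"{summary.median_fold_change:.3f}"
                if summary.median_fold_change is not None else "NA"
            )
            fh.write(
                f"{n}\t{len(controls)}\t{k}\t{fp}\t{sens:.4f}\t{lo:.4f}\t"
                f"{hi:.4f}\t{med}\n"
            )
        from .plotting import paired_maf_plot

        paired_maf_plot(outcomes, out_dir / "paired_maf.svg")
    return summary
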