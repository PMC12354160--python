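import numpy as np
import pytest

from ctdna_horizon.bespoke import (
    CandidateParams,
    IntervalMask,
    MaskSet,
    PanelCandidate,
    apply_exclusion_filters,
    call_personalized_panel,
    call_wgs_candidates,
    masks_from_variants,
    select_panel,
    validate_bona_fide,
)
from ctdna_horizon.exceptions import ConfigurationError
from ctdna_horizon.families import FamilyTable
from ctdna_horizon.genome import Site
from ctdna_horizon.simulate import (
    ErrorModel,
    ParticipantTruth,
    PileupSite,
    TumorProfile,
    sample_duplex_families,
    simulate_wgs_pileups,
)
from ctdna_horizon.variants import Variant

from conftest import make_clean_somatic
from test_duplex import _table


def pileup(chrom="chr1", pos=100, ref="A", alt="C", context="TAT",
           plasma=(6, 100), normal=(0, 30), flags=()):
    return PileupSite(
        Site(chrom, pos, ref, alt, context),
        plasma_depth=plasma[1], plasma_alt=plasma[0],
        normal_depth=normal[1], normal_alt=normal[0],
        flags=frozenset(flags),
    )


class TestCandidateCaller:
    def test_all_thresholds_met_retained(self):
        cands = call_wgs_candidates([pileup(plasma=(6, 100), normal=(0, 30))])
        assert len(cands) == 1 and cands[0].plasma_vaf == pytest.approx(0.06)

    def test_any_leukocyte_support_excludes(self):
        assert call_wgs_candidates([pileup(normal=(1, 30))]) == []

    def test_min_alt_reads(self):
        assert call_wgs_candidates([pileup(plasma=(2, 100))]) == []

    def test_min_vaf(self):
        assert call_wgs_candidates([pileup(plasma=(4, 2000))]) == []

    def test_min_normal_depth(self):
        assert call_wgs_candidates([pileup(normal=(0, 10))]) == []


class TestExclusionFilters:
    def test_repeat_mask_names_filter(self):
        cand = call_wgs_candidates([pileup(pos=150)])
        masks = MaskSet(repeat=IntervalMask([("chr1", 100, 200)]))
        retained = apply_exclusion_filters(cand, masks)
        assert retained == []
        assert cand[0].verdicts["repeat"] is False
        assert all(cand[0].verdicts[f] for f in
                   ("hard_align", "hard_to_amplify", "snp", "cpg_transition"))

    def test_cpg_transition_computed_from_context(self):
        cand = call_wgs_candidates([pileup(ref="C", alt="T", context="ACG")])
        retained = apply_exclusion_filters(cand, MaskSet())
        assert retained == [] and cand[0].verdicts["cpg_transition"] is False

    def test_flag_based_exclusions(self):
        cand = call_wgs_candidates([pileup(flags={"hard_to_amplify"})])
        assert apply_exclusion_filters(cand, MaskSet()) == []

    def test_clean_candidate_passes_all_five(self):
        cand = call_wgs_candidates([pileup()])
        retained = apply_exclusion_filters(cand, MaskSet())
        assert retained == cand and cand[0].passed_all

    def test_overlapping_mask_intervals_normalized(self):
        mask = IntervalMask([("chr1", 10, 30), ("chr1", 20, 40), ("chr1", 35, 50)])
        assert mask.intervals() == [("chr1", 10, 50)]
        assert ("chr1", 39) in mask and ("chr1", 50) not in mask

    def test_masks_from_variants_agree_with_flags(self, genome, rng):
        variants = [
            Variant(genome.random_site(rng), "somatic", 1.0,
                    frozenset({"in_repeat"})),
            Variant(genome.random_site(rng), "germline", 0.5),
        ]
        masks = masks_from_variants(variants)
        assert (variants[0].chrom, variants[0].pos) in masks.repeat
        assert (variants[1].chrom, variants[1].pos) in masks.snp


def _candidates(vafs, chrom="chr1"):
    out = []
    for i, v in enumerate(vafs):
        p = pileup(chrom=chrom, pos=1000 + i, plasma=(int(v * 1000), 1000))
        out.append(PanelCandidate(pileup=p, plasma_vaf=v))
    return out


class TestSelectPanel:
    def test_top_k_by_vaf(self):
        vafs = list(np.linspace(0.01, 0.50, 120))
        design = select_panel(_candidates(vafs), max_panel=96)
        assert len(design.candidates) == 96
        chosen = min(c.plasma_vaf for c in design.candidates)
        unchosen = [v for v in vafs][:120 - 96]
        assert chosen >= max(unchosen)

    def test_small_candidate_set_kept_entirely(self):
        design = select_panel(_candidates([0.02] * 19))
        assert len(design.candidates) == 19

    def test_tie_breaks_by_coordinate(self):
        a = PanelCandidate(pileup(chrom="chr2", pos=500), 0.05)
        b = PanelCandidate(pileup(chrom="chr2", pos=100), 0.05)
        design = select_panel([a, b], max_panel=1)
        assert design.candidates[0].site.pos == 100

    def test_stable_under_input_permutation(self, rng):
        cands = _candidates(list(rng.uniform(0.005, 0.3, size=150)))
        ref_order = [c.site.pos for c in select_panel(cands).candidates]
        for _ in range(3):
            shuffled = list(rng.permutation(cands))
            order = [c.site.pos for c in select_panel(shuffled).candidates]
            assert order == ref_order


class TestBonaFideValidation:
    def _design(self, site):
        return select_panel([PanelCandidate(
            PileupSite(site, 100, 10, 30, 0), 0.1
        )])

    def test_confirmed_everywhere_clean(self):
        site = Site("chr1", 10, "C", "T", "ACT")
        design = self._design(site)
        plasma = _table(10, 990, site=site.key)
        leuko = _table(0, 5000, site=site.key, uid_start=10_000)
        ctrl = _table(0, 1200, site=site.key, uid_start=20_000)
        design = validate_bona_fide(design, plasma, leuko, ctrl)
        assert design.candidates[0].bona_fide
        assert design.candidates[0].evidence["plasma_mutant"] == 10

    def test_unrelated_control_support_rejects(self):
        """Recurrent signal in an unrelated cancer-free plasma marks the
        site as a systematic artifact."""
        site = Site("chr1", 10, "C", "T", "ACT")
        design = self._design(site)
        design = validate_bona_fide(
            design,
            _table(10, 990, site=site.key),
            _table(0, 5000, site=site.key, uid_start=10_000),
            _table(2, 1198, site=site.key, uid_start=20_000),
        )
        assert not design.candidates[0].bona_fide
        assert design.candidates[0].evaluable

    def test_leukocyte_support_rejects(self):
        site = Site("chr1", 10, "C", "T", "ACT")
        design = self._design(site)
        design = validate_bona_fide(
            design,
            _table(10, 990, site=site.key),
            _table(1, 4999, site=site.key, uid_start=10_000),
            _table(0, 1200, site=site.key, uid_start=20_000),
        )
        assert not design.candidates[0].bona_fide

    def test_uncovered_site_unevaluable(self):
        site = Site("chr1", 10, "C", "T", "ACT")
        design = self._design(site)
        design = validate_bona_fide(
            design,
            _table(10, 990, site=site.key),
            FamilyTable.empty(),
            _table(0, 1200, site=site.key, uid_start=20_000),
        )
        assert not design.candidates[0].bona_fide
        assert not design.candidates[0].evaluable


class TestPersonalizedCalling:
    def _bona_design(self, sites):
        cands = []
        for s in sites:
            c = PanelCandidate(PileupSite(s, 100, 10, 30, 0), 0.1)
            c.bona_fide = True
            cands.append(c)
        return select_panel(cands)

    def test_single_mutant_molecule_is_positive(self):
        site = Site("chr1", 10, "C", "T", "ACT")
        design = self._bona_design([site])
        res = call_personalized_panel(design, _table(1, 999, site=site.key))
        assert res.positive and res.n_detected == 1

    def test_all_zero_is_negative(self):
        site = Site("chr1", 10, "C", "T", "ACT")
        design = self._bona_design([site])
        res = call_personalized_panel(design, _table(0, 1000, site=site.key))
        assert not res.positive and res.detected_fraction == 0.0

    def test_detected_fraction(self):
        sites = [Site("chr1", 10 + i, "C", "T", "ACT") for i in range(3)]
        design = self._bona_design(sites)
        sample = FamilyTable.concat([
            _table(2, 500, site=sites[0].key, uid_start=0),
            _table(1, 501, site=sites[1].key, uid_start=2000),
            _table(0, 502, site=sites[2].key, uid_start=4000),
        ])
        res = call_personalized_panel(design, sample)
        assert res.n_detected == 2 and res.n_assessed == 3
        assert res.detected_fraction == pytest.approx(2 / 3)

    def test_empty_bona_fide_set_is_infeasible(self):
        site = Site("chr1", 10, "C", "T", "ACT")
        design = select_panel([PanelCandidate(PileupSite(site, 100, 10, 30, 0),
                                              0.1)])
        with pytest.raises(ConfigurationError, match="infeasible"):
            call_personalized_panel(design, _table(1, 999, site=site.key))


class TestSensitivityGain:
    def test_panel_detection_matches_closed_form(self, genome, rng):
        """A panel of n mutations at per-mutation detection probability q
        detects the sample with probability ~ 1 - (1-q)^n."""
        maf, n_templates, n_panel = 0.001, 1500, 10
        error = ErrorModel()

        def detect(sites, truth, seed):
            fams = sample_duplex_families(
                truth, sites, "early", "plasma", n_templates, error, seed
            )
            design = TestPersonalizedCalling()._bona_design(sites)
            return call_personalized_panel(design, fams).positive

        muts = make_clean_somatic(genome, rng, n_panel)
        truth = ParticipantTruth(
            "P1", True, TumorProfile(early_tumor_fraction=2 * maf),
            tumor_mutations=muts,
        )
        n_single, n_multi = 400, 250
        q_hits = sum(
            detect([muts[0].site], truth, 10_000 + i) for i in range(n_single)
        )
        q = q_hits / n_single
        panel_hits = sum(
            detect([m.site for m in muts], truth, 20_000 + i)
            for i in range(n_multi)
        )
        observed = panel_hits / n_multi
        expected = 1.0 - (1.0 - q) ** n_panel
        se_panel = np.sqrt(expected * (1 - expected) / n_multi)
        se_q = np.sqrt(q * (1 - q) / n_single)
        se = np.sqrt(se_panel**2 + (n_panel * (1 - q) ** (n_panel - 1) * se_q) ** 2)
        assert abs(observed - expected) < 3 * se


class TestTruthSetRecovery:
    def test_cascade_recovers_clonal_mutations(self, genome, rng):
        """>= 90% of clean clonal mutations above the VAF cutoff become bona
        fide; no germline or CHIP variant survives the cascade."""
        muts = make_clean_somatic(genome, rng, 40)
        germline = [Variant(genome.random_site(rng), "germline",
                            0.5 if i % 3 else 1.0) for i in range(12)]
        chip = [Variant(genome.random_site(rng), "chip", cf)
                for cf in (0.02, 0.08, 0.2)]
        truth = ParticipantTruth(
            "P1", True, TumorProfile(early_tumor_fraction=0.26),  # MAF 13%
            tumor_mutations=muts, germline=germline, chip=chip,
        )
        control = ParticipantTruth("U1", False, TumorProfile(),
                                   germline=germline[:2])
        pile = simulate_wgs_pileups(truth, genome, seed=31)
        candidates = call_wgs_candidates(pile)
        filtered = apply_exclusion_filters(candidates, masks_from_variants(
            truth.all_variants()))
        design = select_panel(filtered, participant_id="P1")
        assert len(design.candidates) <= 96
        sites = [c.site for c in design.candidates]
        error = ErrorModel()
        plasma = sample_duplex_families(truth, sites, "early", "plasma",
                                        1500, error, seed=32)
        leuko = sample_duplex_families(truth, sites, "early", "leukocyte",
                                       6000, error, seed=33)
        ctrl = sample_duplex_families(control, sites, "early", "plasma",
                                      1500, error, seed=34)
        design = validate_bona_fide(design, plasma, leuko, ctrl)
        bona_keys = {c.site.key for c in design.bona_fide}
        truth_keys = {m.site.key for m in muts}
        recovered = len(bona_keys & truth_keys)
        assert recovered >= 36  # >= 90% of 40
        contaminant_keys = {v.site.key for v in germline + chip}
        assert not (bona_keys & contaminant_keys)
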