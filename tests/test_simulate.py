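import numpy as np
import pytest

from ctdna_horizon.exceptions import ConfigurationError
from ctdna_horizon.families import BASE_INDEX
from ctdna_horizon.genome import GenomeModel
from ctdna_horizon.simulate import (
    ErrorModel,
    ParticipantTruth,
    ScenarioConfig,
    TumorProfile,
    copy_number_per_bin,
    sample_duplex_families,
    simulate_bin_counts,
    simulate_cohort,
    simulate_wgs_pileups,
)
from ctdna_horizon.variants import Variant

from conftest import make_clean_somatic

NO_ERRORS = ErrorModel(seq_error=0, ss_damage=0, ds_artifact=0, strand_loss=0)


class TestConfig:
    def test_invalid_rate_names_field(self):
        with pytest.raises(ConfigurationError, match="seq_error"):
            ErrorModel(seq_error=1.5)
        with pytest.raises(ConfigurationError, match="strand_loss"):
            ErrorModel(strand_loss=-0.1)

    def test_fold_decrease_and_fractions(self):
        with pytest.raises(ConfigurationError, match="fold_decrease"):
            TumorProfile(early_tumor_fraction=0.1, fold_decrease=0.5)
        with pytest.raises(ConfigurationError, match="early_tumor_fraction"):
            TumorProfile(early_tumor_fraction=1.2)

    def test_very_early_fraction_is_early_over_fold(self):
        p = TumorProfile(early_tumor_fraction=0.1, fold_decrease=50.0)
        assert p.very_early_tumor_fraction == pytest.approx(0.002)
        assert TumorProfile(
            early_tumor_fraction=0.1, fold_decrease=None
        ).very_early_tumor_fraction == 0.0

    def test_config_roundtrip_dict(self, small_config):
        assert ScenarioConfig.from_dict(small_config.to_dict()) == small_config


class TestCohort:
    def test_counts_and_labels(self, small_cohort, small_config):
        assert len(small_cohort.cases) == small_config.n_cases
        assert len(small_cohort.controls) == small_config.n_controls
        assert small_cohort.unrelated_control is not None
        assert not small_cohort.unrelated_control.is_case

    def test_every_case_has_tumor_signal(self, small_cohort):
        for case in small_cohort.cases:
            assert case.tumor_mutations or case.segments

    def test_controls_carry_no_somatic_truth(self, small_cohort):
        for control in small_cohort.controls:
            assert control.tumor_mutations == []
            assert control.segments == []
            assert all(v.truth_class != "somatic" for v in control.all_variants())

    def test_deterministic_under_seed(self, small_config):
        a = simulate_cohort(small_config)
        b = simulate_cohort(small_config)
        for pa, pb in zip(a.participants, b.participants):
            assert pa == pb
        assert a.artifact_sites == b.artifact_sites

    def test_shedders_cannot_exceed_cases(self):
        with pytest.raises(ConfigurationError, match="shedders"):
            ScenarioConfig(
                n_cases=1, shedders=(TumorProfile(), TumorProfile())
            )


class TestDuplexSampling:
    def _solo(self, genome, rng, maf=0.02, n=30):
        tumor = TumorProfile(early_tumor_fraction=2 * maf)
        muts = make_clean_somatic(genome, rng, n)
        return ParticipantTruth("P1", True, tumor, tumor_mutations=muts), muts

    def test_error_free_control_has_zero_nonref(self, genome, rng):
        control = ParticipantTruth("C1", False, TumorProfile())
        sites = [genome.random_site(rng) for _ in range(20)]
        fams = sample_duplex_families(
            control, sites, "early", "plasma", 200, NO_ERRORS, seed=3
        )
        ref_idx = np.array([BASE_INDEX[genome.site(c, p).ref]
                            for c, p in zip(fams.chrom, fams.pos)])
        for counts in (fams.watson, fams.crick):
            nonref = counts.sum(axis=1) - counts[np.arange(len(fams)), ref_idx]
            assert (nonref == 0).all()

    def test_germline_het_leukocyte_af_half(self, genome, rng):
        site = genome.random_site(rng)
        truth = ParticipantTruth(
            "P1", True, TumorProfile(),
            germline=[Variant(site, "germline", 0.5)],
            tumor_mutations=make_clean_somatic(genome, rng, 1),
        )
        fams = sample_duplex_families(
            truth, [site], "early", "leukocyte", 4000, NO_ERRORS, seed=9
        )
        alt_idx = BASE_INDEX[site.alt]
        alt_templates = (fams.watson[:, alt_idx] > 0).sum()
        assert alt_templates / len(fams) == pytest.approx(0.5, abs=0.03)

    def test_somatic_absent_from_leukocytes(self, genome, rng):
        truth, muts = self._solo(genome, rng)
        sites = [m.site for m in muts]
        fams = sample_duplex_families(
            truth, sites, "early", "leukocyte", 500, NO_ERRORS, seed=4
        )
        alt_idx = np.array([BASE_INDEX[genome.site(c, p).alt]
                            for c, p in zip(fams.chrom, fams.pos)])
        assert fams.watson[np.arange(len(fams)), alt_idx].sum() == 0

    def test_binomial_calibration(self, genome, rng):
        """Across >= 500 sites at fixed p, the mutant-template fraction mean
        lies within 3 binomial standard errors of p."""
        p = 0.02
        truth, muts = self._solo(genome, rng, maf=p, n=500)
        n_templates = 400
        fams = sample_duplex_families(
            truth, [m.site for m in muts], "early", "plasma", n_templates,
            NO_ERRORS, seed=21,
        )
        alt_idx = np.array([BASE_INDEX[genome.site(c, p_).alt]
                            for c, p_ in zip(fams.chrom, fams.pos)])
        is_mut = fams.watson[np.arange(len(fams)), alt_idx] > 0
        n_total = len(fams)
        se = np.sqrt(p * (1 - p) / n_total)
        assert abs(is_mut.mean() - p) < 3 * se

    def test_strand_read_conservation(self, genome, rng):
        """Mutant + non-mutant + N read counts per strand account for every
        replicate read (nothing is lost or double counted)."""
        truth, muts = self._solo(genome, rng, n=10)
        fams = sample_duplex_families(
            truth, [m.site for m in muts], "early", "plasma", 200,
            ErrorModel(), seed=5,
        )
        assert (fams.watson.sum(axis=1) >= 0).all()
        df = fams.to_frame()
        regrouped = df.groupby(["uid", "chrom", "pos", "strand"])["reads"].sum()
        back = type(fams).from_frame(df)
        total_before = fams.watson.sum() + fams.crick.sum()
        assert regrouped.sum() == total_before
        assert back.watson.sum() + back.crick.sum() == total_before

    def test_unknown_site_rejected(self, genome, rng):
        truth = ParticipantTruth("C1", False, TumorProfile())
        foreign = GenomeModel.synthetic().random_site(np.random.default_rng(0))
        with pytest.raises(KeyError, match="not in genome registry"):
            sample_duplex_families(
                truth, [foreign], "early", "plasma", 10, NO_ERRORS, seed=1,
                genome=genome,
            )


class TestBinCounts:
    def test_neutral_profile_single_expectation(self, genome):
        truth = ParticipantTruth("C1", False, TumorProfile())
        counts = simulate_bin_counts(truth, genome, seed=2)["count"]
        assert counts.std() / counts.mean() < 0.02  # no segment structure

    @pytest.mark.parametrize(
        "t,cn,expected_ratio", [(1.0, 4, 2.0), (0.1, 3, 1.05), (0.2, 1, 0.9)]
    )
    def test_segment_expected_ratio(self, genome, t, cn, expected_ratio):
        segments = [("chr1", 0, genome.chrom_lengths["chr1"], cn)]
        truth = ParticipantTruth(
            "P1", True, TumorProfile(early_tumor_fraction=t),
            tumor_mutations=make_clean_somatic(
                genome, np.random.default_rng(0), 1
            ),
            segments=segments,
        )
        df = simulate_bin_counts(truth, genome, seed=8)
        in_seg = df["chrom"] == "chr1"
        ratio = df.loc[in_seg, "count"].mean() / df.loc[~in_seg, "count"].mean()
        assert ratio == pytest.approx(expected_ratio, rel=0.01)

    def test_copy_number_lookup(self, genome):
        bins = genome.bins()
        cn = copy_number_per_bin(bins, [("chr2", 0, 2_000_000, 3)])
        sel = (bins["chrom"] == "chr2") & (bins["end"] <= 2_000_000)
        assert (cn[sel.to_numpy()] == 3).all()
        assert (cn[~sel.to_numpy()] == 2).all()


class TestPileups:
    def test_structure_and_compartments(self, genome, rng):
        muts = make_clean_somatic(genome, rng, 10)
        site = genome.random_site(rng)
        truth = ParticipantTruth(
            "P1", True, TumorProfile(early_tumor_fraction=0.3),
            tumor_mutations=muts,
            germline=[Variant(site, "germline", 1.0)],
        )
        pile = simulate_wgs_pileups(truth, genome, seed=6, seq_error=0.0)
        by_key = {p.site.key: p for p in pile}
        assert all(p.plasma_alt <= p.plasma_depth for p in pile)
        hom = by_key[site.key]
        assert hom.plasma_alt == hom.plasma_depth  # homozygous germline
        assert hom.normal_alt == hom.normal_depth
        som = by_key[muts[0].site.key]
        assert som.normal_alt == 0  # somatic absent from leukocytes

    def test_alternate_normal_uses_very_early_plasma(self, genome, rng):
        muts = make_clean_somatic(genome, rng, 200)
        truth = ParticipantTruth(
            "P1", True,
            TumorProfile(early_tumor_fraction=0.4, fold_decrease=2.0),
            tumor_mutations=muts,
        )
        pile = simulate_wgs_pileups(
            truth, genome, seed=7, seq_error=0.0, n_library_artifacts=0,
            normal_source="very_early_plasma",
        )
        # Very Early plasma as normal: somatic signal leaks at t_ve/2 = 0.1
        vafs = np.array([p.normal_alt / p.normal_depth for p in pile])
        assert vafs.mean() == pytest.approx(0.1, abs=0.02)
        with pytest.raises(ConfigurationError):
            simulate_wgs_pileups(truth, genome, normal_source="tumor")
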