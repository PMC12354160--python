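from collections import Counter

import numpy as np
import pytest

from ctdna_horizon.duplex import (
    CallParams,
    MUTANT,
    REFERENCE,
    background_rate,
    call_molecule,
    call_site,
    call_sites,
    molecule_status_kernel,
    single_strand_background_rate,
    strand_consensus,
)
from ctdna_horizon.exceptions import ContractError
from ctdna_horizon.families import BASE_INDEX, DuplexFamily, FamilyTable
from ctdna_horizon.simulate import (
    ErrorModel,
    ParticipantTruth,
    TumorProfile,
    sample_duplex_families,
)

from conftest import make_clean_somatic


def family(uid=1, watson=None, crick=None, site=("chr1", 10)):
    fam = DuplexFamily(uid)
    if watson is not None:
        fam.watson[site] = Counter(watson)
    if crick is not None:
        fam.crick[site] = Counter(crick)
    return fam


class TestStrandConsensus:
    def test_unanimous_reads(self):
        w, c = strand_consensus(family(watson="TTT", crick="TT"), ("chr1", 10))
        assert (w.base, w.agreement) == ("T", 1.0)
        assert c.base == "T"

    def test_disagreement_below_threshold_is_ambiguous(self):
        w, _ = strand_consensus(
            family(watson="TC", crick="TT"), ("chr1", 10), min_agreement=0.9
        )
        assert w.is_ambiguous and w.agreement == 0.5

    def test_insufficient_reads_is_ambiguous(self):
        w, _ = strand_consensus(
            family(watson="T", crick="TT"), ("chr1", 10), min_reads_per_strand=2
        )
        assert w.is_ambiguous

    def test_plurality_with_minor_error(self):
        w, _ = strand_consensus(
            family(watson="TTTTTTTTTC", crick="T"), ("chr1", 10),
            min_agreement=0.9,
        )
        assert w.base == "T" and w.agreement == pytest.approx(0.9)

    def test_tie_is_ambiguous_even_with_low_threshold(self):
        w, _ = strand_consensus(
            family(watson="TTCC", crick="T"), ("chr1", 10), min_agreement=0.1
        )
        assert w.is_ambiguous

    def test_uncovered_site_raises(self):
        with pytest.raises(KeyError):
            strand_consensus(family(watson="T"), ("chr2", 99))


class TestCallMolecule:
    def _consensus_pair(self, watson, crick):
        return strand_consensus(family(watson=watson, crick=crick), ("chr1", 10))

    def test_concordant_nonref_is_mutant(self):
        w, c = self._consensus_pair("TTT", "TTT")
        call = call_molecule(w, c, ref="C")
        assert call.status == "duplex_mutant" and call.alt == "T"

    def test_discordant_strands_not_mutant(self):
        w, c = self._consensus_pair("TTT", "CCC")
        assert call_molecule(w, c, ref="C").status == "discordant"

    def test_lost_strand_is_single_strand_only(self):
        w, c = self._consensus_pair("CCC", None)
        assert call_molecule(w, c, ref="C").status == "single_strand_only"

    def test_both_ref_is_reference(self):
        w, c = self._consensus_pair("CCC", "CC")
        assert call_molecule(w, c, ref="C").status == "duplex_reference"

    def test_uid_mismatch_is_contract_error(self):
        w, _ = self._consensus_pair("TTT", "TTT")
        _, c = strand_consensus(
            family(uid=2, watson="TTT", crick="TTT"), ("chr1", 10)
        )
        with pytest.raises(ContractError):
            call_molecule(w, c, ref="C")


def _table(n_mutant, n_ref, alt="T", ref="C", reads=3, site=("chr1", 10),
           uid_start=0):
    """n_mutant duplex-mutant molecules and n_ref duplex-reference ones."""
    n = n_mutant + n_ref
    watson = np.zeros((n, 5), dtype=np.int32)
    crick = np.zeros((n, 5), dtype=np.int32)
    watson[:n_mutant, BASE_INDEX[alt]] = reads
    crick[:n_mutant, BASE_INDEX[alt]] = reads
    watson[n_mutant:, BASE_INDEX[ref]] = reads
    crick[n_mutant:, BASE_INDEX[ref]] = reads
    return FamilyTable(
        uid_start + np.arange(n),
        np.array([site[0]] * n, dtype=object),
        np.full(n, site[1]),
        watson,
        crick,
    )


class TestCallSite:
    def test_maf_arithmetic(self):
        plasma = _table(3, 997)
        normal = _table(0, 5000, uid_start=10_000)
        call = call_site(plasma, normal, "chr1", 10, "C", "T")
        assert call.mutant_molecules == 3
        assert call.evaluable_molecules == 1000
        assert call.maf == pytest.approx(0.003)
        assert not call.matched_normal_excluded

    def test_normal_support_excludes(self):
        call = call_site(
            _table(5, 995), _table(2, 5998, uid_start=10_000), "chr1", 10, "C", "T"
        )
        assert call.matched_normal_excluded
        assert call.normal_mutant == 2 and call.normal_evaluable == 6000

    def test_insufficient_normal_flagged_not_excluded(self):
        call = call_site(
            _table(5, 995), _table(0, 500, uid_start=10_000), "chr1", 10, "C", "T",
            CallParams(min_normal_templates=1000),
        )
        assert "insufficient_normal" in call.flags
        assert not call.matched_normal_excluded

    def test_no_evaluable_flagged(self):
        empty = FamilyTable.empty()
        call = call_site(empty, None, "chr1", 10, "C", "T")
        assert call.maf is None and "no_evaluable" in call.flags

    def test_batch_matches_single(self):
        plasma = FamilyTable.concat([
            _table(3, 200), _table(7, 150, site=("chr2", 5), uid_start=5000)
        ])
        singles = [
            call_site(plasma, None, "chr1", 10, "C", "T"),
            call_site(plasma, None, "chr2", 5, "C", "T"),
        ]
        batch = call_sites(plasma, None, [("chr1", 10, "C", "T"),
                                          ("chr2", 5, "C", "T")])
        for a, b in zip(singles, batch):
            assert (a.mutant_molecules, a.evaluable_molecules) == (
                b.mutant_molecules, b.evaluable_molecules
            )


class TestCountingConservation:
    def test_statuses_partition_molecules(self, genome, rng):
        truth = ParticipantTruth(
            "P1", True, TumorProfile(early_tumor_fraction=0.2),
            tumor_mutations=make_clean_somatic(genome, rng, 20),
        )
        sites = [m.site for m in truth.tumor_mutations]
        fams = sample_duplex_families(
            truth, sites, "early", "plasma", 300,
            ErrorModel(seq_error=0.01, ss_damage=0.01, strand_loss=0.3),
            seed=77,
        )
        status, _ = molecule_status_kernel(
            fams.watson, fams.crick,
            np.array([BASE_INDEX[genome.site(c, p).ref]
                      for c, p in zip(fams.chrom, fams.pos)]),
        )
        counts = np.bincount(status, minlength=5)
        assert counts.sum() == len(fams)  # partition: every molecule counted


class TestBackgroundRates:
    def _control_batch(self, genome, rng, error, n_sites=40, n_templates=500):
        control = ParticipantTruth("C1", False, TumorProfile())
        sites = [genome.random_site(rng) for _ in range(n_sites)]
        fams = sample_duplex_families(
            control, sites, "early", "plasma", n_templates, error, seed=13
        )
        refs = {s.key: s.ref for s in sites}
        return fams, refs

    def test_error_free_background_zero(self, genome, rng):
        fams, refs = self._control_batch(
            genome, rng, ErrorModel(seq_error=0, ss_damage=0, ds_artifact=0)
        )
        assert background_rate([fams], refs) == 0.0

    def test_duplex_strictly_below_single_strand(self, genome, rng):
        """With any single-strand damage, duplex concordance suppresses the
        background below naive single-strand calling on the same data."""
        error = ErrorModel(ss_damage=2e-3, ds_artifact=0, seq_error=1e-3)
        fams, refs = self._control_batch(genome, rng, error, 60, 800)
        duplex = background_rate([fams], refs)
        single = single_strand_background_rate([fams], refs)
        assert duplex < single
        assert single > 1e-4  # damage clearly visible to single-strand calling

    def test_double_strand_artifacts_are_inescapable(self, genome, rng):
        """With only double-strand artifacts enabled the duplex background
        matches the configured artifact rate."""
        r = 2e-3
        error = ErrorModel(seq_error=0, ss_damage=0, ds_artifact=r)
        fams, refs = self._control_batch(genome, rng, error, 60, 800)
        rate = background_rate([fams], refs)
        n_eval = 60 * 800  # upper bound; SE uses the larger of rate and r
        se = np.sqrt(max(rate, r) / n_eval)
        assert abs(rate - r) < 3 * se
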