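"""The minor/major sub-step rules and pipeline invariants."""

import numpy as np
import pytest

from pedimpute import genotypes as gio
from pedimpute import imputation as imp
from pedimpute.imputation import ImputeConfig, WorkingState
from pedimpute.pedigree import from_records
from pedimpute.phasing import HaplotypeLibrary
from pedimpute.simulate import SimConfig, simulate

from conftest import make_geno


def blank_state(n, s, geno=None):
    return WorkingState(
        phase=np.full((n, s, 2), -1, dtype=np.int8),
        geno=np.full((n, s), 3, dtype=np.int8) if geno is None else geno,
    )


@pytest.fixture
def trio():
    return from_records([("S", "0", "0"), ("D", "0", "0"), ("C", "S", "D")])


class TestMinorSteps:
    def test_minor1_homozygous_parent_fills_gamete(self, trio):
        st = blank_state(3, 2)
        st.phase[0] = [[1, 1], [0, 1]]  # sire hom at snp0, het at snp1
        imp.minor1_parent_homozygous_fill(st, trio)
        assert st.phase[2, 0, 0] == 1  # from hom sire
        assert st.phase[2, 1, 0] == -1  # het parent uninformative

    def test_minor1_idempotent_no_overwrite(self, trio):
        st = blank_state(3, 1)
        st.phase[1, 0] = [0, 0]  # dam hom 0
        st.phase[2, 0, 1] = 0  # already set
        n = imp.minor1_parent_homozygous_fill(st, trio)
        assert n == 0
        assert st.phase[2, 0, 1] == 0

    @pytest.mark.parametrize(
        "geno,known_pat,expect_mat",
        [(1, 0, 1), (2, 1, 1), (1, 1, 0), (0, 0, 0)],
    )
    def test_minor2_complement(self, geno, known_pat, expect_mat):
        st = blank_state(1, 1)
        st.geno[0, 0] = geno
        st.phase[0, 0, 0] = known_pat
        imp.minor2_phase_complement(st)
        assert st.phase[0, 0, 1] == expect_mat

    def test_minor2_impossible_state_logged(self):
        st = blank_state(1, 1)
        st.geno[0, 0] = 0
        st.phase[0, 0, 0] = 1  # genotype 0 with allele 1: conflict
        imp.minor2_phase_complement(st)
        assert st.phase[0, 0, 1] == -1
        assert st.n_conflicts >= 1

    def test_minor3_parent_from_progeny(self, trio):
        st = blank_state(3, 1)
        st.phase[0, 0] = [0, -1]  # sire has a 0, other allele missing
        st.phase[2, 0, 0] = 1  # offspring received a 1 from the sire
        imp.minor3_parents_from_progeny(st, trio)
        assert st.phase[0, 0, 1] == 1

    def test_minor3_consistent_offspring_uninformative(self, trio):
        st = blank_state(3, 1)
        st.phase[0, 0] = [0, -1]
        st.phase[2, 0, 0] = 0  # matches the known allele
        imp.minor3_parents_from_progeny(st, trio)
        assert st.phase[0, 0, 1] == -1

    def test_minor3_requires_exactly_one_known(self, trio):
        st = blank_state(3, 1)
        st.phase[2, 0, 0] = 1
        imp.minor3_parents_from_progeny(st, trio)
        assert (st.phase[0, 0] == -1).all()

    @pytest.mark.parametrize("alleles,expected", [((1, 0), 1), ((1, 1), 2), ((0, 0), 0)])
    def test_minor4_make_genotype(self, alleles, expected):
        st = blank_state(1, 1)
        st.phase[0, 0] = alleles
        imp.minor4_make_genotype(st)
        assert st.geno[0, 0] == expected

    def test_minor4_partial_no_action(self):
        st = blank_state(1, 1)
        st.phase[0, 0, 0] = 1
        imp.minor4_make_genotype(st)
        assert st.geno[0, 0] == 3


class TestVoteKernels:
    def test_library_single_survivor_votes(self):
        gam = np.array([[0, -1, 1, 0]], dtype=np.int8)
        haps = np.array([[0, 1, 1, 0]], dtype=np.int8)
        v0, v1 = imp._library_votes(gam, haps, 0)
        assert v1[0, 1] and not v0[0, 1]

    def test_library_non_unanimous_no_vote(self):
        gam = np.array([[0, -1, 1, 0]], dtype=np.int8)
        haps = np.array([[0, 1, 1, 0], [0, 0, 1, 0]], dtype=np.int8)
        v0, v1 = imp._library_votes(gam, haps, 0)
        assert not v0[0, 1] and not v1[0, 1]

    def test_vote_threshold_application(self):
        st = blank_state(1, 1)
        count0 = np.zeros((1, 1, 2), dtype=np.int16)
        count1 = np.zeros((1, 1, 2), dtype=np.int16)
        count1[0, 0, 0] = 4
        n = imp._apply_vote_counts(st, count0, count1, accept=2, reject=0, step="t")
        assert n == 1 and st.phase[0, 0, 0] == 1

    def test_vote_rejected_when_opposed(self):
        st = blank_state(1, 1)
        count0 = np.zeros((1, 1, 2), dtype=np.int16)
        count1 = np.zeros((1, 1, 2), dtype=np.int16)
        count1[0, 0, 0] = 4
        count0[0, 0, 0] = 1
        n = imp._apply_vote_counts(st, count0, count1, accept=2, reject=0, step="t")
        assert n == 0

    def test_pair_candidates_both_survive_disagree(self):
        gam = np.array([[-1, 1]], dtype=np.int8)
        cands = np.array([[[0, 1], [1, 1]]], dtype=np.int8)
        v0, v1 = imp._pair_candidate_votes(gam, cands, 0)
        assert not v0[0, 0] and not v1[0, 0]  # both survive, disagree at 0
        assert v1[0, 1]  # agree at locus 1

    def test_pair_candidates_unique_survivor(self):
        gam = np.array([[-1, 1]], dtype=np.int8)
        cands = np.array([[[0, 1], [1, 0]]], dtype=np.int8)
        v0, v1 = imp._pair_candidate_votes(gam, cands, 0)
        assert v0[0, 0]  # survivor (0,1) votes 0 at locus 0


class TestMajor8:
    def test_single_origin_full_imputation(self, trio):
        # parent fully phased and het everywhere; child gamete anchored at
        # both ends with the same origin and no crossover
        s = 30
        st = blank_state(3, s)
        st.phase[0, :, 0] = np.tile([0, 1], s // 2)
        st.phase[0, :, 1] = 1 - st.phase[0, :, 0]
        st.geno[2] = 1
        st.phase[2, 0, 0] = st.phase[0, 0, 0]
        st.phase[2, s - 1, 0] = st.phase[0, s - 1, 0]
        st.sync_trust()
        imp.major8_recombination_scan(st, trio, ImputeConfig(), 2)
        assert (st.phase[2, :, 0] == st.phase[0, :, 0]).all()

    def test_planted_crossover_ambiguity_interval_untouched(self, trio):
        s = 40
        st = blank_state(3, s)
        st.phase[0, :, 0] = np.tile([0, 1], s // 2)
        st.phase[0, :, 1] = 1 - st.phase[0, :, 0]
        st.geno[2] = 1
        # child gamete: paternal-strand origin up to snp 10, maternal
        # strand origin from snp 30 (crossover between informative loci)
        truth = np.concatenate([st.phase[0, :20, 0], st.phase[0, 20:, 1]])
        for j in (0, 5, 10):
            st.phase[2, j, 0] = truth[j]
        for j in (30, 35, 39):
            st.phase[2, j, 0] = truth[j]
        st.sync_trust()
        imp.major8_recombination_scan(st, trio, ImputeConfig(), 2)
        got = st.phase[2, :, 0]
        assert (got[:11] == truth[:11]).all()
        assert (got[30:] == truth[30:]).all()
        # strictly between the flanking informative loci: not imputed
        assert (got[11:30][st.phase[2, 11:30, 0] == -1] == -1).all()
        assert (got[11:30] == -1).any()

    def test_recombination_count_threshold_blocks(self, trio):
        s = 40
        st = blank_state(3, s)
        st.phase[0, :, 0] = np.tile([0, 1], s // 2)
        st.phase[0, :, 1] = 1 - st.phase[0, :, 0]
        st.geno[2] = 1
        # alternate origin at every informative locus: many recombinations
        for j in range(0, s, 2):
            origin = (j // 2) % 2
            st.phase[2, j, 0] = st.phase[0, j, origin]
        cfg = ImputeConfig(max_recombinations=(3,), min_double_crossover_gap=(1,),
                           anchor_distance_cap=(1000,))
        st.sync_trust()
        before = st.phase.copy()
        imp.major8_recombination_scan(st, trio, cfg, 0)
        # blocked by the recombination-count restriction: nothing imputed
        # on the paternal gamete beyond complements
        assert (st.phase[2, 1::2, 0] == before[2, 1::2, 0]).all()


class TestPipeline:
    def test_complete_input_is_fixed_point(self, trio):
        g = make_geno(trio, {"S": [0, 2, 1], "D": [0, 2, 2], "C": [0, 2, 1]}, 3)
        res = imp.run_pipeline(trio, g, unmapped_only=True)
        assert np.array_equal(res.genotypes, g.values)
        dosage = res.dosage
        assert np.allclose(dosage, np.round(dosage))
        assert np.allclose(dosage[trio.index["S"]], [0, 2, 1])

    def test_homozygous_parents_force_offspring_exactly(self, trio):
        # offspring of two fully homozygous genotyped parents: dosage
        # equals truth at every SNP, via the parent-homozygous fill alone
        rng = np.random.default_rng(0)
        s = 50
        sire = rng.integers(0, 2, s) * 2
        dam = rng.integers(0, 2, s) * 2
        g = make_geno(trio, {"S": sire, "D": dam}, s)
        res = imp.run_pipeline(trio, g, unmapped_only=True)
        expect = sire / 2 + dam / 2
        assert np.allclose(res.dosage[trio.index["C"]], expect)

    def test_ungenotyped_unrelated_dosage_2p(self):
        ped = from_records([("A", "0", "0"), ("B", "0", "0"), ("L", "0", "0")])
        rows = {"A": [0, 1, 2, 1], "B": [1, 1, 0, 2]}
        g = make_geno(ped, rows, 4)
        res = imp.run_pipeline(ped, g, unmapped_only=True)
        p = gio.allele_frequencies(g, g.genotyped)
        assert np.allclose(res.dosage[ped.index["L"]], 2 * p, atol=1e-6)

    def test_dosage_bounds_and_coherence(self, small_scenario):
        sc = small_scenario
        res = imp.run_pipeline(sc.truth.ped, sc.geno)
        assert (res.dosage >= 0).all() and (res.dosage <= 2).all()
        ph, g = res.phase, res.genotypes
        both = (ph >= 0).all(axis=2)
        known = g != 3
        m = both & known
        assert (ph.sum(axis=2)[m] == g[m]).all()

    def test_monotone_fill_and_determinism(self, small_scenario):
        sc = small_scenario
        r1 = imp.run_pipeline(sc.truth.ped, sc.geno)
        r2 = imp.run_pipeline(sc.truth.ped, sc.geno)
        assert np.array_equal(r1.phase, r2.phase)
        assert np.array_equal(r1.probs, r2.probs)
        # no sub-step reports negative fills; observed data never changed
        assert all(n >= 0 for _, n in r1.fill_log)
        obs = sc.geno.values != 3
        assert np.array_equal(r1.genotypes[obs], sc.geno.values[obs])

    def test_zero_outer_iterations_skips_haplotype_steps(self, small_scenario):
        sc = small_scenario
        cfg = ImputeConfig(n_outer_iterations=0)
        res = imp.run_pipeline(sc.truth.ped, sc.geno, cfg)
        steps = {s for s, n in res.fill_log if n}
        assert "major3" not in steps and "major8" not in steps

    def test_calls_never_contradict_observed(self, small_scenario):
        sc = small_scenario
        res = imp.run_pipeline(sc.truth.ped, sc.geno)
        obs = sc.geno.values
        ph = res.phase
        hom0 = obs == 0
        hom2 = obs == 2
        assert not ((ph[hom0] == 1).any())
        assert not ((ph[hom2] == 0).any())
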