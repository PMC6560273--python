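import numpy as np
import pytest

import convergence as cv
from convergence.phylo_core import AA_INDEX, GAP
from convergence.likelihood import PruningEngine
from conftest import make_alignment

Q, L, Y, V, A_ = (AA_INDEX[x] for x in "QLYVA")


def cartoon_columns(ctree, letters_by_leaf):
    """One column from a dict leaf-name -> aa letter."""
    names = ctree.tree.leaf_names()
    return [AA_INDEX[letters_by_leaf[n]] for n in names]


@pytest.fixture(scope="module")
def example_a(cartoon_ctree):
    # every phenotype transition gains Q; ancestral taxa keep L
    return cartoon_columns(cartoon_ctree, {
        "C1": "Q", "C2": "Q", "C3": "Q",
        "A1": "L", "A2": "L", "A3": "L", "A4": "L", "A5": "L"})


@pytest.fixture(scope="module")
def example_e(cartoon_ctree):
    # substitutions uncorrelated with the phenotype
    return cartoon_columns(cartoon_ctree, {
        "C1": "Q", "C2": "L", "C3": "Q",
        "A1": "Q", "A2": "L", "A3": "L", "A4": "L", "A5": "L"})


class TestIdentical:
    def test_perfect_convergence_scores_one(self, cartoon_ctree, example_a):
        aln = make_alignment(cartoon_ctree, [example_a])
        s = cv.detect_identical(aln, cartoon_ctree)
        assert s.raw[0] == 1.0

    def test_uncorrelated_pattern_not_flagged(self, cartoon_ctree,
                                              example_e):
        aln = make_alignment(cartoon_ctree, [example_e])
        s = cv.detect_identical(aln, cartoon_ctree)
        assert s.raw[0] < 1.0

    def test_constant_column_scores_zero(self, cartoon_ctree):
        aln = make_alignment(cartoon_ctree, [[L] * 8])
        s = cv.detect_identical(aln, cartoon_ctree)
        assert s.raw[0] == 0.0

    def test_requires_transitions(self, cartoon_ctree):
        bare = cv.ConditionedTree(
            tree=cartoon_ctree.tree,
            is_convergent=np.zeros(cartoon_ctree.tree.n_nodes, bool),
            is_transition=np.zeros(cartoon_ctree.tree.n_nodes, bool))
        aln = make_alignment(cartoon_ctree, [[L] * 8])
        with pytest.raises(ValueError):
            cv.detect_identical(aln, bare)


class TestConvergentTopology:
    def test_single_clade_is_identity(self, four_leaf_ctree):
        out = cv.build_convergent_topology(four_leaf_ctree)
        assert out is four_leaf_ctree.tree

    def test_clades_grouped(self, cartoon_ctree):
        out = cv.build_convergent_topology(cartoon_ctree)
        conv = {"C1", "C2", "C3"}
        # some node's subtree leaf set must be exactly the convergent taxa
        subtrees = [{out.names[u] for u in out.subtree(v) if out.is_leaf(u)}
                    for v in range(out.n_nodes)]
        assert conv in subtrees

    def test_leaf_set_preserved(self, cartoon_ctree):
        out = cv.build_convergent_topology(cartoon_ctree)
        assert sorted(out.leaf_names()) == \
            sorted(cartoon_ctree.tree.leaf_names())

    def test_branch_lengths_preserved(self, cartoon_ctree):
        out = cv.build_convergent_topology(cartoon_ctree)
        # convergent pendant branches move unchanged
        for name in ("C1", "C2", "C3"):
            assert out.lengths[out.node_by_name(name)] == pytest.approx(0.4)
        # A1-A3 lose their pruned sibling, so the suppressed unifurcation
        # absorbs the 0.3 stem into the pendant branch
        for name in ("A1", "A2", "A3"):
            assert out.lengths[out.node_by_name(name)] == pytest.approx(0.7)
        # the intact A4/A5 cherry keeps its pendants
        for name in ("A4", "A5"):
            assert out.lengths[out.node_by_name(name)] == pytest.approx(0.4)


class TestTopological:
    def test_monophyletic_convergents_score_zero(self, four_leaf_ctree,
                                                 uniform_model):
        aln = make_alignment(four_leaf_ctree, [[Q, Q, L, L], [L, L, L, L]])
        s = cv.detect_topological(aln, four_leaf_ctree, model=uniform_model)
        np.testing.assert_allclose(s.raw, 0.0, atol=1e-12)

    def test_interleaved_convergence_scores_positive(self, cartoon_ctree,
                                                     uniform_model,
                                                     example_a):
        aln = make_alignment(cartoon_ctree, [example_a])
        s = cv.detect_topological(aln, cartoon_ctree, model=uniform_model)
        assert s.raw[0] > 0.0

    def test_invariant_to_consistent_relabelling(self, cartoon_ctree,
                                                 uniform_model, example_a):
        relabelled = [(s + 3) % 20 for s in example_a]
        s1 = cv.detect_topological(make_alignment(cartoon_ctree,
                                                  [example_a]),
                                   cartoon_ctree, model=uniform_model)
        s2 = cv.detect_topological(make_alignment(cartoon_ctree,
                                                  [relabelled]),
                                   cartoon_ctree, model=uniform_model)
        assert s1.raw[0] == pytest.approx(s2.raw[0], rel=1e-10)


class TestMultinomial:
    def _aln(self, anc, conv):
        taxa = [f"a{i}" for i in range(len(anc))] + \
               [f"c{i}" for i in range(len(conv))]
        conditions = {t: ("ancestral" if t.startswith("a") else "convergent")
                      for t in taxa}
        states = np.array(anc + conv, dtype=int).reshape(-1, 1)
        return cv.Alignment(taxa=taxa, states=states, kind="aa"), conditions

    def test_identical_vectors_score_zero(self):
        aln, cond = self._aln([L] * 10, [L] * 10)
        s = cv.detect_multinomial(aln, cond)
        assert s.raw[0] == 0.0 and s.pvalue[0] == 1.0

    def test_disjoint_vectors_hand_computed(self):
        # 10 L vs 10 V: pooled expectation 5 per cell, chi2 = 4 * 25/5 = 20
        aln, cond = self._aln([L] * 10, [V] * 10)
        s = cv.detect_multinomial(aln, cond)
        assert s.raw[0] == pytest.approx(20.0, rel=1e-12)

    def test_symmetric_under_group_swap(self):
        a1, c1 = self._aln([L] * 6 + [Q] * 2, [V] * 5 + [Q] * 3)
        s1 = cv.detect_multinomial(a1, c1)
        swapped = {t: ("convergent" if v == "ancestral" else "ancestral")
                   for t, v in c1.items()}
        s2 = cv.detect_multinomial(a1, swapped)
        assert s1.raw[0] == pytest.approx(s2.raw[0], rel=1e-12)

    def test_fully_gapped_group_undefined(self):
        aln, cond = self._aln([GAP] * 4, [L] * 4)
        s = cv.detect_multinomial(aln, cond)
        assert np.isnan(s.raw[0]) and np.isnan(s.score[0])

    def test_one_group_empty_rejected(self):
        aln, cond = self._aln([L] * 4, [])
        with pytest.raises(ValueError):
            cv.detect_multinomial(aln, cond)


class TestTDG09Profiles:
    def test_count_threshold_rule(self):
        col = [A_] * 5 + [AA_INDEX["S"]] * 2 + [AA_INDEX["C"]]
        prof, _, _ = cv.tdg09_profiles(col, [False] * len(col))
        assert prof[A_] == pytest.approx(5 / 7)
        assert prof[AA_INDEX["S"]] == pytest.approx(2 / 7)
        assert prof[AA_INDEX["C"]] == 0.0

    def test_single_state(self):
        prof, _, _ = cv.tdg09_profiles([A_, A_, A_], [False] * 3)
        assert prof[A_] == 1.0 and prof.sum() == 1.0

    def test_all_singletons_fallback(self):
        col = [A_, AA_INDEX["S"], AA_INDEX["C"]]
        prof, _, _ = cv.tdg09_profiles(col, [False] * 3)
        for s in col:
            assert prof[s] == pytest.approx(1 / 3)


class TestTDG09:
    def test_constant_column_statistic_zero(self, cartoon_ctree):
        aln = make_alignment(cartoon_ctree, [[L] * 8])
        s = cv.detect_tdg09(aln, cartoon_ctree)
        assert s.raw[0] == 0.0 and s.pvalue[0] == 1.0

    def test_statistics_non_negative(self, cartoon_ctree, example_a,
                                     example_e):
        aln = make_alignment(cartoon_ctree, [example_a, example_e, [L] * 8])
        s = cv.detect_tdg09(aln, cartoon_ctree)
        assert np.all(s.raw >= 0.0)

    def test_strong_profile_change_beats_null_distribution(self, mut, code):
        # simulate H0 sites and one hard profile-change site on a 16-leaf
        # tree; the alternative statistic should exceed the empirical null
        ctree = cv.generate_benchmark_tree(16, 3, seed=4)
        lib = cv.generate_profile_library(30, seed=6)
        sc0 = cv.SimulationScenario(case="profile_change", library=lib,
                                    n_sites=200, fraction_convergent=0.0,
                                    nes_ancestral=4.0, seed=13)
        aln0, _ = cv.simulate_benchmark(ctree, sc0, mut=mut)
        null = cv.detect_tdg09(cv.translate(aln0), ctree).raw
        # deterministic extreme pattern: every convergent leaf switched
        conv = [ctree.is_convergent[v] for v in ctree.tree.leaves()]
        col = [Q if c else L for c in conv]
        aln1 = make_alignment(ctree, [col])
        stat = cv.detect_tdg09(aln1, ctree).raw[0]
        assert stat > np.quantile(null, 0.99)


@pytest.fixture(scope="module")
def pair_library():
    l_rich = np.full(20, 0.01)
    l_rich[L] = 0.81
    qy_rich = np.full(20, 0.01)
    qy_rich[Q] = qy_rich[Y] = 0.41
    return cv.ProfileLibrary(profiles=[
        cv.FitnessProfile.from_frequencies(l_rich / l_rich.sum(),
                                           id="Lrich"),
        cv.FitnessProfile.from_frequencies(qy_rich / qy_rich.sum(),
                                           id="QYrich"),
    ])


class TestPCOC:
    def test_single_profile_library_rejected(self, cartoon_ctree):
        lib = cv.ProfileLibrary(
            profiles=cv.generate_profile_library(1, seed=0).profiles)
        aln = make_alignment(cartoon_ctree, [[L] * 8])
        with pytest.raises(ValueError):
            cv.detect_pcoc(aln, cartoon_ctree, lib)

    def test_profile_change_with_type2_detected(self, cartoon_ctree,
                                                pair_library):
        # convergent clades mix Q and Y (type 2 substitutions), ancestral
        # taxa keep L
        col = cartoon_columns(cartoon_ctree, {
            "C1": "Q", "C2": "Y", "C3": "Q",
            "A1": "L", "A2": "L", "A3": "L", "A4": "L", "A5": "L"})
        aln = make_alignment(cartoon_ctree, [col])
        s = cv.detect_pcoc(aln, cartoon_ctree, pair_library)
        assert s.raw[0] > 0.0

    def test_one_change_constraint_penalises_no_change(self, cartoon_ctree,
                                                       pair_library):
        # when convergent leaves retain the ancestral state, conditioning
        # on a change on transition branches can only lose likelihood
        col = [L] * 8
        aln = make_alignment(cartoon_ctree, [col])
        states = np.array(col).reshape(-1, 1)
        m_a = cv.AAModel.homogeneous(pair_library[0].frequencies)
        m_pair = cv.AAModel(freqs={
            "ancestral": pair_library[0].frequencies,
            "convergent": pair_library[1].frequencies})
        ll_oc = PruningEngine(cartoon_ctree, m_pair,
                              oc_on_transitions=True).loglik(states)[0]
        ll_free = PruningEngine(cartoon_ctree, m_pair).loglik(states)[0]
        assert ll_oc <= ll_free

    def test_score_monotone_in_library(self, cartoon_ctree, pair_library,
                                       library):
        col = cartoon_columns(cartoon_ctree, {
            "C1": "Q", "C2": "Y", "C3": "Q",
            "A1": "L", "A2": "L", "A3": "L", "A4": "L", "A5": "L"})
        aln = make_alignment(cartoon_ctree, [col])
        base = cv.detect_pcoc(aln, cartoon_ctree, library)
        augmented = cv.ProfileLibrary(
            profiles=library.profiles + pair_library.profiles)
        bigger = cv.detect_pcoc(aln, cartoon_ctree, augmented)
        assert bigger.raw[0] >= base.raw[0]
        assert bigger.raw[0] > 0.0


class TestStandardize:
    def test_pvalue_transform(self):
        s = cv.SiteScores(method="multinomial",
                          raw=np.array([1.0, 2.0, 3.0]),
                          pvalue=np.array([0.01, 1.0, np.nan]))
        out = cv.standardize(s)
        assert out.score[0] == pytest.approx(2.0)
        assert out.score[1] == 0.0
        assert np.isnan(out.score[2])

    def test_pvalue_floor(self):
        s = cv.SiteScores(method="tdg09", raw=np.array([1.0]),
                          pvalue=np.array([0.0]))
        out = cv.standardize(s)
        assert out.score[0] == pytest.approx(300.0)

    def test_likelihood_methods_keep_raw(self):
        s = cv.SiteScores(method="pcoc", raw=np.array([-1.5, 2.5]))
        out = cv.standardize(s)
        np.testing.assert_array_equal(out.score, s.raw)


class TestSiteEquivariance:
    def test_scores_follow_site_permutation(self, cartoon_ctree, example_a,
                                            example_e):
        cols = [example_a, example_e, [L] * 8, [Q] * 8]
        aln = make_alignment(cartoon_ctree, cols)
        perm = [2, 0, 3, 1]
        aln_p = make_alignment(cartoon_ctree, [cols[i] for i in perm])
        for method in ("identical", "multinomial", "tdg09"):
            s = cv.run_method(method, aln, cartoon_ctree)
            sp = cv.run_method(method, aln_p, cartoon_ctree)
            np.testing.assert_allclose(sp.raw, s.raw[perm], rtol=1e-10)


class TestScalingInsensitivity:
    def test_profile_methods_blind_to_pure_nes_scaling(self):
        # efficacy scaling alone (4 -> 8) leaves profile detectors without
        # signal: Ha scores are not stochastically greater than H0 scores
        from scipy.stats import mannwhitneyu
        ctree = cv.generate_benchmark_tree(24, 4, seed=3)
        lib = cv.generate_profile_library(50, seed=8)
        sc = cv.SimulationScenario(case="nes_scaling", library=lib,
                                   n_sites=300, fraction_convergent=0.5,
                                   nes_ancestral=4.0, nes_convergent=8.0,
                                   seed=17)
        aln, truth = cv.simulate_benchmark(ctree, sc)
        for method in ("multinomial", "tdg09"):
            s = cv.run_method(method, aln, ctree)
            ha = s.score[truth.labels & ~np.isnan(s.score)]
            h0 = s.score[~truth.labels & ~np.isnan(s.score)]
            p = mannwhitneyu(ha, h0, alternative="greater").pvalue
            assert p > 0.01
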