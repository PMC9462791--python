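import numpy as np
import pandas as pd
import pytest

from ctsevo.epistasis import (EffectComparison, binarize_divergence,
                              divergence_effect_correlation,
                              divergence_matrix, enumerate_comparisons,
                              group_sites, nested_anova_select,
                              permutation_null, substitution_effect,
                              top_groups_r2, variant_sites)
from ctsevo.io_core import Alignment


@pytest.mark.parametrize("wt,mut,expected", [
    (10.0, 15.0, 50.0), (10.0, 10.0, 0.0), (8.0, 2.0, -75.0)])
def test_substitution_effect(wt, mut, expected):
    assert substitution_effect(wt, mut) == pytest.approx(expected)


def test_nonpositive_wildtype_rejected():
    with pytest.raises(ValueError):
        substitution_effect(0.0, 5.0)


class TestEnumerateComparisons:
    def _panel(self, rows):
        return pd.DataFrame(rows, columns=["background", "site", "to_state",
                                           "wt_activity", "mut_activity"])

    def test_two_backgrounds_one_comparison(self):
        panel = self._panel([("CHI", 122, "D", 10.0, 12.0),
                             ("FER", 122, "D", 8.0, 6.0)])
        comps = enumerate_comparisons(panel)
        assert len(comps) == 1
        c = comps[0]
        assert c.backgrounds == ("CHI", "FER")
        # E_CHI = +20, E_FER = -25 -> delta 45
        assert c.delta == pytest.approx(45.0)

    def test_same_background_twice_excluded(self):
        panel = self._panel([("CHI", 122, "D", 10.0, 12.0),
                             ("CHI", 122, "D", 10.0, 13.0)])
        assert enumerate_comparisons(panel) == []

    def test_hand_enumeration_five_constructs(self):
        panel = self._panel([
            ("B1", 111, "R", 10, 12), ("B2", 111, "R", 10, 14),
            ("B3", 111, "R", 10, 9), ("B1", 122, "D", 10, 11),
            ("B2", 122, "H", 10, 8)])
        comps = enumerate_comparisons(panel)
        # site 111 state R on 3 backgrounds -> 3 pairs; 122 D and H never
        # shared -> 0
        keys = {(c.site, c.state, c.backgrounds) for c in comps}
        assert keys == {(111, "R", ("B1", "B2")), (111, "R", ("B1", "B3")),
                        (111, "R", ("B2", "B3"))}


class TestDivergence:
    def _aln(self):
        return Alignment(ids=["B1", "B2", "B3"],
                         matrix=np.array([list("QNARK"), list("QNGRK"),
                                          list("RN-RK")]),
                         column_labels=[111, 122, 300, 301, 302])

    def test_variant_sites(self):
        assert variant_sites(self._aln()) == [111, 300]

    def test_identical_backgrounds_all_zero(self):
        v = binarize_divergence(self._aln(), "B1", "B1", [111, 300])
        assert v.tolist() == [0, 0]

    def test_single_differing_site(self):
        v = binarize_divergence(self._aln(), "B1", "B2", [111, 300])
        assert v.tolist() == [0, 1]

    def test_gap_counts_as_different(self):
        v = binarize_divergence(self._aln(), "B1", "B3", [111, 300])
        assert v.tolist() == [1, 1]

    def test_vector_sum_is_hand_distance(self):
        aln = self._aln()
        sites = variant_sites(aln)
        v = binarize_divergence(aln, "B2", "B3", sites)
        assert v.sum() == 2  # 111 Q/R and 300 G/-


class TestGroupSites:
    def test_duplicated_columns_one_group(self):
        div = pd.DataFrame({"a": [0, 1, 0, 1], "b": [0, 1, 0, 1],
                            "c": [1, 0, 1, 0]})
        groups = group_sites(div, 0.8)
        members = sorted(tuple(g.sites) for g in groups)
        # perfect |r|=1 everywhere: one connected component
        assert members == [("a", "b", "c")]

    def test_orthogonal_columns_separate(self):
        div = pd.DataFrame({"a": [0, 0, 1, 1], "b": [0, 1, 0, 1]})
        groups = group_sites(div, 0.8)
        assert sorted(tuple(g.sites) for g in groups) == [("a",), ("b",)]

    def test_zero_variance_column_own_group(self):
        div = pd.DataFrame({"a": [1, 1, 1, 1], "b": [0, 1, 0, 1]})
        groups = group_sites(div, 0.8)
        assert sorted(tuple(g.sites) for g in groups) == [("a",), ("b",)]

    def test_hand_correlation_graph(self):
        div = pd.DataFrame({
            1: [0, 0, 1, 1, 0, 1], 2: [0, 0, 1, 1, 0, 1],  # r(1,2)=1
            3: [1, 1, 0, 0, 1, 0],                          # r(1,3)=-1
            4: [0, 1, 0, 1, 0, 1], 5: [0, 1, 0, 1, 1, 1],   # r(4,5)~0.63
            6: [1, 0, 0, 1, 1, 0]})
        groups = group_sites(div, 0.8)
        members = sorted(tuple(g.sites) for g in groups)
        assert (1, 2, 3) in members       # |r| = 1 triangle
        assert ((4,) in members and (5,) in members)  # r below 0.8
        assert (6,) in members

    def test_groups_partition_sites(self):
        rng = np.random.default_rng(8)
        div = pd.DataFrame(rng.integers(0, 2, size=(11, 30)),
                           columns=range(30))
        groups = group_sites(div, 0.8)
        all_sites = sorted(s for g in groups for s in g.sites)
        assert all_sites == list(range(30))


class TestNestedSelection:
    def _setup(self, rng, n=12, n_sites=8):
        div = pd.DataFrame(rng.integers(0, 2, size=(n, n_sites)),
                           columns=range(n_sites))
        groups = group_sites(div, 0.8)
        return div, groups

    def test_exact_linear_signal_found_first(self):
        rng = np.random.default_rng(31)
        div, groups = self._setup(rng)
        target = groups[0].representative
        delta = 10.0 * div[target].to_numpy(float)
        sel = nested_anova_select(delta, div, groups, criterion="AIC")
        ordered_first = sel.table.loc[1, "R2"]
        assert ordered_first == pytest.approx(1.0, abs=1e-9)
        assert target in sel.selected_sites

    def test_r2_never_decreases_along_nesting(self):
        rng = np.random.default_rng(32)
        div, groups = self._setup(rng)
        delta = rng.normal(size=len(div))
        sel = nested_anova_select(delta, div, groups)
        r2 = sel.table["R2"].to_numpy()
        assert np.all(np.diff(r2) >= -1e-12)

    def test_pure_noise_selects_null_under_aic(self):
        rng = np.random.default_rng(33)
        chosen = []
        for _ in range(200):
            div, groups = self._setup(rng, n=14, n_sites=6)
            delta = rng.normal(size=14)
            sel = nested_anova_select(delta, div, groups, criterion="AIC")
            chosen.append(sel.best_n_groups)
        # under pure noise AIC keeps the covariate-only model most often
        assert np.mean(np.array(chosen) == 0) > 0.5


class TestPermutationNull:
    def test_perfect_signal_small_p(self):
        rng = np.random.default_rng(41)
        div = pd.DataFrame(rng.integers(0, 2, size=(12, 10)),
                           columns=range(10))
        groups = group_sites(div, 0.8)
        # signal spanned by a single group: its marginal R2 is 1, so the
        # ascertained top-2 model always contains it
        delta = 7.0 * div[groups[0].representative].to_numpy(float)
        obs, sites, null, p = permutation_null(delta, div, groups,
                                               n_perm=200, seed=5)
        assert obs == pytest.approx(1.0, abs=1e-9)
        assert p <= 0.05

    def test_constant_delta_p_one(self):
        rng = np.random.default_rng(42)
        div = pd.DataFrame(rng.integers(0, 2, size=(10, 6)),
                           columns=range(6))
        groups = group_sites(div, 0.8)
        delta = np.full(10, 3.0)
        obs, sites, null, p = permutation_null(delta, div, groups,
                                               n_perm=100, seed=6)
        assert p == 1.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(43)
        div = pd.DataFrame(rng.integers(0, 2, size=(11, 8)),
                           columns=range(8))
        groups = group_sites(div, 0.8)
        delta = rng.normal(size=11)
        r1 = permutation_null(delta, div, groups, n_perm=150, seed=9)
        r2 = permutation_null(delta, div, groups, n_perm=150, seed=9)
        assert r1[3] == r2[3]
        assert np.allclose(r1[2], r2[2])

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_null(np.ones(5), pd.DataFrame({1: [0, 1, 0, 1, 0]}),
                             [], n_perm=10)


class TestDivergenceEffectCorrelation:
    def _div(self):
        return pd.DataFrame({1: [0, 1, 1, 0, 1], 2: [0, 0, 1, 1, 1],
                             3: [1, 0, 0, 0, 1]})

    def test_proportional_delta_r_one(self):
        div = self._div()
        counts = div[[1, 2]].sum(axis=1).to_numpy(float)
        r, p = divergence_effect_correlation(4.0 * counts, div, [1, 2],
                                             n_perm=200, seed=1)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_hand_covariance(self):
        div = self._div()
        delta = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        x = div[[1, 3]].sum(axis=1).to_numpy(float)
        hand = (np.mean(delta * x) - delta.mean() * x.mean()) / (
            np.std(delta) * np.std(x))
        r, _ = divergence_effect_correlation(delta, div, [1, 3],
                                             n_perm=100, seed=2)
        assert r == pytest.approx(hand)

    def test_empty_site_set_rejected(self):
        with pytest.raises(ValueError):
            divergence_effect_correlation(np.ones(3), self._div().iloc[:3],
                                          [], n_perm=100)


def test_selected_model_r2_equals_independent_rss_ratio():
    rng = np.random.default_rng(55)
    div = pd.DataFrame(rng.integers(0, 2, size=(11, 12)), columns=range(12))
    groups = group_sites(div, 0.8)
    delta = rng.normal(10, 3, size=11)
    obs, sites, _, _ = permutation_null(delta, div, groups, n_perm=100,
                                        seed=3)
    assert 0.0 <= obs <= 1.0
    # independent R2: regress delta on the two chosen representatives
    ordered = sorted(groups, key=lambda g: -abs(np.corrcoef(
        div[g.representative], delta)[0, 1]) if div[g.representative].std()
        else 0.0)
    X = np.column_stack([np.ones(11)] +
                        [div[g.representative].to_numpy(float)
                         for g in ordered[:2]])
    beta, *_ = np.linalg.lstsq(X, delta, rcond=None)
    rss = np.sum((delta - X @ beta) ** 2)
    tss = np.sum((delta - delta.mean()) ** 2)
    # the ascertainment chooses by marginal R2 which equals |r| ranking
    assert obs == pytest.approx(1 - rss / tss, abs=1e-6)
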