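import numpy as np
import pytest
from scipy.stats import kstest

from ctsevo import convergence as cv
from ctsevo.convergence import (SubstitutionEvent, cd_ratio, classify_pair,
                                comparable_pairs, convergence_distance_regression,
                                event_outcome_table, extract_substitutions,
                                pair_distance, pair_table, running_trend)
from ctsevo.io_core import Phylogeny


def ev(branch, site, anc, der):
    return SubstitutionEvent(branch, site, anc, der, 0.95, 0.95)


class TestExtractSubstitutions:
    def setup_method(self):
        # ((A,B)N1,(C,D)N2)R with hand-planted states at two sites
        self.tree = Phylogeny.from_newick_string(
            "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        self.ids = {self.tree.labels.get(n, n): n for n in self.tree.nodes()}

    def _states(self, assign):
        """assign: node label/id -> {site: state}; PP set to 0.95."""
        return {self.ids.get(k, k): {s: (st, 0.95) for s, st in v.items()}
                for k, v in assign.items()}

    def test_no_event_when_states_equal(self):
        tree = self.tree
        root = tree.root
        n1 = tree.parent[self.ids["A"]]
        states = self._states({root: {1: "Q"}, n1: {1: "Q"}, "A": {1: "Q"},
                               "B": {1: "Q"}})
        events = extract_substitutions(states, tree)
        assert events == []

    def test_missing_parent_masks_site(self):
        tree = self.tree
        n1 = tree.parent[self.ids["A"]]
        states = self._states({n1: {1: "X"}, "A": {1: "R"}})
        assert extract_substitutions(states, tree) == []

    def test_hand_enumeration(self):
        tree = self.tree
        root, a, b = tree.root, self.ids["A"], self.ids["B"]
        n1 = tree.parent[a]
        n2 = tree.parent[self.ids["C"]]
        states = self._states({
            root: {111: "Q", 122: "N"},
            n1: {111: "Q", 122: "N"}, n2: {111: "R", 122: "N"},
            "A": {111: "R", 122: "N"}, "B": {111: "Q", 122: "D"},
            "C": {111: "R", 122: "N"}, "D": {111: "L", 122: "N"},
        })
        events = extract_substitutions(states, tree)
        got = {(e.branch, e.site, e.ancestral, e.derived) for e in events}
        expected = {(a, 111, "Q", "R"), (b, 122, "N", "D"),
                    (n2, 111, "Q", "R"), (self.ids["D"], 111, "R", "L")}
        assert got == expected

    def test_excluded_range_dropped(self):
        tree = self.tree
        a = self.ids["A"]
        n1 = tree.parent[a]
        states = self._states({n1: {810: "Q", 840: "Q", 841: "Q"},
                               "A": {810: "R", 840: "R", 841: "R"}})
        events = extract_substitutions(states, tree, exclude_sites=(810, 840))
        assert [(e.site) for e in events] == [841]


class TestClassifyPair:
    def test_parallel_is_convergent(self):
        assert classify_pair([ev(1, 111, "Q", "R")],
                             [ev(2, 111, "Q", "R")]) == (1, 0)

    def test_same_ancestor_different_derived_is_divergent(self):
        assert classify_pair([ev(1, 111, "Q", "R")],
                             [ev(2, 111, "Q", "L")]) == (0, 1)

    def test_different_ancestor_same_derived_is_convergent(self):
        # convergence is defined by the shared derived state only
        assert classify_pair([ev(1, 111, "E", "R")],
                             [ev(2, 111, "Q", "R")]) == (1, 0)

    def test_different_ancestor_different_derived_is_neither(self):
        assert classify_pair([ev(1, 111, "E", "H")],
                             [ev(2, 111, "Q", "L")]) == (0, 0)

    def test_disjoint_sites_do_not_count(self):
        assert classify_pair([ev(1, 111, "Q", "R")],
                             [ev(2, 122, "N", "D")]) == (0, 0)


@pytest.mark.parametrize("C,D,expected", [(0, 0, 1.0), (3, 1, 2.0),
                                          (7, 3, 2.0), (0, 4, 0.2)])
def test_cd_ratio(C, D, expected):
    assert cd_ratio(C, D) == pytest.approx(expected)


def test_cd_ratio_monotonicity():
    assert cd_ratio(5, 2) > cd_ratio(4, 2)
    assert cd_ratio(5, 3) < cd_ratio(5, 2)
    assert cd_ratio(0, 7) >= 1 / 8


class TestPairEnumeration:
    def test_balanced_eight_tip_count(self, balanced_eight_tip_tree):
        # 14 branches; C(14,2)=91 minus 7 sister pairs minus 20
        # ancestor-descendant pairs = 64
        assert len(comparable_pairs(balanced_eight_tip_tree)) == 64

    def test_no_sisters_or_nested_pairs(self, balanced_eight_tip_tree):
        t = balanced_eight_tip_tree
        for b1, b2 in comparable_pairs(t):
            assert t.parent[b1] != t.parent[b2]
            assert not t.is_ancestor(b1, b2)
            assert not t.is_ancestor(b2, b1)


class TestPairDistance:
    def test_cousin_branches_hand_sum(self):
        t = Phylogeny.from_newick_string(
            "(((A:0.5,B:0.4):0.1,(C:0.3,D:0.2):0.2):0.05,E:1);")
        a, c = t.tip_for_label("A"), t.tip_for_label("C")
        # path A..C through the two stems: 0.1 + 0.2
        assert pair_distance(t, a, c) == pytest.approx(0.3)

    def test_siblings_children_one_node_apart(self):
        t = Phylogeny.from_newick_string(
            "((A:0.5,B:0.4):0.3,(C:0.3,D:0.2):0.0);")
        a, c = t.tip_for_label("A"), t.tip_for_label("C")
        assert pair_distance(t, a, c) == pytest.approx(0.3)

    def test_symmetry(self, balanced_eight_tip_tree):
        t = balanced_eight_tip_tree
        for b1, b2 in comparable_pairs(t)[:10]:
            assert pair_distance(t, b1, b2) == pair_distance(t, b2, b1)

    def test_nested_pair_rejected(self):
        t = Phylogeny.from_newick_string("((A:1,B:1):1,C:2);")
        a = t.tip_for_label("A")
        n1 = t.parent[a]
        with pytest.raises(ValueError):
            pair_distance(t, n1, a)


class TestRunningTrend:
    def _pairs(self, ratios, distances):
        import pandas as pd
        return pd.DataFrame({"ratio": ratios, "distance": distances})

    def test_flat_input_gives_flat_trend(self):
        pairs = self._pairs([2.0] * 20, np.linspace(0, 0.3, 20))
        trend = running_trend(pairs, seed=1)
        assert np.allclose(trend["mean"], 2.0)
        assert np.allclose(trend["hi"] - trend["lo"], 0.0)

    def test_seeded_bootstrap_reproducible(self):
        rng = np.random.default_rng(3)
        pairs = self._pairs(rng.uniform(0.5, 3, 50), rng.uniform(0, 0.4, 50))
        t1 = running_trend(pairs, seed=11)
        t2 = running_trend(pairs, seed=11)
        assert t1.equals(t2)

    def test_window_mean_matches_hand_mean(self):
        vals = [1.0, 2.0, 3.0, 1.5, 2.5, 0.5, 1.0, 2.0, 3.5, 0.5]
        pairs = self._pairs(vals, [0.01 * i for i in range(10)])
        trend = running_trend(pairs, window=1.0, step=1.0, seed=1)
        assert trend["mean"].iloc[0] == pytest.approx(np.mean(vals))


def _grid_logistic_mle(x, y):
    """Independent oracle: two-stage grid search of the logistic
    log-likelihood over (intercept, slope)."""
    def lnl(b0, b1):
        eta = b0 + b1 * x
        return np.sum(y * eta - np.log1p(np.exp(eta)))

    b0s = np.linspace(-10, 10, 81)
    b1s = np.linspace(-40, 40, 161)
    best = max(((lnl(a, b), a, b) for a in b0s for b in b1s))
    for _ in range(4):
        _, a0, b0 = best
        b0s = np.linspace(a0 - 0.5, a0 + 0.5, 81)
        b1s = np.linspace(b0 - 2, b0 + 2, 81)
        best = max(((lnl(a, b), a, b) for a in b0s for b in b1s))
        b0s = np.linspace(best[1] - 0.02, best[1] + 0.02, 81)
        b1s = np.linspace(best[2] - 0.08, best[2] + 0.08, 81)
        best = max(((lnl(a, b), a, b) for a in b0s for b in b1s))
    return best[2]


class TestConvergenceRegression:
    def _table(self, outcome, distance):
        import pandas as pd
        return pd.DataFrame({"outcome": outcome, "distance": distance,
                             "b1": 0, "b2": 1, "site": 111})

    def test_slope_matches_grid_oracle(self):
        x = np.array([0.05, 0.10, 0.20, 0.30, 0.40, 0.50])
        y = np.array([1, 1, 0, 1, 0, 0])
        slope, p, flag = convergence_distance_regression(self._table(y, x))
        assert flag == "ok"
        assert slope == pytest.approx(_grid_logistic_mle(x, y), abs=1e-3)

    def test_null_simulation_uniform_p(self):
        rng = np.random.default_rng(17)
        slopes, ps = [], []
        for _ in range(40):
            x = rng.uniform(0, 1, 500)
            y = rng.integers(0, 2, 500)
            s, p, flag = convergence_distance_regression(self._table(y, x))
            slopes.append(s)
            ps.append(p)
        assert abs(np.mean(slopes)) < 0.2
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_outcomes_flagged(self):
        s, p, flag = convergence_distance_regression(
            self._table([1, 1, 1], [0.1, 0.2, 0.3]))
        assert flag == "degenerate"


def test_planted_convergence_recovered_end_to_end():
    """Planted convergent events at a focal site produce at least the
    planted number of convergent branch pairs when counted from the true
    states."""
    from ctsevo import asr, simulate
    tree = simulate.simulate_tree(16, seed=31)
    tree = simulate.scale_tree_depth(tree, 0.4)
    planted = simulate.PlantedConvergence(focal_sites=(5,), probability=0.5,
                                          target_state="R")
    aln, truth, events = simulate.simulate_alignment(
        tree, asr.jtt_model(shape=0.7), 10, planted=planted, seed=32)
    # brute-force convergent-pair count at the focal site from truth
    focal = events[(events.site == 5) & (events.derived == "R")]
    ev_objs = [SubstitutionEvent(r.branch, r.site, r.ancestral, r.derived,
                                 1.0, 1.0) for r in events.itertuples()]
    pairs = pair_table(tree, ev_objs)
    branches = set(focal.branch)
    hand_C = sum(1 for r in pairs.itertuples()
                 if r.b1 in branches and r.b2 in branches)
    got_C = sum(r.C for r in pairs.itertuples()
                if r.b1 in branches and r.b2 in branches)
    assert got_C >= hand_C > 0
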