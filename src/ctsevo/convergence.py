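"""Convergent/divergent substitution counting across branch pairs.

Substitutions are called per branch from thresholded ancestral (and tip)
states; every unordered branch pair other than sister branches and
ancestor-descendant pairs is compared; substitutions on two branches at the
same site to the same derived state count as convergences, substitutions
away from a common ancestral state to different derived states as
divergences. The per-pair summary statistic is (C+1)/(D+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_core import Alignment, Phylogeny


@dataclass(frozen=True)
class SubstitutionEvent:
    branch: int  # child-node id of the branch
    site: int  # reference site label (or column index if unlabelled)
    ancestral: str
    derived: str
    pp_ancestral: float
    pp_derived: float

    def __post_init__(self):
        if self.ancestral == self.derived:
            raise ValueError("ancestral and derived states must differ")


def node_states(calls: pd.DataFrame, alignment: Alignment,
                tree: Phylogeny) -> dict[int, dict]:
    """Merge internal-node calls with observed tip states into one
    node -> {site: (state, pp)} map. Tip states carry PP 1."""
    states: dict[int, dict] = {}
    for node, grp in calls.groupby("node"):
        states[node] = {r.site: (r.state, r.pp) for r in grp.itertuples()
                        if r.site is not None}
    for tip in tree.tips():
        row = alignment.row(tree.labels[tip])
        states[tip] = {site: (row[alignment.column_of_site(site)], 1.0)
                       for site in alignment.sites()}
    return states


def extract_substitutions(states: dict[int, dict], tree: Phylogeny,
                          exclude_sites: tuple[int, int] | None = None
                          ) -> list[SubstitutionEvent]:
    """One event per (branch, site) where parent and child states are both
    called (not missing/gap) and differ; sites within ``exclude_sites``
    (an inclusive label range) are dropped."""
    events = []
    for child, parent in tree.parent.items():
        child_states = states.get(child, {})
        parent_states = states.get(parent, {})
        for site, (der, pp_d) in child_states.items():
            if exclude_sites and exclude_sites[0] <= site <= exclude_sites[1]:
                continue
            if site not in parent_states:
                continue
            anc, pp_a = parent_states[site]
            if anc in ("X", "-") or der in ("X", "-"):
                continue
            if anc != der:
                events.append(SubstitutionEvent(child, site, anc, der, pp_a, pp_d))
    return events


def comparable_pairs(tree: Phylogeny) -> list[tuple[int, int]]:
    """All unordered branch pairs except sisters and ancestor-descendant
    pairs. Branches are identified by their child node."""
    branches = sorted(tree.parent)
    pairs = []
    for i, b1 in enumerate(branches):
        for b2 in branches[i + 1:]:
            if tree.parent[b1] == tree.parent[b2]:
                continue  # sisters
            if tree.is_ancestor(b1, b2) or tree.is_ancestor(b2, b1):
                continue  # one branch lies on the other's path to the root
            pairs.append((b1, b2))
    return pairs


def classify_pair(events1, events2) -> tuple[int, int]:
    """Count convergences and divergences between two branches' events.

    Same derived state -> convergence; same ancestral state with different
    derived states -> divergence; different ancestral and different derived
    states fall in neither class.
    """
    by_site1 = {e.site: e for e in events1}
    C = D = 0
    for e2 in events2:
        e1 = by_site1.get(e2.site)
        if e1 is None:
            continue
        if e1.derived == e2.derived:
            C += 1
        elif e1.ancestral == e2.ancestral:
            D += 1
    return C, D


def cd_ratio(C: int, D: int) -> float:
    """The convergence/divergence summary (C+1)/(D+1)."""
    if C < 0 or D < 0:
        raise ValueError("counts must be non-negative")
    return (C + 1) / (D + 1)


def pair_distance(tree: Phylogeny, b1: int, b2: int) -> float:
    """Sum of branch lengths on the path between the two branches' child
    nodes, excluding the two focal branch lengths themselves."""
    if tree.is_ancestor(b1, b2) or tree.is_ancestor(b2, b1):
        raise ValueError("ancestor-descendant pairs have no defined distance")
    return (tree.patristic(b1, b2)
            - tree.branch_length[b1] - tree.branch_length[b2])


def pair_table(tree: Phylogeny, events) -> pd.DataFrame:
    """Per comparable branch pair: C, D, (C+1)/(D+1) and pair distance."""
    by_branch: dict[int, list] = {}
    for e in events:
        by_branch.setdefault(e.branch, []).append(e)
    rows = []
    for b1, b2 in comparable_pairs(tree):
        C, D = classify_pair(by_branch.get(b1, []), by_branch.get(b2, []))
        rows.append((b1, b2, C, D, cd_ratio(C, D), pair_distance(tree, b1, b2)))
    return pd.DataFrame(rows, columns=["b1", "b2", "C", "D", "ratio", "distance"])


def running_trend(pairs: pd.DataFrame, window: float = 0.05,
                  step: float = 0.01, n_boot: int = 100,
                  seed: int | None = None,
                  value_col: str = "ratio") -> pd.DataFrame:
    """Windowed running mean of the pair statistic over pair distance with
    percentile bootstrap confidence bands (pairs resampled within window)."""
    rng = np.random.default_rng(seed)
    d = pairs["distance"].to_numpy()
    v = pairs[value_col].to_numpy()
    rows = []
    lo, hi = d.min(), d.max()
    centers = np.arange(lo + window / 2, hi - window / 2 + step / 2, step)
    if centers.size == 0:
        centers = np.array([(lo + hi) / 2])
    for c in centers:
        mask = (d >= c - window / 2) & (d <= c + window / 2)
        vals = v[mask]
        if vals.size == 0:
            continue  # empty window: point omitted
        boots = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
        rows.append((c, vals.mean(),
                     np.percentile(boots, 2.5), np.percentile(boots, 97.5),
                     vals.size))
    return pd.DataFrame(rows, columns=["distance", "mean", "lo", "hi", "n_pairs"])


def event_outcome_table(tree: Phylogeny, events, site: int | None = None
                        ) -> pd.DataFrame:
    """Per branch pair and shared substituted site: outcome 1 for
    convergence, 0 for divergence, with the pair distance. Used for the
    convergence-vs-distance logistic regression."""
    by_branch: dict[int, list] = {}
    for e in events:
        if site is not None and e.site != site:
            continue
        by_branch.setdefault(e.branch, []).append(e)
    rows = []
    for b1, b2 in comparable_pairs(tree):
        by_site1 = {e.site: e for e in by_branch.get(b1, [])}
        for e2 in by_branch.get(b2, []):
            e1 = by_site1.get(e2.site)
            if e1 is None:
                continue
            if e1.derived == e2.derived:
                outcome = 1
            elif e1.ancestral == e2.ancestral:
                outcome = 0
            else:
                continue
            rows.append((b1, b2, e2.site, outcome,
                         pair_distance(tree, b1, b2)))
    return pd.DataFrame(rows, columns=["b1", "b2", "site", "outcome", "distance"])


def convergence_distance_regression(outcomes: pd.DataFrame):
    """Logistic regression of the binary convergence outcome on pair
    distance. Returns (slope in log-odds per substitutions/site, Wald p,
    flag) where flag marks unreliable fits (degenerate outcome or
    separation)."""
    y = outcomes["outcome"].to_numpy(float)
    if len(np.unique(y)) < 2:
        return float("nan"), float("nan"), "degenerate"
    X = sm.add_constant(outcomes["distance"].to_numpy(float))
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception:
        return float("nan"), float("nan"), "separation"
    slope = float(fit.params[1])
    p = float(fit.pvalues[1])
    flag = "ok"
    if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
        flag = "separation"
    return slope, p, flag
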