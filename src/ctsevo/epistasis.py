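"""Localizing the background sites behind background-dependent substitution
effects.

The effect E of introducing a derived state is the percent change in
activity relative to the wild type; for every unordered pair of backgrounds
that received the same derived state at the same site, Δ = |E1 - E2| is the
background dependence of that substitution. Variant sites distinguishing
the wild-type backgrounds are binarized per comparison (0 same, 1
different), grouped into correlation classes (|Pearson r| above a
threshold), entered into forward-nested linear models ordered by marginal
variance explained, and the selected model's R² is calibrated against a
permutation null that repeats the entire ascertainment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import Alignment


def substitution_effect(wt_activity: float, mut_activity: float) -> float:
    """Percent change in activity relative to the wild type."""
    if wt_activity <= 0:
        raise ValueError("wild-type activity must be positive")
    return (mut_activity - wt_activity) / wt_activity * 100.0


@dataclass
class EffectComparison:
    site: int
    state: str  # introduced derived amino-acid state
    backgrounds: tuple[str, str]
    effects: tuple[float, float]

    @property
    def delta(self) -> float:
        return abs(self.effects[0] - self.effects[1])


def enumerate_comparisons(panel: pd.DataFrame) -> list[EffectComparison]:
    """All unordered background pairs where the same derived state was
    introduced at the same site on both backgrounds.

    ``panel`` has one row per mutant construct: background, site, to_state,
    wt_activity, mut_activity (activities averaged over replicates).
    """
    rows = []
    for r in panel.itertuples():
        rows.append((r.site, r.to_state, r.background,
                     substitution_effect(r.wt_activity, r.mut_activity)))
    eff = pd.DataFrame(rows, columns=["site", "state", "background", "E"])
    out = []
    for (site, state), grp in eff.groupby(["site", "state"]):
        grp = grp.sort_values("background")
        recs = list(grp.itertuples())
        for i, a in enumerate(recs):
            for b in recs[i + 1:]:
                if a.background == b.background:
                    continue
                out.append(EffectComparison(
                    site=site, state=state,
                    backgrounds=(a.background, b.background),
                    effects=(a.E, b.E)))
    return out


def variant_sites(alignment: Alignment, ids=None) -> list[int]:
    """Site labels at which the given wild-type sequences are not all
    identical (a gap counts as a distinct state)."""
    ids = list(ids) if ids is not None else list(alignment.ids)
    rows = np.stack([alignment.row(i) for i in ids])
    out = []
    for site in alignment.sites():
        col = rows[:, alignment.column_of_site(site)]
        if len(set(col)) > 1:
            out.append(site)
    return out


def binarize_divergence(alignment: Alignment, bg1: str, bg2: str,
                        sites) -> np.ndarray:
    """Per-site 0/1 divergence between two wild-type backgrounds over the
    panel's variant sites; gap vs residue counts as different."""
    r1, r2 = alignment.row(bg1), alignment.row(bg2)
    return np.array([int(r1[alignment.column_of_site(s)]
                         != r2[alignment.column_of_site(s)])
                     for s in sites])


def divergence_matrix(alignment: Alignment, comparisons,
                      sites) -> pd.DataFrame:
    """Comparisons x sites 0/1 matrix of pairwise background divergence."""
    rows = [binarize_divergence(alignment, c.backgrounds[0],
                                c.backgrounds[1], sites)
            for c in comparisons]
    idx = [f"{c.backgrounds[0]}-{c.backgrounds[1]}:{c.state}{c.site}"
           for c in comparisons]
    return pd.DataFrame(rows, index=idx, columns=list(sites))


@dataclass
class SiteGroup:
    sites: list
    representative: int
    marginal_r2: float = float("nan")


def group_sites(divergence: pd.DataFrame, r_threshold: float = 0.8
                ) -> list[SiteGroup]:
    """Connected components of the graph joining site columns with
    |Pearson r| > ``r_threshold``; zero-variance columns each form their
    own group. Representative = lowest site label."""
    sites = list(divergence.columns)
    X = divergence.to_numpy(float)
    sd = X.std(axis=0)
    # union-find over columns
    parent = list(range(len(sites)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    nonzero = [i for i, s in enumerate(sd) if s > 0]
    if nonzero:
        Xn = X[:, nonzero]
        R = np.corrcoef(Xn, rowvar=False)
        R = np.atleast_2d(R)
        for a in range(len(nonzero)):
            for b in range(a + 1, len(nonzero)):
                if abs(R[a, b]) > r_threshold:
                    ra, rb = find(nonzero[a]), find(nonzero[b])
                    parent[rb] = ra
    comp: dict[int, list] = {}
    for i in range(len(sites)):
        comp.setdefault(find(i), []).append(sites[i])
    return [SiteGroup(sites=sorted(m), representative=min(m))
            for m in comp.values()]


def _r2(y, X):
    """R² of OLS of y on columns of X plus an intercept."""
    X1 = np.column_stack([np.ones(len(y))] + [np.asarray(c, float) for c in X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        return 0.0
    return float(1.0 - np.sum(resid ** 2) / tss)


def _fit_stats(y, X):
    """(R², rss, n_params incl. intercept, lnL, AIC) for a Gaussian OLS."""
    n = len(y)
    X1 = np.column_stack([np.ones(n)] + [np.asarray(c, float) for c in X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss = float(np.sum((y - X1 @ beta) ** 2))
    k = np.linalg.matrix_rank(X1)
    sigma2 = max(rss / n, 1e-300)
    lnl = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    p = k + 1  # + residual variance
    aic = 2 * p - 2 * lnl
    # small-sample correction; panels here have ~11 comparisons, where
    # plain AIC badly overfits after marginal ordering
    aicc = aic + (2 * p * (p + 1) / (n - p - 1) if n - p - 1 > 0 else np.inf)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    return r2, rss, k, lnl, aic, aicc


def rank_groups(delta, divergence: pd.DataFrame, groups, covariate=None):
    """Order groups by marginal variance in Δ explained by their
    representative divergence indicator (plus the mutated-site covariate,
    if given)."""
    y = np.asarray(delta, float)
    base = [] if covariate is None else [np.asarray(covariate, float)]
    scored = []
    for g in groups:
        x = divergence[g.representative].to_numpy(float)
        r2 = _r2(y, base + [x])
        scored.append(SiteGroup(sites=g.sites, representative=g.representative,
                                marginal_r2=r2))
    return sorted(scored, key=lambda g: (-g.marginal_r2, g.representative))


@dataclass
class ModelSelection:
    table: pd.DataFrame  # one row per nested model
    best_n_groups: int
    best_r2: float
    selected_sites: list
    criterion: str


def nested_anova_select(delta, divergence: pd.DataFrame, groups,
                        covariate=None, criterion: str = "AIC",
                        alpha: float = 0.05) -> ModelSelection:
    """Forward-nested linear models of Δ, adding groups in the order of
    marginal variance explained; models are compared by LRT (stop at the
    first non-significant addition) or AIC (global minimum along the path).
    """
    from scipy.stats import chi2
    y = np.asarray(delta, float)
    ordered = rank_groups(y, divergence, groups, covariate=covariate)
    base_cols = [] if covariate is None else [np.asarray(covariate, float)]
    rows = []
    r2_0, rss0, k0, lnl0, aic0, aicc0 = _fit_stats(y, base_cols)
    rows.append(("null", 0, 0, r2_0, np.nan, lnl0, aic0, aicc0))
    prev_lnl, prev_k = lnl0, k0
    cols = list(base_cols)
    n_sites_cum = 0
    for i, g in enumerate(ordered, start=1):
        cols = cols + [divergence[g.representative].to_numpy(float)]
        r2, rss, k, lnl, aic, aicc = _fit_stats(y, cols)
        if k + 1 >= len(y):  # saturated: stop nesting
            break
        dfree = k - prev_k
        p_lrt = float(chi2.sf(max(0.0, 2 * (lnl - prev_lnl)), max(dfree, 1)))
        n_sites_cum += len(g.sites)
        rows.append((f"groups1-{i}", i, n_sites_cum, r2, p_lrt, lnl, aic,
                     aicc))
        prev_lnl, prev_k = lnl, k
    table = pd.DataFrame(rows, columns=["model", "n_groups", "n_sites",
                                        "R2", "p_LRT", "lnL", "AIC", "AICc"])
    if criterion == "AIC":
        best = int(table.loc[table.AICc.idxmin(), "n_groups"])
    elif criterion == "LRT":
        best = 0
        for r in table.itertuples():
            if r.n_groups == 0:
                continue
            if r.p_LRT < alpha:
                best = r.n_groups
            else:
                break
    else:
        raise ValueError("criterion must be 'AIC' or 'LRT'")
    best_r2 = float(table.loc[table.n_groups == best, "R2"].iloc[0])
    selected = [s for g in ordered[:best] for s in g.sites]
    return ModelSelection(table=table, best_n_groups=best, best_r2=best_r2,
                          selected_sites=sorted(selected), criterion=criterion)


def top_groups_r2(delta, divergence, groups, covariate=None, n_top: int = 2):
    """R² of the model with the ``n_top`` marginally strongest groups (the
    ascertainment step that the permutation null must repeat)."""
    y = np.asarray(delta, float)
    ordered = rank_groups(y, divergence, groups, covariate=covariate)
    cols = [] if covariate is None else [np.asarray(covariate, float)]
    chosen = ordered[:n_top]
    cols = cols + [divergence[g.representative].to_numpy(float) for g in chosen]
    return _r2(y, cols), [s for g in chosen for s in g.sites]


def permutation_null(delta, divergence: pd.DataFrame, groups,
                     covariate=None, n_top: int = 2, n_perm: int = 10_000,
                     seed: int | None = None):
    """Permutation p-value for the selected-model R².

    Δ is permuted across comparisons; for each permutation the full
    ascertainment (re-rank groups, take the best ``n_top``) is repeated.
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    y = np.asarray(delta, float)
    obs, sites = top_groups_r2(y, divergence, groups, covariate, n_top)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = top_groups_r2(rng.permutation(y), divergence, groups,
                                covariate, n_top)[0]
    p = (1 + np.sum(null >= obs - 1e-12)) / (1 + n_perm)
    return obs, sites, null, float(p)


def build_mutant_panel(construct_table: pd.DataFrame,
                       mean_activity: dict) -> pd.DataFrame:
    """Join a construct table (construct, background, site, to_state; wild
    types have a missing site) with measured mean activities into the
    mutant panel that ``enumerate_comparisons`` consumes. Wild-type
    activity is looked up under the background's own construct id."""
    mut = construct_table[construct_table.site.notna()]
    rows = [(r.background, int(r.site), r.to_state,
             mean_activity[r.background], mean_activity[r.construct])
            for r in mut.itertuples()]
    return pd.DataFrame(rows, columns=["background", "site", "to_state",
                                       "wt_activity", "mut_activity"])


@dataclass
class LocalizationResult:
    comparisons: list
    delta: np.ndarray
    divergence: pd.DataFrame
    groups: list
    selection: "ModelSelection"
    top2_r2: float
    top2_sites: list
    permutation_p: float


def localize_background_sites(panel: pd.DataFrame, alignment: Alignment,
                              r_threshold: float = 0.8,
                              n_perm: int = 10_000,
                              seed: int | None = None) -> LocalizationResult:
    """Full localization pipeline: comparisons, divergence binarization,
    correlation grouping, nested selection and the permutation null."""
    comparisons = enumerate_comparisons(panel)
    sites = variant_sites(alignment)
    div = divergence_matrix(alignment, comparisons, sites)
    delta = np.array([c.delta for c in comparisons])
    focal_sites = sorted({c.site for c in comparisons})
    cov = np.array([1.0 if c.site == focal_sites[0] else 0.0
                    for c in comparisons]) if len(focal_sites) > 1 else None
    groups = group_sites(div, r_threshold)
    selection = nested_anova_select(delta, div, groups, covariate=cov)
    obs, top_sites, _, p = permutation_null(delta, div, groups,
                                            covariate=cov, n_perm=n_perm,
                                            seed=seed)
    return LocalizationResult(comparisons=comparisons, delta=delta,
                              divergence=div, groups=groups,
                              selection=selection, top2_r2=obs,
                              top2_sites=top_sites, permutation_p=p)


def divergence_effect_correlation(delta, divergence: pd.DataFrame,
                                  site_set, n_perm: int = 10_000,
                                  seed: int | None = None):
    """Pearson r between Δ and the per-comparison count of differing sites
    within ``site_set``, with a one-sided permutation p (add-one rule)."""
    if not len(site_set):
        raise ValueError("site set must be nonempty")
    y = np.asarray(delta, float)
    x = divergence[list(site_set)].to_numpy(float).sum(axis=1)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
    p = (1 + np.sum(null >= r - 1e-12)) / (1 + n_perm)
    return r, float(p)
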