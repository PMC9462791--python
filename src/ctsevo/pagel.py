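"""Correlated evolution of binary site states (Pagel's discrete model).

Each site is recoded relative to the reconstructed clade ancestor into
ancestral (0) / derived (1) states; pairs of sites evolve on the tree as a
four-state compound chain over (0,0), (0,1), (1,0), (1,1) with no double
transitions. Two nested model families are fitted by maximum likelihood:

* base: independent null (4 rates) vs dependent alternative (8 rates),
  LRT with df = 4;
* restricted: reversal rates to the ancestral state fixed at zero, null
  with shared gain rates q13 = q24 and q12 = q34 (2 rates) vs alternative
  with the 4 gain rates free, LRT with df = 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .io_core import GAP, Alignment, Phylogeny

#: compound states, in order: 1=(0,0), 2=(0,1), 3=(1,0), 4=(1,1)
COMPOUND_STATES = ((0, 0), (0, 1), (1, 0), (1, 1))
RATE_NAMES = ("q12", "q13", "q21", "q24", "q31", "q34", "q42", "q43")
#: (from, to) compound-state index for each named rate
_RATE_CELLS = {"q12": (0, 1), "q13": (0, 2), "q21": (1, 0), "q24": (1, 3),
               "q31": (2, 0), "q34": (2, 3), "q42": (3, 1), "q43": (3, 2)}

#: constraint set -> (free parameter names, mapping free -> rate names)
CONSTRAINT_SETS = {
    "base-null": (("a1", "b1", "a2", "b2"),
                  {"q13": "a1", "q24": "a1", "q31": "b1", "q42": "b1",
                   "q12": "a2", "q34": "a2", "q21": "b2", "q43": "b2"}),
    "base-alt": (RATE_NAMES, {q: q for q in RATE_NAMES}),
    "restricted-null": (("a", "b"),
                        {"q13": "a", "q24": "a", "q12": "b", "q34": "b"}),
    "restricted-alt": (("q12", "q13", "q24", "q34"),
                       {"q12": "q12", "q13": "q13", "q24": "q24", "q34": "q34"}),
}


def rate_matrix(rates: dict[str, float]) -> np.ndarray:
    """4x4 generator from the named rates; unnamed cells (double
    transitions) are zero."""
    Q = np.zeros((4, 4))
    for name, (i, j) in _RATE_CELLS.items():
        Q[i, j] = rates.get(name, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass
class PagelModelFit:
    constraint_set: str
    rates: dict[str, float]
    log_likelihood: float
    n_free: int
    n_starts: int = 0
    converged: bool = True


@dataclass
class BinaryTraitPair:
    """Tip states for the focal and partner site, each 0/1 or None
    (missing); coded relative to the reconstructed clade-MRCA state."""

    tip_states: dict[str, tuple]  # tip label -> (focal, partner)

    def compound_partials(self, tree: Phylogeny) -> dict[int, np.ndarray]:
        out = {}
        for tip in tree.tips():
            s1, s2 = self.tip_states.get(tree.labels[tip], (None, None))
            vec = np.array([1.0 if (s1 in (a, None)) and (s2 in (b, None))
                            else 0.0 for a, b in COMPOUND_STATES])
            out[tip] = vec
        return out


def recode_binary(alignment: Alignment, mrca_states: dict[int, str],
                  site: int) -> dict[str, int | None]:
    """0 where a tip equals the clade-MRCA state at ``site``, 1 otherwise;
    gaps/missing -> None. Raises KeyError if the MRCA state is not called."""
    anc = mrca_states.get(site)
    if anc is None or anc in ("X", GAP):
        raise KeyError(f"MRCA state not called at site {site}")
    col = alignment.column(site)
    out = {}
    for sid, c in zip(alignment.ids, col):
        out[sid] = None if c in (GAP, "X") else (0 if c == anc else 1)
    return out


def filter_sites(binary: pd.DataFrame, max_missing_frac: float = 0.8,
                 min_derived: int = 2) -> list:
    """Retain sites (columns) with >= ``min_derived`` derived tips
    (singletons excluded) and at most ``max_missing_frac`` missing entries
    (a strict "more than" rule: exactly 80% missing is kept)."""
    keep = []
    n = len(binary)
    for site in binary.columns:
        col = binary[site]
        missing = col.isna().sum()
        if missing / n > max_missing_frac:
            continue
        if (col == 1).sum() < min_derived:
            continue
        keep.append(site)
    return keep


def scale_branch_lengths(tree: Phylogeny, target_mean: float = 0.1) -> Phylogeny:
    """Multiply all branch lengths by one constant so their mean equals
    ``target_mean``."""
    lengths = np.array(list(tree.branch_length.values()))
    if lengths.size == 0 or lengths.sum() <= 0:
        raise ValueError("tree has no positive branch lengths to scale")
    factor = target_mean / lengths.mean()
    scaled = tree.copy()
    for k in scaled.branch_length:
        scaled.branch_length[k] *= factor
    return scaled


# -- likelihood machinery ---------------------------------------------

ROOT_PRIORS = ("ancestral", "uniform", "stationary")


def _branch_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) for every branch at once via eigendecomposition, with an expm
    fallback when the eigenbasis is ill-conditioned (defective Q)."""
    lam, V = np.linalg.eig(Q)
    if np.linalg.cond(V) < 1e8:
        Vinv = np.linalg.inv(V)
        E = np.exp(np.multiply.outer(lengths, lam))  # (n, 4)
        P = np.einsum("ij,nj,jk->nik", V, E, Vinv).real
    else:
        from scipy.linalg import expm
        P = np.stack([expm(Q * t) for t in lengths])
    return np.clip(P, 0.0, None)


class PagelLikelihood:
    """Pruning likelihood of one binary trait pair on a fixed tree."""

    def __init__(self, pair: BinaryTraitPair, tree: Phylogeny,
                 root_prior: str = "ancestral"):
        if root_prior not in ROOT_PRIORS:
            raise ValueError(f"root_prior must be one of {ROOT_PRIORS}")
        self.tree = tree
        self.root_prior = root_prior
        self.tips = pair.compound_partials(tree)
        self.postorder = tree.postorder()
        self.branches = sorted(tree.parent)
        self.lengths = np.array([tree.branch_length[b] for b in self.branches])
        self.branch_index = {b: i for i, b in enumerate(self.branches)}

    def _root_pi(self, Q):
        if self.root_prior == "ancestral":
            return np.array([1.0, 0.0, 0.0, 0.0])
        if self.root_prior == "uniform":
            return np.full(4, 0.25)
        # stationary distribution: left null vector of Q
        lam, V = np.linalg.eig(Q.T)
        k = np.argmin(np.abs(lam))
        pi = np.abs(V[:, k].real)
        return pi / pi.sum()

    def __call__(self, rates: dict[str, float]) -> float:
        Q = rate_matrix(rates)
        P = _branch_matrices(Q, self.lengths)
        up, logscale = {}, 0.0
        tree = self.tree
        for n in self.postorder:
            if tree.is_tip(n):
                up[n] = self.tips[n]
            else:
                acc = np.ones(4)
                for c in tree.children[n]:
                    acc = acc * (P[self.branch_index[c]] @ up[c])
                s = acc.max()
                if s <= 0:
                    return -np.inf
                up[n] = acc / s
                logscale += np.log(s)
        lik = float(self._root_pi(Q) @ up[tree.root])
        if lik <= 0:
            return -np.inf
        return np.log(lik) + logscale


def fit_pagel(pair: BinaryTraitPair, tree: Phylogeny, constraint_set: str,
              n_starts: int = 25, seed: int | None = None,
              root_prior: str = "ancestral",
              bounds=(1e-4, 1e3)) -> PagelModelFit:
    """Maximum-likelihood fit of one constraint set by multi-start bounded
    optimization in log-rate space."""
    if constraint_set not in CONSTRAINT_SETS:
        raise ValueError(f"unknown constraint set {constraint_set!r}")
    free_names, mapping = CONSTRAINT_SETS[constraint_set]
    loglik = PagelLikelihood(pair, tree, root_prior=root_prior)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    rng = np.random.default_rng(seed)

    def neg(theta):
        vals = dict(zip(free_names, np.exp(theta)))
        val = -loglik({q: vals[p] for q, p in mapping.items()})
        # keep the objective finite so numerical gradients stay defined
        return min(val, 1e10) if np.isfinite(val) else 1e10

    best, best_x, n_ok = np.inf, None, 0
    starts = [np.zeros(len(free_names))]
    starts += list(rng.uniform(lo, hi, size=(max(0, n_starts - 1),
                                             len(free_names))))
    for x0 in starts:
        res = minimize(neg, x0, method="L-BFGS-B",
                       bounds=[(lo, hi)] * len(free_names))
        if np.isfinite(res.fun) and res.fun < 1e9:
            n_ok += 1
            if res.fun < best:
                best, best_x = res.fun, res.x
    if n_ok == 0:
        raise RuntimeError(
            f"optimizer failed to converge in all {n_starts} starts "
            f"({constraint_set})")
    vals = dict(zip(free_names, np.exp(best_x)))
    rates = {q: vals[p] for q, p in mapping.items()}
    return PagelModelFit(constraint_set=constraint_set, rates=rates,
                         log_likelihood=-best, n_free=len(free_names),
                         n_starts=n_starts, converged=n_ok > 0)


def lrt(null_fit: PagelModelFit, alt_fit: PagelModelFit):
    """Likelihood-ratio test of nested fits: 2ΔlnL vs chi-squared with
    df = difference in free parameters; the statistic is floored at 0."""
    df = alt_fit.n_free - null_fit.n_free
    if df <= 0:
        raise ValueError("alternative must have more free parameters")
    delta = alt_fit.log_likelihood - null_fit.log_likelihood
    if delta < -1e-6:
        raise RuntimeError("alternative lnL below null: optimization failure")
    stat = max(0.0, 2.0 * delta)
    return stat, df, float(chi2.sf(stat, df))


def rank_sites(p_values: dict, quantile: float = 0.05) -> list:
    """Top ``quantile`` of sites by -log p; ties broken by site label."""
    items = sorted(p_values.items(), key=lambda kv: (kv[1], kv[0]))
    k = max(1, int(round(len(items) * quantile)))
    return [site for site, _ in items[:k]]


def site_pair_scan(binary: pd.DataFrame, focal_site, tree: Phylogeny,
                   model_family: str = "restricted", n_starts: int = 8,
                   seed: int | None = None) -> pd.DataFrame:
    """Fit the null/alternative pair for ``focal_site`` against every other
    retained site and tabulate the LRTs."""
    null_name, alt_name = f"{model_family}-null", f"{model_family}-alt"
    rng = np.random.default_rng(seed)
    rows = []
    for site in binary.columns:
        if site == focal_site:
            continue
        pair = BinaryTraitPair(tip_states={
            tip: (None if pd.isna(binary.at[tip, focal_site])
                  else int(binary.at[tip, focal_site]),
                  None if pd.isna(binary.at[tip, site])
                  else int(binary.at[tip, site]))
            for tip in binary.index})
        s1, s2 = int(rng.integers(2**31)), int(rng.integers(2**31))
        null = fit_pagel(pair, tree, null_name, n_starts=n_starts, seed=s1)
        alt = fit_pagel(pair, tree, alt_name, n_starts=n_starts, seed=s2)
        stat, df, p = lrt(null, alt)
        rows.append((site, model_family, null.log_likelihood,
                     alt.log_likelihood, stat, df, p,
                     -np.log10(max(p, 1e-300))))
    return pd.DataFrame(rows, columns=["site", "family", "lnL_null",
                                       "lnL_alt", "LRT", "df", "p",
                                       "neglog10_p"])
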