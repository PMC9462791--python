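"""Marginal ancestral state reconstruction for amino-acid alignments.

Implements Felsenstein's pruning algorithm with an up-pass (partial
likelihoods of the data below each node) and a down-pass (outside partial
likelihoods), combined into per-node marginal posteriors under an empirical
exchangeability model (JTT by default) with discrete-gamma rate
heterogeneity. Gaps are treated as missing data (uniform partial
likelihoods) and a gap state is never called at an ancestor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .io_core import AA_INDEX, AMBIGUITY, AMINO_ACIDS, GAP, Alignment, Phylogeny

N_STATES = 20


def _load_jtt():
    ref = resources.files("ctsevo.data").joinpath("jtt.csv")
    with ref.open() as fh:
        df = pd.read_csv(fh, comment="#", index_col=0)
    order = list(df.index)
    S = df[order].to_numpy(dtype=float)
    freqs = df["freq"].to_numpy(dtype=float)
    # reorder to canonical AMINO_ACIDS order (it already is, but be safe)
    perm = [order.index(a) for a in AMINO_ACIDS]
    return S[np.ix_(perm, perm)], freqs[perm]


@dataclass
class RateModel:
    """Empirical amino-acid substitution model with discrete-gamma rates.

    The generator is Q = S · diag(pi), normalized to one expected
    substitution per unit branch length at equilibrium. ``shape`` is the
    gamma shape alpha; ``n_categories`` discrete categories are taken as
    the means of equal-probability quantile bins (mean relative rate 1).
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    shape: float | None = None
    n_categories: int = 4

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, float)
        self.frequencies = np.asarray(self.frequencies, float)
        if not np.isclose(self.frequencies.sum(), 1.0):
            raise ValueError("equilibrium frequencies must sum to 1")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be positive")

    @property
    def generator(self) -> np.ndarray:
        S = self.exchangeabilities
        pi = self.frequencies
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        return Q / mu

    def category_rates(self) -> np.ndarray:
        if self.shape is None or self.n_categories == 1:
            return np.ones(1)
        return discrete_gamma_rates(self.shape, self.n_categories)

    def with_shape(self, shape: float) -> "RateModel":
        return RateModel(self.exchangeabilities, self.frequencies,
                         shape=shape, n_categories=self.n_categories)


def jtt_model(shape: float | None = None, n_categories: int = 4,
              frequencies: np.ndarray | None = None) -> RateModel:
    """JTT model; pass empirical frequencies for the "+F" variant."""
    S, f = _load_jtt()
    if frequencies is not None:
        f = np.asarray(frequencies, float)
    return RateModel(S, f, shape=shape, n_categories=n_categories)


def empirical_frequencies(alignment: Alignment, pseudocount: float = 0.5):
    """Observed amino-acid frequencies with a small pseudocount ("+F")."""
    counts = np.full(N_STATES, pseudocount)
    for a, i in AA_INDEX.items():
        counts[i] += np.count_nonzero(alignment.matrix == a)
    return counts / counts.sum()


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Means of equal-probability bins of a Gamma(shape, mean 1) density."""
    a = shape
    edges = gamma_dist.ppf(np.linspace(0, 1, n_categories + 1), a, scale=1.0 / a)
    # E[X | bin] via the regularized incomplete gamma of shape a+1
    upper = gammainc(a + 1, a * edges[1:])
    lower = gammainc(a + 1, a * edges[:-1])
    rates = (upper - lower) * n_categories
    return rates / rates.mean()


def _eigen_system(model: RateModel):
    """Eigendecomposition of the symmetrized generator.

    Returns (U, lam, pi_sqrt) with Q = D^{-1/2} U diag(lam) U' D^{1/2},
    D = diag(pi).
    """
    pi = model.frequencies
    d = np.sqrt(pi)
    B = model.generator * d[:, None] / d[None, :]
    B = (B + B.T) / 2.0
    lam, U = np.linalg.eigh(B)
    return U, lam, d


def transition_matrix(model: RateModel, t: float) -> np.ndarray:
    U, lam, d = _eigen_system(model)
    P = (U * np.exp(lam * t)) @ U.T
    P = P / d[:, None] * d[None, :]
    return np.clip(P, 0.0, None)


def tip_partials(alignment: Alignment, tree: Phylogeny) -> dict[int, np.ndarray]:
    """Per-tip (n_col, 20) indicator/partial-likelihood arrays."""
    partials = {}
    for tip in tree.tips():
        label = tree.labels[tip]
        if label not in alignment.ids:
            raise ValueError(f"tip {label!r} has no sequence in the alignment")
        row = alignment.row(label)
        arr = np.zeros((alignment.n_col, N_STATES))
        for j, c in enumerate(row):
            if c in AA_INDEX:
                arr[j, AA_INDEX[c]] = 1.0
            elif c == GAP or c in AMBIGUITY or c not in AA_INDEX:
                allowed = AMBIGUITY.get(c, AMINO_ACIDS)
                for a in allowed:
                    arr[j, AA_INDEX[a]] = 1.0
        partials[tip] = arr
    return partials


class _PruningEngine:
    """Cached transition matrices and scaled up/down passes, one rate
    category at a time."""

    def __init__(self, alignment, tree, model):
        self.alignment = alignment
        self.tree = tree
        self.model = model
        self.tips = tip_partials(alignment, tree)
        self.U, self.lam, self.d = _eigen_system(model)
        self.postorder = tree.postorder()
        self.preorder = tree.preorder()

    def _pmat(self, t):
        P = (self.U * np.exp(self.lam * t)) @ self.U.T
        P = P / self.d[:, None] * self.d[None, :]
        return np.clip(P, 0.0, None)

    def category_pass(self, rate):
        """Return (up, up_logscale, out, out_logscale, site_lik, site_logscale)."""
        tree, nsite = self.tree, self.alignment.n_col
        P = {n: self._pmat(tree.branch_length[n] * rate) for n in tree.parent}
        up, upls = {}, {}
        # child-message cache: M[c][i] = sum_j P_c[i, j] up_c[j]
        msg = {}
        for n in self.postorder:
            if tree.is_tip(n):
                up[n] = self.tips[n].copy()
                upls[n] = np.zeros(nsite)
            else:
                acc = np.ones((nsite, N_STATES))
                ls = np.zeros(nsite)
                for c in tree.children[n]:
                    msg[c] = up[c] @ P[c].T
                    acc = acc * msg[c]
                    ls += upls[c]
                scale = acc.max(axis=1)
                scale[scale == 0] = 1.0
                up[n] = acc / scale[:, None]
                upls[n] = ls + np.log(scale)
            if tree.is_tip(n):
                msg[n] = None  # filled lazily below
        pi = self.model.frequencies
        root = tree.root
        site_lik = up[root] @ pi
        site_ls = upls[root]
        # outside pass
        out, outls = {root: np.tile(pi, (nsite, 1))}, {root: np.zeros(nsite)}
        for n in self.preorder:
            for c in tree.children[n]:
                acc = out[n].copy()
                ls = outls[n].copy()
                for s in tree.children[n]:
                    if s is c:
                        continue
                    if msg.get(s) is None:
                        msg[s] = up[s] @ P[s].T
                    acc = acc * msg[s]
                    ls += upls[s]
                g = acc @ P[c]
                scale = g.max(axis=1)
                scale[scale == 0] = 1.0
                out[c] = g / scale[:, None]
                outls[c] = ls + np.log(scale)
        return up, upls, out, outls, site_lik, site_ls


def log_likelihood(alignment: Alignment, tree: Phylogeny, model: RateModel) -> float:
    """Total pruning log-likelihood, integrated over gamma categories."""
    engine = _PruningEngine(alignment, tree, model)
    rates = model.category_rates()
    w = 1.0 / len(rates)
    per_cat = []
    for r in rates:
        up, upls, *_ = engine.category_pass(r)
        lik = up[tree.root] @ model.frequencies
        per_cat.append(np.log(np.clip(lik, 1e-300, None)) + upls[tree.root])
    L = np.stack(per_cat)  # (ncat, nsite)
    m = L.max(axis=0)
    return float(np.sum(m + np.log(np.mean(np.exp(L - m), axis=0))))


@dataclass
class AncestralStates:
    """Marginal posteriors (node × site × 20) and the site labelling."""

    node_ids: list[int]
    column_labels: list
    posteriors: np.ndarray  # (n_nodes, n_col, 20)

    def __post_init__(self):
        sums = self.posteriors.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("posterior vectors must sum to 1")

    def posterior(self, node, site_col):
        return self.posteriors[self.node_ids.index(node), site_col]


def marginal_asr(alignment: Alignment, tree: Phylogeny,
                 model: RateModel) -> AncestralStates:
    """Marginal posteriors over ancestral amino-acid states at every
    internal node, integrating over gamma rate categories."""
    engine = _PruningEngine(alignment, tree, model)
    rates = model.category_rates()
    internal = tree.internal_nodes()
    nsite = alignment.n_col
    contrib = np.zeros((len(rates), len(internal), nsite, N_STATES))
    logsc = np.zeros((len(rates), len(internal), nsite))
    for k, r in enumerate(rates):
        up, upls, out, outls, _, _ = engine.category_pass(r)
        for i, n in enumerate(internal):
            contrib[k, i] = up[n] * out[n]
            logsc[k, i] = upls[n] + outls[n]
    # combine categories with their scale factors: posterior ∝ Σ_k w·joint_k
    m = logsc.max(axis=0, keepdims=True)
    weighted = contrib * np.exp(logsc - m)[..., None]
    post = weighted.sum(axis=0)
    norm = post.sum(axis=2, keepdims=True)
    norm[norm == 0] = 1.0
    post = post / norm
    return AncestralStates(node_ids=internal,
                           column_labels=list(alignment.column_labels),
                           posteriors=post)


def call_states(post: AncestralStates, threshold: float = 0.8) -> pd.DataFrame:
    """Point calls at max-posterior states exceeding ``threshold``.

    Returns a long table (node, column, site, state, pp); sites whose best
    state has PP <= threshold are reported as missing (state "X").
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    rows = []
    argmax = post.posteriors.argmax(axis=2)
    maxpp = post.posteriors.max(axis=2)
    for i, node in enumerate(post.node_ids):
        for j in range(post.posteriors.shape[1]):
            pp = maxpp[i, j]
            state = AMINO_ACIDS[argmax[i, j]] if pp > threshold else "X"
            rows.append((node, j, post.column_labels[j], state, pp))
    return pd.DataFrame(rows, columns=["node", "column", "site", "state", "pp"])


def fit_gamma_shape(alignment: Alignment, tree: Phylogeny, model: RateModel,
                    bounds=(0.05, 20.0)) -> float:
    """ML gamma shape by 1-D bounded optimization; branch lengths fixed."""
    if model.n_categories == 1:
        warnings.warn("single rate category requested; shape has no effect")
        return float("nan")
    variable = sum(1 for j in range(alignment.n_col)
                   if len({c for c in alignment.matrix[:, j]
                           if c in AA_INDEX}) > 1)
    if variable < 2:
        raise ValueError("need at least 2 variable sites to fit a shape")

    def neg(log_shape):
        m = model.with_shape(float(np.exp(log_shape)))
        return -log_likelihood(alignment, tree, m)

    res = minimize_scalar(neg, bounds=(np.log(bounds[0]), np.log(bounds[1])),
                          method="bounded", options={"xatol": 1e-4})
    shape = float(np.exp(res.x))
    if shape > 0.98 * bounds[1]:
        warnings.warn("likelihood flat in shape; returning upper bound")
    return shape


def write_ancestral_fasta(calls: pd.DataFrame, path):
    """One FASTA record per internal node; missing calls are written as X."""
    with open(path, "w") as fh:
        for node, grp in calls.groupby("node"):
            seq = "".join(grp.sort_values("column").state)
            fh.write(f">node_{node}\n{seq}\n")
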