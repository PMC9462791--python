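"""Seeded generators for every input the pipeline consumes, with recorded
ground truth.

The generators emulate the study conditions: amino-acid alignments evolved
on a Yule tree under an empirical model with optional planted convergence
at focal sites; binary trait pairs evolved as the four-state compound chain
(exact stochastic simulation, no double transitions); and assay panels of
eight wild-type backgrounds with three biological replicates per construct,
fixed-asymptote logistic dose-response curves with Gaussian noise on the
percent scale, and activities whose background dependence is governed by a
planted causal site set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import AMINO_ACIDS, Alignment, AssayRecord, Phylogeny, \
    OUABAIN_CONCENTRATIONS
from .asr import RateModel
from .assays import StandardCurve, logistic4p
from .pagel import COMPOUND_STATES, rate_matrix


# -- trees ------------------------------------------------------------

def simulate_tree(n_tips: int, birth_rate: float = 1.0,
                  seed: int | None = None) -> Phylogeny:
    """Pure-birth (Yule) tree with exponential waiting times between
    speciation events; branch lengths are in units of 1/birth_rate and are
    typically rescaled by the caller to substitutions/site."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    parent, blen, labels = {}, {}, {}
    birth = {0: 0.0}
    next_id = 1
    active = []
    t = 0.0
    for _ in range(2):  # root splits into two lineages
        parent[next_id] = 0
        birth[next_id] = 0.0
        active.append(next_id)
        next_id += 1
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        u = active.pop(rng.integers(len(active)))
        blen[u] = t - birth[u]
        for _ in range(2):
            parent[next_id] = u
            birth[next_id] = t
            active.append(next_id)
            next_id += 1
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for i, u in enumerate(active):
        blen[u] = t - birth[u]
        labels[u] = f"t{i + 1}"
    return Phylogeny(parent, blen, labels, 0)


def yule_tip_count(t: float, birth_rate: float = 1.0,
                   seed: int | None = None, n0: int = 2) -> int:
    """Number of lineages of a pure-birth process at time t (started from
    n0 lineages); E[N(t)] = n0 * exp(birth_rate * t)."""
    rng = np.random.default_rng(seed)
    n, clock = n0, 0.0
    while True:
        clock += rng.exponential(1.0 / (birth_rate * n))
        if clock > t:
            return n
        n += 1


# -- sequence evolution ----------------------------------------------

@dataclass
class PlantedConvergence:
    """Per-branch conversion to a target state at focal sites: each branch
    independently adopts the target state with the given probability,
    giving exact, countable ground truth for convergence counting."""

    focal_sites: tuple = (111,)
    probability: float = 0.15
    target_state: str = "R"


def simulate_alignment(tree: Phylogeny, model: RateModel, n_sites: int,
                       planted: PlantedConvergence | None = None,
                       seed: int | None = None, first_site_label: int = 1):
    """Site-independent CTMC simulation down the tree.

    Returns (tip alignment, true node states dict node -> list of states,
    true event table with one row per branch x site where the parent and
    child states differ, with a 'planted' flag).
    """
    rng = np.random.default_rng(seed)
    pi = model.frequencies
    rates = model.category_rates()
    site_labels = list(range(first_site_label, first_site_label + n_sites))
    focal_cols = set()
    if planted is not None:
        focal_cols = {site_labels.index(s) for s in planted.focal_sites
                      if s in site_labels}
        target_idx = AMINO_ACIDS.index(planted.target_state)
    cat_idx = rng.integers(len(rates), size=n_sites)
    from .asr import _eigen_system
    U, lam, d = _eigen_system(model)

    def pmat(t):
        P = (U * np.exp(lam * t)) @ U.T
        P = P / d[:, None] * d[None, :]
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    states = {tree.root: rng.choice(20, size=n_sites, p=pi)}
    events = []
    for n in tree.preorder():
        for c in tree.children[n]:
            Pcat = [pmat(tree.branch_length[c] * r) for r in rates]
            child = np.empty(n_sites, dtype=int)
            u = rng.random(n_sites)
            for j in range(n_sites):
                cdf = np.cumsum(Pcat[cat_idx[j]][states[n][j]])
                child[j] = int(np.searchsorted(cdf, u[j] * cdf[-1]))
            planted_here = np.zeros(n_sites, dtype=bool)
            for j in focal_cols:
                if rng.random() < planted.probability:
                    child[j] = target_idx
                    planted_here[j] = True
            states[c] = child
            for j in np.nonzero(child != states[n])[0]:
                events.append((c, site_labels[j],
                               AMINO_ACIDS[states[n][j]],
                               AMINO_ACIDS[child[j]],
                               bool(planted_here[j])))
    tips = tree.tips()
    aln = Alignment(
        ids=[tree.labels[t] for t in tips],
        matrix=np.array([[AMINO_ACIDS[s] for s in states[t]] for t in tips]),
        column_labels=site_labels)
    truth = {n: [AMINO_ACIDS[s] for s in arr] for n, arr in states.items()}
    ev = pd.DataFrame(events, columns=["branch", "site", "ancestral",
                                       "derived", "planted"])
    return aln, truth, ev


# -- compound binary chain -------------------------------------------

def simulate_correlated_pair(tree: Phylogeny, rates: dict,
                             root_state=(0, 0), seed: int | None = None):
    """Exact stochastic (Gillespie) simulation of the four-state compound
    chain along every branch. Returns (tip states dict label -> (s1, s2),
    transition count table)."""
    rng = np.random.default_rng(seed)
    Q = rate_matrix(rates)
    start = COMPOUND_STATES.index(tuple(root_state))
    states = {tree.root: start}
    n_trans = np.zeros((4, 4), dtype=int)
    for n in tree.preorder():
        for c in tree.children[n]:
            s = states[n]
            remaining = tree.branch_length[c]
            while True:
                out = -Q[s, s]
                if out <= 0:
                    break
                wait = rng.exponential(1.0 / out)
                if wait > remaining:
                    break
                remaining -= wait
                probs = np.clip(Q[s], 0, None)
                probs[s] = 0
                probs = probs / probs.sum()
                s_new = rng.choice(4, p=probs)
                n_trans[s, s_new] += 1
                s = s_new
            states[c] = s
    tips = {tree.labels[t]: COMPOUND_STATES[states[t]] for t in tree.tips()}
    return tips, n_trans


# -- assay panel ------------------------------------------------------

@dataclass
class PanelSpec:
    """Wild-type backgrounds and the substitutions introduced on them.

    Defaults mirror the study's design scale: eight backgrounds, 113
    variant sites, substitutions at the two key loop sites introduced on
    four backgrounds each. Causal-site states accumulate along a background
    ordering (a ladder), as substitutions do along a lineage, so pairwise
    divergence at causal sites is direction-consistent.
    """

    n_backgrounds: int = 8
    n_variant_sites: int = 113
    n_causal: int = 5
    substitutions: tuple = ((111, "R", 4), (122, "D", 4))  # (site, state, n_bg)
    first_site_label: int = 200  # labels for variant background sites


@dataclass
class AssaySpec:
    slope: float = 1.0
    noise_pct: float = 5.0  # Gaussian noise, percentage points
    n_replicates: int = 3
    ic50_range: tuple = (-7.5, -4.5)  # wild-type log10 IC50 draw
    substitution_shift: float = 1.0  # log10 shift caused by the substitution
    volume_uL: float = 50.0
    protein_mass_mg: float = 0.1
    incubation_min: float = 20.0
    std_slope: float = 0.5  # absorbance per mM Pi
    background_absorbance: float = 0.05


@dataclass
class EpistasisSpec:
    effect: float = 25.0  # percent change in E per causal-site difference
    noise_pct: float = 5.0  # replicate noise on the percent-effect scale
    activity_range: tuple = (3.0, 18.0)  # wild-type nmol Pi/mg/min


@dataclass
class SimulationConfig:
    seed: int = 0
    n_tips: int = 64
    birth_rate: float = 1.0
    n_sites: int = 200
    tree_depth_scale: float = 0.5  # mean root-to-tip depth, subs/site
    planted: PlantedConvergence | None = None
    panel: PanelSpec = field(default_factory=PanelSpec)
    assay: AssaySpec = field(default_factory=AssaySpec)
    epistasis: EpistasisSpec = field(default_factory=EpistasisSpec)


def scale_tree_depth(tree: Phylogeny, mean_depth: float) -> Phylogeny:
    """Rescale so the mean root-to-tip depth equals ``mean_depth``
    substitutions/site."""
    depths = [tree.depth(t) for t in tree.tips()]
    f = mean_depth / np.mean(depths)
    out = tree.copy()
    for k in out.branch_length:
        out.branch_length[k] *= f
    return out


@dataclass
class AssayTruth:
    panel: pd.DataFrame  # one row per construct
    alignment: Alignment  # wild-type backgrounds x variant sites
    causal_sites: list
    effect: float
    log10_ic50: dict  # construct -> true value
    activity: dict  # construct -> true mean activity
    standard_points: tuple  # (conc mM, absorbance)


def simulate_assay_dataset(panel: PanelSpec | None = None,
                           assay: AssaySpec | None = None,
                           epistasis: EpistasisSpec | None = None,
                           seed: int | None = None):
    """Full synthetic assay dataset: AssayRecords (3 biological replicates
    per construct at the six ouabain concentrations plus controls), the
    phosphate standard curve, and the ground truth."""
    panel = panel or PanelSpec()
    assay = assay or AssaySpec()
    epistasis = epistasis or EpistasisSpec()
    rng = np.random.default_rng(seed)

    backgrounds = [f"BG{i + 1}" for i in range(panel.n_backgrounds)]
    sites = list(range(panel.first_site_label,
                       panel.first_site_label + panel.n_variant_sites))
    causal = sorted(rng.choice(panel.n_variant_sites, size=panel.n_causal,
                               replace=False))
    causal_sites = [sites[i] for i in causal]
    # Wild-type divergence follows a background phylogeny: every variant
    # site substitutes once on one branch, so its derived set is a clade
    # (infinite-sites model). This reproduces the strong collinearity of
    # real panels, where many sites share one clade pattern.
    bg_tree = simulate_tree(panel.n_backgrounds,
                            seed=int(rng.integers(2**31)))
    tip_of = {bg_tree.labels[t]: i for i, t in enumerate(bg_tree.tips())}
    clades = {}
    for node in bg_tree.nodes():
        if node == bg_tree.root:
            continue
        below = [tip_of[bg_tree.labels[t]] for t in bg_tree.tips()
                 if node == t or bg_tree.is_ancestor(node, t)]
        if 0 < len(below) < panel.n_backgrounds:
            clades[node] = np.array(below)
    # causal sites form two collinear blocks on NESTED clades (the inner
    # clade strictly inside the outer), so causal divergence between any
    # two backgrounds is direction-consistent and E[delta] = k x effect
    internal = [n for n, tips_ in clades.items()
                if 2 <= len(tips_) <= panel.n_backgrounds - 2]
    rng.shuffle(internal)
    outer = inner = None
    for cand in internal:
        nested = [m for m in clades if m != cand
                  and bg_tree.is_ancestor(cand, m)]
        if nested:
            outer, inner = cand, nested[int(rng.integers(len(nested)))]
            break
    if outer is None:  # degenerate topology: fall back to any two clades
        outer, inner = internal[0], internal[0]
    block_edge = {j: (outer if i < (panel.n_causal + 1) // 2 else inner)
                  for i, j in enumerate(causal)}
    edge_pool = list(clades)
    X = np.zeros((panel.n_backgrounds, panel.n_variant_sites), dtype=int)
    for j in range(panel.n_variant_sites):
        edge = block_edge.get(j)
        if edge is None:
            edge = edge_pool[int(rng.integers(len(edge_pool)))]
        X[clades[edge], j] = 1
    # realize as amino acids: state 0/1 -> two residues per column
    res0 = rng.integers(0, 20, size=panel.n_variant_sites)
    res1 = (res0 + 1 + rng.integers(0, 19, size=panel.n_variant_sites)) % 20
    matrix = np.array([[AMINO_ACIDS[res1[j]] if X[i, j] else AMINO_ACIDS[res0[j]]
                        for j in range(panel.n_variant_sites)]
                       for i in range(panel.n_backgrounds)])
    aln = Alignment(ids=backgrounds, matrix=matrix, column_labels=sites)

    # constructs: wild types plus mutants
    wt_act = dict(zip(backgrounds,
                      rng.uniform(*epistasis.activity_range,
                                  size=panel.n_backgrounds)))
    wt_ic50 = dict(zip(backgrounds,
                       rng.uniform(*assay.ic50_range,
                                   size=panel.n_backgrounds)))
    gamma = epistasis.effect  # percent per causal-site derived state
    rows, true_ic50, true_act = [], {}, {}
    for bg in backgrounds:
        rows.append((bg, bg, None, None))
        true_ic50[bg] = wt_ic50[bg]
        true_act[bg] = wt_act[bg]
    # substitutions are spread so that together they cover the whole panel,
    # as the engineered-construct design spans the available backgrounds
    unassigned = list(rng.permutation(backgrounds))
    for site, state, n_bg in panel.substitutions:
        if len(unassigned) >= n_bg:
            chosen, unassigned = unassigned[:n_bg], unassigned[n_bg:]
        else:
            chosen = list(rng.choice(backgrounds, size=n_bg, replace=False))
        for bg in chosen:
            name = f"{bg}+{site}{state}"
            rows.append((name, bg, site, state))
            shift = assay.substitution_shift * (1 if rng.random() < 0.5 else -1)
            true_ic50[name] = wt_ic50[bg] + shift
            xb = X[backgrounds.index(bg)][causal].sum()
            effect_pct = 10.0 + gamma * xb  # main effect + causal term
            true_act[name] = wt_act[bg] * (1 + effect_pct / 100.0)
    panel_df = pd.DataFrame(rows, columns=["construct", "background",
                                           "site", "to_state"])

    # phosphate standard curve run in parallel
    std_conc = np.array([1.2, 1.0, 0.8, 0.6, 0.4, 0.2, 0.0])
    std_abs = assay.background_absorbance + assay.std_slope * std_conc \
        + rng.normal(0, 0.002, size=std_conc.size)

    records = []
    for r in panel_df.itertuples():
        for rep in range(1, assay.n_replicates + 1):
            act = true_act[r.construct] * (
                1 + rng.normal(0, epistasis.noise_pct / 100.0))
            act = max(act, 0.0)
            pi_mM = act * assay.protein_mass_mg * assay.incubation_min \
                / assay.volume_uL
            control = assay.background_absorbance + assay.std_slope * pi_mM
            doses = {}
            for conc in OUABAIN_CONCENTRATIONS:
                pct = logistic4p(np.log10(conc), true_ic50[r.construct],
                                 assay.slope)
                pct = pct + rng.normal(0, assay.noise_pct)
                ab = assay.background_absorbance \
                    + (pct / 100.0) * (control - assay.background_absorbance)
                doses[conc] = max(ab, 0.0)
            records.append(AssayRecord(
                construct=r.construct, background_id=r.background,
                substitution=None if pd.isna(r.site) else
                ("?", int(r.site), r.to_state),
                replicate=rep, dose_absorbance=doses,
                control_absorbance=float(control),
                background_absorbance=assay.background_absorbance,
                protein_mass_mg=assay.protein_mass_mg,
                incubation_min=assay.incubation_min))

    truth = AssayTruth(panel=panel_df, alignment=aln,
                       causal_sites=causal_sites, effect=gamma,
                       log10_ic50=true_ic50, activity=true_act,
                       standard_points=(std_conc, std_abs))
    return records, StandardCurve.fit(std_conc, std_abs), truth


def simulate_percent_curves(log10_ic50: float, slope: float = 1.0,
                            noise_pct: float = 5.0, n_replicates: int = 3,
                            seed: int | None = None):
    """Noisy percent-activity curves at the six ouabain concentrations;
    convenience generator for dose-response recovery checks."""
    rng = np.random.default_rng(seed)
    x = np.log10(OUABAIN_CONCENTRATIONS)
    curves = []
    for _ in range(n_replicates):
        y = logistic4p(x, log10_ic50, slope) + rng.normal(0, noise_pct,
                                                          size=x.size)
        curves.append(np.clip(y, -20.0, 120.0))
    return x, curves
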