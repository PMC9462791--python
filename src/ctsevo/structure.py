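"""Spatial clustering and set-overlap tests for candidate coevolving sites.

Distances are alpha-carbon to alpha-carbon in Ångströms. Site labels from
the alignment coordinate system are mapped to structure residue numbers via
an explicit two-column table; no automatic sequence-to-structure alignment
is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_core import StructureModel


def read_site_mapping(path) -> dict[int, int]:
    """CSV with columns alignment_site,structure_residue."""
    df = pd.read_csv(path)
    return dict(zip(df["alignment_site"].astype(int),
                    df["structure_residue"].astype(int)))


@dataclass
class ProximityTest:
    focal: int
    candidates: list
    observed_median: float
    p: float
    n_perm: int
    universe_size: int


def median_distance_test(structure: StructureModel, focal: int,
                         candidates, universe, n_perm: int = 1000,
                         seed: int | None = None,
                         mapping: dict[int, int] | None = None
                         ) -> ProximityTest:
    """Permutation test of spatial proximity of candidate sites to a focal
    site.

    Observed statistic: median CA distance from the focal site to the
    candidate set. Null: medians of random equal-size draws from the
    universe of variable sites. p counts null medians <= observed
    (ties included, conservative), with the add-one rule.
    """
    def to_res(site):
        return mapping.get(site, site) if mapping else site

    def usable(sites):
        kept = [s for s in sites if to_res(s) in structure.coords]
        dropped = set(sites) - set(kept)
        if dropped:
            warnings.warn(f"{len(dropped)} site(s) without CA coordinates "
                          "dropped")
        return kept

    focal_res = to_res(focal)
    if focal_res not in structure.coords:
        raise ValueError("focal site has no CA coordinate")
    cand = usable(list(candidates))
    univ = usable(list(universe))
    if not cand or not univ:
        raise ValueError("no mappable sites left")
    fxyz = structure.coords[focal_res]

    def median_dist(sites):
        return float(np.median([np.linalg.norm(structure.coords[to_res(s)]
                                               - fxyz) for s in sites]))

    obs = median_dist(cand)
    rng = np.random.default_rng(seed)
    univ_arr = np.array(univ)
    k = len(cand)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = median_dist(rng.choice(univ_arr, size=k, replace=False))
    p = (1 + np.sum(null <= obs + 1e-12)) / (1 + n_perm)
    return ProximityTest(focal=focal, candidates=cand, observed_median=obs,
                         p=float(p), n_perm=n_perm, universe_size=len(univ))


@dataclass
class OverlapTest:
    size_a: int
    size_b: int
    universe: int
    overlap: int
    p: float


def overlap_test(set_a, set_b, universe_size: int) -> OverlapTest:
    """Hypergeometric upper-tail enrichment P(X >= k) for the overlap of
    two site sets drawn from a universe of ``universe_size`` sites."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than the universe")
    k = len(a & b)
    p = float(hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return OverlapTest(size_a=len(a), size_b=len(b),
                       universe=universe_size, overlap=k, p=min(p, 1.0))
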