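"""Spatial clustering and overlap tests for candidate co-evolving sites.

Builds a toy helical CA trace, asks whether a candidate site set sits
closer to a focal site than random same-size sets of variable sites
(median CA-CA distance, permutation test), and computes the
hypergeometric enrichment of the overlap between two site sets.
"""

import numpy as np

from ctsevo.io_core import StructureModel
from ctsevo.structure import median_distance_test, overlap_test

# toy alpha-helix: 1.5 A rise and 100 degrees per residue
residues = range(100, 160)
coords = {}
for i, res in enumerate(residues):
    theta = np.deg2rad(100 * i)
    coords[res] = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta),
                            1.5 * i])
structure = StructureModel(chain="A", coords=coords)

focal = 111
universe = [r for r in residues if r != focal]
candidates = [108, 110, 114, 115, 118]  # sequence-local neighbours

test = median_distance_test(structure, focal, candidates, universe,
                            n_perm=1000, seed=11)
print(f"median CA distance from site {focal} to the {len(candidates)} "
      f"candidates: {test.observed_median:.1f} A")
print(f"permutation p (1000 draws of {len(candidates)} of "
      f"{test.universe_size} variable sites): {test.p:.4f}")

enrich = overlap_test({102, 112, 527, 676, 111}, {102, 112, 676, 800}, 417)
print(f"\noverlap of two candidate sets: {enrich.overlap} shared sites, "
      f"hypergeometric P(X >= {enrich.overlap}) = {enrich.p:.2e} "
      f"(universe {enrich.universe})")
print("\nSmall p-values indicate spatial clustering around the focal "
      "site, and overlap beyond chance between independently derived "
      "candidate sets.")
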