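"""Localize the background sites behind background-dependent effects.

Simulates a construct panel in which the background dependence of
substitution effects (delta = |E1 - E2|, percent-activity change measured
on two backgrounds) is driven by a planted set of causal sites, then runs
the full localization: binarized pairwise divergence, correlation
grouping, nested model selection, and the 10,000-permutation null that
repeats the whole ascertainment.
"""

import numpy as np

from ctsevo import assays, epistasis, simulate

records, curve, truth = simulate.simulate_assay_dataset(seed=9)

acts = {}
for rec in records:
    _, a = assays.normalize_assay(rec, curve, volume_uL=50.0)
    acts.setdefault(rec.construct, []).append(a.activity)
mean_act = {k: float(np.mean(v)) for k, v in acts.items()}

panel = epistasis.build_mutant_panel(truth.panel, mean_act)
res = epistasis.localize_background_sites(panel, truth.alignment,
                                          r_threshold=0.8, n_perm=10_000,
                                          seed=10)

print(f"pairwise comparisons: {len(res.comparisons)}  "
      f"variant sites: {res.divergence.shape[1]}  "
      f"correlation groups (|r|>0.8): {len(res.groups)}")
print(f"delta range: {res.delta.min():.1f} .. {res.delta.max():.1f} "
      "percentage points")
print("\nnested model selection (groups added by marginal variance):")
print(res.selection.table.to_string(index=False,
                                    float_format=lambda v: f"{v:.3f}"))
print(f"\ntop-2-group model: R2 = {res.top2_r2:.3f}, "
      f"permutation p = {res.permutation_p:.4f}")
print(f"selected sites: {sorted(res.top2_sites)}")
print(f"planted causal sites: {truth.causal_sites}  (recovered "
      f"{len(set(truth.causal_sites) & set(res.top2_sites))} of "
      f"{len(truth.causal_sites)})")
print("\nA small permutation p says two site-groups explaining this much "
      "of the variance in delta would rarely arise by chance, even after "
      "the same best-two-groups ascertainment.")
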