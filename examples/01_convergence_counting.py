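"""Count convergent and divergent substitutions across branch pairs.

Simulates an amino-acid alignment on a Yule tree with convergence planted
at site 111 (each branch adopts arginine with probability 0.15),
reconstructs ancestral states, extracts per-branch substitutions at
PP > 0.8, and summarizes every comparable branch pair with the
(C+1)/(D+1) statistic and its running average over pair distance.
"""

import numpy as np

from ctsevo import asr, convergence, simulate

tree = simulate.simulate_tree(48, seed=1)
tree = simulate.scale_tree_depth(tree, 0.5)
model = asr.jtt_model(shape=0.7)
planted = simulate.PlantedConvergence(focal_sites=(111,), probability=0.15,
                                      target_state="R")
aln, truth, true_events = simulate.simulate_alignment(
    tree, model, 120, planted=planted, seed=2, first_site_label=60)

post = asr.marginal_asr(aln, tree, model)
calls = asr.call_states(post, threshold=0.8)
states = convergence.node_states(calls, aln, tree)
events = convergence.extract_substitutions(states, tree)
pairs = convergence.pair_table(tree, events)
trend = convergence.running_trend(pairs, window=0.05, step=0.01,
                                  n_boot=100, seed=3)

print(f"substitution events called: {len(events)} "
      f"(true simulated changes: {len(true_events)})")
print(f"comparable branch pairs: {len(pairs)}")
print(f"total convergences C = {pairs.C.sum()}, "
      f"divergences D = {pairs.D.sum()}")
print(f"mean (C+1)/(D+1) = {pairs.ratio.mean():.3f}")
print("\nrunning average of (C+1)/(D+1) vs pair distance "
      "(95% bootstrap band):")
print(trend.head(8).to_string(index=False))
print("\nA ratio near 1 means convergences and divergences are equally "
      "common; the planted arginine pushes C up at short-to-intermediate "
      "distances.")
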