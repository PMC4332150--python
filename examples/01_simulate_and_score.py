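"""Simulate a small two-fraction AP-MS screen and score interactions.

Builds a study-shaped dataset (known planted edges and contaminants),
masks bait self-identifications, fits the control-pool background, and
scores every bait-prey-fraction candidate with the Poisson-mixture
posterior.
"""

import fractionscope as fs

cfg = fs.SimulationConfig(
    n_baits=10, n_preys=600, n_unrelated_controls=12, vector_controls=3,
    replicated_baits_per_fraction=0, edge_density=8.0, seed=42,
)
cm, design, truth = fs.simulate_dataset(cfg)
print(f"matrix: {cm.shape[0]} preys x {cm.shape[1]} purifications "
      f"({design.sample_count} samples, {design.control_count} controls)")

masked, ledger = fs.mask_bait_self(cm, design)
bg = fs.estimate_background(masked, design)
scores = fs.score_interactions(masked, design, bg)

print(f"scored {len(scores)} candidate interactions")
top = scores.nlargest(5, "probability")[
    ["bait", "prey", "fraction", "total_count", "probability", "mu"]]
print(top.to_string(index=False))

# probability is the posterior that the counts come from the true-
# interaction Poisson component rather than the control background;
# negative mu means the prey is rarer in controls than the common-
# contaminant baseline.
planted = sum(
    (b, p, f) in truth.true_edges
    for b, p, f in zip(top["bait"], top["prey"], top["fraction"]))
print(f"{planted} of the top 5 scores are planted true edges")
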