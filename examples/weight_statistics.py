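"""Edge-weight and degree statistics of a generated connectome.

Simulates a network at beta = 1, L_s = 1, then reports the three edge/node
level signatures of brain-like organization: the (negative) Pearson
correlation between edge length and log connection weight, the distribution
family that best fits the strength-normalized weights (one-sample KS across
lognormal / gamma / normal / exponential / Weibull), and the discrete
power-law test of the binarized degree sequence (K_min and alpha from the
Clauset procedure, bootstrap goodness-of-fit p; p >= 0.1 means a scale-free
tail is plausible).
"""

import axogrow as ax

layout = ax.default_layout(radius=30.0, n_nodes=84, rho=1.0, seed=7)
config = ax.GrowthConfig(beta=1.0, step_length=1.0, n_axons=100_000, seed=7)
net = ax.build_network(ax.simulate_axons(layout, config))

r = ax.weight_distance_correlation(net)
print(f"edge length vs log10 weight: Pearson r = {r:.3f} "
      "(negative: nearby regions connect more strongly)")

report = ax.fit_weight_distribution(ax.normalize_weights(net))
print("\nweight-distribution fits (smaller KS = better):")
for family, stat in sorted(report.ks_stats().items(), key=lambda kv: kv[1]):
    marker = "  <- best" if family == report.best_family else ""
    print(f"  {family:<12} KS = {stat:.4f}{marker}")

binary = ax.threshold_to_density(net, 0.05, binarize=True)
sf = ax.scalefree_gof(binary.degree, n_boot=250, seed=7)
print(f"\nscale-free test on 5%-density binarized degrees:")
print(f"  K_min = {sf.k_min}, alpha = {sf.alpha:.2f}, "
      f"bootstrap p = {sf.gof_p:.3f} -> {'plausible' if sf.plausible else 'rejected'}")
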