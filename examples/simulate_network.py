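"""Simulate a weighted connectome by dynamic axon growth.

Builds the default circular domain (R = 30, 84 perturbed nodes), grows 50,000
axons under the chemoattractive force field with beta = 1 and step length
L_s = 1, and tallies them into a weighted undirected network.  Printed output:
the fraction of node pairs connected (density), how many axons ended in the
region they started from (discarded self-connections), and how many never
reached the circumference within S_max steps.
"""

import axogrow as ax

layout = ax.default_layout(radius=30.0, n_nodes=84, rho=1.0, seed=42)
config = ax.GrowthConfig(beta=1.0, step_length=1.0, n_axons=50_000, seed=42)

result = ax.simulate_axons(layout, config)
net = ax.build_network(result)

print(f"axons simulated:        {result.n_axons}")
print(f"successful:             {result.n_successful}")
print(f"unsuccessful (S_max):   {result.n_unsuccessful}")
print(f"self-connections:       {net.meta['self_connections']}")
print(f"connectivity density:   {net.density:.1%} of {84 * 83 // 2} node pairs")
print(f"median steps to target: {int(result.n_steps[result.success_mask].mean())}")

# One axon's path, re-propagated with the scalar stepper:
traj = result.trajectory(0)
print(f"axon 0: {traj.status} after {traj.n_steps} steps, "
      f"seed angle -> endpoint distance "
      f"{float(((traj.positions[0] - traj.positions[-1])**2).sum())**0.5:.1f} length units")
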