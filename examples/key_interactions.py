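"""Which residue contacts control the gate? — spring-perturbation scan.

Every spring is stiffened in turn and the first-order drop in the gate
coordinate's fluctuation is recorded; springs with the largest responses are
the key interactions — stiffening them suppresses gate motion the most, so
they mechanically gate the functional movement.
"""

import numpy as np

import icenm

n = 20
model = icenm.make_synthetic("clamshell", n=n, seed=1)
network = icenm.build_network(model)
H = icenm.hessian(network)
pairs = [(("A", n - k), ("B", n - k)) for k in range(4)]
gate = icenm.gate_coordinate(model, pairs)
mixed = icenm.mixed_space(H, gate.grad)

result = icenm.scan(network, mixed, n_modes=30)   # δγ/γ = 1 per spring
selected = icenm.top_fraction(result, fraction=0.05)

print(f"scanned {result.n_springs} springs; top 5% = {len(selected)} selected")
print("rank  interaction      d0 (Å)   δ<(Δr)²>")
frame = result.to_frame()
for idx in selected:
    row = frame.iloc[idx]
    print(
        f"{int(row['rank']):4d}  {row.chain_i}/{int(row.res_i):<3d}—"
        f"{row.chain_j}/{int(row.res_j):<3d}   {row.d0_A:6.2f}  {row.delta_msfic:+.4f}"
    )

hinge = sum(
    1 for idx in selected
    if frame.iloc[idx].chain_i != frame.iloc[idx].chain_j
)
print(
    f"\n{hinge} of {len(selected)} selected interactions bridge the two lobes.\n"
    "Responses are ≤ 0 (stiffening can only damp the fluctuation); the\n"
    "largest magnitudes cluster at the hinge, the pivot of the gate motion."
)
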