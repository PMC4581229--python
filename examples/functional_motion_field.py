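"""How does each residue move when the gate opens? — the correlation field.

The cross-covariance <Δr ΔR_i> between the gate coordinate and each bead's
displacement, summed over the 30 slowest modes, is the functional motion: a
per-residue arrow field showing the amplitude and direction of the movement
coupled to gate opening.  Exported as NMD for arrow rendering.
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

field = icenm.correlation_field(mixed, model.coords, n_modes=30)
arrows = icenm.functional_displacement(field)
icenm.io.write_nmd("functional_motion.nmd", model, arrows, mode_labels=["gate"])

print(f"gate variance over the window: {field.ic_variance:.4f} (kBT/γ units)")
print("strongest-coupled beads (normalized correlation in [0, 1]):")
order = np.argsort(-field.normalized)[:6]
for i in order:
    c, r = model.chain_ids[i], model.res_numbers[i]
    vx, vy, vz = field.vectors[i]
    print(
        f"  {c}/{r:<3d} |corr| = {field.normalized[i]:.3f}  "
        f"direction = ({vx:+.3f}, {vy:+.3f}, {vz:+.3f})"
    )

a_mean = arrows[model.chain_ids == "A"].mean(axis=0)
b_mean = arrows[model.chain_ids == "B"].mean(axis=0)
print(
    f"\nlobe-averaged arrow directions: A = {np.round(a_mean, 3)}, "
    f"B = {np.round(b_mean, 3)}\n"
    "The two lobes move in opposing directions — the hinge-bending motion\n"
    "that opens the mouth.  Arrows written to functional_motion.nmd."
)
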