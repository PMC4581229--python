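"""Which normal modes move the gate? — per-mode gate fluctuation (MSFIC).

Builds a C2-symmetric clamshell bead model (two domains hinged like the
transmembrane dimer of an ABC transporter), defines the gate coordinate as
the mean distance over four bead pairs across the open mouth, and ranks the
30 slowest modes by how much of the gate's thermal fluctuation each carries.
"""

import numpy as np

import icenm

n = 20
model = icenm.make_synthetic("clamshell", n=n, seed=1)
network = icenm.build_network(model)           # 12 Å cutoff, unit springs
H = icenm.hessian(network)

# gate: four cross-lobe pairs at the mouth, mirroring a channel gate defined
# by four residue pairs across the two monomers
pairs = [(("A", n - k), ("B", n - k)) for k in range(4)]
gate = icenm.gate_coordinate(model, pairs)
print(f"{2 * n} beads, {network.n_springs} springs, gate opening r0 = {gate.r0:.2f} Å")

mixed = icenm.mixed_space(H, gate.grad)
profile = icenm.msfic_profile(mixed, n_modes=30)

print(f"total gate variance over 30 modes: {profile.total:.4f} (kBT/γ units)")
print("mode  eigenvalue   MSFIC   distinct")
for k, lam, v, d in zip(
    profile.mode_indices, profile.eigenvalues, profile.msfic, profile.distinct
):
    if v > 0.01 * profile.msfic.max():
        print(f"{k:4d}  {lam:10.4f}  {v:6.4f}  {'  *' if d else ''}")

distinct = profile.mode_indices[profile.distinct]
print(
    f"\n{len(distinct)} of 30 modes dominate the gate motion: {list(distinct)}.\n"
    "MSFIC is each mode's share of <(Δr)²>; a handful of slow modes carrying\n"
    "most of it means the gate opening is encoded in a few collective motions."
)
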