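"""Per-residue displacement between two conformers after superposition.

Given two conformations of the same structure, Kabsch superposition removes
the rigid-body difference and the residual per-residue distances show which
parts actually moved — the experimental counterpart of the computed
functional motion field.
"""

import numpy as np

import icenm

model = icenm.make_synthetic("clamshell", n=20, seed=1)

# make an "open" conformer: swing each lobe 6° further about the hinge (z axis
# through the origin region), mimicking a gate-opening transition
ang = np.deg2rad(6.0)


def rot_y(a):
    return np.array(
        [[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]]
    )


coords = model.coords.copy()
a_mask = model.chain_ids == "A"
coords[a_mask] = coords[a_mask] @ rot_y(ang).T
coords[~a_mask] = coords[~a_mask] @ rot_y(-ang).T
open_model = icenm.CalphaModel(
    model.chain_ids.copy(), model.res_numbers.copy(),
    model.res_names.copy(), coords,
)

rotation, translation, rmsd = icenm.superpose(open_model, model)
print(f"RMSD between conformers after superposition: {rmsd:.3f} Å")

profile = icenm.residue_displacements(open_model, model)
profile.write_csv("displacements.csv")
top = np.argsort(-profile.displacements)[:5]
print("largest displacements:")
for i in top:
    print(
        f"  {profile.chain_ids[i]}/{profile.res_numbers[i]:<3d}"
        f"  {profile.displacements[i]:.2f} Å"
    )
print(
    "\nBeads far from the hinge move the most (lever arm of the opening);\n"
    "full profile written to displacements.csv."
)
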