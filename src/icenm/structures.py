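"""Cα structure handling: PDB input, synthetic bead models, superposition.

A protein is reduced to one bead per residue at its Cα position.  This module
reads such models from PDB files, generates small synthetic bead models for
testing and method validation, and computes per-residue displacements between
two conformers after least-squares rigid superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial import cKDTree


class StructureError(ValueError):
    """Raised for unusable structural input (empty selection, bad pairing...)."""


@dataclass
class CalphaModel:
    """One bead per residue, identified by (chain_id, author residue number).

    Parameters
    ----------
    chain_ids : array of str, shape (N,)
    res_numbers : array of int, shape (N,)
        Author (PDB) numbering; never re-indexed.
    res_names : array of str, shape (N,)
        Three-letter residue codes ("UNK" for synthetic beads).
    coords : array, shape (N, 3)
        Cα coordinates in Å.
    b_exp : optional array, shape (N,)
        Experimental B-factors in Å², if present in the source.
    """

    chain_ids: np.ndarray
    res_numbers: np.ndarray
    res_names: np.ndarray
    coords: np.ndarray
    b_exp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.res_numbers = np.asarray(self.res_numbers, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.b_exp is not None:
            self.b_exp = np.asarray(self.b_exp, dtype=float)
        n = len(self.coords)
        if n < 2:
            raise StructureError("a model needs at least 2 residues")
        if self.coords.shape != (n, 3) or not np.all(np.isfinite(self.coords)):
            raise StructureError("coordinates must be a finite (N, 3) array")
        keys = list(zip(self.chain_ids, self.res_numbers))
        if len(set(keys)) != n:
            raise StructureError("duplicate (chain_id, res_number) identifiers")
        self._index = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self.coords)

    def index_of(self, chain_id: str, res_number: int) -> int:
        """Row index of a residue, by chain and author number."""
        try:
            return self._index[(chain_id, int(res_number))]
        except KeyError:
            raise StructureError(
                f"residue {chain_id}/{res_number} not in model"
            ) from None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CalphaModel":
        """Copy of the model with ``x -> R x + t`` applied to every bead."""
        return CalphaModel(
            self.chain_ids.copy(),
            self.res_numbers.copy(),
            self.res_names.copy(),
            self.coords @ np.asarray(rotation).T + np.asarray(translation),
            None if self.b_exp is None else self.b_exp.copy(),
        )


@dataclass
class DisplacementProfile:
    """Per-residue displacement magnitudes between two superposed conformers."""

    chain_ids: np.ndarray
    res_numbers: np.ndarray
    displacements: np.ndarray  # Å, ordered as in the reference model
    n_unpaired: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chain_id": self.chain_ids,
                "res_number": self.res_numbers,
                "displacement_A": self.displacements,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_calpha_pdb(
    path,
    chains: Sequence[str] | None = None,
    model_index: int = 0,
) -> CalphaModel:
    """Read a PDB file down to one Cα bead per residue.

    Keeps ATOM records named CA of the selected model (default: first),
    resolving alternate locations by highest occupancy (ties by altloc letter).
    HETATM records — ligands, cofactors, nucleotides, waters — are excluded:
    the network nodes are residue Cα atoms only.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(
        model=model_index + 1,
        altloc="occupancy",
        extra_fields=["b_factor"],
    )
    mask = (atoms.atom_name == "CA") & (~atoms.hetero) & (atoms.element == "C")
    if chains is not None:
        mask &= np.isin(atoms.chain_id, list(chains))
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise StructureError("zero Cα atoms after filtering")

    keys = list(zip(atoms.chain_id.tolist(), atoms.res_id.tolist()))
    if len(set(keys)) != len(keys):
        raise StructureError("duplicate Cα for one residue after altloc resolution")
    return CalphaModel(
        np.array(atoms.chain_id, dtype=object),
        np.array(atoms.res_id, dtype=int),
        np.array(atoms.res_name, dtype=object),
        np.array(atoms.coord, dtype=float),
        np.array(atoms.b_factor, dtype=float),
    )


def read_calpha_csv(path) -> CalphaModel:
    """Read a bead model from CSV with columns chain_id,res_number,res_name,x,y,z[,b_exp]."""
    import pandas as pd

    df = pd.read_csv(path)
    return CalphaModel(
        df["chain_id"].astype(str).to_numpy(dtype=object),
        df["res_number"].to_numpy(dtype=int),
        df["res_name"].astype(str).to_numpy(dtype=object)
        if "res_name" in df
        else np.array(["UNK"] * len(df), dtype=object),
        df[["x", "y", "z"]].to_numpy(dtype=float),
        df["b_exp"].to_numpy(dtype=float) if "b_exp" in df else None,
    )


def _paired_indices(a: CalphaModel, b: CalphaModel) -> tuple[np.ndarray, np.ndarray]:
    keys_b = {(c, r): i for i, (c, r) in enumerate(zip(b.chain_ids, b.res_numbers))}
    ia, ib = [], []
    for i, key in enumerate(zip(a.chain_ids, a.res_numbers)):
        j = keys_b.get(key)
        if j is not None:
            ia.append(i)
            ib.append(j)
    return np.array(ia, dtype=int), np.array(ib, dtype=int)


def superpose(
    mobile: CalphaModel, reference: CalphaModel
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares (Kabsch) rigid fit of ``mobile`` onto ``reference``.

    Residues are paired by (chain_id, res_number).  Returns ``(R, t, rmsd)``
    such that ``R x + t`` maps mobile coordinates onto the reference frame;
    R is a proper rotation (det +1) and rmsd is over the paired residues.
    """
    im, ir = _paired_indices(mobile, reference)
    if len(im) < 3:
        raise StructureError(f"only {len(im)} paired residues; need at least 3")
    xm = mobile.coords[im]
    xr = reference.coords[ir]
    cm, cr = xm.mean(axis=0), xr.mean(axis=0)
    dm, dr = xm - cm, xr - cr
    # collinear pairings leave the rotation about the common axis undetermined
    if np.linalg.matrix_rank(dm, tol=1e-8 * max(1.0, np.abs(dm).max())) < 2:
        raise StructureError("paired coordinates are collinear; rotation is degenerate")
    rot, _ = Rotation.align_vectors(dr, dm)
    R = rot.as_matrix()
    t = cr - R @ cm
    rmsd = float(np.sqrt(np.mean(np.sum((xm @ R.T + t - xr) ** 2, axis=1))))
    return R, t, rmsd


def residue_displacements(
    model_a: CalphaModel, model_b: CalphaModel
) -> DisplacementProfile:
    """Per-residue |Δx| (Å) after superposing ``model_a`` onto ``model_b``.

    Residues present in only one conformer are dropped; their count is kept
    on the returned profile.
    """
    R, t, _ = superpose(model_a, model_b)
    ia, ib = _paired_indices(model_a, model_b)
    moved = model_a.coords[ia] @ R.T + t
    disp = np.linalg.norm(moved - model_b.coords[ib], axis=1)
    n_unpaired = (len(model_a) - len(ia)) + (len(model_b) - len(ib))
    return DisplacementProfile(
        model_a.chain_ids[ia].copy(),
        model_a.res_numbers[ia].copy(),
        disp,
        n_unpaired=n_unpaired,
    )


# ---------------------------------------------------------------------------
# synthetic bead models
# ---------------------------------------------------------------------------

#: default minimum separation between synthetic beads (Å); roughly the
#: Cα–Cα virtual bond length of a polypeptide chain.
MIN_SEPARATION = 3.5
_DEFAULT_CUTOFF = 12.0


def _check_model(coords: np.ndarray, min_sep: float, cutoff: float) -> None:
    n = len(coords)
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    if n > 1 and d[:, 1].min() < min_sep - 1e-9:
        raise StructureError(
            f"beads closer than the minimum separation {min_sep} Å"
        )
    # connectivity of the contact graph at the default cutoff
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    if len(pairs) == 0 and n > 1:
        raise StructureError("contact network is disconnected at the default cutoff")
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    ncomp, _ = connected_components(adj, directed=False)
    if ncomp != 1:
        raise StructureError("contact network is disconnected at the default cutoff")


def _rigid_ok(coords: np.ndarray, cutoff: float) -> bool:
    """True when the contact network at ``cutoff`` has exactly 6 zero modes.

    Random bead clouds can contain local mechanisms (e.g. a bead hanging off
    a single spring swings freely); the synthetic generators reject such
    draws so downstream spectra always see a rigid, connected network.
    """
    from .enm import build_network, hessian  # deferred: enm imports this module

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        H = hessian(build_network(coords, cutoff=cutoff))
    w = np.linalg.eigvalsh(H)
    lam_max = max(w[-1], 1.0)
    if int(np.sum(w < 1e-8 * lam_max)) != 6:
        return False
    # also reject near-mechanisms: a barely-constrained bead gives one bead a
    # fluctuation orders of magnitude above the rest, unlike any real protein
    return bool(w[6] >= 1e-4 * lam_max)


def _model_from_coords(
    coords: np.ndarray,
    chain_ids: Iterable[str],
    min_sep: float = MIN_SEPARATION,
    cutoff: float = _DEFAULT_CUTOFF,
    check_rigid: bool = False,
) -> CalphaModel:
    coords = np.asarray(coords, dtype=float)
    _check_model(coords, min_sep, cutoff)
    if check_rigid and not _rigid_ok(coords, cutoff):
        raise StructureError("network has floppy internal mechanisms")
    chain_ids = np.array(list(chain_ids), dtype=object)
    res_numbers = np.zeros(len(coords), dtype=int)
    for c in np.unique(chain_ids.astype(str)):
        sel = chain_ids == c
        res_numbers[sel] = np.arange(1, sel.sum() + 1)
    return CalphaModel(
        chain_ids,
        res_numbers,
        np.array(["UNK"] * len(coords), dtype=object),
        coords,
    )


def _blob(
    n: int, rng: np.random.Generator, min_sep: float, radius_factor: float = 1.2
) -> np.ndarray:
    """Random compact bead cloud (centered) with a minimum pairwise separation.

    Sequential rejection sampling inside a ball whose radius grows with n so
    the construction always terminates; beads stay close enough that the
    contact graph at the default cutoff is connected within the cloud.
    """
    radius = max(6.0, 1.1 * min_sep * n ** (1 / 3) * radius_factor)
    pts: list[np.ndarray] = []
    while len(pts) < n:
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) > radius:
            continue
        if all(np.linalg.norm(p - q) >= min_sep for q in pts):
            pts.append(p)
    return np.array(pts)


def _place_c2(monomer: np.ndarray, min_sep: float, cutoff: float) -> np.ndarray:
    """Slide a monomer along +x until its C2 image clears the separation.

    The image under the 180° z rotation slides the opposite way, so the
    cross-chain minimum distance grows monotonically with the shift; the
    smallest admissible shift keeps the interface within the contact cutoff
    (connected dimer network).
    """
    R = _c2_rotation()
    for shift in np.arange(0.0, 200.0, 0.25):
        a = monomer + np.array([shift, 0.0, 0.0])
        b = a @ R.T
        dmin = np.min(
            np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        )
        if dmin >= min_sep:
            if dmin >= cutoff:
                raise StructureError(
                    "cannot satisfy both separation and connectivity"
                )
            return np.vstack([a, b])
    raise StructureError("failed to place C2 copy")  # pragma: no cover


def make_synthetic(kind: str, **params) -> CalphaModel:
    """Generate a deterministic synthetic bead model.

    Kinds
    -----
    two_node : two beads on the x axis, ``d`` Å apart (default 5), chains A/B.
    chain    : ``n`` beads along x, ``spacing`` Å apart (default 3.8), chain A.
    ring     : ``n`` beads on a circle with ``spacing`` Å arc neighbors.
    c2_dimer : two random blobs of ``n`` beads (chains A, B) exactly symmetric
               under a 180° rotation about the z axis combined with the A↔B
               chain swap; see :func:`c2_symmetry_map`.
    clamshell: two lobes (chains A, B) hinged near the origin and opening
               like a clam in the x–z plane, C2-symmetric about the z axis;
               ``n`` beads per lobe.  The mouth (large-|x|, low-z bead pairs)
               is the natural place to define a gate coordinate.

    All kinds honor a minimum bead separation and a connected contact network
    at the default 12 Å cutoff; violations raise :class:`StructureError`.
    """
    if kind == "two_node":
        d = float(params.get("d", 5.0))
        if d <= 0:
            raise StructureError("d must be positive")
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        # bypass connectivity check: a lone spring pair may exceed the cutoff
        if d < MIN_SEPARATION:
            raise StructureError("two_node separation below minimum")
        return CalphaModel(
            np.array(["A", "B"], dtype=object),
            np.array([1, 1]),
            np.array(["UNK", "UNK"], dtype=object),
            coords,
        )
    if kind == "chain":
        n = int(params.get("n", 10))
        spacing = float(params.get("spacing", 3.8))
        if n < 2 or spacing < MIN_SEPARATION:
            raise StructureError("need n >= 2 and spacing >= minimum separation")
        coords = np.zeros((n, 3))
        coords[:, 0] = spacing * np.arange(n)
        return _model_from_coords(coords, ["A"] * n)
    if kind == "ring":
        n = int(params.get("n", 12))
        spacing = float(params.get("spacing", 3.8))
        if n < 3 or spacing < MIN_SEPARATION:
            raise StructureError("need n >= 3 and spacing >= minimum separation")
        radius = spacing / (2 * np.sin(np.pi / n))
        ang = 2 * np.pi * np.arange(n) / n
        coords = np.stack(
            [radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)], axis=1
        )
        return _model_from_coords(coords, ["A"] * n)
    if kind == "c2_dimer":
        n = int(params.get("n", 20))
        seed = int(params.get("seed", 0))
        if n < 2:
            raise StructureError("need n >= 2 beads per chain")
        for attempt in range(20):  # deterministic retry against floppy draws
            rng = np.random.default_rng([seed, attempt])
            monomer = _blob(n, rng, MIN_SEPARATION)
            coords = _place_c2(monomer, MIN_SEPARATION, _DEFAULT_CUTOFF)
            try:
                return _model_from_coords(
                    coords, ["A"] * n + ["B"] * n, check_rigid=True
                )
            except StructureError:
                continue
        raise StructureError("could not draw a rigid connected c2_dimer")
    if kind == "clamshell":
        n = int(params.get("n", 20))
        seed = int(params.get("seed", 0))
        opening = float(params.get("opening_deg", 50.0))
        if n < 3:
            raise StructureError("need n >= 3 beads per lobe")
        half = np.deg2rad(opening / 2.0)
        rot_y = np.array(
            [
                [np.cos(half), 0.0, np.sin(half)],
                [0.0, 1.0, 0.0],
                [-np.sin(half), 0.0, np.cos(half)],
            ]
        )
        axis = rot_y @ np.array([0.0, 0.0, 1.0])
        for attempt in range(20):  # deterministic retry against floppy draws
            rng = np.random.default_rng([seed, attempt])
            # lobe A: a compact ellipsoidal domain whose long axis tilts away
            # from the C2 (z) axis, so the dimer opens like a clam in x–z;
            # beads are ordered along the axis (residue 1 = hinge end,
            # residue n = mouth tip), making gate pairs easy to name.
            lobe = _blob(n, rng, MIN_SEPARATION, radius_factor=1.0)
            lobe[:, 2] *= 1.8  # elongate; distances only grow, min_sep holds
            lobe = lobe @ rot_y.T
            lobe = lobe[np.argsort(lobe @ axis)]
            coords = _place_c2(lobe, MIN_SEPARATION, _DEFAULT_CUTOFF)
            try:
                return _model_from_coords(
                    coords, ["A"] * n + ["B"] * n, check_rigid=True
                )
            except StructureError:
                continue
        raise StructureError("could not draw a rigid connected clamshell")
    raise StructureError(f"unknown synthetic kind {kind!r}")


def _c2_rotation() -> np.ndarray:
    """180° rotation about the z axis (the declared C2 axis of the dimers)."""
    return np.diag([-1.0, -1.0, 1.0])


def c2_symmetry_map(model: CalphaModel) -> tuple[np.ndarray, np.ndarray]:
    """(rotation, permutation) of the declared C2 symmetry of a synthetic dimer.

    Returns the 3×3 rotation about z and the bead permutation that swaps
    chains A and B residue-by-residue; applying both maps the coordinate set
    onto itself for ``c2_dimer`` and ``clamshell`` models.
    """
    n = len(model)
    perm = np.empty(n, dtype=int)
    swap = {"A": "B", "B": "A"}
    for i in range(n):
        c = str(model.chain_ids[i])
        perm[i] = model.index_of(swap.get(c, c), model.res_numbers[i])
    return _c2_rotation(), perm
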