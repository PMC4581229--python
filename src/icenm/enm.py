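"""Anisotropic network model: Hessian construction, decomposition, observables.

Each residue Cα is a node; node pairs closer than a cutoff (12.0 Å by
default) are joined by identical Hookean springs of constant γ.  The
potential is V = ½ γ ΔRᵀ H ΔR with H the 3N×3N Hessian of the pairwise
distance-restraint energy at the reference coordinates.  Eigendecomposition
of H yields the normal modes; the six zero-eigenvalue modes are rigid-body
translations/rotations and are excluded from all fluctuation sums.

Units are reduced: kBT = γ = 1 unless stated otherwise.  Every quantity used
for ranking modes or interactions is invariant to the kBT/γ prefactor; the
absolute scale only matters for B-factor calibration, which is opt-in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structures import CalphaModel

DEFAULT_CUTOFF = 12.0  # Å


class NetworkError(ValueError):
    pass


class SpectrumError(RuntimeError):
    pass


@dataclass
class ElasticNetwork:
    """Node coordinates plus springs (i < j pairs with reference lengths)."""

    coords: np.ndarray          # (N, 3) Å
    springs: np.ndarray         # (S, 2) int, i < j
    d0: np.ndarray              # (S,) Å reference lengths
    cutoff: float
    gamma: float = 1.0
    connected: bool = True
    chain_ids: np.ndarray | None = None
    res_numbers: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_springs(self) -> int:
        return len(self.springs)

    def spring_index(self, i: int, j: int) -> int:
        i, j = (i, j) if i < j else (j, i)
        hits = np.nonzero((self.springs[:, 0] == i) & (self.springs[:, 1] == j))[0]
        if len(hits) == 0:
            raise NetworkError(f"no spring between nodes {i} and {j}")
        return int(hits[0])

    def labels(self, node: int) -> tuple[str, int]:
        if self.chain_ids is None:
            return ("A", node + 1)
        return (str(self.chain_ids[node]), int(self.res_numbers[node]))


@dataclass
class Spectrum:
    """Eigendecomposition of a symmetric 3N×3N Hessian.

    ``eigenvalues`` ascend; ``eigenvectors[:, k]`` is the k-th (orthonormal)
    mode.  ``n_zero`` eigenvalues fall below ``zero_tol`` and are treated as
    rigid-body modes.  When ``partial`` is True only the lowest modes were
    solved for (enough for truncated-mode analyses of large systems).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int
    zero_tol: float
    partial: bool = False

    @property
    def n_nonzero(self) -> int:
        return len(self.eigenvalues) - self.n_zero

    def nonzero_modes(self, n_modes: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues, eigenvectors) of the first ``n_modes`` non-rigid modes."""
        avail = self.n_nonzero
        if n_modes is None:
            n_modes = avail
        if n_modes < 1 or n_modes > avail:
            raise SpectrumError(
                f"n_modes={n_modes} outside the {avail} available nonzero modes"
            )
        sl = slice(self.n_zero, self.n_zero + n_modes)
        return self.eigenvalues[sl], self.eigenvectors[:, sl]


def build_network(
    model: CalphaModel | np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = 1.0,
) -> ElasticNetwork:
    """Connect every node pair strictly closer than ``cutoff`` with a spring.

    A disconnected contact graph is allowed but flagged (and warned about):
    the Hessian then has more than six zero modes.
    """
    if isinstance(model, CalphaModel):
        coords = model.coords
        chain_ids, res_numbers = model.chain_ids, model.res_numbers
    else:
        coords = np.asarray(model, dtype=float)
        chain_ids = res_numbers = None
    n = len(coords)
    if n < 2:
        raise NetworkError("need at least 2 nodes")
    pairs = cKDTree(coords).query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs) > 0:
        d = np.linalg.norm(coords[pairs[:, 1]] - coords[pairs[:, 0]], axis=1)
        keep = d < cutoff  # strict inequality; boundary ties excluded
        pairs, d = pairs[keep], d[keep]
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs, d = pairs[order], d[order]
    else:
        d = np.zeros(0)
    adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    ncomp, _ = connected_components(adj, directed=False)
    connected = ncomp == 1
    if not connected:
        warnings.warn(
            f"elastic network is disconnected ({ncomp} components); "
            "expect more than six zero modes",
            stacklevel=2,
        )
    return ElasticNetwork(
        coords=np.array(coords, dtype=float),
        springs=pairs.astype(int).reshape(-1, 2),
        d0=d,
        cutoff=float(cutoff),
        gamma=float(gamma),
        connected=connected,
        chain_ids=None if chain_ids is None else chain_ids.copy(),
        res_numbers=None if res_numbers is None else res_numbers.copy(),
    )


def hessian(network: ElasticNetwork) -> np.ndarray:
    """Dense 3N×3N ANM Hessian (unit spring constant; γ enters as prefactor).

    Spring (i, j) contributes the super-element with off-diagonal 3×3 block
    −(r̂)(r̂)ᵀ where r̂ = (r_j − r_i)/d0, and the negated block on the two
    diagonals, so every block row sums to zero (translation invariance).
    """
    n = network.n_nodes
    H = np.zeros((3 * n, 3 * n))
    for (i, j), d0 in zip(network.springs, network.d0):
        dv = (network.coords[j] - network.coords[i]) / d0
        blk = np.outer(dv, dv)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[si, sj] -= blk
        H[sj, si] -= blk
        H[si, si] += blk
        H[sj, sj] += blk
    return H


def decompose(
    H: np.ndarray,
    zero_tol_rel: float = 1e-8,
    n_modes: int | None = None,
    expect_rigid: int | None = 6,
) -> Spectrum:
    """Eigendecompose a symmetric Hessian and identify the zero modes.

    ``n_modes`` requests a partial solve of only the lowest eigenpairs (the
    zero modes are always included in the count).  ``expect_rigid`` triggers a
    warning when the zero-mode count differs from the expectation (6 for a
    connected non-collinear network); pass None to silence it.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise SpectrumError("Hessian must be square")
    if not np.allclose(H, H.T, atol=1e-8 * max(1.0, np.abs(H).max())):
        raise SpectrumError("Hessian must be symmetric")
    dim = H.shape[0]
    partial = n_modes is not None and n_modes < dim
    if partial:
        w, U = scipy.linalg.eigh(H, subset_by_index=[0, n_modes - 1])
        # the relative zero threshold needs the top of the spectrum; bound it
        # cheaply by the max absolute row sum (Gershgorin)
        lam_max = float(np.abs(H).sum(axis=1).max())
    else:
        w, U = scipy.linalg.eigh(H)
        lam_max = float(w[-1]) if w[-1] > 0 else 1.0
    zero_tol = zero_tol_rel * lam_max
    n_zero = int(np.sum(w < zero_tol))
    if np.any(w[n_zero:] <= 0):
        raise SpectrumError("negative eigenvalue beyond the zero-mode threshold")
    if expect_rigid is not None and n_zero != expect_rigid:
        warnings.warn(
            f"found {n_zero} zero modes (expected {expect_rigid}); the network "
            "may be disconnected or collinear",
            stacklevel=2,
        )
    return Spectrum(w, U, n_zero=n_zero, zero_tol=zero_tol, partial=partial)


def residue_msf(
    spectrum: Spectrum,
    kBT_over_gamma: float = 1.0,
    n_modes: int | None = None,
) -> np.ndarray:
    """Per-residue mean-square fluctuation ⟨|ΔR_i|²⟩ over the nonzero modes.

    MSF_i = (kBT/γ) Σ_k λ_k⁻¹ |u_k,i|² with u_k,i the 3-component of mode k
    on residue i; the sum runs over the first ``n_modes`` non-rigid modes
    (all of them by default).
    """
    w, U = spectrum.nonzero_modes(n_modes)
    contrib = (U ** 2) / w  # (3N, k)
    per_coord = contrib.sum(axis=1)
    return kBT_over_gamma * per_coord.reshape(-1, 3).sum(axis=1)


def bfactors(msf: np.ndarray) -> np.ndarray:
    """Crystallographic B-factor from MSF: B_i = (8π²/3)·⟨|ΔR_i|²⟩."""
    return (8.0 * np.pi ** 2 / 3.0) * np.asarray(msf, dtype=float)


def calibrate_gamma(b_calc_unit: np.ndarray, b_exp: np.ndarray) -> float:
    """Spring constant γ matching computed B-factors to experiment.

    ``b_calc_unit`` are B-factors computed at γ = 1, so B_calc(γ) = b_unit/γ;
    the γ minimizing Σ(B_calc − B_exp)² is the through-origin least-squares
    slope γ = Σ b_unit² / Σ b_unit·b_exp.
    """
    b_calc_unit = np.asarray(b_calc_unit, dtype=float)
    b_exp = np.asarray(b_exp, dtype=float) if b_exp is not None else None
    if b_exp is None or len(b_exp) != len(b_calc_unit):
        raise ValueError("experimental B-factors missing or of wrong length")
    denom = float(b_calc_unit @ b_exp)
    if denom <= 0 or not np.any(b_exp):
        raise ValueError("experimental B-factors are all zero or anticorrelated")
    return float(b_calc_unit @ b_calc_unit) / denom


def covariance(
    spectrum: Spectrum,
    kBT_over_gamma: float = 1.0,
    n_modes: int | None = None,
) -> np.ndarray:
    """Mode-limited covariance (kBT/γ)·Σ_k λ_k⁻¹ u_k u_kᵀ (the pseudo-inverse
    of H scaled by kBT/γ when all nonzero modes are used)."""
    w, U = spectrum.nonzero_modes(n_modes)
    return kBT_over_gamma * (U / w) @ U.T


def cross_correlation(
    spectrum: Spectrum,
    i: int,
    j: int,
    kBT_over_gamma: float = 1.0,
    n_modes: int | None = None,
) -> float:
    """⟨ΔR_i·ΔR_j⟩: sum of the three per-axis covariance terms for residues i, j."""
    w, U = spectrum.nonzero_modes(n_modes)
    dim = U.shape[0]
    if not (0 <= 3 * i < dim and 0 <= 3 * j < dim):
        raise IndexError("residue index out of range")
    ui = U[3 * i : 3 * i + 3, :]
    uj = U[3 * j : 3 * j + 3, :]
    return float(kBT_over_gamma * np.sum((ui * uj).sum(axis=0) / w))
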