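"""Function-related internal coordinate and the internal/Cartesian transform.

The internal coordinate Δr is the (weighted) mean of a few inter-residue
distances — e.g. the Cα–Cα separations across a transport channel's
cytoplasmic gate — linearized around the reference structure.  Its gradient
a (a 3N vector) defines a coordinate transform A that replaces one Cartesian
coordinate (index m) with Δr:

    A = I except row m, which is aᵀ           (q = A ΔR)
    H' = (A⁻¹)ᵀ H A⁻¹                         (Hessian in the mixed space)

H' shares the inertia of H (congruence), so the six rigid-body modes stay at
zero; per-mode fluctuation of Δr and its residue correlations then read off
the m-th row/column of the mixed-space spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .enm import Spectrum, decompose
from .structures import CalphaModel, StructureError

ResidueKey = tuple[str, int]


@dataclass
class GateCoordinate:
    """Weighted-mean-distance internal coordinate over residue pairs."""

    pairs: list[tuple[ResidueKey, ResidueKey]]
    pair_indices: np.ndarray   # (P, 2) node indices
    weights: np.ndarray        # (P,), sums to 1
    r0: float                  # reference value, Å
    grad: np.ndarray           # (3N,) gradient a of the coordinate

    @property
    def n_pairs(self) -> int:
        return len(self.weights)


def pair_distance_gradient(
    coord_i: np.ndarray, coord_j: np.ndarray
) -> tuple[float, np.ndarray]:
    """Distance r_ij and its 6-vector of partials w.r.t. (x_i, x_j).

    ∂r/∂x_i = (x_i − x_j)/r and the symmetric partner for j; the two
    3-blocks are antiparallel unit vectors.
    """
    ci = np.asarray(coord_i, dtype=float)
    cj = np.asarray(coord_j, dtype=float)
    diff = ci - cj
    r = float(np.linalg.norm(diff))
    if r <= 0:
        raise ValueError("coincident points: distance gradient undefined")
    g = np.concatenate([diff / r, -diff / r])
    return r, g


def gate_coordinate(
    model: CalphaModel,
    pairs: Sequence[tuple[ResidueKey, ResidueKey]],
    weights: Sequence[float] | None = None,
) -> GateCoordinate:
    """Build the internal coordinate from residue pairs on a model.

    ``pairs`` are ((chain, res_number), (chain, res_number)) tuples; weights
    default to uniform 1/P.  The returned gradient is scattered into the 3N
    vector and is, by construction, orthogonal to the rigid-body space.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one residue pair")
    P = len(pairs)
    if weights is None:
        w = np.full(P, 1.0 / P)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != P or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative and sum to > 0")
        w = w / w.sum()
    n = len(model)
    grad = np.zeros(3 * n)
    idx = np.zeros((P, 2), dtype=int)
    r0 = 0.0
    for p, ((ca, ra), (cb, rb)) in enumerate(pairs):
        ia = model.index_of(ca, ra)
        ib = model.index_of(cb, rb)
        if ia == ib:
            raise StructureError(f"pair {p} references the same residue twice")
        idx[p] = (ia, ib)
        r, g = pair_distance_gradient(model.coords[ia], model.coords[ib])
        r0 += w[p] * r
        grad[3 * ia : 3 * ia + 3] += w[p] * g[:3]
        grad[3 * ib : 3 * ib + 3] += w[p] * g[3:]
    return GateCoordinate(
        pairs=[((str(ca), int(ra)), (str(cb), int(rb))) for (ca, ra), (cb, rb) in pairs],
        pair_indices=idx,
        weights=w,
        r0=float(r0),
        grad=grad,
    )


def choose_replaced_index(grad: np.ndarray) -> int:
    """Cartesian coordinate to replace by the internal coordinate.

    The largest-|a_k| entry maximizes |det A| (= |a_m|) and hence the
    conditioning of the transform; ties break to the lowest index.
    """
    grad = np.asarray(grad, dtype=float)
    if not np.any(grad):
        raise ValueError("zero gradient: internal coordinate is degenerate")
    return int(np.argmax(np.abs(grad)))


@dataclass
class MixedSpace:
    """The internal/Cartesian space: transform, transformed Hessian, spectrum.

    ``A`` is identity except row m = aᵀ; its inverse is identity except row m
    with entries −a_k/a_m (k ≠ m) and 1/a_m at m, so both are applied in
    O(N) without forming matrices.  ``spectrum`` decomposes the symmetrized
    H' = (A⁻¹)ᵀ H A⁻¹; "mixed mode k" is the k-th nonzero mode, ascending.
    """

    grad: np.ndarray
    m: int
    H_mixed: np.ndarray
    spectrum: Spectrum

    @property
    def dim(self) -> int:
        return len(self.grad)

    def matrix_A(self) -> np.ndarray:
        A = np.eye(self.dim)
        A[self.m, :] = self.grad
        return A

    def matrix_A_inv(self) -> np.ndarray:
        B = np.eye(self.dim)
        B[self.m, :] = -self.grad / self.grad[self.m]
        B[self.m, self.m] = 1.0 / self.grad[self.m]
        return B

    def apply_A(self, x: np.ndarray) -> np.ndarray:
        """A x: copy of x with component m replaced by a·x (along axis 0)."""
        y = np.array(x, dtype=float)
        y[self.m] = self.grad @ x
        return y

    def apply_A_inv(self, q: np.ndarray) -> np.ndarray:
        """A⁻¹ q: Cartesian vector whose gate coordinate equals q_m."""
        x = np.array(q, dtype=float)
        a, m = self.grad, self.m
        x[m] = (q[m] - a @ q + a[m] * q[m]) / a[m]
        return x


def mixed_hessian(H: np.ndarray, grad: np.ndarray, m: int) -> np.ndarray:
    """H' = (A⁻¹)ᵀ H A⁻¹ via rank-one updates (A differs from I in one row).

    With A⁻¹ = I + e_m cᵀ (c = row m of A⁻¹ minus e_m):
    H' = H + h cᵀ + c hᵀ + H_mm c cᵀ, h the m-th column of H — symmetric by
    construction; explicitly symmetrized to scrub round-off.
    """
    H = np.asarray(H, dtype=float)
    grad = np.asarray(grad, dtype=float)
    if grad[m] == 0:
        raise ValueError("grad[m] = 0: transform is singular")
    c = -grad / grad[m]
    c[m] = 1.0 / grad[m] - 1.0
    h = H[:, m]
    Hm = H + np.outer(h, c) + np.outer(c, h) + H[m, m] * np.outer(c, c)
    return (Hm + Hm.T) / 2.0


def mixed_space(
    H: np.ndarray,
    grad: np.ndarray,
    m: int | None = None,
    n_modes: int | None = None,
    zero_tol_rel: float = 1e-8,
) -> MixedSpace:
    """Transform a Hessian into the internal/Cartesian space and decompose it.

    ``m`` defaults to :func:`choose_replaced_index`.  ``n_modes`` requests a
    partial eigensolve (lowest modes only) for large systems; it must cover
    the zero modes plus every mode later analyzed.
    """
    grad = np.asarray(grad, dtype=float)
    if m is None:
        m = choose_replaced_index(grad)
    Hm = mixed_hessian(H, grad, m)
    want = None if n_modes is None else n_modes
    spec = decompose(Hm, zero_tol_rel=zero_tol_rel, n_modes=want, expect_rigid=None)
    return MixedSpace(grad=grad, m=int(m), H_mixed=Hm, spectrum=spec)
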