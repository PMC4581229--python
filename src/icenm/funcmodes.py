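"""Per-mode functional fluctuation and the gate-to-residue correlation field.

Two observables quantify how the elastic network's motions relate to the
internal coordinate Δr (the gate opening):

* MSFIC — the mean-square fluctuation of Δr contributed by each mixed-space
  normal mode k:  ⟨(Δr)²⟩_k = (kBT/γ) λ'_k⁻¹ ([u'_k]_m)².  Modes with
  distinctly large MSFIC are the function-related motion modes.
* The correlation field — the cross-covariance ⟨Δr ΔR_i⟩ between the gate
  coordinate and each residue's displacement, summed over a window of the
  slowest mixed modes.  Function-related modes dominate this sum
  automatically; drawn as per-residue arrows it is the functional motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enm import Spectrum
from .funccoord import MixedSpace


@dataclass
class ModeFunctionProfile:
    """MSFIC of the first ``n_modes`` nonzero mixed modes (1-based indexing)."""

    mode_indices: np.ndarray      # 1..n_modes over nonzero mixed modes
    eigenvalues: np.ndarray
    msfic: np.ndarray
    distinct: np.ndarray          # bool, MSFIC >= threshold × window max
    distinct_threshold: float
    total: float                  # Σ MSFIC over the window

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "mode_index": self.mode_indices,
                "eigenvalue": self.eigenvalues,
                "msfic": self.msfic,
                "distinct": self.distinct.astype(int),
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CorrelationField:
    """⟨Δr ΔR_i⟩ per residue, with a bounded normalized magnitude.

    ``vectors[i]`` is the 3-vector cross-covariance between the gate
    coordinate and residue i over the analyzed mode window; ``normalized[i]``
    is |⟨Δr ΔR_i⟩| / sqrt(⟨Δr²⟩⟨|ΔR_i|²⟩) ∈ [0, 1] with all three factors
    taken over the same mode window (0 where the residue does not move).
    """

    vectors: np.ndarray       # (N, 3)
    normalized: np.ndarray    # (N,)
    ic_variance: float        # ⟨Δr²⟩ over the window
    n_modes: int

    def to_frame(self, chain_ids=None, res_numbers=None):
        import pandas as pd

        n = len(self.vectors)
        return pd.DataFrame(
            {
                "chain_id": chain_ids if chain_ids is not None else ["A"] * n,
                "res_number": res_numbers if res_numbers is not None else np.arange(1, n + 1),
                "corr_x": self.vectors[:, 0],
                "corr_y": self.vectors[:, 1],
                "corr_z": self.vectors[:, 2],
                "normalized": self.normalized,
            }
        )

    def write_csv(self, path, chain_ids=None, res_numbers=None) -> None:
        self.to_frame(chain_ids, res_numbers).to_csv(path, index=False)


def msfic_profile(
    mixed: MixedSpace,
    n_modes: int = 30,
    kBT_over_gamma: float = 1.0,
    distinct_threshold: float = 0.5,
) -> ModeFunctionProfile:
    """MSFIC per mixed mode over the first ``n_modes`` nonzero modes.

    The "distinct" flag marks modes whose MSFIC reaches
    ``distinct_threshold`` × the window maximum — the operational reading of
    "relatively large" contribution to the functional motion.
    """
    w, U = mixed.spectrum.nonzero_modes(n_modes)
    msfic = kBT_over_gamma * (U[mixed.m, :] ** 2) / w
    top = msfic.max() if len(msfic) else 0.0
    distinct = msfic >= distinct_threshold * top if top > 0 else np.zeros(len(msfic), bool)
    return ModeFunctionProfile(
        mode_indices=np.arange(1, len(w) + 1),
        eigenvalues=w.copy(),
        msfic=msfic,
        distinct=distinct,
        distinct_threshold=float(distinct_threshold),
        total=float(msfic.sum()),
    )


def ic_variance_direct(
    spectrum: Spectrum,
    grad: np.ndarray,
    n_modes: int | None = None,
    kBT_over_gamma: float = 1.0,
) -> float:
    """⟨(Δr)²⟩ by direct propagation through the Cartesian modes.

    (kBT/γ)·Σ_k λ_k⁻¹ (aᵀu_k)² over the selected nonzero Cartesian modes —
    the independent route to the mixed-space total (they agree exactly over
    full spectra because a is orthogonal to the rigid-body space).
    """
    grad = np.asarray(grad, dtype=float)
    w, U = spectrum.nonzero_modes(n_modes)
    if U.shape[0] != len(grad):
        raise ValueError("gradient does not match spectrum dimension")
    proj = grad @ U
    return float(kBT_over_gamma * np.sum(proj ** 2 / w))


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of rigid translations/rotations about the centroid.

    Returns (3N, 6) columns — or (3N, 5) for collinear structures, whose
    rotation about the axis is not a displacement; the rank cut uses SVD so a
    degenerate geometry never yields a spurious sixth direction.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    centered = coords - coords.mean(axis=0)
    vecs = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        vecs.append(t.reshape(-1))
    for ax in range(3):
        omega = np.zeros(3)
        omega[ax] = 1.0
        vecs.append(np.cross(omega, centered).reshape(-1))
    M = np.stack(vecs, axis=1)
    Q, s, _ = np.linalg.svd(M, full_matrices=False)
    return Q[:, s > 1e-10 * s[0]]


def correlation_field(
    mixed: MixedSpace,
    coords: np.ndarray,
    n_modes: int = 30,
    kBT_over_gamma: float = 1.0,
) -> CorrelationField:
    """Gate-to-residue cross-covariance over the slowest mixed modes.

    The truncated mixed covariance C' = (kBT/γ) Σ_k λ'_k⁻¹ u'_k u'_kᵀ is
    back-transformed to Cartesian coordinates (C = A⁻¹ C' A⁻ᵀ) and projected
    onto the complement of the rigid-body space (the Eckart frame): removing
    the zero modes in the mixed space leaves a spurious net
    translation/rotation in the back-transformed covariance, which the
    projection eliminates — the field of a symmetric structure is then
    symmetric, and over the full spectrum it equals the direct Cartesian
    route aᵀH⁺ exactly.  The field is the row ⟨Δr ΔR⟩ = aᵀC; normalization
    uses ⟨Δr²⟩ = aᵀC a and residue MSFs from diag(C), all over the same
    window, so the magnitudes respect the Cauchy–Schwarz bound.
    ``coords`` are the (N, 3) reference coordinates defining the rigid basis.
    """
    w, U = mixed.spectrum.nonzero_modes(n_modes)
    a, m = mixed.grad, mixed.m
    # back-transform the mode matrix: B = A⁻¹ U (row m is the only change)
    B = np.array(U, dtype=float)
    B[m, :] = (U[m, :] - a @ U + a[m] * U[m, :]) / a[m]
    Q = rigid_body_basis(coords)
    B -= Q @ (Q.T @ B)                    # project out rigid components
    inv_w = kBT_over_gamma / w
    proj_a = B.T @ a
    row = B @ (inv_w * proj_a)            # (P C P) a
    ic_var = float(row @ a)               # = aᵀ C a  (P a = a)
    diag = ((B ** 2) * inv_w).sum(axis=1)
    msf_res = np.clip(diag, 0.0, None).reshape(-1, 3).sum(axis=1)

    vectors = row.reshape(-1, 3)
    mags = np.linalg.norm(vectors, axis=1)
    denom = np.sqrt(np.clip(ic_var, 0.0, None) * msf_res)
    normalized = np.divide(
        mags, denom, out=np.zeros_like(mags), where=denom > 1e-300
    )
    return CorrelationField(
        vectors=vectors,
        normalized=normalized,
        ic_variance=ic_var,
        n_modes=len(w),
    )


def functional_displacement(field: CorrelationField) -> np.ndarray:
    """Per-residue functional-motion arrows, scaled to unit maximum length.

    The covariance-weighted mode sum IS the cross-covariance row, so the
    field's vectors, rescaled for display, are the functional displacement.
    """
    mags = np.linalg.norm(field.vectors, axis=1)
    top = mags.max()
    if top <= 0:
        raise ValueError("all-zero correlation field")
    return field.vectors / top
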