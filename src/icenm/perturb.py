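"""Spring-perturbation scan for interactions controlling the gate motion.

Stiffening one spring γ_ij → γ_ij + δγ changes the Hessian by the standard
ANM super-element of that pair scaled by δγ.  The first-order change in the
gate coordinate's mean-square fluctuation is

    δ⟨(Δr)²⟩ = −(kBT/γ²) · (G δH' G)_mm

with G the mode-limited inverse of the mixed-space Hessian and δH' the
transformed perturbation.  Springs whose perturbation moves ⟨(Δr)²⟩ the most
(largest |δ|) are ranked as the key residue interactions; by first-order
theory every full-spectrum stiffening response is ≤ 0.

Scores are reported per unit fractional stiffening (δγ/γ = 1): the response
is linear in δγ, so the magnitude convention rescales scores but can never
change the ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .enm import ElasticNetwork, NetworkError
from .funccoord import MixedSpace


@dataclass
class SpringPerturbation:
    """Sparse Hessian perturbation for stiffening one spring by δγ."""

    i: int
    j: int
    d0: float
    unit_vector: np.ndarray   # (r_j − r_i)/d0
    dgamma: float

    def block(self) -> np.ndarray:
        """The 3×3 block δγ·(r̂ r̂ᵀ); appears +2 on diagonals, −2 off."""
        return self.dgamma * np.outer(self.unit_vector, self.unit_vector)

    def dense(self, n_nodes: int) -> np.ndarray:
        dH = np.zeros((3 * n_nodes, 3 * n_nodes))
        blk = self.block()
        si, sj = slice(3 * self.i, 3 * self.i + 3), slice(3 * self.j, 3 * self.j + 3)
        dH[si, sj] -= blk
        dH[sj, si] -= blk
        dH[si, si] += blk
        dH[sj, sj] += blk
        return dH


@dataclass
class PerturbationScan:
    """Scored springs: signed responses, magnitude ranks, selection threshold."""

    springs: np.ndarray        # (S, 2) node indices
    d0: np.ndarray
    delta_msfic: np.ndarray    # signed δ⟨(Δr)²⟩ per unit δγ/γ
    ranks: np.ndarray          # 1 = largest |δ|
    n_modes: int
    dgamma_over_gamma: float
    chain_ids: np.ndarray | None = None
    res_numbers: np.ndarray | None = None

    @property
    def n_springs(self) -> int:
        return len(self.springs)

    def _labels(self, node: int) -> tuple[str, int]:
        if self.chain_ids is None:
            return ("A", int(node) + 1)
        return (str(self.chain_ids[node]), int(self.res_numbers[node]))

    def to_frame(self, selected: np.ndarray | None = None):
        import pandas as pd

        li = [self._labels(i) for i in self.springs[:, 0]]
        lj = [self._labels(j) for j in self.springs[:, 1]]
        df = pd.DataFrame(
            {
                "chain_i": [c for c, _ in li],
                "res_i": [r for _, r in li],
                "chain_j": [c for c, _ in lj],
                "res_j": [r for _, r in lj],
                "d0_A": self.d0,
                "delta_msfic": self.delta_msfic,
                "rank": self.ranks,
            }
        )
        if selected is not None:
            sel = np.zeros(self.n_springs, dtype=int)
            sel[selected] = 1
            df["selected"] = sel
        return df

    def write_csv(self, path, selected: np.ndarray | None = None) -> None:
        self.to_frame(selected).to_csv(path, index=False)


def delta_hessian(
    network: ElasticNetwork, spring: int | tuple[int, int], dgamma: float
) -> SpringPerturbation:
    """Perturbation object for stiffening one existing spring by ``dgamma``."""
    if isinstance(spring, tuple):
        s = network.spring_index(*spring)
    else:
        s = int(spring)
        if not 0 <= s < network.n_springs:
            raise NetworkError(f"spring index {s} out of range")
    i, j = (int(v) for v in network.springs[s])
    d0 = float(network.d0[s])
    unit = (network.coords[j] - network.coords[i]) / d0
    return SpringPerturbation(i=i, j=j, d0=d0, unit_vector=unit, dgamma=float(dgamma))


def _gate_response_vector(mixed: MixedSpace, n_modes: int | None) -> np.ndarray:
    """y = A⁻¹ G e_m with G the mode-limited inverse of the unit-γ H'.

    For any perturbation, (G δH' G)_mm = yᵀ δH y, which reduces each spring's
    response to a dot product with the spring direction.
    """
    w, U = mixed.spectrum.nonzero_modes(n_modes)
    g_m = (U / w) @ U[mixed.m, :]
    return mixed.apply_A_inv(g_m)


def perturbation_response(
    mixed: MixedSpace,
    delta: SpringPerturbation,
    n_modes: int | None = 30,
    kBT_over_gamma: float = 1.0,
) -> float:
    """First-order δ⟨(Δr)²⟩ for one spring perturbation.

    With δγ expressed in units of the network spring constant γ (so
    ``delta.dgamma`` is the fractional stiffening δγ/γ), the response is
    −(kBT/γ)·(δγ/γ)·(G δH' G)_mm over unit-γ matrices — identically
    −(kBT/γ²)·δγ·(H'⁻¹δH'H'⁻¹)_mm, so the two-node closed form
    δ⟨Δd²⟩ = −(kBT/γ²)δγ holds exactly.  The prefactor never affects ranking.
    """
    y = _gate_response_vector(mixed, n_modes)
    yi = y[3 * delta.i : 3 * delta.i + 3]
    yj = y[3 * delta.j : 3 * delta.j + 3]
    proj = float(delta.unit_vector @ (yj - yi))
    # yᵀ δH y per unit δγ is (r̂·(y_j − y_i))²
    return -kBT_over_gamma * delta.dgamma * proj ** 2


def scan(
    network: ElasticNetwork,
    mixed: MixedSpace,
    n_modes: int | None = 30,
    dgamma_over_gamma: float = 1.0,
    kBT_over_gamma: float = 1.0,
) -> PerturbationScan:
    """Score every spring by its first-order effect on the gate fluctuation.

    One response per spring, ranked by descending magnitude (stable: ties
    keep spring order, which is sorted by node indices).
    """
    if network.n_springs == 0:
        raise NetworkError("network has no springs to perturb")
    y = _gate_response_vector(mixed, n_modes)
    yi = y.reshape(-1, 3)[network.springs[:, 0]]
    yj = y.reshape(-1, 3)[network.springs[:, 1]]
    units = (network.coords[network.springs[:, 1]] - network.coords[network.springs[:, 0]])
    units /= network.d0[:, None]
    proj = np.einsum("ij,ij->i", units, yj - yi)
    values = -kBT_over_gamma * dgamma_over_gamma * proj ** 2
    order = np.argsort(-np.abs(values), kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return PerturbationScan(
        springs=network.springs.copy(),
        d0=network.d0.copy(),
        delta_msfic=values,
        ranks=ranks,
        n_modes=-1 if n_modes is None else int(n_modes),
        dgamma_over_gamma=float(dgamma_over_gamma),
        chain_ids=None if network.chain_ids is None else network.chain_ids.copy(),
        res_numbers=None if network.res_numbers is None else network.res_numbers.copy(),
    )


def top_fraction(scan_result: PerturbationScan, fraction: float = 0.05) -> np.ndarray:
    """Indices of the springs with the largest |δ⟨(Δr)²⟩|.

    Selects ceil(fraction × S) springs; |score| ties straddling the boundary
    are all included, so the realized count can exceed the nominal one.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    S = scan_result.n_springs
    k = math.ceil(fraction * S)
    mags = np.abs(scan_result.delta_msfic)
    order = np.argsort(-mags, kind="stable")
    threshold = mags[order[k - 1]]
    # tie rule: every spring matching the boundary score is included
    selected = np.nonzero(mags >= threshold)[0]
    return selected[np.argsort(-mags[selected], kind="stable")]
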