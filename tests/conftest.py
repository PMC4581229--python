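"""Shared fixtures: small synthetic networks and their decompositions."""

import numpy as np
import pytest

import icenm


def gate_pairs_mouth(n: int):
    """Gate pairs across the mouth of a clamshell with n beads per lobe."""
    return [(("A", n), ("B", n)), (("A", n - 1), ("B", n - 1))]


def gate_pairs_dimer(n: int):
    """Symmetric cross-chain pairs on a c2_dimer (arbitrary but fixed)."""
    return [(("A", 3), ("B", 3)), (("A", n // 2), ("B", n // 2))]


class Bundle:
    """A model with its network, Hessian, gate coordinate and spectra."""

    def __init__(self, model, pairs):
        self.model = model
        self.pairs = pairs
        self.network = icenm.build_network(model)
        self.H = icenm.hessian(self.network)
        self.gate = icenm.gate_coordinate(model, pairs)
        self.spectrum = icenm.decompose(self.H)
        self.mixed = icenm.mixed_space(self.H, self.gate.grad)


def make_bundle(kind: str, n: int = 14, seed: int = 0) -> Bundle:
    model = icenm.make_synthetic(kind, n=n, seed=seed)
    pairs = gate_pairs_mouth(n) if kind == "clamshell" else gate_pairs_dimer(n)
    return Bundle(model, pairs)


@pytest.fixture(scope="session")
def clamshell():
    return make_bundle("clamshell", n=14, seed=1)


@pytest.fixture(scope="session")
def dimer():
    return make_bundle("c2_dimer", n=14, seed=1)


@pytest.fixture(scope="session")
def two_node():
    model = icenm.make_synthetic("two_node", d=5.0)
    network = icenm.build_network(model)
    H = icenm.hessian(network)
    gate = icenm.gate_coordinate(model, [(("A", 1), ("B", 1))])
    spectrum = icenm.decompose(H, expect_rigid=5)
    mixed = icenm.mixed_space(H, gate.grad)
    b = Bundle.__new__(Bundle)
    b.model, b.network, b.H = model, network, H
    b.gate, b.spectrum, b.mixed = gate, spectrum, mixed
    b.pairs = [(("A", 1), ("B", 1))]
    return b


def rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the six rigid-body displacement vectors."""
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


def rigid_projector(coords: np.ndarray) -> np.ndarray:
    """Projector onto the orthogonal complement of the rigid-body space."""
    Q = rigid_body_basis(coords)
    return np.eye(3 * len(coords)) - Q @ Q.T
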