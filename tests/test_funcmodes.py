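"""Per-mode gate fluctuation (MSFIC) and the gate-residue correlation field."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import icenm
from tests.conftest import make_bundle, rigid_projector


class TestMsficProfile:
    def test_two_node_single_mode_carries_all(self, two_node):
        prof = icenm.msfic_profile(two_node.mixed, n_modes=1)
        assert prof.msfic == pytest.approx([1.0])
        assert prof.distinct.tolist() == [True]

    def test_cartesian_gate_reduces_to_untransformed_modes(self, dimer):
        e = np.zeros(3 * len(dimer.model))
        e[4] = 1.0
        mx = icenm.mixed_space(dimer.H, e)
        prof = icenm.msfic_profile(mx, n_modes=10)
        w, U = dimer.spectrum.nonzero_modes(10)
        assert prof.msfic == pytest.approx(U[4, :] ** 2 / w, abs=1e-10)

    def test_conservation_against_direct_variance(self, dimer, clamshell):
        for b in (dimer, clamshell):
            total = icenm.msfic_profile(b.mixed, n_modes=b.mixed.spectrum.n_nonzero).total
            direct = icenm.ic_variance_direct(b.spectrum, b.gate.grad)
            assert total == pytest.approx(direct, rel=1e-8)

    def test_conservation_against_monte_carlo(self, clamshell):
        """Sample ΔR from the ENM Gaussian and compare var(aᵀΔR) directly."""
        rng = np.random.default_rng(2024)
        w, U = clamshell.spectrum.nonzero_modes()
        n_samp = 100_000
        z = rng.standard_normal((len(w), n_samp))
        samples = U @ (z / np.sqrt(w)[:, None])
        var = np.var(clamshell.gate.grad @ samples, ddof=1)
        expected = icenm.msfic_profile(
            clamshell.mixed, n_modes=clamshell.mixed.spectrum.n_nonzero
        ).total
        se = expected * np.sqrt(2.0 / (n_samp - 1))
        assert abs(var - expected) < 3 * se

    def test_partial_totals_monotone_in_window(self, dimer):
        totals = [
            icenm.msfic_profile(dimer.mixed, n_modes=k).total
            for k in range(1, dimer.mixed.spectrum.n_nonzero + 1)
        ]
        assert np.all(np.diff(totals) >= -1e-15)

    def test_all_values_nonnegative_and_scale_with_temperature(self, dimer):
        p1 = icenm.msfic_profile(dimer.mixed, n_modes=12)
        p10 = icenm.msfic_profile(dimer.mixed, n_modes=12, kBT_over_gamma=10.0)
        assert np.all(p1.msfic >= 0)
        assert p10.msfic == pytest.approx(10 * p1.msfic)
        assert np.array_equal(p10.distinct, p1.distinct)

    def test_window_out_of_range_errors(self, two_node):
        with pytest.raises(icenm.SpectrumError):
            icenm.msfic_profile(two_node.mixed, n_modes=2)

    def test_csv_columns(self, tmp_path, dimer):
        prof = icenm.msfic_profile(dimer.mixed, n_modes=5)
        out = tmp_path / "msfic.csv"
        prof.write_csv(out)
        assert out.read_text().splitlines()[0] == "mode_index,eigenvalue,msfic,distinct"


class TestIcVarianceDirect:
    def test_two_node_unit_variance(self, two_node):
        assert icenm.ic_variance_direct(two_node.spectrum, two_node.gate.grad) == pytest.approx(1.0)

    def test_gradient_orthogonal_to_modes_gives_zero(self, dimer):
        w, U = dimer.spectrum.nonzero_modes(5)
        # build a vector orthogonal to the first 5 nonzero modes
        g = dimer.gate.grad - U @ (U.T @ dimer.gate.grad)
        assert icenm.ic_variance_direct(dimer.spectrum, g, n_modes=5) == pytest.approx(0.0, abs=1e-16)

    @pytest.mark.parametrize("seed", range(6))
    def test_cross_route_equality_random_networks(self, seed):
        b = make_bundle("c2_dimer", n=9, seed=seed)
        direct = icenm.ic_variance_direct(b.spectrum, b.gate.grad)
        total = icenm.msfic_profile(b.mixed, n_modes=b.mixed.spectrum.n_nonzero).total
        assert total == pytest.approx(direct, rel=1e-8)

    def test_dimension_mismatch_errors(self, dimer):
        with pytest.raises(ValueError):
            icenm.ic_variance_direct(dimer.spectrum, np.ones(5))


class TestCorrelationField:
    def test_two_node_antiparallel_unit_correlation(self, two_node):
        fld = icenm.correlation_field(two_node.mixed, two_node.model.coords, n_modes=1)
        v = fld.vectors
        assert v[0] == pytest.approx(-v[1], abs=1e-10)
        assert np.linalg.norm(v[0]) == pytest.approx(np.linalg.norm(v[1]), rel=1e-10)
        assert fld.normalized == pytest.approx([1.0, 1.0], abs=1e-8)

    def test_symmetric_dimer_field_maps_onto_itself(self, dimer):
        """Full-spectrum field of a C2 dimer is exactly chain-swap symmetric.

        Truncated mixed-mode windows are only approximately symmetric: the
        transform privileges one Cartesian coordinate, so the truncated mixed
        eigenbasis is not symmetry-adapted.  Over all nonzero modes the
        asymmetry vanishes.
        """
        fld = icenm.correlation_field(
            dimer.mixed, dimer.model.coords, n_modes=dimer.mixed.spectrum.n_nonzero
        )
        R, perm = icenm.c2_symmetry_map(dimer.model)
        mapped = (fld.vectors @ R.T)[np.argsort(perm)]
        assert np.abs(mapped - fld.vectors).max() < 1e-8
        assert fld.normalized == pytest.approx(fld.normalized[perm], abs=1e-8)

    def test_truncation_asymmetry_vanishes_at_full_window(self, dimer):
        """Mixed-mode truncation may break chain-swap symmetry; the asymmetry
        is a truncation artifact that disappears over the full window."""
        R, perm = icenm.c2_symmetry_map(dimer.model)

        def asym(n_modes):
            fld = icenm.correlation_field(
                dimer.mixed, dimer.model.coords, n_modes=n_modes
            )
            mapped = (fld.vectors @ R.T)[np.argsort(perm)]
            return np.abs(mapped - fld.vectors).max(), np.abs(fld.vectors).max()

        a_trunc, scale = asym(12)
        a_full, _ = asym(dimer.mixed.spectrum.n_nonzero)
        assert a_full < 1e-10
        assert a_trunc < scale  # bounded by the field itself, not symmetric

    @settings(deadline=None, max_examples=8, derandomize=True)
    @given(seed=st.integers(0, 30), n_modes=st.integers(1, 12))
    def test_cauchy_schwarz_bound(self, seed, n_modes):
        b = make_bundle("c2_dimer", n=8, seed=seed)
        fld = icenm.correlation_field(b.mixed, b.model.coords, n_modes=n_modes)
        assert np.all(fld.normalized >= 0.0)
        assert np.all(fld.normalized <= 1.0 + 1e-10)

    def test_full_spectrum_field_matches_cartesian_route_modulo_rigid(self, dimer):
        """Dropping zero modes in mixed vs Cartesian space differs only by a
        rigid-body component of the field."""
        fld = icenm.correlation_field(dimer.mixed, dimer.model.coords, n_modes=dimer.mixed.spectrum.n_nonzero)
        P = rigid_projector(dimer.model.coords)
        direct = dimer.gate.grad @ icenm.covariance(dimer.spectrum)
        assert np.abs(P @ fld.vectors.reshape(-1) - direct).max() < 1e-8

    def test_ic_variance_consistent_with_msfic_total(self, dimer):
        n_all = dimer.mixed.spectrum.n_nonzero
        fld = icenm.correlation_field(dimer.mixed, dimer.model.coords, n_modes=n_all)
        total = icenm.msfic_profile(dimer.mixed, n_modes=n_all).total
        assert fld.ic_variance == pytest.approx(total, rel=1e-8)


class TestFunctionalDisplacement:
    def test_two_node_arrows_open_the_gate(self, two_node):
        fld = icenm.correlation_field(two_node.mixed, two_node.model.coords, n_modes=1)
        arrows = icenm.functional_displacement(fld)
        # positive Δr means the two beads separating: arrows point outward
        bond = np.array([1.0, 0.0, 0.0])
        assert arrows[1] @ bond > 0
        assert arrows[0] @ bond < 0
        assert np.linalg.norm(arrows, axis=1).max() == pytest.approx(1.0)

    def test_scale_invariance_of_unit_arrows(self, dimer):
        f1 = icenm.correlation_field(dimer.mixed, dimer.model.coords, n_modes=10)
        f10 = icenm.correlation_field(dimer.mixed, dimer.model.coords, n_modes=10, kBT_over_gamma=10.0)
        assert icenm.functional_displacement(f10) == pytest.approx(
            icenm.functional_displacement(f1), abs=1e-10
        )

    def test_clamshell_lobes_move_oppositely(self, clamshell):
        fld = icenm.correlation_field(clamshell.mixed, clamshell.model.coords, n_modes=10)
        arrows = icenm.functional_displacement(fld)
        a_mask = clamshell.model.chain_ids == "A"
        mean_a = arrows[a_mask].mean(axis=0)
        mean_b = arrows[~a_mask].mean(axis=0)
        # opening the mouth drives the lobes apart: opposing mean directions
        assert mean_a @ mean_b < 0

    def test_all_zero_field_rejected(self):
        fld = icenm.CorrelationField(
            vectors=np.zeros((3, 3)), normalized=np.zeros(3),
            ic_variance=0.0, n_modes=1,
        )
        with pytest.raises(ValueError):
            icenm.functional_displacement(fld)
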