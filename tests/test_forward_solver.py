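"""Finite-volume conduction solve, tetrapolar impedance, analytic oracle."""

import numpy as np
import pytest

from renoimp import (
    ElectrodeArraySpec,
    LabelGrid,
    StimulationPattern,
    Tissue,
    TissueTable,
    analytic_tetrapolar,
    assemble_conduction_system,
    homogeneous_block_field,
    reciprocity_error,
    solve_potential,
    solve_tetrapolar,
    to_conductivity_field,
    transfer_impedance,
)
from renoimp.forward_solver import AssemblyError
from renoimp.tissue_models import ConductivityField


def _box_field(sigma: np.ndarray, h: float = 1.0) -> ConductivityField:
    dims = sigma.shape
    return ConductivityField(
        voxel_size_h=h,
        dims=dims,
        origin=(h / 2, h / 2, h / 2),
        sigma=sigma,
        electrodes={},
    )


def _bar_pattern(nz: int, current_ma: float = 1.0) -> StimulationPattern:
    """End-to-end drive along z of a 1 x 1 x nz bar, pickup at interior cells."""
    return StimulationPattern(
        current_pair=(np.array([[0, 0]]), np.array([[0, nz - 1]])),
        measurement_pair=(np.array([[0, 2]]), np.array([[0, nz - 3]])),
        current_ma=current_ma,
    )


class TestAnalyticTetrapolar:
    def test_coincident_measuring_electrodes(self):
        assert analytic_tetrapolar(5.0, 0.03, 0.0) == 0.0

    def test_wenner_reduction(self):
        """Equidistant array: Z = rho/(2 pi d); rho = 2 pi, d = 1 gives 1 Ohm."""
        assert analytic_tetrapolar(2 * np.pi, 1.5, 0.5) == pytest.approx(1.0, rel=1e-12)

    def test_kidney_scale_spacing(self):
        assert analytic_tetrapolar(5.84, 0.03, 0.01) == pytest.approx(46.48, abs=0.01)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            analytic_tetrapolar(5.0, 0.01, 0.03)


class TestAssembly:
    def test_interior_row_sums_vanish(self):
        """Conservation: stencil rows sum to zero away from the drive."""
        fld = _box_field(np.ones((3, 3, 3)))
        pat = StimulationPattern(
            current_pair=(np.array([[0, 0]]), np.array([[2, 2]])),
            measurement_pair=(np.array([[0, 2]]), np.array([[2, 0]])),
        )
        system = assemble_conduction_system(fld, pat)
        sums = np.asarray(system.A.sum(axis=1)).ravel()
        assert np.allclose(sums, 0.0, atol=1e-15)

    def test_harmonic_mean_on_offdiagonal(self):
        sigma = np.ones((2, 1, 2))
        sigma[1] = 3.0
        fld = _box_field(sigma, h=1.0)
        pat = StimulationPattern(
            current_pair=(np.array([[0, 0]]), np.array([[1, 0]])),
            measurement_pair=(np.array([[0, 1]]), np.array([[1, 1]])),
        )
        system = assemble_conduction_system(fld, pat)
        A = system.A.toarray()
        i, j = system.index[0, 0, 0], system.index[1, 0, 0]
        assert A[i, j] == pytest.approx(-1e-3 * 2 * 1 * 3 / (1 + 3))  # h * harm(1,3)

    def test_rhs_sums_to_zero(self):
        fld = _box_field(np.ones((4, 4, 4)))
        pat = StimulationPattern(
            current_pair=(np.array([[0, 0], [0, 1]]), np.array([[3, 3]])),
            measurement_pair=(np.array([[1, 2]]), np.array([[2, 1]])),
        )
        system = assemble_conduction_system(fld, pat)
        assert abs(system.b.sum()) < 1e-18

    def test_disconnected_domain_rejected(self):
        sigma = np.ones((5, 1, 1))
        sigma[2] = 0.0
        fld = _box_field(sigma)
        pat = StimulationPattern(
            current_pair=(np.array([[0, 0]]), np.array([[1, 0]])),
            measurement_pair=(np.array([[3, 0]]), np.array([[4, 0]])),
        )
        with pytest.raises(AssemblyError, match="connected"):
            assemble_conduction_system(fld, pat)

    def test_shared_footprints_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            StimulationPattern(
                current_pair=(np.array([[0, 0]]), np.array([[0, 5]])),
                measurement_pair=(np.array([[0, 0]]), np.array([[0, 3]])),
            )


class TestSolvePotential:
    def test_two_segment_bar_has_exact_piecewise_linear_profile(self):
        """Potential drops I/g per face; harmonic-mean faces make this exact."""
        nz = 12
        sigma = np.ones((1, 1, nz))
        sigma[..., nz // 2 :] = 2.0
        fld = _box_field(sigma, h=1.0)
        pat = _bar_pattern(nz)
        system = assemble_conduction_system(fld, pat)
        phi = solve_potential(system)
        prof = phi.phi[0, 0, :]
        current = pat.current_amps
        h_m = 1e-3
        g = h_m * 2 * sigma[0, 0, :-1] * sigma[0, 0, 1:] / (sigma[0, 0, :-1] + sigma[0, 0, 1:])
        expected_drops = current / g
        assert np.allclose(-np.diff(prof), expected_drops, rtol=1e-6)

    def test_conductivity_scaling_inverts_potential(self):
        rng = np.random.default_rng(3)
        sigma = rng.uniform(0.5, 2.0, (6, 5, 7))
        fld1 = _box_field(sigma)
        fld2 = _box_field(4.0 * sigma)
        pat = StimulationPattern(
            current_pair=(np.array([[0, 0]]), np.array([[5, 6]])),
            measurement_pair=(np.array([[0, 6]]), np.array([[5, 0]])),
        )
        p1 = solve_potential(assemble_conduction_system(fld1, pat))
        p2 = solve_potential(assemble_conduction_system(fld2, pat))
        mask = ~np.isnan(p1.phi)
        assert np.allclose(p1.phi[mask], 4.0 * p2.phi[mask], atol=1e-8 * np.abs(p1.phi[mask]).max())

    def test_mirror_symmetric_model_gives_antisymmetric_potential(self):
        # d = 18 at h = 2 puts every electrode on a cell center with no grid
        # phase shift, so the discrete model is exactly mirror-symmetric
        fld = homogeneous_block_field((40, 20, 80), 2.0, 5.0, ElectrodeArraySpec(spacing_d=18.0))
        pat = StimulationPattern.from_field(fld)
        z, phi = solve_tetrapolar(fld, pat)
        m1, m2 = pat.measurement_pair
        v1 = phi.footprint_mean(m1)
        v2 = phi.footprint_mean(m2)
        assert v1 + v2 == pytest.approx(0.0, abs=1e-9 * max(abs(v1), 1e-30) + 1e-12)

    def test_spectral_direct_solve_matches_dense_solution(self):
        fld = homogeneous_block_field((20, 12, 32), 4.0, 5.0, ElectrodeArraySpec(spacing_d=8.0))
        pat = StimulationPattern.from_field(fld)
        system = assemble_conduction_system(fld, pat)
        assert system.uniform_sigma is not None
        phi = solve_potential(system)
        dense = np.linalg.lstsq(system.A.toarray(), system.b, rcond=None)[0]
        dense -= dense.mean()
        mask = ~np.isnan(phi.phi)
        assert np.allclose(phi.phi[mask], dense[system.index[mask]], atol=1e-12)


class TestTransferImpedance:
    def test_coincident_pickup_reads_zero(self):
        fld = homogeneous_block_field((40, 20, 80), 2.0, 5.0, ElectrodeArraySpec(spacing_d=16.0))
        pat = StimulationPattern.from_field(fld)
        _, phi = solve_tetrapolar(fld, pat)
        m1 = pat.measurement_pair[0]
        assert (phi.footprint_mean(m1) - phi.footprint_mean(m1)) == 0.0

    def test_impedance_independent_of_drive_current(self):
        fld = homogeneous_block_field((40, 20, 80), 2.0, 5.0, ElectrodeArraySpec(spacing_d=16.0))
        z1, _ = solve_tetrapolar(fld, StimulationPattern.from_field(fld, current_ma=3.0))
        z2, _ = solve_tetrapolar(fld, StimulationPattern.from_field(fld, current_ma=6.0))
        assert z1 == pytest.approx(z2, rel=1e-12)

    def test_half_space_oracle_within_five_percent(self):
        """Homogeneous block vs the point-electrode half-space formula at h=2."""
        d = 20.0
        fld = homogeneous_block_field(
            (360, 180, 360), 2.0, 5.0, ElectrodeArraySpec(spacing_d=d, disk_diameter=0.9)
        )
        z, _ = solve_tetrapolar(fld)
        z_ref = analytic_tetrapolar(5.0, 1.5 * d * 1e-3, 0.5 * d * 1e-3)
        assert z == pytest.approx(z_ref, rel=0.05)

    def test_monotone_shielding_by_resistive_slab(self):
        """A resistive slab between the electrodes and a conductive interior
        raises the measured impedance."""
        array = ElectrodeArraySpec(spacing_d=16.0)
        base = homogeneous_block_field((80, 40, 120), 2.0, 5.0, array)
        z0, _ = solve_tetrapolar(base)
        shielded = ConductivityField(
            voxel_size_h=base.voxel_size_h,
            dims=base.dims,
            origin=base.origin,
            sigma=base.sigma.copy(),
            electrodes=base.electrodes,
        )
        shielded.sigma[:, 2:5, :] = 1.0 / 40.0  # fat-like slab below the surface
        z1, _ = solve_tetrapolar(shielded)
        assert z1 > z0

    def test_determinism(self):
        fld = homogeneous_block_field((40, 20, 80), 2.0, 5.0, ElectrodeArraySpec(spacing_d=16.0))
        za, _ = solve_tetrapolar(fld)
        zb, _ = solve_tetrapolar(fld)
        assert za == zb


class TestReciprocity:
    def test_homogeneous_model(self):
        fld = homogeneous_block_field((60, 30, 100), 2.0, 5.0, ElectrodeArraySpec(spacing_d=16.0))
        pat = StimulationPattern.from_field(fld)
        assert reciprocity_error(fld, pat) < 1e-6

    def test_heterogeneous_model(self):
        array = ElectrodeArraySpec(spacing_d=16.0)
        fld = homogeneous_block_field((60, 30, 100), 2.0, 5.0, array)
        het = ConductivityField(
            voxel_size_h=fld.voxel_size_h,
            dims=fld.dims,
            origin=fld.origin,
            sigma=fld.sigma.copy(),
            electrodes=fld.electrodes,
        )
        het.sigma[:, :3, :] = 1 / 40.0
        het.sigma[:, 8:, :] = 1 / 2.8
        pat = StimulationPattern.from_field(het)
        assert reciprocity_error(het, pat) < 1e-3
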