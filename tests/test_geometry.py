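"""Voxelization of the layered torso + kidney model and electrode placement."""

import numpy as np
import pytest

from renoimp import (
    ElectrodeArraySpec,
    GeometryError,
    PlacementError,
    ResolutionError,
    Tissue,
    TorsoSpec,
    KidneySpec,
    build_patient_model,
    set_kidney_depth,
)
from renoimp.geometry import ellipsoid_shell_volume

ARRAY = ElectrodeArraySpec(spacing_d=20.0)


def small_torso(**kw):
    """Default trunk cross-section but a shorter axial segment (fits tests)."""
    return TorsoSpec(axial_length=kw.pop("axial_length", 160.0), **kw)


class TestBuildPatientModel:
    def test_fat_slab_thickness_under_electrodes(self, default_fixture):
        """At h=2 mm the 5.54 mm subcutaneous layer spans 2-4 voxels on the
        electrode normal at the posterior mid-line."""
        torso, kidney, _, _ = default_fixture
        grid = build_patient_model(small_torso(), kidney, ARRAY, 2.0)
        i_mid = grid.dims[0] // 2
        column = grid.labels[i_mid, :, grid.dims[2] // 2]
        n_fat = int(np.argmax(column != Tissue.SUBCUTANEOUS_FAT))  # posterior run
        assert 2 <= n_fat <= 4

    def test_layer_order_inward_from_skin(self):
        grid = build_patient_model(small_torso(), KidneySpec(), ARRAY, 2.0)
        # a column clear of the kidney (near the caudal end of the segment)
        column = grid.labels[grid.dims[0] // 2, :, 1]
        first_bg = np.argmax(column == Tissue.BACKGROUND)
        seen = list(dict.fromkeys(column[:first_bg]))
        assert seen == [Tissue.SUBCUTANEOUS_FAT, Tissue.MUSCLE]

    def test_cortex_shell_volume_matches_closed_form(self):
        kidney = KidneySpec()
        grid = build_patient_model(small_torso(), kidney, ARRAY, 1.0)
        vol = grid.tissue_volumes()["cortex"]
        expected = ellipsoid_shell_volume(kidney.semi_axes, kidney.h_c)
        assert vol == pytest.approx(expected, rel=0.10)

    def test_cortex_voxels_lie_between_the_two_ellipsoids(self):
        kidney = KidneySpec()
        grid = build_patient_model(small_torso(), kidney, ARRAY, 2.0)
        idx = np.argwhere(grid.labels == Tissue.CORTEX)
        centers = np.asarray(grid.origin) + grid.voxel_size_h * idx
        rel = centers - np.array([kidney.lateral_offset, kidney.center_y, 0.0])
        outer = np.sum((rel / np.array(kidney.semi_axes)) ** 2, axis=1)
        inner_ax = np.array(kidney.semi_axes) - kidney.h_c
        inner = np.sum((rel / inner_ax) ** 2, axis=1)
        assert np.all(outer <= 1 + 1e-9)
        assert np.all(inner > 1 - 1e-9)

    def test_kidney_deeper_than_torso_is_rejected(self):
        torso = small_torso()
        with pytest.raises(GeometryError):
            build_patient_model(
                torso, KidneySpec(depth=torso.minor_axis_2b1 / 2 + 20), ARRAY, 2.0
            )

    def test_unresolvable_cortex_shell_rejected(self):
        with pytest.raises(ResolutionError):
            build_patient_model(small_torso(), KidneySpec(h_c=5.0), ARRAY, 6.0)

    def test_label_partition_matches_segment_volume(self):
        """Total labelled volume ~ pi*a1*b1*L, off by at most one surface layer."""
        torso = small_torso()
        h = 2.0
        grid = build_patient_model(torso, KidneySpec(), ARRAY, h)
        total = sum(grid.tissue_volumes().values())
        analytic = np.pi * torso.a1 * torso.b1 * grid.dims[2] * h
        surface_area = 2 * np.pi * np.sqrt((torso.a1**2 + torso.b1**2) / 2) * grid.dims[2] * h
        assert abs(total - analytic) <= surface_area * h

    def test_refinement_halving_voxels_preserves_volumes(self):
        torso = small_torso(axial_length=120.0)
        vols = {}
        for h in (2.0, 1.0):
            grid = build_patient_model(torso, KidneySpec(), ARRAY, h)
            vols[h] = grid.tissue_volumes()
        for tissue, v2 in vols[2.0].items():
            assert vols[1.0][tissue] == pytest.approx(v2, rel=0.12)

    def test_mirror_symmetry_about_the_electrode_plane(self):
        grid = build_patient_model(small_torso(), KidneySpec(lateral_offset=0.0), ARRAY, 2.0)
        assert np.array_equal(grid.labels, grid.labels[::-1, :, :])


class TestElectrodePlacement:
    def test_centers_equidistant_and_current_pair_at_3d(self):
        grid = build_patient_model(small_torso(), KidneySpec(), ARRAY, 2.0)
        xc, zc = grid.axis_centers(0), grid.axis_centers(2)
        pos = {
            k: np.array([xc[fp[:, 0]].mean(), zc[fp[:, 1]].mean()])
            for k, fp in grid.electrodes.items()
        }
        h = grid.voxel_size_h
        z_order = [pos[k][1] for k in ("C1", "M1", "M2", "C2")]
        gaps = np.diff(z_order)
        assert np.allclose(gaps, 20.0, atol=h)
        assert pos["C2"][1] - pos["C1"][1] == pytest.approx(60.0, abs=h)
        assert pos["M2"][1] - pos["M1"][1] == pytest.approx(20.0, abs=h)

    def test_overlapping_disks_rejected(self):
        with pytest.raises(PlacementError):
            ElectrodeArraySpec(spacing_d=2.0, disk_diameter=3.0)

    def test_footprint_face_count_at_fine_pitch(self):
        """A 3 mm disk rasterized at h=1 covers ~pi*1.5^2 = 7 +/- 2 faces."""
        from renoimp.forward_solver import homogeneous_block_field

        fld = homogeneous_block_field((80, 20, 120), 1.0, 5.0, ElectrodeArraySpec(spacing_d=20.0))
        for fp in fld.electrodes.values():
            assert 5 <= fp.shape[0] <= 9

    def test_off_grid_array_rejected(self):
        torso = small_torso(axial_length=100.0)
        with pytest.raises(PlacementError):
            build_patient_model(torso, KidneySpec(), ElectrodeArraySpec(spacing_d=40.0), 2.0)


class TestSetKidneyDepth:
    def test_identity_depth_gives_identical_model(self, default_fixture):
        torso, kidney, _, _ = default_fixture
        moved = set_kidney_depth(torso, kidney, kidney.depth)
        assert moved == kidney

    def test_depth_increase_shifts_kidney_labels_inward(self):
        torso = small_torso()
        kidney = KidneySpec()
        h = 2.0
        g0 = build_patient_model(torso, kidney, ARRAY, h)
        g1 = build_patient_model(torso, set_kidney_depth(torso, kidney, kidney.depth + 10), ARRAY, h)
        renal0 = np.isin(g0.labels, (Tissue.CORTEX, Tissue.MEDULLA))
        renal1 = np.isin(g1.labels, (Tissue.CORTEX, Tissue.MEDULLA))
        assert np.array_equal(np.roll(renal0, 5, axis=1), renal1)

    def test_depth_inside_muscle_wall_rejected(self):
        torso = small_torso()
        with pytest.raises(GeometryError):
            set_kidney_depth(torso, KidneySpec(), torso.h_subc + torso.h_m - 1.0)


class TestSpecInvariants:
    def test_torso_layers_must_fit(self):
        with pytest.raises(GeometryError):
            TorsoSpec(h_subc=50.0, h_m=40.0)

    def test_cortex_thickness_bounded_by_semi_axes(self):
        with pytest.raises(GeometryError):
            KidneySpec(h_c=25.0)
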