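"""Phantom generation, ground truth, and sectioning."""

import dataclasses
import math

import numpy as np
import pytest

import lungstereo as ls
from lungstereo.phantom import (
    AIRSPACE_LABELS,
    Label,
    interface_area_um2,
    min_packable_septal_thickness_um,
)


class TestGroundTruth:
    def test_volumes_sum_to_block_volume(self, normoxia_parenchyma):
        gt = normoxia_parenchyma.ground_truth
        assert sum(gt.volumes_um3.values()) == pytest.approx(gt.block_volume_um3)

    def test_alveolus_count_matches_identity_labels(self, normoxia_parenchyma):
        ids = np.unique(normoxia_parenchyma.alveolus_id)
        assert normoxia_parenchyma.ground_truth.alveolus_count == np.count_nonzero(ids)

    def test_empty_block_is_all_background(self):
        ph = ls.Phantom3D(
            labels=np.zeros((64, 64, 64), np.uint8),
            alveolus_id=np.zeros((64, 64, 64), np.int32),
            voxel_um=1.0,
        )
        gt = ls.compute_ground_truth(ph)
        assert gt.alveolus_count == 0
        assert gt.volume([Label.SEPTUM]) == 0.0
        assert gt.septal_surface_um2 == 0.0

    def test_unknown_label_is_rejected_by_name(self):
        labels = np.zeros((64, 64, 64), np.uint8)
        labels[0, 0, 0] = 77
        ph = ls.Phantom3D(labels=labels, alveolus_id=np.zeros_like(labels, np.int32),
                          voxel_um=1.0)
        with pytest.raises(ls.phantom.UnknownLabelError, match="77"):
            ls.compute_ground_truth(ph)

    def test_sphere_volume_and_surface_within_2pct_of_closed_form(self, sphere_phantom):
        gt = sphere_phantom.ground_truth
        ana = sphere_phantom.meta["analytic"]
        v = gt.volume([Label.ALVEOLAR_AIR])
        assert v == pytest.approx(ana["volume_um3"], rel=0.02)
        assert gt.septal_surface_um2 == pytest.approx(ana["surface_um2"], rel=0.02)

    def test_sphere_discretization_error_shrinks_with_voxel_size(self):
        errs = []
        for voxel in (2.0, 1.0):
            ph = ls.build_sphere_phantom(radius_um=20.0, voxel_um=voxel)
            v = ph.ground_truth.volume([Label.ALVEOLAR_AIR])
            errs.append(abs(v - ph.meta["analytic"]["volume_um3"]))
        assert errs[1] < errs[0]

    def test_plate_identity_2v_over_s_is_exact(self):
        ph = ls.build_plate_phantom(thickness_um=5.0, extent_vox=48)
        gt = ph.ground_truth
        assert gt.mean_septal_thickness_um == pytest.approx(5.0)
        # analytic record agrees with the face-count surface
        assert gt.septal_surface_um2 == pytest.approx(
            ph.meta["analytic"]["septal_surface_um2"]
        )

    def test_crofton_vs_faces_on_plate(self):
        # face counting is exact for the axis-aligned plate; the Crofton
        # measure is the isotropic one and differs there by construction
        ph = ls.build_plate_phantom(thickness_um=5.0, extent_vox=48)
        crofton = interface_area_um2(
            ph.labels, [Label.SEPTUM], sorted(AIRSPACE_LABELS), 1.0, method="crofton"
        )
        faces = interface_area_um2(
            ph.labels, [Label.SEPTUM], sorted(AIRSPACE_LABELS), 1.0, method="faces"
        )
        assert faces == pytest.approx(ph.meta["analytic"]["septal_surface_um2"])
        assert crofton != pytest.approx(faces)


class TestParenchymaBuilder:
    def test_requested_count_is_generated(self):
        # a preset asking for ~10 cavities in a small block
        preset = dataclasses.replace(
            ls.NORMOXIA,
            alveolar_number_density_per_um3=10 / (150.0**3),
            duct_site_fraction=0.0,
            edema_airspace_fraction=0.0,
            septal_thickness_um=40.0,
        )
        ph = ls.build_parenchyma_phantom(preset, seed=0, shape=(100, 100, 100))
        assert ph.ground_truth.alveolus_count >= 4  # lattice-limited but nonzero

    def test_cavities_are_disjoint_in_closed_cell_mode(self, normoxia_parenchyma):
        from scipy import ndimage

        air = np.isin(normoxia_parenchyma.labels, sorted(ls.phantom.ALVEOLAR_AIRSPACE_LABELS))
        _lab, n = ndimage.label(air, structure=np.ones((3, 3, 3)))
        assert n == normoxia_parenchyma.ground_truth.alveolus_count

    def test_septal_thickness_ratio_tracks_reference_contrast(
        self, normoxia_parenchyma, hyperoxia_parenchyma
    ):
        tau_n = normoxia_parenchyma.ground_truth.mean_septal_thickness_um
        tau_h = hyperoxia_parenchyma.ground_truth.mean_septal_thickness_um
        ref_n, _, ref_h, _ = ls.REFERENCE_TABLE["tau_sept_um"]
        assert tau_h / tau_n == pytest.approx(ref_h / ref_n, rel=0.10)

    def test_groups_share_mean_alveolar_size(
        self, normoxia_parenchyma, hyperoxia_parenchyma
    ):
        vn_n = normoxia_parenchyma.ground_truth.mean_alveolar_volume_um3
        vn_h = hyperoxia_parenchyma.ground_truth.mean_alveolar_volume_um3
        assert vn_h == pytest.approx(vn_n, rel=0.02)

    def test_infeasible_packing_raises(self):
        bad = dataclasses.replace(
            ls.NORMOXIA, septal_thickness_um=5.0  # unreachable for ~20 um cavities
        )
        with pytest.raises(ls.PackingError):
            ls.build_parenchyma_phantom(bad, seed=0, target_extent_vox=96)

    def test_packing_floor_is_consistent_with_builder(self):
        floor = min_packable_septal_thickness_um(ls.NORMOXIA)
        ok = dataclasses.replace(ls.NORMOXIA, septal_thickness_um=1.05 * floor)
        ls.build_parenchyma_phantom(ok, seed=0, target_extent_vox=128)  # does not raise

    def test_edema_fraction_near_target(self):
        ph = ls.build_parenchyma_phantom(ls.HYPEROXIA, seed=4, target_extent_vox=192)
        gt = ph.ground_truth
        frac = gt.volume([Label.EDEMA, Label.INFLAMMATORY]) / gt.airspace_volume_um3
        assert frac == pytest.approx(ls.HYPEROXIA.edema_airspace_fraction, rel=0.35)

    def test_duct_open_mode_connects_alveoli_to_ducts(self):
        ph = ls.build_parenchyma_phantom(ls.NORMOXIA, mode="duct_open", seed=0,
                                         target_extent_vox=128)
        from scipy import ndimage

        air = np.isin(ph.labels, sorted(AIRSPACE_LABELS))
        _lab, n = ndimage.label(air, structure=np.ones((3, 3, 3)))
        # mouths merge cavities into shared acinar airspaces
        assert n < ph.ground_truth.alveolus_count


class TestVessels:
    def test_cylinder_lumen_identity_4v_over_s(self, vessel_phantom):
        ana = vessel_phantom.meta["analytic"]
        assert 4 * ana["luminal_volume_um3"] / ana["luminal_surface_um2"] == pytest.approx(
            60.0
        )
        # voxel tallies agree with the analytic cylinder within 3%
        gt = vessel_phantom.ground_truth
        assert gt.luminal_volume_um3 == pytest.approx(ana["luminal_volume_um3"], rel=0.03)

    def test_wall_shell_thickness_identity(self, vessel_phantom):
        gt = vessel_phantom.ground_truth
        t = gt.wall_volume_um3 / gt.luminal_surface_um2
        # exact shell identity: V/S = (r2^2 - r1^2) / (2 r1); the voxel
        # tally carries the Crofton-surface discretization of the lumen
        expected = (36.0**2 - 30.0**2) / (2 * 30.0)
        assert t == pytest.approx(expected, rel=0.20)

    def test_nonparenchyma_preset_diameters_differ_between_groups(self):
        assert ls.NORMOXIA.vessel_diameter_um == pytest.approx(76.3)
        assert ls.HYPEROXIA.vessel_diameter_um == pytest.approx(60.1)

    def test_impossible_vessel_geometry_fails_explicitly(self):
        import dataclasses as dc

        bad = dc.replace(ls.NORMOXIA, vessel_diameter_um=500.0, vessels_per_lung=2)
        with pytest.raises(ls.PackingError):
            ls.build_nonparenchyma_phantom(bad, seed=0, shape=(96, 96, 96))


class TestSectioning:
    def test_equatorial_section_shows_full_diameter_disc(self, sphere_phantom):
        c = sphere_phantom.depth_um / 2.0
        sec = ls.extract_section(sphere_phantom, c, 1.0)
        disc = sec.labels == Label.ALVEOLAR_AIR
        assert disc.any()
        width = np.ptp(np.nonzero(disc.any(axis=0))[0]) + 1
        assert abs(width - 40.0) <= 2  # 2 r = 40 um at 1 um pixels

    def test_section_missing_the_cavity_has_no_identity(self, sphere_phantom):
        sec = ls.extract_section(sphere_phantom, 1.0, 1.0)
        assert not (sec.alveolus_id > 0).any()

    def test_pole_straddling_pair_is_a_countable_event(self):
        # 20 um sphere: plane pairs 4.5 um apart bracketing the pole see
        # the profile in exactly one section
        ph = ls.build_sphere_phantom(radius_um=10.0, voxel_um=1.5)
        c = ph.depth_um / 2.0
        z = c + 10.0 - 2.0  # 2 um below the upper pole
        pair = ls.extract_disector_pairs(ph, [z], spacing_within_pair_um=4.5)[0]
        in_ref = (pair.reference.labels == Label.ALVEOLAR_AIR).any()
        in_look = (pair.lookup.labels == Label.ALVEOLAR_AIR).any()
        assert in_ref and not in_look

    def test_disector_pairs_record_the_default_height(self, normoxia_parenchyma):
        pairs = ls.extract_disector_pairs(normoxia_parenchyma, [30.0, 90.0])
        assert all(p.h_um == pytest.approx(4.5) for p in pairs)

    def test_out_of_block_section_fails(self, sphere_phantom):
        with pytest.raises(ValueError):
            ls.extract_section(sphere_phantom, sphere_phantom.depth_um + 5.0, 1.0)

    def test_cavalieri_full_sampling_reconstructs_compartment_volumes(self):
        ph = ls.build_sphere_phantom(radius_um=12.0, voxel_um=1.0)
        a = ph.voxel_um
        total = 0.0
        for k in range(ph.shape[0]):
            sec = ls.extract_section(ph, (k + 0.5) * a, a)
            total += np.count_nonzero(sec.labels == Label.ALVEOLAR_AIR) * a * a * a
        assert total == pytest.approx(ph.ground_truth.volume([Label.ALVEOLAR_AIR]))


def test_lung_phantom_composes_both_compartments():
    lung = ls.build_lung_phantom(ls.NORMOXIA, seed=0, nx=192, ny=192)
    gt = lung.ground_truth
    assert gt.parenchyma_volume_um3 > 0
    assert gt.nonparenchyma_volume_um3 > 0
    assert gt.luminal_volume_um3 > 0
    assert gt.alveolus_count > 10
    # compartments tile the block
    assert gt.parenchyma_volume_um3 + gt.nonparenchyma_volume_um3 == pytest.approx(
        gt.block_volume_um3
    )
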