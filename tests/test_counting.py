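"""Point, intersection, disector and vessel-profile counting rules."""

import numpy as np
import pytest
from scipy import ndimage

import lungstereo as ls
from lungstereo.counting import (
    CountingError,
    _ComponentSelector,
    classify_vessel_profiles,
    count_alveoli_by_identity,
    count_disector_events,
    count_line_intersections,
    count_points,
    count_points_on_field,
)
from lungstereo.phantom import Label, SectionImage
from lungstereo.sampling import LINE_GRID_PARENCHYMA, POINT_GRID_36, build_grid


def _section(labels: np.ndarray, pixel_um: float = 1.0) -> SectionImage:
    return SectionImage(
        labels=labels.astype(np.uint8),
        alveolus_id=np.zeros_like(labels, np.int32),
        z_um=0.0,
        thickness_um=1.0,
        pixel_um=pixel_um,
    )


class TestPointCounting:
    def test_uniform_field_assigns_all_points_to_one_label(self):
        sec = _section(np.full((100, 100), Label.SEPTUM))
        grid = build_grid(POINT_GRID_36, (100.0, 100.0), seed=0)
        counts = count_points_on_field(sec, grid, (0.0, 0.0))
        assert counts == {int(Label.SEPTUM): 36}

    def test_half_and_half_field_splits_evenly_over_seeds(self):
        labels = np.full((100, 100), Label.SEPTUM)
        labels[:, 50:] = Label.ALVEOLAR_AIR
        sec = _section(labels)
        tot = {int(Label.SEPTUM): 0, int(Label.ALVEOLAR_AIR): 0}
        for s in range(200):
            grid = build_grid(POINT_GRID_36, (100.0, 100.0), seed=s)
            for k, v in count_points_on_field(sec, grid, (0.0, 0.0)).items():
                tot[k] += v
        frac = tot[int(Label.SEPTUM)] / sum(tot.values())
        assert frac == pytest.approx(0.5, abs=0.03)

    def test_quarter_area_gets_quarter_of_the_points(self):
        labels = np.full((120, 120), Label.SEPTUM)
        labels[:60, :60] = Label.ALVEOLAR_AIR  # 25% of the area
        sec = _section(labels)
        pix = np.mean(labels == Label.ALVEOLAR_AIR)
        hits = tot = 0
        for s in range(300):
            grid = build_grid(POINT_GRID_36, (120.0, 120.0), seed=s)
            counts = count_points_on_field(sec, grid, (0.0, 0.0))
            hits += counts.get(int(Label.ALVEOLAR_AIR), 0)
            tot += sum(counts.values())
        assert hits / tot == pytest.approx(pix, abs=3 * np.sqrt(pix * (1 - pix) / tot))

    def test_point_off_raster_is_a_placement_bug(self):
        raster = np.zeros((10, 10), np.uint8)
        with pytest.raises(CountingError):
            count_points(raster, np.array([[5, 12]]))


class TestLineIntersections:
    def test_line_crossing_a_plate_counts_two(self):
        labels = np.full((60, 60), Label.ALVEOLAR_AIR)
        labels[:, 20:30] = Label.SEPTUM  # vertical plate crossed by each line
        sec = _section(labels)
        grid = build_grid(LINE_GRID_PARENCHYMA, (60.0, 60.0), seed=0)
        i_cnt, p_ref, length = count_line_intersections(
            sec, grid, (0.0, 0.0), [Label.SEPTUM], [Label.ALVEOLAR_AIR],
            [Label.SEPTUM, Label.ALVEOLAR_AIR],
        )
        assert i_cnt == 2 * 12
        assert length == pytest.approx(p_ref * 9.37)

    def test_line_inside_airspace_counts_zero(self):
        sec = _section(np.full((60, 60), Label.ALVEOLAR_AIR))
        grid = build_grid(LINE_GRID_PARENCHYMA, (60.0, 60.0), seed=0)
        i_cnt, _, _ = count_line_intersections(
            sec, grid, (0.0, 0.0), [Label.SEPTUM], [Label.ALVEOLAR_AIR],
            [Label.ALVEOLAR_AIR],
        )
        assert i_cnt == 0

    def test_circle_crossings_match_exhaustive_geometry(self):
        # disc of radius R: every row within the disc crosses its
        # boundary exactly twice, so scanning all rows gives 2 x (rows
        # intersecting the disc) — compare against the exhaustive count
        R, n = 20, 64
        yy, xx = np.indices((n, n))
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 <= R * R
        labels = np.where(disc, np.uint8(Label.ALVEOLAR_AIR), np.uint8(Label.SEPTUM))
        total = 0
        for row in range(n):
            trace = labels[row]
            total += int(np.count_nonzero(np.diff(trace.astype(int)) != 0))
        rows_hit = int(np.count_nonzero(disc.any(axis=1)))
        assert total == 2 * rows_hit

    def test_intersections_symmetric_under_label_order_and_flips(self):
        from lungstereo.sampling import GridSpec

        rng = np.random.default_rng(0)
        labels = rng.choice(
            [int(Label.SEPTUM), int(Label.ALVEOLAR_AIR)], size=(64, 64), p=[0.4, 0.6]
        ).astype(np.uint8)
        # full-width lines so a horizontal flip maps traces onto traces
        spec = GridSpec(kind="line", n_lines=8, lp_um=8.0, points_per_line=8)
        grid = build_grid(spec, (64.0, 64.0), seed=1)
        ref = [Label.SEPTUM, Label.ALVEOLAR_AIR]

        def count(arr, a, b):
            return count_line_intersections(
                _section(arr), grid, (0.0, 0.0), a, b, ref
            )[0]

        base = count(labels, [Label.SEPTUM], [Label.ALVEOLAR_AIR])
        assert count(labels, [Label.ALVEOLAR_AIR], [Label.SEPTUM]) == base
        assert count(labels[:, ::-1], [Label.SEPTUM], [Label.ALVEOLAR_AIR]) == base


class TestDisector:
    def _pair(self, a, b, h=4.5):
        return ls.DisectorPair(reference=_section(a), lookup=_section(b), h_um=h)

    def test_island_appears_in_exactly_one_direction(self):
        a = np.full((60, 60), Label.SEPTUM)
        b = a.copy()
        b[28:33, 28:33] = Label.ALVEOLAR_AIR  # profile only in the look-up
        ev = count_disector_events(self._pair(a, b), frame_um=None)
        assert (ev.islands_ab, ev.islands_ba) == (1, 0)
        assert ev.net_events == 1

    def test_homogeneous_airspace_has_no_events(self):
        a = np.full((60, 60), Label.ALVEOLAR_AIR)
        ev = count_disector_events(self._pair(a, a.copy()), frame_um=None)
        assert ev.net_events == 0

    def test_merge_counts_bridges(self):
        a = np.full((60, 60), Label.SEPTUM)
        a[10:20, 10:20] = Label.ALVEOLAR_AIR
        a[10:20, 40:50] = Label.ALVEOLAR_AIR
        b = np.full((60, 60), Label.SEPTUM)
        b[10:20, 10:50] = Label.ALVEOLAR_AIR  # the two profiles merged
        ev = count_disector_events(self._pair(a, b), frame_um=None)
        assert ev.bridges_ab == 1  # two reference profiles -> one look-up
        assert ev.islands_ab == 0

    def test_sphere_poles_give_two_events_over_the_stack(self):
        ph = ls.build_sphere_phantom(radius_um=10.0, voxel_um=1.0)
        a = ph.voxel_um
        pairs = ls.extract_disector_pairs(
            ph, [k * a for k in range(ph.shape[0] - 1)], spacing_within_pair_um=a
        )
        net = sum(count_disector_events(p, None).net_events for p in pairs)
        assert net == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exhaustive_tiling_counts_every_cavity_twice(self, seed):
        ph = ls.build_parenchyma_phantom(ls.NORMOXIA, seed=seed, target_extent_vox=128)
        a = ph.voxel_um
        pairs = ls.extract_disector_pairs(
            ph, [k * a for k in range(ph.shape[0] - 1)], spacing_within_pair_um=a
        )
        net = orac = 0
        for p in pairs:
            net += count_disector_events(p, None).net_events
            orac += count_alveoli_by_identity(p, None)
        assert net == 2 * ph.ground_truth.alveolus_count
        assert net == orac

    def test_framed_events_equal_identity_oracle(self, normoxia_parenchyma):
        ph = normoxia_parenchyma
        frame = (20.0, 20.0, 160.0, 160.0)
        for z in (40.0, 90.0, 140.0):
            pair = ls.extract_disector_pairs(ph, [z])[0]
            ev = count_disector_events(pair, frame)
            assert ev.islands_ab + ev.islands_ba == count_alveoli_by_identity(pair, frame)

    def test_identity_oracle_zero_on_identical_sections(self, normoxia_parenchyma):
        sec = ls.extract_section(normoxia_parenchyma, 80.0)
        pair = ls.DisectorPair(reference=sec, lookup=sec, h_um=4.5)
        assert count_alveoli_by_identity(pair, None) == 0

    def test_oracle_requires_identity_raster(self):
        a = np.full((30, 30), Label.SEPTUM)
        pair = ls.DisectorPair(
            reference=SectionImage(a, None, 0.0, 1.0, 1.0),
            lookup=SectionImage(a, None, 4.5, 1.0, 1.0),
            h_um=4.5,
        )
        with pytest.raises(CountingError):
            count_alveoli_by_identity(pair)


class TestFrameRule:
    def test_tiling_counts_each_convex_profile_exactly_once(self):
        h = w = 360
        side = 90
        yy, xx = np.indices((h, w))
        rng = np.random.default_rng(7)
        img = np.zeros((h, w), bool)
        for _ in range(12):
            cy, cx = rng.uniform(60, h - 60), rng.uniform(60, w - 60)
            img |= (yy - cy) ** 2 + (xx - cx) ** 2 <= 15**2
        lab, n = ndimage.label(img, structure=np.ones((3, 3)))
        selector = _ComponentSelector(lab)
        counted = np.zeros(n + 1, int)
        for fy in range(0, h, side):
            for fx in range(0, w, side):
                for i in selector.select((fy, fx, fy + side, fx + side)):
                    counted[i] += 1
        assert np.all(counted[1:] == 1)

    def test_profile_touching_forbidden_edge_is_rejected(self):
        lab = np.zeros((50, 50), int)
        lab[24:30, 8:14] = 1  # crosses the left line of a frame at x=10
        selector = _ComponentSelector(lab)
        assert len(selector.select((0, 10, 40, 40))) == 0
        # ... but accepted once the frame starts left of the profile
        assert len(selector.select((0, 5, 40, 40))) == 1


class TestVesselProfiles:
    @staticmethod
    def _vessel_section(diams_um, pixel_um=1.0):
        n = 300
        labels = np.full((n, n), Label.AIRWAY, np.uint8)
        yy, xx = np.indices((n, n))
        for i, d in enumerate(diams_um):
            cy, cx = 60 + 90 * i, 80 + 60 * i
            r = d / 2.0 / pixel_um
            ring = (yy - cy) ** 2 + (xx - cx) ** 2
            labels[ring <= (r + 8) ** 2] = Label.PERIVASCULAR
            labels[ring <= (r + 4) ** 2] = Label.VESSEL_WALL
            labels[ring <= r**2] = Label.VESSEL_LUMEN
        return _section(labels, pixel_um)

    def test_calibre_cutoff(self):
        sec = self._vessel_section([30.0, 20.0])
        profs = classify_vessel_profiles(sec, min_diameter_um=25.0)
        flags = sorted(p.included for p in profs)
        assert flags == [False, True]

    def test_oblique_cut_judged_by_short_axis(self):
        # 60 x 20 um ellipse: an oblique cut of a 20 um vessel
        n = 120
        labels = np.full((n, n), Label.AIRWAY, np.uint8)
        yy, xx = np.indices((n, n))
        ell = ((yy - 60) / 10.0) ** 2 + ((xx - 60) / 30.0) ** 2 <= 1.0
        labels[ell] = Label.VESSEL_LUMEN
        profs = classify_vessel_profiles(_section(labels), min_diameter_um=25.0)
        (p,) = list(profs)
        assert p.short_axis_um == pytest.approx(20.0, abs=2.0)
        assert not p.included

    def test_wall_and_perivascular_areas_attributed_to_their_lumen(self):
        sec = self._vessel_section([40.0])
        (p,) = list(classify_vessel_profiles(sec))
        r = 20.0
        assert p.lumen_area_um2 == pytest.approx(np.pi * r * r, rel=0.05)
        assert p.wall_area_um2 == pytest.approx(np.pi * ((r + 4) ** 2 - r * r), rel=0.10)
        assert p.boundary_length_um == pytest.approx(2 * np.pi * r, rel=0.05)

    def test_wall_without_lumen_is_excluded_with_warning(self):
        n = 80
        labels = np.full((n, n), Label.AIRWAY, np.uint8)
        labels[30:50, 30:50] = Label.VESSEL_WALL
        with pytest.warns(UserWarning, match="without any lumen"):
            profs = classify_vessel_profiles(_section(labels))
        assert profs.n_included == 0

    def test_phantom_population_count_matches_true_diameters(self):
        preset = ls.NORMOXIA
        ph = ls.build_nonparenchyma_phantom(preset, seed=2, shape=(128, 160, 160))
        sec = ls.extract_section(ph, ph.depth_um / 2.0)
        profs = classify_vessel_profiles(sec, min_diameter_um=25.0)
        assert profs.n_included == preset.vessels_per_lung
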