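import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpoct.geometry import OCTGeometry
from mpoct.quantify.discs import (QuantConfig, adjust_sensitivity, disc_pixels,
                                  eccentricity_deg, hrf_volume_in_disc,
                                  mean_thickness, volume_in_disc)
from mpoct.quantify.table import (MissingRegistrationError, assemble_table,
                                  included_count)
from mpoct.synthgen.eye import HRFComponent
from mpoct.synthgen.sensitivity import point_features


def brute_force_disc(center, geometry, radius):
    """Independent oracle: full lattice scan."""
    out = []
    for b in range(geometry.n_bscans):
        for a in range(geometry.n_ascans):
            dx = a * geometry.ascan_spacing_um - center[0]
            dy = b * geometry.bscan_spacing_um - center[1]
            if dx * dx + dy * dy <= radius * radius:
                out.append((b, a))
    return set(out)


class TestDiscPixels:
    def test_iso10_aligned_center_has_149_pixels(self, iso10_geometry):
        g = iso10_geometry
        center = (100 * g.ascan_spacing_um, 100 * g.bscan_spacing_um)
        disc = disc_pixels(center, g, 70.0)
        assert disc.shape[0] == 149
        assert {tuple(p) for p in disc} == brute_force_disc(center, g, 70.0)

    def test_tiny_radius_single_pixel(self, geometry):
        center = (50 * geometry.ascan_spacing_um, 10 * geometry.bscan_spacing_um)
        disc = disc_pixels(center, geometry, 2.0)
        assert disc.shape[0] == 1
        assert tuple(disc[0]) == (10, 50)

    def test_default_anisotropic_span(self, geometry):
        disc = disc_pixels(geometry.fovea_um, geometry, 70.0)
        n_a = np.ptp(disc[:, 1]) + 1
        n_b = np.ptp(disc[:, 0]) + 1
        assert 11 <= n_a <= 13  # ~140 um / 11.27 um
        assert n_b == 3        # ~140 um / 60 um
        assert np.all(disc[:, 0] >= 0) and np.all(disc[:, 1] >= 0)

    def test_fully_outside_scan_is_empty(self, geometry):
        assert disc_pixels((-500.0, -500.0), geometry, 70.0).shape[0] == 0

    @given(cx=st.floats(-200, 6000), cy=st.floats(-200, 6000),
           r=st.floats(5, 200))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force(self, cx, cy, r):
        g = OCTGeometry(n_bscans=30, n_ascans=40, field_deg=(20.0, 20.0))
        disc = disc_pixels((cx, cy), g, r)
        assert {tuple(p) for p in disc} == brute_force_disc((cx, cy), g, r)

    def test_invalid_radius(self, geometry):
        with pytest.raises(ValueError):
            disc_pixels((0.0, 0.0), geometry, 0.0)


class TestAggregates:
    def test_mean_of_constant_raster(self, geometry):
        raster = np.full(geometry.shape, 29.0)
        disc = disc_pixels(geometry.fovea_um, geometry, 70.0)
        assert mean_thickness(raster, disc) == pytest.approx(29.0)

    def test_mean_of_half_and_half(self):
        raster = np.array([[20.0, 40.0], [20.0, 40.0]])
        disc = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert mean_thickness(raster, disc) == pytest.approx(30.0)

    def test_empty_disc_is_missing(self, geometry):
        assert math.isnan(mean_thickness(np.zeros(geometry.shape),
                                         np.empty((0, 2), dtype=int)))

    def test_zero_height_map_zero_volume(self, geometry):
        disc = disc_pixels(geometry.fovea_um, geometry, 70.0)
        assert volume_in_disc(np.zeros(geometry.shape), disc, geometry) == 0.0

    def test_uniform_height_volume_149px(self, iso10_geometry):
        g = iso10_geometry
        center = (100 * g.ascan_spacing_um, 100 * g.bscan_spacing_um)
        disc = disc_pixels(center, g, 70.0)
        vol = volume_in_disc(np.full(g.shape, 100.0), disc, g)
        assert vol == pytest.approx(1.49)  # 149 px * 100 um * 100 um2 / 1e6

    def test_volume_scales_linearly_with_height(self, geometry, rng):
        h = rng.uniform(0, 50, size=geometry.shape)
        disc = disc_pixels(geometry.fovea_um, geometry, 70.0)
        v1 = volume_in_disc(h, disc, geometry)
        v3 = volume_in_disc(3.0 * h, disc, geometry)
        assert v3 == pytest.approx(3.0 * v1, rel=1e-12)

    def test_volume_invariant_under_refinement(self):
        """Halving pixel pitch changes uniform-field volume by < 10%."""
        vols = []
        for n in (101, 201):
            side = 2000.0 / 288.0
            g = OCTGeometry(n_bscans=n, n_ascans=n, field_deg=(side, side))
            center = (g.field_um[0] / 2, g.field_um[1] / 2)
            disc = disc_pixels(center, g, 70.0)
            vols.append(volume_in_disc(np.full(g.shape, 50.0), disc, g))
        assert abs(vols[1] - vols[0]) / vols[0] < 0.10

    def test_disc_aggregate_equals_pixel_loop(self, cohort20):
        """Oracle equivalence on a real synthetic eye."""
        p = cohort20.patients[0]
        g = cohort20.geometry
        xy = cohort20.grid.enface_positions_um(g)[17]
        disc = disc_pixels(xy, g, 70.0)
        expected = np.mean([p.eye.maps.ez_um[b, a] for b, a in disc])
        assert mean_thickness(p.eye.maps.ez_um, disc) == expected
        expected_v = sum(p.eye.maps.drusen_height_um[b, a] for b, a in disc)
        expected_v *= g.pixel_area_um2 / 1e6
        assert volume_in_disc(p.eye.maps.drusen_height_um, disc, g) == \
            pytest.approx(expected_v, rel=1e-12)


class TestHRF:
    def _component(self, pixels, total):
        n = len(pixels)
        return HRFComponent(0, tuple(pixels), tuple([total / n] * n))

    def test_subthreshold_component_discarded(self, geometry):
        disc = disc_pixels(geometry.fovea_um, geometry, 70.0)
        comp = self._component([tuple(disc[0]), tuple(disc[1])], 0.05)
        assert hrf_volume_in_disc([comp], disc) == 0.0

    def test_suprathreshold_component_counted(self, geometry):
        disc = disc_pixels(geometry.fovea_um, geometry, 70.0)
        comp = self._component([tuple(p) for p in disc[:4]], 0.10)
        assert hrf_volume_in_disc([comp], disc) == pytest.approx(0.10)

    def test_partial_overlap_counts_inside_voxels_only(self, geometry):
        disc = disc_pixels(geometry.fovea_um, geometry, 70.0)
        inside = [tuple(p) for p in disc[:2]]
        outside = [(0, 0), (0, 1), (0, 2)]
        comp = HRFComponent(0, tuple(inside + outside),
                            (0.02, 0.02, 0.02, 0.02, 0.02))
        assert hrf_volume_in_disc([comp], disc) == pytest.approx(0.04)

    def test_disc_level_threshold_flag(self, geometry):
        disc = disc_pixels(geometry.fovea_um, geometry, 70.0)
        inside = [tuple(p) for p in disc[:1]]
        outside = [(0, 0)]
        # total 0.10 (passes global filter) but only 0.05 in disc
        comp = HRFComponent(0, tuple(inside + outside), (0.05, 0.05))
        assert hrf_volume_in_disc([comp], disc) == pytest.approx(0.05)
        cfg = QuantConfig(hrf_disc_level_threshold=True)
        assert hrf_volume_in_disc([comp], disc, cfg) == 0.0


class TestEccentricityAndAdjustment:
    def test_point_at_fovea(self, geometry):
        assert eccentricity_deg(geometry.fovea_um, geometry.fovea_um,
                                geometry) == 0.0

    def test_432um_is_1p5_degrees(self, geometry):
        fx, fy = geometry.fovea_um
        assert eccentricity_deg((fx + 432.0, fy), geometry.fovea_um,
                                geometry) == pytest.approx(1.5)

    @pytest.mark.parametrize("raw,device,expected", [
        (-1.0, "MAIA", 0.0), (34.0, "MP3", 34.0), (36.0, "MAIA", 36.0),
        (0.0, "MP3", 0.0),
    ])
    def test_adjustment(self, raw, device, expected):
        assert adjust_sensitivity(raw, device) == expected

    def test_out_of_range_is_data_error(self):
        with pytest.raises(ValueError):
            adjust_sensitivity(35.0, "MP3")
        with pytest.raises(ValueError):
            adjust_sensitivity(-2.0, "MAIA")

    def test_maia_floor_adjust_can_be_disabled(self):
        cfg = QuantConfig(maia_floor_adjust=False)
        assert adjust_sensitivity(-1.0, "MAIA", cfg) == 0.0  # still clamped


class TestAssembleTable:
    def test_counts_all_included(self, cohort20, table20):
        assert len(table20) == 3600
        assert included_count(table20) == 3600

    def test_ground_truth_recovery_with_true_transform(self, cohort20, table20):
        """Quantifying via the hidden transform reproduces generator features."""
        g = cohort20.geometry
        p = cohort20.patients[0]
        truth = [point_features(p.eye.maps, xy, g)
                 for xy in cohort20.grid.enface_positions_um(g)]
        sub = table20[(table20.patient_id == p.eye.patient_id)
                      & (table20.device == p.acquisitions[0].device)
                      & (table20.run == 1)].sort_values("point_id")
        for row, f in zip(sub.itertuples(), truth):
            assert row.ez_um == pytest.approx(f["ez_um"], abs=1e-9)
            assert row.drusen_nl == pytest.approx(f["drusen_nl"], abs=1e-9)
            assert row.eccentricity_deg == pytest.approx(
                f["eccentricity_deg"], abs=1e-9)

    def test_missing_registration_is_hard_error(self, cohort20):
        with pytest.raises(MissingRegistrationError):
            assemble_table(cohort20, registrations={})

    def test_out_of_area_points_excluded(self, cohort20):
        from mpoct.register.transform import SimilarityTransform
        regs = {}
        for p in cohort20.patients:
            for a in p.acquisitions:
                T = a.true_transform
                regs[(a.patient_id, a.device, a.run)] = SimilarityTransform(
                    T.scale, T.rotation_rad,
                    (T.translation[0] - 1800.0, T.translation[1]))
        table = assemble_table(cohort20, regs)
        excluded = table[~table.included]
        assert len(excluded) > 0
        assert excluded["ez_um"].isna().all()
        assert len(table) == 3600

    def test_column_order(self, table20):
        from mpoct.quantify.table import TABLE_COLUMNS
        assert list(table20.columns) == TABLE_COLUMNS

    def test_pws_within_adjusted_range(self, table20):
        mp3 = table20[table20.device == "MP3"].pws_db
        maia = table20[table20.device == "MAIA"].pws_db
        assert mp3.between(0, 34).all()
        assert maia.between(0, 36).all()
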