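"""Concentric-zone quantification: centroid, mask geometry, per-pixel agreement."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hma.zonation import (
    MultichannelStack,
    WellGeometry,
    locate_well_center,
    quantify_zones,
    zone_mask,
)

from conftest import brute_force_zone_counts, make_stack


class TestLocateWellCenter:
    def test_point_mass(self):
        img = np.zeros((30, 40))
        img[10, 20] = 7.0
        est = locate_well_center(make_stack(img))
        assert (est.y_px, est.x_px) == (10.0, 20.0)
        assert not est.fallback

    def test_all_zero_falls_back_to_geometric_center(self):
        est = locate_well_center(make_stack(np.zeros((21, 31))))
        assert est.fallback
        assert (est.y_px, est.x_px) == (10.0, 15.0)

    def test_two_blob_matches_weighted_mean_oracle(self):
        rng = np.random.default_rng(5)
        img = np.zeros((50, 60))
        img[10:15, 5:9] = rng.uniform(1, 3, (5, 4))
        img[30:40, 40:55] = rng.uniform(0.5, 2, (10, 15))
        est = locate_well_center(make_stack(img))
        total = img.sum()
        cy = sum(i * img[i, j] for i in range(50) for j in range(60)) / total
        cx = sum(j * img[i, j] for i in range(50) for j in range(60)) / total
        assert est.y_px == pytest.approx(cy, abs=1e-12)
        assert est.x_px == pytest.approx(cx, abs=1e-12)


class TestZoneMask:
    def test_center_pixel_is_zone_one_and_rim_is_outer_zone(self):
        g = WellGeometry(diameter_um=500, n_zones=5, um_per_px=1.0, center_um=(250.0, 250.0))
        mask = zone_mask(g, (501, 501))
        assert mask[250, 250] == 1  # r = 0
        assert mask[250, 500] == 5  # r = R exactly: outer bin closed
        assert mask[0, 0] == 0  # corner lies outside the circle

    def test_unresolved_center_rejected(self):
        with pytest.raises(ValueError, match="center"):
            zone_mask(WellGeometry(), (10, 10))

    def test_truncated_well_warns(self):
        g = WellGeometry(diameter_um=100, um_per_px=1.0, center_um=(10.0, 50.0))
        with pytest.warns(UserWarning, match="truncated"):
            zone_mask(g, (101, 101))

    def test_equal_width_zones_have_odd_number_area_ratio(self):
        """Annulus areas of equal-width zones scale as 1:3:5:7:9."""
        g = WellGeometry(diameter_um=500, n_zones=5, um_per_px=1.0, center_um=(249.5, 249.5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # circle grazes the image edge
            mask = zone_mask(g, (500, 500))
        counts = np.bincount(mask.ravel(), minlength=6)[1:]
        expected = np.array([2 * k - 1 for k in range(1, 6)]) / 25.0
        np.testing.assert_allclose(counts / counts.sum(), expected, atol=3e-3)

    def test_matches_brute_force_distance_loop(self):
        g = WellGeometry(diameter_um=30, n_zones=4, um_per_px=0.75, center_um=(12.0, 11.0))
        mask = zone_mask(g, (40, 40))
        for y in range(40):
            for x in range(40):
                r = math.sqrt((y * 0.75 - 12.0) ** 2 + (x * 0.75 - 11.0) ** 2)
                if r > 15.0:
                    expected = 0
                else:
                    expected = min(int(r // (15.0 / 4)) + 1, 4)
                assert mask[y, x] == expected


class TestQuantifyZones:
    def test_single_zone_mass(self, small_geometry):
        img = np.zeros((41, 41))
        img[20, 20] = img[21, 20] = 5.0  # r = 0 and r = 1 < R/5 = 4
        profile = quantify_zones(make_stack(img), small_geometry, threshold=1.0)
        np.testing.assert_allclose(profile.fractions("ch0"), [1, 0, 0, 0, 0])
        assert profile.channels["ch0"].total_area_um2 == 2.0

    def test_empty_channel_reported_missing_not_zero(self, small_geometry):
        pixels = np.zeros((2, 1, 41, 41))
        pixels[0, 0, 20, 20] = 1.0
        stack = make_stack(pixels, ["a", "b"])
        with pytest.warns(UserWarning, match="'b'.*no pixel above threshold"):
            profile = quantify_zones(stack, small_geometry, threshold=0.5)
        assert profile.fractions("b") is None
        assert profile.fractions("a") is not None

    def test_matches_per_pixel_oracle_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            h = int(rng.integers(16, 64))
            c = int(rng.integers(1, 3))
            z = int(rng.integers(1, 3))
            pixels = rng.uniform(0, 1, (c, z, h, h))
            upp = float(rng.uniform(0.5, 2.0))
            extent = (h - 1) * upp
            center = (extent / 2, extent / 2)
            g = WellGeometry(
                diameter_um=0.9 * extent, n_zones=int(rng.integers(1, 6)),
                um_per_px=upp, center_um=center,
            )
            thr = float(rng.uniform(0.2, 0.8))
            profile = quantify_zones(make_stack(pixels, um_per_px=upp), g, threshold=thr)
            for ci, name in enumerate(profile.channels):
                oracle = brute_force_zone_counts(
                    pixels, ci, center, upp, g.radius_um, g.n_zones, thr
                )
                got = profile.channels[name].areas_um2 / upp**2
                np.testing.assert_array_equal(np.rint(got).astype(int), oracle[1:])
                assert profile.channels[name].outside_area_um2 == pytest.approx(
                    oracle[0] * upp**2
                )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        h=st.integers(12, 48),
        n_zones=st.integers(1, 6),
    )
    def test_oracle_equivalence_property(self, seed, h, n_zones):
        """Vectorised zone counts equal the per-pixel loop for arbitrary images."""
        rng = np.random.default_rng(seed)
        pixels = rng.uniform(0, 1, (1, 1, h, h))
        center = ((h - 1) / 2, (h - 1) / 2)
        g = WellGeometry(diameter_um=0.9 * (h - 1), n_zones=n_zones, um_per_px=1.0, center_um=center)
        profile = quantify_zones(make_stack(pixels), g, threshold=0.5)
        oracle = brute_force_zone_counts(pixels, 0, center, 1.0, g.radius_um, n_zones, 0.5)
        np.testing.assert_array_equal(
            np.rint(profile.channels["ch0"].areas_um2).astype(int), oracle[1:]
        )

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        pixels = rng.uniform(0, 1, (1, 2, 41, 41))
        g = WellGeometry(diameter_um=36, um_per_px=1.0, center_um=(20.0, 20.0))
        base = quantify_zones(make_stack(pixels), g, threshold=0.6)
        for k in (1, 2, 3):
            rotated = np.rot90(pixels, k=k, axes=(2, 3)).copy()
            prof = quantify_zones(make_stack(rotated), g, threshold=0.6)
            np.testing.assert_array_equal(
                prof.channels["ch0"].areas_um2, base.channels["ch0"].areas_um2
            )

    def test_resolution_doubling_changes_fractions_below_percent(self):
        from hma.synthetic import (
            PopulationSpec,
            RadialPlacementModel,
            SimulationConfig,
            generate_aggregate_image,
        )

        placement = RadialPlacementModel.from_zone_probs((0.2, 0.2, 0.2, 0.2, 0.2))
        fracs = []
        for upp in (1.0, 0.5):
            g = WellGeometry(diameter_um=200.0, um_per_px=upp)
            cfg = SimulationConfig(
                geometry=g,
                populations=(PopulationSpec("p", "p", 500, 4.0, placement),),
                noise_sd=0.0,
                seed=11,
            )
            stack = generate_aggregate_image(cfg)
            fracs.append(quantify_zones(stack, g, threshold=0.5).fractions("p"))
        np.testing.assert_allclose(fracs[0], fracs[1], atol=0.01)

    def test_off_center_signal_warns(self, small_geometry):
        img = np.zeros((41, 41))
        img[20, 18:23] = 3.0  # some in-well signal
        img[0, 0:12] = 3.0  # corner signal, outside the well
        with pytest.warns(UserWarning, match="outside the outermost zone"):
            quantify_zones(make_stack(img), small_geometry, threshold=1.0)

    def test_fixed_threshold_string_form(self, small_geometry):
        img = np.zeros((41, 41))
        img[20, 20] = 2.0
        p1 = quantify_zones(make_stack(img), small_geometry, threshold="fixed:1.0")
        p2 = quantify_zones(make_stack(img), small_geometry, threshold=1.0)
        np.testing.assert_array_equal(
            p1.channels["ch0"].areas_um2, p2.channels["ch0"].areas_um2
        )

    def test_bad_threshold_spec_rejected(self, small_geometry):
        with pytest.raises(ValueError, match="threshold"):
            quantify_zones(make_stack(np.ones((5, 5))), small_geometry, threshold="median")
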