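"""Kymographs, wound closure, radial band and density profiles."""
import numpy as np
import pytest
from scipy import ndimage

from metaboscope.sim import simulate_spatial_field
from metaboscope.spatial import (
    build_kymograph,
    density_profile,
    fit_length_scale,
    radial_band_profile,
    wound_area,
    wound_closure,
)

from oracles import brute_force_radial_ratio

UM_PER_PX = 2.0


def _ratio_stack(field):
    return np.divide(field["acceptor"], field["donor"],
                     out=np.zeros_like(field["donor"]), where=field["donor"] > 0)


class TestWoundClosure:
    def test_full_closure(self):
        assert wound_closure(100.0, 0.0) == 100.0

    def test_no_closure(self):
        assert wound_closure(100.0, 100.0) == 0.0

    def test_negative_closure_allowed(self):
        assert wound_closure(100.0, 120.0) == pytest.approx(-20.0)

    def test_zero_initial_rejected(self):
        with pytest.raises(ValueError):
            wound_closure(0.0, 10.0)

    def test_eroding_wound_geometry_oracle(self):
        # vertical wound strip eroded 10 px/side per frame
        h, w = 60, 100
        masks = []
        for f in range(3):
            cm = np.ones((h, w), bool)
            half = 30 - 10 * f
            cm[:, 50 - half:50 + half] = False
            masks.append(cm)
        a0 = wound_area(masks[0])
        a2 = wound_area(masks[2])
        assert a0 == 60 * h and a2 == 20 * h
        assert wound_closure(a0, a2) == pytest.approx(100.0 * (60 - 20) / 60)


class TestKymograph:
    def test_uniform_field_constant(self):
        field = simulate_spatial_field("scratch", image_shape=(120, 160),
                                       length_scale_um=1e9, n_frames=4,
                                       um_per_px=UM_PER_PX)
        masks = np.repeat(field["mask"][None], 4, axis=0)
        ky = build_kymograph(_ratio_stack(field), masks, UM_PER_PX, bin_um=40.0)
        vals = ky.values[np.isfinite(ky.values)]
        assert vals.max() - vals.min() < 1e-5

    def test_static_gradient_time_constant_and_scale(self):
        field = simulate_spatial_field("scratch", image_shape=(200, 300),
                                       length_scale_um=200.0, n_frames=3,
                                       um_per_px=UM_PER_PX)
        masks = np.repeat(field["mask"][None], 3, axis=0)
        ky = build_kymograph(_ratio_stack(field), masks, UM_PER_PX, bin_um=20.0)
        # time-constant to machine precision
        assert np.nanmax(np.abs(ky.values - ky.values[0])) == 0.0
        centers = (ky.distance_edges_um[:-1] + ky.distance_edges_um[1:]) / 2
        scale, _, _ = fit_length_scale(centers, ky.values[0])
        assert scale == pytest.approx(200.0, rel=0.10)

    def test_gradient_onset_localized(self):
        field = simulate_spatial_field("scratch", image_shape=(120, 200),
                                       length_scale_um=150.0, n_frames=8,
                                       onset_frame=4, um_per_px=UM_PER_PX)
        masks = np.repeat(field["mask"][None], 8, axis=0)
        ky = build_kymograph(_ratio_stack(field), masks, UM_PER_PX, bin_um=30.0,
                             interval_h=1.0)
        edge_band = ky.values[:, 0]
        jump = np.flatnonzero(np.diff(edge_band) > 0.1)
        assert len(jump) == 1 and abs((jump[0] + 1) - 4) <= 1


class TestRadialBandProfile:
    def test_uniform_ratio_flat(self):
        field = simulate_spatial_field("tumor", image_shape=(160, 160),
                                       length_scale_um=1e9, um_per_px=UM_PER_PX)
        prof = radial_band_profile(field["donor"][0], field["acceptor"][0],
                                   field["mask"], UM_PER_PX)
        vals = prof.ratio[np.isfinite(prof.ratio)]
        np.testing.assert_allclose(vals, vals[0], rtol=1e-5)

    def test_edge_gradient_decreasing_inward(self):
        field = simulate_spatial_field("tumor", image_shape=(300, 300),
                                       length_scale_um=100.0, um_per_px=UM_PER_PX)
        prof = radial_band_profile(field["donor"][0], field["acceptor"][0],
                                   field["mask"], UM_PER_PX, bin_um=40.0)
        assert np.all(np.diff(prof.ratio[:5]) < 0)

    def test_matches_pixel_loop_oracle_exactly(self):
        rng = np.random.default_rng(23)
        h = w = 80
        yy, xx = np.mgrid[0:h, 0:w]
        region = (yy - h / 2) ** 2 + (xx - w / 2) ** 2 <= 35 ** 2
        donor = rng.uniform(10, 200, (h, w))  # heteroscedastic by construction
        acceptor = donor * rng.uniform(1.0, 3.0, (h, w))
        prof = radial_band_profile(donor, acceptor, region, UM_PER_PX, bin_um=30.0)
        d_um = ndimage.distance_transform_edt(region) * UM_PER_PX
        oracle = brute_force_radial_ratio(donor, acceptor, region, d_um,
                                          prof.distance_edges_um)
        np.testing.assert_allclose(prof.ratio, oracle, rtol=1e-12)
        # ratio-of-sums differs from mean-of-ratios on this input
        mean_of_ratios = []
        edges = prof.distance_edges_um
        idx = np.clip(np.searchsorted(edges, d_um[region], side="right") - 1, 0,
                      len(edges) - 2)
        r = (acceptor / donor)[region]
        for b in range(len(edges) - 1):
            mean_of_ratios.append(r[idx == b].mean())
        assert not np.allclose(prof.ratio, mean_of_ratios, rtol=1e-3)

    def test_rotation_invariance_circular_region(self):
        field = simulate_spatial_field("tumor", image_shape=(160, 160),
                                       length_scale_um=120.0, um_per_px=UM_PER_PX)
        donor, acceptor, mask = field["donor"][0], field["acceptor"][0], field["mask"]
        p0 = radial_band_profile(donor, acceptor, mask, UM_PER_PX)
        p90 = radial_band_profile(np.rot90(donor), np.rot90(acceptor),
                                  np.rot90(mask), UM_PER_PX)
        np.testing.assert_allclose(p0.ratio, p90.ratio, rtol=1e-9, equal_nan=True)

    def test_length_scale_recovery(self):
        field = simulate_spatial_field("tumor", image_shape=(300, 300),
                                       length_scale_um=200.0, um_per_px=UM_PER_PX)
        prof = radial_band_profile(field["donor"][0], field["acceptor"][0],
                                   field["mask"], UM_PER_PX, bin_um=20.0)
        centers = (prof.distance_edges_um[:-1] + prof.distance_edges_um[1:]) / 2
        scale, _, _ = fit_length_scale(centers, prof.ratio)
        assert scale == pytest.approx(200.0, rel=0.10)


class TestDensityProfile:
    def test_uniform_nuclei_flat_within_poisson(self):
        field = simulate_spatial_field("tumor", image_shape=(240, 240), n_nuclei=6000,
                                       density_ramp=0.0, seed=6, um_per_px=UM_PER_PX)
        prof = density_profile(field["nuclei_xy"], field["mask"], UM_PER_PX, bin_um=40.0)
        ok = prof["band_area_um2"] > 0
        lam = prof.loc[ok, "count"].to_numpy()
        expected = prof.loc[ok, "band_area_um2"] / field["mask"].sum() / UM_PER_PX ** 2 * 6000
        z = (lam - expected) / np.sqrt(expected)
        assert np.all(np.abs(z) < 4)

    def test_center_only_edge_bins_zero(self):
        h = w = 120
        yy, xx = np.mgrid[0:h, 0:w]
        region = (yy - 60) ** 2 + (xx - 60) ** 2 <= 50 ** 2
        nuclei = np.array([[60.0, 60.0], [61.0, 60.0], [60.0, 61.0]])
        prof = density_profile(nuclei, region, UM_PER_PX, bin_um=20.0)
        assert prof["count"].iloc[0] == 0.0
        assert prof["count"].sum() == 3

    def test_count_conservation(self):
        field = simulate_spatial_field("tumor", image_shape=(200, 200), n_nuclei=1500,
                                       density_ramp=2.0, seed=7, um_per_px=UM_PER_PX)
        prof = density_profile(field["nuclei_xy"], field["mask"], UM_PER_PX, bin_um=30.0)
        total = np.nansum(prof["density_per_um2"] * prof["band_area_um2"])
        assert total == pytest.approx(1500, abs=1e-9)
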