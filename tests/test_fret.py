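"""Segmentation, ratio measurement, tracking, state calls, KS comparison."""
import numpy as np
import pytest
from skimage.draw import disk as skdisk

from metaboscope.fret import (
    classify_state,
    compare_distributions,
    match_labels_iou,
    measure_cell_fret,
    segment_cells,
    track_cells,
)
from metaboscope.scenarios import lineage_scenario
from metaboscope.sim import render_movie, simulate_lineage_cohort
from metaboscope.trace import CellTrace

from oracles import brute_force_ks_statistic


def _disk_frame(*centers, value=100.0, radius=5, shape=(96, 96)):
    img = np.zeros(shape)
    for (y, x) in centers:
        rr, cc = skdisk((y, x), radius, shape=shape)
        img[rr, cc] = value
    return img


class TestSegmentation:
    def test_two_disks_two_labels(self):
        seg = segment_cells(_disk_frame((30, 30), (70, 70)))
        assert seg.max() == 2

    def test_blank_frame_empty_mask(self):
        seg = segment_cells(np.zeros((64, 64)))
        assert seg.max() == 0

    def test_min_area_filter(self):
        img = _disk_frame((30, 30), radius=8)
        img[60, 60] = 100.0  # single-pixel speck
        seg = segment_cells(img, min_area=20)
        assert seg.max() == 1

    def test_raster_order_deterministic(self):
        seg = segment_cells(_disk_frame((70, 20), (20, 70)))
        # the disk whose first pixel comes first in raster order gets label 1
        ys1 = np.nonzero(seg == 1)[0]
        ys2 = np.nonzero(seg == 2)[0]
        assert ys1.min() < ys2.min()

    def test_rendered_cohort_recovered(self):
        scen = lineage_scenario(n_cells=50, rho=0.5, seed=3, duration=30,
                                division_rate=0.0, noise_sd=0.0)
        traces, _ = simulate_lineage_cohort(scen, image_shape=(512, 512))
        donor, _, labels = render_movie(traces, (512, 512), cell_radius=6.0)
        seg = segment_cells(donor[0], min_area=20)
        matches = match_labels_iou(labels[0], seg, min_iou=0.5)
        n_true = len(np.unique(labels[0])) - 1
        assert len(matches) >= 0.95 * n_true


class TestMeasurement:
    def test_uniform_cell_exact_ratio(self):
        mask = np.zeros((32, 32), dtype=np.int32)
        mask[10:20, 10:20] = 1
        donor = np.where(mask, 100.0, 0.0)
        acceptor = np.where(mask, 200.0, 0.0)
        tab = measure_cell_fret(donor, acceptor, mask, background="none")
        assert tab.ratio.iloc[0] == pytest.approx(2.0)

    def test_constant_background_identity(self):
        mask = np.zeros((32, 32), dtype=np.int32)
        mask[10:20, 10:20] = 1
        donor = np.where(mask, 110.0, 10.0)
        acceptor = np.where(mask, 210.0, 10.0)
        tab = measure_cell_fret(donor, acceptor, mask, background="mode")
        assert tab.ratio.iloc[0] == pytest.approx(2.0)

    def test_nonpositive_donor_flagged_not_dropped(self):
        mask = np.zeros((16, 16), dtype=np.int32)
        mask[4:8, 4:8] = 1
        donor = np.full((16, 16), 5.0)
        acceptor = np.full((16, 16), 50.0)
        tab = measure_cell_fret(donor, acceptor, mask, background=10.0)
        assert len(tab) == 1 and not tab.valid.iloc[0] and np.isnan(tab.ratio.iloc[0])

    def test_gain_invariance(self):
        rng = np.random.default_rng(11)
        mask = np.zeros((48, 48), dtype=np.int32)
        mask[5:15, 5:15] = 1
        mask[30:42, 30:42] = 2
        for _ in range(5):
            donor = rng.uniform(50, 150, (48, 48))
            acceptor = rng.uniform(50, 300, (48, 48))
            gain = rng.uniform(0.5, 4.0)
            t1 = measure_cell_fret(donor, acceptor, mask, background="none")
            t2 = measure_cell_fret(gain * donor, gain * acceptor, mask, background="none")
            np.testing.assert_allclose(t1.ratio, t2.ratio, rtol=1e-12)

    def test_noise_free_render_roundtrip_machine_precision(self):
        tr = CellTrace(cell_id=1, times=[0.0, 1.0], ratio=[1.85, 1.85],
                       xy=[[24.0, 24.0]] * 2)
        donor, acceptor, labels = render_movie([tr], (48, 48))
        tab = measure_cell_fret(donor[0], acceptor[0], labels[0].astype(np.int32))
        assert tab.ratio.iloc[0] == pytest.approx(1.85, abs=1e-12)

    def test_poisson_noise_within_three_se(self):
        # ratio-of-means SE via first-order error propagation on Poisson counts
        level, true_ratio = 1000.0, 2.0
        tr = CellTrace(cell_id=1, times=[0.0, 1.0], ratio=[true_ratio] * 2,
                       xy=[[24.0, 24.0]] * 2)
        rng = np.random.default_rng(5)
        donor, acceptor, labels = render_movie([tr], (48, 48), donor_level=level,
                                               poisson_noise=True, rng=rng)
        tab = measure_cell_fret(donor[0], acceptor[0], labels[0].astype(np.int32),
                                background="none")
        n_px = (labels[0] == 1).sum()
        se = true_ratio * np.sqrt(1 / (level * n_px) + 1 / (level * true_ratio * n_px))
        assert abs(tab.ratio.iloc[0] - true_ratio) < 3 * se


class TestTracking:
    def test_single_stationary_cell(self):
        frame = np.zeros((40, 40), dtype=np.uint16)
        rr, cc = skdisk((20, 20), 5)
        frame[rr, cc] = 1
        tracks = track_cells(np.stack([frame] * 10))
        assert len(tracks) == 1 and len(tracks[0].frames) == 10

    def test_division_one_to_two(self):
        def frame_with(*disks):
            m = np.zeros((80, 80), np.uint16)
            for i, (y, x) in enumerate(disks, start=1):
                rr, cc = skdisk((y, x), 5, shape=(80, 80))
                m[rr, cc] = i
            return m

        masks = np.stack([frame_with((40, 40))] * 5 + [frame_with((32, 40), (48, 40))] * 5)
        tracks = track_cells(masks, max_distance=15)
        parents = [t for t in tracks if t.parent_id is None]
        children = [t for t in tracks if t.parent_id is not None]
        assert len(parents) == 1 and len(children) == 2
        assert all(c.parent_id == parents[0].track_id for c in children)

    def test_cohort_links_against_truth(self):
        scen = lineage_scenario(n_cells=50, rho=0.5, seed=4, duration=100,
                                division_rate=0.0, noise_sd=0.0).model_copy(
                                    update={"motion_sd": 1.0})
        traces, _ = simulate_lineage_cohort(scen, image_shape=(512, 512))
        _, _, label_stack = render_movie(traces, (512, 512), cell_radius=6.0)
        tracks = track_cells(label_stack, max_distance=10.0)
        # a link is correct when consecutive frames carry the same true label
        total = sum(len(t.labels) - 1 for t in tracks)
        correct = sum(1 for t in tracks for i in range(1, len(t.labels))
                      if t.labels[i] == t.labels[0])
        assert correct / total >= 0.98


class TestStateClassification:
    def test_octet_quartiles(self):
        calls = classify_state(np.arange(1.0, 9.0))
        assert list(calls.label) == ["low", "low", "mid", "mid", "mid", "mid", "high", "high"]

    def test_constant_population_all_mid(self):
        with pytest.warns(UserWarning):
            calls = classify_state(np.full(12, 2.0))
        assert (calls.label == "mid").all()

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            classify_state(np.arange(5.0))

    def test_bimodal_recovery_jaccard(self):
        rng = np.random.default_rng(8)
        n = 200
        high = rng.random(n) < 0.25
        ratios = np.where(high, rng.normal(2.6, 0.08, n), rng.normal(1.8, 0.08, n))
        calls = classify_state(ratios)
        called_high = set(calls.cell_id[calls.label == "high"])
        true_high = set(np.flatnonzero(high) + 1)
        jac = len(called_high & true_high) / len(called_high | true_high)
        assert jac >= 0.8


class TestKsComparison:
    def test_identical_samples(self):
        x = np.arange(10.0)
        d, p = compare_distributions(x, x)
        assert d == 0.0 and p == 1.0

    def test_disjoint_samples(self):
        d, _ = compare_distributions(np.zeros(3), np.ones(3))
        assert d == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions(np.array([]), np.ones(3))

    def test_statistic_matches_brute_force_ecdf(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            a = rng.normal(size=rng.integers(5, 40))
            b = rng.normal(0.5, 1.2, size=rng.integers(5, 40))
            d, _ = compare_distributions(a, b)
            assert d == pytest.approx(brute_force_ks_statistic(a, b), abs=1e-12)

    def test_power_matches_monte_carlo_oracle(self):
        # oracle: critical D from 1000 null sims of the brute-force statistic
        rng = np.random.default_rng(17)
        n, sims = 100, 1000
        null_d = np.empty(sims)
        for i in range(sims):
            null_d[i] = brute_force_ks_statistic(rng.normal(size=n), rng.normal(size=n))
        crit = np.quantile(null_d, 0.95)
        rej_oracle = rej_impl = 0
        for i in range(sims):
            a, b = rng.normal(size=n), rng.normal(1.0, 1.0, size=n)
            rej_oracle += brute_force_ks_statistic(a, b) > crit
            _, p = compare_distributions(a, b)
            rej_impl += p < 0.05
        assert abs(rej_impl / sims - rej_oracle / sims) <= 0.03
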