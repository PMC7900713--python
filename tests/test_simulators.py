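"""Generator behavior: floors, monotonicity, determinism, closed forms."""
import numpy as np
import pytest
from scipy.stats import pearsonr

from metaboscope.config import BiosensorModel, ScenarioConfig, default_dose_schedule
from metaboscope.scenarios import lineage_scenario, washout_washin_scenario
from metaboscope.sim import (
    render_movie,
    simulate_cell_trace,
    simulate_dose_cohort,
    simulate_lineage_cohort,
    simulate_mid,
    simulate_spatial_field,
    simulate_tcspc_pixel,
)
from metaboscope.sim.tcspc import delta_irf, gaussian_irf
from metaboscope.sim.traces import CellParams


class TestCellTraceSimulation:
    def test_no_substrate_sensor_at_floor(self, biosensor):
        scen = ScenarioConfig(n_cells=1, duration=60, frame_interval=1,
                              glucose_media_schedule=[(0.0, 0.0)], noise_sd=0.0)
        tr = simulate_cell_trace(scen, biosensor, CellParams(1, vup=0.3, vcon=0.2, g0=0.0))
        assert np.allclose(tr.ratio, biosensor.r_min)

    def test_pure_consumption_strictly_decreasing(self, biosensor):
        scen = ScenarioConfig(n_cells=1, duration=60, frame_interval=1,
                              glucose_media_schedule=[(0.0, 0.0)], noise_sd=0.0)
        tr = simulate_cell_trace(scen, biosensor, CellParams(1, vup=0.0, vcon=0.3, g0=1.5))
        assert np.all(np.diff(tr.ratio) < 0)

    def test_negative_rates_rejected(self, biosensor):
        scen = washout_washin_scenario(n_cells=1)
        with pytest.raises(ValueError):
            simulate_cell_trace(scen, biosensor, CellParams(1, vup=-0.1, vcon=0.2, g0=1.0))

    def test_unsorted_schedule_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_cells=1, duration=60, frame_interval=1,
                           glucose_media_schedule=[(10.0, 0.0), (5.0, 25.0)])

    def test_trace_length(self, biosensor):
        scen = washout_washin_scenario(n_cells=1, frame_interval=0.5, duration=70)
        tr = simulate_cell_trace(scen, biosensor, CellParams(1, vup=0.1, vcon=0.3, g0=0.5))
        assert len(tr) == int(70 / 0.5) + 1

    def test_deterministic_given_seed(self, biosensor):
        scen = washout_washin_scenario(n_cells=1, noise_sd=0.05, seed=3)
        cell = CellParams(1, vup=0.1, vcon=0.3, g0=0.5)
        a = simulate_cell_trace(scen, biosensor, cell)
        b = simulate_cell_trace(scen, biosensor, cell)
        c = simulate_cell_trace(scen.model_copy(update={"seed": 4}), biosensor, cell)
        assert np.array_equal(a.ratio, b.ratio)
        assert not np.array_equal(a.ratio, c.ratio)


class TestLineageCohort:
    def test_perfect_inheritance(self):
        scen = lineage_scenario(n_cells=10, rho=1.0, noise_sd=0.0, seed=2, duration=1500)
        traces, truth = simulate_lineage_cohort(scen)
        for cid, p in truth.params.items():
            if p.parent_id is not None:
                assert truth.params[cid].state == pytest.approx(truth.params[p.parent_id].state)

    def test_zero_heritability_null_correlation(self):
        scen = lineage_scenario(n_cells=40, rho=0.0, noise_sd=0.0, seed=5)
        _, truth = simulate_lineage_cohort(scen)
        pairs = [(truth.params[p].state, truth.params[c].state)
                 for p, c in truth.tree.edges]
        assert len(pairs) >= 500
        a, b = np.array(pairs).T
        r = pearsonr(a[:500], b[:500]).statistic
        assert abs(r) < 1.96 / np.sqrt(500)

    def test_no_divisions_full_span_no_edges(self):
        scen = lineage_scenario(n_cells=15, division_rate=0.0, seed=1, duration=500)
        traces, truth = simulate_lineage_cohort(scen)
        assert len(traces) == 15
        assert truth.tree.number_of_edges() == 0
        for tr in traces:
            assert tr.times[0] == 0.0 and tr.times[-1] == 500.0


class TestRenderMovie:
    def test_single_cell_exact_ratio(self):
        from metaboscope.trace import CellTrace
        tr = CellTrace(cell_id=1, times=[0.0, 1.0], ratio=[2.0, 2.0],
                       xy=[[32.0, 32.0], [32.0, 32.0]])
        donor, acceptor, labels = render_movie([tr], (64, 64), cell_radius=6, donor_level=100)
        m = labels[0] == 1
        assert m.sum() > 0
        assert acceptor[0][m].mean() / donor[0][m].mean() == pytest.approx(2.0)

    def test_empty_trace_set(self):
        donor, acceptor, labels = render_movie([], (32, 32))
        assert donor.sum() == 0 and labels.sum() == 0

    def test_overlap_higher_id_wins(self):
        from metaboscope.trace import CellTrace
        trs = [CellTrace(cell_id=i, times=[0.0, 1.0], ratio=[2.0, 2.0],
                         xy=[[30.0 + i, 30.0]] * 2) for i in (1, 2)]
        _, _, labels = render_movie(trs, (64, 64), cell_radius=6)
        # the shared pixels belong to cell 2
        assert labels[0][30, 31] == 2

    def test_tiff_roundtrip_bitexact(self, tmp_path):
        from metaboscope import io as mio
        from metaboscope.trace import CellTrace
        tr = CellTrace(cell_id=1, times=[0.0, 1.0], ratio=[1.7, 1.9],
                       xy=[[20.0, 20.0], [21.0, 20.0]])
        donor, acceptor, labels = render_movie([tr], (48, 48))
        for arr in (donor, acceptor, labels):
            mio.write_stack(tmp_path / "x.tif", arr)
            back = mio.read_stack(tmp_path / "x.tif")
            assert np.array_equal(back, arr)


class TestDoseCohortGeneration:
    def test_strong_only_all_below_control_median(self):
        sched = default_dose_schedule()
        treated, control, _ = simulate_dose_cohort(
            sched, mix=(0.0, 0.0, 1.0), refractory_fraction=0.0,
            n_cells=100, n_control=100, seed=2)
        med = np.median([tr.ratio[-1] for tr in control])
        assert all(tr.ratio[-1] < med for tr in treated)

    def test_all_refractory_all_flagged(self):
        from metaboscope.dose import analyze_dose_cohort
        sched = default_dose_schedule()
        treated, control, _ = simulate_dose_cohort(
            sched, refractory_fraction=1.0, n_cells=80, n_control=100, seed=3)
        df = analyze_dose_cohort(treated, control, sched)
        assert df["refractory"].all()

    def test_empty_schedule_rejected(self):
        from metaboscope.config import DoseSchedule
        with pytest.raises(ValueError):
            DoseSchedule(steps=[])


class TestSpatialFieldGeneration:
    def test_infinite_scale_flat(self):
        f = simulate_spatial_field("scratch", image_shape=(120, 120),
                                   length_scale_um=1e9, noise_sd=0.0)
        ratio = f["acceptor"][0][f["mask"]] / f["donor"][0][f["mask"]]
        assert ratio.max() - ratio.min() < 1e-6

    def test_tumor_density_ramp_sign(self):
        f = simulate_spatial_field("tumor", image_shape=(200, 200), n_nuclei=4000,
                                   density_ramp=3.0, seed=4)
        from metaboscope.spatial import density_profile
        prof = density_profile(f["nuclei_xy"], f["mask"], um_per_px=2.0, bin_um=40.0)
        d = prof["density_per_um2"].to_numpy()
        d = d[np.isfinite(d)]
        slope = np.polyfit(np.arange(len(d)), d, 1)[0]
        assert slope > 0  # density increases toward the center


class TestTcspcSimulation:
    def test_mono_exponential_delta_irf_exact(self):
        n, bw = 128, 0.05
        h = simulate_tcspc_pixel([2.0, 3.0], [1.0, 0.0], delta_irf(n), 1e4, n, bw,
                                 poisson=False)
        t = (np.arange(n) + 0.5) * bw
        expected = np.exp(-t / 2.0)
        np.testing.assert_allclose(h / h[0], expected / expected[0], rtol=1e-10)

    def test_total_counts_poisson_sum(self):
        n, bw = 256, 11.1 / 256
        irf = gaussian_irf(n, bw, 1.0, 0.2)
        h = simulate_tcspc_pixel([1.5, 3.0], [0.7, 0.3], irf, 10_000, n, bw,
                                 rng=np.random.default_rng(7))
        assert abs(h.sum() - 10_000) <= 3 * np.sqrt(10_000)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            simulate_tcspc_pixel([2.0, 3.0], [0.5, 0.5], delta_irf(16), 100, 16, 0.0)


class TestMidSimulation:
    def test_unlabeled_no_abundance(self):
        mid = simulate_mid(4, labeled_fraction=0.0, nat_abund=0.0, seed=0)
        assert np.array_equal(mid, [1, 0, 0, 0, 0])

    def test_natural_abundance_m1_closed_form(self):
        q = 0.0107
        mid = simulate_mid(3, 0.0, nat_abund=q, n_molecules=2_000_000, seed=1)
        expected_m1 = 3 * q * (1 - q) ** 2
        assert mid[1] == pytest.approx(expected_m1, rel=0.02)

    def test_half_labeled_fraction(self):
        mid = simulate_mid(3, 0.5, nat_abund=0.0, n_molecules=500_000, seed=2)
        assert 1 - mid[0] == pytest.approx(1 - 0.5 ** 3, abs=0.005)
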