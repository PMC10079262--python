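"""Random-walk simulators and MSD model fitting."""

import numpy as np
import pytest
from scipy import stats

import celltracks as ct
from celltracks import Track, TracksDataset
from celltracks.simulate import (
    BeaucheminParams,
    BrownianParams,
    beauchemin_msd_asymptote,
    beauchemin_track,
    bootstrap_track,
    brownian_track,
    fit_msd,
    replicate_dataset,
)


class TestBrownian:
    def test_pure_drift_is_straight_with_exact_speed(self):
        p = BrownianParams(n_steps=20, dim=2, delta_t=0.5, step_sd=0.0,
                           drift=(3.0, 4.0))
        tr = brownian_track(p)
        assert np.isclose(ct.speed(tr), 5.0 / 0.5)
        assert np.isclose(ct.straightness(tr), 1.0)

    def test_seed_contract(self):
        p = BrownianParams(n_steps=50, dim=3, seed=5)
        assert brownian_track(p) == brownian_track(p)
        other = brownian_track(BrownianParams(n_steps=50, dim=3, seed=6))
        assert not np.array_equal(brownian_track(p).positions, other.positions)

    def test_increment_moments(self):
        sd = 2.0
        tr = brownian_track(BrownianParams(n_steps=20_000, dim=2, step_sd=sd,
                                           seed=3))
        inc = tr.steps()
        se_mean = sd / np.sqrt(len(inc))
        assert np.all(np.abs(inc.mean(axis=0)) < 3 * se_mean)
        # var of sample variance ~ 2 sd^4 / n
        se_var = sd**2 * np.sqrt(2 / len(inc))
        assert np.all(np.abs(inc.var(axis=0, ddof=1) - sd**2) < 3 * se_var)
        offdiag = np.cov(inc, rowvar=False)[0, 1]
        assert abs(offdiag) < 3 * sd**2 / np.sqrt(len(inc))

    def test_track_invariants_hold(self):
        tr = brownian_track(BrownianParams(n_steps=10, dim=2, delta_t=0.25))
        assert np.allclose(tr.step_durations(), 0.25)
        assert tr.n_steps == 10

    def test_param_validation(self):
        with pytest.raises(ValueError):
            BrownianParams(n_steps=0)
        with pytest.raises(ValueError):
            BrownianParams(n_steps=5, step_sd=-1)


class TestBootstrap:
    def test_straight_reference_gives_straight_track(self, straight_track):
        ref = TracksDataset([straight_track])
        out = bootstrap_track(30, ref, seed=4)
        assert np.isclose(ct.straightness(out), 1.0)
        assert np.allclose(np.linalg.norm(out.steps(), axis=1), 2.0)
        assert np.allclose(out.step_durations(), 1.0)

    def test_step_length_distribution_matches(self):
        ref = replicate_dataset(
            brownian_track, BrownianParams(n_steps=300, dim=2), 5, seed=8
        )
        out = bootstrap_track(10_000, ref, seed=9)
        ref_lengths = np.concatenate(
            [np.linalg.norm(tr.steps(), axis=1) for tr in ref.tracks()]
        )
        sim_lengths = np.linalg.norm(out.steps(), axis=1)
        ks = stats.ks_2samp(ref_lengths, sim_lengths)
        assert ks.pvalue > 0.01
        rel = abs(sim_lengths.mean() - ref_lengths.mean()) / ref_lengths.mean()
        assert rel < 0.05

    @pytest.mark.parametrize("dim", [2, 3])
    def test_turning_angle_mean_preserved(self, dim):
        ref = replicate_dataset(
            brownian_track, BrownianParams(n_steps=300, dim=dim), 5, seed=10
        )
        out = bootstrap_track(5000, ref, seed=11)
        ref_angs = np.concatenate([ct.turning_angles(tr) for tr in ref.tracks()])
        sim_angs = ct.turning_angles(out)
        se = np.sqrt(np.nanvar(sim_angs) / np.isfinite(sim_angs).sum()
                     + np.nanvar(ref_angs) / np.isfinite(ref_angs).sum())
        assert abs(np.nanmean(sim_angs) - np.nanmean(ref_angs)) < 3 * se

    def test_degenerate_reference_rejected(self):
        frozen = TracksDataset([
            Track("f", range(4), np.tile([1.0, 1.0], (4, 1)))
        ])
        with pytest.raises(ValueError):
            bootstrap_track(10, frozen)


class TestBeauchemin:
    def test_phase_aligned_steps_exact(self):
        p = BeaucheminParams(total_time=40, delta_t=2.0, v_free=10.0,
                             t_free=2.0, t_pause=0.0, dim=3, seed=1,
                             stationary=False)
        tr = beauchemin_track(p)
        assert np.allclose(np.linalg.norm(tr.steps(), axis=1), 20.0)

    def test_turning_angles_isotropic(self):
        p = BeaucheminParams(total_time=40, delta_t=2.0, v_free=10.0,
                             t_free=2.0, t_pause=0.0, dim=3, stationary=False)
        ds = replicate_dataset(beauchemin_track, p, 300, seed=6)
        angs = np.concatenate([ct.turning_angles(tr) for tr in ds.tracks()])
        angs = angs[~np.isnan(angs)]
        se = angs.std(ddof=1) / np.sqrt(angs.size)
        assert abs(angs.mean() - 90.0) < 3 * se

    def test_small_delta_t_no_pause_approaches_free_speed(self):
        p = BeaucheminParams(total_time=50, delta_t=0.01, v_free=15.0,
                             t_free=2.0, t_pause=0.0, dim=3, seed=2)
        tr = beauchemin_track(p)
        # steps straddling a turn (fraction delta_t / t_free) are slightly
        # shortened, so observed speed converges at that rate
        assert np.isclose(ct.speed(tr), 15.0, rtol=5 * 0.01 / 2.0)

    def test_seed_determinism(self):
        p = BeaucheminParams(total_time=30, seed=9)
        assert beauchemin_track(p) == beauchemin_track(p)

    def test_pause_keeps_cell_stationary(self):
        p = BeaucheminParams(total_time=50, delta_t=0.1, v_free=10.0,
                             t_free=1.0, t_pause=2.0, dim=2, seed=3,
                             stationary=False)
        tr = beauchemin_track(p)
        speeds = np.linalg.norm(tr.steps(), axis=1) / 0.1
        # two-thirds of the time is pause: many exactly-zero observed speeds
        assert (speeds < 1e-9).mean() > 0.5

    def test_bias_requires_direction(self):
        with pytest.raises(ValueError):
            BeaucheminParams(p_bias=0.5)

    def test_biased_walk_detected_unbiased_calibrated(self):
        biased = BeaucheminParams(total_time=60, delta_t=1.0, dim=2,
                                  bias_dir=(1.0, -1.0), p_bias=0.6)
        ds = replicate_dataset(beauchemin_track, biased, 30, seed=14)
        assert ct.hotellings_test(ds).p_value < 1e-4
        null = BeaucheminParams(total_time=60, delta_t=1.0, dim=2)
        # moderate check at test scale; full calibration in acceptance
        rejections = 0
        for rep in range(40):
            ds0 = replicate_dataset(beauchemin_track, null, 10,
                                    seed=1000 + rep)
            rejections += ct.hotellings_test(ds0, step_spacing=4).p_value < 0.05
        assert rejections <= 6

    def test_long_run_msd_slope(self):
        p = BeaucheminParams(total_time=2500, delta_t=2.5, dim=3, seed=0)
        ds = replicate_dataset(beauchemin_track, p, 60, seed=7)
        curve = ct.aggregate(ds, "square_displacement",
                             lags=[20, 40, 60, 80, 100])
        x = curve.table["lag_time"].to_numpy()
        y = curve.table["mean"].to_numpy()
        slope = np.polyfit(x, y, 1)[0]
        expected, _ = beauchemin_msd_asymptote(p)
        assert abs(slope / expected - 1) < 0.10


class TestReplicates:
    def test_reproducible_and_distinct(self):
        p = BrownianParams(n_steps=10, dim=2)
        d1 = replicate_dataset(brownian_track, p, 5, seed=3)
        d2 = replicate_dataset(brownian_track, p, 5, seed=3)
        assert d1 == d2
        tracks = list(d1.tracks())
        assert not np.array_equal(tracks[0].positions, tracks[1].positions)


class TestFitMSD:
    def _brownian_curve(self, sd=1.2, dim=2, seed=11):
        ds = replicate_dataset(
            brownian_track,
            BrownianParams(n_steps=5000, dim=dim, step_sd=sd), 4, seed=seed,
        )
        return ct.aggregate(ds, "square_displacement", lags=range(1, 21))

    def test_brownian_slope_recovery(self):
        sd = 1.2
        curve = self._brownian_curve(sd)
        fit = fit_msd(curve, "brownian")
        assert abs(fit.params["slope"] / (2 * sd**2) - 1) < 0.05

    def test_model_mismatch_visible(self, straight_track):
        pos = np.column_stack([2.0 * np.arange(50), np.zeros(50)])
        ds = TracksDataset([Track("s", np.arange(50.0), pos)])
        curve = ct.aggregate(ds, "square_displacement", lags=range(1, 11))
        fit = fit_msd(curve, "brownian")
        assert fit.objective > 1e3  # quadratic truth vs linear model

    def test_beauchemin_vfree_recovery(self):
        truth = BeaucheminParams(total_time=120, delta_t=0.5, dim=3)
        data = replicate_dataset(beauchemin_track, truth, 100, seed=21)
        curve = ct.aggregate(data, "square_displacement", lags=range(1, 31))
        start = BeaucheminParams(total_time=120, delta_t=0.5, dim=3,
                                 v_free=12.0)
        fit = fit_msd(curve, "beauchemin", max_fit_lag=20, base_params=start,
                      n_sim=50, seed=9)
        assert abs(fit.params["v_free"] / truth.v_free - 1) < 0.10

    def test_beauchemin_beats_brownian_on_beauchemin_data(self):
        truth = BeaucheminParams(total_time=120, delta_t=0.5, dim=3)
        data = replicate_dataset(beauchemin_track, truth, 60, seed=33)
        curve = ct.aggregate(data, "square_displacement", lags=range(1, 21))
        fb = fit_msd(curve, "brownian", max_fit_lag=20)
        fbe = fit_msd(curve, "beauchemin", max_fit_lag=20,
                      base_params=BeaucheminParams(total_time=120,
                                                   delta_t=0.5, dim=3,
                                                   v_free=10.0),
                      n_sim=40, seed=5)
        assert fbe.objective < fb.objective

    def test_nelder_mead_path_two_free_params(self):
        truth = BeaucheminParams(total_time=60, delta_t=0.5, dim=2,
                                 v_free=15.0, t_free=1.5)
        data = replicate_dataset(beauchemin_track, truth, 40, seed=41)
        curve = ct.aggregate(data, "square_displacement", lags=range(1, 16))
        start = BeaucheminParams(total_time=60, delta_t=0.5, dim=2,
                                 v_free=10.0, t_free=1.0)
        fit = fit_msd(curve, "beauchemin", fit_params=("v_free", "t_free"),
                      base_params=start, n_sim=20, seed=6)
        assert fit.objective >= 0
        assert 5.0 < fit.params["v_free"] < 30.0

    def test_closed_form_option(self):
        truth = BeaucheminParams(total_time=1000, delta_t=5.0, dim=3)
        data = replicate_dataset(beauchemin_track, truth, 50, seed=51)
        curve = ct.aggregate(data, "square_displacement", lags=range(1, 31))
        start = BeaucheminParams(total_time=1000, delta_t=5.0, dim=3,
                                 v_free=12.0)
        fit = fit_msd(curve, "beauchemin", method="closed_form",
                      base_params=start, seed=1)
        # asymptotic form: looser recovery, long lags only
        assert abs(fit.params["v_free"] / truth.v_free - 1) < 0.15

    def test_max_fit_lag_validation(self):
        curve = self._brownian_curve()
        with pytest.raises(ValueError, match="usable lags"):
            fit_msd(curve, "brownian", max_fit_lag=0)

    def test_inverse_variance_weights(self):
        curve = self._brownian_curve()
        fit = fit_msd(curve, "brownian", weights="inverse_variance")
        assert abs(fit.params["slope"] / (2 * 1.2**2) - 1) < 0.05
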