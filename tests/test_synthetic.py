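import datetime as dt
import filecmp

import numpy as np
import pytest

from locotrack.config import GapModel, Priors, RoundSpec, SimConfig
from locotrack.descriptors import classes_from_switch_minutes, default_entropy_r, sample_entropy
from locotrack.kinematics import daily_average_distance, daily_distance
from locotrack.rfid_io import find_group_gaps, parse_rfid_log
from locotrack.synthetic import (
    BirdParams,
    SimulationError,
    generate_dataset,
    sample_bird_parameters,
    simulate_daily_activity_targets,
    simulate_day_switch_minutes,
    simulate_rfid_day,
    simulate_weights,
)

from conftest import make_stream


def _params(**kw):
    base = dict(bird_id="b1", round_id=1, a=24.0, b=-0.5, sigma=2.0, rho=0.3,
                reg=0.5, w0=42.0, adg_true=77.0)
    base.update(kw)
    return BirdParams(**base)


def _one_round_config(n_birds=4, seed=0, **kw):
    rounds = (RoundSpec(1, 1, 35, n_birds, dt.date(2021, 3, 1)),)
    return SimConfig(rounds=rounds, seed=seed, **kw)


class TestBirdParameterSampling:
    def test_seeded_determinism(self):
        cfg = _one_round_config(n_birds=20, seed=3)
        assert sample_bird_parameters(cfg) == sample_bird_parameters(cfg)

    def test_degenerate_sigma_prior(self):
        priors = Priors(sigma_log_mean=float(np.log(2.0)), sigma_log_sd=0.0)
        params = sample_bird_parameters(_one_round_config(n_birds=10), priors)
        assert all(p.sigma == pytest.approx(2.0) for p in params)

    def test_sample_mean_within_3se_of_prior_mean(self):
        priors = Priors()
        params = sample_bird_parameters(_one_round_config(n_birds=1000, seed=5), priors)
        a = np.array([p.a for p in params])
        se = priors.a_sd / np.sqrt(a.size)
        assert abs(a.mean() - priors.a_mean) < 3 * se

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            Priors(rho_bound=1.0)
        with pytest.raises(ValueError):
            Priors(adg_noise_sd=-1.0)

    def test_parameter_invariants_enforced(self):
        with pytest.raises(ValueError):
            _params(sigma=-1.0)
        with pytest.raises(ValueError):
            _params(rho=1.0)


class TestDailyTargets:
    def test_noise_free_targets_on_trend_line(self):
        p = _params(sigma=0.0)
        days = np.arange(1, 16)
        t = simulate_daily_activity_targets(p, days, np.random.default_rng(0))
        assert np.allclose(t, np.maximum(0.0, 24.0 - 0.5 * days))

    def test_truncation_at_zero(self):
        p = _params(a=1.0, b=-0.5, sigma=0.0)
        t = simulate_daily_activity_targets(p, np.arange(1, 16), np.random.default_rng(0))
        assert (t >= 0).all() and t[-1] == 0.0

    @pytest.mark.parametrize("rho,tol", [(0.0, 0.01), (0.6, 0.02)])
    def test_ar1_lag1_autocorrelation(self, rho, tol):
        # large a, zero slope: no truncation, so target - a recovers eps
        p = _params(a=1000.0, b=0.0, sigma=1.0, rho=rho)
        t = simulate_daily_activity_targets(p, np.arange(100_000), np.random.default_rng(8))
        eps = t - 1000.0
        ac = np.corrcoef(eps[:-1], eps[1:])[0, 1]
        assert abs(ac - rho) < tol

    def test_marginal_sd_is_sigma(self):
        p = _params(a=1000.0, b=0.0, sigma=2.0, rho=0.6)
        t = simulate_daily_activity_targets(p, np.arange(100_000), np.random.default_rng(9))
        assert abs(np.std(t - 1000.0) - 2.0) < 0.05

    def test_empty_days_rejected(self):
        with pytest.raises(ValueError):
            simulate_daily_activity_targets(_params(), [], np.random.default_rng(0))


class TestRfidDay:
    def test_zero_target_stays_on_one_antenna(self, grid, schedule):
        times, ants = simulate_rfid_day(0.0, 0.5, grid, schedule, np.random.default_rng(0))
        assert np.unique(ants).size == 1
        s = make_stream(times, ants)
        assert daily_distance(s, grid) == 0.0

    def test_round_trip_dadm_within_ten_percent(self, grid, schedule):
        rng = np.random.default_rng(1)
        times, ants = simulate_rfid_day(20.0, 0.5, grid, schedule, rng)
        keep = (times >= 25_200) & (times < 82_800)
        s = make_stream(times[keep], ants[keep])
        dadm = daily_average_distance(daily_distance(s, grid), 57_600)
        assert 18.0 <= dadm <= 22.0

    def test_round_trip_calibration_across_target_range(self, grid, schedule):
        rng = np.random.default_rng(2)
        rel_err = []
        for target in np.linspace(2, 40, 20):
            for _ in range(3):
                times, ants = simulate_rfid_day(float(target), 0.5, grid, schedule, rng)
                keep = (times >= 25_200) & (times < 82_800)
                s = make_stream(times[keep], ants[keep])
                dadm = daily_average_distance(daily_distance(s, grid), 57_600)
                rel_err.append(abs(dadm - target) / target)
        assert np.quantile(rel_err, 0.95) <= 0.10

    def test_full_and_sparse_modes_agree_on_distance(self, grid, schedule):
        t_full, a_full = simulate_rfid_day(15.0, 0.5, grid, schedule,
                                           np.random.default_rng(7), mode="full")
        t_sp, a_sp = simulate_rfid_day(15.0, 0.5, grid, schedule,
                                       np.random.default_rng(7), mode="sparse")
        def dist(t, a):
            keep = (t >= 25_200) & (t < 82_800)
            return daily_distance(make_stream(t[keep], a[keep]), grid)
        assert t_full.size == 86_400
        assert dist(t_full, a_full) == pytest.approx(dist(t_sp, a_sp))

    def test_impossible_target_raises(self, grid, schedule):
        with pytest.raises(SimulationError):
            simulate_rfid_day(5000.0, 0.5, grid, schedule, np.random.default_rng(0))

    def test_movement_suppressed_in_dark(self, grid, schedule):
        rng = np.random.default_rng(3)
        n_dark, n_light = 0, 0
        for _ in range(5):
            times, ants = simulate_rfid_day(30.0, 0.5, grid, schedule, rng)
            switch = ants[1:] != ants[:-1]
            ts = times[1:][switch]
            dark = np.array([schedule.is_dark(int(t)) for t in ts])
            n_dark += int(dark.sum())
            n_light += int((~dark).sum())
        # dark spans 6 h vs 18 h lit; at equal rates ~1/3 of switches
        # would be dark - the damping factor keeps it far below that
        assert n_dark < 0.05 * n_light

    def test_regularity_lowers_daily_entropy(self, grid, schedule):
        rng = np.random.default_rng(4)
        means = []
        for reg in (0.95, 0.5, 0.05):
            vals = []
            for _ in range(200):
                flags = simulate_day_switch_minutes(20.0, reg, grid, schedule, rng)
                cls = classes_from_switch_minutes(flags).classes
                se = sample_entropy(cls, m=2, r=default_entropy_r(cls))
                if np.isfinite(se):
                    vals.append(se)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestWeights:
    def test_beta_rmse_zero_gives_identical_adg(self):
        priors = Priors(beta_rmse=0.0, adg_noise_sd=0.0,
                        w0_sd=0.0)  # only sigma varies between birds
        params = sample_bird_parameters(_one_round_config(n_birds=10, seed=2), priors)
        assert len({p.adg_true for p in params}) == 1

    def test_end_weight_arithmetic(self):
        p = _params(w0=40.0, adg_true=70.0)
        table, adg = simulate_weights(p, [0, 35])
        # 40 + 70*35 = 2490, already on the 5 g grid
        assert table.loc[table["age_days"] == 35, "weight_g"].item() == 2490.0
        assert adg == 70.0

    def test_rounding_precisions(self):
        p = _params(w0=41.4, adg_true=70.3)
        table, _ = simulate_weights(p, [0, 7, 35])
        w = dict(zip(table["age_days"], table["weight_g"]))
        assert w[0] == 41.0            # start weight to 1 g
        assert w[7] % 5 == 0 and w[35] % 5 == 0   # later weights to 5 g

    def test_negative_weight_raises(self):
        with pytest.raises(SimulationError):
            simulate_weights(_params(w0=40.0, adg_true=-10.0), [0, 35])

    def test_regression_recovers_generating_slope(self):
        priors = Priors(beta_rmse=-1.0, adg_noise_sd=5.0)
        params = sample_bird_parameters(_one_round_config(n_birds=500, seed=6), priors)
        sigma = np.array([p.sigma for p in params])
        w0 = np.array([p.w0 for p in params])
        adg = np.array([p.adg_true for p in params])
        # OLS of ADG on sigma and start weight jointly
        X = np.column_stack([np.ones_like(sigma), sigma, w0])
        beta = np.linalg.lstsq(X, adg, rcond=None)[0]
        assert -1.2 < beta[1] < -0.8


class TestGenerateDataset:
    def test_zero_gap_rate_leaves_no_detectable_gaps(self, small_dataset):
        for df in small_dataset["rfid"].values():
            # heartbeats keep group silence far below the 300 s threshold,
            # so the only detectable gaps are the two scripted ~1 h
            # handling windows (weigh days at ages 8 and 15)
            wins = find_group_gaps(df, threshold_s=300.0)
            assert len(wins) == 2
            assert all(3600 <= w.duration_s < 3700 for w in wins)

    def test_bird_day_bookkeeping(self, small_sim_config, small_dataset):
        cfg = small_sim_config
        for r in cfg.rounds:
            df = small_dataset["rfid"][r.round_id]
            n_days = min(r.end_age, cfg.rfid_max_age) - r.start_age + 1
            per_bird = df.groupby("tag_id")["time"].apply(lambda t: t.dt.date.nunique())
            assert (per_bird == n_days).all()
            assert per_bird.size == r.n_birds

    def test_same_seed_fixtures_byte_identical(self, tmp_path):
        rounds = (RoundSpec(1, 1, 16, 2, dt.date(2021, 3, 1)),)
        cfg = SimConfig(rounds=rounds, seed=42, rfid_max_age=3)
        generate_dataset(cfg, Priors(), outdir=tmp_path / "a")
        generate_dataset(cfg, Priors(), outdir=tmp_path / "b")
        for name in ["rfid_round1.csv", "weights.csv", "sim_truth.csv", "rounds.yaml"]:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_fixture_reread_by_parser(self, tmp_path):
        rounds = (RoundSpec(1, 1, 16, 2, dt.date(2021, 3, 1)),)
        cfg = SimConfig(rounds=rounds, seed=42, rfid_max_age=3,
                        gap_model=GapModel(rate_per_day=0.0))
        res = generate_dataset(cfg, Priors(), outdir=tmp_path)
        df = parse_rfid_log(tmp_path / "rfid_round1.csv", known_antennas=range(1, 31))
        assert len(df) == len(res["rfid"][1])
        assert df.groupby("tag_id")["time"].apply(lambda t: t.dt.date.nunique()).eq(3).all()
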