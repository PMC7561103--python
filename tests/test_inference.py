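"""Tests for least-squares fitting, the grid oracle and the bootstrap."""

import numpy as np
import pandas as pd
import pytest

from emsafit import (
    FitOptions,
    GridSpec,
    ModelParams,
    Scenario,
    TitrationSeries,
    bootstrap_cis,
    fit_model,
    grid_oracle,
    resample_series,
    residual_vector,
    simulate_series,
    summarize_replicates,
)
from emsafit.inference import (
    BootstrapFailureError,
    UnidentifiableSeriesError,
    _default_starts,
)


def noiseless(params, name="s", ladder=(2.5, 10.0, 40.0, 160.0, 640.0), reps=3,
              seed=0):
    return simulate_series(
        Scenario(name, params, ladder=ladder, n_reps=reps, noise_sd=0.0,
                 seed=seed)
    )


class TestResidualVector:
    def test_noiseless_residuals_vanish(self, wt_params):
        series = noiseless(wt_params)
        res = residual_vector(wt_params, series)
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_length_three_per_lane(self, wt_series):
        assert residual_vector(
            ModelParams(40.0, 5.0, 0.85), wt_series
        ).shape == (45,)

    def test_hand_computed_single_lane(self):
        lanes = pd.DataFrame(
            [(10.0, 1, 50.0, 50.0, 0.0)],
            columns=["conc_nM", "replicate", "band0", "band1", "band2"],
        )
        series = TitrationSeries("one", lanes)
        # alpha = 1 at kd = 10; C=1, f=1 predicts (0.25, 0.5, 0.25)
        res = residual_vector(ModelParams(10.0, 1.0, 1.0), series)
        np.testing.assert_allclose(res, [0.25, 0.0, -0.25], atol=1e-12)


class TestFitModel:
    def test_recovers_truth_noiseless(self, wt_params):
        result = fit_model(noiseless(wt_params))
        assert result.converged
        assert result.params.kd == pytest.approx(wt_params.kd, rel=0.01)
        assert result.params.C == pytest.approx(wt_params.C, rel=0.01)
        assert result.params.f == pytest.approx(wt_params.f, rel=0.01)
        assert result.ssr < 1e-12

    def test_recovers_non_cooperative(self):
        truth = ModelParams(40.0, 1.0, 1.0)
        result = fit_model(noiseless(truth))
        assert 0.99 <= result.params.C <= 1.01

    def test_degenerate_single_concentration(self):
        lanes = pd.DataFrame(
            [(40.0, r, 30.0, 40.0, 30.0) for r in range(1, 4)],
            columns=["conc_nM", "replicate", "band0", "band1", "band2"],
        )
        with pytest.raises(UnidentifiableSeriesError):
            fit_model(TitrationSeries("flat", lanes))

    def test_equal_concentrations_padded_to_three_rows_rejected(self):
        # padding identical lanes to 3 rows does not create 3 distinct
        # concentrations, so the design stays unidentifiable
        lanes = pd.DataFrame(
            [(40.0, r, 30.0, 40.0, 30.0) for r in (1, 2, 3)],
            columns=["conc_nM", "replicate", "band0", "band1", "band2"],
        )
        with pytest.raises(UnidentifiableSeriesError):
            fit_model(TitrationSeries("flat", lanes))

    def test_deterministic(self, wt_series):
        a, b = fit_model(wt_series), fit_model(wt_series)
        assert a == b

    def test_ssr_not_above_truth(self, wt_params, wt_series):
        fitted = fit_model(wt_series)
        at_truth = float(np.sum(residual_vector(wt_params, wt_series) ** 2))
        assert fitted.ssr <= at_truth + 1e-12

    def test_scale_equivariance(self, wt_params):
        series = noiseless(wt_params)
        k = 7.0
        scaled_lanes = series.lanes.copy()
        scaled_lanes["conc_nM"] *= k
        scaled = TitrationSeries("scaled", scaled_lanes)
        a, b = fit_model(series), fit_model(scaled)
        assert b.params.kd == pytest.approx(k * a.params.kd, rel=1e-4)
        assert b.params.C == pytest.approx(a.params.C, rel=1e-4)
        assert b.params.f == pytest.approx(a.params.f, rel=1e-4)

    def test_default_start_grid_shape(self, wt_series):
        starts = _default_starts(wt_series)
        # Kd decades 10^0..10^3 x C {0.1, 1, 10} x f {0.5, 0.9}
        assert len(starts) == 4 * 3 * 2

    def test_replicate_means_option(self, wt_series):
        result = fit_model(wt_series, FitOptions(replicate_means=True))
        assert result.n_points == 15
        assert result.params.C == pytest.approx(5.0, rel=0.25)


class TestGridOracle:
    def test_noiseless_truth_on_grid_gives_zero_ssr(self):
        truth = ModelParams(kd=10.0, C=1.0, f=1.0)
        series = noiseless(truth)
        grid = GridSpec(n_kd=5, n_C=5, n_f=2, log10_kd_range=(0.0, 4.0),
                        log10_C_range=(-2.0, 2.0), f_range=(0.0, 1.0))
        result = grid_oracle(series, grid)
        assert result.ssr == pytest.approx(0.0, abs=1e-20)
        assert result.params.kd == pytest.approx(10.0)

    def test_single_point_grid(self, wt_series):
        grid = GridSpec(n_kd=1, n_C=1, n_f=1, log10_kd_range=(1.0, 1.0),
                        log10_C_range=(0.0, 0.0), f_range=(0.5, 0.5))
        result = grid_oracle(wt_series, grid)
        expected = float(
            np.sum(residual_vector(ModelParams(10.0, 1.0, 0.5), wt_series) ** 2)
        )
        assert result.ssr == pytest.approx(expected)

    def test_empty_grid_rejected(self, wt_series):
        with pytest.raises(ValueError):
            grid_oracle(wt_series, GridSpec(n_kd=0))

    def test_fit_beats_oracle(self, rng):
        # optimizer must reach at least the brute-force grid optimum
        for _ in range(5):
            params = ModelParams(
                kd=float(10 ** rng.uniform(1, 2.2)),
                C=float(rng.choice([1.0, 5.0])),
                f=float(rng.uniform(0.6, 1.0)),
            )
            series = simulate_series(
                Scenario("r", params, noise_sd=0.02,
                         seed=int(rng.integers(2**31)))
            )
            fit = fit_model(series)
            oracle = grid_oracle(series, GridSpec(n_kd=25, n_C=25, n_f=10))
            assert fit.ssr <= oracle.ssr + 1e-9


class TestResampleSeries:
    def test_zero_sd_returns_mean_series(self, noiseless_series):
        summary = summarize_replicates(noiseless_series)
        assert not summary.single_replicate
        resampled = resample_series(summary, noiseless_series, seed=1)
        frac = resampled.lanes[["band0", "band1", "band2"]].to_numpy() / 10_000.0
        target = summary.mean.loc[resampled.lanes["conc_nM"]].to_numpy()
        np.testing.assert_allclose(frac, target, atol=1e-12)
        a = resample_series(summary, noiseless_series, seed=1)
        np.testing.assert_array_equal(
            resampled.lanes.to_numpy(), a.lanes.to_numpy()
        )

    def test_deterministic_per_seed(self, wt_series):
        summary = summarize_replicates(wt_series)
        a = resample_series(summary, wt_series, seed=42)
        b = resample_series(summary, wt_series, seed=42)
        np.testing.assert_array_equal(a.lanes.to_numpy(), b.lanes.to_numpy())
        c = resample_series(summary, wt_series, seed=43)
        assert not np.array_equal(a.lanes.to_numpy(), c.lanes.to_numpy())

    def test_single_replicate_refused_without_override(self):
        from conftest import make_series

        series = make_series(reps=1)
        summary = summarize_replicates(series)
        with pytest.raises(ValueError, match="sd_override"):
            resample_series(summary, series, seed=0)
        # with an override it runs
        resample_series(summary, series, seed=0, sd_override=0.02)

    def test_moments_match_summary(self, wt_series):
        # Monte-Carlo: across many resamples of one cell the empirical
        # mean/SD track the summary within 3 standard errors (the slight
        # shrinkage from renormalisation stays inside this band)
        summary = summarize_replicates(wt_series)
        conc = 40.0
        n = 4000
        draws = np.array(
            [
                summarize_replicates(
                    resample_series(summary, wt_series, seed=s)
                ).mean.loc[conc]
                for s in range(n)
            ]
        )
        target_mean = summary.mean.loc[conc].to_numpy()
        target_sd = summary.sd.loc[conc].to_numpy()
        se = target_sd / np.sqrt(3) / np.sqrt(n)
        assert np.all(np.abs(draws.mean(axis=0) - target_mean) < 3 * se + 1e-3)


class TestBootstrap:
    def test_noiseless_gives_zero_width_ci(self, noiseless_series):
        result = bootstrap_cis(noiseless_series, n_boot=20, seed=0)
        for lo, hi in result.ci.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-6)
        assert result.n_failed == 0

    def test_minimal_n_boot(self, wt_series):
        result = bootstrap_cis(wt_series, n_boot=2, seed=0)
        assert result.estimates.shape == (2, 3)
        for lo, hi in result.ci.values():
            assert lo <= hi

    def test_n_boot_below_two_rejected(self, wt_series):
        with pytest.raises(ValueError):
            bootstrap_cis(wt_series, n_boot=1, seed=0)

    def test_deterministic_and_extendable_seed_stream(self, wt_series):
        a = bootstrap_cis(wt_series, n_boot=50, seed=7)
        b = bootstrap_cis(wt_series, n_boot=50, seed=7)
        assert a.ci == b.ci
        np.testing.assert_array_equal(a.estimates, b.estimates)
        # growing n_boot extends the resample stream without reshuffling
        c = bootstrap_cis(wt_series, n_boot=80, seed=7)
        np.testing.assert_array_equal(c.estimates[:50], a.estimates)

    def test_ci_brackets_truth_for_calibrated_case(self, wt_series):
        result = bootstrap_cis(wt_series, n_boot=200, seed=1)
        lo, hi = result.ci["C"]
        assert lo < 5.0 < hi or abs(lo - 5.0) / 5.0 < 0.15

    def test_serialization_fields(self, wt_series):
        result = bootstrap_cis(wt_series, n_boot=10, seed=3)
        d = result.to_dict()
        assert d["n_boot"] == 10
        assert d["ci_level"] == 0.95
        assert set(d["ci"]) == {"kd_nM", "C", "f"}
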