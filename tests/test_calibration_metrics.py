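"""Temperature scaling, conformal offsets, CRPS, metrics, spike labels."""

import math

import numpy as np
import pytest

from cytodose.calibration_metrics import (Calibrator, ConformalOffsets,
                                          TemperatureParams,
                                          conformal_quantile, crps_gaussian,
                                          fit_conformal, fit_temperature,
                                          forecast_metrics, label_spikes,
                                          spike_auroc)
from cytodose.event_schema import CYTOKINES
from cytodose.latent_ctode import ForecastDistribution


def _pairs(rng, n=200, sigma_bias=1.0):
    """Synthetic forecast/observation pairs per cytokine; y ~ N(mu, sigma)
    with reported scale sigma/sigma_bias."""
    out = []
    for c in CYTOKINES:
        mu = rng.normal(3.0, 1.0, n)
        sig = rng.uniform(0.2, 0.8, n)
        y_log = rng.normal(mu, sig)
        for m, s, y in zip(mu, sig, y_log):
            d = ForecastDistribution(c, 12.0, 0.0, m, s / sigma_bias)
            out.append((d, math.expm1(y)))
    return out


class TestTemperature:
    def test_self_consistent_pairs_give_unit_temperature(self):
        t = fit_temperature(_pairs(np.random.default_rng(0)))
        for c in CYTOKINES:
            assert t[c] == pytest.approx(1.0, abs=0.1)

    def test_halved_sigma_recovers_factor_two(self):
        t = fit_temperature(_pairs(np.random.default_rng(1), sigma_bias=2.0))
        for c in CYTOKINES:
            assert t[c] == pytest.approx(2.0, rel=0.1)

    def test_outlier_keeps_temperature_finite_positive(self):
        pairs = _pairs(np.random.default_rng(2), n=50)
        d0, _ = pairs[0]
        pairs[0] = (d0, 1e9)
        t = fit_temperature(pairs)
        for c in CYTOKINES:
            assert np.isfinite(t[c]) and t[c] > 0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="≥20"):
            fit_temperature(_pairs(np.random.default_rng(3), n=4))


class TestConformal:
    def test_order_statistic_hand_computation(self):
        # scores 1..19 at level 0.9: index ceil(20*0.9)=18 -> q=18
        assert conformal_quantile(np.arange(1.0, 20.0), 0.9) == 18.0

    def test_zero_residuals_collapse_intervals(self):
        rng = np.random.default_rng(4)
        pairs = []
        for c in CYTOKINES:
            for _ in range(25):
                mu = rng.normal(3, 1)
                pairs.append((ForecastDistribution(c, 12.0, 0.0, mu, 0.5),
                              math.expm1(mu)))
        t = TemperatureParams({c: 1.0 for c in CYTOKINES})
        conf = fit_conformal(pairs, t)
        for c in CYTOKINES:
            assert conf[c] == 0.0

    def test_minimum_calibration_size_named(self):
        with pytest.raises(ValueError, match="19"):
            conformal_quantile(np.arange(5.0), 0.9)

    @pytest.mark.parametrize("seed", range(10))
    def test_marginal_validity_on_exchangeable_data(self, seed):
        """Distribution-free marginal validity on every seed.

        The conformal guarantee is marginal over the calibration draw as
        well as the test draw, so the 1.96-sigma binomial tolerance counts
        both finite samples: sqrt(0.09/n_cal + 0.09/n_test)."""
        rng = np.random.default_rng(100 + seed)
        n_cal = 150                                   # per cytokine, per stage
        temp_pairs = _pairs(rng, n=n_cal, sigma_bias=1.7)  # miscalibrated
        conf_pairs = _pairs(rng, n=n_cal, sigma_bias=1.7)
        test = _pairs(rng, n=500, sigma_bias=1.7)
        temp = fit_temperature(temp_pairs)
        conf = fit_conformal(conf_pairs, temp)
        cal = Calibrator(temp, conf)
        n, covered = 0, 0
        for d, y in test:
            d = cal.apply(d)
            covered += d.lo90 <= y <= d.hi90
            n += 1
        tol = 1.96 * math.sqrt(0.09 / (4 * n_cal) + 0.09 / n)
        assert covered / n >= 0.90 - tol


class TestCRPS:
    def test_standard_normal_at_mean(self):
        # closed form at y = mu: sigma * (2/sqrt(2*pi) - 1/sqrt(pi)) ≈ 0.2337
        assert crps_gaussian(0.0, 1.0, 0.0) == pytest.approx(0.2337, abs=1e-3)

    def test_monte_carlo_oracle(self):
        """CRPS(F, y) = E|X − y| − 0.5 E|X − X'| via 10^6 samples."""
        rng = np.random.default_rng(7)
        mu, sig, y = 1.3, 0.7, 2.1
        x = rng.normal(mu, sig, 10 ** 6)
        x2 = rng.normal(mu, sig, 10 ** 6)
        mc = np.mean(np.abs(x - y)) - 0.5 * np.mean(np.abs(x - x2))
        assert crps_gaussian(mu, sig, y) == pytest.approx(mc, abs=1e-3)

    def test_positive_homogeneity(self):
        base = crps_gaussian(1.0, 0.5, 2.0)
        assert crps_gaussian(3.0, 1.5, 6.0) == pytest.approx(3 * base)

    def test_tail_limit_approaches_absolute_error(self):
        y = 50.0
        assert crps_gaussian(0.0, 1.0, y) == pytest.approx(abs(y), rel=0.05)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            crps_gaussian(0.0, 0.0, 1.0)


class TestForecastMetrics:
    def _frame(self, preds, trues, lo=None, hi=None):
        import pandas as pd
        n = len(preds)
        return pd.DataFrame({
            "cytokine": ["il6"] * n, "horizon_h": [12.0] * n,
            "origin_t": [0.0] * n, "y_true": trues, "y_pred": preds,
            "mean_log": np.log1p(np.maximum(preds, 0)),
            "sigma_log": [0.5] * n,
            "lo90": lo if lo is not None else [0.0] * n,
            "hi90": hi if hi is not None else [1e9] * n})

    def test_perfect_predictions(self):
        m = forecast_metrics(self._frame([1.0, 2.0], [1.0, 2.0]),
                             stratify=False)
        assert m["mae"][0] == 0.0 and m["rmse"][0] == 0.0
        assert m["coverage90"][0] == 1.0

    def test_hand_computed_mae_rmse(self):
        m = forecast_metrics(self._frame([1.0, 3.0], [2.0, 5.0]),
                             stratify=False)
        assert m["mae"][0] == pytest.approx(1.5)
        assert m["rmse"][0] == pytest.approx(math.sqrt(2.5))

    def test_boundary_hits_count_as_covered(self):
        m = forecast_metrics(self._frame([5.0], [5.0], lo=[5.0], hi=[5.0]),
                             stratify=False)
        assert m["coverage90"][0] == 1.0

    def test_empty_input_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            forecast_metrics(pd.DataFrame())


class TestSpikes:
    def test_relative_rise_rule(self):
        assert label_spikes([0.0, 4.0], [50.0, 95.0]).spike       # +45 in 4 h
        assert not label_spikes([0.0, 4.0], [50.0, 85.0]).spike   # +35 only
        assert not label_spikes([0.0, 8.0], [50.0, 95.0]).spike   # > 6 h apart

    def test_absolute_rule(self):
        assert label_spikes([0.0, 4.0], [50.0, 85.0],
                            criterion="absolute").spike is False
        assert label_spikes([0.0], [101.0], criterion="absolute").spike

    def test_relative_needs_two_points(self):
        with pytest.raises(ValueError):
            label_spikes([0.0], [50.0])

    def test_perfect_separation_auroc_one(self):
        labels = [0, 1, 0, 1, 1, 0, 1, 0, 0, 1]
        assert spike_auroc(labels, labels) == 1.0

    def test_auroc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(8)
        scores = rng.uniform(0, 1, 60)
        labels = (scores + rng.normal(0, 0.3, 60) > 0.5).astype(int)
        a = spike_auroc(scores, labels)
        b = spike_auroc(np.exp(5 * scores), labels)
        assert a == pytest.approx(b)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            spike_auroc([0.1, 0.9], [1, 1])
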