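import numpy as np
import pytest

import edam
from edam.accuracy import (TemporalPrediction, acc_tv, directional_acc,
                           fit_tv_curve, site_changes)
from edam.pipeline import accuracy_by_species


def ideal_prediction():
    """Sites whose observed change, averaged within each level of predicted
    change, lies exactly on the ideal line y = x."""
    #       x = -1,  -0.5, -0.5,  0,   0,  0.5, 0.5,  1,   1
    p1 = [1.0, 0.75, 0.75, 0.5, 0.5, 0.25, 0.25, 0.0, 0.0]
    p2 = [0.0, 0.25, 0.25, 0.5, 0.5, 0.75, 0.75, 1.0, 1.0]
    obs1 = [1, 1, 0, 0, 1, 0, 0, 0, 0]
    obs2 = [0, 0, 0, 0, 1, 1, 0, 1, 1]
    return TemporalPrediction(p1, p2, obs1, obs2)


class TestSiteChanges:
    def test_gain_loss_definitions(self):
        pred = TemporalPrediction([0.2, 0.8, 0.5], [0.9, 0.1, 0.5],
                                  [0, 1, 1], [1, 0, 1])
        x, o, loss, gain = site_changes(pred)
        assert x == pytest.approx([0.7, -0.7, 0.0])
        assert list(o) == [1, -1, 0]
        assert list(loss) == [False, True, False]
        assert list(gain) == [True, False, False]

    def test_no_observed_change_is_zero(self):
        pred = TemporalPrediction([0.2], [0.9], [1], [1])
        _, o, _, _ = site_changes(pred)
        assert list(o) == [0]


class TestFitTvCurve:
    def test_reproduces_linear_signal(self):
        x = np.linspace(-1, 1, 40)
        curve = fit_tv_curve(x, x, df=3)
        assert np.allclose(curve.fitted, x, atol=1e-6)

    def test_flat_response(self):
        x = np.linspace(-1, 1, 30)
        curve = fit_tv_curve(x, np.zeros_like(x), df=3)
        assert np.allclose(curve.fitted, 0.0, atol=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-1, 1, 50)
        o = np.sign(x) * (rng.random(50) < np.abs(x))
        perm = rng.permutation(50)
        c1 = fit_tv_curve(x, o)
        c2 = fit_tv_curve(x[perm], o[perm])
        assert np.allclose(c1.fitted[perm], c2.fitted, atol=1e-9)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_tv_curve(np.ones(10), np.zeros(10))


class TestAccTv:
    def test_ideal_curve_scores_one(self):
        x = np.linspace(-1, 1, 40)
        assert acc_tv(fit_tv_curve(x, x)).acc_tv == pytest.approx(1.0, abs=1e-6)

    def test_zero_curve_hand_value(self):
        # yhat = 0 on x = (-0.5, 0.5): 1 - sum |x| * |x| / sum |x| = 0.5
        x_fit = np.linspace(-1, 1, 20)
        curve = fit_tv_curve(x_fit, np.zeros_like(x_fit))
        res = acc_tv(curve, x=np.array([-0.5, 0.5]))
        assert res.acc_tv == pytest.approx(0.5, abs=1e-10)

    def test_constant_offset(self):
        x = np.linspace(-1, 1, 40)
        c = 0.2
        curve = fit_tv_curve(x, x + c)
        assert acc_tv(curve).acc_tv == pytest.approx(1 - c, abs=1e-6)

    def test_upper_bound_and_duplication_invariance(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(-1, 1, 60)
        o = np.clip(x + rng.normal(0, 0.5, 60), -1, 1)
        one = acc_tv(fit_tv_curve(x, o))
        two = acc_tv(fit_tv_curve(np.tile(x, 2), np.tile(o, 2)))
        assert one.acc_tv <= 1.0
        assert two.acc_tv == pytest.approx(one.acc_tv, abs=1e-9)

    def test_no_predicted_change_rejected(self):
        x_fit = np.linspace(-1, 1, 20)
        curve = fit_tv_curve(x_fit, np.zeros_like(x_fit))
        with pytest.raises(ValueError, match="no predicted change"):
            acc_tv(curve, x=np.zeros(5))


class TestDirectionalAcc:
    def test_ideal_predictions_score_one_everywhere(self):
        pred = ideal_prediction()
        assert directional_acc(pred, "both").acc_tv == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_data_gives_equal_directions(self):
        rng = np.random.default_rng(2)
        x_half = rng.uniform(0.05, 1, 200)
        x = np.concatenate([x_half, -x_half])
        p1 = np.where(x > 0, 0.0, -x)
        obs1 = (x < 0).astype(int)
        obs2 = np.where(x > 0, rng.random(400) < x, ~(rng.random(400) < -x))
        pred = TemporalPrediction(p1, p1 + x, obs1, obs2.astype(int))
        loss = directional_acc(pred, "loss").acc_tv
        gain = directional_acc(pred, "gain").acc_tv
        assert loss == pytest.approx(gain, abs=0.15)

    def test_noisier_gains_score_below_losses(self):
        # average over seeds: noise injected only into positive predictions
        diffs = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.uniform(-1, 1, 300)
            p1 = np.clip(0.5 - x / 2, 0, 1)
            p2_true = np.clip(p1 + x, 0, 1)
            obs1 = rng.random(300) < p1
            obs2 = rng.random(300) < p2_true
            p2 = np.clip(p2_true + (x > 0) * rng.normal(0, 0.25, 300), 0, 1)
            pred = TemporalPrediction(p1, p2, obs1, obs2)
            diffs.append(
                directional_acc(pred, "loss").acc_tv
                - directional_acc(pred, "gain").acc_tv
            )
        assert np.mean(diffs) > 0

    def test_empty_subset_rejected(self):
        pred = TemporalPrediction([0.1, 0.2], [0.5, 0.9], [0, 0], [1, 1])
        with pytest.raises(ValueError):
            directional_acc(pred, "loss")


class TestAccuracyByCpecies:
    def test_degenerate_species_get_nan(self):
        preds = {
            "ok": ideal_prediction(),
            "flat": TemporalPrediction([0.5] * 10, [0.5] * 10, [0] * 10, [0] * 10),
        }
        out = accuracy_by_species(preds, "both")
        assert out["ok"] == pytest.approx(1.0, abs=1e-6)
        assert np.isnan(out["flat"])
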