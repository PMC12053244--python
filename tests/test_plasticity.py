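"""Learning rules: shortcut Hebbian/Oja rule, dopamine-modulated rules."""
import numpy as np
import pytest

from bgdbs.plasticity import (
    DAPlasticityParams,
    ShortcutPlasticityParams,
    da_update,
    prediction_update,
    shortcut_update,
)


def scalar_shortcut_oracle(w, r_pre, r_post, r_mean, p):
    """Brute-force scalar evaluation of the shortcut rule for one synapse."""
    v = max(r_post - r_mean - p.theta_post, 0.0)
    alpha = p.beta_reg * max(r_post - p.theta_reg, 0.0)
    dw = (r_pre * v - alpha * v * v * w) / p.tau_w
    return max(w + dw, 0.0)


class TestShortcutRule:
    def setup_method(self):
        self.p = ShortcutPlasticityParams()

    def test_defaults_match_stated_constants(self):
        assert (self.p.tau_w, self.p.theta_reg, self.p.theta_post, self.p.beta_reg) == (
            150000.0, 0.93, 0.1, 2.0,
        )

    def test_no_update_when_post_at_population_mean(self):
        w = np.full((1, 1), 0.1)
        out = shortcut_update(w, np.array([1.0]), np.array([0.5]), np.array([0.5]), self.p)
        np.testing.assert_array_equal(out, w)

    def test_pure_hebbian_growth_below_regularization_threshold(self):
        """At r_post = 0.9 < theta_reg the Oja-style decay is inactive."""
        w = np.full((1, 1), 0.1)
        out = shortcut_update(w, np.array([1.0]), np.array([0.9]), np.array([0.2]), self.p)
        v = 0.9 - 0.2 - 0.1
        assert out[0, 0] == pytest.approx(0.1 + v / self.p.tau_w)

    def test_matches_scalar_oracle_with_regularization_active(self):
        """r_pre=1, r_post=1.0, mean=0.5, w=0.1: dw/ms = 2.65173e-6, verified
        against an independent scalar evaluation."""
        w = np.full((1, 1), 0.1)
        out = shortcut_update(w, np.array([1.0]), np.array([1.0]), np.array([0.5]), self.p)
        expected = scalar_shortcut_oracle(0.1, 1.0, 1.0, 0.5, self.p)
        assert out[0, 0] == pytest.approx(expected, rel=1e-12)
        assert out[0, 0] - 0.1 == pytest.approx(2.65173e-6, rel=1e-4)

    def test_weights_clamped_nonnegative(self):
        p = ShortcutPlasticityParams(tau_w=1.0)  # absurdly fast to force clipping
        w = np.full((1, 1), 1e-9)
        out = shortcut_update(w, np.array([0.0]), np.array([2.0]), np.array([0.0]), p)
        assert np.all(out >= 0.0)


class TestDopamineRules:
    def params(self, **kw):
        base = dict(tau=100.0, polarity=1, deviation="above", w_max=0.3)
        base.update(kw)
        return DAPlasticityParams(**base)

    def test_no_update_at_baseline_dopamine(self):
        w = np.full((2, 2), 0.05)
        for pol in (1, -1):
            out = da_update(w, np.ones(2), np.array([0.3, 0.1]), 0.1,
                            self.params(polarity=pol))
            np.testing.assert_array_equal(out, w)

    def test_reward_reinforces_selected_channel_d1(self):
        """Positive dopamine deviation with active pre and a below-mean
        (selected) postsynaptic unit strengthens the inhibitory D1 synapse."""
        w = np.full((1, 2), 0.05)
        out = da_update(w, np.ones(1), np.array([0.0, 0.5]), 0.9,
                        self.params(deviation="below"))
        assert out[0, 0] > 0.05  # selected (silenced) channel reinforced
        assert out[0, 1] == 0.05

    def test_omission_teaches_suppression_d2(self):
        """A dopamine dip (rate at 0) with D2 polarity gives a positive update."""
        w = np.full((1, 2), 0.0)
        out = da_update(w, np.ones(1), np.array([0.0, 0.5]), 0.0,
                        self.params(polarity=-1, deviation="below"))
        assert out[0, 0] > 0.0

    def test_weights_respect_bounds(self):
        p = self.params(tau=0.01)
        w = np.full((1, 2), 0.29)
        out = da_update(w, np.ones(1), np.array([1.0, 0.0]), 0.9, p)
        assert out.max() <= p.w_max
        out = da_update(w, np.ones(1), np.array([1.0, 0.0]), 0.0, p)
        assert out.min() >= 0.0

    def test_dip_time_constant_selected_below_baseline(self):
        p = self.params(tau=100.0, tau_dip=10.0)
        w = np.full((1, 2), 0.05)
        slow = da_update(w, np.ones(1), np.array([1.0, 0.0]), 0.2, p)
        fast = da_update(w, np.ones(1), np.array([1.0, 0.0]), 0.0, p)
        # same |kappa| = 0.1 but the dip uses the 10x faster constant
        assert abs(fast[0, 0] - 0.05) == pytest.approx(10 * abs(slow[0, 0] - 0.05))
        assert fast[0, 0] < 0.05 < slow[0, 0]

    def test_prediction_weights_track_prediction_error(self):
        w = np.full((2, 1), 0.1)
        up = prediction_update(w, np.ones(2), 0.5, 1.0, tau_pred=100.0)
        down = prediction_update(w, np.ones(2), -0.5, 1.0, tau_pred=100.0)
        gated = prediction_update(w, np.ones(2), 0.5, 0.0, tau_pred=100.0)
        assert np.all(up > w) and np.all(down < w)
        np.testing.assert_array_equal(gated, w)


class TestLearningEndToEnd:
    def test_weights_stay_bounded_over_full_task(self, small_off_run):
        """No weight goes negative, non-finite, or explodes past 10x its
        initialization scale across 120 trials."""
        for name, w in small_off_run.weights.items():
            assert np.all(np.isfinite(w)), name
            assert w.min() >= 0.0, name
        assert small_off_run.weights["shortcut"].max() < 1.0  # 10 x 0.1

    def test_learning_beats_chance_in_session_one(self):
        """DBS OFF, Session 1: rewarded decisions significantly above the 50%
        chance level (binomial test across seeds)."""
        from scipy import stats

        from bgdbs.task import run_task_batch

        res = run_task_batch(np.arange(40), "off", record_rates=False)
        s1 = res.rewarded[:, :40].sum(axis=1)
        t, p = stats.ttest_1samp(s1, 20.0, alternative="greater")
        assert p < 1e-6
        assert s1.mean() > 24

    def test_plastic_shortcut_increases_late_unrewarded_decisions(self):
        """The habitual bias of the plastic shortcut yields more unrewarded
        Session-3 decisions than the frozen-shortcut model on average."""
        from bgdbs.task import run_task_batch

        seeds = np.arange(48)
        plastic = run_task_batch(seeds, "off", shortcut="plastic", record_rates=False)
        fixed = run_task_batch(seeds, "off", shortcut="fixed", record_rates=False)
        un_p = (~plastic.rewarded[:, 80:]).sum(axis=1).mean()
        un_f = (~fixed.rewarded[:, 80:]).sum(axis=1).mean()
        assert un_p > un_f
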