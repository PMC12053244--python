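"""Downstream analyses: counts, support, pathway influence, regressions."""
import numpy as np
import pandas as pd
import pytest

import bgdbs.analysis as ana
from bgdbs.task import TaskResult, TrialRecord


def fake_result(rewarded, choices=None, session_length=40, **kw):
    rewarded = np.asarray(rewarded, dtype=bool)
    S, T = rewarded.shape
    if choices is None:
        choices = np.zeros((S, T), dtype=np.int64)
    base = dict(
        seeds=np.arange(S),
        dbs_variant="off",
        dbs_on=False,
        shortcut="plastic",
        choices=np.asarray(choices),
        rewarded=rewarded,
        latency=np.ones((S, T), dtype=np.int64),
        psp_shortcut=np.zeros((S, T, 2)),
        psp_gpi=np.zeros((S, T, 2)),
        weights={},
        mean_rates={},
        session_length=session_length,
    )
    base.update(kw)
    return TaskResult(**base)


class TestCountUnrewarded:
    def test_all_rewarded_counts_zero(self):
        df = ana.count_unrewarded(fake_result(np.ones((1, 120))))
        assert df["unrewarded"].tolist() == [0, 0, 0]

    def test_alternating_rewards_split_evenly(self):
        rew = np.tile([True, False], 60)[None, :]
        df = ana.count_unrewarded(fake_result(rew))
        assert df["unrewarded"].tolist() == [20, 20, 20]

    def test_conservation_rewarded_plus_unrewarded(self, small_off_run):
        df = ana.count_unrewarded(small_off_run)
        assert np.all(df["rewarded"] + df["unrewarded"] == 40)
        assert df.groupby("sim")["unrewarded"].sum().tolist() == (
            (~small_off_run.rewarded).sum(axis=1).tolist()
        )

    def test_wrong_trial_count_rejected(self):
        with pytest.raises(ValueError, match="session"):
            ana.count_unrewarded(fake_result(np.ones((1, 97))))


class TestSupport:
    def test_sign_convention(self):
        """GPi inhibiting the chosen side less than the other yields positive
        basal-ganglia support; shortcut exciting the chosen side more yields
        positive shortcut support."""
        rec = TrialRecord(
            trial=0, choice=0, rewarded=True, latency=10,
            psp_shortcut=np.array([0.3, 0.1]), psp_gpi=np.array([0.1, 0.5]),
        )
        sc, bg = ana.compute_support(rec)
        assert sc == pytest.approx(0.2)
        assert bg == pytest.approx(0.4)

    def test_support_flips_with_choice(self):
        rec = TrialRecord(
            trial=0, choice=1, rewarded=True, latency=10,
            psp_shortcut=np.array([0.3, 0.1]), psp_gpi=np.array([0.1, 0.5]),
        )
        sc, bg = ana.compute_support(rec)
        assert sc == pytest.approx(-0.2)
        assert bg == pytest.approx(-0.4)

    def test_missing_traces_raise(self):
        rec = TrialRecord(trial=0, choice=0, rewarded=True, latency=1,
                          psp_shortcut=None, psp_gpi=None)
        with pytest.raises(ValueError, match="traces"):
            ana.compute_support(rec)

    def test_batched_traces_match_per_record_computation(self, small_off_run):
        df = ana.support_traces(small_off_run)
        recs = small_off_run.records(0)
        sc0, bg0 = ana.compute_support(recs[10])
        row = df[(df.sim == 0) & (df.trial == 10)].iloc[0]
        assert row["shortcut_support"] == pytest.approx(sc0)
        assert row["bg_support"] == pytest.approx(bg0)

    def test_untrained_support_near_zero_in_expectation(self):
        """With random symmetric initial weights the first-trial support has
        mean about zero over many seeds."""
        from bgdbs.task import run_task_batch

        res = run_task_batch(np.arange(100), "off", record_rates=False)
        df = ana.support_traces(res)
        first = df[df.trial == 0]
        assert abs(first["shortcut_support"].mean()) < 0.02


class TestPathwayInfluence:
    def test_matches_bruteforce_matrix_product(self):
        rng = np.random.default_rng(0)
        w = {
            "Cor_in->StrD1": rng.random((2, 4)),
            "StrD1->GPi": rng.random((4, 2)),
            "Cor_in->StrD2": rng.random((2, 4)),
            "StrD2->GPe": rng.random((4, 2)),
            "Cor_in->STN": rng.random((2, 4)),
            "STN->GPi": rng.random((4, 2)),
            "shortcut": rng.random((2, 2)),
        }
        out = ana.pathway_influence(w)
        brute = np.zeros(2)
        for j in range(2):
            acc = 0.0
            for i in range(2):
                for k in range(4):
                    acc += w["Cor_in->StrD1"][i, k] * w["StrD1->GPi"][k, j]
            brute[j] = acc / 2
        np.testing.assert_allclose(out["direct"], brute)
        np.testing.assert_allclose(out["shortcut"], w["shortcut"].mean(axis=0))

    def test_initial_influences_reflect_initial_weights(self, small_off_run):
        inf = ana.pathway_influence(small_off_run)
        # StrD2->GPe starts at exactly zero, so the indirect pathway does too
        np.testing.assert_allclose(inf["indirect"][:, 0], 0.0)
        # the plastic shortcut starts at exactly 0.1 per synapse
        np.testing.assert_allclose(inf["shortcut"][:, 0], 0.1)

    def test_dimension_mismatch_raises(self):
        w = {"Cor_in->StrD1": np.ones((2, 3)), "StrD1->GPi": np.ones((4, 2)),
             "Cor_in->StrD2": np.ones((2, 4)), "StrD2->GPe": np.ones((4, 2)),
             "Cor_in->STN": np.ones((2, 4)), "STN->GPi": np.ones((4, 2)),
             "shortcut": np.ones((2, 2))}
        with pytest.raises(ValueError, match="dimension"):
            ana.pathway_influence(w)


class TestMixedRegression:
    def make_summaries(self, rng, shift=0.0, n=40):
        rows = []
        intercepts = rng.normal(0, 1.5, n)
        for sim in range(n):
            for variant, mu in [("off", 10.0), ("stim", 10.0 + shift)]:
                for session in (1, 2, 3):
                    y = mu + intercepts[sim] + rng.normal(0, 1.0)
                    rows.append(
                        {"sim": sim, "session": session, "dbs_variant": variant,
                         "unrewarded": y}
                    )
        return pd.DataFrame(rows)

    def test_identical_conditions_give_null_coefficient(self):
        rng = np.random.default_rng(1)
        tab = ana.fit_mixed_regression(self.make_summaries(rng, 0.0), dv="unrewarded")
        assert np.all(np.abs(tab["coef"]) < 0.8)
        assert np.all(tab["p_corrected"] >= tab["p"])

    def test_recovers_injected_shift(self):
        """Data simulated from the fitted model class with a +3 shift for one
        condition recovers a coefficient of 3 within its confidence interval."""
        rng = np.random.default_rng(2)
        tab = ana.fit_mixed_regression(self.make_summaries(rng, 3.0), dv="unrewarded")
        covered = 0
        for _, row in tab.iterrows():
            assert row["coef"] == pytest.approx(3.0, abs=0.7)
            covered += row["ci_low"] < 3.0 < row["ci_high"]
        assert covered >= 2  # 95% CIs cover the truth in most sessions

    def test_unbalanced_design_warns(self):
        rng = np.random.default_rng(3)
        df = self.make_summaries(rng, 0.0, n=10)
        df = df.drop(df[(df.sim == 0) & (df.dbs_variant == "stim")].index)
        with pytest.warns(UserWarning, match="unbalanced"):
            ana.fit_mixed_regression(df, dv="unrewarded")


class TestParameterSearch:
    def test_self_match_selects_zero_stimulation(self):
        """If the reference equals the model's own OFF behavior, a grid that
        contains alpha = 0 selects it."""
        from bgdbs.task import run_task_batch

        seeds = range(6)
        off = run_task_batch(seeds, "off", record_rates=False)
        ref = ana.session_summary(off).groupby("session")["rewarded"].mean().to_numpy()
        out = ana.dbs_parameter_search(
            "suppression", [0.0, 0.3], ref, seeds=seeds
        )
        assert out["best"] == {"alpha_suppress": 0.0}
        table = out["table"]
        # exhaustive check: the reported winner is the argmin of the table
        assert table["mean_dev"].idxmin() == table.index[
            table["params"] == out["best"]
        ][0]

    def test_single_point_grid_returned(self):
        out = ana.dbs_parameter_search(
            "efferent", [0.05], np.array([30.0, 25.0, 28.0]), seeds=range(2)
        )
        assert out["best"] == {"alpha_axon_efferent": 0.05}

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ana.dbs_parameter_search("efferent", [], [30, 25, 28])


class TestAcuteHistoryMachinery:
    def test_congruent_replay_reproduces_original_run(self):
        """Reloading each Session-3 trial-start state and replaying it under
        the same DBS state reproduces the original outcomes exactly."""
        from bgdbs.task import run_task_batch

        seeds = [0, 1, 2]
        trials = range(80, 120)
        for on in (False, True):
            run = run_task_batch(seeds, "suppression", dbs_on=on,
                                 record_rates=False, snapshot_trials=trials)
            replay = ana.replay_session3(run, acute_on=on, dbs_variant="suppression")
            np.testing.assert_array_equal(replay, run.rewarded[:, 80:120])

    def test_factorial_table_shape(self):
        df = ana.acute_history_experiment(range(2), "suppression")
        assert set(df["history"]) == {"on", "off"}
        assert set(df["acute"]) == {"on", "off"}
        assert len(df) == 2 * 2 * 2
        assert (df["unrewarded"] <= 40).all()
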