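"""Network construction, seeded initialization, snapshot/restore."""
import numpy as np
import pytest

import bgdbs
from bgdbs.connectome import build_default_model, freeze_shortcut, restore, snapshot

# (pre, post, pattern, target) rows of the connection table
EXPECTED_PROJECTIONS = {
    ("GPe", "GPi", "one_to_one", "inh"),
    ("GPe", "STN", "all_to_all", "inh"),
    ("GPi", "GPi", "all_to_all", "inh"),
    ("GPi", "Thalamus", "one_to_one", "inh"),
    ("Cor_in", "STN", "all_to_all", "exc"),
    ("Cor_in", "StrD1", "all_to_all", "exc"),
    ("Cor_in", "StrD2", "all_to_all", "exc"),
    ("PPN", "SNc", "all_to_all", "exc"),
    ("STN", "GPe", "all_to_all", "exc"),
    ("STN", "GPi", "all_to_all", "exc"),
    ("STN", "STN", "all_to_all", "inh"),
    ("StrD1", "GPi", "all_to_all", "inh"),
    ("StrD1", "SNc", "all_to_all", "inh"),
    ("StrD1", "StrD1", "all_to_all", "inh"),
    ("StrD2", "GPe", "all_to_all", "inh"),
    ("StrD2", "StrD2", "all_to_all", "inh"),
    ("StrThal", "GPe", "one_to_one", "inh"),
    ("StrThal", "GPi", "one_to_one", "inh"),
    ("StrThal", "StrThal", "all_to_all", "inh"),
    ("Thalamus", "Cor_dec", "one_to_one", "exc"),
    ("Thalamus", "StrThal", "one_to_one", "exc"),
}


class TestConnectivityCensus:
    def test_projection_table_is_complete(self, cfg):
        """23 projections: the 21 unique rows plus the two cortico-thalamic
        shortcut rows (fixed and plastic) sharing pre/post/pattern/target."""
        assert len(cfg.projections) == 23
        rows = [
            (p.pre, p.post, p.pattern, p.target) for p in cfg.projections.values()
        ]
        shortcut_rows = [r for r in rows if r == ("Cor_in", "Thalamus", "all_to_all", "exc")]
        assert len(shortcut_rows) == 2
        assert set(rows) - {("Cor_in", "Thalamus", "all_to_all", "exc")} == EXPECTED_PROJECTIONS

    def test_population_sizes(self, cfg):
        sizes = {name: p.n for name, p in cfg.populations.items()}
        assert sizes == {
            "Cor_in": 2, "PPN": 1, "SNc": 1, "StrD1": 4, "StrD2": 4, "STN": 4,
            "GPi": 2, "GPe": 2, "Thalamus": 2, "Cor_dec": 2, "StrThal": 2,
        }
        assert cfg.populations["PPN"].tau == 1.0
        assert all(
            p.tau == 10.0 for n, p in cfg.populations.items() if n != "PPN"
        )


class TestBuild:
    def test_same_seed_gives_identical_initial_weights(self):
        a = build_default_model(42)
        b = build_default_model(42)
        for name in a.w:
            np.testing.assert_array_equal(a.w[name], b.w[name])

    def test_different_seeds_differ(self):
        a = build_default_model(1)
        b = build_default_model(2)
        assert not np.array_equal(a.w["Cor_in->StrD1"], b.w["Cor_in->StrD1"])

    def test_fixed_weight_values(self):
        st = build_default_model(0)
        np.testing.assert_array_equal(st.w["GPe->GPi"], 1.5 * np.eye(2))
        np.testing.assert_array_equal(st.w["StrD2->GPe"], np.zeros((1, 4, 2)))
        np.testing.assert_array_equal(st.w["shortcut"], np.full((1, 2, 2), 0.1))

    def test_plastic_weights_within_stated_uniform_bounds(self):
        st = build_default_model(np.arange(20))
        for name, hi in [("Cor_in->StrD1", 0.1), ("Cor_in->StrD2", 0.1),
                         ("Cor_in->STN", 0.1), ("StrD1->GPi", 0.05), ("STN->GPi", 0.05)]:
            w = st.w[name]
            assert w.min() >= 0.0 and w.max() <= hi, name

    def test_lateral_inhibition_excludes_self_connections(self):
        st = build_default_model(0)
        for name in ["GPi->GPi", "STN->STN", "StrD1->StrD1", "StrD2->StrD2", "StrThal->StrThal"]:
            assert np.all(np.diag(st.w[name]) == 0.0), name


class TestFreezeShortcut:
    def test_frozen_weights_stay_put_during_simulation(self):
        from bgdbs.task import Simulator

        st = freeze_shortcut(build_default_model([5]))
        sim = Simulator(st, "off", record_rates=False)
        before = st.w["shortcut"].copy()
        sim.run(until_trial=3)
        np.testing.assert_array_equal(st.w["shortcut"], before)
        np.testing.assert_array_equal(before, np.full_like(before, 0.1))

    def test_plastic_and_fixed_builds_identical_except_tag(self):
        a = build_default_model(9, shortcut="plastic")
        b = build_default_model(9, shortcut="fixed")
        for name in a.w:
            np.testing.assert_array_equal(a.w[name], b.w[name])
        assert a.cfg.projections["shortcut"].plasticity == "shortcut"
        assert b.cfg.projections["shortcut"].plasticity == "none"

    def test_fixed_model_shortcut_support_is_zero(self):
        """Equal shortcut weights onto both thalamic neurons make the
        shortcut-support difference vanish identically."""
        import bgdbs.analysis as ana
        from bgdbs.task import run_task_batch

        res = run_task_batch([3, 4], "off", shortcut="fixed", record_rates=False)
        sup = ana.support_traces(res)
        np.testing.assert_allclose(sup["shortcut_support"], 0.0, atol=1e-12)


class TestSnapshotRestore:
    def test_roundtrip_preserves_trajectory(self):
        from bgdbs.task import Simulator

        st = build_default_model([11, 12])
        sim = Simulator(st, "off", record_rates=False)
        sim.run(until_trial=2)
        payload = snapshot(st)

        st2 = restore(payload)
        sim2 = Simulator(st2, "off", record_rates=False)
        sim2.run(until_trial=4)
        sim.run(until_trial=4)
        # the restored run records from its resume point onward
        np.testing.assert_array_equal(sim.choices[:, 2:4], sim2.choices[:, 2:4])
        np.testing.assert_array_equal(st.mp["GPi"], st2.mp["GPi"])

    def test_corrupt_payload_raises(self):
        with pytest.raises(ValueError, match="corrupt"):
            restore("not json at all {")
        with pytest.raises(ValueError, match="corrupt|version"):
            restore('{"version": 99}')

    def test_restore_preserves_frozen_shortcut_tag(self):
        st = build_default_model([1], shortcut="fixed")
        st2 = restore(snapshot(st))
        assert st2.cfg.projections["shortcut"].plasticity == "none"


def test_paired_seed_runs_share_weights_and_schedule():
    """Two conditions with the same seed draw identical initial weights and
    reward contingencies; only the DBS terms may differ."""
    from bgdbs.task import run_task_batch

    off = run_task_batch([21], "off", record_rates=False)
    on = run_task_batch([21], "suppression", record_rates=False)
    np.testing.assert_array_equal(off.reward_schedule, on.reward_schedule)
    np.testing.assert_array_equal(off.weights["shortcut"][:, 0], on.weights["shortcut"][:, 0])
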