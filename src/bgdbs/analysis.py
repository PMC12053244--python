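"""Analyses over simulation outputs.

Covers: unrewarded-decision session counts and their linear mixed
regressions across DBS variants; the thalamic *support* decomposition
(how strongly the cortico-thalamic shortcut and the basal-ganglia output
each pull the decision toward the selected option); pathway influence
(matrix products of successive plastic connections); acute-vs-history
factorial experiments via state snapshot/reload; acute activity-change
maps of the untrained model; and the DBS parameter search against a
reference behavioral table.
"""
from __future__ import annotations

import warnings
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .connectome import build_default_model
from .dbs import dbs_variant_config
from .specs import NetworkConfig, default_config
from .task import Simulator, TaskResult, TrialRecord, run_extended_trial, run_task_batch

__all__ = [
    "count_unrewarded",
    "session_summary",
    "compute_support",
    "support_traces",
    "session_support",
    "pathway_influence",
    "fit_mixed_regression",
    "fit_unrewarded_regression",
    "welch_ttest",
    "fit_support_regression",
    "activity_change_map",
    "replay_session3",
    "acute_history_experiment",
    "dbs_parameter_search",
]


# ---------------------------------------------------------------------------
# unrewarded decisions
# ---------------------------------------------------------------------------

def count_unrewarded(
    records: Sequence[TrialRecord] | TaskResult,
    session_length: int = 40,
) -> pd.DataFrame:
    """Per-session unrewarded/rewarded decision counts.

    Accepts one simulation's trial records or a batched :class:`TaskResult`;
    returns a tidy frame with one row per simulation x session.  Counts are
    conservative by construction: rewarded + unrewarded equals the session
    length.
    """
    if isinstance(records, TaskResult):
        rew = records.rewarded
        session_length = records.session_length
        sims = np.arange(rew.shape[0])
    else:
        rew = np.asarray([rec.rewarded for rec in records], dtype=bool)[None, :]
        sims = np.array([0])
    n_trials = rew.shape[1]
    if n_trials % session_length or n_trials == 0:
        raise ValueError(
            f"expected a whole number of {session_length}-trial sessions, got {n_trials} trials"
        )
    n_sessions = n_trials // session_length
    by_session = rew.reshape(rew.shape[0], n_sessions, session_length)
    rewarded = by_session.sum(axis=-1)
    rows = []
    for s in sims:
        for k in range(n_sessions):
            rows.append(
                {
                    "sim": int(s),
                    "session": k + 1,
                    "rewarded": int(rewarded[s, k]),
                    "unrewarded": session_length - int(rewarded[s, k]),
                }
            )
    return pd.DataFrame(rows)


def session_summary(result: TaskResult) -> pd.DataFrame:
    """Session counts annotated with the run's condition labels."""
    df = count_unrewarded(result)
    df["seed"] = result.seeds[df["sim"]]
    df["dbs_variant"] = result.dbs_variant if result.dbs_on else "off"
    df["shortcut"] = result.shortcut
    return df


# ---------------------------------------------------------------------------
# thalamic support decomposition
# ---------------------------------------------------------------------------

def compute_support(record: TrialRecord) -> tuple[float, float]:
    """(shortcut support, basal ganglia support) for one trial.

    Support is the difference between the two thalamic neurons' input from a
    source, signed toward the selected option; the GPi contribution is
    multiplied by -1 to account for its inhibitory effect.
    """
    if record.psp_shortcut is None or record.psp_gpi is None:
        raise ValueError("trial record carries no thalamic input traces")
    c = record.choice
    o = 1 - c
    shortcut = float(record.psp_shortcut[c] - record.psp_shortcut[o])
    bg = -float(record.psp_gpi[c] - record.psp_gpi[o])
    return shortcut, bg


def support_traces(result: TaskResult) -> pd.DataFrame:
    """Per-trial support values for a batched run (one row per sim x trial)."""
    S, T = result.choices.shape
    c = result.choices
    o = 1 - c
    s_idx = np.arange(S)[:, None]
    t_idx = np.arange(T)[None, :]
    shortcut = result.psp_shortcut[s_idx, t_idx, c] - result.psp_shortcut[s_idx, t_idx, o]
    bg = -(result.psp_gpi[s_idx, t_idx, c] - result.psp_gpi[s_idx, t_idx, o])
    sim, trial = np.meshgrid(np.arange(S), np.arange(T), indexing="ij")
    return pd.DataFrame(
        {
            "sim": sim.ravel(),
            "trial": trial.ravel(),
            "session": trial.ravel() // result.session_length + 1,
            "shortcut_support": shortcut.ravel(),
            "bg_support": bg.ravel(),
        }
    )


def session_support(result: TaskResult) -> pd.DataFrame:
    """Per-session mean support (per-trial values averaged within session)."""
    df = support_traces(result)
    out = (
        df.groupby(["sim", "session"], as_index=False)[["shortcut_support", "bg_support"]]
        .mean()
    )
    out["dbs_variant"] = result.dbs_variant if result.dbs_on else "off"
    out["shortcut"] = result.shortcut
    return out


# ---------------------------------------------------------------------------
# pathway influence
# ---------------------------------------------------------------------------

def pathway_influence(
    weights: Mapping[str, np.ndarray] | TaskResult,
) -> dict[str, np.ndarray]:
    """Influence of the cortical input on the two outputs, per pathway.

    Successive plastic connectivity matrices of each basal-ganglia pathway
    are combined by matrix multiplication and averaged over the cortical
    input dimension (the two input neurons activate together and learn
    identical patterns), yielding two values per trial per pathway:

    * direct      = mean_i [W(Cor_in->StrD1) @ W(StrD1->GPi)]_{i,:}
    * indirect    = mean_i [W(Cor_in->StrD2) @ W(StrD2->GPe)]_{i,:}
    * hyperdirect = mean_i [W(Cor_in->STN)  @ W(STN->GPi)]_{i,:}
    * shortcut    = mean_i  W(Cor_in->Thalamus, plastic)_{i,:}
    """
    w = weights.weights if isinstance(weights, TaskResult) else weights
    pairs = {
        "direct": ("Cor_in->StrD1", "StrD1->GPi"),
        "indirect": ("Cor_in->StrD2", "StrD2->GPe"),
        "hyperdirect": ("Cor_in->STN", "STN->GPi"),
    }
    out: dict[str, np.ndarray] = {}
    for pathway, (a, b) in pairs.items():
        wa, wb = np.asarray(w[a], dtype=float), np.asarray(w[b], dtype=float)
        if wa.shape[-1] != wb.shape[-2]:
            raise ValueError(f"dimension mismatch combining {a} and {b}")
        out[pathway] = np.matmul(wa, wb).mean(axis=-2)
    out["shortcut"] = np.asarray(w["shortcut"], dtype=float).mean(axis=-2)
    return out


# ---------------------------------------------------------------------------
# mixed-effects regressions
# ---------------------------------------------------------------------------

def fit_mixed_regression(
    data: pd.DataFrame,
    dv: str,
    baseline: str = "off",
    group: str = "sim",
    condition: str = "dbs_variant",
) -> pd.DataFrame:
    """Per-session linear mixed model: ``dv ~ C(condition)`` with random
    intercepts per simulation and the DBS OFF condition as baseline.

    Returns one row per session x non-baseline condition with the
    fixed-effect coefficient, its Wald z, raw and Bonferroni-corrected p
    (over the conditions within a session), and the 95% CI.
    """
    rows = []
    formula = f"{dv} ~ C({condition}, Treatment('{baseline}'))"
    for session, chunk in data.groupby("session"):
        counts = chunk.groupby(group)[condition].count()
        if counts.nunique() > 1:
            warnings.warn(f"unbalanced design in session {session}", stacklevel=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, chunk, groups=chunk[group])
            fit = model.fit(reml=True)
        terms = [t for t in fit.fe_params.index if t.startswith(f"C({condition}")]
        m = len(terms)
        ci = fit.conf_int()
        for term in terms:
            level = term.split("[T.")[-1].rstrip("]")
            p = float(fit.pvalues[term])
            rows.append(
                {
                    "session": session,
                    condition: level,
                    "coef": float(fit.fe_params[term]),
                    "z": float(fit.tvalues[term]),
                    "p": p,
                    "p_corrected": min(1.0, p * m),
                    "ci_low": float(ci.loc[term, 0]),
                    "ci_high": float(ci.loc[term, 1]),
                }
            )
    return pd.DataFrame(rows)


def fit_unrewarded_regression(
    summaries: pd.DataFrame | Iterable[TaskResult],
    baseline: str = "off",
) -> pd.DataFrame:
    """Mixed regression of per-session unrewarded decisions on DBS variant."""
    if not isinstance(summaries, pd.DataFrame):
        summaries = pd.concat([session_summary(r) for r in summaries], ignore_index=True)
    return fit_mixed_regression(summaries, dv="unrewarded", baseline=baseline)


def fit_support_regression(
    results: pd.DataFrame | Iterable[TaskResult],
    dv: str = "shortcut_support",
    baseline: str = "off",
) -> pd.DataFrame:
    """Mixed regression of per-session support on DBS variant."""
    if not isinstance(results, pd.DataFrame):
        results = pd.concat([session_support(r) for r in results], ignore_index=True)
    return fit_mixed_regression(results, dv=dv, baseline=baseline)


def welch_ttest(a, b, paired: bool = False) -> dict[str, float]:
    """Two-sample t-test with assumption checks.

    Checks normality (Shapiro-Wilk) and variance homogeneity (Levene); if
    either fails for an unpaired comparison, Welch's correction is applied.
    Returns the statistic, p-value, and which test was used.
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        t, p = stats.ttest_rel(a, b)
        return {"t": float(t), "p": float(p), "test": "paired"}
    normal = stats.shapiro(a).pvalue > 0.05 and stats.shapiro(b).pvalue > 0.05
    equal_var = stats.levene(a, b).pvalue > 0.05
    use_welch = not (normal and equal_var)
    t, p = stats.ttest_ind(a, b, equal_var=not use_welch)
    return {"t": float(t), "p": float(p), "test": "welch" if use_welch else "student"}


# ---------------------------------------------------------------------------
# activity-change maps (untrained model)
# ---------------------------------------------------------------------------

def activity_change_map(
    variants: Sequence[str] = ("suppression", "afferent", "efferent", "passing_fibers", "combined"),
    seeds: Sequence[int] | np.ndarray = range(100),
    cfg: NetworkConfig | None = None,
    duration_ms: int = 3000,
    window: tuple[int, int] = (2500, 3000),
) -> pd.DataFrame:
    """Mean population-rate changes (ON - OFF) of the untrained model.

    A single extended trial per seed; rates averaged over the late stimulus
    window when the circuit has settled.  Returns one row per variant x
    population with the mean change over seeds and the OFF-condition mean.
    """
    if cfg is None:
        cfg = default_config()
    seeds = np.asarray(list(seeds))
    off = run_extended_trial(seeds, "off", cfg=cfg, duration_ms=duration_ms, window=window)
    rows = []
    for variant in variants:
        on = run_extended_trial(seeds, variant, cfg=cfg, duration_ms=duration_ms, window=window)
        for pop in off:
            rows.append(
                {
                    "dbs_variant": variant,
                    "population": pop,
                    "rate_off": float(np.mean(off[pop])),
                    "rate_on": float(np.mean(on[pop])),
                    "delta": float(np.mean(on[pop] - off[pop])),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# acute vs history factorial (snapshot/reload)
# ---------------------------------------------------------------------------

def replay_session3(
    result: TaskResult,
    acute_on: bool,
    dbs_variant: str,
    cfg: NetworkConfig | None = None,
    trials: Sequence[int] | None = None,
) -> np.ndarray:
    """Replay Session-3 trials from a run's saved trial-start states.

    Each saved state is reloaded and its trial simulated once more with the
    acute DBS state forced ON or OFF; returns the rewarded flags, shape
    ``(n_sims, n_trials_replayed)``.
    """
    if cfg is None:
        cfg = default_config()
    if not result.snapshots:
        raise ValueError("run carries no saved trial-start states")
    if trials is None:
        trials = sorted(result.snapshots)
    state = build_default_model(result.seeds, cfg=cfg, shortcut=result.shortcut)
    sim = Simulator(state, dbs=dbs_variant_config(dbs_variant, cfg), dbs_on=acute_on)
    rewarded = np.zeros((len(result.seeds), len(trials)), dtype=bool)
    for j, k in enumerate(trials):
        sim.load_snapshot(result.snapshots[k])
        sim.run(until_trial=k + 1)
        rewarded[:, j] = sim.rewarded[:, k]
    return rewarded


def acute_history_experiment(
    seeds: Sequence[int] | np.ndarray,
    dbs_variant: str,
    cfg: NetworkConfig | None = None,
    shortcut: str = "plastic",
    replay_all: bool = False,
) -> pd.DataFrame:
    """Factorial decomposition of the DBS effect on Session-3 behavior.

    *history* is the DBS state of the run whose trial-start states are
    reloaded (plasticity accumulated up to each trial); *acute* is the DBS
    state forced during the replayed trial itself.  Returns per-simulation
    Session-3 unrewarded counts per (history, acute) cell.  The congruent
    cells reproduce the original runs exactly (restore determinism) and are
    taken from them unless ``replay_all`` is set.
    """
    if cfg is None:
        cfg = default_config()
    seeds = np.asarray(list(seeds))
    s3 = range(80, 120)
    runs = {
        True: run_task_batch(seeds, dbs_variant, shortcut=shortcut, dbs_on=True,
                             cfg=cfg, record_rates=False, snapshot_trials=s3),
        False: run_task_batch(seeds, dbs_variant, shortcut=shortcut, dbs_on=False,
                              cfg=cfg, record_rates=False, snapshot_trials=s3),
    }
    rows = []
    for history in (False, True):
        for acute in (False, True):
            if acute == history and not replay_all:
                rewarded = runs[history].rewarded[:, 80:120]
            else:
                rewarded = replay_session3(runs[history], acute, dbs_variant, cfg=cfg)
            unrew = (~rewarded).sum(axis=1)
            for i, seed in enumerate(seeds):
                rows.append(
                    {
                        "sim": i,
                        "seed": int(seed),
                        "dbs_variant": dbs_variant,
                        "history": "on" if history else "off",
                        "acute": "on" if acute else "off",
                        "unrewarded": int(unrew[i]),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DBS parameter search
# ---------------------------------------------------------------------------

_PRIMARY_PARAM = {
    "suppression": "alpha_suppress",
    "afferent": "alpha_axon_afferent",
    "efferent": "alpha_axon_efferent",
    "passing_fibers": "alpha_axon_gpe_stn",
}


def dbs_parameter_search(
    variant: str,
    grid: Sequence[float] | Sequence[Mapping[str, float]],
    reference: Sequence[float] | np.ndarray,
    seeds: Sequence[int] | np.ndarray = range(14),
    cfg: NetworkConfig | None = None,
    reference_var: Sequence[float] | None = None,
) -> dict[str, Any]:
    """Grid search of a DBS variant's parameters against reference behavior.

    ``reference`` is the target mean number of rewarded decisions per session
    (three values, e.g., a patient group mean).  Each grid point is scored by
    the mean absolute deviation between the model's per-session mean rewarded
    counts and the reference; ties (within a small tolerance) are broken by
    the variance match if ``reference_var`` is given.  Returns the winning
    parameters and the full score table.
    """
    if len(list(grid)) == 0:
        raise ValueError("empty parameter grid")
    if cfg is None:
        cfg = default_config()
    reference = np.asarray(reference, dtype=float)
    seeds = np.asarray(list(seeds))
    rows = []
    for point in grid:
        if isinstance(point, Mapping):
            overrides = dict(point)
        else:
            if variant not in _PRIMARY_PARAM:
                raise ValueError(
                    f"scalar grid points need a single-parameter variant, not {variant!r}"
                )
            overrides = {_PRIMARY_PARAM[variant]: float(point)}
        res = run_task_batch(
            seeds, variant, dbs_on=True, cfg=cfg, record_rates=False,
            dbs_overrides=overrides,
        )
        counts = session_summary(res).pivot(index="sim", columns="session", values="rewarded")
        mean_dev = float(np.mean(np.abs(counts.mean(axis=0).to_numpy() - reference)))
        var_dev = (
            float(np.mean(np.abs(counts.var(axis=0, ddof=1).to_numpy() - np.asarray(reference_var))))
            if reference_var is not None
            else np.nan
        )
        rows.append({"params": overrides, "mean_dev": mean_dev, "var_dev": var_dev})
    table = pd.DataFrame(rows)
    best = table["mean_dev"].min()
    candidates = table[table["mean_dev"] <= best + 1e-12]
    if reference_var is not None and len(candidates) > 1:
        winner = candidates["var_dev"].idxmin()
    else:
        winner = candidates.index[0]
    return {"best": table.loc[winner, "params"], "table": table}
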