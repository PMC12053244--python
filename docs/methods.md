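# Methods

## The circuit

`bgdbs` simulates decision-making in a rate-coded
cortico-basal-ganglia-thalamo-cortical loop. Two cortical input units
(`Cor_in`) represent the two choice stimuli; they drive three basal-ganglia
pathways that converge on the internal globus pallidus (GPi) — direct
(`Cor_in→StrD1⊣GPi`), indirect (`Cor_in→StrD2⊣GPe⊣GPi`) and hyperdirect
(`Cor_in→STN→GPi`) — and, in parallel, a plastic cortico-thalamic *shortcut*
that bypasses the basal ganglia. The GPi tonically inhibits the thalamus;
disinhibition of one thalamic channel raises the corresponding decision
cortex unit (`Cor_dec`), which reads the choice out. Lateral inhibition
within StrD1, StrD2, StrThal, STN and GPi implements competition between
channels; a thalamo-striatal feedback loop (`Thalamus→StrThal⊣GPe/GPi`)
amplifies the emerging winner.

Every unit is a leaky integrator with a rectified-linear transfer,

    tau dmp/dt = -mp + B + Σpsp_exc − Σpsp_inh + λ·U(−1,1),   r = (mp)+,

integrated by forward Euler at dt = 1 ms. Postsynaptic potentials are
`psp = w·r_pre`, summed over synapses; weights are nonnegative and the sign
of a projection is carried by its excitatory/inhibitory label. Membrane
potentials may go negative; only the rate is rectified. Input-type
populations (`Cor_in`, and the pedunculopontine nucleus `PPN`, which relays
reward delivery) are clamped to their baseline drive with no integration or
noise. Population sizes, time constants, baselines, noise amplitudes and
the full 23-projection table live in `src/bgdbs/config/network.yaml`; the
network is data, not code.

A single substantia-nigra unit (SNc) carries dopamine. Its phasic deviation
from the tonic rate 0.1 encodes a reward prediction error

    δ = (1 − B − Σpsp_StrD1)+        if the PPN signals reward,
    δ = −g · Σpsp_StrD1              otherwise (g = 10),

where `Σpsp_StrD1` is a learned inhibitory prediction from striatal D1
cells. δ drives the SNc membrane potential only during the 60 ms reward
window (gate α). Because the SNc rate is rectified, dopamine *dips*
saturate at rate 0 regardless of the prediction magnitude; this asymmetry
matters for the learning-rule calibration below.

## Plasticity

**Cortico-thalamic shortcut.** A slow Hebbian rule with a covariance-style
threshold and Oja-style regularization:

    τw dw/dt = r_pre·v − α·v²·w,
    v = (r_post − r̄_post − θpost)+,   α = βreg·(r_post − θreg)+,

with τw = 150 000 ms, θpost = 0.1, θreg = 0.93, βreg = 2. `r̄_post` is the
instantaneous thalamic population mean, so only the channel pulling ahead
of its sibling by more than θpost is potentiated, and the regularizer only
engages above θreg (baseline thalamic activity never erodes the weights).
The shortcut therefore slowly accumulates a bias toward whichever option is
repeatedly selected — a habit.

**Dopamine-modulated basal-ganglia rules.** The starred projections
(`Cor_in→{StrD1,StrD2,STN}`, `StrD1⊣GPi`, `StrD2⊣GPe`, `STN→GPi`) follow a
three-factor rule

    dw/dt = (1/τ) · κ · r_pre · dev(r_post),   κ = ±(r_SNc − 0.1),

with D1-like polarity (+) for StrD1-related and hyperdirect synapses and
D2-like polarity (−) for StrD2-related ones. `dev` is the positive part of
the postsynaptic deviation from the population mean, taken *above* the mean
for excitatory targets and *below* the mean for inhibitory targets: an
inhibitory pathway earns credit at the channel it currently silences — the
selected one — so reward strengthens direct-pathway inhibition of the
chosen channel's GPi unit, omission strengthens indirect-pathway
suppression of it, and the hyperdirect pathway learns to suppress the
alternatives. (Taking the deviation above the mean for inhibitory targets
would reward inhibition of the *unchosen* channel and unlearn every
rewarded choice; the rule as implemented is the one consistent with the
circuit's function.)

Two families of constants are deliberate calibration choices of this
implementation, recorded in the config:

* **Asymmetric time constants.** Because dips saturate (κ ≥ −0.1) while
  bursts reach κ ≈ +0.8, a single learning rate would make omission-driven
  learning ~8× weaker than reward-driven learning and the model could never
  reverse. Each rule therefore has a `tau` (dopamine above baseline) and a
  faster `tau_dip` (below baseline).
* **Weight bounds.** The basal-ganglia rules clamp weights to
  [0, w_max] with w_max = 0.1 for the pallidal-target projections. This
  keeps the learned basal-ganglia bias *marginal* relative to the shortcut
  and the membrane noise, which is what lets the shortcut measurably bias
  behavior and DBS measurably shift the balance. With unbounded direct-
  pathway weights the basal ganglia dominate every decision and all
  condition contrasts collapse.

Prediction weights (`StrD1⊣SNc`) integrate `dw/dt = (1/τ_pred)·α·δ·r_pre`
within the reward window, so predictions grow with uncompensated rewards
and shrink on omissions.

All rules are evaluated every millisecond; the dopamine factor self-gates
basal-ganglia learning to reward windows because the SNc sits at baseline
otherwise.

## The task and the operating point

Each of 120 trials: 100 ms without stimulus input, then both `Cor_in`
units are driven at rate 1 until a `Cor_dec` unit crosses the decision
threshold or 3000 ms elapse (the more active unit is then taken); the
chosen option's pre-drawn reward outcome gates the 60 ms reward window.
Reward probabilities are 80:20 and reverse to 20:80 after trial 60; the
120 trials split into three 40-trial sessions. Outcomes are pre-drawn per
(trial, option) from a dedicated RNG stream so paired conditions sharing a
seed share the full contingency table; seeds likewise fix the initial
plastic weights and the membrane noise.

Two operating-point choices required deliberation and differ from a naive
reading of the protocol:

* **Trial-start reset.** The competition loops are attractor-like: once a
  channel wins, the loser's StrThal unit rectifies to zero and the
  asymmetric state persists indefinitely at rest. Without intervention the
  network enters each trial pre-decided by the previous one, decisions are
  instantaneous, and neither learning nor any condition contrast can
  express in behavior. Membrane potentials are therefore reset at trial
  start (the dopamine unit to its tonic baseline); the 100 ms pre-stimulus
  period then rebuilds the baseline state implied by the current weights,
  and every trial runs a fresh competition seeded by the learned biases
  plus noise. `task.reset_between_trials` switches this off.
* **Decision threshold 1.62.** The symmetric stimulated thalamic level in
  this parameterization is ≈ 1.2 (baseline 1.0 plus the cortico-thalamic
  drive); a threshold below that is crossed within a few milliseconds by
  *both* channels, making choices noise-dominated. The threshold is placed
  above the symmetric level and near the asymptote of a fully resolved
  competition, so crossing requires the lateral-inhibition loops to break
  symmetry. Decisions then take hundreds of milliseconds, the untrained
  model frequently runs to the 3000 ms cap (which is why its activity can
  be measured in a late 2500–3000 ms window), latencies shorten with
  learning, and the slow shortcut integrates enough stimulus exposure to
  matter. `task.decision_threshold` exposes the value.

## DBS variants

Stimulation of the GPi is modeled by its idealized tissue effects
(parameters per variant in the config):

* *suppression* — an inhibitory somatic current `α·dbs·(−1 − mp)−` that
  pulls GPi membrane potentials toward −1 and saturates there;
* *afferent* — an axonal rate `r_axon = α·dbs` added to the presynaptic
  rates of all projections terminating on GPi (StrD1, STN, GPe and, by
  default, StrThal terminals);
* *efferent* — the same mechanism on the GPi's output axons: the
  pallido-thalamic projection and the pallidal lateral collaterals (both
  are axons of the stimulated somata);
* *passing fibers* — axonal stimulation of the GPe→STN fibers passing the
  electrode;
* *combined* — suppression + efferent + passing fibers simultaneously.

Stimulation is continuous throughout an ON run, inter-trial periods
included. With the flag off every variant is bit-identical to a run
without any DBS terms.

## Analyses

* **Unrewarded decisions** are counted per 40-trial session; condition
  effects are estimated with a linear mixed model per session (restricted
  maximum likelihood, `statsmodels MixedLM`): unrewarded count ~ DBS
  variant (categorical, OFF baseline) with random intercepts per
  simulation, Bonferroni-corrected over the variants within a session.
* **Support** quantifies how strongly each thalamic input source pulls the
  decision toward the selected option: the difference between the two
  thalamic units' psp from that source, signed toward the chosen option,
  with the GPi contribution multiplied by −1 for its inhibitory effect.
  Per-trial values average the decision epoch (stimulus onset to decision;
  `options.support_window` selects the at-decision alternative), are
  averaged per session, and enter the same mixed-model machinery. For the
  fixed-shortcut model the shortcut support is identically zero.
* **Pathway influence** multiplies the successive plastic connectivity
  matrices of each basal-ganglia pathway (and takes the shortcut matrix
  directly), averaged over the cortical input dimension, giving two values
  per trial — the input's learned pull on each output.
* **Acute vs history** separates stimulation's instantaneous activity
  effect from its accumulated plasticity effect: full ON and OFF runs save
  their state at each Session-3 trial start; each saved state is reloaded
  and its trial replayed with stimulation forced ON or OFF. Congruent
  cells reproduce the source runs bit-exactly (noise is a counter-based
  function of seed and step index, so restoring a state restores the
  future).
* **DBS parameter search** scores a parameter grid by the mean absolute
  deviation between the model's per-session rewarded-decision counts and a
  user-supplied reference table (ties broken by variance match).

## Hierarchical TD model

Choice sequences (from simulations or any 0/1 choice/outcome table) are
fitted with a TD learner: `Q_a ← Q_a + α(r − Q_a)` (single rate, or α+/α−
split by the sign of the prediction error) and softmax choice
`p = e^{βQ1}/(e^{βQ1}+e^{βQ2})`, Bernoulli likelihood. Parameters are
hierarchical and non-centered: `θ_{i,j} = θmax·σ(μ̃ + z_i σ̃ + j(μ̃_DBS +
z_i^DBS σ̃_DBS))` with j ∈ {0,1} the DBS state, normal priors on group
locations, exponential priors on group scales, standard-normal subject
offsets. Priors are stated in the original parameter space (α: mean 0.37,
θmax 1; β: mean 6.6, θmax 20) and mapped to logit space by matching the
location exactly and the spread to first order (delta method); the mapping
of the spread is not uniquely determined and is exposed through
`PriorSpec.to_logit`.

Sampling uses an affine-invariant ensemble (emcee) with the walker
ensemble folded into pseudo-chains for the Gelman–Rubin diagnostic
(required < 1.1; the default budget mirrors 4 chains × 2000 tune × 4000
draws, reducible for testing). P(Explore) reconstructs expected Q
trajectories by averaging per-draw Q paths given the observed data and
counts a trial as exploratory iff the chosen option's expected Q is
*strictly* lower than the alternative's (ties are not evidence of
exploration); it is reported per subject × session × DBS state. Model
variants are ranked by PSIS-LOO expected log predictive density (arviz)
computed on a thinned draw subset.

## What the simulations do and do not show

The generator *is* the study system: there is no external data. Seeds play
the role of subjects; 100-seed batches reproduce the scale at which the
reference effects are quantified. Reproduced: within-session learning
above chance, the post-reversal error spike and recovery, shortcut support
rising through Session 2 and collapsing after reversal while basal-ganglia
support adapts, more Session-3 errors with a plastic than a frozen
shortcut, and Session-3 increases in unrewarded decisions under the
suppression and combined variants (absent for passing fibers, attenuated
with the frozen shortcut), carried by a combination of acute activity
changes and an ON-history-specific preservation of the shortcut's learned
asymmetry.

Known limitations, all traceable to the unpublished details of the
dopamine-modulated rule set that this implementation had to re-derive:
the efferent variant's behavioral effect is much weaker than reported
(its acute effect is channel-symmetric here, leaving it little purchase on
plasticity); the Session-3 shortcut-support shift carries the opposite
sign (our OFF-condition shortcut partially re-learns during long Session-3
trials instead of persisting); and switching stimulation off after an ON
history does not *improve* performance relative to never-stimulated
controls (no learned over-compensation). Simulated subjects are also more
deterministic than patients — exploration arises only from membrane noise
at the competition's seeding, not from any dedicated stochastic policy —
so absolute P(Explore) levels run low in early sessions, as they do for
the simulations in the reference analysis.

## Numerical notes

* Forward Euler, dt = 1 ms, no adaptive stepping; with noise off,
  simulated steady states match an independently damped fixed-point
  iteration to 1e−6.
* Decisions break rate ties toward the lower-indexed option; timeout
  trials resolve by argmax at 3000 ms.
* Lateral (within-population) connections exclude self-synapses
  (`options.lateral_include_self` restores them for sensitivity checks).
* Randomness: three named Philox streams per seed (weights, rewards,
  noise), all keyed by `SeedSequence([seed, stream, block])`; noise is a
  pure function of (seed, step), so state snapshots only store the step
  counter and restore is bit-exact.
* The inner loop is compiled (numba) with a pure-numpy single-step
  reference implementation used for open-ended probes; both share all
  parameter packing. A 100-seed, 120-trial run takes a few seconds on one
  CPU core.
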