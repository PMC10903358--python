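# switchssa

State-switching step-selection analysis for animal movement data.

Animals alternate between behavioural modes — resting, foraging, travelling —
and both their movement and their habitat preferences change with the mode.
Standard (integrated) step-selection analysis ignores this and estimates one
set of selection coefficients for the whole track; the common fix of first
classifying steps with a movement HMM and then fitting per-state models
(the "two-step" approach) confounds selection with movement during
classification and ignores classification uncertainty.  `switchssa`
implements the joint alternative — a **Markov-switching conditional logistic
regression** (HMM-iSSA) — together with both competitors and a simulation
harness that quantifies when and how the shortcuts fail.

The package is aimed at movement ecologists and biostatisticians analysing
regular-interval telemetry tracks with gridded habitat covariates.

## The model

Each step of a track is summarised by its length *l* (gamma, state-dependent
shape *k_i* and rate *r_i*) and turning angle *α* (von Mises, concentration
*κ_i*), and is tilted toward preferred habitat by a log-linear selection
function exp(*Z*ᵀ*β_i*) of the covariates at the step end point.  The state
index *S_t* follows a hidden N-state Markov chain (transition matrix Γ).
Estimation uses a case-control design — each used step is compared against
*M* control steps drawn from a tentative gamma/uniform proposal — with the
state-dependent choice probability

&nbsp;&nbsp;&nbsp;&nbsp;p₀,t,i = exp(C₀ᵀθᵢ + Z₀ᵀβᵢ) / Σₘ exp(Cₘᵀθᵢ + Zₘᵀβᵢ),
&nbsp;&nbsp;&nbsp;&nbsp;C = (log *l*, −*l*, cos *α*),

plugged into the HMM likelihood δᵀP(x̃₃)ΓP(x̃₄)Γ⋯ΓP(x̃_T)𝟙, evaluated by the
scaled forward algorithm and maximised by constrained multi-start
quasi-Newton with analytic gradients.  Fitted movement coefficients are
proposal-relative; natural parameters are recovered as *k* = *k*₀ + θ̂_log l,
*r* = *r*₀ + θ̂₋l, *κ* = κ₀ + θ̂_cos α.  With N = 1 the model reduces to the
plain iSSA; without habitat covariates it reduces to a movement HMM — so
AIC/BIC compare all three on the same data.  States are decoded with the
Viterbi algorithm.  See `docs/methods.md` for the full account.

## Worked example

Simulate a 1000-location track from the "active-inactive" study scenario
(state 1: short undirected steps, no selection; state 2: long directed steps,
attraction β = 2 to a Gaussian-random-field covariate), then re-estimate
everything jointly:

```python
import switchssa as sw

scenario = sw.scenario_parameters(1)            # active-inactive
field = sw.simulate_grf(scenario.grf, seed=1)   # variance 1, range 10
track, truth = sw.simulate_track(scenario.model, field, T=1000, seed=2)

lengths, angles = sw.steps_from_track(track)
proposal = sw.fit_tentative_gamma(lengths)
data = sw.build_case_control(track, field, M=100, proposal=proposal, seed=3)

model = sw.HMMiSSA(n_states=2, n_starts=10, seed=4).fit(data)
print(model.summary_frame().round(3))
decoded = model.predict(data)
print(sw.misclassification_rate(decoded, truth[1:]))
```

Output:

```
    parameter  state  estimate    se      z     p
        shape      1     1.263 0.089    NaN   NaN
        shape      2     2.397 0.132    NaN   NaN
         rate      1     1.319 0.126    NaN   NaN
         rate      2     0.280 0.022    NaN   NaN
concentration      1     0.309 0.078    NaN   NaN
concentration      2     0.948 0.072    NaN   NaN
        beta1      1    -0.109 0.148 -0.734 0.463
        beta1      2     1.998 0.076 26.287 0.000

misclassification vs simulation truth: 4.11%
```

The fit recovers the generating parameters (truth: state 1
k = 1.20, r = 1.25, κ = 0.30, β = 0; state 2 k = 2.50, r = 0.29, κ = 1.00,
β = 2) within two standard errors, flags selection only in the active state,
and mislabels about 4% of the steps.  `TwoStepISSA` and
`MovementHMM` provide the competitors, and
`switchssa.simstudy.run_simulation_study` runs the full multi-run comparison
(significance rates, misclassification, AIC/BIC winners, bias summaries).

## Command line

```sh
switchssa simulate --scenario 1 --T 1000 --seed 1 --out-dir sim/
switchssa fit --track sim/track.csv --field sim/field.grid --n-states 2 --M 100
switchssa ts-fit --track sim/track.csv --field sim/field.grid
switchssa simstudy --config study.yaml --out-dir study/
switchssa show-defaults
```

Every output embeds the seeds and a configuration hash needed to regenerate
it; `simstudy` resumes idempotently from an existing `runs.csv`.

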