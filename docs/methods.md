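# Methods

## The model

`switchssa` estimates state-dependent fine-scale habitat selection from a
regularly sampled animal track `x_1, ..., x_T`.  Each step (the straight-line
segment between consecutive locations) is summarised by its length `l` and its
turning angle `alpha` (change in heading, wrapped to `(-pi, pi]`).  An
unobserved behavioural state sequence `S_1, ..., S_{T-1}` — one state per step
— follows a homogeneous N-state Markov chain with transition matrix `Gamma`
and initial distribution `delta`.  Conditional on the state `i`, the next
location follows the step-selection density

    f_i(x) = phi(l, alpha; theta_i) * exp(Z(x)' beta_i) / normalising constant,

where `phi` is the movement kernel — gamma step lengths with shape `k_i` and
rate `r_i`, and von Mises turning angles with concentration `|kappa_i|` and
mean 0 (`kappa_i > 0`) or pi (`kappa_i < 0`), or a uniform angle — and
`exp(Z' beta_i)` is a log-linear selection function of the habitat covariates
at the step end point (`beta > 0`: preference, `beta < 0`: avoidance).

With exponential-family step lengths and a fixed-mean von Mises angle, the
kernel-times-selection product collapses to a single log-linear exponent in
the movement covariates `C = (log l, -l, cos alpha)` with coefficients
`theta_i = (k_i - 1, r_i, kappa_i)`, plus `Z' beta_i`, minus a `log l`
Jacobian term that accounts for the polar-to-Cartesian change of variables.

### Case-control likelihood

The intractable normalising integral is replaced by a case-control design: for
every observed step, `M` control steps are drawn from a tentative proposal
(gamma lengths fitted to the pooled observed step lengths; uniform angles),
and the state-dependent probability of choosing the used step from the choice
set is the softmax of `C' theta + Z' beta` over the `M + 1` alternatives.  The
`-log l` term drops because sampling happens in polar coordinates.  Because
controls come from the proposal, the probability limits of the fitted
movement coefficients are *proposal-relative* (exponential-family tilting):

    coef(log l) -> k - k0,   coef(-l) -> r - r0,   coef(cos alpha) -> kappa - kappa0,

so natural parameters are recovered by adding the proposal parameters back.
The selection coefficients are invariant to the proposal (for `M` large enough
to stabilise the softmax denominators).

The full likelihood is the hidden-Markov form

    L = delta' P(x~_3) Gamma P(x~_4) Gamma ... Gamma P(x~_T) 1,

with `P` the diagonal matrix of state-dependent choice probabilities,
evaluated by the scaled forward algorithm in O(T N^2).  Tracks broken into
bursts contribute independent forward passes (each restarted at `delta`) whose
log-likelihoods add.  Setting `N = 1` recovers the plain integrated
step-selection analysis (a conditional logistic regression); dropping the
habitat covariates recovers a movement HMM fitted to the same case-control
data — these nested relations are what makes AIC/BIC comparison across the
three candidates meaningful.

### Estimation

Maximum likelihood on a working scale that keeps every parameter in its
natural space: `log k`, `log r` (gamma positivity is structural), free
`kappa` and `beta`, and row-wise multinomial logits for `Gamma` (diagonal
reference).  `delta` is fixed at the stationary distribution of `Gamma`
rather than estimated: it contributes a single observation's worth of
information, destabilises short bursts, and fixing it removes N-1 parameters
from the information criteria.

The optimizer is L-BFGS-B with an *analytic* gradient assembled from
forward-backward posteriors: the score of the coefficients of state `i` is the
posterior-weighted sum of used-minus-softmax-expected covariates, the score of
the transition logits combines the pairwise posteriors with the exact
implicit-function derivative of the stationary `delta` through `Gamma`
(`delta' = 1'(I - Gamma + U)^{-1}`).  The gradient is verified against finite
differences in the test suite for N in {1, 2, 3}, both angle models, with and
without selection, and multi-burst data.

The likelihood is multimodal, so fitting uses random multi-start
initialisation: start 0 is moment-based (an N-quantile split of the used step
lengths gives per-state gamma moments; `kappa` from the mean cosine via the
standard A1-inverse approximation; `beta = 0`; `Gamma` diagonal 0.9), further
starts perturb the movement parameters log-uniformly within [1/4x, 4x], draw
`beta ~ U(-2, 2)` and `Gamma` diagonals `~ U(0.7, 0.95)`.  The default is 50
starts for one-off fits; the simulation study uses 4-5 (the scenarios are
well separated and the moment-based start is usually already in the right
basin — the per-start log-likelihoods are recorded as a multimodality
diagnostic, and starts within 1e-4 log-likelihood count as one optimum).
Convergence: L-BFGS-B `gtol = 1e-6`, `ftol = 1e-11`, at most 2000 iterations.

Standard errors come from the observed information on the working scale,
computed by central finite differences of the analytic gradient (step
`1e-5 * (1 + |x|)`, symmetrised).  Wald p-values are reported for the
selection coefficients (working scale = natural scale); movement parameters
get delta-method standard errors (`se_k = k * se_{log k}`) and no p-values by
default.  AIC `= -2 l + 2p` and BIC `= -2 l + p log(n)` use the number of
choice sets as `n` and `p = N dim(theta) + N dim(beta) + N(N-1)`.

State decoding uses the Viterbi algorithm (global decoding) in log space;
exact ties break toward the lower state index (a measure-zero event in
practice).

### The two-step competitor

`TwoStepISSA` reproduces the widely used classification-first workflow: a
movement-only HMM (gamma x zero-mean von Mises emissions, same forward
machinery, `kappa` constrained positive on a log scale) is fitted to the
steps, the Viterbi sequence splits the data by state, and a single-state
conditional-logistic fit is run per decoded state with controls drawn from
that state's *fitted* step-length and turning-angle distributions (a von Mises
angle proposal, so the `cos alpha` recovery adds the proposal concentration
back).  States with fewer than 30 decoded steps are skipped with a warning.
Classification uncertainty is deliberately not propagated into the
second-stage standard errors; quantifying the resulting overconfidence is the
purpose of including this estimator.

## The synthetic landscape

The habitat covariate is one realisation of a stationary zero-mean Gaussian
random field with exponential covariance `sigma^2 exp(-d / range)`
(`sigma^2 = 1`, `range = 10` in the study).  Because simulated animals are
kept on the domain by toroidal wrapping, the field is simulated directly on
the torus: the planar covariance is periodized (summed over periodic images —
this preserves positive semi-definiteness, unlike truncating at the
half-domain distance), rescaled so the marginal variance is exactly
`sigma^2`, and factored exactly by 2-D FFT (circulant embedding).  Draws are
therefore exact, continuous across domain edges, and cheap.

The default grid is 100 x 100 cells at resolution 1.  The extent was chosen
once, a priori, so that the domain spans about ten correlation ranges and the
largest mean step length in the study (k/r = 2.5/0.29 ~ 8.6) stays small
relative to the domain; the spatial scale of the landscape relative to the
movement is the one study condition that the published design leaves open,
and results that depend on apparent-movement distortion (first-stage HMM
misclassification, two-step bias) are quantitatively sensitive to it.
Covariate lookup is nearest-cell (raster semantics, cell centres at
`origin + (i + 0.5) resolution`); the boundary policy is toroidal wrap for
simulation and an error for fitting real data.

## The track simulator

Tracks are simulated forward from the model: the state chain from
`(delta, Gamma)`, then, given the state, the next location by importance
resampling — `K` candidate steps from the state's movement kernel, one
selected with probability proportional to `exp(Z' beta)` at the candidate end
points (`K = 1000` by default).  The draw is exact as `K` grows and exactly
correct for any `K` on a constant field; the simulator warns when the
resampling effective sample size drops below 10.  The first step has no
previous heading, so its direction is uniform.  Coordinates are continuous
and unbounded; only the covariate lookup wraps.

What the generator does *not* emulate about real telemetry: location error,
irregular sampling, boundary behaviour (fences, home ranges), covariate
measurement error, and inter-individual heterogeneity.  Passing tests
therefore demonstrate correctness of the estimators under the model, not
robustness to these violations.

## The simulation study

Four scenarios (2 persistent states, `gamma_11 = gamma_22 = 0.9`, T = 1000
locations, fresh landscape each run): (1) active-inactive — distinct kernels,
selection only in the active state; (2) switching preferences — shared kernel,
opposite selection (+-2); (3) movement HMM — distinct kernels, no selection;
(4) a single-state control.  The runner fits any subset of
{iSSA, TS-iSSA, HMM-iSSA, no-selection HMM candidate, movement HMM} per run
and aggregates: percent significant selection coefficients (alpha = 0.05),
mean (sd) Viterbi misclassification, percent of runs each candidate wins
AIC/BIC, and estimate distributions/bias.  Before averaging across runs,
state labels are aligned to the simulation truth by the permutation
minimising misclassification, applied to all of a run's parameters.

Reproducibility: every run derives its landscape, track, control-draw and
initialisation seeds from `(master seed, scenario, run index)`, so records
are identical for any worker count or method subset, and each choice set's
controls come from counter-keyed substreams so increasing `M` extends the
draws without reshuffling earlier ones.

Problem sizes: the shipped default profile uses 20 runs at M = 20; the
acceptance script uses 100 runs for the movement-HMM misclassification and
the TS-iSSA/iSSA significance rates, 50 runs for the M = 500 bias summaries,
and 20 runs for the HMM-iSSA significance and model-selection rates, with
4-5 starts per fit.  These scales keep a full reproduction on a single core
to roughly a quarter of an hour while leaving the Monte-Carlo error of each
summary well inside its comparison tolerance.

## Numerical notes and limitations

- Forward/backward and Viterbi are checked against brute-force enumeration
  over all state sequences on small instances (|delta log L| < 1e-10).
- The N = 1 path is checked against an independent conditional-logistic
  solver to 1e-4 (agreement at the optimum is ~1e-9; the reference solver
  needs Newton iterations to reach it).
- Degenerate inputs: zero-length steps either raise or are floored at
  1e-6 x median step length (configurable); (near-)constant step-length
  samples make the tentative gamma MLE degenerate and trigger a warned
  moment-style fallback; reducible transition matrices fall back to a uniform
  stationary distribution with a warning.
- Label switching: the likelihood is invariant under state permutations;
  single fits are reported in arbitrary label order, and only the simulation
  study (which knows the truth) aligns labels.
- The movement HMM fixes the von Mises mean at zero and constrains
  `kappa > 0`; the joint model allows `kappa < 0` (mean pi).
- Model selection among {iSSA, HMM, HMM-iSSA} uses AIC/BIC on the shared
  case-control data; the two-step approach has no proper joint likelihood and
  is excluded by construction.
- Out of scope: covariate-dependent transition probabilities, angular
  covariates (biased random walks), grid/mesh availability sets, irregular
  sampling intervals, and multi-animal random effects.
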