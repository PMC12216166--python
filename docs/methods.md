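# Methods

`volabandit` implements, end to end, the computational analysis of a
child-friendly two-armed bandit with a volatility manipulation: task
generation, a twelve-rung reinforcement-learning model ladder,
hierarchical Bayesian estimation, model comparison by WAIC and 5-fold
cross-validation, posterior-predictive checking, and parameter/model
recovery — exercised on synthetic cohorts because the original
participant data are not publicly available.

## The task

Each trial shows two stimuli (red and blue "pirate chests") displaying
point values that always sum to `points_total = 100`; exactly one
stimulus is rewarded and is revealed after the choice.  A session has
160 trials: an 80-trial **stable** block in which red is rewarded on
exactly 75% of trials, and an 80-trial **volatile** block in which the
dominant stimulus is rewarded on exactly 80% of trials within each
20-trial sub-block and the dominant side alternates between sub-blocks
(three within-volatile reversals).  Block order is counterbalanced
(`stable_first` is the primary arrangement).  A 20-trial passive
familiarisation phase at 80:20 on a separate stimulus pair precedes the
main task.

Reward sequences are **exact-count designs**: a seeded shuffle of a
fixed number of reward assignments per block, so the stated ratios hold
as exact rational fractions for every seed (i.i.d. Bernoulli draws
would only match them in expectation).  Point splits are uniform
integers on [0, 100] for red with blue as the complement; the split
distribution is not otherwise documented for the original task, so this
choice is configurable.  A single master seed feeds independent named
substreams (stable rewards, volatile rewards, point splits, ...), which
makes the two counterbalance orders exact block permutations of each
other under the same seed.

## The model ladder

All delta-rule models track one quantity, the estimated probability
`v = P(red rewarded)`, with blue's value as `1 - v` (exactly one
stimulus is rewarded per trial and the rewarded side is revealed
regardless of choice, so a single complementary value is sufficient).
After each trial the chosen stimulus's value moves toward its realized
outcome:

    delta = r - V_chosen,    V_chosen <- V_chosen + alpha * delta,

where `r` is 1 if the choice was rewarded.  Which learning rate
`alpha` applies may depend on the sign of `delta` (outcome valence) and
on the volatility condition.  Choices follow a softmax on the value
difference,

    P(red) = 1 / (1 + exp(-(v_red - v_blue) / tau)),

parameterized so that a **larger temperature means more exploration**;
the inverse-temperature convention is `beta = 1/tau`.  The initial
value is fixed at 0.5 rather than estimated (standard for this task
length; estimating it mostly adds non-identifiability).  A prediction
error of exactly zero routes to the positive-valence learning rate;
with values in the open unit interval this occurs with probability
zero.

The ladder (see `data/model_space.yaml`; user-overridable) is:

| id  | family | parameters |
|-----|--------|------------|
| M0  | null   | — (P(red) = 0.5) |
| M1  | null   | bias |
| M2  | win-stay/lose-shift | stay_after_win, shift_after_loss |
| M3  | delta rule, alpha fixed at 1 | temperature |
| M4–M11 | delta rule | all learning-rate splits {single, by valence, by condition, by valence x condition} x temperature splits {shared, by condition} |

M11 — four learning rates (positive/negative x stable/volatile) plus a
shared temperature — is the winning model of the analysis the package
reproduces.  The middle rungs are a reconstruction: the original
supplementary listing is not public, so the ladder is composed from the
named endpoints (random, WSLS, M11), a count of twelve, and the natural
split lattice, and is deliberately data-driven (a YAML manifest) so it
can be edited without code changes.  M3's single parameter and M10's
six mean the ladder is not strictly monotone in parameter count; the
fixed endpoints take precedence.

WSLS is probabilistic: after a rewarded trial the previous choice is
repeated with probability `stay_after_win`; after an unrewarded trial
it is abandoned with probability `shift_after_loss`; the first trial is
a coin flip.

The choice rule deliberately ignores the displayed point values: reward
probability is independent of the point split in this task, so
magnitudes carry no information about the rewarded side.

## Hierarchical estimation

Participants' parameters live on unconstrained scales (logit for
learning rates and other probabilities, log for temperature) and are
drawn from a common group distribution:

    z_ik ~ Normal(mu_k, sigma_k),   theta_ik = constrain(z_ik),
    mu_k ~ Normal(0, 1.5),          sigma_k ~ Half-Normal(1).

The hyperpriors are package defaults (the original priors are not
public) and are fully overridable via `PriorConfig`.  On the
unconstrained scale they are weakly informative: prior-predictive
draws cover (0,1) for learning rates and several orders of magnitude
of temperature without piling at the boundaries.

Two algorithms produce the same draw layout:

**`map_laplace`** (default for the heavy studies): marginal MAP by
expectation-maximization with a Laplace E-step.  Each iteration (a)
maximizes every participant's conditional posterior simultaneously — a
single batched L-BFGS problem with analytic gradients through the trial
recursion — and approximates it by a Gaussian with the local negative
Hessian, then (b) updates `(mu, sigma)` in closed form from the
hyperpriors and the E-step moments.  Posterior draws combine a Gaussian
approximation of the group posterior (pooled-precision for `mu`, Fisher
information `2n` plus prior curvature for `log sigma`) with the
per-participant Laplace Gaussians.  Two cheaper designs were tried and
rejected: the centered joint mode does not exist (the joint density is
unbounded as `sigma -> 0`), and the non-centered joint mode
systematically inflates `sigma` (the reparameterization drops the
`-n log sigma` pooling term), destroying partial pooling.  This is also
why the originally planned non-centered parameterization is not used
for optimization.

**`mcmc`** (reference): a blocked Metropolis-within-Gibbs sampler in
centered coordinates — vectorized per-participant random-walk updates
on `z`, a conjugate Gibbs step for each `mu_k`, and a random-walk step
on each `log sigma_k`, with step sizes adapted toward
`target_accept = 0.44` during warmup.  R-hat and effective sample size
are computed for every sampled quantity (arviz); convergence problems
warn rather than fail so that a cross-validation run cannot silently
abort.  Initialization is unconstrained zeros plus Normal(0, 0.1)
jitter, with up to 100 retries if the density is non-finite.

The likelihood kernels are numba-compiled over a packed
(participant x trial) representation; gradients propagate the value
sensitivities `dv/dalpha` through the update recursion (the dependence
of the learning-rate *selection* on the value is piecewise constant and
ignored at its measure-zero kinks).  A pure-Python reference
implementation (`session_loglik`) is kept and cross-checked in the
tests.

## Model comparison

WAIC is computed on the deviance scale from the pointwise posterior
log-likelihoods, `WAIC = -2 (lppd - p_waic)`, with log-sum-exp for the
lppd term and the sample variance (ddof 1) for the penalty.  The
pointwise unit is the **participant-session**, matching the grain of
the cross-validation so the two scales are comparable; a trial-level
variant sits behind the `unit` flag.

5-fold CV partitions participants (seeded, fold sizes differing by at
most one), refits on the retained participants, and scores each
held-out participant by the log of the posterior-averaged likelihood of
their whole session, drawing fresh participant-level parameters from
the group posterior per draw — the honest hierarchical predictive for a
new participant, rather than a plug-in of group means.  The Monte-Carlo
draw count is configurable (`holdout_draws`, default 200).

Evidence differences on the CV scale are labelled weak [0, 2],
positive (2, 6], strong (6, 10], very strong (10, inf).  The source
scale writes the category edges as overlapping ("0–2", "2–6", ...); the
package resolves the ambiguity as closed-on-the-left-category, i.e. a
difference of exactly 2 is still "weak".  Whether categories apply to
elpd differences directly or to deviance-scaled (x2) differences is
also not documented at the source; the default is elpd with
`scale="deviance"` available, and the scale is recorded in the result.
Ranking ties break by parameter count (parsimony), then model id.

## Synthetic cohorts

The study's data are unavailable, so cohorts are simulated: n
participants (121 in the emulated arrangement), ages uniform on
[8, 16], parameters drawn from the group distribution above with
optional age slopes on the unconstrained scale (acting on `age - 12`),
one fresh 160-trial schedule per participant (sharing is configurable),
and choices generated by the chosen model.

Default generating means place the four learning-rate cells at
0.475/0.745 (positive/negative, stable) and 0.575/0.845 (volatile), an
additive decomposition of the reported condition and valence marginals
(stable 0.61, volatile 0.71; positive 0.53, negative 0.80); the
implied mean adjustment score (volatile minus stable) is ~0.10.
Cell-specific logit-scale spreads map the reported constrained SDs
(0.09–0.15) back through `sigma ~= SD / (m(1-m))`.  The temperature
regime (median 0.30, log-scale spread 0.4) is the package's own choice;
no temperature scale is documented for the original cohort.  These
defaults are simulation conditions, never fitting targets.

SDQ questionnaires are generated as 25 items coded 0/1/2: twenty
exchangeable problem items (total difficulties, 0–40) and five
prosocial items (0–10).  A planted association feeds a standardized
model parameter (default the positive-stable learning rate) into a
latent prosocial propensity with a configurable standardized slope;
residual noise keeps the latent at unit variance.  Items are Binomial(2)
draws around the transformed propensity — deliberately free of
item-level psychometrics; only subscale sums carry signal.

What the generator does **not** emulate: parameter correlations across
cells within a participant, gender effects, school clustering, IQ,
missingness, reaction times, and any within-session non-stationarity of
the decision policy.  Passing recovery and calibration checks on these
cohorts therefore demonstrates internal consistency of the pipeline,
not properties of the real cohort.

## Posterior-predictive checks and derived measures

Each predictive simulation draws one joint posterior sample per
participant (propagating posterior uncertainty into the band, unlike
posterior means), replays that participant's own schedule, averages the
choose-red indicator across participants on each trial — the same
averaging applied to the empirical data — and smooths with a centred,
edge-truncated moving average (window 5 trials by default; the original
figure's window is not documented, so the window is a reported
parameter of every output).  Across simulations (default 200) the
package reports the mean curve and a shortest-interval highest-density
band (default 95%), plus the fraction of trials on which the empirical
smoothed curve falls inside the band.

The **adjustment score** is the mean volatile learning rate minus the
mean stable learning rate (overall and per valence) — the task's index
of second-order learning.  Recovery reports give per-parameter
correlation, signed bias and RMSE between generating values and
posterior means, and a model-recovery study tabulates which ladder rung
wins 5-fold CV on cohorts generated from a given rung.

## Numerical choices

- Softmax log-probabilities via `-log1p(exp(±x))` (no overflow for
  extreme temperature draws).
- Per-participant Laplace precisions are eigendecomposed with
  eigenvalues floored at 1e-6; draws are taken in the eigenbasis, so no
  Cholesky of a near-singular matrix is ever required.
- EM stops when group-level moves fall below 1e-6 (max 200 iterations);
  participant Hessians use central differences (step 1e-4) of the
  analytic gradient.
- The HDI is the exact shortest window over sorted samples
  (`ceil(mass * n)` members), not a quantile approximation.
- Degenerate inputs fail loudly: non-integer expected reward counts,
  single-draw WAIC, fewer participants than folds, even smoothing
  windows, sub-20-sample HDIs.

## Study sizes used in the shipped checks

The acceptance checks run the recovery study at n = 40 participants x
160 trials x 3 seeds, the model-recovery study at n = 30 x 10
replicates against the chance, WSLS and single-learning-rate baselines
(5-fold CV, 100 hold-out draws), and the predictive-calibration check
at n = 25 — sizes at which the full pipeline, including every
cross-validation refit, completes in a few minutes on one core while
leaving the qualitative conclusions of the full-size (n = 121) runs
unchanged.

## Known limitations

- Positive-valence learning rates are weakly identified in this regime:
  with negative-PE learning rates near 0.75–0.85 dominating the value
  dynamics, a 160-trial session carries a median Fisher information of
  only ~0.6–1.2 (logit scale) about the positive-PE rates, capping
  true-vs-estimate correlations near 0.4–0.5 at the default generating
  spreads.  The package's estimator sits at this ceiling (it matches an
  oracle given the true group distribution), so weak positive-rate
  recovery reflects the task design, not the fitter.  Note also that
  the reported constrained SDs used to set the generating spreads are
  SDs of *shrunken* estimates and hence lower bounds on the population
  spread.
- The `map_laplace` group posterior is a moment-matched Gaussian; its
  uncertainty is approximate (point estimates agree with MCMC to well
  under 0.05 on the constrained scale in the shipped checks).
- The MH-within-Gibbs sampler can mix slowly for spread parameters of
  weakly identified cells (R-hat warnings at small n); it is the
  reference, not the workhorse.
- The inferential statistics of the original analysis on the real
  cohort (mixed ANCOVA, school-clustered mixed models, gender/age
  regressions) are deliberately out of scope; the package exports
  per-participant parameter tables as CSV for any statistics
  environment.
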