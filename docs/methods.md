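# Methods

This note documents the models and procedures implemented in `mirnn`, the
numerical choices behind them, what the synthetic-data generator does and does
not emulate, and the problem sizes used by the reference studies.

## The constrained recurrent dynamics model

The model is a discrete-time autoregressive recurrent network over the
community state. With species abundances `s_t`, metabolite concentrations
`m_t`, controls `u_t` and latent state `h_t`:

    h_t = LeakyReLU(W_hh h_{t-1} + W_ih [s_{t-1}, m_{t-1}, u_{t-1}, u_t] + b_hh)
    o_t = W_ho h_t + b_ho,      o_t = [s_t, m_t]

The parameter set is `theta = {W_hh, b_hh, W_ih, W_ho, b_ho, h_0}`, where
`h_0` is a single learned latent initial state shared across all experimental
conditions. Controls at both step endpoints are fed in to capture strong
time-dependent control variation; at the reference gut-community dimensions
(25 species, 4 metabolites, no controls, 16 latent units) the flattened
parameter count is 1,245.

Two constraints make predictions physically consistent:

* **Absence preservation.** The species part of the output is multiplied by
  the indicator `1[s_{t-1} > 0]`, so a species absent at one time point cannot
  appear at the next. Because the prediction at step t is the input at step
  t+1, a single spurious emergence would otherwise corrupt the remainder of
  the trajectory. The indicator threshold is strict zero on scaled values;
  measured abundances below a detection floor can be snapped to zero at
  ingest (default floor 0).
* **Non-negativity.** At inference a ReLU is applied to the outputs. During
  training the ReLU is suppressed so that negative raw predictions incur loss
  rather than being silently clipped.

**Data scaling.** All inputs and outputs are divided by their per-feature
maxima over the *training* data. Max-scaling, unlike mean/variance
standardisation, maps zero to zero exactly, which the absence constraint
requires. Features whose training maximum is zero get divisor 1 (they are
constant-zero and pass through unchanged). Controls are scaled by their
absolute maxima.

**A numerical choice: the training-mode mask.** The training objective uses
unrectified rollouts, so an intermediate species prediction can transiently be
negative. If the absence indicator were evaluated on that rolling sign, the
objective would be *discontinuous* in the parameters (flipping the indicator
hard-zeroes a species downstream), and Newton's method stalls on these cliffs
— we observed finite-difference gradients seven orders of magnitude above the
analytic ones at such points. Training-mode rollouts therefore pin the mask to
the initial presence pattern `1[s_0 > 0]`, which coincides exactly with the
recursive indicator for the absent species the constraint exists for, and
keeps the objective piecewise smooth. Inference-mode rollouts and the
single-step API use the fully recursive indicator.

**Unconstrained ablation.** `MiRNN(dims, constrained=False)` disables the
absence mask (the output ReLU is kept). On trajectories where every species
stays strictly positive, the two variants agree exactly.

## Bayesian training

Observations are modelled as `y = M(theta, q) + eps`, `eps ~ N(0, Sigma_y)`
i.i.d. across conditions and time points, with a zero-mean Gaussian prior with
precision `diag(alpha)` (scalar `alpha` by default, per-parameter vectors
supported). The MAP estimate minimises

    E(theta) = 1/2 sum_i r_i^T Sigma_y^{-1} r_i + 1/2 theta^T diag(alpha) theta

by Newton's method with the Gauss-Newton Hessian
`H = diag(alpha) + sum G_i^T Sigma_y^{-1} G_i`, Armijo backtracking
(c1 = 1e-4), and Levenberg-Marquardt damping escalated only when a full step
fails to descend. `H` is always positive definite thanks to the prior term, so
search directions are descent directions. Convergence: gradient infinity-norm
below `tol` (default 1e-5), or relative objective decrease below `ftol`
(default 1e-10) for three consecutive iterations — the second criterion
matters because the LeakyReLU kinks make the objective piecewise smooth and
the gradient need not vanish at a nonsmooth minimiser. Non-convergence is
returned as a flagged result with diagnostics, never a silent success.

**Which residuals enter.** For the constrained model, only species present at
t = 0 (plus all metabolites) enter the likelihood; their excluded rows are
identically zero anyway, so this is exact. For the unconstrained ablation the
full output vector enters, including the zero observations of absent species:
if those rows were dropped, the ablation's absent-species outputs would act as
unpenalised auxiliary latent state feeding back through the autoregression —
we measured that artifact inverting the constrained-vs-unconstrained
comparison before fixing the convention. Performance evaluation always scores
initially-present species only.

**Sensitivities.** The sensitivity matrix `G` (Jacobian of rolled-out outputs
with respect to `theta`) is computed by hand-coded exact forward-mode
differentiation through the recurrence, vectorised across conditions; tests
cross-check it against central finite differences (step 1e-6) to 1e-4
relative. The absence indicator is treated as locally constant, which is exact
almost everywhere and in particular for species that are exactly absent.

**Laplace posterior and predictive.** The posterior is approximated as
`N(theta_MAP, H^{-1})`. The linearised posterior predictive for a condition is
`N(M(theta_MAP, q), Sigma_y + G H^{-1} G^T)`: the sum of aleatory
(measurement) and epistemic (parameter) uncertainty. On models linear in
theta, MAP, Hessian, evidence and predictive all reduce to the closed-form
Bayesian linear-regression results; the test suite enforces agreement to 1e-8.

**Noise covariance.** `Sigma_y` is diagonal by default (full matrices are
supported throughout). It can be estimated by EM: alternate refitting
`theta_MAP` with updating each output's variance from the mean of squared
residuals plus the linearised epistemic term `diag(G H^{-1} G^T)`, flooring
diagonal entries at 1e-8. This update is a standard choice for
Laplace-approximate models; it recovers a known generative noise variance
within 20% in simulation.

**Prior precision.** `alpha` can be selected on training data by maximising
the Laplace evidence
`log p(D|alpha) = -E(theta_MAP) - 1/2 log det H + 1/2 sum log alpha + const`
over a grid (exact for linear models; the constant includes the Gaussian noise
normalisers so the linear case matches the analytic marginal likelihood).
`fit_posterior(..., alpha="evidence")` runs this selection over a default grid
{0.1, 1, 10, 100} with warm-started fits, and it is the default inside the
closed loop: the information-gain ranking depends on `H = alpha I + ...`
directly, and an under-regularised prior makes the EIG reflect raw sensitivity
magnitude rather than genuinely uncertain directions (measurably degrading the
exploration strategy's model accuracy). The cross-validation study fixes
`alpha = 1` for both model variants — the comparison is paired, so the choice
cancels — to keep its fold count affordable.

## Experimental design

The expected information gain of a prospective design `{q_1..q_n}` given the
current posterior precision `H` is approximated by the Bayesian D-optimality
log-determinant difference, computed in two algebraically equal forms:

* dense: `ln det(H + sum_i G_i^T Sigma_y^{-1} G_i) - ln det H`;
* fast: `sum_i ln det(I + Sigma_y^{-1} G_i A_{i-1}^{-1} G_i^T)` with
  `A_0 = H` and `A_i^{-1}` maintained via the Woodbury identity, so only
  `n_y x n_y` systems are solved and `H^{-1}` (computed once) is reused across
  candidate evaluations.

The property suite verifies equality to 1e-6 relative up to n_theta = 500,
along with non-negativity, monotone growth under added conditions, and
permutation invariance. During greedy selection the per-candidate increments
are evaluated in the whitened symmetric form
`sum log(1 + eig(L^{-1} M L^{-T}))` (`Sigma = L L^T`, `M = G A^{-1} G^T`) with
tiny negative eigenvalues clipped at zero; this is immune to the extreme
conditioning that arises when EM drives some noise variances to their floor.

**Acquisition and greedy search.** Designs are scored by
`f = profit + w_I * EIG`. The greedy batch search picks the
profit-maximising condition first; each later pick maximises
`profit + w_I * (incremental EIG given the batch so far)`, where candidates
already in the batch remain in the argmax and the exploration weight `w_I`
(initial 1e-4) is multiplied by 10 whenever the maximiser is a duplicate,
until a novel condition wins (escalations capped at 60, after which the best
novel candidate is taken). Ties break toward the lowest candidate index, so
reruns are deterministic. A design "condition" contributes the stacked
sensitivities of all its measurement times.

Four strategies are provided: `random` (seeded sample without replacement),
`explore` (EIG only; the first pick maximises the single-condition EIG),
`exploit` (profit only, duplicates excluded), and `explore_exploit` (the
combined acquisition above). Previously tested conditions are always excluded.

## The ground-truth bioreactor

A consumer-resource community in a fed-batch reactor (see
`mirnn.bioreactor` for the equations): resources enter via a feed of rate
u(t) and concentrations `r_f`, species grow by consuming resources
(consumption matrix `C`), and a single producer species converts growth into
the target metabolite (growth-associated kinetics, `y_ms`), which decays at
`k_d` and is diluted by the feed.

Random ecosystems: each species depends on each resource with probability
`p_s/r = 0.6`; dependency weights are Uniform(0,1), rows renormalised to sum
to one, and consumption rates drawn `N(Theta_ij, Theta_ij/10)` truncated at
zero; all-zero dependency rows are resampled (and logged). Rates are fixed at
`d = g = 0.01 /h`, `k_d = 0.005 /h`. The producer is the species depending on
the fewest resources, with yield 0.5 — this keeps the optimal feed a
*specific* resource subset rather than simply all resources.

Choices the source conditions leave open, fixed here and configurable:

* **Feed-profile catalog.** Piecewise-constant profiles on 5 equal intervals
  with rates from {0, 0.005, 0.01} L/h; a seeded permutation picks the
  requested number of distinct profiles (the all-zero profile is excluded).
  With 7 resources and 20 profiles the space has 20 x (2^7 - 1) = 2,540
  configurations and 12,700 conditions counting the 5 measurement times.
* **Initial conditions (fed-batch study).** V0 = 1 L, r(0) = 0 (the feed is
  the sole resource source, making the feed design the only control), s0 =
  0.01 g/L per species, m(0) = 0; feed concentrations 1 g/L per selected
  resource.
* **Batch-mode community datasets.** Random species subsets are simulated
  with u = 0 from equal inocula (0.01 g/L); here the initial resources are
  1 g/L each, since nothing is fed. These datasets expose species abundances
  only (metabolite recording is optional).

Integration uses LSODA with rtol 1e-8 / atol 1e-11, segment-by-segment over
the piecewise-constant feed intervals, with the state floored at zero between
segments and at recording; analytic limits (product decay, volume linearity,
resource decay) are matched to better than 1e-6 relative. Each recorded
species/metabolite observation at t > 0 is corrupted with 5% multiplicative
Gaussian noise and clipped at zero; inocula (t = 0) are set, not measured, and
stay exact.

**What the generator does not emulate.** Real community data have
non-Gaussian, abundance-dependent measurement error, compositional artefacts,
irregular sampling, taxa below detection limits and mechanisms beyond resource
competition (cross-feeding, pH coupling, phage). Passing the studies below
therefore shows that the estimator, the information-gain machinery and the
closed loop behave as designed under their own assumptions — not that the
model is adequate for any particular real microbiome.

## The closed loop

Each design-test-learn cycle: fit the posterior on all data so far
(warm-starting from the previous cycle's MAP; the noise covariance is
re-estimated by one EM pass each cycle), select a batch by the chosen
strategy, simulate the selected configurations with measurement noise as the
"experiment", append the data, and record metrics: best observed product so
far, and Pearson R / RMSE between model-predicted and noiseless true end-point
metabolite concentrations over the entire enumerated space.

Cross-validation partitions *conditions* (communities) into k folds per trial,
fits on k-1 folds, predicts the held-out fold from its initial state, and
pools each species' test predictions within a trial into one per-species
Pearson R and RMSE (original units, initially-present species only); per-trial
medians and interquartile ranges are reported.

## Reference study sizes

The three study presets in `mirnn.studies` are the package's desk-scale
defaults; the underlying generators default to the full study conditions
(50 communities of 5-of-20 species against 10 resources; 7 resources x 20
profiles = 2,540 configurations; 5% noise).

* **Sparsity study:** 30 communities, 5-fold CV, 3 trials, 16 -> 8 latent
  units. Reports pooled per-species median R for the constrained and
  unconstrained variants.
* **Strategy study:** 5 species x 7 resources, 20 feed profiles — the full
  2,540-configuration space. Batches of 5 after 5 random initial
  configurations, 10 replicates per strategy against one shared ecosystem,
  8 latent units. Random and explore+exploit run 3 cycles (they carry the
  best-product comparison); explore and exploit run one cycle, which is all
  the post-first-design model-accuracy comparison requires. The space size
  matters scientifically: information-guided selection pays off when a batch
  covers only a small fraction of the candidate space, whereas in spaces of a
  few hundred configurations ten random picks already provide near-uniform
  coverage and random sampling's model accuracy is competitive with directed
  exploration. Reports per-strategy medians of best observed product and of
  model R after the first designed batch.
* **Calibration study:** 5 seeds; per seed a fresh ecosystem, 20 training and
  10 held-out configurations; held-out log-likelihood under the
  condition-dependent predictive covariance versus the fixed noise covariance.

These sizes were chosen so the full acceptance run completes comfortably on a
single core while each directional comparison retains a clear margin; all of
them are keyword arguments and scale up directly.

## Known limitations

* The Laplace/linearisation chain assumes the posterior and predictive are
  approximately Gaussian; strongly multimodal posteriors (small data, flexible
  network) are summarised by a single mode. Multi-restart MAP fitting is
  available (`n_restarts`).
* The EM update for `Sigma_y` is a standard residual-moment-plus-epistemic
  scheme, not derived from any particular reference implementation.
* Greedy batch selection is a heuristic; the test suite checks it attains the
  exhaustive-enumeration optimum on small instances where greedy optimality
  holds, not in general.
* The discrete-time model requires uniformly spaced observations; irregular
  grids are rejected at ingest.
* Training is full-batch Newton; the intended regime is the
  low-data experimental-design loop (tens to hundreds of conditions), not
  large datasets.
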