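# Methods

## The model

`dihsmm` models the choices of an animal learning a two-alternative
forced-choice visual task as arising from a small set of latent behavioral
states.  The observed record is a trial table: sessions of trials, each with
a stimulus contrast on the left or right side (from the set
{1, 0.5, 0.25, 0.125, 0.0625, 0}, weaker contrasts introduced gradually over
sessions) and a response `L`, `R`, or `timeout`.

**Emissions.**  Given its state, a trial's response is Bernoulli in a
logistic regression over four features: transformed left contrast,
transformed right contrast, a perseveration regressor, and a constant bias,

    P(y = R) = sigmoid(f · w_{x, n}),

where `x` is the trial's state and `n` its session.  Contrasts are mapped
through `c~ = tanh(p c) / tanh(p)` with steepness `p = 5`, which compresses
the two easiest stimuli onto nearly the same input (1 and 0.987) to reflect
their near-identical psychophysical difficulty; an alternative lookup
parameterization (1, 0.899, 0.705, 0.416, 0.207, 0) is available.  The
perseveration feature is an exponentially decaying average of previous
choices within the session (decay 0.25; `L = -1`, `R = +1`, timeouts 0,
normalised so a constant history saturates at ±1).  Timeout trials carry no
emission likelihood but keep their slot in the state sequence and in the
perseveration history.

**States and durations.**  Within a session, states form a hidden
semi-Markov chain.  The first segment's state is drawn from `pi0`,
subsequent segments from the previous state's transition row with the
diagonal removed and renormalised (self-transitions prohibited).  Segment
durations are `1 + NB(r_i, p_i)` — support on {1, 2, ...}; `r = 1` would
recover the geometric law of a plain HMM, and the prior `r ~ U(5..704)`
excludes small values so states track behavior over many trials rather than
stimulus statistics.  The final segment of a session is truncated at the
session end and treated as right-censored during inference.

**Transition prior.**  The transition rows share a hierarchical Dirichlet
process prior, used throughout in its weak-limit form with cap `L = 15`:
`beta ~ Dir(gamma/L, ...)`, `pi_i ~ Dir(alpha beta)`, with vague
`Gamma(0.01, 0.01)` priors on both concentrations.  `pi0 ~ Dir(3/L, ...)` is
drawn outside the hierarchy.

**Weight dynamics.**  Each state's weights take a Gaussian random walk
across sessions (`w_1 ~ N(0, 8 I)`, `w_{n+1} ~ N(w_n, sigma I)` with
`sigma = 0.04`, a value set by cross-validation, not inferred).  A state
with no assigned trials in a session keeps its weights fixed across the next
transition, so absent states do not diffuse.  The walk is the model's "slow
process"; the appearance of a new state is the "fast process".

## Inference

Gibbs sampling, one sweep resampling in a fixed order:

1. **Segmentations** — exact forward-filter backward-sample over semi-Markov
   messages per session, in the log domain, durations truncated at the
   session length and the final duration right-censored.  The kernels are
   numba-compiled.
2. **Duration parameters** — censored final durations are completed by a
   draw from the truncated negative binomial under the current `(r, p)`;
   `r` is then drawn by enumerating its 700-point support with `p`
   integrated out (Beta–negative-binomial conjugacy), and `p | r` from its
   Beta conditional.
3. **Transition structure** — each observed segment transition is
   interpreted as rejection sampling from the full row, so the diagonal is
   augmented with a negative-binomial count of virtual self-draws (capped at
   10^6 as a numerical guard); rows are then conjugate Dirichlet draws, and
   `beta` is updated through Chinese-restaurant-franchise table counts
   (exact Bernoulli construction; a clipped normal approximation above 10^5
   customers).
4. **Concentrations** — `gamma | beta` and `alpha | beta, pi` are
   one-dimensional densities, sampled on a 600-point log grid spanning
   1e-4..1e4 with a uniform draw within the selected cell.  This is the
   exact conditional of the weak-limit model up to discretization.
5. **Weights** — Pólya-Gamma augmentation per state: one `PG(1, f·w)` draw
   per assigned response trial turns the logistic likelihood into Gaussian
   pseudo-observations; a Kalman filter runs across sessions (process noise
   `sigma I` after occupied sessions, zero after unoccupied ones) and the
   trajectory is sampled backward.  The PG sampler is an in-package
   Devroye-type rejection sampler (exact; validated against the moment
   identity `E[PG(b,c)] = b tanh(c/2)/(2c)` and against a dense grid
   posterior).

Chains are initialised at random contiguous segmentations with prior-drawn
weights, and every source of randomness flows through one
`numpy.random.Generator` per chain, seeded from a root `SeedSequence`, so
runs are reproducible and chains restartable (carrying the generator forward
continues a chain bit-exactly).  Full-scale defaults are 16 chains of 48,000
sweeps, burn-in 4,000, thinning 25 (1,760 stored samples per chain).

Numerical guards worth knowing about: Dirichlet parameters carry a symmetric
floor of 1e-3 (degenerate draws with vague concentrations otherwise produce
exact zeros); probabilities are clipped at 1e-300 before logs; the backward
messages use a max-shift log-sum-exp.

## Aggregation

State labels are arbitrary and switch within and across chains, so states
are defined by trial co-occupancy rather than labels:

* **Screening** — R-hat (plain, folded, rank-normalized; chains not split)
  on label-independent scalars: alpha, gamma, trial counts of the two
  largest states, and the numbers of states holding >10% and >20% of
  trials.  Chains are greedily discarded (the removal that lowers the max
  R-hat most) down to at least half, and processing requires max R-hat
  < 1.05.  R-hat is floored at 1 so duplicated chains report exactly 1.
* **Mode finding** — trials are cut into 200 contiguous bins ignoring
  session boundaries; per sample, bin-level similarity
  `sum_i (1 - |p_{t,i} - p_{m,i}|)` over within-bin state proportions; the
  flattened matrices are embedded by PCA (3 components) and modes found by
  Gaussian-mixture density estimation with BIC over 1..4 components, keeping
  components of at least 400 samples (the original procedure selected modes
  by hand; the mixture automates it).  The largest mode is analysed.
* **Clustering** — full-resolution co-occupancy averaged over the mode's
  samples (running single-precision mean); `1 - C` is a distance;
  complete-linkage clustering cut at 0.95, so every pair within a cluster
  shares a state in at least 5% of samples.  Clusters below 1% of trials
  count as unassigned; states are numbered by first appearance.  Per-trial
  connectedness is the mean co-assignment with the rest of the cluster
  (singletons: 1 by convention).
* **PMFs** — per sample and session, the psychometric functions of the
  sample's own states are averaged weighted by how many of the cluster's
  trials each owns, then evenly across samples.  PMFs are evaluated with the
  perseveration feature at zero.

## Classification

A state's easy-trial reward rate (mean P(correct) at signed contrasts ±1 and
±0.5; 0% trials excluded) types it per session: < 0.60 type 1 (flat), < 0.78
type 2 (one-sided), else type 3 (fully tuned).  Type 2 splits into
symmetric (100%-contrast error rates within 10 points) or left-/right-biased
by the mean of the PMF.  The animal's stage on a session is the highest type
ever used for a strict majority (>50%) of any session's non-timeout trials —
monotone by construction.  State introductions (excluding each animal's
first state) are reported at normalised training and session positions,
`(index - 1) / (count - 1)`.  Slow changes compare a state's weights at its
first and last appearance (only states present 5–15 sessions); fast changes
compare a new state's weights with the nearest previously existing state,
where nearness is the 1-Wasserstein distance between PMF curves on the
signed-contrast grid (mean absolute difference of P(R); the metric's
construction on a discrete grid is a package choice, recorded here), with
bias deltas split by starting sign so they do not cancel.

## Validation

* **Cross-validation** — tenfold, masking ~10% of each session's trials;
  masked trials keep their duration slot with emission likelihood 1
  (missing-at-random), and fits are scored by summed negative log predictive
  likelihood, averaging per-trial probabilities across samples before the
  log.
* **Posterior predictive checks** — each mode sample free-runs every session
  three times, initialised with the sample's own first-trial state (the
  initial distribution is static); percent correct per session and percent
  rightward per contrast are located as percentiles in the simulated
  distribution.
* **Recovery** — scenarios with known ground truth: one static state; one
  state drifting in constant per-session steps of variance 0.0311 fitted
  with sigma = 0.03; the same drift applied per trial (outside the model
  class); 2–9 planted states; implausible PMFs.  Fits use scaled-down
  chains, and results are compared by cluster count, dominant-cluster
  coverage, adjusted Rand index against the planted assignment, and
  per-session PMF error evaluated on the contrasts introduced by each
  session.

## What the synthetic generator does and does not emulate

The generator reproduces the structure the model assumes: staggered contrast
introduction (easiest first, full set from session 9), uniform sides,
random rewarded side on 0% trials, latent states with explicit durations,
session-to-session weight drift, Bernoulli choices with online perseveration,
and rare timeouts (1% by default).  It does not emulate the debiasing
protocol's stimulus-repetition contingency, performance-dependent session
termination, motivational drift within sessions, or any reaction-time
structure.  Passing recovery tests therefore show that the inference
machinery identifies models of this class from realistic amounts of data;
they do not show that real mice are described by the model — that evidence
comes from held-out likelihood and predictive checks on real data, which are
out of scope here.

## Problem sizes used by the test suite

Recovery tests run at desk scale as a package choice: 2 chains of 1,000
sweeps (burn-in 300, thinning 2, 700 stored samples), state cap L = 8,
15 sessions x 300 trials for the single-state scenarios and 10 x 250 for
three states.  At this scale the R-hat screen is advisory (two chains cannot
be meaningfully pruned), so the recovery harness records the screening
outcome without gating on it.  The oracle tests use exhaustive enumeration
at L = 2, T = 6 (64 segmentations), a 4,001-point grid posterior for the
augmented weight sampler, and 3,000 prior-reproduction sweeps on a
timeout-only dataset.

## Known limitations

* The weak-limit concentration conditionals are exact only up to the log
  grid; extremely large or small concentrations (outside 1e-4..1e4) are
  unreachable.
* The diagonal augmentation can transiently propose astronomical
  self-transition counts when a row's self-mass approaches 1; the cap (1e6)
  truncates a vanishing tail but technically perturbs the conditional.
* Mode finding with a BIC-selected Gaussian mixture can split one broad
  posterior mode into overlapping components on small sample sets; the
  largest component is then a conservative subset.
* `sigma` is fixed, not inferred; the package deliberately provides no
  inference over it.
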