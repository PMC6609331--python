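# Model and methods

## The encoding model

Odors are nonnegative concentration vectors **s** over N = 150 monomolecular
odorant channels; natural odors are K-sparse (default K = 5) and an odor's
*identity* is its support, intensity a common scale factor.  The baseline
component scale is s0 = 1 a.u.; all concentrations in the package are in
these units.

Each of M = 50 ORN types expresses one receptor forming a two-state
(active/inactive) channel with the co-receptor Orco.  With binding in
quasi-equilibrium the active fraction is

    A_a = [ 1 + exp(eps_a) * ((1 + K_a·s) / (1 + K*_a·s))^R ]^(-1)

where `K*_a`, `K_a` (1/a.u.) are the active/inactive-conformation affinity
vectors (agonists only: K* > K), `eps_a` (kT units) is the free-energy
difference between the unbound conformations, and R is the number of
independent binding sites (default 1; the multi-site generalization
multiplies the log-binding term by R).  The expression is evaluated with
`log1p` so arbitrarily high concentrations cannot overflow.

Adaptation is an integral feedback of activity on the free energy,

    tau * d(eps_a)/dt = A_a - A0_a,     eps_L,a <= eps_a <= eps_H,a

with tau = 250 ms and common target A0 = 0.1 (a randomized per-ORN variant,
A0_a ~ U(0.05, 0.15), is available).  On a static odor the fixed point is

    eps_a(sbar) = ln[(1-A0)/A0] - (1 - beta_a) * R * ln((1 + K_a·sbar)/(1 + K*_a·sbar)),

clipped to the bounds.  beta = 0 is exact Weber-Fechner adaptation (the
unclipped fixed point restores A = A0 identically and the gain scales as
A0(1-A0)/sbar); beta = 1 leaves the free energy at its unbound value, which
the calibration places below every eps_L, so "beta = 1" and "free energies
pinned at the floor" coincide.  Note the *relaxation* time near the fixed
point is tau / (A0(1-A0)) ≈ 2.8 s, an order of magnitude above tau itself;
simulations that must reach the fixed point integrate for ≥ 30 s.

Firing is the activity passed through a bi-lobed difference-of-gammas
filter, `h(t) = 190·Gamma(2, 12 ms).pdf − 1.33·Gamma(3, 16 ms).pdf`, and a
linear rectifier with a 5 Hz floor.  The filter's DC gain is 188.67 Hz per
unit activity, so a statically adapted ORN fires at A0·188.67 ≈ 18.9 Hz.
The kernel is discretized by gamma-CDF increments (exact bin averages), so
its discrete sum reproduces the DC gain at any step size; dynamic
simulations use the Euler method at 2 ms steps (halving the step changes
the final free energies by < 1e-6 relative).

## Parameter choices the data do not fix

* **Affinity distribution.**  Dissociation constants KD = 1/K* follow a
  power law p(KD) ∝ KD^(-0.35).  The sampled *range* is two decades
  straddling s0 (KD in [0.1, 10]).  This is a deliberate narrowing from a
  wider literature range: with four decades of per-pair spread, each
  odorant is effectively sensed by a single ORN (measurement-column
  coherence ≈ 0.86) and sparse reconstruction of K = 5 odors is impossible
  even with exact linear constraints (< 15% recovery); two decades keep
  several ORNs comparably sensitive per odorant (coherence ≈ 0.68, ~100%
  clean recovery) — the premise of a combinatorial code.  The inactive
  affinity is K = 1e-6·K*, keeping the sensitive window 1/K* << s << 1/K
  about six decades wide.  Five ORNs receive one "private" high-affinity
  entry (K* = 1e4).
* **Free-energy bounds.**  eps_L,a ~ Normal(4.0, 0.5), truncated to the
  window obtained by inverting the DC gain so spontaneous rates land in
  1–10 Hz.  eps_H,a = eps_L,a + 4·ln 10: adaptation can track backgrounds
  over about four decades of intensity before saturating — the headroom
  that defines the "adaptive tracking range" used to position several study
  conditions below.
* **Rate precision.**  Where an analysis needs a finite response precision
  (information estimates, classification), rates carry additive Gaussian
  jitter with sd 1 Hz, matching the 1 Hz bin width of the information
  analysis.  CS decoding is noiseless: there the intended failure mode is
  linearization error, absorbed by the lax 25%/10% success tolerances.

## Synthetic environments

`sample_sparse_odor` draws a uniform support and component values
s0 + ds with ds ~ Normal(s0/3, s0/9) (clipped at zero).  Sigmoid pulses are
logistic with the 1–99% rise spanning twice the half-max time (50 ms
default).  The plume emulator is an alternating whiff/blank renewal
process: durations from a truncated power law with exponent −3/2 on
[0.05 s, 10 s] (blank bounds rescaled so the long-run whiff fraction hits a
target intermittency, default 0.35 — the mean of that law on [a, b] is
sqrt(ab), which makes the rescaling closed-form); within-whiff intensity is
threshold + LogNormal(ln 4, 1), constant per whiff, so every whiff sample
strictly exceeds the 4 a.u. detection threshold.  The emulator reproduces
the statistics the analyses consume — intermittent whiffs with broadly
distributed durations and intensities — and nothing else: no spatial
structure, no within-whiff filaments, no concentration autocorrelation
beyond the renewal structure, and a single fluctuating identity.  Passing
tests therefore speak to coding under intermittency and intensity spread,
not to full plume physics.

## Mutual information

MI between foreground identity and the M-dimensional rate vector is
H_response − H_noise with P(r|s) taken over backgrounds, a 1 Hz Gaussian
jitter and 1 Hz bins.  Naively counting jittered binned vectors is
degenerate — in 50 dimensions every sample is unique at any feasible size,
pinning the estimate at log2(n_foregrounds) regardless of the code — so
the estimator integrates the jitter analytically (per-bin Gaussian masses,
conditionals as equal-weight mixtures over backgrounds) and estimates both
entropies by Monte-Carlo draws from those mixtures (default 4 draws per
response).  With the jitter disabled the estimator reduces to exact
plug-in counting.  Estimates remain biased at these sample sizes; the bias
is shared by every condition compared, and only differences and orderings
are interpreted.

The default ensemble presents each of 10 foreground identities at a fixed
reference intensity (30·s0, mid dynamic range) atop 50 backgrounds whose
intensities are log-uniform on (10, 3e4)·s0 — a sweep spanning both
systems' failure envelopes: the adaptive system tracks to ~1.3e4·s0 (the
eps_H headroom), the non-adaptive one saturates one to two decades
earlier.  Designs with foreground intensity yoked to the background make
discrimination trivially easy at every beta and were rejected.

## Compressed-sensing decoding

The decoder works with the linearization D_ai = dc_gain · dA_a/ds_i at a
known operating point and solves min ||Δs||_1 s.t. Δr = D Δs (split-variable
LP, scipy HiGHS).  Constraint rows are those whose *measured* rate clears
the 5 Hz rectifier; the baseline prediction on those rows is the decoder's
own unrectified model rate.  In the static experiments the operating point
is the background alone (known to the decoder; adaptive: the beta = 0
adapted state, non-adaptive: the floors) and the decoded perturbation is
the full K-sparse foreground — not small, so linearization error is the
intrinsic failure mode, absorbed by the success tolerances (every true
component within 25%, every zero component below 0.1·s0).

Temporal decoding of plume signals replaces the signed-increment program
with the total-signal form min Σ s_i s.t. s ≥ 0 (nonnegative basis
pursuit), linearized at the decoder's trailing memory estimate — the mean
of its own decoded signal over the last tau_M seconds; where the
linearized equalities are inconsistent on the nonnegative cone (far from
the operating point), a nonnegative least-squares step substitutes.  One
decode pass per time step: the memory, not within-step iteration, carries
background knowledge — with multi-pass re-linearization the decoder
re-derives the background from scratch each step and the tau_M dependence
disappears.  A whiff counts as decoded if the full concentration vector
meets the success criterion at one or more decode times inside it.

IHT decodes through the nonlinear response map directly:
x ← H_K(x + mu·Ĵ_xᵀ(y − F(x))) with unit-normalized Jacobian columns,
mu = 0.5 with halving on residual growth, initialized at zero.  RIP
diagnostics record the extreme eigenvalues of unit-column k-sparse Gram
submatrices of D at random k-sparse operating points.

## Primacy analysis

Activation onset is the first time a rate (for background contexts: the
odor-evoked increment over the adapted background rate) sustains the 5 Hz
rectifier floor; ties break toward the lower ORN index.  The primacy set
of order p is the unordered set of the p earliest onsets.  The
decoding-defined primacy order is the number of active ORNs at the first
time the CS decoder succeeds along a sigmoidal rise.  Consistency across
backgrounds: the nominal set holds the p most frequently occurring ORNs
over background-specific primacy sets, and consistency is their mean
occurrence percentage.  Default condition: odor and backgrounds at
30·s0 — strong enough that an unadapted repertoire begins to saturate,
which is what scrambles its primacy sets.

## Circuit classification

PN rates follow divisive normalization
PN_a = Rmax·r^n/(r^n + sigma^n + (m·Σr)^n) with Rmax = 165 Hz, n = 1.5,
sigma = 12 Hz, m = 0.05 — a saturating Hill form with exponent 1.5 on the
scale of AL gain-control measurements; the specific constants are model
choices.  2500 KCs each draw 7 distinct glomeruli with weights
N(0, 1/7); KC thresholds are set per cell to the 90th percentile of its
claw input over the training batch (~10% activation sparseness).  Only the
readout (logistic for 2 classes, softmax otherwise; unpenalized lbfgs,
default cap 100 iterations, 75 in the budgeted acceptance script) is
trained.

The generalization task: NID sparse identities at concentrations
log-uniform over four decades centered at 100·s0 (the middle of the
adaptive tracking range), 10 train + 10 test concentrations per identity,
disjoint.  All samples ride atop a weak static ambient odor (a K-sparse
identity at 10·s0) — the environment the adaptive system has adapted to.
This ambient-context design matters: adapting each sample to its *own*
identity at its mean level cancels the identity pattern exactly in the
Weber regime (the response becomes a function of relative intensity only)
and destroys the code; adapting to a shared ambient repositions each ORN's
dynamic range ORN-specifically while leaving the identity information
intact.  Without adaptation the free energies stay at their floors and the
upper decades of the span drive the sensitive ORNs into saturation, which
the 1 Hz rate jitter then makes irrecoverable.  Valence classification
assigns each identity a random fixed ±1 label.

## Scale choices

Desk-scale defaults keep every pipeline in minutes on one core: 25–50
backgrounds instead of 1000 for MI and primacy ensembles, 10–20 identity
pairs per decoding-grid cell, 200 RIP draws, NID = 100–200 for
classification sweeps (the acceptance script runs the full NID = 1000).
The test suite integrates the adaptation ODE for 30 s where fixed-point
convergence is asserted and uses an M = 10 repertoire for dynamics-heavy
checks.

## Known limitations

* Agonists only: no inhibitory odorants, antagonism, odorant-binding
  proteins, or ephaptic coupling; one chemoreceptor family.
* The quasi-steady-state binding assumption is kept throughout; no spike
  generation or ORN noise model beyond the 1 Hz rate-precision convention.
* Perfectly adaptive (beta = 0) codes are exactly scale-invariant, so any
  experiment in which each stimulus is also its own adaptation context is
  degenerate by construction; analyses must (and here do) separate the
  adapted context from the probe stimulus.
* The L1 decoder is exact basis pursuit: near the sparse-recovery phase
  transition (e.g. K = 3 with 10 measurements of 20 unknowns) it can
  legitimately return a sparser vector than the truth; this is a property
  of L1 recovery, not of the implementation.
* Plug-in/Monte-Carlo MI values carry small-sample bias and are only
  compared across conditions, never interpreted absolutely.
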