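"""Adaptive ORN encoding model.

Each of M olfactory receptor neuron (ORN) types expresses one receptor that
forms a two-state (active/inactive) ligand-gated channel with the universal
co-receptor Orco.  With binding in quasi-steady state, the active fraction of
channels of type ``a`` facing odor ``s`` is

    A_a = [1 + exp(eps_a + R * ln((1 + K_a . s) / (1 + K*_a . s)))]^(-1)

where ``K*_a`` and ``K_a`` are the active- and inactive-conformation binding
affinity vectors (only agonists: K* > K), ``eps_a`` is the free-energy
difference (in kT) between the inactive and active unbound conformations,
and ``R`` is the number of independent binding sites per complex (R = 1 is
the single-site model).

Adaptation is an integral feedback of channel activity onto ``eps_a``::

    tau * d(eps_a)/dt = A_a(t) - A0_a,      eps_L,a <= eps_a <= eps_H,a

driving activity back to the target ``A0_a`` (~0.1).  At steady state on a
static odor ``sbar`` the free energy sits at

    eps_a(sbar) = ln[(1 - A0_a)/A0_a] - (1 - beta_a) ln((1 + K_a . sbar)/(1 + K*_a . sbar))

where ``beta_a`` interpolates between exact Weber-Fechner gain scaling
(beta = 0: gain ~ 1/sbar) and no adaptation (beta = 1).  The lower bound
``eps_L,a`` sets the spontaneous activity; the upper bound ``eps_H,a`` sets
where adaptation gives out and the neuron saturates.

Firing is a linear-nonlinear cascade: the activity is convolved with a
stereotyped bi-lobed (derivative-taking) filter ``h`` -- a difference of two
gamma densities -- and passed through a linear rectifier with a 5 Hz floor.
The filter's DC gain (integral of ``h``) maps a constant activity ``A`` to a
steady rate ``A * (A_amp - B_amp)`` Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import expit
from scipy.stats import gamma as gamma_dist, truncnorm

from .stimuli import SparseOdor, StimulusTrace, sample_truncated_power_law

__all__ = [
    "ReceptorRepertoire",
    "AdaptationParams",
    "FiringFilter",
    "ORNState",
    "sample_repertoire",
    "sample_adaptation_params",
    "channel_activity",
    "steady_state_epsilon",
    "integrate_encoder",
    "firing_rate",
    "steady_response",
    "steady_rates",
]

M_ORN_TYPES = 50

#: Power-law exponent of the dissociation-constant distribution measured
#: across receptor-odorant pairs.
KD_POWER_LAW_ALPHA = 0.35
#: Dissociation constants are sampled over two decades straddling the
#: baseline component scale s0 = 1 a.u.  A wider spread makes each odorant
#: effectively private to its single most-sensitive ORN (near-parallel
#: measurement columns), destroying the combinatorial code the repertoire
#: is meant to carry; two decades keep several ORNs comparably sensitive
#: to every odorant.
KD_RANGE = (1e-1, 1e1)
#: Inactive-state affinity as a fraction of the active-state affinity; small
#: so that the sensitive regime 1/K* << s << 1/K stays wide.
WEAK_AFFINITY_RATIO = 1e-6


@dataclass(frozen=True)
class ReceptorRepertoire:
    """Binding affinities of an M-type ORN repertoire over N odorants.

    ``kstar`` and ``kweak`` are (M, N) affinity matrices (1/a.u.) for the
    active and inactive channel conformations; agonists only, so
    ``kstar > kweak >= 0`` elementwise.  ``r_sites`` is the number of
    independent binding sites per channel complex.
    """

    kstar: np.ndarray
    kweak: np.ndarray
    r_sites: int = 1
    alpha: float = KD_POWER_LAW_ALPHA
    private_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        ks = np.asarray(self.kstar, dtype=float)
        kw = np.asarray(self.kweak, dtype=float)
        object.__setattr__(self, "kstar", ks)
        object.__setattr__(self, "kweak", kw)
        if ks.shape != kw.shape or ks.ndim != 2:
            raise ValueError("kstar and kweak must be matching (M, N) matrices")
        if self.r_sites < 1:
            raise ValueError("r_sites must be >= 1")
        if np.any(kw < 0) or not np.all(np.isfinite(ks)):
            raise ValueError("affinities must be finite and nonnegative")
        if np.any(ks <= kw):
            raise ValueError("agonists only: require kstar > kweak everywhere")

    @property
    def m(self) -> int:
        return self.kstar.shape[0]

    @property
    def n(self) -> int:
        return self.kstar.shape[1]


@dataclass(frozen=True)
class AdaptationParams:
    """Adaptation targets, bounds and Weber-breaking exponents.

    ``a0`` is the adapted-activity target (scalar or per-ORN), ``beta`` the
    Weber-breaking exponent in [0, 1] (0 = exact Weber-Fechner scaling,
    1 = no adaptation), ``eps_low``/``eps_high`` the per-ORN free-energy
    bounds (kT), and ``tau`` the adaptation time constant (s).
    """

    eps_low: np.ndarray
    eps_high: np.ndarray
    a0: np.ndarray | float = 0.1
    beta: np.ndarray | float = 0.0
    tau: float = 0.25

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.eps_low, dtype=float))
        hi = np.atleast_1d(np.asarray(self.eps_high, dtype=float))
        object.__setattr__(self, "eps_low", lo)
        object.__setattr__(self, "eps_high", hi)
        if np.any(lo >= hi):
            raise ValueError("eps_low must be strictly below eps_high")
        a0 = np.asarray(self.a0, dtype=float)
        if np.any(a0 <= 0) or np.any(a0 >= 1):
            raise ValueError("a0 must lie in (0, 1)")
        beta = np.asarray(self.beta, dtype=float)
        if np.any(beta < 0) or np.any(beta > 1):
            raise ValueError("beta must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def m(self) -> int:
        return self.eps_low.size

    def with_beta(self, beta: np.ndarray | float) -> "AdaptationParams":
        return replace(self, beta=beta)


@dataclass(frozen=True)
class FiringFilter:
    """Bi-lobed temporal filter and rectifier of the firing cascade.

    ``h(t) = A_amp * Gamma(alpha1, tau1).pdf(t) - B_amp * Gamma(alpha2, tau2).pdf(t)``;
    both lobes integrate to their amplitudes, so the DC gain is
    ``A_amp - B_amp`` (Hz per unit activity).  The rectifier zeroes rates
    below ``rect_threshold``.
    """

    a_amp: float = 190.0
    b_amp: float = 1.33
    alpha1: float = 2.0
    alpha2: float = 3.0
    tau1: float = 0.012
    tau2: float = 0.016
    rect_threshold: float = 5.0

    @property
    def dc_gain(self) -> float:
        return self.a_amp - self.b_amp

    def kernel(self, dt: float, t_max: float = 0.3) -> np.ndarray:
        """Sampled kernel on [0, t_max); both gamma tails are negligible there.

        Samples are bin averages (gamma CDF increments over each dt bin), so
        the discrete sum times dt reproduces the continuous integral -- and
        hence the DC gain -- to the truncation tail, at any dt.
        """
        edges = np.arange(0.0, t_max + dt, dt)
        pos = np.diff(gamma_dist.cdf(edges, self.alpha1, scale=self.tau1)) / dt
        neg = np.diff(gamma_dist.cdf(edges, self.alpha2, scale=self.tau2)) / dt
        return self.a_amp * pos - self.b_amp * neg

    def rectify(self, rates: np.ndarray) -> np.ndarray:
        out = np.asarray(rates, dtype=float).copy()
        out[out < self.rect_threshold] = 0.0
        return out


@dataclass
class ORNState:
    """Per-ORN traces from an encoder run: free energy, activity, rates."""

    times: np.ndarray
    eps: np.ndarray       # (T, M), kT
    activity: np.ndarray  # (T, M), in (0, 1)
    rates: np.ndarray     # (T, M), Hz, rectified


# ---------------------------------------------------------------------------
# sampling


def sample_repertoire(
    m: int = M_ORN_TYPES,
    n: int = 150,
    alpha: float = KD_POWER_LAW_ALPHA,
    n_private: int = 5,
    rng: np.random.Generator | None = None,
    kd_range: tuple[float, float] = KD_RANGE,
    weak_ratio: float = WEAK_AFFINITY_RATIO,
    r_sites: int = 1,
    private_kstar: float = 1e4,
) -> ReceptorRepertoire:
    """Sample an ORN repertoire with power-law distributed sensitivities.

    Dissociation constants ``KD = 1/K*`` are drawn from ``p(KD) ~ KD**(-alpha)``
    on ``kd_range``; the inactive-state affinity is a small constant fraction
    of the active-state one.  ``n_private`` distinct ORNs each receive one
    very large ``K*`` entry, mimicking high responders to private odorants.
    """
    if rng is None:
        rng = np.random.default_rng()
    if m < 1 or n < 1 or alpha <= 0:
        raise ValueError("need m, n >= 1 and alpha > 0")
    kd = sample_truncated_power_law(alpha, kd_range[0], kd_range[1], m * n, rng)
    kstar = (1.0 / kd).reshape(m, n)
    private: list[tuple[int, int]] = []
    if n_private > 0:
        orns = rng.choice(m, size=min(n_private, m), replace=False)
        for a in orns:
            i = int(rng.integers(n))
            kstar[a, i] = private_kstar
            private.append((int(a), i))
    kweak = kstar * weak_ratio
    return ReceptorRepertoire(kstar, kweak, r_sites, alpha, tuple(private))


def sample_adaptation_params(
    m: int = M_ORN_TYPES,
    rng: np.random.Generator | None = None,
    filt: FiringFilter | None = None,
    spontaneous_range: tuple[float, float] = (1.0, 10.0),
    eps_low_mean: float = 4.0,
    eps_low_sd: float = 0.5,
    adaptation_decades: float = 4.0,
    a0: float | None = 0.1,
    beta: float = 0.0,
    tau: float = 0.25,
) -> AdaptationParams:
    """Sample per-ORN free-energy bounds.

    ``eps_low`` is normal (mean 4, sd 0.5 kT), truncated to the window
    obtained by inverting the firing cascade's DC gain so that spontaneous
    rates ``dc_gain / (1 + exp(eps_low))`` land in 1-10 Hz.  ``eps_high`` is
    set ``adaptation_decades * ln(10)`` above ``eps_low``: adaptation tracks
    backgrounds over about that many decades of intensity before saturating.
    With ``a0=None``, per-ORN targets are drawn uniformly in [0.05, 0.15]
    (the randomized-target variant); the default is a common target of 0.1.
    """
    if rng is None:
        rng = np.random.default_rng()
    filt = filt or FiringFilter()
    # invert r = dc_gain / (1 + e^eps) at the ends of the spontaneous window
    lo_rate, hi_rate = spontaneous_range
    eps_min = np.log(filt.dc_gain / hi_rate - 1.0)
    eps_max = np.log(filt.dc_gain / lo_rate - 1.0)
    a, b = (eps_min - eps_low_mean) / eps_low_sd, (eps_max - eps_low_mean) / eps_low_sd
    eps_low = truncnorm.rvs(a, b, loc=eps_low_mean, scale=eps_low_sd,
                            size=m, random_state=rng)
    eps_high = eps_low + adaptation_decades * np.log(10.0)
    a0_val: float | np.ndarray
    a0_val = rng.uniform(0.05, 0.15, size=m) if a0 is None else a0
    return AdaptationParams(eps_low, eps_high, a0_val, beta, tau)


# ---------------------------------------------------------------------------
# core model


def _as_conc(s) -> np.ndarray:
    if isinstance(s, SparseOdor):
        return s.concentrations
    return np.asarray(s, dtype=float)


def binding_free_energy(s, repertoire: ReceptorRepertoire) -> np.ndarray:
    """R * ln((1 + K.s) / (1 + K*.s)) for every ORN; shape (..., M).

    Evaluated in log space (log1p of the two binding polynomials) so high
    concentrations cannot overflow.
    """
    conc = _as_conc(s)
    weak = np.log1p(conc @ repertoire.kweak.T)
    strong = np.log1p(conc @ repertoire.kstar.T)
    return repertoire.r_sites * (weak - strong)


def channel_activity(
    s,
    eps,
    repertoire: ReceptorRepertoire,
    orn: int | None = None,
) -> np.ndarray | float:
    """Steady-state active channel fraction A in (0, 1).

    ``s`` may be a :class:`SparseOdor`, an (N,) vector or a (B, N) batch;
    ``eps`` a scalar, (M,) vector or matching batch.  With ``orn`` given,
    returns the activity of that single ORN type.
    """
    f = binding_free_energy(s, repertoire)
    eps = np.asarray(eps, dtype=float)
    if not np.all(np.isfinite(eps)):
        raise ValueError("eps must be finite")
    act = expit(-(eps + f))
    if orn is not None:
        act = act[..., orn] if act.ndim else act
    return float(act) if np.ndim(act) == 0 else act


def steady_state_epsilon(
    sbar,
    params: AdaptationParams,
    repertoire: ReceptorRepertoire,
    beta: np.ndarray | float | None = None,
    clip: bool = True,
) -> np.ndarray:
    """Adapted free energy on a static background; shape (..., M).

    ``ln[(1 - A0)/A0] - (1 - beta) * ln((1 + K.sbar)/(1 + K*.sbar))``,
    clipped to the per-ORN bounds unless ``clip=False``.  ``beta=1`` gives
    the stimulus-independent (non-adapting) value; ``beta=0`` exact
    Weber-Fechner adaptation, for which the unclipped value restores the
    activity to A0 exactly.
    """
    a0 = np.asarray(params.a0, dtype=float)
    if np.any(a0 <= 0) or np.any(a0 >= 1):
        raise ValueError("a0 must lie in (0, 1)")
    b = params.beta if beta is None else beta
    f = binding_free_energy(sbar, repertoire)
    eps = np.log((1.0 - a0) / a0) - (1.0 - np.asarray(b)) * f
    eps = np.broadcast_to(eps, f.shape).copy() if eps.shape != f.shape else eps
    if clip:
        eps = np.clip(eps, params.eps_low, params.eps_high)
    return eps


def firing_rate(
    activity: np.ndarray,
    dt: float,
    filt: FiringFilter | None = None,
    pad_steady: bool = True,
) -> np.ndarray:
    """Firing rates from an activity trace: rectified causal convolution.

    ``activity`` has shape (T,) or (T, M).  ``pad_steady`` prepends the
    initial activity for one kernel length, so a trace that begins in steady
    state produces the steady rate from t=0 instead of an onset artifact.
    """
    filt = filt or FiringFilter()
    act = np.asarray(activity, dtype=float)
    squeeze = act.ndim == 1
    if squeeze:
        act = act[:, None]
    kern = filt.kernel(dt)
    n_pad = kern.size - 1 if pad_steady else 0
    if n_pad:
        act = np.vstack([np.repeat(act[:1], n_pad, axis=0), act])
    raw = fftconvolve(act, kern[:, None], mode="full", axes=0)[: act.shape[0]] * dt
    raw = raw[n_pad:]
    rates = filt.rectify(raw)
    return rates[:, 0] if squeeze else rates


def integrate_encoder(
    trace: StimulusTrace,
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    filt: FiringFilter | None = None,
    preadapt: bool = False,
    preadapt_beta: float | None = None,
    max_dt: float = 0.002,
    freeze_eps: bool = False,
) -> ORNState:
    """Integrate the adaptation ODE along a stimulus with the Euler method.

    The free energies start at the adapted state of the trace's static
    background when ``preadapt`` (requires a background), else at the lower
    bounds.  Each Euler step (``dt <= 2 ms``) updates
    ``eps += (dt / tau) (A - A0)`` with clipping to the per-ORN bounds, then
    the activity trace is passed through the firing cascade.
    ``freeze_eps`` holds the free energies at their initial values -- the
    fully non-adaptive system.
    """
    filt = filt or FiringFilter()
    if trace.dt > max_dt + 1e-12:
        raise ValueError(f"trace.dt={trace.dt} exceeds the {max_dt} s maximum")
    if preadapt and trace.background is None:
        raise ValueError("preadapt requires a background on the trace")
    m = repertoire.m
    total = trace.total()
    n_t = total.shape[0]
    a0 = np.broadcast_to(np.asarray(params.a0, dtype=float), (m,))

    if preadapt:
        eps0 = steady_state_epsilon(trace.background, params, repertoire,
                                    beta=preadapt_beta)
    else:
        eps0 = params.eps_low.copy()
    eps = np.empty((n_t, m))
    act = np.empty((n_t, m))
    e = np.broadcast_to(eps0, (m,)).astype(float).copy()
    coef = trace.dt / params.tau
    for t in range(n_t):
        eps[t] = e
        a = channel_activity(total[t], e, repertoire)
        act[t] = a
        if np.any(~np.isfinite(a)):
            raise FloatingPointError(f"NaN in encoder state at step {t}")
        if not freeze_eps:
            e = np.clip(e + coef * (a - a0), params.eps_low, params.eps_high)
    rates = firing_rate(act, trace.dt, filt)
    return ORNState(trace.times.copy(), eps, act, rates)


def steady_rates(
    s,
    eps,
    repertoire: ReceptorRepertoire,
    filt: FiringFilter | None = None,
) -> np.ndarray:
    """Static firing rates: DC gain times activity, rectified."""
    filt = filt or FiringFilter()
    return filt.rectify(filt.dc_gain * channel_activity(s, eps, repertoire))


def steady_response(
    foreground,
    background,
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    filt: FiringFilter | None = None,
    adaptive: bool = True,
    beta: float | None = None,
) -> np.ndarray:
    """Equilibrium M-vector of rates to foreground presented atop background.

    The free energies are set to the adapted state of the background alone
    (``adaptive``; Weber-breaking exponent ``beta``, default the params')
    or held at the lower bounds (non-adaptive), then the activity is
    evaluated on foreground + background and mapped through the filter's DC
    gain and the rectifier.  Agrees with the long-time limit of
    :func:`integrate_encoder` on a step stimulus.
    """
    fg = _as_conc(foreground)
    bg = _as_conc(background)
    if adaptive:
        eps = steady_state_epsilon(bg, params, repertoire, beta=beta)
    else:
        eps = np.broadcast_to(params.eps_low, (repertoire.m,))
    return steady_rates(fg + bg, eps, repertoire, filt)
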