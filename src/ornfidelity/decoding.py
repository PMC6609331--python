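"""Sparse odor reconstruction from ORN responses.

The odorant space (N = 150) is larger than the sensor space (M = 50), but
natural odors are K-sparse with K << N, so odor identity and intensity can
be recovered by compressed sensing (CS).  The encoding is nonlinear; the
decoder works with its linearization about a known background ``sbar``:

    dr = D @ ds,     D_ai = dc_gain * dA_a/ds_i |_(sbar, eps)

and solves  min ||ds||_1  subject to  dr = D ds  (equality constraints on
the rows whose firing is above the 5 Hz rectifier floor).  In the adaptive
system the free energies ``eps`` sit at their Weber-Fechner steady state for
the background; without adaptation they are pinned at the lower bounds, so
strong backgrounds drive rows into saturation where the gain -- and with it
the usable measurement -- collapses.

Also provided: a success criterion on the reconstruction (nonzero
components within 25%, zero components below 10% of the component scale),
whiff-level decoding of fluctuating plume signals with a finite decoder
memory, iterative hard thresholding (IHT) for decoding directly through the
nonlinear response map, and restricted-isometry (RIP) spectral diagnostics
of the linearized measurement matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, nnls

from .encoder import (
    AdaptationParams,
    FiringFilter,
    ReceptorRepertoire,
    channel_activity,
    steady_rates,
    steady_state_epsilon,
)
from .stimuli import PlumeSignal, SparseOdor

__all__ = [
    "MeasurementMatrix",
    "DecodeResult",
    "WhiffDecodingReport",
    "RIPSpectrum",
    "linearized_measurement_matrix",
    "cs_decode",
    "decode_success",
    "decode_time_series",
    "hard_threshold",
    "iht_decode",
    "rip_spectrum",
]

#: Relative tolerance on the K nonzero components for a correct decode.
TOL_NONZERO = 0.25
#: Absolute tolerance, in units of s0, on the N-K zero components.
TOL_ZERO = 0.10


@dataclass
class MeasurementMatrix:
    """Linearization of the encoding map about an adapted operating point.

    ``d`` is (M, N) in Hz per a.u.; ``active_mask`` marks rows whose
    operating-point firing rate clears the rectifier floor -- the default
    constraint set for static decoding (callers may instead gate rows on
    the measured response).
    """

    d: np.ndarray
    linearization_point: np.ndarray
    eps_state: np.ndarray
    active_mask: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if not np.all(np.isfinite(self.d)):
            raise ValueError("measurement matrix entries must be finite")

    @property
    def m(self) -> int:
        return self.d.shape[0]

    @property
    def n(self) -> int:
        return self.d.shape[1]


@dataclass
class DecodeResult:
    """A sparse estimate and its success flag.

    ``success`` means every true-nonzero component is within
    ``tol_nonzero`` relative error and every true-zero component is below
    ``tol_zero * s0``; it is filled by :func:`decode_success`.
    """

    estimate: np.ndarray
    success: bool = False
    feasible: bool = True
    n_iter: int = 0
    tol_nonzero: float = TOL_NONZERO
    tol_zero: float = TOL_ZERO


@dataclass
class WhiffDecodingReport:
    """Whiff-level scoring of temporal decoding with memory ``tau_m``."""

    tau_m: float
    whiff_decoded: list[bool] = field(default_factory=list)
    decode_times: np.ndarray | None = None
    decode_success_trace: np.ndarray | None = None

    @property
    def percent_whiffs_decoded(self) -> float:
        if not self.whiff_decoded:
            return 0.0
        return 100.0 * float(np.mean(self.whiff_decoded))


@dataclass
class RIPSpectrum:
    """Extreme eigenvalues of unit-column k-sparse Gram submatrices.

    For each draw, the encoding is linearized at a random k-sparse point,
    the k support columns are normalized to unit norm, and the eigenvalues
    of the k x k Gram matrix recorded.  ``delta`` per draw is the largest
    deviation of those eigenvalues from 1; small delta means the matrix
    acts almost orthonormally on k-sparse vectors and CS recovery is
    well-conditioned.
    """

    k: int
    lambda_min: np.ndarray
    lambda_max: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return np.maximum(np.abs(self.lambda_min - 1.0),
                          np.abs(self.lambda_max - 1.0))

    @property
    def median_delta(self) -> float:
        return float(np.median(self.delta))


def linearized_measurement_matrix(
    sbar,
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    adaptive: bool = True,
    filt: FiringFilter | None = None,
    eps: np.ndarray | None = None,
) -> MeasurementMatrix:
    """Measurement matrix D = dc_gain * dA/ds at background ``sbar``.

    The free energies are the Weber-Fechner (beta = 0) adapted state for
    ``sbar`` when ``adaptive``, the lower bounds otherwise, or an explicit
    ``eps`` (used during temporal decoding, where the decoder tracks the
    encoder's integrated state).  ``active_mask`` flags rows whose
    operating-point rate clears the rectifier floor.
    """
    filt = filt or FiringFilter()
    sbar = sbar.concentrations if isinstance(sbar, SparseOdor) else np.asarray(sbar, float)
    if eps is None:
        if adaptive:
            eps = steady_state_epsilon(sbar, params, repertoire, beta=0.0)
        else:
            eps = np.broadcast_to(params.eps_low, (repertoire.m,)).astype(float)
    act = channel_activity(sbar, eps, repertoire)
    # dA/ds_i = A(1-A) * R * (K*_ai/(1+K*_a.s) - K_ai/(1+K_a.s))
    strong = repertoire.kstar / (1.0 + sbar @ repertoire.kstar.T)[:, None]
    weak = repertoire.kweak / (1.0 + sbar @ repertoire.kweak.T)[:, None]
    d = (act * (1.0 - act))[:, None] * repertoire.r_sites * (strong - weak)
    d = filt.dc_gain * d
    rate = filt.dc_gain * act
    # rows whose operating-point rate falls below the rectifier floor; the
    # default constraint set, overridable by a mask on the measured response
    active = rate >= filt.rect_threshold
    return MeasurementMatrix(d, sbar.copy(), np.asarray(eps, float).copy(), active)


def cs_decode(
    dr: np.ndarray,
    matrix: MeasurementMatrix,
    tol: float = 1e-9,
    active: np.ndarray | None = None,
) -> DecodeResult:
    """Equality-constrained L1 minimization (basis pursuit).

    Solves ``min sum_i |ds_i|  s.t.  dr = D ds`` on the active rows via the
    split-variable linear program ``ds = u - v, u, v >= 0`` (scipy HiGHS).
    The problem is convex with a unique global optimum up to degeneracy.
    Infeasible constraints set ``feasible=False`` instead of raising.
    ``active`` overrides the matrix's stored row mask (e.g. to gate on the
    measured response rather than the operating point).
    """
    mask = matrix.active_mask if active is None else np.asarray(active, bool)
    d = matrix.d[mask]
    y = np.asarray(dr, dtype=float)[mask]
    n = matrix.n
    if d.shape[0] == 0:
        return DecodeResult(np.zeros(n), feasible=False)
    c = np.ones(2 * n)
    a_eq = np.hstack([d, -d])
    res = linprog(c, A_eq=a_eq, b_eq=y, bounds=(0, None), method="highs",
                  options={"primal_feasibility_tolerance": tol})
    if not res.success:
        return DecodeResult(np.zeros(n), feasible=False)
    ds = res.x[:n] - res.x[n:]
    return DecodeResult(ds, feasible=True)


def nonneg_l1_decode(
    b: np.ndarray,
    d: np.ndarray,
    tol: float = 1e-9,
) -> DecodeResult:
    """min sum(s) subject to d @ s = b, s >= 0.

    The nonnegative variant of basis pursuit used when the unknown is a
    physical concentration vector rather than a signed fluctuation.
    """
    n = d.shape[1]
    if d.shape[0] == 0:
        return DecodeResult(np.zeros(n), feasible=False)
    res = linprog(np.ones(n), A_eq=d, b_eq=np.asarray(b, float),
                  bounds=(0, None), method="highs",
                  options={"primal_feasibility_tolerance": tol})
    if not res.success:
        return DecodeResult(np.zeros(n), feasible=False)
    return DecodeResult(res.x, feasible=True)


def nonlinear_sparse_decode(
    r_meas: np.ndarray,
    eps: np.ndarray,
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    point0: np.ndarray | None = None,
    n_passes: int = 3,
    filt: FiringFilter | None = None,
) -> DecodeResult:
    """Decode a full concentration vector from measured rates.

    Successive linearization of ``min ||s||_1 s.t. r = F(s), s >= 0`` at
    fixed free energies: each pass solves the nonnegative L1 program with
    the response map linearized at the current point (``point0`` seeds the
    iteration), falling back to nonnegative least squares whenever the
    linearized equalities are inconsistent on the nonnegative cone.
    Constraint rows are those whose measured rate clears the rectifier.
    """
    filt = filt or FiringFilter()
    point = np.zeros(repertoire.n) if point0 is None else \
        np.clip(np.asarray(point0, float), 0.0, None)
    active = np.asarray(r_meas) >= filt.rect_threshold
    if not active.any():
        return DecodeResult(point, feasible=False)
    feasible = False
    for _ in range(max(1, n_passes)):
        mm = linearized_measurement_matrix(point, repertoire, params,
                                           filt=filt, eps=eps)
        r_pred = filt.dc_gain * channel_activity(point, eps, repertoire)
        b = (np.asarray(r_meas) - r_pred)[active] + mm.d[active] @ point
        result = nonneg_l1_decode(b, mm.d[active])
        if result.feasible:
            feasible = True
            point = result.estimate
        else:
            point, _ = nnls(mm.d[active], b)
            feasible = True
    return DecodeResult(point, feasible=feasible)


def decode_success(
    estimate: np.ndarray,
    truth: SparseOdor | np.ndarray,
    s0: float | None = None,
    tol_nonzero: float = TOL_NONZERO,
    tol_zero: float = TOL_ZERO,
) -> bool:
    """Whether a reconstruction counts as a correct decode.

    Every true nonzero component must be within ``tol_nonzero`` relative
    error and every true zero component below ``tol_zero * s0``.
    """
    if isinstance(truth, SparseOdor):
        t = truth.concentrations
        s0 = truth.s0 if s0 is None else s0
    else:
        t = np.asarray(truth, dtype=float)
        if s0 is None:
            raise ValueError("s0 required when truth is a bare vector")
    e = np.asarray(estimate, dtype=float)
    if e.shape != t.shape:
        raise ValueError("estimate and truth must have the same dimension")
    nz = t != 0
    if np.any(np.abs(e[nz] - t[nz]) > tol_nonzero * np.abs(t[nz])):
        return False
    return bool(np.all(np.abs(e[~nz]) < tol_zero * s0))


def hard_threshold(v: np.ndarray, k: int) -> np.ndarray:
    """Keep the k largest-magnitude entries, zero the rest.

    Ties are broken toward the lowest index (stable argsort on -|v|).
    Idempotent; ``k = len(v)`` is the identity.
    """
    v = np.asarray(v, dtype=float)
    if not 1 <= k <= v.size:
        raise ValueError("need 1 <= k <= len(v)")
    out = np.zeros_like(v)
    keep = np.argsort(-np.abs(v), kind="stable")[:k]
    out[keep] = v[keep]
    return out


def iht_decode(
    y: np.ndarray,
    sensing_fn,
    n: int,
    k: int,
    mu: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    x0: np.ndarray | None = None,
    nonnegative: bool = False,
) -> DecodeResult:
    """Iterative hard thresholding through a (possibly nonlinear) sensing map.

    ``sensing_fn(x)`` returns ``(D(x), J_x)``: the response at ``x`` and the
    (M, N) linearization there.  Iterates

        x <- H_K(x + mu * J_hat_x^T (y - D(x)))

    starting from zero, with the columns of ``J_x`` scaled to unit norm
    (the RIP-normalized update).  Default step ``mu = 0.5`` on the
    normalized columns, halved (backtracking) whenever the residual grows;
    divergence over 10 consecutive growing iterations sets the failure
    flag.  For a linear map the iteration is textbook linear IHT.
    """
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    mu = 0.5 if mu is None else mu
    prev_res = np.inf
    n_grow = 0
    for it in range(max_iter):
        fx, jac = sensing_fn(x)
        r = np.asarray(y, float) - np.asarray(fx, float)
        res = float(np.linalg.norm(r))
        if res > prev_res * (1.0 + 1e-12):
            n_grow += 1
            mu *= 0.5
            if n_grow >= 10:
                return DecodeResult(x, feasible=False, n_iter=it)
        else:
            n_grow = 0
        prev_res = min(prev_res, res)
        norms = np.linalg.norm(jac, axis=0)
        norms[norms == 0] = 1.0
        grad = (jac / norms).T @ r
        x_new = hard_threshold(x + mu * grad, k)
        if nonnegative:
            x_new = np.clip(x_new, 0.0, None)
        if np.linalg.norm(x_new - x) <= tol * max(1.0, np.linalg.norm(x)):
            return DecodeResult(x_new, n_iter=it + 1)
        x = x_new
    return DecodeResult(x, n_iter=max_iter)


def make_orn_sensing_fn(
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    eps: np.ndarray,
    filt: FiringFilter | None = None,
):
    """Nonlinear ORN sensing map s -> rates at fixed free energies.

    Returns a callable usable with :func:`iht_decode`: the forward steady
    response (rectified) and the measurement matrix linearized at the
    query point with the same ``eps``.
    """
    filt = filt or FiringFilter()

    def fn(s: np.ndarray):
        s = np.clip(np.asarray(s, dtype=float), 0.0, None)
        rates = steady_rates(s, eps, repertoire, filt)
        mm = linearized_measurement_matrix(s, repertoire, params, filt=filt,
                                          eps=eps)
        return rates, mm.d
    return fn


def rip_spectrum(
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    k: int,
    n_draws: int,
    rng: np.random.Generator,
    intensity: float = 1.0,
    adaptive: bool = True,
    s0: float = 1.0,
    filt: FiringFilter | None = None,
) -> RIPSpectrum:
    """RIP diagnostics of linearized ORN measurement matrices.

    For each draw a random k-sparse odor at the given intensity is the
    linearization point; the k support columns are rescaled to unit norm
    and the extreme eigenvalues of their Gram matrix recorded.
    """
    from .stimuli import sample_sparse_odor

    if k > repertoire.m:
        raise ValueError("k must not exceed the number of ORN types")
    lam_min = np.empty(n_draws)
    lam_max = np.empty(n_draws)
    for t in range(n_draws):
        odor = sample_sparse_odor(repertoire.n, k, s0, rng)
        point = odor.concentrations * intensity
        mm = linearized_measurement_matrix(point, repertoire, params,
                                           adaptive=adaptive, filt=filt)
        cols = mm.d[:, list(odor.support)]
        norms = np.linalg.norm(cols, axis=0)
        norms[norms == 0] = 1.0
        cols = cols / norms
        lam = np.linalg.eigvalsh(cols.T @ cols)
        lam_min[t], lam_max[t] = lam[0], lam[-1]
    return RIPSpectrum(k, lam_min, lam_max)


def gram_spectrum(columns: np.ndarray) -> np.ndarray:
    """Eigenvalues of the unit-column-normalized Gram matrix of ``columns``."""
    norms = np.linalg.norm(columns, axis=0)
    norms[norms == 0] = 1.0
    c = columns / norms
    return np.linalg.eigvalsh(c.T @ c)


def decoding_accuracy_grid(
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    rng: np.random.Generator,
    intensities: np.ndarray | None = None,
    complexities: np.ndarray | None = None,
    n_pairs: int = 20,
    k_foreground: int = 5,
    s0: float = 1.0,
    filt: FiringFilter | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive and non-adaptive accuracy over (intensity x complexity).

    Returns two matrices of shape (len(intensities), len(complexities)).
    Trials are paired: each cell draws ``n_pairs`` foreground/background
    identity pairs once and scores both conditions on the identical
    environments, so condition differences are not masked by sampling
    variance.
    """
    from .stimuli import sample_disjoint_odor, sample_sparse_odor

    filt = filt or FiringFilter()
    if intensities is None:
        intensities = np.array([3.0, 10.0, 30.0, 100.0, 300.0])
    if complexities is None:
        complexities = np.array([1, 2, 5, 10, 20])
    acc_a = np.zeros((len(intensities), len(complexities)))
    acc_n = np.zeros_like(acc_a)
    for ci, c in enumerate(intensities):
        for ki, kbg in enumerate(complexities):
            for _ in range(n_pairs):
                fg = sample_sparse_odor(repertoire.n, k_foreground, s0, rng)
                bg = sample_disjoint_odor(fg, int(kbg), s0, rng)
                bg_vec = bg.concentrations * c
                for adaptive, acc in ((True, acc_a), (False, acc_n)):
                    mm = linearized_measurement_matrix(
                        bg_vec, repertoire, params, adaptive=adaptive,
                        filt=filt)
                    r_full = steady_rates(bg_vec + fg.concentrations,
                                          mm.eps_state, repertoire, filt)
                    r_base = filt.dc_gain * channel_activity(
                        bg_vec, mm.eps_state, repertoire)
                    active = r_full >= filt.rect_threshold
                    res = cs_decode(r_full - r_base, mm, active=active)
                    if res.feasible and decode_success(
                            np.clip(res.estimate, 0.0, None), fg):
                        acc[ci, ki] += 1.0
    return acc_a / n_pairs, acc_n / n_pairs


def decode_time_series(
    plume: PlumeSignal,
    foreground: SparseOdor,
    background: SparseOdor,
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    tau_m: float = 0.5,
    adaptive: bool = True,
    filt: FiringFilter | None = None,
    decode_dt: float = 0.02,
    intensity_scale: float | None = None,
    background_estimate: str = "trailing-mean",
    n_relinearize: int = 1,
) -> WhiffDecodingReport:
    """Whiff-level decoding of a fluctuating foreground atop a static background.

    The foreground follows the plume intensity (identity fixed, magnitude
    ``intensity_scale * intensity(t)``; by default scaled so the whiff
    threshold maps to the foreground's own component scale).  The encoder
    integrates the adaptation ODE through the whole trace (free energies
    pre-adapted to the background; pinned at the lower bounds when
    non-adaptive).  The decoder re-linearizes at every decode step from its
    own trailing background estimate -- the mean of its decoded signal over
    the last ``tau_m`` seconds ("last" decode is the alternative estimator)
    -- and from the encoder's current free-energy state, which is
    observable by integrating the firing rates.  Each step solves the
    total-signal nonnegative L1 program linearized at the memory estimate
    (one pass by default: the trailing memory, not within-step iteration,
    is what carries background knowledge; ``n_relinearize`` enables
    within-step refinement).  A whiff counts as decoded if the full
    concentration vector satisfies :func:`decode_success` at one or more
    decode times inside the whiff.
    """
    from .encoder import integrate_encoder
    from .stimuli import StimulusTrace, compose_environment

    filt = filt or FiringFilter()
    if tau_m <= 0:
        raise ValueError("tau_m must be positive")
    if intensity_scale is None:
        intensity_scale = 1.0 / plume.whiff_threshold
    n = repertoire.n
    env = plume.intensity * intensity_scale
    signal = env[:, None] * foreground.concentrations[None, :]
    trace = StimulusTrace(plume.times, plume.dt, signal, foreground.support)
    trace = compose_environment(trace, background)
    state = integrate_encoder(trace, repertoire, params, filt,
                              preadapt=adaptive,
                              preadapt_beta=0.0,
                              freeze_eps=not adaptive)

    stride = max(1, int(round(decode_dt / plume.dt)))
    decode_idx = np.arange(0, plume.times.size, stride)
    # decodes older than tau_m are forgotten entirely; a memory shorter
    # than one decode interval leaves the decoder bootstrapping from zero
    window = int(np.floor(tau_m / (stride * plume.dt)))
    history: list[np.ndarray] = []
    times_out = []
    ok_out = []
    total = trace.total()
    for idx in decode_idx:
        if history and window >= 1:
            if background_estimate == "trailing-mean":
                sbar_hat = np.mean(history[-window:], axis=0)
            else:  # "last"
                sbar_hat = history[-1]
        else:
            sbar_hat = np.zeros(n)
        sbar_hat = np.clip(sbar_hat, 0.0, None)
        result = nonlinear_sparse_decode(
            state.rates[idx], state.eps[idx], repertoire, params,
            point0=sbar_hat, n_passes=n_relinearize, filt=filt)
        s_hat = result.estimate
        history.append(s_hat)
        ok = result.feasible and decode_success(s_hat, total[idx],
                                                s0=foreground.s0)
        times_out.append(plume.times[idx])
        ok_out.append(ok)

    times_out = np.asarray(times_out)
    ok_out = np.asarray(ok_out, dtype=bool)
    whiff_flags = []
    for start, end in plume.whiffs:
        in_whiff = (times_out >= start) & (times_out < end)
        whiff_flags.append(bool(np.any(ok_out[in_whiff])))
    return WhiffDecodingReport(tau_m, whiff_flags, times_out, ok_out)


def decode_perturbation_trial(
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    rng: np.random.Generator,
    k_foreground: int = 5,
    k_background: int = 0,
    background_intensity: float = 1.0,
    adaptive: bool = True,
    s0: float = 1.0,
    filt: FiringFilter | None = None,
) -> bool:
    """One static CS decoding trial; returns whether the decode succeeded.

    A K-sparse foreground odor (components ``s0 + ds_i`` with
    ``ds_i ~ Normal(s0/3, s0/9)``) arrives atop a static background odor of
    a distinct K-sparse identity at the given intensity (or atop nothing).
    The encoder responds through the full nonlinear steady map.  The
    decoder knows the background -- its linearization point -- and the
    adapted free energies (Weber-Fechner steady state for the background
    when ``adaptive``, the lower bounds otherwise), and solves the
    linearized CS program for the foreground as a perturbation about the
    background.  The foreground is *not* small, so linearization error is
    the intrinsic failure mode; the 25%/10% success tolerances absorb the
    unavoidable part.  Constraint rows are those whose measured response
    survives the rectifier; the baseline prediction on those rows is the
    decoder's own (unrectified) model rate at the background.
    """
    from .stimuli import sample_disjoint_odor, sample_sparse_odor

    filt = filt or FiringFilter()
    n = repertoire.n
    fg = sample_sparse_odor(n, k_foreground, s0, rng)
    if k_background > 0:
        bg = sample_disjoint_odor(fg, k_background, s0, rng)
        bg_vec = bg.concentrations * background_intensity
    else:
        bg_vec = np.zeros(n)
    mm = linearized_measurement_matrix(bg_vec, repertoire, params,
                                       adaptive=adaptive, filt=filt)
    r_full = steady_rates(bg_vec + fg.concentrations, mm.eps_state,
                          repertoire, filt)
    r_base_model = filt.dc_gain * channel_activity(bg_vec, mm.eps_state,
                                                   repertoire)
    active = r_full >= filt.rect_threshold
    result = cs_decode(r_full - r_base_model, mm, active=active)
    if not result.feasible:
        return False
    estimate = np.clip(result.estimate, 0.0, None)
    return decode_success(estimate, fg)


def static_decoding_accuracy(
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    rng: np.random.Generator,
    k_foreground: int = 5,
    k_background: int = 0,
    background_intensity: float = 1.0,
    n_pairs: int = 20,
    adaptive: bool = True,
    s0: float = 1.0,
    filt: FiringFilter | None = None,
) -> float:
    """Fraction of foreground odors correctly decoded over ``n_pairs`` trials.

    Each trial uses a fresh foreground identity and, when ``k_background``
    is positive, a fresh distinct background identity; see
    :func:`decode_perturbation_trial`.
    """
    ok = sum(
        decode_perturbation_trial(
            repertoire, params, rng,
            k_foreground=k_foreground,
            k_background=k_background,
            background_intensity=background_intensity,
            adaptive=adaptive, s0=s0, filt=filt,
        )
        for _ in range(n_pairs)
    )
    return ok / n_pairs
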