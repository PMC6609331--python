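"""Code-fidelity metrics: mutual information, embeddings, gain analysis.

The central question is how much an M-dimensional ORN firing pattern tells a
downstream observer about the *foreground* odor identity when the response is
confounded by background odors and intensity.  That is quantified as the
mutual information between foreground identity and the (discretized)
population response,

    MI = H_response - H_noise,

with the conditional distribution ``P(r | s)`` taken over backgrounds: a
small Gaussian rate jitter (sd 1 Hz) is applied to every component, rates
are binned at 1 Hz, and each binned M-vector is one discrete symbol.
``H_noise`` is the mean conditional symbol entropy given the foreground,
``H_response`` the entropy of the pooled symbol distribution under a
uniform foreground prior.

Numerically, the Gaussian jitter is integrated analytically: the
conditional probability of a binned symbol is the mixture (over
backgrounds) of products of per-component Gaussian bin masses, and the two
entropies are estimated by Monte Carlo draws from those mixtures.  Counting
jittered draws directly would make every M-dimensional symbol unique at
any feasible sample size and pin the estimate at its log2(n_foregrounds)
ceiling regardless of the code, so the analytic-mass form is the
consistent estimator of the same quantity.  With the jitter disabled the
estimator reduces to exact plug-in symbol counting.  Estimates at these
sample sizes remain biased; the bias is common to every condition
compared, and only MI differences and orderings are interpreted.

The module also provides the 2-D t-SNE projection used for visualization
(never for quantitative claims) and the analytic Weber-Fechner gain of the
adapted encoder for dose-response analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .encoder import (
    AdaptationParams,
    FiringFilter,
    ReceptorRepertoire,
    channel_activity,
    steady_rates,
    steady_state_epsilon,
)
from .stimuli import SparseOdor, sample_sparse_odor

__all__ = [
    "FiringEnsemble",
    "MIEstimate",
    "estimate_mi",
    "embed_2d",
    "analytic_gain",
    "dose_response",
    "background_ensemble",
]


@dataclass
class FiringEnsemble:
    """Labeled ORN population responses.

    ``responses`` has shape (n_samples, M); ``labels`` carries one row per
    response with columns ``foreground``, ``background`` and
    ``concentration``.
    """

    responses: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise ValueError("responses must be (n_samples, M)")
        if len(self.labels) != self.responses.shape[0]:
            raise ValueError("labels must have one row per response")
        for col in ("foreground", "background", "concentration"):
            if col not in self.labels.columns:
                raise ValueError(f"labels missing column {col!r}")

    @property
    def m(self) -> int:
        return self.responses.shape[1]

    def to_table(self) -> pd.DataFrame:
        rates = pd.DataFrame(
            self.responses,
            columns=[f"orn_{a}" for a in range(self.m)],
        )
        return pd.concat(
            [self.labels.reset_index(drop=True), rates], axis=1
        )

    def save(self, path: str) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class MIEstimate:
    """A mutual-information estimate in bits, with the estimator settings."""

    bits: float
    n_foregrounds: int
    n_backgrounds: int
    bin_width: float = 1.0
    noise_sd: float = 1.0
    h_response: float = 0.0
    h_noise: float = 0.0


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _count_mi(responses_by_fg: list[np.ndarray], bin_width: float) -> tuple[float, float]:
    """Exact plug-in entropies for noiseless, binned responses."""
    symbols = np.vstack([np.floor(r / bin_width).astype(np.int64)
                         for r in responses_by_fg])
    owner = np.concatenate([np.full(r.shape[0], gi)
                            for gi, r in enumerate(responses_by_fg)])
    _, inverse = np.unique(symbols, axis=0, return_inverse=True)
    n_sym = inverse.max() + 1
    n_fg = len(responses_by_fg)
    h_noise = 0.0
    pooled = np.zeros(n_sym)
    for gi in range(n_fg):
        counts = np.bincount(inverse[owner == gi], minlength=n_sym).astype(float)
        h_noise += _entropy(counts) / n_fg
        pooled += counts / counts.sum() / n_fg  # uniform P(s)
    return _entropy(pooled), h_noise


def _log_bin_mass(draw_bins: np.ndarray, responses: np.ndarray,
                  bin_width: float, noise_sd: float) -> np.ndarray:
    """log P(binned symbol | each response); shape (n_draws, n_responses).

    The probability that response + Gaussian jitter falls in the drawn bin,
    per component, multiplied across components (log-summed).
    """
    from scipy.special import ndtr

    lo = draw_bins * bin_width
    hi = lo + bin_width
    # broadcast (n_draws, 1, M) against (1, n_resp, M)
    z_lo = (lo[:, None, :] - responses[None, :, :]) / noise_sd
    z_hi = (hi[:, None, :] - responses[None, :, :]) / noise_sd
    mass = ndtr(z_hi) - ndtr(z_lo)
    with np.errstate(divide="ignore"):
        return np.log(mass).sum(axis=2)


def estimate_mi(
    ensemble: FiringEnsemble,
    rng: np.random.Generator | None = None,
    bin_width: float = 1.0,
    noise_sd: float = 1.0,
    n_repeats: int = 4,
    chunk: int = 64,
) -> MIEstimate:
    """Mutual information between foreground identity and binned response.

    With ``noise_sd > 0``, each response defines a Gaussian jitter
    distribution (sd in Hz) whose mass over 1-Hz bins is computed
    analytically; ``P(symbol | foreground)`` is the equal-weight mixture
    over that foreground's backgrounds, and the response/noise entropies are
    Monte-Carlo estimates over ``n_repeats`` draws per response.  With
    ``noise_sd = 0`` the estimator is exact plug-in symbol counting.
    Foregrounds are equiprobable.  Returns MI floored at zero; the true
    quantity is at most ``log2(n_foregrounds)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    fg = ensemble.labels["foreground"].to_numpy()
    groups = np.unique(fg)
    n_bg = int(ensemble.labels["background"].nunique())
    if groups.size < 2:
        warnings.warn("single foreground: MI is identically zero")
        return MIEstimate(0.0, int(groups.size), n_bg, bin_width, noise_sd)
    by_fg = [ensemble.responses[fg == g] for g in groups]

    if noise_sd == 0:
        h_response, h_noise = _count_mi(by_fg, bin_width)
        bits = max(0.0, h_response - h_noise)
        return MIEstimate(bits, int(groups.size), n_bg, bin_width, noise_sd,
                          h_response, h_noise)

    n_fg = len(by_fg)
    log_pc = []   # log P(draw | its own foreground)
    log_pp = []   # log P(draw) under the uniform-foreground pool
    for gi, r in enumerate(by_fg):
        draws = np.repeat(r, n_repeats, axis=0)
        draws = draws + rng.normal(0.0, noise_sd, size=draws.shape)
        bins = np.floor(draws / bin_width)
        for start in range(0, bins.shape[0], chunk):
            b = bins[start : start + chunk]
            cond = np.empty((b.shape[0], n_fg))
            for gj, rj in enumerate(by_fg):
                lm = _log_bin_mass(b, rj, bin_width, noise_sd)
                cond[:, gj] = logsumexp(lm, axis=1) - np.log(rj.shape[0])
            log_pc.append(cond[:, gi])
            log_pp.append(logsumexp(cond, axis=1) - np.log(n_fg))
    log_pc = np.concatenate(log_pc)
    log_pp = np.concatenate(log_pp)
    # H = E[-log2 P] under draws from the respective distributions
    h_noise = float(np.mean(-log_pc) / np.log(2))
    h_response = float(np.mean(-log_pp) / np.log(2))
    bits = max(0.0, h_response - h_noise)
    return MIEstimate(bits, int(groups.size), n_bg, bin_width, noise_sd,
                      h_response, h_noise)


def embed_2d(
    ensemble: FiringEnsemble | np.ndarray,
    seed: int = 0,
    perplexity: float = 15.0,
) -> np.ndarray:
    """2-D t-SNE projection of the responses, for visualization only.

    Deterministic under a fixed seed (PCA initialization); the embedding
    preserves neighborhoods, not global distances, and is never used for
    quantitative claims.
    """
    from sklearn.manifold import TSNE

    x = ensemble.responses if isinstance(ensemble, FiringEnsemble) else np.asarray(ensemble)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 responses to embed")
    perplexity = min(perplexity, (x.shape[0] - 1) / 3)
    tsne = TSNE(n_components=2, random_state=seed, init="pca",
                perplexity=perplexity)
    return tsne.fit_transform(x)


def analytic_gain(
    sbar: float,
    kstar: float,
    params: AdaptationParams,
    beta: float = 0.0,
    orn: int = 0,
    form: str = "general",
) -> float:
    """Adapted single-odorant gain dA/ds at mean concentration ``sbar``.

    ``form='general'`` evaluates the full expression

        dA/ds = (1 - A0) A0 K* / [A0 (K* sbar)^((1+b)/2)
                                  + (1 - A0) (K* sbar)^((1-b)/2)]^2,

    valid in the sensitive regime 1/K* << sbar << 1/K; at beta = 0 it
    reduces to ``A0 (1 - A0) / sbar`` (Weber-Fechner).  ``form='small-beta'``
    returns the weak-breaking asymptote

        dA/ds = A0 K* / [(1 - A0) (K* sbar)^(1 - b)],

    whose log-log slope against sbar is exactly -(1 - beta).
    """
    a0 = float(np.atleast_1d(np.asarray(params.a0, dtype=float))[orn])
    x = kstar * sbar
    if x < 10.0:
        warnings.warn("sbar is near or below 1/K*: outside the gain regime")
    if form == "general":
        denom = a0 * x ** ((1 + beta) / 2) + (1 - a0) * x ** ((1 - beta) / 2)
        return (1 - a0) * a0 * kstar / denom**2
    if form == "small-beta":
        return a0 * kstar / ((1 - a0) * x ** (1 - beta))
    raise ValueError("form must be 'general' or 'small-beta'")


def dose_response(
    orn: int,
    background: SparseOdor,
    odorant: int,
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    grid: np.ndarray,
    filt: FiringFilter | None = None,
    beta: float | None = None,
) -> pd.DataFrame:
    """Dose-response of one ORN to one odorant after adapting to a background.

    The free energy is frozen at the adapted state for the background alone;
    the returned frame has the concentration grid, channel activity and
    rectified firing rate.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or np.any(grid < 0):
        raise ValueError("grid must be nonnegative and increasing")
    eps = steady_state_epsilon(background, params, repertoire, beta=beta)[orn]
    n = repertoire.n
    conc = np.tile(background.concentrations, (grid.size, 1))
    conc[:, odorant] += grid
    act = channel_activity(conc, eps, repertoire)[:, orn]
    filt = filt or FiringFilter()
    rate = filt.rectify(filt.dc_gain * act)
    return pd.DataFrame({"concentration": grid, "activity": act, "rate": rate})


def background_ensemble(
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    rng: np.random.Generator,
    n_foregrounds: int = 10,
    n_backgrounds: int = 50,
    k: int = 5,
    s0: float = 1.0,
    foreground_intensity: float = 30.0,
    intensity_range: tuple[float, float] = (10.0, 3e4),
    beta: float = 0.0,
    filt: FiringFilter | None = None,
) -> FiringEnsemble:
    """Foreground-atop-background response ensemble.

    Each of ``n_foregrounds`` foreground identities is presented at a fixed
    reference intensity (``foreground_intensity`` times ``s0``, the middle
    of the repertoire's dynamic range) atop each of ``n_backgrounds``
    backgrounds: fresh K-sparse identities at intensities drawn
    log-uniformly over ``intensity_range``.  The default range spans two
    decades reaching intensities that push a non-adapting repertoire past
    saturation -- the regime where front-end adaptation is at stake.  The
    response is the steady rate to foreground + background with free
    energies adapted to the background alone (Weber-breaking exponent
    ``beta``; ``beta=1`` leaves the free energies at their lower bounds).
    """
    filt = filt or FiringFilter()
    foregrounds = [sample_sparse_odor(repertoire.n, k, s0, rng)
                   for _ in range(n_foregrounds)]
    lo, hi = intensity_range
    rows = []
    resp = []
    for j in range(n_backgrounds):
        bg = sample_sparse_odor(repertoire.n, k, s0, rng)
        c = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        bg_vec = bg.concentrations * c
        eps = steady_state_epsilon(bg_vec, params, repertoire, beta=beta)
        for i, fgo in enumerate(foregrounds):
            total = fgo.concentrations * foreground_intensity + bg_vec
            resp.append(steady_rates(total, eps, repertoire, filt))
            rows.append({"foreground": i, "background": j, "concentration": c})
    return FiringEnsemble(np.array(resp), pd.DataFrame(rows))
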