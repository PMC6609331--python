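"""Synthetic odor environments.

Odors are nonnegative concentration vectors over an N-dimensional space of
monomolecular odorants (N=150 by default).  Natural odors are sparse: only
K << N components are nonzero, and the *identity* of an odor is the set of
nonzero components (its support), while intensity scales all nonzero
components together.

This module generates every stimulus class the analyses assume:

* sparse foreground/background mixtures (:func:`sample_sparse_odor`),
* sigmoidal onset pulses (:func:`make_sigmoid_stimulus`),
* naturalistic plume-like intensity series (:func:`sample_plume_signal`),
  emulating the intermittent whiff/blank statistics of odor concentration
  recorded in a turbulent airstream: whiff and blank durations are broadly
  distributed (truncated power law, exponent -3/2) and whiff intensities
  are right-skewed,
* superpositions of a time-varying foreground on a static background
  (:func:`compose_environment`).

All randomness flows through a caller-supplied :class:`numpy.random.Generator`
so every environment is reproducible byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SparseOdor",
    "StimulusTrace",
    "PlumeSignal",
    "sample_sparse_odor",
    "make_sigmoid_stimulus",
    "sample_plume_signal",
    "detect_whiffs",
    "compose_environment",
    "sample_truncated_power_law",
]

#: Default odorant-space dimension.
N_ODORANTS = 150
#: Default mixture sparsity.
K_DEFAULT = 5
#: Default baseline component scale (a.u.).
S0_DEFAULT = 1.0
#: Default whiff detection threshold (a.u.), matching the convention of
#: demarcating whiffs where the plume signal exceeds 4 a.u.
WHIFF_THRESHOLD = 4.0


@dataclass(frozen=True)
class SparseOdor:
    """A K-sparse nonnegative concentration vector over N odorant channels.

    Parameters
    ----------
    concentrations
        Length-N nonnegative vector (a.u.).
    support
        Sorted indices of the nonzero components.
    s0
        Baseline component scale (a.u.) used when the odor was sampled.
    """

    concentrations: np.ndarray
    support: tuple[int, ...]
    s0: float = S0_DEFAULT

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "support", tuple(int(i) for i in self.support))
        if c.ndim != 1:
            raise ValueError("concentrations must be a 1-D vector")
        if np.any(c < 0):
            raise ValueError("concentrations must be nonnegative")
        nz = set(np.flatnonzero(c).tolist())
        if not nz.issubset(set(self.support)):
            raise ValueError("nonzero entries outside the declared support")

    @property
    def n(self) -> int:
        return self.concentrations.size

    @property
    def k(self) -> int:
        return len(self.support)

    def scaled(self, factor: float) -> "SparseOdor":
        """Return the same identity at a different overall intensity."""
        if factor < 0:
            raise ValueError("intensity factor must be nonnegative")
        return SparseOdor(self.concentrations * factor, self.support, self.s0)

    @staticmethod
    def zero(n: int = N_ODORANTS, s0: float = S0_DEFAULT) -> "SparseOdor":
        return SparseOdor(np.zeros(n), (), s0)


@dataclass
class StimulusTrace:
    """A time-varying odor signal on a uniform grid.

    ``signal`` holds the full concentration time course, shape (T, N); the
    foreground support is fixed in time (identity is constant, magnitude
    varies).  ``background``, if present, is a static odor added to every
    time point; the encoder may pre-adapt to it.
    """

    times: np.ndarray
    dt: float
    signal: np.ndarray
    foreground_support: tuple[int, ...]
    background: SparseOdor | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.signal.shape[0] != self.times.size:
            raise ValueError("signal and times must have matching length")
        if np.any(self.signal < 0):
            raise ValueError("concentrations must be nonnegative")

    @property
    def n_odorants(self) -> int:
        return self.signal.shape[1]

    def total(self) -> np.ndarray:
        """Foreground plus (static) background, shape (T, N)."""
        if self.background is None:
            return self.signal
        return self.signal + self.background.concentrations[None, :]

    def to_table(self) -> "np.ndarray":
        """Two-column-style table: time followed by per-channel values."""
        return np.column_stack([self.times, self.signal])

    def save(self, path: str) -> None:
        """Write a delimited text table plus a JSON metadata sidecar."""
        np.savetxt(path, self.to_table(), delimiter="\t")
        meta = {
            "dt": self.dt,
            "foreground_support": list(self.foreground_support),
            "background_support": (
                list(self.background.support) if self.background else None
            ),
            "background_concentrations": (
                self.background.concentrations[
                    list(self.background.support)
                ].tolist()
                if self.background
                else None
            ),
            "n_odorants": self.n_odorants,
        }
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


@dataclass
class PlumeSignal:
    """A scalar plume intensity series with its whiff annotation.

    Whiffs are the maximal contiguous intervals where the intensity exceeds
    ``whiff_threshold``; the generator records them at construction so that
    downstream whiff-level scoring does not depend on re-detection.
    """

    times: np.ndarray
    dt: float
    intensity: np.ndarray
    whiff_threshold: float = WHIFF_THRESHOLD
    whiffs: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")
        for start, end in self.whiffs:
            if end <= start:
                raise ValueError("whiff intervals must have positive length")

    @property
    def intermittency(self) -> float:
        """Fraction of samples above the whiff threshold."""
        return float(np.mean(self.intensity > self.whiff_threshold))

    def save(self, path: str) -> None:
        np.savetxt(path, np.column_stack([self.times, self.intensity]),
                   delimiter="\t")
        meta = {"dt": self.dt, "whiff_threshold": self.whiff_threshold,
                "whiffs": [list(w) for w in self.whiffs]}
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def sample_sparse_odor(
    n: int = N_ODORANTS,
    k: int = K_DEFAULT,
    s0: float = S0_DEFAULT,
    rng: np.random.Generator | None = None,
) -> SparseOdor:
    """Draw a random K-sparse odor.

    The support is drawn uniformly without replacement.  Each nonzero
    component equals ``s0 + ds`` with ``ds ~ Normal(s0/3, s0/9)`` (mean,
    variance), clipped at zero: concentrations are physical.

    Raises
    ------
    ValueError
        If ``k > n``, ``k < 0`` or ``s0 <= 0``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    conc = np.zeros(n)
    if k == 0:
        return SparseOdor(conc, (), s0)
    support = np.sort(rng.choice(n, size=k, replace=False))
    ds = rng.normal(loc=s0 / 3.0, scale=np.sqrt(s0 / 9.0), size=k)
    conc[support] = np.clip(s0 + ds, 0.0, None)
    return SparseOdor(conc, tuple(support.tolist()), s0)


def sample_disjoint_odor(
    other: SparseOdor,
    k: int = K_DEFAULT,
    s0: float = S0_DEFAULT,
    rng: np.random.Generator | None = None,
) -> SparseOdor:
    """Draw a sparse odor whose support avoids ``other``'s support."""
    if rng is None:
        rng = np.random.default_rng()
    n = other.n
    avail = np.setdiff1d(np.arange(n), np.asarray(other.support, dtype=int))
    if k > avail.size:
        raise ValueError("not enough free channels for a disjoint odor")
    support = np.sort(rng.choice(avail, size=k, replace=False))
    conc = np.zeros(n)
    ds = rng.normal(loc=s0 / 3.0, scale=np.sqrt(s0 / 9.0), size=k)
    conc[support] = np.clip(s0 + ds, 0.0, None)
    return SparseOdor(conc, tuple(support.tolist()), s0)


def make_sigmoid_stimulus(
    odor: SparseOdor,
    t_half: float = 0.05,
    dt: float = 0.002,
    duration: float = 1.0,
) -> StimulusTrace:
    """A monotone logistic onset that reaches half of its plateau at ``t_half``.

    The logistic steepness is set so the 1%-to-99% rise spans about
    ``2 * t_half``; the plateau equals the odor's concentration vector.
    """
    if min(t_half, dt, duration) <= 0:
        raise ValueError("t_half, dt and duration must be positive")
    times = np.arange(0.0, duration, dt)
    # 1->99% span of a logistic is 2*ln(99)/k; set it equal to 2*t_half.
    steepness = np.log(99.0) / t_half
    envelope = 1.0 / (1.0 + np.exp(-steepness * (times - t_half)))
    signal = envelope[:, None] * odor.concentrations[None, :]
    return StimulusTrace(times, dt, signal, odor.support)


def make_step_stimulus(
    odor: SparseOdor,
    dt: float = 0.002,
    duration: float = 2.0,
    onset: float = 0.0,
) -> StimulusTrace:
    """A simple step to the odor's concentration vector at ``onset``."""
    times = np.arange(0.0, duration, dt)
    env = (times >= onset).astype(float)
    return StimulusTrace(times, dt, env[:, None] * odor.concentrations[None, :],
                         odor.support)


def sample_truncated_power_law(
    exponent: float,
    lower: float,
    upper: float,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inverse-CDF draws from p(x) ~ x**(-exponent) on [lower, upper]."""
    if not lower < upper or lower <= 0:
        raise ValueError("need 0 < lower < upper")
    u = rng.uniform(size=size)
    g = 1.0 - exponent
    if abs(g) < 1e-12:  # log-uniform limit
        return lower * (upper / lower) ** u
    lo, hi = lower**g, upper**g
    return (lo + u * (hi - lo)) ** (1.0 / g)


#: Power-law exponent of whiff/blank duration distributions in turbulent
#: plumes; durations are broadly distributed between 50 ms and 10 s.
DURATION_EXPONENT = 1.5
DURATION_BOUNDS = (0.05, 10.0)


def sample_plume_signal(
    duration: float = 100.0,
    dt: float = 0.002,
    rng: np.random.Generator | None = None,
    whiff_threshold: float = WHIFF_THRESHOLD,
    intermittency: float = 0.35,
    intensity_sigma: float = 1.0,
) -> PlumeSignal:
    """Emulate a naturalistic plume intensity series.

    An alternating whiff/blank renewal process: both whiff and blank
    durations follow a truncated power law with exponent -3/2 on
    [0.05 s, 10 s] (blank bounds rescaled so the long-run fraction of time
    spent in whiffs equals ``intermittency``).  Within a whiff the intensity
    is ``whiff_threshold + c`` with ``c ~ LogNormal(ln(threshold),
    intensity_sigma)`` -- a broad, right-skewed distribution -- so every
    whiff sample strictly exceeds the threshold; blanks sit at a low
    sub-threshold level.

    The mean of the truncated power law with exponent -3/2 on [a, b] is
    sqrt(a*b), so blank bounds are scaled by (1 - eta) / eta to hit the
    target intermittency eta in the renewal-process average.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0 < intermittency < 1:
        raise ValueError("intermittency must be in (0, 1)")
    n_t = int(round(duration / dt))
    intensity = np.zeros(n_t)
    whiffs: list[tuple[float, float]] = []
    blank_scale = (1.0 - intermittency) / intermittency
    lo, hi = DURATION_BOUNDS
    # low, sub-threshold baseline during blanks
    blank_level = 0.25 * whiff_threshold

    i = 0
    in_whiff = rng.uniform() < intermittency
    while i < n_t:
        if in_whiff:
            dur = sample_truncated_power_law(DURATION_EXPONENT, lo, hi, 1, rng)[0]
            n = max(1, int(round(dur / dt)))
            n = min(n, n_t - i)
            level = whiff_threshold + rng.lognormal(
                mean=np.log(whiff_threshold), sigma=intensity_sigma
            )
            intensity[i : i + n] = level
            whiffs.append((i * dt, (i + n) * dt))
        else:
            dur = sample_truncated_power_law(
                DURATION_EXPONENT, lo * blank_scale, hi * blank_scale, 1, rng
            )[0]
            n = max(1, int(round(dur / dt)))
            n = min(n, n_t - i)
            intensity[i : i + n] = blank_level * rng.uniform(0.2, 1.0)
        i += n
        in_whiff = not in_whiff

    times = np.arange(n_t) * dt
    return PlumeSignal(times, dt, intensity, whiff_threshold, whiffs)


def detect_whiffs(
    intensity: np.ndarray,
    threshold: float,
    dt: float = 1.0,
    t0: float = 0.0,
) -> list[tuple[float, float]]:
    """Maximal contiguous intervals with intensity strictly above threshold.

    Returns ``[start, end)`` intervals in time units (sample index times
    ``dt`` offset by ``t0``).
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    above = np.asarray(intensity) > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    return [(t0 + s * dt, t0 + e * dt) for s, e in zip(starts, ends)]


def compose_environment(
    foreground: StimulusTrace,
    background: SparseOdor,
    allow_overlap: bool = False,
) -> StimulusTrace:
    """Place a time-varying foreground atop a static background.

    The background is kept as a separate, marked component of the trace so
    the encoder can pre-adapt to it; :meth:`StimulusTrace.total` gives the
    pointwise sum.  Foreground and background supports must be disjoint (the
    background has "a different identity") unless ``allow_overlap`` is set.
    """
    overlap = set(foreground.foreground_support) & set(background.support)
    if overlap and not allow_overlap:
        raise ValueError(
            f"foreground and background supports overlap on {sorted(overlap)}; "
            "pass allow_overlap=True if intended"
        )
    return StimulusTrace(
        foreground.times,
        foreground.dt,
        foreground.signal,
        foreground.foreground_support,
        background=background,
    )
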