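"""Primacy coding: the earliest-responding ORN set as an identity code.

For a rising stimulus, ORN types activate sequentially (most sensitive
first).  The *primacy set of order p* is the unordered set of the p
earliest-responding ORN types; if activation order is invariant to stimulus
strength, primacy sets form a concentration-invariant code for odor
identity.  This module extracts activation orders and primacy sets from
firing-rate traces, finds the smallest number of active ORNs at which the
full CS decoder first succeeds along a rising response, and measures how
consistent an odor's primacy set remains across adapted background
contexts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decoding import decode_success, nonlinear_sparse_decode
from .encoder import (
    AdaptationParams,
    FiringFilter,
    ORNState,
    ReceptorRepertoire,
    integrate_encoder,
)
from .stimuli import SparseOdor, compose_environment, make_sigmoid_stimulus

__all__ = [
    "PrimacySet",
    "ConsistencyReport",
    "activation_order",
    "primacy_set",
    "min_primacy_for_decoding",
    "consistency_across_backgrounds",
]

#: Sentinel returned when an odor can never be decoded along the rise.
NEVER_DECODED = -1


@dataclass(frozen=True)
class PrimacySet:
    """The unordered set of the p earliest-responding ORN types."""

    p: int
    members: frozenset[int]
    active_threshold: float = 5.0

    def __post_init__(self) -> None:
        if len(self.members) != self.p:
            raise ValueError("|members| must equal p")


@dataclass
class ConsistencyReport:
    """Background-(in)variance of an odor's primacy set.

    ``occurrence`` maps each ORN to the percentage of backgrounds whose
    primacy set contains it; the nominal set holds the p most frequent
    ORNs, and ``consistency`` is their mean occurrence percentage --
    100% means the same p ORNs form the primacy set under every
    background.
    """

    p: int
    nominal: PrimacySet
    occurrence: dict[int, float] = field(default_factory=dict)

    @property
    def consistency(self) -> float:
        if not self.nominal.members:
            return 0.0
        return float(np.mean([self.occurrence.get(a, 0.0)
                              for a in self.nominal.members]))


def activation_order(
    state: ORNState | np.ndarray,
    active_threshold: float = 5.0,
    dt: float | None = None,
) -> list[tuple[int, float]]:
    """ORNs ordered by onset time, with the onsets.

    Onset = first time the rate reaches ``active_threshold`` (the firing
    rectifier floor by default).  Never-active ORNs are excluded.  Ties on
    the same sample are broken by ORN index, which is stable under a fixed
    seed.
    """
    if isinstance(state, ORNState):
        rates = state.rates
        times = state.times
    else:
        rates = np.asarray(state)
        if dt is None:
            raise ValueError("dt required when passing a bare rate array")
        times = np.arange(rates.shape[0]) * dt
    active = rates >= active_threshold
    ever = active.any(axis=0)
    onsets = []
    for a in np.flatnonzero(ever):
        onsets.append((int(a), float(times[np.argmax(active[:, a])])))
    onsets.sort(key=lambda pair: (pair[1], pair[0]))
    return onsets


def primacy_set(
    order: list[tuple[int, float]],
    p: int,
    active_threshold: float = 5.0,
) -> PrimacySet | None:
    """First p ORNs of an activation order, as an unordered set.

    Returns None (undefined) when fewer than p ORNs ever activate.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if len(order) < p:
        return None
    return PrimacySet(p, frozenset(a for a, _ in order[:p]), active_threshold)


def min_primacy_for_decoding(
    odor: SparseOdor,
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    background: SparseOdor | None = None,
    filt: FiringFilter | None = None,
    t_half: float = 0.05,
    duration: float = 0.6,
    dt: float = 0.002,
    decode_stride: int = 5,
    adaptive: bool = True,
) -> int:
    """Number of active ORNs when the rising odor is first decoded.

    The odor follows a sigmoid onset (half-max at ``t_half``).  At each
    decode time along the rise, the linearized CS program (about the
    background, with the encoder's current free energies) is solved from
    the measured rates; the result is the count of active ORNs at the
    first success -- the decoding-defined primacy order.  Returns
    ``NEVER_DECODED`` if no time point decodes.
    """
    filt = filt or FiringFilter()
    trace = make_sigmoid_stimulus(odor, t_half=t_half, dt=dt, duration=duration)
    bg = background if background is not None else SparseOdor.zero(odor.n)
    if bg.k > 0:
        trace = compose_environment(trace, bg)
    state = integrate_encoder(trace, repertoire, params, filt,
                              preadapt=adaptive and bg.k > 0,
                              preadapt_beta=0.0,
                              freeze_eps=not adaptive)
    total = trace.total()
    bg_vec = bg.concentrations
    for idx in range(0, total.shape[0], decode_stride):
        r_meas = state.rates[idx]
        active = r_meas >= filt.rect_threshold
        n_active = int(active.sum())
        if n_active == 0:
            continue
        res = nonlinear_sparse_decode(r_meas, state.eps[idx], repertoire,
                                      params, point0=bg_vec, filt=filt)
        if not res.feasible:
            continue
        if decode_success(res.estimate, total[idx], s0=odor.s0):
            return n_active
    return NEVER_DECODED


def consistency_across_backgrounds(
    odor: SparseOdor,
    backgrounds: list[SparseOdor],
    p: int,
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    adaptive: bool = True,
    filt: FiringFilter | None = None,
    t_half: float = 0.05,
    duration: float = 0.4,
    dt: float = 0.002,
    active_threshold: float | None = None,
) -> ConsistencyReport:
    """Primacy-set consistency of one odor across background contexts.

    For each background, the system is adapted to the background (free
    energies at the Weber-Fechner steady state; pinned at the lower bounds
    when non-adaptive) and the odor rises sigmoidally on top; the order-p
    primacy set of the evoked response is recorded.  The nominal set
    collects the p most frequently occurring ORNs, and consistency is
    their mean occurrence percentage across backgrounds.
    """
    filt = filt or FiringFilter()
    thr = filt.rect_threshold if active_threshold is None else active_threshold
    counts: dict[int, int] = {}
    n_valid = 0
    for bg in backgrounds:
        trace = make_sigmoid_stimulus(odor, t_half=t_half, dt=dt,
                                      duration=duration)
        trace = compose_environment(trace, bg, allow_overlap=True)
        state = integrate_encoder(trace, repertoire, params, filt,
                                  preadapt=adaptive,
                                  preadapt_beta=0.0,
                                  freeze_eps=not adaptive)
        # the odor-evoked increment over the adapted background response
        rates_bg = state.rates[0]
        increment = state.rates - rates_bg[None, :]
        order = activation_order(increment, thr, dt=dt)
        pset = primacy_set(order, p, thr)
        if pset is None:
            continue
        n_valid += 1
        for a in pset.members:
            counts[a] = counts.get(a, 0) + 1
    if n_valid == 0:
        return ConsistencyReport(p, PrimacySet(0, frozenset(), thr), {})
    occurrence = {a: 100.0 * c / n_valid for a, c in counts.items()}
    top = sorted(occurrence, key=lambda a: (-occurrence[a], a))[:p]
    nominal = PrimacySet(len(top), frozenset(top), thr)
    return ConsistencyReport(p, nominal, occurrence)
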