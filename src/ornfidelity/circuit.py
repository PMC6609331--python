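"""Antennal-lobe and mushroom-body circuit model with a trained readout.

ORNs expressing the same receptor converge onto one antennal-lobe (AL)
glomerulus, where lateral inhibition implements divisive normalization of
the projection-neuron (PN) output:

    PN_a = Rmax * r_a^n / (r_a^n + sigma^n + (m * sum_b r_b)^n)

PNs then diverge onto Z = 2500 Kenyon cells (KCs), each receiving input
from 7 randomly chosen glomeruli ("claws") with Gaussian weights
N(0, 1/7); KCs are rectified-linear with thresholds set for sparse (~10%)
activation.  A linear readout (J2 ~ N(0, 1/Z) before training) classifies
KC activity by odor identity (softmax over NID classes) or by valence
(binary logistic); only the readout weights and offsets are trained.

:class:`MushroomBodyClassifier` packages the KC expansion plus readout as a
scikit-learn estimator (``fit``/``predict``/``score``), and
:func:`run_classification_experiment` reproduces the held-out-concentration
generalization experiments: train on NID sparse identities at
concentrations drawn over four decades, test on the same identities at
disjoint concentrations, with ORN adaptation and divisive normalization
switchable independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .encoder import (
    AdaptationParams,
    FiringFilter,
    ReceptorRepertoire,
    channel_activity,
    steady_state_epsilon,
)
from .stimuli import sample_sparse_odor

__all__ = [
    "DNParams",
    "CircuitParams",
    "ClassificationTask",
    "AccuracyReport",
    "divisive_normalize",
    "build_circuit",
    "kc_response",
    "train_readout",
    "MushroomBodyClassifier",
    "adapted_orn_rates",
    "run_classification_experiment",
]

Z_KCS = 2500
N_CLAWS = 7


@dataclass(frozen=True)
class DNParams:
    """Divisive-normalization constants of AL gain control.

    Saturating Hill form with exponent ~1.5 as measured for AL lateral
    inhibition; ``m`` scales the pooled population suppression.  The
    specific constants are documented model choices on the scale of
    ORN firing rates (Hz).
    """

    rmax: float = 165.0
    exponent: float = 1.5
    sigma: float = 12.0
    m: float = 0.05


@dataclass
class CircuitParams:
    """Random AL->KC->readout connectivity.

    ``j1`` is (Z, M) with exactly ``claws`` nonzero N(0, 1/claws) weights
    per row; ``j2`` is the (Q, Z) readout initialization N(0, 1/Z);
    ``kc_thresholds`` are rectified-linear offsets, calibrated at fit time
    for a target activation sparseness.
    """

    j1: np.ndarray
    j2: np.ndarray
    kc_thresholds: np.ndarray
    readout_thresholds: np.ndarray
    dn_params: DNParams = field(default_factory=DNParams)

    def __post_init__(self) -> None:
        nnz = (self.j1 != 0).sum(axis=1)
        if nnz.size and not np.all(nnz == nnz[0]):
            raise ValueError("every KC must receive the same number of claws")

    @property
    def z(self) -> int:
        return self.j1.shape[0]

    @property
    def m(self) -> int:
        return self.j1.shape[1]


@dataclass(frozen=True)
class ClassificationTask:
    """Identity or valence classification over NID sparse odor identities."""

    nid: int
    mode: str = "identity"  # or "valence"
    concentration_decades: float = 4.0
    # geometric center of the intensity range, in units of s0: placed in
    # the middle of the adaptive tracking range (well above adaptation
    # onset, with the eps_H headroom covering the upper two decades)
    center_concentration: float = 100.0
    n_train: int = 10
    n_test: int = 10
    k: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("identity", "valence"):
            raise ValueError("mode must be 'identity' or 'valence'")
        if self.nid < 2:
            raise ValueError("need at least two identities")

    @property
    def q(self) -> int:
        return 2 if self.mode == "valence" else self.nid


@dataclass(frozen=True)
class AccuracyReport:
    """Held-out-concentration accuracy (%) under the given condition flags."""

    accuracy: float
    nid: int
    mode: str
    orn_adaptation: bool
    divisive_normalization: bool
    n_test: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 100.0:
            raise ValueError("accuracy must be a percentage")


def divisive_normalize(orn_rates: np.ndarray, dn: DNParams | None = None) -> np.ndarray:
    """PN rates from ORN rates under divisive lateral inhibition.

    Accepts an M-vector or an (n, M) batch.  Bounded in [0, Rmax);
    saturates to Rmax for a lone strongly driven glomerulus and is strictly
    decreasing in the pooled activity of the others.
    """
    dn = dn or DNParams()
    r = np.asarray(orn_rates, dtype=float)
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    squeeze = r.ndim == 1
    if squeeze:
        r = r[None, :]
    rn = r ** dn.exponent
    pool = (dn.m * r.sum(axis=1, keepdims=True)) ** dn.exponent
    pn = dn.rmax * rn / (rn + dn.sigma ** dn.exponent + pool)
    return pn[0] if squeeze else pn


def build_circuit(
    m: int,
    z: int = Z_KCS,
    claws: int = N_CLAWS,
    q: int = 2,
    rng: np.random.Generator | None = None,
    dn: DNParams | None = None,
) -> CircuitParams:
    """Sample the random AL->KC->readout topology.

    Each KC draws ``claws`` distinct glomeruli uniformly; weights are
    N(0, 1/claws).  KC thresholds start at zero and are calibrated when a
    classifier is fitted.
    """
    if rng is None:
        rng = np.random.default_rng()
    if claws > m:
        raise ValueError("claws cannot exceed the number of glomeruli")
    j1 = np.zeros((z, m))
    for row in j1:
        cols = rng.choice(m, size=claws, replace=False)
        row[cols] = rng.normal(0.0, np.sqrt(1.0 / claws), size=claws)
    j2 = rng.normal(0.0, np.sqrt(1.0 / z), size=(q, z))
    return CircuitParams(j1, j2, np.zeros(z), np.zeros(q), dn or DNParams())


def kc_response(
    pn_rates: np.ndarray,
    circuit: CircuitParams,
    as_sparse: bool = False,
) -> np.ndarray | sp.csr_matrix:
    """Rectified-linear KC activations: max(0, J1 @ pn - threshold).

    Accepts an M-vector or (n, M) batch; with ``as_sparse`` the batch
    result is returned as a CSR matrix (KC codes are sparse by
    construction, which keeps the readout training fast).
    """
    pn = np.asarray(pn_rates, dtype=float)
    squeeze = pn.ndim == 1
    if squeeze:
        pn = pn[None, :]
    act = pn @ circuit.j1.T - circuit.kc_thresholds[None, :]
    np.maximum(act, 0.0, out=act)
    if squeeze:
        return act[0]
    return sp.csr_matrix(act) if as_sparse else act


def calibrate_kc_thresholds(
    circuit: CircuitParams,
    pn_batch: np.ndarray,
    sparseness: float = 0.10,
) -> None:
    """Set per-KC thresholds so ~``sparseness`` of inputs activate each KC.

    The threshold of each KC is the (1 - sparseness) quantile of its raw
    claw input over the calibration batch -- the standard way to enforce
    sparse MB codes when thresholds are otherwise unconstrained.
    """
    raw = np.asarray(pn_batch) @ circuit.j1.T
    circuit.kc_thresholds = np.quantile(raw, 1.0 - sparseness, axis=0)


class MushroomBodyClassifier(BaseEstimator, ClassifierMixin):
    """Sparse KC expansion plus trained linear readout.

    A scikit-learn estimator over PN (or raw ORN) rate vectors: ``fit``
    samples the frozen random KC projection (exactly ``claws`` presynaptic
    glomeruli per KC, Gaussian weights), calibrates KC thresholds for the
    target code sparseness on the training batch, and trains only the
    readout -- logistic regression for two classes, softmax cross-entropy
    for more -- to convergence of the convex problem.  J1 and the KC
    thresholds stay fixed during training, mirroring the biology where
    plasticity is confined to MB output synapses.

    Parameters
    ----------
    z, claws : KC count and presynaptic glomeruli per KC.
    kc_sparseness : target fraction of activating inputs per KC.
    random_state : seed for the frozen projection.
    max_iter, tol, C : readout optimization settings; ``C=None`` means an
        unpenalized readout (plain cross-entropy).

    Attributes
    ----------
    circuit_ : the sampled :class:`CircuitParams` (after ``fit``).
    readout_ : the fitted logistic-regression readout.
    classes_ : class labels.
    """

    def __init__(
        self,
        z: int = Z_KCS,
        claws: int = N_CLAWS,
        kc_sparseness: float = 0.10,
        random_state: int = 0,
        max_iter: int = 200,
        tol: float = 1e-4,
        C: float | None = None,
    ) -> None:
        self.z = z
        self.claws = claws
        self.kc_sparseness = kc_sparseness
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.C = C

    def _kc(self, x: np.ndarray) -> sp.csr_matrix:
        return kc_response(np.asarray(x, float), self.circuit_, as_sparse=True)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "MushroomBodyClassifier":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        if x.ndim != 2:
            raise ValueError("x must be (n_samples, n_glomeruli)")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need at least two classes present in y")
        rng = np.random.default_rng(self.random_state)
        self.circuit_ = build_circuit(x.shape[1], self.z, self.claws,
                                      q=classes.size, rng=rng)
        calibrate_kc_thresholds(self.circuit_, x, self.kc_sparseness)
        self.readout_ = LogisticRegression(
            C=np.inf if self.C is None else self.C,
            solver="lbfgs",
            max_iter=self.max_iter,
            tol=self.tol,
        )
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # the iteration cap is a deliberate optimization budget
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.readout_.fit(self._kc(x), y)
        self.classes_ = self.readout_.classes_
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "readout_")
        return self.readout_.predict(self._kc(np.asarray(x, float)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "readout_")
        return self.readout_.predict_proba(self._kc(np.asarray(x, float)))


def train_readout(
    kc_responses: np.ndarray | sp.spmatrix,
    labels: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> LogisticRegression:
    """Train the linear readout alone on precomputed KC activity.

    Logistic regression for two classes, softmax cross-entropy for more;
    unpenalized, optimized to convergence of the convex objective.
    Deterministic given the data and its order.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes present in labels")
    clf = LogisticRegression(C=np.inf, solver="lbfgs",
                             max_iter=max_iter, tol=tol)
    clf.fit(kc_responses, labels)
    return clf


def adapted_orn_rates(
    concentrations: np.ndarray,
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    adaptive: bool = True,
    filt: FiringFilter | None = None,
    context: np.ndarray | None = None,
) -> np.ndarray:
    """Steady ORN rates for a batch of odors under an adaptation context.

    With adaptation, the free energies sit at the Weber-Fechner steady
    state for ``context`` -- the odor environment the system has had time
    to adapt to (e.g. an identity at its mean concentration); samples are
    then read out as excursions of that adapted state.  Adapting to each
    sample's own instantaneous concentration instead would clamp every
    adapted ORN to exactly the target activity and erase the identity
    code.  Without adaptation the free energies are pinned at the lower
    bounds.  ``context`` defaults to the samples themselves (full
    self-adaptation).
    """
    filt = filt or FiringFilter()
    conc = np.asarray(concentrations, dtype=float)
    if adaptive:
        ctx = conc if context is None else np.asarray(context, dtype=float)
        eps = steady_state_epsilon(ctx, params, repertoire, beta=0.0)
    else:
        eps = np.broadcast_to(params.eps_low, (repertoire.m,))
    act = channel_activity(conc, eps, repertoire)
    return filt.rectify(filt.dc_gain * act)


def _sample_concentrations(task: ClassificationTask, rng: np.random.Generator,
                           n: int) -> np.ndarray:
    half = task.concentration_decades / 2.0
    lo = np.log10(task.center_concentration) - half
    hi = np.log10(task.center_concentration) + half
    return 10.0 ** rng.uniform(lo, hi, size=n)


def run_classification_experiment(
    task: ClassificationTask,
    repertoire: ReceptorRepertoire,
    params: AdaptationParams,
    rng: np.random.Generator,
    orn_adaptation: bool = True,
    dn: bool = True,
    dn_params: DNParams | None = None,
    filt: FiringFilter | None = None,
    classifier: MushroomBodyClassifier | None = None,
    concentrations_train: np.ndarray | None = None,
    concentrations_test: np.ndarray | None = None,
    ambient_fraction: float = 0.1,
    rate_noise_sd: float = 1.0,
) -> AccuracyReport:
    """Held-out-concentration classification through the full circuit.

    All samples ride atop a weak static ambient odor (a K-sparse identity
    at ``ambient_fraction`` of the range's center concentration) -- the
    odor environment the adaptive system has had time to adapt to.  With
    ORN adaptation the free energies sit at the Weber-Fechner steady state
    for the ambient, repositioning every ORN's dynamic range around the
    task's intensity span; without adaptation they stay at the lower
    bounds, so the upper decades of the span drive the sensitive ORNs into
    saturation.  (Adapting each sample to its own identity would cancel
    the identity pattern exactly in the Weber regime and erase the code.)

    Pipeline per sample: identity at a drawn concentration + ambient ->
    steady ORN rates -> Gaussian rate jitter (sd ``rate_noise_sd``, the
    1 Hz finite-precision convention of the information analysis) and
    rectification -> optional divisive normalization -> KC expansion ->
    readout.  Train and test concentrations are disjoint draws
    (log-uniform over the task's range unless given explicitly); accuracy
    is measured on the same identities at the held-out concentrations.
    """
    filt = filt or FiringFilter()
    dn_p = dn_params or DNParams()
    identities = [sample_sparse_odor(repertoire.n, task.k, 1.0, rng)
                  for _ in range(task.nid)]
    ambient = sample_sparse_odor(repertoire.n, task.k, 1.0, rng)
    ambient_vec = ambient.concentrations * (
        ambient_fraction * task.center_concentration)
    if orn_adaptation:
        eps = steady_state_epsilon(ambient_vec, params, repertoire, beta=0.0)
    else:
        eps = np.broadcast_to(params.eps_low, (repertoire.m,))
    if task.mode == "valence":
        valence = rng.choice([-1, 1], size=task.nid)

    def build_split(n_per_id, conc_given):
        xs, ys = [], []
        for i, odor in enumerate(identities):
            conc = (_sample_concentrations(task, rng, n_per_id)
                    if conc_given is None else np.asarray(conc_given))
            batch = odor.concentrations[None, :] * conc[:, None] + ambient_vec
            rates = filt.dc_gain * channel_activity(batch, eps, repertoire)
            if rate_noise_sd > 0:
                rates = rates + rng.normal(0.0, rate_noise_sd, rates.shape)
            rates = filt.rectify(np.clip(rates, 0.0, None))
            xs.append(divisive_normalize(rates, dn_p) if dn else rates)
            label = valence[i] if task.mode == "valence" else i
            ys.append(np.full(len(conc), label))
        return np.vstack(xs), np.concatenate(ys)

    x_train, y_train = build_split(task.n_train, concentrations_train)
    x_test, y_test = build_split(task.n_test, concentrations_test)

    clf = classifier or MushroomBodyClassifier(
        random_state=int(rng.integers(2**31 - 1)), max_iter=100, tol=1e-3)
    clf.fit(x_train, y_train)
    acc = 100.0 * float(np.mean(clf.predict(x_test) == y_test))
    return AccuracyReport(acc, task.nid, task.mode, orn_adaptation, dn,
                          n_test=y_test.size)
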