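"""End-to-end experiment pipelines at configurable scale.

Each experiment reproduces one of the package's headline analyses from a
single seeded configuration and writes plain-text artifacts (CSV tables, a
JSON summary, the resolved config) into an output directory:

``mi``
    Mutual information between foreground identity and ORN response as a
    function of the Weber-breaking exponent beta (adaptive beta=0 through
    non-adaptive beta=1).
``decoding``
    Compressed-sensing decoding accuracy over a grid of background
    intensity x complexity, adaptive vs non-adaptive.
``primacy``
    Primacy-set consistency across background identities as a function of
    primacy order, adaptive vs non-adaptive.
``classification``
    Held-out-concentration odor classification through the AL/MB circuit
    under the four adaptation x divisive-normalization conditions.

``scale="desk"`` shrinks the sampled ensembles so a pipeline finishes in
minutes on one core; ``scale="full"`` restores publication-scale numbers.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circuit as cc
from . import decoding as dec
from . import info_metrics as im
from . import primacy as pr
from .encoder import sample_adaptation_params, sample_repertoire
from .stimuli import sample_disjoint_odor, sample_sparse_odor

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENTS"]

EXPERIMENTS = ("mi", "decoding", "primacy", "classification")

#: Aliases for the corresponding publication figures.
FIGURE_ALIASES = {"fig2": "mi", "fig3": "decoding", "fig4": "primacy",
                  "fig5": "classification"}


@dataclass
class ExperimentConfig:
    """Seeded, serializable description of one experiment run."""

    experiment: str
    scale: str = "desk"
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.experiment = FIGURE_ALIASES.get(self.experiment, self.experiment)
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; "
                f"choose from {EXPERIMENTS} or {tuple(FIGURE_ALIASES)}")
        if self.scale not in ("desk", "full"):
            raise ValueError("scale must be 'desk' or 'full'")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        return cls(**json.loads(text))


def _system(seed: int, overrides: dict):
    rng = np.random.default_rng(seed)
    rep = sample_repertoire(
        m=overrides.get("m", 50), n=overrides.get("n", 150), rng=rng)
    par = sample_adaptation_params(m=rep.m, rng=rng)
    return rep, par


def _run_mi(config: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    o = config.overrides
    rep, par = _system(config.seed, o)
    betas = o.get("betas", [0.0, 0.05, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0])
    n_fg = o.get("n_foregrounds", 10)
    n_bg = o.get("n_backgrounds", 50 if config.scale == "full" else 25)
    rows = []
    for beta in betas:
        ens_rng = np.random.default_rng(config.seed + 1)
        ens = im.background_ensemble(rep, par, ens_rng, n_foregrounds=n_fg,
                                     n_backgrounds=n_bg, beta=beta)
        mi = im.estimate_mi(ens, np.random.default_rng(config.seed + 2))
        rows.append({"beta": beta, "mi_bits": mi.bits,
                     "h_response": mi.h_response, "h_noise": mi.h_noise})
    table = pd.DataFrame(rows)
    adaptive = table.loc[table.beta == 0.0, "mi_bits"].iloc[0]
    nonadaptive = table.loc[table.beta == 1.0, "mi_bits"].iloc[0]
    summary = {"mi_adaptive_bits": adaptive,
               "mi_nonadaptive_bits": nonadaptive,
               "mi_margin_bits": adaptive - nonadaptive}
    return table, summary


def _run_decoding(config: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    o = config.overrides
    rep, par = _system(config.seed, o)
    n_pairs = o.get("n_pairs", 20 if config.scale == "full" else 10)
    rng = np.random.default_rng(config.seed + 1)
    intensities = np.asarray(o.get("intensities", [3.0, 10.0, 30.0, 100.0, 300.0]))
    complexities = np.asarray(o.get("complexities", [1, 2, 5, 10, 20]))
    acc_a, acc_n = dec.decoding_accuracy_grid(
        rep, par, rng, intensities=intensities, complexities=complexities,
        n_pairs=n_pairs)
    rows = []
    for ci, c in enumerate(intensities):
        for ki, k in enumerate(complexities):
            rows.append({"background_intensity": c, "background_complexity": k,
                         "accuracy_adaptive": acc_a[ci, ki],
                         "accuracy_nonadaptive": acc_n[ci, ki]})
    table = pd.DataFrame(rows)
    summary = {
        "mean_accuracy_adaptive": float(acc_a.mean()),
        "mean_accuracy_nonadaptive": float(acc_n.mean()),
        "adaptive_dominates": bool(np.all(acc_a >= acc_n)),
        "strict_cells": int((acc_a > acc_n).sum()),
    }
    return table, summary


def _run_primacy(config: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    o = config.overrides
    rep, par = _system(config.seed, o)
    n_bg = o.get("n_backgrounds", 1000 if config.scale == "full" else 50)
    orders = o.get("orders", [5, 10, 15, 20])
    intensity = o.get("intensity", 30.0)
    rng = np.random.default_rng(config.seed + 1)
    odor = sample_sparse_odor(rep.n, o.get("k", 5), 1.0, rng).scaled(intensity)
    bgs = [sample_disjoint_odor(odor, o.get("k", 5), 1.0, rng).scaled(intensity)
           for _ in range(n_bg)]
    rows = []
    for p in orders:
        ca = pr.consistency_across_backgrounds(odor, bgs, p, rep, par,
                                               adaptive=True)
        cn = pr.consistency_across_backgrounds(odor, bgs, p, rep, par,
                                               adaptive=False)
        rows.append({"p": p, "consistency_adaptive": ca.consistency,
                     "consistency_nonadaptive": cn.consistency})
    table = pd.DataFrame(rows)
    high = table[table.p >= 10]
    summary = {
        "adaptive_ge_nonadaptive_for_p_ge_10": bool(
            np.all(high.consistency_adaptive >= high.consistency_nonadaptive)),
        "mean_consistency_adaptive": float(table.consistency_adaptive.mean()),
        "mean_consistency_nonadaptive": float(
            table.consistency_nonadaptive.mean()),
    }
    return table, summary


def _run_classification(config: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    o = config.overrides
    rep, par = _system(config.seed, o)
    nid = o.get("nid", 1000 if config.scale == "full" else 100)
    mode = o.get("mode", "identity")
    task = cc.ClassificationTask(nid=nid, mode=mode,
                                 n_train=o.get("n_train", 10),
                                 n_test=o.get("n_test", 10))
    rows = []
    for adaptation in (True, False):
        for dn in (True, False):
            rng = np.random.default_rng(config.seed + 1)
            report = cc.run_classification_experiment(
                task, rep, par, rng, orn_adaptation=adaptation, dn=dn)
            rows.append({"orn_adaptation": adaptation,
                         "divisive_normalization": dn,
                         "accuracy_percent": report.accuracy})
    table = pd.DataFrame(rows)
    both = table.query("orn_adaptation and divisive_normalization"
                       ).accuracy_percent.iloc[0]
    dn_only = table.query("not orn_adaptation and divisive_normalization"
                          ).accuracy_percent.iloc[0]
    summary = {"nid": nid, "mode": mode,
               "accuracy_adapt_dn": both,
               "accuracy_dn_only": dn_only,
               "adaptation_gain_points": both - dn_only}
    return table, summary


_RUNNERS = {"mi": _run_mi, "decoding": _run_decoding,
            "primacy": _run_primacy, "classification": _run_classification}


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run one experiment pipeline; return (and optionally write) its summary.

    Deterministic under a fixed config.  When ``out_dir`` is given, writes
    ``table.csv``, ``summary.json``, ``config.json`` and a short log there.
    """
    t0 = time.time()
    table, summary = _RUNNERS[config.experiment](config)
    summary = {"experiment": config.experiment, "scale": config.scale,
               "seed": config.seed, **summary}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "table.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        (out / "config.json").write_text(config.to_json())
        (out / "run.log").write_text(
            f"experiment={config.experiment} scale={config.scale} "
            f"seed={config.seed} elapsed_s={time.time() - t0:.1f}\n")
    return summary
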