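# ornfidelity

Does sensory adaptation help or hurt a *combinatorial* code?  Insect
olfactory receptor neurons (ORNs) rescale their gain inversely with the mean
odor concentration — the Weber-Fechner law — through a feedback acting on
the Or/Orco channel rather than on the receptor identity.  Because every
channel adapts the same way, each ORN's dose-response curve slides along the
log-concentration axis to track its own adapted level, and the *pattern* of
activity across the repertoire — the combinatorial code for odor identity —
can survive background odors and intensity changes that would otherwise
saturate or silence it.

`ornfidelity` implements the full analysis chain for this question in
Python, for computational neuroscientists studying olfactory population
codes:

* **Encoding model** — M = 50 ORN types facing an N = 150-dimensional
  odorant space.  Channel activity follows the two-state binding model

  $$A_a = \left[1 + e^{\epsilon_a}\left(\frac{1 + \mathbf{K}_a\cdot\mathbf{s}}{1 + \mathbf{K}^*_a\cdot\mathbf{s}}\right)^{\!R}\,\right]^{-1},$$

  with power-law distributed affinities, and the free energy adapts by
  integral feedback, $\tau\,\dot{\epsilon}_a = A_a - A_{0a}$ with
  $\epsilon_{L,a} \le \epsilon_a \le \epsilon_{H,a}$.  At the adapted state
  the gain obeys $\Delta A_a/\Delta s \simeq A_0(1-A_0)/\bar{s}$ (exact
  Weber-Fechner scaling; a breaking exponent $\beta$ interpolates to the
  non-adapting system).  Firing is the activity convolved with a bi-lobed
  difference-of-gammas filter and rectified at 5 Hz.
* **Synthetic odor environments** — K-sparse mixtures, static backgrounds,
  sigmoidal pulses, and plume-like intensity series with power-law
  (exponent −3/2) whiff/blank durations.
* **Four evaluation pipelines** — mutual information between foreground
  identity and the binned population response; compressed-sensing
  reconstruction ($\min \lVert\Delta s\rVert_1$ s.t.
  $\Delta r = D\,\Delta s$, plus iterative hard thresholding and restricted
  isometry diagnostics); primacy-set consistency; and identity/valence
  classification through divisive normalization and a 2500-Kenyon-cell
  mushroom-body expansion with a trained softmax readout
  (`MushroomBodyClassifier`, a scikit-learn estimator).

## Worked example

```python
import numpy as np
from ornfidelity import (sample_repertoire, sample_adaptation_params,
                         sample_sparse_odor, steady_response, estimate_mi)
from ornfidelity.info_metrics import background_ensemble
from ornfidelity.stimuli import sample_disjoint_odor

rng = np.random.default_rng(0)
repertoire = sample_repertoire(rng=rng)        # M=50 ORN types, N=150 odorants
params = sample_adaptation_params(rng=rng)     # adaptation bounds and targets

odor = sample_sparse_odor(150, 5, 1.0, rng).scaled(30)        # K=5 foreground
background = sample_disjoint_odor(odor, 5, 1.0, rng).scaled(300)

r_adapt = steady_response(odor, background, repertoire, params, beta=0.0)
r_fixed = steady_response(odor, background, repertoire, params, adaptive=False)
print(f"mean rate adapted/non-adapted (Hz):  "
      f"{r_adapt.mean():.1f} / {r_fixed.mean():.1f}")

for beta in (0.0, 1.0):
    ens = background_ensemble(repertoire, params,
                              np.random.default_rng(100), beta=beta)
    mi = estimate_mi(ens, np.random.default_rng(200), n_repeats=4)
    label = "Weber-Fechner (beta=0)" if beta == 0 else "non-adaptive (beta=1)"
    print(f"MI, {label}: {mi.bits:.2f} bits")
```

prints

```
mean rate adapted/non-adapted (Hz):  21.4 / 176.4
MI, Weber-Fechner (beta=0): 2.33 bits
MI, non-adaptive (beta=1): 1.51 bits
```

Adapted to a strong background, the repertoire sits near its target
activity (~21 Hz mean) with headroom to report a novel foreground; without
adaptation the same background drives the population toward saturation
(~176 Hz of a 188.7 Hz ceiling).  Accordingly, across an ensemble of 10
foreground identities on 50 backgrounds spanning the failure envelope of
both systems, the Weber-Fechner code carries ~0.8 bits more foreground
information than the non-adapting one (the ceiling for 10 equiprobable
identities is 3.32 bits).

The same pipelines are scriptable from the shell:

```
ornfidelity run mi --scale desk --seed 0 --out out/mi
ornfidelity run classification --scale desk --seed 0 --out out/cls
ornfidelity plume --duration 60 --seed 1 --out plume.tsv
```

## Layout

| module | contents |
| --- | --- |
| `ornfidelity.stimuli` | sparse odors, pulses, plume-like signals, whiff detection |
| `ornfidelity.encoder` | two-state channel model, adaptation ODE, firing cascade |
| `ornfidelity.info_metrics` | mutual information, t-SNE projection, analytic gain, dose-response |
| `ornfidelity.decoding` | linearized CS, nonnegative/total-signal L1, IHT, RIP, whiff decoding |
| `ornfidelity.primacy` | activation order, primacy sets, background consistency |
| `ornfidelity.circuit` | divisive normalization, KC expansion, `MushroomBodyClassifier` |
| `ornfidelity.experiments` | seeded end-to-end pipelines with CSV/JSON artifacts |

Model assumptions, parameter choices and known limitations are documented
in `docs/methods.md`.
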