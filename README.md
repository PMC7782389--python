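# beamsim

A synthetic EEG bench for beamformer-based source reconstruction and
directed-connectivity analysis. The package simulates multichannel EEG
from sparse multivariate autoregressive (MVAR) source models through an
analytic spherical head model, reconstructs source activity with a
family of spatial filters, and scores both the reconstructed waveforms
and the connectivity structure (PDC/DTF) recovered from them.

## The scientific problem

EEG source reconstruction is an ill-posed inverse problem: activity of a
few cortical sources must be recovered from noisy electrode mixtures of
signal, correlated interference and background brain activity. Spatial
filters (beamformers) attack it with linear constraints — unit gain on
the sources of interest, minimum output variance, optionally exact nulls
on known interference. How well a given filter performs depends on the
noise regime, on the covariance matrix used to build it, and on how
accurately the lead-field (the source-to-sensor propagation model) is
known. Because ground truth is never available in real recordings,
method development needs a simulation bench where truth *is* known and
every one of these factors can be controlled independently.

This package provides that bench:

* **Source model.** Sources of interest and background sources follow
  stable MVAR processes with a shared sparsity mask (by default 80 % of
  the off-diagonal couplings are zero), so the ground-truth directed
  connectivity is known and sparse. Interference sources are maximally
  adversarial: each is the negated copy of a source of interest plus
  equal-power white noise (correlation −1/√2 with the source).
  Optionally an evoked, phase-locked waveform (the first derivative of
  a Gaussian) is added to the post-onset interval.
* **Forward model.** Analytic current-dipole potentials on a spherical
  head (scalp radius 0.100 m, cortical shell 0.078 m, conductivity
  0.33 S/m), average-referenced, with a Fibonacci-lattice electrode
  montage restricted to polar angles ≤ 100°. Geometry errors are modeled
  by perturbing source positions inside a 10 mm cube and orientations
  inside a π/32 cone. Interference, background and measurement noise are
  scaled so the electrode-level dB ratios (SINR/SBNR/SMNR) are met
  *exactly* on the post-onset interval, not just in expectation.
* **Inverse methods.** LCMV, eigenspace-projected LCMV, a nulling
  beamformer with exact zero-gain constraints on a (rank-reducible)
  interference lead-field, and the reduced-rank MV-PURE filter — each
  weighted by either the post-onset signal covariance R or the pre-onset
  noise covariance N.
* **Connectivity.** Partial directed coherence (PDC) and the directed
  transfer function (DTF) on a normalized-frequency grid, plus an MVAR
  refitting routine (stepwise least squares with Schwarz/Akaike order
  selection) applied to the reconstructed sources, closing the loop
  simulation → reconstruction → connectivity recovery.

## Worked example

```python
import beamsim as bs

cfg = bs.generate_default_config()   # 128 electrodes, 5+5+5 sources,
                                     # order-6 MVAR, all ratios 5 dB
results = bs.run_experiment(cfg, seed=0)
print(results[["preset", "cov", "euclidean_error", "correlation"]])
```

which prints (exact numbers, fully determined by the seed):

```
    preset   family cov  rank  euclidean_error  correlation
    LCMV-R     LCMV   R     5            0.710        0.751
    LCMV-N     LCMV   N     5            0.466        0.915
EIG-LCMV-R EIG_LCMV   R     5            0.820        0.625
EIG-LCMV-N EIG_LCMV   N     5            1.067        0.109
      NL-R       NL   R     5            0.787        0.857
      NL-N       NL   N     5            0.788        0.862
   MVP-R-1   MVPURE   R     1            0.950        0.316
   MVP-N-1   MVPURE   N     1            0.896        0.339
   MVP-R-2   MVPURE   R     2            0.904        0.421
   MVP-N-2   MVPURE   N     2            0.747        0.576
   MVP-R-3   MVPURE   R     3            0.825        0.545
   MVP-N-3   MVPURE   N     3            0.630        0.708
   MVP-R-4   MVPURE   R     4            0.738        0.664
   MVP-N-4   MVPURE   N     4            0.455        0.812
```

Two known effects are visible already in this single run: the
noise-covariance-weighted LCMV (LCMV-N, correlation 0.915) clearly beats
its signal-covariance twin (LCMV-R, 0.751), because weighting by R
under correlated interference partially cancels the very sources being
reconstructed; and reduced-rank MV-PURE approaches LCMV as its rank
approaches the number of sources. Under strong interference
(SINR = −10 dB) the nulling beamformer takes over — over seeds 1–5 its
median relative error is 0.442 against 0.828 for plain LCMV (see
`examples/03_beamformer_comparison.py`).

The connectivity loop closes quantitatively: refitting an MVAR model to
a 50 000-sample realization of a known order-3 generator selects order 3,
recovers every coefficient to within 0.0089, and reproduces the |PDC|
profile to a mean absolute deviation of 0.0039
(`examples/04_connectivity.py`).

More narrative walk-throughs live in `examples/`:

| script | shows |
| --- | --- |
| `01_source_simulation.py` | masks, stable MVAR generation, interference, ERP |
| `02_forward_model.py` | montage, lead-fields, perturbation, exact dB calibration |
| `03_beamformer_comparison.py` | the full preset table + LCMV-vs-nulling contrast |
| `04_connectivity.py` | PDC/DTF, hand-checkable values, model refitting |

## Command line

A thin CLI wraps the library:

```bash
beamsim make-config --out config.json        # write the default configuration
beamsim simulate   --config config.json --out sim/
beamsim reconstruct --config config.json --out rec/ --filters LCMV-N,NL-R
beamsim evaluate   --config config.json --filters LCMV,NL
beamsim run        --config config.json --out results/ --seed 3
```

Exit codes: 0 success, 2 configuration error, 3 numerical failure.

## Reproduction

Every run is fully determined by the configuration's `SEED`; independent
named substreams drive geometry, perturbation, masks, model draws and
per-trial noise, so toggling one component does not shift the draws of
another. The two stochastic headline checks can be recomputed for any
seed:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which writes

```json
{
  "t3": {"value": 6, "n": 20000},
  "t5": {"value": 1.0, "n": 50}
}
```

`t3` is the Schwarz-criterion MVAR order selected from a 20 000-sample
realization of the default source model (generator order 6); `t5` is the
maximum |PDC| over 50 random stable models on the full frequency grid
(bounded by 1). Both hold for every seed we tried.

See `docs/methods.md` for the underlying models, numerical choices and
limitations.
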