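# Methods

This note records the models implemented by `beamsim`, the numerical
choices behind them, and their limitations. Symbols: `l` sources of
interest, `k_i` interference sources, `k_b` background sources, `m`
electrodes, `n00` samples per trial (split evenly into a pre-onset and a
post-onset interval), `K00` trials.

## 1. Source dynamics

### Masked stable MVAR models

Sources of interest follow an order-`P00` multivariate autoregression

```
q(n) = Σ_{s=1}^{P00} A_s q(n−s) + ε(n),   ε ~ N(0, I)
```

with a shared binary mask applied to every lag matrix: the diagonal is
always active, and a fraction `frac_zero = 1 − FRAC` (default 0.8) of
the off-diagonal entries is forced to zero at *all* lags. The number of
zeroed couplings is exact: `round(frac_zero · l(l−1))` with half-away
from-zero rounding, positions drawn uniformly without replacement.
Background sources follow an independent order-`R00` model with their
own mask.

Coefficients are drawn i.i.d. uniform on `RNG = (−0.9, 0.9)`. A draw is
accepted only if two criteria hold simultaneously:

1. the spectral radius of the `(l·P00)`-dimensional companion matrix is
   below `STAB = 0.95` (stationarity with margin), and
2. every individual lag matrix has eigenvalue moduli below 1.

A failing draw is rescaled by the common factor `0.95·STAB/ρ` applied to
all lag matrices (up to 8 times per draw); after `ITER = 100` failed
draws a `StabilityError` is raised. Rescaling by a common factor
preserves the mask and the relative coupling pattern.

Realizations start from zeros and discard a 1000-sample burn-in. The
innovation square root is computed from the symmetric eigendecomposition
of the innovation covariance (deterministic: eigenvalues sorted, vector
signs fixed).

### Interference and evoked components

Each interference source is built from a source of interest as
`q_i = −q + n_i`, where `n_i` is white Gaussian noise whose per-row
power equals that of `q`. Consequently `corr(q, q_i) = −1/√2` and
`P(q_i) = 2·P(q)`: interference is strongly negatively correlated with
the very sources a beamformer tries to pass — the adversarial case for
minimum-variance filters. If `k_i ≠ l`, source rows are cycled.

The optional evoked component is the first derivative of a Gaussian,
`ψ(t) ∝ −2ct·exp(−t²)` on `t ∈ [−5, 5]`, normalized to unit energy and
RMS-matched per source; it is added to the post-onset interval only, so
the pre-onset interval remains signal-free under the default flags.

## 2. Forward model

### Geometry and lead-fields

Electrodes sit on a sphere of radius 0.100 m, placed by a Fibonacci
lattice restricted to polar angles ≤ 100° (an upper-head cap). Cortical
sources sit on a shell of radius 0.078 m, grouped into circular patches
of 10° angular radius (one ROI row = one patch), with radial
orientations; optional deep sources are drawn uniformly from a central
ball of radius 0.015 m with uniform random orientations. By default each
patch holds a single source *type* — co-locating interest and
interference sources makes their lead-field columns nearly parallel,
which is both unrealistic and numerically degenerate.

The lead-field uses the infinite homogeneous-medium current-dipole
potential

```
v(r_e) = o · (r_e − r_s) / (4π σ |r_e − r_s|³),   σ = 0.33 S/m
```

followed by average referencing (every column sums to zero). Sources
closer than 1 mm to an electrode raise a `GeometryError`. This is an
analytic idealization: no multi-shell boundary conditions, no realistic
skull conductivity profile — adequate for comparing inverse methods
under controlled conditions, not for individual-subject localization.

### Geometry perturbation

Co-registration error is modeled by displacing each source uniformly
inside a cube of edge `CUBE = 0.010` m (so each axis shift is strictly
below 5 mm) and rotating each orientation by independent azimuth and
elevation angles drawn uniformly from `(−CONE, CONE)`, `CONE = π/32`,
in a local tangent frame (total rotation thus bounded by `2·CONE`).
Filters can be built from the perturbed lead-fields (`H_Src_pert`,
`H_Int_pert`) to study robustness to model mismatch.

### Exact SNR calibration

Components are mixed per the pre/pst flags (defaults: signal absent
pre-onset, everything present post-onset). Before mixing, interference,
background and measurement-noise components are each rescaled so the
electrode-level ratio to the signal component — power pooled over all
channels, samples and trials of the *post-onset* interval — equals the
configured `SINR`/`SBNR`/`SMNR` in dB exactly (to ~1e−9 dB), not just in
expectation. The scale factor is computed from the post-onset slices and
applied to the whole component, so the pre-onset interval keeps the
component's natural power profile.

## 3. Spatial filters

With `C` one of the estimated covariances (R from the post-onset
interval, N from the pre-onset interval; per-trial mean-removed sample
covariances averaged over trials):

* **LCMV** — `W = (HᵀC⁻¹H)⁻¹HᵀC⁻¹`; satisfies `WH = I` and minimizes
  output power among all such filters.
* **EIG-LCMV** — `W = E_r E_rᵀ W_LCMV`, where `E_r` spans the `r`
  dominant eigenvectors of `C`.
* **Nulling (NL)** — stack `F = [H, Ĥ_i]` and keep the first `l` rows of
  the LCMV solution for `F`: `WH = I` and `WĤ_i = 0` exactly. When a
  reduced interference rank is requested, the *scaled left singular
  basis* `U_r s_r` of `H_i` is stacked instead of the truncated matrix
  itself (the truncated matrix has linearly dependent columns by
  construction, making `F` rank deficient); the filter then annuls every
  column of the rank-`r` approximation of `H_i`.
* **MV-PURE** — with `G = (HᵀC⁻¹H)⁻¹`, project onto the eigenvectors of
  `G` carrying its `r` *smallest* eigenvalues: `W = P_r G HᵀC⁻¹`. At
  `r = l` it reproduces LCMV; at lower ranks it trades a small bias for
  a variance reduction that pays off in variance-dominated (low SNR)
  regimes.

Numerical choices: symmetric eigendecompositions are made deterministic
(sorted eigenvalues, sign-fixed vectors); covariances with condition
number above 1e10 receive a ridge of `1e−8 · trace/m`; rank-deficient
lead-fields raise a `RankError` naming the offending columns (pivoted
QR). Covariance weighting by R under correlated interference causes the
well-known self-cancellation of LCMV — the bench exhibits it rather than
hiding it, which is why the noise-weighted variants (`*-N`) are the
accurate ones at high SNR.

## 4. Connectivity

For an MVAR model, the spectral coefficient matrix at normalized
frequency λ (|λ| ≤ 0.5) is `Ā(λ) = I − Σ_s A_s e^(−2πiλs)` with transfer
matrix `H(λ) = Ā(λ)⁻¹` (computed by per-frequency solves, not explicit
inversion). PDC is the column-normalized complex `Ā`; DTF is the
row-normalized transfer magnitude. Squared-magnitude columns (PDC) and
rows (DTF) sum to one; magnitudes are bounded by 1. That bound is exact
in exact arithmetic, and the implementation clamps the ≤ 2-ulp
floating-point rounding excess so it also holds numerically. The default
grid has 129 equispaced points on [0, 0.5]. A coupling masked to zero at
every lag yields exactly zero PDC off the diagonal.

### MVAR refitting

`fit_mvar` fits candidate orders 1..max_order by stepwise least squares
on a common sample (the first `max_order` samples serve as presample for
every candidate, so criteria are comparable) and selects the order
minimizing the Schwarz criterion `log det Σ_p + p l² ln(N)/N` (or Akaike
`+ 2 p l²/N`, or a fixed order). The least-squares step uses the
minimum-norm solution and the criterion floors residual-covariance
eigenvalues, so rank-deficient inputs — exactly what reduced-rank
filters produce — are fitted rather than rejected. At a fixed order on
full-rank data the estimates agree with `statsmodels` VAR (trend-free)
to 1e−8; the suite uses statsmodels only as an independent test oracle.

## 5. Evaluation

Per filter preset the runner reports the relative Euclidean error
`‖q̂ − q‖_F / ‖q‖_F`, the mean per-source Pearson correlation, and three
model-level errors after refitting an MVAR model to the reconstruction
(trials concatenated along time): Frobenius error of the zero-padded
coefficient stacks, and mean absolute |PDC| and DTF deviations over the
grid. Sources are index-aligned (their locations are known to the
filters), so no permutation matching is performed. Every stage is
wrapped in a guard that attaches the stage name to any failure.

## 6. Reproducibility

A root seed feeds named substreams (`geometry`, `perturbation`,
`mask:interest`, `model:interest`, `sig:interest:<trial>`, …) derived
via a CRC32-based spawn key, so enabling or disabling one component does
not shift any other component's draws. All pipeline results are
bit-identical across runs with the same configuration and seed.

## 7. Limitations

* The head model is a single homogeneous sphere with radial cortical
  dipoles — no realistic skull/CSF conductivity, no cortical folding.
* Innovation covariances are identity; cross-source innovation
  correlation is not modeled.
* Interference is tied to sources of interest by construction
  (negation + noise); independent interference processes are not
  provided.
* SNR calibration is exact for the simulated realization, which means
  component powers are data-dependent random variables rescaled post
  hoc — appropriate for controlled comparisons, different from fixing
  generator innovation variances.
* The evaluation aligns sources by index; it does not address the
  permutation/sign ambiguities a blind method would face.
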