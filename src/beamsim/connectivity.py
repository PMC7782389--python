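"""Frequency-domain directed connectivity from MVAR models.

For an l-variate MVAR model with lag matrices A_1..A_p, the spectral
coefficient matrix at normalized frequency lambda (|lambda| <= 0.5) is

    Abar(lambda) = I - sum_s A_s exp(-2 pi i lambda s),

with transfer matrix H(lambda) = Abar(lambda)^-1.  Partial directed
coherence is the column-normalized Abar,

    PDC_ij(lambda) = Abar_ij(lambda) / sqrt(sum_i' |Abar_i'j(lambda)|^2),

quantifying the direct influence j -> i relative to all of j's outflows;
the directed transfer function is the row-normalized transfer magnitude,

    DTF_ji(lambda) = |H_ji(lambda)| / sqrt(sum_i' |H_ji'(lambda)|^2),

the inflow i -> j relative to all inflows into j.  PDC is kept
complex-valued; magnitudes lie in [0, 1], with columns (PDC) and rows
(DTF) of squared magnitudes summing to one.

MVAR models are refitted to reconstructed source signals by stepwise
least squares with Schwarz-criterion (default) or Akaike order selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConditioningError,
    DegenerateInputError,
    InvalidArgumentError,
    SingularFrequencyError,
)
from .mvar import MVARModel

__all__ = [
    "SpectralMVAR",
    "ConnectivityResult",
    "default_freq_grid",
    "spectral_matrix",
    "pdc",
    "dtf",
    "fit_mvar",
    "connectivity_table",
]


def default_freq_grid(resolution: int = 129) -> np.ndarray:
    """Equispaced normalized-frequency grid on [0, 0.5]."""
    return np.linspace(0.0, 0.5, int(resolution))


@dataclass
class SpectralMVAR:
    freqs: np.ndarray              # nfreq
    Abar: np.ndarray               # l x l x nfreq, complex
    transfer: np.ndarray           # l x l x nfreq, complex

    @property
    def n_sources(self) -> int:
        return self.Abar.shape[0]


@dataclass
class ConnectivityResult:
    freqs: np.ndarray
    pdc: Optional[np.ndarray] = None    # complex l x l x nfreq
    dtf: Optional[np.ndarray] = None    # real l x l x nfreq


def spectral_matrix(model: MVARModel, freqs: Optional[Sequence[float]] = None) -> SpectralMVAR:
    """Evaluate Abar(lambda) and the transfer matrix on a frequency grid.

    The transfer matrix is obtained by solving Abar(lambda) X = I per
    frequency rather than by explicit inversion.
    """
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    if np.any(np.abs(freqs) > 0.5):
        raise InvalidArgumentError("normalized frequencies must satisfy |lambda| <= 0.5")
    l = model.n_sources
    nf = freqs.size
    I = np.eye(l)
    Abar = np.empty((l, l, nf), dtype=complex)
    transfer = np.empty((l, l, nf), dtype=complex)
    for f, lam in enumerate(freqs):
        A = I.astype(complex).copy()
        for s in range(model.order):
            A -= model.coeffs[s] * np.exp(-2j * np.pi * lam * (s + 1))
        Abar[:, :, f] = A
        try:
            transfer[:, :, f] = np.linalg.solve(A, I)
        except np.linalg.LinAlgError:
            raise SingularFrequencyError(lam) from None
    return SpectralMVAR(freqs=freqs, Abar=Abar, transfer=transfer)


def pdc(spec: SpectralMVAR) -> ConnectivityResult:
    """Partial directed coherence (complex, column-normalized Abar)."""
    norms = np.sqrt(np.sum(np.abs(spec.Abar) ** 2, axis=0))  # l x nfreq (per column j)
    if np.any(norms == 0.0):
        raise DegenerateInputError("zero column in Abar; PDC undefined")
    ratio = spec.Abar / norms[None, :, :]
    # |PDC| <= 1 holds exactly in exact arithmetic (the numerator is one
    # term of the normalizing sum); clamp the rounding excess so the bound
    # also holds in floating point.  The rescale leaves a couple of ulp of
    # headroom because the vectorized complex magnitude is not correctly
    # rounded and may over-report by up to 2 ulp.
    mag = np.abs(ratio)
    over = mag > 1.0
    if np.any(over):
        scale = np.ones_like(mag)
        scale[over] = (1.0 - 4 * np.finfo(float).eps) / mag[over]
        ratio = ratio * scale
    return ConnectivityResult(freqs=spec.freqs, pdc=ratio)


def dtf(spec: SpectralMVAR) -> ConnectivityResult:
    """Directed transfer function (real magnitudes, row-normalized)."""
    mags = np.abs(spec.transfer)
    norms = np.sqrt(np.sum(mags**2, axis=1))  # l x nfreq (per row j)
    if np.any(norms == 0.0):
        raise DegenerateInputError("zero row in transfer matrix; DTF undefined")
    # same 1-ulp clamp as for PDC: the bound is exact in exact arithmetic
    return ConnectivityResult(freqs=spec.freqs,
                              dtf=np.minimum(mags / norms[:, None, :], 1.0))


def _ols_lagged(x: np.ndarray, order: int, start: int):
    """OLS fit of an order-``order`` VAR on samples from ``start`` on.

    Returns (coeffs (order, l, l), residuals (Neff, l)).  Uses the
    minimum-norm least-squares solution, so it remains well defined for
    rank-deficient (e.g. reduced-rank-reconstructed) data.
    """
    l, n = x.shape
    t_idx = np.arange(start, n)
    Y = x[:, t_idx].T                                   # Neff x l
    Z = np.concatenate([x[:, t_idx - s].T for s in range(1, order + 1)], axis=1)
    B, _, _, _ = np.linalg.lstsq(Z, Y, rcond=None)      # (l*order) x l
    if not np.all(np.isfinite(B)):
        raise ConditioningError("lagged regression produced non-finite coefficients")
    resid = Y - Z @ B
    coeffs = np.stack([B[s * l : (s + 1) * l].T for s in range(order)])
    return coeffs, resid


def _criterion_logdet(resid: np.ndarray) -> float:
    """log det of the ML residual covariance, floored for singular data."""
    sigma = resid.T @ resid / resid.shape[0]
    l = sigma.shape[0]
    w = np.linalg.eigvalsh(0.5 * (sigma + sigma.T))
    floor = max(np.max(w), 1e-300) * 1e-12
    return float(np.sum(np.log(np.clip(w, floor, None))))


def fit_mvar(
    signals: np.ndarray,
    max_order: int = 12,
    criterion: str = "SBC",
) -> MVARModel:
    """Fit an MVAR model to (sources x samples) data by least squares.

    Candidate orders 1..max_order are scored on a common sample (the first
    ``max_order`` samples serve as presample for every candidate) and the
    order minimizing the chosen criterion — Schwarz Bayesian
    ``log det Sigma_p + p l^2 log(N)/N`` by default, 'AIC' with penalty
    ``2 p l^2 / N`` — is refitted on the full usable sample;
    ``criterion='fixed'`` fits exactly at ``max_order``.  The innovation
    covariance is the residual covariance.  The selection criterion floors
    the residual eigenvalues, so rank-deficient inputs (as produced by
    reduced-rank spatial filters) are fitted rather than rejected.
    """
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    l, n = x.shape
    if n <= l * max_order + 1:
        raise InvalidArgumentError(
            f"need more than l*max_order+1 = {l * max_order + 1} samples, got {n}"
        )
    if criterion not in ("SBC", "AIC", "fixed"):
        raise InvalidArgumentError("criterion must be 'SBC', 'AIC' or 'fixed'")
    if criterion == "fixed":
        order = int(max_order)
    else:
        n_eff = n - max_order
        scores = []
        for p in range(1, max_order + 1):
            _, resid = _ols_lagged(x, p, start=max_order)
            logdet = _criterion_logdet(resid)
            n_par = p * l * l
            if criterion == "SBC":
                scores.append(logdet + n_par * np.log(n_eff) / n_eff)
            else:
                scores.append(logdet + 2.0 * n_par / n_eff)
        order = 1 + int(np.argmin(scores))
    coeffs, resid = _ols_lagged(x, order, start=order)
    dof = max(resid.shape[0] - l * order, 1)
    innov = resid.T @ resid / dof
    innov = 0.5 * (innov + innov.T)
    return MVARModel(order=order, coeffs=coeffs, innov_cov=innov)


def connectivity_table(result: ConnectivityResult) -> pd.DataFrame:
    """Long-format table (from, to, freq, |pdc|, dtf) for export."""
    if result.pdc is None and result.dtf is None:
        raise InvalidArgumentError("result carries neither PDC nor DTF")
    ref = result.pdc if result.pdc is not None else result.dtf
    l = ref.shape[0]
    rows = []
    for j in range(l):          # source ("from")
        for i in range(l):      # sink ("to")
            for f, lam in enumerate(result.freqs):
                rows.append({
                    "from": j,
                    "to": i,
                    "freq": lam,
                    "pdc": abs(result.pdc[i, j, f]) if result.pdc is not None else np.nan,
                    "dtf": result.dtf[i, j, f] if result.dtf is not None else np.nan,
                })
    return pd.DataFrame(rows)
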