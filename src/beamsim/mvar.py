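"""Masked, stability-checked MVAR source models and timecourse simulation.

Source dynamics follow an l-variate autoregression of order p,

    q(n) = sum_{s=1..p} A_s q(n-s) + eps(n),   eps(n) ~ N(0, innov_cov),

where each coefficient matrix ``A_s`` is elementwise multiplied by a shared
binary mask that zeroes a configurable fraction of the off-diagonal
couplings (80 % by default).  The mask imposes a sparse, known profile of
directed dependencies between sources, which is what makes the bench
suitable for scoring directed-connectivity estimates (PDC/DTF) downstream.

A generated model is accepted only if it is *stable* in both of the usual
senses: the spectral radius of the companion matrix is below the configured
margin, and every individual ``A_s`` has all eigenvalue moduli below one.

Interference sources are built as the negative of the interest sources plus
white Gaussian noise of matching power, producing strongly (negatively)
correlated interference — the hard case for minimum-variance beamformers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .config import SetupConfig
from .exceptions import DegenerateInputError, InvalidArgumentError, StabilityError
from .rng import RandomStreams

__all__ = [
    "CoeffMask",
    "MVARModel",
    "SourceTimecourses",
    "SourceModels",
    "generate_mask",
    "generate_stable_mvar",
    "simulate_mvar",
    "generate_erp",
    "make_interference",
    "generate_source_models",
    "assemble_sources",
    "save_mvar_json",
    "load_mvar_json",
    "save_timecourses_txt",
]


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

@dataclass
class CoeffMask:
    """Binary mask shared by all lag matrices of one MVAR model."""

    matrix: np.ndarray
    frac_zero: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise InvalidArgumentError("mask must be square")
        if not np.all(np.diag(self.matrix) == 1):
            raise InvalidArgumentError("mask diagonal must be all ones")

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[0]


@dataclass
class MVARModel:
    """MVAR model: order, per-lag coefficient matrices, innovation covariance.

    ``coeffs`` has shape (order, l, l); ``order`` may be zero for fitted
    models of white data (empty coefficient stack).
    """

    order: int
    coeffs: np.ndarray
    innov_cov: np.ndarray
    mask: Optional[np.ndarray] = None
    stability_margin: float = 1.0

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.innov_cov = np.asarray(self.innov_cov, dtype=float)
        l = self.innov_cov.shape[0]
        if self.order < 0:
            raise InvalidArgumentError("order must be >= 0")
        if self.coeffs.shape != (self.order, l, l):
            raise InvalidArgumentError(
                f"coeffs shape {self.coeffs.shape} != ({self.order}, {l}, {l})"
            )
        if not np.allclose(self.innov_cov, self.innov_cov.T):
            raise InvalidArgumentError("innov_cov must be symmetric")

    @property
    def n_sources(self) -> int:
        return self.innov_cov.shape[0]

    def companion(self) -> np.ndarray:
        """Companion (block) form of the lag polynomial."""
        l, p = self.n_sources, self.order
        if p == 0:
            return np.zeros((0, 0))
        C = np.zeros((l * p, l * p))
        C[:l, :] = np.concatenate(self.coeffs, axis=1)
        if p > 1:
            C[l:, :-l] = np.eye(l * (p - 1))
        return C

    def companion_radius(self) -> float:
        if self.order == 0:
            return 0.0
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def per_lag_radius(self) -> float:
        """Largest eigenvalue modulus over the individual lag matrices."""
        if self.order == 0:
            return 0.0
        return max(float(np.max(np.abs(np.linalg.eigvals(A)))) for A in self.coeffs)

    def is_stable(self) -> bool:
        return (
            self.companion_radius() < self.stability_margin
            and self.per_lag_radius() < 1.0
        )

    def stacked_coeffs(self) -> np.ndarray:
        """Horizontal stacking [A_1 ... A_p] (the composite generator matrix)."""
        if self.order == 0:
            return np.zeros((self.n_sources, 0))
        return np.concatenate(self.coeffs, axis=1)


@dataclass
class SourceTimecourses:
    """Simulated source-level activity for one trial.

    ``q`` (interest), ``q_i`` (interference) and ``q_b`` (background) are
    (sources x samples); each trial splits evenly into a pre-onset and a
    post-onset half.  ``erp``, when present, is the deterministic evoked
    component that was added to the *pst* half of ``q`` only.
    """

    q: np.ndarray
    q_i: np.ndarray
    q_b: np.ndarray
    pre_len: int
    pst_len: int
    erp: Optional[np.ndarray] = None

    def __post_init__(self):
        total = self.pre_len + self.pst_len
        for name in ("q", "q_i", "q_b"):
            arr = getattr(self, name)
            if arr.size and arr.shape[1] != total:
                raise InvalidArgumentError(
                    f"{name} has {arr.shape[1]} samples, expected {total}"
                )
        if self.pre_len != self.pst_len:
            raise InvalidArgumentError("pre and pst halves must have equal length")

    @property
    def q_pre(self) -> np.ndarray:
        return self.q[:, : self.pre_len]

    @property
    def q_pst(self) -> np.ndarray:
        return self.q[:, self.pre_len :]


@dataclass
class SourceModels:
    """The pair of generators behind one simulation: interest + background."""

    interest: MVARModel
    background: MVARModel


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def generate_mask(n_sources: int, frac_zero: float, rng: np.random.Generator) -> CoeffMask:
    """Draw a binary coefficient mask: all-ones diagonal, and exactly
    ``round(frac_zero * n(n-1))`` off-diagonal zeros placed uniformly at
    random.  One mask is shared by all lags of a model."""
    if n_sources < 1:
        raise InvalidArgumentError(f"n_sources must be >= 1, got {n_sources}")
    if not (0.0 <= frac_zero <= 1.0):
        raise InvalidArgumentError(f"frac_zero must lie in [0, 1], got {frac_zero}")
    n = int(n_sources)
    n_off = n * (n - 1)
    n_zero = _round_half_away(frac_zero * n_off)
    mask = np.ones((n, n), dtype=int)
    off_idx = [(i, j) for i in range(n) for j in range(n) if i != j]
    if n_zero > 0:
        chosen = rng.choice(len(off_idx), size=n_zero, replace=False)
        for c in chosen:
            i, j = off_idx[c]
            mask[i, j] = 0
    return CoeffMask(matrix=mask, frac_zero=float(frac_zero))


def generate_stable_mvar(
    n_sources: int,
    order: int,
    mask: Optional[CoeffMask] = None,
    stability_margin: float = 0.95,
    eig_range: Sequence[float] = (-0.9, 0.9),
    max_iter: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> MVARModel:
    """Generate a stable masked MVAR model.

    Coefficients are drawn i.i.d. uniform on ``eig_range`` and masked.  If
    the draw is unstable, all lags are rescaled by the common factor
    ``0.95 * stability_margin / rho`` (rho = companion spectral radius);
    the rescale is repeated up to a few times per draw because a common
    factor shrinks, but does not linearly scale, the companion radius.
    Draws are retried up to ``max_iter`` times.
    """
    if n_sources < 1:
        raise InvalidArgumentError("n_sources must be >= 1")
    if order < 1:
        raise InvalidArgumentError("order must be >= 1")
    if not (0 < stability_margin <= 1):
        raise InvalidArgumentError("stability_margin must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    if mask is None:
        mask = CoeffMask(matrix=np.ones((n_sources, n_sources), dtype=int), frac_zero=0.0)
    if mask.n_sources != n_sources:
        raise InvalidArgumentError("mask size does not match n_sources")

    lo, hi = eig_range
    m = mask.matrix.astype(float)
    for _ in range(max_iter):
        coeffs = rng.uniform(lo, hi, size=(order, n_sources, n_sources)) * m
        model = MVARModel(
            order=order,
            coeffs=coeffs,
            innov_cov=np.eye(n_sources),
            mask=mask.matrix.copy(),
            stability_margin=stability_margin,
        )
        for _rescale in range(8):
            if model.is_stable():
                return model
            rho = max(model.companion_radius(), model.per_lag_radius())
            if rho == 0.0:
                break
            factor = 0.95 * stability_margin / rho
            model = MVARModel(
                order=order,
                coeffs=model.coeffs * factor,
                innov_cov=model.innov_cov,
                mask=mask.matrix.copy(),
                stability_margin=stability_margin,
            )
        if model.is_stable():
            return model
    raise StabilityError(
        f"failed to generate a stable MVAR model within {max_iter} draws "
        f"(companion spectral radius bound {stability_margin})"
    )


def simulate_mvar(
    model: MVARModel,
    n_samples: int,
    burn_in: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate a realization of the model (sources x samples).

    The recursion starts from a zero state; the first ``burn_in`` samples
    are discarded so the returned segment is effectively stationary.
    """
    if n_samples < 1:
        raise InvalidArgumentError("n_samples must be >= 1")
    if burn_in < 0:
        raise InvalidArgumentError("burn_in must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    l, p = model.n_sources, model.order
    total = n_samples + burn_in

    # PSD square root of the innovation covariance (handles singular covs).
    w, V = np.linalg.eigh(model.innov_cov)
    w = np.clip(w, 0.0, None)
    sqrt_cov = V * np.sqrt(w)
    eps = rng.standard_normal((total, l)) @ sqrt_cov.T

    x = np.zeros((total + p, l))
    coeffs = model.coeffs
    for n in range(total):
        t = n + p
        acc = eps[n].copy()
        for s in range(p):
            acc += coeffs[s] @ x[t - 1 - s]
        x[t] = acc
    return x[p + burn_in :].T.copy()


def generate_erp(
    n_samples: int,
    amplitude: float = 1.0,
    support: Sequence[float] = (-5.0, 5.0),
) -> np.ndarray:
    """Evoked-response waveform: first derivative of a Gaussian.

    psi(t) = -2 c t exp(-t^2), with c chosen so the sampled waveform has
    unit energy on the grid; the result is scaled by ``amplitude``.
    """
    if n_samples < 2:
        raise InvalidArgumentError("n_samples must be >= 2")
    lo, hi = float(support[0]), float(support[1])
    if not lo < hi:
        raise InvalidArgumentError("support must be a nondegenerate interval")
    t = np.linspace(lo, hi, n_samples)
    psi = -2.0 * t * np.exp(-(t**2))
    energy = np.sqrt(np.sum(psi**2))
    if energy == 0.0:
        raise InvalidArgumentError("ERP waveform has zero energy on this support")
    return amplitude * psi / energy


def make_interference(
    q: np.ndarray,
    rng: np.random.Generator,
    noise_scale: float = 1.0,
) -> np.ndarray:
    """Interference timecourses q_i = -q + n_i.

    ``n_i`` is white Gaussian with per-row power ``noise_scale**2`` times
    the power of the corresponding row of ``q`` (default: equal power, the
    standard construction).  ``noise_scale=0`` yields exactly ``-q``.
    """
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise InvalidArgumentError("q must be nonempty")
    power = np.mean(q**2, axis=1)
    if np.any(power == 0.0):
        raise DegenerateInputError("q has a zero-power row; interference power undefined")
    noise = rng.standard_normal(q.shape) * (noise_scale * np.sqrt(power))[:, None]
    return -q + noise


def generate_source_models(config: SetupConfig, streams: RandomStreams) -> SourceModels:
    """Generate the interest and background MVAR models for one bench run."""
    l, k_b = config.n_interest, config.n_background
    mask_q = generate_mask(l, config.frac_zero, streams.get("mask:interest"))
    interest = generate_stable_mvar(
        l, config.P00, mask_q, config.STAB, config.RNG, config.ITER,
        streams.get("model:interest"),
    )
    if k_b > 0:
        mask_b = generate_mask(k_b, config.frac_zero, streams.get("mask:background"))
        background = generate_stable_mvar(
            k_b, config.R00, mask_b, config.STAB, config.RNG, config.ITER,
            streams.get("model:background"),
        )
    else:
        background = MVARModel(order=1, coeffs=np.zeros((1, 0, 0)),
                               innov_cov=np.zeros((0, 0)))
    return SourceModels(interest=interest, background=background)


def assemble_sources(
    config: SetupConfig,
    streams: RandomStreams,
    models: Optional[SourceModels] = None,
    trial: int = 0,
    burn_in: int = 1000,
) -> SourceTimecourses:
    """Simulate one trial of source-level activity from the bench models.

    Interest sources come from the masked interest model; background
    sources from the independent background model; interference is the
    negative of the interest activity plus equal-power white noise.  When
    the evoked-response flag is set, a first-derivative-of-Gaussian
    waveform (RMS-matched to the stochastic activity, per source) is added
    to the *pst* half of the interest sources only.
    """
    config.validate()
    if models is None:
        models = generate_source_models(config, streams)
    n = config.n00
    pre, pst = config.pre_len, config.pst_len

    q = simulate_mvar(models.interest, n, burn_in, streams.get(f"sig:interest:{trial}"))

    k_i = config.n_interference
    if k_i > 0:
        # Interference mirrors interest sources; if counts differ, interest
        # rows are cycled to the interference count.
        base = q[np.arange(k_i) % q.shape[0]]
        q_i = make_interference(base, streams.get(f"noise:interference:{trial}"))
    else:
        q_i = np.zeros((0, n))

    k_b = config.n_background
    if k_b > 0:
        q_b = simulate_mvar(models.background, n, burn_in,
                            streams.get(f"sig:background:{trial}"))
    else:
        q_b = np.zeros((0, n))

    erp = None
    if config.ERPs:
        psi = generate_erp(pst)            # unit energy
        rms_psi = np.sqrt(np.mean(psi**2))
        rms_q = np.sqrt(np.mean(q[:, pre:] ** 2, axis=1))
        erp = np.outer(rms_q / rms_psi, psi)
        q = q.copy()
        q[:, pre:] += erp

    return SourceTimecourses(q=q, q_i=q_i, q_b=q_b, pre_len=pre, pst_len=pst, erp=erp)


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------

def save_mvar_json(model: MVARModel, path: str | Path, seed: Optional[int] = None) -> None:
    obj = {
        "order": int(model.order),
        "coeffs": model.coeffs.tolist(),
        "innov_cov": model.innov_cov.tolist(),
        "mask": None if model.mask is None else np.asarray(model.mask).tolist(),
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)
        fh.write("\n")


def load_mvar_json(path: str | Path) -> MVARModel:
    with open(path) as fh:
        obj = json.load(fh)
    mask = obj.get("mask")
    return MVARModel(
        order=int(obj["order"]),
        coeffs=np.asarray(obj["coeffs"], dtype=float),
        innov_cov=np.asarray(obj["innov_cov"], dtype=float),
        mask=None if mask is None else np.asarray(mask),
    )


def save_timecourses_txt(array: np.ndarray, path: str | Path) -> None:
    """One row per source, whitespace-delimited."""
    np.savetxt(path, np.asarray(array))
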