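"""Spatial filters (beamformers) for source reconstruction.

Given the sensor recording y and a lead-field H of the l sources of
interest, a spatial filter is a matrix W (l x m) with reconstruction
q_hat = W y.  Four families are implemented:

LCMV
    W = (H' C^-1 H)^-1 H' C^-1 — unit gain to the modelled sources
    (W H = I), minimum output variance.
EIG-LCMV
    LCMV projected onto the dominant rank-r eigenspace of the data
    covariance: W = E_r E_r' W_LCMV.
NL (nulling)
    LCMV with exact-zero gain constraints on a (rank-reduced)
    interference lead-field: stack F = [H, H_i_hat] and keep the first l
    rows of the constrained solution, so W H = I and W H_i_hat = 0.
MV-PURE
    Reduced-rank minimum-variance pseudo-unbiased filter: with
    G = (H' C^-1 H)^-1, project onto the eigenvectors of G with the r
    *smallest* eigenvalues, W = P_r G H' C^-1.  Trades bias for variance
    at low SNR; at full rank it coincides with LCMV.

Each family may be weighted by either the post-onset signal covariance R
or the pre-onset noise covariance N.  A preset table enumerates named
(family, covariance, rank) combinations used by the experiment runner.

Eigendecompositions are made deterministic: eigenvalues sorted, each
eigenvector's sign fixed so its largest-magnitude entry is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import scipy.linalg

from .exceptions import InvalidArgumentError, RankError
from .forward import TrialData
from .head import Leadfield

logger = logging.getLogger(__name__)

__all__ = [
    "CovarianceEstimates",
    "SpatialFilter",
    "FilterSpec",
    "estimate_covariances",
    "lcmv",
    "eig_lcmv",
    "reduce_rank_leadfield",
    "nulling",
    "mv_pure",
    "apply_filter",
    "standard_presets",
    "synthesize_filter",
]

COND_LIMIT = 1e10
AUTO_RIDGE = 1e-8


@dataclass
class CovarianceEstimates:
    """Sensor covariances: R from the pst interval, N from the pre interval."""

    R: np.ndarray
    N: np.ndarray
    shrinkage: float = 0.0

    def get(self, which: str) -> np.ndarray:
        if which not in ("R", "N"):
            raise InvalidArgumentError(f"covariance must be 'R' or 'N', got {which!r}")
        return self.R if which == "R" else self.N


@dataclass
class SpatialFilter:
    W: np.ndarray
    family: str
    rank: int
    cov_used: str = "R"
    leadfield_variant: str = "original"

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if not np.all(np.isfinite(self.W)):
            raise InvalidArgumentError("filter coefficients must be finite")


@dataclass(frozen=True)
class FilterSpec:
    """One named preset: a (family, covariance, rank) combination."""

    family: str            # LCMV | EIG_LCMV | NL | MVPURE
    cov: str = "R"         # R | N
    rank: Optional[int] = None


# ----------------------------------------------------------------------
# covariance estimation
# ----------------------------------------------------------------------

def _sample_cov(x: np.ndarray) -> np.ndarray:
    """Mean-removed sample covariance of a channels x samples segment."""
    xc = x - x.mean(axis=1, keepdims=True)
    return (xc @ xc.T) / (x.shape[1] - 1)


def estimate_covariances(recording: TrialData, shrinkage: float = 0.0) -> CovarianceEstimates:
    """Per-trial mean-removed sample covariances averaged over trials.

    Ridge shrinkage adds ``shrinkage * (trace/m) * I`` to each estimate.
    """
    if recording.pre_len < 2 or recording.pst_len < 2:
        raise InvalidArgumentError("need at least 2 samples per interval")
    m = recording.n_channels
    N = np.mean([_sample_cov(t) for t in recording.y_pre], axis=0)
    R = np.mean([_sample_cov(t) for t in recording.y_pst], axis=0)
    if shrinkage > 0:
        N = N + shrinkage * (np.trace(N) / m) * np.eye(m)
        R = R + shrinkage * (np.trace(R) / m) * np.eye(m)
    return CovarianceEstimates(R=R, N=N, shrinkage=float(shrinkage))


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------

def _gain(H) -> np.ndarray:
    g = H.gain if isinstance(H, Leadfield) else np.asarray(H, dtype=float)
    return np.atleast_2d(g)


def _check_full_column_rank(G: np.ndarray, what: str) -> None:
    r = np.linalg.matrix_rank(G)
    if r < G.shape[1]:
        # identify offending columns via pivoted QR: the non-pivot tail
        _, _, piv = scipy.linalg.qr(G, pivoting=True)
        offending = sorted(int(c) for c in piv[r:])
        raise RankError(
            f"{what} is rank deficient (rank {r} < {G.shape[1]} columns); "
            f"offending columns: {offending}"
        )


def _regularized(C: np.ndarray) -> np.ndarray:
    """Ridge-stabilize C if its condition number exceeds COND_LIMIT."""
    C = np.asarray(C, dtype=float)
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        ridge = AUTO_RIDGE * (np.trace(C) / C.shape[0])
        logger.warning(
            "covariance condition number %.3g exceeds %.0e; adding ridge %.3g",
            cond, COND_LIMIT, ridge,
        )
        C = C + ridge * np.eye(C.shape[0])
    return C


def _solve_spd(C: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve C X = B for symmetric positive-definite C."""
    c, low = scipy.linalg.cho_factor(C)
    return scipy.linalg.cho_solve((c, low), B)


def _deterministic_eigh(C: np.ndarray):
    """Symmetric eigendecomposition, eigenvalues descending, signs fixed
    (largest-magnitude entry of each vector positive, ties by index)."""
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    for j in range(V.shape[1]):
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    return w, V


# ----------------------------------------------------------------------
# filter synthesis
# ----------------------------------------------------------------------

def _lcmv_matrix(G: np.ndarray, C: np.ndarray) -> np.ndarray:
    _check_full_column_rank(G, "lead-field")
    C = _regularized(C)
    Cinv_H = _solve_spd(C, G)
    gram = G.T @ Cinv_H
    return np.linalg.solve(gram, Cinv_H.T)


def lcmv(H, C: np.ndarray, cov_used: str = "R",
         leadfield_variant: str = "original") -> SpatialFilter:
    """Linearly constrained minimum-variance filter; satisfies W H = I."""
    G = _gain(H)
    W = _lcmv_matrix(G, C)
    return SpatialFilter(W=W, family="LCMV", rank=G.shape[1],
                         cov_used=cov_used, leadfield_variant=leadfield_variant)


def eig_lcmv(H, C: np.ndarray, rank: int, cov_used: str = "R",
             leadfield_variant: str = "original") -> SpatialFilter:
    """Eigenspace LCMV: project the LCMV output onto the span of the
    ``rank`` dominant eigenvectors of C."""
    G = _gain(H)
    m = G.shape[0]
    if not (1 <= rank <= m):
        raise InvalidArgumentError(f"rank must lie in [1, {m}], got {rank}")
    W_l = _lcmv_matrix(G, C)
    _, V = _deterministic_eigh(np.asarray(C, dtype=float))
    E = V[:, :rank]
    W = W_l @ (E @ E.T)
    return SpatialFilter(W=W, family="EIG_LCMV", rank=int(rank),
                         cov_used=cov_used, leadfield_variant=leadfield_variant)


def reduce_rank_leadfield(H_i, rank: int) -> Leadfield:
    """Best Frobenius rank-``rank`` approximation (SVD truncation) of an
    interference lead-field — the patch-constrained reduced-rank form used
    by the nulling filter."""
    G = _gain(H_i)
    max_rank = min(G.shape)
    if not (1 <= rank <= max_rank):
        raise InvalidArgumentError(f"rank must lie in [1, {max_rank}], got {rank}")
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    G_hat = (U[:, :rank] * s[:rank]) @ Vt[:rank]
    lf = H_i if isinstance(H_i, Leadfield) else None
    return Leadfield(gain=G_hat,
                     labels=lf.labels if lf is not None else None,
                     perturbed=lf.perturbed if lf is not None else False)


def nulling(H, H_i, C: np.ndarray, int_rank: Optional[int] = None,
            cov_used: str = "R", leadfield_variant: str = "original") -> SpatialFilter:
    """Nulling beamformer: unit gain on H, exact zero gain on the
    (rank-reduced) interference lead-field.  With no interference columns
    it reduces to plain LCMV."""
    G = _gain(H)
    l = G.shape[1]
    Gi = _gain(H_i) if H_i is not None else np.zeros((G.shape[0], 0))
    if Gi.shape[1] == 0:
        f = lcmv(G, C, cov_used=cov_used, leadfield_variant=leadfield_variant)
        return SpatialFilter(W=f.W, family="NL", rank=l, cov_used=cov_used,
                             leadfield_variant=leadfield_variant)
    if int_rank is not None and int_rank < min(Gi.shape):
        # Null the rank-r principal column subspace of H_i: stacking the
        # truncated H_i itself would make F rank deficient (its columns
        # become linearly dependent), so stack the scaled left singular
        # basis instead; W then annuls every column of the reduced H_i.
        U, s, _ = np.linalg.svd(Gi, full_matrices=False)
        Gi = U[:, :int_rank] * s[:int_rank]
    F = np.concatenate([G, Gi], axis=1)
    _check_full_column_rank(F, "stacked [H, H_i] constraint matrix")
    W_full = _lcmv_matrix(F, C)
    return SpatialFilter(W=W_full[:l], family="NL", rank=l, cov_used=cov_used,
                         leadfield_variant=leadfield_variant)


def mv_pure(H, C: np.ndarray, rank: int, cov_used: str = "R",
            leadfield_variant: str = "original") -> SpatialFilter:
    """Minimum-variance pseudo-unbiased reduced-rank filter.

    With G = (H' C^-1 H)^-1, projects onto the eigenvectors of G carrying
    its ``rank`` smallest eigenvalues (the directions of least output
    variance): W = P_r G H' C^-1.  rank = l reproduces LCMV.
    """
    Hm = _gain(H)
    l = Hm.shape[1]
    if not (1 <= rank <= l):
        raise InvalidArgumentError(f"rank must lie in [1, {l}], got {rank}")
    _check_full_column_rank(Hm, "lead-field")
    C = _regularized(C)
    Cinv_H = _solve_spd(C, Hm)
    gram = Hm.T @ Cinv_H
    G_mat = np.linalg.inv(gram)
    G_mat = 0.5 * (G_mat + G_mat.T)
    _, V = _deterministic_eigh(G_mat)       # eigenvalues descending
    E = V[:, l - rank :]                    # rank smallest
    P = E @ E.T
    W = P @ G_mat @ Cinv_H.T
    return SpatialFilter(W=W, family="MVPURE", rank=int(rank),
                         cov_used=cov_used, leadfield_variant=leadfield_variant)


# ----------------------------------------------------------------------
# application & presets
# ----------------------------------------------------------------------

def apply_filter(filt: SpatialFilter, recording) -> np.ndarray:
    """Reconstruct q_hat = W y from the pst interval.

    ``recording`` may be a :class:`TrialData` (returns trials x l x
    pst_len) or a channels x samples array (returns l x samples).
    """
    W = filt.W
    if isinstance(recording, TrialData):
        y = recording.y_pst
        if y.shape[1] != W.shape[1]:
            raise InvalidArgumentError("channel count mismatch")
        return np.einsum("lm,kmn->kln", W, y)
    y = np.atleast_2d(np.asarray(recording, dtype=float))
    if y.shape[0] != W.shape[1]:
        raise InvalidArgumentError("channel count mismatch")
    return W @ y


def standard_presets(n_interest: int, rank_eig: Optional[int] = None,
                     int_rank: Optional[int] = None) -> Dict[str, FilterSpec]:
    """Named preset table spanning the filter families.

    Each family appears weighted by the signal covariance R and the noise
    covariance N; MV-PURE additionally spans reconstruction ranks
    1 .. l-1 (rank l equals LCMV).  Edit here to add variants.
    """
    l = int(n_interest)
    presets: Dict[str, FilterSpec] = {
        "LCMV-R": FilterSpec("LCMV", "R"),
        "LCMV-N": FilterSpec("LCMV", "N"),
        "EIG-LCMV-R": FilterSpec("EIG_LCMV", "R", rank_eig or l),
        "EIG-LCMV-N": FilterSpec("EIG_LCMV", "N", rank_eig or l),
        "NL-R": FilterSpec("NL", "R", int_rank),
        "NL-N": FilterSpec("NL", "N", int_rank),
    }
    for r in range(1, l):
        presets[f"MVP-R-{r}"] = FilterSpec("MVPURE", "R", r)
        presets[f"MVP-N-{r}"] = FilterSpec("MVPURE", "N", r)
    return presets


def synthesize_filter(spec: FilterSpec, H, H_i, cov: CovarianceEstimates,
                      leadfield_variant: str = "original") -> SpatialFilter:
    """Build the filter a preset describes from lead-fields + covariances."""
    C = cov.get(spec.cov)
    l = _gain(H).shape[1]
    if spec.family == "LCMV":
        return lcmv(H, C, cov_used=spec.cov, leadfield_variant=leadfield_variant)
    if spec.family == "EIG_LCMV":
        return eig_lcmv(H, C, spec.rank or l, cov_used=spec.cov,
                        leadfield_variant=leadfield_variant)
    if spec.family == "NL":
        return nulling(H, H_i, C, int_rank=spec.rank, cov_used=spec.cov,
                       leadfield_variant=leadfield_variant)
    if spec.family == "MVPURE":
        return mv_pure(H, C, spec.rank or l, cov_used=spec.cov,
                       leadfield_variant=leadfield_variant)
    raise InvalidArgumentError(f"unknown filter family {spec.family!r}")
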