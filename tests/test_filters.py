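"""Covariance estimation and the spatial-filter family."""

import numpy as np
import pytest

import beamsim as bs
from beamsim.exceptions import InvalidArgumentError, RankError
from beamsim.filters import (
    CovarianceEstimates,
    FilterSpec,
    estimate_covariances,
    reduce_rank_leadfield,
    standard_presets,
    synthesize_filter,
)
from beamsim.forward import TrialData


def _trialdata(y):
    """Wrap a trials x channels x samples array, split evenly pre/pst."""
    n = y.shape[2]
    return TrialData(data=y, pre_len=n // 2, pst_len=n - n // 2)


class TestCovariances:
    def test_white_noise_near_identity(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((2, 4, 100_000))
        cov = estimate_covariances(_trialdata(y))
        for C in (cov.R, cov.N):
            assert np.allclose(C, np.eye(4), atol=0.05)

    def test_constant_channel_zero_row(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal((1, 3, 200))
        y[:, 0, :] = 7.5  # constant channel: zero variance after demeaning
        cov = estimate_covariances(_trialdata(y))
        assert np.allclose(cov.R[0], 0.0) and np.allclose(cov.R[:, 0], 0.0)

    def test_duplicate_trials_average_to_single(self):
        rng = np.random.default_rng(2)
        y1 = rng.standard_normal((1, 3, 100))
        y2 = np.concatenate([y1, y1], axis=0)
        c1 = estimate_covariances(_trialdata(y1))
        c2 = estimate_covariances(_trialdata(y2))
        assert np.allclose(c1.R, c2.R) and np.allclose(c1.N, c2.N)

    def test_shrinkage_adds_scaled_identity(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal((2, 3, 100))
        c0 = estimate_covariances(_trialdata(y))
        c1 = estimate_covariances(_trialdata(y), shrinkage=0.5)
        delta = c1.R - c0.R
        assert np.allclose(delta, delta[0, 0] * np.eye(3))
        assert delta[0, 0] == pytest.approx(0.5 * np.trace(c0.R) / 3)

    def test_bad_selector_rejected(self):
        cov = CovarianceEstimates(R=np.eye(2), N=np.eye(2))
        with pytest.raises(InvalidArgumentError):
            cov.get("Q")


class TestLcmv:
    def test_identity_cov_orthonormal_leadfield(self):
        # C = I and H'H = I make W = (H'H)^-1 H' = H'
        H = np.linalg.qr(np.random.default_rng(4).standard_normal((8, 3)))[0]
        f = bs.lcmv(H, np.eye(8))
        assert np.allclose(f.W, H.T, atol=1e-10)

    def test_square_leadfield_gives_inverse(self):
        rng = np.random.default_rng(5)
        H = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        f = bs.lcmv(H, np.eye(4))
        assert np.allclose(f.W, np.linalg.inv(H), atol=1e-8)

    def test_unit_gain_constraint(self):
        rng = np.random.default_rng(6)
        H = rng.standard_normal((8, 3))
        C = np.cov(rng.standard_normal((8, 500)))
        f = bs.lcmv(H, C)
        assert np.linalg.norm(f.W @ H - np.eye(3)) < 1e-8

    def test_minimum_variance_among_constrained_filters(self):
        # any other W satisfying WH=I has larger output power tr(W C W')
        rng = np.random.default_rng(7)
        H = rng.standard_normal((8, 3))
        A = rng.standard_normal((8, 200))
        C = A @ A.T / 200
        W0 = bs.lcmv(H, C).W
        p0 = np.trace(W0 @ C @ W0.T)
        proj = np.eye(8) - H @ np.linalg.solve(H.T @ H, H.T)
        for _ in range(20):
            Z = rng.standard_normal((3, 8))
            W = W0 + Z @ proj  # still satisfies W H = I
            assert np.linalg.norm(W @ H - np.eye(3)) < 1e-8
            assert np.trace(W @ C @ W.T) >= p0 - 1e-10

    def test_rank_deficient_leadfield_names_columns(self):
        rng = np.random.default_rng(8)
        H = rng.standard_normal((6, 3))
        H[:, 2] = H[:, 0]  # duplicate column
        with pytest.raises(RankError, match="columns"):
            bs.lcmv(H, np.eye(6))


class TestEigLcmv:
    def test_full_rank_equals_lcmv(self):
        rng = np.random.default_rng(9)
        H = rng.standard_normal((6, 2))
        A = rng.standard_normal((6, 300))
        C = A @ A.T / 300
        assert np.allclose(bs.eig_lcmv(H, C, rank=6).W, bs.lcmv(H, C).W, atol=1e-10)

    def test_rows_live_in_dominant_eigenspace(self):
        rng = np.random.default_rng(10)
        H = rng.standard_normal((6, 2))
        A = rng.standard_normal((6, 300))
        C = A @ A.T / 300
        r = 3
        W_l = bs.lcmv(H, C).W
        W_e = bs.eig_lcmv(H, C, rank=r).W
        w, V = np.linalg.eigh(C)
        E = V[:, np.argsort(w)[::-1][:r]]  # top-r eigenvectors
        # rows of W_e have no component outside span(E) ...
        assert np.allclose(W_e @ (np.eye(6) - E @ E.T), 0.0, atol=1e-10)
        # ... and inside span(E) the filter agrees with plain LCMV
        assert np.allclose(W_e @ E, W_l @ E, atol=1e-10)

    def test_diagonal_cov_rank_one_keeps_dominant_axis(self):
        C = np.diag([10.0, 1.0, 0.5])
        H = np.eye(3)[:, :2]
        W = bs.eig_lcmv(H, C, rank=1).W
        # only the first (dominant) sensor axis survives the projection
        assert np.allclose(W[:, 1:], 0.0, atol=1e-12)

    def test_rank_bounds(self):
        with pytest.raises(InvalidArgumentError):
            bs.eig_lcmv(np.eye(3)[:, :2], np.eye(3), rank=0)
        with pytest.raises(InvalidArgumentError):
            bs.eig_lcmv(np.eye(3)[:, :2], np.eye(3), rank=4)


class TestReduceRank:
    def test_rank_is_reduced(self):
        rng = np.random.default_rng(11)
        G = rng.standard_normal((8, 4))
        for r in (1, 2, 3):
            assert np.linalg.matrix_rank(reduce_rank_leadfield(G, r).gain) == r

    def test_full_rank_is_identity_operation(self):
        rng = np.random.default_rng(12)
        G = rng.standard_normal((8, 4))
        assert np.allclose(reduce_rank_leadfield(G, 4).gain, G, atol=1e-10)

    def test_best_frobenius_approximation(self):
        # Eckart-Young: no other rank-r matrix comes closer in Frobenius norm
        rng = np.random.default_rng(13)
        G = rng.standard_normal((8, 4))
        r = 2
        err0 = np.linalg.norm(G - reduce_rank_leadfield(G, r).gain)
        for _ in range(20):
            B = rng.standard_normal((8, r)) @ rng.standard_normal((r, 4))
            assert np.linalg.norm(G - B) >= err0 - 1e-10


class TestNulling:
    def _instance(self, seed=14, m=12, l=2, k=3):
        rng = np.random.default_rng(seed)
        H = rng.standard_normal((m, l))
        Hi = rng.standard_normal((m, k))
        A = rng.standard_normal((m, 5 * m))
        C = A @ A.T / (5 * m)
        return H, Hi, C, rng

    def test_unit_gain_and_exact_nulls(self):
        H, Hi, C, _ = self._instance()
        f = bs.nulling(H, Hi, C)
        assert np.linalg.norm(f.W @ H - np.eye(2)) < 1e-8
        assert np.linalg.norm(f.W @ Hi) < 1e-8

    def test_reduced_rank_nulls_reduced_leadfield(self):
        H, Hi, C, _ = self._instance(seed=15)
        Hi_hat = reduce_rank_leadfield(Hi, 2).gain
        f = bs.nulling(H, Hi, C, int_rank=2)
        assert np.linalg.norm(f.W @ H - np.eye(2)) < 1e-8
        assert np.linalg.norm(f.W @ Hi_hat) < 1e-8

    def test_interference_leakage_suppressed(self):
        H, Hi, C, rng = self._instance(seed=16)
        q_i = rng.standard_normal((3, 100))
        y = Hi @ q_i
        f = bs.nulling(H, Hi, C)
        assert np.linalg.norm(f.W @ y) < 1e-8 * np.linalg.norm(y)

    def test_empty_interference_reduces_to_lcmv(self):
        H, _, C, _ = self._instance(seed=17)
        f = bs.nulling(H, None, C)
        assert np.allclose(f.W, bs.lcmv(H, C).W)
        assert f.family == "NL"

    def test_overlapping_constraints_rejected(self):
        H, _, C, _ = self._instance(seed=18)
        with pytest.raises(RankError):
            bs.nulling(H, H[:, [0]], C)  # interference column duplicates H


class TestMvPure:
    def test_full_rank_equals_lcmv(self):
        rng = np.random.default_rng(19)
        H = rng.standard_normal((8, 3))
        A = rng.standard_normal((8, 400))
        C = A @ A.T / 400
        assert np.allclose(bs.mv_pure(H, C, rank=3).W, bs.lcmv(H, C).W, atol=1e-8)

    def test_row_space_dimension_bounded_by_rank(self):
        rng = np.random.default_rng(20)
        H = rng.standard_normal((10, 4))
        A = rng.standard_normal((10, 400))
        C = A @ A.T / 400
        for r in (1, 2, 3):
            W = bs.mv_pure(H, C, rank=r).W
            assert np.linalg.matrix_rank(W, tol=1e-10) <= r

    def test_rank_bounds(self):
        rng = np.random.default_rng(21)
        H = rng.standard_normal((6, 3))
        with pytest.raises(InvalidArgumentError):
            bs.mv_pure(H, np.eye(6), rank=0)
        with pytest.raises(InvalidArgumentError):
            bs.mv_pure(H, np.eye(6), rank=4)

    def test_beats_lcmv_in_variance_dominated_regime(self):
        # correlated interference at -10 dB and heavy sensor noise at -5 dB:
        # the reduced-rank filter trades a small bias for a large variance
        # reduction and should win most repetitions
        rng = np.random.default_rng(12345)
        wins, reps = 0, 50
        for _ in range(reps):
            m, l, n = 12, 3, 400
            H = rng.standard_normal((m, l))
            Hi = rng.standard_normal((m, l))
            q = rng.standard_normal((l, n))
            q_i = -q + rng.standard_normal((l, n))
            sig = H @ q
            intf = Hi @ q_i
            intf *= np.sqrt(np.mean(sig**2) / (np.mean(intf**2) * 10 ** (-1.0)))
            noise = rng.standard_normal((m, n))
            noise *= np.sqrt(np.mean(sig**2) / (np.mean(noise**2) * 10 ** (-0.5)))
            y = sig + intf + noise
            R = y @ y.T / n
            e_lcmv = np.mean((bs.lcmv(H, R).W @ y - q) ** 2)
            e_mvp = np.mean((bs.mv_pure(H, R, l - 1).W @ y - q) ** 2)
            wins += e_mvp <= e_lcmv
        assert wins / reps >= 0.6


class TestApplyAndPresets:
    def test_apply_identity_filter(self):
        rng = np.random.default_rng(22)
        y = rng.standard_normal((3, 50))
        f = bs.SpatialFilter(W=np.eye(3), family="LCMV", rank=3)
        assert np.array_equal(bs.apply_filter(f, y), y)

    def test_noiseless_reconstruction_is_exact(self):
        rng = np.random.default_rng(23)
        H = rng.standard_normal((8, 3))
        q = rng.standard_normal((3, 200))
        y = H @ q
        f = bs.lcmv(H, np.eye(8))
        assert np.allclose(bs.apply_filter(f, y), q, atol=1e-8)

    def test_trialwise_application_matches_loop(self):
        rng = np.random.default_rng(24)
        y = rng.standard_normal((4, 5, 60))
        td = _trialdata(y)
        W = rng.standard_normal((2, 5))
        f = bs.SpatialFilter(W=W, family="LCMV", rank=2)
        out = bs.apply_filter(f, td)
        assert out.shape == (4, 2, td.pst_len)
        for k in range(4):
            assert np.allclose(out[k], W @ td.y_pst[k])

    def test_preset_table_contents(self):
        presets = standard_presets(n_interest=3)
        assert set(presets) == {
            "LCMV-R", "LCMV-N", "EIG-LCMV-R", "EIG-LCMV-N", "NL-R", "NL-N",
            "MVP-R-1", "MVP-R-2", "MVP-N-1", "MVP-N-2",
        }

    def test_families_coincide_at_full_rank_without_interference(self):
        rng = np.random.default_rng(25)
        m, l = 8, 3
        H = rng.standard_normal((m, l))
        A = rng.standard_normal((m, 400))
        C = A @ A.T / 400
        cov = CovarianceEstimates(R=C, N=np.eye(m))
        W_ref = bs.lcmv(H, C).W
        for spec in (FilterSpec("EIG_LCMV", "R", m), FilterSpec("NL", "R"),
                     FilterSpec("MVPURE", "R", l)):
            W = synthesize_filter(spec, H, None, cov).W
            assert np.allclose(W, W_ref, atol=1e-8)

    def test_synthesis_is_deterministic(self):
        rng = np.random.default_rng(26)
        H = rng.standard_normal((8, 3))
        Hi = rng.standard_normal((8, 2))
        A = rng.standard_normal((8, 400))
        cov = CovarianceEstimates(R=A @ A.T / 400, N=np.eye(8))
        for spec in standard_presets(3).values():
            W1 = synthesize_filter(spec, H, Hi, cov).W
            W2 = synthesize_filter(spec, H, Hi, cov).W
            assert np.array_equal(W1, W2)

    def test_unknown_family_rejected(self):
        cov = CovarianceEstimates(R=np.eye(4), N=np.eye(4))
        with pytest.raises(InvalidArgumentError):
            synthesize_filter(FilterSpec("BOGUS"), np.eye(4)[:, :2], None, cov)
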