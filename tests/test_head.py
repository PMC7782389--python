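"""Geometry, analytic lead-fields and perturbation."""

import math

import numpy as np
import pytest

import beamsim as bs
from beamsim.exceptions import GeometryError, InvalidArgumentError
from beamsim.head import (
    SCALP_RADIUS,
    ElectrodeMontage,
    SourceSpace,
    load_leadfield,
    save_leadfield,
)


def _point_sources(positions, orientations):
    k = len(positions)
    return SourceSpace(
        positions=np.array(positions, dtype=float),
        orientations=np.array(orientations, dtype=float),
        kind=np.array(["interest"] * k),
        roi_id=np.zeros(k, dtype=int),
        deep=np.zeros(k, dtype=bool),
    )


class TestMontage:
    @pytest.mark.parametrize("n", [4, 32, 128])
    def test_count_and_radius(self, n):
        mon = bs.make_montage(n)
        assert mon.n_electrodes == n
        assert np.allclose(np.linalg.norm(mon.positions, axis=1), SCALP_RADIUS,
                           atol=1e-9)

    def test_deterministic(self):
        a, b = bs.make_montage(64), bs.make_montage(64)
        assert np.array_equal(a.positions, b.positions)

    def test_min_angular_separation_positive(self):
        mon = bs.make_montage(4)
        u = mon.positions / SCALP_RADIUS
        cos = u @ u.T
        np.fill_diagonal(cos, -1.0)
        assert np.max(cos) < 1.0  # no coincident electrodes

    def test_upper_cap_restriction(self):
        mon = bs.make_montage(128)
        polar = np.degrees(np.arccos(mon.positions[:, 2] / SCALP_RADIUS))
        assert polar.max() <= 100.0 + 1e-9

    def test_too_few_electrodes(self):
        with pytest.raises(InvalidArgumentError):
            bs.make_montage(3)


class TestSourceSpace:
    def test_single_roi_bookkeeping(self, rng):
        sp = bs.sample_source_space([[1, 1, 1]], rng=rng)
        assert sp.n_sources == 3
        assert len(set(sp.roi_id)) == 1
        assert sorted(sp.kind) == ["background", "interest", "interference"]

    def test_multi_roi_counts(self, rng):
        sp = bs.sample_source_space([[2, 0, 0], [0, 0, 3]], rng=rng)
        assert np.sum(sp.kind == "interest") == 2
        assert np.sum(sp.kind == "background") == 3
        assert len(set(sp.roi_id)) == 2

    def test_cortical_orientations_radial(self, rng):
        sp = bs.sample_source_space([[3, 2, 2]], rng=rng)
        r = np.linalg.norm(sp.positions, axis=1)
        dots = np.einsum("kd,kd->k", sp.orientations, sp.positions / r[:, None])
        assert np.allclose(dots, 1.0, atol=1e-12)

    def test_deep_sources_inside_ball(self, rng):
        sp = bs.sample_source_space([[1, 0, 0]], n_deep=(2, 1, 1), rng=rng)
        deep = sp.positions[sp.deep]
        assert deep.shape[0] == 4
        assert np.all(np.linalg.norm(deep, axis=1) <= 0.015 + 1e-12)
        assert np.all(sp.roi_id[sp.deep] == -1)

    def test_no_interest_sources_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            bs.sample_source_space([[0, 2, 2]], rng=rng)


class TestLeadfield:
    def test_unit_configuration(self):
        # sigma = 1/(4 pi), moment z, electrode 1 m above: potential 1
        mon = ElectrodeMontage(positions=np.array([[0.0, 0.0, 1.0]]), labels=["E1"])
        src = _point_sources([[0, 0, 0]], [[0, 0, 1]])
        lf = bs.compute_leadfield(mon, src, conductivity=1 / (4 * math.pi),
                                  reference=None)
        assert lf.gain[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_moment_zero_potential(self):
        mon = ElectrodeMontage(positions=np.array([[0.0, 0.0, 1.0]]), labels=["E1"])
        src = _point_sources([[0, 0, 0]], [[1, 0, 0]])
        lf = bs.compute_leadfield(mon, src, reference=None)
        assert lf.gain[0, 0] == pytest.approx(0.0, abs=1e-15)

    def test_inverse_square_falloff_on_axis(self):
        mon = ElectrodeMontage(
            positions=np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 2.0]]),
            labels=["E1", "E2"],
        )
        src = _point_sources([[0, 0, 0]], [[0, 0, 1]])
        lf = bs.compute_leadfield(mon, src, reference=None)
        assert lf.gain[0, 0] == pytest.approx(4 * lf.gain[1, 0], rel=1e-12)

    def test_linearity_in_moment(self, rng):
        mon = bs.make_montage(16)
        sp = bs.sample_source_space([[2, 0, 0]], rng=rng)
        lf1 = bs.compute_leadfield(mon, sp)
        scaled = SourceSpace(sp.positions, 3.0 * sp.orientations, sp.kind,
                             sp.roi_id, sp.deep)
        lf3 = bs.compute_leadfield(mon, scaled)
        assert np.allclose(lf3.gain, 3.0 * lf1.gain)

    def test_average_reference_column_sums(self, rng):
        mon = bs.make_montage(32)
        sp = bs.sample_source_space([[3, 3, 3]], n_deep=(1, 0, 0), rng=rng)
        lf = bs.compute_leadfield(mon, sp)
        col_norm = np.linalg.norm(lf.gain, axis=0)
        assert np.all(np.abs(lf.gain.sum(axis=0)) <= 1e-12 * col_norm)

    def test_depth_attenuation(self):
        # deep sources couple more weakly than cortical ones
        mon = bs.make_montage(64)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            sp = bs.sample_source_space([[3, 0, 0]], n_deep=(3, 0, 0), rng=rng)
            lf = bs.compute_leadfield(mon, sp)
            cortical = np.mean(np.abs(lf.gain[:, ~sp.deep]))
            deep = np.mean(np.abs(lf.gain[:, sp.deep]))
            assert deep < cortical

    def test_coincident_source_electrode_rejected(self):
        mon = ElectrodeMontage(positions=np.array([[0.0, 0.0, 0.1]]), labels=["E1"])
        src = _point_sources([[0, 0, 0.1]], [[0, 0, 1]])
        with pytest.raises(GeometryError):
            bs.compute_leadfield(mon, src)


class TestPerturbation:
    def test_zero_perturbation_is_identity(self, rng):
        sp = bs.sample_source_space([[3, 2, 2]], rng=rng)
        out = bs.perturb_sources(sp, 0.0, 0.0, rng)
        assert np.array_equal(out.positions, sp.positions)
        assert np.allclose(out.orientations, sp.orientations, atol=1e-15)

    def test_default_shift_below_5mm_per_axis(self):
        rng = np.random.default_rng(2)
        sp = bs.sample_source_space([[4, 3, 3]], rng=rng)
        shifts = []
        for _ in range(200):
            out = bs.perturb_sources(sp, 0.010, math.pi / 32, rng)
            shifts.append(np.abs(out.positions - sp.positions))
        assert np.max(shifts) < 0.005

    def test_rotation_angle_bounded(self):
        rng = np.random.default_rng(3)
        sp = bs.sample_source_space([[10, 0, 0]], rng=rng)
        cone = math.pi / 32
        max_angle = 0.0
        for _ in range(1000):
            out = bs.perturb_sources(sp, 0.0, cone, rng)
            dots = np.einsum("kd,kd->k", out.orientations, sp.orientations)
            max_angle = max(max_angle, float(np.max(np.arccos(np.clip(dots, -1, 1)))))
        assert max_angle <= 2 * cone + 1e-9
        assert max_angle > 0.0

    def test_unit_norm_preserved(self, rng):
        sp = bs.sample_source_space([[5, 0, 0]], rng=rng)
        out = bs.perturb_sources(sp, 0.010, math.pi / 8, rng)
        assert np.allclose(np.linalg.norm(out.orientations, axis=1), 1.0, atol=1e-12)

    def test_leadfield_difference_shrinks_with_perturbation(self):
        rng = np.random.default_rng(4)
        mon = bs.make_montage(32)
        sp = bs.sample_source_space([[4, 0, 0]], rng=rng)
        lf0 = bs.compute_leadfield(mon, sp)
        diffs = []
        for scale in (1.0, 0.1, 0.01):
            pert = bs.perturb_sources(sp, 0.010 * scale, (math.pi / 32) * scale,
                                      np.random.default_rng(99))
            lf = bs.compute_leadfield(mon, pert)
            diffs.append(np.linalg.norm(lf.gain - lf0.gain) / np.linalg.norm(lf0.gain))
        assert diffs[0] > diffs[1] > diffs[2] > 0.0


class TestIO:
    def test_sfp_roundtrip(self, tmp_path):
        mon = bs.make_montage(16)
        path = tmp_path / "cap.sfp"
        bs.write_sfp(mon, path)
        back = bs.read_sfp(path)
        assert back.labels == mon.labels
        assert np.allclose(back.positions, mon.positions, atol=1e-9)

    def test_leadfield_roundtrip(self, tmp_path, rng):
        mon = bs.make_montage(8)
        sp = bs.sample_source_space([[2, 0, 0]], rng=rng)
        lf = bs.compute_leadfield(mon, sp)
        path = tmp_path / "H.txt"
        save_leadfield(lf, path)
        back = load_leadfield(path)
        assert np.allclose(back.gain, lf.gain)
        assert back.labels == lf.labels
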