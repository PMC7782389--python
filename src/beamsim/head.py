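"""Synthetic head geometry and analytic lead-fields.

The bench replaces a mesh-based volume conductor with a closed-form
forward operator: dipoles in an infinite homogeneous medium, electrodes on
a scalp sphere, average-referenced potentials.  The spatial-filter layer
only ever sees the resulting gain matrix, so it is agnostic to how the
lead-field arose; the analytic kernel keeps the whole pipeline
self-contained and exactly testable.

Geometry conventions: head-centred right-handed coordinates, z up, metres
throughout.  Scalp radius 0.100 m, cortical shell 0.078 m, deep-source
ball 0.015 m (roughly adult-head proportions).  Cortical dipoles point
radially outward, mimicking pyramidal-cell orientation normal to the
cortical surface; deep dipoles have uniformly random orientation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import GeometryError, InvalidArgumentError

__all__ = [
    "ElectrodeMontage",
    "SourceSpace",
    "Leadfield",
    "make_montage",
    "sample_source_space",
    "compute_leadfield",
    "perturb_sources",
    "read_sfp",
    "write_sfp",
    "save_leadfield",
    "load_leadfield",
    "SCALP_RADIUS",
    "CORTEX_RADIUS",
    "DEEP_RADIUS",
    "DEFAULT_CONDUCTIVITY",
]

SCALP_RADIUS = 0.100     # m
CORTEX_RADIUS = 0.078    # m
DEEP_RADIUS = 0.015      # m, radius of the central (thalamic) ball
DEFAULT_CONDUCTIVITY = 0.33  # S/m
PATCH_ANGLE = math.radians(10.0)

KIND_INTEREST = "interest"
KIND_INTERFERENCE = "interference"
KIND_BACKGROUND = "background"
KINDS = (KIND_INTEREST, KIND_INTERFERENCE, KIND_BACKGROUND)


@dataclass
class ElectrodeMontage:
    positions: np.ndarray          # m x 3, metres, on the scalp sphere
    labels: list
    reference: str = "average"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise InvalidArgumentError("electrode labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise InvalidArgumentError("positions/labels length mismatch")

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]


@dataclass
class SourceSpace:
    positions: np.ndarray          # k x 3, metres
    orientations: np.ndarray       # k x 3, unit vectors
    kind: np.ndarray               # k strings from KINDS
    roi_id: np.ndarray             # k ints, -1 for deep sources
    deep: np.ndarray               # k bools

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.orientations = np.asarray(self.orientations, dtype=float).reshape(-1, 3)
        self.kind = np.asarray(self.kind)
        self.roi_id = np.asarray(self.roi_id, dtype=int)
        self.deep = np.asarray(self.deep, dtype=bool)
        k = self.positions.shape[0]
        if not (self.orientations.shape[0] == self.kind.shape[0]
                == self.roi_id.shape[0] == self.deep.shape[0] == k):
            raise InvalidArgumentError("source space field lengths disagree")

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    def select(self, kind: str) -> "SourceSpace":
        """Sub-space of one source kind (interest/interference/background)."""
        idx = self.kind == kind
        return SourceSpace(
            positions=self.positions[idx],
            orientations=self.orientations[idx],
            kind=self.kind[idx],
            roi_id=self.roi_id[idx],
            deep=self.deep[idx],
        )


@dataclass
class Leadfield:
    """Sensors x sources gain matrix (volts per unit dipole moment)."""

    gain: np.ndarray
    labels: Optional[list] = None
    perturbed: bool = False
    reference: str = "average"

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise InvalidArgumentError("gain must be a 2-D matrix")
        if not np.all(np.isfinite(self.gain)):
            raise InvalidArgumentError("gain must be finite")

    @property
    def n_electrodes(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


# ----------------------------------------------------------------------

def make_montage(
    n_electrodes: int,
    scalp_radius: float = SCALP_RADIUS,
    rng: Optional[np.random.Generator] = None,
) -> ElectrodeMontage:
    """Quasi-uniform EEG cap layout on the upper scalp.

    Electrodes are placed on a spherical Fibonacci lattice restricted to
    polar angles <= 100 degrees (slightly below the equator, as real caps
    extend).  Deterministic given the electrode count; ``rng`` is accepted
    for interface uniformity but unused.
    """
    if n_electrodes < 4:
        raise InvalidArgumentError("need at least 4 electrodes")
    n = int(n_electrodes)
    z_min = math.cos(math.radians(100.0))
    i = np.arange(n)
    z = 1.0 - (1.0 - z_min) * (i + 0.5) / n
    golden = math.pi * (3.0 - math.sqrt(5.0))
    phi = i * golden
    r_xy = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pos = scalp_radius * np.stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z], axis=1)
    labels = [f"E{k + 1:03d}" for k in range(n)]
    return ElectrodeMontage(positions=pos, labels=labels)


def _random_unit_upper(rng: np.random.Generator) -> np.ndarray:
    """Uniform unit vector on the upper hemisphere."""
    z = rng.uniform(0.0, 1.0)
    phi = rng.uniform(0.0, 2 * math.pi)
    r = math.sqrt(max(1.0 - z * z, 0.0))
    return np.array([r * math.cos(phi), r * math.sin(phi), z])


def _sample_cap(center: np.ndarray, angle: float, count: int,
                rng: np.random.Generator) -> np.ndarray:
    """Uniform unit vectors within the spherical cap of angular radius
    ``angle`` around ``center``."""
    if count == 0:
        return np.zeros((0, 3))
    cos_min = math.cos(angle)
    c = rng.uniform(cos_min, 1.0, size=count)        # cos of polar offset
    s = np.sqrt(np.clip(1.0 - c**2, 0.0, None))
    phi = rng.uniform(0.0, 2 * math.pi, size=count)
    local = np.stack([s * np.cos(phi), s * np.sin(phi), c], axis=1)
    # rotate local +z to the cap center
    zhat = np.array([0.0, 0.0, 1.0])
    v = np.cross(zhat, center)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if center[2] > 0 else -np.eye(3)
    else:
        axis = v / np.linalg.norm(v)
        ang = math.acos(np.clip(center @ zhat, -1.0, 1.0))
        R = Rotation.from_rotvec(axis * ang).as_matrix()
    return local @ R.T


def sample_source_space(
    srcs_table: Sequence[Sequence[int]],
    n_deep: Sequence[int] = (0, 0, 0),
    cortex_radius: float = CORTEX_RADIUS,
    patch_angle: float = PATCH_ANGLE,
    rng: Optional[np.random.Generator] = None,
) -> SourceSpace:
    """Place cortical and deep dipoles.

    Each row of ``srcs_table`` defines one cortical patch (ROI): a random
    patch centre on the upper hemisphere, with the row's three counts of
    interest / interference / background sources drawn uniformly within
    the patch.  ``n_deep`` adds central sources uniform in the deep ball,
    with uniformly random orientations; cortical orientations are radial.
    """
    if rng is None:
        rng = np.random.default_rng()
    srcs_table = [list(map(int, row)) for row in srcs_table]
    n_deep = list(map(int, n_deep))
    total_interest = sum(r[0] for r in srcs_table) + n_deep[0]
    if total_interest < 1:
        raise InvalidArgumentError("at least one source of interest is required")

    pos, ori, kind, roi, deep = [], [], [], [], []
    for r, row in enumerate(srcs_table):
        center = _random_unit_upper(rng)
        for col, k in enumerate(KINDS):
            dirs = _sample_cap(center, patch_angle, row[col], rng)
            for d in dirs:
                pos.append(cortex_radius * d)
                ori.append(d)                      # radial, outward
                kind.append(k)
                roi.append(r)
                deep.append(False)
    for col, k in enumerate(KINDS):
        for _ in range(n_deep[col]):
            u = rng.uniform()
            direction = _random_unit_sphere(rng)
            pos.append(DEEP_RADIUS * u ** (1.0 / 3.0) * direction)
            ori.append(_random_unit_sphere(rng))
            kind.append(k)
            roi.append(-1)
            deep.append(True)

    return SourceSpace(
        positions=np.array(pos).reshape(-1, 3),
        orientations=np.array(ori).reshape(-1, 3),
        kind=np.array(kind),
        roi_id=np.array(roi, dtype=int),
        deep=np.array(deep, dtype=bool),
    )


def _random_unit_sphere(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def compute_leadfield(
    montage: ElectrodeMontage,
    sources: SourceSpace,
    conductivity: float = DEFAULT_CONDUCTIVITY,
    reference: Optional[str] = "average",
    perturbed: bool = False,
) -> Leadfield:
    """Analytic dipole lead-field.

    The unreferenced potential of a unit dipole with moment direction o at
    position r_s, seen by an electrode at r_e in an infinite homogeneous
    medium of conductivity sigma, is

        v = o . (r_e - r_s) / (4 pi sigma |r_e - r_s|^3).

    With ``reference='average'`` the per-column mean over electrodes is
    subtracted (average reference), making every column sum to zero.
    """
    if sources.n_sources == 0:
        raise InvalidArgumentError("source space is empty")
    diff = montage.positions[:, None, :] - sources.positions[None, :, :]  # m x k x 3
    dist = np.linalg.norm(diff, axis=2)
    if np.any(dist < 1e-3):
        raise GeometryError("electrode within 1 mm of a source")
    gain = np.einsum("mkd,kd->mk", diff, sources.orientations) / (
        4.0 * math.pi * conductivity * dist**3
    )
    if reference == "average":
        gain = gain - gain.mean(axis=0, keepdims=True)
    return Leadfield(gain=gain, labels=list(montage.labels),
                     perturbed=perturbed, reference=reference or "none")


def _tangent_frame(o: np.ndarray) -> tuple:
    """Orthonormal tangent vectors (t1, t2) completing unit vector o."""
    helper = np.array([0.0, 0.0, 1.0])
    if abs(o @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(helper, o)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(o, t1)
    return t1, t2


def perturb_sources(
    sources: SourceSpace,
    cube_edge: float = 0.010,
    cone_half_angle: float = math.pi / 32,
    rng: Optional[np.random.Generator] = None,
) -> SourceSpace:
    """Mislocalization model for reconstruction lead-fields.

    Each position is displaced by a vector uniform in the cube
    (-cube_edge/2, +cube_edge/2)^3 — for the default 10 mm edge the shift
    is below 5 mm in each coordinate.  Each orientation is rotated by an
    azimuth offset, then an elevation offset, each uniform on
    (-cone_half_angle, +cone_half_angle) in the dipole's tangent frame,
    and renormalized.
    """
    if cube_edge < 0:
        raise InvalidArgumentError("cube_edge must be >= 0")
    if not (0 <= cone_half_angle < math.pi / 2):
        raise InvalidArgumentError("cone_half_angle must lie in [0, pi/2)")
    if rng is None:
        rng = np.random.default_rng()
    k = sources.n_sources
    shift = rng.uniform(-cube_edge / 2.0, cube_edge / 2.0, size=(k, 3))
    new_pos = sources.positions + shift
    new_ori = np.empty_like(sources.orientations)
    for idx in range(k):
        o = sources.orientations[idx]
        t1, t2 = _tangent_frame(o)
        az = rng.uniform(-cone_half_angle, cone_half_angle)
        el = rng.uniform(-cone_half_angle, cone_half_angle)
        R_az = Rotation.from_rotvec(t2 * az).as_matrix()
        o1 = R_az @ o
        t1r = R_az @ t1
        o2 = Rotation.from_rotvec(t1r * el).as_matrix() @ o1
        new_ori[idx] = o2 / np.linalg.norm(o2)
    return SourceSpace(
        positions=new_pos,
        orientations=new_ori,
        kind=sources.kind.copy(),
        roi_id=sources.roi_id.copy(),
        deep=sources.deep.copy(),
    )


# ----------------------------------------------------------------------
# text I/O
# ----------------------------------------------------------------------

def write_sfp(montage: ElectrodeMontage, path: str | Path) -> None:
    """Write electrode positions as 'label x y z' rows (metres)."""
    with open(path, "w") as fh:
        for label, p in zip(montage.labels, montage.positions):
            fh.write(f"{label}\t{p[0]:.9g}\t{p[1]:.9g}\t{p[2]:.9g}\n")


def read_sfp(path: str | Path) -> ElectrodeMontage:
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise InvalidArgumentError(f"malformed .sfp line: {line!r}")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return ElectrodeMontage(positions=np.array(rows), labels=labels)


def save_leadfield(lf: Leadfield, path: str | Path) -> None:
    """Gain as delimited text (electrodes as rows) + JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, lf.gain)
    meta = {"labels": lf.labels, "perturbed": lf.perturbed, "reference": lf.reference}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh)
        fh.write("\n")


def load_leadfield(path: str | Path) -> Leadfield:
    path = Path(path)
    gain = np.atleast_2d(np.loadtxt(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return Leadfield(
        gain=gain,
        labels=meta.get("labels"),
        perturbed=bool(meta.get("perturbed", False)),
        reference=meta.get("reference", "average"),
    )
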