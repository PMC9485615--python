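"""Sensor-array geometry: helmets, rigid transforms, and the VMH catalog.

A virtual MEG helmet (VMH) is assembled by recording the same activity at
several head positions and mapping all recordings into a single head frame.
Each head movement is equivalent to the counter movement of the sensor
array, so a VMH behaves like one head position observed by ``248 * n``
magnetometers.  This module builds the base 248-channel array, applies the
rigid counter-movements, assembles VMHs, rejects helmets whose sensors
penetrate the spherical head model, and ships the catalog of helmets used
throughout the simulation experiments.

Coordinates are head coordinates in millimetres with the origin at the
centre of the fitted head sphere; the helmet vertex points toward +z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "HeadModel",
    "RigidTransform",
    "SensorArray",
    "VirtualHelmet",
    "apply_transform",
    "build_vmh",
    "check_clash",
    "counter_transform",
    "helmet_catalog",
    "synthetic_helmet",
    "read_sensor_layout",
    "write_sensor_layout",
]

#: Channels in the base whole-head magnetometer array.
N_CHANNELS = 248

#: Radius (mm) of the fitted spherical head model.
HEAD_RADIUS_MM = 95.5

#: Radius (mm) of the synthetic helmet's spherical sensor shell.
HELMET_RADIUS_MM = 120.0

#: Lowest sensor plane (mm): the cap extends from the +z vertex down to here.
HELMET_RIM_Z_MM = -15.0

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class HeadModel:
    """Homogeneous spherical conductor centred at the head-frame origin."""

    radius: float = HEAD_RADIUS_MM

    def __post_init__(self) -> None:
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ValueError(f"head radius must be positive, got {self.radius}")

    @property
    def center(self) -> np.ndarray:
        return np.zeros(3)


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees, about head-frame x, y, z through the origin) then translation (mm).

    The rotation is extrinsic with composition ``R = Rz @ Ry @ Rx`` and is
    applied before the translation so that the array rotates about an axis
    through the head origin.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        params = np.asarray(self.rotation_deg + self.translation_mm, dtype=float)
        if params.shape != (6,) or not np.all(np.isfinite(params)):
            raise ValueError("transform parameters must be six finite numbers")
        object.__setattr__(self, "rotation_deg", tuple(float(a) for a in self.rotation_deg))
        object.__setattr__(self, "translation_mm", tuple(float(t) for t in self.translation_mm))

    @property
    def is_identity(self) -> bool:
        return all(a == 0 for a in self.rotation_deg) and all(
            t == 0 for t in self.translation_mm
        )

    def matrix(self) -> np.ndarray:
        """The 3x3 rotation matrix Rz @ Ry @ Rx."""
        rx, ry, rz = (math.radians(a) for a in self.rotation_deg)
        cx, sx = math.cos(rx), math.sin(rx)
        cy, sy = math.cos(ry), math.sin(ry)
        cz, sz = math.cos(rz), math.sin(rz)
        R_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        R_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        R_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return R_z @ R_y @ R_x

    def inverse(self) -> "_InverseTransform":
        """The exact inverse map (rotate by R.T after undoing the translation)."""
        return _InverseTransform(self)


@dataclass(frozen=True)
class _InverseTransform:
    """Inverse of a :class:`RigidTransform`: x -> R.T @ (x - t)."""

    forward: RigidTransform

    def matrix(self) -> np.ndarray:
        return self.forward.matrix().T

    @property
    def translation(self) -> np.ndarray:
        return -self.matrix() @ np.asarray(self.forward.translation_mm)


@dataclass(frozen=True)
class SensorArray:
    """Point magnetometers: positions (mm) and unit measurement directions."""

    labels: tuple[str, ...]
    positions: np.ndarray
    orientations: np.ndarray

    def __post_init__(self) -> None:
        pos = np.ascontiguousarray(np.asarray(self.positions, dtype=float))
        ori = np.ascontiguousarray(np.asarray(self.orientations, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 3 or ori.shape != pos.shape:
            raise ValueError("positions and orientations must be (n, 3) arrays")
        if len(self.labels) != pos.shape[0]:
            raise ValueError("label count must match channel count")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(ori))):
            raise ValueError("sensor coordinates must be finite")
        norms = np.linalg.norm(ori, axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("orientations must be unit vectors (tol 1e-9)")
        pos.setflags(write=False)
        ori.setflags(write=False)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "orientations", ori)

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def radial_distances(self) -> np.ndarray:
        return np.linalg.norm(self.positions, axis=1)


@dataclass(frozen=True)
class VirtualHelmet:
    """An ordered combination of sensor arrays sharing one head frame.

    ``arrays[0]`` is the untransformed base array; channel ordering is
    array-major (all channels of array 0, then array 1, ...) and stable.
    """

    arrays: tuple[SensorArray, ...]
    transforms: tuple[RigidTransform, ...]
    serial: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.arrays) != len(self.transforms):
            raise ValueError("need one transform per constituent array")
        object.__setattr__(self, "arrays", tuple(self.arrays))
        object.__setattr__(self, "transforms", tuple(self.transforms))

    @property
    def n_arrays(self) -> int:
        return len(self.arrays)

    @property
    def n_channels(self) -> int:
        return sum(a.n_channels for a in self.arrays)

    @property
    def positions(self) -> np.ndarray:
        return np.vstack([a.positions for a in self.arrays])

    @property
    def orientations(self) -> np.ndarray:
        return np.vstack([a.orientations for a in self.arrays])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for a in self.arrays for lab in a.labels)


# ---------------------------------------------------------------------------
# Synthetic base helmet
# ---------------------------------------------------------------------------

def synthetic_helmet(
    n_channels: int = N_CHANNELS,
    shell_radius: float = HELMET_RADIUS_MM,
    rim_z: float = HELMET_RIM_Z_MM,
) -> SensorArray:
    """Quasi-uniform magnetometer cap standing in for the physical helmet.

    ``n_channels`` point magnetometers are placed on a Fibonacci lattice
    covering the spherical cap of radius ``shell_radius`` mm from the +z
    vertex down to the plane ``z = rim_z``, with radially inward measurement
    directions.  This reproduces whole-head coverage and a realistic
    scalp-sensor standoff with a fully deterministic construction.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be positive")
    golden = math.pi * (3.0 - math.sqrt(5.0))
    # Evenly spaced z gives equal-area rings on the sphere (cap-restricted).
    i = np.arange(n_channels)
    z = shell_radius - (shell_radius - rim_z) * (i + 0.5) / n_channels
    rho = np.sqrt(shell_radius**2 - z**2)
    theta = golden * i
    pos = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    ori = -pos / np.linalg.norm(pos, axis=1, keepdims=True)
    labels = tuple(f"A{k + 1}" for k in range(n_channels))
    return SensorArray(labels=labels, positions=pos, orientations=ori)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def apply_transform(
    array: SensorArray,
    t: RigidTransform | _InverseTransform,
    label_suffix: str | None = None,
) -> SensorArray:
    """Rigidly move a sensor array: rotate about the origin, then translate.

    Orientations are direction vectors and are rotated only, never
    translated.  Labels are preserved, optionally with an array-position
    suffix so channels of a VMH stay distinguishable.
    """
    if isinstance(t, _InverseTransform):
        R = t.matrix()
        trans = t.translation
    else:
        R = t.matrix()
        trans = np.asarray(t.translation_mm, dtype=float)
    pos = array.positions @ R.T + trans
    ori = array.orientations @ R.T
    # Renormalize to absorb rounding so the unit-norm invariant holds exactly.
    ori = ori / np.linalg.norm(ori, axis=1, keepdims=True)
    labels = array.labels
    if label_suffix:
        labels = tuple(f"{lab}{label_suffix}" for lab in labels)
    return SensorArray(labels=labels, positions=pos, orientations=ori)


def counter_transform(head_motion: RigidTransform) -> RigidTransform:
    """Sensor counter-movement equivalent to a given head movement.

    Moving the head by ``T`` inside a static helmet is, in head coordinates,
    the same as moving the helmet by ``T``:sup:`-1` around a static head.
    The inverse of ``x -> R x + t`` is ``x -> R.T x - R.T t``, re-expressed
    here in the package's Rz.Ry.Rx angle-triplet parameterization.
    """
    from scipy.spatial.transform import Rotation

    R_inv = head_motion.matrix().T
    # extrinsic 'xyz' (apply x, then y, then z) is exactly Rz @ Ry @ Rx
    angles = Rotation.from_matrix(R_inv).as_euler("xyz", degrees=True)
    t_inv = -R_inv @ np.asarray(head_motion.translation_mm)
    return RigidTransform(rotation_deg=tuple(angles), translation_mm=tuple(t_inv))


# ---------------------------------------------------------------------------
# VMH assembly and clash testing
# ---------------------------------------------------------------------------

def build_vmh(
    base: SensorArray,
    transforms: Sequence[RigidTransform] = (),
    serial: int | None = None,
    name: str = "",
) -> VirtualHelmet:
    """Assemble a VMH from the base array plus one array per transform.

    An empty transform list yields the standard helmet (n = 1).  The total
    channel count is ``base.n_channels * (1 + len(transforms))`` and channel
    ordering is array-major and deterministic.
    """
    identity = RigidTransform()
    arrays = [apply_transform(base, identity)]
    all_transforms = [identity]
    for k, t in enumerate(transforms, start=2):
        arrays.append(apply_transform(base, t, label_suffix=f"-{k}"))
        all_transforms.append(t)
    return VirtualHelmet(
        arrays=tuple(arrays), transforms=tuple(all_transforms), serial=serial, name=name
    )


def check_clash(helmet: VirtualHelmet, head: HeadModel, margin: float = 0.0) -> bool:
    """True iff any sensor lies within ``head.radius + margin`` of the origin."""
    if margin < 0:
        raise ValueError("margin must be non-negative")
    for array in helmet.arrays:
        if np.any(array.radial_distances() < head.radius + margin):
            return True
    return False


# ---------------------------------------------------------------------------
# Helmet catalog
# ---------------------------------------------------------------------------

# (serial, name, [(rotation_deg, translation_mm), ...]) — the standard helmet
# plus the 13 retained VMHs built from +-20 degree / +-15 mm counter-movements.
_CATALOG_SPEC: tuple[tuple[int, str, tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...]], ...] = (
    (1, "standard", ()),
    (2, "", (((20, 0, 0), (-15, 15, 0)),)),
    (3, "", (((0, 20, 0), (-15, 15, 0)),)),
    (4, "", (((0, 20, 0), (-15, -15, 0)),)),
    (5, "", (((0, 0, 20), (-15, -15, 0)),)),
    (6, "", (((-20, 0, 0), (-15, -15, 0)),)),
    (7, "", (((0, -20, 0), (-15, 15, 0)),)),
    (8, "", (((0, -20, 0), (-15, -15, 0)),)),
    (9, "", (((0, 0, -20), (-15, 15, 0)),)),
    (10, "", (((0, 0, -20), (-15, -15, 0)),)),
    (11, "VMHa", (((20, 20, 20), (15, 15, 15)),)),
    (12, "", (((20, 20, 20), (-15, -15, 0)),)),
    (13, "", (((-20, -20, -20), (-15, -15, 0)),)),
    (14, "VMHb", (((20, 20, 20), (15, 15, 15)), ((-20, -20, -20), (-15, -15, 0)))),
)


def helmet_catalog(
    base: SensorArray | None = None,
    head: HeadModel | None = None,
    exclude_clashing: bool = True,
    margin: float = 0.0,
) -> list[VirtualHelmet]:
    """The standard helmet and the 13 retained VMHs (serials 1-14).

    Candidate helmets whose counter-movements would push sensors through the
    head sphere were already excluded from the catalog; ``exclude_clashing``
    re-checks each shipped entry against the given head model as a guard for
    user-supplied base geometries.
    """
    base = base if base is not None else synthetic_helmet()
    head = head if head is not None else HeadModel()
    helmets = []
    for serial, name, moves in _CATALOG_SPEC:
        transforms = [
            RigidTransform(rotation_deg=rot, translation_mm=tr) for rot, tr in moves
        ]
        helmet = build_vmh(base, transforms, serial=serial, name=name)
        if exclude_clashing and check_clash(helmet, head, margin):
            continue
        helmets.append(helmet)
    return helmets


def catalog_config() -> list[dict]:
    """The catalog as plain structured data (serial, name, angles, translations)."""
    return [
        {
            "serial": serial,
            "name": name,
            "n_arrays": 1 + len(moves),
            "transforms": [
                {"rotation_deg": list(rot), "translation_mm": list(tr)}
                for rot, tr in moves
            ],
        }
        for serial, name, moves in _CATALOG_SPEC
    ]


# ---------------------------------------------------------------------------
# Sensor-layout file I/O
# ---------------------------------------------------------------------------

def write_sensor_layout(array: SensorArray, path: str | Path) -> None:
    """Write a tab-separated layout: label, x_mm, y_mm, z_mm, ox, oy, oz."""
    lines = ["label\tx_mm\ty_mm\tz_mm\tox\toy\toz"]
    for lab, p, o in zip(array.labels, array.positions, array.orientations):
        lines.append(
            f"{lab}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\t{o[0]:.6f}\t{o[1]:.6f}\t{o[2]:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_sensor_layout(path: str | Path) -> SensorArray:
    """Read a tab-separated sensor layout written by :func:`write_sensor_layout`."""
    rows = Path(path).read_text().strip().splitlines()
    if rows and rows[0].startswith("label"):
        rows = rows[1:]
    labels, pos, ori = [], [], []
    for row in rows:
        parts = row.split("\t")
        if len(parts) != 7:
            raise ValueError(f"malformed layout row: {row!r}")
        labels.append(parts[0])
        pos.append([float(v) for v in parts[1:4]])
        ori.append([float(v) for v in parts[4:7]])
    ori_arr = np.asarray(ori)
    ori_arr = ori_arr / np.linalg.norm(ori_arr, axis=1, keepdims=True)
    return SensorArray(labels=tuple(labels), positions=np.asarray(pos), orientations=ori_arr)
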