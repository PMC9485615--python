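"""Spherical-conductor forward model: dipole fields, gain matrices, rank.

The magnetic field of a current dipole inside a homogeneous conducting
sphere centred at the origin has the closed-form solution

    B(r) = (mu0 / 4 pi F^2) * (F (Q x r0) - ((Q x r0) . r) grad F)

with sensor position r, dipole position r0, moment Q, a = r - r0,
F = a (r a + r^2 - r0 . r) and the standard gradient of F (Sarvas'
formula).  Radial moments (Q parallel to r0) are magnetically silent,
which is why the source space carries only tangential bases.

Units: positions in mm, moments in arbitrary units; the mu0/(4 pi)
prefactor is folded into a global scale because every downstream
comparison (correlations, ratios, ranks) is scale-invariant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import HeadModel, SensorArray, VirtualHelmet
from .source_space import DipoleSet, SourceGrid

__all__ = [
    "FieldVector",
    "GainMatrix",
    "dipole_field",
    "gain_matrix",
    "forward_project",
    "effective_rank",
    "save_gain",
    "load_gain",
]

#: Effective-rank tolerance: singular values below this fraction of the
#: largest are treated as zero.
DEFAULT_RANK_TOLERANCE = 1e-3


@dataclass(frozen=True)
class GainMatrix:
    """Forward operator: channels x (2 * grid points).

    Rows follow the helmet's array-major channel order; columns are
    point-major with the (e1, e2) tangential pair per grid point.
    """

    values: np.ndarray
    n_arrays: int
    channels_per_array: int

    def __post_init__(self) -> None:
        vals = np.ascontiguousarray(np.asarray(self.values, dtype=float))
        if vals.ndim != 2:
            raise ValueError("gain must be a 2-D matrix")
        if vals.shape[0] != self.n_arrays * self.channels_per_array:
            raise ValueError("row count must equal n_arrays * channels_per_array")
        if not np.all(np.isfinite(vals)):
            raise ValueError("gain entries must be finite")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_points(self) -> int:
        return self.values.shape[1] // 2

    def array_block(self, k: int) -> np.ndarray:
        """Rows belonging to the k-th constituent array."""
        lo = k * self.channels_per_array
        return self.values[lo: lo + self.channels_per_array]


FieldVector = np.ndarray  # one scalar per channel, helmet channel order


def _sarvas_field(
    r0: np.ndarray, q: np.ndarray, pos: np.ndarray, ori: np.ndarray
) -> np.ndarray:
    """B . orientation at each sensor for dipoles (r0, q).

    ``r0``/``q``: (P, 3) dipole positions (mm) and moments; ``pos``/``ori``:
    (m, 3) sensor positions and unit orientations.  Returns (m, P).
    """
    r = pos[:, None, :]                       # (m, 1, 3)
    r0b = r0[None, :, :]                      # (1, P, 3)
    a_vec = r - r0b                           # (m, P, 3)
    a = np.linalg.norm(a_vec, axis=-1)        # (m, P)
    rn = np.linalg.norm(pos, axis=-1)[:, None]  # (m, 1)
    r0_dot_r = np.einsum("mc,pc->mp", pos, r0)
    # F and its gradient per Sarvas' closed form
    F = a * (rn * a + rn**2 - r0_dot_r)       # (m, P)
    a_dot_r = np.einsum("mpc,mc->mp", a_vec, pos)
    g1 = a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn   # (m, P)
    g2 = a + 2.0 * rn + a_dot_r / a                      # (m, P)
    gradF = g1[..., None] * r - g2[..., None] * r0b      # (m, P, 3)
    q_x_r0 = np.cross(q, r0)                              # (P, 3)
    qr0_dot_r = np.einsum("pc,mc->mp", q_x_r0, pos)
    B = (F[..., None] * q_x_r0[None, :, :] - qr0_dot_r[..., None] * gradF) / (
        F[..., None] ** 2
    )
    return np.einsum("mpc,mc->mp", B, ori)


def dipole_field(
    location: np.ndarray,
    moment: np.ndarray,
    sensors: SensorArray,
    head: HeadModel,
) -> FieldVector:
    """Field of one dipole projected on each sensor's orientation.

    The dipole must lie strictly inside the head sphere; sensors must not
    coincide with the dipole.  The result is linear in ``moment`` and exactly
    zero for radial moments.
    """
    loc = np.asarray(location, dtype=float).reshape(3)
    mom = np.asarray(moment, dtype=float).reshape(3)
    if not (np.all(np.isfinite(loc)) and np.all(np.isfinite(mom))):
        raise ValueError("location and moment must be finite")
    if np.linalg.norm(loc) >= head.radius:
        raise ValueError("dipole location must be strictly inside the head sphere")
    gaps = np.linalg.norm(sensors.positions - loc, axis=1)
    if np.any(gaps < 1e-9):
        raise ValueError("dipole coincides with a sensor position")
    return _sarvas_field(
        loc[None, :], mom[None, :], sensors.positions, sensors.orientations
    )[:, 0]


def gain_matrix(
    helmet: VirtualHelmet, grid: SourceGrid, head: HeadModel
) -> GainMatrix:
    """Forward operator of a helmet over the grid's tangential bases.

    Column ``2*i + b`` holds the field of a unit moment along basis vector
    ``b`` of grid point ``i``; rows are the helmet's channels in array-major
    order.  Deterministic.
    """
    radial = np.linalg.norm(grid.points, axis=1)
    if np.any(radial >= head.radius):
        raise ValueError("all grid points must lie strictly inside the head sphere")
    P = grid.n_points
    blocks = []
    for array in helmet.arrays:
        block = np.empty((array.n_channels, 2 * P))
        for b in range(2):
            block[:, b::2] = _sarvas_field(
                grid.points, grid.basis[:, b, :], array.positions, array.orientations
            )
        blocks.append(block)
    values = np.vstack(blocks)
    return GainMatrix(
        values=values,
        n_arrays=helmet.n_arrays,
        channels_per_array=helmet.arrays[0].n_channels,
    )


def forward_project(gain: GainMatrix, dipoles: DipoleSet) -> FieldVector:
    """Superposed field of a dipole set: gain times the sparse coefficients."""
    field = np.zeros(gain.shape[0])
    for idx, (q1, q2) in zip(dipoles.indices, dipoles.coefficients):
        if not 0 <= idx < gain.n_points:
            raise ValueError(f"dipole index {idx} out of range for gain")
        field += q1 * gain.values[:, 2 * idx] + q2 * gain.values[:, 2 * idx + 1]
    return field


def save_gain(gain: GainMatrix, path: str | Path, grid: SourceGrid | None = None) -> None:
    """Cache a gain as a ``.npy`` array with a JSON sidecar.

    The sidecar records the channel/column ordering conventions and a hash
    of the grid points so a cached gain is never reused against a different
    source space.
    """
    path = Path(path)
    np.save(path.with_suffix(".npy"), gain.values)
    sidecar = {
        "n_arrays": gain.n_arrays,
        "channels_per_array": gain.channels_per_array,
        "channel_order": "array-major",
        "column_order": "point-major (e1, e2)",
        "grid_hash": _grid_hash(grid) if grid is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_gain(path: str | Path, grid: SourceGrid | None = None) -> GainMatrix:
    """Load a cached gain, refusing a grid whose hash does not match."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if grid is not None and sidecar.get("grid_hash") not in (None, _grid_hash(grid)):
        raise ValueError("cached gain was computed on a different source grid")
    values = np.load(path.with_suffix(".npy"))
    return GainMatrix(
        values=values,
        n_arrays=sidecar["n_arrays"],
        channels_per_array=sidecar["channels_per_array"],
    )


def _grid_hash(grid: SourceGrid) -> str:
    digest = hashlib.sha256(np.ascontiguousarray(grid.points).tobytes())
    digest.update(np.ascontiguousarray(grid.basis).tobytes())
    return digest.hexdigest()


def effective_rank(
    gain: GainMatrix | np.ndarray,
    tolerance_fraction: float = DEFAULT_RANK_TOLERANCE,
) -> int:
    """Singular values above ``tolerance_fraction * s_max``, counted.

    Interpreted as the number of effectively independent channels
    (leadfields) the helmet provides.
    """
    if not 0.0 < tolerance_fraction < 1.0:
        raise ValueError("tolerance_fraction must be in (0, 1)")
    values = gain.values if isinstance(gain, GainMatrix) else np.asarray(gain, float)
    if values.size == 0 or not np.all(np.isfinite(values)):
        raise ValueError("gain must be a non-empty finite matrix")
    s = np.linalg.svd(values, compute_uv=False)
    if s[0] == 0.0:
        return 0
    return int(np.sum(s > tolerance_fraction * s[0]))
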