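"""Three-layer spherical source grid, tangential dipole bases, and neighbors.

Sources live on three concentric icosphere layers inside the spherical head
model (10 mm between layers by default).  Because a homogeneous sphere is
silent to radial currents, each grid point carries only a pair of
orthonormal vectors tangential to its layer; a dipole moment is a linear
combination ``q1*e1 + q2*e2`` of that local basis.  Points below the ears
are excluded via a cut plane.

The neighbor graph — first and second tessellation rings within a layer
plus the nearest point on each other layer — drives both the robustness
metric and helmet personalization.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

from .geometry import HeadModel

__all__ = [
    "SourceGrid",
    "DipoleSet",
    "icosphere",
    "build_grid",
    "random_dipoles",
    "neighbor_sets",
    "jitter_dipoles",
]

#: Default layer radii (mm): 10 mm between layers, all inside the head sphere.
DEFAULT_LAYER_RADII = (65.0, 75.0, 85.0)

#: Default below-the-ears cut: points with z < this (mm) are excluded.
DEFAULT_CUT_PLANE_Z = -10.0

#: Icosphere refinement whose in-layer spacing at the default radii falls in
#: the 8-12 mm band (642 vertices per layer).
DEFAULT_SUBDIVISIONS = 3

#: Dipole coefficient amplitudes are drawn uniformly from this range.
AMPLITUDE_RANGE = (0.5, 1.0)

#: Orientation jitter for neighbor (robustness) cases: +-20 %.
JITTER_RANGE = (0.8, 1.2)


def icosphere(subdivisions: int) -> np.ndarray:
    """Unit-sphere vertices of a subdivided icosahedron.

    Vertex count is ``10 * 4**subdivisions + 2`` (12, 42, 162, 642, ...).
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be non-negative")
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(mesh.vertices, dtype=float)
    return verts / np.linalg.norm(verts, axis=1, keepdims=True)


def _icosphere_mesh(subdivisions: int) -> trimesh.Trimesh:
    return trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)


def _tangential_basis(points: np.ndarray) -> np.ndarray:
    """Per point, two orthonormal vectors tangent to the sphere through it.

    ``e1 = normalize(z_hat x r_hat)`` (falling back to ``x_hat x r_hat`` near
    the poles), ``e2 = r_hat x e1``.  Any orthonormal tangent pair spans the
    same moment space; this choice is deterministic.
    """
    r_hat = points / np.linalg.norm(points, axis=1, keepdims=True)
    z_hat = np.array([0.0, 0.0, 1.0])
    x_hat = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(np.broadcast_to(z_hat, r_hat.shape), r_hat)
    norms = np.linalg.norm(e1, axis=1)
    polar = norms < 1e-8
    if np.any(polar):
        e1[polar] = np.cross(np.broadcast_to(x_hat, r_hat.shape)[polar], r_hat[polar])
        norms = np.linalg.norm(e1, axis=1)
    e1 /= norms[:, None]
    e2 = np.cross(r_hat, e1)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    return np.stack([e1, e2], axis=1)  # (P, 2, 3)


@dataclass(frozen=True)
class SourceGrid:
    """Layered spherical grid with per-point tangential bases and neighbors."""

    points: np.ndarray              # (P, 3) mm
    layer_index: np.ndarray         # (P,) in 1..n_layers
    basis: np.ndarray               # (P, 2, 3) orthonormal tangent pairs
    neighbors: tuple[tuple[int, ...], ...]
    layer_radii: tuple[float, ...]
    cut_plane_z: float

    def __post_init__(self) -> None:
        for name in ("points", "layer_index", "basis"):
            arr = getattr(self, name)
            arr.setflags(write=False)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        lines = ["index\tlayer\tx_mm\ty_mm\tz_mm"]
        for i, (layer, p) in enumerate(zip(self.layer_index, self.points)):
            lines.append(f"{i}\t{layer}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")

    def neighbors_to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({str(i): list(nb) for i, nb in enumerate(self.neighbors)})
        )


@dataclass(frozen=True)
class DipoleSet:
    """Dipoles at grid points with coefficients on the local tangential basis."""

    indices: tuple[int, ...]
    coefficients: np.ndarray  # (k, 2): (q1, q2) per dipole

    def __post_init__(self) -> None:
        coeffs = np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        if coeffs.shape != (len(self.indices), 2):
            raise ValueError("coefficients must be (k, 2) matching indices")
        coeffs = np.ascontiguousarray(coeffs)
        coeffs.setflags(write=False)
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def k(self) -> int:
        return len(self.indices)

    def moments(self, grid: SourceGrid) -> np.ndarray:
        """Cartesian moment vectors (k, 3): q1*e1 + q2*e2 per dipole."""
        basis = grid.basis[list(self.indices)]  # (k, 2, 3)
        return np.einsum("kb,kbc->kc", self.coefficients, basis)

    def locations(self, grid: SourceGrid) -> np.ndarray:
        return grid.points[list(self.indices)]


def build_grid(
    head: HeadModel | None = None,
    layer_radii: Sequence[float] = DEFAULT_LAYER_RADII,
    cut_plane_z: float = DEFAULT_CUT_PLANE_Z,
    subdivisions: int = DEFAULT_SUBDIVISIONS,
) -> SourceGrid:
    """Build the layered source grid with bases and neighbor lists.

    Each layer is ``icosphere(subdivisions)`` scaled to its radius; points
    below the cut plane (``z < cut_plane_z``) are removed.  Construction is
    fully deterministic.
    """
    head = head if head is not None else HeadModel()
    radii = tuple(float(r) for r in layer_radii)
    if any(r2 <= r1 for r1, r2 in zip(radii, radii[1:])):
        raise ValueError("layer radii must be strictly increasing")
    if any(r >= head.radius for r in radii):
        raise ValueError("layer radii must be strictly inside the head sphere")

    mesh = _icosphere_mesh(subdivisions)
    unit = np.asarray(mesh.vertices, dtype=float)
    unit = unit / np.linalg.norm(unit, axis=1, keepdims=True)
    ring1 = [tuple(int(j) for j in mesh.vertex_neighbors[i]) for i in range(len(unit))]

    points, layers, kept_per_layer = [], [], []
    for li, radius in enumerate(radii, start=1):
        layer_pts = unit * radius
        keep = np.flatnonzero(layer_pts[:, 2] >= cut_plane_z)
        kept_per_layer.append(keep)
        points.append(layer_pts[keep])
        layers.append(np.full(len(keep), li, dtype=int))

    all_points = np.vstack(points)
    layer_index = np.concatenate(layers)
    basis = _tangential_basis(all_points)

    neighbors = _compute_neighbors(all_points, layer_index, kept_per_layer, ring1)
    return SourceGrid(
        points=all_points,
        layer_index=layer_index,
        basis=basis,
        neighbors=neighbors,
        layer_radii=radii,
        cut_plane_z=float(cut_plane_z),
    )


def _compute_neighbors(
    points: np.ndarray,
    layer_index: np.ndarray,
    kept_per_layer: list[np.ndarray],
    ring1: list[tuple[int, ...]],
) -> tuple[tuple[int, ...], ...]:
    """First + second tessellation ring in-layer, plus one nearest point per
    other layer; self and duplicates removed."""
    n_layers = len(kept_per_layer)
    # Map (layer, mesh-vertex) -> global retained index.
    offsets = np.cumsum([0] + [len(k) for k in kept_per_layer])
    vert_to_global: list[dict[int, int]] = []
    for li, keep in enumerate(kept_per_layer):
        vert_to_global.append({int(v): offsets[li] + j for j, v in enumerate(keep)})

    layer_points = [points[offsets[li]: offsets[li + 1]] for li in range(n_layers)]

    neighbors: list[tuple[int, ...]] = []
    for li, keep in enumerate(kept_per_layer):
        lookup = vert_to_global[li]
        for j, v in enumerate(keep):
            gid = offsets[li] + j
            ring = set(ring1[int(v)])
            ring2 = set()
            for u in ring:
                ring2.update(ring1[u])
            in_layer = {
                lookup[u] for u in (ring | ring2) if u in lookup and lookup[u] != gid
            }
            cross = set()
            for lo in range(n_layers):
                if lo == li or len(layer_points[lo]) == 0:
                    continue
                d2 = np.sum((layer_points[lo] - points[gid]) ** 2, axis=1)
                cross.add(offsets[lo] + int(np.argmin(d2)))
            neighbors.append(tuple(sorted(in_layer | cross)))
    return tuple(neighbors)


def neighbor_sets(grid: SourceGrid) -> tuple[tuple[int, ...], ...]:
    """Per-point neighbor lists (precomputed at grid construction)."""
    return grid.neighbors


def random_dipoles(grid: SourceGrid, k: int, rng: np.random.Generator) -> DipoleSet:
    """k distinct uniform grid locations with coefficients ~ U(0.5, 1.0)."""
    if not 1 <= k <= grid.n_points:
        raise ValueError(f"k must be in [1, {grid.n_points}], got {k}")
    indices = rng.choice(grid.n_points, size=k, replace=False)
    lo, hi = AMPLITUDE_RANGE
    coefficients = rng.uniform(lo, hi, size=(k, 2))
    return DipoleSet(indices=tuple(int(i) for i in indices), coefficients=coefficients)


def jitter_dipoles(
    dipoles: DipoleSet,
    grid: SourceGrid,
    rng: np.random.Generator,
    max_cases: int | None = None,
    jitter: bool = True,
) -> list[DipoleSet]:
    """Neighbor dipole sets for robustness testing.

    One case per combination pairing one neighbor of each original dipole
    (Cartesian product of the per-dipole neighbor lists).  Coefficients are
    scaled per coefficient by independent factors in [0.8, 1.2] (+-20 %
    orientation/magnitude jitter); ``jitter=False`` moves locations only.
    ``max_cases`` subsamples the product without replacement, keeping the
    case list seeded and reproducible.
    """
    neighbor_lists = [grid.neighbors[i] for i in dipoles.indices]
    combos = list(itertools.product(*neighbor_lists))
    # Drop combos that collapse two dipoles onto one grid point.
    combos = [c for c in combos if len(set(c)) == len(c)]
    if max_cases is not None and len(combos) > max_cases:
        chosen = rng.choice(len(combos), size=max_cases, replace=False)
        combos = [combos[int(i)] for i in sorted(chosen)]
    lo, hi = JITTER_RANGE
    cases = []
    for combo in combos:
        if jitter:
            factors = rng.uniform(lo, hi, size=dipoles.coefficients.shape)
        else:
            factors = np.ones_like(dipoles.coefficients)
        cases.append(
            DipoleSet(indices=combo, coefficients=dipoles.coefficients * factors)
        )
    return cases
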