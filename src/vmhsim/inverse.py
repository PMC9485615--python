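"""Sequential single equivalent-current-dipole fitting (SDF).

Each iteration solves, for every grid location i, the overdetermined
least-squares problem

    L_i = argmin_q || Gain_i q - M ||      (Gain_i: channels x 2)

estimates the field M_est_i = Gain_i L_i, and keeps the location whose
estimated field has the highest squared Pearson spatial correlation with
the field being fitted.  That dipole's field is subtracted and the next
single ECD is fitted to the residual, up to six times.  Dipoles whose
coefficient magnitude (Euclidean norm of the 2-vector) falls below 0.3 of
the strongest are discarded.

The whole array is always used (no a-priori channel selection), and ties
in squared correlation break deterministically to the lowest grid index.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .forward import FieldVector, GainMatrix

__all__ = [
    "SolvedDipole",
    "FitResult",
    "LeadfieldSolver",
    "fit_single_ecd",
    "sequential_dipole_fit",
    "prune_dipoles",
]

#: Maximum sequential iterations (candidate dipoles).
MAX_ITERATIONS = 6

#: Dipoles weaker than this fraction of the strongest magnitude are discarded.
PRUNE_THRESHOLD = 0.3

#: Early stop when the residual drops below this fraction of the input norm.
RESIDUAL_STOP_FRACTION = 1e-12


@dataclass(frozen=True)
class SolvedDipole:
    """One fitted ECD on the grid's tangential basis."""

    grid_index: int
    coefficients: tuple[float, float]
    magnitude: float
    r_squared: float
    iteration: int


@dataclass(frozen=True)
class FitResult:
    """Surviving dipoles after pruning, plus the full candidate trail."""

    dipoles: tuple[SolvedDipole, ...]
    all_candidates: tuple[SolvedDipole, ...]
    residual_norm_history: tuple[float, ...]
    early_stop: bool = False

    @property
    def n_solved(self) -> int:
        return len(self.dipoles)

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(d.grid_index for d in self.dipoles)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


class LeadfieldSolver:
    """Per-gain precomputation for fast repeated scans over grid locations.

    For each location the 2x2 normal matrix ``G_i^T G_i`` (pseudo-inverted
    once, so degenerate tangent pairs still get the minimum-norm solution)
    and the column sums are cached; a scan then costs one ``G^T r`` product
    plus O(P) arithmetic, with correlations computed from sufficient
    statistics instead of materializing every estimated field.
    """

    def __init__(self, gain: GainMatrix):
        self.gain = gain
        G = gain.values
        self.m = G.shape[0]
        self.P = gain.n_points
        Gr = G.reshape(self.m, self.P, 2)
        # Normal matrices (P, 2, 2) and their (pseudo-)inverses.
        gtg = np.einsum("mpa,mpb->pab", Gr, Gr)
        self.gtg = gtg
        det = gtg[:, 0, 0] * gtg[:, 1, 1] - gtg[:, 0, 1] ** 2
        trace = gtg[:, 0, 0] + gtg[:, 1, 1]
        good = det > 1e-12 * np.maximum(trace, 1e-300) ** 2
        inv = np.empty_like(gtg)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv[:, 0, 0] = gtg[:, 1, 1] / det
            inv[:, 1, 1] = gtg[:, 0, 0] / det
            inv[:, 0, 1] = -gtg[:, 0, 1] / det
            inv[:, 1, 0] = -gtg[:, 1, 0] / det
        for i in np.flatnonzero(~good):
            inv[i] = np.linalg.pinv(gtg[i])
        self.gtg_inv = inv
        self.colsums = Gr.sum(axis=0)  # (P, 2)

    def scan(self, field: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Least-squares coefficients (P, 2) and squared Pearson correlation
        (P,) of every location's estimated field with ``field``."""
        m = self.m
        gtm = (field @ self.gain.values).reshape(self.P, 2)
        q = np.einsum("pab,pb->pa", self.gtg_inv, gtm)           # (P, 2)
        field_mean = field.mean()
        field_var = field @ field - m * field_mean**2            # m * var
        # cov(M, M_est) * m = Mc . (G_i q) = (G^T Mc)_i . q
        gtm_c = gtm - field_mean * self.colsums
        cov = np.einsum("pa,pa->p", gtm_c, q)
        # var(M_est) * m = q^T GtG q - (colsums . q)^2 / m
        est_ss = np.einsum("pa,pab,pb->p", q, self.gtg, q)
        est_mean_term = np.einsum("pa,pa->p", self.colsums, q) ** 2 / m
        est_var = est_ss - est_mean_term
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = cov**2 / (field_var * est_var)
        r2 = np.where((est_var <= 0) | ~np.isfinite(r2), 0.0, r2)
        return q, np.clip(r2, 0.0, 1.0)

    def estimated_field(self, index: int, q: np.ndarray) -> np.ndarray:
        cols = self.gain.values[:, 2 * index: 2 * index + 2]
        return cols @ q


def fit_single_ecd(
    gain: GainMatrix | LeadfieldSolver, field: FieldVector, iteration: int = 1
) -> SolvedDipole:
    """Best single-dipole explanation of a field over all grid locations.

    Scans every location, solves the per-location least-squares problem,
    and returns the location with the highest squared spatial correlation
    (ties to the lowest index).
    """
    solver = gain if isinstance(gain, LeadfieldSolver) else LeadfieldSolver(gain)
    field = np.asarray(field, dtype=float)
    if field.shape != (solver.m,):
        raise ValueError("field length must match the gain's channel count")
    if solver.m < 3:
        raise ValueError("at least 3 channels are required")
    if np.ptp(field) == 0.0:
        raise ValueError("degenerate input: field has zero spatial variance")
    q, r2 = solver.scan(field)
    best = int(np.argmax(r2))  # argmax returns the lowest index on ties
    qb = q[best]
    return SolvedDipole(
        grid_index=best,
        coefficients=(float(qb[0]), float(qb[1])),
        magnitude=float(np.hypot(qb[0], qb[1])),
        r_squared=float(r2[best]),
        iteration=iteration,
    )


def prune_dipoles(
    candidates: tuple[SolvedDipole, ...] | list[SolvedDipole],
    threshold: float = PRUNE_THRESHOLD,
) -> tuple[SolvedDipole, ...]:
    """Discard dipoles weaker than ``threshold`` times the strongest magnitude."""
    if not candidates:
        return ()
    strongest = max(d.magnitude for d in candidates)
    return tuple(d for d in candidates if d.magnitude >= threshold * strongest)


def sequential_dipole_fit(
    gain: GainMatrix | LeadfieldSolver,
    field: FieldVector,
    max_iter: int = MAX_ITERATIONS,
    prune_threshold: float = PRUNE_THRESHOLD,
) -> FitResult:
    """Sequential single-ECD fit with residual subtraction and pruning.

    Fits at most ``max_iter`` single dipoles, each to the residual left by
    the previous ones, then prunes by relative magnitude.  Stops early when
    the residual is numerically zero.
    """
    solver = gain if isinstance(gain, LeadfieldSolver) else LeadfieldSolver(gain)
    field = np.asarray(field, dtype=float)
    residual = field.copy()
    original_norm = float(np.linalg.norm(residual))
    candidates: list[SolvedDipole] = []
    history = [original_norm]
    early_stop = False
    for it in range(1, max_iter + 1):
        if np.ptp(residual) == 0.0 or (
            np.linalg.norm(residual) < RESIDUAL_STOP_FRACTION * original_norm
        ):
            early_stop = True
            break
        dipole = fit_single_ecd(solver, residual, iteration=it)
        candidates.append(dipole)
        residual = residual - solver.estimated_field(
            dipole.grid_index, np.asarray(dipole.coefficients)
        )
        history.append(float(np.linalg.norm(residual)))
    survivors = prune_dipoles(candidates, prune_threshold)
    return FitResult(
        dipoles=survivors,
        all_candidates=tuple(candidates),
        residual_norm_history=tuple(history),
        early_stop=early_stop,
    )
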