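"""Scoring localizations: dipole matching, helmet precedence, robustness.

Solved dipoles are matched one-to-one to placed dipoles by minimum total
Euclidean distance (optimal assignment); unmatched placed dipoles
(missing) and unmatched solved dipoles (superfluous) do not enter the
distance mean.  Helmets are then ranked by a precedence scheme that values
recovering the right number of dipoles above distance accuracy, and
missing dipoles above superfluous ones; the robustness of a helmet for a
source configuration is the percentage of neighboring configurations on
which it remains the best choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .inverse import FitResult
from .source_space import DipoleSet, SourceGrid

__all__ = [
    "MatchResult",
    "match_dipoles",
    "best_helmet",
    "robustness",
    "permutation_test",
]


@dataclass(frozen=True)
class MatchResult:
    """Optimal pairing of placed and solved dipoles for one helmet/case."""

    pairs: tuple[tuple[int, int, float], ...]  # (placed index, solved index, mm)
    n_placed: int
    n_solved: int
    mean_distance_mm: float  # NaN when no dipole was solved

    @property
    def count_deviation(self) -> int:
        return self.n_solved - self.n_placed

    @property
    def has_distance(self) -> bool:
        return np.isfinite(self.mean_distance_mm)

    def sort_key(self) -> tuple[int, int, float]:
        """Precedence key: |count deviation|, then superfluous-after-missing,
        then mean distance (undefined distance ranks last)."""
        dev = self.count_deviation
        dist = self.mean_distance_mm if self.has_distance else np.inf
        return (abs(dev), 1 if dev > 0 else 0, dist)


def match_dipoles(
    placed: DipoleSet,
    solved: FitResult | DipoleSet,
    grid: SourceGrid,
    method: str = "optimal",
) -> MatchResult:
    """Assign solved to placed dipoles and average the pair distances.

    ``optimal`` (default) minimizes the total distance over one-to-one
    assignments; ``greedy`` repeatedly takes the closest remaining pair
    (kept for sensitivity analysis).  Exactly ``min(n_placed, n_solved)``
    pairs are formed; leftovers on either side are excluded from the mean.
    """
    placed_locs = placed.locations(grid)
    if isinstance(solved, FitResult):
        solved_indices = list(solved.indices)
    else:
        solved_indices = list(solved.indices)
    solved_locs = grid.points[solved_indices] if solved_indices else np.empty((0, 3))

    n_placed, n_solved = len(placed_locs), len(solved_locs)
    if n_solved == 0:
        return MatchResult(
            pairs=(), n_placed=n_placed, n_solved=0, mean_distance_mm=float("nan")
        )

    dist = np.linalg.norm(placed_locs[:, None, :] - solved_locs[None, :, :], axis=-1)
    if method == "optimal":
        rows, cols = linear_sum_assignment(dist)
        pairs = [(int(r), int(c), float(dist[r, c])) for r, c in zip(rows, cols)]
    elif method == "greedy":
        pairs = []
        free_p = set(range(n_placed))
        free_s = set(range(n_solved))
        while free_p and free_s:
            r, c = min(
                ((r, c) for r in free_p for c in free_s), key=lambda rc: dist[rc]
            )
            pairs.append((r, c, float(dist[r, c])))
            free_p.discard(r)
            free_s.discard(c)
    else:
        raise ValueError("method must be 'optimal' or 'greedy'")

    mean_distance = float(np.mean([d for _, _, d in pairs]))
    return MatchResult(
        pairs=tuple(pairs),
        n_placed=n_placed,
        n_solved=n_solved,
        mean_distance_mm=mean_distance,
    )


def best_helmet(
    verdicts: Sequence[tuple[Hashable, MatchResult]]
) -> tuple[Hashable, ...]:
    """Helmets offering the best solution for one placed set.

    Precedence: smallest |n_solved - n_placed| first; at equal deviation a
    missing dipole beats a superfluous one; within the winning count class
    the lowest mean distance wins.  Exact ties all win (a configuration on
    which every helmet ties is a "no-preference" case).  The result is
    invariant to the input order.
    """
    if len(verdicts) < 2:
        raise ValueError("best_helmet needs at least two helmets to compare")
    keys = {helmet: match.sort_key() for helmet, match in verdicts}
    if len(keys) != len(verdicts):
        raise ValueError("helmet identifiers must be unique")
    best_key = min(keys.values())
    return tuple(h for h, _ in verdicts if keys[h] == best_key)


def robustness(
    helmet: Hashable,
    neighbor_best_sets: Sequence[Iterable[Hashable]],
) -> float:
    """Percentage of neighbor cases on which ``helmet`` was among the best."""
    n = len(neighbor_best_sets)
    if n == 0:
        raise ValueError("robustness is undefined with zero neighbor cases")
    hits = sum(1 for best in neighbor_best_sets if helmet in set(best))
    return 100.0 * hits / n


def permutation_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    alternative: str = "two-sided",
) -> float:
    """Permutation p-value for a difference of means.

    Labels are permuted ``n_perm`` times; the p-value uses the add-one
    correction ``p = (1 + #extreme) / (1 + n_perm)`` so it is never zero.
    ``alternative`` is ``two-sided``, ``greater`` (mean_a > mean_b) or
    ``less``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives a very coarse p-value", stacklevel=2)
    if rng is None:
        rng = np.random.default_rng()

    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n_a = a.size
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    diffs = perms[:, :n_a].mean(axis=1) - perms[:, n_a:].mean(axis=1)
    if alternative == "two-sided":
        count = int(np.sum(np.abs(diffs) >= abs(observed) - 1e-12))
    elif alternative == "greater":
        count = int(np.sum(diffs >= observed - 1e-12))
    elif alternative == "less":
        count = int(np.sum(diffs <= observed + 1e-12))
    else:
        raise ValueError("alternative must be two-sided, greater or less")
    return (1 + count) / (1 + n_perm)
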