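"""Simulation drivers: helmet comparison, robustness, and personalization.

Three experiment parts mirror the study design:

* Part I compares the standard helmet against two- and three-array VMHs
  over 1-5 placed dipoles and several noise levels.
* Part II localizes random dipole pairs with the whole helmet catalog and
  measures each helmet's robustness over jittered neighbor configurations.
* Part III builds a prior-based personalized VMH: localize each pair with
  the standard helmet (stage 1), select the VMH that best re-localizes
  that prior and its neighbors (stage 2), then re-localize the true pair
  with the selected helmet (stage 3).

Within one trial the placed dipole set is identical for every compared
helmet; all randomness derives from a master seed via spawned seed
sequences, so every part is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .evaluation import MatchResult, best_helmet, match_dipoles, permutation_test
from .forward import GainMatrix, effective_rank, gain_matrix
from .geometry import HeadModel, VirtualHelmet, helmet_catalog, synthetic_helmet
from .inverse import FitResult, LeadfieldSolver, sequential_dipole_fit
from .noise import NoiseCalibration, calibrate, simulate_measurement
from .source_space import (
    DEFAULT_CUT_PLANE_Z,
    DEFAULT_LAYER_RADII,
    DipoleSet,
    SourceGrid,
    build_grid,
    jitter_dipoles,
    random_dipoles,
)

__all__ = [
    "ExperimentConfig",
    "SimulationContext",
    "build_context",
    "run_part1",
    "run_part2",
    "run_part3",
]

#: Helmets used in Part I: standard, VMHa (2 arrays), VMHb (3 arrays).
PART1_SERIALS = (1, 11, 14)


@dataclass(frozen=True)
class ExperimentConfig:
    """All tunables for the simulation parts.

    Defaults are the study conditions; the replication counts ``n_sims``
    and ``n_pairs`` trade Monte-Carlo resolution for runtime without
    changing any modelled quantity.
    """

    seed: int = 0
    n_sims: int = 200
    dipole_counts: tuple[int, ...] = (1, 2, 3, 4, 5)
    noise_levels: tuple[float, ...] = (0.0, 0.1, 0.3)
    helmet_serials: tuple[int, ...] | None = None
    n_pairs: int = 100
    pair_noise_level: float = 0.1
    max_neighbor_cases: int = 16
    calibration_iters: int = 1000
    bn_mode: str = "per-array"
    include_standard_in_stage2: bool = False
    layer_radii: tuple[float, ...] = DEFAULT_LAYER_RADII
    cut_plane_z: float = DEFAULT_CUT_PLANE_Z
    subdivisions: int = 3
    n_channels: int = 248
    head_radius: float = 95.5
    max_iter: int = 6
    prune_threshold: float = 0.3
    compute_rank: bool = False
    tie_sweep: int = 0

    def __post_init__(self) -> None:
        if self.n_sims < 1 or self.n_pairs < 1:
            raise ValueError("n_sims and n_pairs must be at least 1")
        if self.bn_mode not in ("per-array", "single-draw"):
            raise ValueError("bn_mode must be 'per-array' or 'single-draw'")
        for name in ("dipole_counts", "noise_levels", "layer_radii"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        if self.helmet_serials is not None:
            object.__setattr__(self, "helmet_serials", tuple(self.helmet_serials))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulationContext:
    """Shared geometry, gains and fast solvers for one experiment run."""

    head: HeadModel
    grid: SourceGrid
    helmets: Mapping[int, VirtualHelmet]
    gains: Mapping[int, GainMatrix]
    solvers: Mapping[int, LeadfieldSolver]

    @property
    def standard_gain(self) -> GainMatrix:
        return self.gains[1]


def build_context(
    config: ExperimentConfig, serials: Sequence[int]
) -> SimulationContext:
    """Build the grid, the requested helmets, and their gains/solvers."""
    head = HeadModel(radius=config.head_radius)
    base = synthetic_helmet(n_channels=config.n_channels)
    grid = build_grid(
        head,
        layer_radii=config.layer_radii,
        cut_plane_z=config.cut_plane_z,
        subdivisions=config.subdivisions,
    )
    catalog = {h.serial: h for h in helmet_catalog(base, head)}
    missing = [s for s in serials if s not in catalog]
    if missing:
        raise ValueError(f"helmet serials not in catalog: {missing}")
    helmets = {s: catalog[s] for s in serials}
    gains = {s: gain_matrix(h, grid, head) for s, h in helmets.items()}
    solvers = {s: LeadfieldSolver(g) for s, g in gains.items()}
    return SimulationContext(
        head=head, grid=grid, helmets=helmets, gains=gains, solvers=solvers
    )


def _calibrations(
    config: ExperimentConfig,
    ctx: SimulationContext,
    levels: Sequence[float],
    part: int,
) -> dict[float, NoiseCalibration | None]:
    """One calibration per distinct noise level (None for f = 0).

    The Monte-Carlo means are drawn once; k and c scale linearly with f,
    so every level shares the same calibration draws.
    """
    cals: dict[float, NoiseCalibration | None] = {}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, part, 0xCA11B]))
    ref: NoiseCalibration | None = None
    for f in sorted(set(levels)):
        if f == 0:
            cals[f] = None
            continue
        if ref is None:
            ref = calibrate(ctx.standard_gain, 1.0, config.calibration_iters, rng=rng)
        cals[f] = NoiseCalibration(
            f=float(f),
            k=f * ref.k,
            c=f * ref.c,
            mean_signal_std=ref.mean_signal_std,
            mean_bn_std=ref.mean_bn_std,
            n_iter=ref.n_iter,
            seed=config.seed,
        )
    return cals


def _fit_and_match(
    ctx: SimulationContext,
    serial: int,
    dipoles: DipoleSet,
    cal: NoiseCalibration | None,
    rng: np.random.Generator | None,
    config: ExperimentConfig,
) -> tuple[FitResult, MatchResult]:
    """Simulate a measurement of ``dipoles`` with one helmet and score it."""
    meas = simulate_measurement(
        ctx.gains[serial], dipoles, cal, rng=rng, mode=config.bn_mode
    )
    fit = sequential_dipole_fit(
        ctx.solvers[serial],
        meas,
        max_iter=config.max_iter,
        prune_threshold=config.prune_threshold,
    )
    return fit, match_dipoles(dipoles, fit, ctx.grid)


def _helmet_rngs(
    config: ExperimentConfig, part: int, pair: int, serials: Sequence[int], case: int
) -> dict[int, np.random.Generator]:
    """Independent, reproducible noise streams per helmet and case."""
    ss = np.random.SeedSequence([config.seed, part, pair, 0x0E15E, case])
    children = ss.spawn(len(serials))
    return {s: np.random.default_rng(ch) for s, ch in zip(serials, children)}


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, float)
    if values.size == 0:
        return float("nan")
    return float(np.std(values, ddof=0) / np.sqrt(values.size))


# ---------------------------------------------------------------------------
# Part I
# ---------------------------------------------------------------------------

def run_part1(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Standard vs VMHa vs VMHb across dipole counts and noise levels.

    Returns ``trials`` (one row per trial x helmet) and ``summary``
    (mean +- SEM of solved count and distance error per condition).  The
    placed dipole set of a trial is shared by all helmets.
    """
    serials = config.helmet_serials or PART1_SERIALS
    ctx = build_context(config, serials)
    cals = _calibrations(config, ctx, config.noise_levels, part=1)

    rows = []
    for fi, f in enumerate(config.noise_levels):
        for ki, k in enumerate(config.dipole_counts):
            cond_ss = np.random.SeedSequence([config.seed, 1, fi, ki])
            for trial, tss in enumerate(cond_ss.spawn(config.n_sims)):
                children = tss.spawn(1 + len(serials))
                dipoles = random_dipoles(
                    ctx.grid, k, np.random.default_rng(children[0])
                )
                for hi, serial in enumerate(serials):
                    _, match = _fit_and_match(
                        ctx,
                        serial,
                        dipoles,
                        cals[f],
                        np.random.default_rng(children[1 + hi]),
                        config,
                    )
                    rows.append(
                        {
                            "noise_level": f,
                            "n_placed": k,
                            "trial": trial,
                            "helmet_serial": serial,
                            "helmet_name": ctx.helmets[serial].name or str(serial),
                            "n_arrays": ctx.helmets[serial].n_arrays,
                            "n_solved": match.n_solved,
                            "mean_distance_mm": match.mean_distance_mm,
                            "placed_indices": dipoles.indices,
                        }
                    )
    trials = pd.DataFrame(rows)

    summaries = []
    for (f, k, serial), grp in trials.groupby(
        ["noise_level", "n_placed", "helmet_serial"], sort=True
    ):
        dist = grp["mean_distance_mm"].dropna().to_numpy()
        summaries.append(
            {
                "noise_level": f,
                "n_placed": k,
                "helmet_serial": serial,
                "n_arrays": int(grp["n_arrays"].iloc[0]),
                "n_trials": len(grp),
                "mean_n_solved": grp["n_solved"].mean(),
                "sem_n_solved": _sem(grp["n_solved"].to_numpy()),
                "mean_distance_mm": dist.mean() if dist.size else float("nan"),
                "sem_distance_mm": _sem(dist),
                "n_no_solution": int(grp["mean_distance_mm"].isna().sum()),
                "n_superfluous": int((grp["n_solved"] > grp["n_placed"]).sum()),
            }
        )
    return {"trials": trials, "summary": pd.DataFrame(summaries)}


# ---------------------------------------------------------------------------
# Part II
# ---------------------------------------------------------------------------

def _evaluate_case(
    ctx: SimulationContext,
    serials: Sequence[int],
    dipoles: DipoleSet,
    cal: NoiseCalibration | None,
    rngs: Mapping[int, np.random.Generator],
    config: ExperimentConfig,
) -> dict[int, MatchResult]:
    return {
        s: _fit_and_match(ctx, s, dipoles, cal, rngs[s], config)[1] for s in serials
    }


def run_part2(config: ExperimentConfig) -> dict:
    """Robustness of the full catalog on random dipole pairs.

    For each pair: which helmets are best on the original pair, and on what
    percentage of jittered neighbor configurations each helmet stays best.
    Returns per-pair verdicts, per-(pair, helmet) robustness, the per-helmet
    best-percentage, and the best-on-original vs not dichotomy statistics.
    """
    serials = config.helmet_serials or tuple(range(1, 15))
    ctx = build_context(config, serials)
    f = config.pair_noise_level
    cal = _calibrations(config, ctx, [f], part=2)[f]

    verdict_rows, robust_rows = [], []
    robust_best, robust_other = [], []
    for pair in range(config.n_pairs):
        pair_ss = np.random.SeedSequence([config.seed, 2, pair])
        children = pair_ss.spawn(2)
        placed = random_dipoles(ctx.grid, 2, np.random.default_rng(children[0]))
        jit_rng = np.random.default_rng(children[1])

        rngs = _helmet_rngs(config, 2, pair, serials, case=0)
        original = _evaluate_case(ctx, serials, placed, cal, rngs, config)
        best_orig = set(best_helmet(list(original.items())))

        cases = jitter_dipoles(
            placed, ctx.grid, jit_rng, max_cases=config.max_neighbor_cases
        )
        case_best_sets = []
        for ci, case in enumerate(cases, start=1):
            case_rngs = _helmet_rngs(config, 2, pair, serials, case=ci)
            verdicts = _evaluate_case(ctx, serials, case, cal, case_rngs, config)
            case_best_sets.append(set(best_helmet(list(verdicts.items()))))

        for s in serials:
            match = original[s]
            is_best = s in best_orig
            verdict_rows.append(
                {
                    "pair": pair,
                    "helmet_serial": s,
                    "n_placed": match.n_placed,
                    "n_solved": match.n_solved,
                    "mean_distance_mm": match.mean_distance_mm,
                    "is_best": is_best,
                }
            )
            pct = (
                100.0 * sum(1 for bs in case_best_sets if s in bs) / len(case_best_sets)
                if case_best_sets
                else float("nan")
            )
            robust_rows.append(
                {
                    "pair": pair,
                    "helmet_serial": s,
                    "robustness_pct": pct,
                    "best_on_original": is_best,
                    "n_neighbor_cases": len(case_best_sets),
                }
            )
            if np.isfinite(pct):
                (robust_best if is_best else robust_other).append(pct)

    verdicts_df = pd.DataFrame(verdict_rows)
    robustness_df = pd.DataFrame(robust_rows)
    best_pct = (
        verdicts_df.groupby("helmet_serial")["is_best"]
        .mean()
        .mul(100.0)
        .rename("best_pct")
        .reset_index()
    )
    p_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, 0xD1C0]))
    dichotomy = {
        "mean_robustness_best": float(np.mean(robust_best)) if robust_best else float("nan"),
        "mean_robustness_other": float(np.mean(robust_other)) if robust_other else float("nan"),
        "n_best": len(robust_best),
        "n_other": len(robust_other),
        "p_value": (
            permutation_test(robust_best, robust_other, rng=p_rng, alternative="greater")
            if robust_best and robust_other
            else float("nan")
        ),
    }
    result = {
        "verdicts": verdicts_df,
        "robustness": robustness_df,
        "best_percentage": best_pct,
        "dichotomy": dichotomy,
    }
    if config.compute_rank:
        result["effective_rank"] = pd.DataFrame(
            [
                {
                    "helmet_serial": s,
                    "n_arrays": ctx.helmets[s].n_arrays,
                    "effective_rank": effective_rank(ctx.gains[s]),
                }
                for s in serials
            ]
        )
    return result


# ---------------------------------------------------------------------------
# Part III
# ---------------------------------------------------------------------------

def _prior_from_fit(fit: FitResult) -> DipoleSet | None:
    """Stage-1 estimate as a dipole set: solved locations and coefficients
    used verbatim as the re-projected prior sources."""
    if fit.n_solved == 0:
        return None
    return DipoleSet(
        indices=fit.indices,
        coefficients=np.array([d.coefficients for d in fit.dipoles]),
    )


def _stage2_select(
    ctx: SimulationContext,
    config: ExperimentConfig,
    cal: NoiseCalibration | None,
    pair: int,
    candidates: Sequence[int],
    prior: DipoleSet,
    jit_rng: np.random.Generator,
    tie_rng: np.random.Generator,
) -> tuple[int | None, bool, tuple[int, ...]]:
    """Select the candidate VMH best on the most prior/neighbor cases.

    Returns (selected serial or None, no_preference flag, tied serials).
    """
    cases = [prior] + jitter_dipoles(
        prior, ctx.grid, jit_rng, max_cases=config.max_neighbor_cases
    )
    counts = {s: 0 for s in candidates}
    for ci, case in enumerate(cases, start=1000):
        rngs = _helmet_rngs(config, 3, pair, candidates, case=ci)
        verdicts = _evaluate_case(ctx, candidates, case, cal, rngs, config)
        if len(candidates) == 1:
            counts[candidates[0]] += 1
            continue
        for s in best_helmet(list(verdicts.items())):
            counts[s] += 1
    max_count = max(counts.values())
    ties = tuple(s for s in candidates if counts[s] == max_count)
    if len(ties) == len(candidates) and len(candidates) > 1:
        return None, True, ties
    if len(ties) == 1:
        return ties[0], False, ties
    return ties[int(tie_rng.integers(len(ties)))], False, ties


def run_part3(config: ExperimentConfig) -> dict:
    """Prior-based personalized VMH selection (stages 1-3).

    Stage 1 localizes each placed pair with the standard helmet; stage 2
    re-localizes the stage-1 estimate and its jittered neighbors with every
    candidate VMH and selects the helmet best on the most cases (seeded
    random choice among partial ties; a case where every candidate ties is
    flagged "no preference" and gets no selection); stage 3 scores the
    selected helmet on the original pair.  Also reported: the single VMH
    with the lowest mean error over all pairs, and the theoretical (oracle)
    per-pair best VMH.
    """
    all_serials = config.helmet_serials or tuple(range(1, 15))
    candidates = tuple(
        s for s in all_serials if s != 1 or config.include_standard_in_stage2
    )
    if not candidates:
        raise ValueError("no candidate VMHs for stage 2")
    serials = tuple(sorted(set(all_serials) | {1}))
    ctx = build_context(config, serials)
    f = config.pair_noise_level
    cal = _calibrations(config, ctx, [f], part=3)[f]

    rows = []
    tie_lists: list[tuple[int, ...]] = []
    for pair in range(config.n_pairs):
        pair_ss = np.random.SeedSequence([config.seed, 3, pair])
        children = pair_ss.spawn(3)
        placed = random_dipoles(ctx.grid, 2, np.random.default_rng(children[0]))
        jit_rng = np.random.default_rng(children[1])
        tie_rng = np.random.default_rng(children[2])

        # One localization of the original pair per helmet: serial 1 is the
        # stage-1 recording; the rest feed stage 3, the oracle and the
        # best-single-VMH columns.
        rngs = _helmet_rngs(config, 3, pair, serials, case=0)
        fits: dict[int, FitResult] = {}
        original: dict[int, MatchResult] = {}
        for s in serials:
            fits[s], original[s] = _fit_and_match(ctx, s, placed, cal, rngs[s], config)
        standard_match = original[1]

        prior = _prior_from_fit(fits[1])
        if prior is None:
            selected, no_pref, ties = None, True, ()
        else:
            selected, no_pref, ties = _stage2_select(
                ctx, config, cal, pair, candidates, prior, jit_rng, tie_rng
            )
        tie_lists.append(ties)

        oracle_serial = min(candidates, key=lambda s: original[s].sort_key())
        row = {
            "pair": pair,
            "n_solved_stage1": standard_match.n_solved,
            "standard_error_mm": standard_match.mean_distance_mm,
            "selected_serial": selected,
            "no_preference": no_pref,
            "personalized_error_mm": (
                original[selected].mean_distance_mm
                if selected is not None
                else standard_match.mean_distance_mm
            ),
            "personalized_n_solved": (
                original[selected].n_solved
                if selected is not None
                else standard_match.n_solved
            ),
            "oracle_serial": oracle_serial,
            "oracle_error_mm": original[oracle_serial].mean_distance_mm,
        }
        for s in candidates:
            row[f"error_mm_{s}"] = original[s].mean_distance_mm
        rows.append(row)

    cases_df = pd.DataFrame(rows)

    mean_by_serial = {s: cases_df[f"error_mm_{s}"].dropna().mean() for s in candidates}
    best_single = min(mean_by_serial, key=lambda s: (mean_by_serial[s], s))
    cases_df["best_single_serial"] = best_single
    cases_df["best_single_error_mm"] = cases_df[f"error_mm_{best_single}"]

    summary = _part3_summary(cases_df, config)
    if config.tie_sweep > 0:
        summary["tie_sweep_mean_errors"] = _tie_sweep(cases_df, tie_lists, config)
    return {"cases": cases_df, "summary": summary, "best_single_serial": best_single}


def _error_stats(errors: pd.Series) -> tuple[float, float, int]:
    vals = errors.dropna().to_numpy()
    if vals.size == 0:
        return float("nan"), float("nan"), 0
    return float(vals.mean()), _sem(vals), int(vals.size)


def _part3_summary(cases_df: pd.DataFrame, config: ExperimentConfig) -> dict:
    """Mean distance errors for the four schemes, with and without the
    no-preference pairs, plus improvement percentages and permutation p.

    Where no VMH was selected (no preference) the personalized scheme falls
    back to the standard helmet, so "all pairs" statistics stay defined.
    """
    excl = cases_df[~cases_df["no_preference"]]
    summary: dict = {
        "n_pairs": len(cases_df),
        "n_no_preference": int(cases_df["no_preference"].sum()),
    }
    for tag, frame in (("all", cases_df), ("excl", excl)):
        for scheme, col in (
            ("standard", "standard_error_mm"),
            ("best_single", "best_single_error_mm"),
            ("personalized", "personalized_error_mm"),
            ("theoretical", "oracle_error_mm"),
        ):
            mean, sem, n = _error_stats(frame[col])
            summary[f"mean_{scheme}_{tag}"] = mean
            summary[f"sem_{scheme}_{tag}"] = sem
            summary[f"n_{scheme}_{tag}"] = n
        std_mean = summary[f"mean_standard_{tag}"]
        for scheme in ("best_single", "personalized", "theoretical"):
            mean = summary[f"mean_{scheme}_{tag}"]
            summary[f"improvement_{scheme}_{tag}_pct"] = (
                100.0 * (std_mean - mean) / std_mean if std_mean else float("nan")
            )
        both = frame[["standard_error_mm", "personalized_error_mm"]].dropna()
        if len(both) >= 2:
            p_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 3, 0xD1C0, 0 if tag == "all" else 1])
            )
            summary[f"p_personalized_vs_standard_{tag}"] = permutation_test(
                both["personalized_error_mm"],
                both["standard_error_mm"],
                rng=p_rng,
                alternative="less",
            )
        else:
            summary[f"p_personalized_vs_standard_{tag}"] = float("nan")
    return summary


def _tie_sweep(
    cases_df: pd.DataFrame, tie_lists: Sequence[tuple[int, ...]], config: ExperimentConfig
) -> list[float]:
    """Re-draw the random tie selections ``tie_sweep`` times; per sweep, the
    mean personalized error over preference pairs."""
    means = []
    excl = ~cases_df["no_preference"].to_numpy()
    for i in range(config.tie_sweep):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3, 0x71E, i]))
        errs = []
        for row, ties in zip(cases_df.itertuples(), tie_lists):
            if row.no_preference or not ties:
                continue
            serial = ties[int(rng.integers(len(ties)))] if len(ties) > 1 else ties[0]
            errs.append(getattr(row, f"error_mm_{serial}"))
        vals = np.asarray(errs, float)
        vals = vals[np.isfinite(vals)]
        means.append(float(vals.mean()) if vals.size else float("nan"))
    return means
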