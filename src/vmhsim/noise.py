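"""Technical, brain, and overall noise with Monte-Carlo-calibrated scaling.

Two noise components are added to simulated measurements:

* technical noise (TN): i.i.d. Gaussian per sensor, ``TN ~ k N(0,1)``,
  independent of head position;
* brain noise (BN): Gaussian noise on every grid source projected through
  the helmet gain, ``BN ~ Gain (c N(0,1))``, hence spatially correlated
  over sensors and helmet-dependent.

The scales are calibrated once on the *standard* helmet so that the
overall noise ON is a chosen fraction ``f`` of a reference signal and
``std(BN) = 2 std(TN)``:

    k = f * (1/3) * 0.75 * mean std(signal)        (std(TN) = std(ON)/3)
    c = 2 * std(TN) / mean std(BN | standard)

where the signal reference is the Monte-Carlo mean, over many draws of
three simultaneously active unit dipoles, of the per-realization std of
the standard-helmet field, and 0.75 is the analytic mean of the U(0.5, 1)
amplitude range.  The 1/3 and 2x factors are an additive-std bookkeeping
convention (std(TN) + std(BN) = std(ON)); for independent components the
realized sum has std sqrt(5) k.

Because recording time per head position shrinks with the number of
positions n, the overall noise is ``ON = sqrt(n) (TN + BN)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .forward import FieldVector, GainMatrix, forward_project
from .source_space import DipoleSet

__all__ = [
    "NoiseCalibration",
    "NoiseRealization",
    "calibrate",
    "technical_noise",
    "brain_noise",
    "overall_noise",
    "simulate_measurement",
]

#: Additive-std share of TN in ON: std(TN) = std(ON) / 3.
TN_SHARE = 1.0 / 3.0

#: std(BN) / std(TN) calibration target.
BN_TO_TN = 2.0

#: Mean of the U(0.5, 1) amplitude draw, used to scale the unit-dipole
#: calibration signal to the simulated amplitude range.
MEAN_AMPLITUDE = 0.75

#: Calibration draws use this many simultaneously active unit dipoles.
CALIBRATION_N_DIPOLES = 3

#: Brain-noise modes: an independent source draw per constituent array
#: (separate recording sessions) or a single draw through the full gain.
BN_MODES = ("per-array", "single-draw")


@dataclass(frozen=True)
class NoiseCalibration:
    """Calibrated noise scales for one noise-level fraction ``f``."""

    f: float
    k: float
    c: float
    mean_signal_std: float
    mean_bn_std: float
    n_iter: int
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NoiseCalibration":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class NoiseRealization:
    """One draw of the three noise fields; ``on = sqrt(n) * (tn + bn)``."""

    tn: FieldVector
    bn: FieldVector
    on: FieldVector
    n_arrays: int


def calibrate(
    standard_gain: GainMatrix,
    f: float,
    n_iter: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> NoiseCalibration:
    """Monte-Carlo calibration of k and c on the standard helmet.

    ``mean_signal_std``: mean over ``n_iter`` draws of three random grid
    locations with unit coefficients on both tangential basis vectors,
    projected on the standard helmet, of the per-draw field std.
    ``mean_bn_std``: same over standard-normal source vectors.  Both
    constants are computed on the standard (n = 1) helmet only and reused
    unchanged for every VMH under test.
    """
    if standard_gain.n_arrays != 1:
        raise ValueError("calibration requires the standard (single-array) gain")
    if f < 0:
        raise ValueError("noise fraction f must be non-negative")
    if n_iter < 2:
        raise ValueError("n_iter must be at least 2")
    if rng is None:
        rng = np.random.default_rng(seed)

    G = standard_gain.values
    P = standard_gain.n_points

    # Signal reference: 3 unit dipoles per draw (unit coefficients on both
    # basis vectors; the 0.75 amplitude weight enters k analytically).
    coeffs = np.zeros((2 * P, n_iter))
    for it in range(n_iter):
        idx = rng.choice(P, size=CALIBRATION_N_DIPOLES, replace=False)
        cols = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        coeffs[cols, it] = 1.0
    signal_std = np.std(G @ coeffs, axis=0, ddof=0)
    mean_signal_std = float(np.mean(signal_std))

    # Brain-noise reference: standard-normal vectors over all source
    # components projected on the standard helmet.
    bn_fields = G @ rng.standard_normal((2 * P, n_iter))
    mean_bn_std = float(np.mean(np.std(bn_fields, axis=0, ddof=0)))

    k = f * TN_SHARE * MEAN_AMPLITUDE * mean_signal_std
    c = BN_TO_TN * k / mean_bn_std
    return NoiseCalibration(
        f=float(f),
        k=k,
        c=c,
        mean_signal_std=mean_signal_std,
        mean_bn_std=mean_bn_std,
        n_iter=n_iter,
        seed=seed,
    )


def technical_noise(
    cal: NoiseCalibration, n_channels: int, rng: np.random.Generator
) -> FieldVector:
    """i.i.d. Gaussian sensor noise with scale k; identical k for every
    constituent array of a VMH."""
    return cal.k * rng.standard_normal(n_channels)


def brain_noise(
    cal: NoiseCalibration,
    helmet_gain: GainMatrix,
    rng: np.random.Generator,
    mode: str = "per-array",
) -> FieldVector:
    """Correlated sensor noise from Gaussian sources through the gain.

    ``per-array`` (default) draws an independent source vector for each
    constituent array — separate recording sessions see independent brain
    background — while ``single-draw`` pushes one draw through the full VMH
    gain.  The calibration target (std(BN) = 2 std(TN) on the standard
    helmet) is identical in both modes.
    """
    if mode not in BN_MODES:
        raise ValueError(f"mode must be one of {BN_MODES}")
    n_sources = 2 * helmet_gain.n_points
    if mode == "single-draw":
        src = cal.c * rng.standard_normal(n_sources)
        return helmet_gain.values @ src
    parts = []
    for a in range(helmet_gain.n_arrays):
        src = cal.c * rng.standard_normal(n_sources)
        parts.append(helmet_gain.array_block(a) @ src)
    return np.concatenate(parts)


def overall_noise(tn: FieldVector, bn: FieldVector, n_arrays: int) -> FieldVector:
    """ON = sqrt(n) * (TN + BN): shorter per-position recordings average
    fewer events, inflating the residual noise by sqrt(n)."""
    tn = np.asarray(tn, float)
    bn = np.asarray(bn, float)
    if tn.shape != bn.shape:
        raise ValueError("tn and bn must have matching lengths")
    if n_arrays < 1:
        raise ValueError("n_arrays must be at least 1")
    return np.sqrt(n_arrays) * (tn + bn)


def noise_realization(
    cal: NoiseCalibration,
    helmet_gain: GainMatrix,
    rng: np.random.Generator,
    mode: str = "per-array",
) -> NoiseRealization:
    """Draw TN, BN and the combined ON for one measurement."""
    tn = technical_noise(cal, helmet_gain.shape[0], rng)
    bn = brain_noise(cal, helmet_gain, rng, mode=mode)
    on = overall_noise(tn, bn, helmet_gain.n_arrays)
    return NoiseRealization(tn=tn, bn=bn, on=on, n_arrays=helmet_gain.n_arrays)


def simulate_measurement(
    gain: GainMatrix,
    dipoles: DipoleSet,
    cal: NoiseCalibration | None,
    rng: np.random.Generator | None = None,
    mode: str = "per-array",
) -> FieldVector:
    """Forward-projected dipole field plus one overall-noise realization.

    ``cal=None`` (or f = 0) returns the noiseless projection.
    """
    signal = forward_project(gain, dipoles)
    if cal is None or cal.f == 0:
        return signal
    if rng is None:
        raise ValueError("an rng is required when noise is enabled")
    return signal + noise_realization(cal, gain, rng, mode=mode).on
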