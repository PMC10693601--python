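"""Idealized dead-time model for a photon-counting detector.

An avalanche photodiode is blind for a fixed dead time ``tau`` after each
detected photon.  Under the idealized (non-paralyzable, events during the
dead time have no effect) model, a measured rate ``m`` relates to the true
incident rate ``n`` through

    n = m / (1 - m * tau)

The forward direction (``true_rate``) corrects measured counts during
analysis; the algebraic inverse (``measured_rate``) censors simulated photon
rates so that synthetic data carry the same bias as the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DeadTimeModel",
    "true_rate",
    "measured_rate",
    "underestimation_fraction",
    "correct_counts",
]


@dataclass(frozen=True)
class DeadTimeModel:
    """Detector dead time and the counting window over which rates are defined.

    Parameters
    ----------
    tau : float
        Dead time in seconds.  Default 35 ns, typical of the APDs used in
        correlative tweezers-fluorescence instruments.
    window : float
        Integration window in seconds used to convert counts to rates;
        the confocal pixel dwell time (default 50 us).
    """

    tau: float = 35e-9
    window: float = 50e-6

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError(f"dead time must be >= 0, got {self.tau}")
        if self.window <= 0:
            raise ValueError(f"window must be > 0, got {self.window}")


class SaturationError(ValueError):
    """Measured rate at or beyond the dead-time saturation limit 1/tau."""


def _as_array(x):
    return np.asarray(x, dtype=float)


def true_rate(m, model: DeadTimeModel = DeadTimeModel()):
    """True photon rate (photons/s) from a measured rate ``m`` (photons/s).

    Applies ``n = m / (1 - m*tau)``.  Raises :class:`SaturationError` when
    ``m * tau >= 1`` (the detector cannot measure such a rate).
    """
    m = _as_array(m)
    if np.any(m < 0):
        raise ValueError("measured rate must be >= 0")
    occupancy = m * model.tau
    if np.any(occupancy >= 1):
        raise SaturationError(
            "measured rate at or above the saturation limit 1/tau"
        )
    out = m / (1.0 - occupancy)
    return float(out) if out.ndim == 0 else out


def measured_rate(n, model: DeadTimeModel = DeadTimeModel()):
    """Measured photon rate for a true incident rate ``n`` (photons/s).

    Algebraic inverse of :func:`true_rate`: ``m = n / (1 + n*tau)``.
    Always finite; round-trips with :func:`true_rate` to machine precision.
    """
    n = _as_array(n)
    if np.any(n < 0):
        raise ValueError("true rate must be >= 0")
    out = n / (1.0 + n * model.tau)
    return float(out) if out.ndim == 0 else out


def underestimation_fraction(m, model: DeadTimeModel = DeadTimeModel()):
    """Fraction of true photons lost to dead time at measured rate ``m``.

    Equals ``(true_rate(m) - m) / true_rate(m) = m * tau``.
    """
    m = _as_array(m)
    if np.any(m < 0):
        raise ValueError("measured rate must be >= 0")
    occupancy = m * model.tau
    if np.any(occupancy >= 1):
        raise SaturationError(
            "measured rate at or above the saturation limit 1/tau"
        )
    return float(occupancy) if occupancy.ndim == 0 else occupancy


def correct_counts(counts, model: DeadTimeModel = DeadTimeModel()):
    """Dead-time-correct photon *counts* acquired over ``model.window``.

    Counts are converted to a rate via the window, corrected with
    :func:`true_rate`, and converted back, so 11 counts per 50 us pixel
    dwell is treated as 220e3 photons/s.
    """
    counts = _as_array(counts)
    rate = counts / model.window
    corrected = true_rate(rate, model)
    out = np.asarray(corrected) * model.window
    return float(out) if out.ndim == 0 else out


def censor_counts(counts, model: DeadTimeModel = DeadTimeModel(), rng=None):
    """Thin *realized* photon counts the way the dead time would.

    Each count array element is the number of photons that arrived during
    ``model.window``; the expected kept fraction is ``1/(1 + n*tau)`` with
    ``n`` the implied true rate.  With ``rng`` given, thinning is binomial;
    otherwise the deterministic expected-count transform is applied and
    rounded to the nearest integer.
    """
    counts = np.asarray(counts)
    rate = counts / model.window
    keep = 1.0 / (1.0 + rate * model.tau)
    if rng is None:
        return np.rint(counts * keep).astype(counts.dtype)
    return rng.binomial(counts.astype(np.int64), keep).astype(counts.dtype)
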