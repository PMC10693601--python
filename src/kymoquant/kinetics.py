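"""Dwell-time kinetics: k_off from histogram fits, k_on from unbound times.

The dissociation rate constant k_off is the decay rate of the distribution
of single-molecule residence times: dwell times are histogrammed at 1 s bin
width, the first bin is dropped (it is depleted by the tracker's minimum
trace length and by events shorter than a couple of scan lines), and the
counts are fitted to ``y = A exp(-k_off t) + y0`` by unweighted nonlinear
least squares.  The association rate constant follows from the per-kymograph
unbound time t_on as ``k_on = 1 / ([C] * t_on)``, and K_D = k_off / k_on.

Censoring rule: traces present in the first or last scan line have truncated
dwell times and are excluded from the k_off fit, but their residence time
still counts toward the occupancy sum used for t_on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "DwellTimeSet",
    "DwellHistogram",
    "ExpFitResult",
    "KonEstimate",
    "UnboundTime",
    "dwell_histogram",
    "fit_koff",
    "fit_koff_from_dwells",
    "eligible_dwells",
    "unbound_time",
    "fit_kon",
    "kon_from_bulk_kobs",
    "dissociation_constant",
    "ExponentialDwellFitter",
]


@dataclass
class DwellTimeSet:
    dwells: np.ndarray                 # seconds, one per eligible trace
    concentration: float | None = None  # molar
    source_force_pN: float | None = None

    def __post_init__(self) -> None:
        self.dwells = np.asarray(self.dwells, dtype=float)
        if np.any(self.dwells <= 0):
            raise ValueError("dwell times must be > 0")

    @property
    def n(self) -> int:
        return self.dwells.size


@dataclass
class DwellHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    bin_width_s: float
    first_bin_dropped: bool
    dropped_fraction: float = 0.0      # fraction of dwells in the dropped bin

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ExpFitResult:
    k_off: float
    k_off_stderr: float
    amplitude: float
    y0: float
    r_squared: float
    rmse: float
    bin_width_s: float
    first_bin_dropped: bool
    success: bool = True

    def __post_init__(self) -> None:
        if self.success and self.k_off <= 0:
            raise ValueError("k_off must be > 0")


@dataclass
class UnboundTime:
    t_on_s: float
    overlap_flag: bool = False   # residence sum exceeded the observation time


@dataclass
class KonEstimate:
    t_on_per_kymograph: np.ndarray
    mean_t_on: float
    concentration: float
    k_on: float                     # 1 / ([C] * mean_t_on)
    k_on_per_kymograph: np.ndarray = field(default=None)


def dwell_histogram(
    dwells, bin_width_s: float = 1.0, drop_first: bool = True
) -> DwellHistogram:
    """Histogram dwell times with half-open bins [k*w, (k+1)*w) from zero."""
    if isinstance(dwells, DwellTimeSet):
        dwells = dwells.dwells
    dwells = np.asarray(dwells, dtype=float)
    if dwells.size < 20:
        raise ValueError(f"need >= 20 dwell times, got {dwells.size}")
    n_bins = int(np.floor(dwells.max() / bin_width_s)) + 1
    edges = np.arange(n_bins + 1) * bin_width_s
    counts, edges = np.histogram(dwells, bins=edges)
    dropped_fraction = 0.0
    if drop_first:
        dropped_fraction = counts[0] / dwells.size
        counts, edges = counts[1:], edges[1:]
    return DwellHistogram(
        bin_edges=edges,
        counts=counts,
        bin_width_s=bin_width_s,
        first_bin_dropped=drop_first,
        dropped_fraction=float(dropped_fraction),
    )


class ExponentialDwellFitter(BaseEstimator):
    """Single-exponential decay fit ``y = A exp(-k t) + y0`` to bin counts.

    Unweighted nonlinear least squares on (bin center, count) pairs.  R^2 is
    the coefficient of determination; RMSE is sqrt(RSS / (n - 3)), matching
    the reduced form commercial fitting software reports.
    """

    def __init__(self, min_occupied_bins: int = 4):
        self.min_occupied_bins = min_occupied_bins

    def fit(self, hist: DwellHistogram):
        t = hist.centers
        y = hist.counts.astype(float)
        if np.count_nonzero(y) < self.min_occupied_bins:
            raise ValueError(
                f"need >= {self.min_occupied_bins} occupied bins, "
                f"got {np.count_nonzero(y)}"
            )
        # log-linear initial guess on the positive counts
        pos = y > 0
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        k0 = max(-slope, 1e-3)
        p0 = [float(np.exp(intercept + k0 * 0.0)), k0, 0.0]
        try:
            popt, pcov = curve_fit(
                lambda tt, a, k, c: a * np.exp(-k * tt) + c,
                t, y, p0=p0,
                bounds=([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            success = True
        except RuntimeError:
            popt, pcov = [np.nan] * 3, np.full((3, 3), np.nan)
            success = False
        a, k, c = popt
        if success:
            fitted = a * np.exp(-k * t) + c
            rss = float(np.sum((y - fitted) ** 2))
            tss = float(np.sum((y - y.mean()) ** 2))
            self.r_squared_ = 1.0 - rss / tss if tss > 0 else np.nan
            dof = max(t.size - 3, 1)
            self.rmse_ = float(np.sqrt(rss / dof))
            self.k_off_stderr_ = (
                float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
            )
        else:
            self.r_squared_ = self.rmse_ = self.k_off_stderr_ = np.nan
        self.k_off_, self.amplitude_, self.y0_ = float(k), float(a), float(c)
        self.success_ = success
        self._hist = hist
        return self

    def fit_predict(self, hist: DwellHistogram) -> ExpFitResult:
        self.fit(hist)
        return ExpFitResult(
            k_off=self.k_off_,
            k_off_stderr=self.k_off_stderr_,
            amplitude=self.amplitude_,
            y0=self.y0_,
            r_squared=self.r_squared_,
            rmse=self.rmse_,
            bin_width_s=hist.bin_width_s,
            first_bin_dropped=hist.first_bin_dropped,
            success=self.success_,
        )


def fit_koff(hist: DwellHistogram) -> ExpFitResult:
    """Fit the dwell-time histogram to a single exponential decay."""
    return ExponentialDwellFitter().fit_predict(hist)


def fit_koff_from_dwells(
    dwells, bin_width_s: float = 1.0, drop_first: bool = True
) -> ExpFitResult:
    """Histogram + exponential fit in one call (the full k_off protocol)."""
    return fit_koff(dwell_histogram(dwells, bin_width_s, drop_first))


def eligible_dwells(traces) -> np.ndarray:
    """Residence times eligible for the k_off fit.

    Excludes left-censored traces (present in the first scan line: binding
    time unknown) and right-censored traces (still bound at the end).
    """
    return np.array(
        [
            tr.residence_time_s
            for tr in traces
            if not tr.left_censored and not tr.right_censored
        ]
    )


def unbound_time(kymo_duration_s: float, traces) -> UnboundTime:
    """Per-kymograph unbound time: observation time minus summed residences.

    All traces count toward occupancy, censored or not.  A negative raw value
    (overlapping traces occupy more than the observation time) is clamped to
    zero and flagged.
    """
    if kymo_duration_s <= 0:
        raise ValueError("duration must be > 0")
    occupied = float(sum(tr.residence_time_s for tr in traces))
    raw = kymo_duration_s - occupied
    return UnboundTime(t_on_s=max(raw, 0.0), overlap_flag=raw < 0)


def fit_kon(t_on_values, concentration: float) -> KonEstimate:
    """k_on = 1 / ([C] * mean t_on) from per-kymograph unbound times."""
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    t_on = np.asarray(
        [t.t_on_s if isinstance(t, UnboundTime) else float(t) for t in np.atleast_1d(t_on_values)]
    )
    if t_on.size == 0 or np.any(t_on <= 0):
        raise ValueError("need positive unbound times")
    mean_t_on = float(t_on.mean())
    return KonEstimate(
        t_on_per_kymograph=t_on,
        mean_t_on=mean_t_on,
        concentration=concentration,
        k_on=1.0 / (concentration * mean_t_on),
        k_on_per_kymograph=1.0 / (concentration * t_on),
    )


def kon_from_bulk_kobs(
    k_obs: float, concentration: float, k_obs_unit: str = "per_min"
) -> float:
    """k_on (M^-1 s^-1) from a bulk observed assembly rate, assuming k_off = 0.

    Appropriate when the assembling oligomers are large enough for permanent
    attachment, so the observed relaxation rate is purely associative.
    """
    if k_obs <= 0 or concentration <= 0:
        raise ValueError("k_obs and concentration must be > 0")
    if k_obs_unit == "per_min":
        k_obs_s = k_obs / 60.0
    elif k_obs_unit == "per_s":
        k_obs_s = k_obs
    else:
        raise ValueError("k_obs_unit must be 'per_min' or 'per_s'")
    return k_obs_s / concentration


def dissociation_constant(k_off: float, k_on: float) -> float:
    """Equilibrium dissociation constant K_D = k_off / k_on (molar)."""
    if k_off <= 0 or k_on <= 0:
        raise ValueError("rates must be > 0")
    return k_off / k_on
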