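"""Photobleaching step analysis and single-fluorophore intensity calibration.

A cluster of N labeled molecules bleaches one fluorophore at a time, so its
intensity trajectory is a descending staircase; the size of a single
downward step calibrates the unitary per-fluorophore intensity that converts
photon counts into molecule numbers.  Step detection here is an optimal
piecewise-constant decomposition: for each candidate step count k the
globally RSS-minimal placement of k change points is found by dynamic
programming (Bellman recursion on prefix sums), and k grows while each new
step reduces the residual sum of squares by at least ``min_improvement`` and
is at least ``min_step`` photons tall.  On short trajectories this is
provably identical to exhaustive enumeration of step placements.

Ensemble intensity decay rates (photobleaching of whole clusters) are fitted
as single exponentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

__all__ = [
    "StepFit",
    "UnitaryIntensity",
    "DecayFit",
    "StepFinder",
    "detect_steps",
    "unitary_intensity",
    "decay_rate",
]

_DP_MAX_N = 4000  # above this, fall back to recursive bisection


@dataclass
class StepFit:
    """Piecewise-constant decomposition of an intensity trajectory."""

    plateaus: list          # (start_line, end_line, level), half-open intervals
    steps: list             # (line, size, sign); size = new level - old level
    fit_quality: float      # residual sum of squares
    n_lines: int = 0

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def reconstruction(self) -> np.ndarray:
        out = np.empty(self.n_lines)
        for start, end, level in self.plateaus:
            out[start:end] = level
        return out

    def downward_steps(self) -> np.ndarray:
        """Magnitudes of downward (bleaching) steps."""
        return np.array([-size for _, size, _ in self.steps if size < 0])


@dataclass
class UnitaryIntensity:
    """Calibrated single-fluorophore intensity (photons per line sample)."""

    mean: float
    sd: float
    n_steps: int
    histogram_bin_width: float = 3.0
    method: str = "gaussian"  # "gaussian" histogram fit or "sample" fallback

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"unitary intensity must be > 0, got {self.mean}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class DecayFit:
    """Exponential intensity-decay fit I(t) = I0 exp(-k t) + c."""

    k: float
    k_stderr: float
    amplitude: float
    offset: float
    rss: float
    success: bool = True


# --------------------------------------------------------------------------
# optimal segmentation
# --------------------------------------------------------------------------

def _segment_dp(y: np.ndarray, max_steps: int):
    """Optimal RSS for 0..max_steps change points, with backtracking.

    Returns (rss_per_k, breakpoint_lists) where breakpoint_lists[k] are the
    first lines of each new plateau for the optimal k-step fit.
    """
    n = y.size
    s = np.concatenate(([0.0], np.cumsum(y)))
    q = np.concatenate(([0.0], np.cumsum(y * y)))
    idx = np.arange(n + 1, dtype=float)
    # cost[i, j] = RSS of y[i:j]  (inf for j <= i)
    length = idx[None, :] - idx[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = (q[None, :] - q[:, None]) - (s[None, :] - s[:, None]) ** 2 / length
    cost[length <= 0] = np.inf
    np.nan_to_num(cost, copy=False, nan=np.inf, posinf=np.inf)
    cost = np.maximum(cost, 0.0)

    dp = cost[0].copy()            # k = 0
    argmins = []
    rss_per_k = [float(dp[n])]
    breaks_per_k: list[list[int]] = [[]]
    prev = dp
    for k in range(1, max_steps + 1):
        m = prev[:, None] + cost    # m[i, j]
        arg = np.argmin(m, axis=0)
        cur = m[arg, np.arange(n + 1)]
        argmins.append(arg)
        rss_per_k.append(float(cur[n]))
        bks = []
        j = n
        for kk in range(k - 1, -1, -1):
            j = int(argmins[kk][j])
            bks.append(j)
        breaks_per_k.append(sorted(bks))
        prev = cur
    return rss_per_k, breaks_per_k


def _segment_bisect(y: np.ndarray, max_steps: int):
    """Greedy recursive bisection (long-trajectory fallback)."""
    n = y.size
    s = np.concatenate(([0.0], np.cumsum(y)))
    q = np.concatenate(([0.0], np.cumsum(y * y)))

    def rss(i, j):
        if j - i <= 0:
            return 0.0
        return max((q[j] - q[i]) - (s[j] - s[i]) ** 2 / (j - i), 0.0)

    breaks = [0, n]
    rss_per_k = [rss(0, n)]
    breaks_per_k = [[]]
    for _ in range(max_steps):
        best = None
        for a, b in zip(breaks[:-1], breaks[1:]):
            if b - a < 2:
                continue
            cut = np.arange(a + 1, b, dtype=float)
            sl, sr = s[a + 1 : b] - s[a], s[b] - s[a + 1 : b]
            ql, qr = q[a + 1 : b] - q[a], q[b] - q[a + 1 : b]
            tot = (ql - sl**2 / (cut - a)) + (qr - sr**2 / (b - cut))
            i = int(np.argmin(tot))
            cand = (rss(a, b) - tot[i], int(cut[i]))
            if best is None or cand[0] > best[0]:
                best = cand
        if best is None:
            break
        breaks = sorted(breaks + [best[1]])
        inner = [b for b in breaks if 0 < b < n]
        rss_per_k.append(sum(rss(a, b) for a, b in zip(breaks[:-1], breaks[1:])))
        breaks_per_k.append(inner)
    return rss_per_k, breaks_per_k


class StepFinder(BaseEstimator):
    """Optimal piecewise-constant step detector.

    Parameters
    ----------
    min_step : float
        Minimum accepted step magnitude in photons (default 5, about half
        the unitary single-fluorophore intensity).
    max_steps : int
        Hard cap on the number of steps (default 20).
    min_improvement : float
        A step count k is accepted only while RSS(k) <= (1 - min_improvement)
        * RSS(k-1); default 0.05.
    step_significance : float
        Each step must additionally reduce the local RSS (merged adjacent
        plateaus vs split) by at least ``step_significance * sigma^2 * ln(n)``
        where ``sigma^2`` is the shot-noise variance at the step (mean of the
        two plateau levels, photon counts being Poisson).  The default 2.0 is
        the universal changepoint threshold, which controls spurious splits
        on short noisy plateaus.  Set to 0 to disable.

    Attributes
    ----------
    plateaus_, steps_, rss_, n_steps_ : see :class:`StepFit`.
    """

    def __init__(self, min_step: float = 5.0, max_steps: int = 20,
                 min_improvement: float = 0.05, step_significance: float = 2.0):
        self.min_step = min_step
        self.max_steps = max_steps
        self.min_improvement = min_improvement
        self.step_significance = step_significance

    def _steps_significant(self, traj, s, q, bks) -> bool:
        """Universal-threshold significance of every step in a segmentation."""
        if self.step_significance <= 0:
            return True
        n = traj.size
        thresh_scale = self.step_significance * np.log(n)

        def rss(i, j):
            return max((q[j] - q[i]) - (s[j] - s[i]) ** 2 / (j - i), 0.0)

        for a, b, c in zip(bks[:-2], bks[1:-1], bks[2:]):
            gain = rss(a, c) - rss(a, b) - rss(b, c)
            level = 0.5 * ((s[b] - s[a]) / (b - a) + (s[c] - s[b]) / (c - b))
            if gain < thresh_scale * max(level, 0.0):
                return False
        return True

    def fit(self, trajectory, y=None):
        traj = np.asarray(trajectory, dtype=float).ravel()
        n = traj.size
        if n < 4:
            raise ValueError(f"trajectory too short for step detection ({n} < 4 lines)")
        max_steps = min(self.max_steps, n - 1)
        if n <= _DP_MAX_N:
            rss_per_k, breaks_per_k = _segment_dp(traj, max_steps)
        else:
            rss_per_k, breaks_per_k = _segment_bisect(traj, max_steps)

        s = np.concatenate(([0.0], np.cumsum(traj)))
        q = np.concatenate(([0.0], np.cumsum(traj * traj)))
        chosen = 0
        for k in range(1, len(rss_per_k)):
            if rss_per_k[k] > (1.0 - self.min_improvement) * rss_per_k[chosen]:
                break
            bks = [0] + breaks_per_k[k] + [n]
            levels = [traj[a:b].mean() for a, b in zip(bks[:-1], bks[1:])]
            sizes = np.diff(levels)
            if np.any(np.abs(sizes) < self.min_step):
                break
            if not self._steps_significant(traj, s, q, bks):
                break
            chosen = k

        bks = [0] + breaks_per_k[chosen] + [n]
        levels = [float(traj[a:b].mean()) for a, b in zip(bks[:-1], bks[1:])]
        self.plateaus_ = [
            (a, b, lev) for a, b, lev in zip(bks[:-1], bks[1:], levels)
        ]
        self.steps_ = [
            (bks[i + 1], levels[i + 1] - levels[i],
             1 if levels[i + 1] > levels[i] else -1)
            for i in range(chosen)
        ]
        self.rss_ = rss_per_k[chosen]
        self.n_steps_ = chosen
        self.n_lines_ = n
        return self

    def fit_predict(self, trajectory, y=None) -> StepFit:
        self.fit(trajectory)
        return StepFit(
            plateaus=self.plateaus_,
            steps=self.steps_,
            fit_quality=self.rss_,
            n_lines=self.n_lines_,
        )


def detect_steps(trajectory, min_step: float = 5.0, max_steps: int = 20) -> StepFit:
    """Decompose an intensity trajectory into plateaus and steps."""
    return StepFinder(min_step=min_step, max_steps=max_steps).fit_predict(trajectory)


# --------------------------------------------------------------------------
# unitary-intensity calibration
# --------------------------------------------------------------------------

def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def unitary_intensity(stepfits, bin_width: float = 3.0) -> UnitaryIntensity:
    """Calibrate the single-fluorophore intensity from photobleaching steps.

    The smallest-magnitude downward step of each trajectory is taken as a
    single photobleaching event; the step magnitudes are histogrammed with
    bins of ``bin_width`` photons anchored at zero and fitted to a Gaussian.
    When the histogram is too narrow to constrain a Gaussian (fewer than
    three occupied bins) the sample mean and standard deviation of the
    candidate steps are reported instead (``method='sample'``).
    """
    candidates = []
    for sf in stepfits:
        down = sf.downward_steps()
        if down.size:
            candidates.append(float(down.min()))
    candidates = np.asarray(candidates)
    if candidates.size < 10:
        raise ValueError(
            f"need >= 10 single-step candidates, got {candidates.size}"
        )
    edges = np.arange(0.0, candidates.max() + 2 * bin_width, bin_width)
    hist, edges = np.histogram(candidates, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = int(np.count_nonzero(hist))

    if occupied >= 3:
        mu0 = float(np.average(centers, weights=hist))
        sd0 = float(
            np.sqrt(max(np.average((centers - mu0) ** 2, weights=hist), (bin_width / 2) ** 2))
        )
        try:
            popt, _ = curve_fit(
                _gauss, centers, hist,
                p0=[float(hist.max()), mu0, sd0],
                bounds=([0.0, 0.0, bin_width / 10], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
            return UnitaryIntensity(
                mean=float(popt[1]), sd=float(popt[2]),
                n_steps=int(candidates.size),
                histogram_bin_width=bin_width, method="gaussian",
            )
        except RuntimeError:
            pass
    return UnitaryIntensity(
        mean=float(candidates.mean()), sd=float(candidates.std(ddof=0)),
        n_steps=int(candidates.size),
        histogram_bin_width=bin_width, method="sample",
    )


# --------------------------------------------------------------------------
# intensity decay rate
# --------------------------------------------------------------------------

def decay_rate(trajectory, line_period_s: float) -> DecayFit:
    """Fit I(t) = I0 exp(-k t) + c to an intensity trajectory.

    Returns the per-second decay rate with its standard error; a
    non-converging fit is returned with ``success=False`` rather than raised.
    """
    traj = np.asarray(trajectory, dtype=float).ravel()
    if traj.size < 10:
        raise ValueError(f"trajectory too short for decay fit ({traj.size} < 10 lines)")
    t = np.arange(traj.size) * line_period_s
    c0 = float(traj[-max(traj.size // 10, 1):].mean())
    a0 = max(float(traj[: max(traj.size // 10, 1)].mean()) - c0, 1e-6)
    # crude rate guess from the time the excess halves
    above = np.flatnonzero(traj - c0 < a0 / 2)
    k0 = np.log(2.0) / (t[above[0]] + line_period_s) if above.size else 0.1
    try:
        popt, pcov = curve_fit(
            lambda tt, a, k, c: a * np.exp(-k * tt) + c,
            t, traj, p0=[a0, k0, c0],
            bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return DecayFit(np.nan, np.nan, np.nan, np.nan, np.nan, success=False)
    a, k, c = popt
    resid = traj - (a * np.exp(-k * t) + c)
    stderr = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.nan
    return DecayFit(
        k=float(k), k_stderr=stderr, amplitude=float(a), offset=float(c),
        rss=float(np.sum(resid**2)), success=bool(np.isfinite(k)),
    )
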