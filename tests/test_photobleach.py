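"""Step detection, unitary-intensity calibration, decay fitting."""

import itertools

import numpy as np
import pytest

from kymoquant.config import SimulationConfig
from kymoquant.photobleach import (
    StepFinder,
    StepFit,
    decay_rate,
    detect_steps,
    unitary_intensity,
)
from kymoquant.simulate import simulate_photobleach_trace


def staircase(levels, lengths):
    return np.concatenate([np.full(n, lv, dtype=float) for lv, n in zip(levels, lengths)])


def brute_force_rss(y, k):
    """Exhaustive minimum RSS over all placements of k change points."""
    n = y.size
    s = np.concatenate(([0.0], np.cumsum(y)))
    q = np.concatenate(([0.0], np.cumsum(y * y)))

    def seg(i, j):
        return (q[j] - q[i]) - (s[j] - s[i]) ** 2 / (j - i)

    best = np.inf
    best_bks = None
    for bks in itertools.combinations(range(1, n), k):
        edges = (0,) + bks + (n,)
        rss = sum(seg(a, b) for a, b in zip(edges[:-1], edges[1:]))
        if rss < best - 1e-12:
            best, best_bks = rss, bks
    return best, best_bks


class TestDetectSteps:
    def test_noiseless_staircase_recovered_exactly(self):
        y = staircase([33, 22, 11, 0], [10, 10, 10, 10])
        fit = detect_steps(y)
        assert [(line, size) for line, size, _ in fit.steps] == [
            (10, -11.0), (20, -11.0), (30, -11.0),
        ]
        assert fit.fit_quality == pytest.approx(0.0, abs=1e-9)

    def test_flat_trajectory_has_no_steps(self):
        assert detect_steps(np.full(20, 7.0)).n_steps == 0

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            detect_steps([1.0, 2.0, 3.0])

    def test_upward_steps_detected_with_positive_sign(self):
        y = staircase([0, 11, 22], [15, 15, 15])
        fit = detect_steps(y)
        assert all(sign == 1 for _, _, sign in fit.steps)
        assert fit.downward_steps().size == 0

    def test_idempotent_on_own_reconstruction(self):
        rng = np.random.default_rng(0)
        y = staircase([33, 22, 11, 0], [20, 25, 15, 20]) + rng.normal(0, 2, 80)
        first = detect_steps(y)
        second = detect_steps(first.reconstruction())
        assert [(a, b) for a, b, _ in second.plateaus] == [
            (a, b) for a, b, _ in first.plateaus
        ]
        assert [lv for _, _, lv in second.plateaus] == pytest.approx(
            [lv for _, _, lv in first.plateaus]
        )

    def test_matches_exhaustive_enumeration(self):
        """On short trajectories the DP fit equals brute-force optimal placement."""
        rng = np.random.default_rng(7)
        for _ in range(8):
            n_steps = rng.integers(1, 4)
            lengths = rng.integers(4, 9, size=n_steps + 1)
            levels = 11.0 * np.arange(n_steps, -1, -1)
            y = rng.poisson(np.repeat(levels, lengths)).astype(float)
            if y.size > 30:
                continue
            fit = detect_steps(y, min_step=4.0)
            if fit.n_steps == 0:
                continue
            rss_opt, bks_opt = brute_force_rss(y, fit.n_steps)
            assert fit.fit_quality == pytest.approx(rss_opt, abs=1e-9)
            assert tuple(line for line, _, _ in fit.steps) == bks_opt

    def test_three_fluorophore_step_count_monte_carlo(self):
        """>=80% of simulated 3-fluorophore staircases yield exactly 3 steps."""
        cfg = SimulationConfig(background_rate=0.0)
        rng = np.random.default_rng(3)
        hits = 0
        n_runs = 40
        for _ in range(n_runs):
            traj, steps = simulate_photobleach_trace(3, cfg, rng=rng)
            hits += detect_steps(traj).n_steps == len(steps)
        assert hits / n_runs >= 0.80

    def test_stepfinder_estimator_interface(self):
        finder = StepFinder(min_step=4.0)
        finder.fit(staircase([11, 0], [10, 10]))
        assert finder.n_steps_ == 1
        assert finder.get_params()["min_step"] == 4.0


class TestUnitaryIntensity:
    @staticmethod
    def _stepfits_from_sizes(sizes):
        return [
            StepFit(plateaus=[], steps=[(5, -float(s), -1)], fit_quality=0.0, n_lines=10)
            for s in sizes
        ]

    def test_gaussian_fit_recovers_center(self):
        rng = np.random.default_rng(1)
        sizes = rng.normal(11, 3, size=48).clip(2)
        unit = unitary_intensity(self._stepfits_from_sizes(sizes))
        assert unit.method == "gaussian"
        assert unit.mean == pytest.approx(11.0, abs=1.5)

    def test_recovers_other_ground_truth(self):
        rng = np.random.default_rng(2)
        sizes = rng.normal(20, 4, size=60).clip(2)
        unit = unitary_intensity(self._stepfits_from_sizes(sizes))
        assert unit.mean == pytest.approx(20.0, abs=2.0)

    def test_identical_steps_give_zero_spread(self):
        unit = unitary_intensity(self._stepfits_from_sizes([11.0] * 20))
        assert unit.mean == 11.0
        assert unit.sd == 0.0

    def test_scale_covariance(self):
        rng = np.random.default_rng(3)
        sizes = rng.normal(11, 3, size=60).clip(2)
        u1 = unitary_intensity(self._stepfits_from_sizes(sizes))
        u2 = unitary_intensity(self._stepfits_from_sizes(2 * sizes))
        assert u2.mean == pytest.approx(2 * u1.mean, rel=0.10)

    def test_insufficient_candidates_rejected(self):
        with pytest.raises(ValueError):
            unitary_intensity(self._stepfits_from_sizes([11.0] * 5))

    def test_full_detection_calibration(self):
        """Detection on simulated single-fluorophore staircases recovers ~11."""
        cfg = SimulationConfig(background_rate=0.0)
        rng = np.random.default_rng(4)
        fits = []
        while len(fits) < 20:
            traj, _ = simulate_photobleach_trace(1, cfg, rng=rng)
            sf = detect_steps(traj)
            if sf.downward_steps().size:
                fits.append(sf)
        unit = unitary_intensity(fits)
        assert unit.mean == pytest.approx(11.0, abs=2.0)


class TestDecayRate:
    def test_exact_exponential_recovered(self):
        t = np.arange(0, 10, 0.01)
        fit = decay_rate(100 * np.exp(-0.43 * t), line_period_s=0.01)
        assert fit.success
        assert fit.k == pytest.approx(0.43, rel=1e-4)

    def test_constant_trajectory_gives_zero_rate(self):
        fit = decay_rate(np.full(100, 50.0), line_period_s=0.01)
        assert abs(fit.k * fit.amplitude) < 1.0  # no decaying component

    def test_simulated_cluster_rates_centre_on_bleach_rate(self):
        """Per-cluster decay fits centre on the 0.43/s generator, within the
        0.2-0.5/s range observed across clusters.

        A single 20-fluorophore staircase realization carries ~25% intrinsic
        spread in its fitted rate (discrete stochastic bleaching), so the
        population median, not every individual fit, must land in the range.
        """
        cfg = SimulationConfig(background_rate=0.0)
        rng = np.random.default_rng(5)
        ks = []
        for _ in range(25):
            traj, _ = simulate_photobleach_trace(20, cfg, duration_s=10.0, rng=rng)
            fit = decay_rate(traj, cfg.line_period_s)
            assert fit.success
            ks.append(fit.k)
        assert 0.2 <= np.median(ks) <= 0.5
        assert np.mean(ks) == pytest.approx(cfg.bleach_rate, abs=0.08)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            decay_rate(np.arange(5.0), 0.01)
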