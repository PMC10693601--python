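"""Ground-truth generator: distributions, bookkeeping, determinism."""

import numpy as np
import pytest
from scipy import stats

from kymoquant.config import SimulationConfig
from kymoquant.photobleach import decay_rate
from kymoquant.simulate import (
    simulate_dwell_times,
    simulate_kymograph,
    simulate_photobleach_trace,
)


class TestDwellTimes:
    def test_mean_matches_rate(self):
        means = [
            simulate_dwell_times(0.29, 314, seed=s).mean() for s in range(25)
        ]
        assert np.mean(means) == pytest.approx(1 / 0.29, rel=0.02)

    def test_empirical_cdf_is_exponential(self):
        d = simulate_dwell_times(1.0, 100_000, seed=1)
        ks = stats.kstest(d, "expon").statistic
        assert ks < 0.01

    @pytest.mark.parametrize("k_off, n", [(0.0, 10), (-1.0, 10), (0.29, 0)])
    def test_invalid_inputs_rejected(self, k_off, n):
        with pytest.raises(ValueError):
            simulate_dwell_times(k_off, n)

    def test_reproducible(self):
        assert np.array_equal(
            simulate_dwell_times(0.29, 50, seed=7),
            simulate_dwell_times(0.29, 50, seed=7),
        )


class TestPhotobleachTrace:
    def test_single_fluorophore_level(self):
        """Pre-bleach intensity of one fluorophore averages ~11 counts."""
        cfg = SimulationConfig(background_rate=0.0)
        levels = []
        rng = np.random.default_rng(11)
        for _ in range(50):
            traj, steps = simulate_photobleach_trace(1, cfg, rng=rng)
            n_pre = max(int(steps[0] / cfg.line_period_s) - 1, 1) if steps.size else len(traj)
            levels.append(traj[:n_pre].mean())
        assert np.mean(levels) == pytest.approx(11.0, abs=0.5)

    def test_no_bleaching_is_flat(self):
        cfg = SimulationConfig(bleach_rate=0.0, background_rate=0.0)
        traj, steps = simulate_photobleach_trace(3, cfg, duration_s=5.0, rng=np.random.default_rng(2))
        assert steps.size == 0
        assert traj.mean() == pytest.approx(33.0, rel=0.05)

    def test_cluster_decay_rate_in_reported_range(self):
        """Ensemble decay of a 10-fluorophore cluster ~ bleach_rate 0.43/s."""
        cfg = SimulationConfig(background_rate=0.0)
        rng = np.random.default_rng(3)
        n_lines = 1000
        acc = np.zeros(n_lines)
        for _ in range(40):
            traj, _ = simulate_photobleach_trace(10, cfg, duration_s=10.0, rng=rng)
            acc += traj[:n_lines]
        fit = decay_rate(acc / 40, cfg.line_period_s)
        assert fit.success
        assert 0.2 <= fit.k <= 0.5

    def test_rejects_zero_fluorophores(self):
        with pytest.raises(ValueError):
            simulate_photobleach_trace(0, SimulationConfig())


class TestKymograph:
    def test_no_arrivals_gives_background_only(self):
        cfg = SimulationConfig(
            arrival_rate=0.0, dna_length_bp=10_000, duration_s=10.0, seed=0
        )
        kymo, truth = simulate_kymograph(cfg)
        assert truth.n_events == 0
        assert kymo.counts.mean() == pytest.approx(cfg.background_rate, rel=0.2)

    def test_event_count_poisson(self):
        cfg = SimulationConfig(
            dna_length_bp=10_000, duration_s=600.0, arrival_rate=0.033,
            bleach_rate=30.0, seed=12,
        )
        _, truth = simulate_kymograph(cfg)
        lam = cfg.arrival_rate * cfg.duration_s  # ~19.8
        assert abs(truth.n_events - lam) < 4 * np.sqrt(lam)

    def test_bit_for_bit_determinism(self):
        cfg = SimulationConfig(dna_length_bp=10_000, duration_s=30.0, arrival_rate=0.3, seed=42)
        k1, t1 = simulate_kymograph(cfg)
        k2, t2 = simulate_kymograph(cfg)
        assert np.array_equal(k1.counts, k2.counts)
        assert [e.bind_time_s for e in t1.events] == [e.bind_time_s for e in t2.events]

    def test_permanent_clusters_never_unbind(self):
        cfg = SimulationConfig(
            dna_length_bp=10_000, duration_s=120.0, arrival_rate=0.5,
            primary_growth_rate=0.5, secondary_growth_rate=0.5,
            bleach_rate=30.0, seed=3,
        )
        _, truth = simulate_kymograph(cfg)
        big = [e for e in truth.events if e.max_size >= cfg.permanence_threshold]
        assert big, "expected some permanent clusters at these growth rates"
        assert all(e.unbind_time_s is None for e in big)

    def test_photon_conservation_without_censoring(self):
        """Image sum equals the ground-truth emitted-photon bookkeeping."""
        cfg = SimulationConfig(
            dna_length_bp=10_000, duration_s=60.0, arrival_rate=0.3,
            background_rate=0.0, dead_time_ns=0.0, seed=8,
        )
        kymo, truth = simulate_kymograph(cfg)
        assert kymo.counts.sum() == truth.total_emitted_photons()

    def test_monomer_dwells_are_exponential(self):
        """Ground-truth dwells of detaching monomers pass a KS test vs Exp(k_off)."""
        cfg = SimulationConfig(
            dna_length_bp=5_000, duration_s=200.0, arrival_rate=50.0,
            primary_growth_rate=0.0, secondary_growth_rate=0.0,
            bleach_rate=50.0,  # photophysics irrelevant to binding kinetics
            seed=21,
        )
        _, truth = simulate_kymograph(cfg)
        dwells = truth.monomer_dwells()
        assert dwells.size > 8_000
        p = stats.kstest(dwells, "expon", args=(0, 1 / cfg.k_off_monomer)).pvalue
        assert p > 0.01

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(labeling_efficiency=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(duration_s=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(k_off_monomer=-0.1)
        with pytest.raises(ValueError):
            # 485 pixels * 50 us > 10 ms line period
            SimulationConfig(dna_length_bp=48_502 * 3, line_period_s=0.010)
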