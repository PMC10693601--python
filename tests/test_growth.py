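"""Growth rates, nucleation-direction classification, diffusion verdicts."""

import numpy as np
import pytest

from kymoquant.config import SimulationConfig
from kymoquant.growth import (
    classify_direction,
    classify_mechanism,
    diffusion_stats,
    growth_from_frames,
    growth_rate,
)
from kymoquant.simulate import simulate_growth_frames, simulate_tracked_trace


class TestGrowthRate:
    def test_reported_maximum_rate(self):
        """11 -> 35 molecules in 0.85 s is 28 molecules/s (rounded)."""
        rec = growth_rate([0.0, 0.85], [11.0, 35.0])
        assert round(rec.rate_molecules_per_s) == 28

    def test_constant_counts_zero_rate(self):
        rec = growth_rate([0, 1, 2], [50.0, 50.0, 50.0])
        assert rec.rate_molecules_per_s == 0.0

    def test_photon_molecule_rate_consistency(self, unit11):
        """photons/s = unit.mean x molecules/s at unit labeling efficiency."""
        rec = growth_rate([0.0, 2.0], [110.0, 330.0], unit=unit11, labeling_efficiency=1.0)
        assert rec.rate_photons_per_s == pytest.approx(
            unit11.mean * rec.rate_molecules_per_s
        )

    def test_single_time_point_rejected(self):
        with pytest.raises(ValueError):
            growth_rate([1.0], [10.0])

    def test_recovery_from_simulated_frames(self, unit11):
        """Generator growth of 10 molecules/s recovered within +-20%."""
        cfg = SimulationConfig(bleach_rate=0.0)
        rates = []
        for seed in range(8):
            frames, times, truth = simulate_growth_frames(
                cfg, "primary", n_start=5, n_end=25, n_frames=9,
                frame_period_s=0.25, rng=np.random.default_rng(seed),
            )
            rec = growth_from_frames(frames, times, unit11, cfg.labeling_efficiency)
            rates.append(rec.rate_molecules_per_s / truth["rate_molecules_per_s"])
        assert np.median(rates) == pytest.approx(1.0, abs=0.2)


class TestDirectionClassification:
    CFG = SimulationConfig(bleach_rate=0.0)

    @pytest.mark.parametrize("direction, want", [(+1, "right"), (-1, "left")])
    def test_primary_growth_labeled_along_dna(self, direction, want):
        hits = 0
        for seed in range(10):
            frames, _, _ = simulate_growth_frames(
                self.CFG, "primary", direction=direction,
                rng=np.random.default_rng(seed),
            )
            hits += classify_direction(frames)["label"] == want
        assert hits >= 8

    def test_secondary_growth_labeled_perpendicular(self):
        hits = 0
        for seed in range(10):
            frames, _, _ = simulate_growth_frames(
                self.CFG, "secondary", rng=np.random.default_rng(seed)
            )
            hits += classify_direction(frames)["label"] == "perpendicular"
        assert hits >= 7

    def test_photobleaching_only_is_none(self):
        cfg = SimulationConfig(bleach_rate=0.43)
        for seed in range(5):
            frames, _, _ = simulate_growth_frames(
                cfg, "none", n_start=20, rng=np.random.default_rng(seed)
            )
            assert classify_direction(frames)["label"] == "none"

    def test_mirror_symmetry_swaps_left_right(self):
        frames, _, _ = simulate_growth_frames(
            self.CFG, "primary", direction=+1, rng=np.random.default_rng(1)
        )
        res = classify_direction(frames)
        mirrored = classify_direction(frames[:, :, ::-1])
        assert res["label"] == "right"
        assert mirrored["label"] == "left"
        assert mirrored["centroid_shift_px"] == pytest.approx(
            -res["centroid_shift_px"], abs=0.2
        )

    def test_mechanism_discrimination_accuracy(self):
        """Primary vs secondary called correctly in >=90% of simulations."""
        correct = 0
        n_each = 50
        for mech in ("primary", "secondary"):
            for seed in range(n_each):
                frames, _, _ = simulate_growth_frames(
                    self.CFG, mech, direction=1 if seed % 2 else -1,
                    rng=np.random.default_rng(seed),
                )
                correct += classify_mechanism(frames) == mech
        assert correct / (2 * n_each) >= 0.90

    def test_roi_outside_frame_rejected(self):
        frames, _, _ = simulate_growth_frames(
            self.CFG, "primary", rng=np.random.default_rng(0)
        )
        with pytest.raises(ValueError):
            classify_direction(frames, roi=(0, 0, 100, 100))


class TestDiffusion:
    def test_static_trace_called_static(self):
        tr = simulate_tracked_trace(100, 0.0, rng=np.random.default_rng(0))
        assert diffusion_stats(tr).verdict == "static"

    def test_diffusive_trace_detected_with_correct_coefficient(self):
        """D = 0.1 um^2/s traces are called diffusive, D within a factor 2."""
        ds = []
        for seed in range(10):
            tr = simulate_tracked_trace(200, 0.1, rng=np.random.default_rng(seed))
            st = diffusion_stats(tr)
            assert st.verdict == "diffusive"
            ds.append(st.diffusion_um2_s)
        assert 0.05 <= np.median(ds) <= 0.2

    def test_alternating_jitter_is_static(self):
        """+-0.4 px alternating localization jitter stays below the noise floor."""
        from kymoquant.tracking import Trace

        n = 60
        pos = 30.0 + 0.4 * (-1.0) ** np.arange(n)
        tr = Trace(
            trace_id=0, lines=np.arange(n), positions_px=pos,
            counts=np.full(n, 11.0), line_period_s=0.01, pixel_size_nm=100.0,
        )
        assert diffusion_stats(tr).verdict == "static"

    def test_classification_power(self):
        """>=90% accuracy for D = 0 vs D = 0.1 um^2/s on 100 traces each."""
        correct = 0
        for i, d_true in enumerate([0.0] * 100 + [0.1] * 100):
            tr = simulate_tracked_trace(100, d_true, rng=np.random.default_rng(i))
            verdict = diffusion_stats(tr).verdict
            correct += verdict == ("static" if d_true == 0 else "diffusive")
        assert correct / 200 >= 0.90

    def test_short_trace_rejected(self):
        tr = simulate_tracked_trace(8, 0.0, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            diffusion_stats(tr)

    def test_msd_uses_at_least_ten_lags(self):
        tr = simulate_tracked_trace(50, 0.0, rng=np.random.default_rng(1))
        st = diffusion_stats(tr)
        assert st.lags_s.size >= 10
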