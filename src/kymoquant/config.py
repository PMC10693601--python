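"""Generative parameters and ground-truth bookkeeping for the simulator.

``SimulationConfig`` collects every knob of the synthetic-data generator in
the units the instrument uses (nm, seconds, photons per line sample).  The
defaults reproduce the experimental regime of the optical-tweezers confocal
assay the package targets: lambda-phage dsDNA (48,502 bp, 0.34 nm/bp),
100 nm pixels scanned at 50 us/pixel, one line every 10 ms, ~11 photons per
fluorophore per line sample, 90% labeling efficiency, a 35 ns detector dead
time, per-fluorophore photobleaching at 0.43 /s, monomer dissociation at
0.29 /s, and permanent attachment of clusters of three or more protomers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np

BP_TO_NM = 0.34  # dsDNA rise per base pair

__all__ = ["SimulationConfig", "BindingEvent", "GroundTruth", "BP_TO_NM"]


@dataclass
class SimulationConfig:
    # kinetics
    k_off_monomer: float = 0.29      # /s, dissociation of monomers (and dimers)
    arrival_rate: float = 0.033      # binding events /s over the whole DNA
    concentration: float = 1e-9      # molar, bookkeeping for k_on analysis
    primary_growth_rate: float = 0.05    # /cluster/s, along-DNA incorporation
    secondary_growth_rate: float = 0.02  # /cluster/s, growth atop the cluster
    permanence_threshold: int = 3    # clusters >= this size never detach
    # geometry / scanning
    dna_length_bp: int = 48_502
    pixel_size_nm: float = 100.0
    pixel_dwell_us: float = 50.0
    line_period_s: float = 0.010
    duration_s: float = 600.0
    psf_fwhm_nm: float = 350.0
    growth_step_nm: float = 15.0     # spatial displacement per added protomer
    # photophysics
    unit_intensity: float = 11.0     # mean photons / fluorophore / line sample
    bleach_rate: float = 0.43        # /fluorophore/s
    labeling_efficiency: float = 0.90
    background_rate: float = 0.05    # mean background photons / pixel / line
    dead_time_ns: float = 35.0
    # red-channel emulation (empirical rule; off by default)
    simulate_red: bool = False
    red_mean_counts: float = 14.0    # red photons for clusters > 100 blue counts
    # fluorophore blinking is not modeled (no rate is known); stub only
    blink_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "k_off_monomer": self.k_off_monomer,
            "arrival_rate": self.arrival_rate,
            "primary_growth_rate": self.primary_growth_rate,
            "secondary_growth_rate": self.secondary_growth_rate,
            "bleach_rate": self.bleach_rate,
            "background_rate": self.background_rate,
            "blink_rate": self.blink_rate,
            "dead_time_ns": self.dead_time_ns,
            "unit_intensity": self.unit_intensity,
        }
        for name, value in rates.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if not (0.0 < self.labeling_efficiency <= 1.0):
            raise ValueError(
                f"labeling_efficiency must be in (0, 1], got {self.labeling_efficiency}"
            )
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.pixel_size_nm <= 0 or self.pixel_dwell_us <= 0 or self.line_period_s <= 0:
            raise ValueError("pixel size, pixel dwell and line period must be > 0")
        if self.permanence_threshold < 1:
            raise ValueError("permanence_threshold must be >= 1")
        if self.pixel_dwell_us * 1e-6 * self.n_pixels > self.line_period_s:
            raise ValueError(
                "pixel_dwell_us x pixels-per-line exceeds line_period_s: "
                "the scan cannot cover the DNA within one line period"
            )

    # ---- derived quantities -------------------------------------------------
    @property
    def dna_length_nm(self) -> float:
        return self.dna_length_bp * BP_TO_NM

    @property
    def n_pixels(self) -> int:
        """Pixels per scan line; pixel i covers [i*px, (i+1)*px) nm, half-open."""
        return int(np.ceil(self.dna_length_nm / self.pixel_size_nm))

    @property
    def n_lines(self) -> int:
        return int(round(self.duration_s / self.line_period_s))

    @property
    def psf_sigma_nm(self) -> float:
        return self.psf_fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    @property
    def dead_time_s(self) -> float:
        return self.dead_time_ns * 1e-9

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kwargs) -> "SimulationConfig":
        """Copy with fields replaced (validation re-runs)."""
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class BindingEvent:
    """One ground-truth binding event (a cluster's life on the DNA)."""

    event_id: int
    bind_time_s: float
    unbind_time_s: Optional[float]   # None for permanent / right-open events
    position_nm: float               # position at binding
    cluster_id: int
    # (time_s, n_protomers) after each arrival; protomer count includes
    # unlabeled molecules
    size_trajectory: list = field(default_factory=list)
    # per-fluorophore records: (attach_time_s, bleach_time_s, position_nm)
    fluorophores: list = field(default_factory=list)
    emitted_photons: int = 0         # realized photons, pre-censoring

    @property
    def max_size(self) -> int:
        return max((s for _, s in self.size_trajectory), default=1)

    def dwell_time(self, horizon_s: float) -> float:
        end = self.unbind_time_s if self.unbind_time_s is not None else horizon_s
        return end - self.bind_time_s


@dataclass
class GroundTruth:
    """Everything the generator knows, for recovery tests."""

    events: list                     # list[BindingEvent]
    config: SimulationConfig

    def __post_init__(self) -> None:
        L = self.config.dna_length_nm
        for ev in self.events:
            if ev.unbind_time_s is not None and ev.unbind_time_s <= ev.bind_time_s:
                raise ValueError(f"event {ev.event_id}: unbind <= bind time")
            if not (0.0 <= ev.position_nm <= L):
                raise ValueError(f"event {ev.event_id}: position outside the DNA")
            if (
                ev.max_size >= self.config.permanence_threshold
                and ev.unbind_time_s is not None
            ):
                raise ValueError(
                    f"event {ev.event_id}: permanent cluster carries an unbind time"
                )

    @property
    def n_events(self) -> int:
        return len(self.events)

    def monomer_dwells(self) -> np.ndarray:
        """Dwell times of events that detached while still monomeric."""
        return np.array(
            [
                ev.unbind_time_s - ev.bind_time_s
                for ev in self.events
                if ev.unbind_time_s is not None and ev.max_size == 1
            ]
        )

    def total_emitted_photons(self) -> int:
        return int(sum(ev.emitted_photons for ev in self.events))
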