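# kymoquant

Quantitative single-molecule analysis of protein–DNA assembly from
correlative optical-tweezers / confocal-fluorescence experiments.

The motivating system is the inflammasome DNA sensor AIM2: labeled protein
binds a single dsDNA molecule (λ-phage, 48,502 bp ≈ 16.5 µm) stretched
between two optically trapped beads, and repeated confocal line scans along
the tether build a *kymograph* (position × time photon-count matrix) in
which each binding event is a horizontal trace.  From such data — or from
the package's own ground-truth simulator — `kymoquant` extracts:

- **Stoichiometry.**  Photon counts → fluorophore → molecule numbers, with
  detector dead-time correction `n = m / (1 − mτ)` (τ = 35 ns APD dead
  time), single-fluorophore calibration from photobleaching steps
  (~11 photons per fluorophore per line), an empirical red-emission
  correction (14 red photons ≈ 1 fluorophore for clusters in the 100–575
  blue-count window), labeling-efficiency division (≈0.90), and the
  propagated size error ΔS = 0.17·S.
- **Kinetics.**  Residence (dwell) times of tracked traces, histogrammed at
  1 s bins with the first bin dropped and fitted to
  `y = A·exp(−k_off·t) + y₀`; association rates from per-kymograph unbound
  times via `k_on = 1/([C]·t_on)`; and `K_D = k_off / k_on`.
- **Geometry & growth.**  Gaussian profile fits (FWHM → circular area →
  apparent diameter), dsDNA rulers (0.34 nm/bp, ~10 bp protomer footprint),
  growth rates in molecules/s from time-stamped frames, classification of
  growth direction (along-DNA *primary* vs perpendicular *secondary*
  nucleation), and MSD-based static/diffusive verdicts for traces.
- **Simulation.**  A stochastic generator of kymographs, 2D scans,
  photobleaching staircases and dwell-time sets whose ground truth (every
  binding event, every fluorophore, every emitted photon) is recorded, so
  each analysis stage is testable without instrument data.

Fit-shaped components (`KymographTracker`, `StepFinder`,
`ExponentialDwellFitter`, `GaussianProfiler`, `DiffusionClassifier`) are
scikit-learn-style estimators; every operation is also available as a plain
function.

## Worked example

```python
import kymoquant as kq

# 1) dead-time correction of a measured photon rate
model = kq.DeadTimeModel(tau=35e-9)
print("true rate:", round(kq.true_rate(220e3, model)), "photons/s")
print("underestimation:", f"{kq.underestimation_fraction(220e3, model):.1%}")

# 2) simulate a kymograph and recover the dissociation rate
cfg = kq.SimulationConfig(dna_length_bp=20_000, duration_s=300.0,
                          arrival_rate=0.5, primary_growth_rate=0.0,
                          secondary_growth_rate=0.0, seed=7)
kymo, truth = kq.simulate_kymograph(cfg)
traces = kq.track_traces(kymo)
print(f"{truth.n_events} binding events simulated, {len(traces)} traces tracked")

dwells = kq.eligible_dwells(traces)          # censored traces excluded
fit = kq.fit_koff_from_dwells(dwells, bin_width_s=1.0, drop_first=True)
print(f"k_off = {fit.k_off:.2f} +/- {fit.k_off_stderr:.2f} /s  (R^2 = {fit.r_squared:.2f})")

# 3) molecule count of a cluster from its photon counts
unit = kq.UnitaryIntensity(mean=11.0, sd=4.0, n_steps=48)
m = kq.count_molecules(raw_counts=110, background=0, red_counts=14,
                       unit=unit, labeling_efficiency=0.9, deadtime=model)
print(f"cluster: {m.n_molecules:.1f} +/- {m.size_error:.1f} molecules")

# 4) equilibrium constant from the fitted rates
print(f"K_D = {kq.dissociation_constant(0.29, 1.81e6)*1e9:.0f} nM")
```

prints

```
true rate: 221707 photons/s
underestimation: 0.8%
154 binding events simulated, 148 traces tracked
k_off = 0.76 +/- 0.09 /s  (R^2 = 0.99)
cluster: 13.1 +/- 2.2 molecules
K_D = 160 nM
```

Reading the numbers: a detector measuring 220,000 photons/s (11 photons per
50 µs pixel dwell, one fluorophore) actually received 221,707 photons/s —
an 0.8% undercount.  The tracked-trace `k_off` of 0.76 /s is the *apparent*
off-rate: a trace ends when the molecule unbinds **or** its fluorophore
bleaches, so it approximates `k_off + k_bleach` (0.29 + 0.43 under this
configuration); fitting the simulator's ground-truth dwell times instead
gives 0.33 ± 0.06 /s.  The same photobleaching limitation applies to the
real experiment.  The 110-blue/14-red-photon cluster corresponds to
(110/11 + 14/14)/0.9 ≈ 13.1 molecules with a 17% propagated size error, and
the rate pair (0.29 /s, 1.81×10⁶ /M/s) gives K_D ≈ 160 nM.

A CLI mirrors the stages (`kymoquant simulate kymo`, `track`, `steps`,
`stoich`, `geometry`, `kinetics`, `growth`, `diffuse`, `deadtime`,
`report`); see `kymoquant --help`.

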