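# Methods

This note documents the models implemented in `kymoquant`, the defaults and
why they hold, the numerical choices inside each estimator, and what the
synthetic-data generator does and does not emulate.

## Physical setting and units

A single λ-phage dsDNA (48,502 bp; 0.34 nm/bp ≈ 16.5 µm) is held between two
optically trapped beads and scanned by a confocal line (100 nm pixels,
50 µs/pixel, one line every 10 ms).  Fluorophore-labeled protein binds the
DNA; kymographs record photon counts per (position pixel, scan line).  All
times are seconds, positions nanometres, pixel indices 0-based with pixel
*i* covering `[i·100, (i+1)·100)` nm (half-open), concentrations molar
internally.

## Detector dead time

The photon counter is modelled as ideal and non-paralyzable: after each
detected photon it is blind for τ = 35 ns, and events arriving during the
dead time have no further effect.  A measured rate *m* then relates to the
true rate *n* by `n = m/(1 − mτ)`; the lost fraction is exactly `mτ`.
Counts are converted to rates over the pixel dwell (50 µs), so 11 counts per
dwell ≡ 220×10³ photons/s with an 0.8% undercount; a 10-fluorophore cluster
(2.2×10⁶ photons/s) loses 7.7%, about one fluorophore-equivalent.  The
analysis applies the forward correction per pixel-dwell window; the
simulator applies the algebraic inverse `m = n/(1 + nτ)` as expected-count
thinning (realized as binomial thinning of the drawn counts so images stay
integer-valued).  The forward/inverse pair round-trips to better than 12
significant digits.  Saturation (`mτ ≥ 1`) raises an error rather than
extrapolating.  No afterpulsing, paralyzable behaviour, or wavelength-
dependent detection efficiency is modelled.

## Synthetic-data generator

The generator is the package's ground truth and is treated as first-class,
tested code.  One `numpy.random.Generator` drives everything; a fixed seed
fixes every output bit-for-bit.

**Binding and cluster kinetics.**  Binding events arrive on the DNA as a
Poisson process (`arrival_rate`, default 0.033 /s ≈ 20 events per 600 s
kymograph, matching typical observed trace counts) at uniform positions.
Each cluster then evolves by a Gillespie scheme with three channels:
whole-cluster detachment at `k_off_monomer` (default 0.29 /s) while the
cluster is below `permanence_threshold` (default 3; dimers detach at the
monomer rate for lack of a separate measured rate — overridable), and
protomer gain through two independent Poisson channels, `primary_growth_rate`
(default 0.05 /s, along-DNA) and `secondary_growth_rate` (default 0.02 /s,
atop the cluster).  Clusters reaching the threshold never detach.  Growth
defaults keep most events monomeric, as observed, while letting clusters
nucleate occasionally.

**Growth geometry.**  The data constrain growth rates but not a spatial law,
so each primary protomer extends the cluster by `growth_step_nm` (default
15 nm) along the DNA in a per-cluster random polarity, and each secondary
protomer stacks at the nucleation position (perpendicular growth in 2D
frames).  15 nm/molecule is consistent with observed apparent diameters of
250–440 nm for clusters of a few tens of molecules.

**Photophysics.**  Each protomer is labeled with probability
`labeling_efficiency` (0.90).  A labeled fluorophore emits
Poisson(`unit_intensity` = 11) photons per line sample from attachment until
its exponential bleach time (`bleach_rate` = 0.43 /s per fluorophore),
prorated over the partial line in which it bleaches.  Emission is spread
over pixels by integrating a Gaussian PSF (FWHM 350 nm) over each pixel,
truncated at 4σ.  Background is Poisson per pixel per line
(`background_rate` = 0.05, i.e. ≈ 800 Hz across a 165-pixel line — the
scale of APD dark counts plus residual buffer fluorescence at low laser
power; published kymographs under these conditions are near-black with
sparse single-photon speckle).  Dead-time censoring is applied last.  The
per-event sum of drawn photons is recorded, so with censoring and background
off, image total equals ground-truth total exactly.

Not emulated: optical sectioning and axial structure, polarization and
homo-FRET photophysics, fluorophore blinking (a config stub exists but no
rate is known), bead/trap mechanics, and brightness heterogeneity between
fluorophores.  Consequently, passing recovery tests demonstrates the
*analysis* is faithful to this generative model, not that the model captures
every feature of real data — in particular real step-size histograms are
broader (11 ± 4 photons) than the purely Poisson simulated ones.

**Cluster-count measurements** (`simulate_cluster_counts`) average
`n_line_samples = 4` Poisson line samples per cluster, because a cluster's
intensity is read from a 2D-scan ROI or a multi-line trace, never a single
50 µs dwell; binomial labeling variation, the dominant uncertainty, is kept.

## Trace tracking

Per line, detections are local maxima of the 3-pixel rolling count sum above
`min_counts` (default 4): a single 100 nm pixel holds only ~27% of a 350 nm
PSF, so the summed statistic is the sensitive one.  Sub-pixel positions are
5-pixel centroids; photon counts are 7-pixel aperture sums (±3 px ≈ one PSF
FWHM, ~97% capture) minus the expected background, estimated from the
low-count bulk of the kymograph (counts ≤ 2) since the median of a sparse
Poisson field is zero.  Peaks closer than `min_separation_px` (2) merge into
the stronger one.

Linking is greedy nearest-neighbour within `link_radius_px` (2), tolerating
`max_gap_lines` (3) dark lines; ties break by distance, then higher counts,
then lower pixel index.  Two robustness rules matter in practice: the link
reference is the *median of the last five positions* (one outlier detection
must not freeze the search region), and an unlinked detection within
`spawn_exclusion_px` (3.5 px ≈ one PSF FWHM) of an active trace is discarded
instead of seeding a new trace — a second molecule that close is optically
unresolvable, and such detections are side lobes that otherwise spawn
duplicate traces which alternately steal detections.  Traces with fewer than
`min_samples` (2) lines are dropped.  A trace touching the first line is
left-censored, one touching the last line right-censored; residence time
counts whole lines (`(last − first + 1) × line period`).

On simulated kymographs at the defaults, ≥90% of events visible for ≥2
lines are recovered with sub-pixel position RMSE < 1 px, and monomer traces
average 10–11 counts/line at unit intensity 11 (the ~5% deficit is aperture
truncation plus partial first/last lines — the same deficit the real
tracker shows).

## Photobleaching steps and the unitary intensity

Step detection is an optimal piecewise-constant decomposition.  For each
candidate step count *k*, the globally RSS-minimal placement of *k* change
points is computed by dynamic programming on prefix sums (O(kn²); exact, so
it provably matches exhaustive enumeration — a property the tests check on
≤30-line trajectories).  Trajectories longer than 4,000 lines fall back to
greedy recursive bisection.  *k* grows while three acceptance rules hold:
RSS(k) ≤ 0.95·RSS(k−1); every step ≥ `min_step` (5 photons ≈ half the
unitary intensity); and every step's *local* RSS gain (merged adjacent
plateaus vs split) exceeds the universal changepoint threshold
`2·σ²·ln(n)`, with σ² taken as the mean of the two plateau levels — the
shot-noise variance of photon counts.  The significance rule suppresses
spurious splits of short noisy plateaus without any tuned constant.  Exact
recovery on noiseless staircases and idempotence on a fit's own
reconstruction hold for unambiguous steps; a step sitting exactly at the
significance boundary can legitimately be dropped on refit.

Calibration takes the smallest-magnitude downward step of each trajectory
as a single-fluorophore event, histograms the magnitudes at bin width 3
anchored at zero, and fits a Gaussian by least squares (initialized from the
histogram moments, σ bounded below at bin/10).  When fewer than three bins
are occupied — which happens whenever the candidate steps are tightly
clustered, e.g. simulated staircases with long plateaus at 10 ms lines — the
Gaussian is unconstrained and the sample mean/SD of the candidates is
reported instead, flagged `method="sample"`.  Only downward steps ever feed
calibration; upward steps (binding, blinking-on) are recorded but excluded.

Cluster decay rates fit `I(t) = I₀e^(−kt) + c` by least squares with a
half-life-based initial rate.  A single 20-fluorophore staircase carries
~25% intrinsic spread in its fitted rate (bleaching is a discrete death
process), so population statements (median in 0.2–0.5 /s at a 0.43 /s
generator) are meaningful where per-realization ones are not; the
ensemble-averaged trajectory recovers the generating rate to a few percent.

## Stoichiometry

`count_molecules` performs, in order: background subtraction (clamped at
zero; background is the mean of 3–5 same-aperture off-signal regions),
per-dwell dead-time correction, division by the calibrated unitary
intensity, red-channel addition of `red_counts/14` fluorophore-equivalents
when blue counts lie in [100, 575] (above 575 the red emission grows
non-linearly and no correction is defined — the estimate is flagged
"possibly underestimated" instead), and division by labeling efficiency.
ΔS = 0.17·S exactly.  Molecule counts are reported as reals with a
half-to-even rounded integer alongside.  End-to-end on simulated clusters of
1–20 molecules (90% labeling, 35 ns dead time) the median absolute error is
≤ 1 molecule, dominated by binomial labeling variation.

## Geometry

Intensity profiles (mean over the perpendicular axis of a rectangular ROI)
are fitted to a Gaussian plus constant offset; FWHM = 2√(2 ln 2)·σ.  A
constant profile raises; non-convergence is flagged, not raised.  The FWHM
serves as a circular diameter: area = π(FWHM/2)², inverted by
d = 2√(area/π), a round trip exact to 10 significant digits.  Rulers:
contour length = bp × 0.34 nm; protomer capacity = ⌊bp/footprint⌋ with a
10 bp default footprint (the crystal-structure HIN footprint; the footprint
is exposed as a parameter because published capacity figures imply values
between 10 and ~12 bp).

## Kinetics

Dwell histograms use half-open 1 s bins from zero; the first bin is dropped
by default (it is depleted by the tracker's 2-line minimum and by selection
against the shortest events; the dropped fraction is reported).  The
exponential fit `y = A·exp(−k_off t) + y₀` is unweighted nonlinear least
squares on bin centers, initialized log-linearly, with R² and
RMSE = √(RSS/(n−3)) reported.  On exact exponential bin counts the
generating rate is recovered to < 10⁻³ relative error; at n = 314 dwells the
estimator recovers 0.29 /s within ±0.01 averaged over seeds (single-fit SD
≈ 0.035), and at n = 172, 0.52 /s within ±0.08.

Left- and right-censored traces are excluded from dwell sets but included in
the occupancy sum for `t_on = max(duration − Σ residence, 0)` (negative raw
values are clamped and flagged as overlap).  `k_on = 1/([C]·mean t_on)`,
with per-kymograph values also reported; the estimator is consistent when a
kymograph's unbound time is the waiting time of a binding event at
pseudo-first-order rate `k_on[C]`, and is reported verbatim regardless
because it is the assay's estimator.  For bulk relaxation rates measured
where oligomers are permanently attached, `k_on = k_obs/[C]` with k_off
taken as zero.  `K_D = k_off/k_on`.

Known limitation (deliberate): no censoring-corrected survival analysis or
MLE — the histogram protocol is the method being reproduced.  Apparent
off-rates from tracked traces include photobleaching (a trace ends when the
molecule unbinds *or* its last fluorophore bleaches), so on simulated data
the trace-level rate approximates `k_off + bleach_rate`; ground-truth dwells
recover `k_off` itself.

## Growth and diffusion

Growth rates are `(final − initial)/(Δt)` from 7×7-pixel window sums
anchored at the brightest pixel of the first and last frames, converted to
molecules/s through the unitary intensity and labeling efficiency
(photons/s = unit × molecules/s exactly when efficiency is 1 and dead time
0).  Direction classification compares first and last frames: profiles along
and across the DNA axis are column/row sums with their own medians
subtracted (baseline), characterized by half-max-crossing FWHM of a 3-pixel
smoothed profile and a centroid over pixels above 30% of the peak — moment
statistics are avoided because faint background across the frame dominates
second moments at single-molecule light levels.  Labels: total gain below
5% → `none`; along-axis centroid shift > 1 px → `left`/`right`; cross-axis
FWHM gain > 15% → `perpendicular`; both → `mixed`.  Thresholds were
calibrated on the simulator so that the two generative mechanisms are
labeled correctly and are exposed as parameters.  `classify_mechanism`
resolves `mixed` by the dominant normalized feature for the binary
primary/secondary question (≥95% accuracy on simulated growth from 5 to 35
molecules).  Classification is mirror-symmetric up to the left↔right swap.

Diffusion: MSD over lags 1–10 (gaps interpolated onto the line grid), linear
fit; D = slope/2.  A trace is `diffusive` when D exceeds
`min_diffusion_um2_s` (0.01 µm²/s, an order of magnitude above the
localization-noise floor of static traces at ~0.45 px jitter) *and* the
slope exceeds twice its standard error; otherwise `static`.  At 100-line
traces this separates D = 0 from D = 0.1 µm²/s with ≥99% accuracy and
recovers D within a factor of 2.

## Pipeline, IO, reproducibility

Interchange is 16-bit grayscale TIFF plus a JSON sidecar (`pixel_size_nm`,
`line_period_s`, `channel`, duration); RGB TIFFs are reduced by extracting
the blue plane; an optional hook reads any HDF5 exposing a 2D counts dataset
(the vendor's proprietary layout is out of scope).  Missing sidecar keys are
reported by name.  `run_pipeline` composes ingest/simulate → track →
step-calibration → stoichiometry → kinetics (pooled and per concentration)
→ growth, embeds the full effective configuration including the seed in its
report, and propagates stage failures with stage name and dataset.

Problem sizes in the test-suite and acceptance script (short-DNA kymographs
of 40–300 s, 20–48 staircases per calibration, 25-seed Monte-Carlo averages,
100-trace classification cohorts) are the package's choice of the smallest
sizes at which the statistical assertions are stable; the generator's
physical defaults are never scaled.
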