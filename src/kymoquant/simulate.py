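"""Stochastic ground-truth generator for the single-molecule assay.

Emulates the optical-tweezers confocal experiment end to end: protein
binding events arrive on a tethered dsDNA as a Poisson process, monomers and
dimers detach with exponential dwell times, clusters reaching the permanence
threshold stay bound forever, clusters grow by primary (along-DNA) and
secondary (atop the cluster) incorporation, each labeled fluorophore emits
Poisson photons per scan line until its exponential photobleaching time, the
emission is spread over pixels by a Gaussian point-spread function, and the
detector dead time thins the counts.  Every random quantity is recorded in a
:class:`~kymoquant.config.GroundTruth` so each analysis stage can be tested
against known truth.

All randomness flows through a single ``numpy.random.Generator``; fixing the
seed fixes every output bit-for-bit.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import ndtr

from .config import BindingEvent, GroundTruth, SimulationConfig
from .tracking import Kymograph, Trace

__all__ = [
    "simulate_dwell_times",
    "simulate_photobleach_trace",
    "simulate_kymograph",
    "render_kymograph",
    "render_scan",
    "simulate_growth_frames",
    "simulate_cluster_counts",
    "simulate_tracked_trace",
]


def _rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# --------------------------------------------------------------------------
# dwell times
# --------------------------------------------------------------------------

def simulate_dwell_times(k_off: float, n: int, seed=None) -> np.ndarray:
    """``n`` independent exponential dwell times with rate ``k_off`` (mean 1/k_off)."""
    if k_off <= 0:
        raise ValueError(f"k_off must be > 0, got {k_off}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return _rng(seed).exponential(1.0 / k_off, size=int(n))


# --------------------------------------------------------------------------
# photobleaching staircases
# --------------------------------------------------------------------------

def simulate_photobleach_trace(
    n_fluor: int,
    config: SimulationConfig = SimulationConfig(),
    duration_s: float | None = None,
    rng=None,
    aperture_px: int = 5,
):
    """Intensity trajectory of ``n_fluor`` co-localized fluorophores bleaching.

    Each fluorophore emits ``Poisson(unit_intensity)`` photons per scan line
    until its exponential ``bleach_rate`` bleach time (emission in the bleach
    line is prorated by the live fraction of that line).  Background photons
    for a tracking aperture of ``aperture_px`` pixels are added.

    Returns
    -------
    trajectory : ndarray of int
        Photon counts per scan line.
    step_times : ndarray of float
        True bleach times (s) within the trajectory, sorted.
    """
    if n_fluor < 1:
        raise ValueError(f"n_fluor must be >= 1, got {n_fluor}")
    rng = _rng(rng if rng is not None else config.seed)
    if config.bleach_rate > 0:
        bleach = rng.exponential(1.0 / config.bleach_rate, size=n_fluor)
    else:
        bleach = np.full(n_fluor, np.inf)
    if duration_s is None:
        duration_s = (
            float(np.max(bleach)) * 1.1 + 20 * config.line_period_s
            if np.isfinite(bleach).all()
            else 10.0
        )
    n_lines = max(int(round(duration_s / config.line_period_s)), 4)
    t0 = np.arange(n_lines) * config.line_period_s
    # live fraction of each line for each fluorophore
    frac = np.clip((bleach[:, None] - t0[None, :]) / config.line_period_s, 0.0, 1.0)
    mean = config.unit_intensity * frac.sum(axis=0)
    mean += config.background_rate * aperture_px
    trajectory = rng.poisson(mean)
    step_times = np.sort(bleach[bleach < n_lines * config.line_period_s])
    return trajectory, step_times


# --------------------------------------------------------------------------
# PSF rendering helpers
# --------------------------------------------------------------------------

def _pixel_weights(pos_nm: float, sigma_nm: float, n_pixels: int, pixel_size_nm: float):
    """Gaussian PSF integrated per pixel around ``pos_nm`` (4-sigma support).

    Returns (first_pixel, weights); weights[k] is the probability a photon
    from an emitter at ``pos_nm`` lands in pixel ``first_pixel + k``.
    """
    half = 4.0 * sigma_nm
    j0 = max(int(math.floor((pos_nm - half) / pixel_size_nm)), 0)
    j1 = min(int(math.ceil((pos_nm + half) / pixel_size_nm)), n_pixels)
    if j1 <= j0:
        return 0, np.empty(0)
    edges = np.arange(j0, j1 + 1) * pixel_size_nm
    z = (edges - pos_nm) / sigma_nm
    cdf = ndtr(z)
    return j0, cdf[1:] - cdf[:-1]


def render_kymograph(
    fluorophores,
    config: SimulationConfig,
    rng=None,
    bookkeeping: list | None = None,
):
    """Render a photon-count kymograph from explicit fluorophore records.

    Parameters
    ----------
    fluorophores : sequence of (t_on_s, t_off_s, position_nm[, tag])
        Emission intervals and positions; ``tag`` (optional int) indexes into
        ``bookkeeping`` for per-event emitted-photon sums.
    bookkeeping : list of int, optional
        Mutable list accumulating realized pre-censoring photons per tag.

    Returns
    -------
    Kymograph
    """
    rng = _rng(rng if rng is not None else config.seed)
    n_px, n_lines = config.n_pixels, config.n_lines
    signal = np.zeros((n_px, n_lines), dtype=np.int64)
    mean = np.full((n_px, n_lines), config.background_rate, dtype=float)
    period = config.line_period_s
    sigma = config.psf_sigma_nm

    for rec in fluorophores:
        t_on, t_off, pos = rec[0], rec[1], rec[2]
        tag = rec[3] if len(rec) > 3 else None
        t_off = min(t_off, n_lines * period)
        if t_off <= t_on:
            continue
        i0 = max(int(math.floor(t_on / period)), 0)
        i1 = min(int(math.ceil(t_off / period)), n_lines)
        if i1 <= i0:
            continue
        starts = np.arange(i0, i1) * period
        frac = (np.minimum(t_off, starts + period) - np.maximum(t_on, starts)) / period
        frac = np.clip(frac, 0.0, 1.0)
        j0, w = _pixel_weights(pos, sigma, n_px, config.pixel_size_nm)
        if w.size == 0:
            continue
        block_mean = config.unit_intensity * np.outer(w, frac)
        draws = rng.poisson(block_mean)
        signal[j0 : j0 + w.size, i0:i1] += draws
        mean[j0 : j0 + w.size, i0:i1] += block_mean
        if bookkeeping is not None and tag is not None:
            bookkeeping[tag] += int(draws.sum())

    counts = signal + rng.poisson(config.background_rate, size=signal.shape)
    if config.dead_time_s > 0:
        # expected-count thinning: keep probability from the expected rate in
        # the pixel dwell, realized as binomial so counts stay integers
        rate = mean / (config.pixel_dwell_us * 1e-6)
        keep = 1.0 / (1.0 + rate * config.dead_time_s)
        counts = rng.binomial(counts, keep)
    return Kymograph(
        counts=counts.astype(np.int64),
        pixel_size_nm=config.pixel_size_nm,
        line_period_s=period,
        channel="blue",
    )


# --------------------------------------------------------------------------
# full kymograph simulation
# --------------------------------------------------------------------------

def _simulate_cluster(t0, pos0, config: SimulationConfig, rng, horizon):
    """Gillespie life of one cluster: detachment vs primary/secondary growth."""
    size = 1
    polarity = 1.0 if rng.random() < 0.5 else -1.0
    size_traj = [(t0, 1)]
    arrivals = [(t0, pos0)]
    unbind = None
    n_primary = 0
    t = t0
    while True:
        detach = config.k_off_monomer if size < config.permanence_threshold else 0.0
        total = detach + config.primary_growth_rate + config.secondary_growth_rate
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= horizon:
            break
        u = rng.random() * total
        if u < detach:
            unbind = t
            break
        size += 1
        if u < detach + config.primary_growth_rate:
            n_primary += 1
            p = pos0 + polarity * n_primary * config.growth_step_nm
            p = min(max(p, 0.0), config.dna_length_nm)
        else:
            p = pos0  # secondary growth stacks atop the cluster
        arrivals.append((t, p))
        size_traj.append((t, size))
    return unbind, size_traj, arrivals


def simulate_kymograph(config: SimulationConfig = SimulationConfig(), rng=None):
    """Simulate a full kymograph with ground truth.

    Binding events arrive as a Poisson process at ``arrival_rate`` with
    positions uniform on the DNA; cluster kinetics follow
    :func:`_simulate_cluster`; photon emission, PSF spreading and dead-time
    censoring follow :func:`render_kymograph`.

    Returns
    -------
    (Kymograph, GroundTruth)
    """
    rng = _rng(rng if rng is not None else config.seed)
    horizon = config.n_lines * config.line_period_s

    n_events = rng.poisson(config.arrival_rate * horizon)
    bind_times = np.sort(rng.uniform(0.0, horizon, size=n_events))
    positions = rng.uniform(0.0, config.dna_length_nm, size=n_events)

    events = []
    fluor_records = []
    for k in range(n_events):
        t0, pos0 = float(bind_times[k]), float(positions[k])
        unbind, size_traj, arrivals = _simulate_cluster(t0, pos0, config, rng, horizon)
        fluors = []
        for t_a, p in arrivals:
            labeled = rng.random() < config.labeling_efficiency
            if config.bleach_rate > 0:
                t_bleach = t_a + rng.exponential(1.0 / config.bleach_rate)
            else:
                t_bleach = np.inf
            if labeled:
                t_off = min(t_bleach, unbind if unbind is not None else np.inf)
                fluors.append((t_a, t_bleach, p))
                fluor_records.append((t_a, t_off, p, k))
        events.append(
            BindingEvent(
                event_id=k,
                bind_time_s=t0,
                unbind_time_s=unbind,
                position_nm=pos0,
                cluster_id=k,
                size_trajectory=size_traj,
                fluorophores=fluors,
            )
        )

    emitted = [0] * max(n_events, 1)
    kymo = render_kymograph(fluor_records, config, rng=rng, bookkeeping=emitted)
    for ev in events:
        ev.emitted_photons = emitted[ev.event_id]
    truth = GroundTruth(events=events, config=config)

    if config.simulate_red:
        kymo.red_counts = _render_red_channel(events, config, rng)
    return kymo, truth


def _render_red_channel(events, config: SimulationConfig, rng):
    """Empirical red-emission rule: clusters whose expected blue counts exceed
    100 per line emit a constant mean of ``red_mean_counts`` red photons."""
    n_px, n_lines = config.n_pixels, config.n_lines
    red = rng.poisson(config.background_rate, size=(n_px, n_lines)).astype(np.int64)
    period = config.line_period_s
    for ev in events:
        if not ev.fluorophores:
            continue
        for i in range(n_lines):
            t = i * period
            alive = sum(
                1 for (t_a, t_b, _p) in ev.fluorophores if t_a <= t < min(
                    t_b, ev.unbind_time_s if ev.unbind_time_s is not None else np.inf
                )
            )
            if alive * config.unit_intensity > 100:
                j0, w = _pixel_weights(
                    ev.position_nm, config.psf_sigma_nm, n_px, config.pixel_size_nm
                )
                red[j0 : j0 + w.size, i] += rng.poisson(config.red_mean_counts * w)
    return red


# --------------------------------------------------------------------------
# 2D scans and growth frames
# --------------------------------------------------------------------------

def render_scan(
    emitters,
    config: SimulationConfig,
    shape_px=(32, 64),
    rng=None,
):
    """Render one 2D confocal scan.

    Parameters
    ----------
    emitters : sequence of (x_nm, y_nm, mean_photons)
        Point emitters; ``x`` is the DNA axis (image columns), ``y`` the
        perpendicular axis (rows).  ``mean_photons`` is the expected photon
        yield of the emitter in this frame.
    shape_px : (rows, cols)

    Returns
    -------
    ndarray of int, shape ``shape_px``
    """
    rng = _rng(rng if rng is not None else config.seed)
    ny, nx = shape_px
    mean = np.full((ny, nx), config.background_rate, dtype=float)
    sigma = config.psf_sigma_nm
    for x_nm, y_nm, photons in emitters:
        jx0, wx = _pixel_weights(x_nm, sigma, nx, config.pixel_size_nm)
        jy0, wy = _pixel_weights(y_nm, sigma, ny, config.pixel_size_nm)
        if wx.size == 0 or wy.size == 0:
            continue
        mean[jy0 : jy0 + wy.size, jx0 : jx0 + wx.size] += photons * np.outer(wy, wx)
    if config.dead_time_s > 0:
        rate = mean / (config.pixel_dwell_us * 1e-6)
        mean = mean / (1.0 + rate * config.dead_time_s)
    return rng.poisson(mean)


def simulate_growth_frames(
    config: SimulationConfig,
    mechanism: str = "primary",
    n_start: int = 5,
    n_end: int = 35,
    n_frames: int = 8,
    frame_period_s: float = 1.0,
    shape_px=(32, 64),
    direction: int = +1,
    rng=None,
):
    """Time-stamped 2D frames of one cluster growing by a known mechanism.

    ``mechanism='primary'`` places each added molecule ``growth_step_nm``
    further along the DNA axis (one-sided, ``direction`` = +1 right / -1
    left); ``'secondary'`` stacks molecules atop the cluster, displacing them
    perpendicular to the DNA; ``'none'`` keeps the size constant (the frames
    then show photobleaching only, if bleach_rate > 0).

    Returns
    -------
    frames : ndarray (n_frames, rows, cols)
    times : ndarray of frame timestamps (s)
    truth : dict with the generating mechanism and molecule counts per frame
    """
    if mechanism not in ("primary", "secondary", "none"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    rng = _rng(rng if rng is not None else config.seed)
    ny, nx = shape_px
    x0 = nx / 2 * config.pixel_size_nm
    y0 = ny / 2 * config.pixel_size_nm
    times = np.arange(n_frames) * frame_period_s
    if mechanism == "none":
        n_end = n_start
    n_mol = np.rint(np.linspace(n_start, n_end, n_frames)).astype(int)

    # molecule k's fixed offset from the nucleation point
    offsets = []
    for k in range(max(n_mol)):
        if k < n_start or mechanism == "none":
            offsets.append((0.0, 0.0))
        elif mechanism == "primary":
            offsets.append((direction * (k - n_start + 1) * config.growth_step_nm, 0.0))
        else:
            offsets.append((0.0, (k - n_start + 1) * config.growth_step_nm))

    bleach_factor = np.exp(-config.bleach_rate * times) if mechanism == "none" else np.ones(n_frames)
    labeled = rng.random(max(n_mol)) < config.labeling_efficiency  # fixed per molecule
    frames = np.empty((n_frames, ny, nx), dtype=np.int64)
    for f in range(n_frames):
        emitters = [
            (x0 + dx, y0 + dy, config.unit_intensity * bleach_factor[f])
            for k, (dx, dy) in enumerate(offsets[: n_mol[f]])
            if labeled[k]
        ]
        frames[f] = render_scan(emitters, config, shape_px=shape_px, rng=rng)
    truth = {
        "mechanism": mechanism,
        "direction": direction,
        "n_molecules": n_mol,
        "rate_molecules_per_s": (n_mol[-1] - n_mol[0]) / (times[-1] - times[0])
        if n_frames > 1
        else 0.0,
    }
    return frames, times, truth


# --------------------------------------------------------------------------
# cluster photon counts (stoichiometry recovery)
# --------------------------------------------------------------------------

def simulate_cluster_counts(
    sizes, config: SimulationConfig, rng=None, n_line_samples: int = 4
):
    """Measured photon counts for clusters of known molecule numbers.

    Each cluster of ``n`` molecules carries ``Binomial(n, labeling_efficiency)``
    fluorophores emitting ``Poisson(unit_intensity)`` photons each per line
    sample; the emission is dead-time-thinned at the pixel-dwell rate (the
    same idealized model the analysis inverts).  The reported count is the
    mean over ``n_line_samples`` samples: a cluster's intensity is never read
    off a single pixel dwell — a 2D-scan ROI (or a kymograph trace) integrates
    the same fluorophores over several scan samples.

    Returns an ndarray of measured counts (photons per line sample, real-
    valued after averaging), one per input size.
    """
    rng = _rng(rng if rng is not None else config.seed)
    sizes = np.asarray(sizes, dtype=int)
    n_fluor = rng.binomial(sizes, config.labeling_efficiency)
    true_mean = config.unit_intensity * n_fluor
    if config.dead_time_s > 0:
        rate = true_mean / (config.pixel_dwell_us * 1e-6)
        measured_mean = true_mean / (1.0 + rate * config.dead_time_s)
    else:
        measured_mean = true_mean
    draws = rng.poisson(
        np.broadcast_to(measured_mean, (n_line_samples,) + measured_mean.shape)
    )
    return draws.mean(axis=0)


# --------------------------------------------------------------------------
# tracked traces with known mobility (diffusion tests)
# --------------------------------------------------------------------------

def simulate_tracked_trace(
    n_lines: int,
    diffusion_um2_s: float = 0.0,
    config: SimulationConfig = SimulationConfig(),
    localization_noise_px: float = 0.45,
    rng=None,
) -> Trace:
    """A tracked trace whose true positions follow 1D Brownian motion.

    ``diffusion_um2_s = 0`` gives a static molecule; localization noise
    (default 0.45 px, roughly sigma_PSF/sqrt(photons) at 11 photons/line)
    jitters the reported sub-pixel positions either way.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    rng = _rng(rng if rng is not None else config.seed)
    dt = config.line_period_s
    step_nm = math.sqrt(2.0 * diffusion_um2_s * 1e6 * dt)  # um^2/s -> nm^2/s
    true_nm = np.cumsum(np.concatenate(([0.0], rng.normal(0.0, step_nm, n_lines - 1))))
    pos_px = true_nm / config.pixel_size_nm + 30.0
    pos_px = pos_px + rng.normal(0.0, localization_noise_px, n_lines)
    counts = rng.poisson(config.unit_intensity, n_lines)
    return Trace(
        trace_id=0,
        lines=np.arange(n_lines),
        positions_px=pos_px,
        counts=counts.astype(float),
        line_period_s=dt,
        pixel_size_nm=config.pixel_size_nm,
    )
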