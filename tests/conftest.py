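import pytest

from kymoquant.config import SimulationConfig
from kymoquant.photobleach import UnitaryIntensity


@pytest.fixture
def unit11():
    """Calibrated unitary intensity of 11 photons/fluorophore/line."""
    return UnitaryIntensity(mean=11.0, sd=4.0, n_steps=48)


@pytest.fixture
def small_kymo_config():
    """Short-DNA, short-duration scan config for fast kymograph simulations."""
    return SimulationConfig(
        dna_length_bp=20_000,
        duration_s=60.0,
        arrival_rate=0.2,
        primary_growth_rate=0.0,
        secondary_growth_rate=0.0,
        seed=5,
    )


def visible_dwell_lines(event, config):
    """Ground-truth lines an event is visible for (bound, labeled, unbleached)."""
    if not event.fluorophores:
        return 0.0
    horizon = config.duration_s
    t_end = event.unbind_time_s if event.unbind_time_s is not None else horizon
    last_light = max(min(b, t_end, horizon) for _, b, _ in event.fluorophores)
    return (last_light - event.bind_time_s) / config.line_period_s


@pytest.fixture
def match_events():
    """Matcher: ground-truth events -> nearest overlapping trace."""

    def _match(truth, traces, config, max_dist_px=2.0):
        horizon = config.duration_s
        out = []
        for ev in truth.events:
            if not ev.fluorophores:
                continue
            t_end = ev.unbind_time_s if ev.unbind_time_s is not None else horizon
            t_vis = max(min(b, t_end, horizon) for _, b, _ in ev.fluorophores)
            pos_px = ev.position_nm / config.pixel_size_nm
            best = None
            for tr in traces:
                if tr.t_end_s < ev.bind_time_s or tr.t_start_s > t_vis:
                    continue
                d = abs(tr.mean_position_px - pos_px)
                if d <= max_dist_px and (best is None or d < best[0]):
                    best = (d, tr)
            out.append((ev, best))
        return out

    return _match
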