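"""End-to-end pipeline: simulate/ingest -> track -> calibrate -> quantify.

``run_pipeline`` composes the analysis stages over a manifest of kymographs
(on disk or simulated), producing a JSON-serializable report with the
single-fluorophore calibration, per- and pooled-concentration dissociation
rates (with fit diagnostics), association rates from unbound times, K_D
range, cluster size distribution, and growth records.  The report embeds the
full effective configuration including the seed, so a run can be reproduced
from its own report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .config import SimulationConfig
from .detector import DeadTimeModel
from .io import Manifest, read_image, write_traces_csv
from .kinetics import (
    dissociation_constant,
    dwell_histogram,
    eligible_dwells,
    fit_koff,
    fit_kon,
    unbound_time,
)
from .photobleach import UnitaryIntensity, detect_steps, unitary_intensity
from .simulate import simulate_kymograph
from .stoichiometry import count_molecules, size_distribution
from .tracking import KymographTracker
from .growth import growth_rate

logger = logging.getLogger("kymoquant")

__all__ = ["run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, dataset, err: Exception):
        super().__init__(f"stage {stage!r} failed on dataset {dataset!r}: {err}")
        self.stage = stage
        self.dataset = dataset


def _get_kymograph(entry: dict, manifest: Manifest, index: int):
    if entry.get("simulate"):
        overrides = {
            k: v
            for k, v in entry.items()
            if k in SimulationConfig().__dataclass_fields__
        }
        overrides.setdefault("seed", manifest.seed + index)
        config = SimulationConfig(**overrides)
        kymo, truth = simulate_kymograph(config)
        return kymo, truth
    kymo = read_image(entry["path"], entry.get("sidecar"))
    return kymo, None


def run_pipeline(manifest: Manifest, out_dir=None) -> dict:
    """Execute the full analysis over a manifest; returns the report dict."""
    if isinstance(manifest, (str, Path)):
        manifest = Manifest.from_json(manifest)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    deadtime = DeadTimeModel(
        tau=manifest.dead_time_ns * 1e-9, window=manifest.pixel_dwell_us * 1e-6
    )
    tracker = KymographTracker(
        min_counts=manifest.min_counts,
        max_gap_lines=manifest.max_gap_lines,
        link_radius_px=manifest.link_radius_px,
    )

    per_dataset = []
    all_traces = []
    for i, entry in enumerate(manifest.datasets):
        if entry["kind"] != "kymograph":
            continue
        try:
            kymo, truth = _get_kymograph(entry, manifest, i)
        except Exception as err:  # noqa: BLE001
            raise StageError("ingest", entry.get("path", f"simulated#{i}"), err)
        try:
            traces = tracker.fit_predict(kymo)
        except Exception as err:  # noqa: BLE001
            raise StageError("track", entry.get("path", f"simulated#{i}"), err)
        logger.info("dataset %d: %d traces", i, len(traces))
        duration = float(entry.get("duration_s", kymo.total_duration_s))
        conc = entry.get("concentration")
        t_on = unbound_time(duration, traces)
        per_dataset.append(
            {
                "index": i,
                "concentration_M": conc,
                "duration_s": duration,
                "n_traces": len(traces),
                "t_on_s": t_on.t_on_s,
                "t_on_overlap": t_on.overlap_flag,
                "n_ground_truth_events": truth.n_events if truth else None,
            }
        )
        all_traces.append((conc, traces))
        if out_dir is not None:
            write_traces_csv(traces, out_dir / f"traces_{i:02d}.csv")

    if not per_dataset:
        raise ValueError("manifest contains no kymograph datasets")

    # --- calibration: photobleaching steps from decaying traces ------------
    stepfits = []
    for _, traces in all_traces:
        for tr in traces:
            if tr.n_samples >= 8 and tr.counts[0] > tr.counts[-1]:
                try:
                    sf = detect_steps(tr.counts)
                except ValueError:
                    continue
                if sf.n_steps:
                    stepfits.append(sf)
    try:
        unit = unitary_intensity(stepfits)
        calibration = {
            "mean": unit.mean, "sd": unit.sd, "n_steps": unit.n_steps,
            "method": unit.method, "source": "photobleaching steps",
        }
    except ValueError:
        unit = UnitaryIntensity(
            mean=manifest.unit_intensity, sd=0.0, n_steps=0, method="configured"
        )
        calibration = {
            "mean": unit.mean, "sd": unit.sd, "n_steps": 0,
            "method": "configured", "source": "manifest unit_intensity",
        }

    # --- kinetics -----------------------------------------------------------
    def _koff_section(dwells):
        hist = dwell_histogram(
            dwells, manifest.bin_width_s, manifest.drop_first_bin
        )
        fit = fit_koff(hist)
        return {
            "k_off_per_s": fit.k_off,
            "k_off_stderr": fit.k_off_stderr,
            "r_squared": fit.r_squared,
            "rmse": fit.rmse,
            "n_dwells": int(len(dwells)),
            "dropped_first_bin_fraction": hist.dropped_fraction,
        }

    pooled = np.concatenate(
        [eligible_dwells(traces) for _, traces in all_traces]
    )
    kinetics_report = {"pooled": None, "per_concentration": {}, "k_on": {}, "K_D": {}}
    try:
        kinetics_report["pooled"] = _koff_section(pooled)
    except ValueError as err:
        kinetics_report["pooled"] = {"error": str(err)}

    concentrations = sorted(
        {c for c, _ in all_traces if c is not None}
    )
    for conc in concentrations:
        dwells = np.concatenate(
            [eligible_dwells(tr) for c, tr in all_traces if c == conc]
        )
        try:
            kinetics_report["per_concentration"][f"{conc:.3g}"] = _koff_section(dwells)
        except ValueError as err:
            kinetics_report["per_concentration"][f"{conc:.3g}"] = {"error": str(err)}
        t_ons = [
            d["t_on_s"] for d in per_dataset if d["concentration_M"] == conc
        ]
        if t_ons and min(t_ons) > 0:
            kon = fit_kon(t_ons, conc)
            kinetics_report["k_on"][f"{conc:.3g}"] = {
                "k_on_per_M_s": kon.k_on,
                "mean_t_on_s": kon.mean_t_on,
                "per_kymograph": list(kon.k_on_per_kymograph),
            }

    pooled_koff = kinetics_report["pooled"].get("k_off_per_s")
    kons = [v["k_on_per_M_s"] for v in kinetics_report["k_on"].values()]
    if pooled_koff and kons:
        kds = [dissociation_constant(pooled_koff, k) for k in kons]
        kinetics_report["K_D"] = {
            "min_M": min(kds), "max_M": max(kds),
            "min_nM": min(kds) * 1e9, "max_nM": max(kds) * 1e9,
        }

    # --- stoichiometry -------------------------------------------------------
    measurements = []
    for _, traces in all_traces:
        for tr in traces:
            m = count_molecules(
                raw_counts=tr.mean_counts,
                background=0.0,  # tracker counts are already background-corrected
                red_counts=0.0,
                unit=unit,
                labeling_efficiency=manifest.labeling_efficiency,
                deadtime=deadtime,
            )
            measurements.append(m)
    if measurements:
        dist = size_distribution(measurements, bin_width=3.0)
        size_report = {
            "n_clusters": dist["n"],
            "modal_bin_molecules": dist["modal_bin"],
            "fraction_below_25": dist["fraction_below_25"],
            "bin_edges": dist["bin_edges"].tolist(),
            "counts": dist["counts"].tolist(),
        }
    else:
        size_report = {"n_clusters": 0}

    # --- growth --------------------------------------------------------------
    growth_records = []
    for _, traces in all_traces:
        for tr in traces:
            if tr.n_samples < 5:
                continue
            rec = growth_rate(
                tr.times_s, tr.counts, unit=unit,
                labeling_efficiency=manifest.labeling_efficiency,
            )
            if rec.end_molecules - rec.start_molecules > 1.0:
                growth_records.append(
                    {
                        "trace_id": tr.trace_id,
                        "rate_photons_per_s": rec.rate_photons_per_s,
                        "rate_molecules_per_s": rec.rate_molecules_per_s,
                        "start_molecules": rec.start_molecules,
                        "end_molecules": rec.end_molecules,
                    }
                )

    report = {
        "version": __version__,
        "config": manifest.to_dict(),
        "datasets": per_dataset,
        "calibration": calibration,
        "kinetics": kinetics_report,
        "size_distribution": size_report,
        "growth": growth_records,
    }
    if out_dir is not None:
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
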