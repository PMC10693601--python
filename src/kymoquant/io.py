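"""Readers and writers: TIFF + JSON sidecar images, trace CSVs, manifests.

The native interchange format is a 16-bit grayscale TIFF photon-count matrix
with a JSON sidecar carrying the scan metadata (pixel size, line period,
channel, duration).  RGB TIFFs are accepted by extracting the blue channel
(the detection band of the green-emitting label on these instruments maps to
the blue channel of exported RGB images).  An optional hook reads any HDF5
file exposing a 2D counts dataset plus the same sidecar keys as attributes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import GroundTruth
from .tracking import Kymograph, Trace

__all__ = [
    "write_kymograph",
    "read_image",
    "write_traces_csv",
    "read_traces_csv",
    "write_ground_truth",
    "Manifest",
    "REQUIRED_SIDECAR_KEYS",
]

REQUIRED_SIDECAR_KEYS = ("pixel_size_nm", "line_period_s", "channel")


def _sidecar_path(image_path) -> Path:
    return Path(image_path).with_suffix(".json")


def write_kymograph(kymo: Kymograph, path, extra_meta: dict | None = None) -> Path:
    """Write a kymograph (or 2D scan) as 16-bit TIFF plus JSON sidecar."""
    path = Path(path)
    counts = np.asarray(kymo.counts)
    if counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("photon counts exceed the 16-bit TIFF range")
    tifffile.imwrite(path, counts.astype(np.uint16))
    meta = {
        "pixel_size_nm": kymo.pixel_size_nm,
        "line_period_s": kymo.line_period_s,
        "channel": kymo.channel,
        "duration_s": kymo.total_duration_s,
    }
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def _load_sidecar(path, sidecar) -> dict:
    sc = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {sc}")
    meta = json.loads(sc.read_text())
    missing = [k for k in REQUIRED_SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sc} missing required keys: {missing}")
    return meta


def read_image(path, sidecar=None, channel: str | None = None):
    """Read a kymograph/scan TIFF (or HDF5) with its JSON sidecar.

    RGB images are reduced to one channel: ``channel='blue'`` (default)
    extracts the third RGB plane.  Returns a :class:`Kymograph` for 2D data
    or ``(frames, meta)`` for a 3D grayscale frame stack.
    """
    path = Path(path)
    meta = _load_sidecar(path, sidecar)
    if path.suffix.lower() in (".h5", ".hdf5"):
        counts = _read_hdf5_counts(path)
    else:
        counts = tifffile.imread(path)
    counts = np.asarray(counts)
    want = channel or meta.get("channel", "blue")
    if counts.ndim == 3 and counts.shape[-1] in (3, 4):
        idx = {"red": 0, "green": 1, "blue": 2}.get(want)
        if idx is None:
            raise ValueError(f"cannot extract channel {want!r} from an RGB image")
        counts = counts[..., idx]
    if np.any(counts < 0):
        raise ValueError("photon counts must be non-negative")
    if counts.ndim == 3:
        return counts, meta
    return Kymograph(
        counts=counts.astype(np.int64),
        pixel_size_nm=float(meta["pixel_size_nm"]),
        line_period_s=float(meta["line_period_s"]),
        channel=want,
    )


def _read_hdf5_counts(path):
    import h5py  # optional hook; only needed for HDF5 inputs

    with h5py.File(path, "r") as f:
        names = [k for k in f.keys() if isinstance(f[k], h5py.Dataset)]
        for name in ("counts", "photon_counts") + tuple(names):
            if name in f:
                return f[name][()]
    raise ValueError(f"no counts dataset found in {path}")


# --------------------------------------------------------------------------
# traces
# --------------------------------------------------------------------------

def write_traces_csv(traces, path) -> Path:
    """One row per (trace, line) sample, with censoring flags."""
    rows = []
    for tr in traces:
        for line, pos, cts in zip(tr.lines, tr.positions_px, tr.counts):
            rows.append(
                {
                    "trace_id": tr.trace_id,
                    "line": int(line),
                    "time_s": line * tr.line_period_s,
                    "position_px": pos,
                    "counts": cts,
                    "left_censored": tr.left_censored,
                    "right_censored": tr.right_censored,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "trace_id", "line", "time_s", "position_px", "counts",
            "left_censored", "right_censored",
        ],
    )
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_traces_csv(path, pixel_size_nm: float = 100.0, line_period_s: float | None = None):
    """Rebuild Trace objects from a traces CSV."""
    df = pd.read_csv(path)
    traces = []
    for tid, g in df.groupby("trace_id"):
        g = g.sort_values("line")
        if line_period_s is None:
            lines = g["line"].to_numpy()
            times = g["time_s"].to_numpy()
            period = (
                float(times[1] - times[0]) / (lines[1] - lines[0])
                if len(g) > 1
                else 1.0
            )
        else:
            period = line_period_s
        traces.append(
            Trace(
                trace_id=int(tid),
                lines=g["line"].to_numpy(),
                positions_px=g["position_px"].to_numpy(),
                counts=g["counts"].to_numpy(),
                line_period_s=period,
                pixel_size_nm=pixel_size_nm,
                left_censored=bool(g["left_censored"].iloc[0]),
                right_censored=bool(g["right_censored"].iloc[0]),
            )
        )
    return traces


def write_ground_truth(truth: GroundTruth, csv_path, json_path=None):
    """Ground truth as CSV (one row per event) plus a JSON config dump."""
    rows = [
        {
            "event_id": ev.event_id,
            "bind_time_s": ev.bind_time_s,
            "unbind_time_s": ev.unbind_time_s if ev.unbind_time_s is not None else "",
            "position_nm": ev.position_nm,
            "cluster_id": ev.cluster_id,
            "max_size": ev.max_size,
            "n_fluorophores": len(ev.fluorophores),
            "emitted_photons": ev.emitted_photons,
        }
        for ev in truth.events
    ]
    pd.DataFrame(
        rows,
        columns=[
            "event_id", "bind_time_s", "unbind_time_s", "position_nm",
            "cluster_id", "max_size", "n_fluorophores", "emitted_photons",
        ],
    ).to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(truth.config.to_dict(), indent=2))


# --------------------------------------------------------------------------
# manifest
# --------------------------------------------------------------------------

@dataclass
class Manifest:
    """Dataset list + pipeline configuration for an end-to-end run.

    ``datasets`` entries are dicts with either ``path`` (TIFF on disk) or
    ``simulate: true`` plus config overrides; required keys per entry:
    ``kind`` (kymograph|scan|frames), ``concentration`` (molar) and
    ``duration_s`` for kymographs.
    """

    datasets: list
    unit_intensity: float = 11.0
    labeling_efficiency: float = 0.90
    dead_time_ns: float = 35.0
    pixel_dwell_us: float = 50.0
    bin_width_s: float = 1.0
    drop_first_bin: bool = True
    min_counts: float = 4.0
    max_gap_lines: int = 3
    link_radius_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("manifest contains no datasets")
        for i, entry in enumerate(self.datasets):
            if "kind" not in entry:
                raise ValueError(f"dataset {i}: missing 'kind'")
            if not entry.get("simulate") and "path" not in entry:
                raise ValueError(f"dataset {i}: needs 'path' or 'simulate: true'")
            if "path" in entry and not Path(entry["path"]).exists():
                raise FileNotFoundError(f"dataset {i}: {entry['path']} not found")

    @classmethod
    def from_json(cls, path) -> "Manifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)
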