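"""On-disk formats: FLIM containers, ROI masks, tidy CSVs and YAML configs.

The FLIM container is deliberately plain: a multi-page TIFF holding the
photon-count histograms with dimension order (timepoint, tau_bin, y, x), a
second TIFF with the acceptor/volume channel (timepoint, y, x), and a JSON
sidecar carrying the acquisition metadata.  All three share a path prefix::

    <prefix>.flim.tif       photon counts, uint32, (T, B, Y, X)
    <prefix>.acceptor.tif   acceptor intensity, float32, (T, Y, X)
    <prefix>.json           sidecar, schema below

Sidecar schema (version 1): ``schema_version``, ``times_min`` (strictly
increasing, stimulus onset at 0), ``n_bins``, ``bin_width_ns``,
``period_ns``, ``pixel_size_um``, ``channel_roles``, ``calibration``
(sensor name or null).  Histogram times are in ns, experiment times in
minutes; units are fixed by the schema, not repeated per file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .flim_imaging import FlimStack, RoiSet, TimeCourse
from .frap_exocytosis import FrapExperiment

__all__ = [
    "SIDECAR_SCHEMA_VERSION",
    "ContainerSchemaError",
    "write_flim_container",
    "read_flim_container",
    "write_roi_mask",
    "read_roi_mask",
    "write_timecourse_csv",
    "read_timecourse_csv",
    "write_frap_csv",
    "read_frap_experiment_csv",
    "RunConfig",
    "load_run_config",
    "save_run_config",
]

SIDECAR_SCHEMA_VERSION = 1


class ContainerSchemaError(ValueError):
    """Raised when a FLIM container's sidecar or shapes are inconsistent."""


def _container_paths(prefix: str | Path) -> tuple[Path, Path, Path]:
    p = str(prefix)
    return Path(p + ".flim.tif"), Path(p + ".acceptor.tif"), Path(p + ".json")


def write_flim_container(stack: FlimStack, prefix: str | Path) -> None:
    """Write a stack as TIFF pair + JSON sidecar under a path prefix."""
    flim_path, acc_path, json_path = _container_paths(prefix)
    flim_path.parent.mkdir(parents=True, exist_ok=True)
    # internal layout (T, Y, X, B) -> on-disk (T, B, Y, X)
    counts = np.ascontiguousarray(np.moveaxis(stack.frames, -1, 1)).astype(np.uint32)
    tifffile.imwrite(flim_path, counts)
    tifffile.imwrite(acc_path, stack.acceptor.astype(np.float32))
    sidecar = {
        "schema_version": SIDECAR_SCHEMA_VERSION,
        "times_min": [float(t) for t in stack.times],
        "n_bins": int(stack.n_bins),
        "bin_width_ns": float(stack.bin_width_ns),
        "period_ns": float(stack.period_ns),
        "pixel_size_um": float(stack.pixel_size_um),
        "channel_roles": stack.channel_roles,
        "calibration": stack.calibration_name,
    }
    json_path.write_text(json.dumps(sidecar, indent=2) + "\n")


_REQUIRED_SIDECAR = ("schema_version", "times_min", "n_bins", "bin_width_ns",
                     "period_ns", "pixel_size_um")


def read_flim_container(prefix: str | Path) -> FlimStack:
    """Read a TIFF+JSON FLIM container, validating shapes against the sidecar."""
    flim_path, acc_path, json_path = _container_paths(prefix)
    for p in (flim_path, acc_path, json_path):
        if not p.exists():
            raise ContainerSchemaError(f"missing container file: {p}")
    sidecar = json.loads(json_path.read_text())
    for key in _REQUIRED_SIDECAR:
        if key not in sidecar:
            raise ContainerSchemaError(f"sidecar missing required field {key!r}")
    if sidecar["schema_version"] != SIDECAR_SCHEMA_VERSION:
        raise ContainerSchemaError(
            f"unsupported sidecar schema_version {sidecar['schema_version']!r}"
        )
    counts = tifffile.imread(flim_path)
    acceptor = tifffile.imread(acc_path)
    if counts.ndim != 4:
        raise ContainerSchemaError(
            f"FLIM TIFF must be 4-D (T, B, Y, X), got shape {counts.shape}"
        )
    n_t, n_b = counts.shape[:2]
    if n_b != sidecar["n_bins"]:
        raise ContainerSchemaError(
            f"sidecar field 'n_bins' = {sidecar['n_bins']} but TIFF has {n_b} bins"
        )
    if n_t != len(sidecar["times_min"]):
        raise ContainerSchemaError(
            f"sidecar field 'times_min' lists {len(sidecar['times_min'])} frames "
            f"but TIFF has {n_t}"
        )
    if acceptor.shape != (n_t, *counts.shape[2:]):
        raise ContainerSchemaError(
            f"acceptor TIFF shape {acceptor.shape} does not match FLIM frames"
        )
    return FlimStack(
        frames=np.moveaxis(counts, 1, -1),
        acceptor=acceptor,
        times=np.asarray(sidecar["times_min"], dtype=float),
        bin_width_ns=float(sidecar["bin_width_ns"]),
        period_ns=float(sidecar["period_ns"]),
        pixel_size_um=float(sidecar["pixel_size_um"]),
        channel_roles=sidecar.get("channel_roles", {}),
        calibration_name=sidecar.get("calibration"),
    )


def write_roi_mask(rois: RoiSet, path: str | Path) -> None:
    """8-bit label image (TIFF or PNG by extension)."""
    path = Path(path)
    labels = rois.labels.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, labels)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, labels)


def read_roi_mask(path: str | Path, provenance: str | None = None) -> RoiSet:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        labels = iio.imread(path)
    return RoiSet(labels=np.asarray(labels), provenance=provenance or str(path))


def write_timecourse_csv(tc: TimeCourse, path: str | Path) -> None:
    tc.to_dataframe().to_csv(path, index=False)


def read_timecourse_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_frap_csv(result_df: pd.DataFrame, path: str | Path) -> None:
    result_df.to_csv(path, index=False)


def read_frap_experiment_csv(path: str | Path) -> FrapExperiment:
    """Load raw dual-channel FRAP traces from a tidy CSV.

    Required columns: experiment_id, roi, time_min, reporter, volume.
    """
    df = pd.read_csv(path)
    required = {"roi", "time_min", "reporter", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"FRAP CSV missing columns: {sorted(missing)}")
    times = np.sort(df["time_min"].unique())
    reporter: dict[str, np.ndarray] = {}
    volume: dict[str, np.ndarray] = {}
    for roi, grp in df.groupby("roi"):
        grp = grp.sort_values("time_min")
        if not np.allclose(grp["time_min"].to_numpy(), times):
            raise ValueError(f"ROI {roi!r} is not sampled on the common time grid")
        reporter[str(roi)] = grp["reporter"].to_numpy(dtype=float)
        volume[str(roi)] = grp["volume"].to_numpy(dtype=float)
    exp_id = str(df["experiment_id"].iloc[0]) if "experiment_id" in df.columns else ""
    return FrapExperiment(times=times, reporter=reporter, volume=volume,
                         experiment_id=exp_id)


@dataclasses.dataclass
class RunConfig:
    """Serializable settings for a reproducible analysis run."""

    calibration: str = "mTurquoise2-Rab10"
    n_bins: int = 64
    period_ns: float = 12.5
    t0_ns: float | None = None          # None: determine by image-wide fit
    tau_g_ns: float = 0.15
    baseline_window: tuple[float, float] | None = None  # None: all t < 0
    min_photons_pixel: int = 30
    min_photons_roi: int = 500
    psf_volume_fl: float = 0.1          # no in-package calibration; supply your own
    windows: tuple[str, ...] = ("transient", "sustained_sensor")
    method: str = "window"
    rng_seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_run_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "baseline_window" in data and data["baseline_window"] is not None:
        data["baseline_window"] = tuple(data["baseline_window"])
    if "windows" in data:
        data["windows"] = tuple(data["windows"])
    return RunConfig(**data)


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
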