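"""FRAP quantification of activity-dependent receptor exocytosis.

A pH-sensitive surface reporter (SEP-tagged receptor) fluoresces only at the
plasma membrane.  After photobleaching the surface pool of a dendrite,
fluorescence recovery in a stimulated spine reports newly exocytosed
receptor — but an enlarging spine also gains membrane area, and the residual
unbleached surface fluorescence per unit area (f) scales with that area.
Writing the recovery as

    ΔF = ΔF_t + f·ΔS,        F0 = f·S  (fluorescence immediately post-bleach)

and taking the surface-area change to be the volume change to the 2/3 power
(ΔS/S = (ΔV/V)^(2/3)), the trafficking component is isolated as

    ΔF_t/F = ΔF/F − (ΔV/V)^(2/3)

with ΔF/F referenced to the post-bleach fluorescence and ΔV/V measured from
a cytosolic volume marker referenced to its pre-bleach mean.  Two reference
conventions therefore coexist and are kept explicit: *display* normalization
divides each channel by its pre-bleach mean (the convention of recovery
plots), while the *correction* uses the post-bleach value as F0, per the
derivation above.

For transiently shrinking spines (ΔV/V < 0) the surface term is extended
sign-preservingly as sign(ΔV/V)·|ΔV/V|^(2/3); outputs carry a flag wherever
this extension was active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrapExperiment",
    "NormalizedFrap",
    "FrapResult",
    "frap_normalize",
    "signed_power_2_3",
    "trafficking_component",
    "frap_pipeline",
]


@dataclass
class FrapExperiment:
    """Dual-channel FRAP traces for a set of ROIs.

    ``reporter`` holds the surface-reporter fluorescence and ``volume`` the
    cytosolic volume-marker fluorescence, per ROI, on a common clock in
    minutes.  The default protocol: five pre-bleach frames at 1 min
    intervals, whole-dendrite bleach over [-2, 0] min, glutamate uncaging
    over [0, 1] min, then post frames at 1 min intervals.
    """

    times: np.ndarray
    reporter: dict[str, np.ndarray]
    volume: dict[str, np.ndarray]
    bleach_interval: tuple[float, float] = (-2.0, 0.0)
    uncaging_interval: tuple[float, float] = (0.0, 1.0)
    experiment_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.reporter = {k: np.asarray(v, dtype=float) for k, v in self.reporter.items()}
        self.volume = {k: np.asarray(v, dtype=float) for k, v in self.volume.items()}
        if set(self.reporter) != set(self.volume):
            raise ValueError("reporter and volume must cover the same ROIs")
        for name, tr in {**self.reporter, **self.volume}.items():
            if tr.shape != self.times.shape:
                raise ValueError(f"trace {name!r} length does not match times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.any(self.times < self.bleach_interval[0]):
            raise ValueError("need at least one pre-bleach frame")

    @property
    def rois(self) -> tuple[str, ...]:
        return tuple(self.reporter)

    @property
    def prebleach_mask(self) -> np.ndarray:
        return self.times < self.bleach_interval[0]

    @property
    def postbleach_mask(self) -> np.ndarray:
        return self.times >= self.bleach_interval[1]


@dataclass
class NormalizedFrap:
    """Pre-bleach-normalized (F/F0) traces plus the post-bleach floor per ROI."""

    times: np.ndarray
    reporter_f_over_f0: dict[str, np.ndarray]
    volume_f_over_f0: dict[str, np.ndarray]
    postbleach_floor: dict[str, float]
    bleach_interval: tuple[float, float]
    uncaging_interval: tuple[float, float]
    experiment_id: str = ""


def frap_normalize(exp: FrapExperiment) -> NormalizedFrap:
    """Divide each channel by its pre-bleach mean (display normalization).

    Idempotent: normalizing already-normalized traces leaves them unchanged.
    The reporter's post-bleach floor (F/F0 at the first post-bleach frame,
    typically ~0.15 for an effective bleach) is reported per ROI.
    """
    pre = exp.prebleach_mask
    post_idx = int(np.argmax(exp.postbleach_mask))
    if not exp.postbleach_mask.any():
        raise ValueError("no post-bleach frames")
    rep_norm: dict[str, np.ndarray] = {}
    vol_norm: dict[str, np.ndarray] = {}
    floor: dict[str, float] = {}
    for roi in exp.rois:
        for channel, store in ((exp.reporter, rep_norm), (exp.volume, vol_norm)):
            f0 = channel[roi][pre].mean()
            if f0 <= 0:
                raise ValueError(f"non-positive pre-bleach mean for ROI {roi!r}")
            store[roi] = channel[roi] / f0
        floor[roi] = float(rep_norm[roi][post_idx])
    return NormalizedFrap(
        times=exp.times.copy(),
        reporter_f_over_f0=rep_norm,
        volume_f_over_f0=vol_norm,
        postbleach_floor=floor,
        bleach_interval=exp.bleach_interval,
        uncaging_interval=exp.uncaging_interval,
        experiment_id=exp.experiment_id,
    )


def signed_power_2_3(x):
    """sign(x) * |x|^(2/3): the surface term, extended sign-preservingly to x < 0."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.abs(x) ** (2.0 / 3.0)
    if out.ndim == 0:
        return float(out)
    return out


def trafficking_component(reporter_df_over_f, volume_dv_over_v):
    """Trafficking component ΔF_t/F = ΔF/F − (ΔV/V)^(2/3).

    ``reporter_df_over_f`` must be referenced to the post-bleach fluorescence
    (the F0 of the derivation); ``volume_dv_over_v`` to the pre-bleach
    volume.  Negative ΔV/V uses the sign-preserving power; ΔV/V <= -1 (total
    volume loss) is invalid.  Accepts scalars or arrays.
    """
    dv = np.asarray(volume_dv_over_v, dtype=float)
    if np.any(dv <= -1):
        raise ValueError("volume change dV/V must be > -1")
    out = np.asarray(reporter_df_over_f, dtype=float) - signed_power_2_3(dv)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class FrapResult:
    """Per-ROI corrected trafficking series and timepoint summaries."""

    times: np.ndarray
    normalized: NormalizedFrap
    df_over_f_postref: dict[str, np.ndarray]  # reporter ΔF/F, post-bleach reference
    dv_over_v: dict[str, np.ndarray]          # volume ΔV/V, pre-bleach reference
    trafficking: dict[str, np.ndarray]        # ΔF_t/F per ROI
    negative_dv_flag: dict[str, np.ndarray]   # where the sign-preserving extension applied
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for roi in self.trafficking:
            for i, t in enumerate(self.times):
                rows.append({
                    "experiment_id": self.normalized.experiment_id,
                    "roi": roi,
                    "time_min": float(t),
                    "reporter_f_over_f0": float(self.normalized.reporter_f_over_f0[roi][i]),
                    "volume_f_over_f0": float(self.normalized.volume_f_over_f0[roi][i]),
                    "trafficking_component": float(self.trafficking[roi][i]),
                })
        return pd.DataFrame(rows)


def frap_pipeline(
    exp: FrapExperiment,
    summary_times: tuple[float, ...] = (0.0, 2.0),
) -> FrapResult:
    """Full FRAP analysis: normalization, volume correction, summaries.

    Per ROI: the reporter trace is referenced to its post-bleach value
    (ΔF/F), the volume trace to its pre-bleach mean (ΔV/V), and the two are
    combined into the trafficking component ΔF_t/F over all post-bleach
    frames (pre-bleach frames are NaN).  The summary table reports the
    display-normalized reporter and volume values at the requested times
    (default 0 and 2 min, nearest-frame fallback with a warning).
    """
    norm = frap_normalize(exp)
    post = exp.postbleach_mask
    post_idx = int(np.argmax(post))
    df_ref: dict[str, np.ndarray] = {}
    dvv: dict[str, np.ndarray] = {}
    traff: dict[str, np.ndarray] = {}
    neg_flag: dict[str, np.ndarray] = {}
    for roi in exp.rois:
        f0_post = exp.reporter[roi][post_idx]
        if f0_post <= 0:
            raise ValueError(f"non-positive post-bleach reporter value for ROI {roi!r}")
        df = np.full(exp.times.size, np.nan)
        df[post] = (exp.reporter[roi][post] - f0_post) / f0_post
        dv = norm.volume_f_over_f0[roi] - 1.0
        tr = np.full(exp.times.size, np.nan)
        tr[post] = trafficking_component(df[post], dv[post])
        df_ref[roi] = df
        dvv[roi] = dv
        traff[roi] = tr
        neg_flag[roi] = (dv < 0) & post

    rows = []
    for t_req in summary_times:
        idx = int(np.argmin(np.abs(exp.times - t_req)))
        if abs(exp.times[idx] - t_req) > 1e-9:
            warnings.warn(
                f"no frame at t={t_req:g} min; using nearest frame at "
                f"t={exp.times[idx]:g} min", RuntimeWarning, stacklevel=2,
            )
        for roi in exp.rois:
            rows.append({
                "experiment_id": exp.experiment_id,
                "roi": roi,
                "time_min": float(exp.times[idx]),
                "requested_time_min": float(t_req),
                "reporter_f_over_f0": float(norm.reporter_f_over_f0[roi][idx]),
                "volume_f_over_f0": float(norm.volume_f_over_f0[roi][idx]),
                "trafficking_component": float(traff[roi][idx]),
            })
    return FrapResult(
        times=exp.times.copy(),
        normalized=norm,
        df_over_f_postref=df_ref,
        dv_over_v=dvv,
        trafficking=traff,
        negative_dv_flag=neg_flag,
        summary=pd.DataFrame(rows),
    )
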