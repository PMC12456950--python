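"""Experiment-level FLIM pipeline: ROIs, time courses and window statistics.

A time-lapse experiment is a :class:`FlimStack` — per-pixel photon arrival
histograms plus an acceptor (volume-marker) intensity channel, on a clock in
minutes with the stimulus (uncaging train or bath application) starting at
t = 0.  ROIs label the stimulated spine, an adjacent non-stimulated spine,
and a stretch of dendrite.  The pipeline pools photons per ROI, estimates
the sensor bound fraction per timepoint, and reports changes relative to the
pre-stimulus baseline:

* ΔP_AD(t): absolute change of the bound fraction, in percentage points;
* ΔV/V(t): relative change of the integrated acceptor intensity in the ROI
  (a cytosolic volume proxy), in percent.

Window statistics over the transient (1.3–4 min) and sustained (19–31 min
for sensor signals, 20–35 min for structural volume) phases summarize each
experiment, and group helpers give the mean ± SEM curves and a Welch t-test
used for simple two-group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decay_model import FluorophoreCalibration
from .estimation import (
    InsufficientPhotonsError,
    PhotonHistogram,
    binding_fraction_from_mean_lifetime,
    binding_fraction_windowed,
    mean_lifetime,
    mean_photon_arrival_time,
)

__all__ = [
    "ROI_CLASS_IDS",
    "ROI_NAMES",
    "WINDOW_PRESETS",
    "FlimStack",
    "RoiSet",
    "TimeCourse",
    "GroupSummary",
    "TwoSampleSummary",
    "pool_roi_histogram",
    "roi_timecourse",
    "spine_volume",
    "window_average",
    "resample_timecourse",
    "aggregate_group",
    "two_sample_summary",
]

#: Label-image class ids (0 is background).
ROI_CLASS_IDS: dict[str, int] = {
    "stimulated_spine": 1,
    "adjacent_spine": 2,
    "dendrite": 3,
}
ROI_NAMES = tuple(ROI_CLASS_IDS)

#: Analysis windows in minutes relative to stimulus onset.
WINDOW_PRESETS: dict[str, tuple[float, float]] = {
    "transient": (1.3, 4.0),
    "sustained_sensor": (19.0, 31.0),
    "sustained_structural": (20.0, 35.0),
}


@dataclass
class FlimStack:
    """Time-lapse of per-pixel photon histograms plus acceptor intensity.

    ``frames`` is (T, Y, X, B) photon counts; ``acceptor`` is (T, Y, X)
    volume-marker intensity; ``times`` are minutes relative to stimulus
    onset, strictly increasing, with at least one pre-stimulus frame.
    """

    frames: np.ndarray
    acceptor: np.ndarray
    times: np.ndarray
    bin_width_ns: float
    period_ns: float
    pixel_size_um: float = 0.1
    channel_roles: dict = field(default_factory=lambda: {
        "donor": "FLIM photon histograms",
        "acceptor": "volume marker intensity",
    })
    calibration_name: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 4:
            raise ValueError(f"frames must be (T, Y, X, B), got shape {self.frames.shape}")
        if self.acceptor.shape != self.frames.shape[:3]:
            raise ValueError("acceptor shape must match frames (T, Y, X)")
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("times length must match number of frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.any(self.times < 0):
            raise ValueError("stack needs at least one pre-stimulus (t < 0) frame")
        if np.any(self.frames < 0):
            raise ValueError("photon counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.frames.shape[-1]

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width_ns

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ns


@dataclass
class RoiSet:
    """Label image with the named ROI classes, pairwise disjoint by construction."""

    labels: np.ndarray
    provenance: str = "manual"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D label image")

    def mask(self, name: str) -> np.ndarray:
        try:
            class_id = ROI_CLASS_IDS[name]
        except KeyError:
            raise KeyError(f"unknown ROI {name!r}; known: {ROI_NAMES}") from None
        m = self.labels == class_id
        if not m.any():
            raise ValueError(f"ROI {name!r} is empty in this label image")
        return m


@dataclass
class TimeCourse:
    """Per-ROI ΔP_AD (percentage points) and ΔV/V (%) on a common clock.

    Baseline-normalized by construction: the mean over the baseline window is
    exactly zero for both quantities.  ``p_ad`` holds the raw per-timepoint
    bound fractions, ``baseline_p_ad``/``baseline_volume`` the baseline
    values they were referenced to.
    """

    times: np.ndarray
    delta_p_ad_pct: dict[str, np.ndarray]
    delta_volume_pct: dict[str, np.ndarray]
    p_ad: dict[str, np.ndarray]
    baseline_p_ad: dict[str, float]
    baseline_volume: dict[str, float]
    n_baseline_frames: int
    experiment_id: str = ""

    @property
    def rois(self) -> tuple[str, ...]:
        return tuple(self.delta_p_ad_pct)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for roi in self.rois:
            for i, t in enumerate(self.times):
                rows.append({
                    "experiment_id": self.experiment_id,
                    "roi": roi,
                    "time_min": float(t),
                    "delta_pad_pct": float(self.delta_p_ad_pct[roi][i]),
                    "delta_vol_pct": float(self.delta_volume_pct[roi][i]),
                })
        return pd.DataFrame(rows)


def pool_roi_histogram(frame: np.ndarray, mask: np.ndarray, bin_centers: np.ndarray,
                       label: str = "") -> PhotonHistogram:
    """Binwise sum of pixel histograms within a mask; photon counts conserved."""
    frame = np.asarray(frame)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape[:2]:
        raise ValueError("mask shape must match frame (Y, X)")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    counts = frame[mask].sum(axis=0)
    return PhotonHistogram(bin_centers=np.asarray(bin_centers, dtype=float),
                           counts=counts, label=label)


def roi_timecourse(
    stack: FlimStack,
    rois: RoiSet,
    calib: FluorophoreCalibration,
    t0: float,
    tau_g: float = 0.15,
    *,
    baseline_window: tuple[float, float] | None = None,
    method: str = "window",
    min_roi_photons: int = 500,
    roi_names: tuple[str, ...] = ROI_NAMES,
    experiment_id: str = "",
) -> TimeCourse:
    """Per-ROI binding-fraction and volume time courses, baseline-normalized.

    For each ROI and timepoint the photon histograms are pooled, the mean
    arrival time gives <tau> = <t> - t0, and the bound fraction is obtained
    either by inverting the windowed mean-lifetime map (``method="window"``,
    default — unbiased under acquisition-window truncation; needs ``tau_g``
    from the image-wide fit) or by the plain closed form
    (``method="closed_form"``, which carries a documented bias when the
    window truncates the decay tail).

    ΔP_AD(t) is reported in percentage points relative to the mean bound
    fraction over the baseline window (default: all frames with t < 0);
    ΔV/V(t) is the percent change of the ROI-integrated acceptor intensity
    relative to its baseline mean.  Timepoints whose pooled photon count
    falls below ``min_roi_photons`` are NaN-masked with a warning and are
    excluded from the baseline mean.
    """
    if method not in ("window", "closed_form"):
        raise ValueError(f"unknown method {method!r}")
    if baseline_window is None:
        baseline = stack.times < 0
    else:
        baseline = (stack.times >= baseline_window[0]) & (stack.times <= baseline_window[1])
    if not baseline.any() or stack.times[baseline].max() >= 0:
        raise ValueError("baseline window must cover at least one pre-stimulus frame")

    centers = stack.bin_centers
    edges = stack.bin_edges
    n_t = stack.times.size

    p_ad: dict[str, np.ndarray] = {}
    vol: dict[str, np.ndarray] = {}
    for roi in roi_names:
        mask = rois.mask(roi)
        p_series = np.full(n_t, np.nan)
        v_series = np.full(n_t, np.nan)
        for i in range(n_t):
            hist = pool_roi_histogram(stack.frames[i], mask, centers, label=roi)
            if hist.n_photons < min_roi_photons:
                warnings.warn(
                    f"ROI {roi!r} at t={stack.times[i]:g} min has only "
                    f"{hist.n_photons} photons (< {min_roi_photons}); masked",
                    RuntimeWarning, stacklevel=2,
                )
                continue
            tau = mean_lifetime(mean_photon_arrival_time(hist), t0)
            if method == "window":
                p_series[i] = binding_fraction_windowed(tau, calib, t0, tau_g, edges)
            else:
                p_series[i] = binding_fraction_from_mean_lifetime(
                    tau, calib.tau_d, calib.tau_ad, clip=True
                )
            v_series[i] = stack.acceptor[i][mask].sum()
        p_ad[roi] = p_series
        vol[roi] = v_series

    delta_p: dict[str, np.ndarray] = {}
    delta_v: dict[str, np.ndarray] = {}
    base_p: dict[str, float] = {}
    base_v: dict[str, float] = {}
    for roi in roi_names:
        pb = p_ad[roi][baseline]
        vb = vol[roi][baseline]
        if np.all(np.isnan(pb)):
            raise InsufficientPhotonsError(f"no usable baseline frames for ROI {roi!r}")
        base_p[roi] = float(np.nanmean(pb))
        base_v[roi] = float(np.nanmean(vb))
        delta_p[roi] = (p_ad[roi] - base_p[roi]) * 100.0
        if base_v[roi] <= 0:
            raise ValueError(f"non-positive baseline acceptor intensity in ROI {roi!r}")
        delta_v[roi] = (vol[roi] - base_v[roi]) / base_v[roi] * 100.0

    return TimeCourse(
        times=stack.times.copy(),
        delta_p_ad_pct=delta_p,
        delta_volume_pct=delta_v,
        p_ad=p_ad,
        baseline_p_ad=base_p,
        baseline_volume=base_v,
        n_baseline_frames=int(baseline.sum()),
        experiment_id=experiment_id,
    )


def suggest_structure_mask(acceptor: np.ndarray) -> np.ndarray:
    """Otsu-threshold helper for drawing ROIs on the time-averaged intensity.

    Returns a binary foreground (neurite) mask from the acceptor channel,
    averaged over time if a stack is given.  This only assists manual ROI
    drawing — it does not detect or classify spines.
    """
    from skimage.filters import threshold_otsu

    acceptor = np.asarray(acceptor, dtype=float)
    mean_img = acceptor.mean(axis=0) if acceptor.ndim == 3 else acceptor
    return mean_img > threshold_otsu(mean_img)


def spine_volume(
    intensity_image: np.ndarray,
    spine_mask: np.ndarray,
    dendrite_mask: np.ndarray,
    psf_volume_fl: float,
) -> float:
    """Absolute spine volume in femtoliters.

    V = (integrated spine intensity / mean intensity in the thick dendrite)
    × PSF volume.  The dendrite is assumed thicker than the PSF so its mean
    pixel intensity reports fluorophore concentration; the ratio is then the
    spine volume in PSF units.  Invariant under global intensity scaling.
    """
    if psf_volume_fl <= 0:
        raise ValueError("psf_volume_fl must be > 0")
    intensity_image = np.asarray(intensity_image, dtype=float)
    dend = intensity_image[np.asarray(dendrite_mask, dtype=bool)]
    if dend.size == 0 or dend.mean() <= 0:
        raise ValueError("dendrite reference region is empty or non-positive")
    spine_sum = intensity_image[np.asarray(spine_mask, dtype=bool)].sum()
    return float(spine_sum / dend.mean() * psf_volume_fl)


def _select_quantity(tc: TimeCourse, quantity: str, roi: str) -> np.ndarray:
    if quantity in ("delta_pad_pct", "delta_p_ad_pct"):
        return tc.delta_p_ad_pct[roi]
    if quantity in ("delta_vol_pct", "delta_volume_pct"):
        return tc.delta_volume_pct[roi]
    if quantity == "p_ad":
        return tc.p_ad[roi]
    raise ValueError(f"unknown quantity {quantity!r}")


def window_average(
    tc: TimeCourse,
    window: str | tuple[float, float],
    quantity: str = "delta_pad_pct",
    roi: str = "stimulated_spine",
) -> float:
    """Mean of a time-course quantity over frames inside a time window.

    ``window`` is either a preset name ("transient", "sustained_sensor",
    "sustained_structural") or an explicit (start, end) in minutes; the
    endpoints are inclusive.  NaN-masked timepoints are skipped; an empty
    overlap is an error.
    """
    if isinstance(window, str):
        try:
            lo, hi = WINDOW_PRESETS[window]
        except KeyError:
            raise KeyError(
                f"unknown window preset {window!r}; known: {sorted(WINDOW_PRESETS)}"
            ) from None
    else:
        lo, hi = window
    sel = (tc.times >= lo) & (tc.times <= hi)
    vals = _select_quantity(tc, quantity, roi)[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(f"window [{lo}, {hi}] min contains no usable timepoints")
    return float(vals.mean())


def resample_timecourse(tc: TimeCourse, new_times: np.ndarray) -> TimeCourse:
    """Linear interpolation of all series onto a new time grid."""
    new_times = np.asarray(new_times, dtype=float)

    def interp(y: np.ndarray) -> np.ndarray:
        ok = ~np.isnan(y)
        return np.interp(new_times, tc.times[ok], y[ok])

    return TimeCourse(
        times=new_times,
        delta_p_ad_pct={r: interp(v) for r, v in tc.delta_p_ad_pct.items()},
        delta_volume_pct={r: interp(v) for r, v in tc.delta_volume_pct.items()},
        p_ad={r: interp(v) for r, v in tc.p_ad.items()},
        baseline_p_ad=dict(tc.baseline_p_ad),
        baseline_volume=dict(tc.baseline_volume),
        n_baseline_frames=tc.n_baseline_frames,
        experiment_id=tc.experiment_id,
    )


@dataclass
class GroupSummary:
    """Per-timepoint mean ± SEM across experiments, per ROI and quantity."""

    times: np.ndarray
    mean: dict[tuple[str, str], np.ndarray]  # (roi, quantity) -> (T,)
    sem: dict[tuple[str, str], np.ndarray]
    n: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (roi, quantity), m in self.mean.items():
            s = self.sem[(roi, quantity)]
            for i, t in enumerate(self.times):
                rows.append({
                    "roi": roi, "quantity": quantity, "time_min": float(t),
                    "mean": float(m[i]), "sem": float(s[i]), "n": self.n,
                })
        return pd.DataFrame(rows)


def aggregate_group(timecourses: list[TimeCourse]) -> GroupSummary:
    """Mean, SEM = SD/sqrt(n) and n per timepoint across experiments.

    All time courses must share a common time grid (use
    :func:`resample_timecourse` first otherwise).  With n = 1 the SEM is NaN.
    """
    if not timecourses:
        raise ValueError("need at least one time course")
    times = timecourses[0].times
    for tc in timecourses[1:]:
        if tc.times.shape != times.shape or not np.allclose(tc.times, times):
            raise ValueError("time grids differ; resample to a common grid first")
    n = len(timecourses)
    mean: dict[tuple[str, str], np.ndarray] = {}
    sem: dict[tuple[str, str], np.ndarray] = {}
    for quantity in ("delta_pad_pct", "delta_vol_pct"):
        for roi in timecourses[0].rois:
            arr = np.stack([_select_quantity(tc, quantity, roi) for tc in timecourses])
            mean[(roi, quantity)] = np.nanmean(arr, axis=0)
            if n > 1:
                sem[(roi, quantity)] = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(n)
            else:
                sem[(roi, quantity)] = np.full(times.size, np.nan)
    return GroupSummary(times=times.copy(), mean=mean, sem=sem, n=n)


@dataclass
class TwoSampleSummary:
    difference: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    degenerate: bool = False


def two_sample_summary(
    group_a: list[TimeCourse],
    group_b: list[TimeCourse],
    window: str | tuple[float, float],
    quantity: str = "delta_pad_pct",
    roi: str = "stimulated_spine",
) -> TwoSampleSummary:
    """Welch two-sample t-test on per-experiment window averages.

    Convenience comparison of two experimental groups (e.g. control vs drug)
    on their transient- or sustained-window means.  With zero variance in
    both groups the test is degenerate and flagged (identical groups give
    difference 0 and p = NaN rather than a fabricated p-value).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs n >= 2 experiments")
    a = np.array([window_average(tc, window, quantity, roi) for tc in group_a])
    b = np.array([window_average(tc, window, quantity, roi) for tc in group_b])
    diff = float(a.mean() - b.mean())
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(a, b, equal_var=False)
    return TwoSampleSummary(
        difference=diff,
        t_statistic=float(t_stat),
        p_value=float(p),
        n_a=a.size,
        n_b=b.size,
        degenerate=degenerate,
    )
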