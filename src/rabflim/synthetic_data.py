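"""Synthetic 2pFLIM and FRAP experiments with known ground truth.

Every statistical assumption the analysis makes is reproduced by a forward
model here: photon arrival times follow the two-component IRF-convolved
decay with Poisson counting noise, FLIM stacks carry a dendrite-plus-spines
geometry with programmed per-ROI bound-fraction and volume trajectories, and
FRAP traces are built from the additive surface + trafficking decomposition
that the correction inverts.  Generators are fully determined by their seed.

A subtlety of the photon sampler: under the amplitude convention of the
decay model, a component's photon yield is proportional to its amplitude
*times its lifetime* (a slower component emits for longer).  The probability
that a photon originates from the bound component is therefore

    q_AD = P_AD * tau_AD / (P_D * tau_D + P_AD * tau_AD)

and not P_AD itself.

Trajectory amplitudes shipped in the preset scenarios are qualitative
defaults chosen to resemble typical uncaging experiments (a several-fold
transient spine-volume overshoot decaying to a sub-fold sustained plateau;
a few-percentage-point sensor response); they are configuration, not
reference values, and recovery tests always compare against what a scenario
actually programmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_dilation

from .decay_model import DecayModelParams, expected_bin_counts, get_calibration
from .flim_imaging import ROI_CLASS_IDS, FlimStack, RoiSet
from .frap_exocytosis import FrapExperiment, signed_power_2_3

__all__ = [
    "scenario_from_yaml",
    "scenario_to_yaml",
    "ScenarioConfig",
    "FrapScenarioConfig",
    "StackGroundTruth",
    "FrapGroundTruth",
    "sample_arrival_times",
    "make_flim_stack",
    "make_frap_experiment",
    "sltp_frame_times",
    "nmda_frame_times",
    "rab10_sltp_scenario",
    "rab4_sltp_scenario",
    "null_scenario",
]


def sample_arrival_times(
    params: DecayModelParams,
    n_photons: int,
    seed: int | np.random.Generator | None = None,
    *,
    wrap_period: float | None = None,
    window: tuple[float, float] | None = None,
    return_components: bool = False,
):
    """Draw photon arrival times from the two-component decay model.

    Each photon is ``t = t0 + Normal(0, tau_G) + Exponential(tau_k)`` with
    component k chosen with probability proportional to ``P_k * tau_k``
    (lifetime-weighted photon yield).  ``wrap_period`` folds times into
    [0, period) as a repetitive-excitation detector would; ``window``
    discards photons outside [lo, hi] (so fewer than ``n_photons`` may be
    returned).  With ``return_components`` a boolean array marks photons
    from the bound (AD) component.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    yield_d = params.p_d * params.tau_d
    yield_ad = params.p_ad * params.tau_ad
    q_ad = yield_ad / (yield_d + yield_ad)
    from_ad = rng.random(n_photons) < q_ad
    tau = np.where(from_ad, params.tau_ad, params.tau_d)
    t = params.t0 + rng.normal(0.0, params.tau_g, n_photons) \
        + rng.exponential(1.0, n_photons) * tau
    if wrap_period is not None:
        t = np.mod(t, wrap_period)
    if window is not None:
        keep = (t >= window[0]) & (t <= window[1])
        t = t[keep]
        from_ad = from_ad[keep]
    if return_components:
        return t, from_ad
    return t


# --------------------------------------------------------------------------
# Imaging scenarios
# --------------------------------------------------------------------------

def sltp_frame_times() -> tuple[float, ...]:
    """Default sLTP time grid (min): 4 baseline frames, one frame during the
    0.5 Hz x 60 s uncaging train, dense early sampling, sparser late."""
    return (-4.0, -3.0, -2.0, -1.0, 0.5,
            1.3, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0,
            13.0, 16.0, 19.0, 22.0, 25.0, 28.0, 31.0)


def nmda_frame_times() -> tuple[float, ...]:
    """Bath-application grid: 6 min baseline, 2 min application (t in [0, 2]),
    32 min washout."""
    return (-6.0, -5.0, -4.0, -3.0, -2.0, -1.0, 1.0, 2.0,
            3.0, 4.0, 6.0, 8.0, 10.0, 13.0, 16.0, 19.0, 22.0,
            25.0, 28.0, 31.0, 34.0)


@dataclass
class ScenarioConfig:
    """Everything that defines one synthetic imaging experiment.

    Geometry is a horizontal dendrite shaft with two circular spines above
    it; the stimulated spine carries the programmed bound-fraction and
    volume trajectories, every other ROI stays at baseline.  The seed fully
    determines the generated stack.
    """

    name: str = "custom"
    # geometry
    image_shape: tuple[int, int] = (32, 32)
    pixel_size_um: float = 0.1
    dendrite_rows: tuple[int, int] = (22, 25)          # inclusive row band
    stim_spine_center: tuple[int, int] = (10, 8)
    stim_spine_radius: float = 3.0
    adj_spine_center: tuple[int, int] = (10, 24)
    adj_spine_radius: float = 3.0
    # acquisition
    frame_times: tuple[float, ...] = field(default_factory=sltp_frame_times)
    stimulus: str = "uncaging"                         # "uncaging" (0.5 Hz x 60 s) or "nmda" (2 min bath)
    n_bins: int = 64
    period_ns: float = 12.5
    photons_per_spine: float = 10_000.0
    background_fraction: float = 0.01
    acceptor_scale: float = 150.0                      # counts/pixel at baseline
    # photophysics
    calibration: str = "mTurquoise2-Rab10"
    t0_ns: float = 1.0
    tau_g_ns: float = 0.15
    # programmed trajectories (applied to the stimulated spine)
    baseline_p_ad: dict = field(default_factory=lambda: {
        "stimulated_spine": 0.3, "adjacent_spine": 0.3, "dendrite": 0.3,
    })
    pad_shape: str = "flat"                            # "flat" | "step" | "pulse"
    pad_amplitude: float = 0.0                         # bound-fraction units (signed)
    pad_tau_min: float = 2.0                           # pulse decay constant
    vol_transient: float = 2.5                         # transient dV/V amplitude (fraction)
    vol_sustained: float = 0.8                         # dV/V plateau (fraction)
    vol_tau_min: float = 2.0                           # transient decay constant
    vol_rise_min: float = 0.5                          # rise constant during the train
    growth_mode: str = "intensity"                     # "intensity" | "dilate"
    seed: int = 0

    @property
    def bin_width_ns(self) -> float:
        return self.period_ns / self.n_bins


def rab10_sltp_scenario(**overrides) -> ScenarioConfig:
    """Rab10-like sLTP experiment: sustained sensor step (inactivation) in the
    stimulated spine plus a two-phase volume transient."""
    cfg = ScenarioConfig(
        name="rab10_sltp",
        calibration="mTurquoise2-Rab10",
        pad_shape="step",
        pad_amplitude=-0.05,
    )
    return replace(cfg, **overrides)


def rab4_sltp_scenario(**overrides) -> ScenarioConfig:
    """Rab4-like sLTP experiment: transient sensor pulse (activation, ~2 min
    decay) in the stimulated spine plus a two-phase volume transient."""
    cfg = ScenarioConfig(
        name="rab4_sltp",
        calibration="mEGFP-Rab4a",
        baseline_p_ad={"stimulated_spine": 0.15, "adjacent_spine": 0.15, "dendrite": 0.15},
        pad_shape="pulse",
        pad_amplitude=0.08,
        pad_tau_min=2.0,
    )
    return replace(cfg, **overrides)


def null_scenario(**overrides) -> ScenarioConfig:
    """Flat trajectories everywhere: the negative-control experiment."""
    cfg = ScenarioConfig(name="null", pad_shape="flat", pad_amplitude=0.0,
                         vol_transient=0.0, vol_sustained=0.0)
    return replace(cfg, **overrides)


def _pad_delta(cfg: ScenarioConfig, t: np.ndarray) -> np.ndarray:
    after = t >= 0
    if cfg.pad_shape == "flat":
        return np.zeros_like(t)
    if cfg.pad_shape == "step":
        return np.where(after, cfg.pad_amplitude, 0.0)
    if cfg.pad_shape == "pulse":
        return np.where(after, cfg.pad_amplitude * np.exp(-np.maximum(t, 0.0) / cfg.pad_tau_min), 0.0)
    raise ValueError(f"unknown pad_shape {cfg.pad_shape!r}")


def _two_phase_volume(t: np.ndarray, transient: float, sustained: float,
                      tau_decay: float, tau_rise: float) -> np.ndarray:
    """dV/V(t): zero before onset (dV/V(0) = 0 exactly), rises with
    ``tau_rise`` during the stimulus, decays with ``tau_decay`` from the
    transient amplitude to the sustained plateau."""
    tp = np.maximum(t, 0.0)
    decay = np.exp(-tp / tau_decay)
    rise = 1.0 - np.exp(-tp / tau_rise)
    two_phase = sustained + (transient - sustained) * decay
    return np.where(t >= 0, two_phase * rise, 0.0)


def _vol_delta(cfg: ScenarioConfig, t: np.ndarray) -> np.ndarray:
    return _two_phase_volume(t, cfg.vol_transient, cfg.vol_sustained,
                             cfg.vol_tau_min, cfg.vol_rise_min)


def _disk(shape: tuple[int, int], center: tuple[int, int], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def _render_labels(cfg: ScenarioConfig, stim_radius: float) -> np.ndarray:
    shape = cfg.image_shape
    labels = np.zeros(shape, dtype=np.uint8)
    dend = np.zeros(shape, dtype=bool)
    dend[cfg.dendrite_rows[0]: cfg.dendrite_rows[1] + 1, :] = True
    stim = _disk(shape, cfg.stim_spine_center, stim_radius)
    adj = _disk(shape, cfg.adj_spine_center, cfg.adj_spine_radius)
    if (stim & adj).any() or (stim & dend).any() or (adj & dend).any():
        raise ValueError("ROI geometry overlaps; adjust centers/radii/dendrite rows")
    labels[dend] = ROI_CLASS_IDS["dendrite"]
    labels[stim] = ROI_CLASS_IDS["stimulated_spine"]
    labels[adj] = ROI_CLASS_IDS["adjacent_spine"]
    return labels


@dataclass
class StackGroundTruth:
    """Programmed truth saved alongside a generated stack."""

    config: ScenarioConfig
    times: np.ndarray
    p_ad: dict[str, np.ndarray]              # bound fraction per ROI per frame
    delta_p_ad_pct: dict[str, np.ndarray]    # percentage points vs baseline
    delta_volume_pct: dict[str, np.ndarray]  # percent vs baseline
    t0_ns: float
    tau_g_ns: float
    calibration: str


def make_flim_stack(
    cfg: ScenarioConfig, seed: int | None = None
) -> tuple[FlimStack, RoiSet, StackGroundTruth]:
    """Render a synthetic FLIM experiment from a scenario.

    Per frame and pixel, photon-bin counts are Poisson with intensity equal
    to the pixel rate times the model bin probabilities at the pixel's
    programmed bound fraction (equivalent to sampling individual photon
    arrival times and binning, by Poisson thinning).  The donor photon rate
    and the acceptor intensity of the stimulated spine both scale with
    (1 + dV/V); in ``growth_mode="dilate"`` the spine footprint additionally
    grows as (1 + dV/V)^(1/3) in radius, and the returned ROI mask includes
    a safety margin so the integrated intensity remains inside the mask.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    calib = get_calibration(cfg.calibration)
    times = np.asarray(cfg.frame_times, dtype=float)
    labels0 = _render_labels(cfg, cfg.stim_spine_radius)
    edges = np.arange(cfg.n_bins + 1) * cfg.bin_width_ns

    pad_delta = _pad_delta(cfg, times)
    vol_delta = _vol_delta(cfg, times)
    base_pad = dict(cfg.baseline_p_ad)
    for roi, p0 in base_pad.items():
        target = p0 + (pad_delta if roi == "stimulated_spine" else 0.0)
        if np.any((np.asarray(target) < 0) | (np.asarray(target) > 1)):
            raise ValueError(f"programmed bound fraction for {roi!r} leaves [0, 1]")

    n_stim_pix0 = int((labels0 == ROI_CLASS_IDS["stimulated_spine"]).sum())
    rate0 = cfg.photons_per_spine / n_stim_pix0  # photons / pixel / frame

    def bin_probs(p_ad: float) -> np.ndarray:
        params = DecayModelParams(
            f0=1.0, t0=cfg.t0_ns, tau_d=calib.tau_d, tau_ad=calib.tau_ad,
            tau_g=cfg.tau_g_ns, p_ad=p_ad,
        )
        return expected_bin_counts(params, edges, 1.0, normalization="untruncated")

    shape = cfg.image_shape
    n_t = times.size
    frames = np.zeros((n_t, *shape, cfg.n_bins), dtype=np.int64)
    acceptor = np.zeros((n_t, *shape))

    for i in range(n_t):
        growth = 1.0 + vol_delta[i]
        if cfg.growth_mode == "dilate":
            radius = cfg.stim_spine_radius * growth ** (1.0 / 3.0)
            labels = _render_labels(cfg, radius)
            n_stim_pix = int((labels == ROI_CLASS_IDS["stimulated_spine"]).sum())
        else:
            labels = labels0
            n_stim_pix = n_stim_pix0

        for roi, class_id in ROI_CLASS_IDS.items():
            mask = labels == class_id
            p = base_pad[roi] + (pad_delta[i] if roi == "stimulated_spine" else 0.0)
            probs = bin_probs(float(p))
            if roi == "stimulated_spine":
                # total donor photons and acceptor signal scale with volume
                rate = cfg.photons_per_spine * growth / n_stim_pix
                acc = cfg.acceptor_scale * (n_stim_pix0 / n_stim_pix) * growth
            else:
                rate = rate0
                acc = cfg.acceptor_scale
            npix = int(mask.sum())
            frames[i][mask] = rng.poisson(rate * probs, size=(npix, cfg.n_bins))
            acceptor[i][mask] = rng.poisson(acc, size=npix)

        bg = labels == 0
        bg_rate = cfg.background_fraction * rate0
        bg_probs = bin_probs(base_pad["dendrite"])
        frames[i][bg] = rng.poisson(bg_rate * bg_probs, size=(int(bg.sum()), cfg.n_bins))
        acceptor[i][bg] = rng.poisson(cfg.background_fraction * cfg.acceptor_scale,
                                      size=int(bg.sum()))

    if cfg.growth_mode == "dilate":
        # analysis mask with margin so the grown spine stays inside it
        margin = int(np.ceil(cfg.stim_spine_radius *
                             ((1.0 + max(vol_delta.max(), 0.0)) ** (1.0 / 3.0) - 1.0))) + 1
        stim_mask = binary_dilation(labels0 == ROI_CLASS_IDS["stimulated_spine"],
                                    iterations=margin)
        roi_labels = labels0.copy()
        roi_labels[stim_mask & (labels0 == 0)] = ROI_CLASS_IDS["stimulated_spine"]
    else:
        roi_labels = labels0

    stack = FlimStack(
        frames=frames, acceptor=acceptor, times=times,
        bin_width_ns=cfg.bin_width_ns, period_ns=cfg.period_ns,
        pixel_size_um=cfg.pixel_size_um, calibration_name=cfg.calibration,
    )
    rois = RoiSet(labels=roi_labels, provenance=f"synthetic:{cfg.name}")

    baseline = times < 0
    truth_pad = {}
    truth_dpad = {}
    truth_dvol = {}
    for roi in ROI_CLASS_IDS:
        p_series = base_pad[roi] + (pad_delta if roi == "stimulated_spine" else 0.0)
        p_series = np.broadcast_to(p_series, times.shape).astype(float)
        truth_pad[roi] = p_series.copy()
        truth_dpad[roi] = (p_series - p_series[baseline].mean()) * 100.0
        v_series = 1.0 + (vol_delta if roi == "stimulated_spine" else np.zeros_like(times))
        truth_dvol[roi] = (v_series / v_series[baseline].mean() - 1.0) * 100.0
    truth = StackGroundTruth(
        config=cfg, times=times, p_ad=truth_pad, delta_p_ad_pct=truth_dpad,
        delta_volume_pct=truth_dvol, t0_ns=cfg.t0_ns, tau_g_ns=cfg.tau_g_ns,
        calibration=cfg.calibration,
    )
    return stack, rois, truth


_TUPLE_FIELDS = ("image_shape", "dendrite_rows", "stim_spine_center",
                 "adj_spine_center", "frame_times")


def scenario_to_yaml(cfg: ScenarioConfig, path) -> None:
    import dataclasses
    from pathlib import Path

    import yaml

    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))


def scenario_from_yaml(path) -> ScenarioConfig:
    import dataclasses
    from pathlib import Path

    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    for key in _TUPLE_FIELDS:
        if key in data:
            data[key] = tuple(data[key])
    return ScenarioConfig(**data)


# --------------------------------------------------------------------------
# FRAP scenarios
# --------------------------------------------------------------------------

def _frap_times() -> tuple[float, ...]:
    # five 1-min-interval baseline frames, bleach over [-2, 0], post frames 0..8
    return (-7.0, -6.0, -5.0, -4.0, -3.0,
            0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)


@dataclass
class FrapScenarioConfig:
    """One synthetic FRAP experiment: per-ROI volume and trafficking programs.

    The reporter is generated as f*S(t) + trafficked(t), with the surface
    area following the same 2/3-power convention the correction assumes
    (dS/S = sign(dV/V) |dV/V|^(2/3)); bleach drops the surface brightness per
    area to ``bleach_floor`` of its pre-bleach value.  Trafficking is a
    saturating influx amp*(1 - exp(-t/tau)) expressed as a fraction of the
    post-bleach fluorescence.  ``noise_sd`` is additive Gaussian noise
    relative to each channel's pre-bleach mean; 0 gives the noiseless case.
    """

    name: str = "frap_custom"
    times: tuple[float, ...] = field(default_factory=_frap_times)
    rois: tuple[str, ...] = ("stimulated_spine", "adjacent_spine", "dendrite")
    bleach_floor: float = 0.15
    vol_transient: dict = field(default_factory=lambda: {"stimulated_spine": 3.5})
    vol_sustained: dict = field(default_factory=lambda: {"stimulated_spine": 0.8})
    vol_tau_min: float = 2.0
    vol_rise_min: float = 0.5
    trafficking_amplitude: dict = field(default_factory=lambda: {
        "stimulated_spine": 4.0, "adjacent_spine": 0.3, "dendrite": 0.6,
    })
    trafficking_tau_min: float = 1.5
    reporter_scale: float = 100.0
    volume_scale: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class FrapGroundTruth:
    config: FrapScenarioConfig
    times: np.ndarray
    trafficked_over_f0: dict[str, np.ndarray]  # programmed ΔF_t/F0(post) per ROI
    dv_over_v: dict[str, np.ndarray]


def make_frap_experiment(
    cfg: FrapScenarioConfig, seed: int | None = None
) -> tuple[FrapExperiment, FrapGroundTruth]:
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    times = np.asarray(cfg.times, dtype=float)
    post = times >= 0.0
    reporter: dict[str, np.ndarray] = {}
    volume: dict[str, np.ndarray] = {}
    truth_traff: dict[str, np.ndarray] = {}
    truth_dv: dict[str, np.ndarray] = {}
    for roi in cfg.rois:
        a1 = cfg.vol_transient.get(roi, 0.0)
        a2 = cfg.vol_sustained.get(roi, 0.0)
        dv = _two_phase_volume(times, a1, a2, cfg.vol_tau_min, cfg.vol_rise_min)
        ds = signed_power_2_3(dv)
        surface = cfg.reporter_scale * (1.0 + ds)

        amp = cfg.trafficking_amplitude.get(roi, 0.0)
        traff_frac = np.where(
            post, amp * (1.0 - np.exp(-np.maximum(times, 0.0) / cfg.trafficking_tau_min)), 0.0
        )
        f0_post = cfg.bleach_floor * surface[np.argmax(post)]
        rep = np.where(post, cfg.bleach_floor * surface + traff_frac * f0_post, surface)
        vol = cfg.volume_scale * (1.0 + dv)
        if cfg.noise_sd > 0:
            rep = rep + rng.normal(0.0, cfg.noise_sd * cfg.reporter_scale, times.size)
            vol = vol + rng.normal(0.0, cfg.noise_sd * cfg.volume_scale, times.size)
        reporter[roi] = rep
        volume[roi] = vol
        truth_traff[roi] = np.where(post, traff_frac, np.nan)
        truth_dv[roi] = dv

    exp = FrapExperiment(
        times=times, reporter=reporter, volume=volume,
        bleach_interval=(-2.0, 0.0), uncaging_interval=(0.0, 1.0),
        experiment_id=cfg.name,
    )
    truth = FrapGroundTruth(config=cfg, times=times,
                            trafficked_over_f0=truth_traff, dv_over_v=truth_dv)
    return exp, truth
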