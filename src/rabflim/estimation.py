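"""Lifetime and binding-fraction estimation from photon arrival-time histograms.

Two estimation routes are provided, mirroring common 2pFLIM practice:

1. *Mean arrival time*: the count-weighted mean photon arrival time <t> minus
   the pulse offset t0 gives the mean lifetime <tau>, which a closed form
   converts to the bound fraction P_AD.  Fast enough for per-pixel maps and
   per-ROI time courses.
2. *Curve fitting*: maximum-likelihood fit of the IRF-convolved two-component
   model to a histogram, used image-wide to determine t0 and tau_G, which are
   then frozen for all per-ROI work within a session.

The closed form assumes <tau> is the untruncated amplitude-weighted mean
lifetime.  When the acquisition window cuts off the decay tail (e.g. a
12.5 ns window for a 2.6 ns lifetime), the windowed <tau> is biased low; the
window-aware inversion here removes that bias by inverting the model's
*windowed* mean-lifetime map instead of the closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar

from .decay_model import (
    DecayModelParams,
    FluorophoreCalibration,
    InvalidParameterError,
    expected_bin_counts,
    irf_convolved_exponential_integral,
)

__all__ = [
    "InsufficientPhotonsError",
    "SingularityError",
    "PhotonHistogram",
    "FitResult",
    "mean_photon_arrival_time",
    "mean_lifetime",
    "binding_fraction_from_mean_lifetime",
    "binding_fraction_windowed",
    "model_window_mean_lifetime",
    "fit_decay_curve",
    "lifetime_map",
]


class InsufficientPhotonsError(ValueError):
    """Raised when a histogram has too few photons for the requested estimate."""


class SingularityError(ValueError):
    """Raised when a mean lifetime lies outside the physically invertible range."""


@dataclass
class PhotonHistogram:
    """Binned photon arrival-time counts for one pixel, ROI or frame.

    ``bin_centers`` must be uniformly spaced (constant to within 1e-9 ns);
    ``counts`` are non-negative.
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_centers.shape != self.counts.shape or self.bin_centers.ndim != 1:
            raise ValueError("bin_centers and counts must be 1-D arrays of equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_centers.size > 1:
            spacing = np.diff(self.bin_centers)
            if np.ptp(spacing) > 1e-9 or spacing[0] <= 0:
                raise ValueError("bin_centers must be uniformly spaced and increasing")

    @property
    def n_photons(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    @property
    def bin_edges(self) -> np.ndarray:
        w = self.bin_width
        return np.concatenate([self.bin_centers - w / 2, [self.bin_centers[-1] + w / 2]])


@dataclass
class FitResult:
    """Outcome of a decay-curve fit.

    ``p_ad_raw`` preserves the unconstrained optimum when the fitted bound
    fraction had to be clipped into [0, 1].
    """

    params: DecayModelParams
    fixed: frozenset = field(default_factory=frozenset)
    objective_value: float = np.nan
    n_photons: int = 0
    converged: bool = False
    p_ad_raw: float = np.nan
    message: str = ""


def mean_photon_arrival_time(hist: PhotonHistogram) -> float:
    """Count-weighted mean photon arrival time <t> over the histogram window."""
    total = hist.counts.sum()
    if total < 1:
        raise InsufficientPhotonsError("histogram holds no photons")
    return float((hist.bin_centers * hist.counts).sum() / total)


def mean_lifetime(t_mean: float, t0: float) -> float:
    """Mean fluorescence lifetime <tau> = <t> - t0."""
    return t_mean - t0


def binding_fraction_from_mean_lifetime(tau_mean, tau_d: float, tau_ad: float, *, clip: bool = False):
    """Closed-form bound fraction from the amplitude-weighted mean lifetime.

        P_AD = tau_D (tau_D - <tau>) / [ (tau_D - tau_AD) (tau_D + tau_AD - <tau>) ]

    This inverts <tau> = (P_D tau_D^2 + P_AD tau_AD^2) / (P_D tau_D + P_AD tau_AD)
    exactly.  Accepts scalars or arrays.  With ``clip=True`` results are
    mapped into [0, 1]; keep the raw value for diagnostics if needed.
    """
    if not (tau_d > tau_ad > 0):
        raise InvalidParameterError(f"require tau_d > tau_ad > 0, got {tau_d}, {tau_ad}")
    tau_mean = np.asarray(tau_mean, dtype=float)
    if np.any(tau_mean >= tau_d + tau_ad):
        raise SingularityError(
            f"mean lifetime >= tau_d + tau_ad = {tau_d + tau_ad} ns is outside the "
            "physical range of the two-component model"
        )
    p = tau_d * (tau_d - tau_mean) / ((tau_d - tau_ad) * (tau_d + tau_ad - tau_mean))
    if clip:
        p = np.clip(p, 0.0, 1.0)
    if p.ndim == 0:
        return float(p)
    return p


def model_window_mean_lifetime(
    p_ad: float,
    calib: FluorophoreCalibration,
    t0: float,
    tau_g: float,
    bin_edges: np.ndarray,
) -> float:
    """Model-predicted windowed mean lifetime: binned <t> over the window minus t0.

    Matches exactly how :func:`mean_photon_arrival_time` treats data — same
    bin centers, same truncation — so the inversion below is consistent with
    the measurement.  ``p_ad`` outside [0, 1] is allowed here (signed mixture)
    to let the inversion report raw values beyond the physical range.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])

    def comp(tau: float) -> np.ndarray:
        return np.diff(irf_convolved_exponential_integral(bin_edges, t0, tau, tau_g))

    mix = (1.0 - p_ad) * comp(calib.tau_d) + p_ad * comp(calib.tau_ad)
    total = mix.sum()
    if total <= 0:
        raise InvalidParameterError("mixture mass non-positive in window")
    return float((centers * mix).sum() / total) - t0


def binding_fraction_windowed(
    tau_mean_window: float,
    calib: FluorophoreCalibration,
    t0: float,
    tau_g: float,
    bin_edges: np.ndarray,
    *,
    clip: bool = True,
) -> float:
    """Bound fraction by inverting the *windowed* mean-lifetime map.

    Solves model_window_mean_lifetime(p) = tau_mean_window for p by bisection
    (the map is strictly decreasing in p).  Unbiased under window truncation,
    unlike the plain closed form.  Values outside [0, 1] are bracketed on
    [-0.5, 1.5] (the widest interval on which the signed mixture keeps
    positive mass for all shipped calibrations) so the raw solution is
    recoverable; ``clip`` controls whether the returned value is mapped into
    [0, 1].
    """

    def g(p: float) -> float:
        return model_window_mean_lifetime(p, calib, t0, tau_g, bin_edges) - tau_mean_window

    lo, hi = -0.5, 1.5
    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        # Outside even the extended bracket: fall back to the closed form.
        p = binding_fraction_from_mean_lifetime(
            tau_mean_window, calib.tau_d, calib.tau_ad, clip=False
        )
    else:
        p = brentq(g, lo, hi, xtol=1e-12)
    if clip:
        return float(np.clip(p, 0.0, 1.0))
    return float(p)


def _multinomial_nll(counts: np.ndarray, integrals: np.ndarray) -> float:
    p = integrals / integrals.sum()
    return float(-(counts * np.log(np.maximum(p, 1e-300))).sum())


def _wls_objective(counts: np.ndarray, integrals: np.ndarray) -> float:
    # Neyman-weighted least squares with the amplitude profiled out:
    # weights 1/max(c_i, 1) approximate the Poisson variance
    w = 1.0 / np.maximum(counts, 1.0)
    amp = (w * counts * integrals).sum() / (w * integrals**2).sum()
    return float((w * (counts - amp * integrals) ** 2).sum())


_FREE_DEFAULT = frozenset({"f0", "t0", "tau_g", "p_ad"})
_ALL_PARAMS = ("f0", "t0", "tau_g", "p_ad", "tau_d", "tau_ad")


def fit_decay_curve(
    hist: PhotonHistogram,
    calib: FluorophoreCalibration,
    free: set[str] | frozenset[str] | tuple[str, ...] = _FREE_DEFAULT,
    init: DecayModelParams | None = None,
    *,
    objective: str = "mle",
    min_photons: int = 100,
    wrap_period: float | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the two-component decay to a histogram.

    The likelihood is the multinomial over window-renormalized bin
    probabilities — the Poisson photon-counting likelihood with the amplitude
    profiled out (the amplitude MLE always matches the observed total, so F0
    is recovered afterwards from the total count and is reported free
    whenever "f0" is in ``free``).  Lifetimes stay fixed at the calibration
    values unless "tau_d"/"tau_ad" are explicitly freed.

    For image-wide fits free {f0, t0, tau_g, p_ad} (the default); for per-ROI
    fits freeze t0 and tau_g from the image-wide fit and free {f0, p_ad}.
    Non-convergence is flagged on the result, never silent.
    """
    if objective not in ("mle", "wls"):
        raise ValueError(f"unknown objective {objective!r}")
    loss = _multinomial_nll if objective == "mle" else _wls_objective
    free = frozenset(free)
    unknown = free - set(_ALL_PARAMS)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    if hist.n_photons < min_photons:
        raise InsufficientPhotonsError(
            f"{hist.n_photons} photons < required minimum {min_photons}"
        )

    edges = hist.bin_edges
    counts = np.asarray(hist.counts, dtype=float)

    if init is None:
        tau_g0 = 0.15
        peak_t = float(hist.bin_centers[np.argmax(counts)])
        init = DecayModelParams(
            f0=1.0,
            t0=peak_t - tau_g0,
            tau_d=calib.tau_d,
            tau_ad=calib.tau_ad,
            tau_g=tau_g0,
            p_ad=0.3,
        )

    shape_free = [p for p in ("t0", "tau_g", "p_ad", "tau_d", "tau_ad") if p in free]
    current = {
        "t0": init.t0,
        "tau_g": init.tau_g,
        "p_ad": init.p_ad,
        "tau_d": init.tau_d if "tau_d" in free else calib.tau_d,
        "tau_ad": init.tau_ad if "tau_ad" in free else calib.tau_ad,
    }
    bounds_map = {
        "t0": (edges[0] - 2.0, edges[-1]),
        "tau_g": (5e-3, 2.0),
        "p_ad": (0.0, 1.0),
        "tau_d": (0.05, 10.0),
        "tau_ad": (0.05, 10.0),
    }

    def integrals_for(vals: dict[str, float]) -> np.ndarray:
        params = DecayModelParams(
            f0=1.0,
            t0=vals["t0"],
            tau_d=vals["tau_d"],
            tau_ad=vals["tau_ad"],
            tau_g=vals["tau_g"],
            p_ad=min(max(vals["p_ad"], 0.0), 1.0),
        )
        from .decay_model import _mixture_bin_integrals

        return _mixture_bin_integrals(params, edges, wrap_period)

    raw_p = np.nan
    if shape_free == ["p_ad"]:
        # ROI-fit fast path: t0/tau_g frozen, so the two component integral
        # vectors are constant and the objective is 1-D in p_ad.
        def comp(tau: float) -> np.ndarray:
            v = np.diff(irf_convolved_exponential_integral(edges, current["t0"], tau, current["tau_g"]))
            if wrap_period is not None:
                for k in range(1, 64):
                    extra = np.diff(
                        irf_convolved_exponential_integral(
                            edges + k * wrap_period, current["t0"], tau, current["tau_g"]
                        )
                    )
                    v = v + extra
                    if extra.sum() < 1e-12 * tau:
                        break
            return v

        int_d = comp(current["tau_d"])
        int_ad = comp(current["tau_ad"])

        def nll_p(p: float) -> float:
            return loss(counts, (1.0 - p) * int_d + p * int_ad)

        res = minimize_scalar(nll_p, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-10})
        current["p_ad"] = float(res.x)
        raw_p = float(res.x)
        obj = float(res.fun)
        converged = bool(res.success)
        message = getattr(res, "message", "")
    elif shape_free:
        x0 = np.array([current[p] for p in shape_free])
        bnds = [bounds_map[p] for p in shape_free]

        def nll(x: np.ndarray) -> float:
            vals = dict(current)
            vals.update(dict(zip(shape_free, x)))
            if vals["tau_d"] <= vals["tau_ad"]:
                return 1e12
            try:
                return loss(counts, integrals_for(vals))
            except (InvalidParameterError, FloatingPointError):
                return 1e12

        res = minimize(nll, x0, method="L-BFGS-B", bounds=bnds)
        for p, v in zip(shape_free, res.x):
            current[p] = float(v)
        raw_p = current["p_ad"]
        obj = float(res.fun)
        converged = bool(res.success)
        message = str(res.message)
    else:
        obj = loss(counts, integrals_for(current))
        converged = True
        message = "no free shape parameters"

    p_clipped = float(np.clip(current["p_ad"], 0.0, 1.0))
    ints = integrals_for({**current, "p_ad": p_clipped})
    f0 = hist.n_photons / ints.sum()  # amplitude MLE given the shape
    params = DecayModelParams(
        f0=float(f0),
        t0=current["t0"],
        tau_d=current["tau_d"],
        tau_ad=current["tau_ad"],
        tau_g=current["tau_g"],
        p_ad=p_clipped,
    )
    fixed = frozenset(_ALL_PARAMS) - free
    result = FitResult(
        params=params,
        fixed=fixed,
        objective_value=obj,
        n_photons=hist.n_photons,
        converged=converged,
        p_ad_raw=raw_p,
        message=message,
    )
    if not converged:
        warnings.warn(f"decay fit did not converge: {message}", RuntimeWarning, stacklevel=2)
    return result


def lifetime_map(
    frame: np.ndarray,
    bin_centers: np.ndarray,
    t0: float,
    min_photons: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean-lifetime map <tau> = <t> - t0 from a (Y, X, B) frame.

    Pixels with fewer than ``min_photons`` photons are NaN-masked.  Returns
    ``(tau_map, counts_map)``; the count map supports intensity overlays and
    photon-weighted pooling (the photon-weighted mean of pixel <tau> equals
    the pooled-histogram <tau> exactly).
    """
    frame = np.asarray(frame)
    counts_map = frame.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mean = (frame * np.asarray(bin_centers, dtype=float)).sum(axis=-1) / counts_map
    tau_map = t_mean - t0
    tau_map = np.where(counts_map >= min_photons, tau_map, np.nan)
    return tau_map, counts_map
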