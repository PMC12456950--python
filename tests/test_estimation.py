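"""Estimator checks: closed-form inversion, fits, maps, truncation handling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rabflim.decay_model import CALIBRATIONS, DecayModelParams, expected_bin_counts
from rabflim.estimation import (
    InsufficientPhotonsError,
    PhotonHistogram,
    SingularityError,
    binding_fraction_from_mean_lifetime,
    binding_fraction_windowed,
    fit_decay_curve,
    lifetime_map,
    mean_lifetime,
    mean_photon_arrival_time,
    model_window_mean_lifetime,
)
from rabflim.synthetic_data import sample_arrival_times

RAB4 = CALIBRATIONS["mEGFP-Rab4a"]


def amplitude_weighted_mean_lifetime(p_ad, tau_d, tau_ad):
    """Independent oracle: photon-weighted mean lifetime of the mixture."""
    p_d = 1 - p_ad
    return (p_d * tau_d**2 + p_ad * tau_ad**2) / (p_d * tau_d + p_ad * tau_ad)


def _hist_from_params(params, edges, n, seed=0):
    t = sample_arrival_times(params, n, seed=seed)
    counts, _ = np.histogram(t, bins=edges)
    return PhotonHistogram(0.5 * (edges[:-1] + edges[1:]), counts)


def test_mean_arrival_single_and_symmetric_bins():
    h = PhotonHistogram(np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 0, 7, 0]))
    assert mean_photon_arrival_time(h) == pytest.approx(3.0)
    h = PhotonHistogram(np.array([1.0, 2.0, 3.0, 4.0]), np.array([0, 5, 0, 5]))
    assert mean_photon_arrival_time(h) == pytest.approx(3.0)


def test_mean_arrival_empty_histogram_raises():
    h = PhotonHistogram(np.array([1.0, 2.0]), np.array([0, 0]))
    with pytest.raises(InsufficientPhotonsError):
        mean_photon_arrival_time(h)


def test_mean_lifetime_is_offset_subtraction():
    assert mean_lifetime(3.46, 1.0) == pytest.approx(2.46)
    assert mean_lifetime(1.0, 1.0) == 0.0


def test_mean_arrival_of_single_component_is_t0_plus_tau():
    # ex-Gaussian mean oracle at large n, untruncated window
    params = DecayModelParams(f0=1, t0=1.0, tau_d=2.46, tau_ad=1.10,
                              tau_g=0.1, p_ad=0.0)
    t = sample_arrival_times(params, 10**6, seed=7)
    se = t.std() / np.sqrt(t.size)
    assert abs(t.mean() - 3.46) < 3 * se


@pytest.mark.parametrize("calib", sorted(CALIBRATIONS))
@given(p_ad=st.floats(0.0, 1.0))
def test_closed_form_inverts_amplitude_weighted_mean(calib, p_ad):
    c = CALIBRATIONS[calib]
    tau_mean = amplitude_weighted_mean_lifetime(p_ad, c.tau_d, c.tau_ad)
    got = binding_fraction_from_mean_lifetime(tau_mean, c.tau_d, c.tau_ad)
    assert got == pytest.approx(p_ad, abs=1e-12)


def test_closed_form_limits():
    assert binding_fraction_from_mean_lifetime(2.46, 2.46, 1.10) == pytest.approx(0.0)
    assert binding_fraction_from_mean_lifetime(1.10, 2.46, 1.10) == pytest.approx(1.0)


def test_closed_form_out_of_range_and_clipping():
    raw = binding_fraction_from_mean_lifetime(2.6, 2.46, 1.10)
    assert raw < 0
    clipped = binding_fraction_from_mean_lifetime(2.6, 2.46, 1.10, clip=True)
    assert clipped == 0.0


def test_closed_form_singularity_error():
    with pytest.raises(SingularityError):
        binding_fraction_from_mean_lifetime(3.6, 2.46, 1.10)


def test_closed_form_monotone_decreasing_in_tau():
    taus = np.linspace(0.5, 2.46, 40)
    vals = binding_fraction_from_mean_lifetime(taus, 2.46, 1.10)
    assert np.all(np.diff(vals) < 0)


def test_fit_self_consistency_on_noiseless_model_data(edges64, centers64):
    params = DecayModelParams(f0=1, t0=1.2, tau_d=RAB4.tau_d, tau_ad=RAB4.tau_ad,
                              tau_g=0.15, p_ad=0.25)
    counts = expected_bin_counts(params, edges64, 10**6)
    hist = PhotonHistogram(centers64, counts)
    res = fit_decay_curve(hist, RAB4, free={"f0", "p_ad"}, init=params)
    assert res.converged
    assert res.params.p_ad == pytest.approx(0.25, abs=1e-4)


def test_fit_recovers_p_ad_small_monte_carlo(edges64):
    params = DecayModelParams(f0=1, t0=1.2, tau_d=RAB4.tau_d, tau_ad=RAB4.tau_ad,
                              tau_g=0.15, p_ad=0.40)
    errs = []
    for seed in range(20):
        hist = _hist_from_params(params, edges64, 10**4, seed=seed)
        res = fit_decay_curve(hist, RAB4, free={"f0", "p_ad"}, init=params)
        errs.append(res.params.p_ad - 0.40)
    errs = np.asarray(errs)
    assert abs(errs.mean()) < 3 * errs.std(ddof=1) / np.sqrt(errs.size) + 0.005


def test_imagewide_fit_recovers_offset_and_irf_width(edges64):
    params = DecayModelParams(f0=1, t0=1.2, tau_d=RAB4.tau_d, tau_ad=RAB4.tau_ad,
                              tau_g=0.15, p_ad=0.40)
    hist = _hist_from_params(params, edges64, 10**6, seed=11)
    res = fit_decay_curve(hist, RAB4)
    assert res.converged
    assert res.params.t0 == pytest.approx(1.2, abs=0.02)
    assert res.params.tau_g == pytest.approx(0.15, abs=0.05)
    assert res.params.p_ad == pytest.approx(0.40, abs=0.02)


def test_wls_objective_agrees_with_mle_on_good_data(edges64):
    params = DecayModelParams(f0=1, t0=1.2, tau_d=RAB4.tau_d, tau_ad=RAB4.tau_ad,
                              tau_g=0.15, p_ad=0.35)
    hist = _hist_from_params(params, edges64, 10**5, seed=21)
    mle = fit_decay_curve(hist, RAB4, free={"f0", "p_ad"}, init=params)
    wls = fit_decay_curve(hist, RAB4, free={"f0", "p_ad"}, init=params,
                          objective="wls")
    assert wls.params.p_ad == pytest.approx(mle.params.p_ad, abs=0.01)
    with pytest.raises(ValueError, match="objective"):
        fit_decay_curve(hist, RAB4, objective="chi")


def test_fit_insufficient_photons_raises(centers64):
    hist = PhotonHistogram(centers64, np.zeros(64, dtype=int))
    with pytest.raises(InsufficientPhotonsError):
        fit_decay_curve(hist, RAB4)


def test_windowed_inversion_removes_truncation_bias(edges64, centers64):
    # a 12.5 ns window truncates the 2.46 ns decay tail; the plain closed
    # form is then biased while the window-aware inversion is exact
    params = DecayModelParams(f0=1, t0=1.0, tau_d=RAB4.tau_d, tau_ad=RAB4.tau_ad,
                              tau_g=0.15, p_ad=0.40)
    counts = expected_bin_counts(params, edges64, 1.0, normalization="untruncated")
    tau_win = float((centers64 * counts).sum() / counts.sum()) - 1.0
    naive = binding_fraction_from_mean_lifetime(tau_win, RAB4.tau_d, RAB4.tau_ad)
    assert abs(naive - 0.40) > 0.01
    corrected = binding_fraction_windowed(tau_win, RAB4, 1.0, 0.15, edges64)
    assert corrected == pytest.approx(0.40, abs=1e-6)


def test_window_mean_lifetime_decreasing_in_p_ad(edges64):
    vals = [model_window_mean_lifetime(p, RAB4, 1.0, 0.15, edges64)
            for p in np.linspace(0, 1, 11)]
    assert np.all(np.diff(vals) < 0)


def _uniform_frame(edges, p_ad, shape=(8, 8), rate=200.0, seed=0):
    rng = np.random.default_rng(seed)
    params = DecayModelParams(f0=1, t0=1.0, tau_d=RAB4.tau_d, tau_ad=RAB4.tau_ad,
                              tau_g=0.15, p_ad=p_ad)
    probs = expected_bin_counts(params, edges, 1.0, normalization="untruncated")
    return rng.poisson(rate * probs, size=(*shape, probs.size))


def test_lifetime_map_pooled_equals_photon_weighted_mean(edges64, centers64):
    frame = _uniform_frame(edges64, 0.3)
    tau_map, counts_map = lifetime_map(frame, centers64, t0=1.0, min_photons=1)
    pooled_tau = (frame.sum(axis=(0, 1)) * centers64).sum() / frame.sum() - 1.0
    weighted = np.nansum(tau_map * counts_map) / counts_map.sum()
    assert weighted == pytest.approx(pooled_tau, abs=1e-9)
    # uniform parameters: pixel-to-pixel spread is shot noise only
    assert np.nanstd(tau_map) < 0.5


def test_lifetime_map_two_regions_ordered(edges64, centers64):
    lo = _uniform_frame(edges64, 0.1, shape=(8, 4), seed=1)
    hi = _uniform_frame(edges64, 0.5, shape=(8, 4), seed=2)
    frame = np.concatenate([lo, hi], axis=1)
    tau_map, _ = lifetime_map(frame, centers64, t0=1.0, min_photons=1)
    assert np.nanmean(tau_map[:, :4]) > np.nanmean(tau_map[:, 4:])


def test_lifetime_map_masks_sparse_pixels(edges64, centers64):
    frame = np.zeros((4, 4, 64), dtype=int)
    tau_map, counts_map = lifetime_map(frame, centers64, t0=1.0, min_photons=30)
    assert np.all(np.isnan(tau_map))
    assert counts_map.sum() == 0
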