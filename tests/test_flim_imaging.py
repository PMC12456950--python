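"""Pipeline checks: pooling, baselines, windows, volume, group statistics."""

import numpy as np
import pytest
from scipy import stats

from rabflim.decay_model import get_calibration
from rabflim.flim_imaging import (
    ROI_CLASS_IDS,
    WINDOW_PRESETS,
    RoiSet,
    TimeCourse,
    aggregate_group,
    pool_roi_histogram,
    resample_timecourse,
    roi_timecourse,
    spine_volume,
    two_sample_summary,
    window_average,
)
from rabflim.synthetic_data import make_flim_stack, null_scenario


@pytest.fixture(scope="module")
def null_experiment():
    cfg = null_scenario(image_shape=(24, 24), dendrite_rows=(17, 19),
                        stim_spine_center=(8, 6), adj_spine_center=(8, 17),
                        stim_spine_radius=2.5, adj_spine_radius=2.5, seed=42)
    stack, rois, truth = make_flim_stack(cfg)
    return cfg, stack, rois, truth


def test_pooling_conserves_and_adds(null_experiment, centers64):
    _, stack, rois, _ = null_experiment
    frame = stack.frames[0]
    whole = np.ones(frame.shape[:2], dtype=bool)
    assert pool_roi_histogram(frame, whole, centers64).n_photons == frame.sum()

    yx = np.argwhere(rois.labels == ROI_CLASS_IDS["dendrite"])[0]
    single = np.zeros_like(whole)
    single[tuple(yx)] = True
    np.testing.assert_array_equal(
        pool_roi_histogram(frame, single, centers64).counts, frame[tuple(yx)])

    m1 = rois.labels == ROI_CLASS_IDS["stimulated_spine"]
    m2 = rois.labels == ROI_CLASS_IDS["adjacent_spine"]
    both = pool_roi_histogram(frame, m1 | m2, centers64).counts
    np.testing.assert_array_equal(
        both,
        pool_roi_histogram(frame, m1, centers64).counts
        + pool_roi_histogram(frame, m2, centers64).counts,
    )


def test_pooling_empty_mask_rejected(null_experiment, centers64):
    _, stack, _, _ = null_experiment
    empty = np.zeros(stack.frames.shape[1:3], dtype=bool)
    with pytest.raises(ValueError, match="empty"):
        pool_roi_histogram(stack.frames[0], empty, centers64)


def test_baseline_window_means_are_zero_by_construction(null_experiment):
    cfg, stack, rois, _ = null_experiment
    calib = get_calibration(cfg.calibration)
    tc = roi_timecourse(stack, rois, calib, cfg.t0_ns, cfg.tau_g_ns)
    base = tc.times < 0
    for roi in tc.rois:
        assert abs(np.nanmean(tc.delta_p_ad_pct[roi][base])) < 1e-12
        assert abs(np.nanmean(tc.delta_volume_pct[roi][base])) < 1e-12


def test_null_experiment_timecourses_are_flat(null_experiment):
    cfg, stack, rois, _ = null_experiment
    calib = get_calibration(cfg.calibration)
    tc = roi_timecourse(stack, rois, calib, cfg.t0_ns, cfg.tau_g_ns)
    n_base = int((tc.times < 0).sum())
    for roi in tc.rois:
        post = tc.delta_p_ad_pct[roi][tc.times > 0]
        # the baseline reference is itself estimated from n_base noisy
        # frames, so its error is shared by every post-stimulus point
        se = post.std(ddof=1) * np.sqrt(1 / post.size + 1 / n_base)
        assert abs(post.mean()) < 3 * se


def test_spine_volume_formula_and_scale_invariance():
    img = np.zeros((10, 10))
    spine = np.zeros((10, 10), dtype=bool)
    dend = np.zeros((10, 10), dtype=bool)
    spine[0, :4] = True
    dend[5:, :] = True
    img[0, :4] = 25.0   # integrated spine intensity 100
    img[5:, :] = 50.0   # dendrite mean 50
    assert spine_volume(img, spine, dend, 0.1) == pytest.approx(0.2)
    assert spine_volume(3.7 * img, spine, dend, 0.1) == pytest.approx(0.2)
    img2 = img.copy()
    img2[0, :4] = 0.0
    assert spine_volume(img2, spine, dend, 0.1) == 0.0


def test_spine_volume_bad_reference_rejected():
    img = np.zeros((4, 4))
    mask = np.ones((4, 4), dtype=bool)
    with pytest.raises(ValueError):
        spine_volume(img, mask, mask, 0.1)
    with pytest.raises(ValueError):
        spine_volume(np.ones((4, 4)), mask, mask, -1.0)


def _toy_timecourse(times, stim_pad, stim_vol=None, experiment_id=""):
    times = np.asarray(times, dtype=float)
    stim_pad = np.asarray(stim_pad, dtype=float)
    if stim_vol is None:
        stim_vol = np.zeros_like(times)
    zeros = np.zeros_like(times)
    return TimeCourse(
        times=times,
        delta_p_ad_pct={"stimulated_spine": stim_pad, "adjacent_spine": zeros.copy()},
        delta_volume_pct={"stimulated_spine": np.asarray(stim_vol, dtype=float),
                          "adjacent_spine": zeros.copy()},
        p_ad={"stimulated_spine": stim_pad / 100, "adjacent_spine": zeros.copy()},
        baseline_p_ad={"stimulated_spine": 0.3, "adjacent_spine": 0.3},
        baseline_volume={"stimulated_spine": 1.0, "adjacent_spine": 1.0},
        n_baseline_frames=1,
        experiment_id=experiment_id,
    )


def test_window_average_constant_and_linear_traces():
    tc = _toy_timecourse([-1, 2, 3, 10], [0.5, 0.5, 0.5, 0.5])
    assert window_average(tc, (0, 20)) == pytest.approx(0.5)
    tc = _toy_timecourse([-1, 2, 3, 10], [0, 2, 3, 10])
    assert window_average(tc, "transient") == pytest.approx(2.5)
    assert WINDOW_PRESETS["transient"] == (1.3, 4.0)
    assert WINDOW_PRESETS["sustained_sensor"] == (19.0, 31.0)
    assert WINDOW_PRESETS["sustained_structural"] == (20.0, 35.0)


def test_window_average_empty_overlap_rejected():
    tc = _toy_timecourse([-1, 2], [0, 1])
    with pytest.raises(ValueError, match="no usable timepoints"):
        window_average(tc, (50, 60))


def test_two_phase_trace_orders_transient_above_sustained():
    times = np.array([-1.0, 1.5, 2, 3, 4, 20, 25, 30])
    for a1, a2 in [(3.0, 0.5), (2.0, 1.0), (1.0, 0.2)]:
        vol = np.where(times >= 0, a2 + (a1 - a2) * np.exp(-times / 2.0), 0) * 100
        tc = _toy_timecourse(times, np.zeros_like(times), stim_vol=vol)
        hi = window_average(tc, "transient", "delta_vol_pct")
        lo = window_average(tc, "sustained_sensor", "delta_vol_pct")
        assert hi > lo


def test_aggregate_group_mean_sem_and_errors():
    times = [-1.0, 1.0, 2.0]
    a = _toy_timecourse(times, [0, 1, 2])
    b = _toy_timecourse(times, [0, -1, -2])
    summary = aggregate_group([a, b])
    np.testing.assert_allclose(summary.mean[("stimulated_spine", "delta_pad_pct")],
                               [0, 0, 0], atol=1e-14)
    assert summary.n == 2

    single = aggregate_group([a])
    assert np.all(np.isnan(single.sem[("stimulated_spine", "delta_pad_pct")]))

    c = _toy_timecourse([-1.0, 1.5, 2.0], [0, 1, 2])
    with pytest.raises(ValueError, match="grids differ"):
        aggregate_group([a, c])
    resampled = resample_timecourse(c, np.asarray(times))
    aggregate_group([a, resampled])  # no error after resampling


def test_group_mean_tracks_truth_within_sem():
    rng = np.random.default_rng(5)
    times = np.array([-1.0, 1.0, 5.0, 20.0])
    truth = np.array([0.0, 4.0, 2.0, 1.0])
    tcs = [_toy_timecourse(times, truth + rng.normal(0, 1.0, times.size))
           for _ in range(100)]
    summary = aggregate_group(tcs)
    m = summary.mean[("stimulated_spine", "delta_pad_pct")]
    s = summary.sem[("stimulated_spine", "delta_pad_pct")]
    assert np.all(np.abs(m - truth) < 3 * s)


def test_two_sample_window_comparison_power_and_null():
    rng = np.random.default_rng(11)
    times = np.array([-1.0, 2.0, 3.0])

    def group(shift, n):
        return [_toy_timecourse(times, rng.normal(shift, 1.0, times.size))
                for _ in range(n)]

    # separated by 5 SD: detected
    res = two_sample_summary(group(0.0, 10), group(5.0, 10), (1.3, 4.0))
    assert res.p_value < 0.01
    assert res.difference < 0

    # identical groups: difference 0, degenerate flagged
    same = group(0.0, 5)
    res = two_sample_summary(same, same, (1.3, 4.0))
    assert res.difference == 0.0
    assert res.degenerate or res.p_value > 0.99

    # modest null calibration: type-I error near alpha
    rejections = 0
    n_rep = 400
    for _ in range(n_rep):
        res = two_sample_summary(group(0.0, 10), group(0.0, 10), (1.3, 4.0))
        rejections += res.p_value < 0.05
    rate = rejections / n_rep
    assert 0.02 < rate < 0.08


def test_two_sample_requires_two_per_group():
    tc = _toy_timecourse([-1.0, 2.0], [0, 1])
    with pytest.raises(ValueError, match="n >= 2"):
        two_sample_summary([tc], [tc, tc], (1.3, 4.0))


def test_structure_mask_helper_covers_labeled_rois(null_experiment):
    from rabflim.flim_imaging import suggest_structure_mask

    _, stack, rois, _ = null_experiment
    fg = suggest_structure_mask(stack.acceptor)
    labeled = rois.labels > 0
    overlap = (fg & labeled).sum() / labeled.sum()
    assert overlap > 0.9
    assert fg.sum() < 2 * labeled.sum()  # does not flood the background


def test_roi_set_unknown_and_empty_rois():
    labels = np.zeros((5, 5), dtype=np.uint8)
    labels[0, 0] = ROI_CLASS_IDS["dendrite"]
    rois = RoiSet(labels)
    with pytest.raises(KeyError):
        rois.mask("soma")
    with pytest.raises(ValueError, match="empty"):
        rois.mask("stimulated_spine")
    assert rois.mask("dendrite").sum() == 1
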