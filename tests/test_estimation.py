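"""Unit tests for the displacement estimator: normalization, match metrics,
curve building, Gaussian peak fitting, setpoint referencing."""

import numpy as np
import pytest

from nanolock.estimation import (
    AXES,
    AxisStackConfig,
    DegenerateFrameError,
    FlatCurveError,
    Frame,
    GaussianFit,
    MatchCurve,
    OutOfRangeError,
    ReferenceStack,
    SetupError,
    SortedProfile,
    build_match_curve,
    cross_correlation,
    estimate_error,
    fit_gaussian_peak,
    index_to_nm,
    measure_setpoint_offsets,
    mse,
    normalize_frame,
    sorted_profile,
)
from nanolock.simulator import VirtualMicroscope, DriftModel, image_at
from nanolock.control import engage

from conftest import WORKING_Z


# ---------------------------------------------------------------- normalize


@pytest.mark.parametrize(
    "pixels, expected",
    [
        ([[1, 1], [1, 1]], [[0.25, 0.25], [0.25, 0.25]]),
        ([[2, 0], [0, 2]], [[0.5, 0], [0, 0.5]]),
    ],
)
def test_normalize_frame_divides_by_total(pixels, expected):
    out = normalize_frame(Frame(np.array(pixels, dtype=float)))
    assert out.normalized
    np.testing.assert_allclose(out.pixels, expected)
    # idempotent
    again = normalize_frame(out)
    np.testing.assert_array_equal(again.pixels, out.pixels)


def test_normalize_all_zero_frame_is_degenerate():
    with pytest.raises(DegenerateFrameError):
        normalize_frame(Frame(np.zeros((2, 2))))


def test_frame_rejects_negative_and_nonfinite():
    with pytest.raises(ValueError):
        Frame(np.array([[1.0, -1.0], [0.0, 0.0]]))
    with pytest.raises(ValueError):
        Frame(np.array([[np.nan, 0.0], [0.0, 0.0]]))


# ---------------------------------------------------------- cross-correlation


def test_cross_correlation_examples():
    uniform = Frame(np.full((2, 2), 0.25))
    assert cross_correlation(uniform, uniform) == pytest.approx(0.25)
    a = Frame(np.array([[1.0, 0.0], [0.0, 0.0]]))
    b = Frame(np.array([[0.0, 1.0], [1.0, 1.0]]))
    assert cross_correlation(a, b) == 0.0


def test_cross_correlation_shape_mismatch():
    with pytest.raises(ValueError):
        cross_correlation(Frame(np.ones((2, 2))), Frame(np.ones((3, 2))))


def test_cross_correlation_matches_double_loop_oracle(rng):
    """Elementwise product sum agrees with an explicit double loop to 1e-12."""
    for _ in range(200):
        a = rng.random((16, 16))
        b = rng.random((16, 16))
        expected = 0.0
        for i in range(16):
            for j in range(16):
                expected += a[i, j] * b[i, j]
        got = cross_correlation(Frame(a), Frame(b))
        assert got == pytest.approx(expected, rel=1e-12)


# -------------------------------------------------------------- sorted profile


def test_sorted_profile_sorts_values():
    f = normalize_frame(Frame(np.array([[0.5, 0.1], [0.3, 0.1]])))
    p = sorted_profile(f)
    np.testing.assert_allclose(p.values, np.array([0.1, 0.1, 0.3, 0.5]))


def test_sorted_profile_spatial_permutation_invariant(rng):
    a = rng.random((12, 9))
    f = normalize_frame(Frame(a))
    ft = normalize_frame(Frame(a.T))
    np.testing.assert_array_equal(sorted_profile(f).values, sorted_profile(ft).values)


def test_sorted_profile_matches_counting_sort_oracle(rng):
    """Sorting preserves the value multiset: checked against a counting sort."""
    levels = rng.integers(0, 64, size=(300, 300))
    f = normalize_frame(Frame(levels.astype(float) + 1.0))
    prof = sorted_profile(f)
    assert prof.values.size == 90000
    # library-independent counting sort over the 64 quantized levels
    counts = [0] * 64
    for v in levels.ravel():
        counts[int(v)] += 1
    total = float((levels + 1).sum())
    expected = np.repeat((np.arange(64) + 1.0) / total, counts)
    np.testing.assert_array_equal(prof.values, expected)


def test_sorted_profile_requires_normalized_frame():
    with pytest.raises(ValueError):
        sorted_profile(Frame(np.ones((4, 4))))


# ------------------------------------------------------------------------ mse


def test_mse_examples():
    p = SortedProfile(np.array([0.1, 0.2, 0.7]))
    assert mse(p, p) == 0.0
    a = SortedProfile(np.array([0.0, 1.0]))
    b = SortedProfile(np.array([1.0, 2.0]))
    assert mse(a, b) == pytest.approx(1.0)
    assert mse(b, a) == mse(a, b)


def test_mse_length_mismatch():
    with pytest.raises(ValueError):
        mse(SortedProfile(np.array([0.0, 1.0])), SortedProfile(np.array([1.0])))


def test_mse_matches_loop_oracle(rng):
    for _ in range(200):
        a = np.sort(rng.random(100))
        b = np.sort(rng.random(100))
        expected = 0.0
        for i in range(100):
            expected += (a[i] - b[i]) ** 2
        expected /= 100.0
        got = mse(SortedProfile(a), SortedProfile(b))
        assert got == pytest.approx(expected, rel=1e-12)


# ------------------------------------------------------------ match curves


def _tiny_lateral_stack(rng, n_planes=5):
    """Distinct random frames as stack entries (self-match testing)."""
    entries = [
        normalize_frame(Frame(rng.random((8, 8)) + 0.1)) for _ in range(n_planes)
    ]
    step = 20.0
    half = step * (n_planes // 2)
    return ReferenceStack(
        axis="x",
        entries=entries,
        positions_nm=np.linspace(-half, half, n_planes),
        step_nm=step,
        center_index=n_planes // 2,
    )


def _tiny_z_stack(rng, n_planes=5):
    entries = []
    for _ in range(n_planes):
        f = normalize_frame(Frame(rng.random((8, 8)) + 0.1))
        entries.append(sorted_profile(f))
    step = 20.0
    half = step * (n_planes // 2)
    return ReferenceStack(
        axis="z",
        entries=entries,
        positions_nm=np.linspace(-half, half, n_planes),
        step_nm=step,
        center_index=n_planes // 2,
    )


def test_match_curve_z_self_match_has_zero_mse(rng):
    stack = _tiny_z_stack(rng)
    k = 3
    frame = Frame(
        np.sort(stack.entries[k].values).reshape(8, 8).copy(), normalized=True
    )
    curve = build_match_curve(frame, stack)
    assert curve.raw[k] == 0.0
    assert np.all(curve.raw[np.arange(5) != k] > 0)
    assert curve.scaled[k] == pytest.approx(1.0)


def test_match_curve_lateral_scaled_range(rng):
    stack = _tiny_lateral_stack(rng)
    frame = stack.entries[2]
    curve = build_match_curve(frame, stack)
    assert curve.raw.size == 5
    assert curve.scaled.min() == 0.0
    assert curve.scaled.max() == 1.0


def test_match_curve_flat_raises():
    entries = [Frame(np.full((4, 4), 1 / 16.0), normalized=True) for _ in range(3)]
    stack = ReferenceStack(
        axis="x",
        entries=entries,
        positions_nm=np.array([-20.0, 0.0, 20.0]),
        step_nm=20.0,
        center_index=1,
    )
    with pytest.raises(FlatCurveError):
        build_match_curve(entries[0], stack)


def test_match_curve_midplane_shift_peaks_at_neighbor(scene, engaged_noiseless):
    """A frame midway between planes k and k+1 peaks at one of the two."""
    stacks, _ = engaged_noiseless
    frame = normalize_frame(image_at(scene, (10.0, 0.0, WORKING_Z)))  # half a step
    curve = build_match_curve(frame, stacks["x"])
    assert int(np.argmax(curve.scaled)) in (5, 6)


# ------------------------------------------------------------- Gaussian fit


def _curve_from_gaussian(amp, mu, width, off, n=11, axis="x"):
    u = np.arange(n, dtype=float)
    y = amp * np.exp(-((u - mu) ** 2) / (2 * width**2)) + off
    return MatchCurve(axis=axis, raw=y.copy(), scaled=y)


def test_gaussian_fit_recovers_exact_center():
    curve = _curve_from_gaussian(1.0, 5.3, 2.0, 0.0)
    fit = fit_gaussian_peak(curve)
    assert fit.converged
    assert fit.center_index == pytest.approx(5.3, abs=1e-6)
    assert fit.residual_rms < 1e-9


def test_gaussian_fit_symmetric_curve_centered():
    y = np.array([0.0, 0.1, 0.2, 0.7, 1.0, 0.7, 0.2, 0.1, 0.0])
    fit = fit_gaussian_peak(MatchCurve(axis="x", raw=y, scaled=y))
    assert fit.center_index == pytest.approx(4.0, abs=1e-6)


def test_gaussian_fit_monotone_curve_is_out_of_range():
    y = np.linspace(0, 1, 11)
    with pytest.raises(OutOfRangeError):
        fit_gaussian_peak(MatchCurve(axis="x", raw=y, scaled=y))
    with pytest.raises(OutOfRangeError):
        fit_gaussian_peak(MatchCurve(axis="x", raw=y[::-1], scaled=y[::-1]))


# -------------------------------------------------------------- index_to_nm


def test_index_to_nm_conversion(rng):
    stack = _tiny_lateral_stack(rng)  # center 2, step 20

    def fit_at(mu):
        return GaussianFit(mu, 1.0, 2.0, 0.0, True, 0.0)

    assert index_to_nm(fit_at(2.0), stack) == 0.0
    assert index_to_nm(fit_at(3.0), stack) == pytest.approx(20.0)
    assert index_to_nm(fit_at(1.5), stack) == pytest.approx(-10.0)
    with pytest.raises(ValueError):
        index_to_nm(GaussianFit(np.nan, 1, 1, 0, False, np.nan), stack)


# ------------------------------------------------- setpoint and error signal


def test_setpoint_offsets_zero_without_drift(engaged_noiseless):
    _, setpoint = engaged_noiseless
    assert np.all(np.abs(setpoint.offsets_nm) < 1.0)


def test_setpoint_offsets_detect_drift_during_stack_acquisition(scene, stack_cfgs):
    """Sample drifting between setpoint capture and stack acquisition leaves a
    nonzero offset approximately opposite the accumulated drift."""
    drift = DriftModel.linear((0.4, 0.0, 0.0))
    mic = VirtualMicroscope(
        scene, noise=None, drift=drift, start_position_nm=(0, 0, WORKING_Z), seed=3
    )
    stacks, setpoint, _ = engage(mic, stack_cfgs)
    # drift accumulates over the 3×11 stack frames; the x stack sees the
    # sample shifted, so the setpoint appears displaced backwards
    assert setpoint.offsets_nm[0] < -2.0


def test_setpoint_beyond_stack_range_fails_engagement(scene, engaged_noiseless):
    stacks, _ = engaged_noiseless
    far = normalize_frame(image_at(scene, (150.0, 0.0, WORKING_Z)))
    with pytest.raises(SetupError):
        measure_setpoint_offsets(far, stacks)


def test_estimate_error_zero_at_setpoint(scene, engaged_noiseless):
    stacks, setpoint = engaged_noiseless
    err = estimate_error(setpoint.setpoint_frame, stacks, setpoint)
    assert err.valid.all()
    assert np.all(np.abs(err.e_nm) < 0.5)


def test_estimate_error_recovers_known_displacement(scene, engaged_noiseless):
    stacks, setpoint = engaged_noiseless
    true = np.array([8.0, -3.0, 12.0])
    frame = image_at(scene, (true[0], true[1], WORKING_Z + true[2]))
    err = estimate_error(frame, stacks, setpoint)
    assert err.valid.all()
    np.testing.assert_allclose(err.e_nm, true, atol=2.0)  # 0.1 × step


def test_estimate_error_calibration_scales_linearly(scene, engaged_noiseless):
    stacks, setpoint = engaged_noiseless
    frame = image_at(scene, (10.0, 0.0, WORKING_Z))
    raw = estimate_error(frame, stacks, setpoint, calibration=(1.0, 1.0, 1.0))
    scaled = estimate_error(frame, stacks, setpoint, calibration=(0.9, 1.0, 1.0))
    assert scaled.e_nm[0] == pytest.approx(0.9 * raw.e_nm[0], rel=1e-12)


def test_estimate_error_flags_out_of_range_axis_invalid(scene, engaged_noiseless):
    stacks, setpoint = engaged_noiseless
    frame = image_at(scene, (150.0, 0.0, WORKING_Z))  # beyond ±100 nm stack
    err = estimate_error(frame, stacks, setpoint)
    assert not err.valid[0]
    assert np.isnan(err.e_nm[0])
    assert "message" in err.diagnostics["x"]


def test_lateral_linearity_before_calibration(scene, engaged_noiseless):
    """±k·5 nm staircase of true displacements maps to estimates with
    least-squares slope in [0.85, 1.15] before calibration."""
    stacks, setpoint = engaged_noiseless
    ds = np.arange(-40, 41, 5, dtype=float)
    est = []
    for d in ds:
        frame = image_at(scene, (d, 0.0, WORKING_Z))
        est.append(estimate_error(frame, stacks, setpoint).e_nm[0])
    slope = np.polyfit(ds, est, 1)[0]
    assert 0.85 <= slope <= 1.15
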