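"""Unit tests for the boundary-detection primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octrt import (
    FormatError,
    ParameterError,
    SegmentationParams,
    axial_slope,
    detect_irl,
    detect_orl,
    generate_volume,
    locate_sclera,
    segment_bscan,
    smooth_coarse,
)
from octrt.segmentation import _plateau_extrema

from conftest import random_spec


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_extrema(y):
    """Slow reference: strict local extrema with plateau collapsing."""
    runs = []
    i = 0
    while i < len(y):
        j = i
        while j + 1 < len(y) and y[j + 1] == y[i]:
            j += 1
        runs.append(((i + j) / 2.0, y[i]))
        i = j + 1
    minima, maxima = [], []
    for k in range(1, len(runs) - 1):
        _, prev = runs[k - 1]
        idx, val = runs[k]
        _, nxt = runs[k + 1]
        if val < prev and val < nxt:
            minima.append((idx, val))
        if val > prev and val > nxt:
            maxima.append((idx, val))
    return minima, maxima


def discrete_gaussian_moment(sigma_px: float) -> float:
    """Second moment (px^2) of the truncated discrete Gaussian kernel."""
    radius = int(4.0 * sigma_px + 0.5)
    k = np.arange(-radius, radius + 1)
    w = np.exp(-0.5 * (k / sigma_px) ** 2)
    w /= w.sum()
    return float(np.sum(w * k**2))


# ---------------------------------------------------------------------------
# smoothing


def test_smooth_coarse_preserves_constant():
    img = np.full((40, 30), 3.5)
    out = smooth_coarse(img, 20.0, 4.0, 10.0)
    assert np.allclose(out, 3.5)


def test_smooth_coarse_impulse_second_moment():
    """Physical sigma converts to sigma_um/spacing pixels on each axis."""
    img = np.zeros((201, 101))
    img[100, 50] = 1.0
    out = smooth_coarse(img, 20.0, 4.0, 10.0)
    z = np.arange(201) - 100.0
    x = np.arange(101) - 50.0
    axial_profile = out.sum(axis=1)
    lateral_profile = out.sum(axis=0)
    m_axial = np.sum(axial_profile * z**2) / axial_profile.sum()
    m_lateral = np.sum(lateral_profile * x**2) / lateral_profile.sum()
    assert m_axial == pytest.approx(discrete_gaussian_moment(20.0 / 4.0), rel=1e-6)
    assert m_lateral == pytest.approx(discrete_gaussian_moment(20.0 / 10.0), rel=1e-6)
    # and the kernel moment itself is the nominal sigma^2 to good accuracy
    assert m_axial == pytest.approx((20.0 / 4.0) ** 2, rel=0.02)


def test_smooth_coarse_preserves_linear_ramp_interior():
    z = np.arange(120.0)
    img = np.tile(2.0 * z[:, None] + 1.0, (1, 20))
    out = smooth_coarse(img, 20.0, 4.0, 4.0)
    assert np.allclose(out[40:80, 5:15], img[40:80, 5:15], rtol=1e-10)


def test_smooth_coarse_rejects_bad_sigma():
    with pytest.raises(ParameterError):
        smooth_coarse(np.zeros((10, 10)), 0.0, 4.0, 4.0)


# ---------------------------------------------------------------------------
# sclera localization


def test_locate_sclera_argmax_times_spacing():
    img = np.zeros((400, 3))
    img[310, :] = 1.0
    depths = locate_sclera(img, 3.87)
    assert np.allclose(depths, 310 * 3.87)
    assert depths[0] == pytest.approx(1199.7)


def test_locate_sclera_tie_breaks_to_smaller_depth():
    col = np.zeros((50, 1))
    col[[10, 30], 0] = 7.0
    assert locate_sclera(col, 2.0)[0] == 10 * 2.0


def test_locate_sclera_on_noiseless_phantom(noiseless_small_spec):
    volume, truth = generate_volume(noiseless_small_spec)
    for b, frame in enumerate(volume.frames):
        smoothed = smooth_coarse(frame, 20.0, volume.axial_spacing, volume.lateral_spacing)
        depths = locate_sclera(smoothed, volume.axial_spacing)
        assert np.all(np.abs(depths - truth.sclera_um[b]) <= volume.axial_spacing)


# ---------------------------------------------------------------------------
# axial slope


def test_axial_slope_zero_for_constant():
    col = np.full((50, 2), 4.2)
    assert np.allclose(axial_slope(col, 2.0, 3.87), 0.0)


def test_axial_slope_recovers_ramp_gradient():
    spacing = 3.87
    z = np.arange(100) * spacing
    col = (0.8 * z + 5.0)[:, None]
    slope = axial_slope(col, 2.0, spacing)
    assert np.allclose(slope[5:-5], 0.8, rtol=1e-6)


@pytest.mark.parametrize("scale_um", [3.0, 5.0, 10.0])
def test_axial_slope_peak_at_logistic_midpoint(scale_um):
    """The slope maximum of a rising logistic step sits at its midpoint."""
    spacing = 3.87
    z = np.arange(300) * spacing
    z0 = 150 * spacing + 1.3  # off-grid on purpose
    col = (10.0 / (1.0 + np.exp(-(z - z0) / scale_um)))[:, None]
    slope = axial_slope(col, 2.0, spacing)
    peak_depth = np.argmax(slope[:, 0]) * spacing
    assert abs(peak_depth - z0) <= spacing


def test_axial_slope_needs_three_samples():
    with pytest.raises(FormatError):
        axial_slope(np.zeros((2, 4)), 2.0, 3.87)


# ---------------------------------------------------------------------------
# boundary rules on constructed slope columns


def _slope_with_features(n=200, valleys=(), peaks=()):
    """Smooth baseline with narrow Gaussian bumps/dips at given (idx, amp)."""
    z = np.arange(n, dtype=float)
    col = np.zeros(n)
    for idx, amp in valleys:
        col -= amp * np.exp(-0.5 * ((z - idx) / 2.0) ** 2)
    for idx, amp in peaks:
        col += amp * np.exp(-0.5 * ((z - idx) / 2.0) ** 2)
    return col


def test_detect_orl_unique_valley():
    spacing = 2.0
    col = _slope_with_features(valleys=[(90, 1.0)])
    assert detect_orl(col, 150 * spacing, spacing) == pytest.approx(90 * spacing)


def test_detect_orl_takes_first_valley_above_sclera():
    spacing = 2.0
    col = _slope_with_features(valleys=[(50, 3.0), (90, 1.0)])
    assert detect_orl(col, 150 * spacing, spacing) == pytest.approx(90 * spacing)


def test_detect_orl_ignores_valleys_below_sclera():
    spacing = 2.0
    col = _slope_with_features(valleys=[(120, 1.0), (60, 1.0)])
    assert detect_orl(col, 100 * spacing, spacing) == pytest.approx(60 * spacing)


def test_detect_orl_none_when_monotone():
    spacing = 2.0
    col = np.linspace(-1.0, 1.0, 200)
    assert detect_orl(col, 150 * spacing, spacing) is None


def test_detect_orl_rejects_out_of_extent_sclera():
    with pytest.raises(ParameterError):
        detect_orl(np.zeros(100), 1e6, 2.0)


def test_detect_irl_unique_peak():
    spacing = 2.0
    orl = 210 * spacing
    col = _slope_with_features(valleys=[(210, 1.0)], peaks=[(100, 2.0)])
    got = detect_irl(col, orl, 120.0, spacing)
    assert got == pytest.approx(100 * spacing)
    assert orl - got > 120.0


def test_detect_irl_exclusion_zone_beats_amplitude():
    """A stronger peak inside the 120 um zone is ignored for a weaker one outside."""
    spacing = 1.0
    orl = 420.0
    col = _slope_with_features(
        n=500, peaks=[(320, 5.0), (270, 3.0)]  # orl-100 (amp 5), orl-150 (amp 3)
    )
    assert detect_irl(col, orl, 120.0, spacing) == pytest.approx(270.0)


def test_detect_irl_tie_breaks_toward_orl():
    spacing = 1.0
    col = _slope_with_features(n=500, peaks=[(100, 3.0), (200, 3.0)])
    assert detect_irl(col, 400.0, 120.0, spacing) == pytest.approx(200.0)


def test_detect_irl_none_without_admissible_peak():
    spacing = 1.0
    col = _slope_with_features(n=500, peaks=[(380, 5.0)])
    assert detect_irl(col, 400.0, 120.0, spacing) is None


def test_detect_irl_rejects_bad_offset():
    with pytest.raises(ParameterError):
        detect_irl(np.zeros(100), 50.0, 0.0, 1.0)


def test_plateau_collapses_to_midpoint():
    y = np.array([0.0, -1.0, -1.0, -1.0, 0.0, 2.0, 2.0, 0.0])
    min_idx, min_val, max_idx, max_val = _plateau_extrema(y)
    assert list(min_idx) == [2.0] and list(min_val) == [-1.0]
    assert list(max_idx) == [5.5] and list(max_val) == [2.0]


# ---------------------------------------------------------------------------
# full B-scan


def test_segment_bscan_recovers_noiseless_phantom(noiseless_small_spec, params):
    volume, truth = generate_volume(noiseless_small_spec)
    for b, frame in enumerate(volume.frames):
        trace = segment_bscan(frame, params, volume.axial_spacing, volume.lateral_spacing)
        assert trace.valid.all()
        assert np.all(
            np.abs(trace.thickness_um - truth.thickness_um[b]) <= volume.axial_spacing
        )
        # stated invariant: irl + offset < orl <= sclera
        assert np.all(trace.irl_um + params.min_irl_offset_um < trace.orl_um)
        assert np.all(trace.orl_um <= trace.sclera_um)


def test_segment_bscan_constant_image_all_no_valley(params):
    trace = segment_bscan(np.full((200, 8), 3.0), params, 3.87, 11.0)
    assert not trace.valid.any()
    assert all(r == "no_valley" for r in trace.reason)
    assert np.isnan(trace.thickness_um).all()


def test_segment_bscan_rejects_non_2d(params):
    with pytest.raises(FormatError):
        segment_bscan(np.zeros(10), params, 1.0, 1.0)


@settings(max_examples=10, deadline=None)
@given(
    a=st.floats(min_value=0.05, max_value=50.0),
    b=st.floats(min_value=0.0, max_value=100.0),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_affine_intensity_invariance(a, b, seed):
    """segment_bscan(a*I + b) gives the identical trace for any a > 0."""
    rng = np.random.default_rng(seed)
    spec = random_spec(rng, speckle_k=200.0)
    volume, _ = generate_volume(spec)
    params = SegmentationParams()
    frame = volume.frames[0]
    t1 = segment_bscan(frame, params, volume.axial_spacing, volume.lateral_spacing)
    t2 = segment_bscan(a * frame + b, params, volume.axial_spacing, volume.lateral_spacing)
    assert np.array_equal(t1.valid, t2.valid)
    assert np.array_equal(t1.sclera_um, t2.sclera_um)
    assert np.array_equal(t1.orl_um, t2.orl_um, equal_nan=True)
    assert np.array_equal(t1.irl_um, t2.irl_um, equal_nan=True)
    assert list(t1.reason) == list(t2.reason)


def test_detections_match_brute_force_oracle(params):
    """Sclera/ORL/IRL picks equal exhaustive extremum enumeration, 100 columns."""
    rng = np.random.default_rng(11)
    spacing = 3.87
    for trial in range(100):
        spec = random_spec(rng, speckle_k=rng.uniform(30.0, 400.0))
        volume, _ = generate_volume(spec)
        frame = volume.frames[rng.integers(volume.n_bscans)]
        j = int(rng.integers(frame.shape[1]))
        smoothed = smooth_coarse(frame, 20.0, volume.axial_spacing, volume.lateral_spacing)
        slope = axial_slope(frame, 2.0, volume.axial_spacing)
        col = slope[:, j]

        sclera = locate_sclera(smoothed, volume.axial_spacing)[j]
        assert sclera == float(np.argmax(smoothed[:, j])) * volume.axial_spacing

        minima, maxima = brute_force_extrema(col)
        expected_orl = None
        for idx, _ in reversed(minima):
            if idx * volume.axial_spacing < sclera:
                expected_orl = idx * volume.axial_spacing
                break
        assert detect_orl(col, sclera, volume.axial_spacing) == expected_orl

        if expected_orl is not None:
            cands = [
                (val, idx) for idx, val in maxima
                if expected_orl - idx * volume.axial_spacing > params.min_irl_offset_um
            ]
            expected_irl = max(cands)[1] * volume.axial_spacing if cands else None
            got = detect_irl(col, expected_orl, params.min_irl_offset_um, volume.axial_spacing)
            assert got == expected_irl
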