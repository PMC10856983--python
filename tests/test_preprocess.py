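import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ictalnet.signal_io import EEGRecord
from ictalnet.preprocess import (
    WaveletSpec,
    cwt_scalogram,
    normalize_scalogram,
    plan_windows,
    preprocess_record,
    resample,
    resize_bilinear,
    scale_grid,
    segment,
)
from ictalnet.wavelets import FAMILIES, center_frequency, center_omega, psi_hat


# ------------------------------------------------------------- windowing

@pytest.mark.parametrize(
    "signal_len,window,overlap,hop,n,resampled",
    [
        (4097, 868, 1 / 3, 579, 7, 4342),
        (4097, 1042, 0.25, 782, 5, 4170),
        (500, 500, 0.5, 250, 1, 500),
        (1024, 256, 0.0, 256, 4, 1024),
    ],
)
def test_plan_windows_examples(signal_len, window, overlap, hop, n, resampled):
    plan = plan_windows(signal_len, window, overlap)
    assert plan.hop == hop
    assert plan.n_windows == n
    assert plan.resampled_len == resampled


def test_plan_windows_errors():
    with pytest.raises(ValueError):
        plan_windows(100, 200, 0.0)  # signal shorter than a window
    with pytest.raises(ValueError):
        plan_windows(100, 50, 1.0)


@given(
    signal_len=st.integers(64, 8000),
    window=st.integers(16, 2100),
    overlap=st.sampled_from([0.0, 0.25, 1 / 3, 0.33, 0.5]),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_tiling_identity_property(signal_len, window, overlap):
    if signal_len < window:
        signal_len, window = window, signal_len
    if window < 16:
        window = 16
    if signal_len < window:
        signal_len = window
    plan = plan_windows(signal_len, window, overlap)
    assert plan.window_len + (plan.n_windows - 1) * plan.hop == plan.resampled_len
    assert plan.n_windows >= 1


def test_segment_indices_and_overlap():
    plan = plan_windows(10, 4, 0.5)
    x = np.arange(plan.resampled_len, dtype=float)
    wins = segment(x, plan)
    assert len(wins) == plan.n_windows
    # adjacent windows share window_len - hop samples
    np.testing.assert_array_equal(wins[0][plan.hop:], wins[1][: 4 - plan.hop])
    # last window ends exactly at the resampled end
    np.testing.assert_array_equal(wins[-1], x[-4:])
    with pytest.raises(ValueError):
        segment(x[:-1], plan)


def test_segment_reference_plan_last_index():
    plan = plan_windows(4097, 868, 1 / 3)
    x = np.arange(plan.resampled_len, dtype=float)
    wins = segment(x, plan)
    assert len(wins) == 7
    assert wins[-1][-1] == 4341


def test_segment_zero_overlap_disjoint():
    plan = plan_windows(12, 4, 0.0)
    wins = segment(np.arange(12, dtype=float), plan)
    np.testing.assert_array_equal(np.concatenate(wins), np.arange(12))


# ------------------------------------------------------------- resample

def test_resample_identity_and_midpoint():
    x = np.array([5.0, -1.0, 2.0])
    np.testing.assert_array_equal(resample(x, 3), x)
    np.testing.assert_allclose(resample(np.array([0.0, 2.0]), 3), [0.0, 1.0, 2.0])


def test_resample_linear_ramp_stays_linear():
    ramp = np.linspace(-3.0, 11.0, 57)
    for target in (2, 13, 57, 301):
        out = resample(ramp, target)
        np.testing.assert_allclose(out, np.linspace(-3.0, 11.0, target), atol=1e-12)
        assert out[0] == ramp[0] and out[-1] == ramp[-1]


def test_resample_errors():
    with pytest.raises(ValueError):
        resample(np.array([1.0, 2.0]), 1)
    with pytest.raises(ValueError):
        resample(np.array([]), 5)


# ------------------------------------------------------------- wavelets/CWT

@pytest.mark.parametrize("family", FAMILIES)
def test_psi_hat_analytic_and_peaked(family):
    omega = np.linspace(-10, 25, 2000)
    vals = psi_hat(family, omega)
    assert np.all(vals[omega <= 0] == 0)
    assert np.all(vals >= 0)
    assert vals.max() == pytest.approx(1.0, abs=1e-3)
    wc = center_omega(family)
    assert vals.argmax() == pytest.approx(np.argmin(np.abs(omega - wc)), abs=2)


def test_unknown_family_errors():
    with pytest.raises(ValueError):
        psi_hat("haar", np.array([1.0]))
    with pytest.raises(ValueError):
        WaveletSpec(family="haar")


def test_cwt_zero_input_gives_zero_matrix():
    C, scales = cwt_scalogram(np.zeros(64), "bump", n_scales=16)
    assert C.shape == (16, 64)
    assert np.all(C == 0)
    assert np.all(np.diff(scales) > 0)


@pytest.mark.parametrize("family", FAMILIES)
def test_cwt_homogeneity(family):
    rng = np.random.default_rng(4)
    x = rng.normal(size=128)
    C1, _ = cwt_scalogram(x, family, n_scales=12)
    C2, _ = cwt_scalogram(3.5 * x, family, n_scales=12)
    np.testing.assert_allclose(C2, 3.5 * C1, rtol=1e-9, atol=1e-12)


@pytest.mark.parametrize("family", FAMILIES)
@pytest.mark.parametrize("f", [0.03, 0.1, 0.25])
def test_cwt_sinusoid_peak_row(family, f):
    """Row of maximal energy matches the scale whose center frequency is
    nearest the sinusoid's frequency (brute-force argmax oracle)."""
    n = 256
    t = np.arange(n)
    x = np.sin(2 * np.pi * f * t)
    C, scales = cwt_scalogram(x, family, n_scales=48)
    core = C[:, n // 4 : 3 * n // 4]  # ignore edge effects
    energy_row = int(np.argmax((core**2).sum(axis=1)))
    expected = int(np.argmin([abs(center_frequency(family, s) - f) for s in scales]))
    assert abs(energy_row - expected) <= 2


def test_scale_grid_spans_two_cycles_to_nyquist():
    scales = scale_grid("morlet", 256, 32)
    freqs = np.array([center_frequency("morlet", s) for s in scales])
    assert freqs[0] == pytest.approx(0.5, rel=1e-9)
    assert freqs[-1] == pytest.approx(2.0 / 256, rel=1e-9)


def test_cwt_rejects_short_windows():
    with pytest.raises(ValueError):
        cwt_scalogram(np.ones(4), "morlet", n_scales=8)


# ------------------------------------------------------------- normalize

def test_normalize_forced_example():
    out = normalize_scalogram(np.array([[0.0, 2.0], [4.0, 8.0]]))
    np.testing.assert_allclose(out, [[0.0, 0.25], [0.5, 1.0]])


def test_normalize_constant_and_errors():
    np.testing.assert_array_equal(
        normalize_scalogram(np.full((3, 3), 7.0)), np.zeros((3, 3))
    )
    with pytest.raises(ValueError):
        normalize_scalogram(np.array([[1.0, np.inf]]))


@given(st.integers(0, 10_000))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_normalize_bounds_property(seed):
    rng = np.random.default_rng(seed)
    C = rng.exponential(size=(5, 9))
    out = normalize_scalogram(C)
    assert out.min() == 0.0
    assert out.max() == 1.0
    assert np.all((out >= 0) & (out <= 1))


# ------------------------------------------------------------- end-to-end

def test_preprocess_record_stack_shape_and_normalization():
    rng = np.random.default_rng(8)
    rec = EEGRecord("x", rng.normal(size=512), label="ictal")
    stack = preprocess_record(rec, window_len=128, overlap=0.25,
                              wavelet="morlet", n_scales=16)
    assert stack.tensor.shape[0] == 16
    assert stack.tensor.shape[1] == 128
    assert stack.label == "ictal"
    # per-window normalization: every slice attains 0 and 1
    for j in range(stack.tensor.shape[2]):
        assert stack.tensor[:, :, j].min() == 0.0
        assert stack.tensor[:, :, j].max() == 1.0


def test_preprocess_single_window_and_determinism():
    rng = np.random.default_rng(9)
    samples = rng.normal(size=200)
    rec1 = EEGRecord("a", samples, label="ictal")
    rec2 = EEGRecord("b", samples.copy(), label="ictal")
    s1 = preprocess_record(rec1, window_len=200, overlap=0.5,
                           wavelet="bump", n_scales=8)
    s2 = preprocess_record(rec2, window_len=200, overlap=0.5,
                           wavelet="bump", n_scales=8)
    assert s1.tensor.shape == (8, 200, 1)
    np.testing.assert_array_equal(s1.tensor, s2.tensor)


def test_optional_bilinear_resize_stage():
    rng = np.random.default_rng(10)
    rec = EEGRecord("x", rng.normal(size=300), label="interictal")
    stack = preprocess_record(rec, window_len=100, overlap=0.0,
                              wavelet="gmw", n_scales=12, resize_to=(20, 25))
    assert stack.tensor.shape[:2] == (20, 25)
    # resize of a constant image is constant
    np.testing.assert_allclose(
        resize_bilinear(np.full((7, 11), 3.0), (5, 4)), np.full((5, 4), 3.0)
    )
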