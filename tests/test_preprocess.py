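import numpy as np
import pytest
from scipy.signal import savgol_coeffs, savgol_filter
from scipy.stats import spearmanr

from dmclibs import (PreprocessConfig, PreprocessError, correct_baseline,
                     denoise_comparison_table, fit_baseline, min_max_normalize,
                     preprocess_pipeline, sg_coefficients, sg_filter, snr_db,
                     wavelet_denoise)


# --------------------------------------------------------------------------
# min-max normalisation
# --------------------------------------------------------------------------

def test_min_max_normalize_by_hand():
    assert np.allclose(min_max_normalize(np.array([2.0, 4.0, 6.0])),
                       [0.0, 0.5, 1.0])
    already = np.array([0.0, 0.25, 0.75, 1.0])
    assert np.allclose(min_max_normalize(already), already)


def test_min_max_normalize_is_monotone():
    rng = np.random.default_rng(0)
    y = rng.normal(size=200)
    z = min_max_normalize(y)
    assert z.min() == 0.0 and z.max() == 1.0
    assert spearmanr(y, z).statistic == 1.0


def test_min_max_normalize_degenerate():
    with pytest.raises(PreprocessError, match="degenerate"):
        min_max_normalize(np.full(10, 3.0))


# --------------------------------------------------------------------------
# Savitzky-Golay
# --------------------------------------------------------------------------

def brute_force_center_weights(order, window):
    """Independent oracle: fit the window polynomial per unit basis vector
    and read the central fitted value."""
    m = window // 2
    t = np.arange(-m, m + 1, dtype=float)
    weights = np.empty(window)
    for j in range(window):
        e = np.zeros(window)
        e[j] = 1.0
        coef = np.polynomial.polynomial.polyfit(t, e, order)
        weights[j] = coef[0]                 # value at t = 0
    return weights


@pytest.mark.parametrize("order,window",
                         [(p, w) for w in range(3, 12, 2)
                          for p in range(0, 7) if p < w])
def test_sg_coefficients_match_least_squares_oracle(order, window):
    f = sg_coefficients(order, window)
    oracle = brute_force_center_weights(order, window)
    assert np.abs(f.coefficients - oracle).max() < 1e-10
    assert abs(f.coefficients.sum() - 1.0) < 1e-12
    assert np.allclose(f.coefficients, f.coefficients[::-1], atol=1e-12)


def test_sg_coefficients_cross_checked_against_scipy():
    f = sg_coefficients(5, 7)
    assert np.abs(f.coefficients - savgol_coeffs(7, 5)).max() < 1e-12


def test_sg_order0_is_moving_average():
    f = sg_coefficients(0, 3)
    assert np.allclose(f.coefficients, [1 / 3] * 3)


def test_sg_invalid_args():
    with pytest.raises(PreprocessError):
        sg_coefficients(3, 6)          # even window
    with pytest.raises(PreprocessError):
        sg_coefficients(7, 7)          # window <= order
    with pytest.raises(PreprocessError, match="shorter"):
        sg_filter(np.zeros(3), sg_coefficients(2, 5))


@pytest.mark.parametrize("order,window", [(2, 5), (3, 7), (5, 7), (4, 9)])
def test_sg_filter_reproduces_polynomials_including_edges(order, window):
    x = np.linspace(0.0, 1.0, 50)
    rng = np.random.default_rng(order * window)
    coeffs = rng.normal(size=order + 1)
    y = np.polynomial.polynomial.polyval(x, coeffs)
    out = sg_filter(y, sg_coefficients(order, window))
    assert np.abs(out - y).max() <= 1e-9 * max(np.abs(y).max(), 1.0)


def test_sg_filter_matches_scipy_interp_mode():
    rng = np.random.default_rng(4)
    y = rng.normal(size=120).cumsum()
    ours = sg_filter(y, sg_coefficients(5, 7))
    assert np.abs(ours - savgol_filter(y, 7, 5, mode="interp")).max() < 1e-9


def test_sg_filter_reduces_noise_variance():
    rng = np.random.default_rng(11)
    t = np.linspace(0, 4 * np.pi, 400)
    clean = np.sin(t)
    noisy = clean + rng.normal(0, 0.2, size=t.size)
    smoothed = sg_filter(noisy, sg_coefficients(3, 11))
    assert np.var(smoothed - clean) < np.var(noisy - clean)


# --------------------------------------------------------------------------
# wavelet denoising and SNR
# --------------------------------------------------------------------------

def test_wavelet_zero_in_zero_out():
    out = wavelet_denoise(np.zeros(512), 5)
    assert np.allclose(out, 0.0)


def test_wavelet_preserves_low_order_polynomial():
    u = np.linspace(0, 1, 2048)
    y = 5.0 + 3.0 * u - 2.0 * u ** 2
    out = wavelet_denoise(y, 5)
    assert np.linalg.norm(out - y) / np.linalg.norm(y) < 1e-3


def test_wavelet_does_not_increase_energy():
    rng = np.random.default_rng(2)
    y = rng.normal(size=1024)
    out = wavelet_denoise(y, 6)
    assert np.sum(out ** 2) <= np.sum(y ** 2) * (1 + 1e-9)


def test_wavelet_infeasible_level_raises():
    with pytest.raises(PreprocessError, match="infeasible"):
        wavelet_denoise(np.zeros(256), 19)


def test_wavelet_improves_snr_on_noisy_spectrum():
    # a spectrum whose peaks are well resolved by the grid (several samples
    # per line width), the regime wavelet shrinkage is designed for
    rng = np.random.default_rng(5)
    x = np.linspace(370.0, 1100.0, 2048)
    centers = np.array([480.0, 589.14, 656.26, 766.49, 900.0])
    clean = 100.0 + 800.0 * np.exp(
        -0.5 * ((x[:, None] - centers) / 3.0) ** 2).sum(axis=1)
    noisy = clean + rng.normal(0, 10.0, size=clean.size)
    den = wavelet_denoise(noisy, 5, wavelet="sym4")
    err_before = np.sum((noisy - clean) ** 2)
    err_after = np.sum((den - clean) ** 2)
    assert err_after < err_before


def test_snr_db_analytic():
    d = np.ones(100) * 10.0
    raw = d + np.sqrt(np.sum(d ** 2) / 100 / 100)  # residual power = signal/100
    assert abs(snr_db(raw, d) - 20.0) < 1e-9


def test_snr_db_identical_is_infinite():
    y = np.arange(1.0, 10.0)
    assert snr_db(y, y) == np.inf


def test_snr_db_errors():
    with pytest.raises(PreprocessError, match="zero"):
        snr_db(np.ones(4), np.zeros(4))
    with pytest.raises(PreprocessError, match="length"):
        snr_db(np.ones(4), np.ones(5))


def test_denoise_comparison_table(default_dataset):
    rng = np.random.default_rng(6)
    y = default_dataset.intensities[0] + rng.normal(0, 10, 2048)
    table = denoise_comparison_table(y, wt_levels=range(5, 20))
    assert set(table["method"]) == {"SG", "WT"}
    assert (table["snr_db"] > 0).all()
    # SG(5,7) present and finite, as in the denoiser-selection protocol
    sg57 = table[(table.method == "SG")
                 & (table.parameter == "order=5,window=7")]
    assert len(sg57) == 1 and np.isfinite(sg57.snr_db.iloc[0])


# --------------------------------------------------------------------------
# baseline fitting / correction
# --------------------------------------------------------------------------

@pytest.fixture()
def curved_with_peaks():
    x = np.linspace(370.0, 1100.0, 800)
    u = (x - 370.0) / 730.0
    base = 20.0 + 10.0 * u - 25.0 * u ** 2 + 18.0 * u ** 3
    centers = np.array([450.0, 560.0, 650.0, 820.0, 950.0])
    peaks = 60.0 * np.exp(
        -0.5 * ((x[:, None] - centers) / 2.5) ** 2).sum(axis=1)
    offpeak = np.min(np.abs(x[:, None] - centers), axis=1) > 15.0
    return x, base, base + peaks, offpeak


def test_iterative_baseline_fixed_point_on_peak_free_cubic(curved_with_peaks):
    x, base, _, _ = curved_with_peaks
    fit, r2, iters = fit_baseline(base, x, "iterative_polynomial", degree=3)
    assert np.abs(fit - base).max() < 1e-8
    assert r2 >= 0.999
    assert iters <= 100


def test_iterative_baseline_recovers_under_peaks(curved_with_peaks):
    x, base, y, offpeak = curved_with_peaks
    fit, _, _ = fit_baseline(y, x, "iterative_polynomial", degree=3,
                             max_iter=200, tol=1e-8)
    rel = np.abs(fit - base)[offpeak] / np.abs(base)[offpeak]
    assert rel.max() < 0.02


def test_linear_fit_worse_than_iterative_on_curved(curved_with_peaks):
    x, _, y, _ = curved_with_peaks
    _, r2_lin, _ = fit_baseline(y, x, "linear")
    _, r2_it, _ = fit_baseline(y, x, "iterative_polynomial", degree=3,
                               max_iter=200, tol=1e-8)
    assert r2_lin < r2_it


def test_iterative_baseline_clamp_is_monotone(curved_with_peaks):
    """The fitted baseline never exceeds the running working signal."""
    x, _, y, _ = curved_with_peaks
    fit, _, _ = fit_baseline(y, x, "iterative_polynomial", degree=3,
                             max_iter=50, tol=0.0)
    assert (fit <= y + 1e-6).mean() > 0.95   # clamped under the peaks


def test_baseline_errors():
    with pytest.raises(PreprocessError, match="increasing"):
        fit_baseline(np.ones(10), np.zeros(10))
    with pytest.raises(PreprocessError, match="samples"):
        fit_baseline(np.ones(3), np.arange(3.0), degree=5)
    with pytest.raises(PreprocessError, match="unknown"):
        fit_baseline(np.ones(10), np.arange(10.0), method="magic")


def test_correct_baseline_cases():
    y = np.array([1.0, 5.0, 2.0])
    assert np.allclose(correct_baseline(y, y), 0.0)
    flat = np.array([2.0, 2.0, 2.0])
    peak = flat + np.array([0.0, 7.0, 0.0])
    out = correct_baseline(peak, flat)
    assert np.allclose(out, [0.0, 7.0, 0.0])
    assert (correct_baseline(np.zeros(3), np.ones(3)) == 0.0).all()


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def test_identity_config_passes_through(tiny_dataset):
    cfg = PreprocessConfig(sg_order=0, sg_window=1, baseline_method=None,
                           normalize=False)
    out = preprocess_pipeline(tiny_dataset, cfg)
    assert np.array_equal(out.intensities, tiny_dataset.intensities)


def test_pipeline_default_on_synth(tiny_dataset):
    out = preprocess_pipeline(tiny_dataset, PreprocessConfig())
    assert len(out) == len(tiny_dataset)
    assert np.array_equal(out.labels, tiny_dataset.labels)
    assert out.intensities.min() >= 0.0
    assert out.intensities.max() <= 1.0 + 1e-9
    # off-peak region reduced to near zero after baseline removal
    centers = [589.14, 656.26, 766.49, 450.0]
    off = np.min(np.abs(out.wavelengths[:, None] - np.array(centers)),
                 axis=1) > 30.0
    assert out.intensities[:, off].mean() < 0.02 * out.intensities.max()


def test_pipeline_deterministic(tiny_dataset):
    a = preprocess_pipeline(tiny_dataset)
    b = preprocess_pipeline(tiny_dataset)
    assert np.array_equal(a.intensities, b.intensities)


def test_pipeline_dataset_scope_normalisation(tiny_dataset):
    out = preprocess_pipeline(
        tiny_dataset, PreprocessConfig(normalize_scope="dataset",
                                       baseline_method=None, sg_window=1))
    assert out.intensities.min() == 0.0
    assert abs(out.intensities.max() - 1.0) < 1e-12
    # relative scale between spectra preserved (single affine map)
    raw, new = tiny_dataset.intensities, out.intensities
    ratio = (new[1] - new[0]) / (raw[1] - raw[0] + 1e-300)
    assert np.allclose(ratio[np.abs(raw[1] - raw[0]) > 1.0],
                       ratio[np.abs(raw[1] - raw[0]) > 1.0][0])


def test_config_validation():
    with pytest.raises(PreprocessError):
        PreprocessConfig(sg_order=5, sg_window=4)
    with pytest.raises(PreprocessError):
        PreprocessConfig(baseline_method="nope")
    with pytest.raises(PreprocessError):
        PreprocessConfig(normalize_scope="global")
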