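"""Spectral preprocessing: normalisation, Savitzky-Golay smoothing,
wavelet denoising, SNR scoring and iterative polynomial baseline correction.

The default chain applied to each spectrum is min-max normalisation, then
SG smoothing (order 5, window 7), then subtraction of an iteratively fitted
polynomial baseline; the stage order is configurable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .spectra_io import SpectralDataset

__all__ = ["PreprocessConfig", "SGFilter", "min_max_normalize",
           "sg_coefficients", "sg_filter", "wavelet_denoise", "snr_db",
           "fit_baseline", "correct_baseline", "preprocess_pipeline",
           "denoise_comparison_table", "PreprocessError"]


class PreprocessError(ValueError):
    """Raised for invalid preprocessing inputs or configurations."""


@dataclass
class PreprocessConfig:
    """Settings for the per-spectrum preprocessing chain.

    ``sg_window == 1`` disables smoothing; ``baseline_method=None`` disables
    baseline correction.  ``stage_order`` permutes the three stages.
    """

    sg_order: int = 5
    sg_window: int = 7
    baseline_method: "str | None" = "iterative_polynomial"
    baseline_degree: int = 3
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-6
    normalize: bool = True
    normalize_scope: str = "spectrum"    # or "dataset": one min/max for all
    stage_order: tuple = ("normalize", "sg", "baseline")

    def __post_init__(self):
        if self.normalize_scope not in ("spectrum", "dataset"):
            raise PreprocessError(
                f"normalize_scope must be 'spectrum' or 'dataset', "
                f"got {self.normalize_scope!r}")
        if self.sg_window != 1:
            if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
                raise PreprocessError(
                    f"sg_window must be odd and > sg_order "
                    f"(got window={self.sg_window}, order={self.sg_order})")
        if self.baseline_method not in (None, "none", "linear", "polynomial",
                                        "iterative_polynomial"):
            raise PreprocessError(f"unknown baseline method {self.baseline_method!r}")
        if set(self.stage_order) - {"normalize", "sg", "baseline"}:
            raise PreprocessError(f"unknown stage in {self.stage_order!r}")


@dataclass(frozen=True)
class SGFilter:
    """Central-point Savitzky-Golay smoothing weights c_{-m..m}."""

    order: int
    window: int
    coefficients: np.ndarray

    @property
    def half_width(self) -> int:
        return self.window // 2


def min_max_normalize(y: np.ndarray) -> np.ndarray:
    """Map ``y`` linearly onto [0, 1]: (y - min) / (max - min)."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise PreprocessError("min_max_normalize needs at least 2 samples")
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise PreprocessError("degenerate input: constant vector has no min-max range")
    return (y - lo) / (hi - lo)


def sg_coefficients(order: int, window: int) -> SGFilter:
    """Least-squares smoothing weights for the window's central point.

    Fits a degree-``order`` polynomial to the 2m+1 window samples at integer
    offsets -m..m and reads off the fitted value at offset 0; the weights are
    the first row of (X^T X)^{-1} X^T.  They sum to 1 and are symmetric.
    """
    if window % 2 == 0 or window <= order or order < 0:
        raise PreprocessError(
            f"need odd window > order >= 0 (got order={order}, window={window})")
    m = window // 2
    offsets = np.arange(-m, m + 1, dtype=float)
    X = np.vander(offsets, order + 1, increasing=True)
    coeffs = np.linalg.solve(X.T @ X, X.T)[0]
    return SGFilter(order=order, window=window, coefficients=coeffs)


def sg_filter(y: np.ndarray, f: SGFilter) -> np.ndarray:
    """Apply SG smoothing, y_k = sum_i c_i x_{k+i}, preserving length.

    Edges are handled by fitting the window polynomial anchored at each end
    and evaluating it at the edge positions, so polynomials of degree <= order
    are reproduced exactly end to end.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise PreprocessError("sg_filter expects a 1-D vector")
    if len(y) < f.window:
        raise PreprocessError(
            f"input length {len(y)} shorter than window {f.window}")
    m = f.half_width
    out = np.empty_like(y)
    # interior: correlation with the central-point weights
    out[m:len(y) - m] = np.convolve(y, f.coefficients[::-1], mode="valid")
    if m:
        offsets = np.arange(f.window, dtype=float)
        X = np.vander(offsets, f.order + 1, increasing=True)
        proj = X @ np.linalg.solve(X.T @ X, X.T)   # window-poly projector
        out[:m] = (proj @ y[:f.window])[:m]
        out[len(y) - m:] = (proj @ y[-f.window:])[f.window - m:]
    return out


def wavelet_denoise(y: np.ndarray, levels: int, wavelet: str = "sym4",
                    mode: str = "smooth") -> np.ndarray:
    """Multi-level DWT soft-threshold denoising.

    Noise scale is the median absolute deviation of the finest detail band
    (sigma = MAD/0.6745) and the universal threshold sigma*sqrt(2 ln n) is
    applied softly to all detail bands.
    """
    y = np.asarray(y, dtype=float)
    wav = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(len(y), wav.dec_len)
    if levels < 1 or levels > max_level:
        raise PreprocessError(
            f"decomposition level {levels} infeasible for length {len(y)} "
            f"with {wavelet} (max {max_level})")
    coeffs = pywt.wavedec(y, wav, mode=mode, level=levels)
    d1 = coeffs[-1]
    sigma = np.median(np.abs(d1 - np.median(d1))) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(len(y)))
    if thr > 0:
        coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft")
                                for c in coeffs[1:]]
    out = pywt.waverec(coeffs, wav, mode=mode)
    return out[:len(y)]


def snr_db(raw: np.ndarray, denoised: np.ndarray) -> float:
    """Signal-to-noise ratio in decibels.

    Defined as 10 log10(sum d^2 / sum (raw-d)^2), the power of the retained
    signal over the power of the removed residual.  A zero residual (raw ==
    denoised) returns +inf.
    """
    raw = np.asarray(raw, dtype=float)
    denoised = np.asarray(denoised, dtype=float)
    if raw.shape != denoised.shape:
        raise PreprocessError("raw and denoised must have equal length")
    if not np.any(denoised):
        raise PreprocessError("denoised signal is identically zero")
    res = np.sum((raw - denoised) ** 2)
    if res == 0.0:
        return float("inf")
    return float(10.0 * np.log10(np.sum(denoised ** 2) / res))


def denoise_comparison_table(y: np.ndarray, sg_orders=(3, 5, 7), sg_window: int = 7,
                             wt_levels=range(5, 20), wavelet: str = "sym4"):
    """SNR comparison of SG smoothing vs wavelet denoising on one spectrum.

    Returns a DataFrame with columns (method, parameter, snr_db); wavelet
    levels infeasible for the input length are skipped.
    """
    import pandas as pd

    rows = []
    for p in sg_orders:
        win = max(sg_window, p + 1 + (p % 2 == 0))
        if win % 2 == 0:
            win += 1
        d = sg_filter(y, sg_coefficients(p, win))
        rows.append(("SG", f"order={p},window={win}", snr_db(y, d)))
    max_level = pywt.dwt_max_level(len(y), pywt.Wavelet(wavelet).dec_len)
    for lv in wt_levels:
        if lv > max_level:
            continue
        d = wavelet_denoise(y, lv, wavelet)
        rows.append(("WT", f"levels={lv}", snr_db(y, d)))
    return pd.DataFrame(rows, columns=["method", "parameter", "snr_db"])


def _polyfit_eval(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    # numpy's Polynomial.fit handles domain scaling for conditioning
    return np.polynomial.Polynomial.fit(x, y, degree)(x)


def fit_baseline(y: np.ndarray, x: np.ndarray, method: str = "iterative_polynomial",
                 degree: int = 3, max_iter: int = 100, tol: float = 1e-6):
    """Estimate the continuum baseline under a spectrum.

    ``linear``/``polynomial``: one least-squares fit (degree forced to 1 for
    linear).  ``iterative_polynomial``: repeatedly fit a degree-``degree``
    polynomial to a working signal and clamp the working signal to the
    pointwise minimum of itself and the fit, so emission peaks are
    progressively excluded; stops when the fitted baseline's maximum relative
    change drops below ``tol`` or after ``max_iter`` rounds.

    Returns ``(baseline, r_squared, n_iterations)`` where ``r_squared`` is the
    coefficient of determination of the final fit against its target signal.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise PreprocessError("x and y must have equal length")
    if len(x) >= 2 and not np.all(np.diff(x) > 0):
        raise PreprocessError("wavelength vector must be strictly increasing")
    if method == "linear":
        degree = 1
    if len(y) < degree + 2:
        raise PreprocessError(f"need at least degree+2={degree + 2} samples")

    def r2(target, fit):
        ss_res = np.sum((target - fit) ** 2)
        ss_tot = np.sum((target - target.mean()) ** 2)
        return 1.0 if ss_tot == 0 else float(1.0 - ss_res / ss_tot)

    if method in ("linear", "polynomial"):
        base = _polyfit_eval(x, y, degree)
        return base, r2(y, base), 1

    if method != "iterative_polynomial":
        raise PreprocessError(f"unknown baseline method {method!r}")

    # the design matrix is fixed across iterations: precompute the hat
    # matrix projector on a conditioning-scaled abscissa
    u = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    V = np.vander(u, degree + 1, increasing=True)
    Q = np.linalg.pinv(V)
    work = y.copy()
    prev = None
    iters = 0
    for iters in range(1, max_iter + 1):
        base = V @ (Q @ work)
        if prev is not None:
            scale = max(np.max(np.abs(prev)), 1e-12)
            if np.max(np.abs(base - prev)) / scale < tol:
                break
        work = np.minimum(work, base)
        prev = base
    return base, r2(work, base), iters


def correct_baseline(y: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Subtract the baseline and floor at zero (counts are nonnegative)."""
    y = np.asarray(y, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if y.shape != baseline.shape:
        raise PreprocessError("y and baseline must have equal length")
    return np.clip(y - baseline, 0.0, None)


def preprocess_pipeline(ds: SpectralDataset, cfg: "PreprocessConfig | None" = None
                        ) -> SpectralDataset:
    """Apply the configured chain to every spectrum of a dataset.

    Labels, grid and grouping metadata pass through unchanged; the operation
    is deterministic.
    """
    cfg = cfg or PreprocessConfig()
    sgf = sg_coefficients(cfg.sg_order, cfg.sg_window) if cfg.sg_window != 1 else None
    out = np.array(ds.intensities, dtype=float, copy=True)
    x = ds.wavelengths
    glo, ghi = (out.min(), out.max()) if out.size else (0.0, 1.0)
    if cfg.normalize and cfg.normalize_scope == "dataset" and ghi == glo:
        raise PreprocessError("degenerate dataset: constant intensities")
    for i in range(out.shape[0]):
        y = out[i]
        for stage in cfg.stage_order:
            if stage == "normalize" and cfg.normalize:
                if cfg.normalize_scope == "dataset":
                    y = (y - glo) / (ghi - glo)
                else:
                    y = min_max_normalize(y)
            elif stage == "sg" and sgf is not None:
                y = sg_filter(y, sgf)
            elif stage == "baseline" and cfg.baseline_method not in (None, "none"):
                base, _, _ = fit_baseline(y, x, cfg.baseline_method,
                                          cfg.baseline_degree,
                                          cfg.baseline_max_iter, cfg.baseline_tol)
                y = correct_baseline(y, base)
        out[i] = y
    return ds.with_intensities(out)
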