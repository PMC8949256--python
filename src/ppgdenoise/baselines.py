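"""Classical comparison denoisers.

Two families are provided:

* wavelet shrinkage — decompose, soft-threshold the detail coefficients with
  the universal threshold ``sigma_hat * sqrt(2 ln N)`` (``sigma_hat`` from the
  median absolute deviation of the finest details), reconstruct;
* sliding-window filters — median, local-statistics Wiener, and Gaussian
  smoothing, each with edge replication.

:func:`wavelet_for` and :func:`best_respective` return the published
per-noise-kind configurations this package benchmarks against: e.g. a
discrete Meyer wavelet at level 3 for Gaussian noise, a median filter of
window 5 for salt-and-pepper noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pywt
from scipy import ndimage

from .exceptions import ParameterError
from .signal_core import Segment

__all__ = [
    "WaveletConfig",
    "FilterConfig",
    "wavelet_denoise",
    "median_filter",
    "wiener_filter",
    "gaussian_smooth",
    "wavelet_for",
    "best_respective",
    "gaussian_kernel",
    "apply_filter",
]

_SUPPORTED_WAVELETS = {"dmey", "db18", "db19", "db20", "sym15"}


@dataclass(frozen=True)
class WaveletConfig:
    """Wavelet shrinkage configuration.

    ``wavelet_name`` uses PyWavelets naming (``dmey``, ``db18``, ``db19``,
    ``db20``, ``sym15``). Levels beyond the nominal maximum for the segment
    length are honoured through boundary-extended transforms.
    """

    wavelet_name: str
    level: int
    threshold_rule: Literal["universal-soft"] = "universal-soft"

    def __post_init__(self) -> None:
        if self.wavelet_name not in _SUPPORTED_WAVELETS:
            raise ParameterError(
                f"unsupported wavelet {self.wavelet_name!r}; "
                f"expected one of {sorted(_SUPPORTED_WAVELETS)}"
            )
        if self.level < 1:
            raise ParameterError("level must be >= 1")


@dataclass(frozen=True)
class FilterConfig:
    """Sliding-window filter configuration (median/wiener) or Gaussian sigma."""

    filter_kind: Literal["median", "wiener", "gaussian"]
    window: int = 0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.filter_kind in ("median", "wiener"):
            if self.window < 1 or self.window % 2 == 0:
                raise ParameterError("window must be an odd integer >= 1")
        elif self.filter_kind == "gaussian":
            if self.sigma <= 0:
                raise ParameterError("sigma must be > 0")
        else:
            raise ParameterError(f"unknown filter kind {self.filter_kind!r}")


def _as_array(x) -> tuple[np.ndarray, Segment | None]:
    if isinstance(x, Segment):
        return x.samples, x
    return np.asarray(x, dtype=np.float64), None


def _wrap(y: np.ndarray, seg: Segment | None):
    if seg is None:
        return y
    return seg.with_samples(y, None)


def wavelet_decompose(x: np.ndarray, cfg: WaveletConfig) -> list[np.ndarray]:
    """Multi-level DWT with symmetric boundary extension."""
    with warnings.catch_warnings():
        # levels beyond dwt_max_level are deliberate (boundary-extended)
        warnings.simplefilter("ignore", UserWarning)
        return pywt.wavedec(x, cfg.wavelet_name, mode="symmetric",
                            level=cfg.level)


def wavelet_reconstruct(coeffs: list[np.ndarray], cfg: WaveletConfig,
                        length: int) -> np.ndarray:
    y = pywt.waverec(coeffs, cfg.wavelet_name, mode="symmetric")
    return y[:length]


def wavelet_denoise(x, cfg: WaveletConfig):
    """Universal-threshold soft shrinkage of the detail coefficients.

    The noise scale is estimated from the finest detail band as
    ``MAD/0.6745``; all detail bands are soft-thresholded at
    ``sigma_hat*sqrt(2 ln N)`` and the signal reconstructed. Length is
    preserved.
    """
    arr, seg = _as_array(x)
    n = len(arr)
    if pywt.Wavelet(cfg.wavelet_name).dec_len > 2 * n:
        raise ParameterError("segment too short for this wavelet")
    coeffs = wavelet_decompose(arr, cfg)
    finest = coeffs[-1]
    sigma_hat = np.median(np.abs(finest)) / 0.6745
    thr = sigma_hat * np.sqrt(2.0 * np.log(n))
    if thr == 0.0:  # noise-free details: soft threshold is a no-op
        den = coeffs
    else:
        den = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft")
                             for c in coeffs[1:]]
    return _wrap(wavelet_reconstruct(den, cfg, n), seg)


def median_filter(x, window: int):
    """Sliding-window median with edge replication."""
    if window < 1 or window % 2 == 0:
        raise ParameterError("window must be an odd integer >= 1")
    arr, seg = _as_array(x)
    return _wrap(ndimage.median_filter(arr, size=window, mode="nearest"), seg)


def wiener_filter(x, window: int):
    """Local-statistics Wiener filter.

    Per position, with local mean ``m`` and local variance ``v`` over the
    window and noise power ``nu`` = mean of ``v`` over the segment:
    ``y = m + max(v - nu, 0) / max(v, nu) * (x - m)``. Smooth where the local
    variance is at the noise floor, pass-through where it is far above it.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError("window must be an odd integer >= 1")
    arr, seg = _as_array(x)
    m = ndimage.uniform_filter1d(arr, size=window, mode="nearest")
    m2 = ndimage.uniform_filter1d(arr * arr, size=window, mode="nearest")
    v = np.maximum(m2 - m * m, 0.0)
    nu = v.mean()
    denom = np.maximum(v, nu)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(denom > 0, np.maximum(v - nu, 0.0) / denom, 0.0)
    return _wrap(m + gain * (arr - m), seg)


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Normalized discrete Gaussian kernel truncated at 4 sigma."""
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    radius = max(int(np.ceil(4.0 * sigma)), 0)
    t = np.arange(-radius, radius + 1, dtype=np.float64)
    w = np.exp(-0.5 * (t / sigma) ** 2)
    return w / w.sum()


def gaussian_smooth(x, sigma: float):
    """Convolution with a normalized Gaussian kernel, edge replication."""
    arr, seg = _as_array(x)
    w = gaussian_kernel(sigma)
    radius = len(w) // 2
    padded = np.pad(arr, radius, mode="edge")
    return _wrap(np.convolve(padded, w, mode="valid"), seg)


# Published per-noise-kind configurations benchmarked in this package.
_WAVELET_TABLE = {
    "gaussian": WaveletConfig("dmey", 3),
    "poisson": WaveletConfig("db19", 3),
    "salt_pepper": WaveletConfig("db18", 6),
    "speckle": WaveletConfig("db20", 3),
    "uniform": WaveletConfig("sym15", 9),
}

_FILTER_TABLE = {
    "gaussian": FilterConfig("wiener", window=5),
    "poisson": FilterConfig("median", window=3),
    "salt_pepper": FilterConfig("median", window=5),
    "speckle": FilterConfig("wiener", window=3),
    "uniform": FilterConfig("gaussian", sigma=1.0),
}


def wavelet_for(kind: str) -> WaveletConfig:
    """The benchmark wavelet configuration for a single-noise kind."""
    try:
        return _WAVELET_TABLE[kind]
    except KeyError:
        raise ParameterError(f"no wavelet baseline for noise kind {kind!r}") from None


def best_respective(kind: str) -> FilterConfig:
    """The best conventional filter for a single-noise kind."""
    try:
        return _FILTER_TABLE[kind]
    except KeyError:
        raise ParameterError(f"no filter baseline for noise kind {kind!r}") from None


def apply_filter(x, cfg: FilterConfig):
    """Apply a :class:`FilterConfig` to a segment or array."""
    if cfg.filter_kind == "median":
        return median_filter(x, cfg.window)
    if cfg.filter_kind == "wiener":
        return wiener_filter(x, cfg.window)
    return gaussian_smooth(x, cfg.sigma)
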