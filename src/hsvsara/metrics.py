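"""Evaluation metrics: measurement rate, layer-averaged SNR (dB), and SSIM.

SNR and SSIM are computed on the final RGB images (original vs
reconstructed) so HSV- and RGB-space pipelines are directly comparable; the
three "layers" are the channels of whatever space the images carry.

SSIM uses the community-standard parameterization: 11 x 11 Gaussian window
with sigma = 1.5, k1 = 0.01, k2 = 0.03, dynamic range from the image's
declared channel range, window applied in "valid" mode so borders carry no
padding bias. A "global" (whole-image) window mode exists mainly so the
statistic can be checked against a direct single-window evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .colorspace import ColorImage
from .errors import ContractViolation


@dataclass
class MetricsReport:
    mr: float
    snr_db: float
    ssim: float
    per_layer_snr: tuple
    color_space_of_evaluation: str


def measurement_rate(m: int, n: int) -> float:
    """MR = m / n."""
    if m <= 0 or n <= 0 or m > n:
        raise ContractViolation(f"need 0 < m <= n, got m={m}, n={n}")
    return m / n


def _check_pair(s: ColorImage, s_hat: ColorImage):
    if s.pixels.shape != s_hat.pixels.shape:
        raise ContractViolation("image shapes differ")
    if s.space != s_hat.space:
        raise ContractViolation("color spaces differ")


def snr_db(s: ColorImage, s_hat: ColorImage):
    """Mean over the 3 layers of 20 log10(||s_l|| / ||s_l - s_hat_l||).

    Identical images yield an explicit +inf sentinel (per layer and mean),
    not an exception.

    Returns
    -------
    (mean_snr, per_layer) : float and tuple of 3 floats.
    """
    _check_pair(s, s_hat)
    per_layer = []
    for l in range(3):
        sig = np.linalg.norm(s.pixels[..., l])
        err = np.linalg.norm(s.pixels[..., l] - s_hat.pixels[..., l])
        if err == 0.0:
            per_layer.append(np.inf)
        else:
            per_layer.append(20.0 * np.log10(sig / err))
    per_layer = tuple(per_layer)
    return float(np.mean(per_layer)), per_layer


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    half = (size - 1) / 2.0
    x = np.arange(size) - half
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def _local_stats(a: np.ndarray, b: np.ndarray, window: np.ndarray):
    """Windowed means, variances and cross-covariance ('valid' mode)."""
    mu_a = fftconvolve(a, window, mode="valid")
    mu_b = fftconvolve(b, window, mode="valid")
    var_a = fftconvolve(a * a, window, mode="valid") - mu_a**2
    var_b = fftconvolve(b * b, window, mode="valid") - mu_b**2
    cov = fftconvolve(a * b, window, mode="valid") - mu_a * mu_b
    return mu_a, mu_b, var_a, var_b, cov


def _global_stats(a: np.ndarray, b: np.ndarray):
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return (np.atleast_2d(mu_a), np.atleast_2d(mu_b), np.atleast_2d(var_a),
            np.atleast_2d(var_b), np.atleast_2d(cov))


def ssim(
    s: ColorImage,
    s_hat: ColorImage,
    k1: float = 0.01,
    k2: float = 0.03,
    window: str = "gaussian",
    win_size: int = 11,
    sigma: float = 1.5,
) -> float:
    """Mean structural similarity over window positions, then over 3 layers.

    Per position: ((2 mu_a mu_b + C1)(2 cov + C2)) /
    ((mu_a^2 + mu_b^2 + C1)(var_a + var_b + C2)) with C1 = (k1 L)^2,
    C2 = (k2 L)^2 and L the declared dynamic range of each channel.
    """
    _check_pair(s, s_hat)
    if window not in ("gaussian", "global"):
        raise ContractViolation(f"unknown window mode {window!r}")
    if window == "gaussian":
        if win_size > s.side:
            raise ContractViolation("window larger than image")
        kern = _gaussian_window(win_size, sigma)
    vals = []
    for l in range(3):
        a = s.pixels[..., l].astype(float)
        b = s_hat.pixels[..., l].astype(float)
        L = s.ranges[l][1] - s.ranges[l][0]
        c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
        if window == "gaussian":
            mu_a, mu_b, var_a, var_b, cov = _local_stats(a, b, kern)
        else:
            mu_a, mu_b, var_a, var_b, cov = _global_stats(a, b)
        smap = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
            (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
        )
        vals.append(smap.mean())
    return float(np.mean(vals))


def ssim_components(
    a: np.ndarray, b: np.ndarray, L: float, k1: float = 0.01, k2: float = 0.03
):
    """Global-window luminance, contrast and structure terms for one layer.

    The product form l * c * s with C3 = C2/2 and unit exponents equals the
    two-factor SSIM formula; exposed for verification.
    """
    mu_a, mu_b = a.mean(), b.mean()
    sd_a, sd_b = a.std(), b.std()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    c3 = c2 / 2.0
    lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    con = (2 * sd_a * sd_b + c2) / (sd_a**2 + sd_b**2 + c2)
    struc = (cov + c3) / (sd_a * sd_b + c3)
    return lum, con, struc
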