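"""Synthetic color-image phantoms with controllable sparsity structure.

These stand in for clinical corpora (MRI, capsule endoscopy, colonoscopy,
retinal photographs) in tests and scaled benchmarks: piecewise-constant
shapes are wavelet-compressible the way anatomy-on-background images are,
``wavelet_sparse`` phantoms are *exactly* K-sparse in a named Daubechies
basis for exact-recovery experiments, and smooth gradients exercise the
low-frequency path. They are deterministic in the seed and valid inputs to
the pipeline without padding.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

from . import dictionary as dct
from .colorspace import RGB, ColorImage
from .errors import ContractViolation

KINDS = ("piecewise_constant", "wavelet_sparse", "smooth_gradient", "natural_like")


@dataclass(frozen=True)
class PhantomSpec:
    kind: str
    side: int = 64
    sparsity: int = 20
    seed: int = 0
    levels: int = 4
    color_profile: tuple = ((0.0, 255.0), (0.0, 255.0), (0.0, 255.0))
    quantize: bool = True

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ContractViolation(f"unknown phantom kind {self.kind!r}")
        if self.side % (2**self.levels) != 0:
            raise ContractViolation("side must be divisible by 2^levels")
        if not 0 <= self.sparsity < self.side**2:
            raise ContractViolation("sparsity K must satisfy 0 <= K < N^2")


def _affine_to(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = x.max() - x.min()
    if span == 0:
        return np.full_like(x, (lo + hi) / 2.0)
    return lo + (x - x.min()) * (hi - lo) / span


def _piecewise_channels(N: int, rng: np.random.Generator, profile) -> np.ndarray:
    # Rectangle edges sit on the even-pixel grid: piecewise-constant regions
    # with dyadically aligned boundaries are what makes this phantom strongly
    # Haar-compressible, which is its design purpose.
    yy, xx = np.mgrid[0:N, 0:N]
    img = np.empty((N, N, 3))
    for c, (lo, hi) in enumerate(profile):
        img[..., c] = rng.uniform(lo, lo + 0.25 * (hi - lo))
    for _ in range(6):  # rectangles
        h, w = (rng.integers(N // 8, N // 2, size=2) // 2) * 2
        r0 = (rng.integers(0, N - h) // 2) * 2
        c0 = (rng.integers(0, N - w) // 2) * 2
        for c, (lo, hi) in enumerate(profile):
            img[r0 : r0 + h, c0 : c0 + w, c] = rng.uniform(lo, hi)
    for _ in range(2):  # ellipses: curved boundaries, deliberately unaligned
        cy, cx = rng.uniform(0.2 * N, 0.8 * N, size=2)
        ry, rx = rng.uniform(N / 10, N / 6, size=2)
        mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        for c, (lo, hi) in enumerate(profile):
            img[mask, c] = rng.uniform(lo, hi)
    return img


def _wavelet_sparse_channel(
    N: int, K: int, levels: int, rng: np.random.Generator, wavelet: str = "db1"
) -> np.ndarray:
    """Channel whose db analysis has exactly K nonzeros (pre-quantization).

    All approximation coefficients are set to positive values (so the affine
    map to the display range — a scale plus a constant shift that lands only
    on the approximation block — cannot create or destroy nonzeros), and the
    remaining K - n_approx nonzeros go to random detail positions.
    """
    n_approx = (N // 2**levels) ** 2
    if K < n_approx:
        raise ContractViolation(
            f"wavelet_sparse needs K >= {n_approx} (approximation block size)"
        )
    probe = np.zeros((N, N))
    arr, sl = pywt.coeffs_to_array(
        dct._wavedec2(probe, wavelet, levels)
    )
    side_a = N // 2**levels
    arr[:side_a, :side_a] = rng.uniform(0.5, 1.5, size=(side_a, side_a))
    flat = arr.ravel()
    detail_idx = np.setdiff1d(np.arange(N * N), np.arange(N * N).reshape(N, N)[
        :side_a, :side_a].ravel())
    pick = rng.choice(detail_idx, size=K - n_approx, replace=False)
    flat[pick] = rng.uniform(0.5, 1.5, size=K - n_approx) * rng.choice(
        [-1.0, 1.0], size=K - n_approx
    )
    coeffs = pywt.array_to_coeffs(flat.reshape(N, N), sl, output_format="wavedec2")
    return pywt.waverec2(coeffs, wavelet, mode="periodization")


def make_phantom(spec: PhantomSpec) -> ColorImage:
    """Deterministic synthetic RGB test image; see :class:`PhantomSpec`."""
    rng = np.random.default_rng(
        np.random.SeedSequence([KINDS.index(spec.kind), spec.seed])
    )
    N = spec.side
    if spec.kind == "piecewise_constant":
        img = _piecewise_channels(N, rng, spec.color_profile)
    elif spec.kind == "wavelet_sparse":
        img = np.stack(
            [
                _affine_to(
                    _wavelet_sparse_channel(N, spec.sparsity, spec.levels, rng),
                    lo,
                    hi,
                )
                for lo, hi in spec.color_profile
            ],
            axis=-1,
        )
    elif spec.kind == "smooth_gradient":
        u = np.linspace(0.0, 1.0, N)
        img = np.empty((N, N, 3))
        for c, (lo, hi) in enumerate(spec.color_profile):
            a, b, ph = rng.uniform(0.5, 1.5, 3)
            ramp = a * np.outer(u, np.ones(N)) + b * np.outer(np.ones(N), u)
            ramp += 0.3 * np.sin(2 * np.pi * (u[None, :] + ph))
            img[..., c] = _affine_to(ramp, lo, hi)
    else:  # natural_like
        pw = _piecewise_channels(N, rng, spec.color_profile)
        texture = ndimage.gaussian_filter(rng.standard_normal((N, N, 3)), (1.5, 1.5, 0))
        u = np.linspace(0.0, 1.0, N)
        ramp = np.outer(u, np.ones(N))[..., None]
        img = np.empty((N, N, 3))
        for c, (lo, hi) in enumerate(spec.color_profile):
            mix = 0.6 * pw[..., c] + 0.25 * _affine_to(ramp[..., 0], lo, hi)
            mix += 0.15 * _affine_to(texture[..., c], lo, hi)
            img[..., c] = np.clip(mix, lo, hi)
    if spec.quantize:
        img = np.round(img)
    return ColorImage(img, RGB)


def make_sparse_layer(N: int, K: int, taps: int = 1, levels: int = 4, seed: int = 0):
    """Layer exactly K-sparse in one Daubechies basis, shifted into [0, 1].

    The positivity shift adds a constant image, which perturbs only the
    scaling (approximation) coefficients, so detail sparsity survives; the
    pre-shift analysis has exactly K nonzeros. Returns (layer, dictionary)
    where the dictionary is the single-basis frame the layer is sparse in.
    """
    if not 0 <= K < N * N:
        raise ContractViolation("need 0 <= K < N^2")
    d = dct.make_sa_dictionary(N, taps=(taps,), levels=levels)
    rng = np.random.default_rng(np.random.SeedSequence([max(taps, 1), seed]))
    coeffs = np.zeros(N * N)
    if K > 0:
        pos = rng.choice(N * N, size=K, replace=False)
        coeffs[pos] = rng.uniform(0.5, 1.5, K) * rng.choice([-1.0, 1.0], K)
    layer = dct.synthesis(d, coeffs)
    if layer.min() < 0:
        layer = layer - layer.min()
    peak = layer.max()
    if peak > 0:
        layer = layer / peak
    return layer, d


def write_phantom_corpus(outdir, specs) -> pathlib.Path:
    """Write PNG files + a manifest JSON for the benchmark CLI."""
    import imageio.v3 as iio

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, spec in enumerate(specs):
        img = make_phantom(spec)
        name = f"phantom_{i:03d}_{spec.kind}.png"
        iio.imwrite(outdir / name, img.pixels.astype(np.uint8))
        manifest.append(
            {
                "file": name,
                "kind": spec.kind,
                "side": spec.side,
                "sparsity": spec.sparsity,
                "seed": spec.seed,
                "levels": spec.levels,
                "color_profile": [list(r) for r in spec.color_profile],
            }
        )
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
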