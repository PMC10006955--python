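"""End-to-end compression / reconstruction of a color image.

Per color layer: preparation (normalize to [0, 1] by the channel's canonical
range, clip negatives), spread-spectrum Fourier measurement with a
layer-distinct operator seed, SARA (or plain BPDN) reconstruction, clipping
back to [0, 1], de-normalization, recombination, and — in HSV mode —
conversion back to RGB with 8-bit quantization.

The method matrix is a configuration:

==============  ==========  ===========
color_space     reweighting  method
==============  ==========  ===========
HSV             on          HSV-SARA
RGB             on          RGB-SARA style
RGB             off         RGB-BPSA style
HSV             off         HSV-BPDN ablation
==============  ==========  ===========

Hue is sampled and reconstructed as a plain linear signal on [0, 1]; the
0/360 wrap-around discontinuity is accepted (normalization is a straight
affine map).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import dictionary as dct
from . import sampling as smp
from . import solver as slv
from .colorspace import HSV, RGB, ColorImage, canonical_ranges, hsv_to_rgb, rgb_to_hsv
from .errors import ContractViolation
from .metrics import snr_db, ssim

CHANNELS = {RGB: ("R", "G", "B"), HSV: ("H", "S", "V")}


@dataclass(frozen=True)
class Layer:
    """One prepared channel: N x N values in [0, 1] plus its original range."""

    values: np.ndarray
    channel: str
    original_range: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ContractViolation("layer must be a square 2-D array")
        if not np.isfinite(v).all():
            raise ContractViolation("layer contains NaN/Inf")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ContractViolation("prepared layer must lie in [0, 1]")


@dataclass(frozen=True)
class PipelineConfig:
    color_space: str = HSV
    reweighting: bool = True
    mr: float = 0.3
    seed: int = 0
    taps: tuple = dct.DEFAULT_TAPS
    levels: int = dct.DEFAULT_LEVELS
    recon: slv.ReconConfig = field(default_factory=slv.ReconConfig)

    def __post_init__(self):
        if self.color_space not in (RGB, HSV):
            raise ContractViolation(f"unknown color space {self.color_space!r}")

    @property
    def method_name(self) -> str:
        base = "SARA" if self.reweighting else "BPDN"
        return f"{self.color_space}-{base}"


@dataclass
class CompressedImage:
    """Three per-layer measurements plus everything needed to reconstruct."""

    side: int
    mr: float
    m: int
    color_space: str
    taps: tuple
    levels: int
    layer_seeds: tuple
    original_ranges: tuple
    measurements: list
    original_shape: tuple | None = None  # pre-padding (rows, cols), if padded
    pad_offset: tuple = (0, 0)

    def __post_init__(self):
        if len(self.measurements) != 3 or len(self.layer_seeds) != 3:
            raise ContractViolation("a compressed image carries exactly 3 layers")


@dataclass
class ReconstructionResult:
    image: ColorImage
    reports: list
    converged: bool


def prepare_layer(channel_image: np.ndarray, rng: tuple, channel: str = "V") -> Layer:
    """Normalize a raw channel to [0, 1] by its range, then clip negatives."""
    lo, hi = rng
    if not hi > lo:
        raise ContractViolation(f"degenerate range ({lo}, {hi})")
    vals = (np.asarray(channel_image, dtype=float) - lo) / (hi - lo)
    vals = np.clip(vals, 0.0, 1.0)
    return Layer(values=vals, channel=channel, original_range=(lo, hi))


def compress(
    img: ColorImage, cfg: PipelineConfig, original_shape: tuple | None = None,
    pad_offset: tuple = (0, 0),
) -> CompressedImage:
    """Convert to the working color space, prepare and measure each layer."""
    if img.space != RGB:
        raise ContractViolation("compress expects an RGB image")
    if img.side % (2**cfg.levels) != 0:
        raise ContractViolation(
            f"side {img.side} not divisible by 2^levels; pad the input first"
        )
    work = rgb_to_hsv(img) if cfg.color_space == HSV else img
    ranges = canonical_ranges(cfg.color_space)
    measurements = []
    seeds = tuple(cfg.seed + i for i in range(3))
    m = None
    for i in range(3):
        layer = prepare_layer(work.pixels[..., i], ranges[i], CHANNELS[cfg.color_space][i])
        op = smp.make_ssfs_operator(img.side, cfg.mr, seeds[i])
        measurements.append(smp.forward(op, layer.values))
        m = op.m
    return CompressedImage(
        side=img.side,
        mr=cfg.mr,
        m=m,
        color_space=cfg.color_space,
        taps=tuple(cfg.taps),
        levels=cfg.levels,
        layer_seeds=seeds,
        original_ranges=ranges,
        measurements=measurements,
        original_shape=original_shape,
        pad_offset=tuple(pad_offset),
    )


def _layer_config(cfg: PipelineConfig, y: np.ndarray, m: int, n: int) -> slv.ReconConfig:
    """Resolve epsilon per layer: 0 at full sampling (the system is exactly
    determined, so no denoising radius), else the configured rule."""
    rc = cfg.recon
    if m == n and rc.epsilon is None:
        rc = replace(rc, epsilon=0.0)
    if not cfg.reweighting:
        rc = replace(rc, imax=1)
    return rc


def decompress(c: CompressedImage, cfg: PipelineConfig) -> ReconstructionResult:
    """Reconstruct each layer, recombine, convert back to RGB, quantize."""
    if cfg.color_space != c.color_space or tuple(cfg.taps) != tuple(c.taps) \
            or cfg.levels != c.levels:
        raise ContractViolation("config inconsistent with archive metadata")
    d = dct.make_sa_dictionary(c.side, taps=c.taps, levels=c.levels)
    layers = []
    reports = []
    for i in range(3):
        meas = c.measurements[i]
        op = smp.make_ssfs_operator(c.side, c.mr, c.layer_seeds[i])
        if op.m != c.m:
            raise ContractViolation("regenerated operator disagrees with metadata")
        rc = _layer_config(cfg, meas.y, op.m, op.n)
        rep = slv.reweighted_analysis(meas, op, d, rc)
        est = np.clip(rep.layer_estimate, 0.0, 1.0)
        lo, hi = c.original_ranges[i]
        layers.append(est * (hi - lo) + lo)
        reports.append(rep)
    pixels = np.stack(layers, axis=-1)
    if c.color_space == HSV:
        pixels[..., 0] = np.mod(pixels[..., 0], 360.0)
        rgb = hsv_to_rgb(ColorImage(pixels, HSV))
    else:
        rgb = ColorImage(pixels, RGB)
    quantized = np.clip(np.round(rgb.pixels), 0.0, 255.0)
    image = ColorImage(quantized, RGB)
    return ReconstructionResult(
        image=image,
        reports=reports,
        converged=all(r.converged for r in reports),
    )


def crop_to_original(img: ColorImage, original_shape, pad_offset=(0, 0)) -> np.ndarray:
    """Undo symmetric padding applied at load time (returns a pixel array,
    possibly non-square)."""
    if original_shape is None:
        return img.pixels
    r0, c0 = pad_offset
    h, w = original_shape
    return img.pixels[r0 : r0 + h, c0 : c0 + w, :]


def run_benchmark(images, mrs, methods, method_names=None):
    """Compress + reconstruct every (image, mr, method) cell and score it.

    Returns a list of per-cell records and a list of aggregate rows (one per
    (mr, method): mean and standard deviation of SNR and SSIM over images).
    A cell whose solver fails to converge is still scored but flagged.
    """
    if not images or not mrs or not methods:
        raise ContractViolation("images, mrs and methods must be nonempty")
    if method_names is None:
        method_names = [m.method_name for m in methods]
    records = []
    for mi, (method, name) in enumerate(zip(methods, method_names)):
        for mr in mrs:
            cfg = replace(method, mr=mr)
            for ii, img in enumerate(images):
                comp = compress(img, cfg)
                result = decompress(comp, cfg)
                snr, per_layer = snr_db(img, result.image)
                records.append(
                    {
                        "method": name,
                        "method_index": mi,
                        "mr": mr,
                        "image": ii,
                        "snr_db": snr,
                        "ssim": ssim(img, result.image),
                        "converged": result.converged,
                    }
                )
    aggregates = []
    for mi, name in enumerate(method_names):
        for mr in mrs:
            cell = [
                r for r in records if r["method_index"] == mi and r["mr"] == mr
            ]
            snrs = np.array([r["snr_db"] for r in cell])
            ssims = np.array([r["ssim"] for r in cell])
            aggregates.append(
                {
                    "method": name,
                    "mr": mr,
                    "snr_mean": float(snrs.mean()),
                    "snr_std": float(snrs.std(ddof=1)) if len(snrs) > 1 else 0.0,
                    "ssim_mean": float(ssims.mean()),
                    "ssim_std": float(ssims.std(ddof=1)) if len(ssims) > 1 else 0.0,
                    "n_images": len(cell),
                }
            )
    return records, aggregates
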