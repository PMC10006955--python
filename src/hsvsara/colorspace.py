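"""RGB <-> HSV conversion and canonical channel ranges.

Hue is an angle in degrees on [0, 360), saturation a chroma fraction on
[0, 1], and value the maximum channel intensity on [0, 255] — i.e. V keeps
the 8-bit scale of the RGB input rather than being renormalized to 0–100.
All arithmetic is floating point; quantization to 8-bit integers happens
only at file output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractViolation

RGB = "RGB"
HSV = "HSV"

#: Inclusive per-channel (min, max) bounds. Hue is stored on [0, 360] with
#: 360 identified with 0 by the inverse conversion.
_CANONICAL = {
    RGB: ((0.0, 255.0), (0.0, 255.0), (0.0, 255.0)),
    HSV: ((0.0, 360.0), (0.0, 1.0), (0.0, 255.0)),
}


def canonical_ranges(space: str) -> tuple[tuple[float, float], ...]:
    """Per-channel (min, max) bounds for a color space tag."""
    try:
        return _CANONICAL[space]
    except KeyError:
        raise ContractViolation(f"unknown color space {space!r}") from None


@dataclass
class ColorImage:
    """A square N x N x 3 image tagged with its color space and channel ranges.

    Parameters
    ----------
    pixels : ndarray, shape (N, N, 3)
        Channel values as floats, each within its declared range.
    space : {"RGB", "HSV"}
    ranges : per-channel (min, max) pairs; defaults to the canonical ranges
        of ``space``.
    """

    pixels: np.ndarray
    space: str = RGB
    ranges: tuple[tuple[float, float], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.ranges is None:
            self.ranges = canonical_ranges(self.space)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ContractViolation(
                f"expected N x N x 3 pixel array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise ContractViolation("image must be square")
        if self.pixels.shape[0] < 8:
            raise ContractViolation("side length must be >= 8")
        if not np.isfinite(self.pixels).all():
            raise ContractViolation("pixels contain NaN/Inf")
        for c, (lo, hi) in enumerate(self.ranges):
            ch = self.pixels[..., c]
            if ch.min() < lo - 1e-9 or ch.max() > hi + 1e-9:
                raise ContractViolation(
                    f"channel {c} outside declared range [{lo}, {hi}]: "
                    f"observed [{ch.min()}, {ch.max()}]"
                )

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def rgb_to_hsv(img: ColorImage) -> ColorImage:
    """Convert an 8-bit-scale RGB image to HSV.

    Per pixel, with Imax = max(R,G,B), Imin = min(R,G,B), Idiff = Imax - Imin:

    * H = 0 when Imax = Imin; otherwise the 60-degree sector formula for
      whichever channel attains the maximum, wrapped into [0, 360).
    * S = 0 when Imax = 0, else Idiff / Imax.
    * V = Imax.
    """
    if img.space != RGB:
        raise ContractViolation(f"expected RGB input, got {img.space}")
    r, g, b = img.pixels[..., 0], img.pixels[..., 1], img.pixels[..., 2]
    imax = np.maximum(np.maximum(r, g), b)
    imin = np.minimum(np.minimum(r, g), b)
    idiff = imax - imin
    safe = np.where(idiff > 0, idiff, 1.0)  # avoid 0/0 in unselected branches

    h = np.select(
        [imax == imin, imax == r, imax == g],
        [
            np.zeros_like(r),
            np.mod(60.0 * (g - b) / safe, 360.0),
            60.0 * (b - r) / safe + 120.0,
        ],
        default=60.0 * (r - g) / safe + 240.0,
    )
    s = np.where(imax > 0, idiff / np.where(imax > 0, imax, 1.0), 0.0)
    v = imax
    return ColorImage(np.stack([h, s, v], axis=-1), HSV)


def hsv_to_rgb(img: ColorImage) -> ColorImage:
    """Exact inverse of :func:`rgb_to_hsv` wherever S > 0; S = 0 maps to gray.

    Accepts H = 360 as a synonym for H = 0.
    """
    if img.space != HSV:
        raise ContractViolation(f"expected HSV input, got {img.space}")
    h = np.mod(img.pixels[..., 0], 360.0)
    s = img.pixels[..., 1]
    v = img.pixels[..., 2]

    c = v * s
    hp = h / 60.0
    x = c * (1.0 - np.abs(np.mod(hp, 2.0) - 1.0))
    zero = np.zeros_like(c)

    sector = np.floor(hp).astype(int) % 6
    r1 = np.choose(sector, [c, x, zero, zero, x, c])
    g1 = np.choose(sector, [x, c, c, x, zero, zero])
    b1 = np.choose(sector, [zero, zero, x, c, c, x])

    m = v - c
    rgb = np.stack([r1 + m, g1 + m, b1 + m], axis=-1)
    # guard against float crumbs just outside [0, 255]
    np.clip(rgb, 0.0, 255.0, out=rgb)
    return ColorImage(rgb, RGB)
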