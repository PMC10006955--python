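"""File I/O: raster images, the compressed archive container, configs, tables.

Archive layout (single file, little-endian):

    8-byte magic ``SSFSCS01`` | uint32 header length | UTF-8 JSON header |
    3 blocks of m complex128 samples (interleaved re/im float64)

Operators are never stored: the header carries ``(side, mr, m, layer_seeds)``
and masks/signs are regenerated, which makes the round trip bit-exact.
"""

from __future__ import annotations

import json
import logging
import pathlib
import struct

import numpy as np
import yaml

from .colorspace import RGB, ColorImage
from .errors import ArchiveError, ConfigError, ContractViolation
from .pipeline import CompressedImage
from .sampling import Measurement

log = logging.getLogger("hsvsara")

MAGIC = b"SSFSCS01"
ARCHIVE_VERSION = 1

LOSSY_SUFFIXES = {".jpg", ".jpeg"}


def load_image(path, levels: int = 4) -> tuple[ColorImage, tuple | None, tuple]:
    """Read a raster file, pad to a valid square side, return geometry.

    Returns ``(image, original_shape, pad_offset)`` where ``original_shape``
    is None when no padding was needed. Grayscale inputs are stacked to three
    channels; an alpha channel is dropped with a warning.
    """
    import imageio.v3 as iio

    path = pathlib.Path(path)
    if path.suffix.lower() in LOSSY_SUFFIXES:
        log.warning(
            "%s is a lossy format: metrics will be computed against the "
            "decoded image, not the original scene", path.name,
        )
    arr = np.asarray(iio.imread(path))
    if arr.dtype == np.uint16:
        raise ContractViolation("16-bit inputs are not supported; expected 8-bit")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        log.warning("dropping alpha channel of %s", path.name)
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ContractViolation(f"unsupported image shape {arr.shape}")
    arr = arr.astype(float)

    h, w = arr.shape[:2]
    block = 2**levels
    side = max(h, w, 8)
    if side % block:
        side += block - side % block
    if (h, w) == (side, side):
        return ColorImage(arr, RGB), None, (0, 0)
    top = (side - h) // 2
    left = (side - w) // 2
    padded = np.zeros((side, side, 3))
    padded[top : top + h, left : left + w, :] = arr
    log.info("padded %dx%d input to %dx%d", h, w, side, side)
    return ColorImage(padded, RGB), (h, w), (top, left)


def save_image(path, pixels: np.ndarray) -> None:
    import imageio.v3 as iio

    arr = np.clip(np.round(np.asarray(pixels)), 0, 255).astype(np.uint8)
    iio.imwrite(pathlib.Path(path), arr)


def write_archive(path, c: CompressedImage) -> None:
    header = {
        "version": ARCHIVE_VERSION,
        "side": c.side,
        "mr": c.mr,
        "m": c.m,
        "color_space": c.color_space,
        "taps": list(c.taps),
        "levels": c.levels,
        "layer_seeds": list(c.layer_seeds),
        "original_ranges": [list(r) for r in c.original_ranges],
        "original_shape": list(c.original_shape) if c.original_shape else None,
        "pad_offset": list(c.pad_offset),
    }
    blob = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<I", len(blob)))
        fh.write(blob)
        for meas in c.measurements:
            fh.write(np.ascontiguousarray(meas.y, dtype="<c16").tobytes())


def read_archive(path) -> CompressedImage:
    try:
        data = pathlib.Path(path).read_bytes()
    except OSError as e:
        raise ArchiveError(f"cannot read archive: {e}") from e
    if len(data) < len(MAGIC) + 4 or data[: len(MAGIC)] != MAGIC:
        raise ArchiveError("not a compressed-image archive (bad magic)")
    off = len(MAGIC)
    (hlen,) = struct.unpack_from("<I", data, off)
    off += 4
    try:
        header = json.loads(data[off : off + hlen].decode())
    except (UnicodeDecodeError, json.JSONDecodeError) as e:
        raise ArchiveError(f"corrupt archive header: {e}") from e
    off += hlen
    if header.get("version") != ARCHIVE_VERSION:
        raise ArchiveError(f"unsupported archive version {header.get('version')}")
    m = header["m"]
    block = 16 * m
    if len(data) != off + 3 * block:
        raise ArchiveError("archive truncated or trailing bytes present")
    measurements = []
    for i in range(3):
        y = np.frombuffer(data[off + i * block : off + (i + 1) * block], dtype="<c16")
        measurements.append(
            Measurement(y=y.copy(), operator_id=(header["side"], m,
                                                 header["layer_seeds"][i]))
        )
    return CompressedImage(
        side=header["side"],
        mr=header["mr"],
        m=m,
        color_space=header["color_space"],
        taps=tuple(header["taps"]),
        levels=header["levels"],
        layer_seeds=tuple(header["layer_seeds"]),
        original_ranges=tuple(tuple(r) for r in header["original_ranges"]),
        measurements=measurements,
        original_shape=tuple(header["original_shape"])
        if header["original_shape"]
        else None,
        pad_offset=tuple(header["pad_offset"]),
    )


def load_run_config(path) -> dict:
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except OSError as e:
        raise ConfigError(f"cannot read config: {e}") from e
    except yaml.YAMLError as e:
        raise ConfigError(f"invalid YAML: {e}") from e
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    for key in ("corpus", "mrs", "methods"):
        if key not in cfg:
            raise ConfigError(f"config missing required key {key!r}")
    return cfg


def write_table_csv(aggregates, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=[
                "method", "mr", "snr_mean", "snr_std",
                "ssim_mean", "ssim_std", "n_images",
            ],
        )
        writer.writeheader()
        writer.writerows(aggregates)


def write_table_markdown(aggregates, path) -> None:
    """mean +/- std cells, rows = MR, columns = methods."""
    methods = list(dict.fromkeys(r["method"] for r in aggregates))
    mrs = sorted({r["mr"] for r in aggregates})
    cell = {(r["method"], r["mr"]): r for r in aggregates}
    lines = []
    for metric, label in [("snr", "SNR (dB)"), ("ssim", "SSIM")]:
        lines.append(f"### {label}")
        lines.append("| MR | " + " | ".join(methods) + " |")
        lines.append("|---" * (len(methods) + 1) + "|")
        for mr in mrs:
            row = [f"{mr:g}"]
            for meth in methods:
                r = cell[(meth, mr)]
                row.append(f"{r[metric + '_mean']:.2f}±{r[metric + '_std']:.2f}")
            lines.append("| " + " | ".join(row) + " |")
        lines.append("")
    pathlib.Path(path).write_text("\n".join(lines))


def plot_benchmark(aggregates, outdir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = pathlib.Path(outdir)
    methods = list(dict.fromkeys(r["method"] for r in aggregates))
    for metric, ylabel, fname in [
        ("snr", "SNR (dB)", "snr_vs_mr.png"),
        ("ssim", "SSIM", "ssim_vs_mr.png"),
    ]:
        fig, ax = plt.subplots(figsize=(5, 4))
        for meth in methods:
            rows = sorted(
                (r for r in aggregates if r["method"] == meth), key=lambda r: r["mr"]
            )
            ax.errorbar(
                [r["mr"] for r in rows],
                [r[metric + "_mean"] for r in rows],
                yerr=[r[metric + "_std"] for r in rows],
                marker="o",
                capsize=3,
                label=meth,
            )
        ax.set_xlabel("measurement rate m/n")
        ax.set_ylabel(ylabel)
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / fname, dpi=120)
        plt.close(fig)
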