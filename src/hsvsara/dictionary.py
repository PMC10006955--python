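"""Sparsity-averaging wavelet dictionary: concatenated orthonormal Daubechies bases.

The synthesis operator is the 1/sqrt(p)-scaled horizontal concatenation of p
orthonormal wavelet synthesis operators (periodized boundary, the only mode
that keeps finite-size Daubechies transforms exactly orthonormal). With that
scaling the dictionary is a tight frame: synthesis(analysis(x)) = x and
Parseval holds, so the data-fidelity radius epsilon keeps its meaning for
any number of bases.

The default pair is db1 (Haar) + db8; the full db1..db8 ladder used by the
p = 8 averaging baselines is one argument away (``taps=range(1, 9)``).
Scaling (approximation) coefficients are kept inside the l1 penalty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .errors import ContractViolation

DEFAULT_TAPS = (1, 8)
DEFAULT_LEVELS = 4


def _wavedec2(layer, wavelet, levels):
    with warnings.catch_warnings():
        # periodization keeps orthonormality even when the filter is longer
        # than the coarsest band; pywt's boundary-effect warning is moot here
        warnings.filterwarnings("ignore", message="Level value")
        return pywt.wavedec2(layer, wavelet, mode="periodization", level=levels)


@dataclass(frozen=True)
class SADictionary:
    """Concatenation of p orthonormal Daubechies bases as a tight frame."""

    side: int
    taps: tuple
    levels: int
    slices: tuple  # per-basis coeffs_to_array slice structure

    @property
    def p(self) -> int:
        return len(self.taps)

    @property
    def norm_factor(self) -> float:
        return 1.0 / np.sqrt(self.p)

    @property
    def n_coeffs(self) -> int:
        return self.p * self.side * self.side

    def wavelet(self, tap: int) -> str:
        return f"db{tap}"


def make_sa_dictionary(
    side: int, taps=DEFAULT_TAPS, levels: int = DEFAULT_LEVELS
) -> SADictionary:
    taps = tuple(int(t) for t in taps)
    if not taps:
        raise ContractViolation("taps list must be nonempty")
    if any(t < 1 or t > 38 for t in taps):
        raise ContractViolation(f"unsupported Daubechies tap count in {taps}")
    if levels < 1:
        raise ContractViolation("levels must be >= 1")
    if side % (2**levels) != 0:
        raise ContractViolation(
            f"side {side} not divisible by 2^levels = {2 ** levels}"
        )
    probe = np.zeros((side, side))
    slices = []
    for t in taps:
        _, sl = pywt.coeffs_to_array(_wavedec2(probe, f"db{t}", levels))
        slices.append(sl)
    return SADictionary(side=side, taps=taps, levels=levels, slices=tuple(slices))


def analysis(d: SADictionary, layer: np.ndarray) -> np.ndarray:
    """Psi^H x: per-basis full 2-D DWT, scaled by 1/sqrt(p), blocks concatenated.

    Output layout: contiguous length-N^2 blocks in ``taps`` order, each block
    the pywt coefficient array raveled in C order.
    """
    layer = np.asarray(layer)
    if layer.shape != (d.side, d.side):
        raise ContractViolation(
            f"layer shape {layer.shape} does not match dictionary side {d.side}"
        )
    blocks = []
    for t in d.taps:
        arr, _ = pywt.coeffs_to_array(_wavedec2(layer, f"db{t}", d.levels))
        blocks.append(arr.ravel())
    return np.concatenate(blocks) * d.norm_factor


def synthesis(d: SADictionary, coeffs: np.ndarray) -> np.ndarray:
    """Psi c: sum of per-basis inverse DWTs, scaled by 1/sqrt(p). Adjoint of analysis."""
    coeffs = np.asarray(coeffs)
    n = d.side * d.side
    if coeffs.shape != (d.p * n,):
        raise ContractViolation(
            f"coefficient length {coeffs.shape} != p*N^2 = {d.p * n}"
        )
    out = np.zeros((d.side, d.side), dtype=coeffs.dtype)
    for i, t in enumerate(d.taps):
        arr = coeffs[i * n : (i + 1) * n].reshape(d.side, d.side)
        c = pywt.array_to_coeffs(arr, d.slices[i], output_format="wavedec2")
        out = out + pywt.waverec2(c, f"db{t}", mode="periodization")
    return out * d.norm_factor
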