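"""Spread-spectrum Fourier sampling: the sensing operator Phi = M F S.

S is a Rademacher +/-1 diagonal (the spread-spectrum modulation), F the
unitary 2-D DFT, and M a row-selection mask over DFT bins. With unitary
normalization Phi has orthonormal rows (Phi Phi^H = I_m), which gives the
solver a closed-form projection onto the data-fidelity ball.

Pixel arrays are vectorized in column-major (Fortran) order throughout;
forward and adjoint share the convention, so any consistent choice is
equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractViolation


@dataclass(frozen=True)
class SSFSOperator:
    """Factored sensing operator for one N x N layer.

    Attributes
    ----------
    side : N, the layer side length.
    n : signal length N^2.
    m : number of retained DFT bins (measurements).
    mask_indices : sorted unique flat bin indices, always containing 0 (DC).
    spread_signs : length-n array of +/-1.
    seed : the seed the operator was built from (canonical serialization:
        an operator is regenerated from ``(side, m, seed)``, never stored).
    """

    side: int
    n: int
    m: int
    mask_indices: np.ndarray
    spread_signs: np.ndarray
    seed: int

    @property
    def mr(self) -> float:
        return self.m / self.n


@dataclass(frozen=True)
class Measurement:
    """A compressed layer: m complex DFT samples plus operator identity."""

    y: np.ndarray
    operator_id: tuple  # (side, m, seed)

    def __post_init__(self):
        object.__setattr__(self, "y", np.asarray(self.y, dtype=complex))
        if self.y.ndim != 1:
            raise ContractViolation("measurement vector must be 1-D")


def make_ssfs_operator(
    N: int, mr: float, seed: int, variable_density: bool = False
) -> SSFSOperator:
    """Build the sampling operator for an N x N layer at measurement rate mr.

    The mask is drawn uniformly at random without replacement over the N^2
    DFT bins, always including the DC bin. ``variable_density=True`` instead
    weights bin selection by 1/(1 + rho^2) in normalized radial frequency
    rho (useful for smooth images; not the default). Mask and sign draws use
    independent streams derived deterministically from ``seed``.
    """
    if N < 8:
        raise ContractViolation(f"N must be >= 8, got {N}")
    if not 0 < mr <= 1:
        raise ContractViolation(f"mr must be in (0, 1], got {mr}")
    n = N * N
    m = min(max(int(round(mr * n)), 1), n)

    rng_mask = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    rng_sign = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))

    if m == n:
        mask = np.arange(n)
    elif variable_density:
        u = np.arange(N)
        f = np.minimum(u, N - u) / (N / 2)  # normalized frequency per axis
        # column-major flattening: bin (u, v) -> u + N*v
        rho2 = (f[:, None] ** 2 + f[None, :] ** 2).ravel(order="F")
        w = 1.0 / (1.0 + rho2)
        w[0] = 0.0
        w /= w.sum()
        rest = rng_mask.choice(n, size=m - 1, replace=False, p=w)
        mask = np.sort(np.concatenate(([0], rest)))
    else:
        rest = 1 + rng_mask.choice(n - 1, size=m - 1, replace=False)
        mask = np.sort(np.concatenate(([0], rest)))

    signs = rng_sign.choice(np.array([-1.0, 1.0]), size=n)
    return SSFSOperator(
        side=N, n=n, m=m, mask_indices=mask, spread_signs=signs, seed=int(seed)
    )


def _check_layer(op: SSFSOperator, layer: np.ndarray) -> np.ndarray:
    layer = np.asarray(layer)
    if layer.shape != (op.side, op.side):
        raise ContractViolation(
            f"layer shape {layer.shape} does not match operator side {op.side}"
        )
    if not np.isfinite(layer).all():
        raise ContractViolation("layer contains NaN/Inf")
    return layer


def forward(op: SSFSOperator, layer: np.ndarray) -> Measurement:
    """y = M F S vec(layer): modulate, unitary 2-D DFT, keep masked bins."""
    layer = _check_layer(op, layer)
    spread = (layer.ravel(order="F") * op.spread_signs).reshape(
        (op.side, op.side), order="F"
    )
    spectrum = np.fft.fft2(spread, norm="ortho")
    y = spectrum.ravel(order="F")[op.mask_indices]
    return Measurement(y=y, operator_id=(op.side, op.m, op.seed))


def adjoint(op: SSFSOperator, y) -> np.ndarray:
    """Phi^H y: scatter bins, inverse unitary 2-D DFT, re-modulate.

    Returns an N x N complex array (real part is the back-projection of a
    real image's measurements).
    """
    vec = y.y if isinstance(y, Measurement) else np.asarray(y, dtype=complex)
    if vec.shape != (op.m,):
        raise ContractViolation(
            f"measurement length {vec.shape} does not match operator m={op.m}"
        )
    full = np.zeros(op.n, dtype=complex)
    full[op.mask_indices] = vec
    spectrum = full.reshape((op.side, op.side), order="F")
    spread = np.fft.ifft2(spectrum, norm="ortho")
    return (spread.ravel(order="F") * op.spread_signs).reshape(
        (op.side, op.side), order="F"
    )
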