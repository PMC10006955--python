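# Methods

## Model

A color image `s ∈ Z^{N×N×3}` (8-bit RGB) is compressed layer by layer in a
chosen working color space (HSV by default, RGB for baselines). Each layer is
*prepared* — affinely mapped to `[0, 1]` by its canonical channel range, with
negatives clipped — and measured by the spread-spectrum Fourier operator

    Φ = M F S,

`S` a Rademacher ±1 diagonal, `F` the unitary 2-D DFT, `M` a row selection of
`m = round(MR·N²)` bins drawn uniformly without replacement (DC always
included). Unitary normalization gives `Φ Φᴴ = I_m`, so the projection onto
the data-fidelity ball is closed-form; the spread-spectrum modulation makes
the measurement incoherent with any fixed orthonormal sparsity basis, which
is why a uniform mask suffices (a variable-density mask is available behind a
flag but is not the default). Pixels are vectorized in column-major order;
forward and adjoint share the convention.

Reconstruction solves, per layer,

    min_x ‖W Ψᵀ x‖₁   s.t.  ‖y − Φx‖₂ ≤ ε,  x real, x ≥ 0,

with `Ψ = (1/√p)[Ψ₁ … Ψ_p]` the sparsity-averaging tight frame of `p`
orthonormal Daubechies bases. The `1/√p` scaling is the one that makes
`Ψ Ψᵀ = I` and preserves energy (Parseval), so `ε` keeps its meaning for any
`p`. Boundary handling is periodization — the only mode in which finite-size
Daubechies transforms are exactly orthonormal (verified to ~1e-15 even when
the filter is longer than the coarsest band). Scaling coefficients are kept
inside the ℓ1 penalty. The default pair is db1+db8; the full db1..db8 ladder
is `taps=range(1,9)`.

## Solver

The inner problem is solved by PPXA — Douglas–Rachford splitting on a
(p+2)-fold product space — over complex iterates:

* one block per wavelet basis for the ℓ1 term. The full analysis-ℓ1 norm has
  no closed-form prox for p ≥ 2, but it splits as a sum over bases, and each
  single-basis operator `B_i = (1/√p)Ψ_iᵀ` satisfies `B_i B_iᵀ = I/p`, so the
  Moreau composition formula applies exactly per block. (An earlier variant
  that applied the composition formula to the whole frame converged to a
  step-size-dependent point ~1e-3 off in objective; the split version agrees
  with an independent convex-programming solution to ~1e-13.)
* one block projecting onto `{x : ‖y − Φx‖₂ ≤ ε}` via `Φ Φᴴ = I`;
* one block projecting onto the real nonnegative orthant — the only place
  imaginary parts are discarded. Keeping iterates complex is what makes the
  ball projection exact; restricting to real vectors first would couple the
  masked bins through conjugate symmetry and destroy the closed form.

After the iteration cap or a relative-change stop (`inner_tol`, default
1e-5), a short alternating-projection polish guarantees the returned point
satisfies both the fidelity ball (within 1% relative slack) and positivity
exactly. A solve that still cannot reach the ball is returned flagged
(`converged=False`), not raised. Everything is deterministic: identical
inputs give bit-identical reports.

The objective along DR-type iterations is not per-step monotone (the trace
is recorded and the tests assert the end-to-end decrease, not per-iterate
monotonicity).

Degenerate case: at full sampling with `ε = 0` the constraint set is the
single point `Φᴴy`, and the solver returns its clipped real part directly.
The pipeline sets `ε = 0` whenever `m = n`, which is what makes the
MR = 1.0 round trip lossless to within 8-bit quantization; with the default
relative `ε` the ℓ1 shrinkage could move pixels by more than one intensity
level. For undersampled layers the default is `ε = 1e-3·‖y‖₂` (noiseless
inputs; absolute override available).

Reweighting (the RA loop): solve once with unit weights, then repeat with
`w_i = δ/(δ + |c_i|)` computed from the previous solution's analysis
coefficients, `δ` starting at the standard deviation of those coefficients
("auto") and halving per iteration (floor 1e-6). The loop stops when the
relative ℓ2 change `β` between successive solutions falls below `ra_tol`
(default 1e-3) or after `imax` solves (default 10). Re-solves are
warm-started from the previous solution. With `imax = 1` the pipeline
degenerates to plain BPDN (the "BPSA-style" baselines).

### Parameters that matter

| knob | default | meaning |
|---|---|---|
| `mr` | — | measurement rate m/n per layer |
| `epsilon_rel` | 1e-3 | fidelity radius as a fraction of ‖y‖₂ |
| `gamma` | 1e-2 | ℓ1 prox step; tuned for unit-scale layers, "auto" rescales |
| `inner_max_iter` / `inner_tol` | 500 / 1e-5 | PPXA budget and stop |
| `imax` / `ra_tol` | 10 / 1e-3 | RA solves cap and β stop |
| `delta0` / `delta_decay` | auto / 0.5 | weight floor schedule |
| `taps` / `levels` | (1, 8) / 4 | dictionary composition |

The DR step size `gamma` does not change the limit point (verified against
an SLSQP oracle across γ), only the convergence speed; 1e-2 is a good
compromise for layers normalized to `[0, 1]`.

## Color space

RGB→HSV follows the channel-wise max/min formulas: H is the 60°-sector angle
wrapped into [0, 360), S = Idiff/Imax (0 when Imax = 0), V = Imax — so V
keeps the 8-bit scale rather than a 0–100 display scale, and S is a unit
fraction. All layers are renormalized to `[0, 1]` before sampling, so the
stored scale is immaterial to the reconstruction. Achromatic pixels get
H = 0, and the inverse maps S = 0 to gray regardless of stored hue. Hue is
treated as a *linear* signal during sampling/reconstruction; the 0/360
wrap-around discontinuity is accepted (a reconstruction error across the
wrap shows up as a hue error like any other).

## Metrics

SNR (dB) is the mean over the three channels of `20·log10(‖s_l‖₂/‖s_l−ŝ_l‖₂)`,
computed on the final RGB images so HSV and RGB pipelines are directly
comparable. Identical images yield an explicit +inf sentinel. SSIM uses the
two-factor local form with C1 = (0.01·L)², C2 = (0.03·L)² (L the declared
channel range), an 11×11 Gaussian window (σ = 1.5) applied in valid mode so
borders carry no padding bias; a global-window mode exists for verification
against single-window hand evaluation, and the three-factor
luminance/contrast/structure product with C3 = C2/2 is exposed for the same
purpose.

## Phantoms: what they emulate, and what they do not

The synthetic corpus stands in for clinical images:

* `piecewise_constant` — colored rectangles and ellipses on a background;
  rectangle edges sit on the even-pixel grid so the phantom is strongly
  Haar-compressible (≥ 90% of level-4 detail coefficients exactly zero),
  which is the regime the wavelet prior is designed for. Ellipses are
  deliberately unaligned to keep some curved-boundary content.
* `wavelet_sparse` — each channel has *exactly* K nonzero db1 coefficients
  before 8-bit quantization. All approximation coefficients are drawn
  positive so the affine map to display range (a scale plus a constant,
  which lands only on the approximation block) cannot change the nonzero
  count; K must be at least the approximation-block size.
* `smooth_gradient` and `natural_like` exercise the low-frequency path and
  mixtures with mild texture.
* `make_sparse_layer` builds a single-basis K-sparse layer for recovery
  experiments; its positivity shift adds a constant image, which perturbs
  only scaling coefficients, so detail sparsity survives the shift.

These phantoms validate the *mechanics* (operators, solver, pipeline) and
the qualitative rate–quality trend. They do **not** reproduce the color
statistics of clinical images — in particular the inter-channel structure
that makes the HSV decomposition advantageous on medical data. On random
colored phantoms, hue behaves like a noisy, weakly structured channel, and
the RGB pipeline can match or beat the HSV one; passing tests therefore
demonstrate correctness and the MR-monotone quality trend, not HSV
superiority on real images.

## Problem sizes and numerical choices

Benchmarks in the tests and the acceptance script run on 64×64 phantoms with
a lighter solver preset (`inner_max_iter=300, inner_tol=1e-4, imax=5,
ra_tol=2e-3`), chosen as the point where quality saturates on this corpus
(further iterations change mean SNR by well under 1 dB at MR ≥ 0.1). Exact
recovery experiments use 32×32 layers with K = 20 and `ε = 1e-6·‖y‖₂` —
with the db1+db8 frame, plain BPDN recovers at MR 0.5 to ~120 dB, while at
MR 0.3 it stalls around 30 dB and the reweighting loop restores ~120 dB,
which is the clearest demonstration of what RA buys. Comparisons at the
−0.1 dB level are made against that tiny-ε setup; with the looser default ε
the solution set's diameter alone moves SNR by ±0.2 dB around the ~60 dB
ε-limited floor, swamping such a tolerance.

Ties and degenerate inputs: a degenerate preparation range raises a contract
error; an RA re-solve that misses feasibility is retried once with a doubled
iteration budget before the report is flagged; hue 360 is accepted as a
synonym of 0 on input.

## Known limitations

* Hue's circular topology is ignored (by design, see above).
* The mask is drawn per layer (seeds seed, seed+1, seed+2), so an archive is
  reproducible only together with its seed metadata — masks are regenerated,
  never stored.
* No noise model in the sensor: ε defaults assume noiseless measurements.
* JPEG inputs are accepted but metrics then reference the decoded image.
* No Dirac block in the dictionary and no TV-denoising baseline.
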