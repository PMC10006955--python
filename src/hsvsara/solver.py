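"""Weighted basis-pursuit denoising and the reweighted-analysis (RA) outer loop.

One layer is reconstructed by solving

    min_x || w . Psi^H x ||_1   s.t.  || y - Phi x ||_2 <= eps,  x real, x >= 0

with Psi the tight sparsity-averaging frame and Phi the spread-spectrum
Fourier operator. The solver is PPXA — Douglas–Rachford splitting on a
(p+2)-fold product space — over complex iterates:

  1..p. prox of the weighted l1 norm of each basis' analysis block. The
     full analysis-l1 norm has no closed-form prox for p >= 2, but it splits
     as a sum over bases, and each single-basis term B_i = (1/sqrt p) Psi_i^T
     satisfies B_i B_i^T = (1/p) I, so its prox is exact
     (x + sqrt(p) Psi_i(soft(B_i x, gamma w_i / p) - B_i x));
  p+1. projection onto the data-fidelity ball: exact because Phi Phi^H = I
     (x + Phi^H r (1 - eps/||r||) for residual r with ||r|| > eps);
  p+2. projection onto the real nonnegative orthant (this is where imaginary
     parts are discarded — the other steps stay complex-linear).

The RA loop re-solves with weights w_i = delta/(delta + |c_i|) computed from
the previous solution's analysis coefficients c, with delta decaying
geometrically, and stops when the relative l2 change beta between successive
solutions falls below ``ra_tol`` or after ``imax`` solves in total.

Everything is deterministic: reports are bit-identical for identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import dictionary as dct
from . import sampling as smp
from .errors import ContractViolation

#: Relative slack allowed on the data-fidelity radius of a returned solution.
FEASIBILITY_SLACK = 1.01


@dataclass(frozen=True)
class ReconConfig:
    """Solver and reweighting knobs.

    epsilon : absolute l2 data-fidelity radius, or None to use
        ``epsilon_rel * ||y||_2`` (the default 1e-3 suits noiseless inputs).
    gamma : soft-threshold step of the l1 prox; the 1e-2 default is tuned for
        layers normalized to [0, 1]. "auto" scales it to the back-projection.
    inner_max_iter / inner_tol : PPXA iteration cap and relative-change stop.
    imax : maximum number of BPDN solves in the RA loop (1 = plain BPDN).
    ra_tol : threshold on beta, the relative l2 change between RA solutions.
    delta0 : initial weight floor; "auto" = std of the initial solution's
        analysis coefficients. Decays by ``delta_decay`` per RA iteration,
        floored at ``delta_floor``.
    """

    epsilon: float | None = None
    epsilon_rel: float = 1e-3
    gamma: float | str = 1e-2
    inner_max_iter: int = 500
    inner_tol: float = 1e-5
    imax: int = 10
    ra_tol: float = 1e-3
    delta0: float | str = "auto"
    delta_decay: float = 0.5
    delta_floor: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.epsilon is not None and self.epsilon < 0:
            raise ContractViolation("epsilon must be >= 0")
        if not 0 < self.ra_tol < 1:
            raise ContractViolation("ra_tol must be in (0, 1)")
        if self.imax < 1:
            raise ContractViolation("imax must be >= 1")
        if not 0 < self.delta_decay <= 1:
            raise ContractViolation("delta_decay must be in (0, 1]")
        if self.inner_max_iter < 1:
            raise ContractViolation("inner_max_iter must be >= 1")

    def resolve_epsilon(self, y: np.ndarray) -> float:
        if self.epsilon is not None:
            return float(self.epsilon)
        return float(self.epsilon_rel * np.linalg.norm(y))


@dataclass
class SolveReport:
    """Outcome of one layer reconstruction."""

    layer_estimate: np.ndarray
    objective_trace: list = field(default_factory=list)
    fidelity: float = 0.0
    epsilon: float = 0.0
    ra_iterations: int = 0
    beta_trace: list = field(default_factory=list)
    inner_iterations: list = field(default_factory=list)
    converged: bool = True


def update_weights(coeffs: np.ndarray, delta: float) -> np.ndarray:
    """SARA weight rule w_i = delta / (delta + |c_i|), in (0, 1]."""
    if delta <= 0:
        raise ContractViolation("delta must be > 0")
    return delta / (delta + np.abs(coeffs))


def _soft(c: np.ndarray, thresh: np.ndarray) -> np.ndarray:
    """Complex soft threshold: shrink magnitudes by thresh, keep phase."""
    mag = np.abs(c)
    scale = np.maximum(mag - thresh, 0.0) / np.where(mag > 0, mag, 1.0)
    return c * scale


def _project_ball(op, y, eps, x):
    """Projection of complex x onto {x : ||y - Phi x|| <= eps} via Phi Phi^H = I."""
    r = y - smp.forward(op, x).y
    nr = np.linalg.norm(r)
    if nr <= eps:
        return x, nr
    return x + smp.adjoint(op, r * (1.0 - eps / nr)), nr


def solve_weighted_bpdn(
    y,
    op: smp.SSFSOperator,
    d: dct.SADictionary,
    w: np.ndarray | None,
    cfg: ReconConfig,
    x_init: np.ndarray | None = None,
) -> SolveReport:
    """Solve one weighted BPDN problem; see the module docstring.

    ``w=None`` means unit weights. A solve that cannot reach the fidelity
    ball within the iteration budget returns a report with
    ``converged=False`` rather than raising.
    """
    yvec = y.y if isinstance(y, smp.Measurement) else np.asarray(y, dtype=complex)
    if yvec.shape != (op.m,):
        raise ContractViolation("measurement length does not match operator")
    if not np.isfinite(yvec).all():
        raise ContractViolation("measurement contains NaN/Inf")
    eps = cfg.resolve_epsilon(yvec)
    if w is None:
        w = np.ones(d.n_coeffs)
    else:
        w = np.asarray(w, dtype=float)
        if w.shape != (d.n_coeffs,):
            raise ContractViolation("weight vector length != p*N^2")

    # Fully determined system: the constraint set is the single point
    # Phi^H y; return its real nonnegative projection directly.
    if op.m == op.n and eps == 0.0:
        est = np.maximum(smp.adjoint(op, yvec).real, 0.0)
        obj = float(np.sum(w * np.abs(dct.analysis(d, est))))
        fid = float(np.linalg.norm(yvec - smp.forward(op, est).y))
        return SolveReport(
            layer_estimate=est,
            objective_trace=[obj],
            fidelity=fid,
            epsilon=eps,
            inner_iterations=[0],
            converged=True,
        )

    x0 = smp.adjoint(op, yvec) if x_init is None else x_init.astype(complex)
    if cfg.gamma == "auto":
        gamma = 0.1 * float(np.abs(dct.analysis(d, x0)).max())
    else:
        gamma = float(cfg.gamma)

    # one single-basis sub-frame per wavelet: the l1 prox is exact per block
    p = d.p
    n2 = d.side * d.side
    subs = [dct.make_sa_dictionary(d.side, taps=(t,), levels=d.levels)
            for t in d.taps]
    w_blocks = [w[i * n2 : (i + 1) * n2] for i in range(p)]
    sqrt_p = np.sqrt(p)

    nblocks = p + 2
    zs = [x0.copy() for _ in range(nblocks)]
    xbar = x0.copy()
    obj_trace = []
    n_iter = 0
    for n_iter in range(1, cfg.inner_max_iter + 1):
        ps = []
        for i in range(p):
            c = dct.analysis(subs[i], zs[i]) / sqrt_p
            shrunk = _soft(c, (gamma / p) * w_blocks[i])
            ps.append(zs[i] + sqrt_p * dct.synthesis(subs[i], shrunk - c))
        ball, _ = _project_ball(op, yvec, eps, zs[p])
        ps.append(ball)
        ps.append(np.maximum(zs[p + 1].real, 0.0).astype(complex))
        pbar = sum(ps) / nblocks
        correction = 2.0 * pbar - xbar
        for i in range(nblocks):
            zs[i] += correction - ps[i]
        rel = np.linalg.norm(pbar - xbar) / max(np.linalg.norm(xbar), 1e-300)
        xbar = pbar
        obj_trace.append(float(np.sum(w * np.abs(dct.analysis(d, xbar.real)))))
        if rel < cfg.inner_tol and n_iter > 10:
            break

    # Feasibility polish: alternate ball / positivity projections so the
    # returned point satisfies both constraints, not just in the limit.
    est = np.maximum(xbar.real, 0.0)
    fid = float(np.linalg.norm(yvec - smp.forward(op, est).y))
    polish = 0
    while fid > eps * (1.0 + 1e-3) and polish < 200:
        proj, _ = _project_ball(op, yvec, eps * (1.0 - 1e-6), est.astype(complex))
        est = np.maximum(proj.real, 0.0)
        fid = float(np.linalg.norm(yvec - smp.forward(op, est).y))
        polish += 1

    converged = fid <= eps * FEASIBILITY_SLACK
    obj_trace.append(float(np.sum(w * np.abs(dct.analysis(d, est)))))
    return SolveReport(
        layer_estimate=est,
        objective_trace=obj_trace,
        fidelity=fid,
        epsilon=eps,
        inner_iterations=[n_iter],
        converged=converged,
    )


def reweighted_analysis(
    y, op: smp.SSFSOperator, d: dct.SADictionary, cfg: ReconConfig
) -> SolveReport:
    """SARA reconstruction: unit-weight BPDN followed by reweighted re-solves.

    Solve t (t >= 1) uses delta_t = max(delta0 * decay^(t-1), floor) and
    weights from the previous solution's analysis coefficients; beta_t is the
    relative l2 change between successive solutions. ``imax=1`` degenerates
    to the plain BPDN solve.
    """
    base = solve_weighted_bpdn(y, op, d, None, cfg)
    report = base
    if cfg.imax == 1:
        return report

    x_prev = base.layer_estimate
    c_prev = dct.analysis(d, x_prev)
    if cfg.delta0 == "auto":
        delta0 = float(np.std(c_prev))
        if delta0 <= 0:
            delta0 = cfg.delta_floor
    else:
        delta0 = float(cfg.delta0)

    beta_trace = []
    inner_iters = list(base.inner_iterations)
    solve_cfg = cfg
    t = 0
    for t in range(1, cfg.imax):
        delta = max(delta0 * cfg.delta_decay ** (t - 1), cfg.delta_floor)
        w = update_weights(c_prev, delta)
        rep = solve_weighted_bpdn(y, op, d, w, solve_cfg, x_init=x_prev)
        if not rep.converged:
            # one retry with doubled budget, delta not decayed further
            solve_cfg = replace(solve_cfg, inner_max_iter=2 * solve_cfg.inner_max_iter)
            rep = solve_weighted_bpdn(y, op, d, w, solve_cfg, x_init=x_prev)
            if not rep.converged:
                rep.ra_iterations = t
                rep.beta_trace = beta_trace
                return rep
        x_new = rep.layer_estimate
        beta = np.linalg.norm(x_new - x_prev) / max(np.linalg.norm(x_prev), 1e-300)
        beta_trace.append(float(beta))
        inner_iters.extend(rep.inner_iterations)
        x_prev = x_new
        c_prev = dct.analysis(d, x_prev)
        report = rep
        if beta < cfg.ra_tol:
            break

    report.ra_iterations = t
    report.beta_trace = beta_trace
    report.inner_iterations = inner_iters
    return report
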