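"""Baseline estimation for the series signal form via sparsity-assisted filtering.

The drawn series drifts slowly up or down the page; character separation
needs the signal *aligned* to a flat baseline.  The signal y is modelled as

    y = x + f + w

with x a sparse positive peak component (the characters), f a low-pass
baseline and w noise, and recovered by minimising

    F(x) = 1/2 ||H(y - x)||^2 + lam0 * sum theta_eps(x_n; r)
                               + lam1 * sum phi([D1 x]_n)
                               + lam2 * sum phi([D2 x]_n)

where H = B A^{-1} is the high-pass complement of a zero-phase recursive
low-pass filter with cut-off ``fc`` (banded matrices A, B), D1/D2 are first
and second difference operators, theta_eps the asymmetric sparsity penalty
with asymmetry ``r`` and phi a smoothed absolute value.  The minimiser is
found by majorization-minimization (each iteration solves one banded linear
system); the baseline is the low-pass filtered residual f = L(y - x).

Parameters are data-driven: lam0 = 1/std(y), lam1 = lam2 = 2*lam0, and the
asymmetry r is the inverse variance of the amplitude-normalized signal.
When the estimated baseline overshoots the signal itself the sparsity
weights lam1/lam2 are doubled alternately and the solve repeated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu, spsolve

from .scan_io import ValidationError

logger = logging.getLogger(__name__)


class NumericalError(RuntimeError):
    """Solver failed to make progress (diverging objective)."""


@dataclass
class BeadsParams:
    """Tuning knobs of the sparsity-assisted baseline solver.

    fc : low-pass cut-off in normalized cycles/sample, in (0, 0.5)
    r : asymmetry of the peak penalty (larger = negative peaks cost more)
    lam0, lam1, lam2 : sparsity weights of the peaks and their 1st/2nd
        differences
    d : order of the low-pass filter
    eps : smoothing constant of the differentiable penalties
    n_iter : majorization-minimization iterations
    max_doublings : cap on the adaptive lam1/lam2 doubling loop
    """

    fc: float = 2e-3
    r: float = 1.0
    lam0: float = 1.0
    lam1: float = 2.0
    lam2: float = 2.0
    d: int = 1
    eps: float = 1e-6
    n_iter: int = 30
    max_doublings: int = 10

    def validate(self) -> None:
        if not 0 < self.fc < 0.5:
            raise ValidationError("fc must lie in (0, 0.5)")
        if min(self.lam0, self.lam1, self.lam2) <= 0:
            raise ValidationError("sparsity weights must be positive")
        if self.r <= 0:
            raise ValidationError("asymmetry r must be positive")
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")


@dataclass
class AlignedSignal:
    """A signal split into baseline and aligned (baseline-free) parts.

    ``raw`` is the input shifted so its first sample is zero; conservation
    ``aligned == raw - baseline`` holds element-wise and exactly.
    """

    raw: np.ndarray
    baseline: np.ndarray
    aligned: np.ndarray
    peaks: np.ndarray
    params_used: BeadsParams
    x: np.ndarray | None = None  # image column of each sample
    gap_mask: np.ndarray | None = None
    doublings: int = 0
    exhausted: bool = False

    def __post_init__(self) -> None:
        n = len(self.raw)
        if not (len(self.baseline) == len(self.aligned) == len(self.peaks) == n):
            raise ValidationError("all component series must share one length")


def _ba_filters(d: int, fc: float, n: int) -> tuple[sparse.spmatrix, sparse.spmatrix]:
    """Banded matrices A, B of the zero-phase high-pass filter H = B A^-1."""
    b1 = np.array([1.0, -1.0])
    for _ in range(d - 1):
        b1 = np.convolve(b1, [-1.0, 2.0, -1.0])
    b = np.convolve(b1, [-1.0, 1.0])
    omc = 2 * np.pi * fc
    t = ((1 - np.cos(omc)) / (1 + np.cos(omc))) ** d
    a = np.array([1.0])
    for _ in range(d):
        a = np.convolve(a, [1.0, 2.0, 1.0])
    a = b + t * a
    offsets = np.arange(-d, d + 1)
    A = sparse.diags([a[k + d] * np.ones(n) for k in offsets], offsets,
                     shape=(n, n), format="csc")
    B = sparse.diags([b[k + d] * np.ones(n) for k in offsets], offsets,
                     shape=(n, n), format="csc")
    return A, B


def _diff_ops(n: int) -> sparse.spmatrix:
    e = np.ones(n)
    D1 = sparse.diags([-e[:-1], e[:-1]], [0, 1], shape=(n - 1, n))
    D2 = sparse.diags([e[:-2], -2 * e[:-2], e[:-2]], [0, 1, 2], shape=(n - 2, n))
    return sparse.vstack([D1, D2]).tocsr()


def beads_solve(y: np.ndarray, p: BeadsParams,
                max_objective_rises: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Split ``y`` into sparse peaks and a low-pass baseline.

    Returns ``(peaks, baseline)``.  The majorization-minimization iteration
    descends the (smoothed) objective; the best iterate is returned, and
    sustained growth without any initial progress raises
    :class:`NumericalError`.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("input signal contains non-finite values")
    if len(y) < 16:
        raise ValidationError("signal too short for baseline estimation")
    p.validate()

    n = len(y)
    A, B = _ba_filters(p.d, p.fc, n)
    A_lu = splu(A)
    D = _diff_ops(n)
    BTB = (B.T @ B).tocsc()
    w = np.concatenate([p.lam1 * np.ones(n - 1), p.lam2 * np.ones(n - 2)])
    lin = p.lam0 * (1 - p.r) / 2 * np.ones(n)
    rhs = BTB @ A_lu.solve(y) - A.T @ lin

    def objective(x: np.ndarray) -> float:
        h = B @ A_lu.solve(y - x)
        theta = ((1 + p.r) / 2) * np.sqrt(x**2 + p.eps) + ((1 - p.r) / 2) * x
        dx = D @ x
        phi = np.sqrt(dx**2 + p.eps)
        return float(0.5 * np.sum(h**2) + p.lam0 * np.sum(theta)
                     + np.sum(w * phi))

    x = y.copy()
    init = best = objective(x)
    x_best = x
    rises = 0
    for _ in range(p.n_iter):
        dx = D @ x
        lam_diag = w / np.sqrt(dx**2 + p.eps)
        gamma = p.lam0 * (1 + p.r) / 4 / np.maximum(np.abs(x), p.eps)
        M = 2 * sparse.diags(gamma) + D.T @ sparse.diags(lam_diag) @ D
        Q = (BTB + A.T @ M @ A).tocsc()
        x = A @ spsolve(Q, rhs)
        cur = objective(x)
        # the banded solves are ill-conditioned at very low fc and the
        # eps-clamped majorizer can limit-cycle near the optimum: keep the
        # best iterate, and treat growth as divergence only when the solver
        # never made progress at all
        if cur > best + 1e-2 * abs(best) + 1e-9:
            rises += 1
            if rises > max_objective_rises:
                if best < init:
                    break  # converged to a numerical limit cycle
                raise NumericalError("objective increased repeatedly")
        elif cur < best:
            best = cur
            x_best = x
            rises = 0
    x = x_best
    baseline = (y - x) - B @ A_lu.solve(y - x)  # f = L(y - x)
    return x, baseline


def adaptive_baseline(y: np.ndarray, params: BeadsParams | None = None,
                      x: np.ndarray | None = None,
                      gap_mask: np.ndarray | None = None) -> AlignedSignal:
    """Estimate and subtract the baseline with data-driven, self-tuned weights.

    The signal is first shifted so its first sample is zero; weights start
    at lam0 = 1/std(y), lam1 = lam2 = 2*lam0, and the asymmetry r is the
    inverse variance of the amplitude-normalized signal.  Whenever the
    estimated baseline tops the signal's own maximum (an unambiguously
    pathological fit) one of lam1/lam2 is doubled — lam1 first, alternating —
    and the solve repeated, up to ``max_doublings`` times.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 16:
        raise ValidationError("signal too short for baseline estimation")
    sd = float(np.std(y))  # denominator N
    if sd == 0:
        raise ValidationError("constant signal: no baseline to estimate")
    raw = y - y[0]

    base = params if params is not None else BeadsParams()
    lam0 = 1.0 / sd
    # asymmetry from the inverse variance of the amplitude-normalized
    # signal: unit-free, O(1..20), so negative peak residuals genuinely
    # cost more and the baseline hugs the valley floor
    var_unit = float(np.var(y / (y.max() - y.min())))
    p = replace(base, lam0=lam0, lam1=2 * lam0, lam2=2 * lam0,
                r=1.0 / var_unit)

    peaks, baseline = beads_solve(raw, p)
    doublings = 0
    exhausted = False
    while np.max(baseline) > np.max(raw):
        if doublings >= p.max_doublings:
            exhausted = True
            logger.warning("baseline adaptation exhausted after %d doublings",
                           doublings)
            break
        if doublings % 2 == 0:
            p = replace(p, lam1=2 * p.lam1)
        else:
            p = replace(p, lam2=2 * p.lam2)
        doublings += 1
        peaks, baseline = beads_solve(raw, p)

    return AlignedSignal(raw=raw, baseline=baseline, aligned=raw - baseline,
                         peaks=peaks, params_used=p, x=x, gap_mask=gap_mask,
                         doublings=doublings, exhausted=exhausted)


def align_signal_form(sf, params: BeadsParams | None = None) -> AlignedSignal:
    """Convenience: run :func:`adaptive_baseline` on a preprocessed SignalForm."""
    return adaptive_baseline(sf.y, params=params, x=sf.x, gap_mask=sf.gap_mask)


def dump_aligned_csv(a: AlignedSignal, path) -> None:
    """Debug dump (raw, baseline, aligned) as CSV."""
    np.savetxt(path, np.column_stack([a.raw, a.baseline, a.aligned]),
               delimiter=",", header="raw,baseline,aligned", comments="")
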