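"""Sparse spectral solvers.

Two problems are solved here:

* the sparse leading matrix eigenvalue (sLME) of a symmetric matrix D,
  ``max |v' D v|`` over unit vectors with an L1 budget, via penalized matrix
  decomposition (soft-thresholded power iteration on a PSD shift of D, run on
  both D and -D to realize the absolute value);
* the rank-1 sparse symmetric tensor decomposition (SSTD) of a p x p x 3
  tensor, ``D ~ Lambda v o v o u``, by alternating the PMD v-update on the
  u-contracted matrix with a closed-form u-update.

Sparsity parameter convention: ``R`` is a target support size; the L1 budget
handed to PMD is ``sqrt(R)``, which makes the chain ``|v|_1^2 <= |v|_0 <= R``
hold and makes ``R = p`` exactly non-sparse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MatrixSpectralResult",
    "SpectralResult",
    "pmd_sparse_eigen",
    "sstd",
    "sstd_fit_loss",
    "bic_score",
    "bic_select_R",
]

_SYM_TOL = 1e-8


def _soft(w: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(w) * np.maximum(np.abs(w) - delta, 0.0)


def _truncate_top(w: np.ndarray, r: int) -> np.ndarray | None:
    """Unit vector supported on the r largest-|w| coordinates (stable ties)."""
    idx = np.argsort(-np.abs(w), kind="stable")[:r]
    v = np.zeros_like(w)
    v[idx] = w[idx]
    nrm = np.linalg.norm(v)
    if nrm == 0.0:
        return None
    return v / nrm


def l1_constrained_direction(w: np.ndarray, c: float) -> np.ndarray | None:
    """Maximize <w, v> over ||v||_2 <= 1, ||v||_1 <= c.

    This is the PMD update step: soft-threshold w with the smallest
    threshold delta >= 0 such that the renormalized vector meets the L1
    budget.  The threshold is found in closed form on the sorted magnitudes
    (the L1/L2 ratio is piecewise algebraic in delta); degenerate tie cases
    fall back to hard truncation at support size floor(c^2).

    Returns None when w is identically zero.
    """
    w = np.asarray(w, dtype=float)
    nrm2 = np.linalg.norm(w)
    if nrm2 == 0.0:
        return None
    v = w / nrm2
    if np.abs(v).sum() <= c + 1e-12:
        return v

    fallback_r = max(1, int(np.floor(c * c + 1e-9)))
    if c <= 1.0 + 1e-12:
        return _truncate_top(w, 1)

    a = np.sort(np.abs(w))[::-1]
    p = a.size
    k = np.arange(1, p + 1, dtype=float)
    s1 = np.cumsum(a)
    s2 = np.cumsum(a * a)
    # L1/L2 ratio evaluated at the lower delta-boundary of each support size
    bnd = np.append(a[1:], 0.0)
    num = s1 - k * bnd
    den2 = np.maximum(s2 - 2.0 * bnd * s1 + k * bnd * bnd, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den2 > 0, num / np.sqrt(den2), 0.0)
    feasible = ratio >= c - 1e-12
    if not feasible.any():
        return _truncate_top(w, fallback_r)
    ki = int(np.argmax(feasible))  # smallest support size reaching the budget
    kk = ki + 1.0
    s1k, s2k = s1[ki], s2[ki]
    c2 = c * c
    # solve (s1k - kk*delta)^2 = c^2 (s2k - 2 delta s1k + kk delta^2)
    a2 = kk * (kk - c2)
    a1 = 2.0 * s1k * (c2 - kk)
    a0 = s1k * s1k - c2 * s2k
    lo, hi = bnd[ki], a[ki]
    candidates: list[float] = []
    if abs(a2) < 1e-14:
        if abs(a1) > 1e-14:
            candidates.append(-a0 / a1)
    else:
        disc = max(a1 * a1 - 4.0 * a2 * a0, 0.0)
        root = np.sqrt(disc)
        candidates.extend([(-a1 - root) / (2.0 * a2), (-a1 + root) / (2.0 * a2)])
    eps = 1e-9 * max(1.0, hi)
    for delta in sorted(candidates):
        if lo - eps <= delta <= hi + eps and delta <= s1k / kk + eps:
            out = _soft(w, max(delta, 0.0))
            nrm = np.linalg.norm(out)
            if nrm == 0.0:
                break
            out /= nrm
            if np.abs(out).sum() <= c + 1e-6:
                return out
    return _truncate_top(w, fallback_r)


def _pmd_ascend(
    A: np.ndarray, c: float, v: np.ndarray, iters: int, tol: float
) -> np.ndarray:
    """Soft-thresholded power iteration on PSD matrix A under the L1 budget."""
    for _ in range(iters):
        w = A @ v
        v_new = l1_constrained_direction(w, c)
        if v_new is None:
            break
        if np.abs(v_new - v).max() < tol:
            v = v_new
            break
        v = v_new
    return v


@dataclass
class MatrixSpectralResult:
    """Sparse leading matrix eigenvalue: lambda = |v' D v| with sparse unit v."""

    lambda_: float
    v: np.ndarray
    sign: int  # +1 if attained on D, -1 if on -D

    @property
    def support_size(self) -> int:
        return int(np.count_nonzero(self.v))


def _check_symmetric(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {D.shape}")
    scale = max(1.0, np.abs(D).max(initial=0.0))
    if np.abs(D - D.T).max(initial=0.0) > _SYM_TOL * scale:
        raise ValueError("matrix is not symmetric within tolerance")
    return 0.5 * (D + D.T)


def _fix_v_sign(v: np.ndarray) -> np.ndarray:
    j = int(np.argmax(np.abs(v)))
    return -v if v[j] < 0 else v


def pmd_sparse_eigen(
    D: np.ndarray,
    R: float,
    iters: int = 100,
    seed: int | None = None,
    v0: np.ndarray | None = None,
    tol: float = 1e-6,
) -> MatrixSpectralResult:
    """Approximate ``max |v' D v|`` over unit v with L1 budget sqrt(R).

    Both D and -D are ascended (the larger objective wins), each shifted by
    its most negative eigenvalue so the thresholded power iteration is a
    guaranteed ascent.  Iterations start from the dense leading eigenvector
    of the relevant end of the spectrum, plus ``v0`` (warm start) and an
    optional random start derived from ``seed``.
    """
    D = _check_symmetric(D)
    p = D.shape[0]
    if not 1 <= R <= p:
        raise ValueError(f"sparsity R={R} out of range [1, {p}]")
    c = float(np.sqrt(R))

    if not D.any():
        v = np.zeros(p)
        v[0] = 1.0
        return MatrixSpectralResult(0.0, v, 1)

    evals, evecs = np.linalg.eigh(D)

    if R >= p:
        # the L1 budget sqrt(p) cannot bind for unit vectors, so the exact
        # solution is the dense eigenvector of the largest-|eigenvalue| end
        if abs(evals[-1]) >= abs(evals[0]):
            v, quad = evecs[:, -1], float(evals[-1])
        else:
            v, quad = evecs[:, 0], float(evals[0])
        v = _fix_v_sign(v)
        return MatrixSpectralResult(abs(quad), v, 1 if quad >= 0 else -1)

    extra_inits = []
    if v0 is not None:
        extra_inits.append(np.asarray(v0, dtype=float))
    if seed is not None:
        rng = np.random.default_rng(seed)
        r = rng.standard_normal(p)
        extra_inits.append(r / np.linalg.norm(r))

    best_obj = -np.inf
    best_v = None
    for sign, shift, lead in (
        (1.0, max(0.0, -evals[0]), evecs[:, -1]),
        (-1.0, max(0.0, evals[-1]), evecs[:, 0]),
    ):
        A = sign * D + shift * np.eye(p)
        for init in [lead, *extra_inits]:
            v = _pmd_ascend(A, c, init, iters, tol)
            obj = sign * float(v @ D @ v)
            if obj > best_obj:
                best_obj = obj
                best_v = v

    assert best_v is not None
    best_v = _fix_v_sign(best_v)
    quad = float(best_v @ D @ best_v)
    return MatrixSpectralResult(abs(quad), best_v, 1 if quad >= 0 else -1)


@dataclass
class SpectralResult:
    """Rank-1 SSTD fit: D ~ Lambda * v o v o u with sparse unit v, unit u."""

    Lambda: float
    v: np.ndarray
    u: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    restarts_used: int = 0
    R: float = 0.0
    degenerate: bool = False


def _tensor_slides(D) -> np.ndarray:
    slides = getattr(D, "slides", D)
    slides = np.asarray(slides, dtype=float)
    if slides.ndim != 3 or slides.shape[0] != slides.shape[1]:
        raise ValueError(f"expected a p x p x q tensor, got shape {slides.shape}")
    if not np.all(np.isfinite(slides)):
        raise ValueError("tensor contains non-finite entries")
    return slides


def _contract_u(slides: np.ndarray, u: np.ndarray) -> np.ndarray:
    return slides @ u  # (p, p, q) @ (q,) -> (p, p)


def _contract_vv(slides: np.ndarray, v: np.ndarray) -> np.ndarray:
    return v @ np.tensordot(v, slides, axes=(0, 0))


def sstd(
    D,
    R: float,
    T: int = 50,
    restarts: int = 5,
    seed: int = 0,
    iters: int = 50,
    tol: float = 1e-6,
) -> SpectralResult:
    """Alternating rank-1 sparse symmetric tensor decomposition.

    Per iteration: the PMD subproblem is solved on the u-contracted matrix
    (warm-started at the previous v), then u is the normalized (v, v)
    contraction, which makes Lambda = ||D x1 v x2 v|| >= 0 automatic.  The
    best of ``restarts`` random initializations wins; within a restart the
    objective trace is non-decreasing by construction (a non-improving
    iteration ends the restart).
    """
    slides = _tensor_slides(D)
    p, _, q = slides.shape
    if not 1 <= R <= p:
        raise ValueError(f"sparsity R={R} out of range [1, {p}]")
    if T < 1:
        raise ValueError("need T >= 1 iterations")

    if not slides.any():
        v = np.zeros(p)
        v[0] = 1.0
        u = np.zeros(q)
        u[0] = 1.0
        logger.warning("sstd: all-zero tensor, returning degenerate result")
        return SpectralResult(0.0, v, u, [0.0], restarts, R, degenerate=True)

    best = SpectralResult(-np.inf, np.zeros(p), np.zeros(q), [], restarts, R)
    for r in range(restarts):
        rng = np.random.default_rng([seed, r])
        v = rng.standard_normal(p)
        v /= np.linalg.norm(v)
        u = rng.standard_normal(q)
        u /= np.linalg.norm(u)
        lam = -np.inf
        trace: list[float] = []
        for _ in range(T):
            M = _contract_u(slides, u)
            res = pmd_sparse_eigen(M, R, iters=iters, v0=v, tol=tol)
            w = _contract_vv(slides, res.v)
            lam_new = float(np.linalg.norm(w))
            if lam_new <= lam:
                break  # PMD is approximate; never accept a worse iterate
            v = res.v
            u = w / lam_new
            improved = lam_new - lam
            lam = lam_new
            trace.append(lam)
            if improved < tol * max(1.0, lam):
                break
        if lam > best.Lambda:
            best = SpectralResult(lam, v, u, trace, restarts, R)

    v = _fix_v_sign(best.v)
    return SpectralResult(
        best.Lambda, v, best.u, best.objective_trace, restarts, R,
        degenerate=best.Lambda == 0.0,
    )


def sstd_fit_loss(slides: np.ndarray, res: SpectralResult) -> float:
    """Squared Frobenius residual ||D - Lambda v o v o u||_F^2."""
    slides = _tensor_slides(slides)
    fit = res.Lambda * np.einsum("j,k,l->jkl", res.v, res.v, res.u)
    diff = slides - fit
    return float((diff * diff).sum())


def bic_score(slides: np.ndarray, res: SpectralResult, loss_floor: float = 1e-12) -> float:
    """Information criterion trading residual against achieved support size.

    score = 3 p^2 log(loss / 3p^2) + (2 + 2 ||v||_0) log(3 p^2), with the
    loss floored at ``loss_floor`` so noiseless fits do not hit log(0).
    """
    slides = _tensor_slides(slides)
    p = slides.shape[0]
    n_tot = slides.shape[2] * p * p
    loss = max(sstd_fit_loss(slides, res), loss_floor)
    support = int(np.count_nonzero(res.v))
    return n_tot * np.log(loss / n_tot) + (2 + 2 * support) * np.log(n_tot)


def bic_select_R(
    D,
    grid: list[int],
    T: int = 50,
    restarts: int = 5,
    seed: int = 0,
) -> int:
    """Pick the sparsity R in ``grid`` minimizing :func:`bic_score` (ties -> smallest R)."""
    slides = _tensor_slides(D)
    if len(grid) == 0:
        raise ValueError("empty sparsity grid")
    best_R, best_score = None, np.inf
    for R in sorted(grid):
        res = sstd(slides, R, T=T, restarts=restarts, seed=seed)
        score = bic_score(slides, res)
        logger.debug("BIC: R=%s score=%.4f support=%d", R, score, np.count_nonzero(res.v))
        if score < best_score - 1e-12:
            best_R, best_score = R, score
    assert best_R is not None
    return best_R
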