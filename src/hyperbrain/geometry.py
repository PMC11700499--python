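"""Curvature-parameterized Poincare-ball geometry.

All formulas use the computational scale ``c = |K| > 0`` for a space of
sectional curvature ``K < 0``; the ball is the open set
``{x : sqrt(c) * ||x|| < 1}`` of radius ``1/sqrt(c)``.  Distances follow
the standard conformal convention, so the distance from the origin is
``(2/sqrt(c)) * artanh(sqrt(c) * ||x||)`` and the Euclidean limit of the
metric as ``c -> 0`` is ``2 * ||u - v||``.

The array-level functions (:func:`expmap0`, :func:`mobius_add`, ...)
operate on the trailing axis, broadcast over leading axes, and accept
either plain ndarrays or :class:`~hyperbrain.autograd.Tensor` operands
(including a Tensor curvature), so the HGCN layers reuse them verbatim
under gradient tracking.  A thin typed layer (:class:`Curvature`,
:class:`PoincarePoint`) wraps them for scripting and validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag

__all__ = [
    "EPS_BALL", "Curvature", "PoincarePoint", "project_to_ball",
    "project", "expmap0", "logmap0", "expmap", "logmap", "lambda_x",
    "mobius_add", "mobius_matvec", "dist", "dist0", "dist_arcosh",
    "poincare_distance", "hyperbolic_radius", "frechet_mean", "frechet_agg",
    "center_embedding",
]

EPS_BALL = 1e-5          # boundary guard: points kept at sqrt(c)*||x|| <= 1 - EPS_BALL
_MIN_NORM = 1e-15        # safe denominator for directions
_MAX_ARTANH = 1.0 - 1e-10
_MAX_TANH_ARG = 15.0     # tanh saturates; avoids overflow warnings only


# ---------------------------------------------------------------------------
# array-level operations (ndarray or autograd Tensor; trailing-axis vectors)
# ---------------------------------------------------------------------------

def project(x, c):
    """Rescale any row with sqrt(c)*norm >= 1 - EPS_BALL back into the ball."""
    sqc = ag.sqrt(c)
    n = ag.norm(x)
    cond = ag.data(sqc) * ag.data(n) >= 1.0 - EPS_BALL
    factor = ag.where(cond, (1.0 - EPS_BALL) / (sqc * ag.clamp(n, min=_MIN_NORM)),
                      np.ones_like(ag.data(n)))
    return x * factor


def expmap0(v, c):
    """Exponential map at the origin: tangent vector -> ball point."""
    sqc = ag.sqrt(c)
    n = ag.clamp(ag.norm(v), min=_MIN_NORM)
    out = ag.tanh(ag.clamp(sqc * n, max=_MAX_TANH_ARG)) * v / (sqc * n)
    return project(out, c)


def logmap0(x, c):
    """Logarithmic map at the origin: ball point -> tangent vector."""
    sqc = ag.sqrt(c)
    n = ag.clamp(ag.norm(x), min=_MIN_NORM)
    return ag.artanh(ag.clamp(sqc * n, max=_MAX_ARTANH)) * x / (sqc * n)


def lambda_x(x, c):
    """Conformal factor 2 / (1 - c ||x||^2)."""
    x2 = ag.tsum(x * x, axis=-1, keepdims=True)
    return 2.0 / ag.clamp(1.0 - c * x2, min=1e-12)


def mobius_add(x, y, c):
    """Mobius addition x (+)_c y (broadcasts over leading axes)."""
    x2 = ag.tsum(x * x, axis=-1, keepdims=True)
    y2 = ag.tsum(y * y, axis=-1, keepdims=True)
    xy = ag.tsum(x * y, axis=-1, keepdims=True)
    num = (1.0 + 2.0 * c * xy + c * y2) * x + (1.0 - c * x2) * y
    den = 1.0 + 2.0 * c * xy + (c * c) * x2 * y2
    return num / ag.clamp(den, min=1e-12)


def mobius_matvec(W, x, c):
    """Mobius matrix-vector product: expmap0(logmap0(x) @ W^T).

    ``x`` holds row vectors; ``W`` is [out_dim x in_dim].  A zero tangent
    image maps to the origin (expmap0 of 0).
    """
    v = logmap0(x, c)
    return expmap0(ag.matmul(v, ag.transpose(W)), c)


def expmap(base, v, c):
    """Exponential map at an arbitrary base point."""
    sqc = ag.sqrt(c)
    n = ag.clamp(ag.norm(v), min=_MIN_NORM)
    lam = lambda_x(base, c)
    second = ag.tanh(ag.clamp(sqc * lam * n / 2.0, max=_MAX_TANH_ARG)) * v / (sqc * n)
    return project(mobius_add(base, second, c), c)


def logmap(base, y, c):
    """Logarithmic map at an arbitrary base point."""
    sqc = ag.sqrt(c)
    m = mobius_add(-base, y, c)
    n = ag.clamp(ag.norm(m), min=_MIN_NORM)
    lam = lambda_x(base, c)
    return (2.0 / (sqc * lam)) * ag.artanh(ag.clamp(sqc * n, max=_MAX_ARTANH)) * m / n


def dist(x, y, c):
    """Geodesic distance via the Mobius-addition form (smooth at x == y)."""
    sqc = ag.sqrt(c)
    n = ag.norm(mobius_add(-x, y, c))
    d = (2.0 / sqc) * ag.artanh(ag.clamp(n * sqc, max=_MAX_ARTANH))
    return ag.reshape(d, ag.data(n).shape[:-1])


def dist0(x, c):
    """Distance from the origin (the hyperbolic radius of x)."""
    sqc = ag.sqrt(c)
    n = ag.norm(x)
    d = (2.0 / sqc) * ag.artanh(ag.clamp(n * sqc, max=_MAX_ARTANH))
    return ag.reshape(d, ag.data(n).shape[:-1])


def dist_arcosh(u, v, c):
    """Geodesic distance in the arcosh closed form (ndarray only)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    du2 = np.sum((u - v) ** 2, axis=-1)
    au = 1.0 - c * np.sum(u * u, axis=-1)
    av = 1.0 - c * np.sum(v * v, axis=-1)
    arg = 1.0 + 2.0 * c * du2 / np.maximum(au * av, 1e-15)
    return np.arccosh(np.maximum(arg, 1.0)) / np.sqrt(c)


# ---------------------------------------------------------------------------
# Frechet mean
# ---------------------------------------------------------------------------

def _frechet_objective(mu, points, weights, c):
    d = dist_arcosh(mu[None, :], points, c)
    return float(np.sum(weights * d ** 2))


def frechet_mean(points, c=1.0, weights=None, tol=1e-6, max_iter=200,
                 return_info=False):
    """Weighted Frechet (Karcher) mean of points in the c-ball.

    Fixed-point iteration ``mu <- exp_mu(sum_i w_i log_mu(x_i) / sum_i w_i)``,
    initialized at the input point with the smallest weighted sum of squared
    distances.  On a Hadamard manifold each full step decreases the
    objective; a step-halving guard covers numerically degenerate cases.
    Converged when the tangent step norm falls below ``tol``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("need at least one point of shape [m, D]")
    m = pts.shape[0]
    if weights is None:
        w = np.ones(m)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (m,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
    wn = w / w.sum()

    # init: input point minimizing the objective
    objs = [_frechet_objective(p, pts, wn, c) for p in pts]
    mu = pts[int(np.argmin(objs))].copy()
    obj = min(objs)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        t = logmap(mu[None, :], pts, c)           # [m, D]
        g = (wn[:, None] * t).sum(axis=0)
        step = float(np.linalg.norm(g))
        if step < tol:
            converged = True
            break
        scale = 1.0
        for _ in range(30):
            cand = expmap(mu, scale * g, c)
            cand_obj = _frechet_objective(cand, pts, wn, c)
            if cand_obj <= obj + 1e-15:
                break
            scale *= 0.5
        mu, obj = cand, min(obj, cand_obj)
    if not converged and max_iter > 0:
        warnings.warn(
            f"Frechet mean did not converge in {max_iter} iterations "
            f"(last step {step:.2e}); returning best iterate", RuntimeWarning)
    if return_info:
        return mu, {"converged": converged, "iterations": it, "objective": obj}
    return mu


def frechet_agg(h, weights, c, iters=8, damping=0.5):
    """Per-node weighted Frechet aggregation, unrolled for autodiff.

    ``h`` is [n, D] (Tensor or ndarray); ``weights`` is a constant [n, n]
    row-stochastic matrix (neighbors including self).  A fixed number of
    *damped* tangent-mean steps keeps the computation smooth and
    deterministic: the undamped (full-step) Karcher iteration can
    oscillate when the aggregated points are widely spread in negative
    curvature, whereas the half-step contraction converges for the
    neighborhood spreads graph layers produce.  Initialized at the
    tangent-space mean at the origin.
    """
    n, D = ag.data(h).shape
    w3 = np.asarray(weights)[:, :, None]            # constant [n, n, 1]
    mu = expmap0(ag.matmul(weights, logmap0(h, c)), c)   # [n, D]
    hb = ag.reshape(h, 1, n, D)
    for _ in range(iters):
        mub = ag.reshape(mu, n, 1, D)
        t = logmap(mub, hb, c)                       # [n, n, D]
        g = ag.tsum(w3 * t, axis=1)                  # [n, D]
        mu = expmap(mu, damping * g, c)
    return mu


def center_embedding(coords: np.ndarray, c: float) -> np.ndarray:
    """Translate a point cloud so its Frechet mean sits at the origin.

    The Fermi-Dirac reconstruction objective depends on pairwise
    distances only, so embeddings are determined up to a hyperbolic
    isometry; Mobius-translating the (unweighted) Frechet mean to the
    center fixes that gauge and makes node radii comparable across
    embeddings.
    """
    mu = frechet_mean(coords, c)
    return project(mobius_add(-mu[None, :], coords, c), c)


# ---------------------------------------------------------------------------
# typed layer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Curvature:
    """Sectional curvature K < 0 with computational scale c = |K|."""

    K: float

    def __post_init__(self):
        if not np.isfinite(self.K) or self.K >= 0:
            raise ValueError(f"curvature K must be finite and negative, got {self.K}")

    @property
    def c(self) -> float:
        return -self.K

    @property
    def ball_radius(self) -> float:
        return 1.0 / np.sqrt(self.c)


@dataclass(frozen=True)
class PoincarePoint:
    """A point strictly inside the curvature-scaled Poincare ball."""

    coords: np.ndarray
    curvature: Curvature = field(default_factory=lambda: Curvature(-1.0))

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 1 or not np.all(np.isfinite(coords)):
            raise ValueError("coords must be a finite 1-D vector")
        object.__setattr__(self, "coords", coords)
        if np.sqrt(self.curvature.c) * np.linalg.norm(coords) >= 1.0:
            raise ValueError("point lies on or outside the ball; "
                             "use project_to_ball first")

    @property
    def dim(self) -> int:
        return self.coords.shape[0]


def project_to_ball(x, curvature: Curvature) -> PoincarePoint:
    """Numerical guard: rescale x into the strict interior if needed."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    return PoincarePoint(project(x, curvature.c), curvature)


def _check_pair(u: PoincarePoint, v: PoincarePoint):
    if u.curvature != v.curvature:
        raise ValueError("curvature mismatch between points")
    if u.dim != v.dim:
        raise ValueError("dimension mismatch between points")


def poincare_distance(u: PoincarePoint, v: PoincarePoint) -> float:
    """Geodesic distance (arcosh closed form)."""
    _check_pair(u, v)
    return float(dist_arcosh(u.coords, v.coords, u.curvature.c))


def hyperbolic_radius(x: PoincarePoint) -> float:
    """Distance from the ball center; small radius = high hierarchy."""
    return float(dist0(x.coords[None, :], x.curvature.c)[0])
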