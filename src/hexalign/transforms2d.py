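"""2D affine fitting at several constraint levels, affine decomposition,
RANSAC robust fitting, and rigid moving-least-squares deformation.

Constraint levels for point-set fitting:

``full``
    unconstrained 2x2 linear part (6 dof), ordinary least squares.
``rigid``
    rotation + translation (Kabsch), no scale, no shear.
``rigid+scale``
    rotation + single isotropic scale + translation (Umeyama).
``noshear``
    rotation + independent x/y scales + translation, shear exactly zero
    (the 2D orthogonal, non-orthonormal Procrustes problem, solved in
    closed form).  Physically this models sections compressed along the
    cutting direction but not sheared.

Points are (N, 2) arrays of x, y in nm.  A transform maps source points
to destination points as ``dst = src @ linear.T + translation``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AffineTransform2D",
    "AffineDecomposition",
    "PointCorrespondences",
    "fit_affine",
    "decompose",
    "compose",
    "ransac_fit",
    "mls_rigid",
]

CONSTRAINTS = ("full", "rigid", "rigid+scale", "noshear")


@dataclass(frozen=True)
class AffineTransform2D:
    linear: np.ndarray      # (2, 2)
    translation: np.ndarray  # (2,)

    def __post_init__(self):
        object.__setattr__(self, "linear", np.asarray(self.linear, float).reshape(2, 2))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, float).reshape(2))

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    @classmethod
    def rotation(cls, angle_deg: float, center=(0.0, 0.0)) -> "AffineTransform2D":
        """Rotation by ``angle_deg`` (counter-clockwise in x-right/y-down
        mathematical convention) about ``center``."""
        t = np.deg2rad(angle_deg)
        c, s = np.cos(t), np.sin(t)
        lin = np.array([[c, -s], [s, c]])
        center = np.asarray(center, float)
        return cls(lin, center - lin @ center)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, float))
        return pts @ self.linear.T + self.translation

    def compose_with(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return self ∘ other (apply ``other`` first)."""
        return AffineTransform2D(self.linear @ other.linear,
                                 self.linear @ other.translation + self.translation)

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.linear)
        return AffineTransform2D(inv, -inv @ self.translation)

    def __eq__(self, other):
        return (isinstance(other, AffineTransform2D)
                and np.array_equal(self.linear, other.linear)
                and np.array_equal(self.translation, other.translation))


@dataclass(frozen=True)
class AffineDecomposition:
    """Sequential rotation -> scale -> shear -> translation parameters.

    ``compose`` rebuilds ``linear = R(angle) @ diag(scale) @ Shear`` where
    ``Shear = [[1, shear_x], [shear_y, 1]]``.  The decomposition always
    reports ``shear_y = 0`` (QR convention); ``compose`` accepts both.
    """

    angle_deg: float
    scale_x: float
    scale_y: float
    shear_x: float
    shear_y: float
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, float).reshape(2))


@dataclass
class PointCorrespondences:
    src: np.ndarray
    dst: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.src = np.atleast_2d(np.asarray(self.src, float))
        self.dst = np.atleast_2d(np.asarray(self.dst, float))
        if self.src.shape != self.dst.shape or self.src.shape[1] != 2:
            raise ValueError("src/dst must be matching (N, 2) arrays")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, float)
            if self.weights.shape != (len(self.src),):
                raise ValueError("weights length mismatch")

    def __len__(self):
        return len(self.src)


def _min_points(constraint: str) -> int:
    return 3 if constraint == "full" else 2


def fit_affine(corr: PointCorrespondences, constraint: str = "full") -> AffineTransform2D:
    """Least-squares optimal affine within the given constraint class.

    The translation is the difference of the (weighted) destination and
    source means after the 2x2 linear part is fitted on centered points.
    """
    if constraint not in CONSTRAINTS:
        raise ValueError(f"unknown constraint {constraint!r}")
    n = len(corr)
    if n < _min_points(constraint):
        raise ValueError(f"need >= {_min_points(constraint)} points for {constraint}")
    w = corr.weights if corr.weights is not None else np.ones(n)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights sum to zero")
    mu_s = (w[:, None] * corr.src).sum(0) / wsum
    mu_d = (w[:, None] * corr.dst).sum(0) / wsum
    X = (corr.src - mu_s) * np.sqrt(w)[:, None]
    Y = (corr.dst - mu_d) * np.sqrt(w)[:, None]

    if constraint == "full":
        if np.linalg.matrix_rank(X) < 2:
            raise ValueError("degenerate geometry: points collinear")
        # solve linear.T from X @ linear.T = Y
        lin = np.linalg.lstsq(X, Y, rcond=None)[0].T
    elif constraint in ("rigid", "rigid+scale"):
        # Kabsch / Umeyama on centered points
        H = X.T @ Y  # 2x2 cross-covariance (src x dst)
        U, S, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        D = np.diag([1.0, d])
        R = Vt.T @ D @ U.T
        if constraint == "rigid+scale":
            var_s = (X ** 2).sum()
            if var_s == 0:
                raise ValueError("degenerate geometry: coincident points")
            scale = (S * np.diag(D)).sum() / var_s
            lin = scale * R
        else:
            lin = R
    else:  # noshear: R(theta) @ diag(sx, sy), closed form
        lin = _fit_noshear(X, Y)

    translation = mu_d - lin @ mu_s
    return AffineTransform2D(lin, translation)


def _fit_noshear(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Closed-form 2D orthogonal (non-orthonormal) Procrustes solution.

    Minimizes ``|| R(t) S Xc - Yc ||_F`` over angle t and S = diag(sx, sy).
    Writing B = Xc^T Yc ... expanding the objective, the optimal per-axis
    scales for a fixed rotation are ``s_i = (B R)_ii / D_ii`` with
    ``D_ii = sum of squared centered source i-coordinates``, and the
    reduced objective is a quadratic form in (cos t, sin t) whose maximum
    is the leading eigenvector of a symmetric 2x2 matrix.
    """
    Xc, Yc = X.T, Y.T  # (2, N), rows are coordinates
    D = np.einsum("ij,ij->i", Xc, Xc)  # sum x^2, sum y^2
    if np.any(D <= 0):
        raise ValueError("degenerate geometry: zero variance along an axis")
    B = Xc @ Yc.T  # (2,2), B_ij = sum x_i * y_j  with x=src coords, y=dst
    # (B R)_11 = B00*c + B01*s ; (B R)_22 = -B10*s + B11*c
    q1 = np.array([B[0, 0], B[0, 1]]) / np.sqrt(D[0])
    q2 = np.array([B[1, 1], -B[1, 0]]) / np.sqrt(D[1])
    Q = np.outer(q1, q1) + np.outer(q2, q2)
    evals, evecs = np.linalg.eigh(Q)
    u = evecs[:, -1]  # (cos t, sin t) up to sign
    c, s = u
    R = np.array([[c, -s], [s, c]])
    sx = (B[0, 0] * c + B[0, 1] * s) / D[0]
    sy = (-B[1, 0] * s + B[1, 1] * c) / D[1]
    if sx + sy < 0:  # sign ambiguity of the eigenvector: prefer positive scales
        c, s, sx, sy = -c, -s, -sx, -sy
        R = np.array([[c, -s], [s, c]])
    return R @ np.diag([sx, sy])


def decompose(t: AffineTransform2D) -> AffineDecomposition:
    """Decompose into rotation, per-axis scale, shear, translation.

    Uses the QR-like factorization ``linear = R(angle) @ diag(sx, sy) @
    [[1, hx], [0, 1]]`` with ``sx > 0`` enforced; ``shear_y`` is always 0.
    """
    A = t.linear
    det = np.linalg.det(A)
    if det == 0:
        raise ValueError("singular transform cannot be decomposed")
    Q, R = np.linalg.qr(A)
    # normalize so R diagonal is positive in the first entry
    sign = np.sign(np.diag(R))
    sign[sign == 0] = 1.0
    Q = Q * sign
    R = sign[:, None] * R
    if np.linalg.det(Q) < 0:  # reflections carried as a negative y-scale
        Q = Q @ np.diag([1.0, -1.0])
        R = np.diag([1.0, -1.0]) @ R
    angle = np.degrees(np.arctan2(Q[1, 0], Q[0, 0]))
    sx, sy = R[0, 0], R[1, 1]
    hx = R[0, 1] / sx
    # snap numerically-zero shear (constrained fits produce exact zeros in
    # exact arithmetic; QR leaves ~eps residue)
    if abs(hx) < 1e-12:
        hx = 0.0
    return AffineDecomposition(angle, sx, sy, hx, 0.0, t.translation.copy())


def compose(d: AffineDecomposition) -> AffineTransform2D:
    t = np.deg2rad(d.angle_deg)
    c, s = np.cos(t), np.sin(t)
    R = np.array([[c, -s], [s, c]])
    S = np.diag([d.scale_x, d.scale_y])
    H = np.array([[1.0, d.shear_x], [d.shear_y, 1.0]])
    return AffineTransform2D(R @ S @ H, d.translation)


def residuals(t: AffineTransform2D, corr: PointCorrespondences) -> np.ndarray:
    """Per-point Euclidean residual of ``t`` on the correspondences (nm)."""
    return np.linalg.norm(t.apply(corr.src) - corr.dst, axis=1)


def ransac_fit(
    corr: PointCorrespondences,
    constraint: str = "rigid",
    tolerance_nm: float = 5120.0,
    min_inliers: int = 32,
    max_translation_nm: float | None = None,
    n_iterations: int = 1000,
    seed: int | np.random.Generator = 0,
):
    """RANSAC fit of a constrained affine.

    Returns ``(transform, inlier_mask)`` or ``(None, None)`` (bad match)
    when fewer than ``min_inliers`` correspondences survive, or the fitted
    translation magnitude exceeds ``max_translation_nm``.
    """
    if tolerance_nm <= 0:
        raise ValueError("tolerance must be > 0")
    n = len(corr)
    k = _min_points(constraint)
    if n < max(k, 1):
        return None, None
    rng = np.random.default_rng(seed)

    best_mask = None
    best_count = -1
    best_rss = np.inf
    if n <= k:
        candidates = [np.arange(n)]
    else:
        candidates = [rng.choice(n, size=k, replace=False) for _ in range(n_iterations)]
    for idx in candidates:
        sub = PointCorrespondences(corr.src[idx], corr.dst[idx])
        try:
            model = fit_affine(sub, constraint)
        except (ValueError, np.linalg.LinAlgError):
            continue
        r = residuals(model, corr)
        mask = r <= tolerance_nm
        count = int(mask.sum())
        rss = float((r[mask] ** 2).sum())
        if count > best_count or (count == best_count and rss < best_rss):
            best_count, best_mask, best_rss = count, mask, rss
    if best_mask is None or best_count < k:
        return None, None

    # refit on all inliers, then re-classify once for the final mask
    for _ in range(2):
        sub = PointCorrespondences(corr.src[best_mask], corr.dst[best_mask])
        try:
            model = fit_affine(sub, constraint)
        except (ValueError, np.linalg.LinAlgError):
            return None, None
        best_mask = residuals(model, corr) <= tolerance_nm
        if not best_mask.any():
            return None, None
    if int(best_mask.sum()) < min_inliers:
        return None, None
    if max_translation_nm is not None and np.linalg.norm(model.translation) > max_translation_nm:
        return None, None
    return model, best_mask


def mls_rigid(
    control_src: np.ndarray,
    control_dst: np.ndarray,
    query: np.ndarray,
    alpha: float = 2.0,
) -> np.ndarray:
    """Rigid moving-least-squares deformation evaluated at query points.

    Every query point is mapped by the similarity-class MLS solution
    restricted to rotations (rigid MLS).  The map interpolates the
    controls exactly and reproduces any global rigid transform exactly at
    arbitrary query locations, which makes it suitable both for image
    deformation and for interpolating/extrapolating sparse vector fields.

    Parameters
    ----------
    control_src, control_dst : (K, 2) arrays
        Control point correspondences.
    query : (M, 2) array
        Points at which to evaluate the deformation.
    alpha : float
        Weight falloff exponent; weights are ``1 / |p_i - v|^(2*alpha)``.
    """
    p = np.atleast_2d(np.asarray(control_src, float))
    q = np.atleast_2d(np.asarray(control_dst, float))
    v = np.atleast_2d(np.asarray(query, float))
    if p.shape != q.shape or p.shape[0] < 2:
        raise ValueError("need >= 2 matching control points")
    if np.allclose(p, p[0]):
        raise ValueError("control points all coincident")

    out = np.empty_like(v)
    d2 = ((v[:, None, :] - p[None, :, :]) ** 2).sum(-1)  # (M, K)
    coincident = d2 < 1e-18
    w = np.zeros_like(d2)
    np.divide(1.0, d2 ** alpha, out=w, where=~coincident)

    hit = coincident.any(axis=1)
    if hit.any():
        out[hit] = q[np.argmax(coincident[hit], axis=1)]

    free = ~hit
    if free.any():
        wf = w[free]  # (m, K)
        vs = v[free]
        wsum = wf.sum(1, keepdims=True)
        pstar = (wf @ p) / wsum
        qstar = (wf @ q) / wsum
        # centered controls per query
        phat = p[None, :, :] - pstar[:, None, :]   # (m, K, 2)
        qhat = q[None, :, :] - qstar[:, None, :]
        # rigid MLS: rotation angle from weighted cross/dot sums
        dot = (wf * (phat * qhat).sum(-1)).sum(1)
        crs = (wf * (phat[..., 0] * qhat[..., 1]
                     - phat[..., 1] * qhat[..., 0])).sum(1)
        mu = np.hypot(dot, crs)
        mu[mu == 0] = 1.0
        c, s = dot / mu, crs / mu
        rel = vs - pstar
        rot = np.stack([c * rel[..., 0] - s * rel[..., 1],
                        s * rel[..., 0] + c * rel[..., 1]], axis=-1)
        out[free] = rot + qstar
    return out
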