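"""Superimposition machinery for 2D landmark configurations.

Covers mirroring of right-side elements, thin-plate-spline estimation of
missing landmarks, generalized Procrustes analysis (GPA) with optional
sliding of semilandmarks (minimum bending energy by default, minimum
Procrustes distance on request), centroid sizes, and tangent-space
projection.  Aligned configurations are centred at the origin with unit
centroid size.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .io import LandmarkSet

__all__ = [
    "ShapeData",
    "mirror_config",
    "centroid_size",
    "ThinPlateSpline2D",
    "estimate_missing_tps",
    "GeneralizedProcrustes",
    "gpa_align",
    "procrustes_distance",
    "flatten_shapes",
    "unflatten_shapes",
]


class GeometryError(ValueError):
    pass


def mirror_config(config: np.ndarray, axis: str = "x") -> np.ndarray:
    """Reflect a single k×2 configuration across the stated axis.

    ``axis='x'`` negates the x coordinate (reflection across the vertical
    axis); ``axis='y'`` negates y.  Landmark order is unchanged; mirroring
    twice is the identity.
    """
    config = np.asarray(config, dtype=float)
    out = config.copy()
    if axis == "x":
        out[:, 0] = -out[:, 0]
    elif axis == "y":
        out[:, 1] = -out[:, 1]
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return out


def centroid_size(config: np.ndarray) -> float:
    """√Σ‖xᵢ − x̄‖²: the standard geometric-morphometric size measure."""
    config = np.asarray(config, dtype=float)
    if np.isnan(config).any():
        raise GeometryError("centroid size undefined with missing landmarks")
    centered = config - config.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs <= 1e-300:
        raise GeometryError("degenerate configuration: all landmarks coincide")
    return cs


def flatten_shapes(aligned: np.ndarray) -> np.ndarray:
    """(n, k, 2) → (n, 2k) in landmark-major order (x1, y1, x2, y2, …)."""
    a = np.asarray(aligned, dtype=float)
    return a.reshape(a.shape[0], -1)


def unflatten_shapes(flat: np.ndarray) -> np.ndarray:
    f = np.asarray(flat, dtype=float)
    return f.reshape(f.shape[0], -1, 2)


# ------------------------------------------------------------- thin plate

def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r^2, with U(0) = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


class ThinPlateSpline2D:
    """Exact 2D thin-plate-spline interpolant between point sets.

    Solves the standard system  [[K, Q], [Qᵀ, 0]] [W; A] = [V; 0]  with
    kernel U(r) = r² log r²; the affine part A reproduces any affine map with
    zero bending energy.
    """

    def __init__(self, source: np.ndarray, target: np.ndarray):
        source = np.asarray(source, dtype=float)
        target = np.asarray(target, dtype=float)
        if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 2:
            raise GeometryError("source/target must be matching k×2 arrays")
        k = source.shape[0]
        if k < 3:
            raise GeometryError("thin-plate spline needs at least 3 points")
        d2 = ((source[:, None, :] - source[None, :, :]) ** 2).sum(-1)
        K = _tps_kernel(d2)
        Q = np.column_stack([np.ones(k), source])
        L = np.zeros((k + 3, k + 3))
        L[:k, :k] = K
        L[:k, k:] = Q
        L[k:, :k] = Q.T
        rhs = np.zeros((k + 3, 2))
        rhs[:k] = target
        try:
            sol = np.linalg.solve(L, rhs)
        except np.linalg.LinAlgError as exc:
            raise GeometryError(f"singular thin-plate-spline system: {exc}") from exc
        self.source = source
        self.weights = sol[:k]
        self.affine = sol[k:]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((pts[:, None, :] - self.source[None, :, :]) ** 2).sum(-1)
        U = _tps_kernel(d2)
        Q = np.column_stack([np.ones(len(pts)), pts])
        return U @ self.weights + Q @ self.affine


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """k×k bending-energy matrix of a reference configuration (L⁻¹ top-left block)."""
    ref = np.asarray(reference, dtype=float)
    k = ref.shape[0]
    d2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
    K = _tps_kernel(d2)
    Q = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Linv = np.linalg.pinv(L)
    Be = Linv[:k, :k]
    return (Be + Be.T) / 2


def estimate_missing_tps(
    landmarks: LandmarkSet, reference: np.ndarray | str = "complete-mean"
) -> LandmarkSet:
    """Estimate missing landmarks by thin-plate-spline interpolation.

    For each incomplete specimen, a TPS is solved from the reference's
    landmarks shared with the specimen onto the specimen's observed points;
    the missing coordinates are the mapped positions of the reference's
    corresponding points.  Present points are untouched and the missing mask
    is cleared.  The default reference is the mean of the complete specimens
    after a preliminary GPA restricted to them.

    Exact for specimens that are affine images of the reference (the TPS
    affine part absorbs the map; bending is zero).
    """
    if not landmarks.missing.any():
        return landmarks
    if isinstance(reference, str):
        if reference != "complete-mean":
            raise ValueError("reference must be an array or 'complete-mean'")
        complete = landmarks.complete_specimens()
        if not complete:
            raise GeometryError("no complete specimen available as a reference")
        sub = landmarks.subset(complete)
        if len(complete) == 1:
            ref = sub.coords[0]
        else:
            ref = gpa_align(sub, slide_semilandmarks=False).consensus
    else:
        ref = np.asarray(reference, dtype=float)
    if ref.shape != (landmarks.n_landmarks, 2):
        raise GeometryError("reference shape does not match landmark count")

    coords = landmarks.coords.copy()
    for s, sid in enumerate(landmarks.specimen_ids):
        miss = landmarks.missing[s]
        if not miss.any():
            continue
        present = ~miss
        if present.sum() < 3:
            raise GeometryError(
                f"specimen {sid}: fewer than 3 observed landmarks; cannot interpolate"
            )
        try:
            tps = ThinPlateSpline2D(ref[present], coords[s, present])
        except GeometryError as exc:
            raise GeometryError(f"specimen {sid}: {exc}") from exc
        coords[s, miss] = tps(ref[miss])
    return LandmarkSet(
        list(landmarks.specimen_ids),
        coords,
        landmarks.curves,
        np.zeros_like(landmarks.missing),
        None if landmarks.scale is None else landmarks.scale.copy(),
    )


# ----------------------------------------------------------------- GPA

@dataclass
class ShapeData:
    """Procrustes-aligned shapes: unit centroid size, centred, rotated to consensus."""

    specimen_ids: list[str]
    aligned: np.ndarray  # (n, k, 2)
    centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray  # (k, 2)
    curves: tuple[tuple[int, ...], ...] = ()
    n_iterations: int = 0
    procrustes_ss_path: tuple[float, ...] = ()

    def flat(self) -> np.ndarray:
        return flatten_shapes(self.aligned)


def _optimal_rotation(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (det +1; reflection disallowed) minimizing ‖XR − target‖²."""
    H = X.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance after centring, unit-scaling and optimal rotation."""
    A = np.asarray(a, float) - np.asarray(a, float).mean(0)
    B = np.asarray(b, float) - np.asarray(b, float).mean(0)
    A = A / np.sqrt((A**2).sum())
    B = B / np.sqrt((B**2).sum())
    R = _optimal_rotation(A, B)
    return float(np.sqrt(((A @ R - B) ** 2).sum()))


def _standardize_orientation(X: np.ndarray, consensus: np.ndarray):
    """Rotate all configurations so the consensus lies on its principal axes.

    Makes GPA output deterministic and invariant to the input frame: the
    consensus' major axis becomes x, with loading signs fixed; the rotation
    has det +1 (no reflection is introduced)."""
    cov = consensus.T @ consensus
    _, vecs = np.linalg.eigh(cov)
    V = vecs[:, ::-1]  # major axis first
    if np.linalg.det(V) < 0:
        V[:, 1] *= -1
    c = consensus @ V
    # resolve the remaining 180° ambiguity from the consensus itself: the
    # landmark furthest along the major axis points in +x (negating both
    # coordinates is a proper rotation, so no reflection is introduced)
    i = int(np.argmax(np.abs(c[:, 0])))
    if c[i, 0] < 0:
        V = -V
        c = -c
    return X @ V, c


def _tangent_directions(config: np.ndarray, curves) -> dict[int, np.ndarray]:
    """Unit tangents at interior curve points from finite differences of neighbours."""
    out: dict[int, np.ndarray] = {}
    for curve in curves:
        for pos in range(1, len(curve) - 1):
            j = curve[pos]
            t = config[curve[pos + 1]] - config[curve[pos - 1]]
            norm = np.linalg.norm(t)
            out[j] = t / norm if norm > 0 else np.array([1.0, 0.0])
    return out


def _slide_one(
    X: np.ndarray,
    consensus: np.ndarray,
    curves,
    criterion: str,
    Be: np.ndarray | None,
) -> np.ndarray:
    """Slide semilandmarks of one configuration along curve tangents.

    Minimizes bending energy against the consensus (``criterion='bending_energy'``,
    using the consensus' bending-energy matrix) or the Procrustes distance
    (``criterion='procrustes'``).  Solves the standard linear system
    t = −(UᵀEU)⁻¹UᵀE(v) for tangent displacements.
    """
    tangents = _tangent_directions(X, curves)
    if not tangents:
        return X
    k = X.shape[0]
    sliders = sorted(tangents)
    U = np.zeros((2 * k, len(sliders)))
    for col, j in enumerate(sliders):
        U[2 * j, col] = tangents[j][0]
        U[2 * j + 1, col] = tangents[j][1]
    v = (X - consensus).reshape(-1)
    if criterion == "bending_energy":
        assert Be is not None
        # interleaved (x1,y1,...) layout: E = Be ⊗ I2
        E = np.kron(Be, np.eye(2))
        A = U.T @ E @ U
        b = U.T @ E @ v
    else:
        A = U.T @ U
        b = U.T @ v
    try:
        t = np.linalg.solve(A + 1e-12 * np.eye(A.shape[0]), -b)
    except np.linalg.LinAlgError:
        return X
    return X + (U @ t).reshape(k, 2)


class GeneralizedProcrustes(BaseEstimator):
    """Generalized Procrustes superimposition with optional sliding semilandmarks.

    Parameters
    ----------
    slide_semilandmarks : bool, default True
        Slide the interior points of each curve along their tangent
        directions every outer iteration.
    slide_criterion : {'bending_energy', 'procrustes'}
        Objective minimized while sliding.
    tol : float
        Convergence threshold on the RMS change of the consensus.
    max_iter : int
        Maximum outer iterations before a convergence error is raised.
    project_tangent : bool
        Orthogonally project final coordinates to the tangent space at the
        consensus.

    Attributes (after fit)
    ----------------------
    shape_data_ : ShapeData
    consensus_ : (k, 2) array
    centroid_sizes_ : (n,) array
    n_iter_ : int
    """

    def __init__(
        self,
        slide_semilandmarks: bool = True,
        slide_criterion: str = "bending_energy",
        tol: float = 1e-8,
        max_iter: int = 500,
        max_slide_iter: int = 10,
        slide_tol: float = 1e-6,
        project_tangent: bool = True,
    ):
        self.slide_semilandmarks = slide_semilandmarks
        self.slide_criterion = slide_criterion
        self.tol = tol
        self.max_iter = max_iter
        self.max_slide_iter = max_slide_iter
        self.slide_tol = slide_tol
        self.project_tangent = project_tangent

    def _classical(self, X: np.ndarray, consensus: np.ndarray, ss_path: list[float]):
        """Rotate/re-estimate iterations of classical GPA until the summed
        squared Procrustes residual stabilizes (monotone descent)."""
        n = X.shape[0]
        prev_ss = np.inf
        for it in range(1, self.max_iter + 1):
            for i in range(n):
                X[i] = X[i] @ _optimal_rotation(X[i], consensus)
            ss = float(((X - consensus) ** 2).sum())
            ss_path.append(ss)
            new_consensus = X.mean(0)
            new_consensus = new_consensus - new_consensus.mean(0)
            new_consensus = new_consensus / np.sqrt((new_consensus**2).sum())
            delta = float(np.sqrt(((new_consensus - consensus) ** 2).mean()))
            consensus = new_consensus
            if delta < self.tol or abs(prev_ss - ss) < self.tol * max(1.0, ss):
                return X, consensus, it
            prev_ss = ss
        raise GeometryError(
            f"GPA did not converge in {self.max_iter} iterations (last delta {delta:.3e})"
        )

    def _slide_objective(self, X, consensus) -> float:
        if self.slide_criterion == "bending_energy":
            return total_bending_energy(X, consensus)
        return float(((X - consensus) ** 2).sum())

    def fit(self, landmarks: LandmarkSet, y=None):
        if self.slide_criterion not in {"bending_energy", "procrustes"}:
            raise ValueError("slide_criterion must be 'bending_energy' or 'procrustes'")
        if landmarks.missing is not None and landmarks.missing.any():
            raise GeometryError(
                "missing landmarks present; run estimate_missing_tps before GPA"
            )
        n = landmarks.n_specimens
        sizes = np.array([centroid_size(c) for c in landmarks.coords])
        X = np.array(
            [
                (c - c.mean(0)) / s
                for c, s in zip(landmarks.coords, sizes)
            ]
        )
        consensus = X[0].copy()
        ss_path: list[float] = []
        X, consensus, n_iter = self._classical(X, consensus, ss_path)
        slide = self.slide_semilandmarks and bool(landmarks.curves)
        if slide:
            # discrete sliding cycles: slide against the current consensus,
            # re-superimpose, keep only while the criterion objective drops
            obj = self._slide_objective(X, consensus)
            for _cycle in range(self.max_slide_iter):
                Be = (
                    bending_energy_matrix(consensus)
                    if self.slide_criterion == "bending_energy"
                    else None
                )
                X2 = X.copy()
                for i in range(n):
                    Xi = _slide_one(
                        X2[i], consensus, landmarks.curves, self.slide_criterion, Be
                    )
                    Xi = Xi - Xi.mean(0)
                    X2[i] = Xi / np.sqrt((Xi**2).sum())
                X2, consensus2, it2 = self._classical(X2, consensus.copy(), ss_path)
                obj2 = self._slide_objective(X2, consensus2)
                n_iter += it2
                if obj2 < obj:
                    X, consensus = X2, consensus2
                    if obj - obj2 < self.slide_tol * max(obj, 1e-12):
                        obj = obj2
                        break
                    obj = obj2
                else:
                    break
        for i in range(n):
            X[i] = X[i] @ _optimal_rotation(X[i], consensus)
        if self.project_tangent:
            c = consensus.reshape(-1)
            flat = X.reshape(n, -1)
            proj = c + (flat - (flat @ c)[:, None] * c)
            X = proj.reshape(X.shape)
        X, consensus = _standardize_orientation(X, consensus)
        self.consensus_ = consensus
        self.centroid_sizes_ = sizes
        self.n_iter_ = n_iter
        self.shape_data_ = ShapeData(
            list(landmarks.specimen_ids),
            X,
            sizes,
            consensus,
            landmarks.curves,
            n_iter,
            tuple(ss_path),
        )
        return self

    def fit_transform(self, landmarks: LandmarkSet, y=None) -> ShapeData:
        return self.fit(landmarks).shape_data_


def gpa_align(
    landmarks: LandmarkSet,
    slide_semilandmarks: bool = True,
    slide_criterion: str = "bending_energy",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> ShapeData:
    """Functional wrapper around :class:`GeneralizedProcrustes`."""
    return GeneralizedProcrustes(
        slide_semilandmarks=slide_semilandmarks,
        slide_criterion=slide_criterion,
        tol=tol,
        max_iter=max_iter,
    ).fit_transform(landmarks)


def total_bending_energy(shapes: np.ndarray, reference: np.ndarray) -> float:
    """Σ over specimens of the TPS bending energy of (reference → specimen)."""
    Be = bending_energy_matrix(reference)
    total = 0.0
    for X in shapes:
        v = X - reference
        total += float(v[:, 0] @ Be @ v[:, 0] + v[:, 1] @ Be @ v[:, 1])
    return total
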