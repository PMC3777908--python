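"""Collective coordinates: PCA of quaternary motions and PLS-based FMA.

The quaternary-only trajectory is reduced by principal component
analysis; its first eigenvector is the dominant quaternary mode **cQ**.
Functional Mode Analysis (FMA) then searches the tertiary-only subspace
for the collective coordinate maximally correlated with the projection
onto cQ.  The FMA variant used here builds the model by Partial Least
Squares (PLS): latent vectors in coordinate space are chosen to maximise
covariance with the target, the target is regressed on the latent
projections, and the coordinate-space gradient of the fitted linear
model — an explicit unit 3N-vector — is the coupling mode **cT**.
Reweighting the latent vectors by their share of the coordinate variance
yields the ensemble-weighted mode **cTew**: while cT is the maximally
correlated direction, cTew is the most probable motion correlating with
the target.

Overfitting is controlled by fitting on the first half of the frames and
cross-validating on the second half; the number of latent vectors is the
maximiser of the cross-validation correlation, and the final model is
refit with that number on all frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

logger = logging.getLogger("tqcoupling")

from .errors import ConfigError, DataError
from .geometry import StructureFrame, Trajectory

__all__ = [
    "CollectiveMode",
    "PCAResult",
    "PLSFMAModel",
    "ProjectionSeries",
    "pca",
    "project",
    "pls_fma",
    "select_components",
    "ensemble_weight",
    "pearson",
    "mode_overlap",
    "covariance_rank",
]


def _as_flat(origin) -> np.ndarray:
    if isinstance(origin, StructureFrame):
        return origin.flat.copy()
    return np.asarray(origin, dtype=np.float64).reshape(-1)


@dataclass
class CollectiveMode:
    """A unit 3N-vector (direction in configuration space, nm-normalised).

    ``role`` tags what the mode is (``cQ``, ``cT``, ``cTew``, ``TR_full``,
    ``TR_tertiary``, ``TR_quaternary`` or ``custom``); ``origin`` is the
    flattened structure the mode is anchored at.
    """

    vector: np.ndarray
    role: str = "custom"
    origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64).reshape(-1)
        norm = np.linalg.norm(self.vector)
        if not np.isfinite(norm) or norm == 0:
            raise DataError("collective mode vector must be finite and non-zero")
        if abs(norm - 1.0) > 1e-10:
            self.vector = self.vector / norm
        if self.origin is None:
            self.origin = np.zeros_like(self.vector)
        else:
            self.origin = _as_flat(self.origin)
            if self.origin.shape != self.vector.shape:
                raise DataError("mode origin and vector dimensions differ")

    @property
    def n_atoms(self) -> int:
        return self.vector.size // 3


@dataclass
class PCAResult:
    """Eigen-decomposition of the coordinate covariance about the mean."""

    eigenvalues: np.ndarray  # variances, nm^2, descending
    eigenvectors: np.ndarray  # (k, 3N), orthonormal rows
    mean: np.ndarray  # (3N,)
    explained_fraction: np.ndarray

    def mode(self, i: int = 0, role: str = "cQ") -> CollectiveMode:
        return CollectiveMode(vector=self.eigenvectors[i], role=role, origin=self.mean)


@dataclass
class ProjectionSeries:
    """Per-frame scalar projections (nm) of a trajectory onto a mode."""

    values: np.ndarray
    mode: CollectiveMode | None = None
    split_point: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)


@dataclass
class PLSFMAModel:
    """Fitted PLS-FMA model.

    ``latent_vectors`` are the coordinate-space directions whose
    projections the target is regressed on (rows, 3N each);
    ``coefficients`` are the regression weights per latent vector and
    ``score_variances`` the coordinate variance along each latent vector
    on the data the modes were fit on.
    """

    latent_vectors: np.ndarray  # (k, 3N)
    coefficients: np.ndarray  # (k,)
    score_variances: np.ndarray  # (k,)
    n_components: int
    mode_cT: CollectiveMode
    mode_cTew: CollectiveMode
    fit_r: float
    cv_r: float
    origin: np.ndarray  # training mean, (3N,)
    split_point: int

    def predict(self, traj: Trajectory | np.ndarray) -> np.ndarray:
        x = traj.flat if isinstance(traj, Trajectory) else np.asarray(traj)
        xc = x - self.origin
        scores = xc @ self.latent_vectors.T
        return self._y_mean + scores @ self.coefficients

    _y_mean: float = 0.0


def _fix_sign(vectors: np.ndarray) -> np.ndarray:
    """Flip each row so its largest-magnitude component is positive."""
    out = vectors.copy()
    for row in out:
        i = np.argmax(np.abs(row))
        if row[i] < 0:
            row *= -1.0
    return out


def pca(traj: Trajectory | np.ndarray) -> PCAResult:
    """Principal component analysis of frame coordinates about their mean.

    Frames are expected to be globally fitted to a common reference
    beforehand (see :func:`~tqcoupling.decomposition.remove_global_fit`).
    """
    x = traj.flat if isinstance(traj, Trajectory) else np.asarray(traj, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise DataError("pca needs at least 2 frames of flattened coordinates")
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD of the centred data matrix: eigenvalues are s^2 / (F - 1).
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    eigenvalues = s**2 / (x.shape[0] - 1)
    total = eigenvalues.sum()
    explained = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return PCAResult(
        eigenvalues=eigenvalues,
        eigenvectors=_fix_sign(vt),
        mean=mean,
        explained_fraction=explained,
    )


def covariance_rank(
    traj: Trajectory | np.ndarray,
    rtol: float = 1e-12,
) -> int:
    """Number of covariance eigenvalues above ``rtol`` times the largest.

    The default threshold (1e-12 of the largest eigenvalue) counts the
    degrees of freedom sampled at linear order; see the methods note for
    the effect of finite rotation amplitudes.
    """
    res = pca(traj)
    if res.eigenvalues.size == 0 or res.eigenvalues[0] <= 0:
        return 0
    return int(np.sum(res.eigenvalues > rtol * res.eigenvalues[0]))


def project(
    traj: Trajectory | np.ndarray | StructureFrame,
    mode: CollectiveMode,
    split_point: int | None = None,
) -> ProjectionSeries:
    """Per-frame scalar projection ``(x - origin) · vector`` in nm."""
    if isinstance(traj, StructureFrame):
        x = traj.flat[None, :]
    elif isinstance(traj, Trajectory):
        x = traj.flat
    else:
        x = np.asarray(traj, dtype=np.float64)
        if x.ndim == 3:  # (F, N, 3) coordinate frames
            x = x.reshape(x.shape[0], -1)
        x = np.atleast_2d(x)
    if x.shape[1] != mode.vector.size:
        raise DataError(
            f"dimension mismatch: trajectory has {x.shape[1]} coordinates, "
            f"mode has {mode.vector.size}"
        )
    values = (x - mode.origin) @ mode.vector
    return ProjectionSeries(values=values, mode=mode, split_point=split_point)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation coefficient of two scalar series."""
    a = np.asarray(a, dtype=np.float64).reshape(-1)
    b = np.asarray(b, dtype=np.float64).reshape(-1)
    if a.shape != b.shape or a.size < 3:
        raise DataError("pearson needs two equal-length series of length >= 3")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise DataError("pearson undefined for a zero-variance series")
    return float(np.corrcoef(a, b)[0, 1])


def mode_overlap(m1: CollectiveMode, m2: CollectiveMode) -> float:
    """Absolute scalar product of two normalised modes, in [0, 1]."""
    if m1.vector.size != m2.vector.size:
        raise DataError("mode dimensions differ")
    return float(abs(m1.vector @ m2.vector))


def _fit_pls(x: np.ndarray, y: np.ndarray, k: int):
    """PLS1 fit returning latent vectors, weights and the gradient mode.

    If the deflated data run out of variance before ``k`` components
    (score variance below 1e-10 of the first component's), the fit is
    repeated with the numerically supported count: past that point the
    deflation divides by vanishing norms and the coefficient vector —
    hence the composed mode — degenerates.
    """
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(x, y)
    x_mean = x.mean(axis=0)
    scores = (x - x_mean) @ pls.x_rotations_
    score_var = scores.var(axis=0, ddof=1)
    supported = int(np.sum(score_var > 1e-10 * score_var[0]))
    if supported < k:
        logger.warning(
            "pls_fma: data support only %d of %d requested latent vectors; "
            "refitting with %d", supported, k, supported,
        )
        pls = PLSRegression(n_components=supported, scale=False)
        pls.fit(x, y)
        scores = (x - x_mean) @ pls.x_rotations_
        score_var = scores.var(axis=0, ddof=1)
    rotations = pls.x_rotations_  # (3N, k); scores = (x - mean) @ rotations
    coefs = np.ravel(pls.y_loadings_)  # regression weight per latent score
    grad = np.ravel(pls.coef_)  # coordinate-space gradient of the fit
    return rotations.T, coefs, score_var, grad, x_mean, float(y.mean())


def pls_fma(
    coords: Trajectory | np.ndarray,
    target: ProjectionSeries | np.ndarray,
    n_components: int,
    train_fraction: float = 0.5,
    refit_on_full: bool = False,
) -> PLSFMAModel:
    """Fit a PLS-FMA model of the target on tertiary-only coordinates.

    The model is constructed on the first ``train_fraction`` of the frames
    and cross-validated on the remainder (``fit_r`` / ``cv_r``).  With
    ``refit_on_full=True`` the latent vectors and modes are refit with the
    same number of components on the full data set (as done for the final
    model), keeping the half-split ``cv_r`` as the validation estimate;
    ``fit_r`` then refers to the full data set.
    """
    x = coords.flat if isinstance(coords, Trajectory) else np.asarray(coords, dtype=np.float64)
    y = target.values if isinstance(target, ProjectionSeries) else np.asarray(target, dtype=np.float64)
    y = y.reshape(-1)
    f = x.shape[0]
    if y.size != f:
        raise DataError("coords and target disagree on frame count")
    if y.std() == 0:
        raise DataError("target has zero variance")
    if not 0 < train_fraction <= 1:
        raise ConfigError("train_fraction must be in (0, 1]")
    split = int(round(f * train_fraction))
    split = min(max(split, 2), f)
    if n_components < 1:
        raise ConfigError("n_components must be >= 1")
    if n_components > split - 1:
        raise ConfigError(
            f"n_components={n_components} exceeds training frames - 1 ({split - 1})"
        )

    latent, coefs, svar, grad, x_mean, y_mean = _fit_pls(x[:split], y[:split], n_components)
    pred = y_mean + ((x - x_mean) @ latent.T) @ coefs
    fit_r = pearson(pred[:split], y[:split])
    cv_r = pearson(pred[split:], y[split:]) if split < f - 2 else fit_r

    if refit_on_full and split < f:
        latent, coefs, svar, grad, x_mean, y_mean = _fit_pls(x, y, n_components)
        pred = y_mean + ((x - x_mean) @ latent.T) @ coefs
        fit_r = pearson(pred, y)

    mode_ct = CollectiveMode(vector=grad, role="cT", origin=x_mean)
    ctew_vec = (coefs * svar) @ latent
    mode_ctew = CollectiveMode(vector=ctew_vec, role="cTew", origin=x_mean)
    model = PLSFMAModel(
        latent_vectors=latent,
        coefficients=coefs,
        score_variances=svar,
        n_components=latent.shape[0],
        mode_cT=mode_ct,
        mode_cTew=mode_ctew,
        fit_r=fit_r,
        cv_r=cv_r,
        origin=x_mean,
        split_point=split,
    )
    model._y_mean = y_mean
    return model


def select_components(
    coords: Trajectory | np.ndarray,
    target: ProjectionSeries | np.ndarray,
    k_max: int,
    train_fraction: float = 0.5,
) -> tuple[int, np.ndarray]:
    """Cross-validation curve over 1..k_max latent vectors.

    Returns the maximiser of the cross-validation correlation and the
    full curve.  The final model should be refit with ``k_best`` on all
    frames (``pls_fma(..., refit_on_full=True)``).
    """
    if k_max < 1:
        raise ConfigError("k_max must be >= 1")
    curve = np.empty(k_max)
    for k in range(1, k_max + 1):
        curve[k - 1] = pls_fma(coords, target, k, train_fraction=train_fraction).cv_r
    k_best = int(np.argmax(curve)) + 1
    return k_best, curve


def ensemble_weight(
    model: PLSFMAModel,
    coords: Trajectory | np.ndarray | None = None,
) -> CollectiveMode:
    """Ensemble-weighted coupling mode cTew.

    Reweights the latent vectors by their contribution to the overall
    coordinate variance: ``cTew = normalise( sum_k c_k sigma^2_k v_k )``
    with regression coefficients ``c_k`` and score variances
    ``sigma^2_k``.  If ``coords`` is given, the score variances are
    recomputed on those frames; otherwise the stored (training) variances
    are used.
    """
    svar = model.score_variances
    if coords is not None:
        x = coords.flat if isinstance(coords, Trajectory) else np.asarray(coords)
        scores = (x - model.origin) @ model.latent_vectors.T
        svar = scores.var(axis=0, ddof=1)
    vec = (model.coefficients * svar) @ model.latent_vectors
    return CollectiveMode(vector=vec, role="cTew", origin=model.origin.copy())
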