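"""General linear model for BOLD time series.

Design matrices are built by convolving the stimulus boxcar with a
unit-peak HRF (or each function of an HRF basis set) at an oversampled
grid; voxel-wise least squares with AR(1) prewhitening yields parameter
estimates whose t and F statistics are mapped to z scores through the
standard-normal quantile of their tail probabilities. Cluster-level
family-wise error is controlled by a permutation null of the maximum
cluster extent, built by sign-flipping whitened reduced-model residuals
(Freedman-Lane), with face-connected (6-connectivity) components of
suprathreshold voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special, stats

from neohrf.basis import BasisSet
from neohrf.hrf import HRFParams
from neohrf.synth import StimulusDesign, convolved_regressor

__all__ = [
    "DesignMatrix",
    "GLMFit",
    "StatMaps",
    "Cluster",
    "build_design_matrix",
    "fit_glm",
    "contrast_stats",
    "cluster_threshold",
    "permutation_max_cluster_null",
]

#: z scores are capped here to avoid infinities from vanishing tail mass
Z_CAP = 8.2

#: face connectivity in 3D (conservative cluster definition)
_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class DesignMatrix:
    """Regressors at volume times.

    Task columns come first (one per HRF/basis function, unit peak), then
    the intercept, then drift terms.
    """

    matrix: np.ndarray  # (T, p)
    labels: tuple[str, ...]
    tr: float
    task_columns: tuple[int, ...]
    intercept_column: int

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    @property
    def nuisance_columns(self) -> tuple[int, ...]:
        return tuple(
            i for i in range(self.n_regressors) if i not in self.task_columns
        )


def build_design_matrix(
    design: StimulusDesign,
    hrf_or_basis: HRFParams | BasisSet,
    drift_order: int = 1,
    oversample: int = 10,
) -> DesignMatrix:
    """Convolve the stimulus design into task regressors and append nuisance.

    Each task column is the stimulus boxcar convolved with the unit-peak HRF
    (or one basis function resampled onto the oversampled grid), normalized
    to unit maximum absolute value so effect sizes read in % signal change.
    Nuisance columns: intercept and mean-centred Legendre drift polynomials.
    """
    if len(design.onsets) == 0:
        raise ValueError("design has no stimuli; task regressor would be all-zero")
    cols, labels = [], []
    if isinstance(hrf_or_basis, HRFParams):
        cols.append(convolved_regressor(design, hrf_or_basis, oversample=oversample))
        labels.append("task")
    elif isinstance(hrf_or_basis, BasisSet):
        bs = hrf_or_basis
        for i, f in enumerate(bs.functions):
            cols.append(
                convolved_regressor(
                    design, (bs.times, f), oversample=oversample
                )
            )
            labels.append(f"basis_{i + 1}")
    else:
        raise TypeError("hrf_or_basis must be HRFParams or BasisSet")
    task_idx = tuple(range(len(cols)))

    T = design.n_volumes
    cols.append(np.ones(T))
    labels.append("intercept")
    intercept_idx = len(cols) - 1
    if drift_order >= 1:
        x = np.linspace(-1.0, 1.0, T)
        for order in range(1, drift_order + 1):
            c = np.zeros(order + 1)
            c[order] = 1.0
            col = np.polynomial.legendre.legval(x, c)
            col = col - col.mean()
            cols.append(col)
            labels.append(f"drift_{order}")
    X = np.column_stack(cols)
    return DesignMatrix(
        matrix=X,
        labels=tuple(labels),
        tr=design.tr,
        task_columns=task_idx,
        intercept_column=intercept_idx,
    )


def _as_voxel_matrix(Y: np.ndarray) -> tuple[np.ndarray, tuple[int, ...] | None]:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 4:
        shape = Y.shape[:3]
        return Y.reshape(-1, Y.shape[3]), shape
    if Y.ndim == 2:
        return Y, None
    raise ValueError("Y must be (voxels, time) or 4D (x, y, z, t)")


def _lag1_autocorr(resid: np.ndarray) -> np.ndarray:
    num = np.sum(resid[:, 1:] * resid[:, :-1], axis=1)
    den = np.sum(resid**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    return np.clip(rho, -0.95, 0.95)


def _whiten(series: np.ndarray, rho: float | np.ndarray) -> np.ndarray:
    """AR(1) whitening transform along the last axis.

    First sample scaled by sqrt(1 - rho^2), the rest by first differences
    y[t] - rho*y[t-1].
    """
    rho = np.asarray(rho, dtype=float)
    out = np.empty_like(series)
    if rho.ndim == 0:
        out[..., 0] = series[..., 0] * np.sqrt(1.0 - float(rho) ** 2)
        out[..., 1:] = series[..., 1:] - float(rho) * series[..., :-1]
    else:
        r = rho.reshape(rho.shape + (1,) * (series.ndim - rho.ndim))
        out[..., :1] = series[..., :1] * np.sqrt(1.0 - r**2)
        out[..., 1:] = series[..., 1:] - r * series[..., :-1]
    return out


@dataclass
class GLMFit:
    """Prewhitened least-squares fit over voxels."""

    design: DesignMatrix
    betas: np.ndarray  # (V, p)
    sigma2: np.ndarray  # (V,)
    xtx_inv: np.ndarray  # (V, p, p)
    dof: int
    rho: np.ndarray  # (V,) per-voxel AR(1) coefficients used for whitening
    pooled_rho: float
    spatial_shape: tuple[int, int, int] | None
    whitened_resid_lag1: np.ndarray  # (V,) diagnostics
    _Y: np.ndarray = field(repr=False)  # (V, T) original data

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[0]


def fit_glm(
    Y: np.ndarray,
    X: DesignMatrix,
    ar_order: int = 1,
    pool_rho: bool = False,
    chunk: int = 2048,
) -> GLMFit:
    """OLS, AR(1) estimation from residuals, prewhitening, re-estimation.

    ``pool_rho`` replaces per-voxel AR coefficients by their spatial mean
    (one shared whitening transform). ar_order 0 disables whitening.
    """
    Yv, shape = _as_voxel_matrix(Y)
    M = X.matrix
    T, p = M.shape
    if Yv.shape[1] != T:
        raise ValueError(f"data has {Yv.shape[1]} volumes but design has {T}")
    if ar_order not in (0, 1):
        raise ValueError("only AR orders 0 and 1 are supported")
    rank = np.linalg.matrix_rank(M)
    if rank < p:
        # name the offending columns for the error message
        _, R = np.linalg.qr(M)
        bad = [X.labels[i] for i in range(p) if abs(R[i, i]) < 1e-10]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    pinv = np.linalg.pinv(M)
    beta_ols = Yv @ pinv.T
    resid = Yv - beta_ols @ M.T

    if ar_order == 0:
        rho_vox = np.zeros(Yv.shape[0])
    else:
        rho_vox = _lag1_autocorr(resid)
    pooled = float(rho_vox.mean()) if rho_vox.size else 0.0
    rho_used = np.full_like(rho_vox, pooled) if pool_rho else rho_vox

    V = Yv.shape[0]
    betas = np.empty((V, p))
    sigma2 = np.empty(V)
    xtx_inv = np.empty((V, p, p))
    lag1 = np.empty(V)
    dof = T - p
    for start in range(0, V, chunk):
        sl = slice(start, min(start + chunk, V))
        r = rho_used[sl]
        Yw = _whiten(Yv[sl], r)
        Xw = np.empty((r.size, T, p))
        Xw[:, 0, :] = M[0] * np.sqrt(1.0 - r**2)[:, None]
        Xw[:, 1:, :] = M[None, 1:, :] - r[:, None, None] * M[None, :-1, :]
        xtx = np.einsum("vtp,vtq->vpq", Xw, Xw)
        xty = np.einsum("vtp,vt->vp", Xw, Yw)
        inv = np.linalg.inv(xtx)
        b = np.einsum("vpq,vq->vp", inv, xty)
        rw = Yw - np.einsum("vtp,vp->vt", Xw, b)
        betas[sl] = b
        sigma2[sl] = np.sum(rw**2, axis=1) / dof
        # residual variance indistinguishable from rounding error counts
        # as zero (perfect fit) for downstream guards
        scale = np.mean(Yw**2, axis=1)
        sigma2[sl][sigma2[sl] < 1e-24 * scale] = 0.0
        xtx_inv[sl] = inv
        lag1[sl] = _lag1_autocorr(rw)

    return GLMFit(
        design=X,
        betas=betas,
        sigma2=sigma2,
        xtx_inv=xtx_inv,
        dof=dof,
        rho=rho_used,
        pooled_rho=pooled,
        spatial_shape=shape,
        whitened_resid_lag1=lag1,
        _Y=Yv,
    )


def _z_from_sf(sf: np.ndarray, sign: np.ndarray | float = 1.0) -> np.ndarray:
    """Map a tail probability to a standard-normal quantile, capped."""
    sf = np.clip(sf, 1e-300, 1.0)
    z = -special.ndtri(sf)
    return np.clip(z * np.sign(sign) if np.ndim(sign) else z, -Z_CAP, Z_CAP)


@dataclass(frozen=True)
class StatMaps:
    """Voxel-wise statistics from one contrast / basis-column F-test."""

    effect: np.ndarray  # % signal change
    t: np.ndarray | None
    z: np.ndarray  # from t if a contrast was given, else from F
    F: np.ndarray | None
    dof: int
    capped: np.ndarray  # True where z hit the cap or variance vanished
    spatial_shape: tuple[int, int, int] | None

    def volume(self, name: str = "z") -> np.ndarray:
        arr = getattr(self, name)
        if self.spatial_shape is None:
            raise ValueError("fit was not spatial; no volume shape available")
        return arr.reshape(self.spatial_shape)


def contrast_stats(
    fit: GLMFit,
    contrast: np.ndarray | None = None,
    f_columns: tuple[int, ...] | None = None,
) -> StatMaps:
    """t (and z) for a contrast vector, or F (and z) over a set of columns.

    z is the standard-normal quantile of the statistic's tail probability
    (signed for t, upper-tail for F), capped at +/-8.2. Effect size is in %
    signal change relative to the voxel baseline (the intercept estimate):
    the contrast effect for a t-test, the peak of the fitted task response
    for an F-test.
    """
    X = fit.design
    baseline = fit.betas[:, X.intercept_column]
    with np.errstate(invalid="ignore", divide="ignore"):
        if contrast is not None:
            c = np.asarray(contrast, dtype=float)
            if c.size != X.n_regressors:
                raise ValueError("contrast dimension does not match design columns")
            cb = fit.betas @ c
            var = fit.sigma2 * np.einsum("p,vpq,q->v", c, fit.xtx_inv, c)
            se = np.sqrt(var)
            t = np.where(se > 0, cb / np.where(se > 0, se, 1.0), 0.0)
            capped = se == 0
            # a contrast that is numerically zero on a perfectly fitted
            # voxel is 0/0: guarded to zero, not to the cap
            cb_tiny = np.abs(cb) <= 1e-9 * np.abs(baseline)
            cb = np.where(capped & cb_tiny, 0.0, cb)
            z = _z_from_sf(stats.t.sf(np.abs(t), fit.dof), np.sign(t))
            z = np.where(capped, np.where(cb_tiny, 0.0, np.sign(cb) * Z_CAP), z)
            effect = np.where(baseline != 0, 100.0 * cb / baseline, 0.0)
            capped = capped | (np.abs(z) >= Z_CAP)
            return StatMaps(
                effect=effect, t=t, z=z, F=None, dof=fit.dof,
                capped=capped, spatial_shape=fit.spatial_shape,
            )
        if f_columns is None:
            f_columns = X.task_columns
        k = len(f_columns)
        idx = np.asarray(f_columns)
        q = fit.betas[:, idx]  # (V, k)
        sub = fit.xtx_inv[:, idx[:, None], idx[None, :]]  # (V, k, k)
        Minv = np.linalg.inv(sub)
        quad = np.einsum("vk,vkl,vl->v", q, Minv, q)
        F = np.where(fit.sigma2 > 0, quad / (k * np.where(fit.sigma2 > 0, fit.sigma2, 1.0)), 0.0)
        F = np.maximum(F, 0.0)
        capped = fit.sigma2 == 0
        z = _z_from_sf(stats.f.sf(F, k, fit.dof))
        z = np.where(capped & (quad > 0), Z_CAP, z)
        capped = capped | (z >= Z_CAP)
        # effect: signed peak of the fitted task response, relative to baseline
        task_fit = q @ X.matrix[:, idx].T  # (V, T)
        peak_idx = np.argmax(np.abs(task_fit), axis=1)
        peak = task_fit[np.arange(task_fit.shape[0]), peak_idx]
        effect = np.where(baseline != 0, 100.0 * peak / baseline, 0.0)
        return StatMaps(
            effect=effect, t=None, z=z, F=F, dof=fit.dof,
            capped=capped, spatial_shape=fit.spatial_shape,
        )


@dataclass(frozen=True)
class Cluster:
    """A face-connected suprathreshold component with corrected inference."""

    label: int
    size: int
    mass: float  # sum of (z - threshold) over the cluster
    peak_z: float
    peak_voxel: tuple[int, int, int]
    p_corrected: float
    voxels: np.ndarray  # (size, 3) integer coordinates


def _max_cluster_stat(
    zmap: np.ndarray, thresh: float, statistic: str = "extent"
) -> float:
    """Maximum cluster extent (voxel count) or mass (sum of z - thresh)."""
    supra = zmap > thresh
    labels, n = ndimage.label(supra, structure=_STRUCTURE)
    if n == 0:
        return 0.0
    if statistic == "extent":
        vals = ndimage.sum_labels(supra, labels, index=np.arange(1, n + 1))
    else:
        vals = ndimage.sum_labels(zmap - thresh, labels, index=np.arange(1, n + 1))
    return float(np.max(vals))


def permutation_max_cluster_null(
    fit: GLMFit,
    n_permutations: int,
    seed: int,
    z_thresh: float = 2.3,
    f_columns: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Null distribution of the maximum cluster extent by sign-flipping.

    Whitened (spatially pooled AR(1)) FULL-model residuals are sign-flipped
    per time point (the same flips at every voxel, preserving spatial
    structure), added back to the reduced-model fit, and the F map over the
    task columns is recomputed and thresholded at the F value equivalent to
    ``z_thresh``. Using full-model residuals keeps the null free of task
    signal, so true activation does not inflate (and thereby over-conserve)
    the null cluster sizes.
    """
    if fit.spatial_shape is None:
        raise ValueError("cluster inference requires spatially shaped data")
    X = fit.design
    if f_columns is None:
        f_columns = X.task_columns
    idx = np.asarray(f_columns)
    k = idx.size
    nuis = np.asarray([i for i in range(X.n_regressors) if i not in set(f_columns)])

    rho = fit.pooled_rho
    M = X.matrix
    Xw = _whiten(M.T, rho).T  # (T, p)
    Yw = _whiten(fit._Y, rho)  # (V, T)
    Xr = Xw[:, nuis]
    beta_r = Yw @ np.linalg.pinv(Xr).T
    fitted_r = beta_r @ Xr.T

    pinv_w = np.linalg.pinv(Xw)  # (p, T)
    resid_full = Yw - (Yw @ pinv_w.T) @ Xw.T
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    sub = xtx_inv[np.ix_(idx, idx)]
    Minv = np.linalg.inv(sub)
    dof = fit.dof
    f_crit = stats.f.isf(stats.norm.sf(z_thresh), k, dof)

    rng = np.random.default_rng(seed)
    T = Yw.shape[1]
    out = np.empty(n_permutations, dtype=float)
    for i in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=T)
        Ystar = fitted_r + resid_full * signs
        b = Ystar @ pinv_w.T  # (V, p)
        rss = np.sum((Ystar - b @ Xw.T) ** 2, axis=1)
        sigma2 = rss / dof
        q = b[:, idx]
        quad = np.einsum("vk,kl,vl->v", q, Minv, q)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(sigma2 > 0, quad / (k * sigma2), 0.0)
        out[i] = _max_cluster_stat(F.reshape(fit.spatial_shape), f_crit, "extent")
    return out


def cluster_threshold(
    zmap: np.ndarray,
    z_thresh: float = 2.3,
    alpha: float = 0.05,
    null_max_sizes: np.ndarray | None = None,
    fit: GLMFit | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    f_columns: tuple[int, ...] | None = None,
    statistic: str = "extent",
    return_all: bool = False,
) -> list[Cluster]:
    """Face-connected clusters of voxels with z > z_thresh, with corrected p
    from the permutation null of the maximum cluster statistic.

    Either pass a precomputed ``null_max_sizes`` array (maximum extents, or
    maximum masses when ``statistic='mass'``) or a ``fit`` from which the
    time-domain sign-flipping extent null is generated. Returns clusters
    with corrected p < alpha (all clusters when ``return_all``); an empty
    list when nothing is suprathreshold.
    """
    zmap = np.asarray(zmap, dtype=float)
    if zmap.ndim != 3:
        raise ValueError("zmap must be 3D")
    if not np.all(np.isfinite(zmap)):
        raise ValueError("zmap contains non-finite values")
    if statistic not in ("extent", "mass"):
        raise ValueError("statistic must be 'extent' or 'mass'")
    supra = zmap > z_thresh
    labels, n = ndimage.label(supra, structure=_STRUCTURE)
    if n == 0:
        return []
    if null_max_sizes is None:
        if fit is None:
            raise ValueError("need null_max_sizes or a GLMFit to permute")
        if n_permutations < 100:
            raise ValueError("permutation count must be >= 100")
        if statistic != "extent":
            raise ValueError("the GLM time-permutation null is extent-based")
        null_max_sizes = permutation_max_cluster_null(
            fit, n_permutations, seed, z_thresh=z_thresh, f_columns=f_columns
        )
    null_max_sizes = np.asarray(null_max_sizes, dtype=float)
    n_perm = null_max_sizes.size

    clusters = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        zvals = zmap[tuple(coords.T)]
        peak = int(np.argmax(zvals))
        size = coords.shape[0]
        mass = float(np.sum(zvals - z_thresh))
        obs = float(size) if statistic == "extent" else mass
        p = (1 + int(np.sum(null_max_sizes >= obs))) / (n_perm + 1)
        clusters.append(
            Cluster(
                label=lab,
                size=size,
                mass=mass,
                peak_z=float(zvals[peak]),
                peak_voxel=tuple(int(c) for c in coords[peak]),
                p_corrected=float(p),
                voxels=coords,
            )
        )
    clusters.sort(key=lambda c: c.size, reverse=True)
    if return_all:
        return clusters
    return [c for c in clusters if c.p_corrected < alpha]
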