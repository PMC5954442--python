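"""Gaussian-mixture representation of density maps and analytic overlap integrals.

A cryo-EM density map is represented in two equivalent forms: a voxel grid
(:class:`DensityMap`) and a Gaussian mixture model (:class:`GaussianMixture`).
The mixture form turns the map into a set of quasi-independent data points
(its components), whose pairwise overlap integrals

    ov(a, b) = ∫ G_a(x) G_b(x) dx

have a closed form for Gaussians and are the observables restrained during
ensemble modelling.  All lengths are in nm, densities in nm^-3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GaussianComponent",
    "GaussianMixture",
    "DensityMap",
    "OverlapVector",
    "DegenerateCovarianceError",
    "GridMismatchError",
    "pair_overlap",
    "mixture_component_overlap",
    "self_overlaps",
    "rasterize",
    "global_cc",
    "local_cc",
]

# Smallest admissible covariance eigenvalue (nm^2); below this the summed
# covariance of an overlap pair is treated as numerically singular.
COV_EIGVAL_FLOOR = 1e-10

_TWO_PI_POW_3_2 = (2.0 * np.pi) ** 1.5


class DegenerateCovarianceError(ValueError):
    """Covariance matrix is not symmetric positive-definite."""


class GridMismatchError(ValueError):
    """Two density maps are not defined on the same voxel grid."""


def _validate_cov(cov: np.ndarray, what: str = "covariance") -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (3, 3):
        raise ValueError(f"{what} must be 3x3, got {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-12):
        raise DegenerateCovarianceError(f"{what} is not symmetric")
    ev = np.linalg.eigvalsh(cov)
    if ev[0] <= COV_EIGVAL_FLOOR:
        raise DegenerateCovarianceError(
            f"{what} smallest eigenvalue {ev[0]:.3e} <= {COV_EIGVAL_FLOOR:.0e} nm^2"
        )
    return cov


@dataclass(frozen=True)
class GaussianComponent:
    """One weighted 3-D Gaussian: ``weight * N(mean, cov)``.

    Parameters
    ----------
    weight : float
        Dimensionless positive weight (integral of the component).
    mean : (3,) array
        Centre in nm.
    cov : (3, 3) array
        Symmetric positive-definite covariance in nm^2.
    """

    weight: float
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        mean = np.asarray(self.mean, dtype=float)
        if mean.shape != (3,) or not np.all(np.isfinite(mean)):
            raise ValueError("mean must be a finite 3-vector")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", _validate_cov(self.cov))

    @staticmethod
    def isotropic(weight: float, mean: Sequence[float], var: float) -> "GaussianComponent":
        return GaussianComponent(weight, np.asarray(mean, float), var * np.eye(3))


class GaussianMixture:
    """Ordered collection of :class:`GaussianComponent`.

    Stored internally as packed arrays (``weights`` (K,), ``means`` (K, 3),
    ``covs`` (K, 3, 3)) so that overlap and rasterization kernels vectorize.
    Data-GMMs carry ``normalized=True`` (weights sum to 1); model GMMs built
    by the forward model are unnormalized (their mass is physical).
    """

    def __init__(
        self,
        weights: np.ndarray,
        means: np.ndarray,
        covs: np.ndarray,
        normalized: bool = False,
        label: str = "",
    ) -> None:
        weights = np.asarray(weights, dtype=float).ravel()
        means = np.asarray(means, dtype=float).reshape(-1, 3)
        covs = np.asarray(covs, dtype=float).reshape(-1, 3, 3)
        if not (len(weights) == len(means) == len(covs)):
            raise ValueError("weights/means/covs length mismatch")
        if len(weights) < 1:
            raise ValueError("a mixture needs at least one component")
        if np.any(weights <= 0):
            raise ValueError("all weights must be > 0")
        for c in covs:
            _validate_cov(c)
        if normalized and abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"normalized mixture weights sum to {weights.sum():.12f}, expected 1"
            )
        self.weights = weights
        self.means = means
        self.covs = covs
        self.normalized = bool(normalized)
        self.label = label

    @classmethod
    def from_components(
        cls,
        components: Sequence[GaussianComponent],
        normalized: bool = False,
        label: str = "",
    ) -> "GaussianMixture":
        return cls(
            np.array([c.weight for c in components]),
            np.array([c.mean for c in components]),
            np.array([c.cov for c in components]),
            normalized=normalized,
            label=label,
        )

    def __len__(self) -> int:
        return len(self.weights)

    def __getitem__(self, i: int) -> GaussianComponent:
        return GaussianComponent(self.weights[i], self.means[i], self.covs[i])

    def __iter__(self) -> Iterator[GaussianComponent]:
        return (self[i] for i in range(len(self)))

    def normalize(self, label: str | None = None) -> "GaussianMixture":
        """Return a copy with weights rescaled to sum to 1."""
        w = self.weights / self.weights.sum()
        return GaussianMixture(
            w, self.means.copy(), self.covs.copy(), normalized=True,
            label=self.label if label is None else label,
        )

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Mixture density at ``points`` (n, 3) nm -> (n,) nm^-3."""
        points = np.atleast_2d(np.asarray(points, float))
        out = np.zeros(len(points))
        for w, mu, cov in zip(self.weights, self.means, self.covs):
            out += w * _gauss_eval(points, mu, cov)
        return out


def _gauss_eval(points: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = points - mean
    cinv = np.linalg.inv(cov)
    q = np.einsum("ni,ij,nj->n", d, cinv, d)
    det = np.linalg.det(cov)
    return np.exp(-0.5 * q) / (_TWO_PI_POW_3_2 * np.sqrt(det))


@dataclass
class DensityMap:
    """Voxel grid in real space.

    ``values[i, j, k]`` is the density at position
    ``origin + (i, j, k) * voxel_size`` (voxel centres; nm).
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float).ravel(), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.dims[axis]) * self.voxel_size[axis]

    def same_grid(self, other: "DensityMap", tol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def like(self, values: np.ndarray) -> "DensityMap":
        """New map with the same grid and the given values."""
        return DensityMap(values, self.voxel_size.copy(), self.origin.copy())

    @staticmethod
    def empty(dims: Sequence[int], voxel_size, origin) -> "DensityMap":
        return DensityMap(np.zeros(tuple(dims)), voxel_size, origin)


@dataclass
class OverlapVector:
    """Per-data-component overlaps.

    ``ovDD[i]`` is the overlap of data component i with the whole data-GMM
    (the data point d_i); ``ovMD_bar[i]`` the replica-averaged model overlap
    f_i(X); ``ovMD[r, i]`` optionally the per-replica values.
    """

    ovDD: np.ndarray | None = None
    ovMD_bar: np.ndarray | None = None
    ovMD: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.ovDD is not None:
            self.ovDD = np.asarray(self.ovDD, float)
            if np.any(self.ovDD <= 0):
                raise ValueError("every ovDD entry must be > 0")
        if self.ovMD_bar is not None:
            self.ovMD_bar = np.asarray(self.ovMD_bar, float)
        if self.ovMD is not None:
            self.ovMD = np.asarray(self.ovMD, float)


# ---------------------------------------------------------------------------
# overlap integrals
# ---------------------------------------------------------------------------

def pair_overlap(a: GaussianComponent, b: GaussianComponent) -> float:
    """Overlap integral of two weighted Gaussians (closed form, nm^-3).

    ov = w_a w_b (2π)^{-3/2} det(Σ_a+Σ_b)^{-1/2}
         exp(-½ dᵀ (Σ_a+Σ_b)^{-1} d),  d = μ_a - μ_b.

    Symmetric in its arguments and bilinear in the two weights.
    """
    s = a.cov + b.cov
    ev = np.linalg.eigvalsh(s)
    if ev[0] <= COV_EIGVAL_FLOOR:
        raise DegenerateCovarianceError("summed covariance numerically singular")
    d = a.mean - b.mean
    q = d @ np.linalg.solve(s, d)
    det = np.linalg.det(s)
    return float(a.weight * b.weight * np.exp(-0.5 * q) / (_TWO_PI_POW_3_2 * np.sqrt(det)))


def _component_overlaps(
    weights: np.ndarray,
    means: np.ndarray,
    covs: np.ndarray,
    comp: GaussianComponent,
) -> np.ndarray:
    """Vectorized pair_overlap of many components against one component."""
    s = covs + comp.cov
    d = means - comp.mean
    sinv_d = np.linalg.solve(s, d[..., None])[..., 0]
    q = np.einsum("ki,ki->k", d, sinv_d)
    det = np.linalg.det(s)
    return weights * comp.weight * np.exp(-0.5 * q) / (_TWO_PI_POW_3_2 * np.sqrt(det))


def mixture_component_overlap(
    model: GaussianMixture,
    comp: GaussianComponent,
    pairs: Sequence[int] | None = None,
) -> float:
    """ov_{M,i} = ∫ φ_M(x) φ_i(x) dx, optionally over a neighbor subset.

    ``pairs`` restricts the sum to the listed model-component indices (the
    neighbor-list truncation); an empty subset yields 0.
    """
    if pairs is not None:
        idx = np.asarray(pairs, dtype=int)
        if idx.size == 0:
            return 0.0
        w, m, c = model.weights[idx], model.means[idx], model.covs[idx]
    else:
        w, m, c = model.weights, model.means, model.covs
    return float(_component_overlaps(w, m, c, comp).sum())


def self_overlaps(data: GaussianMixture) -> np.ndarray:
    """ovDD_i: overlap of each component of a normalized data-GMM with the
    whole data-GMM.  These are the data points d_i of the noise model."""
    if not data.normalized:
        raise ValueError("self_overlaps expects a normalized data-GMM")
    out = np.array(
        [mixture_component_overlap(data, data[i]) for i in range(len(data))]
    )
    if np.any(out <= 0):  # pragma: no cover - mathematically impossible
        raise ValueError("non-positive self overlap")
    return out


# ---------------------------------------------------------------------------
# rasterization and map correlation
# ---------------------------------------------------------------------------

def rasterize(
    gmm: GaussianMixture,
    template: DensityMap,
    n_sigma: float = 5.0,
) -> DensityMap:
    """Evaluate a mixture on the voxel centres of ``template``.

    Each component is evaluated only inside its mean ± ``n_sigma``
    standard-deviation bounding box for speed; the voxel sum times the voxel
    volume approximates the total weight when the grid covers the support.
    Warns (does not fail) when a component's ±4σ box leaves the grid.
    """
    lo = template.origin
    hi = template.origin + (np.array(template.dims) - 1) * template.voxel_size
    out = np.zeros(template.dims)
    axes = [template.axis_coords(a) for a in range(3)]
    uncovered = 0
    for w, mu, cov in zip(gmm.weights, gmm.means, gmm.covs):
        sig = np.sqrt(np.linalg.eigvalsh(cov)[-1])
        if np.any(mu - 4 * sig < lo) or np.any(mu + 4 * sig > hi):
            uncovered += 1
        i0 = np.maximum(
            0, np.floor((mu - n_sigma * sig - lo) / template.voxel_size).astype(int)
        )
        i1 = np.minimum(
            np.array(template.dims),
            np.ceil((mu + n_sigma * sig - lo) / template.voxel_size).astype(int) + 1,
        )
        if np.any(i0 >= i1):
            continue
        xs, ys, zs = (axes[a][i0[a]:i1[a]] for a in range(3))
        cinv = np.linalg.inv(cov)
        dx, dy, dz = xs - mu[0], ys - mu[1], zs - mu[2]
        # separable expansion of the quadratic form d^T C^-1 d
        q = (
            cinv[0, 0] * dx[:, None, None] ** 2
            + cinv[1, 1] * dy[None, :, None] ** 2
            + cinv[2, 2] * dz[None, None, :] ** 2
            + 2 * cinv[0, 1] * dx[:, None, None] * dy[None, :, None]
            + 2 * cinv[0, 2] * dx[:, None, None] * dz[None, None, :]
            + 2 * cinv[1, 2] * dy[None, :, None] * dz[None, None, :]
        )
        norm = w / (_TWO_PI_POW_3_2 * np.sqrt(np.linalg.det(cov)))
        out[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] += norm * np.exp(-0.5 * q)
    if uncovered:
        warnings.warn(
            f"{uncovered} mixture component(s) extend beyond the grid "
            "(mean +/- 4 sigma not fully contained)",
            stacklevel=2,
        )
    return template.like(out)


def _check_same_grid(a: DensityMap, b: DensityMap) -> None:
    if not a.same_grid(b):
        raise GridMismatchError(
            "maps are on different grids (dims/voxel/origin); resample first"
        )


def global_cc(a: DensityMap, b: DensityMap, threshold: float | None = None) -> float:
    """Global Pearson cross-correlation of two maps on the same grid.

    ``threshold`` optionally restricts the correlation to voxels where the
    first map exceeds the threshold; by default all voxels enter.
    """
    _check_same_grid(a, b)
    x = a.values.ravel()
    y = b.values.ravel()
    if threshold is not None:
        sel = x > threshold
        if sel.sum() < 2:
            raise ValueError("threshold leaves fewer than 2 voxels")
        x, y = x[sel], y[sel]
    x = x - x.mean()
    y = y - y.mean()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-variance map in global_cc")
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def local_cc(a: DensityMap, b: DensityMap, window: int = 5) -> DensityMap:
    """Per-voxel Pearson correlation in a sliding cubic window.

    The window is ``window`` voxels per side (odd); at the map edges the
    window is truncated to the voxels actually inside the grid, so no
    padding values enter the correlation.  Voxels whose window has zero
    variance in either map get the value 0.
    """
    _check_same_grid(a, b)
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    if window > min(a.dims):
        raise ValueError(f"window {window} exceeds smallest grid dimension {min(a.dims)}")
    x = a.values
    y = b.values
    vol = float(window**3)

    def wsum(arr: np.ndarray) -> np.ndarray:
        # uniform_filter(constant-0 padding) * window^3 == windowed sum with
        # zeros outside; dividing by the windowed count of ones makes the
        # edge statistics exactly those of the truncated window.
        return ndimage.uniform_filter(arr, size=window, mode="constant", cval=0.0) * vol

    n = wsum(np.ones_like(x))
    sx, sy = wsum(x), wsum(y)
    sxx, syy, sxy = wsum(x * x), wsum(y * y), wsum(x * y)
    cov = sxy - sx * sy / n
    vx = sxx - sx * sx / n
    vy = syy - sy * sy / n
    scale = np.sqrt(np.maximum(vx, 0.0) * np.maximum(vy, 0.0))
    # zero-variance windows are reported as 0 correlation
    tol = 1e-12 * max(float(np.abs(x).max()), float(np.abs(y).max()), 1.0) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(scale > tol, cov / np.where(scale > 0, scale, 1.0), 0.0)
    return a.like(np.clip(cc, -1.0, 1.0))
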