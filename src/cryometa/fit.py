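"""Fit a data-GMM to a voxel map by density-weighted expectation-maximization.

Each voxel centre is treated as a sample point weighted by its (clipped)
density, and a Gaussian mixture is fitted by weighted EM.  High component
counts are reached hierarchically: a coarse mixture is fitted globally, the
voxels are partitioned by maximum posterior responsibility, and each
partition is re-fitted with a small number of children whose weights are
rescaled by the parent's mass fraction (divide and conquer).  Refinement
stops at a component budget or when the rasterized fit reaches a target
cross-correlation with the input map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .gmm import DensityMap, GaussianMixture, global_cc, rasterize

__all__ = ["FitConfig", "fit_gmm_em", "divide_and_conquer_fit", "map_points"]


@dataclass
class FitConfig:
    """Configuration of the hierarchical fit.

    ``k0`` components are fitted globally first, then partitions are split
    into ``branching`` children per refinement level until ``budget``
    components or ``target_cc`` is reached.  ``tol`` is the relative change
    of the weighted log-likelihood that stops an EM sub-fit.
    """

    k0: int = 4
    branching: int = 4
    budget: int | None = None
    target_cc: float | None = None
    tol: float = 1e-6
    max_iter: int = 200
    polish_iters: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k0 < 1:
            raise ValueError("k0 must be >= 1")
        if self.branching < 2:
            raise ValueError("branching must be >= 2")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.budget is None and self.target_cc is None:
            raise ValueError("set a component budget and/or a target CC")


def map_points(dmap: DensityMap) -> tuple[np.ndarray, np.ndarray]:
    """Voxel centres and clipped-density weights of the positive voxels."""
    v = np.clip(dmap.values, 0.0, None)
    idx = np.argwhere(v > 0)
    pts = dmap.origin + idx * dmap.voxel_size
    return pts, v[v > 0]


def _floor_cov(cov: np.ndarray, floor: float) -> np.ndarray:
    """Clip covariance eigenvalues from below (prevents voxel-scale collapse)."""
    cov = 0.5 * (cov + cov.T)
    ev, vec = np.linalg.eigh(cov)
    return (vec * np.maximum(ev, floor)) @ vec.T


def _log_gauss(points: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(K, n) log N(x_n | mu_k, Sigma_k)."""
    from scipy.linalg import solve_triangular

    K = len(means)
    out = np.empty((K, len(points)))
    for k in range(K):
        chol = np.linalg.cholesky(covs[k])
        y = solve_triangular(chol, (points - means[k]).T, lower=True)
        q = np.sum(y * y, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[k] = -0.5 * (q + logdet + 3.0 * np.log(2.0 * np.pi))
    return out


def _weighted_em(
    points: np.ndarray,
    w: np.ndarray,
    K: int,
    seed: int,
    tol: float,
    max_iter: int,
    floor: float,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
):
    """Weighted EM; returns (pi, means, covs, resp, ll_trace)."""
    W = w.sum()
    if init is None:
        pi, means, covs = _kmeans_init(points, w, K, seed, floor)
    else:
        pi, means, covs = (np.array(a, float) for a in init)
    ll_trace: list[float] = []
    resp = None
    for _ in range(max_iter):
        log_pdf = _log_gauss(points, means, covs)
        log_wpdf = np.log(pi)[:, None] + log_pdf
        lse = logsumexp(log_wpdf, axis=0)
        ll = float(np.dot(w, lse) / W)
        resp = np.exp(log_wpdf - lse[None, :])
        nk = resp @ w
        keep = nk / W > 1e-12
        if not np.all(keep):
            warnings.warn(
                f"pruned {np.count_nonzero(~keep)} collapsed component(s)",
                stacklevel=2,
            )
            pi, means, covs = pi[keep], means[keep], covs[keep]
            resp, nk = resp[keep], nk[keep]
            nk = np.maximum(nk, 1e-300)
        pi = nk / W
        pi = pi / pi.sum()
        rw = resp * w[None, :]
        means = (rw @ points) / nk[:, None]
        for k in range(len(pi)):
            d = points - means[k]
            cov = (d.T * rw[k]) @ d / nk[k]
            covs[k] = _floor_cov(cov, floor)
        if ll_trace and abs(ll - ll_trace[-1]) <= tol * max(1.0, abs(ll_trace[-1])):
            ll_trace.append(ll)
            break
        ll_trace.append(ll)
    return pi, means, covs, resp, ll_trace


def _kmeans_init(points, w, K, seed, floor):
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=K, n_init=1, random_state=seed)
    labels = km.fit_predict(points, sample_weight=w)
    pi = np.empty(K)
    means = np.empty((K, 3))
    covs = np.empty((K, 3, 3))
    W = w.sum()
    for k in range(K):
        sel = labels == k
        wk = w[sel]
        if wk.sum() <= 0:
            # empty cluster: seed at the heaviest unclaimed point
            j = int(np.argmax(w))
            pi[k] = 1.0 / K
            means[k] = points[j]
            covs[k] = floor * 10 * np.eye(3)
            continue
        pi[k] = wk.sum() / W
        means[k] = np.average(points[sel], weights=wk, axis=0)
        d = points[sel] - means[k]
        covs[k] = _floor_cov((d.T * wk) @ d / wk.sum(), floor)
    pi = pi / pi.sum()
    return pi, means, covs


def _cov_floor_for(dmap: DensityMap) -> float:
    return float((dmap.voxel_size.min() / 2.0) ** 2)


def fit_gmm_em(
    dmap: DensityMap,
    K: int,
    config: FitConfig | None = None,
    init: GaussianMixture | None = None,
    return_info: bool = False,
):
    """Fit a normalized K-component GMM to a map by weighted EM.

    The weighted log-likelihood over voxel centres is non-decreasing across
    iterations (up to the covariance floor of (voxel/2)^2 per axis).
    """
    config = config or FitConfig(budget=K)
    pts, w = map_points(dmap)
    if K > len(pts):
        raise ValueError(
            f"K = {K} exceeds the {len(pts)} positive-density voxels"
        )
    floor = _cov_floor_for(dmap)
    init_arrays = None
    if init is not None:
        init_arrays = (init.weights / init.weights.sum(), init.means, init.covs)
    pi, means, covs, _, ll_trace = _weighted_em(
        pts, w, K, config.seed, config.tol, config.max_iter, floor, init_arrays
    )
    gmm = GaussianMixture(pi, means, covs, normalized=True, label="data-GMM")
    if return_info:
        return gmm, {"log_likelihood": ll_trace, "n_iter": len(ll_trace)}
    return gmm


def divide_and_conquer_fit(
    dmap: DensityMap,
    config: FitConfig,
    return_report: bool = False,
):
    """Hierarchical divide-and-conquer fit (see module docstring).

    Returns a single flat normalized :class:`GaussianMixture`; with
    ``return_report=True`` also a dict of per-level statistics.
    """
    pts, w = map_points(dmap)
    floor = _cov_floor_for(dmap)
    budget = config.budget if config.budget is not None else np.inf
    ss = np.random.SeedSequence(config.seed)

    def next_seed() -> int:
        return int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))

    k_root = int(min(config.k0, budget, len(pts)))
    pi, means, covs, resp, ll = _weighted_em(
        pts, w, k_root, next_seed(), config.tol, config.max_iter, floor
    )
    labels = np.argmax(resp, axis=0)
    # each leaf: (mass fraction, point indices, mean, cov)
    leaves = [
        {"mass": pi[k], "idx": np.nonzero(labels == k)[0],
         "mean": means[k], "cov": covs[k]}
        for k in range(len(pi))
    ]
    report = {"levels": [{"n_comp": len(leaves), "root_ll": ll[-1]}]}

    def assemble() -> GaussianMixture:
        masses = np.array([lf["mass"] for lf in leaves])
        return GaussianMixture(
            masses / masses.sum(),
            np.array([lf["mean"] for lf in leaves]),
            np.array([lf["cov"] for lf in leaves]),
            normalized=True,
            label="data-GMM",
        )

    def current_cc() -> float:
        return global_cc(rasterize(assemble(), dmap), dmap)

    while True:
        if config.target_cc is not None:
            cc = current_cc()
            report["levels"][-1]["cc"] = cc
            if cc >= config.target_cc:
                break
        capacity = budget - len(leaves)
        if capacity < config.branching - 1:
            break
        splittable = sorted(
            (i for i, lf in enumerate(leaves) if len(lf["idx"]) >= 2 * config.branching),
            key=lambda i: -leaves[i]["mass"],
        )
        n_split = min(len(splittable), int(capacity // (config.branching - 1)))
        if n_split == 0:
            break
        chosen = set(splittable[:n_split])
        new_leaves = []
        grew = False
        for i, leaf in enumerate(leaves):
            if i not in chosen:
                new_leaves.append(leaf)
                continue
            idx = leaf["idx"]
            sub_pts, sub_w = pts[idx], w[idx]
            try:
                cpi, cmeans, ccovs, cresp, _ = _weighted_em(
                    sub_pts, sub_w, config.branching, next_seed(),
                    config.tol, config.max_iter, floor,
                )
            except np.linalg.LinAlgError:
                warnings.warn("sub-fit failed; keeping parent component",
                              stacklevel=2)
                new_leaves.append(leaf)
                continue
            if len(cpi) < 2:
                new_leaves.append(leaf)
                continue
            clabels = np.argmax(cresp, axis=0)
            for k in range(len(cpi)):
                new_leaves.append(
                    {"mass": leaf["mass"] * cpi[k],
                     "idx": idx[clabels == k],
                     "mean": cmeans[k], "cov": ccovs[k]}
                )
            grew = True
        leaves = new_leaves
        report["levels"].append({"n_comp": len(leaves)})
        if not grew:
            break

    gmm = assemble()
    # final global refinement: a few EM sweeps over the full mixture remove
    # the hard-partition boundary artifacts of the recursion
    if config.polish_iters > 0 and len(gmm) > 1:
        pi, means, covs, _, pll = _weighted_em(
            pts, w, len(gmm), next_seed(), config.tol, config.polish_iters,
            floor, init=(gmm.weights, gmm.means, gmm.covs),
        )
        gmm = GaussianMixture(
            pi / pi.sum(), means, covs, normalized=True, label="data-GMM"
        )
        report["polish_ll"] = pll[-1] if pll else None
    report["n_components"] = len(gmm)
    report["cc"] = global_cc(rasterize(gmm, dmap), dmap)
    if return_report:
        return gmm, report
    return gmm
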