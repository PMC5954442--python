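"""Bayesian scoring of replica-averaged map overlaps.

The deviation Delta_i = ovDD_i - ovbar_MD,i between each data-GMM component's
self-overlap and the replica-averaged model overlap is scored with a Gaussian
noise model carrying two uncertainty sources: sigma_SEM (statistical error of
the finite-replica average, set to alpha * ovDD_i) and sigma_B (unknown
noise in the data point).  Marginalizing sigma_B under a Jeffreys prior on
the total sigma over [sigma_SEM, inf) gives the closed-form score

    E = -kBT sum_i log[ (1/(2 Delta_i)) erf(Delta_i / (sqrt(2) sigma_SEM,i)) ],

which is even in Delta_i, harmonic near Delta = 0 and logarithmic for large
|Delta| (outliers are automatically down-weighted).  The module provides the
score, its gradients with respect to particle positions, a Gibbs sampler for
the non-marginalized noise parameters, and the a posteriori noise estimator
used to build error density maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .gmm import DensityMap, GaussianMixture, rasterize
from .forward import NeighborList, OverlapCalculator

__all__ = [
    "KB",
    "MetaInfParams",
    "NoiseEstimate",
    "StaleNeighborListError",
    "sigma_sem",
    "gaussian_likelihood",
    "marginal_score",
    "score_terms",
    "score_gradient",
    "gibbs_sample_sigma",
    "estimate_noise_posterior",
    "error_density_map",
]

KB = 0.008314462618  # kJ/mol/K

# below |Delta| / (sqrt(2) sigma) = X_SERIES the erf(x)/x ratio is evaluated
# by its Maclaurin expansion to avoid 0/0
X_SERIES = 1e-4

_SQRT_2PI = np.sqrt(2.0 * np.pi)


class StaleNeighborListError(RuntimeError):
    """Neighbor list is older than its declared update frequency."""


@dataclass
class MetaInfParams:
    """Parameters of the metainference restraint.

    alpha scales the per-component statistical error, sigma_SEM,i =
    alpha * ovDD_i; 0.01 gives the strongest admissible restraint for
    noise-free synthetic maps, 0.1 suits noisy experimental maps.  The
    restraint is recomputed every ``stride`` integration steps.
    """

    alpha: float = 0.1
    temperature: float = 300.0
    marginalized: bool = True
    stride: int = 2
    gibbs_width: float = 0.5  # log-space random-walk width, non-marginalized path

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def kbt(self) -> float:
        return KB * self.temperature


def sigma_sem(ovdd: np.ndarray, alpha: float) -> np.ndarray:
    """Per-component statistical error sigma_SEM,i = alpha * ovDD_i."""
    if alpha < 1e-6:
        raise ValueError(
            f"alpha = {alpha:g} < 1e-6: the restraint becomes singular as "
            "alpha -> 0; use a larger scale"
        )
    ovdd = np.asarray(ovdd, float)
    if np.any(ovdd <= 0):
        raise ValueError("every ovDD entry must be > 0")
    return alpha * ovdd


def gaussian_likelihood(
    ovdd_i: float, ovmd_bar_i: float, sigma_b: float, sigma_sem_i: float
) -> float:
    """Gaussian data likelihood with variance sigma_B^2 + sigma_SEM^2."""
    if sigma_b < 0:
        raise ValueError("sigma_b must be >= 0")
    if sigma_sem_i <= 0:
        raise ValueError("sigma_sem must be > 0")
    var = sigma_b**2 + sigma_sem_i**2
    delta = ovdd_i - ovmd_bar_i
    return float(np.exp(-0.5 * delta**2 / var) / (_SQRT_2PI * np.sqrt(var)))


def _log_erf_ratio(delta: np.ndarray, sig: np.ndarray):
    """log[(1/(2 Delta)) erf(Delta/(sqrt2 sig))] and its d/dDelta, stable at 0."""
    delta = np.asarray(delta, float)
    sig = np.broadcast_to(np.asarray(sig, float), delta.shape)
    x = delta / (np.sqrt(2.0) * sig)
    small = np.abs(x) < X_SERIES
    logf = np.empty_like(x)
    dlogf = np.empty_like(x)

    xs = x[small]
    # erf(x)/(2 Delta) = (1/(sqrt(2 pi) sig)) * (1 - x^2/3 + x^4/10 - ...)
    logf[small] = -np.log(_SQRT_2PI * sig[small]) + np.log1p(
        -(xs**2) / 3.0 + xs**4 / 10.0
    )
    dlogf[small] = (-2.0 * xs / 3.0 + 8.0 * xs**3 / 45.0) / (np.sqrt(2.0) * sig[small])

    xl = x[~small]
    dl = delta[~small]
    e = erf(xl)  # same sign as delta, so e/dl > 0
    logf[~small] = np.log(np.abs(e)) - np.log(2.0 * np.abs(dl))
    dlogf[~small] = (
        (2.0 / np.sqrt(np.pi)) * np.exp(-(xl**2)) / (np.sqrt(2.0) * sig[~small] * e)
        - 1.0 / dl
    )
    return logf, dlogf


def score_terms(
    ovdd: np.ndarray, ovmd_bar: np.ndarray, sig_sem: np.ndarray, kbt: float
):
    """Per-component energies and dE/dDelta for the marginalized score."""
    sig_sem = np.asarray(sig_sem, float)
    if np.any(sig_sem <= 0):
        raise ValueError("sigma_sem must be > 0")
    delta = np.asarray(ovdd, float) - np.asarray(ovmd_bar, float)
    logf, dlogf = _log_erf_ratio(delta, sig_sem)
    return -kbt * logf, -kbt * dlogf


def marginal_score(
    ovdd: np.ndarray,
    ovmd_bar: np.ndarray,
    sig_sem: np.ndarray,
    kbt: float,
    per_component: bool = False,
):
    """Marginalized metainference energy (kJ/mol); see module docstring.

    Finite for every Delta including 0, where the likelihood tends to
    1/(sqrt(2 pi) sigma_SEM,i); only energy differences are meaningful.
    """
    energies, _ = score_terms(ovdd, ovmd_bar, sig_sem, kbt)
    return energies if per_component else float(energies.sum())


def score_gradient(
    coords: np.ndarray,
    calc: OverlapCalculator,
    nl: NeighborList,
    ovdd: np.ndarray,
    sig_sem: np.ndarray,
    kbt: float,
    step: int | None = None,
):
    """Score and per-particle forces for a replica ensemble.

    ``coords`` is (R, n, 3).  Returns ``(energy, forces (R, n, 3),
    ov (R, K))``.  Forces are -dE/dx with the replica average handled by the
    chain rule: d ovbar_i / dx_k^r = (1/N) d ov_i^r / dx_k.  Refuses a
    neighbor list older than its update frequency.
    """
    if step is not None and nl.stale(step):
        raise StaleNeighborListError(
            f"neighbor list built at step {nl.build_step} is stale at step {step}"
        )
    coords = np.asarray(coords, float)
    if coords.ndim == 2:
        coords = coords[None]
    ov, cache = calc.replica_overlaps(coords, nl)
    energies, dEdD = score_terms(ovdd, ov.mean(axis=0), sig_sem, kbt)
    forces = calc.forces_from_dEdD(dEdD, nl, cache, len(coords))
    return float(energies.sum()), forces, ov


# ---------------------------------------------------------------------------
# noise inference
# ---------------------------------------------------------------------------

@dataclass
class NoiseEstimate:
    """Per-component posterior noise summaries.

    ``sigma_b[i]`` is the posterior median of the noise parameter of data
    component i; ``rel_err[i] = sigma_b[i] / ovDD_i`` is the relative error
    visualized on error density maps.
    """

    sigma_b: np.ndarray
    rel_err: np.ndarray
    n_frames: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sigma_b = np.asarray(self.sigma_b, float)
        self.rel_err = np.asarray(self.rel_err, float)
        if np.any(self.sigma_b < 0):
            raise ValueError("sigma_b must be >= 0")

    def write_tsv(self, path) -> None:
        lines = ["component\tsigma_b\trel_err"]
        for i, (s, r) in enumerate(zip(self.sigma_b, self.rel_err)):
            lines.append(f"{i}\t{s:.6e}\t{r:.6e}")
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


def _log_likelihood_on_grid(
    deltas: np.ndarray, sigma_sem_i: float, sigma_grid: np.ndarray
) -> np.ndarray:
    """Sum over frames of the Gaussian log likelihood at each sigma_B."""
    var = sigma_grid[:, None] ** 2 + sigma_sem_i**2
    ll = -0.5 * np.log(2.0 * np.pi * var) - deltas[None, :] ** 2 / (2.0 * var)
    return ll.sum(axis=1)


def gibbs_sample_sigma(
    deltas,
    sigma_sem_i: float,
    bounds: tuple[float, float],
    n_steps: int = 10000,
    width: float = 0.5,
    seed: int = 0,
):
    """Metropolis-within-Gibbs chain for sigma_B given observed deviations.

    Targets p(sigma_B | Delta) proportional to the Jeffreys prior 1/sigma_B
    (on the bounded support ``bounds``) times the Gaussian likelihood of the
    ``deltas``.  Random walk in log sigma_B of the given ``width``.  Returns
    ``(chain, acceptance_rate)``.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must satisfy 0 < lo < hi")
    deltas = np.atleast_1d(np.asarray(deltas, float))
    rng = np.random.default_rng(seed)
    sum_d2 = float(np.sum(deltas**2))
    n = len(deltas)

    # In y = log sigma the Jeffreys prior 1/sigma cancels the Jacobian
    # d sigma = sigma dy, so the target in y is the bare likelihood.
    def logtarget(y: float) -> float:
        var = np.exp(2.0 * y) + sigma_sem_i**2
        return float(-0.5 * n * np.log(2.0 * np.pi * var) - sum_d2 / (2.0 * var))

    y = float(np.log(np.sqrt(lo * hi)))
    lt = logtarget(y)
    chain = np.empty(n_steps)
    accepted = 0
    for t in range(n_steps):
        prop = y + width * rng.standard_normal()
        if lo <= np.exp(prop) <= hi:
            lt_prop = logtarget(prop)
            if np.log(rng.random()) < lt_prop - lt:
                y, lt = prop, lt_prop
                accepted += 1
        chain[t] = np.exp(y)
    return chain, accepted / n_steps


def estimate_noise_posterior(
    ov_traj: np.ndarray,
    ovdd: np.ndarray,
    sig_sem: np.ndarray,
    min_frames: int = 100,
    n_grid: int = 400,
) -> NoiseEstimate:
    """A posteriori per-component noise from an ensemble trajectory.

    ``ov_traj`` is (T, K): the replica-averaged overlap of each data
    component over T saved frames.  For each component the posterior
    p(sigma_B | {Delta_t}) under the Gaussian likelihood and a Jeffreys prior
    on sigma_B (support [1e-6, 1e3] * ovDD_i) is integrated on a log grid and
    summarized by its median.
    """
    ov_traj = np.asarray(ov_traj, float)
    if ov_traj.ndim != 2:
        raise ValueError("ov_traj must be (frames, components)")
    T, K = ov_traj.shape
    if T < min_frames:
        raise ValueError(
            f"noise estimation needs >= {min_frames} frames, got {T}"
        )
    ovdd = np.asarray(ovdd, float)
    sig_sem = np.asarray(sig_sem, float)
    sigma_b = np.empty(K)
    for i in range(K):
        deltas = ovdd[i] - ov_traj[:, i]
        grid = np.geomspace(1e-6 * ovdd[i], 1e3 * ovdd[i], n_grid)
        ll = _log_likelihood_on_grid(deltas, sig_sem[i], grid)
        # Jeffreys prior 1/sigma on a log grid: constant measure
        logp = ll - ll.max()
        mass = np.exp(logp)
        cdf = np.cumsum(mass)
        cdf /= cdf[-1]
        sigma_b[i] = float(np.interp(0.5, cdf, grid))
    return NoiseEstimate(
        sigma_b=sigma_b,
        rel_err=sigma_b / ovdd,
        n_frames=T,
        meta={"estimator": "posterior median, Jeffreys prior", "n_grid": n_grid},
    )


def error_density_map(
    noise: NoiseEstimate, data: GaussianMixture, template: DensityMap
) -> DensityMap:
    """Density-weighted relative-error map.

    Voxel value = sum_i phi_D,i(x) rel_err_i / sum_i phi_D,i(x); voxels with
    total density below 1e-12 are set to 0.
    """
    if len(noise.sigma_b) != len(data):
        raise ValueError("noise estimate / data-GMM component count mismatch")
    num = np.zeros(template.dims)
    den = np.zeros(template.dims)
    for i in range(len(data)):
        single = GaussianMixture(
            data.weights[i : i + 1], data.means[i : i + 1], data.covs[i : i + 1]
        )
        phi = rasterize(single, template).values
        num += phi * noise.rel_err[i]
        den += phi
    out = np.where(den >= 1e-12, num / np.where(den > 0, den, 1.0), 0.0)
    return template.like(out)
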