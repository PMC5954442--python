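import numpy as np
import pytest

from cryometa.gmm import DensityMap, GaussianComponent, GaussianMixture


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_component(rng, aniso: float = 0.08, base_var: float = 0.01):
    """Random anisotropic Gaussian component with SPD covariance."""
    a = rng.standard_normal((3, 3)) * aniso
    cov = a @ a.T + base_var * np.eye(3)
    return GaussianComponent(
        weight=float(rng.uniform(0.5, 2.0)),
        mean=rng.uniform(-0.15, 0.15, 3),
        cov=cov,
    )


def quadrature_overlap(a: GaussianComponent, b: GaussianComponent, n: int = 81):
    """Brute-force overlap integral on a fine grid spanning +/- 6 sigma."""
    spread = 6.0 * max(
        np.sqrt(np.linalg.eigvalsh(a.cov)[-1]), np.sqrt(np.linalg.eigvalsh(b.cov)[-1])
    )
    lo = np.minimum(a.mean, b.mean) - spread
    hi = np.maximum(a.mean, b.mean) + spread
    axes = [np.linspace(lo[i], hi[i], n) for i in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    ga = GaussianMixture(np.array([a.weight]), a.mean[None], a.cov[None]).evaluate(pts)
    gb = GaussianMixture(np.array([b.weight]), b.mean[None], b.cov[None]).evaluate(pts)
    vol = np.prod([(hi[i] - lo[i]) / (n - 1) for i in range(3)])
    return float((ga * gb).sum() * vol)


@pytest.fixture
def small_template():
    return DensityMap.empty((40, 40, 40), 0.05, (-1.0, -1.0, -1.0))
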