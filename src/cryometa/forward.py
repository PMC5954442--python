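"""Forward model: predict a model GMM from particle coordinates.

Each heavy atom is represented by a single isotropic Gaussian whose weight
and variance come from a one-Gaussian least-squares fit of the tabulated
five-Gaussian electron atomic scattering factors over spatial frequency
0-0.5 A^-1.  Coarse-grained beads get one Gaussian each, with width
proportional to the bead size.  The module also provides the neighbor-listed
overlap machinery between the (per-replica) model GMM and a data-GMM.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from .gmm import GaussianMixture, OverlapVector, _TWO_PI_POW_3_2

__all__ = [
    "AtomicModel",
    "ScatteringTable",
    "NeighborList",
    "OverlapCalculator",
    "model_gmm",
    "build_neighbor_list",
    "replica_averaged_overlaps",
    "fit_single_gaussian_factors",
    "PENG_SCATTERING_FACTORS",
    "BEAD_SIGMA_PER_SIZE",
]

# Five-Gaussian parameterization of electron atomic scattering factors
# f(s) = sum_i a_i exp(-b_i s^2), s in A^-1 (Peng-style neutral-atom table).
# a_i dimensionless, b_i in A^2.
PENG_SCATTERING_FACTORS: dict[str, tuple[list[float], list[float]]] = {
    "H": ([0.0349, 0.1201, 0.1970, 0.0573, 0.1195],
          [0.5347, 3.5867, 12.3471, 18.9525, 38.6269]),
    "C": ([0.0893, 0.2563, 0.7570, 1.0487, 0.3575],
          [0.2465, 1.7100, 6.4094, 18.6113, 50.2523]),
    "N": ([0.1022, 0.3219, 0.7982, 0.8197, 0.1715],
          [0.2451, 1.7481, 6.1925, 17.3894, 48.1431]),
    "O": ([0.0974, 0.2921, 0.6910, 0.6990, 0.2039],
          [0.2067, 1.3815, 4.6943, 12.7105, 32.4726]),
    "P": ([0.2548, 0.6106, 1.4541, 2.3204, 0.8477],
          [0.2908, 1.8740, 8.5176, 24.3434, 63.2996]),
    "S": ([0.2497, 0.5628, 1.3899, 2.1865, 0.7715],
          [0.2681, 1.6711, 7.0267, 19.5377, 50.3888]),
}

# Proportionality between bead "size" (nm) and the Gaussian sigma (nm) of a
# coarse-grained bead component.
BEAD_SIGMA_PER_SIZE = 1.0


def fit_single_gaussian_factors(
    s_max: float = 0.5, n_points: int = 101
) -> dict[str, tuple[float, float]]:
    """Least-squares one-Gaussian fit of the scattering factors per element.

    Fits A*exp(-B s^2) to the five-Gaussian form factor on a uniform grid of
    spatial frequencies [0, s_max] A^-1 and converts to a real-space Gaussian:
    with the convention f(s) = w exp(-2 pi^2 sigma^2 s^2), the component
    weight is A and the variance is sigma^2 = B / (2 pi^2), returned in nm^2.
    """
    from scipy.optimize import curve_fit

    s = np.linspace(0.0, s_max, n_points)
    out: dict[str, tuple[float, float]] = {}
    for el, (a, b) in PENG_SCATTERING_FACTORS.items():
        f = np.sum([ai * np.exp(-bi * s**2) for ai, bi in zip(a, b)], axis=0)
        p0 = (f[0], float(np.average(b, weights=a)))
        (amp, width), _ = curve_fit(
            lambda x, amp, width: amp * np.exp(-width * x**2), s, f, p0=p0
        )
        var_a2 = width / (2.0 * np.pi**2)
        out[el] = (float(amp), float(var_a2) * 0.01)  # A^2 -> nm^2
    return out


def _packaged_table() -> dict[str, tuple[float, float]]:
    text = (
        importlib.resources.files("cryometa")
        .joinpath("data/scattering_single_gaussian.tsv")
        .read_text()
    )
    table: dict[str, tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        el, w, v = line.split()
        table[el] = (float(w), float(v))
    return table


@dataclass
class AtomicModel:
    """Particle model: positions (n, 3) in nm plus species labels.

    Species are element symbols ("C", "N", ...) for atomistic models or bead
    type names registered on a :class:`ScatteringTable` for coarse-grained
    models.
    """

    positions: np.ndarray
    species: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if len(self.species) != len(self.positions):
            raise ValueError("species/positions length mismatch")

    def __len__(self) -> int:
        return len(self.positions)

    def with_positions(self, positions: np.ndarray) -> "AtomicModel":
        return AtomicModel(positions, list(self.species))


class ScatteringTable:
    """Per-species single-Gaussian parameters (weight, variance nm^2).

    Element entries come from the packaged scattering-factor fit; bead types
    are registered with :meth:`add_bead`.
    """

    def __init__(self, entries: dict[str, tuple[float, float]] | None = None) -> None:
        self.entries = dict(_packaged_table() if entries is None else entries)
        for sp, (w, v) in self.entries.items():
            if v <= 0 or w <= 0:
                raise ValueError(f"non-positive parameters for species {sp!r}")

    def add_bead(self, name: str, size: float, weight: float = 1.0) -> "ScatteringTable":
        """Register a coarse-grained bead type; sigma = BEAD_SIGMA_PER_SIZE * size."""
        if size <= 0 or weight <= 0:
            raise ValueError("bead size and weight must be > 0")
        sigma = BEAD_SIGMA_PER_SIZE * size
        self.entries[name] = (float(weight), float(sigma**2))
        return self

    @staticmethod
    def beads_only(size: float, weight: float = 1.0, name: str = "BEAD") -> "ScatteringTable":
        return ScatteringTable(entries={}).add_bead(name, size, weight)

    def resolve(self, species: str) -> tuple[float, float]:
        try:
            return self.entries[species]
        except KeyError:
            raise LookupError(
                f"species {species!r} has no scattering-table entry "
                f"(known: {sorted(self.entries)})"
            ) from None

    def resolve_model(self, model: AtomicModel) -> tuple[np.ndarray, np.ndarray]:
        """Per-particle (weights, variances) arrays for a model."""
        wv = np.array([self.resolve(sp) for sp in model.species])
        return wv[:, 0], wv[:, 1]


def model_gmm(model: AtomicModel, table: ScatteringTable) -> GaussianMixture:
    """One isotropic Gaussian per particle; unnormalized (mass is physical)."""
    w, v = table.resolve_model(model)
    covs = v[:, None, None] * np.eye(3)[None]
    return GaussianMixture(w, model.positions.copy(), covs, normalized=False,
                           label="forward model")


# ---------------------------------------------------------------------------
# neighbor-listed overlaps
# ---------------------------------------------------------------------------

@dataclass
class NeighborList:
    """Retained (data component, particle) pairs for overlap evaluation.

    A pair survives when its Gaussian exponent factor
    exp(-1/2 d^T (Sigma_m + Sigma_D,i)^-1 d) is at least ``cutoff`` at build
    time.  ``build_step`` records when it was built; it must be rebuilt every
    ``update_every`` integration steps.
    """

    comp_idx: np.ndarray
    part_idx: np.ndarray
    n_comp: int
    n_part: int
    cutoff: float
    build_step: int = 0
    update_every: int = 100

    def __post_init__(self) -> None:
        self.comp_idx = np.asarray(self.comp_idx, dtype=np.intp)
        self.part_idx = np.asarray(self.part_idx, dtype=np.intp)
        if self.comp_idx.shape != self.part_idx.shape:
            raise ValueError("comp_idx/part_idx shape mismatch")
        if len(self.comp_idx) and (
            self.comp_idx.max() >= self.n_comp or self.part_idx.max() >= self.n_part
        ):
            raise ValueError("neighbor-list index out of range")

    def __len__(self) -> int:
        return len(self.comp_idx)

    def stale(self, step: int) -> bool:
        return step - self.build_step > self.update_every

    @staticmethod
    def dense(n_comp: int, n_part: int) -> "NeighborList":
        ci, pi = np.meshgrid(np.arange(n_comp), np.arange(n_part), indexing="ij")
        return NeighborList(ci.ravel(), pi.ravel(), n_comp, n_part,
                            cutoff=0.0, update_every=np.iinfo(np.int64).max)


class OverlapCalculator:
    """Precomputed kernels for model/data overlaps and their gradients.

    For isotropic model components the summed covariance S_i(v) =
    Sigma_D,i + v*I depends only on the data component i and the particle
    variance v; inverses and normalization prefactors are precomputed per
    (variance group, component).
    """

    def __init__(
        self,
        data: GaussianMixture,
        particle_weights: np.ndarray,
        particle_vars: np.ndarray,
    ) -> None:
        self.data = data
        self.pw = np.asarray(particle_weights, float)
        self.pv = np.asarray(particle_vars, float)
        if self.pw.shape != self.pv.shape:
            raise ValueError("particle weight/variance shape mismatch")
        uniq, group = np.unique(np.round(self.pv, 12), return_inverse=True)
        self.group = group
        K = len(data)
        G = len(uniq)
        self.inv = np.empty((G, K, 3, 3))
        self.pref = np.empty((G, K))
        eye = np.eye(3)
        for g, v in enumerate(uniq):
            s = data.covs + v * eye
            self.inv[g] = np.linalg.inv(s)
            det = np.linalg.det(s)
            self.pref[g] = data.weights / (_TWO_PI_POW_3_2 * np.sqrt(det))

    @property
    def n_comp(self) -> int:
        return len(self.data)

    @property
    def n_part(self) -> int:
        return len(self.pw)

    def build_neighbor_list(
        self,
        coords: np.ndarray,
        cutoff: float = 0.01,
        step: int = 0,
        update_every: int = 100,
    ) -> NeighborList:
        """Pairs whose exponent factor passes ``cutoff`` in ANY replica.

        ``coords`` is (R, n, 3) or (n, 3).
        """
        if not 0.0 < cutoff < 1.0:
            raise ValueError("cutoff must be in (0, 1)")
        coords = np.asarray(coords, float)
        if coords.ndim == 2:
            coords = coords[None]
        qmax = -2.0 * np.log(cutoff)
        keep = np.zeros((self.n_comp, self.n_part), dtype=bool)
        for x in coords:
            d = x[None, :, :] - self.data.means[:, None, :]      # (K, n, 3)
            inv = self.inv[self.group]                            # (n, K, 3, 3)
            q = np.einsum("kni,nkij,knj->kn", d, inv, d)
            keep |= q <= qmax
        ci, pi = np.nonzero(keep)
        return NeighborList(ci, pi, self.n_comp, self.n_part, cutoff,
                            build_step=step, update_every=update_every)

    def replica_overlaps(self, coords: np.ndarray, nl: NeighborList | None = None):
        """ov_MD per replica over the neighbor list.

        Returns ``(ov (R, K), cache)`` where cache holds per-replica pair
        overlaps and S^-1 d vectors for gradient evaluation.
        """
        coords = np.asarray(coords, float)
        if coords.ndim == 2:
            coords = coords[None]
        if nl is None:
            nl = NeighborList.dense(self.n_comp, self.n_part)
        ci, pi = nl.comp_idx, nl.part_idx
        kern = getattr(nl, "_kernels", None)
        if kern is None or kern[0] is not self:
            g = self.group[pi]
            kern = (
                self,
                self.inv[g, ci],                 # (P, 3, 3)
                self.pref[g, ci] * self.pw[pi],  # (P,)
                self.data.means[ci],
            )
            nl._kernels = kern  # type: ignore[attr-defined]
        _, inv, pref, mu = kern
        R = len(coords)
        d = coords[:, pi, :] - mu[None]                          # (R, P, 3)
        sinv_d = np.einsum("pij,rpj->rpi", inv, d)
        q = np.einsum("rpi,rpi->rp", d, sinv_d)
        ov_pairs = pref[None] * np.exp(-0.5 * q)                 # (R, P)
        ov = np.stack(
            [np.bincount(ci, weights=ov_pairs[r], minlength=self.n_comp)
             for r in range(R)]
        )
        cache = [(ov_pairs[r], sinv_d[r]) for r in range(R)]
        return ov, cache

    def forces_from_dEdD(
        self, dEdD: np.ndarray, nl: NeighborList, cache, n_replicas: int
    ) -> np.ndarray:
        """Forces -dE/dx given dE/dDelta_i, with Delta_i = ovDD_i - ovbar_i.

        d ovbar_i / dx_k^r = (1/N) d ov_i^r / dx_k and
        d ov_pair / dx_k = -ov_pair * S^-1 d, so
        F_k^r = -sum_i dEdD_i * (ov_pair/N) * (S^-1 d)_pair.
        """
        ci, pi = nl.comp_idx, nl.part_idx
        R = len(cache)
        forces = np.empty((R, self.n_part, 3))
        for r, (ov_pairs, sinv_d) in enumerate(cache):
            coef = -dEdD[ci] * ov_pairs / n_replicas
            contrib = coef[:, None] * sinv_d
            for a in range(3):
                forces[r, :, a] = np.bincount(
                    pi, weights=contrib[:, a], minlength=self.n_part
                )
        return forces


def build_neighbor_list(
    models,
    data: GaussianMixture,
    table: ScatteringTable,
    cutoff: float = 0.01,
    step: int = 0,
    update_every: int = 100,
) -> NeighborList:
    """Convenience wrapper: neighbor list from per-replica AtomicModels."""
    models = models if isinstance(models, (list, tuple)) else [models]
    pw, pv = table.resolve_model(models[0])
    calc = OverlapCalculator(data, pw, pv)
    coords = np.stack([m.positions for m in models])
    return calc.build_neighbor_list(coords, cutoff, step, update_every)


def replica_averaged_overlaps(
    models,
    data: GaussianMixture,
    table: ScatteringTable,
    nl: NeighborList | None = None,
) -> OverlapVector:
    """Replica-averaged overlaps ovbar_MD,i = (1/N) sum_r ov_MD,i^r."""
    models = models if isinstance(models, (list, tuple)) else [models]
    n0 = len(models[0])
    if any(len(m) != n0 or m.species != models[0].species for m in models):
        raise ValueError("replica topologies differ")
    pw, pv = table.resolve_model(models[0])
    calc = OverlapCalculator(data, pw, pv)
    coords = np.stack([m.positions for m in models])
    ov, _ = calc.replica_overlaps(coords, nl)
    return OverlapVector(ovMD_bar=ov.mean(axis=0), ovMD=ov)
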