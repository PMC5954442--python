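"""Multi-replica sampling of the metainference posterior.

The prior is a pluggable potential-energy surface over particle coordinates
(:class:`PriorPotential`); the packaged :class:`HingeChainPrior` is a bead
chain with two metastable conformations separated by a double-well hinge
angle, the desk-scale stand-in for a molecular-mechanics force field.
Replicas evolve in lockstep under overdamped Langevin dynamics; the
metainference restraint couples them through the replica-averaged overlaps
and is recomputed every ``stride`` steps (multiple-time-step scheme, the
restraint impulse scaled by the stride).  Optional well-tempered
metadynamics on a pluggable collective variable (the per-replica restraint
energy by default) accelerates hopping between conformations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .forward import AtomicModel, OverlapCalculator, ScatteringTable
from .gmm import GaussianMixture, self_overlaps
from .scoring import KB, MetaInfParams, score_gradient, score_terms, sigma_sem

__all__ = [
    "PriorPotential",
    "HingeChainPrior",
    "ReplicaEnsemble",
    "MetadynamicsBias",
    "LangevinConfig",
    "Trajectory",
    "hinge_chain_prior",
    "wt_metadynamics_update",
    "run_metainference",
]


@runtime_checkable
class PriorPotential(Protocol):
    """Energy/gradient contract for prior potentials (coordinates in nm)."""

    def energy(self, coords: np.ndarray) -> float: ...

    def forces(self, coords: np.ndarray) -> np.ndarray: ...


class HingeChainPrior:
    """Bead chain with harmonic bonds/angles and a double-well hinge.

    All bond lengths are restrained to ``bond_length`` and all interior
    angles to pi (straight arms), except the angle at the ``hinge`` bead
    which feels the quartic double well

        U(theta) = barrier * 16 (theta-theta_open)^2 (theta-theta_closed)^2
                   / (theta_open - theta_closed)^4,

    with minima at exactly ``theta_open`` and ``theta_closed`` and the
    stated ``barrier`` (kJ/mol) at the midpoint.  The two minimum-energy
    conformations ("open"/"closed") are planar chains with straight arms.
    The default wells sit symmetrically about pi/2, where the sin(theta)
    volume element of the angle coordinate is itself symmetric, so equal
    wells give equal equilibrium populations.
    """

    def __init__(
        self,
        n_beads: int = 30,
        bond_length: float = 0.15,
        k_bond: float = 1000.0,
        k_angle: float = 300.0,
        theta_open: float = np.pi / 2 + 0.6,
        theta_closed: float = np.pi / 2 - 0.6,
        barrier: float = 5.0,
        hinge: int | None = None,
    ) -> None:
        if n_beads < 4:
            raise ValueError("n_beads must be >= 4")
        self.n = n_beads
        self.b0 = bond_length
        self.k_bond = k_bond
        self.k_angle = k_angle
        self.theta_open = theta_open
        self.theta_closed = theta_closed
        self.barrier = barrier
        self.hinge = n_beads // 2 if hinge is None else hinge
        if not 1 <= self.hinge <= n_beads - 2:
            raise ValueError("hinge must be an interior bead")
        if barrier <= 0 or abs(theta_open - theta_closed) < 0.05:
            warnings.warn(
                f"hinge parameters give an effectively single well "
                f"(barrier = {max(barrier, 0.0):.3g} kJ/mol)",
                stacklevel=2,
            )

    # -- hinge double well ---------------------------------------------------
    def _hinge_u_du(self, theta):
        a, b = self.theta_open, self.theta_closed
        norm = 16.0 / (a - b) ** 4
        u = self.barrier * norm * (theta - a) ** 2 * (theta - b) ** 2
        du = (
            self.barrier
            * norm
            * 2.0
            * (theta - a)
            * (theta - b)
            * ((theta - b) + (theta - a))
        )
        return u, du

    def energy(self, coords: np.ndarray) -> float:
        e, _ = self.batch_energy_forces(np.asarray(coords, float)[None], want_forces=False)
        return float(e[0])

    def forces(self, coords: np.ndarray) -> np.ndarray:
        _, f = self.batch_energy_forces(np.asarray(coords, float)[None])
        return f[0]

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        e, f = self.batch_energy_forces(np.asarray(coords, float)[None])
        return float(e[0]), f[0]

    def batch_energy_forces(self, x: np.ndarray, want_forces: bool = True):
        """Energies (B,) and forces (B, n, 3) for a batch of conformations."""
        x = np.asarray(x, float)
        if x.ndim != 3 or x.shape[1:] != (self.n, 3):
            raise ValueError(f"expected coordinates (B, {self.n}, 3), got {x.shape}")
        f = np.zeros_like(x) if want_forces else None
        # bonds
        dvec = x[:, 1:] - x[:, :-1]
        r = np.sqrt(np.einsum("bji,bji->bj", dvec, dvec))
        e = self.k_bond * np.sum((r - self.b0) ** 2, axis=1)
        if want_forces:
            coef = (2.0 * self.k_bond * (r - self.b0) / np.maximum(r, 1e-12))[..., None]
            f[:, 1:] -= coef * dvec
            f[:, :-1] += coef * dvec
        # angles over the interior beads j = 1 .. n-2
        u = x[:, :-2] - x[:, 1:-1]
        v = x[:, 2:] - x[:, 1:-1]
        ru = np.sqrt(np.einsum("bji,bji->bj", u, u))
        rv = np.sqrt(np.einsum("bji,bji->bj", v, v))
        nu = u / ru[..., None]
        nv = v / rv[..., None]
        c = np.clip(np.einsum("bji,bji->bj", nu, nv), -1.0, 1.0)
        theta = np.arccos(c)
        uj = self.k_angle * (theta - np.pi) ** 2
        duj = 2.0 * self.k_angle * (theta - np.pi)
        hj = self.hinge - 1  # position of the hinge in the angle arrays
        uj[:, hj], duj[:, hj] = self._hinge_u_du(theta[:, hj])
        e = e + uj.sum(axis=1)
        if want_forces:
            s = np.maximum(np.sqrt(np.maximum(1.0 - c * c, 0.0)), 1e-8)
            dth_du = (c[..., None] * nu - nv) / (ru * s)[..., None]
            dth_dv = (c[..., None] * nv - nu) / (rv * s)[..., None]
            f[:, :-2] -= duj[..., None] * dth_du
            f[:, 2:] -= duj[..., None] * dth_dv
            f[:, 1:-1] += duj[..., None] * (dth_du + dth_dv)
        return e, f

    def hinge_angle(self, coords: np.ndarray) -> float:
        return self.hinge_angle_and_grad(coords)[0]

    def hinge_angle_and_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Hinge angle (rad) and its gradient w.r.t. coordinates.

        Usable as a metadynamics collective variable.
        """
        x = np.asarray(coords, float)
        j = self.hinge
        u = x[j - 1] - x[j]
        v = x[j + 1] - x[j]
        ru = np.linalg.norm(u)
        rv = np.linalg.norm(v)
        nu, nv = u / ru, v / rv
        c = float(np.clip(nu @ nv, -1.0, 1.0))
        theta = float(np.arccos(c))
        grad = np.zeros_like(x)
        s = max(np.sqrt(max(1.0 - c * c, 0.0)), 1e-8)
        dth_du = (c * nu - nv) / (ru * s)
        dth_dv = (c * nv - nu) / (rv * s)
        grad[j - 1] = dth_du
        grad[j + 1] = dth_dv
        grad[j] = -(dth_du + dth_dv)
        return theta, grad

    def arm_angle_and_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Angle between the two arm end-to-end vectors, with gradient.

        Collective counterpart of the local hinge angle: u runs from the
        hinge bead to the first bead, v from the hinge to the last bead.
        Unlike the 3-bead hinge angle it cannot be satisfied by a local
        kink, which makes it the appropriate metadynamics CV for driving
        whole-arm conformational transitions.
        """
        x = np.asarray(coords, float)
        j = self.hinge
        u = x[0] - x[j]
        v = x[-1] - x[j]
        ru = np.linalg.norm(u)
        rv = np.linalg.norm(v)
        nu, nv = u / ru, v / rv
        c = float(np.clip(nu @ nv, -1.0, 1.0))
        theta = float(np.arccos(c))
        grad = np.zeros_like(x)
        s = max(np.sqrt(max(1.0 - c * c, 0.0)), 1e-8)
        dth_du = (c * nu - nv) / (ru * s)
        dth_dv = (c * nv - nu) / (rv * s)
        grad[0] = dth_du
        grad[-1] = dth_dv
        grad[j] = -(dth_du + dth_dv)
        return theta, grad

    def conformer(self, state: str) -> np.ndarray:
        """Minimum-energy planar conformation ('open' or 'closed'), nm."""
        theta = {"open": self.theta_open, "closed": self.theta_closed}[state]
        x = np.zeros((self.n, 3))
        for i in range(self.hinge + 1):
            x[i] = ((i - self.hinge) * self.b0, 0.0, 0.0)
        d = np.array([np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0])
        for i in range(self.hinge + 1, self.n):
            x[i] = d * (i - self.hinge) * self.b0
        return x

    def model(self, state: str = "open", species: str = "BEAD") -> AtomicModel:
        return AtomicModel(self.conformer(state), [species] * self.n)


def hinge_chain_prior(
    n_beads: int = 30,
    hinge_stiffness: float = 300.0,
    theta_open: float = np.pi / 2 + 0.6,
    theta_closed: float = np.pi / 2 - 0.6,
    barrier: float = 5.0,
    bond_length: float = 0.15,
    seed: int = 0,
) -> tuple[HingeChainPrior, AtomicModel, AtomicModel]:
    """Build the toy prior plus its two minimized conformers as bead models."""
    prior = HingeChainPrior(
        n_beads=n_beads,
        bond_length=bond_length,
        k_angle=hinge_stiffness,
        theta_open=theta_open,
        theta_closed=theta_closed,
        barrier=barrier,
    )
    return prior, prior.model("open"), prior.model("closed")


@dataclass
class ReplicaEnsemble:
    """N replica coordinate states sharing one topology."""

    coords: np.ndarray  # (R, n, 3) nm
    model: AtomicModel  # shared topology (species labels)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (len(self.model), 3):
            raise ValueError("coords must be (R, n_particles, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("need at least one replica")

    @property
    def n_replicas(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_model(
        cls, model: AtomicModel, n_replicas: int, jitter: float = 0.0, seed: int = 0
    ) -> "ReplicaEnsemble":
        rng = np.random.default_rng(seed)
        coords = np.repeat(model.positions[None], n_replicas, axis=0)
        if jitter > 0:
            coords = coords + jitter * rng.standard_normal(coords.shape)
        return cls(coords, model)


# ---------------------------------------------------------------------------
# well-tempered metadynamics
# ---------------------------------------------------------------------------

@dataclass
class MetadynamicsBias:
    """Well-tempered metadynamics bias on a scalar collective variable.

    Hills of initial height ``w0`` (kJ/mol) and the given ``width`` (CV
    units) are deposited every ``pace`` steps; each new hill is scaled by
    exp(-V(s)/(kB*deltaT)) with deltaT = (gamma - 1) T, so hill heights
    decay geometrically where the bias accumulates.
    """

    w0: float
    gamma: float
    width: float = 2.0
    pace: int = 500
    temperature: float = 300.0
    _centers: np.ndarray = field(default_factory=lambda: np.empty(64), repr=False)
    _heights: np.ndarray = field(default_factory=lambda: np.empty(64), repr=False)
    n_hills: int = 0

    def __post_init__(self) -> None:
        if self.w0 <= 0:
            raise ValueError("w0 must be > 0")
        if self.gamma <= 1:
            raise ValueError("gamma must be > 1")

    @property
    def kb_delta_t(self) -> float:
        return KB * (self.gamma - 1.0) * self.temperature

    @property
    def centers(self) -> np.ndarray:
        return self._centers[: self.n_hills]

    @property
    def heights(self) -> np.ndarray:
        return self._heights[: self.n_hills]

    def add_hill(self, center: float, height: float) -> None:
        if self.n_hills == len(self._centers):
            self._centers = np.concatenate([self._centers, np.empty_like(self._centers)])
            self._heights = np.concatenate([self._heights, np.empty_like(self._heights)])
        self._centers[self.n_hills] = center
        self._heights[self.n_hills] = height
        self.n_hills += 1

    def energy_and_derivative(self, s: float) -> tuple[float, float]:
        if self.n_hills == 0:
            return 0.0, 0.0
        c = self.centers
        g = self.heights * np.exp(-((s - c) ** 2) / (2.0 * self.width**2))
        return float(g.sum()), float(np.sum(g * (c - s)) / self.width**2)

    def energy(self, s: float) -> float:
        return self.energy_and_derivative(s)[0]

    def denergy(self, s: float) -> float:
        return self.energy_and_derivative(s)[1]


def wt_metadynamics_update(
    bias: MetadynamicsBias, cv: float, step: int
) -> tuple[float, float]:
    """Deposit a hill when due and return (bias energy, dV/ds) at ``cv``."""
    if step % bias.pace == 0:
        h = bias.w0 * np.exp(-bias.energy(cv) / bias.kb_delta_t)
        bias.add_hill(float(cv), float(h))
    return bias.energy_and_derivative(cv)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class LangevinConfig:
    """Overdamped Langevin integration parameters.

    ``diffusion`` (nm^2/ps) sets the bead mobility D; each step displaces
    x by F*D*dt/kBT + sqrt(2 D dt) * xi.  The default D is chosen so the
    toy hinge chain hops between wells on the 10^4-10^5 step scale.
    """

    dt: float = 0.002         # ps
    diffusion: float = 0.01   # nm^2/ps
    save_stride: int = 100
    nl_cutoff: float = 0.01
    nl_update: int = 100
    force_bound: float = 1e6  # kJ/mol/nm
    # per-step cap on the deterministic drift of any particle (nm); the
    # marginalized score is nearly harmonic with curvature ~ (alpha ovDD)^-2
    # near a perfect fit, far stiffer than the overdamped step can resolve,
    # so transient near-fit forces are trust-region limited instead of
    # shrinking the timestep globally
    max_drift: float = 0.02


@dataclass
class Trajectory:
    """Saved metainference frames.

    ``frames`` is (F, R, n, 3); ``ov`` (F, R, K) holds the per-replica
    overlaps of each data component at each saved frame (None for
    prior-only runs); ``restraint_energy`` the marginalized score of the
    replica-averaged overlaps; ``bias_energy`` (F, R) the per-replica
    metadynamics bias.
    """

    frames: np.ndarray
    steps: np.ndarray
    ov: np.ndarray | None = None
    restraint_energy: np.ndarray | None = None
    bias_energy: np.ndarray | None = None
    final_coords: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_replicas(self) -> int:
        return self.frames.shape[1]

    def ov_bar(self) -> np.ndarray:
        """Replica-averaged overlaps per frame, (F, K)."""
        if self.ov is None:
            raise ValueError("prior-only trajectory has no overlaps")
        return self.ov.mean(axis=1)

    def pooled_frames(self, discard_fraction: float = 0.0) -> np.ndarray:
        """Frames pooled over replicas, (F*R, n, 3), frame-major order."""
        frames = self.frames
        if discard_fraction > 0:
            start = int(np.floor(self.n_frames * discard_fraction))
            frames = frames[start:]
        F, R, n, _ = frames.shape
        return frames.reshape(F * R, n, 3)

    def save(self, path) -> None:
        arrays = {"frames": self.frames, "steps": self.steps}
        if self.ov is not None:
            arrays["ov"] = self.ov
        if self.restraint_energy is not None:
            arrays["restraint_energy"] = self.restraint_energy
        if self.bias_energy is not None:
            arrays["bias_energy"] = self.bias_energy
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "Trajectory":
        with np.load(path) as z:
            return cls(
                frames=z["frames"],
                steps=z["steps"],
                ov=z["ov"] if "ov" in z else None,
                restraint_energy=(
                    z["restraint_energy"] if "restraint_energy" in z else None
                ),
                bias_energy=z["bias_energy"] if "bias_energy" in z else None,
            )

    def write_pdb(self, path, species: list[str] | None = None) -> None:
        """Pooled frames as a multi-model PDB of pseudo-atoms (nm -> A)."""
        lines = []
        F, R, n, _ = self.frames.shape
        model_i = 0
        for fi in range(F):
            for r in range(R):
                model_i += 1
                lines.append(f"MODEL     {model_i:4d}")
                for a in range(n):
                    x, y, z = self.frames[fi, r, a] * 10.0
                    el = (species[a] if species else "C")[:2].rjust(2)
                    lines.append(
                        f"ATOM  {a + 1:5d}  CA  GLY A{a + 1:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el}"
                    )
                lines.append("ENDMDL")
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


def run_metainference(
    ensemble: ReplicaEnsemble,
    prior: PriorPotential,
    data: GaussianMixture | None,
    params: MetaInfParams,
    steps: int,
    seed: int,
    table: ScatteringTable | None = None,
    bias: MetadynamicsBias | None = None,
    bias_cv=None,
    bias_until: int | None = None,
    config: LangevinConfig | None = None,
    save_from: int = 0,
) -> Trajectory:
    """Sample the metainference posterior with lockstep replicas.

    With ``data=None`` the restraint is disabled and the replicas sample the
    prior alone (useful for detailed-balance checks).  ``bias_cv`` selects
    the metadynamics collective variable: a callable
    ``coords (n, 3) -> (value, gradient (n, 3))`` evaluated per replica, or
    None for the default CV, the replica's own restraint energy.  All
    replicas deposit into one shared bias (multiple-walker scheme); with
    ``bias_until`` the bias acts only before that step, so a metadynamics
    annealing segment can precede an unbiased production run.  Frames
    are recorded from step ``save_from`` on, so an equilibration segment can
    be excluded from the returned trajectory.  Fully reproducible: all
    randomness flows from per-replica counter-based streams derived from
    ``seed``.
    """
    cfg = config or LangevinConfig()
    coords = ensemble.coords.copy()
    R, n, _ = coords.shape
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(R)]

    calc = nl = None
    ovdd = sig = None
    if data is not None:
        if not data.normalized:
            raise ValueError("data-GMM must be normalized")
        if table is None:
            raise ValueError("a ScatteringTable is required when data is given")
        pw, pv = table.resolve_model(ensemble.model)
        calc = OverlapCalculator(data, pw, pv)
        ovdd = self_overlaps(data)
        sig = sigma_sem(ovdd, params.alpha)
        nl = calc.build_neighbor_list(
            coords, cfg.nl_cutoff, step=0, update_every=cfg.nl_update
        )

    kbt = params.kbt
    noise_scale = np.sqrt(2.0 * cfg.diffusion * cfg.dt)
    mob_dt = cfg.diffusion * cfg.dt / kbt

    frames, saved_steps, ov_hist, e_hist, bias_hist = [], [], [], [], []
    restraint_forces = np.zeros_like(coords)
    e_restraint = 0.0
    ov = None
    bias_energies = np.zeros(R)
    halved = False

    batched_prior = getattr(prior, "batch_energy_forces", None)

    for step in range(steps):
        if batched_prior is not None:
            _, forces = batched_prior(coords)
        else:
            forces = np.stack([prior.forces(coords[r]) for r in range(R)])

        if (calc is not None or bias is not None) and step % params.stride == 0:
            if calc is not None:
                if step - nl.build_step >= cfg.nl_update:
                    nl = calc.build_neighbor_list(
                        coords, cfg.nl_cutoff, step=step, update_every=cfg.nl_update
                    )
                e_restraint, restraint_forces, ov = score_gradient(
                    coords, calc, nl, ovdd, sig, kbt, step=step
                )
            else:
                restraint_forces = np.zeros_like(coords)
            bias_active = bias is not None and (
                bias_until is None or step < bias_until
            )
            if bias_active:
                bias_forces = np.zeros_like(coords)
                for r in range(R):
                    if bias_cv is not None:
                        cv, grad_cv = bias_cv(coords[r])
                    else:
                        if calc is None:
                            raise ValueError(
                                "restraint-energy CV requires a data-GMM; "
                                "pass bias_cv for prior-only metadynamics"
                            )
                        # CV: this replica's own restraint energy (N = 1 score)
                        e_r, dEdD = score_terms(ovdd, ov[r], sig, kbt)
                        cv = float(e_r.sum())
                        _, cache = calc.replica_overlaps(coords[r][None], nl)
                        grad_cv = -calc.forces_from_dEdD(dEdD, nl, cache, 1)[0]
                    v, dv = wt_metadynamics_update(bias, float(cv), step)
                    bias_energies[r] = v
                    bias_forces[r] = -dv * grad_cv
                restraint_forces = restraint_forces + bias_forces
            forces += params.stride * restraint_forces

        fmax = float(np.abs(forces).max())
        if fmax > cfg.force_bound:
            if halved:
                raise RuntimeError(
                    f"force overflow at step {step}: |F|max = {fmax:.3e} "
                    f"kJ/mol/nm after halving; check restraint scale/timestep"
                )
            warnings.warn(
                f"force overflow at step {step} (|F|max = {fmax:.3e}); "
                "halving the step once",
                stacklevel=2,
            )
            halved = True
            eff_dt = 0.5
        else:
            halved = False
            eff_dt = 1.0

        for r in range(R):
            xi = rngs[r].standard_normal((n, 3))
            drift = eff_dt * mob_dt * forces[r]
            norms = np.linalg.norm(drift, axis=1, keepdims=True)
            drift *= np.minimum(1.0, cfg.max_drift / np.maximum(norms, 1e-300))
            coords[r] += drift + np.sqrt(eff_dt) * noise_scale * xi

        if step >= save_from and (step - save_from) % cfg.save_stride == 0:
            frames.append(coords.copy())
            saved_steps.append(step)
            if calc is not None:
                ov_hist.append(ov.copy())
                e_hist.append(e_restraint)
                bias_hist.append(bias_energies.copy())

    return Trajectory(
        frames=np.array(frames),
        steps=np.array(saved_steps),
        ov=np.array(ov_hist) if ov_hist else None,
        restraint_energy=np.array(e_hist) if e_hist else None,
        bias_energy=np.array(bias_hist) if bias_hist else None,
        final_coords=coords.copy(),
    )
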