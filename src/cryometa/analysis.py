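"""Trajectory analysis: clustering, populations, collective variables, free energies.

Conformational states are defined by GROMOS clustering (greedy neighbor
counting under a backbone-RMSD cutoff, 0.35 nm by default); their
populations and split-half errors quantify convergence; distances between
atoms or residue geometric centers serve as collective variables whose
histograms are Boltzmann-inverted into free-energy surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClusterResult",
    "FreeEnergySurface",
    "backbone_rmsd",
    "pairwise_rmsd",
    "gromos_cluster",
    "population_errors",
    "distance_cv",
    "free_energy_surface",
]


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0)


def backbone_rmsd(
    frame_a: np.ndarray, frame_b: np.ndarray, selection: np.ndarray | None = None
) -> float:
    """Least-squares optimal-superposition RMSD (Kabsch), nm.

    Rigid translation and rotation are removed before the deviation is
    computed; the measure is symmetric and zero for congruent frames.
    """
    a = np.asarray(frame_a, float)
    b = np.asarray(frame_b, float)
    if selection is not None:
        sel = np.asarray(selection, int)
        a, b = a[sel], b[sel]
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("frames must be matching (n, 3) arrays")
    n = len(a)
    if n < 3:
        raise ValueError("selection must contain at least 3 points")
    ac, bc = _center(a), _center(b)
    if min(np.linalg.matrix_rank(ac, tol=1e-10), np.linalg.matrix_rank(bc, tol=1e-10)) < 2:
        raise ValueError("degenerate (collinear) selection")
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    msd = (np.sum(ac**2) + np.sum(bc**2) - 2.0 * (s[0] + s[1] + d * s[2])) / n
    return float(np.sqrt(max(msd, 0.0)))


def pairwise_rmsd(
    frames: np.ndarray,
    selection: np.ndarray | None = None,
    block: int = 64,
) -> np.ndarray:
    """All-pairs superposition RMSD matrix, batched over 3x3 SVDs."""
    x = np.asarray(frames, float)
    if selection is not None:
        x = x[:, np.asarray(selection, int)]
    F, n, _ = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    sq = np.einsum("fij,fij->f", xc, xc)
    out = np.zeros((F, F))
    for i0 in range(0, F, block):
        i1 = min(i0 + block, F)
        h = np.einsum("ank,bnl->abkl", xc[i0:i1], xc)
        u, s, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        tr = s[..., 0] + s[..., 1] + d * s[..., 2]
        msd = (sq[i0:i1, None] + sq[None, :] - 2.0 * tr) / n
        out[i0:i1] = np.sqrt(np.maximum(msd, 0.0))
    np.fill_diagonal(out, 0.0)
    return out


@dataclass
class ClusterResult:
    """GROMOS clustering output.

    ``centers[c]`` is the frame index of cluster c's center; ``labels[f]``
    the cluster of frame f; populations are frame fractions and sum to 1.
    """

    centers: np.ndarray
    labels: np.ndarray
    populations: np.ndarray
    cutoff: float
    population_errors: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, int)
        self.labels = np.asarray(self.labels, int)
        self.populations = np.asarray(self.populations, float)
        if abs(self.populations.sum() - 1.0) > 1e-9:
            raise ValueError("populations must sum to 1")
        if np.any(self.labels < 0) or self.labels.max() >= len(self.centers):
            raise ValueError("labels must form a complete partition")

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def members(self, c: int) -> np.ndarray:
        return np.nonzero(self.labels == c)[0]


def gromos_cluster(
    frames: np.ndarray,
    cutoff: float = 0.35,
    selection: np.ndarray | None = None,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterResult:
    """Greedy neighbor-count clustering under an RMSD cutoff (nm).

    Iteratively, the unassigned frame with the most unassigned neighbors
    within the cutoff becomes a cluster center; it and its neighbors are
    assigned and removed; ties go to the lowest frame index.  A precomputed
    ``rmsd_matrix`` may be supplied to avoid recomputation.
    """
    frames = np.asarray(frames, float)
    F = len(frames)
    if F < 1:
        raise ValueError("need at least one frame")
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd(frames, selection)
    adj = rmsd_matrix <= cutoff
    labels = np.full(F, -1, dtype=int)
    centers: list[int] = []
    unassigned = np.ones(F, dtype=bool)
    while unassigned.any():
        counts = (adj & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(adj[center] & unassigned)[0]
        labels[members] = len(centers)
        centers.append(center)
        unassigned[members] = False
    pops = np.bincount(labels, minlength=len(centers)) / F
    return ClusterResult(np.array(centers), labels, pops, cutoff)


def population_errors(
    labels: np.ndarray,
    runs: list[tuple[int, int]] | None = None,
    discard_fraction: float = 0.2,
):
    """Split-half cluster populations and their spread, per run.

    For each run (a ``(start, stop)`` frame range; one run covering all
    frames by default) the initial ``discard_fraction`` of its frames is
    dropped, the remainder is split into first and second half, and each
    cluster's population is the mean over the two halves with the standard
    deviation as its error.  Returns ``(populations, errors)`` of shape
    (n_runs, n_clusters).
    """
    labels = np.asarray(labels, int)
    F = len(labels)
    if runs is None:
        runs = [(0, F)]
    n_clusters = int(labels.max()) + 1
    pops = np.empty((len(runs), n_clusters))
    errs = np.empty((len(runs), n_clusters))
    for ri, (start, stop) in enumerate(runs):
        if not (0 <= start < stop <= F):
            raise ValueError(f"run range ({start}, {stop}) outside trajectory")
        seg = labels[start + int(np.floor((stop - start) * discard_fraction)): stop]
        half = len(seg) // 2
        if half == 0:
            raise ValueError("empty half-trajectory after discard")
        halves = [seg[:half], seg[half: 2 * half]]
        p = np.array(
            [np.bincount(h, minlength=n_clusters) / len(h) for h in halves]
        )
        pops[ri] = p.mean(axis=0)
        errs[ri] = p.std(axis=0)
    return pops, errs


def distance_cv(
    frame: np.ndarray,
    group_a: np.ndarray,
    group_b: np.ndarray,
    mode: str = "geometric-centers",
) -> float:
    """Distance (nm) between two atoms or two unweighted geometric centers."""
    x = np.asarray(frame, float)
    ga = np.atleast_1d(np.asarray(group_a, int))
    gb = np.atleast_1d(np.asarray(group_b, int))
    if ga.size == 0 or gb.size == 0:
        raise ValueError("selections must be non-empty")
    if mode == "atom-pair":
        if ga.size != 1 or gb.size != 1:
            raise ValueError("atom-pair mode takes exactly one atom per group")
        pa, pb = x[ga[0]], x[gb[0]]
    elif mode == "geometric-centers":
        pa, pb = x[ga].mean(axis=0), x[gb].mean(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.linalg.norm(pa - pb))


@dataclass
class FreeEnergySurface:
    """Boltzmann-inverted histogram: F = -kBT log(density), min shifted to 0.

    Unvisited bins hold +inf (flagged, not zero).  ``grid`` lists the bin
    centers per dimension.
    """

    grid: list[np.ndarray]
    free_energy: np.ndarray
    counts: np.ndarray
    kbt: float

    def __post_init__(self) -> None:
        finite = self.free_energy[np.isfinite(self.free_energy)]
        if len(finite) and abs(finite.min()) > 1e-9:
            raise ValueError("free energy minimum must be shifted to 0")


def free_energy_surface(
    samples: np.ndarray,
    bins: int = 50,
    kbt: float = 1.0,
    weights: np.ndarray | None = None,
    ranges=None,
) -> FreeEnergySurface:
    """1-D or 2-D free-energy surface from CV samples.

    Optional per-sample ``weights`` reweight biased (e.g. metadynamics)
    trajectories; multiplying all weights by a constant leaves F unchanged.
    Warns when all samples land in a single bin.
    """
    import warnings

    s = np.asarray(samples, float)
    if s.ndim == 1:
        s = s[:, None]
    if s.ndim != 2 or s.shape[1] not in (1, 2):
        raise ValueError("samples must be (N,), (N, 1) or (N, 2)")
    if len(s) < 100:
        raise ValueError("need at least 100 samples")
    counts, edges = np.histogramdd(s, bins=bins, range=ranges, weights=weights)
    if np.count_nonzero(counts) == 1:
        warnings.warn("all samples fall in one bin; surface is flat", stacklevel=2)
    with np.errstate(divide="ignore"):
        f = -kbt * np.log(counts / counts.sum())
    f = f - f[np.isfinite(f)].min()
    grid = [0.5 * (e[1:] + e[:-1]) for e in edges]
    return FreeEnergySurface(grid=grid, free_energy=f, counts=counts, kbt=kbt)
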