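"""I/O for density maps (MRC/CCP4), structures (PDB) and the GMM text dialect.

Internal units are nm; MRC and PDB files are in Å and converted at this
boundary.  Map values are read in the canonical x-fastest axis order
regardless of the MAPC/MAPR/MAPS permutation stored in the file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .gmm import DensityMap, GaussianMixture, _validate_cov, DegenerateCovarianceError
from .forward import AtomicModel

__all__ = [
    "MapFormatError",
    "GmmFormatError",
    "MapHeaderInfo",
    "read_mrc",
    "write_mrc",
    "read_structure",
    "read_gmm",
    "write_gmm",
]

A_PER_NM = 10.0


class MapFormatError(ValueError):
    """Malformed or unsupported MRC/CCP4 file."""


class GmmFormatError(ValueError):
    """Malformed GMM text file."""


@dataclass
class MapHeaderInfo:
    """Selected MRC2014 header fields (lengths already converted to nm)."""

    axis_order: tuple[int, int, int]  # MAPC, MAPR, MAPS (1-based axis ids)
    start: tuple[int, int, int]      # NXSTART/NYSTART/NZSTART in x,y,z order
    cell_nm: tuple[float, float, float]
    mode: int
    origin_record: tuple[float, float, float]  # nm


_SUPPORTED_MODES = (0, 1, 2, 6)


def read_mrc(path, with_header: bool = False):
    """Read an MRC2014/CCP4 map into a :class:`DensityMap` (nm units).

    The voxel array is reordered to canonical x-fastest order.  The origin is
    taken from the ORIGIN header record when any entry is nonzero, otherwise
    from the start indices times the voxel size (legacy CCP4 convention).
    """
    path = str(path)
    m = gemmi.read_ccp4_map(path)
    mode = m.header_i32(4)
    if mode not in _SUPPORTED_MODES:
        raise MapFormatError(f"unsupported MRC mode {mode} in {path}")
    axis_order = tuple(m.header_i32(w) for w in (17, 18, 19))
    if sorted(axis_order) != [1, 2, 3]:
        raise MapFormatError(f"invalid MAPC/MAPR/MAPS {axis_order} in {path}")
    start_crs = [m.header_i32(w) for w in (5, 6, 7)]
    sampling = [m.header_i32(w) for w in (8, 9, 10)]
    if any(s <= 0 for s in sampling):
        raise MapFormatError(f"non-positive cell sampling {sampling} in {path}")
    cell = m.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3
        and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise MapFormatError("only orthogonal (P1, 90/90/90) map cells are supported")
    origin_rec = tuple(float(m.header_float(w)) for w in (50, 51, 52))

    m.setup(0.0, gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, copy=True).astype(float)

    voxel_a = np.array([cell.a, cell.b, cell.c]) / np.array(sampling, float)
    # map file start indices from (column, row, section) to (x, y, z)
    start_xyz = [0, 0, 0]
    for file_axis, xyz_axis in enumerate(axis_order):
        start_xyz[xyz_axis - 1] = start_crs[file_axis]
    if any(abs(o) > 1e-6 for o in origin_rec):
        origin_a = np.array(origin_rec)
    else:
        origin_a = np.array(start_xyz, float) * voxel_a

    dmap = DensityMap(values, voxel_a / A_PER_NM, origin_a / A_PER_NM)
    if with_header:
        header = MapHeaderInfo(
            axis_order=axis_order,  # type: ignore[arg-type]
            start=tuple(start_xyz),  # type: ignore[arg-type]
            cell_nm=(cell.a / A_PER_NM, cell.b / A_PER_NM, cell.c / A_PER_NM),
            mode=mode,
            origin_record=tuple(o / A_PER_NM for o in origin_rec),  # type: ignore[arg-type]
        )
        return dmap, header
    return dmap


def write_mrc(dmap: DensityMap, path) -> None:
    """Write a :class:`DensityMap` as a mode-2 (float32) MRC2014 file."""
    if not np.all(np.isfinite(dmap.values)):
        raise ValueError("refusing to write non-finite map values")
    arr = np.ascontiguousarray(dmap.values, dtype=np.float32)
    grid = gemmi.FloatGrid(arr)
    nx, ny, nz = dmap.dims
    vx = dmap.voxel_size * A_PER_NM
    grid.set_unit_cell(gemmi.UnitCell(nx * vx[0], ny * vx[1], nz * vx[2], 90, 90, 90))
    grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    origin_a = dmap.origin * A_PER_NM
    for w, val in zip((50, 51, 52), origin_a):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

_TWO_LETTER_ELEMENTS = {
    "FE", "ZN", "MG", "MN", "CA", "NA", "CL", "CU", "NI", "CO", "SE", "BR",
}


def _element_from_atom_name(name: str) -> str:
    """PDB atom-name fallback when the element column is blank."""
    stripped = "".join(ch for ch in name.strip() if ch.isalpha()).upper()
    if not stripped:
        return ""
    if stripped[:2] in _TWO_LETTER_ELEMENTS and len(name.strip()) == len(stripped):
        # two-letter metals are left-justified in columns 13-14
        if name[:2].strip().upper() == stripped[:2]:
            return stripped[:2].capitalize()
    return stripped[0]


def read_structure(path, drop_hydrogens: bool = True) -> AtomicModel:
    """Read a PDB file into an :class:`AtomicModel` (positions in nm).

    Keeps the first altLoc, ignores occupancy; hydrogens (and deuterium) are
    dropped by default since the forward model places one Gaussian per heavy
    atom.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="first")
    elements = []
    for el, name in zip(atoms.element, atoms.atom_name):
        el = str(el).strip()
        if not el:
            el = _element_from_atom_name(str(name))
        elements.append(el.capitalize())
    elements = np.array(elements)
    keep = np.ones(len(elements), dtype=bool)
    if drop_hydrogens:
        keep = ~np.isin(elements, ["H", "D"])
    positions = np.asarray(atoms.coord[keep], dtype=float) / A_PER_NM
    return AtomicModel(positions=positions, species=list(elements[keep]))


# ---------------------------------------------------------------------------
# GMM text dialect
# ---------------------------------------------------------------------------
# One component per line:
#   index  mean_x mean_y mean_z  c_xx c_xy c_xz c_yy c_yz c_zz  weight  beta
# lengths in nm, covariances in nm^2; '#' starts a comment; separators may be
# whitespace or commas.

_UT = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def read_gmm(path, label: str | None = None) -> GaussianMixture:
    """Parse the GMM text dialect into a :class:`GaussianMixture`.

    The ``normalized`` flag is set when the weights sum to 1 within 1e-6 (in
    which case they are rescaled to sum to 1 exactly).
    """
    path = Path(path)
    weights, means, covs = [], [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.replace(",", " ").split()
        if len(fields) not in (11, 12):
            raise GmmFormatError(
                f"{path.name}:{lineno}: expected 11 or 12 fields, got {len(fields)}"
            )
        try:
            vals = [float(f) for f in fields[:11]]
        except ValueError as exc:
            raise GmmFormatError(f"{path.name}:{lineno}: {exc}") from exc
        mean = np.array(vals[1:4])
        cov = np.empty((3, 3))
        for v, (i, j) in zip(vals[4:10], _UT):
            cov[i, j] = cov[j, i] = v
        try:
            _validate_cov(cov)
        except DegenerateCovarianceError as exc:
            raise GmmFormatError(f"{path.name}:{lineno}: {exc}") from exc
        weights.append(vals[10])
        means.append(mean)
        covs.append(cov)
    if not weights:
        raise GmmFormatError(f"{path.name}: no components found")
    w = np.array(weights)
    normalized = abs(w.sum() - 1.0) <= 1e-6
    if normalized:
        w = w / w.sum()
    return GaussianMixture(
        w, np.array(means), np.array(covs),
        normalized=normalized, label=label or path.stem,
    )


def write_gmm(gmm: GaussianMixture, path, beta: int = 0) -> None:
    """Write a mixture in the GMM text dialect (9 significant digits)."""
    lines = [
        "# GMM components: index mean(x y z)[nm] "
        "cov(xx xy xz yy yz zz)[nm^2] weight beta"
    ]
    for i in range(len(gmm)):
        mu = gmm.means[i]
        c = gmm.covs[i]
        ut = " ".join(f"{c[a, b]:.9e}" for a, b in _UT)
        lines.append(
            f"{i} {mu[0]:.9e} {mu[1]:.9e} {mu[2]:.9e} {ut} "
            f"{gmm.weights[i]:.9e} {beta}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
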