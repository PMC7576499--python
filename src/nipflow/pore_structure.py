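"""Channel-geometry analysis on PDB structures.

The central operation is the pore-radius profile: at each plane normal to the
channel axis, the largest sphere centred in that plane that touches no atom's
van der Waals surface is found, as in the classic HOLE procedure.  The radius
at plane ``z`` for an in-plane centre ``c`` is

    f(c) = min_atoms( ||atom - (c, z)|| - vdw_atom )

and the profile records ``max_c f(c)`` together with the maximizing centre.
Two search backends are provided: an exhaustive 0.1 A grid (the brute-force
oracle) and a seeded simulated-annealing refinement started from the previous
plane's centre.

Downstream, the profile feeds constriction detection, profile differencing,
pore-lining residue identification, and residue-level hydropathy ratios — a
documented, reproducible stand-in for grid-based hydrophobicity maps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .errors import (
    BlockedChannelError,
    EmptyStructureError,
    InvalidBoundaryError,
    InvalidParameterError,
    NoOverlapError,
    PDBParseError,
    UnknownElementError,
)

__all__ = [
    "Structure",
    "PoreProfile",
    "PoreRegionSplit",
    "HydropathyRatio",
    "ProfileDelta",
    "DEFAULT_VDW_RADII",
    "HYDROPHOBIC_RESIDUES",
    "read_structure",
    "write_structure",
    "assign_vdw_radii",
    "pore_profile",
    "min_constriction",
    "profile_delta",
    "pore_lining_residues",
    "hydropathy_ratio",
    "split_regions",
]

#: Default van der Waals radii by element, Angstrom.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}

#: Fallback radius for unknown elements in lenient mode.
FALLBACK_VDW = 1.70

#: Binary hydropathy scale: residues counted as hydrophobic.
HYDROPHOBIC_RESIDUES: frozenset = frozenset("AVLIMFWCP")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


# --------------------------------------------------------------------------
# structure container and I/O
# --------------------------------------------------------------------------


@dataclass
class Structure:
    """Flat atom table: parallel arrays over atoms."""

    serial: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain: np.ndarray
    coords: np.ndarray  # (n, 3) Angstrom
    vdw: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.serial)
        if self.coords.shape != (n, 3):
            raise InvalidParameterError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise InvalidParameterError("coordinates must be finite")
        if np.any(self.res_id <= 0):
            raise InvalidParameterError("residue numbers must be positive")
        if self.vdw is not None and np.any(np.asarray(self.vdw) <= 0):
            raise InvalidParameterError("vdw radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def require_vdw(self) -> np.ndarray:
        if self.vdw is None:
            raise InvalidParameterError(
                "vdw radii not assigned; call assign_vdw_radii first"
            )
        return self.vdw

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigidly transformed copy: ``x -> R x + t``."""
        return replace(self, coords=self.coords @ rotation.T + translation)


def read_structure(
    path,
    exclude_hetero: bool = False,
    exclude_water: bool = True,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Altloc duplicates are resolved by keeping the highest-occupancy
    conformer.  Waters (HOH/WAT) are excluded by default; other heteroatoms
    optionally.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    with open(path) as fh:
        if not any(line.startswith(("ATOM", "HETATM")) for line in fh):
            raise EmptyStructureError(f"{path}: no ATOM/HETATM records")
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:
        raise PDBParseError(
            f"cannot parse {path}: {exc}", line_number=_find_bad_line(path)
        ) from exc
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records")

    mask = np.ones(atoms.array_length(), dtype=bool)
    if exclude_water:
        mask &= ~np.isin(atoms.res_name, ("HOH", "WAT"))
    if exclude_hetero:
        mask &= ~atoms.hetero
    atoms = atoms[mask]
    if atoms.array_length() == 0:
        raise EmptyStructureError(f"{path}: no atoms left after filtering")

    return Structure(
        serial=np.arange(1, atoms.array_length() + 1),
        element=atoms.element.astype("U2"),
        res_name=atoms.res_name.astype("U3"),
        res_id=atoms.res_id.astype(int),
        chain=atoms.chain_id.astype("U1"),
        coords=np.asarray(atoms.coord, dtype=float),
    )


def _find_bad_line(path) -> int | None:
    """Best-effort location of the first malformed ATOM/HETATM record."""
    try:
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        [float(line[c0:c1]) for c0, c1 in ((30, 38), (38, 46), (46, 54))]
                    except (ValueError, IndexError):
                        return i
    except OSError:
        return None
    return None


def write_structure(structure: Structure, path) -> None:
    """Write minimal PDB ATOM records (occupancy/B-factor 0.0, element set)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    atoms = struc.AtomArray(structure.n_atoms)
    atoms.coord = np.asarray(structure.coords, dtype=np.float32)
    atoms.element = structure.element
    atoms.res_name = structure.res_name
    atoms.res_id = structure.res_id
    atoms.chain_id = structure.chain
    atoms.atom_name = structure.element
    atoms.hetero = np.zeros(structure.n_atoms, dtype=bool)
    atoms.set_annotation("occupancy", np.zeros(structure.n_atoms))
    atoms.set_annotation("b_factor", np.zeros(structure.n_atoms))
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def assign_vdw_radii(
    structure: Structure,
    radius_set: dict[str, float] | None = None,
    on_unknown: str = "default",
) -> Structure:
    """Return a copy with van der Waals radii assigned by element.

    ``on_unknown``: "default" assigns 1.70 A with a warning, "error" raises.
    """
    table = dict(DEFAULT_VDW_RADII if radius_set is None else radius_set)
    radii = np.empty(structure.n_atoms, dtype=float)
    for i, el in enumerate(structure.element):
        key = str(el).strip().upper()
        if key in table:
            radii[i] = table[key]
        elif on_unknown == "error":
            raise UnknownElementError(key)
        else:
            warnings.warn(
                f"element {key!r} not in radius set; using {FALLBACK_VDW} A",
                stacklevel=2,
            )
            radii[i] = FALLBACK_VDW
    return replace(structure, vdw=radii)


# --------------------------------------------------------------------------
# pore profiling
# --------------------------------------------------------------------------


@dataclass
class PoreProfile:
    z: np.ndarray  # ascending, Angstrom
    radius: np.ndarray
    center_xy: np.ndarray  # (n, 2)
    blocked: np.ndarray  # bool

    def __post_init__(self):
        n = len(self.z)
        if not (len(self.radius) == n and len(self.center_xy) == n == len(self.blocked)):
            raise InvalidParameterError("profile arrays must share one length")
        if np.any(self.radius[~self.blocked] < 0):
            raise InvalidParameterError("open planes must have radius >= 0")


@dataclass(frozen=True)
class PoreRegionSplit:
    """Partition of the profiled z range at the ar/R constriction.

    By convention the periplasmic side is +z, so ``upper`` is the interval
    above ``boundary_z``.
    """

    boundary_z: float
    lower: tuple[float, float]  # [z_min, boundary_z]
    upper: tuple[float, float]  # (boundary_z, z_max]
    empty_lower: bool = False
    empty_upper: bool = False


@dataclass(frozen=True)
class HydropathyRatio:
    ratio: float  # may be math.inf when no hydrophilic residues
    n_hydrophobic: int
    n_hydrophilic: int
    region: str  # "whole" | "upper" | "lower"
    scale_name: str


@dataclass(frozen=True)
class ProfileDelta:
    z: np.ndarray
    delta: np.ndarray  # b - a per plane
    mean_delta: float
    at_constriction: float
    constriction_z: float


def _principal_axis_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation (and centroid) aligning the longest principal axis with z.

    The axis sign is fixed by requiring non-negative skewness of the axial
    coordinate (ties broken toward +z of the original frame), which makes the
    orientation reproducible under rigid motion.
    """
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    proj = centered @ axis
    skew = float(np.mean(proj**3))
    if skew < -1e-9 or (abs(skew) <= 1e-9 and axis[2] < 0):
        axis = -axis
    # complete a right-handed orthonormal frame
    helper = np.array([1.0, 0.0, 0.0])
    if abs(float(axis @ helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(helper, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    rotation = np.vstack([e1, e2, axis])  # rows: new basis
    return rotation, centroid


def _plane_objective(
    xy: np.ndarray, z: float, coords: np.ndarray, vdw: np.ndarray, cap: float
) -> float:
    d = np.sqrt(
        (coords[:, 0] - xy[0]) ** 2
        + (coords[:, 1] - xy[1]) ** 2
        + (coords[:, 2] - z) ** 2
    )
    return min(cap, float(np.min(d - vdw))) if len(coords) else cap


def _grid_search(
    z: float,
    coords: np.ndarray,
    vdw: np.ndarray,
    cap: float,
    grid_step: float,
    slab_half_width: float,
) -> tuple[np.ndarray, float]:
    # Candidate centres span only the xy box of atoms close to the plane;
    # otherwise the exhaustive maximum escapes into bulk solvent outside the
    # channel wall.  The objective still sees every atom within capture.
    slab = np.abs(coords[:, 2] - z) <= slab_half_width
    box = coords[slab] if np.any(slab) else coords
    # lattice-aligned grid (origin snapped to multiples of grid_step) so the
    # candidate set is independent of the box extents
    x_lo = math.floor(box[:, 0].min() / grid_step) * grid_step
    y_lo = math.floor(box[:, 1].min() / grid_step) * grid_step
    xs = np.arange(x_lo, box[:, 0].max() + grid_step / 2, grid_step)
    ys = np.arange(y_lo, box[:, 1].max() + grid_step / 2, grid_step)
    best_val = -np.inf
    best_xy = np.zeros(2)
    dz2 = (coords[:, 2] - z) ** 2
    for x0 in range(0, xs.size, 64):  # chunk rows to bound memory
        xc = xs[x0:x0 + 64]
        dx2 = (xc[:, None] - coords[None, :, 0]) ** 2  # (cx, atoms)
        for y0 in range(0, ys.size, 64):
            yc = ys[y0:y0 + 64]
            dy2 = (yc[:, None] - coords[None, :, 1]) ** 2
            d = np.sqrt(dx2[:, None, :] + dy2[None, :, :] + dz2[None, None, :])
            vals = np.min(d - vdw[None, None, :], axis=2)
            idx = np.unravel_index(int(np.argmax(vals)), vals.shape)
            if vals[idx] > best_val:
                best_val = float(vals[idx])
                best_xy = np.array([xc[idx[0]], yc[idx[1]]])
    return best_xy, min(best_val, cap)


def _anneal_search(
    z: float,
    coords: np.ndarray,
    vdw: np.ndarray,
    cap: float,
    start: np.ndarray,
    rng: np.random.Generator,
    n_proposals: int = 200,
    step_sd: float = 0.3,
) -> tuple[np.ndarray, float]:
    def f(xy):
        return _plane_objective(xy, z, coords, vdw, cap)

    cur = np.array(start, dtype=float)
    cur_val = f(cur)
    best, best_val = cur.copy(), cur_val
    temp, cooling = 0.5, (0.01 / 0.5) ** (1.0 / n_proposals)
    for _ in range(n_proposals):
        cand = cur + rng.normal(0.0, step_sd, size=2)
        val = f(cand)
        if val > cur_val or rng.random() < math.exp((val - cur_val) / temp):
            cur, cur_val = cand, val
            if val > best_val:
                best, best_val = cand.copy(), val
        temp *= cooling
    # deterministic local polish of the stochastic optimum
    res = optimize.minimize(
        lambda xy: -f(xy),
        best,
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400},
    )
    if -res.fun > best_val:
        best, best_val = res.x, -float(res.fun)
    return best, min(best_val, cap)


def pore_profile(
    structure: Structure,
    axis: str = "z",
    z_step: float = 0.5,
    search: str = "grid",
    seed: int = 0,
    capture_radius: float = 10.0,
    grid_step: float = 0.1,
    z_range: tuple[float, float] | None = None,
) -> PoreProfile:
    """Largest-inscribed-sphere radius as a function of axial coordinate.

    ``axis='principal'`` first rotates the structure so its longest principal
    axis lies along z.  Planes with no atoms within the capture radius are
    marked open (radius = capture_radius); planes where every centre overlaps
    an atom are flagged blocked with radius 0.
    """
    if structure.n_atoms < 10:
        raise InvalidParameterError("need at least 10 atoms to profile a pore")
    if search not in ("grid", "anneal"):
        raise InvalidParameterError(f"unknown search mode {search!r}")
    vdw = structure.require_vdw()
    coords = structure.coords
    if axis == "principal":
        rotation, centroid = _principal_axis_frame(coords)
        coords = (coords - centroid) @ rotation.T
    elif axis != "z":
        raise InvalidParameterError(f"unknown axis mode {axis!r}")

    if z_range is None:
        z_lo, z_hi = float(coords[:, 2].min()), float(coords[:, 2].max())
    else:
        z_lo, z_hi = z_range
    planes = np.arange(z_lo, z_hi + z_step / 2, z_step)

    max_vdw = float(vdw.max())
    zs, radii, centers, blocked = [], [], [], []
    prev_center: np.ndarray | None = None
    for idx, z in enumerate(planes):
        near = np.abs(coords[:, 2] - z) <= capture_radius + max_vdw
        c_near, v_near = coords[near], vdw[near]
        if len(c_near) == 0:
            center, val = (
                prev_center if prev_center is not None else np.zeros(2)
            ), capture_radius
        elif search == "grid":
            center, val = _grid_search(
                z, c_near, v_near, capture_radius, grid_step,
                slab_half_width=max(2.0, 2.0 * z_step),
            )
        else:
            start = (
                prev_center
                if prev_center is not None
                else c_near[:, :2].mean(axis=0)
            )
            rng = np.random.default_rng((seed * 100_003 + idx) % (2**32))
            center, val = _anneal_search(
                z, c_near, v_near, capture_radius, start, rng
            )
        zs.append(float(z))
        radii.append(max(val, 0.0))
        centers.append(np.asarray(center, dtype=float))
        blocked.append(bool(val <= 0.0))
        prev_center = np.asarray(center, dtype=float)

    return PoreProfile(
        z=np.array(zs),
        radius=np.array(radii),
        center_xy=np.array(centers),
        blocked=np.array(blocked),
    )


def min_constriction(profile: PoreProfile) -> tuple[float, float]:
    """Global radius minimum; ties broken toward smaller z."""
    if len(profile.z) == 0:
        raise InvalidParameterError("empty profile")
    if bool(np.all(profile.blocked)):
        raise BlockedChannelError("every plane is blocked")
    idx = int(np.argmin(profile.radius))  # argmin returns the first minimum
    return float(profile.z[idx]), float(profile.radius[idx])


def profile_delta(a: PoreProfile, b: PoreProfile) -> ProfileDelta:
    """Per-plane radius difference ``b - a`` with summary statistics.

    Profiles on different z grids are compared on the overlap of their ranges
    after linear interpolation of ``b`` onto ``a``'s planes.
    """
    lo = max(float(a.z.min()), float(b.z.min()))
    hi = min(float(a.z.max()), float(b.z.max()))
    if lo > hi:
        raise NoOverlapError("profiles share no z range")
    mask = (a.z >= lo - 1e-9) & (a.z <= hi + 1e-9)
    z = a.z[mask]
    ra = a.radius[mask]
    rb = np.interp(z, b.z, b.radius)
    delta = rb - ra
    zc, _ = min_constriction(a)
    at_c = float(np.interp(zc, z, delta)) if lo <= zc <= hi else math.nan
    return ProfileDelta(
        z=z,
        delta=delta,
        mean_delta=float(delta.mean()),
        at_constriction=at_c,
        constriction_z=zc,
    )


def pore_lining_residues(
    structure: Structure,
    profile: PoreProfile,
    contact_cutoff: float = 1.5,
    axis: str = "z",
) -> set[tuple[str, int, str]]:
    """Residues owning an atom whose vdW surface lies within ``contact_cutoff``
    of any inscribed-sphere surface of the profile."""
    vdw = structure.require_vdw()
    coords = structure.coords
    if axis == "principal":
        rotation, centroid = _principal_axis_frame(coords)
        coords = (coords - centroid) @ rotation.T
    lining = np.zeros(structure.n_atoms, dtype=bool)
    for i in range(len(profile.z)):
        if profile.blocked[i]:
            continue
        center = np.array(
            [profile.center_xy[i, 0], profile.center_xy[i, 1], profile.z[i]]
        )
        d = np.linalg.norm(coords - center, axis=1) - vdw - profile.radius[i]
        lining |= d <= contact_cutoff
    return {
        (str(structure.chain[i]), int(structure.res_id[i]), str(structure.res_name[i]))
        for i in np.nonzero(lining)[0]
    }


def split_regions(profile: PoreProfile, arR_z: float) -> PoreRegionSplit:
    """Split the profiled range at the ar/R constriction position."""
    z_lo, z_hi = float(profile.z.min()), float(profile.z.max())
    if not (z_lo <= arR_z <= z_hi):
        raise InvalidBoundaryError(
            f"boundary {arR_z} outside profiled range [{z_lo}, {z_hi}]"
        )
    return PoreRegionSplit(
        boundary_z=float(arR_z),
        lower=(z_lo, float(arR_z)),
        upper=(float(arR_z), z_hi),
        empty_lower=arR_z <= z_lo,
        empty_upper=arR_z >= z_hi,
    )


def _one_letter(res_name: str) -> str:
    name = res_name.strip().upper()
    if len(name) == 1:
        return name
    return _THREE_TO_ONE.get(name, "X")


def hydropathy_ratio(
    residues,
    structure: Structure | None = None,
    scale: str = "binary",
    region_split: PoreRegionSplit | None = None,
    region: str = "whole",
    kd_threshold: float = 0.0,
    hydrophobic_set: frozenset = HYDROPHOBIC_RESIDUES,
) -> HydropathyRatio:
    """Hydrophobic/hydrophilic count ratio over a residue set.

    ``scale='binary'`` classifies by membership of a fixed hydrophobic set;
    ``scale='kyte-doolittle'`` classifies residues with index >=
    ``kd_threshold`` as hydrophobic.  When a ``region_split`` and a region
    other than "whole" are given, residues are filtered by the z coordinate
    of their centroid (requires ``structure``).
    """
    residues = sorted(residues)
    if region not in ("whole", "upper", "lower"):
        raise InvalidParameterError(f"unknown region {region!r}")
    if region != "whole":
        if region_split is None or structure is None:
            raise InvalidParameterError(
                "region filtering needs a region split and the structure"
            )
        lo, hi = getattr(region_split, region)
        kept = []
        for chain, res_id, res_name in residues:
            sel = (structure.chain == chain) & (structure.res_id == res_id)
            if not np.any(sel):
                continue
            zc = float(structure.coords[sel, 2].mean())
            inside = (
                zc > region_split.boundary_z
                if region == "upper"
                else zc <= region_split.boundary_z
            )
            if inside and lo - 1e-9 <= zc <= hi + 1e-9:
                kept.append((chain, res_id, res_name))
        residues = kept

    n_phobic = n_philic = 0
    for _, _, res_name in residues:
        letter = _one_letter(res_name)
        if scale == "binary":
            is_phobic = letter in hydrophobic_set
        elif scale == "kyte-doolittle":
            is_phobic = KYTE_DOOLITTLE.get(letter, -4.5) >= kd_threshold
        else:
            raise InvalidParameterError(f"unknown scale {scale!r}")
        if is_phobic:
            n_phobic += 1
        else:
            n_philic += 1

    ratio = n_phobic / n_philic if n_philic > 0 else math.inf
    return HydropathyRatio(
        ratio=ratio,
        n_hydrophobic=n_phobic,
        n_hydrophilic=n_philic,
        region=region,
        scale_name=scale,
    )
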