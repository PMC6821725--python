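"""Pentamer structure geometry: superposition, pore axis, HOLE-style profiles.

Operates on crystallographic models of oligomeric membrane proteins (here a
C5-symmetric rhodopsin pentamer with an axial pore).  Parsing goes through
biotite; geometry is computed here: Kabsch rigid superposition, the pore
axis from the chain-center pentagon, a pore-radius profile by in-plane probe
maximization against van der Waals surfaces, ring (water-pentagon) geometry
and minimum interatomic distances.

Distances are in Angstrom.  The axial coordinate z is signed along the
oriented pore axis with origin at the protein center of mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

import biotite.structure as struc
from biotite.structure.io import pdb as pdbio
from biotite.structure.io import pdbx as pdbxio

__all__ = [
    "StructureModel",
    "PoreProfile",
    "RingGeometry",
    "read_structure",
    "write_structure",
    "select_mask",
    "superpose",
    "pairwise_protomer_rmsd",
    "pore_axis",
    "pore_radius_profile",
    "ring_geometry",
    "min_atom_distance",
    "water_ring",
    "BONDI_RADII",
]

#: Bondi van der Waals radii (A); the HOLE default family.  Hydrogens are
#: ignored entirely (not modeled in a 1.9 A crystal structure).
BONDI_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
_DEFAULT_VDW = 1.70

_BACKBONE = ("N", "CA", "C", "O")


@dataclass
class StructureModel:
    """A parsed atomic model (thin wrapper over a biotite ``AtomArray``)."""

    atoms: struc.AtomArray

    @property
    def coords(self) -> np.ndarray:
        return self.atoms.coord

    @property
    def chain_ids(self) -> list[str]:
        return [str(c) for c in np.unique(self.atoms.chain_id)]

    @property
    def n_atoms(self) -> int:
        return self.atoms.array_length()

    def subset(self, mask: np.ndarray) -> "StructureModel":
        return StructureModel(self.atoms[mask])

    def select(self, query: str) -> "StructureModel":
        return self.subset(select_mask(self.atoms, query))

    def center_of_mass(self) -> np.ndarray:
        """Unweighted centroid of all atoms (the profile origin)."""
        return self.atoms.coord.mean(axis=0)


def _infer_elements(atoms: struc.AtomArray) -> struc.AtomArray:
    elem = atoms.element
    missing = np.array([e.strip() == "" for e in elem])
    if np.any(missing):
        warnings.warn(f"{missing.sum()} atoms lack an element; inferring "
                      "from atom names", stacklevel=3)
        inferred = [struc.infer_elements([n])[0]
                    for n in atoms.atom_name[missing]]
        elem = elem.copy()
        elem[missing] = inferred
        atoms.element = elem
    return atoms


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken toward altloc 'A' by file order); the first model is used.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "pdb":
            f = pdbio.PDBFile.read(str(path))
            atoms = pdbio.get_structure(
                f, model=1, altloc="occupancy",
                extra_fields=["occupancy", "b_factor"])
        elif fmt == "mmcif":
            f = pdbxio.CIFFile.read(str(path))
            atoms = pdbxio.get_structure(
                f, model=1, altloc="occupancy",
                extra_fields=["occupancy", "b_factor"])
        else:
            raise ValueError(f"format must be 'pdb' or 'mmcif', got {fmt!r}")
    except ValueError:
        raise
    except Exception as exc:  # malformed records
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no atoms in model 1")
    return StructureModel(_infer_elements(atoms))


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a standard PDB file (no CRYST1; waters keep resname HOH)."""
    atoms = model.atoms.copy()
    atoms.box = None
    f = pdbio.PDBFile()
    pdbio.set_structure(f, atoms)
    f.write(str(path))


# ---------------------------------------------------------------------------
# selection mini-language:  "chain A and resname HOH and name O", values may
# be lists ("name N CA C O"), resnum accepts ranges ("resnum 10:20"), plus
# bare keywords "backbone", "heavy", "water", "protein".
# ---------------------------------------------------------------------------

def select_mask(atoms: struc.AtomArray, query: str) -> np.ndarray:
    n = atoms.array_length()
    mask = np.ones(n, dtype=bool)
    for clause in [c.strip() for c in query.split(" and ")]:
        if not clause:
            continue
        tokens = clause.split()
        key, values = tokens[0].lower(), tokens[1:]
        if key == "chain":
            mask &= np.isin(atoms.chain_id, values)
        elif key == "resname":
            mask &= np.isin(atoms.res_name, [v.upper() for v in values])
        elif key == "name":
            mask &= np.isin(atoms.atom_name, [v.upper() for v in values])
        elif key == "element":
            mask &= np.isin(atoms.element, [v.upper() for v in values])
        elif key == "resnum":
            sub = np.zeros(n, dtype=bool)
            for v in values:
                if ":" in v:
                    lo, hi = (int(x) for x in v.split(":"))
                    sub |= (atoms.res_id >= lo) & (atoms.res_id <= hi)
                else:
                    sub |= atoms.res_id == int(v)
            mask &= sub
        elif key == "backbone" and not values:
            mask &= np.isin(atoms.atom_name, _BACKBONE) & ~atoms.hetero
        elif key == "heavy" and not values:
            mask &= ~np.isin(atoms.element, ["H", "D"])
        elif key == "water" and not values:
            mask &= atoms.res_name == "HOH"
        elif key == "protein" and not values:
            mask &= struc.filter_amino_acids(atoms)
        else:
            raise ValueError(f"cannot parse selection clause {clause!r}")
    return mask


def _as_coords(obj) -> np.ndarray:
    if isinstance(obj, StructureModel):
        obj = obj.atoms
    if isinstance(obj, struc.AtomArray):
        obj = obj.coord
    return np.asarray(obj, dtype=np.float64)


def superpose(moving, fixed) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) such that ``R @ x + t`` maps moving onto fixed.
    """
    mv, fx = _as_coords(moving), _as_coords(fixed)
    if mv.shape != fx.shape:
        raise ValueError(f"paired sets differ in shape: {mv.shape} vs {fx.shape}")
    if mv.shape[0] < 3:
        raise ValueError("need >= 3 paired atoms")
    cm, cf = mv.mean(axis=0), fx.mean(axis=0)
    P, Q = mv - cm, fx - cf
    span = min(np.linalg.svd(P, compute_uv=False)[1],
               np.linalg.svd(Q, compute_uv=False)[1])
    if span < 1e-8:
        raise ValueError("degenerate (collinear) point set")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cf - R @ cm
    diff = (mv @ R.T + t) - fx
    rmsd = float(np.sqrt((diff * diff).sum() / mv.shape[0]))
    return R, t, rmsd


def _backbone_table(atoms: struc.AtomArray, chain: str,
                    atom_names=_BACKBONE) -> dict[tuple[int, str], np.ndarray]:
    m = (atoms.chain_id == chain) & np.isin(atoms.atom_name, atom_names) \
        & struc.filter_amino_acids(atoms)
    sub = atoms[m]
    return {(int(r), str(a)): c
            for r, a, c in zip(sub.res_id, sub.atom_name, sub.coord)}


def pairwise_protomer_rmsd(model: StructureModel, chains=None,
                           atom_names=_BACKBONE) -> pd.DataFrame:
    """Symmetric backbone-RMSD matrix between protomers after superposition.

    Atoms are paired by (residue number, atom name) intersection; chains that
    share no atoms raise.
    """
    if chains is None:
        prot = model.atoms[struc.filter_amino_acids(model.atoms)]
        chains = [str(c) for c in np.unique(prot.chain_id)]
    tables = {c: _backbone_table(model.atoms, c, atom_names) for c in chains}
    n = len(chains)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            common = sorted(set(tables[chains[i]]) & set(tables[chains[j]]))
            if not common:
                raise ValueError(
                    f"chains {chains[i]} and {chains[j]} share no backbone atoms")
            a = np.array([tables[chains[i]][k] for k in common])
            b = np.array([tables[chains[j]][k] for k in common])
            _, _, rmsd = superpose(a, b)
            out[i, j] = out[j, i] = rmsd
    return pd.DataFrame(out, index=chains, columns=chains)


def pore_axis(model: StructureModel, chains=None,
              reference_direction=(0.0, 0.0, 1.0)
              ) -> tuple[np.ndarray, np.ndarray]:
    """Axis of the oligomer pore: (point, unit direction).

    The direction is the normal of the best-fit plane through the chain
    centers of mass (the C5 pentagon); the point is the protein center of
    mass.  The direction is oriented to have a positive dot product with
    ``reference_direction`` (caller's cytoplasmic -> extracellular choice).
    """
    prot = model.atoms[struc.filter_amino_acids(model.atoms)]
    if chains is None:
        chains = [str(c) for c in np.unique(prot.chain_id)]
    if len(chains) < 3:
        raise ValueError(f"need >= 3 chains to define a pore axis, "
                         f"got {len(chains)}")
    coms = np.array([prot.coord[prot.chain_id == c].mean(axis=0)
                     for c in chains])
    centered = coms - coms.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    direction = vt[-1]
    if direction @ np.asarray(reference_direction, dtype=float) < 0:
        direction = -direction
    point = prot.coord.mean(axis=0)
    return point, direction / np.linalg.norm(direction)


def _vdw_radii(atoms: struc.AtomArray) -> np.ndarray:
    return np.array([BONDI_RADII.get(str(e).upper(), _DEFAULT_VDW)
                     for e in atoms.element])


@dataclass
class PoreProfile:
    """Pore radius vs axial position, HOLE-style."""

    z: np.ndarray               # A, relative to protein center of mass
    radius: np.ndarray          # A
    probe_centers: np.ndarray   # (n, 3) lab-frame coordinates
    capped: np.ndarray          # bool: radius hit the cap / empty slab
    cap: float

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "z": self.z, "radius": self.radius,
            "x": self.probe_centers[:, 0], "y": self.probe_centers[:, 1],
            "capped": self.capped.astype(int),
        }).to_csv(path, sep="\t", index=False, float_format="%.4f")


def _plane_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(direction, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    return e1, e2


def pore_radius_profile(model: StructureModel, axis=None,
                        z_range: tuple[float, float] | None = None,
                        step: float = 0.5, cap: float = 15.0,
                        include_waters: bool = False) -> PoreProfile:
    """Largest probe radius fitting in the pore at each axial position.

    At each z the probe center is moved in the slab plane to maximize
    min_atoms(||p - x_a|| - vdw_a) (Nelder-Mead seeded at the previous
    center, HOLE-style continuation, with an on-axis fallback seed).  Radii
    are clipped to ``cap``; slabs with no atoms in reach are flagged.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    atoms = model.atoms
    keep = ~np.isin(atoms.element, ["H", "D"])
    if not include_waters:
        keep &= atoms.res_name != "HOH"
    atoms = atoms[keep]
    if axis is None:
        point, direction = pore_axis(model)
    else:
        point, direction = (np.asarray(axis[0], dtype=float),
                            np.asarray(axis[1], dtype=float))
        direction = direction / np.linalg.norm(direction)
    e1, e2 = _plane_basis(direction)

    coords = atoms.coord
    radii = _vdw_radii(atoms)
    z_all = (coords - point) @ direction
    if z_range is None:
        z_range = (float(z_all.min()), float(z_all.max()))
    z_grid = np.arange(z_range[0], z_range[1] + 0.5 * step, step)

    zs, rs, centers, capped = [], [], [], []
    prev_uv = None
    max_r = radii.max(initial=0.0)
    for z in z_grid:
        near = np.abs(z_all - z) <= cap + max_r
        if not np.any(near):
            zs.append(z)
            rs.append(cap)
            centers.append(point + z * direction)
            capped.append(True)
            prev_uv = None
            continue
        sub_c, sub_r = coords[near], radii[near]
        base = point + z * direction

        def neg_clearance(uv):
            p = base + uv[0] * e1 + uv[1] * e2
            d = np.sqrt(((sub_c - p) ** 2).sum(axis=1)) - sub_r
            return -d.min()

        seeds = [np.zeros(2)] if prev_uv is None else [prev_uv, np.zeros(2)]
        best = None
        for s in seeds:
            res = minimize(neg_clearance, s, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6,
                                    "maxiter": 400})
            cand = (-res.fun, res.x)
            if best is None or cand[0] > best[0] + 1e-6:
                best = cand
            elif abs(cand[0] - best[0]) <= 1e-6 and prev_uv is not None:
                # tie: prefer the center closer to the previous one
                if (np.linalg.norm(cand[1] - prev_uv)
                        < np.linalg.norm(best[1] - prev_uv)):
                    best = cand
        r, uv = best
        hit_cap = r >= cap
        r = float(np.clip(r, 0.0, cap))
        zs.append(z)
        rs.append(r)
        centers.append(base + uv[0] * e1 + uv[1] * e2)
        capped.append(bool(hit_cap))
        prev_uv = uv

    return PoreProfile(np.array(zs), np.array(rs), np.array(centers),
                       np.array(capped), cap)


@dataclass
class RingGeometry:
    """Cyclic geometry of a ring of atoms ordered by azimuth about an axis."""

    coords: np.ndarray            # (n, 3), azimuthal order
    adjacent_distances: np.ndarray
    mean: float
    sd: float
    ring_radius: float = field(default=np.nan)


def ring_geometry(model: StructureModel, selection, axis=None) -> RingGeometry:
    """Adjacent-member distances of a ring (e.g. the axial water pentagon)."""
    if isinstance(selection, str):
        mask = select_mask(model.atoms, selection)
    else:
        mask = np.asarray(selection, dtype=bool)
    sub = model.atoms[mask]
    if sub.array_length() < 3:
        raise ValueError(
            f"ring needs >= 3 atoms, selection yields {sub.array_length()}")
    if axis is None:
        point, direction = pore_axis(model)
    else:
        point, direction = (np.asarray(axis[0], dtype=float),
                            np.asarray(axis[1], dtype=float))
        direction = direction / np.linalg.norm(direction)
    e1, e2 = _plane_basis(direction)
    rel = sub.coord - point
    angles = np.arctan2(rel @ e2, rel @ e1)
    order = np.argsort(angles)
    pts = sub.coord[order]
    d = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    radial = np.linalg.norm(
        np.column_stack([rel[order] @ e1, rel[order] @ e2]), axis=1)
    return RingGeometry(pts, d, float(d.mean()),
                        float(d.std(ddof=1)) if d.size > 1 else 0.0,
                        float(radial.mean()))


def min_atom_distance(model: StructureModel, selection_a, selection_b,
                      heavy_only: bool = True) -> tuple[float, dict]:
    """Minimum distance between two selections, with the closest atom pair."""
    masks = []
    for name, sel in (("a", selection_a), ("b", selection_b)):
        mask = select_mask(model.atoms, sel) if isinstance(sel, str) \
            else np.asarray(sel, dtype=bool)
        if heavy_only:
            mask = mask & ~np.isin(model.atoms.element, ["H", "D"])
        if not np.any(mask):
            raise ValueError(f"selection {name} ({sel!r}) matches no atoms")
        masks.append(mask)
    sub_a, sub_b = model.atoms[masks[0]], model.atoms[masks[1]]
    dm = cdist(sub_a.coord, sub_b.coord)
    i, j = np.unravel_index(np.argmin(dm), dm.shape)

    def describe(at, idx):
        return {"chain": str(at.chain_id[idx]), "resname": str(at.res_name[idx]),
                "resnum": int(at.res_id[idx]), "atom": str(at.atom_name[idx])}

    return float(dm[i, j]), {"a": describe(sub_a, i), "b": describe(sub_b, j)}


def water_ring(model: StructureModel, axis=None, n: int = 5,
               z_center: float | None = None,
               half_width: float = 2.0) -> np.ndarray:
    """Mask of the ``n`` water oxygens nearest the pore axis.

    When ``z_center`` is given only waters within ``z_center +/- half_width``
    along the axis are considered (the operational pick for the pentagon in
    the Leu28 carbonyl plane).
    """
    if axis is None:
        point, direction = pore_axis(model)
    else:
        point, direction = (np.asarray(axis[0], dtype=float),
                            np.asarray(axis[1], dtype=float))
        direction = direction / np.linalg.norm(direction)
    atoms = model.atoms
    mask = (atoms.res_name == "HOH") & (atoms.element == "O")
    idx = np.nonzero(mask)[0]
    if idx.size < n:
        raise ValueError(f"only {idx.size} water oxygens present, need {n}")
    rel = atoms.coord[idx] - point
    z = rel @ direction
    if z_center is not None:
        keep = np.abs(z - z_center) <= half_width
        idx, rel = idx[keep], rel[keep]
        if idx.size < n:
            raise ValueError(
                f"only {idx.size} water oxygens in the z-slab, need {n}")
    radial = np.linalg.norm(rel - np.outer(rel @ direction, direction), axis=1)
    chosen = idx[np.argsort(radial)[:n]]
    out = np.zeros(atoms.array_length(), dtype=bool)
    out[chosen] = True
    return out
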