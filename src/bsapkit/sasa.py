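"""Shrake-Rupley solvent-accessible surface area and exposure references.

The accessible area of an atom is estimated by distributing test points on a
sphere of radius ``r_vdw + r_probe`` and counting the fraction not buried
inside any other inflated sphere of a *context* atom set.  The context is an
explicit argument so that adsorbed excipient molecules can be included as
occluders (the buffer-aware aggregation index needs exactly that).

Test points come from a deterministic Fibonacci lattice, so results are
bit-reproducible for a fixed ``n_points``; no random state is involved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .core_io import (
    BACKBONE_ATOM_NAMES,
    DEFAULT_VDW_RADII,
    ExposureReference,
    Frame,
    MolecularSystem,
)

__all__ = [
    "SasaResult",
    "shrake_rupley",
    "sasa_from_coords",
    "residue_saa",
    "build_exposure_reference",
    "build_trimer",
    "fibonacci_sphere",
]

logger = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS = 0.14  # nm, water-sized probe
DEFAULT_N_POINTS = 960


@dataclass
class SasaResult:
    """Per-atom accessible areas (nm^2) for one frame."""

    per_atom: dict[int, float]
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(sum(self.per_atom.values()))


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform points on the unit sphere (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@lru_cache(maxsize=8)
def _cached_sphere(n: int) -> np.ndarray:
    return fibonacci_sphere(n)


def sasa_from_coords(
    coords: np.ndarray,
    radii: np.ndarray,
    subset: np.ndarray | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Accessible area of each atom in ``subset``, occluded by *all* atoms.

    ``coords``/``radii`` define the full occluding context; the return value
    aligns with ``subset`` (default: every atom).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if subset is None:
        subset = np.arange(len(coords))
    subset = np.asarray(subset, dtype=int)
    if len(subset) == 0:
        return np.empty(0)
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    if n_points < 32:
        raise ValueError("n_points must be >= 32")

    sphere = _cached_sphere(n_points)
    inflated = radii + probe_radius
    tree = cKDTree(coords)
    out = np.empty(len(subset))
    for k, i in enumerate(subset):
        ri = inflated[i]
        neighbors = tree.query_ball_point(coords[i], ri + inflated.max())
        neighbors = [j for j in neighbors if j != i]
        pts = coords[i] + ri * sphere
        if neighbors:
            nb = np.asarray(neighbors, dtype=int)
            # point buried if inside any neighbor's inflated sphere
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 <= (inflated[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[k] = frac * 4.0 * math.pi * ri * ri
    return out


def shrake_rupley(
    frame: Frame,
    system: MolecularSystem,
    atoms: np.ndarray | None = None,
    context: np.ndarray | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    heavy_only: bool = True,
) -> SasaResult:
    """Per-atom SASA of ``atoms`` occluded by ``context`` (both atom-index arrays).

    Defaults: ``context`` is every non-solvent, non-ion heavy atom and
    ``atoms`` equals the context.  ``atoms`` must be a subset of ``context``.
    With ``heavy_only`` (the default convention) hydrogens are dropped from
    both sets.
    """
    if context is None:
        from .core_io import AtomGroup

        context = system.group_indices(
            AtomGroup.PROTEIN, AtomGroup.BUFFER_NEUTRAL, AtomGroup.BUFFER_CHARGED
        )
    context = np.asarray(context, dtype=int)
    if atoms is None:
        atoms = context
    atoms = np.asarray(atoms, dtype=int)
    if heavy_only:
        heavy = system.heavy_mask
        context = context[heavy[context]]
        atoms = atoms[heavy[atoms]]
    if len(atoms) == 0:
        return SasaResult({}, probe_radius, n_points)
    if not np.isin(atoms, context).all():
        raise ValueError("atoms must be a subset of context")

    coords = frame.coordinates[context]
    radii = system.radii[context]
    pos_in_context = {int(a): k for k, a in enumerate(context)}
    subset = np.array([pos_in_context[int(a)] for a in atoms])
    areas = sasa_from_coords(coords, radii, subset, probe_radius, n_points)
    return SasaResult({int(a): float(v) for a, v in zip(atoms, areas)}, probe_radius, n_points)


def residue_saa(
    sasa: SasaResult, system: MolecularSystem, side_chain_only: bool = True
) -> dict[int, float]:
    """Sum per-atom areas over each residue's (side-chain) atoms."""
    side = system.side_chain_mask()
    out: dict[int, float] = {}
    for res in system.residues:
        total = 0.0
        n_found = 0
        for i in range(res.atom_start, res.atom_stop):
            if side_chain_only and not side[i]:
                continue
            if i in sasa.per_atom:
                total += sasa.per_atom[i]
                n_found += 1
        if side_chain_only and n_found == 0 and res.name == "GLY":
            logger.warning("residue %d (GLY) has no side-chain atoms under heavy-only; area 0", res.index)
        out[res.index] = total
    return out


# ---------------------------------------------------------------------------
# Ala-X-Ala exposure reference
# ---------------------------------------------------------------------------

STANDARD_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# ideal peptide geometry (nm / degrees) used to lay out an extended backbone
_B_N_CA, _B_CA_C, _B_C_N = 0.1458, 0.1525, 0.1329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.0, 116.2, 121.7


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a fourth point from three anchors plus internal coordinates."""
    ang, tor = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _extended_backbone(n_res: int) -> np.ndarray:
    """(n_res, 3, 3) array of N, CA, C positions for a fully extended chain."""
    pts = [np.array([0.0, 0.0, 0.0]), np.array([_B_N_CA, 0.0, 0.0])]
    pts.append(_nerf(pts[0] + np.array([0, 0.1, 0]), pts[0], pts[1], _B_CA_C, _A_N_CA_C, 60.0))
    flat = pts
    # continue N-CA-C-N-CA-C... with all torsions at 180 deg
    kinds = ["N", "CA", "C"]
    bonds = {"N": _B_C_N, "CA": _B_N_CA, "C": _B_CA_C}
    angles = {"N": _A_CA_C_N, "CA": _A_C_N_CA, "C": _A_N_CA_C}
    while len(flat) < 3 * n_res:
        kind = kinds[len(flat) % 3]
        flat.append(_nerf(flat[-3], flat[-2], flat[-1], bonds[kind], angles[kind], 180.0))
    return np.asarray(flat).reshape(n_res, 3, 3)


@lru_cache(maxsize=64)
def _ccd_residue(name: str):
    """Ideal residue geometry (atom names, elements, coords in nm) from the CCD."""
    import biotite.structure.info as info

    try:
        arr = info.residue(name)
    except Exception as exc:
        raise ValueError(
            f"no geometry template for residue {name!r}; available: {', '.join(STANDARD_RESIDUES)}"
        ) from exc
    if arr is None:
        raise ValueError(
            f"no geometry template for residue {name!r}; available: {', '.join(STANDARD_RESIDUES)}"
        )
    return (
        [str(n) for n in arr.atom_name],
        [str(e).upper() for e in arr.element],
        np.asarray(arr.coord, dtype=float) / 10.0,
    )


def _superimpose_on_backbone(names, coords, target_ncac: np.ndarray) -> np.ndarray:
    """Rigid transform mapping the residue's N/CA/C onto target positions."""
    idx = [names.index("N"), names.index("CA"), names.index("C")]
    mobile = coords[idx]
    mob_c, tgt_c = mobile.mean(axis=0), target_ncac.mean(axis=0)
    h = (mobile - mob_c).T @ (target_ncac - tgt_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (coords - mob_c) @ rot.T + tgt_c


def build_trimer(center_residue: str, chi_rotation: float = 0.0) -> tuple[MolecularSystem, Frame]:
    """Build an extended Ala-X-Ala trimer with ideal residue geometry.

    ``chi_rotation`` (degrees) spins the central side chain about the CA-CB
    axis, giving a cheap deterministic conformer ensemble.
    """
    from .core_io import Atom, AtomGroup, Residue

    names_check, _, _ = _ccd_residue(center_residue)
    if not {"N", "CA", "C"}.issubset(names_check):
        raise ValueError(
            f"residue {center_residue!r} is not an amino acid template; "
            f"available: {', '.join(STANDARD_RESIDUES)}"
        )
    backbone = _extended_backbone(3)
    seq = ("ALA", center_residue, "ALA")
    atoms = []
    residues = []
    all_coords: list[np.ndarray] = []
    for ri, resname in enumerate(seq):
        names, elements, coords = _ccd_residue(resname)
        placed = _superimpose_on_backbone(names, coords, backbone[ri])
        keep = [
            k
            for k, n in enumerate(names)
            if not (
                (n in ("OXT", "HXT") and ri != 2)
                or (n == "H2" and ri != 0)
            )
        ]
        if ri == 1 and chi_rotation and "CB" in names:
            ca = placed[names.index("CA")]
            cb = placed[names.index("CB")]
            axis = cb - ca
            axis /= np.linalg.norm(axis)
            rot = _axis_rotation(axis, math.radians(chi_rotation))
            side = [k for k, n in enumerate(names) if n not in BACKBONE_ATOM_NAMES and n != "CB"]
            placed[side] = (placed[side] - cb) @ rot.T + cb
        start = len(atoms)
        for k in keep:
            atoms.append(
                Atom(
                    index=len(atoms),
                    name=names[k],
                    element=elements[k],
                    residue_index=ri,
                    residue_name=resname,
                    chain_id="A",
                    vdw_radius=DEFAULT_VDW_RADII.get(elements[k], 0.17),
                    group=AtomGroup.PROTEIN,
                )
            )
            all_coords.append(placed[k])
        residues.append(Residue(ri, resname, "A", start, len(atoms)))
    system = MolecularSystem(atoms=atoms, residues=residues)
    return system, Frame(coordinates=np.asarray(all_coords), box=None, time=0.0)


def _axis_rotation(axis: np.ndarray, theta: float) -> np.ndarray:
    ux, uy, uz = axis
    c, s = math.cos(theta), math.sin(theta)
    return np.array(
        [
            [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
            [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c), uy * uz * (1 - c) - ux * s],
            [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz * uz * (1 - c)],
        ]
    )


def _free_excipient_saa(
    residue_name: str, probe_radius: float, n_points: int, heavy_only: bool
) -> float:
    names, elements, coords = _ccd_residue(residue_name)
    keep = [k for k in range(len(names)) if not (heavy_only and elements[k] == "H")]
    radii = np.array([DEFAULT_VDW_RADII.get(elements[k], 0.17) for k in keep])
    areas = sasa_from_coords(coords[keep], radii, None, probe_radius, n_points)
    return float(areas.sum())


def build_exposure_reference(
    residue_names: tuple[str, ...] | list[str] = STANDARD_RESIDUES,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    conformers: int = 3,
    heavy_only: bool = True,
    excipient: str = "HIS",
) -> ExposureReference:
    """Fully-exposed side-chain areas from ideal-geometry extended trimers.

    For each residue X the side-chain SAA of the central residue of an
    extended Ala-X-Ala trimer is averaged over ``conformers`` deterministic
    side-chain rotamers.  This is a reconstruction built from ideal geometry
    (no solvent-phase dynamics); per-residue values can always be overridden
    from a user TSV via :meth:`ExposureReference.from_tsv`.

    Glycine has no heavy side-chain atoms, so its reference falls back to
    the H-alpha-bearing definition (hydrogens included for GLY only); the
    value is only ever a denominator for a term whose numerator carries the
    glycine hydrophobicity of exactly 0.
    """
    saa: dict[str, float] = {}
    for name in residue_names:
        vals = []
        n_conf = conformers if name not in ("GLY", "ALA", "PRO") else 1
        for c in range(max(1, n_conf)):
            chi = 360.0 * c / max(1, n_conf)
            system, frame = build_trimer(name, chi_rotation=chi)
            use_heavy = heavy_only and not (name == "GLY")
            sasa = shrake_rupley(
                frame,
                system,
                probe_radius=probe_radius,
                n_points=n_points,
                heavy_only=use_heavy,
            )
            per_res = residue_saa(sasa, system, side_chain_only=True)
            vals.append(per_res[1])
        saa[name] = float(np.mean(vals))
    excipient_area = _free_excipient_saa(excipient, probe_radius, n_points, heavy_only)
    return ExposureReference(saa_exposed=saa, saa_exposed_excipient=excipient_area)
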