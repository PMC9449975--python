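"""Spatial aggregation propensity (SAP) and its buffer-aware extension (BSAP).

SAP of atom ``j`` sums, over residues with side-chain atoms within a
neighborhood radius ``r`` (default 0.5 nm), the residue hydrophobicity
weighted by the in-range side-chain accessible area normalized by the
fully-exposed reference area:

    SAP_j = < sum_res  SAA(side-chain atoms of res within r of j)
                       / SAA_exposed(res) * R_h(res) >_frames

Positive values mark solvent-exposed hydrophobic neighborhoods.  BSAP adds
adsorbed excipient molecules in two ways: their atoms occlude the protein
surface in the SAA term, and every excipient molecule with an atom within a
contact cutoff (default 0.4 nm) of ``j`` contributes its own hydrophobicity
scaled by its instantaneous exposure:

    BSAP_j = SAP_b,j + sum_{adsorbed mol} R_h,exc * SAA(mol) / SAA_exposed,exc

With a hydrophilic excipient (R_h < 0) adsorption can only lower the index,
mirroring the shielding mechanism the index was designed to quantify.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_io import (
    AtomGroup,
    ExposureReference,
    HydrophobicityScale,
    MolecularSystem,
    Trajectory,
)
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, shrake_rupley

__all__ = ["SapMode", "SapResult", "sap", "bsap", "atom_sap", "atom_bsap", "sap_score"]

DEFAULT_SAP_RADIUS = 0.5  # nm
DEFAULT_CONTACT_CUTOFF = 0.4  # nm


class SapMode(enum.Enum):
    SAP = "SAP"
    BSAP = "BSAP"


@dataclass
class SapResult:
    per_atom_sap: dict[int, float]
    per_residue_sap: dict[int, float]
    score: float
    neighborhood_radius: float
    mode: SapMode


def sap_score(per_atom: dict[int, float] | "SapResult") -> float:
    """Aggregate score: sum of the positive per-atom values."""
    values = per_atom.per_atom_sap if isinstance(per_atom, SapResult) else per_atom
    return float(sum(v for v in values.values() if v > 0))


def _per_residue(system: MolecularSystem, per_atom: dict[int, float]) -> dict[int, float]:
    out: dict[int, float] = {}
    for res in system.residues:
        vals = [per_atom[i] for i in range(res.atom_start, res.atom_stop) if i in per_atom]
        if vals:
            out[res.index] = float(np.mean(vals))
    return out


def sap(
    trajectory: Trajectory,
    radius: float = DEFAULT_SAP_RADIUS,
    scale: HydrophobicityScale | None = None,
    reference: ExposureReference | None = None,
    atom_indices: np.ndarray | None = None,
    include_buffer: bool = False,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    excipient_hydrophobicity: float | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    heavy_only: bool = True,
    include_own_residue: bool = True,
) -> SapResult:
    """Frame-averaged SAP (or BSAP with ``include_buffer``) for protein atoms.

    ``atom_indices`` restricts the computed atoms (default: all protein
    atoms, heavy only under the default convention).  ``include_own_residue``
    keeps atom ``j``'s own residue in its neighborhood sum.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    system = trajectory.system
    scale = scale or HydrophobicityScale.black_mould()
    if reference is None:
        from .sasa import build_exposure_reference

        reference = build_exposure_reference()
    if include_buffer and excipient_hydrophobicity is None:
        excipient_hydrophobicity = scale["HIS"]

    protein = set(int(i) for i in system.protein_indices)
    if atom_indices is None:
        atom_indices = system.protein_indices
        if heavy_only:
            atom_indices = atom_indices[system.heavy_mask[atom_indices]]
    atom_indices = np.asarray(atom_indices, dtype=int)
    for j in atom_indices:
        if int(j) not in protein:
            raise ValueError(f"atom {int(j)} is not a protein atom")

    side_mask = system.side_chain_mask()
    if heavy_only:
        side_mask = side_mask & system.heavy_mask
    side_idx = np.flatnonzero(side_mask)
    res_of_side = system.residue_indices[side_idx]
    res_names = {r.index: r.name for r in system.residues}
    # hydrophobicity / exposed-area weight per side-chain atom's residue
    weights = np.array(
        [scale[res_names[r]] / reference[res_names[r]] for r in res_of_side]
    )

    buffer_context = (
        system.group_indices(AtomGroup.BUFFER_NEUTRAL, AtomGroup.BUFFER_CHARGED)
        if include_buffer
        else np.empty(0, dtype=int)
    )
    context = np.concatenate([system.protein_indices, buffer_context]).astype(int)

    accum = np.zeros(len(atom_indices))
    for frame in trajectory.frames:
        sasa = shrake_rupley(
            frame,
            system,
            atoms=context,
            context=context,
            probe_radius=probe_radius,
            n_points=n_points,
            heavy_only=heavy_only,
        )
        areas = np.array([sasa.per_atom.get(int(i), 0.0) for i in side_idx])
        tree = cKDTree(frame.coordinates[side_idx])
        own_res = system.residue_indices[atom_indices]
        contrib = np.zeros(len(atom_indices))
        neighbor_lists = tree.query_ball_point(frame.coordinates[atom_indices], radius)
        for k, nbrs in enumerate(neighbor_lists):
            if not nbrs:
                continue
            nbrs = np.asarray(nbrs, dtype=int)
            if not include_own_residue:
                nbrs = nbrs[res_of_side[nbrs] != own_res[k]]
            contrib[k] = float(np.sum(areas[nbrs] * weights[nbrs]))
        if include_buffer:
            contrib += _buffer_term(
                trajectory, frame, sasa, atom_indices, contact_cutoff,
                excipient_hydrophobicity, reference,
            )
        accum += contrib

    per_atom = {int(j): float(v / len(trajectory.frames)) for j, v in zip(atom_indices, accum)}
    mode = SapMode.BSAP if include_buffer else SapMode.SAP
    return SapResult(
        per_atom_sap=per_atom,
        per_residue_sap=_per_residue(system, per_atom),
        score=sap_score(per_atom),
        neighborhood_radius=radius,
        mode=mode,
    )


def _buffer_term(
    trajectory: Trajectory,
    frame,
    sasa,
    atom_indices: np.ndarray,
    contact_cutoff: float,
    excipient_hydrophobicity: float,
    reference: ExposureReference,
) -> np.ndarray:
    """Hydrophilicity contribution of excipient molecules adsorbed near each atom."""
    system = trajectory.system
    out = np.zeros(len(atom_indices))
    coords_j = frame.coordinates[atom_indices]
    denom = reference.saa_exposed_excipient
    if not np.isfinite(denom) or denom <= 0:
        raise ValueError("reference.saa_exposed_excipient must be positive for BSAP")
    for mol in system.buffer_molecules:
        mol_idx = np.asarray(mol.atom_indices, dtype=int)
        mol_saa = float(sum(sasa.per_atom.get(int(i), 0.0) for i in mol_idx))
        term = excipient_hydrophobicity * mol_saa / denom
        # min distance from each computed atom to any atom of this molecule
        d = np.linalg.norm(
            coords_j[:, None, :] - frame.coordinates[mol_idx][None, :, :], axis=2
        ).min(axis=1)
        out[d <= contact_cutoff] += term
    return out


def bsap(trajectory: Trajectory, **kwargs) -> SapResult:
    """Buffer-aware SAP; see :func:`sap` with ``include_buffer=True``."""
    kwargs["include_buffer"] = True
    return sap(trajectory, **kwargs)


def atom_sap(trajectory: Trajectory, j: int, **kwargs) -> float:
    """SAP of one atom (convenience wrapper over :func:`sap`)."""
    result = sap(trajectory, atom_indices=np.array([j]), **kwargs)
    return result.per_atom_sap[j]


def atom_bsap(trajectory: Trajectory, j: int, **kwargs) -> float:
    """BSAP of one atom (convenience wrapper over :func:`bsap`)."""
    result = bsap(trajectory, atom_indices=np.array([j]), **kwargs)
    return result.per_atom_sap[j]
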