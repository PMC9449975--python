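"""Excipient-affinity scoring of protein surfaces.

A protein fragment's affinity for a free excipient (here neutral histidine)
is scored per interaction type alpha (cation-pi, pi-pi stacking, H-pi) as

    S_alpha = sum_i  -E_i^alpha * <SAA_i> / SAA_exposed_i

where E_i^alpha is the pairwise interaction energy (kcal/mol, negative =
attractive) between the excipient and residue type i, <SAA_i> the
trajectory-averaged accessible area of all residues of type i on the
fragment and SAA_exposed_i the fully-exposed side-chain reference area.
The minus sign makes stronger attraction score higher.  Hydrogen bonding is
scored the same way with the shifted Black & Mould hydrophobicity in place
of the energy (hydrophilic residues, hp < 0, are the hydrogen-bond
partners).

The packaged table ships the energies, hydrophobicities and the Fab/Fc
average-SAA columns for the COE3 antibody fragments, so the printed scores
can be reproduced from their own inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import ExposureReference, Trajectory

__all__ = [
    "InteractionType",
    "InteractionEnergyTable",
    "ScoreBreakdown",
    "load_interaction_table",
    "energy_table_from_dataframe",
    "se_score",
    "hbond_score",
    "saa_avg_from_trajectory",
    "fragment_scores",
]

_TABLE_PATH = Path(__file__).parent / "data" / "his0_interaction_table.tsv"


class InteractionType(str, enum.Enum):
    CATION_PI = "cation_pi"
    PI_PI = "pi_pi"
    H_PI = "h_pi"
    H_BOND = "h_bond"


@dataclass
class InteractionEnergyTable:
    """(interaction_type, residue_name) -> energy (kcal/mol) or, for h_bond
    rows, shifted hydrophobicity (dimensionless)."""

    entries: dict[tuple[InteractionType, str], float]

    def __post_init__(self) -> None:
        for key, val in self.entries.items():
            if not np.isfinite(val):
                raise ValueError(f"non-finite entry for {key}")

    def residues(self, interaction_type: InteractionType) -> list[str]:
        return [r for (t, r) in self.entries if t is interaction_type]

    def __getitem__(self, key: tuple[InteractionType, str]) -> float:
        return self.entries[key]


@dataclass
class ScoreBreakdown:
    interaction_type: InteractionType
    per_residue: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.per_residue.values()))


def load_interaction_table() -> pd.DataFrame:
    """Packaged neutral-histidine interaction inputs as a DataFrame."""
    return pd.read_csv(_TABLE_PATH, sep="\t", comment="#")


def energy_table_from_dataframe(df: pd.DataFrame) -> InteractionEnergyTable:
    entries: dict[tuple[InteractionType, str], float] = {}
    for _, row in df.iterrows():
        itype = InteractionType(row["interaction_type"])
        value = row["hydrophobicity"] if itype is InteractionType.H_BOND else row["energy_kcal_per_mol"]
        entries[(itype, str(row["residue_name"]))] = float(value)
    return InteractionEnergyTable(entries)


def _lookup_exposed(reference, residue: str) -> float:
    if isinstance(reference, ExposureReference):
        table = reference.saa_exposed
    else:
        table = reference
    if residue not in table:
        raise KeyError(f"no fully-exposed reference area for residue {residue!r}")
    return float(table[residue])


def se_score(
    interaction_type: InteractionType | str,
    energies: InteractionEnergyTable,
    saa_avg: Mapping[str, float],
    reference: ExposureReference | Mapping[str, float],
) -> ScoreBreakdown:
    """Energy-based affinity score for one interaction type.

    ``saa_avg`` maps residue type to its trajectory-averaged accessible area
    (nm^2); residues absent from it contribute nothing.
    """
    itype = InteractionType(interaction_type)
    if itype is InteractionType.H_BOND:
        raise ValueError("use hbond_score for hydrogen bonding")
    per_residue: dict[str, float] = {}
    for residue, area in saa_avg.items():
        energy = energies[(itype, residue)]
        per_residue[residue] = -energy * area / _lookup_exposed(reference, residue)
    return ScoreBreakdown(interaction_type=itype, per_residue=per_residue)


def hbond_score(
    hydrophobicities: InteractionEnergyTable,
    saa_avg: Mapping[str, float],
    reference: ExposureReference | Mapping[str, float],
) -> ScoreBreakdown:
    """Hydrogen-bond affinity score: hydrophilicity-weighted exposure."""
    per_residue: dict[str, float] = {}
    for residue, area in saa_avg.items():
        hp = hydrophobicities[(InteractionType.H_BOND, residue)]
        per_residue[residue] = -hp * area / _lookup_exposed(reference, residue)
    return ScoreBreakdown(interaction_type=InteractionType.H_BOND, per_residue=per_residue)


def saa_avg_from_trajectory(
    trajectory: Trajectory,
    residue_names: list[str] | None = None,
    heavy_only: bool = True,
    probe_radius: float | None = None,
    n_points: int | None = None,
) -> dict[str, float]:
    """Frame-averaged combined side-chain SAA per residue *type* (nm^2)."""
    import logging

    from . import sasa as sasa_mod

    probe_radius = probe_radius or sasa_mod.DEFAULT_PROBE_RADIUS
    n_points = n_points or sasa_mod.DEFAULT_N_POINTS
    system = trajectory.system
    present = {r.name for r in system.residues}
    if residue_names is None:
        residue_names = sorted(present)
    totals = {name: 0.0 for name in residue_names}
    for name in residue_names:
        if name not in present:
            logging.getLogger(__name__).warning("residue type %s absent from protein", name)
    for frame in trajectory.frames:
        result = sasa_mod.shrake_rupley(
            frame, system, probe_radius=probe_radius, n_points=n_points, heavy_only=heavy_only
        )
        per_res = sasa_mod.residue_saa(result, system, side_chain_only=True)
        for res in system.residues:
            if res.name in totals:
                totals[res.name] += per_res.get(res.index, 0.0)
    n = len(trajectory.frames)
    return {name: v / n for name, v in totals.items()}


def fragment_scores(
    df: pd.DataFrame | None = None, fragment: str = "fc"
) -> dict[InteractionType, ScoreBreakdown]:
    """All four interaction-type scores for a fragment from a table of inputs.

    ``df`` defaults to the packaged COE3 table; ``fragment`` selects its
    ``saa_fc_avg_nm2`` or ``saa_fab_avg_nm2`` column.  Each interaction type
    uses the exposed-area values of its own rows.
    """
    if df is None:
        df = load_interaction_table()
    col = {"fc": "saa_fc_avg_nm2", "fab": "saa_fab_avg_nm2"}[fragment.lower()]
    energies = energy_table_from_dataframe(df)
    out: dict[InteractionType, ScoreBreakdown] = {}
    for itype in InteractionType:
        rows = df[df["interaction_type"] == itype.value]
        if rows.empty:
            continue
        saa_avg = dict(zip(rows["residue_name"], rows[col].astype(float)))
        reference = dict(zip(rows["residue_name"], rows["saa_exposed_nm2"].astype(float)))
        if itype is InteractionType.H_BOND:
            out[itype] = hbond_score(energies, saa_avg, reference)
        else:
            out[itype] = se_score(itype, energies, saa_avg, reference)
    return out
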