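"""Domain types, structure/trajectory I/O and periodic-distance primitives.

Internal units are nm for lengths and ps for times.  PDB files (Å) are
converted on read and write.  Structures are read through MDAnalysis and
mapped onto the lightweight domain types below; the plain multi-frame
XYZ-with-box dialect used for synthetic trajectories is documented in
:func:`read_xyz_trajectory`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomGroup",
    "Atom",
    "Residue",
    "BufferMolecule",
    "MolecularSystem",
    "Frame",
    "Trajectory",
    "HydrophobicityScale",
    "ExposureReference",
    "FormatError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "min_image_distance",
    "min_image_distance_array",
    "DEFAULT_VDW_RADII",
    "ELEMENT_MASSES",
    "BACKBONE_ATOM_NAMES",
]

_DATA_DIR = Path(__file__).parent / "data"


class FormatError(ValueError):
    """Raised when a structure or trajectory file violates its format."""


class AtomGroup(enum.Enum):
    PROTEIN = "protein"
    BUFFER_NEUTRAL = "buffer_neutral"
    BUFFER_CHARGED = "buffer_charged"
    ION = "ion"
    SOLVENT = "solvent"


# Bondi-style van der Waals radii (nm).  A single documented table keeps
# every accessible-area result reproducible from the repository alone.
DEFAULT_VDW_RADII: dict[str, float] = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "F": 0.147,
    "P": 0.180,
    "S": 0.180,
    "CL": 0.175,
    "BR": 0.185,
    "I": 0.198,
    "NA": 0.227,
    "K": 0.275,
    "MG": 0.173,
    "CA": 0.231,
    "ZN": 0.139,
    "FE": 0.194,
}

ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
}

# Peptide backbone atoms (and their hydrogens).  Glycine's alpha hydrogens
# HA2/HA3 are deliberately left out so its H-alpha-bearing "side chain"
# definition stays available as a reference fallback.
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HXT"})

_ION_RESNAMES = frozenset({"NA", "CL", "K", "MG", "CA", "ZN", "SOD", "CLA", "POT", "NA+", "CL-"})
_SOLVENT_RESNAMES = frozenset({"HOH", "SOL", "WAT", "TIP3", "TIP", "SPC", "T3P"})


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    vdw_radius: float
    group: AtomGroup

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.index} ({self.name}): vdw_radius must be > 0")
        if self.residue_index < 0:
            raise ValueError(f"atom {self.index}: negative residue_index")


@dataclass(frozen=True)
class Residue:
    index: int
    name: str
    chain_id: str
    atom_start: int
    atom_stop: int  # exclusive

    @property
    def atom_indices(self) -> np.ndarray:
        return np.arange(self.atom_start, self.atom_stop)


@dataclass(frozen=True)
class BufferMolecule:
    molecule_id: int
    charge_state: int  # 0 or +1
    atom_indices: tuple[int, ...]


@dataclass
class MolecularSystem:
    """Atoms plus residue and buffer-molecule bookkeeping.

    ``residues`` covers all atoms in file order; ``buffer_molecules`` lists
    excipient molecules with their protonation charge state (0 or +1).
    """

    atoms: list[Atom]
    residues: list[Residue]
    buffer_molecules: list[BufferMolecule] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for mol in self.buffer_molecules:
            if mol.charge_state not in (0, 1):
                raise ValueError(f"buffer molecule {mol.molecule_id}: charge_state must be 0 or +1")
            overlap = seen.intersection(mol.atom_indices)
            if overlap:
                raise ValueError(f"buffer molecule atom sets overlap at atoms {sorted(overlap)[:5]}")
            seen.update(mol.atom_indices)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    # ---- cached array views -------------------------------------------------
    def _cache(self, key: str, build):
        store = self.__dict__.setdefault("_arrays", {})
        if key not in store:
            store[key] = build()
        return store[key]

    @property
    def radii(self) -> np.ndarray:
        return self._cache("radii", lambda: np.array([a.vdw_radius for a in self.atoms]))

    @property
    def masses(self) -> np.ndarray:
        return self._cache(
            "masses", lambda: np.array([ELEMENT_MASSES.get(a.element, 12.011) for a in self.atoms])
        )

    @property
    def elements(self) -> np.ndarray:
        return self._cache("elements", lambda: np.array([a.element for a in self.atoms]))

    @property
    def atom_names(self) -> np.ndarray:
        return self._cache("names", lambda: np.array([a.name for a in self.atoms]))

    @property
    def residue_indices(self) -> np.ndarray:
        return self._cache("resix", lambda: np.array([a.residue_index for a in self.atoms]))

    def group_indices(self, *groups: AtomGroup) -> np.ndarray:
        want = set(groups)
        return np.array([a.index for a in self.atoms if a.group in want], dtype=int)

    @property
    def protein_indices(self) -> np.ndarray:
        return self._cache("protein", lambda: self.group_indices(AtomGroup.PROTEIN))

    @property
    def heavy_mask(self) -> np.ndarray:
        return self._cache("heavy", lambda: np.array([a.element != "H" for a in self.atoms]))

    def side_chain_mask(self) -> np.ndarray:
        """True for protein atoms that are not part of the peptide backbone."""

        def build():
            mask = np.zeros(self.n_atoms, dtype=bool)
            for a in self.atoms:
                if a.group is AtomGroup.PROTEIN and a.name not in BACKBONE_ATOM_NAMES:
                    mask[a.index] = True
            return mask

        return self._cache("sidechain", build)

    def buffer_indices(self, charge_state: int | None = None) -> np.ndarray:
        idx: list[int] = []
        for mol in self.buffer_molecules:
            if charge_state is None or mol.charge_state == charge_state:
                idx.extend(mol.atom_indices)
        return np.array(sorted(idx), dtype=int)


@dataclass
class Frame:
    """One trajectory frame: coordinates (nm), triclinic box matrix (nm), time (ps).

    ``box`` is a 3x3 matrix with row vectors; ``None`` means non-periodic.
    """

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (n, 3) array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3, 3):
                raise ValueError("box must be a 3x3 matrix")
            if np.any(np.diag(self.box) <= 0):
                raise ValueError("box diagonal must be strictly positive")


@dataclass
class Trajectory:
    system: MolecularSystem
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = self.system.n_atoms
        for i, f in enumerate(self.frames):
            if f.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {f.coordinates.shape[0]} coordinates for a {n}-atom system"
                )
        times = [f.time for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def timestep(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return float(self.frames[1].time - self.frames[0].time)


# ---------------------------------------------------------------------------
# Hydrophobicity scale and exposure reference
# ---------------------------------------------------------------------------


@dataclass
class HydrophobicityScale:
    """Per-residue hydrophobicity, shifted so that ``shift_reference`` scores 0.

    The packaged default is the Black & Mould scale shifted so glycine is 0;
    negative values mark hydrophilic residues (arginine, at about -0.50, is
    the most hydrophilic on this scale).
    """

    values: dict[str, float]
    shift_reference: str = "GLY"

    def __post_init__(self) -> None:
        ref = self.values.get(self.shift_reference)
        if ref is None:
            raise ValueError(f"shift reference {self.shift_reference!r} missing from scale")
        if ref != 0.0:
            self.values = {k: v - ref for k, v in self.values.items()}

    def __getitem__(self, residue_name: str) -> float:
        return self.values[residue_name]

    def __contains__(self, residue_name: str) -> bool:
        return residue_name in self.values

    @classmethod
    def black_mould(cls) -> "HydrophobicityScale":
        values = _read_two_column_tsv(_DATA_DIR / "black_mould_scale.tsv")
        return cls(values=values, shift_reference="GLY")


@dataclass
class ExposureReference:
    """Fully-exposed side-chain areas (nm^2) used as score denominators.

    ``saa_exposed[X]`` is the side-chain accessible area of residue X in an
    extended Ala-X-Ala trimer; ``saa_exposed_excipient`` is the accessible
    area of the free excipient molecule in solution.
    """

    saa_exposed: dict[str, float]
    saa_exposed_excipient: float = float("nan")

    def __post_init__(self) -> None:
        for name, area in self.saa_exposed.items():
            if area <= 0:
                raise ValueError(f"saa_exposed[{name}] must be > 0")

    def __getitem__(self, residue_name: str) -> float:
        return self.saa_exposed[residue_name]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# fully exposed side-chain accessible area, nm^2\n")
            fh.write("residue_name\tsaa_exposed_nm2\n")
            for name in sorted(self.saa_exposed):
                fh.write(f"{name}\t{self.saa_exposed[name]:.6f}\n")
            if np.isfinite(self.saa_exposed_excipient):
                fh.write(f"EXCIPIENT\t{self.saa_exposed_excipient:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExposureReference":
        values = _read_two_column_tsv(path)
        excipient = values.pop("EXCIPIENT", float("nan"))
        return cls(saa_exposed=values, saa_exposed_excipient=excipient)


def _read_two_column_tsv(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, val = line.split("\t")[:2]
            try:
                out[key] = float(val)
            except ValueError:
                continue  # header row
    return out


# ---------------------------------------------------------------------------
# Element inference and group assignment
# ---------------------------------------------------------------------------


def infer_element(atom_name: str, residue_name: str = "") -> str:
    """Guess the element from a PDB/GRO atom name.

    Two-letter element names are only accepted for ion-like residues
    (``NA``, ``CL`` ...); otherwise the first alphabetic character wins,
    which correctly maps names like ``CA``, ``CB``, ``NE2``, ``1HB``.
    """
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise FormatError(f"cannot infer element from atom name {atom_name!r}")
    upper = stripped.upper()
    if residue_name.strip().upper() in _ION_RESNAMES and upper[:2] in DEFAULT_VDW_RADII:
        return upper[:2]
    first = upper[0]
    if first not in DEFAULT_VDW_RADII:
        raise FormatError(f"unknown element for atom {atom_name!r} (residue {residue_name!r})")
    return first


def assign_group(residue_name: str, buffer_residues: Mapping[str, int] | None) -> AtomGroup:
    name = residue_name.strip().upper()
    if buffer_residues and name in buffer_residues:
        return AtomGroup.BUFFER_CHARGED if buffer_residues[name] else AtomGroup.BUFFER_NEUTRAL
    if name in _ION_RESNAMES:
        return AtomGroup.ION
    if name in _SOLVENT_RESNAMES:
        return AtomGroup.SOLVENT
    return AtomGroup.PROTEIN


# ---------------------------------------------------------------------------
# Structure reading (PDB / GRO via MDAnalysis)
# ---------------------------------------------------------------------------


def read_structure(
    path: str | Path,
    format: str | None = None,
    buffer_residues: Mapping[str, int] | None = None,
    vdw_radii: Mapping[str, float] | None = None,
) -> tuple[MolecularSystem, Frame]:
    """Read a PDB or GRO file into a system plus its single coordinate frame.

    ``buffer_residues`` maps residue names to charge states (0 or +1), e.g.
    ``{"HIS0": 0, "HISP": 1}``; every residue with such a name becomes one
    buffer molecule.  Elements are taken from the file when present and
    inferred from atom names otherwise; van der Waals radii come from
    ``vdw_radii`` (default: the packaged Bondi-style table).
    """
    import warnings

    import MDAnalysis as mda

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt not in ("PDB", "GRO"):
        raise ValueError(f"unsupported structure format {fmt!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    radii_table = dict(DEFAULT_VDW_RADII)
    if vdw_radii:
        radii_table.update({k.upper(): v for k, v in vdw_radii.items()})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
    except Exception as exc:  # pragma: no cover - message content varies
        raise FormatError(f"cannot parse {path.name} as {fmt}: {exc}") from exc

    atoms: list[Atom] = []
    residues: list[Residue] = []
    buffer_mols: list[BufferMolecule] = []
    res_counter = -1
    mol_counter = 0
    for mda_res in u.residues:
        res_counter += 1
        resname = str(mda_res.resname).strip()
        chain = str(getattr(mda_res.atoms[0], "chainID", "") or getattr(mda_res, "segid", "") or "A").strip() or "A"
        start = len(atoms)
        group = assign_group(resname, buffer_residues)
        for mda_atom in mda_res.atoms:
            name = str(mda_atom.name).strip()
            element = ""
            if hasattr(mda_atom, "element"):
                try:
                    element = str(mda_atom.element).strip().upper()
                except Exception:
                    element = ""
            if not element:
                element = infer_element(name, resname)
            if element not in radii_table:
                raise FormatError(
                    f"unknown element {element!r} for atom {name!r} in residue {resname} {res_counter}"
                )
            atoms.append(
                Atom(
                    index=len(atoms),
                    name=name,
                    element=element,
                    residue_index=res_counter,
                    residue_name=resname,
                    chain_id=chain,
                    vdw_radius=radii_table[element],
                    group=group,
                )
            )
        residues.append(Residue(res_counter, resname, chain, start, len(atoms)))
        if group in (AtomGroup.BUFFER_NEUTRAL, AtomGroup.BUFFER_CHARGED):
            charge = 1 if group is AtomGroup.BUFFER_CHARGED else 0
            buffer_mols.append(BufferMolecule(mol_counter, charge, tuple(range(start, len(atoms)))))
            mol_counter += 1

    coords = u.atoms.positions / 10.0  # A -> nm
    box = _mda_dimensions_to_box(u.dimensions)
    system = MolecularSystem(atoms=atoms, residues=residues, buffer_molecules=buffer_mols)
    return system, Frame(coordinates=coords, box=box, time=0.0)


def _mda_dimensions_to_box(dimensions) -> np.ndarray | None:
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=float)
    if np.all(dims[:3] == 0):
        return None
    from MDAnalysis.lib.mdamath import triclinic_vectors

    return np.asarray(triclinic_vectors(dims), dtype=float) / 10.0  # A -> nm


def box_to_mda_dimensions(box: np.ndarray | None) -> np.ndarray | None:
    if box is None:
        return None
    from MDAnalysis.lib.mdamath import triclinic_box

    b = np.asarray(box, dtype=float) * 10.0  # nm -> A
    return np.asarray(triclinic_box(b[0], b[1], b[2]), dtype=float)


# ---------------------------------------------------------------------------
# Structure writing
# ---------------------------------------------------------------------------


def write_structure(path: str | Path, system: MolecularSystem, frame: Frame, format: str | None = None) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "PDB":
        _write_pdb(path, system, frame)
    elif fmt == "GRO":
        _write_gro(path, system, frame)
    else:
        raise ValueError(f"unsupported structure format {fmt!r}")


def _write_pdb(path: Path, system: MolecularSystem, frame: Frame, bfactors: np.ndarray | None = None) -> None:
    lines: list[str] = []
    if frame.box is not None:
        from MDAnalysis.lib.mdamath import triclinic_box

        a, b, c, alpha, beta, gamma = triclinic_box(*(frame.box * 10.0))
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{alpha:7.2f}{beta:7.2f}{gamma:7.2f} P 1           1"
        )
    coords_a = frame.coordinates * 10.0
    for atom in system.atoms:
        record = "ATOM  " if atom.group is AtomGroup.PROTEIN else "HETATM"
        x, y, z = coords_a[atom.index]
        bf = 0.0 if bfactors is None else float(bfactors[atom.index])
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        lines.append(
            f"{record}{atom.index + 1:5d} {name:<4.4s} {atom.residue_name:<4.4s}"
            f"{atom.chain_id[:1]}{(atom.residue_index % 9999) + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{bf:6.2f}          {atom.element:>2.2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_pdb_with_bfactors(
    path: str | Path, system: MolecularSystem, frame: Frame, values: np.ndarray
) -> None:
    """Write a PDB whose B-factor column carries per-atom scores (for surface coloring)."""
    _write_pdb(Path(path), system, frame, bfactors=np.asarray(values, dtype=float))


def _write_gro(path: Path, system: MolecularSystem, frame: Frame) -> None:
    lines = ["bsapkit structure", f"{system.n_atoms:5d}"]
    for atom in system.atoms:
        x, y, z = frame.coordinates[atom.index]
        lines.append(
            f"{(atom.residue_index % 99999) + 1:5d}{atom.residue_name:<5.5s}"
            f"{atom.name:>5.5s}{(atom.index % 99999) + 1:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    if frame.box is not None:
        b = frame.box
        off_diag = b[np.where(~np.eye(3, dtype=bool))]
        if np.allclose(off_diag, 0.0):
            lines.append(f"{b[0,0]:10.5f}{b[1,1]:10.5f}{b[2,2]:10.5f}")
        else:
            lines.append(
                " ".join(f"{v:10.5f}" for v in [b[0, 0], b[1, 1], b[2, 2], b[0, 1], b[0, 2], b[1, 0], b[1, 2], b[2, 0], b[2, 1]])
            )
    else:
        lines.append(f"{0.0:10.5f}{0.0:10.5f}{0.0:10.5f}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Trajectory reading / writing
# ---------------------------------------------------------------------------


def read_trajectory(
    path: str | Path,
    system: MolecularSystem,
    format: str | None = None,
    timestep: float = 1.0,
    lenient: bool = False,
) -> Trajectory:
    """Read an XTC, DCD or XYZ-with-box trajectory over ``system``.

    Times are taken from the file where the format stores them (XTC) and
    synthesized as ``frame_index * timestep`` (ps) otherwise.  ``lenient``
    keeps complete frames preceding a truncated final frame instead of
    raising.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "XYZ":
        return read_xyz_trajectory(path, system, timestep=timestep, lenient=lenient)
    if fmt not in ("XTC", "DCD"):
        raise ValueError(f"unsupported trajectory format {fmt!r}")

    if fmt == "XTC":
        from MDAnalysis.coordinates.XTC import XTCReader as Reader
    else:
        from MDAnalysis.coordinates.DCD import DCDReader as Reader

    frames: list[Frame] = []
    with Reader(str(path)) as reader:
        if reader.n_atoms != system.n_atoms:
            raise FormatError(
                f"trajectory has {reader.n_atoms} atoms but system has {system.n_atoms}"
            )
        for i, ts in enumerate(reader):
            t = float(ts.time) if fmt == "XTC" else i * timestep
            frames.append(
                Frame(
                    coordinates=ts.positions / 10.0,
                    box=_mda_dimensions_to_box(ts.dimensions),
                    time=t,
                )
            )
    if frames and frames[0].time == frames[-1].time and len(frames) > 1:
        for i, f in enumerate(frames):  # XTC written without times
            f.time = i * timestep
    return Trajectory(system=system, frames=frames)


def read_xyz_trajectory(
    path: str | Path, system: MolecularSystem, timestep: float = 1.0, lenient: bool = False
) -> Trajectory:
    """Read the plain-text multi-frame XYZ-with-box dialect.

    Per frame::

        <n_atoms>
        time=<ps> box=<lx> <ly> <lz>
        <atom name> <x> <y> <z>        # nm, one line per atom

    An absent ``time=`` field synthesizes times from ``timestep``; an absent
    ``box=`` field means non-periodic.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path.name}:{i + 1}: expected atom count, got {lines[i]!r}")
        if n != system.n_atoms:
            raise FormatError(
                f"{path.name}:{i + 1}: frame has {n} atoms but system has {system.n_atoms}"
            )
        if i + 1 + n >= len(lines) + 1 and len(lines) - (i + 2) < n:
            if lenient:
                break
            raise FormatError(f"{path.name}: truncated final frame (frame {frame_no})")
        comment = lines[i + 1]
        time = frame_no * timestep
        box = None
        for token in comment.split():
            if token.startswith("time="):
                time = float(token[5:])
        if "box=" in comment:
            tail = comment.split("box=")[1].split()
            box = np.diag([float(v) for v in tail[:3]])
        coords = np.empty((n, 3))
        ok = True
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                if lenient:
                    ok = False
                    break
                raise FormatError(f"{path.name}:{i + 3 + k}: malformed atom line")
            coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if not ok:
            break
        frames.append(Frame(coordinates=coords, box=box, time=time))
        frame_no += 1
        i += 2 + n
    return Trajectory(system=system, frames=frames)


def write_trajectory(path: str | Path, trajectory: Trajectory, format: str | None = None) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "XYZ":
        _write_xyz(path, trajectory)
    elif fmt == "XTC":
        import MDAnalysis as mda
        from MDAnalysis.coordinates.XTC import XTCWriter

        n = trajectory.system.n_atoms
        u = mda.Universe.empty(n, trajectory=True)
        with XTCWriter(str(path), n_atoms=n) as writer:
            for i, frame in enumerate(trajectory.frames):
                u.atoms.positions = frame.coordinates * 10.0
                dims = box_to_mda_dimensions(frame.box)
                if dims is not None:
                    u.trajectory.ts.dimensions = dims
                u.trajectory.ts.time = frame.time
                u.trajectory.ts.frame = i
                writer.write(u.atoms)
    else:
        raise ValueError(f"unsupported trajectory output format {fmt!r}")


def _write_xyz(path: Path, trajectory: Trajectory) -> None:
    names = trajectory.system.atom_names
    with open(path, "w") as fh:
        for frame in trajectory.frames:
            fh.write(f"{trajectory.system.n_atoms}\n")
            comment = f"time={frame.time:g}"
            if frame.box is not None:
                d = np.diag(frame.box)
                comment += f" box={d[0]:g} {d[1]:g} {d[2]:g}"
            fh.write(comment + "\n")
            for name, (x, y, z) in zip(names, frame.coordinates):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Minimum-image distances
# ---------------------------------------------------------------------------


def min_image_distance(a: Sequence[float], b: Sequence[float], box: np.ndarray | None = None) -> float:
    """Minimum-image Euclidean distance between two points (nm).

    Handles triclinic boxes by wrapping the displacement into the central
    cell in fractional coordinates and then scanning the 27 neighbor images;
    with ``box=None`` this is the plain Euclidean distance.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box is None:
        return float(np.linalg.norm(d))
    box = np.asarray(box, dtype=float)
    frac = np.linalg.solve(box.T, d)
    frac -= np.round(frac)
    shifts = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1])).T.reshape(-1, 3)
    cands = (frac + shifts) @ box
    return float(np.min(np.linalg.norm(cands, axis=1)))


def min_image_distance_array(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None
) -> np.ndarray:
    """All-pairs minimum-image distances between coordinate sets (nm)."""
    from MDAnalysis.lib.distances import distance_array

    a = np.ascontiguousarray(np.asarray(a, dtype=np.float32) * 10.0)
    b = np.ascontiguousarray(np.asarray(b, dtype=np.float32) * 10.0)
    dims = box_to_mda_dimensions(box)
    return distance_array(a, b, box=dims).astype(float) / 10.0
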