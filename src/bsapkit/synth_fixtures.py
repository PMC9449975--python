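"""Deterministic synthetic fixtures for the whole toolkit.

Every generator is a pure function of its arguments (fixed seed means
byte-identical output), so the full analysis pipeline can be exercised
without any external data: toy proteins with idealized geometry, protein +
excipient trajectories whose adsorption kinetics are known exactly,
forward-generated survival curves and Ornstein-Uhlenbeck pressure series
with a closed-form Green-Kubo viscosity.

The adsorption generator emulates the bound/unbound telegraph dynamics of
an excipient molecule near a protein surface: bound dwells place the
molecule with a controlled minimum distance strictly inside the contact
cutoff, unbound dwells strictly outside, and the true event list is
returned alongside the trajectory for oracle tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .adsorption import ResidenceEvent, _double_stretched
from .core_io import (
    DEFAULT_VDW_RADII,
    Atom,
    AtomGroup,
    BufferMolecule,
    Frame,
    MolecularSystem,
    Residue,
    Trajectory,
)
from .sasa import _extended_backbone, _nerf

__all__ = [
    "FixtureSpec",
    "make_toy_protein",
    "make_adsorption_trajectory",
    "make_survival_curve",
    "make_ou_pressure_series",
    "BUFFER_RESNAME_NEUTRAL",
    "BUFFER_RESNAME_CHARGED",
]

BUFFER_RESNAME_NEUTRAL = "HS0"
BUFFER_RESNAME_CHARGED = "HSP"

_NO_CB = {"GLY"}


@dataclass
class FixtureSpec:
    """Bundled generator parameters; fixed seed gives byte-identical output."""

    seed: int = 0
    n_frames: int = 100
    timestep: float = 10.0  # ps
    box_length: float = 12.0  # nm
    sequence: tuple[str, ...] = ("ALA", "GLY", "ALA")
    geometry: str = "extended"
    n_neutral: int = 1
    n_charged: int = 0
    kinetics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Toy proteins
# ---------------------------------------------------------------------------


def _backbone_chain(n_res: int, phi: float, psi: float, omega: float = 180.0) -> np.ndarray:
    """(n_res, 3, 3) N/CA/C positions for uniform backbone torsions."""
    from .sasa import _A_C_N_CA, _A_CA_C_N, _A_N_CA_C, _B_C_N, _B_CA_C, _B_N_CA

    pts = [np.array([0.0, 0.0, 0.0]), np.array([_B_N_CA, 0.0, 0.0])]
    pts.append(_nerf(pts[0] + np.array([0, 0.1, 0]), pts[0], pts[1], _B_CA_C, _A_N_CA_C, 60.0))
    torsions = {"N": psi, "CA": omega, "C": phi}
    bonds = {"N": _B_C_N, "CA": _B_N_CA, "C": _B_CA_C}
    angles = {"N": _A_CA_C_N, "CA": _A_C_N_CA, "C": _A_N_CA_C}
    kinds = ["N", "CA", "C"]
    while len(pts) < 3 * n_res:
        kind = kinds[len(pts) % 3]
        pts.append(_nerf(pts[-3], pts[-2], pts[-1], bonds[kind], angles[kind], torsions[kind]))
    return np.asarray(pts).reshape(n_res, 3, 3)


def make_toy_protein(
    sequence: list[str] | tuple[str, ...],
    geometry: str = "extended",
    seed: int = 0,
) -> tuple[MolecularSystem, Frame]:
    """Idealized toy protein: backbone N/CA/C/O plus one CB pseudo side-chain
    atom per residue (except glycine).

    ``geometry``: ``extended`` (all torsions 180 deg), ``helix``
    (phi/psi = -57/-47) or ``globule`` (seeded compact random placement).
    """
    sequence = tuple(s.upper() for s in sequence)
    if not sequence:
        raise ValueError("sequence must be nonempty")
    from .sasa import STANDARD_RESIDUES

    unknown = [s for s in sequence if s not in STANDARD_RESIDUES]
    if unknown:
        raise ValueError(f"unknown residue(s) {unknown}; templates: {STANDARD_RESIDUES}")

    n = len(sequence)
    rng = np.random.default_rng(seed)
    if geometry == "extended":
        backbone = _extended_backbone(n)
    elif geometry == "helix":
        backbone = _backbone_chain(n, phi=-57.0, psi=-47.0)
    elif geometry == "globule":
        radius = 0.30 * n ** (1.0 / 3.0)
        centers = rng.uniform(-radius, radius, size=(n, 3))
        local = _extended_backbone(1)[0] - _extended_backbone(1)[0].mean(axis=0)
        backbone = centers[:, None, :] + local[None, :, :]
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    atoms: list[Atom] = []
    residues: list[Residue] = []
    coords: list[np.ndarray] = []

    def add(name: str, element: str, pos: np.ndarray, ri: int, resname: str) -> None:
        atoms.append(
            Atom(
                index=len(atoms), name=name, element=element, residue_index=ri,
                residue_name=resname, chain_id="A",
                vdw_radius=DEFAULT_VDW_RADII[element], group=AtomGroup.PROTEIN,
            )
        )
        coords.append(pos)

    for ri, resname in enumerate(sequence):
        start = len(atoms)
        n_pos, ca_pos, c_pos = backbone[ri]
        add("N", "N", n_pos, ri, resname)
        add("CA", "C", ca_pos, ri, resname)
        add("C", "C", c_pos, ri, resname)
        add("O", "O", _nerf(n_pos, ca_pos, c_pos, 0.1229, 120.5, -45.0), ri, resname)
        if resname not in _NO_CB:
            add("CB", "C", _nerf(c_pos, n_pos, ca_pos, 0.1530, 110.5, 122.5), ri, resname)
        residues.append(Residue(ri, resname, "A", start, len(atoms)))

    system = MolecularSystem(atoms=atoms, residues=residues)
    return system, Frame(coordinates=np.asarray(coords), box=None, time=0.0)


# ---------------------------------------------------------------------------
# Adsorption trajectories with known kinetics
# ---------------------------------------------------------------------------


def _sample_dwell(rng, distribution: str, mean: float, mu: float) -> float:
    """Dwell time (ps): exponential with the given mean, or stretched
    (Weibull) with shape ``mu`` and the same mean."""
    if distribution == "exponential":
        return float(rng.exponential(mean))
    if distribution == "stretched":
        # Weibull survival exp(-(t/lam)^mu) has mean lam * Gamma(1 + 1/mu)
        lam = mean / math.gamma(1.0 + 1.0 / mu)
        return float(lam * (-np.log(rng.uniform())) ** (1.0 / mu))
    raise ValueError(f"unknown dwell distribution {distribution!r}")


def make_adsorption_trajectory(
    system: MolecularSystem,
    protein_frame: Frame,
    k_on: float,
    n_frames: int,
    seed: int = 0,
    timestep: float = 10.0,
    dwell_distribution: str = "exponential",
    dwell_mean: float = 100.0,
    dwell_mu: float = 0.5,
    n_neutral: int = 1,
    n_charged: int = 0,
    r_cut: float = 0.4,
    grazing: bool = False,
    start_bound: bool = False,
) -> tuple[Trajectory, dict[int, list[ResidenceEvent]]]:
    """Protein + single-atom excipient trajectory with telegraph kinetics.

    Each excipient molecule alternates unbound dwells (rate ``k_on`` per ps;
    0 disables binding) and bound dwells drawn from ``dwell_distribution``.
    Dwells are quantized to whole frames (minimum one).  Bound frames place
    the molecule with d_min strictly inside [0.25, r_cut) nm, unbound frames
    in [1.5 * r_cut, 2] nm; ``grazing`` lets bound frames sit exactly at
    d_min = r_cut with 10% probability, exercising the boundary tie rule
    (d_min == r_cut counts as adsorbed).

    Returns the trajectory and, per molecule id, the true residence events.
    """
    if dwell_mean <= 0 or k_on < 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(seed)
    prot_coords = protein_frame.coordinates[system.protein_indices]

    n_buffer = n_neutral + n_charged
    atoms = list(system.atoms)
    residues = list(system.residues)
    buffer_mols: list[BufferMolecule] = []
    next_res = max(r.index for r in residues) + 1
    for b in range(n_buffer):
        charged = b >= n_neutral
        resname = BUFFER_RESNAME_CHARGED if charged else BUFFER_RESNAME_NEUTRAL
        group = AtomGroup.BUFFER_CHARGED if charged else AtomGroup.BUFFER_NEUTRAL
        idx = len(atoms)
        atoms.append(
            Atom(
                index=idx, name="N1", element="N", residue_index=next_res,
                residue_name=resname, chain_id="B",
                vdw_radius=DEFAULT_VDW_RADII["N"], group=group,
            )
        )
        residues.append(Residue(next_res, resname, "B", idx, idx + 1))
        buffer_mols.append(BufferMolecule(b, int(charged), (idx,)))
        next_res += 1
    full_system = MolecularSystem(atoms=atoms, residues=residues, buffer_molecules=buffer_mols)

    # box large enough that no periodic image comes closer than the real one
    span = prot_coords.max(axis=0) - prot_coords.min(axis=0)
    box_len = float(span.max() + 6.0)
    box = np.diag([box_len] * 3)
    shift = -prot_coords.min(axis=0) + 1.0  # keep everything in the box

    # per-molecule state series and ground-truth events
    bound = np.zeros((n_buffer, n_frames), dtype=bool)
    truth: dict[int, list[ResidenceEvent]] = {m.molecule_id: [] for m in buffer_mols}
    for b, mol in enumerate(buffer_mols):
        f = 0
        state_bound = start_bound
        while f < n_frames:
            if state_bound:
                dwell = _sample_dwell(rng, dwell_distribution, dwell_mean, dwell_mu)
            else:
                if k_on <= 0:
                    break
                dwell = float(rng.exponential(1.0 / k_on))
            nf = max(1, int(round(dwell / timestep)))
            end = min(f + nf, n_frames)
            if state_bound:
                bound[b, f:end] = True
                truth[mol.molecule_id].append(
                    ResidenceEvent(mol.molecule_id, f, end - 1, (end - f) * timestep)
                )
            f = end
            state_bound = not state_bound

    # geometry: place each excipient along an outward direction u at an exact
    # minimum distance d: with p = argmax_u (u . r) over protein atoms, the
    # point r_p + d u is at distance d from p and >= d from every other atom.
    frames: list[Frame] = []
    directions = rng.normal(size=(n_buffer, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    support = np.array([int(np.argmax(prot_coords @ u)) for u in directions])
    coords_buffer = np.empty((n_frames, n_buffer, 3))
    for b in range(n_buffer):
        u = directions[b]
        p = prot_coords[support[b]]
        for f in range(n_frames):
            if bound[b, f]:
                if grazing and rng.uniform() < 0.1:
                    d = r_cut
                else:
                    d = rng.uniform(0.25, r_cut * 0.999)
            else:
                d = rng.uniform(1.5 * r_cut, 2.0)
            coords_buffer[f, b] = p + d * u
    for f in range(n_frames):
        coords = np.vstack([protein_frame.coordinates, coords_buffer[f]]) + shift
        frames.append(Frame(coordinates=coords, box=box.copy(), time=f * timestep))
    return Trajectory(system=full_system, frames=frames), truth


# ---------------------------------------------------------------------------
# Forward-generated survival curves and OU pressure series
# ---------------------------------------------------------------------------


def make_survival_curve(
    amplitude: float,
    k1: float,
    mu1: float,
    k2: float,
    mu2: float,
    t_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Exact double-stretched-exponential curve on ``t_grid`` (ps), with
    optional Gaussian noise clipped to [0, 1]; rates in 1/ns.  S(0) = 1."""
    from .adsorption import SurvivalCurve

    t_grid = np.asarray(t_grid, dtype=float)
    S = _double_stretched(t_grid / 1000.0, amplitude, k1, mu1, k2, mu2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        S = np.clip(S + rng.normal(0.0, noise_sd, size=S.shape), 0.0, 1.0)
    S[t_grid == 0.0] = 1.0
    return SurvivalCurve(lag_times=t_grid, S=S, n_origins=1)


def make_ou_pressure_series(
    sigma: float, tau_c: float, dt: float, n: int, seed: int = 0, n_components: int = 3
) -> np.ndarray:
    """(n_components, n) exact-discretization Ornstein-Uhlenbeck series.

    Stationary variance sigma^2 (bar^2), correlation time tau_c (ps),
    sample spacing dt (ps).  The Green-Kubo integral of such a series over
    t_max >> tau_c is sigma^2 * tau_c.
    """
    if sigma <= 0 or tau_c <= 0 or dt <= 0 or n <= 0:
        raise ValueError("all OU parameters must be positive")
    from scipy.signal import lfilter

    rng = np.random.default_rng(seed)
    rho = math.exp(-dt / tau_c)
    innov_sd = sigma * math.sqrt(1.0 - rho * rho)
    out = np.empty((n_components, n))
    for c in range(n_components):
        w = rng.normal(0.0, innov_sd, size=n)
        w[0] = rng.normal(0.0, sigma)  # stationary start
        out[c] = lfilter([1.0], [1.0, -rho], w)
    return out
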