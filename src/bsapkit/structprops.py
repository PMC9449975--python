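"""Structural and physicochemical observables.

Radius of gyration, interdomain hinge angle, surface-referenced radial
distribution, Green-Kubo shear viscosity from a pressure-tensor series and
Henderson-Hasselbalch buffer composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Frame, Trajectory, min_image_distance_array

__all__ = [
    "AngleDefinition",
    "SurfaceRdf",
    "radius_of_gyration",
    "fab_fc_angle",
    "surface_rdf",
    "green_kubo_viscosity",
    "charged_fraction",
    "buffer_molecule_count",
]

K_BOLTZMANN = 1.380649e-23  # J/K
N_AVOGADRO = 6.02214076e23  # 1/mol


@dataclass(frozen=True)
class AngleDefinition:
    """Four anchor points, each the center of mass of an atom-index set.

    The hinge angle is measured between the vectors A->B and C->D; for an
    antibody, A/B anchor disulfide cystine pairs on one domain and C/D on
    the other.
    """

    a: tuple[int, ...]
    b: tuple[int, ...]
    c: tuple[int, ...]
    d: tuple[int, ...]

    def __post_init__(self) -> None:
        sets = [set(self.a), set(self.b), set(self.c), set(self.d)]
        if any(len(s) == 0 for s in sets):
            raise ValueError("every anchor set must be nonempty")
        for i in range(4):
            for j in range(i + 1, 4):
                if sets[i] & sets[j]:
                    raise ValueError("anchor sets must be disjoint")


@dataclass
class SurfaceRdf:
    """Distance-from-surface histogram: pair counts per bin width (1/nm)."""

    bin_edges: np.ndarray  # nm
    counts_per_width: np.ndarray  # pairs / nm

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts_per_width = np.asarray(self.counts_per_width, dtype=float)
        if np.any(self.counts_per_width < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def radius_of_gyration(
    frame: Frame,
    selection: np.ndarray,
    masses: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> float:
    """Mass-weighted radius of gyration (nm) of the selected atoms."""
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ValueError("empty selection")
    coords = frame.coordinates[selection]
    if mass_weighted and masses is not None:
        m = np.asarray(masses, dtype=float)
        m = m[selection] if len(m) != len(selection) else m
    else:
        m = np.ones(len(selection))
    com = np.average(coords, axis=0, weights=m)
    sq = ((coords - com) ** 2).sum(axis=1)
    return float(np.sqrt(np.average(sq, weights=m)))


def fab_fc_angle(
    frame: Frame, definition: AngleDefinition, masses: np.ndarray | None = None
) -> float:
    """Angle (radians, in [0, pi]) between the anchor vectors A->B and C->D."""

    def com(indices: tuple[int, ...]) -> np.ndarray:
        idx = np.asarray(indices, dtype=int)
        w = np.ones(len(idx)) if masses is None else np.asarray(masses, dtype=float)[idx]
        return np.average(frame.coordinates[idx], axis=0, weights=w)

    v1 = com(definition.b) - com(definition.a)
    v2 = com(definition.d) - com(definition.c)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length anchor vector")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.arccos(cosang))


def surface_rdf(
    trajectory: Trajectory,
    reference_group: np.ndarray,
    target_group: np.ndarray,
    bin_width: float = 0.01,
    r_max: float = 3.0,
) -> SurfaceRdf:
    """Distribution of target atoms by minimum distance to the reference surface.

    For every target atom and frame, the minimum-image distance to the
    nearest reference atom is binned; counts are averaged over frames and
    divided by the bin width (a gmx-rdf-like convention; no volume
    normalization).
    """
    reference_group = np.asarray(reference_group, dtype=int)
    target_group = np.asarray(target_group, dtype=int)
    if len(reference_group) == 0 or len(target_group) == 0:
        raise ValueError("reference and target groups must be nonempty")
    if set(reference_group) & set(target_group):
        raise ValueError("reference and target groups must be disjoint")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for frame in trajectory.frames:
        d = min_image_distance_array(
            frame.coordinates[target_group], frame.coordinates[reference_group], frame.box
        ).min(axis=1)
        hist, _ = np.histogram(d, bins=edges)
        counts += hist
    counts /= len(trajectory.frames)
    return SurfaceRdf(bin_edges=edges, counts_per_width=counts / bin_width)


def _autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased-origin-averaged autocorrelation <x(0) x(t)> via FFT."""
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acf / (n - np.arange(max_lag + 1))


def green_kubo_viscosity(
    pressure_series: np.ndarray,
    volume: float,
    temperature: float,
    t_max: float,
    timestep: float,
) -> float:
    """Shear viscosity (mPa s) from off-diagonal pressure components.

    eta = V / (k_B T) * integral_0^t_max <P_ab(0) P_ab(t)> dt, with the
    autocorrelation averaged over all supplied components and over time
    origins, integrated by the trapezoidal rule.

    Units: ``pressure_series`` (n_components, n_samples) in bar on a uniform
    grid of ``timestep`` ps, ``volume`` in nm^3, ``temperature`` in K,
    ``t_max`` in ps.
    """
    p = np.atleast_2d(np.asarray(pressure_series, dtype=float))
    if p.shape[0] < 3:
        raise ValueError("need at least 3 off-diagonal pressure components")
    if timestep <= 0:
        raise ValueError("timestep must be positive and uniform")
    max_lag = int(round(t_max / timestep))
    if max_lag >= p.shape[1]:
        raise ValueError("t_max exceeds the span of the series")
    acf = np.mean([_autocorrelation(row, max_lag) for row in p], axis=0)
    integral = np.trapezoid(acf, dx=timestep)  # bar^2 ps
    # bar^2 ps * nm^3 / (k_B T) -> Pa s: (1e5)^2 * 1e-12 * 1e-27 = 1e-29
    eta_pa_s = volume * integral / (K_BOLTZMANN * temperature) * 1e-29
    return float(eta_pa_s * 1e3)  # mPa s


def charged_fraction(pH: float, pKa: float) -> float:
    """Henderson-Hasselbalch fraction of the protonated (charged) species."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def buffer_molecule_count(
    concentration: float, box_volume: float, charged_frac: float
) -> tuple[int, int]:
    """(n_charged, n_neutral) buffer molecules for a concentration (mol/L)
    in a box of ``box_volume`` nm^3, split by the charged fraction."""
    import warnings

    if concentration < 0 or box_volume <= 0 or not (0 <= charged_frac <= 1):
        raise ValueError("inputs out of range")
    n_total = int(round(concentration * box_volume * 1e-24 * N_AVOGADRO))
    if n_total == 0:
        warnings.warn("buffer concentration rounds to zero molecules")
    n_charged = int(round(n_total * charged_frac))
    return n_charged, n_total - n_charged
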