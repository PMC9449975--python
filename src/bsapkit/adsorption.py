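"""Excipient adsorption and desorption analysis.

An excipient molecule is adsorbed when the shortest atomic-pair distance to
the protein, d_min, is at or below a cutoff (default 0.4 nm, wide enough to
cover both hydrogen bonds and salt bridges).  Maximal runs of adsorbed
frames are residence events; a departure and return starts a new event.
The survival probability S(t) is the fraction of contacts existing at a
time origin that remain *continuously* intact after a lag t, and is fitted
with a double stretched exponential

    S(t) = A exp(-(k1 t)^mu1) + (1 - A) exp(-(k2 t)^mu2)

whose two terms capture the short- and long-time decays; exponents mu < 1
signal non-Markovian desorption.  The per-residue Buffer Adsorption Index

    BAI_i = -ln(N_avg_i / N_max)        [k_B T]

turns frame-averaged atomic contact counts into a relative free energy of
contact formation; the residue with the most contacts defines the zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core_io import Trajectory, min_image_distance_array

__all__ = [
    "MinDistanceSeries",
    "ResidenceEvent",
    "SurvivalCurve",
    "DesorptionFit",
    "BaiResult",
    "min_distance_series",
    "residence_events",
    "contact_series",
    "survival_probability",
    "survival_from_contact_matrix",
    "fit_desorption",
    "mean_residence_time",
    "contact_counts",
    "bai",
]

DEFAULT_R_CUT = 0.4  # nm


@dataclass
class MinDistanceSeries:
    buffer_molecule_id: int
    times: np.ndarray  # ps
    d_min: np.ndarray  # nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.d_min = np.asarray(self.d_min, dtype=float)
        if self.times.shape != self.d_min.shape:
            raise ValueError("times and d_min must have equal length")
        if np.any(self.d_min < 0):
            raise ValueError("d_min must be non-negative")


@dataclass(frozen=True)
class ResidenceEvent:
    """One maximal adsorbed run; tau_r = (end - start + 1) * dt."""

    buffer_molecule_id: int
    start_frame: int
    end_frame: int
    tau_r: float  # ps


@dataclass
class SurvivalCurve:
    lag_times: np.ndarray  # ps
    S: np.ndarray
    n_origins: int

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if abs(self.S[0] - 1.0) > 1e-9:
            raise ValueError("S(0) must equal 1")
        if np.any(self.S < -1e-12) or np.any(self.S > 1 + 1e-12):
            raise ValueError("S must lie in [0, 1]")


@dataclass
class DesorptionFit:
    amplitude: float
    k1: float  # ns^-1
    k2: float  # ns^-1
    mu1: float
    mu2: float
    stderr: dict[str, float] = field(default_factory=dict)
    residual: float = 0.0

    def evaluate(self, t_ns: np.ndarray) -> np.ndarray:
        return _double_stretched(t_ns, self.amplitude, self.k1, self.mu1, self.k2, self.mu2)


@dataclass
class BaiResult:
    per_residue_n_avg: dict[int, float]
    n_max: float
    per_residue_bai: dict[int, float]  # k_BT; +inf sentinel for zero counts
    charge_state: int

    @property
    def finite_bai(self) -> dict[int, float]:
        return {r: v for r, v in self.per_residue_bai.items() if np.isfinite(v)}


# ---------------------------------------------------------------------------
# Distances and events
# ---------------------------------------------------------------------------


def min_distance_series(trajectory: Trajectory, buffer_molecule: int) -> MinDistanceSeries:
    """Per-frame shortest atomic-pair distance between one excipient molecule
    and the protein (minimum-image under the frame's box)."""
    system = trajectory.system
    try:
        mol = next(m for m in system.buffer_molecules if m.molecule_id == buffer_molecule)
    except StopIteration:
        raise ValueError(f"no buffer molecule with id {buffer_molecule}")
    mol_idx = np.asarray(mol.atom_indices, dtype=int)
    prot_idx = system.protein_indices
    d = np.empty(len(trajectory.frames))
    for fi, frame in enumerate(trajectory.frames):
        dm = min_image_distance_array(
            frame.coordinates[mol_idx], frame.coordinates[prot_idx], frame.box
        )
        d[fi] = dm.min()
    return MinDistanceSeries(buffer_molecule, trajectory.times, d)


def residence_events(series: MinDistanceSeries, r_cut: float = DEFAULT_R_CUT) -> list[ResidenceEvent]:
    """Maximal runs of consecutive frames with d_min <= r_cut.

    The boundary counts as adsorbed (d_min == r_cut is a contact).  The
    duration convention is tau_r = n_frames_in_event * dt.
    """
    if r_cut <= 0:
        raise ValueError("r_cut must be > 0")
    adsorbed = series.d_min <= r_cut
    dt = float(series.times[1] - series.times[0]) if len(series.times) > 1 else 0.0
    events: list[ResidenceEvent] = []
    start = None
    for i, a in enumerate(adsorbed):
        if a and start is None:
            start = i
        elif not a and start is not None:
            events.append(ResidenceEvent(series.buffer_molecule_id, start, i - 1, (i - start) * dt))
            start = None
    if start is not None:
        n = len(adsorbed)
        events.append(ResidenceEvent(series.buffer_molecule_id, start, n - 1, (n - start) * dt))
    return events


def contact_series(
    trajectory: Trajectory, charge_state: int | None = None, r_cut: float = DEFAULT_R_CUT
) -> tuple[np.ndarray, list[int]]:
    """Boolean (n_molecules, n_frames) adsorption matrix for the charge state."""
    system = trajectory.system
    ids = [m.molecule_id for m in system.buffer_molecules if charge_state is None or m.charge_state == charge_state]
    mat = np.zeros((len(ids), len(trajectory.frames)), dtype=bool)
    for row, mol_id in enumerate(ids):
        series = min_distance_series(trajectory, mol_id)
        mat[row] = series.d_min <= r_cut
    return mat, ids


# ---------------------------------------------------------------------------
# Survival probability
# ---------------------------------------------------------------------------


def survival_from_contact_matrix(
    contacts: np.ndarray,
    timestep: float,
    multi_origin: bool = True,
    origin_stride: int = 1,
    max_lag: int | None = None,
) -> SurvivalCurve:
    """S(t) from a boolean (molecules, frames) adsorption matrix.

    A molecule adsorbed at an origin frame survives lag L if it stays
    adsorbed in every frame up to the origin plus L.  With ``multi_origin``
    every ``origin_stride``-th frame with a contact serves as an origin.
    """
    contacts = np.asarray(contacts, dtype=bool)
    n_mol, n_frames = contacts.shape
    if max_lag is None:
        max_lag = n_frames - 1
    # remaining[m, f]: frames (incl. f) the contact persists from f onward
    remaining = np.zeros((n_mol, n_frames), dtype=int)
    for m in range(n_mol):
        run = 0
        for f in range(n_frames - 1, -1, -1):
            run = run + 1 if contacts[m, f] else 0
            remaining[m, f] = run
    origins = range(0, n_frames if multi_origin else 1, origin_stride)
    counts = np.zeros(max_lag + 1)
    totals = np.zeros(max_lag + 1)
    n_origins = 0
    for t0 in origins:
        active = remaining[:, t0]
        on = active > 0
        n_on = int(on.sum())
        if n_on == 0:
            continue
        n_origins += 1
        max_l = min(max_lag, n_frames - 1 - t0)
        lags = np.arange(max_l + 1)
        totals[: max_l + 1] += n_on
        # contact survives lag L iff remaining run covers L+1 frames
        surv = (active[on][:, None] >= (lags[None, :] + 1)).sum(axis=0)
        counts[: max_l + 1] += surv
    if n_origins == 0:
        raise ValueError("no contacts to track at any time origin")
    valid = totals > 0
    S = np.ones(max_lag + 1)
    S[valid] = counts[valid] / totals[valid]
    lags_t = np.arange(max_lag + 1) * timestep
    return SurvivalCurve(lag_times=lags_t[valid], S=S[valid], n_origins=n_origins)


def survival_probability(
    trajectory: Trajectory,
    charge_state: int | None = None,
    r_cut: float = DEFAULT_R_CUT,
    multi_origin: bool = True,
    origin_stride: int = 1,
    max_lag: int | None = None,
) -> SurvivalCurve:
    """Contact survival probability for excipient molecules of one charge state."""
    contacts, ids = contact_series(trajectory, charge_state, r_cut)
    if len(ids) == 0:
        raise ValueError(f"no buffer molecules with charge state {charge_state}")
    return survival_from_contact_matrix(
        contacts, trajectory.timestep, multi_origin, origin_stride, max_lag
    )


def mean_residence_time(events: list[ResidenceEvent]) -> float:
    """Average residence time (ps) over events."""
    if not events:
        raise ValueError("no residence events")
    return float(np.mean([e.tau_r for e in events]))


# ---------------------------------------------------------------------------
# Stretched-exponential desorption fit
# ---------------------------------------------------------------------------


def _double_stretched(t, a, k1, mu1, k2, mu2):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = a * np.exp(-((k1 * t[pos]) ** mu1)) + (1 - a) * np.exp(-((k2 * t[pos]) ** mu2))
    out[~pos] = 1.0
    return out


# deterministic multi-start grid (amplitude, k1/k2 split factors, exponents);
# the model is near-degenerate, so the grid must cover well-separated and
# similar rate pairs plus exponent combinations on both sides of 1
_START_AMPLITUDES = (0.25, 0.5, 0.75)
_START_RATE_FACTORS = ((1.0, 0.1), (1.0, 0.3), (2.0, 0.5), (5.0, 0.5), (5.0, 1.0), (20.0, 2.0))
_START_EXPONENTS = ((1.0, 1.0), (0.9, 0.6), (0.6, 0.35), (0.5, 0.8), (0.35, 0.9))


def fit_desorption(
    curve: SurvivalCurve,
    weights: np.ndarray | None = None,
    tail_weighting: bool = False,
    t_max: float | None = None,
) -> DesorptionFit:
    """Fit S(t) with a double stretched exponential (time in ns).

    Bounds: A in [0, 1], k > 0, mu in (0, 1.5].  A documented multi-start
    grid makes the fit deterministic; parameter standard errors come from
    the Jacobian at the optimum.  ``tail_weighting`` applies weights
    proportional to 1/sqrt(S), emphasizing the rate-sensitive tail.
    """
    t_ns = curve.lag_times / 1000.0  # ps -> ns
    S = curve.S
    if t_max is not None:
        keep = t_ns <= t_max
        t_ns, S = t_ns[keep], S[keep]
    if len(t_ns) < 10:
        raise ValueError("need at least 10 lag points to fit")
    if np.all(S >= 1.0 - 1e-12):
        raise ValueError("no decay in survival curve; cannot fit desorption")
    if weights is None:
        weights = 1.0 / np.sqrt(np.maximum(S, 1e-3)) if tail_weighting else np.ones_like(S)

    span = max(t_ns[-1], t_ns[1])
    k_scale = 1.0 / max(span / 10.0, 1e-9)

    def resid(p):
        a, k1, mu1, k2, mu2 = p
        return (_double_stretched(t_ns, a, k1, mu1, k2, mu2) - S) * weights

    lb = [0.0, 1e-9, 1e-3, 1e-9, 1e-3]
    ub = [1.0, np.inf, 1.5, np.inf, 1.5]
    best = None
    for a0 in _START_AMPLITUDES:
        for f1, f2 in _START_RATE_FACTORS:
            for m1, m2 in _START_EXPONENTS:
                p0 = [a0, f1 * k_scale, m1, f2 * k_scale, m2]
                try:
                    sol = least_squares(resid, p0, bounds=(lb, ub), method="trf", max_nfev=4000)
                except Exception:
                    continue
                if best is None or sol.cost < best.cost:
                    best = sol
    if best is None or not np.isfinite(best.cost):
        raise RuntimeError("desorption fit did not converge from any start point")

    a, k1, mu1, k2, mu2 = best.x
    errs = _fit_stderr(best, len(t_ns))
    # order terms so k1 is the faster rate, matching the reporting convention
    if k2 > k1:
        a, k1, mu1, k2, mu2 = 1 - a, k2, mu2, k1, mu1
        errs = {
            "amplitude": errs["amplitude"],
            "k1": errs["k2"], "mu1": errs["mu2"],
            "k2": errs["k1"], "mu2": errs["mu1"],
        }
    stderr = errs
    return DesorptionFit(
        amplitude=float(a), k1=float(k1), k2=float(k2), mu1=float(mu1), mu2=float(mu2),
        stderr=stderr, residual=float(np.sqrt(2 * best.cost / len(t_ns))),
    )


def _fit_stderr(sol, n_points: int) -> dict[str, float]:
    names = ["amplitude", "k1", "mu1", "k2", "mu2"]
    dof = max(n_points - len(sol.x), 1)
    s_sq = 2 * sol.cost / dof
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(jtj) * s_sq
        errs = np.sqrt(np.clip(np.diag(cov), 0, None))
    except Exception:
        errs = np.full(len(sol.x), np.nan)
    return dict(zip(names, map(float, errs)))


# ---------------------------------------------------------------------------
# Contact counts and the Buffer Adsorption Index
# ---------------------------------------------------------------------------


def contact_counts(
    trajectory: Trajectory, charge_state: int | None = None, cutoff: float = DEFAULT_R_CUT
) -> dict[int, float]:
    """Frame-averaged number of (residue atom, excipient atom) pairs within
    the cutoff, per protein residue, summed over molecules of the charge state."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    system = trajectory.system
    mol_idx = [
        np.asarray(m.atom_indices, dtype=int)
        for m in system.buffer_molecules
        if charge_state is None or m.charge_state == charge_state
    ]
    prot_idx = system.protein_indices
    prot_res = system.residue_indices[prot_idx]
    counts = {int(r.index): 0.0 for r in system.residues if np.any(prot_res == r.index)}
    if not mol_idx:
        return counts
    all_buffer = np.concatenate(mol_idx)
    for frame in trajectory.frames:
        d = min_image_distance_array(
            frame.coordinates[prot_idx], frame.coordinates[all_buffer], frame.box
        )
        within = d <= cutoff
        per_atom_counts = within.sum(axis=1)
        for res_index in counts:
            counts[res_index] += float(per_atom_counts[prot_res == res_index].sum())
    n = len(trajectory.frames)
    return {r: c / n for r, c in counts.items()}


def bai(counts_by_state: dict[int, dict[int, float]]) -> dict[int, BaiResult]:
    """Buffer Adsorption Index per residue and charge state (k_B T).

    ``counts_by_state`` maps a charge state (0 or +1) to per-residue mean
    contact counts.  The normalizing N_max is the largest mean count across
    *all* charge states, so both states share one energy reference.
    Residues with zero counts receive a +inf sentinel.
    """
    n_max = max((c for counts in counts_by_state.values() for c in counts.values()), default=0.0)
    if n_max <= 0:
        raise ValueError("all contact counts are zero; BAI undefined")
    out: dict[int, BaiResult] = {}
    for state, counts in counts_by_state.items():
        per_bai = {
            r: (float(-np.log(c / n_max)) if c > 0 else float("inf")) for r, c in counts.items()
        }
        out[state] = BaiResult(
            per_residue_n_avg=dict(counts), n_max=float(n_max),
            per_residue_bai=per_bai, charge_state=state,
        )
    return out
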