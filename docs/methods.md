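# Methods

This note records the models implemented in `bsapkit`, the conventions and
defaults chosen where several were defensible, and what the synthetic
fixtures do and do not emulate.

## Units and conventions

Lengths are nm, times ps (rates from fits are reported in ns⁻¹), areas nm²,
energies k_BT unless a table states kcal/mol. PDB files (Å) are converted on
read/write. Frames are 0-indexed. Van der Waals radii come from a single
packaged Bondi-style element table (H 0.120, C 0.170, N 0.155, O 0.152,
S 0.180 nm, …) so every area is reproducible from the repository alone.

Distance conventions: excipient–protein distances (minimum-distance series,
contact counts, surface RDFs) are periodic-boundary minimum-image distances
under the frame's (possibly triclinic) box. Neighborhood searches *within*
the protein (the SAP radius) and SASA occlusion use unwrapped coordinates,
on the assumption that analysis frames keep each molecule whole; this
matters only when a molecule is split across the box, which the readers do
not attempt to repair.

A contact exists when the shortest atomic-pair distance `d_min ≤ 0.4 nm`
(boundary inclusive). This single cutoff covers both hydrogen bonds
(acceptor–hydrogen ≈ 0.25 nm) and salt bridges (≈ 0.4 nm).

## Solvent-accessible surface area

Shrake–Rupley with test points on a deterministic Fibonacci (golden-angle)
lattice — no random state, so results are bit-reproducible for a fixed
`n_points`. Defaults: probe radius 0.14 nm, 960 points (both configurable);
isolated spheres are exact by construction, and the lattice agrees with a
10⁶-sample Monte-Carlo surface oracle to better than 2% on small clusters.
The occluding *context* is an explicit argument: the buffer-aware index
passes protein + adsorbed excipient as context while reading areas for
either group. SASA is computed over heavy atoms by default (`heavy_only`
switch), since hydrogen conventions differ between force fields and tools.

Side chain = all atoms except N, CA, C, O, OXT and their hydrogens.
Glycine's side chain is empty under the heavy-only convention; its exposure
reference falls back to the Hα-bearing definition (hydrogens included for
GLY only). The value is only ever a denominator multiplying glycine's
hydrophobicity, which is exactly 0 on the shifted scale, so the fallback
never influences a score — it merely avoids a zero division.

### Fully-exposed reference (Ala–X–Ala)

The normalizing `SAA_exposed` of residue X is the side-chain SASA of the
central residue of an extended Ala–X–Ala trimer. The trimer is built
deterministically: an ideal extended backbone (NeRF placement, φ = ψ = ω =
180°, standard bond lengths/angles) with each residue's ideal geometry from
the Chemical Component Dictionary superimposed on its backbone triad. A
small conformer ensemble (default 3) rotates the central side chain about
the CA–CB axis in even steps and averages the area. The free-excipient
reference `SAA_exposed,exc` is the SASA of the isolated excipient molecule
in its ideal geometry.

This is a reconstruction from ideal geometry, not a solvent-phase MD
ensemble; absolute values differ from MD-averaged references by roughly
10–20% for long flexible side chains. Every score that must reproduce
published numbers takes its reference areas from the published inputs
themselves, and `ExposureReference.from_tsv` lets users substitute their own
(e.g. MD-derived) table throughout.

## SAP and BSAP

SAP of atom *j* (protein atoms only; neighborhood radius default 0.5 nm)
sums, over residues with at least one side-chain atom within the radius,
the in-range side-chain SASA normalized by the fully-exposed reference and
weighted by the shifted Black & Mould hydrophobicity. Implementation-wise
this is a weighted neighbor sum over side-chain atoms (each atom carries
weight `R_h(res)/SAA_exposed(res)`), which is algebraically identical to
the per-residue formulation and is verified against a naive double-loop
reference to 1e-9. The atom's own residue contributes when its side-chain
atoms fall in range (configurable via `include_own_residue`). Per-atom
values are averaged over frames *first*; the aggregate score then sums the
positive time-averaged atomic values. Per-residue SAP is the mean over the
residue's computed atoms.

BSAP adds the buffer two ways, mirroring its physical effect: excipient
atoms join the SASA context globally (occlusion is geometric, with no
cutoff), while the hydrophilicity term is gated by contact membership —
each excipient molecule with any atom within 0.4 nm of atom *j* adds
`R_h,exc · SAA(mol)/SAA_exposed,exc`, with `SAA(mol)` its instantaneous
area in the full protein+buffer context. With a hydrophilic excipient
(`R_h < 0`) both channels can only lower the index, so the BSAP score is
bounded by the SAP score on such systems — the shielding signature the
index exists to measure. Ions and solvent never occlude (analysis
trajectories typically omit solvent coordinates).

The packaged hydrophobicity scale is Black & Mould (1991), shifted so
glycine is 0; arginine (−0.50) is the most hydrophilic residue, and the
shifted values reproduce every published hydrogen-bond-score input.

## Excipient affinity scores

`S_α = Σ_i −E_i^α · ⟨SAA_i⟩ / SAA_exposed,i` per interaction type, where
`⟨SAA_i⟩` is the frame-averaged combined side-chain area of all residues of
type *i* (`saa_avg_from_trajectory`). Energies are attractive (negative),
so the minus sign makes stronger attraction score higher; the hydrogen-bond
variant replaces the energy by the shifted hydrophobicity, so hydrophilic
partners score positive. The packaged table carries the literature energies
and the published Fab/Fc average-SAA columns; deliberately out of scope, as
in the published analysis, are buffer-excipient ↔ protein-histidine π
stacking and ion-mediated pairs.

Reproduction tolerance: the published inputs are printed to 3–4 significant
figures for the energy rows but only 1–2 for the hydrogen-bond
hydrophobicities (e.g. THR −0.05), so table-reproduction tests use 1%
plus the first-order propagation of each printed input's half-ULP; totals
hold at plain 1%.

## Adsorption kinetics

Residence events are maximal runs of consecutive adsorbed frames; a
departure and return starts a new event. Duration convention: `τ_r =
(frames in event) × Δt`, so a single adsorbed frame carries one timestep.

Survival probability `S(t)` is the fraction of contacts existing at a time
origin that persist *continuously* for a lag `t`. Multiple time origins are
on by default (every frame, stride configurable); single-origin estimation
is available and agrees on stationary processes within sampling error.
`S(0) = 1` and monotone non-increase hold by construction.

The desorption fit `S(t) = A·exp(−(k₁t)^μ₁) + (1−A)·exp(−(k₂t)^μ₂)` uses
bounded trust-region least squares (A ∈ [0,1], k > 0, μ ∈ (0, 1.5]) with
time in ns. The model is near-degenerate — distinct parameter sets can
differ by RMS residuals below 1e-5 — so the fit runs a deterministic
90-point multi-start grid (3 amplitudes × 6 rate-pair scalings relative to
the curve span × 5 exponent pairs) and returns the lowest-cost solution,
with the faster rate reported as k₁. Parameter standard errors come from
the Jacobian at the optimum. Weights are uniform by default; optional
1/√S weighting emphasizes the rate-sensitive tail. A curve with no decay or
fewer than 10 lag points is rejected rather than fitted.

BAI: `−ln(N_avg_i / N_max)` with `N_max` shared across excipient charge
states so both use one energy reference; residues with zero contacts get a
+inf sentinel and are reported separately rather than plotted into the
distribution. Only count ratios matter — the index is invariant to
rescaling all counts.

## Structural observables

- Radius of gyration: mass-weighted by default (per-element masses from the
  packaged table), `√(Σ m_i |r_i − r_cm|²/Σ m_i)`.
- Hinge angle: angle in [0, π] between vectors joining centers of mass of
  four user-declared anchor atom sets (A→B vs C→D). Anchors are always
  user-declared — for antibodies the published definition identifies
  disulfide pairs only pictorially, so no inference is attempted.
- Surface RDF: per target atom and frame, the minimum-image distance to the
  nearest reference atom, histogrammed; counts averaged over frames and
  divided by bin width (pairs/nm, no volume normalization — the gmx-rdf
  convention for surface-referenced distributions). Its integral equals the
  mean number of targets within range.
- Green–Kubo viscosity: `η = V/(k_BT) ∫₀^t_max ⟨P_αβ(0)P_αβ(t)⟩ dt`,
  autocorrelation FFT-averaged over all supplied off-diagonal components
  and time origins, trapezoidal integration, default `t_max = 5 ps`. With
  bar/ps/nm³ inputs the conversion to mPa·s is
  `V·I/(k_BT) × 1e-29 × 1e3`. Verified against the closed-form
  Ornstein–Uhlenbeck integral `σ²τ_c`.
- Buffer composition: `f⁺ = 1/(1+10^(pH−pKa))`;
  molecule counts round `c·V·N_A` to the nearest integer and split by the
  charged fraction (charged count rounded, remainder neutral).

## Synthetic fixtures

Generators are pure functions of their arguments; a fixed seed gives
byte-identical output.

`make_adsorption_trajectory` emulates the bound/unbound telegraph dynamics
of excipient molecules near a static protein: unbound dwells are
exponential with rate `k_on`, bound dwells exponential or stretched
(Weibull with shape μ, matched mean), quantized to whole frames (minimum
one). Geometry places each single-atom excipient along a per-molecule
support direction **u** at an exact minimum distance d from its supporting
protein atom (the maximizer of **u**·r), which guarantees `d_min = d`:
bound frames draw d strictly inside [0.25, 0.4) nm, unbound frames in
[0.6, 2.0] nm, and a grazing mode places d exactly at the cutoff to
exercise the boundary tie rule. The generator returns the true event list
for oracle tests. Defaults (Δt = 10 ps, mean bound dwell 100 ps, cutoff
0.4 nm, ~0.1 nm scale of the d_min band) match the dynamic, ~100 ps
residence regime of histidine on antibody surfaces.

What the fixtures do **not** emulate: force-field dynamics, solvent,
multi-atom excipient geometry (adsorption fixtures use single-atom
excipients; realistic side-chain geometry comes from the CCD trimer
templates), surface diffusion of adsorbed molecules, or correlated
binding between molecules. Passing tests therefore demonstrate the
*estimators* are correct on processes with known kinetics and geometry,
not that any particular protein–excipient system behaves a given way.

Test problem sizes were chosen to give comfortable statistical margins at
interactive runtimes: telegraph survival tests use ~20 molecules × 3000
frames (≈5–8·10³ events; discretization analysis shows the multi-origin
estimator deviates from `exp(−t/τ)` by <0.5% at τ/Δt = 10, so the 0.03
absolute tolerance is ≈5× the Monte-Carlo error), and the
Ornstein–Uhlenbeck viscosity check uses 10⁶ samples against the analytic
integral at 5% tolerance.

## Known limitations

- The exposure reference is an ideal-geometry reconstruction (see above);
  absolute SAP/BSAP values depend on it, though comparisons between states
  computed with the same reference are robust.
- SASA totals are rotation invariant only to lattice discretization
  (≈0.5–1% at 960 points); increase `n_points` where tighter invariance
  matters.
- No trajectory alignment, bond perception, or protonation assignment:
  buffer molecules and their charge states are declared by residue name in
  the run config, never inferred.
- The double stretched-exponential fit is reliable on curves that decay
  well below 1 within the fitted window; amplitudes of a pure
  single-exponential input are unidentifiable between the two terms (the
  dominant term's parameters are still recovered).
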