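# bsapkit

Trajectory analysis of **excipient (buffer) adsorption on protein surfaces**
and its effect on **aggregation propensity** — built for formulation
scientists and simulators studying therapeutic proteins (monoclonal
antibodies in histidine buffer being the motivating system).

Protein aggregation is driven by solvent-exposed hydrophobic patches.
Free-histidine buffer molecules adsorb on those patches and shield them;
`bsapkit` quantifies both sides of that story from MD trajectories:

- **SAP** (spatial aggregation propensity) of atom *j*:

  `SAP_j = ⟨ Σ_res  SAA(side-chain atoms of res within r of j) / SAA_exposed(res) × R_h(res) ⟩`

  with neighborhood radius `r = 0.5 nm`, the Black & Mould hydrophobicity
  `R_h` shifted so glycine is 0, and the fully-exposed Ala–X–Ala side-chain
  area as normalizer. Positive SAP marks aggregation-prone surface.

- **BSAP**, the buffer-aware extension: adsorbed excipient molecules occlude
  the surface in the SAA term *and* contribute their own (negative,
  hydrophilic) hydrophobicity weighted by their instantaneous exposure:

  `BSAP_j = SAP_b,j + Σ_adsorbed  R_h,exc × SAA(mol) / SAA_exposed,exc`

  The aggregate score sums positive atomic values; a BSAP score below the
  SAP score means the buffer reduces exposed hydrophobicity.

- **BAI** (buffer adsorption index): per-residue relative free energy of
  excipient contact formation, `BAI_i = −ln(N_avg_i / N_max)` in k_BT, from
  frame-averaged atomic contact counts within 0.4 nm.

- **Excipient affinity scores** `S_α = Σ_i −E_i^α · ⟨SAA_i⟩ / SAA_exposed,i`
  per interaction type (cation-π, π-π, H-π, and a hydrogen-bond variant
  using hydrophobicity in place of energy), with packaged energy tables.

- **Adsorption kinetics**: per-molecule minimum-distance series, residence
  events (`d_min ≤ 0.4 nm` runs), multi-origin survival probability `S(t)`,
  and double stretched-exponential desorption fits
  `S(t) = A·exp(−(k₁t)^μ₁) + (1−A)·exp(−(k₂t)^μ₂)`.

- **Supporting observables**: Shrake–Rupley SASA with an explicit occluder
  context, radius of gyration, interdomain hinge angles, surface-referenced
  RDFs, Green–Kubo viscosity from pressure-tensor series, and
  Henderson–Hasselbalch buffer composition.

A seeded synthetic-fixture module generates toy proteins and protein +
excipient trajectories with *known* adsorption kinetics, so the entire
pipeline is testable without external data.

## Worked example

```python
import numpy as np
from bsapkit import synth_fixtures as sf, sasa, sap_bsap, adsorption as ads

# an all-hydrophobic toy peptide with one permanently adsorbed excipient
system, frame = sf.make_toy_protein(["LEU","ILE","VAL","LEU","PHE"], "extended", seed=5)
traj, truth = sf.make_adsorption_trajectory(
    system, frame, k_on=10.0, n_frames=4, seed=9,
    dwell_mean=1e9, n_neutral=1, start_bound=True)

ref = sasa.build_exposure_reference()
print("SAP score :", round(sap_bsap.sap(traj, reference=ref).score, 3))
print("BSAP score:", round(sap_bsap.bsap(traj, reference=ref).score, 3))

# recover known desorption kinetics from a noisy survival curve
t = np.arange(0, 4000.0, 5.0)
curve = sf.make_survival_curve(0.6, 2.0, 0.5, 0.5, 0.8, t, noise_sd=0.01, seed=13)
fit = ads.fit_desorption(curve)
print(f"k1={fit.k1:.3f}/ns mu1={fit.mu1:.3f}  k2={fit.k2:.3f}/ns mu2={fit.mu2:.3f}")
```

prints

```
SAP score : 8.672
BSAP score: 8.022
k1=2.211/ns mu1=0.506  k2=0.506/ns mu2=0.774
```

The hydrophilic excipient sitting on the hydrophobic patch lowers the
aggregate hydrophobicity score (8.67 → 8.02), and the fit recovers the
generating rates (2.0 and 0.5 ns⁻¹) and stretching exponents (0.5, 0.8)
within the noise.

The same analyses are available from the shell:

```bash
bsapkit synth --n-frames 50 --out-prefix fx        # fixture + ground truth
bsapkit sap fx.pdb -t fx.xyz                        # per-residue SAP + score
bsapkit adsorb survival fx.pdb -t fx.xyz            # S(t) table
bsapkit escore --type cation_pi --fragment fc       # affinity score table
bsapkit props hh --ph 6 --pka 6 --conc 0.02 --volume 1661
```

## Layout

```
src/bsapkit/
  core_io.py            # domain types, PDB/GRO/XTC/DCD/XYZ I/O, PBC distances
  sasa.py               # Shrake–Rupley SASA, Ala–X–Ala exposure reference
  sap_bsap.py           # SAP / BSAP indices and scores
  adsorption.py         # d_min, residence events, S(t), fits, contacts, BAI
  interaction_scores.py # excipient affinity scores + packaged tables
  structprops.py        # Rg, hinge angle, surface RDF, viscosity, buffer pH
  synth_fixtures.py     # seeded generators with known ground truth
  cli.py                # `bsapkit` command-line interface
docs/methods.md         # models, conventions, parameter choices, limitations
```
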