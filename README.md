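# sterolflux

Free-energy analysis of transporter-mediated sterol movement: the complete
desk-side analysis layer for studies that quantify cholesterol transport
energetics and ion coupling in RND-family transporters such as PTCH1 and
DISP1.

The package answers three connected questions about a putative cholesterol
exporter:

1. **How much does export cost?**  Potentials of mean force (PMFs) from
   umbrella-sampling time series are reconstructed with WHAM and composed
   into end-to-end transport paths (e.g. sterol-sensing domain → membrane →
   solvent → sterol-binding domain), with Bayesian-bootstrap errors
   propagated in quadrature, e_T = √(Σᵢ eᵢ²).  Alchemical decoupling legs
   (absolute binding free energies, relative Na⁺/K⁺ perturbations) are
   estimated with MBAR — f_k solving
   f_k = −ln Σₙ exp(−u_kn) / Σⱼ Nⱼ exp(fⱼ − u_jn) — with BAR and exponential
   averaging as cross-checks, and assembled into thermodynamic cycles whose
   closure validates the direct against the indirect estimate.
2. **Can an ion gradient pay for it?**  The electrochemical free energy of
   moving one mole of ion across the membrane,
   ΔG = RT ln(c_in/c_out) + zFΔV, gives the energy each coupling ion can
   contribute; the predicted stoichiometry is
   ⌈ΔG_export / ΔG_per-ion⌉ as a function of membrane potential.
3. **What do the trajectories show?**  Geometric probes quantify TMD
   hydration (cylinder-partitioned water counts), residue–ion contact
   fractions, ligand occupancies, minimum-image Cα distances, ion
   positional RMSD, and time-averaged water density grids.

Every estimator is exercised against synthetic data with known ground
truth: Metropolis-sampled umbrella windows over analytic 1D potentials,
λ-coupled harmonic systems with closed-form ΔG = (RT/2) ln(k₁/k₀), and toy
membrane-protein trajectories with planted waters, ions and helix
scaffolds.

## Worked example

```python
import sterolflux as sf

legs = [
    sf.TransportLeg("SSD", "membrane", sf.FreeEnergyValue(18, 3), provenance="PMF-2"),
    sf.TransportLeg("membrane", "solvent", sf.FreeEnergyValue(88, 1), provenance="PMF-3"),
    sf.TransportLeg("solvent", "SBD", sf.FreeEnergyValue(-83, 3), provenance="PMF-4"),
]
print(sf.compose_path(legs, "SSD", "SBD").summary())

result = sf.coupling_ions(20.0, sf.SODIUM, sf.MembraneCondition(-60.0, 310.0), "influx")
print(f"Na+ driving energy at -60 mV: {result.driving_energy:.2f} kJ/mol")
print(f"ions per cholesterol exported: ratio {result.ratio:.2f} -> count {result.count}")
```

prints

```
Transport path: SSD -> membrane -> solvent -> SBD
        SSD -> membrane   +18 ± 3 kJ/mol  [PMF-2]
   membrane -> solvent    +88 ± 1 kJ/mol  [PMF-3]
    solvent -> SBD        -83 ± 3 kJ/mol  [PMF-4]
  total: +23 ± 4 kJ/mol (raw +23.000 ± 4.359)

Na+ driving energy at -60 mV: 12.21 kJ/mol
ions per cholesterol exported: ratio 1.64 -> count 2
```

Moving cholesterol out of its transmembrane binding site, through the
membrane and solvent, into the extracellular sterol-binding domain costs
+23 ± 4 kJ·mol⁻¹ — export is uphill.  At a resting potential of −60 mV the
Na⁺ gradient releases 12.2 kJ·mol⁻¹ per ion moved inward, so two coupled
Na⁺ suffice to pay a 20 kJ·mol⁻¹ export cost.

The estimators are Model/Results pairs in the statsmodels style:

```python
import numpy as np

windows = sf.gen_umbrella_windows(
    sf.DoubleWellPotential(barrier=20.0), centers=np.arange(0, 1.0001, 0.05),
    force_constant=1000.0, n_samples=5000, temperature=323.0, seed=1,
)
fit = sf.WHAM(windows, n_bins=200).fit()      # -> WHAMResult
fit.bootstrap_error(n_rounds=200, seed=2)     # Bayesian bootstrap, per-bin σ
print(fit.summary())
fit.profile.plot()                            # PMF with ±1σ band
```

## Command line

The `sterolflux` console script exposes the pipeline as subcommands —
`wham`, `mbar`, `fep`, `abfe`, `cycle`, `stoich`, `hydration`, `contacts`,
`distances`, `density`, `zseries`, and `simulate` (synthetic-data
generation with ground-truth files).  For example:

```sh
sterolflux --out sim --seed 7 simulate umbrella --potential double-well
sterolflux --out run --seed 7 wham sim/umbrella/windows.yaml --bootstrap 200
sterolflux --out coupling stoich --ion na --dv-min -100 --dv-max 0 --export-dg 20
```

Each run writes JSON/TSV results plus a manifest recording the version,
seed and parameters.

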