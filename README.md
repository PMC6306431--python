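# minorstate

Detection and characterization of **low-lying excited conformational states**
of proteins, combining four analyses that together map a hierarchical energy
landscape — a fast, barrierless hinge-bending fluctuation and a slower,
low-population exchange into a bound-like "closed" state:

1. **CAPSID** (curvature of amide proton shifts induced by denaturant):
   nested quadratic fits of amide ¹H shifts over a temperature × [GdmHCl]
   grid. A residue in fast exchange with an excited state within
   ~10 kJ mol⁻¹ of the ground state shows temperature-curvature that grows
   systematically with denaturant, because Gdm destabilizes the ground state
   relative to compact alternative states.
2. **CPMG relaxation dispersion**: numerical two-site Bloch–McConnell
   propagation of ¹⁵N magnetization through the echo train,
   R₂eff(ν_CPMG) = −(1/T_CPMG)·ln(I_CPMG/I₀), with global fitting of a shared
   exchange rate k_ex = k_f + k_b and minor population p_B across residues and
   static fields, χ² profiling of the forward rate, and the Millet α
   field-dependence diagnostic.
3. **Ring-current corrections** (Haigh–Mallion): geometric shift
   contributions of aromatic/nucleobase rings at amide ¹⁵N positions, used to
   isolate the conformational part of free→bound shift changes so that
   √(p_A p_B)·|Δω| from the dispersion fit can be regressed against them —
   the conformational-selection test, whose slope gives p_A p_B directly.
4. **Elastic-network normal modes**: all-heavy-atom anisotropic network
   (10 Å cutoff, exp(−(r/5 Å)²) springs), mode trajectories rescaled to a
   target mean RMSD, and superposed RMSD profiles against open/closed
   references. An interior minimum of the subset-RMSD profile along the
   softest hinge mode is the *facilitation* signature: hinge bending carries
   the lip residues toward their closed arrangement before the slower
   closure takes over.

A first-class synthetic-data module generates shift surfaces, two-field
dispersion datasets and hinged two-lobe structures with known ground truth,
so every stage is testable end-to-end without external downloads.

## Worked example

Simulate a two-field (600/800 MHz) CPMG dataset at the free-enzyme regime
(k_ex = 750 s⁻¹, p_B = 2 %, measurement noise 0.2 s⁻¹) and refit it globally:

```python
from minorstate import synthetic as syn, dispersion as d

cfg = syn.DispersionSimConfig(seed=42)
dataset, truth = syn.gen_dispersion_dataset(cfg)
fit = d.fit_global(dataset, t_cpmg=0.040, exclude_reduced_chi2=None,
                   kex_starts=(300.0, 1000.0))
print(f"kex = {fit.model.kex:.0f} +/- {fit.param_sd['kex']:.0f} s^-1")
print(f"p_B = {100*fit.model.p_b:.2f} %")
corr = d.correlate_with_binding_shifts(fit, dict(truth.delta_omega))
print(f"pA*pB = {corr['p_a_p_b']:.4f}, k_f = {corr['k_f']:.1f} s^-1")
```

prints

```
kex = 770 +/- 34 s^-1
p_B = 1.95 %
pA*pB = 0.0199, k_f = 15.6 s^-1
```

against generating values of 750 s⁻¹, 2.0 % and 15 s⁻¹ (the correlation has
r² = 0.997). The global fit recovers the exchange rate within its uncertainty, and
the shift-correlation route independently returns the same minor population
(p_A p_B ≈ 0.02 ⇒ p_B ≈ 2 %) and forward rate (k_f = p_B·k_ex ≈ 15 s⁻¹) —
the consistency that identifies conformational selection.

The same workflow is available from the shell:

```sh
minorstate simulate --out sim --seed 42
minorstate rd-fit sim/dispersion.csv --out rd
minorstate capsid-fit sim/shifts.csv --out capsid
minorstate enm-modes sim/hinge_open.pdb --reference sim/hinge_target.pdb --out enm
minorstate pipeline --config pipeline.yaml
```

## Layout

```
src/minorstate/
  synthetic.py    # generators with ground truth (shift surfaces, CPMG, hinge toys)
  capsid.py       # nested quadratic fits, ±2σ significance, shape classes
  dispersion.py   # Bloch–McConnell forward model, global fits, α, correlation
  ringcurrent.py  # Haigh–Mallion geometric factors, amide-15N shifts
  enm.py          # elastic network, modes, Kabsch, RMSD profiles
  structures.py   # heavy-atom structure container
  io.py           # CSV/TSV/PDB readers and writers (strict validation)
  pipeline.py     # multi-stage orchestration with provenance
  cli.py          # click subcommands
  data/ring_params.yaml  # ring-current intensity factors (configuration)
```

See `docs/methods.md` for the models, parameter choices, and limitations.
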