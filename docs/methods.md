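# Methods

This note documents the models implemented in `minorstate`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer should know about.

## CAPSID: curvature of amide shifts under denaturant

**Model.** A residue exchanging fast (relative to the shift timescale) with
an excited state observes the population-weighted shift
δ_obs(T, g) = δ_G(T) + p_E(T, g)·Δδ, with a linear ground-state baseline
δ_G(T) = δ₀ + b·(T − 298 K) and a two-state population
p_E = 1/(1 + exp(ΔG/RT)), ΔG(T, g) = ΔH − T·ΔS − m·g. The linear m-value
term is the standard denaturant model; it encodes the premise that Gdm
destabilizes the ground state relative to the excited state. Temperature
curvature of δ_obs is second-order in the population response, so it is
weak at fixed conditions but grows systematically as Gdm closes the gap —
that trend is the detection signal.

**Procedure.** Stage 1 fits δ(T) per residue per Gdm level to a quadratic
with temperature centered at the grid mean (centering leaves the
second-order coefficient c invariant and conditions the normal equations);
coefficient uncertainties come from the linear-model covariance with a
fixed per-point sd of 0.0075 ppm (peak-position precision; configurable).
Stage 2 fits c(g) to a quadratic in raw [Gdm] (axis starting at 0 M,
matching how such data are plotted), weighted by the stage-1 sds. A
coefficient is significant when mean ± 2 sd does not span zero; a residue
is significant when the slope or the curvature passes. Because the stage-2
fit is uncentered, the slope test refers to the tangent at 0 M — the
steepest part of the saturating c(g) response — and the slope/curvature
estimates are strongly anticorrelated, which keeps the union false-positive
rate of the two ±2σ tests near 5 % rather than the ~9 % two independent
tests would give.

**Discarding.** Fits with reduced χ² > 10 (either stage) are discarded as
measurement pathologies. The threshold sits far above the noise-only
expectation (~1) deliberately: a genuine excited-state response deviates
*systematically* from a quadratic when strong, and a tight threshold would
preferentially discard exactly the residues the method exists to find. A
by-eye analog of "poor fit" means scatter, not smooth model inadequacy.

**Shape classes.** Weighted-mean c significantly positive → concave →
excited state downfield; significantly negative → convex → upfield;
significant Gdm dependence with mixed-sign c → flat-nonzero, direction
undetermined.

**Generator defaults** (`ShiftSurfaceConfig`): 100 residues, 6 temperatures
(288–313 K every 5 K), Gdm 0–1.6 M in 0.4 M steps, baseline slope
−4.5 ppb/K, noise 0.0075 ppm, 16 % of residues carry an excited state.
Thermodynamics of planted residues: ΔG₀ ∈ [6, 7.5] kJ/mol at 298 K
(within the ~10 kJ/mol detection window), ΔH ∈ [−75, −55] kJ/mol with
ΔS = (ΔH − ΔG₀)/298. The negative-ΔH/negative-ΔS choice describes a
*compact* excited state — better packed and enthalpically favored, but
entropically penalized because closing a hinge restricts conformational
freedom. (An enthalpy-destabilized excited state at the same gap sits near
the sign change of the curvature response at ΔH/RT ≈ 2 and is nearly
undetectable by construction, which is a genuine property of the two-state
model, not a generator artifact.) m ∈ [2, 2.8] kJ/mol/M; |Δδ| ∈
[2, 3.5] ppm with random sign, the hydrogen-bond-scale shift differences
that produce curvature responses a few times the propagated coefficient sd,
as the detected class in real data must. Parameter sets whose excited
population would exceed 50 % anywhere on the grid are rejected (sampled
residues are redrawn; explicit parameters raise).

**What passing tests show.** Recovery of ≥12/16 planted residues at ≤5/84
false positives demonstrates the two-stage statistic under honest noise; it
does not demonstrate performance on residues with small shift differences
(sub-ppm Δδ is genuinely below this design's detection floor), on sloped
baselines that are themselves temperature-curved, or under peak-tracking
errors, none of which are simulated.

## CPMG relaxation dispersion

**Forward model.** Two-site exchange A ⇌ B with populations (p_A, p_B),
shared exchange-free R₂ at both sites, and offsets in the
population-averaged rotating frame (Ω_A = −p_B·Δω, Ω_B = p_A·Δω; Δω in
rad/s, ¹⁵N frequency taken as 0.101329 × the ¹H field). The transverse
magnetization (complex 2-vector) starts at (p_A, p_B) and passes through
n = 2·ν·T_CPMG echoes of [τ/4-evolution, ideal 180° (complex conjugation),
τ/4-evolution]; R₂eff = −(1/T)·ln|M_A + M_B|. Evolution uses the exact 2×2
matrix exponential via eigendecomposition, and the echo unit is raised to
the n-th power as a real 4×4 matrix by binary exponentiation, vectorized
over the ν grid — this is what keeps replicate global fits at seconds each.
Agreement with scipy `expm` propagation is unit-tested to 1e-10, and with
the Luz–Meiboom closed form to <1 % deep in the fast limit.

**Conventions.** The observable is the magnitude of total transverse
magnetization (a single averaged line in fast exchange). Off-resonance
effects and finite pulse widths are not modeled (experimentally handled by
offset interleaving). ν values must give integer echo counts
(ν = n/(2·T_CPMG)); others are rejected listing permissible values. Δω is
stored as a magnitude: its sign is not identifiable from CPMG in this
regime and is taken from a shift table only in the correlation step.

**Fitting.** Residues enter the fit when their dispersion span
max(R₂eff) − min(R₂eff) exceeds 1.0 s⁻¹ at *both* fields. Individual-residue
pre-screens (reduced χ² > 3, configurable) can exclude residues before the
global fit. The global fit shares k_ex and p_B across residues and fields;
each residue keeps |Δω| (ppm) and per-field exchange-free R₂ (CSA makes the
baseline field-dependent). Optimization is trust-region least squares with
bounds (p_B < 0.5) and multistart over k_ex ∈ {100, 300, 1000, 3000} s⁻¹
(fewer starts are accepted wherever the caller knows the regime);
convergence at relative χ² change 1e-10. Parameter sds come from the
Gauss–Newton covariance. Consistency re-fits with fixed forward rate
(p_B = k_f/k_ex) or fixed back rate are supported, and the forward-rate χ²
profile refits all remaining parameters per grid point, reporting the
parabolic-refined minimizer and the Δχ² = 1 interval. On the noiseless χ²
valley the parabola is only as good as the local grid, so profile grids
should be refined near the expected minimum.

**α diagnostic.** Two-point estimator
α = [(B₂+B₁)/(B₂−B₁)]·[(Rex₂−Rex₁)/(Rex₂+Rex₁)] with Rex measured at the
lowest ν against the exchange-free baseline. Its fast-exchange ceiling for
600/800 MHz is 1.96 (algebraic identity), not 2. Reported raw (no
clamping); residues with non-positive Rex are skipped with reasons.

**Conformational-selection correlation.** Through-origin regression of the
fitted √(p_A p_B Δω²) (ppm) against |ring-current-corrected free→bound ¹⁵N
shift changes|. If the excited state is the bound-like closed conformation
the relation is exact with slope √(p_A p_B); p_B is the smaller root of
p(1−p) = slope², and k_f = p_B·k_ex. Slopes whose square exceeds 0.25 are
reported saturated at p_B = 0.5; negative slopes are flagged non-physical.

**Generator defaults** (`DispersionSimConfig`): k_ex = 750 s⁻¹, p_B = 2 %,
fields 600/800 MHz, T_CPMG = 40 ms, ν = 50–750 Hz in 50 Hz steps (15
points), noise 0.2 s⁻¹; six residues with |Δω| = 0.8–2.0 ppm and baseline
R₂ of 17–20 s⁻¹ (600 MHz) / 19–23 s⁻¹ (800 MHz). This produces dispersion
spans of ~1.5–8.5 s⁻¹ and a two-point α of ≈1.4 ± 0.3 — the
close-to-fast-limit regime of interest. Not emulated: temperature series,
repeat-ν error estimation from duplicates, three-site exchange, and the
systematic errors that push real global-fit χ² above its statistical
expectation.

## Ring-current shifts

Haigh–Mallion geometric model: for each ring,
G = Σ_bonds s_ij·(1/r_i³ + 1/r_j³)/2 with s_ij the signed area of the
triangle formed by the projections of the nucleus and the bond into the
ring plane (plane by SVD; traversal-direction independent; G > 0 on the
ring axis). Reported shift δ = −B·i·G with B the proton-calibrated constant
(default 5.455×10⁻⁶ shielding per Å⁻³, i.e. δ[ppm] = −5.455·i·G[Å⁻³]) and i
the benzene-relative intensity factor. The proton calibration is applied
unchanged at ¹⁵N positions — the model is purely geometric, and the induced
field at a point does not depend on which nucleus sits there. Purines
contribute separate 5- and 6-membered rings; pyrimidines one. Intensity
factors live in `data/ring_params.yaml` and are configuration: they are
transcribed literature calibration values with real parameter-choice
uncertainty, and alternative tables can be supplied to the loader. Nuclei
within 1 Å of a ring atom are flagged unreliable; rings with >0.5 Å
out-of-plane deviation warn. Only electron ring currents are modeled — no
electric-field, magnetic-anisotropy, or hydrogen-bond contributions.

## Elastic-network modes and RMSD profiling

All heavy atoms are nodes; pairs within 10 Å get springs
k(r) = exp(−(r/5 Å)²) (pure-cutoff Tirion springs via
`distance_weight=None`). Masses are uniform and eigenvalues are reported in
arbitrary units: only mode shapes and ordering are used. The 3N×3N Hessian
uses the standard anisotropic-network blocks −k·d̂d̂ᵀ with diagonal blocks
closing the row sums, so rigid translations are in the null space exactly;
a connected network must show exactly 6 near-zero modes (|λ| < 1e-8·λ_max)
or the geometry is degenerate and the computation raises. Dense `eigh` by
default, shift-invert `eigsh` (lowest 26) above 3000 atoms.

Mode trajectories are straight-line displacements X(a) = X₀ + a·v along a
unit eigenvector — the harmonic approximation, with no curvilinear
correction — with symmetric, uniformly spaced amplitudes scaled so the mean
all-atom RMSD to X₀ equals the rescale target (default 1.0 Å; amplitude is
parameterized directly in RMSD units rather than any solver-internal
scale). RMSD profiles superpose each frame on the reference over all common
heavy atoms (Kabsch, with reflection guard), then evaluate RMSD on the
requested subset; a flag superposes on the subset instead. The profile
minimum is refined parabolically through the bracketing triple and flagged
interior/boundary — an interior minimum of the lip-subset profile is the
facilitation signature.

**Hinge toy** (`HingeSimConfig`): two flattened ellipsoidal lobes
(half-extents 3.5×2.5×1.0 Å, 24 atoms each) at ±7 Å along x, joined by a
5-atom strut along the z (hinge) axis. Springs to atoms *on* the rotation
axis are invariant under rotation about it, so the in-plane hinge bend is
the softest internal mode by construction (squared overlap with the
open→closed displacement ≈ 0.95; the displacement is compared after Kabsch
superposition, since rotating one lobe moves the joint center of mass).
The closed form rotates one lobe by 20°; the target rotates by 40 % of
that and adds 0.05 Å Gaussian jitter representing a closure component that
hinge bending cannot produce. The jitter default sits at the
coordinate-precision scale and well below the ~1 Å hinge displacement:
the location of the profile minimum must remain estimable (at 0.1 Å jitter
its scatter already reaches the 15 % level used to validate recovery).
This toy shares topology, not scale, with a real enzyme; conclusions about
real open/closed pairs require real coordinates through the same code
path (`enm-modes` on PDB input).

## Pipeline and I/O

CSV/TSV with explicit headers; readers validate and reject (with line
numbers) rather than coerce — including comma-decimal dialects. Intensity
tables convert through the R₂eff relation at read time with per-field
default errors (0.7/1.4 s⁻¹ at 600/800 MHz, 0.2 s⁻¹ otherwise) when no
error column is present; non-positive intensities flag the point invalid
without dropping the series. PDB I/O goes through gemmi: heavy atoms only,
highest-occupancy altloc, waters dropped, HETATM nucleotides kept for ring
definitions. The pipeline quarantines failed stages, skips dependents with
recorded reasons, and stamps every summary with the package version, seed
and config hash; identical configs and seeds reproduce byte-identical
reports.

## Problem sizes

The shipped validation runs use 100-residue shift surfaces (30 grid points
each), 6-residue × 2-field × 15-point dispersion datasets with 25 replicate
fits, a 7-point forward-rate profile, 1000 simulated null residues for the
false-positive rate, and 53-atom hinge toys — sizes chosen so each check
isolates one claim and the full validation completes in minutes on one
CPU core.
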