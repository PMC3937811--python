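# Methods

`sdpgap` analyses small-angle X-ray and neutron scattering (SAXS/SANS) from
multilamellar (MLV) and unilamellar (ULV) lipid vesicles with a single
forward model: a scattering-density-profile (SDP) description of the
bilayer, a modified Caillé theory (MCT) structure factor for the lamellar
stack, and a constrained genetic-algorithm (GA) search that can refine one
X-ray curve alone or several X-ray and neutron curves jointly.

## Bilayer model

The bilayer is parsed into quasi-molecular fragments, each carrying a
volume probability profile P_i(z) along the bilayer normal (z = 0 at the
midplane, symmetric leaflets):

- **CholCH3** (choline methyls), **PCN** (phosphate + CH2CH2N) and **CG**
  (carbonyl + glycerol): mirrored Gaussian pairs at ±z_i with widths σ_i;
  each leaflet Gaussian integrates to V_i/A, where V_i is the fragment
  volume per lipid and A the lateral area per lipid.
- **hydrocarbon core**: an error-function envelope of unit height,
  ½[erf((z+D_C)/√2σ_HC) − erf((z−D_C)/√2σ_HC)], whose half-width D_C is the
  hydrocarbon chain length. Its integral is exactly 2 D_C.
- **CH3** (terminal methyls): a Gaussian pinned at z = 0 by symmetry, total
  area 2 V_CH3/A; **CH2** (methylenes, with methine CH pooled in — the
  CH/CH2 contrast is negligible even for neutrons) is the envelope minus
  the CH3 Gaussian.
- **water**: P_W = 1 − Σ P_i, exactly, by spatial conservation. Negative
  excursions of P_W or P_CH2 are never clipped in the model; they flag an
  infeasible parameter set to the penalty system.

The area per lipid is tied to the chain region, A = V_HC/D_C with
V_HC = V_CH2 + V_CH3 (per lipid). With cholesterol at mole fraction x_c its
volume distribution is merged into CH2 (cholesterol partitions into the
chain region, its hydroxyl near the polar/apolar interface): V_HC and the
CH2 composition gain a share x_c/(1−x_c)·V_chol, with V_chol = 630 Å³.

Scaling each P_i by the fragment scattering density — electrons/V_i for
X-rays, Σb/V_i for neutrons, with H→D substitution per the deuteration spec
— and subtracting the solvent density ρ_W gives the contrast profile whose
cosine transform is the form factor, evaluated in closed form:

    F(q) = (ρ_CH2−ρ_W)·(2 sin(q D_C)/q)·exp(−σ_HC²q²/2)
         + (ρ_CH3−ρ_CH2)·2 a_CH3·exp(−σ_CH3²q²/2)
         + Σ_head (ρ_i−ρ_W)·2 a_i·cos(q z_i)·exp(−σ_i²q²/2)

Atomic constants (Z; coherent b for H, D, C, N, O, P) ship as a built-in
table. Water is modelled at 30.0 Å³ per molecule; the neutron solvent SLD
follows from the H2O/D2O mixing fraction (6.38·10⁻⁶ Å⁻² for pure D2O).

## Lattice model

MLV intensity: I(q) = s·[S(q) + N_diff]·|F(q)|²/q², resolution-smeared,
plus a constant background. The 1/q² Lorentz factor (isotropic powder)
multiplies both the Bragg and the diffuse term. S(q) is the MCT structure
factor

    S(q) = N + 2 Σ_{k=1}^{N−1} (N−k) cos(kqd)
               · exp[−(d/2π)² q² η γ_E] · (πk)^{−(d/2π)² q² η}

with N positionally correlated bilayers, repeat distance d, Caillé
fluctuation parameter η, and γ_E the Euler–Mascheroni constant. N_diff
weighs positionally uncorrelated bilayers contributing pure |F|²/q²
scattering with the same prefactor. Optional domain-size averaging takes
Gaussian weights over integer N, truncated at N ≥ 1 and renormalised.
ULVs drop the structure factor entirely (S ≡ 1; vesicle-size oscillations
are not modelled at these q). The beam profile defaults to a Gaussian of
configurable width σ_q, convolved on the q grid with nearest-value edge
extension.

## Constraints and objective

Following standard practice for this model class:

- z_CH3 = 0 and unit envelope height (bilayer symmetry / conservation);
- σ_CholCH3 fixed at 2.98 Å; σ_HC restricted to [2.0, 2.6] Å;
- |z_CholCH3 − z_PCN| ≤ 2 Å and |D_C − z_CG| ≤ 2 Å (spatial proximity) —
  implemented exactly by encoding the choline-methyl and glycerol
  positions as bounded offset genes relative to the phosphate position and
  the chain interface;
- fragment volumes free within ±5% of their reference values (the
  headgroup references sum to the 331 Å³ target);
- Σ V_head is pulled toward 331 Å³ by a soft quadratic penalty;
- negative P_CH2 or P_W anywhere adds a steep smooth penalty.

The fitness is the pooled reduced χ² over all datasets (shared structural
genes; per-MLV-dataset d, N, η, N_diff) plus the penalty. Per-dataset
intensity scale and constant background are free parameters profiled
analytically (weighted linear least squares) at every evaluation — they
enter the degrees of freedom but not the gene vector. The repeat-distance
gene is bounded to ±10% around a first-pass Bragg indexing of the curve
(d ≈ 2π/q_peak), mirroring how lamellar patterns are always indexed before
refinement.

## Genetic algorithm

A real-coded GA: tournament selection (k = 3), mixed crossover (per-gene
BLX-α with α = 0.3, and fitness-directed whole-vector line crossover that
extrapolates past the better parent — essential for tracking the strongly
correlated valleys of the χ² landscape), per-gene Gaussian mutation with a
geometrically annealed step (5% → 0.2% of the bound range), and
single-elite survival. The population is organised as islands (default 4)
with ring migration every 20 generations; after 35% of the run the islands
merge into one panmictic population, and the final 35% restarts the
population as a tight cloud around the incumbent best and evolves it by
elite-covariance Gaussian resampling ("covariance polish"). Two standard
safeguards keep the polish from collapsing prematurely: the covariance is
inflated by 1.3 per step, and 30% of the offspring are shifted along the
elite mean's drift (anticipated mean shift), which lets the cloud travel
along connected valleys to the basin floor. Convergence is declared when
the best fitness is unchanged for 100 generations (configurable). Because
distinct runs can settle in secondary χ² basins, the protocol repeats the
GA from independent seeds derived from the master seed and keeps the
lowest-χ² solution — multiple random-number seeds being the established way
to obtain robust convergence for this optimizer class. Production fits use
populations of ~2000 and several hundred generations; the scaled-down test
protocol uses population 300 and ≤ 200 generations per start, 4 starts.
Everything is deterministic under a fixed seed.

Parameter uncertainties are estimated empirically as min/max/std spreads
over the best solutions of independent seeds (no covariance-based errors:
the constraint walls make the likelihood non-Gaussian).

## Derived structural parameters

From the fitted profile: D_HH = 2·argmax_{z>0} ρ_total(z) (total electron
density including the water term; parabolic sub-grid refinement on a
0.05 Å grid), D_C directly from the envelope, the Luzzati thickness D_B
either as d − ∫P_W dz or (default for reported values) from a symmetric
error-function fit to P_W — the erf refinement weights the high-contrast
headgroup flank and is applied post hoc, never inside the GA objective,
where it proved unstable. Then A = 2V_L/D_B (apparent variant
A* = 2(V_L + x_c/(1−x_c)·V_chol)/D_B with cholesterol) and D_W = d − D_B.
Fitted profiles legitimately touch the P_W = 0 boundary in the interfacial
region; sub-grid negative excursions up to a few 10⁻² are treated as
numerical and clipped for the Luzzati integral, while anything beyond
−0.05 raises an infeasibility error.

## Synthetic data

The scenario library emulates the systems this method is used on:
saturated (DPPC-like) and monounsaturated (POPC-like) PC bilayers at
fluid-phase magnitudes (A ≈ 63–65 Å², D_C ≈ 14.2–14.3 Å, d = 64–67 Å,
η = 0.06–0.08, N = 20), a +20 mol% cholesterol variant (merged-CH2 scheme,
thicker chain region, smaller η — the condensation/stiffening ordering),
and a neutron contrast pair in pure D2O differing only in sn-1
palmitoyl-d31 chain deuteration. Truth states are exactly feasible (zero
penalty) and sit, like real fits, at the P_W ≥ 0 boundary. Curves are the
exact forward model with multiplicative Gaussian noise, I·(1+ε),
ε ~ N(0, σ_rel²), σ_rel = 1% by default, on 400-point SAXS grids
(0.03–0.8 Å⁻¹) and 150-point SANS grids (0.01–0.3 Å⁻¹). What the generator
does not emulate: instrument-specific smearing kernels (TOF wavelength
spread), multiple scattering, q-dependent backgrounds, vesicle
polydispersity. Passing recovery tests therefore demonstrate the internal
consistency of model + optimizer at realistic noise, not robustness to
every real-beamline artefact.

## What standalone SAXS can and cannot determine

A point that shapes how results from single X-ray curves must be read: the
model's likelihood surface for an MLV SAXS curve at ~1% relative noise is
degenerate along a ridge in which the hydrocarbon envelope edge D_C slides
inward by up to ~1 Å while the CG Gaussian (riding its +2 Å proximity
bound) and additional water fill the vacated interfacial volume. Because
methylene (≈0.30 e/Å³) and water (≈0.333 e/Å³) are nearly iso-electron-
dense, the total electron density profile — all that X-rays measure — is
almost unchanged along the ridge: end-to-end the noise-free curves differ
by a total Δχ² of order 10 over a 400-point curve at 1% noise, i.e. within
the noise. A and D_B move with D_C along the ridge (A = V_HC/D_C,
D_B = 2ΣV_i/A), so single-curve estimates of D_C, A and D_B carry a ~5%
systematic uncertainty at this noise level, whereas d (pinned by the Bragg
positions) and η (peak line shapes) are recovered to well under 1%. The
ridge persists when fragment volumes are fixed exactly at their reference
values, so it is not an artefact of the volume tolerances. At noise levels
of ≲0.3% — routine for synchrotron MLV data — the ridge becomes
statistically resolvable and single-curve D_C recovery tightens
accordingly. The robust remedy, reflected in the test suite, is neutron
contrast: joint SAXS+SANS refinement (protiated and chain-deuterated
curves) pins the backbone region and demonstrably shrinks the across-seed
spread of the glycerol position, while A and D_B shift by less than their
spreads. Multi-seed spreads, not single-fit values, are the honest
uncertainty statement for standalone-SAXS structural parameters.

## Numerical choices and limitations

- z grids: 0.05 Å spacing for structural-parameter extraction, 0.1 Å for
  the feasibility scan inside the penalty (the form factor itself is
  analytic and needs no grid).
- N is a continuous gene rounded to the nearest integer at evaluation.
- Degrees of freedom in joint fits: total points minus total free
  parameters, shared genes counted once, profiled scale/background counted
  per dataset.
- The test/acceptance problem sizes (population 300, ≤ 200 generations per
  start, 4 starts; 6-seed comparisons at population 120) are the package's
  scaled-down protocol for fast, deterministic verification; production
  analyses should use the defaults in the shipped profile.
- Out of scope: gel-phase chain tilt, oriented-film line shapes,
  asymmetric bilayers, steric thickness, decomposition of η into bending
  and compression moduli, Bayesian posterior sampling.
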