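# sdpgap

Global analysis of small-angle X-ray and neutron scattering (SAXS/SANS)
from multilamellar (MLV) and unilamellar (ULV) lipid vesicles.

Fully hydrated liposome suspensions are the easiest membrane samples to
prepare, but their scattering mixes the bilayer form factor with the
quasi-Bragg interference of the lamellar stack, thermally smeared by
bending fluctuations. `sdpgap` fits the whole q-range of such curves with
one physical model and extracts the bilayer structure — area per lipid *A*,
Luzzati thickness *D*<sub>B</sub>, head-to-head distance *D*<sub>HH</sub>,
hydrocarbon chain length *D*<sub>C</sub>, water layer *D*<sub>W</sub> — and
the Caillé fluctuation parameter η. It is aimed at membrane biophysicists
reducing beamline data who want a standalone-SAXS-capable, jointly
SAXS/SANS-refinable analysis.

## Model

The bilayer is a scattering density profile (SDP) built from volume
probability distributions of quasi-molecular fragments — choline methyls,
phosphate+CH₂CH₂N, carbonyl+glycerol as mirrored Gaussian pairs; an
error-function hydrocarbon envelope of half-width *D*<sub>C</sub>; terminal
methyls as a central Gaussian; water as the exact complement
(Σᵢ Pᵢ + P<sub>W</sub> = 1). Its cosine transform gives the form factor
*F(q)* in closed form, for X-ray electron densities or neutron scattering
length densities with arbitrary solvent D₂O fraction and chain deuteration.

MLV intensity follows

&nbsp;&nbsp;*I(q) = s·[S(q) + N*<sub>diff</sub>*]·|F(q)|²/q² + b*

with the modified Caillé theory structure factor

&nbsp;&nbsp;*S(q) = N + 2 Σₖ (N−k)·cos(kqd)·exp[−(d/2π)²q²η·γ_E]·(πk)^(−(d/2π)²q²η)*

for *N* correlated bilayers at repeat distance *d*; *N*<sub>diff</sub>
weighs uncorrelated bilayers, 1/q² is the powder Lorentz factor. ULVs use
*S* ≡ 1. Fitting is a constrained real-coded genetic algorithm (islands
with migration, fitness-directed crossover, final polish phase, multi-start
with lowest reduced χ² winning) under the standard constraint set: fixed
σ<sub>CholCH₃</sub> = 2.98 Å, headgroup volume target 331 Å³, 2 Å proximity
walls, σ_HC and fragment-volume windows, positivity of the water and
methylene distributions. Cholesterol admixtures are merged into the CH₂
distribution (630 Å³ per molecule), and mixtures report the apparent area
per lipid. Derived thicknesses come from the fitted profile: *D*<sub>B</sub>
via an error-function fit to the water distribution (or its exact
integral), *A* = 2V_L/*D*<sub>B</sub>, *D*<sub>W</sub> = d − *D*<sub>B</sub>.

## Worked example

Generate a synthetic POPC-like MLV SAXS curve (d = 64 Å, η = 0.06, 1%
noise) and refit it from scratch:

```bash
sdpgap simulate --preset popc_saxs_mlv --out demo --seed 3
cat > demo/run.yaml <<'YAML'
scheme: {preset: pc, n_CH2: 28, n_CH: 2}
V_L: 1267.8
datasets:
  - path: popc_saxs_mlv.dat
    name: popc
    radiation: xray
    geometry: mlv
fit: {population_size: 300, max_generations: 200, stagnation_generations: 200, n_starts: 4}
output_dir: demo/out
YAML
sdpgap fit --config demo/run.yaml --seed 1
sdpgap report --result demo/out/report.json
```

The fit prints the generation log to stderr and ends with

```
chi2_red = 1.085; report: out/report.json
```

and `report` re-derives the structural parameters from the stored state:

```
D_HH   = 32.600
D_C    = 13.400
D_B    = 36.603
D_W    = 27.397
A      = 69.272
d      = 64.000
eta    = 0.060
```

Reading these numbers: the curve is fit to within its noise
(χ²_red ≈ 1.09), and the lattice quantities are exact — d = 64.000 Å and
η = 0.060 against a ground truth of 64 Å and 0.06. The profile quantities
land on the flat likelihood ridge discussed in `docs/methods.md`: at 1%
noise a single X-ray curve constrains D_C, A and D_B only to ~5% (here
D_C = 13.40 vs 14.32 Å truth, A = 69.3 vs 65.1 Å²), because methylene and
water are nearly iso-electron-dense and the glycerol fragment can absorb a
shift of the chain interface. Joint refinement with SANS contrast pairs —
or simply comparing fits across seeds, which is what the uncertainty
machinery does — exposes and resolves this. `out/` also holds
`profiles.csv` (volume probabilities, electron density, neutron SLD) and
`fit_curve_popc.csv` (data vs model).

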