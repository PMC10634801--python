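# layervn

Layer-dependent (laminar) BOLD fMRI promises to separate feedforward from
feedback processing by resolving activity at different cortical depths, but
gradient-echo BOLD is contaminated by draining veins: intracortical veins
carry deoxygenation changes from deep layers up toward the pial surface
(the *leakage* effect), and large pial veins bleed an extravascular
susceptibility field into neighbouring voxels (the *blooming* effect).
Both inflate the apparent dependency between layers.

`layervn` implements the physics and analysis stack of a velocity-nulled
(VN) laminar fMRI experiment, driven entirely by a synthetic
cortical-column generator so that every stage is testable without scanner
data. It is aimed at researchers who want to reason quantitatively about
vein suppression and laminar connectivity pipelines before (or instead of)
acquiring sub-millimetre data.

## The model

A small bipolar ("velocity-nulling") gradient pair attenuates intravascular
signal according to the intravoxel incoherent motion (IVIM) picture. Each
vascular pool — capillaries, penetrating veins, cortical arteries — is
summarised by a pseudo-diffusion coefficient set by its mean segment length
*l* and blood velocity *v* (here D\* = *l·v*/10, which reproduces the
standard operating points 10⁻⁸, 2.5×10⁻⁷ and 1.2×10⁻⁶ m²/s), and retains

&nbsp;&nbsp;&nbsp;&nbsp;S/S₀ = exp[−b·(D\* + D_blood)] ≈ exp(−b·D\*)

of its signal at diffusion weighting *b*. Because capillary D\* is two
orders of magnitude below venous D\*, a *b* of a few s/mm² strips
draining-vein signal while leaving the microvasculature nearly untouched.
The critical velocity of the pair is v_c = 1/(2γGΔδ); at fixed gradient
amplitude with Δ = δ this gives v_c ∝ b^(−2/3), anchored here at
(b = 6 s/mm², 16.8 mm/s).

On top of that physics, the synthetic generator builds complex-valued,
depth-resolved time series: laminar neural sources (block-design task or
band-limited 0.01–0.1 Hz resting fluctuations with a prescribed
cross-region, cross-layer correlation structure), cumulative upward vein
drainage, an inverse-square pial blooming term in magnitude *and* phase,
VN attenuation per compartment, and complex Gaussian noise. The analysis
side mirrors standard laminar practice: temporal phase unwrapping and
phase regression, zero-phase Butterworth filtering, double-gamma-HRF GLMs,
20 equidistant layers, depth profiles with 95% CIs, seed-based FC,
depth×depth Fisher-z matrices, laminar connectomes, and paired /
one-sample group tests with Benjamini–Hochberg FDR.

## Worked example

```bash
python analysis/01_physics_attenuation.py
```

prints

```
retention at b = 7 s/mm^2:
  capillary 0.9324   vein 0.1738   artery 2.25e-04
critical velocities (mm/s):
  b = 6 -> 16.8
  b = 7 -> 15.2
  b = 8 -> 13.9
```

i.e. at the b = 7 s/mm² operating point the penetrating-vein pool keeps
only 17% of its signal (arteries essentially none) while capillaries keep
93% — the selectivity that makes the VN gradient a draining-vein filter
rather than a global attenuator. The group-level twin of the empirical
inter-layer-dependency result:

```bash
python analysis/03_interlayer_fc_contrast.py
```

```
superficial off-diagonal cells significantly reduced under VN: 30/30
mean dz (b0 - b7) superficial block: 0.369
total significant cells (any direction): 186
```

On a paired 14-subject synthetic cohort, velocity nulling significantly
(FDR q < 0.05) reduces the Fisher-z coupling between superficial depths —
exactly where drained vein signal accumulates — rather than attenuating
all cells uniformly. The remaining drivers (`analysis/02_*`,
`analysis/04_*`) produce the depth-profile and laminar-connectome tables;
each writes TSVs under `results/` and states its finding on stdout.

The same functionality is exposed as a CLI
(`layervn {physics,simulate,preprocess,layers,fc,run}`); see
`layervn --help`.

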