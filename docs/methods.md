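# Methods

## Vascular physics

Intravascular signal under a small bipolar (velocity-nulling) gradient is
modelled as IVIM pseudo-diffusion: blood water moving through a randomly
oriented vessel network behaves like a diffusing spin with coefficient D\*
set by the mean segment length *l* and mean velocity *v* of the pool, and
the retained fraction is S/S₀ = exp[−b (D\* + D_blood)]. The package's
convention is **D\* = l·v/10**. The more common heuristic l·v/6 does not
reproduce the standard published operating points for all three pools
(capillary: l = 100 µm, v = 1 mm/s → 10⁻⁸ m²/s; penetrating vein: 1 mm,
2.5 mm/s → 2.5×10⁻⁷; cortical artery: 1 mm, 12 mm/s → 1.2×10⁻⁶), whereas a
divisor of 10 reproduces all three exactly; we adopt it and note the
discrepancy here. D_blood defaults to 0 (D\* ≫ D_blood); the full form is
available on `VesselCompartment`.

Canonical internal units are mm and s (b in s/mm², D\* in mm²/s).
Constructors accept SI and convert at ingestion, so the attenuation formula
can never mix units.

**Critical velocity.** v_c = 1/(2γGΔδ) when the waveform is known. When
only *b* is known, we assume rectangular back-to-back bipolar lobes at
fixed gradient amplitude with Δ = δ, for which b ∝ δ³ and v_c ∝ δ⁻²,
hence v_c ∝ b^(−2/3). The law is anchored at (b = 6 s/mm², v_c =
16.8 mm/s); it then yields 15.2 and 13.9 mm/s at b = 7 and 8, matching the
published operating points to better than 0.05 mm/s. The absolute G, δ, Δ
of a real implementation are sequence-specific and are deliberately not
assumed.

**Extravascular falloff.** The blooming field of a large pial vessel is
taken as inverse-square in distance *referenced to the vessel surface*:
fold reduction = (distance/radius)². For a 0.3 mm vessel evaluated one
0.9 mm voxel away this gives the 36-fold bound; the surface reference is
the convention that reproduces that bound exactly.

## Synthetic cortical column

Depth runs from −0.125 (below the GM/WM boundary) to 1.0625 (above the
CSF/GM boundary), sampled at 20 bin centres; the grid extends slightly
beyond the ribbon so boundary voxels are represented. Signal units are
percent of a baseline of 100 a.u.

Per depth *d* and time *t* the magnitude forward model is

    m(d,t) = 100
           + A_cap(b) · w_tis(d) · λ(d,t)                  (tissue/capillary)
           + A_vein(b) · w_vein(d) · Σ_{d'≤d} f^(d−d') λ(d',t)   (drained veins)
           + A_art(b) · g_art · w_tis(d) · λ(d,t)          (local arteries)
           + g_pial · (r/ρ(d))² · λ̄(t)                     (pial blooming)
           + ε(d,t)

where λ is the laminar neural signal, A_x(b) the compartment's VN
attenuation, f the per-depth-step drain fraction, w_vein linear in depth
(vessel density grows toward the surface), ρ(d) the distance from the
pial vessel surface (cortical thickness 2 mm, vessel diameter 0.3 mm) and
λ̄ the column-mean signal carried by the pial vein. The pial term is
extravascular and is therefore *not* attenuated by b.

**Phase model.** Voxel phase is proportional to the pial blooming
magnitude only (0.02 rad per unit), plus Gaussian phase noise scaled to
the magnitude SNR. Penetrating veins are sub-voxel and quasi-randomly
oriented, so their net contribution to voxel phase largely cancels; the
coherent phase comes from the single large pial vessel. This is the
minimal model under which phase regression removes pial contamination
(its empirical role) while velocity nulling removes intravascular vein
signal — the two mechanisms stay separable. Tissue carries no phase.

**Defaults and why.** drain fraction 0.4 (substantial but lossy upward
drainage); vein gain 0.6 at the surface, rising linearly from ~0 at the
WM boundary; arterial gain 0.1 (arteries contribute little BOLD);
pial magnitude gain 1.0 a.u. at the surface voxel; task amplitude 2% of
baseline (typical 3T block-design response); resting fluctuation amplitude
1% per unit-variance source; noise SD 1.0 a.u. per volume, i.e. temporal
SNR ≈ 100 for denoised sub-millimetre data. Task runs use 18 blocks of
30 s ON / 30 s OFF at TR 4 s (270 volumes); resting runs use 300 volumes.

**Resting sources.** One band-limited (0.01–0.1 Hz, the analysis band)
unit-variance Gaussian process per (region, layer), correlated across
sources by the Cholesky factor of the network's edge-specified correlation
matrix (validated positive semi-definite; offending edge lists are
reported otherwise). Sources deposit over depth with Gaussian kernels
(σ = 0.12) centred at 0.875 / 0.475 / 0.125 for superficial / middle /
deep — the centres of the canonical projection windows.

**Cohorts.** N = 14 by default, matching the group-study scale the
generator emulates. Each subject's drain fraction, vein gain and
fluctuation amplitude are jittered once (10% between-subject SD), and the
b = 0 and b = 7 runs share the subject's neural sources so paired
contrasts are meaningful; only the acquisition noise differs.

**What the generator does not emulate** (and what passing tests therefore
do not show): 3-D vasculature and voxel geometry, EPI/k-space artefacts,
motion, physiological noise spectra, ICA-cleanable structured artefacts,
and realistic thermal-noise correlations after PCA denoising. Results on
this generator validate the *pipeline logic*, not scanner performance.

## Preprocessing

Phase is unwrapped temporally (successive differences bounded by π; sites
are independent so no spatial unwrapping exists). Phase regression is
ordinary least squares of magnitude on [1, phase] per site, keeping the
residual plus the site mean; it runs *before* filtering. OLS was chosen
over orthogonal-distance variants for determinism and because the phase
regressor is modelled noise-free up to its own Gaussian term; ODR is a
documented alternative. A constant phase regressor degrades to a warning
and pass-through.

Filters are zero-phase forward–backward Butterworth of order 4 (band-pass
0.01–0.1 Hz for rest, high-pass 0.01 Hz for task); band edges above the
Nyquist frequency at the given TR raise errors rather than aliasing.

The HRF is the canonical double gamma (delays 6/16 s, unit dispersions,
undershoot ratio 1/6), peak-normalised; GLM effects are reported as
percent signal change = 100·β·(regressor peak-to-peak)/baseline with OLS
t statistics, converted to z through the Student-t survival function so
large effects stay monotone instead of saturating.

## Layering

Equidistant (not equivolume) layers: layer k of n covers
[lo+(k−1)w, lo+kw) with w = (hi−lo)/n over the −0.125..1.0625 grid, last
interval closed. 20 layers by default (≥ 4 × the effective depth
resolution). Volume-path upsampling is nearest-neighbour replication
(factor 5: 0.9 mm → 0.18 mm) so values are unchanged. Canonical
depth-sampling windows: superficial 0.85–0.90, middle 0.45–0.50, deep
0.10–0.15, overall 0.10–0.90; each narrow window contains exactly one
bin-centre depth of the default grid.

## Connectivity and group statistics

Depth×depth matrices are pairwise Pearson correlations of layer time
series, Fisher-z transformed, averaged over columns when several are
supplied; diagonals (self-correlation) are masked from all statistics, and
constant rows mask their cells with a warning. Seed-based maps offer both
the GLM route (seed time course as regressor; t → z via the normal
quantile of the t tail) and the Pearson/Fisher-z route, matching the dual
usage in the field (GLM for maps, Pearson for matrices).

Group inference is element-wise: paired t for condition contrasts and
layer-pair differences, one-sample t for connectome cells, always on
Fisher-z values, with Benjamini–Hochberg FDR at q = 0.05 across the
unmasked cells of each analysis. Surface-based cluster-extent corrections
are out of scope for the synthetic grid; BH FDR is used uniformly.
Degenerate cells (zero paired variance) map to t = 0 when the mean
difference is also 0, ±∞ otherwise.

## Problem sizes

The bundled analyses and acceptance-grade tests use: one 20-depth column
per region, 270-volume task runs, 300-volume resting runs, 14-subject
cohorts for the condition contrast, 8-subject cohorts across 50 seeds for
connectome-edge recovery, and 100 seeds for null calibration. These sizes
keep every driver in the seconds-to-minutes range on one CPU while leaving
the group effects far from threshold.

## Known limitations

* The leakage model is a one-parameter geometric drain; real venous
  drainage has tree structure, delays, and nonlinear deoxygenation
  coupling.
* Absolute vein/tissue signal fractions are configuration, not
  measurement; only their qualitative ordering is grounded.
* The b ↔ v_c mapping assumes the rectangular Δ = δ waveform; other
  waveforms change the constant (the anchored form sidesteps this but
  cannot extrapolate across hardware).
* Phase is pial-driven by construction, so phase regression cannot be
  *worse* than neutral here; on real data its efficacy varies with vessel
  geometry and coil phase stability.
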