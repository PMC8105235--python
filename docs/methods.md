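# Methods

This note documents the models, numerical choices, and defaults behind
`fpact`, and what the phantom experiments do and do not demonstrate.

## Two-volume first-pass perfusion

The tissue model is a single compartment with inflow only: while
measurements are made before venous contrast outflow, each myocardial
voxel accumulates iodine at a rate proportional to its perfusion. In HU
terms,

    HU(t) = HU_0 + P · ρ · ∫₀ᵗ C_a(τ) dτ,

with `C_a` the arterial enhancement above the blood baseline (HU), `ρ =
1.055 g/mL` the tissue density, and the integral in HU·min. Averaging over
the segmented myocardium and inverting for perfusion gives the estimator
used throughout:

    P_AVE = ΔHU_AVE / (Δt_min · C_in · ρ),
    P_voxel = P_AVE · ΔHU / ΔHU_AVE,

where `C_in` is the aortic-root enhancement averaged between the two
volumes. An explicit voxel-volume factor makes the summed-enhancement form
(`dM_C/dt` normalised by `C_in` and `M_T`) dimensionally consistent; it is
algebraically identical to the closed form above.

**Approximation error.** The estimator replaces the window-mean arterial
enhancement with the two-point average `(C_a(t1) + C_a(t2))/2` — a
trapezoid rule. It is exact when `C_a` is linear across the V1→V2 window
and biased by the curvature term otherwise. On the default phantom bolus
the bias is ≈ +2.8%; the acceptance tests assert < 5%. `C_in` is
baseline-subtracted by default (the derivation requires the
contrast-attributable signal); the unsubtracted variant is available via
`subtract_baseline=False`.

**Conventions.** Grids are (x, y, z), 0-based, world coordinates in mm
with voxel centres at `(index + 0.5) · spacing`; all masks must share the
volume grid exactly. Δt comes from volume timestamps and is converted to
minutes inside the estimator. Negative per-voxel values (noise) are
retained in maps and in regional means; clamping is a display concern
only. Regional CFR is the ratio of paired regional mean perfusions, not
the mean of the voxel-wise ratio map — the two differ under noise, and
the ratio-of-means is the stable choice. Voxel-wise CFR is undefined
(NaN) where rest perfusion falls below a floor (default 0.1 mL/min/g).

## Acquisition logic

Bolus tracking is sample-and-hold: the trigger is the first discrete
sample at or above `baseline + threshold` (default 140 HU), with no
interpolation — this mirrors a scanner monitoring scan and keeps test
oracles exact. An optional whole-frame latency models the gap between the
monitoring frame and the first full volume (default 0). The TDC peak
breaks ties to the earliest sample. ΔT estimation from injection
parameters is not implemented; ΔT is always TDC-derived here.

## Territory assignment

Voxels are labelled by multi-source Dijkstra on the 26-connected voxel
graph with Euclidean-mm edge weights. Paths are restricted to the
myocardium plus a thin straight corridor joining each (epicardial)
centerline voxel to its nearest myocardial voxel; corridors extend the
domain but carry no sources, so distances are measured from the
centerline voxels themselves. The cited assignment literature does not
pin down the cost function; myocardium-restricted Euclidean geodesics are
adopted as the canonical interpretation and isolated behind
`_geodesic_distances` so alternatives can be swapped. Centerlines are
resampled at ≤ half-voxel steps and mapped to nearest voxel centres; ties
between vessels break in the fixed order LAD < LCx < RCA; unreachable
voxels fall back to straight-line distance with a warning. Stenosis
sub-partition splits the vessel's source points at the stenosis
arc-length and re-labels only that vessel's voxels (ties go proximal); a
marker at 0 or at full length is rejected as degenerate.

## Dosimetry

Per-volume CTDIvol (32-cm reference phantom) scales linearly with tube
current at fixed kVp; kVp scaling is deliberately unsupported and errors
out. The low-dose protocol is rest V1 (50 mA) + rest V2/CTA (200 mA) +
two stress volumes (50 mA); the reference protocol is 2 × 20 volumes at
200 mA. SSDE uses the AAPM TG-204 32-cm-phantom exponential fit
`f(D) = 3.704369 · exp(−0.03671937 · D)` (valid 6–55 cm); one shared
factor scales all components. Effective dose is `DLP × k` with
`k = 0.014 mSv/(mGy·cm)` for the chest — the coefficient applies to DLP,
which is forced by the protocol's own arithmetic (8.05 mGy × 16 cm ×
0.014 = 1.80 mSv). The bolus-tracking slab dose is excluded from totals
(an optional field records it). The report computes SSDE from the
configured diameter rather than reproducing any externally stated
SSDE/CTDI ratio, and notes the factor used.

## Agreement statistics

Ordinary least squares of test on reference with t-based 95% CIs; Pearson
r with Fisher-z CI; Lin's CCC with population (1/n) moments (sample-moment
option available) and Lin's asymptotic z-transform CI; RMSE about the
identity line (accuracy); RMSD about the fitted line (precision);
Bland–Altman bias ± 1.96 SD limits of agreement.

## The phantom

The phantom emulates a swine-like acquisition: a half-ellipsoid LV
myocardial shell (outer semi-axes 17×17×34 mm, inner 11×11×28 mm) on a
96³ grid of 0.43 × 0.43 × 0.5 mm voxels, a disjoint aortic-root cylinder,
and three epicardial centerlines (base→apex at azimuths 120° apart) lying
on the outer shell surface. Ground-truth territories are generated with
the same geodesic metric the analysis uses, so territory tests check
implementation agreement at full scale while the independent brute-force
Dijkstra oracle (networkx) establishes correctness on small grids.

**Arterial input.** The default bolus is a gamma-variate
`A·((t−t0)/(αβ))^α·exp(α−(t−t0)/β)` with A = 170 HU above baseline,
α = 1.5, β = 10 s, t0 = 1.5 s, sampled on 26 frames at 0.72 s (≈ one
cardiac cycle at the swine heart rates involved). This broad, flat-topped
bolus — consistent with the protocol's ≈ 8 s contrast injection plus
dispersion — was chosen so the phantom reproduces the study conditions
jointly: a trigger(140 HU)→peak delay of 5.76 s on the frame grid (in-vivo
range 4.10–8.93 s, mean 5.69 s), a two-point C_in curvature error ≈ 2.8%,
and < 2% sensitivity of recovered P_AVE to ± 2-frame mistiming of V2. A
sharp, high-amplitude first-pass spike (several hundred HU) would place
the trigger low on the strongly concave rise and inflate the two-point
error to > 10%, which is not how the validated protocol behaves; the peak
amplitude is therefore a deliberate model choice, not a measured value. A
`LinearRampAIF` is provided to exercise the exactness limit. The
gamma-variate time integral uses the exact closed form through the
regularised lower incomplete gamma function; tests cross-check it against
fine-grid quadrature.

**Flows and noise.** Default per-territory flows are the measured swine
means: rest 0.58/0.53/0.37 and stress 2.07/2.15/1.79 mL/min/g for
LAD/LCx/RCA, with an optional mid-LAD stenosis whose distal stress flow
is 1.20 mL/min/g. Noise is stationary Gaussian in HU with
σ(mA) = σ_ref · (mA_ref/mA)^0.5 (quantum-noise scaling), default 25 HU at
50 mA; structured/streak noise is out of scope. Recirculation drift is an
optional constant HU offset (default 0). Identical spec + seed yields
bit-identical volumes.

**What the phantom does not emulate.** Cardiac/respiratory motion, beam
hardening and metal artifacts, partial-volume at tissue boundaries
(masks are binary on the analysis grid), venous outflow, four-chamber
anatomy (the method integrates over an arbitrary mask, so an LV shell
suffices), and projection-domain physics. Passing phantom tests therefore
demonstrates correctness of the estimator, the geometry pipeline, and the
noise behaviour — not robustness to registration error or motion, which
real acquisitions must handle upstream (inputs are assumed co-registered).

## Flow-capacity classes

Six classes from "scar" to "normal" are assigned on the joint
(CFR, stress perfusion) plane by a lower-left-dominant staircase: a point
gets the best class whose CFR **and** stress lower bounds it meets, so the
worst axis governs. The numeric cutoffs are population-derived and ship as
a mandatory YAML config; the bundled example file contains placeholder
values for phantom experiments and says so prominently.

## Problem sizes

Unit tests run on a 48³ coarse-voxel phantom with identical anatomy; the
acceptance-style tests use the full 96³ default grid (≈ 146 k myocardial
voxels), 20 noise seeds for the stochastic recovery check, and ≤ 32³
grids for brute-force oracle comparisons. These sizes were chosen as the
smallest that exercise full-resolution behaviour.
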