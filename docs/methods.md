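# Methods

## Tissue model

The simulator is a monodomain reaction–diffusion model
∂u/∂t = D∇²u − (J_fi + J_so + J_si) with the three-variable
phenomenological kinetics of the Fenton–Karma family: a fast inward
current J_fi = −v·(1−u)(u−u_c)/τ_d gated by ``v``, an ungated slow outward
current J_so (u/τ_0 below threshold, 1/τ_r above), and a slow inward
plateau current J_si = −w·(1+tanh k(u−u_csi))/(2τ_si) gated by ``w``.
``u`` is dimensionless (0 = diastole, ~1 = peak); millivolt conversion is
the affine map V = DMP + APA·u with DMP = −56 mV, APA = 80 mV, matching
whole-cell recordings from the immature atrial-like phenotype.  This is
the smallest model that supports spiral reentry, APD/CV restitution, and
alternans; it makes no claim about which sarcolemmal currents the real
cells express.

**Numerics.** Explicit forward Euler, 5-point Laplacian, mirror (no-flux)
boundaries on the sheet mask; dt = 0.02 ms, dx = 0.1 mm,
D = 0.0054 mm²/ms.  The diffusive stability bound dx²/(4D) ≈ 0.46 ms is
enforced at configuration time.  Kernels are numba-compiled; a 2.5-s run
of the 100×100 disc takes ~25 s on one CPU.  Planar-front speed at
dx = 0.1 mm agrees with a dx = 0.05 mm reference to ~2%.

**The "hESC-atrial" profile.** The defaults (τ_d = 1, τ_r = 70,
τ_si = 85, τ_0 = 30, τ_v+ = 30, τ_v1− = 250, τ_v2− = 140, τ_w+ = 300,
τ_w− = 120, u_c = 0.13, u_v = 0.04, u_csi = 0.6, k = 10) were tuned once
(`scripts/calibrate_profile.py` re-measures them) to the emergent regime
of the monolayers this package models: single-cell APD90 ≈ 198 ms, planar
CV ≈ 5.2 cm/s at CL 800 ms, monotone CV restitution down to CL 300 ms,
and a stable rotor of CL ≈ 300 ms on the 1-cm disc with a wide S1–S2
vulnerable window (S2 ≈ 260–320 ms).  Two regime choices matter and were
deliberate: slowing the upstroke (τ_d) alone blocks propagation unless the
diastolic outward (τ_0) and the v-gate closing time (τ_v+) are slowed with
it, and a low-excitability medium has a spiral core too large for a 1-cm
sheet — the profile therefore keeps τ_d moderate and reduces D to reach
the ~5 cm/s conduction velocity of the monolayers.

**Rate limits.** With APD90 ≈ 200 ms the tissue cannot follow 1:1 pacing
below CL ≈ 300 ms (2:1 responses appear), so the CV-restitution property
is asserted over CL 800→300 ms.  Real monolayers with comparable optical
APD face the same electrophysiological bound.

**Stimulation.** The spontaneous pacemaker is modelled as a periodic
suprathreshold point stimulus at 78 bpm — it reproduces a focal activation
pattern without extra automaticity variables.  Rotor induction uses
cross-field S1–S2 (planar S1 from the sheet edge, half-field S2 into the
repolarization tail); burst pacing (CL 50 ms) is available and is the
negative control on small sheets, where the ~1.2 cm wavelength exceeds the
geometry and induction correctly fails.

## Drug models

**Use-dependent Na-channel block.** Per beat the blocked fraction relaxes
toward the within-AP equilibrium b_eq with rate k_block during the
activated phase (duration d = 250 ms) and unbinds with constant τ_rec
during diastole; the steady state has the closed form
B = b_eq(1−E)G/(1−EG) with E = e^{−k·d}, G = e^{−(CL−d)/τ_rec}.  The
classical no-unbinding variant is the b_eq = 1 special case — but it is
*infeasible* for the measured operating points: conditioning the fixed
point on B(2 s) = 0.506 pins B(330 ms) into [0.86, 1) for every d, whereas
the measurement is 0.858 ± 2.1%.  Binding *and* unbinding while the
channel is accessible (b_eq < 1) is the standard guarded-receptor
resolution; with k_block saturating (0.05 /ms), two-unknown root-finding
gives b_eq = 0.880, τ_rec = 3162 ms and reproduces both operating points
to < 1e−9.

**Na availability.** Boltzmann inactivation h(V) = 1/(1+e^{(V−V½)/k});
with k fixed at 5.5 mV, V½ = −56.04 mV is solved so the availability loss
between holding potentials −80 and −58 mV equals the measured 40.43%.

**Sheet-level dosing.** The flecainide-like drug scales the fast-inward
conductance; the dofetilide-like drug scales the repolarizing conductance
(default 0.8) and adds a +4 mV diastolic depolarization whose
availability cost also slows the upstroke.  At the full clamp-measured
block (86% at rotor rates) the phenomenological model loses propagation
outright, while the experimental rotors survived 10 μM flecainide — a
single conductance scaling in a 3-variable model overstates propagation
sensitivity.  The default sheet dose is therefore g_fi_scale = 0.70, the
strongest block at which the simulated rotor persists and shows the full
class-Ic signature (CL +27%, peripheral CV −11%, κ −6%, APD +4%); below
~0.6 the simulated rotor terminates (in-silico cardioversion).

## Analysis pipeline

* **Conditioning** — polarity auto-detection by the skewness of dF/dt
  (this dye class darkens on depolarization), per-pixel linear detrend,
  spatial Gaussian (σ = 1 px), zero-phase 40 Hz Butterworth low-pass
  (forward–backward, preserving upstroke timing), per-pixel min–max
  normalization.  Flat pixels are excluded, never interpolated.
* **Activation** — per-pixel time of maximal temporal derivative with
  parabolic sub-frame refinement; 50%-upstroke fallback when the
  derivative SNR < 3; maps with > 30% invalid pixels are flagged.
* **CV** — first-order plane fit of T(x, y) over a 5×5 window (≥ 60%
  valid pixels, residual RMS ≤ 3 ms); v = (b, c)/(b²+c²).  First-order
  rather than quadratic because the sheets are small and optical maps
  noisy; rejected windows carry NaN speed.  Plane-fit speeds are exact to
  < 2% on analytic fronts of 1–10 cm/s in any direction.
* **Phase and PS** — analytic-signal phase of the mean-subtracted trace
  (delay-embedding with τ = quarter period available as a cross-check);
  plaquette winding threshold 1.8π to tolerate discretization; subpixel
  position from the bilinear zero crossing of (cos φ, sin φ); greedy
  nearest-neighbour tracking gated at 1 mm/frame with 3-frame gap
  tolerance.  The rotor CL is the median phase-rotation period on a
  2–3 mm ring around the mean core.
* **Curvature** — isochrone contours (marching squares) at 5 levels
  between the 25th and 75th time percentiles; the longest contour segment
  within 5 mm of the core is fitted with an algebraic (Kåsa) circle;
  κ = 1/R, near-straight fronts capped at κ = 0.01/mm.  Maps of periodic
  activity are first cleaned of the window-edge temporal seam, which would
  otherwise masquerade as a wavefront.  On constructed circles κ matches
  1/R to < 2% for R in 5–50 mm; on rotor data a single-cycle estimate
  still varies by ~±10%, so drug comparisons average κ over ~4 cycles.
* **Rotor metrics** — CV is averaged over a core annulus (< 1.5 mm) and a
  periphery (≥ 3.5 mm; the sheet is only 1 cm, so the periphery cannot sit
  farther out); λ and both excitability gaps use the peripheral CV because
  conduction near the core is electrotonically depressed.  The identities
  temporal_gap = CL − APD90 and spatial_gap = CV·temporal_gap hold exactly
  by construction; CL ≤ APD90 reports zero gaps with a head-to-tail flag.
* **Optical APD** — per-pixel APD90 referenced to the 50% upstroke and the
  per-beat amplitude (robust to alternans), crossings by linear
  interpolation.
* **Single-cell APDs** — referenced to the max-dV/dt activation time
  (patch-clamp convention); repolarization levels per-beat.  Phenotype:
  APD30/APD90 < 0.35 → atrial-like, ≥ 0.35 → ventricular-like, overridden
  to nodal-like when APA < 70 mV and dV/dt_max < 10 V/s; 0.35 sits midway
  between the measured cohort means (0.17 and 0.57) and the comparison is
  always on per-trace ratios, not ratios of cohort-mean APDs.
* **Alternans** — mean |ΔAPD| with a consistent-phase requirement
  (strictly alternating signs) and a 5 ms threshold; 2-ms random jitter
  produces < 5% false positives in a 1000-series null.

## Synthetic data: what it does and does not emulate

Analytic fixtures (planar, target and Archimedean-spiral movies; vortex
phase fields; parametric AP trains with stretched-exponential
repolarization) have exact ground truth and validate each estimator in
isolation.  The reaction-diffusion runs add front curvature effects,
restitution, electrotonic loading and drug responses.  Neither reproduces
motion artifact (suppressed pharmacologically in the experiments),
ratiometric dye behaviour, cellular heterogeneity, fibroblast coupling, or
camera fixed-pattern noise — so passing tests certify the *estimators* and
the *model's qualitative pharmacology*, not quantitative agreement with
any particular dish.

The restitution-pair generator draws CLs evenly over 700–1250 ms and adds
Gaussian noise with σ_e = |slope|·σ_CL·√(1/r²−1), i.e. calibrated to the
published r² = 0.69.  A consequence worth stating: with n = 10 points per
set, the OLS slope standard error is slope·√((1/r²−1)/(n−2)) ≈ 0.064, so
the fitted slope lands within ±0.05 of the true 0.30 in only ~60% of
seeds.  The acceptance test that demands ≥ 90% at n = 10 is therefore
expected to fail for any generator honestly matched to that r²; the
adjacent tests verify instead that the recovery is unbiased and that the
realized r² matches the calibration.

## Known limitations

The simulated rotor is tighter than its experimental counterpart
(κ ≈ 0.4/mm vs 0.08/mm): on the same 1-cm disc the model rotor curls with
a smaller core, so curvature magnitudes are not comparable between model
and dish even though every drug-signature *direction* is.  Core meander is
not analysed (trajectories are tracked but no meander statistics are
derived), multi-rotor interactions are out of scope, and the 3-variable
model cannot separate I_Kr from other repolarizing currents — the
dofetilide-like scaling lumps them.
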