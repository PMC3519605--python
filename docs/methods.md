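# Methods

`vbsflow` re-creates, on synthetic data with known ground truth, the full
analysis chain of an MRI-based hemodynamic study of the vertebrobasilar
system (VBS): the two vertebral arteries (LV, RV) merging into the basilar
artery (BAS). The chain is: fixture generation (geometry + flow), PCMR flow
quantification, pulsatile incompressible flow simulation, and wall-shear /
mixing metrics. This note records the models, the defaults and their
rationale, the numerical choices, and what the synthetic setting does and
does not demonstrate.

## Subject fixtures

Five fixtures (A–E) parameterise the study's published per-subject
characteristics: the configuration class (A, B Walking; C, D Tuning Fork;
E Lambda), the dominant vertebral side (A, D, E right; B, C left), and the
cycle extremes and peak-systole value of the dominant/non-dominant
vertebral flow ratio (A 1.18–2.22, at peak 2.22; B 2.07–3.20, at peak 2.22;
C 1.34–1.90, at peak 1.47; D 1.13–2.13, at peak 1.13; E 1.44–1.95, at peak
1.13). Everything else the study measured per subject (absolute flow
levels, vessel calibres, cycle period) is not published per subject, so the
fixtures use one set of physiologically representative defaults: cardiac
period 1.0 s; combined diastolic flow 1.6 ml/s with a systolic bump of
amplitude 3.4 ml/s (combined peak 5.0 ml/s, in the range of basilar +
vertebral flows reported for healthy adults); vertebral lumen radii 1.7 mm
(dominant) and 1.4 mm (non-dominant), basilar 1.62 mm.

The published table for subject E is internally inconsistent: its
peak-systole ratio (1.13) lies below its own cycle minimum (1.44), which is
impossible for a pointwise ratio with fixed dominance. The fixture carries
the published numbers verbatim; the waveform generator, whose default
policy is `clamp`, pulls the peak-systole target to the nearest band edge
(1.44) and a `strict` policy raises instead. Subject D's peak value equals
its minimum (1.13), which is feasible and used as-is.

## Waveform synthesis

The combined (LV+RV) flow is a diastolic plateau plus a periodic von-Mises
systolic bump, `Q(t) = q_dia + q_amp exp(kappa (cos(2 pi (t - t_ps)/T) - 1))`
with concentration `kappa = 9` (systolic width about a quarter cycle) and
peak systole at 0.16 T. The two vertebral waveforms are obtained by
splitting this total with a time-varying ratio curve `r(t)`:
`Q_dom = Q r/(1+r)`, `Q_non = Q/(1+r)`. The ratio curve is a periodic
monotone (PCHIP) interpolant through control points placed at the ratio
extremes and at peak systole. Because a monotone interpolant takes its
extrema exactly at the data points, the cycle minimum and maximum of the
ratio equal the prescribed values by construction — no parameter solving,
no overshoot. Control instants are snapped onto the cardiac phase grid so
the extremes also survive sparse PCMR sampling (a flat extremum sampled at
a phase instant is reconstructed exactly by the shape-preserving
interpolant).

## PCMR synthesis and quantification

Velocity image series emulate retrospectively gated phase-contrast MR:
21 or 25 cardiac phases, 0.31 mm reconstructed in-plane pixels, VENC
100 cm/s, additive Gaussian velocity noise with standard deviation 2% of
VENC (roughly SNR 50 in the phase-difference reconstruction), optional
velocity wrapping beyond VENC. Each phase map is the analytic pulsatile
profile (Womersley superposition of the waveform's first 10 harmonics,
which is below the reconstruction Nyquist of a 21-phase acquisition) in a
rigid circular tube, sampled at pixel centres with a deterministic
sub-pixel centre offset. The stored ground truth is the flux of the
truncated harmonic series itself, so round-trip errors measure the
quantification chain, not the truncation.

Quantification segments the magnitude of the temporally averaged velocity
map (temporal averaging cancels the zero-mean noise while arterial flow is
unidirectional): an Otsu threshold finds the fast lumen core and a
hysteresis threshold grows it down to a low rim level
(max of 2% of the core mean and background + 4 sd), recovering the slow
no-slip annulus. Flow integration weights boundary pixels by a
partial-volume coverage fraction estimated from the mask's own distance
transform — deliberately truth-free, mirroring real partial-volume
handling. Sparse flow samples are interpolated to the 500-point cycle with
a periodic shape-preserving piecewise cubic (linear interpolation is
available as an option); the interpolant passes through every sample.

Noiseless, the chain recovers the generated waveform to about 0.1% and the
published ratio characteristics to well under 1%. With 2% VENC noise the
per-phase flux noise is irreducible (sigma_Q ≈ sigma_v A_pixel sqrt(N)), so
recovery accuracy is stated relative to the peak flow: ≤1% of peak
noiseless, ≤3% of peak at 2% noise. Pointwise relative errors at the
diastolic minimum are larger — an honest property of PCMR flow
quantification, not of this implementation.

## Geometry

Centerline trees with per-point radii represent each vessel; the lumen is
the union of tubes (a signed-distance field, negative inside), which blends
the junction smoothly. Class construction works in a canonical frame
(basilar initially along +z): vertebrals are circular arcs ending at the
apex with prescribed approach angles, with the final two diameters straight
so that junction tangents — and hence the confluence angle — are well
defined. Walking bends both vertebral arcs the same way and the basilar
continues out of the arcs; Tuning Fork uses mirror-symmetric approaches
with opposite bends; Lambda makes the dominant vertebral nearly collinear
(2 degrees) with the basilar and brings the minor one in at about 50
degrees. The basilar carries a gentle planar curve (45 degrees over 22 mm
by default, bend radius ≈ 23 mm) so Dean-type secondary flow develops as in
vivo. Default confluence angle is 74 degrees, the study population's mean.

Classification uses fixed-precedence rules on centerline data only:
(1) Lambda if one vertebral's terminal tangent deviates < 20 degrees from
the basilar's initial tangent while the other deviates > 40 degrees;
(2) Walking if the two vertebrals' bend directions over their distal thirds
agree — compared as the signs of their binormals (tangent x curvature)
projected on a shared reference normal, which is invariant under rigid
motion and flips consistently under mirroring; (3) otherwise Tuning Fork.
A curvature floor of 2 /m treats nearly straight vertebrals as unbent.
The confluence angle is measured between vertebral tangents averaged over
the two local diameters ending at the apex; where along the vessels such an
angle "should" be measured is not standardised, and this averaging choice
is part of the package's definition.

Flow extensions follow the laminar development length `max(0.06 Re D, 3D)`
per inlet ("developed" policy) and three diameters at the outlet. Because
the solver imposes an analytic fully developed profile at the inlet, the
pipeline's default is the "profile" policy (3D floor everywhere), which
keeps desk-scale domains small without changing the flow that reaches the
junction.

## Flow solver

A from-scratch fractional-step (projection) solver on a uniform staggered
Cartesian grid, with the lumen imposed through the signed-distance field:
cells with negative centre distance are fluid; faces whose centre lies
outside the surface are walls even between interior cells (tight mask); and
the viscous stencil next to a wall places the no-slip plane at its sub-grid
position using the face signed distances (ghost-distance Laplacian). The
pressure Poisson operator mirrors the face graph exactly and is factorised
once per domain (sparse LU), so projected fields are discretely
divergence-free to machine precision — the inflow/outflow mass balance of a
converged field is ~1e-15 relative.

Advection is second-order upwind (first-order fallback at boundaries);
time stepping is explicit with sub-cycling to the advective CFL limit
(CFL 0.4 with a sqrt(3) corner-flow margin). At blood properties
(rho = 1053 kg/m^3, mu = 3.68e-3 Pa s) and desk resolutions (h >= 0.2 mm)
the diffusive stability limit is never binding, so implicit viscosity would
add cost without benefit. Inlets are realised as prescribed-velocity zones:
the first cells of each inlet extension carry the analytic Womersley (or
Poiseuille) profile and the face velocities are rescaled so the discrete
flux entering the free fluid equals the requested flow exactly. The
traction-free outlet is zero normal velocity gradient plus a fixed
reference pressure on the cap layer. Rigid walls, Newtonian fluid, no
turbulence model.

Pulsatile runs follow the study protocol: a steady solve at the
cycle-start flows initialises the run, then `steps_per_cycle` output steps
(500 by default) over `n_cycles` cycles (3 by default), with inter-cycle
L2 velocity differences at matching phases as the periodicity diagnostic.
The steady march stops when the residual `max|du| / (dt U^2/D)` falls below
1e-3 (the study's own convergence criterion is unreported; this tolerance
is surfaced in the configuration).

Validation at 10 cells/diameter: Poiseuille axis velocity within 0.2%
(axis value via a paraboloid fit to the section, removing the half-cell
sampling bias of point interpolation, as one fits discrete velocimetry
profiles), wall shear within ~5%, and Womersley amplitude/phase at
alpha ≈ 2 within 0.3% / 0.1 degree. Errors grow to ~10% at 6
cells/diameter, the coarse setting used for the five-fixture runs.

## Hemodynamic metrics

Wall samples are marching-cubes vertices of the signed-distance surface
with outward normals; samples on caps, inside inlet zones, or near branch
ends are flagged invalid. The WSS vector at a sample is
`mu [g - (g.n)n]` with `g = du/dn` from a one-sided quadratic through the
no-slip wall value and two interpolated probes at d and 2d inside the wall
(d = 2 grid spacings by default: the formula is exact for parabolic
profiles, and deeper probes sit where interpolation is smoothest). TAWSS is
the periodic time average of |tau| over the final cycle; OSI is
`1/2 (1 - |integral tau dt| / integral |tau| dt)` with OSI = 0 where the
denominator vanishes (no shear implies no oscillation). Low-WSS regions
are connected components of wall vertices with TAWSS below 1 Pa, tagged
apex-adjacent (within two basilar diameters of the apex) or inner-wall
(against the local outer-curve direction).

Profile metrics sample the tangent-projected velocity on cross-section
planes: peaks are in-plane local maxima separated by a dip of at least 5%
of the slice maximum (an unstated threshold in the original analysis;
chosen to suppress grid-level ripples at desk resolution), and the skew
index is the offset of the global peak from the lumen centroid along the
outer-wall direction, normalised by the lumen radius. Pathlines integrate
seeds from each inlet disc through the frozen peak-systole field (RK4,
step 0.25 h/U) — matching the single-time-point rendering convention — and
a time-resolved option is available through the field sequence. Mixing is
summarised per basilar station as the origin composition of each half-lumen
(dominant side vs contralateral), and the helicity index is the normalised
velocity–vorticity correlation `<u.w>/(<|u|><|w|>)` over a one-diameter
station slab; it is one operationalisation of "helical flow", not a
claimed equivalent of the original qualitative reading.

The grid-independence protocol solves the steady peak-systole problem on a
base grid (8 cells/diameter) and on a grid with 1.5x as many lumen cells
(spacing divided by 1.5^(1/3)), comparing peak axial velocity on matched
cross-sections and WSS on matched wall samples (probes at the coarse
spacing for both); mean relative differences are reported in percent.

## Problem sizes and determinism

Desk-scale defaults: 6–10 cells/diameter (10–30k lumen cells per
confluence), 100–500 output steps per cycle with CFL sub-cycling, 1–3
cycles. These resolve the qualitative confluence hemodynamics (apex
low-shear pocket, Dean skew and outer-wall shear excess, double-peak
merge, parallel vs mixing pathlines) but sit well below clinical-CFD
fidelity; absolute TAWSS/OSI extremes from subject-specific clinical
models are not reproduced here and are not compared. All randomness
(imaging noise, pathline seeding) flows through explicit integer seeds; a
pipeline case re-run with the same configuration and seed reproduces its
report content hash bit-identically on one platform.

## What the synthetic setting shows — and does not

Passing tests demonstrate that the implemented chain is internally correct
(analytic validation, conservation, metric identities) and that the
published pulse-cycle ratio characteristics, grid-independence behaviour,
and qualitative flow features are recovered end to end from synthetic
inputs with known truth. They do not validate against real TOF/PCMR data:
real lumina are non-circular and tapering, background phase offsets and
ghosting are absent from the noise model, and the tube-union geometry
idealises the junction shape. The published subject-specific WSS/OSI
extremes depend on unreleased MRI data and clinical-resolution solvers and
are therefore out of scope.
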