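# Methods

## Scope and model

`pvsflow` quantifies slow pulsatile flow from time-lapse movies of
individually resolvable tracer particles. The target regime is CSF flow in
pial periarterial spaces: open (non-porous) channels a few tens of μm wide
flanking a surface artery, mean downstream speeds of order 10–20 μm/s,
centerline speeds up to ~50 μm/s, pulsation locked to the cardiac cycle
with the velocity peak a few tens of milliseconds after the ECG R-wave, and
intermittent retrograde motion (backflow) during part of each cycle. The
imaging model is two-photon: 512×512 px frames at 30 Hz, 1.29 μm/px, 16-bit,
red channel for the microspheres and green for the vessel lumen; ECG is
sampled at 1 kHz, respiration at 250 Hz, all sharing t = 0 at the first
frame.

## Synthetic scenes

The generator is first-class code, not a test fixture: it defines the
conditions under which the pipeline is validated.

**Geometry.** Two straight PVS lanes flank a central artery band; flow is
along +x. Default lane width is 0.12× the image height (≈79 μm at 512 px),
in the range of pial PVS widths.

**Flow.** Downstream velocity is V₀·P(y)·M(t): P is the parabola equal to 1
at the lane centerline and 0 at both walls (cross-channel mean ⟨P⟩ = 2/3),
and M(t) = 1 + a_c·g(t−L) + a_r·h(t). g is a train of unit-area
raised-cosine pulses of width 0.15 of the cardiac period centered on each
ECG R-wave, so the "velocity peak follows the R-wave by L" statement is
sharply defined; h is a unit cosine locked to the respiration events. A
`clip_modulation` flag clamps M at zero; it is off by default because
transient flow reversal is a real feature of the measured flows (backflow
fractions around 0.25) and the analytic backflow benchmark requires it.

**Physiology.** Default heart rate 5 Hz and respiration 1.7 Hz — typical
for ketamine/xylazine-anesthetized mice; both configurable. Cardiac cycle
lengths carry 2% Gaussian jitter by default, which also keeps beats from
phase-locking to the 30 Hz frame grid. The ECG trace is a train of 5 ms
Gaussian R-wave spikes; respiration is a cosine with maxima at the breath
events.

**Particles.** Tracers advance by fixed-step RK4 at the frame interval
(sub-stepping available). Because the flow is smooth in space, RK4 at
Δt = 1/30 s is deeply converged for the smooth modulation components; the
0.03 s cardiac pulses are shorter than one frame, so trajectories under
cardiac pulsation carry an integration uncertainty of order 0.1 px over a
second — far below the tracking gate and irrelevant to the statistics
validated here. Each mobile particle also receives a Brownian kick per
frame (D = 0.6 μm²/s, the Stokes–Einstein value for a 1 μm sphere in water
at 37°C), reflecting at the lane walls. This matters: without diffusion
every particle keeps its seeding y forever and the cross-channel profile is
sampled on discrete lanes. Ground-truth velocities are the advective flow
velocities; diffusion is displacement noise. A particle leaving the field
of view re-enters at the opposite edge at the same y under a fresh particle
id. The wrap preserves an exactly uniform spatial sampling density, which
is what makes the 2/3·V₀ cross-channel mean an exact target; uniform
re-seeding of y at the upstream edge would instead equilibrate toward a
density ∝ 1/u(y) and bias the spatial statistics toward slow lanes.

**Rendering.** Particles are isotropic Gaussian blobs (σ = 0.6 px,
amplitude 300 counts) on a 300-count background; with the pipeline's
automatic ~4σ threshold (≈50 counts) a blob occupies 3–4 px, matching the
acquisition this emulates. The green channel is a static artery band plus a
smooth speckle texture (vessel-wall features) so registration has structure
in both axes. The whole scene translates rigidly per frame (uniform jitter,
±1 px default). Noise is Poisson on background+signal plus 5-count Gaussian
read noise; intensities above 65535 warn and clip. Identical config and
seed give bit-identical stacks.

## Analysis choices

**Registration** uses upsampled cross-correlation (matrix-multiply DFT,
upsample factor 10 ⇒ 0.1 px grid) on the green channel — particles move,
the vessel does not — with frame 0 as reference; measured accuracy on known
sub-pixel shifts is ~0.05 px, well inside the 0.2 px contract. Outlier
estimates are flagged automatically (shift deviating >3 px from a ±5-frame
median, or correlation quality below half the running median) and repaired
by linear interpolation; endpoints take the nearest good value. Shifts are
applied by bilinear interpolation on zero-padded frames, so all registered
frames share one geometry at unchanged resolution.

**Masking and detection.** Dynamic background: mean of up to 100 frames
each side, excluding the frame itself, truncated (not padded) at the movie
ends. The default threshold is median + 4× a robust noise scale of the
masked stack; because masking clips negative residuals, the scale comes
from the 84.1th percentile rather than the MAD, which collapses when more
than half the residuals are exactly zero. Area gate 2–30 px brackets the
3–4 px footprint with margin. Centroids are intensity-weighted first
moments — unbiased for symmetric blobs; no deblending of overlapping blobs
is attempted.

**Tracking.** Active tracks forecast by constant-velocity extrapolation
from their last two points; detections within a 5 px gate are assigned by
minimum-total-squared-error bipartite matching, which is deterministic and
(with canonical sorting of detections) invariant to detection order. No gap
closing: a missed detection terminates the track, keeping frames strictly
consecutive so the velocity kernel is well defined. Tracks shorter than 5
frames are dropped. The differentiation kernel is a truncated
derivative-of-Gaussian (σ = 1 frame, support ±3σ) normalized to return
exactly the slope on linear ramps; samples whose kernel window is not fully
inside the track are dropped.

**Velocimetry.** The 70×70 grid of 7.5 px bins is anchored at the
padded-image origin; 70×7.5 = 525 px overruns a 512 px image, and the
trailing bins simply stay empty rather than rescaling the data. û_avg is
defined only in bins with ≥15 samples *and* mean speed above 0.5 μm/s — a
numerically null mean defines no direction. Samples falling in invalid bins
are excluded from downstream statistics and counted. Transect profiles
average speed |u| in equal arc-length bins within a band around the line;
the smooth curve is a shape-preserving (PCHIP) interpolant through the bin
means.

**Pulsatility.** V_rms peaks are detected on a 3-frame moving mean with
prominence 0.25× the interquartile range and sub-sample parabolic
refinement; frames without velocity samples are gaps, never zeros. Delay
pairing: each physiological peak is matched to the first subsequent V_rms
peak, and skipped if none occurs before the next physiological peak, so no
V_rms peak is counted in two cycles; the final physiological peak (no
successor to bound its cycle) is not paired. Phase averages use 20 bins per
cycle; delay histograms 25 ms bins. Peak times are never resampled across
clocks — traces keep their native rates and share only t = 0.

## Validation and problem sizes

Every stage is validated against generator ground truth, with scene sizes
chosen to keep the whole suite fast on one CPU: 224–256 px frames and
10–20 s movies (300–600 frames), particle counts matching the default
seeding density of the 512 px scene. On these scenes the pipeline recovers
the analytic cross-channel mean within ~5%, the transect peak within a few
percent of V₀, the analytic backflow fraction arccos(U/A)/π of a sinusoidal
flow within ~0.005, a generated 0.05 s cardiac lag within ~1 frame, and
≥95% of mobile frame-to-frame links while leaving zero stationary tracks at
stagnant-particle sites. The registration benchmark (50 known shifts in
[−5, 5] px) gives a maximum error near 0.05 px.

Link recovery is scored on ground-truth links whose particle lies at least
4 px inside the x-boundaries: a particle at the field edge is only
partially imaged (its blob is truncated), so it is not a fair detection
target.

## What passing these tests does and does not show

The generator emulates the statistical structure the analysis relies on —
sub-pixel blobs, parabolic pulsatile flow, stagnant particles, rigid
jitter, shot noise, synchronized physiology — but not everything about real
two-photon data: no depth sectioning or z-motion, no scattering or
vignetting, no vessel-wall motion or dilation, straight channels rather
than curved annular PVSs, and a purely Gaussian PSF. Passing therefore
demonstrates the correctness of the computations under the stated model,
not robustness to every in vivo artifact. Known limitations follow
directly: overlapping particles are not deblended (dense seeding degrades
link recovery), particles that are effectively stationary over the
±100-frame background window are suppressed like adhered ones (a floor on
measurable speed of roughly one pixel per window), and no rotation or
non-rigid motion is corrected.
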