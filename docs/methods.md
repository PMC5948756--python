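# Methods

This note documents the models, algorithms, and numerical choices behind
`csfcount`, and what the synthetic validation does and does not establish.

## Units and geometry

All internal lengths are μm, times seconds, volumes nL, concentrations
cells/μL, densities g/mL, viscosities cP; conversion happens only at I/O
boundaries. Image coordinates put pixel centers on integer grid points,
origin at the top-left pixel center, x rightward, y downward; μm
coordinates are pixel index × pixel size.

The default field of view is 610 × 460 μm. The default pixel size,
0.476 μm/px, is chosen so a 1280-px sensor row spans the FOV width; it is
configurable because the sensor is not part of the chamber design. The
analysis volume for concentrations is the instrument constant 588 nL for
four imaged areas. Recomputing it from geometry (610 × 460 μm × 532 μm ×
4) gives ≈597 nL; the two are deliberately kept independent — the printed
constant is what field instruments divide by — and a warning is logged
when a configuration supplies conflicting values. This implies a ~1.5%
systematic scale factor between simulated truth (which fills the
geometric volume) and reported concentrations; it is visible as a small
positive bias in dilution-series slopes and is left in place as a
faithful property of the workflow.

## Circle detection

Detection is a circle Hough transform (CHT) specialized to one size band,
followed by an explicit radial-symmetry score.

1. **Edge map.** 3×3 mean smoothing, central-difference gradients. The
   edge mask keeps pixels with gradient magnitude above
   max(0.30 × 99.5th percentile, 6 × median). The percentile term adapts
   the threshold to image contrast; the median floor (noise scale on
   typical frames, where edges are sparse) keeps pure-noise frames from
   flooding the mask. A constant image yields an empty mask. An explicit
   percentile of nonzero magnitudes can be supplied instead.
2. **Voting.** Each edge pixel votes at center candidates ± r along its
   gradient direction for every candidate radius r in
   [d_min/2, d_max/2] (step 0.5 μm, end point included). Voting both
   polarities makes dark rings (bright-field) and bright disks
   (fluorescence) share one code path. Votes are weighted by gradient
   magnitude scaled so strong edges carry weight ~1, and each radius
   slice is normalized by 2πr px — the vote mass of an ideal one-pixel
   circle — so a clean circle peaks near 1 regardless of size.
3. **Proposals.** Each slice is box-summed 3×3 (recollecting votes
   smeared by rounding and gradient-angle noise); local maxima of the
   (y, x, r) volume above a fixed, permissive proposal level (0.35)
   become candidates. The final accept/reject decision never rests on
   accumulator values, so accumulator calibration is uncritical.
4. **Refinement and scoring.** For each candidate, the gradient-magnitude
   profile is sampled along 32 spokes over radius ± 1.05 μm. Spoke peaks
   that are strong (above the edge threshold) and radially aligned
   (within 30°) enter a one-step geometric fit: the mean peak offset
   corrects the radius, the first circular harmonic of the offsets
   corrects the center (off(θ) ≈ Δr + Δx cosθ + Δy sinθ). The candidate
   is re-sampled at the refined geometry; its score is the fraction of
   spokes with a strong, aligned peak within 0.38 μm of the refined
   radius. That score is the "sensitivity" quantity: 1.0 for a complete
   circle of the right size, degraded in proportion to missing or
   misplaced arc. Detections require score ≥ 0.9 by default.
5. **Size gating.** Candidates whose refined radius leaves the
   [d_min/2, d_max/2] span (plus half a radius step of slack) are
   rejected. This is what removes debris and clumps: an undersized
   disk's true edge sits well below the band, so refinement pulls the
   radius out of band; clump lobes refine above it. Reported radii are
   clipped to the band.
6. **Suppression and borders.** Greedy non-maximum suppression in
   descending (score, accumulator) order with deterministic row-major
   tie-breaks; minimum center distance defaults to d_min (two true cells
   closer than one small-cell diameter are optically merged anyway).
   Frames are padded with their median intensity so border cells keep
   their visible arc; spokes whose nominal circle point leaves the true
   image are excluded from the score denominator (needing ≥8 in-image
   spokes), so cells touching the frame edge are scored on the evidence
   that exists. Detections with centers outside the frame are dropped.

The brute-force oracle used in tests scores every integer (cx, cy, r)
triple by mean gradient-aligned edge support along the circle and applies
the same threshold and suppression; on small frames with isolated
circles, the pipeline and the oracle agree to within 2 px and one radius
step.

## Enumeration

Counting follows the subtraction rule: total = bright-field detections,
WBC = fluorescence detections, RBC = max(total − WBC, 0). A fluorescence
excess is clamped at zero and logged — it signals a staining or detection
QC problem, and the report carries the clamp count. A `matched` mode
(greedy nearest-neighbor pairing of the two channels within a tolerance)
is available for over-detecting fluorescence channels. Concentrations
divide pooled per-area counts by the analysis volume; CVs are reported
across areas within a run and across replicates in the evaluation
harness, labeled distinctly. The counting-statistics floor CV = 1/√N
contextualizes low-count dispersion: at 5.2 cells/μL only ~3 cells occupy
the whole 588 nL, so replicate CVs of tens of percent are expected from
Poisson sampling alone, not from the detector.

## Sedimentation

Settling velocity uses Stokes' law on the sphere of equivalent volume,
computed in SI and reported in μm/s. With the documented RBC parameters
(V_c = 90 μm³ → r = 2.78 μm, Δρ = 0.05 g/mL, μ_m = 1.05 cP, g = 9.81
m/s²) the formula gives 0.802 μm/s. The protocol's citable velocity is
0.92 μm/s; the standard formula does not reproduce that number from the
same inputs (no drag correction or effective radius we consider
defensible closes the gap), so 0.92 μm/s ships as the default
`v_override` — wait-time predictions then match the protocol's 6.1, 9.6,
and 12.9 min for 337, 532, and 713 μm chambers — while the
first-principles value is always computed, logged alongside, and exposed
as `stokes_velocity()`. Cells initially uniform over [0, h_c] descending
at constant v give a linear arrival curve, settled fraction =
min(1, v·t/h_c); `plan_wait_time` recommends max(t_s, t_i), and with the
default protocol (532 μm, t_i = 10 min) staining dominates at 10 min.
No hindered-settling corrections are applied: CSF cell loads are dilute.

## Staining model and SNR

The simulator's staining response is the simplest smooth model with a
saturating signal and an interior SNR maximum: amplitude
s_max · c_d²/(k_half² + c_d²) · (1 − e^(−t_i/τ)) with k_half = 750 μM
and τ = 3.33 min, over a background bg_floor + bg_slope·c_d. With a
Hill exponent of 2 and a small floor, signal/background in c_d is
maximal essentially at k_half, so the sweep's optimum lands at 750 μM by
construction; τ puts the signal within 5% of plateau at 10 min, making
(750 μM, 10 min) the recommended condition. Amplitude defaults
(s_max = 77000, bg_slope = 4, bg_floor = 100, 16-bit units) are
calibrated so the measured SNR at the optimum concentration is ≈6 after
2 min and ~12 at plateau, i.e. comfortably above the 5.4 working level
from the earliest practical time point; absolute intensities are
arbitrary units — only ratios are meaningful. Measured SNR is the mean
intensity inside detection circles divided by the median intensity of
pixels farther than radius + 2 μm from every detection (median for
robustness to undetected dim cells; zero background floors at one unit
with a warning). Ratio-of-means rather than (signal − background)/sd
keeps gain invariance and matches the >5 working scale. Conditions too
dim to detect fall back to ground-truth positions, flagged in the sweep
table; the sweep reuses one seeded scene across conditions so the
staining response is isolated from loading noise.

## Synthetic scenes

`sample_scene` draws per-class counts from Poisson laws at concentration
× the per-frame control volume (610 × 460 × 532 μm ≈ 149 nL), heights
uniform over [0, h_c], apparent diameters uniform per class: cells
9–14 μm (spanning most of the acceptance band), debris 3–7 μm, clumps
18–30 μm with 2–3 overlapping lobes each at ≥90% of the clump diameter,
so clump rejection is a property of the scene (every lobe is over-band)
rather than of tuned detector internals. In-plane positions are uniform
subject to hard-disk exclusion — settled objects are solid and cannot
interpenetrate, and independent placement would create physically
impossible merged pairs that dominate counting error at 10³ cells/μL.
At the highest simulated load the exclusion occupies ~5% of the floor
area, leaving Poisson dispersion (variance/mean within [0.7, 1.3])
intact.

Bright-field rendering: background at 55% of full scale with
low-frequency mottle (0.8% sd, 12 μm correlation), a faint periodic
grid artifact (1.2% dips, 47 μm period) plus a gentle illumination ramp
(the printing-layer artifact of 3D-printed chambers), cells as Gaussian
membrane rings (depth 45% of background, radial σ 0.8 μm), debris and
clump lobes as soft-edged dark disks, 5% lognormal per-object contrast
jitter, additive Gaussian read noise (sd 250), 16-bit quantization.
Fluorescence rendering: flat dye-dependent background, WBC-only bright
disks, read noise sd 150. Defocus is Gaussian blur with σ = 0.02 × height
(μm blur per μm height) applied per object — a single focal plane at the
chamber floor, sufficient to make unsettled cells undetectable and
reproduce the settle-before-imaging requirement. Every render is
bit-reproducible from the scene seed.

What the simulator does not emulate: optical PSFs, filter and LED
spectra, RBC rouleaux or deformation, photobleaching, staining
heterogeneity beyond per-cell amplitude jitter, and real chamber
manufacturing variation. Passing the synthetic suite therefore
demonstrates that the algorithm chain is correct and self-consistent
under the modeled optics, not that the specific accuracy numbers
transfer to real micrographs.

## Evaluation harness

The dilution series runs each cell class as its own suspension (the
other class absent), five expected concentrations 5.2–1040 cells/μL
(~4.3-fold steps) × 3 replicate chambers × 4 areas, fully seeded, and
fits measured on expected by ordinary least squares with intercept
(slope and R² to 4 decimals). These problem sizes keep the full harness
to a few CPU-minutes while leaving ~600 cells at the top concentration —
enough for percent-level slope resolution. Accuracy-versus-truth runs 40
scenes at (100 RBC + 50 WBC)/μL, scoring 1 − |detected − true|/true per
scene on the bright-field total and detection F1 against truth positions
at 3 μm tolerance. Sub-seeds for every scene derive from the user seed
via SHA-256, so any two runs with the same seed are identical and
different stages never share streams.

## Known limitations

- The detector assumes quasi-circular cells; strongly elliptical or
  deformed cells would lose score. No clump splitting is attempted
  (clumps are rejected, as intended, not resolved into members).
- Overlapping settled cells at contact can still merge when their
  refined centers fall within the suppression distance; at
  10³ cells/μL this costs ~1–2% of counts, visible as slopes slightly
  below the volume-bias-corrected unity.
- Subtraction counting inherits any bright-field under-detection into
  the RBC estimate; matched mode trades that for sensitivity to
  channel registration.
- The 588 vs ≈597 nL volume convention (above) is a deliberate,
  documented bias of ~1.5%.
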