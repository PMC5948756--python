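# csfcount

Automated blood-cell counting for cerebrospinal fluid (CSF), built around a
portable dual-modality imaging workflow: cells settle to the floor of a tall
microfluidic counting chamber whose bottom carries a dried nucleic-acid
stain (acridine orange), a miniaturized microscope takes paired
bright-field and fluorescence images of the same areas, and software
enumerates white and red blood cells from the image pair. CSF is normally
nearly acellular (≤ ~5 WBC/μL), so the clinically interesting regime is
*low* counts — exactly where manual hemocytometry and flow cytometry
struggle.

`csfcount` implements the full analysis side of that workflow for
scientists and instrument developers:

- **Circle-Hough cell detection.** Cells are compact, round, and
  micron-scaled; debris and clumps are less radially symmetric and,
  respectively, smaller and larger. Detection runs a from-scratch circle
  Hough transform over the apparent-diameter band [*d*~min~, *d*~max~] =
  [8.6, 14.2] μm, scores each candidate by the fraction of its perimeter
  showing radially aligned edges, and accepts circles with score ≥ the
  sensitivity threshold (default 0.9; raising it accepts fewer, rounder
  objects).
- **Dual-modality enumeration.** AO fluorescence is strongly enhanced when
  bound to DNA, so only nucleated WBCs light up: *n*~wbc~ = fluorescence
  count, *n*~rbc~ = max(bright-field total − *n*~wbc~, 0). Counts from the
  chamber's four imaged areas are divided by the 588 nL analysis volume to
  give concentrations in cells/μL, with across-area and across-replicate
  CVs (Poisson floor 1/√N).
- **Sedimentation planning.** In-focus imaging requires settled cells.
  Stokes' law on the volume-equivalent sphere, *r* = (3*V*~c~/4π)^1/3^,
  *v* = 2(ρ~c~ − ρ~m~)*g* *r*²/(9μ~m~), gives ~0.80 μm/s for RBC parameters
  (*V*~c~ = 90 μm³, Δρ = 0.05 g/mL, μ~m~ = 1.05 cP); the package defaults to
  the protocol's citable 0.92 μm/s and predicts the wait time
  *t*~s~ = *h*~c~/*v* per chamber height, combined with the staining
  incubation into a recommended wait.
- **Staining quality control.** SNR = mean in-cell fluorescence / median
  background. Sweeping dye concentration and incubation time on simulated
  scenes locates the optimum (750 μM, 10 min): above the optimum the cell
  signal saturates while background keeps rising.
- **A ground-truthed synthetic microscope.** Because no image data ship
  with the instrument, a simulator renders the full optical scene — dark
  membrane-ring cells on a textured bright-field background with the faint
  grid/shadow artifact of 3D-printed chambers, WBC-only fluorescence with
  dye-dependent background, sub-band debris, over-band multi-lobed clumps,
  and height-dependent defocus for unsettled cells — with exact per-object
  ground truth, so every stage is testable end to end.

## Worked example

Simulate one imaged area at 100 RBC/μL + 50 WBC/μL, then count it:

```bash
csfcount simulate --c-rbc 100 --c-wbc 50 --seed 42 --out demo --stem demo
csfcount count --bf demo/demo_bf.tif --fl demo/demo_fl.tif --out demo/report.json
```

```
c_wbc = 6.80 cells/μL, c_rbc = 17.01 cells/μL -> demo/report.json
```

The seed-42 scene truly contains 10 RBCs and 4 WBCs (plus 5 debris
particles and 1 clump, all correctly rejected); the pipeline finds 14
bright-field and 4 fluorescence detections, so 4/0.588 μL = 6.80 WBC/μL
and 10/0.588 μL = 17.01 RBC/μL. A single 149 nL area cannot resolve such
low concentrations precisely — a real run images all four areas
(`--bf a1_bf.tif a2_bf.tif …`), and the report carries per-area counts,
CVs, and clamping warnings.

Plan the pre-imaging wait for the default 532 μm chamber:

```bash
csfcount plan-settling
```

```
settling velocity v      : 0.92 μm/s (Stokes first-principles: 0.80 μm/s)
chamber height h_c       : 532 μm
sedimentation time t_s   : 578.3 s = 9.6 min
staining incubation t_i  : 10.0 min
recommended wait         : 10.0 min
```

Sedimentation finishes before staining does, so staining sets the 10 min
wait; a 713 μm chamber flips that (t~s~ = 12.9 min).

Other entry points: `csfcount detect` (one image → detections CSV),
`csfcount qc` (staining sweep → SNR table + recommended optimum),
`csfcount evaluate dilution` / `csfcount evaluate accuracy` (validation
experiments), and the equivalent library functions in
`csfcount.hough`, `csfcount.counting`, `csfcount.sedimentation`,
`csfcount.staining`, `csfcount.simulate`, and `csfcount.evaluate`.

Configuration is a flat YAML file (`--config`); every field — optics,
chamber geometry, detection thresholds, sedimentation parameters,
simulator settings — is overridable and validated (see
`csfcount.config`).

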