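# Methods

This note documents the simulation model behind `servotrack`, the
parameters that matter, and the design decisions taken where the design was
genuinely open.

## Coordinate conventions

Image coordinates are 0-based, x = column rightward, y = row downward,
origin at the top-left pixel centre; the FOV centre of an N-px sensor is
`((N−1)/2, (N−1)/2)`. World coordinates are µm in the chip frame with the
same axis orientation. The stage carries the chip under a fixed camera, so
the chip-frame point imaged at the FOV centre is `−stage.pos`; the servo
command `v = −k_p e` (error `e` = (COG − centre) × pixel pitch) then drives
the stage so the target's image moves to the centre. Posture angles are
undirected body axes in (−π/2, π/2].

## Measurement chain

- **Binarization.** Per-frame global Otsu on the 256-bin intensity
  histogram, foreground = pixels at or below the threshold (dark target,
  brightfield). Computing on the integer histogram makes the threshold
  shift exactly with a global additive illumination change, which is the
  property the adaptive method exists for. A uniform frame yields an empty
  mask. A fixed-level method is available for tests and offline stacks.
- **Moments.** Raw moments to order 2 over the (optionally
  ROI-restricted) mask; COG = first moments over the zeroth; posture from
  order-2 *central* moments via `½·atan2(2µ11, µ20−µ02)`. Central moments
  are used deliberately: raw second moments mix position into shape, and
  only the central form gives a translation-invariant posture (verified by
  the equivariance property tests). An empty foreground is a first-class
  "no target" value, never a NaN.
- **ROI propagation.** The frame-k ellipse is centred on the frame-(k−1)
  COG and rotated to its posture; semi-axes are fixed per experiment
  (bead preset a=b=20 px, elongated-swimmer preset a=100, b=20 px).
  Boundary points count as inside. When the ROI is engaged, the adaptive
  threshold is estimated from the pixels *inside the ellipse only*; noise
  outside the ROI therefore has strictly zero influence on the
  measurement — the exactness the noise-immunity tests assert — and the
  processed pixel count shrinks with the ROI.
- **Threshold hold.** The per-ROI threshold is only re-estimated when the
  ROI's intensity sample spans both classes (range ≥ `min_contrast`,
  default 50 grey levels). When the ROI lies entirely inside a large dark
  target (high magnification, small ROI) the sample is uniform and the
  last valid threshold is held — the high-frame-rate assumption that
  consecutive frames differ little. The ROI then reads all-foreground, the
  COG rides the target's edge, and tracking continues with a bounded
  offset instead of dropping out. This matches the observed behaviour of
  the measurement at 560×–1400× where the 20 px ROI is smaller than the
  100 µm bead's image.

## Servo and stage model

Saturated discrete proportional control: `v = clip(−k_p e, ±1500 mm/s)`,
k_p = 250 /s by default, one frame of actuation latency, dt = 1/500 s
(k_p·dt = 0.5; the loop requires k_p·dt < 2). The reference instrument used
an adaptive control law whose form is not public; its experiments constrain
only closed-loop outcomes, so a proportional law with configurable gain is
used and all closed-loop claims are trend- or property-based. The stage is
an ideal velocity source (no motor dynamics); its 200 nm positioning
accuracy is modelled as Gaussian noise on the *reported* (encoder)
position. Steady-state tracking error for a constant-velocity target is
v/k_p (4 µm at 1 mm/s), which the simulator reproduces to three digits.

Search uses a 3:2 Lissajous path, amplitude 5 mm (covering a
10 mm × 10 mm scatter region), base frequency set so the RMS path speed is
20 mm/s. At 20 mm/s a 100 µm bead stays inside even the smallest (202 µm)
FOV for ≥5 consecutive frames, so detection (foreground count ≥ 50 px)
cannot skip over it.

## Magnification model

Pixel pitch vs. magnification ratio is a PCHIP (shape-preserving monotone
piecewise-cubic) interpolant through the ten factory calibration points
(140×…1400× → 5.50…0.79 µm/px): exact at every point, strictly decreasing
in between, no extrapolation. Zoom is a linear ramp in ratio (default 1 s
for the full range, matching the instrument's dial travel time), with the
pitch re-evaluated every frame so image-space error converts continuously
to stage-space error throughout the ramp. Focal-distance and
light-intensity control are hardware-specific and exposed only as stub
hooks; illumination variation is instead produced by the scene generator
to exercise the adaptive threshold.

## Scene generator

The generator renders what the sensor would see and logs ground truth per
frame. What it emulates, and how:

- **Target.** Ellipse (bead: equal axes) rendered dark (intensity 20) on a
  bright background (200) with 4×4 area-coverage supersampling, so
  sub-pixel motion is visible to the centroid; the noiseless round-trip
  error (measured COG vs projected truth) is ≤ 0.5 px over 500 random
  placements.
- **Trajectories.** `circular` (the bead-on-a-small-stage benchmark: ⌀2 mm
  circle at 1–15 mm/s); `run_and_turn` (cruise 1 mm/s, Poisson
  reorientations, occasional bursts capped at 2 mm/s, specular reflection
  at the 30 mm × 30 mm chip walls) as a stand-in for a ciliate swimmer —
  not biologically calibrated; `stage_driven` for prescribed paths.
- **Noise.** Per-frame re-sampled dark circles, positions uniform over the
  frame, radii uniform in [3, 12] px, rejection-sampled so they never
  touch the target (and, in the robustness study, stay clear of the ROI
  extent + 5 px, so the immunity premise holds by construction; both
  processing methods see identical noise statistics). The size range is a
  design choice: circles are debris-scale, mostly smaller than the 100 µm
  bead's image at 140× (radius 9 px). With much larger circles a single
  one already dominates the area-weighted COG (noise weight ≈ 0.75) and
  the full-FOV method fails within ~0.1 s at *every* density, erasing the
  graded degradation the study exists to measure; with [3, 12] px the four
  densities 1/5/10/15 span noise weights ≈ 0.43/0.79/0.88/0.92 and the
  failure time grades monotonically.
- **Chip edge** as a dark half-plane where the FOV crosses the workspace
  boundary, and a **microtool** as a dark bar of physical width 50 µm
  entering from one side, its tip prescribed per frame.
- Illumination drift: optional sinusoidal background modulation to
  exercise the adaptive threshold.

What it does **not** emulate: cilia/fluid mechanics, 3-D motion or focus
(the chip confines motion to a plane), occlusion between organisms,
motor/thermal stage dynamics, and camera shot noise. Passing tests
therefore validate the tracking *logic* under controlled disturbances, not
performance on real imagery.

Randomness is split into independent streams (trajectory, noise, stage
encoder) spawned from one seed, so runs that differ only in noise density
share an identical target path — this is what makes the bit-for-bit
noise-immunity comparison meaningful.

## Tracker state machine

SEARCH (full-FOV detection while sweeping the Lissajous path) → TRACK
(measure, command, propagate ROI) → LOST (after 25 consecutive empty
frames) → full-FOV re-acquisition at the current magnification. The ROI
engages only after 100 stable TRACK frames, so lock-on always happens on
the full FOV and, in the robustness study, noise is switched on only after
tracking is stable. Re-acquisition after LOST is an extension for
unattended runs, not a behaviour of the reference instrument.

## Evaluation studies — default problem sizes

- **Velocity sweep:** ratios {140, 560, 1400} (the calibration extremes
  plus a mid ratio) × speeds {1, 5, 10, 15} mm/s × both processing
  methods; 300-frame lock-on transient then 1000 steady-state frames per
  point; error = true target–FOV-centre distance.
- **Noise robustness:** 140×, bead circling at 10 mm/s, densities
  {1, 5, 10, 15}, 6 repeats each, 60 s cap, noise enabled after 1 s of
  stable tracking; failure = tracker LOST or target truly outside the
  FOV. The ROI method reaches the cap at every density; the full-FOV
  method's mean time decreases with density.
- **Search:** 20 beads scattered uniformly per repeat in 10 mm × 10 mm,
  identical layout searched at each ratio from the same path start;
  5 repeats, 30 s cap (censored at cap). Along the same path the 140× FOV
  spatially contains the 1400× FOV, so detection at low magnification is
  never later — the mean-ordering claim is structural, the margin is
  what the simulation measures.
- **Tool intrusion:** still elongated target at 840× with the a=100,
  b=20 px ROI; the 50 µm tool enters from the right and stops 120 µm from
  the target — inside the FOV (half-width 139.5 µm) but strictly outside
  the ROI ellipse (109 µm) — so the ROI-engaged trace must equal the
  no-tool run exactly while the full-FOV COG is dragged toward the tool.

All studies are reproducible from (spec, seed) and can retain per-frame
CSV logs. Absolute tracking durations are normalised to the 60 s cap and
only trends are asserted; the reference experiments' absolute times
depended on hardware and are not reproduced.

## Numerical choices and degenerate inputs

- Otsu on a two-valued histogram returns the dark mode (plateau resolved
  to the first maximum); foreground uses ≤, so the dark class is kept.
- `atan2(0, 0)` (isotropic shape) → posture 0 by convention.
- ROI constructed with a < b is normalised by swapping axes and rotating
  by π/2; ROIs outside the frame yield empty masks, counted against the
  loss patience rather than raised.
- FOV side lengths are reported rounded to the nearest µm
  (256 × 0.79 = 202.24 → 202).
- Rendering uses uint8 throughout with round-half-to-even blending at the
  target's anti-aliased rim.
- Rasterization kernels are numba-compiled with a pure-numpy fallback
  producing identical output.

## Known limitations

- The proportional-servo gain is a free parameter; the failure-onset
  velocity and the absolute noise-failure times depend on it, so only
  their monotone trends are meaningful.
- Edge-riding (threshold hold) at high magnification biases the measured
  COG toward the target boundary by up to the target radius; tracking is
  stable but the logged image-space COG is not a centroid of the whole
  body there.
- The run-and-turn swimmer is a caricature (no gait model); it exercises
  the elongated-ROI code path, not biology.
- Search times at high magnification depend on the bead density and path
  parameters; only the low-vs-high magnification ordering is asserted.
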