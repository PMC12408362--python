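# Methods

`mrlqa` verifies step-and-shoot deliveries on an Elekta-Unity-class MR-linac
directly from the machine's delivery log, without any dose calculation. The
core argument: in a magnetic field, recomputing dose independently is either
inaccurate (no field modelling) or too slow for per-fraction QA (Monte
Carlo). The delivered *photon fluence*, however, is fully determined by the
logged MU, leaf and jaw trajectories, and can be compared to the plan's
fluence exactly and cheaply. Delivery errors — leaf miscalibration, MU
counting faults, wrong segment ordering — all surface in the fluence domain.

## Machine model

The treatment head is modelled at the isocenter plane only (all logged and
planned positions are already projected there): SAD 143.5 cm, maximum field
574 mm (IEC X) x 220 mm (IEC Y), 160 leaves in two opposing banks of 80
travelling in Y, and one X jaw pair. Leaf width at isocenter is fixed by
field width / pair count = 7.175 mm; the uniform-width layout is this
package's model (the machine's published field geometry constrains only the
product) and every geometric parameter is overridable via the config for
other machines. Leaf X bands and all aperture intervals are half-open
`[low, high)`, so every point maps to exactly one leaf pair and edge pixels
are assigned deterministically.

## Log semantics and segment extraction

Logs are 40 ms machine-state samples in a documented CSV dialect
(`time_ms, linac_state, step_dose_mu, gantry_deg, x1_mm, x2_mm,
y1_000..y1_079, y2_000..y2_079`). The linac is in one of three states —
`Intersegment`, `Move Only`, `Radiation On` — and radiates only in the last.
The step dose accumulates MU within a segment and resets to zero at beam-off.

Each maximal contiguous beam-on run is one delivered segment:

* segment MU = maximum step dose in the run (robust to the final sample
  landing just before the reset);
* leaf and jaw positions are the means over the run's samples only, which
  suppresses the optical tracking jitter by 1/sqrt(n) (a 17 MU segment spans
  ~111 samples, so a 0.08 mm per-sample sigma becomes ~0.008 mm on the mean);
  per-leaf standard deviations are retained as diagnostics.

Deliveries split over several files (sub-plans, or a therapist pausing the
beam) are merged into one timeline with per-file time offsets. A beam-on
stretch that continues across a file boundary is split into two runs —
the step dose restarts with the new file — and the runs are re-merged into
one segment (MU = sum of the per-run maxima) iff a file boundary separates
them, no `Intersegment` state intervenes, and the gantry angle agrees within
tolerance (default 0.5 deg, circular arithmetic). Merges are flagged in the
report. Beam-on runs that accumulate zero MU are dropped with a warning.

## Plan model

RT Plans are read with pydicom. Only static-gantry step-and-shoot beams are
accepted; segment k's MU is `meterset * (w[k+1] - w[k]) / w_final` from the
cumulative meterset weights, with positions from the segment's opening
control point (omitted positions carry forward per the DICOM standard).
Sub-plan files concatenate in the given order, mirroring log merging. The
bundled writer emits cumulative weights in integer milli-MU so a write/read
round trip reproduces MUs to float round-off (positions are encoded to
0.001 mm). DICOM leaf bank 1 maps to Y1; a config switch swaps banks for
vendors with the opposite convention.

## Fluence reconstruction

A segment aperture is a strictly binary mask: a pixel (judged at its center)
is open iff it lies inside the jaw window and inside the open Y interval of
the leaf pair whose X band contains it. No penumbra, leaf-end curvature,
transmission or output factor is modelled — the comparison is plan-vs-log of
the *same* forward model, so any such refinement would cancel. The fluence
map of a gantry angle is `F = sum_j MU_j * mask_j` at 0.1 mm resolution
(configurable). Grids are auto-cropped to the union bounding box of the
contributing apertures plus a 10 mm margin, with the origin snapped to the
pixel lattice; plan and log maps of a beam share one grid, so no resampling
is ever needed. Full-field grids are available via config; above the 10%
analysis threshold the cropped and full-field results are identical.

## Agreement metrics

**Gamma.** For every plan-map point above 10% of the plan map's maximum,

    gamma = min over log-map points of sqrt(r^2 / dta^2 + delta^2 / dd^2)

with dta = 1 mm, dd = 1% of the plan map's *global* maximum (per gantry
angle), gamma <= 1 a pass, and the passing rate the percentage of evaluated
points passing. The per-gantry PASS bar is strictly above 98%.

Numerics: the production search visits pixel offsets in order of increasing
distance and stops when the distance term alone exceeds every point's
current best gamma — an exact early exit, not an approximation. The search
radius is capped at 3 x dta (beyond it the distance term alone exceeds the
reported cap gamma = 3, so pass/fail is unaffected); reported gammas are
clamped at 3. Distances are computed as integer pixel offsets times the
resolution, and an independent brute-force implementation (literal
minimisation over all evaluated points, no window or ordering) uses the same
lattice arithmetic so the two agree to round-off even at exact pass/fail
ties. Points of the common frame outside the evaluated grid's extent carry
zero fluence, which is exact for cropped-union grids.

**Pearson correlation.** A global similarity score sensitive to systematic
shifts that gamma's DTA term forgives. Computed by default over the union of
pixels above the 10% threshold of either map's own maximum (configurable to
the full grid; which pixels enter the correlation is a package choice — the
underlying method leaves it open). PASS at r >= 0.985 inclusive. A constant
selection yields an undefined r, reported as missing with a warning.

**Deviations.** Per matched segment, MU and jaw deviations are plan - log
(positive = plan larger). Per leaf, the maximum absolute and RMS deviation
over segments, `rms_i = sqrt(mean_j (Y_log - Y_plan)^2)`. Leaf pairs closed
(gap < 0.1 mm) in *both* plan and log contribute nothing for that segment:
their tracked positions are dosimetrically irrelevant; the exclusion is
switchable. Plan and log segments pair by nearest gantry angle (within
tolerance) and within-beam delivery order; any count mismatch is itself a QA
failure and aborts with the offending beam named.

## Synthetic study conditions

The generator manufactures matched plan + log pairs emulating SBRT-like
step-and-shoot cases: 11–17 static gantry angles (default 15, evenly
spaced), ~10 segments per beam (the headline configuration is 109 segments
over 15 beams), per-segment MU uniform in 8–22 MU, and connected
MLC-realizable apertures — a per-beam aperture center within +-15 mm of the
isocenter, per-segment center wobble +-8 mm, side lengths 25–70 mm, and
per-leaf edge in-steps up to 5 mm so the edges are stepped as a real MLC
field is. Parked pairs close at the aperture center.

The delivery model: constant dose rate of 0.155 MU per 40 ms sample (a
~17 MU segment then spans ~111 samples); per-sample Gaussian tracking jitter
sigma 0.08 mm on every leaf and jaw (the scale the optical tracking shows on
a held leaf); per-segment systematic offsets uniform +-0.3 mm on leaves the
plan opens and on the jaws (parked pairs are actively held closed, so they
receive jitter only); per-segment MU error uniform +-0.3 MU; optionally a
constant whole-bank shift (fault injection) and random interruptions that
split the log file mid-run. All draws come from a single seeded generator;
a fixed seed reproduces byte-identical files.

What the generator does *not* emulate: dose-rate modulation and servo
transients at beam-on, gantry-angle readout noise, leaf-position
quantisation, correlated (calibration-drift) leaf errors, and any anatomy.
Passing tests therefore demonstrate the pipeline's correctness and its
sensitivity to the injected error classes, not the error spectrum of a
particular clinical machine.

## Design choices where the design was open

* Segment MU from the step-dose maximum rather than the last sample
  (robustness to reset timing).
* Averaging uses beam-on samples only: by definition the segment is the
  beam-on run.
* The interruption merge rule (file boundary + no intersegment + same
  gantry) is an inference from how resumed deliveries are logged; merges are
  always flagged.
* Dose-difference normalisation is global per gantry-angle map; a local
  (per-point) option exists but is off, matching the global-threshold
  convention.
* Verdict boundaries: gamma strictly `> 98.0`; Pearson inclusive `>= 0.985`.
  The overall verdict requires both, per gantry angle, plus error-free
  pairing (the Pearson contribution is switchable).
* Shift probes use exact pixel translations with zero fill — no
  interpolation — so oracle comparisons stay exact; shifts must be integer
  pixel multiples.

## Degenerate inputs and tolerances

Empty log files, unknown state strings, non-monotonic timestamps, unparseable
numbers, dynamic-gantry plans, wrong leaf counts and inconsistent meterset
weights are all rejected with typed errors naming the offender; the pipeline
converts any stage error into an overall FAIL with the stage name. A fully
closed segment rasterizes to an all-zero mask; an all-zero reference map has
no gamma normalisation and is refused. Grid alignment requires equal
resolutions and whole-pixel origin offsets (guaranteed by construction within
the pipeline). Zero-noise round trips are exact to float round-off
(residuals ~1e-14, asserted at 1e-9); RTPLAN round trips are exact to
0.001 mm / 0.001 MU by encoding precision.

## Problem sizes used in the test suite

The acceptance-level checks run the headline configuration (15 beams, 109
segments) at the analysis resolution of 0.1 mm for the identity and
realistic-noise cases, 0.2 mm for the paired fault-injection comparison, and
50 random fixtures up to 200 x 200 pixels for the gamma oracle-equivalence
check — sizes chosen so the whole suite completes in minutes on one CPU
while exercising the full clinical problem shape.

## Known limitations

* Binary fluence is blind to errors that do not change the aperture or MU
  (e.g. energy or dose-rate deviations) and to anything a log cannot see
  (the log is the machine's own account of itself).
* A 1.0 mm systematic shift sits exactly on the 1 mm DTA criterion: gamma
  alone is a boundary case there (points pass at gamma = 1.0 up to pixel
  quantisation), which is precisely why the Pearson threshold exists as the
  second, shift-sensitive check.
* Per-leaf statistics for leaves that are parked throughout a delivery are
  reported as missing, not zero.
* The CSV dialect is this package's own; adapting a vendor export requires a
  (thin) column-mapping layer.
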