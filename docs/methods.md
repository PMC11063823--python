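# Methods

This note documents the models, numerical choices and known
limitations behind each analysis stage, and what the synthetic-data
generator does and does not emulate.

## Stimulus and imaging model

A moving-bar run is a list of sweeps, each a half-open, 0-based frame
interval `[onset, offset)` tagged with a direction and a trial (block)
index.  Directions are equally spaced on 360°; within every trial
block each direction occurs exactly once, in ascending order or
block-shuffled.  Defaults follow the standard protocol for this
preparation: 8 directions × 3 trials at 2.96 Hz frame rate, 9 stimulus
frames (≈3 s bar traverse at 250 µm/s) and 6 gap frames (≈2 s between
sweeps).

ΔF/F₀ uses a pooled baseline: F₀ is the per-pixel mean over every
stimulus-free frame of the recording, maximizing the baseline sample
size rather than re-estimating it per trial.  Pixels with
F₀ ≤ ε (default ε = 10⁻⁶ × movie maximum) are masked invalid, carry
ΔF/F₀ = 0, and can never enter an ROI.  An optional *baseline guard*
excludes a configurable number of post-sweep frames from F₀: at ~3 Hz
a calcium indicator with a ~0.6 s decay constant leaves a measurable
tail in the first few inter-sweep frames, which would otherwise bias
F₀ upward and push apparent null-direction responses negative.  The
end-to-end pipeline defaults to a 4-frame guard (≈2 decay constants);
the low-level `compute_dff` defaults to no guard.

Per-pixel tuning: each pixel trace is averaged over its spatial
neighborhood (default 3×3; edge pixels use the in-bounds subset), the
peak ΔF/F₀ of the *unsmoothed-in-time* trace is taken inside each
sweep window and averaged over trials per direction, and the
normalized vector sum and DSI are computed from those per-direction
mean peaks.  Where the summed response is ≤ 0 the magnitude is 0 and
the angle is reported as NaN.  The magnitude map is median-filtered
(default 3×3, zero padding beyond the field) to enrich contiguous
cell-like regions of coherent preferred direction; candidate ROIs are
4-connected components of supra-threshold valid pixels (default
magnitude ≥ 0.3, area 20–500 px), ordered deterministically by
bounding-box corner.  This replaces a manual oval-ROI drawing step
with a reproducible segmentation; the thresholds are configurable and
no claim is made that they match any particular manual workflow.

## DSI, preferred/null bins, and ties

The preferred direction is the two-argument arctangent of the vector
sum, mapped to [0, 360).  The pref *bin* is the direction circularly
nearest that angle; an exact tie between bins resolves to the smaller
angle.  For even, equally spaced grids the null bin is the exact 180°
partner; otherwise the bin nearest pref + 180° is used and flagged.
DSI = (R_pref − R_null)/(R_pref + R_null); a non-positive denominator
yields DSI = 0 with a degenerate flag rather than an arbitrary ratio.

## Permutation test

Significance of direction selectivity is assessed by recomputing the
DSI under 1,000 permutations in which the direction labels are
shuffled independently *within each trial block* — peaks stay attached
to their trial, so the per-trial response multiset and any slow drift
across trials are preserved under the null.  The observed DSI's
percentile among the permuted DSIs uses mid-ranking (ties count half),
so a fully degenerate all-equal table sits exactly at the 50th
percentile; significance requires percentile > 95 (configurable).
Each ROI draws its permutations from a generator seeded by
(global seed, CRC-32 of the ROI id), so results are independent of
evaluation order and parallelization.

Two calibration facts follow and are enforced by tests: on
direction-untuned tables with i.i.d. trial noise the percentiles are
uniform (Kolmogorov–Smirnov), and the declared-significant fraction is
≈5%.  One corner case is worth noting: for *noiseless* tables whose
null-direction response is exactly zero, many permuted tables also
reach DSI = 1 (one peak per trial block, empty opposite bin), so the
observed DSI ties with a large mass of permuted DSIs and mid-ranking
keeps the cell below the 95th percentile.  This is a property of the
statistic, not a bug; any physiological noise floor breaks the ties.

## ON vs ON–OFF classification

The onset response is the trial-averaged window maximum at the start
of the preferred-bin sweeps (bar entry), the offset response the same
at the end of the sweep (bar exit); windows default to half the sweep
each and must not overlap.  A phase is responsive when it exceeds
k·SD of the stimulus-free trace (default k = 3).  Because the
indicator decay is slow relative to the frame rate, the onset
transient bleeds into the offset window; the offset therefore must
additionally exceed a configurable fraction (default 0.25) of the
onset response.  This formalizes what is usually a by-eye judgment;
the trial-consistency criterion is likewise formalized as "all trials
above a floor (default 3× baseline SD) in the preferred bin".

## Direction clustering

Preferred angles are embedded as unit vectors and clustered by
k-means (k-means++ seeding, 10 restarts, fixed seed) under the
standard sum-of-squared-Euclidean objective; chord distance is
monotone in angular separation up to 180°, so cluster structure on
the circle is preserved.  Silhouette values use the max-denominator
definition; a singleton cluster has a(i) = 0 and hence SV = 1 when
b(i) > 0, and coincident clusters (a = b = 0) score 0.  The model
either fixes k or selects the k in 2–8 with maximal mean SV (ties to
smaller k).  Anatomical labels are anchored to reference cells:
ventral = cluster nearest the circular mean of the reference angles,
dorsal = nearest ventral + 180°, nasal from its own references (or the
free cluster nearest ±90° off the ventral axis), temporal =
nasal + 180°; labels are injective and fewer than four clusters yield
a partial labeling with a warning.

## Conductance extraction

The measurement model is an instantaneous two-resistor circuit:
series resistance Rs between amplifier and soma, input resistance Rin
and a synaptic conductance g(t) with reversal E_rev from soma to bath,
solved per sample (no membrane capacitance outside the test pulse).
Units are fixed at pA/mV/MΩ/nS.  Processing: average repeats per
holding potential, subtract the pre-stimulus holding current, measure
Rs (= |ΔV|/peak transient) and Rin (= |ΔV|/steady-state − Rs) from the
−5 mV test pulse, apply the compensation equations, and fit ordinary
least squares of Isyn on V across holding potentials at every sample.

One subtlety is load-bearing.  The compensation pair

    Isyn(t) = (Rin + Rs)/Rin · Im(t),   V(t) = Vh − Im(t)·Rs

is *exact* for this circuit — algebraically, Im′(1 + Rs/Rin) =
g·(V − E_rev) holds identically — provided Im in the V(t) equation is
the **total** recorded current, holding current included, because the
holding current also drops voltage across Rs.  The averaged sweep set
therefore carries the subtracted per-Vh baseline, and compensation
re-adds it when computing V(t).  Applying both equations to the
baseline-subtracted current instead leaves a bias of order Rs·g ≈ 2%
under typical parameters.

Vrev = −intercept/slope is reported only where |gT| ≥ 0.05 nS
(slope floor; below it the ratio is numerically meaningless).  The
conductance peak is searched in [stimulus onset, onset + duration +
200 ms] to include the tail current.  R² is stored per timepoint; the
quality gate (default 0.85) is evaluated at the conductance peak.
With exactly two holding potentials the line is fully determined, R²
is reported as 1 and the trace is flagged `determined_fit` instead of
QC-passing.

## Evoked-current indices

Peaks are stored as magnitudes of baseline-subtracted extrema with the
sign convention in metadata; polarity follows the holding potential
(−60 mV → EPSC, +12 mV → IPSC).  The preferred/null axis for DSGC
classification comes from the IPSC vector sum (inhibition carries the
directional signal in this circuit); the DSGC criterion is IPSC
DSI ≥ 0.2, inclusive.  CS = 1 − R_largest/max over spots up to and
including the largest (default 440 µm); a fully nonresponsive cell
scores 0 with a flag.  SI uses the 1,000 vs 250 µm/s peaks.  The E–I
timing offset is IPSC peak time − EPSC peak time in matched windows.

## Morphometry

Skeletons are standard 7-column SWC; the single root is the soma.
Normalized IPL depth maps z linearly onto [0, 1] (0 = INL border).
ON/OFF bands default to [0.55, 0.80] and [0.20, 0.45]; edges are
assigned by midpoint depth, out-of-band edges to the nearer band, and
the ON–OFF index is the signed length fraction.  Sholl intersections
are counted geometrically on the x–y projection — an edge crosses
radius r when its endpoint distances satisfy d_near < r ≤ d_far —
rather than on rasterized images; this is exact and
resolution-independent, so counts can differ slightly from mask-based
pipelines near ring boundaries.  The dendritic center of mass is the
projected-edge-length-weighted mean of projected edge midpoints
(invariant to node resampling).  The asymmetry index intersects the
soma→COM line with the convex-hull boundary in both directions;
AI = |P1S − SP2|/(P1S + SP2), with AI = 0 by convention when the COM
coincides with the soma and an invalid-geometry error when the soma
lies outside the hull.  Tips are non-soma nodes without children;
branch points are non-soma nodes with ≥2 children.

## Synthetic data: what it emulates, and what it does not

The generators encode the statistical structure the analyses assume,
not the biophysics of the preparation:

* **Movies** — disk-shaped cells with von Mises tuning
  (amplitude·exp(κ(cos Δ − 1)), so κ = 0 is flat and κ maps
  monotonically to DSI), a single-exponential indicator kernel
  (default decay 0.6 s) driven by impulses at bar entry (ON) or entry
  and exit (ON–OFF), additive i.i.d. Gaussian noise in ΔF/F₀ units,
  and a constant baseline (default 100 a.u.).  No photon statistics,
  point-spread function, neuropil, motion artifacts beyond optional
  rigid jitter, or z-drift.  Overlapping cells are permitted and
  flagged in the manifest.
* **Sweep families** — the same two-resistor circuit the analysis
  assumes, solved self-consistently per sample, with an alpha-function
  conductance (default peak 2 nS, 10 ms rise), a −5 mV test pulse
  whose capacitive transient charges through Rs plus a 0.1 MΩ residual
  (an instrumentation floor that keeps the Rs = 0 limit finite), and
  additive Gaussian current noise.  No dendritic filtering, space
  clamp errors, or capacitance transients outside the pulse — so
  recovery tests probe the estimator, not cable artifacts.
* **Response tables** — direction peaks on the von Mises profile; spot
  responses rising linearly to a maximum at an intermediate diameter
  and falling so the true CS index equals the requested suppression
  exactly; fast/slow speed peaks amplitude·(1 ± p) so the true SI
  equals p exactly.
* **Skeletons** — radial bifurcating trunks around an arbor center
  displaced from the soma by a known offset; ON/OFF strata at depths
  0.675/0.325, alternating trunks when bistratified.  The manifest's
  reference asymmetry index is computed by an independent
  shapely-based routine, not by the morphology module under test.

Every generator draws from a single explicitly seeded
`numpy.random.Generator`; identical parameters and seed give
bit-identical outputs, and every generated entity appears in exactly
one manifest record.  The response-amplitude and noise defaults are
free choices of plausible magnitudes, not calibrated to any particular
recording system — so passing recovery tests demonstrates estimator
correctness under the stated model, not performance on real tissue.

## Benchmark problem sizes

The validation suite uses desk-scale problems chosen once: permutation
calibration on 500 untuned ROIs × 1,000 shuffles; oracle equivalence
on a 16×16 field, 100 seeded random trees, and 40 clustered points;
end-to-end recovery on a 128×128 movie with 20 tuned (κ = 4) and 20
untuned cells at noise SD 0.05 ΔF/F₀.  The full suite runs in well
under a minute on one CPU.

## Known limitations

* The baseline guard trades baseline sample size against indicator
  tail bias; at very short inter-sweep gaps both cannot be satisfied.
* Mid-rank percentiles make the permutation test conservative for
  noiseless, perfectly tuned responses (see above).
* k selection by maximal mean silhouette can prefer fewer clusters
  than the anatomical four when subtypes overlap heavily; k can be
  forced.
* The conductance model omits membrane capacitance between samples;
  at 20 kHz sampling this is negligible for the millisecond-scale
  conductances simulated, but fast transients in real recordings
  violate it.
* IV fits use all holding potentials, including those near Vrev where
  the synaptic current is small; no potential-exclusion heuristic is
  applied.
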