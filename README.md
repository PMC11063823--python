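# dscircuit

Quantitative analysis of the retinal direction-selective circuit —
the network in which starburst amacrine cells (SACs) wire asymmetric
inhibition onto direction-selective ganglion cells (DSGCs).  The
package turns the raw data modalities of such experiments into the
standard quantitative readouts, and ships a synthetic-data generator
with exact ground truth so every stage is testable end to end without
any recordings.

## What it computes

**Calcium imaging → DS cell detection.**  A two-photon movie plus its
moving-bar schedule is normalized to ΔF/F₀ (baseline F₀ = per-pixel
mean over stimulus-free frames).  Every pixel gets a normalized vector
sum of its per-direction mean peak responses,

    vecsum = Σₙ peakₙ·(cos θₙ, sin θₙ) / Σₙ peakₙ ,
    DSI    = (peak_pref − peak_null) / (peak_pref + peak_null),

where *pref* is the direction bin nearest the vector-sum angle and
*null* is 180° away.  A 2-D median filter enriches cell-like regions of
coherent tuning, connected components become candidate ROIs, and each
ROI is screened by three criteria: trial-consistent responses,
statistical direction selectivity (1,000 within-block shuffles of the
direction labels; the observed DSI must rank above the 95th percentile
of the permuted DSIs), and membership in the expected directional
cluster.  ROIs are further classed ON vs ON–OFF from their onset/offset
transients.

**Preferred-direction clustering.**  Preferred angles are fixed to unit
length, k-means (k = 2–8) runs on the Cartesian coordinates, fitness is
the silhouette value SV(i) = (b(i) − a(i))/max(a(i), b(i)), and
clusters are labeled ventral/dorsal/nasal/temporal anchored to
genetically identified reference cells.

**Paired-recording conductance.**  From voltage-clamp sweep families at
several holding potentials, sweeps are averaged, the holding current
subtracted, series resistance compensated

    Isyn(t) = (Rin + Rs)/Rin · Im(t),     V(t) = Vh − Im(t)·Rs,

with Rs and Rin measured from a −5 mV test pulse, and a line is fitted
to (V, Isyn) across holding potentials at every timepoint: the slope is
the synaptic conductance gT(t), −intercept/slope the reversal potential
Vrev(t), gated by R² ≥ 0.85 at the conductance peak.

**Evoked-current tuning indices.**  From peak onset/offset E/IPSCs per
condition: the Rx/Ry/Rt vector sum and preferred direction,
DSI = (R_PD − R_ND)/(R_PD + R_ND), speed index
SI = (R_fast − R_slow)/(R_fast + R_slow), center–surround index
CS = 1 − R_largespot/R_allspots, DSGC classification (IPSC DSI ≥ 0.2),
and E–I peak-timing offsets.

**Morphometry.**  From SWC skeletons: ON/OFF stratification split and
index, Sholl profiles at 5 µm ring spacing, convex-hull areas,
dendrite–soma center-of-mass distance and angle from the ventral axis,
and the asymmetry index AI = |P1S − SP2|/(P1S + SP2) along the
soma→center-of-mass hull chord.

## Worked example

Simulate a small field with one tuned (von Mises κ = 4, preferred
270°) and one untuned ON–OFF cell, then run the full detection chain:

```python
import numpy as np
from dscircuit import synthetic as syn, pipeline
from dscircuit.conductance import extract_conductance

sched = syn.generate_stimulus_schedule(n_directions=8, n_trials=3, seed=0)
cells = [
    syn.CellSpec(center_xy=(20, 22), radius_px=4, amplitude=1.0,
                 kappa=4.0, preferred_direction_deg=270.0,
                 response_class="ON-OFF"),
    syn.CellSpec(center_xy=(44, 40), radius_px=4, amplitude=1.0,
                 kappa=0.0, preferred_direction_deg=0.0,
                 response_class="ON-OFF"),
]
movie, manifest = syn.generate_calcium_movie(sched, (64, 64), cells,
                                             noise_sd=0.05, seed=0)
table, rois, dff = pipeline.analyze_movie(movie, sched, seed=1)
print(table[["roi_id", "dsi", "preferred_angle_deg",
             "perm_rank_percentile", "is_significant_ds",
             "response_class"]].round(2).to_string(index=False))
```

```
 roi_id  dsi  preferred_angle_deg  perm_rank_percentile  is_significant_ds response_class
roi0000 0.98               270.18                  96.7               True         ON-OFF
```

Only the tuned cell is detected: its DSI (0.98) ranks above the 95th
percentile of the permuted DSIs, its preferred angle recovers the true
270° to within a fraction of a degree, and it is classed ON–OFF.  The
untuned cell never crosses the tuning-magnitude threshold.

Conductance extraction on a simulated SAC→DSGC pair (true g_peak
2 nS, E_rev −60 mV, Rs 10 MΩ, Rin 500 MΩ, 2 pA noise):

```python
sweeps, truth = syn.generate_vclamp_sweeps(g_peak_nS=2.0, e_rev_mV=-60.0,
                                           rs_MOhm=10.0, rin_MOhm=500.0,
                                           noise_sd_pA=2.0, seed=0)
trace = extract_conductance(sweeps)
print(f"peak gT = {trace.peak_gT_nS:.2f} nS, "
      f"Vrev = {trace.vrev_at_peak_mV:.1f} mV, "
      f"R^2 = {trace.r2_at_peak:.3f}, QC pass: {trace.qc_pass}")
```

```
peak gT = 2.02 nS, Vrev = -59.4 mV, R^2 = 1.000, QC pass: True
```

The IV fit recovers the conductance within 1% and the reversal within
1 mV, and the recording passes the R² ≥ 0.85 quality gate.

A `dscircuit` command-line tool wraps the same stages
(`simulate`, `dsmap`, `classify`, `cluster`, `conductance`, `tuning`,
`morpho`); run `dscircuit --help`.

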