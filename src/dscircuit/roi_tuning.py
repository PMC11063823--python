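"""Per-ROI tuning, response classification, and the block-shuffle
permutation test for direction selectivity.

An ROI passes the direction-selective-cell screen when it (1) responds
consistently across trials in its preferred direction, (2) is
significantly direction selective under a permutation test in which the
stimulus direction labels are shuffled within every trial block and the
DSI recomputed (the observed DSI must rank above the 95th percentile of
1,000 permuted DSIs), and (3) falls into the expected directional
cluster (see :mod:`dscircuit.clustering`).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from . import vectorsum
from .imaging import DFFMovie, ROI
from .schedule import StimulusSchedule

__all__ = [
    "TrialPeakTable",
    "ROITuning",
    "PermutationResult",
    "roi_trial_peaks",
    "roi_tuning",
    "consistency_check",
    "classify_on_off",
    "permutation_test",
    "permutation_test_batch",
]


@dataclass
class TrialPeakTable:
    """Peak ΔF/F₀ per (direction, trial) for one ROI."""

    peaks: np.ndarray          # (n_directions, n_trials)
    directions_deg: np.ndarray
    roi_id: str = "roi"

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float)
        self.directions_deg = np.asarray(self.directions_deg, dtype=float)
        if self.peaks.ndim != 2:
            raise ValueError("peaks must be (n_directions, n_trials)")
        if self.peaks.shape[0] != self.directions_deg.shape[0]:
            raise ValueError("directions/peaks length mismatch")
        if not np.all(np.isfinite(self.peaks)):
            raise ValueError("peaks must be finite")
        if np.any(np.diff(self.directions_deg) <= 0):
            raise ValueError("directions must be sorted ascending")

    @property
    def trial_mean(self) -> np.ndarray:
        return self.peaks.mean(axis=1)


@dataclass
class ROITuning:
    roi_id: str
    per_direction_mean_peak: np.ndarray
    directions_deg: np.ndarray
    vector_sum_magnitude: float
    preferred_angle_deg: float
    pref_bin: int
    null_bin: int
    dsi: float
    degenerate: bool = False
    response_class: str | None = None       # "ON" | "ON-OFF" | "nonresponsive"
    consistent: bool | None = None
    perm_rank_percentile: float | None = None
    is_significant_ds: bool | None = None


@dataclass
class PermutationResult:
    perm_rank_percentile: float
    is_significant_ds: bool
    degenerate: bool = False
    n_permutations: int = 0


def roi_trial_peaks(dff: DFFMovie, roi: ROI,
                    schedule: StimulusSchedule | None = None) -> TrialPeakTable:
    """Windowed maxima of the ROI-mean ΔF/F₀ trace per (direction, trial)."""
    sched = schedule if schedule is not None else dff.schedule
    mask = roi.pixel_mask & dff.valid_mask
    if not mask.any():
        raise ValueError(f"ROI {roi.roi_id} lies entirely on invalid pixels")
    trace = dff.values[:, mask].mean(axis=1)
    directions = np.asarray(sched.directions_deg)
    peaks = np.empty((len(directions), sched.n_trials))
    for d, direction in enumerate(directions):
        for t, sweep in enumerate(sched.sweeps_for(direction)):
            peaks[d, t] = trace[sweep.onset_frame:sweep.offset_frame].max()
    return TrialPeakTable(peaks=peaks, directions_deg=directions,
                          roi_id=roi.roi_id)


def roi_tuning(table: TrialPeakTable) -> ROITuning:
    """Vector-sum tuning of a trial-peak table.

    The vector sum of direction unit vectors weighted by trial-mean
    peaks (normalized by their sum) gives magnitude and preferred angle;
    the pref bin is the direction nearest that angle (ties to the
    smaller angle), null is 180° away, and
    DSI = (peak_pref − peak_null)/(peak_pref + peak_null).
    """
    if table.directions_deg.size < 2:
        raise ValueError("need at least 2 directions")
    m = table.trial_mean
    mag, angle = vectorsum.vector_sum(m, table.directions_deg)
    d, pref_bin, null_bin = vectorsum.dsi(m, table.directions_deg,
                                          preferred_angle_deg=angle)
    degenerate = not np.isfinite(angle) or (m[pref_bin] + m[null_bin]) <= 0
    return ROITuning(
        roi_id=table.roi_id,
        per_direction_mean_peak=m,
        directions_deg=table.directions_deg,
        vector_sum_magnitude=float(mag),
        preferred_angle_deg=float(angle),
        pref_bin=int(pref_bin),
        null_bin=int(null_bin),
        dsi=float(d),
        degenerate=bool(degenerate),
    )


def consistency_check(table: TrialPeakTable, min_peak: float,
                      min_trials: int | None = None) -> bool:
    """Trial-consistency criterion: at least ``min_trials`` trials
    (default: all) exceed ``min_peak`` in the ROI's preferred bin."""
    n_trials = table.peaks.shape[1]
    if min_trials is None:
        min_trials = n_trials
    if min_trials > n_trials:
        raise ValueError("min_trials exceeds available trials")
    pref_bin = roi_tuning(table).pref_bin
    return int(np.sum(table.peaks[pref_bin] >= min_peak)) >= min_trials


def classify_on_off(dff: DFFMovie, roi: ROI,
                    schedule: StimulusSchedule | None = None,
                    onset_window_s: float | None = None,
                    offset_window_s: float | None = None,
                    k_sd: float = 3.0, tail_fraction: float = 0.25) -> str:
    """ON vs ON–OFF vs nonresponsive classification.

    The onset response is the trial-averaged maximum of the ROI trace
    in a window at the start of each preferred-bin sweep (bar entry);
    the offset response, in a window ending at the sweep's last frame
    (bar exit).  A phase is responsive when its response exceeds
    ``k_sd`` × the SD of the ROI trace over stimulus-free frames; the
    offset must additionally exceed ``tail_fraction`` × the onset
    response, since at slow frame rates the indicator's decaying onset
    transient bleeds into the offset window.  Windows default to half
    the sweep each and must not overlap.
    """
    sched = schedule if schedule is not None else dff.schedule
    table = roi_trial_peaks(dff, roi, sched)
    tuning = roi_tuning(table)
    pref_dir = table.directions_deg[tuning.pref_bin]
    sweeps = sched.sweeps_for(pref_dir)
    fs = sched.frame_rate_hz
    sweep_frames = sweeps[0].offset_frame - sweeps[0].onset_frame
    if onset_window_s is None:
        onset_window_s = 0.5 * sweep_frames / fs
    if offset_window_s is None:
        offset_window_s = 0.5 * sweep_frames / fs
    on_w = max(1, int(round(onset_window_s * fs)))
    off_w = max(1, int(round(offset_window_s * fs)))
    if on_w + off_w > sweep_frames:
        raise ValueError("onset and offset windows overlap")

    mask = roi.pixel_mask & dff.valid_mask
    trace = dff.values[:, mask].mean(axis=1)
    stim = sched.stimulus_frame_mask(trace.shape[0])
    noise_sd = trace[~stim].std()

    onset_resp = float(np.mean([
        trace[s.onset_frame:s.onset_frame + on_w].max() for s in sweeps]))
    offset_resp = float(np.mean([
        trace[s.offset_frame - off_w:s.offset_frame].max()
        for s in sweeps]))
    threshold = k_sd * noise_sd
    on_hit = onset_resp > threshold
    off_hit = (offset_resp > threshold
               and offset_resp > tail_fraction * max(onset_resp, 0.0))
    if on_hit and off_hit:
        return "ON-OFF"
    if on_hit:
        return "ON"
    return "nonresponsive"


def _roi_rng(seed: int, roi_id: str) -> np.random.Generator:
    # per-ROI stream from (global seed, stable id hash): parallel or
    # reordered evaluation cannot change any ROI's permutations
    return np.random.default_rng([seed, zlib.crc32(roi_id.encode())])


def _permuted_dsi(peaks: np.ndarray, directions: np.ndarray,
                  n_permutations: int, rng: np.random.Generator) -> np.ndarray:
    """DSI of ``n_permutations`` within-block label shuffles of one table."""
    n_dir, n_trials = peaks.shape
    idx = np.broadcast_to(np.arange(n_dir), (n_permutations, n_trials, n_dir))
    idx = rng.permuted(idx.copy(), axis=-1)
    cols = np.broadcast_to(peaks.T, (n_permutations, n_trials, n_dir))
    shuffled = np.take_along_axis(cols, idx, axis=-1)   # (P, trials, dirs)
    mean = shuffled.mean(axis=1)                        # (P, dirs)
    d, _, _ = vectorsum.dsi(mean, directions)
    return d


def permutation_test(table: TrialPeakTable, n_permutations: int = 1000,
                     seed: int = 0, threshold_percentile: float = 95.0
                     ) -> PermutationResult:
    """Block-shuffle permutation test for significant direction
    selectivity.

    Every permutation independently shuffles the direction labels within
    each trial block (peaks stay attached to their trial) and the DSI is
    recomputed.  The observed DSI's mid-rank percentile among the
    permuted DSIs (ties counted half) must exceed
    ``threshold_percentile`` for significance.  A fully degenerate
    (all-equal) table lands at percentile 50 and is not significant.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = _roi_rng(seed, table.roi_id)
    actual = roi_tuning(table).dsi
    if np.ptp(table.peaks) == 0:
        return PermutationResult(50.0, False, degenerate=True,
                                 n_permutations=n_permutations)
    permuted = _permuted_dsi(table.peaks, table.directions_deg,
                             n_permutations, rng)
    percentile = 100.0 * (np.sum(permuted < actual)
                          + 0.5 * np.sum(permuted == actual)) / n_permutations
    return PermutationResult(float(percentile),
                             bool(percentile > threshold_percentile),
                             degenerate=False,
                             n_permutations=n_permutations)


def permutation_test_batch(peaks: np.ndarray, directions_deg: np.ndarray,
                           n_permutations: int = 1000, seed: int = 0,
                           threshold_percentile: float = 95.0,
                           roi_ids: list[str] | None = None
                           ) -> list[PermutationResult]:
    """Run :func:`permutation_test` over a stack of trial-peak tables
    ``peaks`` of shape (n_rois, n_directions, n_trials)."""
    peaks = np.asarray(peaks, dtype=float)
    out = []
    for i in range(peaks.shape[0]):
        roi_id = roi_ids[i] if roi_ids is not None else f"roi{i:04d}"
        table = TrialPeakTable(peaks=peaks[i], directions_deg=directions_deg,
                               roi_id=roi_id)
        out.append(permutation_test(table, n_permutations, seed,
                                    threshold_percentile))
    return out
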