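"""ΔF/F₀ normalization and per-pixel direction-tuning maps.

Converts a raw two-photon calcium movie plus its moving-bar stimulus
schedule into (1) a ΔF/F₀ movie whose baseline F₀ is the per-pixel mean
over all stimulus-free frames, (2) a per-pixel tuning map carrying the
normalized vector-sum magnitude, preferred angle and DSI computed from
per-direction mean peak responses, and (3) candidate direction-selective
ROIs segmented from the median-filter-enriched magnitude map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .schedule import StimulusSchedule
from . import vectorsum

__all__ = [
    "DFFMovie",
    "PixelTuningMap",
    "ROI",
    "compute_dff",
    "pixel_tuning_map",
    "enrich_ds_map",
    "extract_rois",
    "register_movie",
]


class NoBaselineError(ValueError):
    """Raised when a schedule leaves no stimulus-free frames for F₀."""


@dataclass
class DFFMovie:
    """ΔF/F₀ movie with its baseline image and schedule attached."""

    values: np.ndarray        # (T, H, W), dimensionless
    baseline: np.ndarray      # (H, W), fluorescence units
    schedule: StimulusSchedule
    valid_mask: np.ndarray    # (H, W) bool; False where baseline <= eps

    @property
    def shape(self):
        return self.values.shape


@dataclass
class PixelTuningMap:
    vector_sum_magnitude: np.ndarray      # (H, W)
    preferred_angle_deg: np.ndarray       # (H, W), NaN where undefined
    dsi: np.ndarray                       # (H, W)
    per_direction_mean_peak: np.ndarray   # (D, H, W)
    directions_deg: np.ndarray            # (D,)
    valid_mask: np.ndarray                # (H, W)


@dataclass
class ROI:
    roi_id: str
    pixel_mask: np.ndarray    # (H, W) bool, 4-connected, non-empty
    centroid_xy: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        if not self.pixel_mask.any():
            raise ValueError("ROI mask is empty")


def compute_dff(movie: np.ndarray, schedule: StimulusSchedule,
                baseline_epsilon: float | None = None,
                baseline_guard_frames: int = 0) -> DFFMovie:
    """Normalize a raw fluorescence movie to ΔF/F₀.

    Baseline F₀ is the per-pixel mean over every frame outside all sweep
    windows, pooled across the whole recording.  ΔF/F₀ = (F − F₀)/F₀.
    Pixels whose baseline falls at or below ``baseline_epsilon``
    (default ``1e-6 × max(movie)``) are masked invalid and set to 0.

    ``baseline_guard_frames`` additionally excludes that many frames
    after each sweep from the baseline (indicator fluorescence decays
    over ~2 decay constants after a response; at slow frame rates the
    tail would otherwise inflate F₀).
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (frames, height, width)")
    stim_mask = schedule.stimulus_frame_mask(movie.shape[0])
    if baseline_guard_frames:
        stim_mask = stim_mask.copy()
        for s in schedule.sweeps:
            stop = min(movie.shape[0], s.offset_frame + baseline_guard_frames)
            stim_mask[s.offset_frame:stop] = True
    if stim_mask.all():
        raise NoBaselineError("schedule leaves no stimulus-free frames")
    if baseline_epsilon is None:
        baseline_epsilon = 1e-6 * float(movie.max())
    baseline = movie[~stim_mask].mean(axis=0)
    valid = baseline > baseline_epsilon
    safe = np.where(valid, baseline, 1.0)
    values = (movie - baseline) / safe
    values[:, ~valid] = 0.0
    return DFFMovie(values=values, baseline=baseline, schedule=schedule,
                    valid_mask=valid)


def _neighborhood_mean(frames: np.ndarray, size: int) -> np.ndarray:
    """Spatial mean over a size×size window per frame; edge pixels use
    only the in-bounds subset of the window."""
    if size == 1:
        return frames
    kernel = (1, size, size)
    total = ndimage.uniform_filter(frames, size=kernel, mode="constant",
                                   cval=0.0) * (size * size)
    ones = np.ones(frames.shape[1:], dtype=float)
    count = ndimage.uniform_filter(ones, size=(size, size), mode="constant",
                                   cval=0.0) * (size * size)
    return total / count[None, :, :]


def pixel_tuning_map(dff: DFFMovie, neighborhood: int = 3) -> PixelTuningMap:
    """Per-pixel vector-sum tuning map.

    Each pixel trace is first averaged over its spatial neighborhood,
    then the peak ΔF/F₀ inside every sweep window is taken and averaged
    across trials per direction.  The normalized vector sum of the
    per-direction mean peaks gives the tuning magnitude and preferred
    angle; DSI uses the pref/null bins of that angle.
    """
    if neighborhood < 1 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be an odd positive integer")
    sched = dff.schedule
    smoothed = _neighborhood_mean(dff.values, neighborhood)
    directions = np.asarray(sched.directions_deg)
    H, W = dff.values.shape[1:]
    mean_peak = np.empty((len(directions), H, W))
    for d, direction in enumerate(directions):
        sweeps = sched.sweeps_for(direction)
        peaks = np.stack([
            smoothed[s.onset_frame:s.offset_frame].max(axis=0)
            for s in sweeps
        ])
        mean_peak[d] = peaks.mean(axis=0)
    resp = np.moveaxis(mean_peak, 0, -1)          # (H, W, D)
    mag, angle = vectorsum.vector_sum(resp, directions)
    dsi_map, _, _ = vectorsum.dsi(resp, directions, preferred_angle_deg=angle)
    mag = np.where(dff.valid_mask, mag, 0.0)
    angle = np.where(dff.valid_mask, angle, np.nan)
    dsi_map = np.where(dff.valid_mask, dsi_map, 0.0)
    return PixelTuningMap(vector_sum_magnitude=mag, preferred_angle_deg=angle,
                          dsi=dsi_map, per_direction_mean_peak=mean_peak,
                          directions_deg=directions,
                          valid_mask=dff.valid_mask.copy())


def enrich_ds_map(tuning_map: PixelTuningMap,
                  median_kernel: int = 3) -> PixelTuningMap:
    """2D median filter on the magnitude map to enrich cell-like regions
    of coherent direction selectivity; angles and peaks are untouched.
    Out-of-bounds window entries are treated as 0."""
    if median_kernel < 1 or median_kernel % 2 == 0:
        raise ValueError("median_kernel must be an odd positive integer")
    if median_kernel == 1:
        mag = tuning_map.vector_sum_magnitude.copy()
    else:
        mag = ndimage.median_filter(tuning_map.vector_sum_magnitude,
                                    size=median_kernel, mode="constant",
                                    cval=0.0)
    return PixelTuningMap(
        vector_sum_magnitude=mag,
        preferred_angle_deg=tuning_map.preferred_angle_deg,
        dsi=tuning_map.dsi,
        per_direction_mean_peak=tuning_map.per_direction_mean_peak,
        directions_deg=tuning_map.directions_deg,
        valid_mask=tuning_map.valid_mask,
    )


_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def extract_rois(tuning_map: PixelTuningMap, dff: DFFMovie | None = None,
                 magnitude_threshold: float = 0.3, min_area: int = 20,
                 max_area: int = 500) -> list[ROI]:
    """Segment candidate DS ROIs: 4-connected components of
    supra-threshold, valid pixels with area inside [min_area, max_area],
    ordered by the (top, left) corner of their bounding boxes."""
    if not 0 <= magnitude_threshold <= 1:
        raise ValueError("magnitude_threshold must be in [0, 1]")
    if min_area > max_area:
        raise ValueError("min_area must not exceed max_area")
    fg = (tuning_map.vector_sum_magnitude >= magnitude_threshold) \
        & tuning_map.valid_mask
    labels, n = ndimage.label(fg, structure=_FOUR_CONNECTED)
    rois = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        mask = labels == lab
        area = int(mask.sum())
        if not min_area <= area <= max_area:
            continue
        top, left = sl[0].start, sl[1].start
        rr, cc = np.nonzero(mask)
        rois.append((top, left, mask, (cc.mean(), rr.mean())))
    rois.sort(key=lambda r: (r[0], r[1]))
    return [ROI(roi_id=f"roi{i:04d}", pixel_mask=m, centroid_xy=c)
            for i, (_, _, m, c) in enumerate(rois)]


def register_movie(movie: np.ndarray, upsample_factor: int = 1) -> np.ndarray:
    """Optional rigid translational registration (plumbing, off by
    default in the pipeline): aligns every frame to the temporal mean by
    phase cross-correlation.  Input movies are assumed pre-registered;
    use this only for residual x–y jitter."""
    from skimage.registration import phase_cross_correlation

    movie = np.asarray(movie, dtype=float)
    template = movie.mean(axis=0)
    out = np.empty_like(movie)
    for t, frame in enumerate(movie):
        shift, _, _ = phase_cross_correlation(
            template, frame, upsample_factor=upsample_factor)
        out[t] = ndimage.shift(frame, shift, order=1, mode="nearest")
    if np.abs(out - movie).max() > 0:
        warnings.warn("register_movie applied nonzero shifts; input was "
                      "not fully registered", stacklevel=2)
    return out
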