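"""Tuning indices for visually evoked postsynaptic currents.

Peak onset/offset E/IPSCs measured per stimulus condition (direction,
spot diameter, or bar speed) feed the standard index set:

* vector sum: Rx = Σ Ri·cosθi, Ry = Σ Ri·sinθi, Rt = Σ Ri; the
  normalized magnitude √(Rx²+Ry²)/Rt and the quadrant-correct angle of
  (Rx, Ry) give tuning strength and preferred direction;
* DSI = (R_PD − R_ND)/(R_PD + R_ND) with null 180° from preferred;
* CS index = 1 − R_largespot/R_allspots (surround suppression);
* SI = (R_fast − R_slow)/(R_fast + R_slow) (speed preference);
* DSGC classification: IPSC DSI ≥ 0.2 (preferred/null axis taken from
  the IPSC vector sum);
* E–I timing offset: IPSC peak time − EPSC peak time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import vectorsum

__all__ = [
    "ResponseSet",
    "TuningIndices",
    "extract_condition_peaks",
    "direction_vector_sum",
    "dsi_from_peaks",
    "cs_index",
    "speed_index",
    "classify_dsgc",
    "ei_timing_offset",
    "compute_tuning_indices",
]

_COLUMNS = ["polarity", "phase", "condition_type", "condition", "trial",
            "peak_pA"]


@dataclass
class ResponseSet:
    """Tidy per-condition peak table (magnitudes of baseline-subtracted
    current extrema; the sign convention lives in ``metadata``)."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"response table missing columns {missing}")
        if (self.table["peak_pA"] < 0).any():
            raise ValueError("peaks are stored as nonnegative magnitudes")
        keys = self.table[["polarity", "phase", "condition_type",
                           "condition", "trial"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (polarity, phase, condition, trial)")

    def trial_mean(self, polarity: str, phase: str,
                   condition_type: str) -> pd.Series:
        sub = self.table[(self.table.polarity == polarity)
                         & (self.table.phase == phase)
                         & (self.table.condition_type == condition_type)]
        return sub.groupby("condition")["peak_pA"].mean().sort_index()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "ResponseSet":
        return cls(pd.read_csv(path), metadata=metadata or {})


@dataclass
class TuningIndices:
    rx: float
    ry: float
    rt: float
    vector_magnitude_normalized: float
    preferred_deg: float
    r_pd: float
    r_nd: float
    dsi: float
    si: float | None = None
    cs_index_on: float | None = None
    cs_index_off: float | None = None
    is_dsgc: bool | None = None
    degenerate: bool = False


def extract_condition_peaks(traces: dict, sampling_rate_hz: float,
                            onset_window_s: tuple[float, float],
                            offset_window_s: tuple[float, float],
                            baseline_window_s: tuple[float, float],
                            holding_mV: float,
                            condition_type: str = "direction_deg"
                            ) -> ResponseSet:
    """Peak onset/offset currents per condition and trial.

    ``traces`` maps ``(condition, trial)`` to a current trace (pA).  The
    peak is the largest |current − baseline mean| inside each window,
    stored as a magnitude; polarity follows the holding potential
    (−60 mV isolates EPSCs at the inhibitory reversal, +12 mV IPSCs at
    the excitatory reversal).
    """
    if onset_window_s[1] > offset_window_s[0]:
        raise ValueError("onset and offset windows overlap")
    polarity = "EPSC" if holding_mV < -20 else "IPSC"
    fs = sampling_rate_hz

    def window_peak(trace, window, base):
        i0, i1 = (int(round(w * fs)) for w in window)
        return float(np.abs(trace[i0:i1] - base).max())

    rows = []
    for (condition, trial), trace in traces.items():
        trace = np.asarray(trace, dtype=float)
        b0, b1 = (int(round(w * fs)) for w in baseline_window_s)
        base = trace[b0:b1].mean()
        for phase, window in (("onset", onset_window_s),
                              ("offset", offset_window_s)):
            rows.append({"polarity": polarity, "phase": phase,
                         "condition_type": condition_type,
                         "condition": condition, "trial": trial,
                         "peak_pA": window_peak(trace, window, base)})
    return ResponseSet(pd.DataFrame(rows),
                       metadata={"holding_mV": holding_mV,
                                 "sign_convention":
                                 "magnitude of baseline-subtracted extremum"})


def direction_vector_sum(peaks_by_direction: pd.Series | dict):
    """(rx, ry, rt, normalized magnitude, preferred angle in degrees)."""
    peaks = pd.Series(peaks_by_direction).sort_index()
    directions = peaks.index.to_numpy(dtype=float)
    r = peaks.to_numpy(dtype=float)
    theta = np.deg2rad(directions)
    rx = float(np.sum(r * np.cos(theta)))
    ry = float(np.sum(r * np.sin(theta)))
    rt = float(np.sum(r))
    mag = float(np.hypot(rx, ry) / rt) if rt > 0 else 0.0
    pref = float(np.rad2deg(np.arctan2(ry, rx)) % 360.0) if rt > 0 \
        else float("nan")
    return rx, ry, rt, mag, pref


def dsi_from_peaks(peaks_by_direction: pd.Series | dict,
                   preferred_deg: float):
    """(r_pd, r_nd, dsi) against the given preferred-direction angle."""
    peaks = pd.Series(peaks_by_direction).sort_index()
    directions = peaks.index.to_numpy(dtype=float)
    r = peaks.to_numpy(dtype=float)
    d, pref_bin, null_bin = vectorsum.dsi(
        r, directions, preferred_angle_deg=np.asarray(preferred_deg))
    return float(r[pref_bin]), float(r[null_bin]), float(d)


def cs_index(spot_peaks: pd.Series | dict,
             largest_diameter_um: float = 440.0) -> float:
    """Center-surround index 1 − R_largespot/R_allspots over spot
    diameters up to and including the largest; 0 (nonresponsive) when no
    spot evokes a response."""
    peaks = pd.Series(spot_peaks).sort_index()
    peaks = peaks[peaks.index <= largest_diameter_um]
    if largest_diameter_um not in peaks.index:
        raise ValueError("largest spot diameter missing from table")
    r_all = float(peaks.max())
    if r_all <= 0:
        return 0.0
    return float(1.0 - peaks.loc[largest_diameter_um] / r_all)


def speed_index(r_fast: float, r_slow: float) -> float:
    """(R_fast − R_slow)/(R_fast + R_slow); 0 when both are zero."""
    if r_fast < 0 or r_slow < 0:
        raise ValueError("peaks must be nonnegative")
    denom = r_fast + r_slow
    return float((r_fast - r_slow) / denom) if denom > 0 else 0.0


def classify_dsgc(ipsc_dsi: float, dsi_threshold: float = 0.2,
                  bistratified: bool | None = None) -> bool:
    """DSGC call from asymmetric inhibition: IPSC DSI ≥ threshold
    (inclusive).  A morphology flag may be recorded alongside but does
    not veto the call."""
    del bistratified  # recorded by callers; not part of the criterion
    return bool(ipsc_dsi >= dsi_threshold)


def ei_timing_offset(epsc_trace: np.ndarray, ipsc_trace: np.ndarray,
                     sampling_rate_hz: float,
                     window_s: tuple[float, float] | None = None) -> float:
    """IPSC peak time − EPSC peak time (s) within matched windows."""
    if epsc_trace is None or ipsc_trace is None:
        raise ValueError("both polarities are required")
    e = np.asarray(epsc_trace, dtype=float)
    i = np.asarray(ipsc_trace, dtype=float)
    fs = sampling_rate_hz
    if window_s is None:
        sl = slice(0, min(e.shape[0], i.shape[0]))
    else:
        sl = slice(int(round(window_s[0] * fs)), int(round(window_s[1] * fs)))
    t_e = np.argmax(np.abs(e[sl] - e[sl][0]))
    t_i = np.argmax(np.abs(i[sl] - i[sl][0]))
    return float((t_i - t_e) / fs)


def compute_tuning_indices(responses: ResponseSet, phase: str = "onset",
                           fast_speed: float = 1000.0,
                           slow_speed: float = 250.0,
                           dsi_threshold: float = 0.2) -> TuningIndices:
    """All indices for one cell from a tidy response set.

    The preferred/null axis comes from the IPSC vector sum (inhibition
    carries the directional signal in this circuit); EPSC indices, when
    present, are computed against the same axis by the caller.
    """
    polarity = "IPSC" if (responses.table.polarity == "IPSC").any() \
        else "EPSC"
    dir_peaks = responses.trial_mean(polarity, phase, "direction_deg")
    if dir_peaks.empty:
        raise ValueError("no direction-tuning conditions in table")
    rx, ry, rt, mag, pref = direction_vector_sum(dir_peaks)
    degenerate = rt <= 0
    if degenerate:
        r_pd = r_nd = d = 0.0
    else:
        r_pd, r_nd, d = dsi_from_peaks(dir_peaks, pref)

    si = None
    speed_peaks = responses.trial_mean(polarity, phase, "speed_um_per_s")
    if {fast_speed, slow_speed} <= set(speed_peaks.index):
        si = speed_index(speed_peaks[fast_speed], speed_peaks[slow_speed])

    cs_on = cs_off = None
    for ph, slot in (("onset", "on"), ("offset", "off")):
        spot = responses.trial_mean(polarity, ph, "spot_diameter_um")
        if not spot.empty:
            value = cs_index(spot)
            if slot == "on":
                cs_on = value
            else:
                cs_off = value

    return TuningIndices(rx=rx, ry=ry, rt=rt,
                         vector_magnitude_normalized=mag, preferred_deg=pref,
                         r_pd=r_pd, r_nd=r_nd, dsi=d, si=si,
                         cs_index_on=cs_on, cs_index_off=cs_off,
                         is_dsgc=(classify_dsgc(d, dsi_threshold)
                                  if polarity == "IPSC" else None),
                         degenerate=degenerate)
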