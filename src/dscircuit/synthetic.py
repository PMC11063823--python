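"""Synthetic data with known ground truth for every pipeline stage.

Generators emulate the four data modalities the analysis consumes:

* moving-bar calcium movies of tuned and untuned cells (von Mises
  tuning with concentration κ, single-exponential indicator decay,
  ON or ON–OFF response timing, Gaussian noise);
* paired-recording voltage-clamp sweep families produced by an
  instantaneous two-resistor circuit (series resistance Rs, input
  resistance Rin) carrying an alpha-function synaptic conductance, with
  a −5 mV test pulse at the trace end;
* per-direction / spot-size / speed peak-response tables whose true
  DSI, center-surround index and speed index are fixed by construction;
* bistratified dendritic skeletons with a known soma offset, whose
  reference asymmetry index is computed by an independent geometric
  routine (shapely) rather than the morphology module.

Every generator takes an explicit integer seed, draws from one
``numpy.random.Generator``, and returns a :class:`GroundTruthManifest`
describing each generated entity exactly once.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .conductance import SweepSet, TestPulse
from .ephys import ResponseSet
from .morphology import Skeleton
from .schedule import StimulusSchedule, Sweep

__all__ = [
    "CellSpec",
    "CellRecord",
    "EphysRecord",
    "MorphRecord",
    "GroundTruthManifest",
    "generate_stimulus_schedule",
    "generate_calcium_movie",
    "generate_vclamp_sweeps",
    "generate_tuning_table",
    "generate_skeleton",
    "von_mises_weight",
]


# --------------------------------------------------------------- manifest
@dataclass
class CellRecord:
    cell_id: str
    center_xy: tuple[float, float]
    is_ds: bool
    preferred_direction_deg: float
    tuning_concentration: float          # von Mises κ, >= 0
    response_class: str                  # ON | ON-OFF | none
    overlapping: bool = False
    true_cs_index: float | None = None
    true_speed_index: float | None = None


@dataclass
class EphysRecord:
    sweep_set_id: str
    peak_conductance_nS: float
    reversal_mV: float
    rs_MOhm: float
    rin_MOhm: float


@dataclass
class MorphRecord:
    skeleton_id: str
    true_ai: float
    true_asymmetry_angle_deg: float
    n_tips: int
    n_branch_points: int
    total_length_um: float


@dataclass
class GroundTruthManifest:
    seed: int
    cell_records: list[CellRecord] = field(default_factory=list)
    ephys_records: list[EphysRecord] = field(default_factory=list)
    morph_records: list[MorphRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = ([r.cell_id for r in self.cell_records]
               + [r.sweep_set_id for r in self.ephys_records]
               + [r.skeleton_id for r in self.morph_records])
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate entity ids in manifest")
        for r in self.cell_records:
            if r.tuning_concentration < 0:
                raise ValueError("κ must be >= 0")
        for r in self.morph_records:
            if not 0 <= r.true_ai <= 1:
                raise ValueError("true AI must lie in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        d = json.loads(Path(path).read_text())
        return cls(seed=d["seed"],
                   cell_records=[CellRecord(**{**r, "center_xy":
                                               tuple(r["center_xy"])})
                                 for r in d["cell_records"]],
                   ephys_records=[EphysRecord(**r)
                                  for r in d["ephys_records"]],
                   morph_records=[MorphRecord(**r)
                                  for r in d["morph_records"]])


# --------------------------------------------------------------- schedule
def generate_stimulus_schedule(n_directions: int = 8, n_trials: int = 3,
                               frame_rate_hz: float = 2.96,
                               stim_frames: int = 9, gap_frames: int = 6,
                               order: str = "block_shuffled",
                               seed: int = 0) -> StimulusSchedule:
    """Equally spaced directions presented once per trial block.

    ``block_shuffled`` randomizes direction order independently within
    each block (every direction still occurs exactly once per block);
    ``sequential`` presents directions in ascending order.  Sweep
    windows are half-open frame intervals separated (and preceded) by
    ``gap_frames`` stimulus-free frames.
    """
    if n_directions < 2 or n_trials < 1 or stim_frames < 1 or gap_frames < 1:
        raise ValueError("counts must be positive (n_directions >= 2)")
    if order not in ("sequential", "block_shuffled"):
        raise ValueError(f"unknown order {order!r}")
    rng = np.random.default_rng(seed)
    directions = 360.0 * np.arange(n_directions) / n_directions
    sweeps = []
    i = 0
    for trial in range(n_trials):
        block = (directions if order == "sequential"
                 else rng.permutation(directions))
        for direction in block:
            onset = gap_frames + i * (stim_frames + gap_frames)
            sweeps.append(Sweep(direction_deg=float(direction),
                                trial_index=trial, onset_frame=onset,
                                offset_frame=onset + stim_frames))
            i += 1
    return StimulusSchedule(frame_rate_hz=frame_rate_hz, sweeps=sweeps)


# ----------------------------------------------------------------- movie
@dataclass(frozen=True)
class CellSpec:
    center_xy: tuple[float, float]       # (x, y) pixels
    radius_px: float
    amplitude: float                     # peak ΔF/F₀ in preferred direction
    kappa: float                         # von Mises concentration
    preferred_direction_deg: float
    response_class: str = "ON"           # ON | ON-OFF | none


def von_mises_weight(direction_deg, pref_deg, kappa) -> np.ndarray:
    """Tuning weight exp(κ·cosΔ)/exp(κ) in (0, 1]; κ = 0 is flat."""
    delta = np.deg2rad(np.asarray(direction_deg) - pref_deg)
    return np.exp(kappa * (np.cos(delta) - 1.0))


def generate_calcium_movie(schedule: StimulusSchedule,
                           field_size: tuple[int, int],
                           cells: list[CellSpec],
                           baseline_f: float = 100.0,
                           noise_sd: float = 0.05,
                           indicator_decay_s: float = 0.6,
                           seed: int = 0):
    """Synthetic fluorescence movie plus its ground-truth manifest.

    Each cell is a disk that, during a sweep of direction θ, fires a
    transient of amplitude ``amplitude · exp(κ(cos(θ−pref)−1))`` ΔF/F₀
    units at stimulus onset (ON) or at onset and offset (ON–OFF),
    shaped by a single-exponential indicator kernel with unit peak.
    Noise is i.i.d. Gaussian in ΔF/F₀ units on every frame.
    """
    if not schedule.sweeps:
        raise ValueError("schedule has no sweeps")
    H, W = field_size
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for c in cells:
        x, y = c.center_xy
        if not (0 <= x < W and 0 <= y < H):
            raise ValueError(f"cell center {c.center_xy} outside field")
        if c.radius_px <= 0:
            raise ValueError("cell radius must be positive")
    rng = np.random.default_rng(seed)
    gap_tail = schedule.sweeps[0].onset_frame   # leading gap length
    T = schedule.n_frames_min + max(gap_tail, 1)
    fs = schedule.frame_rate_hz

    k_len = max(2, int(np.ceil(5 * indicator_decay_s * fs)))
    kernel = np.exp(-np.arange(k_len) / (indicator_decay_s * fs))

    signal = np.zeros((T, H, W))
    yy, xx = np.mgrid[0:H, 0:W]
    overlap = _overlap_flags(cells)
    records = []
    for i, c in enumerate(cells):
        drive = np.zeros(T)
        if c.response_class in ("ON", "ON-OFF"):
            for s in schedule.sweeps:
                w = float(von_mises_weight(s.direction_deg,
                                           c.preferred_direction_deg,
                                           c.kappa))
                drive[s.onset_frame] += c.amplitude * w
                if c.response_class == "ON-OFF":
                    # bar exit: last stimulus frame of the sweep
                    drive[s.offset_frame - 1] += c.amplitude * w
        trace = np.convolve(drive, kernel)[:T]
        mask = (xx - c.center_xy[0]) ** 2 + (yy - c.center_xy[1]) ** 2 \
            <= c.radius_px ** 2
        signal[:, mask] += trace[:, None]
        records.append(CellRecord(
            cell_id=f"cell{i:03d}", center_xy=tuple(c.center_xy),
            is_ds=(c.kappa > 0 and c.response_class != "none"),
            preferred_direction_deg=float(c.preferred_direction_deg % 360),
            tuning_concentration=float(c.kappa),
            response_class=c.response_class, overlapping=overlap[i]))
    noise = rng.normal(0.0, noise_sd, size=(T, H, W)) if noise_sd > 0 \
        else 0.0
    movie = baseline_f * (1.0 + signal + noise)
    manifest = GroundTruthManifest(seed=seed, cell_records=records)
    return movie, manifest


def _overlap_flags(cells: list[CellSpec]) -> list[bool]:
    flags = [False] * len(cells)
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            d = np.hypot(cells[i].center_xy[0] - cells[j].center_xy[0],
                         cells[i].center_xy[1] - cells[j].center_xy[1])
            if d < cells[i].radius_px + cells[j].radius_px:
                flags[i] = flags[j] = True
    return flags


def write_movie_tiff(path, movie: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, movie.astype(np.float32))


# ------------------------------------------------------------ voltage clamp
#: residual access resistance (MΩ) limiting the capacitive transient;
#: models finite amplifier bandwidth so an Rs = 0 cell still shows a
#: finite, near-zero measured Rs.
RS_TRANSIENT_FLOOR_MOHM = 0.1
MEMBRANE_CAPACITANCE_PF = 20.0


def generate_vclamp_sweeps(g_peak_nS: float = 2.0, t_rise_s: float = 0.01,
                           e_rev_mV: float = -60.0,
                           holding_potentials_mV=(-100, -80, -60, -40,
                                                  -20, 0, 20),
                           rs_MOhm: float = 10.0, rin_MOhm: float = 500.0,
                           leak_rev_mV: float = -60.0,
                           noise_sd_pA: float = 2.0,
                           sampling_rate_hz: float = 20000.0,
                           test_pulse_mV: float = -5.0,
                           n_sweeps: int = 3,
                           stim_onset_s: float = 0.1,
                           stim_duration_s: float = 0.05,
                           trace_duration_s: float = 0.55,
                           seed: int = 0,
                           cell_id: str = "pair0"):
    """Voltage-clamp sweep family from the self-consistent two-resistor
    circuit, plus its ground-truth manifest.

    At each holding potential Vh the recorded current solves, sample by
    sample, V = Vh − Im·Rs and Im = (V − E_leak)/Rin + g(t)(V − E_rev),
    giving Im = [(Vh − E_leak)/Rin + g(Vh − E_rev)] / [1 + Rs(1/Rin + g)].
    The synaptic conductance g(t) is an alpha function with peak
    ``g_peak_nS`` reached ``t_rise_s`` after stimulus onset.  A −5 mV
    test pulse with a capacitive charging transient is appended near the
    trace end.
    """
    if rs_MOhm < 0 or rin_MOhm <= 0 or sampling_rate_hz <= 0:
        raise ValueError("require rs >= 0, rin > 0, sampling_rate > 0")
    g_peak_uS = g_peak_nS * 1e-3
    if rs_MOhm * (1.0 / rin_MOhm + g_peak_uS) >= 1.0:
        raise ValueError("divergent voltage divider: rs·(1/rin + g) >= 1")
    rng = np.random.default_rng(seed)
    fs = sampling_rate_hz
    t = np.arange(int(round(trace_duration_s * fs))) / fs

    s = t - stim_onset_s
    g_uS = np.where(
        s > 0, g_peak_uS * (s / t_rise_s) * np.exp(1.0 - s / t_rise_s), 0.0)

    pulse = TestPulse(start_s=trace_duration_s - 0.1, duration_s=0.05,
                      amplitude_mV=test_pulse_mV)
    i0 = int(round(pulse.start_s * fs))
    i1 = int(round((pulse.start_s + pulse.duration_s) * fs))
    r_eff = rs_MOhm + RS_TRANSIENT_FLOOR_MOHM
    tau_s = r_eff * MEMBRANE_CAPACITANCE_PF * 1e-6
    tp = (np.arange(i1 - i0)) / fs
    steady_nA = pulse.amplitude_mV / (rs_MOhm + rin_MOhm)
    amp_nA = pulse.amplitude_mV / r_eff
    pulse_nA = steady_nA + (amp_nA - steady_nA) * np.exp(-tp / tau_s)

    sweeps: dict[float, list[np.ndarray]] = {}
    for vh in holding_potentials_mV:
        vh = float(vh)
        num_nA = (vh - leak_rev_mV) / rin_MOhm + g_uS * (vh - e_rev_mV)
        den = 1.0 + rs_MOhm * (1.0 / rin_MOhm + g_uS)
        im_pA = 1e3 * num_nA / den
        im_pA[i0:i1] = im_pA[i0:i1] + 1e3 * pulse_nA
        reps = []
        for _ in range(n_sweeps):
            trace = im_pA.copy()
            if noise_sd_pA > 0:
                trace = trace + rng.normal(0.0, noise_sd_pA,
                                           size=trace.shape)
            reps.append(trace)
        sweeps[vh] = reps
    sweep_set = SweepSet(sweeps=sweeps, sampling_rate_hz=fs,
                         stim_onset_s=stim_onset_s,
                         stim_duration_s=stim_duration_s,
                         test_pulse=pulse, cell_id=cell_id)
    manifest = GroundTruthManifest(seed=seed, ephys_records=[EphysRecord(
        sweep_set_id=cell_id, peak_conductance_nS=g_peak_nS,
        reversal_mV=e_rev_mV, rs_MOhm=rs_MOhm, rin_MOhm=rin_MOhm)])
    return sweep_set, manifest


# ------------------------------------------------------------ tuning table
def generate_tuning_table(pref_deg: float = 270.0, kappa: float = 3.0,
                          amplitude_pA: float = 100.0,
                          n_directions: int = 8,
                          speeds_um_per_s=(250.0, 1000.0),
                          spot_diameters_um=(0.0, 110.0, 220.0, 330.0,
                                             440.0),
                          surround_suppression: float = 0.4,
                          noise_sd_pA: float = 0.0,
                          n_trials: int = 3,
                          polarity: str = "IPSC",
                          speed_preference: float = 0.0,
                          seed: int = 0,
                          cell_id: str = "ephys0"):
    """Per-condition peak tables with exactly known tuning truths.

    Direction peaks follow the von Mises profile of (``pref_deg``,
    ``kappa``); spot responses rise linearly to ``amplitude_pA`` at an
    intermediate diameter and fall to ``amplitude·(1 − s)`` at the
    largest, so the true CS index equals ``surround_suppression``; the
    fast/slow speed peaks are ``amplitude·(1 ± p)`` so the true SI
    equals ``speed_preference``.
    """
    import pandas as pd

    if amplitude_pA < 0 or not 0 <= surround_suppression <= 1:
        raise ValueError("require amplitude >= 0 and 0 <= suppression <= 1")
    if not -1 <= speed_preference <= 1:
        raise ValueError("speed_preference must lie in [-1, 1]")
    if n_directions < 2 or len(speeds_um_per_s) < 1 \
            or len(spot_diameters_um) < 2:
        raise ValueError("empty or too-short condition lists")
    rng = np.random.default_rng(seed)
    directions = 360.0 * np.arange(n_directions) / n_directions
    diameters = np.sort(np.asarray(spot_diameters_um, dtype=float))
    d_opt = diameters[(len(diameters) - 1) // 2]
    spot_profile = np.where(
        diameters <= d_opt,
        0.3 + 0.7 * np.divide(diameters, d_opt,
                              out=np.ones_like(diameters),
                              where=d_opt > 0),
        1.0 - surround_suppression * (diameters - d_opt)
        / (diameters[-1] - d_opt))
    speeds = np.asarray(speeds_um_per_s, dtype=float)
    speed_profile = np.where(speeds == speeds.max(),
                             1.0 + speed_preference,
                             1.0 - speed_preference)

    rows = []

    def emit(condition_type, conditions, profile):
        for cond, p in zip(conditions, profile):
            for phase in ("onset", "offset"):
                for trial in range(n_trials):
                    peak = amplitude_pA * p
                    if noise_sd_pA > 0:
                        peak += rng.normal(0.0, noise_sd_pA)
                    rows.append({"polarity": polarity, "phase": phase,
                                 "condition_type": condition_type,
                                 "condition": float(cond), "trial": trial,
                                 "peak_pA": max(peak, 0.0)})

    emit("direction_deg", directions,
         von_mises_weight(directions, pref_deg, kappa))
    emit("spot_diameter_um", diameters, spot_profile)
    emit("speed_um_per_s", speeds, speed_profile)

    responses = ResponseSet(pd.DataFrame(rows),
                            metadata={"cell_id": cell_id,
                                      "bar_width_um": 150.0,
                                      "largest_spot_um": float(
                                          diameters[-1])})
    manifest = GroundTruthManifest(seed=seed, cell_records=[CellRecord(
        cell_id=cell_id, center_xy=(np.nan, np.nan),
        is_ds=kappa > 0, preferred_direction_deg=float(pref_deg % 360),
        tuning_concentration=float(kappa), response_class="ON-OFF",
        true_cs_index=float(surround_suppression),
        true_speed_index=float(speed_preference))])
    return responses, manifest


# --------------------------------------------------------------- skeleton
def generate_skeleton(n_branches: int = 6, field_radius_um: float = 100.0,
                      soma_offset_um: float = 0.0,
                      offset_angle_deg: float = 0.0,
                      depth_profile: str = "bistratified",
                      seed: int = 0, nodes_per_segment: int = 5,
                      ipl_span_um: float = 40.0,
                      skeleton_id: str = "skel0"):
    """Bifurcating radial skeleton with a known soma offset, plus its
    manifest.

    The arbor is laid out around a center displaced ``soma_offset_um``
    from the soma along ``offset_angle_deg``; each of ``n_branches``
    trunks runs from the soma toward the arbor rim and bifurcates at 60%
    of its span.  Depths follow ``depth_profile``: ON stratum at
    normalized depth 0.675, OFF at 0.325, alternating trunks when
    bistratified.  The manifest's reference asymmetry index and angle
    are computed by an independent shapely-based routine on the
    generated geometry.
    """
    profiles = ("monostratified_on", "monostratified_off", "bistratified")
    if depth_profile not in profiles:
        raise ValueError(f"depth_profile must be one of {profiles}")
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    if not 0 <= soma_offset_um < field_radius_um:
        raise ValueError("require 0 <= soma_offset < field_radius")
    rng = np.random.default_rng(seed)
    soma = np.zeros(2)
    center = soma + soma_offset_um * np.array([
        np.cos(np.deg2rad(offset_angle_deg)),
        np.sin(np.deg2rad(offset_angle_deg))])

    on_z, off_z = 0.675, 0.325
    node_xyz = [np.array([0.0, 0.0, 1.0])]   # soma sits at the GCL border
    node_parent = [-1]
    node_type = [1]
    split = 0.6

    def branch_depth(k: int) -> float:
        if depth_profile == "monostratified_on":
            return on_z
        if depth_profile == "monostratified_off":
            return off_z
        return on_z if k % 2 == 0 else off_z

    def add_path(start_idx, p0, p1, depth, n_nodes):
        parent = start_idx
        for j in range(1, n_nodes + 1):
            frac = j / n_nodes
            xy = p0 + frac * (p1 - p0)
            node_xyz.append(np.array([xy[0], xy[1], depth]))
            node_parent.append(parent)
            node_type.append(3)
            parent = len(node_xyz) - 1
        return parent

    for k in range(n_branches):
        phi = 360.0 * k / n_branches + rng.uniform(-10, 10)
        r_k = field_radius_um * rng.uniform(0.85, 1.0)
        depth = branch_depth(k)
        tip_main = center + r_k * np.array([np.cos(np.deg2rad(phi)),
                                            np.sin(np.deg2rad(phi))])
        mid_pt = soma + split * (tip_main - soma)
        fork = add_path(0, soma, mid_pt, depth, nodes_per_segment)
        for dphi in (-12.0, 12.0):
            a = np.deg2rad(phi + dphi)
            tip = center + r_k * np.array([np.cos(a), np.sin(a)])
            add_path(fork, mid_pt, tip, depth, nodes_per_segment)

    xyz = np.array([[p[0], p[1], p[2] * ipl_span_um] for p in node_xyz])
    depth_norm = np.array([p[2] for p in node_xyz])
    n = len(node_xyz)
    skel = Skeleton(node_ids=np.arange(1, n + 1), xyz=xyz,
                    radius=np.full(n, 0.5),
                    parent=np.array([-1 if p == -1 else p + 1
                                     for p in node_parent]),
                    types=np.array(node_type), depth_norm=depth_norm,
                    ventral_axis_deg=0.0)

    true_ai, true_angle = _reference_asymmetry(skel)
    total_len = float(skel.edge_lengths().sum())
    manifest = GroundTruthManifest(seed=seed, morph_records=[MorphRecord(
        skeleton_id=skeleton_id, true_ai=true_ai,
        true_asymmetry_angle_deg=true_angle,
        n_tips=2 * n_branches, n_branch_points=n_branches,
        total_length_um=total_len)])
    return skel, manifest


def _reference_asymmetry(skel: Skeleton) -> tuple[float, float]:
    """Independent AI computation via shapely polygon intersection."""
    from shapely.geometry import LineString, MultiPoint, Point

    e = skel.edges
    a = skel.xyz[e[:, 0], :2]
    b = skel.xyz[e[:, 1], :2]
    w = np.linalg.norm(a - b, axis=1)
    com = np.average(0.5 * (a + b), axis=0, weights=w)
    soma = skel.soma_xyz[:2]
    vec = com - soma
    norm = float(np.linalg.norm(vec))
    bearing = float(np.rad2deg(np.arctan2(vec[1], vec[0])) % 360.0)
    if norm < 1e-9:
        return 0.0, bearing
    u = vec / norm
    hull = MultiPoint([tuple(p) for p in skel.xyz[:, :2]]).convex_hull
    span = 10.0 * np.linalg.norm(skel.xyz[:, :2] - soma, axis=1).max()
    line = LineString([tuple(soma - span * u), tuple(soma + span * u)])
    inter = hull.exterior.intersection(line)
    pts = []
    if inter.is_empty:
        return 0.0, bearing
    if inter.geom_type == "Point":
        pts = [inter]
    else:
        pts = [g for g in inter.geoms if g.geom_type == "Point"]
    ts = [float(np.dot(np.array(p.coords[0]) - soma, u)) for p in pts]
    sp2 = max(max(ts), 0.0)
    p1s = max(-min(ts), 0.0)
    if sp2 + p1s <= 0:
        return 0.0, bearing
    return abs(p1s - sp2) / (p1s + sp2), bearing
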