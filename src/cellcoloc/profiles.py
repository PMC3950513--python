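"""Line-scan profiles, peak calling, and time-lapse focus metrics.

Covers the semiquantitative side of the analysis: per-cell fluorescence
line scans along the long axis (max-normalized to 100%), a peak rule
that accepts a local maximum only when it rises at least 5 percentage
points above its flanking points of inflection, nearest-focus distance
tables between two focus channels, and the time-lapse quantities —
total path length moved along the long axis, the strict 2-px
colocalization call, and the cohesion time between replisome appearance
and origin-focus splitting.

Time-lapse synthesis lives here rather than in the image generator:
tracks are produced directly as (time, axial position) series, with a
programmed origin-splitting event, because none of the track metrics
need rendered images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CellMesh, project_long_axis

PEAK_MIN_RISE_PCT = 5.0
TIMELAPSE_THRESHOLD_PX = 2.0


@dataclass
class LineProfile:
    cell_id: int
    channel: str
    positions_px: np.ndarray  # bin centers along the long axis
    intensity_pct: np.ndarray  # max-normalized to 100 (0 everywhere if degenerate)
    degenerate: bool = False


@dataclass
class Peak:
    position_px: float
    height_pct: float
    bin_index: int


@dataclass
class FocusTrack:
    """One focus followed through a time-lapse: axial position vs. time."""

    track_id: int
    channel: str
    times_min: np.ndarray
    positions_um: np.ndarray
    cell_ids: np.ndarray | None = None
    parent_id: int | None = None  # set for daughters created by a split

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if len(self.times_min) != len(self.positions_um):
            raise ValueError("times and positions differ in length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("track times must be strictly increasing")


def line_profile(
    image: np.ndarray, mesh: CellMesh, n_bins: int = 20, channel: str = ""
) -> LineProfile:
    """Mean in-cell intensity binned by long-axis position, normalized so
    the maximum is 100%.  Scaling the image by any c > 0 leaves the
    profile unchanged.  An all-zero cell yields a flat profile flagged
    degenerate."""
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    proj = np.array([project_long_axis(mesh, p) for p in mesh.pixels])
    extent = mesh.axial_extent_px if mesh.axial_extent_px > 0 else 1.0
    idx = np.clip((proj / extent * n_bins).astype(int), 0, n_bins - 1)
    vals = image[mesh.pixels[:, 0], mesh.pixels[:, 1]].astype(float)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    positions = (np.arange(n_bins) + 0.5) / n_bins * extent
    peak = mean.max()
    if peak <= 0:
        return LineProfile(mesh.cell_id, channel, positions, np.zeros(n_bins), degenerate=True)
    return LineProfile(mesh.cell_id, channel, positions, mean / peak * 100.0)


def _flanking_inflections(y: np.ndarray, i: int) -> tuple[float, float]:
    """Values of the nearest points of inflection on each side of bin i.

    The curvature (discrete second difference) is negative at a peak;
    walking outward, the first bin where it turns positive is the point
    of inflection.  Where the curvature never turns before the profile
    end, the endpoint value is used."""
    d2 = np.diff(y, 2)  # d2[j-1] is the curvature at bin j
    left_val = y[0]
    for j in range(i - 1, 0, -1):
        if d2[j - 1] > 0:
            left_val = y[j]
            break
    right_val = y[-1]
    for j in range(i + 1, len(y) - 1):
        if d2[j - 1] > 0:
            right_val = y[j]
            break
    return left_val, right_val


def detect_peaks(profile: LineProfile, min_rise_pct: float = PEAK_MIN_RISE_PCT) -> list[Peak]:
    """Local maxima rising >= ``min_rise_pct`` percentage points above the
    HIGHER of their two flanking inflection values (the conservative
    reading of "above the neighboring points of inflection").  Profiles
    shorter than 5 bins carry too little curvature information and yield
    no peaks."""
    y = profile.intensity_pct
    if len(y) < 5 or profile.degenerate:
        return []
    peaks = []
    for i in range(1, len(y) - 1):
        if not (y[i] > y[i - 1] and y[i] >= y[i + 1]):
            continue
        left, right = _flanking_inflections(y, i)
        if y[i] - max(left, right) >= min_rise_pct:
            peaks.append(Peak(float(profile.positions_px[i]), float(y[i]), i))
    return peaks


def foci_pairwise_distances(
    foci_a: dict[int, np.ndarray], foci_b: dict[int, np.ndarray]
) -> dict[int, np.ndarray | None]:
    """Per cell: for each focus in A, distance (px) to the nearest focus in
    B; ``None`` where the cell has no B focus.  Histogram-ready."""
    out: dict[int, np.ndarray | None] = {}
    for cid in sorted(set(foci_a) | set(foci_b)):
        a = np.asarray(foci_a.get(cid, np.empty((0, 2))), float).reshape(-1, 2)
        b = np.asarray(foci_b.get(cid, np.empty((0, 2))), float).reshape(-1, 2)
        if len(b) == 0:
            out[cid] = None
        elif len(a) == 0:
            out[cid] = np.empty(0)
        else:
            out[cid] = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2).min(axis=1)
    return out


def track_total_distance(
    track: FocusTrack, t_start: float | None = None, t_end: float | None = None
) -> float:
    """Total path length (µm) along the long axis within [t_start, t_end]:
    the sum of |Δ position| over consecutive frames, not the net
    displacement.  Requires at least two frames in the window."""
    t, x = track.times_min, track.positions_um
    if t_start is not None or t_end is not None:
        lo = -np.inf if t_start is None else t_start
        hi = np.inf if t_end is None else t_end
        sel = (t >= lo) & (t <= hi)
        t, x = t[sel], x[sel]
    if len(t) < 2:
        raise ValueError("need >= 2 time points in the window")
    return float(np.abs(np.diff(x)).sum())


def family_total_distance(
    tracks: list[FocusTrack], t_start: float | None = None, t_end: float | None = None
) -> float:
    """Path length for a focus that may split: the parent's path plus each
    daughter's path from the split are summed (one-point daughters within
    the window contribute zero)."""
    total = 0.0
    for tr in tracks:
        try:
            total += track_total_distance(tr, t_start, t_end)
        except ValueError:
            continue
    return total


def coloc_call_timelapse(
    focus_a, focus_b, threshold_px: float = TIMELAPSE_THRESHOLD_PX
) -> bool:
    """Strict time-lapse colocalization: True iff the two focus centers are
    less than ``threshold_px`` apart (a distance exactly at the threshold
    is NOT colocalized)."""
    d = float(np.linalg.norm(np.asarray(focus_a, float) - np.asarray(focus_b, float)))
    return d < threshold_px


def cohesion_time(replisome_appearance_t: float, ori_split_t: float) -> float:
    """Minutes between replisome-focus appearance and origin-focus
    splitting; events must be ordered."""
    if ori_split_t < replisome_appearance_t:
        raise ValueError("ori split precedes replisome appearance")
    return float(ori_split_t - replisome_appearance_t)


# ---------------------------------------------------------------------------
# synthetic time-lapse series


@dataclass
class TimelapseFrame:
    t_min: float
    replisome_present: bool
    ori_positions_px: np.ndarray  # (k, 2)


def simulate_cohesion_series(
    lag_min: float,
    frame_interval_min: float,
    rng: np.random.Generator,
    n_frames: int = 30,
    appearance_frame: int = 2,
    jitter_px: float = 0.3,
    split_speed_px_per_min: float = 0.5,
) -> list[TimelapseFrame]:
    """Frame series with a replisome appearing at a programmed frame and a
    single origin focus splitting into two ``lag_min`` minutes later; the
    daughters separate at ``split_speed_px_per_min`` along the axis.
    Positions get isotropic Gaussian jitter per frame."""
    t_appear = appearance_frame * frame_interval_min
    t_split = t_appear + lag_min
    center = np.array([10.0, 20.0])
    frames = []
    for i in range(n_frames):
        t = i * frame_interval_min
        if t < t_split:
            ori = center[None, :] + rng.normal(0, jitter_px, size=(1, 2))
        else:
            sep = split_speed_px_per_min * (t - t_split) + 1.5  # visible at once
            offs = np.array([[0.0, -sep], [0.0, sep]])
            ori = center[None, :] + offs + rng.normal(0, jitter_px, size=(2, 2))
        frames.append(TimelapseFrame(t, t >= t_appear, ori))
    return frames


def detect_cohesion_events(
    frames: list[TimelapseFrame], split_sep_px: float = TIMELAPSE_THRESHOLD_PX
) -> tuple[float, float]:
    """First frame times of (replisome appearance, ori splitting).

    The split event is the first frame with two or more origin foci
    separated by more than ``split_sep_px``."""
    t_appear = next((f.t_min for f in frames if f.replisome_present), None)
    if t_appear is None:
        raise ValueError("no replisome appearance in series")
    t_split = None
    for f in frames:
        if len(f.ori_positions_px) >= 2:
            d = np.linalg.norm(f.ori_positions_px[0] - f.ori_positions_px[1])
            if d > split_sep_px:
                t_split = f.t_min
                break
    if t_split is None:
        raise ValueError("no ori splitting in series")
    return float(t_appear), float(t_split)


def link_tracks(
    frames_positions: list[np.ndarray],
    times_min: np.ndarray,
    max_jump_px: float = 5.0,
    channel: str = "",
) -> list[FocusTrack]:
    """Greedy nearest-neighbor frame linkage of axial focus positions.

    ``frames_positions`` holds, per frame, a 1-D array of axial positions
    (µm or px — units pass through).  A detection farther than
    ``max_jump_px`` from every open track starts a new track."""
    open_tracks: list[tuple[list[float], list[float]]] = []
    closed: list[tuple[list[float], list[float]]] = []
    for t, pos in zip(np.asarray(times_min, float), frames_positions):
        pos = list(np.asarray(pos, float).ravel())
        next_open: list[tuple[list[float], list[float]]] = []
        used = [False] * len(pos)
        # extend existing tracks, closest pair first
        pairs = sorted(
            (abs(tr[1][-1] - p), ti, pi)
            for ti, tr in enumerate(open_tracks)
            for pi, p in enumerate(pos)
        )
        taken_tr = set()
        for d, ti, pi in pairs:
            if d > max_jump_px or ti in taken_tr or used[pi]:
                continue
            open_tracks[ti][0].append(t)
            open_tracks[ti][1].append(pos[pi])
            taken_tr.add(ti)
            used[pi] = True
        for ti, tr in enumerate(open_tracks):
            (next_open if ti in taken_tr else closed).append(tr)
        for pi, p in enumerate(pos):
            if not used[pi]:
                next_open.append(([t], [p]))
        open_tracks = next_open
    closed.extend(open_tracks)
    return [
        FocusTrack(i + 1, channel, np.array(ts), np.array(xs))
        for i, (ts, xs) in enumerate(closed)
        if len(ts) >= 1
    ]
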