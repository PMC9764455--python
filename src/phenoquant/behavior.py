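"""Larval locomotion statistics from tracked trajectories.

Consumes planar trajectories (one per larva, uniformly sampled, e.g. from
a 30 Hz webcam tracker) and computes the per-animal statistics used to
compare genotypes: average crawling velocity, a moving/still
classification, and head-cast events — the stereotyped exploratory
behavior in which a larva pauses and swings its head, reorienting its
heading by a large angle.

Speed is path length over elapsed time (the per-frame displacement
convention of trackers), not net displacement over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "HeadCastEvent",
    "HeadCastParams",
    "average_velocity",
    "classify_moving",
    "detect_head_casts",
    "events_per_minute",
    "read_trajectories",
    "write_trajectories",
    "summarize_larvae",
]


@dataclass
class Trajectory:
    """Uniformly sampled planar path of one larva."""

    larva_id: str
    rate_hz: float
    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        if len(self.t_s) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        dt = np.diff(self.t_s)
        if np.any(dt <= 0) or np.max(np.abs(dt - 1.0 / self.rate_hz)) > 1e-6:
            raise ValueError("samples must be uniform at 1/rate_hz spacing")

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def steps(self) -> tuple[np.ndarray, np.ndarray]:
        return np.diff(self.x_mm), np.diff(self.y_mm)


@dataclass
class HeadCastEvent:
    time_s: float
    heading_change_deg: float
    window_s: float


@dataclass
class HeadCastParams:
    """Operational head-cast definition (the assay itself is scored by eye;
    these three thresholds operationalize it and are all exposed)."""

    angle_threshold_deg: float = 45.0
    window_s: float = 1.0
    max_speed_mm_s: float = 0.15
    rel_speed_fraction: float | None = 0.4
    smooth_s: float = 0.5
    min_pause_s: float = 0.8


def average_velocity(traj: Trajectory) -> float:
    """Path length (sum of per-step Euclidean displacements) / elapsed time,
    in mm/s."""
    dx, dy = traj.steps()
    return float(np.hypot(dx, dy).sum() / traj.duration_s)


def classify_moving(traj: Trajectory, min_net_displacement_mm: float = 1.0,
                    min_speed_mm_s: float = 0.02) -> bool:
    """A larva is a mover iff its net start-to-end displacement and its
    average velocity both exceed their thresholds."""
    net = float(np.hypot(traj.x_mm[-1] - traj.x_mm[0],
                         traj.y_mm[-1] - traj.y_mm[0]))
    return net >= min_net_displacement_mm and average_velocity(traj) >= min_speed_mm_s


def _moving_average(a: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return a
    kernel = np.ones(w)
    num = np.convolve(a, kernel, mode="same")
    den = np.convolve(np.ones_like(a), kernel, mode="same")
    return num / den


def detect_head_casts(traj: Trajectory,
                      params: HeadCastParams | None = None) -> list[HeadCastEvent]:
    """Detect pause-and-reorient (head-cast) events.

    Displacement vectors are smoothed with a ``smooth_s`` moving average to
    suppress tracking jitter; the heading is their direction (held through
    near-stationary stretches, then unwrapped). An event is a window of
    ``window_s`` over which the heading changes by at least
    ``angle_threshold_deg`` while the smoothed speed stays below the pause
    gate for at least ``min_pause_s`` consecutive frames in the window —
    the pause; the duration requirement rejects the momentary displacement
    cancellations that sharp noise turns produce. The gate is
    ``rel_speed_fraction`` of the larva's median smoothed speed, capped at
    ``max_speed_mm_s``, so pause detection is insensitive to how fast the
    animal crawls. Events are
    separated by at least ``window_s``; each is reported at the center of
    its best window with the observed heading change.

    Raises on a still trajectory — classify with :func:`classify_moving`
    first.
    """
    params = params or HeadCastParams()
    if not classify_moving(traj):
        raise ValueError("trajectory is still; run classify_moving first and "
                         "only score movers")
    dx, dy = traj.steps()
    w_smooth = max(1, int(round(params.smooth_s * traj.rate_hz)))
    sdx = _moving_average(dx, w_smooth)
    sdy = _moving_average(dy, w_smooth)
    speed = np.hypot(sdx, sdy) * traj.rate_hz

    step_len = np.hypot(sdx, sdy)
    eps = max(1e-12, 1e-3 * float(np.median(step_len[step_len > 0]))
              if np.any(step_len > 0) else 1e-12)
    heading = np.arctan2(sdy, sdx)
    # hold the last well-defined heading through near-zero steps
    defined = step_len > eps
    if not defined.any():
        return []
    idx = np.where(defined, np.arange(len(heading)), -1)
    idx = np.maximum.accumulate(idx)
    first = np.argmax(defined)
    idx[idx < 0] = first
    heading = np.unwrap(heading[idx])

    W = max(1, int(round(params.window_s * traj.rate_hz)))
    n = len(heading)
    if n <= W:
        return []
    dphi = heading[W:] - heading[:-W]
    thr = np.deg2rad(params.angle_threshold_deg)
    # pause condition: a run of >= min_pause_s consecutive low-speed frames
    # starting inside the window
    from scipy.ndimage import maximum_filter1d
    P = max(1, int(round(params.min_pause_s * traj.rate_hz)))
    # the pause gate scales with the larva's own crawling speed (capped at
    # max_speed_mm_s) so pause-dip durations are speed-independent
    gate = params.max_speed_mm_s
    if params.rel_speed_fraction is not None:
        gate = min(gate, params.rel_speed_fraction * float(np.median(speed)))
    low = (speed <= gate).astype(float)
    if len(low) >= P:
        sustained = np.convolve(low, np.ones(P), mode="valid") >= P - 0.5
    else:
        sustained = np.zeros(1, dtype=bool)
    sustained = np.pad(sustained, (0, len(low) - len(sustained)))
    win_pause = maximum_filter1d(sustained.astype(np.uint8), size=W + 1,
                                 mode="constant")[W // 2:W // 2 + n - W] > 0
    cand = (np.abs(dphi) >= thr) & win_pause

    events: list[HeadCastEvent] = []
    i = 0
    while i < len(cand):
        if not cand[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(cand) and cand[j + 1]:
            j += 1
        best = i + int(np.argmax(np.abs(dphi[i:j + 1])))
        center = min(best + W // 2, len(traj.t_s) - 1)
        events.append(HeadCastEvent(
            time_s=float(traj.t_s[center]),
            heading_change_deg=float(np.rad2deg(dphi[best])),
            window_s=params.window_s))
        i = j + W + 1   # refractory: events separated by >= window_s
    return events


def events_per_minute(events, duration_s: float) -> float:
    """Event rate in events per minute."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = len(events) if hasattr(events, "__len__") else int(events)
    return 60.0 * n / duration_s


# ---------------------------------------------------------------------------
# I/O and per-larva summaries

def read_trajectories(path) -> list[Trajectory]:
    """Read a trajectory CSV with columns larva_id, t_s, x_mm, y_mm."""
    df = pd.read_csv(path)
    return trajectories_from_frame(df)


def trajectories_from_frame(df: pd.DataFrame) -> list[Trajectory]:
    out = []
    for lid, g in df.groupby("larva_id", sort=True):
        g = g.sort_values("t_s")
        t = g["t_s"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t)))
        out.append(Trajectory(str(lid), rate, t, g["x_mm"].to_numpy(),
                              g["y_mm"].to_numpy()))
    return out


def write_trajectories(trajs: list[Trajectory], path) -> None:
    frames = [pd.DataFrame({"larva_id": tr.larva_id, "t_s": tr.t_s,
                            "x_mm": tr.x_mm, "y_mm": tr.y_mm})
              for tr in trajs]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def summarize_larvae(trajs: list[Trajectory],
                     head_cast_params: HeadCastParams | None = None,
                     min_net_displacement_mm: float = 1.0,
                     min_speed_mm_s: float = 0.02) -> pd.DataFrame:
    """Per-larva summary: speed, mover flag, head-cast count and rate.

    Head casts are only scored on movers; still larvae get NaN rates.
    """
    rows = []
    for tr in trajs:
        speed = average_velocity(tr)
        mover = classify_moving(tr, min_net_displacement_mm, min_speed_mm_s)
        if mover:
            ev = detect_head_casts(tr, head_cast_params)
            n_ev = len(ev)
            rate = events_per_minute(ev, tr.duration_s)
        else:
            n_ev, rate = 0, float("nan")
        rows.append({"larva_id": tr.larva_id, "speed_mm_s": speed,
                     "mover": mover, "n_head_casts": n_ev,
                     "head_casts_per_min": rate,
                     "duration_s": tr.duration_s})
    return pd.DataFrame(rows)
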