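"""Space-time traces of moving particles and per-trace kinematics.

A trace is an ordered space-time polyline for one particle in one channel,
in calibrated units (seconds, micrometres from the cell-body edge). Traces
come either from manual annotation (ingested tables) or from the automated
kymograph line follower. Kinematics follow the field's conventions:

* direction is called from the sign of the net displacement — a particle
  ending closer to the cell body than it started moved retrogradely, one
  ending farther moved anterogradely; near-zero net displacement is either
  excluded or assigned the direction of motion immediately before the end,
  depending on policy;
* run lengths are per-segment displacements between pauses and reversals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import Kymograph

__all__ = [
    "Trace",
    "TraceSet",
    "KinematicSummary",
    "is_moving",
    "ingest_traces",
    "detect_traces",
    "classify_direction",
    "segment_run_lengths",
    "MOVEMENT_NET_DISPLACEMENT_UM",
    "MOVEMENT_SPEED_UM_S",
    "DIRECTION_TIE_TOL_UM",
]

# Movement criterion defaults: a trace is "moving" if its net displacement
# reaches 1 um or it sustains >= 0.1 um/s for 3 frames; the direction call
# treats |net| below ~2 px as a tie. All configurable.
MOVEMENT_NET_DISPLACEMENT_UM = 1.0
MOVEMENT_SPEED_UM_S = 0.1
MOVEMENT_SUSTAINED_FRAMES = 3
DIRECTION_TIE_TOL_UM = 2 * 0.126


@dataclass
class Trace:
    """Ordered (time, position) anchors of one particle in one channel."""

    id: object
    channel: str
    t: np.ndarray  # seconds, strictly increasing
    x: np.ndarray  # um from the cell-body edge
    length_um: float | None = None  # physical vesicle extent, if known

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.x.shape:
            raise ValueError("trace anchors must be matching 1-D time/position arrays")
        if len(self.t) < 2:
            raise ValueError(f"trace {self.id!r} needs >= 2 anchors")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError(f"trace {self.id!r} has non-monotone time")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def net_displacement(self) -> float:
        return float(self.x[-1] - self.x[0])

    def position_at(self, times: np.ndarray) -> np.ndarray:
        """Linear interpolation of position at the given times (within span)."""
        return np.interp(times, self.t, self.x)


@dataclass
class TraceSet:
    """Traces from one kymograph, with a moving/stationary flag per trace."""

    traces: list[Trace]
    source: str = "manual"  # {"manual", "auto", "truth"}
    kymograph: Kymograph | None = None
    moving: dict = field(default_factory=dict)  # trace id -> bool

    def __post_init__(self) -> None:
        ids = [tr.id for tr in self.traces]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate trace id(s): {dup}")

    def moving_traces(self) -> list[Trace]:
        return [tr for tr in self.traces if self.moving.get(tr.id, False)]

    def __len__(self) -> int:
        return len(self.traces)

    def to_table(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {"trace_id": tr.id, "channel": tr.channel, "t_s": tr.t, "x_um": tr.x}
            )
            for tr in self.traces
        ]
        if not frames:
            return pd.DataFrame(columns=["trace_id", "channel", "t_s", "x_um"])
        return pd.concat(frames, ignore_index=True)


@dataclass
class KinematicSummary:
    """Per-trace kinematics: direction call, speed, runs, pauses."""

    trace_id: object
    direction: str  # {"anterograde", "retrograde", "excluded"}
    mean_speed_um_s: float
    run_lengths_um: list[float]
    mean_run_length_um: float
    pause_count: int
    pause_durations_s: list[float]
    net_displacement_um: float


def is_moving(
    trace: Trace,
    min_net_displacement_um: float = MOVEMENT_NET_DISPLACEMENT_UM,
    speed_threshold_um_s: float = MOVEMENT_SPEED_UM_S,
    sustained_frames: int = MOVEMENT_SUSTAINED_FRAMES,
    frame_interval_s: float | None = None,
) -> bool:
    """Movement criterion: net displacement >= threshold OR speed >=
    threshold sustained for the given number of frames."""
    if abs(trace.net_displacement) >= min_net_displacement_um:
        return True
    dt = np.diff(trace.t)
    dx = np.diff(trace.x)
    fi = frame_interval_s if frame_interval_s is not None else float(np.median(dt))
    fast = np.abs(dx) / dt >= speed_threshold_um_s
    need = sustained_frames * fi - 1e-9
    run = 0.0
    for ok, d in zip(fast, dt):
        run = run + d if ok else 0.0
        if run >= need:
            return True
    return False


# ---------------------------------------------------------------------------
# ingestion


def ingest_traces(
    table: pd.DataFrame,
    kymo: Kymograph,
    source: str = "manual",
    **movement_kwargs,
) -> TraceSet:
    """Build a TraceSet from an annotation table against a kymograph.

    The table must carry ``trace_id`` and ``channel`` plus either calibrated
    coordinates (``t_s``, ``x_um``) or pixel coordinates (``row``, ``col``),
    which are converted using the kymograph's calibration (rows get the
    channel's synchronization time offset added). Rows whose channel does
    not match the kymograph are dropped when the kymograph declares one.
    """
    table = pd.DataFrame(table)
    if "trace_id" not in table.columns:
        raise ValueError("trace table needs a 'trace_id' column")
    if "channel" in table.columns and kymo.channel is not None:
        matching = table[table["channel"] == kymo.channel]
        if len(matching):
            table = matching
    g = kymo.geometry
    if {"t_s", "x_um"}.issubset(table.columns):
        t_all = table["t_s"].to_numpy(dtype=float)
        x_all = table["x_um"].to_numpy(dtype=float)
    elif {"row", "col"}.issubset(table.columns):
        t_all = np.asarray(kymo.row_to_s(table["row"].to_numpy(dtype=float)))
        x_all = np.asarray(kymo.col_to_um(table["col"].to_numpy(dtype=float)))
    else:
        raise ValueError("trace table needs (t_s, x_um) or (row, col) columns")

    span_t = (kymo.n_rows - 1) * g.frame_interval + kymo.time_offset_s + 1e-9
    max_x = (g.n_px - kymo.origin) * g.pixel_size
    traces = []
    for tid, idx in table.groupby("trace_id", sort=True).groups.items():
        sub = table.loc[idx]
        channels = sub["channel"].unique() if "channel" in sub.columns else ["A"]
        if len(channels) > 1:
            raise ValueError(f"duplicate trace id {tid!r} appears in channels {list(channels)}")
        t = t_all[table.index.get_indexer(idx)]
        x = x_all[table.index.get_indexer(idx)]
        if np.any(t < -1e-9) or np.any(t > span_t):
            raise ValueError(f"trace {tid!r} has times outside the kymograph span")
        if np.any(x < -1.0) or np.any(x > max_x + 1.0):
            raise ValueError(f"trace {tid!r} has positions outside the neurite")
        traces.append(Trace(id=tid, channel=str(channels[0]), t=t, x=x))

    moving = {tr.id: is_moving(tr, frame_interval_s=g.frame_interval, **movement_kwargs)
              for tr in traces}
    return TraceSet(traces=traces, source=source, kymograph=kymo, moving=moving)


# ---------------------------------------------------------------------------
# automated detection


def _subpixel_peak(row: np.ndarray, p: int) -> float:
    """Parabolic sub-pixel refinement of a local maximum."""
    if p <= 0 or p >= len(row) - 1:
        return float(p)
    y0, y1, y2 = row[p - 1], row[p], row[p + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(p)
    return float(p + 0.5 * (y0 - y2) / denom)


def _track_vel(rows: list, cols: list, tail: int = 6) -> float:
    """Local velocity (columns per row) from the last few anchors."""
    if len(rows) < 2:
        return 0.0
    r = np.asarray(rows[-tail:], dtype=float)
    c = np.asarray(cols[-tail:], dtype=float)
    return float(np.polyfit(r, c, 1)[0])


def _head_vel(rows: list, cols: list, tail: int = 6) -> float:
    if len(rows) < 2:
        return 0.0
    r = np.asarray(rows[:tail], dtype=float)
    c = np.asarray(cols[:tail], dtype=float)
    return float(np.polyfit(r, c, 1)[0])


def _merge_fragments(tracks: list[dict], merge_gap_rows: int) -> list[dict]:
    """Close gaps between track fragments broken by occlusions.

    Candidate (end, start) fragment pairs are scored by how well the
    earlier fragment extrapolates onto the later one — both with its own
    velocity and with zero velocity (the particle may pause while occluded)
    — plus a velocity-consistency penalty, and joined greedily from the
    best score. The admissible positional error grows with the gap length.
    """
    max_overlap = 5  # rows; duplicate-track races briefly overlap in time
    tracks = sorted(tracks, key=lambda tk: tk["rows"][0])
    while True:
        cand = []
        for i, a in enumerate(tracks):
            for j, b in enumerate(tracks):
                if i == j:
                    continue
                gap = b["rows"][0] - a["rows"][-1]
                if not -max_overlap <= gap <= merge_gap_rows:
                    continue
                best = None
                # the last/first few anchors of a fragment are often corrupt
                # (peak stolen at the break), so try trimmed junctions too
                for tail_trim in (0, 3, 6):
                    keep = len(a["rows"]) - tail_trim
                    if keep < 4:
                        break
                    ra, ca = a["rows"][:keep], a["cols"][:keep]
                    va = _track_vel(ra, ca)
                    for head_trim in (0, 3):
                        skip = head_trim
                        while skip < len(b["rows"]) and b["rows"][skip] <= ra[-1]:
                            skip += 1
                        if len(b["rows"]) - skip < 4:
                            continue
                        rb, cb = b["rows"][skip:], b["cols"][skip:]
                        vb = _head_vel(rb, cb)
                        # opposite running directions: different particles
                        # (joining across a reversal is too ambiguous)
                        if abs(va) > 0.5 and abs(vb) > 0.5 and va * vb < 0:
                            continue
                        eff_gap = rb[0] - ra[-1]
                        if eff_gap > merge_gap_rows:
                            continue
                        tol = 4.0 + 0.35 * eff_gap
                        # the particle may keep moving, pause through the
                        # gap, or resume from a pause: take the best of
                        # forward/backward/zero-velocity extrapolation
                        d_fwd = abs(ca[-1] + va * eff_gap - cb[0])
                        d_back = abs(cb[0] - vb * eff_gap - ca[-1])
                        d_stay = abs(ca[-1] - cb[0])
                        d = min(d_fwd, d_back, d_stay)
                        if d > tol:
                            continue
                        cost = (
                            d
                            + min(abs(va - vb), abs(va), abs(vb))
                            + 0.3 * (tail_trim + head_trim)
                        )
                        if best is None or cost < best[0]:
                            best = (cost, keep, skip)
                if best is not None:
                    cand.append((best[0], i, j, best[1], best[2]))
        if not cand:
            return tracks
        cand.sort(key=lambda c: c[0])
        used = set()
        joins = []
        for _, i, j, keep, skip in cand:
            if i in used or j in used:
                continue
            used.update((i, j))
            joins.append((i, j, keep, skip))
        by_id = {idx: tk for idx, tk in enumerate(tracks)}
        for i, j, keep, skip in joins:
            a, b = by_id[i], by_id[j]
            a["rows"] = a["rows"][:keep] + b["rows"][skip:]
            a["cols"] = a["cols"][:keep] + b["cols"][skip:]
            del by_id[j]
        tracks = sorted(by_id.values(), key=lambda tk: tk["rows"][0])


def _absorb_duplicates(
    tracks: list[dict], min_overlap_rows: int = 10, tol_px: float = 3.0
) -> list[dict]:
    """Fuse tracks that follow the same particle simultaneously.

    A peak-stealing race can leave two tracks shadowing one particle over a
    long common span; two distinct particles cannot stay within a blob
    width of each other for long, so sustained positional agreement means
    one particle. Anchors are merged, keeping one position per row.
    """
    changed = True
    while changed:
        changed = False
        for i in range(len(tracks)):
            for j in range(i + 1, len(tracks)):
                a, b = tracks[i], tracks[j]
                amap = dict(zip(a["rows"], a["cols"]))
                common = [r for r in b["rows"] if r in amap]
                if len(common) < min_overlap_rows:
                    continue
                bmap = dict(zip(b["rows"], b["cols"]))
                gaps = [abs(amap[r] - bmap[r]) for r in common]
                if float(np.mean(gaps)) > tol_px:
                    continue
                merged = dict(bmap)
                merged.update(amap)  # prefer a's positions on shared rows
                rows = sorted(merged)
                tracks[i] = {
                    "rows": rows,
                    "cols": [merged[r] for r in rows],
                    "vel": a["vel"],
                    "misses": 0,
                }
                del tracks[j]
                changed = True
                break
            if changed:
                break
    return tracks


def detect_traces(
    kymo: Kymograph,
    k_sigma: float = 4.0,
    min_separation_px: int = 5,
    max_speed_um_s: float = 2.5,
    max_gap_rows: int = 4,
    merge_gap_rows: int = 25,
    min_anchors: int = 10,
    smooth_sigma_px: float = 1.5,
    position_smooth_rows: int = 5,
    subtract_stationary: bool = True,
    exclude_cell_body: bool = True,
    **movement_kwargs,
) -> TraceSet:
    """Extract particle traces from a kymograph by row-wise peak linking.

    The stationary image component (the per-column temporal median, which
    holds background plus vertical streaks from non-moving particles) is
    subtracted first, so moving particles are tracked without being
    occluded by stationary clusters; stationary structures are reported as
    constant-position traces found in the median profile and flagged
    stationary. Each residual row is lightly smoothed along the spatial
    axis, local maxima above a robust threshold are found and linked
    row-to-row with a constant-velocity/pause motion model; fragments
    broken by occlusions (trace crossings) are re-joined by
    velocity-consistent extrapolation, and the linked positions are
    smoothed with a centred moving average to suppress sub-pixel
    localization jitter. Tracks shorter than ``min_anchors`` rows are
    dropped; every emitted trace is flagged by the movement criterion.

    A flat or empty kymograph yields an empty TraceSet.
    """
    from scipy.ndimage import gaussian_filter1d

    g = kymo.geometry
    raw = kymo.data
    col_min = kymo.origin + 2 if exclude_cell_body else 0

    stationary_cols: list[float] = []
    if subtract_stationary:
        # a low per-column quantile holds background plus structures present
        # essentially all the time (true stationary clusters), while sparing
        # particles that merely dwell or oscillate in one zone
        baseline_profile = np.quantile(raw, 0.2, axis=0)
        data = np.clip(raw - baseline_profile[None, :], 0.0, None)
        # stationary structures appear as peaks of the baseline profile
        prof = gaussian_filter1d(baseline_profile, smooth_sigma_px)
        pbg = float(np.median(prof[col_min:]))
        pmad = float(np.median(np.abs(prof[col_min:] - pbg))) * 1.4826
        pthr = pbg + (k_sigma * pmad if pmad > 0 else 0.1 * max(prof.max() - pbg, 1e-12))
        if prof.max() > pbg:
            pk, _ = find_peaks(prof, height=pthr, distance=min_separation_px)
            stationary_cols = [_subpixel_peak(prof, p) for p in pk if p >= col_min]
    else:
        data = raw

    # noise scale from the raw image (the clipped residual is half zeros)
    raw_sub = raw[:, col_min:]
    bg_raw = float(np.median(raw_sub))
    mad = float(np.median(np.abs(raw_sub - bg_raw))) * 1.4826
    bg = float(np.median(data[:, col_min:]))
    if mad > 0:
        thr = bg + k_sigma * mad
        prominence = 3.0 * mad
    else:  # noise-free image: anything clearly above the flat background
        dyn = float(data[:, col_min:].max()) - bg
        if dyn <= 0 and not stationary_cols:  # perfectly flat: nothing to detect
            return TraceSet(traces=[], source="auto", kymograph=kymo, moving={})
        thr = bg + 0.1 * dyn if dyn > 0 else np.inf
        prominence = 0.05 * dyn if dyn > 0 else None
    gate_px = max_speed_um_s * g.frame_interval / g.pixel_size + 2.0
    tight_gate_px = 5.0
    stay_penalty_px = 1.5
    spawn_exclusion_px = 7.0

    smoothed = (
        gaussian_filter1d(data, smooth_sigma_px, axis=1) if smooth_sigma_px > 0 else data
    )
    active: list[dict] = []
    done: list[dict] = []
    for r in range(kymo.n_rows):
        row = smoothed[r]
        peaks, _ = find_peaks(
            row, height=thr, distance=min_separation_px, prominence=prominence
        )
        peaks = peaks[peaks >= col_min]
        cols = np.array([_subpixel_peak(row, p) for p in peaks])

        # greedy assignment of peaks to track predictions, nearest first;
        # established tracks trust their motion model — the particle either
        # keeps its velocity or pauses (tight gate on the better of the two
        # predictions) — while new tracks accept anything within the
        # speed-limited gate
        cand = []
        for ti, tk in enumerate(active):
            gap = r - tk["rows"][-1]
            pred_move = tk["cols"][-1] + tk["vel"] * gap
            pred_stay = tk["cols"][-1]
            established = len(tk["rows"]) >= 3
            gate = tight_gate_px if established else gate_px
            for pj, c in enumerate(cols):
                # the particle either keeps its velocity or has just paused;
                # the pause hypothesis carries a penalty so it cannot steal
                # a crossing particle's peak from the true continuation
                d = (
                    min(abs(c - pred_move), abs(c - pred_stay) + stay_penalty_px)
                    if established
                    else abs(c - pred_stay)
                )
                if d <= gate:
                    cand.append((d, ti, pj))
        cand.sort(key=lambda item: item[0])
        used_t, used_p = set(), set()
        for d, ti, pj in cand:
            if ti in used_t or pj in used_p:
                continue
            used_t.add(ti)
            used_p.add(pj)
            tk = active[ti]
            tk["rows"].append(r)
            tk["cols"].append(float(cols[pj]))
            tk["vel"] = _track_vel(tk["rows"], tk["cols"])
            tk["misses"] = 0
        survivors = []
        for ti, tk in enumerate(active):
            if ti in used_t:
                survivors.append(tk)
            else:
                tk["misses"] += 1
                if tk["misses"] > max_gap_rows:
                    done.append(tk)
                else:
                    survivors.append(tk)
        active = survivors
        # spawn tracks from leftover peaks, but never right next to an
        # existing track (duplicate tracks on one wide blob degrade linking)
        occupied = np.array(
            [tk["cols"][-1] + tk["vel"] * (r - tk["rows"][-1]) for tk in active]
        )
        for pj, c in enumerate(cols):
            if pj in used_p:
                continue
            if occupied.size and np.min(np.abs(occupied - c)) < spawn_exclusion_px:
                continue
            active.append({"rows": [r], "cols": [float(c)], "vel": 0.0, "misses": 0})
    done.extend(active)

    done = _absorb_duplicates([tk for tk in done if len(tk["rows"]) >= 3])
    done = _merge_fragments(done, merge_gap_rows=merge_gap_rows)
    done = _absorb_duplicates(done)

    traces = []
    for c in stationary_cols:  # constant-position traces spanning the kymograph
        i = len(traces)
        traces.append(
            Trace(
                id=i,
                channel=kymo.channel,
                t=np.asarray(kymo.row_to_s(np.array([0.0, kymo.n_rows - 1.0]))),
                x=np.full(2, float(kymo.col_to_um(c))),
            )
        )
    n_stationary = len(traces)
    for i, tk in enumerate(tk for tk in done if len(tk["rows"]) >= min_anchors):
        rows = np.asarray(tk["rows"], dtype=float)
        cols = np.asarray(tk["cols"], dtype=float)
        if position_smooth_rows > 1:
            w = min(position_smooth_rows, len(cols))
            kernel = np.ones(w) / w
            mid = np.convolve(cols, kernel, mode="same")
            # fix the edge bias of 'same' convolution with partial windows
            counts = np.convolve(np.ones_like(cols), kernel, mode="same")
            cols = mid / counts
        traces.append(
            Trace(
                id=n_stationary + i,
                channel=kymo.channel,
                t=np.asarray(kymo.row_to_s(rows)),
                x=np.asarray(kymo.col_to_um(cols)),
            )
        )
    moving = {tr.id: is_moving(tr, frame_interval_s=g.frame_interval, **movement_kwargs)
              for tr in traces}
    return TraceSet(traces=traces, source="auto", kymograph=kymo, moving=moving)


# ---------------------------------------------------------------------------
# kinematics


def classify_direction(
    trace: Trace,
    tie_tol_um: float = DIRECTION_TIE_TOL_UM,
    tie_policy: str = "exclude",
    check_moving: bool = True,
) -> str:
    """Call a moving trace's direction from the sign of its net displacement.

    A final position farther from the cell body than the start is
    anterograde, closer is retrograde. |net displacement| below
    ``tie_tol_um`` is a tie: excluded from analysis by default, or assigned
    the direction of motion immediately before the trace end when
    ``tie_policy='last'``.
    """
    if tie_policy not in ("exclude", "last"):
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    if check_moving and not is_moving(trace):
        raise ValueError(
            f"trace {trace.id!r} is stationary; filter with the movement criterion first"
        )
    net = trace.net_displacement
    if abs(net) >= tie_tol_um:
        return "anterograde" if net > 0 else "retrograde"
    if tie_policy == "exclude":
        return "excluded"
    dx = np.diff(trace.x)
    nonzero = np.nonzero(dx)[0]
    if len(nonzero) == 0:
        return "excluded"
    return "anterograde" if dx[nonzero[-1]] > 0 else "retrograde"


def segment_run_lengths(
    trace: Trace,
    pause_speed_threshold_um_s: float = 0.05,
    min_pause_frames: int = 2,
    frame_interval_s: float | None = None,
    tie_tol_um: float = DIRECTION_TIE_TOL_UM,
    tie_policy: str = "exclude",
) -> KinematicSummary:
    """Partition a trace at pauses and reversals and measure segment runs.

    A pause is a maximal block of inter-anchor intervals slower than
    ``pause_speed_threshold_um_s`` lasting at least ``min_pause_frames``
    frames. The remaining intervals form runs, additionally split where the
    direction of motion reverses; each run's length is the magnitude of its
    displacement. Pause segments contribute no run length.
    """
    if pause_speed_threshold_um_s <= 0:
        raise ValueError("pause_speed_threshold_um_s must be positive")
    dt = np.diff(trace.t)
    dx = np.diff(trace.x)
    fi = frame_interval_s if frame_interval_s is not None else float(np.median(dt))
    min_pause_s = min_pause_frames * fi - 1e-9
    slow = np.abs(dx) / dt < pause_speed_threshold_um_s

    n = len(dx)
    is_pause = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if slow[i]:
            j = i
            while j < n and slow[j]:
                j += 1
            if dt[i:j].sum() >= min_pause_s:
                is_pause[i:j] = True
            i = j
        else:
            i += 1

    run_lengths: list[float] = []
    pause_durations: list[float] = []
    run_time = 0.0
    run_path = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and is_pause[j] == is_pause[i]:
            j += 1
        block = slice(i, j)
        if is_pause[i]:
            pause_durations.append(float(dt[block].sum()))
        else:
            # split the block at reversals of the direction of motion
            seg_start = i
            prev_sign = 0
            for k in range(i, j):
                s = int(np.sign(dx[k]))
                if s != 0 and prev_sign != 0 and s != prev_sign:
                    run_lengths.append(abs(float(dx[seg_start:k].sum())))
                    seg_start = k
                if s != 0:
                    prev_sign = s
            run_lengths.append(abs(float(dx[seg_start:j].sum())))
            run_time += float(dt[block].sum())
            run_path += float(np.abs(dx[block]).sum())
        i = j

    mean_speed = run_path / run_time if run_time > 0 else 0.0
    return KinematicSummary(
        trace_id=trace.id,
        direction=classify_direction(
            trace, tie_tol_um=tie_tol_um, tie_policy=tie_policy, check_moving=False
        ),
        mean_speed_um_s=mean_speed,
        run_lengths_um=run_lengths,
        mean_run_length_um=float(np.mean(run_lengths)) if run_lengths else 0.0,
        pause_count=len(pause_durations),
        pause_durations_s=pause_durations,
        net_displacement_um=trace.net_displacement,
    )
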