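"""Static and per-kymograph scalar quantifiers.

Penetrance and dendrite extent score how far a fluorescent marker reaches
along a neurite; puncta metrics score discrete spots in cell bodies by
size and punctum/cytosol intensity ratio; kymograph quantifiers measure
vesicle length (FWHM of the sloped line along the spatial axis inside
random non-overlapping ROIs), anterograde flux normalized to a 20 um x 10 s
window, background-subtracted intensity of moving trajectories, and
microtubule polarity from unidirectional plus-end comet counts.

All quantifiers can emit long-format QuantRecord rows
(id, genotype, metric, value, units) for the statistics stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Kymograph
from .tracing import Trace, TraceSet, classify_direction

__all__ = [
    "NeuriteProfile",
    "PunctumRecord",
    "QuantRecord",
    "signal_extent",
    "penetrance",
    "dendrite_extent",
    "puncta_density",
    "puncta_metrics",
    "vesicle_lengths",
    "anterograde_flux",
    "moving_trajectory_intensity",
    "microtubule_polarity",
    "records_to_table",
]

UNITS_VOCABULARY = (
    "percent", "um", "per_10um", "ratio", "per_20um_per_10s", "intensity", "fraction", "count",
)


@dataclass
class NeuriteProfile:
    """1-D intensity profile along a neurite or dendrite.

    ``background`` is (mean, sd) of a signal-free reference region; when
    absent it is estimated from the dimmest decile of the profile.
    ``dendrite_span`` marks (base_um, end_um) when the profile covers a
    dendrite plus some distal background.
    """

    distance_um: np.ndarray
    intensity: np.ndarray
    dendrite_span: tuple[float, float] | None = None
    background: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.distance_um.shape != self.intensity.shape:
            raise ValueError("distance and intensity arrays must match")
        if np.any(self.distance_um < 0) or np.any(np.diff(self.distance_um) <= 0):
            raise ValueError("distances must be non-negative and increasing")


@dataclass(frozen=True)
class PunctumRecord:
    centroid: tuple[float, float]
    area_px: int
    area_um2: float
    mean_intensity: float
    cytosol_intensity: float
    ratio: float


@dataclass(frozen=True)
class QuantRecord:
    id: str
    genotype: str
    metric: str
    value: float
    units: str

    def __post_init__(self) -> None:
        if self.units not in UNITS_VOCABULARY:
            raise ValueError(f"units {self.units!r} not in vocabulary {UNITS_VOCABULARY}")


def records_to_table(records: list[QuantRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records],
                      columns=["id", "genotype", "metric", "value", "units"])
    if df.duplicated(subset=["id", "metric"]).any():
        raise ValueError("one value per (id, metric) is required")
    return df


# ---------------------------------------------------------------------------
# profile quantifiers


def _background_stats(profile: NeuriteProfile) -> tuple[float, float]:
    if profile.background is not None:
        return profile.background
    lo = np.quantile(profile.intensity, 0.10)
    dim = profile.intensity[profile.intensity <= lo]
    return float(dim.mean()), float(max(dim.std(), 1e-9))


def signal_extent(
    profile: NeuriteProfile, k_sigma: float = 3.0, min_run: int = 3,
    threshold: float | None = None,
) -> float:
    """Furthest distance (um) with above-threshold signal.

    Presence requires at least ``min_run`` consecutive samples above
    background mean + ``k_sigma`` SD, so a single noise excursion far from
    the cell body cannot masquerade as signal. Returns 0 when nothing
    crosses the threshold.
    """
    if threshold is None:
        bg_mean, bg_sd = _background_stats(profile)
        threshold = bg_mean + k_sigma * bg_sd
    above = profile.intensity > threshold
    if min_run > 1:
        kernel = np.ones(min_run, dtype=int)
        runs = np.convolve(above.astype(int), kernel, mode="valid") == min_run
        if not runs.any():
            return 0.0
        last_start = int(np.nonzero(runs)[0][-1])
        return float(profile.distance_um[last_start + min_run - 1])
    if not above.any():
        return 0.0
    return float(profile.distance_um[np.nonzero(above)[0][-1]])


def penetrance(
    profiles: list[NeuriteProfile], threshold_distance_um: float, **extent_kwargs
) -> float:
    """Percent of animals with signal at or beyond the distance threshold.

    Typical thresholds are 25, 50 or 150 um from the cell body.
    """
    if not profiles:
        raise ValueError("penetrance needs at least one profile")
    hits = sum(
        signal_extent(p, **extent_kwargs) >= threshold_distance_um for p in profiles
    )
    return 100.0 * hits / len(profiles)


def dendrite_extent(profile: NeuriteProfile, **extent_kwargs) -> float:
    """Percent of the dendrite length showing signal.

    100 x (distance from the dendrite base through the most distal
    above-threshold signal) / (total dendrite length).
    """
    if profile.dendrite_span is None:
        raise ValueError("profile must annotate the dendrite span (base_um, end_um)")
    base, end = profile.dendrite_span
    if end - base <= 0:
        raise ValueError("zero-length dendrite")
    extent = signal_extent(profile, **extent_kwargs)
    # signal running through the most distal sampled point inside the
    # dendrite covers the dendrite to its end (the grid never lands
    # exactly on the anatomical boundary)
    inside = profile.distance_um[profile.distance_um <= end]
    if len(inside) and extent >= inside[-1] - 1e-9:
        extent = end
    extent = min(max(extent - base, 0.0), end - base)
    return 100.0 * extent / (end - base)


def puncta_density(n_puncta: int, roi_length_um: float) -> float:
    """Puncta per 10 um: (count / ROI length) x 10."""
    if roi_length_um <= 0:
        raise ValueError("roi_length_um must be positive")
    if n_puncta < 0:
        raise ValueError("n_puncta must be non-negative")
    return n_puncta / roi_length_um * 10.0


# ---------------------------------------------------------------------------
# cell-body puncta


def puncta_metrics(
    image: np.ndarray,
    cell_body_mask: np.ndarray,
    pixel_size_um: float = 0.126,
    k_sigma: float = 4.0,
    min_area_px: int = 3,
    annulus_px: tuple[int, int] = (2, 4),
) -> tuple[list[PunctumRecord], dict]:
    """Detect puncta in a cell body and score size and intensity ratio.

    Puncta are connected regions above background (median within the mask)
    + ``k_sigma`` robust SDs, at least ``min_area_px`` pixels. Each
    punctum's cytosol reference is the median intensity in an annulus 2-4
    px beyond its boundary, inside the mask and outside every punctum; the
    per-cell ratio is the mean punctum/cytosol ratio.
    """
    image = np.asarray(image, dtype=float)
    cell_body_mask = np.asarray(cell_body_mask, dtype=bool)
    if image.shape != cell_body_mask.shape or image.ndim != 2:
        raise ValueError("image and mask must be matching 2-D arrays")
    if not cell_body_mask.any():
        raise ValueError("empty cell-body mask")

    inside = image[cell_body_mask]
    bg = float(np.median(inside))
    mad = float(np.median(np.abs(inside - bg))) * 1.4826
    sd = mad if mad > 0 else float(inside.std())
    thresh = bg + k_sigma * sd

    blobs = (image > thresh) & cell_body_mask
    labels, n = ndimage.label(blobs)
    any_punctum = labels > 0

    records: list[PunctumRecord] = []
    inner, outer = annulus_px
    for lab in range(1, n + 1):
        region = labels == lab
        area = int(region.sum())
        if area < min_area_px:
            continue
        cy, cx = ndimage.center_of_mass(region)
        mean_int = float(image[region].mean())
        ring = (
            ndimage.binary_dilation(region, iterations=outer)
            & ~ndimage.binary_dilation(region, iterations=inner)
            & cell_body_mask
            & ~any_punctum
        )
        cyt = float(np.median(image[ring])) if ring.any() else bg
        records.append(
            PunctumRecord(
                centroid=(float(cy), float(cx)),
                area_px=area,
                area_um2=area * pixel_size_um**2,
                mean_intensity=mean_int,
                cytosol_intensity=cyt,
                ratio=mean_int / cyt,
            )
        )
    summary = {
        "count": len(records),
        "mean_area_um2": float(np.mean([r.area_um2 for r in records])) if records else 0.0,
        "mean_ratio": float(np.mean([r.ratio for r in records])) if records else float("nan"),
    }
    return records, summary


# ---------------------------------------------------------------------------
# kymograph quantifiers


def _fwhm_um(row: np.ndarray, center_col: float, pixel_size: float,
             window_px: int, bg: float) -> float | None:
    """Full width at half maximum around a column, linearly interpolated."""
    n = len(row)
    c = int(round(center_col))
    lo = max(c - window_px, 0)
    hi = min(c + window_px + 1, n)
    seg = row[lo:hi] - bg
    if len(seg) < 3:
        return None
    p = int(np.argmax(seg))
    peak = seg[p]
    if peak <= 0:
        return None
    half = peak / 2.0
    left = None
    for i in range(p, 0, -1):
        if seg[i - 1] <= half <= seg[i]:
            frac = (seg[i] - half) / (seg[i] - seg[i - 1])
            left = i - frac
            break
    right = None
    for i in range(p, len(seg) - 1):
        if seg[i] >= half >= seg[i + 1]:
            frac = (seg[i] - half) / (seg[i] - seg[i + 1])
            right = i + frac
            break
    if left is None or right is None:
        return None
    return (right - left) * pixel_size


def vesicle_lengths(
    kymo: Kymograph,
    traces: TraceSet,
    n_rois: int = 10,
    roi_size_px: tuple[int, int] = (10, 10),
    seed: int = 0,
    max_rows_per_trace: int = 5,
    isolation_px: float | None = None,
) -> list[float]:
    """Vesicle lengths (um) sampled inside random non-overlapping ROIs.

    Axis-aligned ROIs are drawn uniformly at random (seeded); an ROI
    overlapping a previously accepted one is rejected. Within each ROI,
    every moving trace crossing it is measured — unless another trace
    (moving or stationary) also passes through the ROI, in which case the
    ROI yields nothing for the crossing pair — by the full width at half
    maximum of the intensity profile along the spatial axis, averaged over
    up to ``max_rows_per_trace`` rows.
    """
    g = kymo.geometry
    roi_h, roi_w = roi_size_px
    if roi_h > kymo.n_rows or roi_w > g.n_px:
        raise ValueError("roi_size_px larger than the kymograph")
    rng = np.random.default_rng(seed)
    if isolation_px is None:
        isolation_px = roi_w

    rois: list[tuple[int, int]] = []  # top row, left col
    attempts = 0
    while len(rois) < n_rois and attempts < 200 * n_rois:
        attempts += 1
        r0 = int(rng.integers(0, kymo.n_rows - roi_h + 1))
        c0 = int(rng.integers(kymo.origin, g.n_px - roi_w + 1))
        if any(abs(r0 - r) < roi_h and abs(c0 - c) < roi_w for r, c in rois):
            continue
        rois.append((r0, c0))

    bg = float(np.median(kymo.data))
    lengths: list[float] = []
    all_traces = traces.traces
    for r0, c0 in rois:
        rows = np.arange(r0, r0 + roi_h)
        t_rows = np.asarray(kymo.row_to_s(rows))
        # column of each trace at each ROI row (NaN outside the trace span)
        cols_at = {}
        for tr in all_traces:
            inside_t = (t_rows >= tr.t[0]) & (t_rows <= tr.t[-1])
            col = np.full(roi_h, np.nan)
            col[inside_t] = np.asarray(kymo.um_to_col(tr.position_at(t_rows[inside_t])))
            in_roi = inside_t & (col >= c0) & (col < c0 + roi_w)
            cols_at[tr.id] = (col, in_roi)
        for tr in all_traces:
            if not traces.moving.get(tr.id, False):
                continue
            col, in_roi = cols_at[tr.id]
            if not in_roi.any():
                continue
            # reject when any other trace comes near this one inside the ROI
            clean = in_roi.copy()
            for other in all_traces:
                if other.id == tr.id:
                    continue
                ocol, _ = cols_at[other.id]
                near = np.abs(ocol - col) < isolation_px
                clean &= ~(near & ~np.isnan(ocol))
            if not clean.any():
                continue
            use = np.nonzero(clean)[0]
            mid = use[np.argsort(np.abs(use - (roi_h - 1) / 2))][:max_rows_per_trace]
            vals = []
            for i in mid:
                w = _fwhm_um(kymo.data[rows[i]], col[i], g.pixel_size,
                             window_px=roi_w, bg=bg)
                if w is not None:
                    vals.append(w)
            if vals:
                lengths.append(float(np.mean(vals)))
    return lengths


def anterograde_flux(
    traces: TraceSet, kymo: Kymograph, tie_policy: str = "exclude"
) -> float:
    """Anterograde trace count normalized to a 20 um x 10 s window."""
    g = kymo.geometry
    length_um = (g.n_px - kymo.origin) * g.pixel_size
    duration_s = kymo.n_rows * g.frame_interval
    if length_um <= 0 or duration_s <= 0:
        raise ValueError("degenerate observation window")
    n_antero = sum(
        classify_direction(tr, tie_policy=tie_policy, check_moving=False) == "anterograde"
        for tr in traces.moving_traces()
    )
    return n_antero * (20.0 / length_um) * (10.0 / duration_s)


def moving_trajectory_intensity(
    kymo: Kymograph,
    trace: Trace,
    shift_rows: int | None = None,
    pause_speed_threshold_um_s: float = 0.05,
    min_pause_frames: int = 2,
) -> float:
    """Background-subtracted mean intensity along a moving trajectory.

    The mean intensity sampled along the trace's non-pause anchors minus
    the mean at the same spatial positions ``shift_rows`` rows earlier
    (time progresses vertically downward, so earlier means above); the
    shift defaults to round(1 s / frame interval) — 3 rows at 3 fps.
    Pause anchors are excluded from both means.
    """
    g = kymo.geometry
    if shift_rows is None:
        shift_rows = int(round(1.0 / g.frame_interval))
    # pause mask on anchors (an anchor is paused when both of its flanking
    # intervals are inside a pause), same pause rule as segment_run_lengths

    dt = np.diff(trace.t)
    dx = np.diff(trace.x)
    slow = np.abs(dx) / dt < pause_speed_threshold_um_s
    min_pause_s = min_pause_frames * g.frame_interval - 1e-9
    n = len(dx)
    pause_int = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if slow[i]:
            j = i
            while j < n and slow[j]:
                j += 1
            if dt[i:j].sum() >= min_pause_s:
                pause_int[i:j] = True
            i = j
        else:
            i += 1
    anchor_paused = np.zeros(len(trace.t), dtype=bool)
    anchor_paused[1:-1] = pause_int[:-1] & pause_int[1:]
    anchor_paused[0] = pause_int[0] if n else False
    anchor_paused[-1] = pause_int[-1] if n else False

    rows = np.rint((trace.t - kymo.time_offset_s) / g.frame_interval).astype(int)
    cols = np.rint(np.asarray(kymo.um_to_col(trace.x))).astype(int)
    ok = (
        ~anchor_paused
        & (rows >= shift_rows)
        & (rows < kymo.n_rows)
        & (cols >= 0)
        & (cols < g.n_px)
    )
    if not ok.any():
        raise ValueError(
            f"trace {trace.id!r} has no usable anchors at least {shift_rows} rows below the top"
        )
    on_trace = kymo.data[rows[ok], cols[ok]]
    above = kymo.data[rows[ok] - shift_rows, cols[ok]]
    return float(on_trace.mean() - above.mean())


def microtubule_polarity(
    traces: TraceSet, tie_policy: str = "exclude"
) -> tuple[float, float, int]:
    """Fractions of anterograde and retrograde comets (plus excluded count).

    Plus-end comets are unidirectional, so the excluded class should be
    empty; any exclusions are reported rather than silently dropped.
    """
    calls = [
        classify_direction(tr, tie_policy=tie_policy, check_moving=False)
        for tr in traces.moving_traces()
    ]
    n_a = calls.count("anterograde")
    n_r = calls.count("retrograde")
    n_x = calls.count("excluded")
    if n_a + n_r == 0:
        raise ValueError("no direction-called comets")
    return n_a / (n_a + n_r), n_r / (n_a + n_r), n_x
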