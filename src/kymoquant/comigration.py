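"""Dual-channel co-migration scoring of moving vesicle traces.

Moving traces from two synchronized channels are paired when they follow
the same space-time path; the resulting mutually exclusive counts
(A-only, B-only, both) feed the two standard summary statistics:

    % co-migrating vesicles = 100 * n_both / (n_A_only + n_B_only + n_both)
    fraction of A co-migrating with B = n_both / (n_A_only + n_both)

and symmetrically for B. Stationary structures never enter the counts —
only moving vesicles are scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Movie
from .imaging import build_kymograph, synchronize
from .tracing import Trace, TraceSet, ingest_traces, detect_traces

__all__ = [
    "ComigrationCounts",
    "ComigrationResult",
    "match_traces",
    "categorize",
    "comigration_fractions",
    "run_comigration",
]


@dataclass(frozen=True)
class ComigrationCounts:
    """Mutually exclusive moving-vesicle counts."""

    n_a_only: int
    n_b_only: int
    n_both: int

    def __post_init__(self) -> None:
        if min(self.n_a_only, self.n_b_only, self.n_both) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_a_only + self.n_b_only + self.n_both


@dataclass
class ComigrationResult:
    counts: ComigrationCounts
    percent_comigrating: float  # NaN when total == 0
    fraction_a_with_b: float  # NaN when no A vesicles
    fraction_b_with_a: float  # NaN when no B vesicles
    undefined: list[str] = field(default_factory=list)
    pairs: list[tuple] = field(default_factory=list)  # (A trace id, B trace id)

    def to_report(self) -> str:
        c = self.counts
        lines = [
            "co-migration result",
            f"  A-only moving vesicles : {c.n_a_only}",
            f"  B-only moving vesicles : {c.n_b_only}",
            f"  co-migrating (both)    : {c.n_both}",
            f"  total moving vesicles  : {c.total}",
            f"  % co-migrating         : {self.percent_comigrating:.2f}",
            f"  fraction A with B      : {self.fraction_a_with_b:.4f}",
            f"  fraction B with A      : {self.fraction_b_with_a:.4f}",
        ]
        if self.undefined:
            lines.append(f"  undefined fields       : {', '.join(self.undefined)}")
        return "\n".join(lines)


def _pair_match(
    a: Trace,
    b: Trace,
    tol_um: float,
    min_overlap_fraction: float,
    dt_s: float,
) -> tuple[float, float] | None:
    """Score one candidate pair; None if it fails the matching rules.

    Returns (overlap_s, mean_gap_um) for ranking. A pair matches when over
    their common time span (at least ``min_overlap_fraction`` of the
    shorter trace's duration) the spatial gap stays within ``tol_um`` at
    every compared time, or within half the difference of the two vesicle
    extents (the smaller vesicle riding contained inside the larger one —
    sub-domain co-transport on an identical path).
    """
    t0 = max(a.t[0], b.t[0])
    t1 = min(a.t[-1], b.t[-1])
    overlap = t1 - t0
    shorter = min(a.duration, b.duration)
    if shorter <= 0 or overlap < min_overlap_fraction * shorter:
        return None
    n = max(int(math.ceil(overlap / max(dt_s, 1e-9))) + 1, 2)
    times = np.linspace(t0, t1, n)
    gap = np.abs(a.position_at(times) - b.position_at(times))
    tol = tol_um
    if a.length_um is not None and b.length_um is not None:
        containment = max(abs(a.length_um - b.length_um) / 2.0, 0.0)
        tol = max(tol_um, containment)
    if gap.max() <= tol:
        return float(overlap), float(gap.mean())
    return None


def match_traces(
    set_a: TraceSet,
    set_b: TraceSet,
    tol_um: float = 0.5,
    min_overlap_fraction: float = 0.8,
) -> list[tuple]:
    """One-to-one matching of moving traces across synchronized channels.

    Candidates are scored by temporal overlap (ties broken by smaller mean
    gap, then lexicographically by trace ids) and assigned greedily so that
    a trace certifies at most one partner.
    """
    ka, kb = set_a.kymograph, set_b.kymograph
    dt = 1.0 / 3.0
    if ka is not None and kb is not None:
        ga, gb = ka.geometry, kb.geometry
        if not (
            np.isclose(ga.pixel_size, gb.pixel_size)
            and np.isclose(ga.frame_interval, gb.frame_interval)
        ):
            raise ValueError("trace sets come from kymographs with mismatched calibration")
        if ka.sync_group is None or ka.sync_group != kb.sync_group:
            raise ValueError("kymographs were not synchronized together; call synchronize() first")
        dt = ga.frame_interval
    elif (ka is None) != (kb is None):
        raise ValueError("both trace sets must reference kymographs, or neither")

    mov_a = set_a.moving_traces()
    mov_b = set_b.moving_traces()
    cand = []
    for a in mov_a:
        for b in mov_b:
            scored = _pair_match(a, b, tol_um, min_overlap_fraction, dt)
            if scored is not None:
                overlap, mean_gap = scored
                cand.append((-overlap, mean_gap, str(a.id), str(b.id), a.id, b.id))
    cand.sort()
    used_a, used_b = set(), set()
    pairs = []
    for _, _, _, _, ida, idb in cand:
        if ida in used_a or idb in used_b:
            continue
        used_a.add(ida)
        used_b.add(idb)
        pairs.append((ida, idb))
    return pairs


def categorize(set_a: TraceSet, set_b: TraceSet, pairs: list[tuple]) -> ComigrationCounts:
    """Tally the mutually exclusive categories from a matching."""
    n_both = len(pairs)
    n_a = len(set_a.moving_traces())
    n_b = len(set_b.moving_traces())
    return ComigrationCounts(n_a_only=n_a - n_both, n_b_only=n_b - n_both, n_both=n_both)


def comigration_fractions(
    counts: ComigrationCounts, pairs: list[tuple] | None = None
) -> ComigrationResult:
    """Apply the two printed summary formulas to the category counts."""
    undefined = []
    total = counts.total
    if total >= 1:
        percent = 100.0 * counts.n_both / total
    else:
        percent = float("nan")
        undefined.append("percent_comigrating")
    den_a = counts.n_a_only + counts.n_both
    if den_a >= 1:
        frac_a = counts.n_both / den_a
    else:
        frac_a = float("nan")
        undefined.append("fraction_a_with_b")
    den_b = counts.n_b_only + counts.n_both
    if den_b >= 1:
        frac_b = counts.n_both / den_b
    else:
        frac_b = float("nan")
        undefined.append("fraction_b_with_a")
    return ComigrationResult(
        counts=counts,
        percent_comigrating=percent,
        fraction_a_with_b=frac_a,
        fraction_b_with_a=frac_b,
        undefined=undefined,
        pairs=list(pairs) if pairs else [],
    )


def run_comigration(
    movie_a: Movie,
    movie_b: Movie,
    traces_a: pd.DataFrame | None = None,
    traces_b: pd.DataFrame | None = None,
    mode: str = "simultaneous",
    projection: str = "mean",
    tol_um: float = 0.5,
    min_overlap_fraction: float = 0.8,
    detect_kwargs: dict | None = None,
) -> tuple[ComigrationResult, pd.DataFrame]:
    """End-to-end co-migration analysis of a co-registered channel pair.

    Builds both kymographs with an identical projection, synchronizes them,
    obtains traces (ingesting the provided annotation tables, otherwise by
    automated detection), matches moving traces and applies the formulas.
    Returns the result plus a per-trace provenance table with each moving
    trace's category.
    """
    kymo_a = build_kymograph(movie_a, projection)
    kymo_b = build_kymograph(movie_b, projection)
    kymo_a, kymo_b = synchronize(kymo_a, kymo_b, mode=mode)
    if traces_a is not None:
        set_a = ingest_traces(traces_a, kymo_a)
    else:
        set_a = detect_traces(kymo_a, **(detect_kwargs or {}))
    if traces_b is not None:
        set_b = ingest_traces(traces_b, kymo_b)
    else:
        set_b = detect_traces(kymo_b, **(detect_kwargs or {}))

    pairs = match_traces(set_a, set_b, tol_um=tol_um, min_overlap_fraction=min_overlap_fraction)
    counts = categorize(set_a, set_b, pairs)
    result = comigration_fractions(counts, pairs)

    matched_a = {a for a, _ in pairs}
    matched_b = {b for _, b in pairs}
    rows = []
    for tr in set_a.traces:
        cat = (
            "both" if tr.id in matched_a
            else ("A_only" if set_a.moving.get(tr.id) else "stationary")
        )
        rows.append({"trace_id": tr.id, "channel": "A", "category": cat})
    for tr in set_b.traces:
        cat = (
            "both" if tr.id in matched_b
            else ("B_only" if set_b.moving.get(tr.id) else "stationary")
        )
        rows.append({"trace_id": tr.id, "channel": "B", "category": cat})
    return result, pd.DataFrame(rows, columns=["trace_id", "channel", "category"])
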