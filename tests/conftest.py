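"""Shared fixtures: controlled vesicle fields and truth-matching helpers."""

from __future__ import annotations

import numpy as np
import pytest

from kymoquant.core import PixelGeometry
from kymoquant.simulate import VesicleSpec


@pytest.fixture
def small_geometry():
    """A quick 60 s, 100 um field at the simultaneous-imaging frame rate."""
    return PixelGeometry(n_frames=180, n_px=800)


def comet_field_specs(seed: int, n_antero: int = 17, n_retro: int = 3) -> list[VesicleSpec]:
    """A 20-particle field in which ground-truth identity is well-posed.

    Starts are spread along the neurite and, within each direction, the
    particle ahead in its direction of travel is faster, so same-direction
    paths never cross; the ~50 opposite-direction crossings remain. The
    particles run at constant velocity, as plus-end comets do.
    """
    rng = np.random.default_rng(seed)
    x_a = np.linspace(2, 80, n_antero) + rng.uniform(-1.5, 1.5, n_antero)
    v_a = np.linspace(0.7, 1.2, n_antero) + rng.uniform(-0.01, 0.01, n_antero)
    x_r = np.linspace(50, 95, n_retro) + rng.uniform(-1.5, 1.5, n_retro)
    v_r = (np.linspace(0.7, 1.2, n_retro) + rng.uniform(-0.01, 0.01, n_retro))[::-1]
    specs = []
    i = 0
    for x0, v, dcls in [
        *zip(x_a, v_a, ["anterograde"] * n_antero),
        *zip(x_r, v_r, ["retrograde"] * n_retro),
    ]:
        specs.append(
            VesicleSpec(
                id=i,
                channels=("A",),
                x0=float(x0),
                direction_class=dcls,
                speed=float(v),
                pause_rate=0.0,
                pause_duration_mean=2.0,
                reversal_rate=0.0,
                length=float(rng.uniform(0.9, 1.5)),
                brightness=2000.0,
            )
        )
        i += 1
    return specs


def match_detections_to_truth(
    trace_set, truth, geometry, origin_px: int = 6, min_span_rows: int = 40
):
    """Greedy one-to-one matching of detected moving traces to truth.

    Truth is restricted to in-field frames (a detector cannot see a
    particle outside the imaged region); a detection matches a truth
    particle when their spatiotemporal IoU (rows where both exist and the
    positions agree within 0.5 um, over the union of rows) is >= 0.5.
    Returns (n_detections, precision, recall).
    """
    dt = geometry.frame_interval
    field_max = (geometry.n_px - 1 - origin_px) * geometry.pixel_size
    maps = {}
    for vid, gr in truth.positions.groupby("vesicle_id"):
        infield = gr[(gr.x_um >= 0) & (gr.x_um <= field_max)]
        maps[vid] = dict(zip(infield.frame, infield.x_um))
    moving_ids = [
        v
        for v in truth.vesicles[truth.vesicles.direction_class != "stationary"].id
        if len(maps[v]) >= min_span_rows
    ]

    def iou(trace, vid):
        tmap = maps[vid]
        rows = np.rint(trace.t / dt).astype(int)
        hits = sum(
            1 for r, x in zip(rows, trace.x) if r in tmap and abs(tmap[r] - x) <= 0.5
        )
        return hits / len(set(tmap) | set(rows))

    detections = trace_set.moving_traces()
    if not detections:
        return 0, 0.0, 0.0
    scored = sorted(
        (
            (max(moving_ids, key=lambda v: iou(tr, v)), max(iou(tr, v) for v in moving_ids))
            for tr in detections
        ),
        key=lambda pair: -pair[1],
    )
    matched = set()
    tp = 0
    for vid, score in scored:
        if score >= 0.5 and vid not in matched:
            matched.add(vid)
            tp += 1
    return len(detections), tp / len(detections), tp / len(moving_ids)
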