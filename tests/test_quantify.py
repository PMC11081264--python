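import numpy as np
import pytest

import kymoquant as kq
from kymoquant.core import Kymograph, PixelGeometry
from kymoquant.quantify import (
    NeuriteProfile,
    anterograde_flux,
    dendrite_extent,
    microtubule_polarity,
    moving_trajectory_intensity,
    penetrance,
    puncta_density,
    puncta_metrics,
    signal_extent,
    vesicle_lengths,
)
from kymoquant.simulate import VesicleSpec, simulate_dendrite_cohort, simulate_static_image
from kymoquant.tracing import Trace, TraceSet


def _profile(extent_um, length_um=100.0, step=0.2):
    d = np.arange(0.0, length_um, step)
    i = np.where(d <= extent_um, 100.0, 5.0)
    return NeuriteProfile(distance_um=d, intensity=i, background=(5.0, 1.0))


# ---------------------------------------------------------------------------
# penetrance and extent


def test_penetrance_counts_animals_past_threshold():
    profiles = [_profile(e) for e in [30, 40, 90, 10, 5, 20, 12, 8, 3, 24]]
    assert penetrance(profiles, 25.0) == pytest.approx(30.0)


def test_penetrance_monotone_in_threshold():
    profiles = [_profile(e) for e in [30, 40, 90, 10, 5, 20, 12, 8, 3, 24]]
    assert penetrance(profiles, 50.0) <= penetrance(profiles, 25.0)


def test_penetrance_empty_input_rejected():
    with pytest.raises(ValueError):
        penetrance([], 25.0)


def test_penetrance_recovery_on_noisy_cohort():
    """60% of profiles generated past 50 um -> estimate within 3 binomial SDs."""
    rng = np.random.default_rng(17)
    profiles = []
    n, p_true = 40, 0.6
    n_past = int(n * p_true)
    extents = [rng.uniform(55, 90) for _ in range(n_past)]
    extents += [rng.uniform(5, 45) for _ in range(n - n_past)]
    for i, e in enumerate(extents):
        prof, _ = simulate_static_image(
            "neurite_profile", {"furthest_um": e, "noise": True}, seed=100 + i
        )
        profiles.append(prof)
    est = penetrance(profiles, 50.0)
    sd = 100 * np.sqrt(p_true * (1 - p_true) / n)
    assert abs(est - 60.0) <= 3 * sd


def test_dendrite_extent_trivial_cases():
    d = np.arange(0.0, 50.0, 0.2)
    partial = NeuriteProfile(
        distance_um=d, intensity=np.where(d <= 20.0, 80.0, 4.0),
        dendrite_span=(0.0, 50.0), background=(4.0, 0.5),
    )
    assert dendrite_extent(partial) == pytest.approx(40.0, abs=1.0)
    full = NeuriteProfile(
        distance_um=d, intensity=np.full_like(d, 80.0), dendrite_span=(0.0, 50.0)
    )
    assert dendrite_extent(full, threshold=40.0) == pytest.approx(100.0)


def test_dendrite_extent_requires_span():
    with pytest.raises(ValueError, match="span"):
        dendrite_extent(_profile(10.0))


def test_dendrite_extent_cohort_recovery():
    profiles, truth = simulate_dendrite_cohort((92.0, 2.0), n_animals=20, seed=4)
    measured = [dendrite_extent(p) for p in profiles]
    assert np.mean(measured) == pytest.approx(92.0, abs=5.0)


def test_signal_extent_ignores_isolated_noise_spikes():
    d = np.arange(0.0, 100.0, 0.2)
    i = np.where(d <= 30.0, 100.0, 5.0)
    i[450] = 200.0  # single hot pixel at 90 um
    prof = NeuriteProfile(distance_um=d, intensity=i, background=(5.0, 1.0))
    assert signal_extent(prof) == pytest.approx(30.0, abs=0.5)


# ---------------------------------------------------------------------------
# density


def test_puncta_density_formula():
    assert puncta_density(6, 30.0) == pytest.approx(2.0)
    assert puncta_density(0, 25.0) == 0.0


def test_puncta_density_scale_invariance():
    assert puncta_density(6, 30.0) == pytest.approx(puncta_density(12, 60.0))


def test_puncta_density_rejects_bad_roi():
    with pytest.raises(ValueError):
        puncta_density(3, 0.0)


def test_puncta_density_poisson_recovery():
    lam = 2.5  # per 10 um
    rng = np.random.default_rng(5)
    length = 40.0
    densities = [
        puncta_density(rng.poisson(lam * length / 10), length) for _ in range(50)
    ]
    se = np.sqrt(lam / (length / 10) / 50)
    assert abs(np.mean(densities) - lam) <= 3 * se


# ---------------------------------------------------------------------------
# cell-body puncta


def test_puncta_metrics_recovers_count_and_ratio():
    img, mask, truth = simulate_static_image(
        "cell_body_puncta", {"n_puncta": 5, "ratio": 3.0, "noise": False}, seed=2
    )
    records, summary = puncta_metrics(img, mask)
    assert summary["count"] == 5
    assert summary["mean_ratio"] == pytest.approx(3.0, abs=1e-6)


def test_puncta_metrics_uniform_image_finds_nothing():
    img = np.full((40, 40), 30.0)
    mask = np.ones_like(img, dtype=bool)
    records, summary = puncta_metrics(img, mask)
    assert summary["count"] == 0


def test_puncta_metrics_keeps_cells_separate():
    imgs = []
    for n, seed in [(2, 3), (8, 4)]:
        img, mask, _ = simulate_static_image(
            "cell_body_puncta",
            {"n_puncta": n, "ratio": 3.0, "noise": False, "shape": (96, 96)},
            seed=seed,
        )
        _, summary = puncta_metrics(img, mask)
        imgs.append(summary["count"])
    assert imgs == [2, 8]


def test_puncta_metrics_empty_mask_rejected():
    with pytest.raises(ValueError, match="mask"):
        puncta_metrics(np.zeros((10, 10)), np.zeros((10, 10), dtype=bool))


# ---------------------------------------------------------------------------
# vesicle lengths


def _length_movie(length_um, seed=0):
    g = PixelGeometry(n_frames=100, n_px=100)
    spec = VesicleSpec(
        id=0, channels=("A",), x0=1.0, direction_class="anterograde", speed=0.3,
        pause_rate=0.0, pause_duration_mean=1.0, reversal_rate=0.0,
        length=length_um, brightness=4000.0,
    )
    cfg = kq.SimulationConfig(
        geometry=g, n_vesicles=1, photon_noise=False, read_noise_sd=0.0,
        cell_body_brightness=0.0, origin_px=0, seed=seed,
    )
    movie, _, truth = kq.simulate_movie(cfg, specs=[spec])
    kymo = kq.build_kymograph(movie)
    from kymoquant.tracing import ingest_traces

    traces = ingest_traces(truth.trace_table("A"), kymo, source="truth")
    return kymo, traces


def test_vesicle_length_fwhm_matches_rendered_length():
    kymo, traces = _length_movie(2.0)
    lengths = vesicle_lengths(kymo, traces, n_rois=60, roi_size_px=(10, 30), seed=1)
    assert len(lengths) > 0
    assert np.mean(lengths) == pytest.approx(2.0, abs=kymo.geometry.pixel_size)


def test_vesicle_length_same_seed_is_deterministic():
    kymo, traces = _length_movie(1.5)
    l1 = vesicle_lengths(kymo, traces, n_rois=40, roi_size_px=(10, 30), seed=9)
    l2 = vesicle_lengths(kymo, traces, n_rois=40, roi_size_px=(10, 30), seed=9)
    assert l1 == l2


def test_vesicle_length_roi_larger_than_kymograph_rejected():
    kymo, traces = _length_movie(1.0)
    with pytest.raises(ValueError):
        vesicle_lengths(kymo, traces, roi_size_px=(500, 10))


def test_crossing_traces_not_measured():
    """An ROI containing two crossing traces yields no measurement."""
    g = PixelGeometry(n_frames=20, n_px=40)
    data = np.full((20, 40), 10.0)
    kymo = Kymograph(data, g, origin=0)
    t = np.arange(20) * g.frame_interval
    up = Trace(id="u", channel="A", t=t, x=np.linspace(0.5, 4.0, 20))
    down = Trace(id="d", channel="A", t=t, x=np.linspace(4.0, 0.5, 20))
    traces = TraceSet(traces=[up, down], moving={"u": True, "d": True})
    lengths = vesicle_lengths(
        kymo, traces, n_rois=1, roi_size_px=(20, 40), seed=0
    )
    assert lengths == []


# ---------------------------------------------------------------------------
# flux


def _flux_kymo():
    g = PixelGeometry(pixel_size=0.1, frame_interval=0.5, n_frames=60, n_px=400)
    return Kymograph(np.zeros((60, 400)), g, origin=0)


def test_anterograde_flux_worked_example():
    """4 anterograde traces in a 40 um x 30 s window -> 4 * 0.5 * 1/3."""
    kymo = _flux_kymo()
    traces = []
    for i in range(4):
        t = np.array([0.0, 20.0])
        traces.append(Trace(id=i, channel="A", t=t, x=np.array([i * 5.0, i * 5.0 + 8])))
    ts = TraceSet(traces=traces, moving={i: True for i in range(4)})
    assert anterograde_flux(ts, kymo) == pytest.approx(4 * 0.5 * (10 / 30))


def test_anterograde_flux_zero_without_anterograde_traces():
    kymo = _flux_kymo()
    t = np.array([0.0, 20.0])
    ts = TraceSet(
        traces=[Trace(id=0, channel="A", t=t, x=np.array([30.0, 10.0]))],
        moving={0: True},
    )
    assert anterograde_flux(ts, kymo) == 0.0


def test_flux_normalization_invariant_to_observation_window():
    """Doubling the observation duration at a fixed true spawn rate leaves
    the normalized flux unchanged in expectation (50-seed check)."""
    rng = np.random.default_rng(23)
    rate = 0.8  # anterograde traces per 20 um per 10 s (true rate)
    g1 = PixelGeometry(pixel_size=0.1, frame_interval=0.5, n_frames=60, n_px=200)
    g2 = PixelGeometry(pixel_size=0.1, frame_interval=0.5, n_frames=120, n_px=200)
    fluxes1, fluxes2 = [], []
    for _ in range(50):
        for g, out in [(g1, fluxes1), (g2, fluxes2)]:
            window_factor = (g.n_px * g.pixel_size / 20.0) * (
                g.n_frames * g.frame_interval / 10.0
            )
            n = rng.poisson(rate * window_factor)
            kymo = Kymograph(np.zeros((g.n_frames, g.n_px)), g, origin=0)
            traces = [
                Trace(id=i, channel="A", t=np.array([0.0, 5.0]),
                      x=np.array([1.0, 4.0]))
                for i in range(n)
            ]
            ts = TraceSet(traces=traces, moving={i: True for i in range(n)})
            out.append(anterograde_flux(ts, kymo))
    se = np.std(fluxes1 + fluxes2) / np.sqrt(50)
    assert abs(np.mean(fluxes1) - np.mean(fluxes2)) <= 3 * se


# ---------------------------------------------------------------------------
# moving trajectory intensity


def _diagonal_kymo(value_on=100.0, bg=20.0, above=None, n=40):
    g = PixelGeometry(n_frames=n, n_px=n + 10)
    data = np.full((n, n + 10), bg)
    cols = np.arange(n) + 5
    for r in range(n):
        data[r, cols[r]] = value_on
        if above is not None and r >= 3:
            data[r - 3, cols[r]] = above
    t = np.arange(n) * g.frame_interval
    x = (cols - 0) * g.pixel_size
    kymo = Kymograph(data, g, origin=0)
    trace = Trace(id=0, channel="A", t=t, x=x)
    return kymo, trace


def test_intensity_subtraction_constant_trace_over_uniform_background():
    kymo, trace = _diagonal_kymo()
    assert moving_trajectory_intensity(kymo, trace) == pytest.approx(80.0)


def test_intensity_shift_is_three_rows_at_3fps():
    """The reference is sampled exactly 3 rows above at 3 fps: planting a
    distinct value there changes the result accordingly."""
    kymo, trace = _diagonal_kymo(above=30.0)
    usable = trace.t >= 1.0  # anchors at least 3 rows down
    expected = 100.0 - (
        np.where(np.arange(40) >= 3, 30.0, 20.0)[usable].mean()
    )
    assert moving_trajectory_intensity(kymo, trace) == pytest.approx(expected)


def test_intensity_trace_too_close_to_top_rejected():
    g = PixelGeometry(n_frames=10, n_px=30)
    kymo = Kymograph(np.full((10, 30), 5.0), g, origin=0)
    trace = Trace(id=0, channel="A", t=np.array([0.0, 1 / 3]),
                  x=np.array([1.0, 1.3]))
    with pytest.raises(ValueError, match="rows"):
        moving_trajectory_intensity(kymo, trace)


def test_intensity_pause_anchors_match_literal_rule():
    """The anchors excluded as pauses equal a literal reimplementation of
    the rule (speed below threshold for >= 2 frames; an anchor is paused
    when both flanking intervals are), so the measured value equals the
    mean over the literally-kept anchors minus their shifted references."""
    g = PixelGeometry(n_frames=60, n_px=100)
    bg = 20.0
    data = np.full((60, 100), bg)
    # moving 20 frames, paused 5 frames, moving on
    cols = np.concatenate([10 + np.arange(20), np.full(5, 29), 29 + np.arange(1, 21)])
    for r, c in enumerate(cols):
        data[r, c] = 100.0
    kymo = Kymograph(data, g, origin=0)
    n = len(cols)
    t_all = np.arange(n) * g.frame_interval
    x_all = cols * g.pixel_size
    full = Trace(id=0, channel="A", t=t_all, x=x_all)

    # literal rule, written independently of the implementation
    dt = np.diff(t_all)
    slow = np.abs(np.diff(x_all)) / dt < 0.05
    pause_int = np.zeros(n - 1, dtype=bool)
    i = 0
    while i < n - 1:
        j = i
        while j < n - 1 and slow[j]:
            j += 1
        if j > i and dt[i:j].sum() >= 2 * g.frame_interval - 1e-9:
            pause_int[i:j] = True
        i = max(j, i + 1)
    paused_anchor = np.zeros(n, dtype=bool)
    paused_anchor[1:-1] = pause_int[:-1] & pause_int[1:]
    paused_anchor[0], paused_anchor[-1] = pause_int[0], pause_int[-1]
    keep = ~paused_anchor & (np.arange(n) >= 3)
    rows = np.arange(n)
    expected = float(
        data[rows[keep], cols[keep]].mean() - data[rows[keep] - 3, cols[keep]].mean()
    )
    assert moving_trajectory_intensity(kymo, full) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# microtubule polarity


def test_polarity_fractions():
    t = np.array([0.0, 10.0])
    traces = [Trace(id=i, channel="A", t=t, x=np.array([0.0, 5.0])) for i in range(9)]
    traces += [
        Trace(id=9 + i, channel="A", t=t, x=np.array([10.0, 5.0])) for i in range(3)
    ]
    ts = TraceSet(traces=traces, moving={tr.id: True for tr in traces})
    fa, fr, nx = microtubule_polarity(ts)
    assert (fa, fr) == (0.75, 0.25)
    assert fa + fr == 1.0
    assert nx == 0


def test_polarity_all_anterograde():
    t = np.array([0.0, 10.0])
    traces = [Trace(id=i, channel="A", t=t, x=np.array([0.0, 5.0])) for i in range(5)]
    ts = TraceSet(traces=traces, moving={tr.id: True for tr in traces})
    assert microtubule_polarity(ts)[:2] == (1.0, 0.0)


def test_polarity_zero_comets_rejected():
    ts = TraceSet(traces=[], moving={})
    with pytest.raises(ValueError):
        microtubule_polarity(ts)


def test_polarity_recovery_binomial():
    rng = np.random.default_rng(6)
    t = np.array([0.0, 10.0])
    traces = []
    n, p = 150, 0.8
    n_a = int(rng.binomial(n, p))
    for i in range(n):
        x = np.array([0.0, 5.0]) if i < n_a else np.array([10.0, 5.0])
        traces.append(Trace(id=i, channel="A", t=t, x=x))
    ts = TraceSet(traces=traces, moving={tr.id: True for tr in traces})
    fa, fr, _ = microtubule_polarity(ts)
    sd = np.sqrt(p * (1 - p) / n)
    assert abs(fa - p) <= 3 * sd
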