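import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kymoquant as kq
from kymoquant.comigration import (
    ComigrationCounts,
    categorize,
    comigration_fractions,
    match_traces,
)
from kymoquant.core import Kymograph, PixelGeometry
from kymoquant.tracing import Trace, TraceSet


def _set(traces, lengths=None):
    moving = {tr.id: True for tr in traces}
    return TraceSet(traces=traces, moving=moving)


def _tr(tid, channel, t, x, length=None):
    return Trace(id=tid, channel=channel, t=np.asarray(t, float),
                 x=np.asarray(x, float), length_um=length)


# ---------------------------------------------------------------------------
# formulas


def test_fractions_worked_example():
    res = comigration_fractions(ComigrationCounts(10, 5, 5))
    assert res.percent_comigrating == pytest.approx(25.0)
    assert res.fraction_a_with_b == pytest.approx(1 / 3)
    assert res.fraction_b_with_a == pytest.approx(0.5)


def test_fractions_all_colabeled():
    res = comigration_fractions(ComigrationCounts(0, 0, 7))
    assert res.percent_comigrating == pytest.approx(100.0)
    assert res.fraction_a_with_b == 1.0
    assert res.fraction_b_with_a == 1.0


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    n_a=st.integers(0, 10_000),
    n_b=st.integers(0, 10_000),
    n_both=st.integers(0, 10_000),
)
def test_fraction_invariants_hold_for_all_counts(n_a, n_b, n_both):
    """Percent and fractions stay in range, respect the exact formulas and
    flag (rather than zero-fill) undefined denominators."""
    res = comigration_fractions(ComigrationCounts(n_a, n_b, n_both))
    total = n_a + n_b + n_both
    if total:
        assert res.percent_comigrating == pytest.approx(100 * n_both / total)
        assert 0 <= res.percent_comigrating <= 100
    else:
        assert math.isnan(res.percent_comigrating)
    if n_a + n_both:
        assert res.fraction_a_with_b == pytest.approx(n_both / (n_a + n_both))
        assert 0 <= res.fraction_a_with_b <= 1
    else:
        assert math.isnan(res.fraction_a_with_b)
        assert "fraction_a_with_b" in res.undefined


def test_fractions_flag_undefined_denominators():
    res = comigration_fractions(ComigrationCounts(0, 3, 0))
    assert math.isnan(res.fraction_a_with_b)
    assert "fraction_a_with_b" in res.undefined
    assert res.fraction_b_with_a == 0.0


# ---------------------------------------------------------------------------
# matching


def test_identical_traces_match():
    t = np.arange(20.0)
    a = _set([_tr(0, "A", t, t * 0.5)])
    b = _set([_tr(0, "B", t, t * 0.5)])
    assert match_traces(a, b) == [(0, 0)]


def test_parallel_traces_beyond_tolerance_do_not_match():
    t = np.arange(20.0)
    a = _set([_tr(0, "A", t, t * 0.5)])
    b = _set([_tr(0, "B", t, t * 0.5 + 5.0)])
    assert match_traces(a, b, tol_um=0.5) == []


def test_containment_matches_small_cargo_on_large_vesicle():
    """A short bright trace riding 0.7 um off-centre inside a 2 um vesicle
    matches via the containment rule, not the plain tolerance."""
    t = np.arange(20.0)
    big = _tr(0, "A", t, t * 0.5, length=2.0)
    small = _tr(0, "B", t, t * 0.5 + 0.7, length=0.4)
    assert match_traces(_set([big]), _set([small]), tol_um=0.5) == [(0, 0)]
    # without extent information the same offset fails the 0.5 um tolerance
    big_nolen = _tr(0, "A", t, t * 0.5)
    small_nolen = _tr(0, "B", t, t * 0.5 + 0.7)
    assert match_traces(_set([big_nolen]), _set([small_nolen]), tol_um=0.5) == []


def test_matching_is_one_to_one():
    t = np.arange(20.0)
    a = _set([_tr("a1", "A", t, t * 0.5), _tr("a2", "A", t, t * 0.5 + 0.3)])
    b = _set([_tr("b1", "B", t, t * 0.5)])
    pairs = match_traces(a, b)
    assert len(pairs) == 1
    assert pairs[0] == ("a1", "b1")  # exact-overlap partner wins


def test_unsynchronized_kymographs_rejected():
    g = PixelGeometry(n_frames=20, n_px=50)
    ka = Kymograph(np.zeros((20, 50)), g, channel="A")
    kb = Kymograph(np.zeros((20, 50)), g, channel="B")
    t = np.arange(5.0)
    sa = TraceSet(traces=[_tr(0, "A", t, t)], kymograph=ka, moving={0: True})
    sb = TraceSet(traces=[_tr(0, "B", t, t)], kymograph=kb, moving={0: True})
    with pytest.raises(ValueError, match="synchroniz"):
        match_traces(sa, sb)


# ---------------------------------------------------------------------------
# end-to-end


def _run_preset(preset, seed, swap=False, **config_overrides):
    cfg = kq.make_preset_config(preset, seed=seed, **config_overrides)
    movie_a, movie_b, truth = kq.simulate_movie(cfg)
    ta, tb = truth.trace_table("A"), truth.trace_table("B")
    if swap:
        movie_a, movie_b = movie_b, movie_a
        ta, tb = tb, ta
        ta = ta.assign(channel="A")
        tb = tb.assign(channel="B")
    res, table = kq.run_comigration(movie_a, movie_b, traces_a=ta, traces_b=tb)
    return res, table


def test_channel_swap_symmetry():
    small = dict(geometry=PixelGeometry(n_frames=120, n_px=400), n_vesicles=30)
    res, _ = _run_preset("WT_SNB1_RAB3", seed=5, **small)
    res_swapped, _ = _run_preset("WT_SNB1_RAB3", seed=5, swap=True, **small)
    assert res.counts.n_both == res_swapped.counts.n_both
    assert res.fraction_a_with_b == pytest.approx(res_swapped.fraction_b_with_a)
    assert res.fraction_b_with_a == pytest.approx(res_swapped.fraction_a_with_b)


def test_movie_without_b_signal_gives_zero_comigration():
    cfg = kq.SimulationConfig(
        geometry=PixelGeometry(n_frames=120, n_px=400),
        n_vesicles=20, p_colabel=0.0, p_b_only=0.0, seed=8,
    )
    movie_a, movie_b, truth = kq.simulate_movie(cfg)
    res, _ = kq.run_comigration(
        movie_a, movie_b,
        traces_a=truth.trace_table("A"), traces_b=truth.trace_table("B"),
    )
    assert res.counts.n_both == 0
    assert res.fraction_a_with_b == 0.0


def test_category_conservation_and_provenance_table():
    cfg = kq.make_preset_config(
        "WT_SNB1_RAB3", seed=3,
        geometry=PixelGeometry(n_frames=120, n_px=400), n_vesicles=40,
    )
    movie_a, movie_b, truth = kq.simulate_movie(cfg)
    res, table = kq.run_comigration(
        movie_a, movie_b,
        traces_a=truth.trace_table("A"), traces_b=truth.trace_table("B"),
    )
    c = res.counts
    assert c.total == c.n_a_only + c.n_b_only + c.n_both
    assert (table.category == "both").sum() == 2 * c.n_both  # one row per channel
    assert (table.category == "A_only").sum() == c.n_a_only
    assert (table.category == "B_only").sum() == c.n_b_only


def test_fraction_estimator_consistency():
    """fraction_A_with_B converges to the co-labelling probability
    (>= 2000 A-vesicles pooled, within 3 binomial SDs)."""
    p = 0.4
    n_a_total = 0
    n_both_total = 0
    for seed in range(12):
        cfg = kq.SimulationConfig(
            geometry=PixelGeometry(n_frames=120, n_px=400),
            n_vesicles=250, p_colabel=p, seed=seed,
        )
        _, _, truth = kq.simulate_movie(cfg)
        v = truth.vesicles
        n_a_total += int(v.channel_a.sum())
        n_both_total += int(v.colabeled.sum())
    assert n_a_total >= 2000
    est = n_both_total / n_a_total
    sd = math.sqrt(p * (1 - p) / n_a_total)
    assert abs(est - p) <= 3 * sd
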