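"""Responder-window rules, fold-change arithmetic and cohort classification."""

import numpy as np
import pytest

from eecatlas import calcium as ca
from eecatlas.synthetic_data import SyntheticTraceSpec, generate_traces


def _trace(values, windows):
    return ca.CalciumTrace("cell", np.asarray(values, float), windows=list(windows))


def test_max_near_onset_uses_first_ten():
    vals = np.full(80, 0.5)
    vals[23] = 1.0  # max at window start + 3
    tr = _trace(vals, [ca.StimulusWindow("S", 20, 60)])
    resp, base = ca.response_windows(tr, tr.windows[0])
    np.testing.assert_array_equal(resp, np.arange(20, 30))
    np.testing.assert_array_equal(base, np.arange(10, 20))


def test_max_mid_window_centred():
    vals = np.full(80, 0.5)
    vals[40] = 1.0  # max at window start + 20, window [20, 60)
    tr = _trace(vals, [ca.StimulusWindow("S", 20, 60)])
    resp, _ = ca.response_windows(tr, tr.windows[0])
    np.testing.assert_array_equal(resp, np.arange(35, 45))  # [m-5, m+5)


def test_constant_trace_tie_breaks_to_first_ten():
    tr = _trace(np.full(60, 0.5), [ca.StimulusWindow("S", 20, 40)])
    resp, _ = ca.response_windows(tr, tr.windows[0])
    np.testing.assert_array_equal(resp, np.arange(20, 30))


def test_max_near_window_end_shifts_left():
    vals = np.full(80, 0.5)
    vals[58] = 1.0  # centring would run past window end 60
    tr = _trace(vals, [ca.StimulusWindow("S", 20, 60)])
    resp, _ = ca.response_windows(tr, tr.windows[0])
    np.testing.assert_array_equal(resp, np.arange(50, 60))


def test_windows_disjoint_ten_samples():
    rng = np.random.default_rng(0)
    vals = 0.5 + rng.normal(0, 0.05, 100)
    tr = _trace(vals, [ca.StimulusWindow("S", 30, 70)])
    resp, base = ca.response_windows(tr, tr.windows[0])
    assert len(resp) == len(base) == 10
    assert not set(resp) & set(base)


def test_short_window_rejected():
    tr = _trace(np.full(60, 0.5), [ca.StimulusWindow("S", 20, 25)])
    with pytest.raises(ValueError, match="shorter"):
        ca.response_windows(tr, tr.windows[0])


def test_flat_trace_not_responder():
    tr = _trace(np.full(60, 0.5), [ca.StimulusWindow("S", 20, 40)])
    call = ca.score_response(tr, tr.windows[0])
    assert call.fold == pytest.approx(1.0)
    assert call.p == 1.0 and not call.responder


def test_noiseless_step_fold_and_verdict():
    """Baseline 0.50, response plateau 0.80 -> fold 1.6, responder."""
    vals = np.full(60, 0.5)
    vals[30:40] = 0.8
    tr = _trace(vals, [ca.StimulusWindow("S", 30, 50)])
    call = ca.score_response(tr, tr.windows[0])
    assert call.fold == pytest.approx(1.6)
    assert call.p == 0.0 and call.responder


def test_significant_decrease_not_responder():
    rng = np.random.default_rng(1)
    vals = 0.8 + rng.normal(0, 0.005, 60)
    vals[30:50] -= 0.3
    tr = _trace(vals, [ca.StimulusWindow("S", 30, 50)])
    call = ca.score_response(tr, tr.windows[0])
    assert call.p < 0.01 and call.r < call.r0
    assert not call.responder


def test_fold_invariant_to_positive_scaling():
    rng = np.random.default_rng(2)
    vals = 0.5 + rng.normal(0, 0.02, 80)
    vals[40:50] += 0.2
    tr = _trace(vals, [ca.StimulusWindow("S", 30, 60)])
    call1 = ca.score_response(tr, tr.windows[0])
    call2 = ca.score_response(_trace(3.7 * vals, tr.windows), tr.windows[0])
    assert call2.fold == pytest.approx(call1.fold, rel=1e-12)


def _cohort(seed=3, amp=0.3, noise=0.02, n_cells=40):
    rng = np.random.default_rng(seed)
    stimuli = [
        ("A", 20, 40, ("fixed", amp)),
        ("B", 80, 100, ("fixed", amp)),
        ("KCl", 140, 160, ("fixed", 0.5)),
    ]
    truth = np.column_stack([
        rng.random(n_cells) < 0.5,
        rng.random(n_cells) < 0.5,
        np.ones(n_cells, dtype=bool),
    ])
    spec = SyntheticTraceSpec(
        n_cells=n_cells, n_timepoints=200, stimuli=stimuli,
        responder_matrix=truth, noise_sd=noise, seed=seed,
    )
    return generate_traces(spec)


def test_classify_all_calls_and_venn_totals():
    traces, truth = _cohort()
    calls, venn, summary = ca.classify_all(traces, require_positive_control="KCl")
    n_passing = calls[calls.stimulus == "KCl"].responder.sum()
    assert venn["count"].sum() <= n_passing
    # all-responders cell appears only in the A+B region
    wide = calls.pivot(index="cell_id", columns="stimulus", values="responder")
    both = int((wide["A"] & wide["B"] & wide["KCl"]).sum())
    assert venn.set_index("combination").loc["A+B", "count"] == both
    assert set(summary.stimulus) == {"A", "B"}


def test_positive_control_gating_drops_failing_cells():
    traces, truth = _cohort()
    # sabotage one cell's KCl response
    victim = traces[0]
    w = victim.windows[2]
    victim.values[w.start - 10 : w.end] = victim.values[:1]
    calls, venn, _ = ca.classify_all(traces, require_positive_control="KCl")
    assert not calls[(calls.cell_id == victim.cell_id) & (calls.stimulus == "KCl")].responder.iloc[0]
    assert venn["count"].sum() == (
        calls[calls.passed_control]
        .pivot(index="cell_id", columns="stimulus", values="responder")[["A", "B"]]
        .any(axis=1).sum()
    )


def test_unknown_positive_control_rejected():
    traces, _ = _cohort()
    with pytest.raises(ValueError, match="positive-control"):
        ca.classify_all(traces, require_positive_control="NaCl")


def test_null_rate_anticonservative_but_below_planted():
    """With no transient the max-centred window inflates the responder rate
    above alpha, yet stays well below the planted-responder rate."""
    spec = SyntheticTraceSpec(
        n_cells=150, n_timepoints=120,
        stimuli=[("A", 40, 80, ("fixed", 0.04))],
        responder_matrix=np.zeros((150, 1), dtype=bool),
        noise_sd=0.02, seed=9,
    )
    traces, _ = generate_traces(spec)
    calls, _, _ = ca.classify_all(traces)
    null_rate = calls.responder.mean()

    spec_resp = SyntheticTraceSpec(
        n_cells=150, n_timepoints=120,
        stimuli=[("A", 40, 80, ("fixed", 0.04))],  # amplitude 2 x noise sd
        responder_matrix=np.ones((150, 1), dtype=bool),
        noise_sd=0.02, seed=9,
    )
    traces_r, _ = generate_traces(spec_resp)
    calls_r, _, _ = ca.classify_all(traces_r)
    planted_rate = calls_r.responder.mean()
    assert null_rate < planted_rate
    assert null_rate < 0.5
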