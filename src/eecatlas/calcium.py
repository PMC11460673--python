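"""Fura-2 ratiometric calcium-imaging responder classification.

Traces are 340/380 nm excitation ratios sampled every 2 s during perfusion.
For each stimulus window the response is the mean ratio over 10 time points
(20 s) centred at the in-window maximum, compared against the mean over the
10 time points immediately before stimulus onset.  If the maximum falls
within 5 time points of onset, the first 10 time points of the window are
used instead.  A cell is a responder to a stimulus when the response window
is significantly increased over baseline (Student's t-test, p < 0.01) and
the mean ratio actually rose.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalciumTrace",
    "StimulusWindow",
    "ResponseCall",
    "response_windows",
    "score_response",
    "classify_all",
]

#: samples in the response and baseline windows (10 points = 20 s at 2 s sampling)
WINDOW_SAMPLES = 10
#: "within 5 time points of the onset" rule for using the first-10 window
ONSET_PROXIMITY = 5


@dataclass(frozen=True)
class StimulusWindow:
    """Half-open stimulus window [start, end) in sample indices."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window {self.label!r}: end must exceed start")


@dataclass
class CalciumTrace:
    """Background-subtracted 340/380 ratio time series for one cell."""

    cell_id: str
    values: np.ndarray
    sampling_interval: float = 2.0
    windows: list[StimulusWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        for w in self.windows:
            if w.start < 0 or w.end > self.values.size:
                raise ValueError(f"window {w.label!r} outside trace")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ResponseCall:
    """Per-cell, per-stimulus verdict."""

    cell_id: str
    stimulus: str
    r: float          # mean ratio over the response window
    r0: float         # mean ratio over the 10-sample baseline
    fold: float       # r / r0
    response_indices: np.ndarray
    baseline_indices: np.ndarray
    p: float
    responder: bool


def response_windows(
    trace: CalciumTrace, window: StimulusWindow
) -> tuple[np.ndarray, np.ndarray]:
    """Select the 10-sample response and baseline index sets for one stimulus.

    The response window is centred at the in-window maximum, ``[m - 5, m + 5)``
    (argmax ties break to the earliest sample), unless the maximum occurred
    within 5 time points of stimulus onset, in which case the first 10 samples
    of the window are used.  The response window is kept inside the stimulus
    window by shifting left when centring would run past its end.  The
    baseline is the 10 samples immediately preceding onset.
    """
    n = len(trace)
    if window.end - window.start < WINDOW_SAMPLES:
        raise ValueError(
            f"stimulus window {window.label!r} shorter than {WINDOW_SAMPLES} samples"
        )
    if window.start < WINDOW_SAMPLES:
        raise ValueError(
            f"window {window.label!r} must be preceded by >= {WINDOW_SAMPLES} samples"
        )
    if window.end > n:
        raise ValueError(f"window {window.label!r} outside trace")

    seg = trace.values[window.start : window.end]
    m = window.start + int(np.argmax(seg))  # earliest index on ties

    if m - window.start < ONSET_PROXIMITY:
        lo = window.start
    else:
        hi = min(m + ONSET_PROXIMITY, window.end)
        lo = hi - WINDOW_SAMPLES
        lo = max(lo, window.start)
    response = np.arange(lo, lo + WINDOW_SAMPLES)
    baseline = np.arange(window.start - WINDOW_SAMPLES, window.start)
    return response, baseline


def score_response(
    trace: CalciumTrace, window: StimulusWindow, alpha: float = 0.01
) -> ResponseCall:
    """Compute R/R0 fold change and the responder verdict for one stimulus.

    Two-sample equal-variance Student's t-test between the 10 response samples
    and the 10 baseline samples; responder iff p < alpha AND R > R0 (the
    directionality requirement replaces a one-tailed test).  Degenerate
    zero-variance windows: identical means give p = 1; separated means are
    treated as the p -> 0 limit.
    """
    resp_idx, base_idx = response_windows(trace, window)
    resp = trace.values[resp_idx]
    base = trace.values[base_idx]
    r = float(resp.mean())
    r0 = float(base.mean())
    if np.var(resp) == 0.0 and np.var(base) == 0.0:
        p = 1.0 if r == r0 else 0.0
    else:
        p = float(stats.ttest_ind(resp, base, equal_var=True).pvalue)
    responder = bool(p < alpha and r > r0)
    return ResponseCall(
        cell_id=trace.cell_id,
        stimulus=window.label,
        r=r,
        r0=r0,
        fold=r / r0,
        response_indices=resp_idx,
        baseline_indices=base_idx,
        p=p,
        responder=responder,
    )


def classify_all(
    traces: list[CalciumTrace],
    windows: list[StimulusWindow] | None = None,
    require_positive_control: str | None = None,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Score every cell against every stimulus and summarize the cohort.

    Parameters
    ----------
    windows
        Shared stimulus-window table; defaults to the first trace's windows.
    require_positive_control
        Label of a positive-control stimulus (e.g. 70 mM KCl).  Cells that
        fail it are dropped from the Venn and fold-change summaries (their
        raw calls remain in the calls table, flagged).

    Returns
    -------
    calls
        Tidy per-(cell, stimulus) table with R, R0, fold, p, responder.
    venn
        Count per non-empty responder-membership combination over the test
        stimuli (positive control excluded).
    summary
        Per stimulus: n cells, responder count, mean fold and a one-sample
        one-tailed t-test of fold changes against 1 (increase).
    """
    if not traces:
        raise ValueError("no traces supplied")
    if windows is None:
        windows = traces[0].windows
    if not windows:
        raise ValueError("no stimulus windows supplied")
    labels = [w.label for w in windows]
    if require_positive_control is not None and require_positive_control not in labels:
        raise ValueError(
            f"positive-control label {require_positive_control!r} not among stimuli {labels}"
        )

    rows = []
    for tr in traces:
        for w in windows:
            call = score_response(tr, w, alpha=alpha)
            rows.append(
                {
                    "cell_id": call.cell_id,
                    "stimulus": call.stimulus,
                    "r": call.r,
                    "r0": call.r0,
                    "fold": call.fold,
                    "p": call.p,
                    "responder": call.responder,
                }
            )
    calls = pd.DataFrame(rows)

    if require_positive_control is not None:
        ok = calls[calls["stimulus"] == require_positive_control]
        passing = set(ok.loc[ok["responder"], "cell_id"])
        calls["passed_control"] = calls["cell_id"].isin(passing)
        gated = calls[calls["passed_control"]]
        test_labels = [l for l in labels if l != require_positive_control]
    else:
        calls["passed_control"] = True
        gated = calls
        test_labels = labels

    wide = (
        gated[gated["stimulus"].isin(test_labels)]
        .pivot(index="cell_id", columns="stimulus", values="responder")
        .fillna(False)
        .astype(bool)
    )
    venn_rows = []
    for r in range(1, len(test_labels) + 1):
        for combo in itertools.combinations(test_labels, r):
            in_combo = np.ones(len(wide), dtype=bool)
            for l in test_labels:
                col = wide[l].to_numpy() if l in wide else np.zeros(len(wide), bool)
                in_combo &= col if l in combo else ~col
            venn_rows.append({"combination": "+".join(combo), "count": int(in_combo.sum())})
    venn = pd.DataFrame(venn_rows)

    summary_rows = []
    for l in test_labels:
        sub = gated[gated["stimulus"] == l]
        folds = sub["fold"].to_numpy()
        if folds.size >= 2 and np.std(folds) > 0:
            p_one = float(stats.ttest_1samp(folds, 1.0, alternative="greater").pvalue)
        else:
            p_one = np.nan
        summary_rows.append(
            {
                "stimulus": l,
                "n_cells": len(sub),
                "n_responders": int(sub["responder"].sum()),
                "mean_fold": float(folds.mean()) if folds.size else np.nan,
                "p_fold_gt_1": p_one,
            }
        )
    summary = pd.DataFrame(summary_rows)
    return calls, venn, summary
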