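"""Trial-epoch time courses and time-to-peak statistics.

Each 24 s trial (5 TRs stimulus on + 7 TRs blank at TR = 2 s) is cut into a
12-TR epoch of the ROI-mean signal.  Percent signal change is expressed
relative to the first TR of the epoch (the onset TR), so the curve starts at
0 by construction.  Time-to-peak is the 1-based TR index of the maximum over
TRs 2..12 — "after stimulus onset" excludes the reference TR — with ties
resolved to the earliest TR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synth import RoiTimeSeries

__all__ = [
    "TrialEpoch",
    "EPOCH_TRS",
    "epoch",
    "percent_change",
    "time_to_peak",
    "compare_ttp",
]

EPOCH_TRS = 12  # 5 on + 7 off


@dataclass(frozen=True)
class TrialEpoch:
    trial_id: int
    run_id: int
    condition: str
    label: str | None  # 'fill'/'nofill' for Scotoma trials, else None
    values: np.ndarray  # 12 ROI-mean samples starting at stimulus onset

    def __post_init__(self) -> None:
        if len(self.values) != EPOCH_TRS:
            raise ValueError(f"epoch must have {EPOCH_TRS} TRs")


def epoch(Y: RoiTimeSeries) -> list[TrialEpoch]:
    """One 12-TR ROI-mean epoch per trial, aligned to stimulus onset.

    Onsets must fall exactly on the TR grid; trials whose epoch would run
    past the end of the run are dropped with a warning.
    """
    epochs: list[TrialEpoch] = []
    trial_id = 0
    for ri, run in enumerate(Y.sequence.runs):
        roi_mean = Y.data[ri].mean(axis=1)
        scot_i = 0
        for ev in run.events:
            onset_trs = ev.onset_s / run.tr_s
            if abs(onset_trs - round(onset_trs)) > 1e-9:
                raise ValueError(
                    f"run {run.run_id}: onset {ev.onset_s}s is not on the TR grid")
            i0 = int(round(onset_trs))
            label = None
            if ev.condition == "Scotoma":
                label = Y.labels[ri][scot_i]
                scot_i += 1
            if i0 + EPOCH_TRS > run.n_trs:
                warnings.warn(
                    f"run {run.run_id}: trial at {ev.onset_s}s truncated by run end; dropped")
                trial_id += 1
                continue
            epochs.append(TrialEpoch(
                trial_id=trial_id, run_id=run.run_id, condition=ev.condition,
                label=label, values=roi_mean[i0:i0 + EPOCH_TRS].copy()))
            trial_id += 1
    return epochs


def percent_change(e: TrialEpoch) -> np.ndarray:
    """100 * (x_t - x_1) / x_1 relative to the epoch's first TR."""
    x0 = e.values[0]
    if x0 == 0:
        raise ValueError("first-TR value is zero; trial cannot be normalized")
    return 100.0 * (e.values - x0) / x0


def time_to_peak(e: TrialEpoch) -> int:
    """1-based TR index of the post-onset maximum (TRs 2..12, earliest tie)."""
    post = e.values[1:]
    return int(np.argmax(post)) + 2


def compare_ttp(fill_means: np.ndarray, nofill_means: np.ndarray,
                family_alpha: float = 0.05, n_tests: int = 12) -> dict:
    """Two-tailed paired t-test on per-participant mean time-to-peak values."""
    a = np.asarray(fill_means, dtype=float)
    b = np.asarray(nofill_means, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-D vectors")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if diff.std(ddof=1) == 0:
        return {"t": 0.0 if np.all(diff == 0) else float(np.sign(diff.mean()) * np.inf),
                "p": 1.0 if np.all(diff == 0) else 0.0,
                "df": n - 1, "degenerate": True,
                "alpha_bonferroni": family_alpha / n_tests}
    res = stats.ttest_rel(a, b)
    return {"t": float(res.statistic), "p": float(res.pvalue), "df": n - 1,
            "degenerate": False, "alpha_bonferroni": family_alpha / n_tests}
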