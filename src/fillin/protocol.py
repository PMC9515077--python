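"""Experiment designs and trial-sequence generation.

Encodes the four scanning protocols — retinotopic mapping (rotating wedge +
expanding ring), the block-design scotoma localizer, the pre-test contrast
staircase, and the event-related main experiment (10 s stimulus, 14 s blank,
TR = 2 s, 20 trials/run) — and produces seeded randomized trial sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "DesignSpec",
    "TrialSequence",
    "retinotopy_timing",
    "localizer_design",
    "main_experiment_sequence",
    "pretest_staircase",
    "write_events_tsv",
    "read_events_tsv",
    "MAIN_CONDITIONS",
]

MAIN_CONDITIONS = ("Center", "FullField", "Scotoma")

# Main-experiment constants: 5 TRs on + 7 TRs off at TR = 2 s.
TRIAL_ON_S = 10.0
TRIAL_OFF_S = 14.0
TRIAL_PERIOD_S = TRIAL_ON_S + TRIAL_OFF_S
MAIN_TR_S = 2.0
N_CENTER_PER_RUN = 5
N_FULLFIELD_PER_RUN = 5
N_SCOTOMA_PER_RUN = 10
N_TRIALS_PER_RUN = N_CENTER_PER_RUN + N_FULLFIELD_PER_RUN + N_SCOTOMA_PER_RUN


@dataclass(frozen=True)
class Event:
    onset_s: float
    duration_s: float
    condition: str
    response: str | None = None  # 'fill' / 'nofill' for Scotoma trials


@dataclass
class DesignSpec:
    """One run's timing: TR, scan count, and the ordered event list."""

    tr_s: float
    n_trs: int
    events: list[Event]
    run_id: int = 0

    def __post_init__(self) -> None:
        last = -math.inf
        for ev in self.events:
            if ev.onset_s < 0:
                raise ValueError("event onsets must be non-negative")
            if ev.onset_s <= last:
                raise ValueError("event onsets must be strictly increasing")
            if ev.onset_s + ev.duration_s > self.n_trs * self.tr_s + 1e-9:
                raise ValueError("event extends past the end of the run")
            last = ev.onset_s

    @property
    def duration_s(self) -> float:
        return self.n_trs * self.tr_s

    def boxcar(self, condition: str) -> np.ndarray:
        """TR-resolution indicator of stimulus-on scans for one condition."""
        box = np.zeros(self.n_trs)
        for ev in self.events:
            if ev.condition == condition:
                i0 = int(round(ev.onset_s / self.tr_s))
                i1 = int(round((ev.onset_s + ev.duration_s) / self.tr_s))
                box[i0:i1] = 1.0
        return box


@dataclass
class TrialSequence:
    """Randomized per-run condition orders for the main experiment."""

    runs: list[DesignSpec]
    seed: int | None = None

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def condition_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for run in self.runs:
            for ev in run.events:
                counts[ev.condition] = counts.get(ev.condition, 0) + 1
        return counts

    def scotoma_trials(self) -> list[tuple[int, int]]:
        """(run index, trial index within run) of every Scotoma trial."""
        out = []
        for ri, run in enumerate(self.runs):
            for ti, ev in enumerate(run.events):
                if ev.condition == "Scotoma":
                    out.append((ri, ti))
        return out


def retinotopy_timing(
    wedge_step_deg: float = 22.5,
    ring_start_deg: float = 0.25,
    ring_end_deg: float = 10.6,
    ring_step_deg: float = 0.86,
    tr_s: float = 3.0,
    n_trs: int = 96,
) -> dict[str, float]:
    """Cycle arithmetic for the rotating-wedge / expanding-ring mapping run.

    The wedge steps ``wedge_step_deg`` per TR, so a full revolution takes
    (360 / step) TRs; the ring covers [start, end] in ceil(range / step)
    steps of one TR each.  With the standard parameters (22.5 deg wedge step
    and a 0.25->10.6 deg ring in 0.86 deg steps at TR = 3 s) this gives 48 s
    and 36 s cycles and 6 / 8 cycles over a 288 s run.
    """
    if wedge_step_deg <= 0 or ring_step_deg <= 0:
        raise ValueError("step sizes must be positive")
    wedge_trs = 360.0 / wedge_step_deg
    if abs(wedge_trs - round(wedge_trs)) > 1e-9:
        wedge_trs = round(wedge_trs)  # documented rounding for odd steps
    # nearest-integer step count: the standard 0.25->10.6 deg ring in
    # 0.86 deg steps is 12.03 steps, i.e. a 12-TR (36 s) cycle
    ring_trs = round((ring_end_deg - ring_start_deg) / ring_step_deg)
    run_s = n_trs * tr_s
    wedge_cycle_s = wedge_trs * tr_s
    ring_cycle_s = ring_trs * tr_s
    return {
        "wedge_cycle_s": wedge_cycle_s,
        "ring_cycle_s": ring_cycle_s,
        "wedge_cycles": run_s / wedge_cycle_s,
        "ring_cycles": run_s / ring_cycle_s,
        "run_s": run_s,
    }


def localizer_design(on_trs: int = 6, off_trs: int = 6, n_blocks: int = 6,
                     tr_s: float = 3.0, run_id: int = 0) -> DesignSpec:
    """Block design for the scotoma localizer: on/off blocks repeated."""
    if min(on_trs, off_trs, n_blocks) < 1:
        raise ValueError("block lengths and count must be positive integers")
    events = [
        Event(onset_s=b * (on_trs + off_trs) * tr_s, duration_s=on_trs * tr_s,
              condition="Localizer")
        for b in range(n_blocks)
    ]
    return DesignSpec(tr_s=tr_s, n_trs=(on_trs + off_trs) * n_blocks,
                      events=events, run_id=run_id)


def main_experiment_sequence(
    n_runs: int = 8,
    seed: int | np.random.Generator | None = None,
    tr_s: float = MAIN_TR_S,
) -> TrialSequence:
    """Seeded random trial orders for the event-related main experiment.

    Each run is a random permutation of 5 Center + 5 FullField + 10 Scotoma
    trials on a fixed 24 s trial grid (10 s on, 14 s off); eight runs give
    40 + 40 + 80 trials in total.
    """
    if n_runs < 1:
        raise ValueError("need at least one run")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = (["Center"] * N_CENTER_PER_RUN + ["FullField"] * N_FULLFIELD_PER_RUN
              + ["Scotoma"] * N_SCOTOMA_PER_RUN)
    n_trs = int(N_TRIALS_PER_RUN * TRIAL_PERIOD_S / tr_s)
    runs = []
    for r in range(n_runs):
        order = rng.permutation(labels)
        events = [
            Event(onset_s=i * TRIAL_PERIOD_S, duration_s=TRIAL_ON_S, condition=c)
            for i, c in enumerate(order)
        ]
        runs.append(DesignSpec(tr_s=tr_s, n_trs=n_trs, events=events, run_id=r))
    return TrialSequence(runs=runs, seed=seed if isinstance(seed, int) else None)


def pretest_staircase(fill_reports: int, n_trials: int = 10) -> str:
    """Contrast adjustment after one pre-test run of ``n_trials`` trials.

    More than 6 filling-in reports out of 10 -> the inducer contrast should
    'increase' (make filling-in harder); fewer than 4 -> 'decrease';
    otherwise 'keep', i.e. the ~50% target rate is reached.
    """
    if not 0 <= fill_reports <= n_trials:
        raise ValueError("report count must be within [0, n_trials]")
    if fill_reports > 6:
        return "increase"
    if fill_reports < 4:
        return "decrease"
    return "keep"


def write_events_tsv(seq: TrialSequence, path: str | Path) -> None:
    """BIDS-style events table: onset, duration, trial_type, response, run."""
    rows = []
    for run in seq.runs:
        for ev in run.events:
            rows.append({
                "onset": ev.onset_s,
                "duration": ev.duration_s,
                "trial_type": ev.condition,
                "response": ev.response if ev.response is not None else "n/a",
                "run": run.run_id,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path, tr_s: float = MAIN_TR_S,
                    n_trs: int | None = None) -> TrialSequence:
    """Read an events TSV back into per-run designs (rejects overlaps)."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type", "run"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events file missing columns: {sorted(missing)}")
    runs = []
    for run_id, g in df.groupby("run"):
        g = g.sort_values("onset")
        onsets = g["onset"].to_numpy(float)
        durs = g["duration"].to_numpy(float)
        if np.any(onsets[1:] < onsets[:-1] + durs[:-1] - 1e-9):
            raise ValueError(f"run {run_id}: overlapping trials in events file")
        events = []
        for _, row in g.iterrows():
            resp = row.get("response", "n/a")
            events.append(Event(
                onset_s=float(row["onset"]), duration_s=float(row["duration"]),
                condition=str(row["trial_type"]),
                response=None if pd.isna(resp) or resp == "n/a" else str(resp),
            ))
        trs = n_trs or int(math.ceil((onsets[-1] + durs[-1] + TRIAL_OFF_S) / tr_s))
        runs.append(DesignSpec(tr_s=tr_s, n_trs=trs, events=events, run_id=int(run_id)))
    return TrialSequence(runs=runs)
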