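"""Readers and writers for the pipeline's typed objects.

Time series travel either as NIfTI (ROI voxels unfolded on the first
spatial axis, time = concatenated runs) or as a raw ``.npz`` matrix, both
with a JSON sidecar carrying the design, labels, and geometry so that
``load(save(x))`` reproduces ``x``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .protocol import DesignSpec, Event, TrialSequence
from .synth import RoiTimeSeries

__all__ = [
    "save_timeseries",
    "load_timeseries",
]


def _sequence_to_dict(seq: TrialSequence) -> dict:
    return {
        "seed": seq.seed,
        "runs": [
            {
                "tr_s": run.tr_s,
                "n_trs": run.n_trs,
                "run_id": run.run_id,
                "events": [
                    {"onset_s": ev.onset_s, "duration_s": ev.duration_s,
                     "condition": ev.condition, "response": ev.response}
                    for ev in run.events
                ],
            }
            for run in seq.runs
        ],
    }


def _sequence_from_dict(d: dict) -> TrialSequence:
    runs = [
        DesignSpec(
            tr_s=r["tr_s"], n_trs=r["n_trs"], run_id=r["run_id"],
            events=[Event(onset_s=e["onset_s"], duration_s=e["duration_s"],
                          condition=e["condition"], response=e["response"])
                    for e in r["events"]],
        )
        for r in d["runs"]
    ]
    return TrialSequence(runs=runs, seed=d.get("seed"))


def save_timeseries(Y: RoiTimeSeries, path: str | Path, fmt: str = "npz") -> None:
    """Write a RoiTimeSeries as ``.npz`` or ``.nii.gz`` plus a JSON sidecar."""
    path = Path(path)
    stem = path.with_suffix("") if path.suffix else path
    if fmt == "npz":
        np.savez(stem.with_suffix(".npz"), data=Y.data)
    elif fmt == "nifti":
        n_runs, n_trs, n_vox = Y.data.shape
        vol = Y.data.transpose(2, 0, 1).reshape(n_vox, 1, 1, n_runs * n_trs)
        img = nib.Nifti1Image(vol, affine=np.eye(4))
        img.header["pixdim"][4] = Y.tr_s
        nib.save(img, str(stem) + ".nii.gz")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = {
        "format": fmt,
        "roi_name": Y.roi_name,
        "tr_s": Y.tr_s,
        "shape": list(Y.data.shape),
        "labels": Y.labels,
        "sequence": _sequence_to_dict(Y.sequence),
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_timeseries(path: str | Path) -> RoiTimeSeries:
    """Inverse of :func:`save_timeseries` (format read from the sidecar)."""
    path = Path(path)
    stem = path.with_suffix("") if path.suffix in (".json", ".npz") else path
    if str(stem).endswith(".nii"):
        stem = Path(str(stem)[:-4])
    meta = json.loads(stem.with_suffix(".json").read_text())
    n_runs, n_trs, n_vox = meta["shape"]
    if meta["format"] == "npz":
        data = np.load(stem.with_suffix(".npz"))["data"]
    else:
        vol = np.asarray(nib.load(str(stem) + ".nii.gz").dataobj)
        data = vol.reshape(n_vox, n_runs, n_trs).transpose(1, 2, 0)
    return RoiTimeSeries(
        data=data, sequence=_sequence_from_dict(meta["sequence"]),
        labels=[list(l) for l in meta["labels"]],
        roi_name=meta["roi_name"], tr_s=meta["tr_s"])
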