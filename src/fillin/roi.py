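"""Voxel selection: localizer thresholding, center-dominance pruning, merging.

The analysis ROIs start from ten retinotopically labeled subregions (V1 plus
dorsal/ventral V2 and V3 in each hemisphere).  Within each, voxels are kept
if their localizer t-statistic exceeds a Bonferroni-derived criterion
(default t > 5.09, i.e. |r| > 0.52 at the localizer's residual df), then
pruned to voxels responding at least as strongly to the Center grating as to
the Scotoma grating.  Subregions merge to six univariate ROIs (lV1..rV3) or,
pooling hemispheres, to three MVPA ROIs (V1, V2, V3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "RoiDefinition",
    "threshold_localizer",
    "t_to_r",
    "r_to_t",
    "t_crit_bonferroni",
    "restrict_center_dominant",
    "merge",
    "save_rois_json",
    "load_rois_json",
    "DEFAULT_T_CRIT",
]

DEFAULT_T_CRIT = 5.09

SUBREGIONS = [f"{h}{a}" for h in ("l", "r")
              for a in ("V1", "V2d", "V2v", "V3d", "V3v")]


@dataclass
class RoiDefinition:
    """A named voxel set with the selection steps that produced it."""

    name: str
    voxels: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        if len(np.unique(self.voxels)) != len(self.voxels):
            raise ValueError("voxel ids must be unique")
        if len(self.voxels) == 0:
            self.metadata.setdefault("flags", []).append("empty")

    @property
    def size(self) -> int:
        return len(self.voxels)


def threshold_localizer(t_map: np.ndarray, t_crit: float = DEFAULT_T_CRIT) -> np.ndarray:
    """Voxel indices with localizer t strictly above the criterion."""
    if t_crit <= 0:
        raise ValueError("t_crit must be positive")
    return np.flatnonzero(np.asarray(t_map) > t_crit)


def t_to_r(t: float | np.ndarray, df: int) -> np.ndarray | float:
    """Correlation magnitude equivalent of a t-statistic: r = t/sqrt(t^2+df)."""
    if df <= 0:
        raise ValueError("df must be positive")
    t = np.asarray(t, dtype=float)
    out = t / np.sqrt(t**2 + df)
    return float(out) if out.ndim == 0 else out


def r_to_t(r: float | np.ndarray, df: int) -> np.ndarray | float:
    """Exact inverse of :func:`t_to_r`: t = r*sqrt(df/(1-r^2))."""
    if df <= 0:
        raise ValueError("df must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1")
    out = r * np.sqrt(df / (1.0 - r**2))
    return float(out) if out.ndim == 0 else out


def t_crit_bonferroni(n_voxels: int, df: int, family_alpha: float = 0.05) -> float:
    """One-tail Bonferroni voxelwise t criterion for ``n_voxels`` comparisons.

    Recomputes the selection threshold from a gray-matter voxel count; the
    conventional default 5.09 corresponds to an unreported count and is kept
    as the package default rather than derived.
    """
    if n_voxels < 1 or df <= 0:
        raise ValueError("need positive voxel count and df")
    return float(stats.t.ppf(1.0 - family_alpha / n_voxels, df))


def restrict_center_dominant(beta_center: np.ndarray, beta_scotoma: np.ndarray,
                             voxels: np.ndarray) -> np.ndarray:
    """Keep voxels whose Center response is at least the Scotoma response.

    The removal rule is strict ('scotoma greater than center' is removed),
    so ties are kept.
    """
    beta_center = np.asarray(beta_center)
    beta_scotoma = np.asarray(beta_scotoma)
    voxels = np.asarray(voxels, dtype=int)
    keep = beta_center[voxels] >= beta_scotoma[voxels]
    return voxels[keep]


_UNIVARIATE_GROUPS = {
    "lV1": ["lV1"], "rV1": ["rV1"],
    "lV2": ["lV2d", "lV2v"], "rV2": ["rV2d", "rV2v"],
    "lV3": ["lV3d", "lV3v"], "rV3": ["rV3d", "rV3v"],
}
_MVPA_GROUPS = {
    "V1": ["lV1", "rV1"],
    "V2": ["lV2d", "lV2v", "rV2d", "rV2v"],
    "V3": ["lV3d", "lV3v", "rV3d", "rV3v"],
}


def merge(rois: list[RoiDefinition], scheme: str = "univariate") -> list[RoiDefinition]:
    """Merge subregion ROIs: 'univariate' -> 6 ROIs, 'mvpa' -> 3 ROIs.

    Inputs must be pairwise disjoint voxel sets (they come from disjoint
    retinotopic subregions); the merged sets are unions.
    """
    groups = {"univariate": _UNIVARIATE_GROUPS, "mvpa": _MVPA_GROUPS}.get(scheme)
    if groups is None:
        raise ValueError(f"unknown merge scheme {scheme!r}")
    by_name = {r.name: r for r in rois}
    all_vox = np.concatenate([r.voxels for r in rois]) if rois else np.array([], int)
    if len(np.unique(all_vox)) != len(all_vox):
        raise ValueError("input ROIs overlap; expected disjoint voxel sets")
    merged = []
    for out_name, members in groups.items():
        present = [by_name[m] for m in members if m in by_name]
        if not present:
            continue
        vox = np.sort(np.concatenate([r.voxels for r in present]))
        merged.append(RoiDefinition(
            name=out_name, voxels=vox,
            metadata={"merged_from": [r.name for r in present], "scheme": scheme}))
    return merged


def save_rois_json(rois: list[RoiDefinition], path: str | Path) -> None:
    payload = [{"name": r.name, "voxels": r.voxels.tolist(), "metadata": r.metadata}
               for r in rois]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_rois_json(path: str | Path) -> list[RoiDefinition]:
    payload = json.loads(Path(path).read_text())
    return [RoiDefinition(name=d["name"], voxels=np.array(d["voxels"], int),
                          metadata=d.get("metadata", {})) for d in payload]
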