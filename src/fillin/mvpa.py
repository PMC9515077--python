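"""Trial-wise pattern classification of filling-in reports.

Voxel time series are z-scored across time within each run, rescaled to
[0, 1] per voxel per run, and averaged over the 3rd-7th TRs of each Scotoma
trial's epoch (the peak of the evoked response) to give one feature vector
per trial.  A linear support vector machine (C = 1) is trained and tested
with leave-one-run-out cross-validation (8 folds of 70 training / 10 test
trials in the standard design), and the group-mean accuracy is referred to a
permutation null built by relabeling trials within runs and rerunning the
full cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .synth import RoiTimeSeries

__all__ = [
    "TrialFeature",
    "CvResult",
    "PermutationNull",
    "normalize_runwise",
    "features",
    "loro_cv",
    "permutation_test",
    "FEATURE_TR_SLICE",
]

# "3rd to 7th TRs relative to stimulus onset", 1-based with TR 1 = onset TR,
# i.e. 0-based offsets 2..6 inclusive.
FEATURE_TR_SLICE = slice(2, 7)


@dataclass(frozen=True)
class TrialFeature:
    trial_id: int
    run_id: int
    label: str  # 'fill' / 'nofill'
    vector: np.ndarray


@dataclass
class CvResult:
    fold_accuracies: list[float]
    fold_run_ids: list[int]
    skipped_folds: list[int] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass
class PermutationNull:
    n_iter: int
    null: np.ndarray
    observed: float
    p: float
    early_stopped: bool = False


def normalize_runwise(Y: RoiTimeSeries) -> RoiTimeSeries:
    """Z-score each voxel across time within each run, then min-max to [0, 1].

    Both steps are per voxel per run, so any per-voxel-per-run affine
    transform of the raw signal is absorbed.  A voxel with zero variance in
    any run cannot be normalized consistently and is dropped across all runs
    with a warning (feature vectors must keep one entry per retained voxel).
    """
    data = Y.data.astype(float).copy()
    sd = data.std(axis=1, ddof=0)          # runs x voxels
    bad = np.any(sd == 0, axis=0)
    if np.any(bad):
        warnings.warn(f"{bad.sum()} zero-variance voxel(s) dropped before MVPA")
        data = data[:, :, ~bad]
        sd = sd[:, ~bad]
    mean = data.mean(axis=1)
    z = (data - mean[:, None, :]) / sd[:, None, :]
    zmin = z.min(axis=1)
    zmax = z.max(axis=1)
    scaled = (z - zmin[:, None, :]) / (zmax - zmin)[:, None, :]
    return RoiTimeSeries(data=scaled, sequence=Y.sequence, labels=Y.labels,
                         roi_name=Y.roi_name, tr_s=Y.tr_s)


def features(Y: RoiTimeSeries, normalized: bool = False) -> list[TrialFeature]:
    """One feature vector per Scotoma trial: mean of epoch TRs 3-7 per voxel.

    ``Y`` is normalized run-wise first unless ``normalized`` is set.
    """
    if not normalized:
        Y = normalize_runwise(Y)
    out: list[TrialFeature] = []
    trial_id = 0
    for ri, run in enumerate(Y.sequence.runs):
        scot_i = 0
        for ev in run.events:
            if ev.condition != "Scotoma":
                trial_id += 1
                continue
            onset_trs = ev.onset_s / run.tr_s
            if abs(onset_trs - round(onset_trs)) > 1e-9:
                raise ValueError("trial onset not on the TR grid")
            i0 = int(round(onset_trs))
            window = Y.data[ri, i0 + FEATURE_TR_SLICE.start:i0 + FEATURE_TR_SLICE.stop]
            out.append(TrialFeature(
                trial_id=trial_id, run_id=run.run_id,
                label=Y.labels[ri][scot_i], vector=window.mean(axis=0)))
            scot_i += 1
            trial_id += 1
    return out


def _make_classifier(C: float, tol: float) -> SVC:
    return SVC(kernel="linear", C=C, tol=tol)


def loro_cv(feats: list[TrialFeature], C: float = 1.0, tol: float = 1e-2,
            labels: dict[int, str] | None = None) -> CvResult:
    """Leave-one-run-out cross-validation with a linear SVM.

    ``labels`` optionally overrides the trial labels (by trial id) so a
    permutation test can relabel without rebuilding features.  A training
    split containing a single class cannot be fit; that fold is skipped with
    a warning and recorded.
    """
    run_ids = sorted({f.run_id for f in feats})
    if len(run_ids) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    X = np.vstack([f.vector for f in feats])
    y = np.array([labels[f.trial_id] if labels else f.label for f in feats])
    runs = np.array([f.run_id for f in feats])
    accs, fold_runs, skipped = [], [], []
    for rid in run_ids:
        test = runs == rid
        y_train = y[~test]
        if len(np.unique(y_train)) < 2:
            warnings.warn(f"fold {rid}: single-class training split skipped")
            skipped.append(rid)
            continue
        clf = _make_classifier(C, tol)
        clf.fit(X[~test], y_train)
        accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
        fold_runs.append(rid)
    if not accs:
        raise ValueError("no usable cross-validation folds")
    return CvResult(fold_accuracies=accs, fold_run_ids=fold_runs,
                    skipped_folds=skipped)


def _permute_within_runs(feats: list[TrialFeature],
                         rng: np.random.Generator) -> dict[int, str]:
    """Permute trial labels within each run, preserving run class counts."""
    out: dict[int, str] = {}
    by_run: dict[int, list[TrialFeature]] = {}
    for f in feats:
        by_run.setdefault(f.run_id, []).append(f)
    for fs in by_run.values():
        labs = [f.label for f in fs]
        perm = rng.permutation(len(labs))
        for f, j in zip(fs, perm):
            out[f.trial_id] = labs[j]
    return out


def permutation_test(
    per_participant_feats: list[list[TrialFeature]],
    n_iter: int = 5000,
    seed: int | np.random.Generator | None = None,
    C: float = 1.0,
    tol: float = 1e-2,
    observed: float | None = None,
    early_stop_alpha: float | None = None,
) -> PermutationNull:
    """Group-level permutation test of the mean cross-validated accuracy.

    Each iteration relabels every participant's trials within runs, reruns
    the full leave-one-run-out cross-validation, and averages accuracy over
    participants; p = (1 + #{null >= observed}) / (1 + n_iter), so p is
    never exactly 0.

    ``early_stop_alpha`` stops iterating as soon as significance at that
    level has become arithmetically impossible — the accept/reject decision
    is identical to the full run while null-hypothesis simulations finish in
    a handful of iterations.  The returned p is then an upper bound based on
    the iterations performed and ``early_stopped`` is set.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if observed is None:
        observed = float(np.mean([
            loro_cv(f, C=C, tol=tol).mean_accuracy for f in per_participant_feats]))
    # smallest count of null >= observed that already forces p > alpha
    stop_count = None
    if early_stop_alpha is not None:
        stop_count = int(np.floor(early_stop_alpha * (1 + n_iter)))
    null = []
    exceed = 0
    stopped = False
    for _ in range(n_iter):
        vals = []
        for feats_p in per_participant_feats:
            labels = _permute_within_runs(feats_p, rng)
            vals.append(loro_cv(feats_p, C=C, tol=tol, labels=labels).mean_accuracy)
        g = float(np.mean(vals))
        null.append(g)
        if g >= observed:
            exceed += 1
            if stop_count is not None and exceed >= stop_count:
                stopped = True
                break
    p = (1 + exceed) / (1 + n_iter)
    return PermutationNull(n_iter=n_iter, null=np.asarray(null),
                           observed=observed, p=float(p), early_stopped=stopped)
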