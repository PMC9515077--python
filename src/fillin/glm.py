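"""Voxelwise GLM estimation and group-level inference for the univariate contrasts.

Runs are concatenated with one intercept per run; each condition (Center,
FullField, and the Scotoma trials split by perceptual report into
ScotomaFill / ScotomaNoFill) gets one HRF-convolved boxcar regressor.
Per-voxel contrast t-values are averaged within an ROI per participant and
the participant values are tested against zero with a one-sample t-test
(one-tailed for the FullField - Center suppression hypothesis), with
Cohen's d = t / sqrt(n) and a Bonferroni-corrected alpha reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .protocol import TrialSequence
from .synth import RoiTimeSeries, convolve_boxcar, hrf

__all__ = [
    "DesignMatrix",
    "GlmFit",
    "GroupResult",
    "build_design",
    "fit",
    "contrast_t",
    "contrast_vector",
    "normalize_beta",
    "group_test",
    "bonferroni_alpha",
]

CONDITION_ORDER = ("Center", "FullField", "ScotomaFill", "ScotomaNoFill")


@dataclass
class DesignMatrix:
    """Concatenated-run design: condition regressors then per-run intercepts."""

    X: np.ndarray
    columns: list[str]
    condition_columns: list[str]

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column label count mismatch")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError(self._rank_message())

    def _rank_message(self) -> str:
        bad = []
        for j in range(self.X.shape[1]):
            others = np.delete(self.X, j, axis=1)
            resid = self.X[:, j] - others @ np.linalg.lstsq(others, self.X[:, j], rcond=None)[0]
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(self.X[:, j])):
                bad.append(self.columns[j])
        return f"design matrix is rank deficient; collinear columns: {bad}"


@dataclass
class GlmFit:
    """Per-voxel OLS estimates for one participant's concatenated runs."""

    beta: np.ndarray          # columns x voxels
    sigma2: np.ndarray        # voxels
    df: int
    design: DesignMatrix

    @property
    def n_voxels(self) -> int:
        return self.beta.shape[1]

    def condition_beta(self, condition: str) -> np.ndarray:
        return self.beta[self.design.columns.index(condition)]

    def baseline_beta(self) -> np.ndarray:
        """Per-voxel baseline: mean of the run-intercept coefficients."""
        idx = [i for i, c in enumerate(self.design.columns)
               if c.startswith("intercept")]
        return self.beta[idx].mean(axis=0)


def build_design(sequence: TrialSequence, labels: list[list[str]] | None = None,
                 tr_s: float | None = None, hrf_func=hrf) -> DesignMatrix:
    """One HRF-convolved regressor per condition plus one intercept per run.

    Scotoma trials must carry a fill/nofill label (either in ``labels`` or
    on the events' ``response`` field); they are modeled as separate
    ScotomaFill / ScotomaNoFill regressors so the Fill - NoFill contrast is
    estimable.
    """
    del hrf_func  # regressors use the package HRF; kept for signature clarity
    n_runs = len(sequence.runs)
    onsets: dict[str, list[list[tuple[float, float]]]] = {}

    def add(cond: str, ri: int, ev) -> None:
        onsets.setdefault(cond, [[] for _ in range(n_runs)])[ri].append(
            (ev.onset_s, ev.duration_s))

    for ri, run in enumerate(sequence.runs):
        scot_i = 0
        for ev in run.events:
            if ev.condition == "Scotoma":
                lab = ev.response
                if labels is not None:
                    lab = labels[ri][scot_i]
                scot_i += 1
                if lab not in ("fill", "nofill"):
                    raise ValueError(
                        f"run {run.run_id}: Scotoma trial without fill/nofill label")
                add("ScotomaFill" if lab == "fill" else "ScotomaNoFill", ri, ev)
            else:
                add(ev.condition, ri, ev)

    conditions = [c for c in CONDITION_ORDER if c in onsets]
    conditions += [c for c in sorted(onsets) if c not in conditions]
    tr = tr_s or sequence.runs[0].tr_s
    blocks = []
    for ri, run in enumerate(sequence.runs):
        cols = [np.zeros((run.n_trs, 0))]
        for cond in conditions:
            evs = onsets[cond][ri]
            if evs:
                ons = np.array([o for o, _ in evs])
                dur = evs[0][1]
                cols.append(convolve_boxcar(ons, dur, tr, run.n_trs))
            else:
                cols.append(np.zeros(run.n_trs))
        blocks.append(np.column_stack(cols))
    n_total = sum(run.n_trs for run in sequence.runs)
    X = np.zeros((n_total, len(conditions) + n_runs))
    row = 0
    for ri, run in enumerate(sequence.runs):
        X[row:row + run.n_trs, :len(conditions)] = blocks[ri]
        X[row:row + run.n_trs, len(conditions) + ri] = 1.0
        row += run.n_trs
    columns = conditions + [f"intercept_run{run.run_id}" for run in sequence.runs]
    return DesignMatrix(X=X, columns=columns, condition_columns=conditions)


def fit(Y: RoiTimeSeries | np.ndarray, X: DesignMatrix) -> GlmFit:
    """Ordinary least squares per voxel on the concatenated runs."""
    data = Y.data.reshape(-1, Y.data.shape[-1]) if isinstance(Y, RoiTimeSeries) else np.asarray(Y)
    if data.shape[0] != X.X.shape[0]:
        raise ValueError("row count mismatch between data and design")
    beta, _, rank, _ = np.linalg.lstsq(X.X, data, rcond=None)
    if rank < X.X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    resid = data - X.X @ beta
    df = data.shape[0] - X.X.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / df
    return GlmFit(beta=beta, sigma2=sigma2, df=df, design=X)


def contrast_vector(design: DesignMatrix, weights: dict[str, float]) -> np.ndarray:
    """Build a contrast vector from {column label: weight}."""
    c = np.zeros(len(design.columns))
    for name, w in weights.items():
        c[design.columns.index(name)] = w
    return c


def contrast_t(glm_fit: GlmFit, c: np.ndarray) -> np.ndarray:
    """Per-voxel t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c), df = fit.df."""
    c = np.asarray(c, dtype=float)
    if c.shape != (len(glm_fit.design.columns),):
        raise ValueError("contrast length must equal design column count")
    XtX_inv = np.linalg.inv(glm_fit.design.X.T @ glm_fit.design.X)
    var_scale = float(c @ XtX_inv @ c)
    num = c @ glm_fit.beta
    denom = np.sqrt(glm_fit.sigma2 * var_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, num / denom,
                     np.where(num == 0, 0.0, np.sign(num) * np.inf))
    if np.any(np.isinf(t)):
        warnings.warn("zero residual variance with nonzero contrast: infinite t")
    return t


def normalize_beta(glm_fit: GlmFit, conditions: list[str] | None = None) -> dict[str, np.ndarray]:
    """Condition betas divided per voxel by the baseline (intercept) beta.

    Voxels with zero baseline are excluded (NaN) with a warning.  ROI and
    group averaging of the returned per-voxel values is left to the caller.
    """
    conditions = conditions or glm_fit.design.condition_columns
    base = glm_fit.baseline_beta()
    bad = base == 0
    if np.any(bad):
        warnings.warn(f"{bad.sum()} voxel(s) with zero baseline excluded")
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for cond in conditions:
            v = glm_fit.condition_beta(cond) / base
            v = np.where(bad, np.nan, v)
            out[cond] = v
    return out


@dataclass
class GroupResult:
    t: float
    p: float
    d: float
    df: int
    n: int
    tail: str
    alpha_bonferroni: float | None = None
    degenerate: bool = False


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test alpha after Bonferroni correction."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return family_alpha / n_tests


def group_test(values: np.ndarray, tail: str = "less",
               family_alpha: float = 0.05, n_tests: int = 1) -> GroupResult:
    """One-sample t-test of per-participant values against zero.

    ``tail`` is 'less' (hypothesized negative mean, e.g. FullField - Center
    under lateral inhibition), 'greater', or 'two-sided'.  Cohen's d is
    mean/SD = t/sqrt(n).
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 participants")
    sd = v.std(ddof=1)
    if sd == 0:
        mean = float(v.mean())
        if mean == 0:
            t, p = 0.0, (1.0 if tail == "two-sided" else 0.5)
        else:
            t = float(np.sign(mean) * np.inf)
            in_tail = ((tail == "less" and mean < 0)
                       or (tail == "greater" and mean > 0) or tail == "two-sided")
            p = 0.0 if in_tail else 1.0
        return GroupResult(t=t, p=p, d=0.0, df=n - 1, n=n, tail=tail,
                           alpha_bonferroni=bonferroni_alpha(family_alpha, n_tests),
                           degenerate=True)
    res = stats.ttest_1samp(v, 0.0, alternative=tail if tail != "two-sided" else "two-sided")
    t = float(res.statistic)
    return GroupResult(t=t, p=float(res.pvalue), d=t / np.sqrt(n), df=n - 1, n=n,
                       tail=tail,
                       alpha_bonferroni=bonferroni_alpha(family_alpha, n_tests))
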