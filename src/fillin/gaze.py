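"""Fixation-stability analysis via the bivariate contour ellipse area (BCEA).

Gaze traces recorded during stimulus presentation are cleaned (missing
samples, blinks, off-screen positions, and samples terminating eye movements
faster than 30 deg/s are discarded) and summarized by the BCEA,

    BCEA = 2 * k * pi * sigma_H * sigma_V * sqrt(1 - rho^2),

the area of the ellipse containing a fraction P = 1 - exp(-k) of fixation
samples under a bivariate normal model (k = 1 covers ~63.2%).  Condition
contrasts are assessed with a bootstrap null distribution and a two-level
repeated-measures ANOVA (algebraically the squared paired t), plus an
ellipse-center containment check and kernel-smoothed fixation density maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .synth import GazeRecord

__all__ = [
    "BceaResult",
    "clean",
    "bcea",
    "probability_area",
    "bootstrap_contrast",
    "rm_anova_2",
    "ellipse_contains",
    "density_map",
    "read_gaze_csv",
    "write_gaze_csv",
]


@dataclass
class BceaResult:
    sigma_h: float
    sigma_v: float
    rho: float
    k: float
    bcea: float
    prob_area: float
    center: tuple[float, float]
    cov: np.ndarray
    n_samples: int
    degenerate: bool = False

    @property
    def ellipse_axes(self) -> tuple[float, float]:
        """Semi-axes of the k-contour ellipse (from the covariance eigenvalues)."""
        evals = np.linalg.eigvalsh(self.cov)
        return tuple(np.sqrt(2.0 * self.k * np.maximum(evals, 0.0)))

    @property
    def ellipse_angle_deg(self) -> float:
        """Orientation of the major axis, degrees CCW from horizontal."""
        evals, evecs = np.linalg.eigh(self.cov)
        major = evecs[:, int(np.argmax(evals))]
        return float(np.degrees(np.arctan2(major[1], major[0])))


def probability_area(k: float) -> float:
    """Fraction of bivariate-normal samples inside the k-contour: 1 - e^-k."""
    if k <= 0:
        raise ValueError("k must be positive")
    return 1.0 - float(np.exp(-k))


def clean(g: GazeRecord, screen_bounds: tuple[float, float] = (14.0, 10.5),
          vmax_deg_s: float = 30.0) -> GazeRecord:
    """Remove invalid, missing, off-screen, and fast-moving gaze samples.

    ``screen_bounds`` is the (half-width, half-height) of the display in
    degrees.  Velocity is the Euclidean displacement between consecutive
    *valid* samples times the sampling rate; the sample terminating a
    super-threshold movement is removed.  The first interval after a removed
    gap is not velocity-tested (the elapsed time there is unknown).
    """
    if vmax_deg_s <= 0:
        raise ValueError("vmax must be positive")
    keep = g.valid.astype(bool).copy()
    keep &= ~(np.isnan(g.x_deg) | np.isnan(g.y_deg))
    with np.errstate(invalid="ignore"):
        keep &= (np.abs(g.x_deg) <= screen_bounds[0]) & (np.abs(g.y_deg) <= screen_bounds[1])

    idx = np.flatnonzero(keep)
    consecutive = np.diff(idx) == 1
    dx = g.x_deg[idx[1:]] - g.x_deg[idx[:-1]]
    dy = g.y_deg[idx[1:]] - g.y_deg[idx[:-1]]
    speed = np.hypot(dx, dy) * g.rate_hz
    fast = consecutive & (speed > vmax_deg_s)
    keep[idx[1:][fast]] = False

    if not np.any(keep):
        raise ValueError("no gaze samples survive cleaning")
    return GazeRecord(t_s=g.t_s[keep], x_deg=g.x_deg[keep], y_deg=g.y_deg[keep],
                      valid=np.ones(int(keep.sum()), dtype=bool), rate_hz=g.rate_hz)


def bcea(g: GazeRecord, k: float = 1.0) -> BceaResult:
    """Bivariate contour ellipse area of the valid samples in a record."""
    x, y = g.valid_xy()
    if len(x) < 3:
        raise ValueError("need at least 3 valid samples")
    if k <= 0:
        raise ValueError("k must be positive")
    sh = float(np.std(x, ddof=1))
    sv = float(np.std(y, ddof=1))
    if sh == 0 or sv == 0:
        cov = np.cov(np.vstack([x, y]), ddof=1)
        return BceaResult(sigma_h=sh, sigma_v=sv, rho=0.0, k=k, bcea=0.0,
                          prob_area=probability_area(k),
                          center=(float(np.mean(x)), float(np.mean(y))),
                          cov=cov, n_samples=len(x), degenerate=True)
    rho = float(np.corrcoef(x, y)[0, 1])
    area = 2.0 * k * np.pi * sh * sv * np.sqrt(1.0 - rho**2)
    cov = np.cov(np.vstack([x, y]), ddof=1)
    return BceaResult(sigma_h=sh, sigma_v=sv, rho=rho, k=k, bcea=float(area),
                      prob_area=probability_area(k),
                      center=(float(np.mean(x)), float(np.mean(y))),
                      cov=cov, n_samples=len(x),
                      degenerate=bool(abs(rho) >= 1.0))


def bootstrap_contrast(values_a: np.ndarray, values_b: np.ndarray,
                       n_iter: int = 10000,
                       seed: int | np.random.Generator | None = None) -> dict:
    """Bootstrap test of a paired condition difference in BCEA.

    The observed statistic is mean(a - b).  The null distribution resamples
    participants with replacement and randomly swaps each sampled pair's
    condition assignment (exchangeability under "no condition difference"),
    ``n_iter`` times.  p is the two-tailed add-one bootstrap p-value; each
    tail is conventionally compared to alpha = 0.025.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-D vectors")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 participants")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diff = a - b
    observed = float(diff.mean())
    picks = rng.integers(0, n, size=(n_iter, n))
    signs = rng.choice([-1.0, 1.0], size=(n_iter, n))
    null = (diff[picks] * signs).mean(axis=1)
    p_hi = (1 + np.sum(null >= observed)) / (1 + n_iter)
    p_lo = (1 + np.sum(null <= observed)) / (1 + n_iter)
    return {"mean_diff": observed, "p": float(min(1.0, 2.0 * min(p_hi, p_lo))),
            "p_upper": float(p_hi), "p_lower": float(p_lo),
            "null": null, "n_iter": n_iter}


def rm_anova_2(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """One-way repeated-measures ANOVA with two levels.

    With two conditions the ANOVA collapses to F(1, n-1) = (paired t)^2 with
    an identical p-value, which is how it is computed here.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-D vectors")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 participants")
    diff = a - b
    if diff.std(ddof=1) == 0:
        return {"F": 0.0 if np.all(diff == 0) else np.inf,
                "p": 1.0 if np.all(diff == 0) else 0.0,
                "df": (1, n - 1), "degenerate": True}
    t = float(stats.ttest_rel(a, b).statistic)
    F = t**2
    p = float(stats.f.sf(F, 1, n - 1))
    return {"F": F, "p": p, "df": (1, n - 1), "degenerate": False}


def ellipse_contains(b: BceaResult, point: tuple[float, float]) -> bool:
    """Whether a point lies inside the k-contour BCEA ellipse.

    Containment: squared Mahalanobis distance from the ellipse center,
    under the sample covariance, at most 2k.
    """
    if b.degenerate or np.linalg.det(b.cov) <= 0:
        raise ValueError("containment undefined for a degenerate ellipse")
    d = np.asarray(point, dtype=float) - np.asarray(b.center)
    m2 = float(d @ np.linalg.solve(b.cov, d))
    return m2 <= 2.0 * b.k


def density_map(g: GazeRecord, extent_deg: float = 2.0, n_bins: int = 81,
                bandwidth_deg: float = 0.1) -> dict:
    """Gaussian-smoothed fixation density on a square grid, max-normalized.

    Returns the grid (``density`` with max 1.0 for non-empty input) and the
    bin edges.  ``bandwidth_deg`` is the smoothing kernel SD.
    """
    x, y = g.valid_xy()
    if len(x) == 0:
        raise ValueError("no valid samples")
    edges = np.linspace(-extent_deg, extent_deg, n_bins + 1)
    counts, _, _ = np.histogram2d(x, y, bins=[edges, edges])
    bin_w = edges[1] - edges[0]
    smooth = ndimage.gaussian_filter(counts, sigma=bandwidth_deg / bin_w)
    peak = smooth.max()
    return {"density": smooth / peak if peak > 0 else smooth,
            "x_edges": edges, "y_edges": edges}


def write_gaze_csv(g: GazeRecord, path: str | Path) -> None:
    pd.DataFrame({"t": g.t_s, "x_deg": g.x_deg, "y_deg": g.y_deg,
                  "valid": g.valid.astype(int)}).to_csv(path, index=False)


def read_gaze_csv(path: str | Path, rate_hz: float | None = None,
                  deg_per_px: float | None = None) -> GazeRecord:
    """Read a gaze CSV with columns t, x_deg, y_deg, valid.

    A pixel-coordinate dialect (columns x_px, y_px) is converted with
    ``deg_per_px``.  The sampling rate is inferred from timestamps unless
    given.
    """
    df = pd.read_csv(path)
    if "x_deg" in df.columns:
        x, y = df["x_deg"].to_numpy(float), df["y_deg"].to_numpy(float)
    elif "x_px" in df.columns:
        if deg_per_px is None:
            raise ValueError("pixel-coordinate gaze file needs deg_per_px")
        x = df["x_px"].to_numpy(float) * deg_per_px
        y = df["y_px"].to_numpy(float) * deg_per_px
    else:
        raise ValueError("gaze file needs x_deg/y_deg or x_px/y_px columns")
    t = df["t"].to_numpy(float)
    valid = (df["valid"].to_numpy() != 0) if "valid" in df.columns else np.ones(len(t), bool)
    if rate_hz is None:
        dt = np.median(np.diff(t))
        rate_hz = 1.0 / dt if dt > 0 else 60.0
    return GazeRecord(t_s=t, x_deg=x, y_deg=y, valid=valid, rate_hz=float(rate_hz))
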