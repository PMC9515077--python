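"""Radial sinusoidal grating stimuli for lateral-modulation / filling-in experiments.

The stimuli live on a polar grid centred on fixation.  A radial grating is a
sinusoid in *rotation angle* (polar angle), so the bars radiate outward from
fixation like spokes.  The center stimulus keeps the grating only inside an
annular window centred at 8 deg eccentricity, split into two lateral
crescents by masking out a wedge around the vertical meridian; the scotoma
stimulus is its pixelwise complement (grating everywhere *except* the
crescents, which are blank mean-luminance zones that can perceptually fill
in); the full-field stimulus is the unwindowed grating.

Luminance is in normalized [0, 1] units; no display gamma model is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PolarGrid",
    "GratingParams",
    "StimulusImage",
    "radial_grating",
    "radial_window",
    "window_width",
    "meridian_mask",
    "compose_stimuli",
    "flicker_sequence",
    "save_png",
    "save_matrix",
    "load_matrix",
]


@dataclass(frozen=True)
class PolarGrid:
    """Pixel grid with per-pixel polar coordinates about fixation.

    ``theta`` is the rotation angle in degrees, measured from the upper
    vertical meridian, increasing clockwise, in [0, 360).  ``r`` is the
    eccentricity in degrees of visual angle.  Only the symmetry about the
    vertical meridian matters downstream; the origin/direction convention is
    configurable via :meth:`make`.
    """

    width_px: int
    height_px: int
    deg_per_px: float
    origin: tuple[float, float]
    theta: np.ndarray = field(repr=False)
    r: np.ndarray = field(repr=False)

    @classmethod
    def make(
        cls,
        width_px: int = 800,
        height_px: int = 600,
        deg_per_px: float = 0.035,
        origin: tuple[float, float] | None = None,
        clockwise: bool = True,
    ) -> "PolarGrid":
        if width_px <= 0 or height_px <= 0:
            raise ValueError("grid dimensions must be positive")
        if deg_per_px <= 0:
            raise ValueError("deg_per_px must be positive")
        if origin is None:
            origin = ((width_px - 1) / 2.0, (height_px - 1) / 2.0)
        ox, oy = origin
        px = np.arange(width_px)[None, :]
        py = np.arange(height_px)[:, None]
        dx = px - ox
        dy_up = oy - py  # screen y grows downward; flip so "up" is positive
        if not clockwise:
            dx = -dx
        theta = np.degrees(np.arctan2(dx, dy_up)) % 360.0
        r = np.hypot(dx, dy_up) * deg_per_px
        return cls(width_px, height_px, deg_per_px, (ox, oy), theta, r)


@dataclass(frozen=True)
class GratingParams:
    """Parameters of the radial grating and its annular window.

    ``f`` is in cycles per degree of *rotation* angle (not visual angle):
    f = 0.1 gives 36 cycles around the full 360 deg pattern.  ``r_E`` and
    ``sigma_r`` place and scale the Gaussian-power annulus (deg of visual
    angle); ``power`` sharpens its edges (3 for the main stimuli, 1000 for
    the hard-edged localizer).  ``mask_halfwidth`` is the rotation-angle
    half-width of the vertical-meridian wedge removed on each side.
    """

    B: float = 0.5
    C: float = 1.0
    f: float = 0.1
    r_E: float = 8.0
    sigma_r: float = 1.0
    power: float = 3.0
    mask_halfwidth: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 < self.B <= 1.0:
            raise ValueError("mean luminance B must be in (0, 1]")
        if not 0.0 <= self.C <= 1.0:
            raise ValueError("Michelson contrast C must be in [0, 1]")
        if self.f <= 0:
            raise ValueError("spatial frequency f must be positive")
        if self.sigma_r <= 0:
            raise ValueError("sigma_r must be positive")
        if self.power < 1:
            raise ValueError("window power must be >= 1")
        if not 0.0 < self.mask_halfwidth < 90.0:
            raise ValueError("mask halfwidth must be in (0, 90) deg")


@dataclass(frozen=True)
class StimulusImage:
    """A luminance image on a :class:`PolarGrid`."""

    values: np.ndarray
    kind: str
    grid: PolarGrid
    params: GratingParams

    def modulation(self) -> np.ndarray:
        """Signed contrast modulation around the mean luminance."""
        return self.values - self.params.B


def radial_grating(grid: PolarGrid, params: GratingParams, phase_deg: float = 0.0) -> StimulusImage:
    """Full-field radial sinusoidal grating: B + B*C*cos(2*pi*f*theta)."""
    g = params.B + params.B * params.C * np.cos(
        2.0 * np.pi * params.f * (grid.theta - phase_deg)
    )
    return StimulusImage(g, "full_field", grid, params)


def radial_window(grid: PolarGrid, r_E: float, sigma_r: float, power: float) -> np.ndarray:
    """Gaussian-power annular window W = exp(-(((r - r_E)^2 / (2 sigma^2))^P)).

    Equals 1 exactly on the circle r = r_E and is symmetric in (r - r_E).
    Raising ``power`` flattens the top and sharpens the flanks.
    """
    if sigma_r <= 0:
        raise ValueError("sigma_r must be positive")
    if power < 1:
        raise ValueError("power must be >= 1")
    u = (grid.r - r_E) ** 2 / (2.0 * sigma_r**2)
    # u**power overflows for sharp windows (power ~1000); exp(-inf) -> 0 is
    # exactly the intended hard edge, so silence the overflow
    with np.errstate(over="ignore"):
        return np.exp(-(u**power))


def window_width(sigma_r: float, power: float, level: float = np.exp(-1.0)) -> float:
    """Full radial width of the annular window between crossings of ``level``.

    Closed form: the window drops to ``level`` at |r - r_E| =
    sigma*sqrt(2)*(-ln(level))^(1/(2P)).  At the conventional e^-1 contour
    this is sigma*sqrt(2) regardless of P, i.e. 2.83 deg full width for
    sigma = 1 — the nominal ~2.8 deg crescent width.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    half = sigma_r * np.sqrt(2.0) * (-np.log(level)) ** (1.0 / (2.0 * power))
    return 2.0 * half


def meridian_mask(grid: PolarGrid, halfwidth_deg: float = 30.0) -> np.ndarray:
    """Binary mask that removes a wedge around both vertical meridians.

    Pixels strictly within ``halfwidth_deg`` of rotation angle from the upper
    (theta = 0) or lower (theta = 180) vertical meridian get 0; all others 1.
    Each surviving lateral sector therefore spans 180 - 2*halfwidth rotation
    degrees (120 deg for the default 30 deg halfwidth).
    """
    if not 0.0 <= halfwidth_deg < 90.0:
        raise ValueError("halfwidth must be in [0, 90) deg")
    d_upper = np.minimum(grid.theta, 360.0 - grid.theta)
    d_lower = np.abs(grid.theta - 180.0)
    masked = (d_upper < halfwidth_deg) | (d_lower < halfwidth_deg)
    return (~masked).astype(float)


def _checkerboard(grid: PolarGrid, ang_cycles_per_deg: float = 0.1,
                  rad_cycles_per_deg: float = 1.0) -> np.ndarray:
    """Polar checkerboard carrier (+-1) for the localizer."""
    ang = np.sign(np.cos(2.0 * np.pi * ang_cycles_per_deg * grid.theta))
    rad = np.sign(np.cos(2.0 * np.pi * rad_cycles_per_deg * grid.r))
    return ang * rad


def compose_stimuli(
    grid: PolarGrid,
    params: GratingParams,
    localizer_power: float = 1000.0,
) -> dict[str, StimulusImage]:
    """Build the four stimulus images used by the experiment.

    center = grating modulation restricted to the windowed crescents;
    scotoma = its pixelwise complement (the crescents are blank);
    full_field = the unwindowed grating;
    localizer = high-contrast checkerboard inside a hard-edged (power 1000)
    copy of the same crescents.
    """
    full = radial_grating(grid, params)
    mod = full.modulation()
    w = radial_window(grid, params.r_E, params.sigma_r, params.power)
    m = meridian_mask(grid, params.mask_halfwidth)
    wm = w * m
    center = StimulusImage(params.B + mod * wm, "center", grid, params)
    scotoma = StimulusImage(params.B + mod * (1.0 - wm), "scotoma", grid, params)
    w_loc = radial_window(grid, params.r_E, params.sigma_r, localizer_power)
    carrier = _checkerboard(grid)
    loc = StimulusImage(
        params.B + params.B * params.C * carrier * (w_loc * m),
        "localizer",
        grid,
        params,
    )
    return {"full_field": full, "center": center, "scotoma": scotoma, "localizer": loc}


def flicker_sequence(duration_s: float, flicker_hz: float = 5.0,
                     refresh_hz: float = 60.0) -> np.ndarray:
    """Per-frame contrast signs for counterphase flicker.

    ``flicker_hz`` counts full contrast-reversal cycles per second (so 5 Hz
    at a 60 Hz refresh means a 12-frame period: 6 frames at +1 then 6 at -1).
    """
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    if flicker_hz <= 0:
        raise ValueError("flicker rate must be positive")
    if flicker_hz > refresh_hz / 2.0:
        raise ValueError("flicker rate cannot exceed half the refresh rate")
    n_frames = int(round(duration_s * refresh_hz))
    frames = np.arange(n_frames)
    # phase index: which half of the reversal cycle each frame falls in
    phase = np.floor(frames * 2.0 * flicker_hz / refresh_hz).astype(int)
    return np.where(phase % 2 == 0, 1, -1)


def save_png(img: StimulusImage, path: str | Path) -> None:
    """Write the luminance image as an 8-bit grayscale PNG."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    plt.imsave(str(path), img.values, cmap="gray", vmin=0.0, vmax=1.0)


def save_matrix(img: StimulusImage, path: str | Path) -> None:
    """Raw matrix dump (.npy) plus a JSON sidecar describing the geometry."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), img.values)
    sidecar = {
        "kind": img.kind,
        "width_px": img.grid.width_px,
        "height_px": img.grid.height_px,
        "deg_per_px": img.grid.deg_per_px,
        "origin": list(img.grid.origin),
        "params": {
            "B": img.params.B,
            "C": img.params.C,
            "f": img.params.f,
            "r_E": img.params.r_E,
            "sigma_r": img.params.sigma_r,
            "power": img.params.power,
            "mask_halfwidth": img.params.mask_halfwidth,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_matrix(path: str | Path) -> StimulusImage:
    """Inverse of :func:`save_matrix`."""
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = PolarGrid.make(
        meta["width_px"], meta["height_px"], meta["deg_per_px"],
        origin=tuple(meta["origin"]),
    )
    params = GratingParams(**meta["params"])
    return StimulusImage(values, meta["kind"], grid, params)
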