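"""Synthetic BOLD, behavioral, and gaze data with the structure the analyses assume.

The generator emulates one region of interest (ROI) of an event-related
scanning session: a runs x TRs x voxels array built from HRF-convolved
condition boxcars plus AR(1) Gaussian noise, per-trial filling-in reports
drawn at a ~50% rate, and fixation gaze traces with blinks and saccades.

Two properties matter for the scientific logic downstream and are built in
by construction:

* amplitude suppression — the full-field condition drives every voxel less
  than the center condition (lateral inhibition), detectable by the
  univariate GLM contrast;
* a mean-free multivoxel pattern — filling-in vs no-filling-in trials share
  the same ROI-mean amplitude but differ in a fixed zero-sum voxel pattern,
  so the univariate contrast is null while a linear classifier can separate
  the trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .protocol import DesignSpec, Event, TrialSequence, main_experiment_sequence

__all__ = [
    "SimParams",
    "RoiTimeSeries",
    "GazeRecord",
    "hrf",
    "convolve_boxcar",
    "simulate_bold",
    "simulate_gaze",
]


def hrf(t_s: np.ndarray | float) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak normalized to 1.

    Positive gamma (shape 6, scale 1, mode at 5 s) minus a 1/6-amplitude
    undershoot gamma (shape 16, mode at 15 s); zero for t < 0.
    """
    t = np.atleast_1d(np.asarray(t_s, dtype=float))
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    h[t < 0] = 0.0
    peak = stats.gamma.pdf(5.0, 6.0) - stats.gamma.pdf(5.0, 16.0) / 6.0
    out = h / peak
    return out if np.ndim(t_s) else float(out[0])


def convolve_boxcar(onsets_s: np.ndarray, duration_s: float, tr_s: float,
                    n_trs: int, oversample: int = 10) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at the TR grid."""
    dt = tr_s / oversample
    n_fine = n_trs * oversample
    neural = np.zeros(n_fine)
    for onset in np.atleast_1d(onsets_s):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + duration_s) / dt))
        neural[i0:min(i1, n_fine)] = 1.0
    kernel = hrf(np.arange(0, 32.0, dt))
    conv = np.convolve(neural, kernel)[:n_fine] * dt
    return conv[::oversample]


@dataclass(frozen=True)
class SimParams:
    """Generation parameters for one ROI's BOLD data.

    Amplitudes are in percent-signal units on a baseline of 100 (so 1.5
    means a 1.5% peak evoked response).  ``suppression`` is the decrement of
    the FullField amplitude relative to Center.  ``pattern_strength`` scales
    a fixed zero-sum, unit-RMS voxel pattern added on filling-in /
    no-filling-in trials; it moves no ROI-mean signal.  Noise is stationary
    AR(1) with marginal SD ``noise_sd`` and lag-1 correlation ``ar1_phi``.
    """

    n_voxels: int = 60
    amp: dict = field(default_factory=lambda: {"Center": 1.5, "Scotoma": 1.2,
                                               "Localizer": 3.0})
    suppression: float = 0.5
    pattern_strength: float = 0.04
    noise_sd: float = 1.0
    ar1_phi: float = 0.3
    baseline: float = 100.0
    p_fill: float = 0.5
    amp_jitter_sd: float = 0.1
    drift_per_tr: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not abs(self.ar1_phi) < 1:
            raise ValueError("|ar1_phi| must be < 1 for stationarity")
        if not 0 < self.p_fill < 1:
            raise ValueError("p_fill must be in (0, 1)")
        if self.n_voxels < 2:
            raise ValueError("need at least 2 voxels")

    def amplitude(self, condition: str) -> float:
        if condition == "FullField" and "FullField" not in self.amp:
            return self.amp["Center"] - self.suppression
        try:
            return self.amp[condition]
        except KeyError:
            raise KeyError(f"no amplitude defined for condition {condition!r}")


@dataclass
class RoiTimeSeries:
    """runs x TRs x voxels BOLD data with its design and trial labels."""

    data: np.ndarray
    sequence: TrialSequence
    labels: list[list[str]]  # per run, per Scotoma trial: 'fill' / 'nofill'
    roi_name: str = "ROI"
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be runs x TRs x voxels")
        if len(self.sequence.runs) != self.data.shape[0]:
            raise ValueError("run count mismatch between data and design")
        for run, labs in zip(self.sequence.runs, self.labels):
            n_scot = sum(ev.condition == "Scotoma" for ev in run.events)
            if n_scot != len(labs):
                raise ValueError("every Scotoma trial needs a fill/nofill label")

    @property
    def n_runs(self) -> int:
        return self.data.shape[0]

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[2]


def _zero_sum_patterns(n_voxels: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two orthogonal, zero-sum, unit-RMS voxel patterns."""
    a = rng.standard_normal(n_voxels)
    b = rng.standard_normal(n_voxels)
    a -= a.mean()
    b -= b.mean()
    b -= (b @ a) / (a @ a) * a
    a *= np.sqrt(n_voxels) / np.linalg.norm(a)
    b *= np.sqrt(n_voxels) / np.linalg.norm(b)
    return a, b


def _ar1_noise(shape: tuple[int, ...], sd: float, phi: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise along axis 0 with marginal SD ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal(shape)
    out = np.empty(shape)
    out[0] = eps[0] * sd
    for t in range(1, shape[0]):
        out[t] = phi * out[t - 1] + innov_sd * eps[t]
    return out


def simulate_bold(
    sequence: TrialSequence | None = None,
    params: SimParams | None = None,
    seed: int | np.random.Generator | None = None,
    roi_name: str = "ROI",
) -> RoiTimeSeries:
    """Simulate one ROI's event-related BOLD data.

    signal = baseline + sum over conditions of amplitude x HRF-convolved
    boxcar, with per-trial zero-sum pattern terms on labeled Scotoma trials,
    plus AR(1) noise.  Filling-in labels are Bernoulli(p_fill) per Scotoma
    trial.  Fully reproducible from the seed.
    """
    params = params or SimParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sequence is None:
        sequence = main_experiment_sequence(seed=rng)
    n_runs = len(sequence.runs)
    n_trs = sequence.runs[0].n_trs
    nv = params.n_voxels

    w_fill, w_nofill = _zero_sum_patterns(nv, rng)
    conditions = sorted({ev.condition for run in sequence.runs for ev in run.events})
    # per-voxel, per-condition amplitude gains (fixed across runs)
    gains = {c: 1.0 + params.amp_jitter_sd * rng.standard_normal(nv)
             for c in conditions}

    data = np.empty((n_runs, n_trs, nv))
    labels: list[list[str]] = []
    labeled_runs: list[DesignSpec] = []
    for ri, run in enumerate(sequence.runs):
        signal = np.full((run.n_trs, nv), params.baseline, dtype=float)
        if params.drift_per_tr:
            signal += params.drift_per_tr * np.arange(run.n_trs)[:, None]
        run_labels: list[str] = []
        new_events: list[Event] = []
        for ev in run.events:
            reg = convolve_boxcar(np.array([ev.onset_s]), ev.duration_s,
                                  run.tr_s, run.n_trs)
            amp_v = params.amplitude(ev.condition) * gains[ev.condition]
            if ev.condition == "Scotoma":
                lab = "fill" if rng.random() < params.p_fill else "nofill"
                run_labels.append(lab)
                w = w_fill if lab == "fill" else w_nofill
                amp_v = amp_v + params.pattern_strength * w
                new_events.append(replace(ev, response=lab))
            else:
                new_events.append(ev)
            signal += reg[:, None] * amp_v[None, :]
        signal += _ar1_noise((run.n_trs, nv), params.noise_sd, params.ar1_phi, rng)
        data[ri] = signal
        labels.append(run_labels)
        labeled_runs.append(DesignSpec(tr_s=run.tr_s, n_trs=run.n_trs,
                                       events=new_events, run_id=run.run_id))
    labeled_seq = TrialSequence(runs=labeled_runs, seed=sequence.seed)
    return RoiTimeSeries(data=data, sequence=labeled_seq, labels=labels,
                         roi_name=roi_name, tr_s=sequence.runs[0].tr_s)


@dataclass
class GazeRecord:
    """Timestamped gaze positions in degrees relative to fixation."""

    t_s: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.t_s) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.t_s)

    def valid_xy(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.valid.astype(bool)
        return self.x_deg[m], self.y_deg[m]


def simulate_gaze(
    sigma_h: float = 0.3,
    sigma_v: float = 0.25,
    rho: float = 0.1,
    rate_hz: float = 60.0,
    duration_s: float = 10.0,
    blink_rate: float = 0.1,
    saccade_rate: float = 0.05,
    drift_phi: float = 0.8,
    seed: int | np.random.Generator | None = None,
) -> GazeRecord:
    """Simulate a fixation trace with blinks and saccadic excursions.

    Fixational scatter is a slow bivariate AR(1) drift (lag-1 correlation
    ``drift_phi`` at the sampling rate) with stationary SDs ``sigma_h`` /
    ``sigma_v`` (deg) and horizontal-vertical correlation ``rho`` — smooth
    enough that ordinary drift stays far below a 30 deg/s velocity
    criterion.  Blinks (Poisson at ``blink_rate`` per second, ~0.2 s each)
    are flagged invalid with NaN positions; saccades (Poisson at
    ``saccade_rate``) jump 2-4 deg away for ~0.2 s, producing
    sample-to-sample velocities far above 30 deg/s at the transitions.
    """
    if sigma_h <= 0 or sigma_v <= 0:
        raise ValueError("position SDs must be positive")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if not 0 <= drift_phi < 1:
        raise ValueError("drift_phi must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    cov = np.array([[sigma_h**2, rho * sigma_h * sigma_v],
                    [rho * sigma_h * sigma_v, sigma_v**2]])
    L = np.linalg.cholesky(cov)
    innov = rng.standard_normal((n, 2)) @ L.T
    xy = np.empty((n, 2))
    xy[0] = innov[0]
    scale = np.sqrt(1.0 - drift_phi**2)
    for i in range(1, n):
        xy[i] = drift_phi * xy[i - 1] + scale * innov[i]
    x, y = xy[:, 0].copy(), xy[:, 1].copy()
    valid = np.ones(n, dtype=bool)

    def _events(rate: float) -> np.ndarray:
        k = rng.poisson(rate * duration_s)
        return np.sort(rng.uniform(0, duration_s, size=k))

    for onset in _events(blink_rate):
        i0 = int(onset * rate_hz)
        i1 = min(n, i0 + int(0.2 * rate_hz))
        valid[i0:i1] = False
        x[i0:i1] = np.nan
        y[i0:i1] = np.nan

    # ballistic out-and-back saccades: every intermediate step moves fast
    # enough that a 30 deg/s velocity criterion removes the whole excursion
    for onset in _events(saccade_rate):
        i0 = int(onset * rate_hz)
        angle = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(2.0, 4.0)
        profile = amp * np.array([0.5, 1.0, 0.5])
        i1 = min(n, i0 + len(profile))
        x[i0:i1] += profile[: i1 - i0] * np.cos(angle)
        y[i0:i1] += profile[: i1 - i0] * np.sin(angle)

    return GazeRecord(t_s=t, x_deg=x, y_deg=y, valid=valid, rate_hz=rate_hz)
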