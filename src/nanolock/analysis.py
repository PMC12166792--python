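"""Stabilization performance analysis: stability statistics, step-response
fitting, staircase calibration, and drift-reduction factors.

Operates on feedback-loop logs (lists of :class:`~nanolock.control.LoopRecord`
or DataFrames with ``e_x/e_y/e_z`` columns) and on position tracks
(arrays of shape (n, 3), nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .control import LoopRecord
from .estimation import AXES

__all__ = [
    "StabilityStats",
    "StepResponseFit",
    "CalibrationResult",
    "TrackStats",
    "StepFitError",
    "CalibrationError",
    "records_to_frame",
    "stability_stats",
    "fit_step_response",
    "calibrate",
    "drift_reduction",
]


class StepFitError(Exception):
    """Averaged step response does not decay; exponential fit is meaningless."""


class CalibrationError(Exception):
    """Staircase plateaus indistinguishable from noise (or zero amplitude)."""


def records_to_frame(records: Union[List[LoopRecord], pd.DataFrame]) -> pd.DataFrame:
    """Flatten loop records into a DataFrame (one row per iteration)."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        row = {"iteration": r.iteration, "t": r.timestamp}
        for i, ax in enumerate(AXES):
            row[f"e_{ax}"] = float(r.error_nm[i])
            row[f"valid_{ax}"] = bool(r.valid[i])
            row[f"cmd_{ax}"] = float(r.stage_command_nm[i])
            if r.true_position_nm is not None:
                row[f"true_{ax}"] = float(r.true_position_nm[i])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StabilityStats:
    """Per-axis error-signal σ plus centered rolling mean/σ series.

    The rolling window shrinks at the edges (``min_periods=1``) so the series
    has the same length as the log.  Invalid samples are excluded from σ and
    treated as missing in the rolling series.
    """

    sigma_nm: np.ndarray  # (3,)
    rolling_mean: pd.DataFrame
    rolling_std: pd.DataFrame
    window: int
    n_samples: int
    duration: float


def stability_stats(
    records: Union[List[LoopRecord], pd.DataFrame], window: int = 1000
) -> StabilityStats:
    """Error-signal standard deviations and rolling statistics of a loop log."""
    df = records_to_frame(records)
    if len(df) == 0:
        raise ValueError("empty log")
    sigma = np.zeros(3)
    masked = {}
    for i, ax in enumerate(AXES):
        e = df[f"e_{ax}"].to_numpy(dtype=float)
        v = (
            df[f"valid_{ax}"].to_numpy(dtype=bool)
            if f"valid_{ax}" in df
            else np.isfinite(e)
        )
        ok = e[v & np.isfinite(e)]
        sigma[i] = float(np.std(ok, ddof=1)) if ok.size > 1 else 0.0
        masked[f"e_{ax}"] = np.where(v, e, np.nan)
    mdf = pd.DataFrame(masked)
    roll = mdf.rolling(window, center=True, min_periods=1)
    return StabilityStats(
        sigma_nm=sigma,
        rolling_mean=roll.mean(),
        rolling_std=roll.std(),
        window=window,
        n_samples=len(df),
        duration=float(df["t"].iloc[-1] - df["t"].iloc[0]) if "t" in df else float(len(df) - 1),
    )


@dataclass
class StepResponseFit:
    """Exponential settling fit f(t) = α·exp(−(t−t0)/τ), zero before t0."""

    alpha: float
    t0: float
    tau: float
    residual_rms: float
    n_steps_averaged: int
    averaged_response: np.ndarray = field(repr=False, default=None)


def _exp_decay(t: np.ndarray, alpha: float, tau: float, t0: float) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    m = t >= t0
    out[m] = alpha * np.exp(-(t[m] - t0) / tau)
    return out


def fit_step_response(
    errors: Union[np.ndarray, List[LoopRecord]],
    disturbance_iters: Sequence[int],
    signs: Optional[Sequence[float]] = None,
    axis: str = "x",
    segment_len: Optional[int] = None,
) -> StepResponseFit:
    """Average sign-folded post-disturbance segments and fit the decay.

    Segments start at each disturbance, are folded by the disturbance sign
    (so positive and negative steps average constructively), truncated to the
    shortest inter-disturbance gap, and averaged.  The fit model is
    ``α·exp(−(t−t0)/τ)`` for t ≥ t0 and 0 before: t0 is found by grid search
    (it enters non-smoothly), (α, τ) by least squares at each candidate.
    """
    if isinstance(errors, list) and errors and isinstance(errors[0], LoopRecord):
        errors = records_to_frame(errors)[f"e_{axis}"].to_numpy(dtype=float)
    e = np.asarray(errors, dtype=float)
    times = list(disturbance_iters)
    if len(times) < 1:
        raise ValueError("need at least one disturbance")
    if signs is None:
        signs = [1.0] * len(times)
    if segment_len is None:
        gaps = np.diff(times)
        tail = e.size - times[-1]
        segment_len = int(min(gaps.min() if gaps.size else tail, tail))
    segs = []
    for t, s in zip(times, signs):
        seg = e[t : t + segment_len]
        if seg.size == segment_len and np.all(np.isfinite(seg)):
            segs.append(seg * np.sign(s))
    if not segs:
        raise ValueError("no complete post-disturbance segments")
    avg = np.mean(segs, axis=0)
    peak = int(np.argmax(avg))
    peak_val = float(avg[peak])
    tail_val = float(np.mean(avg[-max(2, segment_len // 5) :]))
    if peak_val <= 0 or tail_val > 0.5 * peak_val:
        raise StepFitError("averaged response does not decay after the disturbance")
    t = np.arange(segment_len, dtype=float)

    def _fit_at(t0: float):
        if (t >= t0).sum() < 3:
            return None
        try:
            popt, _ = curve_fit(
                lambda tt, a, tau: _exp_decay(tt, a, tau, t0),
                t,
                avg,
                p0=(peak_val, max(segment_len / 5.0, 1.0)),
                bounds=([0.0, 1e-6], [np.inf, np.inf]),
                maxfev=2000,
            )
        except RuntimeError:
            return None
        resid = avg - _exp_decay(t, popt[0], popt[1], t0)
        return float(np.sum(resid**2)), float(popt[0]), float(popt[1]), float(t0)

    # t0 enters non-smoothly (the model is exactly invariant to moving t0
    # within an inter-sample gap, with α re-absorbed): grid-search SSE, then
    # take the LARGEST t0 still achieving the minimal SSE — the latest onset
    # consistent with the data — located by bisecting the SSE jump.
    grid = np.linspace(0.0, peak + 1.0, 41)
    fits = [f for f in (_fit_at(t0) for t0 in grid) if f is not None]
    if not fits:
        raise StepFitError("exponential fit failed on the averaged response")
    best = min(fits, key=lambda f: f[0])
    tol = best[0] + 1e-12 * float(np.sum(avg**2)) + 1e-300
    lo, hi = best[3], peak + 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        f_mid = _fit_at(mid)
        if f_mid is not None and f_mid[0] <= tol:
            lo, best = mid, f_mid
        else:
            hi = mid
    sse, alpha, tau, t0 = best
    return StepResponseFit(
        alpha=alpha,
        t0=t0,
        tau=tau,
        residual_rms=float(np.sqrt(sse / segment_len)),
        n_steps_averaged=len(segs),
        averaged_response=avg,
    )


@dataclass
class CalibrationResult:
    """Scale factor mapping error-signal amplitude to physical nanometers."""

    scale: float
    ci: tuple
    staircase_amplitude_nm: float
    n_transitions: int


def calibrate(
    errors: Union[np.ndarray, List[LoopRecord]],
    disturbance_iters: Sequence[int],
    commanded_step_nm: float = 20.0,
    axis: str = "x",
    lead_in: int = 0,
) -> CalibrationResult:
    """Estimate the calibration factor from an open-loop ±step staircase.

    The log is split into plateaus between disturbances; each plateau is
    drift-detrended with a linear fit and the error level extrapolated to the
    shared transition time, so slow drift cancels from the plateau-to-plateau
    differences.  ``scale = commanded step / measured amplitude`` per
    transition; the result is the mean with a 95% t confidence interval.
    """
    if commanded_step_nm == 0:
        raise CalibrationError("staircase amplitude is zero")
    if isinstance(errors, list) and errors and isinstance(errors[0], LoopRecord):
        errors = records_to_frame(errors)[f"e_{axis}"].to_numpy(dtype=float)
    e = np.asarray(errors, dtype=float)
    times = [t for t in disturbance_iters if 0 < t < e.size]
    bounds = [lead_in] + times + [e.size]
    if len(bounds) - 1 < 4:
        raise ValueError("need at least 4 plateaus")
    fits = []  # (slope, intercept) per plateau, in absolute time
    resid_sq = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        tt = np.arange(a, b, dtype=float)
        seg = e[a:b]
        ok = np.isfinite(seg)
        if ok.sum() < 2:
            raise CalibrationError("plateau too short for detrending")
        coef = np.polyfit(tt[ok], seg[ok], 1)
        fits.append(coef)
        resid_sq.extend((seg[ok] - np.polyval(coef, tt[ok])) ** 2)
    noise_sigma = float(np.sqrt(np.mean(resid_sq)))
    diffs = []
    for k, t in enumerate(times):
        before = float(np.polyval(fits[k], t - 0.5))
        after = float(np.polyval(fits[k + 1], t - 0.5))
        diffs.append(after - before)
    amps = np.abs(np.asarray(diffs))
    med_amp = float(np.median(amps))
    if med_amp < 3.0 * noise_sigma / np.sqrt(max(len(amps), 1)) or med_amp <= 0:
        raise CalibrationError("plateaus indistinguishable from noise")
    scales = commanded_step_nm / amps
    n = scales.size
    mean = float(np.mean(scales))
    sd = float(np.std(scales, ddof=1)) if n > 1 else 0.0
    from scipy.stats import t as t_dist

    half = float(t_dist.ppf(0.975, n - 1)) * sd / np.sqrt(n) if n > 1 else np.inf
    return CalibrationResult(
        scale=mean,
        ci=(mean - half, mean + half),
        staircase_amplitude_nm=med_amp,
        n_transitions=n,
    )


@dataclass
class TrackStats:
    """RMS displacement of mean-centered tracks and stabilization factors.

    ``reduction_factor = rms(unstabilized) / rms(stabilized)`` per axis.  When
    the stabilized rms is numerically zero the factor is computed against the
    floor and flagged as a lower bound instead of reported as infinity.
    """

    rms_on_nm: np.ndarray
    rms_off_nm: np.ndarray
    reduction_factor: np.ndarray
    lower_bound: np.ndarray  # bool per axis


def drift_reduction(
    track_on: np.ndarray, track_off: np.ndarray, floor_nm: float = 1e-9
) -> TrackStats:
    """Per-axis rms of mean-centered tracks and off/on reduction factors.

    Both tracks must have equal length (equal duration and sampling).
    """
    on = np.asarray(track_on, dtype=float)
    off = np.asarray(track_off, dtype=float)
    if on.ndim == 1:
        on = on[:, None]
    if off.ndim == 1:
        off = off[:, None]
    if on.shape != off.shape:
        raise ValueError("tracks must have equal shape (equal duration/sampling)")
    on_c = on - on.mean(axis=0)
    off_c = off - off.mean(axis=0)
    rms_on = np.sqrt(np.mean(on_c**2, axis=0))
    rms_off = np.sqrt(np.mean(off_c**2, axis=0))
    lower = rms_on < floor_nm
    factor = rms_off / np.maximum(rms_on, floor_nm)
    return TrackStats(
        rms_on_nm=rms_on,
        rms_off_nm=rms_off,
        reduction_factor=factor,
        lower_bound=lower,
    )
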