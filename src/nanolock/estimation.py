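"""Displacement estimation from camera frames against per-axis reference stacks.

The stabilization camera delivers 2D intensity frames of a static reference
structure (holey carbon film, bead field, or a tile target).  Lateral (x, y)
displacement is read out by cross-correlating the current frame against a
stack of reference frames recorded at known stage positions; axial (z)
displacement is read out by comparing the *sorted* pixel-intensity profile of
the current frame against sorted profiles recorded through a small z range —
the shape of the intensity histogram changes continuously with defocus, which
encodes the axial position without requiring astigmatic optics.

For each axis the per-plane match values (cross-correlation, or negated mean
squared error for z) are min–max scaled to [0, 1] and a four-parameter
Gaussian is fitted; the fractional index of its center, converted through the
stack's step size, is the displacement in nanometers.  Error signals are
referenced to a *setpoint frame* captured before the reference stacks so that
drift during stack acquisition does not bias the hold position.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

AXES = ("x", "y", "z")

__all__ = [
    "AXES",
    "Frame",
    "SortedProfile",
    "AxisStackConfig",
    "ReferenceStack",
    "MatchCurve",
    "GaussianFit",
    "SetpointReference",
    "ErrorSignal3D",
    "EstimationError",
    "DegenerateFrameError",
    "FlatCurveError",
    "OutOfRangeError",
    "SetupError",
    "normalize_frame",
    "cross_correlation",
    "sorted_profile",
    "mse",
    "build_match_curve",
    "fit_gaussian_peak",
    "index_to_nm",
    "measure_setpoint_offsets",
    "estimate_error",
]


class EstimationError(Exception):
    """Base class for displacement-estimation failures."""


class DegenerateFrameError(EstimationError):
    """Frame cannot be normalized (all pixels zero)."""


class FlatCurveError(EstimationError):
    """Match curve is constant; min–max scaling is undefined."""


class OutOfRangeError(EstimationError):
    """Best match sits at a stack boundary — sample drifted beyond the stack range."""


class SetupError(EstimationError):
    """Setpoint referencing failed; stabilization cannot engage."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Frame:
    """One 2D intensity frame from the stabilization camera (or simulator).

    ``normalized`` means the pixel values sum to 1 (intensity normalization —
    each pixel divided by the sum over all pixels).
    """

    pixels: np.ndarray
    exposure_id: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"frame must be 2D, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("frame contains non-finite pixels")
        if np.any(self.pixels < 0):
            raise ValueError("frame contains negative pixels")
        if self.normalized:
            s = float(self.pixels.sum())
            if not math.isclose(s, 1.0, rel_tol=1e-9):
                raise ValueError(f"normalized frame sums to {s}, expected 1")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


@dataclass
class SortedProfile:
    """Pixel intensities of a frame in non-decreasing order (axial readout)."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("profile must be 1D")
        if np.any(np.diff(self.values) < 0):
            raise ValueError("profile values must be non-decreasing")


@dataclass
class AxisStackConfig:
    """Geometry of one per-axis reference stack.

    ``range_nm`` is the total span, symmetric about the starting stage
    position; ``step_nm`` the spacing between planes.  The plane count must be
    odd (so a center plane at displacement 0 exists) and at least 3.
    ``settle_buffer_ms`` is the extra wait after each stage move during
    acquisition (no effect in simulation other than being recorded).
    """

    axis: str
    range_nm: float = 200.0
    step_nm: float = 20.0
    settle_buffer_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be > 0")
        n_steps = self.range_nm / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("range_nm must be an integer multiple of step_nm")
        if self.n_planes < 3:
            raise ValueError("stack needs at least 3 planes")
        if self.n_planes % 2 == 0:
            raise ValueError("plane count must be odd so a center plane exists")

    @property
    def n_planes(self) -> int:
        return int(round(self.range_nm / self.step_nm)) + 1

    @property
    def positions_nm(self) -> np.ndarray:
        half = self.range_nm / 2.0
        return np.linspace(-half, half, self.n_planes)


@dataclass
class ReferenceStack:
    """Per-axis calibration records: frames (x, y) or sorted profiles (z).

    ``positions_nm`` are the stage positions of the entries relative to the
    stack center (strictly increasing, uniform spacing ``step_nm``, zero at
    ``center_index``).
    """

    axis: str
    entries: Sequence[Union[Frame, SortedProfile]]
    positions_nm: np.ndarray
    step_nm: float
    center_index: int

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=np.float64)
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}")
        if len(self.entries) != len(self.positions_nm):
            raise ValueError("one position per entry required")
        diffs = np.diff(self.positions_nm)
        if np.any(diffs <= 0):
            raise ValueError("positions_nm must be strictly increasing")
        if not np.allclose(diffs, self.step_nm, rtol=1e-9, atol=1e-9):
            raise ValueError("positions_nm must be uniformly spaced by step_nm")
        if abs(self.positions_nm[self.center_index]) > 1e-9 * max(self.step_nm, 1.0):
            raise ValueError("positions_nm[center_index] must be 0")
        for e in self.entries:
            if not e.normalized:
                raise ValueError("all stack entries must be normalized")
        want = SortedProfile if self.axis == "z" else Frame
        for e in self.entries:
            if not isinstance(e, want):
                raise TypeError(
                    f"{self.axis}-stack entries must be {want.__name__}"
                )

    @property
    def n_planes(self) -> int:
        return len(self.entries)

    @property
    def half_range_nm(self) -> float:
        return float(self.positions_nm[-1] - self.positions_nm[0]) / 2.0


@dataclass
class GaussianFit:
    """Result of the Gaussian peak fit on a scaled match curve."""

    center_index: float
    amplitude: float
    width: float
    offset: float
    converged: bool
    residual_rms: float


@dataclass
class MatchCurve:
    """Per-plane match values of one frame against one reference stack.

    ``raw`` holds cross-correlations (x, y) or mean squared errors (z);
    ``scaled`` is the min–max-scaled curve in [0, 1] after sign inversion for
    z (so the peak always marks the best-matching plane).
    """

    axis: str
    raw: np.ndarray
    scaled: np.ndarray
    fit: Optional[GaussianFit] = None


@dataclass
class SetpointReference:
    """Setpoint frame plus its measured displacement against each stack.

    Error signals are defined relative to the setpoint frame (captured before
    the reference stacks) rather than to the stack centers, which cancels any
    drift that occurred during stack acquisition.
    """

    setpoint_frame: Frame
    setpoint_profile: SortedProfile
    offsets_nm: np.ndarray  # (3,) in axis order x, y, z

    def __post_init__(self) -> None:
        self.offsets_nm = np.asarray(self.offsets_nm, dtype=np.float64)
        if self.offsets_nm.shape != (3,):
            raise ValueError("offsets_nm must be a 3-vector")
        if not np.all(np.isfinite(self.offsets_nm)):
            raise ValueError("offsets_nm must be finite")


@dataclass
class ErrorSignal3D:
    """Estimated displacement from the setpoint, per axis, in nm.

    Axes whose Gaussian fit failed (or whose match peak railed at a stack
    boundary) are flagged invalid; their values are NaN and must never be fed
    to the controller.
    """

    e_nm: np.ndarray  # (3,)
    valid: np.ndarray  # (3,) bool
    timestamp: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.e_nm = np.asarray(self.e_nm, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.e_nm.shape != (3,) or self.valid.shape != (3,):
            raise ValueError("e_nm and valid must be 3-vectors")

    @property
    def e_x(self) -> float:
        return float(self.e_nm[0])

    @property
    def e_y(self) -> float:
        return float(self.e_nm[1])

    @property
    def e_z(self) -> float:
        return float(self.e_nm[2])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def normalize_frame(frame: Frame) -> Frame:
    """Normalize intensity by dividing each pixel by the sum over all pixels.

    Idempotent; raises :class:`DegenerateFrameError` on an all-zero frame.
    """
    if frame.normalized:
        return frame
    s = float(frame.pixels.sum())
    if s <= 0.0:
        raise DegenerateFrameError("cannot normalize an all-zero frame")
    return Frame(frame.pixels / s, exposure_id=frame.exposure_id, normalized=True)


def cross_correlation(a: Frame, b: Frame) -> float:
    """Unshifted cross-correlation: the sum over all pixels of a·b.

    CC(a, b) = sum_ij a_ij * b_ij.  Symmetric; non-negative for non-negative
    frames.
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(
            f"shape mismatch: {a.pixels.shape} vs {b.pixels.shape}"
        )
    return float(np.sum(a.pixels * b.pixels))


def sorted_profile(frame: Frame) -> SortedProfile:
    """Flatten a normalized frame and sort its pixel values (non-decreasing).

    Invariant under any spatial permutation of the pixels — the axial readout
    depends only on the intensity histogram, not the geometry.
    """
    if not frame.normalized:
        raise ValueError("frame must be normalized before sorting")
    return SortedProfile(np.sort(frame.pixels, axis=None), normalized=True)


def mse(a: SortedProfile, b: SortedProfile) -> float:
    """Mean squared error between two equal-length 1D profiles."""
    if a.values.shape != b.values.shape:
        raise ValueError(
            f"length mismatch: {a.values.size} vs {b.values.size}"
        )
    d = a.values - b.values
    return float(np.mean(d * d))


def build_match_curve(frame: Frame, stack: ReferenceStack) -> MatchCurve:
    """Match a frame against every plane of one reference stack.

    x/y: cross-correlation per plane, then min–max scaling.
    z: MSE of sorted profiles per plane, inverted (×−1), then min–max scaling
    (the pseudo-inversion turns the convex MSE valley into a peak).
    """
    if not frame.normalized:
        raise ValueError("frame must be normalized")
    if stack.axis == "z":
        prof = sorted_profile(frame)
        raw = np.array([mse(prof, e) for e in stack.entries])
        signed = -raw
    else:
        raw = np.array([cross_correlation(frame, e) for e in stack.entries])
        signed = raw
    lo, hi = float(signed.min()), float(signed.max())
    if hi - lo <= 0.0:
        raise FlatCurveError(
            f"{stack.axis}-axis match curve is constant; scaling undefined"
        )
    scaled = (signed - lo) / (hi - lo)
    return MatchCurve(axis=stack.axis, raw=raw, scaled=scaled)


def _gauss(u: np.ndarray, amp: float, mu: float, width: float, off: float) -> np.ndarray:
    return amp * np.exp(-((u - mu) ** 2) / (2.0 * width**2)) + off


def _gauss_jac(u: np.ndarray, amp: float, mu: float, width: float, off: float) -> np.ndarray:
    d = u - mu
    g = np.exp(-(d**2) / (2.0 * width**2))
    return np.stack(
        [g, amp * g * d / width**2, amp * g * d**2 / width**3, np.ones_like(u)],
        axis=1,
    )


def fit_gaussian_peak(curve: MatchCurve) -> GaussianFit:
    """Fit A·exp(−(u−µ)²/(2w²)) + c to the scaled curve; µ is the displacement.

    The fit uses the full curve, initialized at the argmax with width
    plane_count/4, center bounded to [0, plane_count−1].  An argmax at either
    end of the curve means the sample drifted beyond the stack range and
    raises :class:`OutOfRangeError`.  Non-convergence is reported via
    ``converged=False`` (the caller skips actuation for that axis).
    """
    y = np.asarray(curve.scaled, dtype=np.float64)
    n = y.size
    k = int(np.argmax(y))  # ties broken toward the lowest index
    if k == 0 or k == n - 1:
        raise OutOfRangeError(
            f"{curve.axis}-axis match peak at stack boundary (index {k})"
        )
    u = np.arange(n, dtype=np.float64)
    p0 = (float(y[k] - y.min()), float(k), n / 4.0, float(y.min()))
    # Unbounded Levenberg–Marquardt: broad match curves make (A, w, c)
    # jointly near-degenerate, where bounded trust-region solvers crawl; LM
    # handles the flat valley quickly.  The center constraint is enforced
    # post-fit instead.
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _gauss, u, y, p0=p0, jac=_gauss_jac, method="lm", maxfev=10000
            )
    except (RuntimeError, ValueError):
        return GaussianFit(
            center_index=float("nan"),
            amplitude=float("nan"),
            width=float("nan"),
            offset=float("nan"),
            converged=False,
            residual_rms=float("nan"),
        )
    amp, mu, width, off = (float(v) for v in popt)
    width = abs(width)  # the model depends on w² only; report the positive root
    resid = y - _gauss(u, amp, mu, width, off)
    converged = bool(np.all(np.isfinite(popt))) and 0.0 <= mu <= float(n - 1)
    fit = GaussianFit(
        center_index=mu,
        amplitude=amp,
        width=width,
        offset=off,
        converged=converged,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )
    curve.fit = fit
    return fit


def index_to_nm(fit: GaussianFit, stack: ReferenceStack) -> float:
    """Convert a fractional stack index to nanometers of displacement.

    Positive means the sample is displaced toward increasing stage coordinate.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; no displacement available")
    return (fit.center_index - stack.center_index) * stack.step_nm


def _estimate_axis_nm(frame: Frame, stack: ReferenceStack) -> tuple[float, GaussianFit]:
    curve = build_match_curve(frame, stack)
    fit = fit_gaussian_peak(curve)
    if not fit.converged:
        raise EstimationError(f"{stack.axis}-axis Gaussian fit did not converge")
    return index_to_nm(fit, stack), fit


def measure_setpoint_offsets(
    setpoint: Frame, stacks: Mapping[str, ReferenceStack]
) -> SetpointReference:
    """Measure the setpoint frame's displacement against each reference stack.

    The offsets become the zero of the error signal: subsequent errors are
    ``estimate − offset``.  Any axis failure (fit failure, peak beyond the
    stack range) aborts engagement with :class:`SetupError`.
    """
    sp = normalize_frame(setpoint)
    offsets = np.zeros(3)
    for i, axis in enumerate(AXES):
        stack = stacks[axis]
        try:
            off, _ = _estimate_axis_nm(sp, stack)
        except EstimationError as exc:
            raise SetupError(
                f"setpoint referencing failed on axis {axis}: {exc}"
            ) from exc
        if abs(off) >= stack.half_range_nm:
            raise SetupError(
                f"setpoint offset {off:.1f} nm exceeds half the {axis}-stack range"
            )
        offsets[i] = off
    return SetpointReference(
        setpoint_frame=sp,
        setpoint_profile=sorted_profile(sp),
        offsets_nm=offsets,
    )


def estimate_error(
    frame: Frame,
    stacks: Mapping[str, ReferenceStack],
    setpoint: SetpointReference,
    calibration: Sequence[float] = (1.0, 1.0, 1.0),
    timestamp: Optional[float] = None,
) -> ErrorSignal3D:
    """Estimate the 3D error signal of a frame relative to the setpoint.

    Per axis: ``e = calibration × (index_to_nm(fit) − setpoint_offset)``.
    Calibration factors map error-signal amplitude to physical nanometers
    (typically determined from a ±20 nm staircase; values near 1).  Axes whose
    fit fails are flagged invalid with NaN, never silently zeroed.
    """
    cal = np.asarray(calibration, dtype=np.float64)
    if cal.shape != (3,):
        raise ValueError("calibration must be a 3-vector")
    f = normalize_frame(frame)
    e = np.full(3, np.nan)
    valid = np.zeros(3, dtype=bool)
    diagnostics: dict = {}
    for i, axis in enumerate(AXES):
        try:
            raw_nm, fit = _estimate_axis_nm(f, stacks[axis])
        except EstimationError as exc:
            diagnostics[axis] = {"message": str(exc)}
            continue
        e[i] = cal[i] * (raw_nm - setpoint.offsets_nm[i])
        valid[i] = True
        diagnostics[axis] = {
            "center_index": fit.center_index,
            "width": fit.width,
            "residual_rms": fit.residual_rms,
        }
    return ErrorSignal3D(e_nm=e, valid=valid, timestamp=timestamp, diagnostics=diagnostics)
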