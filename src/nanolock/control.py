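"""Discrete-time feedback: PI control with a small second-order integrator.

Each loop iteration the estimator produces a 3D error signal (displacement
from the setpoint, nm); the controller commands the stage by

    correction = −(kp·e + ki·Σe + kii·ΣΣe)

per axis, clamped to a per-iteration output limit.  The second-order
integrator (integral of the summed error) improves rejection of persistent,
accelerating drifts such as those driven by laboratory-temperature swings; it
is kept a small fraction of the first-order term.  The formulation is
per-iteration (no dt scaling): the physical loop runs at a fixed rate, so
gains are dimensionless.

Axes whose estimate is invalid this iteration produce zero correction and
frozen integrators — the loop never actuates on a failed fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Mapping, Optional, Sequence

import numpy as np

from .estimation import (
    AXES,
    AxisStackConfig,
    ErrorSignal3D,
    EstimationError,
    ReferenceStack,
    SetpointReference,
    estimate_error,
    measure_setpoint_offsets,
    normalize_frame,
)

__all__ = [
    "ControllerGains",
    "ControllerState",
    "LoopRecord",
    "ControlFaultError",
    "EngageError",
    "LoopAbortError",
    "controller_update",
    "engage",
    "run_closed_loop",
]

# Defaults chosen from the simulated step response of the default virtual
# stage: settle within ~5 iterations without overshoot beyond 30%.
DEFAULT_KP = 0.75
DEFAULT_KI = 0.2
DEFAULT_KII = 0.005


class ControlFaultError(Exception):
    """Non-finite error marked valid — the estimator contract is broken."""


class EngageError(Exception):
    """Engagement failed; no partial state is left behind."""


class LoopAbortError(Exception):
    """Persistent estimation failure aborted the loop.

    Carries the records accumulated so far in ``.records``.
    """

    def __init__(self, message: str, records: List["LoopRecord"]):
        super().__init__(message)
        self.records = records


@dataclass
class ControllerGains:
    """Per-iteration dimensionless gains plus actuation/travel clamps.

    ``kii`` should stay well below ``ki`` (a small second-order portion);
    ``output_limit_nm`` bounds any single correction, ``stage_limit_nm`` the
    integrator magnitude (anti-windup) and absolute travel.
    """

    kp: float = DEFAULT_KP
    ki: float = DEFAULT_KI
    kii: float = DEFAULT_KII
    output_limit_nm: float = 200.0
    stage_limit_nm: float = 50000.0

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0 or self.kii < 0:
            raise ValueError("gains must be non-negative")
        if self.output_limit_nm <= 0 or self.stage_limit_nm <= 0:
            raise ValueError("limits must be positive")

    @classmethod
    def disengaged(cls) -> "ControllerGains":
        """Zero gains: the stage is never actuated (open loop / calibration)."""
        return cls(kp=0.0, ki=0.0, kii=0.0)


@dataclass
class ControllerState:
    """Integrator accumulators; reset to zero on engage."""

    integral: np.ndarray = field(default_factory=lambda: np.zeros(3))
    double_integral: np.ndarray = field(default_factory=lambda: np.zeros(3))
    last_command_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def reset(self) -> None:
        self.integral[:] = 0.0
        self.double_integral[:] = 0.0
        self.last_command_nm[:] = 0.0


@dataclass
class LoopRecord:
    """One feedback-loop iteration: error, command, and diagnostics."""

    iteration: int
    timestamp: float
    error_nm: np.ndarray
    valid: np.ndarray
    stage_command_nm: np.ndarray
    true_position_nm: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _tolist(v):
            return None if v is None else [float(x) for x in np.asarray(v).ravel()]

        return {
            "iteration": int(self.iteration),
            "timestamp": float(self.timestamp),
            "error_nm": _tolist(self.error_nm),
            "valid": [bool(b) for b in self.valid],
            "stage_command_nm": _tolist(self.stage_command_nm),
            "true_position_nm": _tolist(self.true_position_nm),
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LoopRecord":
        true = d.get("true_position_nm")
        return cls(
            iteration=int(d["iteration"]),
            timestamp=float(d["timestamp"]),
            error_nm=np.asarray(d["error_nm"], dtype=np.float64),
            valid=np.asarray(d["valid"], dtype=bool),
            stage_command_nm=np.asarray(d["stage_command_nm"], dtype=np.float64),
            true_position_nm=None if true is None else np.asarray(true, dtype=np.float64),
            diagnostics=d.get("diagnostics", {}),
        )


def controller_update(
    error: ErrorSignal3D, state: ControllerState, gains: ControllerGains
) -> np.ndarray:
    """One controller step: update integrators, return the correction (nm).

    Per valid axis: integral += e; double_integral += integral;
    correction = −(kp·e + ki·integral + kii·double_integral), clamped to the
    output limit.  Invalid axes: zero correction, integrators untouched.
    """
    correction = np.zeros(3)
    lim_i = gains.stage_limit_nm
    for i in range(3):
        if not error.valid[i]:
            continue
        e = float(error.e_nm[i])
        if not np.isfinite(e):
            raise ControlFaultError(
                f"axis {AXES[i]}: non-finite error marked valid"
            )
        state.integral[i] = float(np.clip(state.integral[i] + e, -lim_i, lim_i))
        state.double_integral[i] = float(
            np.clip(state.double_integral[i] + state.integral[i], -lim_i, lim_i)
        )
        c = -(
            gains.kp * e
            + gains.ki * state.integral[i]
            + gains.kii * state.double_integral[i]
        )
        correction[i] = float(np.clip(c, -gains.output_limit_nm, gains.output_limit_nm))
    state.last_command_nm = correction.copy()
    return correction


def engage(
    mic,
    stack_configs: Mapping[str, AxisStackConfig],
) -> tuple:
    """Capture the setpoint frame, acquire all reference stacks, reference.

    Sequence: (1) save a camera frame as the setpoint; (2) acquire a reference
    stack for every axis by stepping the stage over its symmetric range;
    (3) return the stage to the starting position; (4) measure the setpoint
    frame's offsets against the stacks and zero the integrators.  A failure
    mid-acquisition returns the stage to start and raises :class:`EngageError`
    — nothing is engaged.

    Returns ``(stacks, setpoint_reference, controller_state)``.
    """
    start = mic.stage_position_nm
    setpoint_frame = normalize_frame(mic.acquire_frame())
    stacks: dict = {}
    try:
        for axis in AXES:
            stacks[axis] = mic.acquire_reference_stack(stack_configs[axis])
            mic.move_to(start)
    except Exception as exc:
        mic.move_to(start)
        raise EngageError(f"reference-stack acquisition failed: {exc}") from exc
    mic.move_to(start)
    try:
        setpoint = measure_setpoint_offsets(setpoint_frame, stacks)
    except EstimationError as exc:
        raise EngageError(str(exc)) from exc
    state = ControllerState()
    state.reset()
    return stacks, setpoint, state


def run_closed_loop(
    mic,
    stacks: Mapping[str, ReferenceStack],
    setpoint: SetpointReference,
    gains: ControllerGains,
    n_iterations: int,
    calibration: Sequence[float] = (1.0, 1.0, 1.0),
    state: Optional[ControllerState] = None,
    disturbance_fn: Optional[Callable[[int], Optional[np.ndarray]]] = None,
    max_invalid_streak: int = 10,
    log_writer=None,
) -> List[LoopRecord]:
    """Run the feedback loop: acquire → estimate → correct → move, n times.

    ``disturbance_fn(i)``, if given, may return a stage offset injected at the
    start of iteration ``i`` (used by the staircase/step-response protocols).
    If every axis is invalid for more than ``max_invalid_streak`` consecutive
    iterations the loop aborts with :class:`LoopAbortError` carrying the
    partial log.  Deterministic given the microscope's seeds.
    """
    if state is None:
        state = ControllerState()
    records: List[LoopRecord] = []
    invalid_streak = 0
    for i in range(n_iterations):
        if disturbance_fn is not None:
            offset = disturbance_fn(i)
            if offset is not None:
                mic.move_by(offset)
        frame = mic.acquire_frame()
        err = estimate_error(
            frame, stacks, setpoint, calibration=calibration, timestamp=float(i)
        )
        correction = controller_update(err, state, gains)
        mic.move_by(correction)
        rec = LoopRecord(
            iteration=i,
            timestamp=float(i),
            error_nm=err.e_nm.copy(),
            valid=err.valid.copy(),
            stage_command_nm=mic.stage_position_nm,
            true_position_nm=getattr(mic, "true_position_nm", None),
            diagnostics=err.diagnostics,
        )
        records.append(rec)
        if log_writer is not None:
            log_writer.write(rec)
        if not err.valid.any():
            invalid_streak += 1
            if invalid_streak > max_invalid_streak:
                raise LoopAbortError(
                    f"all axes invalid for {invalid_streak} consecutive iterations",
                    records,
                )
        else:
            invalid_streak = 0
    return records
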