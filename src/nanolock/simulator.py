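"""Virtual widefield microscope for closed-loop testing without hardware.

Renders parametric reference structures (holey carbon film, sparse bead
field, 10 µm tile target) on a supersampled grid, area-bins to camera
pixels, then applies a known 3D sample position (lateral subpixel shift as an
exact Fourier translation; axial defocus as an isotropic Gaussian blur whose
width grows with |z|) and adds shot and read noise.  A virtual piezo stage
with a settle model and pluggable drift closes the loop.

The defocus kernel follows a Gaussian-beam-style broadening
``w(z) = w0 · sqrt(1 + (z/z_R)²)``: it is not a physical diffraction PSF, but
it provides the smooth, monotone dependence of the intensity histogram on
|z − z_focus| that the axial estimator exploits, including the empirically
relevant property that histogram sensitivity to z vanishes exactly in focus
(dw/dz = 0 at z = 0) and is restored at moderate defocus.

Lateral translation is applied in the Fourier domain.  Real-space
interpolation (spline shifting) low-passes the image by an amount that
depends on the fractional part of the shift; because the match statistic
compares sum-normalized frames whose L2 norms differ, that phase-dependent
smoothing masquerades as displacement.  Fourier translation is exact for the
band-limited binned map, norm-preserving, and free of that bias; the rendered
margin is wide enough that periodic wrap-around never reaches the ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .estimation import (
    AXES,
    AxisStackConfig,
    Frame,
    ReferenceStack,
    normalize_frame,
    sorted_profile,
)

__all__ = [
    "VirtualScene",
    "StageState",
    "DriftModel",
    "NoiseModel",
    "VirtualMicroscope",
    "SceneError",
    "render_scene",
    "image_at",
    "stage_step",
    "acquire_reference_stack_sim",
    "staircase_protocol",
]

PATTERNS = ("holey_carbon", "bead_field", "tile_target")


class SceneError(Exception):
    """Invalid scene parameters or out-of-range request."""


@dataclass
class VirtualScene:
    """Parametric ground-truth sample pattern and imaging geometry.

    Lengths are µm for scene geometry (hole/tile/bead sizes) and nm for
    pixel sizes and the defocus model, matching the field's mixed usage.
    ``fov_px`` is the camera ROI (rows, cols); ``margin_px`` extra camera
    pixels rendered on each side so lateral shifts never expose the edge.
    """

    pattern: str = "holey_carbon"
    fov_px: tuple = (160, 160)  # (rows, cols)
    pixel_size_nm: tuple = (75.0, 75.0)  # (x, y); x maps to columns
    # holey carbon: disc lattice of reduced reflectivity
    hole_diameter_um: float = 2.0
    hole_spacing_um: float = 2.0  # edge-to-edge distance between holes
    hole_contrast: float = 0.35  # intensity inside a hole relative to the film
    # bead field
    n_beads: int = 25
    bead_sigma_nm: float = 120.0
    bead_amplitude: float = 3.0
    # tile target
    tile_pitch_um: float = 10.0
    line_width_um: float = 0.6
    line_contrast: float = 0.3
    # image formation
    base_intensity: float = 1.0
    background: float = 0.08
    supersample: int = 4
    margin_px: int = 32
    psf_w0_nm: float = 250.0  # in-focus blur kernel sigma
    psf_zr_nm: float = 1000.0  # defocus depth scale
    z_travel_nm: float = 8000.0
    seed: int = 0

    _cache: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _fft_cache: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise SceneError(f"unknown pattern {self.pattern!r}; choose from {PATTERNS}")
        for name in (
            "hole_diameter_um",
            "hole_spacing_um",
            "tile_pitch_um",
            "line_width_um",
            "bead_sigma_nm",
            "psf_w0_nm",
            "psf_zr_nm",
        ):
            if getattr(self, name) <= 0:
                raise SceneError(f"{name} must be positive")
        if self.supersample < 1:
            raise SceneError("supersample must be >= 1")

    @property
    def kernel_width_nm(self) -> Callable[[float], float]:
        w0, zr = self.psf_w0_nm, self.psf_zr_nm
        return lambda z: w0 * float(np.sqrt(1.0 + (z / zr) ** 2))


def _ss_coords(scene: VirtualScene) -> tuple:
    """Supersampled pixel-center coordinates in nm (x along cols, y along rows)."""
    ss = scene.supersample
    rows = (scene.fov_px[0] + 2 * scene.margin_px) * ss
    cols = (scene.fov_px[1] + 2 * scene.margin_px) * ss
    px_x, px_y = scene.pixel_size_nm
    x = (np.arange(cols) + 0.5) * px_x / ss
    y = (np.arange(rows) + 0.5) * px_y / ss
    return y[:, None], x[None, :], rows, cols


def render_scene(scene: VirtualScene) -> np.ndarray:
    """Render the supersampled ground-truth reflectivity/intensity map.

    Supersampled ≥ 4× relative to camera pixels so subpixel lateral shifts
    can be applied before binning.  Deterministic given (parameters, seed).
    """
    if scene._cache is not None:
        return scene._cache
    yy, xx, rows, cols = _ss_coords(scene)
    px_x, px_y = scene.pixel_size_nm
    ss_px_nm = min(px_x, px_y) / scene.supersample
    rng = np.random.default_rng(scene.seed)
    if scene.pattern == "holey_carbon":
        if scene.hole_diameter_um * 1000.0 < 2 * ss_px_nm:
            raise SceneError("hole diameter below 2 supersampled pixels")
        period = (scene.hole_diameter_um + scene.hole_spacing_um) * 1000.0
        radius = scene.hole_diameter_um * 1000.0 / 2.0
        # irrational-ish lattice phase so holes are never pixel-aligned
        phase = rng.uniform(0.3, 0.7, size=2) * period
        dx = np.abs((xx - phase[0] + period / 2) % period - period / 2)
        dy = np.abs((yy - phase[1] + period / 2) % period - period / 2)
        inside = (dx**2 + dy**2) < radius**2
        img = np.where(inside, scene.hole_contrast, 1.0)
    elif scene.pattern == "bead_field":
        if scene.bead_sigma_nm < 2 * ss_px_nm:
            raise SceneError("bead size below 2 supersampled pixels")
        img = np.full((rows, cols), 0.1)
        x_max = float(xx.max())
        y_max = float(yy.max())
        for _ in range(scene.n_beads):
            cx = rng.uniform(0.1 * x_max, 0.9 * x_max)
            cy = rng.uniform(0.1 * y_max, 0.9 * y_max)
            img = img + scene.bead_amplitude * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * scene.bead_sigma_nm**2)
            )
    else:  # tile_target
        if scene.line_width_um * 1000.0 < 2 * ss_px_nm:
            raise SceneError("line width below 2 supersampled pixels")
        pitch = scene.tile_pitch_um * 1000.0
        width = scene.line_width_um * 1000.0
        phase = rng.uniform(0.2, 0.8, size=2) * pitch
        on_line = ((xx - phase[0]) % pitch < width) | ((yy - phase[1]) % pitch < width)
        img = np.where(on_line, scene.line_contrast, 1.0)
    scene._cache = img
    return img


@dataclass
class NoiseModel:
    """Shot + read noise for a 16-bit camera.

    ``photon_peak`` is the expected count at unit pattern intensity; the
    default puts the brightest pixel around 70% of saturation, matching
    typical operation at 60–80% of the sensor's dynamic range.
    """

    photon_peak: float = 45000.0
    read_sigma: float = 10.0
    offset: float = 100.0
    saturation: float = 65535.0
    seed: int = 0

    def apply(self, mean_img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        counts = rng.poisson(np.clip(mean_img, 0, None) * self.photon_peak).astype(
            np.float64
        )
        counts += rng.normal(0.0, self.read_sigma, size=counts.shape) + self.offset
        return np.clip(counts, 0.0, self.saturation)


def image_at(
    scene: VirtualScene,
    position_nm: Sequence[float],
    noise: Optional[NoiseModel] = None,
    rng: Optional[np.random.Generator] = None,
    exposure_id: int = 0,
) -> Frame:
    """Form a camera frame of the scene at a true sample position (x, y, z) nm.

    The supersampled ground-truth map is area-binned to camera pixels once;
    lateral displacement is then an exact Fourier-domain translation of the
    binned map (cached FFT), z applies the defocus blur kernel, and noise is
    added last.
    """
    pos = np.asarray(position_nm, dtype=np.float64)
    if pos.shape != (3,):
        raise ValueError("position_nm must be a 3-vector")
    px_x, px_y = scene.pixel_size_nm
    ss = scene.supersample
    margin_nm_x = scene.margin_px * px_x / 2.0
    margin_nm_y = scene.margin_px * px_y / 2.0
    if abs(pos[0]) > margin_nm_x or abs(pos[1]) > margin_nm_y:
        raise SceneError(
            f"lateral position {pos[:2]} nm exceeds scene margin "
            f"({margin_nm_x:.0f}, {margin_nm_y:.0f}) nm"
        )
    if abs(pos[2]) > scene.z_travel_nm:
        raise SceneError("z position outside simulated travel")
    m = scene.margin_px
    rows_t = scene.fov_px[0] + 2 * m
    cols_t = scene.fov_px[1] + 2 * m
    if scene._fft_cache is None:
        base = render_scene(scene)
        binned = base.reshape(rows_t, ss, cols_t, ss).mean(axis=(1, 3))
        scene._fft_cache = np.fft.rfft2(binned)
    # sample moved +x → image content moves toward increasing column index
    shift_px = (pos[1] / px_y, pos[0] / px_x)
    shifted = np.fft.irfft2(
        ndimage.fourier_shift(scene._fft_cache, shift_px, n=cols_t),
        s=(rows_t, cols_t),
    )
    w = scene.kernel_width_nm(float(pos[2]))
    blurred = ndimage.gaussian_filter(shifted, sigma=(w / px_y, w / px_x), mode="nearest")
    img = blurred[m : m + scene.fov_px[0], m : m + scene.fov_px[1]]
    img = np.clip(img * scene.base_intensity + scene.background, 0.0, None)
    if noise is not None:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        img = noise.apply(img, rng)
    return Frame(img, exposure_id=exposure_id)


# ---------------------------------------------------------------------------
# Drift and stage
# ---------------------------------------------------------------------------


class DriftModel:
    """Deterministic-given-seed sample drift, advanced one tick per frame.

    Kinds: none, linear (nm/iteration), random_walk (per-step σ),
    sinusoidal (amplitude + period in iterations — emulating periodic
    temperature-coupled stage movements), composite (sum of components).
    """

    def __init__(
        self,
        kind: str = "none",
        rate_nm: Sequence[float] = (0.0, 0.0, 0.0),
        sigma_nm: Sequence[float] = (0.0, 0.0, 0.0),
        amplitude_nm: Sequence[float] = (0.0, 0.0, 0.0),
        period_iters: float = 1000.0,
        components: Optional[List["DriftModel"]] = None,
        seed: int = 0,
    ) -> None:
        if kind not in ("none", "linear", "random_walk", "sinusoidal", "composite"):
            raise ValueError(f"unknown drift kind {kind!r}")
        self.kind = kind
        self.rate_nm = np.asarray(rate_nm, dtype=np.float64)
        self.sigma_nm = np.asarray(sigma_nm, dtype=np.float64)
        self.amplitude_nm = np.asarray(amplitude_nm, dtype=np.float64)
        self.period_iters = float(period_iters)
        self.components = components or []
        self.seed = int(seed)
        self.reset()

    def reset(self) -> None:
        self._rng = np.random.default_rng(self.seed)
        self._tick = 0
        for c in self.components:
            c.reset()

    def step(self) -> np.ndarray:
        """Return the drift increment (3,) for the next tick."""
        i = self._tick
        self._tick += 1
        if self.kind == "none":
            return np.zeros(3)
        if self.kind == "linear":
            return self.rate_nm.copy()
        if self.kind == "random_walk":
            return self._rng.normal(0.0, 1.0, size=3) * self.sigma_nm
        if self.kind == "sinusoidal":
            w = 2.0 * np.pi / self.period_iters
            return self.amplitude_nm * (np.sin(w * (i + 1)) - np.sin(w * i))
        return sum((c.step() for c in self.components), np.zeros(3))

    @classmethod
    def none(cls) -> "DriftModel":
        return cls("none")

    @classmethod
    def linear(cls, rate_nm: Sequence[float]) -> "DriftModel":
        return cls("linear", rate_nm=rate_nm)

    @classmethod
    def random_walk(cls, sigma_nm: Sequence[float], seed: int = 0) -> "DriftModel":
        return cls("random_walk", sigma_nm=sigma_nm, seed=seed)

    @classmethod
    def sinusoidal(
        cls, amplitude_nm: Sequence[float], period_iters: float
    ) -> "DriftModel":
        return cls("sinusoidal", amplitude_nm=amplitude_nm, period_iters=period_iters)

    @classmethod
    def composite(cls, components: List["DriftModel"]) -> "DriftModel":
        return cls("composite", components=components)


@dataclass
class StageState:
    """Virtual piezo stage: commanded vs. actual position plus sample drift.

    The actual position relaxes toward the commanded one by ``settle_fraction``
    per call (1.0 = instant settle).  The sample's true position is
    ``actual + drift``.
    """

    commanded_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    actual_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    drift_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    settle_fraction: float = 1.0
    travel_limit_nm: float = 50000.0
    clamped: bool = False

    def __post_init__(self) -> None:
        self.commanded_nm = np.asarray(self.commanded_nm, dtype=np.float64).copy()
        self.actual_nm = np.asarray(self.actual_nm, dtype=np.float64).copy()
        self.drift_nm = np.asarray(self.drift_nm, dtype=np.float64).copy()
        if not 0.0 < self.settle_fraction <= 1.0:
            raise ValueError("settle_fraction must be in (0, 1]")

    @property
    def true_position_nm(self) -> np.ndarray:
        return self.actual_nm + self.drift_nm


def stage_step(
    state: StageState,
    command_nm: Sequence[float],
    drift: Optional[DriftModel] = None,
) -> StageState:
    """Advance the stage one tick: relative move, settle relaxation, drift.

    Commands beyond the travel limit are clamped with a warning flag rather
    than raising, so a runaway loop degrades gracefully.
    """
    delta = np.asarray(command_nm, dtype=np.float64)
    target = state.commanded_nm + delta
    lim = state.travel_limit_nm
    if np.any(np.abs(target) > lim):
        warnings.warn("stage command clamped at travel limit", stacklevel=2)
        state.clamped = True
        target = np.clip(target, -lim, lim)
    state.commanded_nm = target
    state.actual_nm = state.actual_nm + state.settle_fraction * (
        state.commanded_nm - state.actual_nm
    )
    if drift is not None:
        state.drift_nm = state.drift_nm + drift.step()
    return state


class VirtualMicroscope:
    """Scene + stage + drift + noise behind a minimal hardware-like interface.

    One drift tick elapses per acquired frame (the feedback loop's clock).
    All randomness flows from explicit seeds, so identical configurations
    reproduce identical frame streams.
    """

    def __init__(
        self,
        scene: VirtualScene,
        noise: Optional[NoiseModel] = None,
        drift: Optional[DriftModel] = None,
        stage: Optional[StageState] = None,
        start_position_nm: Sequence[float] = (0.0, 0.0, 0.0),
        seed: int = 0,
    ) -> None:
        self.scene = scene
        self.noise = noise
        self.drift = drift or DriftModel.none()
        self.drift.reset()
        self.stage = stage or StageState()
        start = np.asarray(start_position_nm, dtype=np.float64)
        self.stage.commanded_nm = start.copy()
        self.stage.actual_nm = start.copy()
        self.rng = np.random.default_rng(seed)
        self._exposure = 0

    @property
    def stage_position_nm(self) -> np.ndarray:
        return self.stage.commanded_nm.copy()

    @property
    def true_position_nm(self) -> np.ndarray:
        return self.stage.true_position_nm.copy()

    def move_by(self, delta_nm: Sequence[float]) -> None:
        stage_step(self.stage, delta_nm, drift=None)

    def move_to(self, position_nm: Sequence[float]) -> None:
        self.move_by(np.asarray(position_nm, dtype=np.float64) - self.stage.commanded_nm)

    def acquire_frame(self) -> Frame:
        # a drift tick elapses during each exposure
        stage_step(self.stage, (0.0, 0.0, 0.0), drift=self.drift)
        self._exposure += 1
        return image_at(
            self.scene,
            self.stage.true_position_nm,
            noise=self.noise,
            rng=self.rng,
            exposure_id=self._exposure,
        )

    def acquire_reference_stack(self, cfg: AxisStackConfig) -> ReferenceStack:
        return acquire_reference_stack_sim(self, cfg)


def acquire_reference_stack_sim(
    mic: VirtualMicroscope, cfg: AxisStackConfig
) -> ReferenceStack:
    """Acquire one per-axis reference stack on the virtual microscope.

    Moves the stage to each plane position (symmetric about the current
    position), acquires and normalizes a frame, and appends it — as a sorted
    intensity profile for z, as the frame itself for x and y.  The stage is
    left at the last plane; the engage sequence returns it to start.
    """
    start = mic.stage_position_nm
    axis_idx = AXES.index(cfg.axis)
    entries: list = []
    for pos in cfg.positions_nm:
        target = start.copy()
        target[axis_idx] += pos
        mic.move_to(target)
        frame = normalize_frame(mic.acquire_frame())
        if cfg.axis == "z":
            entries.append(sorted_profile(frame))
        else:
            entries.append(frame)
    return ReferenceStack(
        axis=cfg.axis,
        entries=entries,
        positions_nm=cfg.positions_nm,
        step_nm=cfg.step_nm,
        center_index=cfg.n_planes // 2,
    )


def staircase_protocol(
    mic: VirtualMicroscope,
    stacks,
    setpoint,
    gains,
    calibration: Sequence[float] = (1.0, 1.0, 1.0),
    axis: str = "x",
    step_nm: float = 20.0,
    period_iters: int = 25,
    n_steps: int = 10,
    lead_in_iters: Optional[int] = None,
):
    """Inject a ±step square staircase into the stage command while logging.

    Alternating offsets (+step, −step, …) are applied every ``period_iters``
    iterations, ``n_steps`` in each direction (2·n_steps disturbance events).
    With zero gains this records the open-loop error response (used for
    calibration); with feedback on it records step responses for the
    exponential settling fit.  Returns ``(records, disturbance_iters, signs)``.
    """
    from .control import run_closed_loop  # local import to avoid a cycle

    stack = stacks[axis]
    if step_nm > stack.half_range_nm:
        warnings.warn(
            "staircase step exceeds stack half-range; estimates may rail",
            stacklevel=2,
        )
    if lead_in_iters is None:
        lead_in_iters = period_iters
    axis_idx = AXES.index(axis)
    events = {}
    signs = []
    for k in range(2 * n_steps):
        sign = 1.0 if k % 2 == 0 else -1.0
        it = lead_in_iters + k * period_iters
        vec = np.zeros(3)
        vec[axis_idx] = sign * step_nm
        events[it] = vec
        signs.append(sign)
    n_iters = lead_in_iters + 2 * n_steps * period_iters

    def disturb(i: int):
        return events.get(i)

    records = run_closed_loop(
        mic,
        stacks,
        setpoint,
        gains,
        n_iterations=n_iters,
        calibration=calibration,
        disturbance_fn=disturb,
    )
    return records, sorted(events.keys()), signs
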