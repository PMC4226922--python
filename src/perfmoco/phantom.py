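"""Synthetic first-pass perfusion phantom.

Generates an ECG-triggered 2D+t series showing sequential RV -> LV ->
myocardial contrast enhancement inside a static chest, with quasi-periodic
breathing translation of the heart, per-frame ground-truth segmentations,
dense ground-truth motion fields, and the generating compartment curves.

Geometry is specified in millimetres and converted through the configured
pixel spacing, so the same physical phantom can be rendered at any matrix
size. The heart sits in a uniform mediastinal region; the ground-truth
motion field is the (windowed) heart translation, which maps each frame
back onto the motion-free render exactly up to noise and interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import SegmentationFrame, SegmentationSet, circle_contour
from .series_model import Frame, PerfusionSeries
from .transforms import TransformField

__all__ = [
    "PhantomConfig",
    "PhantomResult",
    "enhancement_curve",
    "breathing_trajectory",
    "generate_series",
]


@dataclass
class CompartmentParams:
    """Gamma-variate bolus on a constant baseline.

    intensity(t) = baseline + amplitude * ((t-onset)/tp)^alpha
                   * exp(alpha * (1 - (t-onset)/tp))   for t > onset
    where ``tp`` is time-to-peak, so the curve peaks at ``onset + tp`` with
    value ``baseline + amplitude``.
    """

    baseline: float
    amplitude: float
    onset: float          # seconds after the first post-PD frame
    time_to_peak: float
    alpha: float = 2.5

    def __post_init__(self):
        if self.alpha <= 0 or self.time_to_peak <= 0:
            raise ValueError("gamma-variate shape parameters must be positive")


def _default_enhancement():
    return {
        "rv": CompartmentParams(baseline=40.0, amplitude=200.0, onset=2.0, time_to_peak=4.0),
        "lv": CompartmentParams(baseline=40.0, amplitude=200.0, onset=8.0, time_to_peak=5.0),
        "myo": CompartmentParams(baseline=90.0, amplitude=55.0, onset=13.0, time_to_peak=9.0, alpha=2.0),
    }


@dataclass
class PhantomConfig:
    n_frames: int = 60
    n_pd_frames: int = 2
    matrix: tuple[int, int] = (192, 256)       # (rows, cols)
    spacing: float = 1.4                       # mm, isotropic
    heart_rate: float = 75.0                   # beats/min -> one frame per beat
    breathing_rate: float = 12.0               # breaths/min
    motion_amplitude: float = 8.0              # mm, head-foot
    motion_mode: str = "free_breathing"        # free_breathing | shallow | none
    enhancement: dict = field(default_factory=_default_enhancement)
    noise_sigma: float = 2.0
    seed: int = 0

    # physical anatomy (mm); LV centre offset is relative to image centre
    lv_center_offset: tuple[float, float] = (4.0, 14.0)    # (down, right)
    endo_radius: float = 16.0
    epi_radius: float = 28.0
    rv_center_distance: float = 40.0           # left of LV centre
    rv_semiaxes: tuple[float, float] = (14.0, 20.0)        # (rows, cols)
    chest_value: float = 60.0
    background_value: float = 10.0

    def __post_init__(self):
        if self.heart_rate <= 0 or self.breathing_rate <= 0:
            raise ValueError("rates must be positive")
        if self.motion_amplitude < 0:
            raise ValueError("motion amplitude must be non-negative")
        if self.n_pd_frames >= self.n_frames:
            raise ValueError("need at least one non-PD frame")
        if self.motion_mode not in ("free_breathing", "shallow", "none"):
            raise ValueError(f"unknown motion mode {self.motion_mode!r}")

    @property
    def frame_interval(self) -> float:
        """Seconds between frames (one frame per heart beat)."""
        return 60.0 / self.heart_rate

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class PhantomResult:
    series: PerfusionSeries
    truth_segmentation: SegmentationSet
    truth_transforms: list[TransformField]
    truth_curves: dict[str, np.ndarray]        # rv/lv/myo intensity per frame
    trajectory_mm: np.ndarray                  # head-foot displacement per frame
    config: PhantomConfig


def enhancement_curve(params: CompartmentParams, times: np.ndarray) -> np.ndarray:
    """Evaluate the gamma-variate bolus model at ``times`` (seconds)."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or (times.size > 1 and np.any(np.diff(times) <= 0)):
        raise ValueError("times must be strictly increasing")
    out = np.full(times.shape, params.baseline, dtype=float)
    rel = (times - params.onset) / params.time_to_peak
    pos = rel > 0
    out[pos] += params.amplitude * rel[pos] ** params.alpha * np.exp(
        params.alpha * (1.0 - rel[pos])
    )
    return out


def gamma_variate_integral(params: CompartmentParams, t_end: float = np.inf) -> float:
    """Closed-form integral of the bolus term above baseline from onset on."""
    from scipy.special import gamma as gamma_fn, gammainc

    a = params.alpha
    tp = params.time_to_peak
    total = params.amplitude * np.exp(a) * tp * gamma_fn(a + 1.0) / a ** (a + 1.0)
    if np.isinf(t_end):
        return float(total)
    x = a * (t_end - params.onset) / tp
    return float(total * gammainc(a + 1.0, max(x, 0.0)))


def breathing_trajectory(config: PhantomConfig, times: np.ndarray) -> np.ndarray:
    """Quasi-periodic head-foot displacement (mm) at the given times.

    A sinusoid at the configured breathing rate whose amplitude and phase
    drift slowly (seeded), emulating irregular free breathing. Zero for
    ``motion_mode='none'``; quartered amplitude for ``'shallow'``.
    """
    times = np.asarray(times, dtype=float)
    if config.motion_mode == "none" or config.motion_amplitude == 0.0:
        return np.zeros_like(times)
    amp = config.motion_amplitude
    if config.motion_mode == "shallow":
        amp *= 0.25
    rng = np.random.default_rng(config.seed + 777)
    f0 = config.breathing_rate / 60.0  # Hz
    duration = max(times[-1] - times[0], 1.0)
    # slow drifts: sinusoids well below the breathing frequency
    da, dp = rng.uniform(0.0, 2.0 * np.pi, size=2)
    fa = rng.uniform(0.3, 0.7) / duration
    fp = rng.uniform(0.3, 0.7) / duration
    amp_t = amp * (1.0 + 0.15 * np.sin(2.0 * np.pi * fa * times + da))
    phase_jitter = 0.35 * np.sin(2.0 * np.pi * fp * times + dp)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    return amp_t * np.sin(2.0 * np.pi * f0 * times + phi0 + phase_jitter)


def _paint_ellipse(img, weight_accum, center_rc, semiaxes_rc, value, edge_px=2.5):
    """Alpha-composite an ellipse of constant value with a soft ~1px edge."""
    rows, cols = img.shape
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    q = np.sqrt(
        ((rr - center_rc[0]) / semiaxes_rc[0]) ** 2
        + ((cc - center_rc[1]) / semiaxes_rc[1]) ** 2
    )
    dist = (q - 1.0) * min(semiaxes_rc)       # approx signed distance, px
    w = np.clip(0.5 - dist / edge_px, 0.0, 1.0)
    img *= 1.0 - w
    img += w * value
    if weight_accum is not None:
        np.maximum(weight_accum, w, out=weight_accum)


def _render_frame(config, heart_shift_px, values, pd=False):
    """Render one frame; ``heart_shift_px`` displaces heart structures."""
    rows, cols = config.matrix
    s = config.spacing
    img = np.full((rows, cols), config.background_value, dtype=float)
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    chest_ax = (0.42 * rows, 0.45 * cols)
    chest_v = 90.0 if pd else config.chest_value
    _paint_ellipse(img, None, center, chest_ax, chest_v)

    lv_c = center + np.asarray(config.lv_center_offset) / s + heart_shift_px
    rv_c = lv_c + np.array([0.0, -config.rv_center_distance / s])
    rv_ax = (config.rv_semiaxes[0] / s, config.rv_semiaxes[1] / s)
    _paint_ellipse(img, None, rv_c, rv_ax, values["rv"])
    epi_r = config.epi_radius / s
    endo_r = config.endo_radius / s
    _paint_ellipse(img, None, lv_c, (epi_r, epi_r), values["myo"])
    _paint_ellipse(img, None, lv_c, (endo_r, endo_r), values["lv"])
    return img, lv_c, rv_c


def _truth_segmentation_frame(config, lv_c, rv_c, index) -> SegmentationFrame:
    s = config.spacing
    epi_r = config.epi_radius / s
    endo_r = config.endo_radius / s
    center_xy = (lv_c[1], lv_c[0])
    # anterior insertion: on the epicardial circle, rotated 55 deg
    # (clockwise on screen, y down) from the LV->RV direction
    to_rv = np.arctan2(rv_c[0] - lv_c[0], rv_c[1] - lv_c[1])
    ang0 = to_rv - np.deg2rad(55.0)
    rays = [
        (
            lv_c[1] + epi_r * np.cos(ang0 + k * 2.0 * np.pi / 3.0),
            lv_c[0] + epi_r * np.sin(ang0 + k * 2.0 * np.pi / 3.0),
        )
        for k in range(3)
    ]
    return SegmentationFrame(
        image_ref=f"frame{index:04d}",
        star_center=center_xy,
        star_rays=rays,
        endocardium=circle_contour(center_xy, endo_r, 48),
        epicardium=circle_contour(center_xy, epi_r, 48),
    )


def _motion_window(config, window_center_rc):
    """Taper field: 1 near the heart, 0 in the static chest periphery."""
    rows, cols = config.matrix
    s = config.spacing
    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    dist_mm = s * np.hypot(rr - window_center_rc[0], cc - window_center_rc[1])
    r1, r2 = 58.0, 88.0
    w = np.clip((r2 - dist_mm) / (r2 - r1), 0.0, 1.0)
    return w * w * (3.0 - 2.0 * w)  # smoothstep


def generate_series(config: PhantomConfig) -> PhantomResult:
    """Generate the phantom series plus all ground truth, reproducibly."""
    rows, cols = config.matrix
    s = config.spacing
    # anatomy must fit: chest ellipse contains heart + motion range
    span_mm = config.rv_center_distance + config.rv_semiaxes[1] + config.epi_radius
    if span_mm / s > 0.45 * cols or (config.epi_radius + config.motion_amplitude) / s > 0.42 * rows:
        raise ValueError("anatomy exceeds the configured matrix")

    times = config.frame_times()
    n_pd = config.n_pd_frames
    bolus_times = times[n_pd:] - times[n_pd]
    curves = {
        name: enhancement_curve(params, bolus_times)
        for name, params in config.enhancement.items()
    }
    full_curves = {
        name: np.concatenate([np.full(n_pd, 110.0), c]) for name, c in curves.items()
    }

    traj = breathing_trajectory(config, times)
    rng = np.random.default_rng(config.seed)

    frames = []
    seg_frames = []
    transforms = []
    window = None
    for t in range(config.n_frames):
        pd = t < n_pd
        shift_mm = np.array([traj[t], 0.2 * traj[t]])
        shift_px = shift_mm / s
        values = {name: full_curves[name][t] for name in full_curves}
        img, lv_c, rv_c = _render_frame(config, shift_px, values, pd=pd)
        if config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
        frames.append(Frame(img, times[t], is_proton_density=pd))
        seg_frames.append(_truth_segmentation_frame(config, lv_c, rv_c, t))
        if window is None:
            center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
            lv0 = center + np.asarray(config.lv_center_offset) / s
            heart_center = lv0 + np.array([0.0, -0.5 * config.rv_center_distance / s])
            window = _motion_window(config, heart_center)
        dense = np.stack([shift_px[0] * window, shift_px[1] * window])
        transforms.append(TransformField((rows, cols), dense=dense))

    series = PerfusionSeries(
        frames,
        (s, s),
        patient_id=f"phantom-{config.seed}",
        study="stress" if config.heart_rate > 100 else "rest",
        slice_level="mid",
    )
    segset = SegmentationSet(
        seg_frames,
        rv_peak_index=n_pd + int(np.argmax(curves["rv"])),
        lv_peak_index=n_pd + int(np.argmax(curves["lv"])),
        slice_level=1,
    )
    return PhantomResult(series, segset, transforms, full_curves, traj, config)


def stress_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Stress parameterization: higher heart rate at unchanged breathing
    rate, stretching one breathing cycle over more frames."""
    overrides.setdefault("heart_rate", 120.0)
    return PhantomConfig(seed=seed, **overrides)
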