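"""Quasi-periodicity-based motion compensation (QUASI-P).

Three steps: (1) pick a global reference and the subset of frames sharing
its breathing phase via NGF similarity; (2) register the subset to the
reference by optimizing NGF; (3) linearly interpolate the registered
subset in time into synthetic references and register the remaining frames
to them with SSD. No maximum temporal gap is imposed when collecting the
subset — on motion-free series the subset deliberately degenerates, which
reproduces the documented failure mode of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._results import MocoResult
from .errors import SubsetSelectionError
from .registration import RegistrationConfig, ngf, register
from .series_model import Frame, PerfusionSeries, strip_proton_density
from .transforms import TransformField

__all__ = ["QuasipConfig", "select_subset", "interpolate_references", "run_quasip"]


@dataclass
class QuasipConfig:
    ngf_eta: float | None = None
    peak_window: int = 3               # local-optimum detection window
    peak_prominence: float = 0.05      # fraction of similarity range
    selection_smoothing: float = 2.0   # image presmoothing (px) for step 1
    registration: RegistrationConfig = field(
        default_factory=lambda: RegistrationConfig(
            measure="ngf",
            kappa=0.1,
            knot_spacing=5.0,
            working_scale=1.0,
            levels=3,
            optimizer="gd",
            max_iter=100,
            gd_start_step=0.01,
            gd_epsilon=0.01,
        )
    )

    def ssd_registration(self) -> RegistrationConfig:
        return replace(self.registration, measure="ssd")


def _selection_stack(series: PerfusionSeries, smoothing: float):
    """Pre-smoothed frames and an edge-scaled NGF eta for subset selection.

    Smoothing suppresses pixel noise so the similarity-vs-time curve is
    driven by anatomy (edges) and enhancement; eta is tied to the upper
    gradient percentile so flat-region noise cannot dominate the measure.
    """
    from scipy.ndimage import gaussian_filter

    stack = series.pixel_array()
    if smoothing > 0:
        stack = np.stack([gaussian_filter(f, smoothing) for f in stack])
    gr, gc = np.gradient(stack[-1])
    eta = 0.5 * float(np.percentile(np.hypot(gr, gc), 90))
    return stack, max(eta, 1e-6)


def _pick_global_reference(stack: np.ndarray, eta) -> int:
    """Frame from the last third maximizing summed NGF similarity to its
    five temporal neighbours (late frames show little enhancement change)."""
    n = stack.shape[0]
    start = max(2 * n // 3, 0)
    best, best_score = start, -np.inf
    for r in range(start, n):
        score = 0.0
        for j in range(max(r - 2, 0), min(r + 3, n)):
            if j != r:
                score -= ngf(stack[j], stack[r], eta)
        if score > best_score:
            best, best_score = r, score
    return best


def select_subset(
    series: PerfusionSeries,
    ngf_eta: float | None = None,
    peak_window: int = 3,
    peak_prominence: float = 0.05,
    selection_smoothing: float = 2.0,
) -> tuple[int, list[int]]:
    """Choose the global reference and the same-breathing-phase subset.

    The subset consists of frames at local optima of the NGF
    similarity-to-reference curve (window ``peak_window``, with a
    prominence filter relative to the curve's range); endpoints count with
    one-sided comparison. If every frame ties (e.g. identical images), all
    frames are kept. Raises :class:`SubsetSelectionError` when fewer than
    2 frames result.
    """
    series = strip_proton_density(series)
    stack, auto_eta = _selection_stack(series, selection_smoothing)
    if ngf_eta is None:
        ngf_eta = auto_eta
    n = stack.shape[0]
    if n < 6:
        raise SubsetSelectionError(f"need at least 6 frames, got {n}")
    ref = _pick_global_reference(stack, ngf_eta)
    sim = np.array([-ngf(stack[t], stack[ref], ngf_eta) for t in range(n)])

    if np.ptp(sim) < 1e-12:       # all frames tie: keep everything
        return ref, list(range(n))

    # the reference's self-similarity is a trivial outlier; replace it by
    # its neighbourhood so it cannot dominate the peak statistics
    others = np.delete(np.arange(n), ref)
    sim[ref] = np.interp(ref, others, sim[others])

    prominence = peak_prominence * np.ptp(sim)
    half = peak_window // 2
    subset = set()
    for t in range(n):
        lo, hi = max(t - half, 0), min(t + half + 1, n)
        window = np.concatenate([sim[lo:t], sim[t + 1:hi]])
        if window.size and sim[t] >= window.max() and (
            sim[t] - window.min() >= prominence
        ):
            subset.add(t)
    subset.add(ref)
    if len(subset) == 1:
        # degenerate (e.g. motion-free input): keep the single most similar
        # frame away from the reference so the pipeline can still run; the
        # resulting two-frame base cannot model the enhancement, which is
        # the documented failure mode of this method on motion-free data
        away = [t for t in range(n) if abs(t - ref) > half]
        if not away:
            raise SubsetSelectionError("pre-aligned subset degenerated to 1 frame")
        subset.add(max(away, key=lambda t: sim[t]))
    return ref, sorted(subset)


def interpolate_references(
    registered_subset: np.ndarray,
    subset_times: np.ndarray,
    all_times: np.ndarray,
) -> np.ndarray:
    """Per-pixel linear interpolation of registered subset frames in time.

    Times outside the subset span are clamped to the first/last frame.
    """
    registered_subset = np.asarray(registered_subset, dtype=float)
    subset_times = np.asarray(subset_times, dtype=float)
    all_times = np.asarray(all_times, dtype=float)
    if registered_subset.shape[0] == 0:
        raise ValueError("empty subset")
    if np.any(np.diff(subset_times) <= 0):
        raise ValueError("subset times must be strictly increasing")
    out = np.empty((all_times.size, *registered_subset.shape[1:]))
    for i, t in enumerate(all_times):
        j = int(np.searchsorted(subset_times, t, side="right")) - 1
        if j < 0:
            out[i] = registered_subset[0]
        elif j >= subset_times.size - 1:
            out[i] = registered_subset[-1] if t >= subset_times[-1] else registered_subset[j]
        else:
            t0, t1 = subset_times[j], subset_times[j + 1]
            w = (t - t0) / (t1 - t0)
            out[i] = (1.0 - w) * registered_subset[j] + w * registered_subset[j + 1]
    return out


def run_quasip(
    series: PerfusionSeries,
    config: QuasipConfig | None = None,
) -> MocoResult:
    """Run the three-step pipeline; failures are reported, not swallowed."""
    config = config or QuasipConfig()
    series = strip_proton_density(series)
    stack = series.pixel_array()
    times = series.times
    n = stack.shape[0]
    shape = series.frame_shape

    try:
        ref_idx, subset = select_subset(
            series, config.ngf_eta, config.peak_window,
            config.peak_prominence, config.selection_smoothing,
        )
    except SubsetSelectionError as exc:
        return MocoResult(
            registered_series=None, transforms=None, method="quasip",
            failed=True, failure_reason=str(exc),
            log=[{"step": "select_subset", "error": str(exc)}],
        )

    log = [{"step": "select_subset", "reference": ref_idx, "subset": subset}]
    transforms: list[TransformField] = [TransformField.identity(shape) for _ in range(n)]
    registered = stack.copy()

    # step 2: NGF registration of the subset to the global reference
    for t in subset:
        if t == ref_idx:
            continue
        tf = register(stack[t], stack[ref_idx], config.registration)
        transforms[t] = tf
        registered[t] = tf.apply_to_image(stack[t])
    log.append({"step": "ngf_subset_registration", "n_registered": len(subset) - 1})

    # step 3: synthetic references by temporal interpolation; SSD for the rest
    subset_stack = np.stack([registered[t] for t in subset])
    references = interpolate_references(subset_stack, times[subset], times)
    ssd_config = config.ssd_registration()
    remaining = [t for t in range(n) if t not in set(subset)]
    for t in remaining:
        tf = register(stack[t], references[t], ssd_config)
        transforms[t] = tf
        registered[t] = tf.apply_to_image(stack[t])
    log.append({"step": "ssd_registration", "n_registered": len(remaining)})

    frames = [Frame(registered[t], times[t]) for t in range(n)]
    out_series = replace(series, frames=frames, pd_stripped=True)
    return MocoResult(
        registered_series=out_series,
        transforms=transforms,
        log=log,
        passes_used=1,
        method="quasip",
    )
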