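"""Multi-pass ICA-based motion compensation (ICA-SP).

Each pass decomposes the current series, labels the motion component
(wavelet analysis first, mean-frequency fallback second), optionally crops
to an RV/LV region of interest when the IC-based cavity segmentation
passes its gravity-centre sanity check, rebuilds motion-free synthetic
references by dropping the motion IC, and registers every frame to its
reference with SSD. Transforms compose across passes; the loop stops when
the incremental displacement falls below half a pixel or after the pass
limit. The rest position is the mean of the breathing range, so all frames
may be altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import ica_analysis as ica
from ._results import MocoResult
from .errors import PipelineError
from .registration import RegistrationConfig, register
from .series_model import Frame, PerfusionSeries, strip_proton_density
from .transforms import TransformField

__all__ = ["IcaspConfig", "run_icasp"]


@dataclass
class IcaspConfig:
    n_components: int = 5
    max_passes: int = 5
    stop_displacement_px: float = 0.5
    use_roi: bool = True
    roi_threshold_mm: float = ica.ROI_DISTANCE_THRESHOLD_MM
    roi_margin_px: int = 10
    fallback_threshold_per_min: float = ica.FALLBACK_FREQUENCY_PER_MIN
    seed: int = 0
    registration: RegistrationConfig = field(
        default_factory=lambda: RegistrationConfig(
            measure="ssd",
            kappa=10.0,
            knot_spacing=16.0,
            working_scale=0.5,
            levels=3,
            optimizer="lbfgs",
            max_iter=300,
            x_tol=1e-3,
            f_tol=1e-3,
        )
    )


def _label_components(decomp, config):
    labels = ica.classify_wavelet(decomp)
    if labels.motion_index is None:
        labels = ica.fallback_motion_label(
            decomp, config.fallback_threshold_per_min, base_labels=labels
        )
    return labels


def _decompose_and_label(series_like, config, pass_no):
    """Deflation-mode ICA first; rerun symmetric when the separation is
    unusable (non-convergence or no motion candidate)."""
    decomp = ica.decompose(
        series_like, config.n_components, mode="deflation",
        seed=config.seed + 101 * pass_no,
    )
    labels = _label_components(decomp, config)
    if decomp.converged and labels.motion_index is not None:
        return decomp, labels
    decomp = ica.decompose(
        series_like, config.n_components, mode="symmetric",
        seed=config.seed + 101 * pass_no,
    )
    return decomp, _label_components(decomp, config)


def _crop_series(series: PerfusionSeries, box) -> PerfusionSeries:
    r0, r1, c0, c1 = box
    frames = [
        Frame(f.pixels[r0:r1, c0:c1], f.acquisition_time) for f in series.frames
    ]
    cropped = replace(series, frames=frames, pd_stripped=True)
    return cropped


def run_icasp(
    series: PerfusionSeries,
    config: IcaspConfig | None = None,
) -> MocoResult:
    """Run the full multi-pass pipeline on a perfusion series.

    PD frames are stripped automatically when present. Raises
    :class:`PipelineError` when no motion component can be identified on
    the first pass by either labeling route.
    """
    config = config or IcaspConfig()
    series = strip_proton_density(series)
    shape = series.frame_shape
    n_frames = series.n_frames
    original = series.pixel_array()

    totals: list[TransformField | None] = [None] * n_frames
    current = original.copy()
    roi = None
    labels = None
    log: list[dict] = []
    passes_used = 0

    for pass_no in range(1, config.max_passes + 1):
        box = roi.roi_box if (roi is not None and not roi.rejected) else None
        if box is not None:
            working = _series_from_stack(series, current)
            working = _crop_series(working, box)
        else:
            working = _series_from_stack(series, current)

        decomp, labels = _decompose_and_label(working, config, pass_no)
        entry = {
            "pass": pass_no,
            "ica_mode": decomp.mode_used,
            "ica_converged": decomp.converged,
            "labeling_method": labels.method_used,
            "motion_index": labels.motion_index,
            "rv_index": labels.rv_index,
            "lv_index": labels.lv_index,
        }
        if labels.motion_index is None:
            if pass_no == 1:
                raise PipelineError("motion component not identified")
            entry["stopped"] = "motion component no longer detectable"
            log.append(entry)
            break

        if (
            config.use_roi
            and roi is None
            and labels.rv_index is not None
            and labels.lv_index is not None
        ):
            roi = ica.segment_rv_lv(
                decomp, labels, series.pixel_spacing,
                distance_threshold_mm=config.roi_threshold_mm,
                margin_px=config.roi_margin_px,
            )
            entry["roi_rejected"] = roi.rejected
            entry["roi_reason"] = roi.reason
            entry["roi_distance_mm"] = roi.center_distance_mm
            if not roi.rejected:
                entry["roi_box"] = roi.roi_box
                # references from this decomposition are full-domain;
                # crop takes effect from the next registration on
                box = roi.roi_box
                working = _crop_series(_series_from_stack(series, current), box)
                decomp, labels = _decompose_and_label(working, config, pass_no)
                if labels.motion_index is None:
                    entry["stopped"] = "motion lost after ROI crop"
                    roi = replace(roi, rejected=True, reason="motion lost after crop")
                    box = None
                    decomp, labels = _decompose_and_label(
                        _series_from_stack(series, current), config, pass_no
                    )

        references = ica.synthetic_references(decomp, labels)
        updates = []
        for t in range(n_frames):
            mov = current[t][box[0]:box[1], box[2]:box[3]] if box else current[t]
            tf = register(mov, references[t], config.registration)
            updates.append(_embed(tf, shape, box).displacement())
        # gauge fixing: a displacement common to all frames is unobservable
        # against references built from the same frames; the rest position
        # is the mean of the breathing range, so the across-frames mean of
        # the per-pass update is removed to stop drift from accumulating
        common = np.mean(updates, axis=0)
        max_update = 0.0
        new_totals = []
        for t in range(n_frames):
            update = TransformField(shape, dense=updates[t] - common)
            max_update = max(max_update, update.max_displacement())
            new_totals.append(
                update if totals[t] is None else update.compose_after(totals[t])
            )
        # re-warp originals by the composed fields (single resampling)
        trial = np.stack(
            [new_totals[t].apply_to_image(original[t]) for t in range(n_frames)]
        )
        entry["max_displacement_update_px"] = max_update
        # motion shows up as temporal high-frequency energy; a pass that
        # raises it chased reference artifacts, not motion — revert it
        # (the first pass always commits: the method runs at least once)
        e_before = float(np.sum(np.diff(current, axis=0) ** 2))
        e_after = float(np.sum(np.diff(trial, axis=0) ** 2))
        entry["temporal_energy_ratio"] = e_after / max(e_before, 1e-30)
        if pass_no > 1 and e_after >= e_before:
            entry["stopped"] = "pass reverted: temporal energy increased"
            log.append(entry)
            break
        totals = new_totals
        current = trial
        passes_used = pass_no
        log.append(entry)
        if max_update < config.stop_displacement_px:
            break

    registered = _series_from_stack(series, current)
    final_transforms = [
        t if t is not None else TransformField.identity(shape) for t in totals
    ]
    return MocoResult(
        registered_series=registered,
        transforms=final_transforms,
        log=log,
        labels=labels,
        roi=roi,
        passes_used=passes_used,
        method="icasp",
    )


def _series_from_stack(series: PerfusionSeries, stack: np.ndarray) -> PerfusionSeries:
    frames = [
        Frame(stack[t], f.acquisition_time)
        for t, f in enumerate(series.frames)
    ]
    return replace(series, frames=frames, pd_stripped=True)


def _embed(tf: TransformField, full_shape, box) -> TransformField:
    """Lift a (possibly ROI-cropped) transform onto the full domain."""
    if box is None:
        if tf.domain_shape == tuple(full_shape):
            return TransformField(full_shape, dense=tf.displacement())
        raise ValueError("transform domain does not match series")
    dense = np.zeros((2, *full_shape))
    r0, r1, c0, c1 = box
    dense[:, r0:r1, c0:c1] = tf.displacement()
    return TransformField(full_shape, dense=dense)
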