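"""ICA decomposition of perfusion series and component labeling.

The series is decomposed into spatial feature images (ICs) with one mixing
curve per component (frames are modelled as mixtures of the spatial ICs).
Breathing motion shows up as the mixing curve with dominant fine-scale
wavelet energy; RV and LV enhancement curves are recognized by the order of
their coarse-scale peaks. A mean-frequency threshold serves as fallback
when the wavelet route fails (e.g. stress studies where one breathing cycle
stretches over many frames).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from . import _dwt
from .series_model import PerfusionSeries

__all__ = [
    "ICADecomposition",
    "ComponentLabels",
    "RoiResult",
    "decompose",
    "classify_wavelet",
    "mean_frequency",
    "fallback_motion_label",
    "segment_rv_lv",
    "synthetic_references",
]

#: gravity-centre distance below which an RV/LV segmentation is rejected
ROI_DISTANCE_THRESHOLD_MM = 30.0
#: mean-frequency threshold (per minute) for the fallback motion label
FALLBACK_FREQUENCY_PER_MIN = 14.0
#: fine-scale wavelet energy must exceed this multiple of the rest
WAVELET_DOMINANCE_MARGIN = 1.0
SYMMETRIC_MAX_ITER = 400


@dataclass
class ICADecomposition:
    """Spatial ICs plus per-frame mixing weights.

    ``mean_image + mixing @ components`` reconstructs the input series.
    """

    components: np.ndarray       # (k, rows, cols)
    mixing: np.ndarray           # (t, k)
    mean_image: np.ndarray       # (rows, cols)
    times: np.ndarray            # (t,) seconds
    mode_used: str = "deflation"
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.mean_image.shape

    def reconstruct(self, drop: set[int] | None = None) -> np.ndarray:
        """Rebuild the (t, rows, cols) series, optionally dropping ICs."""
        keep = [i for i in range(self.n_components) if not drop or i not in drop]
        flat = self.components.reshape(self.n_components, -1)
        out = self.mixing[:, keep] @ flat[keep] + self.mean_image.ravel()[None, :]
        return out.reshape(self.mixing.shape[0], *self.frame_shape)

    def signed_curve(self, index: int) -> np.ndarray:
        """Mixing curve with sign normalized so its extremum is positive."""
        curve = self.mixing[:, index]
        return -curve if abs(curve.min()) > abs(curve.max()) else curve


@dataclass
class ComponentLabels:
    motion_index: int | None = None
    rv_index: int | None = None
    lv_index: int | None = None
    method_used: str | None = None       # 'wavelet' | 'frequency_fallback'
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        resolved = [i for i in (self.motion_index, self.rv_index, self.lv_index) if i is not None]
        if len(resolved) != len(set(resolved)):
            raise ValueError("component labels must be distinct")


@dataclass
class RoiResult:
    rv_mask: np.ndarray | None
    lv_mask: np.ndarray | None
    roi_box: tuple[int, int, int, int] | None    # (r0, r1, c0, c1), exclusive
    rejected: bool
    center_distance_mm: float
    reason: str = ""


def _as_stack_and_times(series):
    if isinstance(series, PerfusionSeries):
        return series.pixel_array(), series.times
    raise TypeError("decompose expects a PerfusionSeries")


def decompose(
    series: PerfusionSeries,
    n_components: int = 5,
    mode: str = "deflation",
    seed: int = 0,
    max_iter: int | None = None,
) -> ICADecomposition:
    """Run fixed-point ICA on a (PD-stripped) series.

    ``mode='deflation'`` extracts components one by one (the first
    attempt); ``mode='symmetric'`` estimates them in parallel with an
    iteration cap and its result is used regardless of convergence.
    """
    stack, times = _as_stack_and_times(series)
    n_frames = stack.shape[0]
    if n_components < 3:
        raise ValueError("need at least 3 components")
    if n_components >= n_frames:
        raise ValueError(f"{n_components} components require more than {n_frames} frames")
    if mode not in ("deflation", "symmetric"):
        raise ValueError(f"unknown ICA mode {mode!r}")

    X = stack.reshape(n_frames, -1)
    algorithm = "deflation" if mode == "deflation" else "parallel"
    if max_iter is None:
        max_iter = 200 if mode == "deflation" else SYMMETRIC_MAX_ITER
    ica = FastICA(
        n_components=n_components,
        algorithm=algorithm,
        whiten="unit-variance",
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(X)      # (t, k): mixing curves
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    components = ica.mixing_.T.reshape(n_components, *stack.shape[1:])
    return ICADecomposition(
        components=components,
        mixing=sources,
        mean_image=ica.mean_.reshape(stack.shape[1:]),
        times=np.asarray(times, dtype=float),
        mode_used=mode,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------

def _wavelet_energy_split(curve: np.ndarray, n_fine_levels: int = 2):
    coeffs = _dwt.wavedec(curve - curve.mean(), level=n_fine_levels + 1)
    energies = _dwt.band_energies(coeffs)
    if len(coeffs) < 2:
        return 0.0, float(energies.sum())
    n_fine = min(n_fine_levels, len(coeffs) - 1)
    fine = float(energies[-n_fine:].sum())
    low = float(energies[:-n_fine].sum())
    return fine, low


def classify_wavelet(
    decomposition: ICADecomposition,
    dominance_margin: float = WAVELET_DOMINANCE_MARGIN,
) -> ComponentLabels:
    """Label motion / RV / LV components from the mixing matrix.

    The motion component is the mixing curve with the largest fine-scale
    detail-energy fraction, accepted only when that energy exceeds
    ``dominance_margin`` times the remaining (low-frequency) energy. RV and
    LV are ordered by the peaks of the coarse-scale reconstructions of the
    other curves (RV enhances first). Unresolved labels stay ``None``.
    """
    k = decomposition.n_components
    fine = np.zeros(k)
    low = np.zeros(k)
    for i in range(k):
        fine[i], low[i] = _wavelet_energy_split(decomposition.mixing[:, i])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(low > 0, fine / low, np.where(fine > 0, np.inf, 0.0))
    motion = int(np.argmax(ratio))
    motion_ok = ratio[motion] > dominance_margin and fine[motion] > 0

    labels = ComponentLabels(
        motion_index=motion if motion_ok else None,
        method_used="wavelet" if motion_ok else None,
        diagnostics={"fine_energy": fine.tolist(), "low_energy": low.tolist()},
    )
    _label_rv_lv(decomposition, labels)
    return labels


def _label_rv_lv(decomposition: ICADecomposition, labels: ComponentLabels):
    """Assign RV/LV by coarse-peak order among non-motion components."""
    n_t = decomposition.mixing.shape[0]
    candidates = []
    for i in range(decomposition.n_components):
        if i == labels.motion_index:
            continue
        curve = decomposition.signed_curve(i)
        coarse = _dwt.coarse_reconstruction(curve - curve.mean(), 2)
        fine, low = _wavelet_energy_split(curve)
        total = fine + low
        if total <= 0 or low / total < 0.5:
            continue
        peak = int(np.argmax(coarse))
        if peak <= 0 or peak >= n_t - 1:
            continue
        prominence = float(coarse[peak] - np.median(coarse))
        if prominence <= 0:
            continue
        candidates.append((prominence, peak, i))
    if len(candidates) >= 2:
        top = sorted(candidates, reverse=True)[:2]
        if top[0][1] != top[1][1]:
            first, second = sorted(top, key=lambda c: c[1])
            labels.rv_index, labels.lv_index = first[2], second[2]
    labels.diagnostics["rv_lv_candidates"] = [
        {"component": i, "peak": p, "prominence": pr} for pr, p, i in candidates
    ]


def mean_frequency(curve: np.ndarray, times: np.ndarray) -> float:
    """Zero-crossing mean frequency of a curve, in cycles per minute.

    frequency = crossings of the mean-subtracted curve / (2 * duration),
    scaled to per-minute. Constant curves have frequency 0.
    """
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    if curve.size < 4:
        raise ValueError("need at least 4 samples")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    x = curve - curve.mean()
    signs = np.sign(x)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0.0
    crossings = int(np.count_nonzero(np.diff(signs)))
    duration = times[-1] - times[0]
    return crossings / (2.0 * duration) * 60.0


def fallback_motion_label(
    decomposition: ICADecomposition,
    threshold_per_min: float = FALLBACK_FREQUENCY_PER_MIN,
    base_labels: ComponentLabels | None = None,
) -> ComponentLabels:
    """Frequency-threshold fallback for the motion label.

    The component with the highest mean mixing-curve frequency is labeled
    motion iff that frequency is strictly above the threshold. A tie for
    the maximum frequency above threshold is reported unresolved (the
    fallback is documented as potentially unreliable near the threshold).
    """
    freqs = np.array(
        [
            mean_frequency(decomposition.mixing[:, i], decomposition.times)
            for i in range(decomposition.n_components)
        ]
    )
    best = int(np.argmax(freqs))
    motion = None
    method = None
    if freqs[best] > threshold_per_min:
        ties = np.flatnonzero(np.isclose(freqs, freqs[best], rtol=0, atol=1e-9))
        if ties.size == 1:
            motion = best
            method = "frequency_fallback"
    rv = base_labels.rv_index if base_labels else None
    lv = base_labels.lv_index if base_labels else None
    # keep labels distinct: motion wins over a clashing rv/lv guess
    if motion is not None:
        rv = None if rv == motion else rv
        lv = None if lv == motion else lv
    labels = ComponentLabels(
        motion_index=motion,
        rv_index=rv,
        lv_index=lv,
        method_used=method,
        diagnostics={"mean_frequencies_per_min": freqs.tolist()},
    )
    if base_labels is not None:
        labels.diagnostics.update(base_labels.diagnostics)
    return labels


# ---------------------------------------------------------------------------
# RV/LV segmentation from IC images
# ---------------------------------------------------------------------------

def _segment_ic_image(image: np.ndarray) -> np.ndarray:
    """Otsu threshold on the positive part, then largest connected blob."""
    positive = image[image > 0]
    if positive.size < 2 or np.ptp(positive) == 0:
        return np.zeros(image.shape, dtype=bool)
    thr = threshold_otsu(positive)
    mask = image > thr
    labeled, n = ndimage.label(mask)
    if n == 0:
        return np.zeros(image.shape, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, np.arange(1, n + 1))
    return labeled == (1 + int(np.argmax(sizes)))


def segment_rv_lv(
    decomposition: ICADecomposition,
    labels: ComponentLabels,
    pixel_spacing: tuple[float, float],
    distance_threshold_mm: float = ROI_DISTANCE_THRESHOLD_MM,
    margin_px: int = 10,
) -> RoiResult:
    """Segment RV/LV cavities from their IC images and sanity-check them.

    The segmentation is rejected when the gravity-centre distance of the
    two masks falls below ``distance_threshold_mm`` (default 30 mm, about a
    third of an adult heart's short-axis extent) or a mask is empty. On
    acceptance, ``roi_box`` is the joint bounding box dilated by
    ``margin_px``.
    """
    if labels.rv_index is None or labels.lv_index is None:
        raise ValueError("RV and LV components must be resolved before segmentation")
    masks = {}
    for name, idx in (("rv", labels.rv_index), ("lv", labels.lv_index)):
        image = decomposition.components[idx]
        curve = decomposition.mixing[:, idx]
        if abs(curve.min()) > abs(curve.max()):   # sign normalization
            image = -image
        masks[name] = _segment_ic_image(image)
    if not masks["rv"].any() or not masks["lv"].any():
        return RoiResult(masks["rv"], masks["lv"], None, True, 0.0,
                         reason="empty mask after thresholding")
    crv = np.array(ndimage.center_of_mass(masks["rv"]))
    clv = np.array(ndimage.center_of_mass(masks["lv"]))
    dist_mm = float(np.hypot(*((crv - clv) * np.asarray(pixel_spacing))))
    if dist_mm < distance_threshold_mm:
        return RoiResult(
            masks["rv"], masks["lv"], None, True, dist_mm,
            reason=f"gravity-centre distance {dist_mm:.1f} mm "
                   f"below {distance_threshold_mm:g} mm",
        )
    union = masks["rv"] | masks["lv"]
    rows = np.flatnonzero(union.any(axis=1))
    cols = np.flatnonzero(union.any(axis=0))
    shape = union.shape
    box = (
        max(int(rows[0]) - margin_px, 0),
        min(int(rows[-1]) + 1 + margin_px, shape[0]),
        max(int(cols[0]) - margin_px, 0),
        min(int(cols[-1]) + 1 + margin_px, shape[1]),
    )
    return RoiResult(masks["rv"], masks["lv"], box, False, dist_mm)


def synthetic_references(
    decomposition: ICADecomposition,
    labels: ComponentLabels,
) -> np.ndarray:
    """Motion-free reference frames: recombination of all ICs but motion."""
    if labels.motion_index is None:
        raise ValueError(
            "motion component unresolved; run the frequency fallback before "
            "building synthetic references"
        )
    return decomposition.reconstruct(drop={labels.motion_index})
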