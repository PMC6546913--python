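"""Classical reference detectors for nuclei and FISH signals, plus matching.

The pipeline treats detectors as a contract: any callable that maps an RGB
image to a list of :class:`NucleusDetection`, or a nucleus crop to a list of
:class:`SignalDetection`, can be plugged in (the original method used two
trained object-localization CNNs here).  This module ships deterministic,
seed-free classical backends:

* nuclei: Gaussian smoothing of the blue (DAPI) channel, Otsu thresholding,
  hole filling, connected components filtered by area, tight boxes;
* appearance grading (the "first read"): background-subtracted HER2-hue and
  CEN17-hue fluorescence masses inside the nucleus box, converted to an
  intensity ratio via per-spot masses calibrated on rendered reference
  spots — deliberately *without* counting individual spots, so the read is
  independent of the signal detector;
* signals (the "second read"): per-hue multiscale Laplacian-of-Gaussian blob
  detection; contiguous HER2-positive regions larger than the cluster area
  threshold are emitted as one ``HER2_cluster`` instead of single spots.

Color unmixing uses HER2 = R - 0.5 G and CEN17 = G - 0.5 R (clipped at 0),
which separates orange and green spots recorded through a single graded
filter; the coefficients are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import blob_log
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .annotations import BoundingBox, NucleusClass, SignalClass
from .scoring import SignalCounts

__all__ = [
    "DetectorParams",
    "NucleusDetection",
    "SignalDetection",
    "Matching",
    "detect_nuclei",
    "classify_nucleus_appearance",
    "detect_signals",
    "assign_signals",
    "match_detections",
    "detection_metrics",
    "calibrated_spot_masses",
]


@dataclass(frozen=True)
class DetectorParams:
    """Tunables of the classical reference backends."""

    # --- nucleus detector ---
    nucleus_smooth_sigma: float = 2.0
    nucleus_threshold: str = "otsu"         # currently the only method
    nucleus_threshold_floor: float = 60.0   # reject thresholds in the noise floor
    nucleus_min_area: float = 1500.0        # px^2 at nominal 40x scale
    nucleus_max_area: float = 60000.0
    # --- hue unmixing (single-filter RGB acquisition) ---
    her2_green_coeff: float = 0.5           # HER2 channel = R - coeff * G
    cen17_red_coeff: float = 0.5            # CEN17 channel = G - coeff * R
    saturation_level: float = 245.0         # red-saturated pixels carry no CEN17 information
    # --- signal detector ---
    psf_sigma: float = 2.0                  # assumed spot scale (px)
    log_min_sigma: float = 1.3
    log_max_sigma: float = 3.0
    log_num_sigma: int = 5
    spot_threshold: float = 0.08            # LoG response on channels scaled to [0, 1]
    cluster_area_threshold: float = 100.0   # px^2 of contiguous HER2-positive area
    nms_iou: float = 0.5
    # --- appearance grading ---
    mass_floor: float = 25.0                # channel counts only this far above background
    artifact_cen17_floor: float = 0.5       # estimated CEN17 spots below this -> artifact
    uncertain_cen17_floor: float = 1.5      # ... below this -> uncertain
    ratio_low_lo: float = 1.5               # intensity-ratio grade boundaries
    ratio_high_lo: float = 6.0
    # reference colors used to calibrate per-spot channel masses (match the
    # simulator defaults; recalibrate for a different acquisition setup)
    calib_nucleus_color: tuple[int, int, int] = (20, 20, 140)
    calib_her2_color: tuple[int, int, int] = (230, 120, 30)
    calib_cen17_color: tuple[int, int, int] = (40, 220, 40)


DEFAULT_PARAMS = DetectorParams()


@dataclass(frozen=True)
class NucleusDetection:
    box: BoundingBox
    appearance_class: NucleusClass
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class SignalDetection:
    box: BoundingBox
    signal_class: SignalClass
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")

    def shift(self, dx: int, dy: int) -> "SignalDetection":
        return SignalDetection(self.box.shift(dx, dy), self.signal_class, self.confidence)


# ---------------------------------------------------------------------------
# Hue unmixing and calibration
# ---------------------------------------------------------------------------

def _check_rgb(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise TypeError(f"expected an (H, W, 3) RGB image, got shape {arr.shape}")
    return arr.astype(float)


def her2_channel(image: np.ndarray, params: DetectorParams = DEFAULT_PARAMS) -> np.ndarray:
    arr = _check_rgb(image)
    return np.clip(arr[..., 0] - params.her2_green_coeff * arr[..., 1], 0, None)


def cen17_channel(image: np.ndarray, params: DetectorParams = DEFAULT_PARAMS) -> np.ndarray:
    """Green minus half red, with red-saturated pixels blanked.

    Inside a dense HER2 accumulation the red channel clips and green bleeds
    through the unmixing; those pixels are uninformative for CEN17 and are
    zeroed rather than misread as green signal.
    """
    arr = _check_rgb(image)
    out = np.clip(arr[..., 1] - params.cen17_red_coeff * arr[..., 0], 0, None)
    out[arr[..., 0] >= params.saturation_level] = 0.0
    return out


def _channel_mass(channel: np.ndarray, floor: float) -> float:
    """Background-subtracted fluorescence mass of one unmixed channel.

    Background is the channel median (the nucleus fill dominates a crop);
    only pixels more than *floor* above it contribute, which suppresses the
    positive half of the noise.
    """
    bg = float(np.median(channel))
    above = channel > bg + floor
    return float((channel[above] - bg).sum())


@lru_cache(maxsize=8)
def calibrated_spot_masses(params: DetectorParams = DEFAULT_PARAMS) -> tuple[float, float]:
    """(HER2, CEN17) channel mass of one rendered reference spot.

    A single Gaussian spot of the reference color is stamped on a nucleus-
    colored patch and measured with the same extraction used at inference,
    so estimated spot counts are unbiased by the mass floor.
    """
    from .synthetic import stamp_spot  # deferred: synthetic imports scoring only

    masses = []
    for color in (params.calib_her2_color, params.calib_cen17_color):
        canvas = np.empty((64, 64, 3), dtype=float)
        canvas[:] = np.asarray(params.calib_nucleus_color, dtype=float)
        stamp_spot(canvas, 32.0, 32.0, params.psf_sigma, np.asarray(color, dtype=float))
        patch = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
        if color is params.calib_her2_color:
            masses.append(_channel_mass(her2_channel(patch, params), params.mass_floor))
        else:
            masses.append(_channel_mass(cen17_channel(patch, params), params.mass_floor))
    her2_mass, cen17_mass = masses
    if her2_mass <= 0 or cen17_mass <= 0:
        raise RuntimeError("spot-mass calibration failed: zero mass measured")
    return her2_mass, cen17_mass


# ---------------------------------------------------------------------------
# Nucleus detection and appearance grading
# ---------------------------------------------------------------------------

def detect_nuclei(
    image: np.ndarray, params: DetectorParams = DEFAULT_PARAMS
) -> list[NucleusDetection]:
    """Localize and grade all nuclei in a whole FISH image.

    Deterministic: thresholded DAPI-channel segmentation followed by
    per-component appearance grading.  Output is sorted by descending
    confidence, ties broken in raster order.
    """
    arr = _check_rgb(image)
    blue = ndimage.gaussian_filter(arr[..., 2], params.nucleus_smooth_sigma)
    if params.nucleus_threshold != "otsu":
        raise ValueError(f"unknown threshold method {params.nucleus_threshold!r}")
    thr = max(float(threshold_otsu(blue)), params.nucleus_threshold_floor)
    mask = ndimage.binary_fill_holes(blue > thr)
    labelled = label(mask, connectivity=2)
    detections = []
    for region in regionprops(labelled):
        if not (params.nucleus_min_area <= region.area <= params.nucleus_max_area):
            continue
        y0, x0, y1, x1 = region.bbox
        box = BoundingBox(int(x0), int(y0), int(x1), int(y1))
        cls, conf = classify_nucleus_appearance(image, box, params)
        detections.append(NucleusDetection(box=box, appearance_class=cls, confidence=conf))
    detections.sort(key=lambda d: (-d.confidence, d.box.y_min, d.box.x_min))
    return detections


def _margin_confidence(value: float, boundaries: Sequence[float], scale: float) -> float:
    """Map distance-to-nearest-decision-boundary onto a [0.05, 1] score."""
    margin = min(abs(value - b) for b in boundaries)
    return float(np.clip(margin / scale, 0.05, 1.0))


def classify_nucleus_appearance(
    image: np.ndarray, box: BoundingBox, params: DetectorParams = DEFAULT_PARAMS
) -> tuple[NucleusClass, float]:
    """First read: grade a nucleus from integrated hue masses, not spot counts.

    Estimated spot-equivalents come from dividing each channel's
    background-subtracted mass by the calibrated one-spot mass.  A nucleus
    with essentially no CEN17 mass is an artifact; about one CEN17 spot is
    uncertain; otherwise the HER2/CEN17 spot-equivalent ratio is graded with
    the usual 1.5 / 6.0 boundaries.  A contiguous HER2-positive area above
    the cluster threshold marks strong amplification directly (the visual
    signature of a HER2 cluster), forcing a ``high`` read.
    """
    arr = _check_rgb(image)
    h, w = arr.shape[:2]
    if box.x_max > w or box.y_max > h:
        raise ValueError(f"box {box} does not fit image of size {(w, h)}")
    crop = arr[box.y_min:box.y_max, box.x_min:box.x_max].astype(np.uint8)
    her2 = her2_channel(crop, params)
    cen17 = cen17_channel(crop, params)
    her2_spot_mass, cen17_spot_mass = calibrated_spot_masses(params)

    n_cen17_est = _channel_mass(cen17, params.mass_floor) / cen17_spot_mass
    n_her2_est = _channel_mass(her2, params.mass_floor) / her2_spot_mass

    if n_cen17_est < params.artifact_cen17_floor:
        conf = _margin_confidence(n_cen17_est, [params.artifact_cen17_floor], 0.5)
        return NucleusClass.ARTIFACT, conf
    if n_cen17_est < params.uncertain_cen17_floor:
        conf = _margin_confidence(
            n_cen17_est, [params.artifact_cen17_floor, params.uncertain_cen17_floor], 0.5
        )
        return NucleusClass.UNCERTAIN, conf

    # cluster signature: one large contiguous HER2-positive area
    bg = float(np.median(her2))
    her2_regions = label(her2 > bg + params.mass_floor, connectivity=2)
    if her2_regions.max() and max(r.area for r in regionprops(her2_regions)) >= params.cluster_area_threshold:
        return NucleusClass.HIGH, 1.0

    ratio = n_her2_est / n_cen17_est if n_her2_est >= 0.5 else 1.0
    conf = _margin_confidence(ratio, [params.ratio_low_lo, params.ratio_high_lo], 1.5)
    if ratio <= params.ratio_low_lo:
        return NucleusClass.NORMAL, conf
    if ratio <= params.ratio_high_lo:
        return NucleusClass.LOW, conf
    return NucleusClass.HIGH, conf


# ---------------------------------------------------------------------------
# Signal detection
# ---------------------------------------------------------------------------

def _nms(detections: list[SignalDetection], iou_threshold: float) -> list[SignalDetection]:
    kept: list[SignalDetection] = []
    for det in sorted(detections, key=lambda d: (-d.confidence, d.box)):
        if all(det.box.iou(k.box) < iou_threshold for k in kept):
            kept.append(det)
    return kept


def _blob_detections(
    channel: np.ndarray, signal_class: SignalClass, params: DetectorParams,
    width: int, height: int,
) -> list[SignalDetection]:
    blobs = blob_log(
        channel / 255.0,
        min_sigma=params.log_min_sigma,
        max_sigma=params.log_max_sigma,
        num_sigma=params.log_num_sigma,
        threshold=params.spot_threshold,
        overlap=0.3,
    )
    half = 3.0 * params.psf_sigma
    out = []
    for y, x, _sigma in blobs:
        x0, y0 = int(round(x - half)), int(round(y - half))
        x1, y1 = int(round(x + half)), int(round(y + half))
        x0, y0 = max(0, x0), max(0, y0)
        x1, y1 = min(width, max(x1, x0 + 1)), min(height, max(y1, y0 + 1))
        peak = float(channel[int(round(y)), int(round(x))]) / 255.0
        out.append(SignalDetection(
            box=BoundingBox(x0, y0, x1, y1),
            signal_class=signal_class,
            confidence=float(np.clip(peak, 0.05, 1.0)),
        ))
    return out


def detect_signals(
    crop: np.ndarray, params: DetectorParams = DEFAULT_PARAMS
) -> list[SignalDetection]:
    """Localize and classify FISH signals in a nucleus crop (crop-local boxes).

    HER2 and CEN17 spots are found independently in their unmixed channels
    by multiscale LoG detection; HER2-positive contiguous regions whose area
    exceeds the cluster threshold become a single ``HER2_cluster`` box, and
    single-HER2 blobs inside any cluster box are suppressed.
    """
    arr = _check_rgb(crop)
    h, w = arr.shape[:2]
    her2 = her2_channel(crop, params)
    cen17 = cen17_channel(crop, params)

    # HER2 clusters: large contiguous positive regions
    bg = float(np.median(her2))
    regions = label(her2 > bg + params.mass_floor, connectivity=2)
    clusters: list[SignalDetection] = []
    for region in regionprops(regions):
        if region.area >= params.cluster_area_threshold:
            y0, x0, y1, x1 = region.bbox
            clusters.append(SignalDetection(
                box=BoundingBox(int(x0), int(y0), int(x1), int(y1)),
                signal_class=SignalClass.HER2_CLUSTER,
                confidence=float(np.clip(region.area / (4 * params.cluster_area_threshold), 0.05, 1.0)),
            ))

    her2_blobs = _blob_detections(her2, SignalClass.HER2, params, w, h)
    her2_blobs = [
        b for b in her2_blobs
        if not any(c.box.contains_point(*b.box.center) for c in clusters)
    ]
    cen17_blobs = _blob_detections(cen17, SignalClass.CEN17, params, w, h)

    detections = (
        _nms(her2_blobs, params.nms_iou)
        + _nms(cen17_blobs, params.nms_iou)
        + clusters
    )
    detections.sort(key=lambda d: (-d.confidence, d.box))
    return detections


# ---------------------------------------------------------------------------
# Signal-to-nucleus assignment
# ---------------------------------------------------------------------------

def assign_signals(
    nuclei: Sequence[NucleusDetection] | Sequence[BoundingBox],
    signals: Sequence[SignalDetection],
) -> tuple[list[SignalCounts], list[int]]:
    """Assign image-coordinate signals to nuclei by box-center containment.

    A signal belongs to the nucleus whose box contains its center; when
    several boxes contain it (overlapping nuclei), the nucleus whose box
    center is nearest wins, ties going to the lower nucleus index.  Returns
    per-nucleus :class:`SignalCounts` and the indices of unassigned signals.
    """
    boxes = [n.box if isinstance(n, NucleusDetection) else n for n in nuclei]
    her2 = [0] * len(boxes)
    cen17 = [0] * len(boxes)
    cluster = [0] * len(boxes)
    unassigned: list[int] = []
    for si, sig in enumerate(signals):
        cx, cy = sig.box.center
        candidates = [i for i, b in enumerate(boxes) if b.contains_point(cx, cy)]
        if not candidates:
            unassigned.append(si)
            continue
        owner = min(candidates, key=lambda i: (math.dist(boxes[i].center, (cx, cy)), i))
        if sig.signal_class is SignalClass.HER2:
            her2[owner] += 1
        elif sig.signal_class is SignalClass.CEN17:
            cen17[owner] += 1
        else:
            cluster[owner] += 1
    counts = [SignalCounts(h, c, k) for h, c, k in zip(her2, cen17, cluster)]
    return counts, unassigned


# ---------------------------------------------------------------------------
# Detection-vs-truth matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Matching:
    """Greedy one-to-one IoU matching between predictions and truths."""

    pairs: tuple[tuple[int, int, float], ...]  # (prediction idx, truth idx, IoU)
    unmatched_predictions: tuple[int, ...]
    unmatched_truths: tuple[int, ...]


def match_detections(
    predictions: Sequence[BoundingBox],
    truths: Sequence[BoundingBox],
    iou_threshold: float = 0.5,
) -> Matching:
    """Greedy matching by descending IoU; pairs below threshold are not made."""
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in (0, 1]")
    candidates = []
    for i, p in enumerate(predictions):
        for j, t in enumerate(truths):
            iou = p.iou(t)
            if iou >= iou_threshold:
                candidates.append((iou, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for iou, i, j in candidates:
        if i in used_p or j in used_t:
            continue
        pairs.append((i, j, iou))
        used_p.add(i)
        used_t.add(j)
    return Matching(
        pairs=tuple(pairs),
        unmatched_predictions=tuple(i for i in range(len(predictions)) if i not in used_p),
        unmatched_truths=tuple(j for j in range(len(truths)) if j not in used_t),
    )


def detection_metrics(
    predictions: Sequence[BoundingBox],
    truths: Sequence[BoundingBox],
    iou_threshold: float = 0.5,
) -> tuple[float, float, Matching]:
    """(precision, recall, matching); empty sides give the conventional 1.0."""
    m = match_detections(predictions, truths, iou_threshold)
    precision = len(m.pairs) / len(predictions) if predictions else 1.0
    recall = len(m.pairs) / len(truths) if truths else 1.0
    return precision, recall, m
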