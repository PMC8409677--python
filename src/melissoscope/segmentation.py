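"""Grain segmentation: RGB box thresholding plus binary post-processing.

Segmentation follows the published semi-automated recipe: a pixel is
foreground iff each of its R, G, B values lies inside an inclusive
per-channel range (one 6-tuple box per modality), followed by optional
object cleaning (small-component removal), morphological opening and
contour smoothing.  Segmentation is intended to run on the EDF composite
of a focal stack, where every grain pixel is in focus.

Per-modality defaults:

====  =============================  =========  ========  =======
mod   threshold box (low), (high)    smoothing  cleaning  opening
====  =============================  =========  ========  =======
BF    (85, 80, 62) – (130, 122, 98)  —          —         —
DF    (100,107,81) – (169,154,118)   16         —         6 × 3×3
Ph    (71, 72, 59) – (136,132, 90)   —          16        3 × 3×3
====  =============================  =========  ========  =======
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .errors import ConfigurationError, ContractViolation

Channel3 = Tuple[int, int, int]


@dataclasses.dataclass(frozen=True)
class ThresholdBox:
    """Inclusive per-channel RGB acceptance range."""

    low: Channel3
    high: Channel3

    def __post_init__(self) -> None:
        if any(l > h for l, h in zip(self.low, self.high)):
            raise ConfigurationError(
                f"threshold box low {self.low} exceeds high {self.high}"
            )

    @classmethod
    def from_sextuple(cls, t) -> "ThresholdBox":
        rl, gl, bl, rh, gh, bh = t
        return cls((rl, gl, bl), (rh, gh, bh))


@dataclasses.dataclass(frozen=True)
class PostprocessSpec:
    """Binary post-processing settings applied after thresholding.

    Order of application: cleaning → opening → smoothing.
    """

    smoothing_size: Optional[int] = None
    cleaning_size: Optional[int] = None
    opening_iterations: int = 0

    def __post_init__(self) -> None:
        for v in (self.smoothing_size, self.cleaning_size, self.opening_iterations):
            if v is not None and v < 0:
                raise ConfigurationError("post-processing sizes must be >= 0")


@dataclasses.dataclass
class GrainMask:
    """One segmented grain: full-frame binary mask plus provenance."""

    mask: np.ndarray
    label_id: int
    bbox: Tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    field_id: str = "field0"
    modality: str = "BF"

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


#: published per-modality settings
THRESHOLDS = {
    "BF": ThresholdBox((85, 80, 62), (130, 122, 98)),
    "DF": ThresholdBox((100, 107, 81), (169, 154, 118)),
    "Ph": ThresholdBox((71, 72, 59), (136, 132, 90)),
}

POSTPROCESS = {
    "BF": PostprocessSpec(),
    "DF": PostprocessSpec(smoothing_size=16, opening_iterations=6),
    "Ph": PostprocessSpec(cleaning_size=16, opening_iterations=3),
}


def threshold_rgb(image: np.ndarray, box: ThresholdBox) -> np.ndarray:
    """Binarize an 8-bit RGB image with an inclusive per-channel box.

    A pixel is foreground iff ``low_c <= value_c <= high_c`` for all three
    channels simultaneously.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ContractViolation("threshold_rgb expects an (H, W, 3) image")
    low = np.asarray(box.low)
    high = np.asarray(box.high)
    return np.logical_and(img >= low, img <= high).all(axis=-1)


_KERNEL3 = np.ones((3, 3), bool)


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = ndi.label(mask, structure=np.ones((3, 3), int))
    if n == 0:
        return mask.copy()
    areas = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_area) + 1
    return np.isin(labels, keep)


def _smooth_contour(mask: np.ndarray, size: int) -> np.ndarray:
    # closing-then-opening with a disc scaled to the stated size; a
    # stand-in for the proprietary contour smoother (see methods note)
    radius = max(1, size // 2)
    footprint = morphology.disk(radius)
    out = morphology.closing(mask, footprint)
    return morphology.opening(out, footprint).astype(bool)


def postprocess(mask: np.ndarray, spec: PostprocessSpec) -> np.ndarray:
    """Apply cleaning → opening → smoothing; an empty spec is the identity."""
    out = np.asarray(mask, bool)
    if spec.cleaning_size:
        out = _remove_small(out, spec.cleaning_size)
    if spec.opening_iterations:
        out = ndi.binary_erosion(out, _KERNEL3,
                                 iterations=spec.opening_iterations)
        out = ndi.binary_dilation(out, _KERNEL3,
                                  iterations=spec.opening_iterations)
    if spec.smoothing_size:
        out = _smooth_contour(out, spec.smoothing_size)
    return out


def label_grains(mask: np.ndarray, min_area: int = 64,
                 border_policy: str = "exclude",
                 field_id: str = "field0",
                 modality: str = "BF") -> List[GrainMask]:
    """Split a binary mask into individual grains.

    8-connected components, labelled in raster order of their first pixel.
    Components touching the image border are dropped under
    ``border_policy='exclude'`` (a partially imaged grain has invalid
    descriptors); components smaller than ``min_area`` pixels are always
    dropped.
    """
    if border_policy not in ("exclude", "keep"):
        raise ConfigurationError(f"unknown border policy {border_policy!r}")
    mask = np.asarray(mask, bool)
    labels, n = ndi.label(mask, structure=np.ones((3, 3), int))
    grains: List[GrainMask] = []
    if n == 0:
        return grains
    slices = ndi.find_objects(labels)
    h, w = mask.shape
    next_id = 0
    for i, sl in enumerate(slices, start=1):
        component = labels == i
        area = int(component.sum())
        if area < min_area:
            continue
        r0, r1 = sl[0].start, sl[0].stop
        c0, c1 = sl[1].start, sl[1].stop
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        if touches and border_policy == "exclude":
            continue
        grains.append(GrainMask(mask=component, label_id=next_id,
                                bbox=(r0, c0, r1, c1),
                                field_id=field_id, modality=modality))
        next_id += 1
    return grains


def segment_field(image: np.ndarray, modality: str,
                  box: ThresholdBox | None = None,
                  spec: PostprocessSpec | None = None,
                  min_area: int = 64,
                  border_policy: str = "exclude",
                  field_id: str = "field0") -> List[GrainMask]:
    """Full segmentation of one composite image under a modality's defaults."""
    if modality not in THRESHOLDS:
        raise ConfigurationError(f"unknown modality {modality!r}")
    box = box or THRESHOLDS[modality]
    spec = spec or POSTPROCESS[modality]
    binary = postprocess(threshold_rgb(image, box), spec)
    return label_grains(binary, min_area=min_area, border_policy=border_policy,
                        field_id=field_id, modality=modality)
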