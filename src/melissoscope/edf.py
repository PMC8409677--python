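"""Extended depth of focus (EDF): focus stacking and height-field measures.

A pollen grain is thicker than the depth of field of a 40× objective, so
each field is acquired as a stack of focal planes.  The EDF composite
takes every pixel from its sharpest plane; the index of the winning plane,
multiplied by the plane spacing, yields a per-pixel height map (Z-map)
which is the basis of the three EDF descriptors:

* ``edf_surface`` — 3D area of the triangulated height field over a grain
  (each pixel cell contributes two triangles, ``a·b/2 + c·d/2``);
* ``edf_roughness`` — ``edf_surface / planimetric area`` (≥ 1, with
  equality iff the height field is flat over the grain);
* ``mean_edf_z`` — mean height over the grain, referenced to the lowest
  point of the grain (absolute stage position carries no meaning across
  fields).

The focus metric is the local variance of the Laplacian of the luminance
(window 9 px by default) — the standard sharpness measure for focus
stacking.  Ties in the per-pixel argmax resolve to the lower plane index.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

from .errors import ParameterError, UndefinedInputError
from .stackio import FocalStack


@dataclasses.dataclass
class EDFResult:
    """Products of focus stacking for one field."""

    composite: np.ndarray       # (H, W, 3) uint8 best-focus colour
    zmap: np.ndarray            # (H, W) float µm, plane_index * spacing
    plane_index: np.ndarray     # (H, W) int winning plane
    focus_scores: np.ndarray    # (n_planes, H, W) float focus maps


def _luminance(plane: np.ndarray) -> np.ndarray:
    return np.asarray(plane, float).mean(axis=-1)


def focus_measure(stack: FocalStack, window: int = 9) -> np.ndarray:
    """Per-plane, per-pixel focus score: local variance of the Laplacian.

    Returns an (n_planes, H, W) nonnegative array.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError("focus window must be odd and >= 3")
    h, w = stack.shape
    if window > min(h, w):
        raise ParameterError("focus window larger than the image")
    scores = np.empty((stack.n_planes, h, w), float)
    for k in range(stack.n_planes):
        lap = ndi.laplace(_luminance(stack.planes[k]))
        m1 = ndi.uniform_filter(lap, size=window)
        m2 = ndi.uniform_filter(lap * lap, size=window)
        scores[k] = np.maximum(m2 - m1 * m1, 0.0)
    return scores


def compose_edf(stack: FocalStack, window: int = 9,
                smooth: bool = True) -> EDFResult:
    """Build the EDF composite and Z-map from a focal stack.

    Per pixel the winning plane is the focus-score argmax (ties resolve to
    the lower index).  With ``smooth`` the index map is passed through a
    3×3 median filter before the colour lookup and height conversion,
    which suppresses isolated misfocus pixels.
    """
    scores = focus_measure(stack, window=window)
    k_star = np.argmax(scores, axis=0)
    if smooth:
        k_star = ndi.median_filter(k_star, size=3)
    rows, cols = np.indices(k_star.shape)
    composite = stack.planes[k_star, rows, cols]
    zmap = k_star.astype(float) * stack.plane_spacing
    return EDFResult(composite=composite, zmap=zmap,
                     plane_index=k_star, focus_scores=scores)


def _corner_heights(zmap: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Heights at pixel corners: mean of the adjacent in-mask pixel centres.

    Returns an (H+1, W+1) array; corners with no adjacent mask pixel are 0
    (they are never referenced by an in-mask cell).
    """
    z = np.where(mask, zmap, 0.0)
    m = mask.astype(float)
    h, w = zmap.shape
    zsum = np.zeros((h + 1, w + 1))
    cnt = np.zeros((h + 1, w + 1))
    for dr in (0, 1):
        for dc in (0, 1):
            zsum[dr:h + dr, dc:w + dc] += z
            cnt[dr:h + dr, dc:w + dc] += m
    with np.errstate(invalid="ignore"):
        corners = np.where(cnt > 0, zsum / np.maximum(cnt, 1), 0.0)
    return corners


def edf_surface(zmap: np.ndarray, mask: np.ndarray, pixel_size: float) -> float:
    """3D surface area (µm²) of the height field over a grain mask.

    Each in-mask pixel is a ps×ps cell whose four corner heights are
    interpolated from the adjacent in-mask pixel centres; the cell is split
    into two triangles and their areas summed.  A flat field yields exactly
    the planimetric area; every cell contributes at least ps², so the
    result is always ≥ the planimetric area.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise UndefinedInputError("edf_surface of an empty mask")
    ps = float(pixel_size)
    corners = _corner_heights(np.asarray(zmap, float), mask)
    c00 = corners[:-1, :-1][mask]
    c01 = corners[:-1, 1:][mask]
    c10 = corners[1:, :-1][mask]
    c11 = corners[1:, 1:][mask]
    # triangle (c00, c10, c01) anchored at c00 and (c11, c01, c10) at c11;
    # each area = ps/2 * sqrt(ps^2 + dz_row^2 + dz_col^2)
    a1 = 0.5 * ps * np.sqrt(ps * ps + (c10 - c00) ** 2 + (c01 - c00) ** 2)
    a2 = 0.5 * ps * np.sqrt(ps * ps + (c01 - c11) ** 2 + (c10 - c11) ** 2)
    return float(np.sum(a1 + a2))


def edf_roughness(surface: float, area: float) -> float:
    """Ratio of 3D surface to planimetric area; ≥ 1 by construction."""
    if area <= 0:
        raise UndefinedInputError("edf_roughness needs a positive area")
    return float(surface) / float(area)


def mean_edf_z(zmap: np.ndarray, mask: np.ndarray) -> float:
    """Mean height (µm) over the grain, referenced to its lowest point."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise UndefinedInputError("mean_edf_z of an empty mask")
    z = np.asarray(zmap, float)[mask]
    return float(np.mean(z - z.min()))
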