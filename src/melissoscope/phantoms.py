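"""Synthetic pollen phantoms: ground-truth masks, rendered focal stacks
and directly sampled feature tables.

The real study material (pollen filtered from honey and imaged under
three transmitted-light modalities) is not deposited anywhere, so every
downstream stage of this package is exercised on phantoms parameterized
from the published per-taxon statistics (:mod:`melissoscope.book`):

* :func:`make_grain_mask` rasterizes one grain: an ellipse whose major
  axis and axis ratio are drawn from the taxon's published length and
  elongation distributions, with the boundary modulated by the taxon's
  exine sculpture class (echinate adds radial spines, reticulate /
  micro-reticulate / striate add low-amplitude boundary perturbation,
  psilate none).
* :func:`render_focal_stack` turns placed grains into a 5-plane RGB
  stack: grain interiors coloured from the published per-modality RGB
  means, a dome-plus-texture height field decides each pixel's sharpest
  plane, and out-of-focus planes are Gaussian-blurred in proportion to
  defocus distance.
* :func:`sample_feature_table` skips rendering entirely and draws
  30-descriptor vectors from independent per-descriptor Gaussians — the
  surrogate used for the classification experiments (the publication
  reports only marginal means/SDs, no covariances, so independence is the
  only available choice; it is optimistic relative to real correlated
  features).

Default pixel size is 0.16 µm/px, typical 40× objective sampling, so the
seven taxa span roughly 110–400 px across.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .book import DESCRIPTORS, EXINE_CLASS, MODALITIES, SIZE_LIKE, TAXA, stats_book
from .errors import ConfigurationError, SizingError
from .segmentation import THRESHOLDS
from .stackio import FeatureTable, FocalStack

EXINE_CLASSES = ("echinate", "striate", "psilate", "reticulate", "micro_reticulate")

#: fixed exine geometry per sculpture class: (spine height µm, spine count,
#: boundary ripple amplitude µm, ripple frequency).  Chosen to reproduce
#: the ordering relations (echinate roughest), not exact texture statistics.
_EXINE_GEOMETRY = {
    "echinate": (2.0, 24, 0.0, 0),
    "striate": (0.0, 0, 0.30, 10),
    "psilate": (0.0, 0, 0.0, 0),
    "reticulate": (0.0, 0, 0.20, 16),
    "micro_reticulate": (0.0, 0, 0.12, 24),
}

_BACKGROUND_RGB = {
    "BF": (205, 205, 208),
    "DF": (14, 14, 18),
    "Ph": (165, 165, 168),
}

_HALO_RGB = {
    "BF": None,
    "DF": (225, 222, 200),
    "Ph": (215, 215, 218),
}


@dataclasses.dataclass
class TaxonAppearance:
    """Everything needed to draw and colour one taxon under one modality."""

    taxon_name: str
    modality: str
    length_mean: float          # µm, published major-axis length
    length_sd: float
    elongation_mean: float      # dimensionless, MaxFeret/MinFeret
    elongation_sd: float
    exine_class: str
    interior_rgb_mean: Tuple[float, float, float]
    interior_rgb_sd: Tuple[float, float, float]
    spine_height: float = 0.0   # µm, echinate only
    ripple_amplitude: float = 0.0  # µm, reticulate/striate classes
    ripple_frequency: int = 0
    spine_count: int = 0
    z_relief_mean: float = 8.0  # µm, dome height driving the EDF Z-map

    def __post_init__(self) -> None:
        if self.length_mean <= 0:
            raise ConfigurationError("length_mean must be positive")
        if self.elongation_mean < 1:
            raise ConfigurationError("elongation_mean must be >= 1")
        if self.length_sd < 0 or self.elongation_sd < 0:
            raise ConfigurationError("sd values must be >= 0")
        if self.exine_class not in EXINE_CLASSES:
            raise ConfigurationError(f"unknown exine class {self.exine_class!r}")
        if not all(0 <= c <= 255 for c in self.interior_rgb_mean):
            raise ConfigurationError("interior_rgb_mean outside [0, 255]")


def appearance_from_book(taxon: str, modality: str,
                         exine_class: Optional[str] = None) -> TaxonAppearance:
    """Build a :class:`TaxonAppearance` from the published statistics."""
    if taxon not in TAXA:
        raise ConfigurationError(f"unknown taxon {taxon!r}")
    if modality not in MODALITIES:
        raise ConfigurationError(f"unknown modality {modality!r}")
    book = stats_book()[modality][taxon]
    exine = exine_class or EXINE_CLASS[taxon]
    spine_h, spine_n, ripple_a, ripple_f = _EXINE_GEOMETRY[exine]
    iv = book["intensity_variation"][0]
    # per-channel sd sqrt(3)*IV so that the per-pixel intensity (channel
    # mean of 3 independent channels) has SD matching the published IV
    channel_sd = iv * math.sqrt(3.0)
    return TaxonAppearance(
        taxon_name=taxon, modality=modality,
        length_mean=book["length"][0], length_sd=book["length"][1],
        elongation_mean=max(book["elongation"][0], 1.0),
        elongation_sd=book["elongation"][1],
        exine_class=exine,
        interior_rgb_mean=(book["mean_red"][0], book["mean_green"][0],
                           book["mean_blue"][0]),
        interior_rgb_sd=(channel_sd, channel_sd, channel_sd),
        spine_height=spine_h, spine_count=spine_n,
        ripple_amplitude=ripple_a, ripple_frequency=ripple_f,
        z_relief_mean=book["mean_edf_z"][0],
    )


@dataclasses.dataclass
class GrainTruth:
    """Ground truth for one rendered grain."""

    taxon: str
    modality: str
    true_major_um: float
    true_minor_um: float
    centroid: Tuple[float, float]    # (row, col) px
    mask: np.ndarray                 # bool, grain-local or full-frame
    appearance: Optional[TaxonAppearance] = None


@dataclasses.dataclass
class SceneConfig:
    """Configuration of one synthetic field of view."""

    taxa: Sequence[TaxonAppearance]
    grains_per_taxon: int = 1
    image_size: int = 768
    pixel_size: float = 0.16          # µm/px, 40x objective sampling
    n_planes: int = 5
    plane_spacing: float = 8.0        # µm
    defocus_sigma_per_um: float = 0.3  # px of Gaussian blur per µm defocus
    clip_colours: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planes < 2:
            raise ConfigurationError("n_planes must be >= 2")
        if self.plane_spacing <= 0 or self.pixel_size <= 0:
            raise ConfigurationError("spacing and pixel size must be positive")


# ---------------------------------------------------------------------------
# grain rasterization
# ---------------------------------------------------------------------------

_N_THETA = 2048


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float) -> float:
    if sd == 0:
        return max(mean, low)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > low:
            return v
    return low + abs(rng.normal(0, sd)) + 1e-9


def make_grain_mask(appearance: TaxonAppearance, pixel_size: float,
                    rng: np.random.Generator,
                    orientation: Optional[float] = None
                    ) -> Tuple[np.ndarray, GrainTruth]:
    """Rasterize one grain; returns (mask, truth).

    The elliptical envelope has its major axis drawn from
    Normal(length_mean, length_sd) truncated at > 2 µm and its axis ratio
    from Normal(elongation_mean, elongation_sd) truncated at ≥ 1; the
    exine class modulates the boundary.  The truth records the drawn axes
    exactly.
    """
    if pixel_size <= 0:
        raise ConfigurationError("pixel_size must be positive")
    major = _truncated_normal(rng, appearance.length_mean,
                              appearance.length_sd, 2.0)
    ratio = max(_truncated_normal(rng, appearance.elongation_mean,
                                  appearance.elongation_sd, 0.0), 1.0)
    minor = major / ratio
    if minor / pixel_size < 20:
        raise SizingError(
            f"grain would span {minor / pixel_size:.1f} px across; "
            "pixel size too coarse (< 20 px minimum)")
    phi = rng.uniform(0, math.pi) if orientation is None else float(orientation)

    a = major / 2.0 / pixel_size   # semi-axes in px
    b = minor / 2.0 / pixel_size
    theta = np.linspace(0.0, 2.0 * math.pi, _N_THETA, endpoint=False)
    # polar radius of the rotated ellipse
    ct, st = np.cos(theta - phi), np.sin(theta - phi)
    r = a * b / np.sqrt((b * ct) ** 2 + (a * st) ** 2)

    if appearance.exine_class == "echinate" and appearance.spine_height > 0:
        n = appearance.spine_count
        phase = rng.uniform(0, 2 * math.pi)
        bump = np.maximum(np.cos(n * theta + phase), 0.0) ** 40
        r = r + (appearance.spine_height / pixel_size) * bump
    elif appearance.ripple_amplitude > 0:
        phase = rng.uniform(0, 2 * math.pi)
        r = r + (appearance.ripple_amplitude / pixel_size) * np.sin(
            appearance.ripple_frequency * theta + phase)

    pad = 4
    half = int(math.ceil(r.max())) + pad
    size = 2 * half + 1
    centre = float(half)
    rows = centre + r * np.sin(theta)
    cols = centre + r * np.cos(theta)
    rr, cc = skdraw.polygon(rows, cols, shape=(size, size))
    mask = np.zeros((size, size), bool)
    mask[rr, cc] = True
    # guarantee a single 4-connected component (spike tips can detach)
    labels, n_comp = ndi.label(mask, structure=np.array([[0, 1, 0],
                                                         [1, 1, 1],
                                                         [0, 1, 0]]))
    if n_comp > 1:
        areas = ndi.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        mask = labels == (1 + int(np.argmax(areas)))
    truth = GrainTruth(taxon=appearance.taxon_name,
                       modality=appearance.modality,
                       true_major_um=major, true_minor_um=minor,
                       centroid=(centre, centre), mask=mask,
                       appearance=appearance)
    return mask, truth


# ---------------------------------------------------------------------------
# scene assembly and rendering
# ---------------------------------------------------------------------------

def make_scene(config: SceneConfig, modality: str,
               rng: Optional[np.random.Generator] = None
               ) -> List[GrainTruth]:
    """Draw and place grains without overlap in a full-frame label image.

    Returned truths carry full-frame masks.  Raises
    :class:`ConfigurationError` when the field cannot host the requested
    grains without overlap.
    """
    if modality not in MODALITIES:
        raise ConfigurationError(f"unknown modality {modality!r}")
    rng = rng or np.random.default_rng(config.rng_seed)
    size = config.image_size
    occupied = np.zeros((size, size), bool)
    drawn: List[Tuple[np.ndarray, GrainTruth]] = []
    for appearance in config.taxa:
        if appearance.modality != modality:
            appearance = dataclasses.replace(appearance, modality=modality)
        for _ in range(config.grains_per_taxon):
            drawn.append(make_grain_mask(appearance, config.pixel_size, rng))
    # place largest grains first: greedy packing succeeds far more often
    drawn.sort(key=lambda item: -int(item[0].sum()))
    placed: List[GrainTruth] = []
    for local, truth in drawn:
        gh, gw = local.shape
        if gh >= size - 2 or gw >= size - 2:
            raise ConfigurationError("grain larger than the field")
        # grow the exclusion zone slightly so grains never touch
        grown = ndi.binary_dilation(local, iterations=3)
        ok = False
        for _try in range(400):
            r0 = int(rng.integers(1, size - gh - 1))
            c0 = int(rng.integers(1, size - gw - 1))
            if not (occupied[r0:r0 + gh, c0:c0 + gw] & grown).any():
                ok = True
                break
        if not ok:
            raise ConfigurationError(
                "could not place grain without overlap; "
                "enlarge image_size or reduce grains_per_taxon")
        occupied[r0:r0 + gh, c0:c0 + gw] |= grown
        full = np.zeros((size, size), bool)
        full[r0:r0 + gh, c0:c0 + gw] = local
        placed.append(GrainTruth(
            taxon=truth.taxon, modality=modality,
            true_major_um=truth.true_major_um,
            true_minor_um=truth.true_minor_um,
            centroid=(truth.centroid[0] + r0, truth.centroid[1] + c0),
            mask=full, appearance=truth.appearance))
    return placed


def build_height_field(grains: Sequence[GrainTruth], config: SceneConfig
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pixel physical height (µm) and the exine-relief pixel set.

    Each grain is a cone in the normalized interior distance ``dn``
    (``h = 3 × z_relief_mean × dn``): the mean of ``dn`` over a disc is
    1/3, so the baseline-referenced mean height over the grain equals the
    published mean EDF-Z, and the height stays below one plane spacing in
    a wide band along the rim, which keeps the rim pixels assigned to the
    bottom focal plane.  Echinate grains get raised apices at the spine
    positions on top of the cone.
    """
    size = config.image_size
    height = np.zeros((size, size))
    relief = np.zeros((size, size), bool)
    for grain in grains:
        mask = grain.mask
        edt = ndi.distance_transform_edt(mask)
        peak = edt.max()
        if peak == 0:
            continue
        dn = edt / peak
        app = grain.appearance
        z_top = 3.0 * (app.z_relief_mean if app is not None else 8.0)
        dome = z_top * dn
        if app is not None and app.exine_class == "echinate" and app.spine_height > 0:
            ring = mask & (dn > 0.15) & (dn < 0.45)
            rows, cols = np.nonzero(ring)
            if rows.size:
                idx = np.arange(0, rows.size, max(1, rows.size // 40))
                spine_px = np.zeros_like(mask)
                spine_px[rows[idx], cols[idx]] = True
                spine_px = ndi.binary_dilation(spine_px, iterations=2) & mask
                dome = np.where(spine_px, dome + 2.0 * app.spine_height, dome)
                relief |= spine_px
        height = np.where(mask, dome, height)
    return height, relief


def render_focal_stack(grains: Sequence[GrainTruth], config: SceneConfig,
                       modality: str,
                       rng: Optional[np.random.Generator] = None,
                       field_id: str = "field0") -> FocalStack:
    """Render placed grains into an n-plane RGB focal stack.

    The all-in-focus colour image is built first (background, grain
    interiors with Gaussian texture noise, rim halo for DF/Ph); the height
    field assigns each pixel its sharpest plane; plane k then shows each
    pixel blurred with sigma = defocus_sigma_per_µm × |z_k − z_pixel|.
    """
    if modality not in _BACKGROUND_RGB:
        raise ConfigurationError(f"unknown modality {modality!r}")
    rng = rng or np.random.default_rng(config.rng_seed + 1)
    size = config.image_size
    base = np.empty((size, size, 3))
    base[...] = np.array(_BACKGROUND_RGB[modality], float)

    all_mask = np.zeros((size, size), bool)
    box = THRESHOLDS[modality]
    for grain in grains:
        mask = grain.mask
        all_mask |= mask
        app = grain.appearance
        if app is None:
            continue
        n_px = int(mask.sum())
        colour = (np.array(app.interior_rgb_mean)
                  + rng.standard_normal((n_px, 3)) * np.array(app.interior_rgb_sd))
        if config.clip_colours:
            colour = np.clip(colour, np.array(box.low, float),
                             np.array(box.high, float))
        base[mask] = colour

    halo = _HALO_RGB[modality]
    if halo is not None:
        ring = ndi.binary_dilation(all_mask, iterations=3) & ~all_mask
        base[ring] = np.array(halo, float)

    height, _ = build_height_field(grains, config)
    k_star = np.clip(np.rint(height / config.plane_spacing), 0,
                     config.n_planes - 1).astype(int)

    # one blurred copy of the base image per defocus level (in planes)
    blurred = []
    for level in range(config.n_planes):
        sigma = config.defocus_sigma_per_um * level * config.plane_spacing
        if sigma == 0:
            blurred.append(base)
        else:
            blurred.append(np.stack(
                [ndi.gaussian_filter(base[..., c], sigma) for c in range(3)],
                axis=-1))
    blurred = np.stack(blurred)            # (levels, H, W, 3)

    rows, cols = np.indices((size, size))
    planes = np.empty((config.n_planes, size, size, 3), np.uint8)
    for k in range(config.n_planes):
        level = np.abs(k - k_star)
        planes[k] = np.clip(blurred[level, rows, cols], 0, 255).astype(np.uint8)
    return FocalStack(planes=planes, pixel_size=config.pixel_size,
                      plane_spacing=config.plane_spacing, modality=modality,
                      field_id=field_id)


# ---------------------------------------------------------------------------
# feature-mode sampling
# ---------------------------------------------------------------------------

def sample_feature_table(stats_book_dict: Optional[Dict] = None,
                         n_per_taxon: int = 300,
                         modality: str = "BF",
                         rng_seed: int | np.random.Generator = 0,
                         taxa: Optional[Sequence[str]] = None) -> FeatureTable:
    """Draw a feature table from independent per-descriptor Gaussians.

    Each row is one synthetic grain; each descriptor is drawn from
    Normal(mean, sd) of the taxon's book entry, with size-like descriptors
    truncated at > 0.  Reproducible under a fixed seed.
    """
    if modality not in MODALITIES:
        raise ConfigurationError(f"unknown modality {modality!r}")
    book = (stats_book_dict or stats_book())[modality]
    use_taxa = tuple(taxa) if taxa is not None else TAXA
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    records = []
    for taxon in use_taxa:
        if taxon not in book:
            raise ConfigurationError(f"no statistics for taxon {taxon!r}")
        entry = book[taxon]
        missing = [d for d in DESCRIPTORS if d not in entry]
        if missing:
            raise ConfigurationError(
                f"taxon {taxon!r} lacks descriptors: {missing}")
        cols = {}
        for desc in DESCRIPTORS:
            mean, sd = entry[desc]
            vals = rng.normal(mean, sd, size=n_per_taxon)
            if desc in SIZE_LIKE and sd > 0:
                for _ in range(100):
                    bad = vals <= 0
                    if not bad.any():
                        break
                    vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                vals = np.abs(vals) + 1e-12 * (vals == 0)
            cols[desc] = vals
        for i in range(n_per_taxon):
            row = {d: float(cols[d][i]) for d in DESCRIPTORS}
            row["grain_id"] = f"{modality}:{taxon}:{i}"
            row["taxon"] = taxon
            row["modality"] = modality
            records.append(row)
    if not records:
        return FeatureTable.empty()
    return FeatureTable.from_records(records)
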