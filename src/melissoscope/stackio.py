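"""Dataset model and file I/O shared by all pipeline stages.

A :class:`FocalStack` is one microscope field of view: an ordered list of
registered 8-bit RGB planes acquired at increasing stage height (default
5 planes, 8 µm apart), plus the physical calibration needed to convert
pixels to micrometres.  A :class:`FeatureTable` is the grains × descriptors
interchange object between feature extraction and statistics.

Calibration deliberately lives in the manifest/config rather than in TIFF
tags: resolution tags are written for convenience but never trusted on
read, which sidesteps TIFF dialect ambiguity.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, List, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .book import DESCRIPTORS, UNITS
from .errors import FormatError, SchemaError, StackError

#: metadata columns of a feature table, in canonical order
META_COLUMNS = ("grain_id", "taxon", "modality")

#: full canonical column order of a feature-table CSV
TABLE_COLUMNS = META_COLUMNS + DESCRIPTORS

VALID_MODALITIES = ("BF", "DF", "Ph")


@dataclasses.dataclass
class FocalStack:
    """One field of view: registered RGB planes bottom→top plus calibration.

    Parameters
    ----------
    planes:
        (n_planes, H, W, 3) uint8 array, plane 0 lowest.
    pixel_size:
        Lateral calibration in µm/px.
    plane_spacing:
        Axial distance between consecutive planes in µm.
    modality:
        One of ``BF`` (bright field), ``DF`` (dark field), ``Ph`` (phase
        contrast).
    field_id:
        Free-form label of the field of view.
    """

    planes: np.ndarray
    pixel_size: float
    plane_spacing: float
    modality: str
    field_id: str = "field0"

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim != 4 or self.planes.shape[-1] != 3:
            raise StackError(
                f"planes must be (n, H, W, 3); got shape {self.planes.shape}"
            )
        if self.planes.shape[0] < 2:
            raise StackError("a focal stack needs at least 2 planes")
        if self.planes.dtype != np.uint8:
            raise StackError("planes must be 8-bit per channel")
        if self.pixel_size <= 0 or self.plane_spacing <= 0:
            raise StackError("pixel_size and plane_spacing must be positive")
        if self.modality not in VALID_MODALITIES:
            raise StackError(f"unknown modality {self.modality!r}")

    @property
    def n_planes(self) -> int:
        return int(self.planes.shape[0])

    @property
    def shape(self) -> tuple:
        return tuple(self.planes.shape[1:3])

    def plane_z(self, k: int) -> float:
        """Stage height of plane ``k`` in µm above the bottom plane."""
        return float(k) * self.plane_spacing


def write_stack(stack: FocalStack, path) -> None:
    """Write the stack as a multi-page 8-bit RGB TIFF (planes bottom→top)."""
    res = 1.0 / (stack.pixel_size * 1e-4)  # px per cm, informational only
    tifffile.imwrite(
        str(path),
        stack.planes,
        photometric="rgb",
        resolution=(res, res),
        resolutionunit="CENTIMETER",
    )


def read_stack(path, pixel_size: float, plane_spacing: float,
               modality: str, field_id: str | None = None) -> FocalStack:
    """Read a multi-page RGB TIFF into a :class:`FocalStack`.

    Calibration is supplied by the caller; TIFF resolution tags are ignored.
    """
    path = Path(path)
    try:
        pages = tifffile.imread(str(path))
    except Exception as exc:  # pragma: no cover - delegated decode errors
        raise FormatError(f"cannot decode {path}: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 3 and pages.shape[-1] == 3:
        raise StackError(f"{path} holds a single plane; a stack needs >= 2")
    if pages.ndim != 4 or pages.shape[-1] != 3:
        raise FormatError(f"{path}: pages are not same-shape RGB images")
    if pages.dtype != np.uint8:
        raise FormatError(f"{path}: expected 8-bit per channel, got {pages.dtype}")
    return FocalStack(
        planes=pages,
        pixel_size=pixel_size,
        plane_spacing=plane_spacing,
        modality=modality,
        field_id=field_id or path.stem,
    )


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as 8-bit PNG, 255=foreground, 0=background."""
    iio.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask_png(path) -> np.ndarray:
    """Read a PNG mask back to boolean (any nonzero pixel is foreground)."""
    arr = iio.imread(str(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


class FeatureTable:
    """Grains × descriptors table with taxon and modality labels.

    Thin validated wrapper around a :class:`pandas.DataFrame` whose column
    set is exactly the 30 canonical descriptors plus the metadata columns
    ``grain_id``, ``taxon``, ``modality``.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in TABLE_COLUMNS if c not in frame.columns]
        extra = [c for c in frame.columns if c not in TABLE_COLUMNS]
        if missing or extra:
            raise SchemaError(
                f"feature table schema mismatch; missing={missing}, extra={extra}"
            )
        frame = frame[list(TABLE_COLUMNS)].reset_index(drop=True)
        if len(frame):
            frame = frame.astype({d: float for d in DESCRIPTORS})
        desc = frame[list(DESCRIPTORS)]
        if len(frame) and not np.isfinite(desc.to_numpy(float)).all():
            raise SchemaError("descriptor columns contain non-finite values")
        self.frame = frame

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "FeatureTable":
        recs = list(records)
        if not recs:
            return cls.empty()
        return cls(pd.DataFrame.from_records(recs))

    @classmethod
    def empty(cls) -> "FeatureTable":
        return cls(pd.DataFrame({c: pd.Series(dtype=object if c in META_COLUMNS
                                              else float)
                                 for c in TABLE_COLUMNS}))

    # -- behaviour ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def descriptors(self) -> pd.DataFrame:
        """The numeric grains × 30 descriptor block."""
        return self.frame[list(DESCRIPTORS)]

    @property
    def taxa(self) -> pd.Series:
        return self.frame["taxon"]

    def values(self) -> np.ndarray:
        return self.descriptors.to_numpy(float)

    @staticmethod
    def units(descriptor: str) -> str:
        return UNITS[descriptor]

    def concat(self, other: "FeatureTable") -> "FeatureTable":
        return FeatureTable(pd.concat([self.frame, other.frame],
                                      ignore_index=True))


def write_feature_table(table: FeatureTable, path) -> None:
    """Write the table as CSV with the fixed canonical header order.

    Floats are written with 10 significant digits so that read∘write is
    the identity at that precision.
    """
    table.frame.to_csv(str(path), index=False, float_format="%.10g")


def read_feature_table(path) -> FeatureTable:
    """Read a feature-table CSV, validating the schema strictly."""
    frame = pd.read_csv(str(path))
    unknown = [c for c in frame.columns if c not in TABLE_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column(s) in {path}: {unknown}")
    if not len(frame):
        # header-only CSV loses dtypes; rebuild an empty table
        missing = [c for c in TABLE_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing column(s) in {path}: {missing}")
        return FeatureTable.empty()
    return FeatureTable(frame)


def write_manifest(records: Sequence[dict], path) -> None:
    """Write the per-grain ground-truth manifest CSV."""
    cols = ["field_id", "grain_id", "taxon", "modality",
            "true_major_um", "true_minor_um", "centroid_row", "centroid_col"]
    pd.DataFrame.from_records(list(records))[cols].to_csv(str(path), index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(str(path))
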