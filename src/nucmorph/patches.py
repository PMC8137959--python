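"""ROI annotations and patch extraction from stained TMA images.

Pathologists mark rectangular regions of interest (ROIs) on each tissue
microarray core; fixed-size non-overlapping patches are tiled from
inside each ROI, starting at its top-left corner, and patches that are
mostly white (little tissue) are discarded.

Rectangles are half-open ``[x0, x1) x [y0, y1)`` in 0-based pixel
coordinates, which makes the tiling arithmetic exact: an ROI of width w
holds exactly ``floor(w / stride)`` patch columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

STAINS = ("HE", "CD10", "BCL6", "MUM1", "BCL2", "MYC")

DEFAULT_PATCH_SIZE = 224
DEFAULT_WHITE_LEVEL = 220
DEFAULT_MAX_WHITE_FRACTION = 0.5


class AnnotationError(ValueError):
    """Malformed ROI annotation row; carries the offending row index."""

    def __init__(self, message: str, row: Optional[int] = None):
        self.row = row
        super().__init__(f"row {row}: {message}" if row is not None else message)


@dataclass(frozen=True)
class ROIAnnotation:
    """One pathologist-annotated rectangle, 40x-magnification pixels.

    (x0, y0) is the upper-left corner, (x1, y1) the lower-right.
    """

    patient_id: str
    tma_id: str
    stain: str
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if self.stain not in STAINS:
            raise AnnotationError(f"unknown stain {self.stain!r} (expected one of {STAINS})")
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise AnnotationError(
                f"inverted/empty rectangle ({self.x0},{self.y0})-({self.x1},{self.y1})"
            )

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0


@dataclass(frozen=True)
class Patch:
    pixels: np.ndarray  # H x W x 3 uint8
    patch_id: str
    origin: tuple[int, int]  # (x, y) of the top-left corner in slide coords
    patient_id: str
    stain: str


#: default column names of the annotation table; a mapping may override
#: them since the released file's exact headers are not fixed
ANNOTATION_COLUMNS = {
    "patient_id": "patient_id",
    "tma_id": "tma_id",
    "stain": "stain",
    "x0": "x0",
    "y0": "y0",
    "x1": "x1",
    "y1": "y1",
}


def load_annotations(
    table: Union[str, Path, pd.DataFrame],
    column_map: Optional[dict] = None,
) -> list[ROIAnnotation]:
    """Read an annotations.csv-style table into ROIAnnotation records.

    Parameters
    ----------
    table:
        CSV path or an already-loaded DataFrame with patient id, TMA id,
        stain and the four corner-coordinate columns.
    column_map:
        optional mapping from canonical names (patient_id, tma_id, stain,
        x0, y0, x1, y1) to the table's actual column headers.

    Raises :class:`AnnotationError` naming the row index for inverted
    rectangles or unknown stains.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table)
    else:
        df = table
    cols = dict(ANNOTATION_COLUMNS)
    if column_map:
        cols.update(column_map)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise AnnotationError(f"annotation table missing columns: {missing}")

    rois = []
    for i, rec in enumerate(df.to_dict("records")):
        try:
            rois.append(
                ROIAnnotation(
                    patient_id=str(rec[cols["patient_id"]]),
                    tma_id=str(rec[cols["tma_id"]]),
                    stain=str(rec[cols["stain"]]),
                    x0=int(rec[cols["x0"]]),
                    y0=int(rec[cols["y0"]]),
                    x1=int(rec[cols["x1"]]),
                    y1=int(rec[cols["y1"]]),
                )
            )
        except AnnotationError as e:
            raise AnnotationError(str(e), row=i) from e
        except (KeyError, TypeError, ValueError) as e:
            raise AnnotationError(f"malformed values: {e}", row=i) from e
    return rois


def extract_patches(
    image: np.ndarray,
    roi: ROIAnnotation,
    size: int = DEFAULT_PATCH_SIZE,
    stride: Optional[int] = None,
) -> list[Patch]:
    """Tile fixed-size patches from inside an ROI, row-major.

    Patch origins are ``(x0 + i*stride, y0 + j*stride)`` for every (i, j)
    where the full ``size x size`` window fits inside the ROI; partial
    windows at the right/bottom edges are dropped, not padded.  With
    ``stride >= size`` (the default stride equals size) patches are
    pairwise non-overlapping.  An ROI smaller than one patch yields an
    empty list.

    Patch ids are deterministic: ``{patient}_{stain}_{row}_{col}``.
    """
    if stride is None:
        stride = size
    if size <= 0 or stride <= 0:
        raise ValueError("size and stride must be positive")
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {img.shape}")
    if roi.x0 < 0 or roi.y0 < 0 or roi.x1 > img.shape[1] or roi.y1 > img.shape[0]:
        raise ValueError(
            f"ROI ({roi.x0},{roi.y0})-({roi.x1},{roi.y1}) outside image {img.shape[1]}x{img.shape[0]}"
        )

    patches = []
    n_cols = max(0, (roi.width - size) // stride + 1) if roi.width >= size else 0
    n_rows = max(0, (roi.height - size) // stride + 1) if roi.height >= size else 0
    for j in range(n_rows):
        for i in range(n_cols):
            x = roi.x0 + i * stride
            y = roi.y0 + j * stride
            patches.append(
                Patch(
                    pixels=img[y : y + size, x : x + size],
                    patch_id=f"{roi.patient_id}_{roi.stain}_{j}_{i}",
                    origin=(x, y),
                    patient_id=roi.patient_id,
                    stain=roi.stain,
                )
            )
    return patches


def is_informative(
    patch: Union[Patch, np.ndarray],
    white_level: int = DEFAULT_WHITE_LEVEL,
    max_white_fraction: float = DEFAULT_MAX_WHITE_FRACTION,
) -> bool:
    """Whether a patch contains enough tissue to keep.

    A pixel is "white" when all three channels exceed ``white_level``;
    the patch is discarded iff the white fraction strictly exceeds
    ``max_white_fraction`` (a patch at exactly the threshold is kept).
    """
    px = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    white = np.all(px > white_level, axis=-1)
    return not (white.mean() > max_white_fraction)


def informative_patches(
    image: np.ndarray,
    roi: ROIAnnotation,
    size: int = DEFAULT_PATCH_SIZE,
    stride: Optional[int] = None,
    white_level: int = DEFAULT_WHITE_LEVEL,
    max_white_fraction: float = DEFAULT_MAX_WHITE_FRACTION,
) -> list[Patch]:
    """Extract patches and drop the mostly-white ones."""
    return [
        p
        for p in extract_patches(image, roi, size=size, stride=stride)
        if is_informative(p, white_level, max_white_fraction)
    ]


def save_patches(patches: list[Patch], out_dir: Union[str, Path]) -> list[Path]:
    """Write patches as PNG under ``{out_dir}/{stain}/{patient_id}/{patch_id}.png``."""
    from PIL import Image

    out = Path(out_dir)
    paths = []
    for p in patches:
        d = out / p.stain / p.patient_id
        d.mkdir(parents=True, exist_ok=True)
        path = d / f"{p.patch_id}.png"
        Image.fromarray(np.ascontiguousarray(p.pixels)).save(path)
        paths.append(path)
    return paths
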