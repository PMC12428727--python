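"""Cell detection and axis measurement in shear-flow microscopy fields.

Computational stand-in for the flow-chamber image analyzer: slide-attached
cells appear as bright elliptical blobs on a dark background; each field
(~0.1 mm^2) is thresholded, connected components are labeled, and every
component is measured by a moment-based ellipse fit to yield the cell's
major/minor axes and elongation ratio ER = A/B.

Conventions (fixed so the moment estimator has an exact analytic oracle):
x grows rightwards (columns), y grows downwards (rows), pixel centers sit
at integer coordinates, 0-based.  Orientation is the angle of the major
axis from the +x axis in this frame, in (-pi/2, pi/2].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .core import (
    ERSample,
    DeformabilityProfile,
    ThresholdScheme,
    aggregate_fields,
    compute_profile,
)
from .errors import (
    DegenerateShapeError,
    DegenerateThresholdError,
    EmptyInputError,
    InvariantViolationError,
)

__all__ = [
    "FieldImage",
    "CellMeasurement",
    "QCParams",
    "fit_axes",
    "segment_field",
    "analyze_specimen",
    "measurements_to_table",
    "load_field_image",
]


@dataclass
class FieldImage:
    """One microscopy field: an intensity grid plus physical pixel size."""

    pixels: np.ndarray
    pixel_size: float  # um per pixel
    field_id: str = "field"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InvariantViolationError("field image must be a non-empty 2-D grid")
        if not self.pixel_size > 0:
            raise InvariantViolationError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def area_mm2(self) -> float:
        h, w = self.pixels.shape
        return h * w * (self.pixel_size * 1e-3) ** 2


@dataclass
class CellMeasurement:
    """One detected cell with its fitted ellipse and QC verdict."""

    cell_id: int
    centroid_x: float
    centroid_y: float
    major_um: float
    minor_um: float
    er: float
    area_um2: float
    orientation: float
    qc_pass: bool
    qc_reason: str = ""


@dataclass(frozen=True)
class QCParams:
    """Detection and quality-control settings.

    Area bounds bracket normal RBC projected areas; ``max_er`` rejects
    absurd shapes (debris, merged cells).  Cells are bright on dark by
    convention; set ``invert`` for dark-on-bright images.
    """

    min_area_um2: float = 20.0
    max_area_um2: float = 200.0
    exclude_border: bool = True
    max_er: float = 6.0
    intensity_threshold_method: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: float | None = None
    invert: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.min_area_um2 < self.max_area_um2):
            raise InvariantViolationError(
                f"need 0 < min_area ({self.min_area_um2}) < max_area ({self.max_area_um2})"
            )
        if not self.max_er > 1:
            raise InvariantViolationError(f"max_er must be > 1, got {self.max_er}")
        if self.intensity_threshold_method == "fixed" and self.fixed_threshold is None:
            raise InvariantViolationError("fixed threshold method needs fixed_threshold")


def fit_axes(
    component_mask: np.ndarray, pixel_size: float
) -> tuple[float, float, float]:
    """Moment-based ellipse fit of a binary component.

    Axis lengths come from the eigenvalues of the second-order central
    moments of the pixel coordinates, scaled so an exactly filled ellipse
    recovers its true full axis lengths (length = 4*sqrt(eigenvalue)).

    Returns ``(major_um, minor_um, orientation)`` with major >= minor and
    orientation the major-axis angle from +x in (-pi/2, pi/2].

    Raises
    ------
    DegenerateShapeError
        for an empty, single-pixel or collinear mask.
    """
    ys, xs = np.nonzero(np.asarray(component_mask))
    n = xs.size
    if n == 0:
        raise DegenerateShapeError("empty mask")
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu_xx = float(x @ x) / n
    mu_yy = float(y @ y) / n
    mu_xy = float(x @ y) / n
    # eigenvalues of [[mu_xx, mu_xy], [mu_xy, mu_yy]]
    tr = mu_xx + mu_yy
    disc = np.sqrt(max((mu_xx - mu_yy) ** 2 + 4 * mu_xy**2, 0.0))
    lam_major = (tr + disc) / 2
    lam_minor = (tr - disc) / 2
    if lam_minor <= 1e-12:
        raise DegenerateShapeError(
            f"mask of {n} px is single-pixel or collinear; cannot fit an ellipse"
        )
    major_um = 4.0 * np.sqrt(lam_major) * pixel_size
    minor_um = 4.0 * np.sqrt(lam_minor) * pixel_size
    orientation = 0.5 * np.arctan2(2 * mu_xy, mu_xx - mu_yy)
    # fold into (-pi/2, pi/2]
    if orientation <= -np.pi / 2:
        orientation += np.pi
    elif orientation > np.pi / 2:
        orientation -= np.pi
    return float(major_um), float(minor_um), float(orientation)


def _foreground_mask(image: FieldImage, qc: QCParams) -> np.ndarray:
    px = np.asarray(image.pixels, dtype=float)
    if qc.invert:
        px = px.max() - px
    if qc.intensity_threshold_method == "otsu":
        if np.ptp(px) == 0:
            return np.zeros_like(px, dtype=bool)  # blank field: no cells
        thr = threshold_otsu(px)
    else:
        thr = float(qc.fixed_threshold)  # validated non-None
    mask = px > thr
    if qc.intensity_threshold_method == "fixed" and mask.all():
        raise DegenerateThresholdError(
            f"fixed threshold {thr} classifies the whole field as foreground"
        )
    return mask


def segment_field(image: FieldImage, qc: QCParams | None = None) -> list[CellMeasurement]:
    """Detect and measure all cells in one field.

    Foreground via the configured threshold, connected components labeled
    (8-connectivity), each component measured by :func:`fit_axes`.
    Components touching the border (when ``exclude_border``), outside the
    area bounds, degenerate, or with ER above ``max_er`` are returned with
    ``qc_pass=False`` and a reason rather than dropped.  A blank field
    returns an empty list.
    """
    if qc is None:
        qc = QCParams()
    mask = _foreground_mask(image, qc)
    if not mask.any():
        return []
    labels = sk_label(mask, connectivity=2)
    h, w = labels.shape
    out: list[CellMeasurement] = []
    for region in regionprops(labels):
        miny, minx, maxy, maxx = region.bbox
        touches_border = miny == 0 or minx == 0 or maxy == h or maxx == w
        area_um2 = region.area * image.pixel_size**2
        cy, cx = region.centroid
        qc_pass, reason = True, ""
        major = minor = er = orientation = np.nan
        if qc.exclude_border and touches_border:
            qc_pass, reason = False, "border"
        elif area_um2 < qc.min_area_um2:
            qc_pass, reason = False, "area_small"
        elif area_um2 > qc.max_area_um2:
            qc_pass, reason = False, "area_large"
        if qc_pass or reason.startswith("area"):
            try:
                major, minor, orientation = fit_axes(
                    region.image, image.pixel_size
                )
                er = major / minor
            except DegenerateShapeError:
                if qc_pass:
                    qc_pass, reason = False, "degenerate"
        if qc_pass and er > qc.max_er:
            qc_pass, reason = False, "elongation"
        out.append(
            CellMeasurement(
                cell_id=int(region.label),
                centroid_x=float(cx),
                centroid_y=float(cy),
                major_um=float(major),
                minor_um=float(minor),
                er=float(er),
                area_um2=float(area_um2),
                orientation=float(orientation),
                qc_pass=qc_pass,
                qc_reason=reason,
            )
        )
    return out


def measurements_to_table(
    cells: Sequence[CellMeasurement], sample_id: str, field_id: str
) -> pd.DataFrame:
    """Cell measurements as a canonical per-cell CSV table."""
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "field_id": field_id,
            "cell_id": [c.cell_id for c in cells],
            "major_um": [c.major_um for c in cells],
            "minor_um": [c.minor_um for c in cells],
            "er": [c.er for c in cells],
            "qc_pass": [c.qc_pass for c in cells],
            "qc_reason": [c.qc_reason for c in cells],
            "centroid_x": [c.centroid_x for c in cells],
            "centroid_y": [c.centroid_y for c in cells],
            "area_um2": [c.area_um2 for c in cells],
            "orientation": [c.orientation for c in cells],
        }
    )


def analyze_specimen(
    images: Sequence[FieldImage],
    qc: QCParams | None = None,
    scheme: ThresholdScheme | None = None,
    sample_id: str = "specimen",
) -> tuple[list[pd.DataFrame], DeformabilityProfile]:
    """Segment every field of a specimen and profile the pooled population.

    Returns the per-field measurement tables (QC failures included, flagged)
    and the deformability profile of all QC-passing cells.
    """
    if len(images) == 0:
        raise EmptyInputError("no field images given")
    tables = [
        measurements_to_table(segment_field(img, qc), sample_id, img.field_id)
        for img in images
    ]
    sample = aggregate_fields(tables, sample_id=sample_id)
    profile = compute_profile(sample, scheme)
    return tables, profile


def load_field_image(path, pixel_size: float, field_id: str | None = None) -> FieldImage:
    """Read a grayscale TIFF/PNG field image.

    ``pixel_size`` (um/px) comes from configuration, never from file tags.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        px = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 3:  # collapse RGB(A) to luminance
        px = px[..., :3].mean(axis=-1)
    return FieldImage(
        pixels=px, pixel_size=pixel_size, field_id=field_id or path.stem
    )
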