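"""Per-section scalar metrics: stain intensity, area fractions, nucleus shape
and orientation statistics, and diameter-normalized variants.

Nucleus shape descriptors come from the equivalent ellipse defined by the
second-order central image moments of each labelled component.  Orientation is
the angle of the major axis to the horizontal image plane, counter-clockwise
with y up, wrapped to [-90, 90); the aspect ratio is minor/major so that 1
means round and values below 1 mean elongated, spindle-shaped nuclei.

Cell alignment is summarised as the full width at half maximum (FWHM) of the
orientation histogram: small FWHM = strongly aligned cells, 180 deg = no
preferred direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .errors import ValidationError
from .io import TwoChannelSection
from .segmentation import (
    BinaryMask,
    LabeledNuclei,
    segment_dot_artifacts,
    segment_nuclei,
    segment_stain,
    segment_vessels,
)

DEFAULT_BIN_WIDTH_DEG = 10.0

#: metrics divided by tendon diameter when it is known
NORMALIZED_METRICS = ("mean_intensity", "nuclei_area_fraction", "vessel_area_fraction")


@dataclass
class NucleusShape:
    """Equivalent-ellipse descriptors of one nucleus."""

    centroid: tuple[float, float]  # (row, col)
    major_axis_px: float
    minor_axis_px: float
    aspect_ratio: float  # minor/major in (0, 1]
    orientation_deg: float  # [-90, 90), CCW from horizontal


@dataclass
class OrientationDistribution:
    bin_edges_deg: np.ndarray
    counts: np.ndarray
    fwhm_deg: float


@dataclass
class SectionMetrics:
    """Scalar outputs of one section; NaN marks undefined/not-applicable fields."""

    section_id: str = ""
    stain_kind: str = ""
    group: str | None = None
    week: int | str | None = None
    mean_intensity: float = math.nan
    stain_area_fraction: float = math.nan
    vessel_area_fraction: float = math.nan
    nuclei_area_fraction: float = math.nan
    mean_aspect_ratio: float = math.nan
    orientation_fwhm_deg: float = math.nan
    nucleus_count: int = 0
    tendon_diameter_mm: float | None = None
    normalized_mean_intensity: float = math.nan
    normalized_nuclei_area_fraction: float = math.nan
    normalized_vessel_area_fraction: float = math.nan

    def to_row(self) -> dict:
        row = {f.name: getattr(self, f.name) for f in fields(self)}
        return row


def mean_intensity(red: np.ndarray, stain_mask: BinaryMask | np.ndarray) -> float:
    """Mean red-channel value over stain-mask pixels, on the 0-255 scale.

    An empty mask means no stained area was detected; the result is NaN (with
    a warning), deliberately distinct from an intensity of 0.
    """
    pixels = stain_mask.pixels if isinstance(stain_mask, BinaryMask) else np.asarray(
        stain_mask, dtype=bool
    )
    red = np.asarray(red)
    if pixels.shape != red.shape:
        raise ValidationError("mask and image shapes differ")
    if not pixels.any():
        warnings.warn("empty stain mask: mean intensity is undefined", stacklevel=2)
        return math.nan
    return float(red[pixels].mean())


def area_fraction(mask: BinaryMask | np.ndarray) -> float:
    """True-pixel count divided by total pixel count."""
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    return float(pixels.mean()) if pixels.size else 0.0


def ellipse_from_coords(coords: np.ndarray) -> tuple[tuple[float, float], float, float, float]:
    """Equivalent ellipse of a pixel set from second-order central moments.

    Returns ``(centroid_rc, major_axis, minor_axis, orientation_deg)`` where
    axis lengths are full lengths (4 sqrt(eigenvalue), matching the usual
    image-moments ellipse) and orientation follows the package convention.
    A 1/12 px^2 term accounts for the finite pixel area, and the minor axis is
    floored at 1 px so collinear components stay well defined.
    """
    coords = np.asarray(coords, dtype=np.float64)
    rows, cols = coords[:, 0], coords[:, 1]
    x = cols
    y = -rows  # y up so CCW angles are positive on screen
    cx, cy = x.mean(), y.mean()
    dx, dy = x - cx, y - cy
    mxx = float((dx * dx).mean()) + 1.0 / 12.0
    myy = float((dy * dy).mean()) + 1.0 / 12.0
    mxy = float((dx * dy).mean())
    common = math.hypot((mxx - myy) / 2.0, mxy)
    l1 = (mxx + myy) / 2.0 + common
    l2 = (mxx + myy) / 2.0 - common
    major = 4.0 * math.sqrt(max(l1, 0.0))
    minor = max(4.0 * math.sqrt(max(l2, 0.0)), 1.0)
    theta = math.degrees(0.5 * math.atan2(2.0 * mxy, mxx - myy))
    theta = wrap_angle_deg(theta)
    return (float(rows.mean()), float(cols.mean())), major, minor, theta


def wrap_angle_deg(theta: float) -> float:
    """Wrap an axial (180-degree periodic) angle to [-90, 90)."""
    wrapped = (theta + 90.0) % 180.0 - 90.0
    return float(wrapped)


def fit_nucleus_shapes(nuclei: LabeledNuclei) -> list[NucleusShape]:
    """One NucleusShape per label, from the moment-equivalent ellipse."""
    if nuclei.count < 1:
        raise ValidationError("no labelled nuclei to fit")
    shapes: list[NucleusShape] = []
    label_map = nuclei.label_map
    order = np.argsort(label_map.ravel(), kind="stable")
    flat = label_map.ravel()[order]
    coords_all = np.column_stack(np.unravel_index(order, label_map.shape))
    boundaries = np.searchsorted(flat, np.arange(1, nuclei.count + 2))
    for k in range(nuclei.count):
        coords = coords_all[boundaries[k] : boundaries[k + 1]]
        centroid, major, minor, theta = ellipse_from_coords(coords)
        minor = min(minor, major)
        shapes.append(
            NucleusShape(
                centroid=centroid,
                major_axis_px=major,
                minor_axis_px=minor,
                aspect_ratio=minor / major if major > 0 else 1.0,
                orientation_deg=theta,
            )
        )
    return shapes


def circular_mean_axial_deg(angles_deg: np.ndarray) -> float:
    """Mean direction of axial angles (period 180 deg), in [-90, 90)."""
    doubled = np.radians(np.asarray(angles_deg, dtype=float) * 2.0)
    mean = math.atan2(np.sin(doubled).mean(), np.cos(doubled).mean())
    return wrap_angle_deg(math.degrees(mean) / 2.0)


def orientation_spread(
    shapes,
    bin_width_deg: float = DEFAULT_BIN_WIDTH_DEG,
) -> OrientationDistribution:
    """Histogram of nucleus orientations and its full width at half maximum.

    Angles are recentred by their circular mean on the 180-degree circle
    before binning, so alignments near +-90 deg are not artificially split
    across the histogram ends.  The FWHM is taken between linear
    interpolations of the half-maximum crossings on either side of the modal
    bin; a flat histogram (no preferred direction) yields 180.
    """
    if bin_width_deg <= 0 or abs(180.0 / bin_width_deg - round(180.0 / bin_width_deg)) > 1e-9:
        raise ValidationError("bin width must evenly divide 180 degrees")
    angles = np.asarray(
        [s.orientation_deg if isinstance(s, NucleusShape) else float(s) for s in shapes],
        dtype=float,
    )
    if angles.size < 2:
        raise ValidationError("orientation spread needs at least 2 nuclei")
    center = circular_mean_axial_deg(angles)
    recentred = np.array([wrap_angle_deg(a - center) for a in angles])
    edges = np.arange(-90.0, 90.0 + bin_width_deg / 2.0, bin_width_deg)
    counts, _ = np.histogram(recentred, bins=edges)
    fwhm = _fwhm_from_histogram(counts, edges)
    return OrientationDistribution(edges, counts, fwhm)


def _fwhm_from_histogram(counts: np.ndarray, edges: np.ndarray) -> float:
    bw = edges[1] - edges[0]
    centers = edges[:-1] + bw / 2.0
    peak = int(np.argmax(counts))
    half = counts[peak] / 2.0
    if counts[peak] == 0:
        return 180.0

    left = edges[0]
    for i in range(peak - 1, -1, -1):
        if counts[i] < half:
            left = centers[i] + (half - counts[i]) / (counts[i + 1] - counts[i]) * bw
            break
    right = edges[-1]
    for i in range(peak + 1, len(counts)):
        if counts[i] < half:
            right = centers[i] - (half - counts[i]) / (counts[i - 1] - counts[i]) * bw
            break
    return float(min(right - left, 180.0))


def normalize_by_diameter(metrics: SectionMetrics, diameter_mm: float) -> SectionMetrics:
    """Divide size-sensitive metrics by the tendon (callus) diameter in mm.

    The healing callus is thicker under more loading; dividing intensity and
    area-fraction metrics by the measured diameter gives a first-order
    correction for callus size when comparing loading groups.
    """
    if not diameter_mm > 0:
        raise ValidationError("diameter must be positive")
    updates = {"tendon_diameter_mm": float(diameter_mm)}
    for name in NORMALIZED_METRICS:
        updates[f"normalized_{name}"] = getattr(metrics, name) / diameter_mm
    return replace(metrics, **updates)


def quantify_section(section: TwoChannelSection, config=None) -> SectionMetrics:
    """Run the stain-specific sub-pipeline on one section.

    Collagen sections: vessel mask -> stain mask -> mean intensity + vessel
    area fraction; collagen-1 sections additionally yield the nucleus metrics
    (density, shape, orientation spread).  Elastin sections: dot-artifact
    mask -> stain mask -> mean intensity; vessels are not visible in elastin
    images, so the vessel fraction stays undefined.  Diameter-normalized
    variants are filled in when the diameter is known.
    """
    from .config import QuantConfig

    cfg = config or QuantConfig()
    out = SectionMetrics(
        section_id=section.section_id,
        stain_kind=section.stain_kind,
        group=section.group,
        week=section.week,
        tendon_diameter_mm=section.tendon_diameter_mm,
    )
    try:
        if section.stain_kind in ("collagen1", "collagen3"):
            vessels = segment_vessels(
                section, cfg.vessel_threshold, cfg.vessel_dilation_px
            )
            stain = segment_stain(section, vessels, cfg.collagen_threshold)
            out.vessel_area_fraction = area_fraction(vessels)
            if section.stain_kind == "collagen1":
                nuclei = segment_nuclei(
                    section, vessels, cfg.dapi_threshold, cfg.min_nucleus_area_px
                )
                out.nucleus_count = nuclei.count
                out.nuclei_area_fraction = area_fraction(nuclei.label_map > 0)
                if nuclei.count >= 1:
                    shapes = fit_nucleus_shapes(nuclei)
                    out.mean_aspect_ratio = float(
                        np.mean([s.aspect_ratio for s in shapes])
                    )
                    if nuclei.count >= 2:
                        out.orientation_fwhm_deg = orientation_spread(
                            shapes, cfg.bin_width_deg
                        ).fwhm_deg
        else:
            dots = segment_dot_artifacts(
                section, cfg.dot_threshold, cfg.roundness_cutoff, cfg.dot_dilation_px
            )
            stain = segment_stain(section, dots, cfg.elastin_threshold)
        out.stain_area_fraction = area_fraction(stain)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.mean_intensity = mean_intensity(section.red, stain)
    except Exception as exc:
        exc.args = (f"section {section.section_id!r}: {exc}",) + exc.args[1:]
        raise
    if section.tendon_diameter_mm is not None:
        out = normalize_by_diameter(out, section.tendon_diameter_mm)
    return out
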