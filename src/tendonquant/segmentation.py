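"""Threshold-based segmentation of stained tendon sections.

Four masks drive every downstream metric:

* **vessel** — high-intensity regions of collagen-stained red channels
  (fraction-of-range threshold 0.9) dilated by a radius-8 disk so the bright
  rim of each vessel is fully captured; vessels are excluded from stain
  quantification and counted as vascular area.
* **stain** — stain-positive pixels above a low threshold (0.12 for the
  collagens, 0.2 for elastin) minus the relevant exclusion mask.
* **dot_artifact** — round saturated dye dots in elastin images (threshold
  0.7), classified by moment-based axis ratio and dilated by a radius-5 disk.
* **nuclei** — connected components of the binarized DAPI channel outside the
  vessel mask, labelled individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .errors import ValidationError
from .io import TwoChannelSection, normalize_threshold

VESSEL_THRESHOLD = 0.9
VESSEL_DILATION_PX = 8
COLLAGEN_STAIN_THRESHOLD = 0.12
ELASTIN_STAIN_THRESHOLD = 0.2
DOT_THRESHOLD = 0.7
DOT_DILATION_PX = 5
DOT_ROUNDNESS_CUTOFF = 0.5
MIN_NUCLEUS_AREA_PX = 5


@dataclass
class BinaryMask:
    """A pixel-membership map plus the parameters that produced it."""

    pixels: np.ndarray
    kind: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValidationError("mask must be 2-D")

    @property
    def area_fraction(self) -> float:
        return float(self.pixels.mean()) if self.pixels.size else 0.0

    @classmethod
    def empty(cls, shape: tuple[int, int], kind: str = "vessel") -> "BinaryMask":
        return cls(np.zeros(shape, dtype=bool), kind, {"empty": True})


@dataclass
class LabeledNuclei:
    """Connected-component label map of nuclei; 0 = background, 1..count = nuclei."""

    label_map: np.ndarray
    count: int

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if self.label_map.ndim != 2:
            raise ValidationError("label map must be 2-D")


def _check_shapes(section: TwoChannelSection, mask: BinaryMask | None) -> None:
    if mask is not None and mask.pixels.shape != section.shape:
        raise ValidationError(
            f"mask shape {mask.pixels.shape} does not match section {section.shape}"
        )


def dilate(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Binary dilation with a Euclidean disk of the given radius (0 = no-op)."""
    if radius_px < 0:
        raise ValidationError("dilation radius must be non-negative")
    if radius_px == 0:
        return np.asarray(mask, dtype=bool)
    return morphology.dilation(
        np.asarray(mask, dtype=bool), morphology.disk(radius_px)
    ).astype(bool)


def segment_vessels(
    section: TwoChannelSection,
    threshold: float = VESSEL_THRESHOLD,
    dilation_px: int = VESSEL_DILATION_PX,
) -> BinaryMask:
    """Vessel mask: red-channel pixels at >= 0.9 of range, dilated by 8 px.

    Only meaningful for collagen-stained sections; vessels are not visible in
    elastin images, so calling this on one is an error.
    """
    if section.stain_kind not in ("collagen1", "collagen3"):
        raise ValidationError(
            f"vessel segmentation applies to collagen sections, not {section.stain_kind}"
        )
    cutoff = normalize_threshold(threshold)
    raw = section.red >= cutoff
    return BinaryMask(
        dilate(raw, dilation_px),
        "vessel",
        {"threshold": threshold, "cutoff": cutoff, "dilation_px": dilation_px},
    )


def segment_stain(
    section: TwoChannelSection,
    exclusion_mask: BinaryMask | None = None,
    threshold: float | None = None,
) -> BinaryMask:
    """Stain-positive mask minus the exclusion mask.

    The exclusion mask is the vessel mask for collagen sections and the
    dot-artifact mask for elastin.  The default threshold depends on the
    stain: 0.12 for collagen 1/3, 0.2 for elastin.
    """
    if threshold is None:
        threshold = (
            ELASTIN_STAIN_THRESHOLD
            if section.stain_kind == "elastin"
            else COLLAGEN_STAIN_THRESHOLD
        )
    _check_shapes(section, exclusion_mask)
    cutoff = normalize_threshold(threshold)
    mask = section.red >= cutoff
    if exclusion_mask is not None:
        mask &= ~exclusion_mask.pixels
    return BinaryMask(
        mask,
        "stain",
        {
            "threshold": threshold,
            "cutoff": cutoff,
            "excluded": exclusion_mask.kind if exclusion_mask is not None else None,
        },
    )


def _component_axis_ratio(coords: np.ndarray) -> float:
    """Minor/major axis ratio of a pixel set from second-order central moments
    (1 = round). Single pixels and other degenerate sets count as round."""
    from .quantification import ellipse_from_coords

    _, major, minor, _ = ellipse_from_coords(coords)
    if major <= 0:
        return 1.0
    return minor / major


def segment_dot_artifacts(
    section: TwoChannelSection,
    threshold: float = DOT_THRESHOLD,
    roundness_cutoff: float = DOT_ROUNDNESS_CUTOFF,
    dilation_px: int = DOT_DILATION_PX,
) -> BinaryMask:
    """Mask of round saturated dye dots in elastin images, dilated by 5 px.

    Bright connected components (>= 0.7 of range) whose minor/major axis
    ratio is at least ``roundness_cutoff`` are treated as unwashed-dye dots
    and excluded from elastin quantification; elongated bright fibers are
    kept in the analysis.
    """
    if section.stain_kind != "elastin":
        raise ValidationError("dot-artifact masking applies only to elastin sections")
    cutoff = normalize_threshold(threshold)
    labels = measure.label(section.red >= cutoff, connectivity=2)
    keep = np.zeros(section.shape, dtype=bool)
    for region in measure.regionprops(labels):
        if _component_axis_ratio(region.coords) >= roundness_cutoff:
            keep[tuple(region.coords.T)] = True
    return BinaryMask(
        dilate(keep, dilation_px),
        "dot_artifact",
        {
            "threshold": threshold,
            "cutoff": cutoff,
            "roundness_cutoff": roundness_cutoff,
            "dilation_px": dilation_px,
        },
    )


def segment_nuclei(
    section: TwoChannelSection,
    vessel_mask: BinaryMask | None = None,
    binarize_threshold: float | None = None,
    min_area_px: int = MIN_NUCLEUS_AREA_PX,
    otsu_floor_fraction: float = 0.15,
) -> LabeledNuclei:
    """Label nuclei in the DAPI channel after masking out blood vessels.

    With ``binarize_threshold=None`` the cutoff is Otsu's method computed on
    the non-vessel blue pixels; a fraction of the 8-bit range can be supplied
    instead.  The Otsu cutoff is floored at ``otsu_floor_fraction`` of the
    range so that a nucleus-free field of dim background noise is not split
    into spurious "nuclei" (DAPI-positive nuclei are bright).  Components
    smaller than ``min_area_px`` are discarded as noise and surviving labels
    are renumbered 1..count.
    """
    _check_shapes(section, vessel_mask)
    excluded = vessel_mask.pixels if vessel_mask is not None else np.zeros(
        section.shape, dtype=bool
    )
    blue = section.blue
    candidates = blue[~excluded]
    if binarize_threshold is not None:
        binary = blue >= normalize_threshold(binarize_threshold)
    else:
        if candidates.size == 0 or candidates.min() == candidates.max():
            return LabeledNuclei(np.zeros(section.shape, dtype=np.int32), 0)
        cutoff = max(threshold_otsu(candidates), normalize_threshold(otsu_floor_fraction))
        binary = blue > cutoff
    binary &= ~excluded
    labels, n = measure.label(binary, connectivity=2, return_num=True)
    if n:
        # drop sub-minimum components, then renumber consecutively
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_area_px
        keep[0] = False
        binary = keep[labels]
    labels, count = measure.label(binary, connectivity=2, return_num=True)
    return LabeledNuclei(labels.astype(np.int32), int(count))
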