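"""Reading two-channel fluorescence sections and the cohort manifest.

A section is one imaged field of a stained tendon slice: the red channel
carries the ECM stain (collagen 1, collagen 3, or elastin), the blue channel
carries the DAPI nuclear counterstain.  Everything downstream operates on the
canonical 8-bit representation produced here; the green channel of RGB inputs
is discarded.

Angle/coordinate convention used throughout the package: arrays are row-major
with the origin at the top-left, x increases rightward along columns, and
angles are measured counter-clockwise from +x (the horizontal image plane) in
degrees, with y taken as pointing up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

STAIN_KINDS = ("collagen1", "collagen3", "elastin")
GROUPS = ("ML", "RL", "FL", "IT")
#: weeks used in the study design; intact reference tendons carry "intact"
WEEKS = (1, 2, 3, 12, 20)

MANIFEST_COLUMNS = (
    "section_id",
    "path_red_or_rgb",
    "path_blue",
    "stain",
    "group",
    "week",
    "diameter_mm",
)


@dataclass
class TwoChannelSection:
    """One imaged field: 8-bit red (stain) and blue (DAPI) planes plus metadata."""

    red: np.ndarray
    blue: np.ndarray
    stain_kind: str
    group: str | None = None
    week: int | str | None = None
    tendon_diameter_mm: float | None = None
    section_id: str = ""

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red)
        self.blue = np.asarray(self.blue)
        if self.red.ndim != 2 or self.blue.ndim != 2:
            raise ValidationError("channel planes must be 2-D arrays")
        if self.red.shape != self.blue.shape:
            raise ValidationError(
                f"red {self.red.shape} and blue {self.blue.shape} shapes differ"
            )
        for name, plane in (("red", self.red), ("blue", self.blue)):
            if plane.size and (plane.min() < 0 or plane.max() > 255):
                raise ValidationError(f"{name} plane has values outside [0, 255]")
        self.red = self.red.astype(np.uint8)
        self.blue = self.blue.astype(np.uint8)
        if self.stain_kind not in STAIN_KINDS:
            raise ValidationError(
                f"unknown stain_kind {self.stain_kind!r}; expected one of {STAIN_KINDS}"
            )
        if self.tendon_diameter_mm is not None and not self.tendon_diameter_mm > 0:
            raise ValidationError("tendon_diameter_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


def normalize_threshold(t: float) -> int:
    """Map a fractional threshold to the smallest 8-bit cutoff ``v >= t*255``.

    Pixels with intensity >= the returned value count as above threshold.  A
    tiny guard absorbs binary-float artifacts (0.2 * 255 is slightly above 51
    in double precision but the intended cutoff is 51).
    """
    if not 0.0 <= t <= 1.0:
        raise ValidationError(f"threshold fraction {t} outside [0, 1]")
    return int(math.ceil(round(t * 255, 9)))


def as_uint8(arr: np.ndarray) -> np.ndarray:
    """Convert an intensity plane to 0-255 by linearly rescaling its nominal
    dynamic range, rounding half up."""
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer):
        top = float(np.iinfo(arr.dtype).max)
        scaled = arr.astype(np.float64) * (255.0 / top)
    elif np.issubdtype(arr.dtype, np.floating):
        # floats are assumed on [0, 1]
        scaled = np.clip(arr.astype(np.float64), 0.0, 1.0) * 255.0
    else:
        raise ValidationError(f"unsupported image dtype {arr.dtype}")
    return np.floor(scaled + 0.5).clip(0, 255).astype(np.uint8)


def _read_plane(path: str | Path) -> np.ndarray:
    try:
        return iio.imread(Path(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise OSError(f"could not read image {path}: {exc}") from exc


def load_section(
    path: str | Path,
    metadata: Mapping[str, object],
    path_blue: str | Path | None = None,
) -> TwoChannelSection:
    """Load one section from an RGB image (or a red + blue single-channel pair).

    ``metadata`` must supply ``stain`` (or ``stain_kind``); ``group``, ``week``,
    ``diameter_mm`` and ``section_id`` are attached when present.
    """
    stain = metadata.get("stain", metadata.get("stain_kind"))
    if stain is None:
        raise ValidationError(f"metadata for {path} is missing 'stain'")

    img = _read_plane(path)
    if img.ndim == 3 and img.shape[-1] in (3, 4):
        red = as_uint8(img[..., 0])
        blue = as_uint8(img[..., 2])
    elif img.ndim == 2:
        if path_blue is None:
            raise ConfigurationError(
                f"{path} is single-channel; a blue-channel path must be supplied"
            )
        red = as_uint8(img)
        blue = as_uint8(_read_plane(path_blue))
    else:
        raise ValidationError(f"unsupported image layout {img.shape} in {path}")

    diameter = metadata.get("diameter_mm", metadata.get("tendon_diameter_mm"))
    if diameter is not None and not (isinstance(diameter, str) and diameter == ""):
        diameter = float(diameter)
        if math.isnan(diameter):
            diameter = None
    else:
        diameter = None

    week = metadata.get("week")
    if week is not None and week != "intact":
        week = int(week)

    return TwoChannelSection(
        red=red,
        blue=blue,
        stain_kind=str(stain),
        group=metadata.get("group"),
        week=week,
        tendon_diameter_mm=diameter,
        section_id=str(metadata.get("section_id", Path(path).stem)),
    )


def save_section(section: TwoChannelSection, path: str | Path) -> Path:
    """Write a section as an RGB raster (green plane zero). Lossless for PNG/TIFF."""
    path = Path(path)
    rgb = np.zeros(section.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = section.red
    rgb[..., 2] = section.blue
    iio.imwrite(path, rgb)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the cohort manifest CSV and validate its required columns."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"manifest {path} does not exist")
    df = pd.read_csv(path, dtype={"section_id": str, "week": str})
    required = {"section_id", "path_red_or_rgb", "stain", "group", "week"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"manifest {path} lacks columns {sorted(missing)}")
    return df


def load_manifest_row(row, root: str | Path = ".") -> TwoChannelSection:
    """Load the section described by one manifest row."""
    root = Path(root)
    meta = {
        "section_id": row["section_id"],
        "stain": row["stain"],
        "group": row["group"],
        "week": row["week"] if row["week"] == "intact" else int(row["week"]),
        "diameter_mm": row.get("diameter_mm"),
    }
    blue = row.get("path_blue")
    blue_path = (
        root / str(blue) if isinstance(blue, str) and blue not in ("", "nan") else None
    )
    return load_section(root / str(row["path_red_or_rgb"]), meta, blue_path)
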