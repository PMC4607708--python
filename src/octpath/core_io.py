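"""Domain types and I/O for calibrated OCT B-scans.

A B-scan is a 2-D grayscale image whose columns are A-scans (axial depth
profiles).  Row 0 is the top of the image, on the vitreous side; depth and
therefore thickness grow with the row index.  Physical calibration arrives
in a small JSON/YAML sidecar next to the raster image rather than being
parsed out of vendor-proprietary scan containers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .errors import ConfigurationError, ValidationError

SIDECAR_KEYS = ("axial_scale_um_per_px", "scan_length_mm", "n_ascans")


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of one B-scan.

    Parameters
    ----------
    axial_scale:
        Axial sampling in micrometres per pixel (row).
    scan_length_mm:
        Nominal lateral extent of the scan in millimetres.
    n_ascans:
        Number of A-scan columns across the scan.

    The lateral sampling (``lateral_scale``, μm per column) is always
    derived from ``scan_length_mm`` and ``n_ascans`` so the two can never
    drift apart.
    """

    axial_scale: float
    scan_length_mm: float
    n_ascans: int

    def __post_init__(self):
        if not (self.axial_scale > 0):
            raise ValidationError(f"axial_scale must be > 0, got {self.axial_scale}")
        if not (self.scan_length_mm > 0):
            raise ValidationError(
                f"scan_length_mm must be > 0, got {self.scan_length_mm}"
            )
        if self.n_ascans < 2:
            raise ValidationError(f"n_ascans must be >= 2, got {self.n_ascans}")

    @property
    def lateral_scale(self) -> float:
        """Lateral sampling in μm per column."""
        return self.scan_length_mm * 1000.0 / self.n_ascans

    def to_dict(self) -> dict:
        return {
            "axial_scale_um_per_px": self.axial_scale,
            "scan_length_mm": self.scan_length_mm,
            "n_ascans": self.n_ascans,
        }


@dataclass
class BScan:
    """One calibrated B-scan: intensity image plus calibration.

    ``image`` is indexed ``[row, column]`` with row 0 at the vitreous side.
    Intensities must be finite and non-negative; the dtype is whatever the
    source provided (8/16-bit integer or float).
    """

    image: np.ndarray
    calibration: Calibration
    scan_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise ValidationError(f"image must be 2-D, got shape {self.image.shape}")
        if self.image.shape[1] != self.calibration.n_ascans:
            raise ValidationError(
                f"image has {self.image.shape[1]} columns but calibration "
                f"declares n_ascans={self.calibration.n_ascans}"
            )
        if not np.all(np.isfinite(self.image)):
            raise ValidationError("image contains non-finite values")
        if self.image.min() < 0:
            raise ValidationError("image contains negative intensities")

    @property
    def n_rows(self) -> int:
        return self.image.shape[0]

    @property
    def n_cols(self) -> int:
        return self.image.shape[1]


@dataclass(frozen=True)
class AnchorPoint:
    """A user-supplied point the boundary path must pass through exactly.

    Replaces the interactive click correction of erroneous automatic
    segmentations: anchors are data (files or CLI arguments), not clicks.
    Coordinates are 0-based ``(column, row)`` image indices.
    """

    column: int
    row: int

    def __post_init__(self):
        if self.column < 0 or self.row < 0:
            raise ValidationError(f"anchor indices must be >= 0, got {self}")


def _read_sidecar(path: Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    # YAML is a superset of JSON, so .yaml/.yml or unknown suffixes all work
    return yaml.safe_load(text)


def load_bscan(image_path, sidecar_path) -> BScan:
    """Read a raster image plus its calibration sidecar into a :class:`BScan`.

    The image may be single-channel or grayscale-stored-in-RGB (vendor
    exports); RGB inputs are collapsed by channel averaging.  The sidecar is
    a JSON or YAML document with keys ``axial_scale_um_per_px``,
    ``scan_length_mm``, ``n_ascans`` and optionally ``id``.

    Raises
    ------
    ConfigurationError
        If the sidecar is missing a required key.
    ValidationError
        If the image column count does not match ``n_ascans``.
    """
    meta = _read_sidecar(Path(sidecar_path))
    if not isinstance(meta, dict):
        raise ConfigurationError(f"sidecar {sidecar_path} is not a mapping")
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise ConfigurationError(
            f"sidecar {sidecar_path} is missing required key(s): {', '.join(missing)}"
        )
    cal = Calibration(
        axial_scale=float(meta["axial_scale_um_per_px"]),
        scan_length_mm=float(meta["scan_length_mm"]),
        n_ascans=int(meta["n_ascans"]),
    )
    img = iio.imread(image_path)
    if img.ndim == 3:  # RGB(A): average the color channels
        img = img[..., :3].mean(axis=2)
    return BScan(image=img, calibration=cal, scan_id=str(meta.get("id", "")))


def save_bscan(scan: BScan, image_path, sidecar_path) -> None:
    """Write a B-scan image and its calibration sidecar.

    Integer images go to PNG or TIFF losslessly; float images require a
    ``.tif``/``.tiff`` path (PNG cannot hold floats bit-exactly).
    """
    image_path = Path(image_path)
    suffix = image_path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(image_path, scan.image)
    elif np.issubdtype(scan.image.dtype, np.integer):
        iio.imwrite(image_path, scan.image)
    else:
        raise ValidationError(
            f"float images must be saved as TIFF, got {image_path.name}"
        )
    meta = scan.calibration.to_dict()
    meta["id"] = scan.scan_id
    sidecar_path = Path(sidecar_path)
    if str(sidecar_path).endswith((".yaml", ".yml")):
        sidecar_path.write_text(yaml.safe_dump(meta))
    else:
        sidecar_path.write_text(json.dumps(meta, indent=2))


def normalize_intensity(scan: BScan) -> BScan:
    """Linearly rescale intensities to [0, 1].

    Makes cost images comparable across 8-bit and 16-bit sources.  A
    constant image maps to all zeros with a warning.  Idempotent on input
    that is already normalized.
    """
    img = scan.image.astype(np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        warnings.warn(
            f"scan {scan.scan_id!r} has constant intensity; normalizing to zeros",
            stacklevel=2,
        )
        out = np.zeros_like(img)
    else:
        out = (img - lo) / (hi - lo)
    return BScan(image=out, calibration=scan.calibration, scan_id=scan.scan_id)
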