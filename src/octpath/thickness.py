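"""Thickness quantification from layer segmentations.

Two layer pairs are measured, both ending at the RPE outer border (the
posterior edge of the RPE–Bruch's membrane complex, chosen for its marked
transition in reflectance):

* ``RETINA`` — ILM to RPE outer, the full retinal thickness;
* ``RPEOS`` — IS/OS top to RPE outer, the outer-segment + RPE complex.

Summaries follow the line-scan measurement grid: the central point
thickness (CPT) at the foveal center (the minimum of the smoothed retinal
thickness profile), the central 1-mm line (mean of the −0.5, 0 and
+0.5 mm points), and all points out to ±3 mm at 0.5 mm spacing (13
points); points whose target column falls outside the scan are masked
missing rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import ValidationError
from .segmentation import LayerSegmentation

LAYER_PAIRS = ("RETINA", "RPEOS")

#: Measurement grid: −3.0 … +3.0 mm in 0.5 mm steps (13 points).
DEFAULT_OFFSETS_MM = tuple(np.round(np.arange(-3.0, 3.01, 0.5), 2))

#: The three central offsets whose mean is the 1-mm line.
CENTRAL_OFFSETS_MM = (-0.5, 0.0, 0.5)


@dataclass
class ThicknessProfile:
    """Per-column thickness in μm with signed lateral coordinates in mm.

    ``lateral_mm`` is 0 at the origin column (scan center unless
    recentred); negative values are nasal by convention when
    ``nasal_is_negative`` is set.
    """

    thickness_um: np.ndarray
    lateral_mm: np.ndarray
    layer_pair: str
    scan_id: str = ""
    nasal_is_negative: bool = True

    def __post_init__(self):
        self.thickness_um = np.asarray(self.thickness_um, dtype=np.float64)
        self.lateral_mm = np.asarray(self.lateral_mm, dtype=np.float64)
        if self.thickness_um.shape != self.lateral_mm.shape:
            raise ValidationError("thickness and lateral coordinate lengths differ")
        if self.layer_pair not in LAYER_PAIRS:
            raise ValidationError(f"unknown layer pair {self.layer_pair!r}")
        if np.any(self.thickness_um < 0):
            raise ValidationError("negative thickness: boundary ordering violated")

    def __len__(self) -> int:
        return len(self.thickness_um)

    @property
    def lateral_step_mm(self) -> float:
        return float(self.lateral_mm[1] - self.lateral_mm[0])


@dataclass
class ThicknessSummary:
    """Grid summary for one scan and one layer pair."""

    cpt_um: float
    line1mm_um: float
    allpoints_um: float
    points: pd.DataFrame  # columns: offset_mm, column, thickness_um, missing
    layer_pair: str = ""
    scan_id: str = ""

    @property
    def n_missing(self) -> int:
        return int(self.points["missing"].sum())


def thickness_profile(
    seg: LayerSegmentation, layer_pair: str, origin_column: int | None = None
) -> ThicknessProfile:
    """Per-column thickness of a layer pair, converted through calibration.

    Thickness is ``(outer_row − inner_row) × axial_scale`` in μm; the
    lateral coordinate is ``(column − origin) × lateral_scale / 1000`` in
    mm, with the origin defaulting to the scan center.
    """
    if seg.calibration is None:
        raise ValidationError("segmentation carries no calibration")
    if layer_pair == "RETINA":
        inner, outer = seg.ilm.rows, seg.rpe_outer.rows
    elif layer_pair == "RPEOS":
        inner, outer = seg.isos.rows, seg.rpe_outer.rows
    else:
        raise ValidationError(f"unknown layer pair {layer_pair!r}")
    diff = outer - inner
    if np.any(diff < 0):
        raise ValidationError("negative row difference: ordering violated")
    cal = seg.calibration
    n = len(inner)
    origin = (n - 1) / 2 if origin_column is None else origin_column
    lateral = (np.arange(n) - origin) * cal.lateral_scale / 1000.0
    return ThicknessProfile(
        thickness_um=diff * cal.axial_scale,
        lateral_mm=lateral,
        layer_pair=layer_pair,
        scan_id=seg.scan_id,
    )


def find_fovea(profile: ThicknessProfile, smooth_halfwidth: int = 5) -> int:
    """Foveal center: argmin of the smoothed retinal thickness profile.

    The foveal center point is where the line scan is thinnest; a moving
    average (half-width in columns) suppresses speckle-driven spurious
    minima.  Ties go to the column nearest the image center, then the
    smaller index.
    """
    if profile.layer_pair != "RETINA":
        raise ValidationError("fovea detection uses the RETINA profile")
    n = len(profile)
    if n <= 2 * smooth_halfwidth:
        raise ValidationError("profile too short for the smoothing window")
    if smooth_halfwidth > 0:
        sm = uniform_filter1d(
            profile.thickness_um, size=2 * smooth_halfwidth + 1, mode="nearest"
        )
    else:
        sm = profile.thickness_um
    min_val = sm.min()
    candidates = np.nonzero(sm == min_val)[0]
    center = (n - 1) / 2
    return int(min(candidates, key=lambda c: (abs(c - center), c)))


def sample_points(
    profile: ThicknessProfile,
    fovea_col: int,
    offsets_mm=DEFAULT_OFFSETS_MM,
    edge_tolerance_cols: float = 1.0,
) -> pd.DataFrame:
    """Read the thickness at fixed lateral offsets from the fovea.

    For each offset, the column nearest ``fovea_col + offset/lateral_step``
    is read; offsets whose target falls outside the image are masked
    missing (on a 6-mm scan a displaced fovea loses a ±3-mm point).  A
    centered fovea on an even column grid puts the ±3-mm targets half a
    column beyond the outermost column centers, so targets within
    ``edge_tolerance_cols`` of the edge column are snapped to it rather
    than masked.  Returns a tidy frame with columns
    ``offset_mm, column, thickness_um, missing``.
    """
    step = profile.lateral_step_mm
    rows = []
    n = len(profile)
    for off in offsets_mm:
        target = fovea_col + off / step
        col = int(np.clip(round(target), 0, n - 1))
        missing = abs(target - col) > edge_tolerance_cols
        if missing:
            rows.append((float(off), int(round(target)), np.nan, True))
        else:
            rows.append((float(off), col, float(profile.thickness_um[col]), False))
    return pd.DataFrame(rows, columns=["offset_mm", "column", "thickness_um", "missing"])


def summarize(
    samples: pd.DataFrame, layer_pair: str = "", scan_id: str = ""
) -> ThicknessSummary:
    """Collapse grid samples into CPT, 1-mm line and all-points means.

    The 1-mm line is the unweighted mean of exactly the −0.5, 0 and
    +0.5 mm points; the all-points mean excludes masked points.  Raises if
    any of the three central points is missing.
    """
    central = samples[samples["offset_mm"].isin(CENTRAL_OFFSETS_MM)]
    if len(central) != 3 or central["missing"].any():
        raise ValidationError("the three central points (−0.5, 0, +0.5 mm) are required")
    present = samples[~samples["missing"]]
    cpt = float(samples.loc[samples["offset_mm"] == 0.0, "thickness_um"].iloc[0])
    return ThicknessSummary(
        cpt_um=cpt,
        line1mm_um=float(central["thickness_um"].mean()),
        allpoints_um=float(present["thickness_um"].mean()),
        points=samples.copy(),
        layer_pair=layer_pair,
        scan_id=scan_id,
    )


def measure_scan(
    seg: LayerSegmentation,
    layer_pair: str,
    offsets_mm=DEFAULT_OFFSETS_MM,
    smooth_halfwidth: int = 5,
) -> ThicknessSummary:
    """Convenience pipeline: profile → fovea → grid samples → summary.

    The fovea is always located on the RETINA profile, then both layer
    pairs are sampled at the same columns.
    """
    retina = thickness_profile(seg, "RETINA")
    fovea = find_fovea(retina, smooth_halfwidth)
    profile = retina if layer_pair == "RETINA" else thickness_profile(seg, layer_pair)
    samples = sample_points(profile, fovea, offsets_mm)
    return summarize(samples, layer_pair=layer_pair, scan_id=seg.scan_id)
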