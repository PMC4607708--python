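"""Shortest-path boundary tracing by dynamic programming.

Each retinal boundary is traced as the minimum-cost left-to-right path
through a cost image: one row per column, with the per-column row change
bounded by ``max_jump``, and the path length defined as the sum of the
pixel values along the path.  Two cost constructions are used:

* the negated intensity image (hyper-reflective areas become dark), which
  pulls a path into the middle of a bright band — used for the RPE
  centerline;
* the negated, polarity-matched vertical gradient, which pulls a path onto
  a dark→bright or bright→dark edge — used for the IS/OS top, the RPE
  outer border and the ILM.

The four boundaries are traced in sequence, each constraining the search
band of the next: a rough RPE row from the brightest image row, the RPE
centerline in a narrow band around it, the IS/OS top above the centerline,
the RPE outer border below it, and finally the ILM above the IS/OS.
User-supplied anchor points (the programmatic stand-in for interactive
click correction) force the path through given pixels by solving each
inter-anchor interval as an independent fixed-endpoint problem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter1d, median_filter, minimum_filter1d

from .core_io import AnchorPoint, BScan, Calibration, normalize_intensity
from .errors import (
    InfeasiblePathError,
    SegmentationOrderingError,
    ValidationError,
)
from .preprocess import ShiftVector, apply_shifts, estimate_column_shifts

#: Sentinel cost for out-of-band pixels; no admissible path can prefer it.
BAND_SENTINEL = np.inf

#: A gradient-traced boundary is flagged low-confidence when the mean
#: gradient along its path falls below this fraction of the scan's
#: strongest gradient response: a real edge is a substantial fraction of
#: the global maximum, while a path forced through edge-free territory
#: rides faint smoothing tails.
LOW_CONFIDENCE_GRADIENT_FRACTION = 0.25

LAYER_NAMES = ("ILM", "ISOS", "RPE_CENTER", "RPE_OUTER")


@dataclass
class CostImage:
    """A per-pixel path cost array plus a tag naming its construction."""

    values: np.ndarray
    description: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("cost image must be finite")


@dataclass
class SearchBand:
    """Per-column inclusive [lower, upper] admissible row range."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=np.int64)
        self.upper = np.asarray(self.upper, dtype=np.int64)
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValidationError("band lower/upper must be 1-D and equal length")
        if np.any(self.lower > self.upper):
            bad = np.nonzero(self.lower > self.upper)[0]
            raise ValidationError(
                f"empty search band at column(s) {bad[:10].tolist()}"
            )
        if np.any(self.lower < 0):
            raise ValidationError("band lower bound below image")

    @classmethod
    def full(cls, n_rows: int, n_cols: int) -> "SearchBand":
        return cls(np.zeros(n_cols, dtype=int), np.full(n_cols, n_rows - 1))

    @classmethod
    def around_rows(
        cls, rows: np.ndarray, below: int, above: int, n_rows: int
    ) -> "SearchBand":
        """Band ``[rows - above, rows + below]`` clipped to the image.

        Raises if clipping empties any column.
        """
        lower = np.clip(rows - above, 0, n_rows - 1)
        upper = np.clip(rows + below, 0, n_rows - 1)
        if np.any((rows - above) > (n_rows - 1)) or np.any((rows + below) < 0):
            raise ValidationError("search band lies entirely outside the image")
        return cls(lower, upper)

    def __len__(self) -> int:
        return len(self.lower)


@dataclass
class BoundaryPath:
    """A traced boundary: one integer row per column, plus its path cost."""

    rows: np.ndarray
    cost: float
    layer_name: str = ""
    low_confidence: bool = False

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def mean_cost(self) -> float:
        return self.cost / max(len(self.rows), 1)


@dataclass
class LayerSegmentation:
    """The four boundaries of one B-scan, in original image coordinates.

    Enforces the anatomical ordering ILM <= IS/OS <= RPE centerline <=
    RPE outer at every column; a violation raises
    :class:`SegmentationOrderingError` carrying the offending columns.
    """

    ilm: BoundaryPath
    isos: BoundaryPath
    rpe_center: BoundaryPath
    rpe_outer: BoundaryPath
    scan_id: str = ""
    calibration: Calibration | None = None

    def __post_init__(self):
        stack = [self.ilm.rows, self.isos.rows, self.rpe_center.rows, self.rpe_outer.rows]
        lens = {len(r) for r in stack}
        if len(lens) != 1:
            raise ValidationError("boundary paths have differing lengths")
        bad = set()
        for inner, outer in zip(stack[:-1], stack[1:]):
            bad.update(np.nonzero(inner > outer)[0].tolist())
        if bad:
            cols = sorted(bad)
            raise SegmentationOrderingError(
                f"boundary ordering violated at {len(cols)} column(s), "
                f"e.g. {cols[:10]}; supply anchors there",
                columns=cols,
            )

    @property
    def boundaries(self) -> dict:
        return {
            "ILM": self.ilm,
            "ISOS": self.isos,
            "RPE_CENTER": self.rpe_center,
            "RPE_OUTER": self.rpe_outer,
        }

    def to_dict(self) -> dict:
        d = {
            "scan_id": self.scan_id,
            "layers": {
                name: {
                    "rows": bp.rows.tolist(),
                    "cost": float(bp.cost),
                    "low_confidence": bool(bp.low_confidence),
                }
                for name, bp in self.boundaries.items()
            },
        }
        if self.calibration is not None:
            d["calibration"] = self.calibration.to_dict()
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "LayerSegmentation":
        cal = None
        if "calibration" in d:
            c = d["calibration"]
            cal = Calibration(
                axial_scale=float(c["axial_scale_um_per_px"]),
                scan_length_mm=float(c["scan_length_mm"]),
                n_ascans=int(c["n_ascans"]),
            )
        layers = {
            name: BoundaryPath(
                rows=np.asarray(spec["rows"]),
                cost=float(spec["cost"]),
                layer_name=name,
                low_confidence=bool(spec.get("low_confidence", False)),
            )
            for name, spec in d["layers"].items()
        }
        return cls(
            ilm=layers["ILM"],
            isos=layers["ISOS"],
            rpe_center=layers["RPE_CENTER"],
            rpe_outer=layers["RPE_OUTER"],
            scan_id=d.get("scan_id", ""),
            calibration=cal,
        )

    @classmethod
    def from_json(cls, path) -> "LayerSegmentation":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SegmentationConfig:
    """Tunable parameters of the boundary-tracing sequence.

    All offsets are in micrometres and converted per scan through the
    axial calibration; pixel parameters are in pixels.
    """

    max_shift: int = 20  # alignment search range, px
    max_jump: int = 2  # per-column row step bound, px
    band_halfwidth: int = 15  # RPE centerline search half-width, px
    isos_offset_min_um: float = 20.0  # IS/OS band above RPE centerline
    isos_offset_max_um: float = 90.0
    rpe_outer_offset_min_um: float = 2.0  # RPE outer band below centerline
    rpe_outer_offset_max_um: float = 40.0
    ilm_margin_um: float = 30.0  # ILM must stay this far above IS/OS
    ilm_max_jump: int = 1  # stiffer continuity for the weak ILM edge
    gradient_smooth_sigma: float = 1.0  # axial Gaussian presmoothing, px
    gradient_lateral_median: int = 5  # lateral median filter on the gradient, cols
    gradient_lateral_sigma: float = 1.0  # lateral Gaussian on the gradient, cols
    center_smooth_sigma: float = 2.0  # smoothing for the RPE centerline trace, px

    @classmethod
    def from_file(cls, path) -> "SegmentationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# cost constructions


def negate_image(values: np.ndarray) -> CostImage:
    """Cost = 1 - intensity: hyper-reflective areas become dark (cheap)."""
    values = np.asarray(values, dtype=np.float64)
    if values.min() < 0 or values.max() > 1:
        raise ValidationError("negate_image expects intensities in [0, 1]")
    return CostImage(1.0 - values, description="negated intensity")


def vertical_gradient(values: np.ndarray, polarity: str) -> CostImage:
    """Negated polarity-matched vertical gradient cost.

    Forward difference ``g[r] = values[r+1] - values[r]`` (last row
    replicated); ``dark_to_bright`` keeps +g, ``bright_to_dark`` keeps -g;
    negative responses are clipped to zero, the result rescaled to [0, 1]
    and negated so a strong polarity-matched edge has cost near 0.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValidationError("vertical_gradient needs at least 2 rows")
    if polarity not in ("dark_to_bright", "bright_to_dark"):
        raise ValidationError(f"unknown polarity {polarity!r}")
    g = np.empty_like(values)
    g[:-1] = values[1:] - values[:-1]
    g[-1] = g[-2]
    if polarity == "bright_to_dark":
        g = -g
    g = np.clip(g, 0.0, None)
    peak = g.max()
    if peak > 0:
        g = g / peak
    return CostImage(1.0 - g, description=f"negated vertical gradient ({polarity})")


# ---------------------------------------------------------------------------
# dynamic-programming shortest path


def _dp_segment(
    cost: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    max_jump: int,
    start_row: int | None,
    end_row: int | None,
) -> np.ndarray:
    """Minimum-cost path across all columns of ``cost``, endpoints optionally fixed.

    Backward DP: ``D[c][r]`` is the best cost of a path from column ``c``
    (entering at row ``r``) to the last column.  The forward reconstruction
    takes the smallest row at every argmin, which yields the
    lexicographically smallest among the optimal paths.
    """
    n_rows, n_cols = cost.shape
    window = 2 * max_jump + 1
    masked = cost.copy()
    rows_idx = np.arange(n_rows)[:, None]
    masked[(rows_idx < lower[None, :]) | (rows_idx > upper[None, :])] = BAND_SENTINEL

    D = np.empty((n_cols, n_rows))
    last = masked[:, -1].copy()
    if end_row is not None:
        fixed = np.full(n_rows, BAND_SENTINEL)
        fixed[end_row] = last[end_row]
        last = fixed
    D[-1] = last
    for c in range(n_cols - 2, -1, -1):
        reach = minimum_filter1d(D[c + 1], size=window, mode="constant", cval=BAND_SENTINEL)
        D[c] = masked[:, c] + reach

    if start_row is not None:
        if not np.isfinite(D[0][start_row]):
            raise InfeasiblePathError(
                "no admissible path from the fixed start row under max_jump"
            )
        r = start_row
    else:
        r = int(np.argmin(D[0]))
        if not np.isfinite(D[0][r]):
            raise InfeasiblePathError("no admissible path through the search band")

    path = np.empty(n_cols, dtype=np.int64)
    path[0] = r
    for c in range(1, n_cols):
        lo = max(0, r - max_jump)
        hi = min(n_rows - 1, r + max_jump)
        seg = D[c][lo : hi + 1]
        r = lo + int(np.argmin(seg))  # first minimum = smallest row
        path[c] = r
    return path


def shortest_path(
    cost: CostImage,
    band: SearchBand,
    max_jump: int = 2,
    anchors: Sequence[AnchorPoint] = (),
    layer_name: str = "",
) -> BoundaryPath:
    """Trace the minimum-cost left-to-right path through a cost image.

    The path visits one row per column; the step between adjacent columns
    is bounded by ``max_jump``; the path length is the sum of the cost
    values along it.  Anchors force passage through given pixels: each
    inter-anchor column interval is solved as an independent problem with
    fixed endpoint rows.  Ties are broken toward the smaller row.

    Raises
    ------
    ValidationError
        Band/anchor inconsistencies (anchor outside band, duplicate
        columns, unsorted anchors).
    InfeasiblePathError
        An anchor pair (or band geometry) admits no path under ``max_jump``.
    """
    values = cost.values
    n_rows, n_cols = values.shape
    if max_jump < 1:
        raise ValidationError(f"max_jump must be >= 1, got {max_jump}")
    if len(band) != n_cols:
        raise ValidationError("band length does not match cost image width")
    if np.any(band.upper > n_rows - 1):
        raise ValidationError("band upper bound below image bottom")

    anchors = list(anchors)
    cols = [a.column for a in anchors]
    if cols != sorted(cols) or len(set(cols)) != len(cols):
        raise ValidationError("anchors must be sorted by column, one per column")
    for a in anchors:
        if not (0 <= a.column < n_cols):
            raise ValidationError(f"anchor column {a.column} outside image")
        if not (band.lower[a.column] <= a.row <= band.upper[a.column]):
            raise ValidationError(
                f"anchor {a} outside search band "
                f"[{band.lower[a.column]}, {band.upper[a.column]}]"
            )
    for a, b in zip(anchors[:-1], anchors[1:]):
        gap = b.column - a.column
        if abs(b.row - a.row) > max_jump * gap:
            raise InfeasiblePathError(
                f"anchors {a} and {b} cannot be joined with max_jump={max_jump}"
            )

    # segment boundaries: column 0 (free), anchor columns (fixed), last column (free)
    rows_out = np.empty(n_cols, dtype=np.int64)
    cut_cols = [0] + cols + [n_cols - 1]
    cut_rows: list[int | None] = [None] + [a.row for a in anchors] + [None]
    if anchors and anchors[0].column == 0:
        cut_cols, cut_rows = cut_cols[1:], cut_rows[1:]
    if anchors and anchors[-1].column == n_cols - 1:
        cut_cols, cut_rows = cut_cols[:-1], cut_rows[:-1]
    if len(cut_cols) == 1:  # single column image, possibly anchored
        r = cut_rows[0]
        rows_out[0] = int(np.argmin(np.where(
            (np.arange(n_rows) >= band.lower[0]) & (np.arange(n_rows) <= band.upper[0]),
            values[:, 0], BAND_SENTINEL))) if r is None else r
    else:
        for (c0, r0), (c1, r1) in zip(
            zip(cut_cols[:-1], cut_rows[:-1]), zip(cut_cols[1:], cut_rows[1:])
        ):
            seg = _dp_segment(
                values[:, c0 : c1 + 1],
                band.lower[c0 : c1 + 1],
                band.upper[c0 : c1 + 1],
                max_jump,
                start_row=r0,
                end_row=r1,
            )
            rows_out[c0 : c1 + 1] = seg

    total = float(values[rows_out, np.arange(n_cols)].sum())
    return BoundaryPath(rows=rows_out, cost=total, layer_name=layer_name)


# ---------------------------------------------------------------------------
# boundary-specific tracing


def estimate_rpe_row(scan: BScan) -> int:
    """Rough RPE location: the image row with the highest intensity sum.

    The RPE is the most hyper-reflective band, so on an aligned scan its
    row dominates the row-wise intensity sum.  Ties go to the smaller row.
    """
    return int(np.argmax(scan.image.sum(axis=1)))


def _smoothed(scan: BScan, sigma: float) -> np.ndarray:
    img = np.asarray(scan.image, dtype=np.float64)
    if sigma > 0:
        img = gaussian_filter1d(img, sigma=sigma, axis=0, mode="nearest")
    return img


def _um_to_px(um: float, cal: Calibration) -> int:
    return int(round(um / cal.axial_scale))


def segment_rpe_center(
    scan: BScan,
    initial_row: int,
    band_halfwidth: int = 15,
    max_jump: int = 2,
    anchors: Sequence[AnchorPoint] = (),
    smooth_sigma: float = 2.0,
) -> BoundaryPath:
    """Refine the RPE centerline: shortest path in the negated B-scan
    within a narrow vertical region around the initial row estimate.

    The image is smoothed axially before negation: averaging a bright
    band with its dimmer surroundings leaves the band interior brightest,
    which pulls the path to the band center (and suppresses speckle).
    """
    n_rows, n_cols = scan.image.shape
    lo = max(0, initial_row - band_halfwidth)
    hi = min(n_rows - 1, initial_row + band_halfwidth)
    band = SearchBand(np.full(n_cols, lo), np.full(n_cols, hi))
    smoothed = _smoothed(scan, smooth_sigma)
    cost = negate_image(np.clip(smoothed, 0.0, 1.0))
    return shortest_path(cost, band, max_jump, anchors, layer_name="RPE_CENTER")


def _gradient_cost(
    scan: BScan,
    polarity: str,
    smooth_sigma: float,
    lateral_median: int,
    lateral_sigma: float,
) -> np.ndarray:
    """Polarity-matched gradient for boundary tracing, speckle-hardened.

    Axial Gaussian smoothing tames per-pixel speckle before the forward
    difference; the lateral median then rejects responses that are not
    laterally consistent (speckle spikes, individually misaligned
    columns) while a real edge, present in most neighboring columns,
    survives; a light lateral Gaussian finally consolidates edge
    continuity.  Returns the raw (unnormalized) gradient response.
    """
    v = _smoothed(scan, smooth_sigma)
    g = np.empty_like(v)
    g[:-1] = v[1:] - v[:-1]
    g[-1] = g[-2]
    if polarity == "bright_to_dark":
        g = -g
    g = np.clip(g, 0.0, None)
    if lateral_median > 1:
        g = median_filter(g, size=(1, lateral_median), mode="nearest")
    if lateral_sigma > 0:
        g = gaussian_filter1d(g, sigma=lateral_sigma, axis=1, mode="nearest")
    return g


def _gradient_boundary(
    scan: BScan,
    band: SearchBand,
    polarity: str,
    max_jump: int,
    anchors: Sequence[AnchorPoint],
    layer_name: str,
    smooth_sigma: float,
    lateral_median: int = 5,
    lateral_sigma: float = 1.0,
) -> BoundaryPath:
    grad = _gradient_cost(scan, polarity, smooth_sigma, lateral_median, lateral_sigma)
    global_max = float(grad.max())
    # rescale the gradient by its maximum inside the search band: the
    # optimal path is invariant (cost is affine in the gradient) and the
    # per-band scale keeps weak-edge boundaries (e.g. the ILM next to the
    # much stronger IS/OS) numerically comparable across layers
    rows_idx = np.arange(grad.shape[0])[:, None]
    in_band = (rows_idx >= band.lower[None, :]) & (rows_idx <= band.upper[None, :])
    band_max = grad[in_band].max() if np.any(in_band) else 0.0
    scaled = grad / band_max if band_max > 0 else grad
    cost = CostImage(1.0 - scaled, description=f"negated vertical gradient ({polarity})")
    path = shortest_path(cost, band, max_jump, anchors, layer_name=layer_name)
    # confidence compares the matched gradient against the scan's
    # strongest response, so a path forced through edge-free territory
    # is flagged even though it is still the best path in its band
    if global_max > 0:
        matched = grad[path.rows, np.arange(grad.shape[1])] / global_max
        path.low_confidence = float(matched.mean()) < LOW_CONFIDENCE_GRADIENT_FRACTION
    else:
        path.low_confidence = True
    return path


def segment_isos(
    scan: BScan,
    rpe_center: BoundaryPath,
    offset_min_um: float = 20.0,
    offset_max_um: float = 90.0,
    max_jump: int = 2,
    anchors: Sequence[AnchorPoint] = (),
    smooth_sigma: float = 1.0,
    lateral_median: int = 5,
    lateral_sigma: float = 1.0,
) -> BoundaryPath:
    """IS/OS top: dark→bright gradient shortest path above the RPE centerline.

    The default window (20–90 μm above the centerline) covers the adult
    range of the IS/OS-to-RPE-center distance while keeping the band's
    inner limit clear of the gradient tail of the RPE band's own top
    edge.
    """
    if not (0 < offset_min_um < offset_max_um):
        raise ValidationError("offsets must satisfy 0 < min < max")
    cal = scan.calibration
    band = SearchBand.around_rows(
        rpe_center.rows,
        below=-_um_to_px(offset_min_um, cal),
        above=_um_to_px(offset_max_um, cal),
        n_rows=scan.n_rows,
    )
    return _gradient_boundary(
        scan, band, "dark_to_bright", max_jump, anchors, "ISOS",
        smooth_sigma, lateral_median, lateral_sigma,
    )


def segment_rpe_outer(
    scan: BScan,
    rpe_center: BoundaryPath,
    offset_min_um: float = 2.0,
    offset_max_um: float = 40.0,
    max_jump: int = 2,
    anchors: Sequence[AnchorPoint] = (),
    smooth_sigma: float = 1.0,
    lateral_median: int = 5,
    lateral_sigma: float = 1.0,
) -> BoundaryPath:
    """RPE outer border: bright→dark gradient shortest path below the centerline."""
    if not (0 < offset_min_um < offset_max_um):
        raise ValidationError("offsets must satisfy 0 < min < max")
    cal = scan.calibration
    lower = rpe_center.rows + _um_to_px(offset_min_um, cal)
    if np.all(lower > scan.n_rows - 1):
        raise ValidationError("RPE outer search band lies entirely below the image")
    band = SearchBand.around_rows(
        rpe_center.rows,
        below=_um_to_px(offset_max_um, cal),
        above=-_um_to_px(offset_min_um, cal),
        n_rows=scan.n_rows,
    )
    return _gradient_boundary(
        scan, band, "bright_to_dark", max_jump, anchors, "RPE_OUTER",
        smooth_sigma, lateral_median, lateral_sigma,
    )


def segment_ilm(
    scan: BScan,
    isos: BoundaryPath,
    margin_um: float = 30.0,
    max_jump: int = 1,
    anchors: Sequence[AnchorPoint] = (),
    smooth_sigma: float = 1.0,
    lateral_median: int = 5,
    lateral_sigma: float = 1.0,
) -> BoundaryPath:
    """ILM (vitreoretinal surface): dark→bright gradient shortest path in
    the region above the detected IS/OS, with a safety margin.

    The default step bound is stiffer than for the other boundaries
    (1 px/column): the vitreoretinal surface is smooth and its edge
    contrast low, so extra stiffness keeps the path from chasing
    speckle while still following a foveal pit at these scan geometries.
    """
    if margin_um < 0:
        raise ValidationError("margin must be >= 0")
    cal = scan.calibration
    upper = np.clip(isos.rows - _um_to_px(margin_um, cal), 0, scan.n_rows - 1)
    if np.any(isos.rows - _um_to_px(margin_um, cal) < 0):
        raise ValidationError("ILM search band empty after clipping")
    band = SearchBand(np.zeros(scan.n_cols, dtype=int), upper)
    return _gradient_boundary(
        scan, band, "dark_to_bright", max_jump, anchors, "ILM",
        smooth_sigma, lateral_median, lateral_sigma,
    )


def segment_all(
    scan: BScan,
    config: SegmentationConfig | None = None,
    anchors: dict[str, Sequence[AnchorPoint]] | None = None,
) -> LayerSegmentation:
    """The full boundary-tracing sequence on one B-scan.

    Normalize → align → rough RPE row → RPE centerline → IS/OS top →
    RPE outer → ILM.  Anchors are given in original (pre-alignment) image
    coordinates, keyed by layer name; output rows are reported in original
    coordinates by adding the alignment shifts back.

    Raises :class:`SegmentationOrderingError` (with the offending columns)
    if the traced boundaries violate the anatomical ordering — the
    programmatic analogue of an erroneous segmentation that needs manual
    anchor correction.
    """
    config = config or SegmentationConfig()
    anchors = anchors or {}
    norm = normalize_intensity(scan)
    shifts = estimate_column_shifts(norm, max_shift=config.max_shift)
    aligned = apply_shifts(norm, shifts)

    def aligned_anchors(layer: str) -> list[AnchorPoint]:
        out = []
        for a in anchors.get(layer, ()):  # original → aligned coordinates
            row = int(a.row) - int(shifts.shifts[a.column])
            if not (0 <= row < aligned.n_rows):
                raise ValidationError(f"anchor {a} leaves the image after alignment")
            out.append(AnchorPoint(column=a.column, row=row))
        return out

    initial = estimate_rpe_row(aligned)
    rpe_center = segment_rpe_center(
        aligned, initial, config.band_halfwidth, config.max_jump,
        aligned_anchors("RPE_CENTER"), config.center_smooth_sigma,
    )
    grad_kw = dict(
        smooth_sigma=config.gradient_smooth_sigma,
        lateral_median=config.gradient_lateral_median,
        lateral_sigma=config.gradient_lateral_sigma,
    )
    isos = segment_isos(
        aligned, rpe_center, config.isos_offset_min_um, config.isos_offset_max_um,
        config.max_jump, aligned_anchors("ISOS"), **grad_kw,
    )
    rpe_outer = segment_rpe_outer(
        aligned, rpe_center, config.rpe_outer_offset_min_um,
        config.rpe_outer_offset_max_um, config.max_jump,
        aligned_anchors("RPE_OUTER"), **grad_kw,
    )
    ilm = segment_ilm(
        aligned, isos, config.ilm_margin_um, config.ilm_max_jump,
        aligned_anchors("ILM"), **grad_kw,
    )

    def back(path: BoundaryPath) -> BoundaryPath:
        rows = np.clip(path.rows + shifts.shifts, 0, scan.n_rows - 1)
        return BoundaryPath(rows, path.cost, path.layer_name, path.low_confidence)

    return LayerSegmentation(
        ilm=back(ilm),
        isos=back(isos),
        rpe_center=back(rpe_center),
        rpe_outer=back(rpe_outer),
        scan_id=scan.scan_id,
        calibration=scan.calibration,
    )
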