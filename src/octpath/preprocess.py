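"""Horizontal alignment (flattening) of a B-scan.

Eye motion during acquisition displaces each A-scan axially.  Before any
boundary is traced, the B-scan is aligned horizontally by maximizing the
intensity correlation between neighboring A-scans.  The estimator works
on square-root intensities (variance stabilization for multiplicative
speckle) with light axial Gaussian smoothing, in two stages:

1. *Pairwise chaining* — for every adjacent column pair, the integer
   axial lag in ``[-max_shift, +max_shift]`` with the highest normalized
   cross-correlation; absolute shifts are the cumulative sum of the
   pairwise lags.  Exact on noise-free images, but each noisy pairwise
   lag error propagates into every column to its right, so the chain
   drifts under speckle.
2. *Iterative local-reference refinement* — the image is flattened with
   the current shifts, a drift-free reference is built per column as the
   lateral mean of the flattened neighborhood, and each raw column's
   total shift is re-estimated against its reference.  The re-estimation
   searches a bounded range (``refine_search``, the scale of plausible
   axial jitter) plus the column's current shift, so a noise-free fixed
   point is never perturbed and spurious distant matches (e.g. locking
   the RPE band of the reference onto the IS/OS band of a column) are
   excluded.  A few iterations converge.

Shifts are integer only (the boundary error budget of the downstream
segmentation is about one pixel), median-centred so the image does not
drift as a whole, and clipped to ``±max_shift``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .core_io import BScan
from .errors import ValidationError


@dataclass
class ShiftVector:
    """Per-column integer axial displacements, in pixels.

    ``shifts[c]`` is the estimated downward displacement of column ``c``
    relative to the (median-centred) ensemble; :func:`apply_shifts` undoes
    it.  Serializable to a plain dict for audit trails.
    """

    shifts: np.ndarray
    reference_column: int = 0

    def __post_init__(self):
        self.shifts = np.asarray(self.shifts, dtype=np.int64)
        if self.shifts.ndim != 1:
            raise ValidationError("shifts must be a 1-D vector")

    def __len__(self) -> int:
        return len(self.shifts)

    def negate(self) -> "ShiftVector":
        return ShiftVector(-self.shifts, self.reference_column)

    def to_dict(self) -> dict:
        return {
            "shifts": self.shifts.tolist(),
            "reference_column": int(self.reference_column),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShiftVector":
        return cls(np.asarray(d["shifts"]), int(d.get("reference_column", 0)))


def _ncc_lag_scores(
    x: np.ndarray, y: np.ndarray, max_shift: int, margin: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise NCC between ``x`` and ``y`` at every lag in ±max_shift.

    A lag ``l`` means ``y`` appears displaced downward by ``l`` relative
    to ``x``.  Correlations are computed on mean-subtracted overlapping
    segments, cropping ``margin`` rows at both ends (where a flattened
    reference may carry fill values).  Returns ``(lags, scores)`` with
    ``scores`` of shape (n_lags, n_cols); unassessable lags score -inf.
    """
    n_rows, n_cols = x.shape
    lags = np.arange(-max_shift, max_shift + 1)
    scores = np.full((len(lags), n_cols), -np.inf)
    for i, lag in enumerate(lags):
        lo = max(margin, -lag)
        hi = n_rows - max(margin, lag)
        if hi - lo < 2:
            continue
        xs = x[lo:hi] - x[lo:hi].mean(axis=0)
        ys = y[lo + lag : hi + lag] - y[lo + lag : hi + lag].mean(axis=0)
        denom = np.sqrt((xs**2).sum(axis=0) * (ys**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            scores[i] = np.where(denom > 0, (xs * ys).sum(axis=0) / denom, 0.0)
    return lags, scores


def _pick_lags(lags: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Argmax lag per column with ties toward smaller |lag|, then negative."""
    order = sorted(range(len(lags)), key=lambda i: (abs(lags[i]), lags[i]))
    n_cols = scores.shape[1]
    out = np.empty(n_cols, dtype=np.int64)
    for c in range(n_cols):
        best = order[0]
        for i in order[1:]:
            if scores[i, c] > scores[best, c]:
                best = i
        out[c] = lags[best]
    return out


def _pairwise_lags(img: np.ndarray, max_shift: int) -> np.ndarray:
    """Best integer lag per adjacent column pair (stage 1)."""
    lags, scores = _ncc_lag_scores(img[:, :-1], img[:, 1:], max_shift)
    return _pick_lags(lags, scores)


def _shift_columns(img: np.ndarray, shifts: np.ndarray, fill: float) -> np.ndarray:
    out = np.full_like(img, fill)
    n_rows = img.shape[0]
    for c, s in enumerate(shifts):
        s = int(s)
        if s == 0:
            out[:, c] = img[:, c]
        elif s > 0:
            out[: n_rows - s, c] = img[s:, c]
        else:
            out[-s:, c] = img[: n_rows + s, c]
    return out


def estimate_column_shifts(
    scan: BScan,
    max_shift: int = 20,
    smooth_sigma: float = 1.0,
    refine_window: int = 31,
    refine_iterations: int = 8,
    refine_search: int = 10,
) -> ShiftVector:
    """Estimate per-column axial displacements from neighboring A-scan correlation.

    Pairwise-cumulative initialization followed by iterative refinement
    against a lateral-mean reference of the flattened image (see the
    module docstring).  Correlations run on square-root intensities with
    per-column axial Gaussian smoothing (``smooth_sigma`` pixels); both
    transforms are monotone per column, so they cannot bias lags between
    columns and noise-free recovery stays exact.  The returned shifts are
    median-centred and clipped to ``[-max_shift, max_shift]`` (cumulative
    sums of bounded pairwise lags are not themselves bounded, e.g. on a
    tilted scan).

    Raises
    ------
    ValidationError
        If ``max_shift < 1`` or the image has fewer than two columns.
    """
    if max_shift < 1:
        raise ValidationError(f"max_shift must be >= 1, got {max_shift}")
    img = np.asarray(scan.image, dtype=np.float64)
    if img.shape[1] < 2:
        raise ValidationError("alignment needs at least 2 columns")
    img = np.sqrt(np.maximum(img, 0.0))
    if smooth_sigma > 0:
        img = gaussian_filter1d(img, sigma=smooth_sigma, axis=0, mode="nearest")

    fill = float(img.min())

    def center_clip(s):
        return np.clip(s - int(np.round(np.median(s))), -max_shift, max_shift)

    def global_score(s):
        """Sum over columns of the NCC between each raw column (at its
        assigned lag) and the lateral-mean reference of the flattened image."""
        flat = _shift_columns(img, s, fill)
        ref = uniform_filter1d(flat, size=refine_window, axis=1, mode="nearest")
        lags, scores = _ncc_lag_scores(ref, img, max_shift, margin=max_shift)
        idx = np.searchsorted(lags, s)
        col_scores = scores[idx, np.arange(len(s))]
        return float(col_scores[np.isfinite(col_scores)].sum())

    # candidate 1: pairwise chain (exact on noise-free input)
    pair_lags = _pairwise_lags(img, max_shift)
    chained = center_clip(np.concatenate([[0], np.cumsum(pair_lags)]))

    # candidate 2: zero-init iterative refinement (robust under speckle)
    search = min(refine_search, max_shift)
    refined = np.zeros(img.shape[1], dtype=np.int64)
    for _ in range(refine_iterations):
        flat = _shift_columns(img, refined, fill)
        ref = uniform_filter1d(flat, size=refine_window, axis=1, mode="nearest")
        lags, scores = _ncc_lag_scores(ref, img, search, margin=search)
        new = _pick_lags(lags, scores)
        if np.array_equal(new, refined):
            break
        refined = new
    refined = center_clip(refined)

    shifts = chained if global_score(chained) > global_score(refined) else refined
    return ShiftVector(shifts=shifts, reference_column=0)


def apply_shifts(scan: BScan, shifts: ShiftVector, fill: float | None = None) -> BScan:
    """Translate each column axially by minus its shift, undoing the displacement.

    Vacated pixels are set to ``fill`` (default: the image minimum, i.e.
    the vitreous-dark level).  Output has the same shape as the input.
    """
    img = np.asarray(scan.image)
    if len(shifts) != img.shape[1]:
        raise ValidationError(
            f"shift vector length {len(shifts)} != column count {img.shape[1]}"
        )
    if fill is None:
        fill = float(img.min())
    out = _shift_columns(img, shifts.shifts, fill)
    return BScan(image=out, calibration=scan.calibration, scan_id=scan.scan_id)
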