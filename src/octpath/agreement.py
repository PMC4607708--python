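"""Inter-device and test-retest agreement statistics.

Implements the comparison battery used to decide whether two spectral-
domain OCT instruments measure the same thickness once a common
segmentation is applied: paired t tests on per-eye differences, Pearson
correlation, Bland–Altman limits of agreement at mean ± 2 SD of the
differences, an OLS conversion line between devices, and test–retest
repeatability (mean absolute difference and the coefficient of
repeatability, 2·SD of the repeat differences expressed as a percentage
of the mean thickness).

All differences are reported as device B − device A, with the device
labels carried through to the output tables.  The multi-point analysis
along the scan line collapses each eye to its mean over the common
unmasked offsets before the paired test, so the within-eye correlation of
neighboring points cannot inflate the effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass
class PairedSample:
    """Per-eye paired measurements from two devices (or two visits)."""

    eye_id: Sequence
    values_a: np.ndarray
    values_b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self):
        self.values_a = np.asarray(self.values_a, dtype=np.float64)
        self.values_b = np.asarray(self.values_b, dtype=np.float64)
        self.eye_id = list(self.eye_id)
        if not (len(self.eye_id) == len(self.values_a) == len(self.values_b)):
            raise ValidationError("eye_id, values_a, values_b must have equal length")
        if len(self.values_a) < 2:
            raise ValidationError("need at least 2 pairs")
        if np.any(~np.isfinite(self.values_a)) or np.any(~np.isfinite(self.values_b)):
            raise ValidationError(
                "missing values in a paired sample; drop incomplete pairs upstream"
            )

    def __len__(self) -> int:
        return len(self.values_a)


@dataclass
class AgreementResult:
    """Paired-difference statistics between two devices or visits.

    ``mean_diff`` is ``mean_b − mean_a``; the Bland–Altman limits are
    ``mean_diff ± 2·sd_diff``; ``pct_diff`` is the mean difference as a
    percentage of the grand mean thickness.
    """

    n: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    mean_diff: float
    sd_diff: float
    pct_diff: float
    t_stat: float
    p_value: float
    pearson_r: float
    ba_lower: float
    ba_upper: float
    label_a: str = "A"
    label_b: str = "B"


@dataclass
class RepeatabilityResult:
    """Test–retest summary: mean |diff| and coefficient of repeatability."""

    n: int
    mean_abs_diff: float
    cor_pct: float  # 100 × 2·SD(diff) / grand mean


@dataclass
class ConversionFit:
    """OLS line converting one device's thickness to the other's scale."""

    intercept: float
    slope: float
    from_device: str = "A"
    to_device: str = "B"
    r_value: float = float("nan")

    def convert(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=np.float64)


def pct_difference(diff: float, mean_a: float, mean_b: float) -> float:
    """Mean difference as a percentage of the mean of the two device means."""
    return 100.0 * diff / ((mean_a + mean_b) / 2.0)


def paired_compare(sample: PairedSample) -> AgreementResult:
    """Paired t test, Pearson r and Bland–Altman limits for one sample.

    The t statistic is ``mean(d) / (sd(d)/√n)`` with the sample SD
    (n−1 denominator) and a two-sided p from the t distribution with
    n−1 degrees of freedom.  If the differences have zero variance, t is
    undefined (NaN) and p is 0 when the mean difference is nonzero, 1
    otherwise.
    """
    a, b = sample.values_a, sample.values_b
    n = len(sample)
    d = b - a
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if sd_d == 0.0:
        t_stat, p = float("nan"), (0.0 if mean_d != 0 else 1.0)
    else:
        t_stat = mean_d / (sd_d / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))
    if a.std() == 0 or b.std() == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(a, b).statistic)
    return AgreementResult(
        n=n,
        mean_a=mean_a,
        mean_b=mean_b,
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        mean_diff=mean_d,
        sd_diff=sd_d,
        pct_diff=pct_difference(mean_d, mean_a, mean_b),
        t_stat=float(t_stat),
        p_value=p,
        pearson_r=r,
        ba_lower=mean_d - 2.0 * sd_d,
        ba_upper=mean_d + 2.0 * sd_d,
        label_a=sample.label_a,
        label_b=sample.label_b,
    )


def per_point_compare(
    table: pd.DataFrame,
    device_a: str,
    device_b: str,
) -> tuple[dict[float, AgreementResult], AgreementResult]:
    """Per-offset and pooled comparison along the measurement grid.

    ``table`` is tidy with columns ``eye_id, device, offset_mm,
    thickness_um`` (NaN thickness = missing point).  Pairs with a missing
    member are dropped listwise per offset.  The pooled analysis collapses
    each eye to its mean over the offsets where both devices measured,
    then runs the paired test on those per-eye means.
    """
    required = {"eye_id", "device", "offset_mm", "thickness_um"}
    if not required.issubset(table.columns):
        raise ValidationError(f"table must have columns {sorted(required)}")
    wide = table.pivot_table(
        index=["eye_id", "offset_mm"], columns="device", values="thickness_um",
        aggfunc="first", dropna=False,
    )
    for dev in (device_a, device_b):
        if dev not in wide.columns:
            raise ValidationError(f"device {dev!r} absent from table")
    wide = wide[[device_a, device_b]].dropna()
    if wide.empty:
        raise ValidationError("no common offsets with complete pairs")

    per_offset: dict[float, AgreementResult] = {}
    for off, grp in wide.groupby(level="offset_mm"):
        if len(grp) < 2:
            continue
        per_offset[float(off)] = paired_compare(
            PairedSample(
                eye_id=grp.index.get_level_values("eye_id"),
                values_a=grp[device_a].to_numpy(),
                values_b=grp[device_b].to_numpy(),
                label_a=device_a,
                label_b=device_b,
            )
        )
    eye_means = wide.groupby(level="eye_id").mean()
    pooled = paired_compare(
        PairedSample(
            eye_id=eye_means.index,
            values_a=eye_means[device_a].to_numpy(),
            values_b=eye_means[device_b].to_numpy(),
            label_a=device_a,
            label_b=device_b,
        )
    )
    return per_offset, pooled


def repeatability(visit1, visit2) -> RepeatabilityResult:
    """Intra-device test–retest variability.

    ``mean_abs_diff`` is the mean |visit2 − visit1|; the Bland–Altman
    coefficient of repeatability is 2·SD of the repeat differences,
    expressed as a percentage of the mean of all measurements.
    """
    v1 = np.asarray(visit1, dtype=np.float64)
    v2 = np.asarray(visit2, dtype=np.float64)
    if v1.shape != v2.shape or v1.ndim != 1:
        raise ValidationError("visits must be 1-D and paired")
    if len(v1) < 2:
        raise ValidationError("need at least 2 eyes for repeatability")
    d = v2 - v1
    grand = float(np.concatenate([v1, v2]).mean())
    return RepeatabilityResult(
        n=len(v1),
        mean_abs_diff=float(np.abs(d).mean()),
        cor_pct=100.0 * 2.0 * float(d.std(ddof=1)) / grand,
    )


def fit_conversion(
    x, y, from_device: str = "A", to_device: str = "B"
) -> ConversionFit:
    """Ordinary least squares line converting device A thickness to device B."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("conversion fit needs >= 3 paired values")
    if x.std() == 0:
        raise ValidationError("zero variance in predictor")
    res = stats.linregress(x, y)
    return ConversionFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        from_device=from_device,
        to_device=to_device,
        r_value=float(res.rvalue),
    )


def summary_table(results: Mapping[str, AgreementResult]) -> pd.DataFrame:
    """Assemble per-level agreement results into a device-comparison table.

    One row per grid level (e.g. foveal center / 1-mm line / all points)
    with per-device mean and SD, the difference (B − A), the percentage
    difference and the p value — the layout of a between-device thickness
    comparison table.
    """
    if not results:
        raise ValidationError("no results to tabulate")
    rows = []
    for level, r in results.items():
        rows.append(
            {
                "level": level,
                f"mean_{r.label_a}": r.mean_a,
                f"sd_{r.label_a}": r.sd_a,
                f"mean_{r.label_b}": r.mean_b,
                f"sd_{r.label_b}": r.sd_b,
                "difference_um": r.mean_diff,
                "pct_difference": r.pct_diff,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)


def bland_altman_data(sample: PairedSample) -> pd.DataFrame:
    """Per-pair (mean, difference) points plus the 2-SD limits, for plotting."""
    a, b = sample.values_a, sample.values_b
    d = b - a
    out = pd.DataFrame(
        {"eye_id": sample.eye_id, "mean": (a + b) / 2.0, "diff": d}
    )
    out.attrs["mean_diff"] = float(d.mean())
    out.attrs["ba_lower"] = float(d.mean() - 2 * d.std(ddof=1))
    out.attrs["ba_upper"] = float(d.mean() + 2 * d.std(ddof=1))
    return out
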