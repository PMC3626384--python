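"""Ventilated-lung-volume quantification and agreement statistics.

Ventilated lung volume (VLV) is the count of mask pixels times the voxel
volume.  Agreement between two segmentations is quantified by the Dice
coefficient

    Dice(A, B) = 2 |A ∩ B| / (|A| + |B|),

Bland-Altman 95% limits of agreement (mean difference ± 1.96 SD), Pearson
correlation with ordinary least-squares regression, and paired/unpaired
t-tests.  Sample standard deviations use the n−1 denominator throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .image_io import MaskStack, same_geometry

__all__ = [
    "VLVResult",
    "BlandAltman",
    "RegressionResult",
    "TTestResult",
    "AgreementReport",
    "compute_vlv",
    "dice",
    "bland_altman",
    "correlate",
    "group_tests",
    "summarize",
    "agreement_report",
]


@dataclass(frozen=True)
class VLVResult:
    """Ventilated lung volume of one mask stack."""

    subject_id: str
    per_slice_ml: np.ndarray
    voxel_volume_mm3: float

    @property
    def total_l(self) -> float:
        return float(np.sum(self.per_slice_ml) / 1000.0)


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    sd_diff: float

    @property
    def loa_low(self) -> float:
        return self.mean_diff - 1.96 * self.sd_diff

    @property
    def loa_high(self) -> float:
        return self.mean_diff + 1.96 * self.sd_diff


@dataclass(frozen=True)
class RegressionResult:
    r: float
    slope: float
    intercept: float
    p: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    paired: bool
    degenerate: bool = False


@dataclass(frozen=True)
class AgreementReport:
    """Bundle of per-subject Dice values and method-agreement summaries."""

    dice: dict[str, float]
    bland_altman_ml: BlandAltman
    regression: RegressionResult
    t_test: TTestResult

    @property
    def mean_dice(self) -> float:
        return float(np.mean(list(self.dice.values())))


def compute_vlv(mask: MaskStack, subject_id: str = "") -> VLVResult:
    """Per-slice and total ventilated volume of a binary mask stack."""
    per_slice_px = mask.slices.reshape(mask.n_slices, -1).sum(axis=1)
    vv = mask.voxel_volume_mm3
    return VLVResult(
        subject_id=subject_id,
        per_slice_ml=per_slice_px * vv / 1000.0,
        voxel_volume_mm3=vv,
    )


def dice(a: MaskStack | np.ndarray, b: MaskStack | np.ndarray) -> float:
    """Dice overlap of two binary masks; both-empty is defined as 1."""
    if isinstance(a, MaskStack) and isinstance(b, MaskStack):
        if not same_geometry(a, b):
            raise ValueError("mask geometries differ")
        aa, bb = a.slices.astype(bool), b.slices.astype(bool)
    else:
        aa = (a.slices if isinstance(a, MaskStack) else np.asarray(a)).astype(bool)
        bb = (b.slices if isinstance(b, MaskStack) else np.asarray(b)).astype(bool)
        if aa.shape != bb.shape:
            raise ValueError(f"shape mismatch {aa.shape} vs {bb.shape}")
    denom = int(aa.sum()) + int(bb.sum())
    if denom == 0:
        return 1.0  # vacuous perfect agreement of two empty masks
    return 2.0 * int((aa & bb).sum()) / denom


def bland_altman(pairs: np.ndarray | list) -> BlandAltman:
    """Mean and SD of paired differences a−b, with 95% limits of agreement."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (a, b) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    return BlandAltman(
        mean_diff=float(diffs.mean()), sd_diff=float(diffs.std(ddof=1))
    )


def correlate(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Pearson r and OLS fit of y on x, with the two-sided t-test p for r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    res = sps.linregress(x, y)
    return RegressionResult(
        r=float(res.rvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p=float(res.pvalue),
    )


def group_tests(a: np.ndarray, b: np.ndarray, paired: bool = False) -> TTestResult:
    """Two-sided t-test, paired or pooled two-sample.

    Zero-variance differences (identical or constant-offset pairs) are
    reported with ``degenerate=True``; exactly identical paired vectors get
    the documented convention t=0, p=1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test requires equal-length vectors")
        diffs = a - b
        if np.all(diffs == diffs[0]):
            if diffs[0] == 0:
                return TTestResult(t=0.0, p=1.0, paired=True, degenerate=True)
            return TTestResult(t=math.inf, p=0.0, paired=True, degenerate=True)
        t, p = sps.ttest_rel(a, b)
    else:
        if np.std(a) == 0 and np.std(b) == 0 and a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0, paired=False, degenerate=True)
        t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(t), p=float(p), paired=paired)


def summarize(values: np.ndarray | list) -> tuple[float, float]:
    """Arithmetic mean and sample (n−1) SD; SD is NaN for a single value."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty vector")
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
    return float(arr.mean()), sd


def agreement_report(
    semiauto: dict[str, MaskStack], manual: dict[str, MaskStack]
) -> AgreementReport:
    """Full method-agreement analysis of two per-subject mask collections."""
    ids = sorted(semiauto)
    if sorted(manual) != ids:
        raise ValueError("subject ids of the two collections differ")
    dices = {sid: dice(semiauto[sid], manual[sid]) for sid in ids}
    vlv_a = np.array([compute_vlv(semiauto[sid], sid).total_l for sid in ids])
    vlv_b = np.array([compute_vlv(manual[sid], sid).total_l for sid in ids])
    ba = bland_altman(np.column_stack([vlv_a * 1000.0, vlv_b * 1000.0]))
    reg = correlate(vlv_b, vlv_a)
    tt = group_tests(vlv_a, vlv_b, paired=True)
    return AgreementReport(dice=dices, bland_altman_ml=ba, regression=reg, t_test=tt)
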