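"""Relative-quantification RT-qPCR analysis (delta-Cq method).

Cq is the amplification cycle at which fluorescence crosses the threshold;
lower Cq means more template.  Each target's Cq is referenced to the mean Cq
of designated reference assays within the same sample:

    dCq = Cq_target - mean(Cq_references);   relative expression = 2^-dCq

which makes dCq invariant to any per-sample additive shift (pipetting or
reverse-transcription efficiency) by construction.  Per target the two groups
are compared on either the dCq (log) or 2^-dCq (linear) scale; each group is
first checked for normality with Shapiro-Wilk and the comparison routed to an
unpaired Student's t-test when both groups pass, otherwise to Mann-Whitney U.
Because Mann-Whitney only ranks values, its p-value is identical on the two
scales, while t-test p-values generally differ between them.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .codeset import ValidationError
from .stats import TestResult, mann_whitney_test, shapiro_normal, student_test

__all__ = [
    "AssayRole",
    "CqTable",
    "ScaleTestResult",
    "QpcrTargetResult",
    "delta_cq",
    "linearize",
    "fold_change",
    "test_target",
    "concordance",
]


class AssayRole(str, enum.Enum):
    TARGET = "target"
    REFERENCE = "reference"
    SPIKEIN = "spikein"
    HEMOLYSIS_MARKER = "hemolysis_marker"


@dataclass
class CqTable:
    """Samples x assays grid of Cq values with group labels and assay roles.

    Missing measurements are NaN (explicit); at least two reference assays
    are required for delta-Cq referencing.
    """

    values: pd.DataFrame  # samples x assays
    groups: pd.Series  # per-sample labels
    roles: Mapping[str, AssayRole]

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values, dtype=float)
        self.groups = pd.Series(self.groups).loc[self.values.index]
        self.roles = {a: AssayRole(r) for a, r in dict(self.roles).items()}
        unknown = [a for a in self.values.columns if a not in self.roles]
        if unknown:
            raise ValidationError(f"assays without a role: {unknown}")
        if len(self.reference_assays()) < 2:
            raise ValidationError("need at least 2 reference assays")

    def reference_assays(self) -> list[str]:
        return [a for a in self.values.columns if self.roles[a] is AssayRole.REFERENCE]

    def target_assays(self) -> list[str]:
        return [a for a in self.values.columns if self.roles[a] is AssayRole.TARGET]

    def group_names(self) -> list[str]:
        return list(dict.fromkeys(self.groups))


@dataclass(frozen=True)
class ScaleTestResult:
    """Group comparison of one target on one scale (dCq or 2^-dCq)."""

    scale: Literal["delta_cq", "linear"]
    shapiro_p: Mapping[str, float]
    normal: Mapping[str, bool]
    test: TestResult

    @property
    def test_used(self) -> str:
        return self.test.test


@dataclass
class QpcrTargetResult:
    """Full per-target validation readout."""

    target: str
    delta_cq: pd.Series  # per sample
    linear: pd.Series  # 2^-dCq per sample
    fold_mean: float
    fold_sd: float
    per_sample_folds: pd.Series
    direction: str  # up_in_b / up_in_a / none, from linear group means
    by_scale: Mapping[str, ScaleTestResult]
    excluded_samples: Sequence[str] = ()
    concordant_with_screen: Optional[bool] = None


def delta_cq(table: CqTable) -> pd.DataFrame:
    """Per-sample, per-target dCq = Cq_target - mean(reference Cqs).

    Samples missing any reference Cq are excluded with a warning -- never
    silently imputed.  Targets missing a Cq in a retained sample keep NaN
    there (explicit missing value).
    """
    refs = table.reference_assays()
    ref_vals = table.values[refs]
    ok = ref_vals.notna().all(axis=1)
    if (~ok).any():
        dropped = list(table.values.index[~ok])
        warnings.warn(f"samples excluded (missing reference Cq): {dropped}")
    ref_mean = ref_vals.loc[ok].mean(axis=1)
    targets = table.target_assays()
    return table.values.loc[ok, targets].sub(ref_mean, axis=0)


def linearize(dcq):
    """2^-dCq: relative expression on the linear scale."""
    return 2.0 ** (-np.asarray(dcq, dtype=float)) if np.ndim(dcq) else 2.0 ** (-float(dcq))


def fold_change(
    table: CqTable, target: str, control_group: Optional[str] = None
) -> tuple[float, float, pd.Series]:
    """Fold change of the non-control group relative to the control mean.

    Per-sample fold = 2^-dCq / mean(2^-dCq of control group); returns the mean
    and SD over the non-control group's per-sample folds plus all per-sample
    folds (control samples included, so the control group means 1 exactly).
    """
    dcq = delta_cq(table)
    if target not in dcq.columns:
        raise ValidationError(f"{target!r} is not a target assay")
    lin = pd.Series(2.0 ** (-dcq[target]), index=dcq.index).dropna()
    groups = table.groups.loc[lin.index]
    names = list(dict.fromkeys(table.groups))
    control = control_group if control_group is not None else names[0]
    test_groups = [g for g in names if g != control]
    if not test_groups:
        raise ValidationError("need a non-control group")
    ctrl = lin[groups == control]
    if len(ctrl) < 2 or len(lin[groups == test_groups[0]]) < 2:
        raise ValidationError("need >=2 samples with dCq per group")
    ctrl_mean = ctrl.mean()
    if ctrl_mean == 0:
        raise ValidationError("control-group mean expression is zero")
    folds = lin / ctrl_mean
    test_folds = folds[groups == test_groups[0]]
    return float(test_folds.mean()), float(test_folds.std(ddof=1)), folds


def test_target(
    table: CqTable,
    target: str,
    scale: str = "both",
    alpha: float = 0.05,
    control_group: Optional[str] = None,
    screen_direction: Optional[str] = None,
) -> QpcrTargetResult:
    """Compare the two groups for one target with normality-routed testing.

    Shapiro-Wilk (at ``alpha``) runs per group *on the scale being tested*, so
    the routing may differ between the dCq and linear scales; both groups must
    pass for the Student's t route, otherwise Mann-Whitney U is used.  The
    one-sided p is half the two-sided p when the observed direction matches
    the hypothesised one (the observed direction by default).
    """
    dcq_all = delta_cq(table)
    if target not in dcq_all.columns:
        raise ValidationError(f"{target!r} is not a target assay")
    dcq = dcq_all[target].dropna()
    excluded = [s for s in table.values.index if s not in dcq.index]
    groups = table.groups.loc[dcq.index]
    names = list(dict.fromkeys(table.groups))
    if len(names) != 2:
        raise ValidationError("qPCR comparison needs exactly 2 groups")
    control = control_group if control_group is not None else names[0]
    other = [g for g in names if g != control][0]
    a = dcq[groups == control]
    b = dcq[groups == other]
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("Shapiro-Wilk needs >=3 samples per group")

    lin = pd.Series(2.0 ** (-dcq), index=dcq.index)
    # NB: 2^-x is decreasing, so group ordering flips between the scales;
    # expression direction is defined on the linear scale.
    scales: dict[str, ScaleTestResult] = {}
    wanted = ["delta_cq", "linear"] if scale == "both" else [scale]
    for sc in wanted:
        xa, xb = (a, b) if sc == "delta_cq" else (lin[a.index], lin[b.index])
        pa, ok_a = shapiro_normal(xa, alpha)
        pb, ok_b = shapiro_normal(xb, alpha)
        if ok_a and ok_b:
            res = student_test(xa, xb)
        else:
            res = mann_whitney_test(xa, xb)
            if res.tied:
                warnings.warn(
                    f"{target}: ties under Mann-Whitney; mid-rank normal "
                    "approximation used"
                )
        scales[sc] = ScaleTestResult(
            scale=sc,
            shapiro_p={control: pa, other: pb},
            normal={control: ok_a, other: ok_b},
            test=res,
        )

    fold_mean, fold_sd, folds = fold_change(table, target, control_group=control)
    lin_dir = "up_in_b" if lin[b.index].mean() > lin[a.index].mean() else (
        "up_in_a" if lin[b.index].mean() < lin[a.index].mean() else "none"
    )
    result = QpcrTargetResult(
        target=target,
        delta_cq=dcq,
        linear=lin,
        fold_mean=fold_mean,
        fold_sd=fold_sd,
        per_sample_folds=folds,
        direction=lin_dir,
        by_scale=scales,
        excluded_samples=excluded,
    )
    if screen_direction is not None:
        result.concordant_with_screen = concordance(result, screen_direction)
    return result


def concordance(qpcr: QpcrTargetResult, screen_direction: str) -> bool:
    """True iff the qPCR direction matches the screening direction."""
    if qpcr.direction == "none":
        return False
    return qpcr.direction == screen_direction
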