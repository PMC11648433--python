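"""Background correction and normalisation.

Background is estimated per lane from the negative-control probes as
``mean + k * sd`` with stringency k in {0, 1, 2}, and applied either by
*thresholding* (raising every count below the background up to it) or by
*subtraction* (subtracting it, floored at zero -- a floor of one would
silently manufacture detections).

Two normalisations scale whole lanes: a technical one driven by the
positive-control titration, and a content normalisation driven by endogenous
normalisers chosen either as the global pool of probes expressed above
background in every lane ("total RNA") or as the most stable subset of that
pool ranked by the NormFinder model.  Both share one factor formula:

    factor_lane = mean_over_lanes(summary) / summary_lane

so that after applying the factors the chosen per-lane summary statistic is
exactly equal across lanes.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .codeset import (
    CountMatrix,
    EmptySelectionError,
    ProbeClass,
    Stage,
    ValidationError,
)
from .normfinder import normfinder_stability

__all__ = [
    "BackgroundMethod",
    "Stringency",
    "BackgroundSpec",
    "LaneFactors",
    "NormalizerSet",
    "lane_background",
    "apply_threshold",
    "apply_subtraction",
    "positive_control_factors",
    "content_factors",
    "apply_factors",
    "select_total_rna_normalizers",
    "select_normfinder_normalizers",
]

_STRINGENCY_K = {"mean": 0.0, "mean_plus_1sd": 1.0, "mean_plus_2sd": 2.0}


class BackgroundMethod(str, enum.Enum):
    NONE = "none"
    THRESHOLD = "threshold"
    SUBTRACT = "subtract"


class Stringency(str, enum.Enum):
    MEAN = "mean"
    MEAN_PLUS_1SD = "mean_plus_1sd"
    MEAN_PLUS_2SD = "mean_plus_2sd"

    @property
    def k(self) -> float:
        return _STRINGENCY_K[self.value]


@dataclass(frozen=True)
class BackgroundSpec:
    """Background-correction choice: a method plus, unless none, a stringency."""

    method: BackgroundMethod
    stringency: Optional[Stringency] = None

    def __post_init__(self) -> None:
        if self.method is BackgroundMethod.NONE and self.stringency is not None:
            raise ValidationError("stringency must be absent when method is none")
        if self.method is not BackgroundMethod.NONE and self.stringency is None:
            raise ValidationError(f"method {self.method.value!r} needs a stringency")


@dataclass
class LaneFactors:
    """Per-lane multiplicative scaling factors with their provenance."""

    factors: pd.Series  # indexed by lane_id, all > 0
    source: Literal["positive_control", "content_total_rna", "content_normfinder"]

    def __post_init__(self) -> None:
        self.factors = pd.Series(self.factors, dtype=float)
        if (self.factors <= 0).any():
            bad = self.factors.index[self.factors <= 0].tolist()
            raise ValidationError(f"non-positive factors for lanes {bad}")


@dataclass
class NormalizerSet:
    """Endogenous normaliser probes selected for content normalisation."""

    probe_ids: list[str]
    method: Literal["total_rna", "normfinder"]
    stability_values: Optional[pd.Series] = None  # normfinder only; lower = stabler

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise EmptySelectionError("empty normaliser set")


def _negative_stats(
    matrix: CountMatrix, sd_ddof: int = 1
) -> tuple[pd.Series, pd.Series]:
    negatives = matrix.subset_by_class(ProbeClass.NEGATIVE)
    if negatives.n_probes < 2:
        raise ValidationError("need at least 2 negative-control probes")
    vals = negatives.values.astype(float)
    return vals.mean(axis=1), vals.std(axis=1, ddof=sd_ddof)


def lane_background(
    matrix: CountMatrix, stringency: Stringency | str, sd_ddof: int = 1
) -> pd.Series:
    """Per-lane background: mean + k*sd of the negative-control counts.

    ``sd_ddof=1`` (sample SD) by default; set 0 for population SD to match
    exports from software using the other convention.
    """
    stringency = Stringency(stringency)
    mean, sd = _negative_stats(matrix, sd_ddof=sd_ddof)
    bg = mean + stringency.k * sd
    bg.name = f"background_{stringency.value}"
    return bg


def _check_background(matrix: CountMatrix, background: pd.Series) -> pd.Series:
    background = pd.Series(background, dtype=float)
    missing = [ln for ln in matrix.lane_ids if ln not in background.index]
    if missing:
        raise ValidationError(f"background missing for lanes {missing}")
    return background.loc[matrix.lane_ids]


def apply_threshold(matrix: CountMatrix, background: pd.Series) -> CountMatrix:
    """Raise every count below its lane background up to the background."""
    bg = _check_background(matrix, background)
    vals = matrix.values.astype(float).clip(lower=bg, axis=0)
    return matrix.with_values(vals, Stage.BACKGROUND_CORRECTED)


def apply_subtraction(
    matrix: CountMatrix, background: pd.Series, floor: float = 0.0
) -> CountMatrix:
    """Subtract the lane background from every count, flooring at ``floor``."""
    bg = _check_background(matrix, background)
    vals = matrix.values.astype(float).sub(bg, axis=0).clip(lower=floor)
    return matrix.with_values(vals, Stage.BACKGROUND_CORRECTED)


def _lane_summaries(
    values: pd.DataFrame, averaging: str, what: str
) -> pd.Series:
    vals = values.astype(float)
    if averaging == "geometric":
        if (vals == 0).any().any():
            warnings.warn(
                f"zero {what} counts replaced by 0.5 for geometric averaging",
                stacklevel=3,
            )
            vals = vals.where(vals > 0, 0.5)
        summary = np.exp(np.log(vals).mean(axis=1))
    elif averaging == "arithmetic":
        summary = vals.mean(axis=1)
    else:
        raise ValueError(f"unknown averaging {averaging!r}")
    return summary


def _factors_from_summaries(summaries: pd.Series, what: str) -> pd.Series:
    if (summaries <= 0).any():
        bad = summaries.index[summaries <= 0].tolist()
        raise ValidationError(f"zero {what} summary in lanes {bad}")
    return summaries.mean() / summaries


def positive_control_factors(
    matrix: CountMatrix, averaging: str = "geometric"
) -> LaneFactors:
    """Technical normalisation factors from the positive-control titration.

    Per lane the positive-control counts are averaged (geometric by default)
    and the factor is the mean of those summaries over lanes divided by the
    lane's own summary.
    """
    positives = matrix.subset_by_class(ProbeClass.POSITIVE)
    if positives.n_probes < 2:
        raise ValidationError("need at least 2 positive-control probes")
    if (positives.values.astype(float).sum(axis=1) == 0).any():
        bad = positives.values.index[
            positives.values.astype(float).sum(axis=1) == 0
        ].tolist()
        raise ValidationError(f"all-zero positive controls in lanes {bad}")
    summaries = _lane_summaries(positives.values, averaging, "positive-control")
    return LaneFactors(
        _factors_from_summaries(summaries, "positive-control"), "positive_control"
    )


def content_factors(
    matrix: CountMatrix, normalizers: NormalizerSet, averaging: str = "geometric"
) -> LaneFactors:
    """Content-normalisation factors: same formula as the positive-control
    factors, but over the chosen endogenous normaliser probes."""
    missing = [p for p in normalizers.probe_ids if p not in matrix.values.columns]
    if missing:
        raise ValidationError(f"normaliser probes absent from matrix: {missing}")
    sub = matrix.values[normalizers.probe_ids]
    summaries = _lane_summaries(sub, averaging, "normaliser")
    source = (
        "content_total_rna" if normalizers.method == "total_rna" else "content_normfinder"
    )
    return LaneFactors(_factors_from_summaries(summaries, "normaliser"), source)


def apply_factors(matrix: CountMatrix, factors: LaneFactors) -> CountMatrix:
    """Multiply every count in a lane by that lane's factor."""
    f = _check_background(matrix, factors.factors)  # same per-lane alignment
    stage = (
        Stage.POSITIVE_NORMALISED
        if factors.source == "positive_control"
        else Stage.CONTENT_NORMALISED
    )
    vals = matrix.values.astype(float).mul(f, axis=0)
    return matrix.with_values(vals, stage)


def select_total_rna_normalizers(
    raw: CountMatrix,
    min_mean_count: Optional[float] = None,
    sd_ddof: int = 1,
) -> NormalizerSet:
    """Global normaliser pool for the total-RNA method.

    On raw counts (no positive-control normalisation), the per-lane background
    at mean + 1 SD of the negatives is computed and every endogenous probe
    whose raw count exceeds that background in *every* lane is kept.  By
    default no minimum-expression filter is applied; pass ``min_mean_count``
    (e.g. 50) to drop low-expressed probes from the pool.
    """
    if raw.stage is not Stage.RAW:
        raise ValidationError("total-RNA normaliser selection runs on raw counts")
    bg = lane_background(raw, Stringency.MEAN_PLUS_1SD, sd_ddof=sd_ddof)
    endo = raw.subset_by_class(ProbeClass.ENDOGENOUS)
    above = endo.values.astype(float).gt(bg, axis=0).all(axis=0)
    chosen = [p for p in endo.probe_ids if above[p]]
    if min_mean_count is not None:
        means = endo.values.astype(float).mean(axis=0)
        chosen = [p for p in chosen if means[p] >= min_mean_count]
    if not chosen:
        raise EmptySelectionError(
            "no endogenous probe exceeds background in every lane; "
            "total-RNA workflows cannot proceed"
        )
    return NormalizerSet(chosen, "total_rna")


def select_normfinder_normalizers(
    pool: NormalizerSet,
    data: CountMatrix,
    groups: Optional[pd.Series] = None,
    n_select: int = 5,
    use_cv_ranking: bool = False,
) -> NormalizerSet:
    """Pick the ``n_select`` most stable probes of ``pool`` by NormFinder.

    Stability is the NormFinder model value (lower = more stable) computed on
    log2 counts of the pool probes; ties break by probe_id so the selection is
    deterministic.  ``use_cv_ranking`` swaps in a coefficient-of-variation
    ranking for cross-checking.
    """
    if n_select > len(pool.probe_ids):
        raise ValidationError(
            f"n_select={n_select} exceeds pool size {len(pool.probe_ids)}"
        )
    if groups is None:
        groups = data.groups()
    sub = data.values[pool.probe_ids].astype(float)
    if use_cv_ranking:
        stab = sub.std(axis=0, ddof=1) / sub.mean(axis=0)
        stab.name = "cv"
    else:
        stab = normfinder_stability(sub, groups.loc[sub.index])
    ranked = stab.sort_values(kind="mergesort")
    # stable sort on values; break value ties lexicographically by probe_id
    order = sorted(ranked.index, key=lambda p: (stab[p], p))
    chosen = order[:n_select]
    return NormalizerSet(chosen, "normfinder", stability_values=stab.loc[order])
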