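"""The 14 analysis workflows and their downstream statistics.

A workflow is one combination of background-correction method (none,
subtraction, thresholding), background stringency (mean of the negative
controls, mean + 1 SD, mean + 2 SD) and content-normalisation method
(NormFinder or total RNA).  Crucially, the three subtypes do *not* share an
operation order:

* thresholding: positive-control normalisation -> content normalisation ->
  threshold against the per-lane background;
* subtraction: background subtraction first, then positive-control and
  content normalisation;
* no background: positive-control then content normalisation.

In thresholding workflows the background a cell is compared against is, by
default, recomputed from the negative-control counts carried through the same
normalisation chain, so the comparison is scale-consistent; a raw-scale
toggle exists because vendor software does not document its choice.

Each workflow ends with a per-probe Welch t-test on the final (linear)
expression values; results across workflows are folded into a consensus
table ranking probes by the number of workflows that called them significant,
with an inconsistency flag when significant workflows disagree in direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .codeset import CountMatrix, ProbeClass, Stage, ValidationError
from .preprocess import (
    BackgroundMethod,
    BackgroundSpec,
    NormalizerSet,
    Stringency,
    apply_factors,
    apply_subtraction,
    apply_threshold,
    content_factors,
    lane_background,
    positive_control_factors,
)
from .stats import welch_test, welch_test_matrix

__all__ = [
    "WorkflowConfig",
    "WorkflowOptions",
    "DEResult",
    "ConsensusTable",
    "DetectionCurve",
    "PcaSummary",
    "enumerate_workflows",
    "run_workflow",
    "run_all_workflows",
    "welch_test",
    "detection_curve",
    "consensus_table",
    "pca_summary",
    "compare_to_reference",
]


@dataclass(frozen=True)
class WorkflowConfig:
    """One of the 14 background x stringency x normalisation combinations."""

    id: int
    background: BackgroundSpec
    normalization: Literal["normfinder", "total_rna"]

    @property
    def label(self) -> str:
        bg = self.background
        stringency = f" {bg.stringency.value}" if bg.stringency else ""
        return f"{self.id}: {bg.method.value}{stringency} + {self.normalization}"


def enumerate_workflows() -> list[WorkflowConfig]:
    """The full workflow grid, ids 1-14 in the canonical published order:
    2 no-background (NF, TR), then subtraction and thresholding blocks each
    ordered stringency 2 SD / 1 SD / mean within NF then TR."""
    configs: list[WorkflowConfig] = []
    nid = 1
    for method, norms in (
        (BackgroundMethod.NONE, None),
        (BackgroundMethod.SUBTRACT, None),
        (BackgroundMethod.THRESHOLD, None),
    ):
        if method is BackgroundMethod.NONE:
            for norm in ("normfinder", "total_rna"):
                configs.append(
                    WorkflowConfig(nid, BackgroundSpec(method), norm)
                )
                nid += 1
            continue
        for norm in ("normfinder", "total_rna"):
            for stringency in (
                Stringency.MEAN_PLUS_2SD,
                Stringency.MEAN_PLUS_1SD,
                Stringency.MEAN,
            ):
                configs.append(
                    WorkflowConfig(nid, BackgroundSpec(method, stringency), norm)
                )
                nid += 1
    return configs


@dataclass(frozen=True)
class WorkflowOptions:
    """Every tunable the engine honours, with the documented defaults."""

    averaging: Literal["geometric", "arithmetic"] = "geometric"
    sd_ddof: int = 1
    alpha: float = 0.05
    welch_on_log2: bool = False
    threshold_background_scale: Literal["normalised", "raw"] = "normalised"
    subtraction_floor: float = 0.0
    detection_threshold: float = 2.0
    multiple_testing: Literal["none", "benjamini_hochberg"] = "none"


@dataclass
class DEResult:
    """Per-endogenous-probe Welch statistics for one workflow.

    ``table`` columns: mean_a, mean_b, fold_change (B/A), t, df, p,
    significant (strict p < alpha), direction.
    """

    workflow_id: int
    table: pd.DataFrame
    alpha: float

    def significant_probes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def run_workflow(
    raw: CountMatrix,
    config: WorkflowConfig,
    normalizer_sets: Mapping[str, NormalizerSet],
    options: WorkflowOptions = WorkflowOptions(),
) -> tuple[CountMatrix, DEResult]:
    """Execute one workflow on raw counts and Welch-test the result.

    ``normalizer_sets`` maps ``"total_rna"`` and ``"normfinder"`` to
    normaliser sets precomputed from the raw data (fixed across workflows).
    """
    if raw.stage is not Stage.RAW:
        raise ValidationError("run_workflow expects a raw-stage matrix")
    if config.normalization not in normalizer_sets:
        raise ValidationError(
            f"no normaliser set for method {config.normalization!r}"
        )
    normalizers = normalizer_sets[config.normalization]
    method = config.background.method

    if method is BackgroundMethod.SUBTRACT:
        bg = lane_background(raw, config.background.stringency, sd_ddof=options.sd_ddof)
        current = apply_subtraction(raw, bg, floor=options.subtraction_floor)
    else:
        current = raw

    pos = positive_control_factors(current, averaging=options.averaging)
    current = apply_factors(current, pos)
    content = content_factors(current, normalizers, averaging=options.averaging)
    current = apply_factors(current, content)

    if method is BackgroundMethod.THRESHOLD:
        if options.threshold_background_scale == "normalised":
            bg = lane_background(
                current, config.background.stringency, sd_ddof=options.sd_ddof
            )
        else:
            bg = lane_background(
                raw, config.background.stringency, sd_ddof=options.sd_ddof
            )
        current = apply_threshold(current, bg)

    de = _welch_de(current, config.id, options)
    return current, de


def _welch_de(
    processed: CountMatrix, workflow_id: int, options: WorkflowOptions
) -> DEResult:
    endo = processed.subset_by_class(ProbeClass.ENDOGENOUS)
    groups = endo.groups()
    names = [g for g in dict.fromkeys(groups) if g is not None]
    if len(names) != 2:
        raise ValidationError("differential expression needs exactly 2 groups")
    ga, gb = names
    a = endo.values.loc[groups == ga].to_numpy(dtype=float).T  # probes x lanes
    b = endo.values.loc[groups == gb].to_numpy(dtype=float).T
    test_a, test_b = (np.log2(a + 1.0), np.log2(b + 1.0)) if options.welch_on_log2 else (a, b)
    t, df, p = welch_test_matrix(test_a, test_b)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean_a > 0, mean_b / mean_a, np.inf)
    p_adj = _bh_adjust(p) if options.multiple_testing == "benjamini_hochberg" else p
    significant = p_adj < options.alpha
    direction = np.where(
        significant,
        np.where(mean_b > mean_a, "up_in_b", np.where(mean_b < mean_a, "up_in_a", "none")),
        "none",
    )
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold,
            "t": t,
            "df": df,
            "p": p_adj,
            "significant": significant,
            "direction": direction,
        },
        index=endo.probe_ids,
    )
    return DEResult(workflow_id=workflow_id, table=table, alpha=options.alpha)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


def run_all_workflows(
    raw: CountMatrix,
    normalizer_sets: Mapping[str, NormalizerSet],
    options: WorkflowOptions = WorkflowOptions(),
    configs: Optional[Sequence[WorkflowConfig]] = None,
) -> tuple[dict[int, CountMatrix], dict[int, DEResult]]:
    """Run every workflow (default: all 14) on one raw matrix."""
    processed: dict[int, CountMatrix] = {}
    de_results: dict[int, DEResult] = {}
    for config in configs if configs is not None else enumerate_workflows():
        matrix, de = run_workflow(raw, config, normalizer_sets, options)
        processed[config.id] = matrix
        de_results[config.id] = de
    return processed, de_results


# -- detection curves ----------------------------------------------------------


@dataclass
class DetectionCurve:
    """Probes detected (count >= threshold) in at least k lanes, k = 1..n."""

    counts: pd.Series  # index k, value = number of probes detected in >= k lanes
    never_detected: int
    threshold: float

    def at_least(self, k: int) -> int:
        return int(self.counts.loc[k])


def detection_curve(matrix: CountMatrix, threshold: float = 2.0) -> DetectionCurve:
    """Cumulative detection over endogenous probes; non-increasing in k."""
    endo = matrix.subset_by_class(ProbeClass.ENDOGENOUS)
    detected_lanes = (endo.values.astype(float) >= threshold).sum(axis=0)
    ks = range(1, endo.n_lanes + 1)
    counts = pd.Series(
        {k: int((detected_lanes >= k).sum()) for k in ks}, name="n_probes"
    )
    return DetectionCurve(
        counts=counts,
        never_detected=int((detected_lanes == 0).sum()),
        threshold=threshold,
    )


# -- consensus -----------------------------------------------------------------


@dataclass
class ConsensusTable:
    """Cross-workflow significance grid with frequency/direction ranking."""

    significance: pd.DataFrame  # probes x workflow ids (bool)
    frequency: pd.Series
    direction: pd.Series  # up_in_b / up_in_a / inconsistent / none
    min_frequency: int

    def ranked(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"frequency": self.frequency, "direction": self.direction}
        )
        out = out.sort_values(
            by=["frequency"], ascending=False, kind="mergesort"
        )
        # ties by probe_id: stable sort over lexicographically sorted index
        out = out.loc[
            sorted(out.index, key=lambda p: (-out.at[p, "frequency"], p))
        ]
        return out

    def candidates(self) -> list[str]:
        ranked = self.ranked()
        return list(ranked.index[ranked["frequency"] >= self.min_frequency])


def consensus_table(
    de_results: Mapping[int, DEResult], min_frequency: int = 2
) -> ConsensusTable:
    """Fold per-workflow Welch results into the consensus grid.

    A probe's direction is the common direction of the workflows that called
    it significant, ``inconsistent`` when those workflows disagree in sign,
    and ``none`` when no workflow called it.
    """
    if not de_results:
        raise ValidationError("no DE results supplied")
    import warnings as _warnings

    if len(de_results) < 14:
        _warnings.warn(
            f"consensus over {len(de_results)} workflows (expected 14)"
        )
    ids = sorted(de_results)
    probes = list(de_results[ids[0]].table.index)
    sig = pd.DataFrame(
        {wf: de_results[wf].table["significant"].reindex(probes) for wf in ids},
        index=probes,
    ).fillna(False)
    frequency = sig.sum(axis=1).astype(int)
    direction = {}
    for probe in probes:
        dirs = {
            de_results[wf].table.at[probe, "direction"]
            for wf in ids
            if sig.at[probe, wf]
        }
        dirs.discard("none")
        if not dirs:
            direction[probe] = "none"
        elif len(dirs) == 1:
            direction[probe] = next(iter(dirs))
        else:
            direction[probe] = "inconsistent"
    return ConsensusTable(
        significance=sig,
        frequency=frequency,
        direction=pd.Series(direction),
        min_frequency=min_frequency,
    )


# -- multivariate summary ------------------------------------------------------


@dataclass
class PcaSummary:
    """First two principal components of the processed lanes plus per-group
    dispersion (trace of the group covariance of the scores) and 2-SD ellipse
    parameters (centre, axis half-lengths, rotation)."""

    scores: pd.DataFrame  # lanes x [PC1, PC2]
    explained_variance_ratio: tuple[float, float]
    group_dispersion: pd.Series
    ellipses: pd.DataFrame  # per group: cx, cy, half_width, half_height, angle_rad


def pca_summary(processed: CountMatrix, log_transform: bool = True) -> PcaSummary:
    """Unsupervised PCA of lanes on per-probe standardised log2(x+1) values."""
    if processed.n_lanes < 3:
        raise ValidationError("PCA needs at least 3 lanes")
    x = processed.values.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValidationError("constant matrix: no variance for PCA")
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(z)
    score_df = pd.DataFrame(scores, index=processed.lane_ids, columns=["PC1", "PC2"])
    groups = processed.groups()
    dispersion = {}
    ellipse_rows = {}
    for g in dict.fromkeys(groups.dropna()):
        pts = score_df.loc[groups == g].to_numpy()
        if len(pts) < 2:
            continue
        cov = np.cov(pts.T)
        dispersion[g] = float(np.trace(cov))
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        ellipse_rows[g] = {
            "cx": float(pts[:, 0].mean()),
            "cy": float(pts[:, 1].mean()),
            "half_width": float(2.0 * np.sqrt(max(eigvals[0], 0.0))),
            "half_height": float(2.0 * np.sqrt(max(eigvals[1], 0.0))),
            "angle_rad": float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0])),
        }
    return PcaSummary(
        scores=score_df,
        explained_variance_ratio=tuple(pca.explained_variance_ratio_[:2]),
        group_dispersion=pd.Series(dispersion, name="dispersion"),
        ellipses=pd.DataFrame.from_dict(ellipse_rows, orient="index"),
    )


# -- diffing against external exports ------------------------------------------


def compare_to_reference(
    processed: CountMatrix,
    reference: CountMatrix,
    abs_tolerance: float = 0.5,
) -> pd.DataFrame:
    """Cell-by-cell diff against an external (e.g. vendor) export.

    Matrices are aligned by lane and probe ids; unalignable ids raise with
    the orphans listed.  Returns one row per cell differing by more than
    ``abs_tolerance`` (lane, probe, ours, theirs, difference); an empty frame
    means agreement.
    """
    orphan_lanes = sorted(
        set(processed.lane_ids) ^ set(reference.lane_ids)
    )
    orphan_probes = sorted(set(processed.probe_ids) ^ set(reference.probe_ids))
    if orphan_lanes or orphan_probes:
        raise ValidationError(
            f"unalignable ids: lanes {orphan_lanes}, probes {orphan_probes}"
        )
    ours = processed.values.astype(float)
    theirs = reference.values.astype(float).loc[ours.index, ours.columns]
    diff = ours - theirs
    mask = diff.abs() > abs_tolerance
    rows = [
        {
            "lane": ln,
            "probe": pr,
            "ours": float(ours.at[ln, pr]),
            "theirs": float(theirs.at[ln, pr]),
            "difference": float(diff.at[ln, pr]),
        }
        for ln in ours.index
        for pr in ours.columns
        if bool(mask.at[ln, pr])
    ]
    return pd.DataFrame(rows, columns=["lane", "probe", "ours", "theirs", "difference"])
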