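"""Pre- and post-hybridisation quality control.

Per-lane metrics: imaging QC (fraction of fields of view successfully
imaged, minimum 0.75), binding density (scanner image-saturation readout,
acceptable 0.1-2.25), positive-control linearity (squared Pearson correlation
of log2 counts vs the known 128-0.125 fM titration, minimum 0.95) and the
limit-of-detection check (a designated low-concentration positive probe must
exceed mean + 2 SD of the negative controls).  Ligation and spike-in probes
are checked against the identical negative-control statistic.  A Cq-based
haemolysis ratio (miR-23a vs erythrocyte-specific miR-451a) and a post-hoc
contamination check over the workflow consensus round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats as sps

from .codeset import CountMatrix, LaneMetadata, ProbeClass, ValidationError

if TYPE_CHECKING:  # circular only for typing
    from .workflows import ConsensusTable

__all__ = [
    "QcThresholds",
    "QcReport",
    "imaging_qc",
    "binding_density_qc",
    "positive_linearity_qc",
    "limit_of_detection_qc",
    "ligation_and_spikein_qc",
    "hemolysis_ratio",
    "contamination_check",
    "run_qc",
]


@dataclass(frozen=True)
class QcThresholds:
    """Acceptance bands for the per-lane QC metrics (vendor conventions)."""

    imaging_min_fraction: float = 0.75
    binding_density_range: tuple[float, float] = (0.1, 2.25)
    linearity_min_r2: float = 0.95
    lod_sd_multiplier: float = 2.0
    hemolysis_delta_cq_max: float = 5.0
    sd_ddof: int = 1  # sample SD for the negative-control statistic
    log_offset: float = 0.5  # added to counts before log2 in linearity QC

    def __post_init__(self) -> None:
        if not 0.0 <= self.imaging_min_fraction <= 1.0:
            raise ValidationError("imaging_min_fraction must be in [0, 1]")
        low, high = self.binding_density_range
        if not low < high:
            raise ValidationError("binding_density_range must be (low, high)")


@dataclass
class QcReport:
    """Per-lane metric values and pass/fail flags.

    ``metrics`` has one row per lane; flag columns hold True/False or pandas
    NA when a metric was not evaluable (missing scanner metadata).  The
    overall flag is True only when every evaluable metric passed in every
    lane and nothing was missing.
    """

    metrics: pd.DataFrame
    spikein_detected_lanes: pd.Series
    thresholds: QcThresholds

    @property
    def lane_pass(self) -> pd.Series:
        flags = self.metrics.filter(like="_pass")
        return flags.fillna(False).all(axis=1)

    @property
    def overall_pass(self) -> bool:
        flags = self.metrics.filter(like="_pass")
        return bool(flags.notna().all().all() and flags.fillna(False).all().all())

    def to_frame(self) -> pd.DataFrame:
        return self.metrics.copy()


def imaging_qc(
    lane: LaneMetadata, thresholds: QcThresholds = QcThresholds()
) -> tuple[Optional[float], Optional[bool]]:
    """Fraction of attempted fields of view that were imaged, and pass flag.

    Missing FOV metadata is reported as not-evaluable (None), not as failure.
    """
    if lane.fov_counted is None or lane.fov_attempted is None:
        return None, None
    fraction = lane.fov_counted / lane.fov_attempted
    return fraction, fraction >= thresholds.imaging_min_fraction


def binding_density_qc(
    lane: LaneMetadata, thresholds: QcThresholds = QcThresholds()
) -> Optional[bool]:
    """Inclusive range check on the scanner's binding-density readout."""
    if lane.binding_density is None:
        return None
    low, high = thresholds.binding_density_range
    return low <= lane.binding_density <= high


def positive_linearity_qc(
    matrix: CountMatrix, thresholds: QcThresholds = QcThresholds()
) -> pd.DataFrame:
    """Per-lane r^2 of log2(count + offset) vs log2(concentration).

    A lane whose positive counts carry no variance has an undefined
    correlation; it is reported as r2 = 0 and fails.
    """
    positives = matrix.subset_by_class(ProbeClass.POSITIVE)
    if positives.n_probes < 3:
        raise ValidationError("need >=3 positive probes with concentrations")
    concs = np.array([p.concentration_fM for p in positives.probes], dtype=float)
    if np.ptp(concs) == 0:
        raise ValidationError("positive-control concentrations have zero variance")
    x = np.log2(concs)
    rows = {}
    for ln in positives.lane_ids:
        y = np.log2(positives.values.loc[ln].to_numpy(dtype=float) + thresholds.log_offset)
        if np.ptp(y) == 0:
            r2 = 0.0
        else:
            r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        rows[ln] = {"r2": r2, "pass": r2 >= thresholds.linearity_min_r2}
    return pd.DataFrame.from_dict(rows, orient="index")


def _negative_threshold(matrix: CountMatrix, thresholds: QcThresholds) -> pd.Series:
    """mean + multiplier*sd of negative controls, per lane.

    Shared by the limit-of-detection and ligation/spike-in checks (the
    identical statistic by design).
    """
    negatives = matrix.subset_by_class(ProbeClass.NEGATIVE)
    if negatives.n_probes < 2:
        raise ValidationError("need at least 2 negative-control probes")
    vals = negatives.values.astype(float)
    return vals.mean(axis=1) + thresholds.lod_sd_multiplier * vals.std(
        axis=1, ddof=thresholds.sd_ddof
    )


def limit_of_detection_qc(
    matrix: CountMatrix,
    lod_probe_id: str,
    thresholds: QcThresholds = QcThresholds(),
) -> pd.Series:
    """Per-lane pass: the designated probe's raw count must exceed the
    negative-control mean + k*SD.  The probe is a parameter because codesets
    differ in which positive-titration point is nominated."""
    if lod_probe_id not in matrix.values.columns:
        raise ValidationError(f"LOD probe {lod_probe_id!r} absent from codeset")
    cutoff = _negative_threshold(matrix, thresholds)
    passed = matrix.values[lod_probe_id].astype(float) > cutoff
    passed.name = "lod_pass"
    return passed


def ligation_and_spikein_qc(
    matrix: CountMatrix, thresholds: QcThresholds = QcThresholds()
) -> tuple[pd.DataFrame, pd.Series]:
    """Detection grid for ligation and spike-in probes plus per-spike-in
    tallies of detected lanes.

    Detected means raw count > mean + k*SD of that lane's negatives -- the
    same statistic as the limit-of-detection check.
    """
    classes = matrix.classes_present()
    probe_ids: list[str] = []
    if ProbeClass.LIGATION in classes:
        probe_ids += matrix.subset_by_class(ProbeClass.LIGATION).probe_ids
    if ProbeClass.SPIKEIN in classes:
        probe_ids += matrix.subset_by_class(ProbeClass.SPIKEIN).probe_ids
    if not probe_ids:
        raise ValidationError("no ligation or spike-in probes in codeset")
    cutoff = _negative_threshold(matrix, thresholds)
    detected = matrix.values[probe_ids].astype(float).gt(cutoff, axis=0)
    spike_ids = [
        p.probe_id for p in matrix.probes if p.probe_class is ProbeClass.SPIKEIN
    ]
    tallies = detected[spike_ids].sum(axis=0) if spike_ids else pd.Series(dtype=int)
    tallies.name = "detected_lanes"
    return detected, tallies


def hemolysis_ratio(
    cq_23a: float, cq_451a: float, thresholds: QcThresholds = QcThresholds()
) -> tuple[float, float, bool]:
    """Blondal-style haemolysis check from two Cq values.

    delta = Cq(miR-23a) - Cq(miR-451a); because lower Cq means more template,
    a large positive delta means the erythrocyte marker dominates.  Both the
    cycle difference and its fold equivalent 2^delta are returned; the flag
    trips when delta exceeds the threshold (default 5 cycles).
    """
    delta = float(cq_23a) - float(cq_451a)
    return delta, float(2.0**delta), delta > thresholds.hemolysis_delta_cq_max


def contamination_check(
    consensus: "ConsensusTable", marker_ids: Sequence[str]
) -> pd.DataFrame:
    """Post-hoc check: is any contamination marker significantly changed in
    any workflow of the consensus?  Markers absent from the codeset are
    skipped with an explicit note rather than failing the run."""
    rows = []
    for marker in marker_ids:
        if marker not in consensus.significance.index:
            rows.append(
                {
                    "marker": marker,
                    "significant_in_any_workflow": False,
                    "workflows": [],
                    "note": "marker not in codeset; skipped",
                }
            )
            continue
        row = consensus.significance.loc[marker]
        hits = [wf for wf in consensus.significance.columns if bool(row[wf])]
        rows.append(
            {
                "marker": marker,
                "significant_in_any_workflow": bool(hits),
                "workflows": hits,
                "note": "",
            }
        )
    return pd.DataFrame(rows).set_index("marker") if rows else pd.DataFrame(
        columns=["significant_in_any_workflow", "workflows", "note"]
    )


def run_qc(
    matrix: CountMatrix,
    thresholds: QcThresholds = QcThresholds(),
    lod_probe_id: Optional[str] = None,
) -> QcReport:
    """All per-lane QC metrics in one report.

    ``lod_probe_id`` defaults to the positive probe closest to 0.5 fM.
    """
    if lod_probe_id is None:
        positives = matrix.subset_by_class(ProbeClass.POSITIVE)
        lod_probe_id = min(
            positives.probes, key=lambda p: abs(p.concentration_fM - 0.5)
        ).probe_id
    linearity = positive_linearity_qc(matrix, thresholds)
    lod = limit_of_detection_qc(matrix, lod_probe_id, thresholds)
    try:
        _, spike_tallies = ligation_and_spikein_qc(matrix, thresholds)
    except ValidationError:
        spike_tallies = pd.Series(dtype=int, name="detected_lanes")
    rows = {}
    for lane in matrix.lanes:
        fraction, img_pass = imaging_qc(lane, thresholds)
        bd_pass = binding_density_qc(lane, thresholds)
        rows[lane.lane_id] = {
            "imaging_fraction": fraction if fraction is not None else pd.NA,
            "imaging_pass": img_pass if img_pass is not None else pd.NA,
            "binding_density": lane.binding_density
            if lane.binding_density is not None
            else pd.NA,
            "binding_density_pass": bd_pass if bd_pass is not None else pd.NA,
            "linearity_r2": linearity.at[lane.lane_id, "r2"],
            "linearity_pass": bool(linearity.at[lane.lane_id, "pass"]),
            "lod_pass": bool(lod[lane.lane_id]),
        }
    metrics = pd.DataFrame.from_dict(rows, orient="index")
    return QcReport(metrics=metrics, spikein_detected_lanes=spike_tallies, thresholds=thresholds)
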