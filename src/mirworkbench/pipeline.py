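"""End-to-end pipeline: QC, normaliser selection, all workflows, consensus,
detection curves, PCA, optional qPCR validation and reference diffing.

Every run echoes its effective configuration into the output directory and
writes a manifest listing each artefact with a checksum, so every number in
every report is reproducible from the echoed config plus the inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .codeset import CountMatrix, ValidationError
from .io import read_counts, write_counts
from .preprocess import NormalizerSet, select_normfinder_normalizers, select_total_rna_normalizers
from .qc import QcThresholds, contamination_check, run_qc
from .qpcr import CqTable, test_target
from .simulate import HEMOLYSIS_MARKER, PLATELET_MARKER
from .workflows import (
    ConsensusTable,
    WorkflowOptions,
    compare_to_reference,
    consensus_table,
    detection_curve,
    enumerate_workflows,
    pca_summary,
    run_all_workflows,
)

logger = logging.getLogger("mirworkbench")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "render_consensus_report"]


@dataclass
class RunConfig:
    """Everything a run needs; serialisable to/from one YAML document."""

    counts_path: str
    lane_metadata_path: Optional[str] = None
    cq_table_path: Optional[str] = None
    reference_export_path: Optional[str] = None
    output_dir: str = "mirworkbench_out"
    qc: QcThresholds = field(default_factory=QcThresholds)
    options: WorkflowOptions = field(default_factory=WorkflowOptions)
    n_normfinder: int = 5
    min_frequency: int = 2
    min_mean_count: Optional[float] = None
    lod_probe_id: Optional[str] = None
    contamination_markers: tuple[str, ...] = (HEMOLYSIS_MARKER, PLATELET_MARKER)
    seed: int = 0

    def to_yaml(self) -> str:
        def detuple(obj):
            if isinstance(obj, tuple):
                return [detuple(x) for x in obj]
            if isinstance(obj, list):
                return [detuple(x) for x in obj]
            if isinstance(obj, dict):
                return {k: detuple(v) for k, v in obj.items()}
            return obj

        payload = detuple(dataclasses.asdict(self))
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        payload = yaml.safe_load(text) or {}
        if "qc" in payload and isinstance(payload["qc"], dict):
            qc = dict(payload["qc"])
            if isinstance(qc.get("binding_density_range"), list):
                qc["binding_density_range"] = tuple(qc["binding_density_range"])
            payload["qc"] = QcThresholds(**qc)
        if "options" in payload and isinstance(payload["options"], dict):
            payload["options"] = WorkflowOptions(**payload["options"])
        if isinstance(payload.get("contamination_markers"), list):
            payload["contamination_markers"] = tuple(payload["contamination_markers"])
        return cls(**payload)


@dataclass
class PipelineResult:
    output_dir: Path
    qc_passed: bool
    consensus: ConsensusTable
    manifest: dict[str, str]


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; artefacts land in ``config.output_dir``.

    QC failure does not abort the run -- the QC report is always written and
    the result carries ``qc_passed`` so callers (e.g. the CLI) can exit
    non-zero.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.yaml").write_text(config.to_yaml(), encoding="utf-8")

    raw = read_counts(config.counts_path, "csv", config.lane_metadata_path)
    logger.info("loaded %d lanes x %d probes", raw.n_lanes, raw.n_probes)

    qc_report = run_qc(raw, config.qc, lod_probe_id=config.lod_probe_id)
    qc_report.to_frame().to_csv(out / "qc_report.csv")
    (out / "qc_report.json").write_text(
        json.dumps(
            {
                "overall_pass": qc_report.overall_pass,
                "lane_pass": {k: bool(v) for k, v in qc_report.lane_pass.items()},
                "spikein_detected_lanes": {
                    k: int(v) for k, v in qc_report.spikein_detected_lanes.items()
                },
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    logger.info("QC overall pass: %s", qc_report.overall_pass)

    total_rna = select_total_rna_normalizers(
        raw, min_mean_count=config.min_mean_count, sd_ddof=config.options.sd_ddof
    )
    normfinder = select_normfinder_normalizers(
        total_rna, raw, n_select=min(config.n_normfinder, len(total_rna.probe_ids))
    )
    sets = {"total_rna": total_rna, "normfinder": normfinder}
    (out / "normalizers.json").write_text(
        json.dumps(
            {
                "total_rna": total_rna.probe_ids,
                "normfinder": normfinder.probe_ids,
                "normfinder_stability": (
                    {}
                    if normfinder.stability_values is None
                    else {k: float(v) for k, v in normfinder.stability_values.items()}
                ),
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    logger.info(
        "normalisers: %d total-RNA pool, %d NormFinder",
        len(total_rna.probe_ids),
        len(normfinder.probe_ids),
    )

    curve = detection_curve(raw, threshold=config.options.detection_threshold)
    curve_df = curve.counts.rename_axis("min_lanes").to_frame()
    curve_df.loc[0] = curve.never_detected  # k=0 row records never-detected
    curve_df.sort_index().to_csv(out / "detection_curve_raw.csv")

    processed, de_results = run_all_workflows(raw, sets, config.options)
    workflows_dir = out / "workflows"
    workflows_dir.mkdir(exist_ok=True)
    pca_rows = []
    for wf in enumerate_workflows():
        write_counts(processed[wf.id], workflows_dir / f"workflow_{wf.id:02d}_counts.csv")
        de_results[wf.id].table.to_csv(workflows_dir / f"workflow_{wf.id:02d}_de.csv")
        summary = pca_summary(processed[wf.id])
        for g, disp in summary.group_dispersion.items():
            pca_rows.append({"workflow": wf.id, "group": g, "dispersion": disp})
        logger.info("workflow %s done", wf.label)
    pd.DataFrame(pca_rows).to_csv(out / "pca_group_dispersion.csv", index=False)

    consensus = consensus_table(de_results, min_frequency=config.min_frequency)
    (out / "consensus.csv").write_text(
        render_consensus_report(consensus), encoding="utf-8"
    )

    contamination = contamination_check(consensus, list(config.contamination_markers))
    contamination.to_csv(out / "contamination_check.csv")

    if config.cq_table_path:
        cq = _read_cq_csv(Path(config.cq_table_path))
        rows = []
        for target in cq.target_assays():
            res = test_target(cq, target)
            for scale, sres in res.by_scale.items():
                rows.append(
                    {
                        "target": target,
                        "scale": scale,
                        "fold_mean": res.fold_mean,
                        "fold_sd": res.fold_sd,
                        "test_used": sres.test_used,
                        "p_two_sided": sres.test.p_two_sided,
                        "p_one_sided": sres.test.p_one_sided,
                        "direction": res.direction,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "qpcr_results.csv", index=False)

    if config.reference_export_path:
        reference = read_counts(config.reference_export_path, "csv")
        for wf_id, matrix in processed.items():
            try:
                diff = compare_to_reference(matrix, reference)
            except ValidationError as exc:
                logger.warning("workflow %d diff skipped: %s", wf_id, exc)
                continue
            diff.to_csv(workflows_dir / f"workflow_{wf_id:02d}_diff.csv", index=False)

    manifest = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return PipelineResult(
        output_dir=out,
        qc_passed=qc_report.overall_pass,
        consensus=consensus,
        manifest=manifest,
    )


def render_consensus_report(consensus: ConsensusTable) -> str:
    """Consensus grid as CSV text: one row per probe ranked by frequency,
    an X per workflow that called it, plus frequency and direction columns."""
    ids = list(consensus.significance.columns)
    header = ["probe", "frequency", "direction"] + [str(i) for i in ids]
    lines = [",".join(header)]
    ranked = consensus.ranked()
    for probe in ranked.index:
        if ranked.at[probe, "frequency"] == 0:
            continue
        marks = [
            "X" if bool(consensus.significance.at[probe, wf]) else "" for wf in ids
        ]
        lines.append(
            ",".join(
                [probe, str(int(ranked.at[probe, "frequency"])), ranked.at[probe, "direction"]]
                + marks
            )
        )
    return "\n".join(lines) + "\n"


def _read_cq_csv(path: Path) -> CqTable:
    """CqTable CSV: first column sample ids, a ``group`` column, then one
    column per assay; assay roles come from a ``#role:`` header block of
    ``# role: <assay> = <role>`` comment lines."""
    roles = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("# role:"):
            spec = line[len("# role:"):].strip()
            assay, role = [s.strip() for s in spec.split("=", 1)]
            roles[assay] = role
        else:
            body.append(line)
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(body)), index_col=0)
    groups = frame.pop("group")
    return CqTable(values=frame, groups=groups, roles=roles)
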