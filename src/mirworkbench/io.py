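"""Reading and writing count matrices.

Two dialects are supported:

* ``csv`` -- the canonical interchange format: a UTF-8 CSV with header
  ``probe_id,probe_class,concentration_fM,<lane_id_1>,...`` and one row per
  probe, plus a YAML sidecar with per-lane metadata (lane_id, group,
  fov_counted, fov_attempted, binding_density).
* ``rcc_collection`` -- a directory of per-lane NanoString RCC files
  (read-only, best effort: the documented ``<Lane_Attributes>`` and
  ``<Code_Summary>`` sections are parsed, unknown sections ignored).
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .codeset import (
    CountMatrix,
    LaneMetadata,
    ParseError,
    ProbeClass,
    ProbeDefinition,
    Stage,
    ValidationError,
)

__all__ = ["read_counts", "write_counts", "lane_sidecar_path"]

_META_COLUMNS = ["probe_id", "probe_class", "concentration_fM"]


def lane_sidecar_path(counts_path: Path | str) -> Path:
    p = Path(counts_path)
    return p.with_suffix(".lanes.yaml")


def read_counts(
    path: Path | str,
    dialect: str = "csv",
    lane_metadata_path: Optional[Path | str] = None,
    stage: Stage | str | None = None,
) -> CountMatrix:
    """Read a count table into a :class:`CountMatrix`.

    ``lane_metadata_path`` defaults to ``<path>.lanes.yaml`` for the CSV
    dialect; missing sidecars yield lanes with marked-missing metadata.
    ``stage=None`` takes the stage recorded in the sidecar (raw if absent).
    """
    if dialect == "csv":
        return _read_csv(
            Path(path), lane_metadata_path, None if stage is None else Stage(stage)
        )
    if dialect == "rcc_collection":
        return _read_rcc_collection(Path(path), lane_metadata_path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv(
    path: Path, lane_metadata_path: Optional[Path | str], stage: Optional[Stage]
) -> CountMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    for i, want in enumerate(_META_COLUMNS):
        if i >= len(header) or header[i] != want:
            got = header[i] if i < len(header) else "<missing>"
            raise ParseError(
                f"{path}: malformed header: expected column {i + 1} to be "
                f"{want!r}, got {got!r}"
            )
    lane_ids = header[len(_META_COLUMNS):]
    if len(set(lane_ids)) != len(lane_ids):
        raise ParseError(f"{path}: duplicate lane columns in header")

    probes: list[ProbeDefinition] = []
    data: dict[str, list[float]] = {ln: [] for ln in lane_ids}
    for irow, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise ParseError(f"{path}: row {irow} has {len(row)} fields, expected {len(header)}")
        probe_id = row[0].strip()
        probe_class = ProbeClass.parse(row[1])
        conc_text = row[2].strip()
        conc = float(conc_text) if conc_text else None
        probes.append(ProbeDefinition(probe_id, probe_class, conc))
        for ln, cell in zip(lane_ids, row[len(_META_COLUMNS):]):
            try:
                value = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric count {cell!r} at lane {ln!r}, "
                    f"probe {probe_id!r}"
                )
            if value < 0:
                raise ValidationError(
                    f"{path}: negative count {cell!r} at lane {ln!r}, "
                    f"probe {probe_id!r}"
                )
            data[ln].append(value)

    lanes, sidecar_stage = _read_lane_metadata(path, lane_metadata_path, lane_ids)
    if stage is None:
        stage = sidecar_stage or Stage.RAW
    values = pd.DataFrame(
        {p.probe_id: [data[ln][i] for ln in lane_ids] for i, p in enumerate(probes)},
        index=lane_ids,
    )
    # transpose built probe-major; re-lay out as lanes x probes
    values = values.loc[lane_ids, [p.probe_id for p in probes]]
    return CountMatrix(lanes=lanes, probes=probes, values=values, stage=stage)


def _read_lane_metadata(
    counts_path: Path,
    lane_metadata_path: Optional[Path | str],
    lane_ids: Sequence[str],
) -> tuple[list[LaneMetadata], Optional[Stage]]:
    sidecar = (
        Path(lane_metadata_path)
        if lane_metadata_path is not None
        else lane_sidecar_path(counts_path)
    )
    meta: dict[str, dict] = {}
    sidecar_stage: Optional[Stage] = None
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or []
        if isinstance(loaded, dict):
            if loaded.get("stage"):
                sidecar_stage = Stage(loaded["stage"])
            loaded = loaded.get("lanes", [])
        for entry in loaded:
            meta[str(entry["lane_id"])] = entry
    lanes = []
    for ln in lane_ids:
        entry = meta.get(ln, {})
        lanes.append(
            LaneMetadata(
                lane_id=ln,
                group=entry.get("group"),
                fov_counted=_maybe_int(entry.get("fov_counted")),
                fov_attempted=_maybe_int(entry.get("fov_attempted")),
                binding_density=_maybe_float(entry.get("binding_density")),
            )
        )
    return lanes, sidecar_stage


def _maybe_int(x) -> Optional[int]:
    return None if x is None else int(x)


def _maybe_float(x) -> Optional[float]:
    return None if x is None else float(x)


def write_counts(
    matrix: CountMatrix,
    path: Path | str,
    lane_metadata_path: Optional[Path | str] = None,
) -> Path:
    """Write the CSV dialect (plus YAML lane sidecar); round-trips with
    :func:`read_counts` bit-identically for raw counts and to full float
    precision (repr round-trip) for processed stages."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_META_COLUMNS + matrix.lane_ids)
        for p in matrix.probes:
            conc = "" if p.concentration_fM is None else repr(p.concentration_fM)
            row = [p.probe_id, p.probe_class.value, conc]
            for ln in matrix.lane_ids:
                v = matrix.values.at[ln, p.probe_id]
                row.append(str(int(v)) if matrix.stage is Stage.RAW else repr(float(v)))
            writer.writerow(row)
    sidecar = (
        Path(lane_metadata_path)
        if lane_metadata_path is not None
        else lane_sidecar_path(path)
    )
    entries = []
    for ln in matrix.lanes:
        entry: dict = {"lane_id": ln.lane_id}
        if ln.group is not None:
            entry["group"] = ln.group
        if ln.fov_counted is not None:
            entry["fov_counted"] = ln.fov_counted
        if ln.fov_attempted is not None:
            entry["fov_attempted"] = ln.fov_attempted
        if ln.binding_density is not None:
            entry["binding_density"] = float(ln.binding_density)
        entries.append(entry)
    with open(sidecar, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"stage": matrix.stage.value, "lanes": entries}, fh, sort_keys=False
        )
    return path


# -- RCC ----------------------------------------------------------------------

_RCC_CLASS_MAP = {
    "endogenous": ProbeClass.ENDOGENOUS,
    "endogenous1": ProbeClass.ENDOGENOUS,
    "positive": ProbeClass.POSITIVE,
    "negative": ProbeClass.NEGATIVE,
    "ligation": ProbeClass.LIGATION,
    "spikein": ProbeClass.SPIKEIN,
    "spikeincontrol": ProbeClass.SPIKEIN,
    "housekeeping": ProbeClass.HOUSEKEEPING,
}

# Positive controls follow the standard 4-fold titration; concentrations are
# recovered from the conventional probe-name suffix when present.
_POS_CONCENTRATIONS = {
    "a": 128.0, "b": 32.0, "c": 8.0, "d": 2.0, "e": 0.5, "f": 0.125,
}


def _read_rcc_collection(
    directory: Path, lane_metadata_path: Optional[Path | str]
) -> CountMatrix:
    if not directory.is_dir():
        raise FileNotFoundError(directory)
    files = sorted(directory.glob("*.RCC")) + sorted(directory.glob("*.rcc"))
    if not files:
        raise ParseError(f"{directory}: no RCC files found")
    per_lane: list[tuple[LaneMetadata, dict[str, tuple[ProbeClass, Optional[float], int]]]] = []
    for f in files:
        per_lane.append(_read_rcc_file(f))
    first_probes = list(per_lane[0][1].keys())
    for meta, table in per_lane[1:]:
        if list(table.keys()) != first_probes:
            raise ValidationError(
                f"RCC lane {meta.lane_id!r}: probe set differs from first lane"
            )
    probes = [
        ProbeDefinition(pid, cls, conc)
        for pid, (cls, conc, _) in per_lane[0][1].items()
    ]
    lanes = [meta for meta, _ in per_lane]
    values = pd.DataFrame(
        [[table[p.probe_id][2] for p in probes] for _, table in per_lane],
        index=[ln.lane_id for ln in lanes],
        columns=[p.probe_id for p in probes],
    )
    matrix = CountMatrix(lanes=lanes, probes=probes, values=values, stage=Stage.RAW)
    if lane_metadata_path is not None:
        sidecar_lanes, _ = _read_lane_metadata(
            Path(lane_metadata_path), lane_metadata_path, matrix.lane_ids
        )
        matrix = CountMatrix(
            lanes=sidecar_lanes, probes=probes, values=values, stage=Stage.RAW
        )
    return matrix


def _read_rcc_file(path: Path):
    section = None
    attrs: dict[str, str] = {}
    counts: dict[str, tuple[ProbeClass, Optional[float], int]] = {}
    with open(path, encoding="utf-8", errors="replace") as fh:
        for raw_line in fh:
            line = raw_line.strip()
            if not line:
                continue
            if line.startswith("<") and line.endswith(">"):
                tag = line.strip("<>").lower()
                section = None if tag.startswith("/") else tag
                continue
            if section == "lane_attributes":
                parts = line.split(",", 1)
                if len(parts) == 2:
                    attrs[parts[0].strip().lower()] = parts[1].strip()
            elif section == "code_summary":
                parts = [c.strip() for c in line.split(",")]
                if parts[0].lower() == "codeclass":
                    continue
                if len(parts) < 4:
                    raise ParseError(f"{path}: malformed Code_Summary line {line!r}")
                cls_key = parts[0].lower()
                if cls_key.startswith("endogenous"):
                    cls_key = "endogenous"
                if cls_key not in _RCC_CLASS_MAP:
                    continue  # unknown probe classes are skipped, not coerced
                cls = _RCC_CLASS_MAP[cls_key]
                name = parts[1]
                conc = None
                if cls is ProbeClass.POSITIVE:
                    conc = _positive_concentration(name)
                try:
                    count = int(float(parts[3]))
                except ValueError:
                    raise ValidationError(
                        f"{path}: non-numeric count {parts[3]!r} for probe {name!r}"
                    )
                if name in counts:
                    raise ValidationError(f"{path}: duplicate probe {name!r}")
                counts[name] = (cls, conc, count)
    lane_id = attrs.get("id") or path.stem
    meta = LaneMetadata(
        lane_id=lane_id,
        group=None,
        fov_counted=_maybe_int(_num_or_none(attrs.get("fovcounted"))),
        fov_attempted=_maybe_int(_num_or_none(attrs.get("fovcount"))),
        binding_density=_num_or_none(attrs.get("bindingdensity")),
    )
    if not counts:
        raise ParseError(f"{path}: no Code_Summary section found")
    return meta, counts


def _positive_concentration(name: str) -> float:
    # names like POS_A(128), POS_F(0.125) or POS_E
    if "(" in name and name.endswith(")"):
        try:
            return float(name[name.index("(") + 1 : -1])
        except ValueError:
            pass
    tail = name.split("_")[-1].split("(")[0].strip().lower()
    if tail in _POS_CONCENTRATIONS:
        return _POS_CONCENTRATIONS[tail]
    raise ParseError(f"cannot infer concentration for positive probe {name!r}")


def _num_or_none(text: Optional[str]) -> Optional[float]:
    if text is None or text == "":
        return None
    try:
        value = float(text)
    except ValueError:
        return None
    return value if math.isfinite(value) else None
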