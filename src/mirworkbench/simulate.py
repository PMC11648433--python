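"""Synthetic nCounter experiments and qPCR Cq tables with known ground truth.

The generator emulates the structure of a two-group plasma-miRNA screening
run: two groups of lanes on one cartridge, per-lane capture-efficiency
scaling, a codeset of endogenous probes dominated by low-abundance targets
sitting near background, a small cohort of stable "housekeeping-like"
endogenous probes (the normaliser pool analogue), planted fold changes on a
subset of probes, low-count negative controls, a six-point positive-control
titration, ligation controls, exogenous spike-ins near the detection limit,
and optional red-blood-cell (miR-451 analogue) or platelet (miR-126 analogue)
contamination signals.

Endogenous counts are negative binomial (biological overdispersion on top of
counting noise); control probes are Poisson (technical-only variance).
Everything is deterministic under the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .codeset import (
    CountMatrix,
    LaneMetadata,
    ProbeClass,
    ProbeDefinition,
    Stage,
    ValidationError,
)
from .qpcr import AssayRole, CqTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "HEMOLYSIS_MARKER",
    "PLATELET_MARKER",
    "simulate_experiment",
    "inject_contamination",
    "simulate_cq_table",
]

HEMOLYSIS_MARKER = "mir-451"
PLATELET_MARKER = "mir-126"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic nCounter run.

    Defaults mirror a 6 vs 6 rat-plasma design on a 420-probe miRNA codeset:
    8 negative controls with mean ~5 counts (so background corrections bite at
    realistic low-expression levels), positives at the standard 128..0.125 fM
    titration, a 36-probe stable cohort, and 10 planted 4-fold changes on
    probes at biomarker-like abundance.
    """

    n_lanes_per_group: int = 6
    n_endogenous: int = 420
    lane_effect_sigma: float = 0.15  # SD of log lane capture efficiency
    baseline_log_mean: float = math.log(8.0)  # most plasma miRNAs sit near background
    baseline_log_sd: float = 1.6
    dispersion: float = 0.1  # NB: var = mu + dispersion * mu^2
    neg_control_mean: float = 5.0
    n_negative: int = 8
    neg_nonspecific_per_lane: float = 1.0  # lane-proportional non-specific term
    pos_control_concentrations_fM: Sequence[float] = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)
    pos_control_counts_per_fM: float = 200.0
    n_de_probes: int = 10
    de_fold_changes: Sequence[float] = (4.0,)
    de_baseline_log_mean: float = math.log(200.0)
    de_baseline_log_sd: float = 0.5
    n_stable_probes: int = 36
    stable_baseline_log_mean: float = math.log(100.0)
    stable_baseline_log_sd: float = 0.8
    stable_dispersion: float = 0.005
    n_ligation: int = 2
    ligation_mean: float = 600.0
    n_spikein: int = 5
    spikein_mean: float = 8.0
    n_housekeeping: int = 5
    housekeeping_mean: float = 300.0
    hemolysis_lanes: Sequence[str] = ()
    hemolysis_magnitude: float = 10.0
    platelet_lanes: Sequence[str] = ()
    platelet_magnitude: float = 10.0
    # marker analogues are well-expressed in plasma (the red-cell marker is
    # abundant enough to enter normaliser pools), so they get fixed baselines
    hemolysis_marker_baseline: float = 150.0
    platelet_marker_baseline: float = 60.0
    fov_attempted: int = 280
    fov_counted: int = 277
    binding_density: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lanes_per_group < 1:
            raise ValidationError("need at least 1 lane per group")
        if self.n_endogenous < 1:
            raise ValidationError("need at least 1 endogenous probe")
        if self.n_de_probes > self.n_endogenous:
            raise ValidationError("n_de_probes exceeds n_endogenous")
        if self.n_stable_probes + self.n_de_probes + 2 > self.n_endogenous:
            raise ValidationError("stable + DE cohorts do not fit in the codeset")
        if any(f <= 0 for f in self.de_fold_changes):
            raise ValidationError("fold changes must be positive")
        if self.dispersion <= 0 or self.stable_dispersion <= 0:
            raise ValidationError("dispersion must be positive")


@dataclass
class GroundTruth:
    """What was planted: recovery target for every downstream stage."""

    lane_effects: pd.Series  # per-lane multiplicative capture efficiency
    de_probes: Mapping[str, float]  # probe_id -> true fold (group B / group A)
    stable_probe_ids: list[str]
    contaminated_lanes: dict[str, list[str]]  # kind -> lane ids
    marker_probes: Mapping[str, str] = field(
        default_factory=lambda: {
            "hemolysis": HEMOLYSIS_MARKER,
            "platelet": PLATELET_MARKER,
        }
    )

    def de_direction(self, probe_id: str) -> str:
        fold = self.de_probes[probe_id]
        return "up_in_b" if fold > 1 else ("up_in_a" if fold < 1 else "none")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion*mu^2 (Poisson limit)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-9:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_experiment(config: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw one synthetic experiment; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_lanes_per_group
    lane_ids = [f"A{i+1}" for i in range(n)] + [f"B{i+1}" for i in range(n)]
    group_of = {ln: ("A" if ln.startswith("A") else "B") for ln in lane_ids}
    lane_effects = pd.Series(
        np.exp(rng.normal(0.0, config.lane_effect_sigma, size=2 * n)), index=lane_ids
    )

    # --- codeset layout -------------------------------------------------------
    n_generic = config.n_endogenous - 2  # two named marker analogues at the end
    endo_ids = [f"mir-{i+1:04d}" for i in range(n_generic)]
    endo_ids += [HEMOLYSIS_MARKER, PLATELET_MARKER]
    stable_ids = endo_ids[:config.n_stable_probes]
    de_ids = endo_ids[config.n_stable_probes:config.n_stable_probes + config.n_de_probes]

    baselines = pd.Series(
        np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, len(endo_ids))),
        index=endo_ids,
    )
    baselines[stable_ids] = np.exp(
        rng.normal(config.stable_baseline_log_mean, config.stable_baseline_log_sd, len(stable_ids))
    )
    baselines[de_ids] = np.exp(
        rng.normal(config.de_baseline_log_mean, config.de_baseline_log_sd, len(de_ids))
    )
    baselines[HEMOLYSIS_MARKER] = config.hemolysis_marker_baseline
    baselines[PLATELET_MARKER] = config.platelet_marker_baseline
    folds = pd.Series(1.0, index=endo_ids)
    de_truth: dict[str, float] = {}
    for i, pid in enumerate(de_ids):
        fc = config.de_fold_changes[i % len(config.de_fold_changes)]
        folds[pid] = fc
        de_truth[pid] = fc
    dispersions = pd.Series(config.dispersion, index=endo_ids)
    dispersions[stable_ids] = config.stable_dispersion

    probes: list[ProbeDefinition] = [
        ProbeDefinition(pid, ProbeClass.ENDOGENOUS) for pid in endo_ids
    ]
    probes += [
        ProbeDefinition(f"POS_{chr(ord('A') + i)}", ProbeClass.POSITIVE, conc)
        for i, conc in enumerate(config.pos_control_concentrations_fM)
    ]
    probes += [
        ProbeDefinition(f"NEG_{chr(ord('A') + i)}", ProbeClass.NEGATIVE)
        for i in range(config.n_negative)
    ]
    probes += [
        ProbeDefinition(f"LIG_{i+1}", ProbeClass.LIGATION) for i in range(config.n_ligation)
    ]
    probes += [
        ProbeDefinition(f"SPIKE_{i+1}", ProbeClass.SPIKEIN) for i in range(config.n_spikein)
    ]
    probes += [
        ProbeDefinition(f"HK_{i+1}", ProbeClass.HOUSEKEEPING)
        for i in range(config.n_housekeeping)
    ]

    # --- counts ---------------------------------------------------------------
    columns: dict[str, np.ndarray] = {}
    eff = lane_effects.to_numpy()
    is_b = np.array([group_of[ln] == "B" for ln in lane_ids])
    for pid in endo_ids:
        mu = eff * baselines[pid] * np.where(is_b, folds[pid], 1.0)
        columns[pid] = _nb_draw(rng, mu, float(dispersions[pid]))
    for p in probes:
        if p.probe_class is ProbeClass.POSITIVE:
            mu = eff * p.concentration_fM * config.pos_control_counts_per_fM
            columns[p.probe_id] = rng.poisson(mu)
        elif p.probe_class is ProbeClass.NEGATIVE:
            mu = config.neg_control_mean + config.neg_nonspecific_per_lane * eff
            columns[p.probe_id] = rng.poisson(mu)
        elif p.probe_class is ProbeClass.LIGATION:
            columns[p.probe_id] = rng.poisson(eff * config.ligation_mean)
        elif p.probe_class is ProbeClass.SPIKEIN:
            columns[p.probe_id] = rng.poisson(
                np.full(2 * n, config.spikein_mean)
            )
        elif p.probe_class is ProbeClass.HOUSEKEEPING:
            columns[p.probe_id] = _nb_draw(rng, eff * config.housekeeping_mean, 0.05)

    lanes = [
        LaneMetadata(
            lane_id=ln,
            group=group_of[ln],
            fov_counted=config.fov_counted,
            fov_attempted=config.fov_attempted,
            binding_density=config.binding_density,
        )
        for ln in lane_ids
    ]
    values = pd.DataFrame(
        {p.probe_id: columns[p.probe_id] for p in probes}, index=lane_ids
    )
    matrix = CountMatrix(lanes=lanes, probes=probes, values=values, stage=Stage.RAW)
    truth = GroundTruth(
        lane_effects=lane_effects,
        de_probes=de_truth,
        stable_probe_ids=list(stable_ids),
        contaminated_lanes={"hemolysis": [], "platelet": []},
    )
    if config.hemolysis_lanes:
        matrix, truth = inject_contamination(
            matrix, truth, "hemolysis", config.hemolysis_magnitude,
            lanes=config.hemolysis_lanes,
        )
    if config.platelet_lanes:
        matrix, truth = inject_contamination(
            matrix, truth, "platelet", config.platelet_magnitude,
            lanes=config.platelet_lanes,
        )
    return matrix, truth


def inject_contamination(
    matrix: CountMatrix,
    truth: GroundTruth,
    kind: str,
    magnitude: float,
    lanes: Optional[Sequence[str]] = None,
) -> tuple[CountMatrix, GroundTruth]:
    """Multiply the contamination-marker counts in the targeted lanes.

    ``kind`` is ``hemolysis`` (red-cell marker, miR-451 analogue) or
    ``platelet`` (miR-126 analogue); ``magnitude=1`` leaves the matrix
    unchanged.  Returns a new matrix and an updated ground truth.
    """
    if kind not in truth.marker_probes:
        raise ValidationError(f"unknown contamination kind {kind!r}")
    if magnitude <= 0:
        raise ValidationError("magnitude must be positive")
    marker = truth.marker_probes[kind]
    if marker not in matrix.values.columns:
        raise ValidationError(f"marker probe {marker!r} absent from codeset")
    target_lanes = list(lanes) if lanes is not None else list(
        truth.contaminated_lanes.get(kind, [])
    )
    missing = [ln for ln in target_lanes if ln not in matrix.values.index]
    if missing:
        raise ValidationError(f"unknown lanes {missing}")
    out = matrix.copy()
    scaled = out.values.loc[target_lanes, marker] * magnitude
    if out.stage is Stage.RAW:
        scaled = np.round(scaled).astype(int)
    out.values.loc[target_lanes, marker] = scaled
    new_truth = GroundTruth(
        lane_effects=truth.lane_effects,
        de_probes=dict(truth.de_probes),
        stable_probe_ids=list(truth.stable_probe_ids),
        contaminated_lanes={
            **{k: list(v) for k, v in truth.contaminated_lanes.items()},
            kind: sorted(set(truth.contaminated_lanes.get(kind, [])) | set(target_lanes)),
        },
        marker_probes=dict(truth.marker_probes),
    )
    return out, new_truth


def simulate_cq_table(
    n_per_group: int,
    targets: Sequence[tuple[str, float]],
    reference_assays: Sequence[str] = ("ref-20a", "ref-27b"),
    cq_noise_sd: float = 0.3,
    seed: int = 0,
    sample_shift_sd: float = 1.0,
    base_cq: float = 25.0,
) -> tuple[CqTable, dict]:
    """Synthetic qPCR plate: Cq = base - log2(expression) + shift + noise.

    The per-sample additive shift (pipetting / RT efficiency) hits every assay
    of a sample, so dCq is shift-invariant by construction.  ``targets`` is a
    list of (assay name, true fold in group B); reference assays have fold 1.
    """
    if len(reference_assays) < 2:
        raise ValidationError("need at least 2 reference assays")
    if n_per_group < 1:
        raise ValidationError("need at least 1 sample per group")
    rng = np.random.default_rng(seed)
    samples = [f"A{i+1}" for i in range(n_per_group)] + [
        f"B{i+1}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        ["A"] * n_per_group + ["B"] * n_per_group, index=samples, name="group"
    )
    shifts = pd.Series(rng.normal(0.0, sample_shift_sd, len(samples)), index=samples)
    roles: dict[str, AssayRole] = {a: AssayRole.REFERENCE for a in reference_assays}
    data: dict[str, np.ndarray] = {}
    is_b = groups.to_numpy() == "B"
    for j, ref in enumerate(reference_assays):
        base = base_cq - 2.0 + 0.5 * j  # references sit a little below targets
        data[ref] = base + shifts.to_numpy() + rng.normal(0, cq_noise_sd, len(samples))
    for j, (name, fold) in enumerate(targets):
        if fold <= 0:
            raise ValidationError(f"target {name!r}: fold must be positive")
        roles[name] = AssayRole.TARGET
        base = base_cq + 0.7 * j
        expr = np.where(is_b, fold, 1.0)
        data[name] = (
            base
            - np.log2(expr)
            + shifts.to_numpy()
            + rng.normal(0, cq_noise_sd, len(samples))
        )
    table = CqTable(
        values=pd.DataFrame(data, index=samples), groups=groups, roles=roles
    )
    truth = {
        "true_folds": {name: fold for name, fold in targets},
        "sample_shifts": shifts,
    }
    return table, truth
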