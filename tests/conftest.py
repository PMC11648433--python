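import numpy as np
import pandas as pd
import pytest

from mirworkbench import (
    CountMatrix,
    LaneMetadata,
    ProbeClass,
    ProbeDefinition,
    SimulationConfig,
    Stage,
    simulate_experiment,
)


def build_matrix(
    counts: dict[str, list[float]],
    classes: dict[str, str],
    groups: list[str] | None = None,
    concentrations: dict[str, float] | None = None,
    stage: Stage = Stage.RAW,
    lane_meta: dict[str, dict] | None = None,
) -> CountMatrix:
    """Hand-build a small CountMatrix from per-probe count lists."""
    concentrations = concentrations or {}
    n_lanes = len(next(iter(counts.values())))
    lane_ids = [f"L{i+1}" for i in range(n_lanes)]
    groups = groups or ["A"] * n_lanes
    lane_meta = lane_meta or {}
    lanes = [
        LaneMetadata(lane_id=ln, group=g, **lane_meta.get(ln, {}))
        for ln, g in zip(lane_ids, groups)
    ]
    probes = [
        ProbeDefinition(pid, ProbeClass.parse(cls), concentrations.get(pid))
        for pid, cls in classes.items()
    ]
    values = pd.DataFrame({pid: counts[pid] for pid in classes}, index=lane_ids)
    return CountMatrix(lanes=lanes, probes=probes, values=values, stage=stage)


@pytest.fixture
def small_matrix() -> CountMatrix:
    """3 lanes (A, A, B), two endogenous probes, positives, negatives, a
    ligation control and a spike-in."""
    return build_matrix(
        counts={
            "mir-a": [10, 12, 30],
            "mir-b": [5, 6, 4],
            "POS_A": [1280, 1280, 1280],
            "POS_B": [320, 320, 320],
            "POS_C": [80, 80, 80],
            "NEG_A": [2, 0, 3],
            "NEG_B": [4, 2, 1],
            "NEG_C": [0, 4, 2],
            "LIG_1": [200, 210, 190],
            "SPIKE_1": [3, 2, 4],
        },
        classes={
            "mir-a": "endogenous",
            "mir-b": "endogenous",
            "POS_A": "positive",
            "POS_B": "positive",
            "POS_C": "positive",
            "NEG_A": "negative",
            "NEG_B": "negative",
            "NEG_C": "negative",
            "LIG_1": "ligation",
            "SPIKE_1": "spikein",
        },
        groups=["A", "A", "B"],
        concentrations={"POS_A": 128.0, "POS_B": 32.0, "POS_C": 8.0},
        lane_meta={
            "L1": {"fov_counted": 99, "fov_attempted": 100, "binding_density": 0.14},
            "L2": {"fov_counted": 100, "fov_attempted": 100, "binding_density": 0.17},
            "L3": {"fov_counted": 98, "fov_attempted": 100, "binding_density": 0.15},
        },
    )


@pytest.fixture(scope="session")
def default_simulation():
    """One default-condition synthetic experiment shared across tests."""
    return simulate_experiment(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def simulated_pipeline(default_simulation):
    """Normaliser sets + all 14 workflow results for the shared simulation."""
    import warnings

    from mirworkbench import (
        consensus_table,
        run_all_workflows,
        select_normfinder_normalizers,
        select_total_rna_normalizers,
    )

    matrix, truth = default_simulation
    pool = select_total_rna_normalizers(matrix)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nf = select_normfinder_normalizers(pool, matrix, n_select=5)
    sets = {"total_rna": pool, "normfinder": nf}
    processed, de = run_all_workflows(matrix, sets)
    return {
        "matrix": matrix,
        "truth": truth,
        "sets": sets,
        "processed": processed,
        "de": de,
        "consensus": consensus_table(de),
    }
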