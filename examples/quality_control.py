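"""Post-hybridisation QC on a synthetic run, plus the Cq haemolysis check.

Prints the per-lane QC table (imaging fraction, binding density,
positive-control linearity r2, limit of detection) and a haemolysis ratio
computed from a pair of Cq values: the difference Cq(miR-23a) - Cq(miR-451a)
in cycles and its 2^delta fold equivalent; more than 5 cycles of excess
red-cell marker flags likely haemolysis.
"""

from mirworkbench import (
    SimulationConfig,
    hemolysis_ratio,
    run_qc,
    simulate_experiment,
)

matrix, _ = simulate_experiment(SimulationConfig(seed=2))
report = run_qc(matrix)
print(report.to_frame().to_string(float_format=lambda x: f"{x:.3f}"))
print(f"\noverall QC pass: {report.overall_pass}")

for cq23, cq451 in [(25.0, 22.0), (28.0, 22.0)]:
    delta, fold, flagged = hemolysis_ratio(cq23, cq451)
    verdict = "HAEMOLYSIS LIKELY" if flagged else "clean"
    print(f"Cq(23a)={cq23:.0f}, Cq(451a)={cq451:.0f} -> "
          f"delta {delta:.1f} cycles ({fold:.0f}-fold) -> {verdict}")
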