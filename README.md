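# mirworkbench

An open, testable re-implementation of the NanoString nCounter
circulating-miRNA analysis stack, built for researchers who screen plasma or
serum miRNA with hybridisation-based counting assays and need their data
processing to be explicit, reproducible and sweepable rather than locked
inside proprietary software.

The central problem it addresses: nCounter analysis requires user-defined
choices — the background-correction method (none, subtraction or
thresholding), the stringency of the background level (mean, mean + 1 SD or
mean + 2 SD of the negative-control probes), and the content-normalisation
method (a global "total RNA" pool or a small NormFinder-selected stable
subset) — and these choices materially change which miRNAs come out as
differentially expressed. `mirworkbench` makes every choice a parameter,
runs the full 14-workflow grid with each subtype's correct operation order,
and ranks candidates by cross-workflow consensus instead of trusting any
single configuration.

## What it computes

For a lanes × probes count matrix with probe-class annotation
(endogenous / positive / negative / ligation / spike-in / housekeeping):

- **QC** — imaging fraction (FOV counted/attempted ≥ 0.75), binding density
  (0.1–2.25), positive-control linearity (r² of log₂ counts vs the known
  128–0.125 fM titration, ≥ 0.95), limit of detection
  (count > mean + 2·SD of negatives), ligation/spike-in detection with the
  same statistic, and a Cq-based haemolysis ratio
  (ΔCq = Cq₂₃ₐ − Cq₄₅₁ₐ, flagged above 5 cycles).
- **Background** — per lane, `bg = mean(negatives) + k·sd(negatives)`,
  k ∈ {0, 1, 2}; *thresholding* sets `x ← max(x, bg)`, *subtraction* sets
  `x ← max(x − bg, 0)`.
- **Normalisation** — per-lane factors
  `f_lane = mean_lanes(summary) / summary_lane` (geometric-mean summaries by
  default), driven by the positive controls (technical) and then by
  endogenous normalisers (content): either the total-RNA pool (every
  endogenous probe above the mean + 1 SD background in *all* lanes) or the
  NormFinder-ranked most-stable subset of that pool.
- **The 14 workflows** — with the operation order that matters:
  thresholding workflows normalise first and floor at the (carried-through)
  background last; subtraction workflows subtract first and normalise after;
  no-background workflows just normalise. Welch's t-test per endogenous
  probe on the final values, strict p < 0.05.
- **Consensus** — probe × workflow significance grid, frequency ranking,
  direction with an `inconsistent` flag when workflows disagree in sign;
  plus detection curves, PCA summaries with per-group dispersion, and a
  cell-level diff utility against external (e.g. vendor) exports.
- **qPCR validation** — ΔCq against the mean of ≥ 2 reference assays,
  2^−ΔCq, fold change vs the control-group mean, Shapiro-Wilk-routed
  Student's t / Mann-Whitney testing recomputed per scale, one- and
  two-tailed p on both scales, and direction concordance with the screen.

A synthetic-data module generates full experiments (negative-binomial
endogenous counts over lane-efficiency effects, Poisson controls, planted
fold changes, a planted stable cohort, optional red-cell/platelet
contamination) with known ground truth, so every stage is testable without
any external download.

## A worked example

`python examples/simulate_and_screen.py` simulates a 6 vs 6 screen with ten
planted 4-fold changes, selects normalisers, runs all 14 workflows and
prints the consensus ranking:

```
simulated 12 lanes x 446 probes; planted 10 four-fold changes
total-RNA pool: 139 probes; NormFinder picks: mir-0026, mir-0013, mir-0005, mir-0035, mir-0003
top of the consensus ranking (frequency = workflows significant):
  mir-0011   freq 14/14 up_in_a
  mir-0037   freq 14/14 up_in_b <- planted
  mir-0038   freq 14/14 up_in_b <- planted
  ...
```

All ten planted probes reach 14/14 workflows with the correct direction;
the occasional unplanted probe at high frequency (here `mir-0011`) is the
expected face of running 14 *correlated* tests per probe with no multiple-
testing correction — exactly the behaviour that makes single-workflow
candidate lists unreliable and validation essential. The other examples show
the QC table, the erosion of probe detection under increasingly stringent
background subtraction, and publication-style qPCR summaries where Mann-Whitney
p-values are identical on the ΔCq and 2^−ΔCq scales while t-test p-values
are not.

A thin CLI wraps the same library surface:

```bash
mirworkbench simulate --seed 1 --out counts.csv
mirworkbench qc counts.csv
mirworkbench normalizers counts.csv
mirworkbench run-all counts.csv --out results/
mirworkbench qpcr plate.csv
mirworkbench diff ours.csv theirs.csv
```

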