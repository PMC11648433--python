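# Methods

## Data model

A `CountMatrix` is a lanes × probes grid of non-negative counts (integers at
the raw stage) with probe-class annotation (endogenous, positive, negative,
ligation, spike-in, housekeeping) and per-lane scanner metadata (group label,
fields of view counted/attempted, binding density). Counts stay on the
linear scale at every processing stage; log transforms happen inside the
operations that need them. The canonical interchange format is a CSV
(`probe_id,probe_class,concentration_fM,<lane...>`) with a YAML sidecar for
lane metadata; NanoString RCC per-lane files are read best-effort (the
documented `<Lane_Attributes>` and `<Code_Summary>` sections, unknown
sections ignored). Unknown probe-class strings are rejected rather than
coerced, because every downstream formula keys on class. Missing scanner
attributes are marked missing, never zero-filled, and QC reports them as
not-evaluable rather than failed.

## Quality control

All metrics are per lane. Imaging QC is `fov_counted / fov_attempted`
against a 0.75 floor; binding density is an inclusive range check
(0.1–2.25); positive-control linearity is the squared Pearson correlation of
`log2(count + 0.5)` against `log2(concentration)` over the 128–0.125 fM
titration (threshold 0.95; the +0.5 offset avoids log(0) and is
configurable — it perturbs r² only in the fourth decimal on clean data).
The limit-of-detection check requires the nominated low-concentration
positive probe (by default the one closest to 0.5 fM — codesets differ on
which probe is nominated, so it is a parameter) to exceed
`mean + 2·sd` of the negative controls; ligation and spike-in detection use
the *same* negative-control statistic through a shared implementation, since
the acceptance wording for those checks ("above the negative controls") is
loose and consistency is worth more than a second convention. Negative-
control SD uses the sample (n−1) convention by default with a population-SD
toggle for matching exports from software using the other choice.

The haemolysis check follows the Blondal convention: ΔCq =
Cq(miR-23a) − Cq(miR-451a); both the cycle difference and its 2^ΔCq fold
equivalent are reported, and the flag trips above 5 — the published
convention conflates "5-fold" and "5 cycles", so the implementation is
explicit that the threshold applies to the cycle difference while the fold
is reported alongside.

## Background correction

Per lane, `bg = mean(negatives) + k·sd(negatives)` with k ∈ {0, 1, 2}
(stringencies "mean", "mean + 1 SD", "mean + 2 SD"). Thresholding raises
every count below `bg` up to it; subtraction subtracts `bg` and floors at
zero. The floor is 0 rather than 1 deliberately: detection analyses count
probes *above* thresholds, and a floor of 1 would silently manufacture
detections (the floor is configurable). Thresholding is idempotent for a
fixed background and bounded below by it; subtraction is bounded below by
zero but is *not* idempotent (subtracting the same background twice keeps
subtracting), which is a mathematical property of the operation, not an
implementation choice.

Subtraction inflates ratios near background — a pair (10, 5) with true ratio
2 becomes (6, 1) with ratio 6 after subtracting 4 — which is the mechanism
by which subtraction workflows overstate fold changes of low-expressed
targets. Far above background (counts ≳ 10× bg) subtraction and
thresholding agree to within a few percent.

## Normalisation

One factor formula serves both normalisation steps:
`factor_lane = mean_over_lanes(summary) / summary_lane`, where the per-lane
summary is the geometric mean (default; arithmetic available, since the
emulated software's convention is not documented) of the relevant probes —
positive controls for the technical step, endogenous normalisers for the
content step. After applying the factors the chosen summary statistic is
equal across lanes as an algebraic identity, testable to machine precision.
Zeros inside a geometric mean are replaced by 0.5 with a loud warning,
because the substitution changes factors and must never be silent.

Normaliser selection:

- **Total-RNA pool** — on raw counts (no positive-control normalisation),
  compute lane backgrounds at mean + 1 SD and keep every endogenous probe
  above that background in *every* lane. No minimum-expression filter by
  default (a `min_mean_count` parameter exists, e.g. 50, for the vendor's
  recommended variant).
- **NormFinder subset** — rank the pool by the model-based stability value
  (below) and keep the 5 most stable, ties broken lexicographically so the
  selection is deterministic.

## NormFinder stability model

Log₂ expression of candidate i in sample j of group g is modelled as
`y_igj = α_ig + β_gj + ε_igj`, `ε ~ N(0, σ²_ig)`: a sample "amount" effect
common to all genes, a gene-and-group effect, and gene-specific noise. The
sample effect is removed by subtracting each sample's mean over candidates.
Because that subtracted mean contains a 1/k share of every gene's noise, the
naive residual variance `s²_ig` is biased; the method-of-moments correction
`σ̂²_ig = (k·s²_ig − s̄²_g)/(k − 2)` with `s̄²_g = Σᵢ s²_ig/(k − 1)` undoes
it exactly in expectation (hence the k ≥ 3 requirement; estimates are
floored at zero). The per-gene group effects `z_ig` estimate the intergroup
bias; their spread, after removing sampling variance and flooring at zero,
estimates the bias variance γ², which shrinks each observed bias toward
zero. The stability value is the group-averaged sum of the shrunken
absolute bias and the sampling SD of the gene effect — intergroup and
intragroup variation on the same log₂ scale; lower is more stable. With a
single group the value degrades gracefully to the intragroup SD (with a
warning). Absolute values are implementation-defined up to this model; the
*ranking* is the contract, and it is invariant to global count rescaling and
lane order. A coefficient-of-variation ranking is available behind a flag
as a cross-check.

The estimators are deliberately well-conditioned only for pools of several
candidates: with k = 3 and one dominant-variance gene, the variance
decomposition is noisy (the correction amplifies by k/(k−2) = 3), which is
inherent to the model, not a defect.

## The 14 workflows

The grid is 2 no-background + 6 subtraction + 6 thresholding configurations
(stringency × content-normalisation), ids 1–14 in the canonical order
(no-background NF/TR; then each block NF at 2 SD/1 SD/mean, TR likewise).
Operation order differs by subtype and the difference is material:

- *thresholding*: positive-control normalisation → content normalisation →
  floor at the per-lane background;
- *subtraction*: background subtraction → positive-control normalisation →
  content normalisation;
- *none*: positive-control → content normalisation.

One traced cell shows why order matters: raw 3, lane factor 2, background 4
gives 6 when normalised first and 8 when floored first. In thresholding
workflows the background a cell is compared against is, by default,
recomputed from negative-control counts carried through the same
normalisation chain, so the comparison is scale-consistent; a raw-scale
toggle exists because the emulated software does not document its choice.
Normaliser *sets* are selected once from raw data and held fixed across
workflows; the factors themselves are recomputed on each workflow's current
matrix.

Each workflow ends with Welch's t-test per endogenous probe on the final
linear values (`t = (m_b − m_a)/√(s²_a/n_a + s²_b/n_b)`,
Welch–Satterthwaite df; a log₂ option exists), strict `p < 0.05`, no
multiple-testing correction by default — matching the emulated analysis and
documented as a limitation; Benjamini–Hochberg is available behind an
option. The consensus table counts, per probe, the workflows that called it
significant, with the direction and an `inconsistent` flag when significant
workflows disagree in sign. Because the 14 workflows reanalyse the same
counts, their tests are strongly correlated: a null probe with a lucky group
split can reach high frequency, which is the false-positive face of the
multi-workflow design and the reason consensus candidates still require
independent validation.

PCA summaries use per-probe standardised log₂(x+1), lanes projected on the
first two components, with a per-group dispersion scalar (trace of the group
covariance of the scores) and 2-SD ellipse parameters. The diff utility
aligns two matrices by lane/probe ids and lists cells differing beyond a
tolerance (default 0.5 counts) — the tool for localising disagreement with
an external export rather than emulating its errors.

## qPCR validation

ΔCq is the target Cq minus the mean Cq of ≥ 2 reference assays in the same
sample, which cancels any per-sample additive shift exactly; samples missing
a reference Cq are excluded with a warning, never imputed. Relative
expression is 2^−ΔCq; fold change divides each sample's 2^−ΔCq by the
control-group mean, and the reported mean ± SD is taken over the non-control
group's per-sample folds (the ± convention is not standardised; this choice
is documented and the per-sample folds are returned for any other
convention). Per target and *per scale* (ΔCq and 2^−ΔCq), each group is
Shapiro-Wilk tested at α = 0.05; both groups normal routes to an unpaired
equal-variance Student's t (the screening engine uses Welch — the two assays
specify different tests, and both route through one shared statistics layer
with the variance assumption as a parameter), otherwise Mann-Whitney U
(exact when untied, mid-rank normal approximation flagged otherwise). The
routing can differ between scales because exponentiation reshapes tails.
Two exact properties hold by construction and are enforced in tests:
Mann-Whitney two-sided p is identical on both scales (ranks are blind to
monotone transforms), and the one-sided p is exactly half the two-sided p
when the observed direction matches the hypothesised one.

## Synthetic data: what it emulates and what it does not

The generator draws a two-group cartridge (default 6 vs 6 lanes) over a
420-probe endogenous codeset plus controls, emulating: per-lane capture
efficiency (log-normal, SD 0.15), a plasma-like abundance profile (log-
normal baselines, median 8 counts — most probes near background), negative
controls as Poisson(5) plus a lane-proportional non-specific term, the
6-point positive titration at 200 counts/fM (placing the 0.5 fM probe at
~100 counts, comfortably above background as in a passing run), a 36-probe
stable cohort (reduced dispersion, no group effect, median ~100 counts)
standing in for the normaliser pool, 10 planted fold-4 changes at
biomarker-like abundance (median ~200 counts), ligation controls, spike-ins
at the detection limit, and named red-cell/platelet marker analogues with
fixed, well-expressed baselines (the red-cell marker is abundant enough in
real plasma to enter normaliser pools). Endogenous counts are negative
binomial (variance = μ + 0.1·μ²) for biological overdispersion; control
probes are Poisson, technical-only. Everything is deterministic under the
config seed.

Not emulated: imaging artefacts and binding-density saturation (those QC
fields are plain metadata), probe-specific hybridisation efficiencies,
empirical non-specific-binding structure (the lane-proportional term is a
modelling choice), and any vendor-software arithmetic errors. Passing tests
therefore demonstrate that the *pipeline arithmetic and statistics* behave
as specified under controlled conditions — not that real plasma data will
be as well-behaved.

## Numerical and test-design choices

- Detection threshold: count ≥ 2 ("a count of 2 or more"), configurable,
  because published phrasings of the detection rule disagree at the
  boundary.
- Significance is strict `p < α`.
- Welch on matrices is vectorised; zero variance in both groups with equal
  means is t = 0, p = 1 (a flat probe is not significant, not an error).
- The Welch calibration check runs on 2,500 null probes in the near-normal
  regime (Poisson-limit dispersion, median ~500 counts, no lane effects)
  where the t model's assumptions hold, with a 3σ binomial band. Under the
  default low-abundance plasma profile the small-sample Welch test is
  mildly *conservative* (empirical rejection ≈ 0.03–0.04 at nominal 0.05)
  because of count skewness and discreteness — a real property of the
  method at n = 6, separate from the implementation's correctness.
- Recovery checks use 25 seeds (planted 4-fold changes significant in
  ≥ 10/14 workflows) and 50 seeds (NormFinder returns only planted-stable
  probes); problem sizes mirror the default study conditions and keep the
  full suite fast.
- Monte-Carlo bands on simulated quantities (e.g. the [2.5, 6.5] band on
  recovered 4-fold ratios) apply to replicate-level averages; single-probe
  draws at n = 6 legitimately stray outside.

## Known limitations

- No mRNA/protein codeset support beyond class tagging; no probe-sequence
  handling; no amplification-curve processing on the qPCR side (Cq values
  are the input boundary).
- No housekeeping-mRNA normalisation (present on codesets, unused here).
- The consensus frequency is a heuristic ranking, not an error-controlled
  statistic; with no multiple-testing correction the per-workflow candidate
  lists carry the full false-positive burden by design.
- RCC parsing is read-only and best-effort; the CSV dialect is the
  canonical format.
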