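# Methods

## Decay model and estimator

The analysis assumes first-order decay after complete transcription
shutoff: I(t) = I₀·e^(−kt). For each probe within each donor, the four
chase arrays (0, 1, 3, 5 h) yield a trajectory of natural-log intensities,
fitted by ordinary least squares of ln I on hours. The half-life is
t½ = ln 2/(−slope). The design matrix is the fixed grid {0, 1, 3, 5}, so
the fit has 2 degrees of freedom of error; R² is recorded per fit and an
optional R² floor can *flag* (never drop) poor fits, replacing ad-hoc
manual inspection of raw traces with a reproducible QC flag.

Three estimator conventions matter:

* **Capping.** Half-lives are truncated at `cap_h` = 24 h. A 5 h chase
  window cannot distinguish a 30 h from a 300 h half-life — the expected
  signal drop (11% vs 1%) is inside the noise — so everything slower is
  reported as "≥ cap", which produces the characteristic spike at the
  right edge of half-life histograms. Capping happens per donor-cell,
  *before* group means and ratios.
* **Zero slope.** Maps to the cap, not to the invalid marker: a flat
  trajectory is a maximally stable transcript, not a failed measurement.
* **Positivity filter.** A positive slope implies a non-positive
  half-life (apparent accumulation under shutoff — noise, or actinomycin
  escape). One positive-slope donor drops the entire gene row: group means
  are only computed over genes measurable in every donor.

Kinetics use natural log throughout; only reporting (fold changes) uses
log2.

## Normalization regimes

Two quantile-normalization regimes serve different questions:

* **total** — all time-0 arrays normalized together; used for
  steady-state differential expression between groups.
* **decay** — each donor's four chase arrays normalized against *each
  other only*. Between-donor scale differences (array batch, input mass)
  then cannot influence within-donor slopes; the simulator plants exactly
  this nuisance (a per-donor multiplicative scale) to keep the property
  testable.

Quantile normalization maps each array's rank vector onto the across-array
mean of sorted intensities. Tied values receive the mean of the reference
quantiles across their tie span — deterministic, permutation-equivariant,
and checkable against a brute-force oracle. Exact invariants (identical
sorted columns, idempotence) hold for tie-free data; with ties the
tie-averaging rule intentionally departs from a strictly shared
distribution. Intensities are floored at `epsilon` (default 1.0) before
taking logs, since background-subtracted exports can contain zeros.

The detection filter precedes the decay normalization, as the protocol
prescribes: probes without significant hybridization above background at
time 0 (detection p ≥ α, default α = 0.05) are excluded. The protocol does
not say whether "at time 0" quantifies over donors; the default policy
requires detection in **all** time-0 arrays, with "any" and
"fraction ≥ f" alternatives exposed.

## Differential stability

Per gene: group mean half-lives (ratio of means, not mean of per-donor
ratios), a strict >2-fold gate in either direction, a two-sample t-test on
the per-donor half-lives of gated genes (Student pooled-variance by
default — era-typical; Welch and log-scale variants via config), and
Benjamini–Hochberg adjustment **over the tested set only**, mirroring the
gate-then-test order of the original protocol; a conservative all-genes
FDR universe is available. The pooled-OA contrast recomputes the pooled
mean over all OA donors rather than averaging the two subgroup means.
Direction is "destabilized" when the OA-side mean is smaller. The t-test
operates on raw hours by default (a log-hours mode is provided); the
original protocol does not state which was used.

The steady-state ("total") analysis is a plain fixed-effects one-way
ANOVA across the three disease groups with an AND-gate: |log2 FC| ≥ 1 and
p < 0.05. The original analysis ran in an external web tool whose internal
error model is not reproduced here; a standard ANOVA stands in.

## Synthetic cohorts

`simulate_cohort` generates what the analysis assumes: per-gene true
half-lives, a per-gene baseline, per-donor scale factors, log-normal
measurement noise, a background fraction of undetected probes, and a
group-wise destabilization effect (true OA half-life = normal half-life /
fold for a flagged fraction of detected genes — matching the empirical
direction that most significantly affected transcripts become *less*
stable in OA). One RNG stream is consumed in a fixed, documented order, so
identical configs are bit-identical.

Defaults mirror the target study design: ~48k probes, three groups of 4
donors, 0/1/3/5 h grid. Where the study reports no distributional
parameters, values were chosen once for realism:

* **Half-life prior**: two-component log-uniform mixture — 5% short-lived
  on (1, 6) h, the rest on (30, 300) h. This is a stand-in for the
  empirical "mostly stable + short-lived tail" shape, not a claim about
  its true form. The short range starts at 1 h because sub-hour mRNA
  half-lives are rare in primary cells at this frequency; the stable range
  sits entirely above the 24 h cap so that in the noise-free all-stable
  limit every detected gene is reported *at* the cap.
* **Baselines**: log-normal, median 1000, σ_log = 1.5 — roughly three
  decades of detected dynamic range, as on a BeadChip. This matters: a
  decaying transcript is only measurable while its intensity stays inside
  the cohort's dynamic range (see limitations).
* **Noise**: σ = 0.1 on natural-log intensities per hybridization
  (per-study runs may override); donor scale σ_log = 0.3; 20% of probes
  drawn at a background mean of 100 with Uniform(0,1) detection p-values,
  detected probes get a small constant (10⁻³) — only the thresholding
  behaviour matters downstream, so no bead-level noise model is attempted.

What the generator does **not** emulate: bead-level Illumina noise, probe
cross-hybridization, batch effects beyond donor scale, correlation between
expression level and half-life. Passing tests therefore demonstrate
correctness of the *procedure* under its own assumptions, not performance
on real arrays.

## Numerical and degenerate-input conventions

* Constant trajectory: slope 0, R² defined as 1 (the constant fit is
  exact).
* All-constant ANOVA/t-test inputs: (F = 0, p = 1) / (t = 0, p = 1) by
  convention, logged.
* Zero within-group variance with separated means: F = ∞, p = 0.
* Quantile normalization of a single-sample subset: identity with a
  warning; empty subsets are rejected.
* Donors missing a chase time point are excluded from decay sets with a
  logged warning; an unclassifiable histology combination (non-OA joint,
  Mankin ≥ 10) is an explicit error, never a silent drop.
* Ratio test with an empty gated set returns an empty (all-NaN-FDR)
  result, not an error.

## Problem sizes used in validation

The automated checks run simulation studies sized to make their
statistical claims sharp but cheap: oracle-agreement suites use 100 random
small instances per primitive; operating characteristics (sensitivity for
planted 3-fold destabilization, empirical FDR, permuted-label null) use
ten seeded cohorts of 2,000 genes with 4 normal + 8 OA donors at noise
σ = 0.05; the short-lived-fraction summary uses one 8,000-gene cohort at
default noise. The pipeline itself has no size-dependent logic — the same
code paths run at 48k probes.

## Known limitations

* **Retention under within-donor quantile normalization.** QN equalizes
  the four arrays' intensity distributions, which constrains the sum of
  per-gene log-slopes over the normalized set to ≈ 0. Genuine bulk decay
  is therefore invisible; only decay *relative to the bulk* is estimated,
  and under noise roughly half of the truly-stable genes drift to slightly
  positive slopes in any one donor. The strict all-donor positivity filter
  then removes most stable genes (e.g. 343 of 8,000 simulated genes
  retained at σ = 0.1), and the retained set over-represents fast-turnover
  transcripts. Real-array retention is far higher, plausibly because the
  measured distribution contains a dense near-background mass that absorbs
  rank drift. Conclusions from the simulated short-lived *fraction* should
  therefore be drawn with care; the differential-stability operating
  characteristics are unaffected (they condition on retained genes).
* **Resolution window.** Transcripts whose intensities decay below the
  cohort's dynamic range within 5 h (t½ well under ~1 h at typical
  baselines) are clamped toward the bottom reference quantile and their
  decay is underestimated; at the other end everything slower than 24 h is
  censored at the cap. Destabilization is only detectable when at least
  one group's half-life falls inside this window.
* The label-permutation null control is run on cohorts generated *without*
  any group effect; permuting labels of an effect-bearing cohort is not a
  pure null (partial-overlap permutations retain group-correlated
  structure) and is not what the control asserts.
* Probe-to-gene collapse is deliberately off by default: hybridization and
  detection are probe-level concepts, and gene mapping is
  annotation-dependent.
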