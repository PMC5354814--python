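# Methods

This note documents the statistical models the package implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Connectivity scoring

A drug perturbation *instance* is one experiment's expression profile,
stored as a permutation of ranks 1..n over the gene universe (rank 1 =
most up-regulated). A query signature is a pair of disjoint up/down gene
sets. Each side is scored with the two-sided KS-type enrichment used
throughout the connectivity-map lineage: with sorted set positions
`V(1)<…<V(t)`, `a = max_j(j/t − V(j)/n)` measures crowding toward the top
and `b = max_j(V(j)/n − (j−1)/t)` toward the bottom; the statistic is `a`
if `a ≥ b`, else `−b`. Note the statistic is mildly asymmetric: a set
packing the top t ranks scores `1 − t/n` while one packing the bottom
scores `−(1 − (t−1)/n)` — a property of the classic formula, not a bug. A
set equal to the whole universe scores 0 by convention.

The instance score is `(ks_up − ks_down)/2` when the halves disagree in
sign and 0 otherwise, giving a score in [−1, 1] whose sign separates
reversers (negative — the therapeutic hypothesis) from mimics (positive —
used for the fusion-silencing approach, where mimicking the knockdown
profile is desirable).

**Aggregation and significance.** Drug score = median of its instance
scores (`max_magnitude` is available). The null scores `n_perm`
(default 1000) random signatures of identical up/down sizes against the
same instances and aggregates identically per drug, so each drug's null
respects its own instance count; `p = (1 + #{|null| ≥ |obs|})/(n_perm+1)`
(add-one pseudocount, making p-values super-uniform with floor
1/(n_perm+1)). Random signatures rather than rank permutations preserve
each instance's internal rank structure. FDR is Benjamini–Hochberg across
drugs within an approach; selection filters FDR < 0.05, sorts toward the
requested tail, truncates to top 20, and breaks ties by p-value then drug
id so runs are reproducible. Reported multiplicity counts a hit drug's
instances whose score lies in the selected tail.

**Robustness filter.** Drugs with ≥ 2 instances are assessed by the
median pairwise Spearman correlation over the full universe (ranks are
already integers, so Pearson on columns); drugs below 0.3 are dropped
whole, singleton drugs are retained but flagged. Filtering is per-drug
(not per-instance) and idempotent. The threshold is a convention exposed
in the API — no published criterion exists for this removal step.

**Resistance signature.** Responder vs non-responder expression is
compared per gene by Wilcoxon rank-sum — exact null when both groups are
≤ 25 samples and tie-free (worth real power at screening-cohort sizes:
sensitivity for a 2 SD shift at n = 10/10 rises from ~0.6 under the
normal approximation to ~0.8 exact), mid-rank normal approximation
otherwise — then BH-FDR, direction by sign of the median difference
(up = higher in non-responders), truncation to the top-n |effect| per
direction. Rank-based testing makes the signature invariant under any
monotone transform of expression. Simulation on the package's own
generator puts sensitivity at ~0.75–0.8 for a 2 SD shift (n = 10/group,
FDR 0.05) and ≥ 0.95 at 2.5 SD; recovery of such contrasts at 2 SD should
not be expected to be complete.

## Screen hit calling

Percent inhibition is `100·(1 − signal/vehicle mean)`, vehicle mean taken
per plate to absorb plate effects; negative values (growth stimulation)
are preserved. Plates must pass `Z′ ≥ 0.5` computed with sample (n−1)
SDs; coincident control means make Z′ undefined and reject the plate.
The hit rule is strict (> 50% in at least one EWS line; exactly 50.0 is
not a hit); nomination additionally requires a clean counter-screen on
every measured non-tumorigenic line, absence from the prescribed-drug
blacklist, and a complete measurement set. Screen values published only
as "< 50" are stored as left-censored objects whose single valid
operation is the `> threshold` predicate for thresholds ≥ 50 — they never
masquerade as numbers.

## Median-effect and combination index

The fit is ordinary least squares of `log10(fa/(1−fa))` on `log10 D`.
Cells with fa outside [0.01, 0.99] are *excluded* rather than clipped:
clipping drags near-boundary points off the median-effect line, whereas
on noiseless model data every retained point lies exactly on it, so the
fit round-trips generated curves to machine precision. Censoring precedes
fitting: a curve never reaching 50% effect reports "> top dose"; one
already ≥ 50% at the lowest dose reports "< bottom dose"; fewer than 4
usable points is a failed fit with a reason, never an exception.

CI uses the mutually exclusive (Loewe-type) Chou–Talalay form without the
third product term, matching the convention of the standard CI software.
CI is computed on replicate-averaged fa per cell (per-replicate remains
possible by passing single-replicate tables). Cells with fa outside
(0, 1) — including negative inhibition — are undefined, and censored
single-agent fits refuse CI computation outright. The published
classification bands leave (0.9, 1) and the exact boundaries ambiguous;
the package pins an explicit, configurable additive band [0.9, 1.1], with
< 0.5 strong synergy and < 0.9 synergy as published.

## Non-compartmental PK

Concentrations are blood elemental gold in µg/mL (auranofin dissociates
immediately in blood; gold = 196.97/678.48 ≈ 29.03% of auranofin mass).
Molar conversion divides by the atomic mass of gold: 12.43 µg/mL ≡
63.10 µmol/L. AUC uses the linear trapezoid (the log-linear variant is an
option); `Kel` comes from log-linear regression over a terminal window —
default: best adjusted-R² among the last 3..6 positive post-Tmax points,
with `last_k` available for a pinned window. A non-negative terminal
slope or < 3 usable points refuses extrapolation: the result then carries
only observed-window quantities plus a flag. `Cl/F = gold dose (µg/kg) /
AUC(0→∞) (µg·hr/mL)` yields mL/hr/kg; doses are per kg and body weight is
metadata only. Repeat-dose troughs are read at the end of each dosing
interval without interpolation; the accumulation ratio is the final
trough over the single-dose concentration at one interval. For n
once-daily doses of a drug with elimination `ke` the superposition value
is `(1 − e^(−n·ke·τ))/(1 − e^(−ke·τ))` once absorption is spent — at
ke = 0.029/hr and n = 5 this is 1.93, noticeably below the
infinite-horizon plateau 1/(1 − e^(−ke·τ)) ≈ 1.99, so finite-course
accumulation should be compared against the finite sum.

## Survival

Kaplan–Meier product-limit estimation and the two-sample log-rank test
(observed − expected over shared risk sets, hypergeometric variance,
1-df chi-square) are implemented directly — both are elementary — and are
cross-checked in the test suite against lifelines trial by trial.
Pairwise comparisons against the vehicle arm are unadjusted for
multiplicity by default. Animals sacrificed for tumor-size endpoints are
events; censoring is reserved for study end.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (config, seed); stream labels are hashed
stably so outputs are bit-identical across processes.

* **Drug profiles.** Each drug owns a bounded latent expression vector
  (uniform ±0.5 per gene) shared by its replicate instances; planted
  reversers/mimics shift signature genes by ∓/±1 on top; per-instance
  gaussian jitter of scale `noise_sd` degrades the planting continuously.
  At `noise_sd = 0` planting is exact (every up-gene of a reverser ranks
  below every non-signature gene) and replicates agree perfectly; the
  bounded base keeps this exactness while giving the robustness filter
  genome-wide replicate agreement to measure. Defaults — 2000 genes, 200
  drugs, 1–5 instances each, 50 genes per signature direction — are
  desk-scale conventions for a connectivity-map-like resource; real
  resources are larger, and real replicate disagreement includes batch
  and cell-context structure this generator does not model.
* **The mimicry approach** is exercised with the disease signature
  direction-swapped (silencing the driver fusion reverses the disease
  program), so one planted drug set serves both reversal and mimicry
  queries in the end-to-end run.
* **Plates** use multiplicative gaussian noise (CV-parameterized, floored
  at 0) because luminescence noise scales with signal; 32+32 control
  wells at 5% CV give Z′ ≥ 0.5 in ≥ 95% of plates. Spatial/edge effects
  are not modeled.
* **Dose matrices** plant an interaction α by solving
  `d1/Dx1(fa) + d2/Dx2(fa) = α` for the observed fa (closed form when
  m1 = m2, bracketed root otherwise), so the downstream CI recovers α
  exactly at zero noise — α = 1 is Loewe additivity, α < 1 synergy.
* **PK** is one-compartment first-order absorption,
  `C(t) = (F·D·ka)/(V(ka−ke))·(e^(−ke t) − e^(−ka t))`, sampled by
  default on the study's 0–48 h grid. Defaults ke = 0.029/hr and gold
  dose 3480 µg/kg are the reported study conditions; V/F = 224 mL/kg and
  ka = 0.33/hr follow algebraically from the reported exposure
  (V/F = Dose/(AUC·ke)) and peak time (tmax = ln(ka/ke)/(ka−ke) = 8 h),
  so the synthetic profile reproduces the reported Cmax ≈ 12.3 µg/mL and
  AUC ≈ 536 µg·hr/mL by construction. `ka = ke` is rejected as the
  flip-flop degenerate case.
* **Survival** uses exponential hazards with administrative censoring —
  sufficient for ordered event times, with no frailty or non-proportional
  hazards.

Passing tests on these generators demonstrate correctness of the
statistical machinery and recoverability of planted structure; they do
not validate performance on real perturbation databases, real screens, or
real PK data, whose noise structures are richer.

## Problem sizes and tolerances in the test suite

The suite runs the connectivity engine at the default 2000-gene/200-drug
scale with 1000 permutations for planted-truth recovery, calibrates null
type-I error on 500 background drugs (two seeds × 250 drugs, one instance
each, 1000-gene universe — standard error ≈ 0.01 for the 0.05 ± 0.02
check), and cross-checks log-rank power on 500 simulated 12-per-arm
trials at hazard ratio 0.5. Exhaustive KS-oracle agreement covers every
possible placement of up to 3 set genes in rankings up to n = 8 (the
statistic depends on a ranking only through the occupied positions).
Noiseless round-trips assert at 1e-6; stochastic recoveries use the
bands stated inline with each test.

## Known limitations

* Gene identifiers match by exact string (upper-cased); no alias or
  ortholog resolution.
* The permutation null is exchangeable across drugs only when instances
  are; strong per-drug latent structure is handled by the per-drug null
  aggregation, but correlated drug families are not modeled.
* CI is undefined (not imputed) wherever fa leaves (0, 1); heavily
  saturated matrices therefore yield few defined cells.
* The NCA refuses extrapolation rather than guessing when no elimination
  phase exists; profiles truncated before the terminal phase yield
  observed-window results only.
* Survival comparisons are pairwise and unadjusted by default (Holm-style
  adjustment can be applied to the emitted p-values).
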