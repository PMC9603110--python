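# Methods

`dpsir-cloud` assesses the environmental impact of an ecological
restoration project across its life-cycle phases — construction period
(CP), short-term operation (SOP) and long-term operation (LOP) — from
expert score panels, using a DPSIR indicator system, signed entropy
weights, and the normal cloud model.

## Indicator system and signed semantics

Fourteen indicators, coded D1…R3, are grouped into the DPSIR causal
categories (Driving force, Pressure, State, Impact, Response). Each carries
an *attribute*:

* **positive** — benefits the environment; its weight enters the
  aggregation with sign +1;
* **negative** — damages the environment; sign −1, so that a project with
  strong negative pressures can score low or even below zero overall;
* **neutral** — can cut either way (the three Response indicators); the
  sign is decided by the panel's mean raw score relative to the midpoint
  0.5 (mean ≥ 0.5 → +1, below → −1; the tie at exactly 0.5 is broken to +1
  and documented here).

The default schema marks S3 as positive. Published accounts of this
indicator set are internally inconsistent about S3 — its description reads
like a pressure, but the attribute partition that is stated as
7 positive / 4 negative / 3 neutral, and the positive S3 weights in both
published per-phase tables, require S3 positive — so the default follows
the partition the downstream tables actually use. The schema is a YAML
file; any other attribute assignment can be supplied via `--schema`.

Expert scores live on [0, 1]. Panels elicited on other scales (1–5 Likert,
percentages) must be mapped by the caller before loading; the package
rejects, rather than rescales, out-of-range values so silent unit mistakes
cannot pass.

## Entropy weighting

For one phase's matrix (m experts × k indicators), every column is min–max
normalized benefit-oriented, `Y = (x − min)/(max − min)`; direction is
carried entirely by the weight sign rather than by flipping cost columns,
so the magnitudes measure dispersion only. The normalized Shannon entropy
of column j is

    E_j = −(ln m)⁻¹ Σ_i p_ij ln p_ij,   p_ij = Y_ij / Σ_i Y_ij,

with the convention 0·ln 0 = 0, and the weight magnitudes are

    w_j = (1 − E_j) / (k − Σ_j E_j).

`m` counts experts: within a single phase the expert axis is the only one
with replication, so inter-expert disagreement is the information an
indicator carries. A constant column normalizes to zeros; it is assigned
the maximal entropy 1 (hence weight 0) with a `DegeneracyWarning` instead
of crashing — a non-discriminating indicator simply drops out. Only if
*every* column is constant are the weights undefined, and a
`DegeneracyError` is raised.

## Cloud model

A cloud (Ex, En, He) represents a fuzzy concept on the score domain:
expectation, entropy (dispersion/fuzziness) and hyper-entropy (uncertainty
of the entropy; visually the droplet band's thickness).

* **Standard clouds** per grade interval (Cmin, Cmax):
  Ex = (Cmax+Cmin)/2, En = (Cmax−Cmin)/6, He = k. The default five grades
  I–V partition [0, 1] into fifths. `k` defaults to 0.01, the conventional
  choice; some published tables print 0.1 instead — the constant is
  configurable, and since grade membership never uses He the choice does
  not affect any reported membership or grade.
* **Backward generator** (indicator clouds from expert scores):
  Ex = mean, En = √(π/2)·mean|x − Ex| (the Gaussian
  mean-absolute-deviation inversion), He = √(S² − En²) with S² the unbiased
  variance. Sampling noise can make S² < En² (common for near-uniform
  score bands, whose |deviation| profile is flatter than a Gaussian's); He
  is then clamped to 0 with a warning rather than producing a complex
  number.
* **Forward generator** (droplets for cloud maps): per droplet
  En′ ~ N(En, He), x ~ N(Ex, En′), certainty y = exp(−(x−Ex)²/(2En′²)).
  Draws with En′ ≤ 0 are rejected and resampled, preserving the
  conditional law on the positive half-line without the bias of
  absolute-value folding; more than 1000 consecutive empty rounds abort
  with a diagnostic (it means N(En, He) has essentially no positive mass).
  Droplet export defaults to 3000 points; rendering is left to the caller.
* **Aggregation** with signed weights w_i:
  Ex = Σ Ex_i w_i, En = √(Σ(En_i w_i)²), He = √(Σ(He_i w_i)²) —
  expectation combines linearly (negative indicators subtract), the
  dispersion terms in quadrature.
* **Membership and grading**: μ_j = exp(−(Ex − Ex_j)²/(2En_j²)) against
  each grade's standard cloud, evaluated deterministically from Ex (no En′
  randomization: membership is a similarity score, not a droplet). The
  grade is the maximal μ; exact ties break toward the more severe grade.
  If all μ underflow to zero the classifier raises and advises falling
  back to the interval containing Ex (the report pipeline applies that
  fallback automatically).

Aggregating the published long-term table with R3's weight taken negative
(its mean score 0.33 is below the neutral midpoint) reproduces the
published comprehensive expectation 0.3332; the construction-period table
reproduces 0.0362 to within 1e−5 (the residual is the table's 4-decimal
rounding). The published comprehensive En values are *not* recoverable
from the rounded per-indicator rows (they were evidently computed from
unrounded data); no attempt is made to force agreement.

## Short-term-operation Monte Carlo

SOP is a transition state experts cannot score reliably. It is simulated
under two assumptions: (i) each expert's SOP score for an indicator lies
between that expert's CP and LOP scores — the cell-wise bracket reading of
"the change is bounded by the two observable phases", which is the only
internally consistent one; and (ii) within the bracket the score is
uniform. Each of n_sims (default 10,000) iterations draws a full score
matrix cell-wise from U[min(cp, lop), max(cp, lop)] and runs the complete
chain — entropy weights are *re-computed per iteration* (the simulated
panel is a panel like any other), signs re-assigned, backward clouds
re-estimated, aggregation applied — collecting the comprehensive Ex. The
run reports the sample mean and a normal-approximation confidence interval
mean ± z·sd/√n (default 95%); the distribution is approximately normal at
these sizes, which the suite checks by skewness/kurtosis bounds.
Memberships are evaluated at the CI bounds and at the mean; the grade is
assigned at the mean. A frozen-weight variant (`fixed_weights=`) exists
for envelope analyses; simulated scores, grades or index-level
expectations are alternative readings of what to randomize — cell-wise
raw scores were chosen as the most granular and are the documented
convention here.

The simulator is vectorized across iterations (a sims × experts ×
indicators array); the suite asserts each vectorized iteration agrees with
the scalar per-matrix pipeline to 1e−12, so the fast path cannot drift
from the reference chain. Same seed → bit-identical results.

## Synthetic panels

The generator draws each expert's score for an indicator from a
per-indicator band (center, half-width), uniform by default (the simplest
structure consistent with the uniform-elicitation assumption; a truncated
normal option exists), clipped to the band ∩ [0, 1]. The bundled default
spec anchors band centers to the published per-indicator expectations for
CP and LOP with a common half-width of 0.15, which yields backward-cloud
entropies near 0.09 — inside the 0.07–0.14 range the published tables
show. What the generator does *not* emulate: inter-expert systematic bias
(everyone draws i.i.d.), correlation between indicators, and panel
heterogeneity by seniority; passing tests therefore demonstrate the
machinery, not robustness to structured expert disagreement. The raw
10-expert matrices behind the published tables are unpublished and are
deliberately not reverse-engineered; the printed (weight, Ex, En, He)
tables themselves ship verbatim as text fixtures, including a variant
with R3's weight sign corrected to negative, which is the variant
consistent with the neutral rule and the published aggregate.

## Numerical conventions and problem sizes

Comparisons against published 4-decimal values use half-up rounding.
Magnitude sums are checked to 1e−9; oracle agreement (entropy brute force,
vectorized-vs-scalar) to 1e−12. The test suite runs the round-trip check
at 10⁴ droplets × 20 fixed seeds and the simulator scaling check at
n_sims ∈ {1000, 4000, 16000} on 10 × 14 panels; the full suite completes
in a few seconds.

## Known limitations

* The maximum-membership grade can disagree with a coarser qualitative
  reading near interval boundaries; published summaries sometimes label
  the long-term phase one grade higher than its membership peak. This
  package always reports the membership vector alongside the grade so the
  ambiguity is visible.
* The CI is a normal approximation, not a bootstrap; at n_sims ≥ 1000 the
  difference is negligible for this statistic.
* No multi-dimensional clouds, no cloud-similarity metrics, and no
  subjective (AHP/Delphi) weighting — the weighting here is purely
  dispersion-based.
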