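# Methods

## Instrument schema

The catalog encodes the 37-question photo-audit pro forma as 60 scoreable
items: multi-part questions (sidewalk surfaces Q3, vehicle counts Q13,
crosswalk features Q17a–f, natural features Q19, street furniture Q25) are
expanded into one item per part because reliability is assessed per part.
Questions 1–32 are objective measures; Q33–Q37 are observer opinions on
4-point agreement scales. Response scales are transcribed from the
instrument's printed level descriptions: yes/no items are coded 0/1, ordinal
items keep their printed 1-based codes (so point maps remain traceable),
vehicle counts and building counts are unbounded non-negative integers, and
the natural-feature percentage is an integer 0–100. Sidewalk type (Q2) is
modelled with an explicit `none` level (0) alongside partial (1) and
complete (2): the instrument prints only partial/complete, but scoring needs
a zero level when no sidewalk exists, and validation would otherwise reject
records for communities without sidewalks.

Missing responses are admissible at the dataset level; each analysis states
its own policy (below). Validation separates structural errors (wrong
columns — raised) from content violations (out-of-range codes, unknown
items, duplicate community×observer×item records — enumerated).

## Domain scores

Scores sum small integer point allocations within six construct domains.
Allocations the published scheme leaves implicit are fixed as the minimal
monotone maps achieving the printed brackets:

- 4-level "none … many" amount items (pedestrian density Q10, vehicle
  density Q12, parked cars Q14, street trees Q21, landscaping Q22) map level
  ℓ → ℓ−1 points (0–3).
- Disorder indicators (litter Q24, graffiti Q23, derelict buildings Q30) and
  public art Q26 score 1 for any non-"none" level; "buildings poorly
  maintained" scores 1 only for the lowest maintenance level of Q31.
- The natural-features indicator is 1 if any Q19 part is present (cap 1);
  street furniture counts bench/trash can/bus shelter/street lamp at 1 point
  each, capped at 4; crosswalk features count painted lines, distinct
  surface, pedestrian signal and crossing signs (cap 4), with traffic
  signals/stop signs collapsed into a single 0–1 "signals/signs" component.
- Median/grass strip (0–2) awards 1 for a median strip present (Q18 ≥ 2 on
  its 1–4 no-strip→high-quality scale) plus 1 for a grass strip along some
  or all of the street (Q7 ≥ 2).
- Sidewalk completeness (0–2) and quality (0–3, Q4 ℓ→ℓ−1) are guarded by
  sidewalk presence: when Q1 = no they contribute 0 regardless of their own
  codes. Bike-lane quality is guarded by lane presence the same way.
- "Street density" in the urban-density domain is bound to pedestrian
  density Q10 — the only remaining density item once street width and
  vehicle counts are excluded; this is an interpretive choice.

Items the study dropped from scoring (buildings present/count, awnings,
parking lots, street width, all vehicle counts, obstacles, building-design
diversity, biking-suitability opinion) appear in no domain. The resulting
brackets — urban density 0–9, aesthetics 0–12, disorder 0–4, appeal 4–16,
pedestrian safety 0–14 — are verified by brute-force enumeration over each
domain's full response space, not just asserted from the component maxima.

**Bike lanes.** The published description is internally inconsistent: the
stated range is 0–4, the listed components (present 0–1, quality 0–2) sum to
3, and the quality item is scaled 1–3. Both readings are implemented:
variant "0-4" (default; raw 1–3 quality points when a lane is present,
matching the realized 0–4 range of the published summary tables) and
variant "0-3" (quality ℓ−1). Neither bracket is treated as an invariant.

**Missing data.** A missing component response contributes 0 points and is
listed in the card's missing-components report — never imputed. A card with
missing appeal items can therefore legitimately fall below the nominal
domain minimum of 4; the report makes that visible.

**Tertiles.** Communities are labelled per domain on the observer-averaged
score against the empirical 1/3 and 2/3 quantiles (linear interpolation):
low ≤ q₁⁄₃ < mid ≤ q₂⁄₃ < high, exact boundary ties falling to the lower
band, and the degenerate all-equal case labelling every community mid. The
source material does not specify a tie rule; this one is deterministic and
documented. At least 3 communities are required.

**Summaries.** Region/urbanicity/overall tables summarize the
observer-averaged per-community score (mean, SD with n−1 denominator, n over
communities); the by-observer table summarizes each observer's own scores.
A single observation reports SD 0 with its n, keeping tables total.

## Reliability

Each item's communities×observers grid is analysed under the two-way
random-effects model y₍ᵢⱼ₎ = μ + cᵢ + oⱼ + e₍ᵢⱼ₎. The ANOVA mean squares
(MS_rows, MS_cols, MS_error with df n−1, k−1, (n−1)(k−1)) give the
single-rater estimates

- absolute agreement (default): (MS_R − MS_E)/(MS_R + (k−1)MS_E + k(MS_C − MS_E)/n)
- consistency: (MS_R − MS_E)/(MS_R + (k−1)MS_E)

Absolute agreement is the default because a systematic observer offset is a
real disagreement for an audit instrument, and because its degenerate-case
behaviour matches the reporting conventions below; single-rater (not
average-of-k) estimates are reported because the instrument is evaluated per
assessor. 95% CIs use the classical F constructions — exact for the
consistency form, Satterthwaite-style approximate denominator degrees of
freedom for the agreement form. Estimates and CIs agree with independent
implementations of the same closed forms to 10⁻¹⁰.

**Coverage caveat.** The agreement-form interval is approximate: with only
k = 3 observers and non-negligible observer variance its realized coverage
in simulation is ≈90–91% rather than 95% (the consistency-form interval
attains nominal coverage of its own estimand, and agreement-form coverage
approaches nominal as k grows or observer variance shrinks). This is a
property of the standard construction, shared by other implementations of
it, and is documented by the test suite rather than patched with a
non-standard interval.

**Conventions.** Per-item listwise deletion drops communities with any
missing observer response (simplest defensible policy; the source is
silent). A grid on which all observers agree exactly for every community,
with a non-floor response somewhere, reports 1.00 with flag
`constant_perfect_agreement` and no CI; a grid constant at the scale floor
(feature never observed) reports `never_observed` with no estimate. The
asymmetry between the two conventions is deliberately preserved from the
source material's reporting, flagged rather than resolved. Fewer than two
complete communities (or observers) yields an `insufficient_data` result,
not an exception. Negative estimates are retained internally (they matter
for simulation studies of the estimator) and clipped to 0 only in display
tables. A grid with MS_R = MS_C = 0 but MS_E > 0 has no defined estimand and
reports NaN.

**Bands.** Band counts use inclusive lower bounds (an estimate of exactly
0.4 falls in the 0.4–0.7 band). Two published threshold sets are supported —
{0.4, 0.7} and {0.4, 0.6, 0.75} — and neither is privileged; never-observed
items are excluded from the bands but kept in the reporting denominator. The
package ships the 60-row published per-item estimate table (59 numeric, one
not calculable) as a fixture for band analyses; the underlying raw observer
responses are not publicly machine-readable, so per-item estimates and
regional band rows reproduce structurally but not numerically from data.

## Synthetic data generator

One latent-Gaussian mechanism serves all item types so the variance-ratio ↔
ICC link stays transparent. Community i in region r has latent truth
t = μ_{r,q} + c, c ~ N(0, σ²_c) per item q; observer j sees
z = t + b_{j,q} + e with a per-observer column effect b ~ N(0, σ²_o) shared
across communities (the two-way model's rater term) and residual
e ~ N(0, σ²_e). Ordinal items discretize z at equally spaced cutpoints
centred on zero (spacing 1.0, configurable — the source gives no
distributional detail beyond coarse percentages); counts are rounded
exponentiated latents; binary truths are Bernoulli(logistic(t)) and each
observer's binary copy flips with miscoding probability ε. Because binary
truths are sampled, they retain per-community randomness even at σ_c = 0;
the deterministic-truth property at σ_c = 0 holds exactly for ordinal and
count items.

`expected_icc` returns σ²_c/(σ²_c+σ²_o+σ²_e) — exact for the continuous
latent scale (`simulate_two_way_matrix` draws those directly for estimator
recovery and coverage experiments) and an upper-bound approximation for
thresholded outputs, since discretization attenuates agreement.

Defaults emulate the study design: 86 communities (Canada 24 urban/13
rural; Brazil 3/3; Colombia 8/6; China 10/4; India 5/10 — regional groups
37/20/29, urbanicity 50/36), 3 observers, σ_c = 1.5, σ_o = 0.35, σ_e = 0.5
(expected latent ICC ≈ 0.86, the middle of the published per-item range),
ε = 0.03. Regional baselines for a subset of items reproduce the reported
qualitative contrasts (sidewalks ~97% prevalent in Canadian communities vs
roughly a third in India; richer landscaping in Canada; more disorder
outside Canada); desert prevalence is effectively zero, so noise-free runs
reproduce the never-observed convention downstream. Other region mixes are
accommodated by largest-remainder rescaling of the design counts.

**What the generator does not emulate.** Items are conditionally independent
given region and community effect — real co-occurrence (sidewalks predict
crosswalk features) is absent. Observer effects are exchangeable Gaussians,
not the systematic perceptual differences described for real observers; and
binary miscoding is symmetric. Passing recovery tests therefore shows the
estimator is correct under the model, not that the instrument behaves this
way on real photographs.

## Problem sizes

Simulation-based tests use the study's design size (n = 86, k = 3) with 300–
500 replicates for recovery, 800–1000 for coverage, and 1000 random grids
(n ≤ 10, k ≤ 4) for oracle-equivalence checks; brute-force bracket
enumeration covers the full response space of every domain (≤ 36 864
combinations). The whole suite runs in well under a minute.

## Known limitations

- Item wordings are best-effort transcriptions of the printed row labels;
  the full instrument booklet is not reproduced.
- The published banded overall counts (53/4/3 at cuts 0.4/0.7) exceed by one
  what the 59 printed per-item estimates yield (52/4/3); the package
  reproduces what the printed values imply and the discrepancy is surfaced,
  not absorbed.
- Regional reliability rows and mean score tables reproduce in structure
  only; the raw multi-observer responses needed to reproduce their numbers
  are not publicly machine-readable.
- The agreement-form CI undercovers at k = 3 (see above).
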