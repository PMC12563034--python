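# Methods

## Data model and units

A line list has one row per suspected adverse drug reaction (ADR); rows
sharing an `icsr_id` belong to one individual case safety report (ICSR).
Reaction terms are handled at MedDRA system-organ-class (SOC) level only —
26 analysis classes plus "social circumstances", which is never analysed.
All contingency, residual, ROR and CA computations count **reactions**;
case-level (ICSR) tallies are used only for population descriptives, where
`summarize(unit="icsr")` collapses each case to its demographics and its
worst seriousness/outcome (fatal > not recovered > recovered with sequelae >
recovering > recovered > unknown > not specified). The precedence order is a
package choice; the public aggregates do not document how multi-reaction
cases were collapsed.

Exclusion filters: the overall pass drops social-circumstance reactions;
the fatal-only pass keeps fatal reactions and additionally drops ear and eye
disorders, investigations, surgical/medical procedures and product issues —
SOCs in which a fatal outcome is implausible or explained by other
conditions. The fatal list is configurable (`FilterSpec`) since the set is
conventional rather than canonical. Descriptive summaries are computed
**before** exclusions so their totals match the raw extract; all
contingency-based stages run after them.

## Reporting odds ratio

`ROR = (a/b)/(c/d)` on the 2×2 report-count table; the comparator is always
"all other drugs in the analysis set", making every profile a within-dataset
contrast. The 95% interval is Woolf's log-normal interval,
`exp(ln ROR ± z·SE)`, `SE = √(1/a+1/b+1/c+1/d)` — the field standard for
disproportionality screening. Any zero cell triggers the Haldane–Anscombe
correction (+0.5 added to **all four** cells) and is flagged `corrected`.
Drug-level seriousness/fatality odds ratios use the same machinery with
"not specified" seriousness counted as non-serious by default
(configurable). No multiplicity adjustment is applied; the RORs are
screening statistics, not hypothesis tests.

Drug-level odds ratios computed from the published aggregate margins (e.g.
rivaroxaban serious ≈ 2.05, dabigatran fatal ≈ 1.63, edoxaban serious
≈ 0.18) are method-identical to, but numerically different from, previously
circulated point estimates for these drugs, which evidently used an
undisclosed exclusion or unit convention; this package treats the printed
*shares* as the exact reproduction surface and asserts only direction and
vicinity for the aggregate ORs.

## Indexed residuals

`E = R·C/n` cell-wise and `r = 100·(O−E)/E`. The relative (not absolute)
form is forced by the published tables, which are percentages with exact
−100.0% entries at never-reported pairs. Zero-margin rows/columns are
dropped with a warning before computation (fatal-only tables routinely lose
SOCs entirely); a table left empty is an error. Exported percentages are
rounded half-away-from-zero to one decimal; raw values are kept internally.

## Correspondence analysis

From-scratch SVD formulation: `P = O/n`, masses `r, c`,
`S = (P − r cᵀ)/√(r cᵀ)`, `S = U Σ Vᵀ` truncated to `K = min(I,J)−1`
dimensions. Principal coordinates `F = D_r^{-1/2} U Σ` (SOCs),
`G = D_c^{-1/2} V Σ` (drugs); inertias `λ_k = σ_k²` sum to χ²/n;
contributions `ctr_row[i,k] = r_i F[i,k]²/λ_k` (columns analogous).

Numerical choices:

- **Sign convention.** SVD signs are fixed by forcing the
  largest-magnitude row loading of each dimension positive, so repeated
  fits are bit-identical.
- **Biplot scaling.** Contribution biplot: drugs as points in principal
  coordinates, SOCs as vectors whose coordinates are the left singular
  vectors `U` (standard coordinates scaled by √mass), giving
  `B[i,k]² = ctr_row[i,k]` exactly — vector length literally encodes
  contribution.
- **Degenerate input.** An exactly independent table is valid: all σ = 0,
  zero coordinates, zero contributions (not 0/0). Singular values below
  1e-14 are treated as zero.
- **Dimension retention.** Average-inertia rule: keep the leading
  dimensions whose inertia share exceeds `1/K`, with a floor of two so a
  biplot is always drawable.
- **Variable importance.** Contributions are aggregated over the retained
  dimensions as the inertia-weighted mean, compared against the uniform
  expectation `1/(number of SOCs)`; top-n ties break lexicographically on
  SOC code. The aggregation rule is a package choice — no standard exists
  for combining per-dimension contributions.

The published two-dimension variance shares for the full extract
(≈53% + 26% overall, ≈85% fatal) depend on the complete drug × SOC count
matrix, which is not public at cell level; they are therefore not asserted
numerically. The CA property suite (inertia = χ²/n to 1e-9, contribution
closure, χ²-distance geometry, eigen-oracle agreement) plus synthetic
recovery stand in for them; on the default synthetic scenario the two
retained dimensions capture ≈78–86% of inertia, the same regime.

## Synthetic ICSR generator

What it emulates: per-drug report volumes, multinomial SOC profiles with
planted similarity clusters, per-reaction seriousness and fatal-outcome
Bernoulli draws, a truncated-geometric reactions-per-case distribution, and
case-level age/sex/country categoricals. What it does **not** emulate:
duplicate and stimulated reporting, under-reporting, exposure denominators,
reaction-term granularity below SOC, or any pharmacology (dose, indication,
interactions). Passing recovery tests therefore show the *pipeline*
identifies structure it was designed to measure, not that real
spontaneous-report data are this clean.

Defaults (the study conditions, chosen once):

- per-drug reaction volumes = the published per-drug totals ÷ 100
  (warfarin 811, acenocumarol 173, dabigatran 871, rivaroxaban 1726,
  apixaban 671, edoxaban 61; ≈4,300 reactions in ≈2,400 cases) so the full
  pipeline runs in seconds;
- per-drug seriousness (0.709–0.955) and fatality (0.060–0.124)
  probabilities = the published per-drug shares;
- reactions per case ~ geometric with mean 1.77 (the published
  reactions-to-cases ratio) truncated at 10;
- age/sex categoricals = the published pooled distributions; country is a
  small categorical including an empty level (non-EEA);
- two archetypes with mixing `profile = α·archetype + (1−α)·global mean`,
  `α = 1` by default: a VKA-like profile (investigations ×3,
  pregnancy-related ×6, injury/poisoning ×1.6 over the base weights,
  reflecting INR-monitoring-driven reporting) and a NOAC-like profile
  (gastrointestinal ×1.7, nervous system ×1.5, reflecting bleeding-site
  reporting). Base SOC weights put ≈30% of mass on gastrointestinal plus
  nervous-system reactions, as in anticoagulant safety data.

Determinism: a single `numpy` generator seeded from the config; identical
config ⇒ byte-identical line list. The emitted ground truth (realized
counts and rates) is an exact recount of the emitted rows.

## Problem sizes in tests and the acceptance script

Property suites run on randomly drawn small tables (≤ 8×8, 100 draws) and
the exhaustive 2×2 grid with cells in 1..6. Recovery runs use 20 replicates
of six drugs × 26 SOCs at 4,000 reactions per drug (≈24,000 reactions
each), at which the planted archetype split is recovered essentially always
and the planted odds ratios land inside their 95% intervals at the nominal
rate. These sizes are the package's chosen study conditions for synthetic
validation.

## Known limitations

- SOC-level coding only; no preferred-term analysis, hence no signal
  localization below organ-class level.
- No de-duplication beyond `icsr_id` grouping; follow-up versions of a case
  are assumed pre-merged.
- The ROR carries all the usual spontaneous-reporting caveats (no exposure
  denominator, reporting biases); the package computes it, it does not
  validate causality.
- CA coordinates are descriptive; no confidence regions or bootstrap are
  provided.
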