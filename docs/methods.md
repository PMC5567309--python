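# Methods

## The procedure and its assumptions

The pipeline treats candidate discovery as a fixed, auditable filter
cascade over set-valued evidence rather than a fitted model. Its inputs
are per-study lists of differentially abundant proteins with a regulation
direction, a pathway database with an optional parent hierarchy,
transcriptomics concept signatures, a confidence-scored protein-interaction
edge list, a tissue-expression table and free-text functional annotations.

Assumptions worth stating explicitly:

* **Direction conflicts are irresolvable.** A gene reported up in one
  study and down in another is removed outright; no majority vote and no
  use of fold changes to break ties (fold change and p-value columns are
  carried as provenance only). Within one study, duplicate rows with the
  same direction collapse silently; with opposite directions they are a
  malformed table and raise.
* **Enrichment is one-sided.** The retention decisions are all about
  over-representation, so the default statistic is the exact hypergeometric
  upper tail P(X ≥ k). A two-sided Fisher option (`laterality="two-sided"`)
  exists for parity with tools whose reports label the statistic
  two-sided; it changes p-values, never the coverage arithmetic.
* **The universe defaults to the pathway database.** N is the number of
  genes appearing in at least one pathway of the loaded GMT; input genes
  outside it are dropped from n with a warning, as in standard ORA
  practice. An explicit universe list can be supplied instead, in which
  case every pathway member must belong to it.
* **Bonferroni is applied over pathways actually tested** — those with at
  least `min_overlap` input genes (default 3). The family size m is
  recorded on every result for auditability. This is deliberately
  conservative; no FDR option is offered because the downstream funnel
  consumes a hard retained/not-retained decision.
* **Concept association is an exact 2×2 test.** Cells are a = predicted ∩
  concept, b = predicted\concept, c = concept\predicted, d = remainder of
  the universe (the same N as enrichment, for internal consistency). The
  odds ratio is the cross-product ad/bc with Haldane +0.5 on all cells
  whenever any cell is zero; without correction a zero denominator is
  reported as infinite with a warning, never silently. The p-value is the
  two-sided Fisher exact (minimum-likelihood) probability; a hypergeometric
  upper-tail alternative is available since the statistic behind concept-
  association services is not documented. Concept direction is not matched
  against protein regulation direction.
* **"Pertinent" interactions are counted within the gene's own pathway
  groups.** The structural filter counts distinct partners with edge score
  ≥ 0.9 that co-occur in at least one of the gene's source groups, passing
  at degree > 1 or group membership > 1 (inclusive or). A
  `global_degree` switch counts partners network-wide instead.
* **The functional screen is a transparent keyword match**, replacing
  manual curation of protein-function databases: case-insensitive
  substring matching of configurable phrase lists for five categories
  (immunity/autoimmunity, blood-pressure regulation, vascular injury,
  oxidative stress, ECM remodelling). Genes missing from the expression or
  annotation tables are conservatively dropped/unmatched, never imputed.

Two analysis arms are supported: the full input, and the input minus a
user-supplied plasma-protein list. Pathway expansion and the funnel run on
the union of both arms' retained pathways, with the full integrated set as
the "already known" input subtracted from the predicted pool. The funnel
stages apply in a fixed order (expansion → concept hit → tissue expression
→ structural → keyword); because every stage after expansion is a per-gene
predicate, the final candidate set is order-independent, and the stage
counts are non-increasing by construction.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | significance level on Bonferroni-adjusted p |
| `min_overlap` | 3 | minimum input genes for a pathway to be tested |
| `laterality` | `upper` | enrichment tail (`upper` or `two-sided`) |
| `or_min` | 2.0 | odds-ratio threshold for concept retention |
| `p_run` / `p_retain` | 1e−4 / 0.05 | concept p thresholds, applied conjunctively (the stricter binds); both kept configurable because their interplay in the source workflow is unstated |
| `min_overlap_genes` | 3 | minimum predicted∩concept genes |
| `min_score` | 0.9 | PPI confidence cutoff ("highest confidence") |
| `tissue` | `kidney` | expression-table tissue used by the filter |

## The synthetic-data generator

`SimulationConfig` defines the study conditions; one seeded generator
derives every file, so a fixed config reproduces the bundle byte for byte.
Defaults emulate a nine-study urinary-proteomics integration at a reduced
universe of 2 000 genes:

* `study_detection_rate=0.015` — each study detects ~30 background genes;
  the nine-study union lands near 250–320 distinct proteins, the scale of
  a few-hundred-protein integrated input;
* `down_fraction=0.7` — the 70/30 down/up skew of such inputs;
* `conflict_rate=0.2` *of the genes shared by ≥ 2 studies* (the only genes
  for which a conflict is defined); with the small shared pool this yields
  a handful of conflicted genes per bundle, matching a 4-in-236 scale;
* `plasma_rate=0.18` — the exclusion list covers roughly a fifth of the
  input (42-of-232 scale);
* 50 pathways of 10–60 members, 5 of them planted: a `planting_strength`
  fraction (default 0.6) of each planted pathway's members is injected
  into one to three study lists. Planted pathways receive 0–2 child
  pathways sharing ≥ 50% of their members, to exercise parent merging;
* 12 concepts sized by tier (top 1/5/10% of the universe), 5 of them
  "disease" concepts that copy a `concept_overlap_strength` fraction of
  the planted members;
* a PPI network dense inside planted pathways (`ppi_within_density=0.25`)
  and sparse elsewhere (`ppi_background_density=0.001`), scores uniform on
  `ppi_score_range`;
* an expression table marking `expression_coverage` (0.7) of genes as
  kidney-detected, with ~3% of genes absent from the table entirely, and
  annotations where ~5% of background genes carry a decoy keyword.

Per planted pathway, three members that appear in **no** study list are
designated *planted relevant genes*: they are force-included in every
disease concept, marked kidney-expressed, wired to two co-members at
score ≥ 0.9, and given a category keyword with probability
`keyword_hit_rate`. These genes can surface only through pathway
expansion, so their funnel survival measures end-to-end recovery.

What the generator does **not** emulate: mass-spectrometry signal or
abundance distributions, peptide-level evidence, identifier-mapping noise,
patient covariates, correlated study biases, or real gene nomenclature
(symbols are synthetic `G000001…` tokens). Passing recovery tests
therefore demonstrate the pipeline's logic and statistics, not robustness
to the messiness of real curated databases.

## Numerical choices

* Hypergeometric tails are evaluated through the log-space survival
  function; two-sided Fisher through the exact minimum-likelihood sum.
  Tests verify both against exhaustive rational-arithmetic enumeration
  (exact to < 1e−12 over all margins N ≤ 24 and sampled margins to N = 60).
* Coverage percentages are reported rounded half-up to two decimals
  (`Decimal` quantization, not banker's rounding); the raw ratio is kept
  internally and satisfies coverage·K/100 = k exactly.
* Result ordering is deterministic everywhere (p then id for enrichment
  and concepts; gene id for traces); ties in parent-group resolution are
  impossible because each pathway has one ultimate root, and hierarchy
  cycles raise.
* Degenerate inputs: empty record lists, empty databases, empty universes,
  impossible contingency margins and unknown tissues raise with named
  messages; an empty predicted pool produces a valid all-zero funnel
  report rather than an error.

## Problem sizes used by the test suite and acceptance script

Unit and property tests run on handcrafted micro-fixtures. Recovery is
measured on 20 seeded bundles of a *strong-effect* configuration —
universe 800, 30 pathways of 15–40 members, detection 0.01,
`planting_strength=0.8`, `concept_overlap_strength=0.6`,
`keyword_hit_rate=1.0` — chosen by a power analysis so that every planted
pathway has comfortable hypergeometric separation from background after
Bonferroni; at weaker settings (e.g. 10-member planted pathways against a
~150-gene input) the exact test rightly lacks power and recovery of the
smallest pathways becomes marginal. The acceptance script runs the same
configurations, deriving all seeds from its `--seed` argument.

## Known limitations

* Bonferroni over the tested family is conservative when many pathways
  overlap heavily (parent/child redundancy inflates m).
* The keyword screen approximates expert functional curation; its
  precision depends entirely on the supplied phrase lists.
* Odds ratios with Haldane correction are biased toward the null for very
  small cells; they are used only as a threshold, never interpreted as an
  effect estimate.
* The concept stage tests each concept marginally; overlapping concepts
  are not de-correlated, and the hit union can be dominated by one large
  concept.
* With `approach="no_plasma"` alone, expansion subtracts only the reduced
  input, so proteins excluded as plasma-like can reappear as predicted
  candidates; run `approach="both"` (the default) to subtract the full
  input.
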