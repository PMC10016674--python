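# Methods

This note records the model assumptions, defaults, numerical choices and
known limitations behind `cosegscan`. It documents how quantities are
computed; every number it mentions is produced by the test suite or the
package itself.

## Variant identity

Variants are keyed by (chrom, pos, ref, alt) after multi-allelic records are
decomposed into one variant per ALT allele. Decomposition happens at read
time because all identity semantics are per-allele; no further
normalization (left-alignment, trimming) is performed, so callers that
represent the same indel differently will only match through the interval
rule below.

Structural classes partition all (ref, alt) pairs: SNV (1 bp → 1 bp),
insertion (alt extends ref as a prefix), deletion (ref extends alt as a
prefix), complex (everything else). Symbolic alleles are rejected.

**SNV identity** is exact key equality. **Indel identity** is fractional
interval overlap: a deletion or complex variant occupies the 0-based
half-open span of its reference allele, `[pos−1, pos−1+len(ref))`; an
insertion occupies a 1 bp anchor `[pos−1, pos)`. Two indels are the same
event when the shared span exceeds `min_frac` (default 0.10) of *both*
intervals — the reciprocal form is a deliberate choice to make identity
symmetric, which the within-family intersection properties require; an
asymmetric single-sided rule would make the consensus depend on argument
order. The inequality is strict: a fraction of exactly 0.10 does not match.
When several candidates pass, the greedy maximum-overlap partner is chosen,
ties broken leftmost, so output is deterministic.

## Consensus and hard filter

The hard filter retains calls with caller quality ≥ 30 and read depth ≥ 10.
These defaults are conventional short-read exome thresholds and are plain
config keys (`qual_min`, `depth_min`); calls missing either value fail when
the corresponding threshold is positive, on the view that a call unable to
demonstrate its quality is not high-confidence. Consensus requires allele
identity only — genotype concordance between callers is *not* required, and
annotations/genotypes are taken from the first caller's representation with
the partner recorded as provenance.

## Censored frequencies

Public-database allele frequencies are often reported only as bounds
("<0.001"). These are modelled as (value, censored) pairs with explicit
ordering semantics: a censored `<v` is definitely below threshold `t` iff
`v ≤ t`; otherwise the comparison is indeterminate and raises rather than
guesses. Consequences:

- the 1% rarity filter resolves all censored annotations whose bound is at
  or below 0.01 — an annotation censored at a bound *above* the threshold
  aborts the run naming the variant, instead of silently passing it;
- the censoring-aware median identifies the set of elements that could
  occupy the median rank under *any* ordering consistent with the
  censoring (via definite pairwise comparisons: censored `<v` is
  definitely below uncensored `u` iff `v ≤ u`; censored-censored and
  uncensored-below-censored pairs are never definite). If all candidates
  agree — one uncensored value, or censored values sharing one bound — that
  is the median, reported censored or not accordingly; otherwise the median
  is genuinely undefined and an error is raised;
- quartile summaries (IQR) use numpy's linear interpolation with censored
  values placed at their bounds; whenever a censored value contributes to a
  quartile the IQR is flagged as an upper bound. The quartile convention is
  named in the output because different conventions give materially
  different IQRs on 13-element lists.

## The filter cascade

Stage order: rarity → conservation → impact → missense deleteriousness.
Each stage is a pure predicate of the variant's annotations, so the cascade
is order-independent over its input and idempotent; the ledger telescopes
(removed + surviving = input at each stage) by construction and by test.

- **Rarity**: removed if ≥ 1% in *either* gnomAD popmax or TOPMed
  (equivalently, retained only when below 1% in both). Absent annotations
  pass, logged — a variant absent from the databases cannot be shown to be
  common.
- **Conservation**: retained if PhastCons-7-way strictly exceeds 0.1.
  Indels frequently lack scores; they pass by default (configurable),
  since conservation annotation coverage for indels is patchy.
- **Impact**: retained if the impact tier is high or moderate. When only a
  consequence term is annotated, a packaged consequence→tier table is used
  (stop-gained/frameshift/splice-disrupting/start- and stop-lost → high;
  missense/inframe/protein-altering → moderate; synonymous/intronic/UTR/
  up-downstream → low/modifier). The table approximates the
  "impactful" classification used by annotation tools, whose exact
  versioned term list is not standardized; it is config-overridable, and
  unknown terms raise rather than default.
- **Missense**: excluded only when SIFT says tolerated *and* PolyPhen says
  benign. The conjunctive reading is a deliberate design decision: the
  reference candidate table retains variants that are tolerated-by-SIFT
  but probably-damaging-by-PolyPhen and vice versa, which the disjunctive
  reading would delete (the acceptance suite demonstrates exactly this
  discrimination).

## Family co-segregation

Within a family, the member callsets are intersected sequentially
(fold-left) in family-table order, using the consensus identity rules. The
first member's representation is carried as the representative. For
SNV-only inputs this is permutation-invariant; for indels the chained
interval rule can in principle depend on member order (overlap is not
transitive), which is why the representative rule is fixed and tested
against an all-members brute-force matcher. Genotype equality across
members is not required — carrier status suffices.

Cross-family overlap is at gene level (symbol equality), not allele level,
because different families overwhelmingly segregate different alleles of a
shared gene. The multi-family threshold defaults to 2 families.

## Gene burden

Qualifying variants are the cascade survivors. Case carriers per gene:
dominant = samples with ≥ 1 qualifying allele; recessive = samples with
≥ 2 (hom-alt counts two; two het sites in one gene count as a putative
compound het — phase is unobserved, so no cis/trans distinction is
attempted). Controls provide only aggregate allele counts, so control
carriers are *expected* counts under site independence:
dominant `N·(1 − Π(1 − af_i))`, recessive `N·(Σ af_i)²` (Hardy–Weinberg),
each rounded half-up to an integer because the exact test needs integer
cells. Both formulas are approximations: they ignore linkage between sites
and treat the per-site allele frequency as a per-individual carrier
probability. Control sites contribute only if the fraction of
well-covered control samples at the position is ≥ 0.90 (inclusive — the
conventional reading of a "90% of samples" QC rule).

The two-sided Fisher exact p-value is the sum of hypergeometric
probabilities, at the observed margins, of all tables no more probable
than the observed one, with a relative slack of 1e-7 when comparing
probabilities so floating-point representations of exactly tied
opposite-tail tables are included. The implementation works in log space
(log-gamma binomials); tests verify it against exact integer-arithmetic
enumeration (|Δp| < 1e-9 over all tables with margins ≤ 30) and against an
independent library implementation on random tables. Reported alongside
the raw p-values is a Bonferroni column over the number of genes tested,
since collapsing tests are usually screened unadjusted at p < 0.05 but
readers differ on correction policy.

Under matched case/control carrier frequencies the test is conservative:
on 1,000 simulated null genes the fraction reaching p < 0.05 (counting
carrier-free genes as p = 1) is about 0.02, against the ≤ 0.07 bound the
suite asserts.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
`P(X ≥ k)` with the universe defaulting to all genes annotated in the term
database (overridable). Adjustment is Benjamini–Hochberg by default, with
Bonferroni optional; the structure-aware g:SCS correction used by some
web services has no published closed form and is deliberately not
imitated — output headers state the method used. The two-analysis
comparison reports terms with raw p below a display threshold (default
0.01) in both runs, and the per-term gene-count increase is tested with a
one-sided two-sample proportion z-test with Yates continuity correction
(pooled variance; degenerate pooled proportions return p = 1). The
continuity correction is not capped at the observed difference, so for
near-equal proportions the statistic is conservative relative to
implementations that cap it.

## Synthetic cohorts

The generator's defaults mirror the study design the package targets: ten
families with member counts (2,2,3,2,2,2,2,2,2,2) — 21 samples — six genes
planted with co-segregating deleterious variants in ≥ 2 families (one gene
in three families; distinct alleles per family, as observed in real
multi-family candidates), two additional family-private planted variants
per family, and 400 background variants. Background variants are
constructed to drop out at exactly one stage: ~15% are private to one
caller (removed at consensus), ~15% private to one family member (removed
at the family intersection), and the rest violate exactly one cascade
criterion in rotation, so every filter is exercised on every default run.
Rare allele frequencies are drawn from Beta(0.5, 800) (clipped below 1%),
common ones from Beta(2, 8) (clipped above 1%), so the 1% threshold
meaningfully bisects the two populations; draws below 0.001 are emitted in
the censored "<0.001" dialect. Caller quality is uniform on [50, 200] and
depths on [15, 80), comfortably above the hard filter, so planted-variant
recovery isolates the intersection/cascade logic rather than the QC
thresholds. The seed fully determines the output, byte-for-byte.

What the generator does *not* emulate: read-level errors, linkage
disequilibrium, pedigree transmission beyond "shared by designated
members", annotation disagreement between callers, or indel representation
drift between callers (planted indels are identically represented in
both). Passing the planted-recovery suite therefore demonstrates the
pipeline's set logic and filter correctness, not robustness to caller
representation differences — real data would exercise the interval-overlap
matcher harder than the generator does, which is why that matcher is
additionally tested against brute-force oracles on adversarial random
intervals.

The null-burden generator emits one site per gene with a control allele
frequency log-uniform on roughly [6×10⁻⁴, 0.16] and case carriers drawn
binomially at exactly the control frequency; any excess of small p-values
is then attributable to the test itself.

## Problem sizes and determinism

The shipped suites run at deliberately modest scale — cohorts of 21
samples with a few hundred background variants, 20 seeds for the
recovery property, 1,000 null genes for calibration, exhaustive
enumeration up to margins of 30 (Fisher) and universes of 50
(hypergeometric) — sizes at which the exhaustive oracles are exact and the
whole suite completes in seconds. All randomness flows from explicit seeds
(numpy `default_rng`), and property tests are derandomized.

## Known limitations

- No left-alignment/normalization: callers must agree on representation
  for SNV identity; indels get the fractional-overlap tolerance only.
- The recessive model's compound-het counting is phase-blind and will
  overcount alleles in cis.
- Control carrier expectations assume site independence and
  Hardy–Weinberg; for genes with many qualifying sites the dominant
  expectation is slightly conservative and the recessive one slightly
  anti-conservative.
- The censored-median error on genuinely ambiguous patterns is a feature,
  but it means pipelines feeding adversarially censored data must be
  prepared to catch it.
- Enrichment treats the input GMT as already propagated; no ontology-graph
  reasoning is performed.
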