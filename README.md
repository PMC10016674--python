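# cosegscan

Rare-variant co-segregation and gene-burden prioritization for whole-exome
studies of multiply affected families.

`cosegscan` is built for the situation where a rare disease clusters in
small pedigrees — pairs and trios of affected relatives — and the question
is which genes carry the damaging variants that travel with the phenotype.
It implements the full prioritization pipeline downstream of variant
calling:

1. **Dual-caller consensus.** Each sample is called by two independent
   pipelines; only variants detected by both are kept. SNVs must match
   exactly on (chrom, pos, ref, alt); indels are identified with each other
   when their genomic intervals reciprocally overlap by strictly more than
   10% of each interval's length.
2. **Deleteriousness cascade.** Consensus variants are filtered, in order,
   by population allele frequency (removed if ≥ 1% in either gnomAD popmax
   or TOPMed — censored annotations like `<0.001` are handled explicitly,
   never imputed), conservation (PhastCons 7-way > 0.1 retained), predicted
   impact (high/moderate consequences retained), and missense
   deleteriousness (removed only when *both* SIFT says tolerated *and*
   PolyPhen says benign). Every stage writes to a telescoping count ledger.
3. **Within-family co-segregation.** Surviving variants are sequentially
   intersected across all affected members of each family; a variant counts
   as co-segregating only if every sequenced member carries it.
4. **Cross-family gene overlap.** Genes with qualifying variants in two or
   more families (locus-level overlap — families typically carry different
   alleles of the same gene) are the primary candidates.
5. **Gene burden vs public controls.** A TRAPD-style collapsing test: per
   gene, case carriers (dominant: ≥ 1 qualifying allele; recessive: ≥ 2,
   hom or putative compound het) are compared against expected carrier
   counts derived from control allele frequencies
   (`N·(1 − Π(1 − af_i))` dominant, `N·(Σ af_i)²` recessive under
   Hardy–Weinberg), via a two-sided Fisher exact test.
6. **Term enrichment.** Hypergeometric over-representation of candidate
   gene lists in GO-MF/Reactome/CORUM/KEGG gene sets (GMT input), with
   BH or Bonferroni adjustment, plus a one-sided two-proportion z-test
   (with continuity correction) for comparing a term's gene counts between
   two analyses.

Because real familial exome data are access-controlled, the package ships a
first-class synthetic-cohort generator (`cosegscan.simulate`) that emits
caller-discordant VCF pairs, family tables, control allele-count tables and
gene sets together with a truth table stating where every generated variant
should drop out of the pipeline.

## Worked example

The packaged reference fixtures transcribe a published 21-participant,
ten-family cholesteatoma cohort and its 13 candidate co-segregating
variants:

```python
import cosegscan as cs
from cosegscan.datasets import load_cohort_table, load_candidate_table, candidate_family_sets

print(cs.summarize_cohort(load_cohort_table()))
# CohortSummary(n_participants=21, n_families=10, n_female=13, pct_female=62,
#               n_bilateral=6, pct_bilateral=29, median_age=11.0, age_range=(1.0, 63.0))

variants = [v for _, v in load_candidate_table()]
vs = cs.summarize_variants(variants)
print(vs.median_gnomad_af, vs.median_topmed_af, vs.n_conserved_high, vs.max_af_percent)
# 0.002 <0.001 12 0.5
```

The cohort is 62% female (13/21), 29% bilateral disease (6/21), median age
at diagnosis 11 (range 1–63). The candidate variants are rare — censoring-
aware median gnomAD popmax frequency 0.002, TOPMed median still censored
below 0.001, the most frequent allele seen in only 0.5% of the general
population — and conserved (12/13 with PhastCons > 0.9). All 13 survive the
filter cascade, and grouping them by family yields exactly six genes
recurring in two or more families:

```python
res = cs.apply_cascade(variants)
for row in res.ledger:
    print(row.stage, row.input_count, row.removed_count, row.output_count)
# rare_af 13 0 13 / conserved 13 0 13 / impactful 13 0 13 / missense_not_benign_tolerated 13 0 13

for h in cs.genes_in_multiple_families(candidate_family_sets()):
    print(h.gene, sorted(h.families, key=int))
# DENND2C ['1', '10']   DNAH7 ['2', '8']   NBEAL1 ['2', '9']
# NEB ['4', '8', '9']   PRRC2C ['2', '3']  SHC2 ['3', '4']
```

A full synthetic run, from VCFs on disk through the CLI:

```bash
cosegscan simulate --seed 7 -o sim/
cosegscan consensus --caller-a sim/1a.callerA.vcf --caller-b sim/1a.callerB.vcf \
    --sample-id 1a -o 1a.consensus.vcf
cosegscan filter 1a.consensus.vcf --sample-id 1a -o 1a.filtered.vcf --ledger 1a.ledger.json
```

## Layout

- `src/cosegscan/types.py` — domain types (censored frequencies, variants,
  callsets, cohorts)
- `src/cosegscan/vcfio.py` — VCF/tabular readers and writers
- `src/cosegscan/consensus.py` — dual-caller intersection
- `src/cosegscan/cascade.py` — the deleteriousness filter cascade
- `src/cosegscan/cosegregation.py` — family sharing, multi-family genes
- `src/cosegscan/burden.py` — collapsing burden test, Fisher exact
- `src/cosegscan/enrich.py` — term over-representation
- `src/cosegscan/report.py` — censoring-aware summaries
- `src/cosegscan/simulate.py` — synthetic cohorts with truth tables
- `docs/methods.md` — models, assumptions, numerical choices
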