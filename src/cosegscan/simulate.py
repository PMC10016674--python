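"""Synthetic multi-family exome cohorts with a machine-readable truth table.

Real familial-exome data live behind controlled access, so every pipeline
stage is exercised on generated cohorts instead. The generator emulates the
study design it mirrors: ten multiply affected families of two or three
sequenced members each (21 samples), two discordant caller outputs per
sample, co-segregating deleterious variants planted in both callers for all
members of their designated families, and benign background variants each
constructed to fail exactly one pipeline stage — removed at consensus
(caller-private), at one of the four cascade filters, or at the within-family
intersection (member-private). Population frequencies below the censoring
threshold are emitted in the ``"<0.001"`` dialect.

The accompanying :class:`TruthTable` records, for every generated variant,
where it should drop out — so planted-variant recovery can be asserted
exactly, with zero tolerance for false positives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .enrich import TermGeneSet, write_gmt
from .types import (
    AnnotatedVariant,
    CensoredFrequency,
    FamilyCohort,
    Phenotype,
    SampleCallset,
    VariantCall,
)
from .vcfio import (
    ControlSiteRecord,
    write_callset_vcf,
    write_control_table,
    write_family_table,
)

__all__ = [
    "SyntheticCohortConfig",
    "TruthTable",
    "SyntheticCohort",
    "generate_cohort",
    "generate_null_burden",
]

_GENE_WINDOW = 100_000
_POS_STEP = 50

# stages at which a background variant is designed to drop out
BACKGROUND_MODES = (
    "caller_private",   # consensus removes it
    "common_af",        # cascade stage 1
    "low_conservation", # cascade stage 2
    "low_impact",       # cascade stage 3
    "benign_missense",  # cascade stage 4
    "member_private",   # family intersection removes it
)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study-design parameters of a generated cohort.

    Defaults mirror the cohort layout under study: ten families with member
    counts (2,2,3,2,2,2,2,2,2,2) — 21 samples — six genes planted with
    co-segregating deleterious variants in two or more families (distinct
    alleles per family), plus per-family private planted variants, benign
    background variation, ~15% caller discordance, and frequency censoring
    below 0.001.
    """

    n_families: int = 10
    members_per_family: tuple[int, ...] = (2, 2, 3, 2, 2, 2, 2, 2, 2, 2)
    n_genes: int = 80
    n_background_variants: int = 400
    n_planted_genes_multifamily: int = 6
    n_planted_per_family: int = 2
    caller_discordance_rate: float = 0.15
    indel_fraction: float = 0.10
    censor_threshold: float = 0.001
    rare_beta_params: tuple[float, float] = (0.5, 800.0)
    common_beta_params: tuple[float, float] = (2.0, 8.0)
    control_n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.members_per_family) != self.n_families:
            raise ValueError("members_per_family length != n_families")
        if any(m < 2 for m in self.members_per_family):
            raise ValueError("every family needs >=2 members")
        for name in ("caller_discordance_rate", "indel_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        n_private_genes = self.n_families * self.n_planted_per_family
        if self.n_planted_genes_multifamily + n_private_genes > self.n_genes:
            raise ValueError(
                "more planted genes than genes: "
                f"{self.n_planted_genes_multifamily} multi-family + "
                f"{n_private_genes} private > {self.n_genes}"
            )


@dataclass
class TruthTable:
    """What was planted where, and where each background variant should die."""

    planted: list[dict] = field(default_factory=list)
    background: list[dict] = field(default_factory=list)

    @property
    def expected_multifamily_genes(self) -> set[str]:
        by_gene: dict[str, set[str]] = {}
        for p in self.planted:
            by_gene.setdefault(p["gene"], set()).update(p["families"])
        return {g for g, fams in by_gene.items() if len(fams) >= 2}

    def to_json(self) -> str:
        return json.dumps(
            {"planted": self.planted, "background": self.background}, indent=1
        )


@dataclass
class SyntheticCohort:
    """A fully specified generated cohort plus its truth table."""

    config: SyntheticCohortConfig
    cohort: FamilyCohort
    callsets: dict[str, dict[str, SampleCallset]]  # sample -> caller_tag -> callset
    controls: list[ControlSiteRecord]
    terms: list[TermGeneSet]
    truth: TruthTable

    def write_to_dir(self, outdir: str | Path) -> None:
        """Emit VCFs, family table, control table, GMT and truth JSON."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for sample, by_caller in self.callsets.items():
            for tag, cs in by_caller.items():
                write_callset_vcf(cs, out / f"{sample}.{tag}.vcf")
        write_family_table(self.cohort, out / "families.tsv")
        write_control_table(self.controls, out / "controls.tsv")
        write_gmt(self.terms, out / "terms.gmt")
        (out / "truth.json").write_text(self.truth.to_json())


def _gene_symbols(n: int) -> list[str]:
    return [f"GENE{i + 1:04d}" for i in range(n)]


def _gene_locus(i: int) -> tuple[str, int]:
    chrom = f"chr{(i % 22) + 1}"
    return chrom, 1_000_000 + i * _GENE_WINDOW


def _draw_rare_af(rng: np.random.Generator, cfg: SyntheticCohortConfig) -> CensoredFrequency:
    a, b = cfg.rare_beta_params
    af = float(np.clip(rng.beta(a, b), 1e-7, 0.009))
    if af < cfg.censor_threshold:
        return CensoredFrequency(cfg.censor_threshold, censored=True)
    return CensoredFrequency(round(af, 6))


def _draw_common_af(rng: np.random.Generator, cfg: SyntheticCohortConfig) -> CensoredFrequency:
    a, b = cfg.common_beta_params
    af = float(np.clip(rng.beta(a, b), 0.01, 0.999))
    return CensoredFrequency(round(af, 6))


def _alleles(rng: np.random.Generator, want_indel: bool) -> tuple[str, str]:
    bases = "ACGT"
    if not want_indel:
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
        return ref, alt
    anchor = bases[rng.integers(4)]
    tail = "".join(bases[rng.integers(4)] for _ in range(1 + int(rng.integers(6))))
    if rng.random() < 0.5:
        return anchor, anchor + tail  # insertion
    return anchor + tail, anchor      # deletion


def _deleterious_annotations(
    rng: np.random.Generator, is_indel: bool
) -> dict:
    """Annotation set guaranteed to pass the impact and missense stages."""
    if is_indel or rng.random() < 0.1:
        return {"consequence": "stop_gained", "impact_tier": "high",
                "sift_label": None, "polyphen_label": None}
    sift = "deleterious" if rng.random() < 0.7 else "tolerated"
    pph = "probably_damaging" if rng.random() < 0.7 else "possibly_damaging"
    if sift == "tolerated":
        pph = "probably_damaging"  # keep at least one damaging verdict
    return {"consequence": "missense", "impact_tier": "moderate",
            "sift_label": sift, "polyphen_label": pph}


class _PositionAllocator:
    """Unique, deterministic positions inside each gene's window."""

    def __init__(self) -> None:
        self._next: dict[int, int] = {}

    def take(self, gene_index: int) -> tuple[str, int]:
        k = self._next.get(gene_index, 0)
        self._next[gene_index] = k + 1
        chrom, base = _gene_locus(gene_index)
        return chrom, base + k * _POS_STEP


def _passing_variant(
    rng: np.random.Generator,
    cfg: SyntheticCohortConfig,
    gene: str,
    chrom: str,
    pos: int,
    is_indel: bool,
) -> AnnotatedVariant:
    ref, alt = _alleles(rng, is_indel)
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        qual=float(np.round(rng.uniform(50, 200), 1)),
        gene=gene,
        gnomad_popmax_af=_draw_rare_af(rng, cfg),
        topmed_af=_draw_rare_af(rng, cfg),
        nfe_af=_draw_rare_af(rng, cfg),
        phastcons7=None if is_indel and rng.random() < 0.5
        else round(float(rng.uniform(0.92, 1.0)), 3),
        **_deleterious_annotations(rng, is_indel),
    )


def _background_variant(
    rng: np.random.Generator,
    cfg: SyntheticCohortConfig,
    mode: str,
    gene: str,
    chrom: str,
    pos: int,
) -> AnnotatedVariant:
    # cascade-failure modes are kept as SNVs so each annotation is meaningful
    is_indel = mode in ("caller_private", "member_private") and (
        rng.random() < cfg.indel_fraction
    )
    v = _passing_variant(rng, cfg, gene, chrom, pos, is_indel)
    if mode == "common_af":
        common = _draw_common_af(rng, cfg)
        if rng.random() < 0.5:
            return _replace_variant(v, gnomad_popmax_af=common)
        return _replace_variant(v, topmed_af=common)
    if mode == "low_conservation":
        return _replace_variant(v, phastcons7=round(float(rng.uniform(0, 0.1)), 3))
    if mode == "low_impact":
        return _replace_variant(
            v, consequence="synonymous", impact_tier="low",
            sift_label=None, polyphen_label=None,
        )
    if mode == "benign_missense":
        return _replace_variant(
            v, consequence="missense", impact_tier="moderate",
            sift_label="tolerated", polyphen_label="benign",
        )
    return v  # caller_private / member_private pass all annotation filters


def _replace_variant(v: AnnotatedVariant, **changes) -> AnnotatedVariant:
    fields = dict(
        chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, qual=v.qual,
        gene=v.gene, rsid=v.rsid, gnomad_popmax_af=v.gnomad_popmax_af,
        topmed_af=v.topmed_af, nfe_af=v.nfe_af, phastcons7=v.phastcons7,
        consequence=v.consequence, impact_tier=v.impact_tier,
        sift_label=v.sift_label, polyphen_label=v.polyphen_label,
    )
    fields.update(changes)
    return AnnotatedVariant(**fields)


def _make_phenotypes(
    rng: np.random.Generator, families: dict[str, list[str]]
) -> dict[str, Phenotype]:
    phen = {}
    for fam, members in families.items():
        for j, s in enumerate(members):
            phen[s] = Phenotype(
                age_at_diagnosis=float(rng.integers(1, 64)),
                age_is_surgery_proxy=bool(rng.random() < 0.2),
                bilateral=bool(rng.random() < 0.3),
                sex="female" if rng.random() < 0.6 else "male",
                relationship="Index" if j == 0 else "Relative",
            )
    return phen


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a full cohort: callset pairs, tables, gene sets, truth.

    Planted variants are present in both callers for all members of their
    designated families and pass every cascade filter by construction; each
    background variant is built to drop out at exactly one pipeline stage.
    The seed in the config fully determines the output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_symbols(cfg.n_genes)
    alloc = _PositionAllocator()

    family_ids = [str(i + 1) for i in range(cfg.n_families)]
    families = {
        fam: [f"{fam}{chr(ord('a') + j)}" for j in range(m)]
        for fam, m in zip(family_ids, cfg.members_per_family)
    }
    cohort = FamilyCohort(families=families, phenotypes=_make_phenotypes(rng, families))
    samples = cohort.sample_ids

    per_sample: dict[str, dict[str, list[VariantCall]]] = {
        s: {"callerA": [], "callerB": []} for s in samples
    }
    truth = TruthTable()

    def add_call(sample: str, v: AnnotatedVariant, callers: Sequence[str],
                 genotype: str = "het") -> None:
        call = VariantCall(
            variant=v, genotype=genotype, depth=int(rng.integers(15, 80))
        )
        for tag in callers:
            per_sample[sample][tag].append(call)

    # --- planted multi-family genes: distinct allele per family, all members
    multi_genes = genes[: cfg.n_planted_genes_multifamily]
    controls: list[ControlSiteRecord] = []
    for i, gene in enumerate(multi_genes):
        k = 3 if i == 0 else 2  # one gene recurs in three families
        fams = sorted(rng.choice(family_ids, size=k, replace=False).tolist(),
                      key=family_ids.index)
        for fam in fams:
            chrom, pos = alloc.take(i)
            is_indel = rng.random() < cfg.indel_fraction
            v = _passing_variant(rng, cfg, gene, chrom, pos, is_indel)
            for member in families[fam]:
                add_call(member, v, ("callerA", "callerB"))
            truth.planted.append({
                "key": list(v.key), "gene": gene, "families": [fam],
                "expected_to_survive_cascade": True,
            })
            controls.append(ControlSiteRecord(
                chrom=chrom, pos=pos, ref=v.ref, alt=v.alt,
                control_ac=int(rng.integers(0, 3)), control_an=2 * cfg.control_n,
                depth_pass_fraction=round(float(rng.uniform(0.92, 1.0)), 3),
            ))

    # --- planted single-family variants in family-unique genes
    gene_cursor = cfg.n_planted_genes_multifamily
    for fam in family_ids:
        for _ in range(cfg.n_planted_per_family):
            gi = gene_cursor
            gene_cursor += 1
            chrom, pos = alloc.take(gi)
            v = _passing_variant(
                rng, cfg, genes[gi], chrom, pos, rng.random() < cfg.indel_fraction
            )
            for member in families[fam]:
                add_call(member, v, ("callerA", "callerB"))
            truth.planted.append({
                "key": list(v.key), "gene": genes[gi], "families": [fam],
                "expected_to_survive_cascade": True,
            })

    # --- background variants, each with a designated removal stage
    n_bg = cfg.n_background_variants
    n_private = round(cfg.caller_discordance_rate * n_bg)
    n_member_private = round(0.15 * n_bg)
    n_cascade = max(0, n_bg - n_private - n_member_private)
    modes = (
        ["caller_private"] * n_private
        + ["member_private"] * n_member_private
        + [BACKGROUND_MODES[1:5][i % 4] for i in range(n_cascade)]
    )
    rng.shuffle(modes)
    removal_stage = {
        "caller_private": "consensus",
        "common_af": "rare_af",
        "low_conservation": "conserved",
        "low_impact": "impactful",
        "benign_missense": "missense_not_benign_tolerated",
        "member_private": "family_intersection",
    }
    for mode in modes:
        gi = int(rng.integers(0, cfg.n_genes))
        chrom, pos = alloc.take(gi)
        v = _background_variant(rng, cfg, mode, genes[gi], chrom, pos)
        fam = family_ids[int(rng.integers(0, cfg.n_families))]
        member = families[fam][int(rng.integers(0, len(families[fam])))]
        genotype = "hom_alt" if rng.random() < 0.1 else "het"
        if mode == "caller_private":
            caller = "callerA" if rng.random() < 0.5 else "callerB"
            add_call(member, v, (caller,), genotype)
        elif mode == "member_private":
            add_call(member, v, ("callerA", "callerB"), genotype)
        else:
            # must reach the cascade: present in both callers; shared by the
            # whole family half the time so cascade stages are also exercised
            # on family-shared variants
            carriers = families[fam] if rng.random() < 0.5 else [member]
            for m in carriers:
                add_call(m, v, ("callerA", "callerB"), genotype)
        truth.background.append({
            "key": list(v.key), "gene": v.gene, "mode": mode,
            "removed_at": removal_stage[mode],
        })

    callsets = {
        s: {
            tag: SampleCallset(sample_id=s, caller_tag=tag, calls=calls)
            for tag, calls in by_caller.items()
        }
        for s, by_caller in per_sample.items()
    }

    # --- term gene-sets: one term per planted multi-family gene cluster plus
    # random background terms, so enrichment has signal to find
    terms: list[TermGeneSet] = []
    terms.append(TermGeneSet(
        "GO:SYN0001", "planted multi-family module",
        frozenset(multi_genes), "GO_MF",
    ))
    for t in range(10):
        size = int(rng.integers(5, 15))
        members = rng.choice(genes, size=size, replace=False).tolist()
        terms.append(TermGeneSet(
            f"REAC:SYN{t + 2:04d}", f"background term {t + 1}",
            frozenset(members), "REAC",
        ))

    # depth-QC failures among control sites so site_qc is exercised
    for j in range(3):
        gi = cfg.n_genes - 1 - j
        chrom, pos = alloc.take(gi)
        controls.append(ControlSiteRecord(
            chrom=chrom, pos=pos, ref="A", alt="G",
            control_ac=1, control_an=2 * cfg.control_n,
            depth_pass_fraction=round(float(rng.uniform(0.2, 0.8)), 3),
        ))

    return SyntheticCohort(
        config=cfg, cohort=cohort, callsets=callsets,
        controls=controls, terms=terms, truth=truth,
    )


def generate_null_burden(
    n_genes: int = 1000,
    n_cases: int = 21,
    n_controls: int = 10_000,
    seed: int = 0,
) -> tuple[dict[str, list[VariantCall]], list[ControlSiteRecord], int]:
    """Null cohort for burden-test calibration.

    One site per gene. Each gene draws a control allele frequency, and every
    case sample carries the variant (het) with exactly that probability — so
    case and control carrier frequencies agree and any p-value excess is
    test miscalibration. Returns (per-sample calls, control records,
    n_controls) ready for :func:`cosegscan.burden.burden_table`.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:03d}" for i in range(n_cases)]
    cohort_calls: dict[str, list[VariantCall]] = {s: [] for s in samples}
    controls: list[ControlSiteRecord] = []
    an = 2 * n_controls
    for gi in range(n_genes):
        chrom, pos = _gene_locus(gi % 2000)
        pos += (gi // 2000) * _POS_STEP
        gene = f"NULL{gi + 1:05d}"
        f_target = 10 ** rng.uniform(-3.2, -0.8)
        ac = max(1, round(f_target * an))
        f = ac / an
        v = AnnotatedVariant(
            chrom=chrom, pos=pos, ref="A", alt="G", qual=99.0, gene=gene,
            gnomad_popmax_af=CensoredFrequency(min(1.0, round(f, 6))),
            consequence="missense", impact_tier="moderate",
            sift_label="deleterious", polyphen_label="probably_damaging",
        )
        carriers = rng.random(n_cases) < f
        for s, hit in zip(samples, carriers):
            if hit:
                cohort_calls[s].append(VariantCall(variant=v, genotype="het", depth=40))
        controls.append(ControlSiteRecord(
            chrom=chrom, pos=pos, ref="A", alt="G",
            control_ac=ac, control_an=an, depth_pass_fraction=0.99,
        ))
    return cohort_calls, controls, n_controls
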