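"""Readers and writers for the VCF and tabular formats the pipeline consumes.

VCF input is parsed with cyvcf2. The annotation dialect is a flat set of INFO
keys (configurable via :class:`VcfDialect`): population frequencies may use
the censored ``"<0.001"`` convention and are therefore carried as INFO strings
and parsed into :class:`~cosegscan.types.CensoredFrequency`. Multi-allelic
records are decomposed into one variant per ALT allele before anything else
touches them, because all identity semantics downstream are per-allele.

VCF output is written as plain v4.2 text: the censored-frequency dialect needs
byte-exact control over INFO strings, so writing is not delegated to a
library writer.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from cyvcf2 import VCF

from .types import (
    AnnotatedVariant,
    CensoredFrequency,
    FamilyCohort,
    Phenotype,
    SampleCallset,
    VariantCall,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VcfDialect",
    "read_callset",
    "write_callset_vcf",
    "read_family_table",
    "write_family_table",
    "read_variant_table",
    "write_variant_table",
    "ControlSiteRecord",
    "read_control_table",
    "write_control_table",
]


@dataclass(frozen=True)
class VcfDialect:
    """Names of the INFO keys carrying each annotation, plus parsing policy.

    ``chrom_style`` controls chromosome-name normalization on read:
    ``"keep"`` (as-is), ``"strip"`` (drop a leading ``chr``) or ``"add"``
    (ensure a leading ``chr``) — GRCh38 resources disagree on the prefix.
    With ``strict=True`` a record missing a mandatory INFO key is rejected;
    by default the annotation is treated as absent and logged.
    """

    gene: str = "GENE"
    gnomad_popmax: str = "GPMAX"
    topmed: str = "TOPMED"
    nfe: str = "NFE"
    phastcons: str = "PC7"
    consequence: str = "CSQ"
    impact: str = "IMPACT"
    sift: str = "SIFT"
    polyphen: str = "PPH"
    rsid: str = "RSID"
    chrom_style: str = "keep"  # keep | strip | add
    strict: bool = False

    def normalize_chrom(self, chrom: str) -> str:
        if self.chrom_style == "strip":
            return chrom[3:] if chrom.startswith("chr") else chrom
        if self.chrom_style == "add":
            return chrom if chrom.startswith("chr") else f"chr{chrom}"
        return chrom


_LABEL_NORM = {
    "probably damaging": "probably_damaging",
    "possibly damaging": "possibly_damaging",
}


def _norm_label(raw: Optional[str]) -> Optional[str]:
    if raw is None:
        return None
    s = str(raw).strip().lower()
    if s in ("", "na", ".", "nan", "absent"):
        return None
    return _LABEL_NORM.get(s, s.replace(" ", "_"))


def _parse_freq(raw, where: str, strict: bool) -> Optional[CensoredFrequency]:
    if raw is None:
        return None
    try:
        return CensoredFrequency.parse(str(raw))
    except ValueError:
        if strict:
            raise ValueError(f"unparseable frequency {raw!r} at {where}")
        logger.warning("unparseable frequency %r at %s treated as absent", raw, where)
        return None


def _split_info(raw, n_alt: int) -> list:
    """Per-ALT values for a decomposed record: comma-split if it matches."""
    if raw is None:
        return [None] * n_alt
    parts = str(raw).split(",")
    if len(parts) == n_alt:
        return parts
    return [raw] * n_alt


def read_callset(
    vcf_path: str | Path,
    sample_id: str,
    caller_tag: str,
    dialect: VcfDialect = VcfDialect(),
) -> SampleCallset:
    """Read one caller's VCF for one sample into a :class:`SampleCallset`.

    One :class:`AnnotatedVariant` is emitted per ALT allele: multi-allelic
    records are decomposed, each allele taking its comma-indexed annotation
    where the INFO value has one entry per allele, or the shared value
    otherwise. Only carrier genotypes (het / hom_alt for that allele) are
    emitted. Censored frequencies (``"<0.001"``) are parsed as such.
    """
    vcf = VCF(str(vcf_path))
    calls: list[VariantCall] = []
    d = dialect
    for rec in vcf:
        n_alt = len(rec.ALT)
        where = f"{rec.CHROM}:{rec.POS}"
        genes = _split_info(rec.INFO.get(d.gene), n_alt)
        gpmax = _split_info(rec.INFO.get(d.gnomad_popmax), n_alt)
        topmed = _split_info(rec.INFO.get(d.topmed), n_alt)
        nfe = _split_info(rec.INFO.get(d.nfe), n_alt)
        pc7 = _split_info(rec.INFO.get(d.phastcons), n_alt)
        csq = _split_info(rec.INFO.get(d.consequence), n_alt)
        impact = _split_info(rec.INFO.get(d.impact), n_alt)
        sift = _split_info(rec.INFO.get(d.sift), n_alt)
        pph = _split_info(rec.INFO.get(d.polyphen), n_alt)
        rsid = _split_info(rec.INFO.get(d.rsid), n_alt)
        if d.strict and rec.INFO.get(d.gnomad_popmax) is None:
            raise ValueError(f"record {where} lacks mandatory INFO key {d.gnomad_popmax}")

        alleles = rec.genotypes[0][:-1] if rec.genotypes else []
        try:
            depth = int(rec.format("DP")[0][0]) if rec.format("DP") is not None else None
        except (TypeError, ValueError):
            depth = None

        for i, alt in enumerate(rec.ALT):
            n_copies = sum(1 for a in alleles if a == i + 1)
            if n_copies == 0:
                continue
            pc_val = pc7[i]
            phast = None
            if pc_val is not None and str(pc_val) not in (".", "", "nan"):
                phast = float(pc_val)
            variant = AnnotatedVariant(
                chrom=d.normalize_chrom(rec.CHROM),
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                # htslib stores QUAL as float32; undo the precision loss
                qual=None if rec.QUAL is None else round(float(rec.QUAL), 4),
                gene=None if genes[i] in (None, ".", "") else str(genes[i]),
                rsid=None if rsid[i] in (None, ".", "") else str(rsid[i]),
                gnomad_popmax_af=_parse_freq(gpmax[i], where, d.strict),
                topmed_af=_parse_freq(topmed[i], where, d.strict),
                nfe_af=_parse_freq(nfe[i], where, d.strict),
                phastcons7=phast,
                consequence=_norm_label(csq[i]),
                impact_tier=_norm_label(impact[i]),
                sift_label=_norm_label(sift[i]),
                polyphen_label=_norm_label(pph[i]),
            )
            calls.append(
                VariantCall(
                    variant=variant,
                    genotype="hom_alt" if n_copies >= 2 else "het",
                    depth=depth,
                )
            )
    return SampleCallset(sample_id=sample_id, caller_tag=caller_tag, calls=calls)


def _chrom_sort_key(chrom: str):
    core = chrom[3:] if chrom.startswith("chr") else chrom
    return (0, int(core)) if core.isdigit() else (1, core)


def _fmt_freq(f: Optional[CensoredFrequency]) -> Optional[str]:
    return None if f is None else str(f)


def write_callset_vcf(
    callset: SampleCallset,
    path: str | Path,
    dialect: VcfDialect = VcfDialect(),
) -> None:
    """Write a callset as a single-sample VCF v4.2 text file."""
    d = dialect
    chroms = sorted({c.variant.chrom for c in callset.calls}, key=_chrom_sort_key)
    header = [
        "##fileformat=VCFv4.2",
        f"##source=cosegscan ({callset.caller_tag})",
        *[f"##contig=<ID={c}>" for c in chroms],
        f'##INFO=<ID={d.gene},Number=A,Type=String,Description="Gene symbol">',
        f'##INFO=<ID={d.gnomad_popmax},Number=A,Type=String,Description="gnomAD popmax AF, possibly censored (<x)">',
        f'##INFO=<ID={d.topmed},Number=A,Type=String,Description="TOPMed AF, possibly censored (<x)">',
        f'##INFO=<ID={d.nfe},Number=A,Type=String,Description="gnomAD NFE AF, possibly censored (<x)">',
        # String, not Float: float32 INFO storage would truncate the score
        f'##INFO=<ID={d.phastcons},Number=A,Type=String,Description="PhastCons 7-way conservation">',
        f'##INFO=<ID={d.consequence},Number=A,Type=String,Description="Consequence term">',
        f'##INFO=<ID={d.impact},Number=A,Type=String,Description="Impact tier">',
        f'##INFO=<ID={d.sift},Number=A,Type=String,Description="SIFT label">',
        f'##INFO=<ID={d.polyphen},Number=A,Type=String,Description="PolyPhen label">',
        f'##INFO=<ID={d.rsid},Number=A,Type=String,Description="dbSNP identifier">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{callset.sample_id}",
    ]
    lines = list(header)
    for call in sorted(
        callset.calls, key=lambda c: (_chrom_sort_key(c.variant.chrom), c.variant.pos,
                                      c.variant.ref, c.variant.alt)
    ):
        v = call.variant
        info_pairs = [
            (d.gene, v.gene),
            (d.gnomad_popmax, _fmt_freq(v.gnomad_popmax_af)),
            (d.topmed, _fmt_freq(v.topmed_af)),
            (d.nfe, _fmt_freq(v.nfe_af)),
            (d.phastcons, None if v.phastcons7 is None else f"{v.phastcons7:g}"),
            (d.consequence, v.consequence),
            (d.impact, v.impact_tier),
            (d.sift, v.sift_label),
            (d.polyphen, v.polyphen_label),
            (d.rsid, v.rsid),
        ]
        info = ";".join(f"{k}={val}" for k, val in info_pairs if val is not None) or "."
        gt = "1/1" if call.genotype == "hom_alt" else "0/1"
        dp = "." if call.depth is None else str(call.depth)
        qual = "." if v.qual is None else f"{v.qual:g}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.rsid or '.'}\t{v.ref}\t{v.alt}\t{qual}\t"
            f"PASS\t{info}\tGT:DP\t{gt}:{dp}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# family / phenotype tables

_FAMILY_COLUMNS = [
    "family_id", "sample_id", "age", "age_is_surgery_proxy",
    "bilateral", "sex", "relationship",
]


def read_family_table(path: str | Path) -> FamilyCohort:
    """Read the tab-separated family/phenotype table.

    Columns: family_id, sample_id, age, age_is_surgery_proxy (0/1),
    bilateral (Y/N), sex (female/male), relationship. Duplicate sample IDs or
    single-member families are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(_FAMILY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"family table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample {dup!r} in family table")
    families: dict[str, list[str]] = {}
    phenotypes: dict[str, Phenotype] = {}
    for row in df.itertuples(index=False):
        families.setdefault(str(row.family_id), []).append(str(row.sample_id))
        age = None if pd.isna(row.age) or str(row.age) == "" else float(row.age)
        phenotypes[str(row.sample_id)] = Phenotype(
            age_at_diagnosis=age,
            age_is_surgery_proxy=str(row.age_is_surgery_proxy) in ("1", "Y", "True", "true"),
            bilateral=str(row.bilateral).upper().startswith("Y"),
            sex=str(row.sex).lower(),
            relationship="" if pd.isna(row.relationship) else str(row.relationship),
        )
    return FamilyCohort(families=families, phenotypes=phenotypes)


def write_family_table(cohort: FamilyCohort, path: str | Path) -> None:
    rows = []
    for fam, members in cohort.families.items():
        for s in members:
            p = cohort.phenotypes.get(s, Phenotype(age_at_diagnosis=None))
            rows.append({
                "family_id": fam,
                "sample_id": s,
                "age": "" if p.age_at_diagnosis is None else (
                    f"{p.age_at_diagnosis:g}"
                ),
                "age_is_surgery_proxy": int(p.age_is_surgery_proxy),
                "bilateral": "Y" if p.bilateral else "N",
                "sex": p.sex,
                "relationship": p.relationship,
            })
    pd.DataFrame(rows, columns=_FAMILY_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# flat variant tables

_VARIANT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "vclass", "qual", "gene", "rsid",
    "gnomad_popmax_af", "topmed_af", "nfe_af", "phastcons7",
    "consequence", "impact_tier", "sift", "polyphen",
]


def write_variant_table(variants: Iterable[AnnotatedVariant], path: str | Path) -> None:
    """Write annotated variants to a headered TSV (round-trip stable)."""
    rows = []
    for v in variants:
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "vclass": v.vclass,
            "qual": "" if v.qual is None else f"{v.qual:g}",
            "gene": v.gene or "", "rsid": v.rsid or "",
            "gnomad_popmax_af": _fmt_freq(v.gnomad_popmax_af) or "",
            "topmed_af": _fmt_freq(v.topmed_af) or "",
            "nfe_af": _fmt_freq(v.nfe_af) or "",
            "phastcons7": "" if v.phastcons7 is None else f"{v.phastcons7:g}",
            "consequence": v.consequence or "",
            "impact_tier": v.impact_tier or "",
            "sift": v.sift_label or "", "polyphen": v.polyphen_label or "",
        })
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def opt(s: str) -> Optional[str]:
        return None if s == "" else s

    out = []
    for row in df.itertuples(index=False):
        out.append(AnnotatedVariant(
            chrom=row.chrom, pos=int(row.pos), ref=row.ref, alt=row.alt,
            qual=None if row.qual == "" else float(row.qual),
            gene=opt(row.gene), rsid=opt(row.rsid),
            gnomad_popmax_af=None if row.gnomad_popmax_af == "" else CensoredFrequency.parse(row.gnomad_popmax_af),
            topmed_af=None if row.topmed_af == "" else CensoredFrequency.parse(row.topmed_af),
            nfe_af=None if row.nfe_af == "" else CensoredFrequency.parse(row.nfe_af),
            phastcons7=None if row.phastcons7 == "" else float(row.phastcons7),
            consequence=opt(row.consequence),
            impact_tier=opt(row.impact_tier),
            sift_label=opt(row.sift), polyphen_label=opt(row.polyphen),
        ))
    return out


# ---------------------------------------------------------------------------
# control allele-count tables (public-control burden input)


@dataclass(frozen=True)
class ControlSiteRecord:
    """Aggregate control-cohort counts at one site.

    ``control_ac`` / ``control_an`` are the alternate allele count and total
    allele number in the control cohort; ``depth_pass_fraction`` is the
    fraction of control samples with sequencing depth above the QC cutoff at
    this position.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    control_ac: int
    control_an: int
    depth_pass_fraction: float

    def __post_init__(self) -> None:
        if not (0 <= self.control_ac <= self.control_an):
            raise ValueError(
                f"control_ac {self.control_ac} outside [0, an={self.control_an}]"
            )
        if not (0.0 <= self.depth_pass_fraction <= 1.0):
            raise ValueError("depth_pass_fraction outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def af(self) -> float:
        return self.control_ac / self.control_an if self.control_an else 0.0


_CONTROL_COLUMNS = ["chrom", "pos", "ref", "alt", "ac", "an", "depth_pass_fraction"]


def read_control_table(path: str | Path) -> list[ControlSiteRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_CONTROL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"control table missing columns: {sorted(missing)}")
    return [
        ControlSiteRecord(
            chrom=str(r.chrom), pos=int(r.pos), ref=r.ref, alt=r.alt,
            control_ac=int(r.ac), control_an=int(r.an),
            depth_pass_fraction=float(r.depth_pass_fraction),
        )
        for r in df.itertuples(index=False)
    ]


def write_control_table(records: Sequence[ControlSiteRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
             "ac": r.control_ac, "an": r.control_an,
             "depth_pass_fraction": f"{r.depth_pass_fraction:g}"}
            for r in records
        ],
        columns=_CONTROL_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
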