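"""Packaged reference fixtures: the published cohort and candidate-variant
tables, transcribed to TSV.

The candidate-variant table prints no genomic coordinates, so the loader
assigns deterministic placeholder positions (one per row, genes on distinct
chromosomes); ref/alt alleles come from the HGVSc coding-change notation.
Everything the pipeline's filters and summaries read — frequencies
(censored where printed as "<0.001"), consequence, SIFT/PolyPhen labels,
conservation scores, family labels — is verbatim from the published table.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import pandas as pd

from .types import AnnotatedVariant, CensoredFrequency, FamilyCohort
from .vcfio import read_family_table

__all__ = ["load_cohort_table", "load_candidate_table", "candidate_family_sets"]

_HGVS_RE = re.compile(r"c\.\d+([ACGT])>([ACGT])$")


def _data_path(name: str) -> Path:
    return Path(resources.files("cosegscan.data") / name)


def load_cohort_table() -> FamilyCohort:
    """The 21-participant, 10-family study cohort with phenotypes."""
    return read_family_table(_data_path("table1.tsv"))


def load_candidate_table() -> list[tuple[str, AnnotatedVariant]]:
    """The 13 multi-family candidate variants as (family_id, variant) pairs."""
    df = pd.read_csv(
        _data_path("table2.tsv"), sep="\t", comment="#", dtype=str,
        keep_default_na=False,
    )
    genes = list(dict.fromkeys(df["gene"]))
    out: list[tuple[str, AnnotatedVariant]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        m = _HGVS_RE.match(row.hgvsc)
        if not m:
            raise ValueError(f"cannot derive alleles from HGVSc {row.hgvsc!r}")
        ref, alt = m.groups()
        variant = AnnotatedVariant(
            chrom=f"chr{genes.index(row.gene) + 1}",
            pos=1000 * (i + 1),  # placeholder: coordinates are not published
            ref=ref,
            alt=alt,
            gene=row.gene,
            rsid=row.rsid,
            gnomad_popmax_af=CensoredFrequency.parse(row.gnomad_popmax_af),
            topmed_af=CensoredFrequency.parse(row.topmed_af),
            nfe_af=CensoredFrequency.parse(row.nfe_af),
            phastcons7=float(row.phastcons7),
            consequence=row.consequence,
            sift_label=row.sift or None,
            polyphen_label=row.polyphen or None,
        )
        out.append((row.family, variant))
    return out


def candidate_family_sets() -> dict[str, list[AnnotatedVariant]]:
    """Candidate variants grouped by the family carrying them."""
    sets: dict[str, list[AnnotatedVariant]] = {}
    for fam, v in load_candidate_table():
        sets.setdefault(fam, []).append(v)
    return sets
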