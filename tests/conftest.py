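"""Shared fixtures: packaged reference tables and small variant builders."""

from __future__ import annotations

import pytest

from cosegscan import (
    AnnotatedVariant,
    CensoredFrequency,
    SampleCallset,
    VariantCall,
)
from cosegscan.datasets import (
    candidate_family_sets,
    load_candidate_table,
    load_cohort_table,
)


def make_snv(
    chrom: str = "chr1",
    pos: int = 100,
    ref: str = "A",
    alt: str = "G",
    **kw,
) -> AnnotatedVariant:
    kw.setdefault("qual", 99.0)
    return AnnotatedVariant(chrom=chrom, pos=pos, ref=ref, alt=alt, **kw)


def make_passing_variant(chrom="chr1", pos=100, ref="A", alt="G", **kw):
    """A variant that passes every cascade stage."""
    defaults = dict(
        qual=99.0,
        gene="GENEX",
        gnomad_popmax_af=CensoredFrequency(0.001, censored=True),
        topmed_af=CensoredFrequency(0.001, censored=True),
        phastcons7=0.95,
        consequence="missense",
        impact_tier="moderate",
        sift_label="deleterious",
        polyphen_label="probably_damaging",
    )
    defaults.update(kw)
    return AnnotatedVariant(chrom=chrom, pos=pos, ref=ref, alt=alt, **defaults)


def make_call(variant: AnnotatedVariant, genotype: str = "het", depth: int = 40):
    return VariantCall(variant=variant, genotype=genotype, depth=depth)


def make_callset(variants, sample_id="S1", caller_tag="callerA", genotype="het"):
    return SampleCallset(
        sample_id=sample_id,
        caller_tag=caller_tag,
        calls=[make_call(v, genotype) for v in variants],
    )


@pytest.fixture(scope="session")
def cohort_table():
    return load_cohort_table()


@pytest.fixture(scope="session")
def candidate_variants():
    return [v for _, v in load_candidate_table()]


@pytest.fixture(scope="session")
def candidate_by_family():
    return candidate_family_sets()
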