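"""Core domain types for family-based rare-variant prioritization.

The pipeline works on annotated variant calls: each variant carries the
population-frequency, conservation and deleteriousness annotations that the
downstream filter cascade consumes, plus per-sample genotype and depth inside
a :class:`SampleCallset`. Population allele frequencies from public databases
are frequently reported only as a bound (``"<0.001"``); these are modelled
explicitly by :class:`CensoredFrequency` rather than being imputed, and every
comparison against a threshold either resolves definitively or raises.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "VariantClass",
    "CensoredFrequency",
    "IndeterminateComparisonError",
    "AnnotatedVariant",
    "VariantCall",
    "SampleCallset",
    "Phenotype",
    "FamilyCohort",
    "classify_variant",
    "variant_key",
]

_ALLELE_RE = re.compile(r"^[ACGTN]+$")

SNV = "snv"
INSERTION = "insertion"
DELETION = "deletion"
COMPLEX = "complex"

#: The four mutually exclusive structural classes a (ref, alt) pair can take.
VariantClass = (SNV, INSERTION, DELETION, COMPLEX)


class IndeterminateComparisonError(ValueError):
    """A censored frequency could not be ordered against a threshold.

    Raised instead of silently guessing whenever the true (unobserved) value
    of a censored annotation may fall on either side of the threshold.
    """


def classify_variant(ref: str, alt: str) -> str:
    """Classify a (ref, alt) allele pair as snv/insertion/deletion/complex.

    The classes partition all valid pairs: a 1bp-to-1bp substitution is an
    SNV; a longer alt with ref as its prefix is an insertion; a longer ref
    with alt as its prefix is a deletion; everything else is complex.

    Raises
    ------
    ValueError
        If either allele is empty or contains characters outside ACGTN
        (symbolic alleles such as ``<DEL>`` are rejected).
    """
    for name, allele in (("ref", ref), ("alt", alt)):
        if not allele or not _ALLELE_RE.match(allele):
            raise ValueError(
                f"{name} allele {allele!r} is not a nonempty ACGTN string"
            )
    if len(ref) == 1 and len(alt) == 1:
        return SNV
    if len(alt) > len(ref) and alt.startswith(ref):
        return INSERTION
    if len(ref) > len(alt) and ref.startswith(alt):
        return DELETION
    return COMPLEX


@dataclass(frozen=True, order=False)
class CensoredFrequency:
    """A population allele frequency, possibly known only as an upper bound.

    ``CensoredFrequency(0.001, censored=True)`` encodes the annotation string
    ``"<0.001"``: the true frequency lies anywhere in ``[0, 0.001)``.

    Ordering against a threshold ``t`` follows the rule: a censored value
    ``<v`` is definitely below ``t`` when ``v <= t``; otherwise the comparison
    is indeterminate and :class:`IndeterminateComparisonError` is raised.
    """

    value: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"frequency {self.value} outside [0, 1]")

    def is_below(self, threshold: float) -> bool:
        """True iff the (true) frequency is strictly below ``threshold``."""
        if not self.censored:
            return self.value < threshold
        if self.value <= threshold:
            return True
        raise IndeterminateComparisonError(
            f"censored frequency <{self.value:g} cannot be ordered against "
            f"threshold {threshold:g}"
        )

    @classmethod
    def parse(cls, text: str) -> "CensoredFrequency":
        """Parse ``"0.005"`` or the censored dialect ``"<0.001"``."""
        text = text.strip()
        if text.startswith("<"):
            return cls(float(text[1:]), censored=True)
        return cls(float(text), censored=False)

    def __str__(self) -> str:
        return f"<{self.value:g}" if self.censored else f"{self.value:g}"


_IMPACT_TIERS = frozenset({"high", "moderate", "low", "modifier"})
_SIFT = frozenset({"deleterious", "tolerated"})
_POLYPHEN = frozenset({"probably_damaging", "possibly_damaging", "benign"})


@dataclass(frozen=True)
class AnnotatedVariant:
    """One called variant with the annotations used by the filter cascade.

    ``vclass`` is derived from (ref, alt) and cannot be supplied. Frequencies
    are :class:`CensoredFrequency` or ``None`` when the annotation is absent;
    ``phastcons7`` may be absent (common for indels). ``sift_label`` /
    ``polyphen_label`` are ``None`` for non-missense consequences.
    """

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    qual: Optional[float] = None
    gene: Optional[str] = None
    rsid: Optional[str] = None
    gnomad_popmax_af: Optional[CensoredFrequency] = None
    topmed_af: Optional[CensoredFrequency] = None
    nfe_af: Optional[CensoredFrequency] = None
    phastcons7: Optional[float] = None
    consequence: Optional[str] = None
    impact_tier: Optional[str] = None
    sift_label: Optional[str] = None
    polyphen_label: Optional[str] = None
    vclass: str = field(init=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos {self.pos} must be >= 1")
        object.__setattr__(self, "vclass", classify_variant(self.ref, self.alt))
        if self.phastcons7 is not None and not (0.0 <= self.phastcons7 <= 1.0):
            raise ValueError(f"phastcons7 {self.phastcons7} outside [0, 1]")
        if self.impact_tier is not None and self.impact_tier not in _IMPACT_TIERS:
            raise ValueError(f"unknown impact tier {self.impact_tier!r}")
        if self.sift_label is not None and self.sift_label not in _SIFT:
            raise ValueError(f"unknown SIFT label {self.sift_label!r}")
        if self.polyphen_label is not None and self.polyphen_label not in _POLYPHEN:
            raise ValueError(f"unknown PolyPhen label {self.polyphen_label!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def variant_key(obj) -> tuple[str, int, str, str]:
    """(chrom, pos, ref, alt) identity key of a variant or variant call."""
    v = obj.variant if isinstance(obj, VariantCall) else obj
    return v.key


@dataclass(frozen=True)
class VariantCall:
    """A variant as observed in one sample: genotype plus read depth.

    Only carriers are represented (``het`` or ``hom_alt``); hom-ref and
    missing genotypes never enter a callset, matching caller output.
    """

    variant: AnnotatedVariant
    genotype: str  # "het" | "hom_alt"
    depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.genotype not in ("het", "hom_alt"):
            raise ValueError(f"genotype must be het or hom_alt, got {self.genotype!r}")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be nonnegative")

    @property
    def allele_count(self) -> int:
        return 2 if self.genotype == "hom_alt" else 1


@dataclass
class SampleCallset:
    """All variant calls for one sample from one caller."""

    sample_id: str
    caller_tag: str
    calls: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [variant_key(c) for c in self.calls]
        if len(keys) != len(set(keys)):
            seen: set[tuple] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise ValueError(f"duplicate variant {dup} in callset {self.sample_id}")

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    @property
    def variants(self) -> list[AnnotatedVariant]:
        return [c.variant for c in self.calls]


@dataclass(frozen=True)
class Phenotype:
    """Per-participant clinical record: age, laterality, sex, relationship."""

    age_at_diagnosis: Optional[float]
    age_is_surgery_proxy: bool = False
    bilateral: bool = False
    sex: str = "female"  # "female" | "male"
    relationship: str = ""

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female or male, got {self.sex!r}")


@dataclass
class FamilyCohort:
    """Families mapped to their sequenced members, with phenotypes.

    Invariants enforced: every sample belongs to exactly one family and each
    family has at least two sequenced members (single-member "families" carry
    no co-segregation information).
    """

    families: dict[str, list[str]]
    phenotypes: dict[str, Phenotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for fam, members in self.families.items():
            if len(members) < 2:
                raise ValueError(f"family {fam!r} has fewer than 2 members")
            for s in members:
                if s in seen:
                    raise ValueError(f"sample {s!r} appears in more than one family")
                seen.add(s)
        for s in self.phenotypes:
            if s not in seen:
                raise ValueError(f"phenotype for unknown sample {s!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s for members in self.families.values() for s in members]

    @property
    def n_participants(self) -> int:
        return len(self.sample_ids)

    @property
    def n_families(self) -> int:
        return len(self.families)
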