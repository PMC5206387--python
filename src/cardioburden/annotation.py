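"""Variant classification: protein domain, functional consequence, rare/damaging calls.

The alpha-myosin heavy chain (1,939 residues) partitions into the globular
head/motor domain, the short neck (lever arm / light-chain binding region)
and the coiled-coil tail.  Default boundaries (head 1-778, neck 779-840,
tail 841-1939) reproduce the domain label of every record in the packaged
variant table; any partition consistent with those labels is accepted via
:class:`DomainBoundaries`.

"Damaging" combines the usual in-silico evidence disjunctively: protein-
truncating and in-frame indel consequences always qualify; missense
variants qualify through PolyPhen-2 >= ``pp2_min`` OR SIFT <= ``sift_max``.
"Rare" means novel (absent from the population database) or below a
population-frequency ceiling in percent.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .exceptions import InputError
from .io import VariantTableRecord

__all__ = [
    "PROTEIN_LENGTH",
    "DomainBoundaries",
    "DamagingConfig",
    "AnnotationConfig",
    "Variant",
    "parse_residue_number",
    "classify_consequence",
    "classify_domain",
    "annotate",
    "DamagingCall",
    "is_damaging",
    "is_rare",
    "VariantSetSummary",
    "summarize_variant_set",
    "to_vcf_style",
]

PROTEIN_LENGTH = 1939


@dataclass(frozen=True)
class DomainBoundaries:
    """Closed residue intervals forming a total partition of 1..protein_length."""

    head: tuple[int, int] = (1, 778)
    neck: tuple[int, int] = (779, 840)
    tail: tuple[int, int] = (841, PROTEIN_LENGTH)

    def __post_init__(self) -> None:
        intervals = [self.head, self.neck, self.tail]
        if any(lo > hi for lo, hi in intervals):
            raise InputError("domain interval with start > end")
        ordered = sorted(intervals)
        if ordered[0][0] != 1:
            raise InputError("domain partition must start at residue 1")
        for (_, hi), (lo, _) in zip(ordered, ordered[1:]):
            if lo != hi + 1:
                raise InputError("domain intervals must tile 1..protein length")

    @property
    def protein_length(self) -> int:
        return max(hi for _, hi in (self.head, self.neck, self.tail))


@dataclass(frozen=True)
class DamagingConfig:
    """Thresholds for the damaging call (PolyPhen-2 floor, SIFT ceiling)."""

    pp2_min: float = 0.5
    sift_max: float = 0.05


@dataclass(frozen=True)
class AnnotationConfig:
    damaging: DamagingConfig = field(default_factory=DamagingConfig)
    max_freq_percent: float = 0.5
    boundaries: DomainBoundaries = field(default_factory=DomainBoundaries)


DEFAULT_ANNOTATION = AnnotationConfig()

_NAME_RE = re.compile(r"^[A-Z](\d+)(.+)$")


def parse_residue_number(variant_name: str) -> int:
    """Residue number from protein notation: R443P -> 443, K850- -> 850, E1754X -> 1754."""
    m = _NAME_RE.match(variant_name)
    if not m:
        raise InputError(f"cannot parse residue number from {variant_name!r}")
    return int(m.group(1))


def classify_consequence(variant_name: str, ref: str, alt: str) -> str:
    """missense / nonsense / inframe_deletion / other from the name and alleles."""
    if variant_name.endswith("X"):
        return "nonsense"
    if alt == "-":
        return "inframe_deletion" if len(ref) % 3 == 0 else "other"
    m = _NAME_RE.match(variant_name)
    if m and re.fullmatch(r"[A-Z]", m.group(2)):
        return "missense"
    return "other"


def classify_domain(
    residue_number: int, boundaries: DomainBoundaries = DomainBoundaries()
) -> str:
    """Assign a residue to head, neck or tail; total over 1..protein_length."""
    if residue_number < 1:
        raise InputError(f"residue number must be >= 1, got {residue_number}")
    if residue_number > boundaries.protein_length:
        raise InputError(
            f"residue {residue_number} beyond protein length {boundaries.protein_length}"
        )
    for name in ("head", "neck", "tail"):
        lo, hi = getattr(boundaries, name)
        if lo <= residue_number <= hi:
            return name
    raise AssertionError("partition invariant violated")  # pragma: no cover


@dataclass(frozen=True)
class Variant(VariantTableRecord):
    """A table record augmented with residue number and functional consequence."""

    residue_number: int = 0
    consequence: str = "other"


def annotate(
    record: VariantTableRecord, boundaries: DomainBoundaries | None = None
) -> Variant:
    """Lift a raw table record to a :class:`Variant`.

    The domain printed in the table is checked against the configured residue
    partition; a mismatch raises, because it means the boundaries are wrong
    for this protein.
    """
    residue = parse_residue_number(record.variant_name)
    consequence = classify_consequence(record.variant_name, record.ref, record.alt)
    if boundaries is not None:
        computed = classify_domain(residue, boundaries)
        if computed != record.domain:
            raise InputError(
                f"{record.variant_name}: table domain {record.domain!r} but residue "
                f"{residue} falls in {computed!r} under the configured boundaries"
            )
    return Variant(
        **{f: getattr(record, f) for f in VariantTableRecord.__dataclass_fields__},
        residue_number=residue,
        consequence=consequence,
    )


class DamagingCall(NamedTuple):
    """Damaging status plus the rule branch that fired.

    ``damaging`` is True/False, or None for a missense variant with both
    scores missing (indeterminate: no evidence either way).
    """

    damaging: bool | None
    reason: str


def is_damaging(variant: Variant, config: DamagingConfig = DamagingConfig()) -> DamagingCall:
    """Disjunctive damaging rule: truncation/indel always, else PP2 or SIFT evidence."""
    if variant.consequence == "nonsense":
        return DamagingCall(True, "nonsense")
    if variant.consequence == "inframe_deletion":
        return DamagingCall(True, "inframe_deletion")
    if variant.pp2 is None and variant.sift is None:
        return DamagingCall(None, "no_scores")
    if variant.pp2 is not None and variant.pp2 >= config.pp2_min:
        return DamagingCall(True, "pp2")
    if variant.sift is not None and variant.sift <= config.sift_max:
        return DamagingCall(True, "sift")
    return DamagingCall(False, "benign_scores")


def is_rare(variant: VariantTableRecord, max_freq_percent: float = 0.5) -> bool:
    """Novel-flagged, or population frequency at or below the ceiling (percent)."""
    if max_freq_percent <= 0:
        raise InputError("max_freq_percent must be > 0")
    if variant.novel:
        return True
    return variant.pop_freq is not None and variant.pop_freq <= max_freq_percent


@dataclass(frozen=True)
class VariantSetSummary:
    """Distinctness-aware counts over a set of observed variants."""

    n_records: int
    n_distinct: int
    n_novel_distinct: int
    per_domain_distinct: dict[str, int]
    per_exon_distinct: dict[int, int]
    n_subjects: int

    def distinct_in_exon(self, exon: int) -> int:
        return self.per_exon_distinct.get(exon, 0)


def summarize_variant_set(variants: Iterable[Variant]) -> VariantSetSummary:
    """Count records, distinct variant names, novel/domain/exon breakdowns, subjects.

    Distinctness keys on the protein-level variant name (the same substitution
    observed in two subjects counts once); subjects are counted uniquely.
    Permutation-invariant in the input order.
    """
    variants = list(variants)
    if not variants:
        raise InputError("summarize_variant_set requires a non-empty variant list")
    by_name: dict[str, Variant] = {}
    for v in variants:
        by_name.setdefault(v.variant_name, v)
    domain_counts = Counter(v.domain for v in by_name.values())
    exon_counts = Counter(v.exon for v in by_name.values())
    return VariantSetSummary(
        n_records=len(variants),
        n_distinct=len(by_name),
        n_novel_distinct=sum(v.novel for v in by_name.values()),
        per_domain_distinct=dict(domain_counts),
        per_exon_distinct=dict(sorted(exon_counts.items())),
        n_subjects=len({v.subject_id for v in variants}),
    )


def to_vcf_style(
    coordinate: int, ref: str, alt: str, anchor_base: str = "N"
) -> tuple[int, str, str]:
    """Convert table-style alleles to left-aligned VCF style.

    SNVs pass through.  A deletion printed as ref="CTT", alt="-" becomes the
    VCF convention (anchor base prepended, position shifted one left); the
    anchor base requires reference sequence context, so callers pass it in
    (defaults to ``N``).
    """
    if alt != "-" and ref != "-":
        return coordinate, ref, alt
    if alt == "-":  # deletion
        return coordinate - 1, anchor_base + ref, anchor_base
    return coordinate, anchor_base, anchor_base + alt  # insertion
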