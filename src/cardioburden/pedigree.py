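"""Stage-1 pedigree engine: segregation filtering and inheritance classification.

The filtering design mirrors a subtractive family study under a dominant
model: a genome-wide variant survives iff the alt allele is present in every
*required* carrier (the affected relatives assumed to share the causal
allele) and confidently absent — genotype 0, not missing — in every
*excluded* carrier (unaffected relatives).  Survivors are collapsed to
candidate genes through an interval map and prioritised by heart expression.

Missingness is handled asymmetrically: an untyped required member fails the
variant (reason ``untyped-required``) because sharing cannot be established,
while an untyped excluded member does not fail it (absence of evidence) but
is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError, MissingDataWarning
from .io import CohortGenotypes, Pedigree, PedigreeMember  # noqa: F401  (re-export)

__all__ = [
    "SegregationFilterConfig",
    "SegregationResult",
    "segregation_filter",
    "GeneReduction",
    "reduce_to_genes",
    "PrioritizedGenes",
    "prioritize_by_expression",
    "classify_inheritance",
    "CompoundHetCall",
    "detect_compound_het",
]


@dataclass(frozen=True)
class SegregationFilterConfig:
    """Who must share the allele and who must lack it."""

    required_carriers: frozenset[str]
    excluded_carriers: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "required_carriers", frozenset(self.required_carriers))
        object.__setattr__(self, "excluded_carriers", frozenset(self.excluded_carriers))
        if self.required_carriers & self.excluded_carriers:
            raise InputError("required and excluded carrier sets overlap")
        if not self.required_carriers:
            raise InputError("at least one required carrier is needed")


@dataclass
class SegregationResult:
    passing: list[str]
    failed: dict[str, str]  # variant id -> reason
    untyped_excluded_logged: list[str] = field(default_factory=list)


def segregation_filter(
    genotypes: CohortGenotypes, config: SegregationFilterConfig
) -> SegregationResult:
    """Apply the sharing/subtraction filter to every variant in the cohort.

    Sharing requires allele *presence* (count >= 1), not matched zygosity:
    the model is dominant with incomplete penetrance.  The result is
    independent of variant order and of any subject not named in the config.
    """
    missing_ids = (config.required_carriers | config.excluded_carriers) - set(
        genotypes.subjects
    )
    if missing_ids:
        raise InputError(f"config names absent subjects: {sorted(missing_ids)}")
    req = sorted(config.required_carriers)
    exc = sorted(config.excluded_carriers)
    counts = genotypes.allele_counts
    passing: list[str] = []
    failed: dict[str, str] = {}
    logged: list[str] = []
    for vid in counts.columns:
        col = counts[vid]
        req_counts = col.loc[req]
        if req_counts.isna().any():
            failed[vid] = "untyped-required"
            continue
        if not (req_counts >= 1).all():
            failed[vid] = "absent-in-required"
            continue
        exc_counts = col.loc[exc]
        if (exc_counts >= 1).any():
            failed[vid] = "present-in-excluded"
            continue
        if exc_counts.isna().any():
            logged.append(vid)  # untyped unaffected: pass, but record it
        passing.append(vid)
    return SegregationResult(passing=passing, failed=failed, untyped_excluded_logged=logged)


@dataclass
class GeneReduction:
    genes: list[str]  # unique symbols, sorted
    variant_genes: dict[str, list[str]]  # passing variant id -> overlapping genes
    n_outside_genes: int


def reduce_to_genes(
    variants: pd.DataFrame, gene_map: pd.DataFrame
) -> GeneReduction:
    """Collapse passing variants to a sorted candidate-gene list.

    ``variants``: metadata frame indexed by variant id with ``chrom``/``pos``;
    ``gene_map``: columns gene, chrom, start, end with 1-based fully-closed
    intervals.  A variant overlapping several genes is assigned to all of
    them; variants outside every interval are dropped and counted.
    """
    for col in ("gene", "chrom", "start", "end"):
        if col not in gene_map.columns:
            raise InputError(f"gene map lacks column {col!r}")
    genes: set[str] = set()
    assignment: dict[str, list[str]] = {}
    n_outside = 0
    map_chrom = gene_map["chrom"].astype(str)  # robust to numeric chromosome names
    for vid, row in variants.iterrows():
        hits = gene_map[
            (map_chrom == str(row["chrom"]))
            & (gene_map["start"] <= row["pos"])
            & (gene_map["end"] >= row["pos"])
        ]["gene"].tolist()
        if hits:
            assignment[vid] = sorted(set(hits))
            genes.update(hits)
        else:
            n_outside += 1
    return GeneReduction(
        genes=sorted(genes), variant_genes=assignment, n_outside_genes=n_outside
    )


@dataclass
class PrioritizedGenes:
    """Candidates passing the expression floor, plus genes with unknown expression."""

    prioritized: list[str]  # ranked by expression, descending
    unknown: list[str]  # candidates absent from the expression table


def prioritize_by_expression(
    candidates: list[str], heart_expression: pd.Series, min_tpm: float = 10.0
) -> PrioritizedGenes:
    """Keep candidates expressed in heart at >= ``min_tpm``, ranked descending.

    Genes missing from the expression table land in the ``unknown`` bucket
    rather than being silently dropped.
    """
    known = [g for g in candidates if g in heart_expression.index]
    unknown = [g for g in candidates if g not in heart_expression.index]
    kept = [(g, float(heart_expression[g])) for g in known if heart_expression[g] >= min_tpm]
    kept.sort(key=lambda item: (-item[1], item[0]))
    return PrioritizedGenes(prioritized=[g for g, _ in kept], unknown=unknown)


def classify_inheritance(
    child_gt: float, mother_gt: float | None, father_gt: float | None
) -> str:
    """Classify parental origin of a carried allele from trio allele counts.

    ``None``/NaN means untyped.  Returns one of de_novo, maternal, paternal,
    biparental, nonmaternal, nonpaternal, unknown.  A typed parent carrying
    the allele implicates that parent; a typed non-carrier parent excludes
    it (non-maternal / non-paternal when the other parent is untyped).
    """

    def _state(gt: float | None) -> str:
        if gt is None or (isinstance(gt, float) and np.isnan(gt)):
            return "untyped"
        return "carrier" if gt >= 1 else "ref"

    if _state(child_gt) != "carrier":
        raise InputError("classify_inheritance requires a carrier child")
    mother, father = _state(mother_gt), _state(father_gt)
    if mother == "carrier" and father == "carrier":
        return "biparental"
    if mother == "carrier":
        return "maternal"
    if father == "carrier":
        return "paternal"
    if mother == "ref" and father == "ref":
        return "de_novo"
    if mother == "ref":  # father untyped
        return "nonmaternal"
    if father == "ref":  # mother untyped
        return "nonpaternal"
    return "unknown"


@dataclass(frozen=True)
class CompoundHetCall:
    flagged: bool
    phase: str  # trans-supported / cis-likely / phase-unknown / not-applicable
    n_sites: int


# which parental chromosome a call constrains the allele to
_MATERNAL_SIDE = {"maternal", "nonpaternal"}
_PATERNAL_SIDE = {"paternal", "nonmaternal"}


def detect_compound_het(inheritance_calls: dict[str, str]) -> CompoundHetCall:
    """Flag a subject carrying >= 2 distinct sites in one gene; summarise phase.

    ``inheritance_calls``: variant id -> inheritance label for one subject and
    one gene.  Phase is ``trans-supported`` when two calls place alleles on
    different parental origins (e.g. maternal + nonmaternal), ``cis-likely``
    when at least two calls agree on one origin and none opposes, otherwise
    ``phase-unknown``.
    """
    if not inheritance_calls:
        raise InputError("detect_compound_het requires at least one variant")
    n = len(inheritance_calls)
    if n < 2:
        return CompoundHetCall(flagged=False, phase="not-applicable", n_sites=n)
    sides = set()
    for call in inheritance_calls.values():
        if call in _MATERNAL_SIDE:
            sides.add("maternal")
        elif call in _PATERNAL_SIDE:
            sides.add("paternal")
    if len(sides) == 2:
        phase = "trans-supported"
    elif len(sides) == 1 and sum(
        c in _MATERNAL_SIDE | _PATERNAL_SIDE for c in inheritance_calls.values()
    ) >= 2:
        phase = "cis-likely"
    else:
        phase = "phase-unknown"
    return CompoundHetCall(flagged=True, phase=phase, n_sites=n)
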