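"""Readers and writers for every tabular format the pipeline touches.

Formats
-------
* variant table — TSV transcription of the published list of rare, damaging
  MYH6 substitutions/indels (one row per observation, duplicates preserved);
* minimal VCF v4.x (GT genotypes only) and 6-column PED pedigrees;
* survival tables (subject, group, time_years, event);
* expression matrices (gene rows x sample columns);
* densitometry tables (pair, genotype, replicate, band, gapdh).

Every ``write_*`` is the exact inverse of its ``read_*``: round-trips are
identities, which the test suite checks format by format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = [
    "VariantTableRecord",
    "CohortGenotypes",
    "PedigreeMember",
    "Pedigree",
    "table1_fixture_path",
    "read_variant_table",
    "write_variant_table",
    "read_vcf_lite",
    "write_vcf_lite",
    "read_pedigree",
    "write_pedigree",
    "read_survival_table",
    "write_survival_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_densitometry_table",
    "write_densitometry_table",
]

#: inheritance codes as printed in the variant table -> canonical labels
INHERITANCE_CODES = {
    "de novo": "de_novo",
    "Mat": "maternal",
    "NonMat": "nonmaternal",
    "Pat": "paternal",
    "NonPat": "nonpaternal",
    "NA": "unknown",
}
_INHERITANCE_LABELS = {v: k for k, v in INHERITANCE_CODES.items()}

VARIANT_TABLE_COLUMNS = [
    "coordinate",
    "ref",
    "alt",
    "domain",
    "exon",
    "variant_name",
    "subject_id",
    "pp2",
    "sift",
    "inherit",
    "pop_freq",
]

N_EXONS = 39


@dataclass(frozen=True)
class VariantTableRecord:
    """One observed variant: genomic change, protein context, scores, provenance.

    ``pp2`` (PolyPhen-2, damaging near 1) and ``sift`` (SIFT, damaging near 0)
    are ``None`` for non-missense records.  ``pop_freq`` is a percentage;
    ``novel`` marks variants unobserved in the reference population database,
    in which case ``pop_freq`` is ``None`` (unobserved, not proven absent).
    """

    coordinate: int
    ref: str
    alt: str
    domain: str
    exon: int
    variant_name: str
    subject_id: str
    pp2: float | None
    sift: float | None
    inherit: str
    pop_freq: float | None
    novel: bool

    def __post_init__(self) -> None:
        if self.coordinate <= 0:
            raise InputError(f"coordinate must be positive, got {self.coordinate}")
        if not 1 <= self.exon <= N_EXONS:
            raise InputError(
                f"exon {self.exon} outside 1..{N_EXONS} for {self.variant_name}"
            )
        if self.inherit not in _INHERITANCE_LABELS:
            raise InputError(f"unknown inheritance label {self.inherit!r}")
        if self.pop_freq is not None and self.pop_freq < 0:
            raise InputError("population frequency must be >= 0")


def table1_fixture_path() -> Path:
    """Path of the packaged variant-table fixture (21 rows)."""
    return Path(resources.files("cardioburden.data") / "table1_myh6_variants.tsv")


def _parse_score(cell: str, line_no: int, col: str) -> float | None:
    cell = cell.strip()
    if cell in ("NA", ""):
        return None
    try:
        value = float(cell)
    except ValueError as exc:
        raise InputError(f"line {line_no}: non-numeric {col} {cell!r}") from exc
    if not 0.0 <= value <= 1.0:
        raise InputError(f"line {line_no}: {col}={value} outside [0, 1]")
    return value


def read_variant_table(path: str | Path) -> list[VariantTableRecord]:
    """Parse a TSV variant table into :class:`VariantTableRecord` rows.

    ``novel`` in the Pop Freq column sets the novel flag with frequency missing;
    ``NA`` scores parse as missing.  Malformed rows raise :class:`InputError`
    naming the 1-based line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise InputError(f"{path}: empty file, expected a header line")
    header = lines[0].rstrip("\n").split("\t")
    if header != VARIANT_TABLE_COLUMNS:
        raise InputError(
            f"{path}: unexpected header {header!r}, expected {VARIANT_TABLE_COLUMNS!r}"
        )
    records: list[VariantTableRecord] = []
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(VARIANT_TABLE_COLUMNS):
            raise InputError(
                f"line {line_no}: expected {len(VARIANT_TABLE_COLUMNS)} columns, "
                f"got {len(cells)}"
            )
        row = dict(zip(VARIANT_TABLE_COLUMNS, cells))
        inherit_code = row["inherit"].strip()
        if inherit_code not in INHERITANCE_CODES:
            raise InputError(
                f"line {line_no}: unknown inheritance code {inherit_code!r}"
            )
        freq_cell = row["pop_freq"].strip()
        if freq_cell == "novel":
            novel, pop_freq = True, None
        else:
            if not freq_cell.endswith("%"):
                raise InputError(
                    f"line {line_no}: population frequency {freq_cell!r} "
                    "must be 'novel' or a percentage like '0.03%'"
                )
            novel = False
            try:
                pop_freq = float(freq_cell[:-1])
            except ValueError as exc:
                raise InputError(
                    f"line {line_no}: non-numeric population frequency {freq_cell!r}"
                ) from exc
        try:
            coordinate = int(row["coordinate"])
            exon = int(row["exon"])
        except ValueError as exc:
            raise InputError(f"line {line_no}: non-integer coordinate or exon") from exc
        records.append(
            VariantTableRecord(
                coordinate=coordinate,
                ref=row["ref"].strip(),
                alt=row["alt"].strip(),
                domain=row["domain"].strip(),
                exon=exon,
                variant_name=row["variant_name"].strip(),
                subject_id=row["subject_id"].strip(),
                pp2=_parse_score(row["pp2"], line_no, "pp2"),
                sift=_parse_score(row["sift"], line_no, "sift"),
                inherit=INHERITANCE_CODES[inherit_code],
                pop_freq=pop_freq,
                novel=novel,
            )
        )
    return records


def _format_score(value: float | None) -> str:
    if value is None:
        return "NA"
    return f"{value:g}"


def write_variant_table(records: Iterable[VariantTableRecord], path: str | Path) -> None:
    lines = ["\t".join(VARIANT_TABLE_COLUMNS)]
    for r in records:
        freq = "novel" if r.novel else f"{r.pop_freq:g}%"
        lines.append(
            "\t".join(
                [
                    str(r.coordinate),
                    r.ref,
                    r.alt,
                    r.domain,
                    str(r.exon),
                    r.variant_name,
                    r.subject_id,
                    _format_score(r.pp2),
                    _format_score(r.sift),
                    _INHERITANCE_LABELS[r.inherit],
                    freq,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# cohort genotypes / minimal VCF
# ---------------------------------------------------------------------------


@dataclass
class CohortGenotypes:
    """Subject x variant alt-allele-count matrix with optional case labels.

    ``allele_counts``: float DataFrame, subjects as index, variant ids as
    columns; entries 0/1/2, NaN = untyped.  ``variants``: per-variant metadata
    (chrom, pos, ref, alt, optionally gene) indexed by variant id.  ``labels``:
    subject -> "case"/"control", present for association cohorts only.
    """

    allele_counts: pd.DataFrame
    variants: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = set(self.allele_counts.columns) - set(self.variants.index)
        if missing:
            raise InputError(f"variants without metadata: {sorted(missing)[:5]}")
        if self.labels is not None:
            bad = set(self.labels.unique()) - {"case", "control"}
            if bad:
                raise InputError(f"labels must be case/control, got {sorted(bad)}")

    @property
    def subjects(self) -> list[str]:
        return list(self.allele_counts.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.allele_counts.columns)

    def subset_variants(self, variant_ids: Sequence[str]) -> "CohortGenotypes":
        return CohortGenotypes(
            self.allele_counts.loc[:, list(variant_ids)],
            self.variants.loc[list(variant_ids)],
            self.labels,
        )


def variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}>{alt}"


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def read_vcf_lite(path: str | Path) -> CohortGenotypes:
    """Read a GT-only text VCF into a :class:`CohortGenotypes`.

    Diploid genotypes become alt-allele counts 0/1/2; ``./.`` becomes NaN
    (missing, distinct from homozygous reference).  Multiallelic ALT fields
    and rows whose sample count disagrees with the header are rejected.
    """
    path = Path(path)
    samples: list[str] | None = None
    counts: dict[str, list[float]] = {}
    meta_rows: list[dict] = []
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("##") or not line.strip():
            continue
        if line.startswith("#CHROM"):
            cols = line.lstrip("#").split("\t")
            if len(cols) < 10 or cols[8] != "FORMAT":
                raise InputError(f"line {line_no}: header lacks FORMAT/sample columns")
            samples = cols[9:]
            continue
        if samples is None:
            raise InputError(f"line {line_no}: data before #CHROM header")
        cells = line.split("\t")
        if len(cells) != 9 + len(samples):
            raise InputError(
                f"line {line_no}: {len(cells) - 9} sample fields for "
                f"{len(samples)} header samples"
            )
        chrom, pos, _vid, ref, alt = cells[0], cells[1], cells[2], cells[3], cells[4]
        if "," in alt:
            raise InputError(
                f"line {line_no}: multiallelic ALT {alt!r}; split the record first"
            )
        fmt = cells[8].split(":")
        if "GT" not in fmt:
            raise InputError(f"line {line_no}: FORMAT {cells[8]!r} lacks GT")
        gt_idx = fmt.index("GT")
        vid = variant_id(chrom, int(pos), ref, alt)
        row: list[float] = []
        for sample_field in cells[9:]:
            gt = sample_field.split(":")[gt_idx]
            alleles = gt.replace("|", "/").split("/")
            if "." in alleles:
                row.append(np.nan)
                continue
            try:
                allele_ints = [int(a) for a in alleles]
            except ValueError as exc:
                raise InputError(f"line {line_no}: malformed GT {gt!r}") from exc
            if any(a > 1 for a in allele_ints):
                raise InputError(
                    f"line {line_no}: GT {gt!r} refers to a second alt allele"
                )
            row.append(float(sum(allele_ints)))
        counts[vid] = row
        meta_rows.append({"id": vid, "chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt})
    if samples is None:
        raise InputError(f"{path}: no #CHROM header line")
    allele_counts = pd.DataFrame(counts, index=pd.Index(samples, name="subject"))
    variants = pd.DataFrame(meta_rows).set_index("id") if meta_rows else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt"]
    )
    return CohortGenotypes(allele_counts=allele_counts, variants=variants)


def _gt_string(count: float) -> str:
    if np.isnan(count):
        return "./."
    return {0: "0/0", 1: "0/1", 2: "1/1"}[int(count)]


def write_vcf_lite(cohort: CohortGenotypes, path: str | Path) -> None:
    """Write a :class:`CohortGenotypes` as a minimal GT-only VCF v4.2 file."""
    samples = cohort.subjects
    lines = [_VCF_HEADER.rstrip("\n")]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    meta = cohort.variants
    for vid in meta.index:
        row = meta.loc[vid]
        gts = "\t".join(_gt_string(c) for c in cohort.allele_counts[vid])
        lines.append(
            f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}"
            f"\t.\t.\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeMember:
    id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" / "female" / "unknown"
    affected: bool
    phenotype_known: bool = True


@dataclass
class Pedigree:
    """A family: members with resolved parent links and affection status."""

    family_id: str
    members: list[PedigreeMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            raise InputError("duplicate individual ids in pedigree")
        known = set(ids)
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in known:
                    raise InputError(f"parent {parent!r} of {m.id!r} not in pedigree")
            if m.id in (m.father_id, m.mother_id):
                raise InputError(f"individual {m.id!r} listed as own parent")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            m.id: [p for p in (m.father_id, m.mother_id) if p is not None]
            for m in self.members
        }
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            if state.get(node) == 1:
                raise InputError(f"cyclic parentage involving {node!r}")
            if state.get(node) == 2:
                return
            state[node] = 1
            for p in parents[node]:
                visit(p)
            state[node] = 2

        for node in parents:
            visit(node)

    def member(self, member_id: str) -> PedigreeMember:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)

    @property
    def affected_ids(self) -> list[str]:
        return [m.id for m in self.members if m.affected]

    @property
    def unaffected_ids(self) -> list[str]:
        return [m.id for m in self.members if m.phenotype_known and not m.affected]


_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_SEX_LABELS = {v: k for k, v in _SEX_CODES.items()}


def read_pedigree(path: str | Path) -> Pedigree:
    """Parse a 6-column PED file (family, id, father, mother, sex, phenotype).

    Phenotype 2 = affected, 1 = unaffected, 0/-9 = unknown; parent id ``0``
    means unrecorded.  All parents named must be present in the file.
    """
    path = Path(path)
    members: list[PedigreeMember] = []
    family_ids: set[str] = set()
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.split()
        if len(cells) != 6:
            raise InputError(f"line {line_no}: expected 6 PED columns, got {len(cells)}")
        fam, iid, father, mother, sex, pheno = cells
        family_ids.add(fam)
        if sex not in _SEX_CODES:
            raise InputError(f"line {line_no}: bad sex code {sex!r}")
        if pheno not in ("0", "1", "2", "-9"):
            raise InputError(f"line {line_no}: bad phenotype code {pheno!r}")
        members.append(
            PedigreeMember(
                id=iid,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=_SEX_CODES[sex],
                affected=pheno == "2",
                phenotype_known=pheno in ("1", "2"),
            )
        )
    if len(family_ids) > 1:
        raise InputError(f"{path}: multiple families {sorted(family_ids)}")
    if not members:
        raise InputError(f"{path}: empty pedigree file")
    return Pedigree(family_id=family_ids.pop(), members=members)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    lines = []
    for m in pedigree.members:
        pheno = ("2" if m.affected else "1") if m.phenotype_known else "0"
        lines.append(
            "\t".join(
                [
                    pedigree.family_id,
                    m.id,
                    m.father_id or "0",
                    m.mother_id or "0",
                    _SEX_LABELS[m.sex],
                    pheno,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# survival / expression / densitometry tables
# ---------------------------------------------------------------------------

SURVIVAL_COLUMNS = ["subject_id", "group", "time_years", "event"]


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a survival TSV: subject_id, group, time_years, event (0/1).

    An optional ``age_years`` column is preserved for eligibility filtering.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "group": str})
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing survival columns {missing}")
    for col in ("time_years", "event"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise InputError(f"{path}: non-numeric {col} at data row {bad + 1}")
    if (df["time_years"] < 0).any():
        raise InputError(f"{path}: negative follow-up time")
    if not df["event"].isin([0, 1]).all():
        raise InputError(f"{path}: event flag must be 0 or 1")
    return df


def write_survival_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample expression TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"{path}: duplicate gene ids {dupes[:5]}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise InputError(f"{path}: non-numeric expression column {non_numeric[0]!r}")
    if (df < 0).any().any():
        raise InputError(f"{path}: negative expression values")
    df.index.name = "gene"
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


DENSITOMETRY_COLUMNS = ["pair_id", "genotype", "replicate", "band", "gapdh"]


def read_densitometry_table(path: str | Path) -> pd.DataFrame:
    """Read a blot densitometry TSV: pair_id, genotype (MUT/WT), replicate, band, gapdh."""
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "genotype": str})
    missing = [c for c in DENSITOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing densitometry columns {missing}")
    for col in ("band", "gapdh"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise InputError(f"{path}: non-numeric {col} column")
        if (df[col] <= 0).any():
            raise InputError(f"{path}: {col} densities must be positive")
    bad = set(df["genotype"].unique()) - {"MUT", "WT"}
    if bad:
        raise InputError(f"{path}: genotype must be MUT/WT, got {sorted(bad)}")
    return df


def write_densitometry_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
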