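"""Stage-2 engine: carrier-collapsing case-control burden association.

A subject is a *carrier* if they hold at least one qualifying (rare and
damaging) variant in the gene; the 2x2 carrier table

    =========  ========  ============
               carriers  non-carriers
    cases      a         b
    controls   c         d
    =========  ========  ============

is tested with a from-scratch two-sided Fisher exact test (probability-mass
definition: the p-value sums hypergeometric probabilities of all tables with
the observed margins whose probability does not exceed the observed one).
Effect size is the sample odds ratio (ad)/(bc) with a Woolf (log-normal)
95% interval, optionally Haldane-corrected for zero cells, plus the percent
enrichment of the case carrier fraction over the control fraction.

The exact test is computed in log space from cached log-factorials, so no
gamma-function library support is assumed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateStatisticsWarning, InputError, MissingDataWarning
from .io import CohortGenotypes

__all__ = [
    "CarrierTable",
    "collapse_carriers",
    "fisher_exact_two_sided",
    "OddsRatioResult",
    "odds_ratio",
    "enrichment_percent",
    "gene_burden_scan",
    "CarrierBurdenModel",
    "CarrierBurdenResults",
]

#: relative tolerance for "at most as probable as observed" tie comparisons
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class CarrierTable:
    """2x2 carrier/non-carrier by case/control table."""

    a: int  # case carriers
    b: int  # case non-carriers
    c: int  # control carriers
    d: int  # control non-carriers

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InputError("carrier table cells must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def case_carrier_fraction(self) -> float:
        return self.a / self.n_cases

    @property
    def control_carrier_fraction(self) -> float:
        return self.c / self.n_controls

    def transpose(self) -> "CarrierTable":
        return CarrierTable(self.a, self.c, self.b, self.d)


# -- cached log-factorials ---------------------------------------------------

_logfact = np.zeros(1)


def _log_factorials(n: int) -> np.ndarray:
    """Cumulative log-factorial table 0..n, grown on demand and cached."""
    global _logfact
    if n >= _logfact.size:
        start = _logfact.size
        extension = np.log(np.arange(start, n + 1, dtype=float))
        _logfact = np.concatenate([_logfact, _logfact[-1] + np.cumsum(extension)])
    return _logfact


def fisher_exact_two_sided(table: CarrierTable) -> float:
    """Two-sided Fisher exact p-value, probability-mass definition.

    Enumerates the full hypergeometric support of tables sharing the observed
    margins and sums the probabilities of those at most as probable as the
    observed table (relative tie tolerance 1e-7).  Returned p is in (0, 1].
    """
    a, n1, n2 = table.a, table.n_cases, table.n_controls
    if n1 == 0 or n2 == 0:
        raise InputError("both margins must be positive")
    m1 = table.a + table.c  # total carriers
    n = n1 + n2
    lf = _log_factorials(n)
    ks = np.arange(max(0, m1 - n2), min(n1, m1) + 1)
    log_p = (
        (lf[n1] - lf[ks] - lf[n1 - ks])
        + (lf[n2] - lf[m1 - ks] - lf[n2 - m1 + ks])
        - (lf[n] - lf[m1] - lf[n - m1])
    )
    log_obs = log_p[np.searchsorted(ks, a)]
    keep = log_p <= log_obs + math.log1p(_TIE_RTOL)
    return float(min(1.0, np.exp(log_p[keep]).sum()))


@dataclass(frozen=True)
class OddsRatioResult:
    estimate: float
    ci_low: float
    ci_high: float
    haldane_applied: bool


def odds_ratio(table: CarrierTable, zero_cell_policy: str = "error") -> OddsRatioResult:
    """Sample odds ratio (ad)/(bc) with a Woolf 95% confidence interval.

    CI = exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).  With a zero
    cell, ``zero_cell_policy="haldane"`` adds 0.5 to every cell; the default
    policy raises instead.
    """
    if zero_cell_policy not in ("error", "haldane"):
        raise InputError(f"unknown zero_cell_policy {zero_cell_policy!r}")
    cells = [float(table.a), float(table.b), float(table.c), float(table.d)]
    haldane = False
    if min(cells) == 0:
        if zero_cell_policy == "error":
            raise InputError(
                "zero cell in carrier table; pass zero_cell_policy='haldane'"
            )
        cells = [x + 0.5 for x in cells]
        haldane = True
    a, b, c, d = cells
    estimate = (a * d) / (b * c)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(estimate)
    return OddsRatioResult(
        estimate=estimate,
        ci_low=math.exp(log_or - 1.96 * se_log),
        ci_high=math.exp(log_or + 1.96 * se_log),
        haldane_applied=haldane,
    )


def enrichment_percent(table: CarrierTable) -> float:
    """Case carrier fraction over control carrier fraction, as a percentage.

    With zero control carriers the enrichment is infinite and reported as
    ``inf`` (with a warning) rather than raising.
    """
    if table.c == 0:
        warnings.warn(
            "no control carriers: enrichment is infinite", DegenerateStatisticsWarning
        )
        return math.inf
    return 100.0 * table.case_carrier_fraction / table.control_carrier_fraction


def collapse_carriers(
    genotypes: CohortGenotypes,
    gene: str,
    qualifying: Callable[[pd.Series], bool] | None = None,
) -> pd.Series:
    """Per-subject carrier status for one gene (>= 1 qualifying variant).

    ``qualifying`` is a predicate over the variant-metadata row (defaults to
    accepting every variant of the gene — upstream filtering usually happens
    in the annotation layer).  Subjects with all genotypes missing at the
    qualifying sites are excluded from the result with a warning.
    """
    if "gene" not in genotypes.variants.columns:
        raise InputError("variant metadata lacks a 'gene' column")
    meta = genotypes.variants[genotypes.variants["gene"] == gene]
    if qualifying is not None:
        meta = meta[[bool(qualifying(row)) for _, row in meta.iterrows()]]
    if meta.empty:
        return pd.Series(False, index=genotypes.allele_counts.index, name=gene)
    counts = genotypes.allele_counts[meta.index]
    all_missing = counts.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} subjects untyped at every {gene} site; "
            "excluded from carrier denominators",
            MissingDataWarning,
        )
    carrier = (counts >= 1).any(axis=1)
    return carrier[~all_missing].rename(gene)


def carrier_table_from_status(carrier: pd.Series, labels: pd.Series) -> CarrierTable:
    """Build the 2x2 table from per-subject carrier status and case labels."""
    labels = labels.reindex(carrier.index)
    if labels.isna().any():
        raise InputError("carrier subjects without case/control labels")
    is_case = labels == "case"
    return CarrierTable(
        a=int((carrier & is_case).sum()),
        b=int((~carrier & is_case).sum()),
        c=int((carrier & ~is_case).sum()),
        d=int((~carrier & ~is_case).sum()),
    )


def gene_burden_scan(
    genotypes: CohortGenotypes,
    genes: Sequence[str],
    qualifying: Callable[[pd.Series], bool] | None = None,
    alpha: float = 0.05,
    zero_cell_policy: str = "haldane",
) -> pd.DataFrame:
    """Carrier-collapse and Fisher-test every candidate gene.

    Returns one row per gene (a, b, c, d, carrier percentages, enrichment,
    p_fisher, OR and Woolf CI) with the Bonferroni-adjusted threshold
    ``alpha / n_genes`` stored in ``result.attrs["bonferroni_alpha"]``;
    raw p-values are always reported.  Genes absent from the genotype data
    yield an NA row and a warning.
    """
    if genotypes.labels is None:
        raise InputError("gene_burden_scan requires case/control labels")
    rows = []
    known_genes = set(genotypes.variants.get("gene", pd.Series(dtype=object)))
    for gene in genes:
        if gene not in known_genes:
            warnings.warn(f"gene {gene} absent from genotype data", MissingDataWarning)
            rows.append({"gene": gene})
            continue
        carrier = collapse_carriers(genotypes, gene, qualifying)
        table = carrier_table_from_status(carrier, genotypes.labels)
        p = fisher_exact_two_sided(table)
        try:
            orr = odds_ratio(table, zero_cell_policy=zero_cell_policy)
            or_fields = {
                "OR": orr.estimate,
                "CI_low": orr.ci_low,
                "CI_high": orr.ci_high,
            }
        except InputError:
            or_fields = {"OR": np.nan, "CI_low": np.nan, "CI_high": np.nan}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateStatisticsWarning)
            enr = enrichment_percent(table)
        rows.append(
            {
                "gene": gene,
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "carrier_pct_cases": 100 * table.case_carrier_fraction,
                "carrier_pct_controls": 100 * table.control_carrier_fraction,
                "enrichment_pct": enr,
                "p_fisher": p,
                **or_fields,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out.attrs["bonferroni_alpha"] = alpha / max(1, len(genes))
    return out.sort_values("p_fisher")


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


class CarrierBurdenModel:
    """Carrier-collapsing burden test for one gene, statsmodels-style.

    Construct from explicit counts (:meth:`from_counts`) or from a labelled
    genotype cohort (:meth:`from_cohort`); :meth:`fit` returns a
    :class:`CarrierBurdenResults` with the exact p-value, odds ratio,
    confidence interval and enrichment.
    """

    def __init__(self, table: CarrierTable, gene: str | None = None):
        self.table = table
        self.gene = gene

    @classmethod
    def from_counts(
        cls, a: int, b: int, c: int, d: int, gene: str | None = None
    ) -> "CarrierBurdenModel":
        return cls(CarrierTable(a, b, c, d), gene=gene)

    @classmethod
    def from_cohort(
        cls,
        genotypes: CohortGenotypes,
        gene: str,
        qualifying: Callable[[pd.Series], bool] | None = None,
    ) -> "CarrierBurdenModel":
        if genotypes.labels is None:
            raise InputError("cohort has no case/control labels")
        carrier = collapse_carriers(genotypes, gene, qualifying)
        return cls(carrier_table_from_status(carrier, genotypes.labels), gene=gene)

    def fit(self, zero_cell_policy: str = "haldane") -> "CarrierBurdenResults":
        table = self.table
        p = fisher_exact_two_sided(table)
        try:
            orr = odds_ratio(table, zero_cell_policy=zero_cell_policy)
        except InputError:
            orr = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateStatisticsWarning)
            enr = enrichment_percent(table)
        return CarrierBurdenResults(
            model=self, table=table, p_value=p, odds_ratio=orr, enrichment_pct=enr
        )


@dataclass
class CarrierBurdenResults:
    model: CarrierBurdenModel
    table: CarrierTable
    p_value: float
    odds_ratio: OddsRatioResult | None
    enrichment_pct: float

    def summary(self) -> str:
        t = self.table
        gene = self.model.gene or "gene"
        lines = [
            f"Carrier burden test — {gene}",
            "=" * 40,
            f"cases:    {t.a:>5d} carriers / {t.n_cases:>5d}  "
            f"({100 * t.case_carrier_fraction:.1f}%)",
            f"controls: {t.c:>5d} carriers / {t.n_controls:>5d}  "
            f"({100 * t.control_carrier_fraction:.1f}%)",
            f"enrichment: {self.enrichment_pct:.1f}%",
            f"Fisher exact (two-sided) p = {self.p_value:.3g}",
        ]
        if self.odds_ratio is not None:
            o = self.odds_ratio
            note = " (Haldane-corrected)" if o.haldane_applied else ""
            lines.append(
                f"odds ratio = {o.estimate:.2f} "
                f"(95% CI {o.ci_low:.2f}–{o.ci_high:.2f}){note}"
            )
        return "\n".join(lines)


# independent-oracle helper used by the tests; enumeration via scipy's
# hypergeometric pmf, deliberately separate from the log-space path above
def _fisher_by_enumeration(table: CarrierTable) -> float:  # pragma: no cover
    m1 = table.a + table.c
    n1, n2 = table.n_cases, table.n_controls
    rv = stats.hypergeom(n1 + n2, m1, n1)
    ks = np.arange(max(0, m1 - n2), min(n1, m1) + 1)
    pmf = rv.pmf(ks)
    obs = rv.pmf(table.a)
    return float(min(1.0, pmf[pmf <= obs * (1 + _TIE_RTOL)].sum()))
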