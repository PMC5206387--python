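"""Stage-4 engine: matched-pair transcript comparison and blot densitometry.

Transcript analysis operates on TPM (transcripts per million; per sample,
``TPM_g = 1e6 * (c_g/l_g) / sum_h (c_h/l_h)``, so each sample column sums to
one million).  Mutant/wild-type tissue pairs — matched by age, tissue type
and, when possible, sex and valve anatomy — are compared per gene with a
paired t-test on log2(MUT/WT) ratios after a small pseudocount; the fold
change reported is the geometric mean of the per-pair ratios.  Scans across
many genes report Benjamini-Hochberg q-values alongside raw p.

Densitometry of protein bands is modelled on the log band/loading (GAPDH)
ratio with a fixed pair-block effect and a genotype effect fit by ordinary
least squares; the genotype coefficient back-transforms to a percent
increase, with its standard error propagated by the delta method.  Pair
blocking absorbs per-pair multiplicative batch factors exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateStatisticsWarning, InputError, MissingDataWarning

__all__ = [
    "compute_tpm",
    "MatchedPairSet",
    "PairedDEResult",
    "paired_de_test",
    "DEScanResult",
    "de_scan",
    "PairedExpressionModel",
    "PairedExpressionResults",
    "DensitometryModel",
    "DensitometryResults",
    "densitometry_model",
]

#: pseudocount added to TPM before log transform
DEFAULT_PSEUDOCOUNT = 0.5
#: published-style call thresholds: fold >= 3, p <= 5e-3
DEFAULT_FOLD_MIN = 3.0
DEFAULT_P_MAX = 5e-3

TISSUES = ("atrial_septum", "right_ventricle")


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from a gene x sample count matrix.

    ``lengths``: effective transcript length per gene (> 0).  Every output
    column sums to 1e6; an all-zero sample cannot be normalised and raises.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise InputError(f"genes without lengths: {missing[:5]}")
    if (lengths <= 0).any():
        raise InputError("effective lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        zero = totals[totals == 0].index.tolist()
        raise InputError(f"all-zero sample(s) {zero}: TPM undefined")
    return rate.div(totals, axis=1) * 1e6


@dataclass
class MatchedPairSet:
    """Matched mutant/wild-type tissue pairs plus their expression matrix.

    ``pairs``: one row per pair with pair_id, mut_sample, wt_sample, tissue
    and optional matching covariates (age, sex, anatomy); ``expression``:
    gene x sample TPM matrix covering every sample named in ``pairs``.
    """

    pairs: pd.DataFrame
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("pair_id", "mut_sample", "wt_sample", "tissue"):
            if col not in self.pairs.columns:
                raise InputError(f"pairs table lacks column {col!r}")
        if self.pairs["pair_id"].duplicated().any():
            raise InputError("duplicate pair_id in pairs table")
        bad_tissue = set(self.pairs["tissue"].unique()) - set(TISSUES)
        if bad_tissue:
            raise InputError(f"unknown tissue labels {sorted(bad_tissue)}")
        named = set(self.pairs["mut_sample"]) | set(self.pairs["wt_sample"])
        absent = named - set(self.expression.columns)
        if absent:
            raise InputError(f"samples missing from expression matrix: {sorted(absent)}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def ratios(self, gene: str, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.Series:
        """log2((MUT + eps) / (WT + eps)) per pair; pairs with the gene at zero
        in both members are dropped with a warning."""
        if gene not in self.expression.index:
            raise InputError(f"gene {gene!r} not in expression matrix")
        mut = self.expression.loc[gene, self.pairs["mut_sample"]].to_numpy(float)
        wt = self.expression.loc[gene, self.pairs["wt_sample"]].to_numpy(float)
        both_zero = (mut == 0) & (wt == 0)
        if both_zero.any():
            warnings.warn(
                f"{gene}: {int(both_zero.sum())} pair(s) with zero expression in "
                "both members dropped",
                MissingDataWarning,
            )
        ratios = np.log2((mut + pseudocount) / (wt + pseudocount))[~both_zero]
        return pd.Series(ratios, index=self.pairs.loc[~both_zero, "pair_id"], name=gene)


@dataclass(frozen=True)
class PairedDEResult:
    gene: str
    fold_change: float  # geometric mean of per-pair MUT/WT ratios
    log2_fold: float
    t_statistic: float
    p_value: float
    n_pairs: int
    per_pair_ratios: pd.Series  # log2 scale


def paired_de_test(
    pair_set: MatchedPairSet, gene: str, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> PairedDEResult:
    """Paired t-test on log2 MUT/WT ratios for one gene.

    Requires at least three usable pairs.  Degenerate all-equal ratios give
    p = 1 at ratio 0 (no change) and p = 0 otherwise, with a warning.
    """
    r = pair_set.ratios(gene, pseudocount=pseudocount)
    if len(r) < 3:
        raise InputError(f"{gene}: need >= 3 usable pairs, have {len(r)}")
    mean = float(r.mean())
    sd = float(r.std(ddof=1))
    if sd == 0.0:
        warnings.warn(
            f"{gene}: zero variance across pair ratios", DegenerateStatisticsWarning
        )
        t_stat, p = (0.0, 1.0) if mean == 0.0 else (np.inf, 0.0)
    else:
        t_stat = mean / (sd / np.sqrt(len(r)))
        p = float(2 * stats.t.sf(abs(t_stat), df=len(r) - 1))
    return PairedDEResult(
        gene=gene,
        fold_change=float(2.0**mean),
        log2_fold=mean,
        t_statistic=float(t_stat),
        p_value=p,
        n_pairs=len(r),
        per_pair_ratios=r,
    )


@dataclass
class DEScanResult:
    """Genome-wide paired scan: per-gene folds, t, raw p and BH q."""

    table: pd.DataFrame  # index gene; fold_change, log2_fold, t, p, q
    highlighted: pd.DataFrame  # genes reported separately from the call list
    fold_min: float
    p_max: float

    @property
    def calls(self) -> pd.DataFrame:
        """Genes passing both thresholds (|log2 fold| and raw p), ranked by p."""
        t = self.table
        passing = (np.abs(t["log2_fold"]) >= np.log2(self.fold_min)) & (
            t["p"] <= self.p_max
        )
        return t[passing].sort_values("p")


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def de_scan(
    pair_set: MatchedPairSet,
    genes: list[str] | None = None,
    fold_min: float = DEFAULT_FOLD_MIN,
    p_max: float = DEFAULT_P_MAX,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    report_separately: tuple[str, ...] = ("MYH6",),
) -> DEScanResult:
    """Vectorised paired scan over many genes with BH correction.

    Genes named in ``report_separately`` (by default the collapsed-test gene
    itself, whose transcript level is a distinct question from its variant
    burden) are excluded from the call list and surfaced in ``highlighted``.
    """
    expr = pair_set.expression
    genes = list(genes) if genes is not None else list(expr.index)
    mut = expr.loc[genes, pair_set.pairs["mut_sample"]].to_numpy(float)
    wt = expr.loc[genes, pair_set.pairs["wt_sample"]].to_numpy(float)
    r = np.log2((mut + pseudocount) / (wt + pseudocount))
    n = r.shape[1]
    if n < 3:
        raise InputError("de_scan needs >= 3 pairs")
    mean = r.mean(axis=1)
    sd = r.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(np.abs(t_stat), df=n - 1)
    zero_sd = sd == 0
    p[zero_sd & (mean == 0)] = 1.0
    p[zero_sd & (mean != 0)] = 0.0
    table = pd.DataFrame(
        {
            "fold_change": 2.0**mean,
            "log2_fold": mean,
            "t": t_stat,
            "p": p,
            "q": _bh_qvalues(p),
        },
        index=pd.Index(genes, name="gene"),
    )
    sep = [g for g in report_separately if g in table.index]
    return DEScanResult(
        table=table.drop(index=sep),
        highlighted=table.loc[sep],
        fold_min=fold_min,
        p_max=p_max,
    )


class PairedExpressionModel:
    """Matched-pair differential expression, statsmodels-style.

    ``fit(genes=...)`` runs the paired scan and returns
    :class:`PairedExpressionResults`; ``fit_gene`` gives the detailed
    single-gene result with per-pair ratios.
    """

    def __init__(self, pair_set: MatchedPairSet, pseudocount: float = DEFAULT_PSEUDOCOUNT):
        self.pair_set = pair_set
        self.pseudocount = pseudocount

    def fit_gene(self, gene: str) -> PairedDEResult:
        return paired_de_test(self.pair_set, gene, pseudocount=self.pseudocount)

    def fit(
        self,
        genes: list[str] | None = None,
        fold_min: float = DEFAULT_FOLD_MIN,
        p_max: float = DEFAULT_P_MAX,
        report_separately: tuple[str, ...] = ("MYH6",),
    ) -> "PairedExpressionResults":
        scan = de_scan(
            self.pair_set,
            genes=genes,
            fold_min=fold_min,
            p_max=p_max,
            pseudocount=self.pseudocount,
            report_separately=report_separately,
        )
        return PairedExpressionResults(model=self, scan=scan)


@dataclass
class PairedExpressionResults:
    model: PairedExpressionModel
    scan: DEScanResult

    @property
    def table(self) -> pd.DataFrame:
        return self.scan.table

    def significant(self) -> pd.DataFrame:
        return self.scan.calls

    def summary(self, top: int = 10) -> str:
        calls = self.scan.calls
        lines = [
            "Matched-pair differential expression",
            "=" * 40,
            f"pairs: {self.model.pair_set.n_pairs}, genes tested: {len(self.scan.table)}",
            f"thresholds: fold >= {self.scan.fold_min:g}, p <= {self.scan.p_max:g}",
            f"significant genes: {len(calls)}",
        ]
        for gene, row in calls.head(top).iterrows():
            lines.append(
                f"  {gene}: fold {row['fold_change']:.2f}, "
                f"p = {row['p']:.2e}, q = {row['q']:.2e}"
            )
        for gene, row in self.scan.highlighted.iterrows():
            lines.append(
                f"  [{gene}, reported separately] fold {row['fold_change']:.2f}, "
                f"p = {row['p']:.2e}"
            )
        return "\n".join(lines)


class DensitometryModel:
    """Pair-blocked linear model for band densities, statsmodels-style.

    Response is log(band / GAPDH); design is an intercept, fixed pair
    effects and a mutant-genotype indicator.  The fitted genotype
    coefficient ``beta`` reports as ``100*(exp(beta) - 1)`` percent with a
    delta-method standard error.
    """

    def __init__(self, records: pd.DataFrame):
        for col in ("pair_id", "genotype", "band", "gapdh"):
            if col not in records.columns:
                raise InputError(f"densitometry records lack column {col!r}")
        if (records["band"] <= 0).any() or (records["gapdh"] <= 0).any():
            raise InputError("band and gapdh densities must be positive")
        genotypes = set(records["genotype"].unique())
        if genotypes != {"MUT", "WT"}:
            raise InputError(
                f"need both MUT and WT observations, got {sorted(genotypes)}"
            )
        if records["pair_id"].nunique() < 2:
            raise InputError("need >= 2 pairs for a blocked analysis")
        self.records = records.copy()

    def fit(self) -> "DensitometryResults":
        import statsmodels.formula.api as smf

        df = self.records.copy()
        df["log_ratio"] = np.log(df["band"] / df["gapdh"])
        df["is_mut"] = (df["genotype"] == "MUT").astype(float)
        ols = smf.ols("log_ratio ~ C(pair_id) + is_mut", data=df).fit()
        beta = float(ols.params["is_mut"])
        se_beta = float(ols.bse["is_mut"])
        percent = 100.0 * (np.exp(beta) - 1.0)
        se_percent = 100.0 * np.exp(beta) * se_beta  # delta method
        return DensitometryResults(
            model=self,
            percent_increase=percent,
            se_percent=se_percent,
            beta_log=beta,
            se_beta_log=se_beta,
            p_value=float(ols.pvalues["is_mut"]),
            ols_results=ols,
        )


@dataclass
class DensitometryResults:
    model: DensitometryModel
    percent_increase: float
    se_percent: float
    beta_log: float
    se_beta_log: float
    p_value: float
    ols_results: object

    def summary(self) -> str:
        n_pairs = self.model.records["pair_id"].nunique()
        return "\n".join(
            [
                "Densitometry (pair-blocked linear model on log band/GAPDH)",
                "=" * 40,
                f"pairs: {n_pairs}, observations: {len(self.model.records)}",
                f"genotype effect: {self.percent_increase:+.1f}% "
                f"(SE {self.se_percent:.1f} points), p = {self.p_value:.3g}",
            ]
        )


def densitometry_model(records: pd.DataFrame) -> DensitometryResults:
    """Functional wrapper: build the pair-blocked model and fit it."""
    return DensitometryModel(records).fit()
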