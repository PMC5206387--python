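"""TPM normalisation, matched-pair DE testing and densitometry modelling."""

import numpy as np
import pandas as pd
import pytest

from cardioburden.exceptions import DegenerateStatisticsWarning, InputError, MissingDataWarning
from cardioburden.expression import (
    DensitometryModel,
    MatchedPairSet,
    PairedExpressionModel,
    compute_tpm,
    de_scan,
    densitometry_model,
    paired_de_test,
)
from cardioburden.simulate import (
    DensitometryConfig,
    ExpressionConfig,
    simulate_densitometry,
    simulate_expression,
)


class TestTpm:
    def test_length_normalisation(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 1000.0, "g2": 2000.0})
        tpm = compute_tpm(counts, lengths)
        assert tpm["s1"].tolist() == pytest.approx([2e6 / 3, 1e6 / 3])

    def test_single_gene_gets_everything(self):
        tpm = compute_tpm(
            pd.DataFrame({"s1": [7]}, index=["g1"]), pd.Series({"g1": 500.0})
        )
        assert tpm.loc["g1", "s1"] == pytest.approx(1e6)

    def test_columns_conserve_one_million(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(50, 6)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(6)],
        )
        lengths = pd.Series(rng.uniform(200, 5000, 50), index=counts.index)
        totals = compute_tpm(counts, lengths).sum(axis=0)
        assert np.allclose(totals, 1e6, rtol=1e-6)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(InputError, match="all-zero"):
            compute_tpm(counts, pd.Series({"g1": 100.0, "g2": 100.0}))


def tiny_pair_set(mut, wt, gene="MYH7", n_extra_genes=0, rng=None):
    n = len(mut)
    pairs = pd.DataFrame(
        {
            "pair_id": [f"P{i}" for i in range(n)],
            "mut_sample": [f"P{i}_M" for i in range(n)],
            "wt_sample": [f"P{i}_W" for i in range(n)],
            "tissue": ["atrial_septum"] * n,
        }
    )
    data = {f"P{i}_M": [mut[i]] for i in range(n)} | {
        f"P{i}_W": [wt[i]] for i in range(n)
    }
    expr = pd.DataFrame(data, index=[gene])
    if n_extra_genes:
        extra = rng.uniform(1, 100, size=(n_extra_genes, 2 * n))
        expr = pd.concat(
            [expr, pd.DataFrame(extra, index=[f"x{i}" for i in range(n_extra_genes)],
                                columns=expr.columns)]
        )
    return MatchedPairSet(pairs=pairs, expression=expr)


class TestPairedDeTest:
    def test_identical_profiles_fold_one_p_one(self):
        ps = tiny_pair_set([5.0, 8.0, 2.0, 4.0], [5.0, 8.0, 2.0, 4.0])
        with pytest.warns(DegenerateStatisticsWarning):
            r = paired_de_test(ps, "MYH7")
        assert r.fold_change == 1.0 and r.p_value == 1.0

    def test_fold_is_geometric_mean_of_pair_ratios(self):
        ps = tiny_pair_set([2.0, 8.0, 4.0], [1.0, 1.0, 1.0])
        r = paired_de_test(ps, "MYH7", pseudocount=0.0)
        assert r.fold_change == pytest.approx((2 * 8 * 4) ** (1 / 3))

    def test_scaling_mut_samples_scales_fold(self):
        rng = np.random.default_rng(2)
        mut = rng.uniform(5, 50, 6)
        wt = rng.uniform(5, 50, 6)
        base = paired_de_test(tiny_pair_set(mut, wt), "MYH7", pseudocount=0.0)
        scaled = paired_de_test(tiny_pair_set(3.0 * mut, wt), "MYH7", pseudocount=0.0)
        assert scaled.fold_change == pytest.approx(3.0 * base.fold_change)

    def test_zero_in_both_members_drops_pair(self):
        ps = tiny_pair_set([0.0, 4.0, 2.0, 8.0], [0.0, 2.0, 1.0, 4.0])
        with pytest.warns(MissingDataWarning):
            r = paired_de_test(ps, "MYH7")
        assert r.n_pairs == 3

    def test_too_few_pairs_rejected(self):
        ps = tiny_pair_set([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(InputError, match=">= 3"):
            paired_de_test(ps, "MYH7")

    def test_planted_fold_recovered(self):
        ps, truth = simulate_expression(ExpressionConfig(n_genes=20), seed=5)
        r = paired_de_test(ps, "MYH7")
        assert abs(r.fold_change - 3.46) / 3.46 < 0.15
        assert r.p_value <= 5e-3


class TestDeScan:
    PLANTED = (("MYH7", 3.46), ("TNNT2", 4.0), ("ACTA1", 6.0),
               ("MYL2", 9.0), ("XIRP2", 12.0))

    def test_planted_genes_called_exactly(self):
        """Five planted upregulated genes among 2000: the call list recovers
        exactly those in the large majority of replicates."""
        seeds = np.random.SeedSequence(31).generate_state(20)
        exact = 0
        for s in seeds:
            ps, truth = simulate_expression(
                ExpressionConfig(n_genes=2000, planted_folds=self.PLANTED),
                seed=int(s) % (2**31),
            )
            calls = de_scan(ps).calls
            exact += set(calls.index) == {g for g, _ in self.PLANTED}
        assert exact / 20 >= 0.9

    def test_larger_fold_ranks_higher(self):
        ps, _ = simulate_expression(
            ExpressionConfig(n_genes=200, planted_folds=self.PLANTED), seed=13
        )
        calls = de_scan(ps).calls
        assert list(calls.index).index("XIRP2") < list(calls.index).index("MYH7")

    def test_infinite_fold_threshold_empties_calls(self):
        ps, _ = simulate_expression(ExpressionConfig(n_genes=50), seed=3)
        assert de_scan(ps, fold_min=np.inf).calls.empty

    def test_burden_gene_reported_separately(self):
        ps, _ = simulate_expression(ExpressionConfig(n_genes=50), seed=3)
        scan = de_scan(ps)
        assert "MYH6" in scan.highlighted.index
        assert "MYH6" not in scan.table.index

    def test_null_fdr_calibration(self):
        """No planted effect: BH at 0.05 calls <= 5% of null genes on average."""
        seeds = np.random.SeedSequence(41).generate_state(10)
        fracs = []
        for s in seeds:
            ps, _ = simulate_expression(
                ExpressionConfig(n_genes=1000, planted_folds=()), seed=int(s) % (2**31)
            )
            scan = de_scan(ps)
            fracs.append((scan.table["q"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05

    def test_model_surface_summary(self):
        ps, _ = simulate_expression(ExpressionConfig(n_genes=100), seed=5)
        res = PairedExpressionModel(ps).fit()
        assert "MYH7" in res.significant().index
        assert "significant genes" in res.summary()


class TestDensitometry:
    def test_identical_genotypes_give_zero_percent(self):
        rows = []
        for p in range(3):
            for genotype in ("MUT", "WT"):
                for rep in range(2):
                    rows.append(
                        {"pair_id": f"p{p}", "genotype": genotype,
                         "replicate": rep, "band": 2.0 + p, "gapdh": 1.0}
                    )
        res = densitometry_model(pd.DataFrame(rows))
        assert res.percent_increase == pytest.approx(0.0, abs=1e-9)

    def test_loading_normalisation_invariance(self):
        df, _ = simulate_densitometry(DensitometryConfig(), seed=6)
        res1 = densitometry_model(df)
        doubled = df.assign(gapdh=2 * df["gapdh"], band=df["band"])
        # doubling GAPDH halves every ratio equally; only the intercept moves
        res2 = densitometry_model(doubled)
        assert res2.percent_increase == pytest.approx(res1.percent_increase)
        assert res2.se_percent == pytest.approx(res1.se_percent)

    def test_pair_batch_factors_absorbed(self):
        df, _ = simulate_densitometry(DensitometryConfig(), seed=6)
        factors = {pid: 2.0 ** i for i, pid in enumerate(df["pair_id"].unique())}
        scaled = df.assign(band=df["band"] * df["pair_id"].map(factors))
        assert densitometry_model(scaled).percent_increase == pytest.approx(
            densitometry_model(df).percent_increase
        )

    def test_single_genotype_rejected(self):
        df, _ = simulate_densitometry(DensitometryConfig(), seed=6)
        with pytest.raises(InputError):
            DensitometryModel(df[df["genotype"] == "MUT"])

    def test_two_se_coverage_near_nominal(self):
        """Planted +62%: the ±2·SE interval covers the truth at the t-based
        nominal rate (~94.7% with 35 df), within binomial noise."""
        seeds = np.random.SeedSequence(61).generate_state(200)
        covered = 0
        for s in seeds:
            df, _ = simulate_densitometry(DensitometryConfig(), seed=int(s) % (2**31))
            r = densitometry_model(df)
            covered += abs(r.percent_increase - 62.0) <= 2 * r.se_percent
        assert covered / 200 >= 0.90  # 3.5 binomial SDs below the 94.7% nominal
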