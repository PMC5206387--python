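"""Exact Fisher test, odds ratio, enrichment and the gene-level burden scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardioburden.burden import (
    CarrierBurdenModel,
    CarrierTable,
    _fisher_by_enumeration,
    carrier_table_from_status,
    collapse_carriers,
    enrichment_percent,
    fisher_exact_two_sided,
    gene_burden_scan,
    odds_ratio,
)
from cardioburden.exceptions import DegenerateStatisticsWarning, InputError, MissingDataWarning
from cardioburden.simulate import CohortConfig, simulate_cohort, simulate_multigene_cohort

from conftest import make_cohort


class TestFisherExact:
    def test_small_table_enumeration_value(self):
        # support C(8,4)=70; tables at most as probable as (3,1): 34/70
        assert fisher_exact_two_sided(CarrierTable(3, 1, 1, 3)) == pytest.approx(
            34 / 70, rel=1e-12
        )

    def test_no_carriers_anywhere_gives_one(self):
        assert fisher_exact_two_sided(CarrierTable(0, 10, 0, 10)) == 1.0

    def test_reconstructed_cohort_table(self):
        """20/190 case carriers vs 31/1063 control carriers: strong enrichment."""
        p = fisher_exact_two_sided(CarrierTable(20, 170, 31, 1032))
        assert p == pytest.approx(
            float(stats.fisher_exact([[20, 170], [31, 1032]])[1]), rel=1e-10
        )
        assert p < 1e-4

    def test_degenerate_margin_rejected(self):
        with pytest.raises(InputError):
            fisher_exact_two_sided(CarrierTable(0, 0, 1, 1))

    def test_negative_cell_rejected(self):
        with pytest.raises(InputError):
            CarrierTable(-1, 1, 1, 1)

    def test_transpose_and_relabel_invariance(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 15, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            t = CarrierTable(int(a), int(b), int(c), int(d))
            p = fisher_exact_two_sided(t)
            assert fisher_exact_two_sided(t.transpose()) == pytest.approx(p, rel=1e-9)
            assert fisher_exact_two_sided(
                CarrierTable(int(c), int(d), int(a), int(b))
            ) == pytest.approx(p, rel=1e-9)

    def test_matches_enumeration_oracle_on_random_tables(self):
        """Log-space implementation vs scipy-pmf enumeration, margins <= 30."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 200:
            a, b, c, d = rng.integers(0, 16, size=4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            t = CarrierTable(int(a), int(b), int(c), int(d))
            assert fisher_exact_two_sided(t) == pytest.approx(
                _fisher_by_enumeration(t), rel=1e-10
            )
            checked += 1


class TestOddsRatio:
    def test_null_table(self):
        assert odds_ratio(CarrierTable(1, 1, 1, 1)).estimate == 1.0

    def test_cohort_table_estimate_and_ci(self):
        r = odds_ratio(CarrierTable(20, 170, 31, 1032))
        assert r.estimate == pytest.approx((20 * 1032) / (170 * 31), rel=1e-12)
        assert r.estimate == pytest.approx(3.92, abs=0.01)
        assert (r.ci_low, r.ci_high) == (pytest.approx(2.18, abs=0.01),
                                         pytest.approx(7.03, abs=0.01))

    def test_haldane_correction_value(self):
        r = odds_ratio(CarrierTable(0, 10, 5, 5), zero_cell_policy="haldane")
        assert r.estimate == pytest.approx((0.5 * 5.5) / (10.5 * 5.5), rel=1e-12)
        assert r.haldane_applied

    def test_zero_cell_without_policy_errors(self):
        with pytest.raises(InputError, match="zero cell"):
            odds_ratio(CarrierTable(0, 10, 5, 5))

    def test_haldane_converges_to_raw_or_for_large_cells(self):
        for k in (1, 10, 100):
            t = CarrierTable(4 * k, 6 * k, 2 * k, 8 * k)
            raw = odds_ratio(t).estimate
            haldane = odds_ratio(
                CarrierTable(t.a, t.b, t.c, t.d), zero_cell_policy="haldane"
            )
            # forcing the correction on a zero-free table: converges as cells grow
            corrected = ((t.a + 0.5) * (t.d + 0.5)) / ((t.b + 0.5) * (t.c + 0.5))
            assert abs(corrected - raw) / raw < 1.0 / k


class TestEnrichment:
    def test_cohort_value(self):
        assert enrichment_percent(CarrierTable(20, 170, 31, 1032)) == pytest.approx(
            360.95, abs=0.01
        )

    @pytest.mark.parametrize("table", [CarrierTable(5, 5, 5, 5), CarrierTable(10, 90, 10, 90)])
    def test_equal_fractions_give_100(self, table):
        assert enrichment_percent(table) == pytest.approx(100.0)

    def test_zero_control_carriers_reports_infinite(self):
        with pytest.warns(DegenerateStatisticsWarning):
            assert enrichment_percent(CarrierTable(5, 5, 0, 10)) == np.inf


class TestCollapseCarriers:
    def test_fixture_cohort_has_20_carriers(self, table1_records):
        """Joining the published variant list to a 190-case cohort yields 20
        carriers: the compound-het subject counts once."""
        subjects = [f"case_{i}" for i in range(190)]
        carrier_of = {}
        for i, r in enumerate(table1_records):
            carrier_of.setdefault(r.subject_id, []).append(i)
        id_map = {s: f"case_{j}" for j, s in enumerate(sorted(carrier_of))}
        counts = {}
        for i, r in enumerate(table1_records):
            counts[f"v{i}"] = {
                s: (1.0 if id_map.get(r.subject_id) == s else 0.0) for s in subjects
            }
        cohort = make_cohort(
            counts,
            labels={s: "case" for s in subjects},
            genes={f"v{i}": "MYH6" for i in range(len(table1_records))},
        )
        carrier = collapse_carriers(cohort, "MYH6")
        assert int(carrier.sum()) == 20

    def test_multi_variant_subject_counts_once(self):
        cohort = make_cohort(
            {"v1": {"s1": 1.0, "s2": 0.0}, "v2": {"s1": 1.0, "s2": 0.0}},
            genes={"v1": "G", "v2": "G"},
        )
        assert int(collapse_carriers(cohort, "G").sum()) == 1

    def test_empty_qualifying_set_gives_zero_carriers(self):
        cohort = make_cohort({"v1": {"s1": 1.0}}, genes={"v1": "G"})
        carrier = collapse_carriers(cohort, "G", qualifying=lambda row: False)
        assert int(carrier.sum()) == 0

    def test_all_missing_subject_excluded_with_warning(self):
        cohort = make_cohort(
            {"v1": {"s1": 1.0, "s2": np.nan}, "v2": {"s1": 0.0, "s2": np.nan}},
            genes={"v1": "G", "v2": "G"},
        )
        with pytest.warns(MissingDataWarning):
            carrier = collapse_carriers(cohort, "G")
        assert "s2" not in carrier.index


class TestBurdenScan:
    def test_planted_gene_has_smallest_p(self):
        cohort, truth = simulate_multigene_cohort(
            n_genes=20, planted_gene="GENE07", seed=5
        )
        report = gene_burden_scan(cohort, truth["genes"])
        assert report.index[0] == "GENE07"
        assert report.attrs["bonferroni_alpha"] == pytest.approx(0.05 / 20)

    def test_null_scan_rarely_beats_bonferroni(self):
        """All-null 20-gene scans: familywise error control at ~alpha."""
        seeds = np.random.SeedSequence(99).generate_state(60)
        clean = 0
        for s in seeds:
            cohort, truth = simulate_multigene_cohort(
                n_genes=20, planted_gene=None, seed=int(s) % (2**31)
            )
            report = gene_burden_scan(cohort, truth["genes"])
            clean += bool((report["p_fisher"] >= 0.05 / 20).all())
        assert clean / len(seeds) >= 0.9

    def test_single_gene_threshold_equals_alpha(self):
        cohort, truth = simulate_multigene_cohort(n_genes=1, planted_gene="GENE01", seed=3)
        report = gene_burden_scan(cohort, ["GENE01"], alpha=0.05)
        assert report.attrs["bonferroni_alpha"] == 0.05

    def test_unknown_gene_gives_na_row_and_warning(self):
        cohort, truth = simulate_multigene_cohort(n_genes=2, planted_gene=None, seed=3)
        with pytest.warns(MissingDataWarning):
            report = gene_burden_scan(cohort, ["GENE01", "NOT_A_GENE"])
        assert np.isnan(report.loc["NOT_A_GENE", "p_fisher"])


class TestModelSurface:
    def test_from_cohort_matches_truth(self):
        cohort, truth = simulate_cohort(CohortConfig(), seed=1)
        res = CarrierBurdenModel.from_cohort(cohort, "MYH6").fit()
        assert res.table.a == truth["case_carriers"]
        assert res.table.c == truth["control_carriers"]
        assert 0 < res.p_value <= 1

    def test_summary_reports_key_quantities(self):
        res = CarrierBurdenModel.from_counts(20, 170, 31, 1032, gene="MYH6").fit()
        text = res.summary()
        assert "MYH6" in text and "odds ratio" in text and "Fisher" in text
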