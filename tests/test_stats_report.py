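import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rumenamp.config_and_io import relative_abundance
from rumenamp.stats_report import (
    build_report,
    fold_change,
    pearson,
    select_main_otus,
    ttest_from_raw,
    ttest_from_summary,
)
from rumenamp.taxonomy import TaxonomyAssignment


class TestSelectMainOtus:
    def _rel(self, rows):
        return pd.DataFrame(
            rows, index=[f"OTU_{i}" for i in range(len(rows))],
            columns=["a1", "a2", "b1", "b2"],
        )

    def test_exactly_one_percent_retained(self):
        rel = self._rel([[1.0, 1.0, 0.1, 0.1]])
        groups = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        assert select_main_otus(rel, groups) == ["OTU_0"]

    def test_just_below_excluded(self):
        rel = self._rel([[0.99, 0.99, 0.99, 0.99]])
        groups = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        assert select_main_otus(rel, groups) == []

    def test_planted_main_taxa_recovered(self, rng):
        n_otu = 20
        base = np.full((n_otu, 10), 0.2)
        planted = [0, 3, 7, 11, 19]
        for p in planted:
            base[p, :5] = 2.0  # >= 1% in group A only
        rel = pd.DataFrame(
            base, index=[f"OTU_{i:02d}" for i in range(n_otu)],
            columns=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)],
        )
        groups = {"A": [f"a{i}" for i in range(5)], "B": [f"b{i}" for i in range(5)]}
        assert select_main_otus(rel, groups) == [f"OTU_{p:02d}" for p in planted]


class TestTTestFromSummary:
    @pytest.mark.parametrize("row, printed", [
        ((43.68, 6.92, 73.22, 6.79), 0.0069),
        ((19.51, 5.32, 2.70, 1.80), 0.008),
        ((44.63, 6.28, 13.45, 6.02), 0.0021),
    ])
    def test_reproduces_printed_p_values(self, row, printed):
        ma, sa, mb, sb = row
        comp = ttest_from_summary(ma, sa, 10, mb, sb, 10)
        decimals = len(str(printed).split(".")[1])
        assert round(comp.p_value, decimals) == printed

    def test_identical_groups(self):
        comp = ttest_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert comp.t_stat == 0.0
        assert comp.p_value == 1.0

    def test_degenerate_zero_spread(self):
        comp = ttest_from_summary(5.0, 0.0, 10, 4.0, 0.0, 10)
        assert comp.degenerate and comp.p_value == 0.0
        comp = ttest_from_summary(5.0, 0.0, 10, 5.0, 0.0, 10)
        assert comp.p_value == 1.0 and not comp.degenerate

    def test_df_and_equal_n_shortcut(self):
        comp = ttest_from_summary(10.0, 2.0, 10, 7.0, 1.0, 10)
        assert comp.df == 18
        # for n_a == n_b pooled t equals (ma-mb)/sqrt(sem_a^2+sem_b^2)
        assert comp.t_stat == pytest.approx(3.0 / math.sqrt(4.0 + 1.0))

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ttest_from_summary(1.0, 0.5, 1, 2.0, 0.5, 10)


class TestTTestFromRaw:
    def test_identical_lists(self):
        comp = ttest_from_raw([1, 2, 3], [1, 2, 3])
        assert comp.p_value == 1.0

    def test_textbook_worked_example(self):
        # [5,7,9,6,8] vs [10,12,14,11,13]: means 7 and 12, each variance 2.5,
        # pooled variance 2.5, SE = sqrt(2.5 * 2/5) = 1, so t = -5, df = 8.
        comp = ttest_from_raw([5, 7, 9, 6, 8], [10, 12, 14, 11, 13])
        assert comp.t_stat == pytest.approx(-5.0)
        assert comp.df == 8
        from scipy import stats as sps
        assert comp.p_value == pytest.approx(2 * sps.t.sf(5.0, 8))

    def test_matches_summary_form(self, rng):
        a = rng.normal(10, 2, size=8)
        b = rng.normal(11, 3, size=12)
        raw = ttest_from_raw(a, b)
        summary = ttest_from_summary(raw.mean_a, raw.sem_a, 8,
                                     raw.mean_b, raw.sem_b, 12)
        assert raw.p_value == pytest.approx(summary.p_value, abs=1e-12)
        assert raw.t_stat == pytest.approx(summary.t_stat, abs=1e-12)

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError):
            ttest_from_raw([1.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_linear(self):
        assert pearson([1, 2, 3, 4], [2, 4, 6, 8]).r == pytest.approx(1.0)

    def test_location_invariance(self):
        x = [1.0, 4.0, 2.0, 8.0, 5.0]
        assert pearson(x, [v + 100 for v in x]).r == pytest.approx(1.0)

    def test_r_half_n_12_closed_form(self):
        # construct data with r exactly 0.5 at n = 12:
        # y = 0.5 x + sqrt(0.75) e with e orthogonal to x, both standardized
        rng = np.random.default_rng(4)
        x = rng.normal(size=12)
        e = rng.normal(size=12)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= x * (e @ x) / (x @ x)
        e /= e.std()
        y = 0.5 * x + math.sqrt(0.75) * e
        res = pearson(x, y)
        assert res.r == pytest.approx(0.5, abs=1e-12)
        # t = 0.5 sqrt(10)/sqrt(0.75) = 1.8257, two-sided p ~ 0.098
        assert res.p_value == pytest.approx(0.0979, abs=5e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])

    def test_min_n(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])


class TestFoldChange:
    def test_paper_ratios(self):
        assert round(fold_change(19.51, 2.70), 1) == 7.2
        assert round(fold_change(3.44, 0.17), 1) == 20.2

    def test_equal_means(self):
        assert fold_change(4.2, 4.2) == pytest.approx(1.0)

    def test_zero_denominator_is_infinite(self):
        assert math.isinf(fold_change(1.0, 0.0))

    @given(st.floats(0.01, 1e6), st.floats(0.01, 1e6))
    def test_reciprocal_property(self, a, b):
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)


def _study_tables(rng, enrich_factor=1.0):
    samples = [f"EO{i:02d}" for i in range(1, 6)] + [f"Co{i:02d}" for i in range(1, 6)]
    otus = [f"OTU_{i:05d}" for i in range(1, 9)]
    counts = pd.DataFrame(
        rng.integers(50, 200, size=(8, 10)), index=otus, columns=samples
    )
    counts.loc["OTU_00001", samples[:5]] = (
        counts.loc["OTU_00001", samples[:5]] * enrich_factor
    ).astype(int)
    lineages = {
        otu: ("Bacteria", phylum, "C", "O", family, "G")
        for otu, (phylum, family) in zip(otus, [
            ("PhylumA", "Fam1"), ("PhylumA", "Fam1"), ("PhylumA", "Fam2"),
            ("PhylumA", "Fam2"), ("PhylumB", "Fam3"), ("PhylumB", "Fam3"),
            ("PhylumB", "Fam4"), ("PhylumB", "Fam4"),
        ])
    }
    assignments = {
        otu: TaxonomyAssignment(
            otu_id=otu, lineage=lineages[otu], raw_lineage=lineages[otu],
            bootstrap_conf=(1.0,) * 6, best_hit_id="REF_000", best_hit_identity=97,
        )
        for otu in otus
    }
    metadata = pd.DataFrame({
        "sample_id": samples,
        "treatment": ["EO"] * 5 + ["Control"] * 5,
        "propionate_mM": rng.normal(35, 5, size=10).round(2),
        "butyrate_mM": rng.normal(6, 1, size=10).round(2),
    }).set_index("sample_id")
    return counts, assignments, metadata


class TestBuildReport:
    def test_total_rows_sum_printed_precision(self, rng):
        counts, assignments, metadata = _study_tables(rng)
        rel = relative_abundance(counts)
        report = build_report(rel, assignments, metadata)
        main = report["main_otus"]
        for phylum in ("PhylumA", "PhylumB"):
            block = main[(main["phylum"] == phylum)
                         & (~main.index.str.startswith("Total"))]
            total = main.loc[f"Total {phylum}"]
            for col in ("mean_EO", "mean_Control"):
                assert total[col] == pytest.approx(
                    round(block[col].round(2).sum(), 2)
                )

    def test_family_abundances_nest_in_phylum(self, rng):
        counts, assignments, metadata = _study_tables(rng)
        rel = relative_abundance(counts)
        report = build_report(rel, assignments, metadata)
        taxa = report["taxa"]
        for phylum in ("PhylumA", "PhylumB"):
            families = taxa[(taxa["level"] == "family") & (taxa["phylum"] == phylum)]
            phylum_row = taxa[(taxa["level"] == "phylum") & (taxa.index == phylum)]
            for col in ("mean_EO", "mean_Control"):
                assert families[col].sum() == pytest.approx(
                    phylum_row[col].iloc[0]
                )

    def test_missing_metadata_sample_rejected(self, rng):
        counts, assignments, metadata = _study_tables(rng)
        rel = relative_abundance(counts)
        with pytest.raises(KeyError):
            build_report(rel, assignments, metadata.drop(index="EO01"))

    def test_planted_enrichment_flagged(self, rng):
        counts, assignments, metadata = _study_tables(rng, enrich_factor=10.0)
        rel = relative_abundance(counts)
        report = build_report(rel, assignments, metadata)
        assert report["main_otus"].loc["OTU_00001", "p_value"] <= 0.05

    def test_correlations_cover_main_otus(self, rng):
        counts, assignments, metadata = _study_tables(rng)
        rel = relative_abundance(counts)
        report = build_report(rel, assignments, metadata)
        corr = report["correlations"]
        assert set(corr["covariate"]) == {"propionate_mM", "butyrate_mM"}
        assert ((corr["r"] >= -1) & (corr["r"] <= 1)).all()

    def test_alpha_block_when_counts_given(self, rng):
        counts, assignments, metadata = _study_tables(rng)
        rel = relative_abundance(counts)
        report = build_report(rel, assignments, metadata, counts=counts)
        assert set(report["alpha"].index) == {
            "chao1", "observed_otus", "shannon", "simpson", "coverage"
        }
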