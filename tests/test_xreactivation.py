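"""X-reactivation classification: sums, binning, intervals, classifiers, DE."""

import numpy as np
import pandas as pd
import pytest

import germase as g
from conftest import make_profiles
from germase.xreactivation import gene_bias, locate_bin


def summaries_frame(rows):
    df = pd.DataFrame(
        rows, columns=["cell_id", "chromosome", "maternal", "paternal",
                       "n_snp_genes"]
    )
    df["total"] = df["maternal"] + df["paternal"]
    df["paternal_fraction"] = df["paternal"] / df["total"]
    df["bias"] = np.maximum(df["maternal"], df["paternal"]) / df["total"]
    return df


class TestPartition:
    def test_no_escapees_all_proper(self, germ_annotation):
        ann = germ_annotation.assign(escapee=False)
        part = g.partition_x_genes(ann)
        assert part.escapee_genes == frozenset()
        assert {"x0", "esc0"} <= set(part.proper_genes)

    def test_all_escapee_empty_proper(self, germ_annotation):
        x_genes = germ_annotation.loc[
            germ_annotation["chromosome"] == "X", "gene"
        ]
        part = g.partition_x_genes(germ_annotation, escapee_list=x_genes)
        assert part.proper_genes == frozenset()

    def test_set_difference_brute_force(self, germ_annotation):
        part = g.partition_x_genes(germ_annotation)
        x_genes = set(
            germ_annotation.loc[germ_annotation["chromosome"] == "X", "gene"]
        )
        assert set(part.proper_genes) | set(part.escapee_genes) == x_genes
        assert len(part.proper_genes) == len(x_genes) - 2


class TestChromosomeSums:
    def test_arithmetic(self, germ_annotation):
        rows = [("c", "a1_0", 3, 1), ("c", "a1_1", 2, 2)]
        m = g.AllelicCountMatrix(pd.DataFrame(
            rows, columns=["cell_id", "gene", "maternal_reads", "paternal_reads"]
        ))
        out = g.chromosome_allelic_sums(m, germ_annotation)
        row = out.iloc[0]
        assert (row["maternal"], row["paternal"]) == (5, 3)
        assert row["bias"] == pytest.approx(0.625)

    def test_single_monoallelic_gene(self, germ_annotation):
        m = g.AllelicCountMatrix(pd.DataFrame(
            [("c", "a1_0", 0, 10)],
            columns=["cell_id", "gene", "maternal_reads", "paternal_reads"],
        ))
        out = g.chromosome_allelic_sums(m, germ_annotation)
        assert out.iloc[0]["bias"] == 1.0

    def test_brute_force_tally(self, germ_sim, germ_annotation):
        matrix, *_ = germ_sim
        part = g.partition_x_genes(germ_annotation)
        out = g.chromosome_allelic_sums(matrix, germ_annotation, part)
        chrom_of = germ_annotation.set_index("gene")["chromosome"].to_dict()
        cell = out["cell_id"].iloc[0]
        tally = {}
        for r in matrix.data[matrix.data["cell_id"] == cell].itertuples():
            c = chrom_of[r.gene]
            if c == "X" and r.gene not in part.proper_genes:
                continue
            m, p = tally.get(c, (0, 0))
            tally[c] = (m + r.maternal_reads, p + r.paternal_reads)
        sub = out[out["cell_id"] == cell].set_index("chromosome")
        for c, (m, p) in tally.items():
            if m + p == 0:
                assert c not in sub.index
            else:
                assert (sub.loc[c, "maternal"], sub.loc[c, "paternal"]) == (m, p)

    def test_escapees_excluded_from_x(self, germ_annotation):
        rows = [("c", "x0", 0, 40), ("c", "esc0", 50, 50)]
        m = g.AllelicCountMatrix(pd.DataFrame(
            rows, columns=["cell_id", "gene", "maternal_reads", "paternal_reads"]
        ))
        part = g.partition_x_genes(germ_annotation)
        out = g.chromosome_allelic_sums(m, germ_annotation, part)
        x = out[out["chromosome"] == "X"].iloc[0]
        assert x["total"] == 40 and x["bias"] == 1.0


class TestXCellFilter:
    @pytest.mark.parametrize(
        "genes, reads, kept",
        [(3, 33, True), (2, 100, False), (3, 32, False), (4, 50, True)],
    )
    def test_boundaries(self, genes, reads, kept):
        s = summaries_frame([("c", "X", reads, 0, genes)])
        assert (("c" in g.filter_x_cells(s)) is kept)

    def test_idempotent(self):
        s = summaries_frame(
            [(f"c{i}", "X", 30 + i, 10, 3 + i % 3) for i in range(10)]
        )
        kept = g.filter_x_cells(s)
        again = g.filter_x_cells(s[s["cell_id"].isin(kept)])
        assert again == kept


class TestActiveX:
    @pytest.mark.parametrize(
        "m, p, expected",
        [(40, 2, "maternal"), (2, 40, "paternal"), (7, 7, "tied")],
    )
    def test_rule(self, m, p, expected):
        assert g.assign_active_x(m, p) == expected

    def test_simulated_xixa_direction_recovered(self, germ_annotation):
        profiles = make_profiles(0, 50, depth=4000.0, dropout=0.0, seed=21)
        matrix, truth = g.simulate_allelic_counts(
            profiles, germ_annotation, seed=22
        )
        part = g.partition_x_genes(germ_annotation)
        sums = g.chromosome_allelic_sums(matrix, germ_annotation, part)
        x = sums[sums["chromosome"] == "X"].set_index("cell_id")
        truth_map = truth.cells.set_index("cell_id")["active_x_parent"]
        correct = [
            g.assign_active_x(int(r["maternal"]), int(r["paternal"]))
            == truth_map[c]
            for c, r in x.iterrows()
        ]
        assert np.mean(correct) >= 0.99


class TestBinning:
    def test_single_bin_holds_all(self):
        edges = g.bin_by_total([5, 10, 20], 1)
        assert [locate_bin(t, edges) for t in (5, 10, 20)] == [0, 0, 0]

    def test_identical_totals_fewer_distinct_than_bins(self):
        with pytest.raises(ValueError, match="distinct totals"):
            g.bin_by_total([10, 10, 10, 10], 2)

    def test_equal_read_shares_cumulative_check(self):
        rng = np.random.default_rng(8)
        totals = rng.negative_binomial(1, 1 / 201, size=100) + 1
        totals = np.unique(totals)  # distinct to keep shares tight
        edges = g.bin_by_total(totals, 4)
        bins = np.array([locate_bin(t, edges) for t in totals])
        grand = totals.sum()
        # brute-force cumulative-sum check: per-bin share within one point
        for b in range(4):
            share = totals[bins == b].sum() / grand
            assert abs(share - 0.25) <= totals.max() / grand

    def test_every_point_in_exactly_one_bin(self):
        totals = np.arange(1, 51)
        edges = g.bin_by_total(totals, 4)
        bins = [locate_bin(t, edges) for t in totals]
        assert set(bins) == {0, 1, 2, 3}
        assert sorted(bins) == bins  # monotone in total


class TestAutosomalInterval:
    def test_linear_interpolation_quantiles(self):
        biases = np.linspace(0.5, 1.0, 101)
        lo, hi = g.autosomal_interval(biases, level=0.95)
        assert lo == pytest.approx(0.5125)
        assert hi == pytest.approx(0.9875)

    def test_degenerate_identical_points(self):
        lo, hi = g.autosomal_interval([0.6] * 30)
        assert lo == hi == 0.6

    def test_level_one_spans_range(self):
        lo, hi = g.autosomal_interval([0.5, 0.62, 0.9], level=1.0)
        assert (lo, hi) == (0.5, 0.9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            g.autosomal_interval([])


class TestClassifyXState:
    def null_with(self, lower=0.50, upper=0.70):
        from germase.xreactivation import BinnedNull
        return BinnedNull(
            edges=np.array([1000]), intervals=[(lower, upper)],
            n_autosome_points=[100], level=0.95,
        )

    def call(self, bias, null):
        s = summaries_frame(
            [("c", "X", int(100 * bias), 100 - int(100 * bias), 5)]
        )
        return g.classify_x_state(s, null).iloc[0]

    def test_above_upper_is_biased(self):
        assert self.call(0.99, self.null_with())["state"] == "XiXa_biased"

    def test_exactly_at_upper_in_range(self):
        assert self.call(0.70, self.null_with())["state"] == "XaXa_range"

    def test_inside_interval_in_range(self):
        assert self.call(0.55, self.null_with())["state"] == "XaXa_range"

    def test_unassessable_cells_flagged(self):
        s = summaries_frame([("c", "X", 60, 40, 5)])
        out = g.classify_x_state(s, self.null_with(), assessable_cells=set())
        assert out.iloc[0]["state"] == "unassessable"

    def test_monotone_in_bias(self):
        """Raising X bias never flips a biased call back into range."""
        null = self.null_with()
        states = [self.call(b, null)["state"] for b in np.linspace(0.5, 1, 26)]
        first = states.index("XiXa_biased")
        assert all(s == "XiXa_biased" for s in states[first:])


class TestGeometricMean:
    def test_degenerate_monoallelic(self):
        assert gene_bias([10], [0], pseudocount=0.0)[0] == 1.0

    def test_balanced_half(self):
        assert gene_bias([5], [5])[0] == 0.5

    def test_outlier_moves_gm_less_than_mean(self):
        biases = np.array([0.5] * 9 + [1.0])
        gm = np.exp(np.mean(np.log(biases)))
        arith = np.mean(biases)
        assert gm - 0.5 < arith - 0.5

    def test_agrees_with_bias_classifier_on_degenerate_cases(
        self, germ_annotation
    ):
        # fully biallelic population: both classifiers call every X in range;
        # fully monoallelic X: both call it biased
        for x_bias, expected in [(0.5, "XaXa_range"), (1.0, "XiXa_biased")]:
            profiles = make_profiles(
                0, 40, depth=6000.0, dropout=0.0, seed=31, x_bias=x_bias
            )
            matrix, _ = g.simulate_allelic_counts(
                profiles, germ_annotation, seed=32
            )
            model = g.XReactivationModel(matrix, germ_annotation)
            res = model.fit()
            assessed = res.calls[res.calls["state"] != "unassessable"]
            gm_assessed = res.gm_calls[res.gm_calls["state"] != "unassessable"]
            assert (assessed["state"] == expected).mean() > 0.9
            merged = assessed.merge(
                gm_assessed, on="cell_id", suffixes=("_bias", "_gm")
            )
            agree = (merged["state_bias"] == merged["state_gm"]).mean()
            assert agree > 0.9


class TestSummariesAndRanking:
    def test_single_cell_fraction_is_its_own(self):
        s = summaries_frame([("c", "X", 30, 10, 5)])
        per_cell, quart = g.paternal_fraction_summary(s)
        assert per_cell.iloc[0]["paternal_fraction"] == 0.25
        assert quart.iloc[0]["q50"] == 0.25

    def test_quartiles_match_brute_force_sorting(self):
        rng = np.random.default_rng(12)
        rows = [
            (f"c{i}", "X", int(m), int(p), 4)
            for i, (m, p) in enumerate(
                zip(rng.integers(1, 100, 30), rng.integers(1, 100, 30))
            )
        ]
        s = summaries_frame(rows)
        per_cell, quart = g.paternal_fraction_summary(s)
        fr = np.sort(per_cell["paternal_fraction"].to_numpy())
        for q, col in [(0.25, "q25"), (0.5, "q50"), (0.75, "q75")]:
            assert quart.iloc[0][col] == pytest.approx(np.quantile(fr, q))

    def test_symmetric_population_median_near_half(self, germ_sim,
                                                   germ_annotation):
        matrix, *_ = germ_sim
        part = g.partition_x_genes(germ_annotation)
        sums = g.chromosome_allelic_sums(matrix, germ_annotation, part)
        _, quart = g.paternal_fraction_summary(sums)
        assert 0.3 < quart.iloc[0]["q50"] < 0.7

    def test_ranking_order_and_determinism(self):
        s = summaries_frame(
            [("hi", "X", 90, 10, 3), ("lo", "X", 60, 40, 3),
             ("tie_big", "X", 180, 20, 3), ("tie_small", "X", 9, 1, 3)]
        )
        ranked = g.rank_cells_by_x_bias(s)
        # hi, tie_big and tie_small all have bias 0.9: totals break the tie
        assert ranked["cell_id"].tolist() == [
            "tie_big", "hi", "tie_small", "lo"
        ]
        shuffled = g.rank_cells_by_x_bias(s.iloc[::-1])
        assert shuffled["cell_id"].tolist() == ranked["cell_id"].tolist()


class TestMedianBiasClassifier:
    @pytest.mark.parametrize(
        "biases, expected",
        [
            ([1.0, 0.96, 0.95], "XCI"),
            ([0.5, 0.5, 0.5], "not_XCI"),
            ([0.95], "XCI"),  # inclusive boundary
            ([], "unassessable"),
        ],
    )
    def test_rule(self, biases, expected):
        assert g.median_bias_classifier(biases) == expected


class TestDifferentialExpression:
    @staticmethod
    def simulate_counts(n_per_group=20, n_genes=40, shift_gene=None,
                        fold=8.0, seed=0):
        rng = np.random.default_rng(seed)
        cells = [f"a{i}" for i in range(n_per_group)] + [
            f"b{i}" for i in range(n_per_group)
        ]
        mu = 20.0
        data = {}
        for j in range(n_genes):
            gene = f"g{j}"
            m_a = mu
            m_b = mu * fold if gene == shift_gene else mu
            r = 5.0  # moderate overdispersion
            counts_a = rng.negative_binomial(r, r / (r + m_a), n_per_group)
            counts_b = rng.negative_binomial(r, r / (r + m_b), n_per_group)
            data[gene] = np.concatenate([counts_a, counts_b])
        return pd.DataFrame(data, index=cells), cells[:n_per_group], cells[n_per_group:]

    def test_null_pvalues_roughly_uniform(self):
        from scipy import stats

        counts, a, b = self.simulate_counts(seed=1)
        out = g.differential_expression_nb(counts, a, b)
        ks = stats.kstest(out["p_value"], "uniform")
        assert ks.pvalue > 0.01
        assert not out["significant"].any()

    def test_power_on_eightfold_shift(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            counts, a, b = self.simulate_counts(shift_gene="g0", seed=seed)
            out = g.differential_expression_nb(counts, a, b)
            q = out.set_index("gene").loc["g0", "q_value"]
            hits += q < 0.05
        assert hits / n_seeds >= 0.95

    def test_bh_step_up_by_hand(self):
        q = g.benjamini_hochberg([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_all_zero_gene_skipped(self):
        counts, a, b = self.simulate_counts(n_genes=3, seed=2)
        counts["dead"] = 0
        out = g.differential_expression_nb(counts, a, b)
        assert "dead" not in set(out["gene"])

    def test_small_group_rejected(self):
        counts, a, b = self.simulate_counts(seed=3)
        with pytest.raises(ValueError):
            g.differential_expression_nb(counts, a[:1], b)


class TestModelResults:
    def test_fit_produces_calls_and_summary(self, germ_sim, germ_annotation):
        matrix, truth, _ = germ_sim
        res = g.XReactivationModel(matrix, germ_annotation).fit()
        assert set(res.calls["state"]) <= {
            "XaXa_range", "XiXa_biased", "unassessable"
        }
        text = res.summary()
        assert "X-reactivation classification" in text
        assert "95%" in text

    def test_plot_returns_axis(self, germ_sim, germ_annotation):
        import matplotlib
        matplotlib.use("Agg")
        matrix, *_ = germ_sim
        res = g.XReactivationModel(matrix, germ_annotation).fit(with_gm=False)
        ax = res.plot_bias()
        assert ax is not None
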