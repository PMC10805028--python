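import numpy as np
import pandas as pd
import pytest

from methyloscan.assign import GeneAssignment
from methyloscan.catalog import SubstrateCategory, SystemRole
from methyloscan.quant import (
    NormalizationParams,
    QuantError,
    abundance_normalized_expression,
    classify_active_methylotroph,
    filter_counts,
    getmm,
    order_activity_fractions,
    pearson_r2,
    relative_abundance,
    tmm_factors,
    trimmed_mean_coverage,
)

# fixture matrix whose TMM factors and geTMM values were cross-computed
# with an independent reference implementation of the same recipe
FIXTURE_COUNTS = pd.DataFrame(
    [
        [100, 200, 50],
        [500, 900, 480],
        [30, 10, 25],
        [8, 40, 12],
        [1200, 700, 1500],
        [60, 120, 65],
        [300, 310, 290],
        [9, 5, 20],
    ],
    index=[f"g{i}" for i in range(1, 9)],
    columns=["s1", "s2", "s3"],
)
FIXTURE_LENGTHS = pd.Series(
    [1000, 2000, 500, 1500, 3000, 800, 1200, 600], index=FIXTURE_COUNTS.index
)
ORACLE_TMM_COUNTS = [1.0221220014, 0.9019048996, 1.0847671303]
ORACLE_TMM_RPK = [0.9901940630, 0.9611955368, 1.0506738816]
ORACLE_GETMM = pd.DataFrame(
    [
        [87412.26592135, 154510.55045161, 39517.13157427],
        [218530.66480338, 347648.73851612, 189682.23155651],
        [52447.35955281, 15451.05504516, 39517.13157427],
        [4661.98751581, 20601.40672688, 6322.74105188],
        [349649.06368541, 180262.30886021, 395171.31574273],
        [65559.19944102, 115882.91283871, 64215.33880819],
        [218530.66480338, 199576.12766666, 190999.46927565],
        [13111.83988820, 6437.93960215, 26344.75438285],
    ],
    index=FIXTURE_COUNTS.index,
    columns=FIXTURE_COUNTS.columns,
)


class TestFilterCounts:
    def test_floor_is_strict(self):
        m = pd.DataFrame({"s": [4, 5]})
        out = filter_counts(m, 5)
        assert out["s"].tolist() == [0, 5]

    def test_all_zero_unchanged(self):
        m = pd.DataFrame(np.zeros((3, 2)))
        assert filter_counts(m, 5).equals(m)

    def test_hand_filtered_fixture(self):
        m = pd.DataFrame([[4, 7], [5, 0], [12, 3]], columns=["a", "b"])
        expected = pd.DataFrame([[0, 7], [5, 0], [12, 0]], columns=["a", "b"])
        assert filter_counts(m, 5).equals(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(QuantError):
            filter_counts(pd.DataFrame({"s": [-1, 3]}), 5)


class TestTmmFactors:
    def test_identical_samples_give_unit_factors(self):
        m = pd.DataFrame({"a": [10, 20, 30, 40], "b": [10, 20, 30, 40]})
        assert np.allclose(tmm_factors(m).to_numpy(), 1.0)

    def test_pure_depth_difference_absorbed(self):
        a = pd.Series([11, 25, 37, 48, 90])
        m = pd.DataFrame({"a": a, "b": 2 * a})
        assert np.allclose(tmm_factors(m).to_numpy(), 1.0)

    def test_hand_computed_four_gene_fixture(self):
        # samples: a=(100,200,300,1000), b=(100,200,300,100): with 30% M-trim
        # (keep ranks 2-3) the outlier g4 and the extreme opposite are cut
        m = pd.DataFrame({"a": [100, 200, 300, 1000], "b": [100, 200, 300, 100]})
        lib_a, lib_b = 1600.0, 700.0
        M = np.log2((m["b"] / lib_b) / (m["a"] / lib_a))
        w = 1.0 / (
            (lib_b - m["b"]) / (lib_b * m["b"]) + (lib_a - m["a"]) / (lib_a * m["a"])
        )
        # n=4: keep M-ranks 2..3 (genes g1..g3 tie on M; g4 is the low
        # outlier) and A-ranks 1..4
        ranks = M.rank()
        keep = (ranks >= 2) & (ranks <= 3)
        f_b = 2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
        expected = pd.Series([1 / np.sqrt(f_b), f_b / np.sqrt(f_b)])
        got = tmm_factors(m, ref_column="a")
        assert np.allclose(got.to_numpy(), expected.to_numpy(), rtol=1e-9)

    def test_matches_reference_implementation(self):
        got = tmm_factors(FIXTURE_COUNTS)
        assert np.allclose(got.to_numpy(), ORACLE_TMM_COUNTS, rtol=1e-8)
        rpk = FIXTURE_COUNTS.div(FIXTURE_LENGTHS / 1000, axis=0)
        assert np.allclose(tmm_factors(rpk).to_numpy(), ORACLE_TMM_RPK, rtol=1e-8)

    def test_geometric_mean_is_one_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            m = pd.DataFrame(
                rng.negative_binomial(5, 0.01, size=(40, 4)) + 1,
                columns=list("abcd"),
            )
            f = tmm_factors(m)
            assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_zero_library_names_sample(self):
        m = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]})
        with pytest.raises(QuantError, match="empty"):
            tmm_factors(m)


class TestGetmm:
    def test_single_sample_length_correction(self):
        m = pd.DataFrame({"s": [10, 10]}, index=["g1", "g2"])
        lengths = pd.Series([1000, 2000], index=m.index)
        out = getmm(m, lengths)
        assert out["s"].tolist() == pytest.approx([2 / 3 * 1e6, 1 / 3 * 1e6])

    def test_uniform_matrix_is_flat(self):
        m = pd.DataFrame(100, index=[f"g{i}" for i in range(5)], columns=list("abc"))
        lengths = pd.Series(1000, index=m.index)
        out = getmm(m, lengths)
        assert np.allclose(out.to_numpy(), 1e6 / 5)

    def test_matches_reference_implementation(self):
        out = getmm(FIXTURE_COUNTS, FIXTURE_LENGTHS, apply_count_floor=False)
        assert np.allclose(out.to_numpy(), ORACLE_GETMM.to_numpy(), rtol=1e-6)

    def test_depth_change_invariance(self):
        # a pure sequencing-depth change is absorbed by the library size:
        # exactly for unweighted TMM (precision weights depend on absolute
        # counts, so the canonical weighted factors shift slightly)
        rng = np.random.default_rng(3)
        m = pd.DataFrame(
            rng.negative_binomial(5, 0.02, size=(30, 3)) + 5, columns=list("abc")
        )
        lengths = pd.Series(rng.integers(500, 3000, size=30), index=m.index)
        scaled = m.copy()
        scaled["b"] = scaled["b"] * 7
        params = NormalizationParams(tmm_weighted=False)
        base = getmm(m, lengths, params, apply_count_floor=False)
        got = getmm(scaled, lengths, params, apply_count_floor=False)
        assert np.allclose(base.to_numpy(), got.to_numpy(), rtol=1e-6)
        # weighted mode still agrees to well under a percent
        base_w = getmm(m, lengths, apply_count_floor=False)
        got_w = getmm(scaled, lengths, apply_count_floor=False)
        assert np.allclose(base_w.to_numpy(), got_w.to_numpy(), rtol=1e-2)

    def test_zero_length_gene_rejected(self):
        m = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
        with pytest.raises(QuantError):
            getmm(m, pd.Series([1000, 0], index=m.index))


class TestTrimmedMeanCoverage:
    def test_uniform_depth(self):
        assert trimmed_mean_coverage([7.0] * 100) == 7.0

    def test_linear_depths_trim_tails(self):
        assert trimmed_mean_coverage(list(range(100))) == 49.5  # mean of 10..89

    def test_length_one_degenerates_to_value(self):
        assert trimmed_mean_coverage([3.5]) == 3.5

    def test_empty_vector_rejected(self):
        with pytest.raises(QuantError):
            trimmed_mean_coverage([])


class TestRelativeAbundance:
    def test_simple_fractions(self):
        cov = pd.DataFrame({"s1": [2.0, 2.0, 4.0]}, index=["a", "b", "c"])
        out = relative_abundance(cov)
        assert out["s1"].tolist() == [0.25, 0.25, 0.5]

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        cov = pd.DataFrame(rng.uniform(0, 10, size=(6, 3)), columns=list("xyz"))
        assert np.allclose(
            relative_abundance(cov).to_numpy(),
            relative_abundance(cov * 13.7).to_numpy(),
        )

    def test_nested_denominator(self):
        # methanogens within archaea: fractions over the subset only
        cov = pd.DataFrame(
            {"s1": [6.0, 2.0, 2.0]}, index=["methanogen1", "methanogen2", "other"]
        )
        out = relative_abundance(cov, ["methanogen1", "methanogen2"])
        assert out["s1"].tolist() == [0.75, 0.25]
        assert "other" not in out.index

    def test_below_detection_group_is_missing(self):
        cov = pd.DataFrame({"palsa": [0.0, 0.0], "fen": [1.0, 3.0]}, index=["a", "b"])
        out = relative_abundance(cov)
        assert out["palsa"].isna().all()
        assert out["fen"].tolist() == [0.25, 0.75]

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(2)
        cov = pd.DataFrame(rng.uniform(0.1, 5, size=(8, 4)))
        assert np.allclose(relative_abundance(cov).sum(axis=0), 1.0, atol=1e-9)


DESIGN = pd.DataFrame(
    {
        "sample": ["b1", "b2", "b3", "f1", "f2", "f3"],
        "group": ["bog", "bog", "bog", "fen", "fen", "fen"],
    }
)


class TestOrderActivityFractions:
    def test_single_order_is_one(self):
        m = pd.DataFrame(
            np.full((2, 6), 10.0), index=["g1", "g2"], columns=DESIGN["sample"]
        )
        out = order_activity_fractions(
            m, {"g1": "M1", "g2": "M1"}, {"M1": "Methanobacteriales"}, DESIGN
        )
        assert np.allclose(out.to_numpy(), 1.0)

    def test_three_to_one_split(self):
        m = pd.DataFrame(
            [[300.0] * 6, [100.0] * 6], index=["g1", "g2"], columns=DESIGN["sample"]
        )
        out = order_activity_fractions(
            m, {"g1": "M1", "g2": "M2"},
            {"M1": "orderA", "M2": "orderB"}, DESIGN,
        )
        assert out.loc["orderA"].tolist() == pytest.approx([0.75, 0.75])
        assert out.loc["orderB"].tolist() == pytest.approx([0.25, 0.25])

    def test_columns_sum_to_one_where_defined(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(10)]
        m = pd.DataFrame(
            rng.uniform(0, 50, size=(10, 6)), index=genes, columns=DESIGN["sample"]
        )
        gene_to_mag = {g: f"M{i % 3}" for i, g in enumerate(genes)}
        orders = {f"M{i}": f"order{i}" for i in range(3)}
        out = order_activity_fractions(m, gene_to_mag, orders, DESIGN)
        assert np.allclose(out.sum(axis=0), 1.0)


class TestAbundanceNormalizedExpression:
    def _means(self, value):
        return pd.DataFrame({"bog": [value]}, index=["g1"])

    def test_simple_division(self):
        ab = pd.DataFrame({"bog": [0.25]}, index=["M1"])
        out = abundance_normalized_expression(self._means(50.0), {"g1": "M1"}, ab)
        assert out.loc["g1", "bog"] == 200.0

    def test_zero_expression_stays_zero(self):
        ab = pd.DataFrame({"bog": [0.0]}, index=["M1"])
        out = abundance_normalized_expression(self._means(0.0), {"g1": "M1"}, ab)
        assert out.loc["g1", "bog"] == 0.0

    def test_zero_abundance_is_missing_not_infinite(self):
        ab = pd.DataFrame({"bog": [0.0]}, index=["M1"])
        out = abundance_normalized_expression(self._means(50.0), {"g1": "M1"}, ab)
        assert np.isnan(out.loc["g1", "bog"])


class TestPearsonR2:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        assert pearson_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert pearson_r2(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_known_fixture(self):
        x = [1.0, 2.0, 4.0, 5.0]
        y = [1.0, 3.0, 3.0, 6.0]
        r = np.corrcoef(x, y)[0, 1]
        assert pearson_r2(x, y) == pytest.approx(r * r)

    def test_zero_variance_rejected(self):
        with pytest.raises(QuantError):
            pearson_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _system_assignments():
    mk = lambda g, role: GeneAssignment(
        gene_id=g, mag_id="M1", role=role, substrate=SubstrateCategory.METHYL_O,
        subtype="mtaB methanol" if role is SystemRole.MTXB else "mtaX",
        best_reference_id="r", best_bitscore=100.0, margin_bits=50.0,
    )
    return [mk("b", SystemRole.MTXB), mk("c", SystemRole.MTXC), mk("a", SystemRole.MTXA)]


class TestActiveMethylotroph:
    def _matrix(self, expressed):
        data = {s: [0.0, 0.0, 0.0] for s in DESIGN["sample"]}
        m = pd.DataFrame(data, index=["b", "c", "a"])
        for g in expressed:
            m.loc[g, :] = 10.0
        return m

    def test_majority_including_b_is_active(self):
        out = classify_active_methylotroph(
            self._matrix({"b", "c"}), _system_assignments(), DESIGN
        )
        assert out.loc["M1", "active_any"]

    def test_majority_without_b_is_inactive(self):
        out = classify_active_methylotroph(
            self._matrix({"c", "a"}), _system_assignments(), DESIGN
        )
        assert not out.loc["M1", "active_any"]

    def test_no_expression_is_inactive(self):
        out = classify_active_methylotroph(
            self._matrix(set()), _system_assignments(), DESIGN
        )
        assert not out.loc["M1", "active_any"]
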