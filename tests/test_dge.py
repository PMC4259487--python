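"""FPKM, upper-quartile normalization, the Fisher exact test against an
exact-arithmetic enumeration oracle and scipy, q-value estimation, and
direction grouping."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from tolmap.dge import (
    CountMatrix,
    DGEResult,
    NormalizationFactors,
    attach_qvalues,
    compute_fpkm,
    dge_contrast,
    estimate_qvalues,
    fisher_exact_two_sided,
    fpkm_filter,
    group_by_direction,
    read_count_matrix,
    upper_quartile_factors,
    write_count_matrix,
)


def fisher_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p by full enumeration of tables
    with the observed margins (point-probability rule)."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, col1 - (c + d) - b + b)  # max(0, col1 - row2)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    denom = comb(n, col1)
    pmf = {
        x: Fraction(comb(row1, x) * comb(n - row1, col1 - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


def _matrix(counts, lengths=None, samples=None):
    counts = np.asarray(counts)
    n, s = counts.shape
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(n)],
        gene_lengths_bp=lengths or [1000] * n,
        sample_ids=samples or [f"s{j}" for j in range(s)],
        counts=counts,
    )


class TestFPKM:
    def test_unit_case(self):
        m = _matrix([[10], [999_990]], lengths=[1000, 10_000_000])
        fpkm = compute_fpkm(m)
        assert fpkm.iloc[0, 0] == pytest.approx(10.0)

    def test_zero_count_zero_fpkm(self):
        m = _matrix([[0], [1_000_000]], lengths=[1000, 1000])
        assert compute_fpkm(m).iloc[0, 0] == 0.0

    def test_arithmetic(self):
        m = _matrix([[25], [4_999_975]], lengths=[2500, 100_000_000])
        assert compute_fpkm(m).iloc[0, 0] == pytest.approx(2.0)

    def test_filter_threshold(self):
        m = _matrix(
            [[10, 0], [1, 10], [999_989, 999_990]],
            lengths=[1000, 1_000_000, 1_000_000],
        )
        assert fpkm_filter(m, "s0", 1.0) == ["g0", "g2"]
        with pytest.raises(KeyError):
            fpkm_filter(m, "nope")


class TestUpperQuartile:
    def test_identical_columns_unit_factors(self):
        m = _matrix([[3, 3], [10, 10], [50, 50], [7, 7]])
        f = upper_quartile_factors(m)
        assert f.scale_factor == pytest.approx([1.0, 1.0])

    def test_doubled_column_geometric_centering(self):
        a = np.array([[3], [10], [50], [7]])
        m = _matrix(np.hstack([a, 2 * a]))
        f = upper_quartile_factors(m)
        assert f.scale_factor == pytest.approx([np.sqrt(2), np.sqrt(2) / 2])
        normalized = m.counts * f.scale_factor
        assert normalized[:, 0] == pytest.approx(normalized[:, 1])

    def test_all_zero_rows_excluded(self):
        m1 = _matrix([[3, 6], [10, 20], [50, 100]])
        m2 = _matrix([[3, 6], [0, 0], [10, 20], [0, 0], [50, 100]])
        assert upper_quartile_factors(m1).scale_factor == pytest.approx(
            upper_quartile_factors(m2).scale_factor
        )

    def test_normalization_idempotence(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson([500, 900, 1400], size=(300, 3))
        m = _matrix(counts)
        f = upper_quartile_factors(m)
        normalized = counts * f.scale_factor
        f2 = upper_quartile_factors(normalized)
        assert np.allclose(f2.scale_factor, 1.0, atol=1e-9)

    def test_zero_upper_quartile_named(self):
        m = _matrix([[1, 0], [1, 0], [1, 0], [1, 0], [1, 1]])
        with pytest.raises(ValueError, match="s1"):
            upper_quartile_factors(m)


class TestFisherExact:
    def test_identical_proportions(self):
        assert fisher_exact_two_sided(5, 95, 5, 95) == pytest.approx(1.0)

    def test_perfect_separation_closed_form(self):
        p = fisher_exact_two_sided(0, 10, 10, 0)
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    def test_row_swap_symmetry(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, 4))
            assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                fisher_exact_two_sided(c, d, a, b), rel=1e-12
            )

    def test_degenerate_margins(self):
        assert fisher_exact_two_sided(0, 0, 0, 0) == 1.0
        assert fisher_exact_two_sided(0, 5, 0, 7) == 1.0

    def test_matches_scipy_point_probability(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 80, 4))
            mine = fisher_exact_two_sided(a, b, c, d)
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_matches_exact_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
            assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12
            )

    def test_doubling_rule_bounds_point_probability(self):
        p_point = fisher_exact_two_sided(2, 8, 8, 2)
        p_double = fisher_exact_two_sided(2, 8, 8, 2, rule="doubling")
        assert p_point <= p_double <= 1.0


class TestDGEContrast:
    def _unit_factors(self, samples):
        k = len(samples)
        return NormalizationFactors(samples, np.ones(k), np.ones(k))

    def test_null_gene(self):
        m = _matrix([[20, 20], [980, 980]])
        res = dge_contrast(m, self._unit_factors(["s0", "s1"]), "s0", "s1")
        assert res[0].fold_change == pytest.approx(1.0)
        assert res[0].p == pytest.approx(1.0)

    def test_fold_change_and_oracle_p(self):
        m = _matrix([[5, 50], [99_995, 99_950]])
        res = dge_contrast(m, self._unit_factors(["s0", "s1"]), "s0", "s1")
        assert res[0].fold_change == pytest.approx(8.5)
        assert res[0].log2fc == pytest.approx(np.log2(8.5))
        assert res[0].p == pytest.approx(fisher_oracle(5, 99_995, 50, 99_950), rel=1e-6)

    def test_zero_zero_gene(self):
        m = _matrix([[0, 0], [500, 500]])
        res = dge_contrast(m, self._unit_factors(["s0", "s1"]), "s0", "s1")
        assert res[0].fold_change == pytest.approx(1.0)
        assert res[0].p == pytest.approx(1.0)

    def test_unknown_sample_rejected(self):
        m = _matrix([[1, 1]])
        with pytest.raises(KeyError):
            dge_contrast(m, self._unit_factors(["s0", "s1"]), "s0", "absent")

    def test_gene_set_restricts_output(self):
        m = _matrix([[5, 5], [7, 7], [9, 9]])
        res = dge_contrast(
            m, self._unit_factors(["s0", "s1"]), "s0", "s1", gene_set=["g1"]
        )
        assert [r.gene_id for r in res] == ["g1"]


class TestQvalues:
    def test_bh_step_up_closed_form(self):
        q = estimate_qvalues([0.01, 0.02, 0.03, 0.04], method="bh")
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert estimate_qvalues([1.0] * 10, method="bh") == pytest.approx([1.0] * 10)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(7)
        for method in ("bh", "storey"):
            for _ in range(25):
                p = rng.random(200)
                q = estimate_qvalues(p, method=method)
                order = np.argsort(p)
                assert (np.diff(q[order]) >= -1e-12).all()

    def test_storey_pi0_null_calibration(self):
        """Uniform p-values: the Storey pi0 estimate stays near 1."""
        rng = np.random.default_rng(8)
        pi0s = []
        for _ in range(20):
            p = rng.random(10_000)
            q = estimate_qvalues(p, method="storey")
            qbh = estimate_qvalues(p, method="bh")
            # pi0 is the ratio of storey to BH q-values
            pi0s.append(np.median(q / np.maximum(qbh, 1e-300)))
        assert 0.9 <= np.mean(pi0s) <= 1.0

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = rng.random(500)
        q = estimate_qvalues(p, method="bh")
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            estimate_qvalues([0.5, 1.5])


class TestGrouping:
    def _res(self, gene, contrast, fc, q):
        return DGEResult(gene, contrast, fc, float(np.log2(fc)), p=q, q=q)

    def test_direction_groups(self):
        pre = [
            self._res("atf3", "wt->pre", 7.7, 0.001),
            self._res("flat", "wt->pre", 1.0, 0.9),
            self._res("ajap1", "wt->pre", 1.0, 0.9),
        ]
        tum = [
            self._res("atf3", "wt->tum", 63.1, 0.001),
            self._res("flat", "wt->tum", 1.0, 0.9),
            self._res("ajap1", "wt->tum", 0.2, 0.001),
        ]
        groups, heat = group_by_direction(pre, tum)
        assert "atf3" in groups["Increased in Tumor"]
        assert "atf3" in groups["Increased in Pretumor"]
        assert "ajap1" in groups["Decreased in Tumor"]
        assert all("flat" not in g for g in groups.values())
        assert heat.loc["atf3", "log2fc_tumor"] == pytest.approx(np.log2(63.1))

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            group_by_direction(
                [self._res("a", "x", 1, 1)], [self._res("b", "y", 1, 1)]
            )


class TestCountMatrixIO:
    def test_round_trip(self, tmp_path):
        m = _matrix([[5, 8, 2], [100, 90, 80]], lengths=[500, 2000],
                    samples=["WildType", "Pretumor", "Tumor"])
        path = tmp_path / "counts.tsv"
        write_count_matrix(m, path)
        back = read_count_matrix(path)
        assert back.gene_ids == m.gene_ids
        assert back.sample_ids == m.sample_ids
        assert (back.counts == m.counts).all()
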