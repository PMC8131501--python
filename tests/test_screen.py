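import warnings

import numpy as np
import pandas as pd
import pytest

from hrdscar.screen import (
    ExpressionMatrix,
    ScreenThresholds,
    bh_adjust,
    differential_expression,
    feature_correlation,
    mad_filter,
    penalized_signature_selection,
    read_counts,
    risk_stratify,
    select_extreme_cohorts,
    tpm_normalize,
    univariate_prognostic_screen,
)
from hrdscar.simulate import simulate_expression, simulate_survival


def _em(counts: dict, lengths: dict, samples) -> ExpressionMatrix:
    data = pd.DataFrame(counts, index=samples).T
    return ExpressionMatrix(data, pd.Series(lengths, dtype=float).loc[data.index])


class TestTpmNormalize:
    def test_single_gene_gets_all_million(self):
        em = _em({"g": [7, 500]}, {"g": 1000.0}, ["a", "b"])
        tpm = tpm_normalize(em)
        assert np.allclose(tpm.data.to_numpy(), 1e6)

    def test_length_normalization_formula(self):
        em = _em({"g1": [10], "g2": [10]}, {"g1": 1000.0, "g2": 2000.0}, ["a"])
        tpm = tpm_normalize(em)
        assert tpm.data.loc["g1", "a"] == pytest.approx(666_666.6667, rel=1e-6)
        assert tpm.data.loc["g2", "a"] == pytest.approx(333_333.3333, rel=1e-6)

    def test_columns_sum_to_million_and_scaling_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 500, (30, 4)), index=[f"g{i}" for i in range(30)]
        )
        lengths = pd.Series(rng.integers(200, 5000, 30).astype(float), index=counts.index)
        em = ExpressionMatrix(counts, lengths)
        tpm = tpm_normalize(em)
        assert np.allclose(tpm.data.sum(axis=0), 1e6, rtol=1e-9)
        scaled = ExpressionMatrix(counts * 3, lengths)
        assert np.allclose(tpm_normalize(scaled).data, tpm.data)

    def test_zero_column_rejected_naming_sample(self):
        em = _em({"g1": [1, 0], "g2": [1, 0]}, {"g1": 1e3, "g2": 1e3}, ["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            tpm_normalize(em)


class TestExtremeCohorts:
    def test_cohort_of_348_gives_seventy_per_group(self):
        scores = pd.Series(np.arange(348), index=[f"s{i:03d}" for i in range(348)])
        high, low = select_extreme_cohorts(scores, 0.2)
        assert len(high) == len(low) == 70
        assert set(low) == {f"s{i:03d}" for i in range(70)}

    def test_small_cohort(self):
        scores = pd.Series(range(10), index=list("abcdefghij"))
        high, low = select_extreme_cohorts(scores, 0.2)
        assert len(high) == len(low) == 2

    def test_boundary_ties_broken_by_sample_id(self):
        scores = pd.Series([0, 1, 5, 5, 5, 9], index=["a", "b", "c", "d", "e", "f"])
        high, low = select_extreme_cohorts(scores, 1 / 3)
        # sorted by (score, id): a b c d e f -> low {a,b}, high {e,f}
        assert low == ["a", "b"] and high == ["e", "f"]

    def test_invalid_fraction(self):
        scores = pd.Series(range(10))
        with pytest.raises(ValueError):
            select_extreme_cohorts(scores, 0.6)


class TestMadFilter:
    def _matrix(self):
        # hand-computable: MADs of log2(TPM+1) rank g_var > g_mid > g_small > g_const
        data = pd.DataFrame(
            {
                "s1": [100, 100, 100, 100],
                "s2": [800, 200, 120, 100],
                "s3": [100, 100, 100, 100],
                "s4": [800, 200, 120, 100],
            },
            index=["g_var", "g_mid", "g_small", "g_const"],
        )
        return ExpressionMatrix(data, pd.Series(1000.0, index=data.index), "TPM")

    def test_hand_ranking_and_constant_last(self):
        em = self._matrix()
        kept = mad_filter(em, 0.75)
        assert set(kept) == {"g_var", "g_mid", "g_small"}
        assert "g_const" not in kept

    def test_keep_all(self):
        em = self._matrix()
        assert len(mad_filter(em, 1.0)) == 4

    def test_empty_matrix_rejected(self):
        em = ExpressionMatrix(
            pd.DataFrame(index=pd.Index([], name="gene")), pd.Series(dtype=float)
        )
        with pytest.raises(ValueError):
            mad_filter(em)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.031])[0] == pytest.approx(0.031)

    def test_step_up_formula_by_hand(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.05]), [0.03, 0.03, 0.05])

    def test_all_ones(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_adjusted_at_least_raw_and_order_preserving(self):
        rng = np.random.default_rng(5)
        p = rng.random(50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDifferentialExpression:
    HIGH = [f"H{i}" for i in range(1, 7)]
    LOW = [f"L{i}" for i in range(1, 7)]

    @pytest.fixture(scope="class")
    def fixture_em(self, data_dir):
        return read_counts(data_dir / "cascade_counts.tsv", data_dir / "cascade_lengths.tsv")

    def test_cascade_survivors_match_independent_recomputation(self, fixture_em):
        """Recompute every filter with plain numpy/scipy on the printed
        10-gene table and compare the survivor set filter by filter."""
        from scipy import stats as ss

        de = differential_expression(fixture_em, self.HIGH, self.LOW)

        # independent TPM
        rate = fixture_em.data.div(fixture_em.lengths, axis=0)
        tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
        log = np.log2(tpm + 1.0)
        abundant = (
            (tpm[self.HIGH].mean(axis=1) > 1) | (tpm[self.LOW].mean(axis=1) > 1)
        )
        assert de["passes_abundance"].equals(abundant)
        assert set(de.index[de["filter_failed"] == "abundance"]) == {"g03"}

        mads = (log.sub(log.median(axis=1), axis=0)).abs().median(axis=1)[abundant]
        keep_n = int(np.ceil(0.75 * abundant.sum()))
        kept = set(mads.sort_values(ascending=False).index[:keep_n])
        assert set(de.index[de["passes_mad"]]) == kept == (
            set(abundant.index[abundant]) - {"g04", "g08"}
        )

        tested = sorted(kept)
        pvals = {
            g: ss.mannwhitneyu(
                log.loc[g, self.HIGH], log.loc[g, self.LOW], alternative="two-sided"
            ).pvalue
            for g in tested
        }
        assert np.allclose(de.loc[tested, "p"], [pvals[g] for g in tested])
        sig = {g for g in tested if de.loc[g, "adj_p"] < 0.05}
        assert sig == {"g01", "g02", "g06"}

        fc = log[self.HIGH].mean(axis=1) - log[self.LOW].mean(axis=1)
        assert np.allclose(de["log2_fc"], fc)
        survivors = {g for g in sig if abs(fc[g]) > np.log2(1.5)}
        assert survivors == set(de.index[de["passes_de"]]) == {"g01", "g06"}
        assert de.loc["g02", "filter_failed"] == "fc"
        assert de.loc["g01", "direction"] == "up_in_high"
        assert de.loc["g06", "direction"] == "down_in_high"

    def test_identical_groups_yield_no_survivors(self):
        groups = pd.Series([0] * 12, index=[f"s{i}" for i in range(12)])
        em, _ = simulate_expression(60, groups, seed=42)
        de = differential_expression(em, list(groups.index[:6]), list(groups.index[6:]))
        assert de["passes_de"].sum() == 0

    def test_degenerate_fold_change_threshold(self, fixture_em):
        th = ScreenThresholds(fc=1.0)
        de = differential_expression(fixture_em, self.HIGH, self.LOW, th)
        tested = de["p"].notna()
        assert de.loc[tested, "passes_fc"].all()

    def test_overlapping_or_tiny_groups_rejected(self, fixture_em):
        with pytest.raises(ValueError, match="overlap"):
            differential_expression(fixture_em, self.HIGH, self.HIGH[:3] + self.LOW[:3])
        with pytest.raises(ValueError, match="at least 3"):
            differential_expression(fixture_em, self.HIGH[:2], self.LOW)


class TestPrognosticScreen:
    def test_no_genes_in_no_genes_out(self):
        groups = pd.Series([0, 1] * 6, index=[f"s{i}" for i in range(12)])
        em, _ = simulate_expression(5, groups, seed=1)
        tpm = tpm_normalize(em)
        clin = simulate_survival(groups.to_numpy(), seed=2, sample_ids=groups.index)
        out = univariate_prognostic_screen(tpm, clin, genes=[])
        assert out.empty

    def test_planted_prognostic_gene_detected_among_nulls(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(900 + rep)
            n = 200
            samples = [f"s{i}" for i in range(n)]
            groups = pd.Series(np.zeros(n, dtype=int), index=samples)
            em, _ = simulate_expression(50, groups, seed=rng)
            tpm = tpm_normalize(em)
            x = np.log2(tpm.data.loc["G0001"] + 1.0)
            z = (x - x.mean()) / x.std()
            clin = simulate_survival(
                np.zeros(n), hr=1.0, seed=rng, linear_predictor=-0.9 * z.to_numpy(),
                sample_ids=samples,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = univariate_prognostic_screen(tpm, clin)
            hits += bool(out.loc["G0001", "prognostic"])
        assert hits >= 9

    def test_null_retention_near_alpha(self):
        retained = []
        for rep in range(6):
            rng = np.random.default_rng(300 + rep)
            n = 150
            samples = [f"s{i}" for i in range(n)]
            groups = pd.Series(np.zeros(n, dtype=int), index=samples)
            em, _ = simulate_expression(80, groups, seed=rng)
            tpm = tpm_normalize(em)
            clin = simulate_survival(np.zeros(n), hr=1.0, seed=rng, sample_ids=samples)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = univariate_prognostic_screen(tpm, clin)
            retained.append(out["prognostic"].mean())
        assert np.mean(retained) == pytest.approx(0.05, abs=0.03)


class TestPenalizedSelection:
    def _cohort(self, seed, betas):
        rng = np.random.default_rng(seed)
        n = 250
        samples = [f"s{i}" for i in range(n)]
        groups = pd.Series(np.zeros(n, dtype=int), index=samples)
        em, _ = simulate_expression(len(betas), groups, seed=rng)
        tpm = tpm_normalize(em)
        log = np.log2(tpm.data + 1.0)
        z = log.sub(log.mean(axis=1), axis=0).div(log.std(axis=1), axis=0)
        lp = (z.T @ np.array(betas)).to_numpy()
        clin = simulate_survival(
            np.zeros(n), hr=1.0, seed=rng, linear_predictor=lp, sample_ids=samples
        )
        return tpm, clin

    def test_single_strong_gene_selected_from_nulls(self):
        hits = 0
        for rep in range(5):
            betas = [-0.9] + [0.0] * 9
            tpm, clin = self._cohort(700 + rep, betas)
            sel = penalized_signature_selection(tpm, clin, list(tpm.genes), seed=rep)
            hits += sel.genes == ["G0001"]
        assert hits >= 4

    def test_all_null_selection_near_empty(self):
        sizes = []
        for rep in range(5):
            tpm, clin = self._cohort(800 + rep, [0.0] * 10)
            sel = penalized_signature_selection(tpm, clin, list(tpm.genes), seed=rep)
            sizes.append(len(sel.genes))
        assert np.median(sizes) <= 2

    def test_fewer_samples_than_folds_rejected(self):
        tpm, clin = self._cohort(1, [0.0, 0.0])
        small = tpm.subset(samples=list(tpm.samples[:5]))
        with pytest.raises(ValueError, match="folds"):
            penalized_signature_selection(small, clin, list(tpm.genes), n_folds=10)


class TestRiskStratify:
    def _clin(self, n, seed=0):
        return simulate_survival(
            np.zeros(n), hr=1.0, seed=seed, sample_ids=[f"s{i}" for i in range(n)]
        )

    def test_even_distinct_scores_split_equally(self):
        n = 20
        scores = pd.Series(np.arange(n, dtype=float), index=[f"s{i}" for i in range(n)])
        strat = risk_stratify(scores, self._clin(n))
        assert (strat.groups == "high").sum() == (strat.groups == "low").sum() == 10

    def test_median_ties_go_to_low_group(self):
        scores = pd.Series([1.0, 2.0, 2.0, 2.0, 2.0, 5.0], index=[f"s{i}" for i in range(6)])
        strat = risk_stratify(scores, self._clin(6))
        # median is 2; the four tied samples all land in the low-risk group
        assert list(strat.groups[scores == 2.0]) == ["low"] * 4
        assert (strat.groups == "high").sum() == 1

    def test_planted_protective_signature_gives_hr_below_one(self):
        ok = 0
        for rep in range(8):
            rng = np.random.default_rng(40 + rep)
            n = 300
            x = rng.normal(size=n)
            clin = simulate_survival(
                np.zeros(n), hr=1.0, seed=rng, linear_predictor=0.9 * x,
                sample_ids=[f"s{i}" for i in range(n)],
            )
            scores = pd.Series(x, index=clin["sample"])
            strat = risk_stratify(scores, clin)
            ok += strat.cox.hr > 1 and strat.cox.ci95_low > 1
        assert ok >= 7

    def test_constant_scores_rejected(self):
        scores = pd.Series([1.0] * 6, index=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError):
            risk_stratify(scores, self._clin(6))


class TestFeatureCorrelation:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert feature_correlation(x, x)[0] == pytest.approx(1.0)
        assert feature_correlation(x, -x)[0] == pytest.approx(-1.0)
        assert feature_correlation(x, x**3, method="spearman")[0] == pytest.approx(1.0)

    def test_five_point_hand_table(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        # direct formula: r = cov / (sd_x sd_y)
        r_hand = np.sum((x - 3) * (y - 3)) / np.sqrt(np.sum((x - 3) ** 2) * np.sum((y - 3) ** 2))
        r, p = feature_correlation(x, y)
        assert r == pytest.approx(r_hand, abs=1e-12)
        assert 0 < p < 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            feature_correlation([1, 1, 1], [1, 2, 3])
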