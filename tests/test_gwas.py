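"""Association tests, retention rate, error models and the validation loop."""

import numpy as np
import pytest
from scipy import stats

from provgen.datamodel import ContingencyTable, Findings, SnpDataset, ValidationError
from provgen.gwas import (
    build_table,
    chi_square_p,
    inject_flipping_error,
    inject_noise_error,
    odds_ratio_p,
    relaxed_threshold,
    retention_rate,
    run_gwas,
    validation_experiment,
)
from provgen.synthetic import generate_case_control


def _pearson_chi2_oracle(arr):
    """Independent textbook Pearson chi-square on a 2xk table."""
    arr = np.asarray(arr, dtype=float)
    row = arr.sum(axis=1, keepdims=True)
    col = arr.sum(axis=0, keepdims=True)
    expected = row * col / arr.sum()
    stat = ((arr - expected) ** 2 / expected).sum()
    df = arr.shape[1] - 1
    return stat, stats.chi2.sf(stat, df)


class TestBuildTable:
    def test_counts(self):
        ds = SnpDataset(
            np.array([[0], [1], [2], [2]]), list("abcd"), ["rs0"],
            ["case", "case", "control", "control"],
        )
        table = build_table(ds, 0)
        assert table.case_counts == (1, 1, 0)
        assert table.control_counts == (0, 0, 2)
        assert table.total == 4

    def test_totals_equal_sample_count(self, small_dataset):
        for j in range(small_dataset.n_snps):
            assert build_table(small_dataset, j).total == small_dataset.n_samples

    def test_missing_phenotype_rejected(self):
        ds = SnpDataset(np.array([[0]]), ["a"], ["rs0"])
        with pytest.raises(ValidationError):
            build_table(ds, 0)


class TestChiSquare:
    def test_proportional_rows_give_p_one(self):
        table = ContingencyTable((10, 20, 10), (20, 40, 20))
        assert chi_square_p(table) == pytest.approx(1.0)

    def test_against_hand_oracle(self):
        table = ContingencyTable((10, 20, 10), (20, 20, 20))
        stat, p_oracle = _pearson_chi2_oracle(table.as_array())
        assert stat == pytest.approx(25 / 9, abs=1e-9)
        assert chi_square_p(table) == pytest.approx(p_oracle, abs=1e-9)

    def test_empty_genotype_column_reduces_df(self):
        table = ContingencyTable((10, 20, 0), (20, 20, 0))
        arr = table.as_array()[:, :2]
        _, p_oracle = _pearson_chi2_oracle(arr)
        assert chi_square_p(table) == pytest.approx(p_oracle, abs=1e-12)

    def test_invariant_under_group_swap(self):
        a = ContingencyTable((5, 9, 2), (11, 3, 7))
        b = ContingencyTable((11, 3, 7), (5, 9, 2))
        assert chi_square_p(a) == pytest.approx(chi_square_p(b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_p(ContingencyTable((0, 0, 0), (1, 2, 3)))


class TestOddsRatio:
    def test_equal_allele_frequencies_give_or_one(self):
        table = ContingencyTable((10, 10, 10), (20, 20, 20))
        or_, p = odds_ratio_p(table)
        assert or_ == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_against_wald_oracle(self):
        # allelic cells a=10, b=90, c=5, d=95
        table = ContingencyTable((40, 10, 0), (45, 5, 0))
        or_, p = odds_ratio_p(table)
        assert or_ == pytest.approx((10 * 95) / (90 * 5), abs=1e-12)
        se = np.sqrt(1 / 10 + 1 / 90 + 1 / 5 + 1 / 95)
        z = np.log(or_) / se
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)

    def test_zero_cell_triggers_correction(self):
        or_, p = odds_ratio_p(ContingencyTable((0, 0, 5), (5, 0, 0)))
        assert np.isfinite(or_) and or_ > 1
        assert 0 <= p <= 1

    def test_reciprocal_under_group_swap(self):
        a = odds_ratio_p(ContingencyTable((5, 9, 2), (11, 3, 7)))[0]
        b = odds_ratio_p(ContingencyTable((11, 3, 7), (5, 9, 2)))[0]
        assert a == pytest.approx(1 / b, abs=1e-12)


class TestRunGwas:
    def test_null_p_values_uniform(self):
        study = generate_case_control(
            m=2000, n_case=150, n_control=150, effect_or=1.0, seed=21
        )
        p = run_gwas(study.dataset, "chi2")
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05

    @pytest.mark.parametrize("test", ["chi2", "odds_ratio"])
    def test_planted_association_detected(self, test):
        study = generate_case_control(
            m=30, n_case=1000, n_control=1000, causal_indices=[3],
            effect_or=3.0, seed=8,
        )
        p = run_gwas(study.dataset, test)
        assert p[3] < 1e-4

    def test_monomorphic_snp_returns_one(self):
        geno = np.zeros((10, 1), dtype=int)
        ds = SnpDataset(
            geno, [f"s{i}" for i in range(10)], ["rs0"],
            ["case"] * 5 + ["control"] * 5,
        )
        assert run_gwas(ds, "chi2")[0] == 1.0
        assert run_gwas(ds, "odds_ratio")[0] == 1.0


class TestRelaxedThreshold:
    def test_headline_value(self):
        assert relaxed_threshold(0.05, 0.8) == pytest.approx(0.0625)

    def test_tolerance_one_is_identity(self):
        assert relaxed_threshold(0.01, 1.0) == pytest.approx(0.01)

    def test_zero_tolerance_rejected(self):
        with pytest.raises(ValidationError):
            relaxed_threshold(0.05, 0.0)


class TestRetentionRate:
    def _findings(self, p_values):
        return Findings(
            records=[(f"rs{i}", p, 0.2) for i, p in enumerate(p_values)],
            alpha=0.05,
        )

    def test_fractions(self):
        reported = self._findings([0.01, 0.02, 0.03, 0.04, 0.9])
        reproduced = {"rs0": 0.01, "rs1": 0.01, "rs2": 0.01, "rs3": 0.99, "rs4": 0.5}
        assert retention_rate(reported, reproduced, 0.0625) == pytest.approx(0.75)
        assert retention_rate(reported, {k: 0.0 for k in reproduced}, 0.0625) == 1.0
        assert retention_rate(reported, {k: 1.0 for k in reproduced}, 0.0625) == 0.0

    def test_scale_free(self):
        reported = self._findings([0.01, 0.02, 0.9])
        reproduced = {"rs0": 0.04, "rs1": 0.08, "rs2": 0.5}
        r1 = retention_rate(reported, reproduced, 0.0625)
        r2 = retention_rate(
            reported, {k: v / 2 for k, v in reproduced.items()}, 0.0625 / 2
        )
        assert r1 == r2

    def test_empty_reported_set_rejected(self):
        with pytest.raises(ValidationError):
            retention_rate(self._findings([0.5, 0.9]), {"rs0": 0.1, "rs1": 0.1}, 0.0625)


class TestErrorInjection:
    def test_zero_rates_are_identity(self, rng):
        p = rng.random(100)
        assert np.array_equal(inject_flipping_error(p, 0.0, 1), p)
        assert inject_noise_error(p, 0.0, 1) == pytest.approx(p)

    def test_flip_replacement_count_exact(self, rng):
        p = np.full(1000, 2.0)  # sentinel outside [0,1]
        for rate in (0.1, 0.25, 0.5):
            out = inject_flipping_error(p, rate, 3)
            assert int((out != 2.0).sum()) == round(rate * 1000)

    def test_full_flip_is_uniform(self):
        p = np.zeros(10_000)
        out = inject_flipping_error(p, 1.0, 4)
        assert stats.kstest(out, "uniform").pvalue > 1e-3

    def test_noise_scale_matches_delta(self, rng):
        p = np.full(100_000, 0.5)
        out = inject_noise_error(p, 0.01, 5)  # small sd: no clipping at 0.5
        assert np.std(out - 0.5) == pytest.approx(0.01, rel=0.05)

    def test_noise_output_clipped(self, rng):
        out = inject_noise_error(rng.random(1000), 2.0, 6)
        assert ((out >= 0) & (out <= 1)).all()


class TestValidationExperiment:
    def test_zero_rate_difference_is_zero_and_monotone_signal(self):
        study = generate_case_control(
            m=60, n_case=150, n_control=150, causal_indices=[0, 1, 2],
            effect_or=3.0, seed=31,
        )
        ds = study.dataset
        rows = validation_experiment(
            ds, ds, error_rates=[0.0, 1.0], repeats=10, seed=1
        )
        assert rows[0].mean_difference == 0.0
        # with released == original and full flipping, retention of a
        # uniform reported set is about the relaxed threshold
        assert rows[1].mean_difference > 0.5

    def test_difference_grows_with_flip_rate_on_released_data(self):
        from provgen.datamodel import PrivacyBudget
        from provgen.ebng import compute_sensitivity
        from provgen.encoding import encode
        from provgen.restoration import release
        from provgen.synthetic import generate_panel

        study = generate_case_control(
            m=60, n_case=150, n_control=150, causal_indices=[0, 1, 2],
            effect_or=4.0, seed=32,
        )
        ds = study.dataset
        labels = np.asarray(ds.phenotype)
        targets = {
            lab: ds.subset_rows(labels == lab).maf() for lab in ("case", "control")
        }
        panel = generate_panel(m=60, n=300, seed=33)
        budget = PrivacyBudget(5.0, compute_sensitivity(60))
        released = release(ds, encode(panel), targets, budget, seed=34)
        rows = validation_experiment(
            ds, released, error_rates=[0.0, 0.1, 1.0], repeats=10, seed=2
        )
        assert rows[0].mean_difference == 0.0
        assert rows[2].mean_difference > rows[1].mean_difference
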