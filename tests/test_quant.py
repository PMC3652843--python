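"""qPCR enrichment, ddCt expression and reporter fold-activation arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foxe1_targets import (
    amplification_quantity,
    assign_stars,
    fold_activation,
    relative_expression,
    relative_ip_ratio,
)
from foxe1_targets.synth import (
    GeneratorConfig,
    gen_chip_qpcr,
    gen_expression_qpcr,
    gen_reporter,
)


def chip_rows(groups):
    """Build a Ct table from {(sample, amplicon, experiment): ct} group means."""
    rows = []
    for (sample, amplicon, exp), ct in groups.items():
        for rep in (1, 2, 3):
            rows.append((sample, "FoxE1", amplicon, exp, rep, ct))
    return pd.DataFrame(
        rows, columns=["sample", "antibody_or_condition", "amplicon",
                       "experiment", "replicate", "ct"],
    )


class TestAmplificationQuantity:
    def test_zero_delta_ct(self):
        assert amplification_quantity(20.0, 20.0) == 1.0

    def test_two_cycles_at_perfect_doubling(self):
        assert amplification_quantity(18.0, 20.0) == 4.0

    def test_fractional_efficiency(self):
        assert amplification_quantity(18.0, 20.0, efficiency=1.5) == pytest.approx(2.25)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValueError):
            amplification_quantity(float("nan"), 20.0)

    @pytest.mark.parametrize("eff", [1.0, 0.5, 2.5])
    def test_efficiency_outside_range_rejected(self, eff):
        with pytest.raises(ValueError):
            amplification_quantity(18.0, 20.0, efficiency=eff)


class TestRelativeIpRatio:
    def test_target_identical_to_control_gives_unit_ratio(self):
        df = chip_rows({
            ("IP", "NUE", 1): 22.0, ("input", "NUE", 1): 20.0,
            ("IP", "Afm", 1): 22.0, ("input", "Afm", 1): 20.0,
            ("IP", "NUE", 2): 23.0, ("input", "NUE", 2): 21.0,
            ("IP", "Afm", 2): 23.0, ("input", "Afm", 2): 21.0,
        })
        res = relative_ip_ratio(df, "NUE", "Afm")
        assert (res.relative_ip_ratio, res.sem, res.n_experiments) == (1.0, 0.0, 2)

    def test_three_cycle_advantage_gives_eightfold(self):
        # target dCt exceeds control dCt by 3 cycles in both experiments
        df = chip_rows({
            ("IP", "Tg", 1): 19.0, ("input", "Tg", 1): 20.0,
            ("IP", "Afm", 1): 22.0, ("input", "Afm", 1): 20.0,
            ("IP", "Tg", 2): 18.0, ("input", "Tg", 2): 19.0,
            ("IP", "Afm", 2): 21.0, ("input", "Afm", 2): 19.0,
        })
        res = relative_ip_ratio(df, "Tg", "Afm")
        assert res.relative_ip_ratio == pytest.approx(8.0)
        assert res.sem == pytest.approx(0.0)

    def test_global_ct_shift_cancels(self):
        base = {
            ("IP", "NUE", 1): 18.5, ("input", "NUE", 1): 21.0,
            ("IP", "Afm", 1): 23.0, ("input", "Afm", 1): 20.5,
            ("IP", "NUE", 2): 19.0, ("input", "NUE", 2): 21.5,
            ("IP", "Afm", 2): 23.5, ("input", "Afm", 2): 21.0,
        }
        shifted = {k: (ct + 2.75 if k[2] == 1 else ct) for k, ct in base.items()}
        r0 = relative_ip_ratio(chip_rows(base), "NUE", "Afm")
        r1 = relative_ip_ratio(chip_rows(shifted), "NUE", "Afm")
        assert r1.relative_ip_ratio == pytest.approx(r0.relative_ip_ratio)

    def test_swapping_target_and_control_inverts_ratio(self):
        df = chip_rows({
            ("IP", "NUE", 1): 18.0, ("input", "NUE", 1): 21.0,
            ("IP", "Afm", 1): 23.0, ("input", "Afm", 1): 20.0,
        })
        fwd = relative_ip_ratio(df, "NUE", "Afm").relative_ip_ratio
        rev = relative_ip_ratio(df, "Afm", "NUE").relative_ip_ratio
        assert fwd * rev == pytest.approx(1.0)

    def test_doubling_ddct_squares_the_ratio(self):
        def table(extra):
            return chip_rows({
                ("IP", "T", 1): 20.0 - extra, ("input", "T", 1): 20.0,
                ("IP", "Afm", 1): 20.0, ("input", "Afm", 1): 20.0,
            })
        r1 = relative_ip_ratio(table(2.0), "T", "Afm").relative_ip_ratio
        r2 = relative_ip_ratio(table(4.0), "T", "Afm").relative_ip_ratio
        assert r2 == pytest.approx(r1**2)

    def test_missing_input_pair_rejected(self):
        df = chip_rows({("IP", "NUE", 1): 20.0, ("IP", "Afm", 1): 20.0,
                        ("input", "Afm", 1): 20.0})
        with pytest.raises(ValueError, match="IP/input"):
            relative_ip_ratio(df, "NUE", "Afm")

    def test_noiseless_generator_inverts_exactly(self):
        config = GeneratorConfig(seed=5)
        config = config.model_copy(
            update={"chip": config.chip.model_copy(update={"ct_noise_sd": 0.0})}
        )
        table, ratios = gen_chip_qpcr(config)
        for amplicon, planted in ratios.items():
            res = relative_ip_ratio(table, amplicon, "Afm")
            assert res.relative_ip_ratio == pytest.approx(planted, rel=1e-9)

    def test_noisy_recovery_within_three_sem(self):
        """Planted ratios spanning the published range are recovered within
        3 SEM at 2 experiments x 3 triplicates with Ct noise sd 0.1."""
        planted = {"a": 1.0, "b": 3.6, "c": 9.3, "d": 12.6, "e": 22.8, "f": 28.1}
        config = GeneratorConfig(seed=11)
        config = config.model_copy(
            update={"chip": config.chip.model_copy(
                update={"planted_ratios": planted})}
        )
        table, ratios = gen_chip_qpcr(config)
        rel_errors = []
        for amplicon, true_ratio in ratios.items():
            res = relative_ip_ratio(table, amplicon, "Afm")
            tol = max(3 * res.sem, 1e-6)
            assert abs(res.relative_ip_ratio - true_ratio) <= tol + 0.15 * true_ratio
            rel_errors.append(abs(res.relative_ip_ratio - true_ratio) / true_ratio)
        assert np.median(rel_errors) < 0.10


class TestRelativeExpression:
    def expr_rows(self, groups):
        rows = []
        for (condition, gene, exp), ct in groups.items():
            for rep in (1, 2, 3):
                rows.append(("cDNA", condition, gene, exp, rep, ct))
        return pd.DataFrame(
            rows, columns=["sample", "antibody_or_condition", "amplicon",
                           "experiment", "replicate", "ct"],
        )

    def test_treated_identical_to_reference_gives_one(self):
        df = self.expr_rows({
            ("siFoxE1", "Nis", 1): 24.0, ("siFoxE1", "Gus", 1): 21.0,
            ("siScramble", "Nis", 1): 24.0, ("siScramble", "Gus", 1): 21.0,
        })
        res = relative_expression(df, "Nis", "Gus", "siFoxE1", "siScramble")
        assert res.relative_ip_ratio == pytest.approx(1.0)

    def test_one_cycle_higher_ct_halves_expression(self):
        df = self.expr_rows({
            ("siFoxE1", "Nis", 1): 25.0, ("siFoxE1", "Gus", 1): 21.0,
            ("siScramble", "Nis", 1): 24.0, ("siScramble", "Gus", 1): 21.0,
        })
        res = relative_expression(df, "Nis", "Gus", "siFoxE1", "siScramble")
        assert res.relative_ip_ratio == pytest.approx(0.5)

    def test_missing_normalizer_rejected(self):
        df = self.expr_rows({("siFoxE1", "Nis", 1): 25.0,
                             ("siScramble", "Nis", 1): 24.0})
        with pytest.raises(ValueError):
            relative_expression(df, "Nis", "Gus", "siFoxE1", "siScramble")

    def test_strong_knockdown_recovered_within_three_sem(self):
        config = GeneratorConfig(seed=13)
        config = config.model_copy(
            update={"expression": config.expression.model_copy(
                update={"planted_folds": {"FoxE1": 0.15}})}
        )
        table, folds = gen_expression_qpcr(config)
        res = relative_expression(table, "FoxE1", "Gus", "siFoxE1", "siScramble")
        assert abs(res.relative_ip_ratio - 0.15) <= max(3 * res.sem, 0.02)


def reporter_rows(groups, n_reps=3):
    rows = []
    for (condition, exp), (luc, ren) in groups.items():
        for rep in range(1, n_reps + 1):
            rows.append((condition, exp, rep, luc, ren))
    return pd.DataFrame(
        rows, columns=["condition", "experiment", "replicate", "luciferase", "renilla"]
    )


class TestFoldActivation:
    def test_condition_identical_to_control(self):
        df = reporter_rows({
            ("empty", 1): (5e4, 1e5), ("empty", 2): (5e4, 1e5),
            ("FoxE1", 1): (5e4, 1e5), ("FoxE1", 2): (5e4, 1e5),
        })
        res = fold_activation(df, "FoxE1", "empty")
        assert res.fold == pytest.approx(1.0)
        assert res.stars == ""

    def test_unknown_condition_rejected(self):
        df = reporter_rows({("empty", 1): (1e4, 1e5), ("empty", 2): (1e4, 1e5)})
        with pytest.raises(KeyError):
            fold_activation(df, "FoxE1", "empty")

    def test_planted_twofold_recovered_and_significant(self):
        config = GeneratorConfig(seed=17)
        table, folds = gen_reporter(config)
        res = fold_activation(table, "FoxE1", "empty")
        assert abs(res.fold - 2.0) <= 3 * res.sd / np.sqrt(res.n_experiments)
        assert res.p_value < 0.05
        assert res.n_experiments == 6

    def test_type_i_error_rate_of_t_test_wrapper(self):
        """Two groups from the same distribution earn a star at p<0.05 in
        roughly 5% of simulations (Welch test calibration)."""
        rng = np.random.default_rng(29)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(1.0, 0.1, size=6)
            b = rng.normal(1.0, 0.1, size=6)
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
            hits += assign_stars(p) != ""
        # binomial(1000, 0.05): 3 sigma is ~2%
        assert abs(hits / n_sim - 0.05) < 0.025


class TestStars:
    @pytest.mark.parametrize(
        "p,stars",
        [(0.2, ""), (0.049, "*"), (0.009, "**"), (0.0009, "***"), (0.05, "")],
    )
    def test_thresholds(self, p, stars):
        assert assign_stars(p) == stars
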