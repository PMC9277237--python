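import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cloverwatch import (
    DegenerateDataError,
    compare_visitor_definitions,
    gaussian_aic,
    sli_vli_regression,
    two_group_seedset_model,
)
from cloverwatch.errors import ConfigurationError


def _index_table(s=None, visited=None, bee=None, vli=None, sli=None, w=None):
    n = len(s if s is not None else vli)
    df = pd.DataFrame(index=pd.Index([f"i{k}" for k in range(n)], name="inflorescence_id"))
    df["s"] = s if s is not None else np.nan
    df["visited_any"] = visited if visited is not None else True
    df["visited_bumblebee"] = bee if bee is not None else df["visited_any"]
    df["vli"] = vli if vli is not None else np.nan
    df["sli"] = sli if sli is not None else np.nan
    df["w"] = w if w is not None else 0.1
    df["fully_recorded"] = True
    return df


def pooled_t(a, b):
    """Hand-computed pooled-variance two-sample t statistic."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    return (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))


class TestTwoGroup:
    def test_f_equals_squared_pooled_t_fixed_example(self):
        a, b = [0.10, 0.20, 0.30], [0.30, 0.40, 0.50]
        tab = _index_table(s=a + b, visited=[False] * 3 + [True] * 3)
        fit = two_group_seedset_model(tab, "any_visit")
        assert fit.F == pytest.approx(pooled_t(b, a) ** 2, rel=1e-10)
        assert fit.df == (1, 4)
        assert fit.mean_difference_pct == pytest.approx((np.mean(b) - np.mean(a)) * 100)

    def test_f_equals_squared_pooled_t_on_many_random_datasets(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            na, nb = rng.integers(2, 12, 2)
            a = rng.normal(0.2, 0.1, na).clip(0, 0.5)
            b = rng.normal(0.3, 0.1, nb).clip(0, 0.5)
            if np.var(a) + np.var(b) == 0:
                continue
            tab = _index_table(
                s=np.concatenate([a, b]), visited=[False] * na + [True] * nb
            )
            fit = two_group_seedset_model(tab, "any_visit")
            assert fit.F == pytest.approx(pooled_t(b, a) ** 2, rel=1e-8)
            # and the F p-value matches the two-sided t p-value
            p_t = 2 * stats.t.sf(abs(pooled_t(b, a)), na + nb - 2)
            assert fit.p_value == pytest.approx(p_t, rel=1e-8)

    def test_constant_response_is_degenerate(self):
        tab = _index_table(s=[0.2] * 6, visited=[False] * 3 + [True] * 3)
        with pytest.raises(DegenerateDataError):
            two_group_seedset_model(tab, "any_visit")

    def test_empty_group_is_degenerate(self):
        tab = _index_table(s=[0.1, 0.2, 0.3], visited=[True] * 3)
        with pytest.raises(DegenerateDataError):
            two_group_seedset_model(tab, "any_visit")

    def test_unknown_grouping(self):
        with pytest.raises(ConfigurationError):
            two_group_seedset_model(_index_table(s=[0.1, 0.2]), "moths_only")

    def test_type_one_error_near_nominal_under_permutation_null(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            s = rng.normal(0.25, 0.08, 20)
            visited = rng.permutation([False] * 10 + [True] * 10)
            fit = two_group_seedset_model(_index_table(s=s, visited=visited), "any_visit")
            rejections += fit.p_value < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.015)


class TestAICComparison:
    def test_equal_rss_gives_zero(self):
        assert gaussian_aic(2.0, 10, 3) - gaussian_aic(2.0, 10, 3) == 0.0

    def test_closed_form_n_ln_ratio(self):
        assert gaussian_aic(4.0, 10, 3) - gaussian_aic(2.0, 10, 3) == pytest.approx(
            10 * math.log(2), rel=1e-12
        )

    def test_better_any_visit_model_positive_delta(self):
        # seed set tracks any-visit, while bumblebee flag is uninformative
        s = [0.1, 0.12, 0.11, 0.3, 0.32, 0.31]
        visited = [False] * 3 + [True] * 3
        bee = [False, True, False, True, False, True]
        tab = _index_table(s=s, visited=visited, bee=bee)
        out = compare_visitor_definitions(tab)
        assert out["delta_aic"] > 0
        n = out["any_visit"].n
        assert out["delta_aic"] == pytest.approx(
            n * math.log(out["bumblebee_only"].rss / out["any_visit"].rss), rel=1e-10
        )


class TestSliVliRegression:
    def test_matches_hand_solved_normal_equations(self):
        # 4 points, unequal weights; closed-form 2x2 weighted normal equations
        x = np.array([-2.0, 0.0, 1.0, 3.0])
        y = np.array([20.0, 35.0, 50.0, 70.0])
        w = np.array([0.05, 0.20, 0.10, 0.15])
        sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
        swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
        slope = (sw * swxy - swx * swy) / (sw * swxx - swx**2)
        intercept = (swy - slope * swx) / sw
        tab = _index_table(vli=x, sli=y, w=w, s=[0.2] * 4)
        fit = sli_vli_regression(tab, weighted=True)
        assert fit.slope == pytest.approx(slope, rel=1e-10)
        assert fit.intercept == pytest.approx(intercept, rel=1e-10)
        assert fit.df_residual == 2

    def test_constant_weights_reduce_to_ols(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=8)
        tab_w = _index_table(vli=x, sli=y, w=[0.2] * 8, s=[0.2] * 8)
        fit_w = sli_vli_regression(tab_w, weighted=True)
        fit_u = sli_vli_regression(tab_w, weighted=False)
        assert fit_w.slope == pytest.approx(fit_u.slope, rel=1e-10)
        assert fit_w.F == pytest.approx(fit_u.F, rel=1e-10)
        assert fit_w.r_squared == pytest.approx(fit_u.r_squared, rel=1e-10)

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=9), rng.normal(size=9)
        w = rng.uniform(0.01, 0.25, 9)
        f1 = sli_vli_regression(_index_table(vli=x, sli=y, w=w, s=[0.2] * 9), True)
        f2 = sli_vli_regression(_index_table(vli=x, sli=y, w=w * 37.5, s=[0.2] * 9), True)
        assert f1.slope == pytest.approx(f2.slope, rel=1e-10)
        assert f1.p_value == pytest.approx(f2.p_value, rel=1e-10)

    def test_collinear_points_r_squared_one(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = sli_vli_regression(
            _index_table(vli=x, sli=10 + 5 * x, w=[0.1, 0.2, 0.1, 0.2], s=[0.2] * 4), True
        )
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_zero_weight_rows_do_not_count(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 9.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, -50.0])
        w = np.array([0.1, 0.1, 0.1, 0.1, 0.0])
        fit = sli_vli_regression(_index_table(vli=x, sli=y, w=w, s=[0.2] * 5), True)
        assert fit.n == 4
        assert fit.df_residual == 2
        assert fit.slope == pytest.approx(1.0, abs=1e-10)

    def test_undefined_indices_excluded(self):
        tab = _index_table(
            vli=[0.0, 1.0, 2.0, np.nan], sli=[1.0, 2.0, 3.0, 4.0], w=[0.1] * 4, s=[0.2] * 4
        )
        assert sli_vli_regression(tab, True).n == 3

    def test_all_zero_weights_degenerate(self):
        tab = _index_table(vli=[0.0, 1.0, 2.0], sli=[1.0, 2.0, 3.0], w=[0.0] * 3, s=[0.2] * 3)
        with pytest.raises(DegenerateDataError):
            sli_vli_regression(tab, True)

    def test_too_few_points(self):
        tab = _index_table(vli=[0.0, 1.0], sli=[1.0, 2.0], w=[0.1] * 2, s=[0.2] * 2)
        with pytest.raises(DegenerateDataError):
            sli_vli_regression(tab, True)
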