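"""Normalization, template construction, correlation and category calls."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy import stats

from bbmprofiler.pattern import (
    ClassifierSettings,
    ProfileNormalizer,
    TemplatePatternClassifier,
    build_templates,
    classify,
    classify_table,
    correlate,
    fold_change,
    normalize_profile,
)
from conftest import make_count_table


class TestNormalizeProfile:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((5, 5, 5, 5), (1.0, 1.0, 1.0, 1.0)),
            ((0, 50, 100, 25), (0.01, 0.5, 1.0, 0.25)),
            ((1, 2, 4, 0), (0.25, 0.5, 1.0, 0.01)),
        ],
    )
    def test_max_normalization_with_floor(self, counts, expected):
        np.testing.assert_allclose(normalize_profile(counts), expected)

    def test_all_zero_profile_is_undefined(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_profile((0, 0, 0, 0))

    def test_maximum_is_exactly_one_and_floor_respected(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = rng.integers(0, 200, size=4)
            if v.max() == 0:
                continue
            p = normalize_profile(v)
            assert p.max() == 1.0
            assert (p >= 0.01).all()

    def test_normalizer_transformer_matches_per_row_function(self):
        X = np.array([[0, 50, 100, 25], [5, 5, 5, 5]])
        out = ProfileNormalizer().fit(X).transform(X)
        for row, x in zip(out, X):
            np.testing.assert_allclose(row, normalize_profile(x))


class TestTemplates:
    def test_default_template_vectors(self):
        tpls = {t.category: t.values for t in build_templates()}
        assert tpls["cat1-up"] == (0.5, 0.8, 0.5, 0.5)
        assert tpls["cat2-up"] == (0.5, 0.5, 0.8, 0.8)
        assert tpls["cat1-down"] == (0.5, 0.2, 0.5, 0.5)
        assert tpls["cat2-down"] == (0.5, 0.5, 0.2, 0.2)

    def test_zero_change_threshold_is_a_configuration_error(self):
        with pytest.raises(ValueError):
            ClassifierSettings(change_threshold=0.0)

    def test_baseline_plus_change_must_stay_within_range(self):
        with pytest.raises(ValueError):
            ClassifierSettings(baseline=0.9, change_threshold=0.3)


class TestCorrelate:
    def test_self_correlation_is_one_with_floored_p(self):
        t = build_templates()[0]
        r, r2, p = correlate(np.array(t.values), t)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert 0 < p < 1e-300

    def test_hand_computed_cross_template_correlation(self):
        # profile matching the cat1 pattern against the cat2-up template
        t = [t for t in build_templates() if t.category == "cat2-up"][0]
        r, r2, _ = correlate((0.5, 0.8, 0.5, 0.5), t)
        assert r == pytest.approx(-1 / np.sqrt(3))
        assert r2 == pytest.approx(1 / 3)

    def test_zero_variance_profile_flags_no_correlation(self):
        r, r2, p = correlate((1.0, 1.0, 1.0, 1.0), build_templates()[0])
        assert np.isnan(r) and np.isnan(r2) and np.isnan(p)

    @given(
        a=st.floats(-2, 2),
        b=st.floats(0.01, 5),
        prof=st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
    )
    @hyp_settings(max_examples=50, deadline=None)
    def test_affine_invariance_of_pearson(self, a, b, prof):
        prof = np.asarray(prof)
        if np.std(prof) < 1e-6:
            return
        base = np.array(build_templates()[0].values)
        r1, _, p1 = correlate(prof, base)
        r2_, _, p2 = correlate(prof, a + b * base)
        assert r1 == pytest.approx(r2_, abs=1e-9)
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_p_value_matches_independent_implementation(self):
        """Closed-form t p-value (df = 2) agrees with scipy.stats.pearsonr."""
        rng = np.random.default_rng(1)
        t = build_templates()[0]
        for _ in range(100):
            prof = rng.uniform(0.01, 1.0, size=4)
            if np.std(prof) < 1e-8:
                continue
            r, _, p = correlate(prof, t)
            ref = stats.pearsonr(prof, np.array(t.values))
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    def test_significance_boundary_at_df2(self):
        """Category-grade significance requires |r| >= t-critical ~ 0.950."""
        tcrit = stats.t.ppf(0.975, 2)
        rcrit = tcrit / np.sqrt(2 + tcrit**2)
        assert rcrit == pytest.approx(0.950, abs=1e-3)
        # p crosses alpha exactly at the critical r on a grid around it
        for r in np.linspace(0.90, 0.99, 19):
            tstat = r * np.sqrt(2 / (1 - r**2))
            p = 2 * stats.t.sf(tstat, 2)
            assert (p < 0.05) == (r > rcrit)


class TestClassify:
    def test_exact_template_match_is_called(self):
        res = classify((0.5, 0.8, 0.5, 0.5))
        assert res["category"] == "cat1-up"
        assert res["r2"] == pytest.approx(1.0)

    def test_all_groups_agreeing_within_nochange_is_null(self):
        assert classify((0.50, 0.55, 0.50, 0.45))["category"] == "null"

    def test_intermediate_deviation_is_unclassified(self):
        # 0.15 exceeds the no-change band but misses the change threshold
        assert classify((0.5, 0.65, 0.5, 0.5))["category"] == "unclassified"

    def test_down_regulation_variant_is_called(self):
        assert classify((1.0, 0.4, 1.0, 1.0))["category"] == "cat1-down"
        assert classify((1.0, 1.0, 0.4, 0.4))["category"] == "cat2-down"

    def test_cross_family_tie_yields_unclassified_with_flag(self):
        # built to correlate identically with both families: centered profile
        # orthogonal to u1 - u2 (unit centered templates)
        tpls = build_templates()
        t1 = np.array(tpls[0].values)
        t2 = np.array(tpls[2].values)
        u1 = (t1 - t1.mean()) / np.linalg.norm(t1 - t1.mean())
        u2 = (t2 - t2.mean()) / np.linalg.norm(t2 - t2.mean())
        prof = 0.5 + 0.3 * (u1 + u2)
        res = classify(prof)
        assert res["tie"]
        assert res["category"] in ("unclassified", "null")

    def test_every_call_satisfies_the_printed_threshold_definitions(self):
        """Assigned categories always obey the >=0.3 / <=0.1 rules."""
        rng = np.random.default_rng(2)
        X = rng.integers(0, 300, size=(400, 4))
        X = X[X.max(axis=1) > 0]
        table = make_count_table(X)
        res, _ = classify_table(table)
        called = res[res["category"].str.startswith("cat")]
        tpl = {t.category: t for t in build_templates()}
        for _, row in called.iterrows():
            prof = row[[f"norm_{g}" for g in ("ctrl_vehicle", "ctrl_glp2", "ko_vehicle", "ko_glp2")]].to_numpy(dtype=float)
            t = tpl[row["category"]]
            unchanged = [k for k in range(4) if k not in t.changed]
            base = prof[unchanged].mean()
            for k in t.changed:
                assert (prof[k] - base) * t.direction >= 0.3
            assert prof[unchanged].max() - prof[unchanged].min() <= 0.1
            assert row["p"] < 0.05

    @given(
        c=st.floats(0.01, 1000),
        counts=st.lists(st.integers(0, 500), min_size=4, max_size=4),
    )
    @hyp_settings(max_examples=60, deadline=None)
    def test_scale_invariance_of_profile_and_call(self, c, counts):
        counts = np.asarray(counts, dtype=float)
        if counts.max() == 0:
            return
        r1 = classify(normalize_profile(counts))
        r2 = classify(normalize_profile(counts * c))
        assert r1["category"] == r2["category"]
        np.testing.assert_allclose(
            [r1["fold_glp2_ctrl"], r1["fold_ko_vehicle"]],
            [r2["fold_glp2_ctrl"], r2["fold_ko_vehicle"]],
            rtol=1e-9,
            equal_nan=True,
        )

    def test_all_zero_proteins_are_excluded_not_fatal(self):
        table = make_count_table([[0, 0, 0, 0], [10, 30, 10, 10]])
        res, excluded = classify_table(table)
        assert excluded == ["P0"]
        assert len(res) == 1

    def test_estimator_params_roundtrip_and_validation(self):
        clf = TemplatePatternClassifier(change_threshold=0.4)
        assert clf.get_params()["change_threshold"] == 0.4
        clf.set_params(change_threshold=0.05)
        with pytest.raises(ValueError):
            clf.fit()  # 0.05 < nochange_threshold violates the ordering


class TestFoldChange:
    @pytest.mark.parametrize(
        "values, num, den, expected",
        [
            ((100, 100, 100, 100), "ctrl_glp2", "ctrl_vehicle", 1.0),
            ((100, 150, 10, 10), "ctrl_glp2", "ctrl_vehicle", 1.5),
            ((50, 50, 120, 50), "ko_vehicle", "ctrl_vehicle", 2.4),
        ],
    )
    def test_plain_ratio(self, values, num, den, expected):
        assert fold_change(values, num, den) == pytest.approx(expected)

    def test_zero_denominator_is_flagged_nan(self):
        assert np.isnan(fold_change((0, 10, 10, 10), "ctrl_glp2", "ctrl_vehicle"))

    def test_identical_on_counts_and_profile(self):
        counts = np.array([40.0, 90.0, 30.0, 55.0])
        prof = normalize_profile(counts)
        assert fold_change(counts, "ctrl_glp2", "ctrl_vehicle") == pytest.approx(
            fold_change(prof, "ctrl_glp2", "ctrl_vehicle")
        )
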