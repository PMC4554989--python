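"""Cohort-level statistics: Tukey exclusion, line summaries, contrasts, correlations."""

import numpy as np
import pandas as pd
import pytest

from springdamp import (
    exclude_outliers,
    fit_cohort,
    generate_cohort,
    line_effect_test,
    parameter_correlations,
    plant_outliers,
    preprocess_cohort,
    summarize_by_line,
    tukey_fences,
)
from springdamp.synthetic import CohortSpec, DEFAULT_LINE_MEDIANS


def make_fit_table(K_values, C_values=None, measure="m", line=None, replicate=None):
    n = len(K_values)
    C_values = C_values if C_values is not None else np.ones(n)
    return pd.DataFrame({
        "individual_id": [f"aq{i}" for i in range(n)],
        "measure": measure,
        "line": line if line is not None else ["A"] * n,
        "replicate": replicate if replicate is not None else ["rep1"] * n,
        "K": np.asarray(K_values, dtype=float),
        "C": np.asarray(C_values, dtype=float),
        "T": np.asarray(C_values, dtype=float) / np.asarray(K_values, dtype=float),
        "x_inf": 0.1 / np.asarray(K_values, dtype=float),
        "excluded": False,
    })


class TestExcludeOutliers:
    def test_single_gross_value_flagged(self):
        table = make_fit_table([1, 1, 1, 1, 1, 1, 1, 100])
        out = exclude_outliers(table)
        assert out["excluded"].tolist() == [False] * 7 + [True]

    def test_identical_values_never_flagged(self):
        # IQR = 0: fences collapse to the point, equality is inside
        out = exclude_outliers(make_fit_table([2.0] * 8, [3.0] * 8))
        assert not out["excluded"].any()

    def test_flag_on_either_parameter(self):
        table = make_fit_table([1, 1, 1, 1, 1, 1, 1, 1],
                               [1, 1, 1, 1, 1, 1, 1, 50])
        out = exclude_outliers(table)
        assert out["excluded"].sum() == 1
        assert out.loc[out["excluded"], "individual_id"].item() == "aq7"

    def test_too_few_rows_warns_without_exclusion(self):
        with pytest.warns(UserWarning, match="too few"):
            out = exclude_outliers(make_fit_table([1, 1, 100]))
        assert not out["excluded"].any()

    def test_idempotent_with_frozen_fences(self):
        table = make_fit_table([1, 1, 1, 1, 1, 1, 1, 100])
        once = exclude_outliers(table)
        twice = exclude_outliers(once)
        assert once["excluded"].tolist() == twice["excluded"].tolist()

    def test_fences_are_type7_quartiles(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        lo, hi = tukey_fences(v)
        assert (lo, hi) == (2.0 - 1.5 * 2.0, 4.0 + 1.5 * 2.0)

    def test_planted_outliers_flagged_exactly(self, single_line_degenerate_spec):
        cohort = generate_cohort(single_line_degenerate_spec)
        planted, ids = plant_outliers(cohort, 1, magnitude=20.0, seed=5)
        pre = preprocess_cohort(
            list(planted.series), single_line_degenerate_spec.baseline_scale
        )
        out = exclude_outliers(fit_cohort(pre))
        flagged = out[out["excluded"]]
        assert sorted(flagged["individual_id"]) == sorted(ids)
        assert set(flagged["measure"]) == {"cortisol_release"}


class TestSummarizeByLine:
    def test_derived_values_averaged_not_recomputed(self):
        # (K,C) = (0.1,2) and (0.3,3): mean T = (20+10)/2 = 15, not 2.5/0.2
        table = make_fit_table([0.1, 0.3], [2.0, 3.0])
        with pytest.warns(UserWarning):  # < 4 rows in the exclusion step
            table = exclude_outliers(table)
        summary = summarize_by_line(table)
        row = summary.iloc[0]
        assert row["T"] == pytest.approx(15.0)
        assert row["C"] / row["K"] == pytest.approx(12.5)

    def test_single_individual_cell_equals_that_individual(self):
        table = make_fit_table([0.2], [1.0])
        summary = summarize_by_line(table)
        assert summary.iloc[0]["K"] == 0.2
        assert summary.iloc[0]["n"] == 1

    def test_excluded_rows_omitted(self):
        table = make_fit_table([1, 1, 1, 1, 1, 1, 1, 100])
        summary = summarize_by_line(exclude_outliers(table))
        assert summary.iloc[0]["K"] == pytest.approx(1.0)
        assert summary.iloc[0]["n"] == 7

    def test_line_ordering_from_reference_medians(self):
        # full pipeline on a noiseless cohort at the default per-line medians:
        # line R comes out stiffer than line A for cortisol release
        spec = CohortSpec(noise_sigma=0.0, dispersion=0.0, seed=0)
        cohort = generate_cohort(spec)
        pre = preprocess_cohort(list(cohort.series), spec.baseline_scale)
        summary = summarize_by_line(exclude_outliers(fit_cohort(pre)))
        cort = summary[summary["measure"] == "cortisol_release"].set_index("line")
        assert cort.loc["R", "K"] > cort.loc["A", "K"]
        ratio = cort.loc["R", "K"] / cort.loc["A", "K"]
        expected = (
            DEFAULT_LINE_MEDIANS["R"]["cortisol_release"][0]
            / DEFAULT_LINE_MEDIANS["A"]["cortisol_release"][0]
        )
        assert ratio == pytest.approx(expected, rel=0.01)


def contrast_table(rng, delta_sd=0.0, n_per_line=8, sigma=0.3, n_replicates=2):
    """Fit-table draws from the generator's lognormal population model."""
    rows = []
    for line in ("A", "R"):
        for i in range(n_per_line):
            shift = delta_sd * sigma if line == "R" else 0.0
            rows.append({
                "individual_id": f"{line}{i}",
                "measure": "m",
                "line": line,
                "replicate": f"rep{1 + i % n_replicates}",
                "K": float(np.exp(np.log(0.03) + shift + sigma * rng.standard_normal())),
                "C": float(np.exp(np.log(0.5) + sigma * rng.standard_normal())),
                "excluded": False,
            })
    return pd.DataFrame(rows)


class TestLineEffect:
    def test_detects_large_separation(self):
        rng = np.random.default_rng(2)
        res = line_effect_test(contrast_table(rng, delta_sd=4.0), "m", "K")
        assert res.p_value < 0.01
        assert res.estimates["R"] > res.estimates["A"]

    def test_estimates_are_backtransformed_log_means(self):
        table = make_fit_table([0.1, 0.1, 0.4, 0.4], line=["A", "A", "R", "R"],
                               replicate=["rep1"] * 4)
        res = line_effect_test(table, "m", "K")
        assert res.estimates["A"] == pytest.approx(0.1)
        assert res.estimates["R"] == pytest.approx(0.4)

    def test_single_replicate_level_dropped(self):
        rng = np.random.default_rng(3)
        table = contrast_table(rng, n_replicates=1)
        res = line_effect_test(table, "m", "K")
        assert "replicate" not in res.formula

    def test_requires_two_lines(self):
        table = make_fit_table([0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError):
            line_effect_test(table, "m", "K")

    def test_excluded_rows_ignored(self):
        rng = np.random.default_rng(4)
        table = contrast_table(rng)
        table.loc[0, "K"] = 1e6
        table.loc[0, "excluded"] = True
        res = line_effect_test(table, "m", "K")
        assert res.n == len(table) - 1


class TestParameterCorrelations:
    def test_matrix_shape_and_bounds(self):
        spec = CohortSpec(seed=3)
        cohort = generate_cohort(spec)
        pre = preprocess_cohort(list(cohort.series), spec.baseline_scale)
        res = parameter_correlations(fit_cohort(pre))
        assert res.r.shape == (8, 8)
        np.testing.assert_allclose(np.diag(res.r.values), 1.0)
        np.testing.assert_allclose(res.r.values, res.r.values.T)
        assert np.nanmax(np.abs(res.r.values)) <= 1.0 + 1e-12

    def test_correlated_generation_recovered(self):
        spec = CohortSpec(seed=3, measure_corr=0.9)
        cohort = generate_cohort(spec)
        pre = preprocess_cohort(list(cohort.series), spec.baseline_scale)
        res = parameter_correlations(fit_cohort(pre))
        r = res.r.loc["cortisol_release:K", "oxygen_consumption:K"]
        assert 0.7 <= r <= 0.98

    def test_independent_generation_yields_small_correlations(self):
        # entries between distinct measures should mostly sit within the
        # +-2/sqrt(n) null band; pooled over seeded replicates
        inside = total = 0
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            n = 16
            rows = []
            for m in ("m1", "m2", "m3"):
                K = np.exp(0.3 * rng.standard_normal(n))
                C = np.exp(0.3 * rng.standard_normal(n))
                rows += [{"individual_id": f"aq{i}", "measure": m, "line": "A",
                          "replicate": "rep1", "K": K[i], "C": C[i],
                          "excluded": False} for i in range(n)]
            res = parameter_correlations(pd.DataFrame(rows))
            off = res.r.values[np.triu_indices(res.r.shape[0], 1)]
            inside += int(np.sum(np.abs(off) <= 2 / np.sqrt(n)))
            total += off.size
        assert inside / total >= 0.9

    def test_insufficient_pairs_absent(self):
        table = make_fit_table([0.1, 0.2], [1.0, 2.0])
        other = make_fit_table([0.3], [1.5], measure="m2")
        res = parameter_correlations(pd.concat([table, other], ignore_index=True))
        assert np.isnan(res.r.loc["m:K", "m2:K"])

    def test_benjamini_hochberg_option(self):
        spec = CohortSpec(seed=3)
        cohort = generate_cohort(spec)
        pre = preprocess_cohort(list(cohort.series), spec.baseline_scale)
        res = parameter_correlations(fit_cohort(pre), adjust=True)
        iu = np.triu_indices(8, 1)
        raw, adj = res.p.values[iu], res.adjusted_p.values[iu]
        ok = ~np.isnan(raw)
        assert np.all(adj[ok] >= raw[ok] - 1e-12)
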