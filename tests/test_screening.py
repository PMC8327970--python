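"""Confounder screens: DA, antisymmetry, size dependency, outliers, ME scan."""

import numpy as np
import pandas as pd
import pytest

from flucasym.io import build_trait_matrices
from flucasym.screening import (
    AsymmetryScreen,
    EliminationRules,
    ScreeningResult,
    apply_elimination,
    grubbs_outliers,
    replicate_scan,
    screen_trait,
)
from flucasym.simulate import (
    STUDY_ROSTER,
    SyntheticConfig,
    make_study_configs,
    simulate_dataset,
    simulate_study,
    simulate_trait_matrix,
)


class TestGrubbs:
    def test_planted_outlier_flagged(self, rng):
        d = rng.normal(0, 1, 50)
        d[17] = 8.0
        assert 17 in grubbs_outliers(d)

    def test_location_scale_invariance(self, rng):
        d = rng.normal(0, 1, 60)
        d[3] = 6.0
        base = grubbs_outliers(d)
        assert grubbs_outliers(5.0 + d) == base
        assert grubbs_outliers(0.01 * d) == base

    def test_iterative_removal_of_two_outliers(self, rng):
        d = rng.normal(0, 1, 80)
        d[10], d[20] = 9.0, -8.0
        flagged = grubbs_outliers(d)
        assert {10, 20} <= set(flagged)

    def test_constant_vector_no_flags(self):
        assert grubbs_outliers(np.zeros(10)) == ()


class TestScreens:
    def test_clean_normal_trait_is_clean(self, rng):
        sc = AsymmetryScreen().fit(rng.normal(0, 0.05, 200), rng.normal(10, 1, 200))
        assert sc.verdict_ == "clean" and sc.evaluable_

    def test_mean_shift_detected_by_t_rule(self, rng):
        d = rng.normal(2 * 0.05, 0.05, 200)  # delta = 2 sigma
        sc = AsymmetryScreen(da_rule="t").fit(d)
        assert sc.mean_d_p_ < 1e-6 and sc.verdict_ == "DA"

    def test_skewed_differences_flag_da(self, rng):
        d = rng.gamma(2.0, 0.05, 200) - 0.1  # strongly right-skewed
        sc = AsymmetryScreen().fit(d)
        assert sc.skew_p_ < 0.01 and sc.verdict_ == "DA"

    def test_antisymmetric_mixture_flags_as(self, rng):
        sigma = 0.04
        d = rng.choice([-1, 1], 200) * 3 * sigma + rng.normal(0, sigma, 200)
        sc = AsymmetryScreen().fit(d)
        assert sc.excess_kurtosis_ < 0
        assert sc.kurtosis_p_ < 0.01 and sc.verdict_ == "AS"

    def test_size_dependency_flagged(self, rng):
        # FA scale grows gently with size: strong rank correlation of |d|
        # with s without the heavy tails that would trip the moment screens
        s = rng.normal(10, 1, 1000)
        d = rng.normal(0, 1, 1000) * 0.05 * (s / 10) ** 2
        sc = AsymmetryScreen().fit(d, s)
        assert sc.size_p_ < 0.01 and sc.verdict_ == "size_dependent"

    def test_platykurtosis_test_survives_transform_branch_flip(self, rng):
        # well-separated bimodal data drive the Anscombe-Glynn cube-root
        # transform onto the wrong branch; the one-sided p must stay small
        from flucasym.screening import platykurtosis_test

        d = rng.choice([-1.0, 1.0], 200) * 0.12 + rng.normal(0, 0.04, 200)
        z, p = platykurtosis_test(d)
        assert z < 0 and p < 1e-6

    def test_small_j_not_evaluable_clean_with_warning(self, rng, caplog):
        with caplog.at_level("WARNING"):
            sc = AsymmetryScreen().fit(rng.normal(0, 1, 5))
        assert not sc.evaluable_ and sc.verdict_ == "clean"
        assert np.isnan(sc.skew_p_)

    def test_constant_d_not_evaluable(self, caplog):
        with caplog.at_level("WARNING"):
            sc = AsymmetryScreen().fit(np.full(20, 0.3))
        assert not sc.evaluable_ and sc.verdict_ == "clean"

    def test_bad_params_rejected(self, rng):
        with pytest.raises(ValueError):
            AsymmetryScreen(da_rule="nope").fit(rng.normal(0, 1, 20))
        with pytest.raises(ValueError):
            AsymmetryScreen(alpha=0).fit(rng.normal(0, 1, 20))

    def test_screen_trait_on_matrix(self):
        cfg = SyntheticConfig(n_individuals=50, n_replicates=3, seed=2)
        res = screen_trait(simulate_trait_matrix(cfg))
        assert isinstance(res, ScreeningResult)
        assert res.n == 50 and 0 <= res.skew_p <= 1


def _fake_result(key, **p):
    base = dict(
        trait_key=key, n=30, skewness=0.0, skew_p=0.5, excess_kurtosis=0.0,
        kurtosis_p=0.5, mean_d=0.0, mean_d_t=0.0, mean_d_p=0.5,
        size_dependency_rho=0.0, size_dependency_p=0.5, outlier_indices=(),
        verdict="clean", evaluable=True,
    )
    base.update(p)
    return ScreeningResult(**base)


class TestElimination:
    def test_no_flags_retains_everything(self):
        results = {k: _fake_result(k) for k in STUDY_ROSTER}
        retained, ledger = apply_elimination(results)
        assert len(retained) == 36 and ledger.empty

    def test_reproduces_reference_elimination_pattern(self):
        # DA in both sexes' mandibular M1/M2 lengths, size dependency in the
        # male maxillary P3 length -> 31 retained, split 9/7/9/6
        da_keys = {
            ("female", "MNM1", "length"), ("female", "MNM2", "length"),
            ("male", "MNM1", "length"), ("male", "MNM2", "length"),
        }
        size_key = ("male", "MXP3", "length")
        results = {}
        for k in STUDY_ROSTER:
            if k in da_keys:
                results[k] = _fake_result(k, skewness=2.0, skew_p=1e-9, verdict="DA")
            elif k == size_key:
                results[k] = _fake_result(
                    k, size_dependency_rho=0.8, size_dependency_p=1e-9,
                    verdict="size_dependent",
                )
            else:
                results[k] = _fake_result(k)
        retained, ledger = apply_elimination(results)
        assert len(ledger) == 5
        assert sorted(ledger["reason"]) == ["DA"] * 4 + ["size_dependent"]
        counts = pd.Series(
            [(sex, metric) for sex, _, metric in retained]
        ).value_counts()
        assert counts[("female", "breadth")] == 9
        assert counts[("female", "length")] == 7
        assert counts[("male", "breadth")] == 9
        assert counts[("male", "length")] == 6

    def test_everything_flagged_warns_and_empties(self, caplog):
        results = {k: _fake_result(k, skew_p=1e-12) for k in STUDY_ROSTER[:3]}
        with caplog.at_level("WARNING"):
            retained, ledger = apply_elimination(results)
        assert retained == [] and len(ledger) == 3

    def test_t_rule_catches_pure_mean_shift(self):
        r = _fake_result(("f", "MXM1", "length"), mean_d_p=1e-9, mean_d_t=9.0)
        retained, ledger = apply_elimination([r], EliminationRules(da_rule="t"))
        assert retained == [] and ledger["reason"].iloc[0] == "DA"


class TestReplicateScan:
    def test_zero_me_all_summaries_zero(self):
        cfgs = make_study_configs(
            SyntheticConfig(n_individuals=10, n_replicates=10, sigma_me=0.0),
            roster=STUDY_ROSTER[:4],
        )
        records = simulate_study(cfgs, seed=3)
        table = replicate_scan(records, ["1-10", "2-5"])
        np.testing.assert_allclose(
            table[["me3_pooled", "mean", "median", "minimum", "maximum"]], 0.0, atol=1e-9
        )

    def test_homogeneous_me_similar_across_equal_size_subsets(self):
        cfgs = make_study_configs(
            SyntheticConfig(n_individuals=60, n_replicates=10,
                            sigma_fa=0.04, sigma_me=0.02),
            roster=STUDY_ROSTER[:8],
        )
        records = simulate_study(cfgs, seed=4)
        table = replicate_scan(records, ["1-4", "4-7", "7-10"]).set_index("subset")
        means = table["mean"]
        assert means.max() - means.min() < 12.0  # percentage points, MC error

    def test_planted_late_trial_noise_raises_late_subset_me(self):
        noisy_tail = tuple([0.02] * 8 + [0.08, 0.08])  # trials 9-10: 4x ME SD
        cfgs = make_study_configs(
            SyntheticConfig(n_individuals=60, n_replicates=10,
                            sigma_fa=0.04, sigma_me=noisy_tail),
            roster=STUDY_ROSTER[:6],
        )
        records = simulate_study(cfgs, seed=5)
        table = replicate_scan(records, ["9-10", "1-8", "3-8"]).set_index("subset")
        assert table.loc["9-10", "mean"] > table.loc["1-8", "mean"]
        assert table.loc["9-10", "mean"] > table.loc["3-8", "mean"]

    def test_min_median_max_ordering_and_range(self):
        cfgs = make_study_configs(
            SyntheticConfig(n_individuals=30, n_replicates=6), roster=STUDY_ROSTER[:6]
        )
        table = replicate_scan(simulate_study(cfgs, seed=6), ["1-6", "2-4"])
        assert (table["minimum"] <= table["median"]).all()
        assert (table["median"] <= table["maximum"]).all()
        np.testing.assert_allclose(table["range"], table["maximum"] - table["minimum"])

    def test_unavailable_subset_named_in_error(self, simulated_trait_records):
        with pytest.raises(ValueError, match="11-12"):
            replicate_scan(simulated_trait_records, ["11-12"])
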