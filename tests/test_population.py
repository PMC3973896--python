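"""Gating, mixtures, peak counting, bands and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.mixture import GaussianMixture

from cytomech import params, population
from cytomech.simulate import (FlowSpec, PopulationSpec,
                               generate_cm_population, generate_flow_events)


class TestGates:
    def test_constant_control_threshold_at_value(self):
        control = pd.DataFrame({"log_sca1": np.ones(100), "log_cd44": np.ones(100)})
        gates = population.derive_gates_from_control(control)
        assert gates.sca1_threshold == pytest.approx(1.0)

    def test_quantile_matches_order_statistic_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 5001)
        control = pd.DataFrame({"log_sca1": x, "log_cd44": x})
        gates = population.derive_gates_from_control(control, percentile=99.5)
        assert gates.sca1_threshold == pytest.approx(
            float(np.percentile(x, 99.5)), rel=1e-12)

    def test_empty_control_raises(self):
        with pytest.raises(ValueError, match="empty"):
            population.derive_gates_from_control(
                pd.DataFrame({"log_sca1": [], "log_cd44": []}))


class TestQuadrantGate:
    def test_all_double_negative(self):
        events = pd.DataFrame({"log_sca1": [-1.0] * 5, "log_cd44": [-2.0] * 5})
        res = population.quadrant_gate(events, population.GateSpec(0.0, 0.0))
        assert res.fractions["--"] == 1.0

    def test_tie_counts_as_negative(self):
        events = pd.DataFrame({"log_sca1": [0.0], "log_cd44": [1.0]})
        res = population.quadrant_gate(events, population.GateSpec(0.0, 0.0))
        assert res.counts["-+"] == 1

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_gating_is_a_partition(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 200))
        events = pd.DataFrame({"log_sca1": rng.normal(0, 2, n),
                               "log_cd44": rng.normal(0, 2, n)})
        res = population.quadrant_gate(events, population.GateSpec(0.0, 0.0))
        assert sum(res.counts.values()) == n
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("group", ["Non-Rec", "Rec"])
    def test_generator_proportions_recovered_within_two_points(self, group):
        spec = FlowSpec.from_group(group, n_events=10_000, seed=11)
        events = generate_flow_events(spec)
        res = population.quadrant_gate(events, population.GateSpec(0.0, 0.0))
        for quad, target in params.QUADRANT_PROPORTIONS[group].items():
            assert res.fractions[quad] == pytest.approx(target, abs=0.02)

    def test_single_quadrant_generator(self):
        spec = FlowSpec(proportions={"++": 1.0, "+-": 0.0, "-+": 0.0, "--": 0.0},
                        n_events=500, seed=0)
        events = generate_flow_events(spec)
        assert (events.truth_quadrant == "++").all()


class TestMixture:
    def test_single_tight_gaussian_selects_k1(self):
        x = np.random.default_rng(0).normal(500.0, 5.0, 300)
        fit = population.fit_mixture(x, seed=0)
        assert fit.k == 1
        assert population.count_peaks(fit).count == 1

    def test_three_separated_components_found_in_most_seeds(self):
        """Means 200/500/800 at sd 20: BIC should pick k=3 nearly always."""
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(200, 20, 100),
                                rng.normal(500, 20, 100),
                                rng.normal(800, 20, 100)])
            fit = population.fit_mixture(x, seed=seed)
            hits += fit.k == 3
        assert hits >= 0.9 * n_seeds

    def test_duplicated_points_handled_by_variance_floor(self):
        x = np.concatenate([np.full(50, 100.0), np.full(50, 100.0001),
                            np.random.default_rng(1).normal(500, 30, 100)])
        fit = population.fit_mixture(x, seed=0)
        assert np.all(fit.sds > 0)

    def test_fewer_than_ten_values_raises(self):
        with pytest.raises(ValueError, match="at least 10"):
            population.fit_mixture(np.arange(9.0), seed=0)

    def test_selected_k_bounded_by_distinct_values(self):
        x = np.repeat([1.0, 2.0, 3.0], 20)
        fit = population.fit_mixture(x, seed=0)
        assert fit.k <= 3

    def test_em_log_likelihood_is_nondecreasing(self):
        """Stepping EM one iteration at a time never lowers the bound."""
        x = np.random.default_rng(3).normal([200, 600], [20, 40],
                                            size=(150, 2)).ravel().reshape(-1, 1)
        gm = GaussianMixture(n_components=2, max_iter=1, warm_start=True,
                             random_state=0, tol=0.0, reg_covar=1e-6)
        bounds = []
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(25):
                gm.fit(x)
                bounds.append(gm.lower_bound_)
        assert np.all(np.diff(bounds) >= -1e-9)


class TestPeakCounting:
    def _fit(self, weights, means, sds, lo=0.0, hi=1200.0):
        return population.MixtureFit(
            property_name="CS", k=len(means),
            weights=np.asarray(weights, float) / np.sum(weights),
            means=np.asarray(means, float), sds=np.asarray(sds, float),
            bic={}, log_likelihood=0.0, data_min=lo, data_max=hi, n=100)

    def test_identical_means_merge_to_one_peak(self):
        fit = self._fit([0.5, 0.5], [500.0, 500.0], [20.0, 40.0])
        assert population.count_peaks(fit).count == 1

    def test_nearby_maxima_merged_by_tolerance(self):
        fit = self._fit([0.5, 0.5], [500.0, 515.0], [6.0, 6.0])
        assert population.count_peaks(fit, merge_tol=25.0).count == 1

    def test_rec_cs_analytic_density_has_four_peaks(self):
        """The four-component recurrence-group CS density (subgroup
        means/spreads, quadrant-proportion weights) has exactly four
        modes on a 1-Pa grid."""
        order = ("++", "+-", "-+", "--")
        fit = self._fit(
            [params.QUADRANT_PROPORTIONS["Rec"][q] for q in order],
            [params.SUBGROUP_CM["Rec"][q]["CS"][0] for q in order],
            [params.SUBGROUP_CM["Rec"][q]["CS"][1] for q in order])
        peaks = population.count_peaks(fit, grid_step=1.0, merge_tol=25.0)
        assert peaks.count == 4
        np.testing.assert_allclose(
            sorted(peaks.locations), [264.3, 397.4, 485.3, 641.3], atol=2.0)

    def test_peak_count_never_exceeds_components(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            k = int(rng.integers(1, 5))
            fit = self._fit(rng.uniform(0.1, 1, k), rng.uniform(100, 900, k),
                            rng.uniform(10, 120, k))
            assert population.count_peaks(fit).count <= k


class TestBandFraction:
    def test_trivial_cases(self):
        assert population.band_fraction([], (500, 800)) == 0.0
        assert population.band_fraction([600, 700], (500, 800)) == 1.0

    def test_uniform_values_match_band_width(self):
        x = np.random.default_rng(0).uniform(0, 1000, 20_000)
        frac = population.band_fraction(x, (500, 800))
        assert frac == pytest.approx(0.30, abs=0.02)

    def test_monotone_in_band_width(self):
        x = np.random.default_rng(1).normal(600, 150, 2000)
        f1 = population.band_fraction(x, (550, 650))
        f2 = population.band_fraction(x, (500, 800))
        f3 = population.band_fraction(x, (400, 900))
        assert f1 <= f2 <= f3

    def test_endpoints_inclusive(self):
        assert population.band_fraction([500.0, 800.0], (500, 800)) == 1.0


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        base = np.random.default_rng(0).normal(500, 30, 40)
        table = pd.DataFrame({
            "group": ["a"] * 40 + ["b"] * 40,
            "cs_pa": np.concatenate([base, base]),
        })
        res = population.compare_groups(table, "cs_pa")
        assert res.anova_f == pytest.approx(0.0, abs=1e-9)
        assert res.anova_p == pytest.approx(1.0, abs=1e-6)
        assert not res.significant

    def test_printed_group_parameters_always_separate(self):
        """Group means 428.7 vs 539.1 with the printed spreads and N are
        separated by ANOVA in essentially every draw."""
        hits, n_seeds = 0, 40
        (m1, s1, n1) = params.GROUP_CM["Non-Rec"]["CS"]
        (m2, s2, n2) = params.GROUP_CM["Rec"]["CS"]
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame({
                "group": ["Non-Rec"] * n1 + ["Rec"] * n2,
                "cs_pa": np.concatenate([rng.normal(m1, s1, n1),
                                         rng.normal(m2, s2, n2)]),
            })
            hits += population.compare_groups(table, "cs_pa").significant
        assert hits >= 0.95 * n_seeds

    def test_anova_p_close_to_permutation_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.8, 1.0, 10)
        table = pd.DataFrame({"group": ["a"] * 10 + ["b"] * 10,
                              "cs_pa": np.concatenate([a, b])})
        res = population.compare_groups(table, "cs_pa")
        # permutation distribution of the F statistic
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            pa, pb = pooled[:10], pooled[10:]
            f = _f_stat(pa, pb)
            count += f >= _f_stat(a, b)
        p_perm = count / n_perm
        assert res.anova_p == pytest.approx(p_perm, abs=0.05)

    def test_tukey_table_lists_all_pairs(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({
            "group": ["a"] * 20 + ["b"] * 20 + ["c"] * 20,
            "cs_pa": rng.normal([400, 500, 600], 30, (20, 3)).T.ravel(),
        })
        res = population.compare_groups(table, "cs_pa")
        assert len(res.tukey) == 3


def _f_stat(a, b):
    na, nb = len(a), len(b)
    grand = np.concatenate([a, b]).mean()
    ssb = na * (a.mean() - grand) ** 2 + nb * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    return (ssb / 1) / (ssw / (na + nb - 2))


class TestPopulationGenerator:
    def test_zero_sd_single_subgroup_is_constant(self):
        spec = PopulationSpec(group="g", n=20, seed=0,
                              proportions={"++": 1.0},
                              components={"++": {"CS": (500.0, 0.0),
                                                 "TS": (600.0, 0.0),
                                                 "AF": (30.0, 0.0)}})
        pop = generate_cm_population(spec)
        assert (pop.cs_pa == 500.0).all()

    def test_default_rec_components_match_study_table(self):
        spec = PopulationSpec.from_group("Rec", seed=0)
        means = sorted(spec.components[q]["CS"][0] for q in spec.components)
        assert means == sorted([641.3, 397.4, 264.3, 485.3])

    def test_component_means_recovered_at_large_n(self):
        """Sample mean of each subgroup within 3 standard errors."""
        spec = PopulationSpec.from_group("Rec", n=10_000, seed=4)
        pop = generate_cm_population(spec)
        for sub, grp in pop.groupby("truth_subgroup"):
            mean, sd = spec.components[sub]["TS"]
            if sd == 0 or len(grp) < 30 or mean < 3 * sd:
                continue  # truncation shifts heavy-left components
            se = sd / np.sqrt(len(grp))
            assert abs(grp.ts_pa.mean() - mean) <= 3 * se

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(group="g", n=10, seed=0, proportions={"++": 1.0},
                           components={"++": {"CS": (500.0, -1.0)}})

    def test_same_seed_reproducible(self):
        spec = PopulationSpec.from_group("Non-Rec", seed=9)
        assert generate_cm_population(spec).equals(generate_cm_population(spec))
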