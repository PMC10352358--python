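"""Cohort statistics: group comparisons, correlations, full analysis."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from fliopipe.simulate import default_population, generate_cohort, generate_regional_cohort
from fliopipe.stats import (
    StatsConfig,
    chi_square_independence,
    cohen_label,
    compare_three_groups,
    compare_two_groups,
    correlate,
    run_full_analysis,
    significance_stars,
    split_by_pack_year_median,
)


def _smoker(pid, pack_year):
    from fliopipe.simulate import Subject
    return Subject(id=pid, group="smoker", age=30, sex="M", bmi=25, iop_od=15,
                   iop_os=15, pack_year=pack_year, years_smoked=10)


def _nonsmoker(pid):
    from fliopipe.simulate import Subject
    return Subject(id=pid, group="non_smoker", age=27, sex="F", bmi=22,
                   iop_od=14, iop_os=14, pack_year=0, years_smoked=0)


class TestMedianSplit:
    def test_even_count_split(self):
        subs = [_smoker(f"s{i}", py) for i, py in enumerate([2, 4, 8, 10])]
        a = split_by_pack_year_median(subs)
        assert a.split_value == 6.0
        assert [a.of(s.id) for s in subs] == ["G1", "G1", "G2", "G2"]

    def test_at_median_goes_to_heavy_group(self):
        subs = [_smoker(f"s{i}", py) for i, py in enumerate([2, 6, 6, 10])]
        a = split_by_pack_year_median(subs)
        assert a.split_value == 6.0
        assert a.of("s1") == "G2" and a.of("s2") == "G2"

    def test_default_cohort_halves_equally(self, population):
        subs = generate_cohort(population, seed=21)
        a = split_by_pack_year_median(subs)
        arms = pd.Series([a.of(s.id) for s in subs]).value_counts()
        assert arms["G0"] == 26 and arms["G1"] == 14 and arms["G2"] == 14
        assert arms.sum() == 54  # partition

    def test_no_smokers_rejected(self):
        with pytest.raises(ValueError):
            split_by_pack_year_median([_nonsmoker("n1"), _nonsmoker("n2")])


class TestTwoGroups:
    def test_identical_groups(self):
        v = [1.0, 2.0, 3.0, 4.0]
        t, p = compare_two_groups(v, v)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_option(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 5, 20)
        _, p_pooled = compare_two_groups(a, b, flavor="pooled")
        _, p_welch = compare_two_groups(a, b, flavor="welch")
        assert p_pooled != p_welch

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            compare_two_groups([1.0], [2.0, 3.0])

    def test_nominal_routes_to_chi_square(self):
        stat, p = compare_two_groups([13, 13], [15, 13], scale="nominal")
        assert p == pytest.approx(0.793, abs=5e-4)

    def test_type_one_error_calibration(self):
        """Under the null, rejection at alpha = 0.05 happens for ~5% of
        replicates (within binomial 99% bounds), and p-values are uniform."""
        rng = np.random.default_rng(2024)
        n_rep = 1000
        ps = np.empty(n_rep)
        for i in range(n_rep):
            ps[i] = compare_two_groups(rng.normal(size=26), rng.normal(size=28))[1]
        rate = (ps < 0.05).mean()
        lo, hi = scipy.stats.binom.ppf([0.005, 0.995], n_rep, 0.05) / n_rep
        assert lo <= rate <= hi
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01


class TestChiSquare:
    def test_published_gender_table(self):
        stat, p = chi_square_independence([[13, 13], [15, 13]])
        assert p == pytest.approx(0.793, abs=5e-4)
        # Hand computation from expected counts gives ~0.0689.
        assert stat == pytest.approx(0.0689, abs=5e-4)

    def test_perfect_independence(self):
        stat, p = chi_square_independence([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_transpose_and_swap_invariance(self):
        t = np.array([[13, 13], [15, 13]])
        base = chi_square_independence(t)
        assert chi_square_independence(t.T) == pytest.approx(base)
        assert chi_square_independence(t[::-1, ::-1]) == pytest.approx(base)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [5, 3]])


class TestThreeGroups:
    def test_identical_groups(self):
        g = {k: np.array([1.0, 2.0, 3.0]) for k in ("G0", "G1", "G2")}
        res = compare_three_groups(g)
        assert res["omnibus_stat"] == pytest.approx(0.0)
        assert res["omnibus_p"] == pytest.approx(1.0)

    def test_shifted_group_detected(self, rng):
        # G2 shifted by +3 SD at n = 14 per group: both G2 contrasts clear
        # significance comfortably (power simulation rationale).
        g = {"G0": rng.normal(0, 1, 14), "G1": rng.normal(0, 1, 14),
             "G2": rng.normal(3, 1, 14)}
        res = compare_three_groups(g)
        assert res["pairwise"][("G0", "G2")] < 0.05
        assert res["pairwise"][("G1", "G2")] < 0.05

    def test_tukey_at_least_as_conservative_as_t(self, rng):
        g = {"G0": rng.normal(0, 1, 14), "G1": rng.normal(0.5, 1, 14),
             "G2": rng.normal(1, 1, 14)}
        tukey = compare_three_groups(g, posthoc="tukey")["pairwise"]
        for pair, p_tukey in tukey.items():
            _, p_t = compare_two_groups(g[pair[0]], g[pair[1]])
            # small slack: the studentized-range p is table-interpolated
            assert p_tukey >= p_t - 1e-3

    def test_nonparametric_route(self, rng):
        g = {"G0": rng.exponential(1, 14), "G1": rng.exponential(1, 14),
             "G2": rng.exponential(3, 14)}
        res = compare_three_groups(g, parametric=False)
        assert set(res["pairwise"]) == {("G0", "G1"), ("G0", "G2"), ("G1", "G2")}
        assert res["pairwise"][("G0", "G2")] < 0.05

    def test_dunn_matches_kruskal_for_two_of_three(self, rng):
        """Sanity: Dunn pairwise z-test p for a pair behaves like the
        two-sample Kruskal-Wallis (Wilcoxon) p in magnitude ordering."""
        g = {"G0": rng.normal(0, 1, 20), "G1": rng.normal(0, 1, 20),
             "G2": rng.normal(2, 1, 20)}
        res = compare_three_groups(g, parametric=False)
        assert res["pairwise"][("G0", "G2")] < res["pairwise"][("G0", "G1")]

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_three_groups({"G0": np.ones(3), "G1": np.ones(3)})


class TestCorrelate:
    def test_perfect_correlation(self):
        r, p, label = correlate([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert label == "large"

    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.05, "negligible"), (0.0999, "negligible"),
            (0.1, "small"), (0.2999, "small"),
            (0.3, "medium"), (0.334, "medium"), (0.4999, "medium"),
            (0.5, "large"), (0.9, "large"),
            (-0.334, "medium"), (-0.05, "negligible"), (-0.7, "large"),
        ],
    )
    def test_cohen_bands_left_closed(self, r, expected):
        assert cohen_label(r) == expected

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        n_rep = 1000
        ps = np.array([correlate(rng.normal(size=54), rng.normal(size=54))[1]
                       for _ in range(n_rep)])
        rate = (ps < 0.05).mean()
        lo, hi = scipy.stats.binom.ppf([0.005, 0.995], n_rep, 0.05) / n_rep
        assert lo <= rate <= hi


class TestSignificanceStars:
    @pytest.mark.parametrize("p,stars", [(0.2, ""), (0.049, "*"), (0.009, "**"),
                                         (0.0009, "***"), (np.nan, "")])
    def test_legend_convention(self, p, stars):
        assert significance_stars(p) == stars


@pytest.fixture(scope="module")
def cohort(population):
    subs = generate_cohort(population, seed=31)
    regional = generate_regional_cohort(population, subs, seed=32)
    return subs, regional


class TestRunFullAnalysis:
    def test_tables_complete(self, cohort):
        subs, regional = cohort
        tables = run_full_analysis(regional, subs)
        # 2 channels x 11 regions x 3 parameters rows in the lifetime table.
        assert len(tables.flt) == 66
        assert set(tables.flt.columns) >= {"p_two_group", "omnibus_p", "p_G0_vs_G2"}
        assert tables.flt.p_two_group.between(0, 1).all()
        assert len(tables.inter_eye) == 18
        assert tables.inter_eye.r.between(-1, 1).all()
        assert (tables.covariates_two_group.covariate == "sex_male").any()

    def test_high_inter_eye_correlation_reported(self, cohort):
        subs, regional = cohort
        tables = run_full_analysis(regional, subs)
        assert (tables.inter_eye.r > 0.8).all()  # generator rho = 0.9

    def test_duplicated_eyes_give_unit_correlation(self, cohort):
        subs, regional = cohort
        od = regional[regional.eye == "OD"]
        dup = pd.concat([od, od.assign(eye="OS")], ignore_index=True)
        tables = run_full_analysis(dup, subs)
        assert len(tables.inter_eye) == 18
        assert tables.inter_eye.r.values == pytest.approx(np.ones(18))
        assert tables.inter_eye.paired_p.values == pytest.approx(np.ones(18))

    def test_null_generator_calibrated(self):
        """With group effects disabled, ~5% of the 22 regional two-group
        tau_m tests come out significant; over many seeds the overall rate
        stays near alpha."""
        pop = default_population(group_effects=False)
        rates = []
        for seed in range(12):
            subs = generate_cohort(pop, seed=seed)
            regional = generate_regional_cohort(pop, subs, seed=1000 + seed)
            tables = run_full_analysis(regional, subs,
                                       StatsConfig(normality_routing=False))
            tm = tables.flt[tables.flt.parameter == "tau_m"]
            rates.append((tm.p_two_group < 0.05).mean())
        overall = np.mean(rates)
        # 12 x 22 partially-correlated tests; generous binomial-style band.
        assert 0.01 <= overall <= 0.11

    def test_published_effect_usually_detected(self, population):
        """With the published SSC inner-ring means (210 vs 220 ps, SDs ~18/15,
        n = 26/28) the smoker difference is positive in nearly every cohort
        and flagged significant in a clear majority (the design's power at
        d ~ 0.6 is ~0.6)."""
        n_pos, n_sig = 0, 0
        for seed in range(12):
            subs = generate_cohort(population, seed=seed)
            regional = generate_regional_cohort(population, subs, seed=2000 + seed)
            tables = run_full_analysis(regional, subs)
            row = tables.flt[(tables.flt.channel == "SSC") & (tables.flt.region == "IR")
                             & (tables.flt.parameter == "tau_m")].iloc[0]
            n_pos += row.smoker_mean > row.nonsmoker_mean
            n_sig += row.p_two_group < 0.05
        assert n_pos >= 10
        assert n_sig >= 4

    def test_fdr_switch_adds_column(self, cohort):
        subs, regional = cohort
        tables = run_full_analysis(regional, subs, StatsConfig(fdr=True))
        assert "p_two_group_fdr" in tables.flt.columns
        assert (tables.flt.p_two_group_fdr >= tables.flt.p_two_group - 1e-12).all()

    def test_missing_cells_skipped_with_note(self, cohort):
        subs, regional = cohort
        broken = regional[~((regional.subject == subs[0].id)
                            & (regional.channel == "SSC")
                            & (regional.region == "C")
                            & (regional.parameter == "tau_m")
                            & (regional.eye == "OD"))]
        tables = run_full_analysis(broken, subs)
        assert len(tables.flt) == 65
        assert any("SSC/C/tau_m" in n for n in tables.notes)
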