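"""Variance partitioning, shrinkage estimates, summaries, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swpergeo import mlm, postest, synth
from swpergeo.errors import InsufficientDataError, LineageError, UndefinedVpcError


def estimates_frame(prevalences, districts=None, states=None, n_women=None):
    n = len(prevalences)
    return pd.DataFrame(
        {
            "community_id": [f"C{i:03d}" for i in range(n)],
            "district_id": districts if districts is not None else ["D0"] * n,
            "state_id": states if states is not None else ["S0"] * n,
            "n_women": n_women if n_women is not None else [10] * n,
            "raw_prev_pct": prevalences,
            "prevalence_pct": prevalences,
        }
    )


class TestVpc:
    @pytest.mark.parametrize(
        "triple, expected",
        [
            # published four-level variance components and their shares
            ((0.86, 0.23, 0.97), (41.7, 11.2, 47.1)),
            ((0.57, 0.15, 0.27), (57.6, 15.2, 27.3)),
            ((0.15, 0.13, 0.64), (16.3, 14.1, 69.6)),
        ],
    )
    def test_geographic_mode_matches_hand_arithmetic(self, triple, expected):
        vpc = postest.compute_vpc(triple)
        assert round(vpc.state, 1) == expected[0]
        assert round(vpc.district, 1) == expected[1]
        assert round(vpc.community, 1) == expected[2]

    def test_symmetric_and_degenerate_triples(self):
        vpc = postest.compute_vpc((1.0, 1.0, 1.0))
        assert vpc.state == pytest.approx(100 / 3)
        vpc = postest.compute_vpc((0.0, 0.0, 5.0))
        assert (vpc.state, vpc.district, vpc.community) == (0.0, 0.0, 100.0)

    def test_all_zero_geographic_mode_undefined(self):
        with pytest.raises(UndefinedVpcError):
            postest.compute_vpc((0.0, 0.0, 0.0))

    def test_latent_mode_adds_logistic_level1_variance(self):
        vpc = postest.compute_vpc((1.0, 1.0, 1.0), mode="latent")
        expected = 100.0 / (3.0 + np.pi**2 / 3.0)
        assert vpc.state == pytest.approx(expected)
        assert vpc.state + vpc.district + vpc.community < 100.0

    @settings(max_examples=200, deadline=None)
    @given(
        st.tuples(
            st.floats(0, 1e3, allow_nan=False),
            st.floats(0, 1e3, allow_nan=False),
            st.floats(1e-12, 1e3, allow_nan=False),
        )
    )
    def test_geographic_partition_sums_to_100(self, triple):
        vpc = postest.compute_vpc(triple)
        assert vpc.state + vpc.district + vpc.community == pytest.approx(100.0, abs=1e-9)


class TestPrecisionWeighted:
    def test_zero_residuals_give_fifty_percent(self, small_survey):
        idx = mlm.build_index(small_survey.records)
        fit = mlm.run_mcmc(
            small_survey.records, idx, mlm.MCMCSettings(burnin=50, monitor=200, seed=1)
        )
        fit.beta0.mean = 0.0
        for level in fit.residuals:
            fit.residuals[level]["post_mean"] = 0.0
        est = postest.precision_weighted_prevalence(fit, idx, small_survey.records)
        assert (est["prevalence_pct"] == 50.0).all()
        assert len(est) == idx.n_communities

    def test_small_community_shrinks_harder_eb_oracle(self):
        # conjugate check on the linearised scale: two communities with the
        # same raw prevalence far from the mean; the 1-woman community must
        # land closer to the grand mean than the 200-woman community
        sizes = [1, 200] + [50] * 30
        rng = np.random.default_rng(0)
        rows = []
        wid = 0
        for j, n in enumerate(sizes):
            p = 1.0 if j < 2 else 0.2  # extreme outliers vs background
            for _ in range(n):
                rows.append(
                    {
                        "state_id": "S1",
                        "district_id": "D1",
                        "community_id": f"C{j:03d}",
                        "woman_id": f"W{wid}",
                        "y": int(rng.random() < p),
                    }
                )
                wid += 1
        rec = pd.DataFrame(rows)
        rec.loc[rec["community_id"] == "C000", "y"] = 1
        rec.loc[rec["community_id"] == "C001", "y"] = 1
        idx = mlm.build_index(rec)
        est = postest.precision_weighted_prevalence(
            None, idx, rec, method="eb_linear"
        ).set_index("community_id")
        grand = est["prevalence_pct"].mean()
        small = est.loc["C000", "prevalence_pct"]
        large = est.loc["C001", "prevalence_pct"]
        assert est.loc["C000", "raw_prev_pct"] == est.loc["C001", "raw_prev_pct"] == 100.0
        assert abs(small - grand) < abs(large - grand)

    def test_lineage_mismatch_raises(self, small_survey):
        idx = mlm.build_index(small_survey.records)
        fit = mlm.run_mcmc(
            small_survey.records, idx, mlm.MCMCSettings(burnin=50, monitor=200, seed=1)
        )
        fit.residuals["community"] = fit.residuals["community"].iloc[:-1]
        with pytest.raises(LineageError):
            postest.precision_weighted_prevalence(fit, idx, small_survey.records)

    def test_posterior_and_eb_modes_agree_roughly(self, small_survey):
        idx = mlm.build_index(small_survey.records)
        fit = mlm.run_mcmc(
            small_survey.records, idx, mlm.MCMCSettings(burnin=500, monitor=2000, seed=2)
        )
        a = postest.precision_weighted_prevalence(fit, idx, small_survey.records)
        b = postest.precision_weighted_prevalence(
            fit, idx, small_survey.records, method="eb_linear"
        )
        r = np.corrcoef(a["prevalence_pct"], b["prevalence_pct"])[0, 1]
        assert r > 0.9


class TestAreaSummaries:
    def test_hand_computable_three_community_area(self):
        est = estimates_frame([10.0, 20.0, 30.0])
        out = postest.summarise_areas(est, "district")
        assert out["mean_prev_pct"].iloc[0] == 20.0
        assert out["sd_prev_pct"].iloc[0] == pytest.approx(10.0)  # sample SD
        assert out["min_prev_pct"].iloc[0] == 10.0
        assert out["max_prev_pct"].iloc[0] == 30.0

    def test_single_community_area_zero_sd(self):
        out = postest.summarise_areas(estimates_frame([42.0]), "state")
        assert out["sd_prev_pct"].iloc[0] == 0.0
        assert out["mean_prev_pct"].iloc[0] == out["min_prev_pct"].iloc[0] == 42.0

    def test_planted_extremes_recovered(self):
        # a state planted with the published extreme community range
        vals = [28.2, 50.0, 60.0, 91.8]
        out = postest.summarise_areas(estimates_frame(vals), "state")
        assert out["min_prev_pct"].iloc[0] == 28.2
        assert out["max_prev_pct"].iloc[0] == 91.8


class TestDispersionCorrelation:
    @staticmethod
    def summaries(means, sds, n_comm=5):
        return pd.DataFrame(
            {
                "district_id": [f"D{i}" for i in range(len(means))],
                "mean_prev_pct": means,
                "sd_prev_pct": sds,
                "n_communities": n_comm,
            }
        )

    def test_perfect_linear_relation(self):
        out = postest.district_dispersion_correlation(
            self.summaries([10, 20, 30, 40], [1, 2, 3, 4])
        )
        assert out["r"] == pytest.approx(1.0)

    def test_constant_sd_flagged(self):
        out = postest.district_dispersion_correlation(
            self.summaries([10, 20, 30], [5, 5, 5])
        )
        assert out["flag"] == "zero-variance"
        assert out["r"] is None

    def test_textbook_formula_oracle(self):
        rng = np.random.default_rng(3)
        means = rng.uniform(10, 90, 40)
        sds = 0.3 * means + rng.normal(0, 5, 40)
        out = postest.district_dispersion_correlation(self.summaries(means, sds))
        mx, my = means.mean(), sds.mean()
        r_direct = np.sum((means - mx) * (sds - my)) / np.sqrt(
            np.sum((means - mx) ** 2) * np.sum((sds - my) ** 2)
        )
        assert out["r"] == pytest.approx(r_direct, abs=0.05)

    def test_single_community_districts_excluded_and_counted(self):
        s = self.summaries([10, 20, 30, 40], [1, 2, 3, 4])
        s.loc[0, "n_communities"] = 1
        out = postest.district_dispersion_correlation(s)
        assert out["n_districts"] == 3
        assert out["n_excluded"] == 1

    def test_insufficient_districts(self):
        with pytest.raises(InsufficientDataError):
            postest.district_dispersion_correlation(self.summaries([1, 2], [1, 2]))


class TestClassification:
    def test_boundary_community_flagged(self):
        est = estimates_frame([20.0, 20.0, 20.0])
        out = postest.classify_under_empowered(est)
        assert out["flags"]["under_empowered"].tolist() == [1, 1, 1]  # >=, not >

    def test_hand_case(self):
        out = postest.classify_under_empowered(estimates_frame([10.0, 20.0, 30.0]))
        assert out["national_mean_pct"] == 20.0
        assert out["flags"]["under_empowered"].tolist() == [0, 1, 1]

    def test_idempotent_with_fixed_mean(self):
        est = estimates_frame(list(np.linspace(5, 95, 20)))
        a = postest.classify_under_empowered(est, national_mean=50.0)
        b = postest.classify_under_empowered(est, national_mean=50.0)
        assert a["flags"]["under_empowered"].tolist() == b["flags"]["under_empowered"].tolist()

    def test_scale_equivariance_percent_vs_proportion(self):
        vals = list(np.linspace(5, 95, 20))
        a = postest.classify_under_empowered(estimates_frame(vals))
        b = postest.classify_under_empowered(estimates_frame([v / 100 for v in vals]))
        assert (
            a["flags"]["under_empowered"].tolist()
            == b["flags"]["under_empowered"].tolist()
        )

    def test_planted_district_tally(self):
        # 50 districts x 10 communities; plant 7 districts fully under-empowered
        rng = np.random.default_rng(5)
        prevs, districts = [], []
        for d in range(50):
            if d < 7:
                vals = rng.uniform(80, 95, 10)  # all above the mean
            else:
                vals = rng.uniform(10, 45, 10)  # below; keeps >90% impossible
            prevs.extend(vals)
            districts.extend([f"D{d:02d}"] * 10)
        est = estimates_frame(prevs, districts=districts)
        out = postest.classify_under_empowered(est)
        assert out["n_districts_over_threshold"] == 7

    def test_strictly_greater_than_threshold(self):
        # exactly 90% under-empowered must NOT count ("more than 90%")
        districts = ["D0"] * 10 + ["D1"] * 10
        prevs = [80.0] * 9 + [0.0] + [80.0] * 10
        out = postest.classify_under_empowered(
            estimates_frame(prevs, districts=districts), national_mean=50.0
        )
        frac = out["district_fractions"].set_index("district_id")
        assert frac.loc["D0", "fraction_under_empowered"] == 0.9
        assert out["n_districts_over_threshold"] == 1


class TestQuadrants:
    def test_four_hand_built_districts_one_per_quadrant(self):
        s = pd.DataFrame(
            {
                "district_id": list("ABCD"),
                "mean_prev_pct": [10.0, 10.0, 90.0, 90.0],
                "sd_prev_pct": [1.0, 9.0, 1.0, 9.0],
                "n_communities": 5,
            }
        )
        out = postest.cross_tabulate_quadrants(s)
        assert out["below_prev_below_sd"] == 1
        assert out["below_prev_above_sd"] == 1
        assert out["above_prev_below_sd"] == 1
        assert out["above_prev_above_sd"] == 1

    def test_identical_districts_single_quadrant_by_boundary_rule(self):
        s = pd.DataFrame(
            {
                "district_id": ["A", "B"],
                "mean_prev_pct": [30.0, 30.0],
                "sd_prev_pct": [5.0, 5.0],
                "n_communities": 5,
            }
        )
        out = postest.cross_tabulate_quadrants(s)
        assert out["above_prev_above_sd"] == 2  # >= on both axes

    def test_planted_counts_recovered(self):
        rng = np.random.default_rng(9)
        rows = []
        planted = {"bb": 12, "ba": 7, "ab": 5, "aa": 16}
        for quad, count in planted.items():
            for _ in range(count):
                m = rng.uniform(5, 45) if quad[0] == "b" else rng.uniform(55, 95)
                s = rng.uniform(0, 4) if quad[1] == "b" else rng.uniform(6, 10)
                rows.append({"mean_prev_pct": m, "sd_prev_pct": s})
        summaries = pd.DataFrame(rows)
        summaries["district_id"] = [f"D{i}" for i in range(len(summaries))]
        summaries["n_communities"] = 5
        out = postest.cross_tabulate_quadrants(summaries, mean_of_means=50.0, mean_of_sds=5.0)
        assert out["below_prev_below_sd"] == planted["bb"]
        assert out["below_prev_above_sd"] == planted["ba"]
        assert out["above_prev_below_sd"] == planted["ab"]
        assert out["above_prev_above_sd"] == planted["aa"]
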