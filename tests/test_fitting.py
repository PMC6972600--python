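"""Fitting engine: MLE quality, covariate-structure selection, profile CIs."""

import itertools
import json
import math

import numpy as np
import pytest

from bmdrisk.fitting import (
    BMDResult,
    CovariateConfig,
    DesignError,
    UnitMismatchError,
    combined_analysis,
    fit_model,
    profile_ci,
    select_covariate_structure,
)
from bmdrisk.models import (
    CriticalEffectSize,
    DoseGroup,
    DoseResponseDataset,
    ModelParams,
    predict,
)
from bmdrisk.simulate import StudyDesign, TrueParams, generate_study

from conftest import CES, noise_free_dataset


def _two_strain(seed, ced_a=10.0, ced_b=10.0, a_a=0.25, a_b=0.25, n=75):
    truth_a = TrueParams(ModelParams("exponential", a=a_a, ced=ced_a, c=4.0, d=1.0, log_sd=0.3))
    truth_b = TrueParams(ModelParams("exponential", a=a_b, ced=ced_b, c=4.0, d=1.0, log_sd=0.3))
    da = generate_study(StudyDesign((0.0, 1.0, 10.0, 100.0), n, "A"), truth_a, seed)
    db = generate_study(StudyDesign((0.0, 1.0, 10.0, 100.0), n, "B"), truth_b, seed + 500_009)
    return DoseResponseDataset(da.groups + db.groups)


class TestFitModel:
    @pytest.mark.parametrize("family", ["exponential", "hill"])
    def test_zero_noise_recovery(self, family):
        truth = ModelParams(family, a=0.25, ced=10.0, c=4.0, d=1.0, log_sd=0.3)
        data = noise_free_dataset(truth, CES, (0.0, 1.0, 3.0, 10.0, 30.0, 100.0))
        fit = fit_model(data, family, CES, seed=3)
        assert fit.a[""] == pytest.approx(0.25, rel=1e-3)
        assert fit.ced[""] == pytest.approx(10.0, rel=1e-3)
        assert fit.c == pytest.approx(4.0, rel=1e-3)
        assert fit.d == pytest.approx(1.0, rel=1e-3)

    def test_true_ced_inside_own_ci_on_two_strain_fixture(self):
        data = _two_strain(seed=1, ced_a=10.0, ced_b=14.0, a_b=0.15)
        cov = CovariateConfig(a_by_covariate=True, ced_by_covariate=True)
        fit = fit_model(data, "exponential", CES, cov, n_starts=8, seed=1)
        res = profile_ci(fit, data, 0.90, seed=1)
        assert res.bmcl["A"] <= 10.0 <= res.bmcu["A"]
        assert res.bmcl["B"] <= 14.0 <= res.bmcu["B"]

    def test_mle_beats_coarse_grid(self, six_group_dataset):
        """Brute-force grid over (a, ced, c, d) with the residual SD profiled
        in closed form must never beat the optimizer."""
        data = six_group_dataset
        fit = fit_model(data, "exponential", CES, seed=2)
        from bmdrisk.models import group_log_stats

        stats_ = [(g.dose, *group_log_stats(g)) for g in data.groups]
        n_total = sum(s[1] for s in stats_)

        def grid_ll(a, ced, c, d):
            p = ModelParams("exponential", a=a, ced=ced, c=c, d=d, log_sd=1.0)
            rss = 0.0
            for dose, n, m, ss in stats_:
                mu = math.log(predict(p, CES, dose))
                rss += ss + n * (m - mu) ** 2
            s2 = rss / n_total
            return -0.5 * n_total * (math.log(2 * math.pi * s2) + 1.0)

        best_grid = -np.inf
        for a, ced, c, d in itertools.product(
            np.geomspace(0.1, 1.0, 8),
            np.geomspace(2.0, 60.0, 8),
            np.geomspace(1.8, 12.0, 8),
            np.geomspace(0.25, 4.0, 8),
        ):
            best_grid = max(best_grid, grid_ll(a, ced, c, d))
        assert best_grid <= fit.log_lik + 1e-6

    def test_aic_identity_and_nesting(self):
        data = _two_strain(seed=4, ced_b=12.0)
        lls = {}
        for cfg in (
            CovariateConfig(),
            CovariateConfig(a_by_covariate=True),
            CovariateConfig(a_by_covariate=True, ced_by_covariate=True),
        ):
            fit = fit_model(data, "exponential", CES, cfg, n_starts=6, seed=4)
            assert fit.aic == pytest.approx(2 * fit.n_free_params - 2 * fit.log_lik, abs=1e-12)
            lls[cfg.label] = fit.log_lik
        assert lls["split:a"] >= lls["all-shared"] - 1e-6
        assert lls["split:a+ced"] >= lls["split:a"] - 1e-6

    def test_fixing_c_near_floor_never_beats_free_fit(self, six_group_dataset):
        free = fit_model(six_group_dataset, "exponential", CES, seed=5)
        # c fixed just above its floor 1 + CES (u at its lower bound)
        fixed = fit_model(
            six_group_dataset,
            "exponential",
            CES,
            seed=5,
            _fixed={2: math.log(1e-4)},  # slot 2 = u -> c = 1 + ces + 1e-4
        )
        assert fixed.log_lik <= free.log_lik + 1e-6

    def test_design_error_below_three_doses(self):
        groups = tuple(DoseGroup(dose=d, responses=(1.0, 1.2, 0.9)) for d in (0.0, 10.0))
        with pytest.raises(DesignError):
            fit_model(DoseResponseDataset(groups), "exponential", CES)

    def test_reproducible_serialization(self):
        data = _two_strain(seed=9, n=20)
        cov = CovariateConfig(a_by_covariate=True)
        r1 = fit_model(data, "exponential", CES, cov, n_starts=6, seed=9).to_dict()
        r2 = fit_model(data, "exponential", CES, cov, n_starts=6, seed=9).to_dict()
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)

    def test_dose_scale_equivariance(self):
        data = _two_strain(seed=6, n=30)
        k = 3.0
        scaled = DoseResponseDataset(
            tuple(
                DoseGroup(dose=g.dose * k, covariate=g.covariate, responses=g.responses)
                for g in data.groups
            )
        )
        cov = CovariateConfig(a_by_covariate=True, ced_by_covariate=True)
        f1 = fit_model(data, "exponential", CES, cov, n_starts=6, seed=6)
        f2 = fit_model(scaled, "exponential", CES, cov, n_starts=6, seed=6)
        for lv in ("A", "B"):
            assert f2.ced[lv] == pytest.approx(k * f1.ced[lv], rel=1e-3)

    def test_response_scale_invariance_of_ced(self):
        data = _two_strain(seed=8, n=30)
        k = 5.0
        scaled = DoseResponseDataset(
            tuple(
                DoseGroup(
                    dose=g.dose,
                    covariate=g.covariate,
                    responses=tuple(r * k for r in g.responses),
                )
                for g in data.groups
            )
        )
        cov = CovariateConfig(a_by_covariate=True, ced_by_covariate=True)
        f1 = fit_model(data, "exponential", CES, cov, n_starts=6, seed=8)
        f2 = fit_model(scaled, "exponential", CES, cov, n_starts=6, seed=8)
        for lv in ("A", "B"):
            assert f2.ced[lv] == pytest.approx(f1.ced[lv], rel=1e-3)
            assert f2.a[lv] == pytest.approx(k * f1.a[lv], rel=1e-3)


class TestCovariateSelection:
    def test_identical_strains_mostly_select_all_shared(self):
        hits = 0
        for rep in range(50):
            data = _two_strain(seed=20_000 + rep, n=30)
            fit = select_covariate_structure(data, "exponential", CES, n_starts=4, seed=rep)
            hits += fit.config.label == "all-shared"
        assert hits >= 40  # >= 80% of 50

    def test_threefold_ced_difference_selects_ced_split(self):
        hits = 0
        for rep in range(50):
            data = _two_strain(seed=30_000 + rep, ced_a=5.0, ced_b=15.0, n=75)
            fit = select_covariate_structure(data, "exponential", CES, n_starts=4, seed=rep)
            hits += fit.config.ced_by_covariate
        assert hits >= 45  # >= 90% of 50

    def test_single_level_returns_all_shared(self, six_group_dataset):
        fit = select_covariate_structure(six_group_dataset, "exponential", CES, n_starts=4, seed=0)
        assert fit.config == CovariateConfig()

    def test_candidate_aics_retained(self):
        data = _two_strain(seed=77, n=20)
        fit = select_covariate_structure(data, "exponential", CES, n_starts=4, seed=0)
        assert set(fit.diagnostics["candidate_aics"]) == {
            "all-shared",
            "split:a",
            "split:a+ced",
            "split:a+ced+log_sd",
        }


class TestProfileCI:
    def test_point_estimate_inside_interval(self, six_group_dataset):
        fit = fit_model(six_group_dataset, "exponential", CES, seed=1)
        res = profile_ci(fit, six_group_dataset, 0.90, seed=1)
        lv = res.levels[0]
        assert res.bmcl[lv] <= res.ced_hat[lv] <= res.bmcu[lv]
        assert res.bmcl[lv] > 0

    def test_higher_level_widens_interval(self, six_group_dataset):
        fit = fit_model(six_group_dataset, "exponential", CES, seed=1)
        r90 = profile_ci(fit, six_group_dataset, 0.90, seed=1)
        r99 = profile_ci(fit, six_group_dataset, 0.99, seed=1)
        lv = r90.levels[0]
        assert r99.bmcl[lv] <= r90.bmcl[lv]
        assert r99.bmcu[lv] >= r90.bmcu[lv]

    def test_profile_endpoints_near_parametric_bootstrap_percentiles(self, six_group_dataset):
        """Independent oracle: refit 500 parametric-bootstrap replicates and
        compare the percentile interval with the profile interval."""
        data = six_group_dataset
        fit = fit_model(data, "exponential", CES, seed=1)
        res = profile_ci(fit, data, 0.90, seed=1)
        lv = res.levels[0]
        truth = ModelParams(
            "exponential",
            a=fit.a[lv],
            ced=fit.ced[lv],
            c=fit.c,
            d=fit.d,
            log_sd=fit.log_sd[lv],
        )
        rng = np.random.default_rng(123)
        ceds = []
        doses = [g.dose for g in data.groups]
        sizes = [g.size for g in data.groups]
        for _ in range(500):
            groups = []
            for d, n in zip(doses, sizes):
                med = predict(truth, CES, d)
                groups.append(
                    DoseGroup(dose=d, responses=tuple(med * np.exp(rng.normal(0, truth.log_sd, n))))
                )
            boot = DoseResponseDataset(tuple(groups))
            bf = fit_model(boot, "exponential", CES, n_starts=0, seed=0)
            ceds.append(bf.ced[lv])
        lo, hi = np.percentile(ceds, [5, 95])
        assert res.bmcl[lv] == pytest.approx(lo, rel=0.15)
        assert res.bmcu[lv] == pytest.approx(hi, rel=0.15)


class TestCombinedAnalysis:
    def test_two_identical_copies_symmetric(self, six_group_dataset):
        res, fit = combined_analysis(
            [six_group_dataset, six_group_dataset],
            "exponential",
            CES,
            0.90,
            labels=["s1", "s2"],
            n_starts=6,
            seed=3,
        )
        assert res.ced_hat["s1"] == pytest.approx(res.ced_hat["s2"], rel=1e-6)
        single = fit_model(six_group_dataset, "exponential", CES, n_starts=6, seed=3)
        assert res.ced_hat["s1"] == pytest.approx(single.ced[""], rel=0.02)

    def test_unit_mismatch_rejected(self, six_group_dataset):
        other = DoseResponseDataset(six_group_dataset.groups, dose_units="mg/m3")
        with pytest.raises(UnitMismatchError):
            combined_analysis([six_group_dataset, other], "exponential", CES)

    def test_duplicate_labels_rejected(self, six_group_dataset):
        with pytest.raises(ValueError):
            combined_analysis(
                [six_group_dataset, six_group_dataset],
                "exponential",
                CES,
                labels=["x", "x"],
            )
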