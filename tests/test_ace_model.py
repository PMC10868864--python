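"""Falconer moments, orthant probabilities, ML fits, model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from twinace import ace_model as am
from twinace.synthetic_data import TrueComponents, simulate_cohort, single_trait_config
from twinace.twin_correlations import pair_table


def _pairs_frame(y_mz, y_dz):
    """Cohort frame from (n,2) member arrays per zygosity."""
    frames = []
    offset = 0
    for zyg, y in (("MZ", y_mz), ("DZ", y_dz)):
        n = len(y)
        frames.append(pd.DataFrame({
            "family_id": np.repeat([f"{zyg}{i + offset}" for i in range(n)], 2),
            "member_index": np.tile([1, 2], n),
            "zygosity": zyg,
            "y": y.ravel(),
        }))
        offset += n
    return pd.concat(frames, ignore_index=True)


class TestFalconer:
    @pytest.mark.parametrize("r_mz,r_dz,h2,c2,e2", [
        (0.19, 0.05, 0.28, 0.0, 0.72),   # c2 = -0.09 truncated to 0
        (0.44, 0.44, 0.0, 0.44, 0.56),   # equal correlations force h2 = 0
        (0.50, 0.30, 0.40, 0.10, 0.50),
    ])
    def test_decomposition(self, r_mz, r_dz, h2, c2, e2):
        comp = am.falconer(r_mz, r_dz)
        assert comp.h2 == pytest.approx(h2, abs=1e-12)
        assert comp.c2 == pytest.approx(c2, abs=1e-12)
        assert comp.e2 == pytest.approx(e2, abs=1e-12)
        assert comp.source == "moment"

    def test_raw_values_recorded(self):
        comp = am.falconer(0.19, 0.05)
        assert comp.raw["c2"] == pytest.approx(-0.09)
        assert comp.raw["h2"] == pytest.approx(0.28)

    def test_extreme_input_still_valid_decomposition(self):
        comp = am.falconer(0.9, 0.1)  # raw h2 = 1.6
        assert comp.h2 + comp.c2 + comp.e2 == pytest.approx(1.0, abs=1e-12)
        assert min(comp.h2, comp.c2, comp.e2) >= 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="r_mz"):
            am.falconer(1.5, 0.0)


class TestOrthant:
    def test_symmetric_independence(self):
        assert am.orthant_probability(0.0, 0.0, 0.0) == pytest.approx(0.25, abs=1e-12)

    def test_comonotone(self):
        assert am.orthant_probability(0.0, 0.0, 1.0) == pytest.approx(0.5, abs=1e-12)

    def test_antithetic(self):
        assert am.orthant_probability(0.0, 0.0, -1.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("t1,t2,rho", [
        (0.5, -0.3, 0.4), (0.0, 1.2, -0.7), (2.0, 2.0, 0.9),
        (-1.5, 0.7, 0.05), (0.674, 0.674, 0.65),
    ])
    def test_four_quadrants_sum_to_one(self, t1, t2, rho):
        p11 = am.orthant_probability(t1, t2, rho)
        p10 = norm.sf(t1) - p11
        p01 = norm.sf(t2) - p11
        p00 = 1 - norm.sf(t1) - norm.sf(t2) + p11
        assert p11 + p10 + p01 + p00 == pytest.approx(1.0, abs=1e-9)
        assert min(p11, p10, p01, p00) >= -1e-12

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            am.orthant_probability(0, 0, 1.5)


class TestContinuousFit:
    def test_parameter_recovery(self, continuous_cohort_5k):
        fit = am.fit_continuous(continuous_cohort_5k, "y", model="ACE")
        assert fit.components.h2 == pytest.approx(0.5, abs=0.04)
        assert fit.components.c2 == pytest.approx(0.2, abs=0.04)
        assert fit.components.h2 + fit.components.c2 + fit.components.e2 == \
            pytest.approx(1.0, abs=1e-8)

    def test_uncorrelated_pairs_are_all_unique_environment(self):
        cfg = single_trait_config(20_000, TrueComponents(0.0, 0.0, 1.0),
                                  kind="continuous", seed=41)
        fit = am.fit_continuous(simulate_cohort(cfg), "y", model="ACE")
        assert fit.components.e2 == pytest.approx(1.0, abs=0.03)
        assert fit.boundary  # h2 or c2 pinned at zero

    def test_moment_ml_coincidence_on_exact_data(self):
        """Data whose sample moments equal the model-implied moments make
        the ML solution coincide with the Falconer moment solution."""
        rng = np.random.default_rng(42)
        n = 400
        targets = {"MZ": 0.6, "DZ": 0.45}  # a2=0.3, c2=0.3, e2=0.4
        ys = {}
        for zyg, r in targets.items():
            x = rng.normal(size=(n, 2))
            x -= x.mean(axis=0)
            cov = (x.T @ x) / n
            L = np.linalg.cholesky(cov)
            target = np.array([[1.0, r], [r, 1.0]])
            ys[zyg] = x @ np.linalg.inv(L).T @ np.linalg.cholesky(target).T
        frame = _pairs_frame(ys["MZ"], ys["DZ"])
        pt = pair_table(frame, "y")
        r_emp = {z: np.corrcoef(pt.loc[pt.zygosity == z, "y1"],
                                pt.loc[pt.zygosity == z, "y2"])[0, 1]
                 for z in ("MZ", "DZ")}
        moment = am.falconer(r_emp["MZ"], r_emp["DZ"])
        fit = am.fit_continuous(frame, "y", model="ACE")
        assert fit.components.h2 == pytest.approx(moment.h2, abs=1e-4)
        assert fit.components.c2 == pytest.approx(moment.c2, abs=1e-4)

    def test_covariate_effect_recovered(self):
        cfg = single_trait_config(2000, TrueComponents(0.4, 0.2, 0.4),
                                  kind="continuous", seed=43)
        cohort = simulate_cohort(cfg)
        cohort["y"] = cohort["y"] + 0.05 * cohort["age_months"]
        fit = am.fit_continuous(cohort, "y", model="ACE",
                                covariates=["age_months"])
        assert fit.params["beta1"] == pytest.approx(0.05, abs=0.01)
        assert fit.components.h2 == pytest.approx(0.4, abs=0.06)

    def test_se_scales_as_inverse_sqrt_n(self):
        ses = {}
        for n in (2000, 8000):
            cfg = single_trait_config(n, TrueComponents(0.4, 0.3, 0.3),
                                      kind="continuous", seed=44)
            fit = am.fit_continuous(simulate_cohort(cfg), "y", model="ACE")
            ses[n] = fit.components.se["h2"]
        assert ses[8000] == pytest.approx(ses[2000] / 2, rel=0.15)


class TestBinaryFit:
    def test_parameter_recovery(self, binary_cohort_10k):
        fit = am.fit_binary(binary_cohort_10k, "y", model="ACE")
        assert fit.scale == "liability"
        assert fit.components.h2 == pytest.approx(0.5, abs=0.07)
        assert fit.components.c2 == pytest.approx(0.2, abs=0.07)
        assert fit.params["tau"] == pytest.approx(norm.isf(0.25), abs=0.05)

    def test_independent_pairs(self):
        cfg = single_trait_config(5000, TrueComponents(0.0, 0.0, 1.0),
                                  kind="binary", prevalence=0.25, seed=45)
        fit = am.fit_binary(simulate_cohort(cfg), "y", model="ACE")
        assert fit.components.h2 + fit.components.c2 == pytest.approx(0.0, abs=0.05)

    def test_non_binary_trait_rejected(self, continuous_cohort_5k):
        with pytest.raises(ValueError, match="binary"):
            am.fit_binary(continuous_cohort_5k, "y")

    def test_covariate_shifted_threshold_recovered(self):
        """A probit covariate effect on the liability threshold is
        recovered alongside the variance components."""
        cfg = single_trait_config(1500, TrueComponents(0.5, 0.0, 0.5),
                                  kind="binary", prevalence=0.25, seed=48)
        cohort = simulate_cohort(cfg).copy()
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, len(cohort)).astype(float)
        # resample the trait with an x-shifted threshold, keeping the
        # familial structure out of it for a clean marginal check
        tau = norm.isf(0.25) - 0.5 * x
        cohort["x"] = x
        cohort["y"] = (rng.standard_normal(len(cohort)) > tau).astype(int)
        fit = am.fit_binary(cohort, "y", model="E", covariates=["x"])
        # threshold = -(beta0 + beta1 x): beta1 should be ~ +0.5
        assert fit.params["beta1"] == pytest.approx(0.5, abs=0.12)
        assert fit.params["beta0"] == pytest.approx(-norm.isf(0.25), abs=0.12)


class TestWaldCI:
    def test_interval_arithmetic(self, binary_cohort_10k):
        fit = am.fit_binary(binary_cohort_10k, "y", model="ACE")
        fit.components.se = {"h2": 0.17}
        fit.components.h2 = 0.04
        comp = am.wald_ci(fit)
        lo, hi = comp.ci["h2"]
        assert lo == pytest.approx(-0.293, abs=0.002)
        assert hi == pytest.approx(0.373, abs=0.002)
        assert comp.p["h2"] == pytest.approx(0.81, abs=0.02)

    def test_untruncated_bounds_may_go_negative(self, binary_cohort_10k):
        fit = am.fit_binary(binary_cohort_10k, "y", model="ACE")
        am.wald_ci(fit)
        for name, (lo, hi) in fit.components.ci.items():
            est = getattr(fit.components, name)
            assert lo < est < hi

    def test_fixed_component_has_no_interval(self, continuous_cohort_5k):
        fit = am.fit_continuous(continuous_cohort_5k, "y", model="AE")
        am.wald_ci(fit)
        assert "c2" not in fit.components.ci


class TestSelection:
    def _fake_fit(self, model, h2, c2, bic):
        comp = am.VarianceComponents(h2=h2, c2=c2, e2=1 - h2 - c2,
                                     scale="liability", source="ml")
        return am.AceFit(model=model, trait="y", scale="liability", params={},
                         loglik=0.0, bic=bic, n_pairs={}, components=comp,
                         converged=True, n_starts=1)

    def test_c2_boundary_reduces_to_ae(self):
        fits = {"ACE": self._fake_fit("ACE", 0.3, 0.0, 100.0),
                "AE": self._fake_fit("AE", 0.3, 0.0, 98.0),
                "CE": self._fake_fit("CE", 0.0, 0.2, 97.0),
                "E": self._fake_fit("E", 0.0, 0.0, 120.0)}
        sel = am.compare_and_reduce(fits)
        assert sel.model == "AE"
        assert "boundary" in sel.selection_note

    def test_h2_boundary_reduces_to_ce(self):
        fits = {"ACE": self._fake_fit("ACE", 0.0, 0.5, 100.0),
                "AE": self._fake_fit("AE", 0.4, 0.0, 96.0),
                "CE": self._fake_fit("CE", 0.0, 0.5, 98.0),
                "E": self._fake_fit("E", 0.0, 0.0, 120.0)}
        assert am.compare_and_reduce(fits).model == "CE"

    def test_interior_optimum_selected_by_bic(self):
        fits = {"ACE": self._fake_fit("ACE", 0.3, 0.3, 90.0),
                "AE": self._fake_fit("AE", 0.5, 0.0, 95.0),
                "CE": self._fake_fit("CE", 0.0, 0.5, 94.0),
                "E": self._fake_fit("E", 0.0, 0.0, 120.0)}
        assert am.compare_and_reduce(fits).model == "ACE"

    def test_selection_consistency_under_ce_truth(self):
        """Cohorts simulated without genetic variance should reduce to CE
        (or an ACE fit with h2 pinned near zero) in >= 90% of replicates."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            cfg = single_trait_config(400, TrueComponents(0.0, 0.5, 0.5),
                                      kind="continuous", seed=500 + rep)
            fits = {m: am.fit_continuous(simulate_cohort(cfg), "y", model=m)
                    for m in am.MODELS}
            sel = am.compare_and_reduce(fits)
            if sel.model == "CE" or (sel.model == "ACE" and sel.components.h2 < 0.05):
                hits += 1
        assert hits >= 0.9 * n_rep


class TestStratified:
    def test_single_stratum_matches_unstratified(self, binary_cohort_10k):
        cohort = binary_cohort_10k.copy()
        table = am.stratified_ace(cohort, "y", "sex", scale="liability")
        assert len(table) == 1
        fits = am.fit_ladder(cohort, "y", scale="liability")
        sel = am.compare_and_reduce(fits)
        row = table.iloc[0]
        assert row["model"] == sel.model
        assert row["h2"] == pytest.approx(sel.components.h2, abs=1e-9)

    def test_small_stratum_reports_descriptives_only(self):
        cfg = single_trait_config(200, TrueComponents(0.4, 0.2, 0.4),
                                  kind="binary", prevalence=0.3, seed=46)
        cohort = simulate_cohort(cfg).copy()
        # carve out a 5-pair stratum
        fams = cohort["family_id"].unique()
        cohort["grp"] = np.where(cohort["family_id"].isin(fams[:5]), "tiny", "big")
        table = am.stratified_ace(cohort, "y", "grp", scale="liability")
        tiny = table.set_index("stratum").loc["tiny"]
        assert "descriptives only" in tiny["status"]
        assert np.isnan(tiny["h2"])
        assert np.isfinite(tiny["prevalence"])

    def test_sex_specific_c2_recovered(self):
        """Strata generated with c2 = 0.55 vs 0.63 are recovered within 0.05."""
        from twinace.synthetic_data import SimulationConfig, StratumSpec, TraitSpec
        strata = (
            StratumSpec("M", "White", 0.5, {"y": TrueComponents(0.09, 0.55, 0.36)},
                        prevalence={"y": 0.28}),
            StratumSpec("F", "White", 0.5, {"y": TrueComponents(0.03, 0.63, 0.34)},
                        prevalence={"y": 0.22}),
        )
        cfg = SimulationConfig(
            n_pairs=40_000, traits=(TraitSpec("y", "binary", prevalence=0.25),),
            strata=strata, dz_fraction=0.5, seed=47)
        cohort = simulate_cohort(cfg)
        table = am.stratified_ace(cohort, "y", "sex", scale="liability").set_index("stratum")
        # compare against the full-ACE fit per stratum regardless of reduction
        for sex, c2_true in (("M", 0.55), ("F", 0.63)):
            sub = cohort[cohort["sex"] == sex]
            fit = am.fit_binary(sub, "y", model="ACE")
            assert fit.components.c2 == pytest.approx(c2_true, abs=0.05)
        assert set(table.index) == {"M", "F"}


def test_likelihood_nesting_quick():
    """ACE dominates AE/CE, which dominate E (nested models)."""
    for seed in (60, 61, 62, 63, 64):
        cfg = single_trait_config(300, TrueComponents(0.3, 0.3, 0.4),
                                  kind="continuous", seed=seed)
        cohort = simulate_cohort(cfg)
        ll = {m: am.fit_continuous(cohort, "y", model=m).loglik
              for m in am.MODELS}
        assert ll["ACE"] >= ll["AE"] - 1e-6
        assert ll["ACE"] >= ll["CE"] - 1e-6
        assert ll["AE"] >= ll["E"] - 1e-6
        assert ll["CE"] >= ll["E"] - 1e-6
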