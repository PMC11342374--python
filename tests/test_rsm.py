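"""Response-surface fit, prediction, optimum location, contour grids."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from peptoids.doe import ModelMatrixSpec, model_matrix, select_design
from peptoids.errors import FitError
from peptoids.rsm import ResponseSurface, contour_grid, find_optimum, fit_rsm
from peptoids.sequences import LipidBlockFactors
from peptoids.simulate import default_truth, simulate_screen


@pytest.fixture(scope="module")
def design(candidates):
    sub, des = select_design(candidates, 34, seed=1)
    return sub, des


def screen_xy(truth, sub, seed, n_rep=3):
    scr = simulate_screen(truth, sub, n_replicates=n_rep, seed=seed)
    total = scr.groupby(["design_id", "replicate"])["flux"].sum().reset_index()
    pts = [sub.points[i - 1] for i in total["design_id"]]
    return pts, np.log10(total["flux"].to_numpy())


class TestFit:
    def test_noiseless_quadratic_interpolates(self, candidates, design):
        sub, des = design
        truth = dataclasses.replace(default_truth(), noise_sd=0.0)
        pts, y = screen_xy(truth, sub, seed=0, n_rep=1)
        fit = fit_rsm(pts, y, spec=des.spec_)
        resid = y - fit.predict(pts)
        assert np.abs(resid).max() < 1e-8
        assert fit.r_squared_ == pytest.approx(1.0, abs=1e-10)
        assert fit.dropped_terms_ == ()

    def test_matches_normal_equations_oracle(self, design):
        sub, des = design
        rng = np.random.default_rng(3)
        pts = sub.points[:20]
        y = rng.normal(size=20)
        fit = fit_rsm(pts, y, spec=des.spec_)
        X, _ = model_matrix(pts, des.spec_)
        Xk = X[list(fit.terms_)].to_numpy()
        beta, *_ = np.linalg.lstsq(Xk, y, rcond=None)
        assert fit.coef_.to_numpy() == pytest.approx(beta, abs=1e-8)

    def test_all_none_design_drops_aliased_columns(self):
        pts = [LipidBlockFactors(n, c, 0, "none")
               for n in (3, 4, 5, 6) for c in (20, 30, 40, 50, 60)]
        rng = np.random.default_rng(0)
        fit = fit_rsm(pts, rng.normal(size=len(pts)))
        dropped = set(fit.dropped_terms_)
        assert any("nonlinear_id" in t for t in dropped)
        assert "nonlinear_id" not in fit.terms_

    def test_non_finite_response_reported_with_rows(self, design):
        sub, des = design
        y = np.zeros(len(sub.points))
        y[3] = np.nan
        with pytest.raises(FitError, match=r"\[3\]"):
            fit_rsm(sub.points, y, spec=des.spec_)

    def test_r_squared_nondecreasing_with_added_term(self, design):
        sub, _ = design
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(sub.points))
        small = ModelMatrixSpec(terms=("intercept", "n_lipid_monomers"))
        big = ModelMatrixSpec(terms=("intercept", "n_lipid_monomers",
                                     "total_lipid_carbons"))
        r_small = fit_rsm(sub.points, y, spec=small).r_squared_
        r_big = fit_rsm(sub.points, y, spec=big).r_squared_
        assert r_big >= r_small - 1e-12

    def test_covariance_symmetric_psd(self, design):
        sub, des = design
        truth = default_truth()
        pts, y = screen_xy(truth, sub, seed=1)
        fit = fit_rsm(pts, y, spec=des.spec_)
        C = fit.cov_.to_numpy()
        assert np.abs(C - C.T).max() < 1e-12
        assert np.linalg.eigvalsh(C).min() > -1e-10

    def test_coefficients_converge_to_truth_as_noise_vanishes(
            self, candidates, design):
        sub, des = design
        truth = dataclasses.replace(default_truth(), noise_sd=1e-8)
        pts, y = screen_xy(truth, sub, seed=2)
        fit = fit_rsm(pts, y, spec=des.spec_)
        expected = truth.model_coefficients(des.spec_)
        err = (fit.coef_.reindex(expected.index).fillna(0.0)
               - expected).abs().max()
        assert err < 1e-6


class TestPredict:
    def test_training_point_reproduced_in_noiseless_case(self, design):
        sub, des = design
        truth = dataclasses.replace(default_truth(), noise_sd=0.0)
        pts, y = screen_xy(truth, sub, seed=0, n_rep=1)
        fit = fit_rsm(pts, y, spec=des.spec_)
        yhat, se = fit.predict([pts[0]], return_se=True)
        assert yhat[0] == pytest.approx(y[0], abs=1e-8)

    def test_center_prediction_is_intercept(self, design):
        sub, des = design
        fit = ResponseSurface(spec=des.spec_)
        fit.fit(sub.points, np.ones(len(sub.points)) * 4.2)
        mid = {k: (lo + hi) / 2 for k, (lo, hi) in des.spec_.ranges.items()}
        df = pd.DataFrame([{**mid, "nonlinear_id": "none"}])
        assert fit.predict(df)[0] == pytest.approx(fit.coef_["intercept"])

    def test_se_smaller_at_design_point_than_extreme_corner(self, design):
        sub, des = design
        truth = default_truth()
        pts, y = screen_xy(truth, sub, seed=4)
        fit = fit_rsm(pts, y, spec=des.spec_)
        corner = pd.DataFrame([{"n_lipid_monomers": 3,
                                "total_lipid_carbons": 108,
                                "n_nonlinear": 3, "nonlinear_id": "Ole"}])
        _, se_design = fit.predict([sub.points[0]], return_se=True)
        _, se_corner = fit.predict(corner, return_se=True)
        assert se_design[0] <= se_corner[0]


class TestOptimum:
    def test_constant_model_ties_to_lowest_lexicographic(self, candidates,
                                                         design):
        sub, des = design
        fit = fit_rsm(sub.points, np.full(len(sub.points), 2.0),
                      spec=des.spec_)
        opt = find_optimum(fit, candidates.points, n_boot=50, seed=0)
        lowest = min(p.as_tuple() for p in candidates.points)
        assert opt.best_point.as_tuple() == lowest
        assert all(sd == 0.0 for sd in opt.factor_sd.values())

    def test_point_estimate_only_when_n_boot_zero(self, candidates, design):
        sub, des = design
        truth = default_truth()
        pts, y = screen_xy(truth, sub, seed=5)
        fit = fit_rsm(pts, y, spec=des.spec_)
        opt = find_optimum(fit, candidates.points, n_boot=0)
        assert opt.n_boot == 0
        assert opt.factor_sd["total_lipid_carbons"] == 0.0

    def test_invariant_to_feasible_enumeration_order(self, candidates,
                                                     design):
        sub, des = design
        truth = default_truth()
        pts, y = screen_xy(truth, sub, seed=6)
        fit = fit_rsm(pts, y, spec=des.spec_)
        fwd = find_optimum(fit, candidates.points, n_boot=100, seed=1)
        rev = find_optimum(fit, list(reversed(candidates.points)),
                          n_boot=100, seed=1)
        assert fwd.best_point == rev.best_point
        assert fwd.factor_mean == rev.factor_mean

    def test_recovers_synthetic_truth_region(self, candidates, design):
        """With default noise the fitted optimum lands in the truth
        neighborhood (6, ~55, 3, Ehx) in >= 90 of 100 seeded screens."""
        sub, des = design
        truth = default_truth()
        hits = 0
        for rep in range(100):
            pts, y = screen_xy(truth, sub, seed=20_000 + rep)
            fit = fit_rsm(pts, y, spec=des.spec_)
            b = find_optimum(fit, candidates.points, n_boot=0).best_point
            hits += (abs(b.n_lipid_monomers - 6) <= 1
                     and abs(b.total_lipid_carbons - 55) <= 6
                     and abs(b.n_nonlinear - 3) <= 1
                     and b.nonlinear_id == "Ehx")
        assert hits >= 90


class TestContourGrid:
    @pytest.fixture()
    def fitted(self, design):
        sub, des = design
        truth = dataclasses.replace(default_truth(), noise_sd=0.0)
        pts, y = screen_xy(truth, sub, seed=0, n_rep=1)
        return fit_rsm(pts, y, spec=des.spec_)

    def test_interior_maximum_near_truth_center(self, fitted):
        grid = contour_grid(fitted, "n_lipid_monomers", "total_lipid_carbons",
                            {"n_nonlinear": 3, "nonlinear_id": "Ehx"},
                            nx=61, ny=61)
        best = grid.loc[grid["prediction"].idxmax()]
        assert abs(best["n_lipid_monomers"] - 6) <= 0.5
        assert abs(best["total_lipid_carbons"] - 55) <= 2.0

    def test_1x1_grid_is_single_prediction(self, fitted):
        grid = contour_grid(fitted, "n_lipid_monomers", "total_lipid_carbons",
                            {"n_nonlinear": 3, "nonlinear_id": "Ehx"},
                            nx=1, ny=1, bounds_x=(6, 6), bounds_y=(54, 54))
        assert len(grid) == 1
        want = fitted.predict(pd.DataFrame([{
            "n_lipid_monomers": 6, "total_lipid_carbons": 54,
            "n_nonlinear": 3, "nonlinear_id": "Ehx"}]))[0]
        assert grid["prediction"].iloc[0] == pytest.approx(want)

    def test_symmetric_about_center_for_symmetric_surface(self, fitted):
        # the truth surface is symmetric in carbons about 55
        grid = contour_grid(fitted, "n_lipid_monomers", "total_lipid_carbons",
                            {"n_nonlinear": 3, "nonlinear_id": "Ehx"},
                            nx=1, ny=11, bounds_x=(6, 6), bounds_y=(45, 65))
        vals = grid["prediction"].to_numpy()
        assert vals == pytest.approx(vals[::-1], abs=1e-8)

    def test_unknown_factor_rejected(self, fitted):
        from peptoids.errors import ValidationError
        with pytest.raises(ValidationError):
            contour_grid(fitted, "bogus", "total_lipid_carbons", {})
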