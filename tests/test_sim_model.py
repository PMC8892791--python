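import itertools
import warnings

import numpy as np
import pytest

import insulreg as ir
from insulreg.design import InsulationDesign, PairTable, build_insulation_design, build_pair_table
from insulreg.hic_io import BinTable, ContactMatrix
from insulreg.sim_model import (
    classify_borders,
    compute_residuals,
    fit_best_subset,
    fit_distance_trend,
    prefilter_lasso,
    run_sim,
)
from insulreg.simulate import GenerativeSpec


def brute_force_best_subset(X, z, lam):
    """Independent oracle: enumerate all supports, centered OLS each."""
    X = np.asarray(X.todense() if hasattr(X, "todense") else X, dtype=float)
    n, k = X.shape
    zc = z - z.mean()
    Xc = X - X.mean(axis=0)
    best = (float(zc @ zc) / n, ())
    for size in range(1, k + 1):
        for supp in itertools.combinations(range(k), size):
            Xs = Xc[:, supp]
            b, *_ = np.linalg.lstsq(Xs, zc, rcond=None)
            r = zc - Xs @ b
            obj = float(r @ r) / n + lam * size
            if obj < best[0] - 1e-12:
                best = (obj, supp)
    return best


class TestDistanceTrend:
    def test_recovers_power_law_curve(self):
        # ~2000 pairs from a pure power-law decay; fitted mean within 5%
        # of the generating curve at interior distances
        spec = GenerativeSpec(p=210, effects={}, alpha=1.2, seed=2, depth_gap1=150)
        m, truth = ir.generate_matrix(spec)
        pairs = build_pair_table(m, max_gap=10)
        assert pairs.n > 2000
        trend = fit_distance_trend(pairs, spline_df=8)
        for g in range(2, 10):
            d = np.log(g * spec.resolution)
            true_mean = np.exp(truth["beta0"] - spec.alpha * d)
            fitted = trend.predict_mean(np.array([d]))[0]
            assert abs(fitted - true_mean) / true_mean < 0.05

    def test_constant_counts_give_flat_trend(self):
        rng = np.random.default_rng(0)
        gaps = rng.integers(1, 11, size=500)
        pairs = PairTable(
            i=np.zeros(500, dtype=int), j=gaps, y=np.full(500, 50.0),
            resolution=10_000, p=600, max_gap=10,
        )
        trend = fit_distance_trend(pairs)
        f = trend.predict_logmean(pairs.d) - np.log(50.0)
        assert np.abs(f).max() < 0.05

    def test_degenerate_counts_fall_back(self):
        y = np.zeros(100)
        y[0] = 5.0
        pairs = PairTable(
            i=np.zeros(100, dtype=int), j=np.tile(np.arange(1, 11), 10),
            y=y, resolution=10_000, p=600, max_gap=10,
        )
        trend = fit_distance_trend(pairs)  # must not raise
        assert np.all(np.isfinite(trend.coef))

    def test_all_zero_counts_rejected(self):
        pairs = PairTable(
            i=np.zeros(60, dtype=int), j=np.tile(np.arange(1, 7), 10),
            y=np.zeros(60), resolution=10_000, p=600, max_gap=10,
        )
        with pytest.raises(ValueError, match="zero"):
            fit_distance_trend(pairs)


class TestResiduals:
    def test_perfect_fit_gives_zero_residuals(self):
        spec = GenerativeSpec(p=60, effects={}, seed=4, depth_gap1=400)
        m, _ = ir.generate_matrix(spec)
        pairs = build_pair_table(m, max_gap=10)
        trend = fit_distance_trend(pairs)
        pairs.y = np.exp(trend.expected_log(pairs.d, 1.0)) - 1.0
        z = compute_residuals(pairs, trend, pseudocount=1.0)
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_doubling_counts_shifts_by_log_two(self):
        spec = GenerativeSpec(p=60, effects={}, seed=4, depth_gap1=400)
        m, _ = ir.generate_matrix(spec)
        pairs = build_pair_table(m, max_gap=10)
        pairs.y = pairs.y + 1.0  # strictly positive
        trend = fit_distance_trend(pairs)
        z1 = compute_residuals(pairs, trend, pseudocount=1e-9)
        pairs2 = PairTable(
            i=pairs.i, j=pairs.j, y=2 * pairs.y,
            resolution=pairs.resolution, p=pairs.p, max_gap=pairs.max_gap,
        )
        z2 = compute_residuals(pairs2, trend, pseudocount=1e-9)
        np.testing.assert_allclose(z2 - z1, np.log(2.0), atol=1e-6)

    def test_planted_border_mean_residual_matches_effect(self):
        beta = -1.0
        spec = GenerativeSpec(p=100, effects={50: beta}, seed=6, depth_gap1=2000)
        m, _ = ir.generate_matrix(spec)
        pairs = build_pair_table(m, max_gap=10)
        trend = fit_distance_trend(pairs)
        z = compute_residuals(pairs, trend)
        spanning = (pairs.i < 50) & (pairs.j > 50)
        assert z[spanning].mean() == pytest.approx(beta, abs=0.15)

    def test_mean_residual_near_zero(self):
        spec = GenerativeSpec(p=100, effects={}, seed=7)
        m, _ = ir.generate_matrix(spec)
        pairs = build_pair_table(m, max_gap=10)
        trend = fit_distance_trend(pairs)
        z = compute_residuals(pairs, trend)
        assert abs(z.mean()) < 0.05


class TestPrefilter:
    def _problem(self, effects, seed, depth=100):
        spec = GenerativeSpec(p=200, effects=effects, seed=seed, depth_gap1=depth)
        m, _ = ir.generate_matrix(spec)
        pairs = build_pair_table(m, max_gap=10)
        trend = fit_distance_trend(pairs)
        z = compute_residuals(pairs, trend)
        return z, build_insulation_design(pairs)

    def test_identity_below_trigger(self):
        z, design = self._problem({}, seed=1)
        kept = prefilter_lasso(z, design, trigger=5000)
        np.testing.assert_array_equal(kept, design.candidate_bins)

    def test_null_passes_few_bins(self):
        z, design = self._problem({}, seed=2)
        kept = prefilter_lasso(z, design, force=True)
        assert len(kept) < 0.05 * design.n_candidates

    def test_planted_border_passes(self):
        z, design = self._problem({100: -2.0}, seed=3)
        kept = prefilter_lasso(z, design, force=True)
        assert 100 in kept

    def test_nonpositive_threshold_rejected(self):
        z, design = self._problem({}, seed=1)
        with pytest.raises(ValueError):
            prefilter_lasso(z, design, threshold=0.0)


class TestBestSubset:
    def _random_problem(self, k, n, seed, signal=True):
        rng = np.random.default_rng(seed)
        spec = GenerativeSpec(p=max(k + 6, 20), effects={}, seed=seed, depth_gap1=80)
        m, _ = ir.generate_matrix(spec)
        pairs = build_pair_table(m, max_gap=min(8, k + 4))
        if pairs.n > n:
            keep = rng.choice(pairs.n, size=n, replace=False)
            keep.sort()
            pairs = PairTable(
                i=pairs.i[keep], j=pairs.j[keep], y=pairs.y[keep],
                resolution=pairs.resolution, p=pairs.p, max_gap=pairs.max_gap,
            )
        cands = np.arange(2, 2 + k)
        design = build_insulation_design(pairs, candidate_bins=cands)
        beta_true = np.zeros(k)
        if signal:
            nz = rng.choice(k, size=rng.integers(1, 3), replace=False)
            beta_true[nz] = rng.uniform(0.5, 1.5, size=len(nz)) * rng.choice([-1, 1], len(nz))
        z = np.asarray(design.X @ beta_true).ravel() + rng.normal(0, 0.3, pairs.n)
        return z, design

    def test_lambda_infinity_empties_model(self):
        z, design = self._random_problem(8, 300, seed=0)
        fit = fit_best_subset(z, design, lambda_grid=np.array([1e6]))
        assert len(fit.selected) == 0

    def test_lambda_zero_single_candidate_is_ols(self):
        z, design = self._random_problem(6, 300, seed=1)
        one = design.restrict([4])
        fit = fit_best_subset(z, one, lambda_grid=np.array([0.0]))
        x = np.asarray(one.X.todense()).ravel()
        xc = x - x.mean()
        ols = float(xc @ (z - z.mean()) / (xc @ xc))
        assert fit.beta[4] == pytest.approx(ols, abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_cd_with_swaps_matches_enumeration(self, seed):
        """The local-search solver finds the exact L0 optimum on problems
        small enough to enumerate."""
        z, design = self._random_problem(8, 250, seed=10 + seed)
        fit = fit_best_subset(z, design, algorithm="cd", cv_folds=5, n_lambda=20,
                              seed=99)
        obj_oracle, supp_oracle = brute_force_best_subset(design.X, z, fit.lambda_)
        b = fit.beta[design.candidate_bins]
        nz = tuple(np.flatnonzero(b))
        zc = z - z.mean()
        Xc = np.asarray(design.X.todense()) - np.asarray(design.X.mean(axis=0))
        r = zc - Xc @ b
        obj_fit = float(r @ r) / len(z) + fit.lambda_ * len(nz)
        assert nz == supp_oracle
        assert obj_fit == pytest.approx(obj_oracle, abs=1e-8)

    def test_deterministic_given_seed(self):
        z, design = self._random_problem(10, 400, seed=5)
        f1 = fit_best_subset(z, design, seed=7)
        f2 = fit_best_subset(z, design, seed=7)
        np.testing.assert_array_equal(f1.beta, f2.beta)
        assert f1.lambda_ == f2.lambda_

    def test_empty_candidate_set_gives_zero_fit(self):
        z, design = self._random_problem(5, 200, seed=2)
        empty = InsulationDesign(
            X=design.X[:, :0], candidate_bins=np.array([], dtype=int), p=design.p
        )
        fit = fit_best_subset(z, empty)
        assert np.all(fit.beta == 0)


class TestClassification:
    def _fit(self, betas):
        beta = np.zeros(10)
        for k, v in betas.items():
            beta[k] = v
        import pandas as pd

        return ir.sim_model.InsulationFit(
            beta=beta, intercept=0.0, lambda_=0.1,
            cv_curve=pd.DataFrame(), candidate_bins=np.arange(10),
        )

    def test_tiers_and_signs(self):
        fit = classify_borders(self._fit({1: -2.5, 2: -1.5, 3: -0.8, 4: 0.8}))
        assert fit.labels[1] == "strong"
        assert fit.labels[2] == "moderate"
        assert fit.labels[3] == "weak"
        assert fit.labels[4] == "facilitator"
        assert fit.labels[5] == "null"

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_borders(self._fit({}), strong=-1.0, moderate=-2.0)


class TestRunSim:
    def test_recovers_planted_effects(self, fixture_fit):
        from conftest import recovery_score

        fit, truth = fixture_fit
        hit_b, hit_f, fp = recovery_score(fit, truth["effects"])
        assert hit_b >= 7
        assert hit_f == 2
        assert fp <= 1

    def test_facilitator_recovered_with_positive_sign(self):
        spec = GenerativeSpec(p=100, effects={50: 1.5}, seed=21)
        m, _ = ir.generate_matrix(spec)
        fit = run_sim(m, seed=1789)
        sel = [b for b in fit.selected if abs(b - 50) <= 1]
        assert sel and all(fit.beta[b] > 0 for b in sel)

    def test_flat_matrix_selects_nothing(self):
        spec = GenerativeSpec(p=200, effects={}, seed=31)
        m, _ = ir.generate_matrix(spec)
        fit = run_sim(m, seed=1789)
        assert len(fit.selected) == 0

    def test_noiseless_signs_and_magnitudes(self):
        """With counts set exactly to the model mean, every planted effect
        is recovered with its sign and magnitude within 10%."""
        effects = {20: -2.0, 40: -1.2, 60: 1.2}
        spec = GenerativeSpec(p=80, effects=effects, seed=0, noise="none",
                              depth_gap1=20_000)
        m, _ = ir.generate_matrix(spec)
        fit = run_sim(m, seed=1789)
        for k, v in effects.items():
            assert fit.beta[k] == pytest.approx(v, rel=0.10)

    def test_reversal_symmetry(self, fixture_matrix):
        """Flipping the chromosome end-to-end reverses the beta profile."""
        m, _ = fixture_matrix
        fit = run_sim(m, seed=1789)
        rev = ContactMatrix(bins=m.bins, counts=m.counts[::-1, ::-1].copy())
        fit_rev = run_sim(rev, seed=1789)
        np.testing.assert_array_equal(
            np.sort(m.p - 1 - fit_rev.selected), fit.selected
        )
        np.testing.assert_allclose(
            fit_rev.beta[::-1], fit.beta, atol=0.15
        )

    def test_masked_bins_never_selected(self):
        spec = GenerativeSpec(p=100, effects={30: -2.0}, seed=13)
        m, _ = ir.generate_matrix(spec)
        counts = m.counts.copy()
        counts[60, :] = 0
        counts[:, 60] = 0
        m2 = ContactMatrix(bins=m.bins, counts=counts)
        fit = run_sim(m2, seed=1789)
        assert 60 not in fit.selected
        assert any(abs(b - 30) <= 1 for b in fit.selected)

    def test_output_frame_and_regions(self, fixture_fit):
        fit, _ = fixture_fit
        df = fit.to_frame()
        assert {"chrom", "start", "end", "beta", "class", "tier"} <= set(df.columns)
        assert (df.loc[df["beta"] < 0, "class"] == "border").all()
        regions = fit.border_regions()
        assert all(a <= b for a, b in regions)
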