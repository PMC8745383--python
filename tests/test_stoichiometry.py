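"""Convolution stoichiometry: density estimation, moment identities of
iterated convolution, exactness of the constrained decomposition, and
degree-of-labeling recovery on simulated populations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.optimize import minimize

from smls import stoichiometry as st
from smls.simulate import (
    FluorophoreModel, GFP_CONTEXT, JF646_CONTEXT, MixtureSpec, TailPolicy,
    sample_intensities,
)


@pytest.fixture(scope="module")
def p1_gfp():
    gfp = FluorophoreModel(157.0, 65.0)
    rng = np.random.default_rng(8)
    return st.estimate_pdf(gfp.draw(rng, 40_000), label="P1")


def slsqp_decompose(p_emp, family):
    """Independent oracle: SLSQP on the simplex-constrained LS problem."""
    A = np.stack([p.density for p in family], axis=1)
    b = p_emp.density
    n = A.shape[1]

    def cost(w):
        r = A @ w - b
        return r @ r

    res = minimize(cost, np.full(n, 1.0 / n), method="SLSQP",
                   bounds=[(0, 1)] * n,
                   constraints={"type": "eq", "fun": lambda w: w.sum() - 1.0},
                   options={"maxiter": 500, "ftol": 1e-14})
    return res.x


class TestEstimatePdf:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=hst.integers(0, 10_000),
           scale=hst.floats(10.0, 500.0),
           shape=hst.floats(1.0, 8.0))
    def test_integral_is_one(self, seed, scale, shape):
        x = np.random.default_rng(seed).gamma(shape, scale, size=120)
        d = st.estimate_pdf(x)
        assert d.integral() == pytest.approx(1.0, abs=1e-6)
        assert np.all(d.density >= 0)

    def test_mean_matches_sample(self, gfp):
        rng = np.random.default_rng(0)
        x = gfp.draw(rng, 100_000)
        d = st.estimate_pdf(x)
        assert d.mean == pytest.approx(157.0, abs=1.0)

    def test_identical_samples_narrow_peak(self):
        d = st.estimate_pdf(np.full(50, 300.0), c_max=600.0, grid_step=1.0)
        assert d.integral() == pytest.approx(1.0, abs=1e-6)
        assert abs(d.grid[np.argmax(d.density)] - 300.0) <= 2.0

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="at least 30"):
            st.estimate_pdf(np.arange(10.0))

    def test_truncnorm_method_recovers_moments(self, gfp):
        rng = np.random.default_rng(1)
        x = gfp.draw(rng, 20_000)
        d = st.estimate_pdf(x, method="truncnorm")
        assert d.mean == pytest.approx(157.0, abs=2.0)
        assert d.sd == pytest.approx(65.0, abs=2.0)


class TestConvolution:
    def test_delta_convolves_to_shifted_delta(self):
        grid = np.arange(0.0, 1000.0, 5.0)
        d = np.zeros_like(grid)
        d[20] = 1.0 / 5.0  # delta at C = 100
        p1 = st.DensityEstimate(grid, d, label="P1")
        p2 = st.convolve_next(p1, p1)
        assert p2.grid[np.argmax(p2.density)] == pytest.approx(200.0)

    def test_pairwise_sum_monte_carlo(self, p1_gfp, gfp):
        # oracle: empirical distribution of X1 + X2
        rng = np.random.default_rng(5)
        pairs = gfp.draw(rng, 200_000).reshape(-1, 2).sum(axis=1)
        p2 = st.convolve_next(p1_gfp, p1_gfp)
        assert p2.mean == pytest.approx(pairs.mean(), abs=1.5)
        assert p2.sd == pytest.approx(pairs.std(ddof=1), abs=2.0)

    def test_moment_identities_up_to_six(self, p1_gfp):
        """mean(Pn) = n mu1 and var(Pn) = n var1 within 0.5% for n <= 6."""
        fam = st.build_family(p1_gfp, 6)
        mu1, var1 = fam[0].mean, fam[0].sd ** 2
        for n, pn in enumerate(fam, start=1):
            assert pn.mean == pytest.approx(n * mu1, rel=5e-3)
            assert pn.sd ** 2 == pytest.approx(n * var1, rel=5e-3)

    def test_grid_mismatch_errors(self, p1_gfp):
        other = st.DensityEstimate(p1_gfp.grid[:-1], p1_gfp.density[:-1])
        with pytest.raises(ValueError, match="identical grids"):
            st.convolve_next(p1_gfp, other)

    def test_mass_loss_beyond_grid_errors(self, gfp):
        rng = np.random.default_rng(2)
        x = gfp.draw(rng, 1000)
        p1 = st.estimate_pdf(x, c_max=400.0, label="P1")  # too short for P2+
        with pytest.raises(ValueError, match="increase c_max"):
            st.build_family(p1, 4)


class TestAnchoring:
    def test_nmax_one_returns_p1(self, p1_gfp):
        fam = st.build_family(p1_gfp, 1)
        assert len(fam) == 1 and fam[0] is p1_gfp

    def test_symmetric_p1_anchoring_negligible(self, p1_gfp):
        plain = st.build_family(p1_gfp, 3, anchoring="none")
        anchored = st.build_family(p1_gfp, 3, anchoring="rescale-to-multiples")
        for a, b in zip(plain[1:], anchored[1:]):
            assert abs(a.mode - b.mode) <= 3 * p1_gfp.grid_step

    def test_skewed_p1_anchored_mode_at_multiple(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(2.0, 100.0, size=5000)  # strongly right-skewed
        p1 = st.estimate_pdf(x, label="P1")
        fam = st.build_family(p1, 3, anchoring="rescale-to-multiples")
        for n, pn in enumerate(fam[1:], start=2):
            assert pn.mode == pytest.approx(n * p1.mean, abs=p1.grid_step)


class TestDecompose:
    def test_identity_decomposition(self, p1_gfp):
        fam = st.build_family(p1_gfp, 4)
        res = st.decompose(fam[0], fam)
        assert res.weights[0] == pytest.approx(1.0, abs=1e-6)
        assert res.fit_residual < 1e-9

    def test_exact_on_grid_mixture_vs_slsqp_oracle(self, p1_gfp):
        fam = st.build_family(p1_gfp, 4)
        true_w = np.array([0.5, 0.5, 0.0, 0.0])
        mix = st.DensityEstimate(
            p1_gfp.grid,
            sum(w * p.density for w, p in zip(true_w, fam)))
        res = st.decompose(mix, fam)
        np.testing.assert_allclose(res.weights, true_w, atol=1e-6)
        assert res.fit_residual < 1e-9
        np.testing.assert_allclose(res.weights, slsqp_decompose(mix, fam),
                                   atol=1e-5)

    def test_random_convex_combinations_vs_oracle(self, p1_gfp):
        fam = st.build_family(p1_gfp, 5)
        rng = np.random.default_rng(6)
        for _ in range(5):
            w = rng.dirichlet(np.ones(5))
            mix = st.DensityEstimate(
                p1_gfp.grid, sum(wi * p.density for wi, p in zip(w, fam)))
            res = st.decompose(mix, fam)
            np.testing.assert_allclose(res.weights, w, atol=1e-6)

    def test_duplicate_family_members_collapsed(self, p1_gfp):
        fam = st.build_family(p1_gfp, 2)
        degenerate = [fam[0], fam[0], fam[1]]
        with pytest.warns(UserWarning, match="duplicates"):
            res = st.decompose(fam[0], degenerate)
        assert res.weights[0] == pytest.approx(1.0, abs=1e-6)
        assert res.weights[1] == 0.0

    def test_weights_sum_to_one(self, p1_gfp, rng):
        fam = st.build_family(p1_gfp, 4)
        noisy = st.DensityEstimate(
            p1_gfp.grid,
            np.maximum(fam[1].density + rng.normal(0, 1e-4, p1_gfp.grid.size), 0))
        res = st.decompose(noisy, fam)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestDolReport:
    def test_single_class(self):
        res = st.StoichiometryResult(np.array([1, 0, 0, 0, 0, 0.0]), 0.0, 6)
        df = st.dol_report(res, aggregate_at=4)
        assert list(df["percent"]) == [100.0, 0.0, 0.0, 0.0]

    def test_tail_aggregation_arithmetic(self):
        w = np.array([0.36, 0.19, 0.03, 0.20, 0.12, 0.10])
        res = st.StoichiometryResult(w, 0.0, 6)
        df = st.dol_report(res, aggregate_at=4)
        assert df.iloc[-1]["percent"] == pytest.approx(42.0)
        assert df["fraction"].sum() == pytest.approx(1.0)


class TestComparePopulations:
    def test_self_comparison_is_single(self, gfp):
        rng = np.random.default_rng(10)
        ref = gfp.draw(rng, 1000)
        samples = gfp.draw(rng, 1000)
        res = st.compare_populations(ref, samples)
        assert res.weights[0] >= 0.9

    def test_pairwise_sums_are_double(self, gfp):
        rng = np.random.default_rng(11)
        ref = gfp.draw(rng, 1000)
        samples = gfp.draw(rng, 2000).reshape(-1, 2).sum(axis=1)
        res = st.compare_populations(ref, samples)
        assert np.argmax(res.weights) == 1
        assert res.weights[1] >= 0.7

    def test_aggregated_population_recovery(self, gfp):
        """In-cell style aggregation mixture (23% single, 46% double,
        31% higher): per-class recovery within 6 points, averaged over
        seeds."""
        weights = (0.23, 0.46, 0.21, 0.10)
        mix = MixtureSpec(weights, TailPolicy("fixed", 4))
        recovered = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            ref = gfp.draw(rng, 500)
            samples, _ = sample_intensities(mix, gfp, 600, rng)
            res = st.compare_populations(ref, samples, n_max=6)
            recovered.append([res.weights[0], res.weights[1],
                              res.weights[2:].sum()])
        mean_rec = np.mean(recovered, axis=0)
        assert abs(mean_rec[0] - 0.23) < 0.06
        assert abs(mean_rec[1] - 0.46) < 0.06
        assert abs(mean_rec[2] - 0.31) < 0.06


class TestRecoveryProperties:
    def test_weight_recovery_mae(self, gfp):
        """Mixtures over n in 1..4 at the on-glass sample size (392):
        mean absolute error of each recovered weight <= 0.05 over
        seeds."""
        true_w = (0.6, 0.25, 0.1, 0.05)
        mix = MixtureSpec(true_w, TailPolicy("fixed", 4))
        errs = []
        for seed in range(25):
            rng = np.random.default_rng(2000 + seed)
            ref = gfp.draw(rng, 247)
            samples, _ = sample_intensities(mix, gfp, 392, rng)
            res = st.compare_populations(ref, samples, n_max=6)
            w4 = np.concatenate([res.weights[:3], [res.weights[3:].sum()]])
            errs.append(np.abs(w4 - np.array(true_w)))
        mae = np.mean(errs, axis=0)
        assert np.all(mae <= 0.05)

    def test_recovery_degrades_with_brightness_cv(self):
        """Identifiability worsens monotonically as the single-
        fluorophore brightness cv grows."""
        true_w = np.array([0.5, 0.3, 0.15, 0.05])
        mix = MixtureSpec(tuple(true_w), TailPolicy("fixed", 4))
        maes = []
        for cv in (0.2, 0.4, 0.8):
            fluor = FluorophoreModel(157.0, cv * 157.0)
            errs = []
            for seed in range(12):
                rng = np.random.default_rng(3000 + seed)
                ref = fluor.draw(rng, 500)
                samples, _ = sample_intensities(mix, fluor, 500, rng)
                res = st.compare_populations(ref, samples, n_max=6)
                w4 = np.concatenate([res.weights[:3], [res.weights[3:].sum()]])
                errs.append(np.abs(w4 - true_w).mean())
            maes.append(np.mean(errs))
        assert maes[0] < maes[1] < maes[2]


class TestNormalizedRatio:
    def test_identical_inputs_unity(self):
        assert st.normalized_signal_ratio(157.0, GFP_CONTEXT,
                                          157.0, GFP_CONTEXT) == 1.0

    def test_jf646_vs_gfp_worked_example(self):
        r = st.normalized_signal_ratio(1445.0, JF646_CONTEXT,
                                       157.0, GFP_CONTEXT)
        assert r == pytest.approx(3.35, abs=0.01)

    def test_linearity_in_illumination_time(self):
        from smls.simulate import AcquisitionContext
        ctx2 = AcquisitionContext(t_ill=2 * JF646_CONTEXT.t_ill,
                                  laser_intensity=JF646_CONTEXT.laser_intensity)
        r1 = st.normalized_signal_ratio(1445.0, JF646_CONTEXT, 157.0, GFP_CONTEXT)
        r2 = st.normalized_signal_ratio(1445.0, ctx2, 157.0, GFP_CONTEXT)
        assert r2 == pytest.approx(r1 / 2)

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError):
            st.normalized_signal_ratio(0.0, GFP_CONTEXT, 157.0, GFP_CONTEXT)
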