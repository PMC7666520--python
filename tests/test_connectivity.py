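"""Seed covariance (IRCA), goodness-of-fit, and the interaction analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neurocovar.connectivity import (
    CANONICAL_SEEDS,
    CovarianceMap,
    NetworkTemplate,
    SeedSlopeModel,
    SlopeInteractionModel,
    gof_profile,
    goodness_of_fit,
    interaction_analysis,
    irca_covariance_map,
)
from neurocovar.errors import (
    ConfigurationError,
    EmptyROIError,
    PartitionError,
    SampleSizeError,
)
from neurocovar.glm import TMap
from neurocovar.simulate import SimulationConfig, generate_masks, simulate_fdg_cohort
from neurocovar.volume import BinaryMask, VolumeGrid

from conftest import full_mask


def simple_regression_t(x, y):
    """Oracle: simple-regression slope t via closed form."""
    x = x - x.mean()
    beta = (x @ y) / (x @ x)
    resid = y - y.mean() - beta * x
    df = len(y) - 2
    se = np.sqrt(resid @ resid / df / (x @ x))
    return beta / se


def partial_corr_t(r, df):
    return r * np.sqrt(df / (1 - r**2))


class TestSeedSlopeModel:
    def test_near_deterministic_coupling_gives_huge_t(self, rng):
        n = 10
        seed = rng.normal(size=n)
        Y = (2.0 * seed)[:, None] + rng.normal(0, 1e-8, (n, 5))
        model = SeedSlopeModel().fit(seed[:, None], Y)
        assert np.all(model.t_ > 100)

    def test_null_seed_slope_t_is_student_t(self, rng):
        """Independent voxels: seed-slope t (adjusted for 2 covariates)
        follows Student-t with df = n - 4 (intercept+seed+2 covariates)."""
        n, v = 30, 500
        X = np.column_stack([rng.normal(size=n), rng.normal(size=n), rng.integers(0, 2, n)])
        Y = rng.normal(size=(n, v))
        model = SeedSlopeModel().fit(X, Y)
        assert model.df_ == n - 4
        ks = stats.kstest(model.t_, stats.t(df=model.df_).cdf)
        assert ks.pvalue > 0.01

    def test_matches_partial_correlation_transform(self, rng):
        """Seed-slope t equals the partial-correlation-to-t transform on
        random instances (two nuisance covariates)."""
        for _ in range(20):
            n = 25
            X = np.column_stack([rng.normal(size=n), rng.normal(size=n), rng.normal(size=n)])
            y = rng.normal(size=n)
            model = SeedSlopeModel().fit(X, y[:, None])
            # oracle: residualize seed and y on [1, covs], correlate
            Z = np.column_stack([np.ones(n), X[:, 1:]])
            P = np.eye(n) - Z @ np.linalg.pinv(Z)
            rs, ry = P @ X[:, 0], P @ y
            r = rs @ ry / np.sqrt((rs @ rs) * (ry @ ry))
            assert model.t_[0] == pytest.approx(partial_corr_t(r, model.df_), abs=1e-8)

    def test_simple_regression_matches_closed_form(self, rng):
        n = 15
        seed = rng.normal(size=n)
        y = 0.5 * seed + rng.normal(size=n)
        model = SeedSlopeModel().fit(seed[:, None], y[:, None])
        assert model.t_[0] == pytest.approx(simple_regression_t(seed, y), abs=1e-10)

    def test_group_too_small_raises(self, rng):
        with pytest.raises(SampleSizeError):
            SeedSlopeModel().fit(rng.normal(size=(3, 3)), rng.normal(size=(3, 2)))


class TestGoodnessOfFit:
    def _covmap(self, grid, t, df=25):
        return CovarianceMap("g", CANONICAL_SEEDS["PCC"], TMap(grid, t, df))

    def _template(self, grid, sl):
        m = np.zeros(grid.shape, dtype=bool)
        m[sl] = True
        return NetworkTemplate("net", BinaryMask(grid, m))

    def test_indicator_map(self, small_grid):
        tpl = self._template(small_grid, np.s_[0:4])
        t = np.where(tpl.mask.membership, 3.5, 0.0)
        score = goodness_of_fit(self._covmap(small_grid, t), tpl, full_mask(small_grid))
        assert score.t_inside == pytest.approx(3.5)
        assert score.t_outside == pytest.approx(0.0)
        assert score.gof == pytest.approx(3.5)

    def test_constant_map_gof_zero(self, small_grid):
        tpl = self._template(small_grid, np.s_[0:4])
        t = np.full(small_grid.shape, 1.7)
        score = goodness_of_fit(self._covmap(small_grid, t), tpl, full_mask(small_grid))
        assert score.gof == pytest.approx(0.0)

    def test_four_voxel_hand_arithmetic(self):
        grid = VolumeGrid((4, 1, 1), np.eye(4))
        t = np.array([3.0, 1.0, 0.0, -2.0]).reshape(4, 1, 1)
        tpl = self._template(grid, np.s_[0:2])
        score = goodness_of_fit(self._covmap(grid, t), tpl, full_mask(grid))
        assert score.t_inside == pytest.approx(2.0)
        assert score.t_outside == pytest.approx(-1.0)
        assert score.gof == pytest.approx(3.0)

    def test_shift_invariance_exact(self, small_grid, rng):
        t = rng.normal(size=small_grid.shape)
        tpl = self._template(small_grid, np.s_[2:6])
        mask = full_mask(small_grid)
        g0 = goodness_of_fit(self._covmap(small_grid, t), tpl, mask).gof
        g1 = goodness_of_fit(self._covmap(small_grid, t + 7.3), tpl, mask).gof
        assert g1 == pytest.approx(g0, abs=1e-10)

    def test_linearity_in_tmap(self, small_grid, rng):
        t1 = rng.normal(size=small_grid.shape)
        t2 = rng.normal(size=small_grid.shape)
        tpl = self._template(small_grid, np.s_[2:6])
        mask = full_mask(small_grid)
        a, b = 2.5, -1.25
        g = goodness_of_fit(self._covmap(small_grid, a * t1 + b * t2), tpl, mask).gof
        g1 = goodness_of_fit(self._covmap(small_grid, t1), tpl, mask).gof
        g2 = goodness_of_fit(self._covmap(small_grid, t2), tpl, mask).gof
        assert g == pytest.approx(a * g1 + b * g2, rel=1e-10)

    def test_template_covering_mask_raises(self, small_grid, rng):
        tpl = NetworkTemplate("all", full_mask(small_grid))
        covmap = self._covmap(small_grid, rng.normal(size=small_grid.shape))
        with pytest.raises(PartitionError):
            goodness_of_fit(covmap, tpl, full_mask(small_grid))


class TestGofProfile:
    def test_composition_and_duplicate_templates(self, small_grid, rng):
        t = rng.normal(size=small_grid.shape)
        cov = {("bvAD", "PCC"): CovarianceMap(
            "bvAD", CANONICAL_SEEDS["PCC"], TMap(small_grid, t, 25)
        )}
        m = np.zeros(small_grid.shape, dtype=bool)
        m[0:3] = True
        tpl = NetworkTemplate("pDMN", BinaryMask(small_grid, m))
        tpl2 = NetworkTemplate("pDMN2", BinaryMask(small_grid, m.copy()))
        table = gof_profile(
            cov, {"pDMN": tpl, "pDMN2": tpl2}, full_mask(small_grid),
            pairing={"pDMN": "PCC", "pDMN2": "PCC"},
        )
        assert len(table) == 2
        direct = goodness_of_fit(cov[("bvAD", "PCC")], tpl, full_mask(small_grid))
        assert table.loc[0, "gof"] == pytest.approx(direct.gof)
        # identical masks -> identical GOF
        assert table["gof"].nunique() == 1

    def test_missing_pairing_raises(self, small_grid, rng):
        cov = {("bvAD", "PCC"): CovarianceMap(
            "bvAD", CANONICAL_SEEDS["PCC"],
            TMap(small_grid, rng.normal(size=small_grid.shape), 25),
        )}
        m = np.zeros(small_grid.shape, dtype=bool)
        m[0] = True
        tpl = NetworkTemplate("mystery", BinaryMask(small_grid, m))
        with pytest.raises(ConfigurationError):
            gof_profile(cov, {"mystery": tpl}, full_mask(small_grid), pairing={})

    def test_pdmn_coupling_recovered_for_pcc_seed(self):
        """Cohorts whose covariance is driven only by the pDMN latent
        factor: the pDMN GOF is the maximum across networks for the PCC
        seed in >= 95% of simulation seeds."""
        wins = 0
        n_seeds = 20
        couplings = {g: {"pDMN": 0.10, "aDMN": 0.0, "SN": 0.0, "ECN": 0.0}
                     for g in ("bvAD", "tAD", "bvFTD", "CN")}
        for s in range(n_seeds):
            cfg = SimulationConfig(
                rng_seed=1000 + s,
                couplings=couplings,
                depths={g: {} for g in ("bvAD", "tAD", "bvFTD", "CN")},
                regional_sigma=0.0,
                global_gm_sigma=0.0,
                group_sizes={"bvAD": 20, "tAD": 4, "bvFTD": 4, "CN": 4},
            )
            cohort, scans, masks, templates, _, _ = simulate_fdg_cohort(cfg)
            rows = cohort[cohort["group"] == "bvAD"]
            cov = irca_covariance_map(
                scans, rows, CANONICAL_SEEDS["PCC"], masks["gm"]
            )
            gofs = {
                name: goodness_of_fit(cov, tpl, masks["gm"]).gof
                for name, tpl in templates.items()
            }
            if max(gofs, key=gofs.get) == "pDMN":
                wins += 1
        assert wins >= 0.95 * n_seeds

    def test_seed_sphere_outside_gm_raises(self, template_grid):
        grid = template_grid
        masks = generate_masks(grid)
        # restrict GM to a corner far from the PCC seed
        m = np.zeros(grid.shape, dtype=bool)
        m[:3, :3, :3] = True
        gm = BinaryMask(grid, m)
        cohort = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(10)],
                "group": ["bvAD"] * 10,
                "age": np.linspace(55, 75, 10),
                "sex": [0, 1] * 5,
            }
        )
        rng = np.random.default_rng(0)
        from neurocovar.volume import ScalarVolume

        scans = {
            f"s{i}": ScalarVolume(grid, rng.normal(size=grid.shape)) for i in range(10)
        }
        with pytest.raises(EmptyROIError):
            irca_covariance_map(scans, cohort, CANONICAL_SEEDS["PCC"], gm)


class TestInteraction:
    def _fit(self, slope_a, slope_b, n=25, sigma=0.05, seed=0, v=40):
        rng = np.random.default_rng(seed)
        seed_vals = rng.normal(1.0, 0.1, 2 * n)
        gb = np.r_[np.zeros(n, bool), np.ones(n, bool)]
        slopes = np.where(gb, slope_b, slope_a)
        cov = np.column_stack([rng.normal(65, 9, 2 * n), rng.integers(0, 2, 2 * n)])
        Y = slopes[:, None] * seed_vals[:, None] + rng.normal(0, sigma, (2 * n, v))
        return SlopeInteractionModel().fit(seed_vals, gb, cov, Y)

    def test_null_slopes_calibrated(self):
        """Identical seed slopes in both groups: ~alpha of voxels pass at
        either threshold."""
        rates = {0.001: [], 0.05: []}
        for s in range(20):
            model = self._fit(1.0, 1.0, sigma=1.0, seed=s, v=200)
            for alpha in rates:
                crit = stats.t.ppf(1 - alpha / 2, model.df_)
                rates[alpha].append(np.mean(np.abs(model.t_) > crit))
        assert np.mean(rates[0.05]) == pytest.approx(0.05, abs=0.02)
        assert np.mean(rates[0.001]) == pytest.approx(0.001, abs=0.003)

    def test_power_at_stated_effect(self):
        """Slope 1.0 vs 0.0, small noise, n=25/25: differing voxels pass
        p<0.001 in >= 95% of seeds."""
        hits = 0
        n_seeds = 40
        for s in range(n_seeds):
            model = self._fit(1.0, 0.0, n=25, sigma=0.05, seed=100 + s, v=5)
            crit = stats.t.ppf(1 - 0.001 / 2, model.df_)
            if np.all(np.abs(model.t_) > crit):
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_group_relabel_negates_tmap(self, rng):
        n = 15
        seed_vals = rng.normal(1.0, 0.1, 2 * n)
        gb = np.r_[np.zeros(n, bool), np.ones(n, bool)]
        cov = rng.normal(size=(2 * n, 2))
        Y = rng.normal(size=(2 * n, 30))
        m1 = SlopeInteractionModel().fit(seed_vals, gb, cov, Y)
        m2 = SlopeInteractionModel().fit(seed_vals, ~gb, cov, Y)
        np.testing.assert_allclose(m1.t_, -m2.t_, atol=1e-10)

    def test_end_to_end_interaction_on_synthetic_cohort(self):
        cfg = SimulationConfig(
            rng_seed=5,
            group_sizes={"bvAD": 12, "tAD": 12, "bvFTD": 4, "CN": 4},
        )
        cohort, scans, masks, _, _, _ = simulate_fdg_cohort(cfg)
        res = interaction_analysis(
            scans, cohort, ("bvAD", "tAD"), CANONICAL_SEEDS["PCC"], masks["gm"]
        )
        assert res.tmap.df == 24 - 6
        res_swap = interaction_analysis(
            scans, cohort, ("tAD", "bvAD"), CANONICAL_SEEDS["PCC"], masks["gm"]
        )
        np.testing.assert_allclose(
            res.tmap.t_values, -res_swap.tmap.t_values, atol=1e-8
        )
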