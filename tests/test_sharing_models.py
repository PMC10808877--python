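"""Collinearity screening, component reduction, mixed fits, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as smapi

from ecobarriers import pair_assembly as pa
from ecobarriers import sharing_models as sm
from ecobarriers.synthetic_world import (
    WorldConfig,
    generate_world,
    simulate_pair_sharing,
)


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        # centered harmonics on a uniform grid are exactly orthogonal
        t = np.linspace(0, 2 * np.pi, 201)[:-1]
        x = np.column_stack([np.cos(t), np.sin(t), np.cos(2 * t), np.sin(2 * t)])
        out = sm.vif(pd.DataFrame(x, columns=list("abcd")))
        assert np.allclose(out, 1.0, atol=1e-10)

    def test_duplicated_column_infinite(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(100, 2))
        df = pd.DataFrame(np.column_stack([x, x[:, 0]]), columns=["a", "b", "a2"])
        out = sm.vif(df)
        assert np.isinf(out["a"]) and np.isinf(out["a2"])
        assert np.isfinite(out["b"])

    def test_bivariate_correlation_closed_form(self):
        """r = 0.9 between two columns gives VIF = 1/(1-0.81) ~ 5.26."""
        rng = np.random.default_rng(2)
        n = 100000
        z = rng.normal(size=n)
        a = z
        b = 0.9 * z + np.sqrt(1 - 0.81) * rng.normal(size=n)
        c = rng.normal(size=n)
        out = sm.vif(pd.DataFrame({"a": a, "b": b, "c": c}))
        assert out["a"] == pytest.approx(5.263, abs=0.15)
        assert out["c"] == pytest.approx(1.0, abs=0.05)


def _block_data(n=2000, seed=0, noise=0.3):
    """Five latent factors, each driving one block of the 11 raw predictors."""
    rng = np.random.default_rng(seed)
    f = {name: rng.normal(size=n) for name in sm.COMPONENT_NAMES}
    cols = {}
    for name, block in sm._COMPONENT_BLOCKS.items():
        for var in block:
            cols[var] = f[name] + noise * rng.normal(size=n)
    return pd.DataFrame(cols)[sm.RAW_PREDICTORS]


class TestVarimax:
    def test_block_factors_recovered(self):
        comps = sm.varimax_components(_block_data())
        for name, block in sm._COMPONENT_BLOCKS.items():
            own = comps.loadings.loc[block, name].abs().min()
            others = [c for c in sm.COMPONENT_NAMES if c != name]
            cross = comps.loadings.loc[block, others].abs().max().max()
            assert own >= 0.7, f"{name} own-block loading {own}"
            assert cross < 0.4, f"{name} cross loading {cross}"

    def test_sign_anchoring_dominant_positive(self):
        comps = sm.varimax_components(_block_data(seed=3))
        for c in comps.loadings.columns:
            dom = comps.loadings[c].abs().idxmax()
            assert comps.loadings.at[dom, c] > 0

    def test_scores_standardized_and_uncorrelated(self):
        comps = sm.varimax_components(_block_data(seed=1))
        s = comps.scores.to_numpy()
        assert np.allclose(s.mean(axis=0), 0, atol=1e-8)
        assert np.allclose(s.std(axis=0, ddof=1), 1, atol=1e-8)
        corr = np.corrcoef(s, rowvar=False)
        off = corr[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() <= 0.1

    def test_rotation_preserves_retained_variance(self):
        """Varimax is orthogonal: total squared loading mass is invariant."""
        raw = _block_data(seed=2)
        comps = sm.varimax_components(raw)
        x = raw.to_numpy()
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        _, s, _ = np.linalg.svd(xs, full_matrices=False)
        unrotated = (s[:5] ** 2).sum() / (len(x) - 1)
        rotated = (comps.loadings.to_numpy() ** 2).sum()
        assert rotated == pytest.approx(unrotated, rel=1e-8)

    def test_deterministic_rerun(self):
        raw = _block_data(seed=5)
        a = sm.varimax_components(raw)
        b = sm.varimax_components(raw)
        pd.testing.assert_frame_equal(a.loadings, b.loadings)
        pd.testing.assert_frame_equal(a.scores, b.scores)


def _dyadic_design(n_pairs=2000, n_soc=150, seed=0):
    """World-derived pair covariates for mixed-model simulations."""
    cfg = WorldConfig(
        grid_n_lat=12, grid_n_lon=16, lat_range=(10.0, 58.0),
        lon_range=(0.0, 64.0), years=20, n_societies=n_soc, seed=seed,
    )
    w = generate_world(cfg)
    pairs = pa.nearest_pairs(w.societies, k=40)
    idx = {s: i for i, s in enumerate(w.societies["id"])}
    a = pairs["id_a"].map(idx).to_numpy()
    b = pairs["id_b"].map(idx).to_numpy()
    th = w.th_by_society
    z = lambda v: (v - v.mean()) / v.std()
    x = np.column_stack(
        [z(pairs["geodesic_km"].to_numpy()), z(np.abs(th[a] - th[b]))]
    )
    rng = np.random.default_rng(seed + 1000)
    sel = rng.choice(len(pairs), min(n_pairs, len(pairs)), replace=False)
    return (
        pd.DataFrame(x[sel], columns=["z_dist", "z_th"]),
        pairs["id_a"].to_numpy()[sel],
        pairs["id_b"].to_numpy()[sel],
    )


class TestMixedLogit:
    def test_zero_variance_world_matches_plain_glm(self):
        design, ida, idb = _dyadic_design(seed=5)
        y = simulate_pair_sharing(
            np.column_stack([np.ones(len(design)), design.to_numpy()]),
            np.array([0.2, -0.4, -0.6]),
            ida, idb, 0.0, np.random.default_rng(5),
        )
        fit = sm.fit_mixed_logit(y, design, ida, idb)
        glm = smapi.GLM(
            y, smapi.add_constant(design.to_numpy()),
            family=smapi.families.Binomial(),
        ).fit()
        assert np.abs(fit.params.to_numpy() - glm.params).max() < 1e-2
        assert fit.sigma2 < 0.05

    def test_matches_frozen_glmer_oracle(self):
        """Independent check against lme4::glmer on a fixed simulated set.

        The reference model estimates two crossed variances where ours
        shares one, so agreement is to ~0.1 on the fixed effects.
        """
        cfg = WorldConfig(
            grid_n_lat=12, grid_n_lon=16, years=20, n_societies=60, seed=11
        )
        w = generate_world(cfg)
        pairs = pa.nearest_pairs(w.societies, k=20)
        idx = {s: i for i, s in enumerate(w.societies["id"])}
        a = pairs["id_a"].map(idx).to_numpy()
        b = pairs["id_b"].map(idx).to_numpy()
        th = w.th_by_society
        z = lambda v: (v - v.mean()) / v.std()
        x = np.column_stack(
            [z(pairs["geodesic_km"].to_numpy()), z(np.abs(th[a] - th[b]))]
        )
        rng = np.random.default_rng(99)
        sel = rng.choice(len(pairs), 600, replace=False)
        y = simulate_pair_sharing(
            np.column_stack([np.ones(600), x[sel]]),
            np.array([-0.2, -0.5, -0.7]),
            pairs["id_a"].to_numpy()[sel],
            pairs["id_b"].to_numpy()[sel],
            0.8,
            np.random.default_rng(7),
        )
        fit = sm.fit_mixed_logit(
            y, pd.DataFrame(x[sel], columns=["x1", "x2"]),
            pairs["id_a"].to_numpy()[sel], pairs["id_b"].to_numpy()[sel],
        )
        # glmer(y ~ x1 + x2 + (1|a) + (1|b), family=binomial) on this dataset
        glmer_params = {"intercept": -0.6051, "x1": -0.5731, "x2": -0.6204}
        glmer_se = {"intercept": 0.1849, "x1": 0.1246, "x2": 0.1375}
        for name, val in glmer_params.items():
            assert fit.params[name] == pytest.approx(val, abs=0.1)
        for name, val in glmer_se.items():
            assert fit.se[name] == pytest.approx(val, abs=0.05)
        # glmer variances: a 0.443, b 0.641; shared variance lies between
        assert 0.3 < fit.sigma2 < 0.9

    def test_parameter_recovery_with_random_effects(self):
        design, ida, idb = _dyadic_design(seed=2)
        ests = []
        for rep in range(5):
            y = simulate_pair_sharing(
                np.column_stack([np.ones(len(design)), design.to_numpy()]),
                np.array([-0.5, -0.3, -0.8]),
                ida, idb, 0.7, np.random.default_rng(300 + rep),
            )
            fit = sm.fit_mixed_logit(y, design, ida, idb)
            ests.append(fit.params["z_th"])
        assert np.mean(ests) == pytest.approx(-0.8, abs=0.25)

    def test_rejects_nonbinary_response(self):
        design, ida, idb = _dyadic_design(seed=3)
        with pytest.raises(ValueError):
            sm.fit_mixed_logit(
                np.full(len(design), 0.5), design, ida, idb
            )


class TestFiltersAndFdr:
    @pytest.mark.parametrize(
        "n,frac,conv,expected_included",
        [
            (500, 0.95, True, False),  # imbalanced
            (49, 0.5, True, False),  # too few datapoints
            (500, 0.5, False, False),  # non-convergence
            (500, 0.5, True, True),
        ],
    )
    def test_exclusion_rules(self, n, frac, conv, expected_included):
        included, _ = sm.model_filters(n, frac, conv)
        assert included is expected_included

    def test_by_adjustment_hand_example(self):
        adj = sm.adjust_fdr(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(adj, [0.055, 0.055, 0.055], atol=1e-12)

    def test_single_p_scaled_by_c1(self):
        # m=1: BY factor c(1)=1, adjusted = p
        assert sm.adjust_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert np.allclose(sm.adjust_fdr(np.ones(5)), 1.0)

    def test_adjustment_never_decreases(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        adj = sm.adjust_fdr(p)
        assert (adj >= p - 1e-12).all()


class TestAuc:
    def test_perfect_separation(self):
        assert sm.auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_three_point_fixtures(self):
        scores = np.array([0.9, 0.8, 0.3])
        assert sm.auc(np.array([1, 0, 0]), scores) == 1.0
        assert sm.auc(np.array([1, 0, 1]), scores) == 0.5

    def test_ties_count_half(self):
        assert sm.auc(np.array([1, 0]), np.array([0.5, 0.5])) == 0.5

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 10000)
        s = rng.normal(size=10000)
        assert sm.auc(y, s) == pytest.approx(0.5, abs=0.02)

    def test_single_class_undefined(self):
        assert np.isnan(sm.auc(np.ones(5), np.arange(5)))


class TestCorrelogram:
    def _midpoints(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"lat": rng.uniform(0, 30, n), "lon": rng.uniform(0, 30, n)}
        )

    def test_planted_gradient_detected_in_first_bin(self):
        mids = self._midpoints(150)
        resid = mids["lat"].to_numpy() / 30.0  # smooth spatial trend
        cg = sm.morans_correlogram(resid, mids, n_bins=5, n_perm=99, seed=1)
        first = cg.table.iloc[0]
        assert first["morans_i"] > 0
        assert first["p_value"] < 0.05

    def test_iid_residuals_mostly_null(self):
        rng = np.random.default_rng(3)
        mids = self._midpoints(120, seed=4)
        hits = 0
        for rep in range(10):
            cg = sm.morans_correlogram(
                rng.normal(size=120), mids, n_bins=5, n_perm=99, seed=rep
            )
            hits += int(cg.table.iloc[0]["p_value"] < 0.05)
        assert hits <= 2

    def test_degenerate_variance_flagged(self):
        mids = self._midpoints(30)
        cg = sm.morans_correlogram(np.zeros(30), mids, n_bins=1, n_perm=19)
        assert cg.table["flagged"].all()


class TestFullPipelineSignRecovery:
    def test_injected_negative_env_effect_recovers_sign(self):
        """Trait histories with strongly env-biased horizontal copying yield
        a negative temperature-turnover coefficient in >= 90% of 20 worlds."""
        from ecobarriers import cost_paths as cp
        from ecobarriers.synthetic_world import evolve_traits, generate_world

        negative = 0
        for rep in range(20):
            cfg = WorldConfig(
                grid_n_lat=15, grid_n_lon=20, years=20, n_societies=150,
                seed=600 + rep, beta_env=-3.0, beta_dist=-0.5,
                mu_vertical=0.4, alpha_horizontal=0.5, donor_pool_size=15,
            )
            w = generate_world(cfg)
            graph = cp.build_graph(w.th)
            th = cp.node_env_values(graph, w.th)
            ai = cp.node_env_values(graph, w.ai)
            elev = cp.node_env_values(graph, w.elevation)
            pairs = pa.nearest_pairs(w.societies, k=30)
            bar = cp.compute_pair_barriers(w.societies, pairs, graph, th, ai, elev)
            cov = bar.assign(relatedness=pa.relatedness(w.tree, bar).to_numpy())
            tt = evolve_traits(w.tree, w.societies, w.th_by_society, cfg)
            share = pa.score_sharing(tt, "T000", cov)
            trans = pa.neighbor_transmission(cov, w.societies, tt, "T000")
            sub = cov.assign(
                share=share.to_numpy(), neighbor_transmission=trans.to_numpy()
            )
            fit, _ = sm.fit_trait(sub, "T000")
            negative += int(fit.params["temp_turnover"] < 0)
        assert negative >= 18


class TestFitTrait:
    def test_too_few_rows_excluded(self, small_barriers, small_world):
        data = small_barriers.head(30).copy()
        data["relatedness"] = 1.0 + np.arange(len(data)) * 0.01
        data["neighbor_transmission"] = np.linspace(0, 1, len(data))
        data["share"] = np.tile([0, 1], 15)
        fit, comps = sm.fit_trait(data, "tiny")
        assert fit.included is False
        assert "fewer than 50" in fit.exclusion_reason
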