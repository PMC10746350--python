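"""Model ladder structure, likelihood oracles, gradients, priors and
small-scale parameter recovery."""

import numpy as np
import pytest
from scipy.stats import norm

import nestvar as nv
from nestvar.dhglm import DhglmModel, _cpc_alphas, chol_from_cpc, chol_from_cpc_grad

from conftest import spec_by_name


# ---------------------------------------------------------------------------
# ladder structure
# ---------------------------------------------------------------------------

def test_ladder_has_nine_models_with_expected_structure():
    ladder = nv.build_ladder()
    assert [s.name for s in ladder] == [f"m1{c}" for c in "abcdefghi"]
    by_name = {s.name: s for s in ladder}
    assert by_name["m1a"].mean_random == frozenset()
    assert by_name["m1c"].mean_random == frozenset({"pair"})
    m1f = by_name["m1f"]
    assert "year_age_slope" in m1f.mean_random and not m1f.correlated
    assert by_name["m1g"].correlated and "year_age_slope" not in by_name["m1g"].mean_random
    assert by_name["m1h"].correlated
    assert "year_brood_slope" in by_name["m1i"].mean_random
    # every model carries the sigma model with a year random intercept
    for s in ladder:
        assert s.sigma_random == frozenset({"year"})
        assert any(
            b.group == "year" and "sigma_intercept" in b.terms for b in s.blocks()
        )


def test_correlated_specs_have_joint_year_block():
    by_name = {s.name: s for s in nv.build_ladder()}
    blocks = {b.group: b for b in by_name["m1h"].blocks() if b.correlated}
    assert blocks["year"].terms == ("mu_intercept", "mu_age", "sigma_intercept")
    assert {b.key for b in by_name["m1f"].blocks()} == {
        "site:mu_intercept",
        "pair:mu_intercept",
        "year:mu_intercept",
        "year:mu_age",
        "year:sigma_intercept",
    }


def test_across_pairs_moves_slope_and_sigma_to_pair_level():
    spec = nv.across_pairs_spec()
    assert spec.correlated and spec.pair_age_slope
    corr_blocks = [b for b in spec.blocks() if b.correlated]
    assert len(corr_blocks) == 1
    assert corr_blocks[0].group == "pair"
    assert corr_blocks[0].terms == ("mu_intercept", "mu_age", "sigma_intercept")
    # year and site intercepts retained in the mean part
    keys = {b.key for b in spec.blocks()}
    assert {"site:mu_intercept", "year:mu_intercept"} <= keys
    # differs from m1h only in the grouping of the slope/sigma effects
    m1h = spec_by_name("m1h")
    assert {b.terms for b in m1h.blocks()} == {b.terms for b in spec.blocks()}


def test_spec_yaml_round_trip():
    for spec in nv.build_ladder() + [nv.across_pairs_spec()]:
        assert nv.ModelSpec.from_yaml(spec.to_yaml()) == spec


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_loglik_standard_normal_closed_form(small_frame):
    spec = spec_by_name("m1a")
    model = DhglmModel(small_frame, spec)
    theta = np.zeros(model.n_params)  # beta, effects, log sd all zero; gamma0 = 0
    ll = nv.log_likelihood(theta, small_frame, spec)
    assert np.allclose(ll, norm.logpdf(small_frame.log_ivi))


@pytest.mark.parametrize("name", ["m1a", "m1d", "m1f", "m1h", "m1i", "across_pairs"])
def test_loglik_matches_naive_scalar_loop(small_frame, name):
    """Vectorized likelihood vs an independent per-row evaluation (1e-10)."""
    spec = spec_by_name(name)
    model = DhglmModel(small_frame, spec)
    rng = np.random.default_rng(1)
    theta = model.initial_point(rng) + 0.3 * rng.standard_normal(model.n_params)
    ll = model.pointwise_loglik(theta)

    con = model.constrain(theta)
    naive = np.empty(small_frame.n_obs)
    for i in range(small_frame.n_obs):
        x = np.array([1.0, small_frame.age_s[i], small_frame.brood_s[i]])
        mu = float(con["beta_mu"] @ x)
        logsig = float(con["beta_sigma"] @ x)
        groups = {"site": small_frame.site[i], "pair": small_frame.pair[i], "year": small_frame.year[i]}
        mult = {"mu_intercept": 1.0, "mu_age": x[1], "mu_brood": x[2], "sigma_intercept": 1.0}
        for b in spec.blocks():
            for term in b.terms:
                e = con[f"effects[{b.group}:{term}]"][groups[b.group]] * mult[term]
                if term == "sigma_intercept":
                    logsig += e
                else:
                    mu += e
        naive[i] = norm.logpdf(small_frame.log_ivi[i], loc=mu, scale=np.exp(logsig))
    assert np.max(np.abs(ll - naive)) < 1e-10


def test_sigma_link_scaling(small_frame):
    spec = spec_by_name("m1a")
    model = DhglmModel(small_frame, spec)
    theta = np.zeros(model.n_params)
    g0 = 2.0
    theta[model._slices["beta_sigma"]][0] = g0
    _, logsig1, _ = model._linear_predictors(theta)
    theta2 = theta.copy()
    theta2[model._slices["beta_sigma"]][0] = 2 * g0
    _, logsig2, _ = model._linear_predictors(theta2)
    # doubling the sigma intercept scales every sigma_i by exp(g0)
    assert np.allclose(np.exp(logsig2) / np.exp(logsig1), np.exp(g0))


def test_nan_covariates_rejected(small_frame):
    import dataclasses

    bad = dataclasses.replace(small_frame, age_s=small_frame.age_s.copy())
    bad.age_s[0] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        DhglmModel(bad, spec_by_name("m1a"))


@pytest.mark.parametrize("name", ["m1h", "across_pairs"])
def test_gradient_matches_finite_differences(small_frame, name):
    model = DhglmModel(small_frame, spec_by_name(name))
    rng = np.random.default_rng(2)
    theta = model.initial_point(rng) + 0.3 * rng.standard_normal(model.n_params)
    _, grad = model.logp_grad(theta)
    eps = 1e-6
    idx = rng.choice(model.n_params, size=40, replace=False)
    for i in idx:
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        fd = (model.logp_grad(tp)[0] - model.logp_grad(tm)[0]) / (2 * eps)
        assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)


def test_cholesky_cpc_transform_and_gradient():
    rng = np.random.default_rng(3)
    for d in (2, 3, 4):
        w = np.tanh(rng.standard_normal(d * (d - 1) // 2))
        L = chol_from_cpc(w, d)
        R = L @ L.T
        assert np.allclose(np.diag(R), 1.0)
        assert np.all(np.linalg.eigvalsh(R) > 0)
        G = rng.standard_normal((d, d))
        dw = chol_from_cpc_grad(w, d, L, G)
        eps = 1e-7
        for k in range(len(w)):
            wp, wm = w.copy(), w.copy()
            wp[k] += eps
            wm[k] -= eps
            fd = (np.sum(G * chol_from_cpc(wp, d)) - np.sum(G * chol_from_cpc(wm, d))) / (2 * eps)
            assert dw[k] == pytest.approx(fd, rel=1e-5, abs=1e-7)


def test_cpc_prior_induces_lkj_marginals():
    """The shifted-Beta CPC prior must induce the LKJ(2) marginal on each
    correlation: Beta(2.5, 2.5) stretched to (-1, 1) for d = 3."""
    rng = np.random.default_rng(4)
    d, eta = 3, 2.0
    alphas = _cpc_alphas(d, eta)
    n = 40_000
    rs = np.empty((n, 3))
    for s in range(n):
        w = 2.0 * rng.beta(alphas, alphas) - 1.0
        R = chol_from_cpc(w, d) @ chol_from_cpc(w, d).T
        rs[s] = [R[1, 0], R[2, 0], R[2, 1]]
    # Beta(2.5,2.5) on (-1,1): mean 0, variance 4 * (2.5^2/(5^2*6)) = 1/6
    assert np.allclose(rs.mean(axis=0), 0.0, atol=0.02)
    assert np.allclose(rs.var(axis=0), 1.0 / 6.0, atol=0.01)


# ---------------------------------------------------------------------------
# prior predictive and fitting
# ---------------------------------------------------------------------------

def test_prior_predictive_sanity(small_frame):
    rng = np.random.default_rng(5)
    y = nv.prior_predictive(spec_by_name("m1h"), small_frame, 200, rng)
    assert np.isfinite(y).all()
    med_ivi = np.exp(np.median(y))
    assert 1.0 <= med_ivi <= 7 * 24 * 60  # between 1 min and 1 week


def test_fixed_effect_recovery_no_random_effects(quick_m1a_fit):
    """With all random-effect SDs zero, m1a must recover the generating
    fixed effects: truth inside every 95% CI and posterior means close."""
    result, truth, _ = quick_m1a_fit
    bm = result.stacked("beta_mu")
    bs = result.stacked("beta_sigma")
    for j in range(3):
        lo, hi = np.quantile(bm[:, j], [0.025, 0.975])
        assert lo - 0.02 <= truth.beta_mu[j] <= hi + 0.02
        lo, hi = np.quantile(bs[:, j], [0.025, 0.975])
        assert lo - 0.02 <= truth.beta_sigma[j] <= hi + 0.02
    assert bm[:, 0].mean() == pytest.approx(truth.beta_mu[0], abs=0.1)
    assert bs[:, 1].mean() == pytest.approx(truth.beta_sigma[1], abs=0.05)


def test_unneeded_random_slope_shrinks_to_zero():
    """Fitting m1f (year age slope) to data generated without one: the
    slope SD posterior must concentrate near zero."""
    design = nv.StudyDesign(n_years=5, n_sites=12, occupancy=0.9, mean_visits_per_day=3)
    truth = nv.GeneratorTruth(
        seed=31, sd_site=0.1, sd_pair=0.15, sd_year=(0.1, 0.0, 0.1),
        failure_rate=0.0, outlier_rate=0.0,
    )
    table, truth = nv.generate_ivi_table(design, truth)
    frame = nv.build_model_frame(table)
    cfg = nv.SamplerConfig(seed=6, chains=2, warmup=300, draws=300)
    result = nv.fit(frame, spec_by_name("m1f"), cfg, check=False)
    slope_sd = np.median(result.stacked("sd[year:mu_age]"))
    resid_sd = float(np.sqrt(np.mean(np.asarray(result.meta["resid_var"]))))
    assert slope_sd < 0.5 * resid_sd


def test_across_pairs_recovers_negative_intercept_sigma_correlation():
    """Pair-level intercept/log-sigma effects generated with rho = -0.8:
    the across-pairs model's correlation posterior must come out negative."""
    rng = np.random.default_rng(51)
    n_pairs, per_pair = 60, 12
    rho = -0.8
    cov = np.array([[0.25**2, rho * 0.25 * 0.3], [rho * 0.25 * 0.3, 0.3**2]])
    eff = rng.multivariate_normal([0, 0], cov, size=n_pairs)  # (u0, v) per pair
    pair = np.repeat(np.arange(n_pairs), per_pair)
    age_s = np.tile(np.linspace(0, 2, per_pair), n_pairs)
    mu = 5.4 - 0.18 * age_s + eff[pair, 0]
    sigma = np.exp(np.log(0.7) + eff[pair, 1])
    y = mu + sigma * rng.standard_normal(len(mu))
    frame = nv.ModelFrame(
        log_ivi=y,
        age_s=age_s,
        brood_s=np.tile(np.linspace(-1, 1, per_pair), n_pairs),
        year=pair % 5,
        site=pair % 12,
        pair=pair,
        year_labels=list(range(5)),
        site_labels=list(range(12)),
        pair_labels=[f"p{i}" for i in range(n_pairs)],
        scaling={"age_sd": 3.45, "brood_mean": 2.8, "brood_sd": 0.93},
    )
    cfg = nv.SamplerConfig(seed=8, chains=2, warmup=250, draws=250)
    result = nv.fit(frame, nv.across_pairs_spec(), cfg, check=False)
    rho_summ = nv.random_effect_correlations(result)["rho(intercept,log_sigma)"]
    assert rho_summ.mode < 0
    assert np.median(result.stacked("corr[pair:mu_intercept,sigma_intercept]")) < 0


def test_single_observation_frame_never_crashes():
    frame = nv.ModelFrame(
        log_ivi=np.array([5.0]),
        age_s=np.array([0.0]),
        brood_s=np.array([0.0]),
        year=np.array([0]),
        site=np.array([0]),
        pair=np.array([0]),
        year_labels=[2015],
        site_labels=[1],
        pair_labels=["p"],
        scaling={"age_sd": 1.0, "brood_mean": 2.0, "brood_sd": 1.0},
    )
    cfg = nv.SamplerConfig(seed=7, chains=1, warmup=150, draws=100)
    try:
        result = nv.fit(frame, spec_by_name("m1a"), cfg, check=False)
        assert np.isfinite(result.stacked("beta_mu")).all()
    except nv.ConvergenceError:
        pass  # acceptable: wide/degenerate posterior flagged, not a crash


def test_result_save_load_round_trip(tmp_path, quick_m1a_fit):
    result, _, _ = quick_m1a_fit
    result.save(tmp_path / "fit")
    loaded = nv.PosteriorResult.load(tmp_path / "fit")
    assert loaded.spec == result.spec
    assert np.allclose(loaded.stacked("beta_mu"), result.stacked("beta_mu"))
    assert np.allclose(loaded.loglik, result.loglik)
    assert loaded.meta["year_labels"] == result.meta["year_labels"]
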