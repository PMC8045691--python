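"""Gibbs sampler: conjugate oracles, determinism, invariances, summaries."""

import numpy as np
import pandas as pd
import pytest

import polyblup as pb
from polyblup.model import (
    ERROR,
    GENOTYPE,
    ModelDataError,
    Prior,
    PriorSpec,
    hpd_interval,
    posterior_summary,
)
from polyblup.pedigree import Individual, Pedigree


def _flat_priors(names, nu=5.0, s2=3.114):
    return PriorSpec({n: Prior(nu, s2) for n in names})


@pytest.fixture(scope="module")
def tiny_ped():
    return pb.backcross_chain(1)


@pytest.fixture(scope="module")
def pure_v_data():
    inds = [Individual(f"V{i}", None, None, "V") for i in range(1, 5)]
    inds += [
        Individual("X1", "V1", "V2", "V"),
        Individual("X2", "V3", "V4", "V"),
        Individual("Y1", "X1", "X2", "V"),
    ]
    ped = Pedigree(inds)
    rng = np.random.default_rng(42)
    data = pd.DataFrame({
        "genotype": ["X1", "X2", "Y1"] * 8,
        "environment": (["E1"] * 3 + ["E2"] * 3) * 4,
        "value": rng.normal(4.0, 1.0, 24),
    })
    return ped, data


def test_prior_only_sampling_matches_prior_mean(tiny_ped):
    # no data: every variance is drawn from its scaled-inv-chi2 prior,
    # whose mean for nu=5, S2=3.114 is 5*3.114/3 = 5.19
    names = [ERROR, "ge"] + list(pb.COMPONENTS)
    model = pb.MultibreedModel(None, tiny_ped, priors=_flat_priors(names))
    res = model.fit(pb.ChainSettings(n_iter=20_000, n_burnin=0), seed=1)
    prior = Prior(5.0, 3.114)
    # iid draws; SE of the mean from the prior's own variance (nu > 4)
    sd = np.sqrt(2 * (5 * 3.114) ** 2 / (3 ** 2 * 1))
    se = sd / np.sqrt(20_000)
    for name in names:
        assert res.variance_draws[name].mean() == pytest.approx(
            prior.mean, abs=3 * se)
        assert (res.variance_draws[name] > 0).all()


def test_error_variance_matches_conjugate_closed_form(tiny_ped):
    # mean-zero, error-only model: sigma2_e | y is exactly
    # ScaledInvChi2(nu + n, (y'y + nu S2)/(nu + n))
    rng = np.random.default_rng(11)
    y = rng.normal(0.0, 1.0, 200)
    data = pd.DataFrame({"genotype": "F1", "environment": "E1", "value": y})
    model = pb.MultibreedModel(
        data, tiny_ped, components=(), include_environment=False,
        include_ge=False, priors=_flat_priors([ERROR], s2=3.0))
    res = model.fit(pb.ChainSettings(n_iter=20_000, n_burnin=0), seed=2)
    nu_post = 5.0 + 200
    scale_post = (y @ y + 5.0 * 3.0) / nu_post
    analytic_mean = nu_post * scale_post / (nu_post - 2)
    analytic_sd = np.sqrt(2 * (nu_post * scale_post) ** 2
                          / ((nu_post - 2) ** 2 * (nu_post - 4)))
    se = analytic_sd / np.sqrt(20_000)
    assert res.variance_draws[ERROR].mean() == pytest.approx(
        analytic_mean, abs=3 * se)


def test_seeded_determinism(pure_v_data):
    ped, data = pure_v_data
    model = pb.MultibreedModel(data, ped)
    r1 = model.fit(pb.ChainSettings(n_iter=400, n_burnin=100), seed=5)
    r2 = model.fit(pb.ChainSettings(n_iter=400, n_burnin=100), seed=5)
    r3 = model.fit(pb.ChainSettings(n_iter=400, n_burnin=100), seed=6)
    for name in r1.variance_draws:
        np.testing.assert_array_equal(r1.variance_draws[name],
                                      r2.variance_draws[name])
    assert not np.array_equal(r1.variance_draws[ERROR],
                              r3.variance_draws[ERROR])


def test_single_breed_equals_one_breed_fit(pure_v_data):
    # all genotypes pure V: the multi-breed fit with only the V component
    # must reproduce the one-breed fit draw for draw under the same seed
    ped, data = pure_v_data
    multi = pb.MultibreedModel(data, ped, components=("V",))
    one = pb.MultibreedModel(data, ped, one_breed=True)
    rm = multi.fit(pb.ChainSettings(n_iter=400, n_burnin=100), seed=9)
    ro = one.fit(pb.ChainSettings(n_iter=400, n_burnin=100), seed=9)
    np.testing.assert_array_equal(rm.variance_draws["V"],
                                  ro.variance_draws[GENOTYPE])
    np.testing.assert_array_equal(rm.variance_draws[ERROR],
                                  ro.variance_draws[ERROR])


def test_environment_label_swap_is_invariant(pure_v_data):
    ped, data = pure_v_data
    swapped = data.copy()
    swapped["environment"] = swapped["environment"].map(
        {"E1": "E2", "E2": "E1"})
    chain = pb.ChainSettings(n_iter=4000, n_burnin=1000)
    res_a = pb.MultibreedModel(data, ped).fit(chain, seed=3)
    res_b = pb.MultibreedModel(swapped, ped).fit(chain, seed=3)
    # fixed effects permute with the labels ...
    fa, fb = res_a.fixed_effect_means, res_b.fixed_effect_means
    assert fa["E1"] == pytest.approx(fb["E2"], abs=0.15)
    assert fa["E2"] == pytest.approx(fb["E1"], abs=0.15)
    # ... and variance posteriors agree within Monte-Carlo error
    for name in res_a.variance_draws:
        ma = res_a.variance_draws[name].mean()
        mb = res_b.variance_draws[name].mean()
        assert ma == pytest.approx(mb, rel=0.25, abs=0.05)


def test_unknown_genotype_is_named(tiny_ped):
    data = pd.DataFrame({"genotype": ["NOPE"], "environment": ["E1"],
                         "value": [1.0]})
    with pytest.raises(ModelDataError, match="NOPE"):
        pb.MultibreedModel(data, tiny_ped)


def test_support_restriction_excludes_foreign_founders(tiny_ped):
    # a pure D founder with data gets no column in the V term
    data = pd.DataFrame({
        "genotype": ["D1", "F1"], "environment": ["E1", "E1"],
        "value": [1.0, 2.0]})
    model = pb.MultibreedModel(data, tiny_ped)
    terms = {t.name: t for t in model._terms}
    assert "D1" in terms["D"].phen_ids
    assert "D1" not in terms["V"].phen_ids


def test_missing_values_dropped(tiny_ped):
    data = pd.DataFrame({
        "genotype": ["F1", "F1", "F1"], "environment": ["E1", "E1", "E1"],
        "value": [1.0, np.nan, 2.0]})
    model = pb.MultibreedModel(data, tiny_ped)
    assert model.nobs == 2


class TestPosteriorSummary:
    def test_constant_draws(self):
        s = posterior_summary({"x": np.full(500, 3.0)})
        assert s.loc["x", "mean"] == 3.0
        assert s.loc["x", "sd"] == 0.0
        assert s.loc["x", "hpd_lower"] == s.loc["x", "hpd_upper"] == 3.0

    def test_normal_hpd_matches_quantiles(self):
        draws = np.random.default_rng(0).normal(0, 1, 100_000)
        lo, hi = hpd_interval(draws)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_hpd_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        draws = np.random.default_rng(1).gamma(2.0, 1.0, 50_000)
        lo, hi = hpd_interval(draws)
        ref = az.hdi(draws, hdi_prob=0.95)
        assert lo == pytest.approx(float(ref[0]), abs=0.02)
        assert hi == pytest.approx(float(ref[1]), abs=0.02)

    def test_skewed_hpd_shorter_than_equal_tails(self):
        draws = np.random.default_rng(2).exponential(1.0, 50_000)
        lo, hi = hpd_interval(draws)
        eq = np.quantile(draws, [0.025, 0.975])
        assert hi - lo < eq[1] - eq[0]

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            posterior_summary({"x": np.ones(50)})


@pytest.fixture(scope="module")
def fitted(pure_v_data):
    ped, data = pure_v_data
    model = pb.MultibreedModel(data, ped, components=("V",))
    return model.fit(pb.ChainSettings(n_iter=600, n_burnin=200), seed=4)


class TestBlup:
    def test_sum_by_origin_is_component_sum(self, fitted):
        blup = fitted.blup()
        comps = blup.drop(columns="total")
        np.testing.assert_allclose(blup["total"], comps.sum(axis=1))

    def test_unphenotyped_parents_get_breeding_values(self, fitted):
        blup = fitted.blup()
        # founders have no records but are in the V support: conditional-mean
        # extension gives them nonzero predictions tied to their offspring
        assert blup.loc["V1", "V"] != 0.0

    def test_one_breed_column_side_by_side(self, pure_v_data):
        ped, data = pure_v_data
        chain = pb.ChainSettings(n_iter=600, n_burnin=200)
        multi = pb.MultibreedModel(data, ped).fit(chain, seed=4)
        one = pb.MultibreedModel(data, ped, one_breed=True).fit(chain, seed=4)
        blup = multi.blup(one_breed=one)
        assert "onebreed" in blup.columns


def test_summary_layout(pure_v_data):
    ped, data = pure_v_data
    res = pb.MultibreedModel(data, ped).fit(
        pb.ChainSettings(n_iter=400, n_burnin=100), seed=8)
    s = res.summary()
    assert list(s.columns) == ["nu", "S2", "mean", "sd", "hpd_lower",
                               "hpd_upper", "ess"]
    assert (s["mean"] > 0).all()
    assert (s["hpd_lower"] <= s["mean"]).all()
    assert (s["mean"] <= s["hpd_upper"]).all()
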