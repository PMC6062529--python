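"""GP surrogate correctness and the decoupled search's behavior."""

import numpy as np
import pytest

from riskpipe import (
    ComponentSpec,
    Dimension,
    KernelParams,
    Registry,
    acquisition,
    kernel,
    optimize,
    planted_landscape,
    propose_next,
    random_search,
)
from riskpipe.bayes_opt import ConfigSpace, SurrogateState, _gram
from riskpipe.pipeline_space import STAGES


def _space_of(names, with_theta=False):
    dims = (Dimension("t", "continuous", 0.0, 1.0, default=0.5),) \
        if with_theta else ()
    comps = tuple(ComponentSpec(n, "classification", dims) for n in names)
    return ConfigSpace("clf", {"classification": comps})


def _pt(space, name, t=None):
    theta = {} if t is None else {"t": t}
    return space.encode({"classification": (name, theta)})


class TestKernel:
    def test_self_covariance_is_signal_variance(self):
        space = _space_of(["a", "b"], with_theta=True)
        p = _pt(space, "a", 0.3)
        params = KernelParams(signal_var=0.37)
        assert kernel(p, p, params) == pytest.approx(0.37)

    def test_disjoint_categories_vanish_at_large_weight(self):
        space = _space_of(["a", "b"])
        params = KernelParams(cat_weight=50.0, signal_var=1.0)
        assert kernel(_pt(space, "a"), _pt(space, "b"), params) < 1e-12

    def test_symmetric(self):
        space = _space_of(["a", "b"], with_theta=True)
        params = KernelParams()
        x, z = _pt(space, "a", 0.1), _pt(space, "b", 0.9)
        assert kernel(x, z, params) == pytest.approx(kernel(z, x, params))

    def test_gram_positive_semidefinite(self):
        rng = np.random.default_rng(0)
        cat = rng.integers(0, 3, size=(12, 2))
        cont = rng.uniform(size=(12, 4))
        K = _gram(cat, cont, cat, cont, KernelParams())
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_schema_mismatch_rejected(self):
        a = _space_of(["a"])
        b = ConfigSpace("other", {"classification": a.stages["classification"]})
        with pytest.raises(ValueError, match="schema"):
            kernel(_pt(a, "a"), _pt(b, "a"), KernelParams())


class TestPosterior:
    def test_prior_before_any_observation(self):
        space = _space_of(["a", "b"], with_theta=True)
        s = SurrogateState(space, KernelParams(signal_var=0.25))
        mu, sd = s.posterior(_pt(space, "a", 0.5))
        assert mu == 0.0
        assert sd == pytest.approx(0.5)

    def test_noise_free_interpolation(self):
        space = _space_of(["a", "b"], with_theta=True)
        s = SurrogateState(space, KernelParams(noise_var=1e-10))
        s.add({"classification": ("a", {"t": 0.4})}, 0.73)
        mu, sd = s.posterior(_pt(space, "a", 0.4))
        assert mu == pytest.approx(0.73, abs=1e-6)
        assert sd**2 <= 1e-6 * s.params.signal_var

    def test_two_point_posterior_matches_direct_linear_algebra(self):
        space = _space_of(["a", "b"], with_theta=True)
        params = KernelParams(0.5, 1.0, 0.25, 1e-3)
        s = SurrogateState(space, params)
        obs = [({"classification": ("a", {"t": 0.2})}, 0.6),
               ({"classification": ("b", {"t": 0.8})}, 0.4)]
        for p, v in obs:
            s.add(p, v)
        q = _pt(space, "a", 0.5)
        mu, sd = s.posterior(q)
        # independent oracle: explicit 2x2 solve
        pts = [space.encode(p) for p, _ in obs]
        K = np.array([[kernel(x, z, params) for z in pts] for x in pts])
        K += (params.noise_var + 1e-8) * np.eye(2)
        ks = np.array([kernel(q, z, params) for z in pts])
        y = np.array([0.6, 0.4])
        mu_direct = y.mean() + ks @ np.linalg.solve(K, y - y.mean())
        var_direct = params.signal_var - ks @ np.linalg.solve(K, ks)
        assert mu == pytest.approx(mu_direct, abs=1e-10)
        assert sd == pytest.approx(np.sqrt(var_direct), abs=1e-10)

    def test_joint_posterior_consistent_with_marginals(self):
        space = _space_of(["a", "b"], with_theta=True)
        s = SurrogateState(space)
        rng = np.random.default_rng(1)
        for _ in range(6):
            s.add(space.sample(rng), rng.uniform())
        pts = [space.sample(rng) for _ in range(4)]
        enc = [space.encode(p) for p in pts]
        mu_j, cov = s.joint_posterior(enc)
        mu_m, sd_m = s.posterior_many(enc)
        np.testing.assert_allclose(mu_j, mu_m, atol=1e-10)
        np.testing.assert_allclose(np.sqrt(np.clip(np.diag(cov), 0, None)),
                                   sd_m, atol=1e-6)


class TestAcquisition:
    def test_kappa_zero_is_the_mean(self):
        assert acquisition(0.4, 0.2, 0.0) == 0.4

    def test_arithmetic(self):
        assert acquisition(0.5, 0.1, 2.0) == pytest.approx(0.7)

    def test_monotone_in_sigma(self):
        vals = [acquisition(0.2, s, 1.5) for s in np.linspace(0, 1, 20)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            acquisition(0.5, -0.1, 1.0)


class TestPropose:
    def test_single_point_space(self):
        space = _space_of(["only"])
        s = SurrogateState(space)
        pt = propose_next(s, pool_size=10, rng=np.random.default_rng(0))
        assert pt["classification"][0] == "only"

    def test_exploitation_proposes_the_high_observation(self):
        space = _space_of(["a", "b", "c"])
        s = SurrogateState(space, KernelParams(noise_var=1e-8, cat_weight=5.0))
        s.add({"classification": ("b", {})}, 0.9)
        s.add({"classification": ("a", {})}, 0.1)
        pt = propose_next(s, pool_size=60, rng=np.random.default_rng(0),
                          kappa=0.0)
        assert pt["classification"][0] == "b"

    def test_fixed_rng_reproducible(self):
        space = _space_of(["a", "b"], with_theta=True)
        s = SurrogateState(space)
        a = propose_next(s, 50, np.random.default_rng(3))
        b = propose_next(s, 50, np.random.default_rng(3))
        assert a == b


class TestOptimize:
    def test_budget_one_gives_single_probe_trace(self, small_registry):
        land = planted_landscape(small_registry,
                                 ("mean", "none", "logistic", "none"))
        res = optimize(None, small_registry, budget=1, seed=0, objective=land)
        assert len(res.trace) == 1
        assert np.isnan(res.trace[0].acq_mf)

    def test_best_explored_utility_nondecreasing(self, small_registry):
        land = planted_landscape(small_registry,
                                 ("median", "pca", "xgboost", "isotonic"),
                                 noise_sd=0.02)
        res = optimize(None, small_registry, budget=20, seed=1, objective=land)
        running = np.maximum.accumulate([r.u_mf for r in res.trace])
        assert all(b >= a for a, b in zip(running, running[1:]))

    def test_decoupled_search_equals_joint_enumeration_on_additive_utility(self):
        comps = {s: tuple(ComponentSpec(f"{s[:3]}{i}", s) for i in range(2))
                 for s in STAGES}
        reg = Registry(comps)
        best = ("imp1", "fea0", "cla1", "cal0")
        land = planted_landscape(reg, best, margin=0.08)
        # joint oracle: enumerate all 16 combinations
        from riskpipe.pipeline_space import enumerate_components

        joint = max(enumerate_components(reg), key=land.base)
        assert joint == best
        res = optimize(None, reg, budget=25, seed=2, objective=land)
        cfg = res.best_config()
        found = (res.best_stage_point(res.surrogate_imputer, "imputation")[0],
                 cfg.processor, cfg.classifier,
                 res.best_stage_point(res.surrogate_calibrator,
                                      "calibration")[0])
        assert found == joint

    def test_failed_evaluations_recorded_as_zero(self, small_registry):
        # the CV evaluation path catches component failures; a dataset with an
        # all-missing covariate makes every pipeline fit fail
        import pandas as pd

        from riskpipe import LabeledDataset

        ds = LabeledDataset(
            pd.DataFrame({"x": [np.nan] * 40,
                          "z": np.r_[np.ones(20), np.zeros(20)]}),
            np.r_[np.ones(20, int), np.zeros(20, int)])
        res = optimize(ds, small_registry, budget=2, k_folds=2, seed=0)
        assert all(r.u_mf == 0.0 for r in res.trace)

    def test_continuous_toy_beats_random_search(self):
        # one classifier with one continuous hyper-parameter; smooth utility
        dims = (Dimension("t", "continuous", 0.0, 1.0, default=0.5),)
        comps = {
            "imputation": (ComponentSpec("i", "imputation"),),
            "feature_processing": (ComponentSpec("f", "feature_processing"),),
            "classification": (ComponentSpec("c", "classification", dims),),
            "calibration": (ComponentSpec("none", "calibration"),),
        }
        reg = Registry(comps)

        def f(cfg):
            t = cfg.theta_m["t"]
            return 0.5 + 0.4 * np.exp(-40 * (t - 0.62) ** 2)

        bo_best, rs_best = [], []
        for seed in range(8):
            res = optimize(None, reg, budget=25, seed=seed, objective=f,
                           pool_size=200)
            bo_best.append(max(r.u_mf for r in res.trace))
            rs = random_search(reg, 25, seed, f)
            rs_best.append(max(v for _, v in rs))
        assert np.mean(bo_best) >= np.mean(rs_best)
        assert np.mean(bo_best) > 0.85

    def test_same_seed_reproducible(self, small_registry):
        land = planted_landscape(small_registry,
                                 ("median", "pca", "xgboost", "isotonic"),
                                 noise_sd=0.01)
        a = optimize(None, small_registry, budget=10, seed=5, objective=land)
        land2 = planted_landscape(small_registry,
                                  ("median", "pca", "xgboost", "isotonic"),
                                  noise_sd=0.01)
        b = optimize(None, small_registry, budget=10, seed=5, objective=land2)
        assert [r.u_mf for r in a.trace] == [r.u_mf for r in b.trace]
        assert a.trace[-1].mf_point == b.trace[-1].mf_point


def test_posterior_mean_tracks_function_at_observations():
    """On a fixed smooth 1-D utility the GP interpolates its observations."""
    dims = (Dimension("t", "continuous", 0.0, 1.0, default=0.5),)
    space = ConfigSpace("clf", {"classification": (
        ComponentSpec("c", "classification", dims),)})
    s = SurrogateState(space, KernelParams(noise_var=1e-8))
    f = lambda t: 0.3 + 0.5 * np.sin(3 * t)  # noqa: E731
    for t in np.linspace(0.05, 0.95, 12):
        s.add({"classification": ("c", {"t": float(t)})}, f(t))
    s.refit_params()
    for t in np.linspace(0.05, 0.95, 12):
        mu, _ = s.posterior(space.encode({"classification": ("c", {"t": float(t)})}))
        assert mu == pytest.approx(f(t), abs=5e-3)
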