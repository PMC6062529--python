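"""Decoupled Gaussian-process Bayesian optimization over pipeline space.

The search treats the cross-validated clinical utility as a black box and
maintains three independent GP surrogates, exploiting the approximation that
imputation and calibration performance do not depend on the rest of the
pipeline:

* one over the joint (classifier, feature processor) space with their
  hyper-parameters,
* one over the imputer space,
* one over the calibrator set.

Each iteration proposes the point maximizing an Upper-Confidence-Bound
acquisition mu + kappa*sigma in every surrogate's space, evaluates the three
utilities by cross-validation, and updates the posteriors.  Imputer utility is
scored with the imputer ahead of a fixed reference (identity processor +
logistic) pipeline; calibrator utility is one minus the cross-validated Brier
score of the calibrated reference pipeline.

The kernel is a product of a Matérn-5/2 over the continuous hyper-parameter
block (normalized to [0,1], inactive dimensions imputed at the midpoint) and
an exponentiated-overlap kernel exp(-gamma * #disagreements) over the
categorical block.  Kernel hyper-parameters are refit by marginal-likelihood
maximization every few iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize

from .pipeline_space import (
    ComponentSpec,
    LabeledDataset,
    PipelineConfig,
    Registry,
)
from .utility import ScoredOutcomes, brier, cv_utility, stratified_folds

JITTER = 1e-8


# --------------------------------------------------------------------------
# encoding
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EncodedPoint:
    """Categorical component indices + normalized continuous hyper-parameters."""

    cat: tuple[int, ...]
    cont: tuple[float, ...]
    schema: str


class ConfigSpace:
    """One surrogate's input space: a subset of pipeline stages.

    A point is ``{stage: (component_name, theta)}``.  Encoding stacks one
    categorical index per stage and one [0,1] coordinate per hyper-parameter
    of every component in the space; hyper-parameters of components not chosen
    by a point are imputed at the domain midpoint 0.5 so that distances
    between points with different components remain defined.
    """

    def __init__(self, name: str, stages: dict[str, tuple[ComponentSpec, ...]]):
        self.name = name
        self.stages = dict(stages)
        self._dims: list[tuple[str, str, object]] = []
        for stage, comps in self.stages.items():
            for comp in comps:
                for d in comp.hyperparams:
                    self._dims.append((stage, comp.name, d))

    @property
    def n_cat(self) -> int:
        return len(self.stages)

    @property
    def n_cont(self) -> int:
        return len(self._dims)

    def encode(self, point: dict) -> EncodedPoint:
        if set(point) != set(self.stages):
            raise ValueError(
                f"schema mismatch: point stages {sorted(point)} != "
                f"space stages {sorted(self.stages)}")
        cat = []
        for stage, comps in self.stages.items():
            names = [c.name for c in comps]
            cat.append(names.index(point[stage][0]))
        cont = []
        for stage, comp_name, dim in self._dims:
            name, theta = point[stage]
            cont.append(dim.normalize(theta[dim.name]) if name == comp_name else 0.5)
        return EncodedPoint(tuple(cat), tuple(cont), self.name)

    def sample(self, rng: np.random.Generator) -> dict:
        point = {}
        for stage, comps in self.stages.items():
            comp = comps[rng.integers(len(comps))]
            point[stage] = (comp.name,
                            {d.name: d.sample(rng) for d in comp.hyperparams})
        return point


# --------------------------------------------------------------------------
# kernel and GP posterior
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelParams:
    lengthscale: float = 0.5
    cat_weight: float = 1.0     # gamma of the exponentiated overlap kernel
    signal_var: float = 0.25
    noise_var: float = 1e-3


def kernel(a: EncodedPoint, b: EncodedPoint, params: KernelParams) -> float:
    """Matérn-5/2 (continuous block) × exponentiated overlap (categorical)."""
    if a.schema != b.schema:
        raise ValueError(f"schema mismatch: {a.schema!r} vs {b.schema!r}")
    return float(_gram(np.array([a.cat]), np.array([a.cont], dtype=float),
                       np.array([b.cat]), np.array([b.cont], dtype=float),
                       params)[0, 0])


def _gram(cat_a, cont_a, cat_b, cont_b, params: KernelParams) -> np.ndarray:
    if cont_a.shape[1]:
        d2 = np.sum((cont_a[:, None, :] - cont_b[None, :, :]) ** 2, axis=2)
        r = np.sqrt(np.maximum(d2, 0.0)) / params.lengthscale
        matern = (1.0 + math.sqrt(5) * r + 5.0 * r**2 / 3.0) * np.exp(-math.sqrt(5) * r)
    else:
        matern = np.ones((cont_a.shape[0], cont_b.shape[0]))
    if cat_a.shape[1]:
        ham = np.sum(cat_a[:, None, :] != cat_b[None, :, :], axis=2)
        overlap = np.exp(-params.cat_weight * ham)
    else:
        overlap = 1.0
    return params.signal_var * matern * overlap


@dataclass
class SurrogateState:
    """GP posterior over a utility function on one configuration space."""

    space: ConfigSpace
    params: KernelParams = field(default_factory=KernelParams)
    points: list = field(default_factory=list)        # EncodedPoint
    raw_points: list = field(default_factory=list)    # {stage: (name, theta)}
    values: list = field(default_factory=list)

    # cached factorization
    _chol: object = None
    _alpha: object = None
    _ymean: float = 0.0

    def add(self, raw_point: dict, value: float) -> None:
        self.points.append(self.space.encode(raw_point))
        self.raw_points.append(raw_point)
        self.values.append(float(value))
        self._chol = None

    def _arrays(self, points=None):
        pts = self.points if points is None else points
        cat = np.array([p.cat for p in pts], dtype=int).reshape(len(pts), -1)
        cont = np.array([p.cont for p in pts], dtype=float).reshape(len(pts), -1)
        return cat, cont

    def _factorize(self):
        if self._chol is not None:
            return
        cat, cont = self._arrays()
        K = _gram(cat, cont, cat, cont, self.params)
        K[np.diag_indices_from(K)] += self.params.noise_var + JITTER
        try:
            self._chol = cho_factor(K, lower=True)
        except np.linalg.LinAlgError:
            K[np.diag_indices_from(K)] += 1e-6
            self._chol = cho_factor(K, lower=True)  # raises if still singular
        y = np.asarray(self.values, dtype=float)
        self._ymean = float(y.mean())
        self._alpha = cho_solve(self._chol, y - self._ymean)

    def posterior(self, point: EncodedPoint) -> tuple[float, float]:
        """Posterior mean and standard deviation at one point."""
        mu, sd = self.posterior_many([point])
        return float(mu[0]), float(sd[0])

    def posterior_many(self, points) -> tuple[np.ndarray, np.ndarray]:
        if not self.points:
            prior_sd = math.sqrt(self.params.signal_var)
            return (np.zeros(len(points)), np.full(len(points), prior_sd))
        self._factorize()
        cat_q, cont_q = self._arrays(points)
        cat, cont = self._arrays()
        Ks = _gram(cat_q, cont_q, cat, cont, self.params)
        mu = self._ymean + Ks @ self._alpha
        v = cho_solve(self._chol, Ks.T)
        var = self.params.signal_var - np.sum(Ks.T * v, axis=0)
        return mu, np.sqrt(np.clip(var, 0.0, None))

    def joint_posterior(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Joint posterior mean vector and covariance over ``points``."""
        cat_q, cont_q = self._arrays(points)
        Kqq = _gram(cat_q, cont_q, cat_q, cont_q, self.params)
        if not self.points:
            return np.zeros(len(points)), Kqq
        self._factorize()
        cat, cont = self._arrays()
        Ks = _gram(cat_q, cont_q, cat, cont, self.params)
        mu = self._ymean + Ks @ self._alpha
        cov = Kqq - Ks @ cho_solve(self._chol, Ks.T)
        cov = 0.5 * (cov + cov.T)
        return mu, cov

    # -- marginal likelihood refit ------------------------------------------

    def _nll(self, log_params: np.ndarray) -> float:
        ls, gamma, sig, noise = np.exp(log_params)
        params = KernelParams(ls, gamma, sig, noise)
        cat, cont = self._arrays()
        K = _gram(cat, cont, cat, cont, params)
        K[np.diag_indices_from(K)] += noise + JITTER
        y = np.asarray(self.values, dtype=float)
        yc = y - y.mean()
        try:
            c = cholesky(K, lower=True)
        except np.linalg.LinAlgError:
            return 1e10
        alpha = cho_solve((c, True), yc)
        return float(0.5 * yc @ alpha + np.sum(np.log(np.diag(c)))
                     + 0.5 * len(y) * math.log(2 * math.pi))

    def refit_params(self) -> None:
        """Maximize the GP marginal likelihood over kernel hyper-parameters."""
        if len(self.values) < 3:
            return
        x0 = np.log([self.params.lengthscale, self.params.cat_weight,
                     self.params.signal_var, max(self.params.noise_var, 1e-6)])
        bounds = [(math.log(0.02), math.log(10.0)),
                  (math.log(0.01), math.log(20.0)),
                  (math.log(1e-4), math.log(4.0)),
                  (math.log(1e-8), math.log(1.0))]
        res = minimize(self._nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 50})
        if res.success or res.fun < self._nll(x0):
            ls, gamma, sig, noise = np.exp(res.x)
            self.params = KernelParams(float(ls), float(gamma),
                                       float(sig), float(noise))
            self._chol = None


def acquisition(mu: float, sigma: float, kappa: float) -> float:
    """Upper Confidence Bound: optimistic utility bound mu + kappa*sigma."""
    if np.any(np.asarray(sigma) < 0):
        raise ValueError("sigma must be nonnegative")
    return mu + kappa * sigma


def propose_next(surrogate: SurrogateState, pool_size: int,
                 rng: np.random.Generator, kappa: float = 2.0) -> dict:
    """Argmax of the acquisition over a random candidate pool.

    Returns the raw point ``{stage: (component, theta)}``; ties in the
    acquisition are broken uniformly at random.
    """
    raw = [surrogate.space.sample(rng) for _ in range(pool_size)]
    enc = [surrogate.space.encode(p) for p in raw]
    mu, sd = surrogate.posterior_many(enc)
    acq = acquisition(mu, sd, kappa)
    best = np.flatnonzero(acq >= acq.max() - 1e-12)
    return raw[int(rng.choice(best))]


# --------------------------------------------------------------------------
# the sequential procedure
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IterationRecord:
    index: int
    mf_point: dict
    imputer_point: dict
    calibrator_point: dict
    u_mf: float
    u_imputer: float
    u_calibrator: float
    acq_mf: float


@dataclass
class OptimizationResult:
    """Trace plus the three surrogates and run bookkeeping."""

    trace: list[IterationRecord]
    surrogate_mf: SurrogateState
    surrogate_imputer: SurrogateState
    surrogate_calibrator: SurrogateState
    registry: Registry
    seed: int
    reference: dict

    def best_index(self) -> int:
        return int(np.argmax([r.u_mf for r in self.trace]))

    def best_config(self) -> PipelineConfig:
        return self.config_at(self.best_index())

    def config_at(self, k: int) -> PipelineConfig:
        """Full pipeline for trace entry ``k``: its (M, F) with the decoupled
        optima of the imputer and calibrator surrogates."""
        rec = self.trace[k]
        imp = self.best_stage_point(self.surrogate_imputer, "imputation")
        cal = self.best_stage_point(self.surrogate_calibrator, "calibration")
        return PipelineConfig(
            imputer=imp[0], theta_i=imp[1],
            processor=rec.mf_point["feature_processing"][0],
            theta_f=rec.mf_point["feature_processing"][1],
            classifier=rec.mf_point["classification"][0],
            theta_m=rec.mf_point["classification"][1],
            calibrator=cal[0],
        )

    @staticmethod
    def best_stage_point(surrogate: SurrogateState, stage: str):
        """Explored point of a single-stage surrogate with highest posterior mean."""
        mu, _ = surrogate.posterior_many(surrogate.points)
        k = int(np.argmax(mu))
        return surrogate.raw_points[k][stage]


def _mf_space(registry: Registry) -> ConfigSpace:
    return ConfigSpace("mf", {
        "classification": registry.stage("classification"),
        "feature_processing": registry.stage("feature_processing"),
    })


def _stage_space(registry: Registry, stage: str) -> ConfigSpace:
    return ConfigSpace(stage, {stage: registry.stage(stage)})


def optimize(dataset: LabeledDataset | None, registry: Registry,
             budget: int = 200, kappa: float = 2.0, k_folds: int = 3,
             seed: int = 0, pool_size: int = 500, n_init: int = 5,
             refit_every: int = 5, objective=None) -> OptimizationResult:
    """Run the decoupled GP-UCB search for ``budget`` iterations.

    ``objective``, when given, replaces cross-validated evaluation with a
    callable ``PipelineConfig -> utility`` (used for synthetic landscapes);
    otherwise utilities are estimated on ``dataset`` with stratified
    ``k_folds``-fold CV, the folds shared across all pipelines.  Component
    fit failures are caught and recorded as utility 0.
    """
    rng = np.random.default_rng(seed)
    spaces = {
        "mf": _mf_space(registry),
        "imputation": _stage_space(registry, "imputation"),
        "calibration": _stage_space(registry, "calibration"),
    }
    surrogates = {k: SurrogateState(v) for k, v in spaces.items()}

    def _ref(stage, preferred):
        names = [c.name for c in registry.stage(stage)]
        name = preferred if preferred in names else names[0]
        return name, registry.get(stage, name).default_theta()

    reference = {
        "imputation": _ref("imputation", "mean"),
        "feature_processing": _ref("feature_processing", "none"),
        "classification": _ref("classification", "logistic"),
        "calibration": _ref("calibration", "none"),
    }

    folds = None
    if objective is None:
        if dataset is None:
            raise ValueError("either a dataset or an objective is required")
        folds = stratified_folds(dataset.y, k_folds, seed)

    def _config(mf=None, imp=None, cal=None) -> PipelineConfig:
        m = mf["classification"] if mf else reference["classification"]
        f = mf["feature_processing"] if mf else reference["feature_processing"]
        i = imp["imputation"] if imp else reference["imputation"]
        c = cal["calibration"][0] if cal else reference["calibration"][0]
        return PipelineConfig(imputer=i[0], theta_i=i[1], processor=f[0],
                              theta_f=f[1], classifier=m[0], theta_m=m[1],
                              calibrator=c)

    def eval_mf(point):
        cfg = _config(mf=point)
        if objective is not None:
            return float(objective(cfg))
        try:
            return cv_utility(cfg, dataset, seed=seed, folds=folds).utility
        except Exception:
            return 0.0

    def eval_imputer(point):
        cfg = _config(imp=point)
        if objective is not None:
            return float(objective(cfg))
        try:
            return cv_utility(cfg, dataset, seed=seed, folds=folds).utility
        except Exception:
            return 0.0

    def eval_calibrator(point):
        cfg = _config(cal=point)
        if objective is not None:
            return float(objective(cfg))
        try:
            from .pipeline_space import assemble_and_fit

            briers = []
            for i, (tr, te) in enumerate(folds):
                fitted = assemble_and_fit(cfg, dataset.subset(tr), seed=seed + i)
                scored = ScoredOutcomes(dataset.y[te],
                                        fitted.predict(dataset.X.iloc[te]))
                briers.append(brier(scored))
            return 1.0 - float(np.mean(briers))
        except Exception:
            return 0.0

    trace: list[IterationRecord] = []
    for k in range(budget):
        if k < n_init:
            mf_pt = spaces["mf"].sample(rng)
            imp_pt = spaces["imputation"].sample(rng)
            cal_pt = spaces["calibration"].sample(rng)
            acq_mf = float("nan")
        else:
            mf_pt = propose_next(surrogates["mf"], pool_size, rng, kappa)
            imp_pt = propose_next(surrogates["imputation"],
                                  min(pool_size, 100), rng, kappa)
            cal_pt = propose_next(surrogates["calibration"], 12, rng, kappa)
            mu, sd = surrogates["mf"].posterior(spaces["mf"].encode(mf_pt))
            acq_mf = acquisition(mu, sd, kappa)

        u_mf = eval_mf(mf_pt)
        u_i = eval_imputer(imp_pt)
        u_c = eval_calibrator(cal_pt)
        surrogates["mf"].add(mf_pt, u_mf)
        surrogates["imputation"].add(imp_pt, u_i)
        surrogates["calibration"].add(cal_pt, u_c)
        trace.append(IterationRecord(k, mf_pt, imp_pt, cal_pt,
                                     u_mf, u_i, u_c, acq_mf))
        if (k + 1) % refit_every == 0:
            for s in surrogates.values():
                s.refit_params()

    return OptimizationResult(trace, surrogates["mf"], surrogates["imputation"],
                              surrogates["calibration"], registry, seed, reference)


def random_search(registry: Registry, budget: int, seed: int,
                  objective) -> list[tuple[PipelineConfig, float]]:
    """Uniform random baseline evaluated in the same harness as the optimizer."""
    from .pipeline_space import sample_config

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(budget):
        cfg = sample_config(registry, rng)
        out.append((cfg, float(objective(cfg))))
    return out


def trace_to_frame(result: OptimizationResult):
    """Flatten a trace into a pandas DataFrame (append-only CSV layout)."""
    import pandas as pd

    rows = []
    for r in result.trace:
        row = {
            "iteration": r.index,
            "classifier": r.mf_point["classification"][0],
            "processor": r.mf_point["feature_processing"][0],
            "imputer": r.imputer_point["imputation"][0],
            "calibrator": r.calibrator_point["calibration"][0],
            "u_mf": r.u_mf,
            "u_imputer": r.u_imputer,
            "u_calibrator": r.u_calibrator,
            "acq_mf": r.acq_mf,
        }
        for stage_key, point in (("classifier", r.mf_point["classification"]),
                                 ("processor", r.mf_point["feature_processing"]),
                                 ("imputer", r.imputer_point["imputation"])):
            for pk, pv in point[1].items():
                row[f"{stage_key}__{pk}"] = pv
        rows.append(row)
    return pd.DataFrame(rows)
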