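"""Pipeline search space: component registries, domains, fit/predict contract.

A pipeline is the ordered chain imputation → feature processing →
classification → calibration, producing a risk score in [0, 1].  The registry
declares the components available at each stage together with their
hyper-parameter domains; the paper-scale registry has stage sizes
(7, 14, 20, 3) for a product of 5,880 pipelines, and this module ships a
default registry with all 7 imputers, 3 processors, 6 classifiers and the
3 calibrators (extensible — the search, ensembling and interpretation
machinery never depends on the menu).

Hyper-parameter domains are conventional ranges (tree counts 10–1000 on a log
scale, PCA components 2–100, ...) declared here so that runs are reproducible;
they are clipped to the data dimensions at fit time where necessary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.cluster import FeatureAgglomeration
from sklearn.decomposition import PCA
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer, SimpleImputer
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

STAGES = ("imputation", "feature_processing", "classification", "calibration")


# --------------------------------------------------------------------------
# domains
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Dimension:
    """One hyper-parameter dimension of a component."""

    name: str
    kind: str  # continuous | integer | categorical
    low: float | None = None
    high: float | None = None
    levels: tuple = ()
    default: object = None
    log: bool = False

    def __post_init__(self):
        if self.kind in ("continuous", "integer"):
            if self.low is None or self.high is None or not (
                np.isfinite(self.low) and np.isfinite(self.high)
            ):
                raise ValueError(f"dimension {self.name}: bounds must be finite")
            if self.low >= self.high:
                raise ValueError(f"dimension {self.name}: low < high required")
        elif self.kind == "categorical":
            if len(self.levels) < 1:
                raise ValueError(f"dimension {self.name}: needs >=1 level")
        else:
            raise ValueError(f"dimension {self.name}: unknown kind {self.kind!r}")

    def contains(self, value) -> bool:
        if self.kind == "categorical":
            return value in self.levels
        if self.kind == "integer" and int(value) != value:
            return False
        return self.low <= value <= self.high

    def sample(self, rng: np.random.Generator):
        if self.kind == "categorical":
            return self.levels[rng.integers(len(self.levels))]
        if self.log:
            v = float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        else:
            v = float(rng.uniform(self.low, self.high))
        if self.kind == "integer":
            v = int(round(v))
            v = int(min(max(v, self.low), self.high))
        return v

    def normalize(self, value) -> float:
        """Map a value into [0, 1] (log scale where flagged)."""
        if self.kind == "categorical":
            return self.levels.index(value) / max(len(self.levels) - 1, 1)
        if self.log:
            return float(
                (np.log(value) - np.log(self.low))
                / (np.log(self.high) - np.log(self.low))
            )
        return float((value - self.low) / (self.high - self.low))

    def denormalize(self, u: float):
        if self.kind == "categorical":
            return self.levels[int(round(u * (len(self.levels) - 1)))]
        if self.log:
            v = float(np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low))))
        else:
            v = float(self.low + u * (self.high - self.low))
        if self.kind == "integer":
            v = int(min(max(round(v), self.low), self.high))
        return v


@dataclass(frozen=True)
class ComponentSpec:
    """A named component at one pipeline stage with its domain."""

    name: str
    stage: str
    hyperparams: tuple[Dimension, ...] = ()

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        names = [d.name for d in self.hyperparams]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.name}: duplicate hyper-parameter names")

    def default_theta(self) -> dict:
        return {d.name: d.default for d in self.hyperparams}

    def validate_theta(self, theta: dict) -> None:
        dims = {d.name: d for d in self.hyperparams}
        if set(theta) != set(dims):
            raise ValueError(
                f"{self.name}: theta keys {sorted(theta)} != domain {sorted(dims)}"
            )
        for k, v in theta.items():
            if not dims[k].contains(v):
                raise ValueError(f"{self.name}.{k}={v!r} outside its domain")


@dataclass(frozen=True)
class Registry:
    """Components available per stage."""

    components: dict[str, tuple[ComponentSpec, ...]]

    def __post_init__(self):
        for stage in STAGES:
            if not self.components.get(stage):
                raise ValueError(f"stage {stage!r} must be non-empty")
            names = [c.name for c in self.components[stage]]
            if len(set(names)) != len(names):
                raise ValueError(f"stage {stage!r}: duplicate component names")

    def stage(self, stage: str) -> tuple[ComponentSpec, ...]:
        return self.components[stage]

    def get(self, stage: str, name: str) -> ComponentSpec:
        for c in self.components[stage]:
            if c.name == name:
                return c
        raise KeyError(f"no component {name!r} at stage {stage!r}")

    def sizes(self) -> tuple[int, int, int, int]:
        return tuple(len(self.components[s]) for s in STAGES)

    def subset(self, **names_per_stage) -> "Registry":
        """Restrict stages to the named components (kwargs keyed by stage)."""
        comps = {}
        for stage in STAGES:
            keep = names_per_stage.get(stage)
            if keep is None:
                comps[stage] = self.components[stage]
            else:
                comps[stage] = tuple(self.get(stage, n) for n in keep)
        return Registry(comps)


def count_pipelines(registry: Registry) -> int:
    """Number of distinct pipelines: product of stage sizes."""
    out = 1
    for n in registry.sizes():
        out *= n
    return out


# --------------------------------------------------------------------------
# default registry
# --------------------------------------------------------------------------

def _int_dim(name, lo, hi, default, log=True):
    return Dimension(name, "integer", lo, hi, default=default, log=log)


def _float_dim(name, lo, hi, default, log=False):
    return Dimension(name, "continuous", lo, hi, default=default, log=log)


def build_default_registry() -> Registry:
    """The stock registry: 7 imputers, 3 processors, 6 classifiers, 3 calibrators.

    Imputation covers mean, median and most-frequent fills, multivariate-normal
    EM, low-rank matrix completion (iterative soft-thresholded SVD), chained
    equations, and iterative random-forest imputation.  Calibrators (Platt
    sigmoid, isotonic, none) have no hyper-parameters.
    """
    imputation = (
        ComponentSpec("mean", "imputation"),
        ComponentSpec("median", "imputation"),
        ComponentSpec("most_frequent", "imputation"),
        ComponentSpec("em", "imputation",
                      (_int_dim("max_iter", 5, 50, 20, log=False),)),
        ComponentSpec("matrix_completion", "imputation",
                      (_float_dim("shrinkage", 0.01, 0.9, 0.2, log=True),
                       _int_dim("max_iter", 5, 50, 20, log=False))),
        ComponentSpec("chained_equations", "imputation",
                      (_int_dim("max_iter", 3, 30, 10, log=False),)),
        ComponentSpec("missforest", "imputation",
                      (_int_dim("n_estimators", 5, 100, 10),
                       _int_dim("max_iter", 2, 10, 5, log=False))),
    )
    feature_processing = (
        ComponentSpec("none", "feature_processing"),
        ComponentSpec("pca", "feature_processing",
                      (_int_dim("n_components", 2, 100, 20),)),
        ComponentSpec("feature_agglomeration", "feature_processing",
                      (_int_dim("n_clusters", 2, 50, 10),)),
    )
    classification = (
        ComponentSpec("logistic", "classification",
                      (_float_dim("C", 1e-3, 1e3, 1.0, log=True),)),
        ComponentSpec("random_forest", "classification",
                      (_int_dim("n_estimators", 10, 1000, 100),
                       _int_dim("max_depth", 2, 16, 8, log=False))),
        ComponentSpec("gradient_boosting", "classification",
                      (_int_dim("n_estimators", 20, 500, 100),
                       _float_dim("learning_rate", 0.01, 0.5, 0.1, log=True),
                       _int_dim("max_depth", 1, 6, 3, log=False))),
        ComponentSpec("xgboost", "classification",
                      (_int_dim("n_estimators", 20, 500, 100),
                       _float_dim("learning_rate", 0.01, 0.5, 0.1, log=True),
                       _int_dim("max_depth", 1, 8, 4, log=False))),
        ComponentSpec("bagging", "classification",
                      (_int_dim("n_estimators", 10, 200, 50),)),
        ComponentSpec("adaboost", "classification",
                      (_int_dim("n_estimators", 20, 500, 100),
                       _float_dim("learning_rate", 0.01, 2.0, 1.0, log=True))),
    )
    calibration = (
        ComponentSpec("none", "calibration"),
        ComponentSpec("sigmoid", "calibration"),
        ComponentSpec("isotonic", "calibration"),
    )
    return Registry({
        "imputation": imputation,
        "feature_processing": feature_processing,
        "classification": classification,
        "calibration": calibration,
    })


def build_small_registry() -> Registry:
    """A fast sub-registry for reduced searches (variable screening, demos).

    Simple imputers only, and tree ensembles capped at 200 trees so a single
    evaluation stays cheap; the search machinery is identical.
    """
    full = build_default_registry()
    classification = (
        full.get("classification", "logistic"),
        ComponentSpec("random_forest", "classification",
                      (_int_dim("n_estimators", 10, 200, 100),
                       _int_dim("max_depth", 2, 10, 6, log=False))),
        ComponentSpec("xgboost", "classification",
                      (_int_dim("n_estimators", 20, 200, 100),
                       _float_dim("learning_rate", 0.01, 0.5, 0.1, log=True),
                       _int_dim("max_depth", 1, 6, 3, log=False))),
    )
    return Registry({
        "imputation": tuple(full.get("imputation", n)
                            for n in ("mean", "median", "most_frequent")),
        "feature_processing": (full.get("feature_processing", "none"),
                               ComponentSpec("pca", "feature_processing",
                                             (_int_dim("n_components", 2, 30, 10),))),
        "classification": classification,
        "calibration": full.stage("calibration"),
    })


# --------------------------------------------------------------------------
# configurations
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """One point in the search space: a component per stage plus its theta."""

    imputer: str
    theta_i: dict
    processor: str
    theta_f: dict
    classifier: str
    theta_m: dict
    calibrator: str

    def validate(self, registry: Registry) -> None:
        registry.get("imputation", self.imputer).validate_theta(self.theta_i)
        registry.get("feature_processing", self.processor).validate_theta(self.theta_f)
        registry.get("classification", self.classifier).validate_theta(self.theta_m)
        registry.get("calibration", self.calibrator)  # calibrators carry no theta

    def to_flat(self) -> dict:
        """Flat key-value record (serializable, round-trippable)."""
        flat = {
            "imputer": self.imputer,
            "processor": self.processor,
            "classifier": self.classifier,
            "calibrator": self.calibrator,
        }
        for prefix, theta in (("imputer", self.theta_i),
                              ("processor", self.theta_f),
                              ("classifier", self.theta_m)):
            for k, v in theta.items():
                flat[f"{prefix}__{k}"] = v
        return flat

    @staticmethod
    def from_flat(flat: dict) -> "PipelineConfig":
        thetas = {"imputer": {}, "processor": {}, "classifier": {}}
        for key, v in flat.items():
            if "__" in key:
                prefix, name = key.split("__", 1)
                thetas[prefix][name] = v
        return PipelineConfig(
            imputer=flat["imputer"], theta_i=thetas["imputer"],
            processor=flat["processor"], theta_f=thetas["processor"],
            classifier=flat["classifier"], theta_m=thetas["classifier"],
            calibrator=flat["calibrator"],
        )

    def with_stages(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


def default_config(registry: Registry, imputer="mean", processor="none",
                   classifier="logistic", calibrator="none") -> PipelineConfig:
    """A config using each named component at its default theta."""
    return PipelineConfig(
        imputer=imputer,
        theta_i=registry.get("imputation", imputer).default_theta(),
        processor=processor,
        theta_f=registry.get("feature_processing", processor).default_theta(),
        classifier=classifier,
        theta_m=registry.get("classification", classifier).default_theta(),
        calibrator=calibrator,
    )


def sample_config(registry: Registry, rng: np.random.Generator) -> PipelineConfig:
    """Uniformly random component per stage, theta uniform within domains."""
    imp = registry.stage("imputation")[rng.integers(len(registry.stage("imputation")))]
    proc = registry.stage("feature_processing")[
        rng.integers(len(registry.stage("feature_processing")))]
    clf = registry.stage("classification")[
        rng.integers(len(registry.stage("classification")))]
    cal = registry.stage("calibration")[rng.integers(len(registry.stage("calibration")))]
    return PipelineConfig(
        imputer=imp.name,
        theta_i={d.name: d.sample(rng) for d in imp.hyperparams},
        processor=proc.name,
        theta_f={d.name: d.sample(rng) for d in proc.hyperparams},
        classifier=clf.name,
        theta_m={d.name: d.sample(rng) for d in clf.hyperparams},
        calibrator=cal.name,
    )


def enumerate_components(registry: Registry):
    """All (imputer, processor, classifier, calibrator) name combinations."""
    return itertools.product(*(
        [c.name for c in registry.stage(s)] for s in STAGES
    ))


# --------------------------------------------------------------------------
# dataset container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledDataset:
    """Covariate frame (NaN = missing) with a binary outcome vector."""

    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y, dtype=int)
        if len(self.X) != y.size:
            raise ValueError("X and y length mismatch")
        nonnum = [c for c in self.X.columns
                  if not pd.api.types.is_numeric_dtype(self.X[c])]
        if nonnum:
            raise ValueError(f"non-numeric covariate columns: {nonnum}")
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def prevalence(self) -> float:
        return float(self.y.mean())

    def subset(self, idx) -> "LabeledDataset":
        return LabeledDataset(self.X.iloc[idx].reset_index(drop=True),
                              self.y[np.asarray(idx)])


# --------------------------------------------------------------------------
# hand-written imputers (no pre-installed equivalent)
# --------------------------------------------------------------------------

class EMImputer:
    """Multivariate-normal EM imputation.

    E-step replaces each row's missing block with its conditional expectation
    given the observed block under the current (mu, Sigma); M-step re-estimates
    the moments.  A small ridge keeps Sigma invertible.
    """

    def __init__(self, max_iter: int = 20, tol: float = 1e-4, ridge: float = 1e-6):
        self.max_iter = max_iter
        self.tol = tol
        self.ridge = ridge

    def fit(self, X, y=None):
        self.mu_, self.sigma_ = self._em(np.asarray(X, dtype=float))
        return self

    def _em(self, X):
        filled = X.copy()
        col_mean = np.nanmean(X, axis=0)
        miss = np.isnan(X)
        filled[miss] = np.take(col_mean, np.where(miss)[1])
        for _ in range(self.max_iter):
            mu = filled.mean(axis=0)
            sigma = np.cov(filled, rowvar=False) + self.ridge * np.eye(X.shape[1])
            new = X.copy()
            for i in np.where(miss.any(axis=1))[0]:
                m = miss[i]
                o = ~m
                if not o.any():
                    new[i, m] = mu[m]
                    continue
                coef = np.linalg.solve(sigma[np.ix_(o, o)], X[i, o] - mu[o])
                new[i, m] = mu[m] + sigma[np.ix_(m, o)] @ coef
            delta = np.nanmax(np.abs(new - filled)) if miss.any() else 0.0
            filled = new
            if delta < self.tol:
                break
        return filled.mean(axis=0), sigma

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = X.copy()
        miss = np.isnan(X)
        for i in np.where(miss.any(axis=1))[0]:
            m, o = miss[i], ~miss[i]
            if not o.any():
                out[i, m] = self.mu_[m]
                continue
            coef = np.linalg.solve(self.sigma_[np.ix_(o, o)], X[i, o] - self.mu_[o])
            out[i, m] = self.mu_[m] + self.sigma_[np.ix_(m, o)] @ coef
        return out


class SoftImputeImputer:
    """Low-rank matrix completion by iterative soft-thresholded SVD.

    The threshold is ``shrinkage`` times the top singular value of the
    mean-filled matrix; observed entries are restored after every iteration.
    """

    def __init__(self, shrinkage: float = 0.2, max_iter: int = 20, tol: float = 1e-4):
        self.shrinkage = shrinkage
        self.max_iter = max_iter
        self.tol = tol

    def _complete(self, X):
        miss = np.isnan(X)
        col_mean = np.nanmean(X, axis=0)
        filled = X.copy()
        filled[miss] = np.take(col_mean, np.where(miss)[1])
        if not miss.any():
            return filled
        lam = self.shrinkage * np.linalg.svd(filled, compute_uv=False)[0]
        for _ in range(self.max_iter):
            u, s, vt = np.linalg.svd(filled, full_matrices=False)
            low = (u * np.maximum(s - lam, 0.0)) @ vt
            new = X.copy()
            new[miss] = low[miss]
            delta = np.max(np.abs(new - filled))
            filled = new
            if delta < self.tol:
                break
        return filled

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.col_mean_ = np.nanmean(X, axis=0)
        self.train_ = X
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X is self.train_ or (X.shape == self.train_.shape
                                and np.array_equal(X, self.train_, equal_nan=True)):
            return self._complete(X)
        # new rows: complete them against the training matrix
        stacked = np.vstack([self.train_, X])
        return self._complete(stacked)[self.train_.shape[0]:]


# --------------------------------------------------------------------------
# component builders
# --------------------------------------------------------------------------

def _make_imputer(name: str, theta: dict, seed: int):
    if name == "mean":
        return SimpleImputer(strategy="mean")
    if name == "median":
        return SimpleImputer(strategy="median")
    if name == "most_frequent":
        return SimpleImputer(strategy="most_frequent")
    if name == "em":
        return EMImputer(max_iter=theta["max_iter"])
    if name == "matrix_completion":
        return SoftImputeImputer(shrinkage=theta["shrinkage"],
                                 max_iter=theta["max_iter"])
    if name == "chained_equations":
        return IterativeImputer(max_iter=theta["max_iter"], sample_posterior=True,
                                random_state=seed, keep_empty_features=True)
    if name == "missforest":
        est = RandomForestRegressor(n_estimators=theta["n_estimators"],
                                    random_state=seed, n_jobs=1)
        return IterativeImputer(estimator=est, max_iter=theta["max_iter"],
                                random_state=seed, keep_empty_features=True)
    raise KeyError(f"unknown imputer {name!r}")


def _make_processor(name: str, theta: dict, seed: int, n_samples: int, n_features: int):
    if name == "none":
        return None
    if name == "pca":
        k = int(min(theta["n_components"], n_features, n_samples))
        return PCA(n_components=k, random_state=seed)
    if name == "feature_agglomeration":
        k = int(min(theta["n_clusters"], n_features))
        return FeatureAgglomeration(n_clusters=k)
    raise KeyError(f"unknown feature processor {name!r}")


def _make_classifier(name: str, theta: dict, seed: int):
    if name == "logistic":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        return make_pipeline(
            StandardScaler(),
            LogisticRegression(C=theta["C"], max_iter=1000, random_state=seed))
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=theta["n_estimators"],
                                      max_depth=theta["max_depth"],
                                      random_state=seed, n_jobs=1)
    if name == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=theta["n_estimators"],
                                          learning_rate=theta["learning_rate"],
                                          max_depth=theta["max_depth"],
                                          random_state=seed)
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(n_estimators=theta["n_estimators"],
                             learning_rate=theta["learning_rate"],
                             max_depth=theta["max_depth"],
                             n_jobs=1, random_state=seed, tree_method="hist",
                             eval_metric="logloss", verbosity=0)
    if name == "bagging":
        return BaggingClassifier(n_estimators=theta["n_estimators"],
                                 random_state=seed, n_jobs=1)
    if name == "adaboost":
        return AdaBoostClassifier(n_estimators=theta["n_estimators"],
                                  learning_rate=theta["learning_rate"],
                                  random_state=seed)
    raise KeyError(f"unknown classifier {name!r}")


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

class FittedPipeline:
    """A fitted impute → transform → classify → calibrate chain."""

    def __init__(self, config, columns, imputer, processor, classifier, calibrator):
        self.config = config
        self.columns = list(columns)
        self._imputer = imputer
        self._processor = processor
        self._classifier = classifier
        self._calibrator = calibrator  # None | ("sigmoid", lr) | ("isotonic", iso)

    def _raw_scores(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ValueError(f"input is missing covariate columns: {missing}")
        Z = self._imputer.transform(X[self.columns].to_numpy(dtype=float))
        if self._processor is not None:
            Z = self._processor.transform(Z)
        return self._classifier.predict_proba(Z)[:, 1]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        s = self._raw_scores(X)
        if self._calibrator is not None:
            kind, model = self._calibrator
            if kind == "sigmoid":
                s = model.predict_proba(s.reshape(-1, 1))[:, 1]
            else:
                s = model.predict(s)
        return np.clip(s, 0.0, 1.0)


def assemble_and_fit(config: PipelineConfig, dataset: LabeledDataset,
                     seed: int = 0) -> FittedPipeline:
    """Fit the four-stage pipeline on a labeled dataset.

    All randomness is controlled by ``seed``.  The calibrator, when present,
    is fit on an internal stratified 20% split held out from the classifier
    (calibrating on the classifier's own training data overfits the Brier
    score).

    Raises
    ------
    ValueError
        For a single-class outcome, an all-missing covariate column, or
        non-finite values surviving imputation.
    """
    classes = np.unique(dataset.y)
    if classes.size < 2:
        raise ValueError("single-class outcome: cannot fit a risk model")
    all_missing = [c for c in dataset.X.columns if dataset.X[c].isna().all()]
    if all_missing:
        raise ValueError(f"all-missing covariate columns: {all_missing}")

    X = dataset.X.to_numpy(dtype=float)
    y = dataset.y
    imputer = _make_imputer(config.imputer, config.theta_i, seed)
    Z = imputer.fit(X).transform(X)
    if not np.isfinite(Z).all():
        raise ValueError(f"non-finite values after {config.imputer} imputation")

    processor = _make_processor(config.processor, config.theta_f, seed,
                                n_samples=Z.shape[0], n_features=Z.shape[1])
    if processor is not None:
        Z = processor.fit_transform(Z)

    classifier = _make_classifier(config.classifier, config.theta_m, seed)
    calibrator = None
    if config.calibrator == "none":
        classifier.fit(Z, y)
    else:
        Z_tr, Z_cal, y_tr, y_cal = train_test_split(
            Z, y, test_size=0.2, stratify=y, random_state=seed)
        classifier.fit(Z_tr, y_tr)
        s_cal = classifier.predict_proba(Z_cal)[:, 1]
        if config.calibrator == "sigmoid":
            lr = LogisticRegression(C=1e6, max_iter=1000)
            lr.fit(s_cal.reshape(-1, 1), y_cal)
            calibrator = ("sigmoid", lr)
        elif config.calibrator == "isotonic":
            iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
            iso.fit(s_cal, y_cal)
            calibrator = ("isotonic", iso)
        else:
            raise KeyError(f"unknown calibrator {config.calibrator!r}")

    return FittedPipeline(config, dataset.X.columns, imputer, processor,
                          classifier, calibrator)
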