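"""The super-pipeline: posterior-weighted ensemble of explored pipelines.

Every explored (classifier, processor) configuration receives a weight equal
to the posterior probability that its clinical utility is the highest among
all explored configurations, estimated by drawing from the *joint* GP
posterior over the explored points (the probability-of-best event is joint, so
correlated draws matter).  Members below a weight threshold (default 0.01) are
pruned and the rest renormalized; surviving members are refit on the full
dataset.  Imputer and calibrator choices are fixed at their decoupled optima.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bayes_opt import OptimizationResult, SurrogateState
from .pipeline_space import (
    LabeledDataset,
    PipelineConfig,
    assemble_and_fit,
)

DEFAULT_WEIGHT_THRESHOLD = 0.01


def prob_best_from_gaussian(mu: np.ndarray, cov: np.ndarray, n_draws: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo probability that each coordinate attains the maximum.

    Draws from N(mu, cov); ties within a draw split their weight equally.
    """
    mu = np.asarray(mu, dtype=float)
    m = mu.size
    if m == 1:
        return np.ones(1)
    cov = np.asarray(cov, dtype=float)
    jitter = 1e-12
    for _ in range(8):
        try:
            L = np.linalg.cholesky(cov + jitter * np.eye(m))
            break
        except np.linalg.LinAlgError:
            jitter *= 100
    else:
        L = np.diag(np.sqrt(np.clip(np.diag(cov), 0.0, None)))
    draws = mu + rng.standard_normal((n_draws, m)) @ L.T
    is_max = draws == draws.max(axis=1, keepdims=True)
    weights = (is_max / is_max.sum(axis=1, keepdims=True)).sum(axis=0) / n_draws
    return weights


def prob_best_weights(surrogate: SurrogateState, explored_points=None,
                      n_draws: int = 1000, seed: int = 0) -> np.ndarray:
    """Probability-of-best weights over a surrogate's explored points."""
    pts = surrogate.points if explored_points is None else explored_points
    if not pts:
        raise ValueError("need at least one explored configuration")
    mu, cov = surrogate.joint_posterior(pts)
    return prob_best_from_gaussian(mu, cov, n_draws, np.random.default_rng(seed))


def prune_normalize(weights: np.ndarray,
                    threshold: float = DEFAULT_WEIGHT_THRESHOLD):
    """Drop weights below ``threshold`` and renormalize.

    Returns (kept indices, renormalized weights).  If everything falls below
    the threshold, the single best member is kept with weight 1.
    """
    w = np.asarray(weights, dtype=float)
    keep = np.flatnonzero(w >= threshold)
    if keep.size == 0:
        keep = np.array([int(np.argmax(w))])
    kept = w[keep] / w[keep].sum()
    return keep, kept


@dataclass
class EnsembleModel:
    """Fitted pipelines combined by probability-of-best weights."""

    configs: list[PipelineConfig]
    fitted: list
    weights: np.ndarray
    weight_threshold: float
    columns: list[str]
    seed: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Weighted arithmetic mean of member risk scores, in [0, 1]."""
        missing = [c for c in self.columns if c not in X.columns]
        if missing:
            raise ValueError(f"input is missing covariate columns: {missing}")
        out = np.zeros(len(X))
        for w, member in zip(self.weights, self.fitted):
            out += w * member.predict(X)
        return np.clip(out, 0.0, 1.0)

    def manifest(self) -> dict:
        return {
            "weight_threshold": self.weight_threshold,
            "seed": self.seed,
            "columns": self.columns,
            "members": [
                {"weight": float(w), "config": cfg.to_flat()}
                for w, cfg in zip(self.weights, self.configs)
            ],
        }

    def save(self, path) -> None:
        """Archive: manifest (flat key-value configs, weights, schema) + blobs."""
        import joblib

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=2, sort_keys=True))
        joblib.dump(self.fitted, path / "members.joblib")

    @staticmethod
    def load(path) -> "EnsembleModel":
        import joblib

        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        fitted = joblib.load(path / "members.joblib")
        return EnsembleModel(
            configs=[PipelineConfig.from_flat(m["config"])
                     for m in manifest["members"]],
            fitted=fitted,
            weights=np.array([m["weight"] for m in manifest["members"]]),
            weight_threshold=manifest["weight_threshold"],
            columns=manifest["columns"],
            seed=manifest["seed"],
        )


def finalize(result: OptimizationResult, dataset: LabeledDataset,
             threshold: float = DEFAULT_WEIGHT_THRESHOLD, n_draws: int = 1000,
             seed: int = 0) -> EnsembleModel:
    """Build the final ensemble from a completed optimization run.

    Weights come from the CV-era (M, F) surrogate posterior over all explored
    points, deduplicated by configuration; pruned members are discarded and
    the survivors refit on the entire dataset.  A member whose refit fails is
    dropped with a warning and the weights renormalized.
    """
    import warnings

    # deduplicate identical explored points (re-examinations share one weight)
    seen: dict[tuple, int] = {}
    uniq_idx = []
    for i, p in enumerate(result.surrogate_mf.points):
        key = (p.cat, p.cont)
        if key not in seen:
            seen[key] = i
            uniq_idx.append(i)
    pts = [result.surrogate_mf.points[i] for i in uniq_idx]
    w = prob_best_weights(result.surrogate_mf, pts, n_draws=n_draws, seed=seed)
    keep, w = prune_normalize(w, threshold)

    configs, fitted, kept_w = [], [], []
    for j, wj in zip(keep, w):
        cfg = result.config_at(uniq_idx[int(j)])
        try:
            member = assemble_and_fit(cfg, dataset, seed=seed)
        except Exception as exc:  # refit failure: drop member, renormalize
            warnings.warn(f"dropping ensemble member {cfg.classifier}: {exc}")
            continue
        configs.append(cfg)
        fitted.append(member)
        kept_w.append(float(wj))
    if not configs:
        raise RuntimeError("every ensemble member failed to refit")
    weights = np.asarray(kept_w)
    weights = weights / weights.sum()
    return EnsembleModel(configs, fitted, weights, threshold,
                         list(dataset.X.columns), seed)
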