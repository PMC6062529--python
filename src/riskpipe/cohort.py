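"""Study-design machinery for registry-style cohorts.

Covers cohort assembly (age, prior-transplant and loss-to-follow-up filters,
with flow counts), the composite endpoint (death or lung transplant within
the horizon) and the pulmonary-decline label, the 9-feature CFTR genotype
encoding, cohort-characterization statistics (Fisher exact, Mann-Whitney U),
the FEV1%-threshold referral baseline, recalibration of external risk scores,
and the single-variable importance protocol.

Expected CSV dialect: header row, empty cell = missing; bookkeeping columns
``id, age, prior_lt, lost_fu, death_3y, lt_3y, fev1pp_y0..fev1pp_ym4,
fev1pp_y3, allele_a, allele_b`` plus free numeric covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit

from .pipeline_space import LabeledDataset

#: columns that are never model covariates
BOOKKEEPING_COLUMNS = ("id", "prior_lt", "lost_fu", "death_3y", "lt_3y",
                       "fev1pp_y3", "allele_a", "allele_b")

#: CFTR mutation -> functional classes (a mutation may sit in several classes)
CFTR_CLASS_MAP: dict[str, tuple[str, ...]] = {
    "G542X": ("I",),
    "W1282X": ("I",),
    "1717-1G->A": ("I",),
    "N1303K": ("II",),
    "F508del": ("II", "III", "VI"),
    "A455E": ("II",),
    "G551D": ("III",),
    "R117H": ("III", "IV"),
    "R347H": ("IV",),
    "R347P": ("IV",),
    "R334W": ("IV",),
    "621+1G->T": ("V",),
    "3849+10kbC->T": ("V",),
    "2789+5G->A": ("V",),
}

GENOTYPE_FEATURES = ("geno_homozygous", "geno_f508del", "geno_g551d",
                     "geno_class_i", "geno_class_ii", "geno_class_iii",
                     "geno_class_iv", "geno_class_v", "geno_class_vi")


@dataclass(frozen=True)
class FlowCounts:
    """Patient-selection flow: adults in, exclusions, final cohort, events."""

    n_initial: int
    n_prior_transplant_excluded: int
    n_lost_excluded: int
    n_final: int
    n_events: int
    n_records: int = 0
    n_age_excluded: int = 0

    def __post_init__(self):
        if self.n_final != (self.n_initial - self.n_prior_transplant_excluded
                            - self.n_lost_excluded):
            raise ValueError("flow counts do not add up")
        if self.n_events > self.n_final:
            raise ValueError("more events than patients")

    @property
    def prevalence(self) -> float:
        return self.n_events / self.n_final if self.n_final else float("nan")

    def report(self) -> str:
        return (
            f"records in registry extract      {self.n_records}\n"
            f"  excluded: under age            {self.n_age_excluded}\n"
            f"adults at baseline               {self.n_initial}\n"
            f"  excluded: prior transplant     {self.n_prior_transplant_excluded}\n"
            f"  excluded: lost to follow-up    {self.n_lost_excluded}\n"
            f"analysis cohort                  {self.n_final}\n"
            f"  adverse outcomes               {self.n_events}"
            f" ({100 * self.prevalence:.1f}%)\n"
        )


def label_outcome(record, horizon_years: int = 3) -> int:
    """Composite endpoint: death OR lung transplant within the horizon.

    A patient who received a transplant and then died counts once.
    """
    return int(bool(record["death_3y"]) or bool(record["lt_3y"]))


def label_decline(record):
    """Pulmonary decline: baseline FEV1% > 30 fell below 30 without transplant.

    Returns None when the horizon FEV1% is missing (such patients are
    excluded from decline analyses rather than imputed).
    """
    base = record["fev1pp_y0"]
    hor = record.get("fev1pp_y3") if hasattr(record, "get") else record["fev1pp_y3"]
    if pd.isna(base):
        raise ValueError("baseline FEV1% must be present")
    if pd.isna(hor):
        return None
    return bool(base > 30.0 and hor < 30.0 and not bool(record["lt_3y"]))


def encode_genotype(allele_a: str, allele_b: str,
                    class_map: dict | None = None) -> dict[str, int]:
    """Encode a CFTR mutation pair as 9 binary features.

    Flags: homozygous (identical alleles), carries F508del, carries G551D,
    one flag per functional class I–VI (set when any carried mutation belongs
    to the class).  Unknown mutations contribute no class flags (warned).
    """
    class_map = class_map if class_map is not None else CFTR_CLASS_MAP
    out = {k: 0 for k in GENOTYPE_FEATURES}
    out["geno_homozygous"] = int(str(allele_a) == str(allele_b))
    for allele in (allele_a, allele_b):
        a = str(allele)
        if a == "F508del":
            out["geno_f508del"] = 1
        if a == "G551D":
            out["geno_g551d"] = 1
        if a in class_map:
            for cls in class_map[a]:
                out[f"geno_class_{cls.lower()}"] = 1
        else:
            warnings.warn(f"unknown CFTR mutation {a!r}: no class flags set")
    return out


def assemble_cohort(records: pd.DataFrame, min_age: float = 18.0,
                    horizon_years: int = 3, age_comparator: str = ">="
                    ) -> tuple[LabeledDataset, FlowCounts]:
    """Apply the selection filters in order age → prior transplant → lost.

    Returns the labeled analysis dataset (genotype columns encoded, future
    and bookkeeping columns dropped) and the flow counts.  An empty cohort is
    allowed and produces all-zero counts.
    """
    n_records = len(records)
    if n_records == 0:
        empty = LabeledDataset(pd.DataFrame({"age": []}), np.zeros(0, dtype=int))
        return empty, FlowCounts(0, 0, 0, 0, 0, 0, 0)

    age = records["age"].to_numpy(dtype=float)
    adult = age > min_age if age_comparator == ">" else age >= min_age
    adults = records.loc[adult]
    prior = adults["prior_lt"].astype(bool).to_numpy()
    after_prior = adults.loc[~prior]
    lost = after_prior["lost_fu"].astype(bool).to_numpy()
    cohort = after_prior.loc[~lost].reset_index(drop=True)

    y = (cohort["death_3y"].astype(bool)
         | cohort["lt_3y"].astype(bool)).to_numpy().astype(int)
    counts = FlowCounts(
        n_initial=int(adult.sum()),
        n_prior_transplant_excluded=int(prior.sum()),
        n_lost_excluded=int(lost.sum()),
        n_final=len(cohort),
        n_events=int(y.sum()),
        n_records=n_records,
        n_age_excluded=int(n_records - adult.sum()),
    )

    X = cohort.drop(columns=[c for c in BOOKKEEPING_COLUMNS if c in cohort],
                    errors="ignore")
    if "allele_a" in cohort.columns and "allele_b" in cohort.columns:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            geno = pd.DataFrame([
                encode_genotype(a, b)
                for a, b in zip(cohort["allele_a"], cohort["allele_b"])
            ], index=cohort.index)
        X = pd.concat([X, geno], axis=1)
    return LabeledDataset(X, y), counts


# --------------------------------------------------------------------------
# cohort characterization statistics
# --------------------------------------------------------------------------

def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value by the probability-mass convention.

    Sums hypergeometric probabilities of all tables (margins fixed) no more
    probable than the observed one; a zero margin returns p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 count table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def mann_whitney_u(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when n_x * n_y <= 400 and the pooled sample is tie-free;
    tie-corrected normal approximation otherwise.  Identical constant samples
    give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def fev1_criterion(fev1_pct, threshold: float = 30.0):
    """Referral baseline: positive iff FEV1% predicted is strictly below threshold."""
    v = np.asarray(fev1_pct, dtype=float)
    if np.isnan(v).any():
        raise ValueError("FEV1% must be present")
    out = (v < threshold).astype(int)
    return out if v.ndim else int(out[()])


# --------------------------------------------------------------------------
# recalibration of external scores
# --------------------------------------------------------------------------

def recalibrate_in_large(scores, target_prevalence: float) -> np.ndarray:
    """Shift scores on the log-odds scale so their mean matches a target.

    Monotone and order-preserving; solves for the intercept shift by 1-D
    root finding.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must lie in (0, 1)")
    s = np.asarray(scores, dtype=float)
    if np.any((s <= 0) | (s >= 1)):
        raise ValueError("scores must lie strictly inside (0, 1)")
    lo = logit(s)

    def gap(delta):
        return expit(lo + delta).mean() - target_prevalence

    if abs(gap(0.0)) < 1e-12:
        return s.copy()
    delta = brentq(gap, -50.0, 50.0, xtol=1e-12)
    return expit(lo + delta)


@dataclass(frozen=True)
class RecalibrationResult:
    slope: float
    intercept: float
    adjusted: np.ndarray
    separated: bool = False


SLOPE_CAP = 25.0


def logistic_recalibration(scores, y) -> RecalibrationResult:
    """Logistic recalibration: refit outcome on the score's log-odds.

    Maximum-likelihood slope and intercept; adjusted scores are the fitted
    probabilities.  Constant scores fall back to an intercept-only fit that
    reproduces the prevalence; perfect separation is flagged and the slope
    capped.
    """
    import statsmodels.api as sm

    s = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes are required")
    if np.unique(s).size == 1:
        prev = float(y.mean())
        return RecalibrationResult(0.0, float(logit(prev)),
                                   np.full(s.size, prev))
    lo = logit(np.clip(s, 1e-12, 1 - 1e-12))
    design = sm.add_constant(lo)
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            intercept, slope = float(fit.params[0]), float(fit.params[1])
        except Exception:
            separated = True
            intercept, slope = 0.0, SLOPE_CAP
    if any("erfectSeparation" in type(w.message).__name__ for w in caught):
        separated = True
        slope = float(np.clip(slope, -SLOPE_CAP, SLOPE_CAP))
    if not separated and (not np.isfinite(slope) or abs(slope) > SLOPE_CAP):
        separated = True
        slope = float(np.sign(slope) * SLOPE_CAP) if np.isfinite(slope) else SLOPE_CAP
    adjusted = expit(intercept + slope * lo)
    return RecalibrationResult(slope, intercept, adjusted, separated)


# --------------------------------------------------------------------------
# single-variable importance
# --------------------------------------------------------------------------

def single_variable_importance(dataset: LabeledDataset, variable: str,
                               metric: str = "auc_roc", seed: int = 0,
                               budget: int = 20, k_folds: int = 3) -> float:
    """Predictive power of one covariate on its own.

    Runs a reduced pipeline search (small registry) on the single-column
    dataset and returns the cross-validated AUC-ROC or AUC-PR of the best
    explored pipeline.  A constant variable scores at the metric's chance
    level (0.5 for AUC-ROC, the prevalence for AUC-PR).
    """
    from .bayes_opt import optimize
    from .pipeline_space import assemble_and_fit, build_small_registry
    from .utility import ScoredOutcomes, auc_pr, auc_roc, stratified_folds

    if metric not in ("auc_roc", "auc_pr"):
        raise ValueError("metric must be 'auc_roc' or 'auc_pr'")
    if variable not in dataset.X.columns:
        raise KeyError(f"no covariate {variable!r}")
    col = dataset.X[[variable]]
    if col[variable].dropna().nunique() <= 1:
        return 0.5 if metric == "auc_roc" else dataset.prevalence
    single = LabeledDataset(col, dataset.y)

    registry = build_small_registry().subset(
        imputation=("mean",), feature_processing=("none",),
        classification=("logistic", "random_forest", "xgboost"))
    result = optimize(single, registry, budget=budget, k_folds=k_folds,
                      seed=seed, pool_size=100, n_init=min(3, budget))
    cfg = result.best_config()
    metric_fn = auc_roc if metric == "auc_roc" else auc_pr
    folds = stratified_folds(single.y, k_folds, seed)
    vals = []
    for i, (tr, te) in enumerate(folds):
        fitted = assemble_and_fit(cfg, single.subset(tr), seed=seed + i)
        scored = ScoredOutcomes(single.y[te], fitted.predict(single.X.iloc[te]))
        vals.append(metric_fn(scored))
    return float(np.mean(vals))
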