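"""Synthetic registry-like data, planted landscapes and planted rules.

Every downstream module is testable without access to restricted registry
data.  The cohort generator emulates the structure of a national CF registry
extract: a single latent severity factor drives a declining FEV1% trajectory,
binary comorbidity/treatment flags, and the composite outcome, whose marginal
prevalence is calibrated by root finding (default 9.4% at n = 4,064, the
scale of the study cohort).  Missingness follows the published per-column
rates for the spirometric history (31.0 / 20.0 / 15.5 / 6.2 / 4.4% for the
years −4…0) and anthropometrics (2.1 / 1.4 / 2.9%), either MCAR or
severity-dependent MAR.

Oxygen therapy carries an outcome effect beyond FEV1 so that precision-range
(AUC-PR) importance can diverge from sensitivity-range (AUC-ROC) importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .pipeline_space import PipelineConfig, Registry, STAGES

#: per-column missingness rates (fraction of cells), registry defaults
DEFAULT_MISSINGNESS = {
    "fev1pp_ym4": 0.310,
    "fev1pp_ym3": 0.200,
    "fev1pp_ym2": 0.155,
    "fev1pp_ym1": 0.062,
    "fev1pp_y0": 0.044,
    "height": 0.021,
    "weight": 0.014,
    "bmi": 0.029,
}

#: allele sampling pool (common CFTR mutations with rough UK frequencies)
ALLELE_POOL = (
    ("F508del", 0.72), ("G551D", 0.04), ("R117H", 0.03), ("G542X", 0.03),
    ("621+1G->T", 0.02), ("N1303K", 0.02), ("W1282X", 0.01),
    ("3849+10kbC->T", 0.01), ("R347P", 0.01), ("other", 0.11),
)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the registry emulator; fully determines output with seed."""

    n: int = 4064
    prevalence: float = 0.094
    seed: int = 0
    # extra rows removed by the assembly filters
    n_prior_transplant: int = 0
    n_lost_followup: int = 0
    n_pediatric: int = 0
    # latent-severity effect sizes on the outcome log-odds
    effect_severity: float = 1.2
    effect_oxygen: float = 1.0
    effect_low_fev1: float = 1.0
    # missingness
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    mar_coef: float = 0.0  # >0: missingness increases with severity
    horizon_fev1_missing: float = 0.0
    # hit round(n * prevalence) events exactly (Gumbel-top-k draw) instead of
    # independent Bernoulli outcomes — for reproducing a printed cohort flow
    exact_prevalence: bool = False

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        for col, r in self.missingness.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missingness rate for {col} must be in [0, 1)")


def _mask(rng, z, rate, mar_coef):
    """Missingness indicator with marginal ``rate``; MAR in z when coef > 0."""
    if rate == 0.0:
        return np.zeros(z.size, dtype=bool)
    if mar_coef == 0.0:
        return rng.uniform(size=z.size) < rate

    def gap(c):
        return expit(c + mar_coef * z).mean() - rate

    c = brentq(gap, -40.0, 40.0)
    return rng.uniform(size=z.size) < expit(c + mar_coef * z)


def _block(rng, n, z, spec, age_low=18.0, age_high=62.0):
    """Covariate block for n patients with latent severity z."""
    fev1_y0 = np.clip(70.0 - 22.0 * z + rng.normal(0, 6, n), 5.0, 199.0)
    decline = 1.0 + 1.8 * np.clip(z, 0, None)  # sicker patients fell faster
    cols = {"age": np.round(rng.uniform(age_low, age_high, n), 1)}
    cols["fev1pp_y0"] = fev1_y0
    for j in (1, 2, 3, 4):
        cols[f"fev1pp_ym{j}"] = np.clip(
            fev1_y0 + j * decline + rng.normal(0, 3, n), 5.0, 199.0)
    cols["fev1pp_y3"] = np.clip(
        fev1_y0 - 3.0 * decline + rng.normal(0, 4, n), 1.0, 199.0)
    height = rng.normal(167.0, 9.0, n)
    weight = np.clip(62.0 - 4.0 * z + rng.normal(0, 9, n), 30.0, 130.0)
    cols["height"] = np.round(height, 1)
    cols["weight"] = np.round(weight, 1)
    cols["bmi"] = np.round(weight / (height / 100.0) ** 2, 1)
    cols["oxygen_therapy"] = (rng.uniform(size=n)
                              < expit(-3.2 + 1.6 * z)).astype(int)
    cols["iv_antibiotics"] = (rng.uniform(size=n)
                              < expit(-0.4 + 0.9 * z)).astype(int)
    cols["diabetes"] = (rng.uniform(size=n) < expit(-1.0 + 0.6 * z)).astype(int)
    cols["chronic_pseudomonas"] = (rng.uniform(size=n)
                                   < expit(0.2 + 0.5 * z)).astype(int)
    names = [a for a, _ in ALLELE_POOL]
    probs = np.array([p for _, p in ALLELE_POOL])
    cols["allele_a"] = rng.choice(names, size=n, p=probs)
    cols["allele_b"] = rng.choice(names, size=n, p=probs)
    return cols


def generate_registry(spec: GeneratorSpec) -> pd.DataFrame:
    """One registry extract in the cohort CSV dialect.

    Rows: ``spec.n`` analysis patients plus the requested prior-transplant,
    lost-to-follow-up and pediatric rows (removed again by
    :func:`riskpipe.cohort.assemble_cohort`).

    Raises
    ------
    ValueError
        When the requested prevalence is unattainable given the effects.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    z = rng.standard_normal(n)
    cols = _block(rng, n, z, spec)

    eta = (spec.effect_severity * z
           + spec.effect_oxygen * cols["oxygen_therapy"]
           + spec.effect_low_fev1 * (cols["fev1pp_y0"] < 30.0))

    def gap(b0):
        return expit(b0 + eta).mean() - spec.prevalence

    try:
        b0 = brentq(gap, -40.0, 40.0)
    except ValueError as exc:
        raise ValueError("prevalence unattainable with these effects") from exc
    if spec.exact_prevalence:
        k = int(round(n * spec.prevalence))
        gumbel = -np.log(-np.log(rng.uniform(size=n)))
        event = np.zeros(n, dtype=bool)
        event[np.argsort(-(b0 + eta + gumbel))[:k]] = True
    else:
        event = rng.uniform(size=n) < expit(b0 + eta)

    # split the composite endpoint: death only / transplant only / both
    u = rng.uniform(size=n)
    death = event & ((u < 0.696) | (u >= 0.968))
    lt = event & (u >= 0.696)
    cols["death_3y"] = death.astype(int)
    cols["lt_3y"] = lt.astype(int)
    cols["prior_lt"] = np.zeros(n, dtype=int)
    cols["lost_fu"] = np.zeros(n, dtype=int)
    frame = pd.DataFrame(cols)

    # missingness on the analysis block
    for col, rate in spec.missingness.items():
        if col in frame:
            frame.loc[_mask(rng, z, rate, spec.mar_coef), col] = np.nan
    if spec.horizon_fev1_missing:
        frame.loc[_mask(rng, z, spec.horizon_fev1_missing, 0.0),
                  "fev1pp_y3"] = np.nan

    extras = []
    for count, flag, ages in (
        (spec.n_prior_transplant, "prior_lt", (18.0, 62.0)),
        (spec.n_lost_followup, "lost_fu", (18.0, 62.0)),
        (spec.n_pediatric, None, (1.0, 17.5)),
    ):
        if count == 0:
            continue
        ze = rng.standard_normal(count)
        block = pd.DataFrame(_block(rng, count, ze, spec,
                                    age_low=ages[0], age_high=ages[1]))
        block["death_3y"] = 0
        block["lt_3y"] = 0
        block["prior_lt"] = 0
        block["lost_fu"] = 0
        if flag:
            block[flag] = 1
        extras.append(block)
    if extras:
        frame = pd.concat([frame] + extras, ignore_index=True)
    frame.insert(0, "id", np.arange(len(frame)))
    return frame


# --------------------------------------------------------------------------
# planted utility landscape
# --------------------------------------------------------------------------

class PlantedLandscape:
    """A deterministic, stage-additive utility over a registry's combinations.

    The components of ``best_combo`` each carry effect 0; every other
    component carries a distinct negative effect of magnitude >= ``margin``,
    so the planted optimum exceeds all other combinations by at least
    ``margin``.  Optional Gaussian evaluation noise.  The true argmax is
    exposed for assertions.
    """

    def __init__(self, registry: Registry, best_combo: tuple[str, str, str, str],
                 margin: float = 0.1, noise_sd: float = 0.0, seed: int = 0,
                 base: float = 0.8):
        self.registry = registry
        self.argmax = tuple(best_combo)
        self.margin = margin
        self.noise_sd = noise_sd
        self.base_value = base
        self._rng = np.random.default_rng(seed)
        self._effects: dict[str, dict[str, float]] = {}
        for stage, best in zip(STAGES, best_combo):
            names = [c.name for c in registry.stage(stage)]
            if best not in names:
                raise ValueError(f"{best!r} not in registry stage {stage!r}")
            eff = {}
            j = 0
            for name in names:
                if name == best:
                    eff[name] = 0.0
                else:
                    eff[name] = -(margin + 0.05 * j)
                    j += 1
            self._effects[stage] = eff

    def base(self, combo: tuple[str, str, str, str]) -> float:
        return float(np.clip(
            self.base_value
            + sum(self._effects[s][c] for s, c in zip(STAGES, combo)),
            0.0, 1.0))

    def combo_of(self, config: PipelineConfig) -> tuple[str, str, str, str]:
        return (config.imputer, config.processor,
                config.classifier, config.calibrator)

    def __call__(self, config: PipelineConfig) -> float:
        v = self.base(self.combo_of(config))
        if self.noise_sd:
            v = float(np.clip(v + self._rng.normal(0.0, self.noise_sd), 0.0, 1.0))
        return v


def planted_landscape(registry: Registry, best_combo, margin: float = 0.1,
                      noise_sd: float = 0.0, seed: int = 0) -> PlantedLandscape:
    return PlantedLandscape(registry, best_combo, margin, noise_sd, seed)


# --------------------------------------------------------------------------
# planted rules
# --------------------------------------------------------------------------

OTHER_LEVEL = "other"


def planted_rules_dataset(rules, n: int, noise: float = 0.0, seed: int = 0,
                          background_frac: float = 0.25,
                          decoy_frac: float = 0.5):
    """Discretized dataset with known ground-truth association rules.

    ``rules`` is a list of ``(antecedent dict {column: level}, consequent)``.
    Rows are split into one block per rule plus a background share; block
    rows carry their rule's full antecedent and receive the consequent label
    with probability ``1 - noise``; background rows are labeled by the
    marginal distribution of consequents.  Outside a rule's own block, every
    antecedent column independently carries a planted level with probability
    ``decoy_frac`` (accidental full matches are knocked out), so proper
    sub-conjunctions and level patterns are label-independent there and only
    the full planted conjunction retains the planted confidence.

    Returns ``(frame, labels)``.
    """
    if not rules:
        raise ValueError("need at least one rule")
    for i, (ant_i, con_i) in enumerate(rules):
        for ant_j, con_j in rules[i + 1:]:
            inter = set(ant_i) & set(ant_j)
            if all(ant_i[c] == ant_j[c] for c in inter) and con_i != con_j \
                    and (set(ant_i) <= set(ant_j) or set(ant_j) <= set(ant_i)):
                raise ValueError("conflicting antecedents with different consequents")

    rng = np.random.default_rng(seed)
    groups = list(dict.fromkeys(con for _, con in rules))
    ant_cols = sorted({c for ant, _ in rules for c in ant})
    levels_per_col = {
        c: sorted({ant[c] for ant, _ in rules if c in ant}) for c in ant_cols}

    n_bg = int(round(n * background_frac))
    block_sizes = np.full(len(rules), (n - n_bg) // len(rules))
    block_sizes[: (n - n_bg) - block_sizes.sum()] += 1

    # decoy base: every antecedent column carries some planted level with
    # probability decoy_frac, independent of the (future) label
    frame = pd.DataFrame({
        c: np.where(rng.uniform(size=n) < decoy_frac,
                    rng.choice(levels_per_col[c], size=n), OTHER_LEVEL)
        for c in ant_cols
    }).astype(object)
    block_id = np.full(n, -1)
    start = 0
    for i, size in enumerate(block_sizes):
        block_id[start:start + size] = i
        start += size

    # with a single consequent the background marginal is degenerate; label
    # background rows with an explicit unaffected group instead
    bg_groups = groups if len(groups) > 1 else ["none"]
    labels = np.empty(n, dtype=object)
    labels[block_id < 0] = rng.choice(bg_groups, size=int((block_id < 0).sum()))
    for i, ((ant, con), size) in enumerate(zip(rules, block_sizes)):
        rows = block_id == i
        for c, level in ant.items():
            frame.loc[rows, c] = level
        lab = np.full(size, con, dtype=object)
        flip = rng.uniform(size=size) < noise
        others = [g for g in groups if g != con] or bg_groups
        if flip.any():
            lab[flip] = rng.choice(others, size=int(flip.sum()))
        labels[rows] = lab

    # knock out accidental full matches outside a rule's own block
    for j, (ant, con) in enumerate(rules):
        m = block_id != j
        for c, level in ant.items():
            m &= (frame[c] == level).to_numpy()
        for r in np.flatnonzero(m):
            own = {} if block_id[r] < 0 else rules[block_id[r]][0]
            eligible = [c for c in ant
                        if not (c in own and own[c] == ant[c])]
            if eligible:
                frame.iloc[r, frame.columns.get_loc(
                    eligible[rng.integers(len(eligible))])] = OTHER_LEVEL

    frame["noise_col"] = rng.choice(["a", "b"], size=n)
    perm = rng.permutation(n)
    return frame.iloc[perm].reset_index(drop=True), labels[perm]
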