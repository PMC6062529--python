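"""Post-hoc interpreter: association rules linking covariates to risk strata.

The fitted ensemble's risk scores are binned into clinician-defined risk
strata (a partition of [0, 1], half-open intervals except the last, default
low <5%, moderate 5–30%, high 30–50%, very high >=50%).  Continuous
covariates are discretized by recursive minimum-description-length (MDL)
entropy splitting against the strata labels — with per-column forced cuts
available, e.g. the classical 30% threshold for FEV1% predicted — and a
greedy k-ruleitem associative classifier mines conjunctive rules

    C_1 AND C_2 AND ... AND C_l  =>  risk group R

kept when they meet minimum confidence and support.  Following the source
convention, *support* is the prevalence of the consequent risk group; the
standard antecedent-and-consequent support is reported alongside as a
secondary statistic.  The interpreter only explains predictions — it never
alters them and optimizes no accuracy metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BREAKPOINTS = (0.05, 0.33, 0.5)
DEFAULT_LABELS = ("low", "moderate", "high", "very_high")
MISSING_LEVEL = "missing"


# --------------------------------------------------------------------------
# risk strata
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskStrata:
    """Ordered partition of [0, 1] into actionable risk groups."""

    breakpoints: tuple[float, ...] = DEFAULT_BREAKPOINTS
    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self):
        b = tuple(float(x) for x in self.breakpoints)
        if len(b) < 1:
            raise ValueError("need at least 2 intervals (>=1 breakpoint)")
        if any(not (0.0 < x < 1.0) for x in b) or list(b) != sorted(set(b)):
            raise ValueError("breakpoints must be strictly increasing in (0, 1)")
        if len(self.labels) != len(b) + 1:
            raise ValueError("need one label per interval")
        object.__setattr__(self, "breakpoints", b)

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def intervals(self) -> list[tuple[float, float]]:
        edges = (0.0,) + self.breakpoints + (1.0,)
        return list(zip(edges[:-1], edges[1:]))


def assign_group(scores, strata: RiskStrata):
    """Interval membership of each score; half-open, last interval closed."""
    s = np.asarray(scores, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    idx = np.searchsorted(strata.breakpoints, s, side="right")
    if s.ndim == 0:
        return strata.labels[int(idx)]
    return np.asarray(strata.labels, dtype=object)[idx]


# --------------------------------------------------------------------------
# MDL discretization (Fayyad–Irani recursive entropy splitting)
# --------------------------------------------------------------------------

def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _best_cut(values: np.ndarray, labels: np.ndarray):
    """Entropy-minimizing boundary cut, or None when no candidate exists."""
    order = np.argsort(values, kind="mergesort")
    v, lab = values[order], labels[order]
    n = v.size
    boundaries = np.flatnonzero(np.diff(v)) + 1  # first index of each new value
    best = None
    for i in boundaries:
        e = (i * _entropy(lab[:i]) + (n - i) * _entropy(lab[i:])) / n
        if best is None or e < best[0]:
            best = (e, i)
    if best is None:
        return None
    e, i = best
    return (v[i - 1] + v[i]) / 2.0, i, e, lab


def mdl_discretize(values, class_labels) -> list[float]:
    """Cut points for one continuous column against class labels.

    Binary entropy splits are accepted recursively when the information gain
    exceeds the MDL bound ``(log2(N-1) + log2(3^k - 2) - k*E + k1*E1 + k2*E2)/N``;
    cut points sit at midpoints between adjacent distinct values.  A constant
    column yields the empty list.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(class_labels)
    if v.shape != lab.shape:
        raise ValueError("values and class_labels must align")
    mask = ~np.isnan(v)
    cuts: list[float] = []
    _mdl_recurse(v[mask], lab[mask], cuts)
    return sorted(cuts)


def _mdl_recurse(v: np.ndarray, lab: np.ndarray, cuts: list[float]) -> None:
    if np.unique(v).size < 2 or np.unique(lab).size < 2:
        return
    found = _best_cut(v, lab)
    if found is None:
        return
    cut, i, _, lab_sorted = found
    order = np.argsort(v, kind="mergesort")
    v_sorted = v[order]
    left_lab, right_lab = lab_sorted[:i], lab_sorted[i:]
    n = v.size
    ent = _entropy(lab_sorted)
    e1, e2 = _entropy(left_lab), _entropy(right_lab)
    gain = ent - (i * e1 + (n - i) * e2) / n
    k = np.unique(lab_sorted).size
    k1 = np.unique(left_lab).size
    k2 = np.unique(right_lab).size
    delta = np.log2(3.0**k - 2.0) - (k * ent - k1 * e1 - k2 * e2)
    if gain <= (np.log2(n - 1) + delta) / n:
        return
    cuts.append(float(cut))
    _mdl_recurse(v_sorted[:i], left_lab, cuts)
    _mdl_recurse(v_sorted[i:], right_lab, cuts)


def _interval_labels(cuts: list[float]) -> list[str]:
    if len(cuts) == 1:
        c = _fmt(cuts[0])
        return [f"<{c}", f">={c}"]
    labels = [f"<{_fmt(cuts[0])}"]
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        labels.append(f"[{_fmt(lo)},{_fmt(hi)})")
    labels.append(f">={_fmt(cuts[-1])}")
    return labels


def _fmt(x: float) -> str:
    return f"{x:g}"


def discretize_dataset(X: pd.DataFrame, class_labels,
                       forced_cuts: dict[str, list[float]] | None = None
                       ) -> pd.DataFrame:
    """Replace continuous columns by interval levels; binaries pass through.

    ``forced_cuts`` overrides the MDL output for named columns (a forced cut
    outside the observed range is applied with a warning).  Missing entries
    map to the level ``"missing"``.
    """
    forced_cuts = forced_cuts or {}
    lab = np.asarray(class_labels)
    out = {}
    for col in X.columns:
        s = X[col]
        vals = s.dropna().unique()
        if col not in forced_cuts and len(vals) <= 2:
            out[col] = s.map(lambda x: _fmt(float(x)), na_action="ignore") \
                        .fillna(MISSING_LEVEL).astype(object)
            continue
        if col in forced_cuts:
            cuts = sorted(float(c) for c in forced_cuts[col])
            lo, hi = s.min(), s.max()
            outside = [c for c in cuts if not (lo <= c <= hi)]
            if outside:
                warnings.warn(
                    f"forced cut(s) {outside} outside observed range of {col!r}")
        else:
            cuts = mdl_discretize(s.to_numpy(dtype=float), lab)
        if not cuts:
            out[col] = pd.Series(np.where(s.isna(), MISSING_LEVEL, "any"),
                                 index=s.index, dtype=object)
            continue
        names = _interval_labels(cuts)
        idx = np.searchsorted(cuts, s.to_numpy(dtype=float), side="right")
        levels = np.asarray(names, dtype=object)[np.clip(idx, 0, len(names) - 1)]
        out[col] = pd.Series(np.where(s.isna(), MISSING_LEVEL, levels),
                             index=s.index, dtype=object)
    return pd.DataFrame(out, index=X.index)


# --------------------------------------------------------------------------
# association rules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationRule:
    """Conjunction of (column, level) conditions implying a risk group."""

    antecedent: tuple[tuple[str, str], ...]
    consequent: str
    confidence: float
    support: float            # prevalence of the consequent risk group
    standard_support: float   # P(antecedent AND consequent)

    def render(self) -> str:
        conds = " AND ".join(f"{c}={v}" for c, v in self.antecedent)
        return (f"IF {conds} THEN {self.consequent} "
                f"(c={self.confidence:.3f}, s={self.support:.3f})")


@dataclass
class RuleSet:
    rules: list[AssociationRule] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self):
        return len(self.rules)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"antecedent": "|".join(f"{c}={v}" for c, v in r.antecedent),
             "consequent": r.consequent,
             "confidence": r.confidence,
             "support": r.support,
             "standard_support": r.standard_support}
            for r in self.rules
        ])

    def report(self) -> str:
        if not self.rules:
            return "No association rules met the thresholds.\n"
        return "\n".join(r.render() for r in self.rules) + "\n"


def _match(disc: pd.DataFrame, antecedent) -> np.ndarray:
    m = np.ones(len(disc), dtype=bool)
    for col, level in antecedent:
        m &= (disc[col] == level).to_numpy()
    return m


def rule_stats(antecedent, consequent, disc: pd.DataFrame, labels
               ) -> tuple[float, float, float]:
    """(support, confidence, standard_support) of a rule on a discretized frame.

    Confidence is the fraction of antecedent-matching rows labeled with the
    consequent (NaN when no row matches); support is the prevalence of the
    consequent group.
    """
    lab = np.asarray(labels)
    m = _match(disc, antecedent)
    hit = lab == consequent
    support = float(hit.mean())
    confidence = float(hit[m].mean()) if m.any() else float("nan")
    standard = float((m & hit).mean())
    return support, confidence, standard


def mine_rules(disc: pd.DataFrame, labels, min_support: float = 0.2,
               min_confidence: float = 0.8, max_len: int = 3) -> RuleSet:
    """Greedy k-ruleitem mining of class-association rules per risk group.

    For each group meeting the support floor, antecedents grow one condition
    at a time, always adding the condition of highest confidence (ties broken
    by higher standard support, then lexicographically).  A grown rule is
    emitted as soon as it meets both thresholds on the full dataset; its
    covered rows are then removed and mining repeats (sequential covering),
    so several rules per group can surface.  Longer rules subsumed by an
    emitted shorter one are never produced.
    """
    lab = np.asarray(labels)
    n = len(disc)
    cols = list(disc.columns)
    level_map = {c: sorted(disc[c].unique().tolist()) for c in cols}
    out = RuleSet()

    for group in pd.unique(lab):
        support = float((lab == group).mean())
        if support < min_support:
            continue
        remaining = np.ones(n, dtype=bool)
        while True:
            rule = _grow_rule(disc, lab, group, remaining, cols, level_map,
                              min_confidence, min_support, max_len)
            if rule is None:
                break
            out.rules.append(rule)
            remaining &= ~_match(disc, rule.antecedent)
            if not remaining.any():
                break
    return out


def _grow_rule(disc, lab, group, remaining, cols, level_map,
               min_confidence, min_support, max_len):
    antecedent: list[tuple[str, str]] = []
    used: set[str] = set()
    base = _match(disc, antecedent) & remaining
    for _ in range(max_len):
        best = None
        for col in cols:
            if col in used:
                continue
            col_vals = disc[col].to_numpy()
            for level in level_map[col]:
                if level == MISSING_LEVEL:
                    continue
                m = base & (col_vals == level)
                k = int(m.sum())
                if k == 0:
                    continue
                conf = float((lab[m] == group).mean())
                std = float((m & (lab == group)).sum()) / len(disc)
                cand = (conf, std, col, str(level), level, m)
                if best is None or (cand[0], cand[1], *_lex(cand)) > \
                        (best[0], best[1], *_lex(best)):
                    best = cand
        if best is None:
            return None
        conf, _, col, _, level, m = best
        antecedent.append((col, level))
        used.add(col)
        base = m
        support, full_conf, std = rule_stats(antecedent, group, disc, lab)
        if full_conf >= min_confidence and support >= min_support:
            return AssociationRule(tuple(antecedent), group,
                                   full_conf, support, std)
    return None


def _lex(cand):
    # invert strings so that tuple max favours lexicographically smaller names
    return (tuple(-ord(ch) for ch in cand[2]), tuple(-ord(ch) for ch in cand[3]))


def explain(ensemble, X: pd.DataFrame, strata: RiskStrata | None = None,
            min_support: float = 0.2, min_confidence: float = 0.8,
            max_len: int = 3,
            forced_cuts: dict[str, list[float]] | None = None) -> RuleSet:
    """Predict → stratify → discretize → mine.  Never alters predictions."""
    strata = strata or RiskStrata()
    scores = ensemble.predict(X)
    groups = assign_group(scores, strata)
    disc = discretize_dataset(X, groups, forced_cuts=forced_cuts)
    return mine_rules(disc, groups, min_support=min_support,
                      min_confidence=min_confidence, max_len=max_len)
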