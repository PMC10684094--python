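"""Bridge between symbolic clinical rules and network parameters.

A rule is a conjunction of (feature, concept) terms with importances in
[0, 1] plus per-class contribution weights — e.g. "IF systolic blood
pressure is low AND ejection fraction is low, THEN refer for advanced
therapies".  The module supports three directions of travel:

* ``init_from_rules`` injects expert rules into a fresh parameter set so
  training starts from clinical knowledge rather than noise;
* ``extract_rules`` reads the trained attention/connection/inference
  weights back into symbolic rules, filtered by firing strength,
  pairwise correlation and term importance;
* ``ensemble_rules`` pools rules extracted from cross-validation folds
  into a compact, de-duplicated set for network re-initialization.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import (
    FeatureSchema,
    NetworkParams,
    StandardizationStats,
    encode,
    raw_from_cutoffs,
    rule_strengths,
)

__all__ = [
    "RuleTerm",
    "Rule",
    "RuleSet",
    "init_from_rules",
    "extract_rules",
    "ensemble_rules",
    "render_rules",
]

RULESET_SCHEMA_VERSION = 1

#: attention/connection targets for knowledge injection: high enough to
#: bias training toward the expert rule, low enough not to pin it
HIGH_INIT = 0.9
LOW_INIT = 0.05

#: standard-normal quantiles (20/40/60/80%) used for cutoff init when no
#: training data are at hand (features are standardized)
_DEFAULT_CUTOFF_QUANTILES = (0.2, 0.4, 0.6, 0.8)


@dataclass(frozen=True)
class RuleTerm:
    feature: str
    concept: str  # "low"/"medium"/"high" or a categorical level name
    importance: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.importance <= 1.0):
            raise ValueError("term importance must lie in [0, 1]")


@dataclass
class Rule:
    terms: list[RuleTerm]
    class_weights: list[float] | None = None  # per-class contribution, >= 0
    strength: float = 0.0  # mean firing over a reference dataset
    origin: int | None = None  # network rule column this rule was read from

    def __post_init__(self):
        if not self.terms:
            raise ValueError("a rule needs at least one term")
        feats = [t.feature for t in self.terms]
        if len(set(feats)) != len(feats):
            raise ValueError("a feature may appear at most once per rule")
        if self.class_weights is not None and any(w < 0 for w in self.class_weights):
            raise ValueError("class weights must be non-negative")

    def term_dict(self) -> dict[tuple[str, str], float]:
        return {(t.feature, t.concept): t.importance for t in self.terms}


@dataclass
class RuleSet:
    rules: list[Rule] = field(default_factory=list)

    def __len__(self):
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def to_json(self, path=None) -> str:
        doc = {
            "format": "tgfnn-ruleset",
            "schema_version": RULESET_SCHEMA_VERSION,
            "rules": [
                {
                    "terms": [
                        {"feature": t.feature, "concept": t.concept,
                         "importance": t.importance}
                        for t in r.terms
                    ],
                    "class_weights": r.class_weights,
                    "strength": r.strength,
                    "origin": r.origin,
                }
                for r in self.rules
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RuleSet":
        text = Path(source).read_text() if not str(source).lstrip().startswith("{") else str(source)
        doc = json.loads(text)
        if doc.get("format") != "tgfnn-ruleset":
            raise ValueError("not a ruleset document")
        return cls(
            [
                Rule(
                    [RuleTerm(t["feature"], t["concept"], t.get("importance", 1.0))
                     for t in r["terms"]],
                    r.get("class_weights"),
                    r.get("strength", 0.0),
                    r.get("origin"),
                )
                for r in doc["rules"]
            ]
        )


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _inv_softplus(y):
    # log(exp(y) - 1), stable for small and large y
    y = np.asarray(y, dtype=np.float64)
    return y + np.log1p(-np.exp(-y))


def init_from_rules(ruleset: RuleSet, schema: FeatureSchema, K: int, seed: int,
                    n_classes: int = 2, positive_class: int = 1,
                    data=None) -> NetworkParams:
    """Parameter initialization with expert rules injected.

    Rule ``k`` (for each symbolic rule) gets attention 0.9 on its
    (feature, concept) slots (scaled by term importance), 0.05 elsewhere
    in that column; connection 0.9 on the rule's features, 0.05 on the
    rest; and a high positive-class inference weight.  The remaining
    ``K - len(ruleset)`` rule columns are seeded randomly at small
    magnitudes.  Membership cutoffs start at the 20/40/60/80% quantiles
    of ``data``'s continuous columns (standard-normal quantiles if no
    data are supplied).
    """
    if K < len(ruleset):
        raise ValueError(f"K={K} is smaller than the {len(ruleset)} supplied rules")
    N, D = schema.n_features, schema.concept_dim
    rng = np.random.default_rng(seed)

    # random low-magnitude background for all columns
    A = rng.uniform(0.02, 0.15, size=(N, D, K))
    M = rng.uniform(0.02, 0.15, size=(N, K))
    W = rng.uniform(0.02, 0.15, size=(K, n_classes))

    for k, rule in enumerate(ruleset):
        A[:, :, k] = LOW_INIT
        M[:, k] = LOW_INIT
        for t in rule.terms:
            i = _feature_index(schema, t.feature)
            d = schema.concept_index(t.feature, t.concept)
            A[i, d, k] = LOW_INIT + (HIGH_INIT - LOW_INIT) * t.importance
            M[i, k] = HIGH_INIT
        if rule.class_weights is not None:
            cw = np.asarray(rule.class_weights, dtype=np.float64)
            scale = cw / cw.max() if cw.max() > 0 else cw
            W[k] = LOW_INIT + (HIGH_INIT - LOW_INIT) * scale
        else:
            W[k] = LOW_INIT
            W[k, positive_class] = HIGH_INIT

    if data is not None:
        Xc = np.atleast_2d(np.asarray(data, dtype=np.float64))[:, schema.continuous_positions]
        cuts = np.nanquantile(Xc, _DEFAULT_CUTOFF_QUANTILES, axis=0).T
        # degenerate columns: fall back to standard-normal quantiles
        from scipy.stats import norm

        bad = np.diff(cuts, axis=-1).min(axis=-1) < 1e-6
        cuts[bad] = norm.ppf(_DEFAULT_CUTOFF_QUANTILES)
    else:
        from scipy.stats import norm

        cuts = np.tile(norm.ppf(_DEFAULT_CUTOFF_QUANTILES), (schema.n_continuous, 1))

    return NetworkParams(
        schema,
        attention_raw=_logit(A),
        connection_raw=_logit(M),
        inference_raw=_inv_softplus(np.maximum(W, 1e-4)),
        cutoff_raw=raw_from_cutoffs(cuts),
    )


def _feature_index(schema: FeatureSchema, name: str) -> int:
    try:
        return schema.index(name)
    except KeyError:
        raise KeyError(
            f"rule references unknown feature {name!r}; schema has {schema.names}"
        ) from None


def _cosine(u, v):
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def extract_rules(params: NetworkParams, firing_data,
                  strength_threshold: float = 0.1,
                  corr_threshold: float = 0.9,
                  importance_threshold: float = 0.2) -> RuleSet:
    """Read the trained network back into a filtered symbolic rule set.

    Rule strength is the mean firing over ``firing_data`` (model-ready
    rows).  Rules below ``strength_threshold`` are discarded; among
    survivors, when two rules' contribution columns have cosine
    similarity above ``corr_threshold`` the weaker is dropped; surviving
    rules keep the terms whose contribution ``S[i,d,k]`` reaches
    ``importance_threshold``.
    """
    X = np.atleast_2d(np.asarray(firing_data, dtype=np.float64))
    if X.size == 0:
        raise ValueError("firing_data must be nonempty")
    enc = encode(X, params.schema, params.membership_params)
    r = rule_strengths(enc, params)  # (B, K)
    strengths = r.mean(axis=0)
    S = params.contribution  # (N, D, K)
    W = params.inference

    order = np.argsort(-strengths, kind="stable")
    alive = [k for k in order if strengths[k] >= strength_threshold]
    kept: list[int] = []
    for k in alive:  # strongest first; drop later (weaker) correlated rules
        col = S[:, :, k].ravel()
        if all(_cosine(col, S[:, :, j].ravel()) <= corr_threshold for j in kept):
            kept.append(k)

    rules = []
    for k in kept:
        terms = []
        for i, f in enumerate(params.schema.features):
            # a feature contributes at most one concept: its strongest slot
            d = int(np.argmax(S[i, : f.n_concepts, k]))
            if S[i, d, k] >= importance_threshold:
                terms.append(
                    RuleTerm(f.name, f.concept_names()[d],
                             float(np.clip(S[i, d, k], 0, 1)))
                )
        if not terms:
            # typical for never-strengthened background columns
            logging.getLogger("tgfnn").debug(
                "rule %d has no term above the importance threshold %g; dropped",
                k, importance_threshold,
            )
            continue
        terms.sort(key=lambda t: -t.importance)
        rules.append(Rule(terms, class_weights=W[k].tolist(),
                          strength=float(strengths[k]), origin=int(k)))
    if not rules:
        warnings.warn("all rules were filtered out; returning an empty rule set")
    return RuleSet(rules)


def _term_matrix(rules: list[Rule]):
    """Vectorize rules over the union of their (feature, concept) pairs."""
    keys = sorted({key for r in rules for key in r.term_dict()})
    idx = {k: i for i, k in enumerate(keys)}
    V = np.zeros((len(rules), len(keys)))
    for j, r in enumerate(rules):
        for key, imp in r.term_dict().items():
            V[j, idx[key]] = imp
    return V, keys


def ensemble_rules(fold_rulesets: list[RuleSet], corr_threshold: float = 0.9,
                   max_rules: int = 10) -> RuleSet:
    """Pool fold rule sets into the strongest, least-correlated subset.

    Rules are sorted by strength and kept greedily while their pairwise
    term-vector cosine similarity stays at or below ``corr_threshold``
    and at most ``max_rules`` survive.  Applying the function to its own
    output is a no-op.
    """
    if not fold_rulesets:
        raise ValueError("need at least one fold ruleset")
    pooled = [r for rs in fold_rulesets for r in rs]
    if not pooled:
        return RuleSet([])
    pooled.sort(key=lambda r: -r.strength)
    V, _ = _term_matrix(pooled)
    kept: list[int] = []
    for j in range(len(pooled)):
        if len(kept) >= max_rules:
            break
        if all(_cosine(V[j], V[i]) <= corr_threshold for i in kept):
            kept.append(j)
    return RuleSet([pooled[j] for j in kept])


DEFAULT_ACTIONS = {
    1: "refer for heart transplantation/ LVAD",
    0: "no referral for advanced therapies",
}


def render_rules(ruleset: RuleSet, stats: StandardizationStats | None = None,
                 display_names: dict[str, str] | None = None,
                 actions: dict[int, str] | None = None):
    """Human-readable IF/AND/THEN report plus the concept-by-rule matrix.

    Returns ``(report_text, heatmap)`` where ``heatmap`` is a pandas
    DataFrame with one row per used feature:concept pair and one column
    per rule, holding term importances — the data behind the usual
    rule-heatmap figure.  Each rule's sentence is followed by its mean
    firing strength and per-class inference weights.
    """
    import pandas as pd

    display_names = display_names or {}
    actions = actions or DEFAULT_ACTIONS
    lines = []
    for j, rule in enumerate(ruleset, start=1):
        clauses = []
        for t in rule.terms:
            name = display_names.get(t.feature, t.feature)
            if stats is not None and t.feature in stats.units:
                name = f"{name} [{stats.units[t.feature]}]"
            clauses.append(f"{name} is {t.concept}")
        target = 1
        if rule.class_weights:
            target = int(np.argmax(rule.class_weights))
        action = actions.get(target, f"class {target}")
        sentence = "IF " + " AND ".join(clauses) + f", THEN {action}"
        lines.append(f"Rule {j}: {sentence}")
        detail = f"  strength={rule.strength:.3f}"
        if rule.class_weights:
            detail += "  class_weights=" + "/".join(f"{w:.3f}" for w in rule.class_weights)
        lines.append(detail)
    report = "\n".join(lines) + ("\n" if lines else "")

    if len(ruleset):
        V, keys = _term_matrix(list(ruleset))
        heatmap = pd.DataFrame(
            V.T,
            index=[f"{display_names.get(f, f)}:{c}" for f, c in keys],
            columns=[f"rule_{j + 1}" for j in range(len(ruleset))],
        )
    else:
        heatmap = pd.DataFrame()
    return report, heatmap
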