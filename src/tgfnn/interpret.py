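"""Post-hoc interpretability: membership curves, concept transition
boundaries in clinical units, and per-sample fired-rule explanations.

The learned membership functions define where a clinical variable stops
being "low" and starts being "medium" (and so on).  We report, per
continuous feature, the x-positions where each membership ramp crosses
0.5: with near-crisp memberships these coincide with the intersections
of adjacent curves, and the 0.5 convention stays well defined even when
the smooth curves do not intersect cleanly.  Boundaries are solved by
bracketed root finding in standardized units and mapped back to clinical
units with the stored standardization statistics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .fuzzy_core import membership
from .network import NetworkParams, StandardizationStats, encode, infer, rule_strengths, softmax
from .rules import RuleSet, render_rules

__all__ = [
    "RangeTable",
    "SampleExplanation",
    "critical_values",
    "explain_sample",
    "membership_curves",
]

#: membership level whose crossing defines a concept transition
BOUNDARY_LEVEL = 0.5
#: bisection tolerance, standardized units
ROOT_XTOL = 1e-6


@dataclass
class RangeTable:
    """Concept transition boundaries per continuous feature.

    ``low`` is where the "low" membership falls through 0.5;
    ``medium_left`` / ``medium_right`` bracket the "medium" plateau;
    ``high`` is where "high" rises through 0.5.  All in clinical units.
    """

    table: pd.DataFrame  # columns: feature, low, medium_left, medium_right, high, unit
    convention: str = "membership = 0.5 crossing of each ramp"

    def to_csv(self, path):
        with open(path, "w") as fh:
            fh.write(f"# boundary convention: {self.convention}\n")
            self.table.to_csv(fh, index=False)


@dataclass
class SampleExplanation:
    """Prediction plus the rules that fired for one sample."""

    prediction: np.ndarray  # class probabilities
    fired_rules: list[dict] = field(default_factory=list)
    # each: rule_index, strength, sentence, terms (feature/concept/degree)

    def to_json(self, path=None) -> str:
        doc = {
            "prediction": np.asarray(self.prediction).tolist(),
            "fired_rules": self.fired_rules,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        lines = [
            "Prediction: "
            + ", ".join(
                f"class {c}: {p:.3f}" for c, p in enumerate(np.asarray(self.prediction))
            )
        ]
        for fr in self.fired_rules:
            lines.append(f"[strength {fr['strength']:.3f}] {fr['sentence']}")
            for t in fr["terms"]:
                lines.append(
                    f"    {t['feature']} is {t['concept']}: degree {t['degree']:.3f}"
                )
        return "\n".join(lines) + "\n"


def _ramp_root(fn, lo, hi):
    """0.5-crossing of a monotone membership ramp on [lo, hi], or None."""
    flo, fhi = fn(lo) - BOUNDARY_LEVEL, fn(hi) - BOUNDARY_LEVEL
    if flo * fhi > 0:
        return None
    return brentq(lambda x: fn(x) - BOUNDARY_LEVEL, lo, hi, xtol=ROOT_XTOL)


def critical_values(params: NetworkParams,
                    stats: StandardizationStats | None = None) -> RangeTable:
    """Concept transition boundaries for every continuous feature.

    Solves, per feature, for the 0.5-crossings of the low (descending),
    medium (ascending and descending) and high (ascending) membership
    ramps by bisection inside a bracket spanning the cutoff range plus
    50% margin.  Features whose ramps do not cross 0.5 (degenerate
    memberships) are flagged and omitted with a warning.
    """
    stats = stats if stats is not None else params.standardization
    cuts = params.cutoffs
    eps1 = params.smoothness.eps
    rows = []
    cont = [params.schema.features[i] for i in params.schema.continuous_positions]
    for i, feat in enumerate(cont):
        a = cuts[i]
        span = max(a[3] - a[0], 1e-3)
        lo_b, hi_b = a[0] - 0.5 * span, a[3] + 0.5 * span

        def deg(concept):
            return lambda x: float(membership(x, a, eps1, concept, validate=False))

        mid = 0.5 * (a[1] + a[2])  # inside the medium plateau
        b_low = _ramp_root(deg("low"), lo_b, hi_b)
        b_med_l = _ramp_root(deg("medium"), lo_b, mid)
        b_med_r = _ramp_root(deg("medium"), mid, hi_b)
        b_high = _ramp_root(deg("high"), lo_b, hi_b)
        if None in (b_low, b_med_l, b_med_r, b_high):
            warnings.warn(
                f"feature {feat.name!r}: membership ramps do not all cross "
                f"{BOUNDARY_LEVEL}; omitting its row"
            )
            continue
        # enforce the ordering invariant against root-solver jitter
        vals = list(np.maximum.accumulate([b_low, b_med_l, b_med_r, b_high]))
        unit = ""
        if stats is not None and feat.name in stats.names:
            vals = [float(stats.unstandardize(feat.name, v)) for v in vals]
            unit = stats.units.get(feat.name, "")
        rows.append(
            {"feature": feat.name, "low": vals[0], "medium_left": vals[1],
             "medium_right": vals[2], "high": vals[3], "unit": unit}
        )
    return RangeTable(pd.DataFrame(
        rows, columns=["feature", "low", "medium_left", "medium_right", "high", "unit"]
    ))


def explain_sample(row, schema, params: NetworkParams, ruleset: RuleSet,
                   top_n: int = 5, display_names: dict | None = None) -> SampleExplanation:
    """Prediction plus the ``top_n`` strongest-firing rules for one row.

    Firing strengths are computed by the exact same forward path as
    training/evaluation; the per-term membership degrees show which
    concept of which feature drove each rule.  ``ruleset`` supplies the
    rendered sentences: rules are matched to network columns by their
    recorded ``origin`` column (falling back to list position).
    """
    row = np.asarray(row, dtype=np.float64)
    enc = encode(row[None], schema, params.membership_params)
    r = rule_strengths(enc, params)[0]
    O = infer(r[None], params)[0]
    probs = softmax(O[None])[0]

    sentences, _ = render_rules(ruleset, params.standardization, display_names)
    sentence_by_rule = [
        line.split(": ", 1)[1]
        for line in sentences.splitlines()
        if line.startswith("Rule ")
    ]
    by_column = {
        (rule.origin if rule.origin is not None else j): (rule, sentence_by_rule[j])
        for j, rule in enumerate(ruleset.rules)
    }

    order = np.argsort(-r, kind="stable")[: max(top_n, 0)]
    fired = []
    for k in order:
        if int(k) in by_column:
            rule, sent = by_column[int(k)]
            terms = []
            for t in rule.terms:
                i = schema.index(t.feature)
                d = schema.concept_index(t.feature, t.concept)
                terms.append(
                    {"feature": t.feature, "concept": t.concept,
                     "degree": float(enc[0, i, d]), "importance": t.importance}
                )
        else:  # network column without a symbolic counterpart
            sent = f"(unlabeled rule column {k})"
            terms = []
        fired.append(
            {"rule_index": int(k), "strength": float(r[k]), "sentence": sent,
             "terms": terms}
        )
    return SampleExplanation(prediction=np.asarray(probs), fired_rules=fired)


def membership_curves(params: NetworkParams, feature: str, grid=None) -> pd.DataFrame:
    """Dense (x, low, medium, high) table for plotting one feature.

    ``grid`` is in standardized units (defaults to 401 points spanning
    the cutoff range plus 50% margin); when standardization statistics
    are attached, a clinical-unit column ``x_unit`` is added.
    """
    cont = params.schema.continuous_positions
    names = [params.schema.features[i].name for i in cont]
    if feature not in names:
        raise KeyError(f"{feature!r} is not a continuous feature of this model")
    i = names.index(feature)
    a = params.cutoffs[i]
    if grid is None:
        span = max(a[3] - a[0], 1e-3)
        grid = np.linspace(a[0] - 0.5 * span, a[3] + 0.5 * span, 401)
    grid = np.asarray(grid, dtype=np.float64)
    deg = membership(grid[:, None], a, params.smoothness.eps, validate=False)
    df = pd.DataFrame(
        {"x": grid, "low": deg[:, 0, 0], "medium": deg[:, 0, 1], "high": deg[:, 0, 2]}
    )
    stats = params.standardization
    if stats is not None and feature in stats.names:
        df.insert(1, "x_unit", stats.unstandardize(feature, grid))
    return df
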