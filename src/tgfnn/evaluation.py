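"""Metrics and the cross-validated training protocol.

The experimental protocol mirrors clinical-prediction practice for
longitudinal EHR cohorts: patients (never individual hospitalization
pairs) are split into a holdout test set and k training folds; each fold
trains a knowledge-initialized network and contributes its extracted
rules; the fold rules are ensembled, the network re-initialized from the
ensemble and retrained on all training patients; the final model is
evaluated once on the holdout patients.  Standardization and imputation
models are fit exclusively on training-role rows (asserted, not just
documented).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .cohort import (
    ID_COL,
    LABEL_COL,
    CohortTable,
    SplitManifest,
    apply_filters,
    build_model_schema,
    build_pairs,
    derive_features,
    impute,
    patient_folds,
    standardize_and_encode,
)
from .interpret import critical_values
from .network import FeatureSchema, NetworkParams, forward, save_checkpoint
from .rules import Rule, RuleSet, RuleTerm, ensemble_rules, extract_rules, init_from_rules
from .training import TrainConfig, fit

logger = logging.getLogger("tgfnn")

__all__ = [
    "EvalReport",
    "compute_metrics",
    "run_cv",
    "run_full_protocol",
    "default_clinical_rules",
    "cv_auc_scorer",
]

METRIC_NAMES = ["accuracy", "recall", "specificity", "precision", "f1",
                "auc", "auprc", "mcc"]


def default_clinical_rules() -> RuleSet:
    """The four expert referral rules used for knowledge initialization.

    Advanced-heart-failure cardiology consensus: a low ejection fraction
    combined with (1) low systolic blood pressure, (2) severe mitral
    regurgitation, (3) rising BNP over the hospitalization, or (4)
    hyponatremia warrants referral for transplant/LVAD evaluation.
    """
    pos = [0.0, 1.0]
    return RuleSet(
        [
            Rule([RuleTerm("lvef", "low"), RuleTerm("sbp", "low")], list(pos)),
            Rule([RuleTerm("lvef", "low"), RuleTerm("mitral_regurg", "high")], list(pos)),
            Rule([RuleTerm("lvef", "low"), RuleTerm("bnp_delta_pct", "high")], list(pos)),
            Rule([RuleTerm("lvef", "low"), RuleTerm("sodium", "low")], list(pos)),
        ]
    )


# -- metrics --------------------------------------------------------------

def compute_metrics(labels, scores, threshold: float = 0.5) -> dict:
    """Confusion-derived and threshold-free metrics for one evaluation.

    ``scores`` are positive-class probabilities; the confusion matrix is
    taken at ``score >= threshold``.  Ratios with zero denominators are
    reported as 0 and listed under ``undefined``; AUC/AUPRC are NaN (and
    flagged) when only one class is present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(y) == 0:
        raise ValueError("need at least one sample")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must be probabilities in [0, 1]")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / len(y)
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        undefined.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    if len(np.unique(y)) < 2:
        undefined += ["auc", "auprc"]
        auc = auprc = float("nan")
    else:
        auc = float(roc_auc_score(y, s))
        auprc = float(average_precision_score(y, s))
    return {
        "accuracy": accuracy, "recall": recall, "specificity": specificity,
        "precision": precision, "f1": f1, "auc": auc, "auprc": auprc,
        "mcc": mcc, "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "n": len(y), "threshold": threshold, "undefined": undefined,
    }


@dataclass
class EvalReport:
    """Per-fold metric rows with mean/SD aggregation."""

    rows: list[dict] = field(default_factory=list)

    def add(self, name, metrics: dict):
        self.rows.append({"split": name, **metrics})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def summary(self) -> pd.DataFrame:
        df = self.to_dataframe()[METRIC_NAMES]
        return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


# -- per-fold preprocessing ----------------------------------------------

def _prepare_split(pairs: CohortTable, train_ids, eval_ids, seed: int):
    """Impute, derive and standardize with training-row statistics only."""
    train_ids, eval_ids = set(train_ids), set(eval_ids)
    assert not (train_ids & eval_ids), "a patient appears in both roles"
    sub = pairs.copy()
    keep = sub.df[ID_COL].isin(train_ids | eval_ids)
    sub.df = sub.df.loc[keep].reset_index(drop=True)
    fit_mask = sub.df[ID_COL].isin(train_ids).to_numpy()
    assert fit_mask.any() and (~fit_mask).any() or not eval_ids

    completed, _ = impute(sub, seed=seed, fit_mask=fit_mask)
    derived = derive_features(completed)
    schema = build_model_schema(derived)
    X, y, stats = standardize_and_encode(derived, schema, fit_mask)
    return X, y, stats, schema, fit_mask


def _fold_seed(master: int, salt: int) -> int:
    return int(np.random.default_rng([master, salt]).integers(2**31 - 1))


@dataclass
class FoldResult:
    fold: int
    params: NetworkParams
    ruleset: RuleSet
    metrics: dict


def run_cv(pairs: CohortTable, config: TrainConfig,
           init_ruleset: RuleSet | None = None,
           manifest: SplitManifest | None = None,
           k: int = 5, seed: int = 0,
           rule_thresholds: dict | None = None):
    """Patient-wise k-fold cross-validation with rule extraction.

    For each fold: preprocessing is fit on the fold-train rows, the
    network is initialized from ``init_ruleset`` (random when None),
    trained, evaluated on the fold's validation patients, and its rules
    extracted.  Returns ``(fold_results, EvalReport)``.
    """
    if manifest is None:
        manifest = patient_folds(pairs, k=k, seed=seed, holdout_fraction=0.0)
    report = EvalReport()
    results = []
    rt = rule_thresholds or {}
    for f in range(manifest.n_folds):
        val_ids = manifest.patients("train", fold=f)
        train_ids = np.setdiff1d(manifest.patients("train"), val_ids)
        fseed = _fold_seed(seed, f + 1)
        X, y, stats, schema, fit_mask = _prepare_split(pairs, train_ids, val_ids, fseed)
        X_tr, y_tr = X[fit_mask], y[fit_mask]
        X_val, y_val = X[~fit_mask], y[~fit_mask]

        cfg = TrainConfig(**{**vars(config), "seed": fseed})
        init = init_from_rules(init_ruleset or RuleSet([]), schema, cfg.n_rules,
                               seed=fseed, data=X_tr)
        init.standardization = stats
        try:
            params, _ = fit(X_tr, y_tr, schema, cfg, init=init)
        except Exception as err:
            raise RuntimeError(f"training failed in fold {f}") from err
        params.standardization = stats
        scores = forward(X_val, schema, params)[:, 1]
        m = compute_metrics(y_val, scores)
        report.add(f"fold_{f}", m)
        ruleset = extract_rules(params, X_tr, **rt)
        results.append(FoldResult(f, params, ruleset, m))
        logger.info("fold %d: AUC=%.3f F1=%.3f (%d rules kept)",
                    f, m["auc"], m["f1"], len(ruleset))
    return results, report


@dataclass
class ProtocolResult:
    params: NetworkParams
    ruleset: RuleSet
    ensembled_init: RuleSet
    cv_report: EvalReport
    holdout_metrics: dict
    manifest: SplitManifest
    schema: FeatureSchema


def run_full_protocol(cohort: CohortTable, config: TrainConfig,
                      init_ruleset: RuleSet | None = None,
                      k: int = 5, seed: int = 0,
                      holdout_fraction: float = 0.2,
                      out_dir=None,
                      rule_thresholds: dict | None = None) -> ProtocolResult:
    """CV, rule ensembling, re-initialized retraining, holdout evaluation.

    Accepts an encounter-level cohort (filters and pairing are applied)
    or a pre-built pair table.  Artifacts (model checkpoint, final rule
    set, range table, evaluation report, split manifest) are written to
    ``out_dir`` when given.
    """
    if cohort.level == "encounter":
        filtered, _ = apply_filters(cohort)
        pairs = build_pairs(filtered)
    else:
        pairs = cohort
    manifest = patient_folds(pairs, k=k, seed=seed, holdout_fraction=holdout_fraction)

    train_manifest = SplitManifest(
        manifest.df.loc[manifest.df["role"] == "train"].reset_index(drop=True)
    )
    fold_results, cv_report = run_cv(
        pairs, config, init_ruleset, manifest=train_manifest, seed=seed,
        rule_thresholds=rule_thresholds,
    )

    ensembled = ensemble_rules([fr.ruleset for fr in fold_results],
                               max_rules=config.n_rules)
    if len(ensembled) == 0 and init_ruleset is not None:
        logger.warning("no rules survived CV extraction; re-using the prior rules")
        ensembled = init_ruleset

    train_ids = manifest.patients("train")
    test_ids = manifest.patients("test")
    final_seed = _fold_seed(seed, 7919)
    X, y, stats, schema, fit_mask = _prepare_split(pairs, train_ids, test_ids, final_seed)
    cfg = TrainConfig(**{**vars(config), "seed": final_seed})
    init = init_from_rules(ensembled, schema, max(cfg.n_rules, len(ensembled)),
                           seed=final_seed, data=X[fit_mask])
    init.standardization = stats
    params, train_log = fit(X[fit_mask], y[fit_mask], schema, cfg, init=init)
    params.standardization = stats

    scores = forward(X[~fit_mask], schema, params)[:, 1]
    holdout = compute_metrics(y[~fit_mask], scores)
    final_rules = extract_rules(params, X[fit_mask], **(rule_thresholds or {}))
    result = ProtocolResult(params, final_rules, ensembled, cv_report, holdout,
                            manifest, schema)

    if out_dir is not None:
        from .interpret import explain_sample
        from .rules import render_rules

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(params, out / "model.json")
        final_rules.to_json(out / "rules.json")
        report_text, heatmap = render_rules(final_rules, stats)
        (out / "rules.txt").write_text(report_text)
        heatmap.to_csv(out / "rule_heatmap.csv")
        critical_values(params, stats).to_csv(out / "ranges.csv")
        X_hold = X[~fit_mask]
        if len(X_hold):  # bedside-style explanation of one holdout sample
            expl = explain_sample(X_hold[0], schema, params, final_rules, top_n=5)
            expl.to_json(out / "explanation.json")
            (out / "explanation.txt").write_text(expl.to_text())
        rep = EvalReport(cv_report.rows + [{"split": "holdout", **holdout}])
        rep.to_csv(out / "evaluation.csv")
        manifest.to_csv(out / "split.csv")
        cfg.to_yaml(out / "config.yaml")
        train_log.to_csv(out / "training_log.csv")
        (out / "manifest.json").write_text(json.dumps({
            "artifacts": ["model.json", "rules.json", "rules.txt",
                          "rule_heatmap.csv", "ranges.csv", "evaluation.csv",
                          "split.csv", "config.yaml", "training_log.csv",
                          "explanation.json", "explanation.txt"],
            "seed": seed,
            "holdout_auc": holdout["auc"],
        }, indent=1))
    return result


def cv_auc_scorer(pairs: CohortTable, schema, config: TrainConfig, k: int = 3,
                  seed: int = 0, init_ruleset: RuleSet | None = None) -> float:
    """Mean validation AUC over a patient-wise CV — the random-search score.

    ``schema`` may be None; the model schema is rebuilt per fold from the
    fold-train preprocessing anyway.
    """
    _, report = run_cv(pairs, config, init_ruleset, k=k, seed=seed)
    return float(np.nanmean([r["auc"] for r in report.rows]))
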