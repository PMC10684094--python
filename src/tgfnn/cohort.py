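"""Longitudinal EHR-style cohort handling.

A cohort is a per-encounter table keyed by ``patient_id`` and an
``encounter`` index.  Consecutive hospitalization pairs form the
prediction samples: features come from the first encounter of a pair and
the binary label (advanced-therapy referral) from the second.  The
module covers pairing and labeling, derived features (mean arterial
pressure, pulse pressure, percent change of BNP and creatinine),
missingness filters, carry-forward plus chained-equation imputation,
train-only standardization, patient-wise fold splitting, and a synthetic
cohort generator with planted conjunctive fuzzy rules for recovery
experiments.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import Feature, FeatureSchema, StandardizationStats
from .rules import Rule, RuleSet, RuleTerm

logger = logging.getLogger("tgfnn")

__all__ = [
    "CohortTable",
    "SplitManifest",
    "SimSpec",
    "build_pairs",
    "derive_features",
    "impute",
    "apply_filters",
    "standardize_and_encode",
    "patient_folds",
    "simulate_cohort",
    "build_model_schema",
]

ID_COL = "patient_id"
ENC_COL = "encounter"
LABEL_COL = "label"
META_COLS = (ID_COL, ENC_COL, LABEL_COL, "advanced_therapy", "too_well")

COHORT_SCHEMA_COMMENT = "# tgfnn-cohort v1"


@dataclass
class CohortTable:
    """Encounter- or pair-level rows plus feature bookkeeping.

    ``df`` holds one row per encounter (or per hospitalization pair);
    missing values are NaN.  ``continuous`` / ``binary`` list the feature
    columns; everything else is metadata.
    """

    df: pd.DataFrame
    continuous: list[str]
    binary: list[str]
    level: str = "encounter"  # or "pairs"
    units: dict[str, str] = field(default_factory=dict)

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.continuous + self.binary if c in self.df.columns]

    @property
    def n_patients(self) -> int:
        return self.df[ID_COL].nunique()

    def copy(self) -> "CohortTable":
        return replace(self, df=self.df.copy())

    def missing_mask(self) -> pd.DataFrame:
        return self.df[self.feature_columns].isna()

    def to_csv(self, path):
        with open(path, "w") as fh:
            fh.write(
                f"{COHORT_SCHEMA_COMMENT} level={self.level} "
                f"continuous={','.join(self.continuous)} "
                f"binary={','.join(self.binary)}\n"
            )
            self.df.to_csv(fh, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith(COHORT_SCHEMA_COMMENT):
                raise ValueError(f"{path}: missing cohort schema comment line")
            meta = dict(
                part.split("=", 1)
                for part in header[len(COHORT_SCHEMA_COMMENT):].split()
            )
            df = pd.read_csv(fh)
        return cls(
            df,
            continuous=[c for c in meta.get("continuous", "").split(",") if c],
            binary=[c for c in meta.get("binary", "").split(",") if c],
            level=meta.get("level", "encounter"),
        )


@dataclass
class SplitManifest:
    """Patient-level fold/role assignment: one row per patient with
    ``role`` in {train, test} and, for training patients, a CV ``fold``."""

    df: pd.DataFrame  # columns: patient_id, role, fold (-1 for test patients)

    def __post_init__(self):
        if self.df[ID_COL].duplicated().any():
            raise ValueError("a patient may appear only once in a split manifest")

    def patients(self, role: str, fold: int | None = None) -> np.ndarray:
        m = self.df["role"] == role
        if fold is not None:
            m &= self.df["fold"] == fold
        return self.df.loc[m, ID_COL].to_numpy()

    @property
    def n_folds(self) -> int:
        return int(self.df.loc[self.df["role"] == "train", "fold"].max()) + 1

    def to_csv(self, path):
        with open(path, "w") as fh:
            fh.write("# tgfnn-split v1\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "SplitManifest":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                fh.seek(0)
            return cls(pd.read_csv(fh))


# -- pairing and labeling -------------------------------------------------

def build_pairs(encounters: CohortTable, negative_regime: str = "all") -> CohortTable:
    """One labeled sample per consecutive hospitalization pair.

    Features are taken from the first encounter of each pair; the label
    is the ``advanced_therapy`` flag of the second.  Patients with a
    single encounter contribute nothing (their count is logged).  With
    ``negative_regime="too_well_only"`` negative pairs are kept only for
    patients flagged ``too_well`` (survived without advanced therapies);
    the default keeps every remaining pair as negative.
    """
    if negative_regime not in ("all", "too_well_only"):
        raise ValueError(f"unknown negative_regime {negative_regime!r}")
    df = encounters.df.sort_values([ID_COL, ENC_COL], kind="stable")
    counts = df.groupby(ID_COL, sort=False).size()
    n_single = int((counts < 2).sum())
    if n_single:
        logger.info("build_pairs: dropped %d single-encounter patients", n_single)

    nxt = df.groupby(ID_COL, sort=False).shift(-1)
    has_next = nxt[ENC_COL].notna()
    pairs = df.loc[has_next].copy()
    pairs[LABEL_COL] = nxt.loc[has_next, "advanced_therapy"].astype(int).to_numpy()
    if negative_regime == "too_well_only" and "too_well" in pairs.columns:
        keep = (pairs[LABEL_COL] == 1) | (pairs["too_well"].astype(bool))
        pairs = pairs.loc[keep]
    pairs = pairs.reset_index(drop=True)
    pairs.attrs["n_single_patients_dropped"] = n_single
    out = replace(encounters, df=pairs, level="pairs")
    return out


# -- derived features -----------------------------------------------------

def derive_features(table: CohortTable | pd.DataFrame) -> CohortTable | pd.DataFrame:
    """Mean arterial pressure, pulse pressure and BNP/creatinine percent
    change over the hospitalization.

    MAP uses the standard clinical estimate ``DBP + (SBP - DBP) / 3``;
    percent change is ``100 * (last - first) / first`` with a zero first
    measurement masked as missing rather than mapped to infinity.
    """
    df = table.df if isinstance(table, CohortTable) else table
    df = df.copy()
    if {"sbp", "dbp"} <= set(df.columns):
        df["map"] = df["dbp"] + (df["sbp"] - df["dbp"]) / 3.0
        df["pulse_pressure"] = df["sbp"] - df["dbp"]
    for name in ("bnp", "creatinine"):
        first, last = f"{name}_first", f"{name}_last"
        if {first, last} <= set(df.columns):
            denom = df[first].where(df[first] != 0.0, np.nan)
            df[f"{name}_delta_pct"] = 100.0 * (df[last] - df[first]) / denom
    if isinstance(table, CohortTable):
        extra = [c for c in ("map", "pulse_pressure", "bnp_delta_pct",
                             "creatinine_delta_pct")
                 if c in df.columns and c not in table.continuous]
        return replace(table, df=df, continuous=table.continuous + extra)
    return df


# -- imputation -----------------------------------------------------------

def impute(cohort: CohortTable, seed: int, fit_mask=None):
    """Two-step missing-value completion.

    Step 1: within each patient (ordered by encounter), carry the most
    recent earlier observation forward.  Step 2: remaining gaps are
    filled by a seeded chained-equations imputation (a single stochastic
    completion) fit on ``fit_mask`` rows only — pass the training-row
    mask to keep evaluation rows out of the imputation model.  Returns
    ``(completed cohort, log)`` where the log records the fill source of
    every imputed cell.  Fully observed cohorts come back unchanged.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    df = cohort.df.copy()
    cols = cohort.feature_columns
    missing_before = df[cols].isna()

    df = df.sort_values([ID_COL, ENC_COL], kind="stable")
    df[cols] = df.groupby(ID_COL, sort=False)[cols].ffill()
    after_cf = df[cols].isna()
    df = df.sort_index()

    if df[cols].isna().any().any():
        mask = np.ones(len(df), dtype=bool) if fit_mask is None else np.asarray(fit_mask)
        imp = IterativeImputer(
            random_state=np.random.default_rng(seed).integers(2**31 - 1),
            sample_posterior=True,
            max_iter=10,
            keep_empty_features=True,
        )
        imp.fit(df.loc[mask, cols].to_numpy())
        filled = imp.transform(df[cols].to_numpy())
        df[cols] = filled
        for b in cohort.binary:
            if b in cols:
                df[b] = df[b].round().clip(0, 1)

    log_rows = []
    after_cf = after_cf.sort_index()
    for col in cols:
        cf_filled = missing_before[col] & ~after_cf[col]
        it_filled = after_cf[col]
        for idx in df.index[cf_filled]:
            log_rows.append((df.at[idx, ID_COL], df.at[idx, ENC_COL], col, "carry_forward"))
        for idx in df.index[it_filled]:
            log_rows.append((df.at[idx, ID_COL], df.at[idx, ENC_COL], col, "iterative"))
    log = pd.DataFrame(log_rows, columns=[ID_COL, ENC_COL, "feature", "method"])
    return replace(cohort, df=df), log


# -- filters --------------------------------------------------------------

def apply_filters(cohort: CohortTable, feature_missing_max: float = 0.6,
                  patient_missing_max: int = 10,
                  exempt: tuple[str, ...] = ("lvef", "lvidd", "mitral_regurg"),
                  cohort_criteria: bool = True):
    """Missingness and eligibility filters with an exclusion log.

    Features missing in more than ``feature_missing_max`` of rows are
    removed (echocardiographic features are exempt — too important for
    heart-failure decisions to drop); then patients with more than
    ``patient_missing_max`` missing cells are excluded.  When the
    corresponding columns exist and ``cohort_criteria`` is set, rows
    violating age 18-80, LVEF <= 35 or BMI <= 50 are excluded (observed
    values only).  Applying the function to its own output is a no-op.
    """
    df = cohort.df
    log = {"features_removed": [], "patients_removed": [], "rows_removed_criteria": 0}

    feat_cols = cohort.feature_columns
    rates = df[feat_cols].isna().mean()
    drop_feats = [c for c in feat_cols
                  if rates[c] > feature_missing_max and c not in exempt]
    log["features_removed"] = drop_feats
    df = df.drop(columns=drop_feats)
    continuous = [c for c in cohort.continuous if c not in drop_feats]
    binary = [c for c in cohort.binary if c not in drop_feats]
    feat_cols = [c for c in continuous + binary if c in df.columns]

    per_patient_missing = df[feat_cols].isna().groupby(df[ID_COL]).sum().sum(axis=1)
    bad_patients = per_patient_missing.index[per_patient_missing > patient_missing_max]
    log["patients_removed"] = list(bad_patients)
    df = df.loc[~df[ID_COL].isin(bad_patients)]

    if cohort_criteria:
        keep = pd.Series(True, index=df.index)
        if "age" in df.columns:
            keep &= df["age"].isna() | df["age"].between(18, 80)
        if "lvef" in df.columns:
            keep &= df["lvef"].isna() | (df["lvef"] <= 35)
        if "bmi" in df.columns:
            keep &= df["bmi"].isna() | (df["bmi"] <= 50)
        log["rows_removed_criteria"] = int((~keep).sum())
        df = df.loc[keep]

    if df.empty:
        raise ValueError("cohort is empty after filtering")
    out = replace(cohort, df=df.reset_index(drop=True),
                  continuous=continuous, binary=binary)
    return out, log


# -- standardization and model matrix ------------------------------------

#: raw ingredients of derived features; never model inputs themselves
RAW_INGREDIENT_COLS = ("dbp", "bnp_first", "bnp_last",
                       "creatinine_first", "creatinine_last")


def build_model_schema(cohort: CohortTable,
                       exclude: tuple[str, ...] = RAW_INGREDIENT_COLS) -> FeatureSchema:
    """Model feature schema: continuous features plus binary comorbidities
    as 2-level categoricals (absent/present).

    Raw ingredients of derived features (DBP, first/last BNP and
    creatinine) are excluded by default: the model sees SBP, MAP, pulse
    pressure and the percent changes instead.
    """
    feats = [Feature(c, "continuous") for c in cohort.continuous
             if c in cohort.df.columns and c not in exclude]
    feats += [
        Feature(c, "categorical", n_levels=2, levels=("absent", "present"))
        for c in cohort.binary
        if c in cohort.df.columns and c not in exclude
    ]
    return FeatureSchema(feats)


def standardize_and_encode(cohort: CohortTable, schema: FeatureSchema, fit_mask):
    """Model-ready matrix: z-scored continuous columns (statistics from
    ``fit_mask`` rows only) and integer level codes for categoricals.

    Returns ``(X, y, stats)``; ``y`` is None for unlabeled tables.
    Zero-variance continuous columns are left centered with a warning.
    """
    df = cohort.df
    fit_mask = np.asarray(fit_mask, dtype=bool)
    if fit_mask.shape[0] != len(df):
        raise ValueError("fit_mask length must equal the number of rows")
    cont = [f.name for f in schema if f.kind == "continuous"]
    cat = [f.name for f in schema if f.kind == "categorical"]
    mean = df.loc[fit_mask, cont].mean().to_numpy()
    sd = df.loc[fit_mask, cont].std(ddof=0).to_numpy()
    zero_var = sd <= 1e-12
    if zero_var.any():
        warnings.warn(
            "zero-variance continuous columns left centered: "
            + ", ".join(np.array(cont)[zero_var])
        )
        sd = np.where(zero_var, 1.0, sd)
    stats = StandardizationStats(cont, mean, sd,
                                 units={k: v for k, v in cohort.units.items() if k in cont})

    X = np.empty((len(df), schema.n_features))
    for j, f in enumerate(schema):
        if f.kind == "continuous":
            i = cont.index(f.name)
            X[:, j] = (df[f.name].to_numpy(dtype=float) - mean[i]) / sd[i]
        else:
            X[:, j] = df[f.name].to_numpy(dtype=float)
    y = df[LABEL_COL].to_numpy(dtype=int) if LABEL_COL in df.columns else None
    return X, y, stats


# -- patient-wise splitting ----------------------------------------------

def patient_folds(cohort: CohortTable, k: int = 5, seed: int = 0,
                  holdout_fraction: float = 0.2) -> SplitManifest:
    """Patient-level holdout split plus stratified k folds on the rest.

    A patient is "positive" if any of their pairs is labeled positive;
    stratification keeps fold positive-rates close to the overall rate.
    Every pair of a patient follows the patient, so no patient spans
    folds or roles.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    df = cohort.df
    pat = df.groupby(ID_COL)[LABEL_COL].max()  # patient-level label
    rng = np.random.default_rng(seed)

    rows = []
    train_ids, train_lbl = [], []
    for lbl, ids in pat.groupby(pat):
        ids = ids.index.to_numpy()
        rng.shuffle(ids)
        n_hold = int(round(holdout_fraction * len(ids)))
        for pid in ids[:n_hold]:
            rows.append((pid, "test", -1))
        train_ids.extend(ids[n_hold:])
        train_lbl.extend([lbl] * (len(ids) - n_hold))
    if len(train_ids) < k:
        raise ValueError(f"only {len(train_ids)} training patients for k={k} folds")

    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    train_ids = np.asarray(train_ids)
    train_lbl = np.asarray(train_lbl)
    for fold, (_, val_idx) in enumerate(skf.split(train_ids, train_lbl)):
        for pid in train_ids[val_idx]:
            rows.append((pid, "train", fold))
    manifest = pd.DataFrame(rows, columns=[ID_COL, "role", "fold"])
    return SplitManifest(manifest.sort_values(ID_COL, kind="stable").reset_index(drop=True))


# -- synthetic cohort -----------------------------------------------------

@dataclass
class SimSpec:
    """Generator settings for the synthetic heart-failure-like cohort.

    Defaults emulate the scale and mix of an advanced-heart-failure
    referral cohort: ~300 patients contributing ~557 consecutive
    hospitalization pairs with ~35% positive labels, continuous vitals /
    labs / echo measures plus binary comorbidities, within-patient
    correlation through a latent severity, missingness concentrated in
    echo measures, and labels generated by an OR of planted conjunctive
    rules on first-encounter features with a 10% label-flip noise.
    """

    n_patients: int = 300
    #: encounters per patient: counts 2..6 with probabilities matching a
    #: cohort where about half the patients have exactly two encounters
    encounter_probs: tuple = ((2, 0.523), (3, 0.220), (4, 0.150), (5, 0.070), (6, 0.037))
    label_noise: float = 0.10
    #: crisp concept thresholds (low, high) per continuous feature,
    #: clinical units; also the semantics of planted rule terms
    concept_thresholds: dict = field(default_factory=lambda: {
        "sbp": (104.0, 130.0),
        "lvef": (20.0, 30.0),
        "sodium": (135.5, 142.0),
        "map": (70.0, 95.0),
        "hgb": (10.0, 14.0),
        "bmi": (21.0, 35.0),
        "bnp_delta_pct": (-40.0, 40.0),
        "creatinine_delta_pct": (-20.0, 20.0),
        "mitral_regurg": (1.0, 3.0),
    })
    #: planted ground-truth rules as (feature, concept) conjunctions
    planted_rules: tuple = (
        (("sbp", "low"), ("lvef", "low")),
        (("lvef", "low"), ("sodium", "low")),
    )
    #: per-feature missing rates; echo measures dominate
    missing_rates: dict = field(default_factory=lambda: {
        "lvidd": 0.40, "mitral_regurg": 0.40, "lvef": 0.15,
        "bnp_first": 0.10, "bnp_last": 0.10,
        "creatinine_first": 0.07, "creatinine_last": 0.07,
        "sodium": 0.07, "potassium": 0.07, "hgb": 0.05,
        "sbp": 0.02, "dbp": 0.02, "bmi": 0.05,
    })
    negative_regime: str = "all"  # or "too_well_only"

    def __post_init__(self):
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label noise must lie in [0, 0.5)")
        if abs(sum(p for _, p in self.encounter_probs) - 1.0) > 1e-6:
            raise ValueError("encounter probabilities must sum to 1")
        if self.n_patients < 2:
            raise ValueError("need at least two patients")
        for f, (lo, hi) in self.concept_thresholds.items():
            if lo >= hi:
                raise ValueError(f"{f}: low threshold must be below high threshold")


CONTINUOUS_FEATURES = [
    "sbp", "dbp", "sodium", "potassium", "lvef", "lvidd", "mitral_regurg",
    "hgb", "bmi", "age",
]
BINARY_FEATURES = ["male", "renal_failure", "liver_disease", "copd", "diabetes"]

UNITS = {
    "sbp": "mmHg", "dbp": "mmHg", "map": "mmHg", "pulse_pressure": "mmHg",
    "sodium": "mmol/L", "potassium": "mmol/L", "lvef": "%", "lvidd": "mm",
    "mitral_regurg": "grade", "hgb": "g/dL", "bmi": "kg/m2", "age": "years",
    "bnp_delta_pct": "%", "creatinine_delta_pct": "%",
}


def _rule_truth(df: pd.DataFrame, spec: SimSpec) -> np.ndarray:
    """OR over planted rules evaluated crisply on (complete) features."""
    total = np.zeros(len(df), dtype=bool)
    for conj in spec.planted_rules:
        sat = np.ones(len(df), dtype=bool)
        for feat, concept in conj:
            lo, hi = spec.concept_thresholds[feat]
            x = df[feat].to_numpy(dtype=float)
            if concept == "low":
                sat &= x < lo
            elif concept == "high":
                sat &= x > hi
            else:
                sat &= (x >= lo) & (x <= hi)
        total |= sat
    return total


def simulate_cohort(spec: SimSpec | None = None, seed: int = 0):
    """Synthetic encounter-level cohort plus its generating rule set.

    Each patient carries a latent severity that shifts blood pressure,
    ejection fraction, sodium, hemoglobin and BNP jointly (sicker
    patients look sick across the board, as in real cohorts) and drifts
    mildly across encounters.  Labels: for each consecutive encounter
    pair, the planted rules are evaluated crisply on the first
    encounter's true (pre-missingness) features, OR-ed, flipped with the
    label-noise rate, and stored as the second encounter's
    ``advanced_therapy`` flag.  Missing values are then punched in
    completely at random per feature.  Deterministic per seed.
    """
    spec = spec or SimSpec()
    rng = np.random.default_rng(seed)
    counts = np.array([c for c, _ in spec.encounter_probs])
    probs = np.array([p for _, p in spec.encounter_probs])
    n_enc = rng.choice(counts, size=spec.n_patients, p=probs)

    rows = []
    for p in range(spec.n_patients):
        sev = rng.normal()  # latent severity, shared across encounters
        age = float(np.clip(rng.normal(56, 14), 18, 80))
        male = int(rng.random() < 0.74)
        renal = int(rng.random() < 0.646)
        liver = int(rng.random() < 0.314)
        copd = int(rng.random() < 0.792)
        diab = int(rng.random() < 0.40)
        bmi = float(np.clip(rng.normal(29, 5.5), 16, 50))
        for t in range(n_enc[p]):
            s = sev + 0.15 * t + rng.normal(0, 0.35)  # mild progression
            sbp = 115 - 12 * s + rng.normal(0, 17)
            dbp = np.clip(70 - 6 * s + rng.normal(0, 10), 30, None)
            dbp = min(dbp, sbp - 10)
            sodium = 138 - 2.2 * s + rng.normal(0, 3.3)
            potassium = 4.24 + rng.normal(0, 0.54)
            lvef = float(np.clip(20 - 5 * s + rng.normal(0, 6.5), 5, 35))
            lvidd = 67 + 5 * s + rng.normal(0, 10)
            mitral = float(np.clip(2.0 + 0.6 * s + rng.normal(0, 0.8), 0, 4))
            hgb = 11.5 - 0.8 * s + rng.normal(0, 1.8)
            bnp_first = float(np.exp(6.3 + 0.5 * s + rng.normal(0, 0.7)))
            bnp_delta = max(rng.normal(15.7, 91.5), -95.0)
            creat_first = float(np.clip(1.4 + 0.25 * s + rng.normal(0, 0.35), 0.4, None))
            creat_delta = rng.normal(1.2, 18.75)
            rows.append(
                dict(patient_id=f"P{p:04d}", encounter=t, sbp=sbp, dbp=dbp,
                     sodium=sodium, potassium=potassium, lvef=lvef, lvidd=lvidd,
                     mitral_regurg=mitral, hgb=hgb, bmi=bmi, age=age,
                     bnp_first=bnp_first,
                     bnp_last=bnp_first * (1 + bnp_delta / 100.0),
                     creatinine_first=creat_first,
                     creatinine_last=creat_first * (1 + creat_delta / 100.0),
                     male=male, renal_failure=renal, liver_disease=liver,
                     copd=copd, diabetes=diab)
            )
    df = pd.DataFrame(rows)

    # labels on the complete (pre-missingness) features
    complete = derive_features(df)
    truth = _rule_truth(complete, spec)
    df["advanced_therapy"] = 0
    df["too_well"] = 0
    flip = rng.random(len(df)) < spec.label_noise
    for pid, grp in df.groupby(ID_COL, sort=False):
        idx = grp.sort_values(ENC_COL).index.to_numpy()
        for a, b in zip(idx[:-1], idx[1:]):
            lbl = bool(truth[a]) ^ bool(flip[a])
            df.at[b, "advanced_therapy"] = int(lbl)
    # survivors without any advanced-therapy encounter are "too well"
    got_at = df.groupby(ID_COL)["advanced_therapy"].transform("max")
    df["too_well"] = ((got_at == 0) & (rng.random(len(df)) > 0.1)).astype(int)

    # punch in missingness (never in the label/meta columns)
    for col, rate in spec.missing_rates.items():
        if col in df.columns and rate > 0:
            df.loc[rng.random(len(df)) < rate, col] = np.nan

    cohort = CohortTable(
        df,
        continuous=[c for c in CONTINUOUS_FEATURES if c in df.columns]
        + ["bnp_first", "bnp_last", "creatinine_first", "creatinine_last"],
        binary=BINARY_FEATURES,
        level="encounter",
        units=dict(UNITS),
    )
    truth_rules = RuleSet(
        [
            Rule([RuleTerm(f, c) for f, c in conj], class_weights=[0.0, 1.0])
            for conj in spec.planted_rules
        ]
    )
    return cohort, truth_rules
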