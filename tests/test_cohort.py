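"""Pairing, derived features, imputation, filters, splits and the simulator."""

import numpy as np
import pandas as pd
import pytest

from tgfnn.cohort import (
    CohortTable,
    SimSpec,
    apply_filters,
    build_model_schema,
    build_pairs,
    derive_features,
    impute,
    patient_folds,
    simulate_cohort,
    standardize_and_encode,
)


def toy_encounters(counts, seed=0):
    """Roster with the given encounters-per-patient counts."""
    rng = np.random.default_rng(seed)
    rows = []
    for p, c in enumerate(counts):
        for t in range(c):
            rows.append(
                {"patient_id": f"P{p}", "encounter": t,
                 "sbp": rng.normal(115, 20), "lvef": rng.uniform(5, 35),
                 "diabetes": int(rng.random() < 0.4),
                 "advanced_therapy": int(rng.random() < 0.3), "too_well": 0}
            )
    df = pd.DataFrame(rows)
    return CohortTable(df, continuous=["sbp", "lvef"], binary=["diabetes"])


class TestBuildPairs:
    def test_three_encounters_give_two_pairs(self):
        cohort = toy_encounters([3])
        pairs = build_pairs(cohort)
        assert len(pairs.df) == 2
        # features from the first encounter of each pair
        assert pairs.df["encounter"].tolist() == [0, 1]

    def test_single_encounter_patient_contributes_nothing(self):
        pairs = build_pairs(toy_encounters([1, 2]))
        assert len(pairs.df) == 1
        assert pairs.df.attrs["n_single_patients_dropped"] == 1

    def test_pair_count_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 6, size=10)
        pairs = build_pairs(toy_encounters(list(counts)))
        assert len(pairs.df) == sum(max(0, c - 1) for c in counts)

    def test_label_comes_from_second_encounter(self):
        cohort = toy_encounters([2])
        cohort.df.loc[0, "advanced_therapy"] = 0
        cohort.df.loc[1, "advanced_therapy"] = 1
        pairs = build_pairs(cohort)
        assert pairs.df["label"].tolist() == [1]

    def test_too_well_only_regime(self):
        cohort = toy_encounters([2, 2])
        cohort.df["advanced_therapy"] = 0
        cohort.df["too_well"] = [1, 1, 0, 0]
        pairs = build_pairs(cohort, negative_regime="too_well_only")
        assert pairs.df["patient_id"].tolist() == ["P0"]


class TestDeriveFeatures:
    def test_map_and_pulse_pressure_closed_form(self):
        df = pd.DataFrame({"sbp": [120.0], "dbp": [60.0]})
        out = derive_features(df)
        assert out["map"].iloc[0] == pytest.approx(80.0)
        assert out["pulse_pressure"].iloc[0] == pytest.approx(60.0)

    def test_percent_change(self):
        df = pd.DataFrame(
            {"creatinine_first": [1.0], "creatinine_last": [1.2],
             "bnp_first": [0.0], "bnp_last": [100.0]}
        )
        out = derive_features(df)
        assert out["creatinine_delta_pct"].iloc[0] == pytest.approx(20.0)
        assert np.isnan(out["bnp_delta_pct"].iloc[0])  # zero denominator masked

    def test_random_table_matches_rowwise_recomputation(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"sbp": rng.uniform(80, 180, 50), "dbp": rng.uniform(40, 100, 50),
             "bnp_first": rng.uniform(10, 5000, 50),
             "bnp_last": rng.uniform(10, 5000, 50)}
        )
        out = derive_features(df)
        for i in range(50):
            s, d = df["sbp"][i], df["dbp"][i]
            assert out["map"][i] == pytest.approx(d + (s - d) / 3)
            f, l = df["bnp_first"][i], df["bnp_last"][i]
            assert out["bnp_delta_pct"][i] == pytest.approx(100 * (l - f) / f)


class TestImpute:
    def test_carry_forward_between_encounters(self):
        cohort = toy_encounters([3])
        cohort.df.loc[1, "sbp"] = np.nan
        completed, log = impute(cohort, seed=0)
        assert completed.df.loc[1, "sbp"] == cohort.df.loc[0, "sbp"]
        assert ("carry_forward" in log["method"].values)

    def test_fully_observed_idempotent(self):
        cohort = toy_encounters([2, 3])
        completed, log = impute(cohort, seed=0)
        pd.testing.assert_frame_equal(completed.df, cohort.df)
        assert log.empty

    def test_beats_column_mean_and_is_deterministic(self):
        """Iterative imputation RMSE < column-mean RMSE on correlated data."""
        rng = np.random.default_rng(4)
        n = 300
        sev = rng.normal(size=n)
        df = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)], "encounter": 0,
             "a": 2 * sev + rng.normal(0, 0.5, n),
             "b": -1.5 * sev + rng.normal(0, 0.5, n),
             "c": sev + rng.normal(0, 0.5, n)}
        )
        cohort = CohortTable(df, continuous=["a", "b", "c"], binary=[])
        holes = rng.random(n) < 0.1
        truth = df.loc[holes, "a"].copy()
        damaged = cohort.copy()
        damaged.df.loc[holes, "a"] = np.nan

        done1, _ = impute(damaged, seed=9)
        done2, _ = impute(damaged, seed=9)
        pd.testing.assert_frame_equal(done1.df, done2.df)

        rmse_iter = np.sqrt(np.mean((done1.df.loc[holes, "a"] - truth) ** 2))
        col_mean = damaged.df["a"].mean()
        rmse_mean = np.sqrt(np.mean((col_mean - truth) ** 2))
        assert rmse_iter < rmse_mean

    def test_no_missing_values_remain(self):
        enc, _ = simulate_cohort(seed=3)
        pairs = build_pairs(enc)
        completed, _ = impute(pairs, seed=3)
        assert not completed.df[completed.feature_columns].isna().any().any()


class TestApplyFilters:
    def _cohort_with_missingness(self):
        rng = np.random.default_rng(0)
        n = 40
        mostly = np.ones(n)
        mostly[:28] = np.nan  # exactly 70% missing
        lvef = np.full(n, 25.0)
        lvef[:26] = np.nan  # 65% missing but exempt
        df = pd.DataFrame(
            {"patient_id": [f"P{i // 2}" for i in range(n)],
             "encounter": [i % 2 for i in range(n)],
             "mostly_missing": mostly, "lvef": lvef,
             "ok": rng.normal(size=n),
             "advanced_therapy": 0, "too_well": 1}
        )
        return CohortTable(df, continuous=["mostly_missing", "lvef", "ok"], binary=[])

    def test_feature_threshold_with_echo_exemption(self):
        cohort = self._cohort_with_missingness()
        out, log = apply_filters(cohort, cohort_criteria=False)
        assert "mostly_missing" in log["features_removed"]
        assert "lvef" in out.df.columns  # exempt despite high missingness

    def test_patient_missing_threshold(self):
        cohort = toy_encounters([2, 2])
        # P0 accumulates 11 missing cells; P1 is fully observed
        extra = {f"x{i}": [np.nan, 1.0, 1.0, 1.0] for i in range(11)}
        cohort.df = cohort.df.assign(**extra)
        cohort.continuous += list(extra)
        out, log = apply_filters(cohort, cohort_criteria=False)
        assert log["patients_removed"] == ["P0"]
        assert set(out.df["patient_id"]) == {"P1"}

    def test_bruteforce_counts_and_rerun_noop(self):
        cohort = self._cohort_with_missingness()
        out, _ = apply_filters(cohort, cohort_criteria=False)
        # brute-force recomputation of both thresholds
        df = cohort.df
        keep_feats = [c for c in cohort.continuous
                      if df[c].isna().mean() <= 0.6 or c in ("lvef", "lvidd", "mitral_regurg")]
        miss = df[keep_feats].isna().groupby(df["patient_id"]).sum().sum(axis=1)
        keep_pat = set(miss.index[miss <= 10])
        assert set(out.df["patient_id"]) == keep_pat
        assert set(out.feature_columns) == set(keep_feats)

        again, log2 = apply_filters(out, cohort_criteria=False)
        pd.testing.assert_frame_equal(again.df, out.df)
        assert not log2["features_removed"] and not log2["patients_removed"]

    def test_eligibility_rows(self):
        cohort = toy_encounters([2, 2])
        cohort.df["age"] = [50.0, 50.0, 85.0, 85.0]
        out, log = apply_filters(cohort)
        assert set(out.df["patient_id"]) == {"P0"}
        assert log["rows_removed_criteria"] == 2

    def test_empty_after_filtering_raises(self):
        cohort = toy_encounters([2])
        cohort.df["age"] = 99.0
        with pytest.raises(ValueError, match="empty"):
            apply_filters(cohort)


class TestStandardizeAndEncode:
    def test_moments_and_leakage_guard(self):
        enc, _ = simulate_cohort(seed=5)
        pairs = build_pairs(enc)
        completed, _ = impute(pairs, seed=5)
        derived = derive_features(completed)
        schema = build_model_schema(derived)
        n = len(derived.df)
        fit_mask = np.zeros(n, dtype=bool)
        fit_mask[: n // 2] = True

        # plant a sentinel in non-fit rows: statistics must not move
        X1, y1, stats1 = standardize_and_encode(derived, schema, fit_mask)
        poisoned = derived.copy()
        poisoned.df.loc[~fit_mask, "sbp"] = 10_000.0
        X2, y2, stats2 = standardize_and_encode(poisoned, schema, fit_mask)
        assert np.array_equal(stats1.mean, stats2.mean)
        assert np.array_equal(stats1.sd, stats2.sd)

        j = schema.index("sbp")
        col = X1[fit_mask, j]
        assert col.mean() == pytest.approx(0.0, abs=1e-9)
        assert col.std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_column_centered_and_flagged(self):
        df = pd.DataFrame(
            {"patient_id": ["P0", "P1"], "encounter": [0, 0],
             "flat": [5.0, 5.0], "label": [0, 1]}
        )
        cohort = CohortTable(df, continuous=["flat"], binary=[])
        schema = build_model_schema(cohort)
        with pytest.warns(UserWarning, match="zero-variance"):
            X, y, stats = standardize_and_encode(cohort, schema, np.array([True, True]))
        assert np.allclose(X[:, 0], 0.0)

    def test_binary_level_codes(self):
        cohort = toy_encounters([2])
        schema = build_model_schema(cohort)
        X, _, _ = standardize_and_encode(cohort, schema,
                                         np.ones(len(cohort.df), dtype=bool))
        j = schema.index("diabetes")
        assert set(np.unique(X[:, j])) <= {0.0, 1.0}


class TestPatientFolds:
    def test_fold_sizes_and_exclusivity(self):
        enc, _ = simulate_cohort(SimSpec(n_patients=10), seed=0)
        pairs = build_pairs(enc)
        manifest = patient_folds(pairs, k=5, seed=0, holdout_fraction=0.0)
        folds = manifest.df.groupby("fold")["patient_id"].apply(set)
        all_ids = set()
        for s in folds:
            assert not (all_ids & s)
            all_ids |= s
        assert len(all_ids) == pairs.df["patient_id"].nunique()
        assert sorted(len(s) for s in folds) == [2, 2, 2, 2, 2]

    def test_stratification_on_default_cohort(self):
        enc, _ = simulate_cohort(seed=2)
        pairs = build_pairs(enc)
        manifest = patient_folds(pairs, k=5, seed=2, holdout_fraction=0.2)
        overall = pairs.df.groupby("patient_id")["label"].max().mean()
        pat_label = pairs.df.groupby("patient_id")["label"].max()
        for f in range(5):
            ids = manifest.patients("train", fold=f)
            rate = pat_label.loc[ids].mean()
            assert abs(rate - overall) < 0.10

    def test_roles_are_disjoint(self):
        enc, _ = simulate_cohort(seed=1)
        pairs = build_pairs(enc)
        manifest = patient_folds(pairs, k=5, seed=1)
        train = set(manifest.patients("train"))
        test = set(manifest.patients("test"))
        assert not (train & test)
        assert len(test) > 0

    def test_too_few_patients(self):
        enc, _ = simulate_cohort(SimSpec(n_patients=3), seed=0)
        pairs = build_pairs(enc)
        with pytest.raises(ValueError):
            patient_folds(pairs, k=5, seed=0, holdout_fraction=0.0)


class TestSimulateCohort:
    def test_deterministic_byte_identical_csv(self, tmp_path):
        enc1, _ = simulate_cohort(seed=13)
        enc2, _ = simulate_cohort(seed=13)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        enc1.to_csv(p1)
        enc2.to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_csv_roundtrip(self, tmp_path):
        enc, _ = simulate_cohort(SimSpec(n_patients=20), seed=0)
        path = tmp_path / "cohort.csv"
        enc.to_csv(path)
        loaded = CohortTable.from_csv(path)
        assert loaded.continuous == enc.continuous
        assert loaded.binary == enc.binary
        pd.testing.assert_frame_equal(
            loaded.df, enc.df.reset_index(drop=True), check_dtype=False
        )

    def test_noise_free_labels_equal_rule_truth(self):
        spec = SimSpec(label_noise=0.0)
        enc, truth = simulate_cohort(spec, seed=7)
        pairs = build_pairs(enc)
        from tgfnn.cohort import _rule_truth

        complete = derive_features(pairs.df)  # features may have NaN...
        # re-evaluate on observed first-encounter values where complete
        mask = complete[["sbp", "lvef", "sodium"]].notna().all(axis=1)
        got = _rule_truth(complete.loc[mask], spec)
        assert np.array_equal(pairs.df.loc[mask, "label"].to_numpy().astype(bool), got)

    def test_prevalence_near_target_over_seeds(self):
        rates = [
            build_pairs(simulate_cohort(seed=s)[0]).df["label"].mean()
            for s in range(10)
        ]
        assert abs(np.mean(rates) - 0.35) < 0.05

    def test_scale_matches_design(self):
        enc, truth = simulate_cohort(seed=0)
        pairs = build_pairs(enc)
        assert 250 <= enc.n_patients <= 300
        assert 450 <= len(pairs.df) <= 650
        assert len(truth) == 2

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            SimSpec(label_noise=0.5)
        with pytest.raises(ValueError):
            SimSpec(n_patients=1)
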