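"""Frame sampling, pair filtering, augmentation, models, importances."""
import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeRegressor

from metakin.attribution import additive_attributions
from metakin.constants import beta
from metakin.exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    MissingTargetError,
    UnsupportedModelError,
    ValidationError,
)
from metakin.features import (
    MODEL_SET,
    StructureKineticsModel,
    augment_dataset,
    feature_columns,
    filter_pairs,
    permutation_importance,
    run_trials,
    sample_frames,
    select_top_features,
)


class TestSampleFrames:
    def test_all_frames_exited_is_an_error(self, tiny_energy_table):
        t = tiny_energy_table.copy()
        t["z"] = 20.0
        with pytest.raises(InsufficientDataError):
            sample_frames(t, n_frames=1)

    def test_exact_count_returns_all_eligible(self, tiny_energy_table):
        out = sample_frames(tiny_energy_table, n_frames=6, seed=0)
        for lid in ("A", "B"):
            frames = out[out.ligand_id == lid][
                ["trajectory_id", "frame_time"]
            ].drop_duplicates()
            assert len(frames) == 6

    def test_sampled_frames_subset_of_eligible(self, small_feature_dataset):
        tables, _, _ = small_feature_dataset
        out = sample_frames(tables, n_frames=100, seed=5)
        big = pd.concat(tables.values(), ignore_index=True)
        eligible = big[big.z <= 15.0]
        key = ["ligand_id", "trajectory_id", "frame_time"]
        sampled_keys = set(map(tuple, out[key].drop_duplicates().values))
        eligible_keys = set(map(tuple, eligible[key].drop_duplicates().values))
        assert sampled_keys <= eligible_keys
        for lid in tables:
            assert len({k for k in sampled_keys if k[0] == lid}) == 100

    def test_deterministic_under_seed(self, small_feature_dataset):
        tables, _, _ = small_feature_dataset
        a = sample_frames(tables, n_frames=50, seed=3)
        b = sample_frames(tables, n_frames=50, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestFilterPairs:
    def test_all_zero_pair_removed(self, tiny_energy_table):
        t = tiny_energy_table.copy()
        t.loc[t.residue_id == "H297", "energy"] = 0.0
        pairs, report = filter_pairs(t, magnitude_cutoff=1.0, spread_cutoff=0.01)
        assert "H297-R4" not in pairs
        assert not report.loc["H297-R4", "survives"]

    def test_zero_spread_pair_removed(self):
        # identical -5 kcal/mol for every ligand: strong but not discriminating
        rows = []
        for lid in ("A", "B", "C"):
            for j in range(4):
                rows.append(
                    dict(ligand_id=lid, trajectory_id="t0", frame_time=10.0 * j,
                         residue_id="D147", substituent="R1", energy=-5.0,
                         frame_bias=0.0, z=5.0)
                )
        pairs, report = filter_pairs(pd.DataFrame(rows), spread_cutoff=0.1)
        assert pairs == []
        assert report.loc["D147-R1", "max_abs_mean"] == pytest.approx(5.0)
        assert report.loc["D147-R1", "spread"] == pytest.approx(0.0)

    def test_matches_brute_force_rules(self, small_feature_dataset):
        tables, _, _ = small_feature_dataset
        sampled = sample_frames(tables, n_frames=150, seed=1)
        mag, spread = 1.0, 0.25
        pairs, report = filter_pairs(sampled, mag, spread)
        # brute-force oracle on the same reweighted means
        df = sampled.copy()
        df["pair"] = df["residue_id"] + "-" + df["substituent"]
        b = beta(300.0)
        expect = []
        for pair in sorted(df["pair"].unique()):
            means = []
            for lid in sorted(df["ligand_id"].unique()):
                sub = df[(df.pair == pair) & (df.ligand_id == lid)]
                w = np.exp(b * sub["frame_bias"].to_numpy())
                means.append(np.sum(w * sub["energy"].to_numpy()) / np.sum(w))
            means = np.asarray(means)
            if np.max(np.abs(means)) >= mag and np.std(means, ddof=1) >= spread:
                expect.append(pair)
        assert pairs == expect


class TestAugmentDataset:
    def test_degenerate_augmentation_is_plain_mean(self, tiny_energy_table):
        # with a single frame per ligand, every block-mean row IS that frame
        l10 = {"A": 1.0, "B": 2.0}
        one = tiny_energy_table[tiny_energy_table.frame_time == 10.0]
        feats = augment_dataset(one, l10, n_aug_per_ligand=1, block_size=1, seed=0)
        a_row = feats[feats.ligand_id == "A"]
        expect = one[(one.ligand_id == "A") & (one.residue_id == "D147")]["energy"]
        assert a_row["D147-R1"].iloc[0] == pytest.approx(float(expect.iloc[0]))
        assert a_row["log10_tau"].iloc[0] == 1.0

    def test_deterministic_under_seed(self, tiny_energy_table):
        l10 = {"A": 1.0, "B": 2.0}
        f1 = augment_dataset(tiny_energy_table, l10, n_aug_per_ligand=5,
                             block_size=3, seed=7)
        f2 = augment_dataset(tiny_energy_table, l10, n_aug_per_ligand=5,
                             block_size=3, seed=7)
        pd.testing.assert_frame_equal(f1, f2)

    def test_variance_shrinks_with_block_size(self, small_feature_dataset):
        tables, l10, _ = small_feature_dataset
        lid = sorted(tables)[0]
        tab = tables[lid]
        sd = {}
        for bs in (10, 250):
            feats = augment_dataset(
                tab, {lid: float(l10[lid])}, n_aug_per_ligand=80,
                block_size=bs, seed=0,
            )
            col = feature_columns(feats)[0]
            sd[bs] = feats[col].std()
        assert sd[250] < sd[10]

    def test_missing_target_error(self, tiny_energy_table):
        with pytest.raises(MissingTargetError):
            augment_dataset(tiny_energy_table, {"A": 1.0}, n_aug_per_ligand=2,
                            block_size=2)

    def test_block_size_larger_than_frames_rejected(self, tiny_energy_table):
        with pytest.raises(InvalidParameterError):
            augment_dataset(tiny_energy_table, {"A": 1.0, "B": 2.0},
                            n_aug_per_ligand=2, block_size=100)


def _linear_feature_table(n_rows=1000, n_features=5, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_rows, n_features))
    y = -0.7 * X[:, 2] + noise * rng.normal(size=n_rows)
    df = pd.DataFrame(X, columns=[f"P{j}-R1" for j in range(n_features)])
    df.insert(0, "ligand_id", [f"L{i % 10}" for i in range(n_rows)])
    df["log10_tau"] = y
    return df


class TestStructureKineticsModel:
    def test_constant_target_reports_nan_r2_zero_rmse(self):
        df = _linear_feature_table(200)
        df["log10_tau"] = 1.5
        res = StructureKineticsModel(df).fit(
            model_set=["random_forest"], tune=False, seed=0
        )
        row = res.metrics_.loc["random_forest"]
        assert np.isnan(row["r2"])
        assert row["rmse"] == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_linear_target_learnable_by_all_models(self):
        df = _linear_feature_table(1000)
        res = StructureKineticsModel(df).fit(model_set=MODEL_SET, tune=False, seed=0)
        assert (res.metrics_["r2"] >= 0.99).all()

    def test_permuted_target_not_learnable(self):
        r2s = []
        for seed in range(20):
            df = _linear_feature_table(300, seed=seed)
            rng = np.random.default_rng(seed)
            df["log10_tau"] = rng.permutation(df["log10_tau"].to_numpy())
            res = StructureKineticsModel(df).fit(
                model_set=["extra_trees"], tune=False, seed=seed
            )
            r2s.append(res.metrics_.loc["extra_trees", "r2"])
        assert np.mean(r2s) < 0.2

    def test_single_ligand_rejected(self):
        df = _linear_feature_table(50)
        df["ligand_id"] = "L0"
        with pytest.raises(InsufficientDataError):
            StructureKineticsModel(df)

    def test_ligand_level_split_holds_out_whole_ligands(self):
        # 10 ligands x 30 rows: a 20% ligand-level split holds out 2 whole
        # ligands, i.e. exactly 60 rows
        df = _linear_feature_table(300)
        skm = StructureKineticsModel(df)
        res = skm.fit(model_set=["extra_trees"], tune=False,
                      split_by_ligand=True, seed=1)
        assert len(res.y_test) == 60


class TestPermutationImportance:
    def test_ignored_feature_scores_exactly_zero(self):
        df = _linear_feature_table(500)
        X = df[feature_columns(df)].to_numpy()
        y = df["log10_tau"].to_numpy()
        stump = DecisionTreeRegressor(max_depth=2, random_state=0).fit(X, y)
        scores = permutation_importance(stump, X, y, n_repeats=3, seed=0)
        used = set(stump.tree_.feature[stump.tree_.feature >= 0])
        for j in range(X.shape[1]):
            if j not in used:
                assert scores[j] == 0.0

    def test_informative_feature_ranks_first(self):
        df = _linear_feature_table(800)
        skm = StructureKineticsModel(df)
        res = skm.fit(model_set=["random_forest"], tune=False, seed=0)
        imp = res.permutation_importance("random_forest", n_repeats=3)
        assert imp.idxmax() == "P2-R1"

    def test_constant_column_scores_zero(self):
        df = _linear_feature_table(300)
        df["P4-R1"] = 1.0  # constant: any permutation is the identity
        skm = StructureKineticsModel(df)
        res = skm.fit(model_set=["extra_trees"], tune=False, seed=0)
        imp = res.permutation_importance("extra_trees", n_repeats=3)
        assert imp["P4-R1"] == 0.0


class TestAttributions:
    def test_local_accuracy_all_models(self):
        df = _linear_feature_table(400)
        skm = StructureKineticsModel(df)
        res = skm.fit(model_set=MODEL_SET, tune=False, seed=0)
        for name in MODEL_SET:
            contribs, base = res.attributions(name)
            pred = res.models_[name].predict(res.X_test)
            scale = np.max(np.abs(pred))
            err = np.max(np.abs(base + contribs.sum(axis=1).to_numpy() - pred))
            assert err <= 1e-6 * scale, name

    def test_stump_attribution_hand_computed(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        y = np.where(X[:, 1] > 0, 2.0, -1.0)
        stump = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        contribs, base = additive_attributions(stump, X)
        assert stump.tree_.feature[0] == 1
        # only the split feature carries attribution
        assert np.allclose(contribs[:, [0, 2]], 0.0)
        assert np.allclose(contribs[:, 1], stump.predict(X) - base)

    def test_constant_model_all_zero(self):
        X = np.zeros((50, 4))
        y = np.full(50, 3.0)
        tree = DecisionTreeRegressor().fit(X, y)
        contribs, base = additive_attributions(tree, X)
        assert np.allclose(contribs, 0.0)
        assert base == pytest.approx(3.0)

    def test_non_tree_model_rejected(self):
        from sklearn.linear_model import LinearRegression

        lm = LinearRegression().fit(np.zeros((10, 2)), np.zeros(10))
        with pytest.raises(UnsupportedModelError):
            additive_attributions(lm, np.zeros((5, 2)))

    def test_stronger_planted_energy_gives_positive_attribution(
        self, small_feature_dataset
    ):
        # more negative planted-pair energies must push predictions up
        tables, l10, truth = small_feature_dataset
        sampled = sample_frames(tables, n_frames=200, seed=0)
        feats = augment_dataset(sampled, l10.to_dict(), n_aug_per_ligand=60,
                                block_size=50, seed=0)
        res = StructureKineticsModel(feats).fit(
            model_set=["random_forest"], tune=False, seed=0
        )
        contribs, _ = res.attributions("random_forest")
        (res_name, sub), w = next(iter(truth.planted_weights.items()))
        col = f"{res_name}-{sub}"
        vals = res.X_test[:, res.feature_names.index(col)]
        r = np.corrcoef(vals, contribs[col].to_numpy())[0, 1]
        assert r < -0.5  # negative energy <-> positive attribution


@pytest.fixture(scope="module")
def report(small_feature_dataset):
    tables, l10, _ = small_feature_dataset
    sampled = sample_frames(tables, n_frames=150, seed=2)
    return run_trials(
        sampled, l10.to_dict(), n_trials=2, n_aug_per_ligand=40,
        block_size=30, model_set=["extra_trees", "xgboost"],
        tune=False, n_repeats=2, seed=2,
    )


class TestTrialsAndSelection:

    def test_aggregate_is_mean_of_normalised_scores(self, report):
        scores = report.scores.copy()

        def norm(g):
            lo, hi = g["score"].min(), g["score"].max()
            g = g.copy()
            g["n"] = 0.0 if hi == lo else (g["score"] - lo) / (hi - lo)
            return g

        out = pd.concat(
            [norm(g) for _, g in scores.groupby(["trial", "model"])]
        )
        expect = out.groupby("feature")["n"].mean()
        got = report.aggregate["mean_score"]
        for feat in expect.index:
            assert got[feat] == pytest.approx(expect[feat])

    def test_single_trial_reduces_to_single_fit(self, small_feature_dataset):
        tables, l10, _ = small_feature_dataset
        sampled = sample_frames(tables, n_frames=100, seed=4)
        rep = run_trials(
            sampled, l10.to_dict(), n_trials=1, n_aug_per_ligand=30,
            block_size=20, model_set=["extra_trees"], tune=False,
            n_repeats=2, seed=4,
        )
        assert rep.scores["trial"].nunique() == 1
        assert len(rep.metrics) == 1

    def test_selection_matches_brute_force_sort(self, report):
        agg = report.aggregate.reset_index()
        expect = agg.sort_values(
            by=["mean_score", "mean_abs_attribution", "feature"],
            ascending=[False, False, True],
        )["feature"].head(5).tolist()
        assert select_top_features(report, k=5) == expect

    def test_k_equal_to_feature_count_is_identity(self, report):
        k = len(report.aggregate)
        assert set(select_top_features(report, k=k)) == set(report.aggregate.index)

    def test_k_too_large_rejected(self, report):
        with pytest.raises(InvalidParameterError):
            select_top_features(report, k=len(report.aggregate) + 1)

    def test_deterministic_under_master_seed(self, small_feature_dataset):
        tables, l10, _ = small_feature_dataset
        sampled = sample_frames(tables, n_frames=80, seed=6)
        kw = dict(
            log10_tau=l10.to_dict(), n_trials=2, n_aug_per_ligand=20,
            block_size=15, model_set=["extra_trees"], tune=False,
            n_repeats=2, seed=6,
        )
        r1 = run_trials(sampled, **kw)
        r2 = run_trials(sampled, **kw)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)
        pd.testing.assert_frame_equal(r1.aggregate, r2.aggregate)


class TestValidation:
    def test_unknown_substituent_rejected(self, tiny_energy_table):
        t = tiny_energy_table.copy()
        t.loc[0, "substituent"] = "R9"
        with pytest.raises(ValidationError):
            sample_frames(t, n_frames=1)
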