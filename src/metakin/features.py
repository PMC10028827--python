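"""Residue-substituent interaction-energy features and tree-ensemble ML.

The pipeline mirrors a structure-kinetics workflow: frame-level
interaction energies between ligand substituents (R1/R2/R4) and receptor
residues are sampled from the bound portion of unbinding trajectories,
noisy/uninformative residue-substituent pairs are filtered on the
magnitude and cross-ligand spread of their reweighted means, block-mean
augmentation turns 19 per-ligand energy tables into a row-rich regression
dataset, and four tree-ensemble regressors (random forest, extremely
randomized trees, gradient boosting, XGBoost) are trained to predict
log10 of the residence time. Kinetic modulators are ranked by permutation
importance (averaged over repeated trials and models) and explained by
exact additive attributions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.model_selection import GridSearchCV, train_test_split
from xgboost import XGBRegressor

from .attribution import additive_attributions
from .constants import DEFAULT_TEMPERATURE, DEFAULT_Z_THRESHOLD, beta
from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    MissingTargetError,
    ValidationError,
)

__all__ = [
    "ENERGY_TABLE_COLUMNS",
    "MODEL_SET",
    "pair_label",
    "validate_energy_table",
    "sample_frames",
    "filter_pairs",
    "augment_dataset",
    "feature_columns",
    "StructureKineticsModel",
    "StructureKineticsResults",
    "permutation_importance",
    "run_trials",
    "ImportanceReport",
    "select_top_features",
]

ENERGY_TABLE_COLUMNS = (
    "ligand_id",
    "trajectory_id",
    "frame_time",
    "residue_id",
    "substituent",
    "energy",
    "frame_bias",
    "z",
)

VALID_SUBSTITUENTS = ("R1", "R2", "R4")

#: The four tree-ensemble regressors used throughout.
MODEL_SET = ("random_forest", "extra_trees", "gradient_boosting", "xgboost")

_FRAME_KEY = ["ligand_id", "trajectory_id", "frame_time"]


def pair_label(residue: str, substituent: str) -> str:
    """Feature name of a (residue, substituent) pair, e.g. ``"H297-R4"``."""
    return f"{residue}-{substituent}"


def validate_energy_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema checks for a frame-level energy table."""
    missing = set(ENERGY_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"energy table missing columns: {sorted(missing)}")
    bad = set(table["substituent"].unique()) - set(VALID_SUBSTITUENTS)
    if bad:
        raise ValidationError(f"unknown substituent tokens: {sorted(bad)}")
    if not np.all(np.isfinite(table["energy"].to_numpy(dtype=float))):
        raise ValidationError("energies must be finite")
    return table


def _as_long_table(tables: Union[pd.DataFrame, Mapping[str, pd.DataFrame]]) -> pd.DataFrame:
    if isinstance(tables, Mapping):
        return pd.concat(tables.values(), ignore_index=True)
    return tables


def sample_frames(
    tables: Union[pd.DataFrame, Mapping[str, pd.DataFrame]],
    n_frames: int,
    seed: int = 0,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Uniform per-ligand sample of bound-state frames, without replacement.

    Eligible frames have ``z <= z_threshold`` (the ligand has not yet
    exited); a frame is one (ligand, trajectory, frame_time) record and is
    drawn with all its residue-substituent rows. Raises
    :class:`InsufficientDataError` naming the first ligand with fewer than
    ``n_frames`` eligible frames.
    """
    table = validate_energy_table(_as_long_table(tables))
    rng = np.random.default_rng(seed)
    out = []
    for lid, sub in table.groupby("ligand_id", sort=True):
        eligible = sub[sub["z"] <= z_threshold]
        frames = eligible[_FRAME_KEY].drop_duplicates()
        if len(frames) < n_frames:
            raise InsufficientDataError(
                f"ligand {lid!r} has {len(frames)} eligible frames, "
                f"needs {n_frames}"
            )
        take = frames.iloc[rng.choice(len(frames), size=n_frames, replace=False)]
        out.append(eligible.merge(take, on=_FRAME_KEY, how="inner"))
    return pd.concat(out, ignore_index=True)


def _reweighted_pair_means(
    table: pd.DataFrame, temperature: float
) -> pd.DataFrame:
    """Per-(ligand, pair) reweighted mean energies.

    Frame weights are exp(frame_bias/kT), normalised within each ligand.
    Returns a DataFrame indexed by ligand with one column per pair label.
    """
    df = table.copy()
    df["pair"] = [
        pair_label(r, s) for r, s in zip(df["residue_id"], df["substituent"])
    ]
    b = beta(temperature)
    out = {}
    for lid, sub in df.groupby("ligand_id", sort=True):
        bv = b * sub["frame_bias"].to_numpy(dtype=float)
        w = np.exp(bv - bv.max())
        e = sub["energy"].to_numpy(dtype=float)
        num = pd.Series(w * e).groupby(sub["pair"].to_numpy()).sum()
        den = pd.Series(w).groupby(sub["pair"].to_numpy()).sum()
        out[lid] = num / den
    return pd.DataFrame(out).T.sort_index()


def filter_pairs(
    tables: Union[pd.DataFrame, Mapping[str, pd.DataFrame]],
    magnitude_cutoff: float = 1.0,
    spread_cutoff: float = 0.25,
    temperature: float = DEFAULT_TEMPERATURE,
) -> Tuple[List[str], pd.DataFrame]:
    """Keep pairs that are both strong and kinetically discriminating.

    A pair survives iff the largest per-ligand reweighted mean magnitude is
    at least ``magnitude_cutoff`` (kcal/mol) AND the standard deviation of
    the per-ligand means across ligands is at least ``spread_cutoff``.
    Returns ``(surviving pair labels, per-pair statistics table)``.
    """
    table = validate_energy_table(_as_long_table(tables))
    means = _reweighted_pair_means(table, temperature)
    report = pd.DataFrame(
        {
            "max_abs_mean": means.abs().max(axis=0),
            "spread": means.std(axis=0, ddof=1),
        }
    )
    report["survives"] = (report["max_abs_mean"] >= magnitude_cutoff) & (
        report["spread"] >= spread_cutoff
    )
    survivors = sorted(report.index[report["survives"]])
    return survivors, report.sort_index()


def augment_dataset(
    tables: Union[pd.DataFrame, Mapping[str, pd.DataFrame]],
    log10_tau: Mapping[str, float],
    pairs: Optional[Sequence[str]] = None,
    n_aug_per_ligand: int = 200,
    block_size: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Block-mean bootstrap augmentation into a regression feature table.

    Each augmented row of a ligand is the per-pair mean energy over a
    freshly drawn (with replacement) block of ``block_size`` frames of
    that ligand; the target column ``log10_tau`` is the ligand's value
    replicated across its rows. Pass ``pairs`` (labels) to restrict the
    feature set, e.g. the survivors of :func:`filter_pairs`.
    """
    table = validate_energy_table(_as_long_table(tables))
    if block_size < 1 or n_aug_per_ligand < 1:
        raise InvalidParameterError("block_size and n_aug_per_ligand must be >= 1")
    df = table.copy()
    df["pair"] = [
        pair_label(r, s) for r, s in zip(df["residue_id"], df["substituent"])
    ]
    if pairs is not None:
        df = df[df["pair"].isin(set(pairs))]
        order = list(pairs)
    else:
        order = sorted(df["pair"].unique())

    rng = np.random.default_rng(seed)
    rows = []
    for lid, sub in df.groupby("ligand_id", sort=True):
        if lid not in log10_tau:
            raise MissingTargetError(f"no residence-time target for ligand {lid!r}")
        wide = sub.pivot_table(
            index=_FRAME_KEY, columns="pair", values="energy", sort=True
        )[order]
        mat = wide.to_numpy(dtype=float)
        n_frames = mat.shape[0]
        if block_size > n_frames:
            raise InvalidParameterError(
                f"block_size {block_size} exceeds {n_frames} frames of {lid!r}"
            )
        idx = rng.integers(0, n_frames, size=(n_aug_per_ligand, block_size))
        feat = mat[idx].mean(axis=1)
        block = pd.DataFrame(feat, columns=order)
        block.insert(0, "ligand_id", lid)
        block["log10_tau"] = float(log10_tau[lid])
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def feature_columns(features: pd.DataFrame) -> List[str]:
    """Feature (pair) columns of an augmented table, in table order."""
    return [c for c in features.columns if c not in ("ligand_id", "log10_tau")]


def _squared_pearson(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared Pearson correlation; NaN when either side is constant."""
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        return float("nan")
    r = stats.pearsonr(y_true, y_pred).statistic
    return float(r * r)


def _make_model(name: str, seed: int, n_jobs: int = 1):
    if name == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=n_jobs)
    if name == "extra_trees":
        return ExtraTreesRegressor(random_state=seed, n_jobs=n_jobs)
    if name == "gradient_boosting":
        return GradientBoostingRegressor(random_state=seed)
    if name == "xgboost":
        return XGBRegressor(
            random_state=seed, n_jobs=n_jobs, verbosity=0, tree_method="hist"
        )
    raise InvalidParameterError(f"unknown model {name!r}")


def _param_grid(name: str) -> dict:
    if name in ("random_forest", "extra_trees"):
        return {"n_estimators": [100, 300], "max_depth": [None, 8]}
    return {"n_estimators": [100, 300], "learning_rate": [0.05, 0.1]}


class StructureKineticsModel:
    """Tree-ensemble regression of log10 residence time on energy features.

    Parameters
    ----------
    features
        Augmented feature table (:func:`augment_dataset` output): one
        ``ligand_id`` column, pair-energy feature columns, and a
        ``log10_tau`` target column.
    """

    def __init__(self, features: pd.DataFrame, target: str = "log10_tau"):
        if target not in features.columns:
            raise MissingTargetError(f"feature table has no {target!r} column")
        if features.isna().any().any():
            raise ValidationError("feature table contains missing values")
        self.features = features.reset_index(drop=True)
        self.target = target
        self.feature_names = [
            c for c in features.columns if c not in ("ligand_id", target)
        ]
        if features["ligand_id"].nunique() < 2:
            raise InsufficientDataError(
                "need at least 2 ligands for a non-degenerate target"
            )
        if len(features) < 10:
            raise InsufficientDataError("need at least 10 rows")

    @classmethod
    def from_energy_tables(
        cls,
        tables: Union[pd.DataFrame, Mapping[str, pd.DataFrame]],
        log10_tau: Mapping[str, float],
        pairs: Optional[Sequence[str]] = None,
        n_aug_per_ligand: int = 200,
        block_size: int = 100,
        seed: int = 0,
    ) -> "StructureKineticsModel":
        feats = augment_dataset(
            tables, log10_tau, pairs=pairs,
            n_aug_per_ligand=n_aug_per_ligand, block_size=block_size, seed=seed,
        )
        return cls(feats)

    def fit(
        self,
        model_set: Sequence[str] = MODEL_SET,
        test_size: float = 0.2,
        cv_folds: int = 10,
        tune: bool = True,
        split_by_ligand: bool = False,
        seed: int = 0,
        n_jobs: int = 1,
    ) -> "StructureKineticsResults":
        """80:20 split, optional CV hyperparameter tuning, held-out metrics.

        The default split is row-level; ``split_by_ligand=True`` holds out
        whole ligands instead (an honest generalization estimate at the
        cost of very few effective samples).
        """
        X = self.features[self.feature_names].to_numpy(dtype=float)
        y = self.features[self.target].to_numpy(dtype=float)
        if split_by_ligand:
            ligands = self.features["ligand_id"].unique()
            rng = np.random.default_rng(seed)
            n_test = max(1, int(round(test_size * len(ligands))))
            test_ligands = set(rng.choice(ligands, size=n_test, replace=False))
            test_mask = self.features["ligand_id"].isin(test_ligands).to_numpy()
            X_tr, X_te = X[~test_mask], X[test_mask]
            y_tr, y_te = y[~test_mask], y[test_mask]
        else:
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=test_size, random_state=seed
            )

        models, metrics = {}, []
        for name in model_set:
            est = _make_model(name, seed=seed, n_jobs=n_jobs)
            best_params: dict = {}
            if tune:
                search = GridSearchCV(
                    est, _param_grid(name), cv=cv_folds,
                    scoring="neg_mean_squared_error", n_jobs=n_jobs, refit=True,
                )
                search.fit(X_tr, y_tr)
                est = search.best_estimator_
                best_params = search.best_params_
            else:
                est.fit(X_tr, y_tr)
            pred = est.predict(X_te)
            rmse = float(np.sqrt(np.mean((pred - y_te) ** 2)))
            metrics.append(
                {
                    "model": name,
                    "r2": _squared_pearson(y_te, pred),
                    "rmse": rmse,
                    "best_params": best_params,
                }
            )
            models[name] = est
        return StructureKineticsResults(
            model=self,
            models_=models,
            metrics_=pd.DataFrame(metrics).set_index("model"),
            X_train=X_tr, y_train=y_tr, X_test=X_te, y_test=y_te,
            seed=seed,
        )


def permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Mean decrease in test score when one feature column is shuffled.

    The score is the squared Pearson correlation between predictions and
    targets; ``score_j = mean over repeats of (score_base - score with
    column j permuted)``. A feature the model never consults scores
    exactly 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise InsufficientDataError("need >= 2 test rows")
    rng = np.random.default_rng(seed)
    base = _squared_pearson(y, model.predict(X))
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drop = 0.0
        for _ in range(n_repeats):
            Xp = X.copy()
            perm = rng.permutation(X.shape[0])
            Xp[:, j] = X[perm, j]
            if np.array_equal(Xp[:, j], X[:, j]):
                continue  # identity permutation (or constant column): no change
            drop += base - _squared_pearson(y, model.predict(Xp))
        scores[j] = drop / n_repeats
    return scores


@dataclass
class StructureKineticsResults:
    """Fitted tree ensembles with held-out metrics and explanations."""

    model: StructureKineticsModel
    models_: Dict[str, object]
    metrics_: pd.DataFrame
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    seed: int

    @property
    def feature_names(self) -> List[str]:
        return self.model.feature_names

    def permutation_importance(
        self, model_name: str, n_repeats: int = 5, seed: Optional[int] = None
    ) -> pd.Series:
        est = self.models_[model_name]
        s = permutation_importance(
            est, self.X_test, self.y_test, n_repeats=n_repeats,
            seed=self.seed if seed is None else seed,
        )
        return pd.Series(s, index=self.feature_names, name=model_name)

    def attributions(self, model_name: str, X: Optional[np.ndarray] = None):
        """Additive attributions ``(contribs DataFrame, base value)``."""
        est = self.models_[model_name]
        X = self.X_test if X is None else np.asarray(X, dtype=float)
        contribs, base = additive_attributions(est, X)
        return pd.DataFrame(contribs, columns=self.feature_names), base

    def summary(self) -> str:
        lines = [
            "Structure-kinetics tree-ensemble regression",
            "=" * 46,
            f"rows: {len(self.model.features)}   "
            f"features: {len(self.feature_names)}   "
            f"ligands: {self.model.features['ligand_id'].nunique()}",
            f"train/test rows: {len(self.y_train)}/{len(self.y_test)}",
            "",
            "held-out test metrics (r2 = squared Pearson):",
        ]
        for name, row in self.metrics_.iterrows():
            lines.append(f"  {name:<18} r2 = {row['r2']:.4f}   rmse = {row['rmse']:.4f}")
        return "\n".join(lines)


@dataclass
class ImportanceReport:
    """Per-trial importance scores and their aggregate ranking.

    ``scores`` has one row per (trial, model, feature) with the raw
    permutation score; ``aggregate`` averages min-max-normalised scores
    across models and trials (with their standard deviation) and carries
    the mean absolute attribution used for tie-breaking.
    """

    scores: pd.DataFrame
    aggregate: pd.DataFrame
    metrics: pd.DataFrame
    n_trials: int
    seed: int

    def ranking(self) -> List[str]:
        return list(self.aggregate.index)


def _normalise(s: pd.Series) -> pd.Series:
    rng_ = s.max() - s.min()
    if rng_ == 0:
        return s * 0.0
    return (s - s.min()) / rng_


def run_trials(
    tables: Optional[Union[pd.DataFrame, Mapping[str, pd.DataFrame]]] = None,
    log10_tau: Optional[Mapping[str, float]] = None,
    pairs: Optional[Sequence[str]] = None,
    features: Optional[pd.DataFrame] = None,
    n_trials: int = 100,
    n_aug_per_ligand: int = 200,
    block_size: int = 100,
    model_set: Sequence[str] = MODEL_SET,
    tune: bool = False,
    cv_folds: int = 10,
    n_repeats: int = 5,
    reaugment: bool = True,
    seed: int = 0,
) -> ImportanceReport:
    """Repeated train/test/importance trials on re-split (or re-augmented) data.

    Each trial derives its own seed from the master seed; importance scores
    are min-max normalised within (trial, model) and averaged across the
    model set and trials into the aggregate ranking. Mean |attribution| on
    the test rows (averaged the same way) is recorded for tie-breaking.
    """
    ss = np.random.SeedSequence(seed)
    trial_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(max(n_trials, 1))]

    if tables is None and features is None:
        raise InvalidParameterError("supply energy tables or a precomputed feature table")
    if reaugment and tables is None:
        raise InvalidParameterError("re-augmentation requires the energy tables")

    base_features = features
    if not reaugment and base_features is None:
        base_features = augment_dataset(
            tables, log10_tau, pairs=pairs,
            n_aug_per_ligand=n_aug_per_ligand, block_size=block_size, seed=seed,
        )

    score_rows, metric_rows, attrib_acc = [], [], []
    for trial, tseed in enumerate(trial_seeds[:n_trials]):
        if reaugment:
            feats = augment_dataset(
                tables, log10_tau, pairs=pairs,
                n_aug_per_ligand=n_aug_per_ligand, block_size=block_size,
                seed=tseed,
            )
        else:
            feats = base_features
        skm = StructureKineticsModel(feats)
        res = skm.fit(model_set=model_set, tune=tune, cv_folds=cv_folds, seed=tseed)
        for name in model_set:
            imp = res.permutation_importance(name, n_repeats=n_repeats, seed=tseed)
            for feat, val in imp.items():
                score_rows.append(
                    {"trial": trial, "model": name, "feature": feat, "score": val}
                )
            contribs, _ = res.attributions(name)
            attrib_acc.append(contribs.abs().mean(axis=0))
            row = res.metrics_.loc[name]
            metric_rows.append(
                {"trial": trial, "model": name, "r2": row["r2"], "rmse": row["rmse"]}
            )

    scores = pd.DataFrame(score_rows)
    normalised = scores.copy()
    normalised["norm_score"] = normalised.groupby(["trial", "model"])["score"].transform(
        _normalise
    )
    agg = normalised.groupby("feature")["norm_score"].agg(["mean", "std"])
    agg.columns = ["mean_score", "sd_score"]
    agg["mean_abs_attribution"] = (
        pd.concat(attrib_acc, axis=1).mean(axis=1).reindex(agg.index)
    )
    agg = agg.reset_index().sort_values(
        by=["mean_score", "mean_abs_attribution", "feature"],
        ascending=[False, False, True],
        kind="stable",
    ).set_index("feature")
    return ImportanceReport(
        scores=scores,
        aggregate=agg,
        metrics=pd.DataFrame(metric_rows),
        n_trials=n_trials,
        seed=seed,
    )


def select_top_features(report: ImportanceReport, k: int = 15) -> List[str]:
    """Top-``k`` features by aggregate score (ties: mean |attribution|, token).

    Use the result to re-augment and retrain via
    :meth:`StructureKineticsModel.from_energy_tables` with ``pairs=...``.
    """
    agg = report.aggregate
    if k > len(agg):
        raise InvalidParameterError(
            f"k={k} exceeds the {len(agg)} reported features"
        )
    ordered = agg.reset_index().sort_values(
        by=["mean_score", "mean_abs_attribution", "feature"],
        ascending=[False, False, True],
        kind="stable",
    )
    return ordered["feature"].head(k).tolist()
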