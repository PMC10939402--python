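"""LT50 regression: bagged base learners, stacking, greedy weighted ensembles.

The trainer mimics the structure of modern tabular Auto-ML systems:

1. each base learner is *bagged* over k folds — k copies are fit, each
   predicting the fold it never saw, which yields leak-free out-of-fold
   (OOF) predictions and an averaged bagged predictor;
2. stack level ℓ > 1 learners see the original features plus the level
   ℓ−1 OOF predictions;
3. every level gets a *weighted ensemble* built by greedy forward
   selection with replacement (Caruana-style) on the OOF predictions,
   initialized at the single best member so the ensemble can never
   validate worse than its best member;
4. among all models within a small RMSE tolerance of the global best, the
   one at the lowest stack level (ties: fewest members) is selected — the
   least complex model that is effectively as good.

All randomness flows from one integer seed recorded in the artifact.
"""

from __future__ import annotations

import json
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field, replace
from functools import partial

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from lightgbm import LGBMRegressor

__all__ = [
    "HardinessDataset",
    "SplitSpec",
    "TrainConfig",
    "BaseLearnerSpec",
    "TrainedEnsemble",
    "ModelRef",
    "EvalReport",
    "default_learner_specs",
    "split_train_test",
    "train",
    "select_model",
    "predict",
    "rmse",
    "evaluate",
    "save_ensemble",
    "load_ensemble",
]


@dataclass
class HardinessDataset:
    """Labelled samples: feature matrix, observed LT50 (°C), row metadata."""

    X: pd.DataFrame
    y: pd.Series
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if self.y.isna().any():
            raise ValueError("missing LT50 labels")
        if self.meta is not None and len(self.meta) != len(self.X):
            raise ValueError("meta length mismatch")

    def __len__(self) -> int:
        return len(self.X)

    def take(self, idx: np.ndarray) -> "HardinessDataset":
        return HardinessDataset(
            self.X.iloc[idx].reset_index(drop=True),
            self.y.iloc[idx].reset_index(drop=True),
            None if self.meta is None else self.meta.iloc[idx].reset_index(drop=True),
        )


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")


def split_train_test(
    data: HardinessDataset, spec: SplitSpec
) -> tuple[HardinessDataset, HardinessDataset]:
    """Uniform-random 90/10-style split; |test| = round(K * test_fraction)."""
    k = len(data)
    if k < 10:
        raise ValueError(f"dataset too small to split (K={k})")
    n_test = int(round(k * spec.test_fraction))
    perm = np.random.default_rng(spec.seed).permutation(k)
    return data.take(perm[n_test:]), data.take(perm[:n_test])


@dataclass(frozen=True)
class BaseLearnerSpec:
    """A named base-learner family; ``factory(seed)`` returns a fresh estimator."""

    name: str
    factory: object  # Callable[[int], estimator]


# factories are module-level (not lambdas) so trained artifacts pickle cleanly
def _make_gbm(seed: int, n_estimators: int):
    return LGBMRegressor(
        n_estimators=n_estimators, learning_rate=0.08, num_leaves=31,
        min_child_samples=10, random_state=seed, n_jobs=1, verbose=-1,
    )


def _make_rf(seed: int, n_estimators: int):
    return RandomForestRegressor(
        n_estimators=n_estimators, min_samples_leaf=2, random_state=seed, n_jobs=1
    )


def _make_ridge(seed: int):
    return make_pipeline(StandardScaler(), Ridge(alpha=1.0))


def _make_knn(seed: int):
    return make_pipeline(
        StandardScaler(), KNeighborsRegressor(n_neighbors=10, weights="distance")
    )


def default_learner_specs(fast: bool = False) -> list[BaseLearnerSpec]:
    """Gradient-boosted trees, random forest, ridge and k-NN.

    ``fast`` shrinks tree counts for quick experiments; defaults are sized
    for datasets of a few thousand rows.
    """
    return [
        BaseLearnerSpec("gbm", partial(_make_gbm, n_estimators=120 if fast else 300)),
        BaseLearnerSpec("rf", partial(_make_rf, n_estimators=80 if fast else 200)),
        BaseLearnerSpec("ridge", _make_ridge),
        BaseLearnerSpec("knn", _make_knn),
    ]


@dataclass(frozen=True)
class TrainConfig:
    num_bag_folds: int = 10
    num_stack_levels: int = 5
    learner_specs: tuple[BaseLearnerSpec, ...] | None = None
    max_ensemble_iters: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_bag_folds < 2:
            raise ValueError("num_bag_folds must be >= 2")
        if self.num_stack_levels < 1:
            raise ValueError("num_stack_levels must be >= 1")


@dataclass
class BaggedModel:
    """One base learner bagged over k folds, with leak-free OOF predictions."""

    name: str
    level: int
    fold_models: list
    oof_pred: np.ndarray
    val_rmse: float


@dataclass
class WeightedEnsemble:
    """Nonnegative member weights summing to 1, fit by greedy forward selection."""

    member_names: list[str]
    weights: np.ndarray
    oof_pred: np.ndarray
    val_rmse: float

    @property
    def n_members(self) -> int:
        return int((self.weights > 0).sum())


@dataclass
class StackLevel:
    level: int
    members: list[BaggedModel]
    ensemble: WeightedEnsemble


@dataclass(frozen=True)
class ModelRef:
    """Pointer into the zoo: ('ensemble' or a member name) at a stack level."""

    level: int
    name: str


@dataclass
class TrainedEnsemble:
    levels: list[StackLevel]
    feature_names: list[str]
    config: TrainConfig
    selected: ModelRef | None = None

    def models(self):
        """Yield (ref, n_members, val_rmse) for every model in the zoo."""
        for lvl in self.levels:
            for m in lvl.members:
                yield ModelRef(lvl.level, m.name), 1, m.val_rmse
            yield ModelRef(lvl.level, "ensemble"), lvl.ensemble.n_members, lvl.ensemble.val_rmse

    def manifest(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "seed": self.config.seed,
            "num_bag_folds": self.config.num_bag_folds,
            "num_stack_levels": self.config.num_stack_levels,
            "selected": None if self.selected is None
            else {"level": self.selected.level, "name": self.selected.name},
            "levels": [
                {
                    "level": lvl.level,
                    "members": {m.name: m.val_rmse for m in lvl.members},
                    "ensemble_weights": dict(
                        zip(lvl.ensemble.member_names, lvl.ensemble.weights.tolist())
                    ),
                    "ensemble_val_rmse": lvl.ensemble.val_rmse,
                }
                for lvl in self.levels
            ],
        }


@contextmanager
def _quiet_estimators():
    # estimators are always fed plain arrays; silence feature-name chatter
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        yield


def rmse(predicted, observed) -> float:
    """Root-mean-square error (°C)."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def _greedy_weighted_ensemble(
    members: list[BaggedModel], y: np.ndarray, max_iters: int
) -> WeightedEnsemble:
    preds = np.column_stack([m.oof_pred for m in members])
    names = [m.name for m in members]
    counts = np.zeros(len(members), dtype=int)

    best = int(np.argmin([m.val_rmse for m in members]))
    counts[best] = 1
    total = preds[:, best].copy()
    cur = rmse(total, y)
    for it in range(1, max_iters):
        cand = (total[:, None] + preds) / (it + 1)
        scores = np.sqrt(np.mean((cand - y[:, None]) ** 2, axis=0))
        j = int(np.argmin(scores))
        if scores[j] >= cur - 1e-12:
            break
        counts[j] += 1
        total += preds[:, j]
        cur = float(scores[j])

    weights = counts / counts.sum()
    return WeightedEnsemble(names, weights, preds @ weights, rmse(preds @ weights, y))


def train(data: HardinessDataset, config: TrainConfig | None = None) -> TrainedEnsemble:
    """Fit the stacked, bagged, greedily weighted model zoo."""
    config = config or TrainConfig()
    specs = list(config.learner_specs or default_learner_specs())
    if len(specs) < 2:
        raise ValueError("need at least 2 base learner specs")

    X = data.X.to_numpy(dtype=float)
    y = data.y.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    k = len(y)
    if k // config.num_bag_folds < 2:
        raise ValueError("folds would contain fewer than 2 rows")

    splitter = KFold(n_splits=config.num_bag_folds, shuffle=True, random_state=config.seed)
    folds = list(splitter.split(X))

    levels: list[StackLevel] = []
    level_input = X
    for level in range(1, config.num_stack_levels + 1):
        members = []
        for s_idx, spec in enumerate(specs):
            oof = np.empty(k)
            fold_models = []
            for tr, va in folds:
                est = spec.factory(config.seed + 997 * level + 31 * s_idx)
                with _quiet_estimators():
                    est.fit(level_input[tr], y[tr])
                    oof[va] = est.predict(level_input[va])
                fold_models.append(est)
            members.append(
                BaggedModel(f"{spec.name}_L{level}", level, fold_models, oof, rmse(oof, y))
            )
        ensemble = _greedy_weighted_ensemble(members, y, config.max_ensemble_iters)
        levels.append(StackLevel(level, members, ensemble))
        level_input = np.hstack([X, np.column_stack([m.oof_pred for m in members])])

    zoo = TrainedEnsemble(levels, list(data.X.columns), config)
    zoo.selected = select_model(zoo)
    return zoo


def select_model(zoo: TrainedEnsemble, tolerance: float = 0.01) -> ModelRef:
    """Least-complexity selection: lowest stack level within ``tolerance`` °C
    of the best validation RMSE; ties broken by fewer ensemble members."""
    entries = list(zoo.models())
    if not entries:
        raise ValueError("empty model zoo")
    best = min(v for _, _, v in entries)
    eligible = [(ref, n, v) for ref, n, v in entries if v <= best + tolerance]
    ref, _, _ = min(eligible, key=lambda e: (e[0].level, e[1], e[2]))
    return ref


def _check_columns(zoo: TrainedEnsemble, X: pd.DataFrame) -> None:
    got, want = list(X.columns), zoo.feature_names
    if got != want:
        missing = [c for c in want if c not in got]
        extra = [c for c in got if c not in want]
        raise ValueError(f"feature column mismatch: missing {missing}, extra {extra}")


def _bagged_predict(member: BaggedModel, X: np.ndarray) -> np.ndarray:
    with _quiet_estimators():
        return np.mean([m.predict(X) for m in member.fold_models], axis=0)


def predict(zoo: TrainedEnsemble, X, ref: ModelRef | None = None) -> np.ndarray:
    """Predict LT50 (°C) per row with the selected (or an explicit) model."""
    if isinstance(X, pd.DataFrame):
        _check_columns(zoo, X)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    ref = ref or zoo.selected or select_model(zoo)

    level_input = X
    for lvl in zoo.levels:
        member_preds = {m.name: _bagged_predict(m, level_input) for m in lvl.members}
        if lvl.level == ref.level:
            if ref.name == "ensemble":
                stacked = np.column_stack(
                    [member_preds[n] for n in lvl.ensemble.member_names]
                )
                return stacked @ lvl.ensemble.weights
            return member_preds[ref.name]
        level_input = np.hstack([X, np.column_stack(list(member_preds.values()))])
    raise ValueError(f"model {ref} not found in zoo")


@dataclass
class EvalReport:
    """Overall / per-group RMSE and signed errors (predicted − observed)."""

    rmse_overall: float
    rmse_by_group: dict[str, pd.Series]
    prediction_error: pd.Series

    def to_frame(self) -> pd.DataFrame:
        rows = [("overall", "", self.rmse_overall)]
        for key, series in self.rmse_by_group.items():
            rows += [(key, str(g), v) for g, v in series.items()]
        return pd.DataFrame(rows, columns=["group_key", "group", "rmse"])


def evaluate(
    zoo: TrainedEnsemble,
    test: HardinessDataset,
    group_keys: tuple[str, ...] = (),
    ref: ModelRef | None = None,
) -> EvalReport:
    """RMSE overall and per metadata group; errors use predicted − observed
    (negative error = the model predicted hardier buds than observed)."""
    pred = predict(zoo, test.X, ref)
    err = pd.Series(pred - test.y.to_numpy(), name="prediction_error")
    by_group: dict[str, pd.Series] = {}
    for key in group_keys:
        if test.meta is None or key not in test.meta.columns:
            raise ValueError(f"no metadata column {key!r}")
        sq = err.to_numpy() ** 2
        by_group[key] = (
            pd.Series(sq).groupby(test.meta[key].to_numpy()).mean().pow(0.5)
        )
    return EvalReport(rmse(pred, test.y), by_group, err)


def save_ensemble(zoo: TrainedEnsemble, path) -> None:
    """Persist the zoo (joblib) with a JSON manifest alongside."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(zoo, path / "ensemble.joblib")
    (path / "model_manifest.json").write_text(json.dumps(zoo.manifest(), indent=2))


def load_ensemble(path) -> TrainedEnsemble:
    from pathlib import Path

    return joblib.load(Path(path) / "ensemble.joblib")
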