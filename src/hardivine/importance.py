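"""Feature-importance quantification: permutation drop and Shapley values.

Two complementary views of what the trained regressor uses:

* **Permutation importance** — shuffle one feature column across rows of a
  held-out subsample and report the increase in RMSE (°C).  A feature the
  model ignores scores ~0; a constant feature scores exactly 0, since every
  permutation of a constant column is the identity.

* **Shapley values** — the average marginal contribution of each feature
  over orderings, estimated by Monte-Carlo permutation sampling with an
  interventional (background-marginal) value function.  For each sampled
  ordering the per-feature contributions telescope, so local accuracy
  (base value + Σ φ = prediction) holds exactly for every instance,
  independent of the number of permutations sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PermutationImportance",
    "permutation_importance",
    "shapley_values",
    "rank_features",
]


@dataclass
class PermutationImportance:
    """Per-feature mean RMSE increase and across-shuffle-set SD (°C)."""

    table: pd.DataFrame  # index: feature; columns: importance, std

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="feature")


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def permutation_importance(
    predict_fn,
    X: pd.DataFrame,
    y,
    num_shuffle_sets: int = 100,
    subsample_size: int = 1000,
    seed: int = 0,
) -> PermutationImportance:
    """Mean RMSE(shuffled) − RMSE(baseline) over shuffle sets, per feature.

    Each shuffle set draws a row subsample of size min(subsample_size, K)
    without replacement, then permutes one column at a time within it.
    """
    if subsample_size < 2:
        raise ValueError("subsample_size must be >= 2")
    if len(X) < 2:
        raise ValueError("need at least 2 test rows")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n_rows = min(subsample_size, len(X))

    deltas = np.zeros((num_shuffle_sets, X.shape[1]))
    for s in range(num_shuffle_sets):
        rows = rng.choice(len(X), size=n_rows, replace=False)
        Xs = X.iloc[rows].reset_index(drop=True)
        ys = y[rows]
        base = _rmse(np.asarray(predict_fn(Xs)), ys)
        perm = rng.permutation(n_rows)
        for j, col in enumerate(X.columns):
            Xp = Xs.copy()
            Xp[col] = Xs[col].to_numpy()[perm]
            deltas[s, j] = _rmse(np.asarray(predict_fn(Xp)), ys) - base
    table = pd.DataFrame(
        {"importance": deltas.mean(axis=0), "std": deltas.std(axis=0, ddof=1) if num_shuffle_sets > 1 else 0.0},
        index=pd.Index(X.columns, name="feature"),
    )
    return PermutationImportance(table)


def shapley_values(
    predict_fn,
    instances: pd.DataFrame,
    background: pd.DataFrame,
    n_permutations: int = 20,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Monte-Carlo permutation-sampling Shapley estimates.

    Returns (per-instance per-feature values, base value), where the base
    value is the mean model output over the background sample.  The value
    function replaces background columns by the instance's values for the
    features "present" in a coalition (interventional expectation).
    """
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    cols = list(instances.columns)
    if list(background.columns) != cols:
        raise ValueError("instances and background must share columns")

    rng = np.random.default_rng(seed)
    bg = background.to_numpy(dtype=float)
    inst = instances.to_numpy(dtype=float)
    n_feat = len(cols)
    base_value = float(np.mean(predict_fn(background)))

    phi = np.zeros((len(inst), n_feat))
    for i, x in enumerate(inst):
        for _ in range(n_permutations):
            order = rng.permutation(n_feat)
            z = bg.copy()
            v_prev = None
            for j in order:
                z[:, j] = x[j]
                v_new = float(
                    np.mean(predict_fn(pd.DataFrame(z, columns=cols)))
                )
                phi[i, j] += v_new - (base_value if v_prev is None else v_prev)
                v_prev = v_new
        phi[i] /= n_permutations
    return pd.DataFrame(phi, columns=cols, index=instances.index), base_value


def rank_features(shapley: pd.DataFrame) -> list[str]:
    """Features ordered by descending mean |Shapley value|; ties keep input order."""
    mean_abs = shapley.abs().mean(axis=0)
    order = np.argsort(-mean_abs.to_numpy(), kind="stable")
    return [shapley.columns[i] for i in order]
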