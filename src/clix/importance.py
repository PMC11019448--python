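"""Random-forest variable importance as percent increase in out-of-bag MSE.

A bagged ensemble of regression trees is fit to the CLix score, with
bootstrap resampling handled here (not delegated) so the out-of-bag (OOB)
membership of every tree is known exactly.  For each predictor, its column
is permuted over the whole sample and the OOB predictions are recomputed;
the importance is

    %IncMSE = 100 * (mean permuted OOB MSE - baseline OOB MSE) / baseline OOB MSE

averaged over a configurable number of permutation repeats.  Irrelevant
variables land near zero (small negative values are possible); the ranking
is by descending %IncMSE.  Tree hyperparameters follow common
regression-forest practice: mtry = max(1, p/3) features per split and a
minimum leaf size of 5.

A ``raw_difference=True`` flag reports the unnormalized MSE increase
instead, for consumers who prefer absolute units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .errors import ConstantInputError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 500
DEFAULT_N_PERMUTATIONS = 50
MIN_CASES = 50


@dataclass(frozen=True)
class VariableImportance:
    name: str
    pct_inc_mse: float
    rank: int


@dataclass(frozen=True)
class ImportanceReport:
    """Ranked per-variable importances plus model metadata."""

    variables: tuple[VariableImportance, ...]
    n_trees: int
    oob_mse: float
    seed: int
    n_permutations: int
    n_cases: int
    n_dropped: int
    raw_difference: bool = False

    def to_dict(self) -> dict:
        return {
            "variables": [
                {"name": v.name, "pct_inc_mse": v.pct_inc_mse, "rank": v.rank}
                for v in self.variables
            ],
            "model_meta": {
                "n_trees": self.n_trees,
                "oob_mse": self.oob_mse,
                "seed": self.seed,
                "n_permutations": self.n_permutations,
                "n_cases": self.n_cases,
                "n_dropped": self.n_dropped,
                "raw_difference": self.raw_difference,
            },
        }

    def ranking(self) -> list[str]:
        return [v.name for v in sorted(self.variables, key=lambda v: v.rank)]


def _oob_mse(trees, oob_masks, X: np.ndarray, y: np.ndarray) -> float:
    """OOB MSE: each case predicted by the mean of the trees that did not see it."""
    pred_sum = np.zeros(len(y))
    pred_cnt = np.zeros(len(y))
    for tree, oob in zip(trees, oob_masks):
        if not oob.any():
            continue
        pred_sum[oob] += tree.predict(X[oob])
        pred_cnt[oob] += 1
    covered = pred_cnt > 0
    resid = y[covered] - pred_sum[covered] / pred_cnt[covered]
    return float(np.mean(resid**2))


def rf_importance(
    features: pd.DataFrame,
    target,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    mtry: int | None = None,
    min_samples_leaf: int = 5,
    raw_difference: bool = False,
) -> ImportanceReport:
    """Fit the forest and rank predictors by permutation %IncMSE.

    ``features`` is a case-by-variable DataFrame (numeric; booleans are cast
    to 0/1); rows with any missing value are dropped listwise and logged.
    The target must be non-constant and at least ``MIN_CASES`` complete
    cases are required.
    """
    if features.shape[1] < 2:
        raise ValidationError("need at least 2 predictor variables")
    y_all = np.asarray(target, dtype=float)
    if len(y_all) != len(features):
        raise ValidationError("target length must match the feature table")

    X_df = features.astype(float)
    keep = ~(X_df.isna().any(axis=1).to_numpy() | np.isnan(y_all))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("listwise deletion dropped %d incomplete cases", n_dropped)
    X = X_df.to_numpy()[keep]
    y = y_all[keep]
    n, p = X.shape
    if n < MIN_CASES:
        raise ValidationError(f"need >= {MIN_CASES} complete cases, got {n}")
    if np.ptp(y) == 0:
        raise ConstantInputError("target is constant")

    rng = np.random.default_rng(seed)
    mtry = mtry or max(1, p // 3)

    trees = []
    oob_masks = []
    for _ in range(n_trees):
        idx = rng.integers(0, n, n)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        oob_masks.append(oob)

    baseline = _oob_mse(trees, oob_masks, X, y)

    names = list(features.columns)
    importances = []
    for j, name in enumerate(names):
        mses = []
        X_perm = X.copy()
        for _ in range(n_permutations):
            X_perm[:, j] = X[rng.permutation(n), j]
            mses.append(_oob_mse(trees, oob_masks, X_perm, y))
        delta = float(np.mean(mses)) - baseline
        value = delta if raw_difference else 100.0 * delta / baseline
        importances.append((name, value))

    order = sorted(range(p), key=lambda i: (-importances[i][1], names[i]))
    ranks = {names[i]: r + 1 for r, i in enumerate(order)}
    variables = tuple(
        VariableImportance(name, value, ranks[name]) for name, value in importances
    )
    return ImportanceReport(
        variables=variables,
        n_trees=n_trees,
        oob_mse=baseline,
        seed=seed,
        n_permutations=n_permutations,
        n_cases=n,
        n_dropped=n_dropped,
        raw_difference=raw_difference,
    )
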