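"""Random-forest condition ranking and frailty-index scoring.

Condition importance is mean decrease accuracy: for each tree, the drop
in out-of-bag accuracy when one condition's column is permuted among the
tree's OOB samples, averaged over trees (the classic randomForest
variable importance, unscaled). Model accuracy for choosing the number
of conditions k is out-of-bag classification accuracy of a forest refit
on the top-k conditions; the selected k maximizes that accuracy, taking
the smallest k on ties. The frailty index itself is the cumulative-
deficit ratio: the number of selected conditions a subject has in the
baseline year divided by k, so scores live on {0, 1/k, ..., 1}.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .claims_deficits import ConditionCatalog, DeficitMatrix
from .exceptions import ConfigError, DataError, DegenerateOutcomeError


@dataclass(frozen=True)
class RFSettings:
    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    seed: int = 0
    class_weight: str | None = None   # None = unweighted fitting

    def validate(self) -> None:
        if self.n_trees <= 0:
            raise ConfigError("n_trees: must be positive")


def _fit_forest(
    X: np.ndarray, y: np.ndarray, settings: RFSettings, oob_score: bool = False
) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=settings.n_trees,
        max_features=settings.max_features,
        random_state=settings.seed,
        class_weight=settings.class_weight,
        bootstrap=True,
        oob_score=oob_score,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def _oob_mask(tree, n: int) -> np.ndarray:
    """Out-of-bag mask for one fitted tree.

    scikit-learn draws each tree's bootstrap sample as
    RandomState(tree.random_state).randint(0, n, n); replaying that draw
    recovers the exact in-bag multiset (the reconstructed OOB majority
    vote reproduces ``forest.oob_score_`` bit-for-bit).
    """
    idx = np.random.RandomState(tree.random_state).randint(0, n, n)
    mask = np.ones(n, dtype=bool)
    mask[idx] = False
    return mask


def oob_accuracy(forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray) -> float:
    """OOB majority-vote accuracy recomputed from per-tree masks."""
    n = len(y)
    votes = np.zeros((n, len(forest.classes_)))
    for tree in forest.estimators_:
        oob = _oob_mask(tree, n)
        votes[oob] += tree.predict_proba(X[oob])
    covered = votes.sum(axis=1) > 0
    pred = forest.classes_[votes.argmax(axis=1)]
    return float((pred[covered] == y[covered]).mean())


def rank_importance(
    matrix: DeficitMatrix, outcome: np.ndarray, settings: RFSettings = RFSettings()
) -> pd.DataFrame:
    """Mean-decrease-accuracy importance per condition, sorted descending.

    Ties are broken by condition_id lexical order. The permutation stream
    is seeded from ``settings.seed``, so results are reproducible.
    """
    settings.validate()
    y = np.asarray(outcome)
    if len(y) != len(matrix.subject_ids):
        raise DataError("rank_importance: outcome not aligned with matrix rows")
    if np.unique(y).size < 2:
        raise DegenerateOutcomeError("rank_importance: outcome has a single class")
    X = matrix.values.astype(np.float64)
    n, p = X.shape
    forest = _fit_forest(X, y, settings)
    rng = np.random.default_rng(settings.seed + 1_000_003)

    drops = np.zeros(p)
    for tree in forest.estimators_:
        oob = _oob_mask(tree, n)
        Xo = X[oob]
        yo = y[oob]
        base_pred = tree.predict(Xo)
        base_acc = (base_pred == yo).mean()
        for j in range(p):
            col = Xo[:, j]
            if col.min() == col.max():
                continue  # constant feature: permutation is a no-op, drop 0
            perm = rng.permutation(len(col))
            Xp = Xo.copy()
            Xp[:, j] = col[perm]
            drops[j] += base_acc - (tree.predict(Xp) == yo).mean()
    drops /= settings.n_trees

    out = pd.DataFrame({"condition_id": matrix.condition_ids, "importance": drops})
    out = out.sort_values(
        ["importance", "condition_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return out


@dataclass
class FrailtyIndexModel:
    """Selected condition set with the accuracy-vs-k trace behind it."""

    ranked: pd.DataFrame                  # condition_id, importance (descending)
    selected_k: int
    accuracy_trace: list[tuple[int, float]]
    rf_settings: RFSettings
    target_outcome: str = "all_cause_mortality"

    @property
    def selected_ids(self) -> list[str]:
        return self.ranked["condition_id"].head(self.selected_k).tolist()

    @property
    def selected_accuracy(self) -> float:
        return dict(self.accuracy_trace)[self.selected_k]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ranked": self.ranked.to_dict(orient="list"),
            "selected_k": self.selected_k,
            "accuracy_trace": [[int(k), float(a)] for k, a in self.accuracy_trace],
            "rf_settings": asdict(self.rf_settings),
            "target_outcome": self.target_outcome,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FrailtyIndexModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            ranked=pd.DataFrame(payload["ranked"]),
            selected_k=int(payload["selected_k"]),
            accuracy_trace=[(int(k), float(a)) for k, a in payload["accuracy_trace"]],
            rf_settings=RFSettings(**payload["rf_settings"]),
            target_outcome=payload["target_outcome"],
        )


def select_k(
    matrix: DeficitMatrix,
    outcome: np.ndarray,
    ranked: pd.DataFrame,
    k_grid: list[int] | None = None,
    settings: RFSettings = RFSettings(),
    target_outcome: str = "all_cause_mortality",
) -> FrailtyIndexModel:
    """Refit on the top-k conditions for each k and pick the OOB-accuracy
    maximizer (smallest k on ties)."""
    settings.validate()
    p = len(matrix.condition_ids)
    if k_grid is None:
        k_grid = list(range(1, p + 1))
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ConfigError("k_grid: must be non-empty")
    if k_grid[0] < 1 or k_grid[-1] > p:
        raise ConfigError("k_grid: values must lie in [1, n_conditions]")
    y = np.asarray(outcome)
    if np.unique(y).size < 2:
        raise DegenerateOutcomeError("select_k: outcome has a single class")

    col = {c: j for j, c in enumerate(matrix.condition_ids)}
    order = [col[c] for c in ranked["condition_id"]]
    X_full = matrix.values.astype(np.float64)[:, order]

    trace: list[tuple[int, float]] = []
    for k in k_grid:
        forest = _fit_forest(X_full[:, :k], y, settings, oob_score=True)
        trace.append((k, float(forest.oob_score_)))
    accs = np.array([a for _, a in trace])
    best = int(np.argmax(accs))          # first index = smallest k on ties
    return FrailtyIndexModel(
        ranked=ranked.reset_index(drop=True),
        selected_k=trace[best][0],
        accuracy_trace=trace,
        rf_settings=settings,
        target_outcome=target_outcome,
    )


def compute_fi(
    matrix: DeficitMatrix, selected_ids: list[str], index_kind: str = "ml_mfi"
) -> pd.DataFrame:
    """Frailty scores: (count of present selected conditions) / k.

    Returns a DataFrame with columns subject_id, value, index_kind.
    """
    if not selected_ids:
        raise ConfigError("selected_ids: must be non-empty")
    missing = [c for c in selected_ids if c not in matrix.condition_ids]
    if missing:
        raise DataError(f"compute_fi: conditions absent from matrix: {missing}")
    col = {c: j for j, c in enumerate(matrix.condition_ids)}
    idx = [col[c] for c in selected_ids]
    counts = matrix.values[:, idx].sum(axis=1)
    return pd.DataFrame(
        {
            "subject_id": matrix.subject_ids,
            "value": counts / len(selected_ids),
            "index_kind": index_kind,
        }
    )


def compute_reference_fi(
    matrix: DeficitMatrix, reference: ConditionCatalog | list[str]
) -> pd.DataFrame:
    """Comparator frailty index over a user-supplied expert condition list."""
    ids = reference.condition_ids if isinstance(reference, ConditionCatalog) else list(reference)
    return compute_fi(matrix, ids, index_kind="reference_mfi")
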