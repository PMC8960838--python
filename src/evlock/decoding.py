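"""Per-TR and windowed decoding of event pairs with cross-validated AUC.

Trials are classified from region activations either at a single TR offset
(one independent classifier per offset, the time-resolved information
profile) or from the full 0-9 TR window (regions x offsets feature matrix).
Evaluation is stratified 5-fold cross-validation reporting mean +- SD of
the test-fold AUC.  Standardization and class balancing (random
undersampling of the training majority) are fitted inside each training
fold only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .prep import TrialTensor

__all__ = [
    "CVConfig",
    "FeatureMatrix",
    "DecodingResult",
    "MODEL_NAMES",
    "build_features",
    "make_model",
    "crossval_auc",
    "per_tr_auc",
]

# lightgbm's sklearn wrapper auto-names ndarray columns at fit time and
# sklearn then warns at predict time; the names carry no information here
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names"
)

C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
GAMMA_GRID = (0.0001, 0.001, 0.01, 0.1, 1.0)


@dataclass
class CVConfig:
    """Cross-validation protocol: 5 stratified folds, the C / gamma grids,
    majority undersampling on training folds, and the tuning mode
    ('nested' = inner grid search inside each training fold, 'none' = grid
    midpoints)."""

    k: int = 5
    c_grid: tuple = C_GRID
    gamma_grid: tuple = GAMMA_GRID
    balance: bool = True
    seed: int = 0
    tune: str = "nested"
    inner_k: int = 3

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 folds")
        if self.tune not in ("nested", "none"):
            raise ValueError("tune must be 'nested' or 'none'")


@dataclass
class FeatureMatrix:
    """Trials x (region, TR-offset) design matrix with binary labels.

    Column order is region-major, offset-minor; ``columns`` keeps the
    bidirectional (region, offset) <-> column mapping.  y = 1 encodes the
    first-named class of the contrast.  Values are raw; standardization
    statistics are computed on training data only at fit time.
    """

    X: np.ndarray
    y: np.ndarray
    columns: list[tuple[str, int]]
    classes: tuple[str, str]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.y), len(self.columns)):
            raise ValueError("X shape must be (n_trials, n_columns)")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def column_of(self, region: str, offset: int) -> int:
        return self.columns.index((region, offset))

    def select(self, column_indices) -> "FeatureMatrix":
        idx = np.asarray(column_indices, dtype=int)
        return FeatureMatrix(
            X=self.X[:, idx],
            y=self.y,
            columns=[self.columns[i] for i in idx],
            classes=self.classes,
        )


@dataclass
class DecodingResult:
    model: str
    fold_aucs: np.ndarray
    params_per_fold: list = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs))


def build_features(
    trials: TrialTensor,
    classes: tuple[str, str],
    tr_offsets=range(0, 10),
) -> FeatureMatrix:
    """Feature matrix over the requested TR offsets (default 0..9).

    With 718 regions and 10 offsets this yields the full 7180-column
    design.
    """
    offsets = list(tr_offsets)
    avail = trials.frame_offsets.tolist()
    bad = [o for o in offsets if o not in avail]
    if bad:
        raise ValueError(f"offsets {bad} not in tensor frame offsets {avail}")
    sub = trials.subset(classes)
    for cls in classes:
        if not sub.mask(cls).any():
            raise ValueError(f"no trials of class {cls!r}")
    cols = [avail.index(o) for o in offsets]
    X = sub.values[:, :, cols].reshape(sub.n_trials, -1)
    columns = [(rid, o) for rid in sub.region_ids for o in offsets]
    y = (sub.labels.astype(str) == classes[0]).astype(int)
    return FeatureMatrix(X=X, y=y, columns=columns, classes=tuple(classes))


# ---------------------------------------------------------------------------
# model registry


def make_model(model_spec, cv: CVConfig):
    """Instantiate a registered model and its hyperparameter grid.

    ``model_spec`` is a name from :data:`MODEL_NAMES` or a dict
    ``{"name": ..., **kwargs}`` (e.g. ``{"name": "mlp", "depth": 3}``).
    """
    if isinstance(model_spec, str):
        name, kw = model_spec, {}
    else:
        spec = dict(model_spec)
        name, kw = spec.pop("name"), spec
    seed = cv.seed
    if name == "logreg":
        est = LogisticRegression(max_iter=2000)
        grid = {"model__C": list(cv.c_grid)}
    elif name == "linear_svm":
        est = LinearSVC(dual="auto")
        grid = {"model__C": list(cv.c_grid)}
    elif name == "rbf_svm":
        est = SVC(kernel="rbf")
        grid = {"model__C": list(cv.c_grid), "model__gamma": list(cv.gamma_grid)}
    elif name == "mlp":
        depth = int(kw.pop("depth", 2))
        if not 1 <= depth <= 3:
            raise ValueError("mlp depth must be 1..3")
        est = MLPClassifier(
            hidden_layer_sizes=(128, 64, 32)[:depth],
            activation="relu",
            early_stopping=True,
            max_iter=400,
            random_state=seed,
            **kw,
        )
        grid = {}
    elif name == "gbdt":
        import lightgbm as lgb

        est = lgb.LGBMClassifier(
            n_estimators=int(kw.pop("n_estimators", 300)),
            random_state=seed,
            verbose=-1,
            **kw,
        )
        grid = {"model__max_depth": [4, 6, 8],
                "model__learning_rate": [0.03, 0.1]}
    else:
        raise ValueError(f"unknown model {name!r}")
    return name, est, grid


MODEL_NAMES = ("logreg", "linear_svm", "rbf_svm", "mlp", "gbdt")


def _undersample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a balanced subset (majority class randomly thinned)."""
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    n = min(len(idx0), len(idx1))
    keep = np.concatenate([
        rng.choice(idx0, size=n, replace=False),
        rng.choice(idx1, size=n, replace=False),
    ])
    return np.sort(keep)


def _scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return est.decision_function(X)
    return est.predict_proba(X)[:, 1]


def crossval_auc(
    features: FeatureMatrix, model_spec, cv: CVConfig | None = None
) -> DecodingResult:
    """Stratified k-fold AUC with in-fold standardization and balancing.

    In nested mode each training fold runs its own inner grid search (AUC
    scoring); the selected parameters are refit on the balanced training
    fold and scored once on the untouched test fold.
    """
    cv = cv or CVConfig()
    name, est, grid = make_model(model_spec, cv)
    skf = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    rng = np.random.default_rng(cv.seed)
    aucs, chosen = [], []
    for train, test in skf.split(features.X, features.y):
        if cv.balance:
            train = train[_undersample(features.y[train], rng)]
        pipe = Pipeline([("scale", StandardScaler()), ("model", est)])
        if cv.tune == "nested" and grid:
            search = GridSearchCV(
                pipe, grid, scoring="roc_auc",
                cv=StratifiedKFold(cv.inner_k, shuffle=True, random_state=cv.seed),
                n_jobs=1,
            )
            search.fit(features.X[train], features.y[train])
            fitted, params = search.best_estimator_, search.best_params_
        else:
            pipe.fit(features.X[train], features.y[train])
            fitted, params = pipe, {}
        y_test = features.y[test]
        if len(np.unique(y_test)) < 2:
            raise RuntimeError("stratified fold lost a class; check inputs")
        aucs.append(roc_auc_score(y_test, _scores(fitted, features.X[test])))
        chosen.append(params)
    return DecodingResult(model=name, fold_aucs=np.asarray(aucs),
                         params_per_fold=chosen)


def per_tr_auc(
    trials: TrialTensor,
    classes: tuple[str, str],
    model_spec="logreg",
    cv: CVConfig | None = None,
    tr_offsets=range(0, 10),
) -> pd.DataFrame:
    """Mean 5-fold AUC of an independent classifier at each TR offset."""
    cv = cv or CVConfig()
    rows = []
    for offset in tr_offsets:
        feats = build_features(trials, classes, tr_offsets=[offset])
        res = crossval_auc(feats, model_spec, cv)
        rows.append({"tr_offset": offset, "mean_auc": res.mean_auc,
                     "sd_auc": res.sd_auc})
    return pd.DataFrame(rows).set_index("tr_offset")
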