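"""Fall-risk classification protocol.

Implements the class-balanced tabular protocol around the gait features:
SMOTE oversampling of the minority class to parity, z-score standardisation
(z = (x − μ)/s, fitted on training data only), a stratified 70:30 split, and
a twelve-model suite with small grid searches, ablations and confusion-matrix
evaluation.  Faller is the positive (high-risk) class.

The central object is :class:`FallRiskClassifier`, a scikit-learn-compatible
estimator (fit/predict/get_params, fitted attributes with a trailing
underscore) that wraps any registered model with its grid search and optional
internal standardisation; the module-level functions are thin wrappers that
operate on labelled feature tables.

Note on protocol fidelity: the source protocol applies SMOTE *before* the
train/test split, so synthetic rows can land in the test set — a
leakage-prone choice reproduced here as the default because it pins the
published counts (65 → 88 → 61/27).  Set ``smote_after_split=True`` in
:class:`ExperimentSpec` for the statistically sound variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
    VotingClassifier,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .exceptions import ParameterError, RegistryError, SchemaError
from .features import AVERAGED_FEATURES, PER_FOOT_FEATURES, detect_schema

LABEL_ORDER = ["non_faller", "faller"]  # confusion-matrix class order


def feature_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Split a labelled feature table into (X, y)."""
    schema = detect_schema(table)
    cols = PER_FOOT_FEATURES if schema == "per_foot" else AVERAGED_FEATURES
    return table[cols].astype(float), table["label"].astype(str)


# ---------------------------------------------------------------------------
# SMOTE


@dataclass
class SmoteParams:
    """k for the nearest-neighbour step and the RNG seed."""

    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ParameterError("k_neighbors must be >= 1")


class SmoteOversampler(BaseEstimator):
    """Synthetic Minority Oversampling to class parity.

    For each synthetic sample: pick a minority feature vector, pick one of
    its ``k_neighbors`` nearest minority neighbours (Euclidean), take the
    difference, multiply it by a uniform random number in (0, 1) and add it
    to the base vector.  Repeats until the classes are balanced.  Original
    rows are preserved bit-exactly; synthetic rows are only appended.
    """

    def __init__(self, k_neighbors: int = 5, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ParameterError(f"need exactly two classes, got {list(classes)}")
        minority = classes[np.argmin(counts)]
        n_minority, n_majority = counts.min(), counts.max()
        n_new = int(n_majority - n_minority)
        if n_new == 0:
            return X.copy(), y.copy()
        if self.k_neighbors >= n_minority:
            raise ParameterError(
                f"k_neighbors={self.k_neighbors} must be < minority class "
                f"size {n_minority}"
            )
        rng = np.random.default_rng(self.random_state)
        Xmin = X[y == minority]
        nn = NearestNeighbors(n_neighbors=self.k_neighbors + 1).fit(Xmin)
        neighbours = nn.kneighbors(Xmin, return_distance=False)[:, 1:]
        new_rows = np.empty((n_new, X.shape[1]))
        for i in range(n_new):
            base = rng.integers(n_minority)
            nb = neighbours[base, rng.integers(self.k_neighbors)]
            u = rng.uniform()
            new_rows[i] = Xmin[base] + u * (Xmin[nb] - Xmin[base])
        X_out = np.vstack([X, new_rows])
        y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
        return X_out, y_out


def smote_oversample(table: pd.DataFrame, params: SmoteParams | None = None) -> pd.DataFrame:
    """Balance a labelled feature table with SMOTE; synthetic rows are
    appended with ``provenance="smote"``."""
    params = params or SmoteParams()
    X, y = feature_matrix(table)
    sampler = SmoteOversampler(k_neighbors=params.k_neighbors,
                               random_state=params.seed)
    X_out, y_out = sampler.fit_resample(X.to_numpy(), y.to_numpy())
    n_new = len(X_out) - len(table)
    if n_new == 0:
        return table.copy().reset_index(drop=True)
    new = pd.DataFrame(X_out[len(table):], columns=X.columns)
    new["label"] = y_out[len(table):]
    if "subject_id" in table.columns:
        new["subject_id"] = [f"smote_{i:03d}" for i in range(n_new)]
    new["provenance"] = "smote"
    out = table.copy()
    if "provenance" not in out.columns:
        out["provenance"] = "primary"
    return pd.concat([out, new], ignore_index=True)


# ---------------------------------------------------------------------------
# Standardisation (z = (x - mu) / s)


@dataclass
class ScalerParams:
    """Per-feature mean and standard deviation fitted on training data."""

    mu: pd.Series
    s: pd.Series


def standard_scale(
    table: pd.DataFrame, fit_params: ScalerParams | None = None
) -> tuple[pd.DataFrame, ScalerParams]:
    """Standardise feature columns: z = (x − μ)/s.

    With ``fit_params`` given, applies the training-fitted μ and s without
    refitting (so test data never contributes statistics).  Raises on
    zero-variance features, naming the column.
    """
    X, _ = feature_matrix(table)
    if fit_params is None:
        mu = X.mean()
        s = X.std(ddof=0)
        zero = s[s == 0]
        if len(zero):
            raise ParameterError(
                f"zero-variance feature column(s): {list(zero.index)}"
            )
        fit_params = ScalerParams(mu=mu, s=s)
    out = table.copy()
    out[X.columns] = (X - fit_params.mu) / fit_params.s
    return out, fit_params


# ---------------------------------------------------------------------------
# Stratified split


def stratified_split(
    table: pd.DataFrame, train_fraction: float = 0.70, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shuffled, class-proportion-preserving train/test split.

    Test size is the ceiling of ``(1 − train_fraction)·n``; per-class test
    counts are the floored proportional quotas with the remainder assigned by
    largest fractional part, ties resolved toward the faller class (so an
    88-row balanced table yields 61 train / 27 test with 13 non-fallers and
    14 fallers in test).  Reproducible under a fixed seed.
    """
    if not 0 < train_fraction < 1:
        raise ParameterError("train_fraction must lie in (0, 1)")
    y = table["label"].astype(str)
    counts = y.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2]
        raise ParameterError(
            f"every class needs >= 2 rows; got {small.to_dict()}"
        )
    n = len(table)
    n_test = math.ceil((1.0 - train_fraction) * n)
    quotas = {c: n_test * counts[c] / n for c in counts.index}
    base = {c: math.floor(q) for c, q in quotas.items()}
    remainder = n_test - sum(base.values())
    # largest fractional part first; faller wins ties, then lexicographic
    order = sorted(counts.index,
                   key=lambda c: (-(quotas[c] - base[c]), c != "faller", c))
    for c in order[:remainder]:
        base[c] += 1

    rng = np.random.default_rng(seed)
    test_idx: list = []
    for c in counts.index:
        members = table.index[y == c].to_numpy()
        rng.shuffle(members)
        test_idx.extend(members[: base[c]])
    test_mask = table.index.isin(test_idx)
    train = table[~test_mask].sample(frac=1.0, random_state=seed).reset_index(drop=True)
    test = table[test_mask].reset_index(drop=True)
    return train, test


# ---------------------------------------------------------------------------
# Model registry


def _make_voting(seed: int) -> VotingClassifier:
    return VotingClassifier(
        estimators=[
            ("dt", DecisionTreeClassifier(random_state=seed)),
            ("knn", KNeighborsClassifier()),
            ("nb", GaussianNB()),
        ],
        voting="hard",
    )


MODEL_REGISTRY: dict[str, callable] = {
    "svm": lambda seed: SVC(random_state=seed),
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "random_forest": lambda seed: RandomForestClassifier(
        n_estimators=100, random_state=seed),
    "lightgbm": None,  # filled below (import style)
    "xgboost": None,
    "gradient_boosting": lambda seed: GradientBoostingClassifier(random_state=seed),
    "adaboost": lambda seed: AdaBoostClassifier(random_state=seed),
    "knn": lambda seed: KNeighborsClassifier(),
    "naive_bayes": lambda seed: GaussianNB(),
    "mlp": lambda seed: MLPClassifier(hidden_layer_sizes=(32,), max_iter=3000,
                                      random_state=seed),
    "bagging": lambda seed: BaggingClassifier(random_state=seed),
    "voting": _make_voting,
}


def _make_lightgbm(seed: int):
    from lightgbm import LGBMClassifier

    return LGBMClassifier(n_estimators=100, min_child_samples=5,
                          random_state=seed, verbose=-1)


def _make_xgboost(seed: int):
    from xgboost import XGBClassifier

    return XGBClassifier(n_estimators=100, max_depth=3, random_state=seed,
                         verbosity=0)


MODEL_REGISTRY["lightgbm"] = _make_lightgbm
MODEL_REGISTRY["xgboost"] = _make_xgboost

#: Small default hyperparameter grids (fully overridable).
DEFAULT_GRIDS: dict[str, dict] = {
    "svm": {"C": [0.1, 1.0, 10.0], "kernel": ["rbf", "linear"]},
    "decision_tree": {"max_depth": [None, 3, 5]},
    "random_forest": {"max_depth": [None, 5]},
    "lightgbm": {"num_leaves": [7, 31]},
    "xgboost": {"max_depth": [3, 6]},
    "gradient_boosting": {"max_depth": [2, 3]},
    "adaboost": {"n_estimators": [50, 100]},
    "knn": {"n_neighbors": [3, 5, 7]},
    "naive_bayes": {},
    "mlp": {"alpha": [1e-4, 1e-2]},
    "bagging": {"n_estimators": [10, 30]},
    "voting": {},
}

MODEL_NAMES = list(MODEL_REGISTRY)


class FallRiskClassifier(BaseEstimator, ClassifierMixin):
    """Grid-searched fall-risk classifier over temporal gait features.

    Parameters
    ----------
    model : str
        Registry name of the underlying model (see ``MODEL_NAMES``).
    param_grid : dict or None
        Hyperparameter grid; None uses the registry default.  An empty dict
        (or grid of size 1) is equivalent to a direct fit.
    cv : int
        Stratified folds for the grid search.
    scale : bool
        Standardise features inside the estimator (fitted on training data).
    random_state : int
        Seed for the model, the CV shuffling, and any stochastic components.

    Fitted attributes: ``model_`` (the refitted best estimator),
    ``best_params_``, ``classes_``, ``feature_names_in_``, ``scaler_``
    (or None), ``feature_importances_`` when the model exposes them.
    """

    def __init__(self, model: str = "lightgbm", param_grid: dict | None = None,
                 cv: int = 5, scale: bool = False, random_state: int = 0):
        self.model = model
        self.param_grid = param_grid
        self.cv = cv
        self.scale = scale
        self.random_state = random_state

    def _encode(self, y) -> np.ndarray:
        y = np.asarray(y)
        bad = set(np.unique(y)) - set(LABEL_ORDER)
        if bad:
            raise SchemaError(f"unknown label values {sorted(bad)}")
        return (y == "faller").astype(int)

    def fit(self, X, y):
        if self.model not in MODEL_REGISTRY:
            raise RegistryError(
                f"unknown model {self.model!r}; registered: {MODEL_NAMES}"
            )
        # keep X as a named DataFrame: several backends record feature names
        # at fit time and warn when predict sees a bare array
        if not isinstance(X, pd.DataFrame):
            X = np.asarray(X, dtype=float)
            X = pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])
        X = X.astype(float)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        y_enc = self._encode(y)
        if self.scale:
            mu = X.mean()
            s = X.std(ddof=0)
            if (s == 0).any():
                bad = list(s.index[s == 0])
                raise ParameterError(f"zero-variance feature column(s): {bad}")
            self.scaler_mu_, self.scaler_s_ = mu, s
            X = (X - mu) / s
        else:
            self.scaler_mu_ = self.scaler_s_ = None

        base = MODEL_REGISTRY[self.model](self.random_state)
        grid = self.param_grid if self.param_grid is not None \
            else DEFAULT_GRIDS.get(self.model, {})
        search = GridSearchCV(
            base, grid, scoring="accuracy",
            cv=StratifiedKFold(self.cv, shuffle=True,
                               random_state=self.random_state),
        )
        search.fit(X, y_enc)
        self.model_ = search.best_estimator_
        self.best_params_ = search.best_params_
        self.best_cv_score_ = search.best_score_
        self.cv_results_ = search.cv_results_
        self.classes_ = np.asarray(LABEL_ORDER, dtype=object)
        if hasattr(self.model_, "feature_importances_"):
            self.feature_importances_ = np.asarray(self.model_.feature_importances_)
        return self

    def _transform(self, X) -> pd.DataFrame:
        names = list(self.feature_names_in_)
        if isinstance(X, pd.DataFrame):
            missing = set(names) - set(X.columns)
            if missing:
                raise SchemaError(f"test table missing feature(s) {sorted(missing)}")
            X = X[names].astype(float)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] != len(names):
                raise SchemaError(
                    f"expected {len(names)} features, got shape {X.shape}"
                )
            X = pd.DataFrame(X, columns=names)
        if self.scaler_mu_ is not None:
            X = (X - self.scaler_mu_) / self.scaler_s_
        return X

    def predict(self, X):
        check_is_fitted(self, "model_")
        pred = np.asarray(self.model_.predict(self._transform(X))).astype(int)
        return self.classes_[pred]

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._transform(X))


# ---------------------------------------------------------------------------
# Protocol drivers


@dataclass
class ModelResult:
    """Evaluation of one fitted model on the test set."""

    model_name: str
    accuracy: float
    confusion_matrix: np.ndarray  # rows true, cols predicted, [non_faller, faller]
    importances: dict[str, float] | None
    best_params: dict

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "accuracy": self.accuracy,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "importances": self.importances,
            "best_params": {k: repr(v) for k, v in self.best_params.items()},
        }


@dataclass
class ExperimentSpec:
    """One experiment: schema, ablations, models and protocol settings."""

    schema: str = "per_foot"
    models: list[str] = field(default_factory=lambda: list(MODEL_NAMES))
    ablations: list[str] = field(
        default_factory=lambda: ["full", "no_smote", "no_scaling", "none"])
    train_fraction: float = 0.70
    seed: int = 0
    k_neighbors: int = 5
    cv: int = 5
    smote_after_split: bool = False
    grids: dict[str, dict] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ParameterError("train_fraction must lie in (0, 1)")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise RegistryError(f"unknown models {sorted(unknown)}")
        bad = set(self.ablations) - {"full", "no_smote", "no_scaling", "none"}
        if bad:
            raise ParameterError(f"unknown ablations {sorted(bad)}")


def fit_model(train: pd.DataFrame, model_name: str, grid: dict | None = None,
              seed: int = 0, cv: int = 5) -> FallRiskClassifier:
    """Grid-search-fit one registered model on a labelled training table."""
    X, y = feature_matrix(train)
    clf = FallRiskClassifier(model=model_name, param_grid=grid, cv=cv,
                             scale=False, random_state=seed)
    return clf.fit(X, y)


def evaluate(model: FallRiskClassifier, test: pd.DataFrame) -> ModelResult:
    """Accuracy, 2×2 confusion matrix and importances on a test table.

    Confusion-matrix rows are true classes and columns predicted classes, in
    the order [non_faller, faller]; accuracy = trace/total.
    """
    if len(test) == 0:
        raise ParameterError("test table is empty")
    X, y = feature_matrix(test)
    pred = model.predict(X)
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(y, pred):
        cm[LABEL_ORDER.index(t), LABEL_ORDER.index(p)] += 1
    accuracy = float(np.trace(cm) / cm.sum())
    importances = None
    if getattr(model, "feature_importances_", None) is not None:
        importances = {
            name: float(v)
            for name, v in zip(model.feature_names_in_, model.feature_importances_)
        }
    return ModelResult(
        model_name=model.model,
        accuracy=accuracy,
        confusion_matrix=cm,
        importances=importances,
        best_params=model.best_params_,
    )


_ABLATION_FLAGS = {
    "full": (True, True),
    "no_smote": (False, True),
    "no_scaling": (True, False),
    "none": (False, False),
}


@dataclass
class ExperimentResult:
    """Accuracy matrix (rows = ablations, cols = models) plus per-run detail."""

    accuracy: pd.DataFrame
    details: dict[tuple[str, str], ModelResult]


def run_experiment(table: pd.DataFrame, spec: ExperimentSpec | None = None) -> ExperimentResult:
    """Run the ablation grid (full / no SMOTE / no scaling / no enhancement)
    for every requested model and collect the accuracy matrix."""
    spec = spec or ExperimentSpec()
    if detect_schema(table) != spec.schema:
        raise SchemaError(
            f"table schema {detect_schema(table)!r} != spec schema {spec.schema!r}"
        )
    grids = spec.grids or {}
    acc = pd.DataFrame(index=spec.ablations, columns=spec.models, dtype=float)
    details: dict[tuple[str, str], ModelResult] = {}
    for ablation in spec.ablations:
        use_smote, use_scaling = _ABLATION_FLAGS[ablation]
        working = table
        if use_smote and not spec.smote_after_split:
            working = smote_oversample(
                working, SmoteParams(spec.k_neighbors, spec.seed))
        train, test = stratified_split(working, spec.train_fraction, spec.seed)
        if use_smote and spec.smote_after_split:
            train = smote_oversample(
                train, SmoteParams(spec.k_neighbors, spec.seed))
        if use_scaling:
            train, scaler = standard_scale(train)
            test, _ = standard_scale(test, scaler)
        for name in spec.models:
            clf = fit_model(train, name, grids.get(name), seed=spec.seed,
                            cv=spec.cv)
            result = evaluate(clf, test)
            acc.loc[ablation, name] = result.accuracy
            details[(ablation, name)] = result
    return ExperimentResult(accuracy=acc, details=details)
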