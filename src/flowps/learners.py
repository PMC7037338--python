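"""Uniform adapter over the seven base classification methods.

Supported methods: ``svm_linear``, ``knn``, ``random_forest``, ``ridge``,
``bernoulli_nb``, ``adaboost``, ``mlp``.  All expose the same three calls:
:func:`fit`, :func:`predict_score` (probability-like score for class 1 in
[0, 1]) and :func:`extract_importance` (non-negative per-feature relevance,
defined for svm_linear / random_forest / ridge / bernoulli_nb / mlp).

``svm_linear`` and ``bernoulli_nb`` sit on fast in-package implementations
because the trimming engine fits them tens of thousands of times on tiny
windows, where scikit-learn's per-call validation dominates the runtime.
Both are exact re-implementations of the corresponding scikit-learn
estimators (`LinearSVC(dual=False)` objective solved to optimality by a
damped Newton iteration; `BernoulliNB`'s smoothed count model) and the test
suite asserts their equivalence on random instances.  The remaining five
methods wrap scikit-learn estimators directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

METHODS = (
    "svm_linear",
    "knn",
    "random_forest",
    "ridge",
    "bernoulli_nb",
    "adaboost",
    "mlp",
)

IMPORTANCE_METHODS = ("svm_linear", "random_forest", "ridge", "bernoulli_nb", "mlp")

_STOCHASTIC = {"random_forest", "adaboost", "mlp"}

_ALLOWED_HYPERPARAMS: dict[str, set[str]] = {
    "svm_linear": {"C", "tol", "max_iter"},
    "knn": {"n_neighbors"},
    "random_forest": {"n_estimators", "criterion", "max_depth", "seed"},
    "ridge": {"alpha"},
    "bernoulli_nb": {"alpha", "binarize", "fit_prior"},
    "adaboost": {"n_estimators", "learning_rate", "seed"},
    "mlp": {"hidden_layer_sizes", "alpha", "max_iter", "seed"},
}

#: Best advanced settings per method, as used for the non-equalized cohorts.
ADVANCED_BEST: dict[str, dict[str, Any]] = {
    "svm_linear": {"C": 1.0},
    "random_forest": {"n_estimators": 30, "criterion": "entropy"},
    "bernoulli_nb": {"alpha": 1.0, "binarize": 0.0, "fit_prior": False},
    "mlp": {"hidden_layer_sizes": 30, "alpha": 0.001},
}


def advanced_grid(method: str) -> list[dict[str, Any]]:
    """The enumerated advanced hyperparameter settings for a method."""
    if method == "random_forest":
        return [
            {"n_estimators": n, "criterion": c}
            for n in (10, 30, 100)
            for c in ("gini", "entropy")
        ]
    if method == "bernoulli_nb":
        return [
            {"alpha": a, "binarize": b, "fit_prior": p}
            for a in (0.0, 1.0)
            for b in (0.0, 1.0)
            for p in (True, False)
        ]
    if method == "mlp":
        return [
            {"hidden_layer_sizes": h, "alpha": a}
            for h in (30, 100)
            for a in (0.01, 0.001, 0.0001)
        ]
    raise ValueError(f"no advanced grid defined for method {method!r}")


class SingleClassError(ValueError):
    """Training labels contain a single class; the caller decides fallback."""


class UnsupportedImportanceError(ValueError):
    """The method has no defined feature-importance formula."""


@dataclass(frozen=True)
class LearnerSpec:
    """Base-method identifier plus hyperparameters and class-balancing flag."""

    method: str
    hyperparams: Mapping[str, Any] = field(default_factory=dict)
    balanced_classes: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )
        unknown = set(self.hyperparams) - _ALLOWED_HYPERPARAMS[self.method]
        if unknown:
            raise ValueError(
                f"unknown hyperparameters for {self.method}: {sorted(unknown)}"
            )
        if self.balanced_classes and self.method not in (
            "svm_linear",
            "random_forest",
        ):
            raise ValueError(
                "balanced_classes is defined for svm_linear and random_forest only"
            )
        if self.method in _STOCHASTIC and "seed" not in self.hyperparams:
            raise ValueError(f"{self.method} requires an explicit 'seed'")
        object.__setattr__(self, "hyperparams", dict(self.hyperparams))

    def get(self, key: str, default: Any = None) -> Any:
        return self.hyperparams.get(key, default)


@dataclass
class FittedModel:
    """Opaque fitted state tied to the feature subspace it was trained in."""

    method: str
    state: Any
    n_features: int
    spec: LearnerSpec


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match X rows")
    classes = np.unique(y)
    if classes.size < 2:
        raise SingleClassError(f"single class in training labels: {classes}")
    if not set(classes.tolist()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return X, y.astype(np.float64)


# ---------------------------------------------------------------------------
# Fast linear SVM (squared hinge, L2, regularized intercept) -- equivalent to
# sklearn.svm.LinearSVC(dual=False) solved to optimality.
# ---------------------------------------------------------------------------

try:  # direct LAPACK Cholesky solve; ~2x less overhead than np.linalg.solve
    from scipy.linalg.lapack import dposv as _dposv
except ImportError:  # pragma: no cover
    _dposv = None


def _spd_solve(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    if _dposv is not None:
        _, x, info = _dposv(H, g, lower=0, overwrite_a=True, overwrite_b=False)
        if info == 0:
            return x
    return np.linalg.solve(H, g)


def _svm_objective(w: np.ndarray, Xa: np.ndarray, ys: np.ndarray,
                   c: np.ndarray) -> float:
    viol = 1.0 - ys * (Xa @ w)
    np.maximum(viol, 0.0, out=viol)
    return 0.5 * float(w @ w) + float(c @ (viol * viol))


def _fit_svm_linear(X: np.ndarray, y: np.ndarray, C: float,
                    balanced: bool, tol: float, max_iter: int,
                    w0: np.ndarray | None = None) -> np.ndarray:
    """Newton solver for min_w 0.5||w||^2 + sum_i c_i max(0, 1 - y_i x_i.w)^2.

    The intercept is an appended all-ones column and is regularized, matching
    liblinear with ``intercept_scaling=1``.  Returns the augmented weight
    vector (coefficients then intercept).  The objective is strictly convex,
    so the optimum — and hence the result — does not depend on the warm
    start ``w0`` beyond float rounding.
    """
    n, d = X.shape
    Xa = np.hstack([X, np.ones((n, 1))])
    ys = 2.0 * y - 1.0
    c = np.full(n, C)
    if balanced:
        n1 = y.sum()
        weights = n / (2.0 * np.array([n - n1, n1]))
        c *= np.where(y > 0.5, weights[1], weights[0])

    w = np.zeros(d + 1) if w0 is None else np.array(w0, dtype=np.float64)
    z = Xa @ w
    viol = np.maximum(1.0 - ys * z, 0.0)
    obj = 0.5 * float(w @ w) + float(c @ (viol * viol))
    for _ in range(max_iter):
        active = viol > 0.0
        Xact = Xa[active]
        cact = c[active]
        grad = w - 2.0 * (Xact.T @ (cact * ys[active] * viol[active]))
        gnorm = float(np.abs(grad).max(initial=0.0))
        if gnorm <= tol * (1.0 + float(np.abs(w).max(initial=0.0))):
            break
        a = Xact.shape[0]
        if a + 8 < d + 1:
            # Woodbury: (I + X'DX)^-1 g = g - X' (D^-1 + XX')^-1 X g
            M = Xact @ Xact.T
            M[np.diag_indices(a)] += 0.5 / cact
            step = grad - Xact.T @ _spd_solve(M, Xact @ grad)
        else:
            H = 2.0 * ((Xact.T * cact) @ Xact)
            H[np.diag_indices(d + 1)] += 1.0
            step = _spd_solve(H, grad)
        z_step = Xa @ step
        # backtracking keeps the piecewise-quadratic Newton iteration monotone
        t = 1.0
        for _ in range(30):
            w_new = w - t * step
            z_new = z - t * z_step
            viol_new = np.maximum(1.0 - ys * z_new, 0.0)
            obj_new = 0.5 * float(w_new @ w_new) + float(c @ (viol_new * viol_new))
            if obj_new <= obj - 1e-12 * t * float(grad @ step):
                break
            t *= 0.5
        if obj_new >= obj - 1e-15 * (1.0 + abs(obj)):
            w, z, viol = w_new, z_new, viol_new
            break
        w, z, viol, obj = w_new, z_new, viol_new, obj_new
    return w


@dataclass
class _SvmState:
    coef: np.ndarray       # (d,)
    intercept: float


@dataclass
class _BnbState:
    feature_count: np.ndarray    # (2, d) per-class binarized counts
    class_count: np.ndarray      # (2,)
    feature_log_prob: np.ndarray
    class_log_prior: np.ndarray
    binarize: float


def _fit_bernoulli_nb(X: np.ndarray, y: np.ndarray, alpha: float,
                      binarize: float, fit_prior: bool) -> _BnbState:
    """Bernoulli naive Bayes with Laplace smoothing, matching BernoulliNB."""
    Xb = (X > binarize).astype(np.float64)
    mask1 = y > 0.5
    feature_count = np.vstack([Xb[~mask1].sum(axis=0), Xb[mask1].sum(axis=0)])
    class_count = np.array([float((~mask1).sum()), float(mask1.sum())])
    a = max(alpha, 1e-10)  # sklearn clips alpha away from exact zero
    smoothed_fc = feature_count + a
    smoothed_cc = class_count + 2.0 * a
    feature_log_prob = np.log(smoothed_fc) - np.log(smoothed_cc)[:, None]
    if fit_prior:
        class_log_prior = np.log(class_count) - np.log(class_count.sum())
    else:
        class_log_prior = np.full(2, -np.log(2.0))
    return _BnbState(feature_count, class_count, feature_log_prob,
                     class_log_prior, binarize)


def _bnb_log_proba(state: _BnbState, X: np.ndarray) -> np.ndarray:
    Xb = (X > state.binarize).astype(np.float64)
    flp = state.feature_log_prob
    neg = np.log1p(-np.exp(flp))
    jll = Xb @ (flp - neg).T + (state.class_log_prior + neg.sum(axis=1))
    m = jll.max(axis=1, keepdims=True)
    logz = m + np.log(np.exp(jll - m).sum(axis=1, keepdims=True))
    return jll - logz


# ---------------------------------------------------------------------------
# scikit-learn backed methods
# ---------------------------------------------------------------------------

def _build_sklearn(spec: LearnerSpec, n_train: int):
    hp = spec.hyperparams
    if spec.method == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        k = int(hp.get("n_neighbors", 5))
        return KNeighborsClassifier(n_neighbors=min(k, n_train))
    if spec.method == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 100)),
            criterion=hp.get("criterion", "gini"),
            max_depth=hp.get("max_depth"),
            class_weight="balanced_subsample" if spec.balanced_classes else None,
            random_state=int(hp["seed"]),
        )
    if spec.method == "ridge":
        from sklearn.linear_model import Ridge

        return Ridge(alpha=float(hp.get("alpha", 1.0)))
    if spec.method == "adaboost":
        from sklearn.ensemble import AdaBoostClassifier

        return AdaBoostClassifier(
            n_estimators=int(hp.get("n_estimators", 50)),
            learning_rate=float(hp.get("learning_rate", 1.0)),
            random_state=int(hp["seed"]),
        )
    if spec.method == "mlp":
        from sklearn.neural_network import MLPClassifier

        return MLPClassifier(
            hidden_layer_sizes=hp.get("hidden_layer_sizes", (100,)),
            alpha=float(hp.get("alpha", 1e-4)),
            max_iter=int(hp.get("max_iter", 200)),
            random_state=int(hp["seed"]),
        )
    raise AssertionError(spec.method)


# ---------------------------------------------------------------------------
# Public adapter surface
# ---------------------------------------------------------------------------

def fit(spec: LearnerSpec, X: np.ndarray, y: np.ndarray,
        seed: int | None = None,
        warm_start: FittedModel | None = None) -> FittedModel:
    """Fit the base method on (X, y).

    ``seed`` overrides the spec's ``seed`` hyperparameter for stochastic
    methods (random_forest, adaboost, mlp); deterministic methods ignore it.
    ``warm_start`` (svm_linear only) seeds the Newton iteration from a
    previously fitted model in the same subspace; the solution is the unique
    optimum either way.  Raises :class:`SingleClassError` when ``y`` holds a
    single class.
    """
    X, y = _check_xy(X, y)
    hp = spec.hyperparams
    if spec.method == "svm_linear":
        w0 = None
        if (
            warm_start is not None
            and warm_start.method == "svm_linear"
            and warm_start.n_features == X.shape[1]
        ):
            w0 = np.append(warm_start.state.coef, warm_start.state.intercept)
        w = _fit_svm_linear(
            X, y,
            C=float(hp.get("C", 1.0)),
            balanced=spec.balanced_classes,
            tol=float(hp.get("tol", 1e-9)),
            max_iter=int(hp.get("max_iter", 200)),
            w0=w0,
        )
        state: Any = _SvmState(coef=w[:-1], intercept=float(w[-1]))
    elif spec.method == "bernoulli_nb":
        state = _fit_bernoulli_nb(
            X, y,
            alpha=float(hp.get("alpha", 1.0)),
            binarize=float(hp.get("binarize", 0.0)),
            fit_prior=bool(hp.get("fit_prior", True)),
        )
    else:
        eff_spec = spec
        if seed is not None and spec.method in _STOCHASTIC:
            eff_spec = LearnerSpec(
                spec.method, {**hp, "seed": int(seed)}, spec.balanced_classes
            )
        est = _build_sklearn(eff_spec, n_train=X.shape[0])
        est.fit(X, y.astype(np.int64) if spec.method != "ridge" else y)
        state = est
    return FittedModel(method=spec.method, state=state,
                       n_features=X.shape[1], spec=spec)


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict_score(model: FittedModel, X: np.ndarray) -> np.ndarray | float:
    """Probability-like score for class 1, always in [0, 1].

    Margin methods (svm_linear, ridge) are squashed through a unit-scale
    logistic, which preserves the native output's ordering; probabilistic
    methods return their class-1 probability.  Accepts a single sample
    (1-D, returns a float) or a matrix (2-D, returns a vector).
    """
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    if model.method == "svm_linear":
        margin = X @ model.state.coef + model.state.intercept
        scores = _logistic(margin)
    elif model.method == "bernoulli_nb":
        scores = np.exp(_bnb_log_proba(model.state, X)[:, 1])
    elif model.method == "ridge":
        scores = _logistic(model.state.predict(X) - 0.5)
    else:
        est = model.state
        proba = est.predict_proba(X)
        col = {c: i for i, c in enumerate(est.classes_)}
        scores = proba[:, col[1]]
    scores = np.clip(scores, 0.0, 1.0)
    return float(scores[0]) if single else scores


def extract_importance(
    model: FittedModel,
    X_train: np.ndarray | None = None,
    ridge_formula: str = "literal",
) -> np.ndarray:
    """Non-negative per-feature importance in the model's fitted subspace.

    svm_linear: |w_f| of the separating hyperplane normal.
    random_forest: impurity-based feature importances.
    ridge: literal sum_t |X_tf| over training samples (``ridge_formula=
    "literal"``) or |coef_f| * sum_t |X_tf| (``"coef_weighted"``); requires
    ``X_train``.
    bernoulli_nb: per-feature binarized counts summed over classes.
    mlp: column sums of |first-layer weights|.

    knn and adaboost raise :class:`UnsupportedImportanceError`.
    """
    if model.method not in IMPORTANCE_METHODS:
        raise UnsupportedImportanceError(
            f"no importance formula for method {model.method!r}"
        )
    if model.method == "svm_linear":
        return np.abs(model.state.coef)
    if model.method == "random_forest":
        return np.asarray(model.state.feature_importances_, dtype=np.float64)
    if model.method == "bernoulli_nb":
        return model.state.feature_count.sum(axis=0)
    if model.method == "mlp":
        return np.abs(model.state.coefs_[0]).sum(axis=1)
    # ridge
    if X_train is None:
        raise ValueError("ridge importance requires X_train")
    magnitude = np.abs(np.asarray(X_train, dtype=np.float64)).sum(axis=0)
    if ridge_formula == "literal":
        return magnitude
    if ridge_formula == "coef_weighted":
        return np.abs(model.state.coef_) * magnitude
    raise ValueError(f"unknown ridge_formula: {ridge_formula!r}")


def supports_importance(method: str) -> bool:
    return method in IMPORTANCE_METHODS
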