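"""Triple leave-one-out trimming engine.

For every held-out sample *i* (outer LOO), every remaining sample *j* is
classified by a base model fitted on a window trimmed around *j* (inner LOO,
pool of N-2), for every trimming pair ``(m, k)`` on a grid.  The resulting
inner ROC AUC surface ``AUC_i(m, k)`` selects the *prediction-accountable
set* ``S_i`` — all cells whose AUC exceeds ``confidence_p`` times the best
cell — and the final score ``P_Fi`` is the mean over ``S_i`` of the query
scores produced by models trimmed around *i* itself on the full N-1 pool.

The no-trimming baseline is the degenerate grid ``{(m=0, k=N-1)}``: one
plain LOO fit per sample.

Cost note: one engine run is ``N * (N-1) * |grid|`` base-model fits, so the
per-query feature mask and distance ordering are computed once per ``(j, m)``
and shared across every ``k`` (window sets are prefixes of one ordering).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .datasets import ExpressionDataset
from .evaluation import roc_auc
from .learners import (
    LearnerSpec,
    _STOCHASTIC,
    extract_importance,
    fit,
    predict_score,
    supports_importance,
)
from .trimming import TrimmingParams, distance_order, relevant_features

logger = logging.getLogger(__name__)

DEFAULT_CONFIDENCE = 0.92  # inside the conventional 0.90-0.95 band


class EngineError(RuntimeError):
    pass


def _quasi_geometric(lo: int, hi: int, n: int) -> list[int]:
    if hi <= lo:
        return [max(hi, lo)] if hi >= 1 or lo == 0 else []
    vals = np.unique(
        np.round(np.geomspace(max(lo, 1), hi, n)).astype(int)
    ).tolist()
    if lo == 0:
        vals = [0] + [v for v in vals if v > 0]
    return vals


@dataclass(frozen=True)
class GridSpec:
    """The (m, k) grid and the accountable-set confidence threshold."""

    m_values: tuple[int, ...]
    k_values: tuple[int, ...]
    confidence_p: float = DEFAULT_CONFIDENCE

    def __post_init__(self) -> None:
        ms = tuple(sorted(int(m) for m in self.m_values))
        ks = tuple(sorted(int(k) for k in self.k_values))
        object.__setattr__(self, "m_values", ms)
        object.__setattr__(self, "k_values", ks)
        if not ms or not ks:
            raise ValueError("m_values and k_values must be non-empty")
        if ms[0] < 0:
            raise ValueError("m values must be >= 0")
        if ks[0] < 1:
            raise ValueError("k values must be >= 1")
        if not 0.0 < self.confidence_p <= 1.0:
            raise ValueError("confidence_p must be in (0, 1]")

    def validate_for_dataset(self, n_samples: int) -> None:
        max_m = (n_samples - 2) // 2
        if self.m_values[-1] > max_m:
            raise ValueError(
                f"max m {self.m_values[-1]} exceeds floor((N-2)/2)={max_m}"
            )
        if self.k_values[-1] > n_samples - 1:
            raise ValueError(
                f"max k {self.k_values[-1]} exceeds N-1={n_samples - 1}"
            )

    @property
    def cells(self) -> list[tuple[int, int]]:
        return [(m, k) for m in self.m_values for k in self.k_values]


def default_grid(
    n_samples: int,
    n_m: int = 4,
    n_k: int = 5,
    k_min: int = 5,
    confidence_p: float = DEFAULT_CONFIDENCE,
) -> GridSpec:
    """Coarse quasi-geometric grid bounded by the dataset size."""
    max_m = (n_samples - 2) // 2
    max_k = n_samples - 2
    m_values = _quasi_geometric(0, max_m, n_m)
    k_values = _quasi_geometric(min(k_min, max_k), max_k, n_k)
    return GridSpec(tuple(m_values), tuple(k_values), confidence_p)


@dataclass
class GridResult:
    """Per-held-out-sample grid surfaces."""

    m_values: tuple[int, ...]
    k_values: tuple[int, ...]
    auc: np.ndarray            # (n_m, n_k) inner-LOO ROC AUC
    query_scores: np.ndarray   # (n_m, n_k) score for the held-out sample
    degenerate: np.ndarray     # (n_m, n_k) any single-class/degenerate window

    def cell_index(self, m: int, k: int) -> tuple[int, int]:
        return self.m_values.index(m), self.k_values.index(k)


@dataclass
class AccountableSet:
    """All grid cells within confidence_p of the best inner AUC."""

    pairs: list[tuple[int, int]]
    max_auc: float

    def __len__(self) -> int:
        return len(self.pairs)


def accountable_set(gr: GridResult, confidence_p: float) -> AccountableSet:
    """Strict-inequality filter ``auc > p * max_auc``; argmax ties always in."""
    if not 0.0 < confidence_p <= 1.0:
        raise ValueError("confidence_p must be in (0, 1]")
    auc = gr.auc
    max_auc = float(np.nanmax(auc))
    pairs: list[tuple[int, int]] = []
    for mi, m in enumerate(gr.m_values):
        for ki, k in enumerate(gr.k_values):
            a = auc[mi, ki]
            if a > confidence_p * max_auc or a == max_auc:
                pairs.append((m, k))
    return AccountableSet(pairs=pairs, max_auc=max_auc)


@dataclass
class FloWPSOutput:
    """Outer-LOO scores plus provenance for a whole dataset run."""

    sample_ids: list[str]
    labels: np.ndarray
    scores: np.ndarray                      # P_Fi per sample
    accountable_sets: list[AccountableSet]
    grid: GridSpec
    spec: LearnerSpec
    run_seed: int
    grid_results: list[GridResult] | None = None
    importance_per_sample: np.ndarray | None = None  # (N, S) embedded
    importance: np.ndarray | None = None             # (S,) dataset mean
    feature_ids: list[str] = field(default_factory=list)

    def loo_auc(self) -> float:
        return roc_auc(self.scores, self.labels)

    # -- text serialization (post-hoc contract checks) ----------------------

    def write_auc_tensor(self, path: str | Path) -> None:
        """Long-format TSV: sample_id, m, k, auc, query_score, degenerate."""
        if self.grid_results is None:
            raise EngineError("grid_results were not retained")
        with open(path, "w") as fh:
            fh.write("sample_id\tm\tk\tauc\tquery_score\tdegenerate\n")
            for sid, gr in zip(self.sample_ids, self.grid_results):
                for mi, m in enumerate(gr.m_values):
                    for ki, k in enumerate(gr.k_values):
                        fh.write(
                            f"{sid}\t{m}\t{k}\t{float(gr.auc[mi, ki])!r}\t"
                            f"{float(gr.query_scores[mi, ki])!r}\t"
                            f"{int(gr.degenerate[mi, ki])}\n"
                        )

    def write_accountable_sets(self, path: str | Path) -> None:
        payload = {
            sid: {"pairs": sorted(s.pairs), "max_auc": s.max_auc}
            for sid, s in zip(self.sample_ids, self.accountable_sets)
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------

def _fit_seed(run_seed: int, i: int, j: int, m: int, k: int,
              method: str) -> int | None:
    if method not in _STOCHASTIC:
        return None
    ss = np.random.SeedSequence([run_seed, i, j, m, k])
    return int(ss.generate_state(1)[0])


def _window_score(
    spec: LearnerSpec,
    X_pool_masked: np.ndarray,
    y_pool: np.ndarray,
    window: np.ndarray,
    x_query_masked: np.ndarray,
    seed: int | None,
    warm_start=None,
) -> tuple[float, bool, object | None]:
    """Fit on one window and score the query.

    Single-class windows short-circuit to the trivial score of the present
    class.  Returns (score, degenerate_flag, fitted_model_or_None).
    """
    y_win = y_pool[window]
    first = y_win[0]
    if np.all(y_win == first):
        return float(first), True, None
    model = fit(spec, X_pool_masked[window], y_win, seed=seed,
                warm_start=warm_start)
    return float(predict_score(model, x_query_masked)), False, model


def _query_contexts(
    X_pool: np.ndarray, x_query: np.ndarray, m_values: Iterable[int]
) -> dict[int, tuple[np.ndarray, np.ndarray, bool]]:
    """Per-m: (effective mask, distance ordering, degenerate flag).

    Both depend only on (query, m); every k reuses a prefix of the ordering.
    An all-false mask falls back to the full feature set, flagged.
    """
    out = {}
    for m in m_values:
        mask = relevant_features(X_pool, x_query, m)
        degenerate = not bool(mask.any())
        if degenerate:
            mask = np.ones(X_pool.shape[1], dtype=bool)
        order = distance_order(X_pool, x_query, mask)
        out[m] = (mask, order, degenerate)
    return out


def inner_scores(
    ds: ExpressionDataset,
    i: int,
    params: TrimmingParams,
    spec: LearnerSpec,
    run_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Inner-LOO scores P_ij for every j != i at a single (m, k).

    For each j the training pool is the dataset minus both i and j (N-2
    samples); the window around j is trimmed with ``params`` and the base
    model scores j.  Returns (scores, degenerate_flags) aligned with the
    pool order (all sample indices except i).
    """
    y = ds.require_labels()
    X = ds.values
    n = ds.n_samples
    pool_i = np.array([t for t in range(n) if t != i], dtype=np.intp)
    params.validate_for_pool(n - 2)

    scores = np.empty(n - 1)
    flags = np.zeros(n - 1, dtype=bool)
    for jj, j in enumerate(pool_i):
        pool_ij = pool_i[pool_i != j]
        Xp, yp, xq = X[pool_ij], y[pool_ij], X[j]
        ctx = _query_contexts(Xp, xq, [params.m])
        mask, order, degenerate = ctx[params.m]
        window = order[: min(params.k, len(pool_ij))]
        seed = _fit_seed(run_seed, i, int(j), params.m, params.k, spec.method)
        score, single, _ = _window_score(
            spec, Xp[:, mask], yp, window, xq[mask], seed
        )
        scores[jj] = score
        flags[jj] = single or degenerate
    return scores, flags


def grid_evaluate(
    ds: ExpressionDataset,
    i: int,
    grid: GridSpec,
    spec: LearnerSpec,
    run_seed: int = 0,
) -> GridResult:
    """Full grid surfaces for held-out sample i (AUC and query scores)."""
    y = ds.require_labels()
    X = ds.values
    n = ds.n_samples
    grid.validate_for_dataset(n)
    pool_i = np.array([t for t in range(n) if t != i], dtype=np.intp)
    y_pool_i = y[pool_i]
    if y_pool_i.min() == y_pool_i.max():
        raise EngineError(
            f"holding out sample {i} leaves a single class; each class needs "
            "at least 2 samples"
        )

    n_m, n_k = len(grid.m_values), len(grid.k_values)
    inner = np.empty((n_m, n_k, n - 1))
    degenerate = np.zeros((n_m, n_k), dtype=bool)

    for jj, j in enumerate(pool_i):
        pool_ij = pool_i[pool_i != j]
        Xp, yp, xq = X[pool_ij], y[pool_ij], X[j]
        ctx = _query_contexts(Xp, xq, grid.m_values)
        for mi, m in enumerate(grid.m_values):
            mask, order, mask_degen = ctx[m]
            Xm = Xp[:, mask]
            xqm = xq[mask]
            # windows are nested in k, so the previous fit warm-starts the
            # next one (exact-optimum solvers: no result dependence)
            prev = None
            for ki, k in enumerate(grid.k_values):
                window = order[: min(k, n - 2)]
                seed = _fit_seed(run_seed, i, int(j), m, k, spec.method)
                score, single, model = _window_score(
                    spec, Xm, yp, window, xqm, seed, warm_start=prev
                )
                if model is not None:
                    prev = model
                inner[mi, ki, jj] = score
                if single or mask_degen:
                    degenerate[mi, ki] = True

    auc = np.empty((n_m, n_k))
    for mi in range(n_m):
        for ki in range(n_k):
            auc[mi, ki] = roc_auc(inner[mi, ki], y_pool_i)

    # final query models for i itself: pool is the whole D_i (N-1 samples)
    query_scores = np.empty((n_m, n_k))
    Xp, yp, xq = X[pool_i], y_pool_i, X[i]
    ctx = _query_contexts(Xp, xq, grid.m_values)
    for mi, m in enumerate(grid.m_values):
        mask, order, mask_degen = ctx[m]
        Xm = Xp[:, mask]
        xqm = xq[mask]
        for ki, k in enumerate(grid.k_values):
            window = order[: min(k, n - 1)]
            seed = _fit_seed(run_seed, i, i, m, k, spec.method)
            score, single, _ = _window_score(spec, Xm, yp, window, xqm, seed)
            query_scores[mi, ki] = score
            if single or mask_degen:
                degenerate[mi, ki] = True

    return GridResult(
        m_values=grid.m_values,
        k_values=grid.k_values,
        auc=auc,
        query_scores=query_scores,
        degenerate=degenerate,
    )


def _sample_importance(
    ds: ExpressionDataset,
    i: int,
    pairs: list[tuple[int, int]],
    spec: LearnerSpec,
    run_seed: int,
    ridge_formula: str,
) -> np.ndarray:
    """Importance for sample i, averaged over its accountable set.

    Each accountable (m, k) refits the query model for i (same derived seed,
    hence the identical model that produced the query score), extracts the
    per-method importance in the trimmed subspace and embeds it into the
    full feature space with zeros outside the mask.
    """
    y = ds.require_labels()
    X = ds.values
    n, s = X.shape
    pool_i = np.array([t for t in range(n) if t != i], dtype=np.intp)
    Xp, yp, xq = X[pool_i], y[pool_i], X[i]
    ctx = _query_contexts(Xp, xq, sorted({m for m, _ in pairs}))
    total = np.zeros(s)
    for m, k in pairs:
        mask, order, _ = ctx[m]
        window = order[: min(k, n - 1)]
        y_win = yp[window]
        if y_win.min() == y_win.max():
            continue  # trivial-score cell: no fitted model, no importance
        seed = _fit_seed(run_seed, i, i, m, k, spec.method)
        Xw = Xp[:, mask][window]
        model = fit(spec, Xw, y_win, seed=seed)
        imp = extract_importance(model, X_train=Xw, ridge_formula=ridge_formula)
        vec = np.zeros(s)
        vec[mask] = imp
        total += vec
    return total / len(pairs)


def flowps_predict_all(
    ds: ExpressionDataset,
    grid: GridSpec,
    spec: LearnerSpec,
    run_seed: int = 0,
    compute_importance: bool | None = None,
    ridge_formula: str = "literal",
    keep_grid_results: bool = True,
) -> FloWPSOutput:
    """Run the full outer-LOO trimming meta-classifier over a dataset."""
    y = ds.require_labels()
    n = ds.n_samples
    if n < 6:
        raise EngineError("need at least 6 samples")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise EngineError("each class needs at least 2 samples")
    if compute_importance is None:
        compute_importance = supports_importance(spec.method)
    if compute_importance and not supports_importance(spec.method):
        raise EngineError(f"method {spec.method!r} has no importance formula")

    scores = np.empty(n)
    sets: list[AccountableSet] = []
    grs: list[GridResult] = []
    imp_matrix = np.zeros((n, ds.n_features)) if compute_importance else None

    for i in range(n):
        gr = grid_evaluate(ds, i, grid, spec, run_seed)
        s_i = accountable_set(gr, grid.confidence_p)
        cells = [gr.cell_index(m, k) for m, k in s_i.pairs]
        scores[i] = float(
            np.mean([gr.query_scores[mi, ki] for mi, ki in cells])
        )
        sets.append(s_i)
        if keep_grid_results:
            grs.append(gr)
        if compute_importance:
            imp_matrix[i] = _sample_importance(
                ds, i, s_i.pairs, spec, run_seed, ridge_formula
            )

    return FloWPSOutput(
        sample_ids=list(ds.sample_ids),
        labels=y.copy(),
        scores=scores,
        accountable_sets=sets,
        grid=grid,
        spec=spec,
        run_seed=run_seed,
        grid_results=grs if keep_grid_results else None,
        importance_per_sample=imp_matrix,
        importance=None if imp_matrix is None else imp_matrix.mean(axis=0),
        feature_ids=list(ds.feature_ids),
    )


def baseline_predict_all(
    ds: ExpressionDataset,
    spec: LearnerSpec,
    run_seed: int = 0,
    compute_importance: bool | None = None,
    ridge_formula: str = "literal",
) -> FloWPSOutput:
    """Plain outer-LOO baseline: the degenerate grid ``{(m=0, k=N-1)}``.

    Skips the inner-LOO grid entirely (there is nothing to select) but uses
    the identical fit path and seed derivation as the trimming engine, so a
    one-cell grid reproduces it bitwise for deterministic learners.
    """
    y = ds.require_labels()
    ds.require_both_classes()
    X = ds.values
    n, s = X.shape
    if n < 3:
        raise EngineError("need at least 3 samples")
    if compute_importance is None:
        compute_importance = supports_importance(spec.method)

    m0, k0 = 0, n - 1
    grid = GridSpec((m0,), (k0,))
    scores = np.empty(n)
    sets: list[AccountableSet] = []
    imp_matrix = np.zeros((n, s)) if compute_importance else None

    all_features = np.ones(s, dtype=bool)
    for i in range(n):
        pool_i = np.array([t for t in range(n) if t != i], dtype=np.intp)
        Xp, yp, xq = X[pool_i], y[pool_i], X[i]
        order = distance_order(Xp, xq, all_features)
        seed = _fit_seed(run_seed, i, i, m0, k0, spec.method)
        score, single, model = _window_score(
            spec, Xp, yp, order[:k0], xq, seed
        )
        scores[i] = score
        sets.append(AccountableSet(pairs=[(m0, k0)], max_auc=float("nan")))
        if compute_importance:
            if model is None:
                raise EngineError("baseline pool is single-class")
            Xw = Xp[order[:k0]]
            imp_matrix[i] = extract_importance(
                model, X_train=Xw, ridge_formula=ridge_formula
            )

    return FloWPSOutput(
        sample_ids=list(ds.sample_ids),
        labels=y.copy(),
        scores=scores,
        accountable_sets=sets,
        grid=grid,
        spec=spec,
        run_seed=run_seed,
        grid_results=None,
        importance_per_sample=imp_matrix,
        importance=None if imp_matrix is None else imp_matrix.mean(axis=0),
        feature_ids=list(ds.feature_ids),
    )
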