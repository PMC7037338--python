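"""Classifier metrics, cost-balanced thresholding and experiment orchestration.

The decision threshold tau minimizes the penalty ``B * FP + FN`` over the
midpoints of consecutive distinct scores (plus -inf/+inf sentinels), where
the *relative balance factor* ``B`` prices a false positive against a false
negative; samples are called positive when ``score >= tau``.

``run_experiment`` drives the whole pipeline for a configured collection of
datasets and methods: marker selection, baseline and trimmed runs, AUC/SN/SP
per balance factor, the paired t-test of with- vs without-trimming AUCs, and
pairwise Pearson/Spearman correlations of the methods' dataset-level feature
importance profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_BALANCE_FACTORS = (0.1, 0.25, 1.0, 4.0, 10.0)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Scalar metrics
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC in the Mann-Whitney formulation; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise EvaluationError("scores and labels must be equal-length vectors")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise EvaluationError("both classes required for ROC AUC")
    ranks = stats.rankdata(scores)
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _confusion(scores: np.ndarray, labels: np.ndarray,
               tau: float) -> tuple[int, int, int, int]:
    calls = scores >= tau
    pos = labels == 1
    tp = int(np.sum(calls & pos))
    fp = int(np.sum(calls & ~pos))
    fn = int(np.sum(~calls & pos))
    tn = int(np.sum(~calls & ~pos))
    return tp, fp, fn, tn


def choose_threshold(scores: np.ndarray, labels: np.ndarray, B: float) -> float:
    """Threshold minimizing ``B * FP + FN``; penalty ties favor the smallest
    tau (higher sensitivity).  Positive call rule: ``score >= tau``."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if not (np.any(labels == 0) and np.any(labels == 1)):
        raise EvaluationError("both classes required to choose a threshold")
    if B <= 0:
        raise EvaluationError("B must be positive")
    distinct = np.unique(scores)
    candidates = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    best_tau = candidates[0]
    best_penalty = np.inf
    for tau in candidates:
        _, fp, fn, _ = _confusion(scores, labels, tau)
        penalty = B * fp + fn
        if penalty < best_penalty - 1e-12:
            best_penalty = penalty
            best_tau = tau
    return float(best_tau)


def sensitivity_specificity(
    scores: np.ndarray, labels: np.ndarray, tau: float
) -> tuple[float, float]:
    """(SN, SP) = (TP/(TP+FN), TN/(TN+FP)) under the ``score >= tau`` rule."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if not (np.any(labels == 0) and np.any(labels == 1)):
        raise EvaluationError("both classes required")
    tp, fp, fn, tn = _confusion(scores, labels, tau)
    return tp / (tp + fn), tn / (tn + fp)


@dataclass
class TTestResult:
    t: float
    p_value: float
    n: int
    mean_difference: float
    degenerate: bool = False  # all differences identical (zero variance)


def paired_ttest(auc_with: Sequence[float],
                 auc_without: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test on AUC differences (df = n - 1)."""
    a = np.asarray(auc_with, dtype=np.float64)
    b = np.asarray(auc_without, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise EvaluationError("need two equal-length vectors with n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return TTestResult(
            t=float("nan"), p_value=float("nan"), n=len(a),
            mean_difference=float(diff.mean()), degenerate=True,
        )
    t, p = stats.ttest_rel(a, b)
    return TTestResult(t=float(t), p_value=float(p), n=len(a),
                       mean_difference=float(diff.mean()))


# ---------------------------------------------------------------------------
# Importance correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Pairwise Pearson/Spearman correlations of importance profiles."""

    methods: list[str]
    pearson: np.ndarray
    spearman: np.ndarray
    defined: np.ndarray  # False where a constant vector makes r undefined

    def pair(self, a: str, b: str) -> tuple[float, float]:
        i, j = self.methods.index(a), self.methods.index(b)
        return float(self.pearson[i, j]), float(self.spearman[i, j])

    def to_frame(self, which: str = "pearson") -> pd.DataFrame:
        mat = self.pearson if which == "pearson" else self.spearman
        return pd.DataFrame(mat, index=self.methods, columns=self.methods)


def importance_correlations(
    profiles: Mapping[str, np.ndarray]
) -> CorrelationMatrix:
    """Pearson on raw importance values, Spearman on average ranks.

    All profiles must live on the identical feature set (equal length,
    >= 3 features).  A constant profile yields undefined correlations with
    everything else: flagged in ``defined`` and set to 0, never NaN.
    """
    methods = list(profiles)
    if len(methods) < 2:
        raise EvaluationError("need at least two importance profiles")
    vecs = [np.asarray(profiles[m], dtype=np.float64) for m in methods]
    length = len(vecs[0])
    if length < 3:
        raise EvaluationError("need at least 3 features")
    if any(v.ndim != 1 or len(v) != length for v in vecs):
        raise EvaluationError("importance profiles differ in feature set size")

    n = len(methods)
    pearson = np.eye(n)
    spearman = np.eye(n)
    defined = np.ones((n, n), dtype=bool)
    constant = [bool(np.all(v == v[0])) for v in vecs]
    ranks = [stats.rankdata(v) for v in vecs]
    for i in range(n):
        for j in range(i + 1, n):
            if constant[i] or constant[j]:
                defined[i, j] = defined[j, i] = False
                pearson[i, j] = pearson[j, i] = 0.0
                spearman[i, j] = spearman[j, i] = 0.0
                continue
            r = float(np.corrcoef(vecs[i], vecs[j])[0, 1])
            rho = float(np.corrcoef(ranks[i], ranks[j])[0, 1])
            pearson[i, j] = pearson[j, i] = r
            spearman[i, j] = spearman[j, i] = rho
    return CorrelationMatrix(methods=methods, pearson=pearson,
                             spearman=spearman, defined=defined)


# ---------------------------------------------------------------------------
# Experiment orchestration
# ---------------------------------------------------------------------------

@dataclass
class MethodComparison:
    """With- vs without-trimming comparison for one method across datasets."""

    method: str
    dataset_names: list[str]
    auc_with: np.ndarray
    auc_without: np.ndarray
    ttest: TTestResult
    sn_sp_with: dict[float, tuple[float, float]]     # median over datasets, per B
    sn_sp_without: dict[float, tuple[float, float]]

    @property
    def median_auc_with(self) -> float:
        return float(np.median(self.auc_with))

    @property
    def median_auc_without(self) -> float:
        return float(np.median(self.auc_without))


@dataclass
class ExperimentResult:
    comparisons: dict[str, MethodComparison]
    correlations_with: CorrelationMatrix | None
    correlations_without: CorrelationMatrix | None
    per_dataset: pd.DataFrame
    per_sample: pd.DataFrame

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for method, comp in self.comparisons.items():
            row: dict[str, Any] = {
                "method": method,
                "median_auc_without": comp.median_auc_without,
                "median_auc_with": comp.median_auc_with,
                "paired_t": comp.ttest.t,
                "paired_p": comp.ttest.p_value,
            }
            for B, (sn, sp) in comp.sn_sp_with.items():
                row[f"median_sn_with_B_{B:g}"] = sn
                row[f"median_sp_with_B_{B:g}"] = sp
            rows.append(row)
        return pd.DataFrame(rows)


def _dataset_from_entry(entry: Mapping[str, Any], seed: int):
    from .datasets import (
        SyntheticConfig,
        attach_labels,
        generate_synthetic,
        read_expression_table,
    )

    if "synthetic" in entry:
        params = dict(entry["synthetic"])
        params.setdefault("seed", seed)
        return generate_synthetic(SyntheticConfig(**params))
    if "expression" in entry:
        ds = read_expression_table(
            entry["expression"],
            orientation=entry.get("orientation", "samples_in_rows"),
            impute=entry.get("impute", "reject"),
        )
        return attach_labels(ds, entry["labels"])
    raise EvaluationError(
        "dataset entry needs either a 'synthetic' spec or 'expression'+'labels'"
    )


def equalize_classes(ds, seed: int = 0):
    """Subsample the majority class (without replacement, seeded) so both
    classes have equal size; returns the dataset unchanged if already equal."""
    import numpy as np

    y = ds.require_labels()
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == n1:
        return ds
    rng = np.random.default_rng(seed)
    minority, majority = (1, 0) if n1 < n0 else (0, 1)
    keep_major = rng.choice(
        np.flatnonzero(y == majority), size=min(n0, n1), replace=False
    )
    idx = np.sort(np.concatenate([np.flatnonzero(y == minority), keep_major]))
    return ds.subset_samples(idx)


def _spec_from_entry(entry: Mapping[str, Any], seed: int):
    from .learners import ADVANCED_BEST, _STOCHASTIC, LearnerSpec

    method = entry["method"]
    if entry.get("preset") == "advanced":
        hp = dict(ADVANCED_BEST.get(method, {}))
    else:
        hp = dict(entry.get("hyperparams", {}))
    if method in _STOCHASTIC:
        hp.setdefault("seed", seed)
    return LearnerSpec(
        method=method,
        hyperparams=hp,
        balanced_classes=bool(entry.get("balanced_classes", False)),
    )


def run_experiment(
    config: Mapping[str, Any], out_dir: str | Path | None = None
) -> ExperimentResult:
    """Run baseline and trimmed classifiers for every dataset x method.

    ``config`` keys: ``seed`` (int), ``datasets`` (list of entries with a
    ``name`` and either a ``synthetic`` mapping or ``expression``/``labels``
    paths), ``methods`` (list of ``{method, preset|hyperparams,
    balanced_classes}``), optional ``grid`` (``m_values``/``k_values``/
    ``confidence_p``), ``balance`` (``B`` list), ``markers`` (``top_n``/
    ``stability_fraction``; omit to skip marker pre-selection) and
    ``equalize_classes`` (bool, default off: seeded subsampling of the
    majority class down to equal class sizes before analysis).
    """
    from . import engine as eng
    from .learners import supports_importance
    from .markers import select_core_markers

    seed = int(config.get("seed", 0))
    b_values = tuple(config.get("balance", {}).get("B", DEFAULT_BALANCE_FACTORS))
    marker_cfg = config.get("markers")

    dataset_rows = []
    sample_rows = []
    auc_with: dict[str, dict[str, float]] = {}
    auc_without: dict[str, dict[str, float]] = {}
    snsp_with: dict[str, dict[float, list]] = {}
    snsp_without: dict[str, dict[float, list]] = {}
    importance_with: dict[str, list[np.ndarray]] = {}
    importance_without: dict[str, list[np.ndarray]] = {}

    methods = [dict(m) for m in config["methods"]]
    for d_index, entry in enumerate(config["datasets"]):
        name = entry.get("name", f"dataset{d_index}")
        ds = _dataset_from_entry(entry, seed + d_index)
        if config.get("equalize_classes", False):
            ds = equalize_classes(ds, seed=seed + d_index)
        if marker_cfg:
            report = select_core_markers(
                ds,
                top_n=int(marker_cfg.get("top_n", 20)),
                stability_fraction=float(
                    marker_cfg.get("stability_fraction", 1.0)
                ),
            )
            ds = ds.subset_features(report.core_set)

        grid_cfg = config.get("grid")
        if grid_cfg:
            grid = eng.GridSpec(
                tuple(grid_cfg["m_values"]),
                tuple(grid_cfg["k_values"]),
                float(grid_cfg.get("confidence_p", eng.DEFAULT_CONFIDENCE)),
            )
        else:
            grid = eng.default_grid(ds.n_samples)

        for m_entry in methods:
            spec = _spec_from_entry(m_entry, seed)
            method = spec.method
            with_imp = supports_importance(method)
            out_f = eng.flowps_predict_all(
                ds, grid, spec, run_seed=seed,
                compute_importance=with_imp, keep_grid_results=False,
            )
            out_b = eng.baseline_predict_all(
                ds, spec, run_seed=seed, compute_importance=with_imp
            )
            row = {"dataset": name, "method": method,
                   "auc_with": out_f.loo_auc(), "auc_without": out_b.loo_auc()}
            auc_with.setdefault(method, {})[name] = row["auc_with"]
            auc_without.setdefault(method, {})[name] = row["auc_without"]
            for out, store, tag in (
                (out_f, snsp_with, "with"),
                (out_b, snsp_without, "without"),
            ):
                for B in b_values:
                    tau = choose_threshold(out.scores, out.labels, B)
                    sn, sp = sensitivity_specificity(out.scores, out.labels, tau)
                    store.setdefault(method, {}).setdefault(B, []).append(
                        (sn, sp)
                    )
                    row[f"sn_{tag}_B_{B:g}"] = sn
                    row[f"sp_{tag}_B_{B:g}"] = sp
            dataset_rows.append(row)
            if with_imp:
                importance_with.setdefault(method, []).append(out_f.importance)
                importance_without.setdefault(method, []).append(
                    out_b.importance
                )
            for sid, label, s_f, s_b in zip(
                ds.sample_ids, ds.labels, out_f.scores, out_b.scores
            ):
                sample_rows.append(
                    {"dataset": name, "method": method, "sample_id": sid,
                     "label": int(label), "score_with": s_f,
                     "score_without": s_b}
                )

    comparisons = {}
    for method in auc_with:
        names = list(auc_with[method])
        a = np.array([auc_with[method][n] for n in names])
        b = np.array([auc_without[method][n] for n in names])
        ttest = (
            paired_ttest(a, b)
            if len(names) >= 2
            else TTestResult(float("nan"), float("nan"), len(names),
                             float(np.mean(a - b)), degenerate=True)
        )
        comparisons[method] = MethodComparison(
            method=method,
            dataset_names=names,
            auc_with=a,
            auc_without=b,
            ttest=ttest,
            sn_sp_with={
                B: tuple(np.median(np.array(v), axis=0))
                for B, v in snsp_with.get(method, {}).items()
            },
            sn_sp_without={
                B: tuple(np.median(np.array(v), axis=0))
                for B, v in snsp_without.get(method, {}).items()
            },
        )

    corr_with = corr_without = None
    if len(importance_with) >= 2:
        # dataset-level profiles require a shared feature set: only defined
        # when every dataset run used the same features (e.g. one dataset,
        # or synthetic replicates of identical shape); correlate per dataset
        # then take the median, mirroring per-cohort correlation analyses
        n_datasets = min(len(v) for v in importance_with.values())
        per_ds_p_with, per_ds_p_wo = [], []
        methods_i = sorted(importance_with)
        for di in range(n_datasets):
            cw = importance_correlations(
                {m: importance_with[m][di] for m in methods_i}
            )
            cwo = importance_correlations(
                {m: importance_without[m][di] for m in methods_i}
            )
            per_ds_p_with.append((cw.pearson, cw.spearman))
            per_ds_p_wo.append((cwo.pearson, cwo.spearman))
        corr_with = CorrelationMatrix(
            methods=methods_i,
            pearson=np.median([p for p, _ in per_ds_p_with], axis=0),
            spearman=np.median([s for _, s in per_ds_p_with], axis=0),
            defined=np.ones((len(methods_i),) * 2, dtype=bool),
        )
        corr_without = CorrelationMatrix(
            methods=methods_i,
            pearson=np.median([p for p, _ in per_ds_p_wo], axis=0),
            spearman=np.median([s for _, s in per_ds_p_wo], axis=0),
            defined=np.ones((len(methods_i),) * 2, dtype=bool),
        )

    result = ExperimentResult(
        comparisons=comparisons,
        correlations_with=corr_with,
        correlations_without=corr_without,
        per_dataset=pd.DataFrame(dataset_rows),
        per_sample=pd.DataFrame(sample_rows),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.summary_frame().to_csv(
            out_dir / "summary.tsv", sep="\t", index=False
        )
        result.per_dataset.to_csv(
            out_dir / "per_dataset.tsv", sep="\t", index=False
        )
        result.per_sample.to_csv(
            out_dir / "per_sample.tsv", sep="\t", index=False
        )
        if corr_with is not None:
            corr_with.to_frame("pearson").to_csv(
                out_dir / "importance_pearson_with.tsv", sep="\t"
            )
            corr_without.to_frame("pearson").to_csv(
                out_dir / "importance_pearson_without.tsv", sep="\t"
            )
            corr_with.to_frame("spearman").to_csv(
                out_dir / "importance_spearman_with.tsv", sep="\t"
            )
            corr_without.to_frame("spearman").to_csv(
                out_dir / "importance_spearman_without.tsv", sep="\t"
            )
    return result
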