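"""Per-query data trimming: relevant-feature masks and nearest-neighbour windows.

A feature is *relevant* for a query if at least ``m`` training projections lie
strictly above the query value on that feature's axis and at least ``m``
strictly below; values exactly equal to the query support neither side.
``m = 0`` keeps every feature.  Within the relevant-feature subspace the
*floating window* keeps the ``k`` training samples closest to the query in
Euclidean distance, ties broken by ascending training-pool index so the whole
pipeline is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateMaskError(ValueError):
    """All-false relevant-feature mask; the caller should fall back."""


@dataclass(frozen=True)
class TrimmingParams:
    """Trimming parameter pair ``(m, k)``."""

    m: int
    k: int

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("m must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def validate_for_pool(self, n_pool: int) -> None:
        if self.m > n_pool // 2:
            raise ValueError(
                f"m={self.m} too large for a training pool of {n_pool} "
                f"(max {n_pool // 2})"
            )
        if self.k > n_pool:
            raise ValueError(f"k={self.k} exceeds pool size {n_pool}")


@dataclass
class TrimmedContext:
    """The trimmed view used to fit one base model for one query."""

    feature_mask: np.ndarray      # bool per feature
    neighbor_indices: np.ndarray  # k training-pool indices, distance order
    query_index: int | str | None = None
    degenerate_mask: bool = False  # mask was all-false; full set substituted


def relevant_features(
    train_values: np.ndarray, query_values: np.ndarray, m: int
) -> np.ndarray:
    """Boolean mask of features on which the query needs no extrapolation.

    ``mask[s]`` is true iff the training column ``s`` has >= m values strictly
    above ``query_values[s]`` and >= m strictly below.  ``m = 0`` keeps all
    features.  An all-false mask is returned as-is; callers decide fallback.
    """
    train_values = np.asarray(train_values, dtype=np.float64)
    query_values = np.asarray(query_values, dtype=np.float64)
    if m < 0:
        raise ValueError("m must be >= 0")
    n_features = train_values.shape[1]
    if m == 0:
        return np.ones(n_features, dtype=bool)
    above = (train_values > query_values).sum(axis=0)
    below = (train_values < query_values).sum(axis=0)
    return (above >= m) & (below >= m)


def distance_order(
    train_values: np.ndarray, query_values: np.ndarray,
    feature_mask: np.ndarray | None = None,
) -> np.ndarray:
    """All training-pool indices sorted by Euclidean distance to the query.

    Distances are computed in the masked subspace (all features when the mask
    is ``None``), ties broken by ascending pool index.  Prefixes of the
    returned ordering are exactly the k-nearest-neighbour sets, so one call
    serves every ``k``.
    """
    train_values = np.asarray(train_values, dtype=np.float64)
    query_values = np.asarray(query_values, dtype=np.float64)
    if feature_mask is not None:
        feature_mask = np.asarray(feature_mask, dtype=bool)
        if not feature_mask.any():
            raise DegenerateMaskError(
                "all-false feature mask: no subspace to measure distances in"
            )
        train_values = train_values[:, feature_mask]
        query_values = query_values[feature_mask]
    diff = train_values - query_values
    d2 = np.einsum("ij,ij->i", diff, diff)
    return np.argsort(d2, kind="stable")


def nearest_neighbors(
    train_values_masked: np.ndarray, query_values_masked: np.ndarray, k: int
) -> np.ndarray:
    """Indices of the ``k`` nearest training rows in the masked subspace."""
    train_values_masked = np.asarray(train_values_masked, dtype=np.float64)
    if train_values_masked.ndim != 2 or train_values_masked.shape[1] == 0:
        raise DegenerateMaskError("masked training matrix has no features")
    if not 1 <= k <= train_values_masked.shape[0]:
        raise ValueError(
            f"k={k} outside [1, {train_values_masked.shape[0]}]"
        )
    return distance_order(train_values_masked, query_values_masked)[:k]


def trim(
    train_values: np.ndarray,
    query_values: np.ndarray,
    params: TrimmingParams,
    query_index: int | str | None = None,
) -> TrimmedContext:
    """Compose relevant-feature selection and neighbour windowing.

    With ``m = 0`` and ``k`` equal to the pool size the context is the
    identity (all features, all samples).  An all-false mask falls back to
    the full feature set for the distance computation and the fit, with the
    ``degenerate_mask`` flag raised.
    """
    train_values = np.asarray(train_values, dtype=np.float64)
    n_pool = train_values.shape[0]
    params.validate_for_pool(n_pool)

    mask = relevant_features(train_values, query_values, params.m)
    degenerate = not bool(mask.any())
    effective = np.ones_like(mask) if degenerate else mask
    order = distance_order(train_values, query_values, effective)
    return TrimmedContext(
        feature_mask=mask if not degenerate else effective,
        neighbor_indices=order[: params.k],
        query_index=query_index,
        degenerate_mask=degenerate,
    )
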