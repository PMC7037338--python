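"""Expression-matrix data model, delimited-text I/O and synthetic benchmarks.

The central container is :class:`ExpressionDataset`: a dense ``samples x
features`` matrix of (already preprocessed, typically log-scale) expression
values together with sample identifiers, feature identifiers and an optional
binary response label per sample (1 = responder, 0 = non-responder).

The synthetic generator emulates the geometry of small clinical cohorts:
a handful of informative genes buried in noise genes, 40-250 samples,
responder fractions between roughly 0.2 and 0.7.  Two geometries are
available: ``global`` (class-shifted Gaussians, linearly separable at large
effect size) and ``local`` (a two-axis checkerboard with zero marginal class
signal per feature, separable only inside local windows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INFORMATIVE_PREFIX = "inf_"
NOISE_PREFIX = "noise_"

Orientation = Literal["samples_in_rows", "samples_in_columns"]


class DatasetError(ValueError):
    """Raised for malformed expression tables or label files."""


@dataclass
class ExpressionDataset:
    """Samples x features expression matrix with optional binary labels.

    Parameters
    ----------
    values
        Dense float matrix, one row per sample, one column per feature.
    sample_ids, feature_ids
        Unique identifier strings, in matrix order.
    labels
        Optional ``{0, 1}`` integer vector aligned with ``sample_ids``
        (1 = responder).  ``None`` until labels are attached.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DatasetError("values must be a 2-D matrix")
        n, s = self.values.shape
        self.sample_ids = [str(x) for x in self.sample_ids]
        self.feature_ids = [str(x) for x in self.feature_ids]
        if len(self.sample_ids) != n:
            raise DatasetError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.feature_ids) != s:
            raise DatasetError(
                f"{len(self.feature_ids)} feature ids for {s} matrix columns"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if np.isnan(self.values).any():
            raise DatasetError("values contain missing entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (n,):
                raise DatasetError("labels length does not match sample count")
            bad = set(np.unique(self.labels)) - {0, 1}
            if bad:
                raise DatasetError(f"labels outside {{0,1}}: {sorted(bad)}")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def require_labels(self) -> np.ndarray:
        if self.labels is None:
            raise DatasetError("dataset has no labels attached")
        return self.labels

    def require_both_classes(self) -> None:
        y = self.require_labels()
        if y.min() == y.max():
            raise DatasetError("labels must contain both classes")

    # -- views ---------------------------------------------------------------

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionDataset":
        """Restrict to the given features, preserving the given order."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise DatasetError(f"unknown features: {missing[:5]}")
        cols = [index[f] for f in feature_ids]
        return ExpressionDataset(
            values=self.values[:, cols],
            sample_ids=list(self.sample_ids),
            feature_ids=list(feature_ids),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(indices, dtype=np.intp)
        return ExpressionDataset(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            labels=None if self.labels is None else self.labels[idx],
        )

    def with_labels(self, labels: np.ndarray) -> "ExpressionDataset":
        return replace(self, labels=np.asarray(labels))


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DatasetError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    if path.suffix.lower() in {".csv"}:
        return ","
    if path.suffix.lower() in {".tsv", ".tab", ".txt"}:
        return "\t"
    head = path.read_text().splitlines()[0] if path.exists() else ""
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_expression_table(
    path: str | Path,
    orientation: Orientation = "samples_in_rows",
    impute: Literal["reject", "median"] = "reject",
    sep: str | None = None,
) -> ExpressionDataset:
    """Read a delimited expression table into an (unlabelled) dataset.

    The on-disk convention is one header line of identifiers and a leading
    identifier column; ``orientation`` states whether rows are samples
    (default) or features.  Missing values are rejected unless per-feature
    median imputation is explicitly requested.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    sep = sep or _sniff_sep(path)
    with open(path) as fh:
        header_ids = fh.readline().rstrip("\n").split(sep)[1:]
    _check_unique([str(x) for x in header_ids], "header")
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    frame.columns = header_ids  # undo pandas' duplicate-name mangling
    if orientation == "samples_in_columns":
        frame = frame.T
    elif orientation != "samples_in_rows":
        raise DatasetError(f"unknown orientation: {orientation!r}")

    sample_ids = [str(x) for x in frame.index]
    feature_ids = [str(x) for x in frame.columns]
    _check_unique(sample_ids, "sample")
    _check_unique(feature_ids, "feature")

    raw = frame.to_numpy()
    values = np.empty(raw.shape, dtype=np.float64)
    na_tokens = {"", "na", "nan", "null", "none"}
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            text = "" if cell is None else str(cell).strip()
            if text.lower() in na_tokens:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(text)
            except ValueError:
                raise DatasetError(
                    f"non-numeric cell {text!r} at sample {sample_ids[i]!r}, "
                    f"feature {feature_ids[j]!r}"
                ) from None

    nan_mask = np.isnan(values)
    if nan_mask.any():
        if impute == "reject":
            i, j = map(int, np.argwhere(nan_mask)[0])
            raise DatasetError(
                f"missing value at sample {sample_ids[i]!r}, feature "
                f"{feature_ids[j]!r} (use impute='median' to allow)"
            )
        if impute != "median":
            raise DatasetError(f"unknown impute policy: {impute!r}")
        medians = np.nanmedian(values, axis=0)
        if np.isnan(medians).any():
            j = int(np.argwhere(np.isnan(medians))[0])
            raise DatasetError(f"feature {feature_ids[j]!r} is entirely missing")
        values[nan_mask] = np.broadcast_to(medians, values.shape)[nan_mask]

    return ExpressionDataset(values=values, sample_ids=sample_ids,
                             feature_ids=feature_ids)


def write_expression_table(
    ds: ExpressionDataset, path: str | Path, sep: str = "\t"
) -> None:
    """Write the matrix as delimited text (samples in rows), full precision."""
    frame = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.feature_ids)
    # repr-precision floats round-trip exactly through read_expression_table
    frame.to_csv(Path(path), sep=sep, float_format=None)


def read_labels(
    path: str | Path,
    sep: str | None = None,
    label_map: Mapping[str, int] | None = None,
) -> dict[str, int]:
    """Read a two-column (sample id, label) file into a mapping.

    Labels must be 0/1 unless ``label_map`` supplies an explicit two-entry
    text-to-{0,1} mapping (e.g. ``{"responder": 1, "non-responder": 0}``);
    textual labels are never guessed.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    if label_map is not None:
        if sorted(label_map.values()) != [0, 1]:
            raise DatasetError(
                "label_map must map exactly two labels onto 0 and 1"
            )
        label_map = {str(k).strip(): int(v) for k, v in label_map.items()}
    sep = sep or _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise DatasetError("label file must have two columns (sample, label)")
    # tolerate an optional header line (second field not a recognized label)
    first = str(frame.iloc[0, 1]).strip()
    if label_map is None:
        try:
            int(first)
        except ValueError:
            frame = frame.iloc[1:]
    elif first not in label_map:
        frame = frame.iloc[1:]
    mapping: dict[str, int] = {}
    for _, row in frame.iterrows():
        sid = str(row.iloc[0]).strip()
        raw = str(row.iloc[1]).strip()
        if label_map is not None:
            if raw not in label_map:
                raise DatasetError(
                    f"label for sample {sid!r} not in label_map: {raw!r}"
                )
            value = label_map[raw]
        elif raw in {"0", "1"}:
            value = int(raw)
        else:
            raise DatasetError(
                f"label for sample {sid!r} outside {{0,1}}: {raw!r}"
            )
        if sid in mapping:
            raise DatasetError(f"duplicate sample {sid!r} in label file")
        mapping[sid] = value
    return mapping


def attach_labels(
    ds: ExpressionDataset,
    label_path: str | Path,
    sep: str | None = None,
    label_map: Mapping[str, int] | None = None,
) -> ExpressionDataset:
    """Attach labels from a two-column file, aligned to dataset sample order.

    Samples present in the label file but absent from the dataset are ignored
    with a warning; dataset samples missing from the file are an error.
    """
    mapping = read_labels(label_path, sep=sep, label_map=label_map)
    missing = [s for s in ds.sample_ids if s not in mapping]
    if missing:
        raise DatasetError(
            f"samples missing from label file: {missing[:5]}"
        )
    extra = sorted(set(mapping) - set(ds.sample_ids))
    if extra:
        logger.warning(
            "label file has %d samples absent from the dataset (e.g. %r); "
            "ignored", len(extra), extra[0],
        )
    labels = np.array([mapping[s] for s in ds.sample_ids], dtype=np.int64)
    return ds.with_labels(labels)


def write_labels(ds: ExpressionDataset, path: str | Path, sep: str = "\t") -> None:
    y = ds.require_labels()
    with open(path, "w") as fh:
        for sid, lab in zip(ds.sample_ids, y):
            fh.write(f"{sid}{sep}{int(lab)}\n")


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Recipe for a synthetic cohort-like dataset.

    ``geometry="global"`` draws informative features from class-shifted unit
    Gaussians with mean separation ``effect_size``.  ``geometry="local"``
    embeds a two-axis checkerboard: each sample carries two latent signs whose
    product encodes the class, and informative features load on one of the
    axes with amplitude ``effect_size``; every informative feature then has
    (near-)zero marginal class signal, yet local neighbourhoods are pure.
    """

    n_samples: int
    n_informative: int
    n_noise: int
    geometry: Literal["global", "local"] = "global"
    effect_size: float = 2.0
    responder_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise DatasetError("n_samples must be >= 8")
        if self.n_informative < 1:
            raise DatasetError("n_informative must be >= 1")
        if self.n_noise < 0:
            raise DatasetError("n_noise must be >= 0")
        if self.geometry not in ("global", "local"):
            raise DatasetError(f"unknown geometry: {self.geometry!r}")
        if not self.effect_size > 0:
            raise DatasetError("effect_size must be > 0")
        if not 0.0 < self.responder_fraction < 1.0:
            raise DatasetError("responder_fraction must be in (0,1)")
        n_resp = int(round(self.n_samples * self.responder_fraction))
        if n_resp < 1 or n_resp > self.n_samples - 1:
            raise DatasetError("responder_fraction leaves a class empty")


def generate_synthetic(cfg: SyntheticConfig) -> ExpressionDataset:
    """Generate a labelled synthetic dataset, deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    n, ni, nn = cfg.n_samples, cfg.n_informative, cfg.n_noise

    n_resp = int(round(n * cfg.responder_fraction))
    labels = np.zeros(n, dtype=np.int64)
    labels[rng.permutation(n)[:n_resp]] = 1

    informative = np.empty((n, ni))
    if cfg.geometry == "global":
        # class 0 centred at 0, class 1 shifted by +effect_size: mean
        # separation = effect_size and exceedance counts carry class signal
        shift = labels * float(cfg.effect_size)
        informative = rng.standard_normal((n, ni)) + shift[:, None]
    else:
        # latent signs (a, b): class = 1 iff a*b > 0, sign pair drawn
        # uniformly within the class so per-feature class means cancel
        a = rng.choice([-1.0, 1.0], size=n)
        b = np.where(labels == 1, a, -a)
        n_axis1 = (ni + 1) // 2
        loading = np.concatenate(
            [np.repeat(a[:, None], n_axis1, axis=1),
             np.repeat(b[:, None], ni - n_axis1, axis=1)], axis=1
        )
        informative = rng.standard_normal((n, ni)) + loading * cfg.effect_size

    noise = rng.standard_normal((n, nn))
    values = np.concatenate([informative, noise], axis=1)

    width = len(str(max(n, 1)))
    sample_ids = [f"s{i:0{width}d}" for i in range(n)]
    feature_ids = [f"{INFORMATIVE_PREFIX}{j:03d}" for j in range(ni)] + [
        f"{NOISE_PREFIX}{j:03d}" for j in range(nn)
    ]
    return ExpressionDataset(values=values, sample_ids=sample_ids,
                             feature_ids=feature_ids, labels=labels)
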