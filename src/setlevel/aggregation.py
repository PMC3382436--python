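"""Set-level feature construction: aggregate a gene set's member expressions
into one value per sample.

Modes
-----
AVG
    Arithmetic mean of the member-gene expressions; independent of other
    samples.
SVD
    Project the sample (centered with the *training* per-gene means) onto the
    maximum-variance direction of the training samples in the set's subspace
    — the first right-singular vector of the centered training submatrix.
SETSIG
    Gene-set signature: the pooled-variance two-sample t statistic contrasting
    the sample's Pearson correlations with class-0 vs class-1 training samples
    within the set's coordinates.  Positive values indicate the sample
    correlates rather with class 0.
NONE
    No aggregation: the member genes themselves (deduplicated union across
    selected sets) become the features.

All modes obey a strict fit-on-train / apply-to-any contract: models are
fitted on training data only and applied identically to training and test
samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ExpressionDataset, GeneSet, effective_set

__all__ = [
    "AggregationModel",
    "FeatureMatrix",
    "AGGREGATION_MODES",
    "aggregate_avg",
    "fit_svd",
    "apply_svd",
    "setsig",
    "fit_aggregation",
    "build_feature_matrix",
]

AGGREGATION_MODES = ("AVG", "SVD", "SETSIG", "NONE")

#: Cap for a SetSig t statistic with zero pooled variance but unequal means.
T_CAP = 1e6


@dataclass
class FeatureMatrix:
    """Samples × features real matrix with named rows and columns."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Elementary aggregators
# ---------------------------------------------------------------------------

def aggregate_avg(sample_expressions: np.ndarray) -> float:
    """Arithmetic mean of the member expressions of one sample."""
    v = np.asarray(sample_expressions, dtype=float)
    if v.size == 0:
        raise ValueError("empty effective set")
    return float(v.mean())


@dataclass
class _SvdState:
    genes: list[str]
    train_means: np.ndarray  # per-gene means of the training samples
    direction: np.ndarray    # unit vector, largest-|loading| coordinate positive


@dataclass
class _SetSigState:
    genes: list[str]
    reference_ids: list[str]
    reference_values: np.ndarray  # references × genes
    reference_labels: np.ndarray  # 0/1 per reference


def fit_svd(train: ExpressionDataset, gene_set: GeneSet) -> "AggregationModel":
    """Fit the maximum-variance (first right-singular) direction of the
    centered training submatrix for one gene set."""
    model = AggregationModel(mode="SVD")
    model._fit(train, [gene_set])
    return model


def apply_svd(model: "AggregationModel", sample_expressions: np.ndarray) -> float:
    """Project one sample's effective-set vector with a fitted SVD model
    (single-set models only)."""
    if model.mode != "SVD" or not model._fitted:
        raise ValueError("model is not a fitted single-set SVD model")
    [state] = model._svd_states
    v = np.asarray(sample_expressions, dtype=float)
    return float((v - state.train_means) @ state.direction)


def _svd_direction(centered: np.ndarray) -> np.ndarray:
    """First right-singular vector of a samples × genes centered matrix with
    a deterministic sign (largest-|loading| coordinate positive)."""
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    pivot = int(np.argmax(np.abs(d)))
    if d[pivot] < 0:
        d = -d
    return d


def _pearson_to_references(sample: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Pearson correlation of one sample vector with each reference row."""
    s = sample - sample.mean()
    ns = np.linalg.norm(s)
    if ns == 0:
        raise ValueError("zero-variance sample vector: correlation undefined")
    r = refs - refs.mean(axis=1, keepdims=True)
    nr = np.linalg.norm(r, axis=1)
    if np.any(nr == 0):
        raise ValueError("zero-variance reference sample: correlation undefined")
    return (r @ s) / (nr * ns)


def _pooled_t(a: np.ndarray, b: np.ndarray, cap: float = T_CAP) -> float:
    """Pooled-variance two-sample Student t for mean(a) − mean(b)."""
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each correlation population needs >= 2 members")
    diff = a.mean() - b.mean()
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if denom == 0:
        if diff == 0:
            return 0.0
        return float(np.sign(diff) * cap)
    return float(diff / denom)


def setsig(sample_expressions: np.ndarray, model: "AggregationModel",
           sample_id: str | None = None, set_index: int = 0) -> float:
    """SetSig signature of one sample under a fitted model.

    Correlates the sample's effective-set vector with every reference
    training sample and returns the pooled-variance t statistic of the
    class-0 vs class-1 correlation populations.  When ``sample_id`` names a
    reference sample (and self-exclusion is on), it is excluded from its own
    class's population.
    """
    if model.mode != "SETSIG" or not model._fitted:
        raise ValueError("model is not a fitted SetSig model")
    state = model._setsig_states[set_index]
    v = np.asarray(sample_expressions, dtype=float)
    cors = _pearson_to_references(v, state.reference_values)
    labels = state.reference_labels
    keep = np.ones(cors.size, dtype=bool)
    if model.self_exclude and sample_id is not None and sample_id in state.reference_ids:
        keep[state.reference_ids.index(sample_id)] = False
    a = cors[keep & (labels == 0)]
    b = cors[keep & (labels == 1)]
    return _pooled_t(a, b)


# ---------------------------------------------------------------------------
# Fitted per-set transformer
# ---------------------------------------------------------------------------

class AggregationModel:
    """Fitted transformer mapping samples to set-level feature values.

    Fit on training data with :meth:`fit` (or :func:`fit_aggregation`), then
    apply to any dataset sharing the training gene universe with
    :meth:`transform`.
    """

    def __init__(self, mode: str, self_exclude: bool = True) -> None:
        mode = mode.upper()
        if mode not in AGGREGATION_MODES:
            raise ValueError(f"mode must be one of {AGGREGATION_MODES}")
        self.mode = mode
        self.self_exclude = self_exclude
        self._fitted = False
        self.set_names: list[str] = []
        self._gene_lists: list[list[str]] = []      # AVG
        self._svd_states: list[_SvdState] = []      # SVD
        self._setsig_states: list[_SetSigState] = []  # SETSIG
        self._none_genes: list[str] = []            # NONE

    # -- fitting ------------------------------------------------------------

    def fit(self, train: ExpressionDataset, selected_sets: Sequence[GeneSet]) -> "AggregationModel":
        self._fit(train, selected_sets)
        return self

    def _fit(self, train: ExpressionDataset, selected_sets: Sequence[GeneSet]) -> None:
        if not selected_sets:
            raise ValueError("no gene sets selected")
        self.set_names = [s.name for s in selected_sets]
        if self.mode == "NONE":
            union: list[str] = []
            seen: set[str] = set()
            covered = set()
            for s in selected_sets:
                covered |= s.genes
            for g in train.gene_ids:  # dataset gene order, duplicates unified
                if g in covered and g not in seen:
                    union.append(g)
                    seen.add(g)
            if not union:
                raise ValueError("selected sets have empty effective gene union")
            self._none_genes = union
            self._fitted = True
            return

        y = train.label_vector()
        for s in selected_sets:
            genes = effective_set(s, train)
            if not genes:
                raise ValueError(f"gene set {s.name!r} has empty effective set")
            idx = train.gene_indices(genes)
            sub = train.values[idx].T  # samples × genes
            if self.mode == "AVG":
                self._gene_lists.append(genes)
            elif self.mode == "SVD":
                if train.n_samples < 2:
                    raise ValueError("SVD aggregation needs >= 2 training samples")
                means = sub.mean(axis=0)
                direction = _svd_direction(sub - means)
                self._svd_states.append(_SvdState(genes, means, direction))
            elif self.mode == "SETSIG":
                if len(genes) < 3:
                    raise ValueError(
                        f"SetSig needs an effective set of >= 3 genes "
                        f"(set {s.name!r} has {len(genes)})"
                    )
                min_per_class = 3 if self.self_exclude else 2
                if (y == 0).sum() < min_per_class or (y == 1).sum() < min_per_class:
                    raise ValueError("SetSig needs >= 2 references per class after exclusion")
                self._setsig_states.append(
                    _SetSigState(genes, list(train.sample_ids), sub.copy(), y.copy())
                )
        self._fitted = True

    # -- application --------------------------------------------------------

    @property
    def feature_names(self) -> list[str]:
        if not self._fitted:
            raise ValueError("model not fitted")
        if self.mode == "NONE":
            return list(self._none_genes)
        return list(self.set_names)

    def transform(self, dataset: ExpressionDataset) -> FeatureMatrix:
        """Reformulate every sample of ``dataset`` to set-level features with
        the training-fitted state (identical for train and test samples)."""
        if not self._fitted:
            raise ValueError("model not fitted")
        gene_pos = {g: j for j, g in enumerate(dataset.gene_ids)}

        def rows_for(genes: list[str]) -> np.ndarray:
            missing = [g for g in genes if g not in gene_pos]
            if missing:
                raise ValueError(f"dataset is missing required genes: {missing}")
            return dataset.values[[gene_pos[g] for g in genes]].T  # samples × genes

        if self.mode == "NONE":
            vals = rows_for(self._none_genes)
            return FeatureMatrix(list(dataset.sample_ids), list(self._none_genes), vals)

        cols: list[np.ndarray] = []
        if self.mode == "AVG":
            for genes in self._gene_lists:
                cols.append(rows_for(genes).mean(axis=1))
        elif self.mode == "SVD":
            for state in self._svd_states:
                sub = rows_for(state.genes)
                cols.append((sub - state.train_means) @ state.direction)
        elif self.mode == "SETSIG":
            for k, state in enumerate(self._setsig_states):
                sub = rows_for(state.genes)
                col = np.array(
                    [
                        setsig(sub[i], self, sample_id=sid, set_index=k)
                        for i, sid in enumerate(dataset.sample_ids)
                    ]
                )
                cols.append(col)
        return FeatureMatrix(
            list(dataset.sample_ids), list(self.set_names), np.column_stack(cols)
        )


def fit_aggregation(
    mode: str,
    train: ExpressionDataset,
    selected_sets: Sequence[GeneSet],
    self_exclude: bool = True,
) -> AggregationModel:
    """Convenience constructor: fit an :class:`AggregationModel` of the given
    mode on the training dataset for the selected sets."""
    return AggregationModel(mode, self_exclude=self_exclude).fit(train, selected_sets)


def build_feature_matrix(
    dataset: ExpressionDataset,
    selected_sets: Sequence[GeneSet],
    model: AggregationModel,
) -> FeatureMatrix:
    """Apply a fitted model to a dataset; ``selected_sets`` must match the
    sets the model was fitted on (in rank order)."""
    if [s.name for s in selected_sets] != model.set_names:
        raise ValueError("selected sets do not match the fitted model")
    return model.transform(dataset)
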