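"""Generic feature selection: information gain and SVM-RFE.

Both scorers apply at the gene level (features = individual genes) and at
the set level (features = aggregated set values; aggregation must precede
ranking, since these scorers see one real value per feature).
"""

from __future__ import annotations

import numpy as np

from sklearn.svm import SVC

from .aggregation import FeatureMatrix, fit_aggregation
from .core import ExpressionDataset, GeneSetCollection
from .ranking import RankingEntry, RankingResult

__all__ = [
    "information_gain",
    "svmrfe_rank",
    "select_top_genes",
    "rank_sets_generic",
]

GENERIC_SCORERS = ("IG", "SVMRFE")


# ---------------------------------------------------------------------------
# Information gain
# ---------------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def information_gain(feature_values: np.ndarray, labels: np.ndarray) -> float:
    """Expected reduction in class entropy (bits) from the best binary split
    of a continuous feature.

    The threshold ranges over midpoints of consecutive distinct sorted
    values (C4.5-style single split); constant features score 0.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.size < 2:
        raise ValueError("need >= 2 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = x.size
    h_y = _entropy(np.bincount(ys, minlength=2))
    # cumulative class-1 counts below each cut position
    cum1 = np.cumsum(ys)
    distinct = np.nonzero(np.diff(xs))[0]  # cut after position i
    if distinct.size == 0:
        return 0.0
    best = h_y  # conditional entropy upper bound
    for i in distinct:
        nl = i + 1
        nr = n - nl
        l1 = cum1[i]
        left = _entropy(np.array([nl - l1, l1]))
        right = _entropy(np.array([nr - (cum1[-1] - l1), cum1[-1] - l1]))
        cond = (nl * left + nr * right) / n
        if cond < best:
            best = cond
    return max(h_y - best, 0.0)


# ---------------------------------------------------------------------------
# SVM-RFE
# ---------------------------------------------------------------------------

def _standardize_columns(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0, keepdims=True)
    sd = values.std(axis=0, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mean) / sd


def svmrfe_rank(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    chunked: bool = False,
) -> list[int]:
    """Recursive feature elimination with a linear soft-margin SVM (C=1).

    Repeatedly trains on the standardized surviving features and eliminates
    the feature(s) with smallest |weight| (ties broken by feature index).
    In chunked mode, iteration ``i`` removes ``floor(F * 2**-i)`` features
    (at least one), where ``F`` is the original feature count.  Returns
    feature indices from best (eliminated last) to worst (eliminated first).
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray(labels, dtype=int)
    n_feat = x.shape[1]
    if n_feat < 2:
        raise ValueError("SVM-RFE needs >= 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    xs = _standardize_columns(x)
    surviving = list(range(n_feat))
    eliminated: list[int] = []
    iteration = 0
    while surviving:
        if len(surviving) == 1:
            eliminated.append(surviving.pop())
            break
        iteration += 1
        chunk = max(int(n_feat * 2.0 ** (-iteration)), 1) if chunked else 1
        chunk = min(chunk, len(surviving) - 1) if len(surviving) > 1 else 1
        clf = SVC(kernel="linear", C=1.0)
        clf.fit(xs[:, surviving], y)
        w = np.abs(np.asarray(clf.coef_).ravel())
        # smallest |weight| first; ties broken by (original) feature index
        order = sorted(range(len(surviving)), key=lambda j: (w[j], surviving[j]))
        drop = sorted(order[:chunk], reverse=True)
        for j in drop:
            eliminated.append(surviving.pop(j))
    return eliminated[::-1]


def rfe_elimination_schedule(n_features: int) -> list[int]:
    """Number of features removed per chunked iteration for F features,
    following the halving schedule floor(F * 2**-i), minimum 1."""
    remaining = n_features
    schedule: list[int] = []
    i = 0
    while remaining > 0:
        i += 1
        chunk = max(int(n_features * 2.0 ** (-i)), 1)
        chunk = min(chunk, remaining - 1) if remaining > 1 else remaining
        schedule.append(chunk)
        remaining -= chunk
    return schedule


# ---------------------------------------------------------------------------
# Gene-level and set-level selection
# ---------------------------------------------------------------------------

def select_top_genes(
    dataset: ExpressionDataset, scorer: str, k: int
) -> list[str]:
    """Top-k genes of the (training) dataset by the generic scorer; ties
    resolved by dataset gene order.  ``k = 22`` and ``k = 228`` are the two
    preset sizes matching the median unique-gene counts of single-set and
    ten-set set-level representations."""
    scorer = scorer.upper()
    if scorer not in GENERIC_SCORERS:
        raise ValueError(f"scorer must be one of {GENERIC_SCORERS}")
    if k <= 0:
        raise ValueError("k must be positive")
    if k > dataset.n_genes:
        raise ValueError(f"k={k} exceeds the {dataset.n_genes} dataset genes")
    y = dataset.label_vector()
    if scorer == "IG":
        scores = np.array(
            [information_gain(dataset.values[j], y) for j in range(dataset.n_genes)]
        )
        order = sorted(range(dataset.n_genes), key=lambda j: (-scores[j], j))
    else:
        ranking = svmrfe_rank(dataset.values.T, y, chunked=True)
        order = ranking
    return [dataset.gene_ids[j] for j in order[:k]]


def rank_sets_generic(
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    scorer: str,
    aggregation_mode: str,
) -> RankingResult:
    """Rank gene sets by a generic scorer applied to their aggregated
    set-level feature values (aggregation precedes ranking).

    The scorer never sees raw gene expressions — only the one-value-per-set
    features built by the aggregation model fitted on this (training)
    dataset.  Generic rankings carry no permutation p-value (NaN).
    """
    scorer = scorer.upper()
    if scorer not in GENERIC_SCORERS:
        raise ValueError(f"scorer must be one of {GENERIC_SCORERS}")
    aggregation_mode = aggregation_mode.upper()
    if aggregation_mode not in ("AVG", "SVD", "SETSIG"):
        raise ValueError(
            "generic set ranking requires an aggregating mode (AVG, SVD or SETSIG)"
        )
    sets = [s for s in collection if dataset.gene_indices(s.genes).size > 0]
    if not sets:
        raise ValueError("no gene set has a non-empty effective set")
    model = fit_aggregation(aggregation_mode, dataset, sets)
    fm = model.transform(dataset)
    y = dataset.label_vector()
    if scorer == "IG":
        scores = np.array(
            [information_gain(fm.values[:, j], y) for j in range(len(sets))]
        )
        order = sorted(
            range(len(sets)), key=lambda j: (-scores[j], sets[j].name)
        )
        stat = scores
    else:
        if len(sets) == 1:
            order = [0]
            stat = np.zeros(1)
        else:
            ranking = svmrfe_rank(fm, y, chunked=True)
            order = ranking
            # statistic: position-based score (higher = better), no natural scale
            stat = np.empty(len(sets))
            for pos, j in enumerate(ranking):
                stat[j] = float(len(sets) - pos)
    entries = [
        RankingEntry(
            name=sets[j].name,
            statistic=float(stat[j]),
            p_value=float("nan"),
            rank=r,
        )
        for r, j in enumerate(order, start=1)
    ]
    return RankingResult(method=scorer, entries=entries, n_permutations=0, seed=None)
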