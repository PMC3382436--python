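"""Gene-set ranking by class-discrimination power.

Three dedicated set-level statistics are provided:

* **GSEA** — the weighted Kolmogorov–Smirnov-like enrichment score: genes are
  sorted by a signal-to-noise association with the binary phenotype and a
  running sum is walked down the list, rising at member genes and falling
  otherwise; the score is the signed maximum deviation from zero.
* **SAM-GS** — the Euclidean distance between the two class centroids in the
  subspace spanned by the set's member genes.
* **Global test** — the score statistic of a random-effects regression of the
  class indicator on the standardized member-gene expressions,
  ``Q = z' X X' z / m`` with centered labels ``z``.

All three share one null machinery: phenotype-label permutation with the
add-one p-value ``(b + 1) / (B + 1)``.  Ranking is deterministic: sets are
ordered by (p ascending, |statistic| descending, name ascending).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import ExpressionDataset, GeneSet, GeneSetCollection

logger = logging.getLogger("setlevel")

__all__ = [
    "RankingEntry",
    "RankingResult",
    "gene_level_snr",
    "gsea_enrichment_score",
    "samgs_statistic",
    "global_test_statistic",
    "permutation_pvalue",
    "rank_gene_sets",
]

#: Cap applied to signal-to-noise scores with zero denominator but unequal means.
SNR_CAP = 1e6

DEDICATED_METHODS = ("GSEA", "SAMGS", "GLOBAL")


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankingEntry:
    name: str
    statistic: float
    p_value: float  # NaN for generic scorers that carry no permutation p
    rank: int


@dataclass
class RankingResult:
    """An ordered ranking of gene sets produced by one method on one training set."""

    method: str
    entries: list[RankingEntry]
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        ranks = sorted(e.rank for e in self.entries)
        if ranks != list(range(1, len(self.entries) + 1)):
            raise ValueError("ranks must be a permutation of 1..n")
        for e in self.entries:
            if not np.isnan(e.p_value) and not (0.0 <= e.p_value <= 1.0):
                raise ValueError(f"p-value out of [0,1] for set {e.name!r}")
        self.entries = sorted(self.entries, key=lambda e: e.rank)

    @property
    def n(self) -> int:
        return len(self.entries)

    def names_for_ranks(self, ranks: Sequence[int]) -> list[str]:
        by_rank = {e.rank: e.name for e in self.entries}
        return [by_rank[r] for r in ranks]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [e.name for e in self.entries],
                "statistic": [e.statistic for e in self.entries],
                "p_value": [e.p_value for e in self.entries],
                "rank": [e.rank for e in self.entries],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "n_permutations": self.n_permutations,
                "seed": self.seed,
                "entries": [e.__dict__ for e in self.entries],
            }
        )


# ---------------------------------------------------------------------------
# Gene-level association score
# ---------------------------------------------------------------------------

def _snr_from_labels(values: np.ndarray, label_cols: np.ndarray, cap: float = SNR_CAP) -> np.ndarray:
    """Signal-to-noise ratio per gene for each column of 0/1 labels.

    ``values`` is genes × samples; ``label_cols`` is samples × B.  Returns a
    genes × B matrix of (mean0 - mean1) / (sd0 + sd1) with n-1 sds.  A zero
    denominator yields 0 for equal means, else a sign-preserving cap.
    """
    L = np.asarray(label_cols, dtype=float)
    if L.ndim == 1:
        L = L[:, None]
    i1 = L
    i0 = 1.0 - L
    n0 = i0.sum(axis=0)
    n1 = i1.sum(axis=0)
    if np.any(n0 < 2) or np.any(n1 < 2):
        raise ValueError("signal-to-noise ratio requires >= 2 samples per class")
    s0 = values @ i0
    s1 = values @ i1
    m0 = s0 / n0
    m1 = s1 / n1
    sq = values**2
    ss0 = sq @ i0
    ss1 = sq @ i1
    var0 = np.maximum(ss0 - n0 * m0**2, 0.0) / (n0 - 1)
    var1 = np.maximum(ss1 - n1 * m1**2, 0.0) / (n1 - 1)
    denom = np.sqrt(var0) + np.sqrt(var1)
    diff = m0 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    zero_div = (denom == 0) & (diff != 0)
    snr = np.where(zero_div, np.sign(diff) * cap, snr)
    return snr


def gene_level_snr(dataset: ExpressionDataset, cap: float = SNR_CAP) -> np.ndarray:
    """Per-gene signal-to-noise association with the binary phenotype,
    (mean0 − mean1)/(sd0 + sd1), sample sds with denominator n − 1."""
    y = dataset.label_vector()
    return _snr_from_labels(dataset.values, y, cap=cap)[:, 0]


# ---------------------------------------------------------------------------
# GSEA enrichment score
# ---------------------------------------------------------------------------

def _es_from_positions(
    positions: np.ndarray, hit_weights: np.ndarray, p: int
) -> float:
    """Enrichment score given 0-based hit positions (sorted ascending) in the
    phenotype-sorted gene list and the corresponding |score|^w hit weights.

    The running sum is piecewise linear between hits, so its extremes occur
    only immediately before and after hit positions; the signed value of
    largest magnitude over those candidates is the enrichment score.
    """
    m = positions.size
    if m == 0 or m >= p:
        raise ValueError("effective set must be a non-empty proper subset of genes")
    miss = 1.0 / (p - m)
    total = hit_weights.sum()
    if total > 0:
        w = hit_weights / total
    else:
        # All hit scores are exactly zero: fall back to equal hit increments.
        w = np.full(m, 1.0 / m)
    cum = np.cumsum(w)
    before = np.concatenate(([0.0], cum[:-1])) - (positions - np.arange(m)) * miss
    after = before + w
    # interleave chronologically so magnitude ties resolve as in a literal walk
    cand = np.empty(2 * m)
    cand[0::2] = before
    cand[1::2] = after
    return float(cand[np.argmax(np.abs(cand))])


def _gsea_es_for_scores(
    scores: np.ndarray, member_idx: np.ndarray, weight_exponent: float
) -> float:
    p = scores.size
    order = np.argsort(-scores, kind="stable")  # descending, ties by gene index
    rank_of = np.empty(p, dtype=int)
    rank_of[order] = np.arange(p)
    pos = np.sort(rank_of[member_idx])
    weights = np.abs(scores[order[pos]]) ** weight_exponent
    return _es_from_positions(pos, weights, p)


def gsea_enrichment_score(
    dataset: ExpressionDataset, gene_set: GeneSet, weight_exponent: float = 1.0
) -> float:
    """Signed maximum deviation of the weighted running sum walked down the
    phenotype-sorted gene list (weight exponent ``w``, default 1).

    Hits add ``|score|^w / sum_hits |score|^w``; misses subtract
    ``1 / (p − N_H)``.  The effective set must be a non-empty proper subset
    of the dataset's genes.
    """
    idx = dataset.gene_indices(gene_set.genes)
    if idx.size == 0:
        raise ValueError(f"gene set {gene_set.name!r} has empty effective set")
    if idx.size >= dataset.n_genes:
        raise ValueError("effective set equals the whole gene list")
    scores = gene_level_snr(dataset)
    return _gsea_es_for_scores(scores, idx, weight_exponent)


# ---------------------------------------------------------------------------
# SAM-GS
# ---------------------------------------------------------------------------

def samgs_statistic(dataset: ExpressionDataset, gene_set: GeneSet) -> float:
    """Euclidean distance between the two class centroids restricted to the
    set's effective genes."""
    idx = dataset.gene_indices(gene_set.genes)
    if idx.size == 0:
        raise ValueError(f"gene set {gene_set.name!r} has empty effective set")
    y = dataset.label_vector()
    sub = dataset.values[idx]
    c0 = sub[:, y == 0].mean(axis=1)
    c1 = sub[:, y == 1].mean(axis=1)
    return float(np.linalg.norm(c0 - c1))


# ---------------------------------------------------------------------------
# Global test
# ---------------------------------------------------------------------------

def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each row to mean 0, sd 1 (n−1).  Returns (standardized,
    boolean mask of rows with nonzero variance); zero-variance rows are set
    to 0 and flagged."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    ok = (sd[:, 0] > 0)
    safe = np.where(sd > 0, sd, 1.0)
    out = (values - mean) / safe
    out[~ok] = 0.0
    return out, ok


def global_test_statistic(dataset: ExpressionDataset, gene_set: GeneSet) -> float:
    """Score statistic Q = z' X X' z / m of the random-effects regression of
    the class indicator on the set's standardized member-gene expressions.

    Genes are standardized across samples (mean 0, sd 1); zero-variance
    genes are dropped; ``z`` is the centered label vector.
    """
    idx = dataset.gene_indices(gene_set.genes)
    if idx.size == 0:
        raise ValueError(f"gene set {gene_set.name!r} has empty effective set")
    sub, ok = _standardize_rows(dataset.values[idx])
    m = int(ok.sum())
    if m == 0:
        raise ValueError(
            f"gene set {gene_set.name!r}: all effective genes are constant"
        )
    y = dataset.label_vector().astype(float)
    z = y - y.mean()
    u = sub @ z  # per-gene score; zero rows contribute nothing
    return float((u**2).sum() / m)


# ---------------------------------------------------------------------------
# Phenotype permutation machinery
# ---------------------------------------------------------------------------

def _permuted_labels(y: np.ndarray, n_permutations: int, rng: np.random.Generator) -> np.ndarray:
    """samples × B matrix of uniformly permuted label vectors (class sizes
    preserved by construction)."""
    n = y.size
    keys = rng.random((n_permutations, n))
    perm = np.argsort(keys, axis=1)
    return y[perm].T


def _statistics_for_labels(
    method: str,
    values: np.ndarray,
    label_cols: np.ndarray,
    member_indices: list[np.ndarray],
    weight_exponent: float = 1.0,
) -> np.ndarray:
    """Statistic of each gene set (rows) under each label column (columns)."""
    method = method.upper()
    n_sets = len(member_indices)
    L = label_cols
    B = L.shape[1]
    out = np.empty((n_sets, B))
    if method == "SAMGS":
        i1 = L.astype(float)
        i0 = 1.0 - i1
        d = values @ (i0 / i0.sum(axis=0)) - values @ (i1 / i1.sum(axis=0))
        d2 = d**2
        for k, idx in enumerate(member_indices):
            out[k] = np.sqrt(d2[idx].sum(axis=0))
    elif method == "GLOBAL":
        std, ok = _standardize_rows(values)
        z = L - L.mean(axis=0, keepdims=True)
        w = std @ z  # genes × B
        w2 = w**2
        for k, idx in enumerate(member_indices):
            m = int(ok[idx].sum())
            if m == 0:
                raise ValueError("all effective genes constant in a gene set")
            out[k] = w2[idx].sum(axis=0) / m
    elif method == "GSEA":
        snr = _snr_from_labels(values, L)
        p = values.shape[0]
        for b in range(B):
            scores = snr[:, b]
            order = np.argsort(-scores, kind="stable")
            rank_of = np.empty(p, dtype=int)
            rank_of[order] = np.arange(p)
            abs_w = np.abs(scores[order]) ** weight_exponent
            for k, idx in enumerate(member_indices):
                pos = np.sort(rank_of[idx])
                out[k, b] = _es_from_positions(pos, abs_w[pos], p)
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    return out


_SINGLE_SET_STATS: dict[str, Callable[[ExpressionDataset, GeneSet], float]] = {
    "GSEA": gsea_enrichment_score,
    "SAMGS": samgs_statistic,
    "GLOBAL": global_test_statistic,
}


def permutation_pvalue(
    statistic: str,
    dataset: ExpressionDataset,
    gene_set: GeneSet,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Observed statistic and phenotype-permutation p-value.

    Labels are permuted uniformly at random (class sizes preserved);
    p = (b + 1)/(B + 1) where b counts permuted statistics at least as
    extreme as the observed one — two-sided in |ES| for GSEA, one-sided
    (stat >= observed) for the nonnegative SAM-GS and Global statistics.
    """
    method = statistic.upper()
    if method not in _SINGLE_SET_STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = _SINGLE_SET_STATS[method](dataset, gene_set)
    idx = dataset.gene_indices(gene_set.genes)
    rng = np.random.default_rng(seed)
    L = _permuted_labels(dataset.label_vector(), n_permutations, rng)
    perm_stats = _statistics_for_labels(method, dataset.values, L, [idx])[0]
    p = _pvalue_from_null(method, observed, perm_stats)
    return observed, p


def _pvalue_from_null(method: str, observed: float, perm_stats: np.ndarray) -> float:
    B = perm_stats.size
    if method == "GSEA":
        b = int((np.abs(perm_stats) >= abs(observed)).sum())
    else:
        b = int((perm_stats >= observed).sum())
    return (b + 1) / (B + 1)


# ---------------------------------------------------------------------------
# Collection-level ranking
# ---------------------------------------------------------------------------

def rank_gene_sets(
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    method: str,
    n_permutations: int = 999,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> RankingResult:
    """Score every gene set on the (training) dataset and rank by
    discrimination power.

    Sets with an empty effective set are dropped with a warning.  The label
    permutations are shared across sets, preserving the gene–gene
    correlation structure of the data under the null.  Sort key:
    (p ascending, |statistic| descending, name ascending); ranks 1..n.
    """
    method = method.upper()
    if method not in DEDICATED_METHODS:
        raise ValueError(
            f"method must be one of {DEDICATED_METHODS}, got {method!r}"
        )
    kept: list[GeneSet] = []
    member_indices: list[np.ndarray] = []
    for s in collection:
        idx = dataset.gene_indices(s.genes)
        if idx.size == 0:
            logger.warning("dropping gene set %s: empty effective set", s.name)
            continue
        kept.append(s)
        member_indices.append(idx)
    if not kept:
        raise ValueError("no gene set has a non-empty effective set")

    y = dataset.label_vector()
    observed = _statistics_for_labels(
        method, dataset.values, y[:, None].astype(int), member_indices,
        weight_exponent=weight_exponent,
    )[:, 0]
    rng = np.random.default_rng(seed)
    L = _permuted_labels(y, n_permutations, rng)
    perm = _statistics_for_labels(
        method, dataset.values, L, member_indices, weight_exponent=weight_exponent
    )
    pvals = np.array(
        [_pvalue_from_null(method, observed[k], perm[k]) for k in range(len(kept))]
    )

    order = sorted(
        range(len(kept)),
        key=lambda k: (pvals[k], -abs(observed[k]), kept[k].name),
    )
    entries = [
        RankingEntry(
            name=kept[k].name,
            statistic=float(observed[k]),
            p_value=float(pvals[k]),
            rank=r,
        )
        for r, k in enumerate(order, start=1)
    ]
    return RankingResult(
        method=method, entries=entries, n_permutations=n_permutations, seed=seed
    )
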