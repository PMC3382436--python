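"""Statistical comparison and reporting over accuracy records.

Factor comparisons use the paired Wilcoxon signed-rank test on
fold-averaged accuracies, pairing measurements equal in all factors except
the one under test; multiplicity is handled with the Bonferroni–Dunn
adjustment (p × m, capped at 1).  Ranking tables summarize method
combinations by median accuracy and by average sub-rank within
dataset × learner cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionDataset, GeneSet, effective_set
from .workflow import AccuracyRecord

__all__ = [
    "ComparisonReport",
    "paired_wilcoxon",
    "bonferroni_dunn_adjust",
    "median_ranking_table",
    "subrank_table",
    "accuracy_trend",
    "gene_set_group_stats",
]

_FACTORS = (
    "gene_sets",
    "ranking_algo",
    "sets_forming_features",
    "aggregation",
    "learner",
    "dataset_id",
)


@dataclass
class ComparisonReport:
    """Outcome of one paired factor comparison."""

    factor: str
    alt_a: str
    alt_b: str
    n_pairs: int
    statistic: float
    p_value: float
    adjusted_p: float
    sided: str            # "two-sided" | "greater" | "less"
    direction: str        # which alternative had the higher mean accuracy

    def __post_init__(self) -> None:
        if self.adjusted_p < self.p_value:
            raise ValueError("adjusted p cannot be below the raw p")


def _record_key(record: AccuracyRecord, exclude: str) -> tuple:
    return tuple(
        getattr(record.config, f) for f in _FACTORS if f != exclude
    )


def _signed_rank(differences: np.ndarray, sided: str) -> tuple[float, float]:
    """Wilcoxon signed-rank on nonzero differences: exact distribution for
    n <= 25 without ties in |d|, otherwise the normal approximation with
    continuity correction."""
    d = differences[differences != 0]
    if d.size == 0:
        raise ValueError("all differences zero")
    absd = np.abs(d)
    use_exact = d.size <= 25 and np.unique(absd).size == absd.size
    method = "exact" if use_exact else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=not use_exact,
        alternative=sided if sided != "two-sided" else "two-sided",
        method=method,
    )
    return float(res.statistic), float(res.pvalue)


def paired_wilcoxon(
    records: Sequence[AccuracyRecord],
    factor: str,
    alt_a: str,
    alt_b: str,
    sided: str = "two-sided",
    m_comparisons: int = 1,
) -> ComparisonReport:
    """Paired Wilcoxon signed-rank test between two alternatives of a factor.

    Measurements are matched on all factors except the tested one; unmatched
    measurements are excluded.  Zero differences are dropped (signed-rank
    convention).  ``sided="greater"`` tests whether ``alt_b`` exceeds
    ``alt_a``.  The Bonferroni–Dunn adjusted p uses ``m_comparisons``.
    """
    if factor not in _FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    if sided not in ("two-sided", "greater", "less"):
        raise ValueError("sided must be two-sided, greater or less")
    side_a: dict[tuple, float] = {}
    side_b: dict[tuple, float] = {}
    for rec in records:
        value = getattr(rec.config, factor)
        if value == alt_a:
            side_a[_record_key(rec, factor)] = rec.mean_accuracy
        elif value == alt_b:
            side_b[_record_key(rec, factor)] = rec.mean_accuracy
    keys = sorted(set(side_a) & set(side_b))
    if not keys:
        raise ValueError("no matched pairs between the two alternatives")
    a = np.array([side_a[k] for k in keys])
    b = np.array([side_b[k] for k in keys])
    diff = b - a
    statistic, p = _signed_rank(diff, sided)
    adj = bonferroni_dunn_adjust([p], m_comparisons)[0]
    direction = alt_b if b.mean() > a.mean() else alt_a
    return ComparisonReport(
        factor=factor, alt_a=alt_a, alt_b=alt_b, n_pairs=len(keys),
        statistic=statistic, p_value=p, adjusted_p=adj, sided=sided,
        direction=direction,
    )


def bonferroni_dunn_adjust(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni–Dunn multiplicity adjustment: ``min(1, p * m)``."""
    if m < len(p_values):
        raise ValueError("m must be at least the number of p-values")
    out = []
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, p * m))
    return out


# ---------------------------------------------------------------------------
# Ranking tables
# ---------------------------------------------------------------------------

def _combo(record: AccuracyRecord) -> tuple[str, str, str]:
    return (
        record.config.sets_forming_features,
        record.config.ranking_algo,
        record.config.aggregation,
    )


def median_ranking_table(records: Sequence[AccuracyRecord]) -> pd.DataFrame:
    """Method combinations ranked by median fold-averaged accuracy.

    One row per (sets forming features, ranking algorithm, aggregation)
    combination, pooling accuracies across datasets and learners.  The IQR
    is Q3 − Q1 with linear-interpolation quantiles.
    """
    if not records:
        raise ValueError("no records")
    rows = []
    df = pd.DataFrame(
        {
            "combo": [" / ".join(_combo(r)) for r in records],
            "sets": [r.config.sets_forming_features for r in records],
            "ranking": [r.config.ranking_algo for r in records],
            "aggregation": [r.config.aggregation for r in records],
            "accuracy": [r.mean_accuracy for r in records],
        }
    )
    for combo, grp in df.groupby("combo", sort=False):
        acc = grp["accuracy"].to_numpy()
        q1, q3 = np.quantile(acc, [0.25, 0.75])
        rows.append(
            {
                "combo": combo,
                "sets": grp["sets"].iloc[0],
                "ranking": grp["ranking"].iloc[0],
                "aggregation": grp["aggregation"].iloc[0],
                "median": float(np.median(acc)),
                "mean": float(acc.mean()),
                "sd": float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
                "iqr": float(q3 - q1),
                "n": int(acc.size),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["median", "combo"], ascending=[False, True], ignore_index=True
    )
    out.index = out.index + 1
    out.index.name = "rank"
    return out


def subrank_table(records: Sequence[AccuracyRecord]) -> pd.DataFrame:
    """Average sub-rank of each method combination across dataset × learner
    cells (rank 1 = most accurate within a cell; ties get average ranks).

    Every combination must be present in every cell; incomplete combinations
    are reported by name.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(
        {
            "combo": [" / ".join(_combo(r)) for r in records],
            "cell": [(r.config.dataset_id, r.config.learner) for r in records],
            "accuracy": [r.mean_accuracy for r in records],
        }
    )
    combos = sorted(df["combo"].unique())
    cells = sorted(df["cell"].unique())
    pivot = df.pivot_table(index="combo", columns="cell", values="accuracy")
    missing = pivot.isna().any(axis=1)
    if missing.any():
        raise ValueError(
            f"incomplete combinations (missing cells): {sorted(pivot.index[missing])}"
        )
    # rank within each cell: highest accuracy -> rank 1, ties averaged
    ranks = pivot.rank(axis=0, ascending=False, method="average")
    out = pd.DataFrame(
        {"combo": pivot.index, "avg_subrank": ranks.mean(axis=1).to_numpy()}
    ).sort_values(["avg_subrank", "combo"], ignore_index=True)
    out.index = out.index + 1
    out.index.name = "rank"
    return out


def accuracy_trend(
    records: Sequence[AccuracyRecord],
    rank_positions: Mapping[str, float] | None = None,
) -> tuple[float, float]:
    """Ordinary least-squares line of mean accuracy against gene-set rank
    position (single-rank records only).  Returns (slope, intercept)."""
    pos_acc: dict[float, list[float]] = {}
    for r in records:
        sel = r.config.sets_forming_features
        if rank_positions is not None:
            if sel not in rank_positions:
                continue
            x = float(rank_positions[sel])
        else:
            # single ranks "1".."10" count from the top; batch and bottom
            # alternatives need the collection size, so callers map them
            # through rank_positions
            try:
                x = float(sel)
            except ValueError:
                continue
        pos_acc.setdefault(x, []).append(r.mean_accuracy)
    if len(pos_acc) < 2:
        raise ValueError("need >= 2 distinct rank positions")
    xs = np.array(sorted(pos_acc))
    ys = np.array([np.mean(pos_acc[x]) for x in xs])
    slope, intercept = np.polyfit(xs, ys, 1)
    return float(slope), float(intercept)


# ---------------------------------------------------------------------------
# Gene-set group statistics
# ---------------------------------------------------------------------------

def _pca_components_for_fraction(
    submatrix: np.ndarray, fraction: float
) -> int:
    """Smallest k such that the top-k covariance eigenvalues of the
    genes × samples submatrix reach ``fraction`` of total variance."""
    centered = submatrix - submatrix.mean(axis=1, keepdims=True)
    if centered.shape[1] < 2:
        return 1
    cov_eigs = np.linalg.svd(centered, compute_uv=False) ** 2
    total = cov_eigs.sum()
    if total == 0:
        return 1
    cum = np.cumsum(cov_eigs) / total
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def gene_set_group_stats(
    groups: Mapping[str, Sequence[GeneSet]],
    dataset: ExpressionDataset,
    bonferroni_m: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Size and complexity statistics per gene-set group, with pairwise
    Mann–Whitney U comparisons.

    Per set: nominal size, effective size, and the number of PCA components
    capturing 50% and 90% of expression variance in the set's effective
    submatrix.  Returns (summary table with means ± standard errors and
    medians, pairwise Bonferroni-adjusted Mann–Whitney p table).  The
    Bonferroni factor defaults to (number of group pairs) × (number of
    metrics) and is recorded in the p-table attrs.
    """
    if not groups:
        raise ValueError("no groups")
    metrics = ("nominal_size", "effective_size", "pca_50", "pca_90")
    per_group: dict[str, dict[str, np.ndarray]] = {}
    for gname, sets in groups.items():
        vals: dict[str, list[float]] = {m: [] for m in metrics}
        for s in sets:
            eff = effective_set(s, dataset)
            if not eff:
                continue
            idx = dataset.gene_indices(s.genes)
            sub = dataset.values[idx]
            vals["nominal_size"].append(len(s))
            vals["effective_size"].append(len(eff))
            vals["pca_50"].append(_pca_components_for_fraction(sub, 0.50))
            vals["pca_90"].append(_pca_components_for_fraction(sub, 0.90))
        if not vals["nominal_size"]:
            raise ValueError(f"group {gname!r} has only empty effective sets")
        per_group[gname] = {m: np.array(v, dtype=float) for m, v in vals.items()}

    rows = []
    for gname, vals in per_group.items():
        row: dict[str, object] = {"group": gname, "n_sets": len(vals["nominal_size"])}
        for m in metrics:
            v = vals[m]
            row[f"{m}_mean"] = float(v.mean())
            row[f"{m}_se"] = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
            row[f"{m}_median"] = float(np.median(v))
        rows.append(row)
    summary = pd.DataFrame(rows)

    names = list(per_group)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    m_factor = bonferroni_m if bonferroni_m is not None else max(len(pairs) * len(metrics), 1)
    prows = []
    for a, b in pairs:
        for metric in metrics:
            u, p = stats.mannwhitneyu(
                per_group[a][metric], per_group[b][metric], alternative="two-sided",
                method="asymptotic",
            )
            prows.append(
                {
                    "group_a": a, "group_b": b, "metric": metric,
                    "U": float(u), "p_raw": float(p),
                    "p_adjusted": min(1.0, float(p) * m_factor),
                }
            )
    ptable = pd.DataFrame(prows)
    ptable.attrs["bonferroni_m"] = m_factor
    return summary, ptable
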