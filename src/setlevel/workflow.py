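"""The set-level learning workflow and the factorial experiment runner.

One workflow execution, per cross-validation fold: rank the gene-set
collection on the training fold, select the sets forming features, fit the
aggregation model on the training fold, reformulate training and testing
samples to the set level, train the learner and score test accuracy.  All
data-dependent choices (ranking, selection, aggregation fitting, feature
standardization) are made on the training fold only.

The factorial design varies six factors — gene sets (genuine/random),
ranking algorithm, sets forming features, aggregation, learner, dataset —
with the testing fold as a seventh implicit factor under 10-fold CV.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .aggregation import FeatureMatrix, fit_aggregation
from .core import ExpressionDataset, GeneSetCollection
from .ranking import RankingResult, rank_gene_sets
from .selection import GENERIC_SCORERS, rank_sets_generic, select_top_genes

__all__ = [
    "LEARNERS",
    "SET_SELECTORS",
    "ExperimentConfig",
    "AccuracyRecord",
    "stratified_folds",
    "learn_and_score",
    "run_workflow",
    "run_baseline",
    "run_factorial",
    "design_counts",
    "enumerate_design",
]

LEARNERS = ("svm", "1nn", "3nn", "nb", "dt")
RANKING_ALGOS = ("GSEA", "SAMGS", "GLOBAL", "IG", "SVMRFE")

#: The 22 alternatives of the sets-forming-features factor: single ranks
#: 1..10 from the top, the 10 bottom ranks n-9..n, and the two batches.
SET_SELECTORS = tuple(
    [str(r) for r in range(1, 11)]
    + [f"n-{k}" for k in range(9, 0, -1)]
    + ["n", "1:10", "n-9:n"]
)


def _selector_ranks(selector: str, n: int) -> list[int]:
    """Resolve a sets-forming-features alternative to concrete rank numbers."""
    selector = selector.strip()
    if selector == "1:10":
        ranks = list(range(1, 11))
    elif selector == "n-9:n":
        ranks = list(range(n - 9, n + 1))
    elif selector == "n":
        ranks = [n]
    elif selector.startswith("n-"):
        ranks = [n - int(selector[2:])]
    else:
        ranks = [int(selector)]
    if any(r < 1 or r > n for r in ranks):
        raise ValueError(
            f"selector {selector!r} asks for ranks outside 1..{n}"
        )
    return ranks


@dataclass(frozen=True)
class ExperimentConfig:
    """One combination of factor alternatives for a workflow execution."""

    gene_sets: str = "GENUINE"          # GENUINE | RANDOM
    ranking_algo: str = "GLOBAL"        # GSEA | SAMGS | GLOBAL | IG | SVMRFE
    sets_forming_features: str = "1:10"  # see SET_SELECTORS
    aggregation: str = "SVD"            # SVD | AVG | SETSIG | NONE
    learner: str = "svm"                # svm | 1nn | 3nn | nb | dt
    dataset_id: str = "d1"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_sets", self.gene_sets.upper())
        object.__setattr__(self, "ranking_algo", self.ranking_algo.upper())
        object.__setattr__(self, "aggregation", self.aggregation.upper())
        object.__setattr__(self, "learner", self.learner.lower())
        if self.gene_sets not in ("GENUINE", "RANDOM"):
            raise ValueError("gene_sets must be GENUINE or RANDOM")
        if self.ranking_algo not in RANKING_ALGOS:
            raise ValueError(f"ranking_algo must be one of {RANKING_ALGOS}")
        if self.sets_forming_features not in SET_SELECTORS:
            raise ValueError(
                f"sets_forming_features must be one of {SET_SELECTORS}"
            )
        if self.aggregation not in ("SVD", "AVG", "SETSIG", "NONE"):
            raise ValueError("invalid aggregation mode")
        if self.learner not in LEARNERS:
            raise ValueError(f"learner must be one of {LEARNERS}")
        if self.ranking_algo in GENERIC_SCORERS and self.aggregation == "NONE":
            raise ValueError(
                "generic ranking (IG/SVM-RFE) scores aggregated set features; "
                "aggregation must not be NONE"
            )

    def key(self) -> str:
        return "|".join(
            [
                self.gene_sets,
                self.ranking_algo,
                self.sets_forming_features,
                self.aggregation,
                self.learner,
                self.dataset_id,
            ]
        )


@dataclass
class FoldDetail:
    """Per-fold diagnostics: what was selected and predicted (used by the
    no-leakage checks and for reporting)."""

    test_samples: list[str]
    selected_sets: list[str]
    feature_names: list[str]
    predictions: list[int]
    accuracy: float


@dataclass
class AccuracyRecord:
    """One workflow execution: configuration plus per-fold accuracies."""

    config: ExperimentConfig
    fold_accuracies: list[float]
    fold_details: list[FoldDetail] = field(default_factory=list, repr=False)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


# ---------------------------------------------------------------------------
# Cross-validation folds
# ---------------------------------------------------------------------------

def stratified_folds(
    dataset: ExpressionDataset, k: int = 10, seed: int = 0
) -> list[list[str]]:
    """Partition samples into k disjoint stratified test folds.

    Class members are shuffled and dealt round-robin, so per-fold class
    proportions stay within one sample of the global proportion.
    Deterministic under ``seed``; classes smaller than ``k`` are allowed
    (with some folds lacking that class) and logged as a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > dataset.n_samples:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    y = dataset.label_vector()
    folds: list[list[str]] = [[] for _ in range(k)]
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        if idx.size < k:
            import logging

            logging.getLogger("setlevel").warning(
                "class %d has %d samples for %d folds; some folds will lack it",
                cls, idx.size, k,
            )
        idx = idx[rng.permutation(idx.size)]
        for pos, i in enumerate(idx):
            folds[pos % k].append(dataset.sample_ids[i])
    return folds


# ---------------------------------------------------------------------------
# Learners
# ---------------------------------------------------------------------------

def _make_learner(learner: str):
    if learner == "svm":
        return SVC(kernel="linear", C=1.0)
    if learner == "1nn":
        return KNeighborsClassifier(n_neighbors=1, metric="euclidean")
    if learner == "3nn":
        return KNeighborsClassifier(n_neighbors=3, metric="euclidean")
    if learner == "nb":
        return GaussianNB()
    if learner == "dt":
        # CART with a leaf-size floor as a mild pruning stand-in
        return DecisionTreeClassifier(min_samples_leaf=2, random_state=0)
    raise ValueError(f"unknown learner {learner!r}")


def _predict(
    train_x: np.ndarray,
    train_y: np.ndarray,
    test_x: np.ndarray,
    learner: str,
) -> np.ndarray:
    """Train a learner and return test predictions.  The SVM consumes
    z-scores fitted on the training features; k-NN, NB and DT see raw
    values."""
    if train_x.shape[1] != test_x.shape[1]:
        raise ValueError("train/test feature dimension mismatch")
    if len(np.unique(train_y)) < 2:
        raise ValueError("training labels contain a single class")
    if learner == "svm":
        mean = train_x.mean(axis=0, keepdims=True)
        sd = train_x.std(axis=0, ddof=1, keepdims=True) if train_x.shape[0] > 1 else None
        sd = np.where(sd > 0, sd, 1.0) if sd is not None else 1.0
        train_x = (train_x - mean) / sd
        test_x = (test_x - mean) / sd
    clf = _make_learner(learner)
    clf.fit(train_x, train_y)
    if learner == "3nn" and train_x.shape[0] < 3:
        raise ValueError("3-NN needs at least 3 training samples")
    return np.asarray(clf.predict(test_x))


def learn_and_score(
    train_features: np.ndarray | FeatureMatrix,
    train_labels: np.ndarray,
    test_features: np.ndarray | FeatureMatrix,
    test_labels: np.ndarray,
    learner: str,
) -> float:
    """Train the given learner and return test accuracy (correct / total)."""
    tx = train_features.values if isinstance(train_features, FeatureMatrix) else np.asarray(train_features, float)
    sx = test_features.values if isinstance(test_features, FeatureMatrix) else np.asarray(test_features, float)
    ty = np.asarray(train_labels, dtype=int)
    sy = np.asarray(test_labels, dtype=int)
    pred = _predict(tx, ty, sx, learner)
    return float((pred == sy).mean())


# ---------------------------------------------------------------------------
# Workflow execution
# ---------------------------------------------------------------------------

def _rank_on_training(
    config: ExperimentConfig,
    train: ExpressionDataset,
    collection: GeneSetCollection,
    n_permutations: int,
    seed: int,
) -> RankingResult:
    if config.ranking_algo in GENERIC_SCORERS:
        return rank_sets_generic(
            train, collection, config.ranking_algo, config.aggregation
        )
    return rank_gene_sets(
        train, collection, config.ranking_algo,
        n_permutations=n_permutations, seed=seed,
    )


def run_workflow(
    config: ExperimentConfig,
    dataset: ExpressionDataset,
    collection: GeneSetCollection,
    n_permutations: int = 199,
    n_folds: int = 10,
    folds: list[list[str]] | None = None,
) -> AccuracyRecord:
    """Execute the full set-level learning workflow under stratified
    cross-validation and return per-fold and mean accuracy.

    Ranking, set selection, aggregation fitting and learner training all see
    the training fold only; test samples are reformulated with the
    training-fitted model before scoring.  ``folds`` overrides the
    seed-derived stratified partition (e.g. to hold the split fixed across
    perturbed variants of a dataset).
    """
    if folds is None:
        folds = stratified_folds(dataset, k=n_folds, seed=config.seed)
    y_all = dataset.labels
    fold_accs: list[float] = []
    details: list[FoldDetail] = []
    for f, test_ids in enumerate(folds):
        train_ids = [s for s in dataset.sample_ids if s not in set(test_ids)]
        train = dataset.subset_samples(train_ids)
        test = dataset.subset_samples(test_ids, require_both_classes=False)
        fold_seed = (config.seed * 1009 + f) % (2**31)
        ranking = _rank_on_training(
            config, train, collection, n_permutations, fold_seed
        )
        ranks = _selector_ranks(config.sets_forming_features, ranking.n)
        selected_names = ranking.names_for_ranks(ranks)
        selected = [collection[name] for name in selected_names]
        model = fit_aggregation(config.aggregation, train, selected)
        train_fm = model.transform(train)
        test_fm = model.transform(test)
        train_y = np.array([y_all[s] for s in train_ids])
        test_y = np.array([y_all[s] for s in test_ids])
        pred = _predict(train_fm.values, train_y, test_fm.values, config.learner)
        acc = float((pred == test_y).mean())
        fold_accs.append(acc)
        details.append(
            FoldDetail(
                test_samples=list(test_ids),
                selected_sets=selected_names,
                feature_names=model.feature_names,
                predictions=[int(v) for v in pred],
                accuracy=acc,
            )
        )
    return AccuracyRecord(config=config, fold_accuracies=fold_accs, fold_details=details)


def run_baseline(
    dataset: ExpressionDataset,
    learner: str,
    seed: int = 0,
    selector: tuple[str, int] | None = None,
    n_folds: int = 10,
    dataset_id: str = "d1",
    folds: list[list[str]] | None = None,
) -> AccuracyRecord:
    """Gene-level baseline under the identical CV protocol: every gene is a
    feature, optionally pre-filtered to the top-k genes by a generic scorer
    computed on each training fold."""
    if folds is None:
        folds = stratified_folds(dataset, k=n_folds, seed=seed)
    y_all = dataset.labels
    fold_accs: list[float] = []
    details: list[FoldDetail] = []
    for test_ids in folds:
        train_ids = [s for s in dataset.sample_ids if s not in set(test_ids)]
        train = dataset.subset_samples(train_ids)
        if selector is not None:
            scorer, k = selector
            genes = select_top_genes(train, scorer, k)
        else:
            genes = list(dataset.gene_ids)
        idx = dataset.gene_indices(genes)
        gene_order = [dataset.gene_ids[j] for j in idx]
        # preserve the scorer's ranking order for selected genes
        if selector is not None:
            pos = {g: r for r, g in enumerate(genes)}
            order = sorted(range(len(gene_order)), key=lambda j: pos[gene_order[j]])
            idx = idx[order]
            gene_order = [gene_order[j] for j in order]
        train_x = train.values[idx].T
        test = dataset.subset_samples(test_ids, require_both_classes=False)
        test_x = test.values[idx].T
        train_y = np.array([y_all[s] for s in train_ids])
        test_y = np.array([y_all[s] for s in test_ids])
        pred = _predict(train_x, train_y, test_x, learner)
        acc = float((pred == test_y).mean())
        fold_accs.append(acc)
        details.append(
            FoldDetail(
                test_samples=list(test_ids),
                selected_sets=[],
                feature_names=gene_order,
                predictions=[int(v) for v in pred],
                accuracy=acc,
            )
        )
    config = ExperimentConfig(
        gene_sets="GENUINE", ranking_algo="GLOBAL",
        sets_forming_features="1:10", aggregation="NONE",
        learner=learner, dataset_id=dataset_id, seed=seed,
    )
    return AccuracyRecord(config=config, fold_accuracies=fold_accs, fold_details=details)


# ---------------------------------------------------------------------------
# Factorial runner
# ---------------------------------------------------------------------------

def _config_seed(master_seed: int, key: str) -> int:
    return zlib.crc32(f"{master_seed}|{key}".encode()) & 0x7FFFFFFF


def enumerate_design(
    n_datasets: int = 30,
    gene_sets: Sequence[str] = ("GENUINE", "RANDOM"),
    ranking_algos: Sequence[str] = ("GSEA", "SAMGS", "GLOBAL"),
    set_selectors: Sequence[str] = SET_SELECTORS,
    aggregations: Sequence[str] = ("SVD", "AVG", "SETSIG", "NONE"),
    learners: Sequence[str] = LEARNERS,
) -> list[tuple[str, str, str, str, str, int]]:
    """Enumerate every combination of factor alternatives of the full design
    (without executing anything)."""
    return [
        combo
        for combo in itertools.product(
            gene_sets, ranking_algos, set_selectors, aggregations, learners,
            range(n_datasets),
        )
    ]


def design_counts(n_datasets: int = 30, n_folds: int = 10) -> dict[str, int]:
    """Execution and measurement counts of the full factorial design.

    With 2 gene-set collections x 3 ranking algorithms x 22 set-selection
    alternatives x 4 aggregations, 5 learners, ``n_datasets`` datasets and
    ``n_folds`` CV folds.
    """
    combos = enumerate_design(n_datasets=n_datasets)
    set_level = len(combos)
    baseline = len(LEARNERS) * n_datasets
    return {
        "set_level_configurations": 2 * 3 * 22 * 4,
        "workflow_executions": set_level * n_folds,
        "set_level_measurements": set_level,
        "baseline_executions": baseline * n_folds,
        "baseline_measurements": baseline,
    }


def run_factorial(
    grid: dict[str, Sequence[str]],
    datasets: dict[str, ExpressionDataset],
    collection: GeneSetCollection,
    random_collections: dict[str, GeneSetCollection] | None = None,
    master_seed: int = 0,
    n_permutations: int = 199,
    n_folds: int = 10,
    existing: dict[str, AccuracyRecord] | None = None,
) -> list[AccuracyRecord]:
    """Run the workflow for every combination of factor alternatives.

    ``grid`` maps factor names (``gene_sets``, ``ranking_algo``,
    ``sets_forming_features``, ``aggregation``, ``learner``) to alternative
    lists; missing factors use single defaults.  Per-config seeds are
    derived deterministically from ``master_seed``, so the runs are
    reproducible and order-independent; ``existing`` records (keyed by
    config key) are reused, making long grids resumable.
    """
    defaults = {
        "gene_sets": ("GENUINE",),
        "ranking_algo": ("GLOBAL",),
        "sets_forming_features": ("1:10",),
        "aggregation": ("SVD",),
        "learner": ("svm",),
    }
    factors = {k: tuple(grid.get(k, v)) for k, v in defaults.items()}
    existing = existing or {}
    records: list[AccuracyRecord] = []
    for dataset_id, dataset in datasets.items():
        for gs, algo, sel, agg, lrn in itertools.product(
            factors["gene_sets"], factors["ranking_algo"],
            factors["sets_forming_features"], factors["aggregation"],
            factors["learner"],
        ):
            cfg = ExperimentConfig(
                gene_sets=gs, ranking_algo=algo, sets_forming_features=sel,
                aggregation=agg, learner=lrn, dataset_id=dataset_id, seed=0,
            )
            cfg = replace(cfg, seed=_config_seed(master_seed, cfg.key()))
            if cfg.key() in existing:
                records.append(existing[cfg.key()])
                continue
            if gs == "RANDOM":
                if random_collections is None or dataset_id not in random_collections:
                    from .randomization import randomize_collection

                    coll = randomize_collection(
                        collection, seed=_config_seed(master_seed, f"rnd|{dataset_id}")
                    )
                else:
                    coll = random_collections[dataset_id]
            else:
                coll = collection
            records.append(
                run_workflow(cfg, dataset, coll, n_permutations=n_permutations,
                             n_folds=n_folds)
            )
    return records
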