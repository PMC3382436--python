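"""Domain types and I/O for expression matrices and gene-set collections.

An :class:`ExpressionDataset` holds a genes × samples matrix of normalized
expression values with binary class labels; a :class:`GeneSetCollection`
holds named gene sets (GMT format, MSigDB dialect).  Values are assumed to
be already normalized — no normalization is performed here, and missing
values are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("setlevel")

__all__ = [
    "ExpressionDataset",
    "GeneSet",
    "GeneSetCollection",
    "read_expression_dataset",
    "write_expression_dataset",
    "read_gmt",
    "write_gmt",
    "filter_by_size",
    "effective_set",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class ExpressionDataset:
    """A genes × samples expression matrix with binary class labels.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene identifiers, one per matrix row.
    sample_ids : sequence of str
        Unique sample identifiers, one per matrix column.
    values : ndarray, shape (n_genes, n_samples)
        Normalized expression values; all entries must be finite.
    labels : mapping sample id -> class in {0, 1}
        Every sample must be labelled and both classes must be non-empty
        (unless ``require_both_classes`` is False, for fold views such as a
        small test fold that happens to hold one class only).
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
        labels: Mapping[str, int],
        require_both_classes: bool = True,
    ) -> None:
        gene_ids = list(gene_ids)
        sample_ids = list(sample_ids)
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        if len(set(gene_ids)) != len(gene_ids):
            dupes = _duplicates(gene_ids)
            raise ValueError(f"duplicate gene identifier: {sorted(dupes)}")
        if len(set(sample_ids)) != len(sample_ids):
            dupes = _duplicates(sample_ids)
            raise ValueError(f"duplicate sample identifier: {sorted(dupes)}")
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        missing = [s for s in sample_ids if s not in labels]
        if missing:
            raise ValueError(f"samples missing a class label: {missing}")
        lab = {s: int(labels[s]) for s in sample_ids}
        if not set(lab.values()) <= {0, 1}:
            raise ValueError("labels must be encoded in {0, 1}")
        if require_both_classes and len(set(lab.values())) < 2:
            raise ValueError("both classes must be non-empty")
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.values = values
        self.labels = lab
        self._gene_index = {g: j for j, g in enumerate(gene_ids)}

    # -- basic accessors ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def label_vector(self) -> np.ndarray:
        """Labels as an int array aligned with ``sample_ids``."""
        return np.array([self.labels[s] for s in self.sample_ids], dtype=int)

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of the given genes (genes absent from the dataset are skipped),
        in dataset gene order."""
        wanted = set(genes)
        return np.array(
            [j for j, g in enumerate(self.gene_ids) if g in wanted], dtype=int
        )

    def subset_samples(
        self, sample_ids: Sequence[str], require_both_classes: bool = True
    ) -> "ExpressionDataset":
        """A new dataset restricted to the given samples, in the given order."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionDataset(
            self.gene_ids,
            list(sample_ids),
            self.values[:, idx],
            {s: self.labels[s] for s in sample_ids},
            require_both_classes=require_both_classes,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n1 = int(self.label_vector().sum())
        return (
            f"ExpressionDataset({self.n_genes} genes, {self.n_samples} samples, "
            f"classes {self.n_samples - n1}+{n1})"
        )


@dataclass(frozen=True)
class GeneSet:
    """A named a priori-defined set of genes with an optional category tag."""

    name: str
    genes: frozenset[str]
    category: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate set name: {sorted(_duplicates(names))}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def gene_pool(self) -> frozenset[str]:
        """The pooled gene universe: union of all member sets."""
        pool: set[str] = set()
        for s in self.sets:
            pool |= s.genes
        return frozenset(pool)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_dataset(matrix_path: str | Path, labels_path: str | Path) -> ExpressionDataset:
    """Read a TSV expression matrix (genes in rows, header of sample ids) and a
    two-column TSV labels file (sample id, class string).

    The two distinct class strings are mapped to {0, 1} in lexicographic
    order (smaller string -> 0).  Samples present in the matrix but absent
    from the labels file raise an error naming the sample.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifier: {dupes}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifier: {dupes}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in expression matrix: {exc}") from exc

    lab_df = pd.read_csv(
        labels_path, sep="\t", header=None, names=["sample", "class"], dtype=str
    )
    if lab_df["sample"].duplicated().any():
        raise ValueError("duplicate sample id in labels file")
    class_strings = sorted(lab_df["class"].unique())
    if len(class_strings) != 2:
        raise ValueError(
            f"labels file must contain exactly two classes, found {class_strings}"
        )
    encoding = {c: k for k, c in enumerate(class_strings)}
    raw = dict(zip(lab_df["sample"], lab_df["class"]))
    missing = [s for s in df.columns if s not in raw]
    if missing:
        raise ValueError(f"samples missing a class label: {missing}")
    labels = {s: encoding[raw[s]] for s in df.columns}
    return ExpressionDataset(list(df.index), list(df.columns), values, labels)


def write_expression_dataset(
    dataset: ExpressionDataset, matrix_path: str | Path, labels_path: str | Path
) -> None:
    """Write the matrix and labels in the format :func:`read_expression_dataset` reads."""
    df = pd.DataFrame(dataset.values, index=dataset.gene_ids, columns=dataset.sample_ids)
    df.to_csv(matrix_path, sep="\t", index_label="gene")
    with open(labels_path, "w", encoding="utf-8") as fh:
        for s in dataset.sample_ids:
            fh.write(f"{s}\t{dataset.labels[s]}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (one set per line: name TAB description TAB gene ...).

    Duplicate gene mentions within a line are deduplicated with a logged
    warning; a duplicate set name is an error.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has fewer than 3 fields"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if name in seen:
                raise ValueError(f"duplicate set name: {name!r}")
            seen.add(name)
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning(
                    "gene set %s: %d duplicate gene mention(s) removed",
                    name, len(genes) - len(unique),
                )
            sets.append(GeneSet(name=name, genes=frozenset(unique), description=description))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; genes sorted for reproducible output."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.name}\t{s.description}\t{genes}\n")


# ---------------------------------------------------------------------------
# Collection operations
# ---------------------------------------------------------------------------

def filter_by_size(
    collection: GeneSetCollection, min_size: int = 5, max_size: int = 200
) -> GeneSetCollection:
    """Retain exactly the sets with ``min_size <= |set| <= max_size``.

    The defaults discard sets with fewer than 5 or more than 200 genes, the
    customary size filter for curated pathway collections.  Order preserved.
    """
    if not (1 <= min_size <= max_size):
        raise ValueError("require 1 <= min_size <= max_size")
    return GeneSetCollection(
        [s for s in collection if min_size <= len(s) <= max_size]
    )


def effective_set(gene_set: GeneSet, dataset: ExpressionDataset) -> list[str]:
    """Members of the gene set actually measured in the dataset, in dataset
    gene order.  Its length is the set's *effective size*."""
    return [g for g in dataset.gene_ids if g in gene_set.genes]


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup
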