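"""Randomized control collections: biologically meaningless gene sets matched
to a genuine collection in set count and cardinality distribution."""

from __future__ import annotations

import numpy as np

from .core import GeneSet, GeneSetCollection

__all__ = ["gene_pool", "randomize_collection"]


def gene_pool(collection: GeneSetCollection) -> frozenset[str]:
    """The pooled gene universe: union of all genes occurring in some member
    set of the collection."""
    if len(collection) == 0:
        raise ValueError("empty collection has no gene pool")
    return collection.gene_pool()


def randomize_collection(collection: GeneSetCollection, seed: int) -> GeneSetCollection:
    """Size-matched random counterpart of a genuine collection.

    For every genuine set of size ``|Γ|``, draws ``|Γ|`` genes uniformly
    without replacement from the pooled gene universe Σ.  Draws are
    independent across sets (a gene may recur in many random sets, as in
    the genuine collection).  Names are suffixed ``_RND``; deterministic
    under ``seed``.
    """
    pool = sorted(gene_pool(collection))
    rng = np.random.default_rng(seed)
    out: list[GeneSet] = []
    for s in collection:
        if len(s) > len(pool):
            raise ValueError(
                f"gene set {s.name!r} is larger than the gene pool ({len(pool)})"
            )
        picked = rng.choice(len(pool), size=len(s), replace=False)
        out.append(
            GeneSet(
                name=s.name + "_RND",
                genes=frozenset(pool[i] for i in picked),
                category=s.category,
                description=s.description,
            )
        )
    return GeneSetCollection(out)
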