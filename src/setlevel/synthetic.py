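"""Synthetic binary-class expression data with planted set-level signal.

The generator emulates the statistical structure the set-level framework
assumes: a genes × samples matrix of normalized expressions where a known
subset of gene sets carries (a) a class-dependent mean shift of ``delta``
expression units on its member genes and (b) within-set equicorrelation
``rho`` induced by a shared latent factor,

    x = sigma * (sqrt(rho) * z_set + sqrt(1 - rho) * eps),

so every gene has variance ``sigma**2`` and every within-set gene pair has
correlation ``rho``.  Background genes are i.i.d. Normal(0, sigma^2).
Gene sets occupy disjoint gene blocks by default (an overlap fraction can
re-use genes between consecutive sets).  Matched null data are the same
construction with ``delta = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ExpressionDataset, GeneSet, GeneSetCollection

__all__ = ["SyntheticSpec", "generate", "generate_null"]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study condition.

    Defaults give a moderately easy two-class problem: 30 + 30 samples,
    200 sets of 5–50 genes over their own gene blocks plus background
    genes, 3 signal sets with a one-sd mean shift (``delta = 1``,
    ``sigma = 1``) and within-set correlation 0.3.
    """

    p: int = 12_000               # total genes (must cover all set blocks)
    n0: int = 30                  # class-0 samples
    n1: int = 30                  # class-1 samples
    n_sets: int = 200             # collection size
    set_size_min: int = 5
    set_size_max: int = 50
    sizes: list[int] | None = None  # explicit sizes (e.g. copied from a template)
    n_signal: int = 3             # planted signal sets
    delta: float = 1.0            # class-1 mean shift per signal gene
    rho: float = 0.3              # within-set equicorrelation
    sigma: float = 1.0            # noise sd
    overlap: float = 0.0          # fraction of each set's genes shared with the previous set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal > self.n_sets:
            raise ValueError("n_signal cannot exceed n_sets")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must lie in [0, 1)")
        if self.sizes is not None and len(self.sizes) != self.n_sets:
            raise ValueError("sizes must have one entry per set")
        if not (1 <= self.set_size_min <= self.set_size_max):
            raise ValueError("invalid set size range")


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, GeneSetCollection, list[str]]:
    """Generate (dataset, collection, signal set names) for one spec.

    Deterministic under ``spec.seed``.  The first ``n_signal`` sets carry
    the class shift; their names are returned as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n0 + spec.n1
    if spec.sizes is not None:
        sizes = list(spec.sizes)
    else:
        sizes = list(
            rng.integers(spec.set_size_min, spec.set_size_max + 1, size=spec.n_sets)
        )

    # Assign gene blocks; with overlap > 0 a set re-uses a prefix of the
    # previous set's genes.
    blocks: list[np.ndarray] = []
    cursor = 0
    prev: np.ndarray | None = None
    for size in sizes:
        n_shared = int(round(spec.overlap * size)) if prev is not None else 0
        n_shared = min(n_shared, len(prev)) if prev is not None else 0
        fresh = size - n_shared
        block = np.concatenate(
            [prev[:n_shared] if n_shared else np.empty(0, dtype=int),
             np.arange(cursor, cursor + fresh)]
        ).astype(int)
        cursor += fresh
        blocks.append(block)
        prev = block
    if spec.p < cursor:
        raise ValueError(
            f"p={spec.p} too small for the requested sets ({cursor} genes needed)"
        )
    p = spec.p

    gene_ids = [f"g{j:05d}" for j in range(p)]
    sample_ids = [f"s{i:03d}" for i in range(n)]
    labels = {s: (0 if i < spec.n0 else 1) for i, s in enumerate(sample_ids)}
    y = np.array([labels[s] for s in sample_ids])

    values = rng.standard_normal((p, n)) * spec.sigma
    if spec.rho > 0:
        factor_scale = np.sqrt(spec.rho) * spec.sigma
        noise_scale = np.sqrt(1.0 - spec.rho)
        seen = np.zeros(p, dtype=bool)
        for block in blocks:
            z = rng.standard_normal(n) * factor_scale
            fresh = block[~seen[block]]
            # genes shared with a previous set keep that set's factor
            values[fresh] = values[fresh] * noise_scale + z
            seen[fresh] = True

    signal_names: list[str] = []
    sets: list[GeneSet] = []
    shifted = np.zeros(p, dtype=bool)  # guard against double shifts under overlap
    for k, block in enumerate(blocks):
        name = f"SET{k:04d}"
        if k < spec.n_signal and spec.delta != 0.0:
            fresh = block[~shifted[block]]
            values[np.ix_(fresh, np.nonzero(y == 1)[0])] += spec.delta
            shifted[fresh] = True
        if k < spec.n_signal:
            signal_names.append(name)
        sets.append(GeneSet(name=name, genes=frozenset(gene_ids[j] for j in block)))
    if spec.delta == 0.0:
        signal_names = []

    dataset = ExpressionDataset(gene_ids, sample_ids, values, labels)
    return dataset, GeneSetCollection(sets), signal_names


def generate_null(spec: SyntheticSpec) -> tuple[ExpressionDataset, GeneSetCollection, list[str]]:
    """Matched no-signal data: ``generate`` with ``delta`` forced to 0; the
    ground-truth list is empty and labels are independent of the data."""
    null_spec = SyntheticSpec(**{**spec.__dict__, "delta": 0.0})
    return generate(null_spec)
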