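"""Core domain types shared across the pipeline.

The central container is :class:`ExpressionMatrix`, a log2-scale
gene-by-sample matrix backed by a pandas DataFrame, optionally carrying a
group/subtype label per sample.  Gene sets and bidirectional (up/down)
signatures are small immutable records with their invariants enforced at
construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "BidirectionalSignature",
    "OrthologMap",
]


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, genes in rows, samples in columns.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
        Values must be finite; missing values are rejected because every
        downstream statistic (ranking, enrichment walks, correlation) is
        undefined on gaps.
    annotations
        Optional mapping sample id -> group label; when present it must
        cover every sample.
    """

    values: pd.DataFrame
    annotations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            n_bad = int((~np.isfinite(arr)).sum())
            raise ValueError(
                f"{n_bad} non-finite expression value(s); "
                "missing values are not allowed"
            )
        if self.annotations is not None:
            missing = [s for s in cols if s not in self.annotations]
            if missing:
                raise ValueError(
                    f"annotations missing for sample(s): {missing[:5]}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_labels(self) -> list[str]:
        """Labels in sample-column order; requires annotations."""
        if self.annotations is None:
            raise ValueError("matrix carries no sample annotations")
        return [self.annotations[s] for s in self.sample_ids]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        ann = None
        if self.annotations is not None:
            ann = {s: self.annotations[s] for s in sample_ids}
        return ExpressionMatrix(self.values[list(sample_ids)], ann)

    def with_annotations(self, labels: list[str]) -> "ExpressionMatrix":
        """Attach labels given in sample-column order (CLS style)."""
        if len(labels) != self.n_samples:
            raise ValueError(
                f"{len(labels)} labels for {self.n_samples} samples"
            )
        return ExpressionMatrix(
            self.values, dict(zip(self.sample_ids, labels))
        )


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene identifiers."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


@dataclass(frozen=True)
class BidirectionalSignature:
    """Paired up- and down-regulated gene sets with derivation provenance.

    The two directions must be disjoint and non-empty: a gene cannot be
    simultaneously enriched and depleted in the same contrast.
    """

    name: str
    up: GeneSet
    down: GeneSet
    provenance: str = ""

    def __post_init__(self) -> None:
        shared = self.up.genes & self.down.genes
        if shared:
            raise ValueError(
                f"signature {self.name!r}: up/down overlap: {sorted(shared)[:5]}"
            )

    def swapped(self) -> "BidirectionalSignature":
        """Exchange the up and down directions (used by antisymmetry tests)."""
        return BidirectionalSignature(
            name=self.name + "_swapped",
            up=self.down,
            down=self.up,
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class OrthologMap:
    """Source-species gene id -> non-empty set of target-species gene ids."""

    pairs: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for src, targets in self.pairs.items():
            targets = frozenset(targets)
            if not targets:
                raise ValueError(f"ortholog entry {src!r} has no targets")
            clean[src] = targets
        object.__setattr__(self, "pairs", clean)

    def targets(self, gene: str) -> frozenset[str]:
        return self.pairs.get(gene, frozenset())

    def __len__(self) -> int:
        return len(self.pairs)
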