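"""Gene-ranking metrics, the fold-change DE filter, and BH adjustment.

Genes are ranked between two phenotype classes with the signal-to-noise
statistic (mu_A - mu_B) / (sigma_A + sigma_B), each class standard deviation
floored at 0.2 * |mu| (absolute floor 0.2 when mu = 0) to prevent division
blow-ups on near-constant genes.  Differential-expression gene sets are
defined by a strict linear fold-change cut (default > 2) on log2-scale
input; Welch-test p-values and their BH adjustment are reported alongside
but do not gate membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionMatrix, GeneSet

__all__ = [
    "RankedList",
    "signal_to_noise",
    "rank_genes",
    "fold_change_filter",
    "bh_adjust",
]


@dataclass(frozen=True)
class RankedList:
    """Genes ordered best-first with their ranking metric values."""

    genes: tuple[str, ...]
    metric: tuple[float, ...]
    tie_rule: str = "lexicographic gene id"

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if len(self.genes) < 2:
            raise ValueError("a ranked list needs at least 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        m = np.asarray(self.metric)
        if (np.diff(m) > 0).any():
            raise ValueError("metric must be non-increasing along the order")

    def __len__(self) -> int:
        return len(self.genes)

    def position(self, gene: str) -> int:
        """1-based rank of a gene."""
        return self.genes.index(gene) + 1

    def reversed(self) -> "RankedList":
        return RankedList(
            genes=self.genes[::-1],
            metric=tuple(-m for m in self.metric[::-1]),
            tie_rule=self.tie_rule,
        )


def _floored_std(x: np.ndarray) -> float:
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    floor = 0.2 * abs(mu) if mu != 0 else 0.2
    return max(sd, floor)


def signal_to_noise(a: np.ndarray, b: np.ndarray) -> float:
    """(mu_A - mu_B) / (sigma_A + sigma_B) with floored class deviations."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 samples")
    return (float(np.mean(a)) - float(np.mean(b))) / (
        _floored_std(a) + _floored_std(b)
    )


def _two_class_split(
    matrix: ExpressionMatrix, labels: list[str], class_a: str | None = None
) -> tuple[np.ndarray, np.ndarray, str, str]:
    if len(labels) != matrix.n_samples:
        raise ValueError(
            f"{len(labels)} labels for {matrix.n_samples} samples"
        )
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"expected exactly 2 classes, got {classes}")
    if class_a is None:
        class_a = classes[0]
    elif class_a not in classes:
        raise ValueError(f"class_a {class_a!r} not among {classes}")
    class_b = next(c for c in classes if c != class_a)
    mask_a = np.array([l == class_a for l in labels])
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    arr = matrix.values.to_numpy()
    return arr[:, mask_a], arr[:, ~mask_a], class_a, class_b


def rank_genes(
    matrix: ExpressionMatrix,
    labels: list[str],
    metric: str = "signal_to_noise",
    class_a: str | None = None,
) -> RankedList:
    """Rank all genes by a two-class metric, best (class-A-high) first.

    ``class_a`` names the phenotype whose upregulation ranks a gene at the
    top (e.g. the tumor class); by default the lexicographically first
    label.  Ties are broken by gene id for determinism.
    """
    if metric != "signal_to_noise":
        raise ValueError(f"unknown metric {metric!r}")
    va, vb, _, _ = _two_class_split(matrix, labels, class_a)
    mu_a = va.mean(axis=1)
    mu_b = vb.mean(axis=1)
    sd_a = va.std(axis=1, ddof=1)
    sd_b = vb.std(axis=1, ddof=1)
    sd_a = np.maximum(sd_a, np.where(mu_a != 0, 0.2 * np.abs(mu_a), 0.2))
    sd_b = np.maximum(sd_b, np.where(mu_b != 0, 0.2 * np.abs(mu_b), 0.2))
    m = (mu_a - mu_b) / (sd_a + sd_b)
    genes = np.asarray(matrix.gene_ids)
    order = np.lexsort((genes, -m))
    return RankedList(
        genes=tuple(genes[order]), metric=tuple(float(x) for x in m[order])
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, monotone and capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change_filter(
    matrix: ExpressionMatrix,
    labels: list[str],
    fc_threshold: float = 2.0,
    class_a: str | None = None,
    set_prefix: str = "DE",
) -> tuple[GeneSet, GeneSet, pd.DataFrame]:
    """Differential-expression gene sets by a strict linear fold-change cut.

    On log2-scale input, log2FC = mean(class A) - mean(class B); a gene is
    ``up`` when log2FC > log2(threshold) and ``down`` when
    log2FC < -log2(threshold), both strict.  Welch-test p and BH-adjusted p
    are reported in the table but never decide membership.  A direction
    with no passing gene is returned as None (gene sets are non-empty by
    construction).
    """
    if fc_threshold <= 1:
        raise ValueError("fold-change threshold must exceed 1")
    va, vb, name_a, name_b = _two_class_split(matrix, labels, class_a)
    log2fc = va.mean(axis=1) - vb.mean(axis=1)
    cut = np.log2(fc_threshold)
    up_mask = log2fc > cut
    down_mask = log2fc < -cut
    p = stats.ttest_ind(va, vb, axis=1, equal_var=False).pvalue
    p = np.nan_to_num(p, nan=1.0)  # zero-variance identical rows
    p_adj = bh_adjust(p)
    direction = np.where(up_mask, "up", np.where(down_mask, "down", "ns"))
    table = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "direction": direction,
        }
    ).set_index("gene")
    genes = np.asarray(matrix.gene_ids)
    desc = f"{name_a} vs {name_b}, |linear FC| > {fc_threshold}"
    up = frozenset(genes[up_mask])
    down = frozenset(genes[down_mask])
    up_set = GeneSet(f"{set_prefix}_UP", up, desc) if up else None
    down_set = GeneSet(f"{set_prefix}_DN", down, desc) if down else None
    return up_set, down_set, table
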