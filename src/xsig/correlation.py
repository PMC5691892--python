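"""Pairwise expression-correlation matrices with exact critical-r
significance.

For n samples, the two-sided Pearson test at level alpha is significant
exactly when |r| exceeds the critical value solving
t = r * sqrt((n - 2) / (1 - r^2)) = t_{1 - alpha/2, n-2}; flagging by
|r| > r_crit and by p < alpha are therefore the same rule, and both are
computed and cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ExpressionMatrix
from .ranking import bh_adjust

__all__ = ["CorrelationResult", "critical_r", "correlation_matrix"]


@dataclass
class CorrelationResult:
    """Symmetric Pearson r / p matrices over a gene panel."""

    panel: list[str]
    n: int
    r: pd.DataFrame
    p: pd.DataFrame
    r_crit: float
    alpha: float
    significant: pd.DataFrame  # boolean, |r| > r_crit off the diagonal

    def pair(self, g1: str, g2: str) -> tuple[float, float, bool]:
        return (
            float(self.r.loc[g1, g2]),
            float(self.p.loc[g1, g2]),
            bool(self.significant.loc[g1, g2]),
        )

    def write_tsv(self, prefix) -> None:
        self.r.to_csv(f"{prefix}_r.tsv", sep="\t")
        self.p.to_csv(f"{prefix}_p.tsv", sep="\t")
        self.significant.astype(int).to_csv(
            f"{prefix}_significant.tsv", sep="\t"
        )


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at level alpha in a two-sided test.

    Inverts the t transform: r_crit = t_c / sqrt(t_c^2 + n - 2) with
    t_c = t_{1 - alpha/2, n - 2}.  Strictly decreasing in n.
    """
    if n < 4:
        raise ValueError("need at least 4 samples")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    t_c = stats.t.ppf(1 - alpha / 2, n - 2)
    return float(t_c / np.sqrt(t_c**2 + n - 2))


def correlation_matrix(
    matrix: ExpressionMatrix,
    panel: list[str],
    alpha: float = 0.05,
    bh: bool = False,
) -> CorrelationResult:
    """Pairwise Pearson correlation over a gene panel.

    Significance is per pair at |r| > critical_r(n, alpha), equivalently
    p < alpha, with no correction across the matrix by default (each pair
    is reported on its own, as in a correlogram); ``bh=True`` switches the
    flag to BH-adjusted p < alpha.
    """
    missing = [g for g in panel if g not in matrix.values.index]
    if missing:
        raise ValueError(f"panel gene(s) not in matrix: {missing[:5]}")
    if len(panel) < 2:
        raise ValueError("panel needs at least 2 genes")
    n = matrix.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples")
    sub = matrix.values.loc[panel].to_numpy()
    sds = sub.std(axis=1)
    for g, sd in zip(panel, sds):
        if sd == 0:
            raise ValueError(f"gene {g!r} has zero variance")
    r = np.corrcoef(sub)
    np.fill_diagonal(r, 1.0)
    r_clip = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r_clip * np.sqrt((n - 2) / (1.0 - r_clip**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    np.fill_diagonal(p, 0.0)
    r_crit = critical_r(n, alpha)
    if bh:
        iu = np.triu_indices(len(panel), k=1)
        adj = bh_adjust(p[iu])
        p_adj = np.zeros_like(p)
        p_adj[iu] = adj
        p_adj = p_adj + p_adj.T
        sig = p_adj < alpha
    else:
        sig = np.abs(r) > r_crit
    np.fill_diagonal(sig, False)
    idx = pd.Index(panel)
    return CorrelationResult(
        panel=list(panel),
        n=n,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        r_crit=r_crit,
        alpha=alpha,
        significant=pd.DataFrame(sig, index=idx, columns=idx),
    )
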