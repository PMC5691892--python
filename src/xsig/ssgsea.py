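"""Single-sample GSEA, cohort normalization, the bidirectional fit score,
threshold classification, and group-level statistics.

Per sample, genes are ranked by that sample's expression (rank 1 = highest,
ties broken by gene id).  With r_i = N - rank_i + 1, in-set positions carry
step weights r_i^alpha normalized to sum 1; out-of-set positions carry
1/(N - k).  The raw score is the sum over all positions of the difference
between the in-set and out-of-set empirical CDFs.  Raw scores are
normalized by the pooled (samples x directions) score range within one
dataset, and the fit score of a bidirectional signature is the normalized
up score minus the normalized down score: a single per-sample measure of
simultaneous enrichment of the up genes and depletion of the down genes.
Samples classify as high (fit > 0.40), moderate (0.25 < fit <= 0.40), or
none — strict inequalities on both thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datamodel import BidirectionalSignature, ExpressionMatrix, GeneSet

__all__ = [
    "FitScoreTable",
    "GroupComparison",
    "ssgsea_score",
    "normalize_scores",
    "fit_score",
    "classify_fit",
    "compare_groups",
]

MODERATE_THRESHOLD = 0.25
HIGH_THRESHOLD = 0.40


@dataclass
class FitScoreTable:
    """Per-sample raw/normalized direction scores, fit score, and class.

    ``table`` columns: sample, group (if annotated), up_es, down_es,
    up_norm, down_norm, fit, fit_class.
    """

    table: pd.DataFrame
    signature_name: str
    alpha: float
    normalization_span: float
    moderate_threshold: float = MODERATE_THRESHOLD
    high_threshold: float = HIGH_THRESHOLD

    @property
    def fit(self) -> pd.Series:
        return self.table["fit"]

    @property
    def fit_class(self) -> pd.Series:
        return self.table["fit_class"]

    def positive_samples(self) -> list[str]:
        """Samples with moderate or high signature fit."""
        mask = self.table["fit_class"].isin(["moderate", "high"])
        return self.table.index[mask].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample")


@dataclass
class GroupComparison:
    """Bartlett, one-way ANOVA, and Tukey HSD results on one variable."""

    bartlett_stat: float
    bartlett_p: float
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # group1, group2, diff, p_adj per unordered pair
    group_means: dict[str, float]

    def tukey_p(self, g1: str, g2: str) -> float:
        t = self.tukey
        row = t[((t.group1 == g1) & (t.group2 == g2))
                | ((t.group1 == g2) & (t.group2 == g1))]
        if row.empty:
            raise KeyError(f"no Tukey pair ({g1}, {g2})")
        return float(row.iloc[0].p_adj)


def _sample_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices sorting one sample's genes descending, ties by gene id."""
    return np.lexsort((gene_ids, -values))


def ssgsea_score(
    matrix: ExpressionMatrix, gene_set: GeneSet, alpha: float = 0.25
) -> pd.Series:
    """Raw single-sample enrichment score per sample.

    Rank-only dependence: any strictly increasing transform of one
    sample's expression leaves that sample's score unchanged.
    """
    gene_ids = np.asarray(matrix.gene_ids)
    in_set = np.isin(gene_ids, sorted(gene_set.genes))
    n = len(gene_ids)
    k = int(in_set.sum())
    if k == 0:
        raise ValueError(
            f"set {gene_set.name!r} does not intersect the matrix"
        )
    if k == n:
        raise ValueError(f"set {gene_set.name!r} covers every gene")
    arr = matrix.values.to_numpy()
    scores = np.empty(matrix.n_samples)
    for j in range(matrix.n_samples):
        order = _sample_order(arr[:, j], gene_ids)
        hits = in_set[order]
        # r = N - rank + 1: N for the top gene, 1 for the bottom one
        r = np.arange(n, 0, -1, dtype=float)
        w = np.where(hits, r ** alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~hits) / (n - k)
        scores[j] = float(np.sum(p_in - p_out))
    return pd.Series(scores, index=matrix.sample_ids, name=gene_set.name)


def normalize_scores(raw: np.ndarray) -> tuple[np.ndarray, float]:
    """Divide pooled raw scores by their global range (max - min).

    Returns the normalized values and the span used, which is recorded in
    output metadata.  Scale-free: multiplying every raw score by c > 0
    leaves the normalized values unchanged.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least 2 raw scores to normalize")
    span = float(raw.max() - raw.min())
    if span == 0:
        raise ValueError("zero score span: all raw scores identical")
    return raw / span, span


def classify_fit(
    fit: float,
    moderate: float = MODERATE_THRESHOLD,
    high: float = HIGH_THRESHOLD,
) -> str:
    """Strict-threshold class: high (> high), moderate (> moderate), none."""
    if fit > high:
        return "high"
    if fit > moderate:
        return "moderate"
    return "none"


def fit_score(
    sig: BidirectionalSignature,
    matrix: ExpressionMatrix,
    alpha: float = 0.25,
    moderate: float = MODERATE_THRESHOLD,
    high: float = HIGH_THRESHOLD,
) -> FitScoreTable:
    """Bidirectional fit score per sample.

    fit = normalized up score - normalized down score, the two directions
    normalized jointly by the pooled score range of the dataset; classes
    assigned by strict thresholds.
    """
    up_raw = ssgsea_score(matrix, sig.up, alpha)
    down_raw = ssgsea_score(matrix, sig.down, alpha)
    pooled = np.concatenate([up_raw.to_numpy(), down_raw.to_numpy()])
    normed, span = normalize_scores(pooled)
    n = matrix.n_samples
    up_norm, down_norm = normed[:n], normed[n:]
    fit = up_norm - down_norm
    classes = [classify_fit(f, moderate, high) for f in fit]
    table = pd.DataFrame(
        {
            "group": (
                matrix.group_labels()
                if matrix.annotations is not None
                else [""] * n
            ),
            "up_es": up_raw.to_numpy(),
            "down_es": down_raw.to_numpy(),
            "up_norm": up_norm,
            "down_norm": down_norm,
            "fit": fit,
            "fit_class": classes,
        },
        index=pd.Index(matrix.sample_ids, name="sample"),
    )
    return FitScoreTable(
        table=table,
        signature_name=sig.name,
        alpha=alpha,
        normalization_span=span,
        moderate_threshold=moderate,
        high_threshold=high,
    )


def compare_groups(
    values: pd.Series | np.ndarray, groups: list[str]
) -> GroupComparison:
    """Bartlett homogeneity, one-way ANOVA, and Tukey HSD across groups."""
    values = np.asarray(values, dtype=float)
    groups = list(groups)
    if len(values) != len(groups):
        raise ValueError("values and group labels differ in length")
    names = sorted(set(groups))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    by_group = [
        values[np.array([g == name for g in groups])] for name in names
    ]
    for name, v in zip(names, by_group):
        if len(v) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    bart = stats.bartlett(*by_group)
    anova = stats.f_oneway(*by_group)
    res = pairwise_tukeyhsd(values, groups)
    tukey = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.lower().replace("-", "_") for c in res.summary().data[0]],
    )[["group1", "group2", "meandiff", "p_adj"]]
    tukey.columns = ["group1", "group2", "diff", "p_adj"]
    tukey["p_adj"] = res.pvalues  # full precision, not the rounded summary
    tukey["diff"] = res.meandiffs
    return GroupComparison(
        bartlett_stat=float(bart.statistic),
        bartlett_p=float(bart.pvalue),
        anova_f=float(anova.statistic),
        anova_p=float(anova.pvalue),
        tukey=tukey,
        group_means={n: float(np.mean(v)) for n, v in zip(names, by_group)},
    )
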