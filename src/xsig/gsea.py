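"""Weighted Kolmogorov-Smirnov gene set enrichment analysis.

The running-sum statistic walks a metric-ranked gene list: at a set member
("hit") it rises by |m_i|^p / N_R (N_R the sum of |m|^p over hits), at a
non-member it falls by 1 / (N - N_H).  The enrichment score ES is the
signed value of the running sum at its point of maximal absolute deviation
from zero.  Significance comes from a gene-permutation null (random
same-size gene subsets), NES rescales ES by the mean magnitude of same-sign
null scores, and the FDR q pools normalized null scores across all tested
sets.  The leading edge (core enrichment) is the set members at or before
the running-sum extremum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import GeneSet
from .ranking import RankedList

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "enrichment_score",
    "gene_permutation_test",
    "leading_edge",
]

_NULL_PERM_CHUNK = 512  # permutations scored per vectorized block


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment statistics for one gene set against one ranked list."""

    set_name: str
    es: float
    nes: float  # NaN when no same-sign null score exists
    p: float    # NaN when no same-sign null score exists
    q: float
    peak_position: int  # 1-based index of the running-sum extremum
    leading_edge: tuple[str, ...]
    n_perm: int
    seed: int | None
    size: int  # set members present in the ranked list

    def __post_init__(self) -> None:
        if self.es != 0 and not np.isnan(self.nes):
            if np.sign(self.nes) != np.sign(self.es):
                raise ValueError("NES sign must match ES sign")
        for name in ("p", "q"):
            v = getattr(self, name)
            if not np.isnan(v) and not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0, 1]")


def _hit_mask(ranked: RankedList, gene_set: GeneSet) -> np.ndarray:
    in_set = np.array([g in gene_set.genes for g in ranked.genes])
    n_absent = len(gene_set) - int(in_set.sum())
    if n_absent:
        logger.info(
            "set %r: %d gene(s) absent from the ranked list ignored",
            gene_set.name, n_absent,
        )
        if in_set.sum() < 0.5 * len(gene_set):
            logger.warning(
                "set %r: fewer than half its genes are in the ranked list",
                gene_set.name,
            )
    return in_set


def _running_sum(
    metric: np.ndarray, hits: np.ndarray, weight_p: float
) -> np.ndarray:
    n = len(metric)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the whole ranked list")
    w = np.where(hits, np.abs(metric) ** weight_p, 0.0)
    nr = w.sum()
    if nr == 0:
        raise ValueError(
            "all hit weights are zero (N_R = 0); "
            "use weight_p = 0 or a non-degenerate metric"
        )
    steps = np.where(hits, w / nr, -1.0 / (n - n_hits))
    return np.cumsum(steps)


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_p: float = 1.0
) -> tuple[float, int, np.ndarray]:
    """ES, 1-based peak position, and the full running sum.

    The extremum is the first position attaining the maximal |running sum|
    (deterministic tie-break).
    """
    metric = np.asarray(ranked.metric)
    hits = _hit_mask(ranked, gene_set)
    run = _running_sum(metric, hits, weight_p)
    # earliest position within float tolerance of the maximal deviation
    dev = np.abs(run)
    peak = int(np.flatnonzero(dev >= dev.max() - 1e-12)[0])
    return float(run[peak]), peak + 1, run


def leading_edge(
    ranked: RankedList,
    gene_set: GeneSet,
    es: float,
    peak_position: int,
) -> tuple[str, ...]:
    """Core-enrichment genes for an already-computed enrichment score.

    For ES > 0: set members at positions <= peak, in rank order.  For
    ES < 0: members at positions >= peak, in reverse-rank order (most
    depleted first).  ES == 0 yields an empty list with a warning.
    """
    if es == 0:
        logger.warning(
            "set %r: ES == 0, leading edge empty", gene_set.name
        )
        return ()
    genes = ranked.genes
    if es > 0:
        members = [g for g in genes[:peak_position] if g in gene_set.genes]
    else:
        members = [
            g for g in genes[peak_position - 1:] if g in gene_set.genes
        ][::-1]
    return tuple(members)


def _null_es(
    metric_abs_p: np.ndarray,
    k: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """ES of ``n_perm`` uniformly drawn size-k gene subsets (vectorized)."""
    n = len(metric_abs_p)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(_NULL_PERM_CHUNK, n_perm - done)
        # random size-k subsets via partial argsort of uniform keys
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        hits = np.zeros((m, n), dtype=bool)
        hits[np.arange(m)[:, None], idx] = True
        w = np.where(hits, metric_abs_p[None, :], 0.0)
        nr = w.sum(axis=1, keepdims=True)
        steps = np.where(hits, w / nr, -1.0 / (n - k))
        run = np.cumsum(steps, axis=1)
        peaks = np.argmax(np.abs(run), axis=1)
        out[done:done + m] = run[np.arange(m), peaks]
        done += m
    return out


def _same_sign_p_nes(
    es: float, null: np.ndarray
) -> tuple[float, float]:
    """Add-one sign-matched permutation p and NES for one set."""
    if es >= 0:
        tail = null[null > 0]
        extreme = int((tail >= es).sum())
    else:
        tail = null[null < 0]
        extreme = int((tail <= es).sum())
    if tail.size == 0:
        return np.nan, np.nan
    p = (1 + extreme) / (1 + tail.size)
    nes = es / float(np.mean(np.abs(tail)))
    return p, nes


def _normalize_null(null: np.ndarray) -> np.ndarray:
    """Null ES rescaled by the same-sign null mean magnitude (null NES)."""
    out = np.full(null.shape, np.nan)
    pos = null > 0
    neg = null < 0
    if pos.any():
        out[pos] = null[pos] / np.mean(null[pos])
    if neg.any():
        out[neg] = -null[neg] / np.mean(null[neg])
    out[null == 0] = 0.0
    return out


def _pooled_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """NES-based pooled-null FDR across all tested sets.

    q(NES*) = [fraction of pooled null NES at least as extreme, same sign]
            / [fraction of observed NES at least as extreme, same sign],
    clipped to [0, 1].
    """
    null_nes = null_nes[np.isfinite(null_nes)]
    q = np.full(obs_nes.shape, np.nan)
    finite_obs = obs_nes[np.isfinite(obs_nes)]
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_frac_denom = int((null_nes >= 0).sum())
            null_frac_num = int((null_nes >= nes).sum())
            obs_denom = int((finite_obs >= 0).sum())
            obs_num = int((finite_obs >= nes).sum())
        else:
            null_frac_denom = int((null_nes < 0).sum())
            null_frac_num = int((null_nes <= nes).sum())
            obs_denom = int((finite_obs < 0).sum())
            obs_num = int((finite_obs <= nes).sum())
        if null_frac_denom == 0 or obs_num == 0:
            q[i] = np.nan
            continue
        null_frac = null_frac_num / null_frac_denom
        obs_frac = obs_num / obs_denom
        q[i] = min(1.0, null_frac / obs_frac)
    return q


def gene_permutation_test(
    ranked: RankedList,
    sets: list[GeneSet],
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """GSEA of several sets against one ranked list with a shared null.

    The null for a size-k set is the ES distribution of n_perm uniformly
    drawn size-k gene subsets (gene-label permutation).  p is the add-one
    sign-matched tail estimate; NES divides ES by the mean magnitude of
    same-sign null scores; q pools normalized null scores across all sets.
    When a single set is tested, q = p (logged).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    metric = np.asarray(ranked.metric)
    metric_abs_p = np.abs(metric) ** weight_p

    es_list, peak_list, le_list, size_list = [], [], [], []
    p_list, nes_list, null_nes_pool = [], [], []
    for gs in sets:
        es, peak, _ = enrichment_score(ranked, gs, weight_p)
        hits = _hit_mask(ranked, gs)
        k = int(hits.sum())
        null = _null_es(metric_abs_p, k, n_perm, rng)
        p, nes = _same_sign_p_nes(es, null)
        if np.isnan(p):
            logger.warning(
                "set %r: no same-sign null ES; p and NES undefined", gs.name
            )
        es_list.append(es)
        peak_list.append(peak)
        size_list.append(k)
        le_list.append(leading_edge(ranked, gs, es, peak))
        p_list.append(p)
        nes_list.append(nes)
        null_nes_pool.append(_normalize_null(null))

    obs_nes = np.array(nes_list)
    if len(sets) == 1:
        logger.info("single set tested: q reported as p")
        q = np.array(p_list)
    else:
        q = _pooled_fdr(obs_nes, np.concatenate(null_nes_pool))

    return [
        EnrichmentResult(
            set_name=gs.name,
            es=es_list[i],
            nes=float(obs_nes[i]),
            p=float(p_list[i]),
            q=float(q[i]),
            peak_position=peak_list[i],
            leading_edge=le_list[i],
            n_perm=n_perm,
            seed=seed,
            size=size_list[i],
        )
        for i, gs in enumerate(sets)
    ]


def results_to_tsv(results: list[EnrichmentResult], path) -> None:
    """Write enrichment results as a TSV table."""
    with open(path, "w") as fh:
        fh.write(
            "set\tsize\tES\tNES\tp\tq\tpeak_position\tleading_edge\n"
        )
        for r in results:
            fh.write(
                f"{r.set_name}\t{r.size}\t{r.es:.6g}\t{r.nes:.6g}\t"
                f"{r.p:.6g}\t{r.q:.6g}\t{r.peak_position}\t"
                + ",".join(r.leading_edge) + "\n"
            )
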