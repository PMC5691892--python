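"""Two-stage cross-study signature construction.

Stage 1 (shared signature): GSEA of a second study's differentially
expressed up/down gene sets against the first study's tumor-vs-control
ranking; the leading edges (core enrichment) of the two runs become the
shared bidirectional signature — the genes co-deregulated in both models.

Stage 2 (tumor-specific refinement): GSEA of the shared up and down sets
against an undifferentiated-vs-differentiated T-cell development ranking;
genes in the same-direction development leading edge are attributed to
normal developmental stage rather than transformation and removed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

from .datamodel import BidirectionalSignature, GeneSet
from .gsea import EnrichmentResult, gene_permutation_test
from .ranking import RankedList

logger = logging.getLogger(__name__)

__all__ = [
    "GseaParams",
    "derive_shared_signature",
    "refine_tumor_specific",
]


@dataclass(frozen=True)
class GseaParams:
    """Permutation-test settings shared by all signature-building runs."""

    n_perm: int = 1000
    weight_p: float = 1.0
    seed: int | None = None
    # optional FDR gate on development-association (default: leading-edge
    # membership alone decides)
    refine_q_max: float | None = None


def _provenance(tag: str, results: list[EnrichmentResult]) -> str:
    return json.dumps(
        {
            tag: [
                {
                    "set": r.set_name,
                    "ES": round(r.es, 6),
                    "NES": round(r.nes, 6),
                    "p": round(r.p, 6),
                    "q": round(r.q, 6),
                    "size": r.size,
                    "n_perm": r.n_perm,
                    "seed": r.seed,
                }
                for r in results
            ]
        }
    )


def derive_shared_signature(
    ranked_study_a: RankedList,
    de_up: GeneSet,
    de_down: GeneSet,
    params: GseaParams = GseaParams(),
    name: str = "SHARED",
) -> BidirectionalSignature:
    """Shared cross-study signature from GSEA leading edges.

    The up (down) direction of the result is the leading edge of the second
    study's up (down) DE set on the first study's ranking.  The up set must
    enrich at the top (ES > 0) and the down set at the bottom (ES < 0);
    a wrong-sign or zero ES is an error naming the direction.  Genes landing
    in both leading edges are dropped from both (disjointness).
    """
    res_up, res_down = gene_permutation_test(
        ranked_study_a,
        [de_up, de_down],
        n_perm=params.n_perm,
        weight_p=params.weight_p,
        seed=params.seed,
    )
    if res_up.es <= 0:
        raise ValueError(
            f"up direction: DE set {de_up.name!r} has ES = {res_up.es:.4g} "
            "<= 0 on the study-A ranking; no shared up signature"
        )
    if res_down.es >= 0:
        raise ValueError(
            f"down direction: DE set {de_down.name!r} has "
            f"ES = {res_down.es:.4g} >= 0 on the study-A ranking; "
            "no shared down signature"
        )
    up = set(res_up.leading_edge)
    down = set(res_down.leading_edge)
    shared = up & down
    if shared:
        logger.warning(
            "shared signature: %d gene(s) in both leading edges dropped: %s",
            len(shared), sorted(shared)[:5],
        )
        up -= shared
        down -= shared
    if not up or not down:
        raise ValueError(
            f"{'up' if not up else 'down'} leading edge empty after "
            "disjointness enforcement"
        )
    return BidirectionalSignature(
        name=name,
        up=GeneSet(f"{name}_UP", frozenset(up), "shared leading edge, up"),
        down=GeneSet(
            f"{name}_DN", frozenset(down), "shared leading edge, down"
        ),
        provenance=_provenance("shared", [res_up, res_down]),
    )


def refine_tumor_specific(
    shared: BidirectionalSignature,
    dev_ranked: RankedList,
    params: GseaParams = GseaParams(),
    name: str | None = None,
) -> BidirectionalSignature:
    """Remove development-associated genes from a shared signature.

    ``dev_ranked`` must rank an undifferentiated-vs-differentiated healthy
    T-cell contrast (undifferentiated high first).  A signature gene counts
    as development-associated when it belongs to the same-direction leading
    edge of the signature's GSEA on that ranking (up set enriched at the
    top, down set at the bottom).  When ``params.refine_q_max`` is set, a
    development run additionally needs q <= refine_q_max for its leading
    edge to trigger removal at all.
    """
    name = name or shared.name + "_TS"
    res_up, res_down = gene_permutation_test(
        dev_ranked,
        [shared.up, shared.down],
        n_perm=params.n_perm,
        weight_p=params.weight_p,
        seed=params.seed,
    )

    def _dev_edge(res: EnrichmentResult, want_positive: bool) -> set[str]:
        if want_positive and res.es <= 0:
            return set()
        if not want_positive and res.es >= 0:
            return set()
        if params.refine_q_max is not None and not (
            res.q <= params.refine_q_max
        ):
            return set()
        return set(res.leading_edge)

    drop_up = _dev_edge(res_up, want_positive=True)
    drop_down = _dev_edge(res_down, want_positive=False)
    if drop_up or drop_down:
        logger.info(
            "tumor-specific refinement removed %d up / %d down "
            "development-associated gene(s): up=%s down=%s",
            len(drop_up), len(drop_down),
            sorted(drop_up), sorted(drop_down),
        )
    up = shared.up.genes - drop_up
    down = shared.down.genes - drop_down
    if not up or not down:
        raise ValueError(
            f"{'up' if not up else 'down'} direction emptied by "
            "development refinement"
        )
    return BidirectionalSignature(
        name=name,
        up=GeneSet(f"{name}_UP", frozenset(up), "tumor-specific, up"),
        down=GeneSet(f"{name}_DN", frozenset(down), "tumor-specific, down"),
        provenance=(
            shared.provenance
            + " | "
            + _provenance("development_refinement", [res_up, res_down])
            + f" | removed_up={sorted(drop_up)}"
            + f" removed_down={sorted(drop_down)}"
        ),
    )
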