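"""End-to-end orchestration: mouse stage -> signature -> human stage ->
three-criteria triage.

The mouse stage derives the cross-study signature: a fold-change DE filter
on the second mouse study defines up/down gene sets, GSEA of those sets on
the primary study's tumor-vs-control signal-to-noise ranking yields the
shared leading-edge signature, and a development-contrast GSEA refines it
to a tumor-specific signature.  The human stage maps the signature across
species, fit-scores every patient sample, and nominates candidate subtypes
that pass all three classification criteria: (1) significantly lower VAV1
abundance than at least one other subtype (Tukey HSD at 0.05), (2)
significant signature enrichment of the subtype's fit scores (highest mean
fit, Tukey-significant against every other subtype), and (3) a significant
inverse VAV1-HES1 correlation within the subtype's signature-positive
samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .correlation import correlation_matrix
from .datamodel import BidirectionalSignature, ExpressionMatrix
from .io import map_orthologs, write_gmt
from .ranking import fold_change_filter, rank_genes
from .signature import GseaParams, derive_shared_signature, \
    refine_tumor_specific
from .simulate import StudyBundle
from .ssgsea import FitScoreTable, compare_groups, fit_score

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineParams",
    "SubtypeVerdict",
    "TriageReport",
    "run_mouse_stage",
    "run_human_stage",
    "run_all",
]

DEFAULT_PANEL = ["VAV1", "HES1", "TLX1", "TLX3"]


@dataclass(frozen=True)
class PipelineParams:
    """Every tunable default of the analysis in one place."""

    fc_threshold: float = 2.0
    n_perm: int = 1000
    weight_p: float = 1.0
    alpha_ssgsea: float = 0.25
    moderate_threshold: float = 0.25
    high_threshold: float = 0.40
    alpha_tests: float = 0.05
    top_leading: int = 25
    seed: int | None = None
    tumor_class: str = "tumor"

    def gsea_params(self) -> GseaParams:
        return GseaParams(
            n_perm=self.n_perm, weight_p=self.weight_p, seed=self.seed
        )


@dataclass
class SubtypeVerdict:
    """Three-criteria outcome for one subtype in one dataset."""

    subtype: str
    n_samples: int
    mean_fit: float
    n_moderate: int
    n_high: int
    low_vav1: bool
    signature_enriched: bool
    inverse_vav1_hes1: bool | None  # None = not evaluable (< 4 positives)
    vav1_hes1_r: float | None
    is_candidate: bool


@dataclass
class TriageReport:
    """Per-dataset verdicts plus the overall candidate subtypes."""

    verdicts: dict[str, list[SubtypeVerdict]]  # dataset -> verdicts
    candidates: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.candidates:
            self.candidates = {
                ds: [v.subtype for v in vs if v.is_candidate]
                for ds, vs in self.verdicts.items()
            }

    def consensus_candidates(self) -> list[str]:
        """Subtypes nominated in every dataset."""
        sets = [set(c) for c in self.candidates.values()]
        return sorted(set.intersection(*sets)) if sets else []

    def to_json(self, path: str | Path) -> None:
        payload = {
            ds: [
                {
                    "subtype": v.subtype,
                    "n_samples": v.n_samples,
                    "mean_fit": v.mean_fit,
                    "n_moderate": v.n_moderate,
                    "n_high": v.n_high,
                    "low_vav1": v.low_vav1,
                    "signature_enriched": v.signature_enriched,
                    "inverse_vav1_hes1": v.inverse_vav1_hes1,
                    "vav1_hes1_r": v.vav1_hes1_r,
                    "is_candidate": v.is_candidate,
                }
                for v in vs
            ]
            for ds, vs in self.verdicts.items()
        }
        with open(path, "w") as fh:
            json.dump(
                {"verdicts": payload, "candidates": self.candidates},
                fh, indent=1,
            )


def _tumor_vs_control_labels(
    matrix: ExpressionMatrix, control_group: str, tumor_class: str
) -> list[str]:
    """Collapse all non-control groups into one tumor class."""
    return [
        control_group if g == control_group else tumor_class
        for g in matrix.group_labels()
    ]


def run_mouse_stage(
    bundle: StudyBundle,
    params: PipelineParams = PipelineParams(),
    outdir: str | Path | None = None,
) -> tuple[BidirectionalSignature, BidirectionalSignature, FitScoreTable]:
    """Derive the shared and tumor-specific signatures from the mouse data.

    Returns (shared signature, tumor-specific signature, fit table of the
    tumor-specific signature on the held-out second mouse study).
    """
    stage = "fold-change filter (study B)"
    try:
        b_labels = bundle.mouse_matrix_b.group_labels()
        # knockout class is the non-control group of study B
        b_classes = sorted(set(b_labels))
        ko = b_classes[1] if b_classes[0] == "control" else b_classes[0]
        de_up, de_down, de_table = fold_change_filter(
            bundle.mouse_matrix_b, b_labels,
            fc_threshold=params.fc_threshold, class_a=ko,
        )
        if de_up is None or de_down is None:
            raise ValueError("a DE direction is empty in study B")

        stage = "signal-to-noise ranking (study A)"
        a_labels = _tumor_vs_control_labels(
            bundle.mouse_matrix_a, "no_tumor", params.tumor_class
        )
        ranked_a = rank_genes(
            bundle.mouse_matrix_a, a_labels, class_a=params.tumor_class
        )

        stage = "shared signature derivation"
        shared = derive_shared_signature(
            ranked_a, de_up, de_down, params.gsea_params(), name="SHARED"
        )

        stage = "tumor-specific refinement"
        dev_labels = bundle.dev_matrix.group_labels()
        ranked_dev = rank_genes(
            bundle.dev_matrix, dev_labels, class_a="undifferentiated"
        )
        tumor_specific = refine_tumor_specific(
            shared, ranked_dev, params.gsea_params()
        )

        stage = "mouse fit scoring (study B held out)"
        fit_b = fit_score(
            tumor_specific, bundle.mouse_matrix_b,
            alpha=params.alpha_ssgsea,
            moderate=params.moderate_threshold,
            high=params.high_threshold,
        )
    except Exception as exc:
        raise RuntimeError(f"mouse stage failed at: {stage}") from exc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        de_table.to_csv(outdir / "study_b_de.tsv", sep="\t")
        for sig, stem in ((shared, "shared"), (tumor_specific,
                                               "tumor_specific")):
            write_gmt([sig.up, sig.down], outdir / f"{stem}_signature.gmt")
            with open(outdir / f"{stem}_provenance.json", "w") as fh:
                fh.write(sig.provenance + "\n")
        fit_b.to_tsv(outdir / "mouse_fit.tsv")
    return shared, tumor_specific, fit_b


def _judge_subtype(
    subtype: str,
    matrix: ExpressionMatrix,
    fit_table: FitScoreTable,
    params: PipelineParams,
    panel: list[str],
) -> SubtypeVerdict:
    labels = matrix.group_labels()
    others = sorted(set(labels) - {subtype})
    alpha = params.alpha_tests
    fit = fit_table.table

    # criterion 1: VAV1 significantly lower than >= 1 other subtype
    vav1 = matrix.values.loc["VAV1"]
    cmp_vav1 = compare_groups(vav1.to_numpy(), labels)
    low_vav1 = any(
        cmp_vav1.group_means[subtype] < cmp_vav1.group_means[o]
        and cmp_vav1.tukey_p(subtype, o) < alpha
        for o in others
    )

    # criterion 2: highest mean fit, Tukey-significant vs every other
    cmp_fit = compare_groups(fit["fit"].to_numpy(), labels)
    enriched = all(
        cmp_fit.group_means[subtype] > cmp_fit.group_means[o]
        and cmp_fit.tukey_p(subtype, o) < alpha
        for o in others
    )

    # criterion 3: inverse VAV1-HES1 correlation among this subtype's
    # signature-positive samples
    sub_samples = [
        s for s, g in zip(matrix.sample_ids, labels) if g == subtype
    ]
    positives = [
        s for s in fit_table.positive_samples() if s in set(sub_samples)
    ]
    inverse: bool | None
    r_val: float | None
    if len(positives) < 4:
        logger.info(
            "subtype %s: only %d signature-positive sample(s); "
            "correlation criterion not evaluable", subtype, len(positives),
        )
        inverse, r_val = None, None
    else:
        corr = correlation_matrix(
            matrix.subset_samples(positives), panel, alpha=alpha
        )
        r, _, sig = corr.pair("VAV1", "HES1")
        inverse = bool(sig and r < 0)
        r_val = r
    sub_fit = fit.loc[fit["group"] == subtype]
    return SubtypeVerdict(
        subtype=subtype,
        n_samples=len(sub_samples),
        mean_fit=float(sub_fit["fit"].mean()),
        n_moderate=int((sub_fit["fit_class"] == "moderate").sum()),
        n_high=int((sub_fit["fit_class"] == "high").sum()),
        low_vav1=low_vav1,
        signature_enriched=enriched,
        inverse_vav1_hes1=inverse,
        vav1_hes1_r=r_val,
        is_candidate=bool(low_vav1 and enriched and inverse),
    )


def run_human_stage(
    signature: BidirectionalSignature,
    bundle: StudyBundle,
    params: PipelineParams = PipelineParams(),
    panel: list[str] | None = None,
    outdir: str | Path | None = None,
) -> TriageReport:
    """Map the signature onto the human cohorts and run the triage."""
    panel = panel or DEFAULT_PANEL
    human_sig = map_orthologs(signature, bundle.ortholog_map)
    verdicts: dict[str, list[SubtypeVerdict]] = {}
    for ds_name, matrix in bundle.human_matrices.items():
        ft = fit_score(
            human_sig, matrix,
            alpha=params.alpha_ssgsea,
            moderate=params.moderate_threshold,
            high=params.high_threshold,
        )
        subtypes = sorted(set(matrix.group_labels()))
        verdicts[ds_name] = [
            _judge_subtype(st, matrix, ft, params, panel)
            for st in subtypes
        ]
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            ft.to_tsv(Path(outdir) / f"{ds_name}_fit.tsv")
    report = TriageReport(verdicts=verdicts)
    if outdir is not None:
        report.to_json(Path(outdir) / "triage_report.json")
    return report


def run_all(
    bundle: StudyBundle,
    params: PipelineParams = PipelineParams(),
    outdir: str | Path | None = None,
) -> tuple[BidirectionalSignature, BidirectionalSignature, FitScoreTable,
           TriageReport]:
    """Full pipeline: mouse stage then human stage."""
    shared, tumor_specific, fit_b = run_mouse_stage(bundle, params, outdir)
    report = run_human_stage(
        tumor_specific, bundle, params, outdir=outdir
    )
    return shared, tumor_specific, fit_b, report
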