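"""Synthetic two-species study bundles with the statistical structure the
pipeline assumes.

The generator emulates, on the log2 scale with Gaussian noise:

* a primary mouse tumor study (study A) with three groups — no-tumor,
  DN tumor, CD8+ tumor — sharing a "common" block of up/down deregulated
  genes in both tumor groups;
* a second mouse knockout study (study B) whose differential expression
  partially overlaps study A's common block;
* a healthy T-cell development contrast (undifferentiated vs
  differentiated) that deregulates a confounder subset of the shared
  genes, mimicking signature genes attributable to developmental stage
  rather than transformation;
* three human leukemia cohorts (64, 52 and 124 patients) split into
  immature / TLX / TAL1 molecular subtypes, where exactly one subtype
  carries the ortholog-mapped (non-confounder) signature, a VAV1
  down-shift, high TLX1/TLX3 marker abundance, and a bivariate-normal
  VAV1/HES1 pair with a configured inverse correlation.

Every draw traces to the single config seed; identical configs give
bitwise-identical bundles.  A complete truth record (which gene plays
which role, with its true effect) accompanies each bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import ExpressionMatrix, OrthologMap
from .io import (
    write_cls,
    write_gct,
    write_ortholog_table,
)

__all__ = ["SimConfig", "StudyBundle", "simulate_study",
           "simulate_null_dataset"]

MARKERS = ("VAV1", "HES1", "TLX1", "TLX3")


def _default_mouse_groups() -> dict[str, int]:
    return {"no_tumor": 3, "dn_tumor": 3, "cd8_tumor": 3}


def _default_study_b_groups() -> dict[str, int]:
    return {"control": 4, "dko": 4}


def _default_dev_groups() -> dict[str, int]:
    return {"undifferentiated": 4, "differentiated": 4}


def _default_human_cohorts() -> dict[str, dict[str, int]]:
    # cohort totals 64 / 52 / 124 split across the three molecular subtypes
    return {
        "dataset1": {"immature": 16, "TLX": 22, "TAL1": 26},
        "dataset2": {"immature": 14, "TLX": 18, "TAL1": 20},
        "dataset3": {"immature": 32, "TLX": 42, "TAL1": 50},
    }


@dataclass
class SimConfig:
    """Generator settings; the defaults are the study conditions."""

    seed: int = 0
    n_genes: int = 1500
    mouse_groups: dict[str, int] = field(
        default_factory=_default_mouse_groups
    )
    study_b_groups: dict[str, int] = field(
        default_factory=_default_study_b_groups
    )
    dev_groups: dict[str, int] = field(default_factory=_default_dev_groups)
    human_cohorts: dict[str, dict[str, int]] = field(
        default_factory=_default_human_cohorts
    )
    n_signature_up: int = 60
    n_signature_down: int = 60
    overlap_fraction: float = 0.7
    n_dev_confounders: int = 12  # split evenly across directions
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5  # log2 units
    vav1_hes1_r: float = -0.8
    vav1_shift: float = 1.5  # VAV1 depression in the positive subtype
    marker_shift: float = 3.0  # TLX1/TLX3 elevation in the positive subtype
    positive_subtype: str = "TLX"

    def __post_init__(self) -> None:
        for grp in (
            self.mouse_groups, self.study_b_groups, self.dev_groups,
            *self.human_cohorts.values(),
        ):
            for name, size in grp.items():
                if size < 2:
                    raise ValueError(f"group {name!r} needs >= 2 samples")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not -1 < self.vav1_hes1_r < 1:
            raise ValueError("vav1_hes1_r must lie in (-1, 1)")
        n_blocks = self.n_signature_up + self.n_signature_down
        if n_blocks * 2 > self.n_genes:
            raise ValueError("signature blocks exceed half of n_genes")
        if self.n_dev_confounders % 2:
            raise ValueError("n_dev_confounders must be even")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TruthRecord:
    """Which synthetic gene plays which role, with true effect sizes."""

    up_genes: list[str]            # study A common up block (mouse ids)
    down_genes: list[str]
    shared_up: list[str]           # also deregulated in study B
    shared_down: list[str]
    b_only_up: list[str]           # study-B-specific deregulation
    b_only_down: list[str]
    confounder_up: list[str]       # shared genes also tied to development
    confounder_down: list[str]
    human_up: list[str]            # human images embedded in the subtype
    human_down: list[str]
    positive_subtype: str
    effect_log2fc: float
    vav1_hes1_r: float

    @property
    def embedded_up(self) -> list[str]:
        """Shared up genes that are genuinely tumor-specific."""
        return [g for g in self.shared_up if g not in self.confounder_up]

    @property
    def embedded_down(self) -> list[str]:
        return [
            g for g in self.shared_down if g not in self.confounder_down
        ]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class StudyBundle:
    """All matrices, the ortholog map, and the ground truth of one run."""

    config: SimConfig
    mouse_matrix_a: ExpressionMatrix
    mouse_matrix_b: ExpressionMatrix
    dev_matrix: ExpressionMatrix
    human_matrices: dict[str, ExpressionMatrix]
    ortholog_map: OrthologMap
    truth: TruthRecord

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        named = {
            "mouse_study_a": self.mouse_matrix_a,
            "mouse_study_b": self.mouse_matrix_b,
            "dev_contrast": self.dev_matrix,
            **{f"human_{k}": v for k, v in self.human_matrices.items()},
        }
        for stem, m in named.items():
            write_gct(m, outdir / f"{stem}.gct")
            write_cls(m.group_labels(), outdir / f"{stem}.cls")
        write_ortholog_table(self.ortholog_map, outdir / "orthologs.tsv")
        self.truth.to_json(outdir / "truth.json")
        self.config.to_yaml(outdir / "config.yaml")


def _mouse_gene_ids(n: int) -> list[str]:
    # Title-case mouse symbols; human images are their uppercase forms
    return [f"Simg{i:04d}" for i in range(1, n + 1)]


def _cohort_matrix(
    rng: np.random.Generator,
    gene_ids: list[str],
    baseline: np.ndarray,
    groups: dict[str, int],
    shifts: dict[str, dict[str, float]],
    noise_sd: float,
    sample_prefix: str,
) -> ExpressionMatrix:
    """Gaussian log2 matrix: baseline + per-group gene shifts + noise."""
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    cols, labels = [], []
    data = []
    for group, size in groups.items():
        mean = baseline.copy()
        for gene, delta in shifts.get(group, {}).items():
            mean[gene_index[gene]] += delta
        block = rng.normal(
            mean[:, None], noise_sd, size=(len(gene_ids), size)
        )
        data.append(block)
        start = len(cols)
        cols += [f"{sample_prefix}_{group}_{start + j + 1:03d}"
                 for j in range(size)]
        labels += [group] * size
    values = pd.DataFrame(
        np.concatenate(data, axis=1), index=gene_ids, columns=cols
    )
    return ExpressionMatrix(values, dict(zip(cols, labels)))


def simulate_null_dataset(
    n_genes: int, n_samples: int, seed: int | None = None,
    noise_sd: float = 0.5,
) -> ExpressionMatrix:
    """Pure i.i.d. noise around gene-specific baselines; no structure."""
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    rng = np.random.default_rng(seed)
    gene_ids = _mouse_gene_ids(n_genes)
    baseline = rng.uniform(4, 12, n_genes)
    values = rng.normal(
        baseline[:, None], noise_sd, size=(n_genes, n_samples)
    )
    cols = [f"null_{j + 1:03d}" for j in range(n_samples)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=cols)
    )


def _bivariate(
    rng: np.random.Generator,
    mean_x: float,
    mean_y: float,
    sd: float,
    rho: float,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    cov = sd**2 * np.array([[1.0, rho], [rho, 1.0]])
    draws = rng.multivariate_normal([mean_x, mean_y], cov, size=n)
    return draws[:, 0], draws[:, 1]


def simulate_study(config: SimConfig) -> StudyBundle:
    """Generate a complete two-species bundle from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = _mouse_gene_ids(n)
    baseline = rng.uniform(4, 12, n)
    eff = config.effect_log2fc

    # -- role assignment ---------------------------------------------------
    n_up, n_down = config.n_signature_up, config.n_signature_down
    roles = rng.choice(n, size=2 * (n_up + n_down), replace=False)
    up_idx = roles[:n_up]
    down_idx = roles[n_up:n_up + n_down]
    b_extra = roles[n_up + n_down:]
    up_genes = [gene_ids[i] for i in up_idx]
    down_genes = [gene_ids[i] for i in down_idx]

    n_shared_up = int(round(config.overlap_fraction * n_up))
    n_shared_down = int(round(config.overlap_fraction * n_down))
    shared_up = up_genes[:n_shared_up]
    shared_down = down_genes[:n_shared_down]
    b_only_up = [gene_ids[i] for i in b_extra[: n_up - n_shared_up]]
    b_only_down = [
        gene_ids[i]
        for i in b_extra[n_up - n_shared_up:
                         (n_up - n_shared_up) + (n_down - n_shared_down)]
    ]
    n_conf = config.n_dev_confounders // 2
    confounder_up = shared_up[:n_conf]
    confounder_down = shared_down[:n_conf]

    # -- study A: three mouse groups, common tumor block -------------------
    a_shifts_tumor = {g: eff for g in up_genes}
    a_shifts_tumor.update({g: -eff for g in down_genes})
    mouse_a = _cohort_matrix(
        rng, gene_ids, baseline, config.mouse_groups,
        {"dn_tumor": a_shifts_tumor, "cd8_tumor": a_shifts_tumor},
        config.noise_sd, "mA",
    )

    # -- study B: overlapping knockout deregulation ------------------------
    b_shifts = {g: eff for g in shared_up + b_only_up}
    b_shifts.update({g: -eff for g in shared_down + b_only_down})
    mouse_b = _cohort_matrix(
        rng, gene_ids, baseline, config.study_b_groups,
        {"dko": b_shifts}, config.noise_sd, "mB",
    )

    # -- development contrast: confounders only ----------------------------
    dev_shifts = {g: eff for g in confounder_up}
    dev_shifts.update({g: -eff for g in confounder_down})
    dev = _cohort_matrix(
        rng, gene_ids, baseline, config.dev_groups,
        {"undifferentiated": dev_shifts}, config.noise_sd, "dev",
    )

    # -- ortholog map: Title-case mouse -> uppercase human, 1:1 ------------
    omap = OrthologMap({g: frozenset({g.upper()}) for g in gene_ids})

    # -- human cohorts ------------------------------------------------------
    human_up = [g.upper() for g in shared_up if g not in confounder_up]
    human_down = [
        g.upper() for g in shared_down if g not in confounder_down
    ]
    human_gene_ids = [g.upper() for g in gene_ids] + list(MARKERS)
    marker_base = {"VAV1": 9.0, "HES1": 8.0, "TLX1": 5.0, "TLX3": 5.0}
    human_baseline = np.concatenate(
        [baseline, [marker_base[m] for m in MARKERS]]
    )
    pos = config.positive_subtype
    pos_shifts = {g: eff for g in human_up}
    pos_shifts.update({g: -eff for g in human_down})
    pos_shifts["VAV1"] = -config.vav1_shift
    pos_shifts["HES1"] = config.vav1_shift

    human_matrices: dict[str, ExpressionMatrix] = {}
    for ds_name, subtypes in config.human_cohorts.items():
        if pos not in subtypes:
            raise ValueError(
                f"{ds_name}: positive subtype {pos!r} not among {subtypes}"
            )
        m = _cohort_matrix(
            rng, human_gene_ids, human_baseline, subtypes,
            {pos: pos_shifts}, config.noise_sd, ds_name,
        )
        # overwrite the VAV1/HES1 pair of the positive subtype with a
        # correlated bivariate draw at the configured rho
        pos_samples = [
            s for s in m.sample_ids if m.annotations[s] == pos
        ]
        vav1, hes1 = _bivariate(
            rng,
            marker_base["VAV1"] - config.vav1_shift,
            marker_base["HES1"] + config.vav1_shift,
            config.noise_sd,
            config.vav1_hes1_r,
            len(pos_samples),
        )
        m.values.loc["VAV1", pos_samples] = vav1
        m.values.loc["HES1", pos_samples] = hes1
        # TLX-high labeling rule: each positive sample is high in TLX1 or
        # TLX3 (never both), as in marker-based subtype calling
        which = rng.random(len(pos_samples)) < 0.5
        tlx1 = m.values.loc["TLX1", pos_samples].to_numpy()
        tlx3 = m.values.loc["TLX3", pos_samples].to_numpy()
        m.values.loc["TLX1", pos_samples] = np.where(
            which, tlx1 + config.marker_shift, tlx1
        )
        m.values.loc["TLX3", pos_samples] = np.where(
            which, tlx3, tlx3 + config.marker_shift
        )
        human_matrices[ds_name] = m

    truth = TruthRecord(
        up_genes=up_genes,
        down_genes=down_genes,
        shared_up=shared_up,
        shared_down=shared_down,
        b_only_up=b_only_up,
        b_only_down=b_only_down,
        confounder_up=confounder_up,
        confounder_down=confounder_down,
        human_up=human_up,
        human_down=human_down,
        positive_subtype=pos,
        effect_log2fc=eff,
        vav1_hes1_r=config.vav1_hes1_r,
    )
    return StudyBundle(
        config=config,
        mouse_matrix_a=mouse_a,
        mouse_matrix_b=mouse_b,
        dev_matrix=dev,
        human_matrices=human_matrices,
        ortholog_map=omap,
        truth=truth,
    )
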