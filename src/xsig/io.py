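"""Readers and writers for the GCT 1.2, GMT, CLS and ortholog-table formats,
plus probe-to-gene collapsing and cross-species signature mapping.

All parsers reject files that violate their declared dialect with a
:class:`ParseError` naming the offending line.  ``write_* o read_*`` is the
identity up to float formatting.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    BidirectionalSignature,
    ExpressionMatrix,
    GeneSet,
    OrthologMap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_gct",
    "write_gct",
    "read_gmt",
    "write_gmt",
    "read_cls",
    "write_cls",
    "read_ortholog_table",
    "write_ortholog_table",
    "collapse_probes",
    "map_orthologs",
    "uppercase_genes",
]


class ParseError(ValueError):
    """A file violated its declared dialect; the message names the line."""


def read_gct(path: str | Path) -> ExpressionMatrix:
    """Read a GCT 1.2 file (header ``#1.2``, declared row/column counts)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        got = lines[0].strip() if lines else "<empty file>"
        raise ParseError(f"{path}:1: expected GCT header '#1.2', got {got!r}")
    try:
        n_genes, n_samples = (int(x) for x in lines[1].split("\t")[:2])
    except (IndexError, ValueError) as exc:
        raise ParseError(
            f"{path}:2: expected tab-separated row and column counts"
        ) from exc
    header = lines[2].split("\t")
    if len(header) != n_samples + 2:
        raise ParseError(
            f"{path}:3: expected NAME, Description and {n_samples} sample "
            f"columns, found {len(header)} fields"
        )
    sample_ids = header[2:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}:3: duplicate sample ids")
    data_lines = [ln for ln in lines[3:] if ln.strip()]
    if len(data_lines) != n_genes:
        raise ParseError(
            f"{path}:2: declared {n_genes} rows but found {len(data_lines)}"
        )
    gene_ids: list[str] = []
    seen: set[str] = set()
    rows = np.empty((n_genes, n_samples))
    for i, ln in enumerate(data_lines):
        lineno = i + 4
        fields = ln.split("\t")
        if len(fields) != n_samples + 2:
            raise ParseError(
                f"{path}:{lineno}: expected {n_samples + 2} fields, "
                f"found {len(fields)}"
            )
        gid = fields[0]
        if gid in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene id {gid!r}")
        seen.add(gid)
        gene_ids.append(gid)
        try:
            rows[i] = [float(x) for x in fields[2:]]
        except ValueError as exc:
            raise ParseError(
                f"{path}:{lineno}: non-numeric expression value"
            ) from exc
    values = pd.DataFrame(rows, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(values)


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("NAME\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in matrix.values.iterrows():
            vals = "\t".join(repr(float(v)) for v in row.to_numpy())
            fh.write(f"{gid}\tna\t{vals}\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one gene set per line, name / description / genes."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for i, ln in enumerate(fh):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{i + 1}: expected >= 3 tab-separated fields "
                    f"(name, description, genes...), found {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if len(set(genes)) != len(genes):
                logger.warning(
                    "%s:%d: duplicate genes in set %r deduplicated",
                    path, i + 1, name,
                )
            sets.append(GeneSet(name=name, genes=frozenset(genes),
                                description=desc))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            desc = s.description or "na"
            fh.write("\t".join([s.name, desc] + s.sorted_genes()) + "\n")


def read_cls(path: str | Path) -> list[str]:
    """Read a categorical CLS file and return one label per sample.

    Both dialects of the third line are accepted: numeric class indices
    into the declared class names, or the class names themselves.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh.read().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ParseError(f"{path}:1: CLS file needs 3 non-empty lines")
    head = lines[0].split()
    try:
        n_samples, n_classes = int(head[0]), int(head[1])
    except (IndexError, ValueError) as exc:
        raise ParseError(
            f"{path}:1: expected 'N_samples N_classes 1'"
        ) from exc
    names_line = lines[1].split()
    if not names_line or names_line[0] != "#":
        raise ParseError(f"{path}:2: expected '# name1 ... nameK'")
    class_names = names_line[1:]
    if len(class_names) != n_classes:
        raise ParseError(
            f"{path}:2: declared {n_classes} classes, "
            f"found {len(class_names)} names"
        )
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise ParseError(
            f"{path}:3: declared {n_samples} samples, "
            f"found {len(tokens)} labels"
        )
    if all(t.isdigit() for t in tokens):
        idx = [int(t) for t in tokens]
        if max(idx) >= n_classes:
            raise ParseError(
                f"{path}:3: class index {max(idx)} out of range"
            )
        return [class_names[i] for i in idx]
    unknown = sorted(set(tokens) - set(class_names))
    if unknown:
        raise ParseError(
            f"{path}:3: label(s) {unknown[:5]} not among declared class names"
        )
    return tokens


def write_cls(labels: list[str], path: str | Path) -> None:
    names = list(dict.fromkeys(labels))  # first-appearance order
    index = {n: i for i, n in enumerate(names)}
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} {len(names)} 1\n")
        fh.write("# " + " ".join(names) + "\n")
        fh.write(" ".join(str(index[l]) for l in labels) + "\n")


def read_ortholog_table(path: str | Path) -> OrthologMap:
    """Read a TSV with columns source_id, target_id (header required)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source_id", "target_id"):
        if col not in df.columns:
            raise ParseError(f"{path}:1: missing required column {col!r}")
    pairs: dict[str, set[str]] = {}
    for src, tgt in zip(df["source_id"], df["target_id"]):
        pairs.setdefault(src, set()).add(tgt)
    return OrthologMap({k: frozenset(v) for k, v in pairs.items()})


def write_ortholog_table(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source_id\ttarget_id\n")
        for src in sorted(omap.pairs):
            for tgt in sorted(omap.pairs[src]):
                fh.write(f"{src}\t{tgt}\n")


def collapse_probes(
    matrix: ExpressionMatrix, probe_to_gene: dict[str, str]
) -> ExpressionMatrix:
    """Collapse probe-level rows to gene level.

    For genes measured by several probes, the probe with the highest mean
    expression across samples is retained (the common GSEA convention, and
    deterministic).  Probes with no mapping are dropped with a logged count.
    """
    mapped = [p for p in matrix.gene_ids if p in probe_to_gene]
    n_dropped = matrix.n_genes - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probe(s)", n_dropped)
    if not mapped:
        raise ValueError("no probe maps to a gene symbol")
    sub = matrix.values.loc[mapped]
    means = sub.mean(axis=1)
    best: dict[str, str] = {}
    for probe in mapped:
        gene = probe_to_gene[probe]
        cur = best.get(gene)
        # max-mean rule; ties broken by lexicographic probe id
        if (
            cur is None
            or means[probe] > means[cur]
            or (means[probe] == means[cur] and probe < cur)
        ):
            best[gene] = probe
    genes = sorted(best)
    out = sub.loc[[best[g] for g in genes]]
    out.index = genes
    return ExpressionMatrix(out, matrix.annotations)


def uppercase_genes(genes: frozenset[str] | set[str]) -> frozenset[str]:
    """Explicit uppercase normalization (mouse Title-case -> human symbols).

    Matching stays case-sensitive elsewhere; silent case-folding would hide
    mapping errors.
    """
    return frozenset(g.upper() for g in genes)


def map_orthologs(
    sig: BidirectionalSignature, omap: OrthologMap
) -> BidirectionalSignature:
    """Map a signature across species through an ortholog table.

    Each source gene expands to all its targets; genes without orthologs are
    dropped and logged.  A target reached from both directions is dropped
    from both (conservative, order-independent conflict rule).
    """
    def _expand(gs: GeneSet) -> tuple[set[str], int]:
        out: set[str] = set()
        lost = 0
        for g in sorted(gs.genes):
            t = omap.targets(g)
            if t:
                out |= t
            else:
                lost += 1
        return out, lost

    up, up_lost = _expand(sig.up)
    down, down_lost = _expand(sig.down)
    if up_lost or down_lost:
        logger.info(
            "map_orthologs(%s): %d up / %d down gene(s) had no ortholog",
            sig.name, up_lost, down_lost,
        )
    conflicts = up & down
    if conflicts:
        logger.warning(
            "map_orthologs(%s): %d target(s) reached from both directions "
            "dropped: %s",
            sig.name, len(conflicts), sorted(conflicts)[:5],
        )
        up -= conflicts
        down -= conflicts
    if not up or not down:
        raise ValueError(
            f"ortholog mapping of {sig.name!r} emptied the "
            f"{'up' if not up else 'down'} direction"
        )
    return BidirectionalSignature(
        name=sig.name,
        up=GeneSet(sig.up.name, frozenset(up), sig.up.description),
        down=GeneSet(sig.down.name, frozenset(down), sig.down.description),
        provenance=sig.provenance + " | ortholog-mapped",
    )
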