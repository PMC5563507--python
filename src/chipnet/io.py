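"""Readers and writers for the standard formats the pipeline touches.

Formats covered: narrowPeak / plain BED peak files, BED6 and minimal GTF
gene annotation, tab-separated differential-expression tables, GMT gene
sets, RNK ranked lists, and the flat edge/node TSVs that Cytoscape
imports natively.

All readers fail fast on structural violations (they never silently
repair); all writers are deterministic — identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import pandas as pd

from .genomic import GeneModel, GenomicInterval, Peak

if TYPE_CHECKING:  # pragma: no cover
    from .enrichment import GeneSet, RankedList
    from .network import RegulatoryNetwork

__all__ = [
    "DERecord",
    "ParseError",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gene_models",
    "write_bed6",
    "read_de_table",
    "write_de_table",
    "write_network_table",
    "read_gmt",
    "write_gmt",
    "read_rnk",
    "write_rnk",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression result in one contrast."""

    gene_id: str
    log2fc: float
    pvalue: float
    fdr: float
    contrast: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"{self.gene_id}: p-value {self.pvalue} outside [0, 1]")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"{self.gene_id}: FDR {self.fdr} outside [0, 1]")


def _fmt(x: float) -> str:
    """Deterministic, round-trippable float formatting."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# Peaks


def read_narrowpeak(path: str, source: str | None = None) -> list[Peak]:
    """Read peaks from a narrowPeak (BED6+4) or plain BED file.

    narrowPeak summits are ``start + column-10 offset``; a ``-1`` offset
    (summit not called) and plain BED lines fall back to the interval
    midpoint (floor).  ``source`` defaults to the file's base name.
    """
    if source is None:
        source = os.path.basename(path)
        for suffix in (".narrowPeak", ".narrowpeak", ".bed"):
            if source.endswith(suffix):
                source = source[: -len(suffix)]
                break
    peaks: list[Peak] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: fewer than 3 columns at line {lineno}")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ParseError(
                    f"{path}: non-integer coordinates at line {lineno}"
                ) from None
            if start >= end:
                raise ParseError(f"{path}: start >= end at line {lineno}")
            name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else None
            score = 0.0
            summit = (start + end) // 2
            if len(cols) >= 10:
                try:
                    offset = int(cols[9])
                except ValueError:
                    raise ParseError(
                        f"{path}: non-integer summit offset at line {lineno}"
                    ) from None
                if offset >= 0:
                    summit = start + offset
                    if not (start <= summit < end):
                        raise ParseError(
                            f"{path}: summit offset outside interval at line {lineno}"
                        )
                try:
                    score = float(cols[8])  # -log10 q-value column
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric q-value column at line {lineno}"
                    ) from None
            elif len(cols) >= 5:
                try:
                    score = float(cols[4])
                except ValueError:
                    score = 0.0
            peak_id = name if name is not None else f"{source}_peak{lineno}"
            if peak_id in seen_ids:
                raise ParseError(f"{path}: duplicate peak id {peak_id!r} at line {lineno}")
            seen_ids.add(peak_id)
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end),
                    summit=summit,
                    score=score,
                    source=source,
                    peak_id=peak_id,
                )
            )
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path: str) -> None:
    """Write peaks as narrowPeak (summit stored as the column-10 offset)."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        p.peak_id,
                        "0",
                        ".",
                        "0",
                        "-1",
                        _fmt(p.score),
                        str(p.summit - iv.start),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene annotation


def read_gene_models(path: str, dialect: str = "bed6") -> list[GeneModel]:
    """Read gene bodies from BED6 or a minimal GTF.

    For GTF input the gene body is the union span (min start, max end)
    over all records sharing one ``gene_id``; a gene spanning multiple
    chromosomes or strands is an error.
    """
    if dialect == "bed6":
        genes: list[GeneModel] = []
        seen: set[str] = set()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                cols = line.split("\t")
                if len(cols) < 6:
                    raise ParseError(f"{path}: BED6 needs 6 columns at line {lineno}")
                try:
                    start, end = int(cols[1]), int(cols[2])
                except ValueError:
                    raise ParseError(
                        f"{path}: non-integer coordinates at line {lineno}"
                    ) from None
                gene_id = cols[3]
                if gene_id in seen:
                    raise ParseError(f"{path}: duplicate gene_id {gene_id!r}")
                seen.add(gene_id)
                genes.append(
                    GeneModel(
                        gene_id=gene_id,
                        symbol=gene_id,
                        body=GenomicInterval(cols[0], start, end),
                        strand=cols[5],
                    )
                )
    elif dialect == "gtf":
        spans: dict[str, list] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 9:
                    raise ParseError(f"{path}: GTF needs 9 columns at line {lineno}")
                attrs = cols[8]
                gene_id = None
                for field_ in attrs.split(";"):
                    field_ = field_.strip()
                    if field_.startswith("gene_id"):
                        gene_id = field_.split(None, 1)[1].strip().strip('"')
                        break
                if gene_id is None:
                    raise ParseError(f"{path}: missing gene_id attribute at line {lineno}")
                start = int(cols[3]) - 1  # GTF is 1-based inclusive
                end = int(cols[4])
                entry = spans.setdefault(
                    gene_id, [cols[0], start, end, cols[6], set()]
                )
                entry[4].add((cols[0], cols[6]))
                entry[1] = min(entry[1], start)
                entry[2] = max(entry[2], end)
        offenders = sorted(g for g, e in spans.items() if len(e[4]) > 1)
        if offenders:
            raise ParseError(
                f"{path}: genes spanning multiple chromosomes/strands: "
                + ", ".join(offenders)
            )
        genes = [
            GeneModel(gene_id=g, symbol=g, body=GenomicInterval(e[0], e[1], e[2]), strand=e[3])
            for g, e in sorted(spans.items())
        ]
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if not genes:
        raise ParseError(f"{path}: empty annotation")
    return genes


def write_bed6(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [g.body.chrom, str(g.body.start), str(g.body.end), g.gene_id, "0", g.strand]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Differential-expression tables

#: Default column-name aliases; first entry is the canonical name used
#: when writing.  edgeR names are included because the upstream tables
#: come from edgeR's exactTest.
DE_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "gene_id": ("gene_id", "gene", "Gene", "symbol", "SYMBOL", "genes"),
    "log2fc": ("log2fc", "logFC", "log2FoldChange", "log2FC"),
    "pvalue": ("pvalue", "PValue", "pval", "P.Value", "p_value"),
    "fdr": ("fdr", "FDR", "padj", "adj.P.Val", "qvalue"),
}


def read_de_table(
    path: str,
    contrast: str = "",
    aliases: Mapping[str, Sequence[str]] | None = None,
) -> list[DERecord]:
    """Read a differential-expression TSV into DERecords.

    The header must contain columns mappable (via ``aliases``) to
    gene_id, log2FC, p and FDR.  Duplicate gene ids and out-of-range
    p/FDR values are errors.
    """
    alias_map = dict(DE_COLUMN_ALIASES)
    if aliases:
        for key, names in aliases.items():
            alias_map[key] = tuple(names)
    df = pd.read_csv(path, sep="\t")
    resolved: dict[str, str] = {}
    for canon, names in alias_map.items():
        found = [c for c in df.columns if c in names]
        if not found:
            raise ParseError(f"{path}: no column mappable to {canon!r} (tried {names})")
        resolved[canon] = found[0]
    records: list[DERecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        gene = str(getattr(row, resolved["gene_id"]))
        if gene in seen:
            raise ParseError(f"{path}: duplicate gene_id {gene!r}")
        seen.add(gene)
        try:
            rec = DERecord(
                gene_id=gene,
                log2fc=float(getattr(row, resolved["log2fc"])),
                pvalue=float(getattr(row, resolved["pvalue"])),
                fdr=float(getattr(row, resolved["fdr"])),
                contrast=contrast,
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
        records.append(rec)
    return records


def write_de_table(records: Sequence[DERecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tpvalue\tfdr\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{_fmt(r.log2fc)}\t{_fmt(r.pvalue)}\t{_fmt(r.fdr)}\n"
            )


# ---------------------------------------------------------------------------
# Network export (Cytoscape-compatible flat TSVs)

EDGE_COLUMNS = (
    "tf",
    "gene_id",
    "directness",
    "mode",
    "kd_log2fc",
    "kd_fdr",
    "n_peaks",
    "manual_flag",
)
NODE_COLUMNS = ("gene_id", "subset_log2fc", "subset_significant")


def write_network_table(
    network: "RegulatoryNetwork", edge_path: str, node_path: str | None = None
) -> None:
    """Write the edge table (and companion node-attribute table) as TSV.

    Rows are sorted by (tf, gene_id) so repeated writes of the same
    network are byte-identical.
    """
    edges = sorted(network.edges, key=lambda e: (e.tf, e.gene_id))
    with open(edge_path, "w") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for e in edges:
            fh.write(
                "\t".join(
                    [
                        e.tf,
                        e.gene_id,
                        e.directness,
                        e.mode,
                        _fmt(e.kd_log2fc),
                        _fmt(e.kd_fdr),
                        str(e.n_peaks),
                        str(bool(e.manual_flag)),
                    ]
                )
                + "\n"
            )
    if node_path is not None:
        with open(node_path, "w") as fh:
            fh.write("\t".join(NODE_COLUMNS) + "\n")
            for gene in sorted(network.node_annotations):
                ann = network.node_annotations[gene]
                lfc = "NA" if ann.subset_log2fc is None else _fmt(ann.subset_log2fc)
                fh.write(f"{gene}\t{lfc}\t{str(bool(ann.significant))}\n")


# ---------------------------------------------------------------------------
# GSEA exchange formats


def write_gmt(sets: Iterable["GeneSet"], path: str) -> None:
    """Write gene sets in GMT (name, description, members...)."""
    with open(path, "w") as fh:
        for s in sets:
            if not s.name:
                raise ValueError("gene set with empty name")
            fh.write("\t".join([s.name, s.description or "na", *sorted(s.members)]) + "\n")


def read_gmt(path: str) -> list["GeneSet"]:
    from .enrichment import GeneSet

    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: GMT line {lineno} has no members")
            sets.append(GeneSet(name=cols[0], members=frozenset(cols[2:]), description=cols[1]))
    return sets


def write_rnk(ranked: "RankedList", path: str) -> None:
    """Write a ranked list as RNK (gene TAB score, descending)."""
    with open(path, "w") as fh:
        for gene, score in ranked.entries:
            fh.write(f"{gene}\t{_fmt(score)}\n")


def read_rnk(path: str) -> "RankedList":
    from .enrichment import RankedList

    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(f"{path}: RNK line {lineno} needs 2 columns")
            gene, score = cols[0], float(cols[1])
            if gene in scores:
                raise ParseError(f"{path}: duplicate gene {gene!r} in RNK")
            scores[gene] = score
    return RankedList.from_scores(scores)
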