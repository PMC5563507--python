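"""Peak-to-gene association.

A peak is associated with a gene when its summit falls within ``W``
bases (default 5,000) up- or downstream of the gene body, or inside the
body itself.  The window is strand-symmetric and the threshold is
inclusive at exactly ``W``.  A peak may associate with several genes
and a gene with several peaks; no nearest-gene collapse is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomic import GeneModel, Peak

__all__ = ["Association", "peak_gene_distance", "map_peaks_to_genes", "write_associations"]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 5000


@dataclass(frozen=True)
class Association:
    """One peak-gene association within the window used at creation."""

    peak_id: str
    gene_id: str
    distance: int  # 0 when the summit lies inside the gene body
    tf: str = ""


def peak_gene_distance(peak: Peak, gene: GeneModel) -> int | None:
    """Bases from the summit to the nearest gene-body edge.

    Returns 0 when the summit lies inside the body, ``None`` when peak
    and gene are on different chromosomes.  For a summit at or past the
    half-open body end the distance is ``summit - end + 1`` (the first
    base past the body is 1 away).
    """
    if peak.chrom != gene.body.chrom:
        return None
    s = peak.summit
    if gene.body.contains(s):
        return 0
    if s < gene.body.start:
        return gene.body.start - s
    return s - gene.body.end + 1


def map_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
) -> list[Association]:
    """Associate peaks with genes by the summit-within-window rule.

    Emits an association iff ``peak_gene_distance <= window``
    (inclusive).  Output is sorted by (gene_id, peak_id).  Raises if
    peaks and genes share no chromosome — a likely namespace mismatch.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if not peaks or not genes:
        return []
    peak_chroms = {p.chrom for p in peaks}
    gene_chroms = {g.body.chrom for g in genes}
    if not peak_chroms & gene_chroms:
        raise ValueError(
            "peaks and gene annotation share no chromosome names: "
            f"peaks use {sorted(peak_chroms)[:5]}, genes use {sorted(gene_chroms)[:5]} "
            "(likely a chromosome-namespace mismatch)"
        )

    # Sorted-summit index per chromosome; each gene window is answered
    # with two binary searches.  Summit within window <=> summit in
    # [body.start - W, body.end + W) by the half-open distance rule.
    by_chrom: dict[str, tuple[np.ndarray, list[Peak]]] = {}
    for chrom in peak_chroms:
        cps = [p for p in peaks if p.chrom == chrom]
        cps.sort(key=lambda p: p.summit)
        by_chrom[chrom] = (np.array([p.summit for p in cps], dtype=np.int64), cps)

    out: list[Association] = []
    for gene in genes:
        entry = by_chrom.get(gene.body.chrom)
        if entry is None:
            continue
        summits, cps = entry
        lo = int(np.searchsorted(summits, gene.body.start - window, side="left"))
        hi = int(np.searchsorted(summits, gene.body.end + window, side="left"))
        for p in cps[lo:hi]:
            d = peak_gene_distance(p, gene)
            assert d is not None and d <= window
            out.append(
                Association(peak_id=p.peak_id, gene_id=gene.gene_id, distance=d, tf=p.source)
            )
    out.sort(key=lambda a: (a.gene_id, a.peak_id))
    return out


def write_associations(associations: Sequence[Association], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tgene_id\ttf\tdistance\n")
        for a in associations:
            fh.write(f"{a.peak_id}\t{a.gene_id}\t{a.tf}\t{a.distance}\n")
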