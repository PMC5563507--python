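"""Putative cis-regulatory modules (pCRMs) and occupancy analytics.

Pooled peaks from several TF ChIP-seq datasets are transitively merged
(>= 1 shared base) into pCRMs; each module carries a per-TF occupancy
vector.  Modules are binned into k clusters (default 8) by k-means on
the binary occupancy matrix for heatmap display.  The module also
classifies differential-binding regions as co-bound (>= 1 base overlap
with a reference TF's peaks), computes overlap fractions / venn counts
between peak sets, and summarizes differential-binding volcano
quadrants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .genomic import GenomicInterval, Peak, merge_overlapping, overlaps

__all__ = [
    "PCRM",
    "DiffRegion",
    "ClusterResult",
    "OverlapSummary",
    "build_pcrms",
    "cluster_pcrms",
    "annotate_cobound",
    "overlap_fraction",
    "diff_summary",
    "write_pcrm_table",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 8


@dataclass
class PCRM:
    """A merged multi-TF region with its occupancy vector."""

    region: GenomicInterval
    member_peaks: list[str] = field(default_factory=list)
    occupancy: dict[str, bool] = field(default_factory=dict)
    signal: dict[str, float] = field(default_factory=dict)  # max peak score per TF
    cluster_id: int | None = None


@dataclass(frozen=True)
class DiffRegion:
    """A differential-binding region (statistics computed upstream)."""

    region: GenomicInterval
    log2fc: float
    pvalue: float
    fdr: float
    cobound: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 and 0.0 <= self.fdr <= 1.0):
            raise ValueError("p and FDR must lie in [0, 1]")


def build_pcrms(peak_sets: Mapping[str, Sequence[Peak]]) -> list[PCRM]:
    """Merge pooled peaks into pCRMs with per-TF occupancy.

    Module regions are the transitive-overlap merge of all peaks across
    the panel; every input peak belongs to exactly one module.
    Occupancy is boolean per TF in the panel; the max peak score per TF
    is kept alongside for signal-mode heatmap shading.
    """
    panel = sorted(peak_sets)
    pooled: list[tuple[Peak, str]] = []
    for tf in panel:
        pooled.extend((p, tf) for p in peak_sets[tf])
    if not pooled:
        raise ValueError("no peaks in any peak set")
    pooled.sort(key=lambda pt: (pt[0].interval.chrom, pt[0].interval.start, pt[0].interval.end))

    modules: list[PCRM] = []
    current: PCRM | None = None
    for peak, tf in pooled:
        iv = peak.interval
        if (
            current is not None
            and current.region.chrom == iv.chrom
            and iv.start < current.region.end
        ):
            if iv.end > current.region.end:
                current.region = GenomicInterval(iv.chrom, current.region.start, iv.end)
        else:
            current = PCRM(region=iv, occupancy={t: False for t in panel},
                           signal={t: 0.0 for t in panel})
            modules.append(current)
        current.member_peaks.append(peak.peak_id)
        current.occupancy[tf] = True
        current.signal[tf] = max(current.signal[tf], peak.score)
    return modules


@dataclass(frozen=True)
class ClusterResult:
    """Cluster assignments plus a heatmap-ready occupancy matrix.

    ``labels`` aligns with the input module order; ``matrix`` rows are
    modules regrouped by cluster (decreasing cluster size), ``row_order``
    gives each matrix row's index into the input list.
    """

    labels: np.ndarray
    k: int
    tf_panel: tuple[str, ...]
    matrix: np.ndarray
    row_order: np.ndarray


def _occupancy_matrix(pcrms: Sequence[PCRM], signal: bool = False) -> tuple[np.ndarray, tuple[str, ...]]:
    panel = tuple(sorted(pcrms[0].occupancy))
    if signal:
        mat = np.array([[m.signal.get(tf, 0.0) for tf in panel] for m in pcrms], dtype=float)
    else:
        mat = np.array([[1.0 if m.occupancy.get(tf, False) else 0.0 for tf in panel] for m in pcrms])
    return mat, panel


def cluster_pcrms(
    pcrms: Sequence[PCRM],
    k: int = DEFAULT_K,
    seed: int = 0,
    signal: bool = False,
) -> ClusterResult:
    """Bin pCRMs into k clusters of occupancy patterns (k-means).

    Deterministic under a fixed seed and invariant to input row order:
    modules are clustered in canonical coordinate order and results are
    mapped back.  Clusters are relabeled in decreasing size order.  If
    fewer than k distinct occupancy patterns exist, k is reduced with a
    warning.  Assignments are also written onto ``PCRM.cluster_id``.
    """
    if not pcrms:
        raise ValueError("empty module list")
    if k < 1:
        raise ValueError("k must be >= 1")
    mat, panel = _occupancy_matrix(pcrms, signal=signal)
    canon = sorted(
        range(len(pcrms)),
        key=lambda i: (pcrms[i].region.chrom, pcrms[i].region.start, pcrms[i].region.end, i),
    )
    mat_c = mat[canon]
    n_patterns = len({tuple(row) for row in mat_c})
    k_eff = min(k, n_patterns, len(pcrms))
    if k_eff < k:
        logger.warning(
            "only %d distinct occupancy patterns: clustering with k=%d instead of %d",
            n_patterns,
            k_eff,
            k,
        )
    if k_eff == 1:
        raw = np.zeros(len(pcrms), dtype=int)
    else:
        km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed)
        raw = km.fit_predict(mat_c)
    # relabel by decreasing size; ties broken by centroid pattern
    sizes: dict[int, int] = {}
    for lab in raw:
        sizes[int(lab)] = sizes.get(int(lab), 0) + 1
    centroid_key = {
        lab: tuple(np.round(mat_c[raw == lab].mean(axis=0), 6)) for lab in sizes
    }
    order = sorted(sizes, key=lambda lab: (-sizes[lab], centroid_key[lab]))
    relabel = {old: new for new, old in enumerate(order)}
    labels_canon = np.array([relabel[int(lab)] for lab in raw], dtype=int)
    labels = np.empty(len(pcrms), dtype=int)
    for pos, idx in enumerate(canon):
        labels[idx] = labels_canon[pos]
    for m, lab in zip(pcrms, labels):
        m.cluster_id = int(lab)
    row_order = np.array(
        [idx for lab in range(k_eff) for pos, idx in enumerate(canon) if labels_canon[pos] == lab],
        dtype=int,
    )
    return ClusterResult(
        labels=labels, k=k_eff, tf_panel=panel, matrix=mat[row_order], row_order=row_order
    )


def annotate_cobound(
    diff_regions: Sequence[DiffRegion], reference_peaks: Sequence[Peak]
) -> list[DiffRegion]:
    """Mark each differential region co-bound iff it shares >= 1 base
    with any reference peak."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in reference_peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p.interval)
    starts_ends: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        starts_ends[chrom] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )
    out: list[DiffRegion] = []
    for r in diff_regions:
        se = starts_ends.get(r.region.chrom)
        cobound = False
        if se is not None:
            starts, ends = se
            cobound = bool(np.any((starts < r.region.end) & (ends > r.region.start)))
        out.append(
            DiffRegion(
                region=r.region,
                log2fc=r.log2fc,
                pvalue=r.pvalue,
                fdr=r.fdr,
                cobound=cobound,
            )
        )
    return out


@dataclass(frozen=True)
class OverlapSummary:
    fraction_a_overlapping: float
    n_a: int
    n_b: int
    a_only: int
    b_only: int
    shared_from_a: int  # A peaks overlapping >= 1 B peak
    shared_from_b: int  # B peaks overlapping >= 1 A peak


def overlap_fraction(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
) -> OverlapSummary:
    """Fraction of A peaks overlapping >= 1 B peak, with venn counts.

    Shared counts are reported from both perspectives, which may differ
    when overlaps are not one-to-one.
    """
    if not peaks_a:
        raise ValueError("peak set A is empty")

    def hits(src: Sequence[Peak], ref: Sequence[Peak]) -> int:
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        tmp: dict[str, list[tuple[int, int]]] = {}
        for p in ref:
            tmp.setdefault(p.interval.chrom, []).append((p.interval.start, p.interval.end))
        for chrom, pairs in tmp.items():
            by_chrom[chrom] = (
                np.array([a for a, _ in pairs], dtype=np.int64),
                np.array([b for _, b in pairs], dtype=np.int64),
            )
        n = 0
        for p in src:
            se = by_chrom.get(p.interval.chrom)
            if se is None:
                continue
            starts, ends = se
            if np.any((starts < p.interval.end) & (ends > p.interval.start)):
                n += 1
        return n

    shared_a = hits(peaks_a, peaks_b)
    shared_b = hits(peaks_b, peaks_a) if peaks_b else 0
    return OverlapSummary(
        fraction_a_overlapping=shared_a / len(peaks_a),
        n_a=len(peaks_a),
        n_b=len(peaks_b),
        a_only=len(peaks_a) - shared_a,
        b_only=len(peaks_b) - shared_b,
        shared_from_a=shared_a,
        shared_from_b=shared_b,
    )


def diff_summary(
    diff_regions: Sequence[DiffRegion],
    fc_threshold: float = 2.0,
    p_threshold: float = 0.01,
    p_cap: float = 1e-25,
) -> dict:
    """Per-subtype percentages of strong differential-binding events.

    Splits regions into co-bound vs non-co-bound and, within each
    subtype, reports the percentage with fold change >= ``fc_threshold``
    and p < ``p_threshold``, separately for gains (log2FC >= +log2(fc))
    and losses (log2FC <= -log2(fc)).  Also returns volcano-plot
    coordinates with the p-value capped at ``p_cap``.
    """
    if any(r.cobound is None for r in diff_regions):
        raise ValueError("all regions must have cobound assigned (run annotate_cobound)")
    lfc_cut = math.log2(fc_threshold)
    summary: dict = {"fc_threshold": fc_threshold, "p_threshold": p_threshold}
    for subtype, flag in (("cobound", True), ("not_cobound", False)):
        regs = [r for r in diff_regions if r.cobound is flag]
        n = len(regs)
        up = sum(1 for r in regs if r.log2fc >= lfc_cut and r.pvalue < p_threshold)
        down = sum(1 for r in regs if r.log2fc <= -lfc_cut and r.pvalue < p_threshold)
        summary[subtype] = {
            "n": n,
            "pct_up": 100.0 * up / n if n else 0.0,
            "pct_down": 100.0 * down / n if n else 0.0,
        }
    summary["volcano"] = [
        {
            "chrom": r.region.chrom,
            "start": r.region.start,
            "end": r.region.end,
            "log2fc": r.log2fc,
            "minus_log10_p": -math.log10(max(r.pvalue, p_cap)),
            "cobound": bool(r.cobound),
        }
        for r in diff_regions
    ]
    return summary


def write_pcrm_table(pcrms: Sequence[PCRM], path: str) -> None:
    """BED-plus-columns TSV: region, cluster, one 0/1 column per TF."""
    if not pcrms:
        raise ValueError("empty module list")
    panel = tuple(sorted(pcrms[0].occupancy))
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcluster_id\tn_peaks\t" + "\t".join(panel) + "\n")
        for m in pcrms:
            occ = "\t".join("1" if m.occupancy.get(tf, False) else "0" for tf in panel)
            cid = "NA" if m.cluster_id is None else str(m.cluster_id)
            fh.write(
                f"{m.region.chrom}\t{m.region.start}\t{m.region.end}\t{cid}\t"
                f"{len(m.member_peaks)}\t{occ}\n"
            )
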