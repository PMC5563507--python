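"""Signature construction, rank metrics, and pre-ranked GSEA.

The enrichment statistic is the weighted Kolmogorov-Smirnov running sum
of Subramanian et al.'s GSEA: walking down a ranked gene list, the sum
is incremented by ``|s_i|^w / sum_hits |s|^w`` at a gene-set hit and
decremented by ``1/(N - N_hits)`` at a miss; the enrichment score (ES)
is the maximum-magnitude signed deviation.  Significance comes from a
gene-set (label) permutation null — the only null coherent for
pre-ranked input.  Benjamini-Hochberg adjustment lives here as a shared
utility.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import DERecord

__all__ = [
    "GeneSet",
    "RankedList",
    "EnrichmentResult",
    "bh_adjust",
    "signature_from_contrast",
    "rank_metric",
    "enrichment_score",
    "gsea_preranked",
]

logger = logging.getLogger(__name__)

#: -log10(p) assigned when p == 0; just below double-precision underflow
#: of 10**-x so ordering stays finite and deterministic.
P_ZERO_CAP = 320.0

DEFAULT_SIGNATURE_SIZE = 100
DEFAULT_NPERM = 10_000


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    description: str = "na"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass(frozen=True)
class RankedList:
    """Genes with scores, ordered descending (ties broken by gene id)."""

    entries: tuple[tuple[str, float], ...]

    @classmethod
    def from_scores(cls, scores: Mapping[str, float]) -> "RankedList":
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(entries=tuple(ordered))

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.entries]
        if len(genes) != len(set(genes)):
            raise ValueError("duplicate genes in ranked list")
        scores = [s for _, s in self.entries]
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValueError("ranked list not in descending score order")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.entries)

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=float)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    nperm: int
    leading_edge: tuple[str, ...]


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def signature_from_contrast(
    de_table: Sequence[DERecord],
    direction: str,
    n: int = DEFAULT_SIGNATURE_SIZE,
    name: str | None = None,
) -> GeneSet:
    """Top-``n`` up- or downregulated genes of a contrast, by raw p-value.

    Ties on p are broken by larger |log2FC|, then by gene id.  If fewer
    than ``n`` genes qualify, all of them are returned with a warning.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if n < 1:
        raise ValueError("n must be >= 1")
    if direction == "up":
        qualifying = [r for r in de_table if r.log2fc > 0]
    else:
        qualifying = [r for r in de_table if r.log2fc < 0]
    if not qualifying:
        raise ValueError(f"no {direction}-regulated genes in contrast")
    qualifying.sort(key=lambda r: (r.pvalue, -abs(r.log2fc), r.gene_id))
    if len(qualifying) < n:
        logger.warning(
            "only %d %s-regulated genes available (requested %d)",
            len(qualifying),
            direction,
            n,
        )
    chosen = qualifying[:n]
    contrast = chosen[0].contrast or "contrast"
    set_name = name or f"{contrast}_{direction}"
    return GeneSet(name=set_name, members=frozenset(r.gene_id for r in chosen))


def rank_metric(de_table: Sequence[DERecord]) -> RankedList:
    """Per-gene score ``-log10(p) * sign(log2FC)``, ranked descending.

    ``p == 0`` is capped at magnitude ``P_ZERO_CAP``; ``log2FC == 0``
    gives score 0 regardless of p.
    """
    if not de_table:
        raise ValueError("empty DE table")
    scores: dict[str, float] = {}
    for r in de_table:
        if r.gene_id in scores:
            raise ValueError(f"duplicate gene {r.gene_id!r} in DE table")
        sign = 0.0 if r.log2fc == 0 else math.copysign(1.0, r.log2fc)
        mag = P_ZERO_CAP if r.pvalue == 0 else -math.log10(r.pvalue)
        mag = min(mag, P_ZERO_CAP)
        scores[r.gene_id] = sign * mag
    return RankedList.from_scores(scores)


def _prefer_positive(hi: float, lo: float) -> bool:
    """True when the positive deviation wins the max-magnitude contest.

    Deviations tied in exact arithmetic can differ by an ulp between
    accumulation orders, so ties are resolved with a small relative
    tolerance, toward the positive deviation.
    """
    tol = 1e-12 * max(abs(hi), abs(lo), 1.0)
    return abs(hi) >= abs(lo) - tol


def _es_curve(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float
) -> tuple[float, np.ndarray, int]:
    """Running sum and signed max-deviation ES for one gene set."""
    n = scores.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the whole ranked universe (degenerate)")
    w = np.abs(scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all member scores are exactly 0 at this weight: fall back to
        # equal hit increments (matches the weight=0 limit)
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hit_mask) / (n - n_hits)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if _prefer_positive(float(running[i_max]), float(running[i_min])):
        es, extremum = float(running[i_max]), i_max
    else:
        es, extremum = float(running[i_min]), i_min
    return es, running, extremum


def enrichment_score(
    ranked: RankedList, geneset: GeneSet, weight: float = 1.0
) -> tuple[float, np.ndarray, tuple[str, ...]]:
    """Weighted-KS enrichment score with running sum and leading edge.

    The leading edge contains the member genes at or before the
    running-sum extremum for positive ES, and at or after it for
    negative ES.  When the largest positive and negative deviations tie
    exactly in magnitude, the positive one is reported.
    """
    genes = ranked.genes
    scores = ranked.scores
    hit_mask = np.array([g in geneset.members for g in genes], dtype=bool)
    es, running, extremum = _es_curve(scores, hit_mask, weight)
    if es >= 0:
        leading = tuple(g for i, g in enumerate(genes) if hit_mask[i] and i <= extremum)
    else:
        leading = tuple(g for i, g in enumerate(genes) if hit_mask[i] and i >= extremum)
    return es, running, leading


def _es_from_positions(
    positions: np.ndarray, w_abs: np.ndarray, n: int
) -> float:
    """ES from sorted hit positions without materializing the full curve.

    Running-sum extrema can only occur immediately after a hit (local
    maxima candidates) or immediately before one (local minima
    candidates), so only ``2 * n_hits`` candidates are examined.
    """
    m = positions.size
    hw = w_abs[positions]
    total = hw.sum()
    if total == 0:
        hw = np.ones(m)
        total = float(m)
    hcum = np.cumsum(hw) / total
    miss_step = 1.0 / (n - m)
    j = np.arange(m)
    after_hit = hcum - (positions - j) * miss_step
    before_hit = np.concatenate(([0.0], hcum[:-1])) - (positions - j) * miss_step
    hi = float(after_hit.max())
    lo = float(before_hit.min())
    return hi if _prefer_positive(hi, lo) else lo


def gsea_preranked(
    ranked: RankedList,
    gene_sets: Iterable[GeneSet],
    nperm: int = DEFAULT_NPERM,
    seed: int = 0,
    weight: float = 1.0,
) -> list[EnrichmentResult]:
    """Pre-ranked GSEA with a gene-set permutation null.

    For each set, ``nperm`` random gene sets of equal size are drawn
    from the ranked universe.  The permutation p-value is plus-one
    corrected, ``(1 + #{same-sign |ES'| >= |ES|}) / (1 + nperm)``, so it
    is never 0 and its floor is ``1/(nperm + 1)``.  NES divides ES by
    the mean |ES'| of same-signed nulls (the GSEA convention).
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    n = len(ranked)
    scores = ranked.scores
    w_abs = np.abs(scores) ** weight
    rng = np.random.default_rng(seed)
    results: list[EnrichmentResult] = []
    for gs in gene_sets:
        m = sum(1 for g in ranked.genes if g in gs.members)
        if m == 0:
            raise ValueError(f"gene set {gs.name!r} has no overlap with the ranked list")
        if m >= n:
            raise ValueError(f"gene set {gs.name!r} is as large as the universe")
        es, _, leading = enrichment_score(ranked, gs, weight=weight)
        null = np.empty(nperm)
        for i in range(nperm):
            pos = np.sort(rng.choice(n, size=m, replace=False))
            null[i] = _es_from_positions(pos, w_abs, n)
        same_sign = null >= 0 if es >= 0 else null < 0
        exceed = int(np.sum(same_sign & (np.abs(null) >= abs(es))))
        p_perm = (1 + exceed) / (1 + nperm)
        same_abs = np.abs(null[same_sign])
        nes = float(es / same_abs.mean()) if same_abs.size else float("nan")
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                es=float(es),
                nes=nes,
                p_perm=float(p_perm),
                nperm=nperm,
                leading_edge=leading,
            )
        )
    return results


def write_enrichment_report(results: Sequence[EnrichmentResult], path: str) -> None:
    """TSV report: set, ES, NES, permutation p, leading-edge size."""
    with open(path, "w") as fh:
        fh.write("set\tes\tnes\tp_perm\tnperm\tleading_edge_size\n")
        for r in sorted(results, key=lambda r: r.set_name):
            fh.write(
                f"{r.set_name}\t{r.es!r}\t{r.nes!r}\t{r.p_perm!r}\t"
                f"{r.nperm}\t{len(r.leading_edge)}\n"
            )
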