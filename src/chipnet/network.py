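"""TF -> gene regulatory-network construction and network-level summaries.

For each TF-knockout contrast, every differentially expressed gene
(FDR < alpha, default 0.05) becomes a network edge.  The edge is DIRECT
when at least one ChIP-seq peak summit for that TF lies within the
association window of the gene body (or the edge is on the manual
DIRECT list), INDIRECT otherwise.  Its mode is ACT when expression
decreased in the knockout (log2FC < 0 in KO-vs-WT orientation) and REP
when it increased.

Also implemented here: the quadrant-concordance comparison of two
knockout contrasts, 4-mode TF-pair cooperative-regulation grouping,
net-effect summaries against a subset contrast, and node annotation
for network rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import DERecord
from .mapping import Association

__all__ = [
    "NetworkConfig",
    "TargetEdge",
    "NodeAnnotation",
    "RegulatoryNetwork",
    "GroupSummary",
    "classify_target",
    "build_network",
    "quadrant_concordance",
    "pair_mode_groups",
    "net_effect_summary",
    "subset_preference",
    "annotate_nodes",
]

logger = logging.getLogger(__name__)

#: Validated targets whose peaks fall outside the 5 kb window but whose
#: direct regulation was established experimentally; DIRECT edges for
#: these are added manually for the Junb network.
DEFAULT_MANUAL_DIRECT: dict[str, tuple[str, ...]] = {
    "Junb": ("Ifng", "Irf8", "Tbx21"),
}

PAIR_MODES = ("ACT:ACT", "ACT:REP", "REP:ACT", "REP:REP")


@dataclass(frozen=True)
class NetworkConfig:
    """Thresholds and conventions for network construction.

    ``alpha`` is the FDR significance cut (strict ``fdr < alpha``);
    ``window_w`` the peak-association window in bases; ``manual_direct``
    maps a TF to genes whose edges are forced DIRECT (they still require
    DE significance).  ``flip_log2fc`` accommodates DE tables supplied
    in WT-vs-KO orientation.
    """

    alpha: float = 0.05
    window_w: int = 5000
    manual_direct: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MANUAL_DIRECT)
    )
    flip_log2fc: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.window_w < 0:
            raise ValueError("window_w must be >= 0")


@dataclass(frozen=True)
class TargetEdge:
    tf: str
    gene_id: str
    directness: str  # DIRECT | INDIRECT
    mode: str  # ACT | REP
    kd_log2fc: float
    kd_fdr: float
    n_peaks: int = 0
    manual_flag: bool = False

    def __post_init__(self) -> None:
        if self.directness not in ("DIRECT", "INDIRECT"):
            raise ValueError(f"bad directness {self.directness!r}")
        if self.mode not in ("ACT", "REP"):
            raise ValueError(f"bad mode {self.mode!r}")
        if self.n_peaks < 0:
            raise ValueError("n_peaks must be >= 0")


@dataclass(frozen=True)
class NodeAnnotation:
    subset_log2fc: float | None  # None marks "not significant"
    significant: bool
    contrast: str = ""


@dataclass
class RegulatoryNetwork:
    edges: list[TargetEdge] = field(default_factory=list)
    node_annotations: dict[str, NodeAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(e.tf, e.gene_id) for e in self.edges]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (tf, gene) edges in network")

    @property
    def tfs(self) -> tuple[str, ...]:
        return tuple(sorted({e.tf for e in self.edges}))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({e.gene_id for e in self.edges}))

    def edges_of(self, tf: str) -> list[TargetEdge]:
        return [e for e in self.edges if e.tf == tf]


def classify_target(
    record: DERecord,
    n_proximal_peaks: int,
    config: NetworkConfig,
    manual: bool = False,
) -> TargetEdge | None:
    """Classify one knockout DE record into a network edge (or drop it).

    Returns ``None`` for non-significant genes (``fdr >= alpha``,
    strict significance at ``fdr < alpha``) and for the degenerate case
    of a significant gene with log2FC exactly 0, which has no defined
    mode and is excluded with a warning.
    """
    if record.fdr >= config.alpha:
        return None
    lfc = -record.log2fc if config.flip_log2fc else record.log2fc
    if lfc == 0:
        logger.warning(
            "gene %s significant (fdr=%g) with log2FC == 0: mode undefined, excluded",
            record.gene_id,
            record.fdr,
        )
        return None
    mode = "ACT" if lfc < 0 else "REP"  # decreased in TF-KO => activation target
    direct = n_proximal_peaks >= 1 or manual
    return TargetEdge(
        tf="",
        gene_id=record.gene_id,
        directness="DIRECT" if direct else "INDIRECT",
        mode=mode,
        kd_log2fc=lfc,
        kd_fdr=record.fdr,
        n_peaks=n_proximal_peaks,
        manual_flag=bool(manual),
    )


def build_network(
    de_tables: Mapping[str, Sequence[DERecord]],
    associations: Mapping[str, Sequence[Association]],
    config: NetworkConfig | None = None,
) -> RegulatoryNetwork:
    """Compile the TF -> gene network from knockout DE plus associations.

    ``de_tables`` maps TF name -> its KO-vs-WT DE table; ``associations``
    maps TF name -> its peak-gene associations (may be missing or empty
    for a TF with no ChIP data).  One edge per significant (tf, gene).
    """
    config = config or NetworkConfig()
    unknown = set(associations) - set(de_tables)
    if unknown:
        raise ValueError(
            f"TFs with associations but no DE table: {sorted(unknown)}"
        )
    edges: list[TargetEdge] = []
    for tf in sorted(de_tables):
        peak_counts: dict[str, int] = {}
        for a in associations.get(tf, ()):
            peak_counts[a.gene_id] = peak_counts.get(a.gene_id, 0) + 1
        manual_genes = set(config.manual_direct.get(tf, ()))
        counts: dict[tuple[str, str], int] = {}
        for rec in de_tables[tf]:
            edge = classify_target(
                rec,
                peak_counts.get(rec.gene_id, 0),
                config,
                manual=rec.gene_id in manual_genes,
            )
            if edge is None:
                continue
            edge = TargetEdge(
                tf=tf,
                gene_id=edge.gene_id,
                directness=edge.directness,
                mode=edge.mode,
                kd_log2fc=edge.kd_log2fc,
                kd_fdr=edge.kd_fdr,
                n_peaks=edge.n_peaks,
                manual_flag=edge.manual_flag,
            )
            edges.append(edge)
            counts[(edge.directness, edge.mode)] = counts.get((edge.directness, edge.mode), 0) + 1
        for (directness, mode), n in sorted(counts.items()):
            logger.info("%s: %d %s %s edges", tf, n, directness, mode)
    edges.sort(key=lambda e: (e.tf, e.gene_id))
    return RegulatoryNetwork(edges=edges)


def quadrant_concordance(
    de_a: Sequence[DERecord],
    de_b: Sequence[DERecord],
    alpha: float = 0.05,
) -> dict:
    """Sign-concordance of two DE contrasts over co-significant genes.

    Restricts to genes with ``fdr < alpha`` in BOTH tables (zero-log2FC
    genes excluded) and reports the fraction falling in each sign
    quadrant plus ``concordance = both_up + both_down``.  The four
    fractions sum to 1.
    """
    a_map = {r.gene_id: r for r in de_a}
    b_map = {r.gene_id: r for r in de_b}
    cosig = [
        g
        for g in a_map
        if g in b_map
        and a_map[g].fdr < alpha
        and b_map[g].fdr < alpha
        and a_map[g].log2fc != 0
        and b_map[g].log2fc != 0
    ]
    if not cosig:
        raise ValueError("no co-significant genes between the two contrasts")
    quads: dict[str, list[str]] = {
        "both_up": [],
        "both_down": [],
        "a_up_b_down": [],
        "a_down_b_up": [],
    }
    for g in sorted(cosig):
        up_a = a_map[g].log2fc > 0
        up_b = b_map[g].log2fc > 0
        if up_a and up_b:
            quads["both_up"].append(g)
        elif not up_a and not up_b:
            quads["both_down"].append(g)
        elif up_a:
            quads["a_up_b_down"].append(g)
        else:
            quads["a_down_b_up"].append(g)
    n = len(cosig)
    fractions = {k: len(v) / n for k, v in quads.items()}
    return {
        "n_cosignificant": n,
        "fractions": fractions,
        "concordance": fractions["both_up"] + fractions["both_down"],
        "genes": quads,
    }


def pair_mode_groups(
    network: RegulatoryNetwork, tf_a: str, tf_b: str
) -> dict[str, str]:
    """Group common targets of two TFs by their 4 cooperative modes.

    Only genes with edges from BOTH TFs appear; the label is
    ``"<mode under tf_a>:<mode under tf_b>"``.
    """
    tfs = set(network.tfs)
    for tf in (tf_a, tf_b):
        if tf not in tfs:
            raise ValueError(f"TF {tf!r} not present in the network")
    a_modes = {e.gene_id: e.mode for e in network.edges_of(tf_a)}
    b_modes = {e.gene_id: e.mode for e in network.edges_of(tf_b)}
    return {
        g: f"{a_modes[g]}:{b_modes[g]}" for g in sorted(set(a_modes) & set(b_modes))
    }


@dataclass(frozen=True)
class GroupSummary:
    """Distribution summary of subset-contrast log2FCs for one group."""

    n: int
    median: float
    q1: float
    q3: float
    values: tuple[float, ...]
    empty: bool

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        if not values:
            return cls(n=0, median=float("nan"), q1=float("nan"), q3=float("nan"),
                       values=(), empty=True)
        arr = np.asarray(values, dtype=float)
        return cls(
            n=len(values),
            median=float(np.median(arr)),
            q1=float(np.percentile(arr, 25)),
            q3=float(np.percentile(arr, 75)),
            values=tuple(float(v) for v in values),
            empty=False,
        )


def net_effect_summary(
    groups: Mapping[str, str],
    subset_de: Sequence[DERecord],
    alpha: float = 0.05,
) -> dict[str, GroupSummary]:
    """Subset-contrast log2FC distributions per cooperative-mode group.

    For each of the 4 mode combinations, restricts the group's genes to
    those significant in the subset contrast (``fdr < alpha``) and
    summarizes their log2FCs.  Empty groups are flagged, not dropped.
    """
    subset = {r.gene_id: r for r in subset_de}
    out: dict[str, GroupSummary] = {}
    for combo in PAIR_MODES:
        genes = sorted(g for g, c in groups.items() if c == combo)
        values = [
            subset[g].log2fc for g in genes if g in subset and subset[g].fdr < alpha
        ]
        out[combo] = GroupSummary.from_values(values)
    return out


def subset_preference(
    network: RegulatoryNetwork,
    tf: str,
    mode: str,
    subset_de: Sequence[DERecord],
    alpha: float = 0.05,
) -> GroupSummary:
    """Subset-contrast log2FC distribution of one TF's ACT (or REP) targets."""
    if tf not in set(network.tfs):
        raise ValueError(f"TF {tf!r} not present in the network")
    if mode not in ("ACT", "REP"):
        raise ValueError("mode must be 'ACT' or 'REP'")
    subset = {r.gene_id: r for r in subset_de}
    genes = sorted(e.gene_id for e in network.edges_of(tf) if e.mode == mode)
    values = [subset[g].log2fc for g in genes if g in subset and subset[g].fdr < alpha]
    return GroupSummary.from_values(values)


def annotate_nodes(
    network: RegulatoryNetwork,
    subset_de: Sequence[DERecord],
    alpha: float = 0.05,
    contrast: str = "",
) -> RegulatoryNetwork:
    """Attach subset-contrast log2FCs to network nodes.

    A node gets its log2FC only when significant in the subset contrast;
    nodes absent from the table or non-significant carry an explicit
    not-significant marker.  The edge set is never altered.
    """
    subset = {r.gene_id: r for r in subset_de}
    label = contrast or (subset_de[0].contrast if subset_de else "")
    annotations: dict[str, NodeAnnotation] = {}
    for gene in network.genes:
        rec = subset.get(gene)
        if rec is not None and rec.fdr < alpha:
            annotations[gene] = NodeAnnotation(
                subset_log2fc=rec.log2fc, significant=True, contrast=label
            )
        else:
            annotations[gene] = NodeAnnotation(
                subset_log2fc=None, significant=False, contrast=label
            )
    return RegulatoryNetwork(edges=list(network.edges), node_annotations=annotations)
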