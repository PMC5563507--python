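"""Synthetic inputs with planted ground truth.

Generates everything the pipeline consumes — gene models, per-TF peak
sets, knockout and subset DE tables — from a planted TF -> gene network
so every stage can be validated against known truth without downloads.

The statistical model mirrors what the analysis assumes of real data:

* true targets of a knocked-out TF are differentially expressed, with
  p ~ Beta(a, 1) (``a < 1`` concentrates mass near 0) and
  |log2FC| ~ LogNormal(mu, sigma), negative in the knockout for
  activation targets and positive for repression targets;
* non-targets are null: p ~ Uniform(0, 1), log2FC ~ Normal(0, 0.1);
* each DIRECT edge receives one ChIP-seq peak whose summit falls within
  the association window of the gene body, then peaks are dropped
  independently at ``peak_dropout``; decoy peaks land in inter-gene
  gaps farther than the window from any gene body;
* gene bodies are spaced at least 2 W apart, so every generated peak
  maps to at most one gene and recovery metrics stay interpretable.

All draws derive from a single integer seed via independent named
streams, so generation is byte-reproducible.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .enrichment import bh_adjust
from .genomic import GeneModel, GenomicInterval, Peak
from .io import DERecord, write_bed6, write_de_table, write_narrowpeak
from .network import PAIR_MODES, RegulatoryNetwork, TargetEdge
from .pcrm import PCRM

__all__ = [
    "TruthSpec",
    "SyntheticTruth",
    "RecoveryMetrics",
    "generate_truth",
    "generate_peaks",
    "generate_de_tables",
    "recovery_metrics",
    "write_dataset",
    "generate_concordant_pair",
    "generate_pcrm_benchmark",
    "fixture_path",
    "FIXTURE_SPEC",
]

SUBSET_CONTRASTS = ("Th17_vs_Th0", "Th17_vs_Th1")


@dataclass(frozen=True)
class TruthSpec:
    """Full parameterization of one synthetic study.

    ``target_p_shape`` is the ``a`` of the Beta(a, 1) true-target
    p-value law; ``effect_size`` holds (mu, sigma) of the lognormal
    |log2FC| magnitude; ``signature_overlap`` is the fraction of ACT
    (resp. REP) targets planted as up- (resp. down-) regulated in the
    subset contrasts.  ``pair_mode_table`` optionally plants shared
    targets for TF pairs with fixed mode combinations, e.g.
    ``{("TF1", "TF2"): {"ACT:ACT": 10, "REP:REP": 5}}``.
    """

    seed: int = 0
    n_genes: int = 200
    n_chroms: int = 2
    chrom_length: int = 3_000_000
    tf_panel: tuple[str, ...] = ("Junb", "Batf", "Irf4")
    n_targets: int = 40
    frac_direct: float = 0.6
    frac_act: float = 0.6
    effect_size: tuple[float, float] = (math.log(2.0), 0.5)
    target_p_shape: float = 0.01
    peak_dropout: float = 0.0
    decoy_peaks_per_tf: int = 20
    pair_mode_table: Mapping[tuple[str, str], Mapping[str, int]] | None = None
    signature_overlap: float = 0.5
    window: int = 5000
    gene_length: tuple[int, int] = (1000, 8000)
    gap_extra: tuple[int, int] = (500, 4000)  # added on top of the 2W minimum

    def __post_init__(self) -> None:
        for name in ("frac_direct", "frac_act", "peak_dropout", "signature_overlap"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_targets > self.n_genes:
            raise ValueError("n_targets cannot exceed n_genes")
        if self.target_p_shape <= 0:
            raise ValueError("target_p_shape must be > 0")


@dataclass
class SyntheticTruth:
    gene_models: list[GeneModel]
    edges: list[TargetEdge]
    signature_members: dict[str, dict[str, frozenset[str]]]
    spec: TruthSpec

    def edges_of(self, tf: str) -> list[TargetEdge]:
        return [e for e in self.edges if e.tf == tf]


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec_seed, spawn_key=(stream,)))


def generate_truth(spec: TruthSpec) -> SyntheticTruth:
    """Place gene models and sample the planted regulatory network."""
    rng = _rng(spec.seed, 0)
    per_chrom = [spec.n_genes // spec.n_chroms] * spec.n_chroms
    for i in range(spec.n_genes % spec.n_chroms):
        per_chrom[i] += 1
    min_gap = 2 * spec.window
    genes: list[GeneModel] = []
    gid = 0
    for ci, n_on_chrom in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = min_gap + int(rng.integers(spec.gap_extra[0], spec.gap_extra[1] + 1))
        for _ in range(n_on_chrom):
            length = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
            if pos + length + min_gap > spec.chrom_length:
                raise ValueError(
                    f"cannot place {spec.n_genes} genes on {spec.n_chroms} chromosomes of "
                    f"{spec.chrom_length} bp; increase chrom_length or n_chroms"
                )
            gid += 1
            name = f"G{gid:05d}"
            genes.append(
                GeneModel(
                    gene_id=name,
                    symbol=name,
                    body=GenomicInterval(chrom, pos, pos + length),
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            gap = min_gap + int(rng.integers(spec.gap_extra[0], spec.gap_extra[1] + 1))
            pos += length + gap

    mu, sigma = spec.effect_size
    edges: list[TargetEdge] = []
    taken: dict[str, set[str]] = {tf: set() for tf in spec.tf_panel}

    def plant(tf: str, gene_id: str, mode: str | None = None) -> None:
        direct = bool(rng.random() < spec.frac_direct)
        if mode is None:
            mode = "ACT" if rng.random() < spec.frac_act else "REP"
        magnitude = float(rng.lognormal(mu, sigma))
        lfc = -magnitude if mode == "ACT" else magnitude
        edges.append(
            TargetEdge(
                tf=tf,
                gene_id=gene_id,
                directness="DIRECT" if direct else "INDIRECT",
                mode=mode,
                kd_log2fc=lfc,
                kd_fdr=0.0,
                n_peaks=1 if direct else 0,
            )
        )
        taken[tf].add(gene_id)

    gene_ids = [g.gene_id for g in genes]
    for tf in spec.tf_panel:
        for idx in rng.choice(spec.n_genes, size=spec.n_targets, replace=False):
            plant(tf, gene_ids[int(idx)])

    if spec.pair_mode_table:
        for (tf_a, tf_b), combos in spec.pair_mode_table.items():
            free = [g for g in gene_ids if g not in taken[tf_a] and g not in taken[tf_b]]
            needed = sum(combos.values())
            if needed > len(free):
                raise ValueError("not enough free genes to plant pair modes")
            chosen = list(rng.choice(len(free), size=needed, replace=False))
            it = iter(chosen)
            for combo in PAIR_MODES:
                for _ in range(combos.get(combo, 0)):
                    g = free[int(next(it))]
                    mode_a, mode_b = combo.split(":")
                    plant(tf_a, g, mode_a)
                    plant(tf_b, g, mode_b)

    # subset-signature membership: ACT targets lean subset-up, REP
    # targets subset-down, each selected at rate signature_overlap
    signature_members: dict[str, dict[str, frozenset[str]]] = {}
    act_genes = sorted({e.gene_id for e in edges if e.mode == "ACT"})
    rep_genes = sorted({e.gene_id for e in edges if e.mode == "REP"})
    for contrast in SUBSET_CONTRASTS:
        up = frozenset(g for g in act_genes if rng.random() < spec.signature_overlap)
        down = frozenset(g for g in rep_genes if rng.random() < spec.signature_overlap)
        signature_members[contrast] = {"up": up, "down": down}

    edges.sort(key=lambda e: (e.tf, e.gene_id))
    return SyntheticTruth(
        gene_models=genes, edges=edges, signature_members=signature_members, spec=spec
    )


def _decoy_ranges(
    genes: Sequence[GeneModel], spec: TruthSpec, margin: int
) -> list[tuple[str, int, int]]:
    """Gap segments whose positions are > window from every gene body."""
    w = spec.window
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.body.chrom, []).append(g)
    ranges: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        gs = sorted(by_chrom[chrom], key=lambda g: g.body.start)
        prev_end = margin  # leave room for the peak interval at chrom start
        for g in gs:
            lo, hi = prev_end, g.body.start - w
            if hi > lo:
                ranges.append((chrom, lo, hi))
            prev_end = g.body.end + w
        hi = spec.chrom_length - margin
        if hi > prev_end:
            ranges.append((chrom, prev_end, hi))
    return ranges


def generate_peaks(
    truth: SyntheticTruth, spec: TruthSpec | None = None
) -> dict[str, list[Peak]]:
    """One peak per surviving DIRECT edge plus decoys in inter-gene gaps.

    Summits for DIRECT edges are uniform in
    ``[body.start - W, body.end + W - 1]``; each peak is dropped
    independently at ``peak_dropout``.  Decoy summits never come within
    W of any gene body, so decoys can never create a DIRECT call.
    """
    spec = spec or truth.spec
    rng = _rng(spec.seed, 1)
    w = spec.window
    gene_by_id = {g.gene_id: g for g in truth.gene_models}
    half_width_range = (100, 250)
    peaks: dict[str, list[Peak]] = {tf: [] for tf in spec.tf_panel}
    for tf in spec.tf_panel:
        counter = 0
        for edge in truth.edges_of(tf):
            if edge.directness != "DIRECT":
                continue
            body = gene_by_id[edge.gene_id].body
            summit = int(rng.integers(body.start - w, body.end + w))
            hw = int(rng.integers(*half_width_range))
            score = float(rng.uniform(5.0, 100.0))
            dropped = rng.random() < spec.peak_dropout
            if dropped:
                continue
            counter += 1
            start = max(0, summit - hw)
            end = min(spec.chrom_length, summit + hw + 1)
            peaks[tf].append(
                Peak(
                    interval=GenomicInterval(body.chrom, start, end),
                    summit=summit,
                    score=score,
                    source=tf,
                    peak_id=f"{tf}_t{counter:05d}",
                )
            )
        gaps = _decoy_ranges(truth.gene_models, spec, margin=half_width_range[1] + 1)
        if spec.decoy_peaks_per_tf and gaps:
            lengths = np.array([hi - lo for _, lo, hi in gaps], dtype=float)
            probs = lengths / lengths.sum()
            for i in range(spec.decoy_peaks_per_tf):
                chrom, lo, hi = gaps[int(rng.choice(len(gaps), p=probs))]
                summit = int(rng.integers(lo, hi))
                hw = int(rng.integers(*half_width_range))
                peaks[tf].append(
                    Peak(
                        interval=GenomicInterval(chrom, summit - hw, summit + hw + 1),
                        summit=summit,
                        score=float(rng.uniform(5.0, 100.0)),
                        source=tf,
                        peak_id=f"{tf}_d{i + 1:05d}",
                    )
                )
        peaks[tf].sort(key=lambda p: (p.interval.chrom, p.interval.start, p.peak_id))
    return peaks


def generate_de_tables(
    truth: SyntheticTruth, spec: TruthSpec | None = None
) -> dict[str, list[DERecord]]:
    """Knockout contrasts per TF plus the subset contrasts.

    Targets draw p ~ Beta(a, 1) and carry their planted log2FC;
    non-targets draw p ~ Uniform(0, 1) and log2FC ~ Normal(0, 0.1).
    The FDR column is the BH adjustment of the p column, row-exact.
    Contrast names are ``"<TF>_KO_vs_WT"`` and the subset contrasts.
    """
    spec = spec or truth.spec
    rng = _rng(spec.seed, 2)
    a = spec.target_p_shape
    gene_ids = [g.gene_id for g in truth.gene_models]
    tables: dict[str, list[DERecord]] = {}

    def make_table(contrast: str, planted: Mapping[str, float]) -> list[DERecord]:
        pvals: list[float] = []
        lfcs: list[float] = []
        for g in gene_ids:
            if g in planted:
                pvals.append(float(rng.beta(a, 1.0)))
                lfcs.append(planted[g])
            else:
                pvals.append(float(rng.uniform()))
                lfcs.append(float(rng.normal(0.0, 0.1)))
        fdrs = bh_adjust(pvals)
        return [
            DERecord(gene_id=g, log2fc=lfcs[i], pvalue=pvals[i], fdr=fdrs[i], contrast=contrast)
            for i, g in enumerate(gene_ids)
        ]

    for tf in spec.tf_panel:
        planted = {e.gene_id: e.kd_log2fc for e in truth.edges_of(tf)}
        tables[f"{tf}_KO_vs_WT"] = make_table(f"{tf}_KO_vs_WT", planted)

    mu, sigma = spec.effect_size
    for contrast in SUBSET_CONTRASTS:
        members = truth.signature_members[contrast]
        planted = {}
        for g in sorted(members["up"]):
            planted[g] = float(rng.lognormal(mu, sigma))
        for g in sorted(members["down"]):
            planted[g] = -float(rng.lognormal(mu, sigma))
        tables[contrast] = make_table(contrast, planted)
    return tables


@dataclass(frozen=True)
class RecoveryMetrics:
    """Edge-recovery metrics of an inferred network against truth.

    Precision is NaN (with ``degenerate`` set) when the inferred
    network is empty; mode/directness accuracies are computed over the
    recovered (intersection) edges.
    """

    precision: float
    recall: float
    f1: float
    mode_accuracy: float
    directness_accuracy: float
    n_inferred: int
    n_true: int
    degenerate: bool = False


def recovery_metrics(
    inferred: RegulatoryNetwork, truth: SyntheticTruth
) -> dict[str, RecoveryMetrics]:
    """Per-TF and pooled precision/recall/F1 plus label accuracies."""
    out: dict[str, RecoveryMetrics] = {}
    tf_list = list(truth.spec.tf_panel)

    def compute(
        inf_edges: Sequence[TargetEdge], true_edges: Sequence[TargetEdge]
    ) -> RecoveryMetrics:
        inf = {(e.tf, e.gene_id): e for e in inf_edges}
        tru = {(e.tf, e.gene_id): e for e in true_edges}
        shared = set(inf) & set(tru)
        if not inf:
            return RecoveryMetrics(
                precision=float("nan"),
                recall=0.0 if tru else float("nan"),
                f1=float("nan"),
                mode_accuracy=float("nan"),
                directness_accuracy=float("nan"),
                n_inferred=0,
                n_true=len(tru),
                degenerate=True,
            )
        precision = len(shared) / len(inf)
        recall = len(shared) / len(tru) if tru else float("nan")
        f1 = (
            2 * precision * recall / (precision + recall)
            if shared and precision + recall > 0
            else 0.0
        )
        if shared:
            mode_acc = sum(inf[k].mode == tru[k].mode for k in shared) / len(shared)
            dir_acc = sum(inf[k].directness == tru[k].directness for k in shared) / len(shared)
        else:
            mode_acc = dir_acc = float("nan")
        return RecoveryMetrics(
            precision=precision,
            recall=recall,
            f1=f1,
            mode_accuracy=mode_acc,
            directness_accuracy=dir_acc,
            n_inferred=len(inf),
            n_true=len(tru),
        )

    out["pooled"] = compute(inferred.edges, truth.edges)
    for tf in tf_list:
        out[tf] = compute(inferred.edges_of(tf), truth.edges_of(tf))
    return out


def write_dataset(
    truth: SyntheticTruth,
    peaks: Mapping[str, Sequence[Peak]],
    de_tables: Mapping[str, Sequence[DERecord]],
    outdir: str,
) -> dict[str, str]:
    """Write the dataset in the same formats the real pipeline reads.

    Produces ``genes.bed``, one ``<TF>.narrowPeak`` per TF, one
    ``<contrast>.de.tsv`` per contrast, and ``truth.json``; returns a
    name -> path mapping.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    gene_path = os.path.join(outdir, "genes.bed")
    write_bed6(truth.gene_models, gene_path)
    paths["genes"] = gene_path
    for tf in truth.spec.tf_panel:
        p = os.path.join(outdir, f"{tf}.narrowPeak")
        write_narrowpeak(list(peaks[tf]), p)
        paths[f"peaks:{tf}"] = p
    for contrast in sorted(de_tables):
        p = os.path.join(outdir, f"{contrast}.de.tsv")
        write_de_table(list(de_tables[contrast]), p)
        paths[f"de:{contrast}"] = p
    truth_path = os.path.join(outdir, "truth.json")
    payload = {
        "spec": {
            "seed": truth.spec.seed,
            "n_genes": truth.spec.n_genes,
            "tf_panel": list(truth.spec.tf_panel),
            "n_targets": truth.spec.n_targets,
            "frac_direct": truth.spec.frac_direct,
            "frac_act": truth.spec.frac_act,
            "target_p_shape": truth.spec.target_p_shape,
            "peak_dropout": truth.spec.peak_dropout,
            "window": truth.spec.window,
        },
        "edges": [
            {
                "tf": e.tf,
                "gene_id": e.gene_id,
                "directness": e.directness,
                "mode": e.mode,
                "kd_log2fc": e.kd_log2fc,
            }
            for e in truth.edges
        ],
        "signature_members": {
            c: {d: sorted(m) for d, m in dirs.items()}
            for c, dirs in truth.signature_members.items()
        },
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# Purpose-built calibration generators


def generate_concordant_pair(
    n_cosig: int = 1000,
    concordance: float = 0.9,
    n_null: int = 500,
    seed: int = 0,
) -> tuple[list[DERecord], list[DERecord]]:
    """Two DE tables with a planted sign-concordance.

    ``n_cosig`` genes are significant in both tables (p drawn far below
    any BH cut); each agrees in log2FC sign between the tables with
    probability ``concordance``.  ``n_null`` clearly non-significant
    genes are appended to both tables.
    """
    rng = np.random.default_rng(seed)
    recs_a: list[DERecord] = []
    recs_b: list[DERecord] = []

    def sig_p() -> float:
        return float(rng.uniform(1e-12, 1e-8))

    for i in range(n_cosig):
        g = f"S{i:05d}"
        sign_a = 1.0 if rng.random() < 0.5 else -1.0
        agree = rng.random() < concordance
        sign_b = sign_a if agree else -sign_a
        recs_a.append(
            DERecord(g, sign_a * float(rng.lognormal(0.5, 0.4)), sig_p(), 0.0, "A")
        )
        recs_b.append(
            DERecord(g, sign_b * float(rng.lognormal(0.5, 0.4)), sig_p(), 0.0, "B")
        )
    for i in range(n_null):
        g = f"N{i:05d}"
        for recs, label in ((recs_a, "A"), (recs_b, "B")):
            recs.append(
                DERecord(
                    g,
                    float(rng.normal(0.0, 0.1)),
                    float(rng.uniform(0.1, 1.0)),
                    0.0,
                    label,
                )
            )
    # recompute honest FDR columns
    for recs in (recs_a, recs_b):
        fdrs = bh_adjust([r.pvalue for r in recs])
        for i, r in enumerate(recs):
            recs[i] = DERecord(r.gene_id, r.log2fc, r.pvalue, min(1.0, fdrs[i]), r.contrast)
    return recs_a, recs_b


#: Occupancy archetypes for the clustering benchmark: the seven
#: weight-4 codewords of the [7,3] simplex code plus all-ones — any two
#: differ in at least 3 of the 7 panel positions.
_BENCHMARK_PANEL = ("Junb", "Jund", "Batf", "Fosl2", "Irf4", "p300", "Rorc")
_ARCHETYPES = np.array(
    [
        [1, 1, 1, 0, 1, 0, 0],
        [0, 1, 1, 1, 0, 1, 0],
        [0, 0, 1, 1, 1, 0, 1],
        [1, 0, 0, 1, 1, 1, 0],
        [0, 1, 0, 0, 1, 1, 1],
        [1, 0, 1, 0, 0, 1, 1],
        [1, 1, 0, 1, 0, 0, 1],
        [1, 1, 1, 1, 1, 1, 1],
    ],
    dtype=int,
)


def generate_pcrm_benchmark(
    n_modules: int = 4000,
    flip_rate: float = 0.05,
    seed: int = 0,
) -> tuple[list[PCRM], np.ndarray]:
    """pCRMs drawn from 8 occupancy archetypes with bit-flip noise.

    Returns the modules plus the planted archetype labels.  A row
    flipped to all-zero occupancy (no TF bound — not a module) has one
    archetype bit restored.
    """
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, len(_ARCHETYPES), size=n_modules)
    occ = _ARCHETYPES[labels].copy()
    flips = rng.random(occ.shape) < flip_rate
    occ = occ ^ flips
    for i in np.where(occ.sum(axis=1) == 0)[0]:
        occ[i, int(np.argmax(_ARCHETYPES[labels[i]]))] = 1
    pcrms = [
        PCRM(
            region=GenomicInterval("chrSim", 1000 * i, 1000 * i + 500),
            member_peaks=[f"bench_p{i}"],
            occupancy={tf: bool(occ[i, j]) for j, tf in enumerate(_BENCHMARK_PANEL)},
            signal={tf: float(occ[i, j]) for j, tf in enumerate(_BENCHMARK_PANEL)},
        )
        for i in range(n_modules)
    ]
    return pcrms, labels


# ---------------------------------------------------------------------------
# Bundled fixture

#: Conditions of the small dataset shipped with the package.
FIXTURE_SPEC = TruthSpec(seed=42, n_genes=200, tf_panel=("Junb", "Batf", "Irf4"),
                         target_p_shape=0.01, peak_dropout=0.0)


def fixture_path() -> str:
    """Directory of the bundled synthetic fixture (200 genes, 3 TFs, seed 42)."""
    return os.path.join(os.path.dirname(__file__), "data", "fixture_seed42")


def fixture_config(out_dir: str):
    """A ready-to-run PipelineConfig over the bundled fixture."""
    from .pipeline import PipelineConfig

    root = fixture_path()
    tfs = list(FIXTURE_SPEC.tf_panel)
    return PipelineConfig(
        genes=os.path.join(root, "genes.bed"),
        peaks={tf: os.path.join(root, f"{tf}.narrowPeak") for tf in tfs},
        de_tables={
            **{
                f"{tf}_KO_vs_WT": os.path.join(root, f"{tf}_KO_vs_WT.de.tsv")
                for tf in tfs
            },
            **{c: os.path.join(root, f"{c}.de.tsv") for c in SUBSET_CONTRASTS},
        },
        ko_contrasts={tf: f"{tf}_KO_vs_WT" for tf in tfs},
        subset_contrasts=list(SUBSET_CONTRASTS),
        annotate_contrast="Th17_vs_Th0",
        quadrant_pairs=[["Junb_KO_vs_WT", "Batf_KO_vs_WT"]],
        pair_modes=[["Junb", "Batf"]],
        gsea_rank_contrast="Junb_KO_vs_WT",
        gsea_signature_sources=["Th17_vs_Th0"],
        out_dir=out_dir,
    )
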