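"""End-to-end orchestration from a single configuration.

Runs, in order: peak-gene association -> network edge/node tables ->
quadrant / pair-mode / net-effect JSON summaries -> pCRM table and
heatmap matrix -> signature GMTs, RNK files and the enrichment report
-> volcano-export TSVs.  Every output is listed in a manifest with a
content hash; a rerun with identical config and inputs reproduces
identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from . import enrichment, io, mapping, network, pcrm
from .io import DERecord

__all__ = ["PipelineConfig", "run_pipeline", "make_volcano_export", "write_volcano_export"]

logger = logging.getLogger(__name__)

#: Volcano trendline conventions: fold change 1.5 and p = 0.01.
VOLCANO_TRENDLINES = {"fold_change": 1.5, "p_value": 0.01}
DEFAULT_DE_P_CAP = 1e-30
DEFAULT_DIFFBIND_P_CAP = 1e-25


@dataclass
class PipelineConfig:
    """All inputs, thresholds and seeds for one pipeline run.

    ``peaks`` maps TF -> narrowPeak/BED path; ``de_tables`` maps
    contrast name -> DE TSV path; ``ko_contrasts`` maps TF -> the name
    of its knockout contrast in ``de_tables``.
    """

    genes: str = ""
    genes_dialect: str = "bed6"
    peaks: dict[str, str] = field(default_factory=dict)
    de_tables: dict[str, str] = field(default_factory=dict)
    ko_contrasts: dict[str, str] = field(default_factory=dict)
    subset_contrasts: list[str] = field(default_factory=list)
    annotate_contrast: str = ""
    quadrant_pairs: list[list[str]] = field(default_factory=list)
    pair_modes: list[list[str]] = field(default_factory=list)
    alpha: float = 0.05
    window_w: int = 5000
    manual_direct: dict[str, list[str]] = field(default_factory=dict)
    pcrm_k: int = 8
    pcrm_seed: int = 0
    gsea_nperm: int = 10_000
    gsea_seed: int = 0
    gsea_weight: float = 1.0
    signature_n: int = 100
    gsea_rank_contrast: str = ""
    gsea_signature_sources: list[str] = field(default_factory=list)
    de_p_cap: float = DEFAULT_DE_P_CAP
    diffbind_p_cap: float = DEFAULT_DIFFBIND_P_CAP
    out_dir: str = "chipnet_out"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def override(self, assignments: Sequence[str]) -> "PipelineConfig":
        """Apply ``key=value`` overrides (YAML-parsed values)."""
        for item in assignments:
            if "=" not in item:
                raise ValueError(f"override must be key=value, got {item!r}")
            key, value = item.split("=", 1)
            if key not in self.__dataclass_fields__:
                raise ValueError(f"unknown config key {key!r}")
            setattr(self, key, yaml.safe_load(value))
        return self

    def validate(self) -> None:
        if not self.genes or not os.path.exists(self.genes):
            raise FileNotFoundError(f"gene annotation not found: {self.genes!r}")
        for tf, path in self.peaks.items():
            if not os.path.exists(path):
                raise FileNotFoundError(f"peak file for {tf} not found: {path!r}")
        for contrast, path in self.de_tables.items():
            if not os.path.exists(path):
                raise FileNotFoundError(f"DE table for {contrast} not found: {path!r}")
        for tf, contrast in self.ko_contrasts.items():
            if contrast not in self.de_tables:
                raise ValueError(f"ko_contrasts[{tf}] = {contrast!r} not among de_tables")


def make_volcano_export(
    de_table: Sequence[DERecord], alpha: float = 0.05, p_cap: float = DEFAULT_DE_P_CAP
) -> dict:
    """Plot-ready volcano table: log2FC, capped -log10 p, significance.

    One row per input gene; the standard trendline parameters (fold
    change 1.5, p = 0.01) travel along as metadata.
    """
    rows = [
        {
            "gene_id": r.gene_id,
            "log2fc": r.log2fc,
            "minus_log10_p": -math.log10(max(r.pvalue, p_cap)),
            "significant": r.fdr < alpha,
        }
        for r in de_table
    ]
    return {"rows": rows, "trendlines": dict(VOLCANO_TRENDLINES), "p_cap": p_cap, "alpha": alpha}


def write_volcano_export(export: dict, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# trendline_fold_change={export['trendlines']['fold_change']}"
            f"\tp={export['trendlines']['p_value']}\tp_cap={export['p_cap']!r}\n"
        )
        fh.write("gene_id\tlog2fc\tminus_log10_p\tsignificant\n")
        for row in export["rows"]:
            fh.write(
                f"{row['gene_id']}\t{row['log2fc']!r}\t{row['minus_log10_p']!r}\t"
                f"{str(bool(row['significant']))}\n"
            )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _summary_to_jsonable(s: network.GroupSummary) -> dict:
    def clean(x: float):
        return None if isinstance(x, float) and math.isnan(x) else x

    return {
        "n": s.n,
        "median": clean(s.median),
        "q1": clean(s.q1),
        "q3": clean(s.q3),
        "values": list(s.values),
        "empty": s.empty,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; return the output manifest."""
    config.validate()
    outdir = config.out_dir
    os.makedirs(outdir, exist_ok=True)
    produced: list[str] = []
    manifest_path = os.path.join(outdir, "manifest.json")

    def out(name: str) -> str:
        produced.append(name)
        return os.path.join(outdir, name)

    stage = "load-inputs"
    try:
        genes = io.read_gene_models(config.genes, dialect=config.genes_dialect)
        peak_sets = {tf: io.read_narrowpeak(path, source=tf) for tf, path in config.peaks.items()}
        de = {
            contrast: io.read_de_table(path, contrast=contrast)
            for contrast, path in sorted(config.de_tables.items())
        }
        gene_ids = {g.gene_id for g in genes}
        de_genes = {r.gene_id for table in de.values() for r in table}
        if de and not (gene_ids & de_genes):
            raise ValueError(
                "gene annotation and DE tables share no gene identifiers "
                "(namespace mismatch: symbols vs ids?)"
            )

        stage = "associations"
        associations: dict[str, list[mapping.Association]] = {}
        for tf in sorted(peak_sets):
            assoc = mapping.map_peaks_to_genes(peak_sets[tf], genes, window=config.window_w)
            associations[tf] = assoc
            mapping.write_associations(assoc, out(f"associations_{tf}.tsv"))

        stage = "network"
        net_config = network.NetworkConfig(
            alpha=config.alpha,
            window_w=config.window_w,
            manual_direct={tf: tuple(g) for tf, g in config.manual_direct.items()},
        )
        ko_de = {tf: de[contrast] for tf, contrast in sorted(config.ko_contrasts.items())}
        net = network.build_network(
            ko_de, {tf: associations.get(tf, []) for tf in ko_de}, net_config
        )
        if config.annotate_contrast:
            net = network.annotate_nodes(
                net, de[config.annotate_contrast], alpha=config.alpha,
                contrast=config.annotate_contrast,
            )
        io.write_network_table(net, out("network_edges.tsv"), out("network_nodes.tsv"))

        stage = "quadrants"
        quad_out = {}
        for pair in config.quadrant_pairs:
            ca, cb = pair
            res = network.quadrant_concordance(de[ca], de[cb], alpha=config.alpha)
            quad_out[f"{ca}__vs__{cb}"] = res
        if quad_out:
            _write_json(quad_out, out("quadrant_concordance.json"))

        stage = "pair-modes"
        pm_out = {}
        for tf_a, tf_b in config.pair_modes:
            groups = network.pair_mode_groups(net, tf_a, tf_b)
            entry: dict = {"groups": groups}
            if config.annotate_contrast:
                eff = network.net_effect_summary(
                    groups, de[config.annotate_contrast], alpha=config.alpha
                )
                entry["net_effect"] = {
                    combo: _summary_to_jsonable(s) for combo, s in eff.items()
                }
            pm_out[f"{tf_a}__{tf_b}"] = entry
        if pm_out:
            _write_json(pm_out, out("pair_modes.json"))

        stage = "pcrm"
        if peak_sets:
            modules = pcrm.build_pcrms(peak_sets)
            result = pcrm.cluster_pcrms(modules, k=config.pcrm_k, seed=config.pcrm_seed)
            pcrm.write_pcrm_table(modules, out("pcrms.tsv"))
            with open(out("pcrm_heatmap_matrix.tsv"), "w") as fh:
                fh.write("module_index\tcluster_id\t" + "\t".join(result.tf_panel) + "\n")
                for row_idx, mat_row in zip(result.row_order, result.matrix):
                    lab = modules[int(row_idx)].cluster_id
                    vals = "\t".join(repr(float(v)) for v in mat_row)
                    fh.write(f"{int(row_idx)}\t{lab}\t{vals}\n")

        stage = "gsea"
        gene_sets: list[enrichment.GeneSet] = []
        for contrast in config.gsea_signature_sources:
            for direction in ("up", "down"):
                gene_sets.append(
                    enrichment.signature_from_contrast(
                        de[contrast], direction, n=config.signature_n,
                        name=f"{contrast}_{direction}",
                    )
                )
        if gene_sets:
            io.write_gmt(gene_sets, out("signatures.gmt"))
        if config.gsea_rank_contrast:
            ranked = enrichment.rank_metric(de[config.gsea_rank_contrast])
            io.write_rnk(ranked, out(f"{config.gsea_rank_contrast}.rnk"))
            if gene_sets:
                results = enrichment.gsea_preranked(
                    ranked,
                    gene_sets,
                    nperm=config.gsea_nperm,
                    seed=config.gsea_seed,
                    weight=config.gsea_weight,
                )
                enrichment.write_enrichment_report(results, out("gsea_report.tsv"))

        stage = "volcano"
        for contrast in sorted(de):
            export = make_volcano_export(de[contrast], alpha=config.alpha, p_cap=config.de_p_cap)
            write_volcano_export(export, out(f"volcano_{contrast}.tsv"))
    except Exception as exc:
        manifest = {
            "complete": False,
            "failed_stage": stage,
            "error": str(exc),
            "files": {name: _sha256(os.path.join(outdir, name)) for name in produced
                      if os.path.exists(os.path.join(outdir, name))},
        }
        _write_json(manifest, manifest_path)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "complete": True,
        "files": {name: _sha256(os.path.join(outdir, name)) for name in sorted(produced)},
    }
    _write_json(manifest, manifest_path)
    logger.info("pipeline complete: %d outputs in %s", len(produced), outdir)
    return manifest
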