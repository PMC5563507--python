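import math

import numpy as np
import pytest

from chipnet.io import DERecord
from chipnet.mapping import map_peaks_to_genes
from chipnet.network import (
    NetworkConfig,
    annotate_nodes,
    build_network,
    classify_target,
    net_effect_summary,
    pair_mode_groups,
    quadrant_concordance,
    subset_preference,
)
from chipnet.simulate import (
    TruthSpec,
    generate_de_tables,
    generate_peaks,
    generate_truth,
    recovery_metrics,
)

CFG = NetworkConfig(manual_direct={})


def _net_from(genes, peaks, de, window=5000, config=CFG):
    assoc = {tf: map_peaks_to_genes(pk, genes, window=window) for tf, pk in peaks.items()}
    return build_network(de, assoc, config)


class TestClassify:
    def test_significant_with_peaks_is_direct_rep(self):
        edge = classify_target(DERecord("G", 1.4, 1e-4, 0.03), 2, CFG)
        assert (edge.directness, edge.mode, edge.n_peaks) == ("DIRECT", "REP", 2)

    def test_fdr_exactly_alpha_is_not_significant(self):
        assert classify_target(DERecord("G", 1.4, 1e-4, 0.05), 2, CFG) is None

    def test_manual_direct_without_peaks(self):
        edge = classify_target(DERecord("Ifng", -2.0, 1e-6, 0.001), 0, CFG, manual=True)
        assert edge.directness == "DIRECT" and edge.mode == "ACT" and edge.manual_flag

    def test_zero_log2fc_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert classify_target(DERecord("G", 0.0, 1e-4, 0.01), 1, CFG) is None
        assert "mode undefined" in caplog.text

    def test_flip_orientation(self):
        cfg = NetworkConfig(manual_direct={}, flip_log2fc=True)
        edge = classify_target(DERecord("G", 1.4, 1e-4, 0.03), 0, cfg)
        assert edge.mode == "ACT" and edge.kd_log2fc == -1.4


class TestBuildNetwork:
    def test_empty_de_tables_give_empty_network(self):
        net = build_network({}, {}, CFG)
        assert net.edges == []

    def test_association_without_de_table_rejected(self):
        with pytest.raises(ValueError, match="no DE table"):
            build_network({}, {"TFA": []}, CFG)

    def test_noise_free_recovery_is_exact(self, noise_free_instance):
        genes, peaks, de, truth = noise_free_instance
        net = _net_from(genes, peaks, de)
        got = {(e.tf, e.gene_id): (e.directness, e.mode) for e in net.edges}
        assert got == truth

    def test_removing_peaks_relabels_but_keeps_genes(self, noise_free_instance):
        genes, peaks, de, truth = noise_free_instance
        net_no_peaks = _net_from(genes, {tf: [] for tf in peaks}, de)
        got = {(e.tf, e.gene_id): e.directness for e in net_no_peaks.edges}
        assert set(got) == set(truth)
        assert all(v == "INDIRECT" for v in got.values())

    def test_manual_direct_still_requires_significance(self):
        cfg = NetworkConfig(manual_direct={"TFA": ("G1",)})
        de = {"TFA": [DERecord("G1", -2.0, 0.5, 0.8)]}
        net = build_network(de, {"TFA": []}, cfg)
        assert net.edges == []


class TestQuadrantConcordance:
    @staticmethod
    def _table(signs, sig=True):
        fdr = 0.001 if sig else 0.5
        return [DERecord(f"G{i}", s * 1.5, 1e-5, fdr) for i, s in enumerate(signs)]

    def test_self_comparison_is_fully_concordant(self):
        t = self._table([1, -1, 1, -1, -1])
        res = quadrant_concordance(t, t)
        assert res["concordance"] == 1.0
        assert math.isclose(sum(res["fractions"].values()), 1.0)

    def test_negated_comparison_is_fully_discordant(self):
        t = self._table([1, -1, 1, -1])
        neg = [DERecord(r.gene_id, -r.log2fc, r.pvalue, r.fdr) for r in t]
        assert quadrant_concordance(t, neg)["concordance"] == 0.0

    def test_only_cosignificant_genes_counted(self):
        a = self._table([1, 1, 1]) + [DERecord("X", 2.0, 0.5, 0.9)]
        b = self._table([1, 1, -1]) + [DERecord("X", 2.0, 1e-6, 0.001)]
        res = quadrant_concordance(a, b)
        assert res["n_cosignificant"] == 3
        assert res["genes"]["a_up_b_down"] == ["G2"]

    def test_no_cosignificant_genes_rejected(self):
        a = self._table([1, -1], sig=False)
        b = self._table([1, -1], sig=True)
        with pytest.raises(ValueError, match="co-significant"):
            quadrant_concordance(a, b)


class TestPairModes:
    @pytest.fixture
    def planted_pair_network(self):
        spec = TruthSpec(
            seed=7,
            n_genes=150,
            n_targets=10,
            tf_panel=("TFA", "TFB"),
            target_p_shape=1e-6,  # targets essentially certain to be significant
            pair_mode_table={("TFA", "TFB"): {"ACT:ACT": 8, "ACT:REP": 5, "REP:ACT": 4, "REP:REP": 6}},
        )
        truth = generate_truth(spec)
        peaks = generate_peaks(truth)
        de = generate_de_tables(truth)
        genes = truth.gene_models
        net = _net_from(
            genes, peaks, {tf: de[f"{tf}_KO_vs_WT"] for tf in spec.tf_panel}
        )
        return truth, net, de

    def test_planted_modes_recovered(self, planted_pair_network):
        truth, net, _ = planted_pair_network
        groups = pair_mode_groups(net, "TFA", "TFB")
        a_modes = {e.gene_id: e.mode for e in truth.edges_of("TFA")}
        b_modes = {e.gene_id: e.mode for e in truth.edges_of("TFB")}
        planted = {
            g: f"{a_modes[g]}:{b_modes[g]}" for g in set(a_modes) & set(b_modes)
        }
        shared = set(groups) & set(planted)
        assert shared and all(groups[g] == planted[g] for g in shared)

    def test_single_tf_genes_absent(self, planted_pair_network):
        _, net, _ = planted_pair_network
        groups = pair_mode_groups(net, "TFA", "TFB")
        only_a = {e.gene_id for e in net.edges_of("TFA")} - {
            e.gene_id for e in net.edges_of("TFB")
        }
        assert not (only_a & set(groups))

    def test_unknown_tf_rejected(self, planted_pair_network):
        _, net, _ = planted_pair_network
        with pytest.raises(ValueError, match="not present"):
            pair_mode_groups(net, "TFA", "Nope")


def sort_quartiles(values):
    """Independent sort-and-interpolate order-statistics oracle."""
    xs = sorted(values)
    n = len(xs)

    def q(p):
        h = p * (n - 1)
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    return q(0.25), q(0.5), q(0.75)


class TestNetEffect:
    def test_summary_matches_order_statistics_oracle(self, rng):
        groups = {f"G{i}": "ACT:ACT" for i in range(40)}
        lfcs = rng.normal(1.0, 2.0, size=40)
        subset = [DERecord(f"G{i}", float(lfcs[i]), 1e-6, 0.001) for i in range(40)]
        res = net_effect_summary(groups, subset)["ACT:ACT"]
        q1, med, q3 = sort_quartiles(lfcs)
        assert res.n == 40
        assert math.isclose(res.median, med) and math.isclose(res.q1, q1) and math.isclose(res.q3, q3)

    def test_empty_group_flagged_not_dropped(self):
        res = net_effect_summary({"G1": "ACT:ACT"}, [DERecord("G1", 1.0, 0.5, 0.9)])
        assert set(res) == {"ACT:ACT", "ACT:REP", "REP:ACT", "REP:REP"}
        assert res["ACT:ACT"].empty and res["ACT:ACT"].n == 0

    def test_planted_coactivated_group_upregulated(self):
        spec = TruthSpec(
            seed=11,
            n_genes=200,
            n_targets=5,
            tf_panel=("TFA", "TFB"),
            target_p_shape=1e-6,
            signature_overlap=1.0,  # every ACT target planted subset-up
            pair_mode_table={("TFA", "TFB"): {"ACT:ACT": 20}},
        )
        truth = generate_truth(spec)
        de = generate_de_tables(truth)
        net = _net_from(
            truth.gene_models,
            generate_peaks(truth),
            {tf: de[f"{tf}_KO_vs_WT"] for tf in spec.tf_panel},
        )
        groups = pair_mode_groups(net, "TFA", "TFB")
        res = net_effect_summary(groups, de["Th17_vs_Th0"])["ACT:ACT"]
        assert res.n > 0 and res.median > 0


class TestSubsetPreference:
    def test_planted_repression_targets_prefer_other_subset(self):
        spec = TruthSpec(
            seed=13, n_genes=300, n_targets=60, tf_panel=("TFA",),
            frac_act=0.5, target_p_shape=1e-6, signature_overlap=1.0,
        )
        truth = generate_truth(spec)
        de = generate_de_tables(truth)
        net = _net_from(truth.gene_models, generate_peaks(truth), {"TFA": de["TFA_KO_vs_WT"]})
        res = subset_preference(net, "TFA", "REP", de["Th17_vs_Th1"])
        assert res.n > 0 and res.median < 0

    def test_values_are_projection_of_subset_table(self, noise_free_instance):
        genes, peaks, de, _ = noise_free_instance
        net = _net_from(genes, peaks, de)
        subset = [DERecord(f"G{i}", float(i) - 3.5, 1e-6, 0.001) for i in range(8)]
        res = subset_preference(net, "TFA", "ACT", subset)
        pool = {r.log2fc for r in subset}
        assert set(res.values) <= pool

    def test_no_edges_of_mode_gives_empty_flag(self, noise_free_instance):
        genes, peaks, de, _ = noise_free_instance
        act_only = {"TFA": de["TFA"], "TFB": [DERecord("G3", -0.7, 1e-12, 1e-10)]}
        net = _net_from(genes, peaks, act_only)
        res = subset_preference(net, "TFB", "REP", [DERecord("G0", 1.0, 1e-6, 0.001)])
        assert res.empty


class TestAnnotateNodes:
    def test_significant_nodes_get_log2fc_others_marked(self, noise_free_instance):
        genes, peaks, de, _ = noise_free_instance
        net = _net_from(genes, peaks, de)
        subset = [DERecord("G0", 2.5, 1e-6, 0.001), DERecord("G1", 1.0, 0.5, 0.9)]
        annotated = annotate_nodes(net, subset, contrast="Th17_vs_Th0")
        assert annotated.node_annotations["G0"].subset_log2fc == 2.5
        assert annotated.node_annotations["G1"].subset_log2fc is None
        assert not annotated.node_annotations["G3"].significant  # absent from table
        assert annotated.edges == net.edges  # edge set never altered


class TestDropoutRelabeling:
    def test_gene_set_invariant_and_monotone_in_dropout(self):
        import dataclasses

        spec = TruthSpec(seed=5, n_genes=300, n_chroms=3, chrom_length=2_500_000,
                         n_targets=60, frac_direct=1.0, tf_panel=("TFA",),
                         target_p_shape=1e-6, decoy_peaks_per_tf=0)
        truth = generate_truth(spec)
        de = {"TFA": generate_de_tables(truth)["TFA_KO_vs_WT"]}
        nets = {}
        for d in (0.0, 0.3, 0.7):
            pk = generate_peaks(truth, dataclasses.replace(spec, peak_dropout=d))
            nets[d] = _net_from(truth.gene_models, pk, de)
        gene_sets = {d: {e.gene_id for e in n.edges} for d, n in nets.items()}
        assert gene_sets[0.0] == gene_sets[0.3] == gene_sets[0.7]
        n_direct = {d: sum(e.directness == "DIRECT" for e in n.edges) for d, n in nets.items()}
        assert n_direct[0.0] >= n_direct[0.3] >= n_direct[0.7]
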