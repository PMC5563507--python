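import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chipnet.genomic import GeneModel, GenomicInterval, Peak
from chipnet.io import DERecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_peak(chrom, start, end, summit=None, source="TF", peak_id=None, score=10.0):
    if summit is None:
        summit = (start + end) // 2
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        summit=summit,
        score=score,
        source=source,
        peak_id=peak_id or f"{source}_{chrom}_{start}",
    )


def make_gene(gene_id, chrom, start, end, strand="+"):
    return GeneModel(gene_id=gene_id, symbol=gene_id, body=GenomicInterval(chrom, start, end), strand=strand)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noise_free_instance():
    """Handcrafted noise-free study: 8 genes, 2 TFs, planted edges.

    Target p-values are far below any BH cut and null p-values far
    above it, so network recovery must be exact.
    """
    genes = [make_gene(f"G{i}", "chr1", 100_000 * (i + 1), 100_000 * (i + 1) + 4000) for i in range(8)]
    # TFA: G0 DIRECT ACT, G1 INDIRECT REP, G2 DIRECT REP
    # TFB: G0 DIRECT REP, G3 INDIRECT ACT
    peaks = {
        "TFA": [
            make_peak("chr1", 99_000, 99_400, summit=99_200, source="TFA", peak_id="a1"),
            make_peak("chr1", 301_000, 301_400, summit=301_200, source="TFA", peak_id="a2"),
        ],
        "TFB": [make_peak("chr1", 104_500, 104_900, summit=104_700, source="TFB", peak_id="b1")],
    }

    def table(planted):
        recs = []
        for i in range(8):
            g = f"G{i}"
            if g in planted:
                recs.append(DERecord(g, planted[g], 1e-12, 1e-10))
            else:
                recs.append(DERecord(g, 0.01, 0.6, 0.9))
        return recs

    de = {
        "TFA": table({"G0": -2.0, "G1": 1.5, "G2": 0.8}),
        "TFB": table({"G0": 1.2, "G3": -0.7}),
    }
    truth_edges = {
        ("TFA", "G0"): ("DIRECT", "ACT"),
        ("TFA", "G1"): ("INDIRECT", "REP"),
        ("TFA", "G2"): ("DIRECT", "REP"),
        ("TFB", "G0"): ("DIRECT", "REP"),
        ("TFB", "G3"): ("INDIRECT", "ACT"),
    }
    return genes, peaks, de, truth_edges
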