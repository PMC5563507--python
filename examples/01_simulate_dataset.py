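"""Generate a synthetic study with planted ground truth.

Creates gene models, per-TF peak sets and knockout/subset DE tables
from a planted TF -> gene network, then writes them in the formats the
real pipeline reads (BED6, narrowPeak, TSV).
"""

import tempfile

from chipnet.simulate import (
    FIXTURE_SPEC,
    generate_de_tables,
    generate_peaks,
    generate_truth,
    write_dataset,
)

truth = generate_truth(FIXTURE_SPEC)
peaks = generate_peaks(truth)
de = generate_de_tables(truth)

n_direct = sum(e.directness == "DIRECT" for e in truth.edges)
print(f"genes placed        : {len(truth.gene_models)}")
print(f"planted edges       : {len(truth.edges)} ({n_direct} DIRECT)")
for tf, pk in peaks.items():
    print(f"peaks for {tf:<6}    : {len(pk)} (incl. decoys far from any gene)")
print(f"DE contrasts        : {sorted(de)}")

with tempfile.TemporaryDirectory() as tmp:
    paths = write_dataset(truth, peaks, de, tmp)
    print(f"wrote {len(paths)} files, e.g. {sorted(paths)[:3]}")

# The planted edges are the ground truth every later stage is checked
# against: DIRECT edges come with a peak summit within 5 kb of the gene
# body, ACT edges with expression decreased in the knockout.
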