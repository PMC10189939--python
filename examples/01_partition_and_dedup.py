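"""Dataset bookkeeping: deduplication and the knottin / non-knottin split.

Builds a label table with the real dataset's class geometry (1227 CDPs:
876 non-knottins of which 513 expressed, 351 knottins of which 165
expressed), plants 22 exact duplicate rows, and shows that reading the
table removes them and that partition reporting reproduces the expressed
percentages.
"""

import tempfile
from pathlib import Path

import numpy as np

from cyspresso import io, synthetic

records = synthetic.make_paper_shaped_dataset(seed=0)
rng = np.random.default_rng(0)
table = records + [records[i] for i in rng.choice(len(records), 22, replace=False)]
table = [table[i] for i in rng.permutation(len(table))]

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "labels.csv"
    io.write_label_table(table, path)
    loaded = io.read_label_table(path)

print(f"rows written: {len(table)}, records after deduplication: {len(loaded)}")

summary = io.partition_dataset(loaded).summary()
for name, stats in summary.items():
    print(
        f"{name:12s} total={stats['total']:4d} expressed={stats['expressed']:3d} "
        f"({stats['expressed_pct']}%)"
    )
# The percentages are the fraction of peptides whose recombinant
# expression succeeded; the skew between partitions is why the pipeline
# trains independent knottin and non-knottin classifier heads.
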