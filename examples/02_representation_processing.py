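"""From raw per-residue blocks to classifier-ready inputs.

One peptide's representation comes as four blocks: single (L x 384),
pair (L x L x 128, reduced to L x 128 by averaging the partner-residue
axis), MSA (L x 256) and structure module (L x 384), plus a per-residue
pLDDT confidence track.  Five prediction runs are produced; the one with
the highest mean pLDDT is kept.  The four blocks concatenate to L x 1152,
are zero-padded to 50 rows for the kernel transform, or mean-pooled over
true residues for the forest.
"""

import numpy as np

from cyspresso.representations import (
    BLOCK_WIDTHS,
    ModelRun,
    ModelRunSet,
    PLDDTTrack,
    ResidueRepresentation,
    concat_blocks,
    mean_pool,
    pad_to,
    reduce_pair,
    select_best_run,
)

rng = np.random.default_rng(0)
L = 34

def make_run(shift):
    blocks = {
        name: ResidueRepresentation(name, rng.normal(size=(L, BLOCK_WIDTHS[name])))
        for name in ("single", "pair_reduced", "msa", "structure")
    }
    return ModelRun(blocks=blocks, plddt=PLDDTTrack(np.clip(70 + shift + rng.normal(0, 3, L), 0, 100)))

runs = ModelRunSet(tuple(make_run(s) for s in (0.0, 6.0, 2.0, -1.0, 3.0)))
best = select_best_run(runs)
print("mean pLDDT per run:", [round(r.plddt.mean_plddt, 1) for r in runs.runs])
print("selected run mean pLDDT:", round(best.plddt.mean_plddt, 1))

raw_pair = rng.normal(size=(L, L, 128))
reduced = reduce_pair(raw_pair)
print("pair tensor", raw_pair.shape, "->", reduced.shape, "(partner axis averaged)")

combined, block_map = concat_blocks(
    best.blocks["single"], best.blocks["pair_reduced"],
    best.blocks["msa"], best.blocks["structure"],
)
print("combined width:", combined.n_channels, "spans:", block_map.spans)
print("channel 511 belongs to:", block_map.block_of(511))

padded = pad_to(combined)
pooled = mean_pool(combined)
print(f"padded to {padded.values.shape} with true_length={padded.true_length}; "
      f"pooled vector length {pooled.shape[0]}")
# Pooling uses only the true residues, so it commutes with padding.
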