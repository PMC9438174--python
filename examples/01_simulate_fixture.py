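"""Generate the canonical synthetic experiment and write it to disk.

Builds a replicated 7-day differentiation time course (days 0-30, 3
replicates) with 10 planted gene-miRNA pairs sharing mirrored trajectories,
500 background genes, 200 background miRNAs and a 510-row interaction table
(10 true pairs + 500 decoy edges), then writes the TSV/JSON fixture bundle.
"""

import tempfile
from pathlib import Path

import mircascade as mc

bundle = mc.generate(mc.canonical_config(seed=42))
out_dir = Path(tempfile.mkdtemp()) / "fixture"
paths = mc.write_fixture(bundle, out_dir)

print(f"genes matrix : {bundle.genes.n_transcripts} transcripts x {bundle.genes.n_samples} samples")
print(f"mirna matrix : {bundle.mirnas.n_transcripts} transcripts x {bundle.mirnas.n_samples} samples")
print(f"interactions : {len(bundle.interactions)} rows "
      f"({len(bundle.truth.true_pairs)} true pairs, "
      f"{len(bundle.interactions) - len(bundle.truth.true_pairs)} decoys)")
print(f"written to   : {out_dir}")
# The truth table records which transcripts carry planted signal, so every
# later stage can be scored for recall/precision against it.
n_planted = sum(1 for v in bundle.truth.labels.values() if v != "background")
print(f"truth labels : {n_planted} planted transcripts, "
      f"{len(bundle.truth.labels) - n_planted} background")
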