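"""Two-tiered redundancy filter on a scaffold set.

Short scaffolds whose k-mer content is already carried by longer scaffolds
are dropped; the report shows the redundant fraction of each removal and how
many distinct k-mers existed only in removed scaffolds (unique content lost).
"""

import numpy as np

from polyqc.redundancy import filter_scaffolds
from polyqc.simulate import random_dna

rng = np.random.default_rng(1)
backbone = random_dna(rng, 8_000)
scaffolds = {
    "scaffold_1": backbone,
    "fragment_dup": backbone[1_000:2_400],      # fully contained
    "fragment_half": backbone[3_000:3_700] + random_dna(rng, 700),  # half novel
    "fragment_new": random_dna(rng, 1_200),     # entirely novel
}

report, kept = filter_scaffolds(scaffolds, min_len=2_000, k=31, redundancy_threshold=0.95)
print(f"kept            : {report.kept_ids}")
for sid, (length, frac) in report.removed_redundant.items():
    print(f"removed         : {sid} ({length} bp, {frac:.0%} redundant)")
print(f"unique k-mers lost: {report.unique_content_lost}")
print(f"N50 {report.n50_before} -> {report.n50_after}")
# only the fully contained fragment is removed; partially novel scaffolds
# stay because their redundant fraction is below the 0.95 threshold
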