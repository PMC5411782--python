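"""Spectra-cn assembly QC: decompose read k-mers by assembly copy number.

A perfect assembly shows no read k-mers at copy number 0 above the error
threshold (missing content) and no assembly k-mers at read multiplicity 0
(artifact content). Deleting a chromosome creates missing content; appending
a random chimera creates artifact content.
"""

from polyqc import kmers
from polyqc.simulate import GenomeConfig, generate_genome, generate_reads, random_dna

import numpy as np

genome, _ = generate_genome(GenomeConfig(n_triads=21, seed=1, spacer_length=200))
reads = generate_reads(genome, coverage=30, read_len=150, error_rate=0.0, seed=2)
read_kmers = kmers.count_kmers(reads, k=31)


def report(label, assembly):
    asm_kmers = kmers.count_kmers(assembly, k=31)
    cn = kmers.spectra_cn(read_kmers, asm_kmers)
    threshold = kmers.error_threshold(read_kmers.spectrum())
    s = kmers.qc_summary(cn, threshold)
    print(
        f"{label:18s} missing={s.missing_kmers:6d} artifact={s.artifact_kmers:6d} "
        f"completeness={s.completeness:.4f}"
    )


perfect = genome.sequences()
report("perfect assembly", perfect)
report("chromosome lost", {n: s for n, s in perfect.items() if n != "3B"})
chimeric = dict(perfect)
chimeric["chimera"] = random_dna(np.random.default_rng(9), 10_000)
report("chimera added", chimeric)
# missing counts content the assembly lacks; artifact counts assembled
# sequence the reads never support (chimeric joins, consensus errors)
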