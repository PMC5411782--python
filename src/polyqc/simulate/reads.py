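"""Short-read simulator: uniform coverage, substitution errors only.

The k-mer QC stage is substitution-sensitive, so the simulator plants
substitutions at the requested per-base rate and no indels. Read names
encode the source coordinates (``name|chromosome|start0|strand``), which
lets tests verify error rates without alignment.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from ..gffio import write_fasta
from ..kmers import revcomp
from .genome import SyntheticGenome, mutate


def generate_reads(
    genome: SyntheticGenome | Mapping[str, str],
    coverage: float,
    read_len: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """Simulate reads to ``coverage``-fold depth over the whole genome.

    Total read bases are within one read of coverage x genome length; reads
    are drawn uniformly per chromosome (largest-remainder apportionment of
    the read count), from either strand.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not 0.0 <= error_rate < 0.1:
        raise ValueError("error_rate must be in [0, 0.1)")
    seqs = genome.sequences() if isinstance(genome, SyntheticGenome) else dict(genome)
    shortest = min(len(s) for s in seqs.values())
    if read_len > shortest:
        raise ValueError(
            f"read_len ({read_len}) exceeds the shortest chromosome ({shortest} bp)"
        )
    rng = np.random.default_rng(seed)
    total = sum(len(s) for s in seqs.values())
    n_reads = round(coverage * total / read_len)

    # largest-remainder apportionment across chromosomes
    names = list(seqs)
    quotas = {name: n_reads * len(seqs[name]) / total for name in names}
    alloc = {name: int(q) for name, q in quotas.items()}
    leftover = n_reads - sum(alloc.values())
    for name in sorted(names, key=lambda n: quotas[n] - alloc[n], reverse=True)[:leftover]:
        alloc[name] += 1

    reads: dict[str, str] = {}
    i = 0
    for name in names:
        seq = seqs[name]
        # fragment starts are drawn with one read length of overhang beyond
        # both chromosome ends and clamped to the boundary, so terminal
        # k-mer windows receive full coverage instead of tapering off
        starts = rng.integers(-(read_len - 1), len(seq), alloc[name])
        starts = np.clip(starts, 0, len(seq) - read_len)
        strands = rng.integers(0, 2, alloc[name])
        for start, flip in zip(starts, strands):
            fragment = seq[start : start + read_len]
            strand = "-" if flip else "+"
            if flip:
                fragment = revcomp(fragment)
            if error_rate > 0:
                fragment = mutate(fragment, error_rate, rng)
            reads[f"r{i}|{name}|{int(start)}|{strand}"] = fragment
            i += 1
    return reads


def write_reads(reads: Mapping[str, str], path: str | Path) -> None:
    write_fasta(reads, path)
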