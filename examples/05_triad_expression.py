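"""Homoeolog triad stress-response classification and translocation calls.

Each homoeolog's stress/control fold change is called UP (> 2x), DOWN
(< 0.5x) or FLAT; the triad pattern summarises the three calls. Outlier
triads — one member anchored outside its homoeologous group — aggregate
into translocation candidates when at least three share a source bin.
"""

from polyqc.simulate import (
    GenomeConfig,
    Translocation,
    generate_expression,
    generate_genome,
    generate_map,
    member_bins_frame,
)
from polyqc.triads import (
    classify_stress,
    detect_translocations,
    pattern_table,
    tpm_normalize,
)

genome, truth = generate_genome(GenomeConfig(n_triads=56, seed=7, spacer_length=200))

data = generate_expression(
    truth.triad_membership, conditions=("D.6h", "H.6h"), dispersion=0.1, seed=8, truth=truth
)
tpm = tpm_normalize(data.counts, data.lengths)
calls = classify_stress(tpm, data.triads, data.meta)
print(pattern_table(calls).to_string(index=False))
# ~80% of triads are not differentially expressed; among DE triads the
# dominant pattern is a single homoeolog UP or DOWN

result = generate_map(
    genome, truth, bins_per_chromosome=2, translocations=[Translocation(4, "B", "7A", 5)]
)
candidates = detect_translocations(member_bins_frame(truth, result), min_support=3)
for c in candidates:
    print(
        f"translocation: bin {c.source_bin} holds {c.n_support} triads whose members "
        f"belong homoeologously on {c.target_chromosome}"
    )
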