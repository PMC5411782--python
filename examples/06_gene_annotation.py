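"""Gene confidence tiers, splicing-event typing and NMD flags.

HC requires >= 60% homolog coverage, wheat transcript support and no repeat
association; P1 marks >= 80% coverage, T1/T2 full-length PacBio / RNA-seq
support. Splicing events are typed against the representative isoform; a
transcript whose stop codon sits > 50 nt upstream of the last exon-exon
junction is a candidate NMD target.
"""

from collections import Counter

from polyqc.genes import Evidence, assign_confidence, classify_as_events, flag_nmd
from polyqc.models import Transcript
from polyqc.simulate import GenomeConfig, generate_genome, generate_transcripts

for cov, pacbio, rnaseq in [(0.85, True, False), (0.70, False, True), (0.55, False, False)]:
    ev = Evidence(cov, pacbio_full=pacbio, rnaseq_full=rnaseq,
                  has_wheat_transcript_support=pacbio or rnaseq)
    conf = assign_confidence(ev)
    print(f"coverage={cov:.2f} pacbio={pacbio} rnaseq={rnaseq} -> "
          f"{conf.tier} P={conf.protein_rank} T={conf.transcript_rank} {conf.lc_reasons}")

genome, truth = generate_genome(GenomeConfig(n_triads=34, seed=9, spacer_length=200))
mix = {"IR": 0.34, "A3SS": 0.27, "ES": 0.20, "A5SS": 0.19}
transcripts = generate_transcripts(genome.gene_models(), mix, seed=10, truth=truth)
events = Counter(e for pair in transcripts.values() for _, _, e in classify_as_events(pair))
total = sum(events.values())
print({e: f"{100 * n / total:.0f}%" for e, n in events.most_common()})
# intron retention dominates the planted mix, as in real wheat transcriptomes

nmd = Transcript(id="t1", gene_id="g1", chrom="1A", strand="+",
                 exons=((1, 300), (401, 700)), cds=((1, 200),))
print(f"stop 100 nt before the last junction -> NMD candidate: {flag_nmd(nmd)}")
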