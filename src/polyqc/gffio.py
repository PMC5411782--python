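"""GFF3 and FASTA I/O.

Reading GFF3 goes through :mod:`gffutils` (in-memory database); writing is
plain GFF3 line formatting. FASTA/FASTQ reading and writing go through
Biopython's SeqIO.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, Transcript


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_reads(path: str | Path) -> dict[str, str]:
    """Read sequencing reads from FASTA or FASTQ, sniffed from the first byte."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), fmt)}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _cds_phases(transcript: Transcript) -> dict[tuple[int, int], int]:
    """GFF3 phase per CDS segment: bases to skip to reach the next codon start."""
    segments = transcript.cds if transcript.strand == "+" else tuple(reversed(transcript.cds))
    phases = {}
    consumed = 0
    for seg in segments:
        phases[seg] = (3 - consumed % 3) % 3
        consumed += seg[1] - seg[0] + 1
    return phases


def format_gff3(genes: Iterable[GeneModel], source: str = "polyqc") -> str:
    """Render gene models as a GFF3 string (gene/mRNA/exon/CDS features)."""
    out = io.StringIO()
    out.write("##gff-version 3\n")
    for gene in sorted(genes, key=lambda g: (g.chrom, g.start, g.id)):
        out.write(
            f"{gene.chrom}\t{source}\tgene\t{gene.start}\t{gene.end}\t.\t{gene.strand}\t.\t"
            f"ID={gene.id}\n"
        )
        for tid in sorted(gene.transcripts):
            t = gene.transcripts[tid]
            rep = ";representative=true" if t.is_representative else ""
            out.write(
                f"{t.chrom}\t{source}\tmRNA\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t"
                f"ID={t.id};Parent={gene.id}{rep}\n"
            )
            for i, (s, e) in enumerate(t.exons, 1):
                out.write(
                    f"{t.chrom}\t{source}\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                    f"ID={t.id}.exon{i};Parent={t.id}\n"
                )
            phases = _cds_phases(t)
            for i, (s, e) in enumerate(t.cds, 1):
                out.write(
                    f"{t.chrom}\t{source}\tCDS\t{s}\t{e}\t.\t{t.strand}\t{phases[(s, e)]}\t"
                    f"ID={t.id}.cds{i};Parent={t.id}\n"
                )
    return out.getvalue()


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "polyqc") -> None:
    Path(path).write_text(format_gff3(genes, source=source))


def read_gff3(path: str | Path) -> dict[str, GeneModel]:
    """Load gene models (gene/mRNA/exon/CDS) from a GFF3 file."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        genes[g.id] = GeneModel(id=g.id, chrom=g.seqid, strand=g.strand)
    for m in db.features_of_type("mRNA"):
        parents = list(db.parents(m, featuretype="gene"))
        gene_id = parents[0].id if parents else m.attributes.get("Parent", [m.id])[0]
        gene = genes.setdefault(gene_id, GeneModel(id=gene_id, chrom=m.seqid, strand=m.strand))
        exons = tuple(
            (f.start, f.end) for f in db.children(m, featuretype="exon", order_by="start")
        )
        cds = tuple((f.start, f.end) for f in db.children(m, featuretype="CDS", order_by="start"))
        rep = m.attributes.get("representative", ["false"])[0].lower() == "true"
        gene.add(
            Transcript(
                id=m.id,
                gene_id=gene_id,
                chrom=m.seqid,
                strand=m.strand,
                exons=exons,
                cds=cds,
                is_representative=rep,
            )
        )
    return genes
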