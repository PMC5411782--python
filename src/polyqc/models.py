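"""Shared gene-model containers.

Coordinates follow GFF3 conventions: 1-based, inclusive on both ends.
A :class:`Transcript` owns its exon chain (sorted, non-overlapping) and an
optional CDS chain; a :class:`GeneModel` groups transcripts and designates a
representative isoform used as the reference when classifying alternative
splicing events.
"""

from __future__ import annotations

from dataclasses import dataclass, field


Interval = tuple[int, int]


def _check_chain(chain: tuple[Interval, ...], what: str) -> None:
    prev_end = 0
    for start, end in chain:
        if start < 1 or end < start:
            raise ValueError(f"malformed {what} interval ({start}, {end})")
        if start <= prev_end:
            raise ValueError(f"{what} intervals overlap or are unsorted at ({start}, {end})")
        prev_end = end


@dataclass(frozen=True)
class Transcript:
    """One isoform: an exon chain plus optional CDS on a chromosome strand."""

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] = ()
    is_representative: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"transcript {self.id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"transcript {self.id}: at least one exon required")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        cds = tuple(sorted(tuple(c) for c in self.cds))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds", cds)
        _check_chain(exons, f"exon ({self.id})")
        _check_chain(cds, f"CDS ({self.id})")
        for cs, ce in cds:
            if not any(es <= cs and ce <= ee for es, ee in exons):
                raise ValueError(f"transcript {self.id}: CDS ({cs}, {ce}) not contained in an exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Intron intervals (1-based inclusive), in genomic order."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1) for i in range(len(self.exons) - 1)
        )

    @property
    def mrna_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def exons_in_mrna_order(self) -> tuple[Interval, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def to_mrna(self, genomic_pos: int) -> int:
        """Map a genomic position inside an exon to its 1-based mRNA coordinate."""
        offset = 0
        for s, e in self.exons_in_mrna_order():
            if s <= genomic_pos <= e:
                if self.strand == "+":
                    return offset + (genomic_pos - s + 1)
                return offset + (e - genomic_pos + 1)
            offset += e - s + 1
        raise ValueError(f"position {genomic_pos} is not exonic in transcript {self.id}")

    def junction_mrna_positions(self) -> tuple[int, ...]:
        """mRNA coordinates of the last base of each exon except the final one."""
        positions = []
        offset = 0
        for s, e in self.exons_in_mrna_order()[:-1]:
            offset += e - s + 1
            positions.append(offset)
        return tuple(positions)

    def stop_codon_mrna_position(self) -> int | None:
        """mRNA coordinate of the last CDS base (the 3' end of the stop codon)."""
        if not self.cds:
            return None
        if self.strand == "+":
            return self.to_mrna(self.cds[-1][1])
        return self.to_mrna(self.cds[0][0])


@dataclass
class GeneModel:
    """A locus with one or more transcripts."""

    id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def add(self, transcript: Transcript) -> None:
        if transcript.gene_id != self.id:
            raise ValueError(f"transcript {transcript.id} belongs to {transcript.gene_id}, not {self.id}")
        self.transcripts[transcript.id] = transcript

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts.values())

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts.values())

    @property
    def representative(self) -> Transcript:
        for t in self.transcripts.values():
            if t.is_representative:
                return t
        # fall back to the longest isoform, ties broken by id for determinism
        return max(self.transcripts.values(), key=lambda t: (t.mrna_length, t.id))

    def overlaps(self, other: "GeneModel", same_strand: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start <= other.end and other.start <= self.end
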