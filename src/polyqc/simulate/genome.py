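"""Synthetic allohexaploid genome with known homoeolog triads.

Every gene is born as an ancestral multi-exon model and copied once per
subgenome, with substitutions sampled per base at the configured divergence
rate — so the three homoeologs of a triad differ only by those sampled
substitutions, and are byte-identical at divergence 0. Intergenic spacers
receive insertions from a per-seed library of random repeat elements, each
flanked by identical target-site duplications (TSDs), which gives the
genome a repeat-borne k-mer multiplicity structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..gffio import write_fasta, write_gff3
from ..models import GeneModel, Transcript
from .config import ConfigurationError, GenomeConfig, TruthTables

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``.

    A substituted base always changes (one of the three other bases), so the
    number of differences from ``seq`` is Binomial(len(seq), rate).
    """
    if rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    code = np.zeros(len(arr), dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[arr == b] = i
    hit = rng.random(len(arr)) < rate
    shift = rng.integers(1, 4, int(hit.sum())).astype(np.uint8)
    code[hit] = (code[hit] + shift) % 4
    return _BASES[code].tobytes().decode("ascii")


@dataclass
class SynGene:
    """One homoeolog: genomic-forward gene sequence plus its exon layout."""

    id: str
    triad_id: str
    subgenome: str
    group: int
    strand: str
    seq: str
    exon_offsets: tuple[tuple[int, int], ...]  # 0-based half-open, relative to seq


@dataclass
class Cassette:
    """Leading intergenic spacer followed by one gene."""

    spacer: str
    gene: SynGene

    @property
    def length(self) -> int:
        return len(self.spacer) + len(self.gene.seq)


@dataclass
class Chromosome:
    name: str
    cassettes: list[Cassette] = field(default_factory=list)
    tail: str = ""

    @property
    def sequence(self) -> str:
        return "".join(c.spacer + c.gene.seq for c in self.cassettes) + self.tail

    @property
    def length(self) -> int:
        return sum(c.length for c in self.cassettes) + len(self.tail)


@dataclass
class SyntheticGenome:
    config: GenomeConfig
    chromosomes: dict[str, Chromosome]
    repeat_library: list[str]

    def sequences(self) -> dict[str, str]:
        return {name: chrom.sequence for name, chrom in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes.values())

    def gene_models(self) -> dict[str, GeneModel]:
        """Gene models with absolute 1-based coordinates, CDS over all exons."""
        genes: dict[str, GeneModel] = {}
        for chrom in self.chromosomes.values():
            offset = 0
            for cassette in chrom.cassettes:
                offset += len(cassette.spacer)
                g = cassette.gene
                exons = tuple((offset + s + 1, offset + e) for s, e in g.exon_offsets)
                model = GeneModel(id=g.id, chrom=chrom.name, strand=g.strand)
                model.add(
                    Transcript(
                        id=f"{g.id}.1",
                        gene_id=g.id,
                        chrom=chrom.name,
                        strand=g.strand,
                        exons=exons,
                        cds=exons,
                        is_representative=True,
                    )
                )
                genes[g.id] = model
                offset += len(g.seq)
        return genes

    def gene_lengths(self) -> dict[str, int]:
        """Spliced (exonic) length of each gene's representative transcript."""
        return {
            gid: model.representative.mrna_length for gid, model in self.gene_models().items()
        }

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(self.sequences(), path)

    def write_gff3(self, path: str | Path) -> None:
        write_gff3(self.gene_models().values(), path)


def _make_ancestral_gene(rng: np.random.Generator, cfg: GenomeConfig) -> tuple[str, tuple[tuple[int, int], ...]]:
    parts: list[str] = []
    offsets = []
    pos = 0
    for i in range(cfg.exons_per_gene):
        exon = random_dna(rng, cfg.exon_length)
        if i == 0:
            exon = "ATG" + exon[3:]
        if i == cfg.exons_per_gene - 1:
            exon = exon[:-3] + "TGA"
        parts.append(exon)
        offsets.append((pos, pos + len(exon)))
        pos += len(exon)
        if i < cfg.exons_per_gene - 1:
            intron = "GT" + random_dna(rng, cfg.intron_length - 4) + "AG"
            parts.append(intron)
            pos += len(intron)
    return "".join(parts), tuple(offsets)


def generate_genome(config: GenomeConfig) -> tuple[SyntheticGenome, TruthTables]:
    """Build the genome and its truth tables; deterministic for a fixed seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    truth = TruthTables()

    library = [
        random_dna(rng, int(rng.integers(cfg.repeat_element_range[0], cfg.repeat_element_range[1] + 1)))
        for _ in range(cfg.n_repeat_elements)
    ]

    chrom_names = [
        f"{group}{sub}"
        for group in range(1, cfg.chromosomes_per_subgenome + 1)
        for sub in cfg.subgenomes
    ]
    chromosomes = {name: Chromosome(name=name) for name in chrom_names}

    n_digits = max(4, len(str(cfg.n_triads)))
    for t in range(cfg.n_triads):
        group = t % cfg.chromosomes_per_subgenome + 1
        triad_id = f"triad{t:0{n_digits}d}"
        strand = "+" if t % 2 == 0 else "-"
        ancestral, offsets = _make_ancestral_gene(rng, cfg)
        members = {}
        for sub in cfg.subgenomes:
            gene_id = f"gene{t:0{n_digits}d}{sub}"
            seq = mutate(ancestral, cfg.homoeolog_divergence, rng)
            gene = SynGene(
                id=gene_id,
                triad_id=triad_id,
                subgenome=sub,
                group=group,
                strand=strand,
                seq=seq,
                exon_offsets=offsets,
            )
            spacer = random_dna(rng, cfg.spacer_length)
            chromosomes[f"{group}{sub}"].cassettes.append(Cassette(spacer=spacer, gene=gene))
            members[sub] = gene_id
        truth.triad_membership[triad_id] = members

    for chrom in chromosomes.values():
        chrom.tail = random_dna(rng, cfg.spacer_length)

    genome = SyntheticGenome(config=cfg, chromosomes=chromosomes, repeat_library=library)
    _insert_repeats(genome, rng)
    return genome, truth


def _insert_repeats(genome: SyntheticGenome, rng: np.random.Generator) -> None:
    """Insert library elements (with TSDs) until the repeat fraction is met."""
    cfg = genome.config
    if cfg.repeat_fraction == 0.0:
        return
    plain = genome.total_length
    target_repeat = cfg.repeat_fraction / (1.0 - cfg.repeat_fraction) * plain
    slots = [
        (name, i)
        for name, chrom in genome.chromosomes.items()
        for i in range(len(chrom.cassettes))
    ]
    if not slots:
        raise ConfigurationError("cannot place repeats in a genome with no cassettes")
    inserted = 0
    while inserted < target_repeat:
        name, i = slots[rng.integers(0, len(slots))]
        element = genome.repeat_library[rng.integers(0, len(genome.repeat_library))]
        tsd = random_dna(rng, cfg.tsd_length)
        block = tsd + element + tsd
        cassette = genome.chromosomes[name].cassettes[i]
        pos = int(rng.integers(0, len(cassette.spacer) + 1))
        cassette.spacer = cassette.spacer[:pos] + block + cassette.spacer[pos:]
        inserted += len(block)
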