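"""Binned genetic map with unique markers and planted translocations.

Markers are unique substrings sampled from gene bodies, so each marker
matches exactly one place in the genome. Chromosomes are partitioned into
consecutive cM bins of cassettes; scaffolds are emitted per bin, which makes
every marker-bearing scaffold uniquely anchorable (class 1) in the
noise-free setting.

A planted translocation mimics a rearrangement segregating in the mapping
population: a block of triad members at the end of one chromosome keeps its
physical position (its markers still *match* there) but its markers are
*recorded* in a novel genetic bin on another chromosome. Anchoring then
places those members on the recorded chromosome, producing triads whose one
member sits outside its homoeologous group — the outlier triads from which
translocations are detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ..anchoring import GeneticMap, parse_chromosome
from ..gffio import write_fasta
from ..kmers import revcomp
from .config import ConfigurationError, TranslocationTruth, TruthTables
from .genome import SyntheticGenome, random_dna


@dataclass(frozen=True)
class Translocation:
    """Request to plant one translocation.

    ``n_triads`` members of ``group``/``subgenome`` (taken from the end of
    chromosome ``{group}{subgenome}``) have their markers recorded in a new
    genetic bin on ``mapped_to``.
    """

    group: int
    subgenome: str
    mapped_to: str
    n_triads: int


@dataclass
class ScaffoldPlan:
    scaffold_id: str
    physical_chromosome: str
    cassette_indices: tuple[int, ...]
    recorded_bin: tuple[str, float]
    with_tail: bool = False


@dataclass
class MapResult:
    gmap: GeneticMap
    marker_seqs: dict[str, str]
    gene_bins: dict[str, tuple[str, float]]  # gene -> recorded (chromosome, cM)
    scaffold_plan: list[ScaffoldPlan]
    bins: list[tuple[str, float]]

    def map_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"marker_id": mid, "chromosome": chrom, "cM_bin": cm}
                for mid, (chrom, cm) in self.gmap.markers.items()
            ]
        )

    def write_map_tsv(self, path: str | Path) -> None:
        self.map_frame().to_csv(path, sep="\t", index=False)

    def write_marker_fasta(self, path: str | Path) -> None:
        write_fasta(self.marker_seqs, path)


def _unique_marker(
    gene_seq: str,
    genome_blob: str,
    marker_length: int,
    rng: np.random.Generator,
    tries: int = 25,
) -> str | None:
    if len(gene_seq) < marker_length:
        return None
    for _ in range(tries):
        off = int(rng.integers(0, len(gene_seq) - marker_length + 1))
        cand = gene_seq[off : off + marker_length]
        if set(cand) - set("ACGT"):
            continue
        if genome_blob.count(cand) + genome_blob.count(revcomp(cand)) == 1:
            return cand
    return None


def generate_map(
    genome: SyntheticGenome,
    truth: TruthTables,
    bins_per_chromosome: int = 4,
    translocations: Sequence[Translocation] = (),
    marker_length: int = 51,
) -> MapResult:
    """Sample unique markers, bin every chromosome, plant translocations.

    Every bin ends with at least one marker or a :class:`ConfigurationError`
    is raised (more unique markers were requested than the genome can
    supply, e.g. at divergence 0 where homoeologs are identical).
    """
    if not 31 <= marker_length <= 100:
        raise ConfigurationError("marker_length must be in [31, 100]")
    if bins_per_chromosome < 1:
        raise ConfigurationError("bins_per_chromosome must be >= 1")
    rng = np.random.default_rng([genome.config.seed, 7])
    genome_blob = "\n".join(genome.sequences().values())

    # which cassettes are claimed by translocations, per physical chromosome
    translocated: dict[str, list[tuple[Translocation, list[int]]]] = {}
    extra_bins: dict[str, int] = {}
    for tr in translocations:
        phys = f"{tr.group}{tr.subgenome}"
        if phys not in genome.chromosomes:
            raise ConfigurationError(f"translocation source chromosome {phys} does not exist")
        if tr.mapped_to not in genome.chromosomes:
            raise ConfigurationError(f"translocation target chromosome {tr.mapped_to} does not exist")
        if parse_chromosome(tr.mapped_to)[0] == tr.group:
            raise ConfigurationError("translocation must map to a non-homoeologous chromosome")
        claimed = sum(len(ixs) for _, ixs in translocated.get(phys, []))
        n_cassettes = len(genome.chromosomes[phys].cassettes)
        if claimed + tr.n_triads >= n_cassettes:
            raise ConfigurationError(
                f"translocation of {tr.n_triads} triads exceeds cassettes on {phys}"
            )
        start = n_cassettes - claimed - tr.n_triads
        translocated.setdefault(phys, []).append((tr, list(range(start, start + tr.n_triads))))

    markers: dict[str, tuple[str, float]] = {}
    marker_seqs: dict[str, str] = {}
    gene_bins: dict[str, tuple[str, float]] = {}
    plan: list[ScaffoldPlan] = []
    bins: list[tuple[str, float]] = []

    def _add_marker(gene, recorded: tuple[str, float]) -> bool:
        cand = _unique_marker(gene.seq, genome_blob, marker_length, rng)
        if cand is None:
            return False
        mid = f"mk_{gene.id}"
        markers[mid] = recorded
        marker_seqs[mid] = cand
        gene_bins[gene.id] = recorded
        return True

    for name, chrom in genome.chromosomes.items():
        claimed_ixs = {i for _, ixs in translocated.get(name, []) for i in ixs}
        normal = [i for i in range(len(chrom.cassettes)) if i not in claimed_ixs]
        if len(normal) < bins_per_chromosome:
            raise ConfigurationError(
                f"chromosome {name}: {len(normal)} genes cannot fill "
                f"{bins_per_chromosome} bins"
            )
        per_bin: dict[int, list[int]] = {}
        for rank, i in enumerate(normal):
            b = rank * bins_per_chromosome // len(normal)
            per_bin.setdefault(b, []).append(i)
        for b in range(bins_per_chromosome):
            recorded = (name, 10.0 * b)
            bins.append(recorded)
            got = 0
            for i in per_bin.get(b, []):
                if _add_marker(chrom.cassettes[i].gene, recorded):
                    got += 1
            if got == 0:
                raise ConfigurationError(
                    f"bin {recorded} received no unique marker; "
                    "the genome cannot supply the requested markers"
                )
            plan.append(
                ScaffoldPlan(
                    scaffold_id=f"scf_{name}_b{b}",
                    physical_chromosome=name,
                    cassette_indices=tuple(per_bin.get(b, [])),
                    recorded_bin=recorded,
                    with_tail=(b == bins_per_chromosome - 1 and name not in translocated),
                )
            )
        for j, (tr, ixs) in enumerate(translocated.get(name, [])):
            cm = 10.0 * (bins_per_chromosome + extra_bins.get(tr.mapped_to, 0))
            extra_bins[tr.mapped_to] = extra_bins.get(tr.mapped_to, 0) + 1
            recorded = (tr.mapped_to, cm)
            bins.append(recorded)
            triad_ids = []
            got = 0
            for i in ixs:
                gene = chrom.cassettes[i].gene
                if _add_marker(gene, recorded):
                    got += 1
                triad_ids.append(gene.triad_id)
            if got == 0:
                raise ConfigurationError(f"translocated bin {recorded} received no unique marker")
            plan.append(
                ScaffoldPlan(
                    scaffold_id=f"scf_{name}_t{j}",
                    physical_chromosome=name,
                    cassette_indices=tuple(ixs),
                    recorded_bin=recorded,
                    with_tail=(j == len(translocated[name]) - 1),
                )
            )
            truth.translocations.append(
                TranslocationTruth(
                    source_bin=recorded,
                    target_chromosome=name,
                    triad_ids=tuple(triad_ids),
                )
            )

    gmap = GeneticMap(markers=markers)
    return MapResult(
        gmap=gmap, marker_seqs=marker_seqs, gene_bins=gene_bins, scaffold_plan=plan, bins=bins
    )


def emit_scaffolds(
    genome: SyntheticGenome, result: MapResult
) -> tuple[dict[str, str], pd.DataFrame]:
    """Cut chromosomes into per-bin scaffolds.

    Returns the scaffold sequences and a truth table with each scaffold's
    physical chromosome and recorded bin.
    """
    scaffolds: dict[str, str] = {}
    rows = []
    for sp in result.scaffold_plan:
        chrom = genome.chromosomes[sp.physical_chromosome]
        seq = "".join(
            chrom.cassettes[i].spacer + chrom.cassettes[i].gene.seq for i in sp.cassette_indices
        )
        if sp.with_tail:
            seq += chrom.tail
        scaffolds[sp.scaffold_id] = seq
        rows.append(
            {
                "scaffold_id": sp.scaffold_id,
                "physical_chromosome": sp.physical_chromosome,
                "chromosome": sp.recorded_bin[0],
                "cM": sp.recorded_bin[1],
                "n_genes": len(sp.cassette_indices),
            }
        )
    return scaffolds, pd.DataFrame(rows)


def member_bins_frame(truth: TruthTables, result: MapResult) -> pd.DataFrame:
    """Per-triad-member recorded bins, the input to translocation detection."""
    rows = []
    for triad_id, members in truth.triad_membership.items():
        for sub, gid in members.items():
            if gid not in result.gene_bins:
                continue
            chrom, cm = result.gene_bins[gid]
            rows.append(
                {"triad_id": triad_id, "subgenome": sub, "chromosome": chrom, "cM": cm}
            )
    return pd.DataFrame(rows)


def make_class_fixtures(
    result: MapResult,
    seed: int = 0,
    spacer: int = 200,
) -> tuple[dict[str, str], dict[str, tuple[str, str]], dict[str, str]]:
    """Construct scaffolds with known anchoring classes 1-7.

    Each fixture scaffold concatenates marker sequences (each marker used in
    at most one fixture) between random spacers. Returns the scaffolds, the
    expected ``{scaffold_id: (base_class, final_class)}`` truth, and a
    prior-arm table that triggers the class 5/6/7 tags.
    """
    rng = np.random.default_rng([seed, 13])
    by_bin: dict[tuple[str, float], list[str]] = {}
    for mid, b in result.gmap.markers.items():
        by_bin.setdefault(b, []).append(mid)
    for mids in by_bin.values():
        mids.sort()
    used: set[str] = set()

    def take(chrom: str, want_bins: int) -> list[str]:
        got: list[str] = []
        for (c, _), mids in sorted(by_bin.items()):
            if c != chrom:
                continue
            for mid in mids:
                if mid not in used:
                    used.add(mid)
                    got.append(mid)
                    break
            if len(got) == want_bins:
                return got
        raise ConfigurationError(f"not enough unused markers on {chrom} for fixtures")

    def chrom_of_group(group: int, sub: str) -> str:
        name = f"{group}{sub}"
        if not any(c == name for c, _ in by_bin):
            raise ConfigurationError(f"no bins on {name} for fixtures")
        return name

    def build(mids: list[str]) -> str:
        parts = [random_dna(rng, spacer)]
        for mid in mids:
            seq = result.marker_seqs[mid]
            if rng.integers(0, 2):
                seq = revcomp(seq)
            parts.append(seq)
            parts.append(random_dna(rng, spacer))
        return "".join(parts)

    # spread fixtures over chromosomes so no per-chromosome marker pool runs dry
    a1 = chrom_of_group(1, "A")
    b1 = chrom_of_group(1, "B")
    a2 = chrom_of_group(2, "A")
    d2 = chrom_of_group(2, "D")
    a3 = chrom_of_group(3, "A")
    b4 = chrom_of_group(4, "B")
    a5 = chrom_of_group(5, "A")
    a6 = chrom_of_group(6, "A")
    a7 = chrom_of_group(7, "A")
    scaffolds: dict[str, str] = {}
    expected: dict[str, tuple[str, str]] = {}
    prior_arms: dict[str, str] = {}

    scaffolds["fix_class1"] = build(take(a1, 1))
    expected["fix_class1"] = ("1", "1")
    prior_arms["fix_class1"] = a1 + "S"

    scaffolds["fix_class2"] = build(take(b1, 2))
    expected["fix_class2"] = ("2", "2")
    prior_arms["fix_class2"] = b1 + "L"

    scaffolds["fix_class3"] = build(take(a2, 1) + take(d2, 1))
    expected["fix_class3"] = ("3", "3")

    scaffolds["fix_class4"] = build(take(a3, 1) + take(b4, 1))
    expected["fix_class4"] = ("4", "4")

    scaffolds["fix_class5"] = build(take(a5, 1))
    expected["fix_class5"] = ("1", "5")  # no prior arm entry on purpose

    scaffolds["fix_class6"] = build(take(a6, 1))
    expected["fix_class6"] = ("1", "6")
    prior_arms["fix_class6"] = b4 + "L"

    scaffolds["fix_class7"] = build(take(a7, 2))
    expected["fix_class7"] = ("2", "7")
    prior_arms["fix_class7"] = b4 + "S"

    return scaffolds, expected, prior_arms
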