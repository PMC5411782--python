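"""Configuration and ground-truth containers for the synthetic genome."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


class ConfigurationError(ValueError):
    """Raised when a generator configuration field is invalid."""


@dataclass(frozen=True)
class GenomeConfig:
    """Parameters of the miniature allohexaploid genome.

    The defaults produce roughly 2 Mb of sequence across 21 chromosomes
    (3 subgenomes x 7 homoeologous groups): enough to carry non-trivial
    k-mer multiplicity structure from repeats and homoeologous similarity
    while every stage still runs at desk scale.
    """

    n_triads: int = 210
    subgenomes: tuple[str, ...] = ("A", "B", "D")
    chromosomes_per_subgenome: int = 7
    homoeolog_divergence: float = 0.03  # substitutions per bp vs the ancestral copy
    repeat_fraction: float = 0.15
    tsd_length: int = 5
    seed: int = 0
    exons_per_gene: int = 4
    exon_length: int = 198  # multiple of 3 so the CDS stays in frame
    intron_length: int = 120
    spacer_length: int = 600
    repeat_element_range: tuple[int, int] = (1000, 5000)
    n_repeat_elements: int = 5

    def __post_init__(self) -> None:
        checks = [
            ("n_triads", self.n_triads >= 1),
            ("subgenomes", len(self.subgenomes) >= 1 and len(set(self.subgenomes)) == len(self.subgenomes)),
            ("chromosomes_per_subgenome", 1 <= self.chromosomes_per_subgenome <= 9),
            ("homoeolog_divergence", 0.0 <= self.homoeolog_divergence <= 0.3),
            ("repeat_fraction", 0.0 <= self.repeat_fraction < 0.9),
            ("tsd_length", self.tsd_length >= 0),
            ("exons_per_gene", self.exons_per_gene >= 2),
            ("exon_length", self.exon_length >= 30 and self.exon_length % 3 == 0),
            ("intron_length", self.intron_length >= 10),
            ("spacer_length", self.spacer_length >= 50),
            ("repeat_element_range", 100 <= self.repeat_element_range[0] <= self.repeat_element_range[1]),
            ("n_repeat_elements", self.n_repeat_elements >= 1),
            ("seed", isinstance(self.seed, int) and self.seed >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigurationError(f"invalid GenomeConfig field: {name}={getattr(self, name)!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "GenomeConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown GenomeConfig fields: {sorted(unknown)}")
        for key in ("subgenomes", "repeat_element_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True)
class TranslocationTruth:
    """A planted rearrangement: content recorded in ``source_bin`` on the map
    belongs homoeologously on ``target_chromosome``."""

    source_bin: tuple[str, float]
    target_chromosome: str
    triad_ids: tuple[str, ...]


@dataclass
class TruthTables:
    """Ground truth for every planted feature, filled in by each generator."""

    triad_membership: dict[str, dict[str, str]] = field(default_factory=dict)  # triad -> {subgenome: gene}
    translocations: list[TranslocationTruth] = field(default_factory=list)
    expression_labels: dict[tuple[str, str], str] = field(default_factory=dict)  # (triad, condition) -> pattern
    balance_labels: dict[str, bool] = field(default_factory=dict)  # triad -> unbalanced?
    as_event_labels: dict[str, str] = field(default_factory=dict)  # transcript -> event type
    redundant_scaffold_ids: list[str] = field(default_factory=list)

    def gene_to_triad(self) -> dict[str, str]:
        return {
            gid: tid for tid, members in self.triad_membership.items() for gid in members.values()
        }
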