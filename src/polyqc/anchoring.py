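"""Genetic-map scaffold anchoring and the seven-class assignment scheme.

Scaffolds are assigned to genetic bins by exact marker matches and
classified:

* class 1 — all usable marker hits fall in a single bin of a single
  chromosome (uniquely anchored);
* class 2 — hits in several cM bins of the same chromosome (ambiguous
  position);
* class 3 — hits split across chromosomes of one homoeologous group;
* class 4 — hits across non-homoeologous chromosomes (conflicting);
* class 5 — class-1 scaffolds with no prior chromosome-arm assignment
  (the map supplies a novel location);
* classes 6/7 — class-1/class-2 scaffolds whose prior arm assignment
  names a different chromosome than the map.

Classes 5–7 are override tags on top of base classes 1–2; reports carry
both the base class and the final (tagged) class so counts can be
aggregated either way.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .kmers import revcomp
from .models import GeneModel

logger = logging.getLogger(__name__)

UNANCHORED = "unanchored"

_CHROM_RE = re.compile(r"^([1-9][0-9]*)([A-Z])$")


def parse_chromosome(name: str) -> tuple[int, str]:
    """Split a chromosome name like ``3B`` into homoeologous group and subgenome."""
    m = _CHROM_RE.match(name)
    if not m:
        raise ValueError(f"unknown chromosome name {name!r}; expected e.g. '3B'")
    return int(m.group(1)), m.group(2)


def arm_chromosome(arm: str) -> str:
    """Chromosome of an arm label: ``5AL`` -> ``5A``; bare names pass through."""
    if arm and arm[-1] in "LS" and _CHROM_RE.match(arm[:-1]):
        return arm[:-1]
    parse_chromosome(arm)
    return arm


@dataclass(frozen=True)
class MarkerHit:
    marker_id: str
    scaffold_id: str
    position: int  # 0-based offset of the match
    strand: str


@dataclass
class GeneticMap:
    """Markers with their chromosome and cM-bin assignments."""

    markers: dict[str, tuple[str, float]]  # marker_id -> (chromosome, cM)

    def __post_init__(self) -> None:
        for mid, (chrom, _) in self.markers.items():
            parse_chromosome(chrom)  # raises on malformed names at load time

    @property
    def bins(self) -> set[tuple[str, float]]:
        return set(self.markers.values())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
        required = {"marker_id", "chromosome", "cM_bin"}
        if not required <= set(df.columns):
            raise ValueError(f"map TSV must have columns {sorted(required)}")
        return cls(
            markers={
                r.marker_id: (r.chromosome, float(r.cM_bin)) for r in df.itertuples()
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {"marker_id": mid, "chromosome": chrom, "cM_bin": cm}
                for mid, (chrom, cm) in self.markers.items()
            ]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class ScaffoldAnchor:
    scaffold_id: str
    marker_hits: list[MarkerHit] = field(default_factory=list)
    prior_arm: str | None = None
    base_class: str = UNANCHORED
    map_class: str = UNANCHORED
    assigned_bin: tuple[str, float] | None = None

    @property
    def n_markers(self) -> int:
        return len(self.marker_hits)


def match_markers(
    markers: Mapping[str, str],
    scaffolds: Mapping[str, str],
    max_hits: int = 2,
) -> tuple[list[MarkerHit], set[str]]:
    """Exact, full-length, strand-aware marker matching.

    Returns all hits plus the ids of multi-locus markers (hitting more than
    ``max_hits`` distinct scaffolds), which callers must exclude from
    classification.
    """
    hits: list[MarkerHit] = []
    per_marker_scaffolds: dict[str, set[str]] = {mid: set() for mid in markers}
    for mid, mseq in markers.items():
        if len(mseq) < 31:
            raise ValueError(f"marker {mid} shorter than 31 bp")
        rc = revcomp(mseq)
        for sid, sseq in scaffolds.items():
            for query, strand in ((mseq, "+"), (rc, "-")):
                start = sseq.find(query)
                while start != -1:
                    hits.append(MarkerHit(mid, sid, start, strand))
                    per_marker_scaffolds[mid].add(sid)
                    start = sseq.find(query, start + 1)
    excluded = {mid for mid, sids in per_marker_scaffolds.items() if len(sids) > max_hits}
    for mid in sorted(excluded):
        logger.info(
            "marker %s hits %d scaffolds (max %d): excluded as multi-locus",
            mid,
            len(per_marker_scaffolds[mid]),
            max_hits,
        )
    return hits, excluded


def classify_scaffold(
    anchor: ScaffoldAnchor, gmap: GeneticMap, apply_prior_tags: bool = True
) -> ScaffoldAnchor:
    """Assign base class 1-4 from marker bins, then apply the 5/6/7 tags.

    ``apply_prior_tags=False`` disables the 5/6/7 overrides, for runs where
    no prior chromosome-arm classification exists at all (every scaffold
    would otherwise be tagged class 5).
    """
    bins = []
    for hit in anchor.marker_hits:
        if hit.marker_id not in gmap.markers:
            raise ValueError(f"marker {hit.marker_id} missing from genetic map")
        bins.append(gmap.markers[hit.marker_id])
    if not bins:
        anchor.base_class = anchor.map_class = UNANCHORED
        anchor.assigned_bin = None
        return anchor
    distinct_bins = set(bins)
    chroms = {chrom for chrom, _ in distinct_bins}
    groups = {parse_chromosome(chrom)[0] for chrom in chroms}
    if len(distinct_bins) == 1:
        anchor.base_class = "1"
        anchor.assigned_bin = next(iter(distinct_bins))
    elif len(chroms) == 1:
        anchor.base_class = "2"
        anchor.assigned_bin = None
    elif len(groups) == 1:
        anchor.base_class = "3"
        anchor.assigned_bin = None
    else:
        anchor.base_class = "4"
        anchor.assigned_bin = None
    anchor.map_class = anchor.base_class
    if not apply_prior_tags:
        return anchor
    if anchor.base_class == "1":
        map_chrom = anchor.assigned_bin[0]
        if anchor.prior_arm is None:
            anchor.map_class = "5"
        elif arm_chromosome(anchor.prior_arm) != map_chrom:
            anchor.map_class = "6"
    elif anchor.base_class == "2":
        map_chrom = next(iter(chroms))
        if anchor.prior_arm is not None and arm_chromosome(anchor.prior_arm) != map_chrom:
            anchor.map_class = "7"
    return anchor


CLASS_ORDER = ["1", "2", "3", "4", "5", "6", "7", UNANCHORED]


def class_percentages(counts: Mapping[str, int], total: int) -> dict[str, float]:
    """Percentage of each class over a common denominator."""
    if total <= 0:
        raise ValueError("total must be positive")
    return {cls: 100.0 * n / total for cls, n in counts.items()}


def percentage(part: int, whole: int) -> float:
    if whole <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * part / whole


def paper_style_percentages(final_counts: Mapping[str, int], total: int) -> dict[str, float]:
    """Class percentages with the denominators used in anchoring reports.

    Classes 1-4 and unanchored are fractions of all scaffolds; the 5/6 tags
    are fractions of uniquely anchored (base class 1) scaffolds; the 7 tag is
    a fraction of base class 2. Base class 1 = final 1 + 5 + 6 tags, base
    class 2 = final 2 + 7.
    """
    base1 = final_counts.get("1", 0) + final_counts.get("5", 0) + final_counts.get("6", 0)
    base2 = final_counts.get("2", 0) + final_counts.get("7", 0)
    out: dict[str, float] = {}
    for cls in CLASS_ORDER:
        n = final_counts.get(cls, 0)
        if cls in {"5", "6"}:
            out[cls] = percentage(n, base1) if base1 else 0.0
        elif cls == "7":
            out[cls] = percentage(n, base2) if base2 else 0.0
        else:
            out[cls] = percentage(n, total)
    return out


def anchor_assembly(
    scaffolds: Mapping[str, str],
    markers: Mapping[str, str],
    gmap: GeneticMap,
    genes: Mapping[str, GeneModel] | None = None,
    prior_arms: Mapping[str, str] | None = None,
    hc_gene_ids: Iterable[str] | None = None,
    max_hits: int = 2,
) -> tuple[list[ScaffoldAnchor], dict]:
    """Anchor every scaffold and summarise the assignment.

    ``genes`` (keyed by gene id, with ``chrom`` equal to a scaffold id) and
    ``hc_gene_ids`` enable the gene-space statistics: how many high-confidence
    genes sit on uniquely binned scaffolds, and how many HC-gene-bearing
    scaffolds the map captures.
    """
    hits, excluded = match_markers(markers, scaffolds, max_hits=max_hits)
    apply_prior_tags = prior_arms is not None
    prior_arms = prior_arms or {}
    by_scaffold: dict[str, list[MarkerHit]] = {sid: [] for sid in scaffolds}
    for hit in hits:
        if hit.marker_id not in excluded:
            by_scaffold[hit.scaffold_id].append(hit)
    anchors = []
    for sid in scaffolds:
        anchor = ScaffoldAnchor(
            scaffold_id=sid,
            marker_hits=by_scaffold[sid],
            prior_arm=prior_arms.get(sid),
        )
        anchors.append(classify_scaffold(anchor, gmap, apply_prior_tags=apply_prior_tags))

    total = len(scaffolds)
    final_counts = {cls: 0 for cls in CLASS_ORDER}
    for a in anchors:
        final_counts[a.map_class] += 1
    anchored = [a for a in anchors if a.assigned_bin is not None]
    anchored_bp = sum(len(scaffolds[a.scaffold_id]) for a in anchored)
    total_bp = sum(len(s) for s in scaffolds.values())
    summary = {
        "n_scaffolds": total,
        "class_counts": final_counts,
        "pct_of_total": class_percentages(final_counts, total),
        "pct_reference": paper_style_percentages(final_counts, total),
        "anchored_scaffolds": len(anchored),
        "anchored_bp": anchored_bp,
        "anchored_fraction": anchored_bp / total_bp if total_bp else 0.0,
    }
    if genes is not None:
        hc = set(hc_gene_ids) if hc_gene_ids is not None else set(genes)
        binned_scaffolds = {a.scaffold_id for a in anchored}
        hc_genes_binned = sum(1 for gid in hc if genes[gid].chrom in binned_scaffolds)
        bearing = {genes[gid].chrom for gid in hc}
        bearing_anchored = len(bearing & binned_scaffolds)
        summary.update(
            {
                "hc_genes": len(hc),
                "hc_genes_binned": hc_genes_binned,
                "hc_genes_binned_fraction": hc_genes_binned / len(hc) if hc else 0.0,
                "hc_scaffolds": len(bearing),
                "hc_scaffolds_anchored": bearing_anchored,
                "hc_scaffolds_anchored_fraction": bearing_anchored / len(bearing) if bearing else 0.0,
            }
        )
    return anchors, summary


def anchors_to_frame(anchors: Sequence[ScaffoldAnchor]) -> pd.DataFrame:
    rows = []
    for a in anchors:
        chrom, cm = a.assigned_bin if a.assigned_bin else ("", "")
        rows.append(
            {
                "scaffold_id": a.scaffold_id,
                "class": a.map_class,
                "base_class": a.base_class,
                "chromosome": chrom,
                "cM": cm,
                "n_markers": a.n_markers,
            }
        )
    return pd.DataFrame(rows)
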