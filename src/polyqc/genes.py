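"""Gene confidence ranking, annotation comparison, splicing events and NMD.

Confidence tiers follow the two-tier scheme used for polyploid wheat
annotation: a locus is high confidence (HC) when it has adequate protein
homology (>= 60% coverage of its best homolog), wheat transcript support,
and is not repeat associated; otherwise low confidence (LC) with the
reasons recorded. Within HC, protein rank P1 marks >= 80% homolog coverage
and transcript ranks T1/T2 mark full-length support by PacBio cDNA or by
assembled short-read RNA-seq respectively.

Alternative splicing events between an alternative isoform and the
representative isoform are typed as intron retention (IR), exon skipping
(ES), alternative 5'/3' splice sites (A5SS/A3SS, assigned in mRNA
orientation) and mutually exclusive exons (MXE). A transcript is a
candidate nonsense-mediated decay (NMD) target when its stop codon lies
more than a configurable distance (default 50 nt) upstream of the last
exon-exon junction in mRNA coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .models import GeneModel, Interval, Transcript

logger = logging.getLogger(__name__)

AS_EVENTS = ("IR", "ES", "A3SS", "A5SS", "MXE")


# ---------------------------------------------------------------------------
# confidence classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Evidence:
    """Per-gene annotation evidence."""

    best_homolog_coverage: float
    pacbio_full: bool = False
    rnaseq_full: bool = False
    repeat_associated: bool = False
    has_wheat_transcript_support: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.best_homolog_coverage <= 1.0:
            raise ValueError(
                f"best_homolog_coverage must be in [0, 1], got {self.best_homolog_coverage}"
            )


@dataclass(frozen=True)
class ConfidenceClass:
    tier: str  # "HC" or "LC"
    protein_rank: str | None  # "P1" or None
    transcript_rank: str | None  # "T1", "T2" or None
    lc_reasons: tuple[str, ...] = ()

    @property
    def lc_reason(self) -> str | None:
        return self.lc_reasons[0] if self.lc_reasons else None


def assign_confidence(
    evidence: Evidence,
    coverage_hc: float = 0.60,
    coverage_p1: float = 0.80,
    gene_id: str | None = None,
) -> ConfidenceClass:
    """Two-tier confidence call with protein and transcript ranks.

    LC when homolog coverage is below ``coverage_hc``, when the gene lacks
    any wheat transcript support, or when it is repeat associated; multiple
    applicable reasons are all reported (short-protein, no-transcript,
    repeat, in that order). HC genes get P1 at coverage >= ``coverage_p1``
    (inclusive) and T1 (PacBio full-length) or else T2 (full RNA-seq
    assembly support).
    """
    if evidence is None:
        raise ValueError(f"missing evidence for gene {gene_id or '<unknown>'}")
    support = (
        evidence.has_wheat_transcript_support or evidence.pacbio_full or evidence.rnaseq_full
    )
    reasons = []
    if evidence.best_homolog_coverage < coverage_hc:
        reasons.append("short-protein")
    if not support:
        reasons.append("no-transcript")
    if evidence.repeat_associated:
        reasons.append("repeat")
    if reasons:
        return ConfidenceClass(tier="LC", protein_rank=None, transcript_rank=None, lc_reasons=tuple(reasons))
    protein_rank = "P1" if evidence.best_homolog_coverage >= coverage_p1 else None
    transcript_rank = "T1" if evidence.pacbio_full else ("T2" if evidence.rnaseq_full else None)
    return ConfidenceClass(tier="HC", protein_rank=protein_rank, transcript_rank=transcript_rank)


def transfer_filter(
    alignments: Iterable[Mapping],
    min_coverage: float = 0.90,
    min_identity: float = 0.95,
) -> list[Mapping]:
    """Keep alignments with at least the required coverage AND identity.

    Bounds are inclusive ("at least"). Each record must carry ``coverage``
    and ``identity`` as fractions.
    """
    kept = []
    for rec in alignments:
        if rec["coverage"] >= min_coverage and rec["identity"] >= min_identity:
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# annotation overlap categories
# ---------------------------------------------------------------------------

OVERLAP_CATEGORIES = ("identical", "contained", "structurally_different", "missing")


def _intron_chain(t: Transcript) -> tuple[Interval, ...]:
    return t.introns


def _is_subchain(sub: tuple, full: tuple) -> bool:
    """True when ``sub`` appears as a contiguous run inside ``full``."""
    if not sub:
        return True
    n, m = len(sub), len(full)
    return any(full[i : i + n] == sub for i in range(m - n + 1))


def _pair_category(ref: Transcript, query: Transcript) -> str:
    """Overlap category of one reference transcript against one query transcript."""
    ref_chain = _intron_chain(ref)
    q_chain = _intron_chain(query)
    if ref_chain or q_chain:
        if ref_chain == q_chain:
            return "identical"
        if ref_chain and _is_subchain(ref_chain, q_chain) and query.start <= ref.start and ref.end <= query.end:
            return "contained"
        if not ref_chain:
            # monoexonic reference inside one query exon
            if any(s <= ref.start and ref.end <= e for s, e in query.exons):
                return "contained"
        return "structurally_different"
    # both monoexonic: same structure when they overlap
    if ref.start <= query.end and query.start <= ref.end:
        if query.start <= ref.start and ref.end <= query.end:
            return "identical" if (ref.start, ref.end) == (query.start, query.end) else "contained"
        return "structurally_different"
    return "structurally_different"


_CATEGORY_RANK = {c: i for i, c in enumerate(OVERLAP_CATEGORIES)}


def compare_annotations(
    reference: Mapping[str, GeneModel],
    query: Mapping[str, GeneModel],
) -> tuple[dict[str, str], dict, set[str]]:
    """Classify every reference gene against a query annotation.

    Overlap is strand-aware: a reference gene overlapping query genes only
    in antisense counts as missing, since antisense loci are annotated
    separately from the coding comparison. For each reference gene the best
    category over all same-strand overlapping (reference transcript, query
    transcript) pairs is reported, in the order identical > contained >
    structurally_different. Query genes overlapped by two or more reference
    genes are returned as putative fusions (reference loci joined into one
    query locus).

    Returns (per-reference-gene category, summary fractions, fused query ids).
    """
    categories: dict[str, str] = {}
    overlap_count: dict[str, set[str]] = {qid: set() for qid in query}
    for rid, rgene in reference.items():
        partners = [q for q in query.values() if rgene.overlaps(q, same_strand=True)]
        if not partners:
            categories[rid] = "missing"
            continue
        for q in partners:
            overlap_count[q.id].add(rid)
        best = "structurally_different"
        for q in partners:
            for rt in rgene.transcripts.values():
                for qt in q.transcripts.values():
                    cat = _pair_category(rt, qt)
                    if _CATEGORY_RANK[cat] < _CATEGORY_RANK[best]:
                        best = cat
        categories[rid] = best
    fused = {qid for qid, rids in overlap_count.items() if len(rids) >= 2}
    total = len(categories)
    summary = {
        "n_reference_genes": total,
        "fractions": {
            c: (sum(1 for v in categories.values() if v == c) / total if total else 0.0)
            for c in OVERLAP_CATEGORIES
        },
        "n_fused_query_genes": len(fused),
    }
    return categories, summary, fused


# ---------------------------------------------------------------------------
# alternative splicing events
# ---------------------------------------------------------------------------

def _internal_exons(t: Transcript) -> tuple[Interval, ...]:
    return t.exons[1:-1]


def _shared_boundary_label(
    left_differs: bool, strand: str
) -> str:
    """Label for a shifted intron boundary: the genomic-left boundary is the
    donor on '+' (A5SS) and the acceptor on '-' (A3SS)."""
    if left_differs:
        return "A5SS" if strand == "+" else "A3SS"
    return "A3SS" if strand == "+" else "A5SS"


def _events_for_pair(alt: Transcript, ref: Transcript) -> list[str]:
    if alt.chrom != ref.chrom or alt.strand != ref.strand:
        raise ValueError("transcripts of one gene must share chromosome and strand")
    strand = alt.strand
    events: list[str] = []

    alt_introns, ref_introns = set(alt.introns), set(ref.introns)
    alt_exons, ref_exons = alt.exons, ref.exons

    # IR: an exon of one transcript fully spans an intron of the other
    for introns, exons in ((ref_introns - alt_introns, alt_exons), (alt_introns - ref_introns, ref_exons)):
        for i_s, i_e in sorted(introns):
            if any(s < i_s and i_e < e for s, e in exons):
                events.append("IR")

    # ES: an internal exon of one transcript absent from the other, which
    # instead runs a single intron across it with shared outer boundaries
    def _skipping(with_exon: Transcript, without: Transcript) -> None:
        w_introns = set(without.introns)
        chain = with_exon.exons
        for idx in range(1, len(chain) - 1):
            s, e = chain[idx]
            left = (chain[idx - 1][1] + 1, s - 1)
            right = (e + 1, chain[idx + 1][0] - 1)
            if (left[0], right[1]) in w_introns:
                events.append("ES")

    _skipping(ref, alt)
    _skipping(alt, ref)

    # MXE: two non-overlapping internal exons, each exclusive to one
    # transcript, sharing the outer boundaries of their flanking introns
    def _flanks(t: Transcript, idx: int) -> tuple[int, int]:
        return (t.exons[idx - 1][1] + 1, t.exons[idx + 1][0] - 1)

    for i in range(1, len(ref_exons) - 1):
        re_ = ref_exons[i]
        if any(s <= re_[1] and re_[0] <= e for s, e in alt_exons):
            continue
        for j in range(1, len(alt_exons) - 1):
            ae = alt_exons[j]
            if any(s <= ae[1] and ae[0] <= e for s, e in ref_exons):
                continue
            if re_[1] < ae[0] or ae[1] < re_[0]:
                if _flanks(ref, i) == _flanks(alt, j):
                    events.append("MXE")

    # A5SS / A3SS: intron pairs sharing exactly one boundary, where the
    # differing region holds no complete exon of either transcript (that
    # situation is exon skipping or MXE, handled above)
    def _region_holds_exon(lo: int, hi: int) -> bool:
        return any(
            lo <= s and e <= hi for s, e in (*ref_exons, *alt_exons)
        )

    for a_s, a_e in sorted(alt_introns - ref_introns):
        for r_s, r_e in sorted(ref_introns - alt_introns):
            if a_s == r_s and a_e != r_e:
                lo, hi = min(a_e, r_e) + 1, max(a_e, r_e)
                if not _region_holds_exon(lo, hi):
                    events.append(_shared_boundary_label(left_differs=False, strand=strand))
            elif a_e == r_e and a_s != r_s:
                lo, hi = min(a_s, r_s), max(a_s, r_s) - 1
                if not _region_holds_exon(lo, hi):
                    events.append(_shared_boundary_label(left_differs=True, strand=strand))
    return events


def classify_as_events(
    transcripts: Sequence[Transcript],
) -> list[tuple[str, str, str]]:
    """Type alternative splicing events against the representative isoform.

    Returns one ``(alternative_id, representative_id, event)`` triple per
    event; a single transcript pair may yield several events. Genes with a
    single transcript yield an empty list.
    """
    if len(transcripts) < 2:
        return []
    reps = [t for t in transcripts if t.is_representative]
    rep = reps[0] if reps else max(transcripts, key=lambda t: (t.mrna_length, t.id))
    out: list[tuple[str, str, str]] = []
    for t in transcripts:
        if t.id == rep.id:
            continue
        for event in _events_for_pair(t, rep):
            out.append((t.id, rep.id, event))
    return out


# ---------------------------------------------------------------------------
# NMD
# ---------------------------------------------------------------------------

def flag_nmd(transcript: Transcript, distance: int = 50) -> bool:
    """Candidate nonsense-mediated decay target?

    True iff the 3' end of the CDS lies strictly more than ``distance``
    nucleotides upstream of the last exon-exon junction in mRNA
    coordinates. Monoexonic transcripts have no junction and are never
    flagged; transcripts without a CDS are not evaluable and return False.
    """
    if not transcript.cds:
        logger.info("transcript %s has no CDS: NMD not evaluable", transcript.id)
        return False
    junctions = transcript.junction_mrna_positions()
    if not junctions:
        return False
    stop = transcript.stop_codon_mrna_position()
    return junctions[-1] - stop > distance
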