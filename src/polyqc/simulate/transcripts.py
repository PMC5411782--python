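"""Alternative-isoform generator with labelled splicing events.

For each selected gene, one alternative transcript realises exactly one
event relative to the representative isoform: intron retention (IR), exon
skipping (ES), an alternative 5' or 3' splice site (A5SS/A3SS, shifted in
mRNA orientation) or mutually exclusive exons (MXE, which replaces the
representative with a sibling isoform so that the two exclusive exons never
co-occur). Event counts follow the requested mix exactly
(largest-remainder apportionment); the randomness only decides which gene
carries which event and which intron is modified.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np

from ..models import GeneModel, Transcript
from .config import TruthTables
from .expression import apportion

logger = logging.getLogger(__name__)

DEFAULT_EVENT_MIX = {"IR": 0.34, "A3SS": 0.27, "ES": 0.20, "A5SS": 0.19}


def _with_exons(t: Transcript, exons, suffix: str, representative: bool = False) -> Transcript:
    return Transcript(
        id=f"{t.gene_id}.{suffix}",
        gene_id=t.gene_id,
        chrom=t.chrom,
        strand=t.strand,
        exons=tuple(exons),
        cds=(),
        is_representative=representative,
    )


def _alternative(rep: Transcript, event: str, rng: np.random.Generator, delta: int) -> list[Transcript] | None:
    """Build the isoform(s) realising ``event``; None when impossible."""
    exons = list(rep.exons)
    n = len(exons)
    if event == "IR":
        j = int(rng.integers(0, n - 1))
        merged = exons[:j] + [(exons[j][0], exons[j + 1][1])] + exons[j + 2 :]
        return [_with_exons(rep, merged, "ir")]
    if event == "ES":
        if n < 3:
            return None
        j = int(rng.integers(1, n - 1))
        return [_with_exons(rep, exons[:j] + exons[j + 1 :], "es")]
    if event in {"A5SS", "A3SS"}:
        j = int(rng.integers(0, n - 1))
        intron_len = exons[j + 1][0] - exons[j][1] - 1
        d = min(delta, intron_len - 2)
        if d < 1:
            return None
        # the mRNA-5' (donor) boundary is the intron's genomic-left end on
        # '+' and its genomic-right end on '-'
        shift_left = (event == "A5SS") == (rep.strand == "+")
        new = exons.copy()
        if shift_left:
            s, e = new[j]
            new[j] = (s, e + d)
        else:
            s, e = new[j + 1]
            new[j + 1] = (s - d, e)
        return [_with_exons(rep, new, event.lower())]
    if event == "MXE":
        if n < 4:
            return None
        j = int(rng.integers(1, n - 2))
        keep_first = exons[:j] + [exons[j]] + exons[j + 2 :]
        keep_second = exons[:j] + [exons[j + 1]] + exons[j + 2 :]
        return [
            _with_exons(rep, keep_first, "mxe_ref", representative=True),
            _with_exons(rep, keep_second, "mxe"),
        ]
    raise ValueError(f"unknown splicing event type {event!r}")


def generate_transcripts(
    genes: Mapping[str, GeneModel],
    as_event_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    delta: int = 9,
    truth: TruthTables | None = None,
) -> dict[str, list[Transcript]]:
    """Plant one labelled splicing event per gene according to the mix.

    Returns ``{gene_id: [representative, alternative]}`` for every gene
    that received an event. Genes structurally unable to host their drawn
    event (e.g. ES on a 2-exon gene) are skipped with a log entry.
    """
    mix = dict(as_event_mix) if as_event_mix is not None else dict(DEFAULT_EVENT_MIX)
    rng = np.random.default_rng([seed, 23])
    gene_ids = sorted(genes)
    alloc = apportion(mix, len(gene_ids))
    order = list(rng.permutation(gene_ids))
    out: dict[str, list[Transcript]] = {}
    pos = 0
    for event in sorted(alloc):
        for gid in order[pos : pos + alloc[event]]:
            rep = genes[gid].representative
            built = _alternative(rep, event, rng, delta)
            if built is None:
                logger.info("gene %s cannot host a %s event: skipped", gid, event)
                continue
            if len(built) == 2:  # MXE replaces the reference isoform
                reference, alt = built
            else:
                reference, alt = rep, built[0]
            out[gid] = [reference, alt]
            if truth is not None:
                truth.as_event_labels[alt.id] = event
        pos += alloc[event]
    return out
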