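"""Homoeolog triad expression analysis and outlier-triad translocation calls.

An allohexaploid triad is one gene copy per subgenome (A/B/D). This module
classifies triad expression balance, per-homoeolog stress responses
(UP / DOWN / FLAT on fold change), triad response patterns, expression
hotspots along the genetic map, and candidate chromosomal translocations
supported by triads whose one member anchors outside its expected
homoeologous group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anchoring import parse_chromosome

SUBGENOMES = ("A", "B", "D")

PATTERNS = ("not-DE", "1-DE", "2-DE-same", "3-DE-same", "opposite")


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: every sample column sums to 1e6.

    ``counts`` is genes x samples; ``lengths`` gives each gene's effective
    length in bp.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"missing effective lengths for genes: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene effective lengths must be > 0")
    rpk = counts.div(lengths / 1e3, axis=0)
    return rpk.div(rpk.sum(axis=0), axis=1) * 1e6


def _condition_samples(meta: pd.DataFrame, condition: str, role: str) -> list[str]:
    sel = meta[(meta["condition"] == condition) & (meta["role"] == role)]
    return list(sel["sample"])


def member_means(
    tpm: pd.DataFrame, gene_ids: Sequence[str], samples: Sequence[str]
) -> np.ndarray:
    return tpm.loc[list(gene_ids), list(samples)].mean(axis=1).to_numpy()


def classify_balance(
    tpm: pd.DataFrame,
    triads: pd.DataFrame,
    meta: pd.DataFrame,
    expression_floor: float = 2.0,
    ratio_threshold: float = 2.0,
    include_control: bool = True,
) -> pd.DataFrame:
    """Balanced vs unbalanced homoeolog expression, per triad per condition.

    A triad is assessed in each condition on its stress-replicate member
    means (plus, optionally, a pooled control assessment). It is excluded as
    not-expressed in a condition when all member means fall below
    ``expression_floor`` (tpm); otherwise it is unbalanced when the maximum
    member mean strictly exceeds ``ratio_threshold`` times the minimum.
    Dominant members are those strictly above ``ratio_threshold`` x minimum.

    Output columns: triad_id, condition, status (balanced / unbalanced /
    not-expressed), dominant (comma-joined subgenomes), plus one summary row
    per triad under condition ``"any"``.
    """
    conditions = list(dict.fromkeys(meta["condition"]))
    assessments: list[tuple[str, list[str]]] = []
    if include_control:
        ctrl = list(meta[meta["role"] == "control"]["sample"])
        if ctrl:
            assessments.append(("control", ctrl))
    for cond in conditions:
        assessments.append((cond, _condition_samples(meta, cond, "stress")))
    rows = []
    for triad in triads.itertuples():
        genes = [getattr(triad, s) for s in SUBGENOMES]
        any_unbalanced = False
        expressed_somewhere = False
        for cond, samples in assessments:
            if not samples:
                continue
            means = member_means(tpm, genes, samples)
            if (means < expression_floor).all():
                rows.append(
                    {"triad_id": triad.triad_id, "condition": cond, "status": "not-expressed", "dominant": ""}
                )
                continue
            expressed_somewhere = True
            lo, hi = means.min(), means.max()
            if hi > ratio_threshold * lo:
                dominant = [s for s, m in zip(SUBGENOMES, means) if m > ratio_threshold * lo]
                any_unbalanced = True
                rows.append(
                    {
                        "triad_id": triad.triad_id,
                        "condition": cond,
                        "status": "unbalanced",
                        "dominant": ",".join(dominant),
                    }
                )
            else:
                rows.append(
                    {"triad_id": triad.triad_id, "condition": cond, "status": "balanced", "dominant": ""}
                )
        summary = (
            "unbalanced" if any_unbalanced else ("balanced" if expressed_somewhere else "not-expressed")
        )
        rows.append({"triad_id": triad.triad_id, "condition": "any", "status": summary, "dominant": ""})
    return pd.DataFrame(rows)


def call_member(ratio: float, up_threshold: float = 2.0, down_threshold: float = 0.5) -> str:
    """UP for fold change strictly above 2, DOWN strictly below 0.5, else FLAT."""
    if ratio > up_threshold:
        return "UP"
    if ratio < down_threshold:
        return "DOWN"
    return "FLAT"


def pattern_from_calls(calls: Sequence[str]) -> str:
    """Triad pattern as a pure function of the three member calls."""
    n_up = sum(c == "UP" for c in calls)
    n_down = sum(c == "DOWN" for c in calls)
    if n_up and n_down:
        return "opposite"
    n = n_up + n_down
    if n == 0:
        return "not-DE"
    if n == 1:
        return "1-DE"
    return f"{n}-DE-same"


def classify_stress(
    tpm: pd.DataFrame,
    triads: pd.DataFrame,
    meta: pd.DataFrame,
    pseudocount: float = 0.5,
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-homoeolog stress calls and triad patterns for every condition.

    For each condition the fold change of each member is the ratio of
    stress to control replicate-mean tpm, with ``pseudocount`` added to both
    means to guard zero expression. Strict thresholds: a member is UP only
    above ``up_threshold`` (twofold) and DOWN only below ``down_threshold``
    (0.5-fold); a fold change of exactly 2.0 or 0.5 is FLAT.
    """
    conditions = list(dict.fromkeys(meta["condition"]))
    rows = []
    for cond in conditions:
        ctrl = _condition_samples(meta, cond, "control")
        stress = _condition_samples(meta, cond, "stress")
        if not ctrl:
            raise ValueError(f"condition {cond!r} has no control samples")
        if not stress:
            raise ValueError(f"condition {cond!r} has no stress samples")
        for triad in triads.itertuples():
            genes = [getattr(triad, s) for s in SUBGENOMES]
            cm = member_means(tpm, genes, ctrl)
            sm = member_means(tpm, genes, stress)
            ratios = (sm + pseudocount) / (cm + pseudocount)
            calls = [call_member(r, up_threshold, down_threshold) for r in ratios]
            rows.append(
                {
                    "triad_id": triad.triad_id,
                    "condition": cond,
                    **{f"ratio_{s}": r for s, r in zip(SUBGENOMES, ratios)},
                    **{f"call_{s}": c for s, c in zip(SUBGENOMES, calls)},
                    "pattern": pattern_from_calls(calls),
                }
            )
    return pd.DataFrame(rows)


def pattern_table(stress_calls: pd.DataFrame, among_de: bool = False) -> pd.DataFrame:
    """Pattern frequency table per condition (counts and fractions).

    With ``among_de=True`` the fractions are over differentially expressed
    triads only (the not-DE class is dropped), matching how DE-triad pattern
    distributions are usually displayed.
    """
    df = stress_calls
    if among_de:
        df = df[df["pattern"] != "not-DE"]
    counts = (
        df.groupby(["condition", "pattern"]).size().unstack(fill_value=0)
    )
    for p in PATTERNS:
        if p not in counts.columns and not (among_de and p == "not-DE"):
            counts[p] = 0
    counts = counts[[p for p in PATTERNS if p in counts.columns]]
    fractions = counts.div(counts.sum(axis=1), axis=0)
    counts.columns = [f"n_{c}" for c in counts.columns]
    fractions.columns = [f"frac_{c}" for c in fractions.columns]
    return pd.concat([counts, fractions], axis=1).reset_index()


def find_hotspots(
    tpm_by_tissue: pd.DataFrame,
    gene_bins: Mapping[str, tuple[str, float]],
    threshold: float = 20.0,
) -> pd.DataFrame:
    """Genetic bins whose median gene expression strictly exceeds a floor.

    ``tpm_by_tissue`` is genes x tissues (already replicate-averaged);
    ``gene_bins`` maps gene ids to their (chromosome, cM) bin. A bin is a
    hotspot in a tissue when the median tpm over its binned genes is
    strictly greater than ``threshold`` (default 20 tpm). Bins with no
    expressed genes are skipped.
    """
    rows = []
    binned = pd.DataFrame(
        [
            {"gene_id": g, "chromosome": b[0], "cM": b[1]}
            for g, b in gene_bins.items()
            if g in tpm_by_tissue.index
        ]
    )
    if binned.empty:
        return pd.DataFrame(
            columns=["tissue", "chromosome", "cM", "median_tpm", "n_genes", "gene_ids"]
        )
    for (chrom, cm), group in binned.groupby(["chromosome", "cM"]):
        genes = list(group["gene_id"])
        for tissue in tpm_by_tissue.columns:
            med = float(tpm_by_tissue.loc[genes, tissue].median())
            if med > threshold:
                rows.append(
                    {
                        "tissue": tissue,
                        "chromosome": chrom,
                        "cM": cm,
                        "median_tpm": med,
                        "n_genes": len(genes),
                        "gene_ids": ",".join(sorted(genes)),
                    }
                )
    return pd.DataFrame(rows, columns=["tissue", "chromosome", "cM", "median_tpm", "n_genes", "gene_ids"])


@dataclass(frozen=True)
class TranslocationCandidate:
    """A genetic bin whose triad members belong homoeologously elsewhere."""

    source_bin: tuple[str, float]
    target_chromosome: str
    supporting_triads: tuple[str, ...]

    @property
    def n_support(self) -> int:
        return len(self.supporting_triads)


def detect_translocations(
    member_bins: pd.DataFrame,
    min_support: int = 3,
) -> list[TranslocationCandidate]:
    """Candidate translocations from outlier triads.

    ``member_bins`` has one row per anchored triad member: columns
    ``triad_id``, ``subgenome`` (the member's A/B/D slot), ``chromosome``
    and ``cM`` (its assigned genetic bin). Only triads with all three
    members anchored are considered. An outlier triad has exactly one
    member whose chromosome lies outside the homoeologous group shared by
    the other two; outliers are grouped by (the outlier's bin, the
    chromosome the member was homoeologously expected on), and groups
    reaching ``min_support`` are reported, largest first.
    """
    candidates: dict[tuple[tuple[str, float], str], list[str]] = {}
    for triad_id, group in member_bins.groupby("triad_id"):
        if len(group) != 3 or set(group["subgenome"]) != set(SUBGENOMES):
            continue
        rows = {r.subgenome: r for r in group.itertuples()}
        groups = {s: parse_chromosome(rows[s].chromosome)[0] for s in SUBGENOMES}
        values = list(groups.values())
        outlier = None
        for s in SUBGENOMES:
            others = [groups[o] for o in SUBGENOMES if o != s]
            if others[0] == others[1] and groups[s] != others[0]:
                outlier = s
                majority = others[0]
        if outlier is None:
            continue
        row = rows[outlier]
        source_bin = (row.chromosome, float(row.cM))
        target = f"{majority}{outlier}"
        candidates.setdefault((source_bin, target), []).append(str(triad_id))
    out = [
        TranslocationCandidate(
            source_bin=key[0], target_chromosome=key[1], supporting_triads=tuple(sorted(ids))
        )
        for key, ids in candidates.items()
        if len(ids) >= min_support
    ]
    out.sort(key=lambda c: (-c.n_support, c.source_bin, c.target_chromosome))
    return out


def translocations_to_frame(candidates: Sequence[TranslocationCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source_chromosome": c.source_bin[0],
                "source_cM": c.source_bin[1],
                "target_chromosome": c.target_chromosome,
                "n_support": c.n_support,
                "triad_ids": ",".join(c.supporting_triads),
            }
            for c in candidates
        ]
    )
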