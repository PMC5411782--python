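"""Two-tiered scaffold redundancy filter.

After scaffolding, short scaffolds whose sequence content is already carried
by longer scaffolds inflate the assembly without adding information. The
filter processes scaffolds in decreasing length order (ties broken by id):
scaffolds at or above the length gate are always retained; a shorter
scaffold is removed iff at least ``redundancy_threshold`` of its distinct
canonical k-mers already occur in the retained set. The report tracks the
distinct k-mers that exist only in removed scaffolds, so the unique-content
cost of the filter is explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .kmers import _encode_codes, _validate_k

logger = logging.getLogger(__name__)


def n50(lengths) -> int:
    """Smallest length L such that sequences >= L hold >= half the bases."""
    lens = sorted((int(x) for x in lengths), reverse=True)
    if not lens:
        return 0
    half = sum(lens) / 2
    acc = 0
    for ln in lens:
        acc += ln
        if acc >= half:
            return ln
    return lens[-1]


def scaffold_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mer codes of one scaffold."""
    return np.unique(_encode_codes(seq, k))


@dataclass
class FilterReport:
    min_len: int
    k: int
    redundancy_threshold: float
    kept_ids: list[str]
    removed_short_ids: list[str]
    removed_redundant: dict[str, tuple[int, float]]  # id -> (length, redundant_fraction)
    unique_content_lost: int
    n50_before: int
    n50_after: int

    @property
    def removed_redundant_ids(self) -> list[str]:
        return list(self.removed_redundant)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for sid in self.kept_ids:
            rows.append({"scaffold_id": sid, "status": "kept", "redundant_fraction": ""})
        for sid in self.removed_short_ids:
            rows.append({"scaffold_id": sid, "status": "removed_short", "redundant_fraction": ""})
        for sid, (_, frac) in self.removed_redundant.items():
            rows.append(
                {"scaffold_id": sid, "status": "removed_redundant", "redundant_fraction": f"{frac:.4f}"}
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class _CodeSet:
    """Growable sorted-array set of k-mer codes with lazy consolidation."""

    def __init__(self) -> None:
        self._base = np.empty(0, dtype=np.uint64)
        self._pending: list[np.ndarray] = []

    def add(self, codes: np.ndarray) -> None:
        if len(codes):
            self._pending.append(codes)
        if len(self._pending) > 16:
            self._consolidate()

    def _consolidate(self) -> None:
        self._base = np.unique(np.concatenate([self._base, *self._pending]))
        self._pending = []

    def contains_fraction(self, codes: np.ndarray) -> float:
        if len(codes) == 0:
            return 0.0
        member = np.zeros(len(codes), dtype=bool)
        for arr in [self._base, *self._pending]:
            if len(arr) == 0:
                continue
            idx = np.minimum(np.searchsorted(arr, codes), len(arr) - 1)
            member |= arr[idx] == codes
        return float(member.sum()) / len(codes)

    def array(self) -> np.ndarray:
        self._consolidate()
        return self._base


def filter_scaffolds(
    scaffolds: Mapping[str, str],
    min_len: int = 500,
    k: int = 31,
    redundancy_threshold: float = 0.95,
    absolute_min_len: int = 0,
) -> tuple[FilterReport, dict[str, str]]:
    """Drop short scaffolds whose k-mer content is already represented.

    Scaffolds of length >= ``min_len`` are always kept. Shorter scaffolds
    are examined in decreasing length order and removed iff at least
    ``redundancy_threshold`` of their distinct k-mers occur in the scaffolds
    retained so far. If ``absolute_min_len`` > 0, scaffolds below it are
    removed outright on length alone (tier 1) before k-mer screening.

    Returns the report and the retained ``{id: sequence}`` dict.
    """
    _validate_k(k)
    if min_len < k:
        raise ValueError(f"min_len ({min_len}) must be >= k ({k})")
    if not 0 < redundancy_threshold <= 1:
        raise ValueError("redundancy_threshold must be in (0, 1]")

    order = sorted(scaffolds, key=lambda sid: (-len(scaffolds[sid]), sid))
    kept: list[str] = []
    removed_short: list[str] = []
    removed_redundant: dict[str, tuple[int, float]] = {}
    retained_codes = _CodeSet()
    removed_code_arrays: list[np.ndarray] = []

    for sid in order:
        seq = scaffolds[sid]
        length = len(seq)
        if length < absolute_min_len:
            removed_short.append(sid)
            removed_code_arrays.append(scaffold_kmer_codes(seq, k))
            continue
        if length >= min_len:
            kept.append(sid)
            retained_codes.add(scaffold_kmer_codes(seq, k))
            continue
        codes = scaffold_kmer_codes(seq, k)
        if length < k:
            logger.info("scaffold %s shorter than k=%d: contributes no k-mers", sid, k)
        fraction = retained_codes.contains_fraction(codes)
        if len(codes) and fraction >= redundancy_threshold:
            removed_redundant[sid] = (length, fraction)
            removed_code_arrays.append(codes)
        else:
            kept.append(sid)
            retained_codes.add(codes)

    if removed_code_arrays:
        removed_union = np.unique(np.concatenate(removed_code_arrays))
        lost = int(len(np.setdiff1d(removed_union, retained_codes.array(), assume_unique=True)))
    else:
        lost = 0

    report = FilterReport(
        min_len=min_len,
        k=k,
        redundancy_threshold=redundancy_threshold,
        kept_ids=sorted(kept),
        removed_short_ids=sorted(removed_short),
        removed_redundant=removed_redundant,
        unique_content_lost=lost,
        n50_before=n50(len(s) for s in scaffolds.values()),
        n50_after=n50(len(scaffolds[sid]) for sid in kept),
    )
    return report, {sid: scaffolds[sid] for sid in sorted(kept)}
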