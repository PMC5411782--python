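"""Canonical k-mer counting and spectra-cn assembly QC.

The spectra-cn analysis decomposes the k-mer spectrum of a read set by the
number of times each k-mer occurs in an assembly. Read k-mers absent from the
assembly (copy number 0) flag missing content; assembly k-mers absent from
the reads (multiplicity 0) flag artefactual content such as chimeric joins or
consensus errors; single-copy read k-mers present more than once flag
artefactual duplication.

Counting is exact. For k <= 31 each k-mer is packed into a 64-bit integer
(2 bits per base, A=0 C=1 G=2 T=3, so integer order equals lexicographic
order) and counted with vectorised numpy; larger odd k up to 63 falls back to
a string dictionary. A k-mer and its reverse complement are collapsed onto
the lexicographically smaller of the two (the canonical form); windows
containing non-ACGT symbols are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .gffio import read_fasta, read_reads

logger = logging.getLogger(__name__)

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _BASE_CODE[_b] = _i

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _validate_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError(f"k must be odd (canonical form is ambiguous for even k), got {k}")
    if not 3 <= k <= 63:
        raise ValueError(f"k must be in [3, 63], got {k}")


def _encode_codes(seq: str, k: int) -> np.ndarray:
    """Canonical integer codes for every valid k-mer window of one sequence."""
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    valid = arr != 255
    base = np.where(valid, arr, 0).astype(np.uint64)
    comp = np.uint64(3) - base
    for j in range(k):
        window = slice(j, j + n)
        fwd = (fwd << np.uint64(2)) | base[window]
        rev = rev | (comp[window] << np.uint64(2 * j))
    bad = np.cumsum(np.concatenate(([0], (~valid).astype(np.int64))))
    ok = (bad[k:] - bad[:-k]) == 0
    return np.minimum(fwd, rev)[ok]


def decode_code(code: int, k: int) -> str:
    return "".join("ACGT"[(code >> (2 * (k - 1 - j))) & 3] for j in range(k))


@dataclass
class KmerSpectrum:
    """Histogram of distinct canonical k-mers by read multiplicity.

    ``hist[m]`` is the number of distinct k-mers seen exactly ``m`` times;
    ``hist[0]`` is always 0.
    """

    k: int
    hist: np.ndarray

    @property
    def total_distinct(self) -> int:
        return int(self.hist.sum())

    def __getitem__(self, multiplicity: int) -> int:
        if multiplicity >= len(self.hist):
            return 0
        return int(self.hist[multiplicity])


@dataclass
class KmerCounts:
    """Exact multiset of canonical k-mers: sorted unique codes and counts."""

    k: int
    codes: np.ndarray
    counts: np.ndarray
    _strings: dict[str, int] | None = field(default=None, repr=False)

    @classmethod
    def from_sequences(cls, sequences: Iterable[str] | Mapping[str, str], k: int) -> "KmerCounts":
        _validate_k(k)
        if isinstance(sequences, Mapping):
            sequences = list(sequences.values())
        else:
            sequences = list(sequences)
        if not sequences:
            raise ValueError("no input sequences")
        if k <= 31:
            chunks = [_encode_codes(s, k) for s in sequences]
            allcodes = (
                np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
            )
            codes, counts = np.unique(allcodes, return_counts=True)
            return cls(k=k, codes=codes, counts=counts.astype(np.int64))
        # fallback: dictionary of canonical strings for 31 < k <= 63
        table: dict[str, int] = {}
        valid = set("ACGT")
        for s in sequences:
            s = s.upper()
            for i in range(len(s) - k + 1):
                w = s[i : i + k]
                if set(w) <= valid:
                    table[canonical(w)] = table.get(canonical(w), 0) + 1
        keys = sorted(table)
        return cls(
            k=k,
            codes=np.arange(len(keys), dtype=np.uint64),
            counts=np.array([table[w] for w in keys], dtype=np.int64),
            _strings=table,
        )

    @property
    def total_distinct(self) -> int:
        return len(self.codes)

    def as_dict(self) -> dict[str, int]:
        """Decode to ``{canonical k-mer: multiplicity}`` (small inputs only)."""
        if self._strings is not None:
            return dict(self._strings)
        return {
            decode_code(int(c), self.k): int(n) for c, n in zip(self.codes, self.counts)
        }

    def spectrum(self) -> KmerSpectrum:
        if len(self.counts) == 0:
            return KmerSpectrum(k=self.k, hist=np.zeros(1, dtype=np.int64))
        m_max = int(self.counts.max())
        hist = np.bincount(self.counts, minlength=m_max + 1).astype(np.int64)
        hist[0] = 0
        return KmerSpectrum(k=self.k, hist=hist)


def count_kmers(sequences: Iterable[str] | Mapping[str, str], k: int = 31) -> KmerCounts:
    """Count canonical k-mers over a collection of sequences."""
    return KmerCounts.from_sequences(sequences, k)


def count_kmers_fasta(path: str | Path, k: int = 31) -> KmerCounts:
    return count_kmers(read_fasta(path), k)


def count_kmers_reads(path: str | Path, k: int = 31) -> KmerCounts:
    return count_kmers(read_reads(path), k)


@dataclass
class SpectraCN:
    """Read k-mer spectrum decomposed by assembly copy number.

    ``matrix[m, c]`` counts distinct canonical k-mers with read multiplicity
    ``m`` (row 0 = absent from the reads) and assembly copy number ``c``
    (column 0 = absent from the assembly); the last column is open-ended and
    accumulates copy numbers >= ``c_max``.
    """

    k: int
    matrix: np.ndarray  # shape (m_max + 1, c_max + 1)
    c_max: int

    @property
    def artifact_row(self) -> np.ndarray:
        """Distinct assembly k-mers never seen in the reads, by copy number."""
        return self.matrix[0]

    @property
    def artifact_total(self) -> int:
        return int(self.matrix[0, 1:].sum())

    def read_spectrum(self) -> KmerSpectrum:
        hist = self.matrix.sum(axis=1)
        hist[0] = 0
        return KmerSpectrum(k=self.k, hist=hist.astype(np.int64))

    def assembly_distinct(self) -> int:
        return int(self.matrix[:, 1:].sum())

    def validate(self, read_counts: KmerCounts, assembly_counts: KmerCounts) -> None:
        """Assert row conservation (reads) and column conservation (assembly)."""
        spectrum = read_counts.spectrum()
        rows = self.matrix.sum(axis=1)
        rows[0] = 0
        expect = np.zeros_like(rows)
        expect[: len(spectrum.hist)] = spectrum.hist
        if not np.array_equal(rows, expect):
            raise AssertionError("spectra-cn row conservation violated")
        if self.assembly_distinct() != assembly_counts.total_distinct:
            raise AssertionError("spectra-cn column conservation violated")

    def to_frame(self):
        import pandas as pd

        cols = [str(c) for c in range(self.c_max)] + [f"{self.c_max}+"]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.index.name = "multiplicity"
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def spectra_cn(
    read_counts: KmerCounts, assembly_counts: KmerCounts, c_max: int = 10
) -> SpectraCN:
    """Join read and assembly k-mer multisets into the copy-number matrix."""
    if read_counts.k != assembly_counts.k:
        raise ValueError(
            f"k mismatch: reads counted at k={read_counts.k}, assembly at k={assembly_counts.k}"
        )
    if read_counts._strings is not None or assembly_counts._strings is not None:
        return _spectra_cn_strings(read_counts, assembly_counts, c_max)
    m_max = int(read_counts.counts.max()) if len(read_counts.counts) else 0
    matrix = np.zeros((m_max + 1, c_max + 1), dtype=np.int64)
    # read-side rows
    idx = np.searchsorted(assembly_counts.codes, read_counts.codes)
    idx_clip = np.minimum(idx, max(len(assembly_counts.codes) - 1, 0))
    if len(assembly_counts.codes):
        present = assembly_counts.codes[idx_clip] == read_counts.codes
        copy = np.where(present, assembly_counts.counts[idx_clip], 0)
    else:
        copy = np.zeros(len(read_counts.codes), dtype=np.int64)
    np.add.at(matrix, (read_counts.counts, np.minimum(copy, c_max)), 1)
    # assembly-only k-mers -> artifact row (multiplicity 0)
    if len(assembly_counts.codes):
        jdx = np.searchsorted(read_counts.codes, assembly_counts.codes)
        jdx_clip = np.minimum(jdx, max(len(read_counts.codes) - 1, 0))
        if len(read_counts.codes):
            in_reads = read_counts.codes[jdx_clip] == assembly_counts.codes
        else:
            in_reads = np.zeros(len(assembly_counts.codes), dtype=bool)
        only = np.minimum(assembly_counts.counts[~in_reads], c_max)
        np.add.at(matrix[0], only, 1)
    return SpectraCN(k=read_counts.k, matrix=matrix, c_max=c_max)


def _spectra_cn_strings(read_counts: KmerCounts, assembly_counts: KmerCounts, c_max: int) -> SpectraCN:
    rd = read_counts.as_dict()
    asm = assembly_counts.as_dict()
    m_max = max(rd.values(), default=0)
    matrix = np.zeros((m_max + 1, c_max + 1), dtype=np.int64)
    for w, m in rd.items():
        matrix[m, min(asm.get(w, 0), c_max)] += 1
    for w, c in asm.items():
        if w not in rd:
            matrix[0, min(c, c_max)] += 1
    return SpectraCN(k=read_counts.k, matrix=matrix, c_max=c_max)


def _smooth(hist: np.ndarray) -> np.ndarray:
    """3-point moving average; minimal smoothing that kills single-bin noise."""
    padded = np.concatenate(([hist[0]], hist, [hist[-1]]))
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def error_threshold(spectrum: KmerSpectrum, default: int = 2) -> int:
    """Multiplicity separating the sequencing-error peak from real content.

    Returns the multiplicity at the first local minimum of the 3-point
    smoothed spectrum (the valley between the error peak near multiplicity 1
    and the main coverage peak). If the spectrum has no such valley — e.g.
    error-free reads, or a monotone histogram — the configured default is
    returned and a warning is logged.
    """
    hist = spectrum.hist.astype(float)
    if len(hist) < 4:
        logger.warning("spectrum too short for valley detection; using default threshold %d", default)
        return default
    s = _smooth(hist)
    if hist[2] >= hist[1]:
        # no descending error peak at low multiplicity (e.g. error-free reads)
        logger.warning(
            "k-mer spectrum has no error peak; using default threshold %d", default
        )
        return default
    for m in range(2, len(s) - 1):
        if s[m] < s[m - 1] and s[m] <= s[m + 1]:
            return m
    logger.warning("no local minimum found in k-mer spectrum; using default threshold %d", default)
    return default


def main_peak(spectrum: KmerSpectrum, threshold: int) -> int:
    """Multiplicity of the main coverage peak (mode above the error threshold)."""
    hist = spectrum.hist.astype(float)
    if threshold >= len(hist):
        return threshold
    s = _smooth(hist)
    return int(np.argmax(s[threshold:]) + threshold)


@dataclass
class QCSummary:
    """Headline spectra-cn statistics.

    * ``missing_kmers`` — solid read k-mers (multiplicity >= threshold)
      absent from the assembly: genuine content the assembly lacks.
    * ``artifact_kmers`` — assembly k-mers never seen in the reads:
      chimeric or erroneous assembled sequence.
    * ``duplicated_kmers`` — k-mers whose read multiplicity sits in the
      expected single-copy band but that occur >= 2 times in the assembly.
    * ``completeness`` — fraction of solid read k-mers represented.
    """

    error_threshold: int
    missing_kmers: int
    artifact_kmers: int
    duplicated_kmers: int
    completeness: float

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame([self.__dict__]).to_csv(path, sep="\t", index=False)


def qc_summary(
    cn: SpectraCN,
    threshold: int,
    single_copy_band: tuple[int, int] | None = None,
) -> QCSummary:
    """Summarise a spectra-cn matrix above an error-multiplicity threshold.

    ``single_copy_band`` bounds (inclusive low, exclusive high) the read
    multiplicities treated as expected-single-copy when counting artefactual
    duplication; by default it is [threshold, 1.5 x main peak).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    m_rows = cn.matrix.shape[0]
    thr = min(threshold, m_rows)
    missing = int(cn.matrix[thr:, 0].sum())
    denom = int(cn.matrix[thr:, :].sum())
    if denom == 0:
        logger.warning("no read k-mers at or above multiplicity %d; completeness set to 1.0", threshold)
        completeness = 1.0
    else:
        completeness = 1.0 - missing / denom
    if single_copy_band is None:
        peak = main_peak(cn.read_spectrum(), threshold)
        single_copy_band = (threshold, max(threshold + 1, int(1.5 * peak)))
    lo, hi = single_copy_band
    lo = min(max(lo, 0), m_rows)
    hi = min(max(hi, lo), m_rows)
    duplicated = int(cn.matrix[lo:hi, 2:].sum())
    return QCSummary(
        error_threshold=threshold,
        missing_kmers=missing,
        artifact_kmers=cn.artifact_total,
        duplicated_kmers=duplicated,
        completeness=completeness,
    )


def plot_spectra_cn(cn: SpectraCN, path: str | Path, m_max: int | None = None) -> None:
    """Stacked histogram of the spectra-cn matrix.

    Colour semantics follow the usual spectra-cn convention: black for
    content absent from the assembly, red for single-copy, green for
    two-copy, then further colours for higher copy numbers. The artefact
    content (multiplicity 0) is drawn as a red bar at x = 0.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colours = ["black", "red", "green", "purple", "orange", "blue"]
    rows = cn.matrix.shape[0] if m_max is None else min(m_max + 1, cn.matrix.shape[0])
    x = np.arange(1, rows)
    fig, ax = plt.subplots(figsize=(8, 5))
    bottom = np.zeros(rows - 1)
    for c in range(cn.matrix.shape[1]):
        colour = colours[min(c, len(colours) - 1)]
        label = "absent" if c == 0 else (f"{c}x" if c < cn.c_max else f"{cn.c_max}+x")
        ax.bar(x, cn.matrix[1:rows, c], width=1.0, bottom=bottom, color=colour, label=label)
        bottom = bottom + cn.matrix[1:rows, c]
    ax.bar([0], [cn.artifact_total], width=1.0, color="red")
    ax.set_xlabel("k-mer multiplicity in reads")
    ax.set_ylabel("distinct k-mers")
    ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
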