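"""Triad expression simulator: negative-binomial counts with planted truth.

The design mirrors a paired stress experiment on seedlings: every condition
(stress x duration) has its own control and stress replicate groups. Each
triad gets a per-condition response pattern drawn from the requested mix
(largest-remainder apportionment, so the planted proportions are exact) and
a constitutive balance state. Planted fold changes default to 3.0x (UP) and
0.3x (DOWN) — comfortably beyond the 2x / 0.5x call boundaries, so that the
planted truth stays recoverable at realistic overdispersion; boundary
behaviour can be studied by overriding the folds.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import TruthTables

logger = logging.getLogger(__name__)

DEFAULT_CONDITIONS = ("D.6h", "H.6h", "DH.6h", "PM.48h", "SR.48h")

DEFAULT_PATTERN_MIX = {
    "not-DE": 0.80,
    "1-DE": 0.17,
    "2-DE-same": 0.02,
    "3-DE-same": 0.005,
    "opposite": 0.005,
}

SUBGENOMES = ("A", "B", "D")


@dataclass
class ExpressionData:
    counts: pd.DataFrame  # genes x samples
    lengths: pd.Series  # effective length per gene
    meta: pd.DataFrame  # sample, condition, role, replicate
    triads: pd.DataFrame  # triad_id, A, B, D

    def write(self, counts_path, lengths_path, meta_path, triads_path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        self.lengths.rename("length").to_csv(lengths_path, sep="\t")
        self.meta.to_csv(meta_path, sep="\t", index=False)
        self.triads.to_csv(triads_path, sep="\t", index=False)


def apportion(mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` items over ``mix`` proportions."""
    total = sum(mix.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"mix proportions must sum to 1, got {total}")
    keys = sorted(mix)
    exact = {k: n * mix[k] / total for k in keys}
    alloc = {k: int(exact[k]) for k in keys}
    leftover = n - sum(alloc.values())
    for k in sorted(keys, key=lambda k: exact[k] - alloc[k], reverse=True)[:leftover]:
        alloc[k] += 1
    return alloc


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0.0:
        return np.rint(mean).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.int64)


def generate_expression(
    triads: Mapping[str, Mapping[str, str]],
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    n_replicates: int = 3,
    imbalance_fraction: float = 0.26,
    pattern_mix: Mapping[str, float] | None = None,
    dispersion: float = 0.1,
    base_mean: float = 150.0,
    up_fold: float = 3.0,
    down_fold: float = 0.3,
    imbalance_factor: float = 4.0,
    gene_lengths: Mapping[str, int] | None = None,
    seed: int = 0,
    truth: TruthTables | None = None,
) -> ExpressionData:
    """Simulate a counts matrix with planted balance and stress patterns.

    ``triads`` maps triad ids to their ``{subgenome: gene id}`` members (the
    shape of ``TruthTables.triad_membership``). Counts are drawn from a
    negative binomial with the given dispersion (variance mu + dispersion
    mu^2); dispersion 0 yields the rounded means, so downstream calls are
    deterministic and planted labels are recovered exactly.
    """
    if n_replicates < 2:
        logger.warning(
            "fewer than 2 replicates per condition: classification runs on single-sample means"
        )
    if n_replicates < 1:
        raise ValueError("at least one replicate per condition is required")
    if not 0.0 <= imbalance_fraction <= 1.0:
        raise ValueError("imbalance_fraction must be in [0, 1]")
    mix = dict(pattern_mix) if pattern_mix is not None else dict(DEFAULT_PATTERN_MIX)
    rng = np.random.default_rng(seed)
    triad_ids = sorted(triads)
    n = len(triad_ids)

    # constitutive balance state
    n_unbalanced = round(n * imbalance_fraction)
    unbalanced_ids = set(rng.permutation(triad_ids)[:n_unbalanced])
    member_factor: dict[str, np.ndarray] = {}
    base: dict[str, float] = {}
    for tid in triad_ids:
        base[tid] = float(np.exp(rng.normal(np.log(base_mean), 0.6)))
        jitter = rng.uniform(0.8, 1.25, 3)  # max/min < 2: stays balanced
        factors = jitter.copy()
        if tid in unbalanced_ids:
            dominant = rng.integers(0, 3)
            factors[dominant] *= imbalance_factor
        member_factor[tid] = factors
        if truth is not None:
            truth.balance_labels[tid] = tid in unbalanced_ids

    # per-condition pattern assignment (exact proportions)
    pattern_of: dict[tuple[str, str], str] = {}
    affected: dict[tuple[str, str], list[tuple[int, float]]] = {}
    n_de_members = {"not-DE": 0, "1-DE": 1, "2-DE-same": 2, "3-DE-same": 3, "opposite": 2}
    for cond in conditions:
        alloc = apportion(mix, n)
        order = list(rng.permutation(triad_ids))
        pos = 0
        for pattern in sorted(alloc):
            for tid in order[pos : pos + alloc[pattern]]:
                pattern_of[(tid, cond)] = pattern
                members = list(rng.permutation(3)[: n_de_members[pattern]])
                if pattern == "opposite":
                    folds = [up_fold, down_fold]
                    rng.shuffle(folds)
                elif pattern == "not-DE":
                    folds = []
                else:
                    f = up_fold if rng.integers(0, 2) else down_fold
                    folds = [f] * len(members)
                affected[(tid, cond)] = list(zip(members, folds))
                if truth is not None:
                    truth.expression_labels[(tid, cond)] = pattern
            pos += alloc[pattern]

    # build the matrix
    genes = [triads[tid][s] for tid in triad_ids for s in SUBGENOMES]
    samples: list[str] = []
    meta_rows = []
    for cond in conditions:
        for role in ("control", "stress"):
            for r in range(1, n_replicates + 1):
                name = f"{cond}.{role}.r{r}"
                samples.append(name)
                meta_rows.append(
                    {"sample": name, "condition": cond, "role": role, "replicate": r}
                )
    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    for ti, tid in enumerate(triad_ids):
        ctrl_mean = base[tid] * member_factor[tid]
        for ci, cond in enumerate(conditions):
            stress_mean = ctrl_mean.copy()
            for member, fold in affected[(tid, cond)]:
                stress_mean[member] = ctrl_mean[member] * fold
            col0 = ci * 2 * n_replicates
            for r in range(n_replicates):
                counts[3 * ti : 3 * ti + 3, col0 + r] = _nb_sample(rng, ctrl_mean, dispersion)
                counts[3 * ti : 3 * ti + 3, col0 + n_replicates + r] = _nb_sample(
                    rng, stress_mean, dispersion
                )

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    counts_df.index.name = "gene_id"
    if gene_lengths is not None:
        lengths = pd.Series({g: gene_lengths[g] for g in genes}, name="length")
    else:
        lengths = pd.Series(900, index=pd.Index(genes, name="gene_id"), name="length")
    triads_df = pd.DataFrame(
        [{"triad_id": tid, **{s: triads[tid][s] for s in SUBGENOMES}} for tid in triad_ids]
    )
    return ExpressionData(
        counts=counts_df,
        lengths=lengths,
        meta=pd.DataFrame(meta_rows),
        triads=triads_df,
    )
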