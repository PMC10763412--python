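"""Per-gene representative-UTR selection and mini-library assembly.

Mirrors the construction of a reporter mini-library from long-read
transcriptome data: one representative 5' UTR per gene (most frequent,
ties to the longest), restriction to highly expressed genes (top 20% by
TPM, emPAI or their ratio), then a seeded draw of poly(A)-containing
entries plus length-stratified poly(A)-free controls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .sequences import UtrSequence, longest_polya


@dataclass(frozen=True)
class UtrCandidate:
    gene_id: str
    seq: str
    frequency: int

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")


@dataclass(frozen=True)
class GeneExpression:
    gene_id: str
    tpm: float | None = None
    empai: float | None = None

    def __post_init__(self) -> None:
        if self.tpm is None and self.empai is None:
            raise ValueError("at least one of tpm/empai must be present")
        for v in (self.tpm, self.empai):
            if v is not None and v < 0:
                raise ValueError("expression values must be >= 0")


@dataclass(frozen=True)
class LibraryEntry:
    gene_id: str
    seq: str
    has_polya: int
    selection_basis: str


def select_representative_utr(candidates: list[UtrCandidate]) -> UtrCandidate:
    """The most frequent candidate; frequency ties go to the longest
    sequence, frequency+length ties to the lexicographically smallest.

    Pure function of the candidate multiset (input order irrelevant).
    """
    if not candidates:
        raise ValueError("no candidates")
    gene_ids = {c.gene_id for c in candidates}
    if len(gene_ids) != 1:
        raise ValueError(f"candidates span multiple genes: {sorted(gene_ids)}")
    return min(candidates, key=lambda c: (-c.frequency, -len(c.seq), c.seq))


def rank_top_fraction(
    expr: list[GeneExpression], metric: str, fraction: float
) -> list[str]:
    """Gene ids of the ``ceil(fraction * n)`` highest values of ``metric``.

    ``metric`` is one of ``tpm``, ``empai`` or ``ratio`` (= empai / tpm).
    Ties at the cut are kept in stable input order.  Genes lacking the
    metric (or with tpm = 0 for the ratio) are excluded with a warning.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if metric not in ("tpm", "empai", "ratio"):
        raise ValueError(f"unknown metric {metric!r}")
    values: list[tuple[str, float]] = []
    for g in expr:
        if metric == "tpm":
            v = g.tpm
        elif metric == "empai":
            v = g.empai
        else:
            if g.tpm is None or g.empai is None:
                v = None
            elif g.tpm == 0:
                warnings.warn(f"gene {g.gene_id}: tpm = 0, excluded from ratio ranking")
                v = None
            else:
                v = g.empai / g.tpm
        if v is not None:
            values.append((g.gene_id, v))
    k = math.ceil(fraction * len(values))
    order = sorted(range(len(values)), key=lambda i: (-values[i][1], i))
    return [values[i][0] for i in order[:k]]


def build_library(
    utrs: dict[str, str],
    expr: list[GeneExpression],
    max_len: int = 200,
    n_polya: int = 207,
    n_control: int = 34,
    fraction: float = 0.2,
    combine: str = "union",
    seed: int = 0,
    min_polya: int = 5,
) -> list[LibraryEntry]:
    """Assemble the mini-library.

    Pipeline: strict length filter (< ``max_len``); eligibility = union
    (default; ``combine="intersection"`` available) of the per-metric
    top-``fraction`` gene sets; a seeded draw of ``n_polya`` UTRs whose
    longest A-run is >= ``min_polya`` nt; ``n_control`` UTRs without such
    a run, stratified so longest-run lengths 0..min_polya-1 are as evenly
    represented as possible (remainders go to the shortest strata).
    """
    if combine not in ("union", "intersection"):
        raise ValueError("combine must be 'union' or 'intersection'")
    top_sets = {
        m: set(rank_top_fraction(expr, m, fraction)) for m in ("tpm", "empai", "ratio")
    }
    if combine == "union":
        eligible = top_sets["tpm"] | top_sets["empai"] | top_sets["ratio"]
    else:
        eligible = top_sets["tpm"] & top_sets["empai"] & top_sets["ratio"]

    def basis(gene: str) -> str:
        for m in ("tpm", "empai", "ratio"):
            if gene in top_sets[m]:
                return m
        return "none"

    pool = [
        (g, s)
        for g, s in sorted(utrs.items())
        if g in eligible and len(s) < max_len
    ]
    polya_pool = []
    control_pools: dict[int, list[tuple[str, str]]] = {
        k: [] for k in range(min_polya)
    }
    for g, s in pool:
        tract = longest_polya(s, min_len=1)
        run = tract.length if tract is not None else 0
        if run >= min_polya:
            polya_pool.append((g, s))
        else:
            control_pools[run].append((g, s))

    rng = np.random.default_rng(seed)
    if len(polya_pool) < n_polya:
        raise ValueError(
            f"poly(A) stratum has {len(polya_pool)} UTRs, {n_polya} requested"
        )
    idx = rng.choice(len(polya_pool), size=n_polya, replace=False)
    entries = [
        LibraryEntry(g, s, 1, basis(g)) for g, s in (polya_pool[i] for i in sorted(idx))
    ]

    # equal strata over longest-run lengths 0..min_polya-1, remainder to shortest
    base, rem = divmod(n_control, min_polya)
    for run in range(min_polya):
        want = base + (1 if run < rem else 0)
        have = control_pools[run]
        if len(have) < want:
            raise ValueError(
                f"control stratum (longest run {run} nt) has {len(have)} UTRs, "
                f"{want} requested"
            )
        idx = rng.choice(len(have), size=want, replace=False)
        entries.extend(
            LibraryEntry(g, s, 0, basis(g)) for g, s in (have[i] for i in sorted(idx))
        )
    return entries


def summarize_lengths(utrs: list[UtrSequence | str], n_bins: int = 10) -> dict:
    """Deterministic length-distribution summary.

    Median and quartiles use lower interpolation; histogram counts sum to n.
    """
    if not utrs:
        raise ValueError("no sequences")
    lengths = np.array(
        [len(u.seq) if isinstance(u, UtrSequence) else len(u) for u in utrs]
    )
    q1, med, q3 = np.percentile(lengths, [25, 50, 75], method="lower")
    counts, edges = np.histogram(lengths, bins=n_bins)
    return {
        "n": int(lengths.size),
        "median": int(med),
        "q1": int(q1),
        "q3": int(q3),
        "min": int(lengths.min()),
        "max": int(lengths.max()),
        "hist_counts": counts.tolist(),
        "hist_edges": edges.tolist(),
    }
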