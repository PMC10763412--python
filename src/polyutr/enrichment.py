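"""Positional base-enrichment statistics and small normalisation formulas.

The enrichment score of base k at position i (relative to AUG) in a set of
sequences against a background set is the signed relative entropy

    E[i, k] = P_set[i, k] * log2(P_set[i, k] / P_back[i, k])

with the limit convention 0 * log(0/q) = 0.  Positive values mark
over-representation, negative under-representation.  Per-position
significance is a two-tailed Fisher exact test on the (base k vs not-k) x
(set vs background) table, uncorrected, with alpha = 0.05 used only for
display classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sequences import UtrSequence

BASES = ("A", "C", "G", "T")


def window_positions(lo: int, hi: int) -> list[int]:
    """Inclusive AUG-relative position range, skipping the nonexistent 0."""
    if lo > hi:
        raise ValueError("window lower bound exceeds upper bound")
    return [i for i in range(lo, hi + 1) if i != 0]


@dataclass
class PositionBaseCounts:
    """Per-position base counts over a window for one sequence set."""

    positions: list[int]
    counts: pd.DataFrame  # index positions, columns BASES
    coverage: pd.Series   # index positions

    @property
    def probabilities(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore"):
            p = self.counts.div(self.coverage, axis=0)
        return p


def count_bases(seqs: list[UtrSequence], window: tuple[int, int]) -> PositionBaseCounts:
    """Count A/C/G/T occurrences at each AUG-relative window position.

    Sequences too short to cover a position contribute nothing there; N
    bases are excluded from both counts and coverage, preserving the
    invariant sum_k counts[i, k] = coverage[i].
    """
    positions = window_positions(*window)
    counts = pd.DataFrame(0, index=positions, columns=list(BASES))
    coverage = pd.Series(0, index=positions)
    for s in seqs:
        for pos in positions:
            b = s.base_at(pos)
            if b in BASES:
                counts.loc[pos, b] += 1
                coverage.loc[pos] += 1
    return PositionBaseCounts(positions=positions, counts=counts, coverage=coverage)


def base_probabilities(
    seqs: list[UtrSequence], window: tuple[int, int]
) -> pd.DataFrame:
    """P[i, k] = counts[i, k] / coverage[i]; NaN rows flag zero coverage."""
    return count_bases(seqs, window).probabilities


def relative_entropy(p_set: pd.DataFrame, p_back: pd.DataFrame) -> pd.DataFrame:
    """Signed relative entropy matrix E = P_set * log2(P_set / P_back).

    E = 0 wherever P_set = 0 (limit convention); P_back = 0 with
    P_set > 0 yields +inf, reported rather than raised.
    """
    ps = np.asarray(p_set, dtype=float)
    pb = np.asarray(p_back, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = ps * np.log2(ps / pb)
    e = np.where(ps == 0, 0.0, e)
    if isinstance(p_set, pd.DataFrame):
        return pd.DataFrame(e, index=p_set.index, columns=p_set.columns)
    return e


def position_significance(
    counts_set: PositionBaseCounts, counts_back: PositionBaseCounts
) -> pd.DataFrame:
    """Two-tailed Fisher exact p-value per (position, base).

    Table per cell: [[set_k, set_not_k], [back_k, back_not_k]].  A table
    with a zero margin yields p = 1.
    """
    p = pd.DataFrame(1.0, index=counts_set.positions, columns=list(BASES))
    for pos in counts_set.positions:
        n_set = int(counts_set.coverage.loc[pos])
        n_back = int(counts_back.coverage.loc[pos])
        for k in BASES:
            a = int(counts_set.counts.loc[pos, k])
            c = int(counts_back.counts.loc[pos, k])
            table = [[a, n_set - a], [c, n_back - c]]
            p.loc[pos, k] = stats.fisher_exact(table, alternative="two-sided")[1]
    return p


@dataclass
class EnrichmentMatrix:
    """Relative entropy + significance for a set vs its background."""

    E: pd.DataFrame
    p: pd.DataFrame
    p_set: pd.DataFrame
    p_back: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        return self.p < self.alpha

    def to_frame(self) -> pd.DataFrame:
        """Long-format (position, base, E, p, significant) table."""
        rows = []
        for pos in self.E.index:
            for k in self.E.columns:
                rows.append(
                    {
                        "position": pos,
                        "base": k,
                        "E": self.E.loc[pos, k],
                        "p": self.p.loc[pos, k],
                        "significant": bool(self.p.loc[pos, k] < self.alpha),
                    }
                )
        return pd.DataFrame(rows)


def enrich(
    set_seqs: list[UtrSequence],
    background_seqs: list[UtrSequence],
    window: tuple[int, int] = (-30, 10),
) -> EnrichmentMatrix:
    """Full positional enrichment of a sequence set against its background.

    The background is the complement of the set (all other sequences),
    recomputed per group by the caller.
    """
    cs = count_bases(set_seqs, window)
    cb = count_bases(background_seqs, window)
    return EnrichmentMatrix(
        E=relative_entropy(cs.probabilities, cb.probabilities),
        p=position_significance(cs, cb),
        p_set=cs.probabilities,
        p_back=cb.probabilities,
    )


@dataclass
class BinFractionResult:
    bin_fractions: list[float]
    bin_counts: list[int]
    spearman_rho: float | None
    spearman_p: float | None
    degenerate: bool = False


def polya_fraction_vs_ratio(
    ratios: np.ndarray, has_property: np.ndarray, n_bins: int = 5
) -> BinFractionResult:
    """Fraction of genes with a poly(A) property across translation-
    efficiency bins.

    Genes are sorted by the protein/mRNA ratio and split into ``n_bins``
    equal-count groups (sizes differ by at most 1); the Spearman rank
    correlation relates bin index to per-bin fraction.  A constant
    fraction profile (e.g. every gene has the property) leaves the
    correlation undefined and is flagged instead of raised.
    """
    ratios = np.asarray(ratios, dtype=float)
    has_property = np.asarray(has_property)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if ratios.size != has_property.size:
        raise ValueError("ratios and flags differ in length")
    if np.unique(ratios).size == 1:
        raise ValueError("all ratios identical: cannot form bins")
    order = np.argsort(ratios, kind="stable")
    groups = np.array_split(has_property[order], n_bins)
    fractions = [float(np.mean(g)) for g in groups]
    counts = [len(g) for g in groups]
    if len(set(fractions)) == 1:
        return BinFractionResult(fractions, counts, None, None, degenerate=True)
    rho, pval = stats.spearmanr(np.arange(n_bins), fractions)
    return BinFractionResult(fractions, counts, float(rho), float(pval))


def relative_abundance(gfp: float, mcherry: float, reference_ratio: float) -> float:
    """Dual-reporter normalisation: (GFP / mCherry) / reference ratio.

    The reference ratio is the GFP/mCherry value of the designated
    reference UTR, which thereby maps to 1.
    """
    if mcherry <= 0 or reference_ratio <= 0:
        raise ValueError("mcherry and reference_ratio must be positive")
    return (gfp / mcherry) / reference_ratio


def relative_mrna_level(ct_target: float, ct_ref: float) -> float:
    """qPCR relative quantification: 2 ** -(Ct_target - Ct_reference)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_ref)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** -(ct_target - ct_ref))
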