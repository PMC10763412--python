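"""Core 5' UTR sequence primitives.

A 5' UTR is represented together with an optional prefix of the downstream
open reading frame (the first <=50 nt of coding sequence, starting at the A
of the start codon).  Coordinates inside the UTR are 0-based, half-open.
Positions relative to the start codon are negative integers, with -1 the
base immediately 5' of AUG; positive positions index into the ORF prefix
(+1 is the A of AUG).  No position 0 exists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

_VALID_BASES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def normalize_sequence(seq: str, *, allow_empty: bool = False) -> str:
    """Upper-case a nucleotide string and map RNA U to DNA T.

    Raises ``ValueError`` on characters outside {A, C, G, T, U, N}.
    """
    s = seq.strip().upper().replace("U", "T")
    if not s and not allow_empty:
        raise ValueError("empty sequence")
    bad = set(s) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid bases {sorted(bad)} in sequence")
    return s


@dataclass(frozen=True)
class UtrSequence:
    """A named 5' UTR with an optional ORF prefix.

    Parameters
    ----------
    id : str
        Record label.
    seq : str
        The UTR sequence over {A, C, G, T, N}.  RNA input (U) and lower
        case are normalised on construction.
    orf_prefix : str
        Up to 50 nt of coding sequence including the start codon.  Longer
        prefixes are accepted and truncated by the folding stage.
    """

    id: str
    seq: str
    orf_prefix: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_sequence(self.seq))
        object.__setattr__(
            self, "orf_prefix", normalize_sequence(self.orf_prefix, allow_empty=True)
        )

    def __len__(self) -> int:
        return len(self.seq)

    def base_at(self, pos: int) -> str | None:
        """Base at an AUG-relative position, or None if not covered.

        Negative positions index the UTR from its 3' end (-1 = last base);
        positive positions index the ORF prefix (+1 = first base of AUG).
        """
        if pos == 0:
            raise ValueError("position 0 does not exist in AUG-relative coordinates")
        if pos < 0:
            idx = len(self.seq) + pos
            return self.seq[idx] if idx >= 0 else None
        idx = pos - 1
        return self.orf_prefix[idx] if idx < len(self.orf_prefix) else None


@dataclass(frozen=True)
class PolyATract:
    """A maximal adenine run inside a UTR.

    ``distance_to_aug`` is measured from the tract's 3' end to the start
    codon by default (the convention used throughout the package; see
    :func:`longest_polya` for the switch).
    """

    start: int
    end: int
    distance_to_aug: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _as_seq(utr: UtrSequence | str) -> str:
    return utr.seq if isinstance(utr, UtrSequence) else normalize_sequence(utr)


def _iter_a_runs(seq: str) -> Iterator[tuple[int, int]]:
    for m in re.finditer(r"A+", seq):
        yield m.start(), m.end()


def find_polya_tracts(utr: UtrSequence | str, min_len: int = 5) -> list[PolyATract]:
    """All maximal A-runs of length >= ``min_len``, ordered 5' to 3'.

    N never extends a run.  An empty result means no qualifying run.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = _as_seq(utr)
    n = len(seq)
    return [
        PolyATract(start=s, end=e, distance_to_aug=n - e)
        for s, e in _iter_a_runs(seq)
        if e - s >= min_len
    ]


def longest_polya(
    utr: UtrSequence | str,
    min_len: int = 1,
    tie: str = "three_prime",
    distance_ref: str = "three_prime",
) -> PolyATract | None:
    """The longest A-run, or None when the sequence contains no adenine.

    Length ties are broken toward the 3'-most tract by default (the tract
    closest to AUG), ``tie="five_prime"`` selects the 5'-most instead.
    ``distance_ref`` switches the distance convention between the tract's
    3' end (default) and its 5' end.
    """
    if tie not in ("three_prime", "five_prime"):
        raise ValueError("tie must be 'three_prime' or 'five_prime'")
    if distance_ref not in ("three_prime", "five_prime"):
        raise ValueError("distance_ref must be 'three_prime' or 'five_prime'")
    tracts = find_polya_tracts(utr, min_len=min_len)
    if not tracts:
        return None
    best_len = max(t.length for t in tracts)
    candidates = [t for t in tracts if t.length == best_len]
    chosen = candidates[-1] if tie == "three_prime" else candidates[0]
    if distance_ref == "five_prime":
        seq = _as_seq(utr)
        chosen = PolyATract(
            start=chosen.start, end=chosen.end, distance_to_aug=len(seq) - chosen.start
        )
    return chosen


def count_oof_uaug(utr: UtrSequence | str, strategy: str = "combined") -> int:
    """Count out-of-frame upstream AUGs and upstream ORFs.

    The main-ORF AUG sits immediately after the UTR, so an ATG starting at
    index ``p`` is out of frame iff ``(len(seq) - p) % 3 != 0``.  An ATG in
    any frame that reaches an in-frame stop codon entirely inside the UTR
    closes an upstream ORF.  Under the default ``"combined"`` strategy an
    ATG qualifying on both grounds counts once.  ``"oof_only"`` and
    ``"uorf_only"`` expose the individual criteria.
    """
    if strategy not in ("combined", "oof_only", "uorf_only"):
        raise ValueError(f"unknown strategy {strategy!r}")
    seq = _as_seq(utr)
    n = len(seq)
    count = 0
    for p in range(n - 2):
        if seq[p : p + 3] != "ATG":
            continue
        out_of_frame = (n - p) % 3 != 0
        has_uorf_stop = any(
            seq[q : q + 3] in STOP_CODONS for q in range(p + 3, n - 2, 3)
        )
        if strategy == "oof_only":
            qualifies = out_of_frame
        elif strategy == "uorf_only":
            qualifies = has_uorf_stop
        else:
            qualifies = out_of_frame or has_uorf_stop
        count += int(qualifies)
    return count


def _parse_motif(motif: str) -> list[frozenset[str]]:
    """Parse a motif string into per-position allowed-base sets.

    ``"CC"`` -> two positions; ``"A/G"`` -> one position matching A or G.
    """
    tokens = re.findall(r"[ACGTU](?:/[ACGTU])+|[ACGTU]", motif.upper())
    if "".join(tokens).replace("/", "") != motif.upper().replace("/", ""):
        raise ValueError(f"cannot parse motif {motif!r}")
    return [
        frozenset(b.replace("U", "T") for b in tok.split("/")) for tok in tokens
    ]


def positional_motif(
    utr: UtrSequence | str, motif: str, positions: Sequence[int]
) -> int:
    """1 iff ``motif`` occupies the given AUG-relative positions exactly.

    Positions are negative (upstream of AUG, -1 immediately 5' of it).
    A sequence too short to cover the window yields 0.  Degenerate motif
    tokens such as "A/G" match either base; N never matches.
    """
    allowed = _parse_motif(motif)
    if len(allowed) != len(positions):
        raise ValueError("motif length does not match number of positions")
    if any(p >= 0 for p in positions):
        raise ValueError("positional motifs are defined at negative positions")
    seq = _as_seq(utr)
    n = len(seq)
    for sets, pos in zip(allowed, positions):
        idx = n + pos
        if idx < 0 or seq[idx] not in sets:
            return 0
    return 1


def contains_motif(utr: UtrSequence | str, motif: str) -> int:
    """1 iff ``motif`` occurs as an exact substring anywhere in the UTR."""
    allowed = _parse_motif(motif)
    if any(len(s) > 1 for s in allowed):
        raise ValueError("contains_motif takes a non-degenerate motif")
    return int("".join(next(iter(s)) for s in allowed) in _as_seq(utr))
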