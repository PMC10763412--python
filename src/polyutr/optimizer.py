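"""Model-guided poly(A) edit proposal and ranking.

The default edit policy encodes the optimisation rule that emerged from
the attribution analysis: tracts far from the start codon depress
abundance, tracts 10..30 nt upstream may help, so (a) every tract of >= 5
nt lying strictly more than 30 nt upstream of AUG is proposed for full
deletion, (b) the longest tract is proposed for shortening (down to 5 nt,
at most 5 variants), and (c) the longest tract is proposed for shifts to
distances 10/20/30 nt.  Deletions never touch tracts within 30 nt of AUG.

Every design records its edit list; replaying the list on the parent
reproduces the mutant exactly, and each proposal is re-extracted through
the feature stage to confirm the realised (length, distance) before it is
emitted (edits whose tract would merge with neighbouring adenines are
dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import features_dataframe
from .model import AbundanceRegressor
from .sequences import PolyATract, UtrSequence, find_polya_tracts, longest_polya


@dataclass(frozen=True)
class EditOp:
    kind: str                  # delete_tract | shorten_tract | shift_tract
    tract: PolyATract
    param: int | None = None   # target length (shorten) or new distance (shift)

    def __post_init__(self) -> None:
        if self.kind not in ("delete_tract", "shorten_tract", "shift_tract"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.kind == "shorten_tract" and (
            self.param is None or not 1 <= self.param < self.tract.length
        ):
            raise ValueError("shorten target must be in [1, tract length)")
        if self.kind == "shift_tract" and (self.param is None or self.param < 0):
            raise ValueError("shift needs a non-negative target distance")


@dataclass
class MutantDesign:
    parent_id: str
    seq: str
    edits: list[EditOp]
    predicted: float | None = None
    fold_change: float | None = None

    @property
    def name(self) -> str:
        if not self.edits:
            return f"{self.parent_id}|wt"
        tags = []
        for e in self.edits:
            tag = {"delete_tract": "del", "shorten_tract": "len", "shift_tract": "pos"}[
                e.kind
            ]
            tags.append(f"{tag}{e.tract.start}" + (f"_{e.param}" if e.param else ""))
        return f"{self.parent_id}|" + "+".join(tags)


def apply_edit(seq: str, edit: EditOp) -> str:
    """Apply one edit to a parent sequence (pure bookkeeping)."""
    t = edit.tract
    if seq[t.start : t.end] != "A" * t.length:
        raise ValueError("edit tract does not match the parent sequence")
    if edit.kind == "delete_tract":
        return seq[: t.start] + seq[t.end :]
    if edit.kind == "shorten_tract":
        # keep the 3' end fixed so the tract's distance to AUG is unchanged
        return seq[: t.start] + "A" * edit.param + seq[t.end :]
    # shift: remove the run, re-insert the same run at the target distance
    removed = seq[: t.start] + seq[t.end :]
    insert_at = len(removed) - edit.param
    if insert_at < 0:
        raise ValueError("target distance exceeds the edited sequence length")
    return removed[:insert_at] + "A" * t.length + removed[insert_at:]


def apply_edits(seq: str, edits: list[EditOp]) -> str:
    for e in edits:
        seq = apply_edit(seq, e)
    return seq


def propose_mutants(
    utr: UtrSequence,
    min_len: int = 5,
    delete_distance_threshold: int = 30,
    max_shorten_variants: int = 5,
    shift_targets: tuple[int, ...] = (10, 20, 30),
    validate: bool = True,
) -> list[MutantDesign]:
    """Enumerate unscored edit designs for one UTR under the default policy.

    With ``validate`` (default) each design is re-extracted and dropped if
    the realised longest-tract (length, distance) differs from the intent,
    e.g. when a shifted run would merge with adjacent adenines.
    """
    tracts = find_polya_tracts(utr, min_len=min_len)
    designs: list[MutantDesign] = []
    for t in tracts:
        if t.distance_to_aug > delete_distance_threshold:
            edit = EditOp("delete_tract", t)
            designs.append(
                MutantDesign(utr.id, apply_edit(utr.seq, edit), [edit])
            )
    main = longest_polya(utr, min_len=min_len)
    if main is not None:
        shorten_lengths = list(range(main.length - 1, min_len - 1, -1))
        for target in shorten_lengths[:max_shorten_variants]:
            edit = EditOp("shorten_tract", main, target)
            designs.append(MutantDesign(utr.id, apply_edit(utr.seq, edit), [edit]))
        for dist in shift_targets:
            if dist == main.distance_to_aug:
                continue
            if len(utr.seq) - main.length - dist < 0:
                continue
            edit = EditOp("shift_tract", main, dist)
            designs.append(MutantDesign(utr.id, apply_edit(utr.seq, edit), [edit]))
    if validate:
        designs = [d for d in designs if _realised_as_intended(d, utr, min_len)]
    return designs


def _realised_as_intended(
    design: MutantDesign, parent: UtrSequence, min_len: int
) -> bool:
    edit = design.edits[0]
    realised = longest_polya(design.seq, min_len=1)
    if edit.kind == "delete_tract":
        # the deleted run must be gone, not recreated by flanking adenines
        deleted_here = not any(
            t.start == edit.tract.start
            for t in find_polya_tracts(design.seq, min_len=min_len)
        )
        return deleted_here
    if realised is None:
        return False
    if edit.kind == "shorten_tract":
        return (
            realised.length == edit.param
            and realised.distance_to_aug == edit.tract.distance_to_aug
        ) or realised.length > edit.param  # another tract dominates: keep
    return (
        realised.length == edit.tract.length
        and realised.distance_to_aug == edit.param
    )


def score_mutants(
    model: AbundanceRegressor,
    designs: list[MutantDesign],
    parent: UtrSequence,
    backend=None,
) -> pd.DataFrame:
    """Predict abundance for designs + parent and rank by fold change.

    Returns a table (one row per design, descending fold change, stable
    for ties) including the parent at fold change 1.  The design objects
    are updated in place with predictions.
    """
    wild = MutantDesign(parent.id, parent.seq, [])
    all_designs = [wild] + list(designs)
    utrs = [
        UtrSequence(d.name, d.seq, parent.orf_prefix) for d in all_designs
    ]
    X = features_dataframe(utrs, backend=backend)
    preds = model.predict(X.to_numpy(dtype=float))
    parent_pred = float(preds[0])
    rows = []
    for d, p in zip(all_designs, preds):
        d.predicted = float(p)
        d.fold_change = float(p) / parent_pred
        rows.append(
            {
                "name": d.name,
                "parent_id": d.parent_id,
                "edit_kind": d.edits[0].kind if d.edits else "wild_type",
                "predicted": d.predicted,
                "fold_change": d.fold_change,
                "seq": d.seq,
            }
        )
    out = pd.DataFrame(rows)
    # secondary key on the design name keeps tied fold changes deterministic
    return out.sort_values(
        ["fold_change", "name"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
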