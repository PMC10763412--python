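"""Checks against the published reporter-library dataset, when available.

The real mini-library measurements (241 natural 5' UTRs with 15 features
and relative GFP abundance) are distributed as journal supplementary
material and are not shipped with this package.  When a user supplies
that table in the canonical TSV schema, this module recomputes the
headline quantities from it: the 207/34 poly(A) composition, the
abundance range, and the repeated-split test R^2 with and without the
poly(A)-related features.
"""

from __future__ import annotations

from pathlib import Path

from .model import ablation_evaluation, repeated_evaluation
from .io import read_dataset_tsv

POLYA_MIN_LENGTH = 5
ABLATED_FEATURES = ("utr_length", "polya_length", "polya_position")


def reference_dataset_report(
    path: str | Path,
    n_splits: int = 5,
    seeds: list[int] | None = None,
) -> dict:
    """Recompute library composition, abundance range and model R^2."""
    ds = read_dataset_tsv(path)
    seeds = list(range(n_splits)) if seeds is None else seeds
    full = repeated_evaluation(ds, n_splits=n_splits, seeds=seeds)
    ablated = ablation_evaluation(
        ds, dropped=ABLATED_FEATURES, n_splits=n_splits, seeds=seeds
    )
    y = ds.y
    return {
        "n": ds.n,
        "n_polya": int((ds.X["polya_length"] >= POLYA_MIN_LENGTH).sum()),
        "n_control": int((ds.X["polya_length"] < POLYA_MIN_LENGTH).sum()),
        "abundance_min": float(y.min()),
        "abundance_max": float(y.max()),
        "abundance_fold_range": float(y.max() / y.min()),
        "mean_test_r2": full.mean_test_r2,
        "mean_test_r2_ablated": ablated.mean_test_r2,
    }
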