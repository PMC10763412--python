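"""The 15-feature representation of a 5' UTR.

Features, in canonical column order:

==============  =====================================================
utr_length      length of the UTR (nt)
oof_uaug        out-of-frame upstream AUGs + upstream ORFs (count)
mfe             minimum free energy of UTR + first 50 nt of ORF
polya_position  distance (nt) from the longest A-run's 3' end to AUG
polya_length    length (nt) of the longest A-run
cacc            >=1 CACC motif anywhere in the UTR
gaca            >=1 GACA motif anywhere
gg              >=1 GG motif anywhere
cc_m7m6         CC at positions [-7, -6]
aa_m3m2         AA at [-3, -2]
a_m1            A at [-1]
ag_m3           A or G at [-3]
t_m3            T at [-3]
ac_m2m1         AC at [-2, -1]
ca_m7m6         CA at [-7, -6]
==============  =====================================================

The longest A-run is taken with a minimum length of 1 so that UTRs without
a bona fide poly(A) tract (>=5 nt) still receive numeric features.  A UTR
with no adenine at all gets ``polya_length = 0`` and ``polya_position =
utr_length`` (maximally distant sentinel).
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .folding import builtin_mfe, get_backend
from .sequences import (
    UtrSequence,
    contains_motif,
    count_oof_uaug,
    longest_polya,
    positional_motif,
)

FEATURE_NAMES: tuple[str, ...] = (
    "utr_length",
    "oof_uaug",
    "mfe",
    "polya_position",
    "polya_length",
    "cacc",
    "gaca",
    "gg",
    "cc_m7m6",
    "aa_m3m2",
    "a_m1",
    "ag_m3",
    "t_m3",
    "ac_m2m1",
    "ca_m7m6",
)

#: motif feature -> (motif, AUG-relative positions); None positions = anywhere
MOTIF_DEFS: dict[str, tuple[str, tuple[int, ...] | None]] = {
    "cacc": ("CACC", None),
    "gaca": ("GACA", None),
    "gg": ("GG", None),
    "cc_m7m6": ("CC", (-7, -6)),
    "aa_m3m2": ("AA", (-3, -2)),
    "a_m1": ("A", (-1,)),
    "ag_m3": ("A/G", (-3,)),
    "t_m3": ("T", (-3,)),
    "ac_m2m1": ("AC", (-2, -1)),
    "ca_m7m6": ("CA", (-7, -6)),
}

ORF_PREFIX_LENGTH = 50


def compute_mfe(
    utr: UtrSequence, backend: Callable[[str], float] | str | None = None
) -> float:
    """MFE of the UTR concatenated with its ORF prefix (truncated at 50 nt)."""
    fold = (
        builtin_mfe
        if backend is None
        else get_backend(backend) if isinstance(backend, str) else backend
    )
    return fold(utr.seq + utr.orf_prefix[:ORF_PREFIX_LENGTH])


def extract_features(
    utr: UtrSequence,
    backend: Callable[[str], float] | str | None = None,
    uaug_strategy: str = "combined",
    tie: str = "three_prime",
    distance_ref: str = "three_prime",
) -> dict[str, float]:
    """Assemble the 15-feature vector for one UTR as an ordered dict."""
    tract = longest_polya(utr, min_len=1, tie=tie, distance_ref=distance_ref)
    feats: dict[str, float] = {
        "utr_length": float(len(utr.seq)),
        "oof_uaug": float(count_oof_uaug(utr, strategy=uaug_strategy)),
        "mfe": compute_mfe(utr, backend=backend),
        "polya_position": float(
            tract.distance_to_aug if tract is not None else len(utr.seq)
        ),
        "polya_length": float(tract.length if tract is not None else 0),
    }
    for name, (motif, positions) in MOTIF_DEFS.items():
        if positions is None:
            feats[name] = float(contains_motif(utr, motif))
        else:
            feats[name] = float(positional_motif(utr, motif, positions))
    return feats


def features_dataframe(
    utrs: Iterable[UtrSequence],
    backend: Callable[[str], float] | str | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Feature matrix (one row per UTR, canonical column order, id index)."""
    rows = {u.id: extract_features(u, backend=backend, **kwargs) for u in utrs}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df[list(FEATURE_NAMES)]


class UtrFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: list of UtrSequence -> 15-column matrix.

    Parameters mirror :func:`extract_features`.  ``transform`` returns a
    DataFrame so the pipeline keeps named columns.
    """

    def __init__(
        self,
        backend: str | None = None,
        uaug_strategy: str = "combined",
        tie: str = "three_prime",
        distance_ref: str = "three_prime",
    ) -> None:
        self.backend = backend
        self.uaug_strategy = uaug_strategy
        self.tie = tie
        self.distance_ref = distance_ref

    def fit(self, X: Iterable[UtrSequence], y=None) -> "UtrFeaturizer":
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X: Iterable[UtrSequence]) -> pd.DataFrame:
        return features_dataframe(
            X,
            backend=self.backend,
            uaug_strategy=self.uaug_strategy,
            tie=self.tie,
            distance_ref=self.distance_ref,
        )

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_NAMES, dtype=object)
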