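"""Synthetic 5' UTR libraries with planted structure and known response.

The generator emulates the study conditions of a natural-UTR reporter
library: 241 UTRs of 12..197 nt, 207 carrying a planted adenine tract of
5..23 nt (geometric-tailed lengths, distance-to-AUG mixture with a mode
near 20 nt) and 34 poly(A)-free controls, an A-rich yeast-like base
composition, planted out-of-frame upstream AUGs, and a shared 50-nt
GFP-like ORF prefix.  Sequences are rejection-sampled so that the planted
tract is exactly the longest adenine run and the planted upstream AUGs
are exactly the ATG occurrences, which makes the feature ground truth
available by construction.

The expected log2 abundance is defined on the features themselves:

    log2 y = b0 - b_len * utr_length/100 - b_oof * oof_uaug
             + b_mfe * mfe/10 - b_alen * max(0, polya_length - 4)
             + b_win * 1[10 <= polya_position <= 30] * min(polya_length, 8)

with multiplicative (log2-scale) Gaussian noise.  Effect directions encode
the qualitative biology the model is meant to recover: long UTRs, upstream
AUGs, stable secondary structure and long tracts depress abundance, while
a tract 10..30 nt upstream of the start codon helps weakly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, features_dataframe
from .model import Dataset
from .sequences import UtrSequence, find_polya_tracts, longest_polya

#: first 50 nt of a GFP-like coding sequence (synthetic constant; starts at ATG)
GFP_ORF_PREFIX = "ATGAGTAAAGGAGAAGAACTTTTCACTGGAGTTGTCCCAATTCTTGTTGA"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Theta:
    """Ground-truth response coefficients (log2-abundance units)."""

    b0: float = 0.0
    b_len: float = 1.0
    b_oof: float = 1.5
    b_mfe: float = 0.5
    b_alen: float = 0.15
    b_win: float = 0.1


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 241
    n_polya: int = 207
    length_range: tuple[int, int] = (12, 197)
    tract_length_min: int = 5
    tract_length_max: int = 23
    tract_length_p: float = 0.35       # geometric tail over the length range
    distance_mode: float = 20.0
    distance_sd: float = 5.0
    distance_uniform_frac: float = 0.5
    gc_range: tuple[float, float] = (0.20, 0.60)  # per-sequence GC content
    a_fraction_of_at: float = 0.58                # A-richness of the AT mass
    uaug_rate: float = 0.008           # planted out-of-frame ATGs per nt
    noise_sigma: float = 0.5           # log2-scale
    orf_prefix: str = GFP_ORF_PREFIX
    rejection_budget: int = 2000

    def __post_init__(self) -> None:
        if self.n_polya > self.n:
            raise ValueError("n_polya cannot exceed n")
        lo, hi = self.length_range
        if not 1 <= lo <= hi <= 199:
            raise ValueError("length range must sit within [1, 199]")
        g_lo, g_hi = self.gc_range
        if not 0 < g_lo <= g_hi < 1:
            raise ValueError("gc_range must sit within (0, 1)")

    def base_probs(self, gc: float) -> tuple[float, float, float, float]:
        """ACGT probabilities at a given GC content."""
        at = 1.0 - gc
        return (at * self.a_fraction_of_at, gc / 2, gc / 2,
                at * (1.0 - self.a_fraction_of_at))


def response_function(features, theta: Theta = Theta()) -> float:
    """Expected log2 abundance of one feature vector under the ground truth."""
    f = dict(features)
    in_window = 10 <= f["polya_position"] <= 30
    return (
        theta.b0
        - theta.b_len * f["utr_length"] / 100.0
        - theta.b_oof * f["oof_uaug"]
        + theta.b_mfe * f["mfe"] / 10.0
        - theta.b_alen * max(0.0, f["polya_length"] - 4.0)
        + theta.b_win * (min(f["polya_length"], 8.0) if in_window else 0.0)
    )


def _has_long_run(seq: str, min_len: int) -> bool:
    return "A" * min_len in seq


def _sample_tract_length(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    extra = int(rng.geometric(cfg.tract_length_p)) - 1
    return min(cfg.tract_length_min + extra, cfg.tract_length_max)


def _sample_distance(cfg: GeneratorConfig, rng, max_distance: int) -> int:
    if rng.random() >= cfg.distance_uniform_frac:
        d = int(round(rng.normal(cfg.distance_mode, cfg.distance_sd)))
    else:
        d = int(rng.integers(0, max_distance + 1))
    return int(np.clip(d, 0, max_distance))


def _plant_uaugs(
    seq: list[str], rng, rate: float, forbidden: range
) -> list[int] | None:
    """Overwrite k ~ Poisson(rate * L) out-of-frame ATGs; None if infeasible."""
    L = len(seq)
    k = int(rng.poisson(rate * L))
    if k == 0:
        return []
    eligible = [
        p
        for p in range(L - 2)
        if (L - p) % 3 != 0 and not (forbidden.start - 2 <= p <= forbidden.stop)
    ]
    rng.shuffle(eligible)
    chosen: list[int] = []
    for p in eligible:
        if all(abs(p - q) >= 3 for q in chosen):
            chosen.append(p)
        if len(chosen) == k:
            break
    if len(chosen) < k:
        return None
    for p in chosen:
        seq[p : p + 3] = list("ATG")
    return sorted(chosen)


def generate_utr(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    uid: str,
    has_polya: bool,
) -> tuple[UtrSequence, dict]:
    """One rejection-sampled UTR with its planted annotations.

    For poly(A) entries the planted tract is guaranteed to be the unique
    longest adenine run; for controls every run is < 5 nt.  ATG occurrences
    equal the planted out-of-frame upstream AUGs exactly, so the expected
    oof_uaug feature equals the planted count.
    """
    lo, hi = cfg.length_range
    min5 = cfg.tract_length_min
    for _ in range(cfg.rejection_budget):
        if has_polya:
            tract_len = _sample_tract_length(cfg, rng)
            L = int(rng.integers(max(lo, tract_len + 2), hi + 1))
            distance = _sample_distance(cfg, rng, L - tract_len)
            start = L - distance - tract_len
        else:
            tract_len, distance, start = 0, None, None
            L = int(rng.integers(lo, hi + 1))

        gc = float(rng.uniform(*cfg.gc_range))
        chars = list(rng.choice(_BASES, size=L, p=cfg.base_probs(gc)))
        if has_polya:
            chars[start : start + tract_len] = ["A"] * tract_len
            non_a = "CGT"
            if start > 0 and chars[start - 1] == "A":
                chars[start - 1] = non_a[rng.integers(3)]
            if start + tract_len < L and chars[start + tract_len] == "A":
                chars[start + tract_len] = non_a[rng.integers(3)]
            forbidden = range(start, start + tract_len)
        else:
            forbidden = range(0, 0)

        if "ATG" in "".join(chars):
            continue
        planted = _plant_uaugs(chars, rng, cfg.uaug_rate, forbidden)
        if planted is None:
            continue
        seq = "".join(chars)

        # verify the ATG inventory and the tract structure survived planting
        actual_atg = [p for p in range(L - 2) if seq[p : p + 3] == "ATG"]
        if actual_atg != planted:
            continue
        long_runs = find_polya_tracts(seq, min_len=min5)
        if has_polya:
            if len(long_runs) != 1:
                continue
            t = long_runs[0]
            if t.length != tract_len or t.distance_to_aug != distance:
                continue
        elif long_runs:
            continue
        run = longest_polya(seq, min_len=1)
        ann = {
            "id": uid,
            "has_polya": int(has_polya),
            "tract_length": run.length if run else 0,
            "tract_distance": run.distance_to_aug if run else L,
            "n_uaug": len(planted),
            "length": L,
        }
        return UtrSequence(uid, seq, cfg.orf_prefix), ann
    raise RuntimeError(
        f"rejection budget exhausted for {uid} "
        f"(has_polya={has_polya}); relax the generator constraints"
    )


@dataclass
class GroundTruth:
    theta: Theta
    response: np.ndarray            # expected log2 abundance per record
    annotations: pd.DataFrame       # planted tract/uAUG structure
    seed: int

    def to_dict(self) -> dict:
        return {
            "theta": asdict(self.theta),
            "seed": self.seed,
            "response": self.response.tolist(),
            "annotations": self.annotations.to_dict(orient="records"),
        }


def generate_library(
    cfg: GeneratorConfig = GeneratorConfig(), seed: int = 0
) -> tuple[list[UtrSequence], pd.DataFrame]:
    """The sequence tier only: n UTRs + planted-annotation table."""
    rng = np.random.default_rng(seed)
    utrs, anns = [], []
    for i in range(cfg.n):
        uid = f"UTR{i + 1:04d}"
        u, a = generate_utr(cfg, rng, uid, has_polya=i < cfg.n_polya)
        utrs.append(u)
        anns.append(a)
    return utrs, pd.DataFrame(anns)


def generate_dataset(
    cfg: GeneratorConfig = GeneratorConfig(),
    theta: Theta = Theta(),
    seed: int = 0,
) -> tuple[Dataset, GroundTruth]:
    """Full synthetic dataset: features, abundance, and ground truth.

    y = 2 ** (response(features) + eps), eps ~ Normal(0, noise_sigma^2).
    The emitted table matches the canonical dataset TSV schema (id, 15
    features, abundance).
    """
    seq_seed, noise_seed = np.random.SeedSequence(seed).spawn(2)
    utrs, anns = generate_library(cfg, seed=np.random.default_rng(seq_seed))
    X = features_dataframe(utrs)
    response = np.array(
        [response_function(row, theta) for _, row in X.iterrows()]
    )
    rng = np.random.default_rng(noise_seed)
    eps = (
        rng.normal(0.0, cfg.noise_sigma, size=len(response))
        if cfg.noise_sigma > 0
        else np.zeros(len(response))
    )
    y = np.power(2.0, response + eps)
    dataset = Dataset(
        X=X.reset_index(drop=True), y=y, ids=list(X.index.astype(str))
    )
    truth = GroundTruth(theta=theta, response=response, annotations=anns, seed=seed)
    return dataset, truth
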