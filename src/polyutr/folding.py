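"""Minimum-free-energy folding backends.

The default backend is a deterministic dynamic program over pseudoknot-free
secondary structures with a base-pair stacking energy model: energy accrues
only on helix steps, i.e. a pair (i, j) stacked directly on (i+1, j-1)
contributes the mean of the two pairs' strengths (GC -3, AT -1, GT wobble
-0.5 kcal/mol); isolated pairs contribute nothing, and hairpin loops must
enclose at least 3 unpaired bases.  Scoring stacks rather than pairs
mirrors how nearest-neighbour thermodynamics assigns stability and makes
the minimum depend on composition, not just length.  The model is
intentionally simple and self-contained; it ranks structures consistently
but its absolute energies are not comparable to full nearest-neighbour
thermodynamic packages.  External thermodynamic predictors (RNAfold) can
be plugged in behind the same callable contract.

N is unpairable, so an all-N or all-A sequence folds to 0.0.
"""

from __future__ import annotations

import shutil
import subprocess
from typing import Callable, Protocol

import numpy as np
from numba import njit

MIN_HAIRPIN = 3

# base encoding: A=0 C=1 G=2 T=3 N=4
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

_PAIR_ENERGY = np.full((5, 5), 0.0)
for _a, _b, _e in [("G", "C", -3.0), ("A", "T", -1.0), ("G", "T", -0.5)]:
    _PAIR_ENERGY[_ENC[_a], _ENC[_b]] = _e
    _PAIR_ENERGY[_ENC[_b], _ENC[_a]] = _e

_CAN_PAIR = _PAIR_ENERGY < 0.0

INF = 1e9


@njit(cache=True)
def _mfe_dp(code: np.ndarray, pair_e: np.ndarray, can_pair: np.ndarray) -> float:
    n = code.shape[0]
    if n < MIN_HAIRPIN + 2:
        return 0.0
    W = np.zeros((n, n))       # min energy of segment [i, j]
    Wn = np.zeros((n, n))      # same, but i and j not paired with each other
    V = np.full((n, n), INF)   # min energy given (i, j) paired
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            if can_pair[code[i], code[j]]:
                # energy accrues only when (i, j) stacks on (i+1, j-1)
                interior = Wn[i + 1, j - 1]
                if V[i + 1, j - 1] < INF:
                    step = 0.5 * (
                        pair_e[code[i], code[j]]
                        + pair_e[code[i + 1], code[j - 1]]
                    )
                    stacked = V[i + 1, j - 1] + step
                    if stacked < interior:
                        interior = stacked
                V[i, j] = interior
            best = W[i + 1, j]
            if W[i, j - 1] < best:
                best = W[i, j - 1]
            for k in range(i, j):
                split = W[i, k] + W[k + 1, j]
                if split < best:
                    best = split
            Wn[i, j] = best
            W[i, j] = best if best < V[i, j] else V[i, j]
    return W[0, n - 1]


def encode(seq: str) -> np.ndarray:
    return np.array([_ENC[b] for b in seq], dtype=np.int8)


def builtin_mfe(seq: str) -> float:
    """MFE (kcal/mol, <= 0) of ``seq`` under the built-in stacking model."""
    if not seq:
        return 0.0
    e = float(_mfe_dp(encode(seq), _PAIR_ENERGY, _CAN_PAIR))
    return min(e, 0.0)


class FoldingBackend(Protocol):
    def __call__(self, seq: str) -> float: ...


class ViennaRnaBackend:
    """MFE via the RNAfold command-line tool (nearest-neighbour model).

    Useful as an external cross-check; absolute values differ from the
    built-in model, as any two energy models do.
    """

    def __init__(self, executable: str = "RNAfold") -> None:
        if shutil.which(executable) is None:
            raise RuntimeError(f"{executable} not found on PATH")
        self.executable = executable

    def __call__(self, seq: str) -> float:
        out = subprocess.run(
            [self.executable, "--noPS"],
            input=seq + "\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout
        # last line: "....structure.... ( -1.20)"
        tail = out.strip().splitlines()[-1]
        return float(tail[tail.rindex("(") + 1 : tail.rindex(")")])


def get_backend(name: str = "builtin") -> Callable[[str], float]:
    if name == "builtin":
        return builtin_mfe
    if name in ("vienna", "rnafold", "external"):
        return ViennaRnaBackend()
    raise ValueError(f"unknown folding backend {name!r}")
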