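"""Nested RNA secondary structure by maximum base pairing.

The folder maximises the number of A-U / G-C / G-U pairs in a
pseudoknot-free structure with a minimum hairpin loop of 3 nt, via the
classic interval dynamic programme. Maximum-pairing (rather than a
thermodynamic energy model) keeps the output exactly reproducible and
testable against a brute-force recursion; a thermodynamic backend can be
substituted behind the same :class:`FoldResult` contract.

Traceback is deterministic: at each interval the 5'-most position is
paired whenever a co-optimal structure allows it, with the outermost
(largest-index) partner preferred, so stems are extended toward the
5' end before positions are left unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import as_dna, encode

MIN_LOOP = 3
MAX_FOLD_LEN = 400

# pair lookup over codes A=0, C=1, G=2, T/U=3: WC plus G-U wobble
_PAIR = np.zeros((4, 4), dtype=np.bool_)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _PAIR[_a, _b] = True

try:
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=True)(func)

except ImportError:  # pragma: no cover - numba is a hard dependency
    def _jit(func):
        return func


def _nussinov_table(codes, pair, min_loop):
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int16)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if pair[codes[i], codes[k]]:
                    left = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = dp[k + 1, j] if k + 1 <= j else 0
                    cand = left + right + 1
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


_nussinov_table = _jit(_nussinov_table)


@dataclass(frozen=True)
class FoldResult:
    """A nested structure: dot-bracket string plus a partner table."""

    sequence: str
    structure: str
    pairs: np.ndarray  # partner index per position, -1 if unpaired

    @property
    def n_pairs(self) -> int:
        return int((self.pairs >= 0).sum()) // 2

    def partner(self, i: int) -> int:
        return int(self.pairs[i])


def _traceback(codes: np.ndarray, dp: np.ndarray) -> np.ndarray:
    n = codes.shape[0]
    partner = np.full(n, -1, dtype=np.int32)
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < MIN_LOOP + 1:
            continue
        target = dp[i, j]
        if target == 0:
            continue
        paired = False
        for k in range(j, i + MIN_LOOP, -1):
            if _PAIR[codes[i], codes[k]]:
                left = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                right = dp[k + 1, j] if k + 1 <= j else 0
                if left + right + 1 == target:
                    partner[i] = k
                    partner[k] = i
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return partner


def fold(sequence: str, *, max_len: int = MAX_FOLD_LEN) -> FoldResult:
    """Fold a sequence into its maximum-base-pair nested structure.

    Accepts ACGU or ACGT spelling. Raises ``ValueError`` on other
    characters or on sequences longer than ``max_len``.
    """
    seq = as_dna(sequence)
    if len(seq) > max_len:
        raise ValueError(f"sequence longer than {max_len} nt")
    codes = encode(seq)
    if (codes < 0).any():
        bad = sorted({c for c in seq if c not in "ACGT"})
        raise ValueError(f"invalid characters in sequence: {bad}")
    if len(seq) == 0:
        return FoldResult("", "", np.empty(0, dtype=np.int32))
    dp = _nussinov_table(codes, _PAIR, MIN_LOOP)
    partner = _traceback(codes, dp)
    chars = np.full(len(seq), ".", dtype="<U1")
    chars[(partner >= 0) & (np.arange(len(seq)) < partner)] = "("
    chars[(partner >= 0) & (np.arange(len(seq)) > partner)] = ")"
    return FoldResult(seq, "".join(chars), partner)
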