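"""Independent oracles used by the test suite.

The local-alignment oracle scores every pair of substrings with a
plain-recursion global affine-gap alignment and takes the maximum (clamped
at zero), which covers every possible local alignment.  It shares no code
with the alignment path under test.
"""

from __future__ import annotations

import math
from functools import lru_cache

_START, _MATCH, _GAP_IN_S, _GAP_IN_Q = 0, 1, 2, 3
_NEG = -math.inf


def global_affine_score(q: str, s: str, matrix, gap_open: int, gap_extend: int) -> float:
    """Best global alignment score of q vs s with affine gaps.

    A gap of length k costs gap_open + k * gap_extend.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: int) -> float:
        """Best score aligning q[:i] with s[:j] whose final column is `last`."""
        if last == _START:
            return 0.0 if i == 0 and j == 0 else _NEG
        if last == _MATCH:
            if i == 0 or j == 0:
                return _NEG
            prev = max(best(i - 1, j - 1, st) for st in range(4))
            return prev + float(matrix[q[i - 1], s[j - 1]])
        if last == _GAP_IN_S:  # column consumes q[i-1] against a gap
            if i == 0:
                return _NEG
            stay = best(i - 1, j, _GAP_IN_S) - gap_extend
            open_ = (
                max(best(i - 1, j, st) for st in (_START, _MATCH, _GAP_IN_Q))
                - gap_open - gap_extend
            )
            return max(stay, open_)
        # _GAP_IN_Q: column consumes s[j-1] against a gap
        if j == 0:
            return _NEG
        stay = best(i, j - 1, _GAP_IN_Q) - gap_extend
        open_ = (
            max(best(i, j - 1, st) for st in (_START, _MATCH, _GAP_IN_S))
            - gap_open - gap_extend
        )
        return max(stay, open_)

    result = max(best(len(q), len(s), st) for st in range(4))
    best.cache_clear()
    return result


def brute_force_local_score(
    q: str, s: str, matrix, gap_open: int = 11, gap_extend: int = 1
) -> float:
    """Max over all substring pairs of the global affine score; >= 0."""
    top = 0.0
    for a in range(len(q)):
        for b in range(a + 1, len(q) + 1):
            for c in range(len(s)):
                for d in range(c + 1, len(s) + 1):
                    top = max(
                        top,
                        global_affine_score(q[a:b], s[c:d], matrix, gap_open, gap_extend),
                    )
    return top
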