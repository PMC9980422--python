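"""Fuzzy string similarity: the partial token sort ratio.

The matcher used to compare product names with reference-food names is the
*partial token sort ratio* on a 0-100 integer scale: both strings are
normalized, their tokens sorted, and the shorter token string is slid over
every window of the longer one, scoring each window with the
Ratcliff/Obershelp matching-blocks ratio and keeping the best.

The window enumeration here is exhaustive, which makes it the normative
definition rather than a heuristic approximation: mainstream fuzzy-matching
libraries use anchor heuristics that can differ between versions, while
exhaustive enumeration is version-proof and exact. Food names are short, so
the extra cost is negligible.
"""

from __future__ import annotations

import math
import re
from difflib import SequenceMatcher

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_text(s: str) -> str:
    """Lowercase, replace every non-alphanumeric run by a single space, strip."""
    return _NON_ALNUM.sub(" ", s.lower()).strip()


def token_sort(s: str) -> str:
    """Sort whitespace-separated tokens lexicographically and rejoin.

    Expects normalized input; sorting uses plain byte order (no locale).
    """
    return " ".join(sorted(s.split()))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _matched_length(a: str, b: str) -> int:
    """Total length of the Ratcliff/Obershelp matching-blocks decomposition.

    The greedy earliest-longest-block recursion is not symmetric in its
    arguments under ties, so the larger of the two orders is taken; this
    makes the ratio a well-defined function of the string *pair*.
    """
    m_ab = sum(
        block.size
        for block in SequenceMatcher(None, a, b, autojunk=False).get_matching_blocks()
    )
    m_ba = sum(
        block.size
        for block in SequenceMatcher(None, b, a, autojunk=False).get_matching_blocks()
    )
    return max(m_ab, m_ba)


def similarity_ratio(a: str, b: str) -> int:
    """Matching-blocks ratio of two normalized strings, 0-100 integer.

    Computes ``100 * 2M / (|a| + |b|)`` rounded half-up, where ``M`` is the
    total matching-blocks length. Both strings empty scores 100; exactly
    one empty scores 0.
    """
    if not a and not b:
        return 100
    if not a or not b:
        return 0
    return _round_half_up(200.0 * _matched_length(a, b) / (len(a) + len(b)))


def partial_ratio(a: str, b: str) -> int:
    """Best matching-blocks ratio of the shorter string against every
    same-length window of the longer string (and the full longer string).

    Symmetric in its arguments; expects normalized input.
    """
    if len(a) > len(b):
        a, b = b, a
    if not a and not b:
        return 100
    if not a:
        return 0
    best = similarity_ratio(a, b)
    n = len(a)
    for start in range(len(b) - n + 1):
        if best == 100:
            break
        score = similarity_ratio(a, b[start : start + n])
        if score > best:
            best = score
    return best


def partial_token_sort_ratio(a: str, b: str) -> int:
    """The full matcher: normalize, token-sort, then partial ratio.

    Accepts raw strings; the score is invariant under permutation of the
    whitespace-separated tokens of either argument, and reaches 100 whenever
    one token-sorted string occurs verbatim inside the other.
    """
    return partial_ratio(token_sort(normalize_text(a)), token_sort(normalize_text(b)))
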