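"""Independent brute-force oracles used to pin the semantics of the
implementation. Everything here is coded from the operation definitions
directly, without importing the implementation modules under test."""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# Fuzzy-matching oracle: normalization, token sort, Ratcliff/Obershelp
# matching blocks by explicit recursion, and exhaustive window enumeration.
# ---------------------------------------------------------------------------

def oracle_normalize(s: str) -> str:
    out = []
    for ch in s.lower():
        out.append(ch if ch.isascii() and ch.isalnum() else " ")
    return " ".join("".join(out).split())


def oracle_token_sort(s: str) -> str:
    return " ".join(sorted(s.split()))


def _longest_match(a: str, b: str) -> tuple[int, int, int]:
    """Earliest-longest common substring (i, j, size); brute force."""
    best = (0, 0, 0)
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            if k > best[2]:
                best = (i, j, k)
    return best


def _greedy_matched(a: str, b: str) -> int:
    i, j, k = _longest_match(a, b)
    if k == 0:
        return 0
    return (
        k
        + _greedy_matched(a[:i], b[:j])
        + _greedy_matched(a[i + k :], b[j + k :])
    )


def _matched_length(a: str, b: str) -> int:
    # the greedy recursion is order-dependent under ties; the ratio is
    # defined on the unordered pair as the larger of the two orders
    return max(_greedy_matched(a, b), _greedy_matched(b, a))


def oracle_similarity(a: str, b: str) -> int:
    if not a and not b:
        return 100
    if not a or not b:
        return 0
    m = _matched_length(a, b)
    return int(math.floor(200.0 * m / (len(a) + len(b)) + 0.5))


def oracle_partial(a: str, b: str) -> int:
    if len(a) > len(b):
        a, b = b, a
    if not a and not b:
        return 100
    if not a:
        return 0
    windows = [b[i : i + len(a)] for i in range(len(b) - len(a) + 1)]
    windows.append(b)
    return max(oracle_similarity(a, w) for w in windows)


def oracle_ptsr(a: str, b: str) -> int:
    return oracle_partial(
        oracle_token_sort(oracle_normalize(a)), oracle_token_sort(oracle_normalize(b))
    )


# ---------------------------------------------------------------------------
# Sift oracle: literal evaluation of the five filter definitions for one
# product over a pool of reference foods. Profiles are plain dicts here.
# ---------------------------------------------------------------------------

CALORIC = ("carbohydrate", "protein", "total_fat", "fiber", "saturated_fat", "sugar")
MACRO = ("carbohydrate", "protein", "total_fat")
SECONDARY = ("fiber", "saturated_fat", "sugar")


def _pct_of_calories(grams, nutrient, energy, factors):
    return 100.0 * grams * factors[nutrient] / energy


def _nutrients_ok(product, food, nutrients, threshold, factors):
    if math.isinf(threshold):
        return True
    if food.get("energy") is None or food["energy"] <= 0:
        return False
    for n in nutrients:
        pg, fg = product.get(n), food.get(n)
        if pg is None or fg is None:
            return False
        diff = abs(
            _pct_of_calories(pg, n, product["energy"], factors)
            - _pct_of_calories(fg, n, food["energy"], factors)
        )
        if not diff < threshold:
            return False
    return True


def oracle_sift(product, pool, params, factors):
    """Return the surviving food ids, evaluating each filter literally.

    ``product``/``pool`` entries are dicts with nutrient fields plus
    ``name`` (and ``id``/``group`` for pool foods); ``params`` is a dict
    with macro/secondary/sodium thresholds, min_fuzzy_score, use_min_fuzzy,
    use_fuzzy_optimization.
    """
    survivors = [f for f in pool if f["group"] == product["group"]]
    survivors = [
        f
        for f in survivors
        if _nutrients_ok(product, f, MACRO, params["macro"], factors)
    ]
    survivors = [
        f
        for f in survivors
        if _nutrients_ok(product, f, SECONDARY, params["secondary"], factors)
    ]
    if not math.isinf(params["sodium"]):
        ps = product.get("sodium")
        if ps is not None and ps > 0:
            kept = []
            for f in survivors:
                fs = f.get("sodium")
                if fs is not None and abs(ps - fs) / ps < params["sodium"]:
                    kept.append(f)
            survivors = kept
    scores = {f["id"]: oracle_ptsr(product["name"], f["name"]) for f in survivors}
    if params["use_min_fuzzy"]:
        survivors = [f for f in survivors if scores[f["id"]] >= params["min_fuzzy_score"]]
    if params["use_fuzzy_optimization"] and survivors:
        best = max(scores[f["id"]] for f in survivors)
        survivors = [f for f in survivors if scores[f["id"]] == best]
    return {f["id"] for f in survivors}
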