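"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's dynamic-programming /
vectorized code paths: structures are enumerated explicitly and maxima
taken over the enumeration.
"""

from __future__ import annotations

COMPLEMENTARY = {
    ("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")
}


def enumerate_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum base-pair count by exhaustive enumeration of all
    non-crossing structures (backtracking over candidate pairs)."""
    n = len(seq)
    candidates = [
        (i, j)
        for i in range(n)
        for j in range(i + min_loop + 1, n)
        if (seq[i], seq[j]) in COMPLEMENTARY
    ]

    best = 0

    def compatible(p, chosen):
        i, j = p
        for a, b in chosen:
            if len({i, j, a, b}) < 4:
                return False
            # crossing: a < i < b < j or i < a < j < b
            if a < i < b < j or i < a < j < b:
                return False
        return True

    def rec(start, chosen):
        nonlocal best
        best = max(best, len(chosen))
        for t in range(start, len(candidates)):
            p = candidates[t]
            if compatible(p, chosen):
                chosen.append(p)
                rec(t + 1, chosen)
                chosen.pop()

    rec(0, [])
    return best
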