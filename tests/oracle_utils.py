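"""Independent brute-force oracles used by the test suite.

Deliberately written in a different style from the package implementation
(per-position scans over the full pair list, O(n^2)) so agreement is a real
cross-check of the loop-decomposition logic.
"""

from __future__ import annotations


def pairs_from_db(db: str) -> dict[int, int]:
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for i, ch in enumerate(db, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
    assert not stack
    return pairs


def oracle_kind(db: str, pos: int) -> str:
    """Substructure kind of 1-based ``pos`` by naive loop decomposition."""
    pairs = pairs_from_db(db)
    if pos in pairs:
        return "helix"
    # innermost enclosing pair
    enclosing = None
    for i, j in pairs.items():
        if i < j and i < pos < j:
            if enclosing is None or i > enclosing[0]:
                enclosing = (i, j)
    if enclosing is None:
        return "strand"
    a, b = enclosing

    def innermost(q: int):
        best = None
        for i, j in pairs.items():
            if i < j and i < q < j and (best is None or i > best[0]):
                best = (i, j)
        return best

    # children: pairs directly inside (a, b)
    children = [
        (i, j)
        for i, j in pairs.items()
        if i < j and a < i < j < b and innermost(i) == (a, b)
    ]
    unpaired = [q for q in range(a + 1, b) if q not in pairs and innermost(q) == (a, b)]
    n_close = 1 + len(children)
    if n_close == 1:
        return "hairpin"
    if n_close == 2:
        (c, d) = children[0]
        left = [q for q in unpaired if q < c]
        right = [q for q in unpaired if q > d]
        return "interior" if left and right else "bulge"
    return "junction"


def _min_hairpin_ok(db: str, min_hairpin: int = 3) -> bool:
    pairs = pairs_from_db(db)
    for i, j in pairs.items():
        if i < j and not any(i < k < j for k in pairs):
            if j - i - 1 < min_hairpin:
                return False
    return True


def enumerate_structures(max_len: int, min_hairpin: int = 3) -> list[str]:
    """All valid dot-bracket strings of length <= max_len (hairpins >= 3)."""
    out: list[str] = []

    def rec(prefix: list[str], n_open: int, remaining: int):
        if remaining == 0:
            if n_open == 0:
                db = "".join(prefix)
                if "(" in db and _min_hairpin_ok(db, min_hairpin):
                    out.append(db)
                elif "(" not in db:
                    out.append(db)
            return
        prefix.append(".")
        rec(prefix, n_open, remaining - 1)
        prefix.pop()
        if remaining > n_open:
            prefix.append("(")
            rec(prefix, n_open + 1, remaining - 1)
            prefix.pop()
        if n_open > 0:
            prefix.append(")")
            rec(prefix, n_open - 1, remaining - 1)
            prefix.pop()

    for length in range(1, max_len + 1):
        rec([], 0, length)
    return out
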