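"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive and self-contained: dynamic-programming
edit distance (no alignment library), exhaustive anchor search over all
offsets and window lengths, and a literal trace of the stated collapse rule.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook O(len(a)*len(b)) edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def brute_force_find_anchor(seq: str, template) -> Optional[Tuple[int, int, str]]:
    """Exhaustive ladder search: all offsets, all window lengths, all edit
    scripts of cost <= 2 (via DP distance), replicating the documented
    tie-break (min distance, then leftmost, then window length nearest the
    anchor length, shorter first)."""
    anchor = template.upstream_anchor
    alen = len(anchor)
    lo = max(0, template.expected_anchor_offset - template.position_tolerance)
    hi = min(template.expected_anchor_offset + template.position_tolerance, len(seq) - alen)

    exact_hits = [s for s in range(lo, hi + 1) if seq[s : s + alen] == anchor]
    if exact_hits:
        s = min(exact_hits)
        return s, s + alen, "exact"

    candidates = []
    for s in range(lo, hi + 1):
        window = seq[s : s + alen]
        if len(window) == alen:
            d = hamming(window, anchor)
            if d <= template.max_anchor_hamming:
                candidates.append((d, s))
    if candidates:
        d, s = min(candidates)
        return s, s + alen, "hamming"

    cap = template.max_anchor_levenshtein
    lo3 = max(0, template.expected_anchor_offset - template.position_tolerance - cap)
    hi3 = min(
        template.expected_anchor_offset + template.position_tolerance + cap,
        len(seq) - (alen - cap),
    )
    best = None
    for s in range(lo3, hi3 + 1):
        for wlen in range(alen - cap, alen + cap + 1):
            window = seq[s : s + wlen]
            if len(window) < wlen:
                continue
            d = dp_levenshtein(anchor, window)
            if d <= cap:
                key = (d, s, abs(wlen - alen), wlen)
                if best is None or key < best[0]:
                    best = (key, s, s + wlen)
    if best is not None:
        return best[1], best[2], "levenshtein"
    return None


def brute_force_extract(seq: str, template) -> Optional[Tuple[str, str]]:
    """(barcode, stage) or None, via the exhaustive anchor search."""
    found = brute_force_find_anchor(seq, template)
    if found is None:
        return None
    _, end, stage = found
    bc = seq[end : end + template.barcode_length]
    if len(bc) < template.barcode_length or "N" in bc:
        return None
    down = seq[end + template.barcode_length : end + template.barcode_length + len(template.downstream_anchor)]
    if down != template.downstream_anchor:
        return None
    return bc, stage


def trace_collapse(totals: Dict[str, int]) -> Dict[str, str]:
    """Literal trace of the collapse rule: visit barcodes in decreasing total
    (ties lexicographic); merge into the highest-ranked finalized parent
    within DP Levenshtein distance 1, else become a parent."""
    order = sorted(totals, key=lambda bc: (-totals[bc], bc))
    parents: List[str] = []
    assignment: Dict[str, str] = {}
    for bc in order:
        within = [p for p in parents if dp_levenshtein(bc, p) <= 1]
        if within:
            # parents list is already in rank order; first hit is most abundant
            assignment[bc] = within[0]
        else:
            assignment[bc] = bc
            parents.append(bc)
    return assignment
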