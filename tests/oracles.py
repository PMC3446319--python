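"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic programs: structures are
enumerated exhaustively, alignments are enumerated window by window, and
degradome categories are recomputed with plain sorting, so agreement is a
genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import statistics

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "T"), ("T", "G")}
COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


# -- maximum base pairing by exhaustive enumeration of nested structures -----

def enumerate_structures(seq: str, i: int, j: int, min_loop: int = 3):
    """Yield every nested pair-set on seq[i..j] (inclusive, 0-based)."""
    if i >= j:
        yield frozenset()
        return
    # i unpaired
    for rest in enumerate_structures(seq, i + 1, j, min_loop):
        yield rest
    # i paired with k
    for k in range(i + min_loop + 1, j + 1):
        if (seq[i], seq[k]) in WC or (seq[i], seq[k]) in WOBBLE:
            for inner in enumerate_structures(seq, i + 1, k - 1, min_loop):
                for outer in enumerate_structures(seq, k + 1, j, min_loop):
                    yield inner | outer | {(i, k)}


def max_pairs_bruteforce(seq: str, min_loop: int = 3) -> int:
    return max(len(s) for s in enumerate_structures(seq, 0, len(seq) - 1, min_loop))


# -- target-alignment enumeration -------------------------------------------

def _col_penalty(m: str, t: str, pos: int, lo: int = 2, hi: int = 13) -> float:
    if (m, t) in WC:
        p = 0.0
    elif (m, t) in WOBBLE:
        p = 0.5
    else:
        p = 1.0
    return p * 2 if lo <= pos <= hi else p


def _bulge_penalty(pos: int, lo: int = 2, hi: int = 13) -> float:
    return 2.0 if lo <= pos <= hi else 1.0


def enumerate_alignments(mirna: str, transcript: str, max_bulges: int = 1):
    """Yield (site_start, site_end, score) for every alignment, 1-based.

    miRNA position 1 pairs the site's 3'-most nucleotide. With one bulge
    allowed: a miRNA bulge at an internal position k skips one miRNA base
    (site is one shorter); a target bulge after miRNA position k inserts
    one unpaired site base (site is one longer). Terminal columns are
    always paired.
    """
    q, t = mirna.upper().replace("U", "T"), transcript.upper().replace("U", "T")
    L, n = len(q), len(t)
    for t3 in range(L, n + 1):  # gapless
        score = sum(_col_penalty(q[p - 1], t[t3 - p], p) for p in range(1, L + 1))
        yield (t3 - L + 1, t3, score)
    if max_bulges < 1:
        return
    for t3 in range(L - 1, n + 1):  # one miRNA bulge at internal position k
        for k in range(2, L):
            score = _bulge_penalty(k)
            ti = t3
            for p in range(1, L + 1):
                if p == k:
                    continue
                score += _col_penalty(q[p - 1], t[ti - 1], p)
                ti -= 1
            if ti >= 0 and t3 - (L - 1) + 1 >= 1:
                yield (t3 - (L - 1) + 1, t3, score)
    for t3 in range(L + 1, n + 1):  # one target bulge after miRNA position k
        for k in range(1, L):
            score = _bulge_penalty(k)
            ti = t3
            ok = True
            for p in range(1, L + 1):
                score += _col_penalty(q[p - 1], t[ti - 1], p)
                ti -= 1
                if p == k:
                    ti -= 1  # the inserted, unpaired site base
            if t3 - (L + 1) + 1 >= 1:
                yield (t3 - (L + 1) + 1, t3, score)


def best_scores_by_interval(mirna: str, transcript: str,
                            max_bulges: int = 1) -> dict[tuple[int, int], float]:
    best: dict[tuple[int, int], float] = {}
    for start, end, score in enumerate_alignments(mirna, transcript, max_bulges):
        if start < 1:
            continue
        iv = (start, end)
        if iv not in best or score < best[iv]:
            best[iv] = score
    return best


# -- degradome category by plain sorting -------------------------------------

def categorize_bruteforce(abundance, position: int) -> int | None:
    x = abundance[position - 1]
    if x == 0:
        return None
    if x == 1:
        return 4
    occupied = sorted(v for v in abundance if v > 0)
    mx = occupied[-1]
    med = statistics.median(occupied)
    if x == mx:
        return 0 if occupied.count(mx) == 1 else 1
    return 2 if x > med else 3
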