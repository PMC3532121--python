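"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in the plainest possible style and
shares no code with the package internals.
"""

from __future__ import annotations

from itertools import combinations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_STOPS = {"TAA", "TAG", "TGA"}

_CODE = {}


def _build_code():
    aas = (
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    )
    b = "TCAG"
    i = 0
    for x in b:
        for y in b:
            for z in b:
                _CODE[x + y + z] = aas[i]
                i += 1


_build_code()


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def translate(nt: str) -> str:
    out = []
    for i in range(0, len(nt) - 2, 3):
        c = nt[i : i + 3]
        out.append("X" if "N" in c else _CODE[c])
    if out:
        out[0] = "M"
    return "".join(out)


def brute_force_orfs(seq: str, min_aa: int, starts) -> set[tuple]:
    """All (start, end, strand, translation) valid ORFs of a linear sequence.

    One ORF per in-frame stop: the earliest start codon since the previous
    stop in the same frame.  Coordinates are forward-strand 1-based
    inclusive, stop codon included.
    """
    starts = set(starts)
    found = set()
    L = len(seq)
    for strand in ("+", "-"):
        s = seq if strand == "+" else rc(seq)
        for f in range(3):
            open_at = None
            i = f
            while i + 3 <= L:
                c = s[i : i + 3]
                if "N" not in c and c in _STOPS:
                    if open_at is not None and (i - open_at) // 3 >= min_aa:
                        a, b = open_at, i + 2  # 0-based inclusive on s
                        if strand == "+":
                            coord = (a + 1, b + 1)
                        else:
                            coord = (L - b, L - a)
                        found.add(
                            (coord[0], coord[1], strand, translate(s[a : i]))
                        )
                    open_at = None
                elif open_at is None and "N" not in c and c in starts:
                    open_at = i
                i += 3
    return found


def orf_key(records) -> set[tuple]:
    return {(r.start, r.end, r.strand, r.translation) for r in records}


def best_nonconflicting(hits, min_frac=0.5):
    """Exhaustively pick the rank-lexicographically best conflict-free subset.

    Hits are ranked by (evalue, -bitscore, accession); among all pairwise
    conflict-free subsets the winner is the one whose membership, read in
    rank order, is lexicographically greatest (include beats exclude).
    """

    def conflict(a, b):
        ov = min(a.query_end, b.query_end) - max(a.query_start, b.query_start) + 1
        sa = a.query_end - a.query_start + 1
        sb = b.query_end - b.query_start + 1
        return ov > min_frac * min(sa, sb)

    ranked = sorted(hits, key=lambda h: (h.evalue, -h.bitscore, h.accession))
    best, best_vec = None, None
    for r in range(len(ranked) + 1):
        for subset in combinations(range(len(ranked)), r):
            ok = all(
                not conflict(ranked[i], ranked[j]) for i, j in combinations(subset, 2)
            )
            if not ok:
                continue
            vec = tuple(1 if i in subset else 0 for i in range(len(ranked)))
            if best_vec is None or vec > best_vec:
                best, best_vec = subset, vec
    return {ranked[i] for i in (best or ())}


def walk_chain(intervals, tf_index, window, max_per_side=10):
    """Brute-force transitive neighbour walk over (start, end) tuples.

    Returns (left_indices, right_indices), nearest first.
    """
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    pos = order.index(tf_index)
    right = []
    k = pos
    while len(right) < max_per_side and k + 1 < len(order):
        a, b = intervals[order[k]], intervals[order[k + 1]]
        gap = max(0, b[0] - a[1] - 1)
        if gap > window:
            break
        right.append(order[k + 1])
        k += 1
    left = []
    k = pos
    while len(left) < max_per_side and k - 1 >= 0:
        a, b = intervals[order[k - 1]], intervals[order[k]]
        gap = max(0, b[0] - a[1] - 1)
        if gap > window:
            break
        left.append(order[k - 1])
        k -= 1
    return left, right


def confusion_counts(predicted, reference, universe):
    tp = fn = fp = tn = 0
    for x in universe:
        p = x in predicted
        r = x in reference
        if p and r:
            tp += 1
        elif not p and r:
            fn += 1
        elif p and not r:
            fp += 1
        else:
            tn += 1
    return tp, fn, fp, tn


def expected_category(receiver, s54_pair, r2r4, r3, has_input, phospho):
    """Hand derivation of the category rules over role-presence flags.

    Assumes a TF-qualifying DBD is present.  Receiver domains are decisive;
    sigma-54 typing precedes sigma-70; region 3 upgrades ECF to RpoD; a
    phosphotransfer domain vetoes the one-component call; TR is residual.
    """
    if receiver:
        return "RR", "none"
    if s54_pair:
        return "SF", "RpoN"
    if r2r4:
        return "SF", "RpoD" if r3 else "ECF"
    if has_input and not phospho:
        return "OCS", "none"
    return "TR", "none"
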