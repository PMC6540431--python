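"""Independent brute-force oracles used to validate the DP implementations.

These deliberately avoid the package's algorithms: alignments are scored
by exhaustive enumeration of monotone paths, ORFs by a naive per-frame
scan, percentiles by explicit order-statistic interpolation.
"""

from __future__ import annotations

import math


def enumerate_local_affine(
    q: str, s: str, score_fn, gap_open: int, gap_extend: int
) -> int:
    """Best local alignment score by exhaustive path enumeration.

    Every pair of substrings is aligned globally by enumerating all
    monotone move sequences; gap runs cost gap_open + len * gap_extend.
    The empty alignment scores 0.
    """
    best = 0
    for i0 in range(len(q)):
        for i1 in range(i0 + 1, len(q) + 1):
            for j0 in range(len(s)):
                for j1 in range(j0 + 1, len(s) + 1):
                    sc = _best_global(q[i0:i1], s[j0:j1], score_fn, gap_open, gap_extend)
                    best = max(best, sc)
    return best


def _best_global(a: str, b: str, score_fn, gap_open: int, gap_extend: int) -> int:
    best = -(10**9)
    stack = [(0, 0, 0, None)]  # i, j, score, last_move
    while stack:
        i, j, score, last = stack.pop()
        if i == len(a) and j == len(b):
            best = max(best, score)
            continue
        if i < len(a) and j < len(b):
            stack.append((i + 1, j + 1, score + score_fn(a[i], b[j]), "d"))
        if j < len(b):
            cost = gap_extend if last == "q" else gap_open + gap_extend
            stack.append((i, j + 1, score - cost, "q"))
        if i < len(a):
            cost = gap_extend if last == "s" else gap_open + gap_extend
            stack.append((i + 1, j, score - cost, "s"))
    return best


def enumerate_dovetail_identity(a: str, b: str) -> float:
    """Identity under the clustering convention, by path enumeration.

    Scoring: match +1, mismatch -1, internal gap -2 per column; gap
    columns while the other sequence is at an end are free. Among
    score-optimal alignments the one with the most matches is counted;
    identity = matches / min(len(a), len(b)).
    """
    m, n = len(a), len(b)
    best: tuple[int, int] = (-(10**9), 0)
    stack = [(0, 0, 0, 0)]  # i, j, score, matches
    while stack:
        i, j, score, matches = stack.pop()
        if i == m and j == n:
            best = max(best, (score, matches))
            continue
        if i < m and j < n:
            if a[i] == b[j]:
                stack.append((i + 1, j + 1, score + 1, matches + 1))
            else:
                stack.append((i + 1, j + 1, score - 1, matches))
        if j < n:
            free = i == 0 or i == m
            stack.append((i, j + 1, score - (0 if free else 2), matches))
        if i < m:
            free = j == 0 or j == n
            stack.append((i + 1, j, score - (0 if free else 2), matches))
    return best[1] / min(m, n)


GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def naive_translate(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - 2, 3):
        out.append(GENETIC_CODE.get(seq[i : i + 3], "X"))
    return "".join(out)


def naive_six_frames(seq: str) -> dict[int, str]:
    rc = naive_revcomp(seq)
    return {
        1: naive_translate(seq), 2: naive_translate(seq[1:]), 3: naive_translate(seq[2:]),
        -1: naive_translate(rc), -2: naive_translate(rc[1:]), -3: naive_translate(rc[2:]),
    }


def naive_orf_scan(seq: str, min_len_aa: int) -> set[tuple[int, str, str]]:
    """ORFs as (frame, peptide, completeness) triples, by direct scanning."""
    out: set[tuple[int, str, str]] = set()
    for frame, pep in naive_six_frames(seq).items():
        segments = []
        start = 0
        for idx, ch in enumerate(pep):
            if ch == "*":
                segments.append((start, idx, True))
                start = idx + 1
        segments.append((start, len(pep), False))
        for seg_start, seg_end, has_stop in segments:
            seg = pep[seg_start:seg_end]
            if not seg:
                continue
            m = seg.find("M")
            if has_stop:
                if m >= 0:
                    peptide, cls = seg[m:], "complete"
                elif seg_start == 0:
                    peptide, cls = seg, "partial5"
                else:
                    peptide, cls = seg, "internal"
            else:
                if m >= 0:
                    peptide, cls = seg[m:], "partial3"
                else:
                    peptide, cls = seg, "internal"
            if len(peptide) >= min_len_aa:
                out.add((frame, peptide, cls))
    return out


def percentile_inc(values: list[float], pct: float) -> float:
    """Spreadsheet PERCENTILE.INC: linear interpolation of order stats."""
    xs = sorted(values)
    if not xs:
        raise ValueError("empty")
    h = (len(xs) - 1) * pct / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    if lo == hi:
        return xs[lo]
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def qc_rescan(pairs, adaptors, min_match, max_n, max_lowq, q_thresh):
    """Brute-force re-check of the three removal criteria, per pair."""
    words = set()
    for ad in adaptors:
        for i in range(len(ad) - min_match + 1):
            words.add(ad[i : i + min_match])

    def fails_adaptor(seq):
        return any(seq[i : i + min_match] in words for i in range(len(seq) - min_match + 1))

    def fails_n(seq):
        return sum(1 for c in seq if c == "N") / len(seq) > max_n

    def fails_q(qual):
        low = sum(1 for c in qual if ord(c) - 33 < q_thresh)
        return low / len(qual) > max_lowq

    counts = {"adaptor": 0, "n": 0, "quality": 0, "kept": 0}
    for p in pairs:
        if fails_adaptor(p.seq1) or fails_adaptor(p.seq2):
            counts["adaptor"] += 1
        elif fails_n(p.seq1) or fails_n(p.seq2):
            counts["n"] += 1
        elif fails_q(p.qual1) or fails_q(p.qual2):
            counts["quality"] += 1
        else:
            counts["kept"] += 1
    return counts
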