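"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementations: the genetic code
comes straight from Bio.Data.CodonTable, substitution counting enumerates
neighbours and mutational pathways explicitly, and the motif oracle checks
every window with plain character-set membership.
"""

from __future__ import annotations

import itertools

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODE = dict(_TABLE.forward_table)
for _s in _TABLE.stop_codons:
    CODE[_s] = "*"
SENSE = sorted(c for c, aa in CODE.items() if aa != "*")
BASES = "ACGT"


def oracle_ng_sites(codon: str) -> tuple[float, float]:
    syn = 0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if CODE[mut] != "*" and CODE[mut] == CODE[codon]:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def oracle_ng_pair(a: str, b: str) -> tuple[float, float]:
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    open_paths, all_paths = [], []
    for order in itertools.permutations(diff):
        cur, syn, nonsyn, blocked = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if CODE[nxt] == "*":
                blocked = True
                nonsyn += 1
            elif CODE[nxt] == CODE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        all_paths.append((syn, nonsyn))
        if not blocked:
            open_paths.append((syn, nonsyn))
    paths = open_paths if open_paths else all_paths
    n = len(paths)
    return sum(p[0] for p in paths) / n, sum(p[1] for p in paths) / n


def oracle_scan(aa: str) -> set[tuple]:
    """All (motif, start, end, anchors) tuples by window enumeration."""
    n = len(aa)
    hits: set[tuple] = set()
    for i in range(n - 5):
        if aa[i] in "ILVS" and aa[i + 2] == "Y" and aa[i + 5] in "LV":
            hits.add(("ITIM", i, i + 6, (i + 2,)))
        if aa[i] == "T" and aa[i + 2] == "Y" and aa[i + 5] in "VI":
            hits.add(("ITSM", i, i + 6, (i + 2,)))
    itam_pairs = set()
    for i in range(n):
        if aa[i] not in "DE":
            continue
        for lead in range(3):
            y1 = i + 1 + lead
            for mid in range(6, 9):
                y2 = y1 + 4 + mid
                end = y2 + 4
                if end > n:
                    continue
                if (
                    aa[y1] == "Y"
                    and aa[y1 + 3] in "LI"
                    and aa[y2] == "Y"
                    and aa[y2 + 3] in "LI"
                ):
                    hits.add(("ITAM", i, end, (y1, y2)))
                    itam_pairs.add((y1, y2))
    for y1 in range(n):
        if aa[y1] != "Y" or y1 + 3 >= n or aa[y1 + 3] not in "LI":
            continue
        for mid in range(6, 9):
            y2 = y1 + 4 + mid
            end = y2 + 4
            if end > n:
                continue
            if aa[y2] != "Y" or aa[y2 + 3] not in "LI":
                continue
            if (y1, y2) in itam_pairs:
                continue
            if any(c in "DE" for c in aa[max(0, y1 - 3) : y1]):
                continue
            hits.add(("ITAM_like", y1, end, (y1, y2)))
    return hits


def oracle_conserved_regions(track, window, factor, min_len, extended_len=20):
    """Run-scan reimplementation of conserved-region delineation."""
    L = len(track)
    overall = sum(track) / L
    if overall == 0:
        return [(0, L, L > extended_len)]
    half = window // 2
    below = []
    for i in range(L):
        lo, hi = max(0, i - half), min(L, i + window - half)
        win = track[lo:hi]
        below.append(sum(win) / len(win) < factor * overall)
    regions = []
    i = 0
    while i < L:
        if below[i]:
            j = i
            while j < L and below[j]:
                j += 1
            if j - i >= min_len:
                regions.append((i, j, (j - i) > extended_len))
            i = j
        else:
            i += 1
    return regions
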