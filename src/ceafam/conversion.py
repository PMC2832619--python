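"""Gene-conversion candidate detection and percent-identity segments.

A recent conversion/recombination tract between paralogs shows up as a
stretch of codons with no (or minimal) synonymous divergence against a
background that has accumulated synonymous substitutions.  The statistic is
the length of the longest run of codons whose pathway-averaged synonymous
difference is at or below a tolerance ``epsilon`` (default 0); significance
comes from permuting the codon values, which conditions on the observed
per-codon synonymous opportunities.  p = (1 + #{null >= observed}) / (B + 1),
so p is in (0, 1] and valid (super-uniform) under the exchangeable null.

Percent-identity segments between two raw gene-locus sequences are found by
exact k-mer seeding followed by ungapped bidirectional extension under an
X-drop rule (match +1, mismatch -1), a tabular analogue of a percent
identity plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon import _PAIR, _usable_codons
from .errors import EmptyOverlapError, InapplicableTestError
from .seqio import CodonAlignment, Sequence

__all__ = [
    "SynDiffTrack",
    "ConversionCall",
    "PipSegment",
    "syn_diff_track",
    "conversion_test",
    "pip_segments",
    "locate_high_identity_region",
]


@dataclass
class SynDiffTrack:
    """Per-codon synonymous differences for one sequence pair."""

    pair: tuple[str, str]
    values: np.ndarray  # float, length = codon count; 0 at excluded codons
    excluded: np.ndarray  # bool; True where the codon was unusable for this pair

    @property
    def n_codons(self) -> int:
        return len(self.values)

    def total(self) -> float:
        return float(self.values[~self.excluded].sum())


def syn_diff_track(i: int, j: int, aln: CodonAlignment) -> SynDiffTrack:
    """Codon-wise synonymous components of the pathway-averaged differences."""
    L = aln.n_codons
    values = np.zeros(L)
    excluded = np.ones(L, dtype=bool)
    for c, ca, cb in _usable_codons(i, j, aln):
        values[c] = _PAIR[(ca, cb)][0]
        excluded[c] = False
    if excluded.all():
        raise EmptyOverlapError(f"rows {i} and {j} share no usable codon")
    return SynDiffTrack(
        pair=(aln.rows[i].id, aln.rows[j].id), values=values, excluded=excluded
    )


def _longest_true_run(mask: np.ndarray) -> tuple[int, int, int]:
    """(length, start, end) of the first maximal run of True values."""
    best = cur = 0
    best_start = best_end = cur_start = 0
    for k, v in enumerate(mask):
        if v:
            if cur == 0:
                cur_start = k
            cur += 1
            if cur > best:
                best = cur
                best_start, best_end = cur_start, k + 1
        else:
            cur = 0
    return best, best_start, best_end


def _longest_run_rows(mat: np.ndarray) -> np.ndarray:
    """Longest True run per row of a boolean matrix (vectorized over rows)."""
    B, L = mat.shape
    out = np.zeros(B, dtype=np.int64)
    cnt = np.zeros(B, dtype=np.int64)
    for k in range(L):
        cnt = np.where(mat[:, k], cnt + 1, 0)
        np.maximum(out, cnt, out=out)
    return out


@dataclass
class ConversionCall:
    """A low-synonymous-divergence run with its permutation p-value.

    Run bounds are codon indices into the original alignment (0-based,
    half-open); excluded codons do not break a run.
    """

    pair: tuple[str, str]
    run_start: int
    run_end: int
    run_length: int
    run_total_syn: float
    p_value: float
    epsilon: float
    B: int
    seed: int

    def report_coords(self) -> tuple[int, int]:
        return self.run_start + 1, self.run_end


def conversion_test(
    track: SynDiffTrack,
    epsilon: float = 0.0,
    B: int = 1000,
    seed: int = 0,
) -> ConversionCall:
    """Permutation test for a conversion-like low-synonymous run.

    Excluded codons are dropped before computing runs (they neither extend
    nor break a run); the null permutes the usable codon values.  Requires a
    positive total synonymous difference — an all-zero track carries no
    information and raises :class:`InapplicableTestError`.
    """
    usable_idx = np.flatnonzero(~track.excluded)
    vals = track.values[usable_idx]
    if vals.size == 0 or vals.sum() <= 0:
        raise InapplicableTestError("track has no synonymous divergence to test against")
    low = vals <= epsilon
    obs_len, lo, hi = _longest_true_run(low)
    rng = np.random.default_rng(seed)
    null = _longest_run_rows(rng.permuted(np.tile(low, (B, 1)), axis=1))
    p = (1.0 + int((null >= obs_len).sum())) / (B + 1.0)
    start = int(usable_idx[lo]) if obs_len else 0
    end = int(usable_idx[hi - 1]) + 1 if obs_len else 0
    return ConversionCall(
        pair=track.pair,
        run_start=start,
        run_end=end,
        run_length=obs_len,
        run_total_syn=float(vals[lo:hi].sum()) if obs_len else 0.0,
        p_value=float(p),
        epsilon=epsilon,
        B=B,
        seed=seed,
    )


@dataclass
class PipSegment:
    """A gap-free matched segment between two sequences."""

    start1: int
    end1: int
    start2: int
    end2: int
    percent_identity: float = field(init=False)
    matches: int = 0

    def __post_init__(self) -> None:
        self.percent_identity = (
            100.0 * self.matches / self.length if self.length else 0.0
        )

    @property
    def length(self) -> int:
        return self.end1 - self.start1


def _xdrop_extend(s1: str, s2: str, i: int, j: int, k: int, xdrop: int) -> tuple[int, int]:
    """Extend an exact k-mer seed at (i, j) in both directions.

    Scoring is +1/-1; extension in each direction stops when the running
    score falls ``xdrop`` below its best, and the extent achieving the best
    score is kept.  Returns the segment on s1 as (start, end)."""
    # right of the seed
    best = score = 0
    best_right = i + k
    a, b = i + k, j + k
    while a < len(s1) and b < len(s2):
        score += 1 if s1[a] == s2[b] else -1
        if score > best:
            best = score
            best_right = a + 1
        if best - score > xdrop:
            break
        a += 1
        b += 1
    # left of the seed
    best = score = 0
    best_left = i
    a, b = i - 1, j - 1
    while a >= 0 and b >= 0:
        score += 1 if s1[a] == s2[b] else -1
        if score > best:
            best = score
            best_left = a
        if best - score > xdrop:
            break
        a -= 1
        b -= 1
    return best_left, best_right


def pip_segments(
    s1: Sequence,
    s2: Sequence,
    k: int = 11,
    xdrop: int = 20,
    min_len: int = 40,
    min_id: float = 60.0,
) -> list[PipSegment]:
    """Ungapped high-identity segments between two raw nucleotide sequences.

    Exact k-mers of ``s2`` seed ungapped X-drop extensions; overlapping
    segments on the same diagonal are merged; segments shorter than
    ``min_len`` or below ``min_id`` percent identity are dropped.  Sorted by
    position in ``s1``.
    """
    a, b = s1.residues.upper(), s2.residues.upper()
    if len(a) < k or len(b) < k:
        return []
    index: dict[str, list[int]] = {}
    for j in range(len(b) - k + 1):
        index.setdefault(b[j : j + k], []).append(j)
    # diagonal -> list of merged (start1, end1) intervals
    by_diag: dict[int, list[list[int]]] = {}
    for i in range(len(a) - k + 1):
        for j in index.get(a[i : i + k], ()):
            diag = i - j
            intervals = by_diag.setdefault(diag, [])
            if intervals and i < intervals[-1][1]:
                continue  # seed already inside the last extension on this diagonal
            lo, hi = _xdrop_extend(a, b, i, j, k, xdrop)
            if intervals and lo <= intervals[-1][1]:
                intervals[-1][1] = max(intervals[-1][1], hi)
            else:
                intervals.append([lo, hi])
    out: list[PipSegment] = []
    for diag, intervals in by_diag.items():
        for lo, hi in intervals:
            length = hi - lo
            if length < min_len:
                continue
            matches = sum(a[p] == b[p - diag] for p in range(lo, hi))
            seg = PipSegment(start1=lo, end1=hi, start2=lo - diag, end2=hi - diag,
                             matches=matches)
            if seg.percent_identity >= min_id:
                out.append(seg)
    out.sort(key=lambda s: (s.start1, s.start2))
    return out


def locate_high_identity_region(
    segments: list[PipSegment],
    annotation: list[tuple[str, int, int]],
) -> dict:
    """Report the maximal-identity segment and the annotated exons it overlaps.

    ``annotation`` holds (exon_name, start, end) intervals in the s1
    coordinate system (0-based half-open).  An empty segment list returns an
    empty report.
    """
    if not segments:
        return {"segment": None, "overlapping_exons": []}
    best = max(segments, key=lambda s: (s.percent_identity, s.length))
    overlaps = [
        name
        for name, lo, hi in annotation
        if max(best.start1, lo) < min(best.end1, hi)
    ]
    return {"segment": best, "overlapping_exons": overlaps}
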