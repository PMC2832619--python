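"""Nei–Gojobori synonymous/nonsynonymous counting and dN/dS summaries.

The classical unweighted counting scheme is used throughout:

* a codon's synonymous-site count is the fraction of its nine single-nucleotide
  neighbours that preserve the encoded amino acid, summed per position (each
  position contributes syn/3 sites), with mutations to stop codons counted as
  nonsynonymous, so s + n = 3 exactly for every sense codon;
* differences between two sense codons differing at k positions are averaged
  over the k! mutational orderings; orderings passing through a stop codon are
  excluded, and if every ordering is blocked the average falls back to all
  orderings with stop steps counted nonsynonymous, so sd + nd = k always;
* proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits with the
  one-parameter formula d = -(3/4) ln(1 - (4/3) p), valid for p < 3/4.

omega = dN/dS is reported only where dS > 0; it is never rendered as infinity.
Alignment-level summaries average over all unordered row pairs — a pairwise
approximation to branch-wise rates, flagged as such in reports.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptyOverlapError,
    ExcludedCodonError,
    SaturationError,
    UndefinedSummaryError,
)
from .seqio import GENETIC_CODE, NT_ALPHABET, SENSE_CODONS, CodonAlignment

__all__ = [
    "NGPairResult",
    "SubstitutionProfile",
    "ConservedRegion",
    "RateSummary",
    "ng_sites",
    "ng_pair_codon",
    "ng_pairwise",
    "dnds_summary",
    "substitution_profile",
    "delineate_conserved_regions",
    "jukes_cantor",
]


def _site_counts(codon: str) -> tuple[float, float]:
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        for alt in NT_ALPHABET:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:  # stop mutants translate '*', never equal
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pair_counts(a: str, b: str) -> tuple[float, float]:
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    open_paths: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = a
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                blocked = True
                nonsyn += 1
            elif GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        all_paths.append((syn, nonsyn))
        if not blocked:
            open_paths.append((syn, nonsyn))
    paths = open_paths or all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


# Tables over the 61 sense codons; lookups dominate profile computation.
_SITES: dict[str, tuple[float, float]] = {c: _site_counts(c) for c in SENSE_CODONS}
_PAIR: dict[tuple[str, str], tuple[float, float]] = {
    (a, b): _pair_counts(a, b) for a in SENSE_CODONS for b in SENSE_CODONS
}


def ng_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s + n = 3) of a sense codon."""
    try:
        return _SITES[codon]
    except KeyError:
        raise ExcludedCodonError(f"{codon!r} is not a sense codon") from None


def ng_pair_codon(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons."""
    try:
        return _PAIR[(a, b)]
    except KeyError:
        raise ExcludedCodonError(f"({a!r}, {b!r}) is not a sense-codon pair") from None


def jukes_cantor(p: float, context: str = "") -> float:
    """One-parameter multiple-hit correction -(3/4) ln(1 - 4p/3)."""
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4{' for ' + context if context else ''}")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class NGPairResult:
    """Pairwise substitution quantities for one row pair."""

    i: int
    j: int
    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int
    pS: float = field(init=False)
    pN: float = field(init=False)
    dS: float = field(init=False)
    dN: float = field(init=False)
    omega: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.pS = self.Sd / self.S if self.S > 0 else 0.0
        self.pN = self.Nd / self.N if self.N > 0 else 0.0
        ctx = f"pair ({self.i},{self.j})"
        self.dS = jukes_cantor(self.pS, ctx)
        self.dN = jukes_cantor(self.pN, ctx)
        self.omega = self.dN / self.dS if self.dS > 0 else None


def _usable_codons(i: int, j: int, aln: CodonAlignment):
    """Yield (col, codon_i, codon_j) where the column is unmasked and both sense."""
    ri, rj = aln.rows[i].residues, aln.rows[j].residues
    for c in np.flatnonzero(aln.mask):
        ca, cb = ri[3 * c : 3 * c + 3], rj[3 * c : 3 * c + 3]
        if ca in _SITES and cb in _SITES:
            yield int(c), ca, cb


def ng_pairwise(i: int, j: int, aln: CodonAlignment) -> NGPairResult:
    """Nei–Gojobori estimates for rows i and j of a codon alignment.

    Sites are averaged over the two rows; differences are pathway averages
    summed over usable codons (unmasked, both rows sense).  Raises
    :class:`EmptyOverlapError` when no codon is usable and
    :class:`SaturationError` when a proportion exceeds the correction domain.
    """
    S_i = S_j = Sd = Nd = 0.0
    n_used = 0
    for _, ca, cb in _usable_codons(i, j, aln):
        si, _ = _SITES[ca]
        sj, _ = _SITES[cb]
        S_i += si
        S_j += sj
        sd, nd = _PAIR[(ca, cb)]
        Sd += sd
        Nd += nd
        n_used += 1
    if n_used == 0:
        raise EmptyOverlapError(f"rows {i} and {j} share no usable codon")
    S = (S_i + S_j) / 2.0
    N = 3.0 * n_used - S
    return NGPairResult(i=i, j=j, S=S, N=N, Sd=Sd, Nd=Nd, n_codons=n_used)


@dataclass
class RateSummary:
    """Mean/SD of omega over row pairs (pairwise approximation to branch rates)."""

    mean_omega: float
    sd_omega: float
    n_pairs: int
    n_undefined: int = 0
    n_saturated: int = 0
    method: str = "pairwise approximation"


def dnds_summary(aln: CodonAlignment) -> RateSummary:
    """Mean and SD of omega over all unordered row pairs with defined omega.

    Pairs with dS = 0 (omega undefined) or saturated proportions are skipped
    and counted.  Raises :class:`UndefinedSummaryError` when no pair remains.
    """
    if aln.n_rows < 2:
        raise UndefinedSummaryError("need at least two rows")
    omegas: list[float] = []
    n_undef = n_sat = 0
    for i in range(aln.n_rows):
        for j in range(i + 1, aln.n_rows):
            try:
                res = ng_pairwise(i, j, aln)
            except SaturationError:
                n_sat += 1
                continue
            except EmptyOverlapError:
                n_undef += 1
                continue
            if res.omega is None:
                n_undef += 1
            else:
                omegas.append(res.omega)
    if not omegas:
        raise UndefinedSummaryError("no pair with defined omega")
    arr = np.asarray(omegas)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return RateSummary(
        mean_omega=float(arr.mean()),
        sd_omega=sd,
        n_pairs=len(omegas),
        n_undefined=n_undef,
        n_saturated=n_sat,
    )


@dataclass
class SubstitutionProfile:
    """Per-codon mean substitution tracks, averaged over all row pairs.

    Masked or non-sense codons contribute 0 to the pair mean and are flagged
    in ``excluded`` when unusable for every pair.
    """

    mean_syn: np.ndarray
    mean_nonsyn: np.ndarray
    cum_syn: np.ndarray = field(init=False)
    cum_nonsyn: np.ndarray = field(init=False)
    excluded: np.ndarray | None = None
    n_pairs: int = 0

    def __post_init__(self) -> None:
        self.cum_syn = np.cumsum(self.mean_syn)
        self.cum_nonsyn = np.cumsum(self.mean_nonsyn)

    @property
    def n_codons(self) -> int:
        return len(self.mean_syn)

    def per_100_codon_rates(self) -> tuple[float, float]:
        L = self.n_codons
        return (
            float(self.cum_syn[-1]) * 100.0 / L,
            float(self.cum_nonsyn[-1]) * 100.0 / L,
        )


def substitution_profile(aln: CodonAlignment) -> SubstitutionProfile:
    """Codon-wise mean synonymous/nonsynonymous differences over all pairs."""
    if aln.n_rows < 2:
        raise EmptyOverlapError("need at least two rows for a profile")
    L = aln.n_codons
    syn = np.zeros(L)
    nonsyn = np.zeros(L)
    used = np.zeros(L, dtype=bool)
    n_pairs = aln.n_rows * (aln.n_rows - 1) // 2
    for i in range(aln.n_rows):
        for j in range(i + 1, aln.n_rows):
            for c, ca, cb in _usable_codons(i, j, aln):
                sd, nd = _PAIR[(ca, cb)]
                syn[c] += sd
                nonsyn[c] += nd
                used[c] = True
    syn /= n_pairs
    nonsyn /= n_pairs
    return SubstitutionProfile(
        mean_syn=syn, mean_nonsyn=nonsyn, excluded=~used, n_pairs=n_pairs
    )


@dataclass
class ConservedRegion:
    """A low-nonsynonymous-rate run; coordinates 1-based inclusive in reports."""

    start: int  # 0-based inclusive codon index
    end: int  # 0-based exclusive
    mean_rate: float
    extended: bool

    @property
    def length(self) -> int:
        return self.end - self.start

    def report_coords(self) -> tuple[int, int]:
        return self.start + 1, self.end


def delineate_conserved_regions(
    profile: SubstitutionProfile,
    window: int = 10,
    factor: float = 0.5,
    min_len: int = 5,
    extended_len: int = 20,
) -> list[ConservedRegion]:
    """Runs of codons whose smoothed nonsynonymous rate falls below
    ``factor`` x the exon-wide mean.

    A centred sliding mean (truncated at the edges) smooths the track;
    below-threshold positions are merged into maximal runs and runs of at
    least ``min_len`` codons are reported, flagged ``extended`` when longer
    than ``extended_len`` codons.  A track with zero exon-wide mean returns
    the whole exon as one region.
    """
    track = np.asarray(profile.mean_nonsyn, dtype=float)
    L = len(track)
    if L < window:
        raise ValueError(f"profile length {L} shorter than window {window}")
    overall = float(track.mean())
    if overall == 0.0:
        return [ConservedRegion(0, L, 0.0, L > extended_len)]
    half = window // 2
    smoothed = np.empty(L)
    for i in range(L):
        lo = max(0, i - half)
        hi = min(L, i + window - half)
        smoothed[i] = track[lo:hi].mean()
    below = smoothed < factor * overall
    regions: list[ConservedRegion] = []
    i = 0
    while i < L:
        if below[i]:
            j = i
            while j < L and below[j]:
                j += 1
            if j - i >= min_len:
                regions.append(
                    ConservedRegion(i, j, float(track[i:j].mean()), (j - i) > extended_len)
                )
            i = j
        else:
            i += 1
    return regions
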