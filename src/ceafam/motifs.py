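"""Immunoreceptor tyrosine-based motif grammars and cytoplasmic classification.

Consensus patterns (x = any residue, sets in brackets):

=============  ==========================================================
ITIM           [ILVS] x Y x x [LV]
ITSM           T x Y x x [VI]
ITAM           [DE] x{0-2} Y x x [LI] x{6-8} Y x x [LI]
ITAM_like      Y x x [LI] x{6-8} Y x x [LI], with no D/E at offsets
               -1..-3 before the first Y
endocytic      Y x x [LMVIF]
GRB2_YxN       Y x N
YxxM_variant   Y x x M
TEHKxS_box     T E H K x S (the alternative spelling T H E K x S is also
               reported, flagged ``variant='THEKxS'``)
=============  ==========================================================

Every admissible spacer combination of a spacer pattern is a separate hit;
classification counts distinct first-tyrosine offsets so nested spacer
variants of one motif count once.  An ITAM_like hit whose tyrosine pair also
satisfies the full ITAM is suppressed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ConfigError, ContractError

__all__ = [
    "MotifHit",
    "CytoplasmicClass",
    "MOTIF_NAMES",
    "scan_motifs",
    "classify_cytoplasmic",
    "itam_second_half_variant",
]

MOTIF_NAMES = (
    "ITIM",
    "ITSM",
    "ITAM",
    "ITAM_like",
    "endocytic",
    "GRB2_YxN",
    "YxxM_variant",
    "TEHKxS_box",
)

_SIMPLE_PATTERNS: dict[str, tuple[str, tuple[int, ...]]] = {
    # name -> (regex, offsets of anchor tyrosines relative to hit start)
    "ITIM": (r"[ILVS].Y..[LV]", (2,)),
    "ITSM": (r"T.Y..[VI]", (2,)),
    "endocytic": (r"Y..[LMVIF]", (0,)),
    "GRB2_YxN": (r"Y.N", (0,)),
    "YxxM_variant": (r"Y..M", (0,)),
}

_ACIDIC = frozenset("DE")
_LEAD_RANGE = range(0, 3)  # spacers between the acidic residue and the first Y
_MID_RANGE = range(6, 9)  # spacers between the two YxxL/I half-motifs


@dataclass(frozen=True)
class MotifHit:
    """One motif match: [start, end) slice of the scanned sequence."""

    motif: str
    start: int
    end: int
    matched: str
    anchor_tyrosines: tuple[int, ...]
    variant: str | None = None


@dataclass
class CytoplasmicClass:
    """Receptor-class label with the hits supporting it."""

    label: str  # ITAM | ITAM_like | ITIM_ITSM | ITIM_ITIM | ITIM_only | none
    hits: list[MotifHit] = field(default_factory=list)


def _findall(pattern: str, aa: str):
    """All (possibly overlapping) match start offsets of an anchored regex."""
    rx = re.compile(f"(?=({pattern}))")
    return [(m.start(), m.group(1)) for m in rx.finditer(aa)]


def _scan_simple(name: str, aa: str) -> list[MotifHit]:
    pattern, y_offsets = _SIMPLE_PATTERNS[name]
    hits = []
    for start, matched in _findall(pattern, aa):
        anchors = tuple(start + o for o in y_offsets)
        hits.append(MotifHit(name, start, start + len(matched), matched, anchors))
    return hits


def _scan_itam(aa: str) -> list[MotifHit]:
    hits = []
    for lead in _LEAD_RANGE:
        for mid in _MID_RANGE:
            pattern = "[DE]" + "." * lead + "Y..[LI]" + "." * mid + "Y..[LI]"
            for start, matched in _findall(pattern, aa):
                y1 = start + 1 + lead
                y2 = y1 + 4 + mid
                hits.append(
                    MotifHit("ITAM", start, start + len(matched), matched, (y1, y2))
                )
    return hits


def _scan_itam_like(aa: str, itam_hits: list[MotifHit]) -> list[MotifHit]:
    itam_pairs = {h.anchor_tyrosines for h in itam_hits}
    hits = []
    for mid in _MID_RANGE:
        pattern = "Y..[LI]" + "." * mid + "Y..[LI]"
        for start, matched in _findall(pattern, aa):
            y1, y2 = start, start + 4 + mid
            if (y1, y2) in itam_pairs:
                continue
            upstream = aa[max(0, y1 - 3) : y1]
            if _ACIDIC & set(upstream):
                continue
            hits.append(
                MotifHit("ITAM_like", start, start + len(matched), matched, (y1, y2))
            )
    return hits


def _scan_tehk(aa: str) -> list[MotifHit]:
    hits = []
    for pattern, variant in (("TEHK.S", None), ("THEK.S", "THEKxS")):
        for start, matched in _findall(pattern, aa):
            hits.append(MotifHit("TEHKxS_box", start, start + 6, matched, (), variant))
    return hits


def scan_motifs(aa: str, which=frozenset(MOTIF_NAMES)) -> list[MotifHit]:
    """All hits of the requested motifs, leftmost-first.

    ``aa`` must be gap-free (callers strip alignment gaps).  Spacer patterns
    report each admissible spacer length as a separate hit; ITAM_like hits
    whose tyrosine pair also satisfies ITAM are suppressed.
    """
    unknown = set(which) - set(MOTIF_NAMES)
    if unknown:
        raise ConfigError(f"unknown motif name(s): {sorted(unknown)}")
    if "-" in aa:
        raise ContractError("scan_motifs requires a gap-free sequence")
    hits: list[MotifHit] = []
    itam_hits = _scan_itam(aa) if {"ITAM", "ITAM_like"} & set(which) else []
    if "ITAM" in which:
        hits.extend(itam_hits)
    if "ITAM_like" in which:
        hits.extend(_scan_itam_like(aa, itam_hits))
    for name in which:
        if name in _SIMPLE_PATTERNS:
            hits.extend(_scan_simple(name, aa))
    if "TEHKxS_box" in which:
        hits.extend(_scan_tehk(aa))
    hits.sort(key=lambda h: (h.start, h.motif, h.end))
    return hits


def _distinct_anchor_count(hits: list[MotifHit], motif: str) -> int:
    return len({h.anchor_tyrosines[0] for h in hits if h.motif == motif})


def classify_cytoplasmic(aa: str) -> CytoplasmicClass:
    """Receptor-class label of a cytoplasmic domain.

    Precedence: ITAM > ITAM_like > (ITIM & ITSM -> ITIM_ITSM) >
    (>=2 distinct ITIM -> ITIM_ITIM) > (1 ITIM -> ITIM_only) > none.
    Motif multiplicity counts distinct first-tyrosine offsets.
    """
    hits = scan_motifs(aa, frozenset({"ITAM", "ITAM_like", "ITIM", "ITSM"}))
    n_itam = _distinct_anchor_count(hits, "ITAM")
    n_itam_like = _distinct_anchor_count(hits, "ITAM_like")
    n_itim = _distinct_anchor_count(hits, "ITIM")
    n_itsm = _distinct_anchor_count(hits, "ITSM")
    if n_itam:
        label = "ITAM"
    elif n_itam_like:
        label = "ITAM_like"
    elif n_itim and n_itsm:
        label = "ITIM_ITSM"
    elif n_itim >= 2:
        label = "ITIM_ITIM"
    elif n_itim == 1:
        label = "ITIM_only"
    else:
        label = "none"
    return CytoplasmicClass(label=label, hits=hits)


INHIBITORY_CLASSES = frozenset({"ITIM_ITSM", "ITIM_ITIM", "ITIM_only"})
ACTIVATING_CLASSES = frozenset({"ITAM", "ITAM_like"})


def itam_second_half_variant(hit: MotifHit, aa: str) -> str:
    """Classify the second half-motif of an ITAM(-like) hit: YxxL_I or YxxM.

    Inspects the residue three positions after the second anchor tyrosine.  A
    methionine there marks the Vav-binding YxxM variant seen in some
    activating family members.
    """
    if hit.motif not in ("ITAM", "ITAM_like"):
        raise ContractError(f"hit is {hit.motif}, not an ITAM/ITAM_like")
    if len(hit.anchor_tyrosines) < 2:
        raise ContractError("ITAM hit lacks a second anchor tyrosine")
    pos = hit.anchor_tyrosines[1] + 3
    if pos >= len(aa) or hit.end > len(aa):
        raise ContractError("hit out of bounds of the supplied sequence")
    return "YxxM" if aa[pos] == "M" else "YxxL_I"
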