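"""Sequence and codon-alignment I/O.

Sequences are plain records (identifier + residues + alphabet tag).  Codon
alignments carry a per-codon-column usability mask: any column in which any
row shows a gap or ambiguity character is excluded from every downstream
computation (complete deletion at codon granularity).  This is the
deterministic stand-in for the manual gap editing customarily applied before
substitution counting.

Coordinates are 0-based half-open internally; report writers print 1-based
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import AlignmentError, FormatError, IdentityError

log = logging.getLogger(__name__)

NT_ALPHABET = "ACGT"
# IUPAC ambiguity codes are legal on input but mask the codon column they sit in.
NT_ALLOWED = set("ACGTUNRYSWKMBDHV-")
AA_ALLOWED = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    GENETIC_CODE[_stop] = "*"
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"))


@dataclass
class Sequence:
    """A named sequence; ``alphabet`` is ``'nt'`` or ``'aa'``."""

    id: str
    residues: str
    alphabet: str = "nt"

    def __len__(self) -> int:
        return len(self.residues)


def _allowed(alphabet: str) -> set[str]:
    if alphabet == "nt":
        return NT_ALLOWED
    if alphabet == "aa":
        return AA_ALLOWED
    raise ValueError(f"unknown alphabet tag {alphabet!r}")


def _normalize(residues: str, alphabet: str) -> str:
    residues = residues.upper()
    if alphabet == "nt":
        residues = residues.replace("U", "T")
    return residues


def _find_bad_char_line(path, record_id: str, bad: str) -> int:
    """Locate the 1-based line number of an illegal residue (error path only)."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == record_id if line[1:].strip() else False
                continue
            if in_record and bad in line.upper():
                return lineno
    return -1


def read_fasta(path, alphabet: str = "nt") -> list[Sequence]:
    """Read a FASTA file into a list of :class:`Sequence`.

    Residues are upper-cased ('U' mapped to 'T' for nucleotide data); record
    order is preserved.  Raises :class:`FormatError` (naming the line) for a
    malformed header or illegal residue, :class:`IdentityError` for duplicate
    identifiers.  An empty file yields an empty list.
    """
    allowed = _allowed(alphabet)
    # Bio.SeqIO silently skips leading junk; enforce the header contract here.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}: line {lineno}: expected FASTA header '>'")
            break

    out: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty identifier")
        if rec.id in seen:
            raise IdentityError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        residues = _normalize(str(rec.seq), alphabet)
        bad = next((c for c in residues if c not in allowed), None)
        if bad is not None:
            lineno = _find_bad_char_line(path, rec.id, bad)
            raise FormatError(
                f"{path}: line {lineno}: illegal {alphabet} character {bad!r} in {rec.id!r}"
            )
        out.append(Sequence(rec.id, residues, alphabet))
    return out


def write_fasta(seqs: list[Sequence], path) -> None:
    """Write sequences as FASTA, wrapping residue lines at 60 columns."""
    with open(path, "w") as fh:
        for seq in seqs:
            if not seq.id:
                raise IdentityError("cannot write sequence with empty identifier")
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), 60):
                fh.write(seq.residues[i : i + 60] + "\n")


def translate(nt: str, frame: int = 0) -> str:
    """Standard-code translation of ``nt`` starting at ``frame``.

    Stops render '*'; codons containing gaps or ambiguity characters render
    'X'; an incomplete trailing codon is dropped.  Degenerate inputs yield ''.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    nt = _normalize(nt, "nt")
    out = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        out.append(GENETIC_CODE.get(codon, "X"))
    return "".join(out)


@dataclass
class CodonAlignment:
    """Frame-preserving aligned coding sequences with a per-codon mask.

    ``mask[c]`` is True when codon column ``c`` is usable: no row has a gap or
    ambiguity character there, so every row shows a plain A/C/G/T codon
    (possibly a stop, which downstream counters handle per pair).
    """

    rows: list[Sequence]
    mask: np.ndarray  # bool, shape (n_codons,)
    n_dropped_columns: int = 0
    masked_count: int = field(init=False)

    def __post_init__(self) -> None:
        self.masked_count = int((~self.mask).sum())

    @property
    def length(self) -> int:
        return len(self.rows[0].residues) if self.rows else 0

    @property
    def n_codons(self) -> int:
        return self.length // 3

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def codon(self, row: int, col: int) -> str:
        return self.rows[row].residues[3 * col : 3 * col + 3]

    def labels(self) -> list[str]:
        return [r.id for r in self.rows]


def build_codon_alignment(rows: list[Sequence]) -> CodonAlignment:
    """Assemble a :class:`CodonAlignment`, computing the usability mask.

    Rows must be equal length; a length not divisible by 3 has its trailing
    1-2 columns dropped (reported via ``n_dropped_columns``).
    """
    if not rows:
        raise AlignmentError("cannot build a codon alignment from zero rows")
    lengths = {len(r.residues) for r in rows}
    if len(lengths) > 1:
        raise AlignmentError(f"rows have unequal lengths: {sorted(lengths)}")
    (length,) = lengths
    dropped = length % 3
    if dropped:
        log.warning("alignment length %d not divisible by 3; dropping %d trailing column(s)",
                    length, dropped)
        rows = [Sequence(r.id, r.residues[: length - dropped], r.alphabet) for r in rows]
        length -= dropped
    n_codons = length // 3
    mask = np.ones(n_codons, dtype=bool)
    plain = set(NT_ALPHABET)
    for r in rows:
        res = r.residues
        for c in range(n_codons):
            if mask[c] and any(ch not in plain for ch in res[3 * c : 3 * c + 3]):
                mask[c] = False
    if n_codons and not mask.any():
        log.warning("no usable codon columns: every column carries a gap or ambiguity")
    return CodonAlignment(rows=list(rows), mask=mask, n_dropped_columns=dropped)
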