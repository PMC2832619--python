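"""Exon-structured gene models and family-delineation rules.

Implements the catalog rules used to delineate an immunoreceptor gene family
from exon-level annotation:

* GT-AG splice-dinucleotide checks;
* pseudogene calling — a gene is a pseudogene iff its N (IgV ligand-binding)
  exon contains an in-frame stop or carries an invalid splice site; in
  "opossum" mode the leader exon is additionally subject to the same lesions;
* donor read-through detection: a defective donor is translated into the
  intron and the first (up to two) in-frame stops within 60 nt are reported,
  classifying the product as secreted-truncated;
* gene counting — distinct N exons are counted by single-linkage clustering
  at a nucleotide p-distance threshold (default 1%);
* paired-receptor pairing — each inhibitory gene is matched to the
  same-species activating gene with maximal N-domain amino-acid identity.

Intron phase follows the convention phase 0 = codon|intron|codon,
phase 1 = one codon nucleotide before the intron, phase 2 = two before.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ContractError, StructureError
from .motifs import ACTIVATING_CLASSES, INHIBITORY_CLASSES, classify_cytoplasmic
from .seqio import Sequence, translate

EXON_TYPES = ("L", "N", "A", "B", "TM", "GPI_signal", "Cyt1", "Cyt2", "Cyt3", "Cyt4")
ANCHOR_CLASSES = ("transmembrane", "secreted", "GPI")

GENE_TABLE_COLUMNS = [
    "gene_id",
    "species",
    "exon_index",
    "exon_type",
    "acceptor",
    "donor",
    "phase_after",
    "frame_offset",
    "sequence",
]


@dataclass
class ExonModel:
    exon_type: str
    sequence: str
    acceptor_dinucleotide: str = ""  # empty for a first exon
    donor_dinucleotide: str = ""  # empty for a terminal exon
    intron_phase_after: int = 0
    frame_offset: int = 0


@dataclass
class SpliceReport:
    acceptor_valid: bool
    donor_valid: bool
    acceptor_checked: bool
    donor_checked: bool

    @property
    def valid(self) -> bool:
        return (not self.acceptor_checked or self.acceptor_valid) and (
            not self.donor_checked or self.donor_valid
        )


@dataclass
class GeneModel:
    gene_id: str
    species: str
    exons: list[ExonModel]
    anchor_class: str = "transmembrane"  # annotation input, never predicted
    status: str = "gene"
    status_reasons: list[str] = field(default_factory=list)
    receptor_class: str = "none"

    def exons_of_type(self, exon_type: str) -> list[ExonModel]:
        return [e for e in self.exons if e.exon_type == exon_type]

    def cytoplasmic_translation(self) -> str:
        """Translation of the concatenated cytoplasmic exons, in exon order."""
        cyt = [e for e in self.exons if e.exon_type.startswith("Cyt")]
        if not cyt:
            return ""
        nt = "".join(e.sequence for e in cyt)
        return translate(nt, cyt[0].frame_offset)


@dataclass
class PairedReceptorCandidate:
    inhibitory_gene: str
    activating_gene: str
    n_identity: float
    species: str


@dataclass
class FamilyCatalog:
    genes: list[GeneModel]
    clusters: list[list[str]] = field(default_factory=list)

    def by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def species_counts(self) -> pd.DataFrame:
        """Per-species class counts in the style of a family-survey table."""
        rows = []
        for sp in sorted({g.species for g in self.genes}):
            genes = [g for g in self.genes if g.species == sp]
            expressed = [g for g in genes if g.status == "gene"]
            rows.append(
                {
                    "species": sp,
                    "total": len(genes),
                    "pseudogenes": sum(g.status == "pseudogene" for g in genes),
                    "itam_itam_like": sum(
                        g.receptor_class in ACTIVATING_CLASSES for g in expressed
                    ),
                    "itim_itsm": sum(
                        g.receptor_class in INHIBITORY_CLASSES for g in expressed
                    ),
                    "secreted": sum(g.anchor_class == "secreted" for g in expressed),
                }
            )
        return pd.DataFrame(rows)


def check_splice_sites(exon: ExonModel) -> SpliceReport:
    """Validate GT-AG dinucleotides; terminal (empty) ends are skipped."""
    acc, don = exon.acceptor_dinucleotide, exon.donor_dinucleotide
    return SpliceReport(
        acceptor_valid=(acc.upper() == "AG"),
        donor_valid=(don.upper() == "GT"),
        acceptor_checked=bool(acc),
        donor_checked=bool(don),
    )


def _exon_lesions(exon: ExonModel, label: str) -> list[str]:
    reasons = []
    aa = translate(exon.sequence, exon.frame_offset)
    if "*" in aa:
        reasons.append(f"stop in {label} exon")
    rep = check_splice_sites(exon)
    if rep.acceptor_checked and not rep.acceptor_valid:
        reasons.append(f"invalid splice acceptor on {label} exon")
    if rep.donor_checked and not rep.donor_valid:
        reasons.append(f"invalid splice donor on {label} exon")
    return reasons


def call_pseudogene(gene: GeneModel, mode: str = "default") -> tuple[str, list[str]]:
    """Apply the pseudogene rules; returns (status, reasons) and updates the gene.

    Default mode inspects the N exon(s) for in-frame stops and invalid splice
    sites; "opossum" mode additionally treats the same lesions on the leader
    exon as pseudogenizing.
    """
    n_exons = gene.exons_of_type("N")
    if not n_exons:
        raise StructureError(f"{gene.gene_id}: no N exon")
    reasons: list[str] = []
    for exon in n_exons:
        reasons.extend(_exon_lesions(exon, "N"))
    if mode == "opossum":
        for exon in gene.exons_of_type("L"):
            reasons.extend(_exon_lesions(exon, "L"))
    gene.status = "pseudogene" if reasons else "gene"
    gene.status_reasons = reasons
    return gene.status, reasons


@dataclass
class ReadthroughReport:
    """In-frame stops reached when a defective donor reads into the intron."""

    stop_codon_numbers: list[int]  # 1-based read-through codon indices
    stop_nt_offsets: list[int]  # 0-based offsets into `downstream`
    truncated: bool
    product_class: str  # "secreted-truncated" or "intact-readthrough"


def detect_donor_readthrough(
    exon: ExonModel, downstream: str, scan_nt: int = 60, max_stops: int = 2
) -> ReadthroughReport:
    """Translate past a defective donor site and report early in-frame stops.

    The reading frame continues from the exon: nucleotides left over beyond
    the exon's last complete codon are prepended to ``downstream``.  The first
    ``max_stops`` stops whose codons begin within ``scan_nt`` nucleotides of
    the intron are reported; finding any stop classifies the product
    "secreted-truncated".
    """
    rep = check_splice_sites(exon)
    if not rep.donor_checked or rep.donor_valid:
        raise ContractError("donor site is valid; read-through not applicable")
    carry_len = (len(exon.sequence) - exon.frame_offset) % 3
    carry = exon.sequence[len(exon.sequence) - carry_len :] if carry_len else ""
    frame = carry + downstream[: scan_nt + 3]
    stop_numbers: list[int] = []
    stop_offsets: list[int] = []
    for k in range(0, len(frame) - 2, 3):
        codon = frame[k : k + 3].upper()
        offset = k - carry_len  # 0-based into downstream (codon may start in carry)
        if offset >= scan_nt:
            break
        if translate(codon) == "*":
            stop_numbers.append(k // 3 + 1)
            stop_offsets.append(offset)
            if len(stop_numbers) >= max_stops:
                break
    truncated = bool(stop_numbers)
    return ReadthroughReport(
        stop_codon_numbers=stop_numbers,
        stop_nt_offsets=stop_offsets,
        truncated=truncated,
        product_class="secreted-truncated" if truncated else "intact-readthrough",
    )


def p_distance(a: str, b: str) -> float:
    """Uncorrected mismatch fraction over positions where both are plain A/C/G/T."""
    plain = set("ACGT")
    used = mism = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in plain and y in plain:
            used += 1
            if x != y:
                mism += 1
    return mism / used if used else 0.0


def cluster_n_exons(
    seqs: list[Sequence], threshold: float = 0.01
) -> tuple[list[list[str]], int]:
    """Single-linkage clustering of N-exon sequences at a divergence threshold.

    Sequences whose pairwise p-distance is <= threshold are joined; the
    number of resulting clusters is the distinct-gene count under the
    ">1% divergence" counting rule.  Returns (clusters, count) with clusters
    sorted by first-member input order.
    """
    n = len(seqs)
    if n == 0:
        return [], 0
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if p_distance(seqs[i].residues, seqs[j].residues) <= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, s in enumerate(seqs):
        groups.setdefault(find(i), []).append(s.id)
    clusters = sorted(groups.values(), key=lambda ids: min(
        i for i, s in enumerate(seqs) if s.id in ids
    ))
    return clusters, len(clusters)


def aa_identity(a: str, b: str) -> float:
    """Fraction of identical residues over gap-free aligned positions."""
    used = same = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            used += 1
            if x == y:
                same += 1
    return same / used if used else 0.0


def assign_receptor_class(gene: GeneModel) -> str:
    """Classify the cytoplasmic translation and store the label on the gene."""
    aa = gene.cytoplasmic_translation().replace("*", "")
    gene.receptor_class = classify_cytoplasmic(aa).label if aa else "none"
    return gene.receptor_class


def pair_receptors(
    catalog: FamilyCatalog,
    n_domain_aa: dict[str, str],
    identity_floor: float = 0.80,
) -> list[PairedReceptorCandidate]:
    """Match each inhibitory gene to its best same-species activating partner.

    For every expressed inhibitory gene the activating gene of the same
    species with maximal N-domain amino-acid identity is emitted, provided
    the identity reaches ``identity_floor``.  Ties break on gene_id so the
    output is invariant to input order.
    """
    expressed = [g for g in catalog.genes if g.status == "gene"]
    inhibitory = sorted(
        (g for g in expressed if g.receptor_class in INHIBITORY_CLASSES),
        key=lambda g: g.gene_id,
    )
    activating = [g for g in expressed if g.receptor_class in ACTIVATING_CLASSES]
    out: list[PairedReceptorCandidate] = []
    for inh in inhibitory:
        if inh.gene_id not in n_domain_aa:
            continue
        best: tuple[float, str] | None = None
        for act in sorted(activating, key=lambda g: g.gene_id):
            if act.species != inh.species or act.gene_id not in n_domain_aa:
                continue
            ident = aa_identity(n_domain_aa[inh.gene_id], n_domain_aa[act.gene_id])
            if best is None or ident > best[0]:
                best = (ident, act.gene_id)
        if best is not None and best[0] >= identity_floor:
            out.append(
                PairedReceptorCandidate(
                    inhibitory_gene=inh.gene_id,
                    activating_gene=best[1],
                    n_identity=best[0],
                    species=inh.species,
                )
            )
    return out


def read_gene_table(path) -> list[GeneModel]:
    """Read the gene-structure TSV (one row per exon) into gene models."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = set(GENE_TABLE_COLUMNS) - {"anchor_class"} - set(df.columns)
    if missing:
        raise StructureError(f"{path}: gene table missing columns {sorted(missing)}")
    genes: list[GeneModel] = []
    for gene_id, grp in df.groupby("gene_id", sort=False):
        grp = grp.sort_values("exon_index", key=lambda s: s.astype(int))
        exons = [
            ExonModel(
                exon_type=row["exon_type"],
                sequence=row["sequence"].upper(),
                acceptor_dinucleotide=row["acceptor"],
                donor_dinucleotide=row["donor"],
                intron_phase_after=int(row["phase_after"]),
                frame_offset=int(row["frame_offset"]),
            )
            for _, row in grp.iterrows()
        ]
        anchor = (
            grp["anchor_class"].iloc[0]
            if "anchor_class" in grp.columns and grp["anchor_class"].iloc[0]
            else "transmembrane"
        )
        genes.append(
            GeneModel(
                gene_id=str(gene_id),
                species=grp["species"].iloc[0],
                exons=exons,
                anchor_class=anchor,
            )
        )
    return genes


def write_gene_table(genes: list[GeneModel], path) -> None:
    rows = []
    for g in genes:
        for idx, e in enumerate(g.exons):
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "species": g.species,
                    "exon_index": idx,
                    "exon_type": e.exon_type,
                    "acceptor": e.acceptor_dinucleotide,
                    "donor": e.donor_dinucleotide,
                    "phase_after": e.intron_phase_after,
                    "frame_offset": e.frame_offset,
                    "sequence": e.sequence,
                    "anchor_class": g.anchor_class,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
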