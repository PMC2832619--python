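"""Synthetic gene families with known ground truth.

Two generators drive the test bench:

``simulate_codon_evolution``
    evolves a random sense-codon sequence down a tree under a
    proposal/acceptance process: nucleotide changes are proposed uniformly at
    rate ``mu`` per site, accepted with probability 1 when synonymous,
    ``omega`` when nonsynonymous and 0 when they would create a stop codon.
    The realized dN/dS of the process approximates ``omega``, giving an
    estimator-recovery oracle without a full codon-model matrix.

``simulate_gene_family``
    assembles exon-structured genes (leader, N, A, optional TM and
    cytoplasmic exons) whose N exons form clusters at configured divergences,
    whose cytoplasmic translations carry a chosen signalling-motif class
    (guaranteed pure by rejection sampling against the scanner), with
    optional pseudogenizing lesions and implanted conversion tracts between
    designated paralog pairs.  Every generated feature is recorded in a
    :class:`SimTruth` for pipeline-versus-truth comparisons.

All randomness flows from a single mandatory seed; identical configurations
produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import ConfigError, GenerationError
from .genes import ExonModel, FamilyCatalog, GeneModel
from .motifs import classify_cytoplasmic
from .seqio import (
    GENETIC_CODE,
    NT_ALPHABET,
    SENSE_CODONS,
    CodonAlignment,
    Sequence,
    build_codon_alignment,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "GeneSpec",
    "FamilyConfig",
    "ConversionTract",
    "simulate_codon_evolution",
    "implant_conversion",
    "simulate_gene_family",
    "random_tree",
]

_CODONS_BY_AA: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _CODONS_BY_AA.setdefault(GENETIC_CODE[_c], []).append(_c)

# Background alphabet for cytoplasmic exons: no Y (anchors every tyrosine
# motif) and no D/E (would acidify an ITAM-like context).
_CYT_BACKGROUND = "ACFGHIKLMNPQRSTVW"

_MOTIF_EXEMPLARS: dict[str, list[tuple[str, str, int]]] = {
    # class -> [(motif name, exemplar, implant offset)]
    "ITIM_ITSM": [("ITIM", "SVYACL", 5), ("ITSM", "TEYSSV", 25)],
    "ITIM_ITIM": [("ITIM", "SVYACL", 5), ("ITIM", "IVYAAV", 25)],
    "ITIM_only": [("ITIM", "SVYACL", 10)],
    "ITAM": [("ITAM", "EAAYAALAAAAAAYAAI", 10)],
    "ITAM_like": [("ITAM_like", "YAALAAAAAAYAAI", 10)],
    "none": [],
}


@dataclass
class SimConfig:
    """Configuration of a codon-alignment simulation."""

    n_codons: int
    omega: float
    seed: int
    tree: str | None = None  # newick; when None a random tree is drawn
    n_taxa: int = 7
    branch_scale: float = 0.06  # mean branch length (proposals per nt site)
    mu: float = 1.0

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ConfigError("omega must be >= 0")
        if self.n_codons < 1:
            raise ConfigError("n_codons must be >= 1")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


@dataclass
class ConversionTract:
    donor: str
    acceptor: str
    start_codon: int  # 0-based
    length: int


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    tree_newick: str | None = None
    omega: dict[str, float] = field(default_factory=dict)
    conversions: list[ConversionTract] = field(default_factory=list)
    motifs: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    lesions: dict[str, str] = field(default_factory=dict)
    clusters: list[list[str]] = field(default_factory=list)
    gene_status: dict[str, str] = field(default_factory=dict)
    receptor_class: dict[str, str] = field(default_factory=dict)
    paired: list[tuple[str, str]] = field(default_factory=list)


def _random_codon_sequence(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def random_tree(n_taxa: int, scale: float, rng: np.random.Generator) -> dendropy.Tree:
    """Random topology by successive joins; branch lengths ~ Exp(scale)."""
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels]
    for node in nodes:
        node.edge.length = float(rng.exponential(scale))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(scale))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns)
    for n in nodes:
        tree.seed_node.add_child(n)
    tree.is_rooted = True
    return tree


def _apply_proposals(seq: str, n_events: int, omega: float, rng: np.random.Generator) -> str:
    """Apply a proposal/acceptance mutation process to a codon sequence."""
    s = list(seq)
    L = len(s)
    for _ in range(n_events):
        pos = int(rng.integers(0, L))
        cur = s[pos]
        alts = [b for b in NT_ALPHABET if b != cur]
        alt = alts[int(rng.integers(0, 3))]
        cstart = pos - pos % 3
        old_codon = "".join(s[cstart : cstart + 3])
        new_codon = old_codon[: pos - cstart] + alt + old_codon[pos - cstart + 1 :]
        if GENETIC_CODE[new_codon] == "*":
            continue  # stops are rejected outright
        if GENETIC_CODE[new_codon] != GENETIC_CODE[old_codon] and rng.random() >= omega:
            continue
        s[pos] = alt
    return "".join(s)


def simulate_codon_evolution(cfg: SimConfig) -> tuple[CodonAlignment, SimTruth]:
    """Evolve a codon alignment along a tree under the acceptance process."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.tree is not None:
        tree = dendropy.Tree.get(data=cfg.tree, schema="newick")
    else:
        tree = random_tree(cfg.n_taxa, cfg.branch_scale, rng)
    root_seq = _random_codon_sequence(cfg.n_codons, rng)
    seqs: dict[int, str] = {id(tree.seed_node): root_seq}
    rows: list[Sequence] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        bl = node.edge.length or 0.0
        n_events = int(rng.poisson(cfg.mu * bl * 3 * cfg.n_codons))
        seqs[id(node)] = _apply_proposals(parent_seq, n_events, cfg.omega, rng)
        if node.is_leaf():
            rows.append(Sequence(node.taxon.label, seqs[id(node)], "nt"))
    rows.sort(key=lambda r: r.id)
    aln = build_codon_alignment(rows)
    truth = SimTruth(
        tree_newick=tree.as_string(schema="newick").strip(),
        omega={r.id: cfg.omega for r in rows},
    )
    return aln, truth


def implant_conversion(
    aln: CodonAlignment,
    donor: str | int,
    acceptor: str | int,
    start_codon: int,
    length: int,
) -> tuple[CodonAlignment, ConversionTract]:
    """Copy the donor row's codons over the acceptor's within a tract."""
    labels = aln.labels()
    di = labels.index(donor) if isinstance(donor, str) else donor
    ai = labels.index(acceptor) if isinstance(acceptor, str) else acceptor
    if length < 0 or start_codon < 0 or start_codon + length > aln.n_codons:
        raise ConfigError(
            f"tract [{start_codon}, {start_codon + length}) outside [0, {aln.n_codons})"
        )
    tract = ConversionTract(labels[di], labels[ai], start_codon, length)
    if length == 0:
        return aln, tract
    lo, hi = 3 * start_codon, 3 * (start_codon + length)
    donor_res = aln.rows[di].residues
    rows = []
    for k, row in enumerate(aln.rows):
        if k == ai:
            res = row.residues[:lo] + donor_res[lo:hi] + row.residues[hi:]
            rows.append(Sequence(row.id, res, row.alphabet))
        else:
            rows.append(row)
    return build_codon_alignment(rows), tract


# ---------------------------------------------------------------------------
# gene-family generation


@dataclass
class GeneSpec:
    """Directives for one synthetic gene."""

    gene_id: str
    species: str = "sim"
    motif_class: str = "none"
    anchor_class: str = "transmembrane"
    cluster: int = 0
    member_divergence: float = 0.002  # nt divergence from the cluster founder
    derive_from: str | None = None  # derive the N exon from another gene's
    codon_t: float | None = None  # proposal rate/site for codon-process derivation
    codon_omega: float = 0.3
    lesion: str | None = None  # stop_in_N | bad_donor_N | bad_acceptor_N |
    #                            leader_stop | leader_bad_donor


@dataclass
class FamilyConfig:
    """Configuration of a synthetic gene family."""

    genes: list[GeneSpec]
    seed: int
    n_codons: int = 120  # N exon length (first 12 codons encode leader residues)
    cyt_len: int = 60  # cytoplasmic translation length (residues)
    cluster_divergence: dict[int, float] = field(default_factory=dict)
    conversions: list[ConversionTract] = field(default_factory=list)
    pseudogene_mode: str = "default"
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate gene_id in family config")
        for t in self.conversions:
            if t.start_codon < 0 or t.start_codon + t.length > self.n_codons:
                raise ConfigError("conversion tract outside the N exon")


def _exact_mutate(nt: str, p: float, rng: np.random.Generator) -> str:
    """Substitute round(p * len) distinct sites, never creating a stop codon."""
    n_sub = int(round(p * len(nt)))
    if n_sub == 0:
        return nt
    s = list(nt)
    sites = list(rng.choice(len(nt), size=min(n_sub, len(nt)), replace=False))
    for pos in sites:
        cstart = pos - pos % 3
        alts = [b for b in NT_ALPHABET if b != s[pos]]
        rng.shuffle(alts)
        for alt in alts:
            codon = "".join(s[cstart:cstart + 3])
            codon = codon[: pos - cstart] + alt + codon[pos - cstart + 1 :]
            if GENETIC_CODE[codon] != "*":
                s[pos] = alt
                break
    return "".join(s)


def _nonsense_mutate(nt: str, from_codon: int) -> str:
    """Introduce an in-frame stop by a single point mutation at/after a codon."""
    n_codons = len(nt) // 3
    for c in list(range(from_codon, n_codons)) + list(range(from_codon)):
        codon = nt[3 * c : 3 * c + 3]
        for pos in range(3):
            for alt in NT_ALPHABET:
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                if GENETIC_CODE[mut] == "*":
                    return nt[: 3 * c] + mut + nt[3 * c + 3 :]
    raise GenerationError("no single-mutation nonsense site found")


def _reverse_translate(aa: str, rng: np.random.Generator) -> str:
    out = []
    for res in aa:
        options = _CODONS_BY_AA[res]
        out.append(options[int(rng.integers(0, len(options)))])
    return "".join(out)


def _cytoplasmic_aa(motif_class: str, cyt_len: int, rng: np.random.Generator,
                    max_attempts: int) -> tuple[str, list[tuple[str, int]]]:
    """Background + implanted exemplars whose class label is exactly the target."""
    implants = _MOTIF_EXEMPLARS[motif_class]
    for _ in range(max_attempts):
        bg = rng.integers(0, len(_CYT_BACKGROUND), size=cyt_len)
        aa = [
            _CYT_BACKGROUND[i] for i in bg
        ]
        coords = []
        for motif, exemplar, offset in implants:
            aa[offset : offset + len(exemplar)] = list(exemplar)
            coords.append((motif, offset))
        seq = "".join(aa)
        if classify_cytoplasmic(seq).label == motif_class:
            return seq, coords
    raise GenerationError(
        f"could not generate a pure {motif_class!r} cytoplasmic exon "
        f"in {max_attempts} attempts"
    )


_PSEUDOGENIZING = {
    "default": {"stop_in_N", "bad_donor_N", "bad_acceptor_N"},
    "opossum": {
        "stop_in_N",
        "bad_donor_N",
        "bad_acceptor_N",
        "leader_stop",
        "leader_bad_donor",
    },
}


def simulate_gene_family(cfg: FamilyConfig) -> tuple[FamilyCatalog, SimTruth]:
    """Generate an exon-structured gene family with full ground truth."""
    rng = np.random.default_rng(cfg.seed)
    ancestor = _random_codon_sequence(cfg.n_codons, rng)
    founders = {
        k: _exact_mutate(ancestor, p, rng)
        for k, p in sorted(cfg.cluster_divergence.items())
    }
    leader_nt = "ATG" + _random_codon_sequence(11, rng)
    a_exon_base = _random_codon_sequence(30, rng)
    tm_base = _random_codon_sequence(22, rng)

    n_seqs: dict[str, str] = {}
    truth = SimTruth()
    for spec in cfg.genes:
        if spec.derive_from is not None:
            if spec.derive_from not in n_seqs:
                raise ConfigError(
                    f"{spec.gene_id}: derive_from {spec.derive_from!r} not yet generated"
                )
            base = n_seqs[spec.derive_from]
        else:
            base = founders.get(spec.cluster, ancestor)
        if spec.codon_t is not None:
            n_events = int(rng.poisson(spec.codon_t * len(base)))
            n_seq = _apply_proposals(base, n_events, spec.codon_omega, rng)
        else:
            n_seq = _exact_mutate(base, spec.member_divergence, rng)
        n_seqs[spec.gene_id] = n_seq

    for tract in cfg.conversions:
        donor_seq = n_seqs[tract.donor]
        acc = n_seqs[tract.acceptor]
        lo, hi = 3 * tract.start_codon, 3 * (tract.start_codon + tract.length)
        n_seqs[tract.acceptor] = acc[:lo] + donor_seq[lo:hi] + acc[hi:]
        truth.conversions.append(tract)

    genes: list[GeneModel] = []
    cluster_members: dict[object, list[str]] = {}
    for spec in cfg.genes:
        n_seq = n_seqs[spec.gene_id]
        leader = leader_nt
        lesion = spec.lesion
        n_donor, n_acceptor = "GT", "AG"
        l_donor = "GT"
        if lesion == "stop_in_N":
            n_seq = _nonsense_mutate(n_seq, cfg.n_codons // 2)
        elif lesion == "bad_donor_N":
            n_donor = "AT"
        elif lesion == "bad_acceptor_N":
            n_acceptor = "AA"
        elif lesion == "leader_stop":
            leader = leader_nt[:6] + "TGA" + leader_nt[9:]
        elif lesion == "leader_bad_donor":
            l_donor = "AT"
        elif lesion is not None:
            raise ConfigError(f"unknown lesion {lesion!r}")
        n_seqs[spec.gene_id] = n_seq

        exons = [
            ExonModel("L", leader, "", l_donor, 0, 0),
            ExonModel("N", n_seq, n_acceptor, n_donor, 0, 0),
            ExonModel("A", _exact_mutate(a_exon_base, 0.01, rng), "AG", "GT", 0, 0),
        ]
        if spec.anchor_class == "transmembrane":
            exons.append(ExonModel("TM", _exact_mutate(tm_base, 0.01, rng), "AG", "GT", 0, 0))
            aa, coords = _cytoplasmic_aa(
                spec.motif_class, cfg.cyt_len, rng, cfg.max_attempts
            )
            exons.append(
                ExonModel("Cyt1", _reverse_translate(aa, rng), "AG", "", 0, 0)
            )
            truth.motifs[spec.gene_id] = coords
        else:
            exons[-1].donor_dinucleotide = ""
            truth.motifs[spec.gene_id] = []
        genes.append(
            GeneModel(
                gene_id=spec.gene_id,
                species=spec.species,
                exons=exons,
                anchor_class=spec.anchor_class,
            )
        )
        pseudo = lesion in _PSEUDOGENIZING[cfg.pseudogene_mode] if lesion else False
        truth.gene_status[spec.gene_id] = "pseudogene" if pseudo else "gene"
        truth.receptor_class[spec.gene_id] = (
            spec.motif_class if spec.anchor_class == "transmembrane" else "none"
        )
        if lesion:
            truth.lesions[spec.gene_id] = lesion
        key = spec.gene_id if spec.derive_from or spec.codon_t else spec.cluster
        cluster_members.setdefault(key, []).append(spec.gene_id)

    truth.clusters = list(cluster_members.values())
    return FamilyCatalog(genes=genes), truth


def truth_as_records(truth: SimTruth) -> list[dict]:
    """Flatten a :class:`SimTruth` for TSV export."""
    rows = []
    for gid, status in truth.gene_status.items():
        rows.append(
            {
                "gene_id": gid,
                "status": status,
                "receptor_class": truth.receptor_class.get(gid, "none"),
                "lesion": truth.lesions.get(gid, ""),
                "motifs": ";".join(f"{m}@{o}" for m, o in truth.motifs.get(gid, [])),
            }
        )
    return rows
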