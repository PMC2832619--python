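"""Distance matrices, neighbour joining, bootstrap supports and newick I/O.

Distances use pairwise-complete deletion (a site is used for a pair only when
both rows carry an unambiguous residue) under four models: raw mismatch
fraction for nucleotides (``p_nt``) or amino acids (``p_aa``), the
one-parameter nucleotide correction ``jc69_nt`` = -(3/4) ln(1 - 4p/3) and the
Poisson amino-acid correction ``poisson_aa`` = -ln(1 - p).

Neighbour joining follows the classical rate-adjusted agglomeration.  For
reproducibility two conventions are fixed: ties in the pair-selection
criterion break on the lexicographically smallest taxon-label pair (each
cluster represented by its smallest member label) and negative intermediate
branch lengths are clamped to zero.  Trees are dendropy objects; bootstrap
supports (percent of replicates containing each internal bipartition of the
point-estimate tree) are stored as internal-node labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import ParseError, SaturationError
from .seqio import CodonAlignment, Sequence

__all__ = [
    "DistanceMatrix",
    "distance_matrix",
    "nj",
    "bootstrap",
    "write_newick",
    "read_newick",
    "tree_distance_matrix",
    "bipartitions",
]

_VALID_NT = set("ACGT")
_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

MODELS = ("p_nt", "jc69_nt", "p_aa", "poisson_aa")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("matrix entries must be finite and non-negative")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])


def _p_distance(a: str, b: str, valid: set[str]) -> float:
    used = mism = 0
    for x, y in zip(a, b):
        if x in valid and y in valid:
            used += 1
            if x != y:
                mism += 1
    return mism / used if used else 0.0


def distance_matrix(rows: list[Sequence], model: str = "p_nt") -> DistanceMatrix:
    """Pairwise distances under the named model with pairwise-complete deletion."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if len(rows) < 2:
        raise ValueError("need at least two sequences")
    valid = _VALID_NT if model.endswith("_nt") else _VALID_AA
    n = len(rows)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = _p_distance(rows[i].residues, rows[j].residues, valid)
            if model == "jc69_nt":
                if p >= 0.75:
                    raise SaturationError(
                        f"p={p:.4f} >= 3/4 for pair ({rows[i].id}, {rows[j].id})"
                    )
                d = -0.75 * math.log1p(-4.0 * p / 3.0)
            elif model == "poisson_aa":
                if p >= 1.0:
                    raise SaturationError(
                        f"p={p:.4f} >= 1 for pair ({rows[i].id}, {rows[j].id})"
                    )
                d = -math.log1p(-p)
            else:
                d = p
            m[i, j] = m[j, i] = d
    return DistanceMatrix([r.id for r in rows], m)


def nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbour-joining tree from a distance matrix (>= 3 taxa).

    Returns an unrooted dendropy tree whose seed node has degree 3.  Exact on
    additive matrices; tie-breaking and clamping conventions are fixed in the
    module docstring.
    """
    if dm.n < 3:
        raise ValueError(f"neighbour joining needs >= 3 taxa, got {dm.n}")
    tns = dendropy.TaxonNamespace(dm.labels)
    nodes: dict[int, dendropy.Node] = {}
    reps: dict[int, str] = {}
    lengths: dict[int, float] = {}  # pending edge length of each active cluster
    D: dict[tuple[int, int], float] = {}
    for i, lab in enumerate(dm.labels):
        nodes[i] = dendropy.Node(taxon=tns.get_taxon(lab))
        reps[i] = lab
    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            D[(i, j)] = float(dm.matrix[i, j])

    def d(a: int, b: int) -> float:
        return D[(a, b) if a < b else (b, a)]

    active = list(range(dm.n))
    next_id = dm.n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best_key = None
        best_pair = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                tie = tuple(sorted((reps[i], reps[j])))
                key = (q, tie)
                if best_key is None or key < best_key:
                    best_key = key
                    best_pair = (i, j)
        i, j = best_pair
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d(i, j) - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        u.add_child(nodes[i])
        u.add_child(nodes[j])
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            key = (k, next_id) if k < next_id else (next_id, k)
            D[key] = dk
        nodes[next_id] = u
        reps[next_id] = min(reps[i], reps[j])
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    tree = dendropy.Tree(taxon_namespace=tns)
    for k, lk in zip((a, b, c), (la, lb, lc)):
        nodes[k].edge.length = max(lk, 0.0)
        tree.seed_node.add_child(nodes[k])
    tree.is_rooted = False
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as leaf-label sets, complement-normalized."""
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    ref = min(leaves)
    n = len(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(leaves) - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def _resample(rows: list[Sequence], idx: np.ndarray, unit: int) -> list[Sequence]:
    out = []
    for r in rows:
        s = r.residues
        parts = [s[unit * c : unit * (c + 1)] for c in idx]
        out.append(Sequence(r.id, "".join(parts), r.alphabet))
    return out


def bootstrap(
    aln,
    model: str = "p_nt",
    B: int = 100,
    seed: int = 0,
    builder=nj,
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """Bootstrap supports for the NJ point-estimate tree.

    Codon alignments resample codon columns (preserving frame structure);
    plain sequence lists resample sites.  Support is the percentage of
    replicate trees containing each internal bipartition of the point tree,
    attached as internal-node labels.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if isinstance(aln, CodonAlignment):
        rows, unit, ncol = aln.rows, 3, aln.n_codons
    else:
        rows, unit, ncol = list(aln), 1, len(aln[0].residues)
    rng = np.random.default_rng(seed)
    point = builder(distance_matrix(rows, model))
    target = bipartitions(point)
    counts = {bp: 0 for bp in target}
    for _ in range(B):
        idx = rng.integers(0, ncol, size=ncol)
        rep_tree = builder(distance_matrix(_resample(rows, idx, unit), model))
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / B for bp, c in counts.items()}
    leaves = [lf.taxon.label for lf in point.leaf_node_iter()]
    ref = min(leaves)
    for node in point.preorder_node_iter():
        if node is point.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(leaves) - side
        if side in supports:
            node.label = f"{supports[side]:g}"
    return point, supports


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with 6-decimal branch lengths; supports stay as node labels."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    ).strip() + "\n"


def read_newick(text: str) -> dendropy.Tree:
    """Parse newick text; malformed input raises :class:`ParseError`."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise ParseError(f"malformed newick: {exc}") from exc
    return tree


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (labels sorted)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pdm.distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, m)
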