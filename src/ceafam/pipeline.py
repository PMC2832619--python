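"""End-to-end analysis: classify -> count -> tree -> dN/dS -> pairs -> conversion.

The pipeline consumes a gene-structure table (one row per exon, sequences
inline), applies the delineation rules, clusters N exons for the distinct-gene
count, builds a bootstrapped NJ tree of the N exons, computes pairwise dN/dS
and the codon-wise substitution profile with conserved-region delineation,
pairs inhibitory with activating receptors by N-domain identity, and runs the
conversion permutation test on each candidate pair.  All stochastic steps
derive from the single run seed; identical config + seed yields identical
reports.

Reports are TSV with a one-line header and a ``#`` metadata preamble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .codon import (
    delineate_conserved_regions,
    dnds_summary,
    ng_pairwise,
    substitution_profile,
)
from .conversion import conversion_test, syn_diff_track
from .errors import CeafamError, ConfigError, InapplicableTestError
from .genes import (
    FamilyCatalog,
    assign_receptor_class,
    call_pseudogene,
    cluster_n_exons,
    pair_receptors,
    read_gene_table,
)
from .phylo import bootstrap, write_newick
from .seqio import Sequence, build_codon_alignment, translate

log = logging.getLogger("ceafam")

_LEVELS = {"quiet": logging.WARNING, "info": logging.INFO, "debug": logging.DEBUG}


@dataclass
class RunConfig:
    gene_table: str
    outdir: str | None = None
    distance_model: str = "p_nt"
    bootstrap_B: int = 100
    seed: int = 0
    cluster_threshold: float = 0.01
    pseudogene_mode: str = "default"
    identity_floor: float = 0.80
    conversion_epsilon: float = 0.0
    conversion_B: int = 1000
    leader_codons: int = 12  # N-exon codons encoding leader residues
    conserved_window: int = 10
    conserved_factor: float = 0.5
    conserved_min_len: int = 5
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if not (0.0 < self.cluster_threshold < 1.0):
            raise ConfigError("cluster_threshold must be in (0, 1)")
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.verbosity not in _LEVELS:
            raise ConfigError(f"verbosity must be one of {sorted(_LEVELS)}")


@dataclass
class AnalysisReport:
    catalog: FamilyCatalog
    catalog_table: pd.DataFrame
    species_table: pd.DataFrame
    clusters: list[list[str]]
    cluster_count: int
    tree_newick: str | None = None
    supports: dict = field(default_factory=dict)
    ng_table: pd.DataFrame | None = None
    dnds = None
    profile_table: pd.DataFrame | None = None
    conserved_table: pd.DataFrame | None = None
    pairs: list = field(default_factory=list)
    conversion_calls: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)


def _stage(report: AnalysisReport, name: str):
    """Decorator-free stage guard: returns a context manager recording errors."""

    class _Guard:
        def __enter__(self):
            log.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and issubclass(exc_type, CeafamError):
                report.errors.append(f"{name}: {exc}")
                log.error("stage %s failed: %s", name, exc)
                return True
            return False

    return _Guard()


def run_full_analysis(cfg: RunConfig) -> AnalysisReport:
    """Execute every analysis stage in dependency order."""
    logging.basicConfig()
    log.setLevel(_LEVELS[cfg.verbosity])
    path = Path(cfg.gene_table)
    if not path.exists():
        raise ConfigError(f"gene table not found: {path}")
    genes = read_gene_table(path)
    if not genes:
        raise ConfigError(f"gene table is empty: {path}")

    for g in genes:
        call_pseudogene(g, mode=cfg.pseudogene_mode)
        assign_receptor_class(g)
    catalog = FamilyCatalog(genes=genes)

    n_seqs = [
        Sequence(g.gene_id, g.exons_of_type("N")[0].sequence, "nt") for g in genes
    ]
    clusters, count = cluster_n_exons(n_seqs, threshold=cfg.cluster_threshold)
    catalog.clusters = clusters

    catalog_table = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "species": g.species,
                "status": g.status,
                "status_reasons": "; ".join(g.status_reasons),
                "receptor_class": g.receptor_class,
                "anchor_class": g.anchor_class,
                "cluster": next(
                    ci for ci, cl in enumerate(clusters) if g.gene_id in cl
                ),
            }
            for g in genes
        ]
    )
    report = AnalysisReport(
        catalog=catalog,
        catalog_table=catalog_table,
        species_table=catalog.species_counts(),
        clusters=clusters,
        cluster_count=count,
        metadata={
            "version": __version__,
            "seed": cfg.seed,
            "distance_model": cfg.distance_model,
            "bootstrap_B": cfg.bootstrap_B,
            "cluster_threshold": cfg.cluster_threshold,
            "pseudogene_mode": cfg.pseudogene_mode,
            "dnds_method": "pairwise approximation",
        },
    )

    aln = None
    with _stage(report, "codon_alignment"):
        aln = build_codon_alignment(n_seqs)

    if aln is not None and aln.n_rows >= 3:
        with _stage(report, "nj_bootstrap"):
            log.debug("bootstrap seed=%d B=%d", cfg.seed, cfg.bootstrap_B)
            tree, supports = bootstrap(
                aln, model=cfg.distance_model, B=cfg.bootstrap_B, seed=cfg.seed
            )
            report.tree_newick = write_newick(tree)
            report.supports = supports

    if aln is not None:
        with _stage(report, "dnds"):
            rows = []
            for i in range(aln.n_rows):
                for j in range(i + 1, aln.n_rows):
                    r = ng_pairwise(i, j, aln)
                    rows.append(
                        {
                            "gene_i": aln.rows[i].id,
                            "gene_j": aln.rows[j].id,
                            "S": r.S,
                            "N": r.N,
                            "Sd": r.Sd,
                            "Nd": r.Nd,
                            "dS": r.dS,
                            "dN": r.dN,
                            "omega": r.omega if r.omega is not None else "",
                        }
                    )
            report.ng_table = pd.DataFrame(rows)
            report.dnds = dnds_summary(aln)

        with _stage(report, "profile"):
            prof = substitution_profile(aln)
            report.profile_table = pd.DataFrame(
                {
                    "codon": range(1, prof.n_codons + 1),
                    "mean_syn": prof.mean_syn,
                    "mean_nonsyn": prof.mean_nonsyn,
                    "cum_syn": prof.cum_syn,
                    "cum_nonsyn": prof.cum_nonsyn,
                }
            )
            regions = delineate_conserved_regions(
                prof,
                window=cfg.conserved_window,
                factor=cfg.conserved_factor,
                min_len=cfg.conserved_min_len,
            )
            report.conserved_table = pd.DataFrame(
                [
                    {
                        "start": r.report_coords()[0],
                        "end": r.report_coords()[1],
                        "mean_nonsyn_rate": r.mean_rate,
                        "extended": r.extended,
                    }
                    for r in regions
                ]
            )

    with _stage(report, "paired_receptors"):
        n_domain_aa = {
            g.gene_id: translate(g.exons_of_type("N")[0].sequence)[cfg.leader_codons :]
            for g in genes
        }
        report.pairs = pair_receptors(
            catalog, n_domain_aa, identity_floor=cfg.identity_floor
        )

    if aln is not None:
        with _stage(report, "conversion"):
            labels = aln.labels()
            for cand in report.pairs:
                i = labels.index(cand.inhibitory_gene)
                j = labels.index(cand.activating_gene)
                track = syn_diff_track(i, j, aln)
                try:
                    call = conversion_test(
                        track,
                        epsilon=cfg.conversion_epsilon,
                        B=cfg.conversion_B,
                        seed=cfg.seed,
                    )
                except InapplicableTestError:
                    log.info(
                        "conversion test inapplicable for %s/%s (no synonymous signal)",
                        cand.inhibitory_gene,
                        cand.activating_gene,
                    )
                    continue
                report.conversion_calls.append(call)

    if cfg.outdir:
        write_report(report, cfg.outdir)
    return report


def _write_tsv(df: pd.DataFrame | None, path: Path, metadata: dict) -> None:
    if df is None:
        return
    with open(path, "w") as fh:
        for k, v in metadata.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_report(report: AnalysisReport, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = report.metadata
    _write_tsv(report.catalog_table, out / "catalog.tsv", meta)
    _write_tsv(report.species_table, out / "species_counts.tsv", meta)
    _write_tsv(report.ng_table, out / "ng_pairwise.tsv", meta)
    _write_tsv(report.profile_table, out / "profile.tsv", meta)
    _write_tsv(report.conserved_table, out / "conserved_regions.tsv", meta)
    if report.pairs:
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "inhibitory": p.inhibitory_gene,
                        "activating": p.activating_gene,
                        "n_identity": p.n_identity,
                        "species": p.species,
                    }
                    for p in report.pairs
                ]
            ),
            out / "paired_receptors.tsv",
            meta,
        )
    if report.conversion_calls:
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "inhibitory": c.pair[0],
                        "activating": c.pair[1],
                        "run_start": c.report_coords()[0],
                        "run_end": c.report_coords()[1],
                        "run_length": c.run_length,
                        "p_value": c.p_value,
                    }
                    for c in report.conversion_calls
                ]
            ),
            out / "conversion_calls.tsv",
            meta,
        )
    if report.tree_newick:
        (out / "n_exon_tree.nwk").write_text(report.tree_newick)
    if report.errors:
        (out / "error_manifest.txt").write_text("\n".join(report.errors) + "\n")
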