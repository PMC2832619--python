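"""Packaged demonstration gene family.

A small synthetic family exercising every pipeline stage: an inhibitory
ITIM/ITSM receptor (CC1) and its activating ITAM-like partner (CC3) linked by
an implanted 60-codon conversion tract, an independent ITAM gene (CC5), a
secreted member (CC7), and a pseudogene (CC9) sitting in CC1's N-exon cluster
(within-cluster divergence well under the 1% counting threshold, all other
genes well over it).  The background divergence between CC1 and CC3 is
generated under a purifying codon process (proposal rate 0.5/site,
omega 0.3), which leaves enough synonymous signal outside the tract for the
conversion run test.
"""

from __future__ import annotations

from .simulate import ConversionTract, FamilyConfig, GeneSpec

DEMO_TRACT = ConversionTract(donor="CC1", acceptor="CC3", start_codon=40, length=60)


def demo_family_config(seed: int) -> FamilyConfig:
    """The demonstration family; ground truth is fully determined by ``seed``."""
    genes = [
        GeneSpec("CC1", motif_class="ITIM_ITSM", cluster=0, member_divergence=0.0),
        GeneSpec("CC3", motif_class="ITAM_like", derive_from="CC1",
                 codon_t=0.50, codon_omega=0.3),
        GeneSpec("CC5", motif_class="ITAM", cluster=1, member_divergence=0.002),
        GeneSpec("CC7", motif_class="none", anchor_class="secreted",
                 cluster=2, member_divergence=0.002),
        GeneSpec("CC9", motif_class="ITIM_only", cluster=0,
                 member_divergence=0.004, lesion="stop_in_N"),
    ]
    return FamilyConfig(
        genes=genes,
        seed=seed,
        n_codons=120,
        cyt_len=60,
        cluster_divergence={0: 0.0, 1: 0.12, 2: 0.18},
        conversions=[DEMO_TRACT],
    )


# Expected truth relations that do not depend on the seed.
DEMO_EXPECTED_PAIR = ("CC1", "CC3")
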