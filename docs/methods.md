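# Methods

## Scope and data model

The package analyses exon-structured receptor gene families of the
CEACAM/PSG kind.  Its inputs are codon-alignable nucleotide sequences
(typically N-domain exons of paralogs or orthologs), amino-acid translations
of cytoplasmic domains, and a gene-structure table carrying, per exon, the
type (L, N, A/B, TM, GPI_signal, Cyt1–4), the flanking splice dinucleotides,
the intron phase after the exon (0 = codon|intron|codon, 1 = one codon
nucleotide before the intron, 2 = two before) and the reading-frame offset.
Membrane-anchor class (transmembrane / GPI / secreted) is taken from the
annotation, never predicted.

Gap handling is uniform: a codon column containing a gap or ambiguity
character in any row is excluded from all substitution counting (complete
deletion at codon granularity).  This is a deterministic stand-in for the
manual, protein-guided gap editing traditionally applied before such
analyses; it discards slightly more data but is reproducible.  Distance
computation for tree building instead uses pairwise-complete deletion at
site level, the convention of the distance packages it mirrors.  Coordinates
are 0-based half-open internally; all report files print 1-based positions.

## Substitution counting and dN/dS

Counting follows the classical unweighted synonymous/nonsynonymous scheme.
Each sense codon contributes s = (number of synonymous one-nucleotide
neighbours)/3 synonymous sites per position, so s + n = 3 exactly; mutations
creating stops count as nonsynonymous.  Differences between two codons
differing at k positions are averaged over the k! mutational orderings;
orderings passing through a stop codon are excluded from the average, and
when every ordering is blocked the average falls back to all orderings with
stop steps counted nonsynonymous.  Both tables (61 codons, 61 × 61 pairs)
are precomputed at import.

Proportions pS = Sd/S and pN = Nd/N (sites averaged over the two sequences)
are corrected for multiple hits with the one-parameter formula
d = −(3/4) ln(1 − 4p/3), which is undefined at p ≥ 3/4 (a saturation error
naming the pair).  ω = dN/dS is reported only where dS > 0 — never as
infinity.  A subtlety worth knowing: pathway averaging can attribute
fractional nonsynonymous steps to a codon that experienced two synonymous
substitutions (one ordering may pass through a different amino acid), so
even a strictly protein-preserving history can yield a tiny positive dN.
The invariant that a ω = 0 process does force is identity of the translated
proteins.

Alignment-level summaries (mean ω ± SD) are computed over all unordered
sequence pairs with defined ω — a pairwise approximation to branch-wise
rates; reports carry the tag `pairwise approximation`.  Pairs whose
proportions saturate are skipped and counted rather than aborting the
summary.  The SD is the sample standard deviation (ddof = 1).

Per-codon substitution profiles average the pathway-averaged codon
differences over all pairs (excluded codons contribute zero and are
flagged); cumulative sums of the two tracks are the tabular analogue of
cumulative-substitution plots, and the final cumulative value × 100/L is the
per-100-codon rate.  Conserved regions are delineated on the nonsynonymous
track: a centred sliding mean (window 10 codons, truncated at the edges) is
thresholded at 0.5 × the exon-wide mean, below-threshold positions are
merged into maximal runs, runs of ≥ 5 codons are reported and runs longer
than 20 codons are flagged *extended*.  Window, factor and minimum length
are configurable; the defaults operationalize what is otherwise a visual
call on a plotted profile.  A track with zero overall mean returns the whole
exon as one region.

## Phylogenetics

Distances: raw mismatch proportion for nucleotides or amino acids,
−(3/4) ln(1 − 4p/3) for corrected nucleotide distances, and the Poisson
correction −ln(1 − p) for amino acids.  Neighbour joining is the standard
rate-adjusted agglomeration with two conventions fixed for reproducibility:
ties in the pair-selection criterion break on the lexicographically smallest
taxon-label pair (each cluster represented by its smallest member label),
and negative intermediate branch-length estimates are clamped to zero.  On
additive matrices the algorithm is exact (verified on random tree metrics up
to 12 taxa).  Trees are dendropy objects; newick serialization keeps branch
lengths to six decimals and stores bootstrap supports as internal-node
labels.

Bootstrap supports resample alignment columns with replacement — codon
columns when the input is a codon alignment, so codon structure survives
resampling — rebuild the tree per replicate, and report for every internal
bipartition of the point-estimate tree the percentage of replicates
containing it.  Given a seed the procedure is fully deterministic.

## Gene family rules

- **Splice validity**: acceptor `AG`, donor `GT`; terminal exon ends are
  skipped.
- **Pseudogene**: an in-frame stop in the N exon or an invalid splice site
  on it; in opossum mode the same lesions on the leader exon also count.
  The call is monotone — adding a lesion can never rescue a gene.
- **Donor read-through**: for a defective donor, translation continues from
  the exon's last complete codon into the intron; the first (up to two)
  in-frame stops whose codons begin within 60 nt are reported and the
  product classed secreted-truncated.  This captures the mechanism by which
  large sets of secreted family members arise from membrane-bound
  ancestors.
- **Gene counting**: distinct N exons are counted by single-linkage
  clustering at uncorrected nucleotide p-distance ≤ 1% (configurable).
  Single linkage was chosen because the counting rule describes
  connectivity ("distinct exons"), not centroids; the distance is computed
  over positions where both sequences carry plain A/C/G/T.  Whether the
  historical rule used nucleotides or amino acids is not documented;
  nucleotide p-distance is this package's convention.
- **Paired receptors**: every expressed inhibitory gene (ITIM/ITSM classes)
  is matched to the same-species activating gene (ITAM/ITAM-like) of
  maximal N-domain amino-acid identity, emitted when identity ≥ 0.80.  The
  floor is a package default, exposed in configuration; ties break on gene
  identifier so results are input-order invariant.

## Motif grammar

Patterns are fixed character-class windows (see the README table).  Spacer
patterns report every admissible spacer length as a separate hit;
classification counts distinct first-tyrosine offsets, so nested spacer
variants of one physical motif count once.  An ITAM-like hit whose tyrosine
pair also satisfies the full ITAM is suppressed.  The acidic residue of the
ITAM may sit 1–3 positions before the first tyrosine.  Both spellings of the
membrane-proximal box (`TEHKxS` and `THEKxS`) are scanned, the second
flagged as a variant, since both circulate in the literature.  The
second-half inspection (`itam_second_half_variant`) flags the `YxxM`
(Vav-binding) variant found in some activating members; the scanner's own
ITAM pattern requires `Yxx(L/I)`, so the flag is meaningful for hits
constructed from relaxed or manual annotation.

Classification precedence is ITAM > ITAM-like > ITIM+ITSM > two ITIMs > one
ITIM > none, mirroring how receptor function is assigned: any activating
motif dominates, then the richest inhibitory configuration.

## Gene-conversion detection

Recent conversion between paralogs leaves a tract where synonymous
divergence is absent while the flanks have accumulated it.  The statistic is
the length of the longest run of codons whose pathway-averaged synonymous
difference is ≤ ε (default ε = 0, reading "no accumulation"; ε > 0 admits
the looser "minimal accumulation" reading).  Codons excluded by the mask
neither extend nor break a run.  Significance comes from B random
permutations of the per-codon values (default B = 1000):
p = (1 + #{null run ≥ observed}) / (B + 1), which is valid (super-uniform)
under the exchangeable null.  A permutation rather than parametric null is
used because synonymous opportunity varies codon to codon; permuting the
observed values conditions on exactly those opportunities.  Since the run
statistic depends only on the indicator value ≤ ε, the implementation
permutes that boolean vector, which is mathematically identical and fast.
An all-zero track is rejected as inapplicable: identical sequences carry no
information about conversion.

The percent-identity segmenter approximates a percent-identity plot by
exact k-mer seeding (k = 11), ungapped bidirectional extension scoring
+1/−1 with X-drop termination (drop 20), merging of overlapping extensions
on one diagonal, and filtering at ≥ 40 nt and ≥ 60% identity.  All four
parameters are configurable; segments (not gapped chains) are returned, and
`locate_high_identity_region` intersects the best segment with an exon
coordinate table to name the exons a conversion region covers.

## Synthetic data

`simulate_codon_evolution` evolves a random sense-codon root down a tree
(supplied newick or a random topology with exponential branch lengths) by a
proposal/acceptance process: nucleotide proposals arrive at rate μ per site
scaled by branch length, synonymous proposals are always accepted,
nonsynonymous ones with probability ω, stop-creating ones never.  The
realized dN/dS approximates ω; the scheme was chosen over a full codon rate
matrix for transparency, and the recovery tolerances used in the test bench
(ω 0.1 recovered in [0.05, 0.2], ω 1.0 in [0.8, 1.25] for 7 taxa × 300
codons) absorb its bias.  Default conditions: 7 taxa, 300 codons, mean
branch length 0.06 proposals per site — enough divergence to estimate from,
far from saturation.

`simulate_gene_family` assembles genes from exon scaffolds: a shared leader,
N exons drawn from cluster founders at configured divergences (exact
substitution counts, never creating stops), optional derivation of one
gene's N exon from another under the codon process above (paralog pairs),
implanted conversion tracts (donor codons copied over the acceptor's),
pseudogenizing lesions (a single-nucleotide nonsense mutation in the N exon,
splice-dinucleotide mutations, leader lesions), and cytoplasmic exons
reverse-translated from amino-acid sequences that carry exactly the
configured motif class — guaranteed by implanting exemplar motifs into a
tyrosine- and acidic-free background and rejection-sampling against the
scanner (bounded at 10,000 attempts).

The packaged demonstration family (`ceafam.fixtures`) couples an inhibitory
and an activating gene by a 60-codon tract on a background generated at
proposal rate 0.5/site and ω 0.3, i.e. background dS ≈ 0.35–0.4 — chosen so
the flanks carry enough synonymous signal that the tract boundary is
statistically identifiable while N-domain amino-acid identity stays above
the pairing floor, the configuration the conversion analysis is designed
for.  Pseudogene divergence within the inhibitory cluster is kept well
under the 1% counting threshold; other clusters sit far above it.

What the generator does **not** emulate: insertions/deletions, non-uniform
base composition, transition/transversion bias, rate heterogeneity among
sites, and recombination other than clean tract replacement.  Passing tests
therefore demonstrate correctness of the algorithms under a clean neutral
model, not robustness to alignment error or compositional bias in real
genomes.

## Pipeline and reproducibility

`run_full_analysis` executes: classification (pseudogene + receptor class)
→ N-exon clustering and counting → bootstrapped NJ tree → pairwise dN/dS
table and summary → substitution profile and conserved regions → receptor
pairing → conversion tests on each pair.  Stage failures are recorded in an
error manifest without discarding completed stages.  Every stochastic call
is seeded from the single run seed and logged; reports are TSV with a
`#`-prefixed metadata preamble (version, seed, parameters) so runs can be
diffed textually.  `scripts/acceptance.py` re-derives the headline
quantities from scratch at modest problem sizes (25 replicates per ω, 100
random matrices, 500 null tracks, 50 power replicates, 300 scanner
sequences) — sizes chosen to keep the whole script in the seconds-to-minutes
range while leaving Monte-Carlo error well inside the margins that matter.

## Known limitations

- Branch-wise dN/dS via ancestral reconstruction is out of scope; the
  pairwise mean is reported and labelled as an approximation.
- The multiple-hit correction is the one-parameter formula throughout; no
  transition/transversion weighting.
- NJ tie-breaking is a package convention; trees can differ from other
  implementations at effectively unresolved nodes.
- The conversion test detects a single dominant tract per pair; multiple
  tracts appear only through the longest one.
- The percent-identity segmenter is ungapped; indel-containing homology is
  reported as separate segments.
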