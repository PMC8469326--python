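# Methods

This note documents the models behind each stage, the parameters that
matter, the synthetic-data generators and what they do and do not
emulate, and the numerical conventions that were pinned where the
design was genuinely open.

## Family identification

The screen retains a candidate protein when its best Smith–Waterman
local-alignment score against any query reaches a threshold (default
80, BLOSUM62, affine gap cost `open + k·extend` with open 11, extend
1). Exact local alignment replaces a heuristic BLASTP search: at
family scale (hundreds of candidates, a handful of queries) the exact
dynamic program is affordable and has the same semantics without
E-value statistics. Alignment is delegated to Biopython's
`PairwiseAligner`; the test suite checks its scores against an
independent Gotoh three-matrix dynamic program on short sequences.

Candidates must then carry every required CaM-recognition motif.
The motif grammars are position-constraint patterns:

| name | pattern | width |
|---|---|---|
| `IQ_long` | `[ILV]QxxxRxxxx[RK]` | 11 |
| `IQ_short` | `IQxxxRGxxxR` | 11 |
| `M_1_5_10` | `[FILVW]xxx[FILV]xxxx[FILVW]` | 10 |
| `M_1_8_14` | `[FILVW]x₆[FAILVW]x₅[FILVW]` | 14 |

The 1-5-10 grammar follows the standard reading of the motif's name
(conserved positions 1, 5 and 10); compact printed renderings of this
pattern are ambiguous about the spacer counts, so the canonical
spacing is used and stated here.

Redundancy removal needs a reproducible rule where curation is often
manual: sequences are grouped by single linkage on pairwise global
identity (identical aligned columns / alignment length) at a default
threshold of 0.95, and each group keeps its longest member (ties:
lexicographically smallest id).

Molecular weight is the sum of average residue masses plus one water
(18.01528 Da), the ProtParam convention, using the average amino-acid
mass table shipped with Biopython. The isoelectric point solves
net-charge(pH) = 0 by bisection on [0, 14] to 10⁻³ pH units, with
Henderson–Hasselbalch terms for the termini and D, E, C, Y, H, K, R.
The default pKa set is Bjellqvist (as used by ExPASy); an EMBOSS set
is selectable. The N-terminal pKa is not residue-specific, which can
shift pI by up to ~0.2 units against ProtParam for unusual N-termini.

`orf_to_protein_length` supports two conventions (`div3`,
`div3_minus1`) because published gene tables are internally
inconsistent about whether the stop codon is counted inside the ORF;
the choice is an explicit argument rather than a silent guess.

## Phylogeny

Protein p-distance counts any character mismatch as a difference;
gaps and `X` are treated as missing and excluded per pair (pairwise
deletion) or per column (complete deletion). A pair with zero
comparable sites is an error naming the pair.

Neighbor joining is the Saitou–Nei algorithm: join the pair minimizing
Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k), with branch lengths from
the standard split formula. Two conventions are pinned for
reproducibility: ties in Q are broken by the smallest (row, column)
index pair in the current working order (the new node replaces the
smaller index), and negative branch lengths are clamped to zero for
display (the raw value is logged at DEBUG). On additive matrices the
implementation recovers the generating topology and all path lengths
to 10⁻⁹, which the suite verifies on random 6–10-taxon trees.

Bootstrap resamples alignment columns with replacement, rebuilds
p-distance + NJ per replicate, and reports for each internal branch
of the full-data tree the percentage of replicates containing its
bipartition, rounded to an integer. A replicate whose resampled
columns leave some pair without comparable sites is redrawn and
counted. Supports are bit-for-bit reproducible under a fixed seed
(`numpy.random.default_rng`).

Subfamily assignment is anchor-based: the caller names one or more
anchor leaves per subfamily and every other leaf takes the subfamily
of its nearest anchor by patristic distance. This makes an otherwise
rooting-dependent judgment explicit and testable; the per-subfamily
monophyly flag reports whether the subfamily's leaves form one side
of a bipartition (a clade on some rooting). Ortholog pairs are
cherries (two-leaf sister pairs) whose members carry different
species labels.

## Duplication classification and dating

Tandem: same chromosome, at most 5 intervening genes, and a combined
span (min start to max end) of at most 100 kb. Segmental: the two
genes fall inside the two intervals of some precomputed duplicated
block, in either orientation, each within 500 kb of its interval.
Blocks are consumed from a TSV rather than inferred, mirroring how
such calls are made against curated collinearity databases; the
synthetic generator emits matching block files. When both rules
match, tandem wins (physical adjacency is the stronger statement).

Ka/Ks is Nei–Gojobori (1986) proportional counting with Jukes–Cantor
correction. Site counts: each codon position contributes the fraction
of its single-nucleotide neighbors that are synonymous, with stop
neighbors excluded from that position's denominator — so synonymous +
nonsynonymous sites always sum to 3. Differences: averaged over all
minimal mutational pathways between two codons, skipping pathways
through stops; if every pathway is blocked, the differing positions
count as nonsynonymous. Gapped codon columns are dropped pairwise
before counting. pS or pN ≥ 3/4 raises a saturation error rather than
returning a complex logarithm. Identical sequences give
Ka = Ks = 0 with an undefined (NaN) ratio.

Divergence time is the strict molecular clock T = Ks/(2λ)·10⁻⁶ Mya,
with λ = 6.5×10⁻⁹ synonymous substitutions/site/year as default (the
rice calibration); λ is a parameter everywhere it appears. Counting
estimators differ across software options (with/without JC
correction, transition bias, etc.); method-level differences of
~10–15% in dated ages should be expected when comparing against other
implementations, which is why dating checks in the suite carry a 15%
tolerance.

## Expression (2^−ΔΔCt)

Replicates are averaged on the Ct scale (the conventional Livak
procedure), then ΔCt = Ct_target − Ct_reference per sample,
ΔΔCt = ΔCt_sample − ΔCt_calibrator, RE = 2^−ΔΔCt. Amplification
efficiency is fixed at 2, as the formula implies; no standard-curve
correction is attempted. RE of the calibrator is exactly 1 by
construction, and adding a constant to all Ct values of one sample
(target and reference alike) leaves RE unchanged.

Responsiveness has no universal numeric definition in the qPCR
literature, so calls are parameterized: up if RE ≥ threshold, down if
RE ≤ 1/threshold, else none, with a 2-fold default. Heat-map matrices
are log₂ RE with optional per-gene z-scaling.

## Co-expression (Mutual Rank)

For each gene, partners are ranked by descending Pearson r (rank 1 =
strongest positive correlation, average rank on ties, self excluded);
MR(a,b) = √(rank_ab·rank_ba). Ranking uses signed r, not |r|,
matching the positive-co-expression convention of rice co-expression
databases. MR is symmetric, ≥ 1, and equals 1 exactly when two genes
are each other's top partner. Guide-gene networks keep edges with
MR ≤ cutoff (default 10; the inclusive comparison is a pinned
convention) at hierarchy 1, and expand one shell outward at
hierarchy 2. Constant-expression genes are excluded before
correlation and reported.

## Synthetic generators

Every generator takes a single seed, emits a machine-readable truth
object, and is byte-reproducible. What they emulate, and what they
deliberately do not:

- **Proteome** (`simulate_family_proteome`): family members are point-
  substituted copies of a motif-bearing ancestor (default 400 aa, 10%
  divergence outside the protected motif window); background proteins
  are random with the ancestor's residue composition. The 10% default
  keeps pairwise family identity near 0.81, far from the 0.95
  redundancy threshold, so planted members model distinct paralogs
  rather than redundant transcripts. Optional motif-ablated homologs
  pass the homology screen but fail motif confirmation. Not emulated:
  domain architecture, indels, compositional heterogeneity along the
  sequence.
- **Paralog pairs** (`simulate_paralog_pair`): synonymous and
  nonsynonymous event counts are Poisson with means p_S·S and p_N·N,
  where p_S, p_N invert the Jukes–Cantor correction of the target Ks
  and Ka = ω·Ks and S, N are the ancestor's NG86 site totals. Events
  apply stop-free single-nucleotide changes on one of the two
  lineages, spread over distinct codon positions (at most one
  synonymous and two nonsynonymous changes per codon across both
  copies), and each placement is required to move the pathway-averaged
  NG86 difference counts by exactly its own type — otherwise
  multiply-hit codons leak between the synonymous and nonsynonymous
  tallies. This realizes "expected NG86 estimate = target" directly;
  it is an independent-site substitution scheme, not a full Markov
  codon model, and does not emulate transition/transversion bias,
  codon-usage bias, or rate variation among sites.
- **Chromosome layouts** (`simulate_chromosome_layout`): gene spans
  and intergenic gaps are drawn at scales (2–6 kb genes, 8–15 kb
  gaps) where the engineered regions guarantee each truth label
  geometrically: tandem plants are adjacent genes ~10 kb apart; one
  decoy spans 105 kb with one intervening gene (distance clause
  fails), one packs six intervening genes into 53 kb (count clause
  fails), and the cross-chromosome decoy sits 600 kb beyond every
  block. Not emulated: realistic gene density, strand clustering,
  nested blocks.
- **Ct tables** (`simulate_ct_table`): reference gene constant at
  Ct 20 up to Gaussian noise; target Ct = calibrator Ct − log₂(fold)
  + noise (default sd 0.2 cycles, 3 replicates). With these settings
  a single recovered RE carries ~17% noise (four mean-Ct terms, each
  sd 0.2/√3), so recovery assertions apply to the median across
  seeds. Not emulated: efficiency differences between amplicons,
  pipetting outliers, detection limits.
- **Expression compendia** (`simulate_expression_compendium`): module
  genes are √ρ·f + √(1−ρ)·ε for a shared latent factor f, giving
  expected within-module correlation ρ (default 0.9, 50 samples);
  background genes are independent noise. Not emulated: correlated
  background structure, batch effects, mean–variance coupling.
- **Clade alignments** (`simulate_clade_alignment`): planted clades
  carry exclusive diagnostic columns over a shared ancestral
  sequence plus independent noise. This produces star-like
  within-clade structure — adequate for testing leaf counts, clade
  recovery and bootstrap saturation, but not for testing branch-length
  accuracy on realistic trees (the additive-matrix tests cover that).

Passing tests on these generators demonstrates that each stage
computes its statistic correctly on data with the assumed structure;
they do not demonstrate robustness to alignment error, annotation
error, or model misspecification in real genomes.

## Problem sizes in the routine suite

The test suite runs at desk scale by design: the ω/Ks recovery grid
uses 3,000-codon pairs with 10 replicates per grid point plus a
single 10,000-codon spot check; planted-recovery loops use 20 seeds
with 40–200 background proteins; bootstrap tests use 10–100
replicates on 6–9 leaves. The acceptance script mirrors these sizes
(10 proteome seeds at 200 background proteins, 5,000-codon dated
pairs). All sizes are package choices balancing statistical
resolution against a quick default run.

## Known limitations

- The homology screen reports raw scores, not E-values; thresholds
  are score-scale and must be re-tuned if the matrix changes.
- NG86 without transition bias systematically differs from
  ML codon-model estimates at higher divergence; the package targets
  the proportional-counting convention, not consensus across methods.
- NJ is a distance method; no likelihood-based tree search is
  provided or planned.
- Subfamily monophyly is evaluated on the NJ topology only; low
  bootstrap branches can flip assignments near subfamily boundaries.
- The co-expression stage computes the MR statistic on a user-supplied
  compendium; it does not curate or normalize the compendium itself.
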