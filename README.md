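# iqfam

Genome-wide characterization of IQ-motif (calmodulin-binding) gene
families, as a tested, reusable pipeline.

Plant genomes carry several families of calmodulin-binding proteins
recognized by short CaM-recruitment motifs — most prominently the IQ
motif `[ILV]QxxxRxxxx[R/K]`, which binds calmodulin
Ca²⁺-independently. Characterizing such a family genome-wide involves
a fixed sequence of analyses: find the members, place them on a
phylogeny, ask how the family expanded (tandem vs segmental
duplication, and when), and profile how the members respond to stress.
`iqfam` implements that whole workflow as a library plus CLI, with a
seeded synthetic-data generator for every stage so the pipeline is
fully testable at desk scale without any genome downloads.

## What it computes

- **Identification** — candidates are screened by exact
  Smith–Waterman local alignment against query proteins (BLOSUM62,
  affine gaps, default open 11 / extend 1), confirmed by consensus
  motif grammars (`IQ_long` `[ILV]QxxxRxxxx[RK]`, `IQ_short`
  `IQxxxRGxxxR`, plus the Ca²⁺-dependent 1-5-10 and 1-8-14 patterns),
  and collapsed for redundancy by single-linkage clustering at 95%
  global identity. Survivors get ProtParam-style descriptors: average
  molecular weight (Σ residue masses + one H₂O) and isoelectric point
  (Henderson–Hasselbalch net charge, bisected to 10⁻³ pH, Bjellqvist
  or EMBOSS pKa sets).
- **Phylogeny** — protein p-distance (fraction of differing sites,
  pairwise or complete deletion), Saitou–Nei neighbor joining on
  Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k), and column-bootstrap
  supports (default 1000 replicates) reported as integer percentages.
  Subfamilies propagate from anchor leaves by patristic distance;
  ortholog pairs are cross-species cherries.
- **Duplication & dating** — tandem pairs: ≤ 5 intervening genes
  within a 100-kb span; segmental pairs: both genes inside the two
  intervals of a precomputed duplicated block (≤ 500 kb offset).
  Ka/Ks by Nei–Gojobori (1986) proportional counting with
  Jukes–Cantor correction; divergence time by the molecular clock
  T = Ks/2λ with λ = 6.5×10⁻⁹ synonymous substitutions/site/year
  (rice calibration).
- **Expression** — Livak 2^−ΔΔCt relative expression from qPCR Ct
  tables (replicates averaged on the Ct scale, target normalized to a
  reference gene and a calibrator sample), threshold-based
  up/down/none responsiveness calls, and log₂ heat-map matrices.
- **Co-expression** — Pearson correlation, Mutual Rank
  MR(a,b) = √(rank_ab·rank_ba) with average tie ranks, and guide-gene
  networks at a configurable MR cutoff (default ≤ 10, hierarchy 1).

## Worked example

Generate a synthetic proteome with five planted IQ-motif homologs
among 50 background proteins, then identify the family:

```
$ iqfam simulate proteome --seed 4 --n-background 50 --n-family 5 --out-dir demo
proteome with 5 planted members -> demo
$ iqfam identify --candidates demo/candidates.fasta --queries demo/queries.fasta --out demo/members.tsv
5 family members -> demo/members.tsv
$ cat demo/members.tsv
id      best_query  score  motif_hits  length  mw       pi
FAM001  QUERY1      1918   IQ_long@50  400     48247.8  7.6
FAM002  QUERY1      1876   IQ_long@50  400     47561.1  8.57
FAM003  QUERY1      1800   IQ_long@50  400     48133.2  8.58
FAM004  QUERY1      1782   IQ_long@50  400     47648.2  8.47
FAM005  QUERY1      1891   IQ_long@50  400     47934.4  7.85
```

Exactly the five planted members are recovered; each line shows the
best local-alignment score against the query set, the IQ-motif hit
position, and the ProtParam-style length/MW/pI descriptors.

Date a duplicate pair evolved at a synonymous divergence of
Ks = 0.2574 under purifying selection (dN/dS = 0.5):

```
$ iqfam simulate paralogs --seed 2 --n-codons 3000 --target-ks 0.2574 --omega 0.5 --out-dir pair
$ python -c "
from iqfam.core_io import read_fasta
from iqfam.duplication_evolution import ka_ks, divergence_time, CodonAlignment
a, b = read_fasta('pair/paralogs.fasta', moltype='dna')
ka, ks, r = ka_ks(CodonAlignment(a.residues, b.residues))
print(f'Ka={ka:.4f} Ks={ks:.4f} Ka/Ks={r:.3f} T={divergence_time(ks):.1f} Mya')"
Ka=0.1330 Ks=0.2505 Ka/Ks=0.531 T=19.3 Mya
```

The NG86 estimator recovers the planted divergence (Ks 0.2505 vs
0.2574 target), the ratio below 1 reflects the purifying regime, and
the clock converts Ks into an age of ~19 million years.

The full pipeline runs from a YAML config
(`iqfam run --config run.yaml`) with one section per stage; outputs
are plain TSV/Newick files plus a summary report and run log, and are
byte-identical under a fixed seed.

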