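"""Synthetic-data generators with planted ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes — planted motif-bearing homologs in a proteome, paralogous
codon sequences evolved at a controlled synonymous distance and dN/dS,
chromosome layouts with tandem/segmental duplicate pairs, Ct tables
with known fold changes, and expression compendia with planted
co-expressed modules — and returns a machine-readable truth object
alongside the data.  All randomness flows from one seeded generator
per call; the same seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, log2, sqrt

import numpy as np
import pandas as pd

from .core_io import Alignment, GeneModel, SequenceRecord
from .duplication_evolution import (
    SENSE_CODONS,
    _CODON_TABLE,
    _STOP_CODONS,
    CodonAlignment,
    DuplicatedBlock,
    ng86_differences,
    ng86_site_counts,
)
from .expression import CT_COLUMNS, CtTable
from .coexpression import ExpressionMatrix
from .identification import IQ_LONG, MotifPattern

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"


def _random_protein(rng: np.random.Generator, length: int, freqs=None) -> str:
    return "".join(rng.choice(list(AA20), size=length, p=freqs))


def _motif_instance(rng: np.random.Generator, pattern: MotifPattern) -> str:
    constrained = dict(pattern.positions)
    out = []
    for i in range(pattern.width):
        if i in constrained:
            out.append(rng.choice(sorted(constrained[i])))
        else:
            out.append(rng.choice(list(AA20)))
    return "".join(out)


def _mutate(rng: np.random.Generator, seq: str, rate: float, protected: set[int]) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = rng.choice(choices)
    return "".join(out)


# ---------------------------------------------------------------------------
# proteome with planted family

@dataclass
class FamilyProteome:
    candidates: list[SequenceRecord]  # family + background, shuffled
    queries: list[SequenceRecord]  # out-of-proteome homologs of the ancestor
    truth_ids: list[str]  # planted family members with intact motif
    ablated_ids: list[str]  # planted homologs whose motif was destroyed


def simulate_family_proteome(
    n_background: int = 200,
    n_family: int = 5,
    seed: int = 0,
    protein_length: int = 400,
    mutation_rate: float = 0.10,
    motif: MotifPattern = IQ_LONG,
    motif_position: int = 50,
    n_ablated: int = 0,
) -> FamilyProteome:
    """Plant ``n_family`` diverged copies of a motif-bearing ancestor
    among composition-matched random background proteins.

    Family members share the ancestor up to point substitutions at
    ``mutation_rate`` outside the motif window, which stays intact.
    The default 10% divergence keeps pairwise identity near 0.81, far
    below the 0.95 redundancy threshold, so planted members model
    distinct paralogs rather than redundant transcripts.
    ``n_ablated`` extra homologs carry a destroyed motif (the invariant
    Q is replaced), so they pass the homology screen but fail motif
    confirmation.
    """
    if n_family < 1:
        raise ValueError("n_family must be >= 1")
    rng = np.random.default_rng(seed)
    ancestor = list(_random_protein(rng, protein_length))
    instance = _motif_instance(rng, motif)
    ancestor[motif_position : motif_position + motif.width] = instance
    ancestor = "".join(ancestor)
    protected = set(range(motif_position, motif_position + motif.width))
    comp = np.array([ancestor.count(a) for a in AA20], dtype=float)
    comp /= comp.sum()

    members: list[SequenceRecord] = []
    truth: list[str] = []
    ablated: list[str] = []
    for k in range(n_family):
        gid = f"FAM{k + 1:03d}"
        members.append(
            SequenceRecord(gid, _mutate(rng, ancestor, mutation_rate, protected))
        )
        truth.append(gid)
    for k in range(n_ablated):
        gid = f"ABL{k + 1:03d}"
        seq = list(_mutate(rng, ancestor, mutation_rate, protected))
        # destroy the motif's invariant Q (offset 1) and anchor residues
        for off, _allowed in motif.positions:
            seq[motif_position + off] = "A"
        members.append(SequenceRecord(gid, "".join(seq)))
        ablated.append(gid)
    background = [
        SequenceRecord(f"BG{k + 1:04d}", _random_protein(rng, protein_length, comp))
        for k in range(n_background)
    ]
    candidates = members + background
    order = rng.permutation(len(candidates))
    candidates = [candidates[i] for i in order]
    queries = [
        SequenceRecord("QUERY1", _mutate(rng, ancestor, mutation_rate, protected))
    ]
    return FamilyProteome(
        candidates=candidates, queries=queries, truth_ids=sorted(truth),
        ablated_ids=sorted(ablated),
    )


# ---------------------------------------------------------------------------
# paralog codon pairs

def _inverse_jc(k: float) -> float:
    """Proportion of differing sites whose Jukes–Cantor correction is k."""
    return 0.75 * (1.0 - exp(-4.0 * k / 3.0))


@dataclass
class ParalogPair:
    alignment: CodonAlignment
    target_ks: float
    omega: float
    n_syn_events: int
    n_nonsyn_events: int


def _syn_neighbors(codon: str) -> list[str]:
    aa = _CODON_TABLE[codon]
    out = []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            nb = codon[:pos] + base + codon[pos + 1 :]
            if nb not in _STOP_CODONS and _CODON_TABLE[nb] == aa:
                out.append(nb)
    return out


def _nonsyn_neighbors(codon: str) -> list[str]:
    aa = _CODON_TABLE[codon]
    out = []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            nb = codon[:pos] + base + codon[pos + 1 :]
            if nb not in _STOP_CODONS and _CODON_TABLE[nb] != aa:
                out.append(nb)
    return out


def simulate_paralog_pair(
    n_codons: int = 1000,
    target_ks: float = 0.2,
    omega: float = 0.5,
    seed: int = 0,
) -> ParalogPair:
    """Evolve two copies of a random ancestor so that the expected
    NG86 estimate of Ks equals ``target_ks`` and of Ka/Ks equals
    ``omega``.

    Synonymous and nonsynonymous event counts are Poisson with means
    p_S*S and p_N*N, where p_S and p_N invert the Jukes–Cantor
    correction of the targets and S, N are the ancestor's NG86 site
    totals; each event applies a random legal (stop-free) synonymous or
    nonsynonymous single-nucleotide change on one of the two lineages.
    Events are spread over distinct codon positions (per lineage, at
    most one synonymous and two nonsynonymous changes per codon) so
    each event yields one observable difference of its type.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    p_s = _inverse_jc(target_ks)
    p_n = _inverse_jc(omega * target_ks)
    if p_s >= 0.7 or p_n >= 0.7:
        raise ValueError("target substitution level too close to saturation")
    rng = np.random.default_rng(seed)
    codons = list(rng.choice(SENSE_CODONS, size=n_codons))
    S = sum(ng86_site_counts(c)[0] for c in codons)
    N = 3 * n_codons - S
    n_syn = int(rng.poisson(p_s * S)) if target_ks > 0 else 0
    n_non = int(rng.poisson(p_n * N)) if omega * target_ks > 0 else 0
    if n_syn > n_codons or n_non > 2 * n_codons:
        raise ValueError("requested divergence exceeds placement capacity")

    lineages = [list(codons), list(codons)]
    # per codon, across both lineages: positions already substituted
    # and change-type counts, so each event stays a distinct visible
    # difference between the two copies
    used_pos: list[set[int]] = [set() for _ in range(n_codons)]
    used_syn = [False] * n_codons
    n_non_at = [0] * n_codons
    events = np.array(["s"] * n_syn + ["n"] * n_non)
    rng.shuffle(events)

    def place(kind: str, lineage_idx: int) -> bool:
        lineage = lineages[lineage_idx]
        for _attempt in range(50 * n_codons):
            i = int(rng.integers(n_codons))
            if kind == "s" and used_syn[i]:
                continue
            if kind == "n" and n_non_at[i] >= 2:
                continue
            nbs = _syn_neighbors(lineage[i]) if kind == "s" else _nonsyn_neighbors(lineage[i])
            nbs = [
                nb
                for nb in nbs
                if next(p for p in range(3) if nb[p] != lineage[i][p]) not in used_pos[i]
            ]
            if not nbs:
                continue
            rng.shuffle(nbs)
            other = lineages[1 - lineage_idx][i]
            old_sd, old_nd = ng86_differences(lineage[i], other) if lineage[i] != other else (0.0, 0.0)
            want = (old_sd + 1, old_nd) if kind == "s" else (old_sd, old_nd + 1)
            for nb in nbs:
                # keep NG86's pathway-averaged counts equal to the typed
                # event counts, else multiply-hit codons leak between
                # the synonymous and nonsynonymous tallies
                new = ng86_differences(nb, other)
                if abs(new[0] - want[0]) < 1e-9 and abs(new[1] - want[1]) < 1e-9:
                    pos = next(p for p in range(3) if nb[p] != lineage[i][p])
                    used_pos[i].add(pos)
                    if kind == "s":
                        used_syn[i] = True
                    else:
                        n_non_at[i] += 1
                    lineage[i] = nb
                    return True
        return False

    for kind in events:
        if not place(kind, int(rng.integers(2))):
            raise RuntimeError("could not place substitution event")
    aln = CodonAlignment("".join(lineages[0]), "".join(lineages[1]))
    return ParalogPair(
        alignment=aln,
        target_ks=target_ks,
        omega=omega,
        n_syn_events=n_syn,
        n_nonsyn_events=n_non,
    )


# ---------------------------------------------------------------------------
# chromosome layout with planted duplications

@dataclass
class LayoutTruth:
    models: list[GeneModel]
    blocks: list[DuplicatedBlock]
    pairs: dict[tuple[str, str], str]  # candidate pair -> expected type


def simulate_chromosome_layout(
    n_chromosomes: int = 4,
    genes_per_chromosome: int = 40,
    planted_tandem: int = 2,
    planted_segmental: int = 3,
    seed: int = 0,
) -> LayoutTruth:
    """Random gene layouts with planted duplicate pairs and decoys.

    Tandem plants are adjacent genes within a 100-kb span; segmental
    plants sit inside emitted duplicated-block intervals on two
    chromosomes.  Decoy pairs each violate exactly one clause: a
    near-tandem pair spanning over 100 kb, a same-chromosome pair with
    six intervening genes, and a cross-chromosome pair lying outside
    every block.
    """
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    min_genes = max(2 * planted_tandem + 11, 21 + planted_segmental)
    if genes_per_chromosome < min_genes:
        raise ValueError(f"genes_per_chromosome must be >= {min_genes}")
    rng = np.random.default_rng(seed)

    def new_gene(chrom: str, idx: int, start: int, length: int) -> GeneModel:
        return GeneModel(
            gene_id=f"{chrom}_g{idx:03d}",
            chromosome=chrom,
            strand="+" if rng.random() < 0.5 else "-",
            start=start,
            end=start + length - 1,
        )

    models: list[GeneModel] = []
    per_chrom: dict[str, list[GeneModel]] = {}
    pairs: dict[tuple[str, str], str] = {}

    # chr1 carries the engineered tandem plants and tandem decoys; the
    # gap schedule guarantees each truth label geometrically.
    chrom = "chr1"
    genes: list[GeneModel] = []
    pos, idx = 20_000, 0

    def push(length: int, gap_after: int) -> GeneModel:
        nonlocal pos, idx
        idx += 1
        g = new_gene(chrom, idx, pos, length)
        genes.append(g)
        pos = g.end + 1 + gap_after
        return g

    for _t in range(planted_tandem):
        a = push(int(rng.integers(3_000, 5_000)), 10_000)
        b = push(int(rng.integers(3_000, 5_000)), 30_000)
        pairs[(a.gene_id, b.gene_id)] = "tandem"
    # decoy: one intervening gene but > 100 kb span (distance clause fails)
    a = push(5_000, 45_000)
    push(5_000, 45_000)
    b = push(5_000, 30_000)
    pairs[(a.gene_id, b.gene_id)] = "none"
    # decoy: six intervening genes in a 53-kb run (count clause fails)
    dense = [push(4_000, 3_000) for _ in range(8)]
    pairs[(dense[0].gene_id, dense[7].gene_id)] = "none"
    while len(genes) < genes_per_chromosome:
        push(int(rng.integers(2_000, 6_000)), int(rng.integers(8_000, 15_000)))
    per_chrom[chrom] = genes
    models.extend(genes)

    for c in range(2, n_chromosomes + 1):
        chrom = f"chr{c}"
        genes = []
        pos, idx = int(rng.integers(10_000, 50_000)), 0
        while len(genes) < genes_per_chromosome:
            push(int(rng.integers(2_000, 6_000)), int(rng.integers(8_000, 15_000)))
        per_chrom[chrom] = genes
        models.extend(genes)

    # segmental plants inside emitted blocks bridging chromosome pairs
    blocks: list[DuplicatedBlock] = []
    for s in range(planted_segmental):
        ca = f"chr{(s % n_chromosomes) + 1}"
        cb = f"chr{((s + 1) % n_chromosomes) + 1}"
        ga = per_chrom[ca][15 + s]
        gb = per_chrom[cb][18 + s]
        blocks.append(
            DuplicatedBlock(
                block_id=f"blk{s + 1}",
                interval_a=(ca, ga.start - 1_000, ga.end + 1_000),
                interval_b=(cb, gb.start - 1_000, gb.end + 1_000),
            )
        )
        pairs[(ga.gene_id, gb.gene_id)] = "segmental"
    # decoy: cross-chromosome pair planted 600 kb beyond every block
    far = []
    for c in (n_chromosomes, n_chromosomes - 1):
        chrom = f"chr{c}"
        last = per_chrom[chrom][-1]
        g = GeneModel(
            gene_id=f"{chrom}_gfar",
            chromosome=chrom,
            strand="+",
            start=last.end + 600_000,
            end=last.end + 603_000,
        )
        per_chrom[chrom].append(g)
        models.append(g)
        far.append(g)
    pairs[(far[0].gene_id, far[1].gene_id)] = "none"
    return LayoutTruth(models=models, blocks=blocks, pairs=pairs)


# ---------------------------------------------------------------------------
# qPCR Ct tables

@dataclass
class CtTruth:
    table: CtTable
    fold_changes: dict[tuple[str, str], float]  # (gene, sample) -> fold
    reference: str
    calibrator: str


def simulate_ct_table(
    genes: list[str] | None = None,
    samples: list[str] | None = None,
    fold_changes: dict[tuple[str, str], float] | None = None,
    replicates: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    reference: str = "eEF1a",
) -> CtTruth:
    """Ct table with known fold changes relative to the first sample.

    The reference gene is constant across samples up to Gaussian Ct
    noise; a target's Ct in a sample is its calibrator Ct minus
    log2(fold change) plus noise.
    """
    genes = genes or ["G1", "G2"]
    samples = samples or ["0h", "6h", "24h"]
    fold_changes = fold_changes or {}
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    calibrator = samples[0]
    rows = []
    ref_base = 20.0
    base_ct = {g: float(rng.uniform(24, 30)) for g in genes}
    truth: dict[tuple[str, str], float] = {}
    for sample in samples:
        for rep in range(1, replicates + 1):
            rows.append(
                dict(
                    gene=reference, sample=sample, condition="ctrl",
                    timepoint=sample, replicate=rep,
                    ct=ref_base + rng.normal(0, noise_sd),
                )
            )
        for g in genes:
            fold = fold_changes.get((g, sample), 1.0)
            if sample == calibrator:
                fold = 1.0
            truth[(g, sample)] = fold
            mu = base_ct[g] - log2(fold)
            for rep in range(1, replicates + 1):
                rows.append(
                    dict(
                        gene=g, sample=sample, condition="treat",
                        timepoint=sample, replicate=rep,
                        ct=mu + rng.normal(0, noise_sd),
                    )
                )
    table = CtTable(pd.DataFrame(rows, columns=CT_COLUMNS))
    return CtTruth(
        table=table, fold_changes=truth, reference=reference, calibrator=calibrator
    )


# ---------------------------------------------------------------------------
# expression compendium with planted modules

@dataclass
class CompendiumTruth:
    matrix: ExpressionMatrix
    modules: list[list[str]]  # gene ids per planted module


def simulate_expression_compendium(
    n_genes: int = 100,
    n_samples: int = 50,
    modules: list[tuple[int, float]] | None = None,
    seed: int = 0,
) -> CompendiumTruth:
    """Background genes are independent noise; each planted module
    draws its genes from a shared latent factor so that the expected
    within-module Pearson correlation equals the requested value."""
    modules = modules if modules is not None else [(5, 0.9)]
    rng = np.random.default_rng(seed)
    rows, ids, planted = [], [], []
    for m, (size, rho) in enumerate(modules, start=1):
        if not 0 <= rho <= 1:
            raise ValueError("module correlation must be in [0, 1]")
        factor = rng.normal(size=n_samples)
        member_ids = []
        for k in range(1, size + 1):
            gid = f"MOD{m}_{k}"
            noise = rng.normal(size=n_samples)
            rows.append(sqrt(rho) * factor + sqrt(1 - rho) * noise)
            ids.append(gid)
            member_ids.append(gid)
        planted.append(member_ids)
    n_bg = n_genes - sum(len(m) for m in planted)
    for k in range(1, n_bg + 1):
        rows.append(rng.normal(size=n_samples))
        ids.append(f"BG{k:04d}")
    data = pd.DataFrame(
        np.array(rows), index=ids,
        columns=[f"S{j + 1:02d}" for j in range(n_samples)],
    )
    return CompendiumTruth(matrix=ExpressionMatrix(data), modules=planted)


# ---------------------------------------------------------------------------
# clade-structured alignments (for tree building at desk scale)

def simulate_clade_alignment(
    clade_sizes: dict[str, int],
    length: int = 300,
    diagnostic_columns: int = 50,
    noise_rate: float = 0.02,
    seed: int = 0,
) -> Alignment:
    """Protein alignment whose sequences fall into planted clades.

    Each clade gets ``diagnostic_columns`` exclusive columns carrying a
    clade-specific residue; the remaining columns are shared ancestral
    residues perturbed independently at ``noise_rate``.  Leaves are
    labeled ``<clade>_<k>``.
    """
    total_diag = diagnostic_columns * len(clade_sizes)
    if total_diag > length:
        raise ValueError("diagnostic columns exceed alignment length")
    rng = np.random.default_rng(seed)
    base = list(_random_protein(rng, length))
    cols = rng.permutation(length)[:total_diag]
    records = []
    for c_idx, (clade, size) in enumerate(sorted(clade_sizes.items())):
        my_cols = cols[c_idx * diagnostic_columns : (c_idx + 1) * diagnostic_columns]
        clade_residues = {
            int(col): rng.choice([a for a in AA20 if a != base[col]])
            for col in my_cols
        }
        for k in range(1, size + 1):
            seq = list(base)
            for col, res in clade_residues.items():
                seq[col] = res
            for i in range(length):
                if i not in clade_residues and rng.random() < noise_rate:
                    seq[i] = rng.choice(list(AA20))
            records.append(
                SequenceRecord(f"{clade}_{k}", "".join(seq), aligned=True)
            )
    return Alignment(records)
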