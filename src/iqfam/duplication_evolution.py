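"""Duplication classification and molecular-evolution dating.

Tandem duplicates are paralogs separated by at most five intervening
genes within a 100-kb span; segmental duplicates are paralogs that fall
inside the two intervals of a precomputed duplicated chromosomal block
(each gene within 500 kb of its interval).  Ka/Ks uses Nei–Gojobori
(1986) proportional counting with Jukes–Cantor correction, and
divergence times follow the molecular clock T = Ks / (2 lambda), with
the rice-calibrated neutral rate lambda = 6.5e-9 synonymous
substitutions per site per year as default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from math import isnan, log, nan

from Bio.Data.CodonTable import standard_dna_table

from .core_io import GeneModel

DEFAULT_LAMBDA = 6.5e-9  # synonymous substitutions / site / year (rice)
TANDEM_MAX_INTERVENING = 5
TANDEM_MAX_SPAN_BP = 100_000
SEGMENTAL_MAX_OFFSET_BP = 500_000

_CODON_TABLE = standard_dna_table.forward_table
_STOP_CODONS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"
SENSE_CODONS = sorted(_CODON_TABLE)  # 61 codons


def _aa(codon: str) -> str | None:
    return _CODON_TABLE.get(codon)


@dataclass
class ChromosomeLayout:
    """All gene models of a genome, indexed per chromosome and sorted
    by start position."""

    genes: dict[str, list[GeneModel]]  # chromosome -> sorted models
    _index: dict[str, tuple[str, int]] = field(default_factory=dict, repr=False)

    @classmethod
    def from_models(cls, models: list[GeneModel]) -> "ChromosomeLayout":
        per_chrom: dict[str, list[GeneModel]] = {}
        for m in models:
            per_chrom.setdefault(m.chromosome, []).append(m)
        for chrom in per_chrom:
            per_chrom[chrom].sort(key=lambda g: (g.start, g.gene_id))
        layout = cls(genes=per_chrom)
        for chrom, gs in per_chrom.items():
            for idx, g in enumerate(gs):
                if g.gene_id in layout._index:
                    raise ValueError(f"duplicate gene id {g.gene_id!r}")
                layout._index[g.gene_id] = (chrom, idx)
        return layout

    def locate(self, gene_id: str) -> tuple[str, int, GeneModel]:
        if gene_id not in self._index:
            raise KeyError(f"unknown gene id {gene_id!r}")
        chrom, idx = self._index[gene_id]
        return chrom, idx, self.genes[chrom][idx]


@dataclass
class DuplicatedBlock:
    block_id: str
    interval_a: tuple[str, int, int]  # (chromosome, start, end) 1-based inclusive
    interval_b: tuple[str, int, int]

    def __post_init__(self) -> None:
        for chrom, s, e in (self.interval_a, self.interval_b):
            if s > e:
                raise ValueError(f"block {self.block_id}: interval ({s},{e}) reversed")


@dataclass
class DuplicationPair:
    gene_a: str
    gene_b: str
    type: str  # {"tandem", "segmental", "none"}
    Ka: float = nan
    Ks: float = nan
    ratio: float = nan
    T_mya: float = nan


@dataclass
class CodonAlignment:
    """Two gap-free coding sequences of equal length (a codon-aware
    pairwise alignment with gapped codon columns already dropped)."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("codon alignment sequences differ in length")
        if len(self.seq_a) < 3 or len(self.seq_a) % 3 != 0:
            raise ValueError("length must be a positive multiple of 3")
        for seq, name in ((self.seq_a, "a"), (self.seq_b, "b")):
            for k in range(0, len(seq), 3):
                codon = seq[k : k + 3]
                if codon in _STOP_CODONS:
                    raise ValueError(f"internal stop codon {codon} in sequence {name}")
                if codon not in _CODON_TABLE:
                    raise ValueError(f"invalid codon {codon!r} in sequence {name}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self):
        for k in range(0, len(self.seq_a), 3):
            yield self.seq_a[k : k + 3], self.seq_b[k : k + 3]


def make_codon_alignment(seq_a: str, seq_b: str) -> CodonAlignment:
    """Build a CodonAlignment, dropping codon columns where either
    sequence has a gap."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned CDS lengths differ")
    kept_a, kept_b = [], []
    for k in range(0, len(seq_a) - len(seq_a) % 3, 3):
        ca, cb = seq_a[k : k + 3], seq_b[k : k + 3]
        if "-" in ca or "-" in cb:
            continue
        kept_a.append(ca)
        kept_b.append(cb)
    return CodonAlignment("".join(kept_a), "".join(kept_b))


# ---------------------------------------------------------------------------
# duplication classification

def classify_tandem(layout: ChromosomeLayout, a: str, b: str) -> bool:
    """True iff the two genes sit on one chromosome with at most 5
    intervening genes and a combined span of at most 100 kb."""
    chrom_a, idx_a, ga = layout.locate(a)
    chrom_b, idx_b, gb = layout.locate(b)
    if chrom_a != chrom_b:
        return False
    intervening = abs(idx_a - idx_b) - 1
    span = max(ga.end, gb.end) - min(ga.start, gb.start) + 1
    return intervening <= TANDEM_MAX_INTERVENING and span <= TANDEM_MAX_SPAN_BP


def _near_interval(g: GeneModel, interval: tuple[str, int, int], max_offset: int) -> bool:
    chrom, s, e = interval
    if g.chromosome != chrom:
        return False
    # distance from the gene to the interval, 0 if overlapping
    if g.end < s:
        return s - g.end <= max_offset
    if g.start > e:
        return g.start - e <= max_offset
    return True


def classify_segmental(
    blocks: list[DuplicatedBlock],
    layout: ChromosomeLayout,
    a: str,
    b: str,
    max_offset: int = SEGMENTAL_MAX_OFFSET_BP,
) -> bool:
    """True iff some duplicated block's two intervals contain the two
    genes (either orientation), each within ``max_offset`` bp."""
    _, _, ga = layout.locate(a)
    _, _, gb = layout.locate(b)
    for blk in blocks:
        if _near_interval(ga, blk.interval_a, max_offset) and _near_interval(
            gb, blk.interval_b, max_offset
        ):
            return True
        if _near_interval(ga, blk.interval_b, max_offset) and _near_interval(
            gb, blk.interval_a, max_offset
        ):
            return True
    return False


def classify_pair(
    layout: ChromosomeLayout,
    blocks: list[DuplicatedBlock],
    a: str,
    b: str,
) -> str:
    """Duplication type of a paralog pair: tandem, segmental, or none.
    Tandem takes precedence (physical adjacency is the stronger call)."""
    if classify_tandem(layout, a, b):
        return "tandem"
    if classify_segmental(blocks, layout, a, b):
        return "segmental"
    return "none"


# ---------------------------------------------------------------------------
# Nei–Gojobori 1986

@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of a sense codon.

    Each of the three positions contributes the fraction of its
    single-nucleotide neighbors that are synonymous; neighbors that are
    stop codons are excluded from that position's denominator, so the
    two counts always sum to 3.
    """
    if codon in _STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa0 = _aa(codon)
    if aa0 is None:
        raise ValueError(f"invalid codon {codon!r}")
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_legal = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1 :]
            if neighbor in _STOP_CODONS:
                continue
            n_legal += 1
            if _aa(neighbor) == aa0:
                n_syn += 1
        if n_legal:
            syn += n_syn / n_legal
        # a position with only stop neighbors contributes 1 nonsyn site
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous change counts over all minimal
    mutational pathways between two sense codons.

    Pathways passing through a stop codon are excluded; if every
    pathway is blocked, the differing positions all count as
    nonsynonymous.
    """
    for c in (codon_a, codon_b):
        if c not in _CODON_TABLE:
            raise ValueError(f"invalid or stop codon {c!r}")
    diff_pos = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diff_pos:
        return 0.0, 0.0
    path_counts: list[tuple[float, float]] = []
    for order in permutations(diff_pos):
        cur = codon_a
        syn = non = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOP_CODONS:
                blocked = True
                break
            if _aa(nxt) == _aa(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        if not blocked:
            path_counts.append((syn, non))
    if not path_counts:
        return 0.0, float(len(diff_pos))
    syn = sum(p[0] for p in path_counts) / len(path_counts)
    non = sum(p[1] for p in path_counts) / len(path_counts)
    return syn, non


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction of a proportion of
    differing sites."""
    if p >= 0.75:
        raise ValueError(f"proportion {p:.4f} >= 3/4: saturated, JC undefined")
    return -0.75 * log(1 - 4 * p / 3)


def ka_ks(pair: CodonAlignment) -> tuple[float, float, float]:
    """NG86 Ka, Ks and their ratio for a pairwise codon alignment.

    Site totals S and N are the means over the two sequences; observed
    proportions pS = Sd/S and pN = Nd/N get the Jukes–Cantor
    correction.  Identical sequences return (0, 0, nan).
    """
    S_a = N_a = S_b = N_b = 0.0
    Sd = Nd = 0.0
    for ca, cb in pair.codons():
        sa, na = ng86_site_counts(ca)
        sb, nb = ng86_site_counts(cb)
        S_a += sa
        N_a += na
        S_b += sb
        N_b += nb
        ds, dn = ng86_differences(ca, cb)
        Sd += ds
        Nd += dn
    S = (S_a + S_b) / 2
    N = (N_a + N_b) / 2
    if S == 0 or N == 0:
        raise ValueError("zero synonymous or nonsynonymous sites")
    pS = Sd / S
    pN = Nd / N
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    ratio = Ka / Ks if Ks > 0 else nan
    return Ka, Ks, ratio


def divergence_time(Ks: float, lambda_rate: float = DEFAULT_LAMBDA) -> float:
    """Molecular-clock dating in Mya: T = Ks / (2 lambda) * 1e-6."""
    if isnan(Ks):
        return nan
    if Ks < 0:
        raise ValueError("Ks must be nonnegative")
    if lambda_rate <= 0:
        raise ValueError("lambda_rate must be positive")
    return Ks / (2 * lambda_rate) * 1e-6


def analyze_pair(
    layout: ChromosomeLayout,
    blocks: list[DuplicatedBlock],
    a: str,
    b: str,
    cds_a: str | None = None,
    cds_b: str | None = None,
    lambda_rate: float = DEFAULT_LAMBDA,
) -> DuplicationPair:
    """Classify a paralog pair and, when CDS are given, date it."""
    dtype = classify_pair(layout, blocks, a, b)
    result = DuplicationPair(gene_a=a, gene_b=b, type=dtype)
    if cds_a and cds_b:
        aln = make_codon_alignment(cds_a, cds_b)
        result.Ka, result.Ks, result.ratio = ka_ks(aln)
        result.T_mya = divergence_time(result.Ks, lambda_rate)
    return result
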