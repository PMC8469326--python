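"""Gene-family identification screen.

Candidates from a proteome are retained when (1) their best local
alignment against any query protein reaches a score threshold, (2) they
carry the required calmodulin-recognition motifs, and (3) they survive
redundancy collapse.  Physicochemical descriptors (length, average
molecular weight, isoelectric point) are computed for the survivors.

The homology screen is exact Smith–Waterman local alignment with a
BLOSUM62 matrix and affine gaps (defaults: open 11, extend 1), i.e. the
same semantics as a BLASTP screen at family scale without E-value
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.IUPACData import protein_weights as _FREE_AA_MASS

from .core_io import SequenceRecord

WATER_MASS = 18.01528  # average mass of H2O, Da

# Calmodulin-recognition consensus motifs.  Positions map window offset
# -> allowed residue set; unconstrained offsets accept any residue.
#   IQ_long   [ILV]QxxxRxxxx[RK]   Ca2+-independent IQ motif
#   IQ_short  IQxxxRGxxxR          strict IQ variant
#   M_1_5_10  [FILVW]xxx[FILV]xxxx[FILVW]     Ca2+-dependent 1-5-10
#   M_1_8_14  [FILVW]x6[FAILVW]x5[FILVW]      Ca2+-dependent 1-8-14


@dataclass(frozen=True)
class MotifPattern:
    name: str
    positions: tuple[tuple[int, frozenset[str]], ...]

    def __post_init__(self) -> None:
        offsets = [o for o, _ in self.positions]
        if offsets != sorted(set(offsets)) or offsets[0] != 0:
            raise ValueError("offsets must be strictly increasing and start at 0")

    @property
    def width(self) -> int:
        return self.positions[-1][0] + 1

    def matches(self, window: str) -> bool:
        if len(window) != self.width:
            return False
        return all(window[off] in allowed for off, allowed in self.positions)


def _pat(name: str, spec: list[tuple[int, str]]) -> MotifPattern:
    return MotifPattern(name, tuple((o, frozenset(a)) for o, a in spec))


IQ_LONG = _pat("IQ_long", [(0, "ILV"), (1, "Q"), (5, "R"), (10, "RK")])
IQ_SHORT = _pat("IQ_short", [(0, "I"), (1, "Q"), (5, "R"), (6, "G"), (10, "R")])
M_1_5_10 = _pat("M_1_5_10", [(0, "FILVW"), (4, "FILV"), (9, "FILVW")])
M_1_8_14 = _pat("M_1_8_14", [(0, "FILVW"), (7, "FAILVW"), (13, "FILVW")])

MOTIF_PATTERNS: dict[str, MotifPattern] = {
    p.name: p for p in (IQ_LONG, IQ_SHORT, M_1_5_10, M_1_8_14)
}


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    pattern: str
    start: int  # 0-based
    end: int  # exclusive
    matched: str


@dataclass
class ProteinProperties:
    length: int
    molecular_weight: float
    isoelectric_point: float


@dataclass
class FamilyCallConfig:
    homology_min_score: float = 80.0
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0  # cost of a length-k gap: open + k*extend
    gap_extend: float = 1.0
    required_motifs: frozenset[str] = frozenset({"IQ_long"})
    redundancy_identity: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.redundancy_identity <= 1:
            raise ValueError("redundancy_identity must be in (0, 1]")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


def scan_motifs(
    protein: SequenceRecord, patterns: list[MotifPattern]
) -> list[MotifHit]:
    """Report every window of ``protein`` satisfying any pattern.

    Overlapping hits are allowed; output is sorted by (start, pattern
    name).
    """
    if not patterns:
        raise ValueError("empty pattern list")
    seq = protein.residues
    hits: list[MotifHit] = []
    for pat in patterns:
        w = pat.width
        for i in range(len(seq) - w + 1):
            window = seq[i : i + w]
            if pat.matches(window):
                hits.append(MotifHit(protein.id, pat.name, i, i + w, window))
    hits.sort(key=lambda h: (h.start, h.pattern))
    return hits


def _local_aligner(config: FamilyCallConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(
        config.substitution_matrix
    )
    # biopython charges open_gap_score for the first gapped position:
    # cost(k) = open + k*extend  =>  first position open+extend, then extend
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def local_alignment_score(
    a: str, b: str, config: FamilyCallConfig | None = None
) -> float:
    """Best Smith–Waterman local alignment score of two protein strings."""
    config = config or FamilyCallConfig()
    return float(_local_aligner(config).score(a, b))


def homology_screen(
    candidates: list[SequenceRecord],
    queries: list[SequenceRecord],
    config: FamilyCallConfig | None = None,
) -> list[tuple[str, str, float]]:
    """Retain candidates whose best local-alignment score against any
    query reaches ``homology_min_score``.

    Returns (candidate id, best query id, score) triples in candidate
    order.
    """
    if not queries:
        raise ValueError("empty query set")
    config = config or FamilyCallConfig()
    aligner = _local_aligner(config)
    out: list[tuple[str, str, float]] = []
    for cand in candidates:
        best_score, best_query = -1.0, ""
        for q in queries:
            s = float(aligner.score(cand.residues, q.residues))
            if s > best_score:
                best_score, best_query = s, q.id
        if best_score >= config.homology_min_score:
            out.append((cand.id, best_query, best_score))
    return out


def global_identity(a: str, b: str) -> float:
    """Fraction of identical positions over global-alignment columns."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    return aln.counts().identities / aln.length


def collapse_redundancy(
    members: list[SequenceRecord], redundancy_identity: float = 0.95
) -> list[SequenceRecord]:
    """Collapse near-identical sequences, keeping one representative.

    Sequences are grouped by single linkage on pairwise global identity
    >= threshold; within each group the longest sequence is kept (ties:
    lexicographically smallest id).  Output preserves input order of
    the representatives.
    """
    n = len(members)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if global_identity(members[i].residues, members[j].residues) >= redundancy_identity:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    keep: set[int] = set()
    for idxs in groups.values():
        best = min(idxs, key=lambda k: (-len(members[k].residues), members[k].id))
        keep.add(best)
    return [m for i, m in enumerate(members) if i in keep]


def identify_family(
    candidates: list[SequenceRecord],
    queries: list[SequenceRecord],
    config: FamilyCallConfig | None = None,
) -> list[SequenceRecord]:
    """Full identification pipeline: homology screen, motif
    confirmation, redundancy collapse.  Output sorted by id."""
    config = config or FamilyCallConfig()
    if not candidates:
        return []
    by_id = {c.id: c for c in candidates}
    screened = homology_screen(candidates, queries, config)
    patterns = [MOTIF_PATTERNS[name] for name in sorted(config.required_motifs)]
    confirmed: list[SequenceRecord] = []
    for cand_id, _q, _s in screened:
        rec = by_id[cand_id]
        ok = all(
            scan_motifs(rec, [pat]) for pat in patterns
        )
        if ok:
            confirmed.append(rec)
    kept = collapse_redundancy(confirmed, config.redundancy_identity)
    return sorted(kept, key=lambda r: r.id)


# ---------------------------------------------------------------------------
# Physicochemical descriptors

def molecular_weight(protein: SequenceRecord | str) -> float:
    """Average (non-monoisotopic) molecular weight in Da.

    Sum of average residue masses plus one water (18.01528 Da), i.e.
    the ProtParam convention.  Nonstandard residues raise with the
    offending letter named.
    """
    seq = protein if isinstance(protein, str) else protein.residues
    total = WATER_MASS
    for aa in seq:
        try:
            total += _FREE_AA_MASS[aa] - WATER_MASS
        except KeyError:
            raise ValueError(f"nonstandard residue {aa!r} in molecular_weight") from None
    return total


# pKa sets for the Henderson–Hasselbalch net-charge model.
PKA_SETS = {
    # Bjellqvist values as used by ExPASy ProtParam
    "bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "K": 10.0, "R": 12.0, "H": 5.98,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    },
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
}
_BASIC = ("Nterm", "K", "R", "H")
_ACIDIC = ("Cterm", "D", "E", "C", "Y")


def net_charge(protein: SequenceRecord | str, pH: float, pka_set: str = "bjellqvist") -> float:
    """Net protein charge at a given pH (Henderson–Hasselbalch)."""
    seq = protein if isinstance(protein, str) else protein.residues
    pka = PKA_SETS[pka_set]
    counts = {aa: seq.count(aa) for aa in "KRHDECY"}
    counts["Nterm"] = counts["Cterm"] = 1
    charge = 0.0
    for grp in _BASIC:
        k = pka[grp]
        charge += counts[grp] * 10 ** k / (10 ** k + 10 ** pH)
    for grp in _ACIDIC:
        k = pka[grp]
        charge -= counts[grp] * 10 ** pH / (10 ** k + 10 ** pH)
    return charge


def isoelectric_point(
    protein: SequenceRecord | str, pka_set: str = "bjellqvist", tol: float = 1e-3
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is
    unique.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if net_charge(protein, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def protein_properties(protein: SequenceRecord, pka_set: str = "bjellqvist") -> ProteinProperties:
    return ProteinProperties(
        length=len(protein.residues),
        molecular_weight=molecular_weight(protein),
        isoelectric_point=isoelectric_point(protein, pka_set),
    )


def orf_to_protein_length(orf_bp: int, convention: str = "div3") -> int:
    """Convert an ORF length in bp to a protein length in residues.

    Annotation databases disagree on whether the stop codon is counted:
    ``div3`` returns orf/3, ``div3_minus1`` returns orf/3 - 1 (stop
    codon included in the ORF).  Both conventions occur within a single
    published gene table, so the choice is explicit.
    """
    if orf_bp % 3 != 0:
        raise ValueError(f"ORF length {orf_bp} not divisible by 3")
    if convention == "div3":
        return orf_bp // 3
    if convention == "div3_minus1":
        return orf_bp // 3 - 1
    raise ValueError(f"unknown convention {convention!r}")
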