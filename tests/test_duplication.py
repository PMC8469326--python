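"""Tandem/segmental classification and NG86 Ka/Ks with clock dating.

The NG86 site and difference counts are checked against independent
enumeration oracles built on Biopython's translation, not on the
implementation's own codon table walk."""

from itertools import permutations, product
from math import isnan, log

import numpy as np
import pytest
from Bio.Seq import Seq

from iqfam.core_io import GeneModel
from iqfam.duplication_evolution import (
    ChromosomeLayout,
    CodonAlignment,
    DuplicatedBlock,
    classify_pair,
    classify_segmental,
    classify_tandem,
    divergence_time,
    ka_ks,
    make_codon_alignment,
    ng86_differences,
    ng86_site_counts,
)
from iqfam.synthetic import simulate_chromosome_layout, simulate_paralog_pair

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
SENSE = [
    "".join(c) for c in product(BASES, repeat=3) if "".join(c) not in STOPS
]


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# layout classification

def genes(*specs):
    return [
        GeneModel(gene_id=g, chromosome=c, strand="+", start=s, end=e)
        for g, c, s, e in specs
    ]


def test_tandem_adjacent_within_100kb():
    layout = ChromosomeLayout.from_models(
        genes(("a", "chr1", 10_000, 12_000), ("b", "chr1", 50_000, 52_000))
    )
    assert classify_tandem(layout, "a", "b")


def test_tandem_fails_on_distance():
    layout = ChromosomeLayout.from_models(
        genes(
            ("a", "chr1", 10_000, 12_000),
            ("m1", "chr1", 40_000, 42_000),
            ("m2", "chr1", 80_000, 82_000),
            ("b", "chr1", 160_000, 162_000),
        )
    )
    assert not classify_tandem(layout, "a", "b")


def test_tandem_fails_on_intervening_count():
    specs = [("a", "chr1", 10_000, 11_000)]
    for i in range(6):
        specs.append((f"m{i}", "chr1", 15_000 + 8_000 * i, 16_000 + 8_000 * i))
    specs.append(("b", "chr1", 70_000, 71_000))
    layout = ChromosomeLayout.from_models(genes(*specs))
    assert not classify_tandem(layout, "a", "b")


def test_tandem_unknown_gene_errors():
    layout = ChromosomeLayout.from_models(genes(("a", "chr1", 1, 100)))
    with pytest.raises(KeyError):
        classify_tandem(layout, "a", "zz")


def test_segmental_inside_block():
    layout = ChromosomeLayout.from_models(
        genes(("a", "chr1", 100_000, 102_000), ("b", "chr2", 500_000, 502_000))
    )
    blocks = [
        DuplicatedBlock("blk1", ("chr1", 90_000, 110_000), ("chr2", 490_000, 510_000))
    ]
    assert classify_segmental(blocks, layout, "a", "b")
    assert classify_segmental(blocks, layout, "b", "a")  # either orientation


def test_segmental_fails_outside_offset():
    layout = ChromosomeLayout.from_models(
        genes(("a", "chr1", 800_000, 802_000), ("b", "chr2", 500_000, 502_000))
    )
    blocks = [
        DuplicatedBlock("blk1", ("chr1", 90_000, 110_000), ("chr2", 490_000, 510_000))
    ]
    assert not classify_segmental(blocks, layout, "a", "b")


@pytest.mark.parametrize("seed", range(20))
def test_planted_layout_classified_exactly(seed):
    sim = simulate_chromosome_layout(
        planted_tandem=2, planted_segmental=3, seed=seed
    )
    layout = ChromosomeLayout.from_models(sim.models)
    for (a, b), expected in sim.pairs.items():
        assert classify_pair(layout, sim.blocks, a, b) == expected, (a, b)


def test_planted_layout_counts_match_truth():
    sim = simulate_chromosome_layout(planted_tandem=2, planted_segmental=3, seed=0)
    layout = ChromosomeLayout.from_models(sim.models)
    calls = [classify_pair(layout, sim.blocks, a, b) for a, b in sim.pairs]
    assert calls.count("tandem") == 2
    assert calls.count("segmental") == 3


# ---------------------------------------------------------------------------
# NG86 site counts vs enumeration oracle

def site_count_oracle(codon: str) -> float:
    """Independent per-position neighbor enumeration using Biopython
    translation."""
    syn = 0.0
    for pos in range(3):
        n_syn = n_ok = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if nb in STOPS:
                continue
            n_ok += 1
            n_syn += translate(nb) == translate(codon)
        if n_ok:
            syn += n_syn / n_ok
    return syn


@pytest.mark.parametrize(
    "codon,expected_syn", [("TTT", 1 / 3), ("GGG", 1.0), ("ATG", 0.0)]
)
def test_site_counts_examples(codon, expected_syn):
    syn, non = ng86_site_counts(codon)
    assert syn == pytest.approx(expected_syn)
    assert syn + non == pytest.approx(3.0)


def test_site_counts_all_61_codons_match_oracle():
    for codon in SENSE:
        syn, non = ng86_site_counts(codon)
        assert syn == pytest.approx(site_count_oracle(codon)), codon
        assert syn + non == pytest.approx(3.0), codon


def test_site_counts_reject_stop():
    with pytest.raises(ValueError):
        ng86_site_counts("TAA")


# ---------------------------------------------------------------------------
# NG86 differences vs pathway oracle

def differences_oracle(a: str, b: str):
    diff = [p for p in range(3) if a[p] != b[p]]
    results = []
    for order in permutations(diff):
        cur, syn, non, ok = a, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if translate(nxt) == translate(cur):
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            results.append((syn, non))
    if not results:
        return (0.0, float(len(diff)))
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("TTT", "TTC", (1.0, 0.0)),
        ("TTT", "TTA", (0.0, 1.0)),
        ("AAA", "AAA", (0.0, 0.0)),
    ],
)
def test_differences_examples(a, b, expected):
    assert ng86_differences(a, b) == pytest.approx(expected)


def test_differences_two_substitutions_pathway_average():
    syn, non = ng86_differences("TTT", "GTA")
    osyn, onon = differences_oracle("TTT", "GTA")
    assert (syn, non) == pytest.approx((osyn, onon))
    assert syn + non == pytest.approx(2.0)


def test_differences_random_codon_pairs_match_oracle():
    rng = np.random.default_rng(3)
    for _ in range(150):
        a, b = rng.choice(SENSE, size=2)
        syn, non = ng86_differences(a, b)
        osyn, onon = differences_oracle(a, b)
        assert (syn, non) == pytest.approx((osyn, onon)), (a, b)


# ---------------------------------------------------------------------------
# Ka/Ks

def test_ka_ks_identical_sequences():
    aln = CodonAlignment("ATGGCT", "ATGGCT")
    ka, ks, ratio = ka_ks(aln)
    assert ka == 0 and ks == 0
    assert isnan(ratio)


def test_jukes_cantor_closed_form():
    from iqfam.duplication_evolution import jukes_cantor

    assert jukes_cantor(0.3) == pytest.approx(-0.75 * log(0.6))
    assert jukes_cantor(0.3) == pytest.approx(0.3831, abs=1e-4)
    with pytest.raises(ValueError):
        jukes_cantor(0.8)


def test_ka_ks_symmetric():
    pair = simulate_paralog_pair(n_codons=300, target_ks=0.2, omega=0.5, seed=4)
    a, b = pair.alignment.seq_a, pair.alignment.seq_b
    assert ka_ks(CodonAlignment(a, b)) == pytest.approx(ka_ks(CodonAlignment(b, a)))


def test_codon_alignment_rejects_internal_stop():
    with pytest.raises(ValueError, match="stop"):
        CodonAlignment("ATGTAAGCT", "ATGGCTGCT")


def test_make_codon_alignment_drops_gapped_columns():
    aln = make_codon_alignment("ATG---GCT", "ATGGCTGCA")
    assert aln.n_codons == 2
    assert aln.seq_a == "ATGGCT"


def test_omega_recovery_grid_median_within_10pct():
    """Simulation-based parameter recovery at reduced problem size
    (3,000 codons, 10 replicates per grid point)."""
    for target_ks in (0.05, 0.2, 0.5):
        for omega in (0.2, 0.5, 1.0, 2.0):
            ratios, kss = [], []
            for seed in range(10):
                pair = simulate_paralog_pair(
                    n_codons=3000, target_ks=target_ks, omega=omega, seed=seed
                )
                ka, ks, ratio = ka_ks(pair.alignment)
                ratios.append(ratio)
                kss.append(ks)
            assert abs(np.median(ratios) / omega - 1) < 0.10, (target_ks, omega)
            assert abs(np.median(kss) / target_ks - 1) < 0.10, (target_ks, omega)


def test_ks_recovery_at_large_scale():
    pair = simulate_paralog_pair(n_codons=10_000, target_ks=0.2, omega=0.5, seed=0)
    ka, ks, ratio = ka_ks(pair.alignment)
    assert 0.18 <= ks <= 0.22
    assert 0.45 <= ratio <= 0.55


# ---------------------------------------------------------------------------
# divergence dating

@pytest.mark.parametrize(
    "ks,expected_mya",
    [(0.13, 10.0), (0.0, 0.0), (0.2574, 19.8)],
)
def test_divergence_time_clock(ks, expected_mya):
    assert divergence_time(ks, 6.5e-9) == pytest.approx(expected_mya)


def test_divergence_time_linear_monotone():
    ks = np.linspace(0, 1, 11)
    times = [divergence_time(k) for k in ks]
    assert all(b > a for a, b in zip(times, times[1:]))
    assert divergence_time(0.4) == pytest.approx(2 * divergence_time(0.2))


def test_divergence_time_negative_ks_errors():
    with pytest.raises(ValueError):
        divergence_time(-0.1)
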