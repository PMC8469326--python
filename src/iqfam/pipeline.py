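"""End-to-end orchestration of the family-characterization stages.

A run is driven by a YAML config with one section per stage
(``identify``, ``phylo``, ``dupl``, ``expr``, ``coexpr``); a stage runs
iff its section is present.  Outputs are plain TSV/Newick files plus a
run log, and are pure functions of the inputs and the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coexpression import (
    ExpressionMatrix,
    edges_to_frame,
    guide_gene_network,
    mutual_rank,
    pearson_matrix,
)
from .core_io import read_alignment, read_fasta, read_gff3, write_newick
from .duplication_evolution import (
    DEFAULT_LAMBDA,
    ChromosomeLayout,
    DuplicatedBlock,
    analyze_pair,
)
from .expression import (
    CtTable,
    heatmap_matrix,
    relative_expression_all,
    responsiveness_calls,
)
from .identification import (
    MOTIF_PATTERNS,
    FamilyCallConfig,
    homology_screen,
    identify_family,
    protein_properties,
    scan_motifs,
)
from .phylogeny import assign_subfamilies, bootstrap_support, ortholog_pairs

logger = logging.getLogger(__name__)

_KNOWN_SECTIONS = {"seed", "out_dir", "identify", "phylo", "dupl", "expr", "coexpr"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "iqfam_out"
    stages: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        stages = {k: raw[k] or {} for k in raw if k not in ("seed", "out_dir")}
        for stage, opts in stages.items():
            for key, val in opts.items():
                if key.endswith(("_file", "_fasta", "_tsv")) or key in _FILE_KEYS.get(stage, ()):
                    if not Path(val).exists():
                        raise FileNotFoundError(f"{stage}.{key}: no such file {val!r}")
        return cls(
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "iqfam_out")),
            stages=stages,
        )


_FILE_KEYS = {
    "identify": ("candidates", "queries"),
    "phylo": ("alignment", "anchors", "species"),
    "dupl": ("gff3", "blocks", "pairs", "cds"),
    "expr": ("ct",),
    "coexpr": ("matrix",),
}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_blocks_tsv(path) -> list[DuplicatedBlock]:
    df = pd.read_csv(path, sep="\t")
    return [
        DuplicatedBlock(
            block_id=str(r.block_id),
            interval_a=(str(r.chrA), int(r.startA), int(r.endA)),
            interval_b=(str(r.chrB), int(r.startB), int(r.endB)),
        )
        for r in df.itertuples()
    ]


def write_blocks_tsv(blocks: list[DuplicatedBlock], path) -> None:
    rows = [
        dict(
            block_id=b.block_id,
            chrA=b.interval_a[0], startA=b.interval_a[1], endA=b.interval_a[2],
            chrB=b.interval_b[0], startB=b.interval_b[1], endB=b.interval_b[2],
        )
        for b in blocks
    ]
    _write_tsv(pd.DataFrame(rows), Path(path))


def run_identify(opts: dict, out: Path) -> pd.DataFrame:
    candidates = read_fasta(opts["candidates"], moltype="protein")
    queries = read_fasta(opts["queries"], moltype="protein")
    config = FamilyCallConfig(
        homology_min_score=float(opts.get("min_score", 80)),
        required_motifs=frozenset(opts.get("require_motifs", ["IQ_long"])),
        redundancy_identity=float(opts.get("redundancy_identity", 0.95)),
    )
    members = identify_family(candidates, queries, config)
    score_of = {
        cid: (q, s) for cid, q, s in homology_screen(members, queries, config)
    }
    rows = []
    for rec in members:
        props = protein_properties(rec)
        hits = scan_motifs(rec, [MOTIF_PATTERNS[m] for m in sorted(config.required_motifs)])
        q, s = score_of[rec.id]
        rows.append(
            dict(
                id=rec.id, best_query=q, score=s,
                motif_hits=";".join(f"{h.pattern}@{h.start}" for h in hits),
                length=props.length,
                mw=round(props.molecular_weight, 2),
                pi=round(props.isoelectric_point, 2),
            )
        )
    table = pd.DataFrame(
        rows, columns=["id", "best_query", "score", "motif_hits", "length", "mw", "pi"]
    )
    _write_tsv(table, out / "members.tsv")
    return table


def run_phylo(opts: dict, out: Path, seed: int) -> dict:
    alignment = read_alignment(opts["alignment"])
    tree = bootstrap_support(
        alignment,
        replicates=int(opts.get("bootstrap", 1000)),
        seed=seed,
        deletion=opts.get("deletion", "pairwise"),
    )
    write_newick(tree, out / "tree.nwk")
    result: dict = {"n_leaves": len(tree.leaf_nodes()), "tree": tree}
    if "anchors" in opts:
        anchors = (
            pd.read_csv(opts["anchors"], sep="\t")
            .set_index("leaf")["subfamily"]
            .astype(str)
            .to_dict()
        )
        assignment = assign_subfamilies(tree, anchors)
        df = pd.DataFrame(
            sorted(assignment.assignments.items()), columns=["leaf", "subfamily"]
        )
        df["monophyletic"] = df["subfamily"].map(assignment.monophyletic)
        _write_tsv(df, out / "subfamilies.tsv")
        result["subfamilies"] = assignment
    if "species" in opts:
        species = (
            pd.read_csv(opts["species"], sep="\t")
            .set_index("leaf")["species"]
            .astype(str)
            .to_dict()
        )
        pairs = ortholog_pairs(tree, species)
        _write_tsv(
            pd.DataFrame(pairs, columns=["leaf_a", "leaf_b"]), out / "ortholog_pairs.tsv"
        )
        result["ortholog_pairs"] = pairs
    return result


def run_dupl(opts: dict, out: Path) -> pd.DataFrame:
    layout = ChromosomeLayout.from_models(read_gff3(opts["gff3"]))
    blocks = read_blocks_tsv(opts["blocks"]) if "blocks" in opts else []
    pairs = pd.read_csv(opts["pairs"], sep="\t")
    cds = {}
    if "cds" in opts:
        cds = {r.id: r.residues for r in read_fasta(opts["cds"], moltype="dna")}
    lam = float(opts.get("lambda", DEFAULT_LAMBDA))
    rows = []
    for r in pairs.itertuples():
        res = analyze_pair(
            layout, blocks, str(r.gene_a), str(r.gene_b),
            cds_a=cds.get(r.gene_a), cds_b=cds.get(r.gene_b), lambda_rate=lam,
        )
        rows.append(
            dict(
                gene_a=res.gene_a, gene_b=res.gene_b, type=res.type,
                Ka=res.Ka, Ks=res.Ks, ratio=res.ratio, T_Mya=res.T_mya,
            )
        )
    table = pd.DataFrame(rows)
    _write_tsv(table, out / "duplication_pairs.tsv")
    return table


def run_expr(opts: dict, out: Path) -> pd.DataFrame:
    table = CtTable.read(opts["ct"])
    re = relative_expression_all(
        table, reference=opts["reference_gene"], calibrator=opts["calibrator"]
    )
    calls = responsiveness_calls(re, float(opts.get("fold_threshold", 2.0)))
    merged = re.data.merge(calls[["gene", "sample", "call"]], on=["gene", "sample"])
    _write_tsv(merged, out / "relative_expression.tsv")
    if opts.get("heatmap", True):
        heatmap_matrix(re, transform="log2", figure_path=out / "expression_heatmap.png")
    return merged


def run_coexpr(opts: dict, out: Path) -> pd.DataFrame:
    matrix = ExpressionMatrix.read(opts["matrix"])
    corr = pearson_matrix(matrix)
    mr = mutual_rank(corr)
    guides = opts["guides"]
    if isinstance(guides, str):
        guides = [g.strip() for g in guides.split(",")]
    edges = guide_gene_network(
        mr,
        guides,
        mr_cutoff=float(opts.get("mr_cutoff", 10)),
        hierarchy=int(opts.get("hierarchy", 1)),
        corr=corr,
    )
    table = edges_to_frame(edges)
    _write_tsv(table, out / "coexpression_edges.tsv")
    return table


_STAGE_RUNNERS = {
    "identify": lambda cfg, opts, out: run_identify(opts, out),
    "phylo": lambda cfg, opts, out: run_phylo(opts, out, cfg.seed),
    "dupl": lambda cfg, opts, out: run_dupl(opts, out),
    "expr": lambda cfg, opts, out: run_expr(opts, out),
    "coexpr": lambda cfg, opts, out: run_coexpr(opts, out),
}
STAGE_ORDER = ["identify", "phylo", "dupl", "expr", "coexpr"]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the enabled stages in order; returns the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"iqfam {__version__}", f"seed {config.seed}"]
    results: dict[str, object] = {}
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        opts = config.stages[stage]
        logger.info("stage %s: start", stage)
        log_lines.append(f"stage {stage}: params {sorted(opts.items())}")
        try:
            results[stage] = _STAGE_RUNNERS[stage](config, opts, out)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(stage, str(exc)) from exc
        logger.info("stage %s: done", stage)
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    _write_summary(results, out)
    return out


def _write_summary(results: dict, out: Path) -> None:
    lines = ["# iqfam run summary", ""]
    if "identify" in results:
        t = results["identify"]
        lines += [f"family members: {len(t)}", t.to_string(index=False), ""]
    if "phylo" in results:
        r = results["phylo"]
        lines.append(f"tree leaves: {r['n_leaves']}")
        if "subfamilies" in r:
            sizes = pd.Series(list(r["subfamilies"].assignments.values())).value_counts()
            lines.append("subfamily sizes: " + ", ".join(f"{k}={v}" for k, v in sorted(sizes.items())))
        if "ortholog_pairs" in r:
            lines.append(f"ortholog pairs: {len(r['ortholog_pairs'])}")
        lines.append("")
    if "dupl" in results:
        lines += ["duplication pairs:", results["dupl"].to_string(index=False), ""]
    if "expr" in results:
        calls = results["expr"]["call"].value_counts().to_dict()
        lines.append(f"responsiveness calls: {calls}")
    if "coexpr" in results:
        lines.append(f"co-expression edges: {len(results['coexpr'])}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
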