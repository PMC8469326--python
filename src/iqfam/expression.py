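"""qPCR relative-expression analysis by the Livak 2^-ddCt method.

Technical/biological replicates are averaged on the Ct scale, the
target gene is normalized to a reference (housekeeping) gene per
sample (dCt), each sample is then normalized to a calibrator sample
(ddCt), and relative expression is RE = 2^-ddCt.  Amplification
efficiency is fixed at 2, as the formula implies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CT_COLUMNS = ["gene", "sample", "condition", "timepoint", "replicate", "ct"]


@dataclass
class CtTable:
    """Raw qPCR cycle thresholds in long format."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        ct = self.data["ct"]
        if not ((ct > 0) & (ct < 45)).all():
            bad = self.data.loc[~((ct > 0) & (ct < 45))].iloc[0]
            raise ValueError(
                f"Ct out of range (0, 45) for gene {bad['gene']!r} sample {bad['sample']!r}"
            )

    @classmethod
    def read(cls, path, sep: str = "\t") -> "CtTable":
        return cls(pd.read_csv(path, sep=sep))

    def write(self, path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index=False, lineterminator="\n")

    def mean_ct(self) -> pd.DataFrame:
        """Replicate-averaged Ct per (gene, sample)."""
        return (
            self.data.groupby(["gene", "sample"], sort=False)["ct"]
            .mean()
            .reset_index()
        )


@dataclass
class RelativeExpression:
    """Per-(gene, sample) fold changes with dCt/ddCt retained."""

    data: pd.DataFrame  # columns: gene, sample, dct, ddct, re
    calibrator: str
    reference: str


def relative_expression(
    table: CtTable, target: str, reference: str, calibrator: str
) -> RelativeExpression:
    """2^-ddCt relative expression of ``target`` across samples.

    Replicates are averaged to a mean Ct first; dCt = Ct_target -
    Ct_reference per sample; ddCt is relative to the calibrator sample;
    RE = 2^-ddCt (so RE of the calibrator is exactly 1).
    """
    mean = table.mean_ct()
    ref = mean[mean["gene"] == reference].set_index("sample")["ct"]
    tgt = mean[mean["gene"] == target].set_index("sample")["ct"]
    if tgt.empty:
        raise ValueError(f"target gene {target!r} not in Ct table")
    for sample in tgt.index:
        if sample not in ref.index:
            raise ValueError(f"reference gene {reference!r} missing in sample {sample!r}")
    if calibrator not in tgt.index:
        raise ValueError(f"calibrator sample {calibrator!r} not measured for {target!r}")
    dct = tgt - ref.loc[tgt.index]
    ddct = dct - dct.loc[calibrator]
    re = np.exp2(-ddct)
    out = pd.DataFrame(
        {
            "gene": target,
            "sample": dct.index,
            "dct": dct.values,
            "ddct": ddct.values,
            "re": re.values,
        }
    )
    return RelativeExpression(data=out, calibrator=calibrator, reference=reference)


def relative_expression_all(
    table: CtTable, reference: str, calibrator: str
) -> RelativeExpression:
    """Relative expression for every non-reference gene in the table."""
    genes = [g for g in table.data["gene"].unique() if g != reference]
    frames = [
        relative_expression(table, g, reference, calibrator).data for g in genes
    ]
    return RelativeExpression(
        data=pd.concat(frames, ignore_index=True),
        calibrator=calibrator,
        reference=reference,
    )


def responsiveness_calls(
    re: RelativeExpression, fold_threshold: float = 2.0
) -> pd.DataFrame:
    """Call each (gene, sample) up/down/none by fold change.

    ``up`` if RE >= threshold, ``down`` if RE <= 1/threshold, else
    ``none``.  The numeric cutoff is a package convention (published
    qualitative calls rarely state one); 2-fold is the default.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    calls = re.data.copy()
    calls["call"] = "none"
    calls.loc[calls["re"] >= fold_threshold, "call"] = "up"
    calls.loc[calls["re"] <= 1 / fold_threshold, "call"] = "down"
    return calls[["gene", "sample", "re", "call"]]


def heatmap_matrix(
    re: RelativeExpression,
    transform: str = "log2",
    row_scale: bool = False,
    figure_path=None,
) -> pd.DataFrame:
    """Gene x sample matrix of (optionally log2, optionally per-gene
    z-scaled) relative expression; optionally renders a heat map."""
    if transform not in ("log2", "none"):
        raise ValueError(f"unknown transform {transform!r}")
    mat = re.data.pivot(index="gene", columns="sample", values="re")
    if mat.isna().any().any():
        missing = [
            (g, s) for g in mat.index for s in mat.columns if pd.isna(mat.loc[g, s])
        ]
        raise ValueError(f"incomplete gene x sample grid: {missing}")
    if transform == "log2":
        mat = np.log2(mat)
    if row_scale:
        mat = mat.sub(mat.mean(axis=1), axis=0).div(mat.std(axis=1, ddof=0), axis=0)
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(1 + 0.5 * mat.shape[1], 1 + 0.4 * mat.shape[0])
        )
        im = ax.imshow(mat.values, aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=7)
        fig.colorbar(im, ax=ax, shrink=0.7)
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return mat
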