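"""Relative qPCR quantification by the 2^(-ddCt) method.

Cycle-threshold (Ct) values of target genes are normalized to the arithmetic
mean Ct of a panel of endogenous reference genes (dCt, equivalent to the
geometric mean of reference quantities), then to the control group's mean
dCt (ddCt); the per-replicate fold change is 2^(-ddCt).  Technical
replicates are collapsed (mean Ct per sample x gene) before dCt, because
biological replicates are the unit of analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "FoldChangeResult",
    "delta_ct",
    "fold_change",
    "read_ct_csv",
]

DEFAULT_REFERENCE_GENES = ("GAPDH", "B2M", "ACTB")


@dataclass
class CtTable:
    """Replicate-level Ct values: rows of (sample_id, group, gene, ct).

    ``reference_genes`` name the endogenous controls; target genes default
    to every other gene in the table.
    """

    data: pd.DataFrame
    reference_genes: tuple = DEFAULT_REFERENCE_GENES
    target_genes: tuple | None = None

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
        ct = self.data["ct"]
        if not ((ct > 0) & (ct < 45)).all():
            raise ValueError("Ct values must lie in (0, 45) cycles")
        self.reference_genes = tuple(self.reference_genes)
        if self.target_genes is None:
            genes = self.data["gene"].unique()
            self.target_genes = tuple(
                g for g in genes if g not in self.reference_genes
            )
        else:
            self.target_genes = tuple(self.target_genes)

    def collapsed(self) -> pd.DataFrame:
        """Mean Ct per (sample, group, gene): technical-replicate collapse."""
        return (
            self.data.groupby(["sample_id", "group", "gene"], as_index=False)["ct"]
            .mean()
        )


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-(gene, group) fold-change summary over biological replicates."""

    gene: str
    group: str
    mean_fold: float
    sd_fold: float
    n: int

    def __post_init__(self) -> None:
        if not self.mean_fold > 0:
            raise ValueError("mean fold must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def delta_ct(table: CtTable) -> pd.DataFrame:
    """dCt per (sample, target gene): Ct_target - mean(Ct of references).

    Samples missing any reference gene are skipped with a warning.
    """
    df = table.collapsed()
    wide = df.pivot_table(index=["sample_id", "group"], columns="gene",
                          values="ct")
    refs = [g for g in table.reference_genes if g in wide.columns]
    if len(refs) < len(table.reference_genes):
        missing = set(table.reference_genes) - set(refs)
        raise ValueError(f"reference gene(s) absent from table: {sorted(missing)}")
    complete = wide[refs].notna().all(axis=1)
    if not complete.all():
        skipped = wide.index[~complete].get_level_values("sample_id").tolist()
        warnings.warn(f"samples missing reference Ct skipped: {skipped}",
                      stacklevel=2)
        wide = wide[complete]
    ref_mean = wide[refs].mean(axis=1)
    rows = []
    for gene in table.target_genes:
        if gene not in wide.columns:
            continue
        dct = wide[gene] - ref_mean
        for (sample, group), val in dct.dropna().items():
            rows.append(
                {"sample_id": sample, "group": group, "gene": gene,
                 "delta_ct": float(val)}
            )
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "delta_ct"])


def fold_change(table: CtTable, control_group: str) -> list[FoldChangeResult]:
    """2^(-ddCt) fold changes of every target gene in every group.

    ddCt centers each sample's dCt on the control group's mean dCt for
    the same gene; per-group mean and SD are taken on the fold scale over
    biological replicates.  Genes without control-group samples are skipped
    with a warning.
    """
    dct = delta_ct(table)
    if control_group not in set(dct["group"]):
        raise ValueError(f"control group {control_group!r} absent from table")
    results: list[FoldChangeResult] = []
    for gene, sub in dct.groupby("gene", sort=False):
        ctrl = sub.loc[sub["group"] == control_group, "delta_ct"]
        if ctrl.empty:
            warnings.warn(f"gene {gene!r} has no control samples; skipped",
                          stacklevel=2)
            continue
        center = ctrl.mean()
        folds = 2.0 ** (-(sub["delta_ct"] - center))
        for group, gsub in folds.groupby(sub["group"], sort=False):
            vals = gsub.to_numpy()
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            results.append(
                FoldChangeResult(gene=str(gene), group=str(group),
                                 mean_fold=float(vals.mean()), sd_fold=sd,
                                 n=int(vals.size))
            )
    return results


def read_ct_csv(path, reference_genes=DEFAULT_REFERENCE_GENES) -> CtTable:
    """Read a ``sample_id,group,gene,ct`` CSV into a CtTable."""
    return CtTable(pd.read_csv(path), reference_genes=reference_genes)
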