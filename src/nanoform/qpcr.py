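"""Relative gene expression by the comparative Ct (2^-ddCt) method.

For each sample the target-gene Ct is normalized to a housekeeping
reference gene (dCt = Ct_target - Ct_reference), calibrated to the mean
dCt of the control group (ddCt = dCt - mean control dCt) and exponentiated
to a fold change 2^-ddCt.  The arithmetic-mean calibrator makes the
geometric mean of control-group fold changes exactly 1, and any constant
shift applied to every Ct (target and reference alike) cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CtTable", "DdctResult", "fold_change_ddct"]


@dataclass
class CtTable:
    """Grouped qPCR Ct records for target and reference genes.

    ``data`` has one row per (sample, gene) with columns ``sample``,
    ``group``, ``gene`` and ``ct``; the reference gene's rows supply the
    per-sample normalizer.
    """

    data: pd.DataFrame = field(repr=False)
    control_group: str = "control"
    reference_gene: str = "GAPDH"

    def __post_init__(self) -> None:
        required = {"sample", "group", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if self.control_group not in set(self.data["group"]):
            raise ValueError(
                f"control group {self.control_group!r} absent from table groups "
                f"{sorted(set(self.data['group']))}"
            )
        ct = self.data["ct"].to_numpy(float)
        if not np.all(np.isfinite(ct)):
            raise ValueError("Ct values must be finite")
        if np.any((ct <= 0) | (ct >= 45)):
            warnings.warn(
                "Ct values outside the typical (0, 45) cycle range",
                UserWarning,
                stacklevel=2,
            )


@dataclass
class DdctResult:
    """Per-sample fold changes and per-group summaries for one target gene."""

    target_gene: str
    per_sample: pd.DataFrame = field(repr=False)  # sample, group, dct, ddct, fold
    per_group: pd.DataFrame = field(repr=False)  # group, n, fold_mean, fold_sd
    calibrator_dct: float = float("nan")


def fold_change_ddct(table: CtTable, target_gene: str) -> DdctResult:
    """Compute 2^-ddCt fold changes for one target gene.

    Samples lacking a reference-gene Ct are excluded with a warning; an
    empty control group (after exclusions) is an error since no calibrator
    can be formed.
    """
    df = table.data
    genes = set(df["gene"])
    if target_gene not in genes:
        raise ValueError(f"target gene {target_gene!r} not in table genes {sorted(genes)}")
    target = df[df["gene"] == target_gene].set_index("sample")
    ref = df[df["gene"] == table.reference_gene].set_index("sample")

    missing_ref = sorted(set(target.index) - set(ref.index))
    if missing_ref:
        warnings.warn(
            f"excluding samples with no {table.reference_gene} Ct: {missing_ref}",
            UserWarning,
            stacklevel=2,
        )
    common = target.index.intersection(ref.index)
    target = target.loc[common]

    dct = target["ct"].to_numpy(float) - ref.loc[common, "ct"].to_numpy(float)
    groups = target["group"].to_numpy()
    control_mask = groups == table.control_group
    if not control_mask.any():
        raise ValueError(
            f"no usable samples in control group {table.control_group!r}"
        )
    calibrator = float(dct[control_mask].mean())
    ddct = dct - calibrator
    fold = 2.0 ** (-ddct)

    per_sample = pd.DataFrame(
        {
            "sample": common,
            "group": groups,
            "dct": dct,
            "ddct": ddct,
            "fold": fold,
        }
    ).reset_index(drop=True)
    per_group = (
        per_sample.groupby("group", sort=False)["fold"]
        .agg(n="size", fold_mean="mean", fold_sd="std")
        .reset_index()
    )
    return DdctResult(
        target_gene=target_gene,
        per_sample=per_sample,
        per_group=per_group,
        calibrator_dct=calibrator,
    )
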