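"""qPCR quantification: 2^-ΔΔCT relative expression and ChIP-qPCR folds.

Relative mRNA levels follow the Livak 2^-ΔΔCT convention: technical
replicates with CT above a cut-off (30 cycles by default) are excluded, the
remaining Ct values are averaged per (sample, gene) on the Ct scale, ΔCT is
taken against a reference gene (GAPDH in the source experiments), ΔΔCT
against a calibrator group whose expression is defined as 1, and the fold
change is 2^-ΔΔCT.  ChIP-qPCR signals are expressed as fold change over the
histone-H3 immunoprecipitate of the same locus, with fold > 1 as the
binding threshold.  Group statistics use the log (expression) or square
root (ChIP) transform conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TTestReport, one_sample_test, welch_test

__all__ = [
    "CtTable",
    "ddct_fold_change",
    "chip_qpcr_fold",
    "relative_level_test",
    "DEFAULT_CT_MAX",
]

DEFAULT_CT_MAX = 30.0


@dataclass
class CtTable:
    """Long-format qPCR cycle-threshold measurements.

    ``data`` columns: ``sample, group, gene, replicate, ct``.  The
    annotations name the reference gene used for ΔCT and the calibrator
    group whose fold change is 1 by construction.
    """

    data: pd.DataFrame
    reference_gene: str
    calibrator_group: str

    def __post_init__(self) -> None:
        required = {"sample", "group", "gene", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if self.calibrator_group not in set(self.data["group"]):
            raise ValueError(f"calibrator group {self.calibrator_group!r} absent from table")


def _mean_ct(table: CtTable, ct_max: float) -> pd.DataFrame:
    """Replicate-filtered mean Ct per (sample, group, gene)."""
    df = table.data
    kept = df[df["ct"] <= ct_max]
    agg = (
        kept.groupby(["sample", "group", "gene"])["ct"]
        .agg(mean_ct="mean", n_used="size")
        .reset_index()
    )
    total = (
        df.groupby(["sample", "group", "gene"])["ct"].size().rename("n_total").reset_index()
    )
    merged = total.merge(agg, on=["sample", "group", "gene"], how="left")
    merged["n_used"] = merged["n_used"].fillna(0).astype(int)
    merged["n_excluded"] = merged["n_total"] - merged["n_used"]
    return merged


def ddct_fold_change(table: CtTable, ct_max: float = DEFAULT_CT_MAX) -> pd.DataFrame:
    """Relative expression per (sample, gene) by the 2^-ΔΔCT method.

    Replicates with ``Ct > ct_max`` are excluded before averaging.  The
    returned frame has one row per (group, sample, gene) excluding the
    reference gene, with ``delta_ct``, ``delta_delta_ct``, ``fold_change``,
    replicate bookkeeping, and an ``absent`` flag for targets whose
    replicates were all excluded.  The calibrator ΔCT per gene is the mean
    over calibrator samples.

    Raises when the reference gene was not measured (or fully excluded) in
    a sample that has target measurements.
    """
    means = _mean_ct(table, ct_max)
    ref = means[means["gene"] == table.reference_gene].set_index("sample")
    targets = means[means["gene"] != table.reference_gene].copy()
    missing_ref = set(targets["sample"]) - set(ref[ref["n_used"] > 0].index)
    if missing_ref:
        raise ValueError(f"reference gene missing for samples: {sorted(missing_ref)}")
    targets["delta_ct"] = (
        targets["mean_ct"].to_numpy() - ref.loc[targets["sample"], "mean_ct"].to_numpy()
    )
    cal = targets[targets["group"] == table.calibrator_group]
    cal_dct = cal.groupby("gene")["delta_ct"].mean()
    unknown = set(targets["gene"]) - set(cal_dct.index)
    if unknown:
        raise ValueError(f"genes missing from calibrator group: {sorted(unknown)}")
    targets["delta_delta_ct"] = targets["delta_ct"].to_numpy() - cal_dct.loc[
        targets["gene"]
    ].to_numpy()
    targets["fold_change"] = 2.0 ** (-targets["delta_delta_ct"])
    targets["absent"] = targets["n_used"] == 0
    cols = [
        "group",
        "sample",
        "gene",
        "delta_ct",
        "delta_delta_ct",
        "fold_change",
        "n_used",
        "n_excluded",
        "absent",
    ]
    return targets[cols].reset_index(drop=True)


def chip_qpcr_fold(
    measurements: pd.DataFrame,
    reference_antibody: str = "H3",
    value_col: str | None = None,
) -> pd.DataFrame:
    """Per-gene fold change of each antibody's signal over the reference
    (H3) immunoprecipitate, with the fold > 1 binding flag.

    ``measurements`` has columns ``gene, antibody`` plus either a
    ``quantity`` column (fold = quantity / H3 quantity) or a ``ct`` column
    (fold = 2^-(Ct_ab - Ct_H3)); ``value_col`` forces the choice when both
    are present.
    """
    if value_col is None:
        value_col = "quantity" if "quantity" in measurements.columns else "ct"
    if value_col not in measurements.columns:
        raise ValueError(f"measurements lack a {value_col!r} column")
    agg = measurements.groupby(["gene", "antibody"])[value_col].mean().reset_index()
    ref = agg[agg["antibody"] == reference_antibody].set_index("gene")[value_col]
    missing = set(agg["gene"]) - set(ref.index)
    if missing:
        raise ValueError(f"no {reference_antibody} measurement for genes: {sorted(missing)}")
    out = agg.copy()
    ref_vals = ref.loc[out["gene"]].to_numpy(dtype=float)
    vals = out[value_col].to_numpy(dtype=float)
    if value_col == "ct":
        out["fold_vs_reference"] = 2.0 ** (-(vals - ref_vals))
    else:
        if (ref_vals <= 0).any():
            raise ValueError("reference quantities must be positive")
        out["fold_vs_reference"] = vals / ref_vals
    out["above_threshold"] = out["fold_vs_reference"] > 1.0
    return out[["gene", "antibody", "fold_vs_reference", "above_threshold"]]


def relative_level_test(
    fold_changes,
    comparison: str = "vs_1",
    other=None,
    transform: str = "log",
) -> TTestReport:
    """Statistics on fold changes across biological replicates.

    ``vs_1``: one-sample t-test of the transformed folds against the
    transformed null value 1 (used against the calibrator condition).
    ``vs_group``: Welch's t-test between two sets of transformed folds.
    ``transform``: ``log`` (expression convention) or ``sqrt`` (ChIP-qPCR
    convention).
    """
    x = np.asarray(fold_changes, dtype=float)
    if transform == "log":
        if (x <= 0).any():
            raise ValueError("log transform requires positive fold changes")
        tx = np.log(x)
        null = 0.0
    elif transform == "sqrt":
        if (x < 0).any():
            raise ValueError("sqrt transform requires nonnegative fold changes")
        tx = np.sqrt(x)
        null = 1.0
    else:
        raise ValueError(f"unknown transform {transform!r}")
    if comparison == "vs_1":
        return one_sample_test(tx, popmean=null, name="fold")
    if comparison == "vs_group":
        if other is None:
            raise ValueError("vs_group comparison requires the second group")
        y = np.asarray(other, dtype=float)
        if transform == "log":
            if (y <= 0).any():
                raise ValueError("log transform requires positive fold changes")
            ty = np.log(y)
        else:
            if (y < 0).any():
                raise ValueError("sqrt transform requires nonnegative fold changes")
            ty = np.sqrt(y)
        return welch_test(tx, ty, names=("a", "b"))
    raise ValueError(f"unknown comparison {comparison!r}")
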