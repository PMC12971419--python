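"""Relative qPCR quantification by the 2^-ddCt method.

Each target gene is normalized against a reference gene measured in the same
sample (dCt = Ct_target - Ct_reference), then against the mean dCt of the
control condition (ddCt). Fold change is 2^-ddCt, assuming amplification
efficiency 2 per cycle. Statistics are computed on ddCt values (log scale),
where technical noise is approximately Gaussian, not on the log-normal folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import InputError

CT_RANGE = (0.0, 45.0)


@dataclass
class CtTable:
    """Raw Ct measurements with a designated reference gene and control condition.

    ``data`` columns: sample, condition, target, ct, replicate. The reference
    gene must be measured in every sample that has any target measurement.
    """

    data: pd.DataFrame
    reference: str
    control: str

    def __post_init__(self) -> None:
        required = {"sample", "condition", "target", "ct", "replicate"}
        missing = required - set(self.data.columns)
        if missing:
            raise InputError(f"Ct table missing columns {sorted(missing)}")
        ct = self.data["ct"].to_numpy(float)
        if np.any(~np.isfinite(ct)) or np.any(ct <= CT_RANGE[0]) or np.any(
            ct >= CT_RANGE[1]
        ):
            raise InputError(f"Ct values must lie in {CT_RANGE}")
        if self.control not in set(self.data["condition"]):
            raise InputError(f"control condition {self.control!r} absent from table")
        has_ref = set(self.data.loc[self.data["target"] == self.reference, "sample"])
        for sample in self.data.loc[self.data["target"] != self.reference, "sample"]:
            if sample not in has_ref:
                raise InputError(
                    f"sample {sample!r} has no Ct for reference gene "
                    f"{self.reference!r}"
                )


@dataclass
class RelExpr:
    """Per-sample and per-condition relative expression (2^-ddCt)."""

    per_sample: pd.DataFrame  # sample, condition, target, dct, ddct, fold
    summary: pd.DataFrame  # condition, target, ddct_mean, ddct_sd, fold, percent_change
    reference: str
    control: str


def read_ct_table(
    path: str, reference: str, control: str
) -> CtTable:
    """Read a Ct TSV (columns sample, condition, target, ct[, replicate])."""
    df = pd.read_csv(path, sep="\t")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return CtTable(df, reference=reference, control=control)


def delta_delta_ct(table: CtTable, average_technical: bool = True) -> RelExpr:
    """Compute per-sample ddCt and 2^-ddCt folds relative to the control condition.

    Technical replicates of a (sample, target) pair are averaged in Ct space
    first (default); ddCt is referenced to the mean dCt of the control
    condition per target. Condition summaries report the geometric-mean fold
    (2^-mean ddCt) with SD in ddCt space.
    """
    df = table.data
    if average_technical:
        df = (
            df.groupby(["sample", "condition", "target"], as_index=False)["ct"]
            .mean()
        )
    ref = df[df["target"] == table.reference].set_index("sample")["ct"]
    targets = df[df["target"] != table.reference].copy()
    if targets.empty:
        raise InputError("no target genes in Ct table")
    missing_ref = sorted(set(targets["sample"]) - set(ref.index))
    if missing_ref:
        raise InputError(f"missing reference Ct for sample {missing_ref[0]!r}")
    targets["dct"] = targets["ct"].to_numpy() - ref.loc[targets["sample"]].to_numpy()

    control_mean = (
        targets[targets["condition"] == table.control]
        .groupby("target")["dct"]
        .mean()
    )
    if control_mean.empty:
        raise InputError(f"control condition {table.control!r} has no target data")
    absent = sorted(set(targets["target"]) - set(control_mean.index))
    if absent:
        raise InputError(f"target {absent[0]!r} not measured in control condition")
    targets["ddct"] = targets["dct"].to_numpy() - control_mean.loc[
        targets["target"]
    ].to_numpy()
    targets["fold"] = 2.0 ** (-targets["ddct"])

    summary = (
        targets.groupby(["condition", "target"])["ddct"]
        .agg(ddct_mean="mean", ddct_sd="std", n="count")
        .reset_index()
    )
    summary["fold"] = 2.0 ** (-summary["ddct_mean"])
    summary["percent_change"] = 100.0 * (summary["fold"] - 1.0)
    cols = ["sample", "condition", "target", "ct", "dct", "ddct", "fold"]
    return RelExpr(
        per_sample=targets[cols].reset_index(drop=True),
        summary=summary,
        reference=table.reference,
        control=table.control,
    )


def knockdown_percent(
    rel: RelExpr, target: str, condition: str | None = None
) -> float:
    """Percent reduction of a target vs the control condition.

    100 x (1 - fold); a fold above 1 yields a negative value (an increase).
    With a single treated condition the condition argument may be omitted.
    """
    summ = rel.summary
    rows = summ[(summ["target"] == target) & (summ["condition"] != rel.control)]
    if condition is not None:
        rows = rows[rows["condition"] == condition]
    if len(rows) == 0:
        raise InputError(f"no non-control measurements for target {target!r}")
    if len(rows) > 1:
        raise InputError(
            f"target {target!r} measured in several conditions; pass condition="
        )
    fold = float(rows["fold"].iloc[0])
    return 100.0 * (1.0 - fold)


def group_compare(
    rel: RelExpr, condition_a: str, condition_b: str, target: str
) -> tuple[float, float]:
    """Welch two-sample t-test between two conditions, on ddCt values.

    Returns (t, two-tailed p). Testing happens on the log scale because folds
    are log-normal under Gaussian Ct noise.
    """
    ps = rel.per_sample
    a = ps[(ps["condition"] == condition_a) & (ps["target"] == target)]["ddct"]
    b = ps[(ps["condition"] == condition_b) & (ps["target"] == target)]["ddct"]
    if len(a) < 2 or len(b) < 2:
        raise InputError("need >= 2 replicates per condition for a t-test")
    a = a.to_numpy(float)
    b = b.to_numpy(float)
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0  # degenerate: identical constant groups
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
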