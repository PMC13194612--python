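"""Relative gene expression by the 2^-ΔΔCt method.

Input is a long Ct table (gene, condition, replicate, ct).  Per replicate,
ΔCt = Ct_target - Ct_reference (paired within condition/replicate, the
reference gene being an internal control such as 16S rRNA).  Per treated
replicate, ΔΔCt = ΔCt - mean control ΔCt, so the control's own mean ΔΔCt is
0 by construction.  Fold change = 2^-ΔΔCt and log2 fold change = -ΔΔCt
(amplification efficiency fixed at 2, the classic assumption).  Gene-wise
treated-vs-control comparisons use Welch t-tests on ΔCt with
Benjamini–Hochberg correction across the gene x condition family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CT_COLUMNS = ("gene", "condition", "replicate", "ct")


def validate_ct_table(ct: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(ct["ct"]).all():
        raise ValueError("Ct values must be finite")
    for cond, sub in ct.groupby("condition"):
        if not (sub["gene"] == reference_gene).any():
            raise ValueError(f"reference gene {reference_gene!r} absent in condition {cond!r}")
    return ct


def delta_ct(
    ct: pd.DataFrame, reference_gene: str, unpaired: str = "drop"
) -> pd.DataFrame:
    """Per-replicate ΔCt = Ct_target - Ct_reference.

    Pairing is by (condition, replicate); if several reference wells share a
    replicate their mean Ct is used.  Target replicates without a matching
    reference replicate are dropped with a warning (``unpaired="error"``
    raises instead).
    """
    validate_ct_table(ct, reference_gene)
    ref = (
        ct[ct["gene"] == reference_gene]
        .groupby(["condition", "replicate"])["ct"]
        .mean()
        .rename("ct_ref")
    )
    targets = ct[ct["gene"] != reference_gene].copy()
    merged = targets.merge(ref, on=["condition", "replicate"], how="left")
    lost = merged["ct_ref"].isna()
    if lost.any():
        if unpaired == "error":
            raise ValueError("unpaired target replicates (no reference Ct)")
        warnings.warn(f"dropping {int(lost.sum())} unpaired target replicate(s)")
        merged = merged[~lost]
    merged["dct"] = merged["ct"] - merged["ct_ref"]
    return merged[["gene", "condition", "replicate", "ct", "ct_ref", "dct"]]


def delta_delta_ct(dct: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Per-replicate ΔΔCt against the gene's mean control ΔCt.

    Adds ``ddct``, ``fold_change`` (= 2^-ΔΔCt) and ``log2_fc`` (= -ΔΔCt)
    columns.  Control replicates carry their own deviation from the control
    mean, so the control averages to ΔΔCt 0 / fold change 1.
    """
    out = []
    for gene, sub in dct.groupby("gene", sort=False):
        control = sub.loc[sub["condition"] == control_condition, "dct"]
        if control.empty:
            raise ValueError(f"no control ΔCt for gene {gene!r}")
        sub = sub.copy()
        sub["ddct"] = sub["dct"] - control.mean()
        out.append(sub)
    res = pd.concat(out, ignore_index=True)
    res["fold_change"] = 2.0 ** (-res["ddct"])
    res["log2_fc"] = -res["ddct"]
    return res


def summarize_expression(ddct: pd.DataFrame) -> pd.DataFrame:
    """Gene x condition summary: mean ΔΔCt, fold change of the mean, log2FC."""
    rows = []
    for (gene, cond), sub in ddct.groupby(["gene", "condition"], sort=False):
        mean_ddct = sub["ddct"].mean()
        rows.append(
            {
                "gene": gene,
                "condition": cond,
                "n": len(sub),
                "dct_mean": sub["dct"].mean(),
                "ddct": mean_ddct,
                "fold_change": 2.0 ** (-mean_ddct),
                "log2_fc": -mean_ddct,
                "log2_fc_sem": sub["log2_fc"].sem() if len(sub) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def expression_tests(
    dct: pd.DataFrame, control_condition: str, family: str = "all"
) -> pd.DataFrame:
    """Welch t-tests of treated vs control ΔCt per gene/condition.

    BH correction is applied across the whole gene x condition family by
    default (``family="per_gene"`` adjusts within each gene instead).
    Groups with < 2 replicates yield a missing p with a warning.
    """
    rows = []
    for (gene, cond), sub in dct.groupby(["gene", "condition"], sort=False):
        if cond == control_condition:
            continue
        control = dct.loc[
            (dct["gene"] == gene) & (dct["condition"] == control_condition), "dct"
        ].to_numpy(float)
        vals = sub["dct"].to_numpy(float)
        if len(vals) < 2 or len(control) < 2:
            warnings.warn(f"<2 replicates for {gene}/{cond}: p-value missing")
            p = np.nan
        elif np.ptp(vals) == 0 and np.ptp(control) == 0 and vals[0] == control[0]:
            p = 1.0
        else:
            p = float(stats.ttest_ind(vals, control, equal_var=False).pvalue)
        rows.append({"gene": gene, "condition": cond, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    if out.empty:
        return out
    if family == "per_gene":
        for gene, sub in out.groupby("gene"):
            mask = sub["p"].notna()
            if mask.any():
                out.loc[sub.index[mask], "p_adj"] = multipletests(
                    sub.loc[mask, "p"], method="fdr_bh"
                )[1]
    else:
        mask = out["p"].notna()
        if mask.any():
            out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


def analyze_expression(
    ct: pd.DataFrame,
    reference_gene: str = "16S",
    control_condition: str = "control",
    family: str = "all",
) -> pd.DataFrame:
    """Full pipeline: ΔCt -> ΔΔCt -> summary joined with test p-values."""
    dct = delta_ct(ct, reference_gene)
    ddct = delta_delta_ct(dct, control_condition)
    summary = summarize_expression(ddct)
    tests = expression_tests(dct, control_condition, family)
    return summary.merge(tests, on=["gene", "condition"], how="left")
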