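"""Relative qPCR quantification by the 2^-ddCt method.

Per sample and target gene, replicate Ct values are averaged arithmetically
and referenced to an endogenous control gene:

    dCt  = mean Ct(target) - mean Ct(reference)
    ddCt = dCt - mean dCt of the calibrator group (per target)
    fold = 2^-ddCt

Amplification efficiency is fixed at 2 (the method's defining assumption).
The group-mean calibrator makes the mean ddCt of the calibrator group
exactly zero, i.e. the geometric mean of calibrator-group folds is 1.
Group comparison is a two-sided Student's t-test on per-sample dCt values —
the log2 scale on which fold changes are additive.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

WELL_COLUMNS = ["sample_id", "group", "target", "replicate", "ct"]


class QPCRError(ValueError):
    pass


def read_wells(path: str | Path) -> pd.DataFrame:
    wells = pd.read_csv(path, sep="\t")
    missing = set(WELL_COLUMNS) - set(wells.columns)
    if missing:
        raise QPCRError(f"well table lacks columns {sorted(missing)}")
    return wells


def _validate_wells(wells: pd.DataFrame) -> None:
    ct = wells["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)) or (ct <= 0).any():
        raise QPCRError("Ct values must be finite and positive")
    dup = wells.duplicated(subset=["sample_id", "target", "replicate"])
    if dup.any():
        raise QPCRError("duplicate replicate index for a (sample, target)")


def relative_expression(
    wells: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str = "control",
) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold changes for every non-reference target.

    The calibrator dCt is the mean dCt of ``calibrator_group`` for each
    target.  Raises when a sample measured for a target lacks reference
    wells or when the calibrator group is absent for a target.
    """
    _validate_wells(wells)
    if reference_gene not in set(wells["target"]):
        raise QPCRError(f"reference gene {reference_gene!r} has no wells")
    mean_ct = (
        wells.groupby(["sample_id", "group", "target"], as_index=False)["ct"]
        .mean()
        .rename(columns={"ct": "mean_ct"})
    )
    ref = mean_ct[mean_ct["target"] == reference_gene][
        ["sample_id", "mean_ct"]
    ].rename(columns={"mean_ct": "mean_ct_reference"})
    tgt = mean_ct[mean_ct["target"] != reference_gene].rename(
        columns={"mean_ct": "mean_ct_target"}
    )
    merged = tgt.merge(ref, on="sample_id", how="left")
    if merged["mean_ct_reference"].isna().any():
        bad = merged.loc[merged["mean_ct_reference"].isna(), "sample_id"].unique()
        raise QPCRError(f"missing reference wells for sample(s) {list(bad)[:5]}")
    merged["delta_ct"] = merged["mean_ct_target"] - merged["mean_ct_reference"]

    calib = (
        merged[merged["group"] == calibrator_group]
        .groupby("target")["delta_ct"]
        .mean()
        .rename("calibrator_delta_ct")
    )
    if calib.empty:
        raise QPCRError(f"no samples in calibrator group {calibrator_group!r}")
    merged = merged.merge(calib, on="target", how="left")
    if merged["calibrator_delta_ct"].isna().any():
        bad = merged.loc[merged["calibrator_delta_ct"].isna(), "target"].unique()
        raise QPCRError(f"calibrator group absent for target(s) {list(bad)}")
    merged["delta_delta_ct"] = merged["delta_ct"] - merged["calibrator_delta_ct"]
    merged["fold"] = 2.0 ** (-merged["delta_delta_ct"])
    return merged[
        ["sample_id", "group", "target", "mean_ct_target", "mean_ct_reference",
         "delta_ct", "delta_delta_ct", "fold"]
    ].reset_index(drop=True)


def compare_groups(
    rel: pd.DataFrame, target: str, groups: tuple[str, str] = ("tumor", "control")
) -> dict:
    """Student's t-test between two groups on per-sample dCt for one target.

    Returns the mean fold ratio 2^-(mean dCt_a - mean dCt_b) and the
    two-sided p-value.  Testing on dCt is identical (up to sign) to testing
    on log2(fold), since ddCt differs from dCt by a per-target constant.
    """
    sub = rel[rel["target"] == target]
    a = sub.loc[sub["group"] == groups[0], "delta_ct"].to_numpy(dtype=float)
    b = sub.loc[sub["group"] == groups[1], "delta_ct"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise QPCRError("need >= 2 samples per group")
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    else:
        _, p = stats.ttest_ind(a, b, equal_var=True)
    ratio = 2.0 ** (-(a.mean() - b.mean()))
    return {
        "target": target,
        "groups": list(groups),
        "mean_fold_ratio": float(ratio),
        "p_value": float(p),
        "n": [int(len(a)), int(len(b))],
    }


def write_relative_expression(rel: pd.DataFrame, path: str | Path) -> None:
    rel.to_csv(path, sep="\t", index=False, float_format="%.8g")


def load_primer_table() -> pd.DataFrame:
    """Reference qPCR primer panel shipped with the package.

    Validation primers for the hub lncRNA NEAT1, the pivotal mRNAs FKBP5,
    CDON and PGAP1, and six additional lncRNA transcripts (id, forward,
    reverse, product length in bp).
    """
    path = Path(__file__).parent / "data" / "primers.tsv"
    return pd.read_csv(path, sep="\t")
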