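"""Relative expression by the 2^-ddCt method with dual reference genes.

Technical replicates are averaged first; the reference aggregate is the
arithmetic mean of the two reference genes' technical-mean Cts (equivalent
to the geometric mean of their expression).  dCt = target - reference
aggregate per biological replicate; ddCt subtracts the calibrator group's
mean dCt; fold change = 2^-ddCt.  Amplification efficiency is fixed at 2.0.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .stats import GroupTestResult, run_group_comparison

__all__ = ["compute_relative_expression", "compare_expression_across_zt"]

REFERENCE_GENES = ("RPS13", "G3PDH")


def _technical_means(records: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "zt", "biological_replicate", "ct"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns {sorted(missing)}")
    if not (records["ct"].dropna() > 0).all():
        raise ValueError("Ct values must be positive")
    return (
        records.groupby(["gene", "zt", "biological_replicate"], sort=False)["ct"]
        .mean()
        .reset_index()
    )


def compute_relative_expression(
    records: pd.DataFrame,
    target: str,
    references: Sequence[str] = REFERENCE_GENES,
    calibrator_zt: str = "ZT1",
    notes: list | None = None,
) -> pd.DataFrame:
    """Per-biological-replicate 2^-ddCt fold changes for one target gene.

    Biological replicates lacking the target or either reference Ct are
    excluded (a note is appended to ``notes`` when given).  The calibrator
    group's mean dCt maps to fold change 1 by construction.
    """
    tech = _technical_means(records)
    tgt = tech[tech["gene"] == target].set_index(["zt", "biological_replicate"])["ct"]
    if tgt.empty:
        raise ValueError(f"no Ct rows for target gene {target!r}")
    refs = []
    for ref in references:
        r = tech[tech["gene"] == ref].set_index(["zt", "biological_replicate"])["ct"]
        if r.empty:
            raise ValueError(f"no Ct rows for reference gene {ref!r}")
        refs.append(r)
    ref_agg = pd.concat(refs, axis=1).mean(axis=1, skipna=False)

    dct = (tgt - ref_agg).dropna()
    dropped = set(tgt.index) - set(dct.index)
    if dropped and notes is not None:
        for zt, bio in sorted(dropped):
            notes.append(f"excluded ({zt}, biological {bio}): missing reference Ct")

    cal = dct.loc[calibrator_zt]
    if cal.empty:
        raise ValueError(f"no calibrator rows at {calibrator_zt!r}")
    ddct = dct - cal.mean()
    out = ddct.reset_index()
    out.columns = ["zt", "biological_replicate", "ddct"]
    out.insert(0, "gene", target)
    out["fold_change"] = np.power(2.0, -out["ddct"])
    out["calibrator"] = calibrator_zt
    return out.drop(columns="ddct")


def compare_expression_across_zt(
    expr: pd.DataFrame, alpha: float = 0.05
) -> GroupTestResult:
    """Group comparison of per-biological fold changes across ZT groups."""
    groups = {
        zt: sub["fold_change"].to_numpy()
        for zt, sub in expr.groupby("zt", sort=True)
    }
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >=2 ZT groups with >=2 biological replicates each")
    return run_group_comparison(groups, alpha=alpha)
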