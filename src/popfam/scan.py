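"""Genome-scan driver: run the combined test across the markers of a cohort."""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import core
from .ped import Cohort

__all__ = ["assoc_scan"]

logger = logging.getLogger(__name__)

COLUMNS = [
    "marker_id", "N", "M", "H", "X", "maf_hat", "P", "F", "w", "tau",
    "z", "p_value", "flags",
]


def assoc_scan(
    cohort: Cohort,
    variance_mode: str = "hwe",
    weight_mode: str = "half",
    maf_source: str = "untransmitted",
    strict: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Run the combined test at every marker of a cohort.

    Returns one row per marker with the component statistics, counts and
    two-sided p-value. Per-marker failures (monomorphic marker, no data)
    are downgraded to flagged rows with missing statistics rather than
    aborting the scan; a marker where only the family component is
    informative reports ``z = F``. With ``bh`` an additional
    Benjamini–Hochberg adjusted p-value column is appended.
    """
    rows = []
    for j in range(cohort.n_markers):
        marker_id = cohort.markers.marker_id.iloc[j]
        flags = []
        row = dict.fromkeys(COLUMNS, math.nan)
        row["marker_id"] = marker_id
        try:
            ds = cohort.dataset(j, strict=strict)
        except Exception as exc:  # strict-mode Mendelian failures propagate
            if strict:
                raise
            logger.warning("marker %s: %s", marker_id, exc)
            row["flags"] = "error"
            rows.append(row)
            continue
        if ds.n_trios < len(cohort.trio_members):
            flags.append("trios_dropped")
        row.update(N=ds.n_cases, M=ds.n_controls, H=ds.H, X=ds.X)
        try:
            res = core.popfam_test(
                ds,
                variance_mode=variance_mode,
                weight_mode=weight_mode,
                maf_source=maf_source,
            )
        except ValueError as exc:
            # degenerate marker: fall back to the family component alone
            if ds.H >= 1:
                F = core.wald_stat(ds.H, ds.T_sum)
                from scipy.stats import norm

                row.update(F=F, z=F, w=0.0, tau=0.0,
                           p_value=float(2 * norm.sf(abs(F))))
                flags.append("family_only")
            else:
                flags.append("uninformative")
            logger.warning("marker %s: %s", marker_id, exc)
            row["flags"] = ",".join(flags) or ""
            rows.append(row)
            continue
        if res.H == 0:
            flags.append("h0_fallback")
        row.update(
            maf_hat=res.maf_hat, P=res.P_stat, F=res.F_stat, w=res.w,
            tau=res.tau, z=res.z, p_value=res.p_value,
        )
        row["flags"] = ",".join(flags)
        rows.append(row)
    table = pd.DataFrame(rows, columns=COLUMNS)
    if bh:
        ok = table.p_value.notna()
        adjusted = np.full(len(table), np.nan)
        if ok.any():
            adjusted[ok.to_numpy()] = multipletests(
                table.p_value[ok].to_numpy(), method="fdr_bh"
            )[1]
        table["p_bh"] = adjusted
    return table
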