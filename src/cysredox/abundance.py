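"""Label-free protein-abundance comparison: normalization, fold change, t tests.

Intensities are total-sum normalized (every sample scaled to the mean raw
column total, the "total peptide amount" convention), fold change is taken on
normalized group means, and the per-protein test is an equal-variance
two-tailed Student's t on log2 intensities.  Significance follows the
|log2FC| > 0 and p < 0.05 rule with no multiple-testing correction.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def read_abundance_matrix(path: str | Path) -> pd.DataFrame:
    """Proteins x samples TSV, first column the protein accession."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("abundance matrix contains negative intensities")
    return df


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet TSV: columns sample, condition, replicate."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "condition", "replicate"):
        if col not in df.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    return df


def total_sum_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so all column totals equal the mean raw total."""
    totals = matrix.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with non-positive totals: {bad}")
    target = float(totals.mean())
    return matrix * (target / totals)


def volcano(
    matrix: pd.DataFrame,
    sample_conditions: dict[str, str],
    conditions: tuple[str, str] = ("RT", "Cold"),
    alpha: float = 0.05,
    log2fc_cutoff: float = 0.0,
    log_scale_test: bool = True,
) -> pd.DataFrame:
    """Per-protein fold change and t test between two conditions.

    log2FC = log2(mean_cold / mean_rt) on the (already normalized)
    intensities; the t test runs on log2 intensities by default (raw-scale
    with ``log_scale_test=False``).  Proteins with a zero group mean have no
    defined fold change: they are flagged ``undefined`` and excluded from
    testing.  ``significant`` requires p < alpha and |log2FC| > cutoff.
    """
    ref, alt = conditions
    ref_cols = [s for s in matrix.columns if sample_conditions.get(s) == ref]
    alt_cols = [s for s in matrix.columns if sample_conditions.get(s) == alt]
    if len(ref_cols) < 2 or len(alt_cols) < 2:
        raise ValueError("need >= 2 replicates per condition for testing")
    rows = []
    for acc, row in matrix.iterrows():
        x = row[ref_cols].to_numpy(dtype=float)
        y = row[alt_cols].to_numpy(dtype=float)
        mx, my = float(x.mean()), float(y.mean())
        if mx <= 0 or my <= 0:
            rows.append(
                {
                    "accession": acc,
                    "log2fc": np.nan,
                    "t": np.nan,
                    "p": np.nan,
                    "significant": False,
                    "undefined": True,
                }
            )
            continue
        log2fc = float(np.log2(my / mx))
        if log_scale_test:
            with np.errstate(divide="ignore"):
                xv, yv = np.log2(x), np.log2(y)
        else:
            xv, yv = x, y
        t, p = stats.ttest_ind(xv, yv, equal_var=True)
        t, p = float(t), float(p)
        if np.isnan(p):  # zero pooled variance with equal means
            p = 1.0
            t = 0.0
        rows.append(
            {
                "accession": acc,
                "log2fc": log2fc,
                "t": t,
                "p": p,
                "significant": bool(p < alpha and abs(log2fc) > log2fc_cutoff),
                "undefined": False,
            }
        )
    return pd.DataFrame(rows)
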