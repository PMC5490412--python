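"""Welch t-tests on log2 expression and Stouffer combination across a gene set.

Expression arrives as a long table (gene, condition, timepoint, replicate,
log2_expression), typically qPCR-derived values already normalized against a
housekeeping gene. Per-gene two-sample comparisons use the Welch (unequal
variance) t-test. To ask whether a *set* of genes responds coordinately, the
per-gene p-values are combined with the Stouffer Z-transform:

    Z_x = Phi^-1(1 - P_x),   Z = sum_x Z_x / sqrt(n),   P = 1 - Phi(Z).

No multiplicity correction is applied across genes; the combined p is itself
the set-level summary.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, UsageError

__all__ = [
    "StoufferResult",
    "welch_t",
    "stouffer_combine",
    "read_expression_table",
    "gene_tests",
    "write_gene_tests",
]

EXPRESSION_COLUMNS = ("gene", "condition", "timepoint", "replicate", "log2_expression")


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch t-statistic, Welch-Satterthwaite degrees of freedom, two-sided p.

    Both groups need at least two finite values; a zero-variance group makes
    the statistic degenerate and raises, naming the offending group — except
    when the two groups are entirely identical, which trivially carries no
    evidence (t = 0, p = 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    for name, values in (("group_a", a), ("group_b", b)):
        if values.size < 2:
            raise ValueError(f"{name} needs at least 2 values, got {values.size}")
        if not np.isfinite(values).all():
            raise ValueError(f"{name} contains non-finite values")
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        df = float(a.size + b.size - 2)
        return 0.0, df, 1.0
    for name, values in (("group_a", a), ("group_b", b)):
        if np.var(values, ddof=1) == 0:
            raise ValueError(f"degenerate (zero) variance in {name}")
    result = stats.ttest_ind(a, b, equal_var=False)
    return float(result.statistic), float(result.df), float(result.pvalue)


@dataclass(frozen=True)
class StoufferResult:
    """Combined evidence over n one-sided normal transforms of p-values."""

    z_values: tuple[float, ...]
    z_combined: float
    p_combined: float
    n: int


def stouffer_combine(pvalues: Sequence[float]) -> StoufferResult:
    """Stouffer Z-transform combination of p-values.

    Each p maps to Z = Phi^-1(1 - p); their sum over sqrt(n) is standard
    normal under the joint null, and the combined p is its upper tail. With a
    single input the combined p equals that input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if ((p <= 0) | (p >= 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie strictly inside (0, 1)")
    z = stats.norm.isf(p)
    z_combined = float(z.sum() / math.sqrt(p.size))
    return StoufferResult(
        z_values=tuple(float(v) for v in z),
        z_combined=z_combined,
        p_combined=float(stats.norm.sf(z_combined)),
        n=int(p.size),
    )


def read_expression_table(path: str | os.PathLike[str]) -> pd.DataFrame:
    """Read the long-format expression TSV and validate its columns."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"expression table is missing columns: {missing}")
    if not np.isfinite(table["log2_expression"]).all():
        raise FormatError("expression table contains non-finite log2 values")
    return table


def gene_tests(
    table: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    timepoint: str | None = None,
) -> tuple[pd.DataFrame, StoufferResult]:
    """Per-gene Welch tests between two conditions plus the set-level summary.

    Returns a frame with one row per gene (t, df, p) and the Stouffer
    combination of all per-gene p-values.
    """
    if timepoint is not None:
        table = table[table["timepoint"].astype(str) == str(timepoint)]
    rows = []
    for gene in sorted(table["gene"].unique()):
        sub = table[table["gene"] == gene]
        a = sub.loc[sub["condition"] == condition_a, "log2_expression"].to_numpy()
        b = sub.loc[sub["condition"] == condition_b, "log2_expression"].to_numpy()
        if a.size < 2 or b.size < 2:
            raise UsageError(
                f"gene {gene!r} lacks >=2 replicates in both conditions "
                f"({condition_a!r}: {a.size}, {condition_b!r}: {b.size})"
            )
        t, df, p = welch_t(a, b)
        rows.append({"gene": gene, "t": t, "df": df, "p": p})
    if not rows:
        raise UsageError("no genes found for the requested comparison")
    frame = pd.DataFrame(rows)
    # p = 1 rows (identical groups) sit on the open-interval boundary; nudge
    usable = frame["p"].clip(upper=1 - 1e-12, lower=1e-300)
    return frame, stouffer_combine(usable.to_numpy())


def write_gene_tests(frame: pd.DataFrame, path: str | os.PathLike[str]) -> None:
    frame.to_csv(path, sep="\t", index=False)
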