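"""Group comparison and relative-expression statistics.

Per-lobe measurements are compared between genotype groups with the
two-sided two-sample Kolmogorov-Smirnov test (exact p-values for small
samples, asymptotic otherwise), summarised per group by mean, SEM and
the 5%/95% percentiles — the same summaries the scatterplots report.
No multiple-testing correction is applied: comparisons are reported as
individual pairwise P-values.

qPCR-style cycle-threshold tables are reduced to fold changes by the
2^-DDCt convention with a single reference gene: per sample
DCt = Ct_target - Ct_reference, per target DDCt = DCt - mean control
DCt, relative expression 2^-DDCt, and the control group is normalised
to ~1 by construction. Group differences in fold change are tested by
Welch's t on the per-sample DDCt values (a configurable convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "FoldChangeResult",
    "ks_compare",
    "summarize_group",
    "fold_change",
    "EXACT_PAIR_PRODUCT_LIMIT",
]

#: use the exact KS p-value when n_a * n_b does not exceed this.
EXACT_PAIR_PRODUCT_LIMIT = 10_000


@dataclass(frozen=True)
class GroupComparison:
    """Two-group KS result with per-group summaries."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    ks_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    pct5_a: float
    pct95_a: float
    pct5_b: float
    pct95_b: float


@dataclass(frozen=True)
class FoldChangeResult:
    """Relative expression of one target gene in one group (control = 1)."""

    target_gene: str
    group_label: str
    fold_change: float
    sem: float
    n: int
    p_value: float  # NaN for the control group


def _check_sample(values, label: str, min_n: int = 3) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size < min_n:
        raise ValueError(f"group {label!r}: need at least {min_n} values, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ValueError(f"group {label!r}: non-finite values")
    return arr


def summarize_group(values: Sequence[float]) -> tuple[float, float, float, float]:
    """(mean, sem, 5th percentile, 95th percentile) of one group.

    SEM uses the n-1 sample standard deviation; a single value yields a
    missing (NaN) SEM. Percentiles use linear interpolation between
    closest ranks.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty group")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in group")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
    pct5, pct95 = np.percentile(arr, [5.0, 95.0], method="linear")
    return mean, sem, float(pct5), float(pct95)


def ks_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Two-sided two-sample Kolmogorov-Smirnov comparison.

    D is the supremum distance between the two empirical CDFs. The
    p-value is exact when ``n_a * n_b <= 10000`` and asymptotic
    otherwise. Groups below 3 values are rejected.
    """
    a = _check_sample(values_a, label_a)
    b = _check_sample(values_b, label_b)
    method = "exact" if a.size * b.size <= EXACT_PAIR_PRODUCT_LIMIT else "asymp"
    res = sps.ks_2samp(a, b, alternative="two-sided", method=method)
    mean_a, sem_a, p5a, p95a = summarize_group(a)
    mean_b, sem_b, p5b, p95b = summarize_group(b)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        ks_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_a=mean_a,
        mean_b=mean_b,
        sem_a=sem_a,
        sem_b=sem_b,
        pct5_a=p5a,
        pct95_a=p95a,
        pct5_b=p5b,
        pct95_b=p95b,
    )


REQUIRED_QPCR_COLUMNS = (
    "sample_id",
    "group_label",
    "target_gene",
    "ct_target",
    "ct_reference",
)


def fold_change(
    table: pd.DataFrame,
    control_label: str,
    fold_change_test: str = "welch",
) -> list[FoldChangeResult]:
    """2^-DDCt relative expression per target gene and group.

    The control group's mean DCt anchors DDCt per target; its own
    reported fold change is the mean of its normalised values (~1, and
    exactly 1 with a single control sample). Fold-change p-values come
    from Welch's t-test on per-sample DDCt against the control group
    (NaN when either side has fewer than 2 samples).

    Invariant: adding any constant to every Ct value (target and
    reference alike) leaves all fold changes unchanged.
    """
    missing = [c for c in REQUIRED_QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"qPCR table lacks columns: {missing}")
    if fold_change_test != "welch":
        raise ValueError(f"unknown fold_change_test {fold_change_test!r}")
    ct = table[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    if control_label not in set(table["group_label"]):
        raise ValueError(f"control group {control_label!r} absent from table")

    df = table.copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    results: list[FoldChangeResult] = []
    for target, sub in df.groupby("target_gene", sort=False):
        ctrl = sub.loc[sub["group_label"] == control_label, "dct"]
        if ctrl.empty:
            raise ValueError(
                f"target {target!r}: no control ({control_label!r}) samples"
            )
        anchor = ctrl.mean()
        for group, grp in sub.groupby("group_label", sort=False):
            ddct = grp["dct"] - anchor
            rel = np.power(2.0, -ddct)
            n = int(rel.size)
            mean = float(rel.mean())
            sem = float(rel.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            if group == control_label:
                p = float("nan")
            elif n >= 2 and ctrl.size >= 2:
                p = float(
                    sps.ttest_ind(ddct, ctrl - anchor, equal_var=False).pvalue
                )
            else:
                p = float("nan")
            results.append(
                FoldChangeResult(
                    target_gene=str(target),
                    group_label=str(group),
                    fold_change=mean,
                    sem=sem,
                    n=n,
                    p_value=p,
                )
            )
    return results


def fold_change_frame(results: Sequence[FoldChangeResult]) -> pd.DataFrame:
    """Fold-change results as a tidy DataFrame."""
    return pd.DataFrame([r.__dict__ for r in results])


def comparison_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Group comparisons as a tidy DataFrame (one row per pair)."""
    return pd.DataFrame([c.__dict__ for c in comparisons])
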