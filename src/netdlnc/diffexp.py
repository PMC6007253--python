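"""Group-wise differential expression with fold-change and p-value gates.

A transcript passes the gate when its linear fold change is at least 2 in
either direction and its two-sided Student's t-test p-value (equal
variance) is below 0.05. The gate runs on raw p-values by default —
multiple-testing control in this pipeline is biological, via the
filter-down intersections that follow — but Benjamini-Hochberg and
Bonferroni adjusted values are always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Recognized comparison labels -> (group_a, group_b) phenotype names.
COMPARISONS: dict[str, tuple[str, str]] = {
    "NEPC_vs_AD": ("AD", "NEPC"),
    "NEPC_vs_NHT": ("NHT", "NEPC"),
    "CRPC_vs_AD": ("AD", "CRPC"),
    "NHT_vs_NAIVE": ("AD_NAIVE", "NHT"),
    "PDX_pre_vs_post": ("PDX_AD", "PDX_NEPC"),
}

#: Comparison (e): transcripts must pass both constituent gates.
COMBINED_E = "COMBINED_E"
COMBINED_E_PARTS = ("NHT_vs_NAIVE", "NEPC_vs_NHT")


@dataclass(frozen=True)
class DifferentialResult:
    transcript_key: str
    comparison: str
    mean_a: float
    mean_b: float
    fold_change: float
    direction: str  # "up" | "down"
    t_statistic: float
    p_value: float
    p_adjusted: Optional[float]
    passes_gate: bool


def t_test_two_sided(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Classical two-sample equal-variance t-test, df = n_a + n_b - 2.

    Zero pooled variance with equal means returns (0, 1); zero pooled
    variance with unequal means is an infinite separation and returns
    (+/-inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def fold_change(
    mean_a: float, mean_b: float, pseudocount: float = 0.1
) -> tuple[float, str]:
    """Linear fold change (mean_b + pc) / (mean_a + pc) with direction.

    With both means 0 and no pseudocount the ratio is undefined; 1.0 is
    returned with direction "down" by convention (ratio <= 1).
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    num, den = mean_b + pseudocount, mean_a + pseudocount
    if den == 0.0 and num == 0.0:
        return 1.0, "down"
    if den == 0.0:
        return float("inf"), "up"
    ratio = num / den
    return ratio, "up" if ratio > 1.0 else "down"


def _gate(fc: float, p: float, fc_gate: float, p_gate: float) -> bool:
    return (fc >= fc_gate or fc <= 1.0 / fc_gate) and p < p_gate


def compare_groups(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    comparison: str,
    fc_gate: float = 2.0,
    p_gate: float = 0.05,
    pseudocount: float = 0.1,
    adjust_method: str = "benjamini_hochberg",
) -> list[DifferentialResult]:
    """Run one named group-wise comparison over all transcripts.

    ``metadata`` must carry a ``phenotype_group`` column indexed by
    sample id. ``COMBINED_E`` is the intersection of its two constituent
    comparisons' gates: a transcript passes only if it passes both; the
    reported statistics are those of the second constituent (NEPC vs NHT).
    """
    if comparison == COMBINED_E:
        part_results = [
            compare_groups(matrix, metadata, part, fc_gate, p_gate, pseudocount,
                           adjust_method)
            for part in COMBINED_E_PARTS
        ]
        passed_first = {
            r.transcript_key for r in part_results[0] if r.passes_gate
        }
        out = []
        for r in part_results[1]:
            out.append(
                DifferentialResult(
                    transcript_key=r.transcript_key,
                    comparison=COMBINED_E,
                    mean_a=r.mean_a,
                    mean_b=r.mean_b,
                    fold_change=r.fold_change,
                    direction=r.direction,
                    t_statistic=r.t_statistic,
                    p_value=r.p_value,
                    p_adjusted=r.p_adjusted,
                    passes_gate=r.passes_gate and r.transcript_key in passed_first,
                )
            )
        return out

    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    name_a, name_b = COMPARISONS[comparison]
    groups = metadata["phenotype_group"]
    # AD-naive samples stand in for plain AD where no AD group exists
    samples_a = groups.index[groups.isin({name_a, "AD_NAIVE"} if name_a == "AD"
                                         else {name_a})]
    samples_b = groups.index[groups == name_b]
    samples_a = [s for s in samples_a if s in matrix.columns]
    samples_b = [s for s in samples_b if s in matrix.columns]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"comparison {comparison}: need >= 2 samples per group "
            f"(got {len(samples_a)} vs {len(samples_b)})"
        )
    sub_a = matrix[samples_a].to_numpy()
    sub_b = matrix[samples_b].to_numpy()
    rows = []
    for i, key in enumerate(matrix.index):
        a, b = sub_a[i], sub_b[i]
        t, p = t_test_two_sided(a, b)
        fc, direction = fold_change(float(a.mean()), float(b.mean()), pseudocount)
        rows.append((key, float(a.mean()), float(b.mean()), fc, direction, t, p))
    p_adj = adjust_p([r[6] for r in rows], adjust_method)
    return [
        DifferentialResult(
            transcript_key=key,
            comparison=comparison,
            mean_a=ma,
            mean_b=mb,
            fold_change=fc,
            direction=direction,
            t_statistic=t,
            p_value=p,
            p_adjusted=pa,
            passes_gate=_gate(fc, p, fc_gate, p_gate),
        )
        for (key, ma, mb, fc, direction, t, p), pa in zip(rows, p_adj)
    ]


def adjust_p(
    p_values: Sequence[float], method: str = "benjamini_hochberg"
) -> list[float]:
    """Multiple-testing adjustment (BH step-up or Bonferroni), clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"benjamini_hochberg": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1].tolist()


def pre_post_overlap(
    results_ar_pos: Iterable[DifferentialResult],
    results_ar_neg: Iterable[DifferentialResult],
) -> tuple[set[str], set[str], set[str]]:
    """Partition gated transcripts of two castration contrasts.

    Returns (common, unique_to_first, unique_to_second) over transcripts
    passing the gate in the AR+ and AR- pre/post-castration comparisons.
    """
    gated_pos = {r.transcript_key for r in results_ar_pos if r.passes_gate}
    gated_neg = {r.transcript_key for r in results_ar_neg if r.passes_gate}
    common = gated_pos & gated_neg
    return common, gated_pos - common, gated_neg - common


def results_to_frame(results: Iterable[DifferentialResult]) -> pd.DataFrame:
    """Tabulate results, one row per transcript x comparison."""
    return pd.DataFrame([r.__dict__ for r in results])
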