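"""Clinical association of candidate lncRNAs.

Class-specific candidate ranking by clinical fold change, liftover of
microarray probe-set regions onto sequenced exons (strict containment),
ROC/AUC for rapid metastasis after androgen deprivation therapy (ADT),
Kaplan-Meier stratification by median expression with a two-group
log-rank test, and relative qPCR quantification (delta-delta-Ct).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import rankdata

from netdlnc.catalogue import TranscriptRecord


@dataclass(frozen=True)
class ProbeRegion:
    """A microarray probe-set genomic region, 0-based half-open."""

    probe_id: str
    chrom: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"probe {self.probe_id!r}: end must exceed start")


# ---------------------------------------------------------------------------
# Candidate ranking

#: How each temporal class turns its clinical fold changes into a rank key.
#: "min" ranks by the smallest (strongest-down) fold change; "max" by the
#: largest magnitude.
CLASS_RANK_RULES: dict[str, tuple[str, tuple[str, ...]]] = {
    "I_Deactivated": ("min", ("NEPC_vs_AD", "CRPC_vs_AD", "NHT_vs_NAIVE")),
    "II_Activated": ("max", ("NEPC_vs_AD",)),
    "III_Persistent": ("max", ("NEPC_vs_AD",)),
    "IV_Transient": ("max_abs", ("NHT_vs_NAIVE", "NEPC_vs_NHT")),
}


def rank_class_transcripts(
    netd_sets: Mapping[str, set[str]],
    fold_changes: Mapping[str, Mapping[str, float]],
    signature_ranked: Optional[pd.DataFrame] = None,
    top_n: int = 20,
    rules: Optional[Mapping[str, tuple[str, tuple[str, ...]]]] = None,
) -> tuple[dict[str, list[str]], list[str]]:
    """Rank each class's NEtD transcripts and select the top candidates.

    ``fold_changes`` maps comparison label -> {transcript: linear fold
    change} (max across cohorts where several cohorts contribute).
    Ranking rules per class: Class I by the minimum fold change over its
    three down contrasts, strongest decline first; Classes II/III by the
    NEPC-vs-AD fold change, largest first; Class IV by the larger
    fold-change magnitude of its two transient contrasts. If a ranked
    signature table is supplied, its top up- and down-regulated members
    form a fifth group of ``top_n``. Returns the per-group selections and
    the de-duplicated union.
    """
    rules = dict(rules) if rules is not None else CLASS_RANK_RULES
    selections: dict[str, list[str]] = {}
    for cls, members in netd_sets.items():
        if cls not in rules:
            continue
        mode, comparisons = rules[cls]
        for comp in comparisons:
            if comp not in fold_changes:
                raise ValueError(f"class {cls}: missing comparison {comp!r}")
        keyed = []
        for t in members:
            fcs = [fold_changes[comp].get(t) for comp in comparisons]
            if any(fc is None for fc in fcs):
                continue
            if mode == "min":
                key = min(fcs)  # smallest ratio = strongest down-regulation
                keyed.append((key, t))
            elif mode == "max":
                keyed.append((-max(fcs), t))
            elif mode == "max_abs":
                mags = [max(fc, 1.0 / fc) for fc in fcs]
                keyed.append((-max(mags), t))
            else:
                raise ValueError(f"unknown rank mode {mode!r}")
        keyed.sort()
        selections[cls] = [t for _k, t in keyed[:top_n]]
    if signature_ranked is not None and len(signature_ranked):
        up = signature_ranked[signature_ranked["fc_cohort_a"] > 1]
        down = signature_ranked[signature_ranked["fc_cohort_a"] <= 1]
        half = top_n // 2
        sig = list(up.index[:half]) + list(down.index[-half:])
        selections["signature"] = sig[:top_n]
    unique: list[str] = []
    seen: set[str] = set()
    for group in selections.values():
        for t in group:
            if t not in seen:
                seen.add(t)
                unique.append(t)
    return selections, unique


# ---------------------------------------------------------------------------
# Probe liftover


def map_probes(
    probes: Iterable[ProbeRegion],
    catalogue: Iterable[TranscriptRecord],
) -> tuple[dict[str, list[str]], dict]:
    """Map probes to transcripts by strict exon containment.

    A probe maps to a transcript iff its [start, end) interval lies
    entirely within one of the transcript's exons; straddling or
    intergenic probes are excluded. Returns {probe_id: [transcript ids]}
    and a report with the mapped fraction and measurable transcripts.
    """
    by_chrom: dict[str, list[TranscriptRecord]] = {}
    for rec in catalogue:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    mapped: dict[str, list[str]] = {}
    probes = list(probes)
    for probe in probes:
        hits = []
        for rec in by_chrom.get(probe.chrom, ()):
            for ex_start, ex_end in rec.exons:
                if ex_start <= probe.start and probe.end <= ex_end:
                    hits.append(rec.transcript_id)
                    break
        if hits:
            mapped[probe.probe_id] = hits
    measurable = sorted({t for hits in mapped.values() for t in hits})
    report = {
        "probes_in": len(probes),
        "probes_mapped": len(mapped),
        "mapped_fraction": len(mapped) / len(probes) if probes else 0.0,
        "measurable_transcripts": measurable,
    }
    return mapped, report


def summarize_probe_expression(
    probe_values: pd.DataFrame, mapped: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Transcript-level array expression = mean of its mapped probes."""
    rows: dict[str, list[str]] = {}
    for probe_id, transcripts in mapped.items():
        if probe_id not in probe_values.index:
            continue
        for t in transcripts:
            rows.setdefault(t, []).append(probe_id)
    out = {
        t: probe_values.loc[probe_ids].mean(axis=0) for t, probe_ids in rows.items()
    }
    return pd.DataFrame(out).T


# ---------------------------------------------------------------------------
# Rapid-metastasis ROC


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC as the Mann-Whitney probability with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative labels")
    ranks = rankdata(scores)  # midranks on ties
    rank_sum_pos = ranks[labels].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def define_rapid_met_groups(
    metadata: pd.DataFrame,
    rapid_months: float = 36.0,
    min_followup_months: float = 120.0,
    arm: str = "treated",
) -> pd.Series:
    """Rapid-metastasis labels among ADT-treated patients.

    Positive: ADT-treated with a metastasis event before ``rapid_months``.
    Negative: ADT-treated, no metastasis, follow-up of at least
    ``min_followup_months``. Everyone else is excluded (NaN).
    ``arm="untreated"`` applies the same outcome definitions to the
    untreated patients instead (the negative-control analysis).
    """
    labels = pd.Series(np.nan, index=metadata.index, dtype=object)
    treated = metadata["adt_treated"].astype(bool)
    if arm == "untreated":
        treated = ~treated
    elif arm != "treated":
        raise ValueError("arm must be 'treated' or 'untreated'")
    event = metadata["metastasis_event"].fillna(False).astype(bool)
    t_met = metadata["time_to_metastasis_months"]
    followup = metadata["followup_months"]
    labels[treated & event & (t_met < rapid_months)] = True
    labels[treated & ~event & (followup >= min_followup_months)] = False
    return labels


# ---------------------------------------------------------------------------
# Kaplan-Meier median split


def km_median_split(
    expression: pd.Series,
    metadata: pd.DataFrame,
    arm: str = "treated",
) -> tuple[dict[str, pd.DataFrame], float]:
    """Stratify one arm by median expression and compare survival curves.

    ``expression`` is one transcript's expression indexed by sample;
    metadata needs ``adt_treated``, ``metastasis_event``,
    ``time_to_metastasis_months`` and ``followup_months``. Ties at the
    median go to the low group. Returns per-group survival tables
    (time, at-risk, survival) and the two-group log-rank p-value.
    """
    if arm not in ("treated", "untreated"):
        raise ValueError("arm must be 'treated' or 'untreated'")
    mask = metadata["adt_treated"].astype(bool)
    if arm == "untreated":
        mask = ~mask
    samples = [s for s in metadata.index[mask] if s in expression.index]
    if len(samples) < 4:
        raise ValueError("need at least 2 samples per group after the split")
    expr = expression.loc[samples]
    event = metadata.loc[samples, "metastasis_event"].fillna(False).astype(bool)
    time = metadata.loc[samples, "time_to_metastasis_months"].where(
        event, metadata.loc[samples, "followup_months"]
    )
    if (time <= 0).all():
        raise ValueError("all survival times are zero")
    median = float(expr.median())
    low = expr <= median  # ties to the low group
    samples_low = [s for s in samples if low[s]]
    samples_high = [s for s in samples if not low[s]]
    groups = {"low": samples_low, "high": samples_high}
    if min(len(samples_low), len(samples_high)) < 2:
        raise ValueError("median split left fewer than 2 samples in a group")
    curves: dict[str, pd.DataFrame] = {}
    for name, members in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(time.loc[members], event.loc[members], label=name)
        table = kmf.event_table
        curves[name] = pd.DataFrame(
            {
                "time": table.index,
                "at_risk": table["at_risk"].to_numpy(),
                "survival": kmf.survival_function_[name]
                .reindex(table.index)
                .to_numpy(),
            }
        ).reset_index(drop=True)
    lr = logrank_test(
        time.loc[samples_low],
        time.loc[samples_high],
        event_observed_A=event.loc[samples_low],
        event_observed_B=event.loc[samples_high],
    )
    return curves, float(lr.p_value)


# ---------------------------------------------------------------------------
# qPCR delta-delta-Ct


def ddct_fold_change(
    ct_triplicates: Mapping[tuple[str, str], Sequence[float]],
    housekeeper_id: str,
    reference_sample: str,
) -> pd.DataFrame:
    """Relative qPCR quantification: fold change = 2^(-ddCt).

    ``ct_triplicates`` maps (target, sample) -> replicate Ct values.
    dCt = mean Ct(target) - mean Ct(housekeeper) per sample; ddCt is taken
    relative to the reference sample.
    """
    means: dict[tuple[str, str], float] = {}
    sds: dict[tuple[str, str], float] = {}
    for key, values in ct_triplicates.items():
        arr = np.asarray(values, dtype=float)
        means[key] = float(arr.mean())
        sds[key] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    samples = sorted({s for _t, s in means})
    targets = sorted({t for t, _s in means if t != housekeeper_id})
    for s in samples:
        if (housekeeper_id, s) not in means:
            raise ValueError(f"missing housekeeper Ct for sample {s!r}")
    rows = []
    for target in targets:
        dct = {
            s: means[(target, s)] - means[(housekeeper_id, s)]
            for s in samples
            if (target, s) in means
        }
        if reference_sample not in dct:
            raise ValueError(
                f"missing reference sample {reference_sample!r} for {target!r}"
            )
        for s, value in dct.items():
            ddct = value - dct[reference_sample]
            rows.append(
                {
                    "target": target,
                    "sample": s,
                    "ct_mean": means[(target, s)],
                    "ct_sd": sds[(target, s)],
                    "delta_ct": value,
                    "delta_delta_ct": ddct,
                    "fold_change": 2.0 ** (-ddct),
                }
            )
    return pd.DataFrame(rows)
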