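"""Temporal classification of the PDX castration time series.

The NEtD xenograft series has three stages — androgen-dependent
adenocarcinoma (AD), post-castration regression (postTX; the 8- and
12-week samples), and relapsed NEPC. Each transcript's stage profile is
reduced to two step ratios (postTX/AD, NEPC/postTX) and assigned one of
four temporal classes:

* Class I, Deactivated — continuous decline (net AD->NEPC drop required);
* Class II, Activated — a single-step rise at either transition;
* Class III, Persistent — monotone rise across both steps;
* Class IV, Transient — maximum at postTX (up then down).

Profiles fitting none of these (including a minimum at postTX) are
Unclassified. Class assignments are then intersected with the clinical
group-wise contrasts to produce the per-class NEtD lncRNA sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from netdlnc.diffexp import DifferentialResult

CLASS_LABELS = (
    "I_Deactivated",
    "II_Activated",
    "III_Persistent",
    "IV_Transient",
    "Unclassified",
)

#: PDX metadata phenotype groups per stage.
STAGE_GROUPS = {
    "AD": ("PDX_AD",),
    "postTX": ("PDX_POSTTX_8W", "PDX_POSTTX_12W"),
    "NEPC": ("PDX_NEPC",),
}


@dataclass(frozen=True)
class TemporalProfile:
    transcript_key: str
    expr_AD: float
    expr_postTX: float
    expr_NEPC: float

    def __post_init__(self) -> None:
        if min(self.expr_AD, self.expr_postTX, self.expr_NEPC) < 0:
            raise ValueError(f"{self.transcript_key}: negative expression")


@dataclass(frozen=True)
class TemporalClassAssignment:
    transcript_key: str
    class_label: str
    step1_ratio: float  # postTX / AD
    step2_ratio: float  # NEPC / postTX


def summarize_timepoints(
    matrix: pd.DataFrame, metadata: pd.DataFrame
) -> list[TemporalProfile]:
    """Arithmetic stage means (linear expression) per transcript.

    All three stages must be represented in the metadata; postTX pools the
    8- and 12-week samples.
    """
    stage_samples: dict[str, list[str]] = {}
    groups = metadata["phenotype_group"]
    for stage, names in STAGE_GROUPS.items():
        samples = [s for s in groups.index[groups.isin(names)] if s in matrix.columns]
        if not samples:
            raise ValueError(f"missing PDX stage {stage!r}")
        stage_samples[stage] = samples
    means = {st: matrix[ss].mean(axis=1) for st, ss in stage_samples.items()}
    return [
        TemporalProfile(key, float(means["AD"][key]), float(means["postTX"][key]),
                        float(means["NEPC"][key]))
        for key in matrix.index
    ]


def _step(ratio: float, step_fold: float) -> str:
    if ratio >= step_fold:
        return "up"
    if ratio <= 1.0 / step_fold:
        return "down"
    return "flat"


def assign_class(
    profile: TemporalProfile, step_fold: float = 2.0, pseudocount: float = 0.1
) -> TemporalClassAssignment:
    """Assign one temporal class from the two step ratios.

    Step directions use a symmetric fold threshold (up if ratio >=
    ``step_fold``, down if <= 1/``step_fold``). Class I additionally
    requires a net AD->NEPC decline of at least ``step_fold`` so that
    borderline (down, flat) drifts do not qualify. (up, up) is checked as
    Class III before the single-step patterns so it can never land in
    Class II.
    """
    if step_fold <= 1.0:
        raise ValueError("step_fold must exceed 1")
    r1 = (profile.expr_postTX + pseudocount) / (profile.expr_AD + pseudocount)
    r2 = (profile.expr_NEPC + pseudocount) / (profile.expr_postTX + pseudocount)
    overall = (profile.expr_NEPC + pseudocount) / (profile.expr_AD + pseudocount)
    s1, s2 = _step(r1, step_fold), _step(r2, step_fold)
    if s1 == "up" and s2 == "up":
        label = "III_Persistent"
    elif s1 == "up" and s2 == "down":
        label = "IV_Transient"
    elif (s1, s2) in (("up", "flat"), ("flat", "up")):
        label = "II_Activated"
    elif (
        (s1, s2) in (("down", "down"), ("down", "flat"), ("flat", "down"))
        and overall <= 1.0 / step_fold
    ):
        label = "I_Deactivated"
    else:
        label = "Unclassified"
    return TemporalClassAssignment(profile.transcript_key, label, r1, r2)


def classify_all(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    step_fold: float = 2.0,
    pseudocount: float = 0.1,
) -> list[TemporalClassAssignment]:
    """Summarize stages and classify every transcript in the matrix."""
    return [
        assign_class(p, step_fold, pseudocount)
        for p in summarize_timepoints(matrix, metadata)
    ]


#: Default model-to-clinic wiring: which clinical gates retain each class.
#: Each entry maps a class to a list of (comparison, direction) conditions;
#: a transcript is retained if it passes the gate in ANY listed condition
#: (direction None = either direction).
DEFAULT_CLASS_MAPPING: dict[str, list[tuple[str, str | None]]] = {
    "I_Deactivated": [
        ("NEPC_vs_AD", "down"),
        ("CRPC_vs_AD", "down"),
        ("NHT_vs_NAIVE", "down"),
    ],
    "II_Activated": [("NEPC_vs_AD", "up"), ("NEPC_vs_NHT", "up")],
    "III_Persistent": [("NEPC_vs_AD", "up")],
    "IV_Transient": [("COMBINED_E", None)],
}


def integrate_clinical(
    assignments: Iterable[TemporalClassAssignment],
    clinical_results: Iterable[DifferentialResult],
    mapping: Mapping[str, list[tuple[str, str | None]]] | None = None,
) -> dict[str, set[str]]:
    """Intersect PDX temporal classes with clinical deregulation gates.

    Returns the per-class NEtD transcript sets: a class member is retained
    when it passes the gate, in the required direction, of at least one of
    the comparisons wired to its class.
    """
    mapping = dict(mapping) if mapping is not None else DEFAULT_CLASS_MAPPING
    for cls in mapping:
        if cls not in CLASS_LABELS:
            raise ValueError(f"unknown class in mapping: {cls!r}")
    gated: dict[tuple[str, str], set[str]] = {}
    for r in clinical_results:
        if r.passes_gate:
            gated.setdefault((r.comparison, r.direction), set()).add(r.transcript_key)
            gated.setdefault((r.comparison, "any"), set()).add(r.transcript_key)
    out: dict[str, set[str]] = {cls: set() for cls in mapping}
    for a in assignments:
        conditions = mapping.get(a.class_label)
        if not conditions:
            continue
        for comparison, direction in conditions:
            hits = gated.get((comparison, direction or "any"), set())
            if a.transcript_key in hits:
                out[a.class_label].add(a.transcript_key)
                break
    return out


def assignments_to_frame(
    assignments: Iterable[TemporalClassAssignment],
) -> pd.DataFrame:
    return pd.DataFrame([a.__dict__ for a in assignments]).set_index("transcript_key")
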