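"""Synthetic-data generators with planted, recoverable structure.

Every input the pipeline consumes can be generated here: the three-stage
PDX castration time series (AD, postTX at 8/12 weeks, relapsed NEPC) with
planted Class I-IV temporal dynamics, two clinical discovery cohorts
(AD-naive / NHT / CRPC / NEPC and AD / NEPC), an ADT outcome cohort with
exponential time-to-metastasis tied to planted predictive transcripts,
promoter sequences with planted IUPAC motifs, paired FASTQ reads, and
microarray probe maps nested in or straddling exons.

Expression noise is multiplicative log2-normal around the class-pattern
means, matching FPKM-like positively skewed data and making log2 fold
changes Gaussian. Truth tables are always emitted alongside the data so
that parameter-recovery checks can score against the planted structure.
All generators are byte-deterministic for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from netdlnc.catalogue import TranscriptRecord
from netdlnc.clinical import ProbeRegion
from netdlnc.read_qc import Read
from netdlnc.tfbs import IUPAC_CODES, scan_consensus, validate_iupac

PLANTED_CLASSES = ("I_Deactivated", "II_Activated", "III_Persistent", "IV_Transient")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for every generator.

    Cohort sizes default to the study design this package emulates: a
    discovery cohort with AD-naive (56), NHT (14), CRPC (5) and NEPC (5)
    samples; a second discovery cohort with AD (30) and NEPC (7); a PDX
    series with duplicate terminal stages and single 8-/12-week
    post-castration samples; and an ADT outcome cohort of 200 with
    long-term follow-up (10-20 years).
    """

    seed: int = 0
    n_transcripts: int = 600
    n_planted_per_class: int = 20
    class_effect_fold: float = 4.0
    cohort_a_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"AD_NAIVE": 56, "NHT": 14, "CRPC": 5, "NEPC": 5}
    )
    cohort_b_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"AD": 30, "NEPC": 7}
    )
    pdx_replicates: int = 2
    noise_sd_log2: float = 0.25
    signature_size: int = 30
    signature_fold: float = 64.0
    clinical_effect_fold: float = 4.0
    n_outcome_samples: int = 200
    n_outcome_planted: int = 3
    outcome_hazard_fold: float = 3.0
    treated_fraction: float = 0.5
    censoring_fraction: float = 0.6
    min_followup_months: float = 120.0
    max_followup_months: float = 240.0
    read_length: int = 100
    n_read_pairs: int = 100
    base_error_profile: Optional[tuple[float, ...]] = None
    low_quality_tail_frac: float = 0.0
    duplicate_fraction: float = 0.0
    promoter_length: int = 600
    n_promoters_per_set: int = 30
    probe_length: int = 25
    probe_containment_fraction: float = 0.87

    def __post_init__(self) -> None:
        for name in (
            "n_transcripts",
            "n_planted_per_class",
            "n_outcome_samples",
            "read_length",
            "n_read_pairs",
            "promoter_length",
            "n_promoters_per_set",
            "probe_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pdx_replicates < 1:
            raise ValueError("pdx_replicates must be at least 1")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if self.class_effect_fold <= 1 or self.clinical_effect_fold <= 1:
            raise ValueError("effect folds must exceed 1")
        if self.outcome_hazard_fold < 1:
            raise ValueError("outcome_hazard_fold must be >= 1")
        if not 0 < self.treated_fraction < 1:
            raise ValueError("treated_fraction must be in (0, 1)")
        if not 0 < self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be in (0, 1)")
        if self.max_followup_months <= self.min_followup_months > 0 or (
            self.min_followup_months <= 0
        ):
            raise ValueError("follow-up horizon must be positive and ordered")
        if not 0 <= self.probe_containment_fraction <= 1:
            raise ValueError("probe_containment_fraction must be in [0, 1]")
        n_planted = 4 * self.n_planted_per_class + self.signature_size + (
            self.n_outcome_planted
        )
        if n_planted > self.n_transcripts:
            raise ValueError(
                f"planted transcripts ({n_planted}) exceed n_transcripts "
                f"({self.n_transcripts})"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["cohort_a_sizes"] = dict(data["cohort_a_sizes"])
        data["cohort_b_sizes"] = dict(data["cohort_b_sizes"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# Per-generator seed offsets keep generators independently deterministic.
_SEED_OFFSETS = {
    "pdx": 11,
    "clinical": 23,
    "outcome": 37,
    "promoters": 53,
    "fastq": 71,
    "probes": 89,
}


def _rng(config: SimulationConfig, which: str) -> np.random.Generator:
    return np.random.default_rng((config.seed, _SEED_OFFSETS[which]))


def transcript_ids(config: SimulationConfig) -> list[str]:
    return [f"TLNC{i:06d}" for i in range(1, config.n_transcripts + 1)]


def planted_assignment(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic transcript -> planted role table shared by generators.

    The first blocks of the transcript list carry the four temporal
    classes, then the NEPC signature transcripts (alternating up/down in
    NEPC), then the outcome-predictive transcripts; the remainder is null.
    """
    ids = transcript_ids(config)
    roles = []
    cursor = 0
    for cls in PLANTED_CLASSES:
        for _ in range(config.n_planted_per_class):
            roles.append((ids[cursor], cls))
            cursor += 1
    for i in range(config.signature_size):
        roles.append((ids[cursor], "signature_up" if i % 2 == 0 else "signature_down"))
        cursor += 1
    for _ in range(config.n_outcome_planted):
        roles.append((ids[cursor], "outcome"))
        cursor += 1
    for tid in ids[cursor:]:
        roles.append((tid, "null"))
    return pd.DataFrame(roles, columns=["transcript_key", "planted_class"]).set_index(
        "transcript_key"
    )


def _noise(rng: np.random.Generator, shape, sd_log2: float) -> np.ndarray:
    return 2.0 ** rng.normal(0.0, sd_log2, size=shape)


def _base_expression(rng: np.random.Generator, n: int) -> np.ndarray:
    # FPKM-like baselines, roughly 2-64
    return 2.0 ** rng.uniform(1.0, 6.0, size=n)


# ---------------------------------------------------------------------------
# PDX time series


def generate_pdx_timeseries(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Three-stage PDX series with planted temporal dynamics.

    Samples: ``pdx_replicates`` AD and NEPC samples plus one 8-week and
    one 12-week post-castration sample. Stage means follow the planted
    class pattern with step size ``class_effect_fold``; Class II rises at
    one step only (alternating between the two transitions across its
    planted transcripts). Returns (matrix, metadata, truth).
    """
    rng = _rng(config, "pdx")
    truth = planted_assignment(config)
    ids = truth.index.to_list()
    f = config.class_effect_fold
    base = _base_expression(rng, len(ids))
    stage_means = np.empty((len(ids), 3))
    class2_step1 = True
    for i, tid in enumerate(ids):
        cls = truth.loc[tid, "planted_class"]
        b = base[i]
        if cls == "I_Deactivated":
            means = (b * f * f, b * f, b)
        elif cls == "II_Activated":
            means = (b, b * f, b * f) if class2_step1 else (b, b, b * f)
            class2_step1 = not class2_step1
        elif cls == "III_Persistent":
            means = (b, b * f, b * f * f)
        elif cls == "IV_Transient":
            means = (b, b * f, b)
        else:
            means = (b, b, b)
        stage_means[i] = means
    samples = (
        [f"PDX_AD_{i + 1}" for i in range(config.pdx_replicates)]
        + ["PDX_POSTTX_8W", "PDX_POSTTX_12W"]
        + [f"PDX_NEPC_{i + 1}" for i in range(config.pdx_replicates)]
    )
    stage_of = (
        [0] * config.pdx_replicates + [1, 1] + [2] * config.pdx_replicates
    )
    values = stage_means[:, stage_of] * _noise(
        rng, (len(ids), len(samples)), config.noise_sd_log2
    )
    matrix = pd.DataFrame(values, index=ids, columns=samples)
    groups = (
        ["PDX_AD"] * config.pdx_replicates
        + ["PDX_POSTTX_8W", "PDX_POSTTX_12W"]
        + ["PDX_NEPC"] * config.pdx_replicates
    )
    metadata = pd.DataFrame(
        {"cohort": "PDX", "phenotype_group": groups}, index=pd.Index(samples, name="sample_id")
    )
    return matrix, metadata, truth


# ---------------------------------------------------------------------------
# Clinical discovery cohorts


def _clinical_multipliers(config: SimulationConfig) -> dict[str, dict[str, float]]:
    """Per planted role: expression multiplier per phenotype group."""
    f = config.clinical_effect_fold
    s = config.signature_fold
    return {
        "I_Deactivated": {
            "AD_NAIVE": 1.0,
            "AD": 1.0,
            "NHT": 1.0 / f,
            "CRPC": 1.0 / f,
            "NEPC": 1.0 / f,
        },
        "II_Activated": {
            "AD_NAIVE": 1.0,
            "AD": 1.0,
            "NHT": 1.0,
            "CRPC": 1.0,
            "NEPC": f,
        },
        "III_Persistent": {
            "AD_NAIVE": 1.0,
            "AD": 1.0,
            "NHT": 1.0,
            "CRPC": 1.0,
            "NEPC": f,
        },
        "IV_Transient": {
            "AD_NAIVE": 1.0,
            "AD": 1.0,
            "NHT": f,
            "CRPC": 1.0,
            "NEPC": 1.0,
        },
        "signature_up": {
            "AD_NAIVE": 1.0,
            "AD": 1.0,
            "NHT": 1.0,
            "CRPC": 1.0,
            "NEPC": s,
        },
        "signature_down": {
            "AD_NAIVE": 1.0,
            "AD": 1.0,
            "NHT": 1.0,
            "CRPC": 1.0,
            "NEPC": 1.0 / s,
        },
    }


def generate_clinical_cohorts(
    config: SimulationConfig,
) -> tuple[
    tuple[pd.DataFrame, pd.DataFrame],
    tuple[pd.DataFrame, pd.DataFrame],
    pd.DataFrame,
]:
    """Two discovery cohorts with planted clinical deregulation.

    Cohort A carries the four phenotype groups (AD-naive, NHT, CRPC,
    NEPC); cohort B carries AD and NEPC only. Planted temporal-class
    transcripts echo their expected clinical behaviour (Class I down in
    treated/NEPC groups, II/III up in NEPC, IV up in NHT only); signature
    transcripts separate NEPC from AD by ``signature_fold`` in both
    cohorts; everything else is null.
    """
    required_a = {"AD_NAIVE", "NHT", "CRPC", "NEPC"}
    required_b = {"AD", "NEPC"}
    if not required_a <= set(config.cohort_a_sizes):
        missing = required_a - set(config.cohort_a_sizes)
        raise ValueError(f"cohort A sizes missing phenotype groups: {missing}")
    if not required_b <= set(config.cohort_b_sizes):
        missing = required_b - set(config.cohort_b_sizes)
        raise ValueError(f"cohort B sizes missing phenotype groups: {missing}")
    rng = _rng(config, "clinical")
    truth = planted_assignment(config)
    ids = truth.index.to_list()
    base = _base_expression(rng, len(ids))
    multipliers = _clinical_multipliers(config)

    def build(cohort: str, sizes: Mapping[str, int]):
        samples, groups = [], []
        for group in sorted(sizes):
            for i in range(sizes[group]):
                samples.append(f"{cohort}_{group}_{i + 1}")
                groups.append(group)
        means = np.empty((len(ids), len(samples)))
        for row, tid in enumerate(ids):
            role = truth.loc[tid, "planted_class"]
            mult = multipliers.get(role)
            for col, group in enumerate(groups):
                m = mult.get(group, 1.0) if mult else 1.0
                means[row, col] = base[row] * m
        values = means * _noise(rng, means.shape, config.noise_sd_log2)
        matrix = pd.DataFrame(values, index=ids, columns=samples)
        metadata = pd.DataFrame(
            {"cohort": cohort, "phenotype_group": groups},
            index=pd.Index(samples, name="sample_id"),
        )
        return matrix, metadata

    cohort_a = build("VA", config.cohort_a_sizes)
    cohort_b = build("WB", config.cohort_b_sizes)
    return cohort_a, cohort_b, truth


# ---------------------------------------------------------------------------
# Outcome cohort


def _solve_baseline_hazard(config: SimulationConfig) -> float:
    """Baseline exponential rate giving the configured censoring fraction.

    For a baseline subject, censoring occurs when the event time exceeds a
    uniform administrative censoring time on [min_followup, max_followup];
    P(censored) = E_C[exp(-lam*C)] is solved for lam by bisection.
    """
    lo, hi = config.min_followup_months, config.max_followup_months

    def censored_prob(lam: float) -> float:
        return (np.exp(-lam * lo) - np.exp(-lam * hi)) / (lam * (hi - lo))

    return float(
        brentq(lambda lam: censored_prob(lam) - config.censoring_fraction, 1e-8, 1.0)
    )


def generate_outcome_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """ADT outcome cohort with exponential time-to-metastasis.

    Each sample carries a latent risk factor z ~ N(0,1) expressed through
    the planted predictive transcripts (log2 loading 1 plus measurement
    noise). In ADT-treated samples the event hazard is the baseline rate
    times ``outcome_hazard_fold ** z``; untreated samples use the baseline
    hazard regardless of expression. Administrative censoring times are
    uniform on [min_followup, max_followup], so every censored patient has
    at least ``min_followup_months`` of event-free follow-up.
    """
    if config.max_followup_months <= 0:
        raise ValueError("non-positive follow-up horizon")
    rng = _rng(config, "outcome")
    truth = planted_assignment(config)
    ids = truth.index.to_list()
    n = config.n_outcome_samples
    samples = [f"OUT_{i + 1}" for i in range(n)]
    z = rng.normal(0.0, 1.0, size=n)
    treated = rng.random(n) < config.treated_fraction
    base = _base_expression(rng, len(ids))
    values = np.empty((len(ids), n))
    planted = truth["planted_class"].to_numpy() == "outcome"
    for row in range(len(ids)):
        if planted[row]:
            means = base[row] * 2.0 ** z
        else:
            means = np.full(n, base[row])
        values[row] = means * _noise(rng, n, config.noise_sd_log2)
    lam0 = _solve_baseline_hazard(config)
    log_fold = np.log(config.outcome_hazard_fold)
    lam = lam0 * np.exp(np.where(treated, log_fold * z, 0.0))
    event_time = rng.exponential(1.0 / lam)
    censor_time = rng.uniform(
        config.min_followup_months, config.max_followup_months, size=n
    )
    event = event_time <= censor_time
    observed = np.minimum(event_time, censor_time)
    matrix = pd.DataFrame(values, index=ids, columns=samples)
    metadata = pd.DataFrame(
        {
            "cohort": "OUTCOME",
            "phenotype_group": "AD",
            "adt_treated": treated,
            "metastasis_event": event,
            "time_to_metastasis_months": np.where(event, observed, np.nan),
            "followup_months": observed,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return matrix, metadata, truth


# ---------------------------------------------------------------------------
# Promoters with planted motifs


def _draw_motif_instance(rng: np.random.Generator, motif: str) -> str:
    return "".join(rng.choice(sorted(IUPAC_CODES[s])) for s in motif)


def generate_promoters_and_hits(
    config: SimulationConfig,
    motifs: Mapping[str, str],
    insertion_rates: Mapping[str, Mapping[str, float]] | None = None,
    both_strands: bool = True,
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Random promoter sets with planted motif insertions + exact hit table.

    ``motifs`` maps motif id -> IUPAC consensus. ``insertion_rates`` maps
    sequence-set id -> {motif id: insertions per sequence}; the integer
    part is planted deterministically, the fractional part as a Bernoulli
    draw. The hit table holds exact scan counts of the emitted sequences,
    so planted and background occurrences are indistinguishable by
    construction.
    """
    if not motifs:
        raise ValueError("motifs must be non-empty")
    motifs = {mid: validate_iupac(m) for mid, m in motifs.items()}
    rates = insertion_rates or {"background": {}}
    rng = _rng(config, "promoters")
    sequences: dict[str, list[str]] = {}
    for set_id in sorted(rates):
        seqs = []
        for _ in range(config.n_promoters_per_set):
            seq = list(rng.choice(list("ACGT"), size=config.promoter_length))
            for motif_id in sorted(rates[set_id]):
                rate = rates[set_id][motif_id]
                count = int(rate) + (1 if rng.random() < rate - int(rate) else 0)
                for _k in range(count):
                    instance = _draw_motif_instance(rng, motifs[motif_id])
                    pos = int(rng.integers(0, config.promoter_length - len(instance)))
                    seq[pos : pos + len(instance)] = list(instance)
            seqs.append("".join(seq))
        sequences[set_id] = seqs
    rows = []
    for set_id, seqs in sequences.items():
        for motif_id, motif in motifs.items():
            counts = scan_consensus(seqs, motif, both_strands=both_strands)
            rows.append(
                {
                    "sequence_set_id": set_id,
                    "motif_id": motif_id,
                    "x": int(np.sum(counts)),
                    "n_sequences": len(seqs),
                }
            )
    return sequences, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTQ reads


def _quality_profile(config: SimulationConfig) -> np.ndarray:
    if config.base_error_profile is not None:
        errors = np.asarray(config.base_error_profile, dtype=float)
        if errors.shape != (config.read_length,):
            raise ValueError("base_error_profile length must equal read_length")
    else:
        # gentle 3' quality decline, Q37 down to ~Q30
        q = np.linspace(37.0, 30.0, config.read_length)
        errors = 10.0 ** (-q / 10.0)
    q = np.clip(np.round(-10.0 * np.log10(errors)), 2, 41).astype(int)
    return q


def generate_fastq(config: SimulationConfig, out1, out2) -> tuple[int, int]:
    """Paired synthetic FASTQ libraries (Phred+33).

    Optional planted artifacts: ``low_quality_tail_frac`` of the pairs get
    a Q2 tail over the last fifth of each mate; ``duplicate_fraction`` of
    the pairs are exact copies of the first pair.
    """
    from netdlnc.read_qc import write_fastq

    rng = _rng(config, "fastq")
    qualities = _quality_profile(config)
    tail_start = config.read_length - max(1, config.read_length // 5)
    reads1, reads2 = [], []
    first_pair: Optional[tuple[str, str]] = None
    n_dup = int(round(config.duplicate_fraction * config.n_read_pairs))
    for i in range(config.n_read_pairs):
        name = f"read_{i + 1}"
        if first_pair is not None and i < 1 + n_dup:
            seq1, seq2 = first_pair
        else:
            seq1 = "".join(rng.choice(list("ACGT"), size=config.read_length))
            seq2 = "".join(rng.choice(list("ACGT"), size=config.read_length))
        if first_pair is None:
            first_pair = (seq1, seq2)
        q = qualities.copy()
        if rng.random() < config.low_quality_tail_frac:
            q[tail_start:] = 2
        reads1.append(Read(name + "/1", seq1, tuple(int(v) for v in q)))
        reads2.append(Read(name + "/2", seq2, tuple(int(v) for v in q)))
    write_fastq(reads1, out1)
    write_fastq(reads2, out2)
    return len(reads1), len(reads2)


# ---------------------------------------------------------------------------
# Probe maps


def generate_probe_map(
    config: SimulationConfig,
    catalogue: Sequence[TranscriptRecord],
) -> tuple[list[ProbeRegion], pd.DataFrame]:
    """Probe regions nested in, or straddling, catalogue exons.

    For ``probe_containment_fraction`` of the transcripts the probe lies
    fully inside an exon; otherwise it straddles an exon boundary (or is
    shifted intergenic when the transcript is single-exon at a chromosome
    edge). Returns the probes and a truth table of planted containment.
    """
    if not catalogue:
        raise ValueError("catalogue must be non-empty")
    rng = _rng(config, "probes")
    probes: list[ProbeRegion] = []
    rows = []
    for idx, rec in enumerate(catalogue):
        if not rec.exons:
            import warnings

            warnings.warn(f"transcript {rec.transcript_id} has no exons; skipped")
            continue
        probe_id = f"PSR_{idx + 1:05d}"
        contained = bool(rng.random() < config.probe_containment_fraction)
        exon = rec.exons[int(rng.integers(0, len(rec.exons)))]
        ex_len = exon[1] - exon[0]
        length = min(config.probe_length, max(1, ex_len))
        if contained:
            start = exon[0] + int(rng.integers(0, ex_len - length + 1))
            end = start + length
        else:
            # straddle the exon 3' boundary by half the probe length
            half = max(1, length // 2)
            start = max(0, exon[1] - half)
            end = start + length
            if end <= exon[1]:  # degenerate short exon; push outside
                end = exon[1] + half
        probes.append(ProbeRegion(probe_id, rec.chrom, start, end))
        rows.append(
            {
                "probe_id": probe_id,
                "transcript_id": rec.transcript_id,
                "planted_contained": contained,
            }
        )
    return probes, pd.DataFrame(rows).set_index("probe_id")


def synthetic_catalogue(
    config: SimulationConfig, n_exons: int = 3, exon_length: int = 200
) -> list[TranscriptRecord]:
    """A toy annotated catalogue matching the synthetic transcript ids."""
    records = []
    gap = 100
    for i, tid in enumerate(transcript_ids(config)):
        offset = i * n_exons * (exon_length + gap) + 1000
        exons = tuple(
            (
                offset + j * (exon_length + gap),
                offset + j * (exon_length + gap) + exon_length,
            )
            for j in range(n_exons)
        )
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_name=f"GLNC{i + 1:06d}",
                biotype="lincRNA",
                chrom="chr1",
                strand="+",
                exons=exons,
            )
        )
    return records
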