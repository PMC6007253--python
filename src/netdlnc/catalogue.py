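"""lncRNA transcript catalogue construction and expression-matrix hygiene.

Builds the working lncRNA catalogue from Ensembl-style GTF annotation:
biotype-to-subclass mapping, selection of the three subclasses that carry
the NEPC/AD separation signal (antisense, lincRNA, pseudogene),
immunoglobulin / T-cell-receptor pseudogene removal, expression flooring of
quantification artifacts, cross-cohort transcript-key unification, and
removal of uncharacterized clone-style identifiers.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class Subclass(str, Enum):
    """Transcript subclass groups (Ensembl core-biotype aggregation)."""

    ANTISENSE = "antisense"
    LINCRNA = "lincRNA"
    PSEUDOGENE = "pseudogene"
    PROCESSED_TRANSCRIPT = "processed_transcript"
    RETAINED_INTRON = "retained_intron"
    SENSE_INTRONIC = "sense_intronic"
    SENSE_OVERLAPPING = "sense_overlapping"
    THREE_PRIME_OVERLAPPING = "three_prime_overlapping"
    PROTEIN_CODING = "protein_coding"
    SHORT_NCRNA = "short_ncRNA"
    OTHER = "other"


#: The eight Ensembl pseudogene biotypes aggregated into the pseudogene
#: subclass. IG_*/TR_* pseudogene biotypes also land in the pseudogene
#: subclass but are removed by :func:`build_lncrna_catalogue`.
PSEUDOGENE_BIOTYPES = frozenset(
    {
        "processed_pseudogene",
        "unprocessed_pseudogene",
        "transcribed_unprocessed_pseudogene",
        "transcribed_processed_pseudogene",
        "translated_processed_pseudogene",
        "polymorphic_pseudogene",
        "unitary_pseudogene",
        "pseudogene",
    }
)

SHORT_NCRNA_BIOTYPES = frozenset(
    {"miRNA", "snoRNA", "snRNA", "rRNA", "misc_RNA", "tRNA", "Mt_tRNA", "Mt_rRNA"}
)

_BIOTYPE_DIRECT = {
    "antisense": Subclass.ANTISENSE,
    "antisense_RNA": Subclass.ANTISENSE,
    "lincRNA": Subclass.LINCRNA,
    "processed_transcript": Subclass.PROCESSED_TRANSCRIPT,
    "retained_intron": Subclass.RETAINED_INTRON,
    "sense_intronic": Subclass.SENSE_INTRONIC,
    "sense_overlapping": Subclass.SENSE_OVERLAPPING,
    "3prime_overlapping_ncRNA": Subclass.THREE_PRIME_OVERLAPPING,
    "3prime_overlapping_ncrna": Subclass.THREE_PRIME_OVERLAPPING,
    "protein_coding": Subclass.PROTEIN_CODING,
}


def subclass_for_biotype(biotype: str) -> Subclass:
    """Map an Ensembl biotype string to its subclass group.

    IG_*/TR_* pseudogene biotypes map to the pseudogene subclass (they are
    filtered out later by prefix); unknown biotypes map to ``other`` with a
    warning.
    """
    if biotype in _BIOTYPE_DIRECT:
        return _BIOTYPE_DIRECT[biotype]
    if biotype in PSEUDOGENE_BIOTYPES:
        return Subclass.PSEUDOGENE
    if (biotype.startswith("IG_") or biotype.startswith("TR_")) and biotype.endswith(
        "pseudogene"
    ):
        return Subclass.PSEUDOGENE
    if biotype in SHORT_NCRNA_BIOTYPES:
        return Subclass.SHORT_NCRNA
    warnings.warn(f"unknown biotype {biotype!r}; mapped to 'other'", stacklevel=2)
    return Subclass.OTHER


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript.

    Exons are 0-based half-open genomic intervals, sorted and
    non-overlapping; their lengths must sum to ``length_nt``.
    """

    transcript_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    subclass_group: Subclass = field(init=False)
    length_nt: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id!r} has no exons")
        prev_end = None
        total = 0
        for start, end in self.exons:
            if end <= start:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: empty/inverted exon "
                    f"({start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: exons overlap or are "
                    f"unsorted at ({start}, {end})"
                )
            prev_end = end
            total += end - start
        object.__setattr__(self, "length_nt", total)
        object.__setattr__(self, "subclass_group", subclass_for_biotype(self.biotype))


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(text))


def read_annotation(path) -> list[TranscriptRecord]:
    """Read an Ensembl-dialect GTF file into transcript records.

    Exon lines are aggregated per ``transcript_id`` and sorted; the biotype
    is taken from ``transcript_biotype`` (falling back to ``gene_biotype``
    then ``biotype``). A transcript mentioned on a ``transcript`` line but
    owning no exon lines raises an error naming it.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}
    declared: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line: {line!r}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("exon", "transcript"):
                continue
            a = _parse_gtf_attributes(attrs)
            tid = a.get("transcript_id")
            if tid is None:
                raise ValueError(f"GTF line without transcript_id: {line!r}")
            if tid not in meta:
                meta[tid] = {
                    "gene_name": a.get("gene_name", a.get("gene_id", tid)),
                    "biotype": a.get(
                        "transcript_biotype",
                        a.get("gene_biotype", a.get("biotype", "")),
                    ),
                    "chrom": chrom,
                    "strand": strand,
                }
            if feature == "transcript":
                declared.append(tid)
            else:
                # GTF is 1-based inclusive; convert to 0-based half-open
                exons.setdefault(tid, []).append((int(start) - 1, int(end)))
    for tid in declared:
        if tid not in exons:
            raise ValueError(f"transcript {tid!r} has no exon lines")
    records = []
    for tid, ex in exons.items():
        m = meta[tid]
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_name=m["gene_name"],
                biotype=m["biotype"] or "unknown",
                chrom=m["chrom"],
                strand=m["strand"],
                exons=tuple(sorted(ex)),
            )
        )
    return records


LNCRNA_SUBCLASSES = (Subclass.ANTISENSE, Subclass.LINCRNA, Subclass.PSEUDOGENE)


def build_lncrna_catalogue(
    records: Iterable[TranscriptRecord],
) -> tuple[list[TranscriptRecord], dict[str, int]]:
    """Select the lncRNA catalogue: antisense + lincRNA + pseudogene.

    Within the pseudogene subclass the immunoglobulin and T-cell-receptor
    pseudogene biotypes (``IG_*``/``TR_*``) are removed. Returns the kept
    records and a count summary per subclass.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record set")
    kept = []
    for rec in records:
        if rec.subclass_group not in LNCRNA_SUBCLASSES:
            continue
        if rec.biotype.startswith("IG_") or rec.biotype.startswith("TR_"):
            continue
        kept.append(rec)
    summary = Counter(rec.subclass_group.value for rec in kept)
    summary["total"] = len(kept)
    return kept, dict(summary)


def floor_expression(matrix: pd.DataFrame, floor: float = 0.1) -> pd.DataFrame:
    """Zero out quantification artifacts strictly below ``floor``.

    Values ``< floor`` become 0; values ``>= floor`` are unchanged (the rule
    is strict). Negative input values are an error.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    values = matrix.to_numpy()
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")
    out = matrix.copy()
    out[out < floor] = 0.0
    return out


def merge_cohort_keys(
    cat_a: Iterable[TranscriptRecord], cat_b: Iterable[TranscriptRecord]
) -> dict[tuple[str, int], list[TranscriptRecord]]:
    """Unify transcripts across cohorts on (transcript_id, length) keys.

    Identical (id, length) pairs unify into one key; the same Ensembl id
    with two different assembled lengths stays two distinct keys.
    """
    unified: dict[tuple[str, int], list[TranscriptRecord]] = {}
    for rec in list(cat_a) + list(cat_b):
        unified.setdefault((rec.transcript_id, rec.length_nt), []).append(rec)
    return unified


#: Clone-style identifier patterns for uncharacterized transcripts:
#: RP/AC/AL/AP/CT prefix, digits, optional dash block, dot version.
DEFAULT_UNCHARACTERIZED_PATTERNS = (
    r"^RP\d+-[A-Z0-9]+\.\d+$",
    r"^(?:AC|AL|AP|CT)\d+\.\d+$",
)


def remove_uncharacterized(
    names: Iterable[str],
    patterns: Sequence[str] = DEFAULT_UNCHARACTERIZED_PATTERNS,
) -> list[str]:
    """Drop clone-style uncharacterized identifiers (RP11-123A4.2 etc.)."""
    compiled = [re.compile(p) for p in patterns]
    return [n for n in names if not any(rx.match(n) for rx in compiled)]


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a transcripts x samples expression TSV (first column = keys)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("expression matrix has missing cells")
    return df


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t")
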