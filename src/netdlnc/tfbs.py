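"""Transcription-factor binding-site scanning and over-representation.

Motifs are IUPAC consensus strings scanned exactly (every position
counted, overlaps allowed, optionally both strands). Over-representation
of a motif in a sequence set is scored with the continuity-corrected
z-score

    z = (x - E - 0.5) / S

where x is the observed match count, E the expected count and S the
spread under the background model. |z| > 2 is called significant
(two-sided normal P of roughly 0.05). When no external background (E, S)
is supplied, a binomial per-position model is used: E = n*p,
S = sqrt(n*p*(1-p)) for n scannable positions and per-position match
probability p.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def validate_iupac(motif: str) -> str:
    motif = motif.upper()
    bad = set(motif) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid IUPAC symbols in motif {motif!r}: {sorted(bad)}")
    return motif


def reverse_complement(motif: str) -> str:
    """Reverse complement of an IUPAC string (degenerate codes included)."""
    return validate_iupac(motif).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    class_label: str
    x: int
    expected: float
    spread: float
    z: float
    significant: bool


def enrichment_z(x: float, expected: float, spread: float) -> float:
    """Continuity-corrected over-representation z-score (x - E - 0.5)/S."""
    if spread <= 0:
        raise ValueError("spread S must be positive")
    return (x - expected - 0.5) / spread


def z_to_p(z: float) -> float:
    """Two-sided normal tail probability 2*(1 - Phi(|z|))."""
    return float(2.0 * norm.sf(abs(z)))


def background_expectation(n_positions: int, p: float) -> tuple[float, float]:
    """Binomial background (E, S) = (n*p, sqrt(n*p*(1-p))).

    S = 0 (p of 0 or 1) is returned as-is; such motifs are unscorable and
    callers must skip them.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("background probability must lie in [0, 1]")
    expected = n_positions * p
    spread = math.sqrt(n_positions * p * (1.0 - p))
    return expected, spread


def motif_match_probability(motif: str) -> float:
    """Per-position match probability under a uniform base background."""
    motif = validate_iupac(motif)
    prob = 1.0
    for symbol in motif:
        prob *= len(IUPAC_CODES[symbol]) / 4.0
    return prob


def _matches_at(seq: str, motif: str, pos: int) -> bool:
    for offset, symbol in enumerate(motif):
        if seq[pos + offset] not in IUPAC_CODES[symbol]:
            return False
    return True


def scan_consensus(
    sequences: Iterable[str], motif: str, both_strands: bool = True
) -> list[int]:
    """Count all (overlapping) IUPAC matches per sequence.

    With ``both_strands`` the reverse-complement pattern is scanned over
    the same forward sequence, so palindromic motifs count twice per site
    (exhaustive-scan semantics).
    """
    motif = validate_iupac(motif)
    if len(motif) < 4:
        raise ValueError("motif length must be >= 4")
    patterns = [motif]
    if both_strands:
        patterns.append(reverse_complement(motif))
    counts = []
    for seq in sequences:
        seq = seq.upper()
        total = 0
        for pat in patterns:
            m = len(pat)
            total += sum(
                1 for i in range(len(seq) - m + 1) if _matches_at(seq, pat, i)
            )
        counts.append(total)
    return counts


def scannable_positions(
    n_sequences: int, seq_length: int, motif_length: int, both_strands: bool = True
) -> int:
    """Number of scan positions for the binomial background."""
    per_seq = max(0, seq_length - motif_length + 1)
    return n_sequences * per_seq * (2 if both_strands else 1)


def class_enrichment(
    hit_tables: Mapping[str, pd.DataFrame],
    backgrounds: Mapping[str, tuple[float, float] | float],
    n_positions: Optional[Mapping[str, Mapping[str, int]]] = None,
    z_cutoff: float = 2.0,
) -> list[EnrichmentResult]:
    """Score motif over-representation per (class, motif).

    ``hit_tables`` maps class label -> DataFrame with columns
    ``motif_id`` and ``x`` (observed counts). ``backgrounds`` maps motif id
    to either an externally supplied (E, S) pair — used verbatim — or a
    per-position probability p, in which case ``n_positions[class][motif]``
    supplies the binomial n. Motifs missing from the background are
    skipped with a warning; unscorable motifs (S = 0) likewise.
    """
    results = []
    for class_label, table in hit_tables.items():
        for _, row in table.iterrows():
            motif_id = row["motif_id"]
            x = int(row["x"])
            if motif_id not in backgrounds:
                warnings.warn(
                    f"motif {motif_id!r} missing from background; skipped",
                    stacklevel=2,
                )
                continue
            bg = backgrounds[motif_id]
            if isinstance(bg, tuple):
                expected, spread = bg
            else:
                if n_positions is None:
                    raise ValueError(
                        "per-position background probability requires n_positions"
                    )
                n = n_positions[class_label][motif_id]
                expected, spread = background_expectation(n, float(bg))
            if spread <= 0:
                warnings.warn(
                    f"motif {motif_id!r} in class {class_label!r} unscorable "
                    "(zero spread); skipped",
                    stacklevel=2,
                )
                continue
            z = enrichment_z(x, expected, spread)
            results.append(
                EnrichmentResult(
                    motif_id=motif_id,
                    class_label=class_label,
                    x=x,
                    expected=expected,
                    spread=spread,
                    z=z,
                    significant=abs(z) > z_cutoff,
                )
            )
    return results


def unique_and_common(
    results: Iterable[EnrichmentResult],
) -> tuple[dict[str, set[str]], set[str]]:
    """Split significant motifs into class-unique and common-to-all sets.

    Unique = significant in exactly one class; common = significant in
    every class present in the results.
    """
    sig: dict[str, set[str]] = {}
    classes = set()
    for r in results:
        classes.add(r.class_label)
        if r.significant:
            sig.setdefault(r.motif_id, set()).add(r.class_label)
    if len(classes) < 2:
        raise ValueError("need results from at least 2 classes")
    unique: dict[str, set[str]] = {c: set() for c in classes}
    common: set[str] = set()
    for motif, hit_classes in sig.items():
        if len(hit_classes) == 1:
            unique[next(iter(hit_classes))].add(motif)
        if hit_classes == classes:
            common.add(motif)
    return unique, common


def tfbs_distribution(
    presence: pd.DataFrame,
) -> pd.DataFrame:
    """Per-motif distribution of presences across classes.

    ``presence`` is indexed by transcript with a ``class_label`` column and
    one boolean/integer column per motif (the top-per-class candidate
    table). Returns one row per motif with class fractions summing to 1;
    motifs absent everywhere are omitted.
    """
    motif_cols = [c for c in presence.columns if c != "class_label"]
    rows = {}
    grouped = presence.groupby("class_label")[motif_cols].sum()
    for motif in motif_cols:
        total = grouped[motif].sum()
        if total == 0:
            continue
        rows[motif] = grouped[motif] / total
    return pd.DataFrame(rows).T.fillna(0.0)
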