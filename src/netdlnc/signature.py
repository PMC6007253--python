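"""Cross-cohort NEPC expression-signature derivation.

The signature is built by selecting, per discovery cohort, the top fifth
percentile of transcripts by standard deviation of log2 expression,
removing uncharacterized clone-style identifiers, intersecting the two
cohort lists, and re-clustering each cohort on the intersection. The
operational readout of "distinct segregation" is the purity of a k=2 cut
of the sample dendrogram against the NEPC/AD phenotype labels. Signature
members are then ranked by NEPC-vs-AD fold change, flagging transcripts
with concordant direction and at least 10-fold magnitude in both cohorts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from netdlnc.catalogue import remove_uncharacterized
from netdlnc.diffexp import fold_change

LOG_PSEUDOCOUNT = 0.1  # matches the expression floor


@dataclass
class ClusteringResult:
    merge_tree: np.ndarray  # scipy linkage matrix
    labels: dict[int, np.ndarray]  # k -> cluster labels per sample
    sample_ids: list[str]
    distance: str
    linkage_method: str

    def cut(self, k: int) -> np.ndarray:
        if k not in self.labels:
            self.labels[k] = fcluster(self.merge_tree, t=k, criterion="maxclust")
        return self.labels[k]


def top_variance_percentile(
    matrix: pd.DataFrame, percentile: float = 5.0
) -> list[str]:
    """Top-percentile transcripts by row SD of log2(x + 0.1).

    Returns ceil(percentile/100 * n) keys; ties at the boundary are broken
    by key order so the selection is deterministic. Sample (n-1) SD.
    """
    n = matrix.shape[0]
    if n < 20:
        raise ValueError("need at least 20 transcripts")
    logged = np.log2(matrix.to_numpy(dtype=float) + LOG_PSEUDOCOUNT)
    sds = pd.Series(logged.std(axis=1, ddof=1), index=matrix.index)
    k = math.ceil(percentile / 100.0 * n)
    order = sorted(zip(-sds.to_numpy(), matrix.index.astype(str)))
    return [key for _neg_sd, key in order[:k]]


def scale_rows(matrix: pd.DataFrame, clip: float = 2.0) -> pd.DataFrame:
    """Row z-score (sample SD) clipped to [-clip, clip]; constant rows -> 0."""
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    z = np.clip(z, -clip, clip)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def hcluster(
    matrix: pd.DataFrame,
    distance: str = "one_minus_pearson",
    linkage_method: str = "average",
) -> ClusteringResult:
    """Agglomerative clustering of samples (columns).

    ``one_minus_pearson`` uses 1 - Pearson correlation between sample
    expression vectors; zero-variance columns are dropped with a warning
    because correlation is undefined for them. ``euclidean`` distances pair
    with Ward linkage for the microarray-cohort variant.
    """
    if matrix.shape[1] < 1:
        raise ValueError("no samples to cluster")
    data = matrix.copy()
    if distance == "one_minus_pearson":
        variances = data.to_numpy(dtype=float).var(axis=0)
        dead = [c for c, v in zip(data.columns, variances) if v == 0]
        if dead:
            warnings.warn(
                f"dropping zero-variance columns under Pearson distance: {dead}",
                stacklevel=2,
            )
            data = data.drop(columns=dead)
        if data.shape[1] < 2:
            raise ValueError("fewer than 2 usable samples")
        corr = np.corrcoef(data.to_numpy(dtype=float).T)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip(dist, 0.0, None)
        condensed = squareform(dist, checks=False)
        tree = linkage(condensed, method=linkage_method)
    elif distance == "euclidean":
        if data.shape[1] < 2:
            raise ValueError("fewer than 2 usable samples")
        tree = linkage(data.to_numpy(dtype=float).T, method=linkage_method,
                       metric="euclidean")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return ClusteringResult(
        merge_tree=tree,
        labels={},
        sample_ids=list(data.columns),
        distance=distance,
        linkage_method=linkage_method,
    )


def cluster_purity(labels: Sequence[int], phenotypes: Sequence[str]) -> float:
    """Max-agreement purity of cluster labels vs phenotype labels."""
    df = pd.DataFrame({"cluster": list(labels), "phenotype": list(phenotypes)})
    agree = df.groupby("cluster")["phenotype"].agg(lambda s: s.value_counts().iloc[0])
    return float(agree.sum()) / len(df)


def derive_signature(
    matrix_a: pd.DataFrame,
    phenotypes_a: pd.Series,
    matrix_b: pd.DataFrame,
    phenotypes_b: pd.Series,
    percentile: float = 5.0,
    uncharacterized_patterns: Optional[Sequence[str]] = None,
) -> tuple[list[str], dict[str, float]]:
    """Derive the cross-cohort signature and per-cohort separation purity.

    Both matrices must share a transcript key space. Steps: drop
    uncharacterized ids, take the top variance percentile per cohort,
    intersect, recluster each cohort on the intersection (Pearson
    distance, average linkage), cut at k=2 and score purity against the
    phenotype labels.
    """
    kwargs = {}
    if uncharacterized_patterns is not None:
        kwargs["patterns"] = uncharacterized_patterns
    keep_a = remove_uncharacterized(matrix_a.index.astype(str), **kwargs)
    keep_b = remove_uncharacterized(matrix_b.index.astype(str), **kwargs)
    top_a = set(top_variance_percentile(matrix_a.loc[keep_a], percentile))
    top_b = set(top_variance_percentile(matrix_b.loc[keep_b], percentile))
    signature = sorted(top_a & top_b)
    purity: dict[str, float] = {}
    if not signature:
        warnings.warn("empty signature intersection", stacklevel=2)
        return signature, purity
    for name, matrix, phen in (
        ("cohort_a", matrix_a, phenotypes_a),
        ("cohort_b", matrix_b, phenotypes_b),
    ):
        sub = scale_rows(np.log2(matrix.loc[signature] + LOG_PSEUDOCOUNT))
        result = hcluster(sub, "one_minus_pearson", "average")
        labels = result.cut(2)
        # separation is judged NEPC vs AD; collapse non-NEPC groups
        phen_used = phen.loc[result.sample_ids].where(
            phen.loc[result.sample_ids] == "NEPC", "AD"
        )
        purity[name] = cluster_purity(labels, phen_used)
    return signature, purity


def rank_signature(
    matrix_a: pd.DataFrame,
    phenotypes_a: pd.Series,
    matrix_b: pd.DataFrame,
    phenotypes_b: pd.Series,
    signature: Sequence[str],
    fold_threshold: float = 10.0,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """NEPC-vs-AD fold change per cohort, with the concordant >=10x flag.

    A transcript is flagged when its fold changes agree in direction and
    both reach ``fold_threshold`` in magnitude (>= threshold up, or <=
    1/threshold down).
    """
    if not len(signature):
        raise ValueError("signature is empty")
    rows = []
    for key in signature:
        fcs = {}
        for name, matrix, phen in (
            ("a", matrix_a, phenotypes_a),
            ("b", matrix_b, phenotypes_b),
        ):
            samples_ad = [
                s for s in phen.index[phen.isin(["AD", "AD_NAIVE"])]
                if s in matrix.columns
            ]
            samples_ne = [
                s for s in phen.index[phen == "NEPC"] if s in matrix.columns
            ]
            mean_ad = float(matrix.loc[key, samples_ad].mean())
            mean_ne = float(matrix.loc[key, samples_ne].mean())
            fcs[name], _ = fold_change(mean_ad, mean_ne, pseudocount)
        concordant = (fcs["a"] > 1) == (fcs["b"] > 1)
        big = all(
            fc >= fold_threshold or fc <= 1.0 / fold_threshold
            for fc in fcs.values()
        )
        rows.append(
            {
                "transcript_key": key,
                "fc_cohort_a": fcs["a"],
                "fc_cohort_b": fcs["b"],
                "concordant": concordant,
                "high_fold_flag": concordant and big,
            }
        )
    df = pd.DataFrame(rows).set_index("transcript_key")
    magnitude = np.maximum(df["fc_cohort_a"], 1.0 / df["fc_cohort_a"])
    return df.loc[magnitude.sort_values(ascending=False).index]


def pca_top3(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-3 principal component scores for samples + variance fractions."""
    n_samples = matrix.shape[1]
    n_comp = min(3, n_samples, matrix.shape[0])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(matrix.to_numpy(dtype=float).T)
    frame = pd.DataFrame(
        scores,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    return frame, pca.explained_variance_ratio_
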