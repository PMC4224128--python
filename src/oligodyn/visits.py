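"""Genus-level community comparison across visits.

Aggregates per-read taxonomy to genus × sample counts, computes the
Morisita-Horn dissimilarity between samples, clusters samples
hierarchically, and compares within-subject paired visits against the
between-subject background — the analysis that asks whether a subject's
tongue community at a return visit resembles their first visit more than
it resembles other people's.

Morisita-Horn similarity between count vectors x and y:

    C_H = 2 * sum_i x_i y_i / ((d_x + d_y) * X * Y)

with X = sum x_i, d_x = sum x_i^2 / X^2 (and likewise for y); the
dissimilarity is 1 - C_H.  The index depends only on relative abundances,
so unequal sample depths need no rarefaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

UNASSIGNED = "unassigned"


def aggregate_genus(assignments: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Count reads per genus per sample.

    ``assignments`` has one row per read with columns ``sample_id`` and
    ``genus`` (missing/None meaning unclassified, tallied in a dedicated
    ``unassigned`` row).  Every manifest sample appears as a column, zero
    where the sample had no reads.
    """
    df = assignments.copy()
    df["genus"] = df["genus"].fillna(UNASSIGNED).replace("", UNASSIGNED)
    table = pd.crosstab(df["genus"], df["sample_id"])
    table = table.reindex(columns=list(manifest["sample_id"]), fill_value=0)
    return table.astype(int)


def morisita_horn(x, y) -> float:
    """Morisita-Horn dissimilarity (1 - similarity) between two count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must have the same length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        raise ValueError("zero-total count vector")
    dx = (x ** 2).sum() / X ** 2
    dy = (y ** 2).sum() / Y ** 2
    sim = 2.0 * (x * y).sum() / ((dx + dy) * X * Y)
    return float(np.clip(1.0 - sim, 0.0, 1.0))


def dissimilarity_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Morisita-Horn dissimilarities between sample columns."""
    ids = list(counts.columns)
    n = len(ids)
    M = np.zeros((n, n))
    cols = [counts[c].to_numpy(dtype=float) for c in ids]
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = morisita_horn(cols[i], cols[j])
    return pd.DataFrame(M, index=ids, columns=ids)


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix
    sample_ids: list[str]
    newick: str

    def flat_clusters(self, height: float) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=height, criterion="distance")
        return pd.Series(labels, index=self.sample_ids, name="cluster")


def cluster_samples(d: pd.DataFrame, linkage_method: str = "average") -> ClusterResult:
    """Agglomerative clustering of a dissimilarity matrix (UPGMA by default)."""
    if d.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if not np.allclose(d.values, d.values.T) or not np.allclose(np.diag(d.values), 0):
        raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")
    condensed = squareform(d.values, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage_method)
    tree = TreeNode.from_linkage_matrix(Z, list(d.index))
    return ClusterResult(Z, list(d.index), str(tree).strip())


def select_paired_subjects(
    manifest: pd.DataFrame,
    min_reads: int = 600,
    min_gap: int = 30,
    max_gap: int = 359,
) -> pd.DataFrame:
    """Subjects with two qualifying visits: read floor met, day gap in bounds.

    Qualifying samples have at least ``min_reads`` reads; each subject's
    earliest two qualifying visits are paired and kept when their day gap
    lies in [min_gap, max_gap].  Returns one row per selected subject.
    """
    qual = manifest[manifest["n_reads"] >= min_reads].sort_values(["subject_id", "day"])
    rows = []
    for subject, grp in qual.groupby("subject_id", sort=True):
        if len(grp) < 2:
            continue
        first, second = grp.iloc[0], grp.iloc[1]
        gap = int(second["day"] - first["day"])
        if min_gap <= gap <= max_gap:
            rows.append(
                (subject, first["sample_id"], second["sample_id"],
                 int(first["day"]), int(second["day"]), gap)
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "sample_1", "sample_2", "day_1", "day_2", "gap"]
    )


@dataclass
class PairedVisitDistances:
    within: pd.Series  # subject -> dissimilarity between their two visits
    between: np.ndarray  # all between-subject sample-pair dissimilarities
    summary: dict[str, float]


def paired_visit_distances(
    selection: pd.DataFrame, d: pd.DataFrame
) -> PairedVisitDistances:
    """Within-subject visit-pair distances vs the between-subject background.

    The "arc length" of each subject is the dissimilarity between their
    two visits; the background is every pairwise dissimilarity between
    samples of different subjects.  Summary holds quantiles of both.
    """
    within = pd.Series(
        {
            row.subject_id: float(d.loc[row.sample_1, row.sample_2])
            for row in selection.itertuples()
        },
        name="within",
        dtype=float,
    )
    sample_subject = {}
    for row in selection.itertuples():
        sample_subject[row.sample_1] = row.subject_id
        sample_subject[row.sample_2] = row.subject_id
    ids = list(sample_subject)
    between = [
        float(d.loc[a, b])
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
        if sample_subject[a] != sample_subject[b]
    ]
    between = np.asarray(between)
    if between.size == 0:
        warnings.warn("fewer than two subjects: no between-subject background", stacklevel=2)
    summary = {}
    if len(within):
        for q in (0.1, 0.5, 0.9):
            summary[f"within_q{int(q * 100)}"] = float(within.quantile(q))
    if between.size:
        for q in (0.1, 0.5, 0.9):
            summary[f"between_q{int(q * 100)}"] = float(np.quantile(between, q))
    return PairedVisitDistances(within, between, summary)
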