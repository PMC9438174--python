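"""Cross-dataset validation and unsupervised grouping diagnostics.

Concordance asks, for each signature transcript, whether independent
time-course datasets move it in the same direction as the reference: the
fold change between each dataset's day 0 and its own final sampled day
("most mature sample available") is reduced to a sign, and the transcript's
support is the percentage of datasets agreeing with the reference direction.
Datasets not covering a transcript do not count toward its denominator;
a transcript passes at >= 50% agreement by default.

Grouping diagnostics summarize how well a transcript subset separates
samples by differentiation day: PCA scores, a Euclidean average-linkage
dendrogram (emitted as Newick so grouping claims are file-diffable) and the
silhouette coefficient of samples grouped by day as a scalar proxy for
between-day separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .datasets import ExpressionDataset, TimeProfile, to_profiles

__all__ = [
    "ConcordanceRecord",
    "GroupingDiagnostics",
    "endpoint_direction",
    "concordance",
    "grouping_diagnostics",
]

_FLAT_EPS = 1e-9


@dataclass
class ConcordanceRecord:
    """Cross-dataset direction-agreement tally for one transcript."""

    transcript_id: str
    reference_direction: str
    n_available: int
    n_same_direction: int
    pct: float
    passed: bool


@dataclass
class GroupingDiagnostics:
    """PCA scores, day-group silhouette and dendrogram for a transcript subset."""

    pca_scores: pd.DataFrame  # samples x components (<= 3)
    explained_variance_ratio: np.ndarray
    silhouette: float
    newick: str


def endpoint_direction(profile: TimeProfile, epsilon: float = _FLAT_EPS) -> str:
    """Sign of the log2 change between a profile's first and final day."""
    if profile.days.size < 2:
        raise ValueError(
            f"{profile.transcript_id}: endpoint direction needs >= 2 days"
        )
    delta = profile.mean_log2[-1] - profile.mean_log2[0]
    if abs(delta) < epsilon:
        return "flat"
    return "up" if delta > 0 else "down"


def _direction_lookup(ds: ExpressionDataset) -> dict[str, str]:
    """Case-insensitive transcript id -> endpoint direction for one dataset."""
    out: dict[str, str] = {}
    for prof in to_profiles(ds):
        out[prof.transcript_id.casefold()] = endpoint_direction(prof)
    return out


def concordance(
    reference: ExpressionDataset,
    externals: list[ExpressionDataset],
    transcript_ids: Iterable[str],
    pass_pct: float = 50.0,
) -> list[ConcordanceRecord]:
    """Fold-change direction agreement of each transcript across datasets.

    Each external dataset uses its own day 0 -> max-day endpoints; transcript
    matching is a case-insensitive symbol match.  A flat direction on either
    side never counts as agreement (but the dataset still counts as
    available).  Transcripts found in zero externals are flagged with
    ``n_available = 0`` and fail.
    """
    if not externals:
        raise ValueError("concordance requires at least one external dataset")
    ref_dirs = _direction_lookup(reference)
    ext_dirs = [_direction_lookup(ds) for ds in externals]

    records = []
    for tid in transcript_ids:
        key = tid.casefold()
        ref_dir = ref_dirs.get(key)
        if ref_dir is None:
            raise KeyError(f"transcript {tid!r} absent from the reference dataset")
        n_avail = 0
        n_same = 0
        for dirs in ext_dirs:
            ext_dir = dirs.get(key)
            if ext_dir is None:
                continue
            n_avail += 1
            if ref_dir != "flat" and ext_dir == ref_dir:
                n_same += 1
        pct = 100.0 * n_same / n_avail if n_avail > 0 else 0.0
        records.append(
            ConcordanceRecord(
                transcript_id=tid,
                reference_direction=ref_dir,
                n_available=n_avail,
                n_same_direction=n_same,
                pct=pct,
                passed=n_avail > 0 and pct >= pass_pct,
            )
        )
    return records


def _linkage_to_newick(node: hierarchy.ClusterNode, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _linkage_to_newick(node.left, labels)
    right = _linkage_to_newick(node.right, labels)
    bl_left = node.dist - node.left.dist
    bl_right = node.dist - node.right.dist
    return f"({left}:{bl_left:.6g},{right}:{bl_right:.6g})"


def grouping_diagnostics(
    ds: ExpressionDataset, transcript_ids: Iterable[str]
) -> GroupingDiagnostics:
    """How well a transcript subset separates samples by day.

    PCA (first <= 3 components) and Euclidean average-linkage clustering run
    on the samples-x-subset matrix; the silhouette coefficient uses the
    differentiation day as the grouping label.
    """
    ids = list(transcript_ids)
    if len(ids) < 2:
        raise ValueError("grouping diagnostics need a subset of >= 2 transcripts")
    if ds.n_samples < 3:
        raise ValueError("grouping diagnostics need >= 3 samples")
    sub = ds.subset(ids)
    x = sub.values.T  # samples x transcripts
    sample_ids = [s.sample_id for s in sub.samples]
    days = sub.sample_days

    n_comp = min(3, x.shape[0], x.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(x)
    score_df = pd.DataFrame(
        scores,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )

    n_groups = np.unique(days).size
    if 2 <= n_groups <= x.shape[0] - 1:
        sil = float(silhouette_score(x, days, metric="euclidean"))
    else:
        sil = float("nan")

    linkage = hierarchy.linkage(x, method="average", metric="euclidean")
    tree = hierarchy.to_tree(linkage)
    newick = _linkage_to_newick(tree, sample_ids) + ";"

    return GroupingDiagnostics(
        pca_scores=score_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        silhouette=sil,
        newick=newick,
    )
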