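"""Sample clustering, paired-sample scatter statistics and per-probe ROC.

These mirror the standard diagnostics run on a two-compartment expression
cohort: complete-linkage hierarchical clustering of samples on Euclidean
distance, R-squared of paired primary/metastasis scatter on the log10
scale, and per-probe AUC computed as the normalized Mann-Whitney U with
half-credit for ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.utils.multiclass import unique_labels

from .errors import (
    DataError,
    DesignError,
    DomainError,
    PairingError,
    UndefinedStatisticError,
)
from .io import NormalizedDataset


# -- hierarchical clustering ---------------------------------------------------


@dataclass
class Dendrogram:
    """Agglomerative merge history in scipy linkage form.

    ``linkage_matrix`` rows are (cluster_a, cluster_b, height, size); leaf i
    is sample ``labels[i]``, and merge k creates cluster ``n + k``.
    """

    linkage_matrix: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        n = self.n_leaves
        Z = self.linkage_matrix

        def height(node: int) -> float:
            return 0.0 if node < n else float(Z[node - n, 2])

        def render(node: int, parent_h: float) -> str:
            bl = parent_h - height(node)
            if node < n:
                return f"{self.labels[node]}:{bl:.6g}"
            a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
            h = height(node)
            return f"({render(a, h)},{render(b, h)}):{bl:.6g}"

        if n == 1:
            return f"{self.labels[0]};"
        root = n + len(Z) - 1
        h = height(root)
        a, b = int(Z[-1, 0]), int(Z[-1, 1])
        return f"({render(a, h)},{render(b, h)});"


@dataclass
class ClusterCut:
    k: int
    assignment: pd.Series  # sample_id -> cluster id (1..k)
    composition: pd.DataFrame  # cluster x tissue_class counts


def hclust_complete(matrix: pd.DataFrame) -> Dendrogram:
    """Cluster samples (columns) by Euclidean distance, complete linkage.

    ``matrix`` is features x samples; with complete linkage the merge
    heights are non-decreasing.
    """
    if matrix.shape[1] < 2:
        raise DomainError("clustering requires >= 2 samples")
    X = matrix.to_numpy(dtype=float).T
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite values in clustering input")
    Z = linkage(X, method="complete", metric="euclidean")
    return Dendrogram(linkage_matrix=Z, labels=list(matrix.columns))


def cut_k(dend: Dendrogram, k: int, sample_meta: pd.DataFrame) -> ClusterCut:
    """Cut into k clusters by undoing the last k-1 merges.

    Cluster ids are 1..k in order of first leaf appearance; composition
    tabulates tissue_class counts per cluster.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise DomainError(f"k must be in [1, {n}]")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step in range(n - k):
        a, b = int(dend.linkage_matrix[step, 0]), int(dend.linkage_matrix[step, 1])
        members[n + step] = members.pop(a) + members.pop(b)
    leaf_cluster: dict[int, int] = {}
    clusters = sorted(members.values(), key=min)
    for cid, leaves in enumerate(clusters, start=1):
        for leaf in leaves:
            leaf_cluster[leaf] = cid
    assignment = pd.Series(
        [leaf_cluster[i] for i in range(n)], index=pd.Index(dend.labels), name="cluster"
    )
    tissue = sample_meta.loc[assignment.index, "tissue_class"]
    composition = (
        pd.crosstab(assignment, tissue)
        .reindex(columns=["primary", "metastasis"], fill_value=0)
    )
    composition.index.name = "cluster"
    return ClusterCut(k=k, assignment=assignment, composition=composition)


def clustering_matrix(
    norm: NormalizedDataset,
    probes: pd.Index | list[str] | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """log2(value+1) expression prepared for clustering.

    Restricted to ``probes`` (default: all endogenous); rows optionally
    standardized to zero mean / unit variance, the heatmap convention.
    Zero-variance rows cannot be standardized and are dropped.
    """
    if probes is None:
        probes = norm.endogenous_probes
    X = np.log2(norm.values.loc[probes] + 1.0)
    if standardize:
        sd = X.std(axis=1, ddof=0)
        X = X.loc[sd > 0]
        X = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=0), axis=0)
    return X


# -- paired scatter ------------------------------------------------------------


def paired_scatter_stats(norm: NormalizedDataset, patient_id: str) -> pd.DataFrame:
    """R-squared per (primary, metastatic) sample pair of one patient.

    R^2 is the squared Pearson correlation of log10(value + 1) across all
    endogenous probes — identical to the least-squares regression R^2.
    """
    meta = norm.sample_meta
    mine = meta[meta["patient_id"] == patient_id]
    if mine.empty:
        raise PairingError(f"unknown patient {patient_id!r}")
    primaries = mine.index[mine["tissue_class"] == "primary"]
    mets = mine.index[mine["tissue_class"] == "metastasis"]
    if len(primaries) == 0 or len(mets) == 0:
        raise PairingError(
            f"patient {patient_id!r} lacks a primary/metastasis pair"
        )
    endo = norm.endogenous_probes
    logv = np.log10(norm.values.loc[endo] + 1.0)
    rows = []
    for p in primaries:
        x = logv[p].to_numpy()
        for m in mets:
            y = logv[m].to_numpy()
            # tolerance absorbs float noise introduced by the scale factors
            tol = 1e-12
            if x.std() <= tol * max(1.0, abs(x.mean())) or (
                y.std() <= tol * max(1.0, abs(y.mean()))
            ):
                raise UndefinedStatisticError(
                    "zero variance in a paired expression vector"
                )
            r = np.corrcoef(x, y)[0, 1]
            rows.append((patient_id, p, m, r * r))
    return pd.DataFrame(
        rows, columns=["patient_id", "primary_sample", "metastatic_sample", "r_squared"]
    )


# -- ROC / AUC -----------------------------------------------------------------


@dataclass
class RocResult:
    probe_id: str
    auc: float  # oriented, in [0.5, 1]
    orientation: str  # metastasis_high | metastasis_low


def _auc_met_high(primary: np.ndarray, met: np.ndarray) -> float:
    """P(metastatic value > primary value) + 0.5 * P(tie), via midranks."""
    combined = np.concatenate([met, primary])
    ranks = rankdata(combined)
    n_met, n_prim = len(met), len(primary)
    u = ranks[:n_met].sum() - n_met * (n_met + 1) / 2.0
    return float(u / (n_met * n_prim))


class ProbeAUC(BaseEstimator):
    """Per-feature diagnostic AUC, sklearn-estimator-shaped.

    ``fit(X, y)`` with samples as rows; each feature's AUC is the
    Mann-Whitney probability that a metastatic value exceeds a primary one
    (ties half-credited), oriented so ``auc_ >= 0.5`` with the flip recorded
    in ``orientation_``.
    """

    def __init__(self, positive_class: str = "metastasis",
                 reference_class: str = "primary"):
        self.positive_class = positive_class
        self.reference_class = reference_class

    def fit(self, X, y):
        feature_names = (
            X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(np.shape(X)[1])
        )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        labels = set(unique_labels(y))
        if labels != {self.positive_class, self.reference_class}:
            raise DesignError(f"y must contain exactly two known classes, got {labels}")
        pos = X[y == self.positive_class]
        ref = X[y == self.reference_class]
        if len(pos) == 0 or len(ref) == 0:
            raise DomainError("both groups must be non-empty")
        raw = np.array(
            [_auc_met_high(ref[:, j], pos[:, j]) for j in range(X.shape[1])]
        )
        flip = raw < 0.5
        self.auc_ = pd.Series(np.where(flip, 1.0 - raw, raw), index=feature_names,
                              name="auc")
        self.orientation_ = pd.Series(
            np.where(flip, "metastasis_low", "metastasis_high"),
            index=feature_names, name="orientation",
        )
        return self


def roc_auc(norm: NormalizedDataset, probe_id: str) -> RocResult:
    """Oriented AUC for one probe of a normalized dataset."""
    if probe_id not in norm.values.index:
        raise DomainError(f"unknown probe {probe_id!r}")
    X = norm.values.loc[[probe_id]].T
    y = norm.sample_meta["tissue_class"].to_numpy()
    est = ProbeAUC().fit(X, y)
    return RocResult(
        probe_id=probe_id,
        auc=float(est.auc_.iloc[0]),
        orientation=str(est.orientation_.iloc[0]),
    )


def roc_auc_table(norm: NormalizedDataset, probe_ids=None) -> pd.DataFrame:
    """Oriented AUC and orientation for many probes (default: endogenous)."""
    if probe_ids is None:
        probe_ids = norm.endogenous_probes
    X = norm.values.loc[probe_ids].T
    y = norm.sample_meta["tissue_class"].to_numpy()
    est = ProbeAUC().fit(X, y)
    return pd.DataFrame({"auc": est.auc_, "orientation": est.orientation_})
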