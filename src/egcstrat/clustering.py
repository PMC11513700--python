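"""Patient stratification: t-SNE embedding of the PI-score matrix, DBSCAN
clustering of the embedding, and cluster characterization.

The embedding is deterministic for a fixed (matrix, perplexity, seed) triple:
t-SNE runs with PCA initialization and the exact gradient (cohort sizes here
are tens of patients, so the O(n^2) method is both affordable and free of the
tree-approximation nondeterminism). DBSCAN's ``eps`` defaults to the median
4-nearest-neighbor distance of the embedded points, a standard k-distance
heuristic. Cluster labels are reassigned 1..k by decreasing cluster size;
noise keeps the label -1 and is excluded from downstream comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .pathways import AlterationProfile
from .stats import (
    ContingencyTable2x2,
    TestMethod,
    TestResult,
    bh_adjust,
    test_2x2,
    wilcoxon_rank_sum,
)

logger = logging.getLogger(__name__)

NOISE = -1

DEFAULT_MIN_SAMPLES = 3
DEFAULT_TSNE_ITER = 1000


@dataclass(frozen=True)
class Embedding:
    """2-D t-SNE coordinates for each patient, with the settings that
    produced them."""

    patient_ids: tuple[str, ...]
    coordinates: np.ndarray  # (n, 2)
    seed: int
    perplexity: float

    def __post_init__(self) -> None:
        if self.coordinates.shape != (len(self.patient_ids), 2):
            raise ValueError("coordinates must be (n_patients, 2)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite embedding coordinates")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates,
            index=pd.Index(self.patient_ids, name="patient_id"),
            columns=["tsne1", "tsne2"],
        )


@dataclass(frozen=True)
class ClusterAssignment:
    """patient_id -> cluster label; labels are 1..k by decreasing size,
    noise is -1."""

    labels: Mapping[str, int]

    def members(self, label: int) -> list[str]:
        return sorted(p for p, l in self.labels.items() if l == label)

    @property
    def cluster_labels(self) -> list[int]:
        return sorted({l for l in self.labels.values() if l != NOISE})

    @property
    def n_noise(self) -> int:
        return sum(1 for l in self.labels.values() if l == NOISE)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": pd.Series(dict(self.labels), name="cluster")}
        ).rename_axis("patient_id")


@dataclass(frozen=True)
class ClusterProfile:
    """What distinguishes one cluster: its significantly shifted pathways and
    its gene mutation frequencies."""

    label: int
    size: int
    defining_pathways: tuple[tuple[str, str, float], ...]  # (pathway, direction, q)
    gene_frequencies: Mapping[str, float]


def default_perplexity(n: int) -> float:
    """Small-cohort-safe default: min(30, floor((n - 1) / 3))."""
    return float(min(30, (n - 1) // 3))


def embed(
    pi: pd.DataFrame,
    perplexity: float | None = None,
    seed: int = 0,
    n_iter: int = DEFAULT_TSNE_ITER,
) -> Embedding:
    """Reduce the patients x pathways PI matrix to two t-SNE dimensions."""
    n = pi.shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 patients to embed, got {n}")
    if not np.all(np.isfinite(pi.to_numpy())):
        raise ValueError("PI matrix contains non-finite values")
    if perplexity is None:
        perplexity = default_perplexity(n)
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < n patients ({n})")
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        method="exact",
        max_iter=n_iter,
    )
    coords = tsne.fit_transform(pi.to_numpy(dtype=float))
    return Embedding(
        patient_ids=tuple(pi.index),
        coordinates=np.asarray(coords, dtype=float),
        seed=seed,
        perplexity=float(perplexity),
    )


def auto_eps(coords: np.ndarray, k: int = 4) -> float:
    """Median distance to the k-th nearest neighbor (k-distance heuristic)."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(coords)))
    nn.fit(coords)
    dists, _ = nn.kneighbors(coords)
    return float(np.median(dists[:, -1]))


def cluster(
    e: Embedding,
    eps: float | None = None,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> ClusterAssignment:
    """Density-based clustering of the embedding.

    ``eps=None`` uses :func:`auto_eps`. Labels are renumbered 1..k by
    decreasing cluster size (ties broken by the smallest member id) so that
    reports are stable; DBSCAN noise points keep -1.
    """
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    coords = e.coordinates
    if eps is None:
        eps = auto_eps(coords)
    raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(coords)
    # stable relabeling by decreasing size
    sizes: dict[int, int] = {}
    first_member: dict[int, str] = {}
    for pid, lab in zip(e.patient_ids, raw):
        if lab == -1:
            continue
        sizes[lab] = sizes.get(lab, 0) + 1
        first_member.setdefault(lab, pid)
    order = sorted(sizes, key=lambda l: (-sizes[l], first_member[l]))
    remap = {old: new for new, old in enumerate(order, start=1)}
    remap[-1] = NOISE
    return ClusterAssignment(
        {pid: remap[int(lab)] for pid, lab in zip(e.patient_ids, raw)}
    )


def characterize(
    pi: pd.DataFrame,
    assignment: ClusterAssignment,
    profiles: Sequence[AlterationProfile] = (),
    alpha: float = 0.05,
) -> list[ClusterProfile]:
    """Defining pathways and gene mutation frequencies per cluster.

    For each cluster, every pathway's scores in-cluster vs out-of-cluster are
    compared with the Wilcoxon rank-sum test; p-values are BH-adjusted across
    pathways within the cluster, and pathways with adjusted p < ``alpha`` are
    the cluster's defining pathways (direction "up" when the in-cluster
    median is higher). Gene frequencies are fractions of cluster members
    whose non-benign alteration profile touches the gene; noise patients are
    ignored throughout.
    """
    labels = assignment.cluster_labels
    if len(labels) < 2:
        raise ValueError("characterization needs >= 2 clusters excluding noise")
    prof_by_pid = {p.patient_id: p.altered_genes for p in profiles}
    clustered = [p for p, l in assignment.labels.items() if l != NOISE]
    out: list[ClusterProfile] = []
    for lab in labels:
        members = assignment.members(lab)
        if not members:
            raise ValueError(f"cluster {lab} is empty after noise removal")
        others = [p for p in clustered if assignment.labels[p] != lab]
        pvals, directions = [], []
        for pw in pi.columns:
            x = pi.loc[members, pw].to_numpy()
            y = pi.loc[others, pw].to_numpy()
            if np.ptp(np.concatenate([x, y])) == 0:  # identical everywhere
                pvals.append(1.0)
                directions.append("up")
                continue
            res = wilcoxon_rank_sum(x, y)
            pvals.append(res.p_value)
            directions.append("up" if np.median(x) >= np.median(y) else "down")
        qvals = bh_adjust(pvals)
        defining = tuple(
            (pw, d, q)
            for pw, d, q in zip(pi.columns, directions, qvals)
            if q < alpha
        )
        freqs = {}
        for pid in members:
            for gene in prof_by_pid.get(pid, {}):
                freqs[gene] = freqs.get(gene, 0) + 1
        out.append(
            ClusterProfile(
                label=lab,
                size=len(members),
                defining_pathways=defining,
                gene_frequencies={g: c / len(members) for g, c in sorted(freqs.items())},
            )
        )
    return out


def compare_clinical(
    assignment: ClusterAssignment,
    clinical: pd.DataFrame,
    covariates: Sequence[str] = ("kodama", "sex", "location", "lauren", "grade",
                                 "pn_status", "lvi"),
) -> pd.DataFrame:
    """Association between cluster membership and categorical covariates.

    Each covariate is cross-tabulated against cluster labels (noise
    excluded). 2x2 tables follow the expected-count rule (Fisher when any
    expected count < 5); larger tables use the Pearson chi-square test.
    Covariates with a single observed level are skipped with a logged reason.
    Returns a tidy frame (covariate, method, statistic, p_value).
    """
    import scipy.stats as st

    if len(assignment.cluster_labels) < 2:
        raise ValueError("need >= 2 clusters")
    clustered = {p: l for p, l in assignment.labels.items() if l != NOISE}
    sub = clinical[clinical["patient_id"].isin(clustered)].copy()
    sub["cluster"] = sub["patient_id"].map(clustered)
    rows = []
    for cov in covariates:
        levels = sub[cov].astype(str)
        if levels.nunique() < 2:
            logger.info("covariate %s has a single level; test skipped", cov)
            continue
        table = pd.crosstab(levels, sub["cluster"]).to_numpy()
        if table.shape == (2, 2):
            t = ContingencyTable2x2(*table.ravel().tolist())
            res = test_2x2(t)
        else:
            chi2, p, _, _ = st.chi2_contingency(table, correction=False)
            res = TestResult(TestMethod.PEARSON_CHI2, float(chi2), float(p))
        rows.append(
            {
                "covariate": cov,
                "method": res.method.value,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows, columns=["covariate", "method", "statistic", "p_value"])
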