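"""t-SNE embedding, DBSCAN clustering (with a brute-force density-
reachability oracle) and cluster characterization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from egcstrat.clustering import (
    ClusterAssignment,
    NOISE,
    auto_eps,
    characterize,
    cluster,
    compare_clinical,
    default_perplexity,
    embed,
    Embedding,
)
from egcstrat.pathways import AlterationProfile


def brute_force_dbscan(coords: np.ndarray, eps: float, min_samples: int) -> list[int]:
    """Literal density-reachability clustering: core points have >= min_samples
    neighbors within eps (self included); clusters are connected components of
    core points under the eps graph; border points join any neighboring core
    cluster; the rest are noise (-1). Written independently of sklearn."""
    n = len(coords)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    neighbors = [set(np.flatnonzero(d[i] <= eps)) for i in range(n)]
    core = [i for i in range(n) if len(neighbors[i]) >= min_samples]
    labels = [-1] * n
    cid = 0
    for seed in core:
        if labels[seed] != -1:
            continue
        stack, labels[seed] = [seed], cid
        while stack:
            i = stack.pop()
            for j in neighbors[i]:
                if labels[j] == -1:
                    labels[j] = cid
                    if j in set(core):
                        stack.append(j)
        cid += 1
    return labels


def random_pi(rng, n, p=12):
    return pd.DataFrame(
        rng.random((n, p)),
        index=pd.Index([f"P{i:02d}" for i in range(n)], name="patient_id"),
        columns=[f"PW{j}" for j in range(p)],
    )


class TestEmbed:
    def test_same_seed_bit_identical(self):
        pi = random_pi(np.random.default_rng(0), 30)
        e1 = embed(pi, seed=42)
        e2 = embed(pi, seed=42)
        assert np.array_equal(e1.coordinates, e2.coordinates)

    def test_duplicate_pi_rows_embed_adjacently(self):
        rng = np.random.default_rng(1)
        pi = random_pi(rng, 24)
        pi.iloc[1] = pi.iloc[0]  # exact duplicate profile
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            e = embed(pi, seed=seed, n_iter=350)
            d = np.sqrt(((e.coordinates[:, None] - e.coordinates[None]) ** 2).sum(-1))
            pair = d[0, 1]
            upper = d[np.triu_indices_from(d, k=1)]
            if pair <= np.percentile(upper, 5):
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_perplexity_must_be_below_n(self):
        pi = random_pi(np.random.default_rng(2), 27)
        with pytest.raises(ValueError, match="perplexity"):
            embed(pi, perplexity=40)

    def test_too_few_patients_rejected(self):
        pi = random_pi(np.random.default_rng(3), 3)
        with pytest.raises(ValueError, match=">= 4"):
            embed(pi)

    def test_non_finite_scores_rejected(self):
        pi = random_pi(np.random.default_rng(4), 10)
        pi.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            embed(pi)

    def test_default_perplexity_small_n_safe(self):
        assert default_perplexity(27) == 8.0
        assert default_perplexity(100) == 30.0


def make_embedding(coords, seed=0):
    coords = np.asarray(coords, dtype=float)
    return Embedding(
        patient_ids=tuple(f"P{i:02d}" for i in range(len(coords))),
        coordinates=coords,
        seed=seed,
        perplexity=5.0,
    )


class TestCluster:
    def test_eps_above_diameter_single_cluster(self):
        rng = np.random.default_rng(0)
        e = make_embedding(rng.normal(size=(12, 2)))
        a = cluster(e, eps=1e6, min_samples=3)
        assert a.cluster_labels == [1]
        assert a.n_noise == 0

    def test_tiny_eps_all_noise(self):
        rng = np.random.default_rng(1)
        e = make_embedding(rng.normal(size=(10, 2)))
        a = cluster(e, eps=1e-9, min_samples=3)
        assert a.cluster_labels == []
        assert a.n_noise == 10

    def test_two_separated_blobs_match_oracle(self):
        rng = np.random.default_rng(2)
        blob1 = rng.normal(0, 1, size=(15, 2))
        blob2 = rng.normal(40, 1, size=(10, 2))  # 20+ sd apart
        coords = np.vstack([blob1, blob2])
        e = make_embedding(coords)
        eps = auto_eps(coords)
        a = cluster(e, eps=eps, min_samples=3)
        assert len(a.cluster_labels) == 2
        oracle = brute_force_dbscan(coords, eps, 3)
        ours = [a.labels[p] for p in e.patient_ids]
        # same partition up to label permutation
        assert _same_partition(ours, oracle)

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_matches_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        coords = rng.normal(size=(n, 2)) * rng.choice([1.0, 3.0])
        eps = auto_eps(coords)
        min_samples = int(rng.integers(2, 5))
        e = make_embedding(coords)
        ours = [cluster(e, eps=eps, min_samples=min_samples).labels[p]
                for p in e.patient_ids]
        oracle = brute_force_dbscan(coords, eps, min_samples)
        assert _same_partition(ours, oracle)

    def test_labels_ordered_by_decreasing_size(self):
        rng = np.random.default_rng(9)
        big = rng.normal(0, 0.5, size=(20, 2))
        small = rng.normal(50, 0.5, size=(5, 2))
        e = make_embedding(np.vstack([small, big]))
        a = cluster(e, eps=3.0, min_samples=3)
        sizes = {l: len(a.members(l)) for l in a.cluster_labels}
        assert sizes[1] >= sizes[2]
        assert sizes[1] == 20

    def test_invalid_min_samples(self):
        e = make_embedding(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            cluster(e, eps=1.0, min_samples=0)


def _same_partition(a, b) -> bool:
    """Identical groupings up to label permutation; noise must match exactly."""
    mapping: dict[int, int] = {}
    back: dict[int, int] = {}
    for x, y in zip(a, b):
        if (x == NOISE) != (y == -1):
            return False
        if x == NOISE:
            continue
        if mapping.setdefault(x, y) != y or back.setdefault(y, x) != x:
            return False
    return True


class TestCharacterize:
    def _assignment(self, n1, n2):
        labels = {f"P{i:02d}": (1 if i < n1 else 2) for i in range(n1 + n2)}
        return ClusterAssignment(labels)

    def test_engineered_pathway_is_defining(self):
        a = self._assignment(10, 10)
        pids = sorted(a.labels)
        pi = pd.DataFrame(
            {"PWsig": [1.0] * 10 + [0.0] * 10, "PWnull": [0.5] * 20},
            index=pd.Index(pids, name="patient_id"),
        )
        profiles = characterize(pi, a)
        c1 = next(p for p in profiles if p.label == 1)
        names = [pw for pw, _, _ in c1.defining_pathways]
        assert names == ["PWsig"]
        assert c1.defining_pathways[0][1] == "up"

    def test_identical_columns_yield_no_defining_pathways(self):
        a = self._assignment(5, 5)
        pids = sorted(a.labels)
        pi = pd.DataFrame({"PW1": [0.3] * 10, "PW2": [0.7] * 10},
                          index=pd.Index(pids, name="patient_id"))
        for prof in characterize(pi, a):
            assert prof.defining_pathways == ()

    def test_gene_frequency_counts_members(self):
        a = self._assignment(4, 4)
        pids = sorted(a.labels)
        pi = pd.DataFrame({"PW1": np.linspace(0, 1, 8)},
                          index=pd.Index(pids, name="patient_id"))
        profs = [AlterationProfile(p, {"TP53": 1.0}) for p in pids[:4]]
        out = characterize(pi, a, profs)
        c1 = next(p for p in out if p.label == 1)
        assert c1.gene_frequencies["TP53"] == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        a = self._assignment(6, 6)
        swapped = ClusterAssignment({p: 3 - l for p, l in a.labels.items()})
        pids = sorted(a.labels)
        rng = np.random.default_rng(13)
        pi = pd.DataFrame(rng.random((12, 5)),
                          index=pd.Index(pids, name="patient_id"),
                          columns=[f"PW{j}" for j in range(5)])
        orig = {(frozenset(a_.defining_pathways)) for a_ in characterize(pi, a)}
        swap = {(frozenset(a_.defining_pathways)) for a_ in characterize(pi, swapped)}
        assert orig == swap

    def test_single_cluster_rejected(self):
        a = ClusterAssignment({f"P{i}": 1 for i in range(6)})
        pi = pd.DataFrame({"PW1": range(6)},
                          index=pd.Index(sorted(a.labels), name="patient_id"))
        with pytest.raises(ValueError, match=">= 2 clusters"):
            characterize(pi, a)


class TestCompareClinical:
    @staticmethod
    def _clinical(pids, covariate):
        return pd.DataFrame({"patient_id": pids, "grp": covariate})

    def test_independent_covariate_rarely_significant(self):
        n = 400
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            pids = [f"P{i}" for i in range(n)]
            a = ClusterAssignment({p: int(rng.integers(1, 3)) for p in pids})
            cov = rng.choice(["x", "y"], size=n)
            out = compare_clinical(a, self._clinical(pids, cov), covariates=("grp",))
            if out.loc[0, "p_value"] > 0.05:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_covariate_equal_to_cluster_label_significant(self):
        pids = [f"P{i}" for i in range(100)]
        a = ClusterAssignment({p: 1 + (i % 2) for i, p in enumerate(pids)})
        cov = ["x" if (i % 2) else "y" for i in range(100)]
        out = compare_clinical(a, self._clinical(pids, cov), covariates=("grp",))
        assert out.loc[0, "p_value"] < 1e-6

    def test_single_level_covariate_skipped(self):
        pids = [f"P{i}" for i in range(10)]
        a = ClusterAssignment({p: 1 + (i % 2) for i, p in enumerate(pids)})
        out = compare_clinical(a, self._clinical(pids, ["x"] * 10), covariates=("grp",))
        assert out.empty
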