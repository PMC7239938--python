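"""Community-type (enterotype) detection by PAM with silhouette selection.

Samples are clustered on a distance matrix by partitioning around medoids
(BUILD then SWAP), the number of clusters is chosen by the maximum mean
silhouette width (silhouette coefficient, SC), and a mean silhouette
above 0.5 is flagged as "reasonable" community structure. A cohort with
SC below 0.5 at every k shows no enterotype-like clustering.

Ties in BUILD and SWAP are broken by lowest sample index so results are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .feature_table import ValidationError


@dataclass
class ClusteringResult:
    k: int
    medoid_ids: list
    labels: pd.Series            # 1..k per sample
    silhouettes: pd.Series
    sc: float                    # mean silhouette width
    reasonable: bool             # SC > 0.5
    objective: float             # total distance to assigned medoid


def _assign(d: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    # nearest medoid; ties go to the medoid appearing first (lowest index order)
    sub = d[:, medoids]
    return np.argmin(sub, axis=1)


def _build(d: np.ndarray, k: int) -> list:
    """Greedy BUILD: first medoid minimizes total distance, each next one
    maximizes the reduction; ties go to the lowest index."""
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return sorted(medoids)


def _swap(d: np.ndarray, medoids: list) -> tuple:
    """Best-improvement SWAP until a local optimum of the total distance
    to the assigned medoid."""
    n = d.shape[0]
    medoids = sorted(medoids)

    def objective(meds):
        return d[:, meds].min(axis=1).sum()

    current = objective(medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None)  # (delta, (out, in))
        med_arr = np.array(medoids)
        non_med = np.array([i for i in range(n) if i not in set(medoids)])
        for j, m in enumerate(medoids):
            others = np.delete(med_arr, j)
            d_others = d[:, others].min(axis=1) if len(others) else np.full(n, np.inf)
            # objective after replacing m by each candidate c, vectorized over c
            cand_obj = np.minimum(d_others[None, :], d[non_med]).sum(axis=1)
            deltas = current - cand_obj
            b = int(np.argmax(deltas))
            if deltas[b] > best[0] + 1e-12:
                best = (float(deltas[b]), (m, int(non_med[b])))
        if best[1] is not None:
            out, inn = best[1]
            medoids.remove(out)
            medoids.append(inn)
            medoids = sorted(medoids)
            current = objective(medoids)
            improved = True
    return medoids, float(current)


def pam(dm: DistanceMatrix, k: int, seed=0, n_restarts: int = 10) -> ClusteringResult:
    """Partitioning around medoids: greedy BUILD then best-improvement SWAP.

    SWAP is a local search, so the BUILD start is supplemented by
    ``n_restarts - 1`` seeded random initial medoid sets and the best
    local optimum is kept. Deterministic given ``seed`` and the
    lowest-index tie rule.
    """
    d = dm.data
    n = d.shape[0]
    if not 2 <= k < n:
        raise ValidationError(f"pam requires 2 <= k < n (k={k}, n={n})")
    medoids, current = _swap(d, _build(d, k))
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_restarts - 1)):
        start = sorted(rng.choice(n, size=k, replace=False).tolist())
        cand, obj = _swap(d, start)
        if obj < current - 1e-12 or (abs(obj - current) <= 1e-12 and cand < medoids):
            medoids, current = cand, obj

    med_arr = np.array(medoids)
    assign = _assign(d, med_arr)
    labels = pd.Series(assign + 1, index=dm.ids, name="cluster")
    sil = silhouette(dm, labels)
    return ClusteringResult(
        k=k,
        medoid_ids=[dm.ids[m] for m in medoids],
        labels=labels,
        silhouettes=sil[0],
        sc=sil[1],
        reasonable=sil[1] > 0.5,
        objective=float(current),
    )


def silhouette(dm: DistanceMatrix, labels) -> tuple:
    """Per-sample silhouette s(i) = (b - a) / max(a, b) and its mean (SC).

    a = mean distance to own cluster (excluding self), b = smallest mean
    distance to any other cluster. Singleton clusters get s(i) = 0.
    """
    labels = pd.Series(labels).reindex(dm.ids)
    lab = labels.to_numpy()
    uniq = pd.unique(lab)
    if len(uniq) < 2:
        raise ValidationError("silhouette needs >= 2 clusters")
    d = dm.data
    n = d.shape[0]
    s = np.zeros(n)
    masks = {g: lab == g for g in uniq}
    for i in range(n):
        own = masks[lab[i]]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, masks[g]].mean() for g in uniq if g != lab[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    per_sample = pd.Series(s, index=dm.ids, name="silhouette")
    return per_sample, float(per_sample.mean())


def select_k(dm: DistanceMatrix, k_range=range(2, 11), seed=0):
    """Run PAM + silhouette for each k; return the argmax-SC result and
    the SC-vs-k table. ``reasonable`` (SC > 0.5) is False for a cohort
    with no community structure."""
    n = len(dm.ids)
    k_range = [k for k in k_range if 2 <= k < n]
    if not k_range:
        raise ValidationError("k_range out of bounds")
    results = {}
    for k in k_range:
        results[k] = pam(dm, k, seed=seed)
    table = pd.DataFrame(
        {"k": list(results), "sc": [results[k].sc for k in results]}
    ).set_index("k")
    best_k = table["sc"].idxmax()
    return results[best_k], table
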