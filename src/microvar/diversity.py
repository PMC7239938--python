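"""Alpha- and beta-diversity and group-dispersion analysis.

Alpha indices are the four reported for the cohort: observed richness,
bias-corrected Chao1, Shannon entropy (natural log) and Fisher's alpha.
Beta diversity covers Bray-Curtis dissimilarity and unweighted / weighted
(normalized) UniFrac over a rooted tree. ``dispersion`` is a betadisper
analogue: distance of each sample to its group centroid in
principal-coordinate space with a permutation ANOVA on those distances.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.stats.distance import DistanceMatrix

from .feature_table import FeatureTable, NormalizedTable, ValidationError


def _as_values(table) -> pd.DataFrame:
    if isinstance(table, FeatureTable):
        return table.counts.astype(float)
    if isinstance(table, NormalizedTable):
        return table.values
    return pd.DataFrame(table)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def fisher_alpha(s_obs: int, n_reads: int) -> float:
    """Solve ``S = alpha * ln(1 + N / alpha)`` for alpha by bracketed
    root-finding. Returns ``inf`` when every individual is its own species
    (no finite solution)."""
    if s_obs <= 0 or n_reads <= 0:
        raise ValidationError("fisher_alpha needs S > 0 and N > 0")
    if s_obs >= n_reads:
        warnings.warn("fisher_alpha: S == N has no finite solution")
        return float("inf")

    def f(a):
        return a * np.log1p(n_reads / a) - s_obs

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover - pathological
            return float("inf")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def alpha_diversity(table) -> pd.DataFrame:
    """Per-sample observed richness, Chao1, Shannon (nats) and Fisher alpha.

    Requires integer counts (e.g. a rarefied table): the estimators are
    defined on abundances of individuals, not on relative values.
    """
    values = _as_values(table)
    arr = values.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise ValidationError("alpha indices require integer counts")
    arr = np.round(arr).astype(np.int64)
    records = []
    for i, sid in enumerate(values.index):
        counts = arr[i]
        pos = counts[counts > 0]
        n = int(pos.sum())
        s = int(pos.size)
        records.append(
            {
                "sample": sid,
                "observed": s,
                "chao1": float(_skbio_chao1(counts, bias_corrected=True)),
                "shannon": float(_skbio_shannon(counts, base=np.e)),
                "fisher_alpha": fisher_alpha(s, n),
            }
        )
    return pd.DataFrame.from_records(records).set_index("sample")


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    A pair of all-zero samples has an undefined dissimilarity; it is
    reported as 0 with a warning.
    """
    values = _as_values(table)
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("Bray-Curtis requires nonnegative values")
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = pdist(arr, metric="braycurtis")
    if np.isnan(cond).any():
        warnings.warn(
            "Bray-Curtis undefined for all-zero sample pair(s); reported as 0"
        )
        cond = np.nan_to_num(cond, nan=0.0)
    return DistanceMatrix(squareform(cond), ids=list(values.index))


def _read_tree(tree) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    text = str(tree)
    if text.strip().endswith(";"):
        return TreeNode.read(io.StringIO(text))
    return TreeNode.read(text)  # path


def unifrac(table, tree, weighted: bool = True, normalized: bool = True) -> DistanceMatrix:
    """UniFrac distance over a rooted tree.

    Unweighted: fraction of total branch length unique to either sample's
    taxon set. Weighted: branch-length-weighted difference of subtree
    relative abundances; ``normalized`` (default) bounds it in [0, 1].
    """
    values = _as_values(table)
    tree = _read_tree(tree)
    leaves = {t.name for t in tree.tips()}
    missing = [t for t in values.columns if t not in leaves]
    if missing:
        raise ValidationError(f"taxa missing from tree: {missing}")
    arr = values.to_numpy(dtype=float)
    kwargs = dict(tree=tree, taxa=list(values.columns))
    if weighted:
        dm = beta_diversity(
            "weighted_unifrac", arr, ids=list(values.index),
            normalized=normalized, **kwargs,
        )
    else:
        dm = beta_diversity(
            "unweighted_unifrac", arr, ids=list(values.index), **kwargs
        )
    return dm


# ---------------------------------------------------------------------------
# Group dispersion (betadisper analogue)
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    distances: pd.Series       # per-sample distance to its group centroid
    group_means: pd.Series
    f_statistic: float
    p_value: float
    permutations: int


def _pcoa_axes(dm: DistanceMatrix):
    """Gower-centered eigendecomposition keeping negative eigenvalues.

    Returns real-axis coordinates and 'imaginary'-axis coordinates; squared
    distances in the embedding are real**2 - imag**2, the standard
    correction for non-Euclidean dissimilarities.
    """
    d2 = dm.data ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    g = (g + g.T) / 2
    vals, vecs = np.linalg.eigh(g)
    tol = max(np.abs(vals).max(), 1.0) * 1e-12
    pos = vals > tol
    neg = vals < -tol
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag


def _centroid_distances(real, imag, labels):
    d2 = np.zeros(real.shape[0])
    for g in np.unique(labels):
        mask = labels == g
        cr = real[mask].mean(axis=0)
        d2[mask] = ((real[mask] - cr) ** 2).sum(axis=1)
        if imag.shape[1]:
            ci = imag[mask].mean(axis=0)
            d2[mask] -= ((imag[mask] - ci) ** 2).sum(axis=1)
    return np.sqrt(np.clip(d2, 0.0, None))


def _anova_f(z, labels):
    grand = z.mean()
    ssb = ssw = 0.0
    k = 0
    for g in np.unique(labels):
        zg = z[labels == g]
        ssb += len(zg) * (zg.mean() - grand) ** 2
        ssw += ((zg - zg.mean()) ** 2).sum()
        k += 1
    n = len(z)
    if ssw <= 0:
        return 0.0 if ssb <= 0 else np.inf
    return (ssb / (k - 1)) / (ssw / (n - k))


def dispersion(dm: DistanceMatrix, groups, n_perm: int = 999, seed=None) -> DispersionResult:
    """Homogeneity of multivariate dispersion between groups.

    Embeds the distance matrix by principal coordinates, computes each
    sample's distance to its group centroid, and tests equality of mean
    distances by a one-way ANOVA F with a label-permutation p-value.
    """
    groups = pd.Series(groups).reindex(dm.ids)
    labels = groups.to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("dispersion needs >= 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValidationError(f"group {small!r} has fewer than 2 samples")
    real, imag = _pcoa_axes(dm)
    z = _centroid_distances(real, imag, labels)
    f_obs = _anova_f(z, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(labels))
        zp = _centroid_distances(real, imag, labels[perm])
        if _anova_f(zp, labels[perm]) >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    distances = pd.Series(z, index=dm.ids, name="dist_to_centroid")
    means = distances.groupby(groups).mean()
    return DispersionResult(distances, means, float(f_obs), float(p), n_perm)
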