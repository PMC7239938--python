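"""Permutation inference on distance matrices and taxon-phenotype association.

Implements the community-level tests used for the cohort's temporal
dynamics: PERMANOVA with sequential sums of squares (and optional
within-stratum permutation for repeated measures), ANOSIM on distance
ranks, SIMPER decomposition of between-group Bray-Curtis dissimilarity,
nonmetric multidimensional scaling (Kruskal stress-1, monotone regression
by pool-adjacent-violators), an envfit-style covariate fit on ordination
scores, paired T2-T1 delta construction, and a genera x phenotype
Pearson cross-correlation grid with Benjamini-Hochberg correction.

All permutation p-values use the add-one estimator
``p = (1 + #{perm >= obs}) / (1 + n_perm)`` and therefore lie in (0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from skbio.stats.distance import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .feature_table import NormalizedTable, ValidationError

logger = logging.getLogger("microvar")


@dataclass
class PermutationTestResult:
    statistic: str            # "pseudo-F", "R" or "r2"
    observed: float
    permutations: int
    p_value: float
    effect_size: float = None


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------

def _permutation_indices(n, n_perm, rng, strata=None):
    """(n_perm, n) array of permuted indices, optionally within strata."""
    perms = np.empty((n_perm, n), dtype=np.intp)
    if strata is None:
        for b in range(n_perm):
            perms[b] = rng.permutation(n)
    else:
        strata = np.asarray(strata)
        base = np.arange(n)
        groups = [np.flatnonzero(strata == g) for g in pd.unique(strata)]
        for b in range(n_perm):
            perm = base.copy()
            for idx in groups:
                perm[idx] = idx[rng.permutation(len(idx))]
            perms[b] = perm
    return perms


def _add_one_p(perm_stats, observed):
    return float((1 + np.sum(perm_stats >= observed - 1e-12)) / (1 + len(perm_stats)))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _design_block(column: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(column):
        return column.to_numpy(dtype=float)[:, None]
    dummies = pd.get_dummies(column.astype("category"), drop_first=True)
    if dummies.shape[1] == 0:
        raise ValidationError(f"term {column.name!r} has a single level")
    return dummies.to_numpy(dtype=float)


def _gower_center(dm: DistanceMatrix) -> np.ndarray:
    d2 = dm.data ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    return (g + g.T) / 2


def _sequential_projectors(design: pd.DataFrame, terms):
    """Orthonormal bases Q_t for the cumulative design after each term."""
    n = len(design)
    x = np.ones((n, 1))
    bases, dfs = [], []
    rank_prev = 1
    for term in terms:
        x = np.hstack([x, _design_block(design[term])])
        q, r = np.linalg.qr(x)
        keep = np.abs(np.diag(r)) > 1e-10
        q = q[:, keep]
        bases.append(q)
        dfs.append(q.shape[1] - rank_prev)
        rank_prev = q.shape[1]
    return bases, dfs


def permanova(
    dm: DistanceMatrix,
    design: pd.DataFrame,
    terms=None,
    n_perm: int = 10_000,
    strata=None,
    seed=None,
) -> pd.DataFrame:
    """Permutational multivariate ANOVA with sequential (Type-I) SS.

    The total sum of squares comes from the Gower-centered matrix of
    squared distances; each term's SS is the increment in explained trace
    when its design block is added after the preceding terms, so term
    order matters and effect sizes (R^2 = SS_term / SS_total) plus the
    residual sum to 1. p-values permute sample labels, optionally within
    ``strata`` (e.g. permute time point within host for repeated
    measures).

    Returns a tidy frame with one row per term plus Residual and Total.
    """
    design = design.loc[list(dm.ids)]
    if terms is None:
        terms = list(design.columns)
    for term in terms:
        if design[term].nunique() < 2 and not pd.api.types.is_numeric_dtype(design[term]):
            raise ValidationError(f"term {term!r} has a single level")
    n = len(design)
    g = _gower_center(dm)
    ss_total = float(np.trace(g))
    bases, dfs = _sequential_projectors(design, terms)
    rank_full = bases[-1].shape[1]
    df_res = n - rank_full
    if df_res <= 0:
        raise ValidationError("saturated design: no residual degrees of freedom")

    def term_f(gmat):
        tr_prev, ss, fstats = 0.0, [], []
        for q, df_t in zip(bases, dfs):
            tr = float(np.einsum("ij,ik,jk->", gmat, q, q))
            ss.append(tr - tr_prev)
            tr_prev = tr
        ss_res = float(np.trace(gmat)) - tr_prev
        for s, df_t in zip(ss, dfs):
            fstats.append((s / df_t) / (ss_res / df_res) if df_t > 0 else np.nan)
        return np.array(ss), np.array(fstats), ss_res

    ss_obs, f_obs, ss_res = term_f(g)
    rng = np.random.default_rng(seed)
    strata_arr = None
    if strata is not None:
        strata_arr = pd.Series(strata).reindex(dm.ids).to_numpy()
    perms = _permutation_indices(n, n_perm, rng, strata_arr)
    # batch-vectorized permutations: G is permuted in chunks, traces of the
    # projected matrices come from one einsum per cumulative design basis
    f_perm = np.empty((n_perm, len(terms)))
    tr_g = float(np.trace(g))
    chunk = max(1, int(2e7 // max(n * n, 1)))
    for start in range(0, n_perm, chunk):
        pc = perms[start:start + chunk]
        gp = g[pc[:, :, None], pc[:, None, :]]          # (B, n, n)
        tr_prev = np.zeros(len(pc))
        ss_chunk = []
        for q in bases:
            tr = np.einsum("bij,ik,jk->b", gp, q, q, optimize=True)
            ss_chunk.append(tr - tr_prev)
            tr_prev = tr
        ss_res_chunk = tr_g - tr_prev
        for t, (s, df_t) in enumerate(zip(ss_chunk, dfs)):
            f_perm[start:start + len(pc), t] = (
                (s / df_t) / (ss_res_chunk / df_res) if df_t > 0 else np.nan
            )
    rows = []
    for t, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "df": dfs[t],
                "SS": ss_obs[t],
                "R2": ss_obs[t] / ss_total,
                "pseudo_F": f_obs[t],
                "p_value": _add_one_p(f_perm[:, t], f_obs[t]),
            }
        )
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res,
                 "R2": ss_res / ss_total, "pseudo_F": np.nan, "p_value": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total,
                 "R2": 1.0, "pseudo_F": np.nan, "p_value": np.nan})
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["permutations"] = n_perm
    return out


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def anosim(dm: DistanceMatrix, groups, n_perm: int = 999, seed=None) -> PermutationTestResult:
    """ANOSIM R: normalized difference of mean between- vs within-group
    distance ranks (midrank ties); p by label permutation."""
    groups = pd.Series(groups).reindex(dm.ids)
    labels = groups.to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValidationError("anosim needs >= 2 groups with >= 2 samples each")
    n = len(labels)
    cond = squareform(dm.data, checks=False)
    rank_pairs = stats.rankdata(cond)  # midrank ties
    denom = n * (n - 1) / 4.0
    iu0, iu1 = np.triu_indices(n, k=1)

    def r_stat(lab2d):
        within = lab2d[:, iu0] == lab2d[:, iu1]          # (B, n_pairs)
        n_w = within.sum(axis=1)
        n_b = within.shape[1] - n_w
        sum_w = within @ rank_pairs
        rw = sum_w / n_w
        rb = (rank_pairs.sum() - sum_w) / n_b
        return (rb - rw) / denom

    r_obs = float(r_stat(labels[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = _permutation_indices(n, n_perm, rng)
    perm_stats = np.concatenate([
        r_stat(labels[perms[s:s + 512]])
        for s in range(0, n_perm, 512)
    ]) if n_perm else np.empty(0)
    return PermutationTestResult(
        statistic="R",
        observed=float(r_obs),
        permutations=n_perm,
        p_value=_add_one_p(perm_stats, r_obs),
    )


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

def simper(table, groups) -> pd.DataFrame:
    """Per-taxon contribution to average between-group Bray-Curtis
    dissimilarity, normalized to sum to 1, sorted descending with
    cumulative sums and per-group mean abundances."""
    values = table.values if isinstance(table, NormalizedTable) else pd.DataFrame(table)
    groups = pd.Series(groups).reindex(values.index)
    uniq = pd.unique(groups.dropna())
    if len(uniq) != 2:
        raise ValidationError("simper expects exactly 2 groups")
    a = values.loc[groups == uniq[0]].to_numpy(dtype=float)
    b = values.loc[groups == uniq[1]].to_numpy(dtype=float)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValidationError("simper: empty group")
    # contribution_k = mean over between pairs of |x_ik - x_jk| / sum_m (x_im + x_jm)
    diff = np.abs(a[:, None, :] - b[None, :, :])            # (na, nb, k)
    denom = (a.sum(1)[:, None] + b.sum(1)[None, :])         # (na, nb)
    contrib = (diff / denom[:, :, None]).mean(axis=(0, 1))
    total = contrib.sum()
    if total > 0:
        contrib = contrib / total
    out = pd.DataFrame(
        {
            "contribution": contrib,
            "mean_" + str(uniq[0]): a.mean(axis=0),
            "mean_" + str(uniq[1]): b.mean(axis=0),
        },
        index=values.columns,
    )
    out = out.sort_values("contribution", ascending=False)
    out["cumulative"] = out["contribution"].cumsum()
    out.index.name = "taxon"
    return out


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class Ordination:
    scores: pd.DataFrame
    stress: float
    converged: bool
    k: int
    stress_history: list = field(default_factory=list, repr=False)


def _nmds_single(delta, n, k, rng, max_iter, tol, init=None):
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression()
    x = init if init is not None else rng.normal(size=(n, k))
    history = []
    prev = np.inf
    converged = False
    iu = np.triu_indices(n, k=1)
    for _ in range(max_iter):
        d = pdist(x)
        d = np.maximum(d, 1e-12)
        dhat = np.empty_like(d)
        dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
        # scale disparities to configuration distances
        dhat *= np.sqrt((d ** 2).sum() / max((dhat ** 2).sum(), 1e-300))
        stress = np.sqrt(((d - dhat) ** 2).sum() / (d ** 2).sum())
        history.append(float(stress))
        # Guttman transform
        ratio = dhat / d
        b = np.zeros((n, n))
        b[iu] = -ratio
        b += b.T
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
        if prev - stress < tol:
            converged = True
            break
        prev = stress
    return x, history[-1], converged, history


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed=None,
) -> Ordination:
    """Nonmetric multidimensional scaling minimizing Kruskal stress-1.

    Each start alternates monotone (pool-adjacent-violators) regression of
    configuration distances on dissimilarity order with a Guttman update;
    the best of ``n_starts`` random initializations is kept. If no start
    converges the result is flagged, not raised.
    """
    n = len(dm.ids)
    if n < k + 2:
        raise ValidationError(f"nmds needs n >= k + 2 (n={n}, k={k})")
    delta = squareform(dm.data, checks=False)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        x, stress, conv, history = _nmds_single(delta, n, k, rng, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, conv, history)
    x, stress, conv, history = best
    x = x - x.mean(axis=0)
    scores = pd.DataFrame(
        x, index=dm.ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return Ordination(scores, float(stress), bool(conv), k, history)


# ---------------------------------------------------------------------------
# envfit analogue
# ---------------------------------------------------------------------------

def _covariate_r2(scores: np.ndarray, column: pd.Series) -> float:
    if pd.api.types.is_numeric_dtype(column):
        y = column.to_numpy(dtype=float)
        yc = y - y.mean()
        sst = (yc ** 2).sum()
        if sst <= 0:
            return 0.0
        x = np.hstack([np.ones((len(y), 1)), scores])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        return float(1 - (resid ** 2).sum() / sst)
    labels = column.to_numpy()
    grand = scores.mean(axis=0)
    sst = ((scores - grand) ** 2).sum()
    if sst <= 0:
        return 0.0
    ssw = 0.0
    for g in pd.unique(labels):
        sub = scores[labels == g]
        ssw += ((sub - sub.mean(axis=0)) ** 2).sum()
    return float(1 - ssw / sst)


def fit_covariates(
    ordination: Ordination,
    metadata: pd.DataFrame,
    covariates=None,
    n_perm: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """envfit-style covariate fit on ordination scores.

    Continuous covariates: squared multiple correlation of the covariate
    with the score axes. Categorical covariates: fraction of score
    variance explained by level centroids. p-values by permuting the
    covariate rows; BH adjustment across all covariates of the call.
    The summed r2 of covariates with adjusted p < 0.05 is reported in
    ``attrs['combined_r2']`` (non-orthogonal: covariates may share
    variance).
    """
    scores = ordination.scores.to_numpy()
    metadata = metadata.loc[ordination.scores.index]
    if covariates is None:
        covariates = list(metadata.columns)
    rng = np.random.default_rng(seed)
    n = scores.shape[0]
    rows = []
    for cov in covariates:
        col = metadata[cov]
        if col.nunique(dropna=False) < 2:
            warnings.warn(f"covariate {cov!r} is constant; r2 = 0")
            rows.append({"covariate": cov, "r2": 0.0, "p_value": np.nan})
            continue
        r2_obs = _covariate_r2(scores, col)
        perm_stats = np.empty(n_perm)
        for b in range(n_perm):
            perm_stats[b] = _covariate_r2(scores, col.iloc[rng.permutation(n)].reset_index(drop=True))
        rows.append(
            {
                "covariate": cov,
                "r2": r2_obs,
                "p_value": _add_one_p(perm_stats, r2_obs),
            }
        )
    out = pd.DataFrame(rows).set_index("covariate")
    valid = out["p_value"].notna()
    adj = np.full(len(out), np.nan)
    if valid.any():
        adj[valid.to_numpy()] = multipletests(out.loc[valid, "p_value"], method="fdr_bh")[1]
    out["p_adjusted"] = adj
    out.attrs["permutations"] = n_perm
    out.attrs["combined_r2"] = float(
        out.loc[(out["p_adjusted"] < 0.05).fillna(False), "r2"].sum()
    )
    return out


# ---------------------------------------------------------------------------
# Delta construction and cross-correlation
# ---------------------------------------------------------------------------

def delta_phenotypes(
    metadata: pd.DataFrame,
    host_col: str = "host_id",
    time_col: str = "timepoint",
    order=("T2", "T1"),
) -> pd.DataFrame:
    """Per-host differences ``x(order[0]) - x(order[1])`` of numeric columns.

    Non-numeric, time-invariant columns (breed, discipline, ...) are
    carried through; hosts missing either time point are dropped and
    logged. Result is indexed by host id.
    """
    later, earlier = order
    present = metadata[time_col].astype(str)
    a = metadata[present == str(later)].set_index(host_col)
    b = metadata[present == str(earlier)].set_index(host_col)
    hosts = a.index.intersection(b.index)
    dropped = sorted(set(a.index).symmetric_difference(b.index))
    if dropped:
        logger.info("delta_phenotypes: dropped host(s) missing a time point: %s", dropped)
    numeric = [
        c for c in metadata.columns
        if c not in (host_col, time_col) and pd.api.types.is_numeric_dtype(metadata[c])
    ]
    out = a.loc[hosts, numeric] - b.loc[hosts, numeric]
    for c in metadata.columns:
        if c in (host_col, time_col) or c in numeric:
            continue
        if (a.loc[hosts, c].astype(str) == b.loc[hosts, c].astype(str)).all():
            out[c] = a.loc[hosts, c]
    out.index.name = host_col
    return out


@dataclass
class CrossCorrelation:
    r: pd.DataFrame
    p: pd.DataFrame
    p_adjusted: pd.DataFrame

    def tidy(self) -> pd.DataFrame:
        rows = []
        for taxon in self.r.index:
            for phen in self.r.columns:
                padj = self.p_adjusted.loc[taxon, phen]
                tier = ""
                if padj < 0.05:
                    tier = "<0.05"
                elif padj < 0.10:
                    tier = "<0.10"
                rows.append(
                    {
                        "taxon": taxon,
                        "phenotype": phen,
                        "r": self.r.loc[taxon, phen],
                        "p_value": self.p.loc[taxon, phen],
                        "p_adjusted": padj,
                        "significance": tier,
                    }
                )
        return pd.DataFrame(rows)


def cross_correlate(taxa, phenotypes: pd.DataFrame, method: str = "pearson") -> CrossCorrelation:
    """Taxon x phenotype correlation grid with matrix-wide BH adjustment.

    Cells with fewer than 3 complete pairs or zero variance are flagged
    NaN and excluded from the BH family. ``method`` is 'pearson'
    (default) or 'spearman'.
    """
    values = taxa.values if isinstance(taxa, NormalizedTable) else pd.DataFrame(taxa)
    phenotypes = phenotypes.loc[values.index]
    taxa_ids = list(values.columns)
    phen_ids = list(phenotypes.columns)
    r = pd.DataFrame(np.nan, index=taxa_ids, columns=phen_ids)
    p = pd.DataFrame(np.nan, index=taxa_ids, columns=phen_ids)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown method {method!r}")
    for phen in phen_ids:
        y = phenotypes[phen].to_numpy(dtype=float)
        for taxon in taxa_ids:
            x = values[taxon].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 3:
                continue
            xs, ys = x[mask], y[mask]
            if np.std(xs) == 0 or np.std(ys) == 0:
                continue
            res = corr(xs, ys)
            r.loc[taxon, phen] = res.statistic
            p.loc[taxon, phen] = res.pvalue
    flat = p.to_numpy().ravel()
    valid = np.isfinite(flat)
    adj = np.full_like(flat, np.nan)
    if valid.any():
        adj[valid] = multipletests(flat[valid], method="fdr_bh")[1]
    p_adj = pd.DataFrame(adj.reshape(p.shape), index=taxa_ids, columns=phen_ids)
    return CrossCorrelation(r, p, p_adj)
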