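"""Microbiability: variance explained by gut community composition.

The phenotype model is a Bayesian linear mixed model

    y = X beta + u_m (+ u_g) + e,
    u_m ~ N(0, sigma2_m * M),   u_g ~ N(0, sigma2_H * K),   e ~ N(0, sigma2_e * I)

where ``M`` is the microbial relationship matrix built from the CSS-log
normalized count table (the sample-by-sample analogue of a genomic
relationship matrix) and ``K`` an optional host kinship. Fixed effects
(intercept, breed, discipline, time) carry flat priors; variances carry
scaled-inverse-chi-square priors. Estimation is by Gibbs sampling of the
full conditionals, worked in the eigenbasis of ``M`` so each sweep is
linear in the number of samples.

Microbiability per posterior draw:

* ``total`` (default): m2 = sigma2_m / (sigma2_m + sigma2_H + sigma2_e),
  a variance fraction bounded in [0, 1];
* ``exclusive``: m2 = sigma2_m / (sigma2_H + sigma2_e), the
  heritability-style ratio with the microbial component excluded from
  the denominator (may exceed 1); kept for comparability with reports
  that print this form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, NormalizedTable, ValidationError, css_log

logger = logging.getLogger("microvar")

M2_DEFINITIONS = ("total", "exclusive")


@dataclass
class MicrobialKernel:
    """Symmetric PSD sample similarity matrix scaled to mean diagonal 1."""

    matrix: pd.DataFrame
    source: str = "css_log"
    jitter: float = 0.0

    @property
    def ids(self) -> list:
        return list(self.matrix.index)

    def subset(self, ids) -> "MicrobialKernel":
        sub = self.matrix.loc[ids, ids]
        return MicrobialKernel(sub, self.source, self.jitter)


def build_kernel(css_table, center: bool = True, scale: bool = False) -> MicrobialKernel:
    """Microbial relationship matrix M = W W' / k from the CSS-log table.

    Columns (taxa) of the normalized matrix W are centered (optionally
    unit-scaled), M is rescaled to mean diagonal 1 so that sigma2_m sits
    on the phenotypic variance scale, and a minimal diagonal jitter is
    recorded if numerical round-off pushes an eigenvalue below zero.
    """
    values = css_table.values if isinstance(css_table, NormalizedTable) else pd.DataFrame(css_table)
    w = values.to_numpy(dtype=float)
    n, k = w.shape
    if k == 0:
        raise ValidationError("kernel needs at least one taxon")
    if center:
        w = w - w.mean(axis=0)
    if scale:
        sd = w.std(axis=0, ddof=1)
        w = w / np.where(sd > 0, sd, 1.0)
    m = w @ w.T / k
    mean_diag = np.trace(m) / n
    if mean_diag > 0:
        m = m / mean_diag
    m = (m + m.T) / 2
    jitter = 0.0
    min_eig = float(np.linalg.eigvalsh(m)[0])
    if min_eig < -1e-8:
        raise ValidationError(
            f"kernel has eigenvalue {min_eig:.3e} below tolerance; "
            "raise the jitter or check the input table"
        )
    if min_eig < 0:
        jitter = -min_eig + 1e-12
        m = m + jitter * np.eye(n)
    source = css_table.normalization if isinstance(css_table, NormalizedTable) else "matrix"
    return MicrobialKernel(pd.DataFrame(m, index=values.index, columns=values.index),
                           source=source, jitter=jitter)


@dataclass
class MixedModelSpec:
    """Phenotype column, fixed-effect columns and chain settings."""

    phenotype: str
    fixed_effects: tuple = ("breed", "discipline", "timepoint")
    iterations: int = 30_000
    burnin: int = 2_000
    thin: int = 10
    #: scaled-inverse-chi-square prior df; None (default) = flat prior on
    #: each variance component, which keeps the null m2 = 0 estimable
    nu: float = None
    #: fraction of var(y) allotted to the prior scales when nu is set
    prior_var_fraction: float = 0.5

    def __post_init__(self):
        if self.iterations <= self.burnin:
            raise ValidationError("iterations must exceed burnin")
        if self.nu is not None and self.nu <= 0:
            raise ValidationError("nu must be positive")
        if self.prior_var_fraction <= 0:
            raise ValidationError("prior_var_fraction must be positive")


@dataclass
class PosteriorDraws:
    """Retained post-burn-in draws and chain metadata."""

    draws: pd.DataFrame          # beta_*, sigma2_m, [sigma2_H,] sigma2_e
    burnin: int
    thin: int
    diagnostics: dict = field(default_factory=dict)

    def m2(self, definition: str = "total") -> pd.Series:
        s_m = self.draws["sigma2_m"]
        s_e = self.draws["sigma2_e"]
        s_h = self.draws.get("sigma2_H", pd.Series(0.0, index=self.draws.index))
        if definition == "total":
            return (s_m / (s_m + s_h + s_e)).rename("m2")
        if definition == "exclusive":
            return (s_m / (s_h + s_e)).rename("m2")
        raise ValidationError(f"unknown m2 definition {definition!r}")


def _design_matrix(data: pd.DataFrame, fixed_effects) -> tuple:
    blocks, names = [np.ones((len(data), 1))], ["intercept"]
    for col in fixed_effects:
        series = data[col]
        if pd.api.types.is_numeric_dtype(series):
            blocks.append(series.to_numpy(dtype=float)[:, None])
            names.append(col)
        else:
            dummies = pd.get_dummies(series.astype("category"), drop_first=True)
            blocks.append(dummies.to_numpy(dtype=float))
            names.extend(f"{col}[{lvl}]" for lvl in dummies.columns)
    x = np.hstack(blocks)
    _, r = np.linalg.qr(x)
    bad = np.abs(np.diag(r)) < 1e-10
    if bad.any():
        aliased = [names[i] for i in np.flatnonzero(bad)]
        raise ValidationError(f"rank-deficient design; aliased columns: {aliased}")
    return x, names


def _signed_eigh(m: np.ndarray) -> tuple:
    """Eigendecomposition with a permutation-invariant sign convention:
    each eigenvector's largest-magnitude entry is positive."""
    vals, vecs = np.linalg.eigh(m)
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vals, vecs * signs


def _scaled_inv_chi2(rng, df, scale_sum):
    return scale_sum / rng.chisquare(df)


def gibbs_fit(
    spec: MixedModelSpec,
    data: pd.DataFrame,
    kernel: MicrobialKernel,
    kinship: pd.DataFrame = None,
    host_col: str = "host_id",
    seed=None,
    rotate: bool = True,
) -> PosteriorDraws:
    """Gibbs sampler for the microbiability mixed model.

    Without a kinship matrix the model is rotated into the eigenbasis of
    M, where the microbial-effect full conditional is diagonal and each
    sweep costs O(n). With a kinship the sampler stays in the original
    basis and draws host effects from their joint conditional. ``rotate``
    exists to cross-check the two routes; results agree within
    Monte-Carlo error.
    """
    ids = kernel.ids
    data = data.loc[ids]
    y = data[spec.phenotype].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValidationError(
            f"phenotype {spec.phenotype!r} has missing values; fit on complete cases"
        )
    x, beta_names = _design_matrix(data, spec.fixed_effects)
    n, p = x.shape
    m = kernel.matrix.to_numpy()
    d, u = _signed_eigh(m)
    d = np.clip(d, 0.0, None)
    keep = d > max(d.max(), 1.0) * 1e-10
    r_rank = int(keep.sum())
    if r_rank == 0:
        raise ValidationError("kernel has no positive eigenvalues")

    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise ValidationError("phenotype has zero variance")
    ncomp = 2 + (kinship is not None)
    flat_prior = spec.nu is None
    nu0 = 0.0 if flat_prior else spec.nu
    s2_prior = 0.0 if flat_prior else spec.prior_var_fraction * vary / ncomp
    # flat prior on sigma2: posterior df = (effects - 2); needs enough effects
    df_shift = -2.0 if flat_prior else nu0
    if flat_prior and (r_rank < 5 or n < 5):
        raise ValidationError(
            "flat variance prior needs >= 5 informative components; "
            "set nu for a proper scaled-inverse-chi-square prior"
        )

    use_rotation = rotate and kinship is None
    rng = np.random.default_rng(seed)

    if use_rotation:
        yt = u.T @ y
        xt = u.T @ x
    else:
        yt, xt = y, x

    xtx = xt.T @ xt
    xtx_inv = np.linalg.inv(xtx)
    l_beta = np.linalg.cholesky(xtx_inv)

    z_host = None
    k_inv = None
    if kinship is not None:
        hosts = pd.unique(data[host_col])
        host_idx = pd.Series(range(len(hosts)), index=hosts)
        z_host = np.zeros((n, len(hosts)))
        z_host[np.arange(n), host_idx[data[host_col]].to_numpy()] = 1.0
        k_mat = kinship.loc[hosts, hosts].to_numpy()
        k_vals, k_vecs = _signed_eigh(k_mat)
        if k_vals.min() <= 1e-10:
            raise ValidationError("kinship matrix is singular; add jitter")
        k_inv = k_vecs @ np.diag(1.0 / k_vals) @ k_vecs.T
        ztz = z_host.T @ z_host

    # state
    sigma2_m = sigma2_e = vary / ncomp
    sigma2_h = vary / ncomp if kinship is not None else 0.0
    beta = np.linalg.lstsq(xt, yt, rcond=None)[0]
    a = np.zeros(n)           # microbial effect in eigen coords
    g = np.zeros(z_host.shape[1]) if kinship is not None else None

    d_kept = d[keep]
    n_draws = (spec.iterations - spec.burnin) // spec.thin
    cols = [f"beta_{bn}" for bn in beta_names] + ["sigma2_m"]
    if kinship is not None:
        cols.append("sigma2_H")
    cols.append("sigma2_e")
    out = np.empty((n_draws, len(cols)))
    stored = 0

    for it in range(spec.iterations):
        if use_rotation:
            u_m_contrib = a
        else:
            u_m_contrib = u @ a
        g_contrib = z_host @ g if kinship is not None else 0.0

        # fixed effects (flat prior)
        resid = yt - u_m_contrib - g_contrib
        beta_hat = xtx_inv @ (xt.T @ resid)
        beta = beta_hat + np.sqrt(sigma2_e) * (l_beta @ rng.standard_normal(p))

        # microbial effect in the eigenbasis of M (diagonal conditional)
        resid = yt - xt @ beta - g_contrib
        rt = resid if use_rotation else u.T @ resid
        v = 1.0 / (1.0 / sigma2_e + 1.0 / (d_kept * sigma2_m))
        mean = v * rt[keep] / sigma2_e
        a = np.zeros(n)
        a[keep] = mean + np.sqrt(v) * rng.standard_normal(r_rank)

        # sigma2_m | a
        quad = float(np.sum(a[keep] ** 2 / d_kept))
        sigma2_m = _scaled_inv_chi2(rng, df_shift + r_rank, nu0 * s2_prior + quad)

        if kinship is not None:
            u_m_contrib = u @ a
            resid = y - x @ beta - u_m_contrib
            prec = ztz / sigma2_e + k_inv / sigma2_h
            l_prec = np.linalg.cholesky(prec)
            rhs = z_host.T @ resid / sigma2_e
            mu_g = np.linalg.solve(prec, rhs)
            g = mu_g + np.linalg.solve(l_prec.T, rng.standard_normal(len(mu_g)))
            quad_g = float(g @ k_inv @ g)
            sigma2_h = _scaled_inv_chi2(rng, df_shift + len(g), nu0 * s2_prior + quad_g)
            g_contrib = z_host @ g

        # residual variance
        if use_rotation:
            eps = yt - xt @ beta - a
        else:
            eps = yt - xt @ beta - (u @ a) - g_contrib
        sigma2_e = _scaled_inv_chi2(rng, df_shift + n, nu0 * s2_prior + float(eps @ eps))

        if it >= spec.burnin and (it - spec.burnin) % spec.thin == 0 and stored < n_draws:
            row = list(beta) + [sigma2_m]
            if kinship is not None:
                row.append(sigma2_h)
            row.append(sigma2_e)
            out[stored] = row
            stored += 1

    draws = pd.DataFrame(out[:stored], columns=cols)
    result = PosteriorDraws(draws, spec.burnin, spec.thin)
    result.diagnostics = _chain_diagnostics(result)
    return result


def _chain_diagnostics(draws: PosteriorDraws) -> dict:
    """Split-chain potential scale reduction and effective sample size of
    the m2 chain (single chain split in half)."""
    m2 = draws.m2("total").to_numpy()
    half = len(m2) // 2
    if half < 4:
        return {"ess": float(len(m2)), "rhat": np.nan}
    import arviz as az

    split = m2[: 2 * half].reshape(2, half)
    ess = float(az.ess(split))
    rhat = float(az.rhat(split))
    if ess < 100:
        logger.warning("low effective sample size for m2 chain: %.0f", ess)
    return {"ess": ess, "rhat": rhat}


def m2_summary(draws: PosteriorDraws, definition: str = "total", ci: float = 0.95) -> dict:
    """Posterior mean, SD and central credible interval of m2."""
    if len(draws.draws) == 0:
        raise ValidationError("no retained draws")
    if definition not in M2_DEFINITIONS:
        raise ValidationError(f"definition must be one of {M2_DEFINITIONS}")
    m2 = draws.m2(definition)
    alpha = (1 - ci) / 2
    return {
        "mean": float(m2.mean()),
        "sd": float(m2.std(ddof=1)),
        "ci_lo": float(m2.quantile(alpha)),
        "ci_hi": float(m2.quantile(1 - alpha)),
    }


def run_microbiability(
    table: FeatureTable,
    metadata: pd.DataFrame,
    phenotypes,
    fixed_effects=("breed", "discipline", "timepoint"),
    kinship: pd.DataFrame = None,
    host_col: str = "host_id",
    iterations: int = 30_000,
    burnin: int = 2_000,
    thin: int = 10,
    definition: str = "total",
    css_quantile: float = 0.5,
    seed=None,
) -> pd.DataFrame:
    """CSS-log -> kernel -> Gibbs fit per phenotype -> m2 report.

    Returns one row per phenotype with the posterior mean and SD of m2
    expressed as percentages of phenotypic variance, the 95% credible
    interval, effective sample size and split-chain R-hat. Phenotypes
    with missing values are fitted on complete cases (count logged).
    """
    css = css_log(table, quantile=css_quantile)
    kernel = build_kernel(css)
    metadata = metadata.loc[kernel.ids]
    seeds = np.random.SeedSequence(seed).spawn(len(list(phenotypes)))
    rows = []
    for phen, ss in zip(phenotypes, seeds):
        mask = metadata[phen].notna()
        if (~mask).sum():
            logger.info("phenotype %s: %d sample(s) dropped for missing values",
                        phen, int((~mask).sum()))
        sub_ids = list(metadata.index[mask])
        sub_kernel = kernel.subset(sub_ids)
        spec = MixedModelSpec(
            phenotype=phen, fixed_effects=tuple(fixed_effects),
            iterations=iterations, burnin=burnin, thin=thin,
        )
        draws = gibbs_fit(
            spec, metadata.loc[sub_ids], sub_kernel,
            kinship=kinship, host_col=host_col,
            seed=ss.generate_state(1)[0] % (2**31),
        )
        summ = m2_summary(draws, definition)
        rows.append(
            {
                "phenotype": phen,
                "m2_mean_pct": 100 * summ["mean"],
                "m2_sd_pct": 100 * summ["sd"],
                "ci95_lo_pct": 100 * summ["ci_lo"],
                "ci95_hi_pct": 100 * summ["ci_hi"],
                "ess": draws.diagnostics["ess"],
                "rhat": draws.diagnostics["rhat"],
                "n_used": len(sub_ids),
            }
        )
    return pd.DataFrame(rows).set_index("phenotype")
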