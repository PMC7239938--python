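"""Synthetic gut-microbiota cohort with known ground truth.

Emulates a two-visit cohort of ~185 hosts sampled at 10,000-60,000 reads:
a stable prevalent core plus high-turnover rare taxa, host-specific
signatures that make between-host divergence exceed within-host
divergence, a global time shift, categorical host factors (breed,
discipline, bedding), a block-by-breed kinship, and continuous
phenotypes generated under the microbiability mixed model with a
configurable true m2. Everything needed for parameter-recovery tests is
returned as a :class:`CohortTruth`.

Counts are Dirichlet-multinomial: a log-scale composition per sample is
softmax-normalized, perturbed by a Dirichlet draw with concentration
``overdispersion`` and sampled at a uniform random depth. Core taxa get
attenuated host-to-host variability (the prevalent genera are the stable
ones; the rare ones carry the turnover), which keeps them above the
core-detection rule.

One global seed expands into independent streams for counts, tree and
phenotypes so each stage can be regenerated on its own.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .feature_table import FeatureTable, ValidationError, write_table, write_taxonomy
from .microbiability import build_kernel, _signed_eigh
from .feature_table import css_log

_PHYLA = (
    "Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
    "Spirochaetes", "Verrucomicrobia", "Fibrobacteres", "Tenericutes",
)


@dataclass
class CohortConfig:
    n_hosts: int = 185
    n_timepoints: int = 2
    n_taxa: int = 200
    n_core_taxa: int = 30
    depth_range: tuple = (10_000, 60_000)
    #: log-scale SD of host-specific taxon intercepts (rare taxa)
    host_sd: float = 1.0
    #: multiplier on host_sd for core taxa (prevalent taxa are stable)
    core_stability: float = 0.35
    #: log-scale SD of the per-taxon T2 shift
    time_shift_sd: float = 0.3
    #: probability a rare taxon flips presence between time points
    rare_turnover: float = 0.3
    #: probability a rare taxon is present in a host at baseline
    rare_prevalence: float = 0.4
    #: Dirichlet concentration; np.inf disables compositional noise
    overdispersion: float = 150.0
    n_breeds: int = 4
    n_disciplines: int = 3
    n_beddings: int = 2
    fixed_effect_sizes: dict = field(
        default_factory=lambda: {"breed": 0.3, "discipline": 0.3, "timepoint": 0.2}
    )
    true_m2: float = 0.25
    true_h2: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.true_m2 <= 1:
            raise ValidationError("true_m2 must be in [0, 1]")
        if not 0 <= self.true_h2 < 1:
            raise ValidationError("true_h2 must be in [0, 1)")
        if self.true_m2 + self.true_h2 >= 1:
            raise ValidationError("true_m2 + true_h2 must be < 1")
        if self.n_core_taxa > self.n_taxa:
            raise ValidationError("n_core_taxa must be <= n_taxa")
        if self.depth_range[0] < 1:
            raise ValidationError("depth_range minimum must be >= 1")
        if self.n_hosts < 1 or self.n_timepoints < 1:
            raise ValidationError("n_hosts and n_timepoints must be >= 1")
        if not 0 <= self.rare_turnover <= 1:
            raise ValidationError("rare_turnover must be in [0, 1]")

    def streams(self):
        """Independent child seeds for (counts, tree, phenotypes)."""
        return np.random.SeedSequence(self.seed).spawn(3)


@dataclass
class CohortTruth:
    """Generator ground truth used by recovery tests."""

    core_taxa: list
    host_signatures: pd.DataFrame          # hosts x taxa log offsets
    time_effects: pd.Series                # per-taxon T2 log shift
    presence_t1: pd.DataFrame = None       # hosts x rare taxa
    presence_t2: pd.DataFrame = None
    m2_true: float = None
    h2_true: float = None
    beta_true: dict = None
    u_microbial: pd.DataFrame = None       # samples x phenotypes
    u_genetic: pd.DataFrame = None


def _taxon_ids(n):
    return [f"taxon_{i + 1:04d}" for i in range(n)]


def _host_ids(n):
    return [f"H{i + 1:03d}" for i in range(n)]


def _make_taxonomy(taxon_ids, rng) -> pd.Series:
    lineages = {}
    for t in taxon_ids:
        phylum = _PHYLA[rng.integers(len(_PHYLA))]
        fam = f"{phylum[:4]}aceae_{rng.integers(1, 9)}"
        genus = f"g_{t.split('_')[1]}"
        lineages[t] = ";".join(
            ["Bacteria", phylum, f"{phylum[:4]}ia", f"{phylum[:4]}ales", fam, genus]
        )
    return pd.Series(lineages, name="lineage")


def simulate_counts(config: CohortConfig):
    """Generate the samples x taxa count table and its ground truth.

    Returns ``(FeatureTable, CohortTruth)``. Sample ids are
    ``<host>_<timepoint>``; the first ``n_core_taxa`` taxa are the
    designated core.
    """
    rng = np.random.default_rng(config.streams()[0])
    taxa = _taxon_ids(config.n_taxa)
    hosts = _host_ids(config.n_hosts)
    core = taxa[: config.n_core_taxa]
    n_rare = config.n_taxa - config.n_core_taxa

    # log-scale base composition: abundant stable core, sparse rare tail;
    # core levels chosen so the core accounts for most of the reads
    base = np.empty(config.n_taxa)
    base[: config.n_core_taxa] = rng.uniform(np.log(0.015), np.log(0.05),
                                             config.n_core_taxa)
    base[config.n_core_taxa:] = np.log(8e-4) + rng.normal(0, 1.0, n_rare)

    sd = np.full(config.n_taxa, config.host_sd)
    sd[: config.n_core_taxa] *= config.core_stability
    host_sig = rng.normal(0.0, 1.0, (config.n_hosts, config.n_taxa)) * sd
    time_eff = rng.normal(0.0, config.time_shift_sd, config.n_taxa)
    time_eff[: config.n_core_taxa] *= config.core_stability

    pres_t1 = rng.random((config.n_hosts, n_rare)) < config.rare_prevalence
    flip = rng.random((config.n_hosts, n_rare)) < config.rare_turnover
    pres_t2 = np.where(flip, ~pres_t1, pres_t1)

    timepoints = [f"T{t + 1}" for t in range(config.n_timepoints)]
    rows, sample_ids = [], []
    for h, host in enumerate(hosts):
        for t, tp in enumerate(timepoints):
            logit = base + host_sig[h] + (time_eff if t > 0 else 0.0)
            mask = np.ones(config.n_taxa, dtype=bool)
            pres = pres_t1[h] if t == 0 else pres_t2[h]
            mask[config.n_core_taxa:] = pres
            weights = np.where(mask, np.exp(logit), 0.0)
            p = weights / weights.sum()
            depth = int(rng.integers(config.depth_range[0],
                                     config.depth_range[1] + 1))
            if np.isinf(config.overdispersion):
                comp = p
            else:
                comp = np.zeros(config.n_taxa)
                alpha = config.overdispersion * p[mask]
                comp[mask] = rng.dirichlet(np.maximum(alpha, 1e-12))
            rows.append(rng.multinomial(depth, comp))
            sample_ids.append(f"{host}_{tp}")

    counts = pd.DataFrame(np.array(rows), index=sample_ids, columns=taxa)
    taxonomy = _make_taxonomy(taxa, rng)
    truth = CohortTruth(
        core_taxa=core,
        host_signatures=pd.DataFrame(host_sig, index=hosts, columns=taxa),
        time_effects=pd.Series(time_eff, index=taxa, name="time_effect"),
        presence_t1=pd.DataFrame(pres_t1, index=hosts, columns=taxa[config.n_core_taxa:]),
        presence_t2=pd.DataFrame(pres_t2, index=hosts, columns=taxa[config.n_core_taxa:]),
        m2_true=config.true_m2,
        h2_true=config.true_h2,
    )
    return FeatureTable(counts, taxonomy), truth


def simulate_tree(n_taxa: int, seed=None, taxon_ids=None) -> str:
    """Rooted binary pure-birth tree over the taxa, as a newick string.

    Leaf labels match the feature-table taxon ids; all branch lengths are
    strictly positive.
    """
    if n_taxa < 2:
        raise ValidationError("a tree needs n_taxa >= 2")
    ids = taxon_ids if taxon_ids is not None else _taxon_ids(n_taxa)
    if len(ids) != n_taxa:
        raise ValidationError("taxon_ids length must equal n_taxa")
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(None if seed is None else int(seed)),
    )
    for leaf, name in zip(tree.leaf_node_iter(), ids):
        leaf.taxon.label = name
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.length <= 0:
            edge.length = 1e-6
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return newick


def assign_host_attributes(config: CohortConfig, hosts, rng) -> pd.DataFrame:
    """Breed / discipline / bedding per host (uniform categorical)."""
    return pd.DataFrame(
        {
            "breed": [f"breed_{rng.integers(config.n_breeds) + 1}" for _ in hosts],
            "discipline": [f"discipline_{rng.integers(config.n_disciplines) + 1}"
                           for _ in hosts],
            "bedding": [f"bedding_{rng.integers(config.n_beddings) + 1}" for _ in hosts],
        },
        index=pd.Index(hosts, name="host_id"),
    )


def breed_kinship(breeds: pd.Series, within: float = 0.25) -> pd.DataFrame:
    """Block-diagonal kinship: 1 on the diagonal, ``within`` between hosts
    of the same breed, 0 otherwise."""
    same = np.equal.outer(breeds.to_numpy(), breeds.to_numpy()).astype(float)
    k = within * same
    np.fill_diagonal(k, 1.0)
    return pd.DataFrame(k, index=breeds.index, columns=breeds.index)


def _level_effects(levels, size):
    """Centered, evenly spread effects over category levels."""
    levels = sorted(levels)
    grid = np.linspace(-1.0, 1.0, len(levels)) if len(levels) > 1 else np.zeros(1)
    return {lvl: float(size * g) for lvl, g in zip(levels, grid)}


def simulate_phenotypes(
    table: FeatureTable,
    truth: CohortTruth,
    config: CohortConfig,
    names=("behaviour",),
) -> pd.DataFrame:
    """Continuous phenotypes under the microbiability model, plus bounded
    behaviour-frequency versions.

    y = mu + X beta + u_m + u_g + e with u_m drawn from N(0, sigma2_m M)
    using the kernel M of the *generated* table, and variances scaled so
    sigma2_m : sigma2_H : sigma2_e = true_m2 : true_h2 : rest. Each
    phenotype ``name`` gets a latent column ``name`` and a [0, 1] column
    ``name_freq`` through a logistic link (the scan-frequency analogue).

    Fills ``truth.u_microbial``, ``truth.u_genetic`` and ``truth.beta_true``.
    """
    if list(table.sample_ids) != list(
        f"{h}_{t}" for h in truth.host_signatures.index
        for t in (f"T{i+1}" for i in range(config.n_timepoints))
    ):
        raise ValidationError("table rows do not align with truth")
    rng = np.random.default_rng(config.streams()[2])
    hosts = list(truth.host_signatures.index)
    sample_ids = table.sample_ids
    host_of = [s.rsplit("_", 1)[0] for s in sample_ids]
    tp_of = [s.rsplit("_", 1)[1] for s in sample_ids]

    attrs = assign_host_attributes(config, hosts, rng)
    kinship = breed_kinship(attrs["breed"])

    sigma2_m = config.true_m2
    sigma2_h = config.true_h2
    sigma2_e = 1.0 - sigma2_m - sigma2_h

    kernel = build_kernel(css_log(table))
    m = kernel.matrix.loc[sample_ids, sample_ids].to_numpy()
    d, u = _signed_eigh(m)
    d = np.clip(d, 0.0, None)
    k_vals, k_vecs = _signed_eigh(kinship.to_numpy())
    k_vals = np.clip(k_vals, 0.0, None)

    beta_true = {
        "breed": _level_effects(attrs["breed"].unique(),
                                config.fixed_effect_sizes.get("breed", 0.0)),
        "discipline": _level_effects(attrs["discipline"].unique(),
                                     config.fixed_effect_sizes.get("discipline", 0.0)),
        "timepoint": {f"T{i+1}": config.fixed_effect_sizes.get("timepoint", 0.0) * i
                      for i in range(config.n_timepoints)},
    }
    xb = np.array(
        [
            beta_true["breed"][attrs.loc[h, "breed"]]
            + beta_true["discipline"][attrs.loc[h, "discipline"]]
            + beta_true["timepoint"][t]
            for h, t in zip(host_of, tp_of)
        ]
    )

    meta = pd.DataFrame(
        {
            "host_id": host_of,
            "timepoint": tp_of,
            "breed": [attrs.loc[h, "breed"] for h in host_of],
            "discipline": [attrs.loc[h, "discipline"] for h in host_of],
            "bedding": [attrs.loc[h, "bedding"] for h in host_of],
        },
        index=pd.Index(sample_ids, name="sample"),
    )

    u_m_all, u_g_all = {}, {}
    host_pos = {h: i for i, h in enumerate(hosts)}
    for name in names:
        if sigma2_m > 0:
            u_m = u @ (np.sqrt(d * sigma2_m) * rng.standard_normal(len(d)))
        else:
            u_m = np.zeros(len(sample_ids))
        if sigma2_h > 0:
            g = k_vecs @ (np.sqrt(k_vals * sigma2_h) * rng.standard_normal(len(k_vals)))
        else:
            g = np.zeros(len(hosts))
        u_g = np.array([g[host_pos[h]] for h in host_of])
        eps = rng.normal(0.0, np.sqrt(sigma2_e), len(sample_ids))
        y = xb + u_m + u_g + eps
        meta[name] = y
        y_std = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
        meta[f"{name}_freq"] = 1.0 / (1.0 + np.exp(-y_std))
        u_m_all[name] = u_m
        u_g_all[name] = u_g

    truth.beta_true = beta_true
    truth.u_microbial = pd.DataFrame(u_m_all, index=sample_ids)
    truth.u_genetic = pd.DataFrame(u_g_all, index=sample_ids)
    return meta


@dataclass
class Cohort:
    config: CohortConfig
    table: FeatureTable
    truth: CohortTruth
    metadata: pd.DataFrame
    tree: str
    kinship: pd.DataFrame


def simulate_cohort(config: CohortConfig, phenotype_names=("behaviour",)) -> Cohort:
    """Run the full generator: counts, tree, phenotypes, kinship."""
    table, truth = simulate_counts(config)
    tree = simulate_tree(
        config.n_taxa,
        seed=config.streams()[1].generate_state(1)[0] % (2**31),
        taxon_ids=table.taxon_ids,
    )
    metadata = simulate_phenotypes(table, truth, config, names=phenotype_names)
    hosts = list(truth.host_signatures.index)
    rng = np.random.default_rng(config.streams()[2])
    attrs = assign_host_attributes(config, hosts, rng)
    kinship = breed_kinship(attrs["breed"])
    return Cohort(config, table, truth, metadata, tree, kinship)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write counts, taxonomy, metadata, tree, kinship and truth JSON with
    deterministic formatting."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(cohort.table, outdir / "counts.tsv")
    write_taxonomy(cohort.table.taxonomy, outdir / "taxonomy.tsv")
    cohort.metadata.to_csv(outdir / "metadata.tsv", sep="\t",
                           float_format="%.10g", index_label="sample")
    (outdir / "tree.nwk").write_text(cohort.tree + "\n")
    cohort.kinship.to_csv(outdir / "kinship.tsv", sep="\t",
                          float_format="%.10g", index_label="host_id")
    truth = {
        "core_taxa": cohort.truth.core_taxa,
        "m2_true": cohort.truth.m2_true,
        "h2_true": cohort.truth.h2_true,
        "beta_true": cohort.truth.beta_true,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cohort.config).items()},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
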