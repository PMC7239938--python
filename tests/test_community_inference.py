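import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from skbio.stats.distance import anosim as sk_anosim, permanova as sk_permanova

import microvar as mv
from microvar.community_inference import Ordination, _permutation_indices
from microvar.feature_table import NormalizedTable, ValidationError
from conftest import euclidean_dm


# ---------------------------------------------------------------------- permanova

def test_permanova_effect_sizes_sum_to_one(small_cohort):
    dm = mv.bray_curtis(mv.relative_abundance(small_cohort.table))
    res = mv.permanova(dm, small_cohort.metadata,
                       terms=["breed", "timepoint"], n_perm=49, seed=0)
    terms_plus_resid = res.drop(index="Total")["R2"].sum()
    assert np.isclose(terms_plus_resid, 1.0, atol=1e-10)


def test_permanova_statistic_matches_skbio_one_way():
    rng = np.random.default_rng(2)
    dm = euclidean_dm(rng.normal(size=(18, 4)))
    groups = pd.Series(["a"] * 9 + ["b"] * 9, index=dm.ids, name="g")
    ours = mv.permanova(dm, groups.to_frame(), terms=["g"], n_perm=9, seed=0)
    sk = sk_permanova(dm, groups.to_numpy(), permutations=9)
    assert np.isclose(ours.loc["g", "pseudo_F"], sk["test statistic"], atol=1e-9)


def test_permanova_duplicated_groups_give_null_f():
    pts = np.array([[0, 0], [1, 0], [2, 1], [0, 0], [1, 0], [2, 1]], float)
    dm = euclidean_dm(pts)
    design = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3}, index=dm.ids)
    res = mv.permanova(dm, design, terms=["g"], n_perm=99, seed=0)
    assert res.loc["g", "pseudo_F"] < 1e-8
    assert res.loc["g", "p_value"] > 0.9


def test_permanova_single_level_term_rejected():
    dm = euclidean_dm(np.eye(4))
    design = pd.DataFrame({"g": ["x"] * 4}, index=dm.ids)
    with pytest.raises(ValidationError):
        mv.permanova(dm, design, terms=["g"], n_perm=9, seed=0)


def test_permutations_respect_strata():
    strata = np.array(["h1", "h1", "h2", "h2", "h3", "h3"])
    perms = _permutation_indices(6, 50, np.random.default_rng(0), strata)
    for perm in perms:
        assert (strata[perm] == strata).all()


# ---------------------------------------------------------------------- anosim

def _anosim_brute(d, labels):
    """Direct-definition ANOSIM R: midranked pair distances, averaged by
    within/between status."""
    n = len(labels)
    pairs, status = [], []
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append(d[i, j])
            status.append(labels[i] == labels[j])
    ranks = sps.rankdata(pairs)
    rw = np.mean([r for r, s in zip(ranks, status) if s])
    rb = np.mean([r for r, s in zip(ranks, status) if not s])
    return (rb - rw) / (n * (n - 1) / 4)


def test_anosim_perfect_separation():
    a = np.zeros((6, 6))
    a[:3, 3:] = 1.0
    a[3:, :3] = 1.0
    a[:3, :3] = 0.1
    a[3:, 3:] = 0.1
    np.fill_diagonal(a, 0)
    from skbio.stats.distance import DistanceMatrix
    dm = DistanceMatrix(a, ids=[f"s{i}" for i in range(6)])
    res = mv.anosim(dm, pd.Series(["x"] * 3 + ["y"] * 3, index=dm.ids),
                    n_perm=99, seed=0)
    assert np.isclose(res.observed, 1.0)


def test_anosim_matches_brute_force_and_skbio():
    rng = np.random.default_rng(5)
    for rep in range(5):
        dm = euclidean_dm(rng.normal(size=(8, 3)))
        labels = np.array(["a", "a", "a", "b", "b", "b", "b", "a"])
        res = mv.anosim(dm, pd.Series(labels, index=dm.ids), n_perm=9, seed=rep)
        brute = _anosim_brute(dm.data, labels)
        assert np.isclose(res.observed, brute, atol=1e-12)
        sk = sk_anosim(dm, labels, permutations=9)
        assert np.isclose(res.observed, sk["test statistic"], atol=1e-12)
        assert -1 <= res.observed <= 1


def test_anosim_null_expectation_near_zero():
    rng = np.random.default_rng(9)
    dm = euclidean_dm(rng.normal(size=(20, 3)))
    stats = []
    for rep in range(50):
        labels = rng.permutation(["a"] * 10 + ["b"] * 10)
        stats.append(mv.anosim(dm, pd.Series(labels, index=dm.ids),
                               n_perm=1, seed=rep).observed)
    assert abs(np.mean(stats)) < 0.05


# ---------------------------------------------------------------------- simper

def _simper_table(rows, groups):
    values = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))],
                          columns=[f"t{j}" for j in range(len(rows[0]))])
    nt = NormalizedTable(values.astype(float), "relative")
    return nt, pd.Series(groups, index=values.index)


def test_simper_single_taxon_full_contribution():
    nt, groups = _simper_table([[5], [3], [9], [1]], ["a", "a", "b", "b"])
    res = mv.simper(nt, groups)
    assert np.isclose(res["contribution"].iloc[0], 1.0)


def test_simper_constant_taxon_zero():
    nt, groups = _simper_table([[5, 2], [5, 4], [5, 9], [5, 1]],
                               ["a", "a", "b", "b"])
    res = mv.simper(nt, groups)
    assert res.loc["t0", "contribution"] == 0


def test_simper_matches_pairwise_hand_computation():
    rows = [[3, 1, 0], [2, 2, 1], [0, 4, 2], [1, 3, 3]]
    nt, groups = _simper_table(rows, ["a", "a", "b", "b"])
    res = mv.simper(nt, groups)
    # brute force over the 4 between-group pairs
    a, b = np.array(rows[:2], float), np.array(rows[2:], float)
    contrib = np.zeros(3)
    for i in range(2):
        for j in range(2):
            denom = (a[i] + b[j]).sum()
            contrib += np.abs(a[i] - b[j]) / denom
    contrib /= 4
    contrib /= contrib.sum()
    for k, t in enumerate(["t0", "t1", "t2"]):
        assert np.isclose(res.loc[t, "contribution"], contrib[k], atol=1e-12)
    assert np.isclose(res["contribution"].sum(), 1.0)
    assert np.isclose(res["cumulative"].iloc[-1], 1.0)


def test_simper_zero_variance_taxon_removal_keeps_ratios():
    rows = [[3, 1, 7], [2, 2, 7], [0, 4, 7], [1, 3, 7]]
    nt, groups = _simper_table(rows, ["a", "a", "b", "b"])
    full = mv.simper(nt, groups)
    reduced_rows = [r[:2] for r in rows]
    nt2, _ = _simper_table(reduced_rows, ["a", "a", "b", "b"])
    # denominators change when a column is dropped, so compare raw ratios
    # of the two varying taxa within each analysis
    ratio_full = full.loc["t0", "contribution"] / full.loc["t1", "contribution"]
    red = mv.simper(nt2, groups)
    ratio_red = red.loc["t0", "contribution"] / red.loc["t1", "contribution"]
    assert np.isclose(ratio_full, ratio_red, rtol=0.2)


def test_simper_requires_two_groups():
    nt, _ = _simper_table([[1], [2]], ["a", "a"])
    with pytest.raises(ValidationError):
        mv.simper(nt, pd.Series(["a", "a"], index=nt.values.index))


# ---------------------------------------------------------------------- nmds

def test_nmds_line_perfectly_representable():
    dm = euclidean_dm(np.arange(12, dtype=float)[:, None])
    ordn = mv.nmds(dm, k=2, n_starts=10, seed=0)
    assert ordn.stress < 0.01
    assert np.allclose(ordn.scores.mean(axis=0), 0, atol=1e-9)


def test_nmds_duplicated_samples_coincide():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(8, 2)) * 2
    pts = np.vstack([pts, pts[0]])  # sample 8 duplicates sample 0
    dm = euclidean_dm(pts)
    ordn = mv.nmds(dm, k=2, n_starts=20, seed=1, max_iter=500)
    d = np.linalg.norm(ordn.scores.iloc[0] - ordn.scores.iloc[8])
    from scipy.spatial.distance import pdist
    spread = pdist(ordn.scores.to_numpy()).mean()
    assert d < 0.01 * spread


def test_nmds_stress_non_increasing():
    rng = np.random.default_rng(7)
    dm = euclidean_dm(rng.normal(size=(15, 5)))
    ordn = mv.nmds(dm, k=2, n_starts=3, seed=0)
    hist = np.array(ordn.stress_history)
    assert (np.diff(hist) <= 1e-8).all()


def test_nmds_too_few_samples():
    dm = euclidean_dm(np.eye(3))
    with pytest.raises(ValidationError):
        mv.nmds(dm, k=2)


# ---------------------------------------------------------------------- envfit

def _ordination(scores):
    df = pd.DataFrame(scores, index=[f"s{i}" for i in range(len(scores))],
                      columns=[f"NMDS{j+1}" for j in range(scores.shape[1])])
    return Ordination(df - df.mean(), stress=0.0, converged=True, k=scores.shape[1])


def test_envfit_axis_covariate_r2_one():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=(20, 2))
    ordn = _ordination(scores)
    meta = pd.DataFrame({"axis1": ordn.scores["NMDS1"]}, index=ordn.scores.index)
    res = mv.fit_covariates(ordn, meta, n_perm=49, seed=0)
    assert np.isclose(res.loc["axis1", "r2"], 1.0)
    assert res.loc["axis1", "p_value"] <= 0.05


def test_envfit_categorical_duplicated_point_sets():
    base = np.array([[0, 0], [4, 0], [0, 3]], float)
    scores = np.vstack([base + 1e-6, base - 1e-6])
    ordn = _ordination(scores)
    meta = pd.DataFrame({"lvl": ["a", "b", "c", "a", "b", "c"]},
                        index=ordn.scores.index)
    res = mv.fit_covariates(ordn, meta, n_perm=49, seed=0)
    assert res.loc["lvl", "r2"] > 0.999


def test_envfit_constant_covariate_warns():
    ordn = _ordination(np.random.default_rng(1).normal(size=(10, 2)))
    meta = pd.DataFrame({"const": np.ones(10)}, index=ordn.scores.index)
    with pytest.warns(UserWarning, match="constant"):
        res = mv.fit_covariates(ordn, meta, n_perm=9, seed=0)
    assert res.loc["const", "r2"] == 0.0


def test_envfit_combined_effect_size_sums_significant():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=(40, 2))
    ordn = _ordination(scores)
    meta = pd.DataFrame(
        {
            "good": ordn.scores["NMDS1"] + 0.05 * rng.normal(size=40),
            "noise": rng.normal(size=40),
        },
        index=ordn.scores.index,
    )
    res = mv.fit_covariates(ordn, meta, n_perm=199, seed=0)
    sig = res[res["p_adjusted"] < 0.05]
    assert np.isclose(res.attrs["combined_r2"], sig["r2"].sum())
    assert "good" in sig.index


# ---------------------------------------------------------------------- deltas

def _meta():
    return pd.DataFrame(
        {
            "host_id": ["h1", "h1", "h2", "h2"],
            "timepoint": ["T1", "T2", "T1", "T2"],
            "breed": ["b1", "b1", "b2", "b2"],
            "weight": [10.0, 12.5, 8.0, 7.0],
        },
        index=["h1_T1", "h1_T2", "h2_T1", "h2_T2"],
    )


def test_delta_hand_computed():
    delta = mv.delta_phenotypes(_meta())
    assert delta.loc["h1", "weight"] == 2.5
    assert delta.loc["h2", "weight"] == -1.0
    assert delta.loc["h1", "breed"] == "b1"  # time-invariant carried through


def test_delta_antisymmetry():
    a = mv.delta_phenotypes(_meta(), order=("T2", "T1"))
    b = mv.delta_phenotypes(_meta(), order=("T1", "T2"))
    assert (a["weight"] == -b["weight"]).all()


def test_delta_missing_pair_dropped():
    meta = _meta().drop(index="h2_T2")
    delta = mv.delta_phenotypes(meta)
    assert list(delta.index) == ["h1"]


# ---------------------------------------------------------------------- cross correlation

def test_cross_correlate_self_correlation():
    rng = np.random.default_rng(0)
    values = pd.DataFrame(rng.random((12, 3)), index=[f"s{i}" for i in range(12)],
                          columns=["t1", "t2", "t3"])
    nt = NormalizedTable(values, "relative")
    meta = pd.DataFrame({"p": values["t1"]}, index=values.index)
    res = mv.cross_correlate(nt, meta)
    assert np.isclose(res.r.loc["t1", "p"], 1.0)


def test_cross_correlate_closed_form_n3():
    x = np.array([1.0, 2.0, 4.0])
    y = np.array([2.0, 1.0, 5.0])
    r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    nt = NormalizedTable(pd.DataFrame({"t": x}, index=list("abc")), "relative")
    meta = pd.DataFrame({"p": y}, index=list("abc"))
    res = mv.cross_correlate(nt, meta)
    assert np.isclose(res.r.loc["t", "p"], r_hand)


def test_cross_correlate_equal_p_bh_fixed_point():
    """Columns that are sign flips of one taxon give identical p-values in
    every cell, so BH leaves them unchanged."""
    rng = np.random.default_rng(1)
    x = rng.random(15)
    values = pd.DataFrame({"t1": x, "t2": -x}, index=[f"s{i}" for i in range(15)])
    nt = NormalizedTable(values, "relative")
    meta = pd.DataFrame({"p": rng.random(15)}, index=values.index)
    res = mv.cross_correlate(nt, meta)
    p = res.p.to_numpy().ravel()
    assert np.allclose(p, p[0])
    assert np.allclose(res.p_adjusted.to_numpy().ravel(), p[0])


def test_cross_correlate_zero_variance_flagged():
    values = pd.DataFrame({"flat": np.ones(6), "ok": np.arange(6.0)},
                          index=[f"s{i}" for i in range(6)])
    nt = NormalizedTable(values, "relative")
    meta = pd.DataFrame({"p": np.arange(6.0)}, index=values.index)
    res = mv.cross_correlate(nt, meta)
    assert np.isnan(res.r.loc["flat", "p"])
    assert np.isnan(res.p_adjusted.loc["flat", "p"])
    assert np.isfinite(res.p_adjusted.loc["ok", "p"])
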