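"""Weighted network modules: adjacency, TOM, clustering, eigengenes,
module membership."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import heartnet as hn
from heartnet.wgcna import (
    ModuleAssignment,
    WeightedNetParams,
    _eigengene,
    detect_weighted_modules,
    module_membership,
    soft_adjacency,
    topological_overlap,
)

from conftest import study_from_matrix


def test_soft_adjacency_power_and_constant_handling(timecourse_conditions):
    x = np.linspace(0, 5, 15)
    mat = np.vstack([x, 2 * x + 1, np.full(15, 4.0)])
    study = study_from_matrix(mat, timecourse_conditions)
    params = WeightedNetParams(beta=10, correlation="pearson")
    a = soft_adjacency(study, params)
    assert a.loc["g0", "g1"] == pytest.approx(1.0)  # |cor| = 1 -> 1 for any beta
    assert a.loc["g0", "g2"] == 0.0                 # constant gene -> 0
    assert np.all(np.diag(a.values) == 0.0)
    # raising beta shrinks any |cor| < 1 adjacency
    rng = np.random.default_rng(0)
    mat2 = rng.normal(size=(5, 15))
    study2 = study_from_matrix(mat2, timecourse_conditions)
    a_lo = soft_adjacency(study2, WeightedNetParams(beta=6, correlation="pearson")).values
    a_hi = soft_adjacency(study2, WeightedNetParams(beta=10, correlation="pearson")).values
    off = ~np.eye(5, dtype=bool)
    assert np.all(a_hi[off] <= a_lo[off] + 1e-15)


def test_tom_matches_triple_loop_oracle():
    rng = np.random.default_rng(6)
    a = rng.uniform(0, 1, size=(6, 6))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    tom = topological_overlap(a)
    k = a.sum(axis=1)
    for i in range(6):
        for j in range(6):
            if i == j:
                assert tom[i, j] == 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(6))
            expected = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
            assert tom[i, j] == pytest.approx(expected, abs=1e-12)


def test_tom_edge_cases():
    # isolated pair with a_ij = 1: TOM = (0 + 1) / (1 + 1 - 1) = 1
    pair = np.array([[0.0, 1.0], [1.0, 0.0]])
    assert topological_overlap(pair)[0, 1] == pytest.approx(1.0)
    # no direct link, no shared neighbours -> 0
    empty = np.zeros((3, 3))
    assert topological_overlap(empty)[0, 1] == 0.0


def test_tom_bounded_on_random_adjacencies():
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(3, 12))
        a = rng.uniform(0, 1, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(a)
        assert np.all(tom >= 0.0) and np.all(tom <= 1.0)


def _block_study(seed, n_block=30, n_noise=40, rho=0.9):
    cfg = hn.SimulationConfig(
        n_genes=n_block * 2 + n_noise,
        seed=seed,
        module_spec=[hn.ModuleSpec(n_block, rho), hn.ModuleSpec(n_block, rho)],
        noise_sd=0.3,
    )
    return hn.generate_timecourse_study(cfg)


def test_two_block_recovery_ari():
    """Planted two-block design: adjusted Rand index >= 0.8 over 20 seeds."""
    aris = []
    for seed in range(20):
        study, truth = _block_study(seed)
        asg = detect_weighted_modules(study, WeightedNetParams(min_module_size=20))
        planted = [truth.module_membership.get(g.split("_")[0], 0) for g in asg.labels.index]
        aris.append(adjusted_rand_score(planted, asg.labels.values))
    assert np.mean(aris) >= 0.8


def test_identical_blocks_are_merged(timecourse_conditions):
    # two copies of the same latent signal: eigengene dissimilarity ~ 0
    rng = np.random.default_rng(3)
    latent = rng.normal(size=15)
    block = np.vstack([latent + rng.normal(scale=0.05, size=15) for _ in range(20)])
    mat = np.vstack([block, block])
    study = study_from_matrix(mat, timecourse_conditions)
    asg = detect_weighted_modules(study, WeightedNetParams(min_module_size=5, correlation="pearson"))
    assert len(asg.sizes) == 1
    assert asg.sizes[1] == 40


def test_single_gene_module_membership_is_one(timecourse_conditions):
    rng = np.random.default_rng(9)
    mat = rng.normal(size=(1, 15))
    study = study_from_matrix(mat, timecourse_conditions)
    eg = _eigengene(study.values)
    assert np.linalg.norm(eg) == pytest.approx(1.0)
    asg = ModuleAssignment(
        labels=pd.Series([1], index=["g0"]),
        eigengenes=pd.DataFrame({1: eg}),
        params=WeightedNetParams(min_module_size=1),
    )
    mm = module_membership(study, asg)
    assert mm.loc["g0", "mm"] == pytest.approx(1.0)
    assert mm.loc["g0", "p"] == pytest.approx(0.0, abs=1e-12)


def test_module_membership_p_closed_form(timecourse_conditions):
    rng = np.random.default_rng(5)
    mat = rng.normal(size=(10, 15))
    mat[:6] += rng.normal(size=15) * 1.5  # one correlated block
    study = study_from_matrix(mat, timecourse_conditions)
    asg = detect_weighted_modules(study, WeightedNetParams(min_module_size=3, correlation="spearman"))
    mm = module_membership(study, asg)
    n = 15
    for g, row in mm.dropna().iterrows():
        if abs(row["mm"]) < 1:
            t = row["mm"] * np.sqrt((n - 2) / (1 - row["mm"] ** 2))
            assert row["p"] == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-10)
            # and MM equals the same-type correlation with the eigengene
            rho = stats.spearmanr(study.values.loc[g], asg.eigengenes[row["module"]]).statistic
            assert row["mm"] == pytest.approx(rho, abs=1e-12)


def test_negative_membership_reported_signed(timecourse_conditions):
    rng = np.random.default_rng(8)
    latent = rng.normal(size=15)
    block = np.vstack([latent + rng.normal(scale=0.1, size=15) for _ in range(10)])
    anti = -latent + rng.normal(scale=0.1, size=15)
    study = study_from_matrix(np.vstack([block, anti[None, :]]), timecourse_conditions)
    asg = detect_weighted_modules(study, WeightedNetParams(min_module_size=3, correlation="pearson"))
    mm = module_membership(study, asg)
    # the anti-correlated gene joins the module (unsigned network) with MM < 0
    assert asg.labels.loc["g10"] == 1
    assert mm.loc["g10", "mm"] < -0.8


def test_merging_never_increases_module_count_and_min_size(timecourse_conditions):
    study, _ = _block_study(4, n_block=25, n_noise=30)
    params = WeightedNetParams(min_module_size=15)
    asg = detect_weighted_modules(study, params)
    for lab, size in asg.sizes.items():
        assert size >= params.min_module_size
    assert set(asg.labels.unique()) - {0} == set(asg.sizes)
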