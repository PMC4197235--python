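"""Moderated differential expression: filtering semantics, shrinkage,
FDR adjustment, and agreement with independent oracles."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

import heartnet as hn
from heartnet.diffexpr import fit_f_dist, moderated_linear_model, adjust_fdr

from conftest import study_from_matrix


# ----------------------------------------------------------------------
# Low-expression filter
# ----------------------------------------------------------------------

def test_filter_floor_semantics(timecourse_conditions):
    mat = np.full((3, 15), 3.0)
    mat[0, :] = 5.9          # never above the floor -> removed
    mat[1, 0] = 6.01         # one excursion above -> retained
    mat[2, :] = 8.0          # clearly expressed -> retained
    study = study_from_matrix(mat, timecourse_conditions)
    kept = hn.filter_low_expression(study, floor=6.0)
    assert list(kept.values.index) == ["g1", "g2"]


def test_filter_empty_result_warns(timecourse_conditions):
    study = study_from_matrix(np.full((2, 15), 1.0), timecourse_conditions)
    with pytest.warns(UserWarning):
        out = hn.filter_low_expression(study, floor=6.0)
    assert out.n_features == 0


# ----------------------------------------------------------------------
# Benjamini-Hochberg
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ([0.2], [0.2]),
    ],
)
def test_bh_hand_examples(p, expected):
    # step-up: adj_i = min_{j>=i} m * p_(j) / j, capped at 1
    assert adjust_fdr(p) == pytest.approx(expected)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        adjust_fdr([0.1, 1.2])
    with pytest.raises(ValueError):
        adjust_fdr([-0.1])


# ----------------------------------------------------------------------
# Moderated model vs an independently coded closed-form oracle
# ----------------------------------------------------------------------

def _oracle_moderated(mat, conditions, order):
    """Straight-line re-implementation: explicit loops, brentq-based
    trigamma inversion (different root-finder than the package)."""
    mat = np.asarray(mat, dtype=float)
    control = order[0]
    contrasts = [c for c in order if c != control]
    cols = {c: [j for j, cc in enumerate(conditions) if cc == c] for c in order}

    n_feat = mat.shape[0]
    s2 = np.empty(n_feat)
    df = np.empty(n_feat)
    means = {}
    for i in range(n_feat):
        rss = 0.0
        nobs = 0
        for c in order:
            vals = mat[i, cols[c]]
            m = vals.mean()
            means[(i, c)] = m
            rss += ((vals - m) ** 2).sum()
            nobs += len(vals)
        df[i] = nobs - len(order)
        s2[i] = rss / df[i]

    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        half_d0 = optimize.brentq(lambda x: special.polygamma(1, x) - evar, 1e-8, 1e8)
        d0 = 2.0 * half_d0
        s02 = np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
    else:
        d0, s02 = np.inf, np.exp(e.mean())

    t_stats = {}
    f_stats = np.empty(n_feat)
    for i in range(n_feat):
        s2post = (d0 * s02 + df[i] * s2[i]) / (d0 + df[i]) if np.isfinite(d0) else s02
        bvec, nvec = [], []
        for c in contrasts:
            b = means[(i, c)] - means[(i, control)]
            v = 1.0 / len(cols[c]) + 1.0 / len(cols[control])
            t_stats[(i, c)] = b / np.sqrt(s2post * v)
            bvec.append(b)
            nvec.append(len(cols[c]))
        bvec, nvec = np.asarray(bvec), np.asarray(nvec)
        U = np.diag(1.0 / nvec) + 1.0 / len(cols[control])
        q = bvec @ np.linalg.solve(U, bvec)
        f_stats[i] = q / (len(contrasts) * s2post)
    return d0, s02, t_stats, f_stats


def test_moderated_stats_match_closed_form_oracle(timecourse_conditions):
    rng = np.random.default_rng(42)
    mat = rng.normal(8.0, 1.0, size=(50, 15))
    order = ["control", "1d", "3d", "5d", "7d"]
    study = study_from_matrix(mat, timecourse_conditions, condition_order=order)
    res = moderated_linear_model(study)
    d0, s02, t_oracle, f_oracle = _oracle_moderated(mat, timecourse_conditions, order)
    assert res.d0 == pytest.approx(d0, abs=1e-8)
    assert res.s02 == pytest.approx(s02, rel=1e-10)
    for i in range(50):
        for c in ["1d", "3d", "5d", "7d"]:
            assert res.table[f"t_{c}"].iloc[i] == pytest.approx(t_oracle[(i, c)], abs=1e-10)
        assert res.table["F"].iloc[i] == pytest.approx(f_oracle[i], abs=1e-10)


def test_moderated_stats_match_limma(tmp_path, timecourse_conditions):
    """Cross-check against the reference empirical-Bayes implementation."""
    rng = np.random.default_rng(7)
    mat = rng.normal(8.0, 1.0, size=(40, 15))
    mat[:8, 3:6] += 2.0  # some real effects at 1d
    order = ["control", "1d", "3d", "5d", "7d"]
    study = study_from_matrix(mat, timecourse_conditions, condition_order=order)
    res = moderated_linear_model(study)

    expr = tmp_path / "expr.tsv"
    pd.DataFrame(mat).to_csv(expr, sep="\t", index=False)
    script = tmp_path / "oracle.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{expr}"))
        cond <- factor(rep(c("control","d1","d3","d5","d7"), each=3),
                       levels=c("control","d1","d3","d5","d7"))
        design <- model.matrix(~0 + cond)
        colnames(design) <- levels(cond)
        fit <- lmFit(x, design)
        cm <- makeContrasts(d1-control, d3-control, d5-control, d7-control, levels=design)
        fit2 <- eBayes(contrasts.fit(fit, cm))
        out <- cbind(fit2$t, F=fit2$F, d0=fit2$df.prior, s02=fit2$s2.prior)
        write.table(format(out, digits=12), "{tmp_path / 'limma.tsv'}", sep="\t",
                    quote=FALSE, row.names=FALSE)
    """))
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
    assert res.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
    assert res.s02 == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
    for py_col, r_col in zip(["t_1d", "t_3d", "t_5d", "t_7d"], ref.columns[:4]):
        np.testing.assert_allclose(res.table[py_col].values, ref[r_col].values, rtol=1e-5)
    np.testing.assert_allclose(res.table["F"].values, ref["F"].values, rtol=1e-5)


def test_complete_pooling_limit():
    # identical sample variances carry no spread information: d0 -> inf
    d0, s02 = fit_f_dist(np.full(20, 0.25), np.full(20, 10.0))
    assert np.isinf(d0)
    assert s02 == pytest.approx(0.25, rel=0.2)


def test_zero_residual_df_feature_excluded(timecourse_conditions):
    mat = np.random.default_rng(0).normal(8, 1, size=(5, 15))
    mat[2, 3:] = np.nan  # only the 3 control samples remain -> df = 0
    study = study_from_matrix(mat, timecourse_conditions)
    with pytest.warns(UserWarning):
        res = moderated_linear_model(study)
    assert "g2" not in res.table.index
    assert len(res.table) == 4


def test_threshold_monotonicity_and_subset_invariance(timecourse_conditions):
    rng = np.random.default_rng(5)
    mat = rng.normal(8.0, 0.5, size=(60, 15))
    mat[:10, 3:9] += 3.0
    mat[40:, :] = rng.normal(4.0, 0.2, size=(20, 15))  # below the floor
    study = study_from_matrix(mat, timecourse_conditions)
    filtered = hn.filter_low_expression(study, floor=6.0)
    res = moderated_linear_model(filtered)
    # filter-then-model == model-on-prefiltered-matrix
    res_direct = moderated_linear_model(study.subset_features(filtered.values.index))
    pd.testing.assert_frame_equal(res.table, res_direct.table)
    counts = [len(res.significant_features(t)) for t in (0.0001, 0.01, 0.05, 0.2)]
    assert counts == sorted(counts)


def test_gene_level_bookkeeping(timecourse_conditions):
    rng = np.random.default_rng(1)
    mat = rng.normal(8, 0.3, size=(6, 15))
    mat[0, 3:6] += 4.0
    mat[1, 3:6] += 4.0  # two probes of the same significant gene
    study = study_from_matrix(mat, timecourse_conditions, feature_ids=[f"f{i}" for i in range(6)])
    study.gene_symbols = pd.Series(
        ["geneA", "geneA", "geneB", "geneB", np.nan, "geneC"], index=study.values.index
    )
    res = moderated_linear_model(study)
    sig = res.significant_genes(0.05)
    assert "geneA" in sig and len(sig & {"geneA"}) == 1  # counted once
    chooser = res.collapse_probes()
    assert set(chooser.index) == {"geneA", "geneB", "geneC"}
    assert chooser["geneA"] in {"f0", "f1"}
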