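"""Low-expression pre-filtering and empirical-Bayes moderated
differential expression across time points.

The model is the standard moderated linear model for small-sample
microarray series: per-feature ordinary least squares on condition
means, residual variances shrunk toward a common prior by fitting a
scaled F distribution to the sample variances (method of moments on
log s^2 with digamma/trigamma inversion), moderated t per
timepoint-vs-control contrast and a moderated omnibus F across the
non-control coefficients.  False discovery rate control uses the
Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .study import ExpressionStudy


# ----------------------------------------------------------------------
# Pre-filtering
# ----------------------------------------------------------------------

def filter_low_expression(study: ExpressionStudy, floor: float = 6.0) -> ExpressionStudy:
    """Drop features that never show expression above ``floor`` (log2).

    A feature is retained iff its maximum over all samples exceeds the
    floor; feature order is preserved.
    """
    if not np.isfinite(floor):
        raise ValueError("floor must be finite")
    maxima = study.values.max(axis=1, skipna=True)
    keep = study.values.index[maxima > floor]
    if len(keep) == 0:
        warnings.warn("low-expression filter removed every feature", stacklevel=2)
    return study.subset_features(keep)


# ----------------------------------------------------------------------
# FDR adjustments
# ----------------------------------------------------------------------

def _check_p(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = _check_p(p_values)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------------
# Variance shrinkage (scaled-F moment fit)
# ----------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Fit s2 ~ s0^2 * F(df, d0) by moments of log s2.

    Returns (d0, s0^2); d0 = inf means complete pooling (the observed
    variances are consistent with a single common value).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    n = e.size
    e_var = np.sum((e - e_mean) ** 2) / (n - 1) - np.mean(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        if not np.isfinite(d0):
            return np.inf, float(np.exp(e_mean))
        s02 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return float(d0), s02
    return np.inf, float(np.exp(e_mean))


# ----------------------------------------------------------------------
# Moderated linear model
# ----------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-feature moderated statistics.

    ``table`` has one row per analysed feature with columns: ``gene``,
    ``F``, ``p_F``, ``fdr_F`` and, per non-control condition ``c``,
    ``logfc_c``, ``t_c``, ``p_c``, ``fdr_c``.  ``d0`` and ``s02`` are
    the prior degrees of freedom and prior variance of the shrinkage
    fit; ``contrasts`` lists the non-control conditions.
    """

    table: pd.DataFrame
    d0: float
    s02: float
    contrasts: list[str]
    control: str

    def significant_features(self, fdr: float = 0.05, how: str = "omnibus") -> pd.Index:
        if how == "omnibus":
            return self.table.index[self.table["fdr_F"] < fdr]
        if how == "any_contrast":
            cols = [f"fdr_{c}" for c in self.contrasts]
            return self.table.index[(self.table[cols] < fdr).any(axis=1)]
        raise ValueError("how must be 'omnibus' or 'any_contrast'")

    def significant_genes(self, fdr: float = 0.05, how: str = "omnibus") -> set[str]:
        """Unique annotated genes among significant features.

        Unannotated features (NaN symbol) are excluded; a gene counts
        once however many of its probes are significant.
        """
        feats = self.significant_features(fdr, how)
        genes = self.table.loc[feats, "gene"].dropna()
        return set(genes.unique())

    def collapse_probes(self) -> pd.Series:
        """Representative feature per annotated gene: smallest omnibus raw p."""
        t = self.table.dropna(subset=["gene"]).copy()
        t["feature"] = t.index
        t = t.sort_values(["gene", "p_F", "feature"], kind="mergesort")
        best = t.groupby("gene", sort=True)["feature"].first()
        return best

    def fold_change_table(self, source: str = "microarray") -> pd.DataFrame:
        """Per-feature log2FC table (gene, condition, log2fc, se, source)."""
        rows = []
        for feat, row in self.table.iterrows():
            for c in self.contrasts:
                rows.append((row["gene"], c, row[f"logfc_{c}"], row[f"se_{c}"], source))
        return pd.DataFrame(rows, columns=["gene", "condition", "log2fc", "se", "source"])


def moderated_linear_model(study: ExpressionStudy) -> DEResult:
    """Fit the moderated one-way (condition means) model.

    Requires at least two conditions and at least two total residual
    degrees of freedom.  Features with zero residual degrees of freedom
    (or a condition with no observation) are excluded with a warning.
    """
    conds = study.condition_order
    if len(conds) < 2:
        raise ValueError("need at least two conditions")
    control = study.control
    contrasts = [c for c in conds if c != control]

    X = study.values.to_numpy(dtype=float)
    n_feat = X.shape[0]
    cond_cols = {c: [i for i, s in enumerate(study.values.columns) if study.conditions[s] == c] for c in conds}

    means = np.empty((n_feat, len(conds)))
    counts = np.empty((n_feat, len(conds)))
    for j, c in enumerate(conds):
        block = X[:, cond_cols[c]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means[:, j] = np.nanmean(block, axis=1)
        counts[:, j] = np.sum(np.isfinite(block), axis=1)

    n_obs = counts.sum(axis=1)
    n_cond_present = (counts > 0).sum(axis=1)
    df_resid = n_obs - n_cond_present
    usable = (df_resid > 0) & (counts > 0).all(axis=1)
    if (~usable).any():
        warnings.warn(
            f"excluded {int((~usable).sum())} feature(s) with zero residual df "
            "or an empty condition",
            stacklevel=2,
        )
    if df_resid[usable].sum() < 2:
        raise ValueError("need at least two total residual degrees of freedom")

    # residual variance per feature
    fitted = np.zeros_like(X)
    for j, c in enumerate(conds):
        fitted[:, cond_cols[c]] = means[:, [j]]
    resid = X - fitted
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rss = np.nansum(resid**2, axis=1)
    s2 = np.where(df_resid > 0, rss / np.maximum(df_resid, 1), np.nan)

    idx = np.where(usable)[0]
    d0, s02 = fit_f_dist(s2[idx], df_resid[idx])
    if np.isfinite(d0):
        s2_post = (d0 * s02 + df_resid[idx] * s2[idx]) / (d0 + df_resid[idx])
        df_total = df_resid[idx] + d0
    else:
        s2_post = np.full(idx.shape, s02)
        df_total = np.full(idx.shape, np.inf)

    feat_ids = study.values.index[idx]
    out = pd.DataFrame(index=feat_ids)
    out["gene"] = study.gene_symbols.iloc[idx].values

    ctrl_j = conds.index(control)
    k = len(contrasts)
    b = np.empty((idx.size, k))
    v = np.empty((idx.size, k))
    for cj, c in enumerate(contrasts):
        j = conds.index(c)
        b[:, cj] = means[idx, j] - means[idx, ctrl_j]
        v[:, cj] = 1.0 / counts[idx, j] + 1.0 / counts[idx, ctrl_j]

    s_tilde = np.sqrt(s2_post)
    for cj, c in enumerate(contrasts):
        se = s_tilde * np.sqrt(v[:, cj])
        t = b[:, cj] / se
        if np.isfinite(d0):
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        else:
            p = 2.0 * stats.norm.sf(np.abs(t))
        out[f"logfc_{c}"] = b[:, cj]
        out[f"se_{c}"] = se
        out[f"t_{c}"] = t
        out[f"p_{c}"] = p
        out[f"fdr_{c}"] = adjust_fdr(p)

    # omnibus moderated F across the non-control coefficients.
    # cov(b) = sigma^2 * (diag(1/n_c) + (1/n_ctrl) J); Sherman-Morrison
    # gives b' U^-1 b = sum n_c b_c^2 - (sum n_c b_c)^2 / (n_ctrl + sum n_c).
    nc = counts[idx][:, [conds.index(c) for c in contrasts]]
    n0 = counts[idx, ctrl_j]
    q = np.sum(nc * b**2, axis=1) - np.sum(nc * b, axis=1) ** 2 / (n0 + nc.sum(axis=1))
    F = q / (k * s2_post)
    if np.isfinite(d0):
        p_f = stats.f.sf(F, k, df_total)
    else:
        p_f = stats.chi2.sf(k * F, k)
    out["F"] = F
    out["p_F"] = p_f
    out["fdr_F"] = adjust_fdr(p_f)

    return DEResult(table=out, d0=float(d0), s02=float(s02), contrasts=contrasts, control=control)


def write_de_result(result: DEResult, path) -> None:
    result.table.to_csv(path, sep="\t", index_label="feature")
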