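"""Between-dataset reproducibility of expression responses.

Two readouts: per-gene Pearson correlation of condition-mean expression
profiles across two studies over matched conditions (genes with r above
a threshold are called concordant), and the global Pearson correlation
between per-gene log2 fold changes of two fold-change tables at one
condition (with r^2 and the two-sided correlation-test p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ConcordanceRecord:
    gene: str
    r: float
    n_conditions: int
    passed: bool


def _match_gene(symbol) -> str | None:
    if symbol is None or (isinstance(symbol, float) and np.isnan(symbol)):
        return None
    return str(symbol).lower()


def profile_concordance(
    a, b, conditions: list[str], r_min: float = 0.8
) -> list[ConcordanceRecord]:
    """Per-gene correlation of condition-mean profiles across studies.

    Genes are matched case-insensitively by the study feature ids
    (collapse probes to genes first).  Conditions must have at least 3
    matched labels for a reported r.  Genes constant across conditions
    in either study are excluded.
    """
    if len(conditions) < 3:
        raise ValueError("need at least 3 matched conditions")
    for study, name in ((a, "first"), (b, "second")):
        missing = [c for c in conditions if c not in study.condition_order]
        if missing:
            raise ValueError(f"{name} study lacks conditions {missing}")
    ma = a.condition_means(conditions)
    mb = b.condition_means(conditions)
    key_a = {(_match_gene(g) or str(g).lower()): g for g in ma.index}
    key_b = {(_match_gene(g) or str(g).lower()): g for g in mb.index}
    shared = sorted(set(key_a) & set(key_b))
    if not shared:
        raise ValueError("no shared genes between studies")
    out: list[ConcordanceRecord] = []
    for k in shared:
        pa = ma.loc[key_a[k]].to_numpy(dtype=float)
        pb = mb.loc[key_b[k]].to_numpy(dtype=float)
        if np.std(pa) == 0 or np.std(pb) == 0:
            continue  # correlation undefined for a flat profile
        r = float(np.corrcoef(pa, pb)[0, 1])
        out.append(ConcordanceRecord(gene=key_a[k], r=r, n_conditions=len(conditions), passed=r > r_min))
    return out


def concordant_genes(records: list[ConcordanceRecord]) -> set[str]:
    return {rec.gene for rec in records if rec.passed}


def foldchange_concordance(
    x: pd.DataFrame, y: pd.DataFrame, condition: str
) -> tuple[float, float, float]:
    """Pearson r, r^2 and two-sided p between the log2FCs of two
    fold-change tables at ``condition`` (genes matched by symbol,
    case-insensitive; at least 3 shared genes required)."""
    def at(tab):
        t = tab[tab["condition"] == condition].copy()
        t["key"] = t["gene"].map(lambda g: str(g).lower())
        return t.groupby("key")["log2fc"].mean()

    sx, sy = at(x), at(y)
    shared = sorted(set(sx.index) & set(sy.index))
    if len(shared) < 3:
        raise ValueError(f"fewer than 3 shared genes at condition {condition!r}")
    vx = sx.loc[shared].to_numpy(dtype=float)
    vy = sy.loc[shared].to_numpy(dtype=float)
    res = stats.pearsonr(vx, vy)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def scatter_table(x: pd.DataFrame, y: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Paired (gene, log2FC_x, log2FC_y) table for external plotting."""
    def at(tab):
        t = tab[tab["condition"] == condition].copy()
        t["key"] = t["gene"].map(lambda g: str(g).lower())
        return t.groupby("key")["log2fc"].mean()

    sx, sy = at(x), at(y)
    shared = sorted(set(sx.index) & set(sy.index))
    return pd.DataFrame({"gene": shared, "log2fc_x": sx.loc[shared].values, "log2fc_y": sy.loc[shared].values})
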