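"""Gene co-expression network construction.

Edges connect gene pairs whose expression profiles correlate strongly
(|r| at or above a threshold, Pearson by default) and whose maximal
information coefficient confirms the relationship (MIC strictly above
a second threshold).  Isolated nodes are dropped from the reported
network.  The thresholds default to the stringent 0.95/0.95 pair used
for small-n time-course data.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .mic import mic_score
from .study import ExpressionStudy


def correlation_matrix(
    study: ExpressionStudy, method: str = "pearson", min_obs: int = 3
) -> pd.DataFrame:
    """Feature-by-feature correlation matrix (pairwise-complete).

    Constant features get NaN coefficients (undefined correlation);
    pairs with fewer than ``min_obs`` complete observations are NaN.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    df = study.values.T  # samples x features
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = df.corr(method=method, min_periods=min_obs)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def build_coexpression_network(
    study: ExpressionStudy,
    genes=None,
    r_min: float = 0.95,
    mic_min: float = 0.95,
    method: str = "pearson",
) -> nx.Graph:
    """Co-expression network over ``genes`` (default: all features).

    An edge is kept iff |r| >= ``r_min`` and MIC > ``mic_min``; MIC is
    only evaluated on pairs that already pass the correlation filter.
    Isolated nodes are dropped.  Edge attributes: ``r``, ``mic``; graph
    attributes record the thresholds and the number of finite
    correlation pairs considered.
    """
    sub = study.subset_features(genes) if genes is not None else study
    corr = correlation_matrix(sub, method=method)
    ids = list(corr.index)
    g = nx.Graph(r_min=r_min, mic_min=mic_min, method=method)
    vals = sub.values
    n_pairs_finite = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = corr.iat[i, j]
            if not np.isfinite(r):
                continue
            n_pairs_finite += 1
            if abs(r) < r_min:
                continue
            x = vals.loc[ids[i]].to_numpy(dtype=float)
            y = vals.loc[ids[j]].to_numpy(dtype=float)
            m = mic_score(x, y)
            if m > mic_min:
                g.add_edge(ids[i], ids[j], r=float(r), mic=float(m))
    g.graph["n_finite_pairs"] = n_pairs_finite
    return g


# ----------------------------------------------------------------------
# Export
# ----------------------------------------------------------------------

def write_sif(network: nx.Graph, path: str | Path, relation: str = "co") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(network.edges()):
            fh.write(f"{u}\t{relation}\t{v}\n")


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))


def annotate_fold_changes(network: nx.Graph, fold_changes: pd.DataFrame) -> None:
    """Attach per-condition mean log2FC node attributes (for export)."""
    piv = fold_changes.pivot_table(index="gene", columns="condition", values="log2fc", aggfunc="mean")
    for node in network.nodes():
        if node in piv.index:
            for cond, val in piv.loc[node].items():
                if np.isfinite(val):
                    network.nodes[node][f"log2fc_{cond}"] = float(val)
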