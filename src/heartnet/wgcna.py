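"""Weighted correlation network modules: soft-thresholded adjacency,
topological overlap, average-linkage clustering with a reduced dynamic
cut, module eigengenes, eigengene-based merging and module membership.

The adjacency is |cor|^beta (soft thresholding, beta = 10 by default,
Spearman correlation with pairwise-complete observations), the
topological overlap measure combines direct adjacency with shared
neighbourhood, and modules are branches of the average-linkage
dendrogram of 1 - TOM.  The dynamic hybrid cut is implemented in a
reduced, documented form: a static height cap, a minimum module size,
and assignment of unlabelled genes to the nearest module by average
TOM distance (within the cap); the published core-scatter branch
evaluation is omitted.  Module eigengenes are first principal
components sign-oriented to the module mean profile; modules whose
eigengenes are closer than the merge height are merged iteratively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .coexpr import correlation_matrix
from .study import ExpressionStudy


@dataclass
class WeightedNetParams:
    beta: float = 10.0
    correlation: str = "spearman"
    min_module_size: int = 20
    merge_height: float = 0.15
    cut_height: float = 0.99

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0.0 <= self.merge_height <= 1.0:
            raise ValueError("merge_height must be in [0, 1]")


@dataclass
class ModuleAssignment:
    """Gene -> module labels (0 = unassigned) with eigengenes.

    ``eigengenes`` is a samples x modules DataFrame (columns are module
    labels); ``sizes`` maps label -> gene count.
    """

    labels: pd.Series
    eigengenes: pd.DataFrame
    params: WeightedNetParams
    sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sizes:
            counts = self.labels[self.labels > 0].value_counts()
            self.sizes = {int(k): int(v) for k, v in counts.items()}


def soft_adjacency(study: ExpressionStudy, params: WeightedNetParams | None = None) -> pd.DataFrame:
    """a_ij = |cor(x_i, x_j)|^beta with zero diagonal.

    Constant genes (undefined correlations) get zero adjacency.
    """
    params = params or WeightedNetParams()
    corr = correlation_matrix(study, method=params.correlation)
    a = np.abs(corr.to_numpy(dtype=float)) ** params.beta
    a = np.nan_to_num(a, nan=0.0)
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


def topological_overlap(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """TOM_ij = (sum_u a_iu*a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1."""
    is_df = isinstance(adjacency, pd.DataFrame)
    a = adjacency.to_numpy(dtype=float) if is_df else np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (a < -1e-12).any() or (a > 1 + 1e-12).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if is_df:
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


def _eigengene(values: pd.DataFrame) -> pd.Series:
    """First principal component over samples of the standardised
    module submatrix, sign-oriented to the module mean profile."""
    X = values.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    eg = vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(eg, mean_profile) < 0:
        eg = -eg
    return pd.Series(eg, index=values.columns)


def detect_weighted_modules(
    study: ExpressionStudy, params: WeightedNetParams | None = None
) -> ModuleAssignment:
    """Cluster 1 - TOM by average linkage; cut; merge close eigengenes.

    Genes in branches below ``min_module_size`` are assigned to the
    nearest module by average TOM distance when within the cut height,
    else labelled 0.  Returns labels renumbered by decreasing size.
    """
    params = params or WeightedNetParams()
    genes = list(study.values.index)
    if len(genes) < params.min_module_size:
        return ModuleAssignment(
            labels=pd.Series(0, index=genes),
            eigengenes=pd.DataFrame(index=study.values.columns),
            params=params,
        )
    adj = soft_adjacency(study, params)
    tom = topological_overlap(adj).to_numpy(dtype=float)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    flat = hierarchy.fcluster(link, t=params.cut_height, criterion="distance")

    labels = np.zeros(len(genes), dtype=int)
    next_label = 1
    for cl in np.unique(flat):
        idx = np.where(flat == cl)[0]
        if idx.size >= params.min_module_size:
            labels[idx] = next_label
            next_label += 1

    # nearest-module assignment for unlabelled genes, within the cap
    if next_label > 1:
        for i in np.where(labels == 0)[0]:
            best_lab, best_d = 0, np.inf
            for lab in range(1, next_label):
                d = dist[i, labels == lab].mean()
                if d < best_d:
                    best_lab, best_d = lab, d
            if best_d <= params.cut_height:
                labels[i] = best_lab

    # eigengenes and iterative merging
    def eigengenes_of(labels: np.ndarray) -> dict[int, pd.Series]:
        return {
            lab: _eigengene(study.values.iloc[np.where(labels == lab)[0]])
            for lab in sorted(set(labels) - {0})
        }

    egs = eigengenes_of(labels)
    while len(egs) > 1:
        labs = sorted(egs)
        best = None  # (diss, lab_i, lab_j)
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                r = float(np.corrcoef(egs[labs[i]], egs[labs[j]])[0, 1])
                diss = 1.0 - r
                if diss < params.merge_height and (best is None or diss < best[0]):
                    best = (diss, labs[i], labs[j])
        if best is None:
            break
        _, li, lj = best
        labels[labels == lj] = li
        egs = eigengenes_of(labels)

    # renumber by decreasing size (ties: old label order)
    sizes = {lab: int((labels == lab).sum()) for lab in sorted(set(labels) - {0})}
    order = sorted(sizes, key=lambda l: (-sizes[l], l))
    remap = {old: new for new, old in enumerate(order, start=1)}
    new_labels = np.array([remap.get(l, 0) for l in labels])
    egs = {remap[l]: e for l, e in eigengenes_of(labels).items()}
    eg_df = pd.DataFrame({lab: egs[lab] for lab in sorted(egs)}) if egs else pd.DataFrame(index=study.values.columns)
    return ModuleAssignment(
        labels=pd.Series(new_labels, index=genes),
        eigengenes=eg_df,
        params=params,
    )


def module_membership(
    study: ExpressionStudy, assignment: ModuleAssignment
) -> pd.DataFrame:
    """Signed MM = cor(gene, own-module eigengene) with the network's
    correlation type; p from the two-sided t-test with df = n - 2.
    Unassigned genes get NaN."""
    method = assignment.params.correlation
    n = study.values.shape[1]
    rows = []
    for gene, lab in assignment.labels.items():
        if lab == 0 or lab not in assignment.eigengenes.columns:
            rows.append((gene, lab, np.nan, np.nan))
            continue
        x = study.values.loc[gene]
        eg = assignment.eigengenes[lab]
        if method == "spearman":
            mm = stats.spearmanr(x, eg).statistic
        else:
            mm = float(np.corrcoef(x, eg)[0, 1])
        mm = float(np.clip(mm, -1.0, 1.0))
        if abs(mm) >= 1.0:
            p = 0.0
        else:
            t = mm * np.sqrt((n - 2) / (1.0 - mm * mm))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
        rows.append((gene, lab, mm, p))
    return pd.DataFrame(rows, columns=["gene", "module", "mm", "p"]).set_index("gene")


def write_assignment_tsv(study: ExpressionStudy, assignment: ModuleAssignment, path) -> None:
    mm = module_membership(study, assignment)
    mm.to_csv(path, sep="\t")


def write_eigengenes_tsv(assignment: ModuleAssignment, path) -> None:
    assignment.eigengenes.T.to_csv(path, sep="\t", index_label="module")
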