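"""Expression-study container and tab-delimited I/O.

An :class:`ExpressionStudy` bundles a log2 expression matrix (features x
samples) with the sample annotation (condition, replicate) and the
feature -> gene-symbol map.  It is the object every analysis stage
consumes.  Multiple features (microarray probes) may map to the same
gene symbol; features may be unannotated (NaN symbol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class StudyError(ValueError):
    """Raised when an expression study violates its invariants."""


@dataclass
class ExpressionStudy:
    """Log2 expression matrix with sample and feature annotation.

    Parameters
    ----------
    values
        DataFrame of log2 expression, features on the index, sample ids
        on the columns.  NaN entries are allowed (missing measurements);
        infinities are not.
    gene_symbols
        Series mapping feature id -> gene symbol (may be many-to-one;
        NaN marks an unannotated feature).
    conditions
        Series mapping sample id -> condition label.
    replicates
        Series mapping sample id -> replicate id (any hashable).
    condition_order
        Optional explicit ordering of condition labels; the first label
        is treated as the reference (control) by downstream contrasts.
        Defaults to order of first appearance in ``conditions``.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series
    conditions: pd.Series
    replicates: pd.Series
    condition_order: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise StudyError("duplicated sample ids in expression matrix")
        if self.values.index.duplicated().any():
            raise StudyError("duplicated feature ids in expression matrix")
        missing = [s for s in self.values.columns if s not in self.conditions.index]
        if missing:
            raise StudyError(f"samples without a condition label: {missing}")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise StudyError("expression matrix contains infinite values")
        self.gene_symbols = self.gene_symbols.reindex(self.values.index)
        self.conditions = self.conditions.loc[list(self.values.columns)]
        self.replicates = self.replicates.reindex(self.values.columns)
        if self.condition_order is None:
            seen: list[str] = []
            for c in self.conditions:
                if c not in seen:
                    seen.append(c)
            self.condition_order = seen
        else:
            self.condition_order = list(self.condition_order)
            unknown = set(self.conditions) - set(self.condition_order)
            if unknown:
                raise StudyError(f"conditions missing from condition_order: {sorted(unknown)}")

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def control(self) -> str:
        """Reference condition (first in ``condition_order``)."""
        return self.condition_order[0]

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]

    def subset_features(self, feature_ids) -> "ExpressionStudy":
        """Return a study restricted to ``feature_ids`` (order preserved)."""
        keep = [f for f in feature_ids if f in self.values.index]
        return ExpressionStudy(
            values=self.values.loc[keep],
            gene_symbols=self.gene_symbols.loc[keep],
            conditions=self.conditions.copy(),
            replicates=self.replicates.copy(),
            condition_order=list(self.condition_order),
        )

    def condition_means(self, conditions: list[str] | None = None) -> pd.DataFrame:
        """Per-feature mean expression per condition (NaN-aware)."""
        conds = conditions if conditions is not None else self.condition_order
        out = {}
        for c in conds:
            cols = self.samples_of(c)
            if not cols:
                raise StudyError(f"condition {c!r} has no samples")
            out[c] = self.values[cols].mean(axis=1, skipna=True)
        return pd.DataFrame(out)

    def gene_level(self, feature_chooser: pd.Series) -> "ExpressionStudy":
        """Collapse to gene level given a gene -> feature map.

        ``feature_chooser`` indexes genes and holds the representative
        feature id per gene (e.g. the probe with smallest omnibus p from
        the differential-expression stage).
        """
        feats = list(feature_chooser.values)
        sub = self.values.loc[feats]
        sub.index = list(feature_chooser.index)
        return ExpressionStudy(
            values=sub,
            gene_symbols=pd.Series(list(feature_chooser.index), index=sub.index),
            conditions=self.conditions.copy(),
            replicates=self.replicates.copy(),
            condition_order=list(self.condition_order),
        )


# ----------------------------------------------------------------------
# Tab-delimited persistence: expression.tsv + features.tsv + samples.tsv
# ----------------------------------------------------------------------

def write_study(study: ExpressionStudy, directory: str | Path) -> None:
    """Write a study as three TSV files under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    study.values.to_csv(d / "expression.tsv", sep="\t", index_label="feature")
    pd.DataFrame({"feature": study.values.index, "gene": study.gene_symbols.values}).to_csv(
        d / "features.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        {
            "sample": study.values.columns,
            "condition": study.conditions.values,
            "replicate": study.replicates.values,
        }
    ).to_csv(d / "samples.tsv", sep="\t", index=False)
    with open(d / "condition_order.txt", "w") as fh:
        fh.write("\n".join(study.condition_order) + "\n")


def read_study(directory: str | Path) -> ExpressionStudy:
    """Read a study written by :func:`write_study`."""
    d = Path(directory)
    values = pd.read_csv(d / "expression.tsv", sep="\t", index_col="feature")
    feats = pd.read_csv(d / "features.tsv", sep="\t", index_col="feature")
    samples = pd.read_csv(d / "samples.tsv", sep="\t", index_col="sample")
    order_file = d / "condition_order.txt"
    order = None
    if order_file.exists():
        order = [l for l in order_file.read_text().splitlines() if l]
    return ExpressionStudy(
        values=values,
        gene_symbols=feats["gene"],
        conditions=samples["condition"],
        replicates=samples["replicate"],
        condition_order=order,
    )
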