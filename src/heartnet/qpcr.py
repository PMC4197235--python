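"""Efficiency-corrected, multi-reference-normalised relative expression
from qPCR Cq tables (delta-delta Cq).

Technical replicates are averaged on the Cq scale; relative quantity is
RQ = E^(mean Cq of the calibrator condition - Cq of the sample), with
each gene's own amplification efficiency E (fold-per-cycle, 2 = 100%).
Per sample, the normalisation factor is the geometric mean of the
reference-gene RQs; biological replicates are combined on the log2
normalised scale: log2FC = mean log2(normalised, injured) - mean
log2(normalised, sham), with the standard error from replicate
variability of both arms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CQ_COLUMNS = ["sample", "condition", "gene", "replicate", "cq", "efficiency"]

DEFAULT_REFERENCE_GENES = ("ef1a", "rpl13a", "tuba1")


def validate_cq_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CQ_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Cq table missing columns: {missing}")
    if (table["cq"] <= 0).any():
        raise ValueError("Cq values must be positive")
    if ((table["efficiency"] <= 1.0) | (table["efficiency"] > 2.0)).any():
        raise ValueError("efficiencies must lie in (1, 2]")
    return table


def _mean_cq(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates on the Cq scale; one row per
    sample x gene with condition and efficiency carried along."""
    return (
        table.groupby(["sample", "condition", "gene", "efficiency"], as_index=False)["cq"]
        .mean()
    )


def relative_quantities(table: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Per sample x gene relative quantity vs the calibrator condition.

    RQ = E^(mean calibrator Cq - sample Cq), per gene with its own E.
    Raises if a gene is missing from the calibrator condition.
    """
    table = validate_cq_table(table)
    mean_cq = _mean_cq(table)
    calib = mean_cq[mean_cq["condition"] == calibrator]
    if calib.empty:
        raise ValueError(f"calibrator condition {calibrator!r} not present")
    calib_mean = calib.groupby("gene")["cq"].mean()
    missing = sorted(set(mean_cq["gene"]) - set(calib_mean.index))
    if missing:
        raise ValueError(f"gene(s) missing in calibrator condition: {missing}")
    out = mean_cq.copy()
    out["rq"] = out["efficiency"] ** (out["gene"].map(calib_mean).to_numpy() - out["cq"].to_numpy())
    return out[["sample", "condition", "gene", "efficiency", "cq", "rq"]]


def _normalised(rq: pd.DataFrame, reference_genes) -> pd.DataFrame:
    """Divide each RQ by the sample's normalisation factor: the
    geometric mean of the reference-gene RQs."""
    wide = rq.pivot_table(index="sample", columns="gene", values="rq")
    missing_ref = [g for g in reference_genes if g not in wide.columns]
    if missing_ref:
        raise ValueError(f"reference gene(s) absent from table: {missing_ref}")
    ref = wide[list(reference_genes)]
    if ref.isna().any().any():
        bad = sorted(ref.index[ref.isna().any(axis=1)])
        raise ValueError(f"reference gene missing in sample(s): {bad}")
    nf = np.exp(np.log(ref).mean(axis=1))
    out = rq.copy()
    out["nf"] = out["sample"].map(nf)
    out["norm"] = out["rq"] / out["nf"]
    return out


def qpcr_fold_changes(
    table: pd.DataFrame,
    reference_genes=DEFAULT_REFERENCE_GENES,
    contrast_pairs: list[tuple[str, str, str]] | None = None,
) -> pd.DataFrame:
    """Per-gene, per-day log2 fold changes of injured vs sham.

    ``contrast_pairs`` lists (injured condition, sham condition, label);
    by default every condition named ``injured-<day>`` is contrasted
    against ``sham-<day>`` with label ``<day>``.  Reference genes are
    excluded from the output.  Returns a fold-change table with columns
    gene, condition, log2fc, se, n, source.
    """
    table = validate_cq_table(table)
    conds = sorted(table["condition"].unique())
    if contrast_pairs is None:
        contrast_pairs = []
        for c in conds:
            if c.startswith("injured-"):
                day = c.split("-", 1)[1]
                sham = f"sham-{day}"
                if sham in conds:
                    contrast_pairs.append((c, sham, day))
        if not contrast_pairs:
            raise ValueError("no injured-vs-sham condition pairs found")
    rows = []
    for injured, sham, label in contrast_pairs:
        sub = table[table["condition"].isin([injured, sham])]
        rq = relative_quantities(sub, calibrator=sham)
        norm = _normalised(rq, reference_genes)
        norm = norm[~norm["gene"].isin(reference_genes)]
        log2n = norm.assign(log2norm=np.log2(norm["norm"]))
        for gene, g in log2n.groupby("gene"):
            inj = g.loc[g["condition"] == injured, "log2norm"].to_numpy()
            sh = g.loc[g["condition"] == sham, "log2norm"].to_numpy()
            if inj.size == 0 or sh.size == 0:
                continue
            lfc = float(inj.mean() - sh.mean())
            var_i = inj.var(ddof=1) / inj.size if inj.size > 1 else 0.0
            var_s = sh.var(ddof=1) / sh.size if sh.size > 1 else 0.0
            rows.append((gene, label, lfc, float(np.sqrt(var_i + var_s)), int(inj.size), "qPCR"))
    return pd.DataFrame(rows, columns=["gene", "condition", "log2fc", "se", "n", "source"])


def run_summary(table: pd.DataFrame, reference_genes=DEFAULT_REFERENCE_GENES) -> pd.DataFrame:
    """Machine-readable reporting fields per gene: efficiency, replicate
    counts, reference-gene panel."""
    table = validate_cq_table(table)
    rows = []
    for gene, g in table.groupby("gene"):
        rows.append(
            {
                "gene": gene,
                "efficiency": float(g["efficiency"].iloc[0]),
                "n_samples": int(g["sample"].nunique()),
                "n_technical_replicates": int(g.groupby("sample")["replicate"].nunique().max()),
                "is_reference": gene in reference_genes,
                "reference_panel": ",".join(reference_genes),
            }
        )
    return pd.DataFrame(rows)
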