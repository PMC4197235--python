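"""End-to-end orchestration and candidate-gene selection.

The pipeline mirrors the discovery workflow: differential expression on
the derivation dataset; three independent network analyses of the
top-ranked genes (cohesive overlapping modules, model-tree directed
network, weighted topological-overlap modules); concordance against a
companion dataset; union-based candidate selection; optional qPCR
fold-change validation.  Every stage writes its table under the run
directory and the run log records all parameters, so each number in
the candidate report is traceable to one stage output file.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohesive as _cohesive
from . import coexpr as _coexpr
from . import concordance as _concordance
from . import diffexpr as _diffexpr
from . import qpcr as _qpcr
from . import simulate as _simulate
from . import treenet as _treenet
from . import wgcna as _wgcna
from .study import ExpressionStudy, read_study, write_study


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": {
        "n_genes": 300,
        "n_probes_per_gene": 1,
        "n_replicates": 3,
        "de_fraction": 0.15,
        "effect_size_sd": 2.0,
        "noise_sd": 0.3,
        "modules": [
            {"size": 30, "rho": 0.95, "profile": [0.0, 2.0, 1.5, 0.5, 0.0]},
            {"size": 30, "rho": 0.95, "profile": [0.0, -1.5, -2.0, -0.5, 0.0]},
        ],
        "module_signal_sd": 0.5,
        "hub": {
            "hub": "G0001",
            "profile": [0.0, 3.0, 2.0, 0.5, 0.0],
            "hub_sd": 0.5,
            "dependents": [
                ["G0002", 1, 1.0, 0.2],
                ["G0003", 1, 0.8, 0.2],
                ["G0004", -1, 1.0, 0.2],
                ["G0005", -1, 0.8, 0.2],
            ],
        },
    },
    "de": {"floor": 6.0, "fdr_top": 1e-4, "fdr_broad": 0.05, "max_top_genes": 120},
    "stages": {
        "coexpr": True,
        "cohesive": True,
        "treenet": True,
        "weighted": True,
        "concordance": True,
        "qpcr": True,
    },
    "coexpr": {"r_min": 0.95, "mic_min": 0.95},
    "cohesive": {"min_size": 5, "penalty": 2.0, "overlap_threshold": 0.8},
    "treenet": {"theta": 0.30, "alpha": 0.05},
    "weighted": {"beta": 10.0, "correlation": "spearman", "min_module_size": 20, "merge_height": 0.15},
    "concordance": {"r_min": 0.8, "concordant_fraction": 0.1, "profile_noise_sd": 0.2},
    "candidates": {"include": [], "exclude": [], "mm_min": 0.8},
    "qpcr": {"cq_noise_sd": 0.15, "efficiency": 1.95},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    return _merge(DEFAULT_CONFIG, user)


def simulation_config_from(cfg: dict, seed: int) -> _simulate.SimulationConfig:
    sim = cfg["simulate"]
    modules = [
        _simulate.ModuleSpec(size=m["size"], rho=m["rho"], profile=tuple(m.get("profile", ())))
        for m in sim.get("modules", [])
    ]
    hub = None
    if sim.get("hub"):
        hub = _simulate.HubSpec(
            hub=sim["hub"]["hub"],
            dependents=[tuple(d) for d in sim["hub"]["dependents"]],
            hub_sd=sim["hub"].get("hub_sd", 2.0),
            profile=tuple(sim["hub"].get("profile", ())),
        )
    return _simulate.SimulationConfig(
        n_genes=sim["n_genes"],
        n_probes_per_gene=sim.get("n_probes_per_gene", 1),
        n_replicates=sim.get("n_replicates", 3),
        de_fraction=sim.get("de_fraction", 0.0),
        effect_size_sd=sim.get("effect_size_sd", 2.0),
        noise_sd=sim.get("noise_sd", 0.3),
        module_signal_sd=sim.get("module_signal_sd", 1.0),
        module_spec=modules,
        hub_spec=hub,
        low_expression_fraction=sim.get("low_expression_fraction", 0.0),
        seed=seed,
    )


def select_candidates(stage_outputs: dict, config: dict | None = None) -> pd.DataFrame:
    """Union of genes flagged by any enabled technique, minus config
    exclusions, plus manual additions; ranked by omnibus FDR then by
    number of flags.

    ``stage_outputs`` may hold: ``de`` (DEResult), ``cohesive`` (list of
    NetworkModule), ``treenet`` (list of DirectedAssociation),
    ``weighted`` (module-membership DataFrame), ``concordance`` (list of
    ConcordanceRecord).
    """
    cfg = _merge(DEFAULT_CONFIG["candidates"], (config or {}).get("candidates", config or {}))
    flags: dict[str, dict] = {}

    def flag(gene, name):
        d = flags.setdefault(str(gene), {})
        d[name] = True

    if not stage_outputs:
        raise ValueError("at least one stage output is required")
    for mod in stage_outputs.get("cohesive") or []:
        for g in mod.members:
            flag(g, "cohesive_module")
    for assoc in stage_outputs.get("treenet") or []:
        flag(assoc.source, "directed_network")
        flag(assoc.target, "directed_network")
    mm = stage_outputs.get("weighted")
    if mm is not None and len(mm):
        sel = mm[(mm["module"] > 0) & (mm["mm"].abs() >= cfg["mm_min"])]
        for g in sel.index:
            flag(g, "weighted_module")
    for rec in stage_outputs.get("concordance") or []:
        if rec.passed:
            flag(rec.gene, "concordant")

    for g in cfg.get("include", []):
        d = flags.setdefault(str(g), {})
        d["manual"] = True
    for g in cfg.get("exclude", []):
        flags.pop(str(g), None)

    if not flags:
        warnings.warn("no candidate genes flagged by any stage", stacklevel=2)

    de = stage_outputs.get("de")
    gene_fdr: dict[str, float] = {}
    gene_lfc: dict[str, dict[str, float]] = {}
    if de is not None:
        t = de.table.dropna(subset=["gene"])
        gene_fdr = t.groupby("gene")["fdr_F"].min().to_dict()
        for c in de.contrasts:
            for g, v in t.groupby("gene")[f"logfc_{c}"].mean().items():
                gene_lfc.setdefault(str(g), {})[c] = float(v)

    flag_cols = ["cohesive_module", "directed_network", "weighted_module", "concordant", "manual"]
    rows = []
    for g, d in flags.items():
        row = {"gene": g}
        for c in flag_cols:
            row[c] = bool(d.get(c, False))
        row["n_flags"] = sum(row[c] for c in flag_cols if c != "manual")
        row["fdr_F"] = gene_fdr.get(g, np.nan)
        for c, v in gene_lfc.get(g, {}).items():
            row[f"log2fc_{c}"] = v
        rows.append(row)
    rep = pd.DataFrame(rows)
    if len(rep):
        rep = rep.sort_values(
            by=["fdr_F", "n_flags", "gene"],
            ascending=[True, False, True],
            na_position="last",
            kind="mergesort",
        ).set_index("gene")
    return rep


def run_pipeline(config, outdir) -> dict:
    """Run the full analysis on a synthetic study; returns stage outputs.

    Stage outputs are pure functions of (config, seed); the run
    directory contains every intermediate table plus a parameter log.
    """
    cfg = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    log_lines = [f"config: {yaml.safe_dump(cfg, sort_keys=True).strip()}"]

    sim_cfg = simulation_config_from(cfg, seed)
    study, truth = _simulate.generate_timecourse_study(sim_cfg)
    write_study(study, out / "derivation_study")
    _simulate.write_ground_truth(truth, out / "ground_truth.txt")

    # differential expression ----------------------------------------
    de_cfg = cfg["de"]
    filtered = _diffexpr.filter_low_expression(study, floor=de_cfg["floor"])
    de = _diffexpr.moderated_linear_model(filtered)
    _diffexpr.write_de_result(de, out / "de_results.tsv")
    log_lines.append(
        f"de: {study.n_features} features -> {filtered.n_features} after floor "
        f"{de_cfg['floor']}; d0={de.d0:.4g} s02={de.s02:.4g}"
    )

    top_feats = de.table.loc[de.significant_features(de_cfg["fdr_top"])]
    top_feats = top_feats.sort_values("p_F").head(de_cfg["max_top_genes"])
    chooser = de.collapse_probes()
    top_genes = sorted(set(top_feats["gene"].dropna()))
    gene_study = filtered.gene_level(chooser)
    log_lines.append(f"top genes (FDR<{de_cfg['fdr_top']}): {len(top_genes)}")

    outputs: dict = {"study": study, "truth": truth, "de": de, "top_genes": top_genes}

    network = None
    if stages.get("coexpr") and len(top_genes) >= 2:
        cx = cfg["coexpr"]
        network = _coexpr.build_coexpression_network(
            gene_study, genes=top_genes, r_min=cx["r_min"], mic_min=cx["mic_min"]
        )
        _coexpr.write_sif(network, out / "coexpression.sif")
        _coexpr.write_graphml(network, out / "coexpression.graphml")
        log_lines.append(
            f"coexpr: {network.number_of_nodes()} nodes, {network.number_of_edges()} edges "
            f"(|r|>={cx['r_min']}, MIC>{cx['mic_min']})"
        )
        outputs["network"] = network

    if stages.get("cohesive") and network is not None and network.number_of_nodes() > 0:
        ch = cfg["cohesive"]
        params = _cohesive.CohesiveParams(
            min_size=ch["min_size"], penalty=ch["penalty"], overlap_threshold=ch["overlap_threshold"]
        )
        modules = _cohesive.detect_cohesive_modules(network, params)
        _cohesive.write_modules_tsv(modules, out / "cohesive_modules.tsv")
        log_lines.append(f"cohesive: {len(modules)} modules")
        outputs["cohesive"] = modules

    if stages.get("treenet") and len(top_genes) >= 2:
        tn = cfg["treenet"]
        assocs = _treenet.infer_directed_network(
            gene_study, genes=[g for g in top_genes], theta=tn["theta"], alpha=tn["alpha"]
        )
        _treenet.associations_table(assocs).to_csv(out / "directed_network.tsv", sep="\t", index=False)
        log_lines.append(f"treenet: {len(assocs)} directed associations")
        outputs["treenet"] = assocs

    if stages.get("weighted"):
        wg = cfg["weighted"]
        broad_feats = de.significant_features(de_cfg["fdr_broad"])
        broad_genes = sorted(set(de.table.loc[broad_feats, "gene"].dropna()))
        wstudy = gene_study.subset_features(broad_genes)
        params = _wgcna.WeightedNetParams(
            beta=wg["beta"],
            correlation=wg["correlation"],
            min_module_size=wg["min_module_size"],
            merge_height=wg["merge_height"],
        )
        assignment = _wgcna.detect_weighted_modules(wstudy, params)
        mm = _wgcna.module_membership(wstudy, assignment)
        mm.to_csv(out / "weighted_membership.tsv", sep="\t")
        _wgcna.write_eigengenes_tsv(assignment, out / "weighted_eigengenes.tsv")
        log_lines.append(
            f"weighted: {len(assignment.sizes)} modules over {len(broad_genes)} genes"
        )
        outputs["weighted"] = mm
        outputs["weighted_assignment"] = assignment

    if stages.get("concordance"):
        cc = cfg["concordance"]
        pair_cfg = _simulate.SimulationConfig(
            n_genes=sim_cfg.n_genes, n_replicates=sim_cfg.n_replicates, noise_sd=sim_cfg.noise_sd,
            conditions=sim_cfg.conditions, seed=seed + 1,
        )
        a2, b2, pair_truth = _simulate.generate_concordant_pair(
            pair_cfg,
            concordant_fraction=cc["concordant_fraction"],
            profile_noise_sd=cc["profile_noise_sd"],
            seed=seed + 1,
        )
        match_conds = list(sim_cfg.conditions[:4])
        records = _concordance.profile_concordance(a2, b2, conditions=match_conds, r_min=cc["r_min"])
        pd.DataFrame(
            [(r.gene, r.r, r.n_conditions, r.passed) for r in records],
            columns=["gene", "r", "n_conditions", "passed"],
        ).to_csv(out / "concordance.tsv", sep="\t", index=False)
        log_lines.append(
            f"concordance: {sum(r.passed for r in records)} / {len(records)} genes with r > {cc['r_min']}"
        )
        outputs["concordance"] = records
        outputs["concordance_truth"] = pair_truth

    report = select_candidates(
        {k: outputs.get(k) for k in ("de", "cohesive", "treenet", "weighted", "concordance")},
        cfg,
    )
    report.to_csv(out / "candidates.tsv", sep="\t")
    log_lines.append(f"candidates: {len(report)} genes")
    outputs["candidates"] = report

    if stages.get("qpcr") and len(report):
        qc = cfg["qpcr"]
        cand = [g for g in report.index if g in truth.de_genes or any(g in e for e in truth.hub_edges)][:12]
        if cand:
            micro_fc = de.fold_change_table()
            day1 = micro_fc[micro_fc["condition"] == de.contrasts[0]].groupby("gene")["log2fc"].mean()
            fold = {g: float(day1.get(g, 0.0)) for g in cand}
            eff = {g: qc["efficiency"] for g in cand}
            eff.update({g: qc["efficiency"] for g in _qpcr.DEFAULT_REFERENCE_GENES})
            cq = _simulate.generate_qpcr_table(
                fold_changes=fold,
                efficiencies=eff,
                cq_noise_sd=qc["cq_noise_sd"],
                seed=seed + 2,
                days=("1d",),
            )
            cq.to_csv(out / "qpcr_cq.tsv", sep="\t", index=False)
            qfc = _qpcr.qpcr_fold_changes(cq)
            qfc.to_csv(out / "qpcr_foldchanges.tsv", sep="\t", index=False)
            if len(set(qfc["gene"])) >= 3:
                r, r2, p = _concordance.foldchange_concordance(micro_fc, qfc, de.contrasts[0])
                log_lines.append(f"qpcr concordance at {de.contrasts[0]}: r={r:.3f} r2={r2:.3f} p={p:.3g}")
                outputs["qpcr_concordance"] = (r, r2, p)
            outputs["qpcr_foldchanges"] = qfc

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    outputs["log"] = log_lines
    return outputs
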