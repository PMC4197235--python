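"""Synthetic time-course expression studies, concordant dataset pairs and
qPCR Cq tables.

The generators emulate the statistical structure the downstream analyses
assume: a 5-condition x 3-replicate log2 expression matrix with multiple
probes per gene, planted differentially expressed genes, planted
correlated modules with a shared latent time profile, a hub gene with
signed linear dependents, a companion dataset sharing concordant
condition profiles, and qPCR quantification cycles consistent with
chosen fold changes and stable reference genes.  Every generator returns
the ground truth alongside the data so parameter-recovery tests can
score each analysis stage.

Module-gene model: ``gene = sqrt(rho) * latent + sqrt(1 - rho) *
idiosyncratic`` with both components standard normal per sample, scaled
by ``module_signal_sd`` and shifted to the gene baseline, which gives an
expected pairwise within-module correlation of exactly ``rho`` when the
shared condition profile is flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .study import ExpressionStudy

DEFAULT_CONDITIONS = ("control", "1d", "3d", "5d", "7d")


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class ModuleSpec:
    """A planted correlated gene module.

    ``profile`` gives the shared per-condition mean offset (log2 units);
    a flat profile leaves the module invisible to differential
    expression while still co-expressed.
    """

    size: int
    rho: float
    profile: tuple[float, ...] = ()


@dataclass
class HubSpec:
    """A hub gene with signed linear dependents.

    ``dependents`` is a list of ``(gene_id, sign, magnitude,
    residual_sd)`` tuples; each dependent equals ``sign * magnitude``
    times the hub's centred signal plus Gaussian residual noise.  An
    optional per-condition ``profile`` makes the hub itself
    injury-responsive (as the central node of a transcriptional
    circuit would be), propagating its time response to dependents.
    """

    hub: str
    dependents: list[tuple[str, int, float, float]] = field(default_factory=list)
    hub_sd: float = 2.0  # matches the planted differential-effect scale
    profile: tuple[float, ...] = ()


@dataclass
class SimulationConfig:
    n_genes: int = 200
    n_probes_per_gene: int | tuple[int, int] = 1
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    baseline_mean: float = 9.0
    baseline_sd: float = 1.0
    de_fraction: float = 0.0
    effect_size_sd: float = 2.0
    module_spec: list[ModuleSpec] = field(default_factory=list)
    module_signal_sd: float = 1.0
    hub_spec: HubSpec | None = None
    noise_sd: float = 0.3
    probe_noise_sd: float = 0.1
    low_expression_fraction: float = 0.0
    expression_floor: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        probes = self.n_probes_per_gene
        if isinstance(probes, tuple):
            if probes[0] < 1 or probes[1] < probes[0]:
                raise ConfigError("n_probes_per_gene range must be >= 1 and ordered")
        elif probes < 1:
            raise ConfigError("n_probes_per_gene must be >= 1")
        if len(self.conditions) < 2:
            raise ConfigError("conditions must list at least two labels")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigError("de_fraction must be in [0, 1]")
        if not 0.0 <= self.low_expression_fraction <= 1.0:
            raise ConfigError("low_expression_fraction must be in [0, 1]")
        for sd_name in ("baseline_sd", "effect_size_sd", "noise_sd", "probe_noise_sd", "module_signal_sd"):
            if getattr(self, sd_name) < 0:
                raise ConfigError(f"{sd_name} must be >= 0")
        sizes = sum(m.size for m in self.module_spec)
        if sizes > self.n_genes:
            raise ConfigError("module_spec sizes sum exceeds n_genes")
        for m in self.module_spec:
            if not 0.0 <= m.rho < 1.0:
                raise ConfigError("module_spec rho must be in [0, 1)")
            if m.profile and len(m.profile) != len(self.conditions):
                raise ConfigError("module_spec profile length must match conditions")
        if self.hub_spec is not None:
            ids = self._gene_ids()
            if self.hub_spec.hub not in ids:
                raise ConfigError("hub_spec hub id not among generated gene ids")
            for dep, sign, mag, rsd in self.hub_spec.dependents:
                if dep not in ids:
                    raise ConfigError(f"hub_spec dependent {dep!r} not among generated gene ids")
                if sign not in (-1, 1):
                    raise ConfigError("hub_spec slope sign must be +1 or -1")
                if mag <= 0 or rsd < 0:
                    raise ConfigError("hub_spec magnitude must be > 0 and residual sd >= 0")
            if self.hub_spec.profile and len(self.hub_spec.profile) != len(self.conditions):
                raise ConfigError("hub_spec profile length must match conditions")

    def _gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    de_genes: set[str] = field(default_factory=set)
    module_membership: dict[str, int] = field(default_factory=dict)
    hub_edges: list[tuple[str, str, int, float]] = field(default_factory=list)
    concordant_genes: set[str] = field(default_factory=set)
    low_genes: set[str] = field(default_factory=set)
    de_effects: dict[str, dict[str, float]] = field(default_factory=dict)


def _sample_ids(conditions, n_replicates) -> tuple[list[str], list[str], list]:
    sample_ids, conds, reps = [], [], []
    for c in conditions:
        nrep = n_replicates[c] if isinstance(n_replicates, dict) else n_replicates
        for r in range(1, nrep + 1):
            sample_ids.append(f"{c}_r{r}")
            conds.append(c)
            reps.append(r)
    return sample_ids, conds, reps


def generate_timecourse_study(config: SimulationConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Generate a time-course study plus ground truth.

    The design mirrors a 5-time-point, 3-replicate amputation series:
    per-condition means model with Gaussian log2 noise.  Planted
    structure (in precedence order: modules from the tail of the gene
    list, hub/dependents at user-chosen ids, DE genes and low-expressed
    genes among the remainder) is recorded in the returned
    :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config._gene_ids()
    n = config.n_genes
    sample_ids, conds, reps = _sample_ids(config.conditions, config.n_replicates)
    n_samp = len(sample_ids)
    cond_idx = {c: i for i, c in enumerate(config.conditions)}
    cond_of_sample = np.array([cond_idx[c] for c in conds])

    truth = GroundTruth()

    # role assignment -------------------------------------------------
    module_genes: dict[str, tuple[int, ModuleSpec]] = {}
    pos = n
    for mi, mod in enumerate(config.module_spec, start=1):
        for g in genes[pos - mod.size : pos]:
            module_genes[g] = (mi, mod)
            truth.module_membership[g] = mi
        pos -= mod.size
    hub_ids: set[str] = set()
    if config.hub_spec is not None:
        hub_ids = {config.hub_spec.hub} | {d[0] for d in config.hub_spec.dependents}
        clash = hub_ids & set(module_genes)
        if clash:
            raise ConfigError(f"hub_spec genes overlap planted modules: {sorted(clash)}")
    free = [g for g in genes if g not in module_genes and g not in hub_ids]
    n_de = int(round(config.de_fraction * n))
    de_genes = list(rng.choice(free, size=min(n_de, len(free)), replace=False))
    truth.de_genes = set(de_genes)
    remaining = [g for g in free if g not in truth.de_genes]
    n_low = int(round(config.low_expression_fraction * n))
    low_genes = list(rng.choice(remaining, size=min(n_low, len(remaining)), replace=False))
    truth.low_genes = set(low_genes)

    # expression ------------------------------------------------------
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    mat = np.empty((n, n_samp))
    gene_pos = {g: i for i, g in enumerate(genes)}

    de_effect_draws = {
        g: np.concatenate([[0.0], rng.normal(0.0, config.effect_size_sd, size=len(config.conditions) - 1)])
        for g in de_genes
    }
    for g, eff in de_effect_draws.items():
        truth.de_effects[g] = {c: float(eff[cond_idx[c]]) for c in config.conditions}

    module_latents = {
        mi: rng.standard_normal(n_samp) for mi in range(1, len(config.module_spec) + 1)
    }
    hub_signal = None
    if config.hub_spec is not None:
        hub_signal = config.hub_spec.hub_sd * rng.standard_normal(n_samp)
        if config.hub_spec.profile:
            prof = np.asarray(config.hub_spec.profile, dtype=float)
            hub_signal = hub_signal + (prof - prof.mean())[cond_of_sample]

    for i, g in enumerate(genes):
        b = baselines[i]
        if g in truth.low_genes:
            row = rng.normal(config.expression_floor - 2.0, 0.3, size=n_samp)
            row = np.minimum(row, config.expression_floor - 0.2)
        elif g in module_genes:
            mi, mod = module_genes[g]
            eps = rng.standard_normal(n_samp)
            sig = np.sqrt(mod.rho) * module_latents[mi] + np.sqrt(1.0 - mod.rho) * eps
            row = b + config.module_signal_sd * sig
            if mod.profile:
                row = row + np.asarray(mod.profile)[cond_of_sample]
        elif config.hub_spec is not None and g == config.hub_spec.hub:
            row = b + hub_signal
        elif config.hub_spec is not None and g in {d[0] for d in config.hub_spec.dependents}:
            dep = next(d for d in config.hub_spec.dependents if d[0] == g)
            _, sign, mag, rsd = dep
            row = b + sign * mag * hub_signal + rng.normal(0.0, rsd, size=n_samp)
        else:
            row = b + rng.normal(0.0, config.noise_sd, size=n_samp)
            if g in de_effect_draws:
                row = row + de_effect_draws[g][cond_of_sample]
        mat[i] = row

    if config.hub_spec is not None:
        truth.hub_edges = [
            (config.hub_spec.hub, dep, sign, mag)
            for dep, sign, mag, _ in config.hub_spec.dependents
        ]

    # probes -----------------------------------------------------------
    feature_rows, feature_ids, feature_genes = [], [], []
    for i, g in enumerate(genes):
        if isinstance(config.n_probes_per_gene, tuple):
            k = int(rng.integers(config.n_probes_per_gene[0], config.n_probes_per_gene[1] + 1))
        else:
            k = config.n_probes_per_gene
        for p in range(1, k + 1):
            noise = rng.normal(0.0, config.probe_noise_sd, size=n_samp) if k > 1 or config.probe_noise_sd > 0 else 0.0
            if p == 1:
                noise = 0.0  # first probe reports the gene signal itself
            feature_rows.append(mat[i] + noise)
            feature_ids.append(f"{g}_p{p}")
            feature_genes.append(g)

    values = pd.DataFrame(np.vstack(feature_rows), index=feature_ids, columns=sample_ids)
    study = ExpressionStudy(
        values=values,
        gene_symbols=pd.Series(feature_genes, index=feature_ids),
        conditions=pd.Series(conds, index=sample_ids),
        replicates=pd.Series(reps, index=sample_ids),
        condition_order=list(config.conditions),
    )
    return study, truth


def generate_concordant_pair(
    config: SimulationConfig,
    concordant_fraction: float,
    profile_noise_sd: float,
    seed: int,
    n_replicates_b: int | dict = 2,
    profile_sd: float = 1.0,
) -> tuple[ExpressionStudy, ExpressionStudy, GroundTruth]:
    """Generate two studies sharing condition-mean profiles for a planted
    fraction of genes.

    Every gene gets a random per-condition profile (sd ``profile_sd``)
    in study A; concordant genes reuse that profile in study B up to
    ``profile_noise_sd`` perturbation, the rest draw independent
    profiles.  Study B may have fewer (or unbalanced) replicates, as in
    a second deposited dataset.
    """
    config.validate()
    if not 0.0 <= concordant_fraction <= 1.0:
        raise ConfigError("concordant_fraction must be in [0, 1]")
    if profile_noise_sd < 0:
        raise ConfigError("profile_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    genes = config._gene_ids()
    n = config.n_genes
    n_cond = len(config.conditions)

    profiles_a = rng.normal(0.0, profile_sd, size=(n, n_cond))
    n_conc = int(round(concordant_fraction * n))
    concordant = list(rng.choice(genes, size=n_conc, replace=False)) if n_conc else []
    conc_set = set(concordant)
    profiles_b = rng.normal(0.0, profile_sd, size=(n, n_cond))
    for i, g in enumerate(genes):
        if g in conc_set:
            profiles_b[i] = profiles_a[i] + rng.normal(0.0, profile_noise_sd, size=n_cond)

    def build(profiles, n_replicates, tag):
        sample_ids, conds, reps = _sample_ids(config.conditions, n_replicates)
        cond_idx = {c: i for i, c in enumerate(config.conditions)}
        cond_of_sample = np.array([cond_idx[c] for c in conds])
        baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
        mat = (
            baselines[:, None]
            + profiles[:, cond_of_sample]
            + rng.normal(0.0, config.noise_sd, size=(n, len(sample_ids)))
        )
        values = pd.DataFrame(mat, index=genes, columns=sample_ids)
        return ExpressionStudy(
            values=values,
            gene_symbols=pd.Series(genes, index=genes),
            conditions=pd.Series(conds, index=sample_ids),
            replicates=pd.Series(reps, index=sample_ids),
            condition_order=list(config.conditions),
        )

    study_a = build(profiles_a, config.n_replicates, "a")
    study_b = build(profiles_b, n_replicates_b, "b")
    truth = GroundTruth(concordant_genes=conc_set)
    return study_a, study_b, truth


# ----------------------------------------------------------------------
# qPCR Cq tables
# ----------------------------------------------------------------------

CQ_COLUMNS = ["sample", "condition", "gene", "replicate", "cq", "efficiency"]


def generate_qpcr_table(
    fold_changes: dict[str, float],
    efficiencies: dict[str, float],
    n_biological_replicates: int = 3,
    cq_noise_sd: float = 0.0,
    reference_genes: tuple[str, ...] = ("ef1a", "rpl13a", "tuba1"),
    seed: int = 0,
    days: tuple[str, ...] = ("1d", "3d"),
    n_technical_replicates: int = 2,
    base_cq_mean: float = 22.0,
    sample_loading_sd: float = 0.15,
) -> pd.DataFrame:
    """Generate a Cq table whose efficiency-corrected dCq structure
    recovers ``fold_changes`` in expectation.

    Cq_(s,g) = base_g - (log2 q_(s,g) + log2 m_s) / log2 E_g + noise,
    where q is the condition-dependent relative quantity (2**log2FC in
    injured arms, 1 in sham) and m_s a sample-specific template-loading
    factor that the multi-reference normalisation must cancel.
    Technical measures are duplicated per the qPCR protocol.
    """
    genes = sorted(set(fold_changes) | set(reference_genes))
    for g in genes:
        if g not in efficiencies:
            raise ConfigError(f"missing amplification efficiency for gene {g!r}")
        if not 1.0 < efficiencies[g] <= 2.0:
            raise ConfigError(f"efficiency for {g!r} must be in (1, 2]")
    for g in reference_genes:
        if fold_changes.get(g, 0.0) != 0.0:
            raise ConfigError(f"reference gene {g!r} must have fold change 0")
    rng = np.random.default_rng(seed)
    base_cq = {g: base_cq_mean + rng.uniform(-2.0, 2.0) for g in genes}

    rows = []
    for day in days:
        for arm in ("sham", "injured"):
            cond = f"{arm}-{day}"
            for b in range(1, n_biological_replicates + 1):
                sample = f"{cond}_b{b}"
                log2_m = rng.normal(0.0, sample_loading_sd) if sample_loading_sd > 0 else 0.0
                for g in genes:
                    fc = fold_changes.get(g, 0.0) if arm == "injured" else 0.0
                    e = efficiencies[g]
                    true_cq = base_cq[g] - (fc + log2_m) / np.log2(e)
                    for t in range(1, n_technical_replicates + 1):
                        cq = true_cq + (rng.normal(0.0, cq_noise_sd) if cq_noise_sd > 0 else 0.0)
                        rows.append((sample, cond, g, t, cq, e))
    return pd.DataFrame(rows, columns=CQ_COLUMNS)


# ----------------------------------------------------------------------
# Ground-truth persistence (plain key-value text)
# ----------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    lines = [
        "de_genes\t" + ",".join(sorted(truth.de_genes)),
        "module_membership\t"
        + ",".join(f"{g}:{m}" for g, m in sorted(truth.module_membership.items())),
        "hub_edges\t"
        + ",".join(f"{h}>{d}:{s}:{m}" for h, d, s, m in truth.hub_edges),
        "concordant_genes\t" + ",".join(sorted(truth.concordant_genes)),
        "low_genes\t" + ",".join(sorted(truth.low_genes)),
    ]
    Path(path).write_text("\n".join(lines) + "\n")
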