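"""Synthetic TCGA-like cohorts with a planted proliferation factor.

The generator emulates the statistical structure the pipeline assumes:

* a latent proliferation factor ``f ~ N(0,1)`` per sample co-regulates a
  signature block (the metagene genes) with loading ``lambda`` and,
  configurably, the repair genes with loading ``rho``;
* a second latent factor ``u ~ N(0,1)``, independent of ``f``, carries the
  planted residual survival signal: planted repair genes load on ``u`` with
  loading ``phi`` (pairwise residual correlation ``phi**2`` within the
  planted set, a realistic co-pathway strength at the 0.6 default);
* age and stage are mildly correlated with ``f`` (confounding) and carry
  their own proportional-hazards effects;
* survival times are exponential proportional-hazards with linear predictor
  ``beta_u*u + gamma*f + age and stage terms``, where ``beta_u`` is derived
  as ``planted_log_hazard / phi`` so that each planted gene's marginal
  per-SD log-hazard equals the configured ``planted_log_hazard`` exactly;
  right-censoring is administrative at the quantile of the realized times
  matching the target censoring fraction;
* mutation / deletion / amplification tables are per-group Bernoulli draws
  at configured per-gene-tumor probabilities.

Mediation modes:

``residual-signal``
    beta > 0: planted genes predict survival beyond proliferation, so
    metagene adjustment must NOT remove significance.
``fully-mediated``
    beta = 0 and planted genes load strongly on ``f``: every association
    with survival runs through proliferation, so metagene adjustment must
    restore null behaviour.
``null``
    no gene-survival association at all.

Expression values are exponentiated latent-normal draws (non-negative,
skewed, RNA-Seq-normalized-like); the rank-based VDW transform downstream
makes this marginal choice immaterial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog as _catalog
from .io import GenomicEventsInput

MEDIATION_MODES = ("residual-signal", "fully-mediated", "null")

#: Per-gene-tumor event probabilities by gene group (driver vs repair).
DEFAULT_EVENT_RATES = {
    "driver": {"mutation": 0.15, "deletion": 0.02, "amplification": 0.03},
    "repair": {"mutation": 0.02, "deletion": 0.01, "amplification": 0.015},
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_samples: int = 400
    n_repair_genes: int = 121
    n_metagene_genes: int = 131
    metagene_loading: float = 0.8        # lambda: signature genes on f
    repair_proliferation_loading: float = 0.3   # rho: repair genes on f
    planted_loading: float = 0.6         # phi: planted genes on u
    n_planted: int = 10
    planted_log_hazard: float = 0.5      # marginal per-SD log-hazard per planted gene
    proliferation_log_hazard: float = 0.5  # gamma, per SD of f
    age_log_hazard: float = 0.3          # per SD of age
    stage_log_hazard: float = 0.3        # per unit of centered stage ordinal
    age_factor_corr: float = 0.3         # corr(age, f)
    stage_factor_corr: float = 0.3       # corr(stage latent, f)
    stage_probs: tuple = (0.35, 0.3, 0.2, 0.15)
    baseline_rate: float = 0.01          # exponential hazard per month at eta=0
    censoring_target: float = 0.4
    mediation_mode: str = "residual-signal"
    has_stage: bool = True
    cancer_code: str = "synthetic"
    event_rates: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_EVENT_RATES.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mediation_mode not in MEDIATION_MODES:
            raise ValueError(f"mediation_mode must be one of {MEDIATION_MODES}")
        if not (0 <= self.censoring_target < 1):
            raise ValueError("censoring_target must be in [0, 1)")
        if self.n_planted > self.n_repair_genes:
            raise ValueError("more planted genes than repair genes")
        for g, rates in self.event_rates.items():
            for k, p in rates.items():
                if not (0 <= p <= 1):
                    raise ValueError(f"event probability {g}/{k} outside [0,1]")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    expression: pd.DataFrame     # genes x samples, non-negative
    clinical: pd.DataFrame
    events: GenomicEventsInput
    truth: dict
    repair_genes: list[str]
    metagene_genes: list[str]
    driver_genes: list[str]


_STAGE_LABELS = ("Stage I", "Stage II", "Stage III", "Stage IV")


def _loading_mix(rng, n, factor, loading):
    """loading*factor + sqrt(1-loading^2)*noise, unit marginal variance."""
    return loading * factor + np.sqrt(max(0.0, 1 - loading ** 2)) * rng.standard_normal(n)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort under the configured study conditions.

    Deterministic given ``config.seed``.  Repair gene names come from the
    packaged pathway catalog (survival pool order); metagene genes are
    PCNASIG### matching the packaged synthetic signature.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples

    cat = _catalog.load_packaged_catalog()
    pool = _catalog.survival_gene_pool(cat)
    if cfg.n_repair_genes > len(pool):
        raise ValueError(f"at most {len(pool)} repair genes available")
    repair_genes = pool[: cfg.n_repair_genes]
    metagene_genes = [f"PCNASIG{i:03d}" for i in range(1, cfg.n_metagene_genes + 1)]
    drivers = _catalog.load_packaged_driver_lists()
    driver_genes = (drivers[cfg.cancer_code].genes if cfg.cancer_code in drivers
                    else drivers["breast"].genes)

    # latent factors
    f = rng.standard_normal(n)                    # proliferation
    u = rng.standard_normal(n)                    # residual survival factor

    # covariates, confounded with f
    age_z = _loading_mix(rng, n, f, cfg.age_factor_corr)
    age_years = np.clip(60 + 12 * age_z, 20, 95)
    stage_latent = _loading_mix(rng, n, f, cfg.stage_factor_corr)
    cuts = np.quantile(stage_latent, np.cumsum(cfg.stage_probs)[:-1])
    stage_ord = np.searchsorted(cuts, stage_latent)        # 0..3
    stage_labels = [_STAGE_LABELS[k] for k in stage_ord]

    # expression latents
    planted_idx = np.arange(cfg.n_planted)
    rho = np.full(cfg.n_repair_genes, cfg.repair_proliferation_loading)
    phi = np.zeros(cfg.n_repair_genes)
    if cfg.mediation_mode == "residual-signal":
        phi[planted_idx] = cfg.planted_loading
    elif cfg.mediation_mode == "fully-mediated":
        # planted genes are survival-associated only through proliferation
        rho[planted_idx] = cfg.planted_loading
    # "null": no planted structure beyond baseline rho

    noise_sd = np.sqrt(np.clip(1 - rho ** 2 - phi ** 2, 0.0, None))
    repair_latent = (rho[:, None] * f + phi[:, None] * u
                     + noise_sd[:, None] * rng.standard_normal((cfg.n_repair_genes, n)))
    meta_latent = (cfg.metagene_loading * f
                   + np.sqrt(1 - cfg.metagene_loading ** 2)
                   * rng.standard_normal((cfg.n_metagene_genes, n)))

    # survival; beta_u scaled so each planted gene's marginal per-SD
    # log-hazard equals planted_log_hazard
    if cfg.mediation_mode == "residual-signal":
        if cfg.planted_loading <= 0:
            raise ValueError("planted_loading must be positive in residual-signal mode")
        beta = cfg.planted_log_hazard / cfg.planted_loading
    else:
        beta = 0.0
    gamma = cfg.proliferation_log_hazard if cfg.mediation_mode != "null" else 0.0
    eta = beta * u + gamma * f
    eta = eta + cfg.age_log_hazard * age_z
    if cfg.has_stage:
        eta = eta + cfg.stage_log_hazard * (stage_ord - stage_ord.mean())
    raw_t = rng.exponential(1.0 / (cfg.baseline_rate * np.exp(eta)))
    if cfg.censoring_target > 0:
        cutoff = np.quantile(raw_t, 1 - cfg.censoring_target)
        os_months = np.minimum(raw_t, cutoff)
        os_event = (raw_t <= cutoff).astype(int)
    else:
        os_months, os_event = raw_t, np.ones(n, dtype=int)

    samples = [f"S{i:04d}" for i in range(n)]
    expr = np.exp(np.vstack([repair_latent, meta_latent]))
    expression = pd.DataFrame(expr, index=repair_genes + metagene_genes,
                              columns=samples)
    clinical = pd.DataFrame({
        "sample": samples,
        "os_months": np.round(os_months, 4),
        "os_event": os_event,
        "age_years": np.round(age_years, 1),
        "stage": stage_labels if cfg.has_stage else [""] * n,
        "cancer_code": cfg.cancer_code,
    })

    events = simulate_event_tables(
        cfg, {"driver": driver_genes, "repair": repair_genes}, samples, rng)

    truth = {
        "f": f, "u": u,
        "planted_genes": [repair_genes[i] for i in planted_idx],
        "beta_per_gene": {repair_genes[i]: beta * phi[i] for i in range(cfg.n_repair_genes)},
        "beta_u": beta, "gamma_f": gamma,
        "rho": rho, "phi": phi,
        "event_probs": cfg.event_rates,
        "censoring_fraction": float(1 - os_event.mean()),
    }
    return SyntheticCohort(
        expression=expression, clinical=clinical, events=events, truth=truth,
        repair_genes=repair_genes, metagene_genes=metagene_genes,
        driver_genes=driver_genes,
    )


def simulate_event_tables(
    config: SimulationConfig,
    groups: dict[str, list[str]],
    samples: list[str],
    rng: np.random.Generator | None = None,
) -> GenomicEventsInput:
    """Bernoulli event tables per gene group.

    Mutations become long-format pathogenic records; deletions and
    amplifications share one CNA matrix, so they can never co-occur for a
    gene-sample pair (deletion wins the tie, drawn first).
    """
    rng = rng or np.random.default_rng(config.seed)
    n = len(samples)
    mut_rows = []
    cna_blocks = []
    gene_order = []
    for group, genes in groups.items():
        rates = config.event_rates.get(group, config.event_rates["repair"])
        g = len(genes)
        mut = rng.random((g, n)) < rates["mutation"]
        for gi, si in zip(*np.nonzero(mut)):
            mut_rows.append((genes[gi], samples[si], 1))
        del_draw = rng.random((g, n)) < rates["deletion"]
        amp_draw = (rng.random((g, n)) < rates["amplification"]) & ~del_draw
        cna = np.zeros((g, n), dtype=int)
        cna[del_draw] = -2
        cna[amp_draw] = 2
        cna_blocks.append(cna)
        gene_order.extend(genes)
    mutations = pd.DataFrame(mut_rows, columns=["gene", "sample", "pathogenic"])
    cna = pd.DataFrame(np.vstack(cna_blocks) if cna_blocks else np.zeros((0, n), int),
                       index=gene_order, columns=samples)
    return GenomicEventsInput(mutations=mutations, cna=cna)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path,
                 config: SimulationConfig | None = None) -> dict[str, Path]:
    """Write the four flat files io reads, plus a ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "mutations": out / "mutations.tsv",
        "cna": out / "cna.tsv",
        "truth": out / "ground_truth.json",
    }
    cohort.expression.to_csv(paths["expression"], sep="\t")
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    cohort.events.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    cohort.events.cna.to_csv(paths["cna"], sep="\t")
    truth = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in cohort.truth.items()
    }
    if config is not None:
        truth["config"] = asdict(config)
    paths["truth"].write_text(json.dumps(truth, indent=1, default=str))
    return paths
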