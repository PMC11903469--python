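"""Synthetic survival cohorts with planted favorable/unfavorable gene programs.

The generator emulates the statistical structure the signature-discovery
analysis assumes: right-skewed positive expression (log-normal per gene) with
correlation blocks inside each planted program, and three positively
correlated right-censored endpoints (DOR, EFS, PFS) whose hazards depend
log-linearly on the standardized log-expression of the planted genes.
Favorable genes carry negative log-hazard effects (high expression protects),
unfavorable genes positive ones.  Everything is deterministic given the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

from .cohort import ClinicalTable, Cohort, ExpressionMatrix, align_cohort

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_survival",
    "generate_cohort",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults are desk-scale analogues of the study design: 134 pretreatment
    samples on the CAR-T arm, a 200-gene panel with two small planted
    programs of effect |beta| = 0.8 per standardized log-expression unit, an
    exponential baseline hazard with ~6-month median event time, and light
    independent censoring giving roughly 70% observed events.
    """

    n_samples: int = 134
    n_genes: int = 200
    n_favorable: int = 5
    n_unfavorable: int = 5
    beta_favorable: float = -0.8
    beta_unfavorable: float = 0.8
    block_correlation: float = 0.3
    baseline_hazard: float = np.log(2) / 180.0  # per day; 180-day median at lp=0
    censor_rate: float = 1.0 / 600.0  # per day
    endpoint_coupling: float = 0.9
    responder_fraction: float = 0.8
    seed: int = 0
    # fraction of samples assigned to the comparator (SOC) arm, and the
    # multiplier applied to planted effects in that arm (0 = predictive-only
    # signal, 1 = equally prognostic in both arms)
    soc_fraction: float = 0.0
    soc_effect_multiplier: float = 1.0
    # EFS events include progression plus additional event types, so its
    # hazard is inflated relative to PFS by construction
    efs_hazard_inflation: float = 1.25
    timepoint: str = "pretreatment"
    # seed of the per-gene location/dispersion parameters; defaults to `seed`.
    # Give two cohorts the same panel_seed to place them on the same gene
    # panel (e.g. pretreatment vs at-progression sample sets).
    panel_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_favorable + self.n_unfavorable > self.n_genes:
            raise ValueError("planted programs cannot exceed the gene panel size")
        if not (0 <= self.block_correlation < 1):
            raise ValueError("block_correlation must lie in [0, 1)")
        if not (0 <= self.endpoint_coupling <= 1):
            raise ValueError("endpoint_coupling must lie in [0, 1]")
        if not (0 < self.responder_fraction <= 1):
            raise ValueError("responder_fraction must lie in (0, 1]")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValueError("hazard and censoring rates must be positive")
        if not (0 <= self.soc_fraction < 1):
            raise ValueError("soc_fraction must lie in [0, 1)")
        if self.efs_hazard_inflation < 1:
            raise ValueError("efs_hazard_inflation must be >= 1")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    favorable_genes: list[str]
    unfavorable_genes: list[str]
    effects: dict[str, float]
    #: per-sample log-hazard contribution of the planted genes (shared across
    #: endpoints; arm multipliers applied downstream)
    linear_predictor: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _program_latents(rng: np.random.Generator, n_genes: int, n_samples: int,
                     rho: float, members: np.ndarray) -> np.ndarray:
    """Standard-normal latents; genes in ``members`` share pairwise correlation rho."""
    z = rng.standard_normal((n_genes, n_samples))
    if rho > 0 and len(members) > 1:
        shared = rng.standard_normal(n_samples)
        z[members] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * z[members]
    return z


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a log-normal expression matrix with planted correlated programs."""
    rng = np.random.default_rng([config.seed, 0])
    nf, nu = config.n_favorable, config.n_unfavorable
    gene_ids = (
        [f"FAV{i + 1:03d}" for i in range(nf)]
        + [f"UNF{i + 1:03d}" for i in range(nu)]
        + [f"BG{i + 1:04d}" for i in range(config.n_genes - nf - nu)]
    )
    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]

    fav_idx = np.arange(nf)
    unf_idx = np.arange(nf, nf + nu)
    z = rng.standard_normal((config.n_genes, config.n_samples))
    for members in (fav_idx, unf_idx):
        if config.block_correlation > 0 and len(members) > 1:
            shared = rng.standard_normal(config.n_samples)
            z[members] = (
                np.sqrt(config.block_correlation) * shared
                + np.sqrt(1 - config.block_correlation) * z[members]
            )

    # per-gene log-scale location and dispersion spanning the dynamic range
    # of normalized linear counts; drawn from the panel seed so cohorts can
    # share a gene panel while differing in samples
    panel_rng = np.random.default_rng(
        [config.seed if config.panel_seed is None else config.panel_seed, 10]
    )
    log_mean = panel_rng.uniform(np.log(20.0), np.log(2000.0), size=config.n_genes)
    log_sd = panel_rng.uniform(0.3, 0.8, size=config.n_genes)
    values = np.exp(log_mean[:, None] + log_sd[:, None] * z)

    expr = ExpressionMatrix(gene_ids, sample_ids, values, unit_label="synthetic_linear_count")

    # effects act on standardized log-expression, so configured betas are
    # scale-free even though the pipeline consumes linear counts
    logx = np.log(values)
    zx = (logx - logx.mean(axis=1, keepdims=True)) / logx.std(axis=1, keepdims=True)
    effects = {g: config.beta_favorable for g in gene_ids[:nf]}
    effects.update({g: config.beta_unfavorable for g in gene_ids[nf:nf + nu]})
    beta = np.zeros(config.n_genes)
    beta[fav_idx] = config.beta_favorable
    beta[unf_idx] = config.beta_unfavorable
    lp = beta @ zx

    truth = GroundTruth(
        favorable_genes=gene_ids[:nf],
        unfavorable_genes=gene_ids[nf:nf + nu],
        effects=effects,
        linear_predictor=lp,
    )
    return expr, truth


def simulate_survival(expr: ExpressionMatrix, truth: GroundTruth,
                      config: SimulationConfig) -> ClinicalTable:
    """Draw arm labels, responder flags and three coupled censored endpoints.

    Event times are exponential given the planted linear predictor
    (proportional hazards hold exactly).  Cross-endpoint dependence uses a
    Gaussian copula on the event-time quantiles with correlation equal to
    ``endpoint_coupling``: endpoints are independent at 0 and share their
    quantile (identical per-sample ranking) at 1, while every marginal stays
    exactly exponential.  Censoring is independent exponential per endpoint.
    """
    import pandas as pd

    rng = np.random.default_rng([config.seed, 1])
    n = expr.n_samples
    lp = np.asarray(truth.linear_predictor, dtype=float)
    if lp.shape != (n,):
        raise ValueError("ground-truth linear predictor does not match the matrix")

    n_soc = int(round(config.soc_fraction * n))
    arm = np.array(["axi-cel"] * n, dtype=object)
    soc_pos = rng.permutation(n)[:n_soc]
    arm[soc_pos] = "SOC"
    lp_eff = np.where(arm == "SOC", config.soc_effect_multiplier * lp, lp)

    # unfavorable-program score drives a weak anti-correlation with response
    if truth.unfavorable_genes:
        unf = expr.subset_genes(truth.unfavorable_genes).values
        logu = np.log(unf)
        zu = (logu - logu.mean(axis=1, keepdims=True)) / logu.std(axis=1, keepdims=True)
        unf_score = zu.mean(axis=0)
        unf_score = (unf_score - unf_score.mean()) / (unf_score.std() or 1.0)
    else:
        unf_score = np.zeros(n)
    if config.responder_fraction >= 1.0:
        responder = np.ones(n, bool)
    else:
        logit = np.log(config.responder_fraction / (1 - config.responder_fraction))
        p_resp = 1.0 / (1.0 + np.exp(-(logit - 0.5 * unf_score)))
        responder = rng.uniform(size=n) < p_resp

    c = config.endpoint_coupling
    z_shared = rng.standard_normal(n)
    hazards = {
        "DOR": config.baseline_hazard,
        "EFS": config.baseline_hazard * config.efs_hazard_inflation,
        "PFS": config.baseline_hazard,
    }
    cols: dict[str, np.ndarray] = {}
    for ep, h0 in hazards.items():
        z_ep = np.sqrt(c) * z_shared + np.sqrt(1 - c) * rng.standard_normal(n)
        u = _st.norm.cdf(z_ep)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        t_event = -np.log(u) / (h0 * np.exp(lp_eff))
        t_cens = rng.exponential(1.0 / config.censor_rate, size=n)
        cols[f"{ep.lower()}_time"] = np.minimum(t_event, t_cens)
        cols[f"{ep.lower()}_event"] = (t_event <= t_cens).astype(float)

    base = pd.Timestamp("2020-01-01")
    dates = [
        (base + pd.Timedelta(days=int(d))).date().isoformat()
        for d in rng.integers(0, 365, size=n)
    ]
    table = pd.DataFrame(
        {
            "sample_id": expr.sample_ids,
            "subject_id": [f"SUBJ{i + 1:04d}" for i in range(n)],
            "arm": arm,
            "timepoint": config.timepoint,
            "collection_date": dates,
            "batch_id": rng.integers(1, 11, size=n),
            "coding_read_fraction": np.round(rng.uniform(0.3, 0.9, size=n), 4),
            "coo": rng.choice(["GCB", "non-GCB"], size=n, p=[0.55, 0.45]),
            "hgbl_flag": rng.choice(["yes", "not_applicable"], size=n, p=[0.1, 0.9]),
            "double_expressor_flag": rng.choice(
                ["yes", "not_applicable"], size=n, p=[0.15, 0.85]
            ),
            "myc_rearranged_flag": rng.choice(
                ["yes", "not_applicable"], size=n, p=[0.1, 0.9]
            ),
            "responder_flag": np.where(responder, "yes", "no"),
            "dor_time": cols["dor_time"],
            "dor_event": cols["dor_event"],
            "efs_time": cols["efs_time"],
            "efs_event": cols["efs_event"],
            "pfs_time": cols["pfs_time"],
            "pfs_event": cols["pfs_event"],
        }
    )
    return ClinicalTable(table)


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Expression + survival simulation composed into an aligned cohort."""
    expr, truth = simulate_expression(config)
    clinical = simulate_survival(expr, truth, config)
    return align_cohort(expr, clinical), truth
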