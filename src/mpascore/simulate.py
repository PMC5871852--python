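"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

A latent per-sample MAPK-activity factor drives correlated expression of the
10 signature genes; housekeeping and negative-control genes are independent
of it.  Drug sensitivity (mean viability and IC50) is monotonically coupled
to activity, mutation flags are Bernoulli with a configurable (default zero)
activity coupling, and survival times follow an exponential baseline hazard
scaled by exp(beta_surv * score) with uniform censoring.  Everything flows
through a single numpy Generator, so a (config, seed) pair reproduces the
cohort bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ClinicalTable, ExpressionMatrix
from .score import ScoreTable
from .signatures import CTRL_GENES, MPAS_GENES, NEGATIVE_CONTROL_GENES
from .doseresponse import DoseResponseSet, SensitivityRecord

__all__ = [
    "CohortConfig",
    "SimulatedCohort",
    "generate_expression",
    "generate_dose_response",
    "generate_clinical",
    "simulate_cohort",
    "default_dose_grid",
    "expected_censoring_fraction",
]


def default_dose_grid(n: int = 9, lo: float = 0.0015, hi: float = 10.0) -> np.ndarray:
    """Vehicle point plus a log-spaced micromolar dose grid (default 0.0015-10)."""
    return np.concatenate([[0.0], np.geomspace(lo, hi, n)])


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters; defaults are panel-scale and documented in the docs.

    Activity is the latent factor in arbitrary z-like units.  Panel counts
    are ``round(exp(c0 + loading * activity + noise))`` for signature genes
    and ``round(exp(c0 + noise))`` for housekeeping genes, so log expression
    is linear in activity.
    """

    n_samples: int = 200
    # latent activity
    mu_activity: float = 0.0
    sigma_activity: float = 1.0
    # expression
    platform: str = "panel"
    gene_loading: float = 1.0          # per-signature-gene slope on activity (ln scale)
    sigma_gene: float = 0.5            # ln-scale expression noise sd
    baseline_log_count: float = 5.0    # ln baseline for signature/housekeeping (~150 counts)
    control_log_count: float = 1.8     # ln baseline for negative controls (~6 counts)
    # drug sensitivity
    sensitivity_coupling: float = 1.0  # k in MV = sigmoid(-k (a - a0)) + noise
    sensitivity_midpoint: float = 0.0  # a0
    mv_noise_sd: float = 0.1
    ic50_log10_intercept: float = 0.0  # median IC50 of 1 uM at average activity
    ic50_log10_slope: float = 0.5      # decades of IC50 per activity unit
    ic50_noise_sd: float = 0.25
    hill: float = 1.0
    viability_noise_sd: float = 0.05
    n_replicates: int = 3
    # mutations
    mutation_rate: float = 0.3
    mutation_coupling: float = 0.0     # logit shift per activity unit (default: none)
    # survival
    baseline_hazard: float = 0.1       # events per time unit at score 0
    beta_survival: float = float(np.log(1.5))
    censoring_max: float = 32.0        # uniform censoring horizon (~30% censoring)
    # optional binary subtype covariate with its own hazard effect
    subtype_rate: float = 0.5
    subtype_log_hr: float = 0.0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.platform not in ("panel", "rnaseq"):
            raise ValueError("platform must be 'panel' or 'rnaseq'")
        for name in ("sigma_activity", "sigma_gene", "mv_noise_sd", "ic50_noise_sd",
                     "viability_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sensitivity_coupling <= 0:
            raise ValueError("sensitivity_coupling must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 <= self.mutation_rate <= 1 or not 0 <= self.subtype_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_max <= 0:
            raise ValueError("censoring_max must be > 0")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


def _expression_values(
    cfg: CohortConfig, activity: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(activity)
    rows = {}
    for g in MPAS_GENES:
        ln = cfg.baseline_log_count + cfg.gene_loading * activity + rng.normal(0, cfg.sigma_gene, n)
        rows[g] = ln
    for g in CTRL_GENES:
        rows[g] = cfg.baseline_log_count + rng.normal(0, cfg.sigma_gene, n)
    if cfg.platform == "panel":
        for g in NEGATIVE_CONTROL_GENES:
            rows[g] = cfg.control_log_count + rng.normal(0, cfg.sigma_gene, n)
    df = pd.DataFrame(rows).T
    df.columns = _sample_ids(n)
    vals = np.exp(df.to_numpy())
    if cfg.platform == "panel":
        vals = np.maximum(np.rint(vals), 0.0)
    df.loc[:, :] = vals
    return df


def generate_expression(
    cfg: CohortConfig, rng: np.random.Generator
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw the latent activity and a raw expression matrix driven by it.

    Returns the matrix in state ``raw`` (integer counts for panel mode,
    continuous positive values for rnaseq) together with the latent activity
    vector, which downstream tests use as the recovery oracle.
    """
    cfg.validate()
    activity = rng.normal(cfg.mu_activity, cfg.sigma_activity, cfg.n_samples)
    df = _expression_values(cfg, activity, rng)
    return ExpressionMatrix(data=df, platform=cfg.platform, state="raw"), activity


def generate_dose_response(
    cfg: CohortConfig,
    activity: np.ndarray,
    rng: np.random.Generator,
    doses: np.ndarray | None = None,
) -> tuple[list[DoseResponseSet], dict[float, ExpressionMatrix]]:
    """Viability curves plus per-dose treated expression sharing one inhibition.

    Each line gets an IC50 from its activity (log10 IC50 = c - d * a + noise)
    and a Hill inhibition E(d) = d^h / (d^h + IC50^h).  Viability is
    1 - E(d) plus replicate noise, and treated expression at dose d is
    generated from the inhibited activity a * (1 - E(d)), so the score
    profile and the viability curve decay together by construction.
    """
    cfg.validate()
    activity = np.asarray(activity, dtype=float)
    if doses is None:
        doses = default_dose_grid()
    doses = np.asarray(doses, dtype=float)
    n = len(activity)
    ids = _sample_ids(n)

    log10_ic50 = (
        cfg.ic50_log10_intercept
        - cfg.ic50_log10_slope * activity
        + rng.normal(0, cfg.ic50_noise_sd, n)
    )
    ic50 = 10.0 ** log10_ic50

    pos = doses > 0
    effect = np.zeros((n, len(doses)))
    effect[:, pos] = doses[pos][None, :] ** cfg.hill / (
        doses[pos][None, :] ** cfg.hill + ic50[:, None] ** cfg.hill
    )

    dr_sets = []
    for i, line in enumerate(ids):
        v = 1.0 - effect[i][:, None] + rng.normal(
            0, cfg.viability_noise_sd, (len(doses), cfg.n_replicates)
        )
        dr_sets.append(DoseResponseSet(line_id=line, doses=doses, viability=v))

    expr_by_dose: dict[float, ExpressionMatrix] = {}
    for j, d in enumerate(doses):
        treated = activity * (1.0 - effect[:, j])
        df = _expression_values(cfg, treated, rng)
        expr_by_dose[float(d)] = ExpressionMatrix(
            data=df, platform=cfg.platform, state="raw"
        )
    return dr_sets, expr_by_dose


def sensitivity_records(
    cfg: CohortConfig, activity: np.ndarray, rng: np.random.Generator
) -> list[SensitivityRecord]:
    """Per-line IC50, mean viability and mutation flags coupled to activity.

    A closed-form shortcut to the full dose-response simulation: MV comes
    from the logistic activity link with Gaussian noise (clipped to
    (-0.5, 1.5)), IC50 from the log-linear link, and the mutation flag from
    a Bernoulli whose logit is shifted by ``mutation_coupling * activity``.
    """
    cfg.validate()
    activity = np.asarray(activity, dtype=float)
    n = len(activity)
    ids = _sample_ids(n)
    mv = 1.0 / (1.0 + np.exp(cfg.sensitivity_coupling * (activity - cfg.sensitivity_midpoint)))
    mv = np.clip(mv + rng.normal(0, cfg.mv_noise_sd, n), -0.5, 1.5)
    log10_ic50 = (
        cfg.ic50_log10_intercept
        - cfg.ic50_log10_slope * activity
        + rng.normal(0, cfg.ic50_noise_sd, n)
    )
    base_logit = np.log(cfg.mutation_rate / (1 - cfg.mutation_rate)) if 0 < cfg.mutation_rate < 1 else None
    if base_logit is None:
        p_mut = np.full(n, float(cfg.mutation_rate))
    else:
        p_mut = 1.0 / (1.0 + np.exp(-(base_logit + cfg.mutation_coupling * activity)))
    flags = (rng.random(n) < p_mut).astype(int)
    return [
        SensitivityRecord(
            line_id=ids[i],
            ic50=float(10.0 ** log10_ic50[i]),
            mean_viability=float(mv[i]),
            mutation_flags={"KRAS": int(flags[i])},
        )
        for i in range(n)
    ]


def generate_clinical(
    cfg: CohortConfig,
    scores: ScoreTable,
    rng: np.random.Generator,
    activity: np.ndarray | None = None,
) -> ClinicalTable:
    """Survival times with hazard lambda0 * exp(beta_surv*score [+ subtype effect]).

    Event times are exponential per sample, censoring is Uniform(0, c_max);
    the observed time is the minimum and ``event`` marks true events.
    Mutation flags and the binary subtype covariate are included as columns.
    """
    cfg.validate()
    s = np.asarray(scores.scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n = len(s)
    subtype = (rng.random(n) < cfg.subtype_rate).astype(int)
    rate = cfg.baseline_hazard * np.exp(cfg.beta_survival * s + cfg.subtype_log_hr * subtype)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0.0, cfg.censoring_max, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # guard against zero observed times from floating underflow
    time = np.maximum(time, 1e-12)

    if activity is None:
        activity = np.zeros(n)
    base_logit = (
        np.log(cfg.mutation_rate / (1 - cfg.mutation_rate))
        if 0 < cfg.mutation_rate < 1 else None
    )
    if base_logit is None:
        p_mut = np.full(n, float(cfg.mutation_rate))
    else:
        p_mut = 1.0 / (1.0 + np.exp(-(base_logit + cfg.mutation_coupling * np.asarray(activity))))
    mutation = (rng.random(n) < p_mut).astype(int)

    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": list(scores.sample_ids),
                "time": time,
                "event": event,
                "score": s,
                "mutation": mutation,
                "subtype": subtype,
            }
        )
    )


def expected_censoring_fraction(cfg: CohortConfig, scores: np.ndarray) -> float:
    """Analytic censoring fraction for Exp(rate) events vs Uniform(0, c) censoring.

    A record is censored when the event time exceeds the uniform censor draw:
    P(censored | rate) = E[exp(-rate C)] = (1 - exp(-rate c)) / (rate c),
    averaged over the per-sample rates implied by the scores.
    """
    rate = cfg.baseline_hazard * np.exp(cfg.beta_survival * np.asarray(scores, float))
    x = rate * cfg.censoring_max
    return float(np.mean((1.0 - np.exp(-x)) / x))


@dataclass(frozen=True)
class SimulatedCohort:
    """Bundle of everything one seeded simulation produces."""

    config: CohortConfig
    seed: int
    expression: ExpressionMatrix
    activity: np.ndarray
    records: list[SensitivityRecord]
    clinical: ClinicalTable | None = None
    scores: ScoreTable | None = None


def simulate_cohort(
    cfg: CohortConfig, seed: int, with_clinical: bool = True
) -> SimulatedCohort:
    """Generate expression, sensitivity records and (optionally) clinical data.

    The clinical hazard is driven by the pathway score computed through the
    standard platform pipeline, so survival analyses exercise the same code
    path real data would.
    """
    from .pipeline import score_pipeline  # local import to avoid cycle

    rng = np.random.default_rng(seed)
    expr, activity = generate_expression(cfg, rng)
    records = sensitivity_records(cfg, activity, rng)
    clinical = None
    scores = None
    if with_clinical:
        scores = score_pipeline(expr)
        clinical = generate_clinical(cfg, scores, rng, activity=activity)
    return SimulatedCohort(
        config=cfg, seed=seed, expression=expr, activity=activity,
        records=records, clinical=clinical, scores=scores,
    )
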