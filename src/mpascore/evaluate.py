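"""Benchmarking pathway scores against alternative drug-sensitivity predictors.

A predictor is reduced to binary sensitive/resistant calls by a median split
of its continuous output, then compared with the IC50-derived ground truth
through TPR = TP/(TP+FN), FPR = FP/(FP+TN) and ACC = (TP+TN)/N, plus the
Spearman correlation of the continuous predictor with observed sensitivity
(1 - mean viability).  The comparator set mirrors the standard benchmark:
the pathway score itself, a housekeeping CTRL score (random-chance control),
a genome-wide elastic-net expression model, and a driver-mutation flag.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from .expression import ExpressionMatrix, zscore_genes
from .score import compute_ctrl_score, compute_score
from .signatures import GeneSignature, mpas_signature
from .doseresponse import SensitivityRecord

__all__ = [
    "ConfusionSummary",
    "EnetModel",
    "BenchmarkDistribution",
    "median_classify",
    "confusion_metrics",
    "mutation_as_predictor",
    "rank_correlation",
    "percentile_in_reference",
    "fit_enet",
    "compare_predictors",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts and the derived rates for binary sensitivity calls."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float | None:
        den = self.tp + self.fn
        return self.tp / den if den else None

    @property
    def fpr(self) -> float | None:
        den = self.fp + self.tn
        return self.fp / den if den else None

    @property
    def acc(self) -> float:
        return (self.tp + self.tn) / self.n


@dataclass(frozen=True)
class BenchmarkDistribution:
    """Reference correlation coefficients from competing predictors."""

    reference_values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.reference_values)
        if any(not -1.0 <= v <= 1.0 for v in vals):
            raise ValueError("reference correlations must lie in [-1, 1]")
        object.__setattr__(self, "reference_values", vals)


def median_classify(scores: np.ndarray, direction: str = "high_is_positive") -> np.ndarray:
    """Binary calls by median split: positive iff strictly above the median.

    Ties at the median are negative; ``direction="low_is_positive"`` negates
    the scores first (used when low predicted viability means sensitive).
    """
    s = np.asarray(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("median classification requires >= 2 samples")
    if direction == "low_is_positive":
        s = -s
    elif direction != "high_is_positive":
        raise ValueError("direction must be 'high_is_positive' or 'low_is_positive'")
    if np.ptp(s) == 0:
        raise ValueError("all scores identical: median classification undefined")
    return s > np.median(s)


def confusion_metrics(predicted: Sequence[bool], truth: Sequence[bool]) -> ConfusionSummary:
    """Count TP/FP/TN/FN of predicted-positive calls against true labels."""
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    return ConfusionSummary(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        tn=int(np.sum(~pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )


def mutation_as_predictor(flags: Sequence[int]) -> np.ndarray:
    """Predict sensitive iff the driver mutation is present."""
    f = np.asarray(flags)
    if not np.isin(f, (0, 1)).all():
        raise ValueError("mutation flags must be 0/1")
    return f.astype(bool)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("rank correlation requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def percentile_in_reference(value: float, ref: BenchmarkDistribution) -> float:
    """Top-oriented percentile of *value* in the reference distribution.

    0 means the value beats every reference predictor; 100 means every
    reference value is strictly greater.
    """
    vals = np.asarray(ref.reference_values)
    if len(vals) == 0:
        raise ValueError("reference distribution is empty")
    return 100.0 * float(np.sum(vals > value)) / len(vals)


# ---------------------------------------------------------------------------
# elastic-net expression model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnetModel:
    """Elastic-net expression model of drug sensitivity (mixing alpha = 0.5).

    Genes are standardized to mean 0 / sd 1 before the penalized fit to
    remove absolute-expression bias; the penalty is chosen by k-fold
    cross-validation over a log-spaced grid, and ``cv_r`` is the Pearson
    correlation of out-of-fold predictions with the response.
    """

    gene_ids: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    alpha_mix: float
    lambda_: float
    cv_r: float
    feature_means: np.ndarray
    feature_sds: np.ndarray

    @property
    def selected_features(self) -> tuple[str, ...]:
        return tuple(g for g, c in zip(self.gene_ids, self.coefficients) if c != 0.0)

    def predict(self, m: ExpressionMatrix) -> np.ndarray:
        missing = sorted(set(self.gene_ids) - set(m.gene_ids))
        if missing:
            raise ValueError(f"model genes absent from matrix: {missing}")
        x = m.data.loc[list(self.gene_ids)].to_numpy().T
        xs = (x - self.feature_means) / self.feature_sds
        return xs @ self.coefficients + self.intercept


def _lambda_grid(xs: np.ndarray, y: np.ndarray, l1_ratio: float, n: int = 100) -> np.ndarray:
    yc = y - y.mean()
    lam_max = np.max(np.abs(xs.T @ yc)) / (len(y) * l1_ratio)
    return np.geomspace(lam_max, lam_max * 1e-4, n)


def fit_enet(
    expr: ExpressionMatrix,
    response: Sequence[float],
    alpha_mix: float = 0.5,
    folds: int = 5,
    seed: int = 0,
) -> EnetModel:
    """Fit the elastic-net viability model with CV-selected penalty.

    ``expr`` must be log-scale expression (state ``log_transformed``);
    ``response`` is the per-sample mean viability.  Fold assignment is
    deterministic given ``seed``.
    """
    if expr.state not in ("log_transformed", "zscored"):
        raise ValueError(f"fit_enet requires log-scale expression, got state={expr.state!r}")
    y = np.asarray(response, dtype=float)
    if len(y) != expr.n_samples:
        raise ValueError("response length must match sample count")
    if not np.isfinite(y).all():
        raise ValueError("response must be finite")
    if expr.n_samples < 30:
        raise ValueError("elastic-net fit requires >= 30 samples")
    if expr.n_samples < folds:
        raise ValueError("fewer samples than folds")

    x = expr.values.T  # samples x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    xs = np.zeros_like(x)
    xs[:, keep] = (x[:, keep] - mu[keep]) / sd[keep]

    lambdas = _lambda_grid(xs[:, keep], y, alpha_mix)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(xs))

    cv_mse = np.zeros(len(lambdas))
    warnings.filterwarnings("ignore", category=ConvergenceWarning)
    for tr, te in splits:
        # warm-started path along the decreasing-penalty grid
        coef = None
        for j, lam in enumerate(lambdas):
            en = ElasticNet(alpha=lam, l1_ratio=alpha_mix, max_iter=5000, tol=1e-4)
            if coef is not None:
                en.coef_ = coef.copy()
                en.intercept_ = float(y[tr].mean())
                en.warm_start = True
            en.fit(xs[tr], y[tr])
            coef = en.coef_
            pred = en.predict(xs[te])
            cv_mse[j] += np.sum((pred - y[te]) ** 2)
    cv_mse /= len(y)
    best_lambda = float(lambdas[int(np.argmin(cv_mse))])

    # out-of-fold predictions at the selected penalty
    oof = np.empty_like(y)
    for tr, te in splits:
        en = ElasticNet(alpha=best_lambda, l1_ratio=alpha_mix, max_iter=5000, tol=1e-4)
        en.fit(xs[tr], y[tr])
        oof[te] = en.predict(xs[te])
    if np.ptp(oof) == 0 or np.ptp(y) == 0:
        cv_r = 0.0
    else:
        cv_r = float(stats.pearsonr(oof, y)[0])

    final = ElasticNet(alpha=best_lambda, l1_ratio=alpha_mix, max_iter=20000, tol=1e-5)
    final.fit(xs, y)
    return EnetModel(
        gene_ids=tuple(expr.gene_ids),
        coefficients=final.coef_.copy(),
        intercept=float(final.intercept_),
        alpha_mix=alpha_mix,
        lambda_=best_lambda,
        cv_r=cv_r,
        feature_means=mu,
        feature_sds=np.where(keep, sd, 1.0),
    )


# ---------------------------------------------------------------------------
# predictor comparison
# ---------------------------------------------------------------------------

def compare_predictors(
    expr_log: ExpressionMatrix,
    records: Sequence[SensitivityRecord],
    signature: GeneSignature | None = None,
    predictors: Sequence[str] = ("mpas", "ctrl", "enet", "mutation"),
    mutation_flag: str = "KRAS",
    seed: int = 0,
) -> pd.DataFrame:
    """One row of confusion metrics + rank correlation per predictor.

    Ground truth is the IC50-derived sensitive/resistant label of each
    record; the continuous comparison axis is observed sensitivity 1 - MV.
    ``expr_log`` must be log-scale expression with samples matching the
    records (order is aligned by line id).
    """
    signature = signature or mpas_signature()
    order = [r.line_id for r in records]
    missing = sorted(set(order) - set(expr_log.sample_ids))
    if missing:
        raise ValueError(f"records without expression: {missing}")
    expr_log = ExpressionMatrix(
        data=expr_log.data[order], platform=expr_log.platform, state=expr_log.state
    )

    truth = np.array([r.label == "sensitive" for r in records])
    mv = np.array([r.mean_viability for r in records])
    sensitivity = 1.0 - mv
    expr_z = zscore_genes(expr_log, zero_variance="zero")

    rows = []
    for name in predictors:
        if name == "mpas":
            cont = compute_score(expr_z, signature).scores
            pred = median_classify(cont, "high_is_positive")
        elif name == "ctrl":
            cont = compute_ctrl_score(expr_z).scores
            pred = median_classify(cont, "high_is_positive")
        elif name == "enet":
            model = fit_enet(expr_log, mv, seed=seed)
            pred_mv = model.predict(expr_log)
            pred = median_classify(pred_mv, "low_is_positive")
            cont = -pred_mv  # predicted sensitivity axis
        elif name == "mutation":
            flags = np.array([r.mutation_flags.get(mutation_flag, 0) for r in records])
            pred = mutation_as_predictor(flags)
            cont = flags.astype(float)
        else:
            raise ValueError(f"unknown predictor {name!r}")
        cm = confusion_metrics(pred, truth)
        if np.ptp(cont) == 0:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = rank_correlation(cont, sensitivity)
        rows.append(
            {
                "predictor": name,
                "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                "tpr": cm.tpr, "fpr": cm.fpr, "acc": cm.acc,
                "spearman_rho": rho, "p": p,
            }
        )
    return pd.DataFrame(rows)
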