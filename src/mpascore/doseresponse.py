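"""Viability processing, four-parameter-logistic fits, IC50/MV and dose profiles.

Viability is day-0 corrected and vehicle-relative: 1.0 means growth equal to
the vehicle control, 0.0 means cell stasis (no net growth since treatment
day) and negative values mean net cell death.  Sensitivity summaries are the
IC50 of a 4PL fit and the mean viability (MV) over the tested positive-dose
grid; the clinical serum-concentration rule calls a line sensitive when
IC50 < 1 uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .expression import ExpressionMatrix
from .signatures import GeneSignature

__all__ = [
    "DoseResponseSet",
    "CurveFit",
    "SensitivityRecord",
    "relative_viability",
    "fit_4pl",
    "mean_viability",
    "classify_sensitivity",
    "mpas_dose_profile",
    "DoseProfileResult",
]

#: fitted inhibition depths (top - bottom) below this are treated as no response
MIN_INHIBITION_DEPTH = 0.05

#: sensitivity threshold: average clinical serum concentration upper bound, uM
SENSITIVITY_THRESHOLD_UM = 1.0


@dataclass(frozen=True)
class DoseResponseSet:
    """Dose grid and replicate viabilities for one cell line.

    ``viability`` is (n_doses, n_replicates); doses are in micromolar,
    ascending, with an optional leading vehicle dose of 0.
    """

    line_id: str
    doses: np.ndarray
    viability: np.ndarray
    day0_corrected: bool = True

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        viab = np.atleast_2d(np.asarray(self.viability, dtype=float))
        if doses.ndim != 1:
            raise ValueError("doses must be 1-D")
        if (doses < 0).any():
            raise ValueError("doses must be >= 0")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if viab.shape[0] != len(doses):
            raise ValueError("viability must have one row per dose")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "viability", viab)

    @property
    def positive_mask(self) -> np.ndarray:
        return self.doses > 0

    @property
    def replicate_means(self) -> np.ndarray:
        return self.viability.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.doses):
            for r, v in enumerate(self.viability[i]):
                rows.append({"line_id": self.line_id, "dose_um": d, "replicate": r + 1, "viability": v})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CurveFit:
    """Four-parameter logistic fit v(d) = bottom + (top-bottom)/(1+(d/ic50)^hill)."""

    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    no_inhibition: bool = False
    extrapolated: bool = False

    def predict(self, doses: np.ndarray) -> np.ndarray:
        d = np.asarray(doses, dtype=float)
        if self.no_inhibition or not np.isfinite(self.ic50):
            return np.full_like(d, self.top)
        return _four_pl(d, self.top, self.bottom, self.ic50, self.hill)


@dataclass(frozen=True)
class SensitivityRecord:
    """Per-line sensitivity summary feeding predictor evaluation."""

    line_id: str
    ic50: float
    mean_viability: float
    mutation_flags: dict[str, int] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return classify_sensitivity(self.ic50)


# ---------------------------------------------------------------------------
# viability processing
# ---------------------------------------------------------------------------

def relative_viability(
    raw: np.ndarray,
    day0: np.ndarray,
    vehicle: np.ndarray,
    doses: Sequence[float],
    line_id: str = "line",
) -> DoseResponseSet:
    """Convert raw luminescence to day-0-corrected, vehicle-relative viability.

    ``viability = (raw - mean(day0)) / (mean(vehicle) - mean(day0))`` so the
    vehicle maps to 1.0, the day-0 level (stasis) to 0.0, and values below
    day 0 (net cell death) stay negative.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if (raw < 0).any():
        raise ValueError("raw luminescence must be >= 0")
    d0 = float(np.mean(day0))
    veh = float(np.mean(vehicle))
    if veh <= d0:
        raise ValueError(
            f"vehicle mean ({veh:g}) must exceed day-0 mean ({d0:g}): no growth window"
        )
    viab = (raw - d0) / (veh - d0)
    return DoseResponseSet(line_id=line_id, doses=np.asarray(doses, float), viability=viab)


def mean_viability(dr: DoseResponseSet) -> float:
    """Unweighted mean of per-dose replicate-mean viabilities over positive doses."""
    mask = dr.positive_mask
    if mask.sum() < 2:
        raise ValueError("mean viability requires >= 2 positive doses")
    return float(dr.replicate_means[mask].mean())


def classify_sensitivity(ic50: float) -> str:
    """Sensitive iff IC50 < 1 uM; 1 uM exactly and +inf are resistant."""
    if np.isnan(ic50) or ic50 <= 0:
        raise ValueError(f"IC50 must be > 0 (or +inf for no inhibition), got {ic50!r}")
    return "sensitive" if ic50 < SENSITIVITY_THRESHOLD_UM else "resistant"


# ---------------------------------------------------------------------------
# 4PL fitting
# ---------------------------------------------------------------------------

def _four_pl(d: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    with np.errstate(over="ignore"):
        frac = np.zeros_like(d, dtype=float)
        pos = d > 0
        frac[pos] = 1.0 / (1.0 + np.power(d[pos] / ic50, hill))
    out = np.empty_like(frac)
    out[pos] = bottom + (top - bottom) * frac[pos]
    out[~pos] = top
    return out


def fit_4pl(dr: DoseResponseSet) -> CurveFit:
    """Least-squares 4PL fit with a deterministic multi-start grid.

    Starts combine hill in {0.5, 1, 2} with IC50 at each tested positive
    dose (plus a flat start), which makes the fit reproducible without
    random restarts.  Data with fitted inhibition depth below
    ``MIN_INHIBITION_DEPTH`` — including flat and monotone-increasing
    series — are flagged ``no_inhibition`` with IC50 = +inf.
    """
    pos_doses = dr.doses[dr.positive_mask]
    if len(np.unique(pos_doses)) < 4:
        raise ValueError("4PL fit requires >= 4 distinct positive doses")
    means = dr.replicate_means
    if not np.all(np.isfinite(means)):
        raise ValueError("replicate means must be finite")

    # fit on every replicate point
    d_all = np.repeat(dr.doses, dr.viability.shape[1])
    v_all = dr.viability.ravel()

    lo_d, hi_d = pos_doses.min(), pos_doses.max()
    bounds_lo = np.array([-np.inf, 0.0, np.log10(lo_d) - 3.0, np.log(0.05)])
    bounds_hi = np.array([np.inf, np.inf, np.log10(hi_d) + 3.0, np.log(20.0)])

    def residuals(theta: np.ndarray) -> np.ndarray:
        top, delta, log10_ic50, log_hill = theta
        return _four_pl(d_all, top, top - delta, 10.0 ** log10_ic50, np.exp(log_hill)) - v_all

    v_top = means[dr.doses == dr.doses.min()][0]
    depth0 = max(v_top - means.min(), 0.0)
    starts = [np.array([float(means.mean()), 0.0, np.log10(np.sqrt(lo_d * hi_d)), 0.0])]
    for hill0 in (0.5, 1.0, 2.0):
        for ic0 in pos_doses:
            starts.append(np.array([v_top, depth0, np.log10(ic0), np.log(hill0)]))

    best = None
    n_fail = 0
    for x0 in starts:
        x0 = np.clip(x0, bounds_lo, bounds_hi)
        try:
            res = optimize.least_squares(
                residuals, x0, bounds=(bounds_lo, bounds_hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:
            n_fail += 1
            continue
        if not res.success and not np.isfinite(res.cost):
            n_fail += 1
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(f"4PL fit failed to converge from any of {n_fail} starts")

    top, delta, log10_ic50, log_hill = best.x
    rss = float(2.0 * best.cost)
    flat_rss = float(np.sum((v_all - v_all.mean()) ** 2))
    if delta < MIN_INHIBITION_DEPTH:
        return CurveFit(
            top=float(v_all.mean()), bottom=float(v_all.mean()), ic50=float("inf"),
            hill=float("nan"), rss=min(rss, flat_rss), no_inhibition=True,
        )
    ic50 = float(10.0 ** log10_ic50)
    extrapolated = not (lo_d / 100.0 <= ic50 <= hi_d * 100.0)
    return CurveFit(
        top=float(top), bottom=float(top - delta), ic50=ic50,
        hill=float(np.exp(log_hill)), rss=rss, extrapolated=extrapolated,
    )


# ---------------------------------------------------------------------------
# dose-dependent pathway-score profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseProfileResult:
    """Per-dose pathway score of one line alongside its viability curve."""

    line_id: str
    doses: np.ndarray
    mpas: np.ndarray
    pearson_r: float
    mpas_fit: CurveFit
    viability_fit: CurveFit

    @property
    def ic50_ratio(self) -> float:
        """IC50 of score inhibition over IC50 of growth inhibition."""
        return self.mpas_fit.ic50 / self.viability_fit.ic50


def mpas_dose_profile(
    expr_by_dose: Mapping[float, ExpressionMatrix],
    sig: GeneSignature,
    dr: DoseResponseSet,
) -> DoseProfileResult:
    """Track dose-dependent inhibition of the pathway score in one line.

    Expression at each dose is reduced to the ``dr.line_id`` sample,
    log2(x+1)-transformed if not already on log scale, and z-scored across
    the dose series of that line (not across a cohort), so the score profile
    is comparable to the line's own viability curve.  Returns the per-dose
    score, its Pearson correlation with viability, and 4PL fits of both the
    viability and the score profile rescaled to [0, 1].
    """
    expr_doses = np.array(sorted(expr_by_dose), dtype=float)
    if len(expr_doses) != len(dr.doses) or not np.allclose(expr_doses, dr.doses):
        raise ValueError("expression dose grid does not match viability dose grid")

    cols = []
    genes = None
    already_log = None
    for d in expr_doses:
        m = expr_by_dose[d]
        if genes is None:
            genes = m.gene_ids
            already_log = m.state in ("log_transformed", "zscored")
        if m.n_samples == 1:
            col = m.data.iloc[:, 0]
        elif dr.line_id in m.sample_ids:
            col = m.data[dr.line_id]
        else:
            raise ValueError(f"sample {dr.line_id!r} absent from expression at dose {d}")
        cols.append(col.reindex(genes).to_numpy())
    mat = np.column_stack(cols)

    present = [g for g in sig.genes if g in set(genes)]
    if not present:
        raise ValueError("no signature genes in dose-series expression")
    idx = [genes.index(g) for g in present]
    sub = mat[idx, :]
    if not already_log:
        if (sub < 0).any():
            raise ValueError("expression values must be >= 0 before log transform")
        sub = np.log2(sub + 1.0)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = np.inf  # constant gene carries no dose information
    z = (sub - mean) / sd
    mpas = z.sum(axis=0) / np.sqrt(len(present))

    viab = dr.replicate_means
    if np.ptp(mpas) == 0 or np.ptp(viab) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(mpas, viab)[0])

    viability_fit = fit_4pl(dr)
    # the score is unit-free, so it is min-max rescaled before the curve fit;
    # because rescaling stretches pure noise across [0, 1] as well, a fit is
    # only attempted when the profile shows a clear decreasing dose trend
    span = np.ptp(mpas)
    trend = stats.spearmanr(mpas, dr.doses)[0] if span > 0 else 0.0
    if span == 0 or trend > -0.6:
        mpas_fit = CurveFit(
            top=float(mpas.mean()), bottom=float(mpas.mean()), ic50=float("inf"),
            hill=float("nan"), rss=float(np.sum((mpas - mpas.mean()) ** 2)),
            no_inhibition=True,
        )
    else:
        rescaled = (mpas - mpas.min()) / span
        mpas_fit = fit_4pl(
            DoseResponseSet(line_id=dr.line_id, doses=dr.doses, viability=rescaled[:, None])
        )
    return DoseProfileResult(
        line_id=dr.line_id, doses=dr.doses, mpas=mpas,
        pearson_r=r, mpas_fit=mpas_fit, viability_fit=viability_fit,
    )
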