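"""Expression-matrix container, I/O, and the panel/RNA-seq normalization chain.

Panel (e.g. Nanostring-style) counts pass through
``raw -> background_filtered -> normalized -> log_transformed -> zscored``;
sequencing-style matrices that arrive already library-normalized skip the
panel steps and go ``raw -> log_transformed -> zscored``.  Every operation
checks the incoming state and returns a new matrix, so an out-of-order call
(e.g. z-scoring raw counts) fails loudly rather than producing a silently
wrong score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "filter_background",
    "normalize_housekeeping",
    "log_transform",
    "zscore_genes",
]

#: allowed processing states, in pipeline order
STATES = ("raw", "background_filtered", "normalized", "log_transformed", "zscored")

PLATFORMS = ("panel", "rnaseq")

#: counts below this are considered below background for panel data,
#: regardless of the negative controls
MIN_BACKGROUND = 10.0


class StateError(ValueError):
    """Raised when an operation receives a matrix in the wrong processing state."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression values with explicit platform and state.

    ``data`` is indexed by upper-cased gene symbol, columns are sample ids.
    Instances are immutable; transformations return new objects.
    """

    data: pd.DataFrame
    platform: str = "panel"
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; expected one of {PLATFORMS}")
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        idx = pd.Index([str(g).upper() for g in self.data.index], name="gene")
        if idx.has_duplicates:
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate gene symbols after case normalization: {dups}")
        if self.data.columns.has_duplicates:
            dups = sorted(set(self.data.columns[self.data.columns.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dups}")
        df = self.data.copy()
        df.index = idx
        df.columns = [str(c) for c in df.columns]
        if not np.issubdtype(df.to_numpy().dtype, np.number):
            raise ValueError("expression values must be numeric")
        object.__setattr__(self, "data", df.astype(float))

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def genes_present(self, genes: Iterable[str]) -> list[str]:
        """Subset of *genes* (case-insensitive) found in this matrix, in input order."""
        have = set(self.data.index)
        return [g.upper() for g in genes if g.upper() in have]

    def _require_state(self, allowed: Sequence[str], op: str) -> None:
        if self.state not in allowed:
            raise StateError(
                f"{op} requires state in {tuple(allowed)}, got {self.state!r} "
                f"(platform={self.platform})"
            )


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample survival outcome plus arbitrary covariates.

    ``time`` must be positive, ``event`` is 1 for death/progression and 0 for
    censoring; covariates live in extra columns of ``data``.
    """

    data: pd.DataFrame = field()

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in ("sample_id", "time", "event"):
            if col not in df.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        if (df["time"] <= 0).any():
            raise ValueError("survival times must be > 0")
        if not df["event"].isin((0, 1)).all():
            raise ValueError("event must be coded 0/1")
        df["event"] = df["event"].astype(int)
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("sample_id", "time", "event")]

    def covariate(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, format: str | None = None, platform: str = "panel") -> ExpressionMatrix:
    """Read a genes-x-samples matrix (first column = gene symbol, header = sample ids).

    ``format`` is ``"tsv"`` or ``"csv"``; when omitted it is inferred from the
    file suffix.  Non-numeric body cells and duplicated gene rows are errors.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if format not in ("tsv", "csv"):
        raise ValueError(f"format must be 'tsv' or 'csv', got {format!r}")
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    # locate offending cell for a useful parse error
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().to_numpy().sum() > df.isna().to_numpy().sum():
        bad = (body.isna() & ~df.isna())
        gene = bad.index[bad.any(axis=1).to_numpy().argmax()]
        col = bad.columns[bad.loc[gene].to_numpy().argmax()]
        raise ValueError(f"non-numeric expression value at gene {gene!r}, sample {col!r}")
    return ExpressionMatrix(data=body, platform=platform, state="raw")


def write_expression(m: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "\t" if format == "tsv" else ","
    m.data.to_csv(path, sep=sep)


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical CSV with columns sample_id, time, event, covariates..."""
    return ClinicalTable(pd.read_csv(path, comment="#"))


def write_clinical(tbl: ClinicalTable, path: str | Path) -> None:
    tbl.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# normalization chain
# ---------------------------------------------------------------------------

def _geometric_mean(x: np.ndarray, axis: int | None = None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return np.exp(np.mean(np.log(x), axis=axis))


def filter_background(m: ExpressionMatrix, negative_control_genes: Sequence[str]) -> ExpressionMatrix:
    """Floor panel counts at the per-sample background level.

    The background for a sample is ``max(10, geometric mean of its negative
    control counts)``; every count below it is raised to the floor, and the
    negative-control rows are dropped from the output.  Counts are floored
    rather than discarded so the matrix keeps its shape for downstream
    scoring.  If no negative-control gene is present, a fixed floor of 10 is
    used and a warning is emitted.
    """
    if m.platform != "panel":
        raise ValueError("background filtering applies to platform='panel' only")
    m._require_state(("raw",), "filter_background")
    if (m.values < 0).any():
        raise ValueError("panel counts must be >= 0")

    controls = m.genes_present(negative_control_genes)
    if controls:
        ctrl = m.data.loc[controls].to_numpy()
        # geometric mean of zero counts is taken as 0 -> floor stays at 10
        with np.errstate(divide="ignore"):
            logs = np.log(np.where(ctrl > 0, ctrl, np.nan))
        gm = np.exp(np.nanmean(logs, axis=0))
        gm = np.where(np.isnan(gm), 0.0, gm)
        floor = np.maximum(MIN_BACKGROUND, gm)
    else:
        warnings.warn(
            "no negative-control genes found; using fixed background floor of "
            f"{MIN_BACKGROUND:g}",
            stacklevel=2,
        )
        floor = np.full(m.n_samples, MIN_BACKGROUND)

    keep = [g for g in m.gene_ids if g not in set(controls)]
    out = m.data.loc[keep].copy()
    out_vals = np.maximum(out.to_numpy(), floor[np.newaxis, :])
    out.loc[:, :] = out_vals
    return ExpressionMatrix(data=out, platform=m.platform, state="background_filtered")


def normalize_housekeeping(m: ExpressionMatrix, housekeeping: Sequence[str]) -> ExpressionMatrix:
    """Scale each sample so housekeeping geometric means agree across samples.

    Per sample ``s`` the factor is ``f_s = G / g_s`` where ``g_s`` is the
    geometric mean of the housekeeping genes in ``s`` and ``G`` the geometric
    mean of the ``g_s`` across samples (i.e. the global housekeeping level).
    """
    if m.platform != "panel":
        raise ValueError("housekeeping normalization applies to platform='panel' only")
    m._require_state(("background_filtered",), "normalize_housekeeping")
    hk = [g.upper() for g in housekeeping]
    missing = sorted(set(hk) - set(m.gene_ids))
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {missing}")
    hk_vals = m.data.loc[hk].to_numpy()
    if (hk_vals <= 0).any():
        raise ValueError("housekeeping counts must be > 0 (run filter_background first)")
    per_sample = _geometric_mean(hk_vals, axis=0)
    factors = _geometric_mean(per_sample) / per_sample
    out = m.data * factors[np.newaxis, :]
    return ExpressionMatrix(data=out, platform=m.platform, state="normalized")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply log2(x + 1), the variance-stabilizing step before z-scoring."""
    allowed = ("normalized", "raw") if m.platform == "rnaseq" else ("normalized",)
    m._require_state(allowed, "log_transform")
    if (m.values < 0).any():
        raise ValueError("log transform requires non-negative values")
    out = np.log2(m.data + 1.0)
    return ExpressionMatrix(data=out, platform=m.platform, state="log_transformed")


def zscore_genes(m: ExpressionMatrix, zero_variance: str = "error") -> ExpressionMatrix:
    """Standardize each gene across samples to mean 0, population sd 1.

    Uses the population (divisor-N) standard deviation so that a two-sample
    cohort gives z = -1/+1 exactly.  ``zero_variance`` selects what happens to
    constant genes: ``"error"`` raises, ``"zero"`` emits a zero row with a
    warning.
    """
    # re-z-scoring an already standardized matrix is a no-op, so it is allowed
    if m.platform == "rnaseq":
        allowed = ("log_transformed", "normalized", "zscored")
    else:
        allowed = ("log_transformed", "zscored")
    m._require_state(allowed, "zscore_genes")
    if zero_variance not in ("error", "zero"):
        raise ValueError("zero_variance must be 'error' or 'zero'")
    if m.n_samples < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    vals = m.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = (sd.ravel() == 0)
    if flat.any():
        genes = [g for g, f in zip(m.gene_ids, flat) if f]
        if zero_variance == "error":
            raise ValueError(f"zero-variance genes: {genes}")
        warnings.warn(f"zero-variance genes set to 0: {genes}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[flat, :] = 0.0
    out = pd.DataFrame(z, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(data=out, platform=m.platform, state="zscored")
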