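"""Aggregated pathway-activity scores.

The MAPK Pathway Activity Score of a sample is the sum of the z-scored
expression of the signature genes divided by the square root of the number
of genes used:

    score_s = sum_i z_{i,s} / sqrt(n_used)

With population-sd z-scores this keeps the score on a stable scale across
signature sizes (a sample with every gene one sd above the cohort mean
scores sqrt(n)).  Scores are relative within the cohort whose z-scores they
were computed from; there is no absolute cross-cohort calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .signatures import GeneSignature, ctrl_signature

__all__ = ["ScoreTable", "compute_score", "compute_ctrl_score", "recenter_scores"]


@dataclass(frozen=True)
class ScoreTable:
    """Per-sample aggregated score for one signature."""

    sample_ids: tuple[str, ...]
    scores: np.ndarray
    signature_name: str
    n_genes_used: int

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1 or len(scores) != len(self.sample_ids):
            raise ValueError("one score per sample required")
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.scores)

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.sample_ids), name=self.signature_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "score": self.scores,
                "signature_name": self.signature_name,
                "n_genes_used": self.n_genes_used,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path: str | Path) -> "ScoreTable":
        df = pd.read_csv(path, comment="#")
        name = str(df["signature_name"].iloc[0]) if "signature_name" in df else "score"
        n_used = int(df["n_genes_used"].iloc[0]) if "n_genes_used" in df else 0
        return ScoreTable(
            sample_ids=tuple(df["sample_id"].astype(str)),
            scores=df["score"].to_numpy(dtype=float),
            signature_name=name,
            n_genes_used=n_used,
        )


def compute_score(
    m: ExpressionMatrix,
    sig: GeneSignature,
    missing: str = "error",
) -> ScoreTable:
    """Aggregate z-scored expression of ``sig`` into a per-sample score.

    ``missing="error"`` (default) requires every signature gene to be in the
    matrix; ``missing="subset"`` scores with the genes that are present,
    re-normalizing by sqrt(n_used) and warning about the omission — the mode
    used when a measurement panel covers only part of the signature.
    """
    if m.state != "zscored":
        raise ValueError(f"compute_score requires a zscored matrix, got state={m.state!r}")
    if missing not in ("error", "subset"):
        raise ValueError("missing must be 'error' or 'subset'")
    present = m.genes_present(sig.genes)
    absent = [g for g in sig.genes if g not in set(present)]
    if absent and missing == "error":
        raise ValueError(f"signature genes absent from matrix: {absent}")
    if not present:
        raise ValueError(f"no genes of signature {sig.name!r} present in matrix")
    if absent:
        warnings.warn(
            f"scoring {sig.name!r} with {len(present)}/{sig.n} genes "
            f"(missing: {absent}); dividing by sqrt({len(present)})",
            stacklevel=2,
        )
    z = m.data.loc[present].to_numpy()
    scores = z.sum(axis=0) / np.sqrt(len(present))
    return ScoreTable(
        sample_ids=tuple(m.sample_ids),
        scores=scores,
        signature_name=sig.name,
        n_genes_used=len(present),
    )


def compute_ctrl_score(m: ExpressionMatrix, missing: str = "error") -> ScoreTable:
    """Negative-control score from the 4 housekeeping genes (same formula)."""
    return compute_score(m, ctrl_signature(), missing=missing)


def recenter_scores(t: ScoreTable, reference: ScoreTable) -> ScoreTable:
    """Shift scores so that 0 is the mean of the reference cohort."""
    if len(reference) == 0:
        raise ValueError("reference score table is empty")
    shift = float(np.mean(reference.scores))
    return ScoreTable(
        sample_ids=t.sample_ids,
        scores=t.scores - shift,
        signature_name=t.signature_name,
        n_genes_used=t.n_genes_used,
    )
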