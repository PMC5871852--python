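"""End-to-end orchestration: simulate -> normalize -> score -> evaluate -> survive.

`score_pipeline` runs the platform-appropriate normalization chain and
aggregates the signature; `run_pipeline` executes a full YAML-configured run
writing deterministic artifacts, each CSV carrying a provenance comment
(package version, seed, config hash) in its first line.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .expression import (
    ExpressionMatrix,
    log_transform,
    normalize_housekeeping,
    filter_background,
    read_clinical,
    read_expression,
    write_clinical,
    write_expression,
    zscore_genes,
)
from .evaluate import compare_predictors
from .score import ScoreTable, compute_score
from .signatures import (
    CTRL_GENES,
    GeneSignature,
    NEGATIVE_CONTROL_GENES,
    load_signature_config,
    mpas_signature,
)
from .simulate import CohortConfig, simulate_cohort
from .survival import cox_fit, km_threshold_scan, multivariate_survival_report, sliding_window_scan
from .doseresponse import SensitivityRecord

log = logging.getLogger("mpascore")

__all__ = ["normalize_pipeline", "score_pipeline", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Aggregated configuration/validation failure raised before any stage runs."""


def normalize_pipeline(
    m: ExpressionMatrix,
    housekeeping=CTRL_GENES,
    negative_controls=NEGATIVE_CONTROL_GENES,
) -> ExpressionMatrix:
    """Run the state chain from raw values to a z-scored matrix.

    Panel counts go background filter -> housekeeping normalization ->
    log2(x+1) -> z-score; rnaseq values skip the panel-specific steps.
    """
    if m.state == "zscored":
        return m
    if m.platform == "panel":
        if m.state == "raw":
            m = filter_background(m, negative_controls)
        if m.state == "background_filtered":
            m = normalize_housekeeping(m, housekeeping)
        if m.state == "normalized":
            m = log_transform(m)
    else:
        if m.state in ("raw", "normalized"):
            m = log_transform(m)
    return zscore_genes(m, zero_variance="zero")


def score_pipeline(
    m: ExpressionMatrix,
    signature: GeneSignature | None = None,
    missing: str = "error",
    housekeeping=CTRL_GENES,
    negative_controls=NEGATIVE_CONTROL_GENES,
) -> ScoreTable:
    """Normalize a raw matrix and compute the aggregated pathway score."""
    z = normalize_pipeline(m, housekeeping=housekeeping, negative_controls=negative_controls)
    return compute_score(z, signature or mpas_signature(), missing=missing)


# ---------------------------------------------------------------------------
# full pipeline runs
# ---------------------------------------------------------------------------

def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=False)


def _validate_run_config(cfg: dict) -> list[str]:
    errors = []
    if not isinstance(cfg, dict):
        return ["run config must be a mapping"]
    if "simulate" not in cfg and "inputs" not in cfg:
        errors.append("config must contain either a 'simulate' block or an 'inputs' block")
    if "simulate" in cfg:
        unknown = set(cfg["simulate"]) - {f.name for f in CohortConfig.__dataclass_fields__.values()}
        if unknown:
            errors.append(f"unknown simulate parameters: {sorted(unknown)}")
    if "inputs" in cfg:
        for key in ("expression", "sensitivity"):
            p = cfg["inputs"].get(key)
            if p is None:
                errors.append(f"inputs block missing {key!r} path")
            elif not Path(p).exists():
                errors.append(f"input path does not exist: {p}")
        clin = cfg["inputs"].get("clinical")
        if clin is not None and not Path(clin).exists():
            errors.append(f"input path does not exist: {clin}")
    sig = cfg.get("signature")
    if sig is not None and not Path(sig).exists():
        errors.append(f"signature config does not exist: {sig}")
    if not isinstance(cfg.get("seed", 0), int):
        errors.append("seed must be an integer")
    for p in cfg.get("predictors", []):
        if p not in ("mpas", "ctrl", "enet", "mutation"):
            errors.append(f"unknown predictor {p!r}")
    return errors


def run_pipeline(cfg: dict[str, Any], out_dir: str | Path) -> dict[str, str]:
    """Execute the configured stages in dependency order; return the manifest.

    The manifest maps artifact names to paths; with the same config and seed
    a rerun produces byte-identical files.  On a stage failure the partial
    manifest is attached to the raised error.
    """
    errors = _validate_run_config(cfg)
    if errors:
        raise PipelineError("invalid run config:\n  - " + "\n  - ".join(errors))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    prov = f"mpascore v{__version__} seed={seed} config_sha256={_config_hash(cfg)}"
    manifest: dict[str, str] = {}

    signature = mpas_signature()
    housekeeping, neg_controls = CTRL_GENES, NEGATIVE_CONTROL_GENES
    if cfg.get("signature"):
        sig_cfg = load_signature_config(cfg["signature"])
        signature = GeneSignature("signature", sig_cfg["signature_genes"])
        housekeeping = sig_cfg["housekeeping_genes"]
        neg_controls = sig_cfg["negative_control_genes"]

    stage = "simulate"
    try:
        t0 = _time.perf_counter()
        if "simulate" in cfg:
            sim_cfg = CohortConfig(**cfg["simulate"])
            cohort = simulate_cohort(sim_cfg, seed)
            expr, clinical, records = cohort.expression, cohort.clinical, cohort.records
            expr_path = out / "expression.tsv"
            with open(expr_path, "w") as fh:
                fh.write(f"# {prov}\n")
                expr.data.to_csv(fh, sep="\t")
            manifest["expression"] = str(expr_path)
            sens = pd.DataFrame(
                [
                    {"line_id": r.line_id, "ic50_um": r.ic50, "mean_viability": r.mean_viability,
                     "label": r.label, **{f"mut_{k}": v for k, v in r.mutation_flags.items()}}
                    for r in records
                ]
            )
            _write_csv(sens, out / "sensitivity.csv", prov)
            manifest["sensitivity"] = str(out / "sensitivity.csv")
            _write_csv(clinical.data, out / "clinical.csv", prov)
            manifest["clinical"] = str(out / "clinical.csv")
            truth = {
                "seed": seed,
                "activity": cohort.activity.tolist(),
                "config": {k: getattr(sim_cfg, k) for k in sim_cfg.__dataclass_fields__},
            }
            (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
            manifest["truth"] = str(out / "truth.json")
        else:
            inputs = cfg["inputs"]
            expr = read_expression(inputs["expression"], platform=cfg.get("platform", "panel"))
            sens = pd.read_csv(inputs["sensitivity"], comment="#")
            records = [
                SensitivityRecord(
                    line_id=str(r["line_id"]), ic50=float(r["ic50_um"]),
                    mean_viability=float(r["mean_viability"]),
                    mutation_flags={
                        c[4:]: int(r[c]) for c in sens.columns if c.startswith("mut_")
                    },
                )
                for r in sens.to_dict("records")
            ]
            clinical = read_clinical(inputs["clinical"]) if inputs.get("clinical") else None
        log.info("stage simulate/load done in %.2fs", _time.perf_counter() - t0)

        stage = "score"
        t0 = _time.perf_counter()
        z = normalize_pipeline(expr, housekeeping=housekeeping, negative_controls=neg_controls)
        scores = compute_score(z, signature, missing=cfg.get("missing", "error"))
        score_df = scores.to_frame()
        _write_csv(score_df, out / "scores.csv", prov)
        manifest["scores"] = str(out / "scores.csv")
        log.info("stage score done in %.2fs", _time.perf_counter() - t0)

        stage = "evaluate"
        t0 = _time.perf_counter()
        predictors = cfg.get("predictors", ["mpas", "ctrl", "enet", "mutation"])
        expr_log = _to_log(expr, housekeeping, neg_controls)
        evaluation = compare_predictors(
            expr_log, records, signature=signature, predictors=predictors, seed=seed
        )
        _write_csv(evaluation, out / "evaluation.csv", prov)
        manifest["evaluation"] = str(out / "evaluation.csv")
        log.info("stage evaluate done in %.2fs", _time.perf_counter() - t0)

        if clinical is not None:
            stage = "survive"
            t0 = _time.perf_counter()
            surv_cfg = cfg.get("survival", {})
            terms = surv_cfg.get("terms", ["score"])
            fit = multivariate_survival_report(clinical, terms)
            _write_csv(fit.summary(), out / "cox.csv", prov)
            manifest["cox"] = str(out / "cox.csv")
            svals = clinical.covariate("score")
            tscan = km_threshold_scan(clinical, svals, **surv_cfg.get("threshold_scan", {}))
            _write_csv(tscan.table, out / "threshold_scan.csv", prov)
            manifest["threshold_scan"] = str(out / "threshold_scan.csv")
            wscan = sliding_window_scan(clinical, svals, **surv_cfg.get("window_scan", {}))
            _write_csv(wscan.table, out / "window_scan.csv", prov)
            manifest["window_scan"] = str(out / "window_scan.csv")
            log.info("stage survive done in %.2fs", _time.perf_counter() - t0)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(
            f"stage {stage!r} failed: {exc}; partial manifest: {manifest}"
        ) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _to_log(expr: ExpressionMatrix, housekeeping, neg_controls) -> ExpressionMatrix:
    """Bring a matrix to log scale without z-scoring (elastic-net input)."""
    m = expr
    if m.state == "log_transformed":
        return m
    if m.platform == "panel":
        if m.state == "raw":
            m = filter_background(m, neg_controls)
        if m.state == "background_filtered":
            m = normalize_housekeeping(m, housekeeping)
    return log_transform(m)
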