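"""Gene-set definitions for pathway-activity scoring.

The MPAS signature is the fixed 10-gene MAPK transcriptional-output set;
the CTRL signature is the 4 housekeeping genes used as a negative control
score that should carry no pathway information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "GeneSignature",
    "MPAS_GENES",
    "CTRL_GENES",
    "NEGATIVE_CONTROL_GENES",
    "mpas_signature",
    "ctrl_signature",
    "load_signature_config",
]

#: the 10 MAPK target genes aggregated into MPAS
MPAS_GENES = (
    "PHLDA1", "SPRY2", "SPRY4", "DUSP4", "DUSP6",
    "CCND1", "EPHA2", "EPHA4", "ETV4", "ETV5",
)

#: housekeeping genes forming the negative-control (CTRL) score
CTRL_GENES = ("MLH1", "SMARCA4", "U2AF", "CLTC")

#: synthetic negative-control probe names used by the panel simulator
NEGATIVE_CONTROL_GENES = tuple(f"NEG_{c}" for c in "ABCDEF")


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set; ``n`` is the √n divisor of the aggregate score."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        genes = tuple(g.upper() for g in self.genes)
        if len(genes) == 0:
            raise ValueError("signature must contain at least one gene")
        if len(set(genes)) != len(genes):
            raise ValueError(f"duplicate genes in signature {self.name!r}")
        object.__setattr__(self, "genes", genes)

    @property
    def n(self) -> int:
        return len(self.genes)


def mpas_signature() -> GeneSignature:
    return GeneSignature("MPAS", MPAS_GENES)


def ctrl_signature() -> GeneSignature:
    return GeneSignature("CTRL", CTRL_GENES)


def load_signature_config(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Load a YAML/JSON signature config.

    Expected keys: ``signature_genes``, ``housekeeping_genes``,
    ``negative_control_genes`` (the latter two optional, defaulting to the
    built-in CTRL genes and panel negative-control probes).
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict) or "signature_genes" not in cfg:
        raise ValueError(f"signature config {path} must define 'signature_genes'")
    return {
        "signature_genes": tuple(str(g).upper() for g in cfg["signature_genes"]),
        "housekeeping_genes": tuple(
            str(g).upper() for g in cfg.get("housekeeping_genes", CTRL_GENES)
        ),
        "negative_control_genes": tuple(
            str(g).upper() for g in cfg.get("negative_control_genes", NEGATIVE_CONTROL_GENES)
        ),
    }
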