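"""Pipeline configuration: every tunable threshold in one validated place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and defaults used by the full pipeline.

    Units: glucose_threshold mg C L^-1; pcd_lag hours; ev_threshold and
    explained variances percent; fold_threshold linear fold; alpha an
    adjusted-p cutoff; preedge window eV.
    """

    species: str = "paxillus"
    seed: int = 1
    # phases
    glucose_threshold: float = 1.0
    ammonium_threshold: float | None = None      # None -> 2% of initial
    pcd_lag: float = 150.0
    # MCR-ALS
    k_max: int = 6
    ev_threshold: float = 99.9
    mcr_tol: float = 1e-8
    mcr_max_iter: int = 500
    mcr_restarts: int = 5
    # Fe pre-edge
    preedge_window: tuple[float, float] = (7108.0, 7118.0)
    # pyrolysis
    toc_correction: str = "divide"
    # expression
    alpha: float = 0.01
    min_dispersion: float = 0.01
    top_quantile: float = 0.20
    min_fold: float = 2.0
    # response types
    fold_threshold: float = 2.0
    corr_threshold: float = 0.8
    permutation_B: int = 199
    # synthetic cohort
    n_per_pattern: int = 20
    n_null: int = 500

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "preedge_window" in data:
            data = {**data, "preedge_window": tuple(data["preedge_window"])}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["preedge_window"] = list(d["preedge_window"])
        return d

    def content_hash(self) -> str:
        """Stable hash of the configuration for the run manifest."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load a YAML (or JSON) config file, rejecting unknown keys."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return PipelineConfig.from_dict(data)
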