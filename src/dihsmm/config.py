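"""Run configuration: every tunable constant in one serialisable place.

A run is fully reproducible from a RunConfig plus its root seed: the root
seed spawns independent streams for each chain and each downstream stage
through :class:`numpy.random.SeedSequence`, so results do not depend on
scheduling or on which stages are re-run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .gibbs import ChainConfig
from .model import HyperParams

__all__ = ["AggregationConfig", "ClassificationConfig", "RunConfig"]


@dataclass
class AggregationConfig:
    n_bins: int = 200
    cut: float = 0.95
    min_mode_samples: int = 400
    min_cluster_frac: float = 0.01
    rhat_threshold: float = 1.05
    min_keep: int = 8


@dataclass
class ClassificationConfig:
    type_boundaries: tuple = (0.60, 0.78)
    symmetry_band: float = 0.10
    bias_band: float = 0.05


@dataclass
class RunConfig:
    """All knobs of a full pipeline run; defaults are the full-scale values."""

    hyper: HyperParams = field(default_factory=HyperParams)
    chains: ChainConfig = field(default_factory=ChainConfig)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    seed: int = 0

    _SECTIONS = {
        "hp": ("hyper", HyperParams),
        "chain": ("chains", ChainConfig),
        "agg": ("aggregation", AggregationConfig),
        "cls": ("classification", ClassificationConfig),
    }

    def to_flat_dict(self) -> dict:
        """Flat key-value form (``hp_L``, ``chain_thin``, ...)."""
        out = {"seed": self.seed}
        for prefix, (attr, _) in self._SECTIONS.items():
            for key, val in asdict(getattr(self, attr)).items():
                out[f"{prefix}_{key}"] = list(val) if isinstance(val, tuple) else val
        return out

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "RunConfig":
        kwargs = {"seed": int(flat.get("seed", 0))}
        for prefix, (attr, klass) in cls._SECTIONS.items():
            section = {}
            names = {f.name for f in fields(klass)}
            for key, val in flat.items():
                if key.startswith(prefix + "_") and key[len(prefix) + 1 :] in names:
                    name = key[len(prefix) + 1 :]
                    section[name] = tuple(val) if isinstance(val, list) else val
            kwargs[attr] = klass(**section)
        # the chain seed is derived from the root seed unless set explicitly
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_flat_dict(yaml.safe_load(fh) or {})

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_flat_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
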