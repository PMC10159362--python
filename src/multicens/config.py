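"""Run configuration shared by the CLI subcommands.

A YAML file can supply any subset of the knobs; CLI flags override file
values.  All randomness in a run funnels through the single ``seed``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields

import yaml

logger = logging.getLogger("multicens")


@dataclass
class RunConfig:
    p: float = 0.85            # restart/damping parameter of all solvers
    tol: float = 1e-10         # L-infinity convergence tolerance
    max_iter: int = 1000
    lam: float = 0.5           # RWR-H inter-layer jump probability
    top_k: int = 10000         # variance filter size per tissue
    prune_threshold: float | None = None  # optional edge-weight cutoff (off)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 <= self.p < 1):
            raise ValueError(f"p must lie in [0, 1); got {self.p}")
        if not (0 <= self.lam <= 1):
            raise ValueError(f"lambda must lie in [0, 1]; got {self.lam}")
        if self.tol <= 0 or self.max_iter <= 0 or self.top_k <= 0:
            raise ValueError("tol, max_iter and top_k must be positive")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def digest(self) -> str:
        """Short hash identifying the effective configuration."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def log_startup(self) -> None:
        logging.basicConfig(level=self.log_level)
        logger.info("config %s: %s", self.digest(), asdict(self))
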