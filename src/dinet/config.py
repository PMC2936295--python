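"""Run configuration: validated once, stamped into every output header."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import yaml

from .estimators import EstimatorConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, in one validated record.

    Serialized (as a short hash plus key=value pairs) into the header
    comment of every output file so results remain traceable to their
    settings.
    """

    estimator: str = "bspline"
    bins: int = 10
    spline_order: int = 3
    bandwidth: float | str = "auto"
    include_zero_pad: bool = False
    match_samples: bool = False
    precision_target: float | None = 0.4
    z_min: float | None = None
    top_k: int | None = None
    pseudocount: float = 0.5
    score_threshold: float | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.estimator_config()  # validates estimator fields
        selections = [
            self.precision_target is not None,
            self.z_min is not None,
            self.top_k is not None,
        ]
        if sum(selections) > 1:
            raise ValueError(
                "precision_target, z_min and top_k are mutually exclusive"
            )
        if self.precision_target is not None and not 0 < self.precision_target <= 1:
            raise ValueError("precision_target must be in (0, 1]")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")

    def estimator_config(self) -> EstimatorConfig:
        return EstimatorConfig(
            method=self.estimator,
            bins=self.bins,
            spline_order=self.spline_order,
            bandwidth=self.bandwidth,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header(self) -> str:
        pairs = " ".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
        return f"config {self.digest()} {pairs}"
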