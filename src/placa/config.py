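"""Run configuration: every pipeline knob with its default, YAML round-trip,
and the verbatim echo that goes into each JSON run report."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .inference import InferenceConfig
from .scoring import ScoringConfig


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run.

    Defaults follow the published procedure: 95% one-sided sign consistency,
    Euclidean activity-score normalisation, normal-CDF P-scores, leave-one-out
    resampling, and 4-of-5 experiment consensus.
    """

    alpha: float = 0.05
    two_sided: bool = False
    activity_norm: str = "L2"            # L2 | L1
    p_distribution: str = "normal"       # normal | t
    resampler: str = "jackknife"         # jackknife | bootstrap
    n_bootstrap: int = 0
    rcond_min: float = 1e-10
    max_missing: float = 0.2
    consensus_k: int = 4
    consensus_e: int = 5
    seed: int = 0
    baseline_condition: str = "baseline"

    def scoring(self) -> ScoringConfig:
        return ScoringConfig(activity_norm=self.activity_norm,
                             p_distribution=self.p_distribution)

    def inference(self) -> InferenceConfig:
        return InferenceConfig(alpha=self.alpha, two_sided=self.two_sided,
                               rcond_min=self.rcond_min,
                               max_missing=self.max_missing,
                               resampler=self.resampler,
                               n_bootstrap=self.n_bootstrap,
                               scoring=self.scoring())

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    @classmethod
    def from_overrides(cls, **overrides: Any) -> "RunConfig":
        return cls(**{k: v for k, v in overrides.items() if v is not None})
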