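"""Pipeline configuration shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    """Tunable parameters of the influence pipeline.

    Attributes
    ----------
    radius : float
        Spatial discretization threshold R in meters. Velocity vectors are
        computed from the displacement to the first fix at least ``radius``
        meters away. Default 10 m, a biologically meaningful scale for
        cohesive terrestrial foragers.
    q : float
        Reference quantile of the pooled signed predictor at which influence
        curves are evaluated. Default 0.9.
    min_obs : int
        Minimum number of (predictor, outcome) rows required to fit an
        influence curve for an individual. Default 200.
    max_gap : float
        Longest gap (seconds) that preprocessing bridges by linear
        interpolation. Longer gaps stay invalid. Default 10 s.
    n_boot : int
        Bootstrap replicates (resampling recording sessions) for the 90%
        score interval. Default 1000.
    symmetrize_turn : bool
        Evaluate the turn score as (P(q90) + 1 - P(q10)) / 2, which is exactly
        invariant under a left-right mirror of the data. The speed score is
        always the single upper-quantile evaluation because its baseline is
        not 1/2. Default True.
    displacement_mode : str
        'displacement' (default): the R-crossing uses straight-line
        displacement from the reference fix. 'path': cumulative path length.
    ci_level : float
        Bootstrap interval coverage. Default 0.90.
    """

    radius: float = 10.0
    q: float = 0.9
    min_obs: int = 200
    max_gap: float = 10.0
    n_boot: int = 1000
    symmetrize_turn: bool = True
    displacement_mode: str = "displacement"
    ci_level: float = 0.90
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.displacement_mode not in ("displacement", "path"):
            raise ValueError("displacement_mode must be 'displacement' or 'path'")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
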