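"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from .truth import FOLLOWUP_WEEKS


class RunConfig(BaseModel):
    """Everything a pipeline run depends on besides the data itself.

    Serializes losslessly to JSON; every random operation's seed is
    derived from ``seed`` plus a stage tag.
    """

    scenario: str | None = "paper_like"
    input_csv: str | None = None
    n_patients: int = 2000
    latent: bool = False
    weeks: list[int] = Field(default_factory=lambda: list(FOLLOWUP_WEEKS))
    seed: int = 0
    # estimation
    rule: str = "AND"
    folds: int = 10
    n_lambda: int = 50
    min_ratio: float = 1e-4
    lambda_policy: str = "min"
    # bootstrap
    bootstrap_B: int = 0  # 0 disables the bootstrap stage
    bootstrap_reselect: bool = True
    bootstrap_weeks: list[int] | None = None
    # sensitivity
    covariates: list[str] = Field(default_factory=list)
    # output
    outdir: str = "ssrinet_run"
    plots: bool = True

    @field_validator("weeks")
    @classmethod
    def _weeks_nonempty(cls, v):
        if not v:
            raise ValueError("weeks must not be empty")
        return v

    @field_validator("scenario")
    @classmethod
    def _scenario_known(cls, v):
        if v is not None and v not in ("paper_like", "null", "dense_random"):
            raise ValueError(f"unknown scenario {v!r}")
        return v

    def mgm_config(self):
        from .model import MGMConfig
        return MGMConfig(rule=self.rule, folds=self.folds, n_lambda=self.n_lambda,
                         min_ratio=self.min_ratio, lambda_policy=self.lambda_policy)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def config_hash(self) -> str:
        """Hash of the analysis-defining fields (the output directory does
        not change what is computed, so it is excluded)."""
        payload = self.model_dump()
        payload.pop("outdir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
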