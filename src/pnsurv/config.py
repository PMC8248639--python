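"""Run-level configuration for the surveillance analysis.

All analysis-wide constants live here so that every stage (episode building,
person-time, incidence, screening, imputation) reads the same values: the
length of a person-month, the CI level, the early/late risk windows, the
depression-score threshold, the crude screening p-value, the events-per-
parameter cap and the imputation settings.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator


class RunConfig(BaseModel):
    """Analysis configuration.

    Parameters
    ----------
    month_days:
        Days per person-month used to convert follow-up days into
        person-months (365.25 / 12 by default).
    ci_alpha:
        Two-sided alpha for confidence intervals.
    early_window_end:
        Last day (inclusive) of the early infection window.
    late_window_end:
        Last day (inclusive) of the late infection window.
    epds_threshold:
        Total depression score at or above which a woman is classified as
        having possible depression.
    crude_screen_p:
        Crude Wald p-value below which a risk factor is carried into the
        adjusted model.
    params_per_event:
        Fraction of the event count allowed as model parameters (0.10 means
        at most one parameter per ten events).
    mice_m:
        Number of imputed datasets.
    mice_cycles:
        Chained-equation cycles per imputed dataset.
    mice_max_missing_fraction:
        Variables missing more than this fraction are excluded from
        imputation altogether.
    """

    month_days: float = Field(default=30.4375, gt=0)
    ci_alpha: float = Field(default=0.05, gt=0, lt=1)
    early_window_end: int = Field(default=7, gt=0)
    late_window_end: int = Field(default=28, gt=0)
    epds_threshold: int = Field(default=6, gt=0)
    epds_item_max: int = Field(default=6, gt=0)
    crude_screen_p: float = Field(default=0.1, gt=0, lt=1)
    params_per_event: float = Field(default=0.10, gt=0)
    mice_m: int = Field(default=10, ge=2)
    mice_cycles: int = Field(default=10, ge=1)
    mice_max_missing_fraction: float = Field(default=0.35, gt=0, le=1)
    random_seed: int = 20180315

    @model_validator(mode="after")
    def _windows_ordered(self) -> "RunConfig":
        if self.early_window_end >= self.late_window_end:
            raise ValueError("early_window_end must precede late_window_end")
        return self


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig(**(data or {}))
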