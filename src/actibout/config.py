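"""YAML configuration for cut points, wear rules, and clock windows."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .processing import CutPoints, WearRules, _parse_clock

__all__ = ["Config", "load_config"]


@dataclass(frozen=True)
class Config:
    cut_points: CutPoints
    wear_rules: WearRules
    analysis_window: tuple[float, float]
    sampling_rate_hz: int


def load_config(path: "str | Path | None" = None) -> Config:
    """Load a processing config; with no path, the packaged defaults."""
    if path is None:
        text = resources.files("actibout").joinpath("data/default_config.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    cp = raw.get("cut_points", {})
    wr = raw.get("wear_rules", {})
    win = raw.get("windows", {}).get("analysis", ["07:00", "22:00"])
    return Config(
        cut_points=CutPoints(
            sedentary_upper=float(cp.get("sedentary_upper_gs", 11.40)),
            light_upper=float(cp.get("light_upper_gs", 18.84)),
        ),
        wear_rules=WearRules(
            min_hours_per_day=float(wr.get("min_hours_per_day", 10)),
            nonwear_sedentary_fraction=float(wr.get("nonwear_sedentary_fraction", 0.80)),
            nonwear_window=tuple(wr.get("nonwear_window", (6.0, 21.0))),
            min_valid_days=int(wr.get("min_valid_days", 3)),
        ),
        analysis_window=tuple(_parse_clock(v) for v in win),
        sampling_rate_hz=int(raw.get("sampling_rate_hz", 60)),
    )
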