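"""Analysis configuration: severity cutpoints, reliability thresholds, visit windows.

All clinically meaningful constants live here as named fields of
:class:`AnalysisConfig` so a study can be re-run with different conventions
from a single YAML file.  The defaults encode the conventions used throughout
the package:

* severity strata on mean deviation (MD, dB): severe ``MD < -15``, moderate
  ``-15 <= MD < -7``, mild ``-7 <= MD < -2``, normal ``MD >= -2``;
* reliability: keep a field only if fixation losses are strictly below 33%
  and false positives / false negatives strictly below 15%;
* visit windows: presentation at day 0, early interim up to day 75, late
  interim up to day 150, final visit within 150-365 days (five to twelve
  months) of presentation;
* a percent weight of at least 9% counts as clinically meaningful.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    severity_cutpoints: tuple[float, float, float] = (-15.0, -7.0, -2.0)
    fl_max: float = 33.0
    fp_max: float = 15.0
    fn_max: float = 15.0
    mirror_left_eyes: bool = False
    interim_break_day: int = 75
    interim_end_day: int = 150
    final_window: tuple[int, int] = (150, 365)
    meaningful_cutoff_pct: float = 9.0
    n_archetypes: int = 14

    def __post_init__(self) -> None:
        lo, mid, hi = self.severity_cutpoints
        if not lo < mid < hi:
            raise ValueError("severity cutpoints must be strictly increasing")
        if min(self.fl_max, self.fp_max, self.fn_max) <= 0:
            raise ValueError("reliability thresholds must be positive")
        if not 0 < self.meaningful_cutoff_pct < 100:
            raise ValueError("meaningful_cutoff_pct must lie in (0, 100)")
        w0, w1 = self.final_window
        if not 0 < w0 < w1:
            raise ValueError("final_window must be an increasing positive pair")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("severity_cutpoints", "final_window"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["severity_cutpoints"] = list(self.severity_cutpoints)
        data["final_window"] = list(self.final_window)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


DEFAULT_CONFIG = AnalysisConfig()
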