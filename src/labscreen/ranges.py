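"""Eligibility ranges for clinical laboratory parameters.

An eligibility range is the interval of a lab parameter that a trial protocol
deems acceptable ("valid", label 1); values outside it are label 0. The shipped
defaults are the eight complete-blood-count / liver / kidney parameters used in
bioequivalence screens of gastric-cancer patients. The ALT default interval
(40–41 U/L) is implausibly narrow and is kept only for fidelity to its source
table, which likely carries a typo (0–41 would be the conventional range);
override it via configuration for real use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["EligibilityRange", "default_ranges", "load_ranges", "dump_ranges"]


@dataclass(frozen=True)
class EligibilityRange:
    """Valid interval for one laboratory parameter.

    Bounds are inclusive on both ends by default, matching how protocol
    tables print closed ranges such as "0-1.2 mg/dL".
    """

    parameter: str
    low: float
    high: float
    units: str = ""
    inclusive_low: bool = True
    inclusive_high: bool = True

    def __post_init__(self) -> None:
        if not (self.low < self.high):
            raise ValueError(
                f"eligibility range for {self.parameter!r} needs low < high, "
                f"got [{self.low}, {self.high}]"
            )

    def contains(self, value: float) -> bool:
        lo_ok = self.low <= value if self.inclusive_low else self.low < value
        hi_ok = value <= self.high if self.inclusive_high else value < self.high
        return lo_ok and hi_ok


#: Default valid ranges (label 1) per parameter.
_DEFAULTS = [
    ("hemoglobin", 13.0, 18.0, "g/dL"),
    ("neutrophil_count", 40.0, 74.0, "%"),
    ("platelet_count", 130.0, 400.0, "1000/uL"),
    ("bilirubin", 0.0, 1.2, "mg/dL"),
    ("ast", 0.0, 40.0, "U/L"),
    ("alt", 40.0, 41.0, "U/L"),  # suspected typo in the source table; override in practice
    ("alp", 40.0, 129.0, "U/L"),
    ("creatinine", 0.7, 1.2, "mg/dL"),
]


def default_ranges() -> dict[str, EligibilityRange]:
    """Return the default per-parameter eligibility ranges, keyed by parameter."""
    return {
        name: EligibilityRange(name, low, high, units)
        for name, low, high, units in _DEFAULTS
    }


def load_ranges(path: str | Path) -> dict[str, EligibilityRange]:
    """Load eligibility ranges from a YAML or JSON file.

    The file maps parameter name to ``{low, high, units?, inclusive_low?,
    inclusive_high?}``.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValueError(f"ranges file {path} must map parameter -> {{low, high, ...}}")
    out: dict[str, EligibilityRange] = {}
    for name, entry in raw.items():
        out[name] = EligibilityRange(
            parameter=name,
            low=float(entry["low"]),
            high=float(entry["high"]),
            units=str(entry.get("units", "")),
            inclusive_low=bool(entry.get("inclusive_low", True)),
            inclusive_high=bool(entry.get("inclusive_high", True)),
        )
    return out


def dump_ranges(ranges: Mapping[str, EligibilityRange], path: str | Path) -> None:
    """Write ranges to YAML (or JSON when the path ends in .json)."""
    path = Path(path)
    raw = {
        name: {
            "low": r.low,
            "high": r.high,
            "units": r.units,
            "inclusive_low": r.inclusive_low,
            "inclusive_high": r.inclusive_high,
        }
        for name, r in ranges.items()
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(raw, indent=2))
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=True))
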