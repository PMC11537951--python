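"""Published acceptability thresholds for reliability statistics.

Cutoffs in common use for anthropometric training exercises:

* ``carsley2019`` — %TEM < 2.0 for weight and length/height in
  paediatric measurement programmes;
* ``perini_beginner`` / ``perini_experienced`` — stricter %TEM cutoffs
  for adult weight and height, differentiated by anthropometrist
  experience (beginner: inter < 2.0, intra < 1.5; experienced:
  inter < 1.5, intra < 1.0);
* ``icc_excellent`` — ICC and R above 0.90 read as "excellent"
  reliability.

A :class:`ThresholdSet` is a named list of rules; rules may be loaded
from a small YAML/JSON config so surveys can encode their own standards.
"""

from __future__ import annotations

import json
import math
import operator
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .tem import ReliabilityResult

__all__ = [
    "ThresholdRule",
    "ThresholdSet",
    "Classification",
    "BUILTIN_THRESHOLDS",
    "builtin_threshold_set",
    "load_threshold_sets",
    "classify_reliability",
]

_OPS = {"<": operator.lt, "<=": operator.le, ">": operator.gt, ">=": operator.ge}
_STATISTICS = ("pct_tem", "icc", "r_coef", "tem")
_MODES = ("inter", "intra", "any")


@dataclass(frozen=True)
class ThresholdRule:
    """One acceptability rule: ``<statistic> <comparison> <cutoff>``.

    ``mode`` restricts the rule to inter- or intra-rater results
    ("any" applies to both); ``parameters`` optionally restricts it to
    specific anthropometric parameters (None = all).
    """

    name: str
    statistic: str
    comparison: str
    cutoff: float
    mode: str = "any"
    parameters: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.statistic not in _STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.comparison not in _OPS:
            raise ValueError(f"unknown comparison {self.comparison!r}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")

    def applies_to(self, result: ReliabilityResult) -> bool:
        if self.mode != "any" and result.mode != self.mode:
            return False
        if self.parameters is not None and result.parameter not in self.parameters:
            return False
        return True


@dataclass(frozen=True)
class ThresholdSet:
    name: str
    rules: tuple[ThresholdRule, ...]

    def __post_init__(self) -> None:
        names = [r.name for r in self.rules]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate rule names in threshold set {self.name!r}")


@dataclass(frozen=True)
class Classification:
    """Outcome of one rule on one result; ``passed`` is None when the
    referenced statistic is undefined (not-evaluable)."""

    rule: str
    statistic: str
    observed: float
    cutoff: float
    comparison: str
    passed: bool | None

    def label(self) -> str:
        if self.passed is None:
            return f"{self.rule}: not evaluable"
        return f"{self.rule}: {'pass' if self.passed else 'fail'}"


_WEIGHT_LENGTH = ("weight", "length_height")

BUILTIN_THRESHOLDS: dict[str, ThresholdSet] = {
    "carsley2019": ThresholdSet(
        "carsley2019",
        (
            ThresholdRule("pct_tem_lt_2", "pct_tem", "<", 2.0, "any", _WEIGHT_LENGTH),
        ),
    ),
    "perini_beginner": ThresholdSet(
        "perini_beginner",
        (
            ThresholdRule("inter_pct_tem_lt_2", "pct_tem", "<", 2.0, "inter", _WEIGHT_LENGTH),
            ThresholdRule("intra_pct_tem_lt_1.5", "pct_tem", "<", 1.5, "intra", _WEIGHT_LENGTH),
        ),
    ),
    "perini_experienced": ThresholdSet(
        "perini_experienced",
        (
            ThresholdRule("inter_pct_tem_lt_1.5", "pct_tem", "<", 1.5, "inter", _WEIGHT_LENGTH),
            ThresholdRule("intra_pct_tem_lt_1", "pct_tem", "<", 1.0, "intra", _WEIGHT_LENGTH),
        ),
    ),
    "icc_excellent": ThresholdSet(
        "icc_excellent",
        (
            ThresholdRule("icc_gt_0.9", "icc", ">", 0.9),
            ThresholdRule("r_gt_0.9", "r_coef", ">", 0.9),
        ),
    ),
}


def builtin_threshold_set(name: str) -> ThresholdSet:
    try:
        return BUILTIN_THRESHOLDS[name]
    except KeyError:
        raise KeyError(
            f"unknown threshold set {name!r}; built-ins: {sorted(BUILTIN_THRESHOLDS)}"
        ) from None


def load_threshold_sets(path: str | Path) -> dict[str, ThresholdSet]:
    """Load threshold sets from a YAML or JSON file.

    Layout::

        my_survey:
          - {name: inter_pct_tem, statistic: pct_tem, comparison: "<",
             cutoff: 2.5, mode: inter, parameters: [muac, waist]}
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    sets: dict[str, ThresholdSet] = {}
    for set_name, rules in data.items():
        parsed = []
        for r in rules:
            params = r.get("parameters")
            parsed.append(
                ThresholdRule(
                    name=r["name"],
                    statistic=r["statistic"],
                    comparison=r["comparison"],
                    cutoff=float(r["cutoff"]),
                    mode=r.get("mode", "any"),
                    parameters=tuple(params) if params else None,
                )
            )
        sets[set_name] = ThresholdSet(set_name, tuple(parsed))
    return sets


def classify_reliability(result: ReliabilityResult, thresholds: ThresholdSet) -> list[Classification]:
    """Evaluate every applicable rule of a threshold set on one result."""
    out: list[Classification] = []
    for rule in thresholds.rules:
        if not rule.applies_to(result):
            continue
        observed = float(getattr(result, rule.statistic))
        if math.isnan(observed):
            passed: bool | None = None
        else:
            passed = bool(_OPS[rule.comparison](observed, rule.cutoff))
        out.append(
            Classification(rule.name, rule.statistic, observed, rule.cutoff, rule.comparison, passed)
        )
    return out
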