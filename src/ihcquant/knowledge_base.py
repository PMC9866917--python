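"""Declarative IF-THEN rule store binding measurements to algorithm parameters.

Three rule families are supported:

``window``
    condition on ``psnr_db`` -> median filter window side.
``threshold``
    condition on ``image_type`` (biomarker kind) -> lower/upper thresholds.
``alpha``
    condition on ``y`` (mean brightness) -> brightness gain.

Defaults reproduce the published tables exactly.  An override document (YAML
or JSON) merges rule-by-rule via rule ids; after every load each family is
checked to partition its input space (exactly one rule fires for any input).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ihcquant.core_io import BiomarkerKind

logger = logging.getLogger(__name__)

_CONDITION_OPS = {"le", "lt", "ge", "gt", "eq"}
_KNOWN_FAMILIES = ("window", "threshold", "alpha")


class RulesetError(ValueError):
    """Malformed ruleset document."""


class PartitionError(ValueError):
    """A rule family does not partition its input space."""


class UncoveredInputError(LookupError):
    """No rule matches the given inputs."""


@dataclass(frozen=True)
class Rule:
    family: str
    rule_id: str
    condition: dict
    action: dict
    priority: int = 0

    def matches(self, inputs: dict) -> bool:
        for var, spec in self.condition.items():
            if var not in inputs:
                raise UncoveredInputError(
                    f"rule {self.rule_id!r} requires input {var!r}, got {sorted(inputs)}"
                )
            value = inputs[var]
            if isinstance(value, BiomarkerKind):
                value = value.value
            if not isinstance(spec, dict):
                spec = {"eq": spec}
            for op, ref in spec.items():
                if op == "eq":
                    if isinstance(ref, str):
                        if str(value).upper() != ref.upper():
                            return False
                    elif value != ref:
                        return False
                elif op == "le":
                    if not value <= ref:
                        return False
                elif op == "lt":
                    if not value < ref:
                        return False
                elif op == "ge":
                    if not value >= ref:
                        return False
                elif op == "gt":
                    if not value > ref:
                        return False
                else:
                    raise RulesetError(f"unknown condition operator {op!r} in rule {self.rule_id!r}")
        return True


def _default_rules() -> list[Rule]:
    rules = [
        Rule("window", "window-noisy", {"psnr_db": {"le": 20}}, {"window_side": 5}),
        Rule("window", "window-clean", {"psnr_db": {"gt": 20}}, {"window_side": 3}),
        Rule("alpha", "alpha-darkest", {"y": {"le": 10}}, {"alpha": 20}),
        Rule("alpha", "alpha-dark", {"y": {"gt": 10, "le": 40}}, {"alpha": 12}),
        Rule("alpha", "alpha-mid", {"y": {"gt": 40, "le": 150}}, {"alpha": 8}),
        Rule("alpha", "alpha-bright", {"y": {"gt": 150, "le": 200}}, {"alpha": 6}),
        Rule("alpha", "alpha-brightest", {"y": {"gt": 200}}, {"alpha": 4}),
    ]
    thresholds = {"PR": (160, 180), "ER": (180, 210), "HER2": (40, 230), "KI67": (160, 180)}
    for name, (low, high) in thresholds.items():
        rules.append(
            Rule(
                "threshold",
                f"threshold-{name.lower()}",
                {"image_type": {"eq": name}},
                {"t_low": low, "t_high": high},
            )
        )
    return rules


# sweep grids used to verify that each family partitions its input space
_PARTITION_SWEEPS = {
    "window": lambda: [*np.arange(0.0, 100.25, 0.25), math.inf],
    "alpha": lambda: list(np.arange(0.0, 255.25, 0.25)),
    "threshold": lambda: [k.value for k in BiomarkerKind],
}
_SWEEP_VARS = {"window": "psnr_db", "alpha": "y", "threshold": "image_type"}


@dataclass
class RuleStore:
    rules: dict = field(default_factory=dict)  # family -> list[Rule]

    def family(self, name: str) -> list[Rule]:
        try:
            return self.rules[name]
        except KeyError:
            raise UncoveredInputError(f"unknown rule family {name!r}") from None

    def fire(self, family: str, **inputs) -> dict:
        """Return the unique matching rule's action; error if none or many."""
        matching = [r for r in self.family(family) if r.matches(inputs)]
        if not matching:
            raise UncoveredInputError(f"no rule in family {family!r} covers inputs {inputs}")
        if len(matching) > 1:
            matching.sort(key=lambda r: -r.priority)
            if matching[0].priority == matching[1].priority:
                ids = [r.rule_id for r in matching]
                raise PartitionError(f"multiple rules fire in family {family!r}: {ids}")
        rule = matching[0]
        logger.info("knowledge base fired rule %s/%s -> %s", family, rule.rule_id, rule.action)
        return dict(rule.action)

    def validate_partition(self) -> None:
        """Check each known family fires exactly once over a domain sweep."""
        for family, grid in _PARTITION_SWEEPS.items():
            if family not in self.rules:
                continue
            var = _SWEEP_VARS[family]
            for value in grid():
                matching = [r for r in self.family(family) if r.matches({var: value})]
                if len(matching) != 1:
                    ids = [r.rule_id for r in matching]
                    raise PartitionError(
                        f"family {family!r} must fire exactly one rule for "
                        f"{var}={value}, matched {ids or 'none'}"
                    )


def _parse_rule(family: str, raw: dict, index: int) -> Rule:
    if not isinstance(raw, dict):
        raise RulesetError(f"rule #{index} in family {family!r} must be a mapping")
    try:
        rule_id = str(raw["id"])
        condition = raw["if"]
        action = raw["then"]
    except KeyError as exc:
        raise RulesetError(
            f"rule #{index} in family {family!r} is missing key {exc.args[0]!r}"
        ) from None
    if not isinstance(condition, dict) or not isinstance(action, dict):
        raise RulesetError(f"rule {rule_id!r}: 'if' and 'then' must be mappings")
    for var, spec in condition.items():
        if isinstance(spec, dict) and not set(spec) <= _CONDITION_OPS:
            bad = sorted(set(spec) - _CONDITION_OPS)
            raise RulesetError(f"rule {rule_id!r}: unknown condition operators {bad}")
    return Rule(family, rule_id, condition, action, priority=int(raw.get("priority", 0)))


def load_rules(config: str | Path | None = None) -> RuleStore:
    """Build the rule store: published defaults, optionally merged with overrides.

    Overrides replace default rules with the same id within a family; rules
    with new ids are appended.  The merged store must still partition each
    family's input space.
    """
    families: dict[str, list[Rule]] = {}
    for rule in _default_rules():
        families.setdefault(rule.family, []).append(rule)

    if config is not None:
        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(f"ruleset file not found: {path}")
        try:
            doc = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            where = f" at line {mark.line + 1}" if mark else ""
            raise RulesetError(f"malformed ruleset {path}{where}: {exc}") from exc
        if doc is None:
            doc = {}
        if not isinstance(doc, dict) or not isinstance(doc.get("families", {}), dict):
            raise RulesetError(f"ruleset {path}: top level must be a mapping with 'families'")
        for family, raw_rules in doc.get("families", {}).items():
            if family not in _KNOWN_FAMILIES:
                raise RulesetError(
                    f"ruleset {path}: unknown family {family!r} (expected one of {_KNOWN_FAMILIES})"
                )
            if not isinstance(raw_rules, list):
                raise RulesetError(f"ruleset {path}: family {family!r} must hold a list of rules")
            existing = {r.rule_id: i for i, r in enumerate(families.get(family, []))}
            for index, raw in enumerate(raw_rules):
                rule = _parse_rule(family, raw, index)
                if rule.rule_id in existing:
                    families[family][existing[rule.rule_id]] = rule
                else:
                    families.setdefault(family, []).append(rule)

    store = RuleStore(rules=families)
    store.validate_partition()
    return store
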