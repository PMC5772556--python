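"""Interpretable activation/repression rules and the canonical four-rule set.

A rule's antecedent is a conjunction of predicates; each predicate requires
a named scalar (the ``Region`` location variable or a 4-mer count) to fall
in a union of intervals with explicit open/closed endpoints.  The canonical
set ships the four published rules:

* A1 (activator): Region <= -49.5 or Region >= 49.5, and at most two TTTT
  motifs in the site.
* A2 (activator): Region in [-70.5, -28.5] and no AACG motif.
* R1 (repressor): 2 < Region < 70.5 or -49.5 <= Region < -10, and no TTAC
  motif.
* R2 (repressor): Region in [-31, 23] and neither TTAC nor GAGC motif.

Classification is first-match in the order [A1, A2, R1, R2]; all matching
rules are reported, and sites matching none fall back to the configured
policy (``uncovered`` by default).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .sites import ROLE_ACTIVATOR, ROLE_REPRESSOR

UNCOVERED = "uncovered"
INF = math.inf


@dataclass(frozen=True)
class Interval:
    """A real interval with explicit endpoint openness."""

    lo: float = -INF
    hi: float = INF
    lo_closed: bool = True
    hi_closed: bool = True

    def contains(self, x: float) -> bool:
        if x < self.lo or (x == self.lo and not self.lo_closed):
            return False
        if x > self.hi or (x == self.hi and not self.hi_closed):
            return False
        return True

    def to_json(self) -> dict:
        return {
            "lo": None if self.lo == -INF else self.lo,
            "hi": None if self.hi == INF else self.hi,
            "lo_closed": self.lo_closed,
            "hi_closed": self.hi_closed,
        }

    @staticmethod
    def from_json(d: dict) -> "Interval":
        return Interval(
            lo=-INF if d["lo"] is None else d["lo"],
            hi=INF if d["hi"] is None else d["hi"],
            lo_closed=d["lo_closed"],
            hi_closed=d["hi_closed"],
        )


@dataclass(frozen=True)
class Predicate:
    """feature value must lie in the union of ``intervals``."""

    feature: str
    intervals: tuple[Interval, ...]

    def holds(self, values: Mapping[str, float]) -> bool:
        if self.feature not in values:
            raise KeyError(f"rule predicate needs feature {self.feature!r}")
        x = float(values[self.feature])
        return any(iv.contains(x) for iv in self.intervals)


def motif_absent(motif: str) -> Predicate:
    return Predicate(f"4mer_{motif}", (Interval(0, 0),))


def motif_at_most(motif: str, count: int) -> Predicate:
    return Predicate(f"4mer_{motif}", (Interval(0, count),))


@dataclass
class Rule:
    name: str
    predicates: tuple[Predicate, ...]
    consequent: str
    #: (correct, covered_class_total, correct, covered_total) bookkeeping
    stats: dict = field(default_factory=dict)

    def matches(self, values: Mapping[str, float]) -> bool:
        return all(p.holds(values) for p in self.predicates)

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "consequent": self.consequent,
            "predicates": [
                {"feature": p.feature, "intervals": [iv.to_json() for iv in p.intervals]}
                for p in self.predicates
            ],
            "stats": self.stats,
        }

    @staticmethod
    def from_json(d: dict) -> "Rule":
        return Rule(
            name=d["name"],
            predicates=tuple(
                Predicate(
                    p["feature"],
                    tuple(Interval.from_json(iv) for iv in p["intervals"]),
                )
                for p in d["predicates"]
            ),
            consequent=d["consequent"],
            stats=d.get("stats", {}),
        )


@dataclass
class RuleSet:
    rules: list[Rule]
    fallback: str = UNCOVERED  # "uncovered" | "majority" | "model"
    majority_class: str = ROLE_ACTIVATOR

    def to_json(self) -> dict:
        return {
            "rules": [r.to_json() for r in self.rules],
            "fallback": self.fallback,
            "majority_class": self.majority_class,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2)

    @staticmethod
    def load(path) -> "RuleSet":
        with open(path) as fh:
            d = json.load(fh)
        return RuleSet(
            rules=[Rule.from_json(r) for r in d["rules"]],
            fallback=d.get("fallback", UNCOVERED),
            majority_class=d.get("majority_class", ROLE_ACTIVATOR),
        )


def canonical_ruleset() -> RuleSet:
    """The published four-rule classifier with verbatim thresholds.

    The paired region conditions of A1 and R1 are unions of intervals: the
    published per-branch cover counts (87 + 1 activators for A1's two
    branches, 9 + 5 repressors for R1's) show both branches fire
    independently.
    """
    a1 = Rule(
        "A1",
        (
            Predicate(
                "Region",
                (Interval(hi=-49.5), Interval(lo=49.5)),
            ),
            motif_at_most("TTTT", 2),
        ),
        ROLE_ACTIVATOR,
    )
    a2 = Rule(
        "A2",
        (
            Predicate("Region", (Interval(-70.5, -28.5),)),
            motif_absent("AACG"),
        ),
        ROLE_ACTIVATOR,
    )
    r1 = Rule(
        "R1",
        (
            Predicate(
                "Region",
                (
                    Interval(2, 70.5, lo_closed=False, hi_closed=False),
                    Interval(-49.5, -10, hi_closed=False),
                ),
            ),
            motif_absent("TTAC"),
        ),
        ROLE_REPRESSOR,
    )
    r2 = Rule(
        "R2",
        (
            Predicate("Region", (Interval(-31, 23),)),
            motif_absent("TTAC"),
            motif_absent("GAGC"),
        ),
        ROLE_REPRESSOR,
    )
    return RuleSet(rules=[a1, a2, r1, r2])


def apply_ruleset(
    values: Mapping[str, float], ruleset: RuleSet
) -> tuple[str, list[str]]:
    """Classify one site: first-match role plus all matching rule names."""
    matched = [r.name for r in ruleset.rules if r.matches(values)]
    if matched:
        first = next(r for r in ruleset.rules if r.name == matched[0])
        return first.consequent, matched
    if ruleset.fallback == "majority":
        return ruleset.majority_class, []
    return UNCOVERED, []


def classify_frame(features: pd.DataFrame, ruleset: RuleSet) -> pd.DataFrame:
    """Apply the ruleset to every row of a feature matrix."""
    roles, matches = [], []
    for _, row in features.iterrows():
        role, m = apply_ruleset(row, ruleset)
        roles.append(role)
        matches.append(",".join(m))
    return pd.DataFrame(
        {"role": roles, "matched_rules": matches}, index=features.index
    )


def rule_coverage(
    ruleset: RuleSet, features: pd.DataFrame, labels: Iterable[str]
) -> pd.DataFrame:
    """Per-rule coverage and accuracy on a labeled dataset.

    coverage = consequent-class sites matching the antecedent / class total;
    accuracy = consequent-class sites among all antecedent matches (NA when
    the rule matches nothing).  Also reports the overall covered fraction.
    """
    labels = list(labels)
    if len(labels) != len(features):
        raise ValueError("labels/features length mismatch")
    class_totals: dict[str, int] = {}
    for y in labels:
        class_totals[y] = class_totals.get(y, 0) + 1

    records = []
    covered_any = np.zeros(len(features), dtype=bool)
    for rule in ruleset.rules:
        match_mask = np.array(
            [rule.matches(row) for _, row in features.iterrows()], dtype=bool
        )
        covered_any |= match_mask
        n_match = int(match_mask.sum())
        correct = int(
            sum(1 for m, y in zip(match_mask, labels) if m and y == rule.consequent)
        )
        class_total = class_totals.get(rule.consequent, 0)
        rule.stats = {
            "coverage_count": correct,
            "covered_class_total": class_total,
            "correct": correct,
            "covered_total": n_match,
        }
        records.append(
            {
                "rule": rule.name,
                "consequent": rule.consequent,
                "matches": n_match,
                "correct": correct,
                "class_total": class_total,
                "coverage": correct / class_total if class_total else np.nan,
                "accuracy": correct / n_match if n_match else np.nan,
            }
        )
    table = pd.DataFrame(records).set_index("rule")
    table.attrs["covered_fraction"] = float(covered_any.mean()) if len(features) else 0.0
    return table
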