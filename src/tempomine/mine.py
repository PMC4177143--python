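"""Apriori association-rule mining over clinical item transactions.

Frequent itemsets are found level-wise using the downward-closure
(anti-monotonicity) property: every non-empty subset of a frequent itemset
is itself frequent, so candidates at level k are built only from frequent
sets at level k-1 and pruned when any (k-1)-subset is infrequent.

All supports and confidences are exact rationals (:class:`fractions.Fraction`
over transaction counts); thresholds at exactly 30% support or 85%
confidence therefore behave exactly, with no float edge cases. Percentages
are rendered only at report time, truncated (not rounded) to two decimals —
the convention under which the shipped reference rule table is
integer-consistent.

The module also carries brute-force oracles (`exhaustive_frequent_itemsets`,
`exhaustive_rules`) that enumerate every candidate without pruning; they are
deliberately independent of the level-wise code paths and exist to
cross-check them on small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import chain, combinations
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .errors import ConfigurationError, UndefinedInputError

Itemset = frozenset
Threshold = Union[Fraction, float, int, str]

#: Default mining thresholds: frequent itemsets at >= 30% support; rules
#: generated at >= 50% confidence then kept at >= 85% (two-stage filter,
#: the second threshold reflecting a clinically-reviewed cutoff).
MIN_SUPPORT = Fraction(3, 10)
MIN_CONFIDENCE_FIRST = Fraction(1, 2)
MIN_CONFIDENCE_FINAL = Fraction(17, 20)


@dataclass(frozen=True)
class Transaction:
    """One mining transaction: an id and a non-empty set of item tokens."""

    id: str
    items: frozenset[str]

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError(f"transaction {self.id!r}: items must be non-empty")


@dataclass(frozen=True)
class AssociationRule:
    """A rule X => Y with exact support/confidence and cosine correlation."""

    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: Fraction  # support of X ∪ Y
    confidence: Fraction
    correlation: float

    @property
    def support_pct(self) -> float:
        return truncate_pct(self.support)

    @property
    def confidence_pct(self) -> float:
        return truncate_pct(self.confidence)

    @property
    def correlation_pct(self) -> float:
        return truncate_pct(self.correlation)


def truncate_pct(fraction) -> float:
    """Render a fraction in [0, 1] as a percentage truncated to two
    decimals (21/37 -> 56.75, not 56.76)."""
    return math.floor(Fraction(fraction) * 10000) / 100


def _as_fraction(x: Threshold) -> Fraction:
    """Coerce a threshold to an exact Fraction.

    Floats go through ``limit_denominator`` so that e.g. 0.3 means exactly
    3/10 rather than its nearest binary double.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        return Fraction(x).limit_denominator(10**6)
    return Fraction(x)


def support(transactions: Sequence[Transaction], itemset: Iterable[str]) -> Fraction:
    """Fraction of transactions containing every item of ``itemset``."""
    items = frozenset(itemset)
    if not items:
        raise UndefinedInputError("support of the empty itemset is undefined")
    if not transactions:
        raise UndefinedInputError("support over an empty transaction list is undefined")
    count = sum(1 for t in transactions if items <= t.items)
    return Fraction(count, len(transactions))


def apriori(transactions: Sequence[Transaction],
            min_support: Threshold = MIN_SUPPORT) -> dict[Itemset, Fraction]:
    """All itemsets with support >= min_support, with their exact supports.

    Level-wise candidate generation: level-k candidates are unions of
    overlapping (k-1)-itemsets, pruned when any (k-1)-subset is infrequent,
    then counted against the transactions.
    """
    if not transactions:
        raise UndefinedInputError("apriori over an empty transaction list is undefined")
    ms = _as_fraction(min_support)
    if not 0 < ms <= 1:
        raise ConfigurationError(f"min_support must be in (0, 1], got {ms}")
    n = len(transactions)
    min_count = ms * n

    # Level 1
    counts: dict[Itemset, int] = {}
    for t in transactions:
        for item in t.items:
            key = frozenset((item,))
            counts[key] = counts.get(key, 0) + 1
    frequent: dict[Itemset, Fraction] = {
        s: Fraction(c, n) for s, c in counts.items() if c >= min_count
    }
    level = [s for s in frequent]

    while level:
        # join step: union pairs differing in exactly one item
        candidates: set[Itemset] = set()
        for i in range(len(level)):
            for j in range(i + 1, len(level)):
                union = level[i] | level[j]
                if len(union) == len(level[i]) + 1:
                    candidates.add(union)
        # prune step: all (k-1)-subsets must already be frequent
        k = len(level[0]) + 1
        pruned = [
            c for c in candidates
            if all(frozenset(sub) in frequent for sub in combinations(c, k - 1))
        ]
        next_level = []
        for cand in pruned:
            count = sum(1 for t in transactions if cand <= t.items)
            if count >= min_count:
                frequent[cand] = Fraction(count, n)
                next_level.append(cand)
        level = next_level
    return frequent


def correlation_measure(transactions: Sequence[Transaction],
                        antecedent: Iterable[str],
                        consequent: Iterable[str]) -> float:
    """Cosine correlation of two itemsets:
    support(X ∪ Y) / sqrt(support(X) * support(Y)).

    An implementation choice of association measure: 1.0 for identical
    itemsets, sqrt(support) for statistically independent ones.
    """
    x, y = frozenset(antecedent), frozenset(consequent)
    sx, sy = support(transactions, x), support(transactions, y)
    if sx == 0 or sy == 0:
        raise UndefinedInputError("correlation undefined when either side has zero support")
    sxy = support(transactions, x | y)
    return float(sxy) / math.sqrt(float(sx) * float(sy))


def _rule_sort_key(rule: AssociationRule):
    return (-rule.support, -rule.confidence,
            tuple(sorted(rule.antecedent)), tuple(sorted(rule.consequent)))


def generate_rules(frequent: Mapping[Itemset, Fraction],
                   transactions: Sequence[Transaction],
                   min_confidence: Threshold = MIN_CONFIDENCE_FINAL,
                   ) -> list[AssociationRule]:
    """All rules X => Y with X ∪ Y frequent, X, Y non-empty and disjoint,
    and confidence = support(X∪Y)/support(X) >= min_confidence.

    Consequents may contain multiple items. Output is deterministically
    sorted by (descending support, descending confidence, antecedent,
    consequent).
    """
    mc = _as_fraction(min_confidence)
    if not 0 < mc <= 1:
        raise ConfigurationError(f"min_confidence must be in (0, 1], got {mc}")
    rules = []
    for itemset, sup in frequent.items():
        if len(itemset) < 2:
            continue
        items = sorted(itemset)
        for r in range(1, len(items)):
            for ant in combinations(items, r):
                antecedent = frozenset(ant)
                consequent = itemset - antecedent
                s_ant = frequent.get(antecedent)
                if s_ant is None:  # cannot happen for truly frequent sets
                    s_ant = support(transactions, antecedent)
                conf = sup / s_ant
                if conf >= mc:
                    corr = correlation_measure(transactions, antecedent, consequent)
                    rules.append(AssociationRule(antecedent, consequent, sup, conf, corr))
    rules.sort(key=_rule_sort_key)
    return rules


def mine_rules(transactions: Sequence[Transaction],
               min_support: Threshold = MIN_SUPPORT,
               min_confidence_first: Threshold = MIN_CONFIDENCE_FIRST,
               min_confidence_final: Threshold = MIN_CONFIDENCE_FINAL,
               ) -> list[AssociationRule]:
    """Two-stage pipeline: Apriori at ``min_support``, rules generated at
    ``min_confidence_first`` and kept at ``min_confidence_final``."""
    frequent = apriori(transactions, min_support)
    first = generate_rules(frequent, transactions, min_confidence_first)
    final = _as_fraction(min_confidence_final)
    return [r for r in first if r.confidence >= final]


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the level-wise code above)
# ---------------------------------------------------------------------------

def exhaustive_frequent_itemsets(transactions: Sequence[Transaction],
                                 min_support: Threshold) -> dict[Itemset, Fraction]:
    """Enumerate every non-empty subset of the observed item universe and
    count each against the transactions. Exponential; testing oracle only."""
    if not transactions:
        raise UndefinedInputError("no transactions")
    ms = _as_fraction(min_support)
    universe = sorted(set(chain.from_iterable(t.items for t in transactions)))
    n = len(transactions)
    out: dict[Itemset, Fraction] = {}
    for r in range(1, len(universe) + 1):
        for combo in combinations(universe, r):
            s = frozenset(combo)
            count = sum(1 for t in transactions if s <= t.items)
            if Fraction(count, n) >= ms:
                out[s] = Fraction(count, n)
    return out


def exhaustive_rules(transactions: Sequence[Transaction],
                     min_support: Threshold,
                     min_confidence: Threshold) -> list[AssociationRule]:
    """Enumerate every (X, Y) split of every frequent itemset directly."""
    frequent = exhaustive_frequent_itemsets(transactions, min_support)
    mc = _as_fraction(min_confidence)
    rules = []
    for itemset, sup in frequent.items():
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for ant in combinations(sorted(itemset), r):
                antecedent = frozenset(ant)
                conf = sup / support(transactions, antecedent)
                if conf >= mc:
                    corr = correlation_measure(
                        transactions, antecedent, itemset - antecedent)
                    rules.append(AssociationRule(
                        antecedent, itemset - antecedent, sup, conf, corr))
    rules.sort(key=_rule_sort_key)
    return rules


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_transactions(transactions: Sequence[Transaction], path) -> None:
    """One row per transaction; items semicolon-joined in sorted order."""
    pd.DataFrame(
        {"id": [t.id for t in transactions],
         "items": [";".join(sorted(t.items)) for t in transactions]}
    ).to_csv(path, index=False)


def read_transactions(path) -> list[Transaction]:
    frame = pd.read_csv(path, dtype=str)
    if "id" not in frame.columns or "items" not in frame.columns:
        raise ConfigurationError(f"{path}: expected columns 'id' and 'items'")
    return [
        Transaction(str(row.id), frozenset(str(row.items).split(";")))
        for row in frame.itertuples(index=False)
    ]


def rules_frame(rules: Sequence[AssociationRule]) -> pd.DataFrame:
    """Rules as a report table with truncated percentage columns."""
    return pd.DataFrame(
        {
            "antecedent": [", ".join(sorted(r.antecedent)) for r in rules],
            "consequent": [", ".join(sorted(r.consequent)) for r in rules],
            "support_pct": [r.support_pct for r in rules],
            "confidence_pct": [r.confidence_pct for r in rules],
            "correlation_pct": [r.correlation_pct for r in rules],
        }
    )


def write_rules(rules: Sequence[AssociationRule], path) -> None:
    rules_frame(rules).to_csv(path, index=False)


def find_rule(rules: Sequence[AssociationRule],
              antecedent: Iterable[str],
              consequent: Iterable[str]) -> AssociationRule:
    """Look up one rule by exact antecedent/consequent itemsets."""
    a, c = frozenset(antecedent), frozenset(consequent)
    for r in rules:
        if r.antecedent == a and r.consequent == c:
            return r
    raise KeyError(f"rule {sorted(a)} => {sorted(c)} not among {len(rules)} rules")
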