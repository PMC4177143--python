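"""Deterministic reconstruction of the reference mining dataset.

The original per-patient transaction data behind the reference association
rules for the brain-tumour cohort are not available; only the rule metrics
(support% and confidence% per rule) survive. Because those percentages are
ratios of integer counts, they can be inverted: a support of 56.75% is only
consistent with 21 transactions out of 37, and a confidence of 85.29% on a
rule with 29 joint occurrences forces an antecedent count of 34.

This module (a) scans candidate denominators to recover the transaction
count n from the printed percentages, (b) inverts every rule row into
integer count constraints (flagging rows whose printed values are not
consistent with any integer count — one confidence cell fails this check
and is treated as a typographical inconsistency), and (c) deterministically
builds a 37-transaction dataset satisfying every unflagged constraint
exactly, verified by recounting. Mining the built dataset reproduces the
unflagged reference support/confidence cells to the printed two decimals.

Percentages in the reference table are truncated, not rounded, to two
decimals (21/37 = 56.756% prints as 56.75); ``mine.truncate_pct`` mirrors
this convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ConstructionError, InversionError
from .mine import Transaction, support

STATE_ITEM = "STATE=1"

#: The reference rule metrics: (antecedent, consequent, support%, confidence%,
#: correlation%). The correlation column's defining measure is unknown and is
#: not used for inversion (the package's own cosine measure does not
#: reproduce it; it is reported for completeness only).
REFERENCE_RULE_TABLE: list[tuple[tuple[str, ...], tuple[str, ...], float, float, float]] = [
    (("KFT_Creatinine=HIGH",), ("KFT_BUN=HIGH",), 56.75, 100.0, 77.45),
    (("KFT_Creatinine=HIGH",), (STATE_ITEM,), 56.75, 100.0, 77.77),
    (("KFT_BUN=HIGH",), (STATE_ITEM,), 78.37, 85.29, 90.8),
    (("KFT_Creatinine=HIGH", "KFT_BUN=HIGH"), (STATE_ITEM,), 56.75, 100.0, 79.77),
    (("LFT_SGOT=HIGH",), (STATE_ITEM,), 62.16, 98.83, 81.72),
    (("LFT_SGOT=HIGH",), ("LFT_SGPT=HIGH", STATE_ITEM), 62.16, 95.83, 85.71),
    (("LFT_SGPT=HIGH",), (STATE_ITEM,), 81.08, 88.23, 89.56),
    (("Haemoglobin_content=NORMAL",), (STATE_ITEM,), 59.45, 100.0, 81.64),
]

#: Filler item for transactions that carry no derived item (every analyte in
#: range, no disease state recorded); keeps item sets non-empty while staying
#: far below any support threshold of interest.
FILLER_ITEM = "KFT_Creatinine=NORMAL"

ROUNDING_TOLERANCE = 0.02  # max distance from an integer for a derived count


@dataclass(frozen=True)
class CountConstraint:
    """Exact occurrence count of an itemset over the n transactions."""

    itemset: frozenset[str]
    count: int

    def describe(self) -> str:
        return f"count({' & '.join(sorted(self.itemset))}) = {self.count}"


def recover_n(support_pcts: Sequence[float],
              lo: int = 20, hi: int = 60,
              tol: float = ROUNDING_TOLERANCE) -> list[int]:
    """Candidate transaction counts n in [lo, hi] for which every support
    percentage corresponds to an integer count within ``tol``.

    Returns all consistent n (the reference percentages admit exactly one).
    """
    pcts = sorted({p for p in support_pcts if p < 100.0})
    candidates = []
    for n in range(lo, hi + 1):
        if all(abs(p * n / 100 - round(p * n / 100)) <= tol for p in pcts):
            candidates.append(n)
    return candidates


def invert_rule_table(rows: Sequence[tuple], n: int,
                      tol: float = ROUNDING_TOLERANCE,
                      ) -> tuple[list[CountConstraint], list[int]]:
    """Invert (antecedent, consequent, support%, confidence%) rows into
    integer count constraints over n transactions.

    For each row: count(X ∪ Y) = support% * n / 100 and
    count(X) = count(X ∪ Y) / (confidence% / 100); both must land within
    ``tol`` of an integer, otherwise the row index is flagged as
    inconsistent and contributes no constraints.
    """
    if n < 1:
        raise InversionError(f"n must be >= 1, got {n}")
    constraints: dict[frozenset, int] = {}
    flagged: list[int] = []
    for idx, row in enumerate(rows):
        antecedent, consequent = frozenset(row[0]), frozenset(row[1])
        support_pct, confidence_pct = float(row[2]), float(row[3])
        xy_real = support_pct * n / 100
        xy = round(xy_real)
        if abs(xy_real - xy) > tol:
            flagged.append(idx)
            continue
        x_real = xy / (confidence_pct / 100)
        x = round(x_real)
        if abs(x_real - x) > tol:
            flagged.append(idx)
            continue
        for itemset, count in ((antecedent | consequent, xy), (antecedent, x)):
            prev = constraints.get(itemset)
            if prev is not None and prev != count:
                raise InversionError(
                    f"conflicting counts for {sorted(itemset)}: {prev} vs {count}")
            constraints[itemset] = count
    out = [CountConstraint(s, c) for s, c in constraints.items()]
    out.sort(key=lambda c: (len(c.itemset), sorted(c.itemset)))
    return out, flagged


def build_transactions(constraints: Sequence[CountConstraint], n: int,
                       state_support: int = 30) -> list[Transaction]:
    """Deterministic greedy interval layout satisfying every constraint.

    Transactions 1..state_support carry the STATE item. Each non-STATE item
    A occupies a prefix 1..k_A of the STATE block (k_A = the largest count
    required jointly with STATE) plus a prefix of the non-STATE block for
    its remaining occurrences. Nested prefixes make every joint count the
    minimum of the member prefixes, which the constraint system here is
    consistent with; the layout is recounted against every constraint
    before returning and any violation raises :class:`ConstructionError`.
    """
    if not 0 <= state_support <= n:
        raise ConstructionError(f"state_support {state_support} outside [0, {n}]")

    totals: dict[str, int] = {}
    in_state: dict[str, int] = {}
    for c in constraints:
        items = set(c.itemset)
        has_state = STATE_ITEM in items
        items.discard(STATE_ITEM)
        if has_state and not items:
            if c.count != state_support:
                raise ConstructionError(
                    f"STATE count {c.count} conflicts with state_support {state_support}")
            continue
        if not has_state and len(items) == 1:
            (item,) = items
            prev = totals.get(item)
            if prev is not None and prev != c.count:
                raise ConstructionError(f"conflicting totals for {item!r}")
            totals[item] = c.count
        if has_state:
            for item in items:
                in_state[item] = max(in_state.get(item, 0), c.count)

    members: dict[int, set[str]] = {i: set() for i in range(1, n + 1)}
    for i in range(1, state_support + 1):
        members[i].add(STATE_ITEM)
    for item in sorted(set(totals) | set(in_state)):
        state_count = in_state.get(item, 0)
        total = totals.get(item, state_count)
        nonstate = total - state_count
        if state_count > state_support or nonstate < 0 or state_support + nonstate > n:
            raise ConstructionError(
                f"item {item!r}: counts (total {total}, with-state {state_count}) "
                f"do not fit n={n}, state_support={state_support}")
        for i in range(1, state_count + 1):
            members[i].add(item)
        for i in range(state_support + 1, state_support + nonstate + 1):
            members[i].add(item)

    transactions = [
        Transaction(f"T{i:02d}", frozenset(items if items else {FILLER_ITEM}))
        for i, items in members.items()
    ]

    # recount every constraint exactly before returning
    for c in constraints:
        got = sum(1 for t in transactions if c.itemset <= t.items)
        if got != c.count:
            raise ConstructionError(
                f"layout violates {c.describe()}: recounted {got}")
    return transactions


@dataclass
class Fixture:
    """A reconstructed mining dataset plus its derivation audit trail."""

    transactions: list[Transaction]
    constraints: list[CountConstraint]
    flagged_rows: list[int]
    n: int
    state_support: int

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"itemset": [" & ".join(sorted(c.itemset)) for c in self.constraints],
             "count": [c.count for c in self.constraints],
             "n": self.n}
        )


def build_fixture(n: int | None = None, state_support: int = 30,
                  rows: Sequence[tuple] | None = None) -> Fixture:
    """Recover n (if not given), invert the reference table and build the
    transaction set; the full round trip used by the mining reproduction."""
    rows = list(rows) if rows is not None else REFERENCE_RULE_TABLE
    if n is None:
        candidates = recover_n([r[2] for r in rows])
        if len(candidates) != 1:
            raise InversionError(
                f"denominator recovery did not isolate a unique n: {candidates}")
        n = candidates[0]
    constraints, flagged = invert_rule_table(rows, n)
    transactions = build_transactions(constraints, n, state_support)
    return Fixture(transactions, constraints, flagged, n, state_support)
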