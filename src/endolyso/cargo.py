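"""Candidate endocytic-cargo classification.

A candidate cargo is an IP-enriched protein with at least one
transmembrane segment that is annotated as localized in the cell
membrane.  Headline fractions — the share of all such plasma-membrane
proteins (or of those with synaptic annotation) captured in the
endosome IP — are reported both unrounded and rounded half-up to integer
percent, matching the convention of headline reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

log = logging.getLogger("endolyso")


def cargo_fraction(in_ip: int, universe: int) -> tuple[float, int]:
    """Percentage of a protein universe captured in the IP.

    Returns ``(percent, headline)`` where percent = 100 * in_ip / universe
    and headline is that value rounded half-up to an integer.
    """
    if universe <= 0:
        raise ValueError("universe must be > 0")
    if in_ip > universe:
        raise ValueError(f"in_ip ({in_ip}) exceeds universe ({universe})")
    pct = 100.0 * in_ip / universe
    headline = int(Decimal(str(pct)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return pct, headline


@dataclass
class CargoCallSet:
    """Candidate cargo with the counts behind the headline fractions."""

    candidates: frozenset[str]
    unclassifiable: frozenset[str]
    pm_universe: int
    pm_in_ip: int
    syngo_pm_universe: int
    syngo_pm_in_ip: int

    @property
    def pm_fraction(self) -> float:
        return cargo_fraction(self.pm_in_ip, self.pm_universe)[0]

    @property
    def pm_fraction_headline(self) -> int:
        return cargo_fraction(self.pm_in_ip, self.pm_universe)[1]

    @property
    def syngo_fraction(self) -> float:
        return cargo_fraction(self.syngo_pm_in_ip, self.syngo_pm_universe)[0]

    @property
    def syngo_fraction_headline(self) -> int:
        return cargo_fraction(self.syngo_pm_in_ip, self.syngo_pm_universe)[1]

    def summary(self) -> str:
        lines = [
            f"candidate cargo: {len(self.candidates)} "
            f"({len(self.unclassifiable)} enriched proteins unannotated)",
            f"PM/TM proteins in IP: {self.pm_in_ip}/{self.pm_universe} "
            f"({self.pm_fraction:.1f}% -> {self.pm_fraction_headline}%)",
        ]
        if self.syngo_pm_universe:
            lines.append(
                f"synaptic PM/TM in IP: {self.syngo_pm_in_ip}/{self.syngo_pm_universe} "
                f"({self.syngo_fraction:.1f}% -> {self.syngo_fraction_headline}%)")
        return "\n".join(lines)


def _is_pm_tm(ann: pd.DataFrame, p: str) -> bool:
    return bool(ann.at[p, "cell_membrane"]) and int(ann.at[p, "tm_count"]) >= 1


def select_candidate_cargo(enriched: set[str], ann: pd.DataFrame,
                           universe: set[str] | None = None,
                           syngo: set[str] | None = None) -> CargoCallSet:
    """Apply the cargo rule: enriched AND tm_count >= 1 AND cell_membrane.

    ``universe`` (default: all annotated proteins) defines the denominator
    of the plasma-membrane fraction; ``syngo`` restricts the synaptic
    denominator.  Enriched proteins missing from the annotation table are
    returned in an ``unclassifiable`` bin, not silently dropped.
    """
    universe = set(ann.index) if universe is None else set(universe)
    syngo = set() if syngo is None else set(syngo)
    annotated = set(ann.index)

    unclassifiable = frozenset(enriched - annotated)
    if unclassifiable:
        log.warning("[cargo] %d enriched protein(s) lack annotations", len(unclassifiable))
    candidates = frozenset(p for p in (enriched & annotated) if _is_pm_tm(ann, p))

    pm_universe = {p for p in (universe & annotated) if _is_pm_tm(ann, p)}
    syngo_pm = pm_universe & syngo
    return CargoCallSet(
        candidates=candidates,
        unclassifiable=unclassifiable,
        pm_universe=len(pm_universe),
        pm_in_ip=len(pm_universe & enriched),
        syngo_pm_universe=len(syngo_pm),
        syngo_pm_in_ip=len(syngo_pm & enriched),
    )


def domain_family_matrix(candidates: set[str], ann: pd.DataFrame,
                         syngo: set[str] | None = None
                         ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Binary candidate-by-annotation presence matrix plus category counts.

    Columns are ``domain:<name>`` and ``family:<name>``; rows are grouped
    by (first) family then sorted by identifier, with a ``synaptic``
    membership flag.  Counts partition the candidates into ``both`` (at
    least one domain and one family), ``one`` (exactly one of the two
    annotation kinds), and ``neither``.
    """
    syngo = set() if syngo is None else set(syngo)
    members = sorted(candidates & set(ann.index))
    domains = sorted(set().union(*(ann.at[p, "domains"] for p in members))) if members else []
    families = sorted(set().union(*(ann.at[p, "families"] for p in members))) if members else []

    counts = {"both": 0, "one": 0, "neither": 0}
    rows = []
    for p in members:
        d, f = ann.at[p, "domains"], ann.at[p, "families"]
        if d and f:
            counts["both"] += 1
        elif d or f:
            counts["one"] += 1
        else:
            counts["neither"] += 1
        row = {"protein": p,
               "family_group": min(f) if f else "~none",
               "synaptic": p in syngo}
        row.update({f"domain:{x}": int(x in d) for x in domains})
        row.update({f"family:{x}": int(x in f) for x in families})
        rows.append(row)
    matrix = pd.DataFrame(rows)
    if len(matrix):
        matrix = (matrix.sort_values(["family_group", "protein"], kind="stable")
                        .set_index("protein"))
    return matrix, counts
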