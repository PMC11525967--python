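"""Timed cell-lineage trees and fate-classification rules.

A lineage record is what a 4D-microscopy observer produces: every tracked cell
carries its birth time, and at most one terminal event — a division or a
corpse ("erythrocyte"-stage, button-like appearance under DIC) — plus the last
time it was seen.  Times are float minutes from the start of the recording.

Cell names follow Sulston nomenclature: a founder blastomere (AB, MS, E, C, D,
...) followed by one letter per division giving the daughter's position
(a/p, l/r, d/v), e.g. ``ABalaapapa``.  Postembryonic names may contain dots
(``QL.pp``), which do not count as divisions.

Programmed-death candidates are scored with the rules used in 4D lineaging of
cell-death mutants: a candidate that has not formed a corpse before the next
round of division starts in other cells of its generation, or within a time
corresponding to twice its mother's cell-cycle length (whichever comes first),
is called *cell_death_blocked*; candidates that can be followed past neither
criterion are *lost*; mothers that fail to divide or die precociously are
reported as their own categories.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "LineageNode",
    "LineageRecord",
    "RecordingMetadata",
    "FateRuleConfig",
    "FateCall",
    "CELL_DEATH",
    "CELL_DEATH_BLOCKED",
    "LOST",
    "MOTHER_DIVISION_BLOCKED",
    "MOTHER_DIES",
    "SISTER_CATEGORIES",
    "parse_lineage",
    "records_to_csv",
    "records_to_json",
    "mother_name",
    "sister_name",
    "generation",
    "cell_cycle_length",
    "time_to_corpse",
    "classify_death_fate",
    "classify_sister_fate",
    "percent_blocked",
    "fate_summary",
    "sister_fate_analysis",
    "lineage_cycle_series",
]

# fate categories for programmed-death candidates
CELL_DEATH = "cell_death"
CELL_DEATH_BLOCKED = "cell_death_blocked"
LOST = "lost"
MOTHER_DIVISION_BLOCKED = "mother_division_blocked"
MOTHER_DIES = "mother_dies"
FATE_CATEGORIES = (
    CELL_DEATH,
    CELL_DEATH_BLOCKED,
    LOST,
    MOTHER_DIVISION_BLOCKED,
    MOTHER_DIES,
)

# categories for sisters of programmed-death candidates
SISTER_CATEGORIES = (
    "divided",
    "division_blocked",
    "inappropriate_death",
    "lost",
    "not_applicable",
)

# founder blastomeres, matched longest-first so "ABa..." resolves to AB etc.
# Depth = number of divisions separating the founder itself from the zygote,
# so `generation` is comparable across founders (AB8-letter cells and MSpaapp
# are both generation 9 — the first wave of cell death).
_FOUNDER_DEPTH = {
    "P0": 0, "AB": 1, "P1": 1, "EMS": 2, "P2": 2,
    "MS": 3, "E": 3, "C": 3, "P3": 3, "D": 4, "P4": 4,
    "Z2": 5, "Z3": 5,
    # postembryonic Q neuroblasts (AB descendants)
    "Q": 10, "QL": 10, "QR": 10,
}
_TRUE_FOUNDERS = tuple(_FOUNDER_DEPTH)

_PAIR = {"a": "p", "p": "a", "l": "r", "r": "l", "d": "v", "v": "d"}


class CellNeverDividedError(ValueError):
    """Raised when a cycle length is requested for a cell with no division.

    Distinct from a *blocked* classification: absence of a division event is a
    data condition, blocking is a biological call made by the classifier.
    """


def _founder(name: str) -> str:
    for f in sorted(_TRUE_FOUNDERS, key=len, reverse=True):
        if name.startswith(f):
            return f
    raise ValueError(f"cell name {name!r} does not start with a known founder")


def generation(name: str) -> int:
    """Number of divisions separating a cell from the zygote."""
    founder = _founder(name)
    suffix = name[len(founder):]
    return _FOUNDER_DEPTH[founder] + sum(1 for c in suffix if c != ".")


def mother_name(name: str) -> str:
    """Name of the mother cell (one suffix letter shorter)."""
    base = name[:-1]
    base = base.rstrip(".")
    if not base:
        raise ValueError(f"cell {name!r} has no mother name")
    return base


def sister_name(name: str) -> str:
    """Name of the sister cell (last letter flipped within its a/p, l/r, d/v pair)."""
    last = name[-1]
    if last not in _PAIR:
        raise ValueError(f"cannot derive a sister for {name!r}: last letter {last!r}")
    return name[:-1] + _PAIR[last]


@dataclass(frozen=True)
class RecordingMetadata:
    """Acquisition metadata of a 4D recording (not enforced on the times)."""

    frame_interval_s: float = 35.0
    temperature_c: float = 25.0
    daughter_marking_lag_s: float = 105.0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0 or self.daughter_marking_lag_s <= 0:
            raise ValueError("recording intervals must be positive")


@dataclass
class LineageNode:
    """One tracked cell: birth, optional terminal event, last observation."""

    name: str
    birth_min: float
    division_min: Optional[float] = None
    corpse_min: Optional[float] = None
    last_observed_min: Optional[float] = None
    parent: Optional[str] = None
    children: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.division_min is not None and self.corpse_min is not None:
            raise ValueError(
                f"{self.name}: a cell cannot both divide and form a corpse"
            )
        for label, t in (("division", self.division_min),
                         ("corpse", self.corpse_min),
                         ("last_observed", self.last_observed_min)):
            if t is not None and t < self.birth_min:
                raise ValueError(
                    f"{self.name}: {label} time {t} precedes birth {self.birth_min}"
                )

    @property
    def observed_until(self) -> float:
        """Latest time the cell (or its terminal event) was seen."""
        times = [self.birth_min]
        for t in (self.division_min, self.corpse_min, self.last_observed_min):
            if t is not None:
                times.append(t)
        return max(times)


class LineageRecord:
    """A validated forest of :class:`LineageNode` for one embryo."""

    def __init__(
        self,
        embryo_id: str,
        nodes: Iterable[LineageNode],
        metadata: RecordingMetadata | None = None,
    ) -> None:
        self.embryo_id = embryo_id
        self.metadata = metadata or RecordingMetadata()
        self.nodes: dict[str, LineageNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise ValueError(f"duplicate cell name {node.name!r}")
            self.nodes[node.name] = node
        self._link_and_validate()

    def _link_and_validate(self) -> None:
        for node in self.nodes.values():
            node.children = []
        for node in self.nodes.values():
            if node.parent is None:
                continue
            if node.parent not in self.nodes:
                raise ValueError(
                    f"{node.name}: parent {node.parent!r} not in record "
                    f"(orphan node)"
                )
            mother = self.nodes[node.parent]
            if node.birth_min < mother.birth_min:
                raise ValueError(
                    f"{node.name}: born at {node.birth_min} before its mother "
                    f"{mother.name} (born {mother.birth_min})"
                )
            mother.children.append(node.name)
        # cycle detection on parent links
        for start in self.nodes:
            seen = set()
            cur: Optional[str] = start
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cyclic parentage involving {cur!r}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __getitem__(self, name: str) -> LineageNode:
        return self.nodes[name]

    @property
    def roots(self) -> list[LineageNode]:
        return [n for n in self.nodes.values() if n.parent is None]

    def cohort_next_division(self, gen: int) -> Optional[float]:
        """Earliest division time among tracked cells of generation ``gen``.

        This is the start of the "next round of cell division" relative to the
        cells born into that generation.
        """
        times = [
            n.division_min
            for n in self.nodes.values()
            if n.division_min is not None and generation(n.name) == gen
        ]
        return min(times) if times else None


@dataclass(frozen=True)
class FateRuleConfig:
    """Thresholds for calling a programmed cell death blocked.

    ``block_threshold_factor`` — multiple of the mother's cell-cycle length a
    candidate is allowed to survive before being called blocked (the 4D
    lineaging convention is 2.0, i.e. twice the mother's cycle).
    ``also_blocked_if_next_round_started`` — additionally treat the start of
    the next division round in the candidate's generation cohort as the
    deadline, whichever comes first.
    """

    block_threshold_factor: float = 2.0
    also_blocked_if_next_round_started: bool = True

    def __post_init__(self) -> None:
        if self.block_threshold_factor <= 0:
            raise ValueError("block_threshold_factor must be positive")


@dataclass(frozen=True)
class FateCall:
    """Outcome of classifying one programmed-death candidate."""

    candidate: str
    category: str
    birth_min: Optional[float] = None
    time_to_corpse_min: Optional[float] = None
    mother_cycle_min: Optional[float] = None
    deadline_min: Optional[float] = None
    note: str = ""


# ---------------------------------------------------------------------------
# elementary measurements
# ---------------------------------------------------------------------------

def cell_cycle_length(node: LineageNode) -> float:
    """Minutes from a cell's birth to its own division."""
    if node.division_min is None:
        raise CellNeverDividedError(
            f"{node.name} has no division event; cycle length undefined"
        )
    length = node.division_min - node.birth_min
    if length == 0:
        warnings.warn(
            f"{node.name}: degenerate division at the moment of birth",
            stacklevel=2,
        )
    return length


def time_to_corpse(node: LineageNode) -> float:
    """Minutes from a cell's birth to corpse ("erythrocyte" stage) formation."""
    if node.corpse_min is None:
        raise ValueError(f"{node.name} has no corpse event")
    return node.corpse_min - node.birth_min


# ---------------------------------------------------------------------------
# fate classification
# ---------------------------------------------------------------------------

def _death_deadline(
    record: LineageRecord,
    candidate: str,
    birth: float,
    mother_cycle: float,
    rules: FateRuleConfig,
) -> float:
    deadline = birth + rules.block_threshold_factor * mother_cycle
    if rules.also_blocked_if_next_round_started:
        nxt = record.cohort_next_division(generation(candidate))
        if nxt is not None:
            deadline = min(deadline, nxt)
    return deadline


def classify_death_fate(
    record: LineageRecord,
    candidate: str,
    rules: FateRuleConfig | None = None,
) -> FateCall:
    """Assign exactly one fate category to a programmed-death candidate.

    Categories: ``mother_dies`` (precocious mother death),
    ``mother_division_blocked`` (mother never divided), ``cell_death`` (corpse
    before the deadline), ``cell_death_blocked`` (no corpse, observed past the
    deadline), ``lost`` (neither criterion could be evaluated).
    """
    rules = rules or FateRuleConfig()
    mname = mother_name(candidate)
    if mname not in record:
        raise ValueError(
            f"mother {mname!r} of candidate {candidate!r} missing from record "
            f"{record.embryo_id}"
        )
    mother = record[mname]
    if mother.corpse_min is not None:
        return FateCall(candidate, MOTHER_DIES, note=f"mother {mname} died")
    if mother.division_min is None:
        return FateCall(
            candidate, MOTHER_DIVISION_BLOCKED, note=f"mother {mname} never divided"
        )

    mother_cycle = mother.division_min - mother.birth_min
    node = record.nodes.get(candidate)
    birth = node.birth_min if node is not None else mother.division_min
    deadline = _death_deadline(record, candidate, birth, mother_cycle, rules)

    if node is None:
        return FateCall(
            candidate, LOST, birth, None, mother_cycle, deadline,
            note="candidate untracked after mother division",
        )
    if node.corpse_min is not None:
        ttc = node.corpse_min - node.birth_min
        if node.corpse_min <= deadline:
            return FateCall(candidate, CELL_DEATH, birth, ttc, mother_cycle, deadline)
        return FateCall(
            candidate, LOST, birth, ttc, mother_cycle, deadline,
            note="corpse formed only after the deadline",
        )
    if node.observed_until >= deadline:
        return FateCall(
            candidate, CELL_DEATH_BLOCKED, birth, None, mother_cycle, deadline
        )
    return FateCall(
        candidate, LOST, birth, None, mother_cycle, deadline,
        note="observation window too short",
    )


def percent_blocked(calls: Iterable[FateCall]) -> float:
    """100 × blocked / (blocked + died); NaN when no candidate is scoreable.

    Lost candidates and mother phenotypes are excluded from the denominator
    (they are tabulated separately by :func:`fate_summary`).
    """
    calls = list(calls)
    if not calls:
        raise ValueError("no fate calls given")
    blocked = sum(c.category == CELL_DEATH_BLOCKED for c in calls)
    died = sum(c.category == CELL_DEATH for c in calls)
    if blocked + died == 0:
        return math.nan
    return 100.0 * blocked / (blocked + died)


def fate_summary(calls: Iterable[FateCall]) -> dict:
    """Counts per category plus the blocked percentage."""
    calls = list(calls)
    counts = {cat: sum(c.category == cat for c in calls) for cat in FATE_CATEGORIES}
    return {
        "n_candidates": len(calls),
        "counts": counts,
        "percent_blocked": percent_blocked(calls),
    }


def classify_sister_fate(
    record: LineageRecord,
    candidate: str,
    rules: FateRuleConfig | None = None,
) -> str:
    """Fate category of the sister of a programmed-death candidate.

    ``not_applicable`` when the mother already shows a phenotype (died or
    failed to divide); otherwise ``divided``, ``inappropriate_death``,
    ``division_blocked`` (followed at least ``block_threshold_factor`` mother
    cycles without dividing) or ``lost``.
    """
    rules = rules or FateRuleConfig()
    mname = mother_name(candidate)
    if mname not in record:
        raise ValueError(f"mother {mname!r} of {candidate!r} missing from record")
    mother = record[mname]
    if mother.corpse_min is not None or mother.division_min is None:
        return "not_applicable"
    sname = sister_name(candidate)
    if sname not in record:
        warnings.warn(
            f"sister {sname} of {candidate} missing from record "
            f"{record.embryo_id}; counting as lost",
            stacklevel=2,
        )
        return "lost"
    sister = record[sname]
    if sister.corpse_min is not None:
        return "inappropriate_death"
    if sister.division_min is not None:
        return "divided"
    mother_cycle = mother.division_min - mother.birth_min
    if sister.observed_until >= sister.birth_min + rules.block_threshold_factor * mother_cycle:
        return "division_blocked"
    return "lost"


def sister_fate_analysis(
    record_or_records,
    candidates: Iterable[str],
    rules: FateRuleConfig | None = None,
) -> pd.DataFrame:
    """Tabulate sister fates across one or several records.

    Returns a DataFrame indexed by category with ``count``, ``fraction`` (of
    all sisters) and ``fraction_applicable`` (of sisters whose mother showed
    no phenotype and that were not lost — the denominator used when reporting
    e.g. the fraction of sisters whose division is blocked).
    """
    records = (
        [record_or_records]
        if isinstance(record_or_records, LineageRecord)
        else list(record_or_records)
    )
    candidates = list(candidates)
    cats = []
    for rec in records:
        for cand in candidates:
            cats.append(classify_sister_fate(rec, cand, rules))
    counts = {c: cats.count(c) for c in SISTER_CATEGORIES}
    total = len(cats)
    applicable = sum(
        counts[c] for c in ("divided", "division_blocked", "inappropriate_death")
    )
    rows = {}
    for c in SISTER_CATEGORIES:
        rows[c] = {
            "count": counts[c],
            "fraction": counts[c] / total if total else math.nan,
            "fraction_applicable": (
                counts[c] / applicable
                if applicable and c not in ("lost", "not_applicable")
                else math.nan
            ),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def lineage_cycle_series(
    record: LineageRecord,
    terminal_name: str,
    start_name: str | None = None,
) -> list[float]:
    """Cell-cycle lengths along the ancestry path down to a terminal cell.

    Follows parent links from the terminal cell's mother back to
    ``start_name`` (default: the root ancestor) and returns the cycle length
    of each ancestor in division order, e.g. the five cycles from ABarp to the
    birth of ABarpppppp.
    """
    if terminal_name not in record:
        raise ValueError(f"terminal cell {terminal_name!r} not in record")
    if start_name == terminal_name:
        return []
    chain: list[LineageNode] = []
    cur = record[terminal_name]
    while cur.parent is not None:
        cur = record[cur.parent]
        chain.append(cur)
        if start_name is not None and cur.name == start_name:
            break
    else:
        if start_name is not None:
            raise ValueError(
                f"ancestry path from {terminal_name!r} breaks at {cur.name!r} "
                f"before reaching {start_name!r}"
            )
    chain.reverse()
    return [cell_cycle_length(n) for n in chain]


# ---------------------------------------------------------------------------
# serialisation: CSV (flat) and JSON (nested tree)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "embryo_id", "cell_name", "parent_name",
    "birth_min", "division_min", "corpse_min", "last_observed_min",
]


def records_to_frame(records: Iterable[LineageRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for node in rec.nodes.values():
            rows.append({
                "embryo_id": rec.embryo_id,
                "cell_name": node.name,
                "parent_name": node.parent or "",
                "birth_min": node.birth_min,
                "division_min": node.division_min,
                "corpse_min": node.corpse_min,
                "last_observed_min": node.last_observed_min,
            })
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def records_to_csv(records: Iterable[LineageRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def _node_to_tree(record: LineageRecord, node: LineageNode) -> dict:
    return {
        "name": node.name,
        "birth_min": node.birth_min,
        "division_min": node.division_min,
        "corpse_min": node.corpse_min,
        "last_observed_min": node.last_observed_min,
        "children": [
            _node_to_tree(record, record[c]) for c in sorted(node.children)
        ],
    }


def records_to_json(records: Iterable[LineageRecord], path) -> None:
    payload = {
        "embryos": [
            {
                "embryo_id": rec.embryo_id,
                "roots": [_node_to_tree(rec, r)
                          for r in sorted(rec.roots, key=lambda n: n.name)],
            }
            for rec in records
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def _frame_to_records(df: pd.DataFrame, source: str) -> list[LineageRecord]:
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing columns {missing}")
    records = []
    for embryo_id, group in df.groupby("embryo_id", sort=False):
        nodes = []
        for idx, row in group.iterrows():
            def _opt(v):
                return None if pd.isna(v) else float(v)
            parent = row["parent_name"]
            parent = None if (pd.isna(parent) or parent == "") else str(parent)
            try:
                nodes.append(LineageNode(
                    name=str(row["cell_name"]),
                    birth_min=float(row["birth_min"]),
                    division_min=_opt(row["division_min"]),
                    corpse_min=_opt(row["corpse_min"]),
                    last_observed_min=_opt(row["last_observed_min"]),
                    parent=parent,
                ))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{source}, row {idx}: {exc}") from exc
        records.append(LineageRecord(str(embryo_id), nodes))
    return records


def _tree_to_nodes(tree: dict, parent: str | None, out: list[LineageNode]) -> None:
    out.append(LineageNode(
        name=tree["name"],
        birth_min=float(tree["birth_min"]),
        division_min=tree.get("division_min"),
        corpse_min=tree.get("corpse_min"),
        last_observed_min=tree.get("last_observed_min"),
        parent=parent,
    ))
    for child in tree.get("children", []):
        _tree_to_nodes(child, tree["name"], out)


def parse_lineage(path) -> list[LineageRecord]:
    """Read lineage records from a CSV table or a nested-JSON tree file.

    Validation is strict: orphan nodes, duplicate names, cyclic parentage and
    time inversions are rejected with row-level messages.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        records = []
        for emb in payload["embryos"]:
            nodes: list[LineageNode] = []
            for root in emb["roots"]:
                _tree_to_nodes(root, None, nodes)
            records.append(LineageRecord(emb["embryo_id"], nodes))
        return records
    df = pd.read_csv(path, comment="#")
    return _frame_to_records(df, str(path))
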