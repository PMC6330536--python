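"""Homologous-group assignment, congruous-loci summaries and rearrangement calls.

Each linkage group of the polyploid map is anchored to the diploid
relative's genome through its markers' reference gene models.  The group
is assigned to the homologous group (HG) of its majority anchor
chromosome; markers anchored there are "congruous", and a block of at
least three markers anchored to a different chromosome is called as an
interchromosomal rearrangement (translocation signature).  Events found
in two species' maps are matched by unordered chromosome pair — events
on the same pair in both species predate the speciation split.

Anchors to unplaced scaffolds ("other") count toward group totals but
never toward congruous markers nor rearrangement events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "HGAssignment",
    "RearrangementEvent",
    "SharedEventsReport",
    "OTHER",
    "assign_hg",
    "congruous_percent",
    "congruous_summary",
    "detect_events",
    "shared_events",
    "shared_percentage",
    "collinearity",
    "analyze_map",
    "MapAnalysis",
]

OTHER = "other"


@dataclass
class HGAssignment:
    """One linkage group's anchor-majority chromosome assignment."""

    group_id: str
    chrom: str | None            # None when no marker is anchored
    congruous: int
    total: int                   # all anchored markers, incl. "other"
    counts: dict[str, int]
    tied: bool = False

    @property
    def fraction(self) -> float:
        return self.congruous / self.total if self.total else float("nan")


@dataclass(frozen=True)
class RearrangementEvent:
    """>=3 markers of one group anchored to a non-majority chromosome."""

    group_id: str
    majority: str
    foreign: str
    markers: tuple[str, ...]

    @property
    def support(self) -> int:
        return len(self.markers)

    @property
    def pair(self) -> frozenset:
        return frozenset((self.majority, self.foreign))


def _longest_run(chrom_seq: list[str], chrom: str) -> int:
    best = cur = 0
    for c in chrom_seq:
        cur = cur + 1 if c == chrom else 0
        best = max(best, cur)
    return best


def assign_hg(group_id: str, ordered_markers: list[str],
              anchors: dict[str, str]) -> HGAssignment:
    """Assign a group to its majority anchor chromosome.

    ``ordered_markers`` follow the map order; ``anchors`` maps marker id
    to reference chromosome (``"other"`` for unplaced scaffolds;
    unanchored markers may be absent).  Ties on the count are broken
    toward the chromosome with the longest run of map-adjacent markers,
    then the lexicographically smallest chromosome, and flagged.
    """
    seq = [anchors[m] for m in ordered_markers if m in anchors]
    counts: dict[str, int] = {}
    for c in seq:
        counts[c] = counts.get(c, 0) + 1
    real = {c: n for c, n in counts.items() if c != OTHER}
    if not real:
        return HGAssignment(group_id=group_id, chrom=None, congruous=0,
                            total=len(seq), counts=counts)
    top = max(real.values())
    tied = sorted(c for c, n in real.items() if n == top)
    if len(tied) == 1:
        chrom = tied[0]
        was_tie = False
    else:
        runs = {c: _longest_run(seq, c) for c in tied}
        best_run = max(runs.values())
        chrom = sorted(c for c in tied if runs[c] == best_run)[0]
        was_tie = True
    return HGAssignment(group_id=group_id, chrom=chrom, congruous=real[chrom],
                        total=len(seq), counts=counts, tied=was_tie)


def congruous_percent(congruous: int, total: int) -> float:
    """Percentage of mapped markers anchored to their majority chromosome."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * congruous / total, 1)


def congruous_summary(assignments: list[HGAssignment]) -> tuple[pd.DataFrame, float]:
    """Per-HG congruous counts and the overall percentage.

    HGs aggregate linkage groups by assigned chromosome; the overall
    fraction is sum(congruous)/sum(total) over all assigned groups,
    which equals the total-weighted mean of per-group fractions.
    """
    assigned = [a for a in assignments if a.chrom is not None]
    if not assigned:
        raise ValueError("no assigned groups")
    rows = []
    for chrom in sorted({a.chrom for a in assigned}):
        sub = [a for a in assigned if a.chrom == chrom]
        cong = sum(a.congruous for a in sub)
        tot = sum(a.total for a in sub)
        rows.append({"hg": chrom, "n_groups": len(sub), "congruous": cong,
                     "total": tot, "percent": congruous_percent(cong, tot)})
    table = pd.DataFrame(rows)
    overall = congruous_percent(int(table["congruous"].sum()), int(table["total"].sum()))
    return table, overall


def detect_events(group_id: str, ordered_markers: list[str],
                  anchors: dict[str, str], assignment: HGAssignment,
                  min_support: int = 3) -> list[RearrangementEvent]:
    """Interchromosomal rearrangement calls for one linkage group.

    One event per foreign chromosome with at least ``min_support``
    anchored markers in the group; unplaced-scaffold anchors never form
    events.  Foreign markers need not be adjacent in the map.
    """
    if assignment.chrom is None:
        return []
    events = []
    for chrom in sorted(assignment.counts):
        if chrom in (assignment.chrom, OTHER):
            continue
        support = tuple(m for m in ordered_markers
                        if anchors.get(m) == chrom)
        if len(support) >= min_support:
            events.append(RearrangementEvent(group_id=group_id,
                                             majority=assignment.chrom,
                                             foreign=chrom, markers=support))
    return events


@dataclass
class SharedEventsReport:
    """Cross-species intersection of rearrangement events.

    Events are matched by unordered chromosome pair; several groups
    detecting the same pair within a species collapse to one pair for
    matching but every event stays listed.  ``percent`` is the shared
    event count (summed over both species) over the combined event
    count, as a percentage.
    """

    n_a: int
    n_b: int
    shared_pairs: set = field(default_factory=set)
    shared_a: int = 0
    shared_b: int = 0

    @property
    def shared_total(self) -> int:
        return self.shared_a + self.shared_b

    @property
    def percent(self) -> float:
        return shared_percentage(self.shared_total, self.n_a, self.n_b)


def shared_percentage(n_shared_total: int, n_a: int, n_b: int) -> float:
    """Shared events over combined events, in percent (1 decimal)."""
    if n_a + n_b <= 0:
        raise ValueError("no events")
    return round(100.0 * n_shared_total / (n_a + n_b), 1)


def shared_events(events_a: list[RearrangementEvent],
                  events_b: list[RearrangementEvent]) -> SharedEventsReport:
    """Match two species' rearrangement events by chromosome pair."""
    pairs_a = {e.pair for e in events_a}
    pairs_b = {e.pair for e in events_b}
    common = pairs_a & pairs_b
    return SharedEventsReport(
        n_a=len(events_a), n_b=len(events_b), shared_pairs=common,
        shared_a=sum(e.pair in common for e in events_a),
        shared_b=sum(e.pair in common for e in events_b),
    )


def collinearity(ordered_markers: list[str], anchors_pos: dict[str, tuple[str, int]],
                 assignment: HGAssignment, min_markers: int = 5) -> float | None:
    """Spearman rho between map order and reference position of congruous markers.

    |rho| near 1 indicates collinearity with the reference chromosome;
    the sign gives orientation.  Not computed (None) below
    ``min_markers`` congruous markers — only groups with significant
    synteny are summarised.
    """
    if assignment.chrom is None:
        return None
    ranks, positions = [], []
    for rank, m in enumerate(ordered_markers):
        if m in anchors_pos and anchors_pos[m][0] == assignment.chrom:
            ranks.append(rank)
            positions.append(anchors_pos[m][1])
    if len(ranks) < min_markers:
        return None
    rho, _ = spearmanr(ranks, positions)
    return float(rho)


@dataclass
class MapAnalysis:
    """Synteny analysis of one species' map."""

    assignments: list[HGAssignment]
    events: list[RearrangementEvent]
    hg_table: pd.DataFrame
    overall_percent: float
    collinearity: dict[str, float | None]


def analyze_map(map_df: pd.DataFrame, anchors_df: pd.DataFrame,
                min_support: int = 3, min_collinear: int = 5) -> MapAnalysis:
    """Full synteny pass over a map table.

    ``map_df`` needs columns (group, order, marker_id); ``anchors_df``
    needs (marker_id, chrom) and optionally pos for collinearity.
    """
    anchors = dict(zip(anchors_df["marker_id"], anchors_df["chrom"]))
    pos = (dict(zip(anchors_df["marker_id"],
                    zip(anchors_df["chrom"], anchors_df["pos"])))
           if "pos" in anchors_df.columns else {})
    assignments, events, rho = [], [], {}
    for group, sub in map_df.sort_values(["group", "order"]).groupby("group", sort=True):
        ordered = list(sub["marker_id"])
        a = assign_hg(str(group), ordered, anchors)
        assignments.append(a)
        events.extend(detect_events(str(group), ordered, anchors, a,
                                    min_support=min_support))
        rho[str(group)] = collinearity(ordered, pos, a, min_markers=min_collinear) \
            if pos else None
    hg_table, overall = congruous_summary(assignments)
    return MapAnalysis(assignments=assignments, events=events, hg_table=hg_table,
                       overall_percent=overall, collinearity=rho)
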