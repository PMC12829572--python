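"""Partition genomes into intervals between consecutive persistent genes
and group intervals across genomes into spots.

An *interval* is the region delimited by two consecutive persistent genes
on a contig; on a circular contig with k persistent genes there are
exactly k intervals, including the wrap-around one. A *spot* is the set
of intervals, across genomes, flanked by the same unordered pair of
persistent gene families — the unit of accessory-genome variability.
Persistent genes themselves belong to no interval.

Prophage and defense-system calls are assigned to intervals by the
midpoint rule: a call lies in the unique interval containing its span
midpoint. Span overlaps are additionally counted so elements crossing a
persistent gene (breaking adjacency) are reported, not silently merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: flank sentinels for linear contigs
CONTIG_START = "<contig-start>"
CONTIG_END = "<contig-end>"


@dataclass
class Interval:
    """A region between two consecutive persistent genes in one genome.

    ``span`` is [start, end) in bp, exclusive of the bounding persistent
    genes. A wrap-around interval on a circular contig has ``wraps=True``
    and numerically start >= end. A ``degenerate`` interval covers a whole
    contig with no persistent genes.
    """

    genome_id: str
    left_family: str
    right_family: str
    start: int
    end: int
    genes: tuple[str, ...] = ()
    wraps: bool = False
    degenerate: bool = False

    @property
    def flank_pair(self) -> tuple[str, str]:
        return tuple(sorted((self.left_family, self.right_family)))  # type: ignore[return-value]

    def contains(self, pos: int, genome_length: int) -> bool:
        """Membership of a coordinate, wrap-aware."""
        if self.degenerate:
            return 0 <= pos < genome_length
        if self.wraps:
            return pos >= self.start or pos < self.end
        return self.start <= pos < self.end

    def segments(self, genome_length: int) -> list[tuple[int, int]]:
        """The interval as 1-2 linear [start, end) segments."""
        if self.degenerate:
            return [(0, genome_length)]
        if self.wraps:
            segs = []
            if self.start < genome_length:
                segs.append((self.start, genome_length))
            if self.end > 0:
                segs.append((0, self.end))
            return segs
        return [(self.start, self.end)] if self.start < self.end else []


@dataclass
class Spot:
    """Cross-genome group of intervals sharing a flank pair of persistent families."""

    spot_id: str
    flank_pair: tuple[str, str]
    intervals: list[Interval] = field(default_factory=list)
    has_prophage: bool = False
    has_defense: bool = False

    @property
    def has_both(self) -> bool:
        return self.has_prophage and self.has_defense

    def duplicated_genomes(self) -> set[str]:
        """Genomes contributing >=2 intervals (locally duplicated persistent flank)."""
        seen: dict[str, int] = {}
        for iv in self.intervals:
            seen[iv.genome_id] = seen.get(iv.genome_id, 0) + 1
        return {g for g, c in seen.items() if c >= 2}


def build_intervals(
    genes: pd.DataFrame,
    family_of: Mapping[str, str],
    persistent: set[str],
    genome_length: int,
    circular: bool = True,
    genome_id: str | None = None,
) -> list[Interval]:
    """Split one genome's gene order into intervals between persistent genes.

    ``genes`` is the single-genome gene table (gene_id, start, end, ...),
    any order; it is sorted by start. Every gene whose family is not a
    flanking persistent gene is assigned to exactly one interval.
    """
    genes = genes.sort_values("start", kind="mergesort").reset_index(drop=True)
    gid = genome_id if genome_id is not None else (
        str(genes["genome"].iloc[0]) if "genome" in genes and len(genes) else "?"
    )
    order = list(genes[["gene_id", "start", "end"]].itertuples(index=False, name=None))
    pers_idx = [i for i, (g, _, _) in enumerate(order) if family_of.get(g) in persistent]

    if not pers_idx:
        return [
            Interval(
                genome_id=gid,
                left_family=CONTIG_START if not circular else "<none>",
                right_family=CONTIG_END if not circular else "<none>",
                start=0,
                end=genome_length,
                genes=tuple(g for g, _, _ in order),
                degenerate=True,
            )
        ]

    def fam(i: int) -> str:
        return family_of[order[i][0]]

    intervals: list[Interval] = []
    n = len(order)
    if circular:
        k = len(pers_idx)
        for j in range(k):
            i0, i1 = pers_idx[j], pers_idx[(j + 1) % k]
            wraps = j == k - 1  # the interval closing the circle
            if wraps:
                members = [order[i][0] for i in range(i0 + 1, n)] + [
                    order[i][0] for i in range(0, i1)
                ]
            else:
                members = [order[i][0] for i in range(i0 + 1, i1)]
            intervals.append(
                Interval(
                    genome_id=gid,
                    left_family=fam(i0),
                    right_family=fam(i1),
                    start=order[i0][2],
                    end=order[i1][1],
                    genes=tuple(members),
                    wraps=wraps,
                )
            )
        return intervals

    # linear contig: contig-end sentinels on both sides
    if len(pers_idx) < 2:
        warnings.warn(
            f"genome {gid}: fewer than 2 persistent genes on a linear contig; "
            "using contig-end sentinels",
            stacklevel=2,
        )
    bounds = [(-1, CONTIG_START)] + [(i, fam(i)) for i in pers_idx] + [(n, CONTIG_END)]
    for (i0, f0), (i1, f1) in zip(bounds, bounds[1:]):
        members = [order[i][0] for i in range(i0 + 1, i1)]
        start = order[i0][2] if i0 >= 0 else 0
        end = order[i1][1] if i1 < n else genome_length
        intervals.append(
            Interval(
                genome_id=gid,
                left_family=f0,
                right_family=f1,
                start=start,
                end=end,
                genes=tuple(members),
            )
        )
    return intervals


def group_spots(intervals: Iterable[Interval]) -> list[Spot]:
    """Group intervals by unordered flank pair into spots.

    Orientation-invariant: flanks (F3,F4) and (F4,F3) land in one spot.
    Degenerate whole-contig intervals are grouped under their sentinel
    pair rather than dropped.
    """
    by_pair: dict[tuple[str, str], list[Interval]] = {}
    for iv in intervals:
        by_pair.setdefault(iv.flank_pair, []).append(iv)
    spots = []
    for i, pair in enumerate(sorted(by_pair)):
        spots.append(Spot(spot_id=f"SPOT{i:05d}", flank_pair=pair, intervals=by_pair[pair]))
    return spots


def _midpoint(start: int, end: int, genome_length: int) -> int:
    mid = (start + end) // 2
    return mid % genome_length if genome_length else mid


def _span_segments(start: int, end: int, genome_length: int) -> list[tuple[int, int]]:
    """A possibly wrap-spanning call span as linear segments."""
    if end <= genome_length:
        return [(start, end)]
    return [(start, genome_length), (0, end - genome_length)]


def _overlaps(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> bool:
    return any(s0 < e1 and s1 < e0 for s0, e0 in a for s1, e1 in b)


@dataclass
class SpotContent:
    """Result of assigning prophage/defense calls to intervals and spots."""

    spots: list[Spot]
    counts: dict[str, int]
    prophage_assignments: pd.DataFrame  # call index -> spot / interval / n_overlaps
    defense_assignments: pd.DataFrame


def classify_spot_content(
    spots: list[Spot],
    prophage_calls: pd.DataFrame,
    defense_calls: pd.DataFrame,
    genome_lengths: Mapping[str, int],
) -> SpotContent:
    """Flag spot content and tabulate cohort counts.

    A spot has a prophage (defense system) iff at least one member
    interval contains the midpoint of at least one call. ``n_overlaps``
    records how many intervals each call's span overlaps; values > 1 mark
    elements crossing a persistent gene.

    Call tables need columns ``genome, start, end`` (defense calls also
    ``system_id``). Raises on calls naming genomes absent from the
    collection.
    """
    by_genome: dict[str, list[tuple[Spot, Interval]]] = {}
    for spot in spots:
        for iv in spot.intervals:
            by_genome.setdefault(iv.genome_id, []).append((spot, iv))

    def assign(calls: pd.DataFrame, kind: str) -> pd.DataFrame:
        rows = []
        for idx, row in calls.iterrows():
            genome = row["genome"]
            if genome not in genome_lengths:
                raise ValueError(f"{kind} call on unknown genome {genome!r}")
            glen = genome_lengths[genome]
            mid = _midpoint(int(row["start"]), int(row["end"]), glen)
            call_segs = _span_segments(int(row["start"]), int(row["end"]), glen)
            hit_spot, hit_iv, n_over = None, None, 0
            for spot, iv in by_genome.get(genome, []):
                if _overlaps(iv.segments(glen), call_segs):
                    n_over += 1
                if iv.contains(mid, glen):
                    hit_spot, hit_iv = spot, iv
            rows.append(
                {
                    "call_index": idx,
                    "genome": genome,
                    "midpoint": mid,
                    "spot_id": hit_spot.spot_id if hit_spot else None,
                    "interval_start": hit_iv.start if hit_iv else None,
                    "n_overlaps": n_over,
                }
            )
            if hit_spot is not None:
                if kind == "prophage":
                    hit_spot.has_prophage = True
                else:
                    hit_spot.has_defense = True
        return pd.DataFrame(
            rows,
            columns=["call_index", "genome", "midpoint", "spot_id", "interval_start", "n_overlaps"],
        )

    pro = assign(prophage_calls, "prophage")
    dfn = assign(defense_calls, "defense")
    if "system_id" in defense_calls.columns and len(dfn):
        dfn["system_id"] = defense_calls["system_id"].to_numpy()
    counts = {
        "n_spots": len(spots),
        "n_with_prophage": sum(s.has_prophage for s in spots),
        "n_with_defense": sum(s.has_defense for s in spots),
        "n_with_both": sum(s.has_both for s in spots),
    }
    return SpotContent(spots=spots, counts=counts, prophage_assignments=pro, defense_assignments=dfn)


def spots_to_frame(spots: Iterable[Spot]) -> pd.DataFrame:
    rows = [
        {
            "spot_id": s.spot_id,
            "flank_a": s.flank_pair[0],
            "flank_b": s.flank_pair[1],
            "n_intervals": len(s.intervals),
            "n_duplicated_genomes": len(s.duplicated_genomes()),
            "has_prophage": s.has_prophage,
            "has_defense": s.has_defense,
            "has_both": s.has_both,
        }
        for s in spots
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "spot_id", "flank_a", "flank_b", "n_intervals",
            "n_duplicated_genomes", "has_prophage", "has_defense", "has_both",
        ],
    )
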