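"""Position defense systems relative to prophages and packaging direction;
compute lateral-transduction (LT) regions and headful-distance maps.

A headful packager that initiates at its pac site and runs off the end of
an integrated prophage keeps packaging chromosomal DNA, one capsid
headful (~45 kb) at a time, downstream of the attachment site. Defense
systems are located by the midpoint of their (possibly multi-gene) span
and labelled relative to each oriented prophage: before the terminase
genes (not packaged by LT), between terminase and the prophage end
(packaged), or in flanking chromosomal windows.

All coordinates are 0-based half-open; circular genomes wrap.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import percentage
from .prophagecls import ProphageCall

DEFAULT_HEADFUL_BP = 45_000
DEFAULT_WINDOW_BP = 25_000


@dataclass
class DefenseSystem:
    """One called defense system: possibly several consecutive genes."""

    genome: str
    system_id: str
    system_name: str
    start: int
    end: int
    gene_ids: tuple[str, ...] = ()


class RegionLabel(enum.Enum):
    """Location of a defense system relative to one oriented prophage.

    In the packaging frame (prophage reading rightward from its Int/att
    end), ``int_to_terminase`` spans prophage start to the end of TerL
    (DNA ahead of the packaging signal, not moved by LT) and
    ``terminase_to_end`` spans from after TerL to the prophage end (DNA
    behind the signal, mobilized by LT along with downstream chromosome).
    """

    upstream_of_prophage = "upstream_of_prophage"
    int_to_terminase = "int_to_terminase"
    terminase_to_end = "terminase_to_end"
    downstream_window = "downstream_window"
    chromosomal_far = "chromosomal_far"


def midpoint(system: DefenseSystem, genome_length: int | None = None) -> int:
    """floor((start+end)/2); wrap-spanning spans are unwrapped then reduced.

    A system crossing the origin of a circular genome is given with
    end > genome_length (unwrapped); its midpoint is computed on the
    unwrapped span and reduced modulo the genome length.
    """
    if system.start >= system.end:
        raise ValueError(f"invalid span [{system.start},{system.end}) for {system.system_id}")
    mid = (system.start + system.end) // 2
    if genome_length:
        mid %= genome_length
    return mid


def _gene_span(call: ProphageCall, gene: str, gene_coords: Mapping[str, tuple[int, int]]) -> tuple[int, int]:
    if gene not in gene_coords:
        raise ValueError(f"no coordinates for gene {gene!r}")
    return gene_coords[gene]


def _packaging_frame_offset(
    pos: int, call: ProphageCall, genome_length: int, circular: bool
) -> int:
    """Directed offset of `pos` from the prophage's att/Int end.

    Rightward-packaging prophages measure from `start` increasing with
    the coordinate; leftward ones are mirrored so one code path serves
    both. Circular genomes take the offset modulo genome length, then
    shift offsets in the upstream half back to negative values so that
    "just before the prophage" is a small negative number.
    """
    if call.orientation == "packaging_rightward":
        off = pos - call.start
    elif call.orientation == "packaging_leftward":
        off = call.end - 1 - pos
    else:
        raise ValueError(
            f"prophage {call.prophage_id or call.genome} has unknown orientation; "
            "exclude unoriented prophages from packaging-frame analyses"
        )
    if circular:
        off %= genome_length
        if off > genome_length // 2 + (call.end - call.start):
            off -= genome_length
    return off


def terl_end_offset(
    call: ProphageCall, gene_coords: Mapping[str, tuple[int, int]]
) -> int:
    """Offset of the downstream edge of TerL from the att end, packaging frame."""
    if call.terL_gene is None:
        raise ValueError("prophage has no TerL assignment")
    s, e = _gene_span(call, call.terL_gene, gene_coords)
    if call.orientation == "packaging_rightward":
        return e - call.start
    return call.end - s


def label_defense_vs_prophage(
    system: DefenseSystem,
    call: ProphageCall,
    gene_coords: Mapping[str, tuple[int, int]],
    genome_length: int,
    circular: bool = True,
    window: int = DEFAULT_WINDOW_BP,
) -> RegionLabel:
    """Assign one region label to a defense system in one prophage context.

    The system's midpoint is placed in the prophage's packaging frame:

    * [prophage start, TerL end)          -> ``int_to_terminase``
    * [TerL end, prophage end)            -> ``terminase_to_end``
      (a midpoint exactly at the TerL edge counts as after the terminase)
    * [prophage end, end + window)        -> ``downstream_window``
    * [start - window, start)             -> ``upstream_of_prophage``
    * elsewhere                           -> ``chromosomal_far``

    Prophages lacking a terminase assignment cannot split the internal
    region; their internal systems are labelled ``int_to_terminase``.
    """
    mid = midpoint(system, genome_length)
    length = call.end - call.start
    off = _packaging_frame_offset(mid, call, genome_length, circular)
    if 0 <= off < length:
        if call.terL_gene is None:
            return RegionLabel.int_to_terminase
        t = terl_end_offset(call, gene_coords)
        return RegionLabel.int_to_terminase if off < t else RegionLabel.terminase_to_end
    if length <= off < length + window:
        return RegionLabel.downstream_window
    if -window <= off < 0:
        return RegionLabel.upstream_of_prophage
    return RegionLabel.chromosomal_far


#: report rows of the window-count table, in output order
WINDOW_REGIONS = (
    "25kb-from-int-start",   # chromosomal window on the att/Int side
    "int-to-terminase",
    "terminase-to-end",
    "25kb-past-end",         # chromosomal window on the LT-proximal side
)

_LABEL_TO_REGION = {
    RegionLabel.upstream_of_prophage: "25kb-from-int-start",
    RegionLabel.int_to_terminase: "int-to-terminase",
    RegionLabel.terminase_to_end: "terminase-to-end",
    RegionLabel.downstream_window: "25kb-past-end",
}


def count_defense_windows(
    prophages: Iterable[ProphageCall],
    defenses: Iterable[DefenseSystem],
    gene_coords: Mapping[str, tuple[int, int]],
    genome_lengths: Mapping[str, int],
    circular: bool = True,
    window: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Count defense systems per prophage-relative region, split pac vs other.

    Every oriented prophage contributes one context; each defense system
    in the same genome is labelled once per context and tallied into the
    four reportable regions (far-chromosomal positions are not counted).
    Both raw counts and per-prophage rates are returned, since either
    normalization may be wanted.
    """
    counts = {(r, c): 0 for r in WINDOW_REGIONS for c in ("pac", "other")}
    n_ctx = {"pac": 0, "other": 0}
    by_genome: dict[str, list[DefenseSystem]] = {}
    for d in defenses:
        by_genome.setdefault(d.genome, []).append(d)
    for call in prophages:
        if call.orientation == "unknown":
            continue
        cls = "pac" if call.pac_related else "other"
        n_ctx[cls] += 1
        glen = genome_lengths[call.genome]
        for d in by_genome.get(call.genome, []):
            label = label_defense_vs_prophage(d, call, gene_coords, glen, circular, window)
            region = _LABEL_TO_REGION.get(label)
            if region is not None:
                counts[(region, cls)] += 1
    rows = []
    for region in WINDOW_REGIONS:
        for cls in ("pac", "other"):
            c = counts[(region, cls)]
            rows.append(
                {
                    "region": region,
                    "prophage_class": cls,
                    "n_defense_systems": c,
                    "n_prophages": n_ctx[cls],
                    "per_prophage": c / n_ctx[cls] if n_ctx[cls] else float("nan"),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class LTRegion:
    """A directed run of consecutive capsid headfuls downstream of an origin.

    ``origin`` is the integration/att site or the pac-proximal prophage
    boundary; the region covers ``n_headfuls`` windows of ``headful_size``
    bp in ``direction``. ``boundaries`` are the successive headful marks
    (origin + k * headful_size, directed, wrapped on circular genomes).
    """

    origin: int
    direction: str  # 'rightward' | 'leftward'
    headful_size: int
    n_headfuls: int
    genome_length: int
    circular: bool
    truncated: bool = False

    @property
    def length(self) -> int:
        full = self.n_headfuls * self.headful_size
        if self.circular:
            return full
        if self.direction == "rightward":
            return min(full, self.genome_length - self.origin)
        return min(full, self.origin)

    @property
    def boundaries(self) -> list[int]:
        marks = []
        for k in range(1, self.n_headfuls + 1):
            d = k * self.headful_size
            m = self.origin + d if self.direction == "rightward" else self.origin - d
            if self.circular:
                m %= self.genome_length
            else:
                m = min(max(m, 0), self.genome_length)
            marks.append(m)
        return marks

    def contains(self, pos: int) -> bool:
        if self.direction == "rightward":
            off = pos - self.origin
        else:
            off = self.origin - pos
        if self.circular:
            off %= self.genome_length
        return 0 <= off < self.length

    def span(self) -> tuple[int, int]:
        """Linearized [start, end) (end may exceed genome_length when wrapping)."""
        if self.direction == "rightward":
            return self.origin, self.origin + self.length
        return self.origin - self.length, self.origin


def lt_region(
    att_or_boundary: int,
    direction: str,
    n_headfuls: int,
    genome_length: int,
    headful_size: int = DEFAULT_HEADFUL_BP,
    circular: bool = True,
) -> LTRegion:
    """Build the LT-mobilizable region downstream of an att/pac origin.

    On linear genomes the region is clipped at the contig end and flagged
    truncated. On circular genomes a region at least as long as the
    genome would overlap itself and is rejected.
    """
    if n_headfuls < 1:
        raise ValueError("n_headfuls must be >= 1")
    if direction not in ("rightward", "leftward"):
        raise ValueError(f"bad direction {direction!r}")
    full = n_headfuls * headful_size
    if circular and full >= genome_length:
        raise ValueError(
            f"LT region of {full} bp would self-overlap on a circular genome of "
            f"{genome_length} bp"
        )
    region = LTRegion(
        origin=att_or_boundary,
        direction=direction,
        headful_size=headful_size,
        n_headfuls=n_headfuls,
        genome_length=genome_length,
        circular=circular,
    )
    region.truncated = (not circular) and region.length < full
    return region


def headful_distance_map(
    genome_length: int,
    integration_sites: Sequence[tuple[int, str]],
    headful_size: int = DEFAULT_HEADFUL_BP,
    resolution: int = 1_000,
    circular: bool = True,
) -> pd.DataFrame:
    """Minimum distance, in headful units, from each genome bin to a site.

    ``integration_sites`` are (position, direction) with direction in
    {'rightward', 'leftward', 'both'}: the direction in which packaging
    initiated at the site would reach DNA. The distance of a bin start
    ``p`` from a site ``s`` is ceil(directed_distance / headful_size);
    a bin exactly on a site has distance 0. Returns a table with one row
    per bin (``bin_start``, ``headfuls``).
    """
    if not integration_sites:
        raise ValueError("at least one integration site is required")
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    positions = np.arange(0, genome_length, resolution, dtype=np.int64)
    best = np.full(positions.shape, np.iinfo(np.int64).max, dtype=np.int64)
    for site, direction in integration_sites:
        for d in ("rightward", "leftward"):
            if direction not in (d, "both"):
                continue
            if d == "rightward":
                dist = positions - site
            else:
                dist = site - positions
            if circular:
                dist = np.mod(dist, genome_length)
            else:
                dist = np.where(dist < 0, np.iinfo(np.int64).max, dist)
            head = np.where(
                dist == np.iinfo(np.int64).max,
                np.iinfo(np.int64).max,
                -(-dist // headful_size),  # ceil division
            )
            best = np.minimum(best, head)
    return pd.DataFrame({"bin_start": positions, "headfuls": best})


def headful_fraction_within(distance_map: pd.DataFrame, k_max: int | None = None) -> pd.DataFrame:
    """Fraction of genome bins within k headfuls, k = 1..K."""
    h = distance_map["headfuls"].to_numpy()
    if k_max is None:
        k_max = int(h[h < np.iinfo(np.int64).max].max(initial=1))
    rows = [
        {"k": k, "fraction_within": float(np.mean(h <= k))}
        for k in range(1, k_max + 1)
    ]
    return pd.DataFrame(rows)


def defense_in_prophage_spot_fraction(
    defense_assignments: pd.DataFrame,
    prophage_spot_ids: set[str],
) -> float | None:
    """Percent of defense systems sitting in prophage-bearing spots.

    ``defense_assignments`` is the spot-content assignment table (one row
    per defense call with its ``spot_id``); systems in no spot (midpoint
    on a persistent gene) count in the denominator but not the numerator.
    One-decimal percentage; None when there are no defense systems.
    """
    total = len(defense_assignments)
    if total == 0:
        return None
    hits = int(defense_assignments["spot_id"].isin(prophage_spot_ids).sum())
    return percentage(hits, total)
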