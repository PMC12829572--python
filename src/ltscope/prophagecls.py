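"""Prophage annotation: integrase detection, orientation, terminase pair,
and pac/headful classification.

Temperate phages integrate with their integrase (Int) gene at one end of
the element; the Int end marks the attachment-site side and therefore the
direction in which a headful packager would read into the chromosome.
Prophages whose large terminase (TerL) resembles the TerL of known
pac-type (headful-packaging) phages above a similarity threshold are
classified pac-related — the class mechanistically capable of lateral
transduction.

Evidence arrives as tables, not raw searches:

* HMM hits (``protein, profile_accession, evalue, profile_coverage``) from
  a profile search with tyrosine-recombinase profile PF00589 and the
  serine-recombinase profile pair PF00239 + PF07508;
* terminase hits (``query, ref_role, evalue, query_coverage,
  pct_similarity``) from a protein search against TerS/TerL pairs of
  reference pac-phages, complemented by product-annotation keywords.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import percentage

TYROSINE_PROFILE = "PF00589"
SERINE_PROFILES = ("PF00239", "PF07508")
TERMINASE_KEYWORDS = {
    "TerL": "terminase large subunit",
    "TerS": "terminase small subunit",
}

HMM_COLUMNS = ["protein", "profile_accession", "evalue", "profile_coverage"]
TERMINASE_COLUMNS = ["query", "ref_role", "evalue", "query_coverage", "pct_similarity"]


@dataclass
class IntegraseThresholds:
    evalue_max: float = 1e-3     # strict: evalue < max
    coverage_min: float = 0.5    # inclusive: coverage >= min


@dataclass
class TerminaseThresholds:
    evalue_max: float = 1e-5
    coverage_min: float = 0.5
    gene_window: int = 3         # max positional distance between TerS and TerL


@dataclass
class ProphageCall:
    """One prophage with its derived packaging attributes."""

    genome: str
    start: int
    end: int
    genes: tuple[str, ...]  # ordered by genome coordinate
    int_gene: str | None = None
    int_end: str | None = None  # 'left' | 'right'
    orientation: str = "unknown"  # packaging_rightward | packaging_leftward | unknown
    terS_gene: str | None = None
    terL_gene: str | None = None
    terL_similarity: float | None = None
    pac_related: bool = False
    prophage_id: str | None = None
    distinct_interval: bool | None = None

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def _validate_hits(hits: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    for col in columns:
        if col not in hits.columns:
            raise ValueError(f"{what} table lacks column {col!r}")
    for i, row in hits.iterrows():
        try:
            ev = float(row["evalue"])
        except (TypeError, ValueError):
            raise ValueError(f"{what} row {i}: unparseable evalue {row['evalue']!r}")
        if not math.isfinite(ev) or ev < 0:
            raise ValueError(f"{what} row {i}: invalid evalue {ev}")


def detect_integrase(
    genes: Sequence[str],
    hmm_hits: pd.DataFrame,
    evalue_max: float = 1e-3,
    coverage_min: float = 0.5,
) -> tuple[str, str] | None:
    """Find the integrase gene of a prophage and the end it sits at.

    A gene qualifies through the tyrosine-recombinase profile PF00589
    alone, or through *both* serine-recombinase profiles PF00239 and
    PF07508 passing thresholds on the same protein (either profile alone
    is not enough). Thresholds follow the search conventions: evalue
    strictly below ``evalue_max``, profile coverage at least
    ``coverage_min``. Among qualifying genes the one closest to either
    end of the (coordinate-ordered) gene list wins; ties prefer the left
    end. Returns (gene_id, 'left'|'right') or None.
    """
    _validate_hits(hmm_hits, HMM_COLUMNS, "HMM hit")
    gene_set = set(genes)
    passing: dict[str, set[str]] = {}
    for _, row in hmm_hits.iterrows():
        prot = row["protein"]
        if prot not in gene_set:
            continue
        if float(row["evalue"]) < evalue_max and float(row["profile_coverage"]) >= coverage_min:
            passing.setdefault(prot, set()).add(str(row["profile_accession"]))

    qualifiers = [
        g
        for g in genes
        if g in passing
        and (
            TYROSINE_PROFILE in passing[g]
            or all(p in passing[g] for p in SERINE_PROFILES)
        )
    ]
    if not qualifiers:
        return None
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}

    def end_distance(g: str) -> tuple[int, int]:
        i = index[g]
        return (min(i, n - 1 - i), i)  # tie at equal distance -> leftmost

    best = min(qualifiers, key=end_distance)
    i = index[best]
    end = "left" if i <= n - 1 - i else "right"
    return best, end


def terminal_gene_count(n_genes: int, end_fraction: float = 0.10) -> int:
    """Size of the terminal zone defining "at one end" (min 1 gene)."""
    return max(1, math.ceil(end_fraction * n_genes))


def orient_prophage(call: ProphageCall, end_fraction: float = 0.10) -> str:
    """Derive packaging orientation from the integrase position.

    The Int within the terminal ``end_fraction`` of the gene list at the
    left end implies the element reads (and a headful packager proceeds)
    rightward; at the right end, leftward. An interior Int leaves the
    orientation unknown and the prophage is excluded from oriented
    analyses.
    """
    if call.int_gene is None:
        raise ValueError("orient_prophage requires int_gene to be set")
    i = call.genes.index(call.int_gene)
    zone = terminal_gene_count(call.n_genes, end_fraction)
    if i < zone:
        return "packaging_rightward"
    if i >= call.n_genes - zone:
        return "packaging_leftward"
    return "unknown"


def _terminase_candidates(
    genes: Sequence[str],
    products: Mapping[str, str],
    hits: pd.DataFrame,
    thresholds: TerminaseThresholds,
) -> dict[str, dict[str, float | None]]:
    """Per role, candidate genes with their min passing similarity (None if keyword-only)."""
    _validate_hits(hits, TERMINASE_COLUMNS, "terminase hit")
    gene_set = set(genes)
    cands: dict[str, dict[str, float | None]] = {"TerS": {}, "TerL": {}}
    for role, keyword in TERMINASE_KEYWORDS.items():
        for g in genes:
            if keyword in str(products.get(g, "")).lower():
                cands[role][g] = None
    for _, row in hits.iterrows():
        g, role = row["query"], str(row["ref_role"])
        if g not in gene_set or role not in cands:
            continue
        if (
            float(row["evalue"]) < thresholds.evalue_max
            and float(row["query_coverage"]) >= thresholds.coverage_min
        ):
            sim = float(row["pct_similarity"])
            prev = cands[role].get(g)
            # keep the LOWEST similarity among passing reference hits:
            # the conservative, defining value for pac classification
            cands[role][g] = sim if prev is None else min(prev, sim)
    return cands


def find_terminase_pair(
    genes: Sequence[str],
    products: Mapping[str, str],
    terminase_hits: pd.DataFrame,
    thresholds: TerminaseThresholds | None = None,
) -> tuple[str, str, float | None] | None:
    """Locate an adjacent TerS/TerL pair in a prophage.

    Candidates come from case-insensitive product keywords ("terminase
    small/large subunit") or from reference-terminase homology hits
    passing thresholds. A pair is accepted when the TerS and TerL genes
    are at most ``gene_window`` positions apart (they are typically
    adjacent). Among qualifying pairs the smallest positional gap wins,
    then the highest TerL similarity. Returns
    (terS_gene, terL_gene, terL_similarity) or None.
    """
    thresholds = thresholds or TerminaseThresholds()
    cands = _terminase_candidates(genes, products, terminase_hits, thresholds)
    if not cands["TerS"] or not cands["TerL"]:
        return None
    index = {g: i for i, g in enumerate(genes)}
    pairs = []
    for s, _ in cands["TerS"].items():
        for l, sim in cands["TerL"].items():
            if s == l:
                continue
            gap = abs(index[s] - index[l])
            if gap <= thresholds.gene_window:
                pairs.append((gap, -(sim if sim is not None else -math.inf), s, l, sim))
    if not pairs:
        return None
    pairs.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    _, _, s, l, sim = pairs[0]
    return s, l, sim


def classify_pac(call: ProphageCall, pac_similarity_threshold: float = 60.0) -> bool:
    """Pac-related iff the TerL similarity strictly exceeds the threshold.

    The defining criterion is the lowest similarity observed among the
    prophage's passing TerL reference hits (already folded into
    ``terL_similarity``); exactly 60% is *not* pac-related.
    """
    if call.terL_gene is None or call.terL_similarity is None:
        return False
    return call.terL_similarity > pac_similarity_threshold


def annotate_prophage(
    genome: str,
    span: tuple[int, int],
    genes: Sequence[str],
    products: Mapping[str, str],
    hmm_hits: pd.DataFrame,
    terminase_hits: pd.DataFrame,
    integrase_thresholds: IntegraseThresholds | None = None,
    terminase_thresholds: TerminaseThresholds | None = None,
    pac_similarity_threshold: float = 60.0,
    end_fraction: float = 0.10,
    prophage_id: str | None = None,
) -> ProphageCall:
    """Run the full per-prophage classification chain on one call."""
    it = integrase_thresholds or IntegraseThresholds()
    call = ProphageCall(
        genome=genome, start=span[0], end=span[1], genes=tuple(genes), prophage_id=prophage_id
    )
    hit = detect_integrase(call.genes, hmm_hits, it.evalue_max, it.coverage_min)
    if hit is not None:
        call.int_gene, call.int_end = hit
        call.orientation = orient_prophage(call, end_fraction)
    pair = find_terminase_pair(call.genes, products, terminase_hits, terminase_thresholds)
    if pair is not None:
        call.terS_gene, call.terL_gene, call.terL_similarity = pair
    call.pac_related = classify_pac(call, pac_similarity_threshold)
    return call


def summarize_prophage_cohort(calls: Iterable[ProphageCall]) -> dict:
    """Cohort counts: total, with Int, with terminase pair, pac-related.

    Percentages are one-decimal, half-away-from-zero, computed on the
    convention that terminase carriage is reported among Int-bearing
    prophages. Zero denominators yield None, never 0.
    """
    calls = list(calls)
    with_int = [c for c in calls if c.int_gene is not None]
    with_ter = [c for c in with_int if c.terS_gene is not None and c.terL_gene is not None]
    pac = [c for c in calls if c.pac_related]
    return {
        "total": len(calls),
        "with_int": len(with_int),
        "with_terminases": len(with_ter),
        "pac_related": len(pac),
        "pct_with_terminases": percentage(len(with_ter), len(with_int)),
    }


def calls_to_frame(calls: Iterable[ProphageCall]) -> pd.DataFrame:
    rows = [
        {
            "prophage_id": c.prophage_id,
            "genome": c.genome,
            "start": c.start,
            "end": c.end,
            "n_genes": c.n_genes,
            "int_gene": c.int_gene,
            "int_end": c.int_end,
            "orientation": c.orientation,
            "terS_gene": c.terS_gene,
            "terL_gene": c.terL_gene,
            "terL_similarity": c.terL_similarity,
            "pac_related": c.pac_related,
            "distinct_interval": c.distinct_interval,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "prophage_id", "genome", "start", "end", "n_genes", "int_gene", "int_end",
            "orientation", "terS_gene", "terL_gene", "terL_similarity",
            "pac_related", "distinct_interval",
        ],
    )
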