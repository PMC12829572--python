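"""Gene-family clustering and persistent-family calling.

Proteins are clustered into pangenome families by single-linkage at a
percent-identity threshold: two proteins share a family iff they are
connected by a path of pairwise alignments, each meeting the identity
threshold and a coverage floor on both partners. A family is *persistent*
when at least a configurable fraction of genomes (default 90%) carry
exactly one member — the conserved single-copy backbone that delimits
accessory intervals. Genomes carrying two or more members do not count
toward persistence.

Identity edges arrive as a table (``prot_a``, ``prot_b``, ``pct_identity``,
``coverage_a``, ``coverage_b``) produced by any pairwise aligner; this
module only applies the clustering rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

EDGE_COLUMNS = ["prot_a", "prot_b", "pct_identity", "coverage_a", "coverage_b"]


@dataclass
class PersistenceParams:
    """Thresholds for family clustering and persistence calling.

    identity_threshold : percent identity floor for single linkage
        (inclusive: an edge at exactly the threshold links).
    persistence_fraction : fraction of genomes that must carry exactly one
        member for a family to be persistent.
    coverage_floor : minimum aligned fraction required of *both* proteins
        on an edge (inclusive).
    """

    identity_threshold: float = 80.0
    persistence_fraction: float = 0.90
    coverage_floor: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_threshold <= 100.0:
            raise ValueError(f"identity_threshold out of [0,100]: {self.identity_threshold}")
        if not 0.0 <= self.persistence_fraction <= 1.0:
            raise ValueError(f"persistence_fraction out of [0,1]: {self.persistence_fraction}")
        if not 0.0 <= self.coverage_floor <= 1.0:
            raise ValueError(f"coverage_floor out of [0,1]: {self.coverage_floor}")


@dataclass
class GeneFamily:
    family_id: str
    members: dict[str, str] = field(default_factory=dict)  # protein id -> genome id
    persistent: bool = False

    def __len__(self) -> int:
        return len(self.members)

    def genomes_exactly_one(self) -> int:
        """Number of genomes carrying exactly one member of this family."""
        counts: dict[str, int] = {}
        for genome in self.members.values():
            counts[genome] = counts.get(genome, 0) + 1
        return sum(1 for c in counts.values() if c == 1)


def cluster_families(
    edges: pd.DataFrame,
    proteins: Mapping[str, str],
    params: PersistenceParams | None = None,
) -> list[GeneFamily]:
    """Single-linkage clustering of proteins into gene families.

    Parameters
    ----------
    edges : DataFrame with columns ``prot_a, prot_b, pct_identity,
        coverage_a, coverage_b``. Undirected; duplicates are harmless.
    proteins : mapping of protein id -> genome id covering the whole
        protein universe. Proteins without qualifying edges become
        singleton families.
    params : thresholds; defaults to 80% identity, 0.8 coverage.

    Returns
    -------
    Families sorted by smallest member id, with deterministic ids
    ``FAM00000, FAM00001, ...``. Every protein appears in exactly one
    family (partition property).
    """
    params = params or PersistenceParams()
    missing = sorted(
        set(edges["prot_a"]).union(edges["prot_b"]) - set(proteins)
    )
    if missing:
        shown = ", ".join(missing[:10])
        raise ValueError(
            f"{len(missing)} edge endpoint(s) not in the protein set: {shown}"
        )

    keep = (
        (edges["pct_identity"] >= params.identity_threshold)
        & (edges["coverage_a"] >= params.coverage_floor)
        & (edges["coverage_b"] >= params.coverage_floor)
    )
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(proteins)
    graph.add_edges_from(edges.loc[keep, ["prot_a", "prot_b"]].itertuples(index=False))

    components = sorted(nx.connected_components(graph), key=min)
    families = []
    for i, comp in enumerate(components):
        members = {p: proteins[p] for p in sorted(comp)}
        families.append(GeneFamily(family_id=f"FAM{i:05d}", members=members))
    return families


def persistence_min_genomes(n_genomes: int, fraction: float) -> int:
    """ceil(fraction * n_genomes), guarded against float noise."""
    return int(math.ceil(fraction * n_genomes - 1e-9))


def call_persistent(
    families: Iterable[GeneFamily],
    genome_ids: Iterable[str],
    params: PersistenceParams | None = None,
) -> set[str]:
    """Flag persistent families; returns the set of persistent family ids.

    A family is persistent iff the number of genomes containing exactly one
    member is >= ceil(persistence_fraction * n_genomes). Genomes with two
    or more members are excluded from the count (a "single, unique
    representative" reading), so widespread duplication blocks persistence.
    """
    params = params or PersistenceParams()
    genome_ids = set(genome_ids)
    if not genome_ids:
        raise ValueError("empty genome set: persistence is undefined")
    need = persistence_min_genomes(len(genome_ids), params.persistence_fraction)
    persistent: set[str] = set()
    for fam in families:
        fam.persistent = fam.genomes_exactly_one() >= need
        if fam.persistent:
            persistent.add(fam.family_id)
    return persistent


def families_to_frame(families: Iterable[GeneFamily]) -> pd.DataFrame:
    """Long-format membership table (family_id, protein_id, genome_id, persistent)."""
    rows = [
        (fam.family_id, prot, genome, fam.persistent)
        for fam in families
        for prot, genome in fam.members.items()
    ]
    return pd.DataFrame(rows, columns=["family_id", "protein_id", "genome_id", "persistent"])
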