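"""Synthetic genome collections with known ground truth.

Emulates the statistical structure of a collection of related bacterial
genomes: a shared persistent-gene backbone present single-copy in most
genomes, accessory intervals between backbone genes, planted prophages
with an integrase at one end and an adjacent TerS/TerL terminase pair of
controlled similarity to reference pac-phage terminases, and planted
multi-gene defense systems both inside prophages (before or after the
terminase genes) and in chromosomal spots.

The generator writes exactly the table formats the pipeline ingests
(gene tables, identity edges, HMM hits, terminase hits, prophage and
defense calls) plus per-genome FASTA/GFF3, and returns a
:class:`GroundTruth` object recording where everything was planted.
Identical seeds give byte-identical output.

Layout conventions: genes are placed on a fixed 1 kb pitch (900 bp gene,
100 bp spacer), genomes are single-contig and circular by default, and
coordinates are 0-based half-open internally (GFF3 is written 1-based
inclusive). Protein "identity" is matches over columns of the implied
gapless alignment of equal-length family variants, so planted identity
is exact by construction. No nucleotide-level evolution is simulated:
the genome sequence is random and independent of the gene content.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

GENE_PITCH = 1_000   # bp per gene slot
GENE_OFFSET = 50     # gene starts this far into its slot
GENE_LEN = 900       # gene length in bp

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

DEFENSE_NAME_PALETTE = (
    "RM_typeI", "CBASS", "retron", "gabija", "thoeris", "abi", "druantia", "wadjet",
)

#: profile accessions used in emitted HMM hit tables
TYROSINE_PROFILE = "PF00589"
SERINE_PROFILES = ("PF00239", "PF07508")


class InfeasibleSpecError(ValueError):
    """The requested synthetic layout cannot be realized; names the constraint."""


@dataclass
class ProphagePlan:
    """Blueprint for one planted prophage.

    length : element size in bp; the gene count is length // 1 kb pitch.
    int_end : which end carries the integrase ('left'|'right'); the
        opposite end is the LT-proximal side.
    terL_similarity_to_reference : percent similarity the emitted TerL
        blast hit reports against the reference pac-phage terminases
        (> 60 makes the prophage pac-related by the pipeline's rule).
    terS_terL_gene_gap : positional distance between TerS and TerL in
        the gene list (1 = adjacent with no gene between).
    planted_defense_positions : internal defense systems, each either
        'pre_terminase' (between Int and TerS) or 'post_terminase'
        (between TerL and the far end).
    """

    length: int = 40_000
    int_end: str = "left"
    integrase_type: str = "tyrosine"  # 'tyrosine' | 'serine' | 'none'
    has_terminase_pair: bool = True
    terL_similarity_to_reference: float = 85.0
    terS_terL_gene_gap: int = 1
    planted_defense_positions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.int_end not in ("left", "right"):
            raise ValueError(f"int_end must be left/right, got {self.int_end!r}")
        if not 0 <= self.terL_similarity_to_reference <= 100:
            raise ValueError("terL_similarity_to_reference out of [0,100]")
        if self.terS_terL_gene_gap < 0:
            raise ValueError("terS_terL_gene_gap must be >= 0")
        if self.planted_defense_positions and not self.has_terminase_pair:
            raise InfeasibleSpecError(
                "internal defense positions are defined relative to the terminase pair; "
                "set has_terminase_pair=True"
            )
        for p in self.planted_defense_positions:
            if p not in ("pre_terminase", "post_terminase"):
                raise ValueError(f"bad defense position {p!r}")

    @property
    def n_genes(self) -> int:
        return max(6, self.length // GENE_PITCH)


@dataclass
class DefensePlan:
    """Blueprint for one chromosomal (spot-resident) defense system."""

    system_name: str = "retron"
    n_genes: int = 2

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("defense systems need >= 1 gene")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic genome collection.

    ``persistence_rate`` is the per-genome presence probability of each
    backbone gene (families flanking planted spots are always present so
    planted content sits between well-defined flanks).
    ``backbone_identity`` is the fractional identity of each family
    member to its family reference sequence; pairwise member identity is
    correspondingly lower but stays far above the 80% clustering
    threshold at the default.
    """

    n_genomes: int = 20
    n_persistent: int = 50
    persistence_rate: float = 0.95
    backbone_identity: float = 0.95
    n_spots_with_prophage: int = 0
    n_spots_with_defense: int = 0
    n_spots_with_both: int = 0
    prophage_specs: list[ProphagePlan] = field(default_factory=list)
    defense_specs: list[DefensePlan] = field(default_factory=list)
    n_filler_per_genome: int = 0
    circular: bool = True
    rng_seed: int = 0
    backbone_protein_length: int = 250
    cargo_protein_length: int = 200
    write_fasta: bool = True
    #: fraction used when recording which families are persistent in the
    #: ground truth; matches the pipeline's default persistence call.
    persistence_call_fraction: float = 0.90
    #: pairing window assumed when recording pac-relatedness in the truth
    terminase_pair_window: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistence_rate <= 1.0:
            raise ValueError("persistence_rate out of [0,1]")
        if not 0.0 <= self.backbone_identity <= 1.0:
            raise ValueError("backbone_identity out of [0,1]")
        if self.n_spots_with_both > min(self.n_spots_with_prophage, self.n_spots_with_defense):
            raise ValueError(
                "n_spots_with_both cannot exceed min(n_spots_with_prophage, "
                "n_spots_with_defense)"
            )
        n_gaps = self.n_persistent if self.circular else self.n_persistent - 1
        planted = (
            self.n_spots_with_prophage + self.n_spots_with_defense - self.n_spots_with_both
        )
        if planted > n_gaps:
            raise InfeasibleSpecError(
                f"{planted} planted spots exceed the {n_gaps} backbone gaps available"
            )
        if self.n_spots_with_prophage > 0 and not self.prophage_specs:
            raise InfeasibleSpecError("prophage spots requested but no prophage plans given")
        if len(self.prophage_specs) < self.n_spots_with_prophage:
            raise InfeasibleSpecError(
                f"{self.n_spots_with_prophage} prophage spots need at least that many "
                f"prophage plans (got {len(self.prophage_specs)})"
            )

    @classmethod
    def default_scenario(cls, rng_seed: int = 0) -> "SyntheticSpec":
        """The standard study-scale scenario used throughout the tests.

        20 genomes of roughly 200 genes over a 50-family backbone
        (presence rate 0.95), 12 planted prophages — six pac-like
        (TerL similarity 85%) each carrying one defense system before
        and one after the terminase pair, six non-pac (similarity 40%) —
        and 18 chromosomal defense systems, for 30 systems in total
        across 8 prophage spots, 7 defense spots, 4 shared.
        """
        pac_positions = ("pre_terminase", "post_terminase")
        prophages = []
        for i in range(6):
            prophages.append(
                ProphagePlan(
                    length=40_000,
                    int_end="left" if i % 2 == 0 else "right",
                    integrase_type="serine" if i == 5 else "tyrosine",
                    terL_similarity_to_reference=85.0,
                    terS_terL_gene_gap=(1, 1, 2, 1, 3, 1)[i],
                    planted_defense_positions=pac_positions,
                )
            )
        for i in range(6):
            prophages.append(
                ProphagePlan(
                    length=35_000,
                    int_end="left" if i % 2 == 1 else "right",
                    integrase_type="serine" if i == 4 else "tyrosine",
                    terL_similarity_to_reference=40.0,
                    terS_terL_gene_gap=1,
                )
            )
        defenses = [
            DefensePlan(
                system_name=DEFENSE_NAME_PALETTE[i % len(DEFENSE_NAME_PALETTE)],
                n_genes=1 + i % 3,
            )
            for i in range(18)
        ]
        return cls(
            n_genomes=20,
            n_persistent=50,
            persistence_rate=0.95,
            backbone_identity=0.95,
            n_spots_with_prophage=8,
            n_spots_with_defense=7,
            n_spots_with_both=4,
            prophage_specs=prophages,
            defense_specs=defenses,
            n_filler_per_genome=120,
            rng_seed=rng_seed,
        )


def mutate_family(protein: str, target_identity: float, seed: int) -> str:
    """Return a same-length variant at a controlled ungapped identity.

    Exactly ``round(L * (1 - target/100))`` positions are substituted
    with a different residue, so the realized position-wise identity
    equals the target up to the rounding granularity of 1/L (well within
    +/- 2 percentage points for proteins of ordinary length).
    """
    if not protein:
        raise ValueError("cannot mutate an empty sequence")
    if not 0.0 <= target_identity <= 100.0:
        raise ValueError(f"target_identity out of [0,100]: {target_identity}")
    rng = np.random.default_rng(seed)
    length = len(protein)
    n_sub = int(round(length * (1.0 - target_identity / 100.0)))
    if n_sub == 0:
        return protein
    positions = rng.choice(length, size=n_sub, replace=False)
    seq = list(protein)
    for pos in positions:
        alternatives = [a for a in AA_ALPHABET if a != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(seq)


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity over the columns of a gapless equal-length alignment."""
    if len(a) != len(b):
        raise ValueError("identity is defined for equal-length sequences only")
    if not a:
        raise ValueError("empty sequences")
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), size=length))


# ---------------------------------------------------------------------------
# internal plan records

@dataclass
class _GeneDraft:
    role: str            # backbone|integrase|terS|terL|cargo|defense|filler
    product: str
    family: str | None = None     # backbone family id, else None
    system_id: str | None = None  # for defense genes
    strand: str = "+"
    gene_id: str = ""
    start: int = -1
    end: int = -1


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification.

    ``family_members`` maps every emitted protein to its true family
    (backbone family id, or the protein's own id for singletons).
    ``spots`` lists the expected flank pairs over the whole collection
    with their content flags; ``spot_counts`` aggregates them.
    """

    spec: dict
    genome_lengths: dict[str, int]
    genes: pd.DataFrame
    family_members: dict[str, str]
    persistent_families: list[str]
    spots: pd.DataFrame          # flank_a, flank_b, has_prophage, has_defense
    spot_counts: dict[str, int]
    prophages: pd.DataFrame
    defenses: pd.DataFrame

    @staticmethod
    def _pack(df: pd.DataFrame) -> dict:
        return {"columns": list(df.columns), "data": df.to_numpy().tolist()}

    @staticmethod
    def _unpack(raw: dict) -> pd.DataFrame:
        return pd.DataFrame(raw["data"], columns=raw["columns"])

    def to_json(self, path: Path) -> None:
        payload = {
            "spec": self.spec,
            "genome_lengths": self.genome_lengths,
            "genes": self._pack(self.genes),
            "family_members": self.family_members,
            "persistent_families": self.persistent_families,
            "spots": self._pack(self.spots),
            "spot_counts": self.spot_counts,
            "prophages": self._pack(self.prophages),
            "defenses": self._pack(self.defenses),
        }
        path.write_text(json.dumps(payload, sort_keys=True, indent=1, default=str))

    @classmethod
    def from_json(cls, path: Path) -> "GroundTruth":
        raw = json.loads(path.read_text())
        return cls(
            spec=raw["spec"],
            genome_lengths=raw["genome_lengths"],
            genes=cls._unpack(raw["genes"]),
            family_members=raw["family_members"],
            persistent_families=raw["persistent_families"],
            spots=cls._unpack(raw["spots"]),
            spot_counts=raw["spot_counts"],
            prophages=cls._unpack(raw["prophages"]),
            defenses=cls._unpack(raw["defenses"]),
        )


@dataclass
class CollectionPaths:
    """File layout of one emitted collection."""

    root: Path

    @property
    def genes(self) -> Path:
        return self.root / "genes.tsv"

    @property
    def contigs(self) -> Path:
        return self.root / "contigs.tsv"

    @property
    def identity_edges(self) -> Path:
        return self.root / "identity_edges.tsv"

    @property
    def hmm_hits(self) -> Path:
        return self.root / "hmm_hits.tsv"

    @property
    def terminase_hits(self) -> Path:
        return self.root / "terminase_hits.tsv"

    @property
    def prophage_calls(self) -> Path:
        return self.root / "prophage_calls.tsv"

    @property
    def defense_calls(self) -> Path:
        return self.root / "defense_calls.tsv"

    @property
    def ground_truth(self) -> Path:
        return self.root / "ground_truth.json"

    def genome_fasta(self, genome: str) -> Path:
        return self.root / "genomes" / f"{genome}.fna"

    def genome_gff(self, genome: str) -> Path:
        return self.root / "genomes" / f"{genome}.gff"


def _build_prophage_draft(
    plan: ProphagePlan, prophage_id: str, defense_counter: Iterable[int]
) -> tuple[list[_GeneDraft], list[dict]]:
    """Role list for one prophage in genome (left-to-right) order.

    Returns the drafts and the internal defense descriptors
    (system_id, position, genes as indices into the draft list).
    """
    pre = [p for p in plan.planted_defense_positions if p == "pre_terminase"]
    post = [p for p in plan.planted_defense_positions if p == "post_terminase"]
    counter = iter(defense_counter)

    def defense_block(position: str, k: int) -> tuple[list[_GeneDraft], dict]:
        idx = next(counter)
        sid = f"{prophage_id}_DF{idx:02d}"
        name = DEFENSE_NAME_PALETTE[idx % len(DEFENSE_NAME_PALETTE)]
        drafts = [
            _GeneDraft(role="defense", product=f"{name} defense protein {j}", system_id=sid)
            for j in range(2)
        ]
        return drafts, {"system_id": sid, "system_name": name, "position": position}

    drafts: list[_GeneDraft] = []
    internal: list[dict] = []
    int_product = {
        "tyrosine": "site-specific tyrosine integrase",
        "serine": "serine recombinase",
        "none": "hypothetical protein",
    }[plan.integrase_type]
    drafts.append(_GeneDraft(role="integrase" if plan.integrase_type != "none" else "cargo",
                             product=int_product))

    cargo = lambda: _GeneDraft(role="cargo", product="hypothetical protein")

    pre_drafts: list[_GeneDraft] = []
    for p in pre:
        block, desc = defense_block(p, 2)
        pre_drafts.extend(block)
        internal.append(desc | {"drafts": block})
    post_drafts: list[_GeneDraft] = []
    for p in post:
        block, desc = defense_block(p, 2)
        post_drafts.extend(block)
        internal.append(desc | {"drafts": block})

    ter_drafts: list[_GeneDraft] = []
    if plan.has_terminase_pair:
        ter_drafts.append(_GeneDraft(role="terS", product="phage terminase small subunit"))
        ter_drafts.extend(cargo() for _ in range(plan.terS_terL_gene_gap - 1))
        ter_drafts.append(_GeneDraft(role="terL", product="phage terminase large subunit"))

    base = 1 + len(pre_drafts) + len(ter_drafts) + len(post_drafts)
    pad = plan.n_genes - base
    if pad < 0:
        raise InfeasibleSpecError(
            f"prophage plan of {plan.n_genes} genes cannot host {base} planted genes; "
            "increase length"
        )
    a1 = pad // 4
    a2 = pad // 4
    a3 = pad // 4
    a4 = pad - a1 - a2 - a3
    drafts.extend(cargo() for _ in range(a1))
    drafts.extend(pre_drafts)
    drafts.extend(cargo() for _ in range(a2))
    drafts.extend(ter_drafts)
    drafts.extend(cargo() for _ in range(a3))
    drafts.extend(post_drafts)
    drafts.extend(cargo() for _ in range(a4))

    if plan.int_end == "right":
        drafts.reverse()
    strand = "+" if plan.int_end == "left" else "-"
    for d in drafts:
        d.strand = strand
    return drafts, internal


def _assign_round_robin(items: list, slots: list) -> dict:
    """items -> slots cyclically; every slot gets at least one item if possible."""
    assignment: dict[int, list] = {i: [] for i in range(len(slots))}
    for k, item in enumerate(items):
        assignment[k % len(slots)].append(item)
    return assignment


def generate_collection(spec: SyntheticSpec, outdir: Path | str) -> tuple[CollectionPaths, GroundTruth]:
    """Generate and write a synthetic collection; see the module docstring.

    All randomness flows from ``spec.rng_seed``; identical specs give
    byte-identical files.
    """
    outdir = Path(outdir)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    paths = CollectionPaths(root=outdir)
    rng = np.random.default_rng(spec.rng_seed)

    genomes = [f"G{m:03d}" for m in range(spec.n_genomes)]
    bb_fams = [f"BB{i:03d}" for i in range(spec.n_persistent)]
    bb_refs = {f: _random_protein(rng, spec.backbone_protein_length) for f in bb_fams}

    n_gaps = spec.n_persistent if spec.circular else spec.n_persistent - 1
    n_pro, n_def, n_both = (
        spec.n_spots_with_prophage, spec.n_spots_with_defense, spec.n_spots_with_both,
    )
    planted_total = n_pro + n_def - n_both
    planted_gaps = (
        sorted(int(g) for g in rng.choice(n_gaps, size=planted_total, replace=False))
        if planted_total
        else []
    )
    both_gaps = planted_gaps[:n_both]
    pro_only_gaps = planted_gaps[n_both : n_both + (n_pro - n_both)]
    def_only_gaps = planted_gaps[n_both + (n_pro - n_both) :]
    prophage_gaps = both_gaps + pro_only_gaps
    defense_gaps = both_gaps + def_only_gaps

    # --- assign prophage plans to (gap, genome) -------------------------------
    plans_with_def = [p for p in spec.prophage_specs if p.planted_defense_positions]
    plans_plain = [p for p in spec.prophage_specs if not p.planted_defense_positions]
    if plans_with_def and not both_gaps:
        raise InfeasibleSpecError(
            "prophage plans carry internal defense systems but n_spots_with_both is 0"
        )
    gap_of_plan: list[tuple[ProphagePlan, int]] = []
    if plans_with_def:
        for k, p in enumerate(plans_with_def):
            gap_of_plan.append((p, both_gaps[k % len(both_gaps)]))
    covered = {g for _, g in gap_of_plan}
    needy = [g for g in prophage_gaps if g not in covered]
    targets = needy + [g for g in prophage_gaps if g in covered]
    for k, p in enumerate(plans_plain):
        if not targets:
            raise InfeasibleSpecError("prophage plans given but no prophage spots requested")
        gap_of_plan.append((p, targets[k % len(targets)]))
    got = {g for _, g in gap_of_plan}
    missing = [g for g in prophage_gaps if g not in got]
    if missing:
        raise InfeasibleSpecError(
            f"{len(missing)} prophage spot(s) would receive no prophage; "
            "provide at least one plan per prophage spot"
        )

    used_slots: set[tuple[int, int]] = set()
    prophage_placements = []  # (plan, gap, genome_index, prophage_id)
    for k, (plan, gap) in enumerate(gap_of_plan):
        m = k % spec.n_genomes
        while (gap, m) in used_slots:
            m = (m + 1) % spec.n_genomes
        used_slots.add((gap, m))
        prophage_placements.append((plan, gap, m, f"PP{k:03d}"))

    # --- assign chromosomal defense plans -------------------------------------
    both_with_internal = {
        gap for (plan, gap, _, _) in prophage_placements if plan.planted_defense_positions
    }
    needy_def = [g for g in defense_gaps if g not in both_with_internal]
    chrom_defense_placements = []  # (plan, gap, genome_index, system_id)
    if spec.defense_specs and not defense_gaps:
        raise InfeasibleSpecError("defense plans given but no defense spots requested")
    for k, plan in enumerate(spec.defense_specs):
        if k < len(needy_def):
            gap = needy_def[k]
        elif defense_gaps:
            gap = defense_gaps[k % len(defense_gaps)]
        else:
            break
        m = k % spec.n_genomes
        chrom_defense_placements.append((plan, gap, m, f"CD{k:03d}"))
    still_needy = set(needy_def) - {g for _, g, _, _ in chrom_defense_placements}
    if still_needy:
        raise InfeasibleSpecError(
            f"{len(still_needy)} defense spot(s) would receive no defense system; "
            "provide more defense plans"
        )

    # --- backbone presence matrix ----------------------------------------------
    forced = set()
    for gap in planted_gaps:
        forced.add(gap)
        forced.add((gap + 1) % spec.n_persistent if spec.circular else gap + 1)
    presence = rng.random((spec.n_genomes, spec.n_persistent)) < spec.persistence_rate
    for i in forced:
        presence[:, i] = True

    # --- filler assignment ------------------------------------------------------
    filler_gap = {
        m: rng.integers(0, n_gaps, size=spec.n_filler_per_genome)
        for m in range(spec.n_genomes)
    }

    # --- build per-genome drafts -----------------------------------------------
    gene_rows = []
    family_members: dict[str, str] = {}
    genome_lengths: dict[str, int] = {}
    prophage_records: list[dict] = []
    defense_records: list[dict] = []
    edge_rows: list[tuple] = []
    hmm_rows: list[tuple] = []
    ter_rows: list[tuple] = []
    pcall_rows: list[tuple] = []

    bb_member_seqs: dict[str, list[tuple[str, str]]] = {f: [] for f in bb_fams}

    # pre-build prophage drafts (deterministic order)
    pro_by_slot: dict[tuple[int, int], list] = {}
    internal_def_counter = iter(range(10_000))
    for plan, gap, m, pid in prophage_placements:
        drafts, internal = _build_prophage_draft(plan, pid, internal_def_counter)
        pro_by_slot.setdefault((m, gap), []).append((plan, pid, drafts, internal))

    chrom_by_slot: dict[tuple[int, int], list] = {}
    for plan, gap, m, sid in chrom_defense_placements:
        drafts = [
            _GeneDraft(
                role="defense",
                product=f"{plan.system_name} defense protein {j}",
                system_id=sid,
            )
            for j in range(plan.n_genes)
        ]
        chrom_by_slot.setdefault((m, gap), []).append((plan, sid, drafts))

    for m, genome in enumerate(genomes):
        units_by_gap: dict[int, list[list[_GeneDraft]]] = {g: [] for g in range(n_gaps)}
        unit_meta: dict[int, list] = {g: [] for g in range(n_gaps)}
        for (mm, gap), entries in sorted(pro_by_slot.items()):
            if mm != m:
                continue
            for plan, pid, drafts, internal in entries:
                units_by_gap[gap].append(drafts)
                unit_meta[gap].append(("prophage", plan, pid, internal))
        for (mm, gap), entries in sorted(chrom_by_slot.items()):
            if mm != m:
                continue
            for plan, sid, drafts in entries:
                units_by_gap[gap].append(drafts)
                unit_meta[gap].append(("defense", plan, sid, None))
        for gap in filler_gap[m]:
            d = [_GeneDraft(role="filler", product="hypothetical protein",
                            strand="+" if rng.random() < 0.5 else "-")]
            units_by_gap[int(gap)].append(d)
            unit_meta[int(gap)].append(("filler", None, None, None))

        # uniform-random unit order within each gap
        for gap in range(n_gaps):
            k = len(units_by_gap[gap])
            if k > 1:
                perm = rng.permutation(k)
                units_by_gap[gap] = [units_by_gap[gap][i] for i in perm]
                unit_meta[gap] = [unit_meta[gap][i] for i in perm]

        drafts_in_order: list[_GeneDraft] = []
        unit_slices: list[tuple[str, object, object, object, int, int]] = []
        for i in range(spec.n_persistent):
            if presence[m, i]:
                drafts_in_order.append(
                    _GeneDraft(
                        role="backbone",
                        product=f"conserved backbone protein {bb_fams[i]}",
                        family=bb_fams[i],
                    )
                )
            if i < n_gaps:
                for unit, meta in zip(units_by_gap[i], unit_meta[i]):
                    lo = len(drafts_in_order)
                    drafts_in_order.extend(unit)
                    unit_slices.append((*meta, lo, len(drafts_in_order)))

        # coordinates & ids
        glen = len(drafts_in_order) * GENE_PITCH
        genome_lengths[genome] = glen
        for idx, d in enumerate(drafts_in_order):
            d.gene_id = f"{genome}_g{idx:05d}"
            d.start = idx * GENE_PITCH + GENE_OFFSET
            d.end = d.start + GENE_LEN
            fam = d.family if d.family else d.gene_id
            family_members[d.gene_id] = fam
            gene_rows.append(
                (genome, genome, d.gene_id, d.start, d.end, d.strand, d.product, d.role, fam)
            )
            if d.role == "backbone":
                seed = int(rng.integers(0, 2**31 - 1))
                seq = mutate_family(bb_refs[d.family], spec.backbone_identity * 100.0, seed)
                bb_member_seqs[d.family].append((d.gene_id, seq))

        # per-unit bookkeeping now that coordinates exist
        for kind, plan, ident, internal, lo, hi in unit_slices:
            unit = drafts_in_order[lo:hi]
            if kind == "prophage":
                span_start = unit[0].start - GENE_OFFSET
                span_end = unit[-1].end + (GENE_PITCH - GENE_OFFSET - GENE_LEN)
                pcall_rows.append((genome, ident, span_start, span_end))
                by_role = {d.role: d for d in unit}
                int_gene = by_role.get("integrase")
                terS, terL = by_role.get("terS"), by_role.get("terL")
                orientation = (
                    "unknown"
                    if plan.integrase_type == "none"
                    else ("packaging_rightward" if plan.int_end == "left" else "packaging_leftward")
                )
                sim = plan.terL_similarity_to_reference if terL is not None else None
                pair_gap = abs(unit.index(terS) - unit.index(terL)) if terS and terL else None
                pairable = pair_gap is not None and pair_gap <= spec.terminase_pair_window
                prophage_records.append(
                    {
                        "prophage_id": ident,
                        "genome": genome,
                        "start": span_start,
                        "end": span_end,
                        "n_genes": len(unit),
                        "int_gene": int_gene.gene_id if int_gene else None,
                        "int_end": plan.int_end if int_gene else None,
                        "orientation": orientation,
                        "terS_gene": terS.gene_id if terS and pairable else None,
                        "terL_gene": terL.gene_id if terL and pairable else None,
                        "terL_similarity": sim if pairable else None,
                        "pac_related": bool(pairable and sim is not None and sim > 60.0),
                        "terS_terL_gap": pair_gap,
                    }
                )
                # evidence rows
                if int_gene is not None:
                    if plan.integrase_type == "tyrosine":
                        hmm_rows.append((int_gene.gene_id, TYROSINE_PROFILE, 1e-10, 0.90))
                    else:
                        hmm_rows.append((int_gene.gene_id, SERINE_PROFILES[0], 1e-8, 0.80))
                        hmm_rows.append((int_gene.gene_id, SERINE_PROFILES[1], 1e-8, 0.80))
                cargo_genes = [d for d in unit if d.role == "cargo"]
                if cargo_genes:  # sub-threshold decoys
                    hmm_rows.append((cargo_genes[0].gene_id, TYROSINE_PROFILE, 5e-2, 0.90))
                if len(cargo_genes) > 1:
                    hmm_rows.append((cargo_genes[1].gene_id, TYROSINE_PROFILE, 1e-6, 0.30))
                if terS is not None:
                    ter_rows.append((terS.gene_id, "pacref_P1", "TerS", 1e-12, 0.70, 30.0))
                if terL is not None:
                    ter_rows.append(
                        (terL.gene_id, "pacref_P1", "TerL", 1e-15, 0.80, sim)
                    )
                    ter_rows.append(
                        (terL.gene_id, "pacref_P22", "TerL", 1e-12, 0.75, min(100.0, sim + 5.0))
                    )
                if cargo_genes:  # failing terminase decoy
                    ter_rows.append((cargo_genes[0].gene_id, "pacref_P1", "TerL", 1e-3, 0.80, 70.0))
                for desc in internal:
                    block = desc["drafts"]
                    d_start, d_end = block[0].start, block[-1].end
                    if block[0].start > block[-1].end:  # reversed prophage
                        d_start, d_end = block[-1].start, block[0].end
                    expected = (
                        "int_to_terminase"
                        if desc["position"] == "pre_terminase"
                        else "terminase_to_end"
                    )
                    defense_records.append(
                        {
                            "system_id": desc["system_id"],
                            "genome": genome,
                            "system_name": desc["system_name"],
                            "gene_ids": ",".join(d.gene_id for d in block),
                            "start": d_start,
                            "end": d_end,
                            "location": "prophage",
                            "prophage_id": ident,
                            "position": desc["position"],
                            "expected_label": expected,
                        }
                    )
            elif kind == "defense":
                defense_records.append(
                    {
                        "system_id": ident,
                        "genome": genome,
                        "system_name": plan.system_name,
                        "gene_ids": ",".join(d.gene_id for d in unit),
                        "start": unit[0].start,
                        "end": unit[-1].end,
                        "location": "chromosomal",
                        "prophage_id": None,
                        "position": None,
                        "expected_label": None,
                    }
                )

        # genome FASTA + GFF3
        if spec.write_fasta:
            nt = rng.integers(0, 4, size=glen)
            seq = np.frombuffer(b"ACGT", dtype="S1")[nt].tobytes().decode()
            with open(paths.genome_fasta(genome), "w") as fh:
                fh.write(f">{genome}\n")
                for i in range(0, glen, 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(paths.genome_gff(genome), "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {genome} 1 {glen}\n")
            for d in drafts_in_order:
                attrs = f"ID={d.gene_id};product={d.product}"
                fh.write(
                    f"{genome}\tsynthio\tgene\t{d.start + 1}\t{d.end}\t.\t{d.strand}\t.\t{attrs}\n"
                )

    # --- identity edges ---------------------------------------------------------
    for fam in bb_fams:
        members = bb_member_seqs[fam]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                (ga, sa), (gb, sb) = members[i], members[j]
                edge_rows.append((ga, gb, round(pairwise_identity(sa, sb), 2), 1.0, 1.0))
    # cross-family decoy pairs (far below any sane threshold)
    for i in range(0, spec.n_persistent, 5):
        fa, fb = bb_fams[i], bb_fams[(i + 7) % spec.n_persistent]
        if bb_member_seqs[fa] and bb_member_seqs[fb] and fa != fb:
            ga, sa = bb_member_seqs[fa][0]
            gb, sb = bb_member_seqs[fb][0]
            edge_rows.append((ga, gb, round(pairwise_identity(sa, sb), 2), 1.0, 1.0))

    # --- realized persistent families -------------------------------------------
    need = int(
        np.ceil(spec.persistence_call_fraction * spec.n_genomes - 1e-9)
    )
    persistent = [
        bb_fams[i] for i in range(spec.n_persistent) if int(presence[:, i].sum()) >= need
    ]
    persistent_idx = {i for i in range(spec.n_persistent) if bb_fams[i] in set(persistent)}

    # --- expected spots: adjacency of realized-persistent genes -----------------
    # Only persistent families delimit intervals, so a backbone family that
    # fell below the persistence threshold merges its two neighboring gaps.
    pair_content: dict[tuple[str, str], dict[str, bool]] = {}
    gap_pair = {
        g: tuple(
            sorted(
                (bb_fams[g], bb_fams[(g + 1) % spec.n_persistent if spec.circular else g + 1])
            )
        )
        for g in range(n_gaps)
    }
    for m in range(spec.n_genomes):
        present = [
            i for i in range(spec.n_persistent) if presence[m, i] and i in persistent_idx
        ]
        if not present:
            continue
        if len(present) == 1:
            pairs = [(present[0], present[0])] if spec.circular else []
        else:
            pairs = list(zip(present, present[1:]))
            if spec.circular:
                pairs.append((present[-1], present[0]))
        for i0, i1 in pairs:
            key = tuple(sorted((bb_fams[i0], bb_fams[i1])))
            pair_content.setdefault(key, {"has_prophage": False, "has_defense": False})
    for _, gap, _, _ in prophage_placements:
        pair_content[gap_pair[gap]]["has_prophage"] = True
    for rec in defense_records:
        if rec["location"] == "chromosomal":
            gap = next(
                g for _, g, mm, sid in chrom_defense_placements if sid == rec["system_id"]
            )
            pair_content[gap_pair[gap]]["has_defense"] = True
        else:
            pid = rec["prophage_id"]
            gap = next(g for _, g, _, p in prophage_placements if p == pid)
            pair_content[gap_pair[gap]]["has_defense"] = True

    spot_rows = [
        {"flank_a": k[0], "flank_b": k[1], **v} for k, v in sorted(pair_content.items())
    ]
    spots_df = pd.DataFrame(
        spot_rows, columns=["flank_a", "flank_b", "has_prophage", "has_defense"]
    )
    spot_counts = {
        "n_spots": len(spot_rows),
        "n_with_prophage": int(sum(r["has_prophage"] for r in spot_rows)),
        "n_with_defense": int(sum(r["has_defense"] for r in spot_rows)),
        "n_with_both": int(sum(r["has_prophage"] and r["has_defense"] for r in spot_rows)),
    }

    # --- write tables -------------------------------------------------------------
    genes_df = pd.DataFrame(
        gene_rows,
        columns=["genome", "contig", "gene_id", "start", "end", "strand", "product",
                 "true_role", "true_family"],
    )
    genes_df.drop(columns=["true_role", "true_family"]).to_csv(
        paths.genes, sep="\t", index=False
    )
    pd.DataFrame(
        [(g, g, genome_lengths[g], "circular" if spec.circular else "linear") for g in genomes],
        columns=["genome", "contig", "length", "topology"],
    ).to_csv(paths.contigs, sep="\t", index=False)
    pd.DataFrame(
        edge_rows, columns=["prot_a", "prot_b", "pct_identity", "coverage_a", "coverage_b"]
    ).to_csv(paths.identity_edges, sep="\t", index=False)
    pd.DataFrame(
        hmm_rows, columns=["protein", "profile_accession", "evalue", "profile_coverage"]
    ).to_csv(paths.hmm_hits, sep="\t", index=False)
    pd.DataFrame(
        ter_rows,
        columns=["query", "ref_name", "ref_role", "evalue", "query_coverage", "pct_similarity"],
    ).to_csv(paths.terminase_hits, sep="\t", index=False)
    pd.DataFrame(pcall_rows, columns=["genome", "prophage_id", "start", "end"]).to_csv(
        paths.prophage_calls, sep="\t", index=False
    )
    defenses_df = pd.DataFrame(
        defense_records,
        columns=["system_id", "genome", "system_name", "gene_ids", "start", "end",
                 "location", "prophage_id", "position", "expected_label"],
    )
    defenses_df.drop(
        columns=["location", "prophage_id", "position", "expected_label"]
    ).to_csv(paths.defense_calls, sep="\t", index=False)

    prophages_df = pd.DataFrame(
        prophage_records,
        columns=["prophage_id", "genome", "start", "end", "n_genes", "int_gene", "int_end",
                 "orientation", "terS_gene", "terL_gene", "terL_similarity", "pac_related",
                 "terS_terL_gap"],
    )
    truth = GroundTruth(
        spec={
            k: v
            for k, v in asdict(spec).items()
            if k not in ("prophage_specs", "defense_specs")
        }
        | {
            "n_prophage_plans": len(spec.prophage_specs),
            "n_defense_plans": len(spec.defense_specs),
        },
        genome_lengths=genome_lengths,
        genes=genes_df,
        family_members=family_members,
        persistent_families=persistent,
        spots=spots_df,
        spot_counts=spot_counts,
        prophages=prophages_df,
        defenses=defenses_df,
    )
    truth.to_json(paths.ground_truth)
    return paths, truth
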