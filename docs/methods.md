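# Methods

## The question the pipeline answers

Temperate phages that package DNA by the headful mechanism (*pac* phages)
can initiate packaging at the *pac* site of an integrated prophage and run
past the element's end into the chromosome, moving large blocks of host DNA
— lateral transduction (LT). One capsid holds roughly 45 kbp, and packaging
can continue for several headfuls, so genes within a few hundred kbp
downstream of an attachment site are mobilizable. `ltscope` quantifies, over
a collection of related genomes, how anti-phage defense systems are placed
relative to (i) the chromosomal spots where prophages integrate and (ii) the
packaging direction and terminase position of the prophages themselves —
the two geometries that decide whether LT can move them.

## Model and procedure

**Gene families and the persistent backbone.** Proteins are clustered by
single-linkage over a pairwise-identity edge table: two proteins share a
family iff connected by a chain of alignments each with ≥ 80% identity
(inclusive) and ≥ 0.8 aligned fraction of *both* partners. The coverage
floor is a package default, configurable and echoed into output headers;
identity can come from any aligner since only the edge list is consumed. A
family is *persistent* when ≥ ⌈0.9 · n_genomes⌉ genomes carry **exactly
one** member; genomes with two or more members do not count ("single,
unique" is read as exactly-one-copy). The ceiling is computed with a 1e-9
guard against float noise.

**Intervals and spots.** Each genome is partitioned into the regions between
consecutive persistent genes; a circular contig with k persistent genes
yields exactly k intervals including the wrap-around one, and persistent
genes belong to no interval. A *spot* is the cross-genome set of intervals
sharing an unordered flank pair of persistent families — unordered so that
inversions do not split spots. Prophage and defense calls are assigned to
the unique interval containing their span midpoint; the number of intervals
a call's span overlaps is reported alongside, so elements crossing a
persistent gene are visible rather than silently merged. Genomes
contributing two intervals to one spot (locally duplicated flank) are
flagged, not merged.

**Prophage classification.** Within each called prophage span, the integrase
is a gene hit by the tyrosine-recombinase profile PF00589, or by *both*
serine-recombinase profiles PF00239 and PF07508 on the same protein, at
e-value < 1e-3 (strict, per "smaller than") and profile coverage ≥ 0.5
(inclusive, per "at least"); among qualifiers the gene nearest either end
wins, ties to the left. An integrase within the terminal 10% of the gene
list (minimum one gene — a tolerance the source definition of "at one end"
leaves open) fixes the orientation: left end ⇒ the element reads and
packages rightward, right end ⇒ leftward, interior ⇒ unknown and excluded
from oriented analyses. TerS/TerL candidates come from case-insensitive
product keywords ("terminase small/large subunit") or homology hits against
reference pac-phage terminase pairs (e-value < 1e-5, query coverage ≥ 0.5);
a pair is accepted when the two genes are ≤ 3 positions apart (they are
typically adjacent), smallest gap first, then highest TerL similarity. A
prophage is *pac-related* iff its TerL similarity strictly exceeds 60%
(exactly 60 is not pac); when several reference TerLs pass, the **lowest**
passing similarity is the defining value — the conservative reading of a
threshold chosen on the low tail. Whether "similarity" is identity or
positives is aligner-dependent; the pipeline treats the column as an opaque
percentage.

**Defense positioning.** Each defense system (possibly several consecutive
genes) is reduced to its span midpoint, ⌊(start+end)/2⌋, with wrap-spanning
spans unwrapped then reduced modulo genome length. Relative to one oriented
prophage, all coordinates are mapped into the packaging frame (leftward
prophages mirrored, so one code path serves both) and the midpoint is
labelled: [prophage start, TerL end) → `int_to_terminase` (ahead of the
packaging signal, not moved by LT); [TerL end, prophage end) →
`terminase_to_end` (moved by LT) — a midpoint exactly on the TerL edge
counts as after it; [end, end+25 kb) → `downstream_window`;
[start−25 kb, start) → `upstream_of_prophage`; else `chromosomal_far`.
All intervals are half-open throughout the package (0-based internally,
GFF3 written 1-based inclusive); the window membership is therefore
[boundary, boundary+window) rather than a closed right edge — at 25-kb
windows the two conventions differ by a single base pair. Window counts are
tabulated per region and prophage class (pac vs other), both as raw counts
and per-prophage rates, since the right normalization depends on cohort
composition.

**LT regions and headful distance.** An LT region is n consecutive headfuls
(default headful 45,000 bp; default report n = 6, covering the
several-hundred-kbp scale of observed transfer) directed away from an
att/pac origin; on circular genomes a region ≥ genome length would
self-overlap and is rejected, on linear contigs it is clipped and flagged
truncated. The headful-distance map bins the genome (default 1 kb) and
assigns each bin the minimum over integration sites of
⌈directed distance / headful⌉; a site may emit rightward, leftward, or both.
The summary is the fraction of the genome within k headfuls of the nearest
site.

**Reporting.** Percentages are half-away-from-zero at one decimal (or
nearest integer where that convention is used); zero denominators render
"NA", never 0. Every output table carries a `# key = value` provenance
header that round-trips through the config parser, and identical inputs +
configuration reproduce byte-identical outputs.

## The synthetic-data generator

`synthio` emulates the statistical structure of a collection of complete,
single-contig, circular genomes of one species:

* a backbone of 50 persistent families (default), present per genome with
  probability 0.95, each member an equal-length variant of the family
  reference at 95% identity to it (pairwise member identity ≈ 90%, well
  above the 80% clustering threshold; families are separated by ~5%
  background identity). "Identity" is matches over columns of the implied
  gapless alignment, so planted values are exact by construction;
* accessory gaps between backbone genes, filled with unique filler proteins
  in uniform-random order (120 per genome by default, giving ~200 genes /
  ~200 kb per genome on the fixed 1 kb gene pitch);
* planted prophages (40 kb / 40 genes by default) with an integrase at one
  end, a TerS/TerL pair at a controlled positional gap, blast-style hit rows
  at a controlled TerL similarity, plus sub-threshold decoy hits; defense
  systems can be planted before or after the terminase pair;
* chromosomal defense systems (1–3 genes) in designated spots.

Families flanking planted spots are always present so planted content sits
between well-defined flanks; all other presence/absence is Bernoulli. The
ground truth (family membership, realized persistent set, expected spots
with flags, prophage attributes, defense locations and expected region
labels) is computed from the generator's own plan and presence matrix —
not from the emitted files — so pipeline-recovery tests compare two
independent paths. The default scenario plants 12 prophages (six pac-like
at TerL similarity 85%, each with one pre- and one post-terminase defense
system; six non-pac at 40%) and 18 chromosomal systems across 8 prophage
spots, 7 defense spots, 4 shared.

What the generator does **not** emulate: nucleotide-level evolution (the
genome sequence is random and independent of gene content), indels or
length variation within families, rearrangement or gene-order divergence
between genomes, prophages spanning persistent genes, multi-contig or draft
assemblies, and homology between different prophages. Tests passing on this
material therefore demonstrate the correctness of the interval/threshold/
coordinate logic under the stated assumptions, not robustness to annotation
noise, fragmented assemblies, or borderline homology calls in real data.

## Numerical and degenerate-input choices

* Thresholds follow the stated wording: e-values strict (<), coverages and
  identity inclusive (≥), pac similarity strict (>).
* Persistence ceiling guarded: ⌈f·n − 1e-9⌉.
* Integrase end ties (equidistant from both ends) resolve to the left end.
* Terminase pair ties: smallest positional gap, then highest TerL
  similarity, then lexicographic gene order — fully deterministic.
* A genome with zero persistent genes becomes one degenerate whole-contig
  interval; one persistent gene on a circular contig gives a single
  wrap-around interval flanked by that family on both sides; fewer than two
  on a linear contig warns and uses contig-end sentinels.
* Calls whose midpoint falls on a persistent gene belong to no interval;
  they stay in denominators and are visible as unassigned rows.
* Problem sizes: the standard scenario (20 genomes × ~200 genes) runs the
  full pipeline in a few seconds; oracle suites use 50-protein / 50-row /
  ≤100-kb instances, sizes at which exhaustive re-computation is exact and
  fast.

## Known limitations

* The 60% pac threshold is taken as a fixed parameter; re-deriving it from
  a similarity histogram requires a real hit corpus.
* Spot identity is the flank pair only — no synteny check beyond adjacency;
  large-scale rearrangements that reuse a flank pair elsewhere would
  conflate spots.
* Prophages overlapping persistent genes are reported (overlap count > 1)
  but not resolved into sub-intervals.
* The pipeline consumes prophage and defense *calls*; it does not detect
  elements de novo, and inherits whatever boundary error the upstream
  caller makes.
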