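# ltscope

Comparative genomics of defense-system mobilization by lateral
transduction (LT).

Temperate *pac*-type phages package DNA by the headful: packaging starts at
the *pac* site and, for an integrated prophage, can run off the element's
end and carry on into the chromosome, one ~45 kbp capsid headful at a time.
Chromosomal genes — including anti-phage defense islands — that sit within
a few headfuls downstream of a prophage attachment site are therefore
mobilizable between strains. `ltscope` is for microbial comparative
genomicists who want to quantify that geometry across a collection of
related genomes:

* cluster proteins into gene families (single-linkage at ≥ 80% identity)
  and call the **persistent** backbone — families single-copy in ≥ 90% of
  genomes;
* partition each genome into the intervals between consecutive persistent
  genes and group them across genomes into **spots**, the recurrent
  integration loci of the accessory genome, flagging which spots carry
  prophages and/or defense systems;
* classify each prophage by integrase position (tyrosine PF00589 or serine
  PF00239+PF07508 profiles) → packaging **orientation**, locate its
  TerS/TerL terminase pair, and call it **pac-related** when TerL
  similarity to reference pac-phage terminases exceeds 60%;
* position every defense system (by span midpoint) relative to each
  oriented prophage — before the terminase (not moved by LT), after it
  (moved by LT), or in the 25-kb flanking windows — and compute
  **LT regions** (n × 45 kb downstream of an att site) and genome-wide
  **headful-distance maps**.

Upstream detection (prophage spans, defense-system calls, HMM and blastp
searches) is consumed as plain TSV tables; `ltscope` does not re-run those
tools. A synthetic-collection generator (`ltscope.synthio`) emits the full
input layout with known ground truth, so the entire pipeline is exercisable
— and tested — without any downloads.

## Worked example

```bash
ltscope synth --outdir demo --seed 1     # 20 synthetic genomes + truth
ltscope run --input-dir demo --output-dir demo_out
```

prints the cohort summary:

```
genomes	20
spots	61
spots_with_prophage	8
spots_with_defense	7
spots_with_both	4
prophages	12
prophages_distinct_interval	12 (100%)
prophages_with_int	12
prophages_with_terminases	12 (100.0%)
prophages_pac_related	6
defense_systems	30
defense_in_prophage_spots	21 (70.0%)
defenses_per_interval	1:17, 2:5, 3:1
```

Reading it: the 20 genomes share a 50-family persistent backbone that
partitions them into 61 spots; 8 spots carry a prophage somewhere in the
collection, 7 carry defense systems, 4 carry both. All 12 prophages have a
terminal integrase (orientation known) and an adjacent TerS/TerL pair; the
6 whose TerL resembles reference pac-phage terminases at > 60% similarity
are pac-related, i.e. mechanistically capable of LT. 21 of the 30 defense
systems (70.0%) sit in spots where a prophage integrates in at least one
genome — exactly the planted layout, which `demo/ground_truth.json`
records. Per-stage tables (families, intervals, spots, annotated
prophages, region counts) land in `demo_out/`, each with a `# key = value`
provenance header.

The same machinery is available as a library:

```python
from ltscope import synthio, report_cli
spec = synthio.SyntheticSpec.default_scenario(rng_seed=1)
paths, truth = synthio.generate_collection(spec, "demo")
result = report_cli.run_pipeline(
    report_cli.PipelineConfig(input_dir="demo", output_dir="demo_out")
)
result.summary.n_pac          # 6
result.window_counts          # defense counts per prophage-relative region
```

`ltscope ltmap` writes the headful-distance map (minimum capsid headfuls
from every genome bin to the nearest integration site);
`ltscope defense-windows` the per-region defense counts split pac vs other.
See `docs/methods.md` for the model, parameter defaults, and what the
synthetic generator does and does not emulate.

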