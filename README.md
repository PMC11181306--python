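# panplastome

A toolkit for pan-plastome comparative analysis: quadripartite structure
metrics, alignment-based variant-event calling with a four-way typology,
haplotype and diversity statistics, median-joining haplotype networks, and
hypervariable-marker screening — with a bundled synthetic plastome-population
generator that plants ground-truth events for end-to-end validation.

## What it does

- **structure** — detects the LSC / IRb / SSC / IRa architecture of a
  circular plastome from its longest disjoint inverted-repeat pair,
  canonicalizes rotation and LSC/SSC orientation against a reference, and
  reports per-region lengths and GC content.
- **annotation** — loads GenBank or GFF3 gene annotations, counts unique
  genes per functional category (IR-duplicated genes counted once), lists
  intron-containing genes, and builds a total CDS / intron / IGS context
  index over the genome.
- **variants** — merges maximal runs of non-invariant alignment columns into
  events classified as SNV (one substituted column), block substitution
  (two or more consecutive substituted columns), InDel (a maximal
  gap-containing run), or mixed (a run combining substitutions and gaps),
  then partitions them by region, genic context, and gene.
- **popgen** — complete-deletion haplotype collapsing, haplotype diversity
  `Hd = n(1 − Σp²)/(n − 1)`, nucleotide diversity Π, Tamura-Nei (TN93)
  distances, Hudson-style pairwise Fst (`1 − Hw/Hb`) on SNV columns, PCA on
  indicator-encoded SNVs, and a neighbor-joining tree.
- **network** — minimum spanning networks (union of all MSTs) and
  median-joining networks with majority-rule median vectors, plus per-node
  group compositions.
- **markers** — sliding-window diversity profiles and clade-diagnostic
  SNV/InDel sites (states carried by every member of a cluster set and
  nobody else).
- **synthetic_data** — a seeded generator producing a quadripartite ancestor,
  gene model, cluster genealogy, and a true alignment with planted events of
  all four categories and machine-readable truth.
- **pipeline** — runs everything in dependency order from one YAML config
  and writes a deterministic consolidated JSON report.

## CLI

Every module has a subcommand under a single entry point:

```sh
panplastome structure --fasta genomes.fasta --min-ir-len 1000 \
    --reference ref.fasta --out-prefix out/structure
panplastome annotate  --annotation genes.gff3 --fasta genome.fasta \
    --out-prefix out/genes
panplastome variants  --alignment aln.fasta --annotation genes.gff3 \
    --no-collapse-ir --out-prefix out/variants
panplastome popgen    --alignment aln.fasta --clusters clusters.tsv \
    --model tn93 --out-prefix out/popgen
panplastome network   --alignment aln.fasta --groups clusters.tsv \
    --epsilon 0 --out-prefix out/network
panplastome markers   --alignment aln.fasta --clusters clusters.tsv \
    --annotation genes.gff3 --window 600 --step 200 --out-prefix out/markers
panplastome simulate  --seed 1 --out-dir out/sim
panplastome run       --config pipeline.yaml
```

A pipeline config selects either real inputs or a simulation:

```yaml
output_dir: out
simulation:
  seed: 1
  n_clusters: 6
  samples_per_cluster: [8, 8, 8, 8, 8, 8]
  within_cluster_extra_snvs: [0, 3, 1, 0, 0, 2]
params:
  model: tn93
  window: 600
  step: 200
```

or

```yaml
output_dir: out
inputs:
  fasta: genomes.fasta
  alignment: aln.fasta
  annotation: genes.gff3
  clusters: clusters.tsv
```

Exit codes: 0 ok, 1 input error, 2 internal error.

## Conventions worth knowing

- Coordinates are 0-based half-open on the canonical rotation
  (position 0 = LSC start); TSV/GFF3 outputs use the formats' own
  conventions.
- Complete deletion (drop any column with a gap/N anywhere) is used for
  haplotypes, Hd and Π; pairwise deletion for model distances.
- `tn93_distance` raises a saturation error when a logarithm argument is
  non-positive; aggregate statistics (Fst, NJ input matrices) substitute the
  p-distance for the affected pair with a warning.
- All randomness flows through a single seeded generator; identical
  config + seed reproduce byte-identical outputs.
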