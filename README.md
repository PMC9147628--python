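# igsflow

Amplicon ribotype and plastid haplotype analysis for polyploid plant
complexes.

Multi-copy nuclear markers such as the 5S rDNA intergenic spacer (5S-IGS)
record the subgenome composition of allopolyploids: a single genome carries
several divergent spacer lineages, some private to a species, some shared
across species through common ancestry, hybridization, or incomplete
lineage sorting. High-throughput amplicon sequencing of the spacer turns
this into data — hundreds of unique sequence variants per sample with wildly
skewed abundances — but extracting the biology requires a careful chain of
preprocessing and cross-sample bookkeeping. `igsflow` implements that chain
as a tested, reusable Python package, alongside the plastid-side toolkit
(haplotype collapse, diversity, median-joining networks) that such studies
pair with the nuclear data.

## What it does

**Amplicon pipeline** (`preprocess`, `classify`, `pipeline` modules)

1. **Pair merging** with the ΔQ rule: overlapping read pairs are assembled;
   a disagreeing base is resolved in favour of the read whose Phred score is
   at least `dq_threshold` (default 6) higher, otherwise the position
   becomes `N` (and the contig is discarded under the default zero-N
   policy).
2. **Dereplication** into a `VariantTable` — unique variant × sample read
   counts, by exact string identity.
3. **De-novo chimera screening**: a variant is flagged when a single
   crossover between two ≥2×-more-abundant variants explains it with at
   least 3 fewer mismatches than any single parent, leaves almost no
   residual mismatches, and draws diagnostic sites from both parents.
4. **Abundance and length filters** (dataset-wide total ≥ 5 by default,
   optional minimum length), with per-criterion removal bookkeeping.
5. **Classification** of every retained variant by its cross-sample
   abundance pattern: `specific:<species>` (read share > 99.95% in one
   species, seen in ≥ 2 of its samples), `local:<sample>` (species-exclusive
   but confined to one of several samples), or one of four `ambiguous`
   categories defined over species roles (shared with an outgroup; shared
   between the *tricolor* role and the rest of the complex; shared between
   the *arvensis* role and *kitaibeliana*/*hymettia*; shared only within the
   *kitaibeliana*/*hymettia* pair) — evaluated in that precedence order.
   Per-sample class compositions are abundance-weighted.

**Divergence statistics** (`divergence`): uncorrected p-distances with
pairwise (or complete) deletion of gaps/`N`; within- and between-group means
over all unordered sequence pairs; standard errors by site-resampling
bootstrap. Intra-genomic divergence of a sample = mean pairwise distance
among its aligned unique variants.

**Plastid haplotypes** (`haplotypes`): exact-identity collapse with gaps as
a fifth character state; per-taxon totals, shared-haplotype counts, and
Nei's haplotype diversity `Hd = n/(n−1)·(1 − Σ p_i²)`; a median-joining
network (ε-relaxed minimum spanning network plus cost-reducing
majority-consensus medians, degree-<3 medians pruned) with a configurable
mutation cut (default > 10) to delineate deep haplotype lineages.

**Indel coding** (`indels`): Simple Indel Coding — one binary character per
distinct internal gap run; exact run = 1, absent = 0, subsumed by a longer
run = missing; terminal gap runs are missing data. Export as a two-partition
(DNA + binary) NEXUS file for relaxed-clock dating tools.

**Tree clusters** (`trees`): counts the maximal bootstrap-supported
(≥ 70 by default) clades of ≥ 2 tips on per-sample variant trees — a proxy
for the number of distinct ribotype lineages per genome.

**Synthetic data** (`simulate`): a fully traceable generator of
allopolyploid amplicon communities (shared/private lineages, partially
homogenized repeat copies, lognormal abundances, quality-coupled sequencing
error, PCR chimeras, overlapping read pairs) and of plastid datasets with
configured haplotype frequencies and deep lineage splits. Every read and
variant carries ground truth, so the entire pipeline is testable without
downloading anything.

## Worked example

Simulate a four-species community (two samples per species, the sharing
structure typical of an annual pansy complex), run the pipeline, and
classify:

```sh
igsflow simulate --seed 42 --reads-per-sample 5000 --out demo
igsflow preprocess --manifest demo/manifest.tsv --reads-dir demo/reads \
    --min-abundance 5 --out demo/pre
igsflow classify --table demo/pre/table.tsv --manifest demo/manifest.tsv \
    --out demo/cls
```

The preprocess step reports, per sample, how many pairs merged
(`V_hymettia_s1: 4989/5000 merged` — the remainder were rejected by the
ΔQ/N rule) and ends with

```
83 variants kept (17 chimeric, 1587 low-abundance, 0 short removed)
```

i.e. of all unique merged sequences, 17 were flagged as two-parent
chimeras, 1587 (mostly singleton error reads) fell below total abundance 5,
and 83 variants survived. `demo/cls/labels.tsv` assigns each a class:

```
variant_id           kind       detail
var00001;size=8651   ambiguous  gr_tricolor
var00002;size=6199   ambiguous  gr_arvensis
```

and `compositions.tsv` gives the per-sample class proportions (rows sum to
1; abundance-weighted):

```
                   gr_arvensis  gr_tricolor  kit_hym  local  specific:V_tricolor
V_tricolor_s1            0.000        0.307    0.000  0.222                0.471
V_arvensis_s1            0.404        0.538    0.000  0.058                0.000
V_kitaibeliana_s1        0.296        0.349    0.208  0.147                0.000
V_hymettia_s1            0.559        0.134    0.235  0.071                0.000
```

Read this as the subgenome signature of each sample: only *V. tricolor*
carries species-specific variants (its private lineage), every sample
shares the complex-wide `gr_tricolor` pool, the `gr_arvensis` pool is
confined to the *arvensis*/*kitaibeliana*/*hymettia* trio, and `kit_hym`
marks the variants those two species alone share.

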