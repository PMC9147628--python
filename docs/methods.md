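# Methods

This note documents the models, rules and numerical choices behind
`igsflow`, in the order the pipeline applies them, followed by the
synthetic-data model and known limitations.

## Read merging (ΔQ rule)

A read pair is merged by reverse-complementing the mate and locating the
ungapped offset that maximises base matches. The implementation first tries
a seed-and-verify shortcut (exact 24-mer lookup, accepted when ≤ 5% of the
implied overlap mismatches) and falls back to the exhaustive offset scan;
the scan additionally requires ≥ 60% matches in the chosen overlap, so a
pair with no credible overlap is rejected rather than merged at the
least-bad offset. Within the overlap, agreeing bases keep the higher Phred
score; disagreeing bases take the base whose score exceeds the other's by
at least `dq_threshold` (default 6, the conventional contig-making value),
otherwise the position becomes `N`. The default `max_n_fraction = 0`
discards any contig containing an `N`: downstream dereplication is exact
string identity, and a single ambiguous base would fragment a variant into
spurious singletons. Minimum overlap is 20 bases. Phred+33 encoding only;
files whose scores decode above 62 are rejected as likely Phred+64 rather
than silently re-decoded.

## Dereplication

Contigs collapse by exact identity into a variant × sample count matrix.
No reverse-complement collapsing is performed — a single primer pair fixes
amplicon orientation. Variant identifiers encode abundance rank and total
count (`var00001;size=8651`), with ties broken lexicographically so output
is deterministic.

## Chimera screening

The detector is an explicit, transparent simplification of de-novo
chimera scoring. Candidates are scanned in decreasing total abundance;
eligible parents are unflagged variants at least `skew = 2` times more
abundant. For each candidate–parent pair a global alignment (edlib) yields
a per-position mismatch profile; prefix sums then give, for every crossover
point, the cost of a left-parent-prefix + right-parent-suffix model. A
candidate is flagged when the best such model

* improves on the best single parent by ≥ `min_improvement = 3` mismatches,
* leaves at most `max(2, 2% of length)` residual mismatches — a chimera is
  by definition almost fully explained by its parents; without this
  condition, optimising the crossover point between unrelated sequences
  yields chance improvements and clean variants get flagged, and
* draws at least one diagnostic site from each parent segment.

Candidates with total abundance < 2 are skipped: they cannot act as parents
and every configuration of the pipeline removes them at the abundance
filter anyway. Parameters are deliberately conservative; exact numeric
reproduction of the cited tool's h-score is a non-goal.

## Abundance and length filters

Thresholds are inclusive (`total ≥ min_total_abundance`, dataset-wide, not
per sample) and each removal is attributed to exactly one criterion,
abundance first. The pipeline records counts at every stage so that read
and variant totals reconcile across the chain.

## Variant classification

The exclusivity threshold τ (default 0.9995) compares **read-abundance
share**, not sample-presence share: one stray read (index bleed-through, an
unflagged chimera fragment) must not flip a variant's class. The decision
tree: if one species holds > τ of a variant's reads, the variant is
`specific` to that species when it occurs in ≥ 2 of the species' samples
(or when the species has only one sample in the dataset — single-sample
outgroups thus yield specific classes, never local); it is `local` to the
single sample that carries it otherwise. Genuinely shared variants fall
into four categories, evaluated in fixed precedence: shared with an
outgroup → `sect_melanium`; the tricolor role with any other complex member
→ `gr_tricolor`; the arvensis role with the kitaibeliana/hymettia role →
`gr_arvensis`; only within the kitaibeliana/hymettia pair → `kit_hym`.
Species roles come from the manifest's YAML companion (or name-pattern
inference), so the scheme is configuration, not hard-coded taxon names. A
sharing set matched by no rule (e.g. outgroups only) falls back to
`sect_melanium` with a warning — a declared choice for a case the scheme
leaves open. Compositions are abundance-weighted; a variant-count-weighted
alternative is available (`weight="variants"`) as a sensitivity check.
Raising τ can only move variants from specific/local to ambiguous, never
the reverse; this monotonicity is property-tested.

## Divergence

Distances are uncorrected p-distances ("base differences per compared
site") — no substitution-model correction, matching the marker's short
length and high divergence where model fits are unstable. Pairwise deletion
(default) drops a site only for pairs where either sequence has a gap or
`N`; complete deletion drops columns with any gap/`N` globally. Group means
average all unordered pairs of unique sequences, unweighted by read
abundance. Standard errors come from a site-resampling bootstrap (resample
alignment columns with replacement, recompute all means; SE = standard
deviation over replicates; 1000 replicates by default, seeded). The
implementation is vectorised over pairs; the SE of a mean distance scales
roughly as L^(−1/2) in alignment length, which the tests check empirically.

## Haplotypes and the median-joining network

Haplotype collapse treats `-` as a fifth character state, so indel variants
separate even when bases agree. `Hd = n/(n−1)·(1 − Σ p_i²)` is exactly the
probability that two distinct sampled individuals carry different
haplotypes (the tests verify this identity by pair enumeration).

The network follows the median-joining idea: build the ε-relaxed minimum
spanning network over the current nodes (Hamming distance, every change
weight 1, equal weights for all substitution types; ε = 0 by default), add
the majority-consensus median of node triples whenever doing so strictly
reduces the minimum-spanning cost, and finally prune inferred medians of
degree < 3. Two deliberate search choices: candidate medians are taken from
**all** triples of the current node set (with ε = 0 the classic
near-connected restriction can starve the candidate pool and strand the
search in a local minimum), and when no single median reduces cost on a
small input (≤ 60 candidates), coordinated pairs of medians are tried —
two medians can open a shortcut neither opens alone. Ties resolve to the
lexicographically smallest sequence, making output deterministic. On
genealogy-like instances of ≤ 6 haplotypes the network cost equals a
brute-force optimum over all subsets of observed-triple medians (checked on
200 instances). Multi-column indels are *not* condensed to single events;
each gap column counts as one change, which inflates some edge weights and
is the main caveat when comparing against tools that condense indels.
Haplotype lineage groups are obtained by severing edges above a mutation
cut (default > 10) and collecting connected observed haplotypes.

## Simple indel coding

One binary character per distinct internal gap run (0-based half-open
interval internally; 1-based inclusive in NEXUS output). A sequence scores
1 for an exact run match, missing when a strictly longer run of that
sequence contains the interval, 0 otherwise. Leading and trailing gap runs
are treated as missing data throughout — amplicon length variation produces
terminal gaps that are not indel events. The NEXUS export writes the
nucleotide and indel matrices as two character blocks plus a sets block;
binary states 0/1 with `?` for missing.

## Tree cluster counting

Inputs are per-sample phylograms with bootstrap supports as internal node
labels (missing labels count as support 0; values outside [0, 100] are
errors). Unrooted trees are midpoint-rooted first. Three details make the
scan robust, all documented as this package's formalization of a rule the
underlying studies apply visually:

1. supports are properties of edge *splits*, so they are recorded per
   bipartition before rerooting and re-attached afterwards (newick node
   labels otherwise migrate relative to their splits when the root moves);
2. when the midpoint falls within 25% of an internal node along the
   subdivided edge, the tree is rooted at that node — on star-like
   backbones the midpoint lies essentially at the hub, and keeping a
   hair-thin subdivision would let the complement of one lineage absorb all
   others;
3. a child of the root qualifies through the root-split support only when
   its subtree diameter is at most twice its subtending branch: the split's
   support attests the tighter side's coherence, not the complement's.

A major cluster is then a maximal clade with support ≥ `min_support`
(default 70) and ≥ `min_size` (default 2) tips whose ancestors do not
already qualify; supported clades nested inside one are reported as
sub-clusters; uncovered tips are singleton outliers. Note the cluster
*count* is not monotone in the support threshold under maximality
(disqualifying a deep clade can free several subclades); the set of tips
covered by clusters is, and that is the property the tests assert.

## Synthetic community model

The generator encodes the study conditions the pipeline assumes:

* **Lineages.** Each ribotype lineage is a template evolved from a common
  root by a stated divergence (defaults 0.05–0.12 substitutions/site) with
  its own amplicon length (300–380 bp). Carrier species sets define the
  sharing structure; the default configuration has four species × two
  samples with a tricolor-private lineage, a complex-wide lineage, an
  arvensis+kitaibeliana+hymettia lineage, and a kitaibeliana/hymettia
  lineage.
* **Concerted evolution.** Each lineage contributes `loci × copies` repeat
  copies per carrier genome; a copy matches the lineage consensus with
  probability `homogenization = 0.7`, else it carries private variation at
  0.01 substitutions/site. Homogenized copies collapse to one dominant
  variant — exactly how partially homogenized arrays look after
  dereplication. Two additional sample-private variants per sample provide
  true `local` classes.
* **Abundances.** Per sample, each available variant gets a lognormal
  weight (σ = 1.2) and reads are drawn multinomially — the heavy-tailed
  spread that makes abundance filters meaningful.
* **Reads.** 2 × 300 bp pairs cut from each amplicon (so 300 bp amplicons
  are double-covered end to end and 380 bp ones have 80 bp single-covered
  flanks), per-base error 0.001 by default, with miscalled bases carrying
  low Phred scores (2–20) against 25–40 for correct calls. This
  quality/error coupling is what makes ΔQ overlap correction effective, as
  in real basecalls.
* **Chimeras.** `chimera_fraction = 0.01` of reads come from a few distinct
  chimeric variants per sample (single crossover between two same-sample
  templates, one crossover point each, lognormal weights) — PCR chimeras
  amplify clonally; per-read random crossovers would all be singletons and
  invisible to any abundance-aware detector.
* **Ground truth.** Every template records its lineage, carrier samples and
  chimera status; true class labels derive from carrier sets with the same
  decision rules the classifier uses, and read ids carry a chimera tag.

What the generator does **not** emulate: realistic polymerase error
spectra, PCR-cycle dynamics, quality decay along reads, indels inside the
community amplicons (plastid simulation injects indels; community templates
are substitution-only so that equal-length configurations stay alignment-
free), and primer/adapter artefacts. Passing the recovery tests therefore
shows the analysis chain is correct under its stated assumptions, not that
those assumptions hold for any particular instrument.

Class-recovery accounting: ground truth defines classes for simulated
templates. Sequencing-error derivatives that survive the abundance filter
(recurrent same-site miscalls on very abundant templates, mostly in
single-covered flanks) have no truth label; the recovery metric is computed
over truth-matched retained variants, while the composition comparison is
read-weighted and so absorbs the error-derived rest. At the default
conditions (20,000 read pairs/sample, error 0.001) recovery is 100% and the
maximum per-sample composition deviation ≈ 2–3 percentage points across
seeds.

The plastid generator samples individuals multinomially from configured
per-taxon haplotype frequencies over a pool whose members sit on two
lineages separated by ≥ 15 mutations (so a cut at 10 recovers them); under
multinomial sampling `E[Hd] = 1 − Σ p²` exactly, which the tests verify to
Monte-Carlo precision. The per-sample tree generator builds
bootstrap-annotated neighbour-joining trees from k simulated lineages
(default 600 sites, 0.12 between- and 0.01 within-lineage divergence);
shorter markers at this divergence accumulate enough inter-lineage
homoplasy to lend spurious support to backbone resolutions of the star
radiation, which is a property of the data, not the counter.

## Problem sizes and defaults

The shipped tests and the acceptance script run the full pipeline at 20,000
read pairs × 8 samples (≈ 20 s end to end) and smaller unit-scale
configurations elsewhere; bootstrap SEs default to 1000 replicates in the
API and use 50–300 in tests. All randomness flows through explicit seeds;
reruns are byte-identical.

## Known limitations

* The chimera detector is a crossover-scan simplification; borderline
  chimeras with < 3 diagnostic sites per side are invisible by design.
* p-distances carry no substitution-model correction; for deeply diverged
  groups the values undercount multiple hits.
* The MJ search is a greedy cost descent (with the pair rescue); global
  optimality is only guaranteed empirically on small genealogy-like inputs.
* Merging assumes the mate starts at or after the forward read's start
  (no read-through past the amplicon into adapters); adapter-clipped input
  is expected.
* The cluster counter's rooting and cohesion rules are a formalization of a
  visual procedure; trees whose deep backbone is both well-supported and
  genuinely nested will count the deepest supported clades, not every
  visually separate blob.
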