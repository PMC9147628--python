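"""Synthetic allopolyploid amplicon communities and plastid datasets.

The community generator emulates the statistical structure of a multi-copy
ribosomal spacer amplicon study of an allopolyploid species complex:

* each species carries several divergent ribotype *lineages*, some private
  and some shared between defined species subsets (the signature of shared
  subgenomes and incomplete lineage sorting);
* within a lineage, tandem-repeat copies are partially homogenized by
  concerted evolution — a fraction of copies match the lineage consensus
  exactly, the rest carry private low-level variation;
* per-sample variant abundances are heavy-tailed (lognormal weights over
  the sample's available variants, multinomial read sampling);
* reads are cut as overlapping pairs from each amplicon, carry per-base
  Phred scores, and are mutated at a per-base sequencing error rate;
* a configurable fraction of reads comes from two-parent single-crossover
  PCR chimeras formed between same-sample templates.

Every emitted read is traceable: the ground truth records each template's
source lineage, its intended carrier samples, and its true class label
(derived with the same decision rules the classifier uses, from the
configuration alone).

A second generator produces aligned plastid individuals with configured
haplotype frequencies per taxon and two deep lineages separated by more
than ten mutations, to exercise haplotype collapse, diversity statistics
and network lineage cuts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .classify import ClassLabel, Kind, _ambiguous_category
from .errors import ConfigError
from .seqio import (
    Sample,
    SampleManifest,
    SequenceRecord,
    SpeciesRole,
    reverse_complement,
    write_fastq,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate(rng: np.random.Generator, seq: str, rate: float, min_changes: int = 0) -> str:
    """Apply substitutions at ``rate`` per site (at least ``min_changes``),
    uniform across sites and substitution types."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = max(int(rng.binomial(len(seq), rate)), min_changes)
    if n == 0:
        return seq
    n = min(n, len(seq))
    pos = rng.choice(len(seq), size=n, replace=False)
    idx = _BASE_INDEX[arr[pos]]
    shift = rng.integers(1, 4, size=n)
    arr[pos] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Community configuration


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    group: str = "complex_member"
    n_samples: int = 2
    is_tricolor: bool = False
    is_arvensis: bool = False
    is_kit_or_hym: bool = False
    n_individuals: int = 1


@dataclass(frozen=True)
class LineageSpec:
    """One ribotype lineage: a diverged spacer template and its carriers."""

    name: str
    divergence: float  # substitutions/site from the ancestral root template
    carriers: tuple[str, ...]
    length: int | None = None
    loci: int = 2  # loci bearing this lineage in each carrier genome
    copies: int = 3  # sampled repeat copies per locus


@dataclass
class CommunityConfig:
    """Study conditions of a simulated amplicon community.

    Defaults describe a realistic allopolyploid spacer survey: partially
    homogenized repeat arrays, heavy-tailed variant abundances, low
    Illumina-like error, a small PCR-chimera load, and read pairs that
    overlap across the full amplicon length range.
    """

    species: list[SpeciesSpec]
    lineages: list[LineageSpec]
    seed: int
    homogenization: float = 0.7
    within_lineage_divergence: float = 0.01
    locals_per_sample: int = 2
    local_divergence: float = 0.02
    reads_per_sample: int = 20000
    lognormal_sigma: float = 1.2
    error_rate: float = 0.001
    chimera_fraction: float = 0.01
    chimeric_variants_per_sample: int = 3
    read_length: int = 300
    length_range: tuple[int, int] = (300, 380)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for rate in (
            self.homogenization,
            self.within_lineage_divergence,
            self.local_divergence,
            self.error_rate,
            self.chimera_fraction,
        ):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"rate {rate} outside [0, 1]")
        carried = {sp for lin in self.lineages for sp in lin.carriers}
        for sp in self.species:
            if sp.name not in carried:
                raise ConfigError(f"species {sp.name!r} carries no lineage")
        names = {sp.name for sp in self.species}
        for lin in self.lineages:
            unknown = set(lin.carriers) - names
            if unknown:
                raise ConfigError(
                    f"lineage {lin.name!r} lists unknown carriers {sorted(unknown)}"
                )
        if self.length_range[0] > self.length_range[1]:
            raise ConfigError("length_range must be (low, high)")
        if self.read_length * 2 <= self.length_range[1]:
            raise ConfigError(
                "read pairs must overlap: 2*read_length must exceed the "
                "longest amplicon"
            )

    def sample_ids(self, species: str) -> list[str]:
        sp = next(s for s in self.species if s.name == species)
        return [f"{species}_s{i + 1}" for i in range(sp.n_samples)]

    def to_manifest(self) -> SampleManifest:
        samples = []
        roles = {}
        for sp in self.species:
            roles[sp.name] = SpeciesRole(
                group=sp.group,
                is_tricolor=sp.is_tricolor,
                is_arvensis=sp.is_arvensis,
                is_kit_or_hym=sp.is_kit_or_hym,
            )
            for sid in self.sample_ids(sp.name):
                samples.append(
                    Sample(
                        sample_id=sid,
                        species=sp.name,
                        group=sp.group,
                        n_individuals=sp.n_individuals,
                    )
                )
        return SampleManifest(samples=samples, roles=roles)


@dataclass
class TrueVariant:
    seq: str
    lineage: str
    carrier_samples: tuple[str, ...]
    is_chimera: bool = False


@dataclass
class GroundTruth:
    """Per-template provenance plus per-sample emitted read counts."""

    variants: dict[str, TrueVariant]
    reads_by_sample: dict[str, dict[str, int]]  # sample -> template seq -> reads
    manifest: SampleManifest

    def true_label(self, seq: str) -> ClassLabel | None:
        """Class the template would deserve given its intended carriers.

        Returns None for chimeric templates (their true fate is removal).
        Uses the same decision rules as the classifier, on presence of the
        configured carrier samples.
        """
        tv = self.variants.get(seq)
        if tv is None or tv.is_chimera:
            return None
        carriers = tv.carrier_samples
        species = {self.manifest.species_of(s) for s in carriers}
        if len(species) == 1:
            sp = species.pop()
            if len(self.manifest.samples_of(sp)) == 1 or len(carriers) >= 2:
                return ClassLabel(Kind.SPECIFIC, sp)
            return ClassLabel(Kind.LOCAL, carriers[0])
        return ClassLabel(
            Kind.AMBIGUOUS, _ambiguous_category(species, self.manifest).value
        )

    def n_reads(self, sample: str | None = None) -> int:
        if sample is not None:
            return sum(self.reads_by_sample[sample].values())
        return sum(self.n_reads(s) for s in self.reads_by_sample)

    def true_compositions(self):
        """Per-sample class proportions over non-chimeric emitted reads."""
        import pandas as pd

        rows = {}
        for sample, counts in self.reads_by_sample.items():
            props: dict[str, float] = {}
            total = 0
            for seq, c in counts.items():
                label = self.true_label(seq)
                if label is None:
                    continue
                total += c
                props[label.category] = props.get(label.category, 0) + c
            if total:
                rows[sample] = {k: v / total for k, v in props.items()}
        return pd.DataFrame(rows).T.fillna(0.0)


@dataclass
class CommunityData:
    pairs: dict[str, list[tuple[SequenceRecord, SequenceRecord]]]
    truth: GroundTruth
    config: CommunityConfig

    def write_fastq_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample, pairs in self.pairs.items():
            write_fastq((r1 for r1, _ in pairs), outdir / f"{sample}_R1.fastq")
            write_fastq((r2 for _, r2 in pairs), outdir / f"{sample}_R2.fastq")


def _make_reads(
    rng: np.random.Generator,
    template: str,
    count: int,
    read_length: int,
    error_rate: float,
    sample: str,
    serial_start: int,
    tag: str,
) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """Cut ``count`` overlapping read pairs from a template amplicon.

    Miscalled bases carry low Phred scores (2..20) while correct bases sit
    in the 25..40 band, mirroring the quality/error coupling of real basecalls
    that makes dQ-based overlap correction effective.
    """
    L = len(template)
    R = min(read_length, L)
    arr = np.frombuffer(template.encode(), dtype=np.uint8)
    fwd = arr[:R]
    rev = np.frombuffer(
        reverse_complement(template[L - R :]).encode(), dtype=np.uint8
    )
    data = {}
    for which, tmpl in (("1", fwd), ("2", rev)):
        reads = np.broadcast_to(tmpl, (count, R)).copy()
        quals = rng.integers(25, 41, size=(count, R), dtype=np.uint8)
        if error_rate > 0:
            mask = rng.random((count, R)) < error_rate
            n_err = int(mask.sum())
            if n_err:
                idx = _BASE_INDEX[reads[mask]]
                shift = rng.integers(1, 4, size=n_err)
                reads[mask] = _BASES[(idx + shift) % 4]
                quals[mask] = rng.integers(2, 21, size=n_err, dtype=np.uint8)
        data[which] = (reads, quals)
    out = []
    for i in range(count):
        rid = f"{sample}.{serial_start + i}.{tag}"
        r1 = SequenceRecord(
            id=rid + "/1",
            seq=data["1"][0][i].tobytes().decode(),
            quals=data["1"][1][i].tobytes(),
        )
        r2 = SequenceRecord(
            id=rid + "/2",
            seq=data["2"][0][i].tobytes().decode(),
            quals=data["2"][1][i].tobytes(),
        )
        out.append((r1, r2))
    return out


def simulate_community(config: CommunityConfig) -> CommunityData:
    """Generate per-sample paired reads plus ground truth."""
    rng = np.random.default_rng(config.seed)
    manifest = config.to_manifest()

    max_len = config.length_range[1]
    root = random_sequence(rng, max_len)

    # lineage templates and their repeat-copy variant pools
    truth_variants: dict[str, TrueVariant] = {}
    pool_by_lineage: dict[str, list[str]] = {}
    template_by_lineage: dict[str, str] = {}
    for lin in config.lineages:
        length = (
            lin.length
            if lin.length is not None
            else int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        )
        template = mutate(rng, root, lin.divergence, min_changes=1)[:length]
        template_by_lineage[lin.name] = template
        carrier_samples = tuple(
            sid for sp in lin.carriers for sid in config.sample_ids(sp)
        )
        entries: list[str] = []
        for _ in range(lin.loci * lin.copies):
            if rng.random() < config.homogenization:
                seq = template
            else:
                seq = mutate(
                    rng, template, config.within_lineage_divergence, min_changes=1
                )
            entries.append(seq)
            if seq not in truth_variants:
                truth_variants[seq] = TrueVariant(
                    seq=seq, lineage=lin.name, carrier_samples=carrier_samples
                )
        pool_by_lineage[lin.name] = entries

    # per-sample private ("local") variants
    local_by_sample: dict[str, list[str]] = {s: [] for s in manifest.sample_ids}
    for sample in manifest.sample_ids:
        species = manifest.species_of(sample)
        carried = [lin for lin in config.lineages if species in lin.carriers]
        for _ in range(config.locals_per_sample):
            lin = carried[int(rng.integers(0, len(carried)))]
            seq = mutate(
                rng,
                template_by_lineage[lin.name],
                config.local_divergence,
                min_changes=2,
            )
            while seq in truth_variants:
                seq = mutate(rng, template_by_lineage[lin.name], config.local_divergence, min_changes=2)
            truth_variants[seq] = TrueVariant(
                seq=seq, lineage=lin.name, carrier_samples=(sample,)
            )
            local_by_sample[sample].append(seq)

    pairs: dict[str, list[tuple[SequenceRecord, SequenceRecord]]] = {}
    reads_by_sample: dict[str, dict[str, int]] = {}
    for sample in manifest.sample_ids:
        species = manifest.species_of(sample)
        entries: list[str] = []
        for lin in config.lineages:
            if species in lin.carriers:
                entries.extend(pool_by_lineage[lin.name])
        entries.extend(local_by_sample[sample])

        weights = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=len(entries))
        n_chim = int(round(config.chimera_fraction * config.reads_per_sample))
        n_plain = config.reads_per_sample - n_chim
        counts = rng.multinomial(n_plain, weights / weights.sum())

        emitted: dict[str, int] = {}
        for seq, c in zip(entries, counts):
            if c:
                emitted[seq] = emitted.get(seq, 0) + int(c)

        # chimeric templates: one crossover per chimeric variant, reads
        # multinomially spread over the sample's chimeric variants
        if n_chim > 0 and len(set(entries)) >= 2:
            uniq = sorted(set(entries))
            chim_templates: list[str] = []
            attempts = 0
            while (
                len(chim_templates) < config.chimeric_variants_per_sample
                and attempts < 50
            ):
                attempts += 1
                i, j = rng.choice(len(uniq), size=2, replace=False)
                p1, p2 = uniq[int(i)], uniq[int(j)]
                lo = int(0.3 * min(len(p1), len(p2)))
                hi = int(0.7 * min(len(p1), len(p2)))
                k = int(rng.integers(lo, hi + 1))
                chim = p1[:k] + p2[k:]
                if chim in truth_variants or chim in chim_templates:
                    continue
                chim_templates.append(chim)
                truth_variants[chim] = TrueVariant(
                    seq=chim,
                    lineage=f"chimera:{sample}",
                    carrier_samples=(sample,),
                    is_chimera=True,
                )
            if chim_templates:
                cw = rng.lognormal(0.0, 1.0, size=len(chim_templates))
                ccounts = rng.multinomial(n_chim, cw / cw.sum())
                for seq, c in zip(chim_templates, ccounts):
                    if c:
                        emitted[seq] = emitted.get(seq, 0) + int(c)

        sample_pairs: list[tuple[SequenceRecord, SequenceRecord]] = []
        serial = 0
        for seq in sorted(emitted):
            c = emitted[seq]
            tag = "C" if truth_variants[seq].is_chimera else "V"
            sample_pairs.extend(
                _make_reads(
                    rng,
                    seq,
                    c,
                    config.read_length,
                    config.error_rate,
                    sample,
                    serial,
                    tag,
                )
            )
            serial += c
        pairs[sample] = sample_pairs
        reads_by_sample[sample] = emitted

    truth = GroundTruth(
        variants=truth_variants, reads_by_sample=reads_by_sample, manifest=manifest
    )
    return CommunityData(pairs=pairs, truth=truth, config=config)


def tricolor_complex_config(
    seed: int,
    reads_per_sample: int = 20000,
    error_rate: float = 0.001,
    chimera_fraction: float = 0.01,
    n_samples: int = 2,
    uniform_length: int | None = None,
) -> CommunityConfig:
    """The default study conditions: four focal species with the sharing
    structure characteristic of the pansy complex — a tricolor-private
    lineage, a complex-wide shared lineage, an arvensis+kitaibeliana+
    hymettia lineage, and a kitaibeliana/hymettia-only lineage."""
    species = [
        SpeciesSpec("V_tricolor", n_samples=n_samples, is_tricolor=True),
        SpeciesSpec("V_arvensis", n_samples=n_samples, is_arvensis=True),
        SpeciesSpec("V_kitaibeliana", n_samples=n_samples, is_kit_or_hym=True),
        SpeciesSpec("V_hymettia", n_samples=n_samples, is_kit_or_hym=True),
    ]
    def L(default):
        return uniform_length if uniform_length is not None else default

    lineages = [
        LineageSpec(
            "tricolor_private",
            divergence=0.10,
            carriers=("V_tricolor",),
            length=L(370),
        ),
        LineageSpec(
            "complex_shared",
            divergence=0.05,
            carriers=("V_tricolor", "V_arvensis", "V_kitaibeliana", "V_hymettia"),
            length=L(340),
        ),
        LineageSpec(
            "arv_kit_hym",
            divergence=0.08,
            carriers=("V_arvensis", "V_kitaibeliana", "V_hymettia"),
            length=L(325),
        ),
        LineageSpec(
            "kit_hym",
            divergence=0.12,
            carriers=("V_kitaibeliana", "V_hymettia"),
            length=L(310),
        ),
    ]
    return CommunityConfig(
        species=species,
        lineages=lineages,
        seed=seed,
        reads_per_sample=reads_per_sample,
        error_rate=error_rate,
        chimera_fraction=chimera_fraction,
    )


# ---------------------------------------------------------------------------
# Plastid simulation


@dataclass
class PlastidConfig:
    """Configured haplotype pool and per-taxon sampling frequencies.

    Two deep lineages are separated by ``deep_split_mutations`` changes
    (> 10 by default, so a mutation cut at 10 recovers them); haplotypes
    within a lineage differ by 1..``max_within_steps`` changes from their
    lineage ancestor.  ``taxa`` maps taxon -> (n individuals, frequency
    vector over the haplotype pool).
    """

    taxa: dict[str, tuple[int, Sequence[float]]]
    n_haplotypes: int
    seed: int
    length: int = 1200
    deep_split_mutations: int = 15
    max_within_steps: int = 3
    second_lineage_haplotypes: int = 0  # how many pool members sit on lineage 2
    indel_events: int = 0
    indel_max_length: int = 4

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        for taxon, (n, freqs) in self.taxa.items():
            if n < 1:
                raise ConfigError(f"taxon {taxon!r}: n must be >= 1")
            if len(freqs) != self.n_haplotypes:
                raise ConfigError(
                    f"taxon {taxon!r}: frequency vector length != n_haplotypes"
                )
            if abs(sum(freqs) - 1.0) > 1e-9 or min(freqs) < 0:
                raise ConfigError(f"taxon {taxon!r}: frequencies must sum to 1")
        if not 0 <= self.second_lineage_haplotypes <= self.n_haplotypes:
            raise ConfigError("second_lineage_haplotypes out of range")


@dataclass
class PlastidData:
    records: list[SequenceRecord]  # aligned individuals
    taxon_of: dict[str, str]
    haplotype_of: dict[str, int]  # individual -> pool index
    pool: list[str]
    lineage_of: list[int]  # pool index -> 1 or 2


def simulate_plastid(config: PlastidConfig) -> PlastidData:
    """Sample aligned individuals from a configured haplotype pool."""
    rng = np.random.default_rng(config.seed)
    ancestor = random_sequence(rng, config.length)
    lineage2_anc = mutate(
        rng, ancestor, 0.0, min_changes=config.deep_split_mutations
    )
    pool: list[str] = []
    lineage_of: list[int] = []
    for h in range(config.n_haplotypes):
        on_second = h < config.second_lineage_haplotypes
        base = lineage2_anc if on_second else ancestor
        steps = int(rng.integers(1, config.max_within_steps + 1))
        seq = mutate(rng, base, 0.0, min_changes=steps)
        while seq in pool:
            seq = mutate(rng, base, 0.0, min_changes=steps)
        pool.append(seq)
        lineage_of.append(2 if on_second else 1)

    if config.indel_events:
        # carve short gap runs into random pool members (aligned: gaps, not
        # length changes), avoiding terminal positions
        for _ in range(config.indel_events):
            h = int(rng.integers(0, len(pool)))
            glen = int(rng.integers(1, config.indel_max_length + 1))
            start = int(rng.integers(1, config.length - glen - 1))
            s = pool[h]
            pool[h] = s[:start] + "-" * glen + s[start + glen :]

    records: list[SequenceRecord] = []
    taxon_of: dict[str, str] = {}
    haplotype_of: dict[str, int] = {}
    for taxon in sorted(config.taxa):
        n, freqs = config.taxa[taxon]
        draws = rng.choice(config.n_haplotypes, size=n, p=np.asarray(freqs, dtype=float))
        for i, h in enumerate(draws):
            ind = f"{taxon}_{i + 1}"
            records.append(SequenceRecord(id=ind, seq=pool[int(h)]))
            taxon_of[ind] = taxon
            haplotype_of[ind] = int(h)
    return PlastidData(
        records=records,
        taxon_of=taxon_of,
        haplotype_of=haplotype_of,
        pool=pool,
        lineage_of=lineage_of,
    )


def simulate_mj_instance(
    seed: int,
    n_observed: int = 6,
    length: int = 100,
    hidden_prob: float = 0.4,
) -> list[str]:
    """A small haplotype set drawn from a random genealogy.

    Haplotypes evolve along a growing random tree; every mutation hits a
    previously unmutated site (the infinite-sites regime that long,
    low-divergence plastid markers approximate).  Some internal haplotypes
    are hidden, leaving Steiner points for the network algorithm to infer.
    Returns the observed haplotypes, sorted.
    """
    rng = np.random.default_rng(seed)
    root = random_sequence(rng, length)
    free_sites = list(range(length))
    rng.shuffle(free_sites)
    pool: list[str] = [root]
    observed: list[str] = []
    while len(observed) < n_observed:
        parent = pool[int(rng.integers(0, len(pool)))]
        n_mut = int(rng.integers(1, 4))
        if n_mut > len(free_sites):
            break
        arr = np.frombuffer(parent.encode(), dtype=np.uint8).copy()
        for _ in range(n_mut):
            site = free_sites.pop()
            idx = _BASE_INDEX[arr[site]]
            arr[site] = _BASES[(idx + int(rng.integers(1, 4))) % 4]
        child = arr.tobytes().decode()
        pool.append(child)
        if rng.random() >= hidden_prob or len(pool) <= 2:
            observed.append(child)
    return sorted(set(observed))


# ---------------------------------------------------------------------------
# Synthetic per-sample variant trees (for the cluster counter)


def simulate_sample_tree(
    n_lineages: int,
    tips_per_lineage: int,
    seed: int,
    length: int = 600,
    between_divergence: float = 0.12,
    within_divergence: float = 0.01,
    bootstrap_reps: int = 50,
):
    """Build a support-annotated neighbour-joining tree from simulated
    variants of ``n_lineages`` well-separated lineages.

    Returns (dendropy tree with bootstrap supports as internal labels,
    mapping tip label -> true lineage index).  Supports are classic
    nonparametric bootstrap proportions over resampled alignment columns.
    """
    import dendropy
    from io import StringIO
    from skbio import DistanceMatrix
    from skbio.tree import nj

    rng = np.random.default_rng(seed)
    root = random_sequence(rng, length)
    seqs: list[str] = []
    names: list[str] = []
    lineage_of_tip: dict[str, int] = {}
    for l in range(n_lineages):
        anc = mutate(rng, root, between_divergence, min_changes=5)
        for t in range(tips_per_lineage):
            name = f"L{l + 1}t{t + 1}"
            seqs.append(mutate(rng, anc, within_divergence, min_changes=1))
            names.append(name)
            lineage_of_tip[name] = l
    mat = np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])

    def nj_tree(cols: np.ndarray | None) -> str:
        m = mat if cols is None else mat[:, cols]
        d = (m[:, None, :] != m[None, :, :]).mean(axis=2)
        np.fill_diagonal(d, 0.0)
        buf = StringIO()
        nj(DistanceMatrix(d, ids=names)).write(buf)
        return buf.getvalue()

    def to_tree(newick: str, taxa) -> "dendropy.Tree":
        return dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            taxon_namespace=taxa,
        )

    taxa = dendropy.TaxonNamespace()
    main = to_tree(nj_tree(None), taxa)
    main.encode_bipartitions()
    counts = {b.split_bitmask: 0 for b in main.bipartition_encoding}
    for _ in range(bootstrap_reps):
        cols = rng.integers(0, mat.shape[1], size=mat.shape[1])
        rep = to_tree(nj_tree(cols), taxa)
        rep.encode_bipartitions()
        rep_masks = {b.split_bitmask for b in rep.bipartition_encoding}
        for mask in counts:
            if mask in rep_masks:
                counts[mask] += 1
    for node in main.preorder_node_iter():
        if not node.is_leaf() and node.edge.bipartition is not None:
            pct = 100.0 * counts.get(node.edge.bipartition.split_bitmask, 0) / bootstrap_reps
            node.label = f"{pct:.0f}"
    return main, lineage_of_tip
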