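"""Paired-read preprocessing: merge, dereplicate, chimera-flag, filter.

The chain turns per-sample paired FASTQ reads into a filtered table of
unique amplicon variants by sample:

1.  :func:`merge_pair` assembles each read pair into a contig.  Overlap is
    found on ungapped offsets; disagreeing bases in the overlap are resolved
    by the quality difference (dQ) rule: the base whose Phred score exceeds
    the other's by at least ``dq_threshold`` wins, otherwise the position
    becomes 'N'.  Contigs with too many 'N' (default: any) are rejected.
2.  :func:`dereplicate` collapses contigs by exact string identity into a
    :class:`VariantTable` (variant x sample read counts).
3.  :func:`flag_chimeras` marks variants explainable as a single-crossover
    recombinant of two more-abundant variants.  This is a deliberate,
    transparent simplification of de-novo chimera scoring: a candidate is
    flagged when some left-parent prefix + right-parent suffix explains it
    with at least ``min_improvement`` fewer mismatches than the best single
    parent does, with both parents contributing diagnostic sites.
4.  :func:`filter_variants` applies the dataset-wide abundance and minimum
    length thresholds and reports what each criterion removed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import edlib

from .errors import IgsflowError
from .seqio import SequenceRecord, reverse_complement


@dataclass(frozen=True)
class MergeParams:
    """Knobs of the pair-merging step.

    dq_threshold: minimum Phred difference for resolving a disagreement in
        favour of the higher-quality base (conventional contig-making value).
    min_overlap: minimum number of aligned bases for an accepted offset.
    max_n_fraction: contigs whose 'N' fraction exceeds this are rejected;
        the default 0.0 discards any contig containing an 'N'.
    """

    dq_threshold: int = 6
    min_overlap: int = 20
    max_n_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.dq_threshold < 0:
            raise ValueError("dq_threshold must be >= 0")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.max_n_fraction <= 1.0:
            raise ValueError("max_n_fraction must be in [0, 1]")


def _best_offset_scan(s1: str, s2: str, min_overlap: int) -> tuple[int | None, int]:
    """Exhaustive ungapped-offset scan.

    Returns (offset, n_matches) maximising matches over offsets where the
    reverse-complemented mate starts at position ``offset`` of read 1 and the
    overlap spans at least ``min_overlap`` bases.  Ties resolve to the
    smallest offset (longest contig is the largest offset; the smallest
    offset is the most conservative overlap claim — deterministic either
    way, smallest keeps the scan order natural).
    """
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    best: tuple[int | None, int] = (None, -1)
    for off in range(0, len(s1) - min_overlap + 1):
        k = min(len(s1) - off, len(s2))
        if k < min_overlap:
            break
        matches = int(np.count_nonzero(a1[off : off + k] == a2[:k]))
        if matches > best[1]:
            best = (off, matches)
    return best


_SEED_LEN = 24
#: A seeded offset is trusted when at most this fraction of overlap bases
#: mismatch; otherwise the exhaustive scan decides.
_SEED_MAX_MISMATCH_FRAC = 0.05


def _find_offset(s1: str, s2: str, min_overlap: int) -> int | None:
    """Locate the merge offset: seed-and-verify first, full scan as fallback."""
    for seed_start in (0, _SEED_LEN, 2 * _SEED_LEN):
        if seed_start + _SEED_LEN > len(s2):
            break
        seed = s2[seed_start : seed_start + _SEED_LEN]
        pos = s1.find(seed)
        if pos < 0:
            continue
        off = pos - seed_start
        if off < 0:
            continue
        k = min(len(s1) - off, len(s2))
        if k < min_overlap:
            continue
        if s1[off : off + k] == s2[:k]:
            return off
        a = np.frombuffer(s1[off : off + k].encode(), dtype=np.uint8)
        b = np.frombuffer(s2[:k].encode(), dtype=np.uint8)
        if int(np.count_nonzero(a != b)) <= max(1.0, _SEED_MAX_MISMATCH_FRAC * k):
            return off
    off, matches = _best_offset_scan(s1, s2, min_overlap)
    if off is None:
        return None
    k = min(len(s1) - off, len(s2))
    # demand a credible overlap, not just the least-bad offset
    if matches < 0.6 * k:
        return None
    return off


def merge_pair(
    r1: SequenceRecord,
    r2: SequenceRecord,
    params: MergeParams = MergeParams(),
    with_quals: bool = True,
) -> SequenceRecord | None:
    """Assemble a read pair into a contig, or return None on rejection.

    The mate is reverse-complemented, the overlap offset located by
    maximising ungapped matches, and overlap bases resolved by the dQ rule.
    ``with_quals=False`` skips assembling the merged quality string (the
    dereplication stage needs only sequences); base resolution is identical.
    """
    if r1.quals is None or r2.quals is None:
        raise IgsflowError("merge_pair requires quality scores on both reads")
    s2 = reverse_complement(r2.seq)
    q2 = r2.quals[::-1]
    s1, q1 = r1.seq, r1.quals

    off = _find_offset(s1, s2, params.min_overlap)
    if off is None:
        return None

    k = min(len(s1) - off, len(s2))
    head = s1[:off]
    tail = s2[k:]
    if len(s1) > off + len(s2):  # mate fully contained in read 1
        tail = s1[off + len(s2):]

    o1, o2 = s1[off : off + k], s2[:k]
    if o1 == o2:
        mid = o1
        mid_src = None  # all agree
    else:
        a = np.frombuffer(o1.encode(), dtype=np.uint8)
        b = np.frombuffer(o2.encode(), dtype=np.uint8)
        mismatch_at = np.nonzero(a != b)[0]
        buf = bytearray(o1.encode())
        mid_src = {}
        for i in map(int, mismatch_at):
            qa, qb = q1[off + i], q2[i]
            if qa - qb >= params.dq_threshold:
                pass  # keep read-1 base
            elif qb - qa >= params.dq_threshold:
                buf[i] = ord(o2[i])
                mid_src[i] = "r2"
            else:
                buf[i] = ord("N")
                mid_src[i] = "N"
        mid = buf.decode()

    seq = head + mid + tail
    if seq.count("N") > params.max_n_fraction * len(seq):
        return None

    quals = None
    if with_quals:
        qa = np.asarray(q1[off : off + k], dtype=np.int16)
        qb = np.asarray(q2[:k], dtype=np.int16)
        mq = np.maximum(qa, qb)
        if mid_src:
            for i, src in mid_src.items():
                mq[i] = qb[i] if src == "r2" else min(qa[i], qb[i])
            # positions kept from read 1 on a disagreement carry read 1's score
            for i in map(int, mismatch_at):
                if i not in mid_src:
                    mq[i] = qa[i]
        head_q = q1[:off]
        if len(s1) > off + len(s2):
            tail_q = q1[off + len(s2):]
        else:
            tail_q = q2[k:]
        quals = (
            tuple(head_q) + tuple(int(x) for x in mq) + tuple(tail_q)
        )
    return SequenceRecord(id=r1.id, seq=seq, quals=quals)


@dataclass
class MergeStats:
    n_pairs: int = 0
    n_merged: int = 0

    @property
    def n_rejected(self) -> int:
        return self.n_pairs - self.n_merged


def merge_sample(
    pairs: Iterable[tuple[SequenceRecord, SequenceRecord]],
    params: MergeParams = MergeParams(),
) -> tuple[list[str], MergeStats]:
    """Merge every pair of one sample; returns contig strings + stats."""
    stats = MergeStats()
    contigs: list[str] = []
    for r1, r2 in pairs:
        stats.n_pairs += 1
        merged = merge_pair(r1, r2, params, with_quals=False)
        if merged is not None:
            stats.n_merged += 1
            contigs.append(merged.seq)
    return contigs, stats


# ---------------------------------------------------------------------------
# Variant table


@dataclass
class VariantTable:
    """Unique amplicon variants x samples read-count matrix.

    Variants are exact strings (no reverse-complement collapsing: a single
    primer pair fixes orientation).  Rows are ordered by decreasing total
    abundance, ties broken lexicographically, which also fixes variant ids.
    """

    variants: list[str]
    samples: list[str]
    counts: np.ndarray  # shape (n_variants, n_samples), int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.variants), len(self.samples)):
            raise IgsflowError("counts shape does not match variants x samples")
        if len(set(self.variants)) != len(self.variants):
            raise IgsflowError("variants must be unique")
        if np.any(self.counts < 0):
            raise IgsflowError("negative abundance")
        if len(self.variants) and np.any(self.counts.sum(axis=1) == 0):
            raise IgsflowError("variant with all-zero abundance row")

    @classmethod
    def from_contigs(cls, contigs_by_sample: Mapping[str, Iterable[str]]) -> "VariantTable":
        samples = list(contigs_by_sample)
        counters = {s: Counter(contigs_by_sample[s]) for s in samples}
        all_variants = set()
        for c in counters.values():
            all_variants.update(c)
        totals = {
            v: sum(counters[s].get(v, 0) for s in samples) for v in all_variants
        }
        variants = sorted(all_variants, key=lambda v: (-totals[v], v))
        counts = np.zeros((len(variants), len(samples)), dtype=np.int64)
        for j, s in enumerate(samples):
            for i, v in enumerate(variants):
                c = counters[s].get(v)
                if c:
                    counts[i, j] = c
        return cls(variants=variants, samples=samples, counts=counts)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(v) for v in self.variants])

    def variant_id(self, i: int) -> str:
        return f"var{i + 1:05d};size={int(self.totals[i])}"

    def row(self, variant: str) -> np.ndarray:
        return self.counts[self.variants.index(variant)]

    def subset(self, keep: Sequence[int]) -> "VariantTable":
        keep = list(keep)
        return VariantTable(
            variants=[self.variants[i] for i in keep],
            samples=list(self.samples),
            counts=self.counts[keep, :].copy(),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.counts,
            index=[self.variant_id(i) for i in range(self.n_variants)],
            columns=self.samples,
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("variant_id\tsequence\t" + "\t".join(self.samples) + "\n")
            for i, v in enumerate(self.variants):
                row = "\t".join(str(int(c)) for c in self.counts[i])
                fh.write(f"{self.variant_id(i)}\t{v}\t{row}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "VariantTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            samples = header[2:]
            variants, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                variants.append(parts[1])
                rows.append([int(x) for x in parts[2:]])
        counts = np.array(rows, dtype=np.int64) if rows else np.zeros((0, len(samples)), dtype=np.int64)
        return cls(variants=variants, samples=samples, counts=counts)

    def write_fasta(self, path: str | Path) -> None:
        from .seqio import write_fasta, SequenceRecord as SR

        write_fasta(
            (SR(id=self.variant_id(i), seq=v) for i, v in enumerate(self.variants)),
            path,
        )


def dereplicate(contigs_by_sample: Mapping[str, Iterable[str]]) -> VariantTable:
    """Collapse contigs per sample by exact identity into a VariantTable."""
    return VariantTable.from_contigs(contigs_by_sample)


# ---------------------------------------------------------------------------
# Chimera flagging

import re

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


def _mismatch_profile(candidate: str, parent: str) -> np.ndarray:
    """Per-candidate-position mismatch costs of a global alignment to parent.

    The vector sums to the edit distance; insertions/deletions are charged
    to the candidate position at which they occur (clamped to the last
    position for trailing target overhang).
    """
    res = edlib.align(candidate, parent, mode="NW", task="path")
    profile = np.zeros(len(candidate), dtype=np.int32)
    i = 0  # candidate cursor
    for n_str, ch in _CIGAR_RE.findall(res["cigar"]):
        n = int(n_str)
        if ch == "=":
            i += n
        elif ch == "X":
            profile[i : i + n] += 1
            i += n
        elif ch == "I":  # candidate bases absent from parent
            profile[i : i + n] += 1
            i += n
        elif ch == "D":  # parent bases absent from candidate
            profile[min(i, len(candidate) - 1)] += n
    return profile


@dataclass
class ChimeraHit:
    candidate: int
    left_parent: int
    right_parent: int
    crossover: int
    improvement: int


def flag_chimeras(
    table: VariantTable,
    skew: float = 2.0,
    min_improvement: int = 3,
    max_parents: int = 30,
    min_candidate_abundance: int = 2,
    max_model_dissimilarity: float = 0.02,
) -> list[ChimeraHit]:
    """Flag variants explainable as two-parent single-crossover recombinants.

    Candidates are scanned in decreasing total abundance.  Eligible parents
    are unflagged variants with total abundance >= ``skew`` times the
    candidate's.  A candidate is flagged when the best prefix+suffix model
    (a) beats the best single parent by >= ``min_improvement`` mismatches,
    (b) leaves at most ``max(2, max_model_dissimilarity * len)`` residual
    mismatches — a chimera is essentially *explained* by its parents, which
    screens out chance crossover gains between unrelated sequences — and
    (c) draws at least one diagnostic site from each parent segment.

    Candidates below ``min_candidate_abundance`` total reads are not
    examined: they can never act as parents and are removed by any
    downstream abundance filter regardless.
    Returns hits in candidate-scan order; flagged indices are
    ``{h.candidate for h in hits}``.
    """
    totals = table.totals
    order = sorted(range(table.n_variants), key=lambda i: (-totals[i], table.variants[i]))
    flagged: set[int] = set()
    hits: list[ChimeraHit] = []
    for idx in order:
        if totals[idx] < min_candidate_abundance:
            continue
        cand = table.variants[idx]
        eligible = [
            j
            for j in order
            if j != idx and j not in flagged and totals[j] >= skew * totals[idx]
        ]
        if len(eligible) < 2:
            continue
        eligible = eligible[:max_parents]
        L = len(cand)
        profiles = np.vstack([_mismatch_profile(cand, table.variants[j]) for j in eligible])
        cums = np.concatenate(
            [np.zeros((len(eligible), 1), dtype=np.int64), np.cumsum(profiles, axis=1)],
            axis=1,
        )  # cums[p, k] = mismatches of parent p on cand[:k]
        parent_tot = cums[:, -1]
        best_single = int(parent_tot.min())
        # cheap screen: the best conceivable crossover mixes the per-point
        # minima over all parents; if even that cannot improve enough, the
        # expensive pair scan is pointless
        ks = np.arange(1, L)
        max_resid = max(2.0, max_model_dissimilarity * L)
        left_min = cums[:, ks].min(axis=0)
        right_min = (parent_tot[:, None] - cums[:, ks]).min(axis=0)
        best_possible = int((left_min + right_min).min())
        if best_single - best_possible < min_improvement or best_possible > max_resid:
            continue
        best_hit = None
        for a in range(len(eligible)):
            la = cums[a, ks]
            for b in range(len(eligible)):
                if a == b:
                    continue
                rb = parent_tot[b] - cums[b, ks]
                tot = la + rb
                k_best = int(np.argmin(tot))
                score = int(tot[k_best])
                improvement = best_single - score
                if improvement < min_improvement or score > max_resid:
                    continue
                k = int(ks[k_best])
                # each segment must carry >=1 diagnostic site
                if cums[b, k] - cums[a, k] < 1:
                    continue
                if (parent_tot[a] - cums[a, k]) - (parent_tot[b] - cums[b, k]) < 1:
                    continue
                if best_hit is None or improvement > best_hit.improvement:
                    best_hit = ChimeraHit(idx, eligible[a], eligible[b], k, improvement)
        if best_hit is not None:
            flagged.add(idx)
            hits.append(best_hit)
    return hits


def remove_chimeras(
    table: VariantTable, skew: float = 2.0, min_improvement: int = 3
) -> tuple[VariantTable, list[ChimeraHit]]:
    hits = flag_chimeras(table, skew=skew, min_improvement=min_improvement)
    bad = {h.candidate for h in hits}
    keep = [i for i in range(table.n_variants) if i not in bad]
    return table.subset(keep), hits


# ---------------------------------------------------------------------------
# Abundance / length filtering


@dataclass
class FilterReport:
    n_input: int = 0
    removed_by_abundance: int = 0
    removed_by_length: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_input - self.removed_by_abundance - self.removed_by_length


def filter_variants(
    table: VariantTable,
    min_total_abundance: int = 5,
    min_length: int | None = None,
) -> tuple[VariantTable, FilterReport]:
    """Keep variants with dataset-wide total abundance >= threshold (inclusive)
    and, if requested, length >= ``min_length``.

    Each removed variant is attributed to exactly one criterion, abundance
    first (a short, rare variant counts as an abundance removal).
    """
    if min_total_abundance < 0 or (min_length is not None and min_length < 0):
        raise ValueError("thresholds must be >= 0")
    report = FilterReport(n_input=table.n_variants)
    totals = table.totals
    lengths = table.lengths
    keep = []
    for i in range(table.n_variants):
        if totals[i] < min_total_abundance:
            report.removed_by_abundance += 1
        elif min_length is not None and lengths[i] < min_length:
            report.removed_by_length += 1
        else:
            keep.append(i)
    return table.subset(keep), report
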