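"""Pair merging, dereplication, chimera flagging and variant filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igsflow import (
    MergeParams,
    VariantTable,
    dereplicate,
    filter_variants,
    flag_chimeras,
    merge_pair,
    merge_sample,
    SequenceRecord,
)
from igsflow.seqio import reverse_complement
from igsflow.simulate import simulate_community, tricolor_complex_config


def _pair(seq1, seq2_fwd, q1=None, q2=None):
    """Build a read pair where read 2 covers ``seq2_fwd`` in reverse."""
    q1 = q1 or tuple([35] * len(seq1))
    q2 = q2 or tuple([35] * len(seq2_fwd))
    r1 = SequenceRecord("p/1", seq1, tuple(q1))
    r2 = SequenceRecord("p/2", reverse_complement(seq2_fwd), tuple(q2)[::-1])
    return r1, r2


AMPLICON = "ACGTAGGCTTACGATCGATCGGATCCATAG"  # 30 bp


class TestMergePair:
    def test_identical_full_overlap(self):
        r1, r2 = _pair(AMPLICON, AMPLICON)
        merged = merge_pair(r1, r2)
        assert merged.seq == AMPLICON
        assert "N" not in merged.seq

    def test_partial_overlap_contig(self):
        # r1 covers [0:25], r2 covers [5:30]: contig is the full amplicon
        r1, r2 = _pair(AMPLICON[:25], AMPLICON[5:])
        merged = merge_pair(r1, r2)
        assert merged.seq == AMPLICON

    def test_dq_rule_keeps_higher_quality_base(self):
        # disagreement at position 10, quals 30 vs 20 (delta 10 >= 6)
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}[AMPLICON[10]]
        seq2 = AMPLICON[:10] + flip + AMPLICON[11:]
        q1 = [30] * 30
        q2 = [20] * 30
        r1, r2 = _pair(AMPLICON, seq2, q1, q2)
        merged = merge_pair(r1, r2)
        assert merged.seq == AMPLICON
        assert merged.quals[10] == 30

    def test_dq_rule_subthreshold_gives_n_and_rejection(self):
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}[AMPLICON[10]]
        seq2 = AMPLICON[:10] + flip + AMPLICON[11:]
        q1 = [22] * 30
        q2 = [20] * 30
        r1, r2 = _pair(AMPLICON, seq2, q1, q2)
        # delta 2 < 6: N at the site; default max_n_fraction 0 rejects
        assert merge_pair(r1, r2) is None
        # but a permissive N budget keeps the contig with the N
        merged = merge_pair(r1, r2, MergeParams(max_n_fraction=0.5))
        assert merged.seq[10] == "N"

    def test_no_overlap_rejected(self):
        r1, r2 = _pair("ACGTACGTACGTACGTACGTAC", "GGGTTTCCCAAAGGGTTTCCCA")
        assert merge_pair(r1, r2) is None

    def test_min_overlap_enforced(self):
        # true overlap of 5 bases < min_overlap 20
        r1, r2 = _pair(AMPLICON[:18], AMPLICON[13:])
        assert merge_pair(r1, r2, MergeParams(min_overlap=20)) is None


class TestDereplicate:
    def test_counts_per_sample(self):
        table = dereplicate({"S1": ["AAA", "AAA", "AAT"]})
        assert table.n_variants == 2
        assert table.row("AAA").tolist() == [2]
        assert table.row("AAT").tolist() == [1]

    def test_identity_collapse_across_samples(self):
        table = dereplicate({"S1": ["AAA"], "S2": ["AAA"]})
        assert table.n_variants == 1
        assert table.row("AAA").tolist() == [1, 1]

    def test_no_reverse_complement_collapsing(self):
        table = dereplicate({"S1": ["AAA", "TTT"]})
        assert table.n_variants == 2

    def test_empty_input(self):
        assert dereplicate({}).n_variants == 0
        assert dereplicate({"S1": []}).n_variants == 0

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(st.text(alphabet="ACGT", min_size=1, max_size=8), max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_order_independent_and_idempotent(self, reads, rnd):
        table = dereplicate({"S": reads})
        shuffled = list(reads)
        rnd.shuffle(shuffled)
        table2 = dereplicate({"S": shuffled})
        assert table.variants == table2.variants
        assert np.array_equal(table.counts, table2.counts)
        # re-dereplicating the unique variants once each yields each once
        table3 = dereplicate({"S": table.variants})
        assert sorted(table3.variants) == sorted(table.variants)
        assert table3.totals.sum() == table3.n_variants

    def test_read_conservation_through_merge_chain(self):
        config = tricolor_complex_config(seed=11, reads_per_sample=300)
        data = simulate_community(config)
        total_pairs = merged = 0
        contigs = {}
        for sample, pairs in data.pairs.items():
            contigs[sample], stats = merge_sample(pairs)
            total_pairs += stats.n_pairs
            merged += stats.n_merged
        table = dereplicate(contigs)
        assert total_pairs == sum(len(p) for p in data.pairs.values())
        assert int(table.totals.sum()) == merged
        assert merged + (total_pairs - merged) == total_pairs


def _table(rows: dict[str, list[int]]) -> VariantTable:
    samples = [f"S{i+1}" for i in range(len(next(iter(rows.values()))))]
    variants = sorted(rows, key=lambda v: (-sum(rows[v]), v))
    counts = np.array([rows[v] for v in variants], dtype=np.int64)
    return VariantTable(variants=variants, samples=samples, counts=counts)


class TestFlagChimeras:
    def _chimera_setup(self, rng, n_chim=10, parent_abundance=1000):
        bases = "ACGT"
        p1 = "".join(rng.choice(list(bases)) for _ in range(120))
        # second parent differs at ~20% of sites: many diagnostic positions
        p2 = "".join(
            bases[(bases.index(c) + 1) % 4] if rng.random() < 0.2 else c for c in p1
        )
        rows = {p1: [parent_abundance], p2: [parent_abundance]}
        chimeras = []
        for i in range(n_chim):
            k = int(30 + i * 6)
            c = p1[:k] + p2[k:]
            if c not in rows:
                rows[c] = [parent_abundance // 10]
                chimeras.append(c)
        # unrelated clean variants at similar abundance
        clean = []
        for _ in range(10):
            v = "".join(rng.choice(list(bases)) for _ in range(120))
            rows[v] = [parent_abundance // 10]
            clean.append(v)
        return _table(rows), chimeras, clean

    def test_constructed_crossover_flagged(self):
        # explicit mid-point crossover: >= 3 diagnostic sites on each side
        import random

        rng = random.Random(1)
        bases = "ACGT"
        p1 = "".join(rng.choice(bases) for _ in range(120))
        p2 = "".join(
            bases[(bases.index(c) + 1) % 4] if rng.random() < 0.2 else c for c in p1
        )
        chim = p1[:60] + p2[60:]
        table = _table({p1: [1000], p2: [1000], chim: [100]})
        hits = flag_chimeras(table)
        flagged = {table.variants[h.candidate] for h in hits}
        assert flagged == {chim}
        hit = hits[0]
        # oracle: exhaustive crossover-point scan over the two parents
        diffs1 = [i for i in range(120) if chim[i] != p1[i]]
        diffs2 = [i for i in range(120) if chim[i] != p2[i]]
        best = min(
            sum(1 for i in diffs1 if i < k) + sum(1 for i in diffs2 if i >= k)
            for k in range(1, 120)
        )
        assert best == 0  # the model reconstructs the chimera exactly
        assert len(diffs1) >= 3 and len(diffs2) >= 3
        # edit-distance improvement can undercut positional hamming slightly
        assert 3 <= hit.improvement <= min(len(diffs1), len(diffs2))
        assert {hit.left_parent, hit.right_parent} == {
            table.variants.index(p1),
            table.variants.index(p2),
        }

    def test_recall_and_false_positive_rate(self):
        import random

        table, chimeras, clean = self._chimera_setup(random.Random(7))
        flagged = {table.variants[h.candidate] for h in flag_chimeras(table)}
        recall = len(flagged & set(chimeras)) / len(chimeras)
        fpr = len(flagged & set(clean)) / len(clean)
        assert recall >= 0.9
        assert fpr <= 0.05

    def test_candidate_identical_to_parent_not_flagged(self):
        table = _table({"AAAACCCC": [100], "AAAATTTT": [100], "AAAACCCA": [10]})
        flagged = {table.variants[h.candidate] for h in flag_chimeras(table)}
        assert "AAAACCCC" not in flagged

    def test_most_abundant_variant_has_no_parents(self):
        table = _table({"AAAACCCC": [100], "CCCCAAAA": [40], "GGGGTTTT": [40]})
        flagged = {table.variants[h.candidate] for h in flag_chimeras(table)}
        assert "AAAACCCC" not in flagged

    def test_clean_error_free_community_flags_nothing(self):
        config = tricolor_complex_config(
            seed=13, reads_per_sample=1500, error_rate=0.0, chimera_fraction=0.0
        )
        data = simulate_community(config)
        contigs = {s: merge_sample(p)[0] for s, p in data.pairs.items()}
        table = dereplicate(contigs)
        assert flag_chimeras(table) == []


class TestFilterVariants:
    def test_abundance_threshold_inclusive(self):
        table = _table({"AAA": [5], "CCC": [4], "GGG": [25]})
        kept, report = filter_variants(table, min_total_abundance=5)
        assert kept.n_variants == 2
        assert report.removed_by_abundance == 1

    def test_length_threshold(self):
        table = _table({"A" * 279: [30], "C" * 280: [30]})
        kept, report = filter_variants(table, 5, min_length=280)
        assert kept.variants == ["C" * 280]
        assert report.removed_by_length == 1

    def test_no_thresholds_is_identity(self):
        table = _table({"AAA": [1], "CCC": [2]})
        kept, report = filter_variants(table, 0, None)
        assert kept.variants == table.variants
        assert report.removed_by_abundance == report.removed_by_length == 0

    def test_fixture_bookkeeping(self, filter_fixture_path, filter_fixture_expected):
        table = VariantTable.read_tsv(filter_fixture_path)
        exp = filter_fixture_expected
        assert table.n_variants == exp["n_variants"]
        kept5, rep5 = filter_variants(table, 5)
        assert rep5.removed_by_abundance == exp["removed_abundance_lt5"]
        assert kept5.n_variants == exp["kept_abundance_ge5"]
        kept25, rep25 = filter_variants(table, 25, min_length=280)
        assert rep25.removed_by_abundance == exp["removed_abundance_lt25"]
        assert rep25.removed_by_length == exp["removed_short_at_ab25"]
        assert kept25.n_variants == exp["kept_ab25_len280"]
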