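"""The synthetic community and plastid generators and their ground truth."""

import numpy as np
import pytest

import igsflow as ig
from igsflow import (
    ClassLabel,
    CommunityConfig,
    Kind,
    LineageSpec,
    PlastidConfig,
    SpeciesSpec,
    collapse_haplotypes,
    mj_network,
    simulate_community,
    simulate_plastid,
)
from igsflow.errors import ConfigError
from igsflow.preprocess import dereplicate, filter_variants, merge_sample
from igsflow.simulate import tricolor_complex_config


def small_config(seed, **kw):
    defaults = dict(reads_per_sample=1200, error_rate=0.0, chimera_fraction=0.0)
    defaults.update(kw)
    return tricolor_complex_config(seed=seed, **defaults)


class TestConfigValidation:
    def test_species_without_lineage_rejected(self):
        with pytest.raises(ConfigError, match="carries no lineage"):
            CommunityConfig(
                species=[SpeciesSpec("A"), SpeciesSpec("B")],
                lineages=[LineageSpec("l1", 0.05, carriers=("A",))],
                seed=1,
            )

    def test_unknown_carrier_rejected(self):
        with pytest.raises(ConfigError, match="unknown carriers"):
            CommunityConfig(
                species=[SpeciesSpec("A")],
                lineages=[LineageSpec("l1", 0.05, carriers=("A", "X"))],
                seed=1,
            )

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            tricolor_complex_config(seed=1, error_rate=1.5)

    def test_non_overlapping_reads_rejected(self):
        with pytest.raises(ConfigError, match="overlap"):
            CommunityConfig(
                species=[SpeciesSpec("A")],
                lineages=[LineageSpec("l1", 0.05, carriers=("A",))],
                seed=1,
                read_length=100,
                length_range=(250, 300),
            )


class TestCommunityTruth:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        for d in ("one", "two"):
            simulate_community(small_config(77)).write_fastq_dir(tmp_path / d)
        for f in sorted((tmp_path / "one").iterdir()):
            assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes()

    def test_private_lineage_truth_is_specific(self):
        data = simulate_community(small_config(3))
        truth = data.truth
        found = 0
        for seq, tv in truth.variants.items():
            if tv.lineage == "tricolor_private":
                assert truth.true_label(seq) is not None
                if len(set(tv.carrier_samples)) > 1:
                    assert truth.true_label(seq) == ClassLabel(
                        Kind.SPECIFIC, "V_tricolor"
                    )
                    found += 1
        assert found > 0

    def test_kit_hym_lineage_truth(self):
        truth = simulate_community(small_config(3)).truth
        labels = {
            truth.true_label(seq)
            for seq, tv in truth.variants.items()
            if tv.lineage == "kit_hym" and len(tv.carrier_samples) > 2
        }
        assert labels == {ClassLabel(Kind.AMBIGUOUS, "kit_hym")}

    def test_local_variants_are_single_sample(self):
        truth = simulate_community(small_config(9)).truth
        locals_ = [
            (seq, tv)
            for seq, tv in truth.variants.items()
            if not tv.is_chimera and len(tv.carrier_samples) == 1
        ]
        assert locals_
        for seq, tv in locals_:
            label = truth.true_label(seq)
            assert label.kind is Kind.LOCAL
            assert label.detail == tv.carrier_samples[0]

    def test_chimeras_have_no_true_class_and_are_tagged(self):
        data = simulate_community(small_config(5, chimera_fraction=0.05))
        truth = data.truth
        chimeric = [seq for seq, tv in truth.variants.items() if tv.is_chimera]
        assert chimeric
        for seq in chimeric:
            assert truth.true_label(seq) is None
        # read ids carry the chimera tag for read-level traceability
        tagged = {
            rid.rsplit(".", 1)[-1].split("/")[0]
            for pairs in data.pairs.values()
            for r1, _ in pairs
            for rid in [r1.id]
        }
        assert tagged == {"C", "V"}

    def test_truth_covers_every_emitted_read(self):
        data = simulate_community(small_config(2))
        for sample, pairs in data.pairs.items():
            assert len(pairs) == data.truth.n_reads(sample)
        assert data.truth.n_reads() == sum(len(p) for p in data.pairs.values())

    def test_true_compositions_rows_sum_to_one(self):
        comp = simulate_community(small_config(4)).truth.true_compositions()
        assert np.allclose(comp.sum(axis=1), 1.0)


class TestClassRecoveryNoError:
    def test_error_free_classes_recovered(self):
        """With no sequencing error or chimeras, the pipeline's classes match
        ground truth for nearly all retained variants."""
        data = simulate_community(small_config(21))
        contigs = {s: merge_sample(p)[0] for s, p in data.pairs.items()}
        table, _ = filter_variants(dereplicate(contigs), 5)
        labels = ig.assign_all(table, data.truth.manifest)
        ok = total = 0
        for i, v in enumerate(table.variants):
            want = data.truth.true_label(v)
            if want is None:
                continue
            total += 1
            ok += labels[i] == want
        assert total >= 20
        assert ok / total >= 0.95


class TestIntragenomicRecovery:
    def test_divergence_estimate_tracks_configuration(self):
        """Mean intra-sample divergence of equal-length simulated variants
        falls within 15% of the divergence implied by the generator's own
        templates for that sample."""
        config = small_config(31, uniform_length=340)
        data = simulate_community(config)
        contigs = {s: merge_sample(p)[0] for s, p in data.pairs.items()}
        table, _ = filter_variants(dereplicate(contigs), 5)
        sample = data.truth.manifest.sample_ids[0]
        j = table.samples.index(sample)
        variants = [
            ig.SequenceRecord(f"v{i}", v)
            for i, v in enumerate(table.variants)
            if table.counts[i, j] > 0
        ]
        d, _ = ig.intragenomic_divergence(variants, bootstrap_reps=0)
        # expectation from the templates the sample actually carries
        truth_variants = [
            seq
            for seq, tv in data.truth.variants.items()
            if sample in tv.carrier_samples and not tv.is_chimera
        ]
        exp, _ = ig.intragenomic_divergence(
            [ig.SequenceRecord(f"t{i}", s) for i, s in enumerate(truth_variants)],
            bootstrap_reps=0,
        )
        assert d == pytest.approx(exp, rel=0.15)


class TestPlastid:
    def cfg(self, seed=1, **kw):
        defaults = dict(
            taxa={
                "A": (9, [0.6, 0.4, 0.0, 0.0]),
                "B": (6, [0.0, 0.5, 0.3, 0.2]),
            },
            n_haplotypes=4,
            second_lineage_haplotypes=2,
            seed=seed,
        )
        defaults.update(kw)
        return PlastidConfig(**defaults)

    def test_no_sharing_gives_zero_h_sh(self):
        cfg = self.cfg(
            taxa={"A": (5, [0.5, 0.5, 0, 0]), "B": (5, [0, 0, 0.5, 0.5])}
        )
        data = simulate_plastid(cfg)
        hs = collapse_haplotypes(data.records, data.taxon_of)
        assert hs.h_sh("A") == 0 and hs.h_sh("B") == 0

    def test_shared_haplotype_reported_for_both_taxa(self):
        cfg = self.cfg(
            taxa={"A": (9, [1.0, 0, 0, 0]), "B": (6, [1.0, 0, 0, 0])}
        )
        data = simulate_plastid(cfg)
        hs = collapse_haplotypes(data.records, data.taxon_of)
        assert hs.h_sh("A") == 1 and hs.h_sh("B") == 1
        assert hs.h_tot("A") == hs.h_tot("B") == 1

    def test_deep_lineages_recovered_by_network_cut(self):
        cfg = self.cfg(
            taxa={
                "A": (8, [0.5, 0.5, 0.0, 0.0]),
                "B": (8, [0.0, 0.0, 0.5, 0.5]),
            }
        )
        data = simulate_plastid(cfg)
        hs = collapse_haplotypes(data.records, data.taxon_of)
        net = mj_network(hs)
        groups = net.lineage_groups(cut=10)
        assert len(groups) == 2

    def test_hd_matches_analytic_expectation(self):
        """E[Hd] over multinomial sampling equals 1 - sum(p^2) exactly;
        200 replicates stay within 3 Monte-Carlo standard errors."""
        freqs = [0.5, 0.3, 0.2, 0.0]
        n = 12
        expected = 1.0 - sum(p * p for p in freqs)
        vals = []
        for rep in range(200):
            cfg = self.cfg(seed=1000 + rep, taxa={"A": (n, freqs)})
            data = simulate_plastid(cfg)
            hs = collapse_haplotypes(data.records, data.taxon_of)
            vals.append(hs.hd("A"))
        vals = np.array(vals)
        mc_err = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) <= 3 * mc_err

    def test_indel_events_produce_gap_characters(self):
        cfg = self.cfg(indel_events=5, seed=8)
        data = simulate_plastid(cfg)
        assert any("-" in s for s in data.pool)
        from igsflow import simple_indel_coding

        m = simple_indel_coding(data.records)
        assert m.n_characters >= 1
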