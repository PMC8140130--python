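"""The synthetic-cohort generator: determinism, structure, plantedness."""

import numpy as np
import pandas as pd
import pytest

from dmrcompare.fixtures import (
    FixtureConfig,
    child_rng,
    generate_genome,
    plant_betas,
    plant_dmrs,
    plant_expression,
    plant_motifs,
    plant_te_methylation,
)
from dmrcompare.genome_model import IntervalSet
from conftest import small_fixture_config


class TestDeterminism:
    def test_same_seed_identical_genome(self, small_config):
        g1 = generate_genome(small_config)
        g2 = generate_genome(small_fixture_config())
        assert [g.gene_id for g in g1.annotation.genes] == [
            g.gene_id for g in g2.annotation.genes
        ]
        assert [g.body.start for g in g1.annotation.genes] == [
            g.body.start for g in g2.annotation.genes
        ]
        for chrom in g1.annotation.cpg_positions:
            assert (g1.annotation.cpg_positions[chrom]
                    == g2.annotation.cpg_positions[chrom]).all()
        assert g1.background.bins == g2.background.bins
        eid = g1.stack18.epigenome_ids[0]
        assert g1.stack18.epigenomes[eid] == g2.stack18.epigenomes[eid]

    def test_same_seed_identical_planting(self, small_config, small_genome):
        p1 = plant_dmrs(small_config, small_genome)
        p2 = plant_dmrs(small_config, small_genome)
        assert p1.consensus == p2.consensus
        assert p1.calls == p2.calls

    def test_child_streams_independent(self):
        # regenerating one layer must not perturb another
        a = child_rng(5, "genome").integers(0, 10**9)
        _ = child_rng(5, "dmrs").integers(0, 10**9)
        b = child_rng(5, "genome").integers(0, 10**9)
        assert a == b


class TestGenomeStructure:
    def test_island_cpg_density_exceeds_background(self):
        for seed in range(5):
            g = generate_genome(small_fixture_config(seed))
            islands = g.annotation.cpg_islands
            island_bp = islands.total_bp
            genome_bp = sum(g.annotation.chrom_sizes.values())
            n_in = 0
            n_total = 0
            for chrom, pos in g.annotation.cpg_positions.items():
                n_total += len(pos)
                arr = islands.arrays().get(chrom)
                if arr is None:
                    continue
                lo = np.searchsorted(pos, arr[:, 0], side="left")
                hi = np.searchsorted(pos, arr[:, 1], side="left")
                n_in += int((hi - lo).sum())
            dens_in = n_in / island_bp
            dens_out = (n_total - n_in) / (genome_bp - island_bp)
            assert dens_in > dens_out

    def test_annotation_passes_validation(self, small_genome):
        small_genome.annotation.validate()  # raises on violation

    def test_background_is_grid_subset(self, small_genome):
        grid_keys = {b.key for b in small_genome.grid}
        assert set(small_genome.background.bins) <= grid_keys

    def test_segmentations_cover_every_chromosome_fully(self, small_genome):
        sizes = small_genome.annotation.chrom_sizes
        for eid, segs in small_genome.stack18.epigenomes.items():
            by_chrom = {}
            for iv, _ in segs:
                by_chrom.setdefault(iv.chrom, []).append(iv)
            for chrom, ivs in by_chrom.items():
                ivs.sort(key=lambda v: v.start)
                assert ivs[0].start == 0
                assert ivs[-1].end == sizes[chrom]
                for a, b in zip(ivs, ivs[1:]):
                    assert a.end == b.start  # no gaps, no overlaps

    def test_infeasible_gene_count_rejected(self):
        cfg = small_fixture_config()
        cfg.n_genes = 10**6
        with pytest.raises(ValueError, match="infeasible"):
            generate_genome(cfg)


class TestPlanting:
    def test_consensus_counts_match_config(self, small_config, small_planted):
        for cancer in ("A", "B"):
            assert len(small_planted.consensus[cancer]["hyper"]) == small_config.n_hyper[cancer]
            assert len(small_planted.consensus[cancer]["hypo"]) == small_config.n_hypo[cancer]

    def test_planted_bins_lie_in_background(self, small_genome, small_planted):
        bg = small_genome.background.bin_set
        for cancer in ("A", "B"):
            for bins in small_planted.consensus[cancer].values():
                assert bins <= bg

    def test_shared_fraction_respected(self, small_config, small_planted):
        for direction in ("hyper", "hypo"):
            a = small_planted.consensus["A"][direction]
            b = small_planted.consensus["B"][direction]
            n_req = {"hyper": small_config.n_hyper, "hypo": small_config.n_hypo}[direction]["B"]
            expected_copied = round(small_config.shared_fraction * n_req)
            assert len(a & b) >= expected_copied  # copied bins plus chance overlap

    def test_pure_promoter_mixture_all_hyper_in_promoters(self, small_genome):
        from dmrcompare.regulatory import define_promoters

        cfg = small_fixture_config()
        cfg.hyper_weights = {"promoter": 1.0, "enhancer": 0.0, "te": 0.0, "intergenic": 0.0}
        cfg.n_hyper = {"A": 100, "B": 50}
        planted = plant_dmrs(cfg, small_genome)
        ann = small_genome.annotation
        promoters = define_promoters(ann.genes, "extended_2p5kb", ann.chrom_sizes).interval_set()
        for chrom, start in planted.consensus["A"]["hyper"]:
            assert promoters.overlaps_interval(chrom, start, start + 500)

    def test_infeasible_count_rejected(self, small_genome):
        cfg = small_fixture_config()
        cfg.n_hyper = {"A": 10**6, "B": 10}
        with pytest.raises(ValueError):
            plant_dmrs(cfg, small_genome)

    def test_noise_calls_do_not_survive_recurrence(self, small_config, small_planted):
        from dmrcompare.dmr_compare import call_recurrent

        rec = call_recurrent(
            small_planted.calls["A"], small_config.n_samples["A"],
            small_config.min_support["A"], "A",
        )
        planted_all = (small_planted.consensus["A"]["hyper"]
                       | small_planted.consensus["A"]["hypo"])
        called = {b for b, _, _ in rec.dmrs}
        # singleton noise calls almost never collide across samples, so the
        # recurrent set is essentially the planted consensus: at most a
        # handful of chance collisions, and most planted bins recovered
        assert len(called - planted_all) <= 5
        assert len(called & planted_all) >= 0.9 * len(planted_all)


class TestPlantedLayers:
    def test_expression_zero_effect_centered(self, small_config):
        genes = [f"GENE{i:04d}" for i in range(40)]
        expr, groups = plant_expression(small_config, genes, {})
        from dmrcompare.expression_motifs import fold_change

        results, _ = fold_change(expr, groups, genes)
        fcs = [r.log2_fold_change for r in results]
        assert abs(float(np.mean(fcs))) < 0.1

    def test_dangling_gene_link_rejected(self, small_config):
        with pytest.raises(ValueError, match="unknown genes"):
            plant_expression(small_config, ["GENE0001"], {"NOPE": -2.0})

    def test_beta_shift_recovered_at_planted_probes(self, small_config, small_genome):
        # plant on background bins guaranteed to contain at least one probe
        probe_map = small_genome.annotation.probe_manifests["synthetic"]
        with_probe = []
        for chrom, start in small_genome.background.bins:
            pos = probe_map.positions.get(chrom)
            if pos is not None and np.searchsorted(pos, start + 500) > np.searchsorted(pos, start):
                with_probe.append((chrom, start))
        hyper = set(with_probe[:50])
        betas, groups, _ = plant_betas(small_config, small_genome, hyper, set())
        probes = small_genome.annotation.probe_manifests["synthetic"]
        hyper_set = IntervalSet.from_bins(hyper)
        affected = []
        for chrom in probes.positions:
            for pid, pos in zip(probes.probe_ids[chrom], probes.positions[chrom]):
                if hyper_set.overlaps_interval(chrom, int(pos), int(pos) + 1):
                    affected.append(str(pid))
        if not affected:
            pytest.skip("no probe fell in the sampled bins for this seed")
        tumor = [s for s, g in groups.items() if g == "tumor"]
        normal = [s for s, g in groups.items() if g == "normal"]
        diff = betas.loc[affected, tumor].mean().mean() - betas.loc[affected, normal].mean().mean()
        assert diff == pytest.approx(small_config.beta_shift, abs=0.05)

    def test_motif_layer_recoverable(self, small_config):
        labels = [f"chr1:{i * 500}-{i * 500 + 500}" for i in range(150)]
        table, hits, tf_to_motifs = plant_motifs(small_config, labels)
        assert set(hits.columns) == set(tf_to_motifs)
        assert hits.isin([0, 1]).all().all()
        # planted-enriched TFs (first half) hit more often than the rest
        enriched = [f"TF{i:02d}" for i in range(small_config.n_tfs // 2)]
        rest = [t for t in hits.columns if t not in enriched]
        assert hits[enriched].mean().mean() > hits[rest].mean().mean() + 0.2

    def test_te_methylation_target_subfamily_reduced_in_tumor(self, small_config, small_genome):
        from dmrcompare.te_methylation import copy_methylation

        tables, groups = plant_te_methylation(small_config, small_genome.annotation.te_table)
        target = [t for t in small_genome.annotation.te_table
                  if t.subfamily == small_config.hypomethylated_subfamily][:20]
        means = {}
        for sid, rows in tables.items():
            vals = [v for v in copy_methylation(target, rows).values() if v is not None]
            means[sid] = float(np.mean(vals))
        tumor_mean = np.mean([m for s, m in means.items() if groups[s] == "tumor"])
        normal_mean = np.mean([m for s, m in means.items() if groups[s] == "normal"])
        assert tumor_mean < normal_mean - 0.2
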