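"""Generator contracts: layout, determinism, read models, truth tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromdyn import SimParams, reads_to_dyads, simulate_genome
from chromdyn.config import CONDITIONS
from chromdyn.synthetic import (simulate_expression, simulate_study,
                                write_study)

SMALL = dict(n_chrom=1, chrom_len=120_000, n_genes=12, n_enhancers=5,
             chip_depth=100_000)


class TestGenomeLayout:
    def test_feature_counts_conserved(self):
        sizes, genes, enh = simulate_genome(SimParams(**SMALL))
        assert len(genes) == 12
        assert len(enh) == 5
        assert genes["tss"].nunique() == 12

    def test_zero_enhancers(self):
        _, _, enh = simulate_genome(SimParams(**{**SMALL, "n_enhancers": 0}))
        assert len(enh) == 0

    def test_packing_error(self):
        with pytest.raises(ValueError, match="pack"):
            simulate_genome(SimParams(n_chrom=1, chrom_len=1000, n_genes=10,
                                      n_enhancers=0))

    def test_genes_and_enhancers_disjoint(self):
        _, genes, enh = simulate_genome(SimParams(**SMALL))
        for e in enh.itertuples():
            ov = genes[(genes["start"] < e.end) & (genes["end"] > e.start)]
            assert len(ov) == 0

    def test_enhancers_clear_of_promoters(self):
        _, genes, enh = simulate_genome(SimParams(**SMALL))
        for e in enh.itertuples():
            assert (np.abs(genes["tss"] - e.center) > 1000).all()


class TestDeterminism:
    def test_same_seed_reproduces_everything(self):
        p = SimParams(**SMALL, rng_seed=9)
        a, b = simulate_study(p), simulate_study(p)
        pd.testing.assert_frame_equal(a.nucleosomes, b.nucleosomes)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.mnase_reads("cond1"),
                                      b.mnase_reads("cond1"))
        pd.testing.assert_frame_equal(a.chip_reads("H3K9ac", "cond2"),
                                      b.chip_reads("H3K9ac", "cond2"))

    def test_read_count_allocation_matches_emission(self):
        study = simulate_study(SimParams(**SMALL, rng_seed=4))
        counts = study.mnase_read_counts("cond1")
        n_expected = int(round(study.params.mnase_depth_per_nucleosome
                               * (study.nucleosomes["dyad_1"] >= 0).sum()))
        n_bg = int(round(study.params.background_read_frac * n_expected))
        assert counts.sum() == n_expected - n_bg
        assert len(study.mnase_reads("cond1")) == n_expected


class TestMnaseModel:
    def test_total_reads_equal_configured_depth(self):
        study = simulate_study(SimParams(**SMALL, rng_seed=2))
        for cond in CONDITIONS:
            n = (study.nucleosomes[
                {"cond1": "dyad_1", "cond2": "dyad_2"}[cond]] >= 0).sum()
            expect = int(round(study.params.mnase_depth_per_nucleosome * n))
            assert len(study.mnase_reads(cond)) == expect

    def test_zero_depth_empty(self):
        study = simulate_study(SimParams(**SMALL,
                                         mnase_depth_per_nucleosome=0.0))
        assert len(study.mnase_reads("cond1")) == 0

    def test_noise_free_midpoints_equal_planted_dyads(self):
        study = simulate_study(SimParams(**SMALL, dyad_jitter_sd_bp=0.0,
                                         background_read_frac=0.0,
                                         rng_seed=5))
        reads = study.mnase_reads("cond1")
        mids, _ = reads_to_dyads(reads, study.sizes)
        planted = set(study.nucleosomes.loc[
            study.nucleosomes["dyad_1"] >= 0, "dyad_1"])
        observed = set(np.concatenate(list(mids.values())))
        assert observed <= planted

    def test_noise_free_caller_recovers_planted_exactly(self):
        from chromdyn import PipelineConfig, call_nucleosomes
        study = simulate_study(SimParams(**SMALL, dyad_jitter_sd_bp=0.0,
                                         background_read_frac=0.0,
                                         rng_seed=5))
        cfg = PipelineConfig()
        reads = study.mnase_reads("cond1")
        dyads, _ = reads_to_dyads(reads, study.sizes)
        calls = call_nucleosomes(dyads, study.sizes, cfg,
                                 total_reads=len(reads))
        planted = set(study.nucleosomes.loc[
            study.nucleosomes["dyad_1"] >= 0, "dyad_1"])
        called = set(calls["dyad"])
        assert called <= planted
        counts = study.mnase_read_counts("cond1")
        well_covered = set(study.nucleosomes.loc[
            (study.nucleosomes["dyad_1"] >= 0)
            & (counts >= cfg.min_call_reads), "dyad_1"])
        assert well_covered <= called


class TestChipModel:
    def test_unknown_mark_rejected(self):
        study = simulate_study(SimParams(**SMALL))
        with pytest.raises(ValueError, match="mark"):
            study.chip_reads("H3K36me3", "cond1")

    def test_zero_depth_empty(self):
        study = simulate_study(SimParams(**{**SMALL, "chip_depth": 0}))
        assert len(study.chip_reads("H3K9ac", "cond1")) == 0

    def test_all_negative_mark_is_uniform(self):
        # without enhancers no feature is ever H3K27ac-positive
        study = simulate_study(SimParams(**{**SMALL, "n_enhancers": 0},
                                         rng_seed=3))
        reads = study.chip_reads("H3K27ac", "cond1")
        mids, _ = reads_to_dyads(reads, study.sizes)
        pos = np.concatenate(list(mids.values()))
        hist, edges = np.histogram(pos, bins=40,
                                   range=(100, study.params.chrom_len - 100))
        assert stats.chisquare(hist).pvalue > 0.01

    def test_planted_positive_promoter_strongly_enriched(self, study, chip,
                                                         cfg):
        from chromdyn.promoters import build_promoter_profiles
        prof = build_promoter_profiles(chip[("H3K27me3", "cond1")],
                                       study.genes, study.sizes, cfg)
        truth = study.promoter_states.query(
            "condition == 'cond1'").set_index("gene_id")["H3K27me3"]
        totals = prof.totals()
        pos = truth.loc[prof.gene_ids].to_numpy()
        assert totals[pos].min() >= 5 * prof.expected_uniform_total


class TestExpressionModel:
    @staticmethod
    def _genes(n, archetype):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                             "archetype": archetype})

    def test_zero_noise_gives_exact_fold(self):
        genes = self._genes(10, "up")
        params = SimParams(expression_lognorm_sd=0.0, up_fold_change=2.0)
        out = simulate_expression(genes, params, np.random.default_rng(0))
        np.testing.assert_allclose(out["rpkm_2"] / out["rpkm_1"], 2.0)

    def test_most_upregulated_exceed_cut(self):
        genes = self._genes(100, "up")
        params = SimParams(expression_lognorm_sd=0.1, up_fold_change=2.0)
        out = simulate_expression(genes, params, np.random.default_rng(1))
        assert (out["rpkm_2"] / out["rpkm_1"] > 1.5).sum() >= 95

    def test_empty_gene_set(self):
        out = simulate_expression(self._genes(0, "up"), SimParams(),
                                  np.random.default_rng(0))
        assert len(out) == 0

    def test_de_flags_track_q_values(self, study):
        expr = study.expression
        assert (expr.loc[expr["de"], "q_value"] < 0.05).all()
        assert (expr.loc[~expr["de"], "q_value"] >= 0.05).all()


class TestTruthTables:
    def test_event_labels_partition_entities(self, study):
        lab = study.truth_event_label()
        assert set(lab) <= {"fixed", "shift", "lost", "gained", "relocated"}
        assert len(lab) == len(study.nucleosomes)
        fr = study.truth_unit_fractions()
        assert abs(sum(fr.values()) - 1.0) < 1e-12

    def test_shift_and_relocation_distance_rules(self, study):
        lab = study.truth_event_label()
        both = study.nucleosomes[(study.nucleosomes["dyad_1"] >= 0)
                                 & (study.nucleosomes["dyad_2"] >= 0)]
        dist = (both["dyad_1"] - both["dyad_2"]).abs()
        shift = lab.loc[both.index] == "shift"
        reloc = lab.loc[both.index] == "relocated"
        assert (147 - dist[shift] > 20).all()
        assert (dist[shift] >= 1).all()
        assert (147 - dist[reloc] <= 20).all()

    def test_planted_ndrs_lie_inside_enhancers(self, study):
        planted = study.enhancers[study.enhancers["has_ndr"]]
        # NDR within 600 bp of the enhancer center by construction
        assert ((planted["ndr_start"] > planted["center"] - 600)
                & (planted["ndr_end"] < planted["center"] + 600)).all()

    def test_within_condition_exclusion_spacing(self, study):
        for col in ("dyad_1", "dyad_2"):
            for chrom, sub in study.nucleosomes.groupby("chrom"):
                d = np.sort(sub.loc[sub[col] >= 0, col].to_numpy())
                assert np.diff(d).min() >= 147

    def test_active_genes_outexpress_repressed(self, study):
        expr = study.expression.set_index("gene_id")
        arch = study.genes.set_index("gene_id")["archetype"]
        mean = expr.groupby(arch)["rpkm_1"].mean()
        assert mean["stable_active"] > mean["repressed"]


def test_write_study_emits_consistent_files(tmp_path):
    study = simulate_study(SimParams(**SMALL, rng_seed=6))
    write_study(study, tmp_path)
    for name in ("chrom.sizes", "genes.gtf", "expression.tsv",
                 "nucleosomes_truth.tsv", "enhancers_truth.tsv",
                 "mnase_cond1.bed", "H3K4me1_cond2.bed", "sim_params.yaml"):
        assert (tmp_path / name).exists()
    nuc = pd.read_csv(tmp_path / "nucleosomes_truth.tsv", sep="\t")
    assert len(nuc) == len(study.nucleosomes)
    bed = pd.read_csv(tmp_path / "mnase_cond1.bed", sep="\t", header=None)
    assert len(bed) == len(study.mnase_reads("cond1"))
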