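"""Peak calling, merging/filtering, profiles and enhancer states."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from chromdyn import ChromSizes, PipelineConfig
from chromdyn.config import CONDITIONS
from chromdyn.enhancers import (build_enhancer_profiles, call_peaks,
                                classify_enhancer_state,
                                enhancer_mark_totals, mark_positive_2means,
                                merge_and_filter, transition_table,
                                window_scan)

CFG = PipelineConfig()
SIZES = ChromSizes({"chr1": 200_000})


def _uniform_reads(rng, n, lo=100, hi=199_800):
    start = rng.integers(lo, hi, n)
    return pd.DataFrame({"chrom": "chr1", "start": start, "end": start + 49,
                         "strand": rng.choice(["+", "-"], n)})


class TestCallPeaks:
    def test_planted_block_yields_one_covering_peak(self):
        rng = np.random.default_rng(0)
        bg = _uniform_reads(rng, 20_000)
        s = rng.integers(100_000, 102_000, 2_000)  # 10x over a 2-kb block
        block = pd.DataFrame({"chrom": "chr1", "start": s, "end": s + 49,
                              "strand": "+"})
        peaks = call_peaks(pd.concat([bg, block], ignore_index=True),
                           SIZES, CFG)
        assert len(peaks) == 1
        assert peaks.iloc[0]["start"] <= 100_000
        assert peaks.iloc[0]["end"] >= 102_000

    def test_uniform_background_rarely_significant(self):
        rng = np.random.default_rng(1)
        windows = window_scan(_uniform_reads(rng, 50_000), SIZES, CFG)
        frac = (windows["q_value"] <= CFG.enhancer_fdr).mean()
        assert frac <= 2 * CFG.enhancer_fdr

    def test_empty_reads_error(self):
        with pytest.raises(ValueError, match="reads"):
            call_peaks(pd.DataFrame(columns=["chrom", "start", "end",
                                             "strand"]), SIZES, CFG)


def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


class TestMergeAndFilter:
    no_promoters = pd.DataFrame(columns=["chrom", "start", "end"])

    def test_close_pair_keeps_higher_score(self):
        merged = merge_and_filter(
            _peaks([("chr1", 1000, 2000, 5.0)]),
            _peaks([("chr1", 2300, 3000, 9.0)]), self.no_promoters, CFG)
        assert len(merged) == 1
        assert merged.iloc[0]["start"] == 2300
        assert merged.iloc[0]["score"] == 9.0

    def test_peak_mostly_inside_promoter_dropped(self):
        promoters = pd.DataFrame({"chrom": ["chr1"], "start": [900],
                                  "end": [2900]})
        merged = merge_and_filter(_peaks([("chr1", 1000, 2000, 5.0)]),
                                  _peaks([]), promoters, CFG)
        assert len(merged) == 0

    def test_chain_fixpoint_matches_exhaustive_orderings(self):
        """A-B-C each 300 bp apart, scores 3 < 5 > 4: B must survive, and
        the iterated left-to-right rule agrees with every pairwise merge
        order."""
        chain = [("chr1", 1000, 1500, 3.0), ("chr1", 1800, 2300, 5.0),
                 ("chr1", 2600, 3100, 4.0)]
        merged = merge_and_filter(_peaks(chain), _peaks([]),
                                  self.no_promoters, CFG)
        assert merged[["start", "score"]].values.tolist() == [[1800, 5.0]]

        def exhaustive(peaks):
            # apply the pairwise rule in every order until stable
            best = None
            for order in itertools.permutations(range(len(peaks))):
                alive = {i: peaks[i] for i in range(len(peaks))}
                changed = True
                while changed:
                    changed = False
                    for i, j in itertools.combinations(sorted(alive), 2):
                        a, b = alive[i], alive[j]
                        gap = max(a[1], b[1]) - min(a[2], b[2])
                        if gap < CFG.enhancer_merge_bp:
                            drop = i if a[3] < b[3] else j
                            del alive[drop]
                            changed = True
                            break
                survivors = sorted(v[1] for v in alive.values())
                assert best is None or best == survivors
                best = survivors
            return best

        assert exhaustive(chain) == [1800]


class TestProfiles:
    enh = pd.DataFrame({"enh_id": ["e0"], "chrom": ["chr1"],
                        "start": [99_600], "end": [100_400],
                        "score": [5.0], "center": [100_000]})

    def test_center_reads_one_hot(self):
        reads = pd.DataFrame({"chrom": ["chr1"] * 5, "start": [100_000 - 73] * 5,
                              "end": [100_000 - 24] * 5, "strand": ["+"] * 5})
        mat = build_enhancer_profiles(self.enh, reads, SIZES, CFG)
        assert mat.shape == (1, 120)
        assert mat[0, 60] == pytest.approx(1.0)
        assert mat.sum() == pytest.approx(1.0)

    def test_uniform_reads_flat_profile(self):
        start = np.arange(96_700, 103_200, 2)
        reads = pd.DataFrame({"chrom": "chr1", "start": start,
                              "end": start + 49, "strand": "+"})
        mat = build_enhancer_profiles(self.enh, reads, SIZES, CFG)
        np.testing.assert_allclose(mat[0], 1 / 120, atol=2e-3)

    def test_depth_invariance(self):
        rng = np.random.default_rng(2)
        reads = _uniform_reads(rng, 5_000, 96_000, 104_000)
        m1 = build_enhancer_profiles(self.enh, reads, SIZES, CFG)
        m2 = build_enhancer_profiles(
            self.enh, pd.concat([reads, reads], ignore_index=True), SIZES,
            CFG)
        np.testing.assert_allclose(m1, m2)

    def test_zero_read_region_stays_zero(self):
        reads = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [59],
                              "strand": ["+"]})
        mat = build_enhancer_profiles(self.enh, reads, SIZES, CFG)
        assert mat.sum() == 0.0


class TestStateRule:
    def _pos(self, k4me1, k27ac, k27me3):
        return {("H3K4me1", "cond1"): np.array(k4me1),
                ("H3K27ac", "cond1"): np.array(k27ac),
                ("H3K27me3", "cond1"): np.array(k27me3),
                ("H3K4me1", "cond2"): np.array(k4me1),
                ("H3K27ac", "cond2"): np.array(k27ac),
                ("H3K27me3", "cond2"): np.array(k27me3)}

    def test_three_way_rule(self):
        pos = self._pos([True, True, True, False],
                        [True, False, True, True],
                        [False, True, True, False])
        states = classify_enhancer_state(pos)
        assert states["state_cond1"].tolist() == [
            "active", "poised", "intermediate", "intermediate"]

    def test_k4me1_negative_everywhere_all_intermediate(self):
        pos = self._pos([False] * 3, [True] * 3, [True] * 3)
        states = classify_enhancer_state(pos)
        assert (states["state_cond1"] == "intermediate").all()

    def test_alternative_poised_convention(self):
        pos = self._pos([True], [False], [False])
        states = classify_enhancer_state(pos, poised_requires_k27me3=False)
        assert states["state_cond1"].tolist() == ["poised"]

    def test_transition_rows_sum_to_condition1_counts(self):
        rng = np.random.default_rng(3)
        states = pd.DataFrame({
            "state_cond1": rng.choice(["active", "poised", "intermediate"],
                                      50),
            "state_cond2": rng.choice(["active", "poised", "intermediate"],
                                      50)})
        table, persistence = transition_table(states)
        assert table.sum(axis=1).to_dict() == \
            states["state_cond1"].value_counts().reindex(
                ["active", "poised", "intermediate"], fill_value=0).to_dict()
        n_poised = (states["state_cond1"] == "poised").sum()
        assert persistence == pytest.approx(
            table.loc["poised", "poised"] / n_poised)


class TestPositivity2Means:
    def test_clear_separation(self):
        rng = np.random.default_rng(4)
        counts = np.concatenate([rng.poisson(1000, 30), rng.poisson(80, 50)])
        pos = mark_positive_2means(counts.astype(float), 100.0, CFG, seed=0)
        assert pos[:30].all() and not pos[30:].any()

    def test_unimodal_counts_use_threshold(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(100, 60).astype(float)
        pos = mark_positive_2means(counts, 100.0, CFG, seed=0)
        assert not pos.any()


class TestRecoveryOnStudy:
    def test_called_enhancers_match_planted(self, study, called_enhancers):
        assert len(called_enhancers) == len(study.enhancers)
        for row in called_enhancers.itertuples():
            d = (study.enhancers["center"] - row.center).abs().min()
            assert d < 300

    def test_state_recovery_and_poised_persistence(self, study, chip, cfg,
                                                   called_enhancers):
        genome_len = sum(study.sizes.values())
        positivity = {}
        for mark in ("H3K4me1", "H3K27ac", "H3K27me3"):
            for cond in CONDITIONS:
                reads = chip[(mark, cond)]
                counts = enhancer_mark_totals(called_enhancers, reads,
                                              study.sizes, cfg)
                expected = len(reads) * 1000 / genome_len
                positivity[(mark, cond)] = mark_positive_2means(
                    counts, expected, cfg, seed=0)
        states = classify_enhancer_state(positivity)
        # match back to planted enhancers by center
        planted = study.enhancers.set_index("chrom", append=False)
        for cond, col in (("cond1", "state_1"), ("cond2", "state_2")):
            correct = 0
            for i, row in enumerate(called_enhancers.itertuples()):
                sub = study.enhancers[study.enhancers["chrom"] == row.chrom]
                j = (sub["center"] - row.center).abs().idxmin()
                correct += (states.iloc[i][f"state_{cond}"]
                            == study.enhancers.loc[j, col])
            assert correct / len(called_enhancers) >= 0.90
        _, persistence = transition_table(states)
        truth_p1 = study.enhancers["state_1"] == "poised"
        truth_persist = (study.enhancers.loc[truth_p1, "state_2"]
                         == "poised").mean()
        assert persistence == pytest.approx(truth_persist, abs=0.1)
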