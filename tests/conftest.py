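"""Shared fixtures: the default synthetic study and the pipeline stages run
on it. Heavy objects are session-scoped so the whole suite pays for the
simulation and read generation once."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chromdyn import (
    ChromSizes,
    PipelineConfig,
    SimParams,
    build_occupancy,
    call_nucleosomes,
    call_peaks,
    merge_and_filter,
    reads_to_dyads,
)
from chromdyn.config import CONDITIONS
from chromdyn.nucleosomes import promoter_intervals
from chromdyn.synthetic import simulate_study


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def study():
    """The default two-condition study (seed 0): 2 x 500 kb, ~5,000
    nucleosomes, event mix 2/90/4/4, depth 30 reads/nucleosome."""
    return simulate_study(SimParams())


@pytest.fixture(scope="session")
def mnase(study, cfg):
    """Per-condition MNase reads, dyads, occupancy track and calls."""
    out = {}
    for cond in CONDITIONS:
        reads = study.mnase_reads(cond)
        dyads, _ = reads_to_dyads(reads, study.sizes, cfg.nucleosome_len_bp)
        track = build_occupancy(dyads, study.sizes, len(reads), cfg)
        calls = call_nucleosomes(dyads, study.sizes, cfg,
                                 total_reads=len(reads))
        out[cond] = {"reads": reads, "dyads": dyads, "track": track,
                     "calls": calls}
    return out


@pytest.fixture(scope="session")
def chip(study):
    """ChIP read tables for every (mark, condition)."""
    marks = ("H3K4me1", "H3K4me3", "H3K9ac", "H3K27ac", "H3K27me3")
    return {(m, c): study.chip_reads(m, c) for m in marks for c in CONDITIONS}


@pytest.fixture(scope="session")
def called_enhancers(study, chip, cfg):
    """Enhancers called from H3K4me1 in both conditions, merged, filtered."""
    peaks = {c: call_peaks(chip[("H3K4me1", c)], study.sizes, cfg)
             for c in CONDITIONS}
    promoters = promoter_intervals(study.genes, cfg.promoter_flank_bp,
                                   study.sizes)
    return merge_and_filter(peaks["cond1"], peaks["cond2"], promoters, cfg)


@pytest.fixture()
def tiny_sizes() -> ChromSizes:
    return ChromSizes({"chr1": 10_000})


def make_calls(chrom_dyads: dict[str, list[int]]) -> pd.DataFrame:
    """Helper: a call table from per-chromosome dyad lists."""
    rows = [(c, d, 1.0, 1.0) for c, ds in chrom_dyads.items() for d in ds]
    return pd.DataFrame(rows, columns=["chrom", "dyad", "occupancy", "score"])
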