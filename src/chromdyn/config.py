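"""Tunable parameters for the analysis pipeline and the simulator.

All genomic distances are in base pairs; all fractions are relative to a
genome-wide mean unless noted otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class PipelineConfig:
    """Every tunable constant of the analysis, with field defaults.

    The defaults encode the analysis conventions: 5-bp occupancy bins
    smoothed over 5 bins, promoters as TSS +/- 1 kb, a 147-bp nucleosome
    footprint, a 20-bp maximum footprint overlap for calling a nucleosome
    lost or gained, enhancer peak calling in 1000-bp windows at FDR 0.1%
    with sub-500-bp merging, and NDRs of at least 150 bp.
    """

    # nucleosome calling (Gaussian-kernel greedy peak picking)
    gaussian_sigma_bp: int = 20
    exclusion_zone_bp: int = 147
    nucleosome_len_bp: int = 147
    min_call_reads: int = 3

    # occupancy tracks and promoter profiles
    bin_bp: int = 5
    smooth_bins: int = 5
    promoter_flank_bp: int = 1000

    # NDR detection
    promoter_ndr_window: tuple[int, int] = (-200, 50)
    ndr_min_len_bp: int = 150
    ndr_depletion_frac: float = 0.20
    ndr_prior_occupancy_frac: float = 0.25

    # dynamics classification
    gain_loss_max_overlap_bp: int = 20

    # enhancer calling and profiling
    enhancer_window_bp: int = 1000
    enhancer_step_bp: int = 100
    enhancer_fdr: float = 0.001
    enhancer_merge_bp: int = 500
    enhancer_promoter_overlap_frac: float = 0.50
    enhancer_profile_flank_bp: int = 3000
    enhancer_profile_bin_bp: int = 50

    # expression grouping
    fold_change_cut: float = 1.5
    de_fdr: float = 0.05

    # clustering
    kmeans_k_promoter: int = 2
    kmeans_k_ndr_modes: int = 3
    eviction_peak_halfwidth_bp: int = 40

    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gaussian_sigma_bp", "exclusion_zone_bp", "nucleosome_len_bp",
            "bin_bp", "smooth_bins", "promoter_flank_bp", "ndr_min_len_bp",
            "enhancer_window_bp", "enhancer_step_bp", "enhancer_merge_bp",
            "enhancer_profile_flank_bp", "enhancer_profile_bin_bp",
            "eviction_peak_halfwidth_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "ndr_depletion_frac", "ndr_prior_occupancy_frac",
            "enhancer_promoter_overlap_frac", "enhancer_fdr", "de_fdr",
        ):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        lo, hi = self.promoter_ndr_window
        if lo >= hi:
            raise ValueError("promoter_ndr_window must be an increasing pair")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "promoter_ndr_window" in raw:
            raw["promoter_ndr_window"] = tuple(raw["promoter_ndr_window"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["promoter_ndr_window"] = list(d["promoter_ndr_window"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class SimParams:
    """Study conditions for the two-state synthetic genome.

    The defaults describe the simulated differentiation experiment used
    throughout the test suite: a 2 x 500 kb genome tiled with ~5,000
    nucleosomes at 200-bp spacing, an event mix of 2% fixed / 90% shift /
    4% lost / 4% gained, MNase depth of 30 reads per nucleosome, and five
    histone-mark ChIP libraries of 1M reads each at 10x enrichment over
    positive features.
    """

    n_chrom: int = 2
    chrom_len: int = 500_000
    n_genes: int = 200
    n_enhancers: int = 80

    # nucleosome landscape
    nucleosome_spacing_bp: int = 200
    event_mix: tuple[float, float, float, float] = (0.02, 0.90, 0.04, 0.04)
    # capped at 25 bp so two neighbors on the 200-bp grid shifting toward
    # each other still respect the 147-bp exclusion footprint
    shift_range_bp: tuple[int, int] = (10, 25)
    mnase_depth_per_nucleosome: float = 30.0
    dyad_jitter_sd_bp: float = 10.0
    background_read_frac: float = 0.05
    occupancy_gamma_shape: float = 2.0
    read_len_bp: int = 49

    # enhancer NDR planting
    ndr_len_bp: int = 200
    ndr_shift_range_bp: tuple[int, int] = (150, 200)
    enhancer_ndr_frac: float = 0.6
    ndr_mode_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    # ChIP-seq model
    chip_depth: int = 1_000_000
    chip_enrichment: float = 10.0

    # expression model
    expression_lognorm_sd: float = 0.15
    up_fold_change: float = 2.0
    frac_up: float = 0.15
    frac_down: float = 0.15
    frac_repressed: float = 0.15
    frac_bivalent: float = 0.02
    frac_silent: float = 0.23

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.event_mix) - 1.0) > 1e-9:
            raise ValueError("event_mix must sum to 1")
        if abs(sum(self.ndr_mode_mix) - 1.0) > 1e-9:
            raise ValueError("ndr_mode_mix must sum to 1")
        if self.mnase_depth_per_nucleosome < 0 or self.chip_depth < 0:
            raise ValueError("depths must be >= 0")
        if self.dyad_jitter_sd_bp < 0:
            raise ValueError("dyad_jitter_sd_bp must be >= 0")
        if not (0.0 <= self.background_read_frac < 1.0):
            raise ValueError("background_read_frac must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        for key in ("event_mix", "shift_range_bp", "ndr_shift_range_bp",
                    "ndr_mode_mix"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("event_mix", "shift_range_bp", "ndr_shift_range_bp",
                    "ndr_mode_mix"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


MARKS = ("H3K4me1", "H3K4me3", "H3K9ac", "H3K27ac", "H3K27me3")
CONDITIONS = ("cond1", "cond2")
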