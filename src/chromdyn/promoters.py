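"""Promoter histone-modification states.

For each gene and mark, ChIP reads are extended to 147 bp, their midpoints
binned in 5-bp intervals across TSS +/- 1 kb (strand-oriented), RPM
normalized and smoothed over 5 bins. Promoters are split into mark-positive
and mark-negative groups by K-means (K = 2) on the profile vectors, and the
per-mark calls combine into chromatin states: active (H3K4me3+/H3K9ac+),
repressed (H3K27me3+), bivalent (H3K4me3+/H3K27me3+), or none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .config import PipelineConfig
from .intervals import ChromSizes
from .nucleosomes import reads_to_dyads, smooth_moving_average

COMBINED_STATES = ("active", "repressed", "bivalent", "none")


@dataclass
class ProfileMatrix:
    """Per-gene signal profiles for one (mark, condition) library.

    ``matrix`` is genes x bins, RPM units, strand-oriented (upstream on the
    left). ``expected_uniform_total`` is the profile total a library of the
    same depth would give if reads were spread uniformly over the genome;
    it anchors the degenerate-clustering fallback threshold.
    """

    gene_ids: np.ndarray
    matrix: np.ndarray
    mark: str
    condition: str
    expected_uniform_total: float

    def totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def build_promoter_profiles(reads: pd.DataFrame, genes: pd.DataFrame,
                            sizes: ChromSizes, cfg: PipelineConfig,
                            mark: str = "", condition: str = ""
                            ) -> ProfileMatrix:
    """Bin read midpoints around each TSS into a smoothed RPM profile."""
    flank = cfg.promoter_flank_bp
    n_bins = 2 * flank // cfg.bin_bp
    midpoints, _ = reads_to_dyads(reads, sizes, cfg.nucleosome_len_bp)
    total_reads = max(1, len(reads))
    by_chrom = {c: np.sort(v) for c, v in midpoints.items()}
    mat = np.zeros((len(genes), n_bins))
    for i, row in enumerate(genes.itertuples()):
        mids = by_chrom.get(row.chrom)
        if mids is None or mids.size == 0:
            continue
        lo = np.searchsorted(mids, row.tss - flank, side="left")
        hi = np.searchsorted(mids, row.tss + flank + 1, side="right")
        window = mids[lo:hi]
        dist = (window - row.tss if row.strand == "+" else row.tss - window)
        keep = (dist >= -flank) & (dist < flank)
        idx = (dist[keep] + flank) // cfg.bin_bp
        counts = np.bincount(idx.astype(np.int64), minlength=n_bins)
        rpm = counts * 1e6 / total_reads
        mat[i] = smooth_moving_average(rpm, cfg.smooth_bins)
    genome_len = sum(sizes.values())
    expected_total = 2 * flank / genome_len * 1e6
    return ProfileMatrix(gene_ids=genes["gene_id"].to_numpy(), matrix=mat,
                         mark=mark, condition=condition,
                         expected_uniform_total=expected_total)


def classify_mark_kmeans(profiles: ProfileMatrix, cfg: PipelineConfig,
                         seed: int | None = None,
                         use_totals: bool = False) -> pd.DataFrame:
    """Split promoters into mark-positive and mark-negative by 2-means.

    The cluster with the higher mean total signal is called "+". When the
    two cluster means differ by less than 2x (no real bimodality), the
    split is replaced by a fixed threshold at twice the uniform-coverage
    expectation, so unimodal data is not cut arbitrarily in half.
    """
    if seed is None:
        seed = cfg.rng_seed
    totals = profiles.totals()
    gene_ids = profiles.gene_ids
    if len(gene_ids) == 0:
        return pd.DataFrame({"gene_id": [], "positive": []})
    fallback_cut = 2.0 * profiles.expected_uniform_total
    if np.allclose(totals, 0.0):
        positive = np.zeros(len(gene_ids), dtype=bool)
    elif len(gene_ids) < 2:
        positive = totals > fallback_cut
    else:
        feats = (totals[:, None] if use_totals else profiles.matrix)
        km = KMeans(n_clusters=cfg.kmeans_k_promoter, n_init=10,
                    random_state=seed)
        labels = km.fit_predict(feats)
        means = np.array([totals[labels == k].mean() if (labels == k).any()
                          else 0.0 for k in range(cfg.kmeans_k_promoter)])
        hi, lo = means.max(), means.min()
        if lo <= 0 or hi / max(lo, 1e-300) >= 2.0:
            positive = labels == int(np.argmax(means))
            if (~positive).all() or positive.all():
                positive = totals > fallback_cut
        else:
            positive = totals > fallback_cut
    return pd.DataFrame({"gene_id": gene_ids, "positive": positive})


def combine_states(mark_calls: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine per-mark +/- calls into one chromatin state per promoter.

    Requires H3K4me3, H3K9ac and H3K27me3 calls; precedence is
    bivalent > active > repressed > none.
    """
    for mark in ("H3K4me3", "H3K9ac", "H3K27me3"):
        if mark not in mark_calls:
            raise ValueError(f"missing {mark} calls")
    merged = None
    for mark, calls in mark_calls.items():
        col = calls.rename(columns={"positive": mark})
        merged = col if merged is None else merged.merge(col, on="gene_id")
    k4me3 = merged["H3K4me3"].to_numpy()
    k9ac = merged["H3K9ac"].to_numpy()
    k27me3 = merged["H3K27me3"].to_numpy()
    state = np.full(len(merged), "none", dtype=object)
    state[k27me3] = "repressed"
    state[k4me3 & k9ac] = "active"
    state[k4me3 & k27me3] = "bivalent"
    merged["state"] = state
    return merged


def annotate_expression(expression: pd.DataFrame, cfg: PipelineConfig
                        ) -> pd.DataFrame:
    """Add fold change (pseudocount 1 RPKM), group and DE flag columns.

    Group is up / down / no-change against the 1.5-fold cut; the DE flag
    additionally requires q < de_fdr.
    """
    out = expression.copy()
    fc = (out["rpkm_2"] + 1.0) / (out["rpkm_1"] + 1.0)
    out["fold_change"] = fc
    group = np.full(len(out), "no-change", dtype=object)
    group[fc > cfg.fold_change_cut] = "up"
    group[fc < 1.0 / cfg.fold_change_cut] = "down"
    out["group"] = group
    out["de"] = (out["q_value"] < cfg.de_fdr) & (group != "no-change")
    return out


def state_expression_report(profiles_1: dict[str, ProfileMatrix],
                            profiles_2: dict[str, ProfileMatrix],
                            expression: pd.DataFrame,
                            cfg: PipelineConfig,
                            gene_subset: list[str] | None = None,
                            n_boot: int = 1000,
                            seed: int | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame,
                                       pd.DataFrame]:
    """Relate promoter-signal change to expression change.

    Returns (per-gene table, per-group mean delta with bootstrap CI,
    per-mark Spearman correlation between delta signal and log2 fold
    change).
    """
    if seed is None:
        seed = cfg.rng_seed
    rng = np.random.default_rng(seed)
    expr = annotate_expression(expression, cfg)
    marks = sorted(set(profiles_1) & set(profiles_2))
    base = None
    for mark in marks:
        p1, p2 = profiles_1[mark], profiles_2[mark]
        if not np.array_equal(p1.gene_ids, p2.gene_ids):
            raise ValueError("profile gene sets differ between conditions")
        delta = p2.matrix.mean(axis=1) - p1.matrix.mean(axis=1)
        col = pd.DataFrame({"gene_id": p1.gene_ids, f"delta_{mark}": delta})
        base = col if base is None else base.merge(col, on="gene_id")
    per_gene = base.merge(
        expr[["gene_id", "fold_change", "group", "de"]], on="gene_id")
    if gene_subset is not None:
        per_gene = per_gene[per_gene["gene_id"].isin(gene_subset)]
    per_gene = per_gene.reset_index(drop=True)
    per_gene["log2_fc"] = np.log2(per_gene["fold_change"])

    group_rows = []
    for mark in marks:
        for group, sub in per_gene.groupby("group"):
            d = sub[f"delta_{mark}"].to_numpy()
            mean = float(d.mean()) if d.size else np.nan
            if d.size > 1:
                boots = rng.choice(d, size=(n_boot, d.size)).mean(axis=1)
                lo, hi = np.quantile(boots, [0.025, 0.975])
            else:
                lo = hi = np.nan
            group_rows.append((mark, group, d.size, mean, lo, hi))
    group_summary = pd.DataFrame(
        group_rows, columns=["mark", "group", "n", "mean_delta",
                             "ci_lo", "ci_hi"])

    corr_rows = []
    for mark in marks:
        d = per_gene[f"delta_{mark}"].to_numpy()
        if d.size >= 3 and np.ptp(d) > 0:
            rho, p = stats.spearmanr(d, per_gene["log2_fc"])
        else:
            rho, p = np.nan, np.nan
        corr_rows.append((mark, d.size, rho, p))
    correlations = pd.DataFrame(
        corr_rows, columns=["mark", "n", "spearman_rho", "p_value"])
    return per_gene, group_summary, correlations
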