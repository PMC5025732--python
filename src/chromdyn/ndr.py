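"""Nucleosome-depleted regions (NDRs) in promoters and enhancers.

A position is depleted when the mean occupancy over the nucleosome-sized
(147-bp) window centered on it falls below ``ndr_depletion_frac`` x the
genome-wide mean — i.e. the window holds no meaningful fraction of a
positioned nucleosome. An NDR is a depleted run of at least
``ndr_min_len_bp`` (about one nucleosome) inside a promoter window
(strand-oriented [-200, +50] bp of the TSS) or an enhancer. An NDR "forms" during differentiation when the same interval was
occupied in the other condition (mean occupancy >= ``ndr_prior_occupancy_frac``
x the genome mean there). Formed enhancer NDRs are clustered (K-means,
K = 3) on the prior-condition occupancy around the NDR center; the position
of each cluster's composite peak tells the formation mode apart: a peak at
the center means the nucleosome was evicted in place, a displaced peak means
a flanking nucleosome shifted away.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d
from sklearn.cluster import KMeans

from .config import PipelineConfig
from .nucleosomes import OccupancyTrack

MODES = ("eviction", "shift_upstream", "shift_downstream")


def promoter_ndr_regions(genes: pd.DataFrame, cfg: PipelineConfig
                         ) -> pd.DataFrame:
    """Strand-oriented promoter NDR search windows around each TSS."""
    lo, hi = cfg.promoter_ndr_window
    tss = genes["tss"].to_numpy()
    plus = genes["strand"].to_numpy() == "+"
    start = np.where(plus, tss + lo, tss - hi + 1)
    end = np.where(plus, tss + hi + 1, tss - lo + 1)
    return pd.DataFrame({"chrom": genes["chrom"], "start": start, "end": end,
                         "context": "promoter", "ref_id": genes["gene_id"]})


def enhancer_ndr_regions(enhancers: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({"chrom": enhancers["chrom"],
                         "start": enhancers["start"],
                         "end": enhancers["end"],
                         "context": "enhancer",
                         "ref_id": enhancers["enh_id"]})


def footprint_mean(track: OccupancyTrack, footprint_bp: int = 147
                   ) -> dict[str, np.ndarray]:
    """Occupancy averaged over a nucleosome-sized window around each bin."""
    width = max(1, int(round(footprint_bp / track.bin_bp)))
    return {c: uniform_filter1d(v, size=width, mode="nearest")
            for c, v in track.values.items()}


def detect_ndrs(track: OccupancyTrack, regions: pd.DataFrame,
                cfg: PipelineConfig) -> pd.DataFrame:
    """Find depleted runs of >= ndr_min_len_bp inside each region.

    Depletion is assessed on the footprint-scale mean (147-bp window), so a
    stray background fragment does not break up a genuinely nucleosome-free
    stretch. Boundaries are at bin resolution, clipped to the region.
    Returns one row per NDR with the region's context/ref_id and the mean
    occupancy of the detected interval.
    """
    threshold = cfg.ndr_depletion_frac * track.genome_mean()
    fp = footprint_mean(track, cfg.nucleosome_len_bp)
    bin_bp = track.bin_bp
    min_bins = -(-cfg.ndr_min_len_bp // bin_bp)
    rows = []
    for row in regions.itertuples():
        if row.chrom not in track.values:
            raise KeyError(f"region on unknown chromosome {row.chrom!r}")
        v = track.values[row.chrom]
        b0, b1 = row.start // bin_bp, -(-row.end // bin_bp)
        if b0 < 0 or b1 > v.size:
            raise ValueError(
                f"region {row.chrom}:{row.start}-{row.end} outside track")
        depleted = fp[row.chrom][b0:b1] < threshold
        # maximal runs of depleted bins
        padded = np.concatenate(([False], depleted, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s < min_bins:
                continue
            start_bp = (b0 + int(s)) * bin_bp
            end_bp = (b0 + int(e)) * bin_bp
            rows.append((row.chrom, start_bp, end_bp, row.context, row.ref_id,
                         float(v[b0 + s:b0 + e].mean())))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "context",
                                       "ref_id", "mean_occupancy"])


def formed_ndrs(ndrs: pd.DataFrame, prior_track: OccupancyTrack,
                cfg: PipelineConfig) -> pd.DataFrame:
    """Keep NDRs whose interval was occupied in the prior condition.

    Occupation is the peak footprint-scale occupancy over the interval
    interior (positions whose 147-bp window lies inside the NDR, so signal
    from flanking nucleosomes cannot leak in): it asks whether a nucleosome
    sat anywhere in the interval, independent of interval length.
    """
    cutoff = cfg.ndr_prior_occupancy_frac * prior_track.genome_mean()
    fp = footprint_mean(prior_track, cfg.nucleosome_len_bp)
    half = (cfg.nucleosome_len_bp - 1) // 2
    bin_bp = prior_track.bin_bp
    prior = np.empty(len(ndrs))
    for i, r in enumerate(ndrs.itertuples()):
        b0 = (r.start + half) // bin_bp
        b1 = (r.end - half) // bin_bp
        v = fp[r.chrom]
        b0, b1 = max(0, b0), min(v.size, max(b0 + 1, b1))
        prior[i] = float(v[b0:b1].max())
    out = ndrs.copy()
    out["prior_occupancy"] = prior
    return out[out["prior_occupancy"] >= cutoff].reset_index(drop=True)


def _ndr_feature_matrix(ndrs: pd.DataFrame, prior_track: OccupancyTrack,
                        flank_bp: int = 300) -> np.ndarray:
    """Prior occupancy within each NDR, aligned on centers, sum-normalized.

    Bins outside the NDR's own interval are zeroed: the nucleosome whose
    disappearance formed the NDR must have sat inside it, while flanking
    nucleosomes (still present in both conditions) carry no mode signal and
    would otherwise dominate the clustering with locus-specific phasing.
    """
    bin_bp = prior_track.bin_bp
    n_bins = 2 * flank_bp // bin_bp
    mat = np.zeros((len(ndrs), n_bins))
    for i, row in enumerate(ndrs.itertuples()):
        center = (row.start + row.end) // 2
        v = prior_track.values[row.chrom]
        b0 = (center - flank_bp) // bin_bp
        src_lo = max(0, b0, row.start // bin_bp)
        src_hi = min(v.size, b0 + n_bins, -(-row.end // bin_bp))
        if src_hi <= src_lo:
            continue
        dst_lo = src_lo - b0
        mat[i, dst_lo:dst_lo + (src_hi - src_lo)] = v[src_lo:src_hi]
        s = mat[i].sum()
        if s > 0:
            mat[i] /= s
    return mat


def _mode_from_peak_offset(offset_bp: float, halfwidth: int) -> str:
    if abs(offset_bp) <= halfwidth:
        return "eviction"
    return "shift_upstream" if offset_bp < 0 else "shift_downstream"


def classify_ndr_mode(ndrs: pd.DataFrame, prior_track: OccupancyTrack,
                      cfg: PipelineConfig, seed: int | None = None,
                      flank_bp: int = 300
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign a formation mode to each formed enhancer NDR.

    K-means (K = 3) clusters the prior-condition occupancy profiles; each
    cluster is labeled by where its composite profile peaks relative to the
    NDR center (within ``eviction_peak_halfwidth_bp`` -> eviction, left ->
    shift_upstream, right -> shift_downstream). With fewer NDRs than K the
    per-NDR peak position is used directly.

    Returns (ndrs with a mode column, composite-profile table).
    """
    if seed is None:
        seed = cfg.rng_seed
    out = ndrs.copy()
    if len(ndrs) == 0:
        out["mode"] = pd.Series(dtype=object)
        return out, pd.DataFrame()
    mat = _ndr_feature_matrix(ndrs, prior_track, flank_bp)
    bin_bp = prior_track.bin_bp
    offsets = (np.arange(mat.shape[1]) + 0.5) * bin_bp - flank_bp
    halfwidth = cfg.eviction_peak_halfwidth_bp
    if len(ndrs) < cfg.kmeans_k_ndr_modes:
        modes = [_mode_from_peak_offset(offsets[int(np.argmax(prof))],
                                        halfwidth)
                 for prof in mat]
        out["mode"] = modes
        return out, pd.DataFrame()
    km = KMeans(n_clusters=cfg.kmeans_k_ndr_modes, n_init=10,
                random_state=seed)
    labels = km.fit_predict(mat)
    composites = []
    cluster_mode = {}
    for k in range(cfg.kmeans_k_ndr_modes):
        members = labels == k
        comp = (mat[members].mean(axis=0) if members.any()
                else np.zeros(mat.shape[1]))
        peak = float(offsets[int(np.argmax(comp))]) if comp.any() else 0.0
        cluster_mode[k] = _mode_from_peak_offset(peak, halfwidth)
        composites.append(pd.DataFrame({
            "cluster": k, "mode": cluster_mode[k], "offset_bp": offsets,
            "occupancy": comp, "n_members": int(members.sum())}))
    out["mode"] = [cluster_mode[k] for k in labels]
    return out, pd.concat(composites, ignore_index=True)


def promoter_ndr_occupancy(track: OccupancyTrack, genes: pd.DataFrame,
                           cfg: PipelineConfig) -> pd.DataFrame:
    """Mean occupancy of each gene's [-200, +50] TSS window."""
    regions = promoter_ndr_regions(genes, cfg)
    occ = [track.region_mean(r.chrom, r.start, r.end)
           for r in regions.itertuples()]
    return pd.DataFrame({"gene_id": regions["ref_id"], "occupancy": occ})


def nearest_tss_gene(ndrs: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Associate each NDR with the gene whose TSS is closest to its center."""
    gene_ids = []
    by_chrom = {c: s.sort_values("tss") for c, s in genes.groupby("chrom")}
    for row in ndrs.itertuples():
        sub = by_chrom.get(row.chrom)
        if sub is None or len(sub) == 0:
            gene_ids.append(None)
            continue
        center = (row.start + row.end) // 2
        i = int(np.argmin(np.abs(sub["tss"].to_numpy() - center)))
        gene_ids.append(sub["gene_id"].iloc[i])
    return pd.Series(gene_ids, index=ndrs.index, name="gene_id")


def ndr_expression_report(promoter_occ_1: pd.DataFrame,
                          promoter_occ_2: pd.DataFrame,
                          expression: pd.DataFrame,
                          formed_ndr_genes: list[str] | None = None,
                          enhancer_ndr_states: pd.DataFrame | None = None
                          ) -> dict:
    """Association statistics between NDRs and expression.

    Returns a dict with Spearman correlations (promoter occupancy vs
    log RPKM, per condition), a paired expression test for genes with
    formed NDRs, and a mode-by-state contingency test when enhancer NDR
    states are supplied (columns: mode, state).
    """
    report: dict = {}
    expr = expression.set_index("gene_id")
    for cond, occ in (("cond1", promoter_occ_1), ("cond2", promoter_occ_2)):
        merged = occ.merge(expression, on="gene_id")
        if len(merged) >= 3:
            x = merged["occupancy"].to_numpy()
            y = np.log2(merged[f"rpkm_{cond[-1]}"].to_numpy() + 1.0)
            rho, p = stats.spearmanr(x, y)
        else:
            rho, p = np.nan, np.nan
        report[f"spearman_{cond}"] = {"rho": float(rho), "p": float(p),
                                      "n": len(merged)}
    if formed_ndr_genes:
        genes = [g for g in formed_ndr_genes if g in expr.index]
        r1 = expr.loc[genes, "rpkm_1"].to_numpy(dtype=float)
        r2 = expr.loc[genes, "rpkm_2"].to_numpy(dtype=float)
        if len(genes) >= 6 and np.any(r1 != r2):
            stat, p = stats.wilcoxon(r2, r1)
        else:
            stat, p = np.nan, np.nan
        report["formed_ndr_expression"] = {
            "n": len(genes), "median_rpkm_1": float(np.median(r1)) if genes
            else np.nan,
            "median_rpkm_2": float(np.median(r2)) if genes else np.nan,
            "wilcoxon_p": float(p)}
    if enhancer_ndr_states is not None and len(enhancer_ndr_states):
        table = pd.crosstab(enhancer_ndr_states["mode"],
                            enhancer_ndr_states["state"])
        if table.shape[0] > 1 and table.shape[1] > 1:
            chi2, p, _, _ = stats.chi2_contingency(table)
        else:
            chi2, p = np.nan, np.nan
        report["mode_state_independence"] = {
            "table": table, "chi2": float(chi2), "p": float(p)}
    return report
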