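"""Enhancer calling and chromatin-state classification.

Enhancers are H3K4me1-enriched regions found by a Poisson sliding-window
scan (1000-bp windows, 100-bp step) with Benjamini-Hochberg control at
q <= 0.001. Peaks from the two conditions are pooled, peaks closer than
500 bp collapse to the higher-scoring one, and survivors mostly covered by
promoters are dropped. Each enhancer gets per-mark +/-3 kb profiles (120
windows of 50 bp, self-normalized) and a state per condition:

* active        H3K4me1+ / H3K27ac+ / H3K27me3-
* poised        H3K4me1+ / H3K27ac- / H3K27me3+
* intermediate  everything else
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .config import PipelineConfig
from .intervals import ChromSizes
from .nucleosomes import reads_to_dyads

STATES = ("active", "poised", "intermediate")


def window_scan(reads: pd.DataFrame, sizes: ChromSizes, cfg: PipelineConfig
                ) -> pd.DataFrame:
    """Count read midpoints in sliding windows and attach Poisson p-values.

    The null is a genome-wide uniform rate: lambda = total midpoints x
    window / genome length. Returns one row per window with count, fold
    enrichment and BH-adjusted q-value.
    """
    if len(reads) == 0:
        raise ValueError("no reads: cannot call peaks")
    midpoints, _ = reads_to_dyads(reads, sizes, cfg.nucleosome_len_bp)
    total = sum(int(v.size) for v in midpoints.values())
    if total == 0:
        raise ValueError("no usable reads after extension")
    genome_len = sum(sizes.values())
    lam = total * cfg.enhancer_window_bp / genome_len
    frames = []
    for chrom in sorted(sizes):
        mids = np.sort(midpoints.get(chrom, np.empty(0, dtype=np.int64)))
        starts = np.arange(0, max(1, sizes[chrom] - cfg.enhancer_window_bp + 1),
                           cfg.enhancer_step_bp)
        ends = starts + cfg.enhancer_window_bp
        counts = (np.searchsorted(mids, ends, side="left")
                  - np.searchsorted(mids, starts, side="left"))
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                    "end": ends, "count": counts}))
    windows = pd.concat(frames, ignore_index=True)
    windows["fold"] = windows["count"] / lam
    pvals = stats.poisson.sf(windows["count"].to_numpy() - 1, lam)
    windows["q_value"] = stats.false_discovery_control(pvals, method="bh")
    return windows


def call_peaks(reads: pd.DataFrame, sizes: ChromSizes, cfg: PipelineConfig
               ) -> pd.DataFrame:
    """Merge significant windows (q <= enhancer_fdr) into scored peaks."""
    windows = window_scan(reads, sizes, cfg)
    sig = windows[windows["q_value"] <= cfg.enhancer_fdr]
    rows = []
    for chrom, sub in sig.groupby("chrom", observed=True):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        cur_score = 0.0
        for row in sub.itertuples():
            if cur_s is None:
                cur_s, cur_e, cur_score = row.start, row.end, row.fold
            elif row.start <= cur_e:
                cur_e = max(cur_e, row.end)
                cur_score = max(cur_score, row.fold)
            else:
                rows.append((chrom, cur_s, cur_e, cur_score))
                cur_s, cur_e, cur_score = row.start, row.end, row.fold
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, cur_score))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


def _overlap_with_set(chrom: str, start: int, end: int,
                      iv_starts: np.ndarray, iv_ends: np.ndarray) -> int:
    if iv_starts.size == 0:
        return 0
    ov = np.minimum(end, iv_ends) - np.maximum(start, iv_starts)
    return int(np.clip(ov, 0, None).sum())


def merge_and_filter(peaks_1: pd.DataFrame, peaks_2: pd.DataFrame,
                     promoters: pd.DataFrame, cfg: PipelineConfig
                     ) -> pd.DataFrame:
    """Pool condition peaks, collapse near-duplicates, drop promoter peaks.

    Any two peaks with an inter-peak gap below ``enhancer_merge_bp`` reduce
    to the higher-scoring one (left wins ties); the rule is applied
    left-to-right and iterated to a fixpoint. A survivor is dropped when at
    least ``enhancer_promoter_overlap_frac`` of its length lies inside the
    promoter set. Returns the enhancer table with centers.
    """
    parts = [p for p in (peaks_1, peaks_2) if len(p)]
    peaks = (pd.concat(parts, ignore_index=True) if parts
             else peaks_1.copy())
    peaks = peaks.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    changed = True
    while changed:
        changed = False
        keep = np.ones(len(peaks), dtype=bool)
        arr = peaks.to_records(index=False)
        prev = None
        for i in range(len(arr)):
            if not keep[i]:
                continue
            if prev is not None and arr[i]["chrom"] == arr[prev]["chrom"] \
                    and arr[i]["start"] - arr[prev]["end"] < cfg.enhancer_merge_bp:
                if arr[i]["score"] > arr[prev]["score"]:
                    keep[prev] = False
                    prev = i
                else:
                    keep[i] = False
                changed = True
            else:
                prev = i
        peaks = peaks[keep].reset_index(drop=True)
    # promoter-overlap filter (promoters merged per chromosome)
    keep_rows = []
    for row in peaks.itertuples():
        p = promoters[promoters["chrom"] == row.chrom]
        ov = _overlap_with_set(row.chrom, row.start, row.end,
                               p["start"].to_numpy(), p["end"].to_numpy())
        if ov < cfg.enhancer_promoter_overlap_frac * (row.end - row.start):
            keep_rows.append(row.Index)
    out = peaks.loc[keep_rows].reset_index(drop=True)
    out["center"] = (out["start"] + out["end"]) // 2
    out.insert(0, "enh_id", [f"enh{i:04d}" for i in range(len(out))])
    return out


def build_enhancer_profiles(enhancers: pd.DataFrame,
                            reads: pd.DataFrame, sizes: ChromSizes,
                            cfg: PipelineConfig) -> np.ndarray:
    """Per-enhancer +/-3 kb profile of one library, 50-bp windows.

    Each row is normalized by its own total read count, so profiles are
    invariant to library depth; zero-read regions stay all-zero.
    """
    flank = cfg.enhancer_profile_flank_bp
    bin_bp = cfg.enhancer_profile_bin_bp
    n_bins = 2 * flank // bin_bp
    midpoints, _ = reads_to_dyads(reads, sizes, cfg.nucleosome_len_bp)
    by_chrom = {c: np.sort(v) for c, v in midpoints.items()}
    mat = np.zeros((len(enhancers), n_bins))
    for i, row in enumerate(enhancers.itertuples()):
        mids = by_chrom.get(row.chrom)
        if mids is None or mids.size == 0:
            continue
        lo = np.searchsorted(mids, row.center - flank, side="left")
        hi = np.searchsorted(mids, row.center + flank, side="left")
        window = mids[lo:hi]
        idx = (window - (row.center - flank)) // bin_bp
        counts = np.bincount(idx.astype(np.int64), minlength=n_bins).astype(float)
        s = counts.sum()
        mat[i] = counts / s if s > 0 else counts
    return mat


def enhancer_mark_totals(enhancers: pd.DataFrame, reads: pd.DataFrame,
                         sizes: ChromSizes, cfg: PipelineConfig,
                         halfwidth_bp: int = 500) -> np.ndarray:
    """Raw read-midpoint counts in enhancer center +/- halfwidth."""
    midpoints, _ = reads_to_dyads(reads, sizes, cfg.nucleosome_len_bp)
    by_chrom = {c: np.sort(v) for c, v in midpoints.items()}
    counts = np.zeros(len(enhancers))
    for i, row in enumerate(enhancers.itertuples()):
        mids = by_chrom.get(row.chrom)
        if mids is None:
            continue
        counts[i] = (np.searchsorted(mids, row.center + halfwidth_bp)
                     - np.searchsorted(mids, row.center - halfwidth_bp))
    return counts


def mark_positive_2means(counts: np.ndarray, expected_background: float,
                         cfg: PipelineConfig, seed: int | None = None
                         ) -> np.ndarray:
    """Mark positivity by 2-means on log(1 + count) totals.

    Falls back to a fixed 2x-background threshold when the two clusters are
    not clearly separated (< 2x ratio of mean raw counts) or collapse into
    one group.
    """
    if seed is None:
        seed = cfg.rng_seed
    fallback = counts > 2.0 * expected_background
    if counts.size < 2 or np.allclose(counts, counts[0]):
        return fallback
    feats = np.log1p(counts)[:, None]
    labels = KMeans(n_clusters=2, n_init=10, random_state=seed).fit_predict(feats)
    means = np.array([counts[labels == k].mean() if (labels == k).any()
                      else 0.0 for k in range(2)])
    hi, lo = means.max(), means.min()
    if lo > 0 and hi / lo < 2.0:
        return fallback
    positive = labels == int(np.argmax(means))
    if positive.all() or (~positive).all():
        return fallback
    return positive


def classify_enhancer_state(positivity: dict[tuple[str, str], np.ndarray],
                            conditions: tuple[str, str] = ("cond1", "cond2"),
                            poised_requires_k27me3: bool = True
                            ) -> pd.DataFrame:
    """Apply the three-way state rule per condition.

    ``positivity`` maps (mark, condition) to boolean vectors. With
    ``poised_requires_k27me3`` False, poised relaxes to
    H3K4me1+/H3K27ac- regardless of H3K27me3 (an alternative convention
    seen for poised enhancers).
    """
    n = len(next(iter(positivity.values())))
    out = {}
    for cond in conditions:
        k4me1 = positivity[("H3K4me1", cond)]
        k27ac = positivity[("H3K27ac", cond)]
        k27me3 = positivity[("H3K27me3", cond)]
        state = np.full(n, "intermediate", dtype=object)
        state[k4me1 & k27ac & ~k27me3] = "active"
        if poised_requires_k27me3:
            state[k4me1 & ~k27ac & k27me3] = "poised"
        else:
            state[k4me1 & ~k27ac] = "poised"
        out[f"state_{cond}"] = state
    return pd.DataFrame(out)


def transition_table(states: pd.DataFrame,
                     conditions: tuple[str, str] = ("cond1", "cond2")
                     ) -> tuple[pd.DataFrame, float]:
    """Counts of state pairs across conditions and poised persistence.

    Persistence is the fraction of condition-1 poised enhancers that remain
    poised in condition 2 (NaN when there are none).
    """
    c1, c2 = (states[f"state_{c}"] for c in conditions)
    table = pd.crosstab(c1, c2).reindex(index=STATES, columns=STATES,
                                        fill_value=0)
    n_poised = int((c1 == "poised").sum())
    persistence = (float(((c1 == "poised") & (c2 == "poised")).sum() / n_poised)
                   if n_poised else float("nan"))
    return table, persistence
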