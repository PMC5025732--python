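"""Cross-condition nucleosome dynamics.

Each called nucleosome is paired with the closest call of the other
condition on the same chromosome; the footprint overlap implied by the dyad
distance (overlap = max(0, 147 - distance)) classifies it:

* distance 0            -> fixed (the pair counts once)
* overlap <= 20 bp      -> lost (condition-1 call) or gained (condition-2)
* otherwise             -> shift (each condition's call counts once)

Headline fractions use this unit scheme, whose denominator is the union of
calls with fixed pairs counted once; a per-call convention (fixed calls
counted once per condition) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import ChromSizes
from .nucleosomes import OccupancyTrack

LABELS = ("fixed", "shift", "lost", "gained")


def match_nearest(calls_a: pd.DataFrame, calls_b: pd.DataFrame
                  ) -> pd.DataFrame:
    """For every call in ``calls_a``, the nearest call of ``calls_b``.

    Nearness is |dyad difference| on the same chromosome; ties resolve to
    the smaller partner coordinate. Calls on chromosomes absent from the
    other set get partner = -1 and distance = inf.

    Returns a copy of ``calls_a`` with columns partner_dyad and distance.
    """
    partner = np.full(len(calls_a), -1, dtype=np.int64)
    distance = np.full(len(calls_a), np.inf)
    by_chrom = {c: np.sort(s["dyad"].to_numpy())
                for c, s in calls_b.groupby("chrom", observed=True)}
    for chrom, sub in calls_a.groupby("chrom", observed=True):
        other = by_chrom.get(chrom)
        if other is None or other.size == 0:
            continue
        pos = sub["dyad"].to_numpy()
        right = np.searchsorted(other, pos, side="left")
        left = np.clip(right - 1, 0, other.size - 1)
        right = np.clip(right, 0, other.size - 1)
        d_left = np.abs(pos - other[left])
        d_right = np.abs(pos - other[right])
        # strict < keeps the left (smaller-coordinate) partner on ties
        use_right = d_right < d_left
        best = np.where(use_right, other[right], other[left])
        idx = sub.index.to_numpy()
        partner[idx] = best
        distance[idx] = np.where(use_right, d_right, d_left)
    out = calls_a.copy()
    out["partner_dyad"] = partner
    out["distance"] = distance
    return out


@dataclass
class DynamicsSummary:
    """Class counts and fractions under both denominators."""

    unit_counts: dict[str, int]
    unit_fractions: dict[str, float]
    call_counts: dict[str, int]
    call_fractions: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for label in LABELS:
            rows.append((label, self.unit_counts[label],
                         self.unit_fractions[label],
                         self.call_counts[label],
                         self.call_fractions[label]))
        return pd.DataFrame(rows, columns=["label", "units", "unit_fraction",
                                           "calls", "call_fraction"])


def classify_dynamics(calls_1: pd.DataFrame, calls_2: pd.DataFrame,
                      cfg: PipelineConfig
                      ) -> tuple[pd.DataFrame, DynamicsSummary]:
    """Label every call fixed / shift / lost / gained.

    Returns the record table (one row per classified unit: a fixed pair is a
    single row with both dyads; every other row carries one condition's
    call) and the summary fractions.
    """
    nuc_len = cfg.nucleosome_len_bp
    max_ov = cfg.gain_loss_max_overlap_bp
    m1 = match_nearest(calls_1, calls_2)
    m2 = match_nearest(calls_2, calls_1)

    rows = []
    for row in m1.itertuples():
        dist = row.distance
        overlap = max(0.0, nuc_len - dist) if np.isfinite(dist) else 0.0
        if np.isfinite(dist) and dist == 0:
            rows.append((row.chrom, row.dyad, row.partner_dyad, 0.0, overlap,
                         "fixed"))
        elif overlap <= max_ov:
            rows.append((row.chrom, row.dyad, -1, dist, overlap, "lost"))
        else:
            rows.append((row.chrom, row.dyad, row.partner_dyad, dist, overlap,
                         "shift"))
    for row in m2.itertuples():
        dist = row.distance
        overlap = max(0.0, nuc_len - dist) if np.isfinite(dist) else 0.0
        if np.isfinite(dist) and dist == 0:
            continue  # already recorded once from the condition-1 side
        if overlap <= max_ov:
            rows.append((row.chrom, -1, row.dyad, dist, overlap, "gained"))
        else:
            rows.append((row.chrom, -1, row.dyad, dist, overlap, "shift"))
    records = pd.DataFrame(
        rows, columns=["chrom", "dyad_1", "dyad_2", "distance", "overlap",
                       "label"])

    unit_counts = {lab: int((records["label"] == lab).sum()) for lab in LABELS}
    n_units = max(1, len(records))
    unit_fractions = {lab: unit_counts[lab] / n_units for lab in LABELS}
    # per-call convention: a fixed pair contributes one call per condition
    call_counts = dict(unit_counts)
    call_counts["fixed"] *= 2
    n_calls = max(1, sum(call_counts.values()))
    call_fractions = {lab: call_counts[lab] / n_calls for lab in LABELS}
    summary = DynamicsSummary(unit_counts, unit_fractions, call_counts,
                              call_fractions)
    return records, summary


def compare_windows(track_1: OccupancyTrack, track_2: OccupancyTrack,
                    sizes: ChromSizes, window_bp: int = 200,
                    delta_threshold: float = 0.0) -> pd.DataFrame:
    """Tile the genome in non-overlapping windows and compare occupancy.

    Window occupancy is the mean RPM of the bins it covers; difference is
    condition 2 minus condition 1.
    """
    if set(track_1.values) != set(track_2.values):
        raise ValueError("tracks cover different chromosome sets")
    if track_1.bin_bp != track_2.bin_bp:
        raise ValueError("tracks are on different bin grids")
    bin_bp = track_1.bin_bp
    bins_per_window = window_bp // bin_bp
    frames = []
    for chrom in sorted(sizes):
        v1, v2 = track_1.values[chrom], track_2.values[chrom]
        n_win = v1.size // bins_per_window
        if n_win == 0:
            continue
        m1 = v1[: n_win * bins_per_window].reshape(n_win, -1).mean(axis=1)
        m2 = v2[: n_win * bins_per_window].reshape(n_win, -1).mean(axis=1)
        starts = np.arange(n_win) * window_bp
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + window_bp,
            "occupancy_1": m1, "occupancy_2": m2, "difference": m2 - m1}))
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=["chrom", "start", "end", "occupancy_1",
                                      "occupancy_2", "difference"]))
    out.attrs["n_increased"] = int((out["difference"] > delta_threshold).sum())
    out.attrs["n_decreased"] = int((out["difference"] < -delta_threshold).sum())
    return out
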