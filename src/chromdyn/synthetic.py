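"""Two-condition synthetic genome with fully known ground truth.

The simulator emulates the differentiation experiment the pipeline
analyzes: a small genome tiled with nucleosomes at regular spacing, a
planted mix of positioning events between two conditions (fixed / shift /
lost / gained), promoters with planted histone states and open/closed
[-200, +50] windows, enhancers with planted chromatin states and NDRs
formed by eviction or directional shift, stranded single-end 49-bp reads
for MNase and five ChIP marks, and an expression table coupled to the
planted chromatin.

Everything derives deterministically from ``SimParams.rng_seed``; each
track uses an independent child stream so simulating one track never
perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CONDITIONS, MARKS, SimParams
from .intervals import ChromSizes
from . import io as cio

ARCHETYPES = ("stable_active", "up", "down", "repressed", "bivalent",
              "silent")

# per-archetype promoter truth: (K4me3, K9ac, K27me3, open) per condition
_PROMOTER_PATTERNS = {
    "stable_active": {"cond1": (True, True, False, True),
                      "cond2": (True, True, False, True)},
    "up":            {"cond1": (False, False, False, False),
                      "cond2": (True, True, False, True)},
    "down":          {"cond1": (True, True, False, True),
                      "cond2": (False, False, False, False)},
    "repressed":     {"cond1": (False, False, True, False),
                      "cond2": (False, False, True, False)},
    "bivalent":      {"cond1": (True, False, True, False),
                      "cond2": (True, False, True, False)},
    "silent":        {"cond1": (False, False, False, False),
                      "cond2": (False, False, False, False)},
}

# mean RPKM per condition by archetype (active promoters express highest,
# repressed lowest; up/down genes change by the planted fold)
_BASE_RPKM = {"stable_active": 50.0, "down": 20.0, "up": 10.0,
              "bivalent": 5.0, "silent": 4.0, "repressed": 2.0}

# enhancer mark truth per state: (K4me1, K27ac, K27me3)
_ENHANCER_PATTERNS = {
    "active": (True, True, False),
    "poised": (True, False, True),
    "intermediate": (True, False, False),
}

_STATE_TRANSITIONS = {
    "active": (("active", 0.85), ("intermediate", 0.10), ("poised", 0.05)),
    "poised": (("poised", 0.89), ("active", 0.06), ("intermediate", 0.05)),
    "intermediate": (("intermediate", 0.80), ("active", 0.10),
                     ("poised", 0.10)),
}

_GENE_SLOT = 3500
_ENH_SLOT = 3000
_MARGIN = 2000
_ENHANCER_HALF = 400          # planted enhancer interval = center +/- 400


@dataclass
class SyntheticStudy:
    """Simulated inputs plus the truth tables behind them."""

    params: SimParams
    sizes: ChromSizes
    genes: pd.DataFrame          # gene_id chrom start end strand tss archetype
    enhancers: pd.DataFrame      # enh_id chrom start end center state_1
    #                              state_2 has_ndr ndr_mode ndr_start ndr_end
    nucleosomes: pd.DataFrame    # chrom dyad_1 dyad_2 weight (-1 = absent)
    promoter_states: pd.DataFrame  # gene_id condition marks... state open
    expression: pd.DataFrame     # gene_id rpkm_1 rpkm_2 q_value + truth cols

    def _rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng([self.params.rng_seed & 0x7FFFFFFF, *key])

    # -- truth summaries -------------------------------------------------
    def truth_event_label(self) -> pd.Series:
        """Event label per nucleosome entity, derived from the dyads.

        A relocation larger than the 20-bp-overlap rule allows for a shift
        is, by the classifier's own taxonomy, one lost plus one gained
        nucleosome ("relocated" here).
        """
        d1 = self.nucleosomes["dyad_1"].to_numpy()
        d2 = self.nucleosomes["dyad_2"].to_numpy()
        dist = np.abs(d1 - d2)
        label = np.full(len(d1), "shift", dtype=object)
        label[(d1 >= 0) & (d2 < 0)] = "lost"
        label[(d1 < 0) & (d2 >= 0)] = "gained"
        both = (d1 >= 0) & (d2 >= 0)
        label[both & (dist == 0)] = "fixed"
        label[both & (147 - dist <= 20)] = "relocated"
        return pd.Series(label, index=self.nucleosomes.index)

    def truth_unit_fractions(self) -> dict[str, float]:
        """Planted class fractions in classifier units.

        A fixed pair is one unit; a shifted nucleosome is one unit per
        condition; lost and gained are one unit each; a relocation counts
        as one lost plus one gained.
        """
        lab = self.truth_event_label()
        counts = {
            "fixed": int((lab == "fixed").sum()),
            "shift": 2 * int((lab == "shift").sum()),
            "lost": int((lab == "lost").sum()) + int((lab == "relocated").sum()),
            "gained": (int((lab == "gained").sum())
                       + int((lab == "relocated").sum())),
        }
        total = sum(counts.values())
        return {k: v / total for k, v in counts.items()}

    def dyads_for(self, condition: str) -> pd.DataFrame:
        col = {"cond1": "dyad_1", "cond2": "dyad_2"}[condition]
        sub = self.nucleosomes[self.nucleosomes[col] >= 0]
        return pd.DataFrame({"chrom": sub["chrom"], "dyad": sub[col],
                             "weight": sub["weight"]})

    def mnase_read_counts(self, condition: str) -> np.ndarray:
        """Realized MNase reads allocated to each nucleosome entity.

        Aligned with ``self.nucleosomes`` (0 where the entity is absent from
        the condition). Reproduces exactly the multinomial allocation that
        :meth:`mnase_reads` samples for the same condition.
        """
        rng = self._rng(0, CONDITIONS.index(condition))
        dyads, counts, _ = _mnase_allocation(self, condition, rng)
        out = np.zeros(len(self.nucleosomes), dtype=np.int64)
        if counts.size:
            out[dyads.index.to_numpy()] = counts
        return out

    def truth_depleted_intervals(self, condition: str = "cond2",
                                 min_len_bp: int = 150,
                                 require_prior: bool = True,
                                 visible_mask: np.ndarray | None = None,
                                 prior_mask: np.ndarray | None = None
                                 ) -> pd.DataFrame:
        """Geometric oracle: gaps left between planted nucleosome footprints.

        A truth NDR is a stretch of >= ``min_len_bp`` not covered by any
        planted 147-bp footprint in ``condition``; with ``require_prior`` it
        must also contain a planted dyad of the other condition (i.e. it
        formed rather than being constitutively open). Computed purely from
        the planted dyads, independent of any detection code. The optional
        boolean masks (aligned with ``self.nucleosomes``) restrict which
        entities count as present — e.g. only nucleosomes that actually
        received reads in the simulated library (:meth:`mnase_read_counts`).
        """
        other = "cond1" if condition == "cond2" else "cond2"
        rows = []
        n = len(self.nucleosomes)
        visible = np.ones(n, bool) if visible_mask is None else visible_mask
        prior_vis = np.ones(n, bool) if prior_mask is None else prior_mask
        chrom_arr = self.nucleosomes["chrom"].to_numpy()
        for chrom in self.sizes:
            on_chrom = chrom_arr == chrom
            sub = self.nucleosomes[on_chrom & visible]
            col = {"cond1": "dyad_1", "cond2": "dyad_2"}[condition]
            d = np.sort(sub.loc[sub[col] >= 0, col].to_numpy())
            ocol = {"cond1": "dyad_1", "cond2": "dyad_2"}[other]
            osub = self.nucleosomes[on_chrom & prior_vis]
            od = np.sort(osub.loc[osub[ocol] >= 0, ocol].to_numpy())
            # complement of merged footprints (dyad +/- 73)
            gaps_start = d[:-1] + 74
            gaps_end = d[1:] - 73
            for s, e in zip(gaps_start, gaps_end):
                if e - s < min_len_bp:
                    continue
                if require_prior:
                    k = np.searchsorted(od, [s, e])
                    if k[1] == k[0]:
                        continue
                rows.append((chrom, int(s), int(e)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    # -- read simulation -------------------------------------------------
    def mnase_reads(self, condition: str) -> pd.DataFrame:
        """MNase-seq reads for one condition (see simulate_mnase_reads)."""
        return simulate_mnase_reads(
            self, condition, self._rng(0, CONDITIONS.index(condition)))

    def chip_reads(self, mark: str, condition: str) -> pd.DataFrame:
        if mark not in MARKS:
            raise ValueError(f"unknown mark {mark!r}")
        return simulate_chip_reads(
            self, mark, condition,
            self._rng(1 + MARKS.index(mark), CONDITIONS.index(condition)))


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def simulate_genome(params: SimParams,
                    rng: np.random.Generator | None = None
                    ) -> tuple[ChromSizes, pd.DataFrame, pd.DataFrame]:
    """Lay out chromosomes, genes and enhancer skeletons without overlap.

    Genes and enhancers occupy alternating slots (shuffled order) with all
    enhancer centers at least the promoter flank away from every TSS.
    Raises when the requested features cannot be packed.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed & 0x7FFFFFFF)
    names = _chrom_names(params.n_chrom)
    sizes = ChromSizes({c: params.chrom_len for c in names})
    genes_per = _split_counts(params.n_genes, params.n_chrom)
    enh_per = _split_counts(params.n_enhancers, params.n_chrom)
    gene_rows, enh_rows = [], []
    g_idx = e_idx = 0
    for ci, chrom in enumerate(names):
        slots = ["gene"] * genes_per[ci] + ["enh"] * enh_per[ci]
        need = (2 * _MARGIN + genes_per[ci] * _GENE_SLOT
                + enh_per[ci] * _ENH_SLOT)
        if need > params.chrom_len:
            raise ValueError(
                f"cannot pack {genes_per[ci]} genes and {enh_per[ci]} "
                f"enhancers into {chrom} ({params.chrom_len} bp); "
                "increase chrom_len or reduce feature counts")
        order = rng.permutation(len(slots))
        slots = [slots[i] for i in order]
        slack = params.chrom_len - need
        gap = slack // (len(slots) + 1) if slots else 0
        pos = _MARGIN + gap
        for kind in slots:
            if kind == "gene":
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    tss = pos + 1200
                    start, end = tss, tss + 2000
                else:
                    start, end = pos + 300, pos + 2300
                    tss = end - 1
                gene_rows.append((f"g{g_idx:04d}", chrom, start, end, strand,
                                  tss))
                g_idx += 1
                pos += _GENE_SLOT + gap
            else:
                center = pos + _ENH_SLOT // 2
                enh_rows.append((f"E{e_idx:04d}", chrom,
                                 center - _ENHANCER_HALF,
                                 center + _ENHANCER_HALF, center))
                e_idx += 1
                pos += _ENH_SLOT + gap
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start",
                                             "end", "strand", "tss"])
    enhancers = pd.DataFrame(enh_rows, columns=["enh_id", "chrom", "start",
                                                "end", "center"])
    return sizes, genes, enhancers


def _split_counts(total: int, n: int) -> list[int]:
    base = total // n
    out = [base] * n
    for i in range(total - base * n):
        out[i] += 1
    return out


def _assign_archetypes(n: int, params: SimParams, rng: np.random.Generator,
                       up_bias_idx: np.ndarray | None = None) -> np.ndarray:
    """Distribute gene archetypes at the configured fractions.

    ``up_bias_idx`` marks genes (by position) preferentially given the
    "up" archetype — used to couple expression gain to enhancer NDR
    formation, as differentiation-activated genes are the ones whose
    enhancers open.
    """
    fracs = {"up": params.frac_up, "down": params.frac_down,
             "repressed": params.frac_repressed,
             "bivalent": params.frac_bivalent, "silent": params.frac_silent}
    counts = {k: int(round(v * n)) for k, v in fracs.items()}
    n_rest = n - sum(counts.values())
    if n_rest < 0:
        raise ValueError("archetype fractions exceed 1")
    out = np.empty(n, dtype=object)
    w = np.ones(n)
    if up_bias_idx is not None and len(up_bias_idx):
        w[up_bias_idx] = 10.0
    n_up = min(counts.get("up", 0), n)
    up_idx = (rng.choice(n, size=n_up, replace=False, p=w / w.sum())
              if n_up else np.empty(0, dtype=np.int64))
    out[up_idx] = "up"
    rest_labels = (["stable_active"] * n_rest
                   + [k for k, c in counts.items() if k != "up"
                      for _ in range(c)])
    rest_idx = np.setdiff1d(np.arange(n), up_idx)
    out[rest_idx] = np.array(rest_labels, dtype=object)[
        rng.permutation(len(rest_labels))]
    return out


# P(enhancer state_1) given the expression tier of the nearest gene: genes
# flanked by active enhancers express highest, by poised enhancers lowest
_STATE_BY_TIER = {
    "high": (0.65, 0.10, 0.25),
    "mid": (0.30, 0.40, 0.30),
    "low": (0.10, 0.65, 0.25),
}


def _plant_enhancer_states(tiers: np.ndarray, rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    state_1 = np.array([
        rng.choice(["active", "poised", "intermediate"],
                   p=_STATE_BY_TIER[t]) for t in tiers], dtype=object)
    state_2 = np.empty(len(tiers), dtype=object)
    for i, s1 in enumerate(state_1):
        targets, probs = zip(*[(t, p) for t, p in _STATE_TRANSITIONS[s1]])
        state_2[i] = rng.choice(targets, p=np.array(probs) / sum(probs))
    return state_1, state_2


def _expression_tier(archetype: str) -> str:
    base = _BASE_RPKM[archetype]
    if base >= 20.0:
        return "high"
    if base <= 5.0:
        return "low"
    return "mid"


def _nearest_gene(enhancers: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    out = np.empty(len(enhancers), dtype=object)
    by_chrom = {c: s.reset_index(drop=True)
                for c, s in genes.groupby("chrom")}
    for i, row in enumerate(enhancers.itertuples()):
        sub = by_chrom[row.chrom]
        j = int(np.argmin(np.abs(sub["tss"].to_numpy() - row.center)))
        out[i] = sub["gene_id"].iloc[j]
    return out


def _enhancer_core(center: int, has_ndr: bool, mode: str | None,
                   params: SimParams, rng: np.random.Generator
                   ) -> tuple[list[tuple[int, int]], tuple[int, int] | None]:
    """Planted dyad pairs (cond1, cond2) around one enhancer center.

    Geometry: an evicted nucleosome sits at the future NDR center; a
    shifting nucleosome starts offset from the center and moves 150-200 bp
    away, with the vacated footprint plus the adjacent linker forming the
    depleted run. Flanking nucleosomes delimiting the gap undergo the same
    small positional shifts as the genome-wide landscape, directed away
    from the gap so within-condition spacing never drops below the caller's
    exclusion zone (their condition-2 position anchors the gap). -1 marks
    absence in a condition.
    """
    lo, hi = params.shift_range_bp

    def flank(anchor: int, away: int) -> tuple[int, int]:
        s = int(rng.integers(lo, hi + 1))
        return anchor + away * s, anchor

    def middle(anchor: int) -> tuple[int, int]:
        # capped at 26 bp: keeps >= 147 bp to flanks displaced >= 10 bp away
        s = int(rng.integers(lo, max(lo, min(hi, 26)) + 1))
        s *= -1 if rng.random() < 0.5 else 1
        return anchor + s, anchor

    off = params.ndr_len_bp // 2 + 73  # flank dyads delimiting a planted gap
    if not has_ndr:
        return [flank(center - off, -1), middle(center),
                flank(center + off, +1)], None
    if mode == "eviction":
        pairs = [flank(center - off, -1), (center, -1),
                 flank(center + off, +1)]
        ndr = (center - off + 74, center + off - 73)
        return pairs, ndr
    d = int(rng.integers(params.ndr_shift_range_bp[0],
                         params.ndr_shift_range_bp[1] + 1))
    g = d - 26  # cond1 linker sized so the composite peak sits ~60 bp off
    if mode == "shift_upstream":
        p = center - 60
        pairs = [flank(p - d - 200, -1), (p, p - d),
                 flank(p + 146 + g, +1)]
        ndr = (p - d + 74, p + 73 + g)
    elif mode == "shift_downstream":
        p = center + 60
        pairs = [flank(p - 146 - g, -1), (p, p + d),
                 flank(p + d + 200, +1)]
        ndr = (p - 72 - g, p + d - 73)
    else:
        raise ValueError(f"unknown NDR mode {mode!r}")
    return pairs, ndr


def simulate_study(params: SimParams | None = None) -> SyntheticStudy:
    """Build the full two-condition study (genome, truth, expression)."""
    params = params or SimParams()
    root = np.random.default_rng(params.rng_seed & 0x7FFFFFFF)
    sizes, genes, enhancers = simulate_genome(params, root)

    genes = genes.copy()
    nearest = _nearest_gene(enhancers, genes)

    # NDR enhancers are drawn first; the genes they flank are then biased
    # toward the up-regulated archetype (enhancer opening activates its
    # target), and enhancer chromatin states couple to the expression tier
    # of the nearest gene
    n_ndr = int(round(params.enhancer_ndr_frac * len(enhancers)))
    has_ndr = np.zeros(len(enhancers), dtype=bool)
    if n_ndr:
        has_ndr[root.choice(len(enhancers), size=n_ndr, replace=False)] = True
    gene_pos = {g: i for i, g in enumerate(genes["gene_id"])}
    linked = (np.unique([gene_pos[g] for g in nearest[has_ndr]])
              if has_ndr.any() else None)
    genes["archetype"] = _assign_archetypes(len(genes), params, root, linked)
    arch_of = dict(zip(genes["gene_id"], genes["archetype"]))
    tiers = np.array([_expression_tier(arch_of[g]) for g in nearest])
    state_1, state_2 = _plant_enhancer_states(tiers, root)
    enhancers = enhancers.assign(gene_id=nearest, state_1=state_1,
                                 state_2=state_2)
    modes = np.full(len(enhancers), "", dtype=object)
    if n_ndr:
        mode_pool = root.choice(["eviction", "shift_upstream",
                                 "shift_downstream"], size=n_ndr,
                                p=list(params.ndr_mode_mix))
        modes[has_ndr] = mode_pool
    enhancers["has_ndr"] = has_ndr
    enhancers["ndr_mode"] = modes

    # --- nucleosome entities: planted enhancer cores + background tiling --
    rows: list[tuple[str, int, int]] = []
    ndr_starts = np.full(len(enhancers), -1, dtype=np.int64)
    ndr_ends = np.full(len(enhancers), -1, dtype=np.int64)
    core_pos: dict[str, list[int]] = {c: [] for c in sizes}
    keepout: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}
    for i, row in enumerate(enhancers.itertuples()):
        pairs, ndr = _enhancer_core(row.center, row.has_ndr, row.ndr_mode
                                    or None, params, root)
        rows.extend((row.chrom, a, b) for a, b in pairs)
        core_pos[row.chrom].extend(p for pair in pairs for p in pair if p >= 0)
        if ndr is not None:
            ndr_starts[i], ndr_ends[i] = ndr
            keepout[row.chrom].append((int(ndr[0]) - 74, int(ndr[1]) + 74))
    enhancers["ndr_start"] = ndr_starts
    enhancers["ndr_end"] = ndr_ends

    # background grid avoids planted cores (no two dyads closer than an
    # exclusion zone in either condition) and planted depleted gaps
    mix = np.array(params.event_mix)
    clear_dist = 147 + 2 * params.shift_range_bp[1]
    for chrom in sizes:
        grid = np.arange(100, sizes[chrom] - 100, params.nucleosome_spacing_bp)
        clear = np.zeros(grid.size, dtype=bool)
        cores = np.array(sorted(core_pos[chrom]), dtype=np.int64)
        if cores.size:
            idx = np.searchsorted(cores, grid)
            left = cores[np.clip(idx - 1, 0, cores.size - 1)]
            right = cores[np.clip(idx, 0, cores.size - 1)]
            near = np.minimum(np.abs(grid - left), np.abs(grid - right))
            clear |= near < clear_dist
        for lo, hi in keepout[chrom]:
            clear |= (grid >= lo) & (grid < hi)
        grid = grid[~clear]
        events = root.choice(4, size=grid.size, p=mix)
        shifts = root.integers(params.shift_range_bp[0],
                               params.shift_range_bp[1] + 1, size=grid.size)
        signs = root.choice([-1, 1], size=grid.size)
        for g, ev, s in zip(grid, events, shifts * signs):
            if ev == 0:
                rows.append((chrom, int(g), int(g)))
            elif ev == 1:
                rows.append((chrom, int(g), int(g + s)))
            elif ev == 2:
                rows.append((chrom, int(g), -1))
            else:
                rows.append((chrom, -1, int(g)))

    nucs = pd.DataFrame(rows, columns=["chrom", "dyad_1", "dyad_2"])
    nucs["weight"] = root.gamma(params.occupancy_gamma_shape, 1.0,
                                size=len(nucs))

    # --- promoter truth and open-window carving -------------------------
    prom_rows = []
    for row in genes.itertuples():
        pat = _PROMOTER_PATTERNS[row.archetype]
        for cond in CONDITIONS:
            k4me3, k9ac, k27me3, is_open = pat[cond]
            prom_rows.append((row.gene_id, cond, k4me3, k9ac, k27me3,
                              False, False, _combined(k4me3, k9ac, k27me3),
                              is_open))
            if is_open:
                w0, w1 = _promoter_window(row)
                col = "dyad_1" if cond == "cond1" else "dyad_2"
                hit = ((nucs["chrom"] == row.chrom)
                       & (nucs[col] >= w0 - 73) & (nucs[col] < w1 + 73))
                nucs.loc[hit, col] = -1
    nucs = nucs[(nucs["dyad_1"] >= 0) | (nucs["dyad_2"] >= 0)]
    nucs = nucs.reset_index(drop=True)
    promoter_states = pd.DataFrame(
        prom_rows, columns=["gene_id", "condition", "H3K4me3", "H3K9ac",
                            "H3K27me3", "H3K4me1", "H3K27ac", "state",
                            "open"])

    expression = simulate_expression(genes, params, root)
    return SyntheticStudy(params=params, sizes=sizes, genes=genes,
                          enhancers=enhancers, nucleosomes=nucs,
                          promoter_states=promoter_states,
                          expression=expression)


def _combined(k4me3: bool, k9ac: bool, k27me3: bool) -> str:
    if k4me3 and k27me3:
        return "bivalent"
    if k4me3 and k9ac:
        return "active"
    if k27me3:
        return "repressed"
    return "none"


def _promoter_window(gene_row) -> tuple[int, int]:
    """Strand-oriented [-200, +50] window in absolute coordinates."""
    if gene_row.strand == "+":
        return gene_row.tss - 200, gene_row.tss + 51
    return gene_row.tss - 50, gene_row.tss + 201


def _emit_reads(mids: np.ndarray, chrom_idx: np.ndarray, names: list[str],
                read_len: int, rng: np.random.Generator) -> pd.DataFrame:
    """49-bp single-end reads from either end of the 147-bp fragment."""
    minus = rng.random(mids.size) < 0.5
    start = np.where(minus, mids + 74 - read_len, mids - 73)
    end = start + read_len
    chrom = pd.Categorical.from_codes(chrom_idx, categories=names)
    return pd.DataFrame({"chrom": chrom,
                         "start": start.astype(np.int64),
                         "end": end.astype(np.int64),
                         "strand": np.where(minus, "-", "+")})


def _mnase_allocation(study: SyntheticStudy, condition: str,
                      rng: np.random.Generator
                      ) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Multinomial allocation of MNase reads over planted nucleosomes.

    Returns (per-condition dyad table, reads per nucleosome, background
    count). This is the first draw from the track's RNG stream, so the
    allocation is recoverable independently of read emission.
    """
    params = study.params
    dyads = study.dyads_for(condition)
    n_total = int(round(params.mnase_depth_per_nucleosome * len(dyads)))
    if n_total == 0:
        return dyads, np.zeros(len(dyads), dtype=np.int64), 0
    n_bg = int(round(params.background_read_frac * n_total))
    w = dyads["weight"].to_numpy()
    counts = rng.multinomial(n_total - n_bg, w / w.sum())
    return dyads, counts, n_bg


def simulate_mnase_reads(study: SyntheticStudy, condition: str,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Sample MNase reads: 147-bp fragments with Gaussian dyad jitter.

    Total reads = round(depth_per_nucleosome x planted nucleosomes in the
    condition); a ``background_read_frac`` portion is uniform over the
    genome; the rest is multinomial over nucleosomes proportional to their
    planted occupancy weight.
    """
    params = study.params
    names = list(study.sizes)
    dyads, counts, n_bg = _mnase_allocation(study, condition, rng)
    if counts.sum() == 0 and n_bg == 0:
        return _emit_reads(np.empty(0, np.int64), np.empty(0, np.int8),
                           names, params.read_len_bp, rng)
    mids = np.repeat(dyads["dyad"].to_numpy(), counts).astype(float)
    if params.dyad_jitter_sd_bp > 0:
        mids += rng.normal(0.0, params.dyad_jitter_sd_bp, mids.size)
    mids = np.rint(mids).astype(np.int64)
    chrom_codes = np.repeat(
        pd.Categorical(dyads["chrom"], categories=names).codes, counts)
    bg_chrom, bg_mids = _uniform_positions(study.sizes, n_bg, rng)
    mids = np.concatenate([mids, bg_mids])
    chrom_codes = np.concatenate([chrom_codes, bg_chrom]).astype(np.int8)
    lens = np.array([study.sizes[c] for c in names])[chrom_codes]
    mids = np.clip(mids, 74, lens - 75)
    return _emit_reads(mids, chrom_codes, names, params.read_len_bp, rng)


def _uniform_positions(sizes: ChromSizes, n: int, rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    names = list(sizes)
    lens = np.array([sizes[c] for c in names], dtype=float)
    chrom = rng.choice(len(names), size=n, p=lens / lens.sum())
    pos = rng.integers(74, (lens - 75).astype(np.int64)[chrom] + 1)
    return chrom.astype(np.int8), pos.astype(np.int64)


def simulate_chip_reads(study: SyntheticStudy, mark: str, condition: str,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Sample ChIP reads: uniform background plus enriched features.

    Positive promoters are enriched TSS-proximally (+/-500 bp; +/-1 kb for
    the broad H3K27me3) and positive enhancers across the enhancer body, at
    ``chip_enrichment`` x the background density.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}")
    params = study.params
    names = list(study.sizes)
    name_idx = {c: i for i, c in enumerate(names)}
    genome_len = sum(study.sizes.values())
    extra = params.chip_enrichment - 1.0

    feats: list[tuple[int, int, int]] = []  # (chrom_idx, start, end)
    half = 1000 if mark == "H3K27me3" else 500
    pstates = study.promoter_states
    pos_genes = set(pstates.loc[(pstates["condition"] == condition)
                                & pstates[mark], "gene_id"])
    for row in study.genes.itertuples():
        if row.gene_id in pos_genes:
            feats.append((name_idx[row.chrom], row.tss - half,
                          row.tss + half))
    state_col = {"cond1": "state_1", "cond2": "state_2"}[condition]
    for row in study.enhancers.itertuples():
        k4me1, k27ac, k27me3 = _ENHANCER_PATTERNS[getattr(row, state_col)]
        positive = {"H3K4me1": k4me1, "H3K27ac": k27ac,
                    "H3K27me3": k27me3}.get(mark, False)
        if positive:
            feats.append((name_idx[row.chrom], row.start, row.end))

    weights = [float(genome_len)] + [extra * (e - s) for _, s, e in feats]
    weights = np.array(weights)
    if params.chip_depth == 0:
        return _emit_reads(np.empty(0, np.int64), np.empty(0, np.int8),
                           names, params.read_len_bp, rng)
    counts = rng.multinomial(params.chip_depth, weights / weights.sum())
    bg_chrom, bg_mids = _uniform_positions(study.sizes, counts[0], rng)
    mid_parts = [bg_mids]
    chrom_parts = [bg_chrom]
    for (ci, s, e), k in zip(feats, counts[1:]):
        mid_parts.append(rng.integers(s, e, size=k).astype(np.int64))
        chrom_parts.append(np.full(k, ci, dtype=np.int8))
    mids = np.concatenate(mid_parts)
    chrom_codes = np.concatenate(chrom_parts)
    lens = np.array([study.sizes[c] for c in names])[chrom_codes]
    mids = np.clip(mids, 74, lens - 75)
    return _emit_reads(mids, chrom_codes, names, params.read_len_bp, rng)


def simulate_expression(genes: pd.DataFrame, params: SimParams,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Log-normal RPKM around archetype means; q-values planted for DE genes."""
    n = len(genes)
    mu1 = np.array([_BASE_RPKM[a] for a in genes["archetype"]])
    mu2 = mu1.copy()
    up = genes["archetype"].to_numpy() == "up"
    down = genes["archetype"].to_numpy() == "down"
    mu2[up] = mu1[up] * params.up_fold_change
    mu2[down] = mu1[down] / params.up_fold_change
    sd = params.expression_lognorm_sd
    rpkm1 = np.exp(rng.normal(np.log(mu1), sd)) if n else np.empty(0)
    rpkm2 = np.exp(rng.normal(np.log(mu2), sd)) if n else np.empty(0)
    de = up | down
    q = np.where(de, rng.uniform(0.001, 0.049, n) if n else 0.0,
                 rng.uniform(0.06, 1.0, n) if n else 0.0)
    return pd.DataFrame({"gene_id": genes["gene_id"], "rpkm_1": rpkm1,
                         "rpkm_2": rpkm2, "q_value": q,
                         "planted_fold": mu2 / np.maximum(mu1, 1e-12),
                         "de": de,
                         "archetype": genes["archetype"]})


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write the simulated study as plain-text files (reads, truth, config)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.sizes.to_tsv(out / "chrom.sizes")
    cio.write_genes_gtf(study.genes, out / "genes.gtf")
    study.genes.to_csv(out / "genes_truth.tsv", sep="\t", index=False)
    study.enhancers.to_csv(out / "enhancers_truth.tsv", sep="\t", index=False)
    study.nucleosomes.assign(event=study.truth_event_label()).to_csv(
        out / "nucleosomes_truth.tsv", sep="\t", index=False)
    study.promoter_states.to_csv(out / "promoter_states_truth.tsv", sep="\t",
                                 index=False)
    study.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    for cond in CONDITIONS:
        cio.write_bed_reads(study.mnase_reads(cond),
                            out / f"mnase_{cond}.bed")
        for mark in MARKS:
            cio.write_bed_reads(study.chip_reads(mark, cond),
                                out / f"{mark}_{cond}.bed")
    study.params.to_yaml(out / "sim_params.yaml")
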