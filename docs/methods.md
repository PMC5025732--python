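# Methods

This note records the models behind each pipeline stage, the parameter
defaults and why they were chosen, what the synthetic study does and does
not emulate, and the numerical conventions that matter for reproducing
results.

## Coordinates and input model

All internal coordinates are 0-based half-open; GTF/GFF input (1-based,
closed) is converted on read. Inputs are mapped-read *intervals* (BED), not
alignments: the pipeline deliberately starts downstream of mapping, and a
chromosome-sizes table is mandatory so every record is validated on entry.
Reads are single-end and stranded; duplicate collapsing is off by default
(`deduplicate=True` / `--dedup` enables it), since the digestion-based
protocols this consumes are commonly analyzed without duplicate marking.

## Nucleosome maps

A nucleosome protects ~147 bp, so each read is extended toward its 3′ end to
147 bp and the extension midpoint taken as the dyad estimate: for a + read
starting at *s*, dyad = *s* + 73; for a − read ending (exclusive) at *e*,
dyad = *e* − 74. Reads whose extension leaves the chromosome are dropped and
counted. The same extension is applied to MNase and ChIP reads.

**Occupancy track.** Dyads are binned at 5 bp, normalized to reads per
million (RPM) of the library, and smoothed with a centered 5-bin moving
average whose window is truncated at chromosome ends (each position is the
mean of the bins actually in the window, so a uniform track is a fixed
point and an isolated spike spreads to five bins of a fifth its height).

**Calling.** The dyad kernel density (Gaussian, σ = 20 bp, evaluated at
1-bp resolution, kernel truncated at ±4σ — relative error < 3 × 10⁻⁴, and a
linear-time convolution) is scanned greedily: candidates are the density's
local maxima, visited in decreasing height with ties to the leftmost
position (then lexicographic chromosome name), and each accepted peak claims
a 147-bp exclusion zone, so calls are pairwise ≥ 147 bp apart. Restricting
candidates to local maxima matters: without it, the residual flank of an
accepted peak just outside its exclusion zone would be called as a second
nucleosome. A call must be supported by at least `min_call_reads` (3) dyads
within ±73 bp; at the depths this pipeline targets (tens of reads per
nucleosome) anything below that is indistinguishable from scattered
background and would otherwise seed spurious calls inside genuinely
nucleosome-free gaps. Call occupancy is the RPM-normalized dyad count within
±73 bp — the footprint, rather than any internal window of the caller.

σ and the exclusion width are the canonical choices for 147-bp nucleosomes;
both are exposed in `PipelineConfig`.

## Positioning dynamics

For each call the nearest call of the other condition (same chromosome,
ties to the smaller coordinate) defines a dyad distance *D* and implied
footprint overlap max(0, 147 − *D*). Classification: *D* = 0 → fixed
(strict equality on the 1-bp grid — the natural reading of "exactly the
same position", and the only rule under which the fixed class stays rare);
overlap ≤ 20 bp → lost (condition-1 call) or gained (condition-2 call);
otherwise shift. Matching is plain nearest-neighbor, not one-to-one
assignment.

Because the natural denominator is ambiguous (does a shifted nucleosome
count once or once per condition?), the summary reports two conventions:
the headline *unit* fractions (a fixed pair counts once; every other call
counts once; the fractions partition the union of calls and sum to 1) and
per-call fractions (fixed calls counted once per condition). Swapping the
condition labels swaps lost and gained and preserves fixed and shift — an
invariant the test suite enforces on random inputs.

Genome-wide occupancy change is additionally summarized in non-overlapping
200-bp windows (mean RPM per window, difference = condition 2 − 1).

## Promoter chromatin states

Per mark and condition, read-extension midpoints are binned at 5 bp across
TSS ± 1 kb (strand-oriented, upstream left), RPM-normalized by the
library's total mapped reads, and 5-bin smoothed — 400-bin profiles that
are invariant under depth scaling. K-means with K = 2 (10 restarts, seeded)
on the raw smoothed profile vectors splits promoters into mark-positive and
mark-negative; the cluster with the higher mean total signal is "+". Raw
vectors rather than z-scores or totals keep the clustering on the signal
itself; scalar totals are available behind `use_totals=True`.

Degenerate guard: when the two clusters' mean totals differ by less than
2×, the data is effectively unimodal and an arbitrary split would be
meaningless; all promoters are then labeled by a fixed threshold of twice
the uniform-coverage expectation (the profile total a library of the same
depth would give if reads were spread evenly over the genome). All-zero
profiles are all "−" without clustering.

Combined states with precedence bivalent > active > repressed > none:
bivalent = H3K4me3⁺ ∧ H3K27me3⁺, active = H3K4me3⁺ ∧ H3K9ac⁺,
repressed = H3K27me3⁺.

Expression records get fold change (condition 2 / condition 1) with a
pseudocount of 1 RPKM — silent genes would otherwise divide by zero — and a
three-way group (up / down / no-change) at the 1.5-fold cut; a separate DE
flag additionally requires the input q-value < 0.05 (differential testing
itself is consumed, not performed). The signal-versus-expression report
gives per-group mean signal change with a seeded bootstrap CI (1000
resamples) and a Spearman correlation between per-gene signal change and
log₂ fold change per mark.

## Enhancers

H3K4me1 peak calling is a Poisson scan: read midpoints counted in 1000-bp
windows stepped by 100 bp (10× oversampling of the window), each count
tested against a genome-wide uniform rate λ = total midpoints × window /
genome length, Benjamini–Hochberg across all windows at q ≤ 0.001,
significant overlapping windows merged, peak score = best window's fold
enrichment. A genome-wide null is the simplest defensible model at the
stated window size and FDR; there is no input-library normalization
(out of scope).

Peaks from both conditions are pooled; any two peaks with an inter-peak gap
< 500 bp collapse to the higher-scoring one (left wins ties), applied
left-to-right and iterated to a fixpoint — on score chains like 3 < 5 > 4
the middle peak is the unique survivor under every merge order, which the
tests verify exhaustively. Survivors with ≥ 50% of their length inside the
promoter set are dropped.

Profiles: per (enhancer, mark, condition), midpoint counts in 120 windows
of 50 bp over center ± 3 kb, each vector divided by its own total (zero-read
regions stay all-zero), hence depth-invariant.

Mark positivity per condition is 2-means on log(1 + count) of raw midpoint
counts in center ± 500 bp — the enhancer-proximal signal, where a positive
mark is ~8× background rather than the ~2× it would be diluted to over the
full ±3 kb. The same degenerate-cluster guard applies, with the fallback
threshold at twice the expected background count. States: active =
H3K4me1⁺/H3K27ac⁺/H3K27me3⁻, poised = H3K4me1⁺/H3K27ac⁻/H3K27me3⁺, else
intermediate. The poised definition requires H3K27me3 by default; the
looser convention (H3K4me1⁺/H3K27ac⁻ regardless of H3K27me3) is available
via `poised_requires_k27me3=False`. The transition table counts state pairs
across conditions and reports the fraction of condition-1 poised enhancers
remaining poised.

Enhancer–gene association, where needed, is nearest TSS — a convention, not
a claim about physical targets.

## NDR detection and formation modes

The occupancy track registers dyad *positions*, so single 5-bp bins go to
zero in every linker and a lone background fragment lights one bin up;
neither says anything about nucleosome-scale depletion. Depletion is
therefore assessed at footprint scale: a position is depleted when the mean
occupancy over the 147-bp window centered on it falls below
`ndr_depletion_frac` (0.20) of the genome-wide mean. At 30 reads per
nucleosome that threshold tolerates ~3 stray background fragments per
window while sitting far below even a weakly occupied nucleosome
(~8× higher). An NDR is a maximal depleted run of ≥ 150 bp (about one
nucleosome) within a promoter window ([−200, +50] bp of the TSS,
strand-oriented) or an enhancer, reported at bin resolution and clipped to
the region; on a clean planted gap the footprint-scale rule erodes each
boundary by ≲ 15 bp. Detection is monotone: lowering the depletion
fraction or raising the minimum length never adds NDRs.

An NDR *formed* if the prior condition held a nucleosome in the interval.
The statistic is the peak footprint-scale occupancy over the interval
interior (positions whose window lies inside the NDR, so flanking
nucleosomes cannot leak in), compared against `ndr_prior_occupancy_frac`
(0.25) of the genome mean. The interior *peak* rather than the interval
mean makes the test independent of interval length — a single prior
nucleosome in a 350-bp interval is exactly as detectable as in a 180-bp
one — and 0.25× sits between the uniform-background plateau (~0.1×) and
weakly occupied nucleosomes.

Formation modes: formed enhancer NDRs are clustered (K-means, K = 3,
seeded) on the prior-condition occupancy within the NDR interval, aligned
on NDR centers over ±300 bp and sum-normalized. Masking outside the
interval is deliberate: the nucleosome whose disappearance formed the NDR
must have sat inside it, while flanking nucleosomes persist in both
conditions and would dominate the clustering with locus-specific phasing.
Each cluster is labeled by its composite-profile peak position relative to
the center: within ±40 bp (about the spread of a positioned dyad versus one
displaced by at least a linker) → eviction; left → shift upstream; right →
shift downstream. With fewer NDRs than K, each NDR is labeled by its own
peak position.

Association reports: Spearman correlation between promoter-window mean
occupancy and log RPKM per condition; a Wilcoxon signed-rank comparison of
expression across conditions for genes whose promoter NDR formed; and a
mode-by-state contingency test (χ²) for formed enhancer NDRs.

## The synthetic study

The generator plants a complete two-condition experiment whose defaults are
the study conditions used throughout the tests: 2 chromosomes × 500 kb, 200
genes and 80 enhancers in non-overlapping slots, nucleosomes tiled every
200 bp (~4,700 entities after feature carving), event mix 2% fixed / 90%
shift / 4% lost / 4% gained, shift distances uniform on 10–25 bp (capped so
two neighbors shifting toward each other still respect the 147-bp exclusion
geometry), per-nucleosome occupancy weights gamma-distributed (shape 2),
MNase depth 30 reads per nucleosome with dyad jitter sd 10 bp and a 5%
uniform background, five ChIP libraries of 1M reads per condition at 10×
enrichment over positive features, and log-normal expression noise
(sd 0.15). Reads are 49-bp single-end, emitted from either end of the
idealized 147-bp fragment; jitter applies to the dyad, never the fragment
length, so the truth stays crisp. Everything derives from one seed through
independent per-track streams; per-track read totals equal the configured
depth exactly.

Genes carry archetypes (constitutively active, up-regulated, down-regulated,
repressed, bivalent, silent) that jointly determine promoter mark states,
promoter openness ([−200, +50] windows cleared of nucleosomes per
condition), and expression means — so active promoters out-express
repressed ones and promoter-window occupancy anticorrelates with expression
by construction. Enhancers couple to their nearest gene: NDR-forming
enhancers preferentially flank up-regulated genes, and enhancer states
follow the gene's expression tier (active enhancers at high expressors,
poised at low), with poised states persisting across conditions at a high
planted rate. Enhancer NDRs (60% of enhancers, modes ⅓/⅓/⅓) are planted
geometrically: eviction removes the central nucleosome between flanks
delimiting a 200-bp gap; shifts move a nucleosome 150–200 bp away with the
adjacent linker sized so the vacated footprint sits ~60 bp off the
resulting gap's center — the displacement the mode classifier reads out.
A relocation that large is, by the 20-bp-overlap rule's own taxonomy, one
lost plus one gained nucleosome, and the truth tables count it that way.

What the generator does **not** emulate: sequence (no FASTA, mappability or
GC bias), paired ends, replicates, MNase digestion bias, irregular linker
lengths or fuzzy nucleosomes beyond Gaussian jitter, input-library
structure for ChIP, or partial mark enrichment. Passing recovery tests
therefore demonstrate that the implementations invert the stated data
model at realistic depth and noise — not that they are robust to every
artifact of real chromatin data.

A note on benchmarking against the truth: at 30 reads per nucleosome,
~2% of planted nucleosomes receive too few reads (under the 3-read calling
floor) to be visible in any analysis. Recovery oracles therefore take
per-entity visibility masks derived from the realized read allocation
(`mnase_read_counts`), which the generator exposes precisely so that
benchmarks measure the method rather than Poisson vanishing. The NDR truth
oracle (`truth_depleted_intervals`) is geometric — footprint gaps between
planted dyads — and independent of all detection code.

## Problem sizes and determinism

The default test and acceptance workloads are one simulated study
(~260k MNase reads and 10M ChIP reads across ten libraries), chosen so the
full suite runs in well under a minute of compute while leaving every class
of planted event with enough instances (≥ 48 NDRs, 80 enhancers, 200
promoters, ~9,000 dynamics units) for stable recovery statistics. All
stochastic steps — simulation, K-means restarts, bootstrap — take explicit
seeds; reruns with the same seed are bit-identical.

## Known limitations

* The Poisson peak caller has no input normalization and assumes a globally
  uniform background; on real data with copy-number or accessibility bias
  it will over-call in high-background regions.
* Fixed-position detection relies on exact dyad equality at 1 bp; true
  fixed nucleosomes observed through sampling jitter are mostly classified
  as small shifts, so the fixed class is a conservative lower bound.
* NDR boundaries are footprint-smoothed and systematically ~10–15 bp inside
  the geometric gap; lengths are correspondingly conservative.
* Mark positivity by 2-means assumes each mark is genuinely bimodal across
  features; graded enrichment landscapes will be forced into two groups or
  fall back to the coverage threshold.
* Enhancer–gene assignment by nearest TSS ignores long-range regulation.
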