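# Methods

This note documents the models implemented in `secircuit`, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions that make runs reproducible.

## Coordinates and interval algebra

All genomic intervals are BED-style 0-based half-open `[start, end)`.
"Overlap" means ≥ 1 shared base unless a minimum is given; adjacency
(`end == start`) is not overlap. Histone-mark and TF peaks are treated as
unstranded. In the two-set comparison, shared peaks are counted from the
first set's members (each member counted once even under many-to-many
overlaps) and percentages are taken over shared + A-specific + B-specific.

## Super-enhancer calling

Enhancer peaks are merged transitively when the gap to the next peak is
≤ 12,000 bp (the stitching window; a gap of exactly 12 kb still merges).
Each stitched element's signal is the sum over its constituent peaks of
per-base treatment coverage minus optional input control, floored at zero.
Elements are ranked by ascending signal; rank and signal are rescaled to the
unit square (x = rank/n, y = signal/max). The discrete tangent slope at each
rank is a symmetric difference over a 3-point window (one-sided at the ends)
— more robust to single-point noise than adjacent differences while
remaining exactly checkable against a brute-force scan. The cutoff rank is
the smallest rank from which the slope is ≥ 1 all the way to the top;
elements with signal strictly greater than the signal at that rank are
super-enhancers. Consequences worth knowing:

- perfectly linear signals give slope ≡ 1 everywhere, so the cutoff lands at
  rank 1 and everything above the minimum signal is "super" (documented
  boundary behaviour, not an error);
- if no rank satisfies the condition the cutoff falls back to the top rank
  and nothing is super;
- multiplying all signals by any c > 0 leaves the partition unchanged, and
  raising one element's signal never demotes it.

Signal ties in ranking break by genomic position, so results are
deterministic. TSS exclusion (dropping constituents wholly inside TSS ± w
before stitching) is available but off by default.

## Element classification and co-binding groups

An H3K27ac region is a *promoter* when it overlaps H3K4me3 **and** a
strand-aware TSS window (default −1000/+100 bp around the TSS); otherwise an
*enhancer* when it overlaps H3K4me1; regions carrying neither mark are
dropped. Promoter takes precedence when both definitions fit. Genes are
assigned by nearest TSS to the region midpoint with a signed distance
(negative = upstream in the gene's orientation); ties break by gene name.

Co-binding groups come from ≥ 1 bp overlap with each of exactly three TF
peak sets: trio (3), dual (2), solo (1), none (0). Expression linkage uses
the per-gene mean of log2(FPKM + 1) across the chosen condition's samples;
group differences are Welch's unequal-variance t-tests on those per-gene
values (log scale, because FPKM is heavily right-skewed and the comparison
is of typical expression, not totals). Groups with fewer than two genes are
flagged and skipped rather than tested.

The motif-span statistic is the minimum, over one PWM hit per TF inside a
region, of (max hit end − min hit start). "Span" (first-to-last extent) was
chosen over largest pairwise gap; both are computable from the same hit
lists. The PWM scanner scores log2-odds against a background over both
strands with a small pseudocount; non-ACGT bases contribute zero log-odds
(scored as background) rather than erroring.

## Differential expression stand-in

FPKM is counts · 1e9 / (library size · gene length). The built-in DE engine
is deliberately simple and labeled as such: Welch's t on log2(FPKM + 1), BH
adjustment, and calls `up`/`down` when |log2FC| > 0.584 and p < 0.05 (both
configurable). It is calibrated (type-I ≈ 0.05 under the null) but it is not
a negative-binomial GLM: with total-count normalization, fold-change
estimates shrink when differentially expressed genes carry a large share of
the library (composition bias). Externally produced DE tables
(gene, log2fc, p) can be imported instead and flow through the same schema.
A pseudocount of 1 FPKM unit stabilizes fold changes at low expression.

## Circuit nomination

Candidates are SE-driven genes that are upregulated and in a user-supplied
TF catalog. Pairwise Pearson r over patient samples with the two-sided
t-test p (n − 2 df); constant genes are excluded with a warning. Candidate
circuits are maximal cliques (Bron–Kerbosch with pivoting) of the graph
whose edges satisfy r ≥ r_min and p ≤ p_max, reported sorted by size then
minimum edge r. The thresholds default to r_min = 0.5, p_max = 0.05 and are
always part of the report: the nomination is an explicit rule, not a
heatmap judgment call. At 13 samples the binding constraint is effectively
r̂ ≥ 0.553 (where the two-sided p crosses 0.05), so with a true pairwise
correlation of 0.8 a planted trio survives all three edge tests in roughly
85–90% of draws — worth remembering when interpreting a single cohort.

## Enrichment and survival

Preranked GSEA uses the classic weighted running sum: at hits it adds
|score|^p normalized by the in-set total (default weight p = 1, the usual
preranked default), at misses it subtracts 1/(N − k); the ES is the signed
maximum deviation. The null permutes gene labels; p = (1 + exceedances) /
(n_perm + 1); NES divides by the mean |ES| of same-sign permutations and is
flagged undefined when that side of the null is empty.

ssGSEA ranks a single sample's genes by expression (average ranks on ties),
weights hit steps by rank^α (α = 0.25, the method's canonical default) and
miss steps uniformly, sums the ECDF differences, and normalizes by the
maximum attainable magnitude (set at the top of the ranking), so scores lie
in [−1, 1] and only depend on ranks — adding a constant to all expression
values changes nothing.

The survival cutpoint maximizes the absolute standardized two-group
log-rank statistic over all observed score values inside a quantile band
(default 10–90%) that leave both groups non-empty. Its p-value is obtained
by permuting the score-to-outcome assignment and recomputing the maximum —
the selection-adjusted p, not the naive log-rank p at the chosen cutpoint.
Permutation (default) was preferred over asymptotic improved-Bonferroni
bounds for exactness at these cohort sizes. Note the *location* of the
argmax is intrinsically noisy (cutpoint estimators converge slowly); the
induced high/low partition is far more stable than the cutpoint value
itself, and the package reports both.

## Drug synergy

The median-effect model is fit as a least-squares line of log10(fa/(1−fa))
on log10(D); points with fa at exactly 0 or 1 carry no information on this
scale and are excluded with a warning. Dm = 10^(−intercept/slope) is the
dose at fa = 0.5 and doubles as the IC50 estimate; IC50s beyond the tested
dose range are reported censored ("> max dose"). The combination index uses
the two-term (mutually exclusive) form CI = d1/Dx1 + d2/Dx2, matching the
additivity convention stated with the statistic; the three-term variant is
out of scope.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, with
a `TruthManifest` recording everything planted:

- **Annotation**: `chr1..chrN`, evenly spaced TSSs with ±2 kb jitter. Each
  gene owns five element slots (promoter at the TSS, enhancers at ±20/40 kb),
  which keeps every element nearest its own TSS and non-SE elements more
  than one stitch gap apart. The TSS spacing must exceed ~110 kb for this
  layout; the pipeline sizes chromosomes accordingly and the generator
  raises an error on any placement collision.
- **Epigenome**: background stitched signals are uniform on [10, 100];
  planted SE elements are 2–3 peak clusters whose totals are geometrically
  spaced (with jitter) across [500, 5000] — a convex ascending tail with at
  least 5× separation from background, which is the hockey-stick shape the
  slope rule presumes. I.i.d. tail draws were rejected because they produce
  occasional flat runs that no sustained-slope rule should be expected to
  classify. Background elements split into shared/A-specific/B-specific
  (defaults 0.31/0.30/0.39, mirroring the shared-peak fraction scale of a
  resistant-vs-parental comparison); SEs are B-specific. Background
  elements are placed only on genes without planted elements so gene-level
  group comparisons stay clean. bedGraph coverage is constant per peak at
  signal/width, so coverage summed over a peak equals its assigned signal.
- **TF binding**: footprints sit inside the first constituent peak of each
  bound element; with the false-positive rate at 0 the TF peak sets equal
  the manifest's bound elements exactly.
- **Expression**: gamma-Poisson counts (variance μ + φμ², default
  φ = 0.01, cell-line grade). Gene means: lognormal baseline (log2 sd 1),
  plus 1 log2 unit per bound TF (both conditions), plus the planted
  `expr_effect` (default 1 log2 unit) in condition B for all SE-driven
  genes. The patient-like matrix is on the log2 scale; circuit TFs share a
  single latent factor with loading √r so each pair has Pearson correlation
  exactly `corr_r` (default 0.8). Default universe: 5000 genes, so planted
  DE genes are ~1% of the library and FPKM composition bias is negligible —
  the regime real transcriptomes are in.
- **Survival**: exponential event times, hazard ×`hazard_ratio` (default 4)
  for samples above the planted score cutpoint, independent exponential
  censoring tuned to ~10% in the low-risk group.
- **Dose-response**: exact median-effect curves plus optional Gaussian fa
  noise; the fixed-ratio combination's fa at each dose solves
  d1/Dx1(fa) + d2/Dx2(fa) = CI, so a zero-noise round trip through the
  synergy fit recovers the planted CI to numerical precision. Default drug
  parameters put the sensitive-line IC50 at 9.3 µM.

What it does **not** emulate: read-level noise, fragment-size effects, peak
caller artifacts, copy number, batch effects, correlated background genes,
non-exponential hazards, or plate effects in viability assays. Passing
recovery tests therefore demonstrates correctness of the inference chain
under its stated assumptions, not robustness to every artifact of real data.

All generator functions are deterministic given (manifest, seed): identical
inputs produce byte-identical output files.

## Pipeline scales and reproducibility

Default end-to-end run: 5000 genes on 4 chromosomes, 1000 planted +
background elements, 4 RNA-seq replicates per condition, 13 patient-like
samples for the correlation network, 200 samples in the survival cohort,
499 maxstat permutations. These sizes keep a full run in single-digit
seconds while leaving every statistic in its intended operating regime; all
are configurable in `RunConfig`, which serializes losslessly to JSON.
Every stage writes SHA-256 digests of its outputs into `report.json`;
identical config + seed reproduces identical digests. Test and acceptance
simulations use the same machinery at reduced replicate counts.

## Known limitations

- The DE stand-in is not DESeq2; for publication-grade DE import an external
  table.
- Enhancer-gene assignment is nearest-TSS only; no 3D contact information.
- The maxstat asymptotic p approximation is not implemented (permutation
  only).
- The motif scanner reports raw log2-odds scores; no p-value calibration of
  thresholds.
- Shared peaks are represented in the first set's coordinates; the counts
  are symmetric only up to many-to-many overlap structure.
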