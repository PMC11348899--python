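# Methods

## Scope and data model

`methdriver` analyzes per-CpG methylation (beta values on the 0–100
percent scale) for labeled tumor/normal cohorts, together with a gene ×
sample expression table and a survival table. Native coordinates are
1-based inclusive everywhere; BED output converts to 0-based half-open
at the I/O boundary. The beta matrix is assembled on the intersection of
CpGs covered in all samples by default (per-CpG rank-sum tests need
complete rows); a union mode with explicit missing cells exists for
inspection. Per-CpG coverage filtering defaults to ≥ 4 reads. Whether
CpG dyad strands are collapsed before assembly is exposed as a flag
(`collapse_strands`); both behaviors are supported because conventions
differ between callers.

## Differential methylation

Per-CpG testing is a two-sided Wilcoxon rank-sum (Mann-Whitney) of tumor
vs normal betas with BH-FDR control at 0.05. Mid-ranks handle ties. When
both groups have ≤ 8 samples the p-value is computed by full enumeration
of the C(n₁+n₂, n₁) label assignments (p = P(|U − n₁n₂/2| ≥ |U_obs −
n₁n₂/2|)); larger designs use the tie-corrected normal approximation
with continuity correction. The cutoff of 8 keeps the exact branch
affordable genome-wide (≤ 12,870 assignments per CpG) while remaining
exact for every design the test oracles enumerate. Constant rows return
p = 1 and are flagged degenerate.

The delta track is Δ = mean(tumor betas) − mean(normal betas) per CpG,
in percent points. DMC testing and segmentation are parallel readouts:
by default CBS runs genome-wide; a `significant_only` flag restricts the
input to FDR-significant DMCs.

## Circular binary segmentation

For each chromosome's ordered delta series, the best arc (i, j]
maximizes

  T(i, j) = |mean(arc) − mean(complement)| / (s_p · √(1/n_arc + 1/n_rest))

where s_p pools the within-part variance (n − 2 denominator). A zero
pooled SD with differing means scores +∞ (an exact changepoint); argmax
ties break toward the lexicographically smallest (i, j). An arc and its
complement induce the same split, so downstream comparisons canonicalize
to cut points.

Split acceptance uses a seeded permutation test at α = 0.01 with up to
1,000 shuffles of the stretch. Permutations are evaluated sequentially
with early stopping: the scan aborts as soon as the decision is settled
— rejection once the exceedance count k reaches ⌊α(n_perm+1)⌋ (the
p-value (1+k)/(1+m) can no longer drop to α), acceptance when k = 0
after ⌈1/α⌉−1 = 99 shuffles (p̂ = 1/100+1 ≤ α already). This keeps
clear splits and clear non-splits cheap while borderline stretches use
the full budget; it is what makes genome-scale segmentation run in
seconds. Stretches shorter than 6 points are never split. Accepted
splits cut the stretch at both arc boundaries and recursion continues on
the pieces, so segments always partition the CpG series. There is no
post-hoc segment-merging ("undo") step. Per-stretch permutation seeds
come from a SeedSequence spawned deterministically in recursion order,
so a fixed seed reproduces the segmentation exactly.

The O(n²) arc scans are compiled with numba; a plain-python exhaustive
scan serves as the independent oracle in the tests.

Segment constraints: any segment spanning ≥ 1 Mb is recursively split at
its largest internal inter-CpG gap; any segment with < 3 CpGs is
dropped; survivors are re-scored. Classification is a pure function of
the segment delta with inclusive boundaries: hyper at Δ ≥ 10, hypo at
Δ ≤ −15, other in between. The mean adjacent-CpG gap reported per DMR is
the average of successive position differences within the DMR (not
span/(n−1)); the two conventions differ only for irregular spacing and
this one was pinned for testability.

## Annotation and gene association

Gene models carry exactly one transcript; GTF reading keeps the longest
transcript per gene by genomic span, ties to the lexicographically
smallest transcript id. The promoter window is [TSS−2000, TSS)
(excluding the TSS base) and the downstream window (end, end+200], both
strand-aware; the half-open choices are pinned conventions.

Location categories are assigned by precedence — Whole-body >
Upstream-Body > Body-Downstream > Upstream > Downstream > Inner-genic >
Body > Intergenic — which makes them mutually exclusive and exhaustive.
"Body" means fully inside the gene span and overlapping ≥ 1 exon;
"Inner-genic" means fully contained in a single intron. These two labels
have no standard definition, so the disjoint pair above was chosen to
make both testable. Multi-gene overlaps resolve to the gene with the
largest overlap (ties to nearest TSS, then gene id), and the nearest
TSS distance is always reported.

A DMR associates with a gene's upstream (promoter) or downstream
regulatory region when the overlap reaches 50% of the DMR length
(boundary inclusive) or the DMR lies entirely inside the window; one DMR
may associate with several genes. Region methylation summaries are
unweighted means over all (CpG, sample) pairs inside each named region;
the six transcript-anchored regions anchor the 5′/3′ UTRs to the first
and last exon in transcription order (the toy models have no annotated
CDS), and regulatory elements (Enhancer, Promoter, Silencer,
Cis-regulatory region, Insulator) come from a user-supplied BED.

## Expression integration

Genes averaging < 10 TPM across all samples (tumor and normal pooled, as
worded) are excluded before testing, which also sets the BH denominator.
DEG direction is the sign of (median tumor − median normal) for
significant genes — medians for robustness and consistency with the
rank test; no fold-change threshold is applied (a flag exists). A DEG
with ≥ 1 associated classified DMR becomes a Methy-DEG; genes linked to
both hyper and hypo DMRs are flagged ambiguous and resolved by the
larger |Δ|. The candidate set is exactly hyper-down ∪ hypo-up; the
concordant-direction combinations are retained in the table but never
marked candidate.

## Stratification, survival, ROC

The panel score is the unweighted mean of the panel genes' expression
per sample (optionally after log2(x+1)); the panel is a runtime input so
3- or 4-gene panels work unchanged. Clustering is k-means (k = 3
default, k-means++ with 50 restarts, fixed seed) on per-gene z-scores of
log2(TPM+1) — the standard transform for expression k-means; clusters
are relabeled C1..Ck by decreasing mean panel score so assignments are
stable across seeds that find the same partition. `silhouette_by_k`
reports mean silhouette widths over a k range as a diagnostic but never
auto-selects k.

Survival records with < 30 days of follow-up or missing fields are
excluded by `filter_survival` before estimation. Kaplan-Meier curves and
the unstratified G-sample log-rank test (df = G−1) come from lifelines;
with no events the test is reported undefined rather than raising. DMR
ROC scores each sample by the mean beta over member CpGs, orients the
score so tumor is the positive class (higher for hyper-DMRs, lower for
hypo-DMRs), computes AUC by the Mann-Whitney relation with ties counted
half, and reports the cutoff maximizing Youden's J (ties to higher
specificity) on the original beta scale.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* **Genome** — 2 chromosomes × 2 Mb by default, single-transcript genes
  in evenly spaced slots with 2–4 exons, dense CpG islands (25 bp
  spacing, runs of ≥ 5) in promoter windows covering `island_fraction`
  of CpGs, and sparse background CpGs on a jittered grid with all gaps
  > 100 bp (so `island_fraction=0` yields no island-like adjacency).
* **Methylome** — betas drawn from a Beta distribution parameterized by
  mean and dispersion (variance = μ(1−μ)·φ, default φ = 0.005 ≈ 3.5
  points SD at mid-range), giving bounded percent values without
  clipping artifacts. Normal means sit at 70% (promoter CpGs dipped 20
  points); tumor means shift down 5 points genome-wide except inside
  planted segments, where tumor mean = normal mean + Δ_target. Paired
  samples share a per-patient offset (SD 2 points); its strength is a
  free parameter, not calibrated to any real cohort, and the pipeline
  treats the groups as unpaired regardless. Default 10 samples per arm.
* **Expression** — TPM columns normalized to 10⁶; driver genes' log
  expression decreases linearly in promoter mean beta (0.05 natural-log
  units per percent point, centered per gene so coupling does not move
  a gene's overall abundance), log-normal noise SD 0.5. Drivers must
  carry a planted promoter DMR, enforced at generation time.
* **Survival** — exponential event times per subgroup hazard (defaults
  1/2000, 1/1000, 1/400 events/day for C1–C3, i.e., ~5-fold hazard
  spread) with independent exponential censoring (1/3000 per day),
  integer day times ≥ 1.

What the generator does *not* emulate: read-level data, bisulfite
conversion error, coverage non-uniformity beyond Poisson export depth,
copy number, batch effects, or realistic genome annotation complexity
(one transcript per gene; the longest-transcript rule is exercised on
hand-built multi-transcript fixtures instead). Passing recovery tests
therefore demonstrate correctness of the pipeline's logic under its own
model assumptions, not performance on real WGBS data.

## Benchmark problem sizes

The packaged benchmarks (`methdriver.validation`) use 2 chromosomes ×
2,000 CpGs with 20 planted promoter DMRs (five each at Δ = ±30 and ±15)
for DMR recovery, and 500 genes / 10 drivers over 2 × 1,500 CpGs for
integration recovery, both at 10 samples per arm and swept over 20 seeds
in the test suite (10 in the acceptance script). These sizes give stable
recovery estimates (≈ 99% of |Δ| = 30 segments, ≥ 9/10 drivers, ~0 false
candidates) in a few minutes of CPU time.

## Degenerate inputs and numerical choices

Constant delta series return a single unsplit segment; constant rows
test at p = 1; empty DMR classes are omitted from summaries (never
reported as zero); regions without CpGs are reported absent; a log-rank
with no events is undefined, not an error. Beta means are clipped to
[0.5, 99.5] before sampling so Beta parameters stay proper. All
randomness flows from explicit seeds through SeedSequence children
(generator streams 1–4 for genome/methylome/expression/survival), and
the pipeline manifest records seed, config hash, input checksums, and
any non-default threshold; reruns are byte-identical.

## Known limitations

Single-arc CBS cannot cleanly split a stretch whose signal alternates
densely (e.g., many planted segments packed back-to-back); planted
benchmarks space their segments apart, which matches the promoter-scale
sparsity the method targets. The sequential permutation rule can, on
borderline stretches, decide differently than an exhaustive 1,000-shuffle
evaluation would; both are valid level-α tests. Exact rank-sum
enumeration stops at 8 samples per group. No smoothing, beta-binomial
dispersion modeling, covariate adjustment, or Cox regression is
implemented.
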