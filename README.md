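# methdriver

Methylation-driven gene discovery for tumor/normal cohorts profiled by
WGBS and RNA-seq.

Cancer genomes typically show global hypomethylation punctuated by focal
promoter hypermethylation, and promoter methylation gains are a classic
mechanism of tumor-suppressor silencing. `methdriver` implements, as a
tested and reusable library, the analysis chain that turns per-CpG
methylation tables and an expression matrix into a ranked set of
methylation-driven candidate genes, and then evaluates those candidates
as biomarkers:

1. **DMC testing** — per-CpG two-sided Wilcoxon rank-sum (tumor vs
   normal) with Benjamini-Hochberg FDR control (significant at
   FDR < 0.05).
2. **DMR calling** — the per-CpG delta track
   Δ = β̄<sub>tumor</sub> − β̄<sub>normal</sub> (percent points) is
   segmented per chromosome by circular binary segmentation (CBS):
   the arc (i, j] maximizing the two-sample t-like statistic
   |mean(arc) − mean(rest)| / (s<sub>p</sub>·√(1/n₁ + 1/n₂)) is tested
   against a seeded permutation null and accepted splits recurse.
   Segments are forced under 1 Mb (split at the largest internal CpG
   gap), segments with < 3 CpGs are dropped, and survivors classify as
   **hyper** (Δ ≥ 10), **hypo** (Δ ≤ −15), or **other**.
3. **Annotation** — each DMR gets one of eight transcript-anchored
   location categories (Upstream … Whole-body, Intergenic) against
   longest-transcript gene models, and associates with a gene's
   promoter window [TSS−2000, TSS) or downstream window
   (end, end+200] when the overlap reaches 50% of the DMR length.
4. **Expression integration** — genes with mean TPM < 10 are excluded;
   the rest get a rank-sum DEG test (FDR < 0.05). Crossing DEG
   direction with associated DMR class yields four categories; the
   candidate set is exactly **hyper-down ∪ hypo-up**.
5. **Stratification** — per-sample panel score (equal-weight mean
   expression of a gene panel), k-means subgroups (k = 3) on z-scored
   log2(TPM+1) panel expression relabeled C1..Ck by decreasing score,
   Kaplan-Meier / log-rank survival comparison (records under 30 days
   of follow-up excluded), and DMR-methylation ROC
   (Mann-Whitney AUC, Youden-optimal cutoff).

A first-class synthetic-data module generates toy genomes, planted
hyper-/hypo-methylated segments, methylation-coupled expression, and
subgroup-dependent survival, so the whole chain is testable end to end
with no sequencing data.

## Worked example

`examples/` holds one short script per capability. Calling DMRs on a
cohort with planted ±30-point promoter segments
(`python examples/02_call_dmrs.py`):

```
class counts: {'other': 6, 'hyper': 2, 'hypo': 2}
called hyper/hypo DMRs (the planted promoters):
chrom  start    end  n_cpgs      delta dmr_class
 chr1  18111  19717      24  29.613170     hyper
 chr1 571979 572529      23  29.939740     hyper
 chr2  19665  20215      23 -29.628332      hypo
 chr2 560727 561344      24 -29.575358      hypo
```

All four planted promoter segments come back with the correct class and
near-target segment deltas; the mildly hypomethylated background
(Δ ≈ −5) stays in "other". Integrating with expression
(`python examples/04_integrate_expression.py`, 500 genes, 10 coupled
drivers):

```
genes tested after TPM>=10 filter: 500
significant DEGs (FDR<0.05): 10
planted drivers recovered: 10/10, false candidates: 0
```

The same stages are exposed as a thin CLI (`methdriver simulate`,
`matrix`, `dmr`, `annotate`, `regions`, `integrate`, `stratify`, `run`),
with every threshold defaulting to the published analysis values and any
override recorded in the run manifest.

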