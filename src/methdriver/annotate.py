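"""DMR location annotation, region methylation summaries, gene association.

Location categories (mutually exclusive, assigned by precedence):

    Whole-body      DMR covers the entire gene span
    Upstream-Body   DMR crosses the TSS (overlaps the 2 kb upstream window
                    and the gene span)
    Body-Downstream DMR crosses the gene end (overlaps the gene span and
                    the 200 bp downstream window)
    Upstream        DMR overlaps only the 2 kb upstream window
    Downstream      DMR overlaps only the 200 bp downstream window
    Inner-genic     DMR fully inside the gene span, within a single intron
    Body            DMR fully inside the gene span, overlapping >= 1 exon
    Intergenic      none of the above

A DMR is associated with a gene's upstream (promoter) or downstream
regulatory region when the overlap reaches 50% of the DMR length or the
DMR lies entirely within the window; a DMR may associate with several
genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genes import GeneModel, Genome, overlap_bp

logger = logging.getLogger(__name__)

LOCATION_CATEGORIES = [
    "Upstream", "Upstream-Body", "Inner-genic", "Body", "Body-Downstream",
    "Downstream", "Whole-body", "Intergenic",
]

TRANSCRIPT_REGIONS = [
    "5'UTR upstream 5k", "5'UTR upstream 2k", "5'UTR", "Transcript",
    "3'UTR", "3'UTR downstream 2k",
]


def _categorize_vs_gene(
    dmr: tuple[int, int],
    gene: GeneModel,
    promoter_bp: int = 2000,
    downstream_bp: int = 200,
) -> str | None:
    """Location of a DMR interval relative to one gene, or None if disjoint
    from the gene span and both regulatory windows."""
    span = (gene.tx_start, gene.tx_end)
    up = gene.promoter_window_sized(promoter_bp)
    down = gene.downstream_window_sized(downstream_bp)
    in_span = overlap_bp(dmr, span) > 0
    in_up = overlap_bp(dmr, up) > 0
    in_down = overlap_bp(dmr, down) > 0
    if dmr[0] <= span[0] and dmr[1] >= span[1]:
        return "Whole-body"
    if in_span and in_up:
        return "Upstream-Body"
    if in_span and in_down:
        return "Body-Downstream"
    if in_up and not in_span:
        return "Upstream"
    if in_down and not in_span:
        return "Downstream"
    if in_span:
        # fully inside the gene span here (crossing an edge implies window
        # overlap, handled above)
        touches_exon = any(overlap_bp(dmr, ex) > 0 for ex in gene.exons)
        return "Body" if touches_exon else "Inner-genic"
    return None


def annotate_dmr_location(
    dmrs: pd.DataFrame,
    genes: list[GeneModel] | Genome,
    promoter_bp: int = 2000,
    downstream_bp: int = 200,
) -> pd.DataFrame:
    """Assign each DMR a location category, best gene hit, and TSS distance.

    Multi-gene overlaps resolve to the gene with the largest overlap with
    the DMR (gene span first, regulatory windows as fallback); ties break
    by TSS distance then gene id.  DMRs touching nothing are Intergenic,
    with the nearest gene's TSS distance still reported.
    """
    if isinstance(genes, Genome):
        genes = genes.genes
    out = dmrs.copy().reset_index(drop=True)
    cats, hit_ids, tss_dists = [], [], []
    for _, d in out.iterrows():
        iv = (int(d["start"]), int(d["end"]))
        mid = (iv[0] + iv[1]) / 2
        best = None  # (overlap_key, category, gene)
        nearest = None
        for g in [g for g in genes if g.chrom == d["chrom"]]:
            dist = abs(g.tss - mid)
            if nearest is None or dist < nearest[0]:
                nearest = (dist, g)
            cat = _categorize_vs_gene(iv, g, promoter_bp, downstream_bp)
            if cat is None:
                continue
            ov = max(
                overlap_bp(iv, (g.tx_start, g.tx_end)),
                overlap_bp(iv, g.promoter_window_sized(promoter_bp)),
                overlap_bp(iv, g.downstream_window_sized(downstream_bp)),
            )
            key = (-ov, dist, g.gene_id)
            if best is None or key < best[0]:
                best = (key, cat, g)
        if best is None:
            cats.append("Intergenic")
            hit_ids.append(None)
            tss_dists.append(float(nearest[0]) if nearest else np.nan)
        else:
            _, cat, g = best
            cats.append(cat)
            hit_ids.append(g.gene_id)
            tss_dists.append(float(abs(g.tss - mid)))
    out["location"] = cats
    out["gene_id"] = hit_ids
    out["tss_distance"] = tss_dists
    return out


def location_proportions(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-class fractions over the eight location categories (sum to 1).

    Classes with no DMRs are omitted with a logged notice.
    """
    rows = []
    for cls in ("hyper", "hypo", "other"):
        grp = annotated[annotated["dmr_class"] == cls]
        if grp.empty:
            logger.info("class %s empty; omitted from location proportions", cls)
            continue
        counts = grp["location"].value_counts()
        for cat in LOCATION_CATEGORIES:
            rows.append(
                {
                    "dmr_class": cls,
                    "location": cat,
                    "fraction": counts.get(cat, 0) / len(grp),
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------- region sets

def build_region_set(genome: Genome) -> pd.DataFrame:
    """Named strand-aware intervals: six transcript-anchored regions per
    gene plus any regulatory elements carried by the genome.

    The toy genes have one transcript and no annotated CDS, so the 5'UTR
    and 3'UTR anchors are the first and last exon in transcription order.
    Intervals are clipped to chromosome bounds.
    """
    rows = []
    for g in genome.genes:
        L = genome.chrom_lengths[g.chrom]
        exons = sorted(g.exons)
        if g.strand == "+":
            utr5, utr3 = exons[0], exons[-1]
            anchors = {
                "5'UTR upstream 5k": (g.tss - 5000, g.tss - 2001),
                "5'UTR upstream 2k": (g.tss - 2000, g.tss - 1),
                "5'UTR": utr5,
                "Transcript": (g.tx_start, g.tx_end),
                "3'UTR": utr3,
                "3'UTR downstream 2k": (g.gene_end + 1, g.gene_end + 2000),
            }
        else:
            utr5, utr3 = exons[-1], exons[0]
            anchors = {
                "5'UTR upstream 5k": (g.tss + 2001, g.tss + 5000),
                "5'UTR upstream 2k": (g.tss + 1, g.tss + 2000),
                "5'UTR": utr5,
                "Transcript": (g.tx_start, g.tx_end),
                "3'UTR": utr3,
                "3'UTR downstream 2k": (g.gene_end - 2000, g.gene_end - 1),
            }
        for name, (lo, hi) in anchors.items():
            lo, hi = max(1, lo), min(L, hi)
            if lo <= hi:
                rows.append(
                    {"region": name, "chrom": g.chrom, "start": lo, "end": hi}
                )
    for etype, chrom, lo, hi in genome.elements:
        rows.append({"region": etype, "chrom": chrom, "start": lo, "end": hi})
    return pd.DataFrame(rows)


def region_methylation_summary(
    meth_matrix: pd.DataFrame,
    region_set: pd.DataFrame,
    sample_sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Unweighted mean beta over all (CpG, sample) pairs per named region,
    separately for tumor and normal.  Regions containing no CpGs are
    reported absent (omitted)."""
    tumor = sample_sheet.loc[sample_sheet["group"] == "tumor", "sample_id"]
    normal = sample_sheet.loc[sample_sheet["group"] == "normal", "sample_id"]
    rows = []
    for name, regions in region_set.groupby("region", sort=False):
        pieces = []
        for _, r in regions.iterrows():
            try:
                sub = meth_matrix.xs(r["chrom"], level="chrom")
            except KeyError:
                continue
            pos = sub.index.to_numpy()
            hit = sub.loc[(pos >= r["start"]) & (pos <= r["end"])]
            if not hit.empty:
                pieces.append(hit)
        if not pieces:
            continue
        block = pd.concat(pieces)
        rows.append(
            {
                "region": name,
                "n_cpgs": len(block),
                "tumor_mean_beta": float(block[list(tumor)].to_numpy().mean()),
                "normal_mean_beta": float(block[list(normal)].to_numpy().mean()),
            }
        )
    return pd.DataFrame(rows)


# -------------------------------------------------------- gene association

def associate_dmr_gene(
    dmrs: pd.DataFrame,
    genes: list[GeneModel] | Genome,
    overlap_fraction: float = 0.5,
    promoter_bp: int = 2000,
    downstream_bp: int = 200,
) -> pd.DataFrame:
    """Link DMRs to gene regulatory regions by the 50%-overlap rule.

    A DMR associates with a gene's upstream (promoter) region when
    overlap(DMR, promoter window) >= overlap_fraction * DMR length, or the
    DMR lies entirely inside the window; likewise for the 200 bp
    downstream window.  Output rows: dmr_index, gene_id, region in
    {upstream_regulatory, downstream_regulatory}.
    """
    if isinstance(genes, Genome):
        genes = genes.genes
    rows = []
    for idx, d in dmrs.reset_index(drop=True).iterrows():
        iv = (int(d["start"]), int(d["end"]))
        length = iv[1] - iv[0] + 1
        for g in [g for g in genes if g.chrom == d["chrom"]]:
            for region, window in (
                ("upstream_regulatory", g.promoter_window_sized(promoter_bp)),
                ("downstream_regulatory", g.downstream_window_sized(downstream_bp)),
            ):
                ov = overlap_bp(iv, window)
                inside = window[0] <= iv[0] and iv[1] <= window[1]
                if inside or ov >= overlap_fraction * length:
                    rows.append(
                        {"dmr_index": idx, "gene_id": g.gene_id, "region": region}
                    )
    return pd.DataFrame(rows, columns=["dmr_index", "gene_id", "region"])
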