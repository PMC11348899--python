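"""Differential expression and methylation-expression integration.

Genes averaging under 10 TPM across all samples (tumor and normal pooled)
are excluded before testing; the remainder get a two-sided rank-sum test
with BH-FDR control at 0.05.  A DEG carrying a classified DMR in a
regulatory region becomes a Methy-DEG in one of four direction
combinations; the candidate set — genes plausibly driven by methylation —
is exactly hyper-down plus hypo-up.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .genes import Genome, overlap_bp
from .stats import bh_fdr, ranksum_p_rows

MIN_MEAN_TPM = 10.0
DEG_FDR = 0.05

CANDIDATE_CATEGORIES = ("hyper-down", "hypo-up")


def compute_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Length-normalize raw counts to TPM (each column sums to 1e6)."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValidationError(f"genes without lengths: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValidationError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValidationError(f"zero library after length normalization: {empty}")
    return rate.div(totals, axis=1) * 1e6


def deg_test(
    tpm: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    min_mean_tpm: float = MIN_MEAN_TPM,
    fdr_threshold: float = DEG_FDR,
) -> pd.DataFrame:
    """Rank-sum DEG test on the TPM-filtered gene set.

    Direction is the sign of (median tumor - median normal) for
    significant genes, 'ns' otherwise; constant genes are ns with p = 1.
    The BH denominator is the number of genes that survive the filter.
    """
    tumor = sample_sheet.loc[sample_sheet["group"] == "tumor", "sample_id"].tolist()
    normal = sample_sheet.loc[sample_sheet["group"] == "normal", "sample_id"].tolist()
    if len(tumor) < 2 or len(normal) < 2:
        raise ValidationError("need >=2 samples per group for DEG testing")
    mean_all = tpm[tumor + normal].mean(axis=1)
    kept = tpm.loc[mean_all >= min_mean_tpm]
    x = kept[tumor].to_numpy(float)
    y = kept[normal].to_numpy(float)
    if len(kept) == 0:
        return pd.DataFrame(
            columns=["mean_tpm_all", "p_value", "fdr", "direction"]
        )
    p = ranksum_p_rows(x, y)
    fdr = bh_fdr(p)
    med_diff = np.median(x, axis=1) - np.median(y, axis=1)
    direction = np.where(
        fdr < fdr_threshold, np.where(med_diff > 0, "up", "down"), "ns"
    )
    # a significant gene with exactly equal medians has no direction
    direction = np.where(
        (fdr < fdr_threshold) & (med_diff == 0), "ns", direction
    )
    return pd.DataFrame(
        {
            "mean_tpm_all": mean_all.loc[kept.index],
            "p_value": p,
            "fdr": fdr,
            "direction": direction,
        },
        index=kept.index,
    )


def classify_methy_deg(
    deg_table: pd.DataFrame,
    associations: pd.DataFrame,
    dmrs: pd.DataFrame,
) -> pd.DataFrame:
    """Cross DEG directions with associated DMR classes.

    Only significant DEGs (direction up/down) with at least one associated
    hyper/hypo DMR appear.  Genes linked to both hyper and hypo DMRs are
    flagged ambiguous and resolved by the larger |delta| DMR.  Candidates
    are the hyper-down and hypo-up combinations.
    """
    dmrs = dmrs.reset_index(drop=True)
    rows = []
    sig = deg_table[deg_table["direction"].isin(["up", "down"])]
    assoc_by_gene = (
        associations.groupby("gene_id")["dmr_index"].apply(list)
        if not associations.empty else pd.Series(dtype=object)
    )
    for gene_id, deg in sig.iterrows():
        if gene_id not in assoc_by_gene.index:
            continue
        linked = dmrs.loc[assoc_by_gene[gene_id]]
        linked = linked[linked["dmr_class"].isin(["hyper", "hypo"])]
        if linked.empty:
            continue
        classes = set(linked["dmr_class"])
        ambiguous = len(classes) > 1
        top = linked.loc[linked["delta"].abs().idxmax()]
        meth_direction = top["dmr_class"]
        expr_direction = deg["direction"]
        category = f"{meth_direction}-{expr_direction}"
        rows.append(
            {
                "gene_id": gene_id,
                "meth_direction": meth_direction,
                "expr_direction": expr_direction,
                "category": category,
                "candidate": category in CANDIDATE_CATEGORIES,
                "ambiguous": ambiguous,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "meth_direction", "expr_direction", "category",
            "candidate", "ambiguous",
        ],
    )


def dmr_expression_correlation(
    meth_matrix: pd.DataFrame,
    tpm: pd.DataFrame,
    genome: Genome,
    gene_id: str,
    dmr: tuple[str, int, int],
    min_shared: int = 5,
) -> pd.DataFrame:
    """Per-CpG Spearman correlation between beta and the gene's TPM.

    CpGs within the gene's promoter window, span, and downstream window
    are profiled and flagged in/out of the given DMR interval; p-values
    are BH-adjusted across the profiled CpGs.
    """
    gene = genome.gene(gene_id)
    shared = [s for s in meth_matrix.columns if s in tpm.columns]
    if len(shared) < min_shared:
        raise ValidationError(
            f"only {len(shared)} shared samples (<{min_shared})"
        )
    expr = tpm.loc[gene_id, shared].to_numpy(float)
    windows = [
        gene.promoter_window, (gene.tx_start, gene.tx_end),
        gene.downstream_window,
    ]
    sub = meth_matrix.xs(gene.chrom, level="chrom")[shared]
    pos = sub.index.to_numpy()
    mask = np.zeros(len(pos), dtype=bool)
    for lo, hi in windows:
        mask |= (pos >= lo) & (pos <= hi)
    sub = sub.loc[mask]
    pos = pos[mask]
    chrom, lo, hi = dmr
    rows = []
    for p, (_, betas) in zip(pos, sub.iterrows()):
        b = betas.to_numpy(float)
        if np.all(b == b[0]) or np.all(expr == expr[0]):
            rho, pval = np.nan, 1.0
        else:
            rho, pval = sps.spearmanr(b, expr)
        rows.append(
            {
                "pos": int(p),
                "rho": rho,
                "p_value": pval,
                "in_dmr": bool(chrom == gene.chrom and lo <= p <= hi),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    return out
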