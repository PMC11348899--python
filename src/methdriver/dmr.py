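"""DMR calling: per-CpG testing, delta track, CBS segmentation, classification.

The comparison is unpaired tumor vs normal.  Per-CpG differential
methylation (DMC) is a two-sided rank-sum test with BH-FDR control; the
delta track is the per-CpG difference of group mean betas
(tumor average - normal average, percent points).  Circular binary
segmentation partitions each chromosome's delta series; segments are then
forced under the 1 Mb span limit, segments with fewer than three CpGs are
dropped, and surviving regions are classified:

    hyper:  delta >= +10
    hypo:   delta <= -15
    other:  in between

Both class thresholds are inclusive.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from ._cbs import best_arc, sequential_perm_test
from .errors import ValidationError
from .stats import bh_fdr, ranksum_p_rows

logger = logging.getLogger(__name__)

HYPER_DELTA = 10.0
HYPO_DELTA = -15.0
MAX_SPAN_BP = 1_000_000
MIN_CPGS = 3
DMC_FDR = 0.05

DMR_COLUMNS = [
    "chrom", "start", "end", "n_cpgs", "span_bp", "delta",
    "mean_adjacent_gap_bp",
]


def _group_columns(sample_sheet: pd.DataFrame, group: str) -> list[str]:
    cols = sample_sheet.loc[sample_sheet["group"] == group, "sample_id"].tolist()
    return cols


def build_delta_track(
    meth_matrix: pd.DataFrame, sample_sheet: pd.DataFrame
) -> pd.DataFrame:
    """Per-CpG group means and their difference.

    Returns a frame indexed like the matrix with columns
    ``t_average``, ``n_average``, ``delta`` (= t_average - n_average).
    """
    tumor = _group_columns(sample_sheet, "tumor")
    normal = _group_columns(sample_sheet, "normal")
    if not tumor or not normal:
        raise ValidationError("both tumor and normal groups must be non-empty")
    t_avg = meth_matrix[tumor].mean(axis=1)
    n_avg = meth_matrix[normal].mean(axis=1)
    out = pd.DataFrame(
        {"t_average": t_avg, "n_average": n_avg, "delta": t_avg - n_avg},
        index=meth_matrix.index,
    )
    return out


def dmc_test(
    meth_matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    fdr_threshold: float = DMC_FDR,
) -> pd.DataFrame:
    """Per-CpG two-sided rank-sum test (tumor vs normal) with BH FDR.

    Constant rows (identical betas across both groups) are flagged
    ``degenerate`` and given p = 1 by convention.
    """
    tumor = _group_columns(sample_sheet, "tumor")
    normal = _group_columns(sample_sheet, "normal")
    if len(tumor) < 2 or len(normal) < 2:
        raise ValidationError("need >=2 tumor and >=2 normal samples")
    x = meth_matrix[tumor].to_numpy(float)
    y = meth_matrix[normal].to_numpy(float)
    pooled = np.concatenate([x, y], axis=1)
    degenerate = np.all(pooled == pooled[:, :1], axis=1)
    p = ranksum_p_rows(x, y)
    fdr = bh_fdr(p)
    return pd.DataFrame(
        {
            "p_value": p,
            "fdr": fdr,
            "significant": fdr < fdr_threshold,
            "degenerate": degenerate,
        },
        index=meth_matrix.index,
    )


def _segment_stretch(
    x: np.ndarray,
    lo: int,
    hi: int,
    alpha: float,
    n_perm: int,
    min_split_size: int,
    seed_pool: np.ndarray,
    counter: list[int],
) -> list[tuple[int, int]]:
    n = hi - lo
    if n < min_split_size:
        return [(lo, hi)]
    obs, bi, bj = best_arc(x[lo:hi])
    if not (obs > 0):
        return [(lo, hi)]
    stop_exceed = max(1, math.floor(alpha * (n_perm + 1)))
    accept_after = min(n_perm, math.ceil(1.0 / alpha) - 1)
    seed = int(seed_pool[counter[0] % len(seed_pool)])
    counter[0] += 1
    k, m = sequential_perm_test(
        x[lo:hi], obs, n_perm, stop_exceed, accept_after, seed
    )
    p = (1 + k) / (1 + m)
    if p > alpha:
        return [(lo, hi)]
    cuts = [lo, lo + bi, lo + bj, hi]
    pieces = []
    for a, b in zip(cuts, cuts[1:]):
        if b > a:
            pieces.extend(
                _segment_stretch(
                    x, a, b, alpha, n_perm, min_split_size, seed_pool, counter
                )
            )
    return pieces


def cbs_segment(
    delta_track: pd.DataFrame,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    seed: int = 0,
    min_split_size: int = 6,
) -> pd.DataFrame:
    """Circular binary segmentation of the per-chromosome delta series.

    For each chromosome (CpGs sorted by position) the best arc (i, j] by
    the t-like statistic is tested against a seeded permutation null; an
    accepted split cuts the stretch at both arc boundaries and recursion
    continues on the pieces.  The returned segments partition every CpG.

    Columns: chrom, start, end (positions of first/last member CpG),
    start_idx/end_idx (half-open indices into the chromosome's CpG
    series), n_cpgs, delta (mean of member CpG deltas).
    """
    if not delta_track.index.is_monotonic_increasing:
        delta_track = delta_track.sort_index()
    rows = []
    chroms = delta_track.index.get_level_values(0).unique()
    for ci, chrom in enumerate(chroms):
        sub = delta_track.xs(chrom, level=0)
        pos = sub.index.to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise ValidationError(f"{chrom}: CpG positions not strictly increasing")
        x = sub["delta"].to_numpy(float)
        seed_pool = np.random.SeedSequence([int(seed), ci]).generate_state(4096)
        counter = [0]
        for lo, hi in _segment_stretch(
            x, 0, len(x), alpha, n_permutations, min_split_size, seed_pool, counter
        ):
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[lo]),
                    "end": int(pos[hi - 1]),
                    "start_idx": lo,
                    "end_idx": hi,
                    "n_cpgs": hi - lo,
                    "delta": float(x[lo:hi].mean()),
                }
            )
    return pd.DataFrame(rows)


def _mean_adjacent_gap(positions: np.ndarray) -> float:
    """Average of successive CpG position differences (NaN for a lone CpG)."""
    if len(positions) < 2:
        return float("nan")
    return float(np.diff(positions).mean())


def enforce_dmr_constraints(
    segments: pd.DataFrame,
    delta_track: pd.DataFrame,
    max_span_bp: int = MAX_SPAN_BP,
    min_cpgs: int = MIN_CPGS,
) -> pd.DataFrame:
    """Apply the DMR size rules: span < 1 Mb (recursively split at the
    largest internal inter-CpG gap), >= 3 member CpGs (smaller segments
    dropped).  Survivors are re-scored (delta, span, adjacent-CpG gap).
    """
    out = []
    for chrom, chrom_segs in segments.groupby("chrom", sort=False):
        sub = delta_track.xs(chrom, level=0)
        pos = sub.index.to_numpy()
        delta = sub["delta"].to_numpy(float)

        def emit(lo: int, hi: int):
            span = int(pos[hi - 1] - pos[lo] + 1)
            if span >= max_span_bp and hi - lo >= 2:
                gaps = np.diff(pos[lo:hi])
                cut = lo + 1 + int(np.argmax(gaps))
                emit(lo, cut)
                emit(cut, hi)
                return
            if hi - lo < min_cpgs:
                return
            out.append(
                {
                    "chrom": chrom,
                    "start": int(pos[lo]),
                    "end": int(pos[hi - 1]),
                    "n_cpgs": hi - lo,
                    "span_bp": span,
                    "delta": float(delta[lo:hi].mean()),
                    "mean_adjacent_gap_bp": _mean_adjacent_gap(pos[lo:hi]),
                }
            )

        for _, seg in chrom_segs.iterrows():
            emit(int(seg["start_idx"]), int(seg["end_idx"]))
    return pd.DataFrame(out, columns=DMR_COLUMNS)


def classify_dmrs(
    dmrs: pd.DataFrame,
    hyper_threshold: float = HYPER_DELTA,
    hypo_threshold: float = HYPO_DELTA,
) -> pd.DataFrame:
    """Attach ``dmr_class``: hyper (delta >= 10), hypo (delta <= -15), other.

    Both boundaries are inclusive; classification is a pure function of
    delta and is idempotent.
    """
    out = dmrs.copy()
    delta = out["delta"].to_numpy(float)
    cls = np.where(
        delta >= hyper_threshold, "hyper",
        np.where(delta <= hypo_threshold, "hypo", "other"),
    )
    out["dmr_class"] = cls
    return out


def summarize_dmrs(dmrs: pd.DataFrame) -> dict:
    """Per-class DMR summaries and between-class rank-sum comparisons.

    Returns {"per_class": frame (n, span/CpG-count quartiles, mean
    adjacent-CpG gap), "comparisons": frame of pairwise rank-sum p-values
    on span, CpG count and gap (None when < 2 classes present)}.
    """
    per_class_rows = []
    for cls, grp in dmrs.groupby("dmr_class"):
        if grp.empty:
            continue
        q25, q50, q75 = np.percentile(grp["span_bp"], [25, 50, 75])
        c25, c50, c75 = np.percentile(grp["n_cpgs"], [25, 50, 75])
        per_class_rows.append(
            {
                "dmr_class": cls,
                "n": len(grp),
                "span_q25": q25, "span_median": q50, "span_q75": q75,
                "ncpg_q25": c25, "ncpg_median": c50, "ncpg_q75": c75,
                "mean_adjacent_gap_bp": float(
                    grp["mean_adjacent_gap_bp"].mean()
                ),
            }
        )
    per_class = pd.DataFrame(per_class_rows)
    classes = per_class["dmr_class"].tolist() if not per_class.empty else []
    if len(classes) < 2:
        logger.info("fewer than two DMR classes present; between-class tests skipped")
        return {"per_class": per_class, "comparisons": None}
    comp_rows = []
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            ga = dmrs[dmrs["dmr_class"] == a]
            gb = dmrs[dmrs["dmr_class"] == b]
            for metric in ("span_bp", "n_cpgs", "mean_adjacent_gap_bp"):
                xa = ga[metric].dropna().to_numpy(float)
                xb = gb[metric].dropna().to_numpy(float)
                p = float(
                    ranksum_p_rows(xa[None, :], xb[None, :])[0]
                ) if len(xa) and len(xb) else float("nan")
                comp_rows.append(
                    {"class_a": a, "class_b": b, "metric": metric, "p_value": p}
                )
    return {"per_class": per_class, "comparisons": pd.DataFrame(comp_rows)}


def call_dmrs(
    meth_matrix: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    seed: int = 0,
    max_span_bp: int = MAX_SPAN_BP,
    min_cpgs: int = MIN_CPGS,
    hyper_threshold: float = HYPER_DELTA,
    hypo_threshold: float = HYPO_DELTA,
    significant_only: bool = False,
    dmc_fdr: float = DMC_FDR,
) -> pd.DataFrame:
    """Full DMR-calling chain: delta track -> CBS -> constraints -> classes.

    ``significant_only`` restricts segmentation to FDR-significant DMCs
    (the default segments genome-wide; DMC testing is a parallel readout).
    """
    delta = build_delta_track(meth_matrix, sample_sheet)
    if significant_only:
        dmc = dmc_test(meth_matrix, sample_sheet, fdr_threshold=dmc_fdr)
        delta = delta.loc[dmc["significant"].to_numpy()]
    segs = cbs_segment(
        delta, alpha=alpha, n_permutations=n_permutations, seed=seed
    )
    dmrs = enforce_dmr_constraints(
        segs, delta, max_span_bp=max_span_bp, min_cpgs=min_cpgs
    )
    return classify_dmrs(
        dmrs, hyper_threshold=hyper_threshold, hypo_threshold=hypo_threshold
    )
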