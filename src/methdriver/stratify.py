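"""Panel scoring, k-means subgrouping, survival and ROC evaluation.

The panel score is the unweighted mean expression of a gene panel per
sample (the paper-style "retinol score" generalized to any panel).
Tumors are clustered by k-means (k = 3 by default) on per-gene z-scores
of log2(TPM+1) panel expression; clusters are relabeled C1..Ck in
decreasing order of mean panel score so labels are stable across runs.
Survival uses Kaplan-Meier estimation and the G-sample log-rank test
after excluding records with under 30 days of follow-up; DMR-based
tumor/normal discrimination is summarized by the Mann-Whitney AUC with a
Youden-optimal cutoff.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import ValidationError
from .stats import mann_whitney_auc

logger = logging.getLogger(__name__)

MIN_FOLLOWUP_DAYS = 30


def panel_score(
    expression: pd.DataFrame, panel: list[str], log2_transform: bool = False
) -> pd.Series:
    """Equal-weight mean of the panel genes' expression per sample.

    Scores are on the input scale unless ``log2_transform`` applies
    log2(x+1) first.  A panel gene missing from the table is an error.
    """
    missing = [g for g in panel if g not in expression.index]
    if missing:
        raise ValidationError(f"panel genes missing from expression table: {missing}")
    block = expression.loc[list(panel)]
    if log2_transform:
        block = np.log2(block + 1.0)
    return block.mean(axis=0).rename("panel_score")


def cluster_subgroups(
    expression: pd.DataFrame,
    panel: list[str],
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 50,
) -> pd.Series:
    """K-means subgroups on z-scored log2(TPM+1) panel expression.

    Returns sample -> label in {C1..Ck}, labels ordered by decreasing
    cluster mean panel score (C1 highest).  Fewer distinct sample
    profiles than k is an error.
    """
    missing = [g for g in panel if g not in expression.index]
    if missing:
        raise ValidationError(f"panel genes missing from expression table: {missing}")
    if expression.shape[1] < k:
        raise ValidationError(f"need >= {k} samples for k={k}")
    logged = np.log2(expression.loc[list(panel)] + 1.0)
    sd = logged.std(axis=1, ddof=0).replace(0, 1.0)
    z = logged.sub(logged.mean(axis=1), axis=0).div(sd, axis=0)
    points = z.T.to_numpy(float)
    if len(np.unique(points, axis=0)) < k:
        raise ValidationError(
            f"fewer than {k} distinct sample profiles; cannot form {k} clusters"
        )
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(points)
    scores = panel_score(expression, panel, log2_transform=True)
    order = (
        pd.DataFrame({"raw": raw, "score": scores.to_numpy()})
        .groupby("raw")["score"].mean().sort_values(ascending=False).index
    )
    relabel = {int(old): f"C{rank + 1}" for rank, old in enumerate(order)}
    return pd.Series(
        [relabel[int(r)] for r in raw], index=expression.columns, name="subgroup"
    )


def silhouette_by_k(
    expression: pd.DataFrame,
    panel: list[str],
    k_values: tuple[int, ...] = (2, 3, 4, 5),
    seed: int = 0,
) -> pd.Series:
    """Mean silhouette width of the k-means partition for each k.

    A diagnostic only — it never auto-selects k (the default stays 3).
    Uses the same z-scored log2(TPM+1) panel space as
    :func:`cluster_subgroups`.
    """
    logged = np.log2(expression.loc[list(panel)] + 1.0)
    sd = logged.std(axis=1, ddof=0).replace(0, 1.0)
    points = logged.sub(logged.mean(axis=1), axis=0).div(sd, axis=0).T.to_numpy()
    out = {}
    for k in k_values:
        if not 2 <= k < len(points):
            continue
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(points)
        if len(np.unique(labels)) < 2:
            continue
        out[k] = float(silhouette_score(points, labels))
    return pd.Series(out, name="mean_silhouette")


def filter_survival(
    survival: pd.DataFrame, min_followup_days: int = MIN_FOLLOWUP_DAYS
) -> pd.DataFrame:
    """Drop records with missing fields or follow-up under 30 days."""
    out = survival.dropna(subset=["sample", "time_days", "event"])
    return out[out["time_days"] >= min_followup_days].reset_index(drop=True)


def km_estimate(
    survival: pd.DataFrame, groups: pd.Series
) -> dict[str, dict]:
    """Kaplan-Meier product-limit curve per group.

    Expects records already passed through :func:`filter_survival` (the
    30-day rule is a separate step).  Returns group -> {"curve": frame
    (time, survival), "median": median survival time (inf when never
    crossed), "n": group size}.  Empty groups are omitted with a notice.
    """
    filtered = survival
    out = {}
    for grp in pd.unique(groups):
        members = groups[groups == grp].index
        sub = filtered[filtered["sample"].isin(members)]
        if sub.empty:
            logger.info("group %s empty after follow-up filtering; omitted", grp)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_days"], event_observed=sub["event"])
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        out[str(grp)] = {
            "curve": curve,
            "median": float(kmf.median_survival_time_),
            "n": int(len(sub)),
        }
    return out


def logrank_test(survival: pd.DataFrame, groups: pd.Series) -> dict:
    """G-sample log-rank test across subgroups (expects filtered records).

    Returns {"statistic", "df", "p_value", "defined"}; with no events the
    test is undefined and reported as such (NaN statistic/p).
    """
    merged = survival.merge(
        groups.rename("group"), left_on="sample", right_index=True
    )
    n_groups = merged["group"].nunique()
    if n_groups < 2:
        raise ValidationError("log-rank needs >= 2 groups after filtering")
    if merged["event"].sum() == 0:
        logger.info("no events in any group; log-rank undefined")
        return {
            "statistic": float("nan"), "df": n_groups - 1,
            "p_value": float("nan"), "defined": False,
        }
    res = multivariate_logrank_test(
        merged["time_days"], merged["group"], merged["event"]
    )
    return {
        "statistic": float(res.test_statistic),
        "df": int(n_groups - 1),
        "p_value": float(res.p_value),
        "defined": True,
    }


def dmr_roc(
    meth_matrix: pd.DataFrame,
    dmr: dict | pd.Series,
    sample_sheet: pd.DataFrame,
) -> dict:
    """Tumor-vs-normal ROC of a DMR's per-sample mean methylation.

    The per-sample score is the mean beta over member CpGs.  Orientation
    makes tumor the positive class: higher score is tumor-like for a
    hyper-DMR, lower for a hypo-DMR.  AUC comes from the Mann-Whitney
    relation (ties count half); the reported cutoff maximizes Youden's
    J = sensitivity + specificity - 1 (ties to higher specificity) and is
    on the original beta scale.
    """
    tumor = sample_sheet.loc[sample_sheet["group"] == "tumor", "sample_id"].tolist()
    normal = sample_sheet.loc[sample_sheet["group"] == "normal", "sample_id"].tolist()
    if not tumor or not normal:
        raise ValidationError("both tumor and normal samples required for ROC")
    sub = meth_matrix.xs(dmr["chrom"], level="chrom")
    pos = sub.index.to_numpy()
    member = sub.loc[(pos >= dmr["start"]) & (pos <= dmr["end"])]
    if member.empty:
        raise ValidationError("DMR contains no CpGs in the matrix")
    score = member.mean(axis=0)
    sign = -1.0 if dmr.get("dmr_class") == "hypo" else 1.0
    pos_scores = sign * score[tumor].to_numpy(float)
    neg_scores = sign * score[normal].to_numpy(float)
    auc = mann_whitney_auc(pos_scores, neg_scores)

    thresholds = np.unique(np.concatenate([pos_scores, neg_scores]))
    best = None
    for thr in thresholds:
        sens = float(np.mean(pos_scores >= thr))
        spec = float(np.mean(neg_scores < thr))
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    _, cutoff, sens, spec = best
    return {
        "auc": float(auc),
        "cutoff": float(sign * cutoff),
        "sensitivity": sens,
        "specificity": spec,
        "n_cpgs": int(len(member)),
    }


def subgroup_report(
    assignments: pd.Series,
    scores: pd.Series,
    survival: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Per-subgroup sizes and score distributions, Kruskal-Wallis p for
    score vs subgroup (and vs each categorical covariate), KM curves and
    the log-rank p across subgroups.
    """
    orphans = sorted(set(assignments.index) ^ set(scores.index))
    if orphans:
        raise ValidationError(f"misaligned sample ids: {orphans}")
    table = pd.DataFrame({"subgroup": assignments, "score": scores})
    per_group = table.groupby("subgroup")["score"].agg(
        n="count", mean="mean", median="median", q25=lambda s: s.quantile(0.25),
        q75=lambda s: s.quantile(0.75),
    )
    groups = [g["score"].to_numpy() for _, g in table.groupby("subgroup")]
    if len(groups) < 2:
        logger.info("single subgroup; between-group comparisons skipped")
        kw_p = float("nan")
    else:
        kw_p = float(sps.kruskal(*groups).pvalue)
    result = {
        "per_subgroup": per_group,
        "score_kruskal_p": kw_p,
        "km": None,
        "logrank": None,
        "covariate_kruskal_p": {},
    }
    if covariates is not None:
        for col in covariates.columns:
            merged = table.join(covariates[col], how="inner").dropna()
            levels = [
                g["score"].to_numpy() for _, g in merged.groupby(col)
            ]
            result["covariate_kruskal_p"][col] = (
                float(sps.kruskal(*levels).pvalue) if len(levels) > 1 else float("nan")
            )
    if survival is not None and len(groups) > 1:
        filtered = filter_survival(survival)
        result["km"] = km_estimate(filtered, assignments)
        result["logrank"] = logrank_test(filtered, assignments)
    return result
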