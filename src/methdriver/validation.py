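"""Recovery benchmarks on planted synthetic cohorts.

These harnesses run the full pipeline chain on generated data with known
ground truth and measure how much of it is recovered: planted-DMR
recovery (class-correct calls with reciprocal CpG overlap), driver-gene
recovery through the expression integration, subgroup survival ordering,
and agreement of the segmentation arc search with an exhaustive scan.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import dmr, annotate, integrate, stratify
from ._cbs import best_arc
from .simulate import (
    SimConfig,
    choose_spread_genes,
    generate_genome,
    generate_methylome,
    generate_survival,
    plant_promoter_dmrs,
)


def _reciprocal_overlap_recovered(genome, dmrs, planted, expected_class) -> bool:
    """True when some called DMR of the right class shares >= 50% of CpGs
    with the planted segment in both directions."""
    pos = genome.cpg_positions[planted.chrom]
    truth = set(
        pos[(pos >= planted.start_bp) & (pos <= planted.end_bp)].tolist()
    )
    hits = dmrs[(dmrs["chrom"] == planted.chrom)
                & (dmrs["dmr_class"] == expected_class)]
    for _, r in hits.iterrows():
        member = set(pos[(pos >= r["start"]) & (pos <= r["end"])].tolist())
        shared = len(truth & member)
        if shared >= 0.5 * len(truth) and shared >= 0.5 * len(member):
            return True
    return False


def recovery_cohort(seed: int):
    """The planted-DMR benchmark cohort: 2 chromosomes x 2,000 CpGs,
    20 promoter DMRs at |delta| in {15, 30} (5 each sign/magnitude),
    10 tumor and 10 normal samples."""
    cfg = SimConfig(seed=seed, n_chromosomes=2, n_cpgs_per_chrom=2000,
                    n_genes=40)
    genome = generate_genome(cfg)
    hosts = choose_spread_genes(genome, 20)
    planted = (
        plant_promoter_dmrs(genome, hosts[0::4], +30.0)
        + plant_promoter_dmrs(genome, hosts[1::4], -30.0)
        + plant_promoter_dmrs(genome, hosts[2::4], +15.0)
        + plant_promoter_dmrs(genome, hosts[3::4], -15.0)
    )
    cfg = dataclasses.replace(cfg, planted_dmrs=tuple(planted))
    matrix, sheet = generate_methylome(cfg, genome)
    return cfg, genome, matrix, sheet, planted


def planted_dmr_recovery(seeds) -> dict:
    """Fraction of strong (|delta| = 30) planted DMRs recovered with the
    correct class and >= 50% reciprocal CpG overlap, pooled over seeds."""
    recovered = 0
    total = 0
    for seed in seeds:
        cfg, genome, matrix, sheet, planted = recovery_cohort(seed)
        dmrs = dmr.call_dmrs(matrix, sheet, seed=seed)
        for d in planted:
            if abs(d.delta_target) != 30.0:
                continue
            expected = "hyper" if d.delta_target > 0 else "hypo"
            total += 1
            recovered += int(
                _reciprocal_overlap_recovered(genome, dmrs, d, expected)
            )
    return {"recovered": recovered, "total": total,
            "fraction": recovered / total if total else float("nan")}


def integration_cohort(seed: int):
    """Driver-gene benchmark: 500 genes over 2 chromosomes, 10 spread
    drivers with planted promoter hyper-DMRs (+30) negatively coupled to
    expression, 10 samples per arm."""
    cfg = SimConfig(seed=seed, n_chromosomes=2, chrom_length_bp=5_000_000,
                    n_cpgs_per_chrom=1500, island_fraction=0.2, n_genes=500)
    genome = generate_genome(cfg)
    drivers = choose_spread_genes(genome, 10)
    planted = plant_promoter_dmrs(genome, drivers, +30.0)
    cfg = dataclasses.replace(
        cfg, planted_dmrs=tuple(planted),
        driver_genes={g: -1 for g in drivers},
    )
    return cfg, genome, drivers


def integration_recovery(seeds) -> dict:
    """Driver genes recovered as hyper-down candidates and the
    false-candidate rate among non-driver genes, pooled over seeds."""
    from .simulate import generate_expression

    drivers_found = []
    false_candidates = 0
    non_driver_genes = 0
    for seed in seeds:
        cfg, genome, drivers = integration_cohort(seed)
        matrix, sheet = generate_methylome(cfg, genome)
        tpm = generate_expression(cfg, genome, matrix)
        dmrs = dmr.call_dmrs(matrix, sheet, seed=seed)
        assoc = annotate.associate_dmr_gene(dmrs, genome)
        deg = integrate.deg_test(tpm, sheet)
        methy = integrate.classify_methy_deg(deg, assoc, dmrs)
        candidates = set(methy.loc[methy["candidate"], "gene_id"])
        drivers_found.append(len(candidates & set(drivers)))
        false_candidates += len(candidates - set(drivers))
        non_driver_genes += len(genome.genes) - len(drivers)
    return {
        "mean_drivers_recovered": float(np.mean(drivers_found)),
        "n_drivers": 10,
        "false_candidate_rate": false_candidates / non_driver_genes,
        "n_seeds": len(drivers_found),
    }


def survival_direction(seed: int, n_per_group: int = 100) -> dict:
    """Hazards increasing C1 -> C3 should give C1 the best KM curve and a
    significant log-rank difference."""
    cfg = SimConfig(seed=seed)
    ids = [f"s{i}" for i in range(3 * n_per_group)]
    assignment = pd.Series(
        ["C1"] * n_per_group + ["C2"] * n_per_group + ["C3"] * n_per_group,
        index=ids,
    )
    surv = generate_survival(cfg, assignment)
    filtered = stratify.filter_survival(surv)
    km = stratify.km_estimate(filtered, assignment)
    lr = stratify.logrank_test(filtered, assignment)
    return {
        "medians": {g: km[g]["median"] for g in km},
        "logrank_p": lr["p_value"],
        "c1_best": km["C1"]["median"] > km["C2"]["median"] > km["C3"]["median"],
    }


def _python_best_arc(x: np.ndarray):
    """Plain-python exhaustive arc scan (oracle for the compiled kernel)."""
    n = len(x)
    best = (-1.0, 0, 0)
    for i in range(n):
        for j in range(i + 1, n + 1):
            if j - i >= n:
                continue
            arc = x[i:j]
            rest = np.concatenate([x[:i], x[j:]])
            ss = float(((arc - arc.mean()) ** 2).sum()
                       + ((rest - rest.mean()) ** 2).sum())
            diff = abs(float(arc.mean() - rest.mean()))
            if ss < 1e-12:
                stat = np.inf if diff > 1e-9 else 0.0
            else:
                stat = diff / np.sqrt(
                    ss / (n - 2) * (1 / len(arc) + 1 / len(rest))
                )
            if stat > best[0]:
                best = (stat, i, j)
    return best


def cbs_first_split_agreement(n_series: int = 50, max_len: int = 25,
                              seed: int = 0) -> dict:
    """Agreement between the segmentation arc search and an exhaustive
    python scan on short noisy series (with and without planted steps)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for k in range(n_series):
        n = int(rng.integers(6, max_len + 1))
        x = rng.normal(0, 5, n)
        if k % 2:
            lo, hi = sorted(rng.integers(0, n, 2))
            x[lo:hi] += 25
        _, i, j = best_arc(x)
        _, bi, bj = _python_best_arc(x)
        # an arc and its complement induce the same split; compare cut sets
        cuts = {c for c in (i, j) if 0 < c < n}
        bcuts = {c for c in (bi, bj) if 0 < c < n}
        agree += int(cuts == bcuts)
    return {"agree": agree, "total": n_series, "fraction": agree / n_series}
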