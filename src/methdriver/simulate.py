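"""Synthetic tumor/normal methylome, expression, and survival generator.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without any sequencing data:

* a toy multi-chromosome genome with single-transcript genes, dense
  island-like CpG runs at promoters and sparse background CpGs;
* paired tumor/normal beta matrices (percent scale) with a mild global
  tumor hypomethylation shift and planted hyper-/hypo-methylated
  segments of controllable width and delta;
* a TPM expression table in which designated driver genes are negatively
  coupled to their promoter methylation;
* exponential survival times with subgroup-specific hazards and
  independent exponential censoring.

Beta values are drawn from a mean/dispersion-parameterized Beta
distribution (bounded support, no clipping artifacts).  All four
generators are bit-reproducible under a fixed seed: each consumes an
independent child stream of ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SizingError, ValidationError
from .genes import GeneModel, Genome, overlap_bp

__all__ = [
    "PlantedDMR", "SimConfig", "generate_genome", "generate_methylome",
    "generate_expression", "generate_survival", "plant_promoter_dmrs",
    "simulate_cohort",
]

_ISLAND_SPACING_BP = 25  # dense promoter runs, well under the 100 bp island gap


@dataclass(frozen=True)
class PlantedDMR:
    """A ground-truth differential segment (1-based inclusive coordinates)."""

    chrom: str
    start_bp: int
    end_bp: int
    delta_target: float  # percent points, tumor minus normal
    n_cpgs: int = 3

    def __post_init__(self):
        if self.end_bp - self.start_bp >= 1_000_000:
            raise ValidationError(
                f"planted DMR {self.chrom}:{self.start_bp}-{self.end_bp} spans >= 1 Mb"
            )
        if self.n_cpgs < 3:
            raise ValidationError("planted DMRs need at least 3 CpGs")
        if not -100 <= self.delta_target <= 100:
            raise ValidationError("delta_target must be within [-100, 100]")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 2_000_000
    n_cpgs_per_chrom: int = 2000
    island_fraction: float = 0.3
    n_genes: int = 60
    n_tumor: int = 10
    n_normal: int = 10
    planted_dmrs: tuple[PlantedDMR, ...] = ()
    driver_genes: dict = field(default_factory=dict)  # gene_id -> coupling sign
    baseline_beta_normal: float = 70.0
    promoter_beta_dip: float = 20.0
    global_hypomethylation_shift: float = 5.0
    beta_dispersion: float = 0.005
    patient_effect_sd: float = 2.0
    coupling_slope: float = 0.05  # natural-log expression units per beta point
    expression_log_sd: float = 0.5
    expression_base_log_mean: float = 5.7  # ~exp(5.7)=300 relative units
    expression_base_log_sd: float = 1.0
    survival_hazards: dict = field(
        default_factory=lambda: {"C1": 1 / 2000, "C2": 1 / 1000, "C3": 1 / 400}
    )
    censoring_rate: float = 1 / 3000

    def __post_init__(self):
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValidationError("need at least 2 samples per group")
        if not 0 <= self.island_fraction <= 1:
            raise ValidationError("island_fraction must be in [0, 1]")
        if self.censoring_rate <= 0 or any(
            h <= 0 for h in self.survival_hazards.values()
        ):
            raise ValidationError("all rates must be positive")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_genome(config: SimConfig) -> Genome:
    """Build gene models and CpG positions (deterministic in ``seed``).

    CpG positions per chromosome are strictly increasing and total exactly
    ``n_cpgs_per_chrom``.  A fraction ``island_fraction`` of CpGs sits in
    dense promoter runs (gap 25 bp); the remainder lies on a jittered grid
    with all gaps > 100 bp, so ``island_fraction=0`` yields no island-like
    adjacency at all.
    """
    rng = _rng(config, 1)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chrom_length_bp for c in chrom_names}
    genes: list[GeneModel] = []
    cpgs: dict[str, np.ndarray] = {}
    elements: list[tuple[str, str, int, int]] = []

    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    gene_no = 0
    for ci, chrom in enumerate(chrom_names):
        g = per_chrom[ci]
        L = config.chrom_length_bp
        n_cpg = config.n_cpgs_per_chrom

        # genes in evenly spaced slots, away from chromosome edges
        chrom_genes = []
        if g > 0:
            slot = (L - 12_000) / g
            if slot < 9_000:
                raise SizingError(
                    f"{chrom}: {L} bp too short for {g} genes with promoters"
                )
            for k in range(g):
                gene_no += 1
                slot_start = 6_000 + k * slot
                span = rng.uniform(0.25, 0.55) * (slot - 6_000)
                tx_start = int(slot_start + 3_000 + rng.uniform(0, 0.2) * slot)
                tx_end = int(min(tx_start + max(2_000, span), slot_start + slot - 2_500))
                strand = "+" if rng.random() < 0.5 else "-"
                exons = _make_exons(tx_start, tx_end, rng)
                gene = GeneModel(
                    gene_id=f"G{gene_no:04d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exons=exons,
                    transcript_id=f"G{gene_no:04d}.t1",
                )
                chrom_genes.append(gene)
                elements.append(("Promoter", chrom, *gene.promoter_window))
                # a toy distal enhancer upstream of the promoter window
                pw = gene.promoter_window
                if gene.strand == "+":
                    elements.append(("Enhancer", chrom, max(1, pw[0] - 2000), pw[0] - 1001))
                else:
                    elements.append(("Enhancer", chrom, pw[1] + 1001, pw[1] + 2000))
        genes.extend(chrom_genes)

        # island CpGs: dense runs inside promoter windows
        n_island = int(round(config.island_fraction * n_cpg))
        island_pos: list[int] = []
        if n_island > 0:
            if not chrom_genes:
                raise SizingError(f"{chrom}: islands requested but no genes placed")
            # island runs shorter than 5 CpGs are not meaningful dense runs;
            # when the budget is thin, spread full-size runs over an evenly
            # spaced subset of host genes instead of truncating every run
            per_gene = max(5, int(np.ceil(n_island / len(chrom_genes))))
            per_gene = min(per_gene, 1 + (2000 - 1) // _ISLAND_SPACING_BP)
            n_hosts = max(1, int(np.ceil(n_island / per_gene)))
            stride = max(1, len(chrom_genes) // n_hosts)
            hosts = chrom_genes[::stride][:n_hosts]
            for gene in hosts:
                if len(island_pos) >= n_island:
                    break
                take = min(per_gene, n_island - len(island_pos))
                lo, hi = gene.promoter_window
                anchor = hi - (take - 1) * _ISLAND_SPACING_BP
                if anchor < lo:
                    raise SizingError(
                        f"{chrom}: promoter window too small for {take} island CpGs"
                    )
                island_pos.extend(
                    anchor + np.arange(take) * _ISLAND_SPACING_BP
                )
            n_island = len(island_pos)

        # sparse background on a jittered grid, all gaps > 100 bp
        n_sparse = n_cpg - n_island
        positions = np.asarray(sorted(island_pos), dtype=np.int64)
        if n_sparse > 0:
            spacing = L / n_sparse
            if spacing < 300:
                raise SizingError(
                    f"{chrom}: {L} bp too short for {n_sparse} sparse CpGs "
                    "(need >=300 bp average spacing)"
                )
            grid = (np.arange(n_sparse) + 0.5) * spacing
            jitter = rng.uniform(-spacing / 4, spacing / 4, size=n_sparse)
            sparse = np.clip((grid + jitter).astype(np.int64), 1, L)
            taken = set(int(p) for p in positions)
            fixed = []
            for p in sparse:
                q = int(p)
                while q in taken:
                    q += 7
                taken.add(q)
                fixed.append(q)
            positions = np.asarray(sorted(taken), dtype=np.int64)
        if len(positions) != n_cpg:
            raise SizingError(f"{chrom}: CpG placement collision left {len(positions)} != {n_cpg}")
        cpgs[chrom] = positions

    return Genome(
        chrom_lengths=chrom_lengths, genes=genes, cpg_positions=cpgs,
        elements=elements,
    )


def _make_exons(tx_start: int, tx_end: int, rng: np.random.Generator):
    """2-4 exons with internal introns, all inside the transcript span."""
    span = tx_end - tx_start + 1
    n_exons = int(rng.integers(2, 5)) if span > 4000 else 2
    bounds = np.sort(rng.uniform(0.1, 0.9, size=2 * (n_exons - 1)))
    cuts = [0.0, *bounds.tolist(), 1.0]
    exons = []
    for k in range(n_exons):
        lo = tx_start + int(cuts[2 * k] * (span - 1))
        hi = tx_start + int(cuts[2 * k + 1] * (span - 1))
        exons.append((lo, max(lo, hi)))
    exons[-1] = (exons[-1][0], tx_end)
    exons[0] = (tx_start, exons[0][1])
    return tuple(exons)


def genes_with_promoter_cpgs(genome: Genome, min_cpgs: int = 3) -> list[str]:
    """Gene ids whose promoter window holds at least ``min_cpgs`` CpGs."""
    out = []
    for g in genome.genes:
        lo, hi = g.promoter_window
        pos = genome.cpg_positions[g.chrom]
        if int(((pos >= lo) & (pos <= hi)).sum()) >= min_cpgs:
            out.append(g.gene_id)
    return out


def choose_spread_genes(genome: Genome, n: int) -> list[str]:
    """Pick n gene ids with CpG-bearing promoters, spread evenly along the
    genome so planted promoter DMRs are isolated in background rather than
    stacked into one block."""
    ids = genes_with_promoter_cpgs(genome)
    if n > len(ids):
        raise ConfigurationError(
            f"requested {n} genes, only {len(ids)} have promoter CpG runs"
        )
    step = max(1, len(ids) // n)
    picked = ids[::step][:n]
    # pad from the remainder if integer stepping came up short
    for gid in ids:
        if len(picked) >= n:
            break
        if gid not in picked:
            picked.append(gid)
    return picked


def plant_promoter_dmrs(
    genome: Genome, gene_ids: list[str], delta_target: float
) -> list[PlantedDMR]:
    """Construct planted DMRs covering the promoter CpG runs of given genes."""
    planted = []
    for gid in gene_ids:
        gene = genome.gene(gid)
        lo, hi = gene.promoter_window
        pos = genome.cpg_positions[gene.chrom]
        inside = pos[(pos >= lo) & (pos <= hi)]
        if len(inside) < 3:
            raise ConfigurationError(
                f"gene {gid}: promoter window holds {len(inside)} CpGs (<3); "
                "raise island_fraction"
            )
        planted.append(
            PlantedDMR(
                chrom=gene.chrom,
                start_bp=int(inside[0]),
                end_bp=int(inside[-1]),
                delta_target=float(delta_target),
                n_cpgs=int(len(inside)),
            )
        )
    return planted


def _sample_ids(config: SimConfig) -> pd.DataFrame:
    """Sample sheet: paired tumor/normal where patient indices overlap."""
    rows = []
    for i in range(config.n_tumor):
        rows.append({"sample_id": f"T{i + 1:02d}", "group": "tumor",
                     "patient_id": f"P{i + 1:02d}"})
    for i in range(config.n_normal):
        rows.append({"sample_id": f"N{i + 1:02d}", "group": "normal",
                     "patient_id": f"P{i + 1:02d}"})
    return pd.DataFrame(rows)


def generate_methylome(
    config: SimConfig, genome: Genome
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the CpG x sample beta matrix (percent) and its sample sheet.

    Normal means sit at ``baseline_beta_normal`` (promoter CpGs dipped by
    ``promoter_beta_dip``); tumor means are shifted down genome-wide by
    ``global_hypomethylation_shift`` except inside planted DMRs, where the
    tumor mean is the normal mean plus ``delta_target`` (clipped to the
    percent scale).  A shared per-patient offset links paired samples.
    """
    rng = _rng(config, 2)
    sheet = _sample_ids(config)

    index_tuples = []
    means_normal = []
    promoter_ivs = {
        chrom: [g.promoter_window for g in genome.genes_on(chrom)]
        for chrom in genome.cpg_positions
    }
    planted_by_chrom: dict[str, list[PlantedDMR]] = {}
    for d in config.planted_dmrs:
        if d.chrom not in genome.cpg_positions:
            raise ConfigurationError(f"planted DMR on unknown chromosome {d.chrom}")
        planted_by_chrom.setdefault(d.chrom, []).append(d)

    delta_map = []  # per CpG: planted delta or NaN
    for chrom, pos in genome.cpg_positions.items():
        pos = np.asarray(pos)
        base = np.full(len(pos), config.baseline_beta_normal, dtype=float)
        for lo, hi in promoter_ivs[chrom]:
            base[(pos >= lo) & (pos <= hi)] -= config.promoter_beta_dip
        planted_delta = np.full(len(pos), np.nan)
        for d in planted_by_chrom.get(chrom, []):
            inside = (pos >= d.start_bp) & (pos <= d.end_bp)
            if inside.sum() < 3:
                raise ConfigurationError(
                    f"planted DMR {d.chrom}:{d.start_bp}-{d.end_bp} covers "
                    f"{int(inside.sum())} CpGs (<3): outside any CpG run"
                )
            planted_delta[inside] = d.delta_target
        index_tuples.extend((chrom, int(p)) for p in pos)
        means_normal.append(base)
        delta_map.append(planted_delta)

    mean_n = np.concatenate(means_normal)
    planted = np.concatenate(delta_map)
    mean_t = np.where(
        np.isnan(planted),
        mean_n - config.global_hypomethylation_shift,
        mean_n + planted,
    )
    mean_n = np.clip(mean_n, 0.5, 99.5)
    mean_t = np.clip(mean_t, 0.5, 99.5)

    n_pat = max(config.n_tumor, config.n_normal)
    patient_fx = (
        rng.normal(0.0, config.patient_effect_sd, size=n_pat)
        if config.patient_effect_sd > 0 else np.zeros(n_pat)
    )

    cols = {}
    for _, row in sheet.iterrows():
        pidx = int(row["patient_id"][1:]) - 1
        mean = mean_t if row["group"] == "tumor" else mean_n
        mu = np.clip(mean + patient_fx[pidx], 0.5, 99.5) / 100.0
        if config.beta_dispersion <= 0:
            vals = mu * 100.0
        else:
            nu = 1.0 / config.beta_dispersion - 1.0
            vals = rng.beta(mu * nu, (1.0 - mu) * nu) * 100.0
        cols[row["sample_id"]] = vals

    index = pd.MultiIndex.from_tuples(index_tuples, names=["chrom", "pos"])
    matrix = pd.DataFrame(cols, index=index).sort_index()
    return matrix, sheet


def promoter_mean_beta(
    genome: Genome, meth_matrix: pd.DataFrame, gene_id: str
) -> pd.Series:
    """Per-sample mean beta over a gene's promoter-window CpGs."""
    gene = genome.gene(gene_id)
    lo, hi = gene.promoter_window
    sub = meth_matrix.xs(gene.chrom, level="chrom")
    pos = sub.index.to_numpy()
    inside = sub.loc[(pos >= lo) & (pos <= hi)]
    if inside.empty:
        raise ConfigurationError(f"gene {gene_id}: no CpGs in promoter window")
    return inside.mean(axis=0)


def generate_expression(
    config: SimConfig, genome: Genome, meth_matrix: pd.DataFrame
) -> pd.DataFrame:
    """TPM table (gene x sample, columns summing to 1e6).

    Driver genes (coupling sign -1) have log-expression decreasing
    linearly in their promoter-window mean beta; other genes are
    independent of methylation.  Driver genes must carry a planted DMR in
    their promoter window.
    """
    rng = _rng(config, 3)
    samples = meth_matrix.columns.tolist()

    for gid, sign in config.driver_genes.items():
        gene = genome.gene(gid)  # KeyError -> unknown gene id
        pw = gene.promoter_window
        covered = any(
            d.chrom == gene.chrom and overlap_bp(pw, (d.start_bp, d.end_bp)) > 0
            for d in config.planted_dmrs
        )
        if not covered:
            raise ConfigurationError(
                f"driver gene {gid} has no planted DMR in its promoter window"
            )
        if sign not in (-1, 1):
            raise ConfigurationError(f"driver gene {gid}: coupling sign must be +/-1")

    base = rng.normal(
        config.expression_base_log_mean,
        config.expression_base_log_sd,
        size=len(genome.genes),
    )
    log_rate = np.tile(base[:, None], (1, len(samples)))
    gene_ids = [g.gene_id for g in genome.genes]
    for gi, gid in enumerate(gene_ids):
        if gid in config.driver_genes:
            beta = promoter_mean_beta(genome, meth_matrix, gid).loc[samples]
            sign = config.driver_genes[gid]
            # sign is the methylation->expression coupling direction:
            # -1 couples high promoter beta to low expression.  Centering on
            # the cross-sample mean keeps the gene's overall abundance at its
            # baseline so coupling does not push drivers under the TPM filter.
            centered = beta.to_numpy() - float(beta.mean())
            log_rate[gi] += sign * config.coupling_slope * centered
    noise = rng.normal(0.0, config.expression_log_sd, size=log_rate.shape)
    rate = np.exp(log_rate + noise)
    tpm = rate / rate.sum(axis=0, keepdims=True) * 1e6
    return pd.DataFrame(tpm, index=gene_ids, columns=samples)


def generate_survival(
    config: SimConfig, subgroup_assignment: pd.Series
) -> pd.DataFrame:
    """Exponential event/censoring times per subgroup hazard.

    ``subgroup_assignment`` maps sample id -> subgroup label; every label
    must have a hazard in ``config.survival_hazards``.  Columns: sample,
    time_days (integer >= 1), event (1 = death observed, 0 = censored).
    """
    rng = _rng(config, 4)
    rows = []
    for sample, grp in subgroup_assignment.items():
        if grp not in config.survival_hazards:
            raise ConfigurationError(f"no hazard configured for subgroup {grp!r}")
        t_event = rng.exponential(1.0 / config.survival_hazards[grp])
        t_cens = rng.exponential(1.0 / config.censoring_rate)
        t = min(t_event, t_cens)
        rows.append(
            {
                "sample": sample,
                "time_days": max(1, int(np.ceil(t))),
                "event": int(t_event <= t_cens),
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimConfig):
    """Genome + methylome + expression in one call (convenience wrapper)."""
    genome = generate_genome(config)
    matrix, sheet = generate_methylome(config, genome)
    tpm = generate_expression(config, genome, matrix)
    return genome, matrix, sheet, tpm
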