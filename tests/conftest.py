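import dataclasses

import numpy as np
import pandas as pd
import pytest

from methdriver import dmr
from methdriver.genes import GeneModel
from methdriver.simulate import (
    SimConfig,
    choose_spread_genes,
    generate_genome,
    generate_methylome,
    plant_promoter_dmrs,
)


def make_matrix(tumor_rows, normal_rows, positions=None, chrom="chr1"):
    """Build a CpG x sample matrix from per-group row lists.

    ``tumor_rows[i][j]`` is the beta of CpG i in tumor sample j.
    """
    tumor_rows = np.atleast_2d(np.asarray(tumor_rows, dtype=float))
    normal_rows = np.atleast_2d(np.asarray(normal_rows, dtype=float))
    n = tumor_rows.shape[0]
    if positions is None:
        positions = [100 * (i + 1) for i in range(n)]
    index = pd.MultiIndex.from_tuples(
        [(chrom, p) for p in positions], names=["chrom", "pos"]
    )
    cols = {}
    for j in range(tumor_rows.shape[1]):
        cols[f"T{j + 1:02d}"] = tumor_rows[:, j]
    for j in range(normal_rows.shape[1]):
        cols[f"N{j + 1:02d}"] = normal_rows[:, j]
    return pd.DataFrame(cols, index=index)


def make_sheet(n_tumor, n_normal):
    rows = [
        {"sample_id": f"T{j + 1:02d}", "group": "tumor", "patient_id": f"P{j + 1}"}
        for j in range(n_tumor)
    ] + [
        {"sample_id": f"N{j + 1:02d}", "group": "normal", "patient_id": f"P{j + 1}"}
        for j in range(n_normal)
    ]
    return pd.DataFrame(rows)


def delta_track_from(values, positions=None, chrom="chr1"):
    values = np.asarray(values, dtype=float)
    if positions is None:
        positions = 1000 * (np.arange(len(values)) + 1)
    index = pd.MultiIndex.from_tuples(
        [(chrom, int(p)) for p in positions], names=["chrom", "pos"]
    )
    return pd.DataFrame(
        {"t_average": values, "n_average": np.zeros_like(values), "delta": values},
        index=index,
    )


def plus_gene(gene_id="G1", chrom="chr1", start=10_000, end=20_000, exons=None):
    exons = exons or ((start, start + 2_000), (end - 2_000, end))
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand="+", tx_start=start, tx_end=end,
        exons=tuple(exons), transcript_id=f"{gene_id}.t1",
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A planted two-chromosome cohort shared by annotation/ROC tests."""
    cfg = SimConfig(
        seed=20, n_chromosomes=2, chrom_length_bp=1_000_000,
        n_cpgs_per_chrom=600, n_genes=16,
    )
    genome = generate_genome(cfg)
    drivers = choose_spread_genes(genome, 4)
    planted = plant_promoter_dmrs(genome, drivers[:2], +30) + \
        plant_promoter_dmrs(genome, drivers[2:], -30)
    cfg = dataclasses.replace(
        cfg, planted_dmrs=tuple(planted), driver_genes={g: -1 for g in drivers}
    )
    matrix, sheet = generate_methylome(cfg, genome)
    return {
        "config": cfg, "genome": genome, "matrix": matrix, "sheet": sheet,
        "drivers": drivers, "planted": planted,
    }


@pytest.fixture(scope="session")
def small_dmrs(small_cohort):
    return dmr.call_dmrs(
        small_cohort["matrix"], small_cohort["sheet"], seed=99
    )
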