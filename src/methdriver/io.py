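"""Readers and writers for the pipeline's file dialects.

Native coordinates are 1-based inclusive; BED output is 0-based
half-open.  Readers validate rather than coerce: malformed rows raise
:class:`~methdriver.errors.ParseError` with a line number, impossible
values raise :class:`~methdriver.errors.ValidationError`.

Dialects
--------
cytosine report   TSV: chrom, pos, strand, count_methylated,
                  count_unmethylated, context (Bismark CpG-report style)
DMR BED           BED6+2: chrom, start0, end, class, score (|delta|*10
                  clamped to [0, 1000]), strand '.', raw delta, n_cpgs
GTF               gene/transcript/exon features; reading retains only the
                  longest transcript per gene (genomic span, ties to the
                  lexicographically smallest transcript id)
expression TSV    gene_id column + one column per sample
sample sheet TSV  sample_id, group in {tumor, normal}, optional patient_id
survival TSV      sample, time_days (int > 0), event in {0, 1}
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .genes import GeneModel, Genome

logger = logging.getLogger(__name__)

CYTOSINE_COLUMNS = [
    "chrom", "pos", "strand", "meth_count", "unmeth_count", "context",
]


# ---------------------------------------------------------------- CpG tables

def read_cytosine_report(path, min_coverage: int = 4) -> pd.DataFrame:
    """Read a Bismark-style CpG report; drop rows under ``min_coverage``.

    Returns a frame sorted by (chrom, pos) with a computed ``beta``
    (percent) column.  Unsorted input is sorted with a logged notice.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(
                    f"expected >=6 tab-separated fields, got {len(parts)}",
                    line=lineno,
                )
            try:
                pos = int(parts[1])
                meth = int(parts[3])
                unmeth = int(parts[4])
            except ValueError as exc:
                raise ParseError(f"non-integer field ({exc})", line=lineno) from exc
            if parts[2] not in ("+", "-", "."):
                raise ParseError(f"bad strand {parts[2]!r}", line=lineno)
            if meth < 0 or unmeth < 0:
                raise ValidationError(
                    f"line {lineno}: negative counts ({meth}, {unmeth})"
                )
            rows.append((parts[0], pos, parts[2], meth, unmeth, parts[5]))
    df = pd.DataFrame(rows, columns=CYTOSINE_COLUMNS)
    if not df.empty:
        sorted_df = df.sort_values(["chrom", "pos"], kind="mergesort")
        if not sorted_df.index.equals(df.index):
            logger.info("%s: input not sorted by (chrom, pos); sorting", path)
        df = sorted_df.reset_index(drop=True)
    df["coverage"] = df["meth_count"] + df["unmeth_count"]
    df = df[df["coverage"] >= min_coverage].reset_index(drop=True)
    with np.errstate(invalid="ignore"):
        df["beta"] = 100.0 * df["meth_count"] / df["coverage"]
    return df


def write_cytosine_report(df: pd.DataFrame, path) -> None:
    df[CYTOSINE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def collapse_strands(df: pd.DataFrame) -> pd.DataFrame:
    """Merge CpG dyads: a '-' record at pos p+1 is summed onto the '+'
    record at p; lone records pass through unchanged.  Counts conserve.
    """
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    plus = df[df["strand"] != "-"].set_index(["chrom", "pos"])
    minus = df[df["strand"] == "-"]
    merged = plus.copy()
    orphans = []
    for _, row in minus.iterrows():
        key = (row["chrom"], row["pos"] - 1)
        if key in merged.index:
            merged.loc[key, "meth_count"] += row["meth_count"]
            merged.loc[key, "unmeth_count"] += row["unmeth_count"]
        else:
            orphans.append(row)
    out = merged.reset_index()
    if orphans:
        out = pd.concat([out, pd.DataFrame(orphans)], ignore_index=True)
    out["strand"] = "+"
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    out["coverage"] = out["meth_count"] + out["unmeth_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["beta"] = 100.0 * out["meth_count"] / out["coverage"]
    return out


def build_meth_matrix(
    tables: dict[str, pd.DataFrame],
    sample_sheet: pd.DataFrame,
    policy: str = "intersection",
) -> pd.DataFrame:
    """Assemble the CpG x sample beta matrix from per-sample tables.

    ``policy`` is 'intersection' (CpGs covered in every sample; default,
    rank-sum tests need complete rows) or 'union' (missing cells NaN).
    Column order follows the sample sheet.
    """
    if policy not in ("intersection", "union"):
        raise ValidationError(f"unknown matrix policy {policy!r}")
    ids = sample_sheet["sample_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValidationError(f"duplicate sample ids in sheet: {dupes}")
    missing = [s for s in ids if s not in tables]
    if missing:
        raise ValidationError(f"samples in sheet without a table: {missing}")
    series = {
        s: tables[s].set_index(["chrom", "pos"])["beta"] for s in ids
    }
    joined = pd.concat(series, axis=1, join="inner" if policy == "intersection" else "outer")
    joined.columns = ids
    joined.index.names = ["chrom", "pos"]
    return joined.sort_index()


# ------------------------------------------------------------------ DMR BED

def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """BED6+2: 0-based half-open, class as name, |delta|*10 clamped score,
    raw delta and CpG count as extra columns."""
    with open(path, "w") as fh:
        for _, d in dmrs.iterrows():
            score = int(np.clip(round(abs(d["delta"]) * 10), 0, 1000))
            fh.write(
                f"{d['chrom']}\t{int(d['start']) - 1}\t{int(d['end'])}\t"
                f"{d.get('dmr_class', 'other')}\t{score}\t.\t"
                f"{d['delta']:.6g}\t{int(d['n_cpgs'])}\n"
            )


def read_dmr_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ParseError("DMR BED needs 8 columns", line=lineno)
            try:
                rows.append(
                    {
                        "chrom": parts[0],
                        "start": int(parts[1]) + 1,
                        "end": int(parts[2]),
                        "dmr_class": parts[3],
                        "delta": float(parts[6]),
                        "n_cpgs": int(parts[7]),
                    }
                )
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
    df = pd.DataFrame(rows)
    if not df.empty:
        df["span_bp"] = df["end"] - df["start"] + 1
    return df


# --------------------------------------------------------------------- GTF

def write_gtf(genome: Genome, path) -> None:
    """Emit gene/transcript/exon features (1-based inclusive, GTF native)."""
    with open(path, "w") as fh:
        for g in genome.genes:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}";'
            fh.write(
                f"{g.chrom}\tmethdriver\tgene\t{g.tx_start}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\tgene_id \"{g.gene_id}\";\n"
            )
            fh.write(
                f"{g.chrom}\tmethdriver\ttranscript\t{g.tx_start}\t{g.tx_end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for lo, hi in g.exons:
                fh.write(
                    f"{g.chrom}\tmethdriver\texon\t{lo}\t{hi}\t.\t{g.strand}"
                    f"\t.\t{attrs}\n"
                )


def _gtf_attr(attrs: str, key: str) -> str | None:
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + " "):
            return chunk.split(" ", 1)[1].strip().strip('"')
    return None


def read_gene_models(path) -> list[GeneModel]:
    """Parse a GTF and keep one (longest) transcript per gene.

    Longest is by genomic span (tx_end - tx_start); ties go to the
    lexicographically smallest transcript id.  Transcript bounds fall back
    to the exon extent when no transcript feature is present.  A gene id
    appearing at two disjoint loci is a validation error.
    """
    transcripts: dict[tuple[str, str], dict] = {}
    gene_chrom: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError("GTF needs 9 columns", line=lineno)
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            if feature not in ("transcript", "exon"):
                continue
            gid = _gtf_attr(attrs, "gene_id")
            tid = _gtf_attr(attrs, "transcript_id")
            if gid is None or tid is None:
                raise ParseError("missing gene_id/transcript_id", line=lineno)
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if gid in gene_chrom and gene_chrom[gid] != chrom:
                raise ValidationError(
                    f"gene {gid} appears on both {gene_chrom[gid]} and {chrom}"
                )
            gene_chrom[gid] = chrom
            rec = transcripts.setdefault(
                (gid, tid),
                {"chrom": chrom, "strand": strand, "start": None, "end": None,
                 "exons": []},
            )
            if feature == "transcript":
                rec["start"], rec["end"] = start_i, end_i
            else:
                rec["exons"].append((start_i, end_i))

    by_gene: dict[str, list[tuple[str, dict]]] = {}
    for (gid, tid), rec in transcripts.items():
        if rec["start"] is None:
            if not rec["exons"]:
                continue
            rec["start"] = min(lo for lo, _ in rec["exons"])
            rec["end"] = max(hi for _, hi in rec["exons"])
        by_gene.setdefault(gid, []).append((tid, rec))

    genes = []
    for gid, cands in sorted(by_gene.items()):
        # longest genomic span; ties -> lexicographically smallest tid
        tid, rec = min(
            cands, key=lambda item: (-(item[1]["end"] - item[1]["start"]), item[0])
        )
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                tx_start=rec["start"],
                tx_end=rec["end"],
                exons=tuple(sorted(rec["exons"])) or ((rec["start"], rec["end"]),),
                transcript_id=tid,
            )
        )
    return genes


def write_gene_bed12(genome: Genome, path) -> None:
    """Simplified BED12 export of the single-transcript gene models."""
    with open(path, "w") as fh:
        for g in genome.genes:
            exons = sorted(g.exons)
            sizes = ",".join(str(hi - lo + 1) for lo, hi in exons) + ","
            starts = ",".join(str(lo - g.tx_start) for lo, _ in exons) + ","
            fh.write(
                f"{g.chrom}\t{g.tx_start - 1}\t{g.tx_end}\t{g.gene_id}\t0\t"
                f"{g.strand}\t{g.tx_start - 1}\t{g.tx_end}\t0\t{len(exons)}\t"
                f"{sizes}\t{starts}\n"
            )


def write_element_bed(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for etype, chrom, lo, hi in genome.elements:
            fh.write(f"{chrom}\t{lo - 1}\t{hi}\t{etype}\n")


def read_element_bed(path) -> list[tuple[str, str, int, int]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError("element BED needs 4 columns", line=lineno)
            out.append((parts[3], parts[0], int(parts[1]) + 1, int(parts[2])))
    return out


# ------------------------------------------------------------- simple TSVs

def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_sheet(df)


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise ValidationError(f"sample sheet needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dupes}")
    bad = set(df["group"]) - {"tumor", "normal"}
    if bad:
        raise ValidationError(f"unknown groups: {sorted(bad)}")
    return df.reset_index(drop=True)


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValidationError("duplicate gene ids in expression table")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time_days", "event"}
    if not required.issubset(df.columns):
        raise ValidationError(f"survival table needs columns {sorted(required)}")
    if (df["time_days"] <= 0).any():
        raise ValidationError("time_days must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError("event must be 0 or 1")
    return df


def write_survival(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_meth_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_meth_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=[0, 1])
    df.index.names = ["chrom", "pos"]
    return df
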