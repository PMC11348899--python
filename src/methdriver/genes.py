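"""Gene models and genome containers.

All native coordinates are 1-based inclusive; BED export converts to
0-based half-open at the I/O boundary.  A gene carries exactly one
transcript (the longest-transcript selection applied at GTF read time),
with strand-aware regulatory windows:

* promoter window: the 2,000 bp immediately upstream of the TSS,
  excluding the TSS base itself;
* downstream window: the 200 bp immediately past the gene end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PROMOTER_BP = 2000
DOWNSTREAM_BP = 200


@dataclass(frozen=True)
class GeneModel:
    """A single-transcript gene record.

    ``tx_start``/``tx_end`` are 1-based inclusive genomic bounds of the
    retained (longest) transcript; ``exons`` is a list of 1-based
    inclusive ``(start, end)`` intervals inside the transcript span.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...] = ()
    transcript_id: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start > tx_end")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def gene_end(self) -> int:
        """The transcription end (opposite anchor to the TSS)."""
        return self.tx_end if self.strand == "+" else self.tx_start

    def promoter_window_sized(self, bp: int) -> tuple[int, int]:
        """[TSS-bp, TSS) on the gene's own strand, 1-based inclusive."""
        if self.strand == "+":
            return (max(1, self.tss - bp), self.tss - 1)
        return (self.tss + 1, self.tss + bp)

    def downstream_window_sized(self, bp: int) -> tuple[int, int]:
        """(gene end, gene end + bp] on the gene's own strand."""
        if self.strand == "+":
            return (self.gene_end + 1, self.gene_end + bp)
        return (max(1, self.gene_end - bp), self.gene_end - 1)

    @property
    def promoter_window(self) -> tuple[int, int]:
        return self.promoter_window_sized(PROMOTER_BP)

    @property
    def downstream_window(self) -> tuple[int, int]:
        return self.downstream_window_sized(DOWNSTREAM_BP)

    @property
    def span_bp(self) -> int:
        return self.tx_end - self.tx_start + 1


@dataclass
class Genome:
    """A toy genome: chromosome sizes, gene models, CpG positions, elements.

    ``cpg_positions`` maps chromosome id to a strictly increasing int64
    array of 1-based CpG coordinates.  ``elements`` is an optional list of
    ``(element_type, chrom, start, end)`` regulatory-element intervals.
    """

    chrom_lengths: dict[str, int]
    genes: list[GeneModel]
    cpg_positions: dict[str, np.ndarray]
    elements: list[tuple[str, str, int, int]] = field(default_factory=list)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def n_cpgs(self) -> int:
        return int(sum(len(p) for p in self.cpg_positions.values()))


def overlap_bp(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the intersection of two 1-based inclusive intervals."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    return max(0, hi - lo + 1)
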