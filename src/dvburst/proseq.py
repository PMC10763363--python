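"""Run-on sequencing quantification: windows, counting, normalization, pausing.

Reads are represented by their 3' end (the engaged polymerase position) as
single-base stranded intervals.  The pausing index of a gene is
PI = PC / (PC + GBC), the fraction of its signal that sits in the promoter
window (-50 to +100 around the TSS, strand-aware): near 1 means highly
paused, near 0 means elongating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountTable
from .genome import GeneModel, GenomicInterval

PROMOTER_UPSTREAM = 50
PROMOTER_DOWNSTREAM = 100


@dataclass
class SizeFactors:
    """Per-sample scale factors, renormalized to geometric mean 1."""

    factors: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.factors.values()), dtype=float)
        if (vals <= 0).any():
            raise ValueError("size factors must be positive")
        gm = np.exp(np.mean(np.log(vals)))
        self.factors = {k: float(v / gm) for k, v in self.factors.items()}

    def __getitem__(self, sample: str) -> float:
        return self.factors[sample]

    def as_series(self) -> pd.Series:
        return pd.Series(self.factors)


def promoter_window(gene: GeneModel) -> GenomicInterval:
    """Window from 50 bp upstream to 100 bp downstream of the TSS.

    The window is mirrored through the TSS on the minus strand and clipped
    at position 0.  Plus strand: [tss-50, tss+100); minus strand:
    [tss-100+1, tss+50+1).
    """
    if gene.strand == "+":
        start, end = gene.tss - PROMOTER_UPSTREAM, gene.tss + PROMOTER_DOWNSTREAM
    else:
        start, end = gene.tss - PROMOTER_DOWNSTREAM + 1, gene.tss + PROMOTER_UPSTREAM + 1
    start = max(0, start)
    return GenomicInterval(gene.chrom, start, end, gene.strand, f"{gene.gene_id}_prom")


def count_window(
    reads: list[GenomicInterval],
    window: GenomicInterval,
    strand_mode: str = "sense",
) -> int:
    """Number of 3'-end read positions inside the window.

    ``strand_mode`` is one of sense / antisense / both; the first two
    require a stranded window.
    """
    if strand_mode not in ("sense", "antisense", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    if strand_mode != "both" and window.strand not in ("+", "-"):
        raise ValueError("sense/antisense counting requires a stranded window")
    n = 0
    for r in reads:
        if r.length != 1:
            raise ValueError(f"read {r.name!r} is not a single-base 3' end")
        if not window.overlaps(r):
            continue
        if strand_mode == "both":
            n += 1
        elif strand_mode == "sense":
            n += r.strand == window.strand
        else:
            n += r.strand != window.strand and r.strand in ("+", "-")
    return n


def select_major_isoform(gene: GeneModel, gbc_per_transcript: dict[str, float]) -> str:
    """Transcript with the highest length-normalized gene-body count.

    Ties break to the lexicographically smallest transcript id.
    """
    best_id, best_rate = None, -np.inf
    any_length = False
    for tx in gene.transcripts:
        if tx.cds_length == 0:
            continue
        any_length = True
        rate = gbc_per_transcript.get(tx.transcript_id, 0.0) / tx.cds_length
        if rate > best_rate or (rate == best_rate and tx.transcript_id < best_id):
            best_id, best_rate = tx.transcript_id, rate
    if not any_length:
        raise ValueError(f"gene {gene.gene_id}: all transcripts have zero CDS length")
    return best_id


def size_factors_median_of_ratios(table: CountTable) -> SizeFactors:
    """Median-of-ratios size factors (the DESeq2 estimator, re-implemented).

    factor_j = median over all-positive genes g of counts[g, j] / geomean_g,
    rescaled so the factors have geometric mean 1.
    """
    counts = table.counts.values.astype(float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene with strictly positive counts in every sample")
    sub = counts[all_pos]
    log_geomean = np.mean(np.log(sub), axis=1, keepdims=True)
    # median taken in log space (the DESeq2 convention; with an even gene
    # count the interpolated median is then the geometric mean of the two
    # middle ratios)
    factors = np.exp(np.median(np.log(sub) - log_geomean, axis=0))
    return SizeFactors(dict(zip(table.sample_ids, factors)))


def filter_low_expression(table: CountTable, min_reads: int = 10) -> CountTable:
    """Drop genes with fewer than ``min_reads`` total gene-body reads.

    Totals are summed across all samples so borderline genes are not
    condition-biased; removal is strict (< min_reads removed, == kept).
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= min_reads].index.tolist()
    return table.subset_entities(keep)


def pausing_index(pc: float, gbc: float) -> float:
    """PI = PC / (PC + GBC); NaN (undefined) when both are zero."""
    if pc < 0 or gbc < 0:
        raise ValueError("counts must be non-negative")
    total = pc + gbc
    if total == 0:
        return float("nan")
    return pc / total


def compute_pause_metrics(
    promoter: CountTable, gene_body: CountTable, factors: SizeFactors | None = None
) -> pd.DataFrame:
    """Per-gene, per-sample normalized PC, GBC and PI, plus replicate means.

    Size factors (median-of-ratios on the gene-body table by default) scale
    both windows of a sample identically, so PI is unchanged within a
    sample; they matter only when replicate PIs are averaged, which is done
    after the per-replicate ratio.
    """
    if list(promoter.counts.index) != list(gene_body.counts.index):
        common = promoter.counts.index.intersection(gene_body.counts.index)
        promoter = promoter.subset_entities(list(common))
        gene_body = gene_body.subset_entities(list(common))
    factors = factors or size_factors_median_of_ratios(gene_body)
    rows = []
    for gene in promoter.entity_ids:
        for sample in promoter.sample_ids:
            f = factors[sample]
            pc = promoter.counts.at[gene, sample] / f
            gbc = gene_body.counts.at[gene, sample] / f
            rows.append(
                {
                    "gene_id": gene,
                    "sample_id": sample,
                    "condition": promoter.condition_of[sample],
                    "promoter_count": pc,
                    "gene_body_count": gbc,
                    "pausing_index": pausing_index(pc, gbc),
                }
            )
    return pd.DataFrame(rows)


def mean_pause_index_by_condition(metrics: pd.DataFrame) -> pd.DataFrame:
    """Average per-replicate PIs within condition, dropping undefined PIs."""
    defined = metrics.dropna(subset=["pausing_index"])
    return (
        defined.groupby(["gene_id", "condition"], sort=False)["pausing_index"]
        .mean()
        .reset_index()
    )


def log2_tpm(counts: CountTable, lengths: dict[str, float], pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(TPM + pseudocount) per entity and sample.

    TPM[g, j] = 1e6 * (count/length)_g / sum_g (count/length)_g.
    """
    lens = np.array([lengths[e] for e in counts.entity_ids], dtype=float)
    if (lens <= 0).any():
        raise ValueError("entity lengths must be positive")
    rate = counts.counts.values / lens[:, None]
    col_sums = rate.sum(axis=0)
    if (col_sums == 0).any():
        bad = [s for s, c in zip(counts.sample_ids, col_sums) if c == 0]
        raise ValueError(f"all-zero samples: {bad}")
    tpm = 1e6 * rate / col_sums
    return pd.DataFrame(
        np.log2(tpm + pseudocount), index=counts.entity_ids, columns=counts.sample_ids
    )
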