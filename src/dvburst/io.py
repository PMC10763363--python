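"""Readers and writers for the plain-text formats the pipeline exchanges.

BED for intervals/TADs/enhancers, TSV for count and score tables, and
MatrixMarket triplets for UMI counts.  Readers validate invariants on load
and convert any 1-based dialect at the boundary; everything in memory is
0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountTable, UmiMatrix
from .genome import GeneModel, GenomicInterval, TadDomain, Transcript, validate_tads

logger = logging.getLogger("dvburst")


def stage_log(stage: str, **fields) -> None:
    """One structured line per pipeline stage (shapes, thresholds, survivors)."""
    payload = " ".join(f"{k}={v}" for k, v in fields.items())
    logger.info("stage=%s %s", stage, payload)


# ---------------------------------------------------------------------------
# BED intervals


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ into intervals.

    Missing strand becomes "."; missing name becomes ``region_<line>``.
    Malformed lines and inverted coordinates raise with the line number.
    """
    intervals: list[GenomicInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"region_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand, name)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate name {name!r}")
            seen.add(name)
            intervals.append(iv)
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t.\t{iv.strand}\n")


def read_tads(path: str | Path) -> list[TadDomain]:
    tads = [TadDomain(interval=iv, id=iv.name) for iv in read_bed(path)]
    return validate_tads(tads)


# ---------------------------------------------------------------------------
# Count tables


def read_condition_map(path: str | Path) -> tuple[dict[str, str], dict[str, int]]:
    """TSV with columns sample, condition[, replicate]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "condition": str})
    if "sample" not in df.columns or "condition" not in df.columns:
        raise ValueError(f"{path}: need columns 'sample' and 'condition'")
    condition_of = dict(zip(df["sample"], df["condition"]))
    if "replicate" in df.columns:
        replicate_of = dict(zip(df["sample"], df["replicate"].astype(int)))
    else:
        replicate_of = {s: i for i, s in enumerate(df["sample"])}
    return condition_of, replicate_of


def read_counts_tsv(path: str | Path, condition_map: str | Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate entity id {dup!r}")
    condition_of, replicate_of = read_condition_map(condition_map)
    missing = [s for s in df.columns if s not in condition_of]
    if missing:
        raise ValueError(f"{path}: samples missing from condition map: {missing}")
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative count")
    return CountTable(df, condition_of, replicate_of)


def write_counts_tsv(table: CountTable, path: str | Path) -> None:
    """Canonical formatting: integer counts stay integers, floats use repr."""
    df = table.counts
    if np.allclose(df.values, np.round(df.values)):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label=df.index.name or "entity")


def write_condition_map(table: CountTable, path: str | Path) -> None:
    rows = [
        {
            "sample": s,
            "condition": table.condition_of[s],
            "replicate": table.replicate_of.get(s, 0),
        }
        for s in table.sample_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# UMI matrices (MatrixMarket triplet + sidecar files)


def read_mtx_triplet(
    matrix: str | Path,
    genes: str | Path,
    cells: str | Path,
    clusters: str | Path,
) -> UmiMatrix:
    """MatrixMarket coordinate file (1-based indices) plus gene/cell/cluster
    sidecars.  Zero entries are implicit; values must be integers."""
    mat = spio.mmread(str(matrix))
    mat = sparse.csr_matrix(mat)
    if mat.data.size and (np.mod(mat.data, 1) != 0).any():
        raise ValueError(f"{matrix}: non-integer value in UMI matrix")
    gene_ids = [ln.strip() for ln in open(genes) if ln.strip()]
    cell_ids = [ln.strip() for ln in open(cells) if ln.strip()]
    cl = pd.read_csv(clusters, sep="\t", dtype=str)
    if "cell" not in cl.columns or "cluster" not in cl.columns:
        raise ValueError(f"{clusters}: need columns 'cell' and 'cluster'")
    cluster_of = dict(zip(cl["cell"], cl["cluster"]))
    return UmiMatrix(mat.astype(np.int64), gene_ids, cell_ids, cluster_of)


def write_mtx_triplet(
    umi: UmiMatrix,
    matrix: str | Path,
    genes: str | Path,
    cells: str | Path,
    clusters: str | Path,
) -> None:
    spio.mmwrite(str(matrix), sparse.coo_matrix(umi.counts), field="integer")
    Path(genes).write_text("".join(g + "\n" for g in umi.gene_ids))
    Path(cells).write_text("".join(c + "\n" for c in umi.cell_ids))
    pd.DataFrame(
        {"cell": umi.cell_ids, "cluster": [umi.cluster_of[c] for c in umi.cell_ids]}
    ).to_csv(clusters, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models
#
# TSV dialect: gene_id, chrom, strand, tss, transcript_id, cds_blocks where
# cds_blocks is "start-end;start-end" in 0-based half-open coordinates.


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chrom", "strand", "tss", "transcript_id", "cds_blocks"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    genes: list[GeneModel] = []
    for gene_id, group in df.groupby("gene_id", sort=False):
        chrom = group["chrom"].iloc[0]
        strand = group["strand"].iloc[0]
        tss = int(group["tss"].iloc[0])
        transcripts = []
        for _, row in group.iterrows():
            cds = []
            for k, block in enumerate(str(row["cds_blocks"]).split(";")):
                start, end = (int(x) for x in block.split("-"))
                cds.append(
                    GenomicInterval(
                        chrom, start, end, strand, f"{row['transcript_id']}_cds{k}"
                    )
                )
            transcripts.append(Transcript(row["transcript_id"], tuple(cds)))
        genes.append(GeneModel(gene_id, chrom, tss, strand, tuple(transcripts)))
    return genes


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    rows = []
    for g in genes:
        for tx in g.transcripts:
            blocks = ";".join(f"{iv.start}-{iv.end}" for iv in tx.cds)
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "strand": g.strand,
                    "tss": g.tss,
                    "transcript_id": tx.transcript_id,
                    "cds_blocks": blocks,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
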