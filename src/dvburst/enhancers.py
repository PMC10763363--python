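"""Enhancer calling, chromatin-state scoring, and TAD-constrained gene pairing.

Candidate regions (peaks) are scored per assay (ATAC accessibility, CBP
occupancy, H3K27ac) with the latent-axis z procedure; regions in the top
fraction (default 5%) for a condition in at least one assay become
candidate enhancers there.  The combined chromatin-state score of a region
in a condition is the sum of its three assay z-scores.  Candidates pair to
tissue-specific genes of the same condition whose TSS lies in the same TAD;
pairs within 700 bp of the TSS are proximal, the rest distal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountTable
from .genome import (
    GeneModel,
    GenomicInterval,
    TadDomain,
    tad_of_position,
    tad_of_region,
    validate_tads,
)
from .latent import LatentAxes

logger = logging.getLogger("dvburst")

ASSAYS = ("ATAC", "CBP", "H3K27ac")


@dataclass
class RegionScores:
    """Per-region per-condition assay z-scores, combined scores, candidacy."""

    z: pd.DataFrame  # columns: region, condition, assay, z
    combined: pd.DataFrame  # columns: region, condition, combined_score
    candidates: pd.DataFrame  # columns: region, condition, assay flags, candidate

    def candidate_regions(self, condition: str) -> list[str]:
        sub = self.candidates[
            (self.candidates["condition"] == condition) & self.candidates["candidate"]
        ]
        return sub["region"].tolist()


def score_regions(
    tables: dict[str, CountTable],
    pc_subsets: dict[str, list[int]] | None = None,
    top_fraction: float = 0.05,
) -> RegionScores:
    """Latent-axis z-scores per assay plus combined scores and candidate flags.

    All assay tables must cover the same regions.  A region is a candidate
    enhancer for a condition when its z is within the top ``top_fraction``
    for that condition in at least one assay (ties broken by region name).
    """
    assays = list(tables)
    regions = tables[assays[0]].entity_ids
    for assay in assays[1:]:
        if tables[assay].entity_ids != regions:
            raise ValueError(f"region sets differ between {assays[0]} and {assay}")
    if len(regions) < 20:
        raise ValueError(f"need >= 20 regions for a stable top quantile, got {len(regions)}")

    pc_subsets = pc_subsets or {}
    z_rows = []
    flags: dict[tuple[str, str, str], bool] = {}
    conditions = tables[assays[0]].conditions
    n_top = max(1, math.floor(top_fraction * len(regions) + 1e-9))
    for assay in assays:
        res = LatentAxes(tables[assay]).fit(pc_subset=pc_subsets.get(assay))
        for cond in conditions:
            sc = res.score_features(cond)
            # top fraction = strictly above the (1 - fraction) quantile,
            # capped at n_top regions (ties broken by region name); regions
            # tied at the threshold itself are not candidates
            q = np.quantile(sc["z"].values, 1.0 - top_fraction)
            above = sc[sc["z"] > q]
            order = sorted(zip(-above["z"].values, above["feature_id"].values))
            top = {name for _, name in order[:n_top]}
            for fid, z in zip(sc["feature_id"], sc["z"]):
                z_rows.append({"region": fid, "condition": cond, "assay": assay, "z": z})
                flags[(fid, cond, assay)] = fid in top

    z = pd.DataFrame(z_rows)
    combined = (
        z.groupby(["region", "condition"], sort=False)["z"]
        .sum()
        .reset_index()
        .rename(columns={"z": "combined_score"})
    )
    cand_rows = []
    for region in regions:
        for cond in conditions:
            row = {"region": region, "condition": cond}
            for assay in assays:
                row[f"top_{assay}"] = flags[(region, cond, assay)]
            row["candidate"] = any(row[f"top_{assay}"] for assay in assays)
            cand_rows.append(row)
    candidates = pd.DataFrame(cand_rows)
    logger.info(
        "stage=score_regions regions=%d conditions=%d n_top=%d candidates=%d",
        len(regions),
        len(conditions),
        n_top,
        int(candidates["candidate"].sum()),
    )
    return RegionScores(z=z, combined=combined, candidates=candidates)


def exclude_tss_regions(
    regions: list[GenomicInterval], genes: list[GeneModel], flank: int = 150
) -> list[GenomicInterval]:
    """Drop regions overlapping any TSS +/- flank (promoter elements)."""
    windows = [
        GenomicInterval(g.chrom, max(0, g.tss - flank), g.tss + flank, ".", g.gene_id)
        for g in genes
    ]
    kept = [r for r in regions if not any(r.overlaps(w) for w in windows)]
    logger.info(
        "stage=exclude_tss_regions flank=%d input=%d kept=%d", flank, len(regions), len(kept)
    )
    return kept


@dataclass(frozen=True)
class EnhancerAssignment:
    enhancer: GenomicInterval
    gene_id: str
    condition: str
    tad_id: str
    distance_to_tss: int
    proximity: str  # proximal | distal


def _distance_to_tss(region: GenomicInterval, tss: int) -> int:
    """Minimum distance from the region edge to the TSS; 0 if inside."""
    return max(0, region.start - tss, tss - (region.end - 1))


def assign_enhancers(
    candidates: dict[str, list[str]],
    regions: list[GenomicInterval],
    dv_genes: dict[str, str],
    genes: list[GeneModel],
    tads: list[TadDomain],
    proximal_bp: int = 700,
) -> list[EnhancerAssignment]:
    """Pair candidate enhancers to same-condition genes in the same TAD.

    ``candidates`` maps condition -> candidate region names; ``dv_genes``
    maps gene_id -> assigned condition.  A candidate pairs with *every*
    matching-condition gene whose TSS shares its TAD.  A region spanning a
    TAD boundary is assigned by its midpoint (logged).  Distance <=
    ``proximal_bp`` is proximal (inclusive).
    """
    validate_tads(tads)
    region_by_name = {r.name: r for r in regions}
    gene_by_id = {g.gene_id: g for g in genes}
    out: list[EnhancerAssignment] = []
    for condition in sorted(candidates):
        for rname in sorted(candidates[condition]):
            region = region_by_name[rname]
            tad = tad_of_region(region, tads)
            if tad is None:
                continue
            if not (
                tad.interval.start <= region.start and region.end <= tad.interval.end
            ):
                logger.info(
                    "stage=assign_enhancers region=%s spans a TAD boundary; "
                    "assigned by midpoint to %s",
                    rname,
                    tad.id,
                )
            for gene_id in sorted(dv_genes):
                if dv_genes[gene_id] != condition:
                    continue
                gene = gene_by_id[gene_id]
                gtad = tad_of_position(gene.chrom, gene.tss, tads)
                if gtad is None or gtad.id != tad.id:
                    continue
                dist = _distance_to_tss(region, gene.tss)
                out.append(
                    EnhancerAssignment(
                        enhancer=region,
                        gene_id=gene_id,
                        condition=condition,
                        tad_id=tad.id,
                        distance_to_tss=dist,
                        proximity="proximal" if dist <= proximal_bp else "distal",
                    )
                )
    logger.info("stage=assign_enhancers pairs=%d", len(out))
    return out


def predict_expression(
    assignments: list[EnhancerAssignment],
    combined: pd.DataFrame,
    gene_z: pd.DataFrame,
    condition: str,
) -> tuple[float, float, float, float]:
    """OLS of gene tissue z on enhancer combined chromatin-state score.

    One point per enhancer-gene pair of the given condition (genes with
    several enhancers contribute several points).  Returns (slope,
    intercept, R^2, p) with R^2 the squared Pearson correlation and p from
    the t-statistic of the slope.
    """
    comb = combined[combined["condition"] == condition].set_index("region")[
        "combined_score"
    ]
    xs, ys = [], []
    for a in assignments:
        if a.condition != condition:
            continue
        xs.append(comb[a.enhancer.name])
        ys.append(gene_z.loc[a.gene_id, condition])
    if len(xs) < 3:
        raise ValueError(f"need >= 3 pairs for condition {condition!r}, got {len(xs)}")
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    if np.ptp(xs) == 0:
        raise ValueError("zero-variance predictor")
    fit = stats.linregress(xs, ys)
    return (
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue**2),
        float(fit.pvalue),
    )


@dataclass(frozen=True)
class AccessibilityDynamics:
    region: str
    condition: str
    timepoint: str
    log2_fc: float
    dynamics_class: str  # gained | lost | stable


def accessibility_class(log2_fc: float, fc_cutoff: float = 0.5) -> str:
    """gained iff FC >= cutoff, lost iff FC <= -cutoff, else stable."""
    if log2_fc >= fc_cutoff:
        return "gained"
    if log2_fc <= -fc_cutoff:
        return "lost"
    return "stable"


def classify_accessibility(
    atac_by_time: pd.DataFrame,
    condition: str,
    baseline: str = "3h",
    fc_cutoff: float = 0.5,
) -> list[AccessibilityDynamics]:
    """Gained / lost / stable accessibility relative to the 3 h baseline.

    ``atac_by_time`` is regions x time points of (normalized) counts in the
    condition of expression.  FC = log2((later + 1) / (baseline + 1));
    gained iff FC >= fc_cutoff, lost iff FC <= -fc_cutoff, else stable.
    """
    if baseline not in atac_by_time.columns:
        raise ValueError(f"baseline column {baseline!r} missing")
    out = []
    for tp in [c for c in atac_by_time.columns if c != baseline]:
        fc = np.log2((atac_by_time[tp] + 1.0) / (atac_by_time[baseline] + 1.0))
        for region, val in fc.items():
            cls = accessibility_class(float(val), fc_cutoff)
            out.append(
                AccessibilityDynamics(
                    region=region,
                    condition=condition,
                    timepoint=tp,
                    log2_fc=float(val),
                    dynamics_class=cls,
                )
            )
    return out


def quantify_erna(
    enhancer: GenomicInterval,
    reads_by_condition: dict[str, list[GenomicInterval]],
    genic: bool,
    host_strand: str | None = None,
    pseudocount: float = 1.0,
) -> tuple[dict[str, int], dict[tuple[str, str], float]]:
    """eRNA counts per condition and pairwise log2 fold changes.

    Intergenic enhancers count run-on 3' ends on both strands inside the
    peak; genic enhancers count only reads antisense to the host gene (the
    non-coding strand), so nascent host-gene transcription is ignored.
    """
    from .proseq import count_window

    if genic:
        if host_strand not in ("+", "-"):
            raise ValueError("genic enhancer requires a host_strand of + or -")
        window = GenomicInterval(
            enhancer.chrom, enhancer.start, enhancer.end, host_strand, enhancer.name
        )
        counts = {
            cond: count_window(reads, window, "antisense")
            for cond, reads in reads_by_condition.items()
        }
    else:
        counts = {
            cond: count_window(reads, enhancer, "both")
            for cond, reads in reads_by_condition.items()
        }
    conds = list(counts)
    fcs = {
        (a, b): float(
            np.log2((counts[a] + pseudocount) / (counts[b] + pseudocount))
        )
        for i, a in enumerate(conds)
        for b in conds[i + 1 :]
    }
    return counts, fcs


def shuffle_regions(
    regions: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    seed: int,
    exclude: list[GenomicInterval] | None = None,
    max_tries: int = 1000,
) -> list[GenomicInterval]:
    """Relocate each region uniformly at random on its own chromosome.

    Lengths are preserved exactly; placements overlapping ``exclude`` are
    rejection-sampled up to ``max_tries`` before erroring.
    """
    rng = np.random.default_rng(seed)
    exclude = exclude or []
    out = []
    for region in regions:
        size = chrom_sizes.get(region.chrom)
        if size is None or region.length > size:
            raise ValueError(f"region {region.name!r} does not fit chromosome")
        placed = None
        for _ in range(max_tries):
            start = int(rng.integers(0, size - region.length + 1))
            candidate = GenomicInterval(
                region.chrom, start, start + region.length, region.strand, region.name
            )
            if not any(candidate.overlaps(e) for e in exclude):
                placed = candidate
                break
        if placed is None:
            raise ValueError(
                f"could not place {region.name!r} after {max_tries} tries"
            )
        out.append(placed)
    return out
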