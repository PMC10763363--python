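"""Synthetic data generators with the statistical structure the analysis assumes.

Three genotype conditions (uniform dorsal ectoderm, neuroectoderm, and
mesoderm embryos) x two replicates for bulk run-on counts; per-cluster UMI
counts drawn from the Beta-Poisson steady state with known rates; and a toy
genome on one synthetic chromosome ("chrS") with TADs, genes, and enhancers
whose chromatin signal is coupled to the planted gene effects at a known
correlation.  All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import CountTable, UmiMatrix
from .genome import GeneModel, GenomicInterval, TadDomain, Transcript
from .telegraph import beta_poisson_rvs

CONDITIONS = ("gd7", "Tollrm9rm10", "Toll10B")  # dorsal ecto / neuro ecto / mesoderm


@dataclass
class TruthTable:
    """Planted ground truth used by recovery tests.

    genes: gene_id, condition ("none" for background), log2fc
    kinetics: gene_id, cluster, k_on, k_off, k_syn
    enhancers: name, gene_id, condition, latent_signal, proximal
    """

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    kinetics: pd.DataFrame = field(default_factory=pd.DataFrame)
    enhancers: pd.DataFrame = field(default_factory=pd.DataFrame)
    size_factors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.kinetics):
            rates = self.kinetics[["k_on", "k_off", "k_syn"]].values
            if (rates <= 0).any():
                raise ValueError("true kinetic rates must be strictly positive")


# ---------------------------------------------------------------------------
# Single-cell generators


def simulate_beta_poisson_gene(
    k_on: float, k_off: float, k_syn: float, n_cells: int, seed: int
) -> np.ndarray:
    """UMI counts for one gene: m ~ Poisson(k_syn * p), p ~ Beta(k_on, k_off)."""
    rng = np.random.default_rng(seed)
    return beta_poisson_rvs(k_on, k_off, k_syn, n_cells, rng)


def simulate_umi_dataset(
    truth: TruthTable, cells_per_cluster: dict[str, int], seed: int
) -> tuple[UmiMatrix, TruthTable]:
    """Per-cluster UMI matrix drawn from the planted kinetic rates.

    ``truth.kinetics`` must contain one row per (gene, cluster).  Clusters
    with no cells are an error; recovery tests need >= 100 cells per cluster.
    """
    if len(cells_per_cluster) < 2:
        raise ValueError("need >= 2 clusters")
    for cluster, n in cells_per_cluster.items():
        if n < 1:
            raise ValueError(f"empty cluster {cluster!r}")
    kin = truth.kinetics
    genes = list(dict.fromkeys(kin["gene_id"]))
    clusters = list(cells_per_cluster)
    rng = np.random.default_rng(seed)

    cell_ids: list[str] = []
    cluster_of: dict[str, str] = {}
    for cluster in clusters:
        for i in range(cells_per_cluster[cluster]):
            cid = f"{cluster}_cell{i}"
            cell_ids.append(cid)
            cluster_of[cid] = cluster

    blocks = []
    for gene in genes:
        row = np.zeros(len(cell_ids), dtype=np.int64)
        offset = 0
        for cluster in clusters:
            n = cells_per_cluster[cluster]
            rec = kin[(kin["gene_id"] == gene) & (kin["cluster"] == cluster)]
            if len(rec):
                r = rec.iloc[0]
                row[offset : offset + n] = beta_poisson_rvs(
                    r["k_on"], r["k_off"], r["k_syn"], n, rng
                )
            offset += n
        blocks.append(row)
    mat = sparse.csr_matrix(np.vstack(blocks))
    return UmiMatrix(mat, genes, cell_ids, cluster_of), truth


# ---------------------------------------------------------------------------
# Bulk run-on generator


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2 (Poisson if 0)."""
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_tissue_bulk(
    n_genes: int = 2060,
    n_planted_per_condition: int = 20,
    effect_log2fc: float = 3.0,
    dispersion: float = 0.05,
    pause_enrichment: float = 2.0,
    seed: int = 0,
    low_fraction: float = 0.05,
) -> tuple[CountTable, CountTable, TruthTable]:
    """Promoter and gene-body count tables for 3 genotypes x 2 replicates.

    Gene-body counts are negative binomial around log-uniform baselines in
    [20, 2000], multiplied by 2^effect_log2fc in the planted condition.
    Promoter counts share the baseline scaled by ``pause_enrichment`` in
    every condition, emulating tissue-invariant pausing.  A ``low_fraction``
    of background genes get near-zero baselines so the low-count filter is
    exercised.  Per-sample size factors are drawn uniformly in [0.5, 2].
    """
    if effect_log2fc <= 0:
        raise ValueError("effect_log2fc must be > 0")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if pause_enrichment < 0:
        raise ValueError("pause_enrichment must be >= 0")
    if n_planted_per_condition * len(CONDITIONS) > n_genes:
        raise ValueError("more planted genes than genes")

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"{cond}_rep{r}" for cond in CONDITIONS for r in (1, 2)]
    condition_of = {s: s.rsplit("_", 1)[0] for s in samples}
    replicate_of = {s: int(s[-1]) for s in samples}
    size_factors = rng.uniform(0.5, 2.0, size=len(samples))

    baselines = np.exp(rng.uniform(np.log(20.0), np.log(2000.0), size=n_genes))
    n_low = int(round(low_fraction * n_genes))
    low_idx = rng.choice(n_genes, size=n_low, replace=False)
    baselines[low_idx] = rng.uniform(0.2, 1.2, size=n_low)

    planted_condition = np.array(["none"] * n_genes, dtype=object)
    eligible = np.setdiff1d(np.arange(n_genes), low_idx)
    planted = rng.choice(
        eligible, size=n_planted_per_condition * len(CONDITIONS), replace=False
    )
    for k, cond in enumerate(CONDITIONS):
        planted_condition[
            planted[k * n_planted_per_condition : (k + 1) * n_planted_per_condition]
        ] = cond

    gb = np.zeros((n_genes, len(samples)))
    pr = np.zeros((n_genes, len(samples)))
    for j, s in enumerate(samples):
        cond = condition_of[s]
        boost = np.where(planted_condition == cond, 2.0 ** effect_log2fc, 1.0)
        mu_gb = baselines * boost * size_factors[j]
        mu_pr = baselines * pause_enrichment * size_factors[j]
        gb[:, j] = _nb_sample(rng, mu_gb, dispersion)
        pr[:, j] = _nb_sample(rng, mu_pr, dispersion)

    gene_body = CountTable(
        pd.DataFrame(gb, index=gene_ids, columns=samples), condition_of, replicate_of
    )
    promoter = CountTable(
        pd.DataFrame(pr, index=gene_ids, columns=samples), condition_of, replicate_of
    )
    truth = TruthTable(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "condition": planted_condition,
                "log2fc": np.where(planted_condition == "none", 0.0, effect_log2fc),
                "baseline": baselines,
            }
        ),
        size_factors=dict(zip(samples, size_factors)),
    )
    return promoter, gene_body, truth


# ---------------------------------------------------------------------------
# Toy genome


@dataclass
class ToyGenome:
    genes: list[GeneModel]
    tads: list[TadDomain]
    enhancers: list[GenomicInterval]
    background_regions: list[GenomicInterval]
    region_counts: dict[str, CountTable]  # assay -> regions x samples
    gene_counts: CountTable  # gene-body counts for the same samples
    truth: TruthTable

    @property
    def all_regions(self) -> list[GenomicInterval]:
        return list(self.enhancers) + list(self.background_regions)


ASSAYS = ("ATAC", "CBP", "H3K27ac")


def simulate_toy_genome(
    n_tads: int = 8,
    genes_per_tad: int = 3,
    enhancers_per_gene: int = 2,
    coupling_r: float = 0.9,
    seed: int = 0,
    tad_length: int = 100_000,
    dispersion: float = 0.01,
    proximal_fraction: float = 0.2,
    background_per_enhancer: int = 6,
    noiseless: bool = False,
) -> ToyGenome:
    """One synthetic chromosome of consecutive TADs with genes and enhancers.

    Each gene gets a condition (cycled through the three genotypes) and a
    planted effect size; each of its enhancers carries a latent signal
    correlated with the gene effect at ``coupling_r`` (the same latent
    signal drives all three assays, so the combined chromatin score tracks
    expression at about that correlation).  Enhancers live in their target
    gene's TAD, never overlap any TSS +/- 150 bp, and a
    ``proximal_fraction`` of them sit within 700 bp of the TSS.  Background
    regions with condition-independent signal make the top-5% cut
    meaningful.  ``noiseless=True`` replaces count sampling with exact
    means and sets the enhancer latent noise to zero (the coupling_r = 1
    limit used by exactness tests).
    """
    if not 0 < coupling_r <= 1:
        raise ValueError("coupling_r must lie in (0, 1]")
    gene_span = 4000
    if tad_length < genes_per_tad * (gene_span + 4000) + 4000:
        raise ValueError("TAD too small for the requested gene count")

    rng = np.random.default_rng(seed)
    chrom = "chrS"
    tads = [
        TadDomain(
            GenomicInterval(chrom, i * tad_length, (i + 1) * tad_length, ".", f"tad_{i}"),
            f"tad_{i}",
        )
        for i in range(n_tads)
    ]

    genes: list[GeneModel] = []
    gene_rows = []
    slot = tad_length // genes_per_tad
    for t in range(n_tads):
        for g in range(genes_per_tad):
            gid = f"gene_{t}_{g}"
            tss = t * tad_length + g * slot + slot // 2
            strand = "+" if (t + g) % 2 == 0 else "-"
            if strand == "+":
                cds = GenomicInterval(chrom, tss + 200, tss + 200 + gene_span, strand, f"{gid}_cds")
            else:
                cds = GenomicInterval(chrom, tss - 200 - gene_span, tss - 200, strand, f"{gid}_cds")
            genes.append(
                GeneModel(gid, chrom, tss, strand, (Transcript(f"{gid}_t1", (cds,)),))
            )
            cond = CONDITIONS[(t * genes_per_tad + g) % len(CONDITIONS)]
            effect = float(rng.uniform(1.0, 4.0))
            gene_rows.append({"gene_id": gid, "condition": cond, "log2fc": effect})
    truth_genes = pd.DataFrame(gene_rows)

    # standardized gene effects, used to couple enhancer latent signals
    eff = truth_genes["log2fc"].values
    eff_std = (eff - eff.mean()) / eff.std()

    tss_windows = [
        GenomicInterval(g.chrom, max(0, g.tss - 150), g.tss + 150, ".", f"tssw_{g.gene_id}")
        for g in genes
    ]

    def _clear_of_tss(start: int, end: int) -> bool:
        probe = GenomicInterval(chrom, max(0, start), end, ".", "probe")
        return not any(probe.overlaps(w) for w in tss_windows)

    enhancers: list[GenomicInterval] = []
    enh_rows = []
    width = 500
    for gi, gene in enumerate(genes):
        tad = tads[gi // genes_per_tad]
        for e in range(enhancers_per_gene):
            name = f"enh_{gene.gene_id}_{e}"
            proximal = rng.random() < proximal_fraction
            placed = None
            for _ in range(1000):
                if proximal:
                    offset = int(rng.integers(160, 700 - width)) if 700 - width > 160 else 160
                    start = gene.tss + offset if rng.random() < 0.5 else gene.tss - offset - width
                else:
                    start = int(
                        rng.integers(tad.interval.start, tad.interval.end - width)
                    )
                start = max(tad.interval.start, min(start, tad.interval.end - width))
                if _clear_of_tss(start, start + width):
                    placed = GenomicInterval(chrom, start, start + width, ".", name)
                    # distal placements must actually be distal
                    dist = max(0, start - gene.tss, gene.tss - (start + width - 1))
                    if proximal == (dist <= 700):
                        break
                    placed = None
            if placed is None:
                raise ValueError(f"could not place enhancer {name} (TAD too crowded)")
            if noiseless or coupling_r == 1.0:
                latent = eff_std[gi]
            else:
                latent = coupling_r * eff_std[gi] + np.sqrt(1 - coupling_r**2) * rng.normal()
            enhancers.append(placed)
            enh_rows.append(
                {
                    "name": name,
                    "gene_id": gene.gene_id,
                    "condition": truth_genes.loc[gi, "condition"],
                    "latent_signal": latent,
                    "proximal": proximal,
                }
            )
    truth_enh = pd.DataFrame(enh_rows)

    background: list[GenomicInterval] = []
    n_bg = background_per_enhancer * len(enhancers)
    b = 0
    while len(background) < n_bg:
        start = int(rng.integers(0, n_tads * tad_length - width))
        if _clear_of_tss(start, start + width):
            background.append(GenomicInterval(chrom, start, start + width, ".", f"bg_{b:05d}"))
            b += 1

    samples = [f"{cond}_rep{r}" for cond in CONDITIONS for r in (1, 2)]
    condition_of = {s: s.rsplit("_", 1)[0] for s in samples}
    replicate_of = {s: int(s[-1]) for s in samples}
    disp = 0.0 if noiseless else dispersion

    # per-assay region counts: boost in the enhancer's condition, scaled by
    # the latent signal; background regions are condition-flat
    region_names = [iv.name for iv in enhancers] + [iv.name for iv in background]
    region_counts: dict[str, CountTable] = {}
    amp = {"ATAC": 1.0, "CBP": 1.2, "H3K27ac": 0.8}
    for assay in ASSAYS:
        base = np.exp(rng.uniform(np.log(50.0), np.log(500.0), size=len(region_names)))
        mat = np.zeros((len(region_names), len(samples)))
        for j, s in enumerate(samples):
            cond = condition_of[s]
            mu = base.copy()
            for i, row in truth_enh.iterrows():
                if row["condition"] == cond:
                    # offset keeps the boost well above 1 across the latent range
                    mu[i] *= 2.0 ** (amp[assay] * (2.0 + 0.5 * row["latent_signal"]))
            if noiseless:
                mat[:, j] = mu
            else:
                mat[:, j] = _nb_sample(rng, mu, disp)
        region_counts[assay] = CountTable(
            pd.DataFrame(mat, index=region_names, columns=samples),
            condition_of,
            replicate_of,
        )

    # gene-body counts with the planted condition effects
    gbase = np.exp(rng.uniform(np.log(100.0), np.log(1000.0), size=len(genes)))
    gmat = np.zeros((len(genes), len(samples)))
    for j, s in enumerate(samples):
        cond = condition_of[s]
        boost = np.where(
            truth_genes["condition"].values == cond,
            2.0 ** truth_genes["log2fc"].values,
            1.0,
        )
        mu = gbase * boost
        gmat[:, j] = mu if noiseless else _nb_sample(rng, mu, disp)
    gene_counts = CountTable(
        pd.DataFrame(gmat, index=[g.gene_id for g in genes], columns=samples),
        condition_of,
        replicate_of,
    )

    truth = TruthTable(genes=truth_genes, enhancers=truth_enh)
    return ToyGenome(
        genes=genes,
        tads=tads,
        enhancers=enhancers,
        background_regions=background,
        region_counts=region_counts,
        gene_counts=gene_counts,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Planted integration records (chromatin <-> kinetics coupling)


def simulate_integration_records(
    n_genes: int = 40,
    r_frequency: float = 0.75,
    r_size: float = 0.0,
    noise_sd: float = 0.3,
    proximal_fraction: float = 0.3,
    size_shift_proximal: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene integration records with planted chromatin-kinetics coupling.

    The combined enhancer chromatin-state difference (Dchromatin) is drawn
    standard normal; the log2 burst-frequency difference is correlated with
    it at ``r_frequency`` and the burst-size difference at ``r_size``.
    ``size_shift_proximal`` adds a burst-size-only shift to proximal genes
    (used by the proximity power test).
    """
    rng = np.random.default_rng(seed)
    chrom = rng.normal(size=n_genes)
    dkon = r_frequency * chrom + np.sqrt(max(0.0, 1 - r_frequency**2)) * rng.normal(
        size=n_genes
    )
    dbs = r_size * chrom + np.sqrt(max(0.0, 1 - r_size**2)) * rng.normal(size=n_genes)
    dkon = dkon + noise_sd * rng.normal(size=n_genes)
    proximal = rng.random(n_genes) < proximal_fraction
    dbs = dbs + size_shift_proximal * proximal
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "delta_chromatin": chrom,
            "delta_k_on": dkon,
            "delta_burst_size": dbs,
            "proximity": np.where(proximal, "proximal", "distal"),
        }
    )
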