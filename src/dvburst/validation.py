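"""Simulation-based self-checks of the pipeline.

Each function generates data with known ground truth, runs the relevant
stage end-to-end, and returns the measured quantities as a flat dict.
These power both the test suite and the reproduction script; all
randomness derives from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .enhancers import (
    accessibility_class,
    assign_enhancers,
    exclude_tss_regions,
    predict_expression,
    score_regions,
)
from .integrate import correlation_matrix
from .latent import LatentAxes, roc_curve
from .proseq import (
    compute_pause_metrics,
    filter_low_expression,
    mean_pause_index_by_condition,
    pausing_index,
)
from .simulate import (
    simulate_integration_records,
    simulate_tissue_bulk,
    simulate_toy_genome,
)
from .telegraph import (
    TelegraphModel,
    beta_poisson_pmf,
    beta_poisson_rvs,
    ci_width_filter,
    mixture_filter,
)


def _spawn(seed: int, offset: int) -> int:
    return (int(seed) * 7919 + offset) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Beta-Poisson pmf checks


def check_pmf(seed: int = 0, n_mc: int = 1_000_000) -> dict:
    """Normalization over a 3x3x3 grid, Monte-Carlo agreement, the
    Beta(1,1) closed form, and the Poisson concentration limit."""
    max_norm_err = 0.0
    for k_on in (0.1, 1.0, 10.0):
        for k_off in (1.0, 10.0, 100.0):
            for k_syn in (10.0, 100.0, 500.0):
                m = np.arange(0, int(k_syn * 4 + 200))
                total = beta_poisson_pmf(m, k_on, k_off, k_syn).sum()
                max_norm_err = max(max_norm_err, abs(total - 1.0))

    rng = np.random.default_rng(_spawn(seed, 1))
    frac_within = []
    for (a, b, k) in [(1, 9, 100), (0.5, 5, 50), (3, 3, 30), (0.3, 10, 200), (2, 1, 20)]:
        x = beta_poisson_rvs(a, b, k, n_mc, rng)
        hi = int(x.max()) + 1
        emp = np.bincount(x, minlength=hi) / n_mc
        pmf = beta_poisson_pmf(np.arange(hi), a, b, k)
        se = np.sqrt(pmf * (1 - pmf) / n_mc)
        frac_within.append(float((np.abs(emp - pmf) <= 3 * se + 1e-12).mean()))

    k = 10.0
    p0_err = abs(beta_poisson_pmf(0, 1, 1, k) - (1 - np.exp(-k)) / k)

    m = np.arange(0, 100)
    tv = 0.5 * np.abs(
        beta_poisson_pmf(m, 1000, 1000, 20) - stats.poisson.pmf(m, 10)
    ).sum()

    return {
        "pmf_normalization_max_error": float(max_norm_err),
        "pmf_monte_carlo_within_3se": float(np.mean(frac_within)),
        "pmf_beta11_p0_error": float(p0_err),
        "pmf_poisson_limit_tv": float(tv),
    }


# ---------------------------------------------------------------------------
# Parameter recovery and bootstrap coverage


def check_parameter_recovery(
    seed: int = 0,
    n_cells: int = 2000,
    genes_per_cell: int = 10,
    k_syn: float = 200.0,
) -> dict:
    """MLE recovery over the k_on x burst-size grid.

    k_syn is held fixed and k_off chosen to produce the requested burst
    sizes.  Reports median relative errors of k_on and burst size.
    """
    rng = np.random.default_rng(_spawn(seed, 2))
    rel_kon, rel_bs = [], []
    for k_on in (0.3, 1.0, 3.0):
        for bs in (5.0, 20.0):
            k_off = k_syn / bs
            for _ in range(genes_per_cell):
                sub = int(rng.integers(2**31 - 1))
                x = beta_poisson_rvs(k_on, k_off, k_syn, n_cells, np.random.default_rng(sub))
                res = TelegraphModel(x).fit(seed=sub)
                rel_kon.append(abs(res.params.k_on - k_on) / k_on)
                rel_bs.append(abs(res.burst_size - bs) / bs)
    return {
        "kon_median_rel_error": float(np.median(rel_kon)),
        "burst_size_median_rel_error": float(np.median(rel_bs)),
    }


def check_ci_coverage(
    seed: int = 0,
    n_genes: int = 100,
    n_cells: int = 1000,
    n_boot: int = 100,
    k_on: float = 1.0,
    k_off: float = 10.0,
    k_syn: float = 100.0,
) -> dict:
    """Bootstrap CI coverage of the true k_on over replicate genes.

    Each gene is an independent draw of ``n_cells`` cells at the reference
    rates; the fraction of genes whose 95% bootstrap CI contains the true
    k_on estimates the interval's coverage.
    """
    rng = np.random.default_rng(_spawn(seed, 21))
    covered = []
    for _ in range(n_genes):
        sub = int(rng.integers(2**31 - 1))
        x = beta_poisson_rvs(k_on, k_off, k_syn, n_cells, np.random.default_rng(sub))
        res = TelegraphModel(x).fit(seed=sub).bootstrap(n_boot, seed=sub + 1)
        covered.append(res.ci_k_on[0] <= k_on <= res.ci_k_on[1])
    return {"kon_ci_coverage": float(np.mean(covered))}


# ---------------------------------------------------------------------------
# Filters


def check_filters(seed: int = 0) -> dict:
    """CI-width inequalities on analytic boundary cases and the mixture
    filter on a planted bimodal sample."""
    # (k_on, width_kon, bs, width_bs, expected pass)
    cases = [
        (1.0, 19.0, 10.0, 10.0, True),
        (1.0, 21.0, 10.0, 10.0, False),
        (1.0, 10.0, 10.0, 60.0, True),
        (1.0, 10.0, 10.0, 70.0, False),
        (10.0, 100.0, 10.0, 10.0, True),    # 2.0 < 1.3 + 0.8
        (10.0, 130.0, 10.0, 10.0, False),   # 2.11 >= 2.1
        (1.0, 1.0, 1.0, 5.0, True),
        (1.0, 1.0, 1.0, 11.0, False),       # 1.04 >= 1.0
    ]
    correct = [
        ci_width_filter(k, wk, b, wb) is exp for k, wk, b, wb, exp in cases
    ]

    rng = np.random.default_rng(_spawn(seed, 3))
    low = 10.0 ** rng.normal(-2, 0.3, size=200)
    high = 10.0 ** rng.normal(1, 0.3, size=200)
    keep, _ = mixture_filter(np.concatenate([low, high]), seed=seed)
    return {
        "ci_filter_boundary_accuracy": float(np.mean(correct)),
        "mixture_high_component_retained": float(keep[200:].mean()),
        "mixture_low_component_retained": float(keep[:200].mean()),
    }


# ---------------------------------------------------------------------------
# Latent-axis differential expression


def check_dv_recovery(seed: int = 0) -> dict:
    """Recall/FDR at z >= 3 and AUROC for planted tissue-specific genes."""
    cfg = AnalysisConfig()
    _, gene_body, truth = simulate_tissue_bulk(
        n_genes=2060, n_planted_per_condition=20, effect_log2fc=3.0,
        dispersion=0.05, seed=_spawn(seed, 4),
    )
    filtered = filter_low_expression(gene_body, cfg.min_gene_body_reads)
    res = LatentAxes(filtered).fit()
    z = res.z_matrix()
    labels = res.classify(cfg.z_cutoff)
    planted = truth.genes.set_index("gene_id").loc[z.index, "condition"]
    is_planted = planted != "none"
    recall = float(
        np.mean([labels[g] == c for g, c in planted[is_planted].items()])
    )
    called = labels[labels != "none"]
    fdr = (
        float(np.mean([planted[g] != lab for g, lab in called.items()]))
        if len(called)
        else 0.0
    )
    _, auroc = roc_curve(z.max(axis=1).values, is_planted.values)
    return {"dv_recall": recall, "dv_fdr": fdr, "dv_auroc": float(auroc)}


# ---------------------------------------------------------------------------
# Pausing


def check_pausing(seed: int = 0) -> dict:
    """PI exactness on a fixture and tissue-invariance of pausing on
    synthetic bulk data with a shared pause enrichment."""
    fixture = [(50.0, 150.0, 0.25), (5.0, 0.0, 1.0), (0.0, 7.0, 0.0), (30.0, 30.0, 0.5)]
    pi_err = max(abs(pausing_index(pc, gbc) - expected) for pc, gbc, expected in fixture)

    promoter, gene_body, truth = simulate_tissue_bulk(
        effect_log2fc=3.0, pause_enrichment=2.0, seed=_spawn(seed, 5)
    )
    filtered = filter_low_expression(gene_body, 10)
    promoter = promoter.subset_entities(filtered.entity_ids)
    metrics = compute_pause_metrics(promoter, filtered)
    by_cond = mean_pause_index_by_condition(metrics)
    planted = truth.genes[truth.genes["condition"] != "none"]["gene_id"]
    med = (
        by_cond[by_cond["gene_id"].isin(planted)]
        .groupby("condition")["pausing_index"]
        .median()
    )
    spread = float(med.max() - med.min())

    norm = gene_body.counts / pd.Series(truth.size_factors)
    fcs = []
    for _, row in truth.genes[truth.genes["condition"] != "none"].iterrows():
        own = norm.loc[row["gene_id"], gene_body.samples_of(row["condition"])].mean()
        rest = [
            s for s in gene_body.sample_ids
            if gene_body.condition_of[s] != row["condition"]
        ]
        fcs.append(np.log2(own / norm.loc[row["gene_id"], rest].mean()))
    return {
        "pause_pi_fixture_max_error": float(pi_err),
        "pause_pi_median_spread": spread,
        "genebody_log2fc_median": float(np.median(fcs)),
    }


# ---------------------------------------------------------------------------
# Enhancer pipeline


def _run_enhancer_pipeline(coupling_r: float, noiseless: bool, seed: int):
    toy = simulate_toy_genome(coupling_r=coupling_r, noiseless=noiseless, seed=seed)
    regions = exclude_tss_regions(toy.all_regions, toy.genes)
    tables = {
        a: t.subset_entities([r.name for r in regions])
        for a, t in toy.region_counts.items()
    }
    scores = score_regions(tables)
    te = toy.truth.enhancers
    recall = float(
        np.mean(
            [row["name"] in scores.candidate_regions(row["condition"]) for _, row in te.iterrows()]
        )
    )
    gene_z = LatentAxes(toy.gene_counts).fit().z_matrix()
    dv = dict(zip(toy.truth.genes["gene_id"], toy.truth.genes["condition"]))
    pairs = assign_enhancers(
        {c: scores.candidate_regions(c) for c in toy.gene_counts.conditions},
        regions, dv, toy.genes, toy.tads,
    )
    planted = set(zip(te["name"], te["gene_id"]))
    if pairs:
        assignment_acc = float(
            np.mean([(a.enhancer.name, a.gene_id) in planted for a in pairs])
        )
    else:
        assignment_acc = 0.0
    r2s = [
        predict_expression(pairs, scores.combined, gene_z, c)[2]
        for c in toy.gene_counts.conditions
    ]
    return toy, pairs, recall, assignment_acc, float(np.mean(r2s))


def check_enhancer_pipeline(seed: int = 0, n_noisy_replicates: int = 5) -> dict:
    """Recovery/assignment/R^2 in the noiseless limit and at coupling 0.9,
    plus exactness of the accessibility classes and the proximal split."""
    _, _, recall1, acc1, r2_1 = _run_enhancer_pipeline(1.0, True, _spawn(seed, 6))

    recalls, r2s = [], []
    for rep in range(n_noisy_replicates):
        _, _, rec, _, r2 = _run_enhancer_pipeline(0.9, False, _spawn(seed, 7 + rep))
        recalls.append(rec)
        r2s.append(r2)

    fc_cases = [(0.5, "gained"), (-0.5, "lost"), (0.49, "stable"), (-0.49, "stable")]
    access_ok = float(
        np.mean([accessibility_class(fc) == cls for fc, cls in fc_cases])
    )

    toy, pairs, _, _, _ = _run_enhancer_pipeline(0.9, False, _spawn(seed, 20))
    split_ok = [
        (a.distance_to_tss <= 700) == (a.proximity == "proximal") for a in pairs
    ]
    return {
        "enhancer_recall_noiseless": recall1,
        "enhancer_assignment_accuracy_noiseless": acc1,
        "enhancer_r2_noiseless": r2_1,
        "enhancer_recall_coupled": float(np.mean(recalls)),
        "enhancer_r2_coupled": float(np.mean(r2s)),
        "accessibility_class_accuracy": access_ok,
        "proximal_split_accuracy": float(np.mean(split_ok)),
    }


# ---------------------------------------------------------------------------
# Integration contrast


def check_integration_contrast(seed: int = 0, n_seeds: int = 40) -> dict:
    """Fraction of seeds in which the chromatin-frequency R^2 exceeds the
    chromatin-size R^2 when only frequency is coupled (r = 0.75)."""
    wins = 0
    for i in range(n_seeds):
        rec = simulate_integration_records(
            n_genes=40, r_frequency=0.75, r_size=0.0, seed=_spawn(seed, 30 + i)
        )
        mat = correlation_matrix(
            rec, ["delta_chromatin"], ["delta_k_on", "delta_burst_size"]
        ).set_index("kinetic")
        wins += int(
            mat.loc["delta_k_on", "r2"] > mat.loc["delta_burst_size", "r2"]
        )
    return {"frequency_r2_wins_fraction": wins / n_seeds}


# ---------------------------------------------------------------------------
# CLI determinism


def check_cli_determinism(seed: int = 0, workdir=None) -> dict:
    """Every CLI stage re-run with the same seed is byte-identical."""
    import filecmp
    import tempfile
    from pathlib import Path

    from click.testing import CliRunner

    from .cli import main as cli_main
    from .simulate import simulate_integration_records

    def run(args):
        res = CliRunner().invoke(cli_main, args)
        if res.exit_code != 0:
            raise RuntimeError(f"CLI failed: {args}\n{res.output}")

    def identical(d1: Path, d2: Path) -> bool:
        names = sorted(p.name for p in d1.iterdir())
        if names != sorted(p.name for p in d2.iterdir()):
            return False
        return all(filecmp.cmp(d1 / n, d2 / n, shallow=False) for n in names)

    results = {}
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        sim1, sim2 = tmp / "sim1", tmp / "sim2"
        run(["simulate", "--preset", "all", "--seed", str(seed), "--out-dir", str(sim1)])
        run(["simulate", "--preset", "all", "--seed", str(seed), "--out-dir", str(sim2)])
        results["simulate"] = identical(sim1, sim2)

        stages = {
            "pause-index": [
                "pause-index",
                "--promoter", str(sim1 / "promoter_counts.tsv"),
                "--genebody", str(sim1 / "genebody_counts.tsv"),
                "--condition-map", str(sim1 / "condition_map.tsv"),
            ],
            "dv-genes": [
                "dv-genes",
                "--genebody", str(sim1 / "genebody_counts.tsv"),
                "--condition-map", str(sim1 / "condition_map.tsv"),
            ],
            "bursts": [
                "bursts",
                "--matrix", str(sim1 / "matrix.mtx"),
                "--genes", str(sim1 / "genes.txt"),
                "--cells", str(sim1 / "cells.txt"),
                "--clusters", str(sim1 / "clusters.tsv"),
                "--max-genes", "2",
            ],
        }
        rec = simulate_integration_records(n_genes=40, seed=seed)
        rec_path = tmp / "records.tsv"
        rec.to_csv(rec_path, sep="\t", index=False)
        stages["integrate"] = ["integrate", "--records", str(rec_path)]

        dv_out = tmp / "dv_toy"
        run([
            "dv-genes",
            "--genebody", str(sim1 / "toy_genebody_counts.tsv"),
            "--condition-map", str(sim1 / "toy_condition_map.tsv"),
            "--out-dir", str(dv_out), "--seed", str(seed),
        ])
        stages["enhancers"] = [
            "enhancers",
            "--atac", str(sim1 / "atac_region_counts.tsv"),
            "--cbp", str(sim1 / "cbp_region_counts.tsv"),
            "--k27ac", str(sim1 / "h3k27ac_region_counts.tsv"),
            "--condition-map", str(sim1 / "toy_condition_map.tsv"),
            "--gene-models", str(sim1 / "gene_models.tsv"),
            "--regions", str(sim1 / "regions.bed"),
            "--tads", str(sim1 / "tads.bed"),
            "--dv-labels", str(dv_out / "dv_labels.tsv"),
        ]
        for name, args in stages.items():
            o1, o2 = tmp / f"{name}_1", tmp / f"{name}_2"
            run(args + ["--out-dir", str(o1), "--seed", str(seed)])
            run(args + ["--out-dir", str(o2), "--seed", str(seed)])
            results[name] = identical(o1, o2)
    return {"cli_stages_byte_identical_fraction": float(np.mean(list(results.values())))}
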