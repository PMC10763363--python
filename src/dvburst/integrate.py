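"""Cross-tissue integration of kinetic and chromatin-state differences.

For each gene with a significant kinetic change, the change in burst
frequency and burst size between the active and inactive tissues is
correlated against the change in chromatin state at its enhancers and
promoter, and kinetics are compared between genes regulated by proximal
versus distal enhancers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def delta_scores(scores: pd.DataFrame, active: str) -> pd.Series:
    """z_active - mean(z_inactive) per feature.

    ``scores`` is features x conditions.
    """
    if scores.shape[1] < 2:
        raise ValueError("need >= 2 conditions")
    if active not in scores.columns:
        raise ValueError(f"unknown active condition {active!r}")
    inactive = [c for c in scores.columns if c != active]
    return scores[active] - scores[inactive].mean(axis=1)


def build_integration_records(
    comparisons: pd.DataFrame,
    enhancer_delta: pd.DataFrame,
    assignments=None,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """One record per gene: kinetic fold changes plus chromatin deltas.

    ``comparisons`` carries per-gene log2fc_k_on / log2fc_burst_size /
    kinetic_class / active_cluster; ``enhancer_delta`` maps enhancer region
    -> gene_id and delta columns.  Genes with several enhancers aggregate
    enhancer-layer deltas by mean (``aggregate='pairs'`` keeps one row per
    enhancer-gene pair instead).
    """
    if aggregate not in ("mean", "pairs"):
        raise ValueError("aggregate must be 'mean' or 'pairs'")
    delta_cols = [c for c in enhancer_delta.columns if c.startswith("delta_")]
    if aggregate == "mean":
        enh = enhancer_delta.groupby("gene_id", sort=False)[delta_cols].mean()
        merged = comparisons.merge(enh, left_on="gene_id", right_index=True, how="inner")
    else:
        merged = comparisons.merge(enhancer_delta, on="gene_id", how="inner")
    if assignments is not None:
        prox = (
            pd.DataFrame(
                {
                    "gene_id": [a.gene_id for a in assignments],
                    "proximal": [a.proximity == "proximal" for a in assignments],
                }
            )
            .groupby("gene_id", sort=False)["proximal"]
            .any()
        )
        merged = merged.merge(prox, left_on="gene_id", right_index=True, how="left")
        merged["proximity"] = np.where(
            merged["proximal"].fillna(False), "proximal", "distal"
        )
        merged = merged.drop(columns=["proximal"])
    return merged


def correlate_layers(
    records: pd.DataFrame, x_layer: str, y_kinetic: str
) -> tuple[float, float, float]:
    """(Pearson r, R^2, two-sided p) between a chromatin layer and a kinetic
    difference across genes."""
    sub = records[[x_layer, y_kinetic]].dropna()
    if len(sub) < 5:
        raise ValueError(f"need >= 5 finite records, got {len(sub)}")
    x, y = sub[x_layer].values, sub[y_kinetic].values
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance variable")
    fit = stats.linregress(x, y)
    return float(fit.rvalue), float(fit.rvalue**2), float(fit.pvalue)


def correlation_matrix(
    records: pd.DataFrame,
    layers: list[str],
    kinetics: list[str],
    bh_correct: bool = False,
) -> pd.DataFrame:
    """R^2 / p for each layer x kinetic cell (the Fig-5g-style heatmap)."""
    rows = []
    for layer in layers:
        for kin in kinetics:
            r, r2, p = correlate_layers(records, layer, kin)
            rows.append({"layer": layer, "kinetic": kin, "r": r, "r2": r2, "p": p})
    out = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def proximity_kinetics_test(
    records: pd.DataFrame,
    kinetic_cols: tuple[str, str] = ("delta_burst_size", "delta_k_on"),
    proximity_col: str = "proximity",
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of kinetic fold changes, proximal vs distal.

    Exact null for group sizes <= 12, normal approximation with tie
    correction otherwise.
    """
    prox = records[records[proximity_col] == "proximal"]
    dist = records[records[proximity_col] == "distal"]
    if len(prox) < 3 or len(dist) < 3:
        raise ValueError(
            f"need >= 3 genes per proximity group (proximal={len(prox)}, distal={len(dist)})"
        )
    rows = []
    for col in kinetic_cols:
        a, b = prox[col].dropna().values, dist[col].dropna().values
        # the exact null assumes no ties; fall back to the tie-corrected
        # normal approximation when ties are present or groups are large
        has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if max(len(a), len(b)) <= 12 and not has_ties else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append(
            {
                "kinetic": col,
                "statistic": float(res.statistic),
                "p": float(res.pvalue),
                "n_proximal": len(a),
                "n_distal": len(b),
                "method": method,
            }
        )
    return pd.DataFrame(rows)
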